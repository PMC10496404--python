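"""Keyed substructure fingerprints: SMARTS dictionaries and a fast matcher.

A keyed fingerprint assigns one bit per SMARTS pattern in a fixed dictionary;
the bit is set iff the molecule contains the substructure (presence only,
multiplicity ignored). This module provides

* :class:`SmartsKeyMatcher` — compiles a pattern list once and evaluates all
  bits for a molecule, using an element/ring-count prescreen so that only a
  small fraction of patterns reach the (comparatively expensive) subgraph
  matcher;
* deterministic generators for two **synthetic stand-in dictionaries**: a
  4,860-pattern fragment dictionary with the cardinality of the published
  Klekota–Roth set, and an 881-key list backing the PubChem-width fingerprint.
  Both are built from curated functional groups plus combinatorial ring and
  chain families; they reproduce the size and the bit semantics of the
  originals, not their exact pattern identities (which are not redistributable
  here).

All generated patterns use concrete atoms only (no wildcards), which is what
makes the count-based prescreen an exact necessary condition.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from rdkit import Chem

#: Klekota–Roth dictionary cardinality.
KRFP_SIZE = 4860
#: PubChem fingerprint width.
PUBCHEM_SIZE = 881

_PRESCREEN_ELEMENTS = (6, 7, 8, 16, 15, 9, 17, 35, 53)  # C N O S P F Cl Br I


class DictionaryIntegrityError(RuntimeError):
    """A bundled SMARTS dictionary failed validation at load time."""


def _profile(mol: Chem.Mol, is_query: bool = False) -> np.ndarray:
    """Count vector used for prescreening: per-element, aromatic and ring atoms.

    Ring-atom counting is binary membership, which is identical under SSSR
    (sanitized molecules) and fast ring perception (SMARTS queries).
    """
    counts = np.zeros(len(_PRESCREEN_ELEMENTS) + 2, dtype=np.int32)
    if is_query:
        Chem.FastFindRings(mol)  # queries carry no ring perception
    ring_info = mol.GetRingInfo()
    for atom in mol.GetAtoms():
        z = atom.GetAtomicNum()
        if z in _PRESCREEN_ELEMENTS:
            counts[_PRESCREEN_ELEMENTS.index(z)] += 1
        if atom.GetIsAromatic():
            counts[-2] += 1
        if ring_info.NumAtomRings(atom.GetIdx()):
            counts[-1] += 1
    return counts


class SmartsKeyMatcher:
    """Compiled SMARTS dictionary evaluating presence bits for molecules.

    Patterns containing only concrete atoms admit an exact necessary
    condition: every element (and aromatic/ring atom) count required by the
    query must be available in the target. The prescreen evaluates that
    condition for all patterns at once with one NumPy comparison, and only
    surviving candidates run a full substructure match.
    """

    def __init__(self, patterns: list[str]):
        self.patterns = list(patterns)
        self._queries = []
        profiles = []
        for smarts in self.patterns:
            q = Chem.MolFromSmarts(smarts)
            if q is None:
                raise DictionaryIntegrityError(f"invalid SMARTS in dictionary: {smarts!r}")
            self._queries.append(q)
            profiles.append(_profile(q, is_query=True))
        self._requirements = np.asarray(profiles, dtype=np.int32)

    def __len__(self) -> int:
        return len(self.patterns)

    def match(self, mol: Chem.Mol) -> np.ndarray:
        """Return the uint8 presence vector (one bit per dictionary pattern)."""
        target = _profile(mol)
        candidates = np.flatnonzero((self._requirements <= target).all(axis=1))
        bits = np.zeros(len(self.patterns), dtype=np.uint8)
        for i in candidates:
            if mol.HasSubstructMatch(self._queries[i]):
                bits[i] = 1
        return bits


# ---------------------------------------------------------------------------
# Pattern families (deterministic generators)
# ---------------------------------------------------------------------------

#: Curated functional-group and heterocycle patterns. The synthetic-data
#: grammar's plantable fragments all appear here so that alert mining can
#: rediscover them.
CURATED_GROUPS: tuple[str, ...] = (
    # carbonyl chemistry
    "C=O", "C(=O)O", "C(=O)OC", "C(=O)N", "NC(=O)C", "NC=O", "C(=O)Cl",
    "OC(=O)C", "C(=O)c1ccccc1", "NC(=O)c1ccccc1", "O=C(N)N", "N=C(N)N",
    "CC(=O)C", "O=C1CCCCC1", "O=C1CCCC1",
    # sulfur groups
    "S(=O)(=O)N", "S(=O)(=O)O", "S(=O)(=O)C", "S(=O)C", "SC", "S", "CS(C)=O",
    "NS(=O)(=O)c1ccccc1", "S(=O)(=O)Nc1ccccc1",
    # nitrogen groups
    "[N+](=O)[O-]", "C#N", "N(C)C", "NC", "N", "N=N", "NO", "N=O",
    "NN", "C=N", "N(CC)CC", "[NH2]c1ccccc1", "Cn1ccnc1",
    # phosphorus
    "P(=O)(O)O", "OP(=O)(O)O", "P",
    # halogens / haloalkyl
    "C(F)(F)F", "ClC(Cl)Cl", "FC(F)F", "Clc1ccccc1", "Fc1ccccc1",
    "Brc1ccccc1", "Ic1ccccc1",
    # oxygen groups
    "O", "OC", "OCC", "COC", "Oc1ccccc1", "COc1ccccc1", "OCO", "C=C", "C#C",
    "OCCO", "C1CO1",
    # carbo- and heterocycles
    "c1ccccc1", "c1ccncc1", "c1ccnnc1", "c1cncnc1", "c1cnccn1",
    "c1ccoc1", "c1ccsc1", "c1cc[nH]c1", "c1cncn1", "c1cscn1", "c1cocn1",
    "c1cnnn1", "c1cnn(C)c1", "c1ccc2ccccc2c1", "c1ccc2[nH]ccc2c1",
    "c1ccc2ncccc2c1", "c1ccc2occc2c1", "c1ccc2sccc2c1",
    "c1ccc(-c2ccccc2)cc1", "C1CCCCC1", "C1CCCC1", "C1CCC1", "C1CC1",
    "C1CCNCC1", "C1CCOCC1", "C1CCSCC1", "C1CNCCN1", "C1COCCN1", "C1CCNC1",
    "C1CCOC1", "N1CCNCC1",
    # fused / drug-like motifs
    "O=c1cc[nH]c2ccccc12", "O=c1ccnc2ccccc12", "Nc1ncnc2ncnc12",
    "c1ccc2c(c1)Nc1ccccc1S2", "c1ccc2c(c1)Nc1ccccc1N2", "c1ccc2c(c1)Oc1ccccc1O2",
    "O=C1CCCN1", "O=C1CCCCN1", "O=C1NCCN1", "O=C1NC(=O)NC(=O)C1",
    "O=C1NC(=O)c2ccccc21", "O=S1(=O)NCCN1",
    # chains with terminal groups
    "CCCCCC", "CCCCCCCC", "CCCCCCCCCC", "OCCCC", "NCCCC", "CCCCCC(=O)O",
    "C=CC=C", "CC(C)C", "CC(C)(C)C", "CC(C)O", "CC(C)N",
)

_RING_SUBSTITUENTS: tuple[str, ...] = (
    "C", "N", "O", "S", "F", "Cl", "Br", "I",
    "C#N", "C(=O)O", "C(=O)N", "[N+](=O)[O-]", "S(=O)(=O)N", "C(F)(F)F",
    "OC", "N(C)C", "CC", "CCC", "CCCC", "CCO", "OC(=O)C", "NC(=O)C",
    "S(=O)(=O)C", "OCC", "NCC", "CCl", "C=O", "C(=O)OC", "NC=O", "C=C",
)

_MONO_RING_TEMPLATES: tuple[str, ...] = (
    "c1ccc({0})cc1",          # benzene
    "c1ccnc({0})c1",          # pyridine
    "c1cc({0})oc1",           # furan
    "c1cc({0})sc1",           # thiophene
    "c1cc({0})[nH]c1",        # pyrrole
    "C1CCC({0})CC1",          # cyclohexane
    "C1CCN({0})CC1",          # N-subst. piperidine
    "c1ccc2cc({0})ccc2c1",    # naphthalene
)

_DI_RING_TEMPLATES: tuple[str, ...] = (
    "c1cc({0})ccc1{1}",       # 1,4-disubstituted benzene
    "c1c({0})cccc1{1}",       # 1,2-disubstituted benzene
    "c1cc({0})cc({1})c1",     # 1,3-disubstituted benzene
    "c1nc({0})ccc1{1}",       # disubstituted pyridine
    "C1CC({0})CCC1{1}",       # disubstituted cyclohexane
)


def _ring_patterns():
    for tpl in _MONO_RING_TEMPLATES:
        for sub in _RING_SUBSTITUENTS:
            yield tpl.format(sub)
    for tpl in _DI_RING_TEMPLATES:
        for a, b in itertools.product(_RING_SUBSTITUENTS, repeat=2):
            yield tpl.format(a, b)


def _chain_patterns():
    for length in (2, 3, 4, 5):
        for combo in itertools.product("CNOS", repeat=length):
            yield "".join(combo)
    for combo in itertools.product("CNO", repeat=6):
        yield "".join(combo)


def _generate(master_size: int, families) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for fam in families:
        for smarts in fam:
            if smarts in seen:
                continue
            seen.add(smarts)
            out.append(smarts)
            if len(out) == master_size:
                return out
    raise DictionaryIntegrityError(
        f"pattern families exhausted at {len(out)} < {master_size}"
    )


@lru_cache(maxsize=1)
def krfp_patterns() -> tuple[str, ...]:
    """The bundled 4,860-pattern fragment dictionary (synthetic stand-in).

    Deterministically generated: curated functional groups first (so that
    pharmacologically meaningful motifs occupy stable indices), then
    substituted-ring and heteroatom-chain families, truncated to exactly
    :data:`KRFP_SIZE` unique patterns.
    """
    return tuple(_generate(KRFP_SIZE, (CURATED_GROUPS, _ring_patterns(), _chain_patterns())))


@lru_cache(maxsize=1)
def pubchem_smarts_keys(n: int) -> tuple[str, ...]:
    """SMARTS-key block of the PubChem-width fingerprint (synthetic stand-in)."""
    return tuple(_generate(n, (CURATED_GROUPS, _chain_patterns(), _ring_patterns())))


@lru_cache(maxsize=4)
def get_matcher(dictionary: str = "krfp") -> SmartsKeyMatcher:
    """Compiled matcher for a bundled dictionary (cached per process)."""
    if dictionary == "krfp":
        return SmartsKeyMatcher(list(krfp_patterns()))
    raise KeyError(f"unknown dictionary {dictionary!r}")
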