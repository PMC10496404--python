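"""Molecular fingerprints: MACCS, PubChem-width keyed, and folded ECFP.

Six fingerprint kinds are exposed, matching the characterization grid used by
the classifier pipeline:

====== ===== =====================================================
kind   width definition
====== ===== =====================================================
MACCS    166 public MACCS keys (toolkit implementation, key 0 dropped)
PubChem  881 keyed fingerprint of PubChem width — element/ring count
             bits plus SMARTS keys (synthetic stand-in dictionary)
ECFP4-1 1024 circular fingerprint, radius 2, folded to 1024 bits
ECFP4-2 2048 circular fingerprint, radius 2, folded to 2048 bits
ECFP6-1 1024 circular fingerprint, radius 3, folded to 1024 bits
ECFP6-2 2048 circular fingerprint, radius 3, folded to 2048 bits
====== ===== =====================================================
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

from .smartskeys import PUBCHEM_SIZE, SmartsKeyMatcher, pubchem_smarts_keys

FINGERPRINT_KINDS = ("MACCS", "PubChem", "ECFP4-1", "ECFP4-2", "ECFP6-1", "ECFP6-2")

FINGERPRINT_WIDTHS = {
    "MACCS": 166,
    "PubChem": PUBCHEM_SIZE,
    "ECFP4-1": 1024,
    "ECFP4-2": 2048,
    "ECFP6-1": 1024,
    "ECFP6-2": 2048,
}

_ECFP = {  # kind -> (radius, nbits)
    "ECFP4-1": (2, 1024),
    "ECFP4-2": (2, 2048),
    "ECFP6-1": (3, 1024),
    "ECFP6-2": (3, 2048),
}


class FingerprintError(ValueError):
    pass


# --- PubChem-width surrogate -------------------------------------------------

# (symbol, threshold) count bits; thresholds follow the usual doubling ladder.
_COUNT_BITS: tuple[tuple[str, int], ...] = tuple(
    (sym, t)
    for sym, thresholds in (
        ("C", (1, 2, 4, 8, 16, 24, 32)),
        ("N", (1, 2, 4, 8)),
        ("O", (1, 2, 4, 8, 12, 16)),
        ("S", (1, 2, 4)),
        ("P", (1, 2)),
        ("F", (1, 2, 4, 8)),
        ("Cl", (1, 2, 4)),
        ("Br", (1, 2)),
        ("I", (1,)),
    )
    for t in thresholds
)
_RING_SIZE_BITS = tuple((size, t) for size in (3, 4, 5, 6, 7, 8) for t in (1, 2))
_AROMATIC_RING_BITS = (1, 2, 3, 4, 5)
_HEAVY_ATOM_BITS = (5, 10, 15, 20, 25, 30, 40)
_N_STRUCT_BITS = (
    len(_COUNT_BITS) + len(_RING_SIZE_BITS) + len(_AROMATIC_RING_BITS) + len(_HEAVY_ATOM_BITS)
)


@lru_cache(maxsize=1)
def _pubchem_matcher() -> SmartsKeyMatcher:
    return SmartsKeyMatcher(list(pubchem_smarts_keys(PUBCHEM_SIZE - _N_STRUCT_BITS)))


def _pubchem_like(mol: Chem.Mol) -> np.ndarray:
    bits = np.zeros(_N_STRUCT_BITS, dtype=np.uint8)
    symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    pos = 0
    for sym, t in _COUNT_BITS:
        bits[pos] = symbols.count(sym) >= t
        pos += 1
    ring_sizes = [len(r) for r in mol.GetRingInfo().AtomRings()]
    for size, t in _RING_SIZE_BITS:
        bits[pos] = ring_sizes.count(size) >= t
        pos += 1
    n_arom = sum(
        1
        for ring in mol.GetRingInfo().AtomRings()
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring)
    )
    for t in _AROMATIC_RING_BITS:
        bits[pos] = n_arom >= t
        pos += 1
    for t in _HEAVY_ATOM_BITS:
        bits[pos] = mol.GetNumHeavyAtoms() >= t
        pos += 1
    return np.concatenate([bits, _pubchem_matcher().match(mol)])


# --- public API --------------------------------------------------------------

def compute_fingerprint(mol: Chem.Mol, kind: str) -> np.ndarray:
    """Fixed-width binary vector (uint8) for one molecule."""
    if kind == "MACCS":
        fp = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, bit 0 always unset
        arr = np.zeros(167, dtype=np.uint8)
        for b in fp.GetOnBits():
            arr[b] = 1
        return arr[1:]
    if kind == "PubChem":
        return _pubchem_like(mol)
    if kind in _ECFP:
        radius, nbits = _ECFP[kind]
        gen = _morgan_generator(radius, nbits)
        arr = np.zeros(nbits, dtype=np.uint8)
        for b in gen.GetFingerprint(mol).GetOnBits():
            arr[b] = 1
        return arr
    raise FingerprintError(f"unknown fingerprint kind {kind!r}")


@lru_cache(maxsize=8)
def _morgan_generator(radius: int, nbits: int):
    return rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)


def fingerprint_names(kind: str) -> list[str]:
    return [f"{kind}:{i}" for i in range(FINGERPRINT_WIDTHS[kind])]
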