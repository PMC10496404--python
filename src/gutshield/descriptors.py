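"""Molecular descriptor panels: the 13-descriptor physchem panel and the
full toolkit 2-D panel (RDMD).

The 13-descriptor panel (13MD) covers lipophilicity, solubility, size,
surface area, hydrogen bonding and ring/flexibility counts. The original
panel was produced by commercial software; here every member is an open
surrogate, so numerical fidelity to commercially computed values is not
claimed:

* ``AlogP`` — Crippen atomic-contribution logP
* ``logD`` — distribution coefficient; not computable without pKa, so a
  user-supplied column is accepted and otherwise AlogP is substituted with a
  warning
* ``S`` — ESOL-style aqueous solubility estimate (log mol/L)
* ``MW`` — molecular weight (g/mol)
* ``MSA`` — Labute approximate molecular surface area (Å²)
* ``PSA`` — topological polar surface area (Å²)
* ``MFPSA`` — fractional polar surface area, PSA/MSA (dimensionless)
* ``n-HBA`` / ``n-HBD`` — hydrogen-bond acceptor / donor counts
* ``n-R`` / ``n-AR`` — ring / aromatic-ring counts
* ``NplusO`` — heavy-atom nitrogen + oxygen count
* ``n-RB`` — rotatable-bond count
"""

from __future__ import annotations

import logging
import math
from typing import Optional

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

log = logging.getLogger(__name__)

DESCRIPTOR_SETS = ("13MD", "RDMD")

PANEL_13MD = (
    "AlogP", "logD", "S", "MW", "MSA", "PSA", "MFPSA",
    "n-HBA", "n-HBD", "n-R", "n-AR", "NplusO", "n-RB",
)

_warned_logd = False


def _esol_logs(mol: Chem.Mol, logp: float, mw: float) -> float:
    """ESOL aqueous-solubility estimate (Delaney-style linear model)."""
    rb = rdMolDescriptors.CalcNumRotatableBonds(mol)
    heavy = mol.GetNumHeavyAtoms()
    n_arom = sum(1 for a in mol.GetAtoms() if a.GetIsAromatic())
    ap = n_arom / heavy if heavy else 0.0
    return 0.16 - 0.63 * logp - 0.0062 * mw + 0.066 * rb - 0.74 * ap


def compute_13md(mol: Chem.Mol, logd: Optional[float] = None) -> dict[str, float]:
    """The 13-descriptor physchem panel for one molecule (ordered dict)."""
    global _warned_logd
    logp = Crippen.MolLogP(mol)
    mw = Descriptors.MolWt(mol)
    msa = rdMolDescriptors.CalcLabuteASA(mol)
    psa = rdMolDescriptors.CalcTPSA(mol)
    if logd is None:
        if not _warned_logd:
            log.warning("no logD supplied; substituting AlogP for logD")
            _warned_logd = True
        logd = logp
    return {
        "AlogP": logp,
        "logD": logd,
        "S": _esol_logs(mol, logp, mw),
        "MW": mw,
        "MSA": msa,
        "PSA": psa,
        "MFPSA": psa / msa if msa > 0 else 0.0,
        "n-HBA": float(rdMolDescriptors.CalcNumHBA(mol)),
        "n-HBD": float(rdMolDescriptors.CalcNumHBD(mol)),
        "n-R": float(rdMolDescriptors.CalcNumRings(mol)),
        "n-AR": float(rdMolDescriptors.CalcNumAromaticRings(mol)),
        "NplusO": float(sum(1 for a in mol.GetAtoms() if a.GetSymbol() in ("N", "O"))),
        "n-RB": float(rdMolDescriptors.CalcNumRotatableBonds(mol)),
    }


def rdmd_names() -> list[str]:
    """Names of the full toolkit 2-D descriptor panel, in canonical order."""
    return [name for name, _ in Descriptors.descList]


def compute_rdmd(mol: Chem.Mol) -> dict[str, float]:
    """Full 2-D descriptor panel; failures and non-finite values become NaN.

    NaNs are imputed downstream with training-set medians so that dataset
    sizes stay fixed.
    """
    out: dict[str, float] = {}
    for name, fn in Descriptors.descList:
        try:
            v = float(fn(mol))
        except Exception:  # individual descriptor failures must not kill a row
            v = math.nan
        if not math.isfinite(v):
            v = math.nan
        out[name] = v
    if any(math.isnan(v) for v in out.values()):
        log.debug("non-finite descriptor values for %s", Chem.MolToSmiles(mol))
    return out


def compute_descriptors(mol: Chem.Mol, set_id: str, logd: Optional[float] = None) -> dict[str, float]:
    """Named numeric descriptor vector for one molecule."""
    if set_id == "13MD":
        return compute_13md(mol, logd=logd)
    if set_id == "RDMD":
        return compute_rdmd(mol)
    raise KeyError(f"unknown descriptor set {set_id!r}")


def descriptor_names(set_id: str) -> list[str]:
    if set_id == "13MD":
        return list(PANEL_13MD)
    if set_id == "RDMD":
        return rdmd_names()
    raise KeyError(f"unknown descriptor set {set_id!r}")


def descriptor_matrix(mols: list[Chem.Mol], set_id: str) -> np.ndarray:
    """n × p matrix over the panel, NaN where a descriptor failed."""
    names = descriptor_names(set_id)
    rows = np.empty((len(mols), len(names)), dtype=np.float64)
    for i, mol in enumerate(mols):
        vals = compute_descriptors(mol, set_id)
        rows[i] = [vals[n] for n in names]
    return rows
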