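"""Synthetic labeled SMILES datasets with planted structure–activity signal.

Molecules are assembled from a curated scaffold/decoration grammar (drug-like
aromatic and aliphatic cores, common substituents, variable-length alkyl
chains), which guarantees chemically valid, single-fragment, whitelist-only
structures. Activity labels are drawn from a logistic model whose linear
predictor combines

* planted alert fragments — each multiplies the odds of being anti-commensal
  by a configured factor when present; and
* optional descriptor effects — population-standardized physchem descriptor
  values times a coefficient (e.g. lipophilicity driving activity).

The intercept is calibrated by bisection so the expected positive fraction
matches ``pos_fraction`` (default 391/1181 ≈ 0.331, the class balance of the
screening dataset the pipeline emulates), then labels are flipped with
probability ``label_noise``. Everything is bit-reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem

from .dataio import MoleculeDataset, MoleculeRecord
from .descriptors import compute_13md

#: Class balance of the emulated screening data: 391 of 1,181 compounds
#: inhibit at least one gut bacterial strain.
DEFAULT_POS_FRACTION = 391 / 1181


class SynthConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedAlert:
    """A fragment planted into molecules with an odds multiplier on activity."""

    fragment: str  # substituent SMILES inserted by the grammar
    smarts: str    # pattern that detects it (present in the fragment dictionary)
    odds: float = 8.0
    insert_probability: float = 0.5

    def __post_init__(self):
        if self.odds <= 0:
            raise SynthConfigError("odds multiplier must be positive")
        if Chem.MolFromSmarts(self.smarts) is None:
            raise SynthConfigError(f"invalid SMARTS {self.smarts!r}")


DEFAULT_ALERTS = (PlantedAlert(fragment="S(=O)(=O)N", smarts="S(=O)(=O)N", odds=8.0),)


@dataclass(frozen=True)
class SynthConfig:
    n_molecules: int = 1181
    pos_fraction: float = DEFAULT_POS_FRACTION
    alerts: tuple[PlantedAlert, ...] = DEFAULT_ALERTS
    descriptor_effect: tuple[tuple[str, float], ...] = ()
    label_noise: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.pos_fraction < 1:
            raise SynthConfigError("pos_fraction must be in (0, 1)")
        if not 0 <= self.label_noise < 0.5:
            raise SynthConfigError("label_noise must be in [0, 0.5)")
        if self.n_molecules < 1:
            raise SynthConfigError("n_molecules must be positive")


@dataclass
class SynthTruth:
    """Ground truth of a generated dataset, for recovery tests."""

    eta: np.ndarray            # linear predictor per molecule (incl. intercept)
    intercept: float
    alert_smarts: list[str]
    alert_presence: np.ndarray  # n × n_alerts
    n_pos: int
    n_neg: int


# --- grammar -----------------------------------------------------------------

_ONE_SLOT = (
    "c1ccc({0})cc1",
    "c1ccnc({0})c1",
    "c1cc({0})oc1",
    "c1cc({0})sc1",
    "C1CCC({0})CC1",
    "C1CCN({0})CC1",
)
_TWO_SLOT = (
    "c1cc({0})ccc1{1}",
    "c1cc({0})cc({1})c1",
    "c1c({0})cccc1{1}",
    "c1nc({0})ccc1{1}",
    "C1CC({0})CCC1{1}",
    "c1cc({0})sc1{1}",
)

#: Substituent vocabulary. Alkyl chains of graded length give the population a
#: wide, nearly continuous spread of size/lipophilicity descriptors.
_DECORATIONS = tuple(
    ["C" * k for k in range(1, 11)]
    + [
        "O", "OC", "OCC", "N", "NC", "N(C)C", "Cl", "F", "C#N",
        "C(=O)O", "C(=O)N", "OC(=O)C", "C(F)(F)F", "c1ccccc1", "C=C",
        "CCO", "CCN", "C(=O)OC", "CC=C",
    ]
)


def _assemble(rng: np.random.Generator, alerts: Sequence[PlantedAlert]) -> str:
    """Draw one molecule from the grammar, possibly planting alert fragments."""
    two_slot = rng.random() < 0.6
    if two_slot:
        template = _TWO_SLOT[rng.integers(len(_TWO_SLOT))]
        slots = [
            _DECORATIONS[rng.integers(len(_DECORATIONS))],
            _DECORATIONS[rng.integers(len(_DECORATIONS))],
        ]
    else:
        template = _ONE_SLOT[rng.integers(len(_ONE_SLOT))]
        slots = [_DECORATIONS[rng.integers(len(_DECORATIONS))]]
    slot_cursor = 0
    for alert in alerts:
        if rng.random() < alert.insert_probability and slot_cursor < len(slots):
            slots[slot_cursor] = alert.fragment
            slot_cursor += 1
    smiles = template.format(*slots)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:  # grammar is curated; this would be a programming error
        raise SynthConfigError(f"grammar produced invalid SMILES {smiles!r}")
    return Chem.MolToSmiles(mol)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _sigmoid(eta + mid).mean() < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_dataset(config: SynthConfig) -> tuple[MoleculeDataset, SynthTruth]:
    """Generate a labeled dataset with planted substructure–activity signal."""
    rng = np.random.default_rng(config.seed)
    smiles = [_assemble(rng, config.alerts) for _ in range(config.n_molecules)]

    queries = [Chem.MolFromSmarts(a.smarts) for a in config.alerts]
    presence = np.zeros((config.n_molecules, len(config.alerts)), dtype=np.uint8)
    match_cache: dict[str, np.ndarray] = {}
    for i, smi in enumerate(smiles):
        if smi not in match_cache:
            mol = Chem.MolFromSmiles(smi)
            match_cache[smi] = np.array(
                [mol.HasSubstructMatch(q) for q in queries], dtype=np.uint8
            )
        presence[i] = match_cache[smi]

    eta = presence @ np.log([a.odds for a in config.alerts])
    if config.descriptor_effect:
        desc_cache: dict[str, dict] = {}
        for name, coef in config.descriptor_effect:
            vals = np.empty(config.n_molecules)
            for i, smi in enumerate(smiles):
                if smi not in desc_cache:
                    desc_cache[smi] = compute_13md(Chem.MolFromSmiles(smi))
                vals[i] = desc_cache[smi][name]
            sd = vals.std()
            z = (vals - vals.mean()) / sd if sd > 0 else np.zeros_like(vals)
            eta = eta + coef * z

    intercept = _calibrate_intercept(eta, config.pos_fraction)
    eta = eta + intercept
    labels = (rng.random(config.n_molecules) < _sigmoid(eta)).astype(int)
    if config.label_noise > 0:
        flips = rng.random(config.n_molecules) < config.label_noise
        labels = np.where(flips, 1 - labels, labels)

    records = [
        MoleculeRecord(id=f"SYN{i:05d}", smiles=smi, label=int(lab))
        for i, (smi, lab) in enumerate(zip(smiles, labels))
    ]
    dataset = MoleculeDataset(
        records=records,
        name=f"synthetic-seed{config.seed}",
        provenance="gutshield.synthdata.generate_dataset",
    )
    truth = SynthTruth(
        eta=eta,
        intercept=intercept,
        alert_smarts=[a.smarts for a in config.alerts],
        alert_presence=presence,
        n_pos=int(labels.sum()),
        n_neg=int(len(labels) - labels.sum()),
    )
    return dataset, truth


def null_dataset(
    n: int,
    seed: int = 0,
    pos_fraction: float = DEFAULT_POS_FRACTION,
) -> MoleculeDataset:
    """Grammar molecules with labels independent of structure (pure noise)."""
    if n < 1:
        raise SynthConfigError("n must be positive")
    rng = np.random.default_rng(seed)
    smiles = [_assemble(rng, ()) for _ in range(n)]
    labels = (rng.random(n) < pos_fraction).astype(int)
    records = [
        MoleculeRecord(id=f"NUL{i:05d}", smiles=smi, label=int(lab))
        for i, (smi, lab) in enumerate(zip(smiles, labels))
    ]
    return MoleculeDataset(
        records=records,
        name=f"null-seed{seed}",
        provenance="gutshield.synthdata.null_dataset",
    )
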