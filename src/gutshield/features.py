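"""Characterization sets: fingerprint/descriptor fusion and min–max scaling.

A :class:`FeatureSpec` names one characterization set — a fingerprint, a
descriptor panel, or their concatenation (e.g. ``13MD+MACCS``). The default
grid enumerates 6 fingerprints × {none, 13MD, RDMD} = 18 sets; a third
descriptor panel slot (CCMD, a pretrained-embedding panel) can be supplied by
a plugin, completing the 24-set grid, and is reported as unavailable
otherwise.

Descriptor columns are min–max scaled, x* = (x − x_min)/(x_max − x_min), with
the column extrema fitted on training data only; out-of-range external values
are clipped to [0, 1] and constant columns map to 0. Fingerprint bits are
never rescaled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Optional

import numpy as np
from rdkit import Chem

from . import descriptors as D
from . import fingerprints as FP
from .dataio import MoleculeDataset

log = logging.getLogger(__name__)

#: Optional plugin hook: maps a SMILES list to (matrix, names) for the CCMD
#: embedding panel. Left as None, the 24-set grid degrades to 18 sets.
CCMD_PLUGIN: Optional[Callable[[list[str]], tuple[np.ndarray, list[str]]]] = None


class FeatureSpecError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureSpec:
    """One characterization set: fingerprint and/or descriptor panel."""

    fingerprint: Optional[str] = None
    descriptors: Optional[str] = None

    def __post_init__(self):
        if self.fingerprint is None and self.descriptors is None:
            raise FeatureSpecError("spec needs a fingerprint or a descriptor set")
        if self.fingerprint is not None and self.fingerprint not in FP.FINGERPRINT_KINDS:
            raise FeatureSpecError(f"unknown fingerprint {self.fingerprint!r}")
        if self.descriptors is not None and self.descriptors not in D.DESCRIPTOR_SETS:
            raise FeatureSpecError(f"unknown descriptor set {self.descriptors!r}")

    @property
    def name(self) -> str:
        parts = [p for p in (self.descriptors, self.fingerprint) if p]
        return "+".join(parts)

    @classmethod
    def parse(cls, name: str) -> "FeatureSpec":
        fp = desc = None
        for part in name.split("+"):
            if part in FP.FINGERPRINT_KINDS:
                fp = part
            elif part in D.DESCRIPTOR_SETS:
                desc = part
            else:
                raise FeatureSpecError(f"cannot parse feature spec {name!r}")
        return cls(fingerprint=fp, descriptors=desc)


def enumerate_specs(include_descriptor_only: bool = False) -> list[FeatureSpec]:
    """The default characterization grid.

    6 fingerprints alone plus 6 × 2 descriptor combinations = 18 sets; with a
    CCMD plugin installed the grid grows to the full 24. Descriptor-only
    specs (for ablation/importance studies) are appended on request.
    """
    specs = [FeatureSpec(fingerprint=fp) for fp in FP.FINGERPRINT_KINDS]
    for desc in D.DESCRIPTOR_SETS:
        specs += [FeatureSpec(fingerprint=fp, descriptors=desc) for fp in FP.FINGERPRINT_KINDS]
    if CCMD_PLUGIN is None:
        log.info("CCMD plugin not installed: characterization grid has %d of 24 sets", len(specs))
    if include_descriptor_only:
        specs += [FeatureSpec(descriptors=d) for d in D.DESCRIPTOR_SETS]
    return specs


@dataclass
class FeatureMatrix:
    """A numeric matrix with named columns for one characterization set."""

    values: np.ndarray
    feature_names: list[str]
    spec: FeatureSpec
    ids: list[str]
    descriptor_mask: np.ndarray  # True for descriptor (scalable) columns
    scaled: bool = False

    def __post_init__(self):
        assert self.values.shape == (len(self.ids), len(self.feature_names))
        assert self.descriptor_mask.shape == (len(self.feature_names),)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def rows(self, ids: list[str]) -> "FeatureMatrix":
        index = {rid: i for i, rid in enumerate(self.ids)}
        idx = [index[r] for r in ids]
        return FeatureMatrix(
            values=self.values[idx],
            feature_names=self.feature_names,
            spec=self.spec,
            ids=list(ids),
            descriptor_mask=self.descriptor_mask,
            scaled=self.scaled,
        )


@dataclass
class ScalerState:
    """Fitted per-column min/max (and medians for NaN imputation)."""

    spec_name: str
    x_min: np.ndarray
    x_max: np.ndarray
    median: np.ndarray
    descriptor_mask: np.ndarray


def fit_scaler(train: FeatureMatrix) -> ScalerState:
    """Fit column extrema on the training rows of the descriptor columns."""
    cols = train.values[:, train.descriptor_mask]
    with np.errstate(all="ignore"):
        x_min = np.nanmin(cols, axis=0) if cols.size else np.empty(0)
        x_max = np.nanmax(cols, axis=0) if cols.size else np.empty(0)
        median = np.nanmedian(cols, axis=0) if cols.size else np.empty(0)
    x_min = np.nan_to_num(x_min, nan=0.0)
    x_max = np.nan_to_num(x_max, nan=0.0)
    median = np.nan_to_num(median, nan=0.0)
    return ScalerState(
        spec_name=train.spec.name,
        x_min=x_min,
        x_max=x_max,
        median=median,
        descriptor_mask=train.descriptor_mask.copy(),
    )


def apply_scaler(state: ScalerState, matrix: FeatureMatrix) -> FeatureMatrix:
    """Min–max scale descriptor columns; fingerprint bits pass through.

    NaNs are imputed with training medians before scaling; values outside the
    training range clip to [0, 1]; constant columns map to 0.
    """
    if state.spec_name != matrix.spec.name:
        raise FeatureSpecError(
            f"scaler fitted for {state.spec_name!r}, matrix is {matrix.spec.name!r}"
        )
    values = matrix.values.astype(np.float64, copy=True)
    mask = matrix.descriptor_mask
    cols = values[:, mask]
    nan_rows = np.isnan(cols)
    if nan_rows.any():
        cols[nan_rows] = np.broadcast_to(state.median, cols.shape)[nan_rows]
    span = state.x_max - state.x_min
    constant = span == 0
    safe_span = np.where(constant, 1.0, span)
    scaled = (cols - state.x_min) / safe_span
    scaled[:, constant] = 0.0
    np.clip(scaled, 0.0, 1.0, out=scaled)
    values[:, mask] = scaled
    return FeatureMatrix(
        values=values,
        feature_names=matrix.feature_names,
        spec=matrix.spec,
        ids=matrix.ids,
        descriptor_mask=matrix.descriptor_mask,
        scaled=True,
    )


# ---------------------------------------------------------------------------
# Matrix assembly (with per-SMILES caching: the synthetic grammar reuses
# structures heavily, and fingerprints/descriptors are pure functions of the
# canonical SMILES)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=200_000)
def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES {smiles!r}")
    return mol


@lru_cache(maxsize=200_000)
def _fp_row(smiles: str, kind: str) -> np.ndarray:
    return FP.compute_fingerprint(_mol_from_smiles(smiles), kind)


@lru_cache(maxsize=200_000)
def _desc_row(smiles: str, set_id: str) -> tuple[float, ...]:
    vals = D.compute_descriptors(_mol_from_smiles(smiles), set_id)
    return tuple(vals[n] for n in D.descriptor_names(set_id))


def build_feature_set(
    dataset: MoleculeDataset,
    spec: FeatureSpec,
    scaler: Optional[ScalerState] = None,
    scale: bool = True,
) -> FeatureMatrix:
    """Assemble ``[fingerprint bits | descriptors]`` for a dataset.

    With ``scale=True`` (default) descriptor columns are min–max scaled — by
    a scaler fitted on this dataset, or by the supplied fitted ``scaler``
    (e.g. the training-set scaler when featurizing external compounds). With
    ``scale=False`` the raw matrix is returned, for estimators that fit the
    scaler inside cross-validation folds.
    """
    if len(dataset) == 0:
        raise ValueError("cannot featurize an empty dataset")
    blocks: list[np.ndarray] = []
    names: list[str] = []
    mask_parts: list[np.ndarray] = []
    if spec.fingerprint:
        fp_block = np.stack([_fp_row(s, spec.fingerprint) for s in dataset.smiles])
        blocks.append(fp_block.astype(np.float64))
        names += FP.fingerprint_names(spec.fingerprint)
        mask_parts.append(np.zeros(fp_block.shape[1], dtype=bool))
    if spec.descriptors:
        d_block = np.array([_desc_row(s, spec.descriptors) for s in dataset.smiles])
        blocks.append(d_block)
        names += [f"{spec.descriptors}:{n}" for n in D.descriptor_names(spec.descriptors)]
        mask_parts.append(np.ones(d_block.shape[1], dtype=bool))
    matrix = FeatureMatrix(
        values=np.hstack(blocks),
        feature_names=names,
        spec=spec,
        ids=dataset.ids,
        descriptor_mask=np.concatenate(mask_parts),
    )
    if not scale:
        return matrix
    if scaler is None:
        scaler = fit_scaler(matrix)
    return apply_scaler(scaler, matrix)
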