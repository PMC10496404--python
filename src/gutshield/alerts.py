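"""Structural-alert mining: information gain and class-frequency enrichment.

A structural alert (SA) is a substructure statistically responsible for the
anti-commensal effect: it carries high mutual information with the class
label (information gain, IG, in bits) and occurs relatively more often in
anti-commensal than commensal compounds (freq_p > freq_n). Candidate
fragments come from the bundled 4,860-pattern keyed fragment dictionary;
presence is binary per compound (multiplicity ignored), and only fragments
seen more than ``min_occurrence`` times in the dataset are scored.

Definitions (for a fragment present in m_pos of n_pos positives and m_neg of
n_neg negatives, N = n_pos + n_neg, m = m_pos + m_neg):

* IG = H(label) − H(label | fragment), entropies base 2 with 0·log 0 := 0 —
  the mutual information between fragment presence and the label;
* freq_c = (m_c / n_c) / (m / N) — within-class prevalence normalized by
  overall prevalence, > 1 meaning enrichment in class c.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np
from rdkit import Chem

from .dataio import InputError, MoleculeDataset
from .smartskeys import KRFP_SIZE, get_matcher, krfp_patterns


@dataclass
class FragmentStats:
    """Per-fragment contingency counts and derived statistics."""

    fragment_id: int
    smarts: str
    m_pos: int
    m_neg: int
    n_pos: int
    n_neg: int
    IG: float = math.nan
    freq_p: float = math.nan
    freq_n: float = math.nan

    def __post_init__(self):
        if not (0 <= self.m_pos <= self.n_pos and 0 <= self.m_neg <= self.n_neg):
            raise ValueError("fragment counts exceed class sizes")


@dataclass
class StructuralAlert:
    stats: FragmentStats
    rank: int
    representatives: list[str] = field(default_factory=list)


def compute_krfp(mol: Chem.Mol) -> np.ndarray:
    """Presence bit vector over the bundled fragment dictionary."""
    return get_matcher("krfp").match(mol)


@lru_cache(maxsize=200_000)
def _krfp_cached(smiles: str) -> np.ndarray:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"unparseable SMILES {smiles!r}")
    return compute_krfp(mol)


def krfp_matrix(dataset: MoleculeDataset) -> np.ndarray:
    """n × 4860 presence matrix (per-SMILES cached across calls)."""
    return np.stack([_krfp_cached(s) for s in dataset.smiles])


def _entropy2(probabilities) -> float:
    h = 0.0
    for p in probabilities:
        if p > 0:
            h -= p * math.log2(p)
    return h


def information_gain(stats: FragmentStats) -> float:
    """Mutual information (bits) between fragment presence and class label."""
    n = stats.n_pos + stats.n_neg
    if n == 0:
        raise ValueError("empty dataset")
    m = stats.m_pos + stats.m_neg
    h_label = _entropy2([stats.n_pos / n, stats.n_neg / n])
    h_cond = 0.0
    for m_p, m_n in ((stats.m_pos, stats.m_neg), (stats.n_pos - stats.m_pos, stats.n_neg - stats.m_neg)):
        cell = m_p + m_n
        if cell:
            h_cond += (cell / n) * _entropy2([m_p / cell, m_n / cell])
    return h_label - h_cond


def class_frequency(stats: FragmentStats) -> tuple[float, float]:
    """(freq_p, freq_n): class prevalence normalized by overall prevalence."""
    n = stats.n_pos + stats.n_neg
    m = stats.m_pos + stats.m_neg
    if m == 0:
        raise ValueError("fragment occurs in no compound")
    overall = m / n
    freq_p = (stats.m_pos / stats.n_pos) / overall if stats.n_pos else math.nan
    freq_n = (stats.m_neg / stats.n_neg) / overall if stats.n_neg else math.nan
    return freq_p, freq_n


def fragment_counts(
    dataset: MoleculeDataset,
    min_occurrence: int = 10,
    presence: Optional[np.ndarray] = None,
) -> list[FragmentStats]:
    """Contingency counts for every fragment seen more than ``min_occurrence``
    times (strict inequality) in the dataset.

    ``presence`` may supply a precomputed n × 4860 bit matrix.
    """
    labels = dataset.labels
    if any(l is None for l in labels):
        raise InputError("fragment mining requires a fully labeled dataset")
    y = np.asarray(labels, dtype=int)
    if presence is None:
        presence = krfp_matrix(dataset)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    m_pos = presence[y == 1].sum(axis=0)
    m_neg = presence[y == 0].sum(axis=0)
    total = m_pos + m_neg
    patterns = krfp_patterns()
    return [
        FragmentStats(
            fragment_id=int(i),
            smarts=patterns[i],
            m_pos=int(m_pos[i]),
            m_neg=int(m_neg[i]),
            n_pos=n_pos,
            n_neg=n_neg,
        )
        for i in np.flatnonzero(total > min_occurrence)
    ]


def score_fragments(stats_list: list[FragmentStats]) -> list[FragmentStats]:
    """Fill IG and enrichment frequencies in place (and return the list)."""
    for st in stats_list:
        st.IG = information_gain(st)
        st.freq_p, st.freq_n = class_frequency(st)
    return stats_list


def identify_alerts(
    dataset: MoleculeDataset,
    top_k: Optional[int] = 7,
    ig_floor: Optional[float] = None,
    min_occurrence: int = 10,
    presence: Optional[np.ndarray] = None,
    max_representatives: int = 3,
) -> list[StructuralAlert]:
    """Mine ranked structural alerts from a labeled dataset.

    Fragments enriched in the positive class (freq_p > freq_n) are ranked by
    IG descending; the top ``top_k`` (or all above ``ig_floor``) are returned,
    each carrying up to ``max_representatives`` positive compound ids that
    contain the fragment. May return fewer than ``top_k``.
    """
    if presence is None:
        presence = krfp_matrix(dataset)
    stats_list = score_fragments(fragment_counts(dataset, min_occurrence, presence))
    candidates = [st for st in stats_list if st.freq_p > st.freq_n]
    candidates.sort(key=lambda st: (-st.IG, st.fragment_id))
    if ig_floor is not None:
        candidates = [st for st in candidates if st.IG >= ig_floor]
    elif top_k is not None:
        candidates = candidates[:top_k]
    y = np.asarray(dataset.labels, dtype=int)
    ids = np.asarray(dataset.ids)
    alerts = []
    for rank, st in enumerate(candidates, start=1):
        holders = ids[(presence[:, st.fragment_id] == 1) & (y == 1)]
        alerts.append(
            StructuralAlert(stats=st, rank=rank, representatives=list(holders[:max_representatives]))
        )
    return alerts


KRFP_DICTIONARY_SIZE = KRFP_SIZE
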