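"""The consensus-modeling protocol: repeated random splits, voting, the
18-member consensus, the applicability domain and the model audits.

Protocol overview:

1. The labeled dataset is randomly split 18 times into training and external
   validation sets at a ratio of 8:2 (stratified; split *i* is seeded by
   ``base_seed + i``).
2. On every split, every (characterization set × algorithm) cell is tuned by
   repeated stratified cross-validation. Per split, each characterization set
   credits its best-F1 algorithm; the algorithm with the largest total credit
   over all splits wins ("algorithm vote", a Table-1-style ratio table).
3. With the algorithm fixed, each split credits its best characterization
   set; the modal set wins ("feature-set vote").
4. One member model per split is trained on its training portion with the
   winning (set, algorithm) and its split-tuned hyperparameters; the
   consensus prediction for a new molecule is the arithmetic mean of the 18
   member probabilities, thresholded at 0.5.
5. An applicability domain (AD) per member: a new compound is in-domain when
   its Euclidean distance to the training-set centroid (in the scaled
   feature space) does not exceed the 99th percentile of training distances.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .dataio import InputError, MoleculeDataset
from .features import FeatureMatrix, FeatureSpec, build_feature_set
from .metrics import MetricsReport, aggregate_reports, evaluate_predictions, metric_key
from .modeling import CVResult, LearnerSpec, ModelingError, TrainedMember, fit_final, tune_and_evaluate


@dataclass(frozen=True)
class Split:
    """One random 8:2 partition of the dataset."""

    index: int
    train_ids: tuple[str, ...]
    valid_ids: tuple[str, ...]
    seed: int


def make_splits(
    dataset: MoleculeDataset,
    n_splits: int = 18,
    valid_fraction: float = 0.2,
    base_seed: int = 0,
) -> list[Split]:
    """Independent stratified random 8:2 partitions, split i seeded base+i."""
    labels = dataset.labels
    if any(l is None for l in labels):
        raise InputError("splitting requires a fully labeled dataset")
    n = len(dataset)
    if n < 10:
        raise InputError("dataset too small to split")
    n_valid = round(valid_fraction * n)
    y = np.asarray(labels)
    ids = np.asarray(dataset.ids)
    splits = []
    for i in range(1, n_splits + 1):
        train_idx, valid_idx = train_test_split(
            np.arange(n),
            test_size=n_valid,
            stratify=y,
            random_state=base_seed + i,
        )
        splits.append(
            Split(
                index=i,
                train_ids=tuple(ids[np.sort(train_idx)]),
                valid_ids=tuple(ids[np.sort(valid_idx)]),
                seed=base_seed + i,
            )
        )
    return splits


# ---------------------------------------------------------------------------
# CV grid + voting
# ---------------------------------------------------------------------------

CVGrid = dict[tuple[int, str, str], CVResult]  # (split index, spec name, algorithm)


def run_cv_grid(
    dataset: MoleculeDataset,
    splits: Sequence[Split],
    specs: Sequence[FeatureSpec],
    algorithms: Sequence[str] = ("SVM", "kNN", "RF", "NB", "GBM", "XGB"),
    grids: Optional[dict[str, dict]] = None,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
) -> CVGrid:
    """Tune every (split × characterization set × algorithm) cell."""
    results: CVGrid = {}
    for spec in specs:
        matrix = build_feature_set(dataset, spec, scale=False)
        label_of = dict(zip(dataset.ids, dataset.labels))
        for split in splits:
            X_tr = matrix.rows(list(split.train_ids))
            y_tr = [label_of[r] for r in split.train_ids]
            for algo in algorithms:
                lspec = LearnerSpec(
                    algorithm=algo,
                    grid=(grids or {}).get(algo),
                    fixed_seed=seed,
                )
                res = tune_and_evaluate(
                    lspec, X_tr, y_tr, folds=folds, repeats=repeats, seed=split.seed
                )
                res.split_index = split.index
                results[(split.index, spec.name, algo)] = res
    return results


@dataclass
class VoteTable:
    """Credit table of a vote: rows = splits, columns = contestants."""

    credits: pd.DataFrame  # index: split, columns: contestant, values: credit
    n_contested: int
    winner: str

    def ratio_table(self) -> pd.DataFrame:
        """Table-1-style presentation, entries 'k/N'."""
        def fmt(v):
            return f"{v:g}/{self.n_contested}"
        return self.credits.map(fmt)


def _check_complete(results: CVGrid, splits, specs, algorithms):
    missing = [
        (s.index, spec.name, a)
        for s in splits
        for spec in specs
        for a in algorithms
        if (s.index, spec.name, a) not in results
    ]
    if missing:
        raise ModelingError(f"incomplete CV grid; missing cells: {missing[:10]} ...")


def vote_algorithm(
    results: CVGrid,
    splits: Sequence[Split],
    specs: Sequence[FeatureSpec],
    algorithms: Sequence[str],
) -> VoteTable:
    """Per split, each characterization set credits its best-F1 algorithm(s);
    exact ties split the credit equally. Winner has the largest total credit
    (ties break by mean F1, then mean AUC)."""
    _check_complete(results, splits, specs, algorithms)
    credits = pd.DataFrame(0.0, index=[s.index for s in splits], columns=list(algorithms))
    for split in splits:
        for spec in specs:
            f1s = {a: results[(split.index, spec.name, a)].metrics.F1 for a in algorithms}
            best = max(metric_key(v) for v in f1s.values())
            winners = [a for a, v in f1s.items() if metric_key(v) == best]
            for a in winners:
                credits.loc[split.index, a] += 1.0 / len(winners)
    totals = credits.sum(axis=0)
    mean_f1 = {
        a: np.nanmean([results[(s.index, sp.name, a)].metrics.F1 for s in splits for sp in specs])
        for a in algorithms
    }
    mean_auc = {
        a: np.nanmean([results[(s.index, sp.name, a)].metrics.AUC for s in splits for sp in specs])
        for a in algorithms
    }
    winner = max(
        algorithms,
        key=lambda a: (totals[a], metric_key(mean_f1[a]), metric_key(mean_auc[a])),
    )
    return VoteTable(credits=credits, n_contested=len(specs), winner=winner)


def vote_feature_set(
    results: CVGrid,
    splits: Sequence[Split],
    specs: Sequence[FeatureSpec],
    algorithm: str,
) -> tuple[str, pd.DataFrame]:
    """With the algorithm fixed, each split names its best-F1 set; the modal
    set wins (modal ties break toward higher mean F1 across splits).

    Returns (winning spec name, per-split table of best set and F1).
    """
    _check_complete(results, splits, specs, [algorithm])
    rows = []
    for split in splits:
        f1s = {sp.name: results[(split.index, sp.name, algorithm)].metrics.F1 for sp in specs}
        best_name = max(f1s, key=lambda nm: (metric_key(f1s[nm]), nm))
        rows.append({"split": split.index, "best_spec": best_name, "F1": f1s[best_name]})
    table = pd.DataFrame(rows).set_index("split")
    tally = Counter(table["best_spec"])
    top = max(tally.values())
    contenders = [nm for nm, c in tally.items() if c == top]
    mean_f1 = {
        nm: np.nanmean([results[(s.index, nm, algorithm)].metrics.F1 for s in splits])
        for nm in contenders
    }
    winner = max(contenders, key=lambda nm: (metric_key(mean_f1[nm]), nm))
    return winner, table


# ---------------------------------------------------------------------------
# Consensus model
# ---------------------------------------------------------------------------

@dataclass
class ConsensusModel:
    """Probability-averaging ensemble of per-split member models."""

    members: list[TrainedMember]
    feature_spec: FeatureSpec
    threshold: float = 0.5
    mode: str = "probability"  # or "label": majority vote of hard labels

    def __post_init__(self):
        names = {m.feature_spec for m in self.members}
        if len(names) > 1:
            raise ModelingError(f"members disagree on feature spec: {names}")

    def member_scores(self, dataset: MoleculeDataset) -> np.ndarray:
        X = build_feature_set(dataset, self.feature_spec, scale=False)
        return np.stack([m.predict_proba(X) for m in self.members])

    def predict_proba(self, dataset: MoleculeDataset) -> np.ndarray:
        scores = self.member_scores(dataset)
        if self.mode == "label":
            return (scores >= self.threshold).mean(axis=0)
        return scores.mean(axis=0)

    def predict(self, dataset: MoleculeDataset) -> np.ndarray:
        return (self.predict_proba(dataset) >= self.threshold).astype(int)


def build_consensus(
    dataset: MoleculeDataset,
    splits: Sequence[Split],
    results: CVGrid,
    spec: FeatureSpec,
    algorithm: str,
    threshold: float = 0.5,
    seed: int = 0,
) -> ConsensusModel:
    """Train one member per split (its tuned hyperparameters, its training
    portion) and bundle them into the probability-averaging consensus."""
    label_of = dict(zip(dataset.ids, dataset.labels))
    matrix = build_feature_set(dataset, spec, scale=False)
    members = []
    for split in splits:
        key = (split.index, spec.name, algorithm)
        if key not in results:
            raise ModelingError(f"no CV result for cell {key}")
        params = results[key].best_params
        X_tr = matrix.rows(list(split.train_ids))
        y_tr = [label_of[r] for r in split.train_ids]
        members.append(fit_final(algorithm, params, X_tr, y_tr, seed=seed))
    return ConsensusModel(members=members, feature_spec=spec, threshold=threshold)


def evaluate_consensus(
    cm: ConsensusModel,
    dataset: MoleculeDataset,
    splits: Sequence[Split],
    results: Optional[CVGrid] = None,
) -> dict[str, MetricsReport]:
    """Internal (cross-validation) and external (hold-out) aggregates.

    Internal: each member's tuned CV metrics, aggregated over splits.
    External: member *i* predicts only its own held-out 20% — the one
    evaluation with no train/test overlap — aggregated over splits.
    """
    label_of = dict(zip(dataset.ids, dataset.labels))
    external_reports = []
    for member, split in zip(cm.members, splits):
        leaked = set(split.valid_ids) & set(member.train_ids)
        if leaked:
            raise ModelingError(
                f"leakage: split {split.index} validation ids in member training set: "
                f"{sorted(leaked)[:5]}"
            )
        valid = dataset.subset(list(split.valid_ids))
        X_va = build_feature_set(valid, cm.feature_spec, scale=False)
        scores = member.predict_proba(X_va)
        y_va = [label_of[r] for r in split.valid_ids]
        external_reports.append(evaluate_predictions(y_va, scores, cm.threshold))
    out = {"external": aggregate_reports(external_reports)}
    if results is not None:
        internal = [
            results[(s.index, cm.feature_spec.name, m.algorithm)].metrics
            for s, m in zip(splits, cm.members)
        ]
        out["internal"] = aggregate_reports(internal)
    return out


# ---------------------------------------------------------------------------
# Applicability domain
# ---------------------------------------------------------------------------

@dataclass
class ADModel:
    """Euclidean-distance applicability domain in the scaled feature space."""

    centroid: np.ndarray
    cutoff_distance: float
    percentile: float
    spec_name: str
    method: str = "centroid"
    reference: Optional[np.ndarray] = None  # training matrix, for knn method
    k: int = 5


def _distances(ad: ADModel, values: np.ndarray) -> np.ndarray:
    if ad.method == "centroid":
        return np.linalg.norm(values - ad.centroid, axis=1)
    if ad.method == "knn":
        d = np.linalg.norm(values[:, None, :] - ad.reference[None, :, :], axis=2)
        d.sort(axis=1)
        return d[:, : ad.k].mean(axis=1)
    raise ValueError(f"unknown AD method {ad.method!r}")


def fit_ad(
    train: FeatureMatrix,
    percentile: float = 99.0,
    method: str = "centroid",
    k: int = 5,
) -> ADModel:
    """Fit the AD on a scaled training matrix.

    The cutoff is the empirical ``percentile`` (linear interpolation) of the
    training compounds' distances — to the centroid by default, or the mean
    distance to the ``k`` nearest other training compounds (``method="knn"``).
    """
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    values = train.values
    centroid = values.mean(axis=0)
    ad = ADModel(
        centroid=centroid,
        cutoff_distance=math.nan,
        percentile=percentile,
        spec_name=train.spec.name,
        method=method,
        reference=values if method == "knn" else None,
        k=k,
    )
    if method == "knn":
        # leave-self-out: a training compound is not its own neighbour
        d = np.linalg.norm(values[:, None, :] - values[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        d.sort(axis=1)
        train_d = d[:, :k].mean(axis=1)
    else:
        train_d = _distances(ad, values)
    ad.cutoff_distance = float(np.percentile(train_d, percentile))
    return ad


def in_domain(ad: ADModel, matrix: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(inside flags, distances) for the rows of a scaled feature matrix."""
    if matrix.spec.name != ad.spec_name:
        raise ValueError(f"AD fitted for {ad.spec_name!r}, matrix is {matrix.spec.name!r}")
    d = _distances(ad, matrix.values)
    return d <= ad.cutoff_distance, d


def coverage(ad: ADModel, matrix: FeatureMatrix) -> float:
    """Fraction of compounds inside the domain."""
    inside, _ = in_domain(ad, matrix)
    return float(inside.mean())


# ---------------------------------------------------------------------------
# Audits
# ---------------------------------------------------------------------------

def single_descriptor_importance(
    dataset: MoleculeDataset,
    splits: Sequence[Split],
    panel: str = "13MD",
    algorithm: str = "XGB",
    grid: Optional[dict] = None,
    folds: int = 5,
    repeats: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank panel descriptors by the mean cross-validated sensitivity of
    single-descriptor models (full-panel row included for reference).

    Constant (zero-variance) descriptors are flagged and ranked last.
    """
    spec = FeatureSpec(descriptors=panel)
    matrix = build_feature_set(dataset, spec, scale=False)
    label_of = dict(zip(dataset.ids, dataset.labels))
    rows = []
    columns = list(matrix.feature_names) + ["__full__"]
    for col in columns:
        if col == "__full__":
            sub = matrix
        else:
            j = matrix.feature_names.index(col)
            sub = FeatureMatrix(
                values=matrix.values[:, [j]],
                feature_names=[col],
                spec=spec,
                ids=matrix.ids,
                descriptor_mask=matrix.descriptor_mask[[j]],
            )
        constant = bool(np.all(np.nan_to_num(sub.values) == np.nan_to_num(sub.values[0])))
        se_values = []
        for split in splits:
            X_tr = sub.rows(list(split.train_ids))
            y_tr = [label_of[r] for r in split.train_ids]
            lspec = LearnerSpec(algorithm=algorithm, grid=grid or {}, fixed_seed=seed)
            res = tune_and_evaluate(lspec, X_tr, y_tr, folds=folds, repeats=repeats, seed=split.seed)
            se_values.append(res.metrics.SE)
        rows.append(
            {
                "descriptor": "full panel" if col == "__full__" else col.split(":", 1)[1],
                "mean_SE": float(np.nanmean(se_values)),
                "sd_SE": float(np.nanstd(se_values, ddof=1)) if len(se_values) > 1 else 0.0,
                "constant": constant,
            }
        )
    table = pd.DataFrame(rows)
    single = table[table["descriptor"] != "full panel"].copy()
    single.sort_values(
        by=["constant", "mean_SE"], ascending=[True, False], inplace=True, kind="mergesort"
    )
    full = table[table["descriptor"] == "full panel"]
    return pd.concat([single, full], ignore_index=True)


def misclassification_report(
    external_predictions: Sequence[tuple[int, str, int, int]],
    dataset: MoleculeDataset,
    min_times: int = 5,
) -> pd.DataFrame:
    """Recurrently misclassified anti-commensal compounds.

    ``external_predictions`` holds (split index, compound id, true label,
    predicted label) for every hold-out prediction. For each positive
    compound the number of validation appearances where it was predicted
    negative is counted; compounds at or above ``min_times`` are returned,
    sorted by count descending (ties by id).
    """
    times: dict[str, int] = defaultdict(int)
    appearances: dict[str, int] = defaultdict(int)
    for _, cid, y_true, y_pred in external_predictions:
        if y_true == 1:
            appearances[cid] += 1
            if y_pred == 0:
                times[cid] += 1
    smiles_of = dict(zip(dataset.ids, dataset.smiles))
    rows = [
        {
            "id": cid,
            "smiles": smiles_of.get(cid, ""),
            "times_misclassified": cnt,
            "times_in_validation": appearances[cid],
        }
        for cid, cnt in times.items()
        if cnt >= min_times
    ]
    rows.sort(key=lambda r: (-r["times_misclassified"], r["id"]))
    return pd.DataFrame(rows, columns=["id", "smiles", "times_misclassified", "times_in_validation"])


def collect_external_predictions(
    cm: ConsensusModel,
    dataset: MoleculeDataset,
    splits: Sequence[Split],
) -> list[tuple[int, str, int, int]]:
    """Hold-out predictions (member i on its own validation set) per split."""
    label_of = dict(zip(dataset.ids, dataset.labels))
    preds = []
    for member, split in zip(cm.members, splits):
        valid = dataset.subset(list(split.valid_ids))
        X_va = build_feature_set(valid, cm.feature_spec, scale=False)
        scores = member.predict_proba(X_va)
        for cid, s in zip(split.valid_ids, scores):
            preds.append((split.index, cid, label_of[cid], int(s >= cm.threshold)))
    return preds
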