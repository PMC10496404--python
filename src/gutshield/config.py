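"""Run configuration: seeds, protocol sizes and thresholds, YAML-loadable.

Defaults encode the protocol's study conditions: 18 random 8:2 splits,
5-fold cross-validation repeated 10 times, AD percentile 99, consensus
threshold 0.5, alert occurrence floor 10 and misclassification floor 5.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .dataio import ConfigurationError


@dataclass
class RunConfig:
    seed: int = 0
    n_splits: int = 18
    valid_fraction: float = 0.2
    folds: int = 5
    repeats: int = 10
    algorithms: list[str] = field(
        default_factory=lambda: ["SVM", "kNN", "RF", "NB", "GBM", "XGB"]
    )
    feature_specs: Optional[list[str]] = None  # None -> full default grid
    grids: dict = field(default_factory=dict)  # per-algorithm overrides
    ad_percentile: float = 99.0
    consensus_threshold: float = 0.5
    alert_min_occurrence: int = 10
    misclassification_min_times: int = 5
    id_column: str = "id"
    smiles_column: str = "smiles"
    label_column: str = "label"
    strains_column: str = "n_inhibited"

    def digest(self) -> str:
        """Short content hash identifying this configuration."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: Optional[str | Path]) -> RunConfig:
    if path is None:
        return RunConfig()
    try:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"invalid YAML in {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config root must be a mapping in {path}")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)
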