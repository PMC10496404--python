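"""Reading, cleaning, labelling and writing molecule datasets.

The pipeline's universal input is a :class:`MoleculeDataset`: an ordered
collection of compounds, each a canonical SMILES with a binary activity label
(1 = anti-commensal, i.e. the compound inhibits growth of at least one
representative gut bacterial strain; 0 = commensal). Labels may alternatively
be derived from a per-compound count of inhibited strains.

Cleaning follows two rules: for disconnected (multi-fragment) structures only
the largest organic fragment is retained, and compounds containing elements
outside a configurable organic-chemistry whitelist are rejected.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from rdkit import Chem
from rdkit.Chem import Descriptors, RDConfig  # noqa: F401  (Descriptors used for MW tie-break)
from rdkit import RDLogger

log = logging.getLogger(__name__)

# Suppress per-molecule RDKit parse chatter; failures are counted and logged here.
RDLogger.DisableLog("rdApp.error")

#: Default element whitelist ("common elements" of organic chemistry).
DEFAULT_ELEMENTS = frozenset({"H", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I"})


class InputError(ValueError):
    """Raised for malformed or unusable user input."""


class ConfigurationError(ValueError):
    """Raised for invalid configuration (missing columns, unknown options)."""


@dataclass(frozen=True)
class MoleculeRecord:
    """One compound: identifier, canonical SMILES and optional label."""

    id: str
    smiles: str
    label: Optional[int] = None
    inhibited_strains: Optional[int] = None

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in (0, 1):
            raise InputError(f"label must be 0/1, got {self.label!r}")
        if self.inhibited_strains is not None:
            if self.inhibited_strains < 0:
                raise InputError("inhibited_strains must be non-negative")
            expected = assign_label(self.inhibited_strains)
            if self.label is not None and self.label != expected:
                raise InputError(
                    f"label {self.label} inconsistent with "
                    f"inhibited_strains={self.inhibited_strains}"
                )


@dataclass
class MoleculeDataset:
    """An ordered, uniquely-identified collection of molecule records."""

    records: list[MoleculeRecord] = field(default_factory=list)
    name: str = "dataset"
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            raise InputError("duplicate record ids in dataset")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def smiles(self) -> list[str]:
        return [r.smiles for r in self.records]

    @property
    def labels(self) -> list[Optional[int]]:
        return [r.label for r in self.records]

    def subset(self, ids: Sequence[str], name: Optional[str] = None) -> "MoleculeDataset":
        wanted = set(ids)
        recs = [r for r in self.records if r.id in wanted]
        if len(recs) != len(wanted):
            missing = wanted - {r.id for r in recs}
            raise InputError(f"unknown ids requested: {sorted(missing)[:5]} ...")
        return MoleculeDataset(records=recs, name=name or self.name, provenance=self.provenance)


@dataclass(frozen=True)
class Rejection:
    """A record dropped during cleaning, with the reason."""

    id: str
    smiles: str
    reason: str


def assign_label(inhibited_strains: int, threshold: int = 1) -> int:
    """Binary activity label from a strain-inhibition count.

    A compound is anti-commensal (label 1) iff it inhibits at least
    ``threshold`` of the assayed gut bacterial strains (default 1).
    """
    if inhibited_strains < 0:
        raise InputError("inhibited_strains must be non-negative")
    return int(inhibited_strains >= threshold)


def _fragment_sort_key(frag: Chem.Mol) -> tuple:
    smi = Chem.MolToSmiles(frag)
    # heavy atoms desc, MW desc, canonical SMILES asc — deterministic choice
    return (-frag.GetNumHeavyAtoms(), -Descriptors.MolWt(frag), smi)


def clean_structure(
    record: MoleculeRecord,
    allowed_elements: frozenset[str] = DEFAULT_ELEMENTS,
) -> MoleculeRecord | Rejection:
    """Apply the structure-cleaning rules to one record.

    For disconnected structures (salts, mixtures) only the largest organic
    fragment — most heavy atoms among fragments containing carbon — is kept;
    ties break by molecular weight then canonical SMILES. Records whose
    retained fragment contains an element outside ``allowed_elements`` are
    rejected, as are records with no carbon-containing fragment.
    Charges and stereo flags are preserved as given.
    """
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        return Rejection(record.id, record.smiles, "unparseable")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    organic = [f for f in frags if any(a.GetSymbol() == "C" for a in f.GetAtoms())]
    if not organic:
        return Rejection(record.id, record.smiles, "inorganic")
    best = min(organic, key=_fragment_sort_key)
    bad = {a.GetSymbol() for a in best.GetAtoms()} - allowed_elements
    if bad:
        return Rejection(record.id, record.smiles, f"element:{','.join(sorted(bad))}")
    return replace(record, smiles=Chem.MolToSmiles(best))


def clean_dataset(
    dataset: MoleculeDataset,
    allowed_elements: frozenset[str] = DEFAULT_ELEMENTS,
) -> tuple[MoleculeDataset, list[Rejection]]:
    """Clean every record; return the kept dataset and the rejection list."""
    kept: list[MoleculeRecord] = []
    rejected: list[Rejection] = []
    for rec in dataset:
        out = clean_structure(rec, allowed_elements)
        if isinstance(out, Rejection):
            rejected.append(out)
        else:
            kept.append(out)
    if rejected:
        log.warning("cleaning rejected %d/%d records", len(rejected), len(dataset))
    return (
        MoleculeDataset(records=kept, name=dataset.name, provenance=dataset.provenance),
        rejected,
    )


def summarize(dataset: MoleculeDataset) -> dict:
    """Class-balance summary: ``{n_total, n_pos, n_neg, pos_fraction}``."""
    labels = dataset.labels
    if any(l is None for l in labels):
        raise InputError("summarize requires a fully labeled dataset")
    n_pos = sum(labels)
    n_total = len(labels)
    return {
        "n_total": n_total,
        "n_pos": n_pos,
        "n_neg": n_total - n_pos,
        "pos_fraction": n_pos / n_total if n_total else float("nan"),
    }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_dataset(
    path: str | Path,
    format: Optional[str] = None,
    *,
    id_column: str = "id",
    smiles_column: str = "smiles",
    label_column: str = "label",
    strains_column: str = "n_inhibited",
    sdf_label_property: str = "active",
    name: Optional[str] = None,
) -> tuple[MoleculeDataset, int]:
    """Read a molecule table from CSV/TSV or SDF.

    Returns ``(dataset, n_unparseable)``. Rows whose SMILES cannot be parsed
    are counted and logged, never silently dropped without trace. Labels come
    either from a 0/1 label column or are derived from an inhibited-strain
    count column; at least one of the two must be present in a CSV.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if format is None:
        format = "sdf" if path.suffix.lower() == ".sdf" else "csv"
    if format == "csv":
        records, n_bad = _read_csv(path, id_column, smiles_column, label_column, strains_column)
    elif format == "sdf":
        records, n_bad = _read_sdf(path, sdf_label_property)
    else:
        raise ConfigurationError(f"unknown format {format!r}")
    if not records:
        raise InputError(f"no parseable records in {path}")
    if n_bad:
        log.warning("%d unparseable rows in %s", n_bad, path)
    return MoleculeDataset(records=records, name=name or path.stem, provenance=str(path)), n_bad


def _read_csv(path, id_col, smi_col, label_col, strains_col):
    delim = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        cols = reader.fieldnames or []
        if smi_col not in cols:
            raise ConfigurationError(f"missing SMILES column {smi_col!r} in {path}")
        has_label = label_col in cols
        has_strains = strains_col in cols
        if not has_label and not has_strains:
            raise ConfigurationError(
                f"need a {label_col!r} or {strains_col!r} column in {path}"
            )
        records, n_bad = [], 0
        for i, row in enumerate(reader):
            smiles = (row.get(smi_col) or "").strip()
            if Chem.MolFromSmiles(smiles) is None:
                n_bad += 1
                continue
            rid = (row.get(id_col) or "").strip() or f"row{i}"
            strains = None
            label = None
            if has_strains and (row.get(strains_col) or "").strip() != "":
                strains = int(float(row[strains_col]))
                label = assign_label(strains)
            if has_label and (row.get(label_col) or "").strip() != "":
                label = int(float(row[label_col]))
            records.append(
                MoleculeRecord(id=rid, smiles=smiles, label=label, inhibited_strains=strains)
            )
    return records, n_bad


def _read_sdf(path, label_property):
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    records, n_bad = [], 0
    for i, mol in enumerate(supplier):
        if mol is None:
            n_bad += 1
            continue
        rid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i}"
        label = None
        if mol.HasProp(label_property):
            label = int(float(mol.GetProp(label_property)))
        records.append(MoleculeRecord(id=rid, smiles=Chem.MolToSmiles(mol), label=label))
    return records, n_bad


def write_dataset(dataset: MoleculeDataset, path: str | Path) -> None:
    """Write the dataset as UTF-8 CSV with columns id,smiles,label[,n_inhibited]."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    has_strains = any(r.inhibited_strains is not None for r in dataset)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        header = ["id", "smiles", "label"] + (["n_inhibited"] if has_strains else [])
        writer.writerow(header)
        for r in dataset:
            row = [r.id, r.smiles, "" if r.label is None else r.label]
            if has_strains:
                row.append("" if r.inhibited_strains is None else r.inhibited_strains)
            writer.writerow(row)
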