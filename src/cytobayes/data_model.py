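"""Domain types and file I/O for assay tables, labels and serialized models.

All downstream modules consume these containers; nothing else in the
package reads files directly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import pandas as pd

MODEL_SCHEMA_VERSION = 1

PERCENT_INHIBITION = "percent_inhibition"
PIC50 = "pIC50"
READOUTS = (PERCENT_INHIBITION, PIC50)

#: percent-inhibition values outside this range are kept but flagged
PI_PLAUSIBLE_RANGE = (-20.0, 100.0)


class FormatError(ValueError):
    """Raised when an input file violates the expected layout."""


class ModelVersionError(ValueError):
    """Raised when a serialized model's schema version is unsupported."""


@dataclass(frozen=True)
class MoleculeRecord:
    """One compound: identity, optional structure, sparse features, descriptors.

    ``features`` are non-negative integer identifiers of binary
    (presence/absence) substructure features; ``descriptors`` maps
    descriptor name to a finite real value (AlogP unitless, MW in Da,
    HBD/HBA/rotatable-bond counts, fractional polar surface area in [0,1]).
    """

    id: str
    smiles: str | None = None
    features: frozenset[int] = frozenset()
    descriptors: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("molecule id must be non-empty")
        if any((not isinstance(f, int)) or f < 0 for f in self.features):
            raise ValueError(f"{self.id}: features must be non-negative integers")
        for name, v in self.descriptors.items():
            if not math.isfinite(v):
                raise ValueError(f"{self.id}: descriptor {name!r} not finite")


@dataclass
class AssayDataset:
    """One assay's measurements plus free-form metadata.

    ``readout`` is fixed per assay: percent inhibition (in %) or pIC50
    (−log10 molar). Higher values mean more cytotoxic for both.
    """

    assay_id: str
    readout: str
    measurements: dict[str, float]
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.readout not in READOUTS:
            raise ValueError(f"unknown readout {self.readout!r}; expected one of {READOUTS}")
        for cid, v in self.measurements.items():
            if not math.isfinite(v):
                raise ValueError(f"{self.assay_id}/{cid}: non-finite value")

    def __len__(self) -> int:
        return len(self.measurements)

    @property
    def ids(self) -> list[str]:
        return list(self.measurements)


@dataclass
class LabelledSet:
    """Binary toxic/non-toxic labels plus the rule that produced them.

    ``rule`` is a provenance record (name + parameters) sufficient to
    reconstruct the labels from the source dataset's values.
    """

    labels: dict[str, bool]
    rule: dict[str, Any] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_toxic(self) -> int:
        return sum(self.labels.values())

    @property
    def prevalence(self) -> float:
        return self.n_toxic / len(self.labels) if self.labels else float("nan")


@dataclass
class TruthTable:
    """2x2 confusion matrix; counts may be raw integers or percentages."""

    tp: float
    fp: float
    tn: float
    fn: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("truth-table cells must be non-negative")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float | None:
        """TP/(TP+FN); None when no positives were evaluated."""
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self) -> float | None:
        """TN/(TN+FP); None when no negatives were evaluated."""
        d = self.tn + self.fp
        return self.tn / d if d else None

    @property
    def accuracy(self) -> float | None:
        return (self.tp + self.tn) / self.total if self.total else None

    def as_percentages(self) -> "TruthTable":
        t = self.total
        return TruthTable(*(100.0 * c / t for c in (self.tp, self.fp, self.tn, self.fn)))


@dataclass
class AssayReadResult:
    dataset: AssayDataset
    records: list[MoleculeRecord]
    n_dropped: int
    flagged_out_of_range: list[str]


def read_assay_table(
    path: str | Path,
    assay_id: str | None = None,
    readout: str = PERCENT_INHIBITION,
    on_duplicate: str = "error",
    metadata_path: str | Path | None = None,
) -> AssayReadResult:
    """Read a delimited assay table into an :class:`AssayDataset`.

    The file must carry a header naming ``compound_id`` and ``value``
    columns; an optional ``smiles`` column is attached to the returned
    molecule records. Rows with null or non-finite endpoint values are
    excluded and counted (standard business rule: zero stays, null goes).
    Duplicate ids with conflicting values are handled per ``on_duplicate``:
    ``error`` (default), ``keep-first`` or ``mean``.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype={"compound_id": str})
    for col in ("compound_id", "value"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    if on_duplicate not in {"error", "keep-first", "mean"}:
        raise ValueError(f"unknown on_duplicate policy {on_duplicate!r}")

    values = pd.to_numeric(df["value"], errors="coerce")
    keep = values.notna() & values.apply(math.isfinite)
    n_dropped = int((~keep).sum())
    df = df.loc[keep].assign(value=values[keep])

    measurements: dict[str, float] = {}
    smiles: dict[str, str] = {}
    for row in df.itertuples(index=False):
        cid, val = str(row.compound_id), float(row.value)
        if cid in measurements:
            if on_duplicate == "error" and measurements[cid] != val:
                raise FormatError(f"{path}: conflicting duplicate values for {cid!r}")
            # keep-first: ignore; mean: resolved wholesale below
        else:
            measurements[cid] = val
        sm = getattr(row, "smiles", None)
        if isinstance(sm, str) and sm and cid not in smiles:
            smiles[cid] = sm
    if on_duplicate == "mean":
        grouped = df.groupby("compound_id", sort=False)["value"].mean()
        measurements = {str(k): float(v) for k, v in grouped.items()}

    metadata: dict[str, Any] = {}
    if metadata_path is not None:
        metadata = json.loads(Path(metadata_path).read_text())
    ds = AssayDataset(
        assay_id=assay_id or path.stem,
        readout=readout,
        measurements=measurements,
        metadata=metadata,
    )
    lo, hi = PI_PLAUSIBLE_RANGE
    flagged = (
        [cid for cid, v in measurements.items() if not lo <= v <= hi]
        if readout == PERCENT_INHIBITION
        else []
    )
    records = [
        MoleculeRecord(id=cid, smiles=smiles.get(cid)) for cid in measurements
    ]
    return AssayReadResult(ds, records, n_dropped, flagged)


def write_assay_table(ds: AssayDataset, path: str | Path,
                      smiles: Mapping[str, str] | None = None) -> None:
    """Write the assay back out as TSV/CSV (inverse of :func:`read_assay_table`)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    cols = {"compound_id": list(ds.measurements), "value": list(ds.measurements.values())}
    if smiles:
        cols["smiles"] = [smiles.get(cid, "") for cid in ds.measurements]
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False)


def read_smiles_file(path: str | Path) -> list[MoleculeRecord]:
    """Read a SMILES file: one molecule per line, id after whitespace."""
    records = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smi = parts[0]
        cid = parts[1].strip() if len(parts) > 1 else f"mol{i + 1}"
        records.append(MoleculeRecord(id=cid, smiles=smi))
    return records


def write_labels(labelled: LabelledSet, path: str | Path) -> None:
    """Write labels as TSV (compound_id, label 0/1) with a JSON provenance sidecar."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("compound_id\tlabel\n")
        for cid, lab in labelled.labels.items():
            fh.write(f"{cid}\t{int(lab)}\n")
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(labelled.rule, indent=1))


def read_labels(path: str | Path) -> LabelledSet:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"compound_id": str})
    rule_path = path.with_suffix(path.suffix + ".json")
    rule = json.loads(rule_path.read_text()) if rule_path.exists() else {}
    return LabelledSet({str(r.compound_id): bool(r.label) for r in df.itertuples()}, rule)


def write_model(model: "Any", path: str | Path) -> None:
    """Serialize a fitted Bayes model to versioned JSON.

    Round-trip safe: ``read_model(write_model(m))`` scores any molecule
    bit-identically (floats survive JSON via repr round-trip).
    """
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "n_active": model.n_active,
        "n_inactive": model.n_inactive,
        "feature_stats": {t: [a, tot, w] for t, (a, tot, w) in model.feature_stats.items()},
        "descriptor_bins": {k: list(v) for k, v in model.descriptor_bins.items()},
        "classification_threshold": model.classification_threshold,
        "config": dict(model.config),
    }
    Path(path).write_text(json.dumps(payload))


def read_model(path: str | Path) -> "Any":
    from .bayes import BayesModel  # local import to avoid a cycle

    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not a valid model file ({exc})") from exc
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ModelVersionError(
            f"{path}: schema version {version!r}, this build reads {MODEL_SCHEMA_VERSION}"
        )
    return BayesModel(
        n_active=payload["n_active"],
        n_inactive=payload["n_inactive"],
        feature_stats={t: (a, tot, w) for t, (a, tot, w) in payload["feature_stats"].items()},
        descriptor_bins={k: tuple(v) for k, v in payload["descriptor_bins"].items()},
        classification_threshold=payload["classification_threshold"],
        config=payload.get("config", {}),
    )


def build_store(records: Iterable[MoleculeRecord]) -> dict[str, MoleculeRecord]:
    """Index records by id, rejecting duplicate ids."""
    store: dict[str, MoleculeRecord] = {}
    for r in records:
        if r.id in store:
            raise ValueError(f"duplicate molecule id {r.id!r}")
        store[r.id] = r
    return store
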