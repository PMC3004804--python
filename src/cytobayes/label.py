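"""Binary toxic/non-toxic labelling of continuous assay readouts.

Three rules, all with "higher value = more toxic" and strict ``>`` at
the cutoff: a fixed threshold (e.g. pIC50 > 5.5), the top fraction of
compounds by activity (equal hit rates across heterogeneous assays), and
mean + k·SD of the readout distribution (the conservative HTS hit rule).
"""

from __future__ import annotations

import math
import warnings
from statistics import fmean

from .data_model import AssayDataset, LabelledSet


def label_fixed(ds: AssayDataset, cutoff: float) -> LabelledSet:
    """Toxic iff value > cutoff (strict)."""
    if not math.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    labels = {cid: v > cutoff for cid, v in ds.measurements.items()}
    return LabelledSet(labels, {"kind": "fixed_cutoff", "threshold": cutoff})


def label_top_fraction(ds: AssayDataset, fraction: float = 0.20) -> LabelledSet:
    """Label the top ``ceil(fraction*n)`` compounds by value as toxic.

    Ties at the boundary are broken by ascending compound id so the
    labelling is deterministic. ceil (not floor) guarantees at least one
    active even for tiny assays.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if not ds.measurements:
        raise ValueError("dataset is empty")
    n_toxic = math.ceil(fraction * len(ds.measurements))
    ranked = sorted(ds.measurements.items(), key=lambda kv: (-kv[1], kv[0]))
    toxic = {cid for cid, _ in ranked[:n_toxic]}
    labels = {cid: cid in toxic for cid in ds.measurements}
    return LabelledSet(labels, {"kind": "top_fraction", "fraction": fraction})


def label_mean_ksd(
    ds: AssayDataset, k: float = 3.0, population_sd: bool = False
) -> tuple[LabelledSet, float]:
    """Label by value > mean + k·SD; returns (labels, cutoff).

    Sample SD (n−1) by default; ``population_sd`` switches to n. A
    zero-variance assay degenerates to cutoff = mean (with a warning).
    """
    values = list(ds.measurements.values())
    if len(values) < 2:
        raise ValueError("mean + k*SD needs at least 2 measurements")
    mean = fmean(values)
    ddof = 0 if population_sd else 1
    var = sum((v - mean) ** 2 for v in values) / (len(values) - ddof)
    sd = math.sqrt(var)
    if sd == 0:
        warnings.warn(f"{ds.assay_id}: zero variance; cutoff degenerates to the mean")
    cutoff = mean + k * sd
    labels = {cid: v > cutoff for cid, v in ds.measurements.items()}
    rule = {"kind": "mean_plus_ksd", "k": k, "population_sd": population_sd,
            "cutoff": cutoff}
    return LabelledSet(labels, rule), cutoff


def filter_min_actives(labelled: LabelledSet, min_actives: int = 10) -> bool:
    """True iff the set has at least ``min_actives`` toxic compounds.

    Assays failing this filter are too information-poor to train a
    cross-prediction model and are dropped from network panels.
    """
    return labelled.n_toxic >= min_actives


def apply_rule(ds: AssayDataset, rule: dict) -> LabelledSet:
    """Re-apply a stored provenance rule; reproduces the labels exactly."""
    kind = rule.get("kind")
    if kind == "fixed_cutoff":
        return label_fixed(ds, rule["threshold"])
    if kind == "top_fraction":
        return label_top_fraction(ds, rule["fraction"])
    if kind == "mean_plus_ksd":
        return label_mean_ksd(ds, rule["k"], rule.get("population_sd", False))[0]
    raise ValueError(f"unknown label rule {kind!r}")
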