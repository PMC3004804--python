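"""Laplacian-corrected naive Bayes classifier for sparse molecular features.

The learner counts, for every binary feature D, how many training
actives (A_D) and how many training molecules in total (T_D) contain it.
The raw conditional P(active | D) = A_D / T_D is unreliable for rare
features, so it is shrunk toward the baseline hit rate P(active) by
adding K = 1/P(active) virtual samples at that baseline rate:

    P_corr(active | D) = (A_D + P(active)·K) / (T_D + K)

As T_D → 0 the corrected probability converges to P(active): an unseen
or barely-seen feature carries no evidence. A molecule's score is the
sum over its features of ln(P_corr / P(active)) — the log of the product
of relative likelihoods — so 0 is the natural neutral threshold:
positive scores mean above-baseline toxicity likelihood. No feature
pre-selection or class balancing is required; uninformative features get
weights near zero and simply do not matter.

Continuous descriptors participate as categorical tokens: each
descriptor is discretized into quantile bins learned from the training
data, and "descriptor d falls in bin b" behaves exactly like a
fingerprint feature. Values outside the training range map to the
nearest extreme bin.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np

from .data_model import LabelledSet, MoleculeRecord

DEFAULT_DESCRIPTOR_BINS = 10


class DegenerateTrainingError(ValueError):
    """Training set has a single class or too few molecules."""


def laplace_probability(A_D: int, T_D: int, p_active: float) -> float:
    """Laplace-corrected P(active | feature D).

    (A_D + p·K) / (T_D + K) with K = 1/p, which simplifies to
    (A_D + 1) / (T_D + 1/p). Strictly inside (0, 1); equals ``p_active``
    exactly when the feature was never observed (T_D = 0).
    """
    if not 0 < p_active < 1:
        raise DegenerateTrainingError(
            f"baseline active rate must be in (0,1), got {p_active}"
        )
    if not 0 <= A_D <= T_D:
        raise ValueError(f"need 0 <= A_D <= T_D, got A_D={A_D}, T_D={T_D}")
    K = 1.0 / p_active
    return (A_D + p_active * K) / (T_D + K)


@dataclass
class BayesModel:
    """A fitted Laplacian-modified naive Bayes model.

    ``feature_stats`` maps each token (fingerprint feature ``f:<id>`` or
    descriptor-bin token ``d:<name>:<bin>``) to (A_D, T_D, w_D) where
    w_D = ln(P_corr / P(active)) is the additive log-weight.
    """

    n_active: int
    n_inactive: int
    feature_stats: dict[str, tuple[int, int, float]]
    descriptor_bins: dict[str, tuple[float, ...]]
    classification_threshold: float = 0.0
    config: dict[str, Any] = field(default_factory=dict)

    @property
    def p_active(self) -> float:
        return self.n_active / (self.n_active + self.n_inactive)

    @property
    def K(self) -> float:
        return 1.0 / self.p_active

    def tokens(self, record: MoleculeRecord) -> list[str]:
        """All tokens a molecule presents: features plus descriptor bins.

        A molecule missing a descriptor contributes no token for it
        (feature-absent, not imputed).
        """
        toks = [f"f:{fid}" for fid in record.features]
        for name, edges in self.descriptor_bins.items():
            v = record.descriptors.get(name)
            if v is None:
                continue
            b = int(np.searchsorted(edges, v, side="right"))
            toks.append(f"d:{name}:{b}")
        return toks


@dataclass(frozen=True)
class ScoredMolecule:
    id: str
    score: float
    predicted: bool
    n_known_features: int = 0

    @property
    def neutral(self) -> bool:
        """True when no training-time token was present (score forced to 0)."""
        return self.n_known_features == 0


def _learn_bins(
    records: Sequence[MoleculeRecord], n_bins: int
) -> dict[str, tuple[float, ...]]:
    by_name: dict[str, list[float]] = {}
    for r in records:
        for name, v in r.descriptors.items():
            by_name.setdefault(name, []).append(v)
    bins: dict[str, tuple[float, ...]] = {}
    for name, vals in by_name.items():
        qs = np.quantile(vals, np.linspace(0, 1, n_bins + 1)[1:-1])
        # collapse duplicate edges from heavily tied descriptors (e.g. counts)
        edges = tuple(dict.fromkeys(float(q) for q in qs))
        bins[name] = edges
    return bins


def fit(
    records: Sequence[MoleculeRecord],
    labels: LabelledSet,
    n_descriptor_bins: int = DEFAULT_DESCRIPTOR_BINS,
    use_descriptors: bool = True,
) -> BayesModel:
    """Fit the model: learn descriptor bins, count per-token class stats.

    Requires at least 2 molecules and both classes present. Training is
    one linear pass; identical input yields an identical model.
    """
    records = list(records)
    if len(records) < 2:
        raise DegenerateTrainingError("need at least 2 training molecules")
    missing = [r.id for r in records if r.id not in labels.labels]
    if missing:
        raise ValueError(f"unlabelled training molecules: {missing[:5]}")
    n_active = sum(labels.labels[r.id] for r in records)
    n_inactive = len(records) - n_active
    if n_active == 0 or n_inactive == 0:
        raise DegenerateTrainingError(
            "degenerate training set: both classes must be present"
        )

    model = BayesModel(
        n_active=n_active,
        n_inactive=n_inactive,
        feature_stats={},
        descriptor_bins=_learn_bins(records, n_descriptor_bins) if use_descriptors else {},
        config={"n_descriptor_bins": n_descriptor_bins, "use_descriptors": use_descriptors},
    )
    p = model.p_active
    counts: dict[str, list[int]] = {}
    for r in records:
        is_active = labels.labels[r.id]
        for tok in model.tokens(r):
            c = counts.setdefault(tok, [0, 0])
            c[0] += is_active
            c[1] += 1
    log_p = math.log(p)
    model.feature_stats = {
        tok: (a, t, math.log(laplace_probability(a, t, p)) - log_p)
        for tok, (a, t) in counts.items()
    }
    return model


def score(model: BayesModel, record: MoleculeRecord) -> ScoredMolecule:
    """Score one molecule: sum of log-weights over its known tokens.

    Tokens unseen in training contribute 0 (they carry no evidence), so
    a molecule with no known tokens scores exactly 0 — neutral.
    """
    total = 0.0
    n_known = 0
    stats = model.feature_stats
    for tok in model.tokens(record):
        entry = stats.get(tok)
        if entry is not None:
            total += entry[2]
            n_known += 1
    return ScoredMolecule(
        id=record.id,
        score=total,
        predicted=total > model.classification_threshold,
        n_known_features=n_known,
    )


def score_batch(
    model: BayesModel, records: Iterable[MoleculeRecord]
) -> dict[str, ScoredMolecule]:
    return {r.id: score(model, r) for r in records}


def choose_threshold(
    scores: Mapping[str, float],
    labels: LabelledSet | None = None,
    method: str = "zero",
) -> float:
    """Pick the classification threshold.

    ``zero`` returns 0 (the model's neutral point). ``best_split``
    maximizes Youden's J = sensitivity + specificity − 1 over midpoints
    between adjacent distinct scores on labelled data; ties resolve to
    the lower threshold.
    """
    if method == "zero":
        return 0.0
    if method != "best_split":
        raise ValueError(f"unknown threshold method {method!r}")
    if labels is None:
        raise ValueError("best_split requires labelled data")
    pairs = [(s, labels.labels[cid]) for cid, s in scores.items()]
    uniq = sorted({s for s, _ in pairs})
    if len(uniq) == 1:
        warnings.warn("all scores identical; threshold degenerate, J=0")
        return uniq[0]
    n_pos = sum(lab for _, lab in pairs)
    n_neg = len(pairs) - n_pos
    candidates = [(uniq[i] + uniq[i + 1]) / 2 for i in range(len(uniq) - 1)]
    candidates = [uniq[0] - 1.0] + candidates  # allow "everything positive"
    best_t, best_j = candidates[0], -math.inf
    for t in candidates:
        tp = sum(1 for s, lab in pairs if lab and s > t)
        tn = sum(1 for s, lab in pairs if not lab and s <= t)
        j = tp / n_pos + tn / n_neg - 1
        if j > best_j:  # strict: ties keep the lower threshold
            best_t, best_j = t, j
    return best_t
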