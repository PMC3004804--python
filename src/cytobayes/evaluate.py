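"""ROC analysis, truth tables, cross-validation, cutoff scanning and
chemical-space similarity diagnostics.

The ROC score (AUC) is computed as the Mann-Whitney rank statistic with
midranks for ties: the probability that a randomly chosen active
outranks a randomly chosen inactive. This equals the trapezoidal area
under the (FPR, TPR) curve traced over all thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from . import bayes
from .data_model import AssayDataset, LabelledSet, MoleculeRecord, TruthTable
from .featurize import tanimoto


class SingleClassError(ValueError):
    pass


@dataclass
class ROCResult:
    auc: float
    curve: list[tuple[float, float]]
    n_pos: int
    n_neg: int


def roc_auc(scores: Mapping[str, float], labels: LabelledSet) -> ROCResult:
    """Rank-based ROC score with midrank tie handling, plus the ROC curve."""
    ids = list(scores)
    y = np.array([labels.labels[cid] for cid in ids], dtype=bool)
    s = np.array([scores[cid] for cid in ids], dtype=float)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0:
        raise SingleClassError("no positive (toxic) compounds in the evaluation set")
    if n_neg == 0:
        raise SingleClassError("no negative (non-toxic) compounds in the evaluation set")
    ranks = rankdata(s)  # midranks for ties
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    # curve: sweep thresholds from high to low, grouping tied scores
    order = np.argsort(-s, kind="mergesort")
    ys = y[order]
    ss = s[order]
    curve = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = len(ss)
    while i < n:
        j = i
        while j < n and ss[j] == ss[i]:
            j += 1
        tp += int(ys[i:j].sum())
        fp += (j - i) - int(ys[i:j].sum())
        curve.append((fp / n_neg, tp / n_pos))
        i = j
    return ROCResult(auc=float(auc), curve=curve, n_pos=n_pos, n_neg=n_neg)


def truth_table(
    scored: Iterable[bayes.ScoredMolecule], labels: LabelledSet
) -> TruthTable:
    """Confusion matrix of predicted vs experimental class.

    Derived rates (sensitivity TP/(TP+FN), specificity TN/(TN+FP),
    accuracy) are properties of the returned table; an empty denominator
    yields None rather than propagating NaN.
    """
    tp = fp = tn = fn = 0
    for sm in scored:
        actual = labels.labels[sm.id]
        if sm.predicted and actual:
            tp += 1
        elif sm.predicted:
            fp += 1
        elif actual:
            fn += 1
        else:
            tn += 1
    return TruthTable(tp=tp, fp=fp, tn=tn, fn=fn)


def constant_classifier_accuracy(labels: LabelledSet, predict_toxic: bool) -> float:
    """Accuracy of the trivial all-toxic / all-non-toxic baseline.

    Equals the toxic prevalence (all-toxic) or 1 − prevalence
    (all-non-toxic); the sanity floor any real model must beat.
    """
    prev = labels.prevalence
    return prev if predict_toxic else 1.0 - prev


@dataclass
class CVResult:
    k: int
    fold_rocs: list[ROCResult | None]
    fold_tables: list[TruthTable]
    mean_auc: float
    sd_auc: float
    seed: int
    warnings: list[str] = field(default_factory=list)

    @property
    def aucs(self) -> list[float]:
        return [r.auc for r in self.fold_rocs if r is not None]


def _folds(ids: Sequence[str], k: int, seed: int) -> list[list[str]]:
    rng = np.random.default_rng(seed)
    perm = list(np.array(ids, dtype=object)[rng.permutation(len(ids))])
    return [perm[i::k] for i in range(k)]


def kfold_cv(
    records: Sequence[MoleculeRecord],
    labels: LabelledSet,
    k: int = 5,
    seed: int = 0,
    **fit_kwargs: Any,
) -> CVResult:
    """k-fold cross-validation: k random equal-sized splits (unstratified),
    fit on k−1 folds, evaluate ROC and the threshold-0 truth table on the
    held-out fold. Reports mean ± sample SD of the fold AUCs.

    A fold whose test part has a single class gets an undefined ROC,
    excluded from the mean with a warning.
    """
    records = list(records)
    by_id = {r.id: r for r in records}
    n_pos = sum(labels.labels[r.id] for r in records)
    msgs: list[str] = []
    if min(n_pos, len(records) - n_pos) < k:
        msgs.append(
            f"minority class has fewer than k={k} members; folds may be single-class"
        )
        warnings.warn(msgs[-1])
    folds = _folds([r.id for r in records], k, seed)
    fold_rocs: list[ROCResult | None] = []
    fold_tables: list[TruthTable] = []
    for i in range(k):
        test_ids = folds[i]
        train_ids = [cid for j in range(k) if j != i for cid in folds[j]]
        model = bayes.fit(
            [by_id[cid] for cid in train_ids],
            LabelledSet({cid: labels.labels[cid] for cid in train_ids}),
            **fit_kwargs,
        )
        scored = bayes.score_batch(model, (by_id[cid] for cid in test_ids))
        test_labels = LabelledSet({cid: labels.labels[cid] for cid in test_ids})
        fold_tables.append(truth_table(scored.values(), test_labels))
        try:
            fold_rocs.append(
                roc_auc({cid: sm.score for cid, sm in scored.items()}, test_labels)
            )
        except SingleClassError as exc:
            msgs.append(f"fold {i}: ROC undefined ({exc})")
            warnings.warn(msgs[-1])
            fold_rocs.append(None)
    aucs = [r.auc for r in fold_rocs if r is not None]
    mean = float(np.mean(aucs)) if aucs else float("nan")
    sd = float(np.std(aucs, ddof=1)) if len(aucs) > 1 else float("nan")
    return CVResult(k=k, fold_rocs=fold_rocs, fold_tables=fold_tables,
                    mean_auc=mean, sd_auc=sd, seed=seed, warnings=msgs)


@dataclass
class CutoffScan:
    grid: list[float]
    auc_at_cutoff: dict[float, float | None]
    skipped: dict[float, str]
    optimum: float | None

    def to_rows(self) -> list[tuple[float, float | None]]:
        return [(c, self.auc_at_cutoff.get(c)) for c in self.grid]


def default_cutoff_grid(lo: float = -20.0, hi: float = 100.0, step: float = 1.0) -> list[float]:
    n = int(round((hi - lo) / step))
    return [lo + i * step for i in range(n + 1)]


def cutoff_scan(
    primary: AssayDataset,
    records: Sequence[MoleculeRecord],
    confirmed_actives: set[str],
    grid: Sequence[float] | None = None,
    eval_mode: str = "full",
    k: int = 5,
    seed: int = 0,
    **fit_kwargs: Any,
) -> CutoffScan:
    """Activity-cutoff optimisation for a percent-inhibition screen.

    One model is trained per candidate cutoff (toxic iff value > cutoff)
    and judged by its ROC score at retrieving the confirmed actives
    (e.g. follow-up IC50 hits) as positives against all other screened
    compounds as negatives. ``full`` trains on all data and scores every
    compound; ``cv`` averages the ROC over k held-out folds. The optimum
    is the cutoff with the highest (mean) ROC, ties going to the lowest
    cutoff. Grid points leaving fewer than 2 compounds in either class
    are skipped with a reason.
    """
    if grid is None:
        grid = default_cutoff_grid()
    grid = sorted(grid)
    if not grid:
        raise ValueError("cutoff grid is empty")
    unknown = confirmed_actives - set(primary.measurements)
    if unknown:
        raise ValueError(f"confirmed actives not in the primary screen: {sorted(unknown)[:5]}")
    if eval_mode not in {"full", "cv"}:
        raise ValueError(f"unknown eval_mode {eval_mode!r}")
    records = [r for r in records if r.id in primary.measurements]
    by_id = {r.id: r for r in records}
    eval_labels = LabelledSet(
        {cid: cid in confirmed_actives for cid in primary.measurements},
        {"kind": "confirmed_actives"},
    )

    aucs: dict[float, float | None] = {}
    skipped: dict[float, str] = {}
    for cutoff in grid:
        train_labels = {cid: v > cutoff for cid, v in primary.measurements.items()}
        n_act = sum(train_labels.values())
        if n_act < 2 or len(train_labels) - n_act < 2:
            skipped[cutoff] = (
                f"cutoff {cutoff} leaves {n_act} actives / "
                f"{len(train_labels) - n_act} inactives (need >= 2 each)"
            )
            aucs[cutoff] = None
            continue
        tl = LabelledSet(train_labels, {"kind": "fixed_cutoff", "threshold": cutoff})
        if eval_mode == "full":
            model = bayes.fit(records, tl, **fit_kwargs)
            scores = {cid: sm.score for cid, sm in bayes.score_batch(model, records).items()}
            aucs[cutoff] = roc_auc(scores, eval_labels).auc
        else:
            fold_aucs = []
            for i, test_ids in enumerate(_folds(list(by_id), k, seed)):
                train_ids = [cid for cid in by_id if cid not in set(test_ids)]
                sub = LabelledSet({cid: train_labels[cid] for cid in train_ids}, tl.rule)
                if not 0 < sum(sub.labels.values()) < len(train_ids):
                    continue
                model = bayes.fit([by_id[c] for c in train_ids], sub, **fit_kwargs)
                scores = {
                    c: bayes.score(model, by_id[c]).score for c in test_ids
                }
                try:
                    fold_aucs.append(
                        roc_auc(scores, LabelledSet(
                            {c: eval_labels.labels[c] for c in test_ids})).auc
                    )
                except SingleClassError:
                    continue
            aucs[cutoff] = float(np.mean(fold_aucs)) if fold_aucs else None

    defined = [(c, a) for c, a in aucs.items() if a is not None]
    optimum = None
    if defined:
        best = max(a for _, a in defined)
        optimum = min(c for c, a in defined if a == best)  # ties -> lowest cutoff
    return CutoffScan(grid=list(grid), auc_at_cutoff=aucs, skipped=skipped, optimum=optimum)


def max_within_class_similarity(
    records: Sequence[MoleculeRecord], labels: LabelledSet
) -> dict[str, float | None]:
    """Per-compound maximum Tanimoto similarity to any other same-class
    compound. A compound alone in its class gets None. Class means of
    these maxima diagnose how clustered each class is in chemical space:
    a tight toxic class is learnable, a scattered one is not.
    """
    by_class: dict[bool, list[MoleculeRecord]] = {True: [], False: []}
    for r in records:
        by_class[labels.labels[r.id]].append(r)
    out: dict[str, float | None] = {}
    for cls, members in by_class.items():
        for r in members:
            best = None
            for other in members:
                if other.id == r.id:
                    continue
                t = tanimoto(r.features, other.features)
                if best is None or t > best:
                    best = t
            out[r.id] = best
    return out


def class_mean_similarity(
    sim: Mapping[str, float | None], labels: LabelledSet
) -> dict[bool, float]:
    """Mean of the per-compound maxima, per class, ignoring undefined entries."""
    sums: dict[bool, list[float]] = {True: [], False: []}
    for cid, v in sim.items():
        if v is not None:
            sums[labels.labels[cid]].append(v)
    return {cls: (float(np.mean(v)) if v else float("nan")) for cls, v in sums.items()}


def cross_set_similarity(
    query_records: Sequence[MoleculeRecord],
    reference_records: Sequence[MoleculeRecord],
    reference_labels: LabelledSet,
) -> dict[str, tuple[float, float]]:
    """For each query compound: (max Tanimoto vs toxic references,
    max vs non-toxic references)."""
    tox = [r for r in reference_records if reference_labels.labels[r.id]]
    nontox = [r for r in reference_records if not reference_labels.labels[r.id]]
    if not tox or not nontox:
        raise SingleClassError("both reference classes must be non-empty")
    out = {}
    for q in query_records:
        out[q.id] = (
            max(tanimoto(q.features, r.features) for r in tox),
            max(tanimoto(q.features, r.features) for r in nontox),
        )
    return out


@dataclass
class AgreementTable:
    edges_a: np.ndarray
    edges_b: np.ndarray
    counts: np.ndarray        # shape (n_bins, n_bins)
    toxic_fraction: np.ndarray  # NaN where a cell is empty


def score_agreement_table(
    scores_a: Mapping[str, float],
    scores_b: Mapping[str, float],
    labels: LabelledSet,
    n_bins: int = 16,
) -> AgreementTable:
    """2-D binned comparison of two models' scores on the same compounds.

    Equal-width bins over each score range; each cell carries a total
    count and the toxic fraction within it (the data behind a binned
    pie-chart panel). Agreement concentrates mass on the diagonal; for
    two useful toxicity models the toxic fraction rises toward the
    high-high corner.
    """
    ids = [cid for cid in scores_a if cid in scores_b]
    if not ids:
        raise ValueError("score maps share no compound ids")
    a = np.array([scores_a[c] for c in ids])
    b = np.array([scores_b[c] for c in ids])
    y = np.array([labels.labels[c] for c in ids], dtype=bool)

    def edges(x: np.ndarray) -> np.ndarray:
        if x.min() == x.max():
            warnings.warn("constant scores on one axis; using a single bin")
            return np.array([x.min() - 0.5, x.max() + 0.5])
        return np.linspace(x.min(), x.max(), n_bins + 1)

    ea, eb = edges(a), edges(b)
    ia = np.clip(np.digitize(a, ea) - 1, 0, len(ea) - 2)
    ib = np.clip(np.digitize(b, eb) - 1, 0, len(eb) - 2)
    counts = np.zeros((len(ea) - 1, len(eb) - 1), dtype=int)
    tox = np.zeros_like(counts)
    for i, j, t in zip(ia, ib, y):
        counts[i, j] += 1
        tox[i, j] += t
    with np.errstate(invalid="ignore"):
        frac = np.where(counts > 0, tox / np.maximum(counts, 1), np.nan)
    return AgreementTable(edges_a=ea, edges_b=eb, counts=counts, toxic_fraction=frac)


def write_roc_tsv(roc: ROCResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("fpr\ttpr\n")
        for fpr, tpr in roc.curve:
            fh.write(f"{fpr!r}\t{tpr!r}\n")


def write_scan_tsv(scan: CutoffScan, path) -> None:
    with open(path, "w") as fh:
        fh.write("cutoff\troc\n")
        for c, a in scan.to_rows():
            fh.write(f"{c!r}\t{'' if a is None else repr(a)}\n")
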