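import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytobayes import bayes, evaluate, label
from cytobayes.bayes import ScoredMolecule
from cytobayes.data_model import LabelledSet, TruthTable
from cytobayes.evaluate import (
    SingleClassError,
    constant_classifier_accuracy,
    cutoff_scan,
    kfold_cv,
    roc_auc,
    truth_table,
)

from conftest import make_record


def brute_force_auc(scores, labels):
    """Pairwise concordance count: the Mann-Whitney definition, directly."""
    pos = [s for c, s in scores.items() if labels.labels[c]]
    neg = [s for c, s in scores.items() if not labels.labels[c]]
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg
    )
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        scores = {"a": 3.0, "b": 2.0, "c": -1.0, "d": -2.0}
        labels = LabelledSet({"a": True, "b": True, "c": False, "d": False})
        r = roc_auc(scores, labels)
        assert r.auc == 1.0
        assert r.curve[0] == (0.0, 0.0) and r.curve[-1] == (1.0, 1.0)

    def test_four_point_example(self):
        scores = {"a": 3.0, "b": 2.0, "c": 1.0, "d": 0.0}
        labels = LabelledSet({"a": True, "b": False, "c": True, "d": False})
        # brute force over the 4 pos x neg pairs: 3 wins, 1 loss
        assert roc_auc(scores, labels).auc == pytest.approx(0.75)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        labels = LabelledSet({f"m{i}": i < 2500 for i in range(5000)})
        scores = {f"m{i}": float(v) for i, v in enumerate(rng.random(5000))}
        assert roc_auc(scores, labels).auc == pytest.approx(0.5, abs=0.03)

    def test_single_class_error_names_class(self):
        with pytest.raises(SingleClassError, match="positive"):
            roc_auc({"a": 1.0}, LabelledSet({"a": False}))
        with pytest.raises(SingleClassError, match="negative"):
            roc_auc({"a": 1.0}, LabelledSet({"a": True}))

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(42)
        for trial in range(25):
            n = int(rng.integers(5, 120))
            scores = {f"m{i}": float(rng.integers(0, 6)) for i in range(n)}
            y = {f"m{i}": bool(rng.random() < 0.4) for i in range(n)}
            if len(set(y.values())) < 2:
                continue
            labels = LabelledSet(y)
            assert roc_auc(scores, labels).auc == pytest.approx(
                brute_force_auc(scores, labels)
            )

    def test_matches_sklearn_oracle(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(5)
        ids = [f"m{i}" for i in range(300)]
        scores = {c: float(rng.normal()) for c in ids}
        labels = LabelledSet({c: bool(rng.random() < 0.3) for c in ids})
        ours = roc_auc(scores, labels).auc
        theirs = sk.roc_auc_score(
            [labels.labels[c] for c in ids], [scores[c] for c in ids]
        )
        assert ours == pytest.approx(theirs, abs=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(shift=st.floats(min_value=-5, max_value=5),
           scale=st.floats(min_value=0.01, max_value=10))
    def test_invariant_under_increasing_transform(self, shift, scale):
        rng = np.random.default_rng(1)
        ids = [f"m{i}" for i in range(50)]
        scores = {c: float(rng.normal()) for c in ids}
        labels = LabelledSet({c: i % 3 == 0 for i, c in enumerate(ids)})
        transformed = {c: scale * s + shift for c, s in scores.items()}
        assert roc_auc(transformed, labels).auc == pytest.approx(
            roc_auc(scores, labels).auc
        )

    def test_sign_flip_maps_auc_to_complement(self):
        rng = np.random.default_rng(2)
        ids = [f"m{i}" for i in range(80)]
        scores = {c: float(rng.normal()) for c in ids}
        labels = LabelledSet({c: i % 4 == 0 for i, c in enumerate(ids)})
        a = roc_auc(scores, labels).auc
        b = roc_auc({c: -s for c, s in scores.items()}, labels).auc
        assert a + b == pytest.approx(1.0)

    def test_curve_monotone(self):
        rng = np.random.default_rng(3)
        ids = [f"m{i}" for i in range(60)]
        scores = {c: float(rng.integers(0, 4)) for c in ids}
        labels = LabelledSet({c: i % 2 == 0 for i, c in enumerate(ids)})
        curve = roc_auc(scores, labels).curve
        xs, ys = zip(*curve)
        assert list(xs) == sorted(xs) and list(ys) == sorted(ys)


class TestTruthTable:
    def test_counts_and_rates(self):
        scored = [
            ScoredMolecule("a", 1.0, True), ScoredMolecule("b", 1.0, True),
            ScoredMolecule("c", -1.0, False), ScoredMolecule("d", -1.0, False),
        ]
        labels = LabelledSet({"a": True, "b": False, "c": True, "d": False})
        t = truth_table(scored, labels)
        assert (t.tp, t.fp, t.fn, t.tn) == (1, 1, 1, 1)
        assert t.sensitivity == 0.5 and t.specificity == 0.5 and t.accuracy == 0.5

    def test_mean_percentage_cells_give_printed_rates(self):
        # a cross-validated percent-cell table: sensitivity 21/37, specificity 45/63
        t = TruthTable(tp=21, fn=16, fp=18, tn=45)
        assert round(t.sensitivity, 2) == 0.57
        assert round(t.specificity, 2) == 0.71

    def test_undefined_rates_are_none(self):
        t = TruthTable(tp=0, fn=0, fp=2, tn=3)
        assert t.sensitivity is None
        assert t.specificity == 0.6

    def test_all_toxic_baseline_equals_prevalence(self):
        labels = LabelledSet({f"m{i}": i < 640 for i in range(775)})
        acc = constant_classifier_accuracy(labels, predict_toxic=True)
        assert acc == pytest.approx(640 / 775)
        assert round(100 * acc) == 83

    def test_all_nontoxic_baseline_complements_prevalence(self):
        labels = LabelledSet({f"m{i}": i < 37 for i in range(100)})
        acc = constant_classifier_accuracy(labels, predict_toxic=False)
        assert acc == pytest.approx(0.63)


class TestKFoldCV:
    def test_learnable_synthetic_set(self, universe, default_screen):
        labels = label.label_top_fraction(default_screen, 0.2)
        recs = [universe.store[c] for c in default_screen.measurements]
        cv = kfold_cv(recs, labels, k=5, seed=1)
        assert cv.mean_auc >= 0.8
        assert len(cv.fold_rocs) == 5

    def test_shuffled_labels_near_half(self, universe, default_screen):
        labels = label.label_top_fraction(default_screen, 0.2)
        rng = np.random.default_rng(0)
        vals = list(labels.labels.values())
        rng.shuffle(vals)
        shuffled = LabelledSet(dict(zip(labels.labels, vals)))
        recs = [universe.store[c] for c in default_screen.measurements]
        cv = kfold_cv(recs, shuffled, k=5, seed=1)
        assert cv.mean_auc == pytest.approx(0.5, abs=0.05)

    def test_same_seed_reproduces(self, toy_records_medium):
        recs, labels = toy_records_medium
        a = kfold_cv(recs, labels, k=4, seed=9)
        b = kfold_cv(recs, labels, k=4, seed=9)
        assert a.aucs == b.aucs

    def test_folds_partition_and_balance(self, toy_records_medium):
        recs, labels = toy_records_medium
        folds = evaluate._folds([r.id for r in recs], 5, seed=3)
        flat = [c for f in folds for c in f]
        assert sorted(flat) == sorted(r.id for r in recs)
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1

    def test_leave_one_out_structure(self):
        recs = [make_record(f"m{i}", {i % 3, 10 + i % 2}) for i in range(8)]
        labels = LabelledSet({r.id: i % 2 == 0 for i, r in enumerate(recs)})
        with pytest.warns(UserWarning):
            cv = kfold_cv(recs, labels, k=len(recs), seed=0)
        assert len(cv.fold_rocs) == len(recs)
        # every singleton test fold is single-class: all ROCs undefined
        assert all(r is None for r in cv.fold_rocs)


class TestCutoffScan:
    def test_single_point_grid(self, followup_scenario):
        fs = followup_scenario
        scan = cutoff_scan(fs.primary, fs.universe.records, fs.confirmed_actives,
                           grid=[30.0])
        assert scan.optimum == 30.0

    def test_degenerate_cutoffs_skipped_with_reason(self, followup_scenario):
        fs = followup_scenario
        # no value exceeds the clip ceiling, so the top grid point is empty
        scan = cutoff_scan(fs.primary, fs.universe.records, fs.confirmed_actives,
                           grid=[100.0])
        assert scan.optimum is None
        assert "actives" in scan.skipped[100.0]

    def test_unknown_confirmed_ids_rejected(self, followup_scenario):
        fs = followup_scenario
        with pytest.raises(ValueError, match="not in the primary screen"):
            cutoff_scan(fs.primary, fs.universe.records, {"nope"}, grid=[30.0])

    def test_tie_resolves_to_lowest_cutoff(self):
        # two cutoffs between the same pair of adjacent values label
        # identically, so their models and AUCs tie exactly
        from cytobayes.data_model import AssayDataset

        rng = np.random.default_rng(4)
        recs = [make_record(f"m{i}", {i % 4, 10 + (i // 8)}) for i in range(32)]
        values = {r.id: (80.0 if i % 4 == 0 else float(rng.uniform(0, 20)))
                  for i, r in enumerate(recs)}
        ds = AssayDataset("p", "percent_inhibition", values)
        confirmed = {r.id for i, r in enumerate(recs) if i % 4 == 0}
        scan = cutoff_scan(ds, recs, confirmed, grid=[40.0, 50.0], use_descriptors=False)
        assert scan.auc_at_cutoff[40.0] == scan.auc_at_cutoff[50.0]
        assert scan.optimum == 40.0

    def test_cv_mode_runs(self, followup_scenario):
        fs = followup_scenario
        scan = cutoff_scan(fs.primary, fs.universe.records, fs.confirmed_actives,
                           grid=[30.0, 50.0], eval_mode="cv", seed=2)
        assert all(a is not None for a in scan.auc_at_cutoff.values())


class TestSimilarityDiagnostics:
    def test_identical_pair_and_singleton(self):
        recs = [
            make_record("t1", {1, 2}), make_record("t2", {1, 2}),
            make_record("t3", {30, 31}),
            make_record("n1", {5, 6}), make_record("n2", {7, 8}),
        ]
        labels = LabelledSet({"t1": True, "t2": True, "t3": True,
                              "n1": False, "n2": False})
        sim = evaluate.max_within_class_similarity(recs, labels)
        assert sim["t1"] == sim["t2"] == 1.0
        assert sim["t3"] == 0.0  # toxic but disjoint from the other toxics
        assert sim["n1"] == 0.0

    def test_singleton_class_undefined(self):
        recs = [make_record("t1", {1}), make_record("n1", {2}),
                make_record("n2", {2, 3})]
        labels = LabelledSet({"t1": True, "n1": False, "n2": False})
        sim = evaluate.max_within_class_similarity(recs, labels)
        assert sim["t1"] is None

    def test_clustered_toxics_score_higher(self, universe, default_screen):
        # SAR series make same-series toxics near neighbours of each other
        labels = label.label_top_fraction(default_screen, 0.2)
        sample_ids = sorted(default_screen.measurements)[:300]
        recs = [universe.store[c] for c in sample_ids]
        sub = LabelledSet({c: labels.labels[c] for c in sample_ids})
        means = evaluate.class_mean_similarity(
            evaluate.max_within_class_similarity(recs, sub), sub)
        assert means[True] > 0.2

    def test_cross_set_similarity_hand_values(self):
        refs = [make_record("rt", {1, 2, 3}), make_record("rn", {7, 8})]
        ref_labels = LabelledSet({"rt": True, "rn": False})
        out = evaluate.cross_set_similarity(
            [make_record("q", {2, 3, 7})], refs, ref_labels)
        vs_toxic, vs_nontoxic = out["q"]
        assert vs_toxic == pytest.approx(2 / 4)
        assert vs_nontoxic == pytest.approx(1 / 4)

    def test_query_identical_to_toxic_ref(self):
        refs = [make_record("rt", {1, 2}), make_record("rn", {9})]
        out = evaluate.cross_set_similarity(
            [make_record("q", {1, 2})], refs, LabelledSet({"rt": True, "rn": False}))
        assert out["q"][0] == 1.0


class TestScoreAgreement:
    def test_identical_scores_concentrate_on_diagonal(self):
        rng = np.random.default_rng(0)
        scores = {f"m{i}": float(rng.normal()) for i in range(200)}
        labels = LabelledSet({c: i % 5 == 0 for i, c in enumerate(scores)})
        table = evaluate.score_agreement_table(scores, scores, labels, n_bins=8)
        off_diagonal = table.counts.sum() - np.trace(table.counts)
        assert off_diagonal == 0

    def test_constant_axis_warns(self):
        scores_a = {"a": 1.0, "b": 1.0}
        scores_b = {"a": 0.0, "b": 2.0}
        labels = LabelledSet({"a": True, "b": False})
        with pytest.warns(UserWarning, match="constant"):
            table = evaluate.score_agreement_table(scores_a, scores_b, labels)
        assert table.counts.shape[0] == 1

    def test_counts_complete_and_fractions_valid(self):
        rng = np.random.default_rng(1)
        a = {f"m{i}": float(rng.normal()) for i in range(150)}
        b = {f"m{i}": float(rng.normal()) for i in range(150)}
        labels = LabelledSet({c: bool(rng.random() < 0.3) for c in a})
        t = evaluate.score_agreement_table(a, b, labels)
        assert t.counts.sum() == 150
        frac = t.toxic_fraction[~np.isnan(t.toxic_fraction)]
        assert ((frac >= 0) & (frac <= 1)).all()


@pytest.fixture
def toy_records_medium():
    rng = np.random.default_rng(8)
    recs = [
        make_record(f"m{i}", set(rng.choice(40, size=8, replace=False).tolist()))
        for i in range(60)
    ]
    labels = LabelledSet({r.id: bool(rng.random() < 0.4) for r in recs})
    return recs, labels
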