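"""Evaluation statistics against independent oracles and hand computations."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from sitbdetect.evaluation import (
    RocCurve,
    agreement_stats,
    auroc,
    confusion_metrics,
    cv_confidence_interval,
    delong_paired,
    delong_variance,
    mean_roc,
    pairwise_comparison_matrix,
    permutation_importance,
    roc_points,
    subgroup_audit,
)


def auroc_all_pairs(scores, labels):
    """Oracle: concordance over every positive-negative pair, ties credit 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_constant_scores(self):
        assert auroc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_tied_pair_half_credit(self):
        assert auroc([0.9, 0.5, 0.5, 0.1], [1, 1, 0, 0]) == pytest.approx(0.875)

    def test_single_class_undefined(self):
        assert np.isnan(auroc([0.2, 0.8], [1, 1]))

    @pytest.mark.parametrize("n", [10, 50, 200])
    def test_matches_all_pairs_oracle(self, n):
        rng = np.random.default_rng(n)
        scores = np.round(rng.random(n), 2)  # rounding forces some ties
        labels = rng.integers(0, 2, n)
        if len(np.unique(labels)) < 2:
            labels[0] = 1 - labels[0]
        assert auroc(scores, labels) == pytest.approx(auroc_all_pairs(scores, labels))

    @given(st.integers(0, 1000))
    def test_complement_invariant(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        scores = rng.random(n)  # continuous: tie-free a.s.
        labels = rng.integers(0, 2, n)
        if len(np.unique(labels)) < 2:
            labels[0] = 1 - labels[0]
        assert auroc(scores, labels) + auroc(scores, 1 - labels) == pytest.approx(1.0)


class TestConfusionMetrics:
    def test_perfect_predictions(self):
        b = confusion_metrics([1, 0, 1], [1, 0, 1])
        for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
            assert getattr(b, name).value == 1.0

    def test_hand_checked_two_by_two(self):
        # TP=40, FP=10, FN=20, TN=30
        labels = [1] * 60 + [0] * 40
        preds = [1] * 40 + [0] * 20 + [1] * 10 + [0] * 30
        b = confusion_metrics(preds, labels)
        assert b.sensitivity.value == pytest.approx(0.667, abs=5e-4)
        assert b.specificity.value == pytest.approx(0.75)
        assert b.ppv.value == pytest.approx(0.8)
        assert b.npv.value == pytest.approx(0.6)
        assert b.accuracy.value == pytest.approx(0.7)

    def test_empty_denominators_flagged(self):
        b = confusion_metrics([0, 0, 0], [0, 0, 0])
        assert b.sensitivity.value is None
        assert b.ppv.value is None
        assert b.specificity.value == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_metrics([1, 0], [1])


def delong_permutation_oracle(a, b, labels, n_reps=20000, seed=0):
    """Paired exchangeability oracle: randomly swap the two score vectors
    per subject; two-sided p for the AUROC difference."""
    from scipy.stats import rankdata

    rng = np.random.default_rng(seed)
    a, b = np.asarray(a, float), np.asarray(b, float)
    labels = np.asarray(labels, int)
    pos = labels == 1
    m, nneg = pos.sum(), (~pos).sum()

    def batch_auroc(S):  # rows = replicates
        ranks = rankdata(S, axis=1)
        return (ranks[:, pos].sum(axis=1) - m * (m + 1) / 2) / (m * nneg)

    observed = abs(auroc(a, labels) - auroc(b, labels))
    swap = rng.integers(0, 2, size=(n_reps, len(a))).astype(bool)
    A = np.where(swap, b, a)
    B = np.where(swap, a, b)
    diffs = np.abs(batch_auroc(A) - batch_auroc(B))
    return float(np.mean(diffs >= observed - 1e-12))


class TestDelong:
    def test_identical_scores_degenerate(self):
        labels = [1, 0, 1, 0, 1, 0]
        s = [0.8, 0.3, 0.7, 0.2, 0.9, 0.4]
        res = delong_paired(s, s, labels)
        assert res.z == 0.0 and res.p == 1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        a, b = rng.random(60), rng.random(60)
        r1 = delong_paired(a, b, labels)
        r2 = delong_paired(b, a, labels)
        assert r1.z == pytest.approx(-r2.z)
        assert r1.p == pytest.approx(r2.p)

    def test_p_in_unit_interval_and_var_nonnegative(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            labels = rng.integers(0, 2, 40)
            labels[:2] = [0, 1]
            res = delong_paired(rng.random(40), rng.random(40), labels)
            assert 0.0 < res.p <= 1.0
        a, var = delong_variance(rng.random(40), labels)
        assert var >= 0.0

    def test_agrees_with_permutation_oracle(self):
        # n=30 paired design; Monte-Carlo tolerance on 20,000 replicates
        rng = np.random.default_rng(7)
        n = 30
        labels = np.array([1] * 15 + [0] * 15)
        base = rng.normal(size=n) + labels * 1.2
        a = base + rng.normal(scale=0.6, size=n)
        b = base + rng.normal(scale=0.9, size=n)
        res = delong_paired(a, b, labels)
        p_perm = delong_permutation_oracle(a, b, labels, n_reps=20000, seed=3)
        assert res.p == pytest.approx(p_perm, abs=0.07)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            delong_paired([0.1, 0.2], [0.3], [1, 0])

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_cross_check_against_pROC(self, tmp_path):
        """Independent implementation check: R pROC's paired roc.test."""
        rng = np.random.default_rng(11)
        n = 80
        labels = np.array([1] * 40 + [0] * 40)
        a = rng.normal(size=n) + labels * 1.0
        b = rng.normal(size=n) + labels * 0.6
        df = pd.DataFrame({"y": labels, "a": a, "b": b})
        csv = tmp_path / "scores.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "delong.R"
        script.write_text(
            'suppressMessages(library(pROC))\n'
            f'd <- read.csv("{csv}")\n'
            'r <- roc.test(roc(d$y, d$a, quiet=TRUE), roc(d$y, d$b, quiet=TRUE),'
            ' method="delong", paired=TRUE)\n'
            'cat(r$statistic, r$p.value, "\\n")\n'
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=120
        )
        assert out.returncode == 0, out.stderr
        z_r, p_r = map(float, out.stdout.split())
        res = delong_paired(a, b, labels)
        assert res.z == pytest.approx(z_r, abs=1e-6)
        assert res.p == pytest.approx(p_r, abs=1e-6)  # R prints 7 significant digits


class TestCvInterval:
    def test_zero_variance(self):
        assert cv_confidence_interval([0.9] * 10) == (0.9, 0.9, 0.9)

    def test_symmetric_before_clipping(self):
        mean, lo, hi = cv_confidence_interval([0.2, 0.4, 0.6, 0.8], clip=None)
        assert hi - mean == pytest.approx(mean - lo)

    def test_clipped_to_unit_interval(self):
        _, lo, hi = cv_confidence_interval([0.97, 0.99, 1.0, 0.98])
        assert 0.0 <= lo <= hi <= 1.0

    def test_too_few_folds(self):
        with pytest.raises(ValueError):
            cv_confidence_interval([0.5])

    def test_t_interval_wider_than_normal(self):
        vals = [0.7, 0.8, 0.9, 0.85, 0.75]
        _, lo_z, hi_z = cv_confidence_interval(vals, clip=None, use_t=False)
        _, lo_t, hi_t = cv_confidence_interval(vals, clip=None, use_t=True)
        assert lo_t < lo_z and hi_t > hi_z


class TestMeanRoc:
    def _smooth_curve(self, auc_like, n=400, seed=0):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        scores = rng.normal(size=n) + labels * auc_like
        return roc_points(scores, labels)

    def test_identical_curves_idempotent(self):
        c = self._smooth_curve(1.5)
        m = mean_roc([c, c, c])
        assert m.auroc == pytest.approx(c.auroc, abs=0.01)

    def test_tpr_nondecreasing_and_endpoints(self):
        curves = [self._smooth_curve(1.0, seed=s) for s in range(5)]
        m = mean_roc(curves)
        assert np.all(np.diff(m.tpr) >= -1e-12)
        assert m.fpr[0] == 0.0 and m.fpr[-1] == 1.0
        assert m.tpr[0] == 0.0 and m.tpr[-1] == 1.0

    def test_area_close_to_mean_fold_auroc(self):
        curves = [self._smooth_curve(1.2, seed=s) for s in range(8)]
        m = mean_roc(curves)
        assert m.auroc == pytest.approx(np.mean([c.auroc for c in curves]), abs=0.01)

    def test_empty_input(self):
        with pytest.raises(ValueError):
            mean_roc([])


class TestAgreement:
    def test_identical_vectors(self):
        res = agreement_stats([1, 0, 1, 0], [1, 0, 1, 0])
        assert res.percent_agreement == 100.0 and res.kappa == 1.0

    def test_study_scale_counts(self):
        # 3695 of 3828 ratings concordant
        r1 = np.zeros(3828, dtype=int)
        r2 = np.zeros(3828, dtype=int)
        r1[:1760] = 1
        r2[:1760] = 1
        r2[:133] = 0  # 133 discordant pairs
        res = agreement_stats(r1, r2)
        assert res.n_agree == 3695
        assert round(res.percent_agreement, 1) == 96.5

    def test_kappa_hand_computation(self):
        # both-yes 45, both-no 45, discordant 5 + 5 -> kappa 0.8
        r1 = [1] * 45 + [0] * 45 + [1] * 5 + [0] * 5
        r2 = [1] * 45 + [0] * 45 + [0] * 5 + [1] * 5
        res = agreement_stats(r1, r2)
        assert res.kappa == pytest.approx(0.8)
        assert res.percent_agreement == pytest.approx(90.0)

    def test_kappa_zero_at_chance_agreement(self):
        # observed agreement equals chance agreement under the marginals
        r1 = [1, 1, 0, 0]
        r2 = [1, 0, 1, 0]
        assert agreement_stats(r1, r2).kappa == pytest.approx(0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            agreement_stats([], [])


class TestPermutationImportance:
    def test_dominant_feature_ranks_first_and_deterministic(self):
        from sklearn.ensemble import RandomForestClassifier

        rng = np.random.default_rng(0)
        n = 500
        y = rng.integers(0, 2, n)
        X = np.column_stack([y.astype(float), rng.normal(size=n), rng.normal(size=n)])
        model = RandomForestClassifier(n_estimators=50, random_state=0, n_jobs=1).fit(X, y)
        imp1 = permutation_importance(model, X, y, n_repeats=5, seed=1)
        imp2 = permutation_importance(model, X, y, n_repeats=5, seed=1)
        assert np.argmax(imp1) == 0
        assert np.array_equal(imp1, imp2)


class TestSubgroupAudit:
    @pytest.fixture
    def pooled(self):
        rng = np.random.default_rng(3)
        n = 400
        labels = rng.integers(0, 2, n)
        probs = np.clip(labels * 0.25 + rng.random(n) * 0.75, 0, 1)
        return probs, labels

    def test_single_stratum_matches_overall(self, pooled):
        probs, labels = pooled
        report = subgroup_audit(probs, labels, {"all": np.ones(len(labels), bool)})
        assert report.strata["all"]["metrics"].auroc.value == pytest.approx(
            auroc(probs, labels)
        )
        assert report.gap == 0.0

    def test_gap_is_max_minus_min(self, pooled):
        probs, labels = pooled
        half = len(labels) // 2
        masks = {
            "first": np.arange(len(labels)) < half,
            "second": np.arange(len(labels)) >= half,
        }
        report = subgroup_audit(probs, labels, masks)
        values = [info["metrics"].auroc.value for info in report.strata.values()]
        assert report.gap == pytest.approx(max(values) - min(values))
        assert report.gap >= 0

    def test_printed_gap_arithmetic(self):
        # highest 0.965 vs lowest 0.680 -> gap 0.285
        assert 0.965 - 0.68 == pytest.approx(0.285)

    def test_single_class_stratum_flagged_excluded(self, pooled):
        probs, labels = pooled
        mask_pos = labels == 1
        report = subgroup_audit(
            probs, labels, {"cases_only": mask_pos, "everyone": np.ones(len(labels), bool)}
        )
        assert "cases_only" in report.undefined_strata
        assert report.strata["cases_only"]["metrics"].auroc.value is None
        assert report.gap == 0.0  # only one defined stratum

    def test_relabeling_invariance(self, pooled):
        probs, labels = pooled
        half = np.arange(len(labels)) < 200
        r1 = subgroup_audit(probs, labels, {"a": half, "b": ~half})
        r2 = subgroup_audit(probs, labels, {"x": half, "y": ~half})
        assert r1.gap == r2.gap
        assert (
            r1.strata["a"]["metrics"].auroc.value
            == r2.strata["x"]["metrics"].auroc.value
        )

    def test_ci_bounds_bracket_point(self, pooled):
        probs, labels = pooled
        report = subgroup_audit(probs, labels, {"all": np.ones(len(labels), bool)})
        m = report.strata["all"]["metrics"].auroc
        lo, hi = m.ci
        assert lo <= m.value <= hi

    def test_bar_counts(self, pooled):
        probs, labels = pooled
        report = subgroup_audit(
            probs, labels, {"all": np.ones(len(labels), bool)}, bars=(0.5, 0.99)
        )
        assert report.n_at_bar[0.5] == 1
        assert report.n_at_bar[0.99] == 0


class TestPairwiseMatrix:
    @pytest.fixture
    def three_sets(self):
        rng = np.random.default_rng(5)
        n = 300
        labels = rng.integers(0, 2, n)
        scores = {
            "A": labels + rng.normal(scale=0.8, size=n),
            "B": labels + rng.normal(scale=1.5, size=n),
            "C": rng.normal(size=n),
        }
        return scores, labels

    def test_diagonal_zero_and_antisymmetric(self, three_sets):
        scores, labels = three_sets
        diff, pval = pairwise_comparison_matrix(scores, labels)
        assert np.allclose(np.diag(diff), 0.0)
        assert np.allclose(diff.to_numpy(), -diff.to_numpy().T)

    def test_pvalues_match_delong(self, three_sets):
        scores, labels = three_sets
        _, pval = pairwise_comparison_matrix(scores, labels)
        expected = delong_paired(scores["A"], scores["B"], labels).p
        assert pval.loc["A", "B"] == pytest.approx(expected)
        assert pval.loc["B", "A"] == pytest.approx(expected)

    def test_misaligned_rejected(self, three_sets):
        scores, labels = three_sets
        scores = dict(scores)
        scores["D"] = scores["A"][:-1]
        with pytest.raises(ValueError, match="align"):
            pairwise_comparison_matrix(scores, labels)

    def test_misaligned_encounter_ids_rejected(self, three_sets):
        scores, labels = three_sets

        class FakeResult:
            def __init__(self, p, ids):
                self.pooled_probabilities = p
                self.encounter_ids = ids

        n = len(labels)
        results = {
            "A": FakeResult(scores["A"], [f"e{i}" for i in range(n)]),
            "B": FakeResult(scores["B"], [f"e{i}" for i in reversed(range(n))]),
        }
        with pytest.raises(ValueError, match="misaligned"):
            pairwise_comparison_matrix(results, labels)
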