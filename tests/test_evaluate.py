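"""Evaluation contracts: AUC-U equivalence, confusion, 0.632+, confounders."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methsig.evaluate import (
    bootstrap_632plus,
    confusion_metrics,
    enumerate_confusion,
    fit_confounder_model,
    merge_small_karyotypes,
    roc_auc,
)


def _pair_auc(scores, labels, positive):
    """Brute-force concordant-pair count over n1*n2 pairs."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_ordering(self):
        _, auc = roc_auc([0.9, 0.8, 0.4, 0.2], ["+", "+", "-", "-"], "+")
        assert auc == 1.0

    def test_all_ties_give_half(self):
        _, auc = roc_auc([0.5] * 6, ["+", "-", "+", "-", "+", "-"], "+")
        assert auc == 0.5

    def test_refuses_single_class(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], ["+", "+"], "+")

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 6), min_size=4, max_size=25), st.data())
    def test_matches_pair_oracle_with_ties(self, score_bins, data):
        n = len(score_bins)
        labels = data.draw(
            st.lists(st.sampled_from("pn"), min_size=n, max_size=n)
        )
        if len(set(labels)) < 2:
            labels[0], labels[1] = "p", "n"
        scores = [s / 6 for s in score_bins]
        _, auc = roc_auc(scores, labels, "p")
        assert auc == pytest.approx(_pair_auc(scores, labels, "p"), abs=1e-12)

    def test_auc_u_statistic_identity(self, rng):
        # AUC * n1 * n2 equals the tie-corrected Mann-Whitney U
        from scipy import stats

        for _ in range(30):
            n = int(rng.integers(6, 40))
            scores = rng.integers(0, 8, size=n).astype(float)
            labels = rng.choice(["p", "n"], size=n)
            if len(set(labels)) < 2:
                continue
            pos, neg = scores[labels == "p"], scores[labels == "n"]
            u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
            _, auc = roc_auc(scores, labels, "p")
            assert auc * len(pos) * len(neg) == pytest.approx(u, abs=1e-9)

    def test_roc_points_monotone(self, rng):
        roc, _ = roc_auc(rng.random(30), rng.choice(["p", "n"], 30), "p")
        assert (np.diff(roc["fpr"]) >= 0).all()
        assert (np.diff(roc["tpr"]) >= 0).all()


class TestConfusionMetrics:
    def test_reference_matrix_rates(self):
        cm = confusion_metrics(
            ["CR"] * 28 + ["RD"] * 2 + ["CR"] * 12 + ["RD"] * 9,
            ["CR"] * 30 + ["RD"] * 21,
        )
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (28, 2, 12, 9)
        assert cm.sensitivity * 100 == pytest.approx(93.3, abs=0.05)
        assert cm.specificity * 100 == pytest.approx(42.86, abs=0.05)
        assert cm.ppv * 100 == pytest.approx(70.0, abs=1e-9)
        assert cm.npv * 100 == pytest.approx(81.8, abs=0.05)

    def test_perfect_and_degenerate_calls(self):
        perfect = confusion_metrics(["CR", "RD"], ["CR", "RD"])
        assert perfect.misclassification == 0.0
        assert perfect.sensitivity == perfect.specificity == 1.0
        allpos = confusion_metrics(["CR"] * 4, ["CR", "CR", "RD", "RD"])
        assert allpos.sensitivity == 1.0 and allpos.specificity == 0.0

    def test_empty_refused(self):
        with pytest.raises(ValueError):
            confusion_metrics([], [])


class TestBoot632:
    @staticmethod
    def _overfit_trainer(X, y):
        from sklearn.neighbors import KNeighborsClassifier

        return KNeighborsClassifier(n_neighbors=1).fit(X, y)

    def test_formula_edge_cases(self):
        from methsig.evaluate import _632plus

        r, w, e = _632plus(err_bar=0.2, err1=0.2, gamma=0.5)
        assert (r, w) == (0.0, 0.632)
        assert e == pytest.approx(0.2)
        r, w, e = _632plus(err_bar=0.0, err1=0.5, gamma=0.5)
        assert (r, w) == (1.0, 1.0)
        assert e == pytest.approx(0.5)

    def test_overfit_trainer_corrected_to_gamma(self, rng):
        # null signal, memorizing trainer: apparent error ~0 but the
        # 0.632+ estimate lands near the no-information rate
        X = pd.DataFrame(rng.normal(size=(40, 5)))
        y = np.array(["CR", "RD"] * 20)
        report = bootstrap_632plus(X, y, self._overfit_trainer, B=60, seed=1)
        assert report.err_bar == 0.0
        assert abs(report.err632plus - report.gamma) < 0.05
        assert 0.632 <= report.w <= 1.0

    def test_invariant_bounds_random_runs(self, rng):
        from sklearn.linear_model import LogisticRegression

        def trainer(X, y):
            return LogisticRegression(max_iter=500).fit(X, y)

        for seed in range(3):
            X = pd.DataFrame(rng.normal(size=(30, 3)))
            y = rng.choice(["CR", "RD"], size=30)
            while len(set(y)) < 2 or min((y == "CR").sum(), (y == "RD").sum()) < 5:
                y = rng.choice(["CR", "RD"], size=30)
            rep = bootstrap_632plus(X, y, trainer, B=50, seed=seed)
            assert 0.632 <= rep.w <= 1.0
            assert 0.0 <= rep.R <= 1.0
            err1p = min(rep.err1, rep.gamma)
            lo, hi = min(rep.err_bar, err1p), max(rep.err_bar, err1p)
            assert lo - 1e-12 <= rep.err632plus <= hi + 1e-12

    def test_determinism(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 4)))
        y = np.array(["CR", "RD"] * 15)
        a = bootstrap_632plus(X, y, self._overfit_trainer, B=50, seed=9)
        b = bootstrap_632plus(X, y, self._overfit_trainer, B=50, seed=9)
        assert a == b

    def test_rejects_small_b(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 2)))
        y = np.array(["CR", "RD"] * 5)
        with pytest.raises(ValueError):
            bootstrap_632plus(X, y, self._overfit_trainer, B=10)


class TestConfusionEnumeration:
    def test_unique_reconstruction(self):
        hits = enumerate_confusion(
            93.3, 42.85, 70.0, 81.8, max_total=57,
            positive_multiple=15, negative_multiple=7,
        )
        assert len(hits) == 1
        cm = hits[0]
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (28, 2, 12, 9)


def _irls_logistic(X, y01, iters=200):
    """Independent IRLS implementation of ML logistic regression."""
    X = np.column_stack([np.ones(len(X)), X])
    beta = np.zeros(X.shape[1])
    for _ in range(iters):
        eta = X @ beta
        p = 1 / (1 + np.exp(-eta))
        w = p * (1 - p)
        z = eta + (y01 - p) / np.maximum(w, 1e-10)
        wx = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ wx, X.T @ (w * z))
        if np.max(np.abs(beta_new - beta)) < 1e-12:
            beta = beta_new
            break
        beta = beta_new
    return beta


class TestConfounderModel:
    def test_matches_irls_oracle(self, rng):
        n = 120
        cov = pd.DataFrame(
            {"age": rng.normal(60, 10, n), "mut": rng.integers(0, 2, n)}
        )
        score = pd.Series(rng.normal(size=n))
        logits = 0.8 * score - 0.02 * (cov["age"] - 60) + 0.5 * cov["mut"]
        y = pd.Series(np.where(rng.random(n) < 1 / (1 + np.exp(-logits)),
                               "RD", "CR"))
        table = fit_confounder_model(score, cov, y)
        expected = _irls_logistic(
            np.column_stack([score, cov["age"], cov["mut"]]),
            (y == "RD").to_numpy().astype(float),
        )
        np.testing.assert_allclose(table["coef"].to_numpy(), expected, atol=1e-6)
        assert not table.attrs["penalized_fallback"]
        assert (table["ci_low"] <= table["coef"]).all()

    def test_signature_ci_excludes_zero_with_planted_effect(self, rng):
        n = 150
        score = pd.Series(rng.normal(size=n))
        y = pd.Series(np.where(
            rng.random(n) < 1 / (1 + np.exp(-2.5 * score)), "RD", "CR"))
        cov = pd.DataFrame({"age": rng.normal(60, 10, n)})
        table = fit_confounder_model(score, cov, y)
        assert table.loc["signature", "ci_low"] > 0

    def test_collinear_covariate_flagged(self, rng):
        n = 60
        cov = pd.DataFrame({"a": rng.normal(size=n)})
        cov["b"] = cov["a"]  # exact duplicate
        score = pd.Series(rng.normal(size=n))
        y = pd.Series(rng.choice(["CR", "RD"], size=n))
        table = fit_confounder_model(score, cov, y)
        assert table.attrs["collinear"]

    def test_separation_falls_back_penalized(self):
        score = pd.Series(np.r_[np.full(20, -3.0), np.full(20, 3.0)])
        y = pd.Series(["CR"] * 20 + ["RD"] * 20)
        cov = pd.DataFrame({"age": np.linspace(40, 70, 40)})
        table = fit_confounder_model(score, cov, y)
        assert table.attrs["penalized_fallback"]

    def test_karyotype_merge_rule(self):
        k = pd.Series(["CN"] * 10 + ["complex"] * 5 + ["del5q"] * 2
                      + ["t11q23"] * 2 + ["other"] * 11)
        merged = merge_small_karyotypes(k)
        assert set(merged) == {"CN", "complex", "other"}
        assert (merged == "other").sum() == 15
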