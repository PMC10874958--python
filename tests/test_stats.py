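import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from octlayers.stats import (
    ConstantInputError,
    SingularDesignError,
    gee_fit,
    pairwise_contrasts,
    roc_auc,
    spearman,
)


def brute_force_auc(scores, labels):
    """Concordant-pair count with ties worth one half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def simulate_clustered(rng, n_clusters=200, rho=0.5, beta=(1.0, 2.0)):
    """Two observations per cluster with exchangeable correlation rho."""
    z = rng.normal(size=(n_clusters, 1))
    e = np.sqrt(rho) * z + np.sqrt(1 - rho) * rng.normal(size=(n_clusters, 2))
    x = rng.normal(size=(n_clusters, 2))
    y = beta[0] + beta[1] * x + e
    return pd.DataFrame({
        "y": y.ravel(), "x": x.ravel(),
        "patient_id": np.repeat(np.arange(n_clusters), 2),
        "age": np.repeat(rng.normal(50, 10, n_clusters), 2),
        "sex": np.repeat(rng.choice(["M", "F"], n_clusters), 2),
    })


class TestROC:
    def test_perfect_separation(self):
        r = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0

    def test_spec_example_three_of_four_concordant(self):
        assert roc_auc([1, 2, 3, 4], [0, 1, 0, 1]).auc == pytest.approx(0.75)

    def test_equals_mann_whitney_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            n = int(rng.integers(6, 30))
            scores = rng.integers(0, 10, n).astype(float)  # ties on purpose
            labels = np.zeros(n, int)
            labels[rng.choice(n, size=int(rng.integers(2, n - 1)), replace=False)] = 1
            if labels.sum() in (0, n):
                continue
            r = roc_auc(scores, labels)
            bf = brute_force_auc(scores, labels)
            bf = bf if r.polarity == 1 else 1 - bf
            assert r.auc == pytest.approx(bf, abs=1e-12)

    def test_permuted_labels_average_half(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=40)
        aucs = []
        for _ in range(1000):
            labels = np.zeros(40, int)
            labels[rng.choice(40, 20, replace=False)] = 1
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            aucs.append(np.mean(pos[:, None] > neg[None, :]))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.01)

    def test_curve_monotone_and_ci_brackets(self):
        rng = np.random.default_rng(7)
        scores = np.concatenate([rng.normal(0, 1, 60), rng.normal(1, 1, 60)])
        labels = np.repeat([0, 1], 60)
        r = roc_auc(scores, labels)
        assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)
        assert 0 <= r.ci_low <= r.auc <= r.ci_high <= 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestGEE:
    def test_singleton_clusters_equal_ols(self):
        rng = np.random.default_rng(8)
        n = 120
        df = pd.DataFrame({
            "y": rng.normal(size=n), "x": rng.normal(size=n),
            "patient_id": np.arange(n),
            "age": rng.normal(50, 10, n), "sex": rng.choice(["M", "F"], n),
        })
        fit = gee_fit(df, "y", ["x"])
        X = pd.DataFrame({"Intercept": 1.0, "x": df.x,
                          "age_c": df.age - df.age.mean(),
                          "sex_male": (df.sex == "M").astype(float)})
        ols = sm.OLS(df.y, X).fit()
        assert np.max(np.abs(fit.params.values - ols.params.values)) < 1e-8

    def test_duplicating_clusters_keeps_estimates_shrinks_se(self):
        rng = np.random.default_rng(9)
        df = simulate_clustered(rng, n_clusters=100)
        fit1 = gee_fit(df, "y", ["x"])
        dup = pd.concat([df, df.assign(patient_id=df.patient_id + 1000)],
                        ignore_index=True)
        fit2 = gee_fit(dup, "y", ["x"])
        assert np.allclose(fit1.params["x"], fit2.params["x"], atol=1e-3)
        assert fit2.robust_se["x"] < fit1.robust_se["x"]

    def test_coefficient_recovery_and_coverage(self):
        """500 clustered datasets (rho=0.5): bias small, ~95% robust coverage."""
        rng = np.random.default_rng(10)
        beta_true = 2.0
        hits = 0
        estimates = []
        reps = 500
        for _ in range(reps):
            df = simulate_clustered(rng, n_clusters=200, rho=0.5,
                                    beta=(1.0, beta_true))
            fit = gee_fit(df, "y", ["x"], covariates=())
            lo, hi = fit.conf_int().loc["x"]
            hits += lo <= beta_true <= hi
            estimates.append(fit.params["x"])
        estimates = np.asarray(estimates)
        se_mc = estimates.std() / np.sqrt(reps)
        assert abs(estimates.mean() - beta_true) < 3 * se_mc
        assert 0.92 <= hits / reps <= 0.98

    def test_working_correlation_estimated(self):
        rng = np.random.default_rng(11)
        df = simulate_clustered(rng, n_clusters=300, rho=0.5)
        fit = gee_fit(df, "y", ["x"], covariates=())
        assert fit.working_correlation == pytest.approx(0.5, abs=0.1)
        assert fit.n_clusters == 300 and fit.n_observations == 600

    def test_singular_design_rejected(self):
        rng = np.random.default_rng(12)
        n = 40
        df = pd.DataFrame({"y": rng.normal(size=n), "x": np.ones(n),
                           "patient_id": np.arange(n),
                           "age": rng.normal(50, 5, n),
                           "sex": rng.choice(["M", "F"], n)})
        with pytest.raises(SingularDesignError):
            gee_fit(df, "y", ["x"])


class TestPairwiseContrasts:
    @staticmethod
    def three_group_frame(rng, shift=(0.0, 0.0, 0.0), n_per=30):
        rows = []
        pid = 0
        for g, mu in zip(("normal", "NPDR", "PDR"), shift):
            for _ in range(n_per):
                rows.append({"y": rng.normal(mu, 1), "group": g,
                             "patient_id": f"p{pid}",
                             "age": rng.normal(50, 10),
                             "sex": rng.choice(["M", "F"])})
                pid += 1
        return pd.DataFrame(rows)

    def test_output_schema(self):
        rng = np.random.default_rng(13)
        out = pairwise_contrasts(self.three_group_frame(rng), "y")
        assert {"p_overall", "P1", "P2", "P3"} <= set(out)

    def test_separated_group_pattern(self):
        rng = np.random.default_rng(14)
        out = pairwise_contrasts(self.three_group_frame(rng, shift=(0, 0, 3)), "y")
        assert out["P2"] < 0.001 and out["P3"] < 0.001  # PDR differs from both
        assert out["P1"] > 0.01                          # normal vs NPDR: null

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(15)
        rejections = 0
        reps = 150
        for _ in range(reps):
            out = pairwise_contrasts(self.three_group_frame(rng, n_per=40), "y")
            rejections += out["p_overall"] < 0.05
        # nominal 5% with Monte-Carlo + small-sample slack
        assert 0.01 <= rejections / reps <= 0.13

    def test_missing_group_rejected(self):
        rng = np.random.default_rng(16)
        df = self.three_group_frame(rng)
        with pytest.raises(ValueError, match="missing"):
            pairwise_contrasts(df[df.group != "PDR"], "y")


class TestSpearman:
    def test_monotone_perfect(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [10, 20, 25, 40, 100])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman([1, 2, 3, 4, 5], [-1, -2, -3, -4, -5])
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_formula_oracle(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        rho, _ = spearman(x, y)
        rx = np.argsort(np.argsort(x)) + 1.0
        ry = np.argsort(np.argsort(y)) + 1.0
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ConstantInputError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])
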