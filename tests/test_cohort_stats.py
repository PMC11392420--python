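"""ANCOVA, chi-square, tract regressions, BH-FDR, PCA regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from proprio_disconnect.cohort_stats import (
    DegenerateDataError,
    ancova_side,
    bh_fdr,
    chi_square_2x2,
    cohens_f2,
    pc_regression,
    pca_predictors,
    standardize,
    tract_regression,
    tract_regression_battery,
)


class TestStandardize:
    def test_three_values(self):
        np.testing.assert_allclose(standardize([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0])

    def test_idempotent(self, rng):
        x = standardize(rng.normal(3, 7, 50))
        np.testing.assert_allclose(standardize(x), x, atol=1e-12)

    def test_moments(self, rng):
        z = standardize(rng.gamma(2, 3, 200))
        assert abs(z.mean()) < 1e-12
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_constant_rejected(self):
        with pytest.raises(DegenerateDataError):
            standardize(np.ones(10))


class TestAncova:
    def test_equal_groups_f_near_zero(self):
        y = np.tile([1.0, 3.0, 2.0, 4.0], 2)  # not collinear with the covariate
        side = np.repeat([0, 1], 4)
        vol = np.tile([5.0, 6.0, 7.0, 8.0], 2)
        res = ancova_side(y, side, vol)
        assert res.F == pytest.approx(0.0, abs=1e-16)

    def test_matches_hat_matrix_oracle(self, rng):
        """From-scratch projection-matrix F for the side term."""
        n = 40
        side = rng.integers(0, 2, n).astype(float)
        vol = rng.gamma(3, 10, n)
        y = 0.8 * side + 0.02 * vol + rng.normal(0, 1, n)
        X_full = np.column_stack([np.ones(n), side, vol])
        X_red = np.column_stack([np.ones(n), vol])

        def rss(X):
            H = X @ np.linalg.inv(X.T @ X) @ X.T
            r = y - H @ y
            return r @ r

        rss_full, rss_red = rss(X_full), rss(X_red)
        F_oracle = (rss_red - rss_full) / (rss_full / (n - 3))
        res = ancova_side(y, side, vol)
        assert res.F == pytest.approx(F_oracle, abs=1e-8)
        assert res.p == pytest.approx(sps.f.sf(F_oracle, 1, n - 3), abs=1e-10)

    def test_side_labels_accepted(self, rng):
        y = rng.normal(size=30)
        side = np.where(rng.random(30) < 0.5, "left", "right")
        vol = rng.gamma(2, 5, 30)
        res = ancova_side(y, side, vol)
        assert 0 <= res.p <= 1

    def test_power_with_real_side_effect(self):
        """A 0.5 SD side effect at n=203 is detected in >=90% of seeds."""
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n = 203
            side = (rng.random(n) < 118 / 203).astype(float)
            vol = rng.lognormal(3, 0.8, n)
            y = 0.5 * side + 0.01 * vol + rng.normal(0, 1, n)
            hits += ancova_side(y, side, vol).p < 0.05
        assert hits >= 45


class TestChiSquare:
    def test_reconstructed_cohort_table(self):
        chi2, p = chi_square_2x2([[13, 72], [24, 94]])
        assert chi2 == pytest.approx(0.844, abs=5e-4)
        assert p == pytest.approx(0.358, abs=5e-3)

    def test_no_association(self):
        chi2, _ = chi_square_2x2([[10, 10], [10, 10]])
        assert chi2 == pytest.approx(0.0)

    def test_perfect_association_closed_form(self):
        chi2, _ = chi_square_2x2([[20, 0], [0, 20]])
        assert chi2 == pytest.approx(40.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateDataError):
            chi_square_2x2([[0, 0], [5, 5]])


class TestTractRegression:
    def test_noise_free_recovery(self, rng):
        n = 50
        load = rng.gamma(2, 10, n)
        side = rng.integers(0, 2, n).astype(float)
        gm = rng.gamma(3, 4, n)
        y = 0.7 * standardize(load) - 0.3 * standardize(side) + 0.2 * standardize(gm)
        res = tract_regression(y, load, side, gm)
        # outcome standardisation rescales all coefficients by 1/sd(y)
        scale = 1.0 / np.std(y, ddof=1)
        np.testing.assert_allclose(
            res.coefficients["coef"],
            np.array([0.7, -0.3, 0.2]) * scale,
            atol=1e-8,
        )
        assert res.r2 == pytest.approx(1.0)

    def test_f2_identity(self):
        assert cohens_f2(0.24) == pytest.approx(0.24 / 0.76, abs=1e-12)
        res_r2 = 0.4
        assert cohens_f2(res_r2) == pytest.approx(res_r2 / (1 - res_r2))

    def test_collinear_design_rejected(self, rng):
        load = rng.gamma(2, 10, 30)
        with pytest.raises(DegenerateDataError):
            tract_regression(rng.normal(size=30), load, load, 2.0 * load)

    def test_battery_family_size_and_fdr(self, rng):
        n = 80
        loads = pd.DataFrame(
            {f"t{i}": rng.gamma(2, 10, n) for i in range(23)}
        )
        side = rng.integers(0, 2, n)
        gm = rng.gamma(3, 4, n)
        y = rng.normal(size=n)
        out = tract_regression_battery(
            y, loads, list(loads.columns), side, gm
        )
        assert len(out) == 69  # 23 tracts x 3 coefficients
        assert (out["p_fdr"] >= out["p"] - 1e-12).all()


class TestBhFdr:
    def test_hand_computed_thresholds(self):
        reject, _ = bh_fdr([0.001, 0.01, 0.03, 0.2], q=0.05)
        # thresholds kq/m = 0.0125, 0.025, 0.0375, 0.05 -> first three rejected
        assert reject.tolist() == [True, True, True, False]

    def test_all_ones_rejects_none(self):
        reject, _ = bh_fdr(np.ones(10))
        assert not reject.any()

    def test_single_p_below_q_rejected(self):
        reject, adj = bh_fdr([0.04])
        assert reject.tolist() == [True]
        assert adj[0] == pytest.approx(0.04)

    def test_null_uniform_false_rejection_rate(self, rng):
        """BH on independent nulls yields false rejections w.p. <= q."""
        any_reject = 0
        for _ in range(400):
            reject, _ = bh_fdr(rng.random(20), q=0.05)
            any_reject += reject.any()
        assert any_reject / 400 <= 0.08


def _whitened(rng, n, m):
    """Exactly uncorrelated standardised columns."""
    X = rng.normal(size=(n, m))
    X = X - X.mean(0)
    cov = X.T @ X / (n - 1)
    X = X @ np.linalg.inv(np.linalg.cholesky(cov)).T
    return pd.DataFrame(X, columns=[f"v{i}" for i in range(m)])


class TestPca:
    def test_identity_correlation_unit_eigenvalues(self, rng):
        df = _whitened(rng, 100, 6)
        res = pca_predictors(df)
        np.testing.assert_allclose(res.eigenvalues, np.ones(6), atol=1e-8)
        np.testing.assert_allclose(res.pct_variance, 100.0 / 6, atol=1e-6)

    def test_duplicated_predictor_doubles_top_eigenvalue(self, rng):
        df = _whitened(rng, 200, 5)
        df["dup"] = df["v0"]
        res = pca_predictors(df)
        assert res.eigenvalues[0] == pytest.approx(2.0, abs=1e-8)

    def test_variance_sums_and_ordering(self, rng):
        df = pd.DataFrame(rng.gamma(2, 5, size=(60, 8)))
        df.columns = [f"c{i}" for i in range(8)]
        res = pca_predictors(df)
        assert res.pct_variance.sum() == pytest.approx(100.0)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_full_reconstruction(self, rng):
        df = pd.DataFrame(
            rng.normal(size=(50, 5)), columns=[f"c{i}" for i in range(5)]
        )
        res = pca_predictors(df)
        Z = np.column_stack([standardize(df[c].to_numpy()) for c in df])
        np.testing.assert_allclose(
            res.scores @ res.loadings.to_numpy().T, Z, atol=1e-8
        )

    def test_selection_rule_95(self, rng):
        df = _whitened(rng, 100, 20)
        res = pca_predictors(df)
        cum = np.cumsum(res.pct_variance)
        k = res.n_selected
        assert cum[k - 1] >= 95.0 - 1e-6
        assert k == 1 or cum[k - 2] < 95.0


class TestPcRegression:
    def test_signal_on_first_component_only(self, rng):
        df = _whitened(rng, 150, 4)
        df["v0"] = df["v0"] * 3  # standardisation undoes this; use loadings
        pca = pca_predictors(df)
        noise = rng.normal(0, 1.0, 150)
        other = pca.scores[:, 1:]
        noise = noise - other @ np.linalg.lstsq(other, noise, rcond=None)[0]
        y = pca.scores[:, 0] * 2.0 + noise  # exactly orthogonal to PC2..k
        res = pc_regression(pca, y)
        assert res.table["significant"].tolist()[0]
        assert not any(res.table["significant"].tolist()[1:])

    def test_coefficient_eigenvalue_identity(self, rng):
        """Orthogonality: coef_j = cov(y, score_j) / eigenvalue_j."""
        df = pd.DataFrame(
            rng.normal(size=(80, 5)) @ rng.normal(size=(5, 5)),
            columns=[f"c{i}" for i in range(5)],
        )
        pca = pca_predictors(df, variance_threshold=100.0)
        y = rng.normal(size=80)
        res = pc_regression(pca, y, standardize_outcome=False)
        for j in range(pca.n_selected):
            s = pca.scores[:, j]
            cov = ((y - y.mean()) * (s - s.mean())).sum() / (len(y) - 1)
            expected = cov / pca.eigenvalues[j]
            assert res.table["coef"].iloc[j] == pytest.approx(expected, abs=1e-8)
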