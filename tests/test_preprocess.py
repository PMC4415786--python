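"""Tests of the four-step array preprocessing chain and delta-Ct
normalization: glog closed forms and likelihood fitting, the additive
control-probe model with iterative outlier rejection, and replicate
summarization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from synovclass import synthetic as syn
from synovclass.containers import CONTROL_ROLES, ExpressionMatrix
from synovclass.preprocess import (
    ControlModelFit,
    GlogParams,
    apply_normalization,
    fit_control_model,
    fit_glog,
    glog_inverse,
    glog_transform,
    qpcr_delta_ct,
    subtract_background,
    summarize_replicates,
)


def _batch(records):
    return pd.DataFrame(
        records,
        columns=["sample", "probe", "role", "replicate", "foreground", "background"],
    )


class TestBackground:
    def test_subtraction_and_negative_retention(self):
        batch = _batch(
            [
                ("s1", "p1", "diagnostic", 1, 500.0, 120.0),
                ("s1", "p1", "diagnostic", 2, 50.0, 80.0),
                ("s1", "p1", "diagnostic", 3, 10.0, 0.0),
            ]
        )
        out = subtract_background(batch)
        assert list(out["intensity"]) == [380.0, -30.0, 10.0]

    def test_missing_background_is_error(self):
        batch = _batch([("s1", "p1", "diagnostic", 1, 500.0, np.nan)])
        with pytest.raises(ValueError, match="background"):
            subtract_background(batch)


class TestGlogTransform:
    @pytest.mark.parametrize(
        "x, lam, alpha, expected",
        [
            (0.0, 1.0, 0.0, 0.0),  # ln(0 + 1) = 0
            (10.0, 0.0, 0.0, np.log(20.0)),  # ln(2x) at lambda = 0
            (3.0, 16.0, 0.0, np.log(8.0)),  # 3-4-5: ln(3 + 5)
            (5.0, 1.0, 5.0, 0.0),  # x = alpha
        ],
    )
    def test_closed_forms(self, x, lam, alpha, expected):
        assert glog_transform(x, GlogParams(lam, alpha)) == pytest.approx(expected)

    @given(
        st.floats(-1e4, 1e4),
        st.floats(-1e4, 1e4),
        st.floats(1e-3, 1e6),
    )
    def test_monotone_and_invertible(self, x1, x2, lam):
        p = GlogParams(lam)
        lo, hi = sorted([x1, x2])
        assert glog_transform(lo, p) <= glog_transform(hi, p)
        # cancellation in u + sqrt(u^2 + lam) limits round-trip precision
        # for large negative x
        assert glog_inverse(glog_transform(x1, p), p) == pytest.approx(
            x1, rel=1e-6, abs=1e-4
        )

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            GlogParams(-1.0)


class TestFitGlog:
    def test_single_grid_point_returned_exactly(self):
        x = syn.constant_glog_variance_intensities(
            np.linspace(3, 8, 10), 3, 0.2, 500.0, seed=4
        )
        p = fit_glog(x, lambda_grid=[500.0], alpha_grid=[0.0], refine=False)
        assert (p.lam, p.alpha) == (500.0, 0.0)
        assert np.isfinite(p.loglik)

    def test_lambda_recovery_within_factor_two(self):
        """Median fitted lambda over independent 50-probe x 3-replicate
        datasets generated at lambda* = 1000 lies within a factor of 2."""
        lams = []
        for s in range(5):
            centers = np.random.default_rng(s).uniform(2.5, 9.0, 50)
            x = syn.constant_glog_variance_intensities(
                centers, 3, 0.2, 1000.0, seed=100 + s
            )
            lams.append(fit_glog(x).lam)
        assert 500.0 <= np.median(lams) <= 2000.0

    def test_pure_multiplicative_noise_drives_lambda_small(self):
        """No additive component: fitted transform behaves like a log —
        transformed replicate SD decorrelates from the mean."""
        x = syn.two_component_intensities(
            np.linspace(100, 20000, 50), 4, mult_sd=0.2, add_sd=1e-6, seed=5
        )
        p = fit_glog(x)
        z = glog_transform(x, p)
        r = np.corrcoef(z.mean(axis=1), z.std(axis=1, ddof=1))[0, 1]
        assert abs(r) < 0.3
        assert p.lam < 100.0  # essentially a shifted log

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError, match="replicate groups"):
            fit_glog(np.array([[1.0, 2.0]]))


def _control_frame(mu, a, b, noise=None, rng=None, n_rep=3):
    """Long control-probe frame from known coefficients."""
    rows = []
    for i, (s, ai) in enumerate(a.items()):
        for j, (p, bj) in enumerate(b.items()):
            for k in range(n_rep):
                z = mu + ai + bj
                if noise is not None:
                    z += rng.normal(0, noise)
                rows.append((s, p, k + 1, z))
    return pd.DataFrame(rows, columns=["sample", "probe", "replicate", "value"])


class TestControlModel:
    A = {"s1": 0.0, "s2": 0.7, "s3": -0.4, "s4": 1.2}
    B = {f"p{j}": v for j, v in enumerate([0.0, 0.3, -0.2, 0.5, 0.1], start=1)}

    def test_noiseless_recovery_matches_closed_form(self):
        df = _control_frame(5.0, self.A, self.B)
        fit = fit_control_model(df)
        assert fit.mu == pytest.approx(5.0, abs=1e-10)
        for s, ai in self.A.items():
            assert fit.sample_bias[s] == pytest.approx(ai, abs=1e-10)
        for p, bj in self.B.items():
            assert fit.probe_bias[p] == pytest.approx(bj, abs=1e-10)
        # balanced two-way OLS a_i equals row mean minus first-row mean
        row_means = df.groupby("sample")["value"].mean()
        for s in self.A:
            assert fit.sample_bias[s] == pytest.approx(
                row_means[s] - row_means["s1"], abs=1e-10
            )
        assert not fit.outlier_mask.any()

    def test_displaced_replicate_flagged_and_fit_unchanged(self):
        df = _control_frame(5.0, self.A, self.B)
        clean = fit_control_model(df)
        spiked = df.copy()
        spiked.loc[7, "value"] += 0.3  # one replicate displaced
        fit = fit_control_model(spiked)
        assert fit.outlier_mask[7]
        pd.testing.assert_series_equal(
            fit.sample_bias, clean.sample_bias, atol=1e-6, rtol=0.0
        )

    def test_idempotent_on_own_inlier_subset(self):
        rng = np.random.default_rng(9)
        df = _control_frame(5.0, self.A, self.B, noise=0.05, rng=rng)
        df.loc[[3, 20], "value"] += 0.5
        fit = fit_control_model(df)
        refit = fit_control_model(df.loc[~fit.outlier_mask])
        pd.testing.assert_series_equal(
            refit.sample_bias, fit.sample_bias, atol=1e-10, rtol=0.0
        )
        pd.testing.assert_series_equal(
            refit.probe_bias, fit.probe_bias, atol=1e-10, rtol=0.0
        )

    def test_single_sample_is_error(self):
        df = _control_frame(5.0, {"s1": 0.0}, self.B)
        with pytest.raises(ValueError, match="2 samples"):
            fit_control_model(df)

    def test_multiple_gross_outliers_all_flagged(self):
        """Several gross spot outliers spread over samples are all rejected
        and the remaining coefficients match the uncontaminated fit."""
        rng = np.random.default_rng(10)
        df = _control_frame(5.0, self.A, self.B, noise=0.01, rng=rng)
        clean = fit_control_model(df)
        spots = [2, 17, 23, 40, 55]
        df.loc[spots, "value"] += rng.choice([-50.0, 50.0], size=len(spots))
        fit = fit_control_model(df)
        assert sorted(df.index[fit.outlier_mask]) == spots
        pd.testing.assert_series_equal(
            fit.sample_bias, clean.sample_bias, atol=0.02, rtol=0.0
        )


class TestNormalization:
    def test_zero_bias_is_identity_and_shift_subtracts(self):
        data = pd.DataFrame(
            np.arange(6.0).reshape(2, 3),
            index=["g1", "g2"],
            columns=["s1", "s2", "s3"],
        )
        em = ExpressionMatrix(data, "glog")
        fit = ControlModelFit(
            mu=0.0,
            sample_bias=pd.Series({"s1": 0.0, "s2": 2.0, "s3": 0.0}),
            probe_bias=pd.Series(dtype=float),
            residuals=pd.Series(dtype=float),
            outlier_mask=pd.Series(dtype=bool),
            n_iterations=1,
        )
        out = apply_normalization(em, fit)
        assert (out.data["s1"] == data["s1"]).all()
        assert (out.data["s2"] == data["s2"] - 2.0).all()
        # within-sample gene contrasts untouched
        pd.testing.assert_series_equal(
            out.data.loc["g2"] - out.data.loc["g1"],
            data.loc["g2"] - data.loc["g1"],
        )

    def test_missing_sample_is_error(self):
        em = ExpressionMatrix(
            pd.DataFrame([[1.0]], index=["g"], columns=["sX"]), "glog"
        )
        fit = ControlModelFit(
            0.0, pd.Series({"s1": 0.0}), pd.Series(dtype=float),
            pd.Series(dtype=float), pd.Series(dtype=bool), 1,
        )
        with pytest.raises(KeyError, match="sX"):
            apply_normalization(em, fit)

    def test_full_chain_removes_most_sample_bias(self):
        """End to end on generator output with known a_i: the fitted sample
        coefficients track the planted ones to a few percent."""
        spec = syn.known_cohort_spec(n_genes=15, markers_per_class=2)
        expr, *_ = syn.generate_expression_cohort(spec, 23)
        batch, truth = syn.generate_raw_array(expr, bias_sd=0.3, seed=29)
        from synovclass.preprocess import preprocess_array

        matrix, _, fit = preprocess_array(batch)
        a_true = pd.Series(truth.true_sample_bias)
        resid = (fit.sample_bias - a_true).to_numpy()
        assert np.std(resid) < 0.1 * np.std(a_true.to_numpy())
        assert matrix.shape == (15, 39)


class TestSummarize:
    def test_median_conventions(self):
        batch = pd.DataFrame(
            {
                "sample": ["s1"] * 3 + ["s2"] * 2,
                "probe": ["g1"] * 5,
                "replicate": [1, 2, 3, 1, 2],
                "value": [1.0, 2.0, 9.0, 4.0, 8.0],
            }
        )
        em = summarize_replicates(batch)
        assert em.data.at["g1", "s1"] == 2.0  # odd count: middle value
        assert em.data.at["g1", "s2"] == 6.0  # even count: midpoint mean

    def test_outlier_masked_before_median(self):
        batch = pd.DataFrame(
            {
                "sample": ["s1"] * 3,
                "probe": ["g1"] * 3,
                "replicate": [1, 2, 3],
                "value": [1.0, 2.0, 50.0],
            }
        )
        mask = pd.Series([False, False, True], index=batch.index)
        em = summarize_replicates(batch, outlier_mask=mask)
        assert em.data.at["g1", "s1"] == 1.5
        assert summarize_replicates(batch).data.at["g1", "s1"] == 2.0

    def test_no_surviving_replicates_warns_missing(self):
        batch = pd.DataFrame(
            {
                "sample": ["s1", "s1", "s2"],
                "probe": ["g1", "g1", "g1"],
                "replicate": [1, 2, 1],
                "value": [1.0, 3.0, 7.0],
            }
        )
        mask = pd.Series([False, False, True], index=batch.index)
        with pytest.warns(UserWarning, match="no surviving replicate"):
            em = summarize_replicates(batch, outlier_mask=mask)
        assert np.isnan(em.data.at["g1", "s2"])
        assert em.data.at["g1", "s1"] == 2.0


class TestDeltaCt:
    def test_definition_and_zero_case(self):
        ct = pd.DataFrame(
            {"s1": [25.0, 15.0, 15.0], "s2": [20.0, 18.0, 18.0]},
            index=["gA", "gB", "hk"],
        )
        em = qpcr_delta_ct(ct, "hk")
        assert em.data.at["gA", "s1"] == -10.0
        assert (em.data.loc["gB"] == 0.0).all()  # Ct equal to housekeeping
        assert em.scale == "delta_ct"
        assert "hk" not in em.genes

    def test_housekeeping_missing_anywhere_is_error(self):
        ct = pd.DataFrame({"s1": [25.0, np.nan]}, index=["gA", "hk"])
        with pytest.raises(ValueError, match="s1"):
            qpcr_delta_ct(ct, "hk")
        with pytest.raises(KeyError):
            qpcr_delta_ct(ct, "absent")
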