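import numpy as np
import pandas as pd
import pytest

from accelagree.agreement import (
    IdentifiabilityError,
    RankDeficiencyError,
    agreement_report,
    bland_altman_multilevel,
    fit_proportional_bias,
    fit_random_intercept,
    make_pairs,
)

from .oracles import balanced_anova_reml, gridsearch_reml


def pairs_frame(subjects, d, m=None):
    d = np.asarray(d, dtype=float)
    m = np.zeros_like(d) if m is None else np.asarray(m, dtype=float)
    return pd.DataFrame(
        {
            "subject_id": np.asarray(subjects),
            "d": d,
            "m": m,
            "om_value": m + d / 2,
            "ag_value": m - d / 2,
            "date": pd.Timestamp("2024-01-01"),
        }
    )


class TestFitRandomIntercept:
    def test_balanced_closed_form_example(self):
        # oracle: sigma2_w = MSE = 2, sigma2_b = (MSB - MSE)/n = 7, se = sqrt(MSB/(a n)) = 2
        vc = fit_random_intercept({"A": [1, 3], "B": [5, 7]})
        assert vc.mu == pytest.approx(4.0, abs=1e-10)
        assert vc.sigma2_w == pytest.approx(2.0, abs=1e-8)
        assert vc.sigma2_b == pytest.approx(7.0, abs=1e-8)
        assert vc.se_mu == pytest.approx(2.0, abs=1e-8)
        assert vc.n_subjects == 2 and vc.n_obs == 4

    def test_matches_balanced_anova_on_random_layouts(self, rng):
        for _ in range(25):
            a, n = rng.integers(2, 6), rng.integers(2, 6)
            y = rng.integers(0, 10, (a, n)).astype(float)
            if np.ptp(y) == 0:
                continue
            mu, se, s2b, s2w = balanced_anova_reml(y)
            vc = fit_random_intercept(y.ravel(), np.repeat(np.arange(a), n))
            assert vc.mu == pytest.approx(mu, abs=1e-8)
            assert vc.se_mu == pytest.approx(se, abs=1e-8)
            assert vc.sigma2_b == pytest.approx(s2b, abs=1e-8)
            assert vc.sigma2_w == pytest.approx(s2w, abs=1e-8)

    def test_unbalanced_matches_gridsearch_oracle(self):
        # NB: a two-observation group with zero internal spread (e.g. [0, 0])
        # sends the REML likelihood to infinity as sigma2_w -> 0, so the
        # smallest well-posed unbalanced layout needs within-group variance.
        y = np.array([0.0, 2.0, 4.0])
        groups = np.array(["A", "A", "B"])
        beta, _, s2b, s2w = gridsearch_reml(y, groups)
        vc = fit_random_intercept(y, groups)
        assert vc.mu == pytest.approx(float(beta[0]), abs=1e-4)
        assert vc.sigma2_b == pytest.approx(s2b, abs=1e-4)
        assert vc.sigma2_w == pytest.approx(s2w, abs=1e-4)

    def test_unbalanced_random_matches_gridsearch_oracle(self, rng):
        sizes = rng.integers(1, 5, 6)
        groups = np.repeat(np.arange(6), sizes)
        y = rng.normal(0, 1, len(groups)) + np.repeat(rng.normal(0, 1.2, 6), sizes)
        beta, cov, s2b, s2w = gridsearch_reml(y, groups)
        vc = fit_random_intercept(y, groups)
        assert vc.mu == pytest.approx(float(beta[0]), abs=1e-6)
        assert vc.sigma2_b == pytest.approx(s2b, abs=1e-5)
        assert vc.sigma2_w == pytest.approx(s2w, abs=1e-5)
        assert vc.se_mu == pytest.approx(float(np.sqrt(cov[0, 0])), abs=1e-6)

    def test_all_identical_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            vc = fit_random_intercept({"A": [5, 5], "B": [5, 5]})
        assert (vc.mu, vc.sigma2_b, vc.sigma2_w) == (5.0, 0.0, 0.0)
        assert vc.degenerate

    def test_single_subject_raises(self):
        with pytest.raises(IdentifiabilityError):
            fit_random_intercept({"A": [1, 2, 3]})

    def test_boundary_truncation_flagged(self):
        # groups more alike than their insides: unconstrained sigma2_b < 0
        vc = fit_random_intercept({"A": [0, 10], "B": [1, 9], "C": [2, 8]})
        assert vc.sigma2_b == 0.0
        assert vc.at_boundary

    def test_singleton_groups_fall_back_to_single_level(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        with pytest.warns(UserWarning, match="unidentifiable"):
            vc = fit_random_intercept(y, np.arange(4))
        assert vc.sigma2_b == 0.0
        assert vc.sigma2_w == pytest.approx(np.var(y, ddof=1))
        assert vc.mu == pytest.approx(y.mean())


class TestBlandAltman:
    def test_loa_matches_printed_bounds_shape(self):
        # invert the printed "+23 (LoA -17; 63)": half-width 40 => total SD 40/1.96
        total_var = (40.0 / 1.96) ** 2
        v = 1.0
        u = np.sqrt((total_var - v**2) / 2.0)
        pairs = pairs_frame(
            ["A", "A", "B", "B"], [23 + u + v, 23 + u - v, 23 - u + v, 23 - u - v]
        )
        res = bland_altman_multilevel(pairs, 1.96)
        assert res.components.mu == pytest.approx(23.0, abs=1e-9)
        assert res.loa_lower == pytest.approx(-17.0, abs=1e-6)
        assert res.loa_upper == pytest.approx(63.0, abs=1e-6)

    def test_unit_case(self):
        # mu 0, total variance exactly 1 (sigma2_b = 0.44, sigma2_w = 0.28)
        u, v = 0.6, np.sqrt(0.28)
        pairs = pairs_frame(["A", "A", "B", "B"], [u + v, u - v, -u + v, -u - v])
        res = bland_altman_multilevel(pairs, 1.96)
        assert res.loa_lower == pytest.approx(-1.96, abs=1e-9)
        assert res.loa_upper == pytest.approx(1.96, abs=1e-9)

    def test_zero_variance_collapse(self):
        pairs = pairs_frame(["A", "A", "B", "B"], [23.0] * 4)
        with pytest.warns(UserWarning):
            res = bland_altman_multilevel(pairs)
        assert res.loa_lower == res.loa_upper == 23.0

    def test_symmetry_and_width(self, rng):
        for _ in range(10):
            subj = np.repeat(np.arange(8), 4)
            d = rng.normal(5, 3, len(subj)) + np.repeat(rng.normal(0, 2, 8), 4)
            res = bland_altman_multilevel(pairs_frame(subj, d))
            mu = res.components.mu
            assert res.loa_upper - mu == pytest.approx(mu - res.loa_lower, abs=1e-9)
            width = 2 * 1.96 * np.sqrt(res.components.sigma2_b + res.components.sigma2_w)
            assert res.loa_upper - res.loa_lower == pytest.approx(width, abs=1e-9)
            assert res.loa_lower <= mu <= res.loa_upper

    def test_reduces_to_classical_single_level(self, rng):
        d = rng.normal(10, 4, 40)
        with pytest.warns(UserWarning, match="unidentifiable"):
            res = bland_altman_multilevel(pairs_frame(np.arange(40), d))
        sd = np.std(d, ddof=1)
        assert res.components.mu == pytest.approx(d.mean())
        assert res.loa_lower == pytest.approx(d.mean() - 1.96 * sd, abs=1e-9)
        assert res.loa_upper == pytest.approx(d.mean() + 1.96 * sd, abs=1e-9)


class TestProportionalBias:
    def test_constant_d_zero_slope(self):
        pairs = pairs_frame(["A", "A", "B", "B"], [7.0] * 4, m=[1.0, 2.0, 3.0, 4.0])
        with pytest.warns(UserWarning, match="degenerate"):
            res = fit_proportional_bias(pairs)
        assert res.beta1 == pytest.approx(0.0, abs=1e-12)

    def test_noise_free_exact_interpolation(self):
        m = np.array([10.0, 20.0, 30.0, 40.0, 50.0, 60.0])
        pairs = pairs_frame(["A", "A", "B", "B", "C", "C"], 2.0 + 0.1 * m, m=m)
        with pytest.warns(UserWarning, match="degenerate"):
            res = fit_proportional_bias(pairs)
        assert res.beta0 == pytest.approx(2.0, abs=1e-10)
        assert res.beta1 == pytest.approx(0.1, abs=1e-12)

    def test_constant_m_raises(self):
        pairs = pairs_frame(["A", "A", "B", "B"], [1.0, 2.0, 3.0, 4.0], m=[5.0] * 4)
        with pytest.raises(RankDeficiencyError):
            fit_proportional_bias(pairs)

    def test_matches_gridsearch_oracle(self, rng):
        sizes = rng.integers(2, 5, 6)
        groups = np.repeat(np.arange(6), sizes)
        m = rng.normal(50, 10, len(groups))
        d = 1.5 + 0.2 * m + np.repeat(rng.normal(0, 1.0, 6), sizes) + rng.normal(0, 0.8, len(groups))
        X = np.column_stack([np.ones(len(d)), m])
        beta, cov, s2b, s2w = gridsearch_reml(d, groups, X)
        res = fit_proportional_bias(pairs_frame(groups, d, m=m))
        assert res.beta0 == pytest.approx(float(beta[0]), abs=1e-5)
        assert res.beta1 == pytest.approx(float(beta[1]), abs=1e-6)
        assert res.se_beta1 == pytest.approx(float(np.sqrt(cov[1, 1])), abs=1e-6)
        assert res.sigma2_b == pytest.approx(s2b, abs=1e-4)
        assert res.sigma2_w == pytest.approx(s2w, abs=1e-4)
        assert 0 < res.p_beta1 < 1


class TestMakePairsAndReport:
    def test_make_pairs_identities(self, rng):
        daily = pd.DataFrame(
            {
                "subject_id": ["S1", "S1", "S2"],
                "date": pd.date_range("2024-01-01", periods=3),
                "om_steps": [7000, 8000, 9000],
                "ag_steps": [7100, 7900, 9050],
                "om_mvpa_min": [60, 70, 80],
                "ag_mvpa_min": [40, 50, 55],
                "wear_min": [700, 700, 700],
                "valid": True,
            }
        )
        p = make_pairs(daily, "steps")
        np.testing.assert_allclose(p["d"], daily["om_steps"] - daily["ag_steps"])
        np.testing.assert_allclose(p["m"], (daily["om_steps"] + daily["ag_steps"]) / 2)
        p = make_pairs(daily, "mvpa")
        np.testing.assert_allclose(p["d"], [20, 20, 25])
        with pytest.raises(ValueError, match="outcome"):
            make_pairs(daily, "kcal")

    def test_report_payload_shape(self, rng):
        subj = np.repeat(np.arange(10), 5)
        m = rng.normal(50, 8, 50)
        d = 5 + np.repeat(rng.normal(0, 2, 10), 5) + rng.normal(0, 3, 50)
        pairs = pairs_frame(subj, d, m=m)
        payload = agreement_report(bland_altman_multilevel(pairs), fit_proportional_bias(pairs))
        assert set(payload) >= {"mu", "se", "sigma2_b", "sigma2_w", "loa", "slope"}
        lo, hi = payload["loa"]
        assert lo < payload["mu"] < hi
        assert payload["slope"]["se"] > 0
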