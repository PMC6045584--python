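"""3PL fitting, activity-area AUC scoring and robust Z standardisation."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chemoscreen.dose_response import (
    MAD_SCALE,
    ThreePLFit,
    auc_scaled,
    auc_unscaled,
    fit_three_pl,
    pool_replicates,
    robust_z_scores,
    three_pl,
)
from chemoscreen.qc import SurvivingFractionTable
from chemoscreen.simulate import DOSE_SERIES

C_MIN, C_MAX = DOSE_SERIES[0], DOSE_SERIES[-1]


def make_fit(b, d, e, **kw):
    defaults = dict(
        compound_id="cpd", cell_line_id="cl", converged=True, rss=0.0, n_points=8
    )
    defaults.update(kw)
    return ThreePLFit(b=b, d=d, e=e, **defaults)


def brute_force_auc_unscaled(b, d, e, c_min, c_max, n=100_000):
    u = np.linspace(np.log(c_min), np.log(c_max), n + 1)
    sf = np.clip(three_pl(np.exp(u), b, d, e), 0.0, 1.0)
    return np.trapezoid(sf, u) / (u[-1] - u[0])


def brute_force_auc_scaled(b, d, e, c_min, c_max, n=100_000):
    u = np.linspace(np.log(c_min), np.log(c_max), n + 1)
    a = np.clip(1.0 - three_pl(np.exp(u), b, d, e), 0.0, 1.0)
    excess = np.maximum(0.0, a - max(0.0, a[0]))
    return 1.0 - np.trapezoid(excess, u) / (u[-1] - u[0])


def _param_draws(n, seed):
    rng = np.random.default_rng(seed)
    for _ in range(n):
        yield (
            rng.uniform(0.2, 8.0),                       # b
            rng.uniform(0.1, 1.5),                       # d
            np.exp(rng.uniform(np.log(0.05), np.log(1e4))),  # e
        )


class TestPooling:
    def _sf_table(self, n_reps=3, drop=None):
        reps = []
        for r in range(n_reps):
            rep = {("cpd", c): 0.5 for c in DOSE_SERIES}
            if drop and r == drop[0]:
                del rep[("cpd", drop[1])]
            reps.append(rep)
        return SurvivingFractionTable("CL1", tuple(reps))

    def test_three_replicates_eight_doses(self):
        assert len(pool_replicates(self._sf_table(), "cpd")) == 24

    def test_missing_dose_absent(self):
        pts = pool_replicates(self._sf_table(drop=(1, 50.0)), "cpd")
        assert len(pts) == 23

    def test_unknown_compound_raises(self):
        with pytest.raises(KeyError):
            pool_replicates(self._sf_table(), "nope")


class TestFitThreePL:
    def test_noise_free_recovery(self):
        b, d, e = 1.0, 1.0, 50.0
        pts = [(c, float(three_pl(c, b, d, e))) for c in DOSE_SERIES] * 3
        fit = fit_three_pl(pts)
        assert fit.converged
        assert fit.b == pytest.approx(b, rel=1e-4)
        assert fit.d == pytest.approx(d, rel=1e-4)
        assert fit.e == pytest.approx(e, rel=1e-4)

    def test_flat_survival_yields_unit_auc(self):
        pts = [(c, 1.0) for c in DOSE_SERIES]
        fit = fit_three_pl(pts)
        assert fit.converged
        assert fit.d == pytest.approx(1.0, abs=1e-6)
        assert auc_unscaled(fit, C_MIN, C_MAX) == pytest.approx(1.0, abs=1e-5)
        assert auc_scaled(fit, C_MIN, C_MAX) == pytest.approx(1.0, abs=1e-5)

    def test_single_dose_underdetermined(self):
        with pytest.raises(ValueError, match="distinct doses"):
            fit_three_pl([(10.0, 0.5)] * 6)

    def test_nonpositive_dose_raises(self):
        with pytest.raises(ValueError, match="positive"):
            fit_three_pl([(0.0, 1.0), (1.0, 0.9), (10.0, 0.5), (100.0, 0.1)])


class TestAUC:
    def test_no_effect_is_one(self):
        fit = make_fit(b=1.0, d=1.0, e=1e12)
        assert auc_unscaled(fit, C_MIN, C_MAX) == pytest.approx(1.0, abs=1e-6)

    def test_complete_kill_is_zero(self):
        fit = make_fit(b=1.0, d=0.0, e=50.0)
        assert auc_unscaled(fit, C_MIN, C_MAX) == pytest.approx(0.0, abs=1e-6)

    def test_step_at_geometric_midpoint_is_half(self):
        e_mid = float(np.sqrt(C_MIN * C_MAX))
        fit = make_fit(b=10.0, d=1.0, e=e_mid)
        oracle = brute_force_auc_unscaled(10.0, 1.0, e_mid, C_MIN, C_MAX)
        val = auc_unscaled(fit, C_MIN, C_MAX)
        assert val == pytest.approx(oracle, abs=1e-5)
        assert val == pytest.approx(0.5, abs=0.02)

    def test_scaled_reduces_to_unscaled_when_no_low_dose_activity(self):
        # SF(c_min) > 1 clips to activity 0 at the lowest dose
        fit = make_fit(b=1.0, d=1.2, e=50.0)
        assert three_pl(C_MIN, 1.0, 1.2, 50.0) > 1.0
        assert auc_scaled(fit, C_MIN, C_MAX) == pytest.approx(
            auc_unscaled(fit, C_MIN, C_MAX), abs=1e-6
        )

    def test_dose_flat_activity_scores_one(self):
        # d < 1 with a huge ED50: constant activity, no dose dependence
        fit = make_fit(b=1.0, d=0.7, e=1e12)
        assert auc_scaled(fit, C_MIN, C_MAX) == pytest.approx(1.0, abs=1e-6)

    def test_matches_brute_force_quadrature(self):
        fit = make_fit(b=1.0, d=1.0, e=50.0)
        assert auc_scaled(fit, C_MIN, C_MAX) == pytest.approx(
            brute_force_auc_scaled(1.0, 1.0, 50.0, C_MIN, C_MAX), abs=1e-5
        )
        assert auc_unscaled(fit, C_MIN, C_MAX) == pytest.approx(
            brute_force_auc_unscaled(1.0, 1.0, 50.0, C_MIN, C_MAX), abs=1e-5
        )

    def test_nonconverged_fit_scores_missing(self):
        fit = ThreePLFit(
            "cpd", "cl", b=np.nan, d=np.nan, e=np.nan,
            converged=False, rss=np.nan, n_points=8,
        )
        assert np.isnan(auc_unscaled(fit, C_MIN, C_MAX))
        assert np.isnan(auc_scaled(fit, C_MIN, C_MAX))

    def test_invalid_range_raises(self):
        with pytest.raises(ValueError):
            auc_unscaled(make_fit(1.0, 1.0, 50.0), 100.0, 10.0)

    def test_monotone_in_ed50(self):
        # less potent (higher e) => higher surviving-fraction AUC
        for b, d, _ in _param_draws(20, seed=11):
            es = np.exp(np.linspace(np.log(0.1), np.log(1e4), 6))
            aucs = [auc_unscaled(make_fit(b, d, e), C_MIN, C_MAX) for e in es]
            assert all(y2 >= y1 - 1e-9 for y1, y2 in zip(aucs, aucs[1:]))

    @given(factor=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=20, deadline=None)
    def test_concentration_scale_invariance(self, factor):
        b, d, e = 1.3, 0.95, 40.0
        base_u = auc_unscaled(make_fit(b, d, e), C_MIN, C_MAX)
        base_s = auc_scaled(make_fit(b, d, e), C_MIN, C_MAX)
        scaled_u = auc_unscaled(
            make_fit(b, d, e * factor), C_MIN * factor, C_MAX * factor
        )
        scaled_s = auc_scaled(
            make_fit(b, d, e * factor), C_MIN * factor, C_MAX * factor
        )
        assert scaled_u == pytest.approx(base_u, abs=1e-6)
        assert scaled_s == pytest.approx(base_s, abs=1e-6)


class TestRobustZ:
    def test_hand_computed_column(self):
        m = pd.DataFrame({"drug": [0.2, 0.5, 0.8]}, index=["a", "b", "c"])
        z = robust_z_scores(m)["drug"]
        expected = 0.3 / (MAD_SCALE * 0.3)  # = 1/1.4826 = 0.67449
        assert z.tolist() == pytest.approx([-expected, 0.0, expected])
        assert expected == pytest.approx(0.6745, abs=1e-4)

    def test_median_element_is_zero(self):
        m = pd.DataFrame({"drug": [0.11, 0.47, 0.93, 0.2, 0.8]})
        z = robust_z_scores(m)["drug"]
        assert z.iloc[1] == pytest.approx(0.0, abs=1e-12)

    def test_constant_column_warns_and_is_missing(self):
        m = pd.DataFrame({"drug": [0.5, 0.5, 0.5, 0.5]})
        with pytest.warns(RuntimeWarning, match="zero MAD"):
            z = robust_z_scores(m)
        assert z["drug"].isna().all()

    def test_too_few_values_raise(self):
        m = pd.DataFrame({"drug": [0.5, np.nan, np.nan, 0.7]})
        with pytest.raises(ValueError, match=">=3"):
            robust_z_scores(m)

    def test_affine_invariances(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame({"drug": rng.uniform(0, 1, size=12)})
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            z0 = robust_z_scores(m)["drug"]
            z_shift = robust_z_scores(m + 0.37)["drug"]
            z_scale = robust_z_scores(m * 4.2)["drug"]
        np.testing.assert_allclose(z_shift, z0, atol=1e-10)
        np.testing.assert_allclose(z_scale, z0, atol=1e-10)

    def test_missing_values_propagate(self):
        m = pd.DataFrame({"drug": [0.2, np.nan, 0.5, 0.8]})
        z = robust_z_scores(m)["drug"]
        assert np.isnan(z.iloc[1]) and np.isfinite(z.iloc[0])
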