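import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tempyll.attribution import (
    attributable_fraction,
    attributable_series,
    attribute,
    find_mmt,
    mc_eci,
)
from tempyll.basis import SplineSpec, spline_basis
from tempyll.first_stage import ReducedAssociation
from tempyll.series import CityDailySeries

VAR_SPEC = SplineSpec(
    family="bspline", internal_knots=(14.0, 22.0), boundary_knots=(0.0, 32.0), degree=2
)


def make_assoc(eta, vcov=None, lo=10.0, hi=30.0):
    eta = np.asarray(eta, dtype=float)
    return ReducedAssociation(
        eta=eta,
        vcov=np.zeros((len(eta), len(eta))) if vcov is None else vcov,
        var_spec=VAR_SPEC,
        reference_temperature=20.0,
        temp_percentiles={1: lo, 25: 15.0, 50: 20.0, 75: 25.0, 99: hi},
        temp_range=(lo, hi),
        city_id="toy",
    )


def eta_for_function(f):
    """Project f onto span{basis, 1}; exact for quadratics (the basis plus a
    constant spans all quadratic splines on these knots)."""
    x = np.linspace(0.0, 32.0, 400)
    B = np.column_stack([spline_basis(x, VAR_SPEC), np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(B, f(x), rcond=None)
    return coef[:-1]


def make_series(temps, yll=100.0):
    temps = np.asarray(temps, dtype=float)
    idx = pd.date_range("2014-01-01", periods=len(temps))
    data = pd.DataFrame(
        {"yll": np.full(len(temps), float(yll)), "temp": temps, "rh": 70.0, "ws": 1.0,
         "sunshine": 5.0, "ap": 844.0, "holiday": False}, index=idx,
    )
    return CityDailySeries("toy", data)


class TestFindMmt:
    def test_quadratic_vertex_found_exactly(self):
        assoc = make_assoc(eta_for_function(lambda x: 0.5 * (x - 20.0) ** 2))
        assert find_mmt(assoc) == pytest.approx(20.0, abs=1e-9)

    def test_monotone_curve_returns_lower_search_bound(self):
        assoc = make_assoc(eta_for_function(lambda x: 3.0 * x))
        assert find_mmt(assoc) == pytest.approx(10.0, abs=1e-9)

    def test_matches_fine_grid_oracle_within_step(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            assoc = make_assoc(rng.normal(0, 5, 4))
            coarse = find_mmt(assoc)
            fine = np.arange(10.0, 30.0 + 1e-9, 0.001)
            vals = spline_basis(fine, VAR_SPEC) @ assoc.eta
            assert abs(coarse - fine[np.argmin(vals)]) <= 0.1 + 1e-9

    def test_tie_breaks_toward_lower_temperature(self):
        assoc = make_assoc(np.zeros(4))  # flat curve: every grid point ties
        assert find_mmt(assoc) == pytest.approx(10.0, abs=1e-9)


class TestAttributableSeries:
    def test_reference_exposure_contributes_nothing(self):
        assoc = make_assoc(eta_for_function(lambda x: (x - 18.0) ** 2))
        s = make_series(np.full(12, 18.0))
        at = attributable_series(s, assoc, mmt=18.0)
        assert np.allclose(at["attributable_yll"], 0.0)
        assert (at["label"] == "reference").all()

    def test_null_association_contributes_nothing(self):
        s = make_series(np.linspace(5, 30, 15))
        at = attributable_series(s, make_assoc(np.zeros(4)), mmt=20.0)
        assert np.allclose(at["attributable_yll"], 0.0)

    def test_toy_series_matches_per_day_hand_computation(self):
        eta = np.array([3.0, -1.0, 2.0, 0.5])
        assoc = make_assoc(eta)
        temps = [12.0, 25.0, 20.0, 8.0, 30.0, 17.0, 21.5, 19.9, 23.0, 14.0]
        s = make_series(temps)
        at = attributable_series(s, assoc, mmt=20.0)
        Bm = spline_basis(np.array([20.0]), VAR_SPEC)[0]
        for day, x in enumerate(temps):
            expected = spline_basis(np.array([x]), VAR_SPEC)[0] @ eta - Bm @ eta
            assert at["attributable_yll"].iloc[day] == pytest.approx(expected, abs=1e-12)
            assert at["label"].iloc[day] == ("cold" if x < 20 else "heat" if x > 20 else "reference")

    def test_centering_invariance(self):
        eta = np.array([1.0, 2.0, -0.5, 0.3])
        s = make_series(np.linspace(5, 30, 20))
        a1 = dataclasses.replace(make_assoc(eta), reference_temperature=12.0)
        a2 = dataclasses.replace(make_assoc(eta), reference_temperature=25.0)
        r1 = attributable_series(s, a1, mmt=20.0)["attributable_yll"]
        r2 = attributable_series(s, a2, mmt=20.0)["attributable_yll"]
        assert np.allclose(r1, r2, atol=1e-12)

    def test_out_of_range_temperatures_clamped_and_counted(self):
        assoc = make_assoc(np.ones(4))
        s = make_series([-5.0, 10.0, 40.0])
        at = attributable_series(s, assoc, mmt=20.0)
        assert at.attrs["n_clamped"] == 2
        assert np.isfinite(at["attributable_yll"]).all()


class TestAttributableFraction:
    def test_flat_curve_gives_zero_fractions(self):
        s = make_series(np.linspace(5, 30, 30))
        res = attributable_fraction(s, make_assoc(np.zeros(4)), 20.0)
        assert res.af_total == res.af_cold == res.af_heat == 0.0

    @given(st.integers(0, 10_000))
    def test_partition_identity_on_arbitrary_inputs(self, seed):
        rng = np.random.default_rng(seed)
        assoc = make_assoc(rng.normal(0, 5, 4))
        s = make_series(rng.uniform(2, 31, 40), yll=rng.uniform(50, 200))
        res = attributable_fraction(s, assoc, float(rng.uniform(12, 28)))
        assert res.af_cold + res.af_heat == pytest.approx(res.af_total, abs=1e-12)

    def test_scaling_eta_scales_attributable_yll_linearly(self):
        rng = np.random.default_rng(7)
        eta = rng.normal(0, 2, 4)
        s = make_series(rng.uniform(5, 30, 25))
        r1 = attributable_fraction(s, make_assoc(eta), 20.0)
        r3 = attributable_fraction(s, make_assoc(3.0 * eta), 20.0)
        assert r3.attributable_yll_total == pytest.approx(3.0 * r1.attributable_yll_total, rel=1e-12)
        assert r3.attributable_yll_cold == pytest.approx(3.0 * r1.attributable_yll_cold, rel=1e-12)

    def test_province_pooling_divides_summed_attributable_by_summed_total(self):
        rng = np.random.default_rng(8)
        series = [make_series(rng.uniform(5, 30, 30), yll=80.0),
                  make_series(rng.uniform(5, 30, 30), yll=160.0)]
        assocs = [make_assoc(rng.normal(0, 2, 4)) for _ in range(2)]
        mmts = [18.0, 22.0]
        pooled = attributable_fraction(series, assocs, mmts)
        per = [attributable_fraction(s, a, m) for s, a, m in zip(series, assocs, mmts)]
        num = sum(r.attributable_yll_total for r in per)
        den = sum(r.total_yll for r in per)
        assert pooled.af_total == pytest.approx(num / den, abs=1e-12)

    def test_zero_total_yll_rejected(self):
        s = make_series(np.linspace(5, 30, 10), yll=0.0)
        with pytest.raises(ValueError, match="positive"):
            attributable_fraction(s, make_assoc(np.ones(4)), 20.0)


class TestMonteCarloEci:
    def test_degenerate_vcov_collapses_to_point_estimate(self):
        eta = np.array([2.0, 1.0, 3.0, 0.5])
        s = make_series(np.linspace(5, 30, 40))
        assoc = make_assoc(eta)  # vcov = 0
        point = attributable_fraction(s, assoc, 20.0)
        eci = mc_eci(s, assoc, 20.0, n_iter=50, seed=1)
        for part in ("total", "cold", "heat"):
            lo, hi = eci[part]
            assert lo == pytest.approx(getattr(point, f"af_{part}"), abs=1e-12)
            assert hi == pytest.approx(getattr(point, f"af_{part}"), abs=1e-12)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        assoc = make_assoc(rng.normal(0, 2, 4), vcov=np.eye(4) * 0.2)
        s = make_series(rng.uniform(5, 30, 40))
        assert mc_eci(s, assoc, 20.0, n_iter=100, seed=5) == mc_eci(s, assoc, 20.0, n_iter=100, seed=5)

    def test_interval_widens_with_coefficient_uncertainty(self):
        rng = np.random.default_rng(10)
        eta = rng.normal(0, 2, 4)
        s = make_series(rng.uniform(5, 30, 60))
        narrow = mc_eci(s, make_assoc(eta, vcov=np.eye(4) * 0.01), 20.0, n_iter=400, seed=2)
        wide = mc_eci(s, make_assoc(eta, vcov=np.eye(4) * 1.0), 20.0, n_iter=400, seed=2)
        assert wide["total"][1] - wide["total"][0] > narrow["total"][1] - narrow["total"][0]

    def test_refind_policy_moves_mmt_per_draw(self):
        rng = np.random.default_rng(11)
        eta = eta_for_function(lambda x: 0.3 * (x - 20.0) ** 2)
        s = make_series(rng.uniform(5, 30, 60))
        assoc = make_assoc(eta, vcov=np.eye(4) * 0.5)
        fixed = mc_eci(s, assoc, 20.0, n_iter=200, seed=3, mmt_policy="fixed")
        refound = mc_eci(s, assoc, 20.0, n_iter=200, seed=3, mmt_policy="refind")
        assert fixed != refound

    def test_invalid_arguments(self):
        s = make_series(np.linspace(5, 30, 10))
        with pytest.raises(ValueError, match="n_iter"):
            mc_eci(s, make_assoc(np.ones(4)), 20.0, n_iter=1)
        with pytest.raises(ValueError, match="policy"):
            mc_eci(s, make_assoc(np.ones(4)), 20.0, mmt_policy="sometimes")


class TestAttributeWrapper:
    def test_full_attribution_searches_mmt_and_attaches_eci(self):
        rng = np.random.default_rng(12)
        eta = eta_for_function(lambda x: 0.4 * (x - 19.0) ** 2)
        assoc = make_assoc(eta, vcov=np.eye(4) * 0.05)
        s = make_series(rng.uniform(5, 30, 80))
        res = attribute(s, assoc, n_iter=200, seed=4)
        assert res.mmt == pytest.approx(19.0, abs=0.11)
        assert res.n_mc == 200
        assert res.eci_95["total"][0] <= res.af_total <= res.eci_95["total"][1]
        assert res.af_cold + res.af_heat == pytest.approx(res.af_total, abs=1e-12)
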