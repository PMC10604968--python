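"""Efficacy metrics: kill fraction, AUC, half-width, axis profiles."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import i0

from ipchemo import metrics as mt
from ipchemo.errors import AxisOutsideError, BadSeriesError, InvalidConcentrationError


class TestFractionKilled:
    @pytest.mark.parametrize(
        "ci,fk",
        [
            (0.0, 0.0),
            (np.log(2) / 0.6603, 0.5),      # inversion of the kill law
            (0.3456, 0.204),                 # FK at C_I = 0.3456 mol/m^3
        ],
    )
    def test_pointwise_values(self, ci, fk):
        val, mean = mt.fraction_killed(ci)
        assert val == pytest.approx(fk, abs=5e-4)
        assert mean == pytest.approx(fk, abs=5e-4)

    def test_area_weighted_mean(self):
        fk, mean = mt.fraction_killed(np.array([0.0, 1.0]), omega=1.0,
                                      weights=np.array([3.0, 1.0]))
        assert mean == pytest.approx((1.0 - np.exp(-1.0)) / 4.0)

    def test_negative_concentration_is_error(self):
        with pytest.raises(InvalidConcentrationError):
            mt.fraction_killed(np.array([0.1, -0.01]))

    def test_monotone_in_time(self):
        ci = np.linspace(0, 0.5, 50)  # C_I is non-decreasing in t
        fk = 1.0 - np.exp(-0.6603 * ci)
        assert np.all(np.diff(fk) >= 0)


class TestAUC:
    def test_constant_and_ramp(self):
        t = np.linspace(0, 60, 61)
        assert mt.auc_mean_free(t, np.ones(61)) == pytest.approx(60.0)
        assert mt.auc_mean_free(t, t / 60.0) == pytest.approx(30.0)

    def test_exponential_decay_closed_form(self):
        t = np.arange(0.0, 3600.0 + 1, 1.0)
        tau = 600.0
        auc = mt.auc_mean_free(t, np.exp(-t / tau))
        assert auc == pytest.approx(tau * (1 - np.exp(-6.0)), rel=1e-3)

    def test_additive_over_partitions(self):
        rng = np.random.default_rng(5)
        t = np.linspace(0, 100, 201)
        v = rng.random(201)
        total = mt.auc_mean_free(t, v)
        split = mt.auc_mean_free(t[:101], v[:101]) + mt.auc_mean_free(t[100:], v[100:])
        assert split == pytest.approx(total, rel=1e-12)

    def test_bad_series_is_error(self):
        with pytest.raises(BadSeriesError):
            mt.auc_mean_free(np.array([0.0, 2.0, 1.0]), np.ones(3))
        with pytest.raises(BadSeriesError):
            mt.auc_mean_free(np.array([0.0]), np.array([1.0]))


class TestHalfWidth:
    def test_linear_profile(self):
        d = np.linspace(0, 1, 101)
        c = 0.8 * (1 - d)
        assert mt.half_width(d, c, 0.8) == pytest.approx(0.5, abs=1e-9)

    def test_exponential_profile_analytic_crossing(self):
        d = np.linspace(0, 1.0, 2001)
        c = 0.8 * np.exp(-d / 0.2)
        assert mt.half_width(d, c, 0.8) == pytest.approx(0.2 * np.log(2), abs=1e-4)

    def test_uniform_profile_no_crossing(self):
        d = np.linspace(0, 1, 11)
        assert mt.half_width(d, np.full(11, 0.8), 0.8) is None

    def test_profile_starting_below_half_is_no_crossing(self):
        d = np.linspace(0, 1, 11)
        assert mt.half_width(d, np.linspace(0.3, 0.0, 11), 0.8) is None


class TestAxisProfiles:
    def test_constant_field_constant_profiles(self, disc_mesh):
        field = np.full(disc_mesh.n_nodes, 3.25)
        profs = mt.axis_profiles(disc_mesh, field, n_samples=50)
        assert set(profs) == {"Axis1", "Axis2", "Axis3", "Axis4"}
        for df in profs.values():
            inside = ~df["in_lumen"]
            assert np.allclose(df.loc[inside, "value"], 3.25)

    def test_eight_surface_intersections(self, disc_geometry):
        segs = mt.AxisSpec().segments(disc_geometry)
        pts = [p for seg in segs.values() for p in seg]
        assert len(pts) == 8
        for p in pts:
            assert np.hypot(p[0] / 1.755, p[1] / 1.755) == pytest.approx(1.0, abs=1e-9)

    def test_bessel_profile_symmetry_and_accuracy(self, disc_mesh, disc_flow, tissue_params):
        profs = mt.axis_profiles(disc_mesh, disc_flow.IFP, n_samples=201)
        R = 1.755e-3
        Pe = tissue_params.effective_pressure
        a = tissue_params.alpha
        for df in profs.values():
            r = np.hypot(df["x"], df["y"]).to_numpy() * 1e-3
            exact = Pe * (1 - i0(a * r) / i0(a * R))
            assert np.nanmax(np.abs(df["value"].to_numpy() - exact)) < 0.01 * Pe
            v = df["value"].to_numpy()
            both = np.isfinite(v) & np.isfinite(v[::-1])  # chord tips may graze the hull
            assert np.allclose(v[both], v[::-1][both], atol=0.015 * Pe)

    def test_anchor_outside_is_error(self, disc_geometry):
        with pytest.raises(AxisOutsideError):
            mt.AxisSpec(anchor=(5.0, 0.0)).segments(disc_geometry)

    def test_half_widths_from_both_ends(self):
        d = np.linspace(0, 2, 401)
        v = 0.8 * np.exp(-d / 0.2) + 0.8 * np.exp(-(2 - d) / 0.4)
        profs = {"AxisX": pd.DataFrame({"s": d, "value": v})}
        w = mt.half_widths(profs, 0.8)
        assert w["AxisX:start"] == pytest.approx(0.2 * np.log(2), abs=5e-3)
        assert w["AxisX:end"] == pytest.approx(0.4 * np.log(2), abs=5e-3)
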