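import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stproj as sp
from stproj.covariance import LagBinGrid


def quadratic_root_oracle(h: float, tau: float, model: sp.SeparableCovModel) -> float:
    """Independent oracle: solve the speed quadratic with numpy.roots and
    select the root keeping the projected lag positive."""
    roots = np.roots(
        [model.alpha_t * tau, -2.0 * model.alpha_t * h, -model.alpha_s**2]
    )
    admissible = [r.real for r in roots if abs(r.imag) < 1e-12 and h - r.real * tau > 0]
    assert len(admissible) == 1
    return admissible[0]


class TestSolveVelocity:
    def test_printed_spot_check_origin(self, printed_model):
        v = sp.solve_velocity(0.0, 2.0, printed_model)
        assert v == pytest.approx(-5000.0)
        assert v == pytest.approx(quadratic_root_oracle(0.0, 2.0, printed_model))

    def test_printed_spot_check_10km(self, printed_model):
        v = sp.solve_velocity(10_000.0, 2.0, printed_model)
        assert v == pytest.approx(5000.0 * (1 - np.sqrt(2.0)))
        assert v == pytest.approx(quadratic_root_oracle(10_000.0, 2.0, printed_model))

    def test_quadratic_residual_zero(self, printed_model):
        for h, tau in [(0.0, 2.0), (10_000.0, 2.0), (25_000.0, 1.0)]:
            v = sp.solve_velocity(h, tau, printed_model)
            res = (
                printed_model.alpha_t * tau * v**2
                - 2 * printed_model.alpha_t * h * v
                - printed_model.alpha_s**2
            )
            assert abs(res) <= 1e-9 * printed_model.alpha_s**2

    def test_tau_zero_rejected(self, printed_model):
        with pytest.raises(ValueError, match="singular"):
            sp.solve_velocity(5_000.0, 0.0, printed_model)

    @given(
        h=st.floats(min_value=0.0, max_value=50_000.0),
        tau=st.floats(min_value=0.01, max_value=5.0),
        alpha_s=st.floats(min_value=1_000.0, max_value=50_000.0),
        alpha_t=st.floats(min_value=0.5, max_value=5.0),
    )
    @settings(max_examples=300, deadline=None)
    def test_root_property_and_consistency(self, h, tau, alpha_s, alpha_t):
        model = sp.SeparableCovModel(1.0, alpha_s, alpha_t)
        v = sp.solve_velocity(h, tau, model)
        res = alpha_t * tau * v**2 - 2 * alpha_t * h * v - alpha_s**2
        assert abs(res) <= 1e-9 * alpha_s**2
        r_hat = h - v * tau
        assert r_hat > 0
        assert r_hat == pytest.approx(sp.projected_lag(h, tau, model), rel=1e-9)


class TestProjectedLag:
    def test_tau_zero_reduces_to_h(self, printed_model):
        assert sp.projected_lag(10_000.0, 0.0, printed_model) == pytest.approx(10_000.0)

    def test_printed_diagonal(self, printed_model):
        assert sp.projected_lag(10_000.0, 2.0, printed_model) == pytest.approx(
            10_000.0 * np.sqrt(2.0)
        )

    def test_pure_temporal(self, printed_model):
        assert sp.projected_lag(0.0, 2.0, printed_model) == pytest.approx(10_000.0)

    def test_negative_tau_rejected(self, printed_model):
        with pytest.raises(ValueError):
            sp.projected_lag(1.0, -0.5, printed_model)


class TestVelocitySurface:
    def test_contains_printed_cell(self, printed_model):
        surf = sp.velocity_surface(printed_model, [0.0, 10_000.0], [1.0, 2.0])
        cell = surf[(surf["h_m"] == 0.0) & (surf["tau_yr"] == 2.0)]
        assert cell["velocity_m_per_yr"].iloc[0] == pytest.approx(-5000.0)

    def test_increasing_in_h(self, printed_model):
        h = np.linspace(0, 50_000, 21)
        surf = sp.velocity_surface(printed_model, h, [2.0])
        v = surf["velocity_m_per_yr"].to_numpy()
        assert np.all(np.diff(v) > 0)

    def test_every_cell_is_a_root(self, printed_model):
        surf = sp.velocity_surface(
            printed_model, np.linspace(0, 50_000, 11), np.arange(1.0, 6.0)
        )
        h = surf["h_m"].to_numpy()
        tau = surf["tau_yr"].to_numpy()
        v = surf["velocity_m_per_yr"].to_numpy()
        res = (
            printed_model.alpha_t * tau * v**2
            - 2 * printed_model.alpha_t * h * v
            - printed_model.alpha_s**2
        )
        assert np.max(np.abs(res)) <= 1e-9 * printed_model.alpha_s**2

    def test_rejects_nonpositive_tau(self, printed_model):
        with pytest.raises(ValueError):
            sp.velocity_surface(printed_model, [0.0], [0.0])


def _single_bin_grid(h, tau, count=10):
    return LagBinGrid(
        spatial_edges=np.array([0.0, 50_000.0]),
        cov=np.array([[np.nan, np.nan], [np.nan, 0.5]]),
        count=np.array([[0, 0], [0, count]], dtype=np.int64),
        h_mean=np.array([[np.nan, np.nan], [np.nan, h]]),
        temporal_edges=np.array([0.0, 5.0]),
        t_mean=np.array([[np.nan, np.nan], [np.nan, tau]]),
    )


def _two_bin_grid(h1, h2, tau, c1, c2):
    return LagBinGrid(
        spatial_edges=np.array([0.0, 25_000.0, 50_000.0]),
        cov=np.array([[np.nan, 0.5], [np.nan, 0.4], [np.nan, 0.3]]),
        count=np.array([[0, 0], [0, c1], [0, c2]], dtype=np.int64),
        h_mean=np.array([[np.nan, np.nan], [np.nan, h1], [np.nan, h2]]),
        temporal_edges=np.array([0.0, 5.0]),
        t_mean=np.array([[np.nan, np.nan], [np.nan, tau], [np.nan, tau]]),
    )


class TestRepresentativeVelocity:
    def test_single_bin_degenerate_mean(self, printed_model):
        grid = _single_bin_grid(0.0, 2.0)
        vel = sp.representative_velocity(grid, printed_model, "paircount_mean")
        assert vel.speed == pytest.approx(-5000.0)

    def test_fixed_strategy(self, printed_model):
        grid = _single_bin_grid(0.0, 2.0)
        vel = sp.representative_velocity(grid, printed_model, "fixed:0")
        assert vel.speed == 0.0

    def test_equal_counts_arithmetic_mean(self, printed_model):
        grid = _two_bin_grid(0.0, 10_000.0, 2.0, 7, 7)
        vel = sp.representative_velocity(grid, printed_model, "paircount_mean")
        expected = 0.5 * (
            sp.solve_velocity(0.0, 2.0, printed_model)
            + sp.solve_velocity(10_000.0, 2.0, printed_model)
        )
        assert vel.speed == pytest.approx(expected)

    def test_paircount_weighting(self, printed_model):
        grid = _two_bin_grid(0.0, 10_000.0, 2.0, 30, 10)
        vel = sp.representative_velocity(grid, printed_model, "paircount_mean")
        v1 = sp.solve_velocity(0.0, 2.0, printed_model)
        v2 = sp.solve_velocity(10_000.0, 2.0, printed_model)
        assert vel.speed == pytest.approx(0.75 * v1 + 0.25 * v2)

    def test_no_temporal_bins_fails(self, printed_model):
        grid = LagBinGrid(
            spatial_edges=np.array([0.0, 5_000.0]),
            cov=np.array([1.0, 0.5]),
            count=np.array([3, 3], dtype=np.int64),
            h_mean=np.array([0.0, 2_500.0]),
        )
        with pytest.raises(ValueError):
            sp.representative_velocity(grid, printed_model, "paircount_mean")

    def test_unknown_strategy(self, printed_model):
        with pytest.raises(ValueError, match="unknown velocity strategy"):
            sp.representative_velocity(
                _single_bin_grid(0.0, 2.0), printed_model, "bogus"
            )

    def test_variogram_match_recovers_speed(self, small_field):
        rec = sp.detrend(small_field.records, 100_000.0, 2.0)
        grid = sp.empirical_covariance(
            rec[["x_m", "y_m"]].to_numpy(),
            rec["residual"].to_numpy(),
            years=rec["year"].to_numpy(),
        )
        fit = sp.fit_model(grid, "separable_gaussian_exponential")
        vel = sp.representative_velocity(
            grid, fit.model, "variogram_match", records=rec
        )
        true_literal = small_field.true_params.speed / np.sqrt(2.0)
        assert vel.speed == pytest.approx(true_literal, rel=0.4)


class TestProjectCoordinates:
    def test_zero_speed_identity(self):
        vel = sp.VelocityResult(speed=0.0)
        xy = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = sp.project_coordinates(xy, np.array([2008, 2012]), vel, 2008)
        np.testing.assert_array_equal(out, xy)

    def test_literal_printed_example(self):
        vel = sp.VelocityResult(speed=5_000.0)
        out = sp.project_coordinates(
            np.array([[10_000.0, 20_000.0]]), np.array([2.0]), vel, 0.0
        )
        np.testing.assert_allclose(out, [[0.0, 10_000.0]])

    def test_roundtrip(self):
        rng = np.random.default_rng(0)
        xy = rng.uniform(0, 1e5, size=(30, 2))
        t = rng.integers(2008, 2013, size=30)
        vel = sp.VelocityResult(speed=-3_777.0)
        back = sp.backproject_coordinates(
            sp.project_coordinates(xy, t, vel, 2008), t, vel, 2008
        )
        np.testing.assert_allclose(back, xy, atol=1e-9)

    def test_vector_mode(self):
        vel = sp.VelocityResult(
            speed=-1000.0, mode="vector", direction=np.array([1.0, 0.0])
        )
        out = sp.project_coordinates(
            np.array([[5_000.0, 5_000.0]]), np.array([2010]), vel, 2008
        )
        np.testing.assert_allclose(out, [[3_000.0, 5_000.0]])

    def test_vector_mode_requires_unit_direction(self):
        with pytest.raises(ValueError, match="unit"):
            sp.VelocityResult(speed=1.0, mode="vector", direction=np.array([2.0, 0.0]))

    def test_nonfinite_speed_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            sp.VelocityResult(speed=np.nan)


class TestBacktransformEstimates:
    def test_single_point(self):
        out = sp.backtransform_estimates({"p1": 3.5}, {("s", 2008): "p1"})
        assert out == {("s", 2008): 3.5}

    def test_permutation_invariant(self):
        est = {"a": 1.0, "b": 2.0}
        m1 = {("x", 1): "a", ("y", 2): "b"}
        m2 = {("y", 2): "b", ("x", 1): "a"}
        assert sp.backtransform_estimates(est, m1) == sp.backtransform_estimates(
            est, m2
        )

    def test_missing_image_fails(self):
        with pytest.raises(KeyError):
            sp.backtransform_estimates({}, {("x", 1): "nowhere"})

    def test_composition_identity(self):
        # projecting and relabeling back leaves values untouched
        vel = sp.VelocityResult(speed=-2000.0)
        xy = np.array([[0.0, 0.0], [10_000.0, 5_000.0]])
        t = np.array([2008, 2010])
        proj = sp.project_coordinates(xy, t, vel, 2008)
        est_at_proj = {tuple(p): v for p, v in zip(proj, [1.1, 2.2])}
        image = {
            (tuple(s), int(ti)): tuple(p) for s, ti, p in zip(xy, t, proj)
        }
        out = sp.backtransform_estimates(est_at_proj, image)
        assert list(out.values()) == [1.1, 2.2]
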