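"""Closed-form flow model against independent numerical oracles.

Every closed form (perimeter mean, region mean, field mean) is checked
against brute-force quadrature of the density, which only uses the
kernel definition and never the closed forms themselves.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

import maizeflow as mf
from maizeflow.model import SquareFlowModel, calibrate

ORACLE_SIDES = [10.0, 50.0, 120.0, 700.0]


def perimeter_mean_oracle(model: SquareFlowModel, d: float, n: int = 200_000) -> float:
    """Line integral of the density around the side-(a-2d) square / perimeter."""
    a = model.a
    s = a - 2 * d
    t = (np.arange(n) + 0.5) / n * s + d  # positions along one side
    # by symmetry, all four sides integrate identically; use side y = d
    vals = np.array([model.density(x, d) for x in t])
    return float(vals.mean())


def field_mean_oracle(model: SquareFlowModel) -> float:
    quad, _ = integrate.dblquad(
        model.density, 0, model.a, 0, model.a, epsabs=1e-12, epsrel=1e-10
    )
    return quad / model.a**2


def region_mean_oracle(model: SquareFlowModel, d1: float, d2: float) -> float:
    quad_outer, _ = integrate.dblquad(
        model.density, d1, model.a - d1, d1, model.a - d1, epsabs=1e-12, epsrel=1e-10
    )
    s2 = model.a - 2 * d2
    quad_inner = 0.0
    if s2 > 0:
        quad_inner, _ = integrate.dblquad(
            model.density, d2, model.a - d2, d2, model.a - d2,
            epsabs=1e-12, epsrel=1e-10,
        )
    area = (model.a - 2 * d1) ** 2 - max(s2, 0.0) ** 2
    return (quad_outer - quad_inner) / area


class TestDensity:
    def test_center_value(self):
        m = SquareFlowModel(K=0.94385, a=120.0)
        assert m.density(60.0, 60.0) == pytest.approx(4 * 0.94385 / 61.0)
        # worked example: ~0.06% at the centre
        assert m.density(60.0, 60.0) == pytest.approx(0.0619, abs=5e-4)

    def test_corner_value(self):
        m = SquareFlowModel(K=2.0, a=50.0)
        assert m.density(0.0, 0.0) == pytest.approx(2.0 * (2.0 + 2.0 / 51.0))

    @given(
        x=st.floats(0, 120), y=st.floats(0, 120), k=st.floats(0.01, 10)
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetries_and_positivity(self, x, y, k):
        m = SquareFlowModel(K=k, a=120.0)
        v = m.density(x, y)
        assert v >= 0
        assert v == pytest.approx(m.density(120.0 - x, y), rel=1e-12)
        assert v == pytest.approx(m.density(x, 120.0 - y), rel=1e-12)
        assert v == pytest.approx(m.density(y, x), rel=1e-12)

    def test_outside_square_rejected(self):
        m = SquareFlowModel(K=1.0, a=120.0)
        with pytest.raises(ValueError):
            m.density(-1.0, 50.0)
        with pytest.raises(ValueError):
            m.density(50.0, 121.0)


class TestPerimeterMean:
    def test_against_line_integral_oracle(self):
        m = SquareFlowModel(K=1.0, a=120.0)
        oracle = perimeter_mean_oracle(m, 3.0)
        assert oracle == pytest.approx(0.31785, abs=1e-5)
        assert m.perimeter_mean(3.0) == pytest.approx(oracle, rel=1e-8)

    @pytest.mark.parametrize("a", ORACLE_SIDES)
    @pytest.mark.parametrize("dfrac", [0.0, 0.05, 0.25, 0.45])
    def test_oracle_equivalence_across_sizes(self, a, dfrac):
        m = SquareFlowModel(K=1.7, a=a)
        d = dfrac * a / 2
        assert m.perimeter_mean(d) == pytest.approx(
            perimeter_mean_oracle(m, d), rel=1e-6
        )

    def test_degenerate_center(self):
        m = SquareFlowModel(K=3.0, a=80.0)
        assert m.perimeter_mean(40.0) == pytest.approx(m.center_density())
        # the closed form is continuous approaching the centre
        assert m.perimeter_mean(40.0 - 1e-7) == pytest.approx(
            m.center_density(), rel=1e-6
        )

    def test_strictly_decreasing_in_depth(self):
        m = SquareFlowModel(K=1.0, a=120.0)
        ds = np.linspace(0.0, 60.0, 121)
        vals = [m.perimeter_mean(d) for d in ds]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_large_field_limit_recovers_hyperbola(self):
        # a -> infinity: K-bar(d)/K-bar(0) -> 1/(d+1)
        m = SquareFlowModel(K=1.0, a=1e7)
        for d in (1.0, 3.0, 10.0, 25.0):
            ratio = m.perimeter_mean(d) / m.perimeter_mean(0.0)
            assert ratio == pytest.approx(1.0 / (d + 1.0), rel=1e-4)

    def test_depth_out_of_range_rejected(self):
        m = SquareFlowModel(K=1.0, a=120.0)
        with pytest.raises(ValueError):
            m.perimeter_mean(-0.5)
        with pytest.raises(ValueError):
            m.perimeter_mean(61.0)


class TestRegionAndFieldMean:
    def test_field_mean_against_quadrature(self):
        m = SquareFlowModel(K=1.0, a=120.0)
        oracle = field_mean_oracle(m)
        assert oracle == pytest.approx(0.15986, abs=1e-5)
        assert m.field_mean() == pytest.approx(oracle, rel=1e-8)

    @pytest.mark.parametrize("a", ORACLE_SIDES)
    def test_field_mean_oracle_across_sizes(self, a):
        m = SquareFlowModel(K=0.6, a=a)
        assert m.field_mean() == pytest.approx(field_mean_oracle(m), rel=1e-6)

    def test_region_mean_interior_against_quadrature(self):
        # the 160 x 190 m stripping example, calibrated from K_0 = 10.625
        m = SquareFlowModel(K=9.96995, a=172.0)
        oracle = region_mean_oracle(m, 3.0, 86.0)
        assert oracle == pytest.approx(0.9008, abs=2e-4)
        assert m.region_mean(3.0, 86.0) == pytest.approx(oracle, rel=1e-6)

    def test_whole_field_identity(self):
        m = SquareFlowModel(K=2.3, a=90.0)
        assert m.region_mean(0.0, 45.0) == pytest.approx(m.field_mean(), rel=1e-12)

    def test_area_weighted_additivity(self):
        m = SquareFlowModel(K=1.1, a=120.0)
        a = m.a
        area_ring = a**2 - (a - 20.0) ** 2
        area_core = (a - 20.0) ** 2
        combined = (
            m.region_mean(0.0, 10.0) * area_ring
            + m.region_mean(10.0, a / 2) * area_core
        )
        assert combined == pytest.approx(m.field_mean() * a**2, rel=1e-12)

    def test_invalid_depth_order_rejected(self):
        m = SquareFlowModel(K=1.0, a=120.0)
        with pytest.raises(ValueError):
            m.region_mean(10.0, 10.0)

    def test_conservation_of_ring_weighted_perimeter_means(self):
        # integral of K-bar(d) * 4(a-2d) dd over [0, a/2] equals the
        # field mean times the area
        m = SquareFlowModel(K=1.0, a=120.0)
        val, _ = integrate.quad(
            lambda d: m.perimeter_mean(d) * 4 * (m.a - 2 * d), 0, m.a / 2, limit=200
        )
        assert val / m.a**2 == pytest.approx(m.field_mean(), rel=1e-6)


class TestCalibrate:
    def test_worked_example_constant(self):
        m = calibrate(120.0, 3.0, 0.3)
        assert m.K == pytest.approx(0.94385, abs=1e-5)

    @given(
        a=st.floats(20, 2000),
        dfrac=st.floats(0, 0.49),
        v=st.floats(0, 20),
    )
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, a, dfrac, v):
        d = dfrac * a / 2
        m = calibrate(a, d, v)
        assert m.perimeter_mean(d) == pytest.approx(v, rel=1e-12, abs=1e-15)

    def test_zero_observation_gives_null_model(self):
        m = calibrate(120.0, 3.0, 0.0)
        assert m.K == 0.0
        assert m.field_mean() == 0.0
        assert m.density(10.0, 20.0) == 0.0


class TestDecayCurveFamily:
    @pytest.mark.parametrize("I", [27.0, 175.0])
    def test_normalized_curves_bracketed(self, I):
        """Finite-field decay curves are attenuated relative to the
        infinite-field hyperbola: they sit between 1/(d+1) and the
        small-field (I = 10) curve, approaching 1/(d+1) as I grows."""
        m = SquareFlowModel(K=1.0, a=4 * I)
        m_small = SquareFlowModel(K=1.0, a=4 * 10.0)
        for d in np.linspace(0.5, 19.5, 20):
            norm = m.perimeter_mean(d) / m.perimeter_mean(0.0)
            small = m_small.perimeter_mean(d) / m_small.perimeter_mean(0.0)
            hyper = 1.0 / (d + 1.0)
            assert hyper <= norm <= small

    def test_pointwise_convergence_to_hyperbola(self):
        d = 10.0
        gaps = []
        for I in (25.0, 100.0, 400.0, 1600.0):
            m = SquareFlowModel(K=1.0, a=4 * I)
            norm = m.perimeter_mean(d) / m.perimeter_mean(0.0)
            gaps.append(abs(norm - 1.0 / (d + 1.0)))
        assert all(g1 > g2 for g1, g2 in zip(gaps, gaps[1:]))
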