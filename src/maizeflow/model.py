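"""Closed-form cross-fertilization model on the equivalent square.

Cross-fertilization by foreign pollen decays from each field border into
the interior as an equilateral hyperbola 1/(d+1), where ``d`` is the
distance to that border in metres.  On a square of side ``a`` the four
borders superpose, giving the density (in percent cross-fertilized
kernels)

    rho(x, y) = K * [ 1/(x+1) + 1/(y+1) + 1/(a-x+1) + 1/(a-y+1) ]

with a single proportionality constant ``K``.  ``K`` is *not* the border
mean: every mean quantity (border mean K_0, perimeter mean at depth d,
region means, whole-field mean %GM) is an integral of rho and comes out
in closed form below.  Calibrating ``K`` from one observed perimeter mean
at any depth therefore determines every other mean of the field.

All %GM quantities are on the 0-100 percent scale throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "SquareFlowModel",
    "calibrate",
]

#: Below this fraction of ``a``, a residual inner-square side ``a - 2d``
#: is treated as the degenerate single-point perimeter at the centre.
_DEGENERATE_SIDE_RTOL = 1e-12


@dataclass(frozen=True)
class SquareFlowModel:
    """Border-kernel flow model on a square field of side ``a``.

    Parameters
    ----------
    K:
        Proportionality constant of the density, percent units, >= 0.
    a:
        Side of the (equivalent) square in metres, > 0.
    """

    K: float
    a: float

    def __post_init__(self) -> None:
        if not self.K >= 0:
            raise ValueError(f"K must be >= 0, got {self.K}")
        if not self.a > 0:
            raise ValueError(f"square side a must be > 0, got {self.a}")

    # ------------------------------------------------------------------ #

    def density(self, x: float, y: float) -> float:
        """Pointwise cross-fertilization density rho(x, y), percent.

        Symmetric under x <-> a-x, y <-> a-y and x <-> y.  Defined on
        the closed square 0 <= x, y <= a.
        """
        a = self.a
        if not (0.0 <= x <= a and 0.0 <= y <= a):
            raise ValueError(f"point ({x}, {y}) outside the [0, {a}]^2 square")
        return self.K * (
            1.0 / (x + 1.0)
            + 1.0 / (y + 1.0)
            + 1.0 / (a - x + 1.0)
            + 1.0 / (a - y + 1.0)
        )

    def center_density(self) -> float:
        """Density at the field centre, 4K/(a/2 + 1)."""
        return 4.0 * self.K / (self.a / 2.0 + 1.0)

    def perimeter_mean(self, d: float) -> float:
        """Mean density along the perimeter at depth ``d`` (K-bar(d)).

        All points at distance ``d`` from the border lie on the concentric
        square of side a-2d; the mean is the line integral of the density
        around that square divided by its perimeter:

            K * [ 2 ln((a-d+1)/(d+1)) + (a-2d) (1/(d+1) + 1/(a-d+1)) ]
              / (a - 2d)

        At d = a/2 the perimeter degenerates to the centre point and the
        centre density is returned (the closed form is continuous there).
        """
        a = self.a
        if not 0.0 <= d <= a / 2.0:
            raise ValueError(f"depth d={d} outside [0, {a / 2}]")
        side = a - 2.0 * d
        if side <= a * _DEGENERATE_SIDE_RTOL:
            return self.center_density()
        log_term = math.log((a - d + 1.0) / (d + 1.0))
        return (
            self.K
            * (2.0 * log_term + side * (1.0 / (d + 1.0) + 1.0 / (a - d + 1.0)))
            / side
        )

    def border_mean(self) -> float:
        """Mean density along the field border, K_0 = perimeter_mean(0)."""
        return self.perimeter_mean(0.0)

    def region_mean(self, d1: float, d2: float) -> float:
        """Mean density over the concentric region between depths d1 < d2.

        The region is the frame between the inner squares at depths d1
        and d2 (for d2 = a/2, the full central portion beyond d1):

            [ 4K (a-2d1) ln((a-d1+1)/(d1+1))
              - 4K (a-2d2) ln((a-d2+1)/(d2+1)) ]
            / [ (a-2d1)^2 - (a-2d2)^2 ]
        """
        a = self.a
        if not (0.0 <= d1 < d2 <= a / 2.0):
            raise ValueError(f"need 0 <= d1 < d2 <= a/2, got d1={d1}, d2={d2}")

        def _num(d: float) -> float:
            side = a - 2.0 * d
            if side <= 0.0:
                return 0.0
            return side * math.log((a - d + 1.0) / (d + 1.0))

        s1 = a - 2.0 * d1
        s2 = max(a - 2.0 * d2, 0.0)
        return 4.0 * self.K * (_num(d1) - _num(d2)) / (s1 * s1 - s2 * s2)

    def field_mean(self) -> float:
        """Overall %GM of the field, 4K ln(a+1)/a (= region_mean(0, a/2))."""
        return 4.0 * self.K * math.log(self.a + 1.0) / self.a

    # ------------------------------------------------------------------ #

    def profile(self, depths) -> list[tuple[float, float]]:
        """(d, perimeter_mean(d)) pairs, handy for curve export/plotting."""
        return [(float(d), self.perimeter_mean(float(d))) for d in depths]


def calibrate(a: float, d: float, K_d_observed: float) -> SquareFlowModel:
    """Fit K so the model's perimeter mean at depth ``d`` equals an observation.

    The perimeter mean is proportional to K, so the fit is a single
    division by the unit-K mean; the round trip
    ``calibrate(a, d, v).perimeter_mean(d) == v`` is exact.

    Parameters
    ----------
    a:
        Equivalent square side (4I) in metres.
    d:
        Sampling depth of the observation, 0 <= d <= a/2.
    K_d_observed:
        Observed mean cross-fertilization at depth ``d``, percent, >= 0.
    """
    if not K_d_observed >= 0:
        raise ValueError(f"observed mean must be >= 0, got {K_d_observed}")
    unit = SquareFlowModel(K=1.0, a=a)
    return SquareFlowModel(K=K_d_observed / unit.perimeter_mean(d), a=a)
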