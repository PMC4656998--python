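"""Whole-field %GM estimators from one or two sample summaries.

Two estimators cover the simplified sampling designs:

* **single-ring** — from the pooled perimeter mean ``K_d`` at sampling
  depth ``d`` alone: calibrate the equivalent-square flow model and read
  off its field mean.  Exact when all adventitious GM is external pollen
  flow; *halves* any GM of internal origin (seed admixture, volunteers),
  because internal GM raises K_d by its full amount but the model then
  spreads only the border-driven decay pattern over the field.

* **two-part** — from ``K_3`` plus a centre sample ``K_c``: the field is
  split into the 10 m peripheral ring (mean well approximated by K_3)
  and the central portion (mean taken from the centre sample), and the
  overall %GM is their area-weighted average.  The centre sample sees
  internal GM at full strength, so this estimator detects admixture.

The difference between the two is an estimate of the internally
originated contribution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .geometry import FieldGeometry, equivalent_square_side, ring_partition
from .model import SquareFlowModel, calibrate

__all__ = [
    "GMEstimate",
    "SamplingDepthError",
    "estimate_single_ring",
    "predict_center",
    "estimate_two_part",
    "internal_contribution",
    "sample_size",
    "DEFAULT_Z",
    "DEFAULT_KERNELS_PER_COB",
]

#: z-statistic for ~95% reliability used in the sample-size helper.
DEFAULT_Z = 1.95
#: Working assumption for kernels on one cob; configurable in sample_size.
DEFAULT_KERNELS_PER_COB = 189
#: Above this Self-Protection Index the central-portion mean in the
#: two-part estimator tends to be overestimated by about 0.0002*I percent.
CENTRAL_OVERESTIMATE_I = 67.0


class SamplingDepthError(ValueError):
    """Sampling depth deeper than the field half-width (d > a/2 = 2I)."""


@dataclass(frozen=True)
class GMEstimate:
    """A whole-field %GM point estimate with its provenance.

    ``method`` is one of ``single_ring``, ``two_part`` or
    ``standard_grid``; ``inputs_echo`` records the measured values and
    geometry the estimate was computed from.
    """

    value: float
    method: str
    inputs_echo: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.value >= 0:
            raise ValueError(f"%GM estimate must be >= 0, got {self.value}")

    def to_dict(self) -> dict:
        return {"value_pct": self.value, "method": self.method, **self.inputs_echo}


def _calibrated(K_d: float, d: float, I: float) -> SquareFlowModel:
    a = equivalent_square_side(I)
    if d < 0:
        raise ValueError(f"sampling depth must be >= 0, got {d}")
    if d > a / 2.0:
        raise SamplingDepthError(
            f"sampling depth d={d} m exceeds the equivalent-square half-width "
            f"a/2 = {a / 2} m (I = {I} m)"
        )
    return calibrate(a, d, K_d)


def estimate_single_ring(K_d: float, d: float, I: float) -> GMEstimate:
    """Overall %GM from one pooled perimeter mean at depth ``d``.

    Calibrates the flow model on the equivalent square a = 4I so its
    perimeter mean at ``d`` matches ``K_d``, then returns the model's
    whole-field mean 4K ln(a+1)/a.  Any sampling depth up to a/2 is
    supported (surveys at d = 6 or 8 m use the same route).

    Linear in ``K_d``: doubling the measured mean doubles the estimate.
    """
    model = _calibrated(K_d, d, I)
    return GMEstimate(
        value=model.field_mean(),
        method="single_ring",
        inputs_echo={"K_d_pct": K_d, "d_m": d, "I_m": I},
    )


def predict_center(K_d: float, d: float, I: float) -> float:
    """Model-predicted cross-fertilization at the field centre.

    The centre is depth a/2, where the calibrated density evaluates to
    4K/(a/2 + 1) = 4K/(2I + 1).  Comparing this prediction with a
    measured centre sample is how internal GM shows up.
    """
    return _calibrated(K_d, d, I).center_density()


def estimate_two_part(
    K_3: float,
    K_c: float,
    geom: FieldGeometry,
    ring_w: float = 10.0,
) -> GMEstimate:
    """Overall %GM from the 3 m perimeter mean and a centre sample.

    The mean over the 10 m peripheral ring approximately equals the mean
    at 3 m depth, so the ring is valued at ``K_3``, the central portion
    at the measured ``K_c``, and the field %GM is the area-weighted
    average (K_3*A_R + K_c*A_C)/A_T.  For small fields where the ring
    covers everything (A_C = 0) this degenerates to ``K_3``.

    For fields with I > 67 m the central-portion term tends to
    overestimate by about 0.0002*I percent; this is reported as a
    warning, not corrected, because cross-pollination reaching the
    centre of such large fields is rare.
    """
    if K_3 < 0 or K_c < 0:
        raise ValueError("measured %GM values must be >= 0")
    I = geom.index
    if I > CENTRAL_OVERESTIMATE_I:
        warnings.warn(
            f"field I = {I:.1f} m > {CENTRAL_OVERESTIMATE_I:.0f} m: the central "
            f"portion of the two-part estimate tends to be overestimated by "
            f"about {2e-4 * I:.4f}%",
            stacklevel=2,
        )
    part = ring_partition(geom, ring_w, exact=False)
    total = part.total_area_m2
    value = (K_3 * part.ring_area_m2 + K_c * part.central_area_m2) / total
    return GMEstimate(
        value=value,
        method="two_part",
        inputs_echo={
            "K_3_pct": K_3,
            "K_c_pct": K_c,
            "ring_w_m": ring_w,
            "ring_area_m2": part.ring_area_m2,
            "central_area_m2": part.central_area_m2,
            "area_m2": geom.area_m2,
            "perimeter_m": geom.perimeter_m,
        },
    )


def internal_contribution(
    K_3: float,
    K_c: float,
    geom: FieldGeometry,
    d: float = 3.0,
    I: float | None = None,
    ring_w: float = 10.0,
) -> float:
    """Estimated %GM of internal origin (seed admixture, volunteers).

    The single-ring estimate counts only border-driven pollen flow while
    the two-part estimate includes internal GM at full strength in the
    centre term; their difference, floored at zero, attributes the
    internally originated share.  On fields generated by the pure flow
    model the two estimators are highly coherent and the difference is
    approximately zero.
    """
    if I is None:
        I = geom.index
    external = estimate_single_ring(K_3, d, I).value
    total = estimate_two_part(K_3, K_c, geom, ring_w).value
    return max(0.0, total - external)


def sample_size(
    p_gm: float,
    z: float = DEFAULT_Z,
    E: float = 0.1,
    kernels_per_cob: int = DEFAULT_KERNELS_PER_COB,
) -> int:
    """Cobs needed to estimate a GM percentage within +/- E percent.

    Binomial sample size in kernels, n = z^2 p (100 - p) / E^2 with p
    and E on the percent scale, converted to whole cobs.  At the 0.9%
    EU labelling threshold with z = 1.95 and E = 0.1 this gives ~33,917
    kernels, i.e. 180 cobs of 189 kernels.
    """
    if not 0.0 < p_gm < 100.0:
        raise ValueError(f"p_gm must be in (0, 100), got {p_gm}")
    if z <= 0 or E <= 0:
        raise ValueError("z and E must be > 0")
    if kernels_per_cob <= 0:
        raise ValueError("kernels_per_cob must be > 0")
    kernels = z * z * p_gm * (100.0 - p_gm) / (E * E)
    return max(1, math.ceil(kernels / kernels_per_cob))


def required_kernels(p_gm: float, z: float = DEFAULT_Z, E: float = 0.1) -> float:
    """Raw binomial kernel count z^2 p (100-p) / E^2 (percent scale)."""
    if not 0.0 < p_gm < 100.0:
        raise ValueError(f"p_gm must be in (0, 100), got {p_gm}")
    if z <= 0 or E <= 0:
        raise ValueError("z and E must be > 0")
    return z * z * p_gm * (100.0 - p_gm) / (E * E)
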