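"""Coexistence thresholds: maximum %GM, protective index, periphery stripping.

Under the worst realistic external pressure — a synchronized GM donor
surrounding the whole field — the border mean cannot exceed an empirical
ceiling K0_max (10.625% for MON810: half of the 21.3% cross-fertilization
measured by the xenia effect, the event being homozygous).  Feeding that
ceiling into the flow model yields, for any Self-Protection Index I, the
maximum whole-field %GM a field can reach, and by inverting it, the
critical index I_thld above which a field can never exceed a labelling
threshold from external pollen flow alone.

Because maize harvesting usually starts with the field periphery, a
second family of calculations values the interior left after stripping a
peripheral ring, and a printed rule of thumb (I > 43 m, or
K_3 < (1 + I)/22) flags fields whose interior falls below 0.9% once a
3 m ring is commercialized separately.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.optimize import brentq

from .geometry import FieldGeometry, equivalent_square_side
from .model import SquareFlowModel, calibrate

__all__ = [
    "ThresholdConfig",
    "max_gm",
    "protective_index",
    "interior_after_strip",
    "strip_rule",
]

#: Empirical ceiling on the border mean K_0 under full synchronized donor
#: pressure, percent (MON810).  Stored verbatim.
DEFAULT_K0_MAX = 10.625
#: EU labelling threshold for adventitious GM presence, percent.
DEFAULT_GM_THRESHOLD = 0.9

_BISECTION_BRACKET = (1e-3, 1e4)  # metres
_BISECTION_XTOL = 1e-3  # metres; results are reported to 0.1 m


@dataclass(frozen=True)
class ThresholdConfig:
    """Regulatory parameters: border-pressure ceiling and labelling threshold."""

    K0_max: float = DEFAULT_K0_MAX
    gm_threshold: float = DEFAULT_GM_THRESHOLD

    def __post_init__(self) -> None:
        if not self.K0_max > 0:
            raise ValueError(f"K0_max must be > 0, got {self.K0_max}")
        if not self.gm_threshold > 0:
            raise ValueError(f"gm_threshold must be > 0, got {self.gm_threshold}")


def max_gm(I: float, K0_max: float = DEFAULT_K0_MAX) -> float:
    """Maximum whole-field %GM a field of index ``I`` can reach.

    Calibrates the flow model so the border mean (d = 0) equals
    ``K0_max`` and returns the field mean.  Strictly decreasing in I:
    as I -> 0 the whole field is border and the value tends to K0_max.
    """
    model = calibrate(equivalent_square_side(I), 0.0, K0_max)
    return model.field_mean()


def protective_index(
    K0_max: float = DEFAULT_K0_MAX, gm_threshold: float = DEFAULT_GM_THRESHOLD
) -> float:
    """Critical Self-Protection Index I_thld for a labelling threshold.

    The smallest I for which even maximal border pressure keeps the
    whole-field %GM at the threshold: the root of
    ``max_gm(I, K0_max) = gm_threshold``.  max_gm is strictly decreasing
    in I so the root is unique; it is found by a bracketed 1-D solve to
    1e-3 m and conventionally reported to one decimal.

    With the MON810 ceiling 10.625% and the EU 0.9% threshold this gives
    62.2 m (a square field of roughly 6.2 ha).
    """
    if not 0.0 < gm_threshold < K0_max:
        raise ValueError(
            f"threshold must lie in (0, K0_max): got threshold={gm_threshold}, "
            f"K0_max={K0_max}"
        )
    lo, hi = _BISECTION_BRACKET
    return float(
        brentq(lambda I: max_gm(I, K0_max) - gm_threshold, lo, hi, xtol=_BISECTION_XTOL)
    )


def interior_after_strip(
    field: FieldGeometry | float,
    strip_w: float,
    *,
    K_0: float | None = None,
    K_d: float | None = None,
    d: float | None = None,
) -> float:
    """Mean %GM of the interior left after stripping a peripheral ring.

    ``field`` is a FieldGeometry or a bare Self-Protection Index in
    metres.  The model is calibrated from either a border mean ``K_0``
    or a perimeter mean ``K_d`` at depth ``d``, and the mean over depths
    [strip_w, a/2] is returned.  As strip_w -> 0 this tends to the field
    mean; as strip_w -> a/2, to the centre value.
    """
    I = field.index if isinstance(field, FieldGeometry) else float(field)
    a = equivalent_square_side(I)
    if not 0.0 < strip_w < a / 2.0:
        raise ValueError(
            f"strip width must be in (0, a/2) = (0, {a / 2}), got {strip_w}"
        )
    model = _calibrate_from_observation(a, K_0=K_0, K_d=K_d, d=d)
    return model.region_mean(strip_w, a / 2.0)


def _calibrate_from_observation(
    a: float, *, K_0: float | None, K_d: float | None, d: float | None
) -> SquareFlowModel:
    if K_0 is not None:
        if K_d is not None or d is not None:
            raise ValueError("give either K_0 or (K_d, d), not both")
        return calibrate(a, 0.0, K_0)
    if K_d is None or d is None:
        raise ValueError("calibration needs K_0 or the pair (K_d, d)")
    return calibrate(a, d, K_d)


def strip_rule(I: float, K_3: float) -> bool:
    """Periphery-stripping rule of thumb (flagged heuristic).

    True when, after separately commercializing a 3 m-wide peripheral
    ring, the remaining interior will be below 0.9% GM:

        I > 43   or   K_3 < (1 + I) / 22

    The first clause reflects that under the maximal border pressure
    ceiling the interior of any field with I > 43 m computes below 0.9%
    (see :func:`interior_after_strip`); the second is the printed
    observational shortcut for lower measured pressure.  Kept as stated;
    cross-checked, not derived, against the exact interior calculation.
    """
    if I <= 0 or K_3 < 0:
        raise ValueError("I must be > 0 and K_3 >= 0")
    return I > 43.0 or K_3 < (1.0 + I) / 22.0
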