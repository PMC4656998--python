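"""Decision support for adventitious GM content in conventional fields.

The recommended workflow after the simplified 9-sample survey:

1. Estimate the whole-field %GM from the pooled periphery sample
   (single-ring); with a centre determination, also the two-part
   estimate, which governs because it captures GM of internal origin
   (seed admixture, volunteers) that the single-ring route halves.
2. Compare the governing estimate with the labelling threshold
   (0.9% in the EU, overridable for other jurisdictions).
3. If liability matters, qPCR the 8 individual periphery samples: those
   facing a GM donor field read clearly higher, so outliers above the
   ring's typical level point at the donor direction.
4. Attribute the internal vs external origin of the measured GM by
   differencing the two estimators.

Every rule fired is recorded in an audit trail, since the output may
feed regulatory decisions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .estimators import (
    GMEstimate,
    estimate_single_ring,
    estimate_two_part,
    internal_contribution,
    predict_center,
)
from .geometry import FieldGeometry
from .sampling import IncompleteDataError, SampleSet, pool_periphery

__all__ = [
    "DecisionReport",
    "decide",
    "identify_donor_sides",
    "attribute_origin",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.9  # EU labelling threshold, percent
#: A periphery sample is flagged as facing a donor when it exceeds
#: ``alpha`` times the median of the 8 (and an absolute floor).
DEFAULT_DONOR_ALPHA = 2.0
DEFAULT_DONOR_FLOOR = 0.01  # qPCR LOD, percent
#: Internal origin is "suspected" when it exceeds this fraction of the
#: governing estimate.
DEFAULT_INTERNAL_FRACTION = 0.25


@dataclass(frozen=True)
class DecisionReport:
    """Outcome of the decision workflow for one field."""

    estimates: dict  # method -> GMEstimate
    threshold_pct: float
    governing_method: str
    label_required: bool
    donor_sides: list = field(default_factory=list)  # (sample index, value) desc
    internal_pct: float | None = None
    internal_suspected: bool | None = None
    audit: list = field(default_factory=list)

    @property
    def governing_estimate(self) -> GMEstimate:
        return self.estimates[self.governing_method]

    def to_dict(self) -> dict:
        return {
            "estimates": {m: e.to_dict() for m, e in self.estimates.items()},
            "threshold_pct": self.threshold_pct,
            "governing_method": self.governing_method,
            "label_required": self.label_required,
            "donor_sides": [
                {"sample_index": int(i), "value_pct": float(v)}
                for i, v in self.donor_sides
            ],
            "internal_pct": self.internal_pct,
            "internal_suspected": self.internal_suspected,
            "audit": list(self.audit),
        }


def identify_donor_sides(
    individual_values,
    alpha: float = DEFAULT_DONOR_ALPHA,
    floor: float = DEFAULT_DONOR_FLOOR,
) -> list[tuple[int, float]]:
    """Rank the periphery samples that point at a GM donor field.

    A sample is flagged when its value exceeds ``max(floor, alpha *
    median)`` of the 8 individual periphery determinations; flagged
    samples are returned ranked by value, highest first.  The
    alpha-times-median rule is a practical screening device (the
    asymmetry between donor-facing and sheltered borders is strongest at
    shallow depth); alpha and the absolute floor are configurable.
    """
    values = np.asarray(list(individual_values), dtype=float)
    if values.size != 8:
        raise ValueError(f"expected the 8 periphery values, got {values.size}")
    if np.any(values < 0):
        raise ValueError("periphery values must be >= 0")
    cut = max(floor, alpha * float(np.median(values)))
    flagged = [(int(i), float(v)) for i, v in enumerate(values) if v > cut]
    flagged.sort(key=lambda iv: -iv[1])
    return flagged


def attribute_origin(
    K_3: float,
    K_c: float,
    geom: FieldGeometry,
    d: float = 3.0,
    internal_fraction: float = DEFAULT_INTERNAL_FRACTION,
) -> tuple[float, bool]:
    """Internal-origin %GM and whether it dominates enough to flag.

    The internal share is the (floored) difference between the two-part
    and single-ring estimates; it is flagged "internal-origin suspected"
    when it exceeds ``internal_fraction`` of the two-part total.
    """
    internal = internal_contribution(K_3, K_c, geom, d=d)
    total = estimate_two_part(K_3, K_c, geom).value
    suspected = total > 0 and internal > internal_fraction * total
    return internal, suspected


def decide(
    geom: FieldGeometry,
    sample_set: SampleSet | None = None,
    *,
    k_d: float | None = None,
    d: float = 3.0,
    k_c: float | None = None,
    individual_values=None,
    threshold: float = DEFAULT_THRESHOLD,
    donor_alpha: float = DEFAULT_DONOR_ALPHA,
    internal_fraction: float = DEFAULT_INTERNAL_FRACTION,
) -> DecisionReport:
    """Run the decision workflow for one field.

    Inputs can be a measured simplified :class:`SampleSet` (pooled value
    and centre/individual values are extracted from it) or the bare
    measurements ``k_d`` (pooled periphery mean at depth ``d``),
    optional ``k_c`` and optional 8 ``individual_values``.

    The single-ring estimate is always computed; when a centre value is
    available the two-part estimate is added and governs the labelling
    decision.  ``label_required`` is True iff the governing estimate
    reaches ``threshold``, and raising any measured value can never
    clear a label that was required.
    """
    audit: list[str] = []
    if sample_set is not None:
        if sample_set.design != "simplified":
            raise ValueError("decide expects a simplified sample set")
        k_d = pool_periphery(sample_set)
        d = sample_set.depth
        centers = [
            p.value_pct for p in sample_set.by_role("center") if p.value_pct is not None
        ]
        k_c = centers[0] if centers else k_c
        peri_vals = [p.value_pct for p in sample_set.by_role("perimeter")]
        if individual_values is None and all(v is not None for v in peri_vals):
            individual_values = peri_vals
        audit.append(f"pooled periphery mean K_{d:g} = {k_d:.4f}% from sample set")
    if k_d is None:
        raise IncompleteDataError("a pooled periphery measurement is required")

    I = geom.index
    estimates: dict[str, GMEstimate] = {}
    single = estimate_single_ring(k_d, d, I)
    estimates["single_ring"] = single
    audit.append(
        f"single-ring estimate from K_{d:g}={k_d:.4f}%, I={I:.2f} m: "
        f"{single.value:.4f}%"
    )
    internal_pct: float | None = None
    internal_suspected: bool | None = None
    if k_c is not None:
        two = estimate_two_part(k_d, k_c, geom)
        estimates["two_part"] = two
        governing = "two_part"
        audit.append(
            f"two-part estimate from K_3={k_d:.4f}%, K_c={k_c:.4f}%: "
            f"{two.value:.4f}% (governs: captures internal-origin GM)"
        )
        internal_pct, internal_suspected = attribute_origin(
            k_d, k_c, geom, d=d, internal_fraction=internal_fraction
        )
        predicted_c = predict_center(k_d, d, I)
        audit.append(
            f"centre predicted {predicted_c:.4f}% vs measured {k_c:.4f}%; "
            f"internal contribution {internal_pct:.4f}%"
            + (" -> internal origin suspected" if internal_suspected else "")
        )
    else:
        governing = "single_ring"
        audit.append("no centre sample: single-ring estimate governs")

    label_required = estimates[governing].value >= threshold
    audit.append(
        f"governing estimate {estimates[governing].value:.4f}% "
        f"{'>=' if label_required else '<'} threshold {threshold}% -> "
        f"{'label required' if label_required else 'no label required'}"
    )

    donor_sides: list[tuple[int, float]] = []
    if individual_values is not None:
        donor_sides = identify_donor_sides(individual_values, alpha=donor_alpha)
        if donor_sides:
            audit.append(
                "donor direction: periphery samples "
                + ", ".join(f"#{i} ({v:.3f}%)" for i, v in donor_sides)
            )
        else:
            audit.append("no periphery sample stands out: no donor side flagged")

    for line in audit:
        logger.info("%s", line)
    return DecisionReport(
        estimates=estimates,
        threshold_pct=threshold,
        governing_method=governing,
        label_required=label_required,
        donor_sides=donor_sides,
        internal_pct=internal_pct,
        internal_suspected=internal_suspected,
        audit=audit,
    )
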