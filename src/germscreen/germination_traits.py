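"""Germination and seedling traits.

Seven traits summarise each germplasm under each condition:

* ``GR`` — germination rate, fraction of seeds germinated by day 7
  (``G7 / N``).
* ``GE`` — germination energy, fraction germinated by day 1 (``G1 / N``);
  an early-vigor measure.
* ``GI`` — germination index, ``sum_t G_t / t`` over days 1..7 with ``G_t``
  the cumulative count on day ``t``; rewards both complete and fast
  germination.
* ``RL`` — root length (cm) at day 7.
* ``FW`` — seedling fresh weight (g) at day 7.
* ``WC`` — water content, ``(FW - DW) / FW``.
* ``GVI`` — germination vigor index, ``GI * AFW`` with AFW the average
  seedling fresh weight of the same condition.

Rates (GR, GE, WC) are stored as fractions in [0, 1]; percentage display is
left to callers.  Per-replicate germination traits are computed first and
then averaged across biological replicates; endpoint measures are averaged
over the replicates where they could be measured.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .panel_io import (
    CONDITIONS,
    GermscreenError,
    N_DAYS,
    TRAITS,
    EndpointMeasures,
    GerminationTimeCourse,
)

__all__ = [
    "TraitVector",
    "germination_rate",
    "germination_energy",
    "germination_index",
    "germination_vigor_index",
    "water_content",
    "compute_trait_vector",
    "max_germination_index",
]


@dataclass(frozen=True)
class TraitVector:
    """The seven evaluated traits for one germplasm under one condition.
    ``RL``, ``GVI``, ``FW`` and ``WC`` may be missing (``None``) when no
    seedling could be measured."""

    germplasm_id: str
    condition: str
    GR: float
    GI: float
    GE: float
    RL: Optional[float] = None
    GVI: Optional[float] = None
    FW: Optional[float] = None
    WC: Optional[float] = None

    def get(self, trait: str) -> Optional[float]:
        if trait not in TRAITS:
            raise GermscreenError(f"unknown trait {trait!r}")
        return getattr(self, trait)


def germination_rate(course: GerminationTimeCourse) -> float:
    """Final germination fraction G7/N."""
    return course.counts[-1] / course.n_seeds


def germination_energy(course: GerminationTimeCourse) -> float:
    """Day-1 germination fraction G1/N."""
    return course.counts[0] / course.n_seeds


def germination_index(course: GerminationTimeCourse) -> float:
    """Sum over days of (cumulative germinated count on day t) / t."""
    return sum(c / t for t, c in enumerate(course.counts, start=1))


def max_germination_index(n_seeds: int) -> float:
    """Upper bound of GI: all seeds germinated on day 1, N * H_7 with H_7 the
    7th harmonic number."""
    return n_seeds * sum(1 / t for t in range(1, N_DAYS + 1))


def germination_vigor_index(gi: float, afw: Optional[float]) -> Optional[float]:
    """GI scaled by average seedling fresh weight; missing when AFW is."""
    if afw is None:
        return None
    if gi < 0 or afw < 0:
        raise GermscreenError("germination_vigor_index requires gi >= 0 and afw >= 0")
    return gi * afw


def water_content(fw: Optional[float], dw: Optional[float]) -> Optional[float]:
    """(FW - DW)/FW as a fraction; missing if either weight is missing or
    FW is zero (nothing to weigh)."""
    if fw is None or dw is None or fw == 0:
        return None
    if dw > fw:
        raise GermscreenError(f"dry weight {dw} exceeds fresh weight {fw}")
    return (fw - dw) / fw


def _mean_present(values: Sequence[Optional[float]]) -> Optional[float]:
    present = [v for v in values if v is not None]
    return float(np.mean(present)) if present else None


def compute_trait_vector(
    courses: Sequence[GerminationTimeCourse],
    endpoints: Sequence[EndpointMeasures] = (),
) -> TraitVector:
    """Aggregate replicate time courses and endpoint measures into one
    :class:`TraitVector`.

    GR/GE/GI are computed per replicate and averaged.  RL, FW and DW are
    averaged over the replicates where they were measured; WC is the ratio of
    mean weights ((mean FW − mean DW)/mean FW) and GVI is mean GI times the
    same-condition AFW (= mean FW).  A trait whose inputs are entirely
    missing is marked missing.
    """
    if not courses:
        raise GermscreenError("compute_trait_vector needs at least one time course")
    keys = {(c.germplasm_id, c.condition) for c in courses} | {
        (e.germplasm_id, e.condition) for e in endpoints
    }
    if len(keys) != 1:
        raise GermscreenError(
            f"mixed germplasm/condition inputs: {sorted(keys)}"
        )
    gid, condition = next(iter(keys))

    gr = float(np.mean([germination_rate(c) for c in courses]))
    ge = float(np.mean([germination_energy(c) for c in courses]))
    gi = float(np.mean([germination_index(c) for c in courses]))

    rl = _mean_present([e.root_length for e in endpoints])
    afw = _mean_present([e.fresh_weight for e in endpoints])
    mean_dw = _mean_present([e.dry_weight for e in endpoints])
    wc = water_content(afw, mean_dw)
    gvi = germination_vigor_index(gi, afw)

    return TraitVector(
        germplasm_id=gid,
        condition=condition,
        GR=gr,
        GI=gi,
        GE=ge,
        RL=rl,
        GVI=gvi,
        FW=afw,
        WC=wc,
    )
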