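"""Fuzzy membership-function evaluation and five-grade classification.

Each trait's STI is min–max normalised across the screened panel to a
membership-function value (MFV) in [0, 1]:

    MFV = (STI - STI_min) / (STI_max - STI_min)

with the extremes taken over all germplasms in the panel.  The unweighted
mean of the seven trait MFVs is the composite tolerance score a panel is
graded on.  Grades cut the panel at its mean mean-MFV plus/minus 1 and 1.64
standard deviations (1.64 is the two-sided normal 90% quantile, putting
about 5% of an approximately normal panel in each extreme grade):

    HST  mean MFV >= m + 1.64 s      highly salt-tolerant
    ST   m + 1.64 s > mean MFV >= m + s
    MST  m + s > mean MFV >= m - s   the bulk of the panel
    SS   m - s > mean MFV >= m - 1.64 s
    HSS  mean MFV < m - 1.64 s       highly salt-sensitive

Interval lower bounds are inclusive.  MFVs and mean MFVs are stored as
fractions in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .panel_io import GRADES, TRAITS, GermscreenError, PanelConfig
from .stress_tolerance_index import StiProfile

__all__ = [
    "PanelExtremes",
    "MembershipProfile",
    "GradeScheme",
    "panel_extremes",
    "mfv",
    "membership_profile",
    "mean_mfv",
    "grade_scheme_from_panel",
    "published_grade_scheme",
    "classify",
    "PUBLISHED_GRADE_CUTS",
]

#: Grade cut points of the published 552-line sunflower screening
#: (panel mean mean-MFV 0.287, SD 0.143): mean ± 1.64 SD and ± 1 SD,
#: computed there from unrounded moments.
PUBLISHED_GRADE_CUTS: tuple[float, float, float, float] = (
    0.5216,
    0.4302,
    0.1446,
    0.0532,
)


@dataclass(frozen=True)
class PanelExtremes:
    """Per-trait min and max STI observed across the panel."""

    extremes: dict[str, tuple[float, float]]

    def __post_init__(self):
        for trait, (lo, hi) in self.extremes.items():
            if trait not in TRAITS:
                raise GermscreenError(f"unknown trait {trait!r}")
            if hi < lo:
                raise GermscreenError(f"max < min for trait {trait}: {hi} < {lo}")

    def range_of(self, trait: str) -> tuple[float, float]:
        return self.extremes[trait]


@dataclass(frozen=True)
class MembershipProfile:
    """Per-trait MFVs (fractions in [0,1]) and their unweighted mean."""

    germplasm_id: str
    mfv: dict[str, float]
    mean_mfv: float


@dataclass(frozen=True)
class GradeScheme:
    """Five-grade classification scheme: panel mean and SD of mean MFV plus
    the four decreasing cut points (m+1.64s, m+s, m-s, m-1.64s)."""

    mean: float
    sd: float
    cuts: tuple[float, float, float, float]

    def __post_init__(self):
        c = self.cuts
        if self.sd > 0 and not (c[0] > c[1] > c[2] > c[3]):
            raise GermscreenError(f"cuts must be strictly decreasing, got {c}")


def panel_extremes(profiles: Sequence[StiProfile]) -> PanelExtremes:
    """Per-trait min and max STI over the panel, ignoring missing entries
    (zero-filled entries are present and participate)."""
    if len(profiles) < 2:
        raise GermscreenError("panel_extremes needs at least two germplasms")
    extremes: dict[str, tuple[float, float]] = {}
    for trait in TRAITS:
        values = [p.sti[trait] for p in profiles if p.sti.get(trait) is not None]
        if not values:
            raise GermscreenError(f"trait {trait} has no present STI in the panel")
        extremes[trait] = (min(values), max(values))
    return PanelExtremes(extremes)


def mfv(x: float, extremes: tuple[float, float]) -> float:
    """Min–max normalise one STI value to [0, 1] given the panel extremes."""
    lo, hi = extremes
    if hi == lo:
        raise GermscreenError(
            f"degenerate trait: panel min == max == {lo}, normalisation undefined"
        )
    if not (lo <= x <= hi):
        raise GermscreenError(f"value {x} outside panel extremes [{lo}, {hi}]")
    return (x - lo) / (hi - lo)


def mean_mfv(trait_mfvs: dict[str, float]) -> float:
    """Unweighted arithmetic mean of the seven trait MFVs."""
    missing = [t for t in TRAITS if trait_mfvs.get(t) is None]
    if missing:
        raise GermscreenError(f"missing trait MFVs: {missing}")
    return float(np.mean([trait_mfvs[t] for t in TRAITS]))


def membership_profile(
    profile: StiProfile, extremes: PanelExtremes
) -> MembershipProfile:
    """Normalise a complete STI profile against the panel extremes."""
    if not profile.is_complete():
        missing = [t for t in TRAITS if profile.sti.get(t) is None]
        raise GermscreenError(
            f"incomplete STI profile for {profile.germplasm_id}: missing {missing}"
        )
    values = {t: mfv(profile.sti[t], extremes.range_of(t)) for t in TRAITS}
    return MembershipProfile(
        germplasm_id=profile.germplasm_id, mfv=values, mean_mfv=mean_mfv(values)
    )


def grade_scheme_from_panel(
    mean_mfvs: Iterable[float], config: PanelConfig | None = None
) -> GradeScheme:
    """Derive the grading scheme from a panel's mean MFVs (sample SD by
    default; ``config.sd_ddof`` switches to population SD)."""
    config = config or PanelConfig()
    values = np.asarray(list(mean_mfvs), dtype=float)
    if values.size < 2:
        raise GermscreenError("grade scheme needs at least two mean MFVs")
    m = float(values.mean())
    s = float(values.std(ddof=config.sd_ddof))
    if s == 0 or np.all(values == values[0]):
        raise GermscreenError("zero panel SD: no discrimination possible")
    cuts = (m + 1.64 * s, m + s, m - s, m - 1.64 * s)
    return GradeScheme(mean=m, sd=s, cuts=cuts)


def published_grade_scheme() -> GradeScheme:
    """The grading scheme of the published 552-line sunflower panel
    (mean 0.287, SD 0.143, cuts 0.5216/0.4302/0.1446/0.0532), for grading
    new germplasms without re-normalising a full panel."""
    return GradeScheme(mean=0.287, sd=0.143, cuts=PUBLISHED_GRADE_CUTS)


def classify(value: float, scheme: GradeScheme) -> str:
    """Assign a mean MFV (or Y score) to one of the five grades; each grade's
    lower bound is inclusive."""
    if not np.isfinite(value):
        raise GermscreenError(f"cannot classify non-finite value {value}")
    c1, c2, c3, c4 = scheme.cuts
    if value >= c1:
        return "HST"
    if value >= c2:
        return "ST"
    if value >= c3:
        return "MST"
    if value >= c4:
        return "SS"
    return "HSS"
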