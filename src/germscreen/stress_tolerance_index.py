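"""Salt-tolerance indices (STI).

For each trait the STI is the treatment/control ratio ``V_salt / V_control``:
1 means the trait is unaffected by salt, 0 means fully suppressed, and values
above 1 (occasionally seen for fresh weight and water content) mean the trait
was slightly increased under salt.

A line that fails to germinate under salt has no measurable traits at all;
under the default ``zero_fill`` policy every trait of such a line is assigned
STI 0, so it enters the membership stage as an ordinary (maximally sensitive)
row rather than being dropped.  Each value carries a provenance flag so
zero-filled entries remain auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .panel_io import TRAITS, GermscreenError, PanelConfig
from .germination_traits import TraitVector

__all__ = [
    "MEASURED",
    "ZERO_FILLED",
    "MISSING_CONTROL",
    "MISSING_TREATMENT",
    "StiProfile",
    "sti",
    "sti_profile",
]

# Provenance flags
MEASURED = "measured"
ZERO_FILLED = "zero_filled_no_germination"
MISSING_CONTROL = "missing_control"
MISSING_TREATMENT = "missing_treatment"


@dataclass(frozen=True)
class StiProfile:
    """Per-trait salt-tolerance indices for one germplasm, with provenance
    flags (measured / zero-filled / missing-control / missing-treatment)."""

    germplasm_id: str
    sti: dict[str, Optional[float]]
    flags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.sti) - set(TRAITS)
        if unknown:
            raise GermscreenError(f"unknown traits in profile: {sorted(unknown)}")
        for t, v in self.sti.items():
            if v is not None and v < 0:
                raise GermscreenError(f"negative STI {v} for trait {t}")

    def is_complete(self) -> bool:
        return all(self.sti.get(t) is not None for t in TRAITS)


def sti(
    treatment_value: Optional[float], control_value: Optional[float]
) -> tuple[Optional[float], str]:
    """Treatment/control ratio with a provenance flag.

    Returns ``(ratio, "measured")`` when both values are present and the
    control is positive; otherwise ``(None, flag)`` naming the side that
    prevents the ratio (a zero control counts as a missing denominator, not
    an exception).
    """
    if control_value is None or control_value == 0:
        return None, MISSING_CONTROL
    if treatment_value is None:
        return None, MISSING_TREATMENT
    if treatment_value < 0 or control_value < 0:
        raise GermscreenError("STI inputs must be nonnegative")
    return treatment_value / control_value, MEASURED


def sti_profile(
    salt: TraitVector, control: TraitVector, config: PanelConfig | None = None
) -> StiProfile:
    """Build the per-trait STI profile for one germplasm.

    Under ``zero_fill`` (default): if the line did not germinate under salt
    (salt GR = 0) all seven STIs are set to 0; otherwise traits unmeasurable
    under salt (missing treatment value) are set to 0.  Both carry the
    ``zero_filled_no_germination`` flag.  Under ``exclude_trait`` the
    unmeasurable traits stay missing with their diagnostic flag.
    """
    config = config or PanelConfig()
    if salt.germplasm_id != control.germplasm_id:
        raise GermscreenError(
            f"germplasm mismatch: salt={salt.germplasm_id!r} "
            f"control={control.germplasm_id!r}"
        )
    if salt.condition != "salt" or control.condition != "control":
        raise GermscreenError(
            "sti_profile expects (salt TraitVector, control TraitVector), got "
            f"({salt.condition!r}, {control.condition!r})"
        )

    zero_fill = config.missing_sti_policy == "zero_fill"
    no_germination = salt.GR == 0

    values: dict[str, Optional[float]] = {}
    flags: dict[str, str] = {}
    for trait in TRAITS:
        if zero_fill and no_germination:
            values[trait], flags[trait] = 0.0, ZERO_FILLED
            continue
        value, flag = sti(salt.get(trait), control.get(trait))
        if value is None and zero_fill and flag == MISSING_TREATMENT:
            # germinated but the seedling trait could not be measured
            # (e.g. no cotyledon growth): treated as complete suppression
            value, flag = 0.0, ZERO_FILLED
        values[trait] = value
        flags[trait] = flag
    return StiProfile(germplasm_id=salt.germplasm_id, sti=values, flags=flags)
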