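"""End-to-end panel evaluation: raw records -> traits -> STI -> MFV ->
grades -> tolerance model.

This is the glue the command-line interface and the parameter-recovery
harness run; each stage is a thin call into the corresponding module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .panel_io import (
    EVALUATION_COLUMNS,
    TRAITS,
    EndpointMeasures,
    GerminationTimeCourse,
    GermscreenError,
    PanelConfig,
    logger,
)
from .germination_traits import TraitVector, compute_trait_vector
from .stress_tolerance_index import StiProfile, sti_profile
from .membership_grading import (
    GradeScheme,
    PanelExtremes,
    classify,
    grade_scheme_from_panel,
    membership_profile,
    panel_extremes,
)
from .regression_model import (
    ToleranceModel,
    fit_tolerance_model,
    predict_y,
    validate_model,
)

__all__ = ["EvaluationResult", "compute_panel_traits", "evaluate_panel"]


@dataclass
class EvaluationResult:
    """Everything the evaluation pipeline produces for one panel."""

    table: pd.DataFrame
    extremes: PanelExtremes
    scheme: GradeScheme
    profiles: list[StiProfile]
    model: Optional[ToleranceModel] = None
    validation: Optional[dict[str, float]] = None


def compute_panel_traits(
    courses: Sequence[GerminationTimeCourse],
    endpoints: Sequence[EndpointMeasures] = (),
) -> dict[tuple[str, str], TraitVector]:
    """One TraitVector per (germplasm, condition), replicates aggregated."""
    course_groups: dict[tuple[str, str], list[GerminationTimeCourse]] = {}
    for c in courses:
        course_groups.setdefault((c.germplasm_id, c.condition), []).append(c)
    endpoint_groups: dict[tuple[str, str], list[EndpointMeasures]] = {}
    for e in endpoints:
        endpoint_groups.setdefault((e.germplasm_id, e.condition), []).append(e)
    return {
        key: compute_trait_vector(group, endpoint_groups.get(key, []))
        for key, group in sorted(course_groups.items())
    }


def traits_table(traits: dict[tuple[str, str], TraitVector]) -> pd.DataFrame:
    """Flatten per-(germplasm, condition) trait vectors to a DataFrame."""
    rows = []
    for (gid, cond), tv in sorted(traits.items()):
        row: dict = {"germplasm": gid, "condition": cond}
        row.update({t: tv.get(t) for t in TRAITS})
        rows.append(row)
    return pd.DataFrame(rows, columns=["germplasm", "condition", *TRAITS])


def evaluate_panel(
    courses: Sequence[GerminationTimeCourse],
    endpoints: Sequence[EndpointMeasures] = (),
    config: PanelConfig | None = None,
    scheme: GradeScheme | str = "panel",
    model: ToleranceModel | str | None = "fit",
) -> EvaluationResult:
    """Run the full evaluation on one panel.

    ``scheme='panel'`` derives the grade cuts from this panel; passing a
    :class:`GradeScheme` (e.g. the published one) grades against fixed cuts.
    ``model='fit'`` fits the tolerance model on this panel's complete rows;
    a :class:`ToleranceModel` scores with fixed coefficients; ``None`` skips
    the Y column.

    Germplasms with incomplete STI profiles (possible only under the
    ``exclude_trait`` policy) are carried through with missing MFV/grade/Y.
    """
    config = config or PanelConfig()
    traits = compute_panel_traits(courses, endpoints)

    germplasms = sorted({gid for gid, _ in traits})
    profiles: list[StiProfile] = []
    for gid in germplasms:
        salt = traits.get((gid, "salt"))
        control = traits.get((gid, "control"))
        if salt is None or control is None:
            raise GermscreenError(
                f"germplasm {gid} lacks a {'salt' if salt is None else 'control'} "
                "condition"
            )
        profiles.append(sti_profile(salt, control, config))

    extremes = panel_extremes(profiles)
    complete = [p for p in profiles if p.is_complete()]
    n_incomplete = len(profiles) - len(complete)
    if n_incomplete:
        logger.info(
            "%d of %d germplasms have incomplete STI profiles and get no "
            "composite score",
            n_incomplete,
            len(profiles),
        )
    memberships = {
        p.germplasm_id: membership_profile(p, extremes) for p in complete
    }

    if scheme == "panel":
        scheme_obj = grade_scheme_from_panel(
            [m.mean_mfv for m in memberships.values()], config
        )
    elif isinstance(scheme, GradeScheme):
        scheme_obj = scheme
    else:
        raise GermscreenError(f"scheme must be 'panel' or a GradeScheme, got {scheme!r}")

    X = pd.DataFrame(
        [[p.sti[t] for t in TRAITS] for p in complete],
        columns=list(TRAITS),
        index=[p.germplasm_id for p in complete],
    )
    y = np.array([memberships[g].mean_mfv for g in X.index])

    model_obj: Optional[ToleranceModel]
    validation = None
    if model == "fit":
        model_obj = fit_tolerance_model(X, y)
    elif isinstance(model, ToleranceModel) or model is None:
        model_obj = model
    else:
        raise GermscreenError(f"model must be 'fit', None or a ToleranceModel")
    if model_obj is not None and len(X):
        validation = validate_model(model_obj, X, y)

    rows = []
    for p in profiles:
        row: dict = {"germplasm": p.germplasm_id}
        for t in TRAITS:
            row[f"STI_{t}"] = p.sti.get(t)
        m = memberships.get(p.germplasm_id)
        if m is not None:
            for t in TRAITS:
                row[f"MFV_{t}"] = m.mfv[t]
            row["mean_MFV"] = m.mean_mfv
            row["grade"] = classify(m.mean_mfv, scheme_obj)
            if model_obj is not None:
                row["Y"] = predict_y(model_obj, p)
        rows.append(row)
    table = (
        pd.DataFrame(rows)
        .reindex(columns=EVALUATION_COLUMNS)
        .sort_values("germplasm")
        .reset_index(drop=True)
    )
    return EvaluationResult(
        table=table,
        extremes=extremes,
        scheme=scheme_obj,
        profiles=profiles,
        model=model_obj,
        validation=validation,
    )
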