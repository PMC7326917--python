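"""Linear tolerance-score model and correlation diagnostics.

The composite mean MFV requires a whole panel (it is normalised against
panel extremes).  To score a *new* germplasm without re-screening a panel,
the mean MFV is regressed on the seven raw STIs by ordinary least squares:

    Y = b_GR*STI_GR + b_GI*STI_GI + b_GE*STI_GE + b_RL*STI_RL
        + b_GVI*STI_GVI + b_FW*STI_FW + b_WC*STI_WC + u

On a panel with complete STI rows the regression is exact by construction:
mean MFV is an affine function of the STIs,

    mean MFV = sum_i (STI_i - min_i) / (7 * (max_i - min_i)),

so OLS recovers b_i = 1/(7*range_i) and intercept -sum_i min_i/(7*range_i)
with R^2 = 1 and residuals at floating-point noise (when every trait's panel
minimum is 0 the intercept vanishes).  The fitted coefficients then score
any future line from its seven STIs alone.

Diagnostics mirror standard screening practice: the 8x8 Pearson correlation
matrix over the seven STIs and mean MFV, per-trait simple-regression R^2
against mean MFV (identifying which single traits best track tolerance), and
standardised coefficients b_i * sd(STI_i)/sd(Y).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .panel_io import TRAITS, GermscreenError
from .membership_grading import (
    GradeScheme,
    PUBLISHED_GRADE_CUTS,
    published_grade_scheme,
)
from .stress_tolerance_index import StiProfile

__all__ = [
    "ToleranceModel",
    "fit_tolerance_model",
    "predict_y",
    "validate_model",
    "correlation_matrix",
    "per_trait_r2",
    "standardized_coefficients",
    "published_model",
    "PUBLISHED_COEFFICIENTS",
    "save_model_json",
    "load_model_json",
]

#: Coefficients of the published sunflower germination-stage tolerance model
#: (trait order GR, GI, GE, RL, GVI, FW, WC) and its intercept.
PUBLISHED_COEFFICIENTS: dict[str, float] = {
    "GR": 0.143,
    "GI": 0.146,
    "GE": 0.152,
    "RL": 0.213,
    "GVI": 0.369,
    "FW": 0.119,
    "WC": 0.088,
}
PUBLISHED_INTERCEPT: float = -3.33e-16


@dataclass(frozen=True)
class ToleranceModel:
    """Seven regression coefficients plus intercept defining the Y score."""

    coefficients: dict[str, float]
    intercept: float
    fitted_on: Optional[int] = None
    r_squared: Optional[float] = None

    def __post_init__(self):
        if tuple(self.coefficients) != TRAITS:
            raise GermscreenError(
                f"coefficients must cover exactly {TRAITS} in order, "
                f"got {tuple(self.coefficients)}"
            )

    def coef_array(self) -> np.ndarray:
        return np.array([self.coefficients[t] for t in TRAITS], dtype=float)


def _as_matrix(sti_matrix) -> np.ndarray:
    """Coerce a germplasm x 7-trait container to a dense float matrix."""
    if isinstance(sti_matrix, pd.DataFrame):
        missing = [t for t in TRAITS if t not in sti_matrix.columns]
        if missing:
            raise GermscreenError(f"sti_matrix missing trait columns {missing}")
        X = sti_matrix[list(TRAITS)].to_numpy(dtype=float)
    else:
        X = np.asarray(sti_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(TRAITS):
        raise GermscreenError(
            f"sti_matrix must be n x {len(TRAITS)}, got shape {X.shape}"
        )
    if np.isnan(X).any():
        raise GermscreenError(
            "sti_matrix contains missing entries; apply the zero_fill policy "
            "or drop incomplete rows before fitting"
        )
    return X


def fit_tolerance_model(sti_matrix, mean_mfvs) -> ToleranceModel:
    """Ordinary least squares of mean MFV on the seven STIs, with intercept.

    Solved via numpy's SVD-based least squares (numerically stable); a
    constant trait column or an otherwise rank-deficient design is rejected.
    """
    X = _as_matrix(sti_matrix)
    y = np.asarray(mean_mfvs, dtype=float)
    n = X.shape[0]
    if y.shape != (n,):
        raise GermscreenError(f"mean_mfvs length {y.shape} != panel size {n}")
    if n < len(TRAITS) + 2:
        raise GermscreenError(
            f"need at least {len(TRAITS) + 2} germplasms to fit, got {n}"
        )
    ptp = X.max(axis=0) - X.min(axis=0)
    constant = [t for t, r in zip(TRAITS, ptp) if r == 0]
    if constant:
        raise GermscreenError(f"constant trait column(s): {constant}")
    design = np.column_stack([np.ones(n), X])
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise GermscreenError("rank-deficient design: collinear trait columns")
    fitted = design @ beta
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return ToleranceModel(
        coefficients={t: float(b) for t, b in zip(TRAITS, beta[1:])},
        intercept=float(beta[0]),
        fitted_on=n,
        r_squared=r2,
    )


def predict_y(model: ToleranceModel, profile) -> float:
    """Tolerance score Y = intercept + sum_i b_i * STI_i.

    ``profile`` may be a :class:`StiProfile`, a trait->value mapping or a
    length-7 array in trait order; all seven STIs must be present
    (zero-filled values count as present).
    """
    if isinstance(profile, StiProfile):
        values = profile.sti
    elif isinstance(profile, dict):
        values = profile
    else:
        arr = np.asarray(profile, dtype=float)
        if arr.shape != (len(TRAITS),):
            raise GermscreenError(
                f"expected {len(TRAITS)} STI values, got shape {arr.shape}"
            )
        values = dict(zip(TRAITS, arr))
    missing = [t for t in TRAITS if values.get(t) is None]
    if missing or any(np.isnan(values[t]) for t in TRAITS):
        raise GermscreenError(f"missing STI for traits {missing or 'NaN entries'}")
    return float(
        model.intercept + sum(model.coefficients[t] * values[t] for t in TRAITS)
    )


def validate_model(model: ToleranceModel, sti_matrix, mean_mfvs) -> dict[str, float]:
    """Mean, max and min of |Y - mean MFV| over a panel."""
    X = _as_matrix(sti_matrix)
    y = np.asarray(mean_mfvs, dtype=float)
    if X.shape[0] == 0:
        raise GermscreenError("validate_model needs a non-empty panel")
    pred = model.intercept + X @ model.coef_array()
    diff = np.abs(pred - y)
    return {
        "mean_abs_diff": float(diff.mean()),
        "max_abs_diff": float(diff.max()),
        "min_abs_diff": float(diff.min()),
    }


def _check_variance(X: np.ndarray, names: Sequence[str]) -> None:
    sd = X.std(axis=0)
    zero = [n for n, s in zip(names, sd) if s == 0]
    if zero:
        raise GermscreenError(f"zero-variance column(s): {zero}")


def correlation_matrix(sti_matrix, mean_mfvs) -> pd.DataFrame:
    """8x8 Pearson correlation matrix over the seven STIs and mean MFV."""
    X = _as_matrix(sti_matrix)
    y = np.asarray(mean_mfvs, dtype=float)
    if X.shape[0] < 3:
        raise GermscreenError("correlation_matrix needs at least 3 germplasms")
    cols = list(TRAITS) + ["mean_MFV"]
    data = np.column_stack([X, y])
    _check_variance(data, cols)
    return pd.DataFrame(np.corrcoef(data, rowvar=False), index=cols, columns=cols)


def per_trait_r2(sti_matrix, mean_mfvs) -> dict[str, float]:
    """R^2 of the simple least-squares line of mean MFV on each STI
    (equals the squared Pearson correlation with mean MFV)."""
    corr = correlation_matrix(sti_matrix, mean_mfvs)
    return {t: float(corr.loc[t, "mean_MFV"] ** 2) for t in TRAITS}


def standardized_coefficients(
    model: ToleranceModel, sti_matrix, mean_mfvs
) -> dict[str, float]:
    """Standardised betas b_i * sd(STI_i) / sd(mean MFV) on the training
    panel (invariant to rescaling any trait)."""
    X = _as_matrix(sti_matrix)
    y = np.asarray(mean_mfvs, dtype=float)
    _check_variance(np.column_stack([X, y]), list(TRAITS) + ["mean_MFV"])
    sd_x = X.std(axis=0, ddof=1)
    sd_y = y.std(ddof=1)
    return {
        t: float(model.coefficients[t] * s / sd_y) for t, s in zip(TRAITS, sd_x)
    }


def published_model() -> ToleranceModel:
    """The published seven-trait sunflower tolerance model (coefficients
    0.143/0.146/0.152/0.213/0.369/0.119/0.088, intercept ~0, fitted on the
    552-line panel with R^2 = 1 by the affine-MFV construction)."""
    return ToleranceModel(
        coefficients=dict(PUBLISHED_COEFFICIENTS),
        intercept=PUBLISHED_INTERCEPT,
        fitted_on=552,
        r_squared=1.0,
    )


# ---------------------------------------------------------------------------
# model.json

def save_model_json(
    path, model: ToleranceModel, scheme: GradeScheme | None = None
) -> None:
    """Persist a model (and optionally its grading scheme) as JSON with
    trait-ordered coefficients at full precision."""
    payload: dict = {
        "traits": list(TRAITS),
        "coefficients": [model.coefficients[t] for t in TRAITS],
        "intercept": model.intercept,
        "fitted_on": model.fitted_on,
        "r_squared": model.r_squared,
    }
    if scheme is not None:
        payload["grade_scheme"] = {
            "mean": scheme.mean,
            "sd": scheme.sd,
            "cuts": list(scheme.cuts),
        }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def load_model_json(path) -> tuple[ToleranceModel, Optional[GradeScheme]]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("traits") != list(TRAITS):
        raise GermscreenError(
            f"model file traits {payload.get('traits')} != expected {list(TRAITS)}"
        )
    model = ToleranceModel(
        coefficients=dict(zip(TRAITS, payload["coefficients"])),
        intercept=payload["intercept"],
        fitted_on=payload.get("fitted_on"),
        r_squared=payload.get("r_squared"),
    )
    scheme = None
    if "grade_scheme" in payload:
        gs = payload["grade_scheme"]
        scheme = GradeScheme(mean=gs["mean"], sd=gs["sd"], cuts=tuple(gs["cuts"]))
    return model, scheme
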