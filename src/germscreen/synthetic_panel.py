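"""Synthetic germplasm-panel generator.

Real screening panels of this kind share a few structural features the
evaluation method depends on: near-complete germination under control
conditions (only pre-screened high-vigor seed lots enter the panel),
salt-dependent suppression *and* delay of germination, day-1 germination
almost absent under salt (so the panel-mean STI for germination energy is
very small, around 0.06), a handful of lines that fail to germinate under
salt altogether, and seedling biomass that rises with the line's underlying
tolerance — occasionally exceeding the control (STI slightly above 1).

The generator reproduces those features from a single latent tolerance
``theta`` in [0, 1] per germplasm:

* seed-level salt germination is Bernoulli with probability
  ``sigmoid(logit_intercept + logit_slope * theta)``;
* the germination day under salt is the control day plus a Poisson delay
  with mean ``delay_rate * (1 - theta)``, censored at day 7; day-1
  germinations are additionally thinned by ``day1_salt_prob_scale``;
* replicate biomass is the control mean times a monotone response
  ``floor + gain * theta**exponent`` with multiplicative lognormal noise;
  dry matter fraction increases as tolerance falls, lowering water content.

A single ``theta`` driving every trait (plus trait-specific noise) yields
the strong positive inter-trait STI correlations real panels show.  The
generator makes no attempt to mimic sunflower genetics or any particular
panel's trait distributions beyond these qualitative features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import spearmanr

from .panel_io import (
    EndpointMeasures,
    GerminationTimeCourse,
    GermscreenError,
    N_DAYS,
    PanelConfig,
    write_endpoint_csv,
    write_germination_csv,
)
from .pipeline import EvaluationResult, evaluate_panel

__all__ = ["SimulationConfig", "SyntheticPanel", "generate_panel",
           "recover_tolerance", "write_panel"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic panel; defaults emulate a pre-screened
    sunflower germplasm panel germinated in water vs 300 mM NaCl with 11
    seeds per dish and 4 biological replicates."""

    n_germplasms: int = 100
    n_replicates: int = 4
    n_seeds: int = 11
    #: Beta(a, b) shape of the latent tolerance theta; right-skewed with
    #: appreciable mass near 0 (most lines moderately sensitive, a few
    #: highly tolerant or completely failing).
    tolerance_beta: tuple[float, float] = (0.9, 2.1)
    #: Pre-screened seed lots: near-complete control germination.
    control_germination_prob: float = 0.995
    #: Control germination-day distribution over days 1..3.
    control_day_probs: tuple[float, ...] = (0.6, 0.3, 0.1)
    #: Per-seed salt germination probability = sigmoid(a + b * theta).
    salt_germination_logit: tuple[float, float] = (-4.0, 7.0)
    #: Mean Poisson germination delay under salt is delay_rate * (1 - theta).
    delay_rate: float = 3.5
    #: Thinning factor for day-1 germination under salt (seeds pushed to
    #: day 2); calibrated so the default panel-mean STI_GE sits near 0.06.
    day1_salt_prob_scale: float = 0.9
    #: Control biomass means: root length (cm), fresh weight (g), and dry
    #: matter fraction DW/FW.
    rl_control_mean: float = 5.0
    fw_control_mean: float = 0.40
    dry_fraction: float = 0.10
    #: Salt biomass response floor + gain * theta**exponent (fraction of the
    #: control mean); the FW response tops out slightly above 1 so tolerant
    #: lines can show STI_FW > 1.
    rl_response: tuple[float, float, float] = (0.03, 0.97, 1.5)
    fw_response: tuple[float, float, float] = (0.05, 1.00, 1.2)
    #: Extra dry-matter fraction for fully sensitive lines (lowers WC).
    dry_fraction_salt_gain: float = 0.12
    #: Coefficient of variation of multiplicative lognormal biomass noise.
    noise_cv: float = 0.20
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_germplasms < 1 or self.n_replicates < 1 or self.n_seeds < 1:
            raise GermscreenError("panel dimensions must all be >= 1")
        a, b = self.tolerance_beta
        if a <= 0 or b <= 0:
            raise GermscreenError("tolerance_beta shapes must be positive")
        if not 0 <= self.control_germination_prob <= 1:
            raise GermscreenError("control_germination_prob must be in [0, 1]")
        if not 0 <= self.day1_salt_prob_scale <= 1:
            raise GermscreenError("day1_salt_prob_scale must be in [0, 1]")
        probs = np.asarray(self.control_day_probs, dtype=float)
        if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            raise GermscreenError("control_day_probs must be a distribution")
        if len(probs) > N_DAYS:
            raise GermscreenError(f"control_day_probs longer than {N_DAYS} days")
        if self.noise_cv < 0 or self.delay_rate < 0:
            raise GermscreenError("noise_cv and delay_rate must be >= 0")
        if not 0 < self.dry_fraction < 1:
            raise GermscreenError("dry_fraction must be in (0, 1)")


@dataclass
class SyntheticPanel:
    """Generated records plus the ground truth behind them."""

    truth: pd.DataFrame  # columns: germplasm, theta
    courses: list[GerminationTimeCourse]
    endpoints: list[EndpointMeasures]
    config: SimulationConfig


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size if size is not None else ())
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=size)


def _replicate_course(
    rng: np.random.Generator, cfg: SimulationConfig, theta: float, condition: str
) -> tuple[np.ndarray, int]:
    """Germination days for one dish; returns (cumulative counts, n germinated)."""
    n = cfg.n_seeds
    base_days = 1 + rng.choice(
        len(cfg.control_day_probs), size=n, p=np.asarray(cfg.control_day_probs)
    )
    if condition == "control":
        viable = rng.random(n) < cfg.control_germination_prob
        days = base_days
    else:
        a, b = cfg.salt_germination_logit
        viable = rng.random(n) < expit(a + b * theta)
        days = base_days + rng.poisson(cfg.delay_rate * (1 - theta), size=n)
        day1 = days == 1
        pushed = day1 & (rng.random(n) >= cfg.day1_salt_prob_scale)
        days = np.where(pushed, 2, days)
    germinated = viable & (days <= N_DAYS)
    counts = np.array(
        [int(np.sum(germinated & (days <= t))) for t in range(1, N_DAYS + 1)]
    )
    return counts, int(counts[-1])


def _response(theta: float, params: tuple[float, float, float]) -> float:
    floor, gain, exponent = params
    return floor + gain * theta**exponent


def generate_panel(config: SimulationConfig | None = None) -> SyntheticPanel:
    """Draw a complete synthetic panel, reproducible from ``config.rng_seed``."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    width = max(4, len(str(cfg.n_germplasms)))
    thetas = rng.beta(*cfg.tolerance_beta, size=cfg.n_germplasms)

    courses: list[GerminationTimeCourse] = []
    endpoints: list[EndpointMeasures] = []
    truth_rows = []
    for i, theta in enumerate(thetas, start=1):
        gid = f"G{i:0{width}d}"
        truth_rows.append({"germplasm": gid, "theta": float(theta)})
        for condition in ("control", "salt"):
            for rep in range(1, cfg.n_replicates + 1):
                counts, n_germ = _replicate_course(rng, cfg, theta, condition)
                courses.append(
                    GerminationTimeCourse(
                        germplasm_id=gid,
                        condition=condition,
                        replicate=rep,
                        n_seeds=cfg.n_seeds,
                        counts=tuple(counts),
                    )
                )
                if n_germ == 0:
                    # nothing grew in this dish: no seedling to measure
                    endpoints.append(
                        EndpointMeasures(gid, condition, rep, None, None, None)
                    )
                    continue
                if condition == "control":
                    rl_mean = cfg.rl_control_mean
                    fw_mean = cfg.fw_control_mean
                    dry_frac = cfg.dry_fraction
                else:
                    rl_mean = cfg.rl_control_mean * _response(theta, cfg.rl_response)
                    fw_mean = cfg.fw_control_mean * _response(theta, cfg.fw_response)
                    dry_frac = cfg.dry_fraction + cfg.dry_fraction_salt_gain * (
                        1 - theta
                    )
                rl = rl_mean * _lognormal_factor(rng, cfg.noise_cv, None)
                fw = fw_mean * _lognormal_factor(rng, cfg.noise_cv, None)
                frac = float(
                    np.clip(
                        dry_frac * _lognormal_factor(rng, cfg.noise_cv / 2, None),
                        0.01,
                        0.95,
                    )
                )
                endpoints.append(
                    EndpointMeasures(
                        germplasm_id=gid,
                        condition=condition,
                        replicate=rep,
                        root_length=float(rl),
                        fresh_weight=float(fw),
                        dry_weight=float(fw * frac),
                    )
                )
    truth = pd.DataFrame(truth_rows, columns=["germplasm", "theta"])
    return SyntheticPanel(
        truth=truth, courses=courses, endpoints=endpoints, config=cfg
    )


def write_panel(panel: SyntheticPanel, out_dir) -> None:
    """Write germination.csv, endpoints.csv and truth.csv to a directory."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_germination_csv(out / "germination.csv", panel.courses)
    write_endpoint_csv(out / "endpoints.csv", panel.endpoints)
    panel.truth.to_csv(out / "truth.csv", index=False)


def recover_tolerance(
    panel: SyntheticPanel, config: PanelConfig | None = None
) -> dict:
    """Run the full pipeline on a synthetic panel and measure how well the
    composite scores rank the latent truth.

    Returns Spearman rank correlations of theta with mean MFV and with the
    fitted Y score, plus the full :class:`~germscreen.pipeline.EvaluationResult`
    under key ``"result"``.
    """
    result: EvaluationResult = evaluate_panel(
        panel.courses, panel.endpoints, config=config, scheme="panel", model="fit"
    )
    merged = panel.truth.merge(result.table, on="germplasm", validate="1:1")
    rho_mfv = float(spearmanr(merged["theta"], merged["mean_MFV"]).statistic)
    rho_y = float(spearmanr(merged["theta"], merged["Y"]).statistic)
    return {
        "spearman_theta_mean_mfv": rho_mfv,
        "spearman_theta_y": rho_y,
        "result": result,
    }
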