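"""Data model, CSV interchange, configuration and logging for germination
salt-tolerance screening panels.

The pipeline evaluates a panel of germplasm lines (genetically distinct seed
stocks) germinated under a control condition (distilled water) and a salt
treatment (300 mM NaCl).  The raw observations are

* daily cumulative germination counts for days 1..7 per replicate dish, and
* endpoint seedling measures (root length, fresh weight, dry weight) per
  replicate.

All interchange is plain UTF-8 CSV with a required header.  Three file
schemas are supported:

``germination.csv``
    ``germplasm,condition,replicate,n_seeds,day,cum_germinated``
``endpoints.csv``
    ``germplasm,condition,replicate,root_length_cm,fresh_weight_g,dry_weight_g``
    (blank cell = missing measurement)
``evaluation.csv``
    one row per germplasm with STI, MFV, mean MFV, grade and (optionally) the
    Y tolerance score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "TRAITS",
    "CONDITIONS",
    "N_DAYS",
    "GRADES",
    "GermscreenError",
    "SchemaError",
    "GerminationTimeCourse",
    "EndpointMeasures",
    "PanelConfig",
    "configure_logging",
    "logger",
    "read_germination_csv",
    "read_endpoint_csv",
    "write_germination_csv",
    "write_endpoint_csv",
    "write_evaluation_csv",
    "read_evaluation_csv",
]

#: Fixed evaluation-trait order used everywhere downstream: germination rate,
#: germination index, germination energy, root length, germination vigor
#: index, fresh weight, water content.
TRAITS: tuple[str, ...] = ("GR", "GI", "GE", "RL", "GVI", "FW", "WC")

CONDITIONS: tuple[str, str] = ("control", "salt")

#: Scoring horizon: counts are recorded daily for one week.
N_DAYS: int = 7

#: Five tolerance grades, most to least tolerant: highly salt-tolerant,
#: salt-tolerant, moderately salt-tolerant, salt-sensitive, highly
#: salt-sensitive.
GRADES: tuple[str, ...] = ("HST", "ST", "MST", "SS", "HSS")

logger = logging.getLogger("germscreen")


def configure_logging(level: str = "INFO") -> None:
    """Attach a stderr handler to the package logger (idempotent)."""
    logger.setLevel(level.upper())
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)


class GermscreenError(Exception):
    """Base class for all package errors."""


class SchemaError(GermscreenError):
    """Malformed or invariant-violating tabular input."""


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return False


@dataclass(frozen=True)
class GerminationTimeCourse:
    """Cumulative daily germination counts for one replicate dish.

    ``counts[t-1]`` is the cumulative number of germinated seeds by day ``t``
    (a seed counts as germinated once its radicle reaches half the seed
    length).  Counts are therefore non-decreasing and bounded by the number
    of seeds sown.
    """

    germplasm_id: str
    condition: str
    replicate: int
    n_seeds: int
    counts: tuple[int, ...]

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise SchemaError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if self.replicate < 1:
            raise SchemaError(f"replicate must be >= 1, got {self.replicate}")
        if self.n_seeds < 1:
            raise SchemaError(f"n_seeds must be >= 1, got {self.n_seeds}")
        counts = tuple(int(c) for c in self.counts)
        object.__setattr__(self, "counts", counts)
        if len(counts) != N_DAYS:
            raise SchemaError(
                f"expected {N_DAYS} daily counts, got {len(counts)} "
                f"({self.germplasm_id}/{self.condition}/rep {self.replicate})"
            )
        prev = 0
        for day, c in enumerate(counts, start=1):
            if c < prev:
                raise SchemaError(
                    f"decreasing cumulative count on day {day} "
                    f"({self.germplasm_id}/{self.condition}/rep {self.replicate}): "
                    f"{c} < {prev}"
                )
            if c < 0 or c > self.n_seeds:
                raise SchemaError(
                    f"count {c} on day {day} outside [0, n_seeds={self.n_seeds}] "
                    f"({self.germplasm_id}/{self.condition}/rep {self.replicate})"
                )
            prev = c


@dataclass(frozen=True)
class EndpointMeasures:
    """Endpoint seedling measures for one replicate: root length (cm), fresh
    weight (g) and oven-dry weight (g).  Any measure may be missing (``None``),
    e.g. when seeds germinated without cotyledon growth and no seedling could
    be weighed."""

    germplasm_id: str
    condition: str
    replicate: int
    root_length: Optional[float] = None
    fresh_weight: Optional[float] = None
    dry_weight: Optional[float] = None

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise SchemaError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        for name in ("root_length", "fresh_weight", "dry_weight"):
            v = getattr(self, name)
            if _is_missing(v):
                object.__setattr__(self, name, None)
            elif v < 0:
                raise SchemaError(
                    f"negative {name} ({v}) for {self.germplasm_id}/"
                    f"{self.condition}/rep {self.replicate}"
                )
        if (
            self.dry_weight is not None
            and self.fresh_weight is not None
            and self.dry_weight > self.fresh_weight
        ):
            raise SchemaError(
                f"dry_weight {self.dry_weight} exceeds fresh_weight "
                f"{self.fresh_weight} for {self.germplasm_id}/"
                f"{self.condition}/rep {self.replicate}"
            )


@dataclass(frozen=True)
class PanelConfig:
    """Pipeline configuration.

    missing_sti_policy
        ``zero_fill`` (default): traits unmeasurable under salt (including
        whole non-germinating lines) get STI 0, so every line enters the
        membership stage with a complete profile.  ``exclude_trait``: such
        traits stay missing and the line gets no composite score.
    count_interpretation
        ``cumulative`` (default): the count column already holds cumulative
        totals by day.  ``daily_new``: the column holds newly germinated
        seeds per day and is cumulated on ingest.
    sd_ddof
        Delta degrees of freedom for the panel standard deviation used in
        grading (1 = sample SD, the default).
    """

    missing_sti_policy: str = "zero_fill"
    count_interpretation: str = "cumulative"
    trait_names: tuple[str, ...] = TRAITS
    sd_ddof: int = 1

    def __post_init__(self):
        if self.missing_sti_policy not in ("zero_fill", "exclude_trait"):
            raise GermscreenError(
                f"unknown missing_sti_policy {self.missing_sti_policy!r}"
            )
        if self.count_interpretation not in ("cumulative", "daily_new"):
            raise GermscreenError(
                f"unknown count_interpretation {self.count_interpretation!r}"
            )
        if tuple(self.trait_names) != TRAITS:
            raise GermscreenError(
                f"trait_names must be exactly {TRAITS} in this order"
            )
        if self.sd_ddof not in (0, 1):
            raise GermscreenError(f"sd_ddof must be 0 or 1, got {self.sd_ddof}")


# ---------------------------------------------------------------------------
# germination.csv

_GERM_COLS = ["germplasm", "condition", "replicate", "n_seeds", "day", "cum_germinated"]


def read_germination_csv(
    path, config: PanelConfig | None = None
) -> list[GerminationTimeCourse]:
    """Read per-day germination counts and assemble one
    :class:`GerminationTimeCourse` per (germplasm, condition, replicate).

    Each record needs exactly one row per day 1..7.  Duplicated days, gaps,
    decreasing cumulative counts or counts exceeding ``n_seeds`` are rejected
    with the offending CSV row number in the message.
    """
    config = config or PanelConfig()
    df = pd.read_csv(path, dtype={"germplasm": str}, float_precision="round_trip")
    missing_cols = [c for c in _GERM_COLS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing columns {missing_cols}")
    # +2: header line plus 1-based indexing
    df = df.assign(_row=df.index + 2)

    courses: list[GerminationTimeCourse] = []
    for (gid, cond, rep), grp in df.groupby(
        ["germplasm", "condition", "replicate"], sort=True
    ):
        days = grp["day"].tolist()
        dup = grp[grp["day"].duplicated()]
        if not dup.empty:
            raise SchemaError(
                f"{path}: duplicate day {int(dup['day'].iloc[0])} for "
                f"{gid}/{cond}/rep {rep} (row {int(dup['_row'].iloc[0])})"
            )
        if sorted(days) != list(range(1, N_DAYS + 1)):
            gaps = sorted(set(range(1, N_DAYS + 1)) - set(days))
            raise SchemaError(
                f"{path}: {gid}/{cond}/rep {rep} missing day(s) {gaps} "
                f"(rows {int(grp['_row'].min())}..{int(grp['_row'].max())})"
            )
        n_seeds = grp["n_seeds"].unique()
        if len(n_seeds) != 1:
            raise SchemaError(
                f"{path}: inconsistent n_seeds {sorted(n_seeds)} for "
                f"{gid}/{cond}/rep {rep}"
            )
        ordered = grp.sort_values("day")
        counts = ordered["cum_germinated"].to_numpy()
        if config.count_interpretation == "daily_new":
            counts = counts.cumsum()
        try:
            course = GerminationTimeCourse(
                germplasm_id=str(gid),
                condition=str(cond),
                replicate=int(rep),
                n_seeds=int(n_seeds[0]),
                counts=tuple(int(c) for c in counts),
            )
        except SchemaError as exc:
            raise SchemaError(
                f"{path}: rows {int(ordered['_row'].min())}.."
                f"{int(ordered['_row'].max())}: {exc}"
            ) from None
        courses.append(course)
    return courses


def write_germination_csv(path, courses: Iterable[GerminationTimeCourse]) -> None:
    """Write time courses in the ``germination.csv`` schema (one row per day),
    sorted by (germplasm, condition, replicate, day)."""
    rows = []
    for c in sorted(
        courses, key=lambda c: (c.germplasm_id, c.condition, c.replicate)
    ):
        for day, count in enumerate(c.counts, start=1):
            rows.append(
                dict(
                    germplasm=c.germplasm_id,
                    condition=c.condition,
                    replicate=c.replicate,
                    n_seeds=c.n_seeds,
                    day=day,
                    cum_germinated=count,
                )
            )
    pd.DataFrame(rows, columns=_GERM_COLS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# endpoints.csv

_ENDPOINT_COLS = [
    "germplasm",
    "condition",
    "replicate",
    "root_length_cm",
    "fresh_weight_g",
    "dry_weight_g",
]


def read_endpoint_csv(path) -> list[EndpointMeasures]:
    """Read endpoint seedling measures; blank cells become missing values."""
    df = pd.read_csv(path, dtype={"germplasm": str}, float_precision="round_trip")
    missing_cols = [c for c in _ENDPOINT_COLS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing columns {missing_cols}")
    seen: set[tuple] = set()
    records: list[EndpointMeasures] = []
    for idx, row in df.iterrows():
        key = (row["germplasm"], row["condition"], int(row["replicate"]))
        if key in seen:
            raise SchemaError(
                f"{path}: duplicate endpoint record {key} (row {idx + 2})"
            )
        seen.add(key)
        try:
            rec = EndpointMeasures(
                germplasm_id=str(row["germplasm"]),
                condition=str(row["condition"]),
                replicate=int(row["replicate"]),
                root_length=row["root_length_cm"],
                fresh_weight=row["fresh_weight_g"],
                dry_weight=row["dry_weight_g"],
            )
        except SchemaError as exc:
            raise SchemaError(f"{path}: row {idx + 2}: {exc}") from None
        records.append(rec)
    return records


def write_endpoint_csv(path, records: Iterable[EndpointMeasures]) -> None:
    rows = [
        dict(
            germplasm=r.germplasm_id,
            condition=r.condition,
            replicate=r.replicate,
            root_length_cm=r.root_length,
            fresh_weight_g=r.fresh_weight,
            dry_weight_g=r.dry_weight,
        )
        for r in sorted(
            records, key=lambda r: (r.germplasm_id, r.condition, r.replicate)
        )
    ]
    pd.DataFrame(rows, columns=_ENDPOINT_COLS).to_csv(
        path, index=False, float_format="%.17g"
    )


# ---------------------------------------------------------------------------
# evaluation.csv

EVALUATION_COLUMNS = (
    ["germplasm"]
    + [f"STI_{t}" for t in TRAITS]
    + [f"MFV_{t}" for t in TRAITS]
    + ["mean_MFV", "grade", "Y"]
)


def write_evaluation_csv(path, table: pd.DataFrame, round_display: bool = False) -> None:
    """Write the per-germplasm evaluation table.

    Rows are sorted by germplasm id and columns follow the fixed schema.  By
    default values are written at full precision so a write/read round trip
    is lossless; ``round_display=True`` applies the conventional display
    rounding instead (3 decimals for STI and MFV columns, 5 for Y).
    """
    df = table.copy()
    for col in EVALUATION_COLUMNS:
        if col not in df.columns:
            df[col] = float("nan") if col != "grade" else None
    df = df[EVALUATION_COLUMNS].sort_values("germplasm").reset_index(drop=True)
    if round_display:
        sti_mfv = [c for c in df.columns if c.startswith(("STI_", "MFV_"))]
        df[sti_mfv + ["mean_MFV"]] = df[sti_mfv + ["mean_MFV"]].round(3)
        df["Y"] = df["Y"].round(5)
    df.to_csv(path, index=False, float_format="%.17g")


def read_evaluation_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"germplasm": str}, float_precision="round_trip")
    missing_cols = [c for c in EVALUATION_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing columns {missing_cols}")
    return df
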