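"""Domain records, configuration, cohort IO and exclusion filtering.

One :class:`CatRecord` per cat holds the clinical, body-composition and
analyte values plus the flags driving cohort exclusion.  Cohort tables are
plain CSV (UTF-8, header row); insulin may be supplied in mU/L or ng/L —
ng/L values are converted at the boundary and stored internally in mU/L
only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Iterator, Literal, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .homa import insulin_ngL_to_mUL

logger = logging.getLogger("felhoma")

#: Fixed precedence of exclusion reasons (first triggering reason reported).
EXCLUSION_ORDER = (
    "stressed",
    "underage",
    "pregnant",
    "nonfasted",
    "diabetes_suspected",
    "insulin_interference",
)


class CatRecord(BaseModel):
    """Clinical and analyte data for one cat."""

    cat_id: str
    age_years: float = Field(ge=0)
    sex: Literal["male", "female"]
    neutered: bool
    breed: str = ""
    bcs_value: int
    bcs_scale: Literal[5, 9]
    insulin_mUL: float = Field(gt=0)
    glucose_mmolL: float = Field(gt=0)
    fructosamine: Optional[float] = Field(default=None, ge=0)
    bf_percent: Optional[float] = Field(default=None, gt=0, lt=100)
    stressed: bool = False
    locomotor_signs: bool = False
    insulin_interference: bool = False
    fasted: bool = True
    pregnant: bool = False

    @model_validator(mode="after")
    def _bcs_within_scale(self) -> "CatRecord":
        if not 1 <= self.bcs_value <= self.bcs_scale:
            raise ValueError(
                f"BCS {self.bcs_value} outside 1..{self.bcs_scale} for cat {self.cat_id}"
            )
        return self


class AnalysisConfig(BaseModel):
    """Run-wide settings; every pipeline run logs the fully resolved values.

    ``fructosamine_ri_upper`` is site-configurable (µmol/L): the upper bound
    of the laboratory's fructosamine reference interval used, together with
    the glucose threshold, to call suspected diabetes mellitus.  The default
    is a plausible laboratory value, not a study-derived constant.
    """

    z_value: float = Field(default=1.96, gt=0)
    rcv_probability: float = Field(default=0.95, gt=0, lt=1)
    bootstrap_B: int = Field(default=5000, ge=1)
    rng_seed: int = 0
    glucose_dm_threshold_mmolL: float = Field(default=10.0, gt=0)
    fructosamine_ri_upper_umolL: float = Field(default=340.0, gt=0)
    min_age_years: float = Field(default=1.0, ge=0)
    histogram_bin_width_HU: float = Field(default=1.0, gt=0)
    hu_window: tuple[int, int] = (-250, 250)

    @model_validator(mode="after")
    def _window_ordered(self) -> "AnalysisConfig":
        if self.hu_window[0] >= self.hu_window[1]:
            raise ValueError(f"hu_window must be (low, high), got {self.hu_window}")
        return self


@dataclasses.dataclass
class ExclusionReport:
    """Which cats were removed and why, plus follow-up flags.

    ``followup`` lists retained cats with glucose above the DM threshold but
    fructosamine normal or unmeasured (stress hyperglycemia suspects).
    """

    excluded: list[tuple[str, str]]
    retained_count: int
    followup: list[str] = dataclasses.field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "excluded": [list(e) for e in self.excluded],
            "retained_count": self.retained_count,
            "followup": list(self.followup),
        }


@dataclasses.dataclass
class ReadResult:
    """Validated records plus per-row errors collected during reading."""

    records: list[CatRecord]
    errors: list[tuple[int, str]]

    def __iter__(self) -> Iterator[CatRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


class SchemaError(ValueError):
    """The cohort table is missing mandatory columns."""


_MANDATORY = [
    "cat_id",
    "age_years",
    "sex",
    "neutered",
    "bcs_value",
    "bcs_scale",
    "glucose_mmolL",
]
_BOOL_FIELDS = [
    "neutered",
    "stressed",
    "locomotor_signs",
    "insulin_interference",
    "fasted",
    "pregnant",
]


def _as_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    s = str(v).strip().lower()
    if s in ("true", "1", "yes", "y"):
        return True
    if s in ("false", "0", "no", "n"):
        return False
    raise ValueError(f"cannot interpret {v!r} as boolean")


def read_cohort(path: str | Path) -> ReadResult:
    """Read a cohort CSV into validated :class:`CatRecord` objects.

    The insulin column must be named ``insulin_mUL`` or ``insulin_ngL``;
    ng/L values are multiplied by 0.023 on load.  Rows failing validation
    are collected as ``(row_number, message)`` (1-based data rows) and
    skipped; a missing mandatory column or a fully invalid file raises.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _MANDATORY if c not in df.columns]
    if "insulin_mUL" not in df.columns and "insulin_ngL" not in df.columns:
        missing.append("insulin_mUL|insulin_ngL")
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {missing}")

    records: list[CatRecord] = []
    errors: list[tuple[int, str]] = []
    for i, row in enumerate(df.to_dict(orient="records"), start=1):
        try:
            data = {k: v for k, v in row.items() if not pd.isna(v)}
            if "insulin_ngL" in data:
                data["insulin_mUL"] = insulin_ngL_to_mUL(float(data.pop("insulin_ngL")))
            for b in _BOOL_FIELDS:
                if b in data:
                    data[b] = _as_bool(data[b])
            if "cat_id" in data:
                data["cat_id"] = str(data["cat_id"])
            records.append(CatRecord(**data))
        except (ValueError, TypeError) as exc:
            errors.append((i, str(exc)))
    if len(df) > 0 and not records:
        raise ValueError(f"{path}: no valid rows ({len(errors)} row errors)")
    for i, msg in errors:
        logger.warning("row %d rejected: %s", i, msg)
    return ReadResult(records=records, errors=errors)


def write_cohort(records: Iterable[CatRecord], path: str | Path) -> None:
    """Write records back to CSV; read -> write -> read is lossless."""
    rows = [r.model_dump() for r in records]
    # %.17g guarantees float round-trip through the text format
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def apply_exclusions(
    records: Sequence[CatRecord], cfg: AnalysisConfig | None = None
) -> tuple[list[CatRecord], ExclusionReport]:
    """Apply the cohort exclusion rules; pure and idempotent.

    Removed: stressed cats, cats under the minimum age, pregnant or
    non-fasted cats, suspected diabetics (glucose above threshold AND
    fructosamine above the configured reference upper bound), and cats with
    suspected assay interference.  Hyperglycemic cats whose fructosamine is
    normal or unmeasured are retained and listed for follow-up.
    """
    cfg = cfg or AnalysisConfig()
    retained: list[CatRecord] = []
    excluded: list[tuple[str, str]] = []
    followup: list[str] = []
    for r in records:
        hyperglycemic = r.glucose_mmolL > cfg.glucose_dm_threshold_mmolL
        dm_suspected = (
            hyperglycemic
            and r.fructosamine is not None
            and r.fructosamine > cfg.fructosamine_ri_upper_umolL
        )
        reasons = {
            "stressed": r.stressed,
            "underage": r.age_years < cfg.min_age_years,
            "pregnant": r.pregnant,
            "nonfasted": not r.fasted,
            "diabetes_suspected": dm_suspected,
            "insulin_interference": r.insulin_interference,
        }
        hit = next((name for name in EXCLUSION_ORDER if reasons[name]), None)
        if hit is not None:
            excluded.append((r.cat_id, hit))
        else:
            retained.append(r)
            if hyperglycemic:
                followup.append(r.cat_id)
    report = ExclusionReport(
        excluded=excluded, retained_count=len(retained), followup=followup
    )
    logger.info(
        "exclusions: %d in, %d retained, %d excluded (%d follow-up)",
        len(records),
        report.retained_count,
        len(excluded),
        len(followup),
    )
    return retained, report


def write_run_manifest(
    path: str | Path, cfg: AnalysisConfig, report: ExclusionReport | None = None, **extra
) -> None:
    """Serialize the resolved config (and optional exclusion report) as JSON."""
    payload: dict = {"config": cfg.model_dump()}
    if report is not None:
        payload["exclusion_report"] = report.to_dict()
    payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
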