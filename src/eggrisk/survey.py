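"""Sample-level contaminant surveys: ingest, censoring, summary statistics.

The survey design this package targets is a market basket of whole hen
eggs: a fixed set of brands sampled with a small number of replicates per
brand in each of two seasons, with each ICP-MS measurement reported in
µg/kg wet weight.  Measurements below the analytical limit of detection
(LOD) are censored and replaced according to an explicit policy before any
statistic is computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, SchemaError, ValidationError

SEASONS = ("winter", "summer")

#: replacement value assigned to a measurement below the LOD, per policy
CENSOR_POLICIES = ("zero", "half_lod", "lod")

#: default CSV column names for :func:`read_survey`
DEFAULT_SCHEMA: Mapping[str, str] = {
    "brand_id": "brand",
    "season": "season",
    "replicate": "replicate",
    "metal": "metal",
    "concentration": "conc_ugkg",
}


@dataclass(frozen=True)
class ConcentrationRecord:
    """One contaminant measurement on one egg sample.

    Parameters
    ----------
    brand_id : str
        Identifier of the commercial brand (the pairing unit across seasons).
    season : str
        Sampling season, ``"winter"`` or ``"summer"``.
    replicate : int
        1-based replicate index within brand and season.
    metal : str
        Element symbol, e.g. ``"As"`` or ``"Hg"``.
    concentration : float
        Concentration in µg/kg wet weight (after censoring, if applied).
    below_lod : bool
        True once the raw value was found below the LOD and substituted.
    """

    brand_id: str
    season: str
    replicate: int
    metal: str
    concentration: float
    below_lod: bool = False

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise ValidationError(
                f"unknown season {self.season!r}; expected one of {SEASONS}"
            )
        if self.replicate < 1:
            raise ValidationError(f"replicate must be >= 1, got {self.replicate}")
        if not self.metal:
            raise ValidationError("metal symbol must be non-empty")
        if not math.isfinite(self.concentration) or self.concentration < 0:
            raise ValidationError(
                f"concentration must be finite and >= 0, got {self.concentration}"
            )


@dataclass(frozen=True)
class CensoringRule:
    """Limit of detection/quantification and the below-LOD substitution policy."""

    lod: float = 0.0003
    loq: float = 0.001
    policy: str = "zero"

    def __post_init__(self) -> None:
        if not (0 < self.lod <= self.loq):
            raise ValidationError(
                f"require 0 < lod <= loq, got lod={self.lod}, loq={self.loq}"
            )
        if self.policy not in CENSOR_POLICIES:
            raise ValidationError(
                f"unknown policy {self.policy!r}; expected one of {CENSOR_POLICIES}"
            )

    @property
    def replacement(self) -> float:
        if self.policy == "zero":
            return 0.0
        if self.policy == "half_lod":
            return self.lod / 2.0
        return self.lod


@dataclass(frozen=True)
class SurveySummary:
    """Descriptive statistics of one metal x season group (or the pooled set).

    ``se`` is the standard error of the mean, computed with the n-1 sample
    standard deviation; it is defined as 0 for a single-record group.
    """

    metal: str
    season: str  # "winter" / "summer" / "pooled"
    n: int
    min: float
    max: float
    mean: float
    se: float

    @property
    def sd(self) -> float:
        """Sample standard deviation recovered from the standard error."""
        return self.se * math.sqrt(self.n)


def read_survey(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> list[ConcentrationRecord]:
    """Read a survey CSV into a list of :class:`ConcentrationRecord`.

    The CSV must be comma-separated UTF-8 with a header row; ``schema`` maps
    record fields to column names (default :data:`DEFAULT_SCHEMA`).  Row
    count is preserved; malformed rows are reported with their CSV line
    number (header is line 1).

    Raises
    ------
    SchemaError
        If a required column is missing.
    ValidationError
        If any row holds a non-numeric or negative concentration; the
        message cites every offending line.
    """
    schema = dict(DEFAULT_SCHEMA if schema is None else schema)
    path = Path(path)
    df = pd.read_csv(path, dtype=str, encoding="utf-8", skipinitialspace=True)
    missing = [col for col in schema.values() if col not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s) {missing}; "
            f"found {list(df.columns)}"
        )

    records: list[ConcentrationRecord] = []
    problems: list[str] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2  # +1 header, +1 one-based
        try:
            conc = float(row[schema["concentration"]])
        except (TypeError, ValueError):
            problems.append(
                f"line {line}: concentration "
                f"{row[schema['concentration']]!r} is not a number"
            )
            continue
        try:
            records.append(
                ConcentrationRecord(
                    brand_id=str(row[schema["brand_id"]]),
                    season=str(row[schema["season"]]).strip().lower(),
                    replicate=int(float(row[schema["replicate"]])),
                    metal=str(row[schema["metal"]]).strip(),
                    concentration=conc,
                )
            )
        except (ValidationError, ValueError) as exc:
            problems.append(f"line {line}: {exc}")
    if problems:
        raise ValidationError(
            f"{path.name}: {len(problems)} malformed row(s):\n  " + "\n  ".join(problems)
        )
    return records


def apply_censoring(
    records: Iterable[ConcentrationRecord], rule: CensoringRule
) -> list[ConcentrationRecord]:
    """Substitute every concentration below ``rule.lod`` per the policy.

    Records at or above the LOD pass through unchanged.  The returned list
    preserves order.
    """
    out: list[ConcentrationRecord] = []
    for rec in records:
        if rec.concentration < rule.lod:
            out.append(
                replace(rec, concentration=rule.replacement, below_lod=True)
            )
        else:
            out.append(rec)
    return out


def records_frame(records: Sequence[ConcentrationRecord]) -> pd.DataFrame:
    """Convert records to a tidy DataFrame (one measurement per row)."""
    return pd.DataFrame(
        {
            "brand": [r.brand_id for r in records],
            "season": [r.season for r in records],
            "replicate": [r.replicate for r in records],
            "metal": [r.metal for r in records],
            "conc_ugkg": [r.concentration for r in records],
            "below_lod": [r.below_lod for r in records],
        }
    )


def write_survey_csv(records: Sequence[ConcentrationRecord], path: str | Path) -> None:
    """Write records in the survey CSV schema read by :func:`read_survey`."""
    records_frame(records).drop(columns="below_lod").to_csv(path, index=False)


def summarize(
    records: Sequence[ConcentrationRecord],
    group_by: Sequence[str] = ("metal", "season"),
) -> list[SurveySummary]:
    """Per-group n / min / max / mean / standard error.

    ``group_by`` is ``("metal", "season")`` for seasonal rows or
    ``("metal",)`` for the pooled (two-season) row, in which case the
    summary's season is reported as ``"pooled"`` and the mean is the
    arithmetic mean over all pooled records.
    """
    if not records:
        raise DegenerateDataError("cannot summarize an empty record collection")
    group_by = tuple(group_by)
    if "metal" not in group_by:
        raise ValidationError("group_by must include 'metal'")
    df = records_frame(records)
    out: list[SurveySummary] = []
    for keys, grp in df.groupby(list(group_by), sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        info = dict(zip(group_by, keys))
        vals = grp["conc_ugkg"].to_numpy(dtype=float)
        n = len(vals)
        # se is exactly 0 for a constant group (no floating-point residue)
        if n == 1 or vals.max() == vals.min():
            se = 0.0
        else:
            se = float(np.std(vals, ddof=1) / math.sqrt(n))
        out.append(
            SurveySummary(
                metal=str(info["metal"]),
                season=str(info.get("season", "pooled")),
                n=n,
                min=float(vals.min()),
                max=float(vals.max()),
                mean=float(vals.mean()),
                se=se,
            )
        )
    return out


def summaries_frame(summaries: Sequence[SurveySummary]) -> pd.DataFrame:
    """Summary rows as a DataFrame (metal, season, n, min, max, mean, se)."""
    return pd.DataFrame(
        {
            "metal": [s.metal for s in summaries],
            "season": [s.season for s in summaries],
            "n": [s.n for s in summaries],
            "min": [s.min for s in summaries],
            "max": [s.max for s in summaries],
            "mean": [s.mean for s in summaries],
            "se": [s.se for s in summaries],
        }
    )


def mean_of_seasonal_means(summaries: Sequence[SurveySummary], metal: str) -> float:
    """Two-season mean concentration as the average of the seasonal means.

    With equal per-season sample sizes this equals the pooled mean over all
    records; it is exposed separately because report tables conventionally
    derive their "mean" rows this way.
    """
    means = [s.mean for s in summaries if s.metal == metal and s.season in SEASONS]
    if not means:
        raise DegenerateDataError(f"no seasonal summaries for metal {metal!r}")
    return float(np.mean(means))
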