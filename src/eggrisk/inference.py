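"""Normality screening and paired seasonal comparison of concentrations.

Two classical procedures: a one-sample Kolmogorov-Smirnov test against a
normal reference (parameters estimated from the sample by default, with an
optional Lilliefors-corrected p-value), and a paired two-sided t-test of
winter vs summer concentrations, paired by brand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, PairingError
from .survey import ConcentrationRecord

__all__ = [
    "NormalityResult",
    "PairedComparison",
    "ks_normality",
    "paired_seasonal_test",
    "seasonal_brand_values",
    "seasonal_comparison",
]


@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    p_value: float
    normal: bool
    alpha: float = 0.05


@dataclass(frozen=True)
class PairedComparison:
    """Outcome of a paired seasonal t-test for one metal.

    ``mean_difference`` is winter minus summer, in µg/kg.
    """

    metal: str
    n_pairs: int
    mean_difference: float
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    significant: bool
    alpha: float = 0.05


def ks_normality(
    values: Sequence[float],
    alpha: float = 0.05,
    lilliefors: bool = False,
) -> NormalityResult:
    """One-sample KS test of normality, D = sup |F_n - F0|.

    The reference normal uses the sample mean and the n-1 sample standard
    deviation.  With ``lilliefors=True`` the p-value is corrected for that
    parameter estimation (Lilliefors test); by default the uncorrected,
    conservative KS p-value is reported.

    Raises
    ------
    DegenerateDataError
        For n < 3, non-finite values, or a zero-variance sample.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise DegenerateDataError(f"need at least 3 values, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise DegenerateDataError("values must be finite")
    if x.max() == x.min():
        raise DegenerateDataError("zero-variance sample: normality is undefined")
    mu = float(x.mean())
    sd = float(x.std(ddof=1))
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        stat, p = _lf(x, dist="norm")
    else:
        res = stats.kstest(x, "norm", args=(mu, sd))
        stat, p = float(res.statistic), float(res.pvalue)
    return NormalityResult(
        statistic=float(stat), p_value=float(p), normal=bool(p > alpha), alpha=alpha
    )


def paired_seasonal_test(
    winter: Mapping[object, float],
    summer: Mapping[object, float],
    metal: str = "",
    alpha: float = 0.05,
) -> PairedComparison:
    """Two-sided paired t-test of winter vs summer values.

    ``winter`` and ``summer`` map the pairing key (typically the brand id)
    to one value per season; keys must match one-to-one.

    Raises
    ------
    PairingError
        If either season has keys absent from the other (orphans listed).
    DegenerateDataError
        If the per-pair differences have zero variance (the t statistic is
        undefined), or there are fewer than 2 pairs.
    """
    w_keys, s_keys = set(winter), set(summer)
    if w_keys != s_keys:
        orphans = sorted(map(str, w_keys.symmetric_difference(s_keys)))
        raise PairingError(f"unpaired units across seasons: {orphans}")
    keys = sorted(winter, key=str)
    if len(keys) < 2:
        raise DegenerateDataError("paired t-test needs at least 2 pairs")
    diffs = np.array([winter[k] - summer[k] for k in keys], dtype=float)
    n = diffs.size
    mean_diff = float(diffs.mean())
    # range check, not sd == 0: identical values can leave ~1e-16 of
    # floating-point residue in the standard deviation
    if diffs.max() == diffs.min():
        raise DegenerateDataError(
            "all paired differences identical (sd = 0); t statistic undefined"
        )
    sd = float(diffs.std(ddof=1))
    t = mean_diff / (sd / math.sqrt(n))
    df = n - 1
    p = float(2.0 * stats.t.sf(abs(t), df))
    return PairedComparison(
        metal=metal,
        n_pairs=n,
        mean_difference=mean_diff,
        t_statistic=float(t),
        degrees_of_freedom=df,
        p_value=p,
        significant=bool(p < alpha),
        alpha=alpha,
    )


def seasonal_brand_values(
    records: Sequence[ConcentrationRecord],
    metal: str,
    pairing: str = "brand_mean",
) -> tuple[dict[object, float], dict[object, float]]:
    """Collapse records into per-season paired values for one metal.

    ``pairing="brand_mean"`` averages replicates within each brand and
    season (the default, since replicates are not individually matched
    across seasons); ``pairing="replicate"`` pairs on (brand, replicate).
    """
    if pairing not in ("brand_mean", "replicate"):
        raise PairingError(f"unknown pairing {pairing!r}")
    per_season: dict[str, dict[object, list[float]]] = {"winter": {}, "summer": {}}
    for rec in records:
        if rec.metal != metal:
            continue
        key = rec.brand_id if pairing == "brand_mean" else (rec.brand_id, rec.replicate)
        per_season[rec.season].setdefault(key, []).append(rec.concentration)
    winter = {k: float(np.mean(v)) for k, v in per_season["winter"].items()}
    summer = {k: float(np.mean(v)) for k, v in per_season["summer"].items()}
    return winter, summer


def seasonal_comparison(
    records: Sequence[ConcentrationRecord],
    metal: str,
    pairing: str = "brand_mean",
    alpha: float = 0.05,
) -> PairedComparison:
    """Convenience wrapper: pair records by brand and run the seasonal test."""
    winter, summer = seasonal_brand_values(records, metal, pairing=pairing)
    return paired_seasonal_test(winter, summer, metal=metal, alpha=alpha)
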