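"""Monte Carlo propagation of concentration uncertainty through the risk
equations.

The deterministic metrics (EDI, THQ, ILCR) are linear in the mean
concentration, so a single-point estimate hides the spread of the survey.
Here a probability distribution is fitted to the survey summary (lognormal
by moment matching, by default), propagated draw-by-draw through the same
formulas as :mod:`eggrisk.risk`, and summarized by interpolated percentile
order statistics and an empirical cumulative curve.  Exposure factors are
held at point values unless the caller supplies distributions for a
sensitivity run.
"""

from __future__ import annotations

import math
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError, ValidationError
from .risk import ExposureParams, ToxProfile
from .survey import SurveySummary

__all__ = [
    "DistributionSpec",
    "MCConfig",
    "MCResult",
    "build_distribution",
    "draw_samples",
    "run_mcs",
    "summarize_mcs",
    "plot_cumulative_curve",
]

log = logging.getLogger(__name__)

FAMILIES = ("point", "normal", "lognormal", "uniform", "triangular")
METRICS = ("THQ", "ILCR", "EDI")


@dataclass(frozen=True)
class DistributionSpec:
    """A stochastic input: family, family-specific parameters, truncation.

    Parameter keys by family: ``point``: value; ``normal``: mean, sd;
    ``lognormal``: mu, sigma (log scale); ``uniform``: low, high;
    ``triangular``: left, mode, right.  ``lower``/``upper`` truncate by
    rejection (concentrations default to lower = 0).
    """

    family: str
    params: dict = field(default_factory=dict)
    lower: Optional[float] = 0.0
    upper: Optional[float] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown family {self.family!r}")
        if (
            self.lower is not None
            and self.upper is not None
            and self.upper < self.lower
        ):
            raise ValidationError(
                f"infeasible truncation: upper {self.upper} < lower {self.lower}"
            )
        p = self.params
        need = {
            "point": ("value",),
            "normal": ("mean", "sd"),
            "lognormal": ("mu", "sigma"),
            "uniform": ("low", "high"),
            "triangular": ("left", "mode", "right"),
        }[self.family]
        missing = [k for k in need if k not in p]
        if missing:
            raise ValidationError(f"{self.family}: missing parameter(s) {missing}")
        if self.family == "normal" and p["sd"] <= 0:
            raise ValidationError("normal: sd must be > 0")
        if self.family == "lognormal" and p["sigma"] <= 0:
            raise ValidationError("lognormal: sigma must be > 0")
        if self.family == "uniform" and p["high"] <= p["low"]:
            raise ValidationError("uniform: high must exceed low")
        if self.family == "triangular" and not (
            p["left"] <= p["mode"] <= p["right"] and p["left"] < p["right"]
        ):
            raise ValidationError("triangular: require left <= mode <= right, left < right")

    @property
    def analytic_mean(self) -> float:
        """Mean of the untruncated distribution (closed form)."""
        p = self.params
        if self.family == "point":
            return float(p["value"])
        if self.family == "normal":
            return float(p["mean"])
        if self.family == "lognormal":
            return float(math.exp(p["mu"] + p["sigma"] ** 2 / 2.0))
        if self.family == "uniform":
            return float((p["low"] + p["high"]) / 2.0)
        return float((p["left"] + p["mode"] + p["right"]) / 3.0)

    def describe(self) -> str:
        inner = ", ".join(f"{k}={v:.6g}" for k, v in sorted(self.params.items()))
        return f"{self.family}({inner})"


@dataclass(frozen=True)
class MCConfig:
    """Simulation settings: iteration count, seed, reported percentiles."""

    n_iterations: int = 10_000
    seed: int = 0
    percentiles: tuple[float, ...] = (5.0, 50.0, 95.0)

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValidationError("n_iterations must be >= 1")
        if any(not (0.0 < p < 100.0) for p in self.percentiles):
            raise ValidationError("percentiles must lie strictly in (0, 100)")


@dataclass(frozen=True)
class MCResult:
    """Draws and summaries for one simulated metric."""

    metric: str
    metal: str
    draws: np.ndarray
    mean: float
    percentile_table: dict[float, float]
    config: MCConfig
    conc_spec: DistributionSpec

    @property
    def cumulative_curve(self) -> np.ndarray:
        """Empirical CDF: column 0 sorted draws, column 1 probability i/n."""
        x = np.sort(self.draws)
        p = np.arange(1, x.size + 1) / x.size
        return np.column_stack([x, p])


def build_distribution(
    summary: "SurveySummary | float",
    sd: Optional[float] = None,
    family: str = "lognormal",
) -> DistributionSpec:
    """Fit a sampling distribution to a survey summary by moment matching.

    From a :class:`SurveySummary` the spread is the sample standard
    deviation ``se * sqrt(n)``; with an explicit mean, ``sd`` must be
    given.  Lognormal matching: ``sigma^2 = ln(1 + s^2/m^2)``,
    ``mu = ln m - sigma^2/2``, so the analytic mean recovers ``m``
    exactly.  A zero spread downgrades any family to a point mass (logged).
    """
    if isinstance(summary, SurveySummary):
        m, s = summary.mean, summary.sd
    else:
        m = float(summary)
        if sd is None:
            raise ValidationError("sd is required when passing a bare mean")
        s = float(sd)
    if s < 0:
        raise ValidationError(f"sd must be >= 0, got {s}")
    if family not in FAMILIES:
        raise ValidationError(f"unknown family {family!r}")
    if s == 0.0 or family == "point":
        if s == 0.0 and family not in ("point",):
            log.info("zero spread: downgrading %s to a point mass at %g", family, m)
        return DistributionSpec("point", {"value": m})
    if family == "normal":
        return DistributionSpec("normal", {"mean": m, "sd": s})
    if family == "lognormal":
        if m <= 0:
            raise ValidationError(f"lognormal fit needs mean > 0, got {m}")
        sigma2 = math.log(1.0 + (s / m) ** 2)
        mu = math.log(m) - sigma2 / 2.0
        return DistributionSpec("lognormal", {"mu": mu, "sigma": math.sqrt(sigma2)})
    if family == "uniform":
        half = s * math.sqrt(3.0)
        return DistributionSpec("uniform", {"low": m - half, "high": m + half})
    # symmetric triangular with matching mean and sd
    half = s * math.sqrt(6.0)
    return DistributionSpec(
        "triangular", {"left": m - half, "mode": m, "right": m + half}
    )


def _draw_raw(spec: DistributionSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    p = spec.params
    if spec.family == "point":
        return np.full(n, float(p["value"]))
    if spec.family == "normal":
        return rng.normal(p["mean"], p["sd"], size=n)
    if spec.family == "lognormal":
        return rng.lognormal(p["mu"], p["sigma"], size=n)
    if spec.family == "uniform":
        return rng.uniform(p["low"], p["high"], size=n)
    return rng.triangular(p["left"], p["mode"], p["right"], size=n)


def draw_samples(spec: DistributionSpec, config: MCConfig) -> np.ndarray:
    """Draw ``config.n_iterations`` values, truncating by rejection.

    Reproducible: the same spec and config (including seed) always yield
    the identical vector.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_iterations
    lo = -math.inf if spec.lower is None else spec.lower
    hi = math.inf if spec.upper is None else spec.upper
    out = np.empty(0)
    for _ in range(1000):  # guard against a vanishing acceptance region
        batch = _draw_raw(spec, n, rng)
        out = np.concatenate([out, batch[(batch >= lo) & (batch <= hi)]])
        if out.size >= n:
            return out[:n]
    raise ConfigError(
        f"truncation [{spec.lower}, {spec.upper}] rejects nearly all draws of "
        f"{spec.describe()}"
    )


def run_mcs(
    conc_spec: DistributionSpec,
    exposure: ExposureParams,
    tox: ToxProfile,
    config: MCConfig,
    metric: str = "THQ",
    convention: str = "paper",
) -> MCResult:
    """Propagate concentration draws through the risk equations.

    Each draw is treated as a candidate mean concentration (µg/kg) and run
    through exactly the same formulas as the deterministic engine, so with
    a point-mass input the simulation degenerates to the deterministic
    result to full precision.

    Raises
    ------
    ConfigError
        If ``metric="ILCR"`` but the profile carries no cancer slope factor.
    """
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if metric == "ILCR" and tox.csf is None:
        raise ConfigError(
            f"ILCR not computed for {tox.metal}: CSF unavailable"
        )
    cm = draw_samples(conc_spec, config)
    if metric == "EDI":
        draws = exposure.fir * cm / exposure.wab
        if convention == "strict":
            draws = draws / 1000.0
    elif metric == "THQ":
        draws = (
            (exposure.ef * exposure.ed * exposure.fir * (cm / 1000.0))
            / (tox.rfd * exposure.wab * exposure.ta)
            * 1e-3
        )
    else:  # ILCR from the paper-convention EDI
        edi_paper = exposure.fir * cm / exposure.wab
        draws = (edi_paper / 1000.0) * tox.csf
    pct = {
        float(p): float(np.percentile(draws, p, method="linear"))
        for p in config.percentiles
    }
    return MCResult(
        metric=metric,
        metal=tox.metal,
        draws=np.asarray(draws, dtype=float),
        mean=float(np.mean(draws)),
        percentile_table=pct,
        config=config,
        conc_spec=conc_spec,
    )


def summarize_mcs(result: MCResult) -> dict:
    """One report row: mean, requested percentiles, provenance.

    Percentiles use linear interpolation between order statistics at rank
    ``1 + (n-1) p``; re-derived here from the stored draws so the row is
    self-consistent even if the requested levels change.
    """
    if result.draws.size == 0:
        raise ValidationError("draws are empty")
    row = {
        "metric": result.metric,
        "metal": result.metal,
        "mean": result.mean,
        "n_iterations": result.config.n_iterations,
        "seed": result.config.seed,
        "distribution": result.conc_spec.describe(),
    }
    for p in result.config.percentiles:
        row[f"p{p:g}"] = float(np.percentile(result.draws, p, method="linear"))
    return row


def plot_cumulative_curve(result: MCResult, path) -> None:
    """Write the cumulative probability graph of the simulated metric."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    curve = result.cumulative_curve
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve[:, 0], curve[:, 1], lw=1.5)
    p95 = float(np.percentile(result.draws, 95, method="linear"))
    ax.axvline(p95, color="tab:red", ls="--", lw=1, label=f"95th pct = {p95:.3g}")
    ax.set_xlabel(f"{result.metric} ({result.metal})")
    ax.set_ylabel("cumulative probability")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
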