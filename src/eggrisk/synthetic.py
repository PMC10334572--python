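"""Synthetic market-basket surveys with a prescribed design and moments.

The generator emulates the study design behind the default constants: 21
brands, two replicate eggs per brand, two seasons, one ICP-MS value per
egg and metal.  Concentrations are drawn i.i.d. from a family
moment-matched to the target (mean, SE) of each metal x season cell, then
censored at the LOD like real data, so every downstream stage — ingest,
summaries, seasonal tests, risk metrics, Monte Carlo — can be exercised
end to end without any external dataset.

An optional multiplicative brand-level random effect (off by default, to
keep the i.i.d. assumption of the summary statistics) induces the
within-brand correlation that the paired seasonal test exploits.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from . import defaults
from .errors import ConfigError
from .montecarlo import MCConfig, build_distribution, draw_samples
from .survey import CensoringRule, ConcentrationRecord, apply_censoring

__all__ = ["SyntheticSurveyConfig", "generate_survey", "write_truth_json"]


@dataclass(frozen=True)
class SyntheticSurveyConfig:
    """Design and moment targets of a synthetic survey.

    ``targets`` maps (metal, season) to (mean, se) in µg/kg, SE being the
    standard error of the mean at the cell's sample size
    ``n_brands * replicates_per_brand``; the generating standard deviation
    is ``se * sqrt(n)``.  A zero SE yields a point mass (uniform cell).
    """

    n_brands: int = defaults.N_BRANDS
    replicates_per_brand: int = defaults.REPLICATES_PER_BRAND
    seasons: tuple[str, ...] = ("winter", "summer")
    targets: Mapping[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(defaults.SURVEY_MOMENTS)
    )
    family: str = "lognormal"
    censoring: CensoringRule = field(default_factory=lambda: defaults.DEFAULT_CENSORING)
    brand_effect_sd: float = 0.0  # multiplicative brand intercept, 0 = off
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_brands < 1 or self.replicates_per_brand < 1:
            raise ConfigError("n_brands and replicates_per_brand must be >= 1")
        if self.brand_effect_sd < 0:
            raise ConfigError("brand_effect_sd must be >= 0")
        for (metal, season), (mean, se) in self.targets.items():
            if season not in self.seasons:
                raise ConfigError(f"target season {season!r} not in {self.seasons}")
            if mean < 0 or se < 0:
                raise ConfigError(
                    f"targets must be non-negative, got ({metal}, {season}): "
                    f"mean={mean}, se={se}"
                )

    @property
    def n_per_cell(self) -> int:
        return self.n_brands * self.replicates_per_brand


def generate_survey(
    config: SyntheticSurveyConfig,
) -> tuple[list[ConcentrationRecord], dict]:
    """Draw one survey; returns (records, truth).

    Records are ordered by metal, season, brand, replicate and already
    censored per ``config.censoring``.  ``truth`` captures everything
    needed to regenerate or audit the draw: the seed, the design, and the
    moment-matched generating distribution of every cell.

    Identical configs (same seed) produce identical surveys.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_per_cell
    records: list[ConcentrationRecord] = []
    truth_cells: dict[str, dict] = {}

    brand_ids = [f"B{i + 1:02d}" for i in range(config.n_brands)]
    for metal, season in sorted(config.targets):
        mean, se = config.targets[(metal, season)]
        sd = se * math.sqrt(n)
        spec = build_distribution(mean, sd=sd, family=config.family)
        # one independent child seed per cell keeps the streams decoupled
        cell_seed = int(rng.integers(0, 2**31 - 1))
        values = draw_samples(spec, MCConfig(n_iterations=n, seed=cell_seed))
        if config.brand_effect_sd > 0 and spec.family != "point":
            bspec = build_distribution(
                1.0, sd=config.brand_effect_sd, family="lognormal"
            )
            bseed = int(rng.integers(0, 2**31 - 1))
            b = draw_samples(bspec, MCConfig(n_iterations=config.n_brands, seed=bseed))
            values = values * np.repeat(b, config.replicates_per_brand)
        raw: list[ConcentrationRecord] = []
        k = 0
        for brand in brand_ids:
            for rep in range(1, config.replicates_per_brand + 1):
                raw.append(
                    ConcentrationRecord(
                        brand_id=brand,
                        season=season,
                        replicate=rep,
                        metal=metal,
                        concentration=float(values[k]),
                    )
                )
                k += 1
        records.extend(apply_censoring(raw, config.censoring))
        truth_cells[f"{metal}/{season}"] = {
            "target_mean": mean,
            "target_se": se,
            "generating_sd": sd,
            "distribution": spec.describe(),
            "cell_seed": cell_seed,
        }

    truth = {
        "seed": config.seed,
        "n_brands": config.n_brands,
        "replicates_per_brand": config.replicates_per_brand,
        "n_per_cell": n,
        "family": config.family,
        "brand_effect_sd": config.brand_effect_sd,
        "censoring": {
            "lod": config.censoring.lod,
            "loq": config.censoring.loq,
            "policy": config.censoring.policy,
        },
        "cells": truth_cells,
    }
    return records, truth


def write_truth_json(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True))
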