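"""End-to-end orchestration: ingest -> seasonal stats -> deterministic risk
-> Monte Carlo -> machine-readable report.

A :class:`PipelineConfig` names exactly one input source (a survey CSV or
a synthetic-survey configuration) plus exposure, toxicology, censoring,
Monte Carlo and reporting settings.  :func:`run_pipeline` produces a
:class:`RunReport` of tidy tables; :func:`write_report` serializes them as
CSV files and a single JSON bundle.  Every random stage is seeded and the
manifest records a hash of the configuration, so a run is reproducible
byte for byte from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import defaults, survey
from ._util import round_half_up, round_sig
from .errors import ConfigError, DegenerateDataError, PairingError
from .inference import seasonal_comparison
from .montecarlo import MCConfig, build_distribution, run_mcs, summarize_mcs
from .risk import ExposureParams, ToxProfile, assess, compare_guidelines
from .survey import CensoringRule
from .synthetic import SyntheticSurveyConfig, generate_survey

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "write_report", "load_config"]

log = logging.getLogger(__name__)

REPORT_FILES = ("summary.csv", "intakes.csv", "risk.csv", "mcs.csv", "report.json")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs; exactly one of ``survey_path`` /
    ``synthetic`` must be set."""

    survey_path: Optional[Path] = None
    synthetic: Optional[SyntheticSurveyConfig] = None
    censoring: CensoringRule = field(default_factory=CensoringRule)
    exposure: ExposureParams = field(default_factory=ExposureParams)
    tox: dict[str, ToxProfile] = field(
        default_factory=lambda: dict(defaults.TOX_PROFILES)
    )
    mc: Optional[MCConfig] = field(default_factory=MCConfig)
    mc_family: str = "lognormal"  # concentration distribution; "point" to disable spread
    convention: str = "paper"

    def __post_init__(self) -> None:
        if (self.survey_path is None) == (self.synthetic is None):
            raise ConfigError(
                "specify exactly one input source: survey_path or synthetic"
            )


@dataclass
class RunReport:
    """Tidy result tables plus a reproducibility manifest."""

    summary: pd.DataFrame
    seasonal_tests: pd.DataFrame
    intakes: pd.DataFrame
    risk: pd.DataFrame
    guidelines: pd.DataFrame
    mcs: pd.DataFrame
    manifest: dict


def _canonical(obj):
    """JSON-serializable, deterministic view of nested config objects."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _canonical(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _canonical(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(_canonical(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage and assemble the report tables.

    Stage errors propagate with the stage name prefixed; degenerate
    seasonal tests (zero-variance differences) are reported as a table row
    with a note rather than aborting the run.
    """
    t0 = time.perf_counter()
    if config.survey_path is not None:
        records = survey.apply_censoring(
            survey.read_survey(config.survey_path), config.censoring
        )
        source = str(config.survey_path)
    else:
        records, _truth = generate_survey(config.synthetic)
        source = f"synthetic(seed={config.synthetic.seed})"
    log.info("ingest: %d records from %s", len(records), source)

    seasonal = survey.summarize(records, group_by=("metal", "season"))
    pooled = survey.summarize(records, group_by=("metal",))
    summary_df = pd.concat(
        [survey.summaries_frame(seasonal), survey.summaries_frame(pooled)],
        ignore_index=True,
    )
    metals = sorted({s.metal for s in seasonal})

    # paired seasonal comparison per metal (brand-mean pairing)
    test_rows = []
    for metal in metals:
        try:
            cmp_res = seasonal_comparison(records, metal)
            test_rows.append(
                {
                    "metal": metal,
                    "n_pairs": cmp_res.n_pairs,
                    "mean_difference": cmp_res.mean_difference,
                    "t": cmp_res.t_statistic,
                    "df": cmp_res.degrees_of_freedom,
                    "p_value": cmp_res.p_value,
                    "significant": cmp_res.significant,
                    "note": "",
                }
            )
        except (DegenerateDataError, PairingError) as exc:
            test_rows.append(
                {
                    "metal": metal,
                    "n_pairs": pd.NA,
                    "mean_difference": pd.NA,
                    "t": pd.NA,
                    "df": pd.NA,
                    "p_value": pd.NA,
                    "significant": pd.NA,
                    "note": str(exc),
                }
            )
    tests_df = pd.DataFrame(test_rows)

    if config.convention == "paper":
        log.warning(
            "paper-convention units active: EDI/EWI/EMI numerals are 1000x "
            "the strictly dimensional µg/kg bw/day values"
        )

    intake_rows, risk_rows, guide_rows = [], [], []
    for metal in metals:
        tox = config.tox.get(metal)
        if tox is None:
            raise ConfigError(f"risk: no ToxProfile configured for metal {metal!r}")
        cells = {s.season: s for s in seasonal if s.metal == metal}
        season_means = {
            name: cells[name].mean
            for name in ("winter", "summer")
            if name in cells
        }
        # the report's "mean" row averages the seasonal means
        season_means["mean"] = survey.mean_of_seasonal_means(seasonal, metal)
        for season, cm in season_means.items():
            est = assess(
                cm, tox, config.exposure, convention=config.convention, season=season
            )
            intake_rows.append(
                {
                    "metal": metal,
                    "season": season,
                    "conc_ugkg": cm,
                    "edi": round_half_up(est.edi, 2),
                    "ewi": round_half_up(est.ewi, 2),
                    "emi": round_half_up(est.emi, 2),
                    "edi_raw": est.edi,
                    "ewi_raw": est.ewi,
                    "emi_raw": est.emi,
                }
            )
            risk_rows.append(
                {
                    "metal": metal,
                    "season": season,
                    "thq": round_sig(est.thq, 2),
                    "thq_raw": est.thq,
                    "thq_class": est.thq_class,
                    "ilcr": None if est.ilcr is None else round_sig(est.ilcr, 3),
                    "ilcr_raw": est.ilcr,
                    "ilcr_class": est.ilcr_class,
                    "note": "" if est.ilcr is not None else "ILCR not computed: CSF unavailable",
                }
            )
            if season == "mean" and tox.ptwi is not None:
                g = compare_guidelines(est.ewi, est.emi, config.exposure, tox)
                guide_rows.append(
                    {
                        "metal": metal,
                        "ewi": est.ewi,
                        "ptwi": tox.ptwi,
                        "ewi_fraction": g.ewi_fraction_of_ptwi,
                        "emi": est.emi,
                        "ptmi": tox.ptmi_effective,
                        "emi_fraction": g.emi_fraction_of_ptmi,
                        "within_limits": g.within_limits,
                    }
                )
    intakes_df = pd.DataFrame(intake_rows)
    risk_df = pd.DataFrame(risk_rows)
    guidelines_df = pd.DataFrame(guide_rows)

    mcs_rows = []
    if config.mc is not None:
        task = 0
        for metal in metals:
            tox = config.tox[metal]
            pool = next(s for s in pooled if s.metal == metal)
            spec = build_distribution(pool, family=config.mc_family)
            for metric in ("THQ", "ILCR"):
                if metric == "ILCR" and tox.csf is None:
                    mcs_rows.append(
                        {
                            "metric": metric,
                            "metal": metal,
                            "note": "not computed: CSF unavailable",
                        }
                    )
                    continue
                cfg = dataclasses.replace(config.mc, seed=config.mc.seed + task)
                task += 1
                res = run_mcs(
                    spec, config.exposure, tox, cfg, metric=metric,
                    convention=config.convention,
                )
                row = summarize_mcs(res)
                row["note"] = ""
                mcs_rows.append(row)
    mcs_df = pd.DataFrame(mcs_rows)

    manifest = {
        "source": source,
        "n_records": len(records),
        "metals": metals,
        "convention": config.convention,
        "mc_seed": None if config.mc is None else config.mc.seed,
        "config_sha256": config_hash(config),
        "elapsed_s": round(time.perf_counter() - t0, 4),
    }
    log.info("pipeline complete: %d metals, %.3f s", len(metals), manifest["elapsed_s"])
    return RunReport(
        summary=summary_df,
        seasonal_tests=tests_df,
        intakes=intakes_df,
        risk=risk_df,
        guidelines=guidelines_df,
        mcs=mcs_df,
        manifest=manifest,
    )


def _stamp(convention: str, units: str) -> str:
    return f"# convention={convention}; {units}\n"


def write_report(
    report: RunReport,
    outdir: str | Path,
    formats: set[str] | None = None,
    convention: str = "paper",
) -> list[Path]:
    """Write the report under ``outdir``; returns the created paths.

    ``formats`` defaults to ``{"csv", "json"}``.  CSVs carry a leading
    ``#`` comment line stamping the unit convention (readable back with
    ``pandas.read_csv(..., comment="#")``); the JSON bundle holds every
    table plus the manifest.  The manifest's elapsed time is excluded from
    the JSON so identical runs serialize identically.
    """
    formats = {"csv", "json"} if formats is None else set(formats)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    csv_tables = {
        "summary.csv": (report.summary, "concentrations µg/kg wet weight"),
        "seasonal_tests.csv": (report.seasonal_tests, "differences winter-summer µg/kg"),
        "intakes.csv": (report.intakes, "EDI per day, EWI per week, EMI per month"),
        "risk.csv": (report.risk, "THQ and ILCR dimensionless"),
        "guidelines.csv": (report.guidelines, "fractions of JECFA PTWI/PTMI"),
        "mcs.csv": (report.mcs, "Monte Carlo summaries, dimensionless metrics"),
    }
    if "csv" in formats:
        for name, (df, units) in csv_tables.items():
            path = outdir / name
            with open(path, "w", encoding="utf-8", newline="") as fh:
                fh.write(_stamp(convention, units))
                df.to_csv(fh, index=False)
            written.append(path)

    if "json" in formats:
        manifest = {k: v for k, v in report.manifest.items() if k != "elapsed_s"}
        bundle = {
            "manifest": manifest,
            "tables": {
                name.removesuffix(".csv"): df.to_dict(orient="records")
                for name, (df, _units) in csv_tables.items()
            },
        }
        path = outdir / "report.json"
        path.write_text(json.dumps(bundle, indent=2, sort_keys=True, default=str))
        written.append(path)
    return written


def load_config(path: str | Path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a TOML file.

    Recognized tables: ``[input]`` (``survey`` path or
    ``[input.synthetic]`` with ``seed``, optional design overrides),
    ``[exposure]``, ``[tox.<metal>]``, ``[censoring]``, ``[mc]``,
    ``[report]`` (``convention``).  Omitted blocks fall back to package
    defaults.
    """
    import tomllib

    raw = tomllib.loads(Path(path).read_text())
    inp = raw.get("input", {})
    survey_path = inp.get("survey")
    synthetic = None
    if "synthetic" in inp:
        syn = dict(inp["synthetic"])
        cens = raw.get("censoring", {})
        kwargs = {
            k: syn[k]
            for k in ("n_brands", "replicates_per_brand", "family", "seed",
                      "brand_effect_sd")
            if k in syn
        }
        if cens:
            kwargs["censoring"] = CensoringRule(**cens)
        synthetic = SyntheticSurveyConfig(**kwargs)
    if (survey_path is None) == (synthetic is None):
        raise ConfigError(f"{path}: [input] must set exactly one of survey/synthetic")

    exposure = ExposureParams(**raw.get("exposure", {}))
    tox = dict(defaults.TOX_PROFILES)
    for metal, block in raw.get("tox", {}).items():
        tox[metal] = ToxProfile(metal=metal, **block)
    censoring = CensoringRule(**raw.get("censoring", {}))
    mc_raw = raw.get("mc", None)
    mc_family = "lognormal"
    mc: Optional[MCConfig] = MCConfig()
    if mc_raw is not None:
        mc_raw = dict(mc_raw)
        if not mc_raw.pop("enabled", True):
            mc = None
        else:
            mc_family = mc_raw.pop("family", "lognormal")
            if "percentiles" in mc_raw:
                mc_raw["percentiles"] = tuple(mc_raw["percentiles"])
            mc = MCConfig(**mc_raw)
    convention = raw.get("report", {}).get("convention", "paper")
    return PipelineConfig(
        survey_path=None if survey_path is None else Path(survey_path),
        synthetic=synthetic,
        censoring=censoring,
        exposure=exposure,
        tox=tox,
        mc=mc,
        mc_family=mc_family,
        convention=convention,
    )
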