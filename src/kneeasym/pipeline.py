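"""End-to-end batch pipeline: exclusions -> datasets -> statistics -> reports.

``run_pipeline`` reads the three cohort tables, applies the baseline
exclusion cascade, assembles the analysis datasets for the requested mode
(baseline knee-level, subject-level asymmetry, longitudinal, or all), runs
the statistics (odds-ratio risk table, covariate-adjusted group
comparisons, demographic Kruskal-Wallis/Dunn tests) and writes tidy CSV
results, a JSON odds-ratio report, the exclusion audit, and a run manifest
(config + versions + seed) sufficient to reproduce every output exactly.
The analysis itself is deterministic; the seed is recorded for the
simulation stage and any downstream bootstrap.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import (
    Cohort,
    ExclusionConfig,
    apply_baseline_exclusions,
    build_asymmetry_dataset,
    build_baseline_knee_dataset,
    build_longitudinal_dataset,
)
from .errors import ConfigError
from .morphometry import MEASURE_FIELDS
from .risk import AsymmetryRiskModel
from .stats import DEFAULT_EXPOSURES, compare_groups_adjusted, kruskal_dunn, mean_ci

__all__ = ["RunConfig", "RunResult", "run_pipeline"]

logger = logging.getLogger("kneeasym")

MODES = ("baseline-knee", "asymmetry", "longitudinal", "all")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    data_dir: str
    out_dir: str
    mode: str = "all"
    seed: int = 0
    exposures: tuple = DEFAULT_EXPOSURES
    exclusions: ExclusionConfig = field(default_factory=ExclusionConfig)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["exposures"] = [e.name for e in self.exposures]
        return d


@dataclass
class RunResult:
    config: RunConfig
    audit: object
    datasets: dict[str, pd.DataFrame]
    risk_results: object | None
    comparisons: pd.DataFrame | None
    out_dir: Path


def _group_comparisons(df: pd.DataFrame, measure_cols, group_col, covar_cols, cluster_col):
    from .errors import InsufficientDataError

    frames = []
    for mcol in measure_cols:
        sub = df[df[mcol].notna()]
        try:
            res = compare_groups_adjusted(
                sub[mcol],
                sub[group_col],
                covariates=sub[list(covar_cols)] if covar_cols else None,
                cluster=sub[cluster_col] if cluster_col else None,
                measure=mcol,
            )
        except InsufficientDataError as exc:
            logger.warning("skipping group comparison for %s: %s", mcol, exc)
            continue
        frames.append(res.to_frame())
    if not frames:
        return pd.DataFrame(
            columns=["measure", "group_a", "group_b", "estimate", "se", "p_raw", "p_adjusted", "method"]
        )
    return pd.concat(frames, ignore_index=True)


def _group_summaries(df: pd.DataFrame, measure_cols, group_col) -> pd.DataFrame:
    rows = []
    for mcol in measure_cols:
        for grp, sub in df.groupby(group_col):
            vals = sub[mcol].dropna()
            if len(vals) < 2:
                continue
            m, lo, hi = mean_ci(vals)
            rows.append(
                {"measure": mcol, "group": grp, "n": len(vals), "mean": m, "ci_low": lo, "ci_high": hi}
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the configured analyses and write the report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("loading cohort from %s", config.data_dir)
    cohort = Cohort.from_dir(config.data_dir)
    filtered, audit = apply_baseline_exclusions(cohort, config.exclusions)
    datasets: dict[str, pd.DataFrame] = {}
    risk_results = None
    comparison_frames = []

    covars = ("age_baseline", "sex", "weight_y0", "height_mm")

    if config.mode in ("baseline-knee", "all"):
        knee_ds = build_baseline_knee_dataset(filtered, audit)
        datasets["baseline_knee"] = knee_ds
        knee_ds.to_csv(out / "baseline_knee_dataset.csv", index=False)
        _group_summaries(knee_ds, MEASURE_FIELDS, "group").to_csv(
            out / "baseline_knee_summaries.csv", index=False
        )
        comp = _group_comparisons(knee_ds, MEASURE_FIELDS, "group", covars, "subject_id")
        comp.insert(0, "analysis", "baseline-knee")
        comparison_frames.append(comp)

    if config.mode in ("asymmetry", "all"):
        asym_ds = build_asymmetry_dataset(filtered, audit)
        datasets["asymmetry"] = asym_ds
        asym_ds.to_csv(out / "asymmetry_dataset.csv", index=False)
        asym_cols = [f"asym_{m}" for m in MEASURE_FIELDS]
        _group_summaries(asym_ds, asym_cols, "group").to_csv(
            out / "asymmetry_summaries.csv", index=False
        )
        comp = _group_comparisons(asym_ds, asym_cols, "group", covars, None)
        comp.insert(0, "analysis", "asymmetry")
        comparison_frames.append(comp)
        demo_rows = []
        from .errors import InsufficientDataError

        for col in ("age_baseline", "height_mm", "weight_y0"):
            try:
                res = kruskal_dunn(asym_ds[col], asym_ds["group"], measure=col)
            except InsufficientDataError as exc:
                logger.warning("skipping demographic test for %s: %s", col, exc)
                continue
            frame = res.to_frame()
            frame["omnibus_p"] = res.omnibus_p
            demo_rows.append(frame)
        if demo_rows:
            pd.concat(demo_rows, ignore_index=True).to_csv(out / "demographics_tests.csv", index=False)
        else:
            (out / "demographics_tests.csv").write_text("")

        model = AsymmetryRiskModel(asym_ds, exposures=config.exposures)
        risk_results = model.fit()
        risk_results.to_json(out / "or_report.json")
        risk_results.to_frame().to_csv(out / "or_table.csv", index=False)

    if config.mode in ("longitudinal", "all"):
        long_ds = build_longitudinal_dataset(filtered, audit)
        datasets["longitudinal"] = long_ds
        long_ds.to_csv(out / "longitudinal_dataset.csv", index=False)
        fu_cols = [f"{m}_fu8" for m in MEASURE_FIELDS]
        _group_summaries(long_ds, fu_cols, "group").to_csv(
            out / "longitudinal_summaries.csv", index=False
        )
        stats_ds = long_ds[long_ds["in_kl34"]].copy()
        stats_ds["group"] = stats_ds["group"].replace({"KL34S": "KL34"})
        for m in MEASURE_FIELDS:
            stats_ds[f"{m}_change"] = stats_ds[f"{m}_fu8"] - stats_ds[f"{m}_baseline"]
        comp = _group_comparisons(
            stats_ds, [f"{m}_change" for m in MEASURE_FIELDS], "group", covars, "subject_id"
        )
        comp.insert(0, "analysis", "longitudinal-change")
        comparison_frames.append(comp)

    comparisons = pd.concat(comparison_frames, ignore_index=True) if comparison_frames else None
    if comparisons is not None:
        comparisons.to_csv(out / "group_comparisons.csv", index=False)

    audit.to_json(out / "audit.json")
    manifest = {
        "package": "kneeasym",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "versions": _versions(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("pipeline complete; outputs in %s", out)
    return RunResult(
        config=config, audit=audit, datasets=datasets,
        risk_results=risk_results, comparisons=comparisons, out_dir=out,
    )


def _versions() -> dict[str, str]:
    import numpy
    import scipy
    import statsmodels

    return {
        "numpy": numpy.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }
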