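"""Threshold-based OA risk analysis as a Model/Results pair.

``AsymmetryRiskModel`` wraps a subject-level dataset (one row per subject
with an ``oa`` outcome flag, demographics and the baseline medial
joint-space asymmetry) and a set of exposure schemes; ``fit()`` tabulates
each exposure category against its reference and returns an
``AsymmetryRiskResults`` carrying the unadjusted odds ratios with Woolf
confidence intervals, a tidy frame, and a text ``summary()`` laid out like
a risk-factor table (variable, category vs reference, OR with CI, cells).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import SchemaError, ZeroCellError
from .stats import (
    DEFAULT_EXPOSURES,
    ExposureScheme,
    OddsRatioResult,
    build_exposure_tables,
    odds_ratio,
)

__all__ = ["AsymmetryRiskModel", "AsymmetryRiskResults"]


class AsymmetryRiskModel:
    """Unadjusted odds-ratio risk model over exposure categories.

    Parameters
    ----------
    data : DataFrame
        Subject-level rows with the outcome column (default ``"oa"``,
        truthy = advanced radiographic OA at follow-up) and every column the
        exposure schemes reference (``sex``, ``age_baseline``,
        ``bmi_baseline``, ``asym_medial_js_mm`` with the defaults).
    exposures : sequence of ExposureScheme, optional
        Defaults to the risk-factor layout: sex (vs male), age >= 60
        (vs < 60), BMI 25-<30 and >= 30 (vs < 25), and cumulative medial JS
        asymmetry thresholds >= 10 / 12.5 / 15 % (vs < 10 %).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        exposures: Sequence[ExposureScheme] | None = None,
        outcome: str = "oa",
    ) -> None:
        self.exposures = tuple(exposures) if exposures is not None else DEFAULT_EXPOSURES
        self.outcome = outcome
        needed = {outcome} | {s.column for s in self.exposures}
        missing = sorted(needed - set(data.columns))
        if missing:
            raise SchemaError(f"risk dataset is missing columns {missing}")
        self.data = data.reset_index(drop=True)

    @classmethod
    def from_cohort(cls, cohort, exposures=None, exclusions=None):
        """Build from raw cohort tables: runs the baseline exclusion cascade
        and the subject-level asymmetry dataset assembly."""
        from .cohort import apply_baseline_exclusions, build_asymmetry_dataset

        filtered, audit = apply_baseline_exclusions(cohort, exclusions)
        dataset = build_asymmetry_dataset(filtered, audit)
        model = cls(dataset, exposures=exposures)
        model.audit = audit
        return model

    def fit(self, alpha: float = 0.05, continuity: bool = False) -> "AsymmetryRiskResults":
        """Tabulate every exposure category and compute OR + Woolf CI.

        Zero-cell categories are reported with a note instead of an
        estimate unless ``continuity`` enables the +0.5 correction.
        """
        rows: list[dict] = []
        for scheme in self.exposures:
            for label, table in build_exposure_tables(self.data, scheme, self.outcome):
                row = {
                    "variable": scheme.name,
                    "category": label,
                    "reference": scheme.reference,
                    "a": table.a,
                    "b": table.b,
                    "c": table.c,
                    "d": table.d,
                    "note": "",
                }
                try:
                    res = odds_ratio(
                        table, alpha=alpha, continuity=continuity,
                        exposure=label, reference=scheme.reference,
                    )
                    row.update(
                        or_point=res.or_point, ci_low=res.ci_low, ci_high=res.ci_high,
                        result=res,
                    )
                except ZeroCellError:
                    row.update(
                        or_point=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
                        result=None, note="zero cell",
                    )
                rows.append(row)
        return AsymmetryRiskResults(model=self, rows=rows, alpha=alpha)


@dataclass
class AsymmetryRiskResults:
    """Fitted odds ratios for every exposure category."""

    model: AsymmetryRiskModel
    rows: list[dict]
    alpha: float

    @property
    def odds_ratios(self) -> list[OddsRatioResult]:
        return [r["result"] for r in self.rows if r["result"] is not None]

    def to_frame(self) -> pd.DataFrame:
        cols = ["variable", "category", "reference", "or_point", "ci_low", "ci_high",
                "a", "b", "c", "d", "note"]
        return pd.DataFrame([{k: r[k] for k in cols} for r in self.rows])

    def to_dict(self) -> dict:
        out: dict = {"alpha": self.alpha, "n": int(len(self.model.data)), "variables": []}
        for variable in dict.fromkeys(r["variable"] for r in self.rows):
            rows = [r for r in self.rows if r["variable"] == variable]
            out["variables"].append(
                {
                    "variable": variable,
                    "reference": rows[0]["reference"],
                    "categories": [
                        {
                            "category": r["category"],
                            "or": r["or_point"],
                            "ci_low": r["ci_low"],
                            "ci_high": r["ci_high"],
                            "cells": {k: r[k] for k in "abcd"},
                            "note": r["note"],
                        }
                        for r in rows
                    ],
                }
            )
        return out

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.to_dict(), indent=1, sort_keys=True, allow_nan=True)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def summary(self) -> str:
        ci_pct = int(round((1 - self.alpha) * 100))
        lines = [
            f"Odds of advanced OA (KL34S) by exposure category, n = {len(self.model.data)}",
            f"{'Variable':<38}{'Category':<14}{'OR (' + str(ci_pct) + ' % CI)':<24}a/b/c/d",
            "-" * 90,
        ]
        for r in self.rows:
            if r["note"]:
                or_txt = f"-- ({r['note']})"
            else:
                or_txt = f"{r['or_point']:.2f} ({r['ci_low']:.2f} - {r['ci_high']:.2f})"
            var = f"{r['variable']} (vs {r['reference']})"
            lines.append(
                f"{var:<38}{r['category']:<14}{or_txt:<24}"
                f"{r['a']}/{r['b']}/{r['c']}/{r['d']}"
            )
        return "\n".join(lines)

    def plot_forest(self, ax=None):
        """Forest plot of the ORs on a log scale (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.5 * len(self.rows) + 1))
        ys, labels = [], []
        for i, r in enumerate(reversed(self.rows)):
            labels.append(f"{r['variable']}: {r['category']}")
            ys.append(i)
            if not r["note"]:
                ax.plot([r["ci_low"], r["ci_high"]], [i, i], "-", color="0.3")
                ax.plot(r["or_point"], i, "s", color="k")
        ax.axvline(1.0, color="0.7", ls="--")
        ax.set_xscale("log")
        ax.set_yticks(ys)
        ax.set_yticklabels(labels)
        ax.set_xlabel("odds ratio (log scale)")
        return ax
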