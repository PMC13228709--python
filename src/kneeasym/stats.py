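"""Statistics: unadjusted odds ratios over exposure categories, adjusted
group comparisons, and the nonparametric demographic tests.

The odds ratio of a 2x2 exposure/outcome table is ``(a*d)/(b*c)`` with the
Woolf (log-normal) confidence interval

    exp( ln OR  +/-  z_{1-alpha/2} * sqrt(1/a + 1/b + 1/c + 1/d) ).

Zero cells are signalled, never silently corrected; the Haldane-Anscombe
+0.5 correction is available behind an explicit flag.  Odds ratios are
deliberately unadjusted (descriptive); no covariate-adjusted OR mode is
offered.

Group comparisons of continuous measures use a linear model of the value on
group and the demographic covariates.  With clustered observations (knees
within subjects; repeated timepoints within knees) a linear mixed model
with random intercepts is fitted; with one observation per cluster the fit
reduces to ordinary least squares, which is used directly.  Pairwise group
contrasts are Bonferroni-adjusted.  Demographics are compared with the
Kruskal-Wallis test followed by Dunn's pairwise test with Bonferroni
correction (implemented here; the z statistic uses the standard
tie-corrected rank variance).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, InvariantError, ModelError, ZeroCellError

__all__ = [
    "ContingencyTable2x2",
    "OddsRatioResult",
    "ExposureScheme",
    "GroupComparisonResult",
    "GroupComparisonResults",
    "odds_ratio",
    "build_exposure_tables",
    "compare_groups_adjusted",
    "kruskal_dunn",
    "mean_ci",
    "DEFAULT_EXPOSURES",
    "AGE_FOUR_LEVEL",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: a = exposed with outcome, b = exposed without, c = unexposed
    with outcome, d = unexposed without."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise InvariantError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class OddsRatioResult:
    """OR point estimate with its Woolf 95% (or 1-alpha) CI and source table."""

    or_point: float
    ci_low: float
    ci_high: float
    table: ContingencyTable2x2
    exposure: str = ""
    reference: str = ""
    alpha: float = 0.05
    continuity: bool = False


def odds_ratio(
    table: ContingencyTable2x2,
    alpha: float = 0.05,
    continuity: bool = False,
    exposure: str = "",
    reference: str = "",
) -> OddsRatioResult:
    """Unadjusted odds ratio with the Woolf log-method confidence interval.

    Raises :class:`ZeroCellError` when any cell is zero, unless
    ``continuity`` enables the Haldane-Anscombe +0.5 correction.
    """
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    if min(a, b, c, d) == 0.0:
        if not continuity:
            raise ZeroCellError(f"zero cell in table {table}; OR/CI undefined without correction")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_point = (a * d) / (b * c)
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    log_or = math.log(or_point)
    return OddsRatioResult(
        or_point=or_point,
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        table=table,
        exposure=exposure,
        reference=reference,
        alpha=alpha,
        continuity=continuity,
    )


# ---------------------------------------------------------------------------
# exposure schemes (Table-2-style layout)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExposureScheme:
    """How one variable is split into exposed categories vs a reference.

    kinds:

    * ``categorical`` — label column; every entry of ``categories`` is
      compared against the ``reference`` label.
    * ``bins`` — numeric column cut into half-open intervals ``[lo, hi)``;
      ``categories`` holds ``(label, lo, hi)`` and ``reference_bin`` the
      reference interval.
    * ``cumulative`` — numeric column with inclusive thresholds
      (``(label, t)``: exposed iff ``x >= t``); the reference is always
      ``x < reference_upper``, so the cumulative categories deliberately
      overlap while the reference stays fixed.
    """

    name: str
    column: str
    kind: str
    reference: str
    categories: tuple = ()
    reference_bin: tuple[float, float] | None = None
    reference_upper: float | None = None
    scale: float = 1.0  # applied to the column before binning (e.g. fraction -> %)

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "bins", "cumulative"):
            raise InvariantError(f"unknown exposure kind {self.kind!r}")
        if self.kind == "bins" and self.reference_bin is None:
            raise InvariantError("bins scheme requires reference_bin")
        if self.kind == "cumulative" and self.reference_upper is None:
            raise InvariantError("cumulative scheme requires reference_upper")


DEFAULT_EXPOSURES: tuple[ExposureScheme, ...] = (
    ExposureScheme(
        name="Sex", column="sex", kind="categorical", reference="Male",
        categories=(("Female", "female"),),
    ),
    ExposureScheme(
        name="Age (years)", column="age_baseline", kind="bins", reference="< 60",
        categories=(("≥ 60", 60.0, math.inf),), reference_bin=(-math.inf, 60.0),
    ),
    ExposureScheme(
        name="BMI (kg m^-2)", column="bmi_baseline", kind="bins", reference="< 25",
        categories=(("25 to < 30", 25.0, 30.0), ("≥ 30", 30.0, math.inf)),
        reference_bin=(-math.inf, 25.0),
    ),
    ExposureScheme(
        name="Medial JS asymmetry (%)", column="asym_medial_js_mm", kind="cumulative",
        reference="< 10.0",
        categories=(("≥ 10.0", 10.0), ("≥ 12.5", 12.5), ("≥ 15.0", 15.0)),
        reference_upper=10.0, scale=100.0,
    ),
)

#: Finer age split (<50 reference, 50-54, 55-59, >=60).
AGE_FOUR_LEVEL = ExposureScheme(
    name="Age (years)", column="age_baseline", kind="bins", reference="< 50",
    categories=(("50–54", 50.0, 55.0), ("55–59", 55.0, 60.0), ("≥ 60", 60.0, math.inf)),
    reference_bin=(-math.inf, 50.0),
)


def build_exposure_tables(
    dataset: pd.DataFrame,
    scheme: ExposureScheme,
    outcome_col: str = "oa",
) -> list[tuple[str, ContingencyTable2x2]]:
    """One 2x2 table per non-reference category of the scheme.

    Threshold categories are inclusive (a value exactly on a cumulative
    threshold is exposed) and the cumulative reference is fixed at
    ``x < reference_upper`` for every threshold.
    """
    outcome = dataset[outcome_col].astype(bool).to_numpy()
    tables: list[tuple[str, ContingencyTable2x2]] = []

    def tab(exp_mask: np.ndarray, ref_mask: np.ndarray, label: str) -> None:
        tables.append(
            (
                label,
                ContingencyTable2x2(
                    a=int((exp_mask & outcome).sum()),
                    b=int((exp_mask & ~outcome).sum()),
                    c=int((ref_mask & outcome).sum()),
                    d=int((ref_mask & ~outcome).sum()),
                ),
            )
        )

    if scheme.kind == "categorical":
        col = dataset[scheme.column].astype(str).str.lower().to_numpy()
        ref_mask = col == scheme.reference.lower()
        for label, value in scheme.categories:
            tab(col == str(value).lower(), ref_mask, label)
    else:
        x = dataset[scheme.column].to_numpy(dtype=float) * scheme.scale
        if scheme.kind == "bins":
            lo, hi = scheme.reference_bin
            ref_mask = (x >= lo) & (x < hi)
            for label, blo, bhi in scheme.categories:
                tab((x >= blo) & (x < bhi), ref_mask, label)
        else:  # cumulative
            ref_mask = x < scheme.reference_upper
            for label, t in scheme.categories:
                tab(x >= t, ref_mask, label)
    return tables


# ---------------------------------------------------------------------------
# adjusted group comparisons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparisonResult:
    measure: str
    group_a: str
    group_b: str
    estimate: float
    se: float
    p_raw: float
    p_adjusted: float
    method: str


@dataclass
class GroupComparisonResults:
    results: list[GroupComparisonResult]
    omnibus_p: float | None = None
    method: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.results])


def _design(groups: pd.Series, covariates: pd.DataFrame | None):
    levels = sorted(pd.unique(groups.astype(str)))
    if len(levels) < 2:
        raise InsufficientDataError("need at least two groups")
    g = pd.get_dummies(pd.Categorical(groups.astype(str), categories=levels), drop_first=True)
    g.columns = [f"group[{c}]" for c in levels[1:]]
    parts = [pd.Series(1.0, index=g.index, name="const"), g.astype(float)]
    if covariates is not None:
        cov = covariates.reset_index(drop=True)
        for col in cov.columns:
            if cov[col].dtype == object or isinstance(cov[col].dtype, pd.CategoricalDtype):
                dummies = pd.get_dummies(cov[col].astype(str), prefix=col, drop_first=True)
                parts.append(dummies.astype(float))
            else:
                parts.append(cov[col].astype(float))
    X = pd.concat(parts, axis=1)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the first column whose removal restores full rank
        for col in X.columns[::-1]:
            sub = X.drop(columns=[col])
            if np.linalg.matrix_rank(sub.to_numpy()) == rank:
                raise ModelError(f"singular design: column {col!r} is collinear")
        raise ModelError("singular design matrix")
    return X, levels


def compare_groups_adjusted(
    values: Sequence[float],
    groups: Sequence[str],
    covariates: pd.DataFrame | None = None,
    cluster: Sequence | None = None,
    knee: Sequence | None = None,
    alpha: float = 0.05,
    measure: str = "",
) -> GroupComparisonResults:
    """Covariate-adjusted pairwise group contrasts.

    Fits ``value ~ group + covariates`` with random intercepts per
    ``cluster`` (subject) and, when ``knee`` ids are supplied for
    longitudinal data, per knee within subject.  With at most one
    observation per cluster the mixed model is degenerate and the fit is the
    ordinary-least-squares one (the two coincide there).  Pairwise contrasts
    are Bonferroni-adjusted over the number of group pairs.
    """
    import statsmodels.api as sm

    y = pd.Series(np.asarray(values, dtype=float)).reset_index(drop=True)
    groups = pd.Series(list(groups)).reset_index(drop=True)
    X, levels = _design(groups, covariates)

    use_mixed = cluster is not None and pd.Series(list(cluster)).duplicated().any()
    if use_mixed:
        import statsmodels.formula.api as smf

        df = X.copy()
        df["_y"] = y.to_numpy()
        df["_cluster"] = list(cluster)
        vc = None
        if knee is not None:
            df["_knee"] = [str(k) for k in knee]
            vc = {"knee": "0 + C(_knee)"}
        rhs = " + ".join(f"Q('{c}')" for c in X.columns if c != "const") or "1"
        model = smf.mixedlm(
            f"_y ~ {rhs}", df, groups=df["_cluster"], re_formula="1", vc_formula=vc
        )
        try:
            fit = model.fit(reml=False)
        except np.linalg.LinAlgError:
            fit = model.fit(reml=False, method="cg")
        param_names = list(fit.fe_params.index)

        def coef_index(col):
            return param_names.index("Intercept" if col == "const" else f"Q('{col}')")

        params = fit.fe_params.to_numpy()
        cov_params = fit.cov_params().to_numpy()[: len(param_names), : len(param_names)]
        method = "mixed-model"
    else:
        fit = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
        params = fit.params
        cov_params = fit.cov_params()

        def coef_index(col):
            return list(X.columns).index(col)

        method = "ols"

    pairs = list(itertools.combinations(levels, 2))
    k = len(pairs)
    results = []
    ref = levels[0]
    p_dim = len(params)
    for ga, gb in pairs:
        L = np.zeros(p_dim)
        if ga != ref:
            L[coef_index(f"group[{ga}]")] -= 1.0
        if gb != ref:
            L[coef_index(f"group[{gb}]")] += 1.0
        est = float(L @ params)
        se = float(math.sqrt(L @ cov_params @ L))
        if se == 0.0:
            raise ModelError(f"degenerate contrast {ga} vs {gb}")
        if method == "ols":
            dof = fit.df_resid
            p = 2.0 * sps.t.sf(abs(est / se), dof)
        else:
            p = 2.0 * sps.norm.sf(abs(est / se))
        results.append(
            GroupComparisonResult(
                measure=measure, group_a=ga, group_b=gb, estimate=est, se=se,
                p_raw=float(p), p_adjusted=float(min(1.0, p * k)), method=method,
            )
        )
    return GroupComparisonResults(results=results, method=method)


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn-Bonferroni
# ---------------------------------------------------------------------------

def kruskal_dunn(
    values: Sequence[float],
    groups: Sequence[str],
    alpha: float = 0.05,
    measure: str = "",
) -> GroupComparisonResults:
    """Kruskal-Wallis omnibus test with Dunn pairwise z tests,
    Bonferroni-adjusted (``p_adjusted = min(1, p * n_pairs)``)."""
    y = np.asarray(values, dtype=float)
    g = np.asarray(list(groups))
    levels = sorted(pd.unique(g))
    if len(levels) < 2:
        raise InsufficientDataError("need at least two groups")
    samples = [y[g == lev] for lev in levels]
    if any(len(s) < 2 for s in samples):
        raise InsufficientDataError("each group needs at least two observations")

    if len(np.unique(y)) == 1:
        omnibus_p = 1.0  # all observations identical: no evidence, by convention
    else:
        omnibus_p = float(sps.kruskal(*samples).pvalue)

    n = len(y)
    ranks = sps.rankdata(y)
    mean_ranks = {lev: float(ranks[g == lev].mean()) for lev in levels}
    sizes = {lev: int((g == lev).sum()) for lev in levels}
    _, tie_counts = np.unique(y, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))

    pairs = list(itertools.combinations(levels, 2))
    k = len(pairs)
    results = []
    for ga, gb in pairs:
        diff = mean_ranks[gb] - mean_ranks[ga]
        se = math.sqrt(var_base * (1.0 / sizes[ga] + 1.0 / sizes[gb]))
        if se == 0.0:
            p = 1.0
            z = 0.0
        else:
            z = diff / se
            p = 2.0 * sps.norm.sf(abs(z))
        results.append(
            GroupComparisonResult(
                measure=measure, group_a=ga, group_b=gb, estimate=diff, se=se,
                p_raw=float(p), p_adjusted=float(min(1.0, p * k)), method="kruskal-dunn",
            )
        )
    return GroupComparisonResults(results=results, omnibus_p=omnibus_p, method="kruskal-dunn")


def mean_ci(values: Sequence[float], alpha: float = 0.05) -> tuple[float, float, float]:
    """Mean with its normal-approximation CI (mean +/- z * SE), as used for
    the figure-style group summaries."""
    y = np.asarray(values, dtype=float)
    if len(y) < 2:
        raise InsufficientDataError("mean_ci needs at least two values")
    m = float(y.mean())
    se = float(y.std(ddof=1) / math.sqrt(len(y)))
    z = float(sps.norm.ppf(1.0 - alpha / 2.0))
    return m, m - z * se, m + z * se
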