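"""Comparative analyses across groups of species.

Per-group allometry-form fits, ANCOVA interaction tests, the data-source
split analysis with its high-RTD frequency comparison, and the outlier
exclusion rule.  The interaction tests replace a REML linear mixed model
with an OLS ANCOVA F-test (study carried as a fixed blocking factor when
requested); only the interaction p-values feed downstream decisions, and
every report carries a ``method`` field naming the substitution.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .regression import NonlinearFit, nls_allometric_fit

__all__ = [
    "GroupFitReport",
    "InteractionTest",
    "DataSourceReport",
    "fit_by_group",
    "interaction_test",
    "data_source_analysis",
    "exclude_outliers",
    "split_correlations",
]

MIN_GROUP_N = 10
ANCOVA_METHOD = "OLS ANCOVA interaction F-test (fixed-effects substitution)"


@dataclass(frozen=True)
class InteractionTest:
    f_statistic: float
    p_value: float
    df_num: int
    df_den: int
    factor: str
    method: str = ANCOVA_METHOD

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class GroupFitReport:
    grouping: str
    response: str
    fits: dict[str, NonlinearFit]
    skipped: dict[str, int]  # level -> n, for levels below MIN_GROUP_N
    interaction: InteractionTest | None
    n_analyzed: int
    n_excluded: int = 0

    def r2_table(self) -> pd.DataFrame:
        rows = [
            {"level": lvl, "r2": f.r2, "n": f.n, "converged": f.converged}
            for lvl, f in self.fits.items()
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "grouping": self.grouping,
            "response": self.response,
            "fits": {k: f.to_dict() for k, f in self.fits.items()},
            "skipped": self.skipped,
            "interaction": self.interaction.to_dict() if self.interaction else None,
            "n_analyzed": self.n_analyzed,
            "n_excluded": self.n_excluded,
        }


@dataclass(frozen=True)
class DataSourceReport:
    fits: dict[str, dict[str, NonlinearFit]]  # response -> class -> fit
    high_rtd_threshold: float
    high_rtd_frequency: dict[str, float]
    frequency_gap: float  # correlated minus uncorrelated
    r2_ordering_holds: dict[str, bool]  # response -> correlated R2 > uncorrelated

    def to_dict(self) -> dict:
        return {
            "fits": {
                resp: {cls: f.to_dict() for cls, f in by_cls.items()}
                for resp, by_cls in self.fits.items()
            },
            "high_rtd_threshold": self.high_rtd_threshold,
            "high_rtd_frequency": self.high_rtd_frequency,
            "frequency_gap": self.frequency_gap,
            "r2_ordering_holds": self.r2_ordering_holds,
        }


def _complete(table: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    return table.dropna(subset=cols)


def fit_by_group(
    table: pd.DataFrame,
    y: str,
    grouping: str,
    x: str = "diameter",
    min_n: int = MIN_GROUP_N,
    with_interaction: bool = True,
) -> GroupFitReport:
    """Allometry-form NLS of ``y`` on ``x`` within each level of a factor.

    Levels with fewer than ``min_n`` complete records are listed as
    skipped, not fitted.  When at least two levels are fitted, an ANCOVA
    interaction F-test (slope heterogeneity) accompanies the fits.
    """
    if grouping not in table.columns:
        raise KeyError(f"unknown grouping column {grouping!r}")
    data = _complete(table, [x, y, grouping])
    fits: dict[str, NonlinearFit] = {}
    skipped: dict[str, int] = {}
    fitted_levels = []
    for level, sub in data.groupby(grouping, sort=True):
        if len(sub) < min_n:
            skipped[str(level)] = len(sub)
            continue
        fits[str(level)] = nls_allometric_fit(sub[x], sub[y])
        fitted_levels.append(level)
    interaction = None
    if with_interaction and len(fitted_levels) >= 2:
        sub = data[data[grouping].isin(fitted_levels)]
        interaction = interaction_test(sub, y=y, x=x, factor=grouping)
    return GroupFitReport(
        grouping=grouping,
        response=y,
        fits=fits,
        skipped=skipped,
        interaction=interaction,
        n_analyzed=len(data),
        n_excluded=len(table) - len(data),
    )


def interaction_test(
    table: pd.DataFrame,
    y: str,
    factor: str,
    x: str = "diameter",
    covariates: list[str] | None = None,
) -> InteractionTest:
    """F-test of slope heterogeneity: ``y ~ x + factor`` vs ``y ~ x * factor``.

    Additional covariates (e.g. climatic zone, study) enter both models
    additively.  Requires >= 2 factor levels with >= 3 records each.
    """
    covariates = covariates or []
    data = _complete(table, [x, y, factor] + covariates).copy()
    counts = data[factor].value_counts()
    if len(counts) < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 levels")
    if (counts < 3).any():
        small = counts[counts < 3].index.tolist()
        raise ValueError(f"levels with n < 3 in {factor!r}: {small}")
    extra = "".join(f" + C(Q('{c}'))" for c in covariates)
    base = smf.ols(
        f"Q('{y}') ~ Q('{x}') + C(Q('{factor}')){extra}", data=data
    ).fit()
    full = smf.ols(
        f"Q('{y}') ~ Q('{x}') * C(Q('{factor}')){extra}", data=data
    ).fit()
    if np.linalg.matrix_rank(full.model.exog) < full.model.exog.shape[1]:
        raise ValueError("rank-deficient interaction design")
    comparison = anova_lm(base, full)
    f_stat = float(comparison["F"].iloc[1])
    p_val = float(comparison["Pr(>F)"].iloc[1])
    return InteractionTest(
        f_statistic=f_stat,
        p_value=p_val,
        df_num=int(comparison["df_diff"].iloc[1]),
        df_den=int(full.df_resid),
        factor=factor,
    )


def data_source_analysis(
    table: pd.DataFrame,
    responses: tuple[str, ...] = ("RTD", "RN"),
    x: str = "diameter",
    rtd_threshold: float | None = None,
) -> DataSourceReport:
    """Split fits and the high-RTD frequency comparison by data source.

    Fits the allometry-form curve for each response within each
    data-source class, and compares the frequency of high-RTD records
    (RTD above ``rtd_threshold``, defaulting to the mean RTD of the
    analyzed records) between the classes.  The report records whether
    the correlated class fits better (higher R²) for each response.
    """
    if "data_source_class" not in table.columns:
        raise ValueError("data_source_class column is missing")
    classes = ["correlated", "uncorrelated"]
    present = set(table["data_source_class"].dropna().unique())
    missing = [c for c in classes if c not in present]
    if missing:
        raise ValueError(f"data-source class absent from table: {missing}")
    rtd = table["RTD"].dropna()
    threshold = float(rtd.mean()) if rtd_threshold is None else rtd_threshold
    freq = {}
    for cls in classes:
        sub = table[table["data_source_class"] == cls]["RTD"].dropna()
        freq[cls] = float((sub > threshold).mean()) if len(sub) else 0.0
    fits: dict[str, dict[str, NonlinearFit]] = {}
    ordering: dict[str, bool] = {}
    for resp in responses:
        fits[resp] = {}
        for cls in classes:
            sub = _complete(table[table["data_source_class"] == cls], [x, resp])
            fits[resp][cls] = nls_allometric_fit(sub[x], sub[resp])
        ordering[resp] = fits[resp]["correlated"].r2 > fits[resp]["uncorrelated"].r2
    return DataSourceReport(
        fits=fits,
        high_rtd_threshold=threshold,
        high_rtd_frequency=freq,
        frequency_gap=freq["correlated"] - freq["uncorrelated"],
        r2_ordering_holds=ordering,
    )


def exclude_outliers(
    table: pd.DataFrame,
    columns: tuple[str, ...] = ("RN", "PRS"),
    k: float = 4.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop records beyond ``k`` interquartile ranges from a column median.

    The rule emulates the by-hand exclusion of wild literature records
    (one exceptionally high RN, one exceptionally high PRS) with a
    reproducible criterion.  Applied only at the PRS-relationship stage.
    Returns ``(kept, exclusion_log)``; the log lists species, column and
    offending value, and ``len(kept) + len(log) == len(table)`` always.
    """
    mask = pd.Series(False, index=table.index)
    reasons: dict = {}
    for col in columns:
        if col not in table.columns:
            continue
        vals = table[col]
        finite = vals.dropna()
        if len(finite) < 4:
            continue
        q1, med, q3 = finite.quantile([0.25, 0.5, 0.75])
        iqr = q3 - q1
        if iqr == 0:
            continue
        out = (vals - med).abs() > k * iqr
        out = out.fillna(False)
        for idx in table.index[out & ~mask]:
            reasons[idx] = (col, float(vals.loc[idx]))
        mask |= out
    log_rows = [
        {
            "species": table.loc[idx, "species"] if "species" in table else str(idx),
            "column": col,
            "value": val,
            "rule": f"|value - median| > {k} IQR",
        }
        for idx, (col, val) in sorted(reasons.items())
    ]
    log = pd.DataFrame(log_rows, columns=["species", "column", "value", "rule"])
    kept = table[~mask]
    assert len(kept) + len(log) == len(table)
    return kept, log


def split_correlations(
    table: pd.DataFrame, x: str = "diameter", y: str = "RTD"
) -> dict[str, float]:
    """|Pearson r| on the steep (x < median) vs flat (x >= median) halves.

    For any monotone convex decreasing relationship, restricting the
    sample to its flat region attenuates the correlation magnitude — the
    sampling-bias mechanism behind conflicting literature reports.
    """
    data = _complete(table, [x, y])
    med = data[x].median()
    lo = data[data[x] < med]
    hi = data[data[x] >= med]
    out = {"full": float(abs(data[x].corr(data[y])))}
    out["steep_half"] = float(abs(lo[x].corr(lo[y]))) if len(lo) > 2 else float("nan")
    out["flat_half"] = float(abs(hi[x].corr(hi[y]))) if len(hi) > 2 else float("nan")
    return out
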