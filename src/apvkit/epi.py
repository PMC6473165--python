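"""Prevalence estimation and binomial-GLM comparisons.

Prevalence is the percentage of virus-positive individuals over the total
number of individuals tested (individuals, not swabs: repeated samples of
one bird collapse to a single row, positive if any sample was positive).
Group comparisons use a binomial GLM with a single categorical predictor;
the test statistic is the deviance (likelihood-ratio) chi-square
G = 2*sum o*ln(o/e), which is exactly the statistic the printed values in
the source count tables reproduce.

Two independent routes to the deviance are provided: :func:`lr_test`
computes the G statistic directly from the level-by-status table, while
:func:`fit_binomial_glm` fits the GLM by IRLS (statsmodels) and reports the
null-minus-residual deviance; the two agree to numerical precision.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2
from statsmodels.stats.proportion import proportion_confint


@dataclass
class CohortTable:
    """Individuals x categorical covariates x virus status."""

    df: pd.DataFrame  # columns: individual, <factors...>, status

    def __post_init__(self) -> None:
        cols = set(self.df.columns)
        if "individual" not in cols or "status" not in cols:
            raise ValueError("cohort table needs 'individual' and 'status' columns")
        bad = set(self.df["status"]) - {"positive", "negative"}
        if bad:
            raise ValueError(f"bad status values: {sorted(bad)}")
        if self.df["individual"].duplicated().any():
            self.df = collapse_individuals(self.df)

    @classmethod
    def from_tsv(cls, path) -> "CohortTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def counts_by(self, factor: str) -> tuple[list[str], np.ndarray, np.ndarray]:
        """Per-level (positives, totals) in first-appearance level order."""
        if factor not in self.df.columns:
            raise ValueError(f"unknown factor {factor!r}")
        levels = list(dict.fromkeys(self.df[factor]))
        ks, ns = [], []
        for lv in levels:
            sub = self.df[self.df[factor] == lv]
            ks.append(int((sub["status"] == "positive").sum()))
            ns.append(len(sub))
        return levels, np.array(ks), np.array(ns)


def collapse_individuals(df: pd.DataFrame) -> pd.DataFrame:
    """One row per individual; positive if any of its samples is positive."""
    any_pos = (
        df.assign(_pos=df["status"] == "positive")
        .groupby("individual", sort=False)["_pos"]
        .any()
    )
    out = df.drop_duplicates("individual", keep="first").copy()
    out["status"] = out["individual"].map(
        lambda i: "positive" if any_pos[i] else "negative"
    )
    return out.reset_index(drop=True)


@dataclass
class PrevalenceEstimate:
    k: int
    n: int
    pct: float
    ci95: tuple[float, float]


@dataclass
class GlmTestResult:
    df: int
    chi2: float
    p: float
    method: str = "deviance_lr"


@dataclass
class GlmFit:
    levels: list[str]
    fitted: np.ndarray  # fitted proportion per level
    deviance: float  # residual deviance
    null_deviance: float
    boundary: list[str]  # levels with k=0 or k=n (coefficient at infinity)


def prevalence(k: int, n: int) -> PrevalenceEstimate:
    """Point prevalence (1 decimal) with a Wilson 95% interval."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    # half-up to 1 decimal (13/16 -> 81.3, not banker's 81.2)
    pct = math.floor(1000.0 * k / n + 0.5) / 10.0
    return PrevalenceEstimate(k, n, pct, (100.0 * lo, 100.0 * hi))


# ---------------------------------------------------------------------------
# Deviance (G) test — direct route
# ---------------------------------------------------------------------------

def g_statistic(ks, ns) -> float:
    """2*sum o*ln(o/e) over the level-by-status table; zero cells contribute 0."""
    ks = np.asarray(ks, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if np.any(ns < 1) or np.any(ks < 0) or np.any(ks > ns):
        raise ValueError("invalid counts")
    p = ks.sum() / ns.sum()
    g = 0.0
    for k, n in zip(ks, ns):
        for o, e in ((k, n * p), (n - k, n * (1.0 - p))):
            if o > 0:
                g += 2.0 * o * math.log(o / e)
    return g


def lr_test_from_counts(ks, ns) -> GlmTestResult:
    ks = np.asarray(ks)
    if len(ks) < 2:
        raise ValueError("need >= 2 levels")
    g = g_statistic(ks, ns)
    df = len(ks) - 1
    return GlmTestResult(df=df, chi2=g, p=float(chi2.sf(g, df)))


def lr_test(table: CohortTable, factor: str) -> GlmTestResult:
    """Deviance chi-square for a single categorical predictor."""
    _, ks, ns = table.counts_by(factor)
    return lr_test_from_counts(ks, ns)


# ---------------------------------------------------------------------------
# GLM route (IRLS, logit link)
# ---------------------------------------------------------------------------

def fit_binomial_glm(table: CohortTable, factor: str) -> GlmFit:
    """Binomial GLM with one categorical predictor.

    With a single factor the model is saturated in levels, so the fitted
    proportions equal the observed k/n exactly; separated levels (k=0 or
    k=n) keep that property and are reported as boundary cases.
    """
    levels, ks, ns = table.counts_by(factor)
    if len(levels) < 2:
        raise ValueError("need >= 2 levels")
    endog = np.column_stack([ks, ns - ks]).astype(float)
    X = np.zeros((len(levels), len(levels)))
    X[:, 0] = 1.0
    for i in range(1, len(levels)):
        X[i, i] = 1.0
    with warnings.catch_warnings():
        # separated levels are expected (0% or 100% groups); fitted
        # proportions still equal k/n and are all we report
        warnings.simplefilter("ignore")
        fit = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
        null = sm.GLM(endog, np.ones((len(levels), 1)), family=sm.families.Binomial()).fit()
    boundary = [lv for lv, k, n in zip(levels, ks, ns) if k == 0 or k == n]
    return GlmFit(
        levels=levels,
        fitted=np.asarray(fit.fittedvalues, dtype=float),
        deviance=float(fit.deviance),
        null_deviance=float(null.deviance),
        boundary=boundary,
    )


# ---------------------------------------------------------------------------
# Packaged count fixtures (survey count tables and in-text comparisons)
# ---------------------------------------------------------------------------

#: species-level screening counts: species -> (positives, individuals tested)
SURVEY_COUNTS: dict[str, tuple[int, int]] = {
    "atlantic_puffin": (5, 51),
    "common_murre": (0, 41),
    "thick_billed_murre": (0, 2),
    "razorbill": (0, 30),
    "american_herring_gull": (16, 94),
    "great_black_backed_gull": (1, 38),
    "iceland_gull": (0, 4),
    "ring_billed_gull": (0, 9),
    "black_legged_kittiwake": (13, 16),
    "mallard": (1, 10),
    "american_black_duck": (30, 102),
    "black_duck_x_mallard": (1, 4),
}

#: in-text group comparisons: name -> (levels, positives, totals)
COMPARISON_TABLES: dict[str, tuple[list[str], list[int], list[int]]] = {
    # duck seasonality: late winter/early spring vs fall
    "duck_season": (["feb_may", "sep_nov"], [23, 9], [41, 72]),
    # positivity across the four gull species
    "gull_species": (
        ["american_herring", "great_black_backed", "iceland", "ring_billed"],
        [16, 1, 0, 0],
        [94, 38, 4, 9],
    ),
    # herring-gull age groups, reconstructed from the printed percentages
    # (24.1% of 29 juveniles = 7; 13.8% of 65 adults = 9)
    "herring_gull_age": (["juvenile", "adult"], [7, 9], [29, 65]),
    # puffin sampling locations
    "puffin_location": (["witless_bay", "gannet_islands"], [2, 3], [9, 42]),
}


def comparison_cohort(name: str) -> CohortTable:
    """Materialize a packaged comparison as an individual-level cohort."""
    levels, ks, ns = COMPARISON_TABLES[name]
    rows = []
    i = 0
    for lv, k, n in zip(levels, ks, ns):
        for j in range(n):
            rows.append(
                {
                    "individual": f"{name}-{i}",
                    "group": lv,
                    "status": "positive" if j < k else "negative",
                }
            )
            i += 1
    return CohortTable(pd.DataFrame(rows))
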