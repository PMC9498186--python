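"""Cohort-level statistics: per-group summaries, a four-test normality
battery, routed parametric/non-parametric two-sample comparisons, and the
Pearson χ² test for categorical composition.

Routing rule: a two-sample comparison runs Welch's t-test when both samples
pass the Shapiro–Wilk gate at the chosen α, otherwise the two-sided
Mann–Whitney U test. The other three normality tests (Anderson–Darling,
D'Agostino–Pearson, Kolmogorov–Smirnov/Lilliefors) are reported but do not
gate. Raw p-values only — no multiple-testing adjustment is applied.
"""
from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors, normal_ad

from .errors import DegenerateSampleError, InputError

#: Image counts per diagnosis group as enrolled in the source cohort.
STUDY_IMAGE_COUNTS = {"SCN": 30, "Non-SCN": 81, "Pseudocyst": 59}

#: Patient counts per diagnosis group.
STUDY_PATIENT_COUNTS = {"SCN": 11, "Non-SCN": 32, "Pseudocyst": 32}

#: Female/male patient counts per group (columns SCN, Non-SCN, Pseudocyst) —
#: the cohort's gender composition table.
STUDY_GENDER_TABLE = pd.DataFrame(
    [[9, 23, 20], [2, 9, 12]],
    index=["female", "male"],
    columns=["SCN", "Non-SCN", "Pseudocyst"],
)

#: Minimum sample size for which all four normality tests are defined.
MIN_NORMALITY_N = 8


@dataclasses.dataclass(frozen=True)
class NormalityReport:
    """Statistics and p-values of the four-test normality battery.

    ``verdict`` is True when the gate test (Shapiro–Wilk) does not reject at
    level ``alpha``; the other three tests are informational.
    """

    shapiro_wilk: tuple[float, float]
    dagostino_pearson: tuple[float, float]
    anderson_darling: tuple[float, float]
    kolmogorov_smirnov: tuple[float, float]
    alpha: float
    verdict: bool


@dataclasses.dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    name: str
    statistic: float
    p_value: float
    significant: bool
    route: str  # "parametric" | "nonparametric" | "categorical"
    alpha: float = 0.05
    df: Optional[float] = None


@dataclasses.dataclass(frozen=True)
class GroupSummary:
    """Per-group descriptive summary of one metric (sem = sd/√n)."""

    group: str
    metric: str
    n: int
    mean: float
    sd: float
    sem: float


def normality_battery(sample: Sequence[float], alpha: float = 0.05) -> NormalityReport:
    """Run all four normality tests on one sample.

    Requires n ≥ 8 (the smallest n for which every test in the battery is
    defined) and a non-constant sample. The Kolmogorov–Smirnov entry is the
    Lilliefors variant (normal with estimated parameters), the form
    implemented by mainstream statistics packages for composite normality.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < MIN_NORMALITY_N:
        raise InputError(f"normality battery requires n >= {MIN_NORMALITY_N}, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateSampleError("normality undefined for a constant sample")
    sw_stat, sw_p = sps.shapiro(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dp_stat, dp_p = sps.normaltest(x)
        ad_stat, ad_p = normal_ad(x)
        ks_stat, ks_p = lilliefors(x, dist="norm")
    return NormalityReport(
        shapiro_wilk=(float(sw_stat), float(sw_p)),
        dagostino_pearson=(float(dp_stat), float(dp_p)),
        anderson_darling=(float(ad_stat), float(ad_p)),
        kolmogorov_smirnov=(float(ks_stat), float(ks_p)),
        alpha=alpha,
        verdict=bool(sw_p >= alpha),
    )


def _is_normal(x: np.ndarray, alpha: float) -> bool:
    """Gate verdict with the small-sample / degenerate fallbacks.

    Samples too small for the battery, or constant samples, are routed to
    the non-parametric branch with a warning.
    """
    if x.size < MIN_NORMALITY_N:
        warnings.warn(
            f"sample of n={x.size} too small for the normality battery; "
            "routing non-parametric",
            stacklevel=3,
        )
        return False
    if np.ptp(x) == 0:
        return False
    return normality_battery(x, alpha=alpha).verdict


def compare_two_samples(a, b, alpha: float = 0.05) -> TestResult:
    """Two-sample comparison with the normality-gated route.

    Both samples normal → Welch's (unequal-variance) independent t-test;
    otherwise → two-sided Mann–Whitney U (exact for small tie-free samples,
    normal approximation with tie correction otherwise).
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InputError("compare_two_samples requires n >= 2 in each sample")
    if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
        # identical constants: no evidence of a difference, U at its midpoint
        return TestResult(
            name="mann-whitney-u",
            statistic=x.size * y.size / 2.0,
            p_value=1.0,
            significant=False,
            route="nonparametric",
            alpha=alpha,
        )
    if _is_normal(x, alpha) and _is_normal(y, alpha):
        stat, p = sps.ttest_ind(x, y, equal_var=False)
        # Welch–Satterthwaite degrees of freedom
        vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
        df = (vx + vy) ** 2 / (vx**2 / (x.size - 1) + vy**2 / (y.size - 1))
        return TestResult(
            name="welch-t",
            statistic=float(stat),
            p_value=float(p),
            significant=bool(p < alpha),
            route="parametric",
            alpha=alpha,
            df=float(df),
        )
    stat, p = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return TestResult(
        name="mann-whitney-u",
        statistic=float(stat),
        p_value=float(p),
        significant=bool(p < alpha),
        route="nonparametric",
        alpha=alpha,
    )


def chi_square_counts(table, alpha: float = 0.05) -> TestResult:
    """Pearson χ² test on an r×c contingency table (no continuity correction).

    Warns when any expected count is below 5 (asymptotic approximation is
    then questionable); zero row/column margins are rejected.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or (obs < 0).any():
        raise InputError("contingency table must be a 2-D array of non-negative counts")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise InputError("contingency table has a zero margin")
    stat, p, df, expected = sps.chi2_contingency(obs, correction=False)
    if (expected < 5).any():
        warnings.warn(
            f"chi-square: {int((expected < 5).sum())} cells have expected count < 5",
            stacklevel=2,
        )
    return TestResult(
        name="pearson-chi2",
        statistic=float(stat),
        p_value=float(p),
        significant=bool(p < alpha),
        route="categorical",
        alpha=alpha,
        df=float(df),
    )


# ---------------------------------------------------------------------------
# comparison table
# ---------------------------------------------------------------------------

#: Metrics compared between groups, in output order.
COMPARED_METRICS = [
    "area_whole_mm2",
    "area_cystic_mm2",
    "area_solid_mm2",
    "area_ratio",
    "mean_whole",
    "mean_cystic",
    "mean_solid",
    "sd_whole",
    "sd_cystic",
    "sd_solid",
    "density_whole",
    "density_cystic",
    "density_solid",
    "lobule_count",
    "parenchyma_mean",
    "parenchyma_sd",
]

_GROUP_ORDER = ["SCN", "Non-SCN", "Pseudocyst"]


@dataclasses.dataclass
class ComparisonTable:
    """Group summaries and pairwise test results for every metric."""

    summaries: list[GroupSummary]
    tests: dict[tuple[str, str, str], TestResult]  # (metric, group_a, group_b)
    alpha: float

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "metric": s.metric,
                    "group": s.group,
                    "n": s.n,
                    "mean": s.mean,
                    "sd": s.sd,
                    "sem": s.sem,
                }
                for s in self.summaries
            ]
        )

    def test_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "metric": metric,
                    "pair": f"{ga} vs {gb}",
                    "route": t.route,
                    "statistic": t.statistic,
                    "p_value": t.p_value,
                    "significant": t.significant,
                }
                for (metric, ga, gb), t in self.tests.items()
            ]
        )

    def to_csv(self, path) -> None:
        """Write the two-block comparison CSV: summaries, blank line, tests."""
        with open(path, "w", encoding="utf-8", newline="") as fh:
            self.summary_frame().to_csv(fh, index=False, float_format="%.10g")
            fh.write("\n")
            self.test_frame().to_csv(fh, index=False, float_format="%.10g")


def build_comparison_table(
    measurements,
    alpha: float = 0.05,
    per_patient: bool = False,
) -> ComparisonTable:
    """Per-group summaries plus all pairwise two-sample tests per metric.

    ``measurements`` is a sequence of :class:`~eusquant.metrics.LesionMeasurement`
    carrying group labels (or a DataFrame with the measurement columns and a
    ``group`` column). Groups with fewer than 2 images are excluded with a
    warning; metrics missing for a group are skipped with a warning.
    ``per_patient=True`` averages images within each patient first (requires
    patient ids).
    """
    if isinstance(measurements, pd.DataFrame):
        frame = measurements.copy()
    else:
        rows = []
        for m in measurements:
            row = m.to_row()
            row["patient_id"] = m.patient_id
            rows.append(row)
        frame = pd.DataFrame(rows)
    if "group" not in frame.columns or frame["group"].isna().all():
        raise InputError("measurements carry no group labels")
    frame = frame[frame["group"].notna()]
    if per_patient:
        if "patient_id" not in frame.columns or frame["patient_id"].isna().any():
            raise InputError("per_patient aggregation requires patient ids on every record")
        metric_cols = [c for c in COMPARED_METRICS if c in frame.columns]
        frame = (
            frame.groupby(["group", "patient_id"], as_index=False)[metric_cols].mean()
        )

    counts = frame["group"].value_counts()
    usable = [g for g in counts.index if counts[g] >= 2]
    dropped = [g for g in counts.index if counts[g] < 2]
    if dropped:
        warnings.warn(f"groups excluded with < 2 images: {dropped}", stacklevel=2)
    if len(usable) < 2:
        raise InputError("need at least 2 groups with >= 2 images each")
    groups = [g for g in _GROUP_ORDER if g in usable] + [
        g for g in usable if g not in _GROUP_ORDER
    ]

    summaries: list[GroupSummary] = []
    tests: dict[tuple[str, str, str], TestResult] = {}
    for metric in COMPARED_METRICS:
        if metric not in frame.columns:
            continue
        per_group: dict[str, np.ndarray] = {}
        for g in groups:
            vals = frame.loc[frame["group"] == g, metric].dropna().to_numpy(dtype=float)
            if vals.size < 2:
                warnings.warn(f"metric {metric!r} skipped for group {g!r} (n < 2)", stacklevel=2)
                continue
            per_group[g] = vals
            summaries.append(
                GroupSummary(
                    group=g,
                    metric=metric,
                    n=int(vals.size),
                    mean=float(vals.mean()),
                    sd=float(vals.std(ddof=1)),
                    sem=float(vals.std(ddof=1) / math.sqrt(vals.size)),
                )
            )
        gs = [g for g in groups if g in per_group]
        for i in range(len(gs)):
            for j in range(i + 1, len(gs)):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    tests[(metric, gs[i], gs[j])] = compare_two_samples(
                        per_group[gs[i]], per_group[gs[j]], alpha=alpha
                    )
    return ComparisonTable(summaries=summaries, tests=tests, alpha=alpha)
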