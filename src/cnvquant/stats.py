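"""Agreement and comparison statistics for vessel-density measurements.

Covers the analysis set of a two-modality longitudinal study:
Bland-Altman limits of agreement between methods, Pearson correlation,
paired and (Welch) unpaired t-tests, the Wilcoxon signed-rank test as
the paired nonparametric comparison, and descriptive group summaries.

Conventions pinned here once:

* limits of agreement use the conventional 1.96 multiplier on the
  sample SD (n-1) of the paired differences; the CI of the mean
  difference uses the t distribution with n-1 df;
* the paired nonparametric test is the Wilcoxon signed-rank test with
  an exact tie-aware null distribution for n <= 25 and a tie-corrected
  normal approximation above;
* quantiles use linear interpolation between order statistics;
* the unpaired t-test is Welch's form (no variance-homogeneity
  assumption; group sizes in such studies are small and unequal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import NoInformationError, SampleSizeError, ValidationError

LOA_MULTIPLIER = 1.96
EXACT_WILCOXON_MAX_N = 25


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: int
    name: str


@dataclass
class BlandAltmanResult:
    """Agreement between two methods from paired measurements (d = x - y)."""

    n: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ci_mean: tuple[float, float]
    pairs: np.ndarray  # (n, 2) columns: average, difference

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "ci_mean": list(self.ci_mean),
            "pairs": self.pairs.tolist(),
        }


def _paired(x, y, min_n: int, name: str) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(f"{name}: x and y must be equal-length 1-D sequences")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError(f"{name}: non-finite values")
    if len(x) < min_n:
        raise SampleSizeError(f"{name}: needs at least {min_n} pairs, got {len(x)}")
    return x, y


def bland_altman(x, y) -> BlandAltmanResult:
    """Limits of agreement for paired measurements of the same quantity.

    Differences are ``x - y``; limits are ``mean +- 1.96 sd`` with the
    sample SD; the 95% CI of the mean difference uses t with n-1 df.
    """
    x, y = _paired(x, y, 3, "bland_altman")
    d = x - y
    n = len(d)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    half = sps.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    return BlandAltmanResult(
        n=n,
        mean_diff=mean,
        sd_diff=sd,
        loa_low=mean - LOA_MULTIPLIER * sd,
        loa_high=mean + LOA_MULTIPLIER * sd,
        ci_mean=(mean - half, mean + half),
        pairs=np.column_stack([(x + y) / 2.0, d]),
    )


def pearson_correlation(x, y) -> TestResult:
    """Pearson r with the two-sided p from the t transform (n-2 df)."""
    x, y = _paired(x, y, 3, "pearson_correlation")
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("correlation undefined for zero-variance input")
    r, p = sps.pearsonr(x, y)
    return TestResult(statistic=float(r), p_value=float(p), n=len(x), name="pearson")


def paired_t_test(x, y) -> TestResult:
    """Two-sided paired t-test on differences x - y.

    Edge conventions: all-zero differences give t = 0, p = 1; zero-SD
    differences with nonzero mean give p = 0 (the test statistic is
    unbounded).
    """
    x, y = _paired(x, y, 2, "paired_t_test")
    d = x - y
    n = len(d)
    if d.std(ddof=1) == 0:
        if d.mean() == 0:
            return TestResult(statistic=0.0, p_value=1.0, n=n, name="paired_t")
        return TestResult(
            statistic=np.inf if d.mean() > 0 else -np.inf,
            p_value=0.0,
            n=n,
            name="paired_t",
        )
    t, p = sps.ttest_rel(x, y)
    return TestResult(statistic=float(t), p_value=float(p), n=n, name="paired_t")


def unpaired_t_test(x, y) -> TestResult:
    """Welch's two-sided unpaired t-test."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) < 2 or len(y) < 2:
        raise SampleSizeError("unpaired_t_test: both groups need n >= 2")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("unpaired_t_test: non-finite values")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if x.mean() == y.mean():
            return TestResult(0.0, 1.0, len(x) + len(y), "welch_t")
        return TestResult(
            np.inf if x.mean() > y.mean() else -np.inf, 0.0, len(x) + len(y), "welch_t"
        )
    t, p = sps.ttest_ind(x, y, equal_var=False)
    return TestResult(float(t), float(p), len(x) + len(y), "welch_t")


def _signed_rank_exact_p(ranks2: np.ndarray, w2: float) -> float:
    """Two-sided exact p for the signed-rank statistic with tied ranks.

    ``ranks2`` are doubled ranks (integers even under ties), ``w2`` the
    doubled observed W+.  The null distribution of W+ is built by the
    generating-function convolution over all 2^n sign assignments.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2i = int(round(w2))
    p_low = counts[: w2i + 1].sum()
    p_high = counts[w2i:].sum()
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def wilcoxon_signed_rank(x, y) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired data.

    Zero differences are dropped; at least 5 informative pairs are
    required.  Ties receive average ranks.  The exact tie-aware null
    distribution is enumerated for n <= 25; above that a tie-corrected
    normal approximation is used.  The statistic reported is W+ (sum of
    ranks of positive differences).
    """
    x, y = _paired(x, y, 2, "wilcoxon_signed_rank")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise NoInformationError("all paired differences are zero")
    if n < 5:
        raise SampleSizeError(
            f"wilcoxon_signed_rank: needs >= 5 nonzero differences, got {n}"
        )
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_WILCOXON_MAX_N:
        p = _signed_rank_exact_p(np.round(2 * ranks).astype(int), 2 * w_plus)
    else:
        mean = n * (n + 1) / 4.0
        # tie correction on the variance
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum() / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (w_plus - mean) / np.sqrt(var)
        p = float(2.0 * sps.norm.sf(abs(z)))
    return TestResult(statistic=w_plus, p_value=min(p, 1.0), n=n, name="wilcoxon")


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U (unpaired nonparametric), for completeness."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) < 2 or len(y) < 2:
        raise SampleSizeError("mann_whitney_u: both groups need n >= 2")
    u, p = sps.mannwhitneyu(x, y, alternative="two-sided")
    return TestResult(float(u), float(p), len(x) + len(y), "mann_whitney_u")


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float  # 0 with the n=1 flag set when undefined
    median: float
    q1: float
    q3: float
    sd_undefined: bool = False

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean": self.mean,
            "sd": self.sd,
            "median": self.median,
            "iqr": [self.q1, self.q3],
            "sd_undefined": self.sd_undefined,
        }


def group_summary(values) -> GroupSummary:
    """Mean, sample SD, median and IQR (linear-interpolation quantiles)."""
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValidationError("group_summary: empty input")
    if not np.all(np.isfinite(v)):
        raise ValidationError("group_summary: non-finite values")
    n = int(v.size)
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75], method="linear")
    if n == 1:
        return GroupSummary(1, float(v[0]), 0.0, float(med), float(q1), float(q3), True)
    return GroupSummary(
        n, float(v.mean()), float(v.std(ddof=1)), float(med), float(q1), float(q3)
    )
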