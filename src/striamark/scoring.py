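"""Cleaning-experiment scoring and the study's statistical toolkit.

Cleaned cut marks are scored against five microscopic criteria: coarse
striations detectable, fine striations detectable, complete mark
detectable, no shine, no dots. Each fulfilled criterion scores 1, an
unfulfilled one 0; *no dots* additionally scores −1 when more dots appear
than on the untreated reference mark. The total score TS therefore lies
in [−1, 5]. A cleaning method's effect is its delta score DS: the mean TS
of cleaned samples minus the mean TS of their references.

The module also provides a summary-statistics two-sample t-test (used for
comparing the cast-dot diameters against chondrocyte diameters when only
mean ± sd and n are reported) and thin wrappers over the standard tests:
Mann–Whitney U, Wilcoxon signed-rank, Pearson correlation, and
Kolmogorov–Smirnov (Lilliefors) / Shapiro–Wilk normality checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import SIGNIFICANCE_LEVEL
from .exceptions import StatisticsError, ValidationError

__all__ = [
    "CleaningScore",
    "DiameterSummary",
    "score_sample",
    "delta_score",
    "ttest_from_summary",
    "test_battery",
    "SIGNIFICANCE_LEVEL",
]

#: Threshold for exact (vs normal-approximation) Mann–Whitney U p-values.
_EXACT_MANNWHITNEY_MAX_N = 25

_BINARY_CRITERIA = ("coarse_striations", "fine_striations", "complete_mark", "no_shine")


@dataclass
class CleaningScore:
    """One sample's outcome on the five cleaning criteria."""

    coarse_striations: int
    fine_striations: int
    complete_mark: int
    no_shine: int
    no_dots: int

    def __post_init__(self) -> None:
        for name in _BINARY_CRITERIA:
            if getattr(self, name) not in (0, 1):
                raise ValidationError(f"{name} must be 0 or 1")
        if self.no_dots not in (-1, 0, 1):
            raise ValidationError("no_dots must be -1, 0 or 1")

    @property
    def total(self) -> int:
        return (self.coarse_striations + self.fine_striations + self.complete_mark
                + self.no_shine + self.no_dots)


@dataclass
class DiameterSummary:
    """Summary statistics (mean, sd, n) of a diameter sample, µm."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError("sd must be non-negative")
        if self.n < 2:
            raise ValidationError("n must be at least 2")


def score_sample(criteria: dict) -> CleaningScore:
    """Build a :class:`CleaningScore` from criterion outcomes.

    ``criteria`` maps the five criterion names to their outcomes; only
    ``no_dots`` may take −1 (more dots than on the reference mark).
    """
    unknown = set(criteria) - set(_BINARY_CRITERIA) - {"no_dots"}
    if unknown:
        raise ValidationError(f"unknown criteria: {sorted(unknown)}")
    return CleaningScore(**{k: int(criteria[k]) for k in (*_BINARY_CRITERIA, "no_dots")})


def delta_score(ts_sample, ts_reference):
    """Delta score DS = cleaned-sample mean TS minus reference mean TS.

    Each argument is either a ``(mean, sd, n)`` *tuple* or a list/array of
    raw per-sample totals. With raw scores on both sides of equal length,
    a per-sample DS list is returned alongside the mean.
    """
    def unpack(x):
        if isinstance(x, tuple):
            if len(x) != 3:
                raise ValidationError("summary form must be a (mean, sd, n) tuple")
            return float(x[0]), None
        arr = np.asarray(x, dtype=float)
        return float(arr.mean()), arr

    mean_s, raw_s = unpack(ts_sample)
    mean_r, raw_r = unpack(ts_reference)
    ds_mean = mean_s - mean_r
    if raw_s is not None and raw_r is not None and raw_s.size == raw_r.size:
        return ds_mean, list(raw_s - raw_r)
    return ds_mean, None


def ttest_from_summary(a: DiameterSummary, b: DiameterSummary, flavor: str = "welch"):
    """Two-sample t-test from summary statistics.

    ``welch`` uses the Welch–Satterthwaite degrees of freedom; ``pooled``
    assumes equal variances. Returns ``(t, df, p)`` with a two-sided p.
    Degenerate contract: zero variance on both sides gives p = 1 for equal
    means and p = 0 otherwise.
    """
    if flavor not in ("welch", "pooled"):
        raise StatisticsError(f"unknown t-test flavor {flavor!r}")
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            return 0.0, float(a.n + b.n - 2), 1.0
        return float("inf"), float(a.n + b.n - 2), 0.0
    t, p = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=(flavor == "pooled")
    )
    if flavor == "pooled":
        df = a.n + b.n - 2
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return float(t), float(df), float(p)


def test_battery(x, y=None, test: str = "mann-whitney-u"):
    """Uniform front end to the study's standard tests.

    Supported: ``mann-whitney-u`` (exact for combined n <= 25, else
    normal approximation with tie correction), ``wilcoxon-signed-rank``
    (paired), ``pearson``, ``ks-normality`` (Lilliefors) and
    ``shapiro-normality`` (these two take only ``x``). All p-values are
    two-sided. Returns ``(statistic, p)``.
    """
    x = np.asarray(x, dtype=float)
    if test in ("ks-normality", "shapiro-normality"):
        if x.size < 4:
            raise StatisticsError("normality tests need at least 4 values")
        if test == "shapiro-normality":
            res = stats.shapiro(x)
            return float(res.statistic), float(res.pvalue)
        from statsmodels.stats.diagnostic import lilliefors

        stat, p = lilliefors(x, dist="norm")
        return float(stat), float(p)

    if y is None:
        raise StatisticsError(f"test {test!r} needs two samples")
    y = np.asarray(y, dtype=float)

    if test == "mann-whitney-u":
        if x.size < 1 or y.size < 1:
            raise StatisticsError("Mann-Whitney needs non-empty samples")
        method = "exact" if x.size + y.size <= _EXACT_MANNWHITNEY_MAX_N else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    if test == "wilcoxon-signed-rank":
        if x.size != y.size or x.size < 1:
            raise StatisticsError("Wilcoxon needs paired samples of equal length")
        d = x - y
        if np.all(d == 0):
            return 0.0, 1.0  # no discordant pairs: no evidence of a shift
        res = stats.wilcoxon(x, y, alternative="two-sided", zero_method="wilcox")
        return float(res.statistic), float(res.pvalue)
    if test == "pearson":
        if x.size != y.size or x.size < 3:
            raise StatisticsError("Pearson needs paired samples of length >= 3")
        if np.std(x) == 0 or np.std(y) == 0:
            raise StatisticsError("zero-variance input: correlation undefined")
        res = stats.pearsonr(x, y)
        return float(res.statistic), float(res.pvalue)
    raise StatisticsError(f"unknown test {test!r}")
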