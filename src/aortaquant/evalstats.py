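"""Method-comparison and detector-evaluation statistics.

Implements the agreement battery used to compare automated against manual
diameter series — ICC(2,1) (two-way, absolute agreement, single rater),
Bland–Altman bias and limits of agreement, Wilcoxon matched-pairs signed-rank
test, Spearman correlation, absolute/systematic error summaries with a
normality check — plus sensitivity/specificity/accuracy with exact
Clopper–Pearson confidence intervals for the dissection detector.

Conventions that matter for reproducibility: differences are auto − manual;
LoA use the n−1 sample SD and ±1.96; Wilcoxon drops zero differences and uses
mid-ranks for ties, with an exact tail computed by dynamic programming for
n ≤ 25 and a tie-corrected normal approximation beyond; quartiles use linear
interpolation; the Kolmogorov–Smirnov normality test plugs in fitted
parameters (Lilliefors caveat: its p-value is conservative and flagged as
such).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import InputError

__all__ = ["PairedMeasurements", "AgreementStats", "DiagnosticCounts",
           "DiagnosticMetrics", "icc_2_1", "icc_band", "bland_altman",
           "paired_nonparametrics", "error_summary", "agreement_stats",
           "diagnostic_metrics", "clopper_pearson", "wilcoxon_exact_p"]


@dataclass
class PairedMeasurements:
    """Automated vs manual measurement series (mm), case-aligned."""

    auto: np.ndarray
    manual: np.ndarray
    labels: list | None = None

    def __post_init__(self) -> None:
        self.auto = np.asarray(self.auto, dtype=float)
        self.manual = np.asarray(self.manual, dtype=float)
        if self.auto.shape != self.manual.shape or self.auto.ndim != 1:
            raise InputError("auto and manual must be equal-length 1D series")
        if len(self.auto) < 3:
            raise InputError("need at least 3 pairs")
        if not (np.all(np.isfinite(self.auto)) and np.all(np.isfinite(self.manual))):
            raise InputError("measurements must be finite")

    @property
    def n(self) -> int:
        return len(self.auto)

    @property
    def diff(self) -> np.ndarray:
        return self.auto - self.manual


@dataclass
class AgreementStats:
    icc: float
    icc_band: str
    bias: float
    loa_low: float
    loa_high: float
    spearman_r: float
    wilcoxon_p: float
    abs_error_median: float
    abs_error_iqr: tuple[float, float]
    sys_error_median: float
    sys_error_iqr: tuple[float, float]
    normality_p: float
    flags: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def icc_band(value: float) -> str:
    """Qualitative interpretation bands for ICC values."""
    if value < 0.5:
        return "poor"
    if value < 0.75:
        return "moderate"
    if value <= 0.9:
        return "good"
    return "excellent"


def icc_2_1(p: PairedMeasurements) -> tuple[float, str, list[str]]:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    From the two-way ANOVA of the n x 2 (targets x raters) table:
        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    Zero total variance is a degenerate input; perfect agreement (ICC 1.0)
    is returned with a flag.
    """
    data = np.stack([p.manual, p.auto], axis=1)
    n, k = data.shape
    if np.allclose(data.var(), 0.0):
        return 1.0, icc_band(1.0), ["degenerate: zero total variance"]
    grand = data.mean()
    row_m = data.mean(axis=1)
    col_m = data.mean(axis=0)
    ssr = k * np.sum((row_m - grand) ** 2)
    ssc = n * np.sum((col_m - grand) ** 2)
    sse = np.sum((data - row_m[:, None] - col_m[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return float(icc), icc_band(float(icc)), []


def bland_altman(p: PairedMeasurements) -> tuple[float, float, float]:
    """Mean bias and 95% limits of agreement (bias ± 1.96 · SD_{n-1})."""
    d = p.diff
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def _signed_rank_stat(d: np.ndarray) -> tuple[float, np.ndarray]:
    """W+ (sum of positive-difference mid-ranks) and the mid-ranks."""
    ranks = stats.rankdata(np.abs(d))
    return float(ranks[d > 0].sum()), ranks


def wilcoxon_exact_p(d: np.ndarray) -> float:
    """Exact two-sided signed-rank p-value under the symmetry null.

    Dynamic programming over the distribution of W+ across all 2^n sign
    assignments; mid-ranks (possibly half-integer) are doubled to keep the
    support integral. Zero differences must be removed beforehand.
    """
    w_plus, ranks = _signed_rank_stat(d)
    r2 = np.round(ranks * 2).astype(int)
    total = int(r2.sum())
    # counts[w] = number of sign assignments with doubled W+ equal to w
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[: total + 1 - r]
    counts /= counts.sum()
    w2 = int(round(w_plus * 2))
    # two-sided: fold the symmetric distribution around its mean
    mean = total / 2.0
    dev = abs(w2 - mean)
    p = counts[np.abs(np.arange(total + 1) - mean) >= dev - 1e-9].sum()
    return float(min(1.0, p))


def paired_nonparametrics(p: PairedMeasurements) -> tuple[float, float, list[str]]:
    """(wilcoxon_p, spearman_r, flags).

    Zero differences are dropped (Wilcoxon's convention, flagged); the exact
    distribution is used for n ≤ 25, a tie-corrected normal approximation
    beyond.
    """
    flags = []
    d = p.diff
    nz = d[d != 0]
    if (d == 0).any():
        flags.append(f"dropped {int((d == 0).sum())} zero differences")
    if len(nz) == 0:
        flags.append("all differences zero")
        wp = 1.0
    elif len(nz) <= 25:
        wp = wilcoxon_exact_p(nz)
    else:
        res = stats.wilcoxon(nz, zero_method="wilcox", correction=True,
                             method="approx")
        wp = float(res.pvalue)
    rho = float(stats.spearmanr(p.auto, p.manual).statistic)
    return wp, rho, flags


def error_summary(p: PairedMeasurements):
    """Absolute and systematic error medians (IQR) and KS normality p.

    abs error = |auto - manual|; systematic error = auto - manual. Quartiles
    by linear interpolation. The KS test uses fitted mean/SD (Lilliefors
    caveat; flagged).
    """
    d = p.diff
    abs_e = np.abs(d)
    q = lambda x: (float(np.percentile(x, 25)), float(np.percentile(x, 75)))
    sd = d.std(ddof=1)
    if sd < 1e-12:
        ks_p = 0.0
        flags = ["degenerate differences: zero variance"]
    else:
        ks_p = float(stats.kstest(d, "norm", args=(d.mean(), sd)).pvalue)
        flags = ["KS normality uses fitted parameters (Lilliefors caveat)"]
    return (float(np.median(abs_e)), q(abs_e),
            float(np.median(d)), q(d), ks_p, flags)


def agreement_stats(p: PairedMeasurements) -> AgreementStats:
    """The full agreement battery for one paired series."""
    icc, band, f1 = icc_2_1(p)
    bias, lo, hi = bland_altman(p)
    wp, rho, f2 = paired_nonparametrics(p)
    abs_med, abs_iqr, sys_med, sys_iqr, ks_p, f3 = error_summary(p)
    return AgreementStats(icc, band, bias, lo, hi, rho, wp,
                          abs_med, abs_iqr, sys_med, sys_iqr, ks_p,
                          flags=f1 + f2 + f3)


# ---------------------------------------------------------------------------
# diagnostic metrics

@dataclass
class DiagnosticCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise InputError("counts must be non-negative")


@dataclass
class DiagnosticMetrics:
    sensitivity: float | None
    sensitivity_ci: tuple[float, float] | None
    specificity: float | None
    specificity_ci: tuple[float, float] | None
    accuracy: float | None
    accuracy_ci: tuple[float, float] | None
    flags: list[str] = field(default_factory=list)


def clopper_pearson(successes: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval (beta quantiles)."""
    if not (0 <= successes <= n) or n <= 0:
        raise InputError("need 0 <= successes <= n, n > 0")
    lo = 0.0 if successes == 0 else float(stats.beta.ppf(alpha / 2, successes,
                                                         n - successes + 1))
    hi = 1.0 if successes == n else float(stats.beta.ppf(1 - alpha / 2, successes + 1,
                                                         n - successes))
    return lo, hi


def diagnostic_metrics(c: DiagnosticCounts, alpha: float = 0.05) -> DiagnosticMetrics:
    """Sensitivity, specificity, accuracy, each with an exact 95% CI."""
    flags = []

    def ratio(num, den, name):
        if den == 0:
            flags.append(f"{name}: zero denominator")
            return None, None
        return num / den, clopper_pearson(num, den, alpha)

    sens, sens_ci = ratio(c.tp, c.tp + c.fn, "sensitivity")
    spec, spec_ci = ratio(c.tn, c.tn + c.fp, "specificity")
    total = c.tp + c.fp + c.tn + c.fn
    acc, acc_ci = ratio(c.tp + c.tn, total, "accuracy")
    return DiagnosticMetrics(sens, sens_ci, spec, spec_ci, acc, acc_ci, flags)
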