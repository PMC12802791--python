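"""Summary statistics for per-image test metrics.

For each metric over the test images: Shapiro-Wilk normality check at
alpha = 0.05, then arithmetic mean, sample standard deviation (n-1
denominator), standard error of the mean, and the 95 % confidence interval
from the t-distribution with n-1 degrees of freedom,

    CI = mu +/- t_{(1+level)/2, n-1} * s / sqrt(n).

Summaries are reported on the percent scale (0-100) with half-up rounding to
two decimals in formatted output.  When normality fails the CI is still
computed but flagged, since the parametric interval then only has descriptive
value.

:func:`infer_sample_size` inverts the CI half-width formula over integer n —
given a printed (mean, s, interval) triple it recovers the sample size that
produced it, which is how the package pins down a test-set size that a report
states only implicitly through its interval widths.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "MetricSummary",
    "shapiro_wilk",
    "t_confidence_interval",
    "summarize",
    "infer_sample_size",
    "round_half_up",
    "format_table",
]

logger = logging.getLogger(__name__)

SUMMARY_METRICS = ("mean_iou_2class", "auroc", "accuracy")


@dataclass(frozen=True)
class MetricSummary:
    """Distribution summary of one metric over the test set (percent scale).

    ``normality_ok`` is None when the Shapiro-Wilk test is not applicable
    (degenerate sample), in which case ``shapiro_w``/``shapiro_p`` are NaN.
    """

    metric: str
    n: int
    mu: float
    s: float
    sem: float
    ci_low: float
    ci_high: float
    shapiro_w: float
    shapiro_p: float
    normality_ok: bool | None


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk statistic W and p-value for 3 <= n <= 5000 samples.

    A zero-variance sample has no defined W and raises ``ValueError``.
    """
    values = np.asarray(values, dtype=np.float64)
    if not 3 <= values.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(values) == 0.0:
        raise ValueError("Shapiro-Wilk undefined for a zero-variance sample")
    w, p = sps.shapiro(values)
    return float(w), float(p)


def t_confidence_interval(mu: float, s: float, n: int, level: float = 0.95):
    """(low, high) of the t-distribution confidence interval for the mean."""
    if n < 2:
        raise ValueError("confidence interval requires n >= 2")
    if s < 0:
        raise ValueError("standard deviation must be non-negative")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    half = sps.t.ppf(0.5 * (1.0 + level), n - 1) * s / math.sqrt(n)
    return mu - half, mu + half


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal rounding with ties away from zero (spreadsheet convention)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def summarize(per_image_metrics, metrics=SUMMARY_METRICS, level: float = 0.95,
              alpha: float = 0.05) -> list[MetricSummary]:
    """One :class:`MetricSummary` per metric over the test images.

    Values are converted from fractions to percent.  The CI is computed even
    when the normality check fails, with a logged caveat.
    """
    if len(per_image_metrics) < 2:
        raise ValueError("summaries require at least two test images")
    out = []
    for name in metrics:
        vals = np.array([getattr(m, name) for m in per_image_metrics], dtype=np.float64)
        vals = vals * 100.0
        n = vals.size
        mu = float(vals.mean())
        s = float(vals.std(ddof=1))
        sem = s / math.sqrt(n)
        lo, hi = t_confidence_interval(mu, s, n, level)
        try:
            w, p = shapiro_wilk(vals)
            ok = bool(p >= alpha)
        except ValueError:
            w, p, ok = float("nan"), float("nan"), None
        if ok is False:
            logger.warning(
                "metric %s fails the Shapiro-Wilk normality check (p=%.3g); "
                "the parametric CI is reported but descriptive only", name, p,
            )
        out.append(
            MetricSummary(metric=name, n=n, mu=mu, s=s, sem=sem, ci_low=lo,
                          ci_high=hi, shapiro_w=w, shapiro_p=p, normality_ok=ok)
        )
    return out


def infer_sample_size(s: float, half_width: float, n_range=(2, 100),
                      level: float = 0.95, decimals: int = 2) -> list[int]:
    """All n in ``n_range`` whose t-CI half-width (given s) rounds to ``half_width``.

    Exhaustive scan; a single-element result pins the sample size behind a
    printed interval.
    """
    lo, hi = n_range
    hits = []
    for n in range(lo, hi + 1):
        half = sps.t.ppf(0.5 * (1.0 + level), n - 1) * s / math.sqrt(n)
        if round_half_up(half, decimals) == round_half_up(half_width, decimals):
            hits.append(n)
    return hits


def format_table(summaries: list[MetricSummary]) -> str:
    """Plain-text table of mean, SD and 95 % CI per metric (percent scale)."""
    lines = [f"{'Metric':<18}{'Mean':>8}{'SD':>8}  95% CI"]
    for m in summaries:
        lines.append(
            f"{m.metric:<18}"
            f"{round_half_up(m.mu):>8.2f}"
            f"{round_half_up(m.s):>8.2f}"
            f"  [{round_half_up(m.ci_low):.2f}, {round_half_up(m.ci_high):.2f}]"
        )
    return "\n".join(lines)
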