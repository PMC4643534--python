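"""Method-comparison and repeatability statistics.

The statistical toolkit for comparing a semi-quantitative ultrasound
score against a gravimetric reference, and for quantifying repeatability
of paired readings:

* Pearson correlation with the t-transform p-value,
* Welch's two-sample t-test (unequal variances; group SDs here differ
  by factors of several, so the pooled-variance test is inappropriate),
* Bland–Altman bias and limits of agreement, bias ± k·SD with k = 2 by
  default (the "differences exceed 2 SD" screening rule),
* a concordance index for paired quantitative readings: Lin's
  concordance correlation coefficient (CCC) with a 95% CI through the
  Fisher z-transform, or ICC(2,1) as an alternative.

Lin's CCC for paired series (x, y) with moment estimates (1/n
denominators) is

    CCC = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²),

i.e. the Pearson correlation attenuated by the location and scale shift
between the two readings, so |CCC| ≤ |r| always.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PairedSeries",
    "AgreementReport",
    "pearson",
    "welch_t",
    "bland_altman",
    "concordance",
    "icc21",
    "plot_agreement",
]

DEFAULT_BA_MULTIPLIER = 2.0


@dataclass(frozen=True)
class PairedSeries:
    """Two measurements per subject, paired by position."""

    labels: tuple[str, ...]
    x: tuple[float, ...]
    y: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.labels) == len(self.x) == len(self.y)):
            raise ValueError("labels, x and y must have equal lengths")
        if len(self.x) < 2:
            raise ValueError("paired series needs at least 2 observations")
        if any(v is None or not math.isfinite(v) for v in (*self.x, *self.y)):
            raise ValueError("paired series must be free of missing values")

    def __len__(self) -> int:
        return len(self.x)

    @classmethod
    def from_arrays(cls, labels, x, y) -> "PairedSeries":
        return cls(tuple(str(l) for l in labels),
                   tuple(float(v) for v in x),
                   tuple(float(v) for v in y))


@dataclass(frozen=True)
class AgreementReport:
    """Bundle of agreement statistics for a cohort or a repeatability pair."""

    n: int
    pearson_r: Optional[float] = None
    pearson_p: Optional[float] = None
    t_stat: Optional[float] = None
    t_df: Optional[float] = None
    t_p: Optional[float] = None
    ba_bias: Optional[float] = None
    ba_sd: Optional[float] = None
    ba_limits: Optional[tuple[float, float]] = None
    ba_n_outside: Optional[int] = None
    ccc: Optional[float] = None
    ccc_ci: Optional[tuple[float, float]] = None
    concordance_method: str = "lin"

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.ba_limits is not None:
            d["ba_limits"] = list(self.ba_limits)
        if self.ccc_ci is not None:
            d["ccc_ci"] = list(self.ccc_ci)
        return d


def pearson(series: PairedSeries) -> tuple[float, float]:
    """Sample Pearson r and the two-sided p-value (t-transform, n−2 df)."""
    x = np.asarray(series.x, dtype=float)
    y = np.asarray(series.y, dtype=float)
    if len(x) < 3:
        raise ValueError("Pearson correlation needs n ≥ 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for a zero-variance series")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's t statistic, Welch–Satterthwaite df, two-sided p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("Welch t-test needs n ≥ 2 in both groups")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    if se2 == 0:
        return 0.0, float(na + nb - 2), 1.0
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def bland_altman(
    m1: Sequence[float],
    m2: Sequence[float],
    k: float = DEFAULT_BA_MULTIPLIER,
) -> tuple[float, float, tuple[float, float], int]:
    """Bland–Altman agreement of paired measurements.

    Returns (bias, SD of differences, (lower, upper) limits bias ± k·SD,
    and the count of differences outside the limits).
    """
    d = np.asarray(m1, dtype=float) - np.asarray(m2, dtype=float)
    if len(np.asarray(m1)) != len(np.asarray(m2)):
        raise ValueError("Bland–Altman requires equal-length series")
    if len(d) < 2:
        raise ValueError("Bland–Altman needs n ≥ 2")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    limits = (bias - k * sd, bias + k * sd)
    n_outside = int(np.sum(np.abs(d - bias) > k * sd))
    return bias, sd, limits, n_outside


def _lin_ccc(x: np.ndarray, y: np.ndarray) -> float:
    # moment (1/n) estimators, per the original formulation
    sx2 = x.var()
    sy2 = y.var()
    sxy = ((x - x.mean()) * (y - y.mean())).mean()
    denom = sx2 + sy2 + (x.mean() - y.mean()) ** 2
    if denom == 0:
        raise ValueError("concordance undefined: both series constant and equal")
    return float(2.0 * sxy / denom)


def concordance(
    series: PairedSeries,
    method: str = "lin",
    confidence: float = 0.95,
) -> tuple[float, float, float]:
    """Concordance index with a confidence interval.

    ``method='lin'``: Lin's CCC, CI via the Fisher z-transform with
    Lin's asymptotic variance. ``method='icc'``: ICC(2,1); CI via the
    same z-transform applied to the ICC (approximate).
    """
    x = np.asarray(series.x, dtype=float)
    y = np.asarray(series.y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("concordance needs n ≥ 3")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("concordance undefined when both series are constant")

    if method == "icc":
        ccc = icc21(x, y)
    elif method == "lin":
        ccc = _lin_ccc(x, y)
    else:
        raise ValueError(f"unknown concordance method {method!r} (use 'lin' or 'icc')")

    if abs(ccc) >= 1.0 - 1e-12:
        return ccc, ccc, ccc

    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return ccc, float("nan"), float("nan")

    r = float(np.corrcoef(x, y)[0, 1])
    z = math.atanh(ccc)
    u = (x.mean() - y.mean()) / math.sqrt(x.std() * y.std())
    c2 = ccc * ccc
    if r == 0:
        se_z = 1.0 / math.sqrt(n - 3)  # fall back to the plain Fisher SE
    else:
        var_z = (
            (1 - r * r) * c2 / ((1 - c2) * r * r)
            + 2 * ccc**3 * (1 - ccc) * u * u / (r * (1 - c2) ** 2)
            - ccc**4 * u**4 / (2 * r * r * (1 - c2) ** 2)
        ) / (n - 2)
        se_z = math.sqrt(max(var_z, 0.0))
    q = stats.norm.ppf(0.5 + confidence / 2.0)
    lo, hi = math.tanh(z - q * se_z), math.tanh(z + q * se_z)
    return ccc, float(lo), float(hi)


def icc21(x: Sequence[float], y: Sequence[float]) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rating.

    Closed form for n subjects × 2 raters from the ANOVA mean squares.
    """
    data = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValueError("ICC undefined: no variance in the data")
    return float((msr - mse) / denom)


def plot_agreement(series: PairedSeries, scatter_path, ba_path,
                   k: float = DEFAULT_BA_MULTIPLIER,
                   xlabel: str = "method 1", ylabel: str = "method 2") -> None:
    """Scatter plot and Bland–Altman plot for a paired series."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(series.x, float)
    y = np.asarray(series.y, float)

    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter(x, y, s=25, alpha=0.8, edgecolor="k", linewidth=0.4)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    r, p = pearson(series) if len(series) >= 3 else (float("nan"), float("nan"))
    ax.set_title(f"r = {r:.3f} (p = {p:.2g}, n = {len(series)})")
    fig.tight_layout()
    fig.savefig(scatter_path, dpi=150)
    plt.close(fig)

    bias, sd, limits, _ = bland_altman(x, y, k=k)
    mean_xy = (x + y) / 2.0
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter(mean_xy, x - y, s=25, alpha=0.8, edgecolor="k", linewidth=0.4)
    ax.axhline(bias, color="k", lw=1)
    for lim in limits:
        ax.axhline(lim, color="k", lw=1, ls="--")
    ax.set_xlabel("mean of readings")
    ax.set_ylabel("difference")
    ax.set_title(f"bias = {bias:.3f}, limits = bias ± {k:g}·SD")
    fig.tight_layout()
    fig.savefig(ba_path, dpi=150)
    plt.close(fig)
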