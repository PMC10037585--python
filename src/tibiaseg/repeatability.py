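"""Test-retest precision statistics for segmented volumes.

Two scans of the same animal on consecutive days should segment to the same
volume; the scatter of the paired differences is pure measurement error.

* wCV — within-subject coefficient of variation, pooled in the per-pair
  relative form  wCV^2 = mean_i( d_i^2 / (2 m_i^2) )  with d_i the pair
  difference and m_i the pair mean (QIBA convention).  Reported in percent.
* wCV confidence interval — chi-square interval on a standard deviation with
  df = n_pairs - 1:  wCV * sqrt(df / chi2_{1-a/2, df}) .. wCV *
  sqrt(df / chi2_{a/2, df}).
* Bland-Altman — bias (mean difference) and 95% limits of agreement
  bias +/- 1.96 * SD of differences.
* Pearson R — product-moment agreement between two volume series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PairedVolumes",
    "WcvResult",
    "BlandAltmanResult",
    "wcv",
    "wcv_ci",
    "wcv_with_ci",
    "bland_altman",
    "plot_bland_altman",
    "pearson_r",
]


@dataclass(frozen=True)
class PairedVolumes:
    """Test/retest volume pairs (mm^3) with their pair identifiers."""

    test: tuple[float, ...]
    retest: tuple[float, ...]
    pair_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.test) != len(self.retest):
            raise ValueError("test and retest series differ in length")
        if len(self.test) < 1:
            raise ValueError("at least one pair is required")
        if any(v <= 0 for v in self.test) or any(v <= 0 for v in self.retest):
            raise ValueError("volumes must be positive")
        if self.pair_ids and len(self.pair_ids) != len(self.test):
            raise ValueError("pair_ids length mismatch")

    @property
    def n(self) -> int:
        return len(self.test)

    @property
    def differences(self) -> np.ndarray:
        """Retest minus test, per pair."""
        return np.asarray(self.retest) - np.asarray(self.test)

    @property
    def means(self) -> np.ndarray:
        return (np.asarray(self.retest) + np.asarray(self.test)) / 2.0


@dataclass(frozen=True)
class WcvResult:
    wcv: float  # %
    ci_low: float  # %
    ci_high: float  # %
    n_pairs: int


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float  # mm^3
    loa_low: float  # mm^3
    loa_high: float  # mm^3
    sd_diff: float  # mm^3
    n: int


def wcv(pairs: PairedVolumes, pooling: str = "relative") -> float:
    """Within-subject coefficient of variation in percent.

    ``pooling="relative"`` (default) is the per-pair relative form
    sqrt(mean(d_i^2 / (2 m_i^2))); ``pooling="grand-mean"`` is the
    alternative sqrt(mean(d_i^2) / 2) / grand mean.
    """
    d = pairs.differences
    m = pairs.means
    if pooling == "relative":
        return 100.0 * float(np.sqrt(np.mean(d**2 / (2.0 * m**2))))
    if pooling == "grand-mean":
        return 100.0 * float(np.sqrt(np.mean(d**2) / 2.0) / m.mean())
    raise ValueError(f"unknown pooling {pooling!r}")


def wcv_ci(
    wcv_value: float, n_pairs: int, level: float = 0.95
) -> tuple[float, float]:
    """Chi-square confidence interval for a wCV estimated from n pairs.

    Uses df = n_pairs - 1 degrees of freedom; the interval multiplies the
    point estimate by sqrt(df / chi2_{1-a/2, df}) and sqrt(df / chi2_{a/2, df}).
    """
    if n_pairs < 2:
        raise ValueError("confidence interval requires n_pairs >= 2")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    df = n_pairs - 1
    alpha = 1.0 - level
    lo = wcv_value * np.sqrt(df / stats.chi2.ppf(1.0 - alpha / 2.0, df))
    hi = wcv_value * np.sqrt(df / stats.chi2.ppf(alpha / 2.0, df))
    return float(lo), float(hi)


def wcv_with_ci(
    pairs: PairedVolumes, level: float = 0.95, pooling: str = "relative"
) -> WcvResult:
    point = wcv(pairs, pooling=pooling)
    lo, hi = wcv_ci(point, pairs.n, level=level)
    return WcvResult(wcv=point, ci_low=lo, ci_high=hi, n_pairs=pairs.n)


def bland_altman(pairs: PairedVolumes) -> BlandAltmanResult:
    """Bland-Altman bias and 95% limits of agreement for paired volumes.

    Differences are retest - test for repeatability input; for accuracy-mode
    input, load the candidate series as ``retest`` and the reference as
    ``test`` so positive bias means over-estimation versus the reference.
    """
    if pairs.n < 2:
        raise ValueError("Bland-Altman analysis requires n >= 2")
    d = pairs.differences
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        sd_diff=sd,
        n=pairs.n,
    )


def plot_bland_altman(
    pairs: PairedVolumes,
    path,
    title: str = "Bland-Altman",
    units: str = "mm$^3$",
) -> BlandAltmanResult:
    """Write a Bland-Altman plot (solid bias line, dashed 95% LOA) and
    return the underlying statistics."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = bland_altman(pairs)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(pairs.means, pairs.differences, s=28, alpha=0.8)
    ax.axhline(res.bias, color="k", lw=1.5)
    for y in (res.loa_low, res.loa_high):
        ax.axhline(y, color="k", lw=1.0, ls="--")
    ax.set_xlabel(f"pair mean ({units})")
    ax.set_ylabel(f"retest - test ({units})")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return res


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation between two volume series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("pearson_r needs two equal-length series of >= 3")
    if np.isclose(x.std(), 0.0) or np.isclose(y.std(), 0.0):
        raise ValueError("pearson_r is undefined for zero-variance input")
    return float(stats.pearsonr(x, y)[0])
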