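"""Shannon-Wiener diversity with bootstrap zone comparison, plus
rank-abundance curve summary statistics.

The Shannon-Wiener index is computed in nats, H = -sum p_i ln p_i over the
positive proportions.  The bootstrap resamples *reads*: B multinomial draws
of the observed depth from the empirical proportions, H recomputed per
draw.  Genome-level resampling of a proportions vector would be degenerate;
read resampling is the standard abundance bootstrap.  Zones are compared
with a Welch two-sample t-test on the two bootstrap H distributions.

A caveat the numbers inherit: bootstrap replicates of one community are not
independent samples, so the t-test on them is anticonservative — it rejects
a true null far more often than the nominal level.  It reproduces the
published procedure and is useful as a descriptive contrast, not as a
calibrated significance test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .tables_io import ViractiveError

__all__ = [
    "DiversityResult",
    "CurveStats",
    "shannon",
    "bootstrap_shannon",
    "compare_diversity",
    "curve_stats",
]


def shannon(values) -> float:
    """Shannon-Wiener index in nats of a non-negative abundance vector."""
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise ViractiveError("Shannon index needs non-negative values")
    total = v.sum()
    if total <= 0:
        raise ViractiveError("Shannon index undefined for an all-zero vector")
    p = v[v > 0] / total
    return float(-(p * np.log(p)).sum())


@dataclass
class DiversityResult:
    zone: str
    assay: str
    H_plugin: float
    bootstrap_mean: float
    bootstrap_sd: float
    B: int
    seed: int | None
    n_reads_resampled: int
    boot_H: np.ndarray = field(repr=False, default=None)


def bootstrap_shannon(counts, B: int = 1000, seed: int | None = None,
                      rng: np.random.Generator | None = None,
                      zone: str = "", assay: str = "") -> DiversityResult:
    """Bootstrap the Shannon index by multinomial read resampling.

    ``counts`` is an integer per-genome read-count vector; each of the B
    resamples draws ``sum(counts)`` reads from the empirical proportions.
    Fully reproducible from ``seed`` (or an explicit ``rng``).
    """
    c = np.asarray(counts, dtype=np.int64)
    total = int(c.sum())
    if total < 1:
        raise ViractiveError("bootstrap needs at least one read")
    if B < 2:
        raise ViractiveError("bootstrap needs B >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    p = c / total
    draws = rng.multinomial(total, p, size=B).astype(float)
    draws /= total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(draws > 0, draws * np.log(draws), 0.0)
    boot_H = -terms.sum(axis=1)
    return DiversityResult(zone, assay, shannon(c), float(boot_H.mean()),
                           float(boot_H.std(ddof=1)), B, seed, total, boot_H)


def compare_diversity(result_a: DiversityResult,
                      result_b: DiversityResult) -> tuple[float, float]:
    """Welch two-sided t on the two bootstrap H distributions.

    Returns ``(t, p)``.  When both distributions are degenerate (zero sd)
    the statistic is undefined and ``(nan, nan)`` is returned, except for
    the trivial equal-mean case which gives ``(0.0, 1.0)``.
    """
    a, b = result_a.boot_H, result_b.boot_H
    if a is None or b is None:
        raise ViractiveError("bootstrap distributions were not retained")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("nan"), float("nan")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


@dataclass
class CurveStats:
    zone: str
    assay: str
    evenness: float          # Pielou J = H / ln S
    top_decile_share: float  # value share of the top ceil(n/10) ranks
    skewness: float          # sample skewness of the value distribution


def curve_stats(values, zone: str = "", assay: str = "") -> CurveStats:
    """Evenness, dominance and skew of a rank-abundance value vector."""
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        raise ViractiveError("curve statistics need at least 2 values")
    s = int((v > 0).sum())
    if s <= 1:
        evenness = 0.0
    else:
        evenness = shannon(v) / np.log(s)
    top = int(np.ceil(n / 10))
    srt = np.sort(v)[::-1]
    total = v.sum()
    share = float(srt[:top].sum() / total) if total > 0 else float("nan")
    skew = 0.0 if np.ptp(v) == 0 else float(stats.skew(v, bias=False))
    return CurveStats(zone, assay, float(evenness), share, skew)
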