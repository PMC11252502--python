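"""Count normalization: RPKM, CPM, TMM scaling factors, and z-scores.

RPKM divides each count by genome length (kb) and library size (millions),
so it is comparable across genomes and samples of one assay.  TMM (trimmed
mean of M-values) estimates a per-sample scaling factor that corrects for
composition bias: a doubly trimmed, precision-weighted mean of gene-wise
log2 ratios against a reference sample.  "TMM values" downstream are
counts-per-million computed on the effective library size (library size x
TMM factor).

The TMM recipe implemented here, in full:

1. reference sample = the sample whose 75th-percentile CPM is closest to the
   mean of all samples' 75th-percentile CPMs;
2. for sample k vs reference r, over genes with positive counts in both:
   ``M_g = log2((y_gk/N_k)/(y_gr/N_r))`` and
   ``A_g = 0.5*log2((y_gk/N_k)*(y_gr/N_r))``;
3. double trimming, 30% on M and 5% on A by default: keep gene g iff
   ``trim <= rank(g)/(n+1) <= 1-trim`` on both statistics (average ranks, so
   ties keep or drop all tied members together);
4. ``f_k = 2**(sum(w_g M_g)/sum(w_g))`` with precision weights
   ``w_g = (N_k-y_gk)/(N_k y_gk) + (N_r-y_gr)/(N_r y_gr)``;
5. rescale all factors to geometric mean 1 (the reference has factor 1
   before rescaling).

If fewer than 10 genes survive the trimming, the factor falls back to the
unweighted mean of the untrimmed M values (with a warning).  Genes with a
zero count in either the sample or the reference are excluded from M/A (no
pseudocounts): the log-ratio is undefined there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .tables_io import CountTable, ViractiveError

__all__ = [
    "NormalizedTable",
    "library_sizes",
    "rpkm",
    "cpm",
    "tmm_factors",
    "tmm_normalize",
    "zscore_across_zones",
]


@dataclass
class NormalizedTable:
    """Normalized expression values plus the per-sample factors behind them."""

    values: pd.DataFrame
    method: str  # RPKM | CPM | TMM
    library_size: pd.Series
    tmm_factor: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        if self.tmm_factor is None:
            self.tmm_factor = pd.Series(1.0, index=self.library_size.index)

    @property
    def effective_library_size(self) -> pd.Series:
        return self.library_size * self.tmm_factor

    def factor_table(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "library_size": self.library_size,
            "tmm_factor": self.tmm_factor,
            "effective_library_size": self.effective_library_size,
        })
        df.index.name = "sample_id"
        return df


def library_sizes(counts: CountTable | pd.DataFrame, *, warn_zero=True) -> pd.Series:
    """Per-sample totals of raw counts.  All-zero samples are flagged."""
    df = counts.counts if isinstance(counts, CountTable) else counts
    totals = df.sum(axis=0).astype(np.int64)
    if warn_zero and (totals == 0).any():
        zero = list(totals.index[totals == 0])
        warnings.warn(f"samples with zero total counts: {zero}", stacklevel=2)
    totals.name = "library_size"
    return totals


def rpkm(counts: CountTable) -> NormalizedTable:
    """Reads per kilobase of genome per million mapped reads."""
    totals = library_sizes(counts, warn_zero=False)
    if (totals == 0).any():
        s = totals.index[totals == 0][0]
        raise ViractiveError(f"sample {s!r} has zero library size; RPKM undefined")
    kb = counts.lengths.to_numpy()[:, None] / 1e3
    per_million = totals.to_numpy()[None, :] / 1e6
    vals = counts.counts.to_numpy() / (kb * per_million)
    return NormalizedTable(
        pd.DataFrame(vals, index=counts.counts.index, columns=counts.counts.columns),
        "RPKM", totals)


def cpm(counts: CountTable | pd.DataFrame, factors: pd.Series | None = None,
        method: str = "CPM") -> NormalizedTable:
    """Counts per million, optionally on effective (TMM-scaled) library sizes."""
    df = counts.counts if isinstance(counts, CountTable) else counts
    totals = library_sizes(df, warn_zero=False)
    if factors is None:
        factors = pd.Series(1.0, index=totals.index)
    eff = totals * factors
    if (eff == 0).any():
        s = eff.index[eff == 0][0]
        raise ViractiveError(f"sample {s!r} has zero effective library size")
    vals = df.to_numpy() / (eff.to_numpy()[None, :] / 1e6)
    return NormalizedTable(pd.DataFrame(vals, index=df.index, columns=df.columns),
                           method, totals, factors)


def _tmm_one(y_k, y_r, N_k, N_r, trim_M, trim_A, weighted) -> float:
    """TMM factor of one sample against the reference, before rescaling."""
    mask = (y_k > 0) & (y_r > 0)
    if not mask.any():
        raise ViractiveError("no gene has positive counts in both sample and reference")
    yk, yr = y_k[mask].astype(float), y_r[mask].astype(float)
    pk, pr = yk / N_k, yr / N_r
    M = np.log2(pk / pr)
    A = 0.5 * np.log2(pk * pr)
    n = M.size
    rM = rankdata(M, method="average") / (n + 1)
    rA = rankdata(A, method="average") / (n + 1)
    keep = (rM >= trim_M) & (rM <= 1 - trim_M) & (rA >= trim_A) & (rA <= 1 - trim_A)
    if keep.sum() < 10:
        warnings.warn(
            f"only {int(keep.sum())} genes survive TMM trimming; "
            "falling back to the unweighted mean of untrimmed M values",
            stacklevel=3)
        return float(2.0 ** M.mean())
    Mk, ykk, yrk = M[keep], yk[keep], yr[keep]
    if weighted:
        w = (N_k - ykk) / (N_k * ykk) + (N_r - yrk) / (N_r * yrk)
        if w.sum() <= 0:
            return float(2.0 ** Mk.mean())
        return float(2.0 ** (np.sum(w * Mk) / np.sum(w)))
    return float(2.0 ** Mk.mean())


def tmm_factors(counts: CountTable | pd.DataFrame, trim_m: float = 0.30,
                trim_a: float = 0.05, weighted: bool = True,
                reference: str = "auto") -> pd.Series:
    """Per-sample TMM scaling factors, rescaled to geometric mean 1."""
    df = counts.counts if isinstance(counts, CountTable) else counts
    if df.shape[1] < 2:
        raise ViractiveError("TMM needs at least 2 samples")
    totals = library_sizes(df, warn_zero=False)
    if (totals == 0).any():
        s = totals.index[totals == 0][0]
        raise ViractiveError(f"sample {s!r} has zero library size; TMM undefined")
    arr = df.to_numpy().astype(float)
    N = totals.to_numpy().astype(float)
    cpm_arr = arr / (N[None, :] / 1e6)
    q75 = np.quantile(cpm_arr, 0.75, axis=0)
    if reference == "auto":
        ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    else:
        if reference not in df.columns:
            raise ViractiveError(f"reference sample {reference!r} not found")
        ref_idx = list(df.columns).index(reference)
    f = np.ones(df.shape[1])
    for k in range(df.shape[1]):
        if k == ref_idx:
            continue
        f[k] = _tmm_one(arr[:, k], arr[:, ref_idx], N[k], N[ref_idx],
                        trim_m, trim_a, weighted)
    f = f / np.exp(np.mean(np.log(f)))
    return pd.Series(f, index=df.columns, name="tmm_factor")


def tmm_normalize(counts: CountTable | pd.DataFrame, **kwargs) -> NormalizedTable:
    """TMM-normalized expression: CPM on effective library sizes."""
    factors = tmm_factors(counts, **kwargs)
    return cpm(counts, factors, method="TMM")


def zscore_across_zones(values) -> np.ndarray:
    """Across-zone z-scores (sample sd, ddof=1); constant input maps to zeros."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ViractiveError("z-scores need values from at least 2 zones")
    if not np.isfinite(x).all():
        raise ViractiveError("z-scores need finite values")
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd
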