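"""Per-zone activity classification of viral genomes.

Paired DNA (abundance) and RNA (activity) read mapping gives every genome
two RPKM values per zone.  Classification proceeds in four steps:

1. rank genomes on each axis (rank 1 = largest, average ranks for ties);
2. find the rank where each sorted RPKM curve flatlines and mark genomes
   past both cutoffs as ``low_nonactive`` — these are the genomes the data
   cannot distinguish from undetected;
3. agglomeratively cluster the remaining genomes on a one-dimensional
   activity:abundance ratio (Euclidean distance, tree cut into k=3 groups);
4. label the groups ``highly_active`` / ``active_abundant`` /
   ``abundant_nonactive`` by their mean RPKM activity:abundance ratio.

The ratio used for clustering is configurable: ``rpkm`` (default) uses
log2((activity_rpkm+eps)/(abundance_rpkm+eps)); ``rank`` uses
log2((rank_abundance+0.5)/(rank_activity+0.5)).  Either way, positive means
more active than abundant and the scale is symmetric around zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .config import ClassConfig
from .normalization import rpkm
from .tables_io import CountTable, ViractiveError

CATEGORIES = ("highly_active", "active_abundant", "abundant_nonactive",
              "low_nonactive")

PROFILE_COLUMNS = ("genome_id", "zone", "abundance_rpkm", "activity_rpkm",
                   "rank_abundance", "rank_activity", "ratio", "category",
                   "rpkm_ratio")

__all__ = [
    "CATEGORIES",
    "PROFILE_COLUMNS",
    "CutoffResult",
    "ZoneClassification",
    "rank_values",
    "flatline_cutoff",
    "apply_lowclass",
    "cluster_ratios",
    "refine_cut",
    "label_groups",
    "classify_zone",
    "global_category_union",
]


def rank_values(values, descending: bool = True) -> np.ndarray:
    """Rank a vector (1 = largest by default); ties get average ranks."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ViractiveError("cannot rank an empty vector")
    if not np.isfinite(x).all():
        raise ViractiveError("cannot rank non-finite values")
    return rankdata(-x if descending else x, method="average")


@dataclass
class CutoffResult:
    zone: str
    axis: str  # abundance | activity
    cutoff_rank: int
    window_used: int
    tolerance_used: float


def flatline_cutoff(sorted_rpkm, window: int = 10, rel_tol: float = 0.01,
                    zone: str = "", axis: str = "") -> CutoffResult:
    """First rank where the descending curve has flattened out.

    The cutoff is the smallest rank ``r`` such that every successive
    decrement within ranks ``[r, r+window]`` is at most
    ``rel_tol * max(sorted_rpkm)``; if no rank qualifies the cutoff is ``n``
    (nothing excluded).  ``rel_tol=0`` demands a literal plateau.
    """
    v = np.asarray(sorted_rpkm, dtype=float)
    n = v.size
    if n < window + 1:
        raise ViractiveError(f"need at least window+1={window + 1} values, got {n}")
    if np.any(np.diff(v) > 0):
        raise ViractiveError("flatline_cutoff expects a descending vector")
    tol = rel_tol * (v[0] if n else 0.0)
    dec = -np.diff(v)  # dec[i] = v[i] - v[i+1] >= 0
    flat = dec <= tol
    cutoff = n
    # windows of `window` successive decrements starting at rank r (1-based)
    run = np.convolve(flat.astype(int), np.ones(window, dtype=int), "valid")
    hits = np.nonzero(run == window)[0]
    if hits.size:
        cutoff = int(hits[0]) + 1
    return CutoffResult(zone, axis, cutoff, window, tol)


def apply_lowclass(rank_abundance, rank_activity, cutoff_abundance: CutoffResult,
                   cutoff_activity: CutoffResult) -> np.ndarray:
    """Boolean mask: genome is low/non-active iff past BOTH flatline cutoffs."""
    ra = np.asarray(rank_abundance, dtype=float)
    rc = np.asarray(rank_activity, dtype=float)
    return (ra >= cutoff_abundance.cutoff_rank) & (rc >= cutoff_activity.cutoff_rank)


# -- 1-D agglomerative clustering -------------------------------------

def _lance_williams_cut(x: np.ndarray, k: int, linkage: str) -> np.ndarray:
    """Agglomerate sorted-order points; deterministic tie-breaking.

    Clusters occupy the slot of their smallest member index; among
    equal-distance pairs the lexicographically smallest (i, j) merges first.
    """
    n = x.size
    D = np.abs(x[:, None] - x[None, :]).astype(float)
    if linkage == "ward":
        D = D ** 2 / 2.0
    D[np.tril_indices(n)] = np.inf  # only the upper triangle is live
    size = np.ones(n)
    parent = np.arange(n)
    for _ in range(n - k):
        i, j = np.unravel_index(np.argmin(D), D.shape)
        ni, nj = size[i], size[j]
        dij = D[i, j]
        # gather distances of every cluster m to i and to j (live side only)
        dim = np.minimum(D[i, :], D[:, i])
        djm = np.minimum(D[j, :], D[:, j])
        if linkage == "average":
            new = (ni * dim + nj * djm) / (ni + nj)
        elif linkage == "complete":
            new = np.maximum(dim, djm)
        else:  # ward (Lance-Williams on squared half-distances)
            new = ((size + ni) * dim + (size + nj) * djm - size * dij) / (size + ni + nj)
        new[i] = np.inf
        new[j] = np.inf
        # merged cluster lives at slot i (its smallest member index)
        D[i, i + 1:] = new[i + 1:]
        D[:i, i] = new[:i]
        D[j, :] = np.inf
        D[:, j] = np.inf
        size[i] = ni + nj
        parent[parent == j] = i
    # renumber groups 1..k in order of first (smallest) member index
    order: dict = {}
    labels = np.empty(n, dtype=int)
    for idx in range(n):
        root = parent[idx]
        if root not in order:
            order[root] = len(order) + 1
        labels[idx] = order[root]
    return labels


def cluster_ratios(ratios, k: int = 3, linkage: str = "average") -> np.ndarray:
    """Cut a 1-D Euclidean agglomerative tree into exactly k groups.

    The points are canonically sorted by value before agglomeration, so the
    result is invariant to input order (up to group relabeling).  Group ids
    are 1..k, numbered by the input order of first appearance.
    """
    x = np.asarray(ratios, dtype=float)
    if linkage not in ("average", "complete", "ward"):
        raise ViractiveError(f"unknown linkage {linkage!r}")
    n = x.size
    if n == 0:
        raise ViractiveError("cannot cluster an empty ratio vector")
    if n < k:
        warnings.warn(f"fewer than k={k} genomes to cluster; one group returned",
                      stacklevel=2)
        return np.ones(n, dtype=int)
    uniq = np.unique(x)
    if uniq.size == 1:
        if k > 1:
            warnings.warn("all ratios equal; one effective group returned",
                          stacklevel=2)
        return np.ones(n, dtype=int)
    if uniq.size <= k:
        # identical values can never be split deterministically: group by value
        labels_sorted = {v: i for i, v in enumerate(uniq)}
        raw = np.array([labels_sorted[v] for v in x])
    else:
        order = np.argsort(x, kind="stable")
        lab_sorted = _lance_williams_cut(x[order], k, linkage)
        raw = np.empty(n, dtype=int)
        raw[order] = lab_sorted
    out = np.empty(n, dtype=int)
    seen: dict = {}
    for idx, g in enumerate(raw):
        if g not in seen:
            seen[g] = len(seen) + 1
        out[idx] = seen[g]
    return out


def refine_cut(values, groups, max_iter: int = 100) -> np.ndarray:
    """Nearest-centroid refinement of a tree cut (1-D, deterministic).

    A k-group tree cut fixes *which* genomes seed each group, but on noisy
    one-dimensional data the cut boundary can sit away from the midpoint
    between group centers.  Reassigning each point to its nearest group mean
    and iterating to convergence (a k-means pass initialized from the cut)
    places every boundary halfway between adjacent centers, which removes
    that wobble without changing the number of groups.  If a reassignment
    would empty a group the previous labeling is kept.
    """
    x = np.asarray(values, dtype=float)
    lab = np.asarray(groups).copy()
    ids = sorted(set(lab.tolist()))
    if len(ids) < 2:
        return lab
    for _ in range(max_iter):
        centers = np.array([x[lab == g].mean() for g in ids])
        nearest = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        new = np.array([ids[i] for i in nearest])
        if len(set(new.tolist())) < len(ids):
            break  # refinement would drop a group; keep the last labeling
        if (new == lab).all():
            break
        lab = new
    return lab


def label_groups(groups, rpkm_ratio, activity_rpkm) -> dict:
    """Map group id -> category label by mean RPKM activity:abundance ratio.

    The group with the largest mean ratio is ``highly_active``, the smallest
    ``abundant_nonactive``, anything between ``active_abundant``; ties are
    broken toward the group with the larger mean activity RPKM.  A group
    whose activity is identically zero can only be ``abundant_nonactive``.
    """
    groups = np.asarray(groups)
    rr = np.asarray(rpkm_ratio, dtype=float)
    act = np.asarray(activity_rpkm, dtype=float)
    ids = sorted(set(groups.tolist()))
    stats = []
    for g in ids:
        m = groups == g
        stats.append((g, rr[m].mean(), act[m].mean()))
    stats.sort(key=lambda t: (t[1], t[2]), reverse=True)
    labels: dict = {}
    for pos, (g, _, act_mean) in enumerate(stats):
        if act_mean == 0.0:
            labels[g] = "abundant_nonactive"
        elif pos == 0:
            labels[g] = "highly_active"
        elif pos == len(stats) - 1:
            labels[g] = "abundant_nonactive"
        else:
            labels[g] = "active_abundant"
    return labels


@dataclass
class ZoneClassification:
    zone: str
    profile: pd.DataFrame
    cutoff_abundance: CutoffResult
    cutoff_activity: CutoffResult


def _zone_mean_rpkm(counts: CountTable, zone: str, assay: str) -> pd.Series:
    samples = counts.samples(zone=zone, assay=assay)
    if not samples:
        raise ViractiveError(f"no {assay} sample for zone {zone!r}")
    # a sample with zero mapped reads carries zero signal for every genome
    # (e.g. a zone whose RNA library is empty); RPKM itself would be 0/0
    totals = counts.counts[samples].sum(axis=0)
    live = [s for s in samples if totals[s] > 0]
    if not live:
        return pd.Series(0.0, index=counts.counts.index)
    sub = counts.subset_samples(live)
    return rpkm(sub).values[live].mean(axis=1)


def classify_zone(count_dna: CountTable, count_rna: CountTable, zone: str,
                  config: ClassConfig | None = None) -> ZoneClassification:
    """Full four-way classification of one zone from paired count tables."""
    cfg = config or ClassConfig()
    if list(count_dna.counts.index) != list(count_rna.counts.index):
        raise ViractiveError("DNA and RNA tables must share the genome universe")
    ab = _zone_mean_rpkm(count_dna, zone, "DNA")
    act = _zone_mean_rpkm(count_rna, zone, "RNA")
    genomes = ab.index
    n = len(genomes)
    rank_ab = rank_values(ab.to_numpy())
    rank_act = rank_values(act.to_numpy())
    window = min(cfg.window, n - 1)
    cut_ab = flatline_cutoff(np.sort(ab.to_numpy())[::-1], window, cfg.rel_tol,
                             zone, "abundance")
    cut_act = flatline_cutoff(np.sort(act.to_numpy())[::-1], window, cfg.rel_tol,
                              zone, "activity")
    low = apply_lowclass(rank_ab, rank_act, cut_ab, cut_act)

    eps = cfg.epsilon
    rpkm_ratio = (act.to_numpy() + eps) / (ab.to_numpy() + eps)
    rank_ratio = np.log2((rank_ab + 0.5) / (rank_act + 0.5))

    category = np.empty(n, dtype=object)
    category[low] = "low_nonactive"
    rest = ~low
    if rest.any():
        ab_r, act_r = ab.to_numpy()[rest], act.to_numpy()[rest]
        # degenerate ratios cannot inform the tree cut: a genome with zero
        # activity can only be abundant_nonactive, and one detected in RNA but
        # not DNA is maximal-contrast highly active.
        zero_act = act_r == 0.0
        zero_ab = (ab_r == 0.0) & (act_r > 0.0)
        clusterable = ~(zero_act | zero_ab)
        sub = np.full(clusterable.sum(), "", dtype=object)
        if clusterable.any():
            if cfg.ratio_basis == "rpkm":
                basis = np.log2(rpkm_ratio[rest][clusterable])
            else:
                basis = rank_ratio[rest][clusterable]
            groups = cluster_ratios(basis, cfg.k, cfg.linkage)
            if cfg.refine:
                groups = refine_cut(basis, groups)
            labels = label_groups(groups, rpkm_ratio[rest][clusterable],
                                  act_r[clusterable])
            sub = np.array([labels[g] for g in groups], dtype=object)
        rest_cat = np.empty(rest.sum(), dtype=object)
        rest_cat[zero_act] = "abundant_nonactive"
        rest_cat[zero_ab] = "highly_active"
        rest_cat[clusterable] = sub
        category[rest] = rest_cat

    profile = pd.DataFrame({
        "genome_id": genomes,
        "zone": zone,
        "abundance_rpkm": ab.to_numpy(),
        "activity_rpkm": act.to_numpy(),
        "rank_abundance": rank_ab,
        "rank_activity": rank_act,
        "ratio": rank_ratio,
        "category": category,
        "rpkm_ratio": rpkm_ratio,
    })
    return ZoneClassification(zone, profile, cut_ab, cut_act)


def global_category_union(profiles) -> dict:
    """Deduplicated union of genomes per category across per-zone profiles.

    ``profiles`` is an iterable of ActivityProfile DataFrames (or
    ZoneClassification objects).  Returns {category: sorted genome list}.
    """
    union: dict = {c: set() for c in CATEGORIES}
    for p in profiles:
        df = p.profile if isinstance(p, ZoneClassification) else p
        for cat in CATEGORIES:
            union[cat].update(df.loc[df["category"] == cat, "genome_id"])
    return {c: sorted(v) for c, v in union.items()}
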