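"""Zone-specific expression calls, top-gene reports, and marker scoring.

A virus is *zone-specific* when its total TMM-normalized expression at one
zone is more than ``fold`` (default 10x) higher than the other zones
combined AND that total exceeds ``min_tmm`` (default 1).  Both inequalities
are strict, so a genome sitting exactly at 10x the other zones combined is
not called.  With fold >= 1 at most one zone can ever be called per genome.

Marker scoring (e.g. phage integrase as the transcriptional marker of
lysogeny) normalizes raw marker reads for library size and for each zone's
share of total viral activity:

    score_z = (marker_reads_z / library_size_z) / (activity_z / sum_z activity_z)

which leaves pairwise zone ratios invariant to globally rescaling either the
library sizes or the activity totals.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .normalization import zscore_across_zones
from .tables_io import GeneTable, ViractiveError

__all__ = [
    "call_zone_specific",
    "top_genes",
    "marker_zone_ratios",
    "amg_summary",
]


def call_zone_specific(tmm_totals: pd.DataFrame, fold: float = 10.0,
                       min_tmm: float = 1.0) -> pd.DataFrame:
    """Apply the zone-specificity rule to a genome x zone TMM-totals table.

    Returns a DataFrame indexed by genome id with the per-zone totals,
    ``called_zone`` ("" when no zone qualifies), ``fold`` (best zone vs the
    others combined; inf when the others are all zero) and
    ``passed_min_tmm`` for the best zone.
    """
    if tmm_totals.shape[1] < 2:
        raise ViractiveError("zone-specificity needs at least 2 zones")
    vals = tmm_totals.to_numpy(dtype=float)
    total = vals.sum(axis=1)
    best = np.argmax(vals, axis=1)
    best_val = vals[np.arange(len(vals)), best]
    others = total - best_val
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(others > 0, best_val / others,
                         np.where(best_val > 0, np.inf, 0.0))
    passed_min = best_val > min_tmm
    called = (ratio > fold) & passed_min
    out = tmm_totals.copy()
    out["called_zone"] = np.where(called, tmm_totals.columns.to_numpy()[best], "")
    out["fold"] = ratio
    out["passed_min_tmm"] = passed_min
    out.index.name = "genome_id"
    return out


def top_genes(gene_expr: pd.DataFrame, genes: GeneTable, group,
              n: int = 20, samples=None) -> pd.DataFrame:
    """Rank a genome group's genes by their summed normalized expression.

    ``gene_expr`` holds normalized values (RPKM or TMM) per gene x sample;
    the sum runs over ``samples`` (default: all columns).  Ties are broken
    lexicographically by gene id, and the top-n list is therefore always a
    prefix of the top-(n+1) list.
    """
    group = set(group)
    if not group:
        raise ViractiveError("top_genes needs a non-empty genome group")
    member = genes.table["genome_id"].isin(group)
    gene_ids = genes.table.index[member]
    cols = list(samples) if samples is not None else list(gene_expr.columns)
    sums = gene_expr.loc[gene_ids, cols].sum(axis=1)
    ranked = pd.DataFrame({
        "sum_value": sums,
        "genome_id": genes.table.loc[gene_ids, "genome_id"],
        "functional_label": genes.table.loc[gene_ids, "functional_label"],
        "category_label": genes.table.loc[gene_ids, "category_label"],
    })
    # stable sort on a lexicographically pre-sorted index breaks ties by gene id
    ranked = ranked.sort_index().sort_values("sum_value", ascending=False,
                                             kind="stable")
    if n > len(ranked):
        warnings.warn(f"requested top {n} genes but only {len(ranked)} available",
                      stacklevel=2)
    out = ranked.head(n)
    out.index.name = "gene_id"
    return out


def marker_zone_ratios(genes: GeneTable, sample_map: pd.DataFrame,
                       marker_tag: str, viral_activity_totals: pd.Series,
                       library_sizes: pd.Series) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-zone normalized marker scores and their pairwise fold ratios.

    ``viral_activity_totals`` is indexed by zone (total viral activity TMM);
    ``library_sizes`` by RNA sample id (summed per zone here).  Returns
    ``(scores, ratios)`` where ratios[i, j] = score_i / score_j; zones with
    an undefined score are excluded from the ratio matrix.
    """
    marker_genes = genes.genes_with_flag(marker_tag)
    zones = list(viral_activity_totals.index)
    if not marker_genes:
        warnings.warn(f"marker tag {marker_tag!r} not present in any gene",
                      stacklevel=2)
        empty = pd.DataFrame(columns=["marker_tag", "raw_reads", "library_size",
                                      "activity_total", "score"])
        empty.index.name = "zone"
        return empty, pd.DataFrame(index=zones, columns=zones, dtype=float)
    rna_samples = {z: [s for s in genes.sample_ids
                       if s in sample_map.index
                       and sample_map.loc[s, "zone"] == z
                       and sample_map.loc[s, "assay"] == "RNA"]
                   for z in zones}
    counts = genes.counts()
    act_share_denom = float(viral_activity_totals.sum())
    rows = []
    for z in zones:
        reads = int(counts.loc[marker_genes, rna_samples[z]].to_numpy().sum())
        lib = float(library_sizes.reindex(rna_samples[z]).sum())
        act = float(viral_activity_totals[z])
        if lib > 0 and act > 0 and act_share_denom > 0:
            score = (reads / lib) / (act / act_share_denom)
        else:
            score = np.nan
        rows.append((z, marker_tag, reads, lib, act, score))
    scores = pd.DataFrame(rows, columns=["zone", "marker_tag", "raw_reads",
                                         "library_size", "activity_total",
                                         "score"]).set_index("zone")
    ratios = pd.DataFrame(np.nan, index=zones, columns=zones, dtype=float)
    for a in zones:
        for b in zones:
            sa, sb = scores.loc[a, "score"], scores.loc[b, "score"]
            if np.isfinite(sa) and np.isfinite(sb) and sb > 0:
                ratios.loc[a, b] = sa / sb
    return scores, ratios


def amg_summary(genes: GeneTable, tmm_values: pd.DataFrame,
                sample_map: pd.DataFrame, zones=None,
                amg_prefix: str = "AMG:") -> pd.DataFrame:
    """Across-zone z-scores of summed TMM expression per AMG pathway.

    Pathway membership comes from ``AMG:<pathway>`` marker flags.  A pathway
    expressed in no zone yields an all-zero row.
    """
    if zones is None:
        zones = list(dict.fromkeys(sample_map["zone"]))
    if len(zones) < 2:
        raise ViractiveError("AMG z-scores need at least 2 zones")
    rna = {z: [s for s in tmm_values.columns
               if sample_map.loc[s, "zone"] == z
               and sample_map.loc[s, "assay"] == "RNA"] for z in zones}
    pathways: dict = {}
    for gid in genes.table.index:
        for tag in genes.flags(gid):
            if tag.startswith(amg_prefix):
                pathways.setdefault(tag[len(amg_prefix):], []).append(gid)
    rows = {}
    for pw in sorted(pathways):
        sums = np.array([float(tmm_values.loc[pathways[pw], rna[z]].to_numpy().sum())
                         for z in zones])
        rows[pw] = zscore_across_zones(sums)
    out = pd.DataFrame(rows, index=zones).T
    out.index.name = "pathway"
    return out
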