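"""End-to-end orchestration: normalize -> classify -> zone specificity ->
markers/AMGs -> diversity, with a machine-readable run summary.

Every stage is also callable on its own (see :mod:`viractive.cli`); this
module wires them together in the order the analysis requires and writes
one TSV per result table plus ``run_summary.json``.  Reruns with identical
inputs and config are byte-identical: no timestamps enter any output, and
all randomness flows from the single configured seed through named
per-zone substreams.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .activity import CATEGORIES, classify_zone, global_category_union
from .config import RunConfig
from .diversity import bootstrap_shannon, compare_diversity, curve_stats
from .normalization import library_sizes, rpkm, tmm_normalize
from .simulate import _substream
from .tables_io import (CountTable, GeneTable, ViractiveError, read_count_table,
                        read_gene_table, write_results)
from .zonespec import amg_summary, call_zone_specific, marker_zone_ratios, top_genes

log = logging.getLogger("viractive")

__all__ = ["PipelineResult", "run_pipeline", "rna_tmm_zone_totals"]


@dataclass
class PipelineResult:
    tables: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    out_dir: Path | None = None


def rna_tmm_zone_totals(count_rna: CountTable, **tmm_kwargs) -> pd.DataFrame:
    """Genome x zone totals of TMM-normalized RNA expression."""
    norm = tmm_normalize(count_rna, **tmm_kwargs)
    zones = count_rna.zones
    cols = {z: norm.values[count_rna.samples(zone=z, assay="RNA")].sum(axis=1)
            for z in zones}
    out = pd.DataFrame(cols)
    out.index.name = "genome_id"
    return out


def _load_inputs(cfg: RunConfig):
    ct_dna = read_count_table(cfg.counts_dna, cfg.sample_map)
    ct_rna = read_count_table(cfg.counts_rna, cfg.sample_map)
    genes = read_gene_table(cfg.genes) if cfg.genes else None
    if genes is not None:
        genes.validate_against(ct_rna)
    return ct_dna, ct_rna, genes


def run_pipeline(config: RunConfig, *, inputs=None) -> PipelineResult:
    """Execute the full analysis; ``inputs`` may supply in-memory tables
    ``(count_dna, count_rna, gene_table_or_None)`` instead of paths."""
    cfg = config
    caught: list = []
    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")
        result = _run(cfg, inputs)
        caught = [f"{w.category.__name__}: {w.message}" for w in wrec]
    result.summary["warnings"] = sorted(set(caught))
    if result.out_dir is not None:
        # rewrite summary with collected warnings for byte-stable reruns
        write_results(result.tables, result.out_dir, config=_echo_config(cfg),
                      seed=cfg.seed, warnings_seen=sorted(set(caught)))
    return result


def _echo_config(cfg: RunConfig) -> dict:
    # the summary lives inside the output directory; echoing that path would
    # make otherwise-identical runs differ byte-wise
    d = cfg.to_dict()
    d.pop("out_dir", None)
    return d


def _run(cfg: RunConfig, inputs) -> PipelineResult:
    stage = "input"
    try:
        if inputs is not None:
            ct_dna, ct_rna, genes = inputs
        else:
            ct_dna, ct_rna, genes = _load_inputs(cfg)
        zones = [z for z in ct_dna.zones if z in set(ct_rna.zones)]
        if not zones:
            raise ViractiveError("no zone has both a DNA and an RNA sample")
        tables: dict = {}

        stage = "normalize"
        log.info("[normalize] TMM per assay over %d genomes", len(ct_dna.genome_ids))
        tmm_kw = dict(trim_m=cfg.tmm.trim_m, trim_a=cfg.tmm.trim_a,
                      weighted=cfg.tmm.weighted, reference=cfg.tmm.reference)
        norm_dna = tmm_normalize(ct_dna, **tmm_kw)
        norm_rna = tmm_normalize(ct_rna, **tmm_kw)
        tables["factors_dna"] = norm_dna.factor_table()
        tables["factors_rna"] = norm_rna.factor_table()

        stage = "classify"
        profiles, cutoffs = [], []
        for z in zones:
            zc = classify_zone(ct_dna, ct_rna, z, cfg.classes)
            profiles.append(zc.profile)
            for c in (zc.cutoff_abundance, zc.cutoff_activity):
                cutoffs.append((c.zone, c.axis, c.cutoff_rank, c.window_used,
                                c.tolerance_used))
        profile_df = pd.concat(profiles, ignore_index=True)
        tables["activity_profiles"] = profile_df
        tables["cutoffs"] = pd.DataFrame(
            cutoffs, columns=["zone", "axis", "cutoff_rank", "window_used",
                              "tolerance_used"])
        counts = (profile_df.groupby(["zone", "category"]).size()
                  .unstack(fill_value=0).reindex(columns=list(CATEGORIES),
                                                 fill_value=0))
        counts.index.name = "zone"
        tables["category_counts"] = counts

        stage = "union"
        union = global_category_union(profiles)
        tables["category_union"] = pd.DataFrame(
            [(c, len(v), ";".join(v)) for c, v in union.items()],
            columns=["category", "n_genomes", "genome_ids"])

        stage = "zonespec"
        totals = rna_tmm_zone_totals(ct_rna, **tmm_kw)[zones]
        calls = call_zone_specific(totals, cfg.zonespec.fold, cfg.zonespec.min_tmm)
        tables["zone_calls"] = calls

        if genes is not None:
            stage = "top_genes"
            gene_counts = genes.counts()
            rna_samples = [s for s in gene_counts.columns
                           if s in ct_rna.sample_map.index
                           and ct_rna.sample_map.loc[s, "assay"] == "RNA"]
            glen = genes.table["gene_length_bp"]
            libs = library_sizes(ct_rna, warn_zero=False)
            gene_rpkm = gene_counts[rna_samples] / (
                glen.to_numpy()[:, None] / 1e3
                * libs.reindex(rna_samples).to_numpy()[None, :] / 1e6)
            try:
                gene_tmm = tmm_normalize(gene_counts[rna_samples], **tmm_kw).values
            except ViractiveError:
                gene_tmm = gene_rpkm
            ha = set(union["highly_active"])
            other = set(ct_rna.genome_ids) - ha
            if ha:
                tables["top_genes_highly_active"] = top_genes(
                    gene_rpkm, genes, ha, cfg.topgenes.n_activity_groups)
            if other:
                tables["top_genes_other"] = top_genes(
                    gene_rpkm, genes, other, cfg.topgenes.n_activity_groups)
            for z in zones:
                grp = set(calls.index[calls["called_zone"] == z])
                if not grp:
                    continue
                zsamples = [s for s in rna_samples
                            if ct_rna.sample_map.loc[s, "zone"] == z]
                basis = gene_tmm if cfg.topgenes.basis == "sum_tmm" else gene_rpkm
                tables[f"top_genes_zone_{z}"] = top_genes(
                    basis, genes, grp, cfg.topgenes.n_zone_groups, zsamples)

            stage = "markers"
            zone_act_totals = totals.sum(axis=0)
            scores, ratios = marker_zone_ratios(genes, ct_rna.sample_map,
                                                "integrase", zone_act_totals,
                                                libs)
            tables["marker_scores"] = scores
            ratios.index.name = "zone"
            tables["marker_ratios"] = ratios

            stage = "amg"
            amg = amg_summary(genes, gene_tmm, ct_rna.sample_map, zones)
            tables["amg_zscores"] = amg

        stage = "diversity"
        div_rows, test_rows, curve_rows = [], [], []
        results = {}
        for ct, assay in ((ct_dna, "DNA"), (ct_rna, "RNA")):
            rpkm_vals = rpkm(ct).values
            for z in zones:
                pooled = ct.counts[ct.samples(zone=z, assay=assay)].sum(axis=1)
                rng = _substream(cfg.seed, f"diversity/{assay}/{z}")
                res = bootstrap_shannon(pooled.to_numpy(),
                                        B=cfg.diversity.bootstraps,
                                        rng=rng, zone=z, assay=assay)
                results[(assay, z)] = res
                div_rows.append((z, assay, res.H_plugin, res.bootstrap_mean,
                                 res.bootstrap_sd, res.B, cfg.seed,
                                 res.n_reads_resampled))
                cs = curve_stats(
                    rpkm_vals[ct.samples(zone=z, assay=assay)].mean(axis=1),
                    zone=z, assay=assay)
                curve_rows.append((z, assay, cs.evenness, cs.top_decile_share,
                                   cs.skewness))
            for i, za in enumerate(zones):
                for zb in zones[i + 1:]:
                    t, p = compare_diversity(results[(assay, za)],
                                             results[(assay, zb)])
                    test_rows.append((za, zb, assay, t, p))
        tables["diversity"] = pd.DataFrame(
            div_rows, columns=["zone", "assay", "H", "boot_mean", "boot_sd",
                               "B", "seed", "n_reads"])
        tables["diversity_tests"] = pd.DataFrame(
            test_rows, columns=["zone_a", "zone_b", "assay", "t", "p"])
        tables["curve_stats"] = pd.DataFrame(
            curve_rows, columns=["zone", "assay", "evenness",
                                 "top_decile_share", "skewness"])

        stage = "write"
        out_dir = Path(cfg.out_dir) if cfg.out_dir else None
        summary = {}
        if out_dir is not None:
            summary = write_results(tables, out_dir, config=_echo_config(cfg),
                                    seed=cfg.seed)
        return PipelineResult(tables, summary, out_dir)
    except ViractiveError as err:
        raise ViractiveError(f"[{stage}] {err}") from err
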