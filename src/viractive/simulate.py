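"""Synthetic brine-pool-style viral communities with known ground truth.

The generator emulates the post-mapping count structure of a paired
metagenome/metatranscriptome study of a stratified community: three zones,
~1200 viral genomes, a strongly left-skewed (log-normal) abundance
distribution, four latent activity categories expressed as per-category
activity multipliers, negative-binomial sampling noise, planted
zone-specific viruses with an expression contrast comfortably above the
10x calling threshold, and per-genome gene sets with integrase-bearing
temperate viruses concentrated in one zone.

Per genome g and zone z, with base abundance lambda_g ~ LogNormal(mu, sigma)
(or a near-zero trace draw when the genome is latent-class low in z):

    DNA mean = lambda_gz * length_g/1e3 * lib_DNA/1e6
    RNA mean = lambda_gz * length_g/1e3 * lib_RNA/1e6 * mult(category_gz)
               [* fold at the focal zone, / fold elsewhere, when planted
                zone-specific]
    counts ~ NegativeBinomial(mean, dispersion)   (variance m + a*m^2)

Gene counts are multinomial splits of the genome's counts proportional to
gene length, so gene and genome tables are mutually consistent.  All
randomness derives from one seed through named substreams, so tables are
bit-reproducible across platforms and iteration orders.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .tables_io import CountTable, GeneTable, ViractiveError, write_count_table, write_table

CATEGORY_ORDER = ("highly_active", "active_abundant", "abundant_nonactive",
                  "low_nonactive")

__all__ = ["CommunitySpec", "Truth", "simulate_community", "make_fixtures",
           "TOY10_EXPECTED_CALLS"]


@dataclass
class CommunitySpec:
    """Parameters of the synthetic community.  Defaults are the study-scale
    conditions used throughout testing; see docs/methods.md for rationale."""

    zones: tuple = ("GR", "OR", "PL")
    n_genomes: int = 1200
    category_mix: dict = field(default_factory=lambda: {
        "highly_active": 0.10, "active_abundant": 0.45,
        "abundant_nonactive": 0.25, "low_nonactive": 0.20})
    abundance_lognormal: tuple = (1.5, 1.5)       # (mu, sigma) of log RPKM-scale
    low_abundance_lognormal: tuple = (-8.0, 0.5)  # trace draw for latent-low
    activity_multiplier: dict = field(default_factory=lambda: {
        "highly_active": 8.0, "active_abundant": 1.0,
        "abundant_nonactive": 0.1, "low_nonactive": 0.05})
    nb_dispersion: float = 0.1
    library_size: dict = field(default_factory=lambda: {"DNA": 2_000_000,
                                                        "RNA": 2_000_000})
    zone_specific_fraction: float = 0.05
    zone_specific_fold: float = 20.0
    genes_per_genome: tuple = (5, 30)
    genome_length: tuple = (10_000, 100_000)
    integrase_fraction: dict = field(default_factory=lambda: {
        "GR": 0.6, "OR": 0.15, "PL": 0.05})
    amg_fraction: float = 0.08
    amg_pathways: tuple = ("sulfur", "methane", "carbohydrate",
                           "nucleotide", "cofactor", "arsenic")
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.category_mix.values()) - 1.0) > 1e-9:
            raise ViractiveError("category_mix proportions must sum to 1")
        if self.n_genomes < 1 or len(self.zones) < 2:
            raise ViractiveError("need >=1 genome and >=2 zones")
        if any(v <= 0 for v in self.library_size.values()):
            raise ViractiveError("library sizes must be positive")
        if self.zone_specific_fold <= 1:
            raise ViractiveError("zone_specific_fold must exceed 1")
        if self.nb_dispersion < 0:
            raise ViractiveError("nb_dispersion must be >= 0")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "CommunitySpec":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("zones", "abundance_lognormal", "low_abundance_lognormal",
                    "genes_per_genome", "genome_length", "amg_pathways"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class Truth:
    """Latent ground truth of a simulated community."""

    table: pd.DataFrame            # per genome: origin, categories, flags
    expected_mean_dna: pd.DataFrame
    expected_mean_rna: pd.DataFrame


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named, platform-stable RNG substream derived from one top seed."""
    digest = hashlib.sha256(name.encode()).digest()
    key = int.from_bytes(digest[:4], "little")
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def _nb_sample(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """NB(mean, a) with variance mean + a*mean^2; a=0 is the noise-free limit."""
    if dispersion == 0:
        return np.rint(mean).astype(np.int64)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p).astype(np.int64)


def simulate_community(spec: CommunitySpec) -> tuple[CountTable, CountTable,
                                                     GeneTable, Truth]:
    """Generate paired DNA/RNA count tables, a gene table and ground truth."""
    spec.validate()
    zones = list(spec.zones)
    n = spec.n_genomes
    genome_ids = [f"vMAG_{i:05d}" for i in range(1, n + 1)]
    mu, sigma = spec.abundance_lognormal
    mu_low, sigma_low = spec.low_abundance_lognormal

    rng_len = _substream(spec.seed, "lengths")
    lengths = rng_len.integers(spec.genome_length[0], spec.genome_length[1] + 1,
                               size=n)
    rng_ab = _substream(spec.seed, "abundance")
    base_lambda = rng_ab.lognormal(mu, sigma, size=n)

    rng_cat = _substream(spec.seed, "category")
    mix = np.array([spec.category_mix[c] for c in CATEGORY_ORDER])
    cats = np.array(CATEGORY_ORDER, dtype=object)
    # one latent category per genome, shared across zones: zone contrast comes
    # only from sampling noise and the explicitly planted zone-specific flags,
    # so incidental genomes never pass the 10x calling rule
    cat_draw = cats[rng_cat.choice(len(cats), size=n, p=mix)]
    category = {z: cat_draw.copy() for z in zones}

    # per-zone lambda: trace draw where the genome is latent-low in that zone
    rng_low = _substream(spec.seed, "low_draw")
    lam = {}
    for z in zones:
        low = category[z] == "low_nonactive"
        lz = base_lambda.copy()
        lz[low] = rng_low.lognormal(mu_low, sigma_low, size=int(low.sum()))
        lam[z] = lz

    # plant zone-specific genomes among those active at their focal zone
    rng_zs = _substream(spec.seed, "zone_specific")
    zs_zone = np.array([""] * n, dtype=object)
    eligible = np.nonzero([
        any(category[z][i] in ("highly_active", "active_abundant") for z in zones)
        for i in range(n)])[0]
    n_zs = int(round(spec.zone_specific_fraction * n))
    picked = rng_zs.choice(eligible, size=min(n_zs, eligible.size), replace=False)
    for i in picked:
        ok = [z for z in zones if category[z][i] in ("highly_active",
                                                     "active_abundant")]
        zs_zone[i] = ok[rng_zs.integers(len(ok))]

    # expected means and counts
    mult = {c: spec.activity_multiplier[c] for c in CATEGORY_ORDER}
    lib_dna = float(spec.library_size["DNA"])
    lib_rna = float(spec.library_size["RNA"])
    kb = lengths / 1e3
    mean_dna, mean_rna = {}, {}
    effective_category = {}
    for z in zones:
        m_dna = lam[z] * kb * (lib_dna / 1e6)
        mults = np.array([mult[c] for c in category[z]])
        fold_adj = np.where(zs_zone == z, spec.zone_specific_fold,
                            np.where(zs_zone != "", 1.0 / spec.zone_specific_fold,
                                     1.0))
        m_rna = lam[z] * kb * (lib_rna / 1e6) * mults * fold_adj
        mean_dna[z], mean_rna[z] = m_dna, m_rna
        # ground truth records the class actually planted in this zone: the
        # zone-specific fold moves a genome's effective activity multiplier,
        # so its per-zone truth is the nearest non-low multiplier class
        eff = category[z].copy()
        nonlow_classes = [c for c in CATEGORY_ORDER if c != "low_nonactive"]
        log_m = {c: np.log(mult[c]) for c in nonlow_classes}
        for i in np.nonzero((zs_zone != "") & (eff != "low_nonactive"))[0]:
            m_eff = np.log(mult[category[z][i]] * fold_adj[i])
            eff[i] = min(nonlow_classes, key=lambda c: abs(m_eff - log_m[c]))
        effective_category[z] = eff

    rng_dna = _substream(spec.seed, "counts_dna")
    rng_rna = _substream(spec.seed, "counts_rna")
    counts_dna = {f"{z}_DNA": _nb_sample(rng_dna, mean_dna[z], spec.nb_dispersion)
                  for z in zones}
    counts_rna = {f"{z}_RNA": _nb_sample(rng_rna, mean_rna[z], spec.nb_dispersion)
                  for z in zones}

    sample_map_dna = pd.DataFrame(
        {"zone": zones, "assay": "DNA"}, index=[f"{z}_DNA" for z in zones])
    sample_map_rna = pd.DataFrame(
        {"zone": zones, "assay": "RNA"}, index=[f"{z}_RNA" for z in zones])
    sample_map_dna.index.name = sample_map_rna.index.name = "sample_id"
    idx = pd.Index(genome_ids, name="genome_id")
    lengths_s = pd.Series(lengths, index=idx, name="length")
    ct_dna = CountTable(pd.DataFrame(counts_dna, index=idx), lengths_s,
                        sample_map_dna)
    ct_rna = CountTable(pd.DataFrame(counts_rna, index=idx), lengths_s,
                        sample_map_rna)

    # genome metadata: zone of origin = a zone where the genome is not latent-low
    rng_origin = _substream(spec.seed, "origin")
    origin = np.empty(n, dtype=object)
    for i in range(n):
        non_low = [z for z in zones if category[z][i] != "low_nonactive"]
        pool = non_low if non_low else zones
        origin[i] = pool[rng_origin.integers(len(pool))]

    genes = _simulate_genes(spec, genome_ids, lengths, category, origin,
                            ct_dna, ct_rna)
    carries_int = genes.table.loc[genes.genes_with_flag("integrase"),
                                  "genome_id"].unique()
    truth_tab = pd.DataFrame({
        "origin_zone": origin,
        **{f"category_{z}": effective_category[z] for z in zones},
        "zone_specific_zone": zs_zone,
        "carries_integrase": [g in set(carries_int) for g in genome_ids],
    }, index=idx)
    truth = Truth(truth_tab,
                  pd.DataFrame(mean_dna, index=idx),
                  pd.DataFrame(mean_rna, index=idx))
    return ct_dna, ct_rna, genes, truth


def _simulate_genes(spec, genome_ids, lengths, category, origin,
                    ct_dna, ct_rna) -> GeneTable:
    zones = list(spec.zones)
    rng_g = _substream(spec.seed, "genes")
    rng_split = _substream(spec.seed, "gene_counts")
    func_vocab = {
        "lysogeny": ("phage integrase", "resolvase", "CI repressor"),
        "structure": ("major capsid protein", "tail fiber", "portal protein"),
        "replication": ("DNA polymerase A", "ribonucleotide reductase",
                        "terminase large subunit", "AAA domain protein"),
        "metabolism": ("virulence-associated protein", "methyltransferase"),
        "unknown": ("hypothetical protein",),
    }
    cat_labels = list(func_vocab)
    records = []
    count_blocks = []
    sample_ids = list(ct_dna.counts.columns) + list(ct_rna.counts.columns)
    lo, hi = spec.genes_per_genome
    for gi, gid in enumerate(genome_ids):
        ng = int(rng_g.integers(lo, hi + 1))
        w = rng_g.dirichlet(np.ones(ng))
        gl = np.maximum((w * lengths[gi]).astype(np.int64), 100)
        is_ha_somewhere = any(category[z][gi] == "highly_active" for z in zones)
        p_int = spec.integrase_fraction.get(origin[gi], 0.0)
        has_int = is_ha_somewhere and (rng_g.random() < p_int)
        has_amg = rng_g.random() < spec.amg_fraction
        amg_pw = spec.amg_pathways[rng_g.integers(len(spec.amg_pathways))]
        for k in range(ng):
            flags = []
            if has_int and k == 0:
                label, catlab = "phage integrase", "lysogeny"
                flags.append("integrase")
            elif has_amg and k == 1:
                label, catlab = f"AMG {amg_pw} pathway protein", "metabolism"
                flags.append(f"AMG:{amg_pw}")
            else:
                catlab = cat_labels[int(rng_g.integers(len(cat_labels)))]
                vocab = func_vocab[catlab]
                label = vocab[int(rng_g.integers(len(vocab)))]
            records.append((f"{gid}_g{k + 1:03d}", gid, int(gl[k]), label,
                            catlab, ";".join(flags)))
        # split genome counts onto genes, proportional to gene length
        p = gl / gl.sum()
        block = np.zeros((ng, len(sample_ids)), dtype=np.int64)
        for sj, s in enumerate(sample_ids):
            tot = int(ct_dna.counts.loc[gid, s]) if s in ct_dna.counts.columns \
                else int(ct_rna.counts.loc[gid, s])
            block[:, sj] = rng_split.multinomial(tot, p)
        count_blocks.append(block)
    meta = pd.DataFrame(records, columns=["gene_id", "genome_id",
                                          "gene_length_bp", "functional_label",
                                          "category_label", "marker_flags"])
    counts = pd.DataFrame(np.vstack(count_blocks), columns=sample_ids)
    table = pd.concat([meta, counts], axis=1).set_index("gene_id")
    return GeneTable(table)


# -- canonical fixtures ------------------------------------------------

#: Hand-applied zone-specificity rule on the toy10 TMM-totals table below:
#: called iff focal > 10 x (sum of others) AND focal > 1, both strict.
TOY10_EXPECTED_CALLS = {
    "tv01": "GR",   # (22, 1, 1): 22 > 20 and 22 > 1
    "tv02": "OR",   # (1, 22, 1)
    "tv03": "",     # (20, 1, 1): 20 = 10 x 2 fails the strict inequality
    "tv04": "",     # (0.9, 0.01, 0.01): passes fold, fails TMM > 1
    "tv05": "",     # (5, 5, 5): no contrast
    "tv06": "",     # (0, 0, 0): nothing expressed
    "tv07": "GR",   # (30, 2, 0.5): 30 > 25
    "tv08": "GR",   # (12, 1, 0.05): 12 > 10.5
    "tv09": "OR",   # (2, 30, 0.9): 30 > 29
    "tv10": "",     # (1, 1, 15): 15 < 20
}

_TOY10_TOTALS = {
    "tv01": (22, 1, 1), "tv02": (1, 22, 1), "tv03": (20, 1, 1),
    "tv04": (0.9, 0.01, 0.01), "tv05": (5, 5, 5), "tv06": (0, 0, 0),
    "tv07": (30, 2, 0.5), "tv08": (12, 1, 0.05), "tv09": (2, 30, 0.9),
    "tv10": (1, 1, 15),
}


def _toy10_tables():
    """Hand-written 10-genome fixture exercising rule boundaries."""
    zones = ("GR", "OR", "PL")
    ids = [f"tv{i:02d}" for i in range(1, 11)]
    idx = pd.Index(ids, name="genome_id")
    lengths = pd.Series([10_000, 20_000, 10_000, 50_000, 10_000, 40_000,
                         10_000, 10_000, 20_000, 30_000], index=idx,
                        name="length")
    # DNA counts: tv03/tv04 tie on GR (rank ties); tv09/tv10 barely abundant
    dna = pd.DataFrame({
        "GR_DNA": [900, 500, 300, 300, 200, 100, 80, 40, 10, 0],
        "OR_DNA": [400, 900, 250, 260, 210, 90, 60, 35, 40, 5],
        "PL_DNA": [300, 200, 150, 150, 500, 60, 30, 20, 15, 60],
    }, index=idx)
    # RNA counts: tv09/tv10 silent everywhere (zero-activity genomes)
    rna = pd.DataFrame({
        "GR_RNA": [2400, 300, 500, 100, 210, 20, 220, 130, 0, 0],
        "OR_RNA": [250, 2600, 240, 90, 200, 15, 25, 20, 0, 0],
        "PL_RNA": [150, 120, 100, 60, 480, 10, 8, 6, 0, 0],
    }, index=idx)
    smap_dna = pd.DataFrame({"zone": zones, "assay": "DNA"},
                            index=pd.Index([f"{z}_DNA" for z in zones],
                                           name="sample_id"))
    smap_rna = pd.DataFrame({"zone": zones, "assay": "RNA"},
                            index=pd.Index([f"{z}_RNA" for z in zones],
                                           name="sample_id"))
    ct_dna = CountTable(dna, lengths, smap_dna)
    ct_rna = CountTable(rna, lengths.copy(), smap_rna)
    genes = _toy10_genes(ids, rna)
    totals = pd.DataFrame(_TOY10_TOTALS, index=list(zones)).T
    totals.index.name = "genome_id"
    return ct_dna, ct_rna, genes, totals


def _toy10_genes(ids, rna) -> GeneTable:
    rows = []
    counts = []
    for gid in ids:
        for k, (label, cat, flags, frac) in enumerate([
                ("phage integrase" if gid == "tv01" else "major capsid protein",
                 "lysogeny" if gid == "tv01" else "structure",
                 "integrase" if gid == "tv01" else "", 0.6),
                ("hypothetical protein", "unknown",
                 "AMG:sulfur" if gid == "tv05" else "", 0.4)]):
            rows.append((f"{gid}_g{k + 1}", gid, 5_000, label, cat, flags))
            counts.append([int(rna.loc[gid, c] * frac) for c in rna.columns])
    meta = pd.DataFrame(rows, columns=["gene_id", "genome_id", "gene_length_bp",
                                       "functional_label", "category_label",
                                       "marker_flags"])
    cdf = pd.DataFrame(counts, columns=list(rna.columns))
    return GeneTable(pd.concat([meta, cdf], axis=1).set_index("gene_id"))


#: marker35: integrase reads chosen at equal activity totals and library
#: sizes so the normalized zone ratios are exactly 455/130 = 3.5 (GR vs OR)
#: and 455/35 = 13 (GR vs PL).
_MARKER35_READS = {"GR": 455, "OR": 130, "PL": 35}


def _marker35_tables():
    zones = ("GR", "OR", "PL")
    meta = pd.DataFrame(
        [("mk_int_1", "mkv01", 1_200, "phage integrase", "lysogeny",
          "integrase")],
        columns=["gene_id", "genome_id", "gene_length_bp", "functional_label",
                 "category_label", "marker_flags"])
    counts = pd.DataFrame([[_MARKER35_READS[z] for z in zones]],
                          columns=[f"{z}_RNA" for z in zones])
    genes = GeneTable(pd.concat([meta, counts], axis=1).set_index("gene_id"))
    smap = pd.DataFrame({"zone": zones, "assay": "RNA"},
                        index=pd.Index([f"{z}_RNA" for z in zones],
                                       name="sample_id"))
    activity_totals = pd.Series([100.0, 100.0, 100.0], index=list(zones),
                                name="activity_total")
    library_sizes = pd.Series([1_000_000.0] * 3,
                              index=[f"{z}_RNA" for z in zones],
                              name="library_size")
    return genes, smap, activity_totals, library_sizes


RECOVERY_SEED = 20_240_614  # embedded seed of the recovery1200 fixture


def make_fixtures(out_dir) -> dict:
    """Write the three canonical fixtures; returns {name: path}."""
    out = Path(out_dir)
    paths = {}

    toy = out / "toy10"
    toy.mkdir(parents=True, exist_ok=True)
    ct_dna, ct_rna, genes, totals = _toy10_tables()
    write_count_table(ct_dna, toy / "counts_dna.tsv", toy / "sample_map_dna.tsv")
    write_count_table(ct_rna, toy / "counts_rna.tsv", toy / "sample_map_rna.tsv")
    smap = pd.concat([ct_dna.sample_map, ct_rna.sample_map])
    smap.index.name = "sample_id"
    write_table(smap, toy / "sample_map.tsv", index_label="sample_id")
    write_table(genes.table, toy / "genes.tsv", index_label="gene_id")
    write_table(totals, toy / "tmm_rna_totals.tsv", index_label="genome_id")
    expected = pd.DataFrame({"called_zone": pd.Series(TOY10_EXPECTED_CALLS)})
    expected.index.name = "genome_id"
    write_table(expected, toy / "expected_zone_calls.tsv", index_label="genome_id")
    paths["toy10"] = toy

    rec = out / "recovery1200"
    rec.mkdir(parents=True, exist_ok=True)
    spec = CommunitySpec(seed=RECOVERY_SEED)
    spec.to_yaml(rec / "community_spec.yaml")
    d, r, g, truth = simulate_community(spec)
    write_count_table(d, rec / "counts_dna.tsv", rec / "sample_map_dna.tsv")
    write_count_table(r, rec / "counts_rna.tsv", rec / "sample_map_rna.tsv")
    smap = pd.concat([d.sample_map, r.sample_map])
    smap.index.name = "sample_id"
    write_table(smap, rec / "sample_map.tsv", index_label="sample_id")
    write_table(g.table, rec / "genes.tsv", index_label="gene_id")
    write_table(truth.table, rec / "truth.tsv", index_label="genome_id")
    paths["recovery1200"] = rec

    mk = out / "marker35"
    mk.mkdir(parents=True, exist_ok=True)
    genes_m, smap_m, act, libs = _marker35_tables()
    write_table(genes_m.table, mk / "genes.tsv", index_label="gene_id")
    write_table(smap_m, mk / "sample_map.tsv", index_label="sample_id")
    write_table(act.to_frame(), mk / "activity_totals.tsv", index_label="zone")
    write_table(libs.to_frame(), mk / "library_sizes.tsv", index_label="sample_id")
    expected = pd.DataFrame({"zone_a": ["GR", "GR"], "zone_b": ["OR", "PL"],
                             "ratio": [3.5, 13.0]})
    write_table(expected, mk / "expected_ratios.tsv")
    paths["marker35"] = mk
    return paths


def toy10() -> tuple[CountTable, CountTable, GeneTable, pd.DataFrame]:
    """In-memory toy10 fixture: (dna, rna, genes, hand TMM totals)."""
    return _toy10_tables()


def marker35():
    """In-memory marker35 fixture: (genes, sample_map, activity_totals, libs)."""
    return _marker35_tables()
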