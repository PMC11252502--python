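# Methods

This note records the model behind each stage of `viractive`, the tunable
parameters with their defaults and rationale, what the synthetic-data
generator does and does not emulate, and the numerical choices that make
runs deterministic.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Inputs and their meaning

The pipeline starts from two genome × sample matrices of raw mapped-read
counts: a DNA (metagenomic) matrix measuring **abundance** and an RNA
(metatranscriptomic) matrix measuring **activity**, one sample per
(zone, assay) at minimum.  Counts are treated as opaque non-negative
integers — whether the upstream mapper counted reads or read pairs does not
affect any statistic used here.  Genome lengths ride in the count table
(or come from FASTA) because RPKM needs them adjacent to counts.  Gene
annotations, including marker flags (`integrase`, `AMG:<pathway>`), arrive
as an input table: annotation is upstream of this package.

## Normalization

**RPKM** — count / ((length/10³) × (library/10⁶)) — removes genome length
and sequencing depth, and is the scale for ranks, rank-abundance curves and
the activity:abundance ratio.

**TMM** estimates a per-sample scaling factor correcting composition bias
(a few very large features dragging down everything else's
counts-per-million).  The recipe, implemented from first principles:

1. reference sample = the one whose 75th-percentile CPM is closest to the
   mean of all samples' 75th-percentile CPMs;
2. per gene g positive in both sample k and reference r:
   M_g = log2((y_gk/N_k)/(y_gr/N_r)), A_g = ½ log2((y_gk/N_k)(y_gr/N_r));
3. double trimming: keep g iff trim_M ≤ rank(M_g)/(n+1) ≤ 1−trim_M and the
   analogous condition on A, with average ranks so tied genes are kept or
   dropped together; defaults trim_M = 0.30, trim_A = 0.05 — the canonical
   published defaults, the only reproducible reading when a study names
   only "TMM";
4. f_k = 2^(Σ w_g M_g / Σ w_g), precision weights
   w_g = (N_k−y_gk)/(N_k y_gk) + (N_r−y_gr)/(N_r y_gr) (delta-method
   inverse variances of M_g);
5. rescale so the geometric mean of all factors is 1.

Genes with a zero count in sample or reference are excluded (no
pseudocounts): the log-ratio is undefined there.  If fewer than 10 genes
survive trimming, the factor falls back to the unweighted mean of the
untrimmed M values with a warning — small panels simply cannot support
30% + 5% double trimming.  "TMM values" downstream are CPM on the effective
library size N_k·f_k.  DNA and RNA libraries are normalized separately by
default (they are different molecule populations; a config switch exists
but the pipeline never mixes assays in one factor computation).

Two exactness caveats, asserted as such in the tests: the trimmed weighted
mean is invariant to rescaling one sample's counts only under unit weights
(precision weights scale by 1/c on one side of each pair), and the doubly
trimmed estimator carries a small shrink-toward-reference bias under
one-sided contamination (~1–2% at 5% contaminated genes), which is why the
planted-factor recovery experiment is checked to 5% rather than to noise
level.

## Per-zone activity classification

Per zone, every genome gets abundance and activity RPKM (mean over the
zone's samples of each assay), ranks on both axes (1 = largest, average
ranks for ties), and then:

**Flatline cutoff.**  The sorted curve's cutoff is the smallest rank r such
that every successive decrement within ranks [r, r+window] is
≤ rel_tol × max(curve).  A genome past the cutoff on *both* axes is
`low_nonactive`: the data cannot distinguish it from undetected.
Operation defaults are window = 10, rel_tol = 0.01; the *pipeline* default
is rel_tol = 0 (strict plateau).  The reason is structural: a descending
curve over n genomes has average decrement max/n, so for n beyond a few
hundred a tolerance expressed as a fraction of the peak is met almost
immediately and the cutoff collapses to the top of the curve regardless of
the data.  What a large mapped-read dataset actually has is a literal
plateau — the block of zero (and tied) counts — and rel_tol = 0 finds
exactly that.  On small curves with a genuine flat tail the two settings
agree.

**Ratio and clustering.**  Remaining genomes are clustered on a
one-dimensional Euclidean distance, agglomerative with average linkage
(complete and Ward available), tree cut at k = 3.  The cluster basis is
log2((activity_rpkm+ε)/(abundance_rpkm+ε)) with ε = 10⁻⁶ RPKM
(`ratio_basis: rpkm`, the default) or the rank-based
log2((rank_abundance+0.5)/(rank_activity+0.5)) (`ratio_basis: rank`).  The
RPKM basis is the default because it measures the activity contrast
directly; the rank basis entangles a genome's abundance *quantile* with its
activity contrast (a highly active genome that happens to rank first on
both axes has rank-ratio ≈ 0), which blurs the boundary between the
active+abundant and abundant-non-active classes in mixed communities.

Determinism: points are canonically sorted by value before agglomeration
(so the result is input-order invariant up to relabeling) and merge-distance
ties resolve to the lexicographically smallest pair of slots.  Two
degenerate-ratio groups are assigned before clustering: zero-activity
genomes can only be `abundant_nonactive`, and zero-abundance /
positive-activity genomes are maximal-contrast `highly_active`; with a
finite ε either would otherwise sit ±20 log2 units outside the data and
hijack the k = 3 cut.  After the cut, one deterministic nearest-centroid
pass (`classes.refine`, default on) reassigns boundary points to the
nearest group mean: the raw tree cut places the AA/AN boundary erratically
on noisy data, and the refinement pins every boundary midway between
adjacent group centers without changing the group structure.

**Labels.**  Groups are named by their mean RPKM activity:abundance ratio:
largest → `highly_active`, smallest → `abundant_nonactive`, middle →
`active_abundant`; ties break toward the larger mean activity RPKM; a group
with identically zero activity can only be `abundant_nonactive`.
Cross-zone totals are deduplicated unions of per-zone label sets.

## Zone specificity, top genes, markers

A genome is **zone-specific** iff its total TMM expression over one zone's
RNA samples is strictly greater than `fold` (10) times the other zones'
totals combined *and* strictly greater than `min_tmm` (1).  Both
inequalities are strict — "greater than" applied literally at the boundary,
so exactly-10× is not called.  With fold ≥ 1 at most one zone can qualify.

**Top genes** are ranked by summed normalized expression (sum RPKM for the
highly-active vs other contrast, n = 20; sum TMM within zone-specific
groups, n = 18), ties broken lexicographically by gene id so top-n is
always a prefix of top-(n+1).

**Marker scores** (integrase = the transcriptional marker of lysogeny):

    score_z = (marker_reads_z / library_size_z) / (activity_z / Σ activity)

one concrete reading of "normalized for total viral activity and library
sizes"; pairwise zone ratios are invariant to global rescaling of either
normalizer, which is the property the fixtures assert.  **AMG summaries**
sum TMM per `AMG:<pathway>` tag per zone and z-score across zones (sample
sd, ddof = 1; constant rows map to zeros rather than NaN).

## Diversity

Shannon–Wiener H = −Σ p ln p in nats over positive proportions.  The
bootstrap resamples *reads*: B = 1000 multinomial draws at the observed
depth from the empirical proportions (genome-level resampling of one
proportion vector would be degenerate).  Zones are compared by Welch
two-sided t on the two bootstrap H distributions.  This reproduces a common
published procedure but is **anticonservative**: bootstrap replicates of
one community are not independent observations, so the test rejects a true
null far above the nominal level.  The suite asserts this as a documented
property; treat the p-values as descriptive contrasts, not calibrated
significance.  Within a single sample TMM rescaling leaves proportions
unchanged, so H is computed on pooled raw counts per (zone, assay).
Curve statistics: Pielou evenness J = H/ln S over the S detected genomes
(J := 0 when S ≤ 1), top-decile share = value fraction of the top ⌈n/10⌉
ranks, and bias-corrected sample skewness (0 for constant vectors).

## Synthetic communities and what passing tests mean

The generator emulates the *post-mapping count structure* of a stratified
three-zone viral community (zones GR, OR, PL):

- ~1200 genomes, lengths uniform 10–100 kb, 5–30 genes each;
- base abundance λ ~ LogNormal(μ=1.5, σ=1.5) on the RPKM scale — strongly
  left-skewed rank-abundance curves (top-decile share > 0.4), with μ set so
  the realized mapped totals match the declared 2×10⁶ library size (a
  mismatch would make single stray reads worth whole TMM units and corrupt
  the min-TMM clause);
- one latent category per genome shared across zones, mix 10% highly
  active / 45% active+abundant / 25% abundant-non-active / 20%
  low/non-active; activity multipliers 8 / 1 / 0.1 / 0.05; the low class
  additionally draws trace abundance LogNormal(−8, 0.5) — effectively
  undetected, as for genomes assembled in another zone;
- counts ~ NB(mean, dispersion 0.1) (variance m + 0.1 m²), the standard
  observation model for mapped-read counts; dispersion 0 is the noise-free
  limit (counts = rounded means);
- 5% of eligible genomes planted zone-specific: RNA mean ×20 at the focal
  zone and ÷20 elsewhere, comfortably above the 10×-vs-sum calling rule;
  the per-zone truth records the *effective* multiplier class after this
  adjustment, since the plant genuinely changes the genome's activity
  contrast in every zone;
- gene counts are multinomial splits of genome counts by gene length, so
  gene and genome tables are mutually consistent; integrase genes are
  planted preferentially in highly active genomes originating at GR,
  AMG-tagged genes uniformly.

All randomness flows from one seed through named SHA-256-derived
substreams, so tables are bit-reproducible regardless of platform or
iteration order.  Three canonical fixtures are generated by
`make_fixtures`: `toy10` (10 hand-written genomes exercising the
20-vs-22 zone-call boundary, the min-TMM clause, rank ties and
zero-activity genomes, with the expected calls recorded next to the
fixture), `recovery1200` (default community, embedded seed) and `marker35`
(marker reads 455/130/35 at equal activity totals and libraries, so the
integrase zone ratios are exactly 3.5 and 13 by construction).

What passing recovery tests show — and do not show.  The generator's
categories are separated by known multipliers with a single dispersion, its
communities have no batch effects, no genome-length bias in mapping, no
shared reads between related genomes, and zone-specificity is planted
rather than emergent.  Recovery of ~98% of labels here demonstrates that
the pipeline's operations implement their definitions and compose
correctly, not that real communities separate this cleanly; on real data
the category boundaries are exactly as sharp as the underlying contrast.

## Problem sizes and determinism

The shipped experiments run at: 100 random 20-gene × 4-sample matrices for
the TMM oracle check; 1000 genes × 3 samples for factor recovery; 1200
genomes × 3 zones for category/zone-call recovery; 100 random curves for
the cutoff oracle; B = 1000 bootstrap replicates at 10⁵ reads for
diversity; 20 seeds × 120 genomes for the shuffle/partition property — a
few seconds to ~2 minutes each on one CPU.  Reruns with the same config and
inputs are byte-identical: no timestamps enter outputs, floats are written
at 12 significant digits, and the run summary echoes the full effective
config (minus the output path) plus its hash.

## Known limitations

- The flatline cutoff detects plateaus, not knees; on noiseless continuous
  curves with no exact plateau it excludes nothing (rel_tol = 0) or nearly
  everything (rel_tol ≫ 1/n).  Knee detection on log-scale curves would be
  a different operation.
- The k = 3 cut assumes three ratio modes exist among non-low genomes; in
  communities where a mode is empty the labels degrade gracefully (the
  nearest-centroid pass cannot empty a group) but the middle label loses
  meaning.
- The marker normalization is one defensible formula among several; only
  ratios between zones, not absolute scores, should be interpreted.
- The bootstrap t-test inherits the anticonservativeness described above.
- Weighted TMM factors are only approximately invariant to per-sample
  depth rescaling (exact for unit weights).
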