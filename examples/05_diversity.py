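"""Bootstrap Shannon diversity per zone and the Welch contrast between
zones, plus rank-abundance curve shape statistics.

The bootstrap resamples reads (multinomial at observed depth).  The t-test
on bootstrap distributions mirrors a common published procedure but is
anticonservative: read its p-values as descriptive contrasts.
"""

from viractive import (CommunitySpec, bootstrap_shannon, compare_diversity,
                       curve_stats, rpkm, simulate_community)

spec = CommunitySpec(n_genomes=400, seed=11)
dna, rna, genes, truth = simulate_community(spec)

results = {}
for z in spec.zones:
    counts = rna.counts[f"{z}_RNA"].to_numpy()
    results[z] = bootstrap_shannon(counts, B=1000, seed=11, zone=z,
                                   assay="RNA")
    r = results[z]
    print(f"{z}: H = {r.H_plugin:.4f} nats, bootstrap {r.bootstrap_mean:.4f}"
          f" +- {r.bootstrap_sd:.4f} (B={r.B}, {r.n_reads_resampled:,} reads)")

t, p = compare_diversity(results["GR"], results["OR"])
print(f"\nGR vs OR: Welch t = {t:.1f}, p = {p:.3g} "
      "(anticonservative by construction)")

print("\nrank-abundance curve shape (RNA RPKM):")
vals = rpkm(rna).values
for z in spec.zones:
    cs = curve_stats(vals[f"{z}_RNA"].to_numpy(), zone=z, assay="RNA")
    print(f"  {z}: evenness J = {cs.evenness:.3f}, "
          f"top-decile share = {cs.top_decile_share:.2f}, "
          f"skewness = {cs.skewness:.1f}")
print("\nA few genomes carry most of the activity in every zone — the")
print("left skew that motivates the flatline cutoff.")
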