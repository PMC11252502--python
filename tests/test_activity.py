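import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_count_table
from oracles import agglomerate_oracle, flatline_cutoff_oracle
from viractive.activity import (CATEGORIES, apply_lowclass, classify_zone,
                                cluster_ratios, flatline_cutoff,
                                global_category_union, label_groups,
                                rank_values, refine_cut)
from viractive.config import ClassConfig
from viractive.simulate import CommunitySpec, simulate_community
from viractive.tables_io import ViractiveError


class TestRankValues:
    @pytest.mark.parametrize("values,expected", [
        ((10, 5, 1), (1, 2, 3)),
        ((7, 7, 1), (1.5, 1.5, 3)),
        ((1, 2, 3), (3, 2, 1)),
    ])
    def test_descending_with_average_ties(self, values, expected):
        np.testing.assert_allclose(rank_values(values), expected)

    @given(st.lists(st.floats(-1e9, 1e9), min_size=1, max_size=40))
    def test_rank_sum_conserved(self, xs):
        n = len(xs)
        assert rank_values(xs).sum() == pytest.approx(n * (n + 1) / 2)

    def test_empty_errors(self):
        with pytest.raises(ViractiveError):
            rank_values([])


class TestFlatlineCutoff:
    def test_sharp_drop_then_plateau(self):
        v = [100, 50, 25] + [0.1] * 12
        assert flatline_cutoff(v, window=10, rel_tol=0.01).cutoff_rank == 4

    def test_constant_curve_cuts_at_one(self):
        assert flatline_cutoff([3.3] * 15, window=10, rel_tol=0.01).cutoff_rank == 1

    def test_geometric_decay_closed_form(self):
        v = [100 * 0.5 ** i for i in range(20)]
        got = flatline_cutoff(v, window=5, rel_tol=0.01).cutoff_rank
        # first rank r where the largest step in [r, r+5], 50*0.5^(r-1), <= 1
        closed = next(r for r in range(1, 16) if 50 * 0.5 ** (r - 1) <= 1.0)
        assert got == closed == flatline_cutoff_oracle(v, 5, 0.01)

    def test_no_flat_region_returns_n(self):
        v = [100 - 10 * i for i in range(11)]
        assert flatline_cutoff(v, window=5, rel_tol=0.001).cutoff_rank == 11

    def test_unsorted_rejected(self):
        with pytest.raises(ViractiveError, match="descending"):
            flatline_cutoff([1, 2, 3] + [0] * 10)

    def test_oracle_equivalence_random_curves(self):
        rng = np.random.default_rng(20_240_614)
        for _ in range(100):
            n = int(rng.integers(15, 120))
            v = np.sort(rng.lognormal(0, rng.uniform(0.3, 2.5), n))[::-1]
            if rng.random() < 0.5:  # append a plateau half the time
                v = np.concatenate([v, np.full(int(rng.integers(5, 30)),
                                               v[-1] * 0.5)])
            window = int(rng.integers(2, 12))
            rel_tol = float(rng.choice([0.0, 0.001, 0.01, 0.05]))
            if len(v) < window + 1:
                continue
            got = flatline_cutoff(v, window, rel_tol).cutoff_rank
            assert got == flatline_cutoff_oracle(v, window, rel_tol)


class TestApplyLowclass:
    def _cut(self, axis, rank):
        from viractive.activity import CutoffResult
        return CutoffResult("GR", axis, rank, 10, 0.0)

    def test_requires_both_axes(self):
        ab, act = self._cut("abundance", 5), self._cut("activity", 5)
        n = 6
        low = apply_lowclass([n, 1, 5], [n, n, 5], ab, act)
        np.testing.assert_array_equal(low, [True, False, True])

    def test_matches_set_intersection_brute_force(self):
        rng = np.random.default_rng(11)
        ra, rc = rng.permutation(50) + 1, rng.permutation(50) + 1
        ab, act = self._cut("abundance", 30), self._cut("activity", 22)
        low = apply_lowclass(ra, rc, ab, act)
        brute = {i for i in range(50) if ra[i] >= 30} & \
                {i for i in range(50) if rc[i] >= 22}
        assert set(np.nonzero(low)[0]) == brute


class TestClusterRatios:
    def test_three_planted_pairs(self):
        groups = cluster_ratios([-3, -3.1, 0, 0.1, 3, 3.2], k=3)
        assert groups[0] == groups[1]
        assert groups[2] == groups[3]
        assert groups[4] == groups[5]
        assert len(set(groups)) == 3

    def test_all_equal_is_one_group_with_warning(self):
        with pytest.warns(UserWarning, match="equal"):
            groups = cluster_ratios([1.0] * 8, k=3)
        assert set(groups) == {1}

    def test_fewer_than_k_is_one_group(self):
        with pytest.warns(UserWarning, match="fewer"):
            assert set(cluster_ratios([1.0, 5.0], k=3)) == {1}

    @pytest.mark.parametrize("linkage", ["average", "complete", "ward"])
    def test_exhaustive_oracle_small_vectors(self, linkage):
        rng = np.random.default_rng(20_240_614)
        for _ in range(60):
            n = int(rng.integers(3, 9))
            k = int(rng.integers(2, min(n, 4) + 1))
            x = np.round(rng.normal(0, 10, n), 3)
            if len(np.unique(x)) <= k:
                continue
            groups = cluster_ratios(x, k=k, linkage=linkage)
            got = {frozenset(np.nonzero(groups == g)[0].tolist())
                   for g in set(groups)}
            assert got == agglomerate_oracle(x, k, linkage)

    def test_permutation_invariance_up_to_relabel(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0, 5, 40)
        base = cluster_ratios(x, k=3)
        perm = rng.permutation(40)
        permuted = cluster_ratios(x[perm], k=3)
        # same partition of genome identities
        part_a = {frozenset(np.nonzero(base == g)[0].tolist())
                  for g in set(base)}
        part_b = {frozenset(perm[np.nonzero(permuted == g)[0]].tolist())
                  for g in set(permuted)}
        assert part_a == part_b


class TestRefineCut:
    def test_noop_on_separated_groups(self):
        x = np.array([-3.0, -3.1, 0.0, 0.1, 3.0, 3.2])
        groups = cluster_ratios(x, k=3)
        np.testing.assert_array_equal(refine_cut(x, groups), groups)

    def test_moves_boundary_to_midpoint(self):
        # point at 1.4 is nearer the center of group B (2) than A (0)
        x = np.array([0.0, 0.1, -0.1, 1.4, 2.0, 2.1, 1.9])
        groups = np.array([1, 1, 1, 1, 2, 2, 2])
        refined = refine_cut(x, groups)
        assert refined[3] == 2


class TestLabelGroups:
    def test_ordering(self):
        groups = [1, 1, 2, 2, 3, 3]
        rr = [10.0, 10.0, 1.1, 1.1, 0.1, 0.1]
        act = [5, 5, 4, 4, 3, 3]
        labels = label_groups(groups, rr, act)
        assert labels == {1: "highly_active", 2: "active_abundant",
                          3: "abundant_nonactive"}

    def test_tie_broken_by_activity(self):
        groups = [1, 2, 3]
        rr = [1.0, 1.0, 5.0]
        act = [9.0, 2.0, 1.0]
        labels = label_groups(groups, rr, act)
        assert labels[3] == "highly_active"
        assert labels[1] == "active_abundant"   # tie: higher activity wins
        assert labels[2] == "abundant_nonactive"

    def test_invariant_to_renumbering(self):
        rr = [8.0, 8.0, 1.0, 1.0, 0.2, 0.2]
        act = [4, 4, 3, 3, 2, 2]
        a = label_groups([1, 1, 2, 2, 3, 3], rr, act)
        b = label_groups([3, 3, 1, 1, 2, 2], rr, act)
        assert [a[g] for g in (1, 2, 3)] == [b[g] for g in (3, 1, 2)]


class TestClassifyZone:
    def test_zero_activity_zone_forces_two_categories(self):
        rng = np.random.default_rng(13)
        n = 40
        dna_counts = np.concatenate([rng.integers(50, 500, n - 15),
                                     np.zeros(15, dtype=np.int64)])
        dna = make_count_table({"GR_DNA": dna_counts, "OR_DNA": dna_counts})
        rna = make_count_table({"GR_RNA": np.zeros(n, dtype=np.int64),
                                "OR_RNA": rng.integers(0, 50, n)})
        zc = classify_zone(dna, rna, "GR")
        assert set(zc.profile["category"]) <= {"low_nonactive",
                                               "abundant_nonactive"}

    def test_every_genome_gets_exactly_one_category(self, small_community):
        spec, (dna, rna, genes, truth) = small_community
        zc = classify_zone(dna, rna, "GR")
        assert len(zc.profile) == spec.n_genomes
        assert zc.profile["category"].isin(CATEGORIES).all()
        assert zc.profile["genome_id"].is_unique

    def test_partition_and_shuffle_determinism_many_seeds(self):
        for seed in range(20):
            spec = CommunitySpec(n_genomes=120, seed=seed)
            dna, rna, genes, truth = simulate_community(spec)
            zc = classify_zone(dna, rna, "OR")
            cats = zc.profile.set_index("genome_id")["category"]
            assert cats.isin(CATEGORIES).all() and len(cats) == 120
            perm = np.random.default_rng(seed).permutation(120)
            from viractive.tables_io import CountTable
            dna2 = CountTable(dna.counts.iloc[perm], dna.lengths.iloc[perm],
                              dna.sample_map)
            rna2 = CountTable(rna.counts.iloc[perm], rna.lengths.iloc[perm],
                              rna.sample_map)
            cats2 = classify_zone(dna2, rna2, "OR").profile.set_index(
                "genome_id")["category"]
            pd.testing.assert_series_equal(cats.sort_index(), cats2.sort_index())

    def test_monotone_in_rna_counts(self, small_community):
        spec, (dna, rna, genes, truth) = small_community
        base = classify_zone(dna, rna, "GR").profile.set_index("genome_id")
        target = base.index[base["category"] == "highly_active"][0]
        boosted = rna.counts.copy()
        boosted.loc[target] *= 10
        from viractive.tables_io import CountTable
        rna2 = CountTable(boosted, rna.lengths, rna.sample_map)
        after = classify_zone(dna, rna2, "GR").profile.set_index("genome_id")
        assert after.loc[target, "category"] != "abundant_nonactive"

    def test_recovery_on_small_default_community(self, small_community):
        spec, (dna, rna, genes, truth) = small_community
        agree = 0
        for z in spec.zones:
            pred = classify_zone(dna, rna, z).profile.set_index(
                "genome_id")["category"]
            agree += (pred.loc[truth.table.index]
                      == truth.table[f"category_{z}"]).sum()
        assert agree / (3 * spec.n_genomes) > 0.85


class TestGlobalUnion:
    def test_dedup_and_bounds(self):
        p1 = pd.DataFrame({"genome_id": ["a", "b", "c"], "zone": "GR",
                           "category": ["highly_active"] * 3})
        p2 = pd.DataFrame({"genome_id": ["b", "d"], "zone": "OR",
                           "category": ["highly_active"] * 2})
        union = global_category_union([p1, p2])
        assert union["highly_active"] == ["a", "b", "c", "d"]

    def test_disjoint_sets_sum(self):
        frames = []
        for zone, ids in (("GR", "abc"), ("OR", "def"), ("PL", "ghij")):
            frames.append(pd.DataFrame({
                "genome_id": list(ids), "zone": zone,
                "category": ["active_abundant"] * len(ids)}))
        union = global_category_union(frames)
        assert len(union["active_abundant"]) == 10
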