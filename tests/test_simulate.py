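import numpy as np
import pytest

from mike import simulate
from mike.distance import DistanceMatrix
from mike.kmer_io import KmerParams, count_kmers
from mike.simulate import (
    RegionMap,
    SimGenome,
    evolve_allotetraploid,
    evolve_autotetraploid,
    evolve_haploid,
    evolve_polyploid,
    jc_mutate,
    make_ancestor,
    sample_read_matrix,
    seq_to_str,
    simulate_reads,
    true_distance_matrix,
)
from mike.tree import nj, rf_distance

import _oracles as oracle


class TestAncestor:
    def test_seed_determinism(self):
        assert np.array_equal(make_ancestor(1000, 0.5, 7), make_ancestor(1000, 0.5, 7))

    def test_gc_zero_gives_at_only(self):
        seq = make_ancestor(500, 0.0, 1)
        assert set(np.unique(seq)) <= {0, 3}  # A and T codes

    def test_gc_fraction_within_binomial_ci(self):
        L = 200_000
        target = 0.42
        seq = make_ancestor(L, target, 3)
        gc = np.isin(seq, [1, 2]).mean()
        se = np.sqrt(target * (1 - target) / L)
        assert abs(gc - target) <= 3 * se


class TestRegionMap:
    def test_alternating_tiles_exactly(self):
        rm = RegionMap.alternating(25_000, 0.5, block=10_000)
        assert rm.intervals[-1][1] == 25_000
        assert rm.n_mutable + int(rm.conserved_fraction * 25_000) == 25_000

    def test_gap_or_overlap_rejected(self):
        with pytest.raises(ValueError):
            RegionMap(10, [(0, 4, "conserved"), (5, 10, "mutable")])
        with pytest.raises(ValueError):
            RegionMap(10, [(0, 6, "conserved"), (5, 10, "mutable")])

    def test_unknown_tag_rejected(self):
        with pytest.raises(ValueError):
            RegionMap(10, [(0, 10, "weird")])


class TestJCMutate:
    def test_rate_zero_is_noop(self):
        seq = make_ancestor(1000, 0.5, 0)
        out, n = jc_mutate(seq, 0.0, RegionMap.all_mutable(1000), 1)
        assert n == 0 and np.array_equal(out, seq)

    def test_conserved_regions_untouched(self):
        L = 2000
        seq = make_ancestor(L, 0.5, 0)
        rm = RegionMap(L, [(0, L, "conserved")])
        out, n = jc_mutate(seq, 0.5, rm, 1)
        assert n == 0 and np.array_equal(out, seq)

    def test_substitutions_change_base_and_stay_in_mutable(self):
        L = 10_000
        seq = make_ancestor(L, 0.5, 0)
        rm = RegionMap(L, [(0, 5000, "conserved"), (5000, L, "mutable")])
        out, n = jc_mutate(seq, 0.2, rm, 2)
        diff = np.flatnonzero(out != seq)
        assert n == diff.size
        assert diff.min() >= 5000
        assert np.all(out[diff] != seq[diff])

    def test_substitution_count_matches_binomial(self):
        L = 20_000
        rate = 0.01
        seq = make_ancestor(L, 0.5, 0)
        rm = RegionMap.all_mutable(L)
        counts = [jc_mutate(seq, rate, rm, 1000 + i)[1] for i in range(200)]
        mean = np.mean(counts)
        se = np.sqrt(L * rate * (1 - rate) / 200)
        assert abs(mean - L * rate) <= 3 * se


class TestHaploid:
    def test_no_evolution_gives_identical_offspring(self):
        lin = evolve_haploid(L=5000, rate=1e-3, generations=0, n_offspring=4, seed=1)
        assert len(lin.genomes) == 4
        assert np.all(lin.true_div.values == 0.0)
        for g in lin.genomes[1:]:
            assert np.array_equal(g.copies, lin.genomes[0].copies)

    def test_sisters_closer_than_outgroup(self):
        lin = evolve_haploid(L=30_000, rate=2e-3, generations=24, n_offspring=4, seed=3)
        # recorded genealogy: find a sister pair and an outgroup leaf
        tree = lin.true_tree
        cherry = next(
            nd for nd in tree.postorder_node_iter()
            if not nd.is_leaf() and all(c.is_leaf() for c in nd.child_nodes())
        )
        a, b = [c.taxon.label for c in cherry.child_nodes()]
        out = next(
            l.taxon.label for l in tree.leaf_node_iter() if l.taxon.label not in (a, b)
        )
        assert lin.true_div[a, b] < lin.true_div[a, out]
        assert lin.true_div[a, b] < lin.true_div[b, out]

    @pytest.mark.parametrize("seed", range(10))
    def test_nj_on_true_divergence_recovers_genealogy(self, seed):
        lin = evolve_haploid(L=30_000, rate=2e-3, generations=32, n_offspring=8, seed=seed)
        assert rf_distance(nj(lin.true_div), lin.true_tree) == 0.0

    def test_conserved_columns_identical_across_lineage(self):
        lin = evolve_haploid(L=20_000, rate=5e-3, generations=20, n_offspring=4, seed=5)
        cons = ~lin.regions.mutable_mask
        ref = lin.genomes[0].copies[0][cons]
        for g in lin.genomes[1:]:
            assert np.array_equal(g.copies[0][cons], ref)

    def test_true_distance_matrix_matches_hamming_oracle(self):
        lin = evolve_haploid(L=10_000, rate=5e-3, generations=10, n_offspring=4, seed=7)
        m = true_distance_matrix(lin)
        idx = lin.regions.mutable_idx
        for i in range(4):
            for j in range(4):
                a = lin.genomes[i].copies[0][idx]
                b = lin.genomes[j].copies[0][idx]
                assert m.values[i, j] == pytest.approx(np.mean(a != b))


class TestAutotetraploid:
    def test_ploidy_and_conservation(self):
        lin = evolve_autotetraploid(L=10_000, rate=2e-3, generations=16, n_offspring=4, seed=1)
        cons = ~lin.regions.mutable_mask
        ref = lin.genomes[0].copies[0][cons]
        for g in lin.genomes:
            assert g.ploidy == 4
            for c in range(4):
                assert np.array_equal(g.copies[c][cons], ref)

    def test_divergence_grows_with_generations(self):
        means = []
        for gens in (8, 32):
            vals = []
            for seed in range(5):
                lin = evolve_autotetraploid(
                    L=10_000, rate=2e-3, generations=gens, n_offspring=4, seed=seed
                )
                v = lin.true_div.values
                vals.append(v[np.triu_indices_from(v, 1)].mean())
            means.append(np.mean(vals))
        assert means[1] > means[0]


class TestAllotetraploid:
    def test_leaf_count_and_ploidy(self):
        lin = evolve_allotetraploid(L=8000, rate=2e-3, n_offspring=4, seed=2)
        assert len(lin.genomes) == 8  # 2n offspring
        assert all(g.ploidy == 4 for g in lin.genomes)

    def test_hybrids_carry_both_parental_origins(self):
        # with zero post-divergence noise, each hybrid copy must equal one of
        # the pool chromosomes; pools are distinguishable after divergence
        lin = evolve_allotetraploid(
            L=8000, rate=3e-3, n_offspring=3, seed=4, divergence_generations=30
        )
        # same-generation sisters share parental state: their cross-pool
        # divergence structure means every genome has 2+2 copies, and sister
        # pairs are closer than cross-generation pairs on average
        v = lin.true_div.values
        sister = [v[2 * g, 2 * g + 1] for g in range(3)]
        far = v[0, 5]
        assert np.mean(sister) < far

    def test_nj_recovers_sister_cherries(self):
        from _oracles import bipartitions

        lin = evolve_allotetraploid(
            L=30_000, rate=2e-3, n_offspring=4, seed=1, divergence_generations=40
        )
        inferred = nj(lin.true_div)
        newick = inferred.as_string(schema="newick", unquoted_underscores=True)
        splits = bipartitions(newick)
        labels = set(lin.labels)
        for g in range(4):
            pair = frozenset({f"allo{2 * g + 1:02d}", f"allo{2 * g + 2:02d}"})
            assert frozenset({pair, frozenset(labels - pair)}) in splits


class TestPolyploid:
    def test_default_schedule_emits_six_ploidies(self):
        lin = evolve_polyploid(L=6000, rate=1e-3, generations=24, seed=1)
        assert sorted(g.ploidy for g in lin.genomes) == [2, 4, 6, 8, 12, 16]

    def test_wgd_doubles_copy_count(self):
        lin = evolve_polyploid(
            L=4000, rate=1e-3, generations=12, seed=1,
            schedule=(("wgd", "x2", "x4"), ("wgd", "x4", "x8"), ("wgd", "x8", "x16")),
        )
        assert sorted(g.ploidy for g in lin.genomes) == [2, 4, 8, 16]

    def test_hybrid_of_4_and_8_gives_6(self):
        lin = evolve_polyploid(
            L=4000, rate=1e-3, generations=12, seed=1,
            schedule=(("wgd", "x2", "x4"), ("wgd", "x4", "x8"), ("hyb", ("x4", "x8"), "x6")),
        )
        assert 6 in {g.ploidy for g in lin.genomes}

    def test_incompatible_hybridisation_fatal(self):
        with pytest.raises(ValueError, match="ploid"):
            evolve_polyploid(
                L=2000, generations=12, seed=1,
                schedule=(("wgd", "x2", "x4"), ("hyb", ("x2", "x4"), "x3")),
            )

    def test_conserved_columns_identical_across_all_copies(self):
        lin = evolve_polyploid(L=6000, rate=5e-3, generations=18, seed=3)
        cons = ~lin.regions.mutable_mask
        ref = lin.genomes[0].copies[0][cons]
        for g in lin.genomes:
            for c in range(g.ploidy):
                assert np.array_equal(g.copies[c][cons], ref)


class TestReads:
    def _genome(self, L=4000, seed=0, ploidy=1):
        anc = make_ancestor(L, 0.5, seed)
        return SimGenome(np.repeat(anc[None, :], ploidy, axis=0), "g")

    def test_error_free_reads_are_exact_substrings(self):
        g = self._genome()
        source = seq_to_str(g.copies[0])
        both = source + "#" + oracle.revcomp(source)
        for _, seq, _ in simulate_reads(g, coverage=5, read_len=80, err_rate=0.0, seed=1):
            assert seq in both

    def test_total_bases_meet_coverage_target(self):
        g = self._genome(ploidy=4)
        reads = sample_read_matrix(g, coverage=7, read_len=90, err_rate=0.0, seed=1)
        total = reads.size
        target = 7 * g.length * 4
        assert target <= total <= target * 1.02 + 90

    def test_error_rate_within_binomial_ci(self):
        g = self._genome(L=20_000)
        err = 0.01
        clean = sample_read_matrix(g, coverage=10, read_len=100, err_rate=0.0, seed=9)
        noisy = sample_read_matrix(g, coverage=10, read_len=100, err_rate=err, seed=9)
        # identical seed => identical read layout; mismatches are exactly the errors
        n = clean.size
        assert n >= 1e5
        observed = np.mean(clean != noisy)
        se = np.sqrt(err * (1 - err) / n)
        assert abs(observed - err) <= 3 * se

    def test_read_longer_than_genome_fatal(self):
        with pytest.raises(ValueError):
            sample_read_matrix(self._genome(L=50), coverage=1, read_len=100)

    def test_quality_string_encodes_error_rate(self):
        g = self._genome()
        _, seq, qual = next(simulate_reads(g, 1, 50, 0.01, 1))
        assert qual == chr(20 + 33) * 50  # Q20 for 1% error
        assert len(seq) == 50

    def test_reads_feed_kmer_counter(self):
        g = self._genome(L=3000)
        seqs = [s for _, s, _ in simulate_reads(g, 10, 60, 0.0, 2)]
        kset = count_kmers(seqs, KmerParams(k=21, min_count=2))
        genome_kmers = count_kmers([seq_to_str(g.copies[0])], KmerParams(k=21, min_count=1))
        # error-free deep coverage recovers nearly all genomic k-mers
        assert kset.n_kmers >= 0.95 * genome_kmers.n_kmers


class TestDeterminism:
    def test_lineage_and_reads_bit_identical_across_reruns(self):
        a = evolve_haploid(L=8000, rate=2e-3, generations=16, n_offspring=4, seed=11)
        b = evolve_haploid(L=8000, rate=2e-3, generations=16, n_offspring=4, seed=11)
        for ga, gb in zip(a.genomes, b.genomes):
            assert np.array_equal(ga.copies, gb.copies)
        assert a.true_tree.as_string(schema="newick") == b.true_tree.as_string(schema="newick")
        ra = sample_read_matrix(a.genomes[0], 5, 80, 0.01, seed=3)
        rb = sample_read_matrix(b.genomes[0], 5, 80, 0.01, seed=3)
        assert np.array_equal(ra, rb)
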