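"""Regulation maps, co-occupancy, clustering, enrichment."""

import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import chromcobind as cb
from chromcobind import integration
from chromcobind.profiles import SignalMatrix


def summit(pos, tf="NFE2", chrom="chr1"):
    iv = cb.GenomicInterval(chrom, max(0, pos - 100), pos + 100)
    return cb.PeakSummit(iv, pos, 10.0, tf)


def gene(gene_id, tss, chrom="chr1", expr_imm=1.0, expr_mat=1.0, fdr=0.5):
    return cb.GeneRecord(gene_id, chrom, "+", tss, expr_imm, expr_mat, fdr)


class TestNearestSummitDistance:
    def test_picks_the_closer_side(self):
        entries = cb.nearest_summit_distance(
            [gene("g1", 5_000)], [summit(4_000), summit(10_000)]
        )
        assert entries[0].distance == 1_000
        assert entries[0].nearest_summit.summit == 4_000

    def test_summit_at_tss_gives_zero(self):
        entries = cb.nearest_summit_distance([gene("g1", 5_000)], [summit(5_000)])
        assert entries[0].distance == 0

    def test_no_summit_on_chromosome_is_undefined(self):
        entries = cb.nearest_summit_distance(
            [gene("g1", 5_000, chrom="chr2")], [summit(4_000)]
        )
        assert entries[0].distance is None

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(10)
        genes = [
            gene(f"g{i}", int(rng.integers(0, 1_000_000)),
                 chrom=f"chr{rng.integers(1, 4)}")
            for i in range(200)
        ]
        summits = [
            summit(int(rng.integers(100, 1_000_000)),
                   chrom=f"chr{rng.integers(1, 4)}")
            for _ in range(500)
        ]
        entries = cb.nearest_summit_distance(genes, summits)
        for g, e in zip(genes, entries):
            same = [abs(s.summit - g.tss) for s in summits if s.chrom == g.chrom]
            expected = min(same) if same else None
            assert e.distance == expected

    def test_log2_fc_uses_min_positive_pseudocount(self):
        genes = [gene("g1", 100, expr_imm=0.0, expr_mat=4.0),
                 gene("g2", 200, expr_imm=2.0, expr_mat=2.0)]
        entries = cb.nearest_summit_distance(genes, [summit(100)])
        delta = 2.0  # smallest positive expression value in the table
        assert entries[0].log2_fc == pytest.approx(np.log2((4 + delta) / delta))
        assert entries[1].log2_fc == 0.0


class TestDistanceCdfTest:
    def _entries(self, dist_a, dist_b):
        out = []
        for i, d in enumerate(dist_a):
            out.append(cb.RegulationEntry(f"a{i}", d, 1.0))
        for i, d in enumerate(dist_b):
            out.append(cb.RegulationEntry(f"b{i}", d, -1.0))
        return out

    def test_identical_classes_score_zero(self):
        entries = self._entries([100, 200, 300], [])
        pred = lambda e: e.gene_id.startswith("a")
        res = cb.distance_cdf_test(entries, pred, pred)
        assert res.ks_statistic == 0.0 and res.p_value == 1.0

    def test_disjoint_supports_score_one(self):
        rng = np.random.default_rng(0)
        entries = self._entries(rng.integers(0, 1_000, 50),
                                rng.integers(100_000, 200_000, 50))
        res = cb.distance_cdf_test(
            entries,
            lambda e: e.gene_id.startswith("a"),
            lambda e: e.gene_id.startswith("b"),
        )
        assert res.ks_statistic == 1.0
        assert res.p_value < 1e-10

    def test_empty_class_rejected(self):
        entries = self._entries([100], [200])
        with pytest.raises(cb.ParameterError):
            cb.distance_cdf_test(entries, lambda e: False,
                                 lambda e: True)

    def test_cdfs_reach_one(self):
        entries = self._entries([10, 20, 30], [5, 15])
        res = cb.distance_cdf_test(
            entries,
            lambda e: e.gene_id.startswith("a"),
            lambda e: e.gene_id.startswith("b"),
        )
        assert res.cdf_a[-1] == 1.0 and res.cdf_b[-1] == 1.0


class TestBindingFrequencyByBin:
    def _bins(self, pair_specs, bin_size=2):
        pairs = []
        for chrom, left, right, nsd in pair_specs:
            p = cb.NucleosomePair(
                chrom=chrom,
                left=cb.Nucleosome(chrom, left, 1.0),
                right=cb.Nucleosome(chrom, right, 1.0),
            )
            p.nsd = nsd
            pairs.append(p)
        return cb.rank_and_bin(pairs, bin_size=bin_size)

    def test_no_summits_all_zero(self):
        bins = self._bins([("chr1", 1_000, 1_350, 0.5),
                           ("chr1", 5_000, 5_350, -0.5)], bin_size=1)
        assert list(cb.binding_frequency_by_bin(bins, [])) == [0, 0]

    def test_one_summit_marks_one_pair(self):
        bins = self._bins([("chr1", 1_000, 1_350, 0.5),
                           ("chr1", 5_000, 5_350, -0.5)], bin_size=1)
        counts = cb.binding_frequency_by_bin(bins, [summit(1_100)])
        assert list(counts) == [1, 0]

    def test_span_includes_flanking_nucleosome_footprint(self):
        bins = self._bins([("chr1", 1_000, 1_350, 0.5)], bin_size=1)
        inside = cb.binding_frequency_by_bin(bins, [summit(1_000 - 73)])
        outside = cb.binding_frequency_by_bin(bins, [summit(1_000 - 74)])
        assert list(inside) == [1] and list(outside) == [0]


class TestPairCountByExpressionBin:
    def _pair(self, center, chrom="chr1"):
        return cb.NucleosomePair(
            chrom=chrom,
            left=cb.Nucleosome(chrom, center - 175, 1.0),
            right=cb.Nucleosome(chrom, center + 175, 1.0),
        )

    def test_bin_count(self):
        genes = [gene(f"g{i}", 10_000 * i) for i in range(100)]
        res = cb.pair_count_by_expression_bin(genes, [], gene_bin=50)
        assert len(res.means) == 2 and not res.partial_last

    def test_distance_band_is_half_open(self):
        genes = [gene("g1", 100_000)]
        pairs = [self._pair(101_000), self._pair(105_000)]
        res = cb.pair_count_by_expression_bin(genes, pairs, gene_bin=1)
        assert res.means[0] == 1.0  # only the 5 kb pair qualifies

    def test_no_pairs_all_zero(self):
        genes = [gene(f"g{i}", 10_000 * i) for i in range(60)]
        res = cb.pair_count_by_expression_bin(genes, [], gene_bin=50)
        assert np.all(res.means == 0) and res.partial_last


class TestSummitDistanceHistogram:
    def test_identical_summit_lists_mass_in_first_bin(self):
        positions = [1_000, 5_000, 9_000]
        by_tf = {
            "NFE2": [summit(p, "NFE2") for p in positions],
            "FLI1": [summit(p, "FLI1") for p in positions],
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hist = cb.summit_distance_histogram(by_tf)
        assert hist.counts[0] == 6
        assert hist.counts[1:].sum() == 0

    def test_single_cross_pair_falls_back_to_default(self):
        by_tf = {
            "NFE2": [summit(1_000, "NFE2")],
            "FLI1": [summit(1_500, "FLI1")],
        }
        with pytest.warns(UserWarning, match="inflection"):
            hist = cb.summit_distance_histogram(by_tf)
        assert hist.counts[500 // 20] == 2  # both summits report the pair
        assert hist.used_default and hist.inflection == 300

    def test_inflection_detected_near_mixture_boundary(self):
        rng = np.random.default_rng(42)
        # co-bound pairs: offsets |delta| <= 280 (triangular), plus sparse
        # uniform background pairs out to 10 kb
        positions_a, positions_b = [], []
        base = 10_000
        for i in range(3_000):
            a = base + i * 3_000
            d = int(abs(rng.uniform(0, 280) - rng.uniform(0, 280)))
            positions_a.append(a)
            positions_b.append(a + d)
        for i in range(300):
            a = base + 9_500_000 + i * 30_000
            positions_a.append(a)
            positions_b.append(a + int(rng.uniform(350, 10_000)))
        by_tf = {
            "NFE2": [summit(p, "NFE2") for p in positions_a],
            "FLI1": [summit(p, "FLI1") for p in positions_b],
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hist = cb.summit_distance_histogram(by_tf)
        assert not hist.used_default
        assert abs(hist.inflection - 300) <= 40

    def test_single_tf_rejected(self):
        with pytest.raises(cb.ParameterError):
            cb.summit_distance_histogram({"NFE2": [summit(1_000)]})


class TestMergeCooccupancy:
    def test_worked_example(self):
        by_tf = {
            "NFE2": [summit(1_000, "NFE2")],
            "FLI1": [summit(1_200, "FLI1")],
            "RUNX1": [summit(2_000, "RUNX1")],
        }
        loci = cb.merge_cooccupancy(by_tf, threshold=300)
        combos = sorted(
            ("+".join(sorted(l.tf_combination)) for l in loci)
        )
        assert combos == ["FLI1+NFE2", "RUNX1"]

    def test_chain_merges_by_single_linkage(self):
        by_tf = {
            "NFE2": [summit(1_000, "NFE2")],
            "FLI1": [summit(1_290, "FLI1")],
            "RUNX1": [summit(1_580, "RUNX1")],
        }
        loci = cb.merge_cooccupancy(by_tf, threshold=300)
        assert len(loci) == 1
        assert loci[0].tf_combination == {"NFE2", "FLI1", "RUNX1"}

    def test_exactly_threshold_does_not_merge(self):
        by_tf = {
            "NFE2": [summit(1_000, "NFE2")],
            "FLI1": [summit(1_300, "FLI1")],
        }
        loci = cb.merge_cooccupancy(by_tf, threshold=300)
        assert len(loci) == 2

    def test_idempotent_and_order_independent(self):
        rng = np.random.default_rng(3)
        by_tf = {
            tf: [summit(int(p), tf) for p in
                 np.sort(rng.integers(1_000, 500_000, 80))]
            for tf in ("NFE2", "FLI1", "RUNX1")
        }
        loci = cb.merge_cooccupancy(by_tf)
        # re-merge the members of each locus: same loci back
        remerged = cb.merge_cooccupancy(
            {"all": [s for l in loci for s in l.members]}
        )
        assert [(l.chrom, l.span.start, l.span.end) for l in loci] == \
            [(l.chrom, l.span.start, l.span.end) for l in remerged]
        shuffled = {tf: list(reversed(s)) for tf, s in by_tf.items()}
        again = cb.merge_cooccupancy(shuffled)
        assert [(l.span.start, l.span.end) for l in again] == \
            [(l.span.start, l.span.end) for l in loci]


class TestGeneCombinationAssignment:
    def _loci(self, specs):
        out = []
        for pos, tfs in specs:
            members = [summit(pos + 10 * i, tf) for i, tf in enumerate(tfs)]
            out.append(
                cb.CooccupancyLocus(
                    chrom="chr1",
                    span=cb.GenomicInterval("chr1", pos, pos + 10 * len(tfs) + 1),
                    members=members,
                )
            )
        return out

    def test_triple_locus_in_range(self):
        loci = self._loci([(105_000, ("NFE2", "FLI1", "RUNX1"))])
        labels = cb.gene_combination_assignment([gene("g1", 100_000)], loci)
        assert labels["g1"] == {"NFE2", "FLI1", "RUNX1"}

    def test_union_over_loci_in_range(self):
        loci = self._loci([(103_000, ("NFE2",)), (118_000, ("FLI1",))])
        labels = cb.gene_combination_assignment([gene("g1", 100_000)], loci)
        assert labels["g1"] == {"NFE2", "FLI1"}

    def test_out_of_range_is_none(self):
        loci = self._loci([(125_000, ("NFE2",))])
        labels = cb.gene_combination_assignment([gene("g1", 100_000)], loci)
        assert labels["g1"] == frozenset()

    def test_recovers_planted_combinations(self, genome, truth):
        summits_by_tf = {
            tf: cb.simulate.true_summits(truth, tf) for tf in cb.TF_NAMES
        }
        loci = cb.merge_cooccupancy(summits_by_tf, threshold=300)
        labels = cb.gene_combination_assignment(genome.genes, loci,
                                                cutoff=20_000)
        # exact oracle: union of planted tf_sets within the cutoff
        correct = total = 0
        for g in genome.genes:
            expected = set()
            for e in truth:
                if e.chrom != g.chrom:
                    continue
                near = min(abs(e.summit_position(tf) - g.tss) for tf in e.tf_set)
                if near <= 20_000:
                    expected |= e.tf_set
            total += 1
            correct += labels[g.gene_id] == frozenset(expected)
        assert correct / total >= 0.95


class TestFractionBoundWithin:
    def test_counted_fractions(self):
        genes = [gene(f"g{i}", t) for i, t in
                 enumerate([1_000, 19_000, 30_000, 60_000])]
        by_tf = {"NFE2": [summit(0)]}
        res = cb.fraction_bound_within(genes, by_tf, cutoffs=(20_000, 50_000))
        assert res["NFE2"][20_000] == pytest.approx(0.5)
        assert res["NFE2"][50_000] == pytest.approx(0.75)

    def test_summit_at_every_tss(self):
        genes = [gene(f"g{i}", 10_000 * (i + 1)) for i in range(4)]
        by_tf = {"NFE2": [summit(g.tss) for g in genes]}
        res = cb.fraction_bound_within(genes, by_tf)
        assert all(v == 1.0 for v in res["NFE2"].values())

    def test_no_summits_gives_zero(self):
        genes = [gene("g1", 1_000)]
        res = cb.fraction_bound_within(genes, {"NFE2": []})
        assert res["NFE2"][20_000] == 0.0

    def test_empty_subset_rejected(self):
        with pytest.raises(cb.ParameterError):
            cb.fraction_bound_within([], {"NFE2": []})


def three_group_matrix(rng, n_per_group=40, n_bins=100):
    """Rows from three planted signal classes over (NFE2, FLI1, RUNX1)."""
    blocks = []
    labels = []
    shape = np.exp(-0.5 * ((np.arange(n_bins) - n_bins / 2) / 8) ** 2)
    for grp, (fli1, runx1) in enumerate([(8.0, 8.0), (8.0, 0.0), (0.0, 0.0)]):
        for _ in range(n_per_group):
            nfe2 = 6.0 * shape + rng.normal(0, 0.3, n_bins)
            f = fli1 * shape + rng.normal(0, 0.3, n_bins)
            r = runx1 * shape + rng.normal(0, 0.3, n_bins)
            blocks.append(np.concatenate([nfe2, f, r]))
            labels.append(grp)
    m = SignalMatrix(
        matrix=np.clip(np.array(blocks), 0, None),
        tf_order=("NFE2", "FLI1", "RUNX1"),
        n_bins_per_tf=n_bins,
    )
    return m, np.array(labels)


class TestKmeansSites:
    def test_recovers_planted_groups(self):
        rng = np.random.default_rng(7)
        m, labels = three_group_matrix(rng)
        assignment = cb.kmeans_sites(m, k=3, seed=0)
        assert adjusted_rand_score(labels, assignment.labels) >= 0.8

    def test_cluster_one_has_highest_cofactor_signal(self):
        rng = np.random.default_rng(7)
        m, labels = three_group_matrix(rng)
        assignment = cb.kmeans_sites(m, k=3, seed=0)
        stats = assignment.cluster_order_statistic
        assert np.all(np.diff(stats) <= 0)
        # the co-bound planted group (0) should map to cluster 1
        majority = np.bincount(assignment.labels[labels == 0]).argmax()
        assert majority == 1

    def test_identical_rows_degenerate(self):
        m = SignalMatrix(
            matrix=np.ones((10, 30)), tf_order=("NFE2", "FLI1", "RUNX1"),
            n_bins_per_tf=10,
        )
        with pytest.warns(UserWarning, match="constant"):
            assignment = cb.kmeans_sites(m, k=3, seed=0)
        assert assignment.degenerate
        assert np.all(assignment.labels == 1)

    def test_row_permutation_permutes_labels(self):
        rng = np.random.default_rng(8)
        m, _ = three_group_matrix(rng)
        assignment = cb.kmeans_sites(m, k=3, seed=0)
        perm = rng.permutation(m.matrix.shape[0])
        m2 = SignalMatrix(matrix=m.matrix[perm], tf_order=m.tf_order,
                          n_bins_per_tf=m.n_bins_per_tf)
        assignment2 = cb.kmeans_sites(m2, k=3, seed=0)
        assert np.array_equal(assignment2.labels, assignment.labels[perm])

    def test_k_exceeding_rows_rejected(self):
        m = SignalMatrix(matrix=np.ones((2, 10)), tf_order=("NFE2",),
                         n_bins_per_tf=10)
        with pytest.raises(cb.ParameterError):
            cb.kmeans_sites(m, k=3, seed=0)


class TestEnrichment:
    def test_odds_ratio_of_reported_table(self):
        res = cb.fisher_enrichment([[270, 422], [60, 348]])
        assert res.odds_ratio == pytest.approx(270 * 348 / (422 * 60), rel=1e-9)

    def test_proportional_table_is_null(self):
        res = cb.fisher_enrichment([[30, 70], [60, 140]])
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value >= 0.99

    def test_zero_cell_gets_continuity_correction(self):
        res = cb.fisher_enrichment([[10, 0], [5, 5]])
        expected = (10.5 * 5.5) / (0.5 * 5.5)
        assert res.odds_ratio == pytest.approx(expected)

    def test_gene_level_contingency(self):
        labels = {f"m{i}": "triple" if i < 8 else "none" for i in range(10)}
        labels.update({f"o{i}": "triple" if i < 2 else "none" for i in range(10)})
        res = cb.enrichment_test(labels, "triple", lambda g: g.startswith("m"))
        assert res.contingency.tolist() == [[8, 2], [2, 8]]
        assert res.odds_ratio > 1

    def test_group_must_be_proper_subset(self):
        labels = {"a": 1, "b": 2}
        with pytest.raises(cb.ParameterError):
            cb.enrichment_test(labels, 1, lambda g: True)

    def test_planted_triples_enrich_mat_selective_genes(self, genome, truth):
        summits_by_tf = {
            tf: cb.simulate.true_summits(truth, tf) for tf in cb.TF_NAMES
        }
        loci = cb.merge_cooccupancy(summits_by_tf)
        labels = cb.gene_combination_assignment(genome.genes, loci)
        triple = frozenset(cb.TF_NAMES)
        mat_ids = {
            g.gene_id for g in genome.genes
            if cb.expression_class(g) == "mat"
        }
        flat = {g: (lab == triple) for g, lab in labels.items()}
        res = cb.enrichment_test(flat, True, lambda g: g in mat_ids)
        assert res.odds_ratio > 1.0
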