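"""Locus grouping, gene assignment, power-matched selection, block comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from traitspec import loci
from traitspec.loci import (
    assign_genes,
    group_loci,
    ld_block_compare,
    locus_concordance,
    nearest_gene_hit_counts,
    overlap_fraction,
    select_top_locus_genes,
)


def hits_frame(rows):
    return pd.DataFrame(rows, columns=["variant", "chrom", "pos", "pval"])


def genes_frame(rows):
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


def burden_frame(rows):
    df = pd.DataFrame(rows, columns=["gene", "pval"])
    df["beta"], df["se"] = 0.1, 0.05
    return df


class TestGroupLoci:
    def test_hand_traced_closure(self):
        # 2.7 Mb hit joins via transitive closure (0.9 Mb from the 1.8 Mb hit)
        hits = hits_frame([
            ("a", "chr1", 1_000_000, 1e-30),
            ("b", "chr1", 1_800_000, 1e-10),
            ("c", "chr1", 2_700_000, 1e-9),
            ("d", "chr1", 10_000_000, 1e-8),
        ])
        out = group_loci(hits)
        assert len(out) == 2
        assert sorted(out[0].members["variant"]) == ["a", "b", "c"]
        assert list(out[1].members["variant"]) == ["d"]
        assert out[0].min_p == 1e-30

    def test_single_hit_single_locus(self):
        out = group_loci(hits_frame([("x", "chr2", 500, 1e-9)]))
        assert len(out) == 1 and out[0].n_hits == 1

    def test_chromosomes_never_merge(self):
        hits = hits_frame([("a", "chr1", 100, 1e-10), ("b", "chr2", 100, 1e-9)])
        assert len(group_loci(hits)) == 2

    def test_duplicate_ids_rejected(self):
        hits = hits_frame([("a", "chr1", 100, 1e-10), ("a", "chr1", 200, 1e-9)])
        with pytest.raises(ValueError, match="duplicate"):
            group_loci(hits)

    def test_invariants_on_random_hit_sets(self):
        # partition, cross-locus separation, and row-order independence
        rng = np.random.default_rng(0)
        for trial in range(100):
            n = rng.integers(2, 60)
            hits = hits_frame([
                (f"v{i}", f"chr{rng.integers(1, 4)}",
                 int(rng.integers(1, 30_000_000)), float(10.0 ** -rng.uniform(8, 30)))
                for i in range(n)
            ])
            out = group_loci(hits)
            assigned = [v for loc in out for v in loc.members["variant"]]
            assert sorted(assigned) == sorted(hits["variant"])  # partition
            for i, a in enumerate(out):
                for b in out[i + 1:]:
                    if a.chrom != b.chrom:
                        continue
                    gap = min(abs(pa - pb)
                              for pa in a.members["pos"] for pb in b.members["pos"])
                    assert gap > 1_000_000
            shuffled = hits.sample(frac=1.0, random_state=trial).reset_index(drop=True)
            out2 = group_loci(shuffled)
            key = lambda locs: sorted((l.chrom, l.start, l.end, l.n_hits) for l in locs)
            assert key(out) == key(out2)


class TestAssignGenes:
    @pytest.mark.parametrize("start,end,expect", [
        (1_200_000, 1_300_000, True),   # strictly inside
        (900_000, 1_000_000, True),     # shares exactly the boundary base
        (100_000, 999_999, False),      # one base short
    ])
    def test_inclusive_overlap_rule(self, start, end, expect):
        locus_list = group_loci(hits_frame([
            ("a", "chr1", 1_000_000, 1e-10), ("b", "chr1", 1_500_000, 1e-9)]))
        genes = genes_frame([("g1", "chr1", start, end)])
        assign_genes(locus_list, genes)
        assert (locus_list[0].genes == ["g1"]) is expect

    def test_other_chromosome_not_assigned(self):
        locus_list = group_loci(hits_frame([("a", "chr1", 1_000_000, 1e-10)]))
        assign_genes(locus_list, genes_frame([("g1", "chr2", 900_000, 1_100_000)]))
        assert locus_list[0].genes == []


def three_locus_toy():
    """Three loci; five genes; three burden-significant genes total."""
    hits = hits_frame([
        ("a", "chr1", 1_000_000, 1e-40),   # locus 1 (top)
        ("b", "chr1", 10_000_000, 1e-20),  # locus 2
        ("c", "chr1", 20_000_000, 1e-10),  # locus 3
    ])
    genes = genes_frame([
        ("g1", "chr1", 900_000, 1_000_000),
        ("g2", "chr1", 1_000_000, 1_050_000),
        ("g5", "chr1", 9_900_000, 10_100_000),
        ("g7", "chr1", 19_900_000, 20_100_000),
    ])
    burden = burden_frame([
        ("g1", 1e-8), ("g2", 1e-7),   # significant, locus 1
        ("g5", 1e-3),                 # locus 2 best, not significant
        ("g7", 1e-9),                 # significant, locus 3
        ("g9", 0.5),
    ])
    locus_list = assign_genes(group_loci(hits), genes)
    return locus_list, burden


class TestTopLocusSelection:
    def test_hand_traced_walk(self):
        locus_list, burden = three_locus_toy()
        selected, top = select_top_locus_genes(locus_list, burden, 2.7e-6)
        # 3 significant genes genome-wide; locus 1 gives {g1, g2}, locus 2
        # gives its min-p gene g5, reaching the target of 3
        assert selected == {"g1", "g2", "g5"}
        assert len(top) == 2

    def test_one_significant_gene_per_locus(self):
        hits = hits_frame([
            ("a", "chr1", 1_000_000, 1e-40), ("b", "chr1", 10_000_000, 1e-20)])
        genes = genes_frame([
            ("g1", "chr1", 950_000, 1_050_000), ("g2", "chr1", 9_950_000, 10_050_000)])
        burden = burden_frame([("g1", 1e-9), ("g2", 1e-8)])
        locus_list = assign_genes(group_loci(hits), genes)
        selected, top = select_top_locus_genes(locus_list, burden, 2.7e-6)
        assert len(top) == 2 and selected == {"g1", "g2"}

    def test_empty_locus_consumes_a_rank_slot(self):
        hits = hits_frame([
            ("a", "chr1", 1_000_000, 1e-40),   # top locus: no genes
            ("b", "chr1", 10_000_000, 1e-20)])
        genes = genes_frame([("g2", "chr1", 9_950_000, 10_050_000)])
        burden = burden_frame([("g2", 1e-8)])
        locus_list = assign_genes(group_loci(hits), genes)
        selected, top = select_top_locus_genes(locus_list, burden, 2.7e-6)
        assert selected == {"g2"} and len(top) == 2

    def test_no_significant_genes_warns_empty(self):
        locus_list, burden = three_locus_toy()
        burden["pval"] = 0.5
        with pytest.warns(RuntimeWarning, match="empty"):
            selected, top = select_top_locus_genes(locus_list, burden, 2.7e-6)
        assert selected == set() and top == []

    def test_overshoot_versus_strict_stop(self):
        # one locus holding three significant genes against a target of two
        hits = hits_frame([("a", "chr1", 1_000_000, 1e-40),
                           ("z", "chr2", 1_000_000, 1e-6)])
        genes = genes_frame([("g1", "chr1", 950_000, 1_000_000),
                             ("g2", "chr1", 1_000_000, 1_020_000),
                             ("g3", "chr1", 1_000_000, 1_010_000),
                             ("g4", "chr2", 900_000, 1_100_000)])
        burden = burden_frame([("g1", 1e-9), ("g2", 1e-8), ("g3", 1e-7)])
        # g4 absent from burden; only 3 significant but target counts all 3
        locus_list = assign_genes(group_loci(hits), genes)
        full, _ = select_top_locus_genes(locus_list, burden, 2.7e-6)
        assert full == {"g1", "g2", "g3"}
        strict, _ = select_top_locus_genes(locus_list, burden, 2.7e-6, strict_stop=True)
        assert len(strict) == 3


class TestOverlapFraction:
    def test_extremes_and_toy(self):
        locus_list, burden = three_locus_toy()
        _, top = select_top_locus_genes(locus_list, burden, 2.7e-6)
        sig = burden.loc[burden["pval"] < 2.7e-6, "gene"]
        # g1, g2 sit in top locus 1; g7's locus 3 was not needed
        assert overlap_fraction(sig, top) == pytest.approx(2 / 3)
        assert overlap_fraction(sig, []) == 0.0
        with pytest.raises(ValueError):
            overlap_fraction([], top)


class TestConcordance:
    def make(self, gwas_ps, burden_ps):
        hits = hits_frame([
            (f"v{i}", "chr1", 1_000_000 + 5_000_000 * i, p)
            for i, p in enumerate(gwas_ps)])
        genes = genes_frame([
            (f"g{i}", "chr1", 1_000_000 + 5_000_000 * i - 1000,
             1_000_000 + 5_000_000 * i + 1000) for i in range(len(gwas_ps))])
        burden = burden_frame([(f"g{i}", p) for i, p in enumerate(burden_ps)])
        return assign_genes(group_loci(hits), genes), burden

    def test_identical_ranking_rho_one(self):
        ps = [1e-30, 1e-20, 1e-15, 1e-10, 1e-8]
        locus_list, burden = self.make(ps, ps)
        _, rho = locus_concordance(locus_list, burden)
        assert rho == pytest.approx(1.0)

    def test_reversed_ranking_rho_minus_one(self):
        locus_list, burden = self.make(
            [1e-30, 1e-20, 1e-15, 1e-10, 1e-8],
            [1e-8, 1e-10, 1e-15, 1e-20, 1e-30])
        _, rho = locus_concordance(locus_list, burden)
        assert rho == pytest.approx(-1.0)

    def test_hand_computed_five_locus_rho(self):
        gwas = [1e-30, 1e-20, 1e-15, 1e-10, 1e-8]
        burden = [1e-12, 1e-30, 1e-6, 1e-9, 1e-3]
        # ranks of -log10: gwas (1..5), burden (2,1,4,3,5): rho = 1 - 6*4/120
        locus_list, btab = self.make(gwas, burden)
        _, rho = locus_concordance(locus_list, btab)
        assert rho == pytest.approx(1 - 6 * 4 / (5 * 24))

    def test_too_few_loci_flagged(self):
        locus_list, burden = self.make([1e-30, 1e-8], [1e-9, 1e-3])
        table, rho = locus_concordance(locus_list, burden)
        assert rho is None and len(table) == 2

    def test_concordance_rises_as_noise_falls(self, synth_universe, scaled_grid):
        # regenerate burden statistics at three noise levels over the same
        # truth and GWAS: rank concordance must increase with sample size
        from traitspec import synthetic
        truth = synth_universe["truth"]
        genes = synth_universe["genes"]
        hits = synth_universe["gwas"].hits(0)
        locus_list = assign_genes(group_loci(hits), genes)
        rhos = []
        for n_samples in (40_000, 360_000, 3_240_000):
            burden = synthetic.generate_burden_stats(truth, n_samples, seed=21)
            b0 = burden.loc[burden["trait"] == 0]
            _, rho = locus_concordance(locus_list, b0)
            rhos.append(rho)
        assert rhos[0] < rhos[1] < rhos[2]
        assert rhos[1] > 0


class TestLdBlockCompare:
    def blocks(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def test_four_block_toy_values(self):
        blocks = self.blocks([("chr1", 1, 1000), ("chr1", 1001, 2000),
                              ("chr1", 2001, 3000), ("chr1", 3001, 4000)])
        gwas = hits_frame([("a", "chr1", 500, 1e-9), ("b", "chr1", 1500, 1e-12),
                           ("c", "chr1", 2500, 1e-7), ("d", "chr1", 3500, 1e-20)])
        genes = genes_frame([("g1", "chr1", 400, 600), ("g2", "chr1", 1400, 1600),
                             ("g3", "chr1", 2400, 2600), ("g4", "chr1", 3400, 3600)])
        burden = burden_frame([("g1", 1e-3), ("g2", 1e-8), ("g3", 0.5), ("g4", 1e-5)])
        out = ld_block_compare(blocks, gwas, burden, genes)
        assert len(out) == 4
        np.testing.assert_allclose(out["min_gwas_p"], [1e-9, 1e-12, 1e-7, 1e-20])
        np.testing.assert_allclose(out["min_burden_p"], [1e-3, 1e-8, 0.5, 1e-5])

    def test_spanning_gene_drops_both_blocks(self):
        blocks = self.blocks([("chr1", 1, 1000), ("chr1", 1001, 2000),
                              ("chr1", 2001, 3000)])
        gwas = hits_frame([("a", "chr1", 500, 1e-9), ("b", "chr1", 1500, 1e-12),
                           ("c", "chr1", 2500, 1e-7)])
        genes = genes_frame([("g1", "chr1", 800, 1200),   # spans blocks 1-2
                             ("g3", "chr1", 2400, 2600)])
        burden = burden_frame([("g1", 1e-10), ("g3", 0.5)])
        out = ld_block_compare(blocks, gwas, burden, genes)
        assert list(out["min_burden_gene"]) == ["g3"]

    def test_unique_min_gene_blocks_never_dropped(self):
        blocks = self.blocks([("chr1", 1, 1000), ("chr1", 1001, 2000)])
        gwas = hits_frame([("a", "chr1", 500, 1e-9), ("b", "chr1", 1500, 1e-12)])
        genes = genes_frame([("g1", "chr1", 400, 600), ("g2", "chr1", 1400, 1600)])
        burden = burden_frame([("g1", 1e-5), ("g2", 1e-6)])
        out = ld_block_compare(blocks, gwas, burden, genes)
        assert len(out) == 2

    def test_block_without_variants_excluded(self):
        blocks = self.blocks([("chr1", 1, 1000), ("chr1", 1001, 2000)])
        gwas = hits_frame([("a", "chr1", 500, 1e-9)])
        genes = genes_frame([("g1", "chr1", 400, 600), ("g2", "chr1", 1400, 1600)])
        burden = burden_frame([("g1", 1e-5), ("g2", 1e-6)])
        out = ld_block_compare(blocks, gwas, burden, genes)
        assert list(out["block"]) == [0]

    def test_overlapping_blocks_rejected(self):
        blocks = self.blocks([("chr1", 1, 1000), ("chr1", 500, 2000)])
        with pytest.raises(ValueError, match="overlap"):
            ld_block_compare(blocks, hits_frame([]), burden_frame([]), genes_frame([]))


class TestNearestGene:
    def test_exact_midpoint_and_tie_rule(self):
        genes = genes_frame([("g1", "chr1", 100, 300), ("g2", "chr1", 500, 700)])
        # midpoints 200 and 600; hit at 200 exact; hit at 400 equidistant
        hits = hits_frame([("a", "chr1", 200, 1e-9), ("b", "chr1", 400, 1e-9)])
        counts = nearest_gene_hit_counts(hits, genes)
        assert counts["g1"] == 2 and counts["g2"] == 0

    def test_counts_conserved(self, rng):
        genes = genes_frame([
            (f"g{i}", "chr1", int(p), int(p) + 100)
            for i, p in enumerate(np.sort(rng.integers(1, 10_000_000, 50)))])
        hits = hits_frame([
            (f"v{i}", "chr1", int(p), 1e-9)
            for i, p in enumerate(rng.integers(1, 10_000_000, 200))])
        counts = nearest_gene_hit_counts(hits, genes)
        assert counts.sum() == 200

    def test_chromosome_without_genes_warns(self):
        genes = genes_frame([("g1", "chr1", 100, 300)])
        hits = hits_frame([("a", "chr2", 200, 1e-9)])
        with pytest.warns(RuntimeWarning, match="no genes"):
            counts = nearest_gene_hit_counts(hits, genes)
        assert counts.sum() == 0
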