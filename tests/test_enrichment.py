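"""Upstream-window density statistic and the Monte Carlo resampling null."""

import numpy as np
import pytest
from scipy import stats

from alusite import (
    DensityResult,
    GeneRecord,
    GenomeSequence,
    GuideSiteEnrichment,
    GuideSpec,
    WindowSpec,
    find_guide_sites,
    gene_density,
    mc_enrichment,
    set_mean_density,
    upstream_window,
)
from alusite.simulate import simulate_dataset

from _oracles import count_starts_in_window, exact_subset_p
from conftest import small_config

PROTO = "GATTCGCAAGCTGT"


class TestUpstreamWindow:
    def test_plus_strand_default_window(self):
        gene = GeneRecord("g", "c1", 50_000, "+")
        assert upstream_window(gene, WindowSpec(), 100_000) == (40_000, 51_000, 11.0)

    def test_minus_strand_mirrors(self):
        gene = GeneRecord("g", "c1", 50_000, "-")
        assert upstream_window(gene, WindowSpec(), 100_000) == (49_000, 60_000, 11.0)

    def test_clipped_at_contig_start(self):
        gene = GeneRecord("g", "c1", 500, "+")
        assert upstream_window(gene, WindowSpec(), 100_000) == (0, 1_500, 1.5)

    def test_clipped_at_contig_end(self):
        gene = GeneRecord("g", "c1", 99_900, "-")
        start, end, kb = upstream_window(gene, WindowSpec(), 100_000)
        assert (start, end) == (98_900, 100_000) and kb == pytest.approx(1.1)


def _planted_genome(positions, length=30_000):
    seq = list("T" * length)
    for pos in positions:
        seq[pos : pos + 17] = list(PROTO + "AGG")
    return GenomeSequence({"c1": "".join(seq)})


class TestGeneDensity:
    def test_zero_hits(self):
        genome = _planted_genome([])
        gene = GeneRecord("g", "c1", 15_000, "+")
        assert gene_density([], gene, WindowSpec(), genome) == 0.0

    def test_unit_density(self):
        # 11 sites in the full 11-kb window -> 1.0 per kb
        gene = GeneRecord("g", "c1", 15_000, "+")
        positions = [5_000 + 1_000 * i for i in range(11)]
        genome = _planted_genome(positions)
        hits = find_guide_sites(genome, GuideSpec("g1", PROTO))
        assert gene_density(hits, gene, WindowSpec(), genome) == pytest.approx(1.0)

    def test_degenerate_window_rejected(self):
        # upstream-only window at the very start of a contig clips to nothing
        gene = GeneRecord("g", "c1", 0, "+")
        with pytest.raises(ValueError, match="degenerate"):
            gene_density([], gene, WindowSpec(10.0, 0.0), GenomeSequence({"c1": "A"}))

    def test_matches_brute_force_recount(self, small_dataset, small_hits, rng):
        spec = small_dataset.config.window
        for gene in list(small_dataset.genes)[:20]:
            start, end, kb = upstream_window(
                gene, spec, small_dataset.genome.length_of(gene.contig)
            )
            expected = count_starts_in_window(small_hits, gene.contig, start, end) / kb
            got = gene_density(small_hits, gene, spec, small_dataset.genome)
            assert got == pytest.approx(expected)


class TestSetMeanDensity:
    def test_single_gene(self, small_dataset, small_hits):
        gene = small_dataset.genes[0]
        d = gene_density(small_hits, gene, small_dataset.config.window,
                         small_dataset.genome)
        res = set_mean_density([gene], small_hits, small_dataset.config.window,
                               small_dataset.genome)
        assert res.n_genes == 1 and res.mean_density == pytest.approx(d)

    def test_mean_is_unweighted_mean_in_input_order(self, small_dataset, small_hits):
        genes = list(small_dataset.genes)[:10]
        res = set_mean_density(genes, small_hits, small_dataset.config.window,
                               small_dataset.genome)
        per_gene = [
            gene_density(small_hits, g, small_dataset.config.window,
                         small_dataset.genome)
            for g in genes
        ]
        assert list(res.per_gene_density) == pytest.approx(per_gene)
        assert res.mean_density == pytest.approx(np.mean(per_gene))

    def test_empty_set_rejected(self, small_dataset, small_hits):
        with pytest.raises(ValueError, match="non-empty"):
            set_mean_density([], small_hits, WindowSpec(), small_dataset.genome)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            DensityResult("s", 2, (0.1,), 0.1)
        with pytest.raises(ValueError):
            DensityResult("s", 1, (-0.1,), -0.1)


def _toy_model(densities, window_kb=11.0):
    """Pool with prescribed per-gene densities via planted single-contig genes."""
    # one gene per 12-kb slot on a long T contig; plant round(d * 11) sites
    n = len(densities)
    length = 12_000 * n + 2_000
    seq = list("T" * length)
    genes = []
    for i, d in enumerate(densities):
        win_start = 1_000 + 12_000 * i
        tss = win_start + 10_000
        genes.append(GeneRecord(f"g{i}", "c1", tss, "+"))
        count = int(round(d * 11.0))
        for j in range(count):
            pos = win_start + 20 * j
            seq[pos : pos + 17] = list(PROTO + "AGG")
    genome = GenomeSequence({"c1": "".join(seq)})
    hits = find_guide_sites(genome, GuideSpec("g1", PROTO))
    return genome, genes, hits


class TestMCEnrichment:
    def test_homogeneous_pool_gives_p_one(self):
        genome, genes, hits = _toy_model([2 / 11.0] * 8)
        observed = set_mean_density(genes[:3], hits, WindowSpec(), genome)
        res = mc_enrichment(observed, genes, hits, WindowSpec(), genome,
                            n_perm=500, seed=5)
        assert res.p_value == 1.0
        assert res.exceed_count == 500

    def test_matches_exact_enumeration_oracle(self):
        # densities {0,0,0,1,1} sites/kb, n=2, observed mean 1.0 -> exact p=1/10
        genome, genes, hits = _toy_model([0, 0, 0, 1, 1])
        observed = set_mean_density(genes[3:], hits, WindowSpec(), genome)
        assert observed.mean_density == pytest.approx(1.0)
        pool_densities = set_mean_density(genes, hits, WindowSpec(), genome)
        exact = exact_subset_p(pool_densities.per_gene_density, 2, 1.0)
        assert exact == pytest.approx(0.1)
        n_perm = 100_000
        res = mc_enrichment(observed, genes, hits, WindowSpec(), genome,
                            n_perm=n_perm, seed=123)
        se = np.sqrt(exact * (1 - exact) / n_perm)
        assert abs(res.p_value - exact) <= 3 * se

    def test_reproducible_from_seed(self):
        genome, genes, hits = _toy_model([0, 1, 2, 0, 1, 3, 0, 2])
        observed = set_mean_density(genes[:3], hits, WindowSpec(), genome)
        r1 = mc_enrichment(observed, genes, hits, WindowSpec(), genome,
                           n_perm=2_000, seed=42)
        r2 = mc_enrichment(observed, genes, hits, WindowSpec(), genome,
                           n_perm=2_000, seed=42)
        assert r1 == r2

    def test_exceed_count_monotone_in_observed_mean(self):
        genome, genes, hits = _toy_model([0, 1, 2, 0, 1, 3, 0, 2])
        model = GuideSiteEnrichment(None, genes, hits, genome)
        counts = []
        for mean in [0.0, 0.05, 0.1, 0.15, 0.2, 0.3]:
            obs = DensityResult("s", 3, (mean, mean, mean), mean)
            counts.append(model._fit_observed(obs, 1_000, seed=9,
                                              estimator="plain").exceed_count)
        assert counts == sorted(counts, reverse=True)

    def test_zero_exceedance_flagged(self):
        # an observed mean above every pool density can never be exceeded
        genome, genes, hits = _toy_model([0, 0, 0, 0, 0, 2])
        observed = DensityResult("s", 2, (5.0, 5.0), 5.0)
        res = mc_enrichment(observed, genes, hits, WindowSpec(), genome,
                            n_perm=200, seed=1)
        assert res.exceed_count == 0 and res.p_value == 0.0
        assert res.p_flag == "p < 0.005"

    def test_plus_one_estimator(self):
        genome, genes, hits = _toy_model([0, 0, 0, 0, 0, 2])
        observed = DensityResult("s", 2, (5.0, 5.0), 5.0)
        res = mc_enrichment(observed, genes, hits, WindowSpec(), genome,
                            n_perm=200, seed=1, estimator="plus_one")
        assert res.p_value == pytest.approx(1 / 201)
        assert res.p_flag is None

    def test_set_larger_than_pool_rejected(self):
        genome, genes, hits = _toy_model([0, 1, 2])
        observed = set_mean_density(genes, hits, WindowSpec(), genome)
        with pytest.raises(ValueError, match="pool"):
            mc_enrichment(observed, genes, hits, WindowSpec(), genome,
                          n_perm=10, seed=0)

    def test_pool_precompute_equals_per_gene_recomputation(
        self, small_dataset, small_hits
    ):
        model = GuideSiteEnrichment(
            small_dataset.enriched_genes, small_dataset.genes, small_hits,
            small_dataset.genome, small_dataset.config.window,
        )
        recomputed = [
            gene_density(small_hits, g, small_dataset.config.window,
                         small_dataset.genome)
            for g in model.pool_genes
        ]
        assert list(model.pool_densities) == pytest.approx(recomputed)

    def test_aggregate_statistic_is_total_over_total(self, small_dataset, small_hits):
        model = GuideSiteEnrichment(
            small_dataset.enriched_genes, small_dataset.genes, small_hits,
            small_dataset.genome, small_dataset.config.window,
            statistic="aggregate",
        )
        obs = model.observed_density()
        counts = [
            gene_density(small_hits, g, small_dataset.config.window,
                         small_dataset.genome) * 11.0
            for g in small_dataset.enriched_genes
        ]
        assert obs.mean_density == pytest.approx(sum(counts) / (11.0 * len(counts)))


class TestNullCalibration:
    def test_resampled_set_pvalues_are_uniform_like(self, small_dataset, small_hits):
        # p-values of sets drawn from the pool itself pass a KS uniformity
        # sanity check at alpha = 0.01
        rng = np.random.default_rng(7)
        model = GuideSiteEnrichment(None, small_dataset.genes, small_hits,
                                    small_dataset.genome,
                                    small_dataset.config.window)
        pool = model.pool_genes
        pvals = []
        for i in range(200):
            subset = [pool[j] for j in rng.choice(len(pool), size=13, replace=False)]
            observed = set_mean_density(subset, small_hits,
                                        small_dataset.config.window,
                                        small_dataset.genome)
            res = model._fit_observed(observed, n_perm=800, seed=int(rng.integers(2**31)),
                                      estimator="plain")
            pvals.append(res.p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_modestly_planted_sets_are_mostly_nonsignificant(self):
        # sets planted at 0.280/kb (n=13) and 0.224/kb (n=15) over the 0.215
        # background mostly fail to reach p < 0.05, as expected for rates
        # this close to the null; pooled over both set kinds
        pvals = []
        for kind, (size, rate) in enumerate({13: 0.280, 15: 0.224}.items()):
            for rep in range(15):
                cfg = small_config(
                    1_000 * kind + rep,
                    pool_size=200,
                    enriched_set_size=size,
                    enriched_density=rate,
                    n_contigs=6,
                    contig_length=620_000,
                )
                ds = simulate_dataset(cfg, with_peaks=False)
                hits = find_guide_sites(ds.genome, cfg.guide)
                model = GuideSiteEnrichment(
                    ds.enriched_genes, ds.genes, hits, ds.genome, cfg.window,
                )
                pvals.append(model.fit(n_perm=2_000, seed=rep).p_value)
        assert sum(p > 0.05 for p in pvals) > len(pvals) / 2
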