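import math

import numpy as np
import pytest

from soi.model import GenePair, gene_index
from soi.oi import annotate_blocks, filter_blocks
from soi.simulate import (
    SPECIES_PAIRS,
    ConfusionCounts,
    SimulationConfig,
    detect_blocks,
    default_fp_rate,
    derive_seed,
    emulate_orthology_calls,
    evaluate,
    family_homolog_pairs,
    fragment_assembly,
    merged_genome,
    run_benchmark,
    run_replicate,
    simulate_history,
    subsample_annotation,
)

from conftest import make_gene_records
from oracles import chain_oracle


QUIET = dict(loss_rate=0.0, inversion_rate=0.0, transposition_rate=0.0,
             duplication_rate=0.0, origination_rate=0.0)


class TestSimulateHistory:
    def test_no_event_limit(self):
        cfg = SimulationConfig(n_genes=40, n_chromosomes=2, delta_t=0.3,
                               seed=0, **QUIET)
        truth = simulate_history(cfg)
        for sp in ("A1", "A2", "B1", "B2", "O"):
            assert len(truth.genomes[sp]) == 40
        # orthologs: A1-B1 and A2-B2 per family; out-paralogs the other combos
        assert len(truth.true_orthologs) == 2 * 40
        assert len(truth.true_outparalogs) == 2 * 40
        assert truth.dup_pairs == set()
        # every A-vs-B homolog pair labeled
        n_pairs = sum(
            len(truth.homolog_pairs(x, y)) for x, y in SPECIES_PAIRS
        )
        assert n_pairs == 4 * 40

    def test_truth_classes_are_disjoint_and_exhaustive(self):
        cfg = SimulationConfig(n_genes=120, n_chromosomes=3, delta_t=0.2,
                               fold=300, seed=5)
        truth = simulate_history(cfg)
        assert not truth.true_orthologs & truth.true_outparalogs
        assert not truth.true_orthologs & truth.dup_pairs
        assert not truth.true_outparalogs & truth.dup_pairs
        labeled = truth.true_orthologs | truth.true_outparalogs | truth.dup_pairs
        all_pairs = {
            p.key() for x, y in SPECIES_PAIRS for p in truth.homolog_pairs(x, y)
        }
        assert labeled == all_pairs

    def test_fixed_seed_reproduces_identical_truth(self):
        cfg = SimulationConfig(n_genes=80, delta_t=0.1, fold=200, seed=9)
        t1, t2 = simulate_history(cfg), simulate_history(cfg)
        assert t1.true_orthologs == t2.true_orthologs
        assert t1.true_outparalogs == t2.true_outparalogs
        assert [
            (r.gene_id, r.chrom, r.order_index) for r in t1.genomes["A1"]
        ] == [
            (r.gene_id, r.chrom, r.order_index) for r in t2.genomes["A1"]
        ]
        assert t1.ks == t2.ks

    def test_loss_survival_matches_closed_form(self):
        # tune the loss rate so each branch removes ~10% of its genes
        n = 2000
        rate = 0.1  # per gene per unit branch; branches below are length 1
        cfg = SimulationConfig(
            n_genes=n, n_chromosomes=4, delta_t=1.0, post_speciation_t=1.0,
            pre_wgd_t=0.0, stem_t=0.0, loss_rate=rate / 10,
            inversion_rate=0.0, transposition_rate=0.0,
            duplication_rate=0.0, origination_rate=0.0,
            fold=1.0, seed=13,
        )
        # expected: gene survives the shared W->S branch (delta_t) and both
        # post-speciation branches independently; each branch removes a
        # Poisson(rate*L*n0) draw of uniformly chosen genes, so per-branch
        # survival is ~(1 - rate*L) = 0.99 for W->S at rate/10, 0.99 each side
        p_branch = 1 - cfg.loss_rate * 1.0
        expected_pairs = 2 * n * p_branch * p_branch * p_branch
        truth = simulate_history(cfg)
        observed = len(truth.true_orthologs)
        sd = math.sqrt(2 * n * 0.25)  # loose binomial bound
        assert abs(observed - expected_pairs) < 3.5 * sd

    def test_excessive_loss_is_hard_error(self):
        with pytest.raises(ValueError, match="surviv"):
            simulate_history(SimulationConfig(n_genes=50, delta_t=0.5,
                                              loss_rate=0.5, fold=100))

    def test_specific_wgd_scenario_has_no_cross_outparalogs(self):
        cfg = SimulationConfig(n_genes=60, n_chromosomes=2, delta_t=0.2,
                               scenario="specific_wgd", seed=2, **QUIET)
        truth = simulate_history(cfg)
        assert truth.true_outparalogs == set()
        # every combination of subgenomes is orthologous: 4 pairs per family
        assert len(truth.true_orthologs) == 4 * 60


class TestEmulation:
    def test_zero_error_reproduces_truth_exactly(self):
        cfg = SimulationConfig(n_genes=50, delta_t=0.2, seed=1,
                               fp_rate=lambda dt: 0.0,
                               fn_rate=lambda dt: 0.0, **QUIET)
        truth = simulate_history(cfg)
        omap = emulate_orthology_calls(truth)
        assert {frozenset(p) for p in omap} == truth.true_orthologs

    def test_inverted_error_reproduces_outparalogs_exactly(self):
        cfg = SimulationConfig(n_genes=50, delta_t=0.2, seed=1,
                               fp_rate=lambda dt: 1.0,
                               fn_rate=lambda dt: 1.0, **QUIET)
        truth = simulate_history(cfg)
        omap = emulate_orthology_calls(truth)
        assert {frozenset(p) for p in omap} == truth.true_outparalogs

    def test_realized_rates_within_binomial_bounds(self):
        cfg = SimulationConfig(n_genes=2500, n_chromosomes=5, delta_t=0.2,
                               seed=3, fp_rate=lambda dt: 0.15,
                               fn_rate=lambda dt: 0.15, **QUIET)
        truth = simulate_history(cfg)
        omap = emulate_orthology_calls(truth)
        called = {frozenset(p) for p in omap}
        n_orth, n_outp = len(truth.true_orthologs), len(truth.true_outparalogs)
        fp = len(called & truth.true_outparalogs)
        fn = n_orth - len(called & truth.true_orthologs)
        for observed, n in ((fp, n_outp), (fn, n_orth)):
            sd = math.sqrt(n * 0.15 * 0.85)
            assert abs(observed - 0.15 * n) < 3 * sd

    def test_invalid_rate_is_hard_error(self):
        cfg = SimulationConfig(n_genes=30, delta_t=0.2, seed=1,
                               fp_rate=lambda dt: 1.5, **QUIET)
        truth = simulate_history(cfg)
        with pytest.raises(ValueError):
            emulate_orthology_calls(truth)

    def test_default_error_model_anchors(self):
        assert default_fp_rate(0.01) == pytest.approx(0.15)
        assert default_fp_rate(0.05) == pytest.approx(0.15)
        assert default_fp_rate(0.5) == pytest.approx(0.01)
        assert default_fp_rate(1.0) == pytest.approx(0.01)


def grid_pairs(coords, genome_a="X", genome_b="Y", chrom_a="c1", chrom_b="c1"):
    """GenePairs + gene index realizing the given (x, y) rank coordinates."""
    genes = {}
    pairs = []
    from soi.model import GeneRecord

    for x, y in coords:
        ga = f"{genome_a}_{chrom_a}_{x}"
        gb = f"{genome_b}_{chrom_b}_{y}"
        genes[ga] = GeneRecord(genome_a, chrom_a, x * 10 + 1, x * 10 + 5,
                               "+", ga, x)
        genes[gb] = GeneRecord(genome_b, chrom_b, y * 10 + 1, y * 10 + 5,
                               "+", gb, y)
        pairs.append(GenePair(gene_a=ga, gene_b=gb, genome_a=genome_a,
                              genome_b=genome_b))
    return pairs, genes


class TestDetectBlocks:
    def test_perfect_collinear_run_is_one_block(self):
        pairs, genes = grid_pairs([(i, i) for i in range(10)])
        blocks = detect_blocks(pairs, genes, min_block=5, max_gap=25)
        assert len(blocks) == 1 and blocks[0].n_pairs == 10

    def test_gap_beyond_max_gap_splits_block(self):
        coords = [(i, i) for i in range(6)] + \
            [(i + 36, i + 36) for i in range(6)]
        pairs, genes = grid_pairs(coords)
        blocks = detect_blocks(pairs, genes, min_block=5, max_gap=25)
        assert [b.n_pairs for b in blocks] == [6, 6]

    def test_inverted_block_orientation(self):
        pairs, genes = grid_pairs([(i, 20 - i) for i in range(8)])
        (block,) = detect_blocks(pairs, genes, min_block=5)
        assert block.orientation == "inverted"

    def test_short_chains_dropped(self):
        pairs, genes = grid_pairs([(i, i) for i in range(4)])
        assert detect_blocks(pairs, genes, min_block=5) == []

    def test_agreement_with_exhaustive_chaining_oracle(self):
        rng = np.random.default_rng(7)
        for trial in range(15):
            n = int(rng.integers(20, 200))
            xs = rng.choice(400, size=n, replace=False)
            ys = rng.choice(400, size=n, replace=False)
            coords = sorted(zip(xs.tolist(), ys.tolist()))
            pairs, genes = grid_pairs(coords)
            blocks = detect_blocks(pairs, genes, min_block=3, max_gap=20)
            ours = sorted(
                tuple((p.gene_a, p.gene_b) for p in b.pairs) for b in blocks
            )
            points = [(x, y, (f"X_c1_{x}", f"Y_c1_{y}")) for x, y in coords]
            ref = sorted(chain_oracle(points, min_block=3, max_gap=20))
            assert ours == ref


class TestDegradation:
    def test_relative_n50_one_is_identity(self):
        genome = make_gene_records("A", {"c1": 60, "c2": 40})
        out = fragment_assembly(genome, 1.0, seed=0)
        assert {r.chrom for r in out} == {"c1", "c2"}
        assert len(out) == 100

    def test_fragmentation_halves_n50_and_keeps_content(self):
        genome = make_gene_records("A", {"c1": 100})
        out = fragment_assembly(genome, 0.5, seed=1)
        sizes = {}
        for r in out:
            sizes[r.chrom] = sizes.get(r.chrom, 0) + 1
        total = sum(sizes.values())
        acc, n50 = 0, 0
        for s in sorted(sizes.values(), reverse=True):
            acc += s
            if acc * 2 >= total:
                n50 = s
                break
        assert n50 <= 50
        assert sorted(r.gene_id for r in out) == \
            sorted(r.gene_id for r in genome)

    def test_invalid_relative_n50_is_error(self):
        with pytest.raises(ValueError):
            fragment_assembly(make_gene_records("A", {"c1": 10}), 1.5)

    def test_subsample_fraction_one_is_identity(self):
        genome = make_gene_records("A", {"c1": 30})
        kept, removed = subsample_annotation(genome, 1.0, seed=0)
        assert len(kept) == 30 and removed == []

    def test_subsample_within_binomial_bounds(self):
        genome = make_gene_records("A", {"c1": 500, "c2": 500})
        kept, removed = subsample_annotation(genome, 0.5, seed=2)
        sd = math.sqrt(1000 * 0.25)
        assert abs(len(kept) - 500) < 3 * sd

    def test_subsample_partition(self):
        genome = make_gene_records("A", {"c1": 50})
        kept, removed = subsample_annotation(genome, 0.6, seed=3)
        assert sorted([r.gene_id for r in kept] + removed) == \
            sorted(r.gene_id for r in genome)
        # order indices contiguous after removal
        by_chrom = {}
        for r in kept:
            by_chrom.setdefault(r.chrom, []).append(r.order_index)
        for idxs in by_chrom.values():
            assert sorted(idxs) == list(range(len(idxs)))


class TestEvaluate:
    def test_formulas(self):
        c = ConfusionCounts(tp=9, fp=1, fn=1)
        assert c.precision == pytest.approx(0.9)
        assert c.recall == pytest.approx(0.9)
        assert c.f1 == pytest.approx(0.9)

    def test_perfect_calls(self):
        cfg = SimulationConfig(n_genes=30, delta_t=0.2, seed=1, **QUIET)
        truth = simulate_history(cfg)
        c = evaluate(truth.true_orthologs, truth)
        assert (c.precision, c.recall, c.f1) == (1.0, 1.0, 1.0)

    def test_empty_calls_use_zero_convention(self):
        cfg = SimulationConfig(n_genes=30, delta_t=0.2, seed=1, **QUIET)
        truth = simulate_history(cfg)
        c = evaluate(set(), truth)
        assert (c.precision, c.recall, c.f1) == (0.0, 0.0, 0.0)

    def test_unlabeled_pairs_ignored(self):
        cfg = SimulationConfig(n_genes=30, delta_t=0.2, seed=1, **QUIET)
        truth = simulate_history(cfg)
        noise = {frozenset(("zz1", "zz2"))}
        c = evaluate(truth.true_orthologs | noise, truth)
        assert c.precision == 1.0


class TestBenchmark:
    def test_one_condition_one_replicate_gives_one_row_per_cutoff(self):
        summary = run_benchmark(
            delta_t_grid=(0.2,), fold_grid=(100.0,), replicates=1,
            oi_cutoffs=(0.5, 0.6), seed=0, n_genes=100,
        )
        assert len(summary) == 2
        assert sorted(summary["cutoff"]) == [0.5, 0.6]

    def test_same_master_seed_reproduces_table(self):
        kwargs = dict(delta_t_grid=(0.1, 0.3), fold_grid=(200.0,),
                      replicates=2, seed=7, n_genes=100)
        t1 = run_benchmark(**kwargs)
        t2 = run_benchmark(**kwargs)
        assert t1.equals(t2)

    def test_derived_seeds_below_2_31(self):
        for key in ((0, 0, 0), (4, 0, 19)):
            assert 0 <= derive_seed(123, *key) < 2**31

    def test_filtering_beats_raw_calls_when_hidden_paralogs_abound(self):
        (row,) = run_benchmark(
            delta_t_grid=(0.05,), fold_grid=(100.0,), replicates=3,
            seed=3, n_genes=200,
        ).to_dict("records")
        assert row["median_precision"] >= row["median_raw_precision"]
        assert row["median_precision"] > 0.95


class TestDepthRecovery:
    @staticmethod
    def depth_pattern(scenario, seed):
        from soi.depth import compute_depth, depth_ratio

        cfg = SimulationConfig(n_genes=300, n_chromosomes=3, delta_t=0.2,
                               fold=1.0, scenario=scenario, seed=seed)
        truth = simulate_history(cfg)
        omap = emulate_orthology_calls(truth)
        genome_a = merged_genome(truth, ("A1", "A2"), "A")
        genome_b = merged_genome(truth, ("B1", "B2"), "B")
        genes = gene_index(genome_a + genome_b)
        pairs = family_homolog_pairs(genome_a, genome_b, truth.families,
                                     truth.ks)
        annotated = annotate_blocks(detect_blocks(pairs, genes), omap)
        retained = filter_blocks(annotated)
        before = depth_ratio(compute_depth(annotated, genome_a),
                             compute_depth(annotated, genome_b))
        after = depth_ratio(compute_depth(retained, genome_a),
                            compute_depth(retained, genome_b))
        return before, after

    def test_shared_wgd_collapses_to_one_one_after_filtering(self):
        before, after = self.depth_pattern("shared_wgd", seed=3)
        assert before == (2, 2)
        assert after == (1, 1)

    def test_specific_wgds_stay_two_two_after_filtering(self):
        before, after = self.depth_pattern("specific_wgd", seed=3)
        assert after == (2, 2)
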