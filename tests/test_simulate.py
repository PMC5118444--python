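"""Synthetic-data generators: ground-truth recovery, determinism, bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from cnvrkit.cnvr import filter_by_frequency, merge_cnvs, reciprocal_overlap
from cnvrkit.expression import call_expressed, combine_experiments
from cnvrkit.simulate import (
    SimulationConfig,
    default_expression_design,
    simulate_all,
    simulate_cnv_calls,
    simulate_expression,
    simulate_gene_models,
    simulate_ppi,
    write_scenario,
)


def small_config(**kwargs):
    defaults = dict(seed=11, n_samples=20, n_true_cnvrs=12, n_genes=80, n_codons=60)
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


class TestCnvCalls:
    def test_zero_jitter_calls_equal_planted_regions(self):
        cfg = small_config(boundary_jitter_sd=0.0)
        calls, truth = simulate_cnv_calls(cfg)
        planted = {(r.chrom, r.start, r.end) for r in truth.itertuples()}
        assert {(c.chrom, c.start, c.end) for c in calls} == planted
        merged = merge_cnvs(calls)
        assert {(r.chrom, r.start, r.end) for r in merged} == planted

    def test_jittered_calls_keep_half_reciprocal_overlap_with_truth(self):
        cfg = small_config(boundary_jitter_sd=500.0)
        calls, truth = simulate_cnv_calls(cfg)
        regions = {
            (r.chrom): [] for r in truth.itertuples()
        }
        truth_list = [(r.chrom, r.start, r.end) for r in truth.itertuples()]
        for c in calls:
            best = max(
                reciprocal_overlap((c.chrom, c.start, c.end), t) for t in truth_list
            )
            assert best >= 0.5

    def test_rare_planted_region_removed_by_frequency_filter(self):
        cfg = small_config(boundary_jitter_sd=0.0)
        calls, truth = simulate_cnv_calls(cfg)
        merged = merge_cnvs(calls)
        kept, removed = filter_by_frequency(merged, min_samples=3)
        rare = truth[truth.n_carriers < 3]
        kept_extents = {(r.chrom, r.start, r.end) for r in kept}
        for r in rare.itertuples():
            assert (r.chrom, r.start, r.end) not in kept_extents
        assert len(removed) == len(rare)

    def test_mixed_regions_have_both_directions(self):
        cfg = small_config(seed=5, state_probs=(0.0, 0.0, 1.0))
        calls, truth = simulate_cnv_calls(cfg)
        genome = cfg.genome
        for r in truth.itertuples():
            assert r.state == "mixed"
            members = [c for c in calls if c.chrom == r.chrom and r.start - 1e6 < c.start < r.end]
            baseline = genome[r.chrom].expected_copy_number
            assert any(c.copy_number < baseline for c in members)
            assert any(c.copy_number > baseline for c in members)

    def test_infeasible_spacing_raises(self):
        from cnvrkit.io_formats import make_genome

        cfg = SimulationConfig(
            seed=0,
            genome=make_genome({"1": 50_000}),
            n_true_cnvrs=50,
            min_region_size=5_000,
            max_region_size=10_000,
        )
        with pytest.raises(RuntimeError, match="place"):
            simulate_cnv_calls(cfg)


class TestGeneModels:
    def test_planted_gene_classes_follow_region_states(self):
        cfg = small_config(boundary_jitter_sd=0.0)
        calls, truth = simulate_cnv_calls(cfg)
        genes, gene_truth = simulate_gene_models(cfg, truth)
        state_to_class = {"gain": "duplication", "loss": "deletion", "mixed": "mixed"}
        by_id = {r.cnvr_id: r.state for r in truth.itertuples()}
        cnv_rows = gene_truth[gene_truth.gene_class != "neutral"]
        assert len(cnv_rows) == cfg.n_true_cnvrs * cfg.genes_per_cnvr
        for row in cnv_rows.itertuples():
            assert row.gene_class == state_to_class[by_id[row.cnvr_id]]

    def test_neutral_genes_clear_of_planted_regions(self):
        cfg = small_config()
        calls, truth = simulate_cnv_calls(cfg)
        genes, gene_truth = simulate_gene_models(cfg, truth)
        neutral_ids = set(gene_truth[gene_truth.gene_class == "neutral"].gene_id)
        regions = [(r.chrom, r.start, r.end) for r in truth.itertuples()]
        for g in genes:
            if g.gene_id in neutral_ids:
                assert all(
                    not (g.chrom == c and min(g.end, e) - max(g.start, s) > 0)
                    for c, s, e in regions
                )


class TestExpression:
    def test_design_covers_panel_with_shared_tissues(self):
        design = default_expression_design(SimulationConfig().tissues)
        covered = [t for spec in design.values() for t in spec["tissues"]]
        assert set(covered) == set(SimulationConfig().tissues)
        assert len(covered) > len(set(covered))  # some tissues assayed twice

    def test_planted_breadth_recovered_exactly(self):
        cfg = small_config()
        classes = {f"G{i:03d}": ("duplication" if i < 10 else "neutral") for i in range(40)}
        matrices, truth = simulate_expression(cfg, classes)
        callset = combine_experiments([call_expressed(m) for m in matrices])
        recovered = callset.breadths()
        for row in truth.itertuples():
            assert recovered[row.gene_id] == row.breadth
            assert callset.tissues_by_gene[row.gene_id] == frozenset(row.tissues.split(";"))


class TestPpi:
    def test_handshake_lemma_and_no_self_loops(self):
        cfg = small_config()
        classes = {f"G{i:03d}": ("mixed" if i < 5 else "neutral") for i in range(60)}
        edges, truth = simulate_ppi(cfg, classes)
        assert all(a != b for a, b in edges)
        assert len(set(edges)) == len(edges)
        degree: dict[str, int] = {}
        for a, b in edges:
            degree[a] = degree.get(a, 0) + 1
            degree[b] = degree.get(b, 0) + 1
        assert sum(degree.values()) == 2 * len(edges)


class TestDeterminism:
    def test_same_seed_same_scenario(self):
        cfg = small_config(seed=42)
        a = simulate_all(cfg)
        b = simulate_all(small_config(seed=42))
        assert a.calls == b.calls
        pd.testing.assert_frame_equal(a.cnvr_truth, b.cnvr_truth)
        assert [p.seq_query for p in a.pairs] == [p.seq_query for p in b.pairs]
        assert a.edges == b.edges

    def test_different_seed_different_scenario(self):
        a = simulate_all(small_config(seed=1))
        b = simulate_all(small_config(seed=2))
        assert a.calls != b.calls

    def test_written_scenario_is_byte_identical(self, tmp_path):
        cfg = small_config(seed=9, n_genes=30, n_true_cnvrs=5, n_codons=30)
        for d in ("one", "two"):
            write_scenario(simulate_all(cfg), tmp_path / d)
        for f in sorted((tmp_path / "one").rglob("*")):
            if f.is_file():
                twin = tmp_path / "two" / f.relative_to(tmp_path / "one")
                assert f.read_bytes() == twin.read_bytes(), f.name
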