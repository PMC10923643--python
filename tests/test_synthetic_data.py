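import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fruitmethyl.association import classify_degs, deg_dmg_enrichment
from fruitmethyl.mc_stats import estimate_conversion, weighted_level
from fruitmethyl.methylome_io import read_annotations
from fruitmethyl.synthetic_data import (
    GroundTruth,
    SimulationSpec,
    file_digest,
    generate_genome,
    run_simulation,
    simulate_expression,
    simulate_methylomes,
)


def small_spec(**kw):
    kw.setdefault("genome_length", 60_000)
    kw.setdefault("n_genes", 12)
    kw.setdefault("n_tes", 6)
    kw.setdefault("control_length", 8000)
    return SimulationSpec(**kw)


class TestGenerateGenome:
    def test_gc_content_matches_request(self):
        spec = SimulationSpec(genome_length=200_000, gc_fraction=0.5,
                              n_genes=40, seed=1)
        sequences, _, _ = generate_genome(spec)
        genome = "".join(
            s for name, s in sequences.items() if name != spec.control_name
        )
        gc = (genome.count("G") + genome.count("C")) / len(genome)
        assert abs(gc - 0.5) <= 0.02

    def test_zero_genes_empty_gff3(self, tmp_path):
        spec = small_spec(n_genes=0, seed=2)
        generate_genome(spec, outdir=tmp_path)
        text = (tmp_path / "genes.gff3").read_text()
        assert text == "##gff-version 3\n"
        assert read_annotations(tmp_path / "genes.gff3") == []

    def test_seed_determinism_contract(self):
        spec = small_spec(seed=1)
        s1, _, _ = generate_genome(spec)
        s2, _, _ = generate_genome(small_spec(seed=1))
        s3, _, _ = generate_genome(small_spec(seed=2))
        assert s1 == s2
        assert s1["chr1"] != s3["chr1"]

    def test_genes_do_not_overlap(self):
        spec = small_spec(seed=3)
        _, genes, _ = generate_genome(spec)
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        for ivals in by_chrom.values():
            ivals.sort()
            for (s1, e1), (s2, _) in zip(ivals, ivals[1:]):
                assert e1 <= s2

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError, match="genome_length"):
            SimulationSpec(genome_length=5000, n_genes=50)

    def test_control_sequence_present(self):
        spec = small_spec(seed=4)
        sequences, _, _ = generate_genome(spec)
        assert len(sequences[spec.control_name]) == spec.control_length


class TestSimulateMethylomes:
    def test_level_zero_no_conversion_error_all_zero(self):
        means = {s: {"CG": 0.0, "CHG": 0.0, "CHH": 0.0} for s in ("YF", "EF", "MF")}
        spec = small_spec(
            context_level_means=means, non_conversion_rate=0.0,
            diff_window_fraction=0.0, seed=5,
        )
        sequences, genes, _ = generate_genome(spec)
        tables, _ = simulate_methylomes(spec, sequences, genes=genes)
        for table in tables.values():
            assert (table["c_count"] == 0).all()

    def test_no_diff_fraction_empty_truth(self):
        spec = small_spec(diff_window_fraction=0.0, seed=6)
        sequences, genes, _ = generate_genome(spec)
        _, truth = simulate_methylomes(spec, sequences, genes=genes)
        assert len(truth.true_diff_windows) == 0
        assert truth.true_dmg_ids == []

    def test_count_soundness(self):
        spec = small_spec(seed=7)
        sequences, genes, _ = generate_genome(spec)
        tables, _ = simulate_methylomes(spec, sequences, genes=genes)
        for table in tables.values():
            assert (table["c_count"] >= 0).all()
            assert (table["c_count"] <= table["total_count"]).all()
            assert (table["total_count"] >= 1).all()

    def test_truth_windows_inside_genome(self):
        spec = small_spec(seed=8)
        sequences, genes, _ = generate_genome(spec)
        _, truth = simulate_methylomes(spec, sequences, genes=genes)
        sizes = {k: len(v) for k, v in sequences.items()}
        for _, w in truth.true_diff_windows.iterrows():
            assert w["chrom"] in sizes and w["chrom"] != spec.control_name
            assert 0 <= w["start"] < w["end"] <= sizes[w["chrom"]]

    def test_control_calibration_recovers_non_conversion(self):
        spec = small_spec(non_conversion_rate=0.012, control_length=20_000, seed=9)
        sequences, genes, _ = generate_genome(spec)
        tables, _ = simulate_methylomes(spec, sequences, genes=genes)
        ctrl = tables["YF"][tables["YF"]["chrom"] == spec.control_name]
        est = estimate_conversion(ctrl)
        r = spec.non_conversion_rate
        se = np.sqrt(r * (1 - r) / est.n_reads)
        assert abs(est.non_conversion_rate - r) <= 3 * se


class TestSimulateExpression:
    def test_full_coupling_makes_every_dmg_a_deg(self):
        spec = small_spec(expression_coupling=1.0, seed=10)
        sequences, genes, _ = generate_genome(spec)
        _, truth = simulate_methylomes(spec, sequences, genes=genes)
        assert truth.true_dmg_ids  # the default shift plan hits some genes
        expr = simulate_expression(spec, genes, truth)
        degs = classify_degs(expr)
        deg_ids = set(degs.loc[degs["direction"] != "ns", "gene_id"])
        assert set(truth.true_dmg_ids) <= deg_ids

    def test_sparse_coupled_study_shows_enrichment(self):
        # with a sparse shift plan DMGs are a strict subset of genes, so
        # full DMG->DEG coupling must surface as hypergeometric enrichment
        spec = SimulationSpec.flat(
            diff_effect={"CG": 0.0, "CHG": 0.0, "CHH": 0.15},
            diff_window_fraction=0.01,
            genome_length=400_000, n_genes=60,
            expression_coupling=1.0, seed=15,
        )
        sequences, genes, _ = generate_genome(spec)
        _, truth = simulate_methylomes(spec, sequences, genes=genes)
        assert 0 < len(truth.true_dmg_ids) < len(genes)
        expr = simulate_expression(spec, genes, truth)
        degs = classify_degs(expr)
        sub = degs[degs["comparison"] == "EF_vs_YF"]
        deg_ids = set(sub.loc[sub["direction"] != "ns", "gene_id"])
        dmg_ids = set(truth.true_dmg_ids)
        res = deg_dmg_enrichment(
            len(genes), len(dmg_ids), len(deg_ids), len(deg_ids & dmg_ids)
        )
        assert dmg_ids <= deg_ids
        assert res.p_value < 0.05

    def test_empty_truth_null_statistics_only(self):
        spec = small_spec(background_deg_rate=0.0, seed=11)
        _, genes, _ = generate_genome(spec)
        truth = GroundTruth(
            true_diff_windows=pd.DataFrame(
                columns=["chrom", "start", "end", "context", "direction"]
            ),
            true_dmg_ids=[], true_deg_ids=[],
        )
        expr = simulate_expression(spec, genes, truth)
        degs = classify_degs(expr)
        assert (degs["direction"] == "ns").all()
        assert truth.true_deg_ids == []

    def test_uncoupled_enrichment_p_is_uniform(self):
        # coupling 0: DEG status is independent of DMG status, so the
        # hypergeometric enrichment p over many seeds is ~Uniform(0,1)
        n_genes = 500
        p_values = []
        for seed in range(200):
            spec = SimulationSpec(
                genome_length=500_000, n_genes=n_genes,
                expression_coupling=0.0, seed=seed,
            )
            gene_ids = [f"gene{i:04d}" for i in range(1, n_genes + 1)]
            from fruitmethyl.methylome_io import GeneModel

            genes = [
                GeneModel(g, "chr1", 1000 * i, 1000 * i + 500, "+")
                for i, g in enumerate(gene_ids)
            ]
            dmg_ids = gene_ids[: n_genes // 3]
            truth = GroundTruth(
                true_diff_windows=pd.DataFrame(
                    columns=["chrom", "start", "end", "context", "direction"]
                ),
                true_dmg_ids=dmg_ids, true_deg_ids=[],
            )
            expr = simulate_expression(spec, genes, truth)
            degs = classify_degs(expr)
            sub = degs[degs["comparison"] == "EF_vs_YF"]
            deg_ids = set(sub.loc[sub["direction"] != "ns", "gene_id"])
            res = deg_dmg_enrichment(
                n_genes, len(dmg_ids), len(deg_ids), len(deg_ids & set(dmg_ids))
            )
            p_values.append(res.p_value)
        ks = stats.kstest(p_values, "uniform")
        assert ks.pvalue > 1e-3

    def test_coupled_genes_shared_across_comparisons(self):
        spec = small_spec(expression_coupling=1.0, background_deg_rate=0.0, seed=12)
        sequences, genes, _ = generate_genome(spec)
        _, truth = simulate_methylomes(spec, sequences, genes=genes)
        expr = simulate_expression(spec, genes, truth)
        degs = classify_degs(expr)
        by_comp = {
            comp: set(sub.loc[sub["direction"] != "ns", "gene_id"])
            for comp, sub in degs.groupby("comparison")
        }
        sets = list(by_comp.values())
        assert sets[0] == sets[1]


class TestFileOutputs:
    def test_run_simulation_deterministic_files(self, tmp_path):
        spec = small_spec(seed=13)
        p1 = run_simulation(spec, tmp_path / "a")
        p2 = run_simulation(small_spec(seed=13), tmp_path / "b")
        for key in p1:
            assert file_digest(p1[key]) == file_digest(p2[key]), key

    def test_different_seed_changes_outputs(self, tmp_path):
        p1 = run_simulation(small_spec(seed=13), tmp_path / "a")
        p3 = run_simulation(small_spec(seed=14), tmp_path / "c")
        assert file_digest(p1["genome"]) != file_digest(p3["genome"])
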