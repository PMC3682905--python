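import numpy as np
import pandas as pd
import pytest

from ervkit.alignments import build_mate_pairs, read_sam
from ervkit.chimeric_transcripts import detect_chimeric_candidates, FragmentStats
from ervkit.genome_model import (
    assemble_full_length_elements,
    read_gene_models,
    read_repeat_annotation,
)
from ervkit.stage_specificity import classify_2c_specific
from ervkit.synthetic_data import (
    FamilySim,
    GeneSim,
    PlacementError,
    SimConfig,
    StageSim,
    default_config,
    generate_toy_genome,
    run_simulation,
    simulate_chip_reads,
    simulate_rnaseq_pairs,
    simulate_stage_table,
)

from conftest import rnaseq_test_config


def one_element_config(seed, expected_pairs=30.0):
    return SimConfig(
        seed=seed,
        genome={"chr1": 40_000},
        families=[FamilySim("MERVL", "MT2_Mm", "MERVL-int",
                            n_full_length=1, n_solo_ltr=0,
                            expected_pairs=expected_pairs)],
        genes=GeneSim(n_genes=0, fraction_near_mt2=0.0),
        stage=StageSim(n_2c_specific=0),
        samples={"wt": {"MERVL": 1.0}},
    )


class TestGenerateToyGenome:
    def test_zero_elements_genes_only(self, tmp_path):
        cfg = SimConfig(seed=0, genome={"chr1": 200_000}, families=[],
                        genes=GeneSim(n_genes=3, fraction_near_mt2=0.0),
                        stage=StageSim(n_2c_specific=0), samples={})
        repeats, genes, truth = generate_toy_genome(cfg)
        assert repeats == [] and len(genes) == 3

    def test_full_length_truth_round_trip(self):
        cfg = SimConfig(
            seed=1,
            genome={"chr1": 500_000},
            families=[FamilySim("MERVL", "MT2_Mm", "MERVL-int",
                                n_full_length=20, n_solo_ltr=0)],
            genes=GeneSim(n_genes=0, fraction_near_mt2=0.0),
            stage=StageSim(n_2c_specific=0), samples={},
        )
        repeats, _, truth = generate_toy_genome(cfg)
        recovered = assemble_full_length_elements(repeats, cfg.family_specs())
        assert len(recovered) == 20
        assert [e.element_id for e in recovered] == [
            e.element_id for e in truth.full_length["MERVL"]
        ]

    def test_infeasible_placement_raises(self):
        cfg = SimConfig(
            seed=0, genome={"chr1": 30_000},
            families=[FamilySim("MERVL", "MT2_Mm", "MERVL-int",
                                n_full_length=10)],
            genes=GeneSim(n_genes=0), stage=StageSim(n_2c_specific=0),
            samples={},
        )
        with pytest.raises(PlacementError, match="genome too small"):
            generate_toy_genome(cfg)

    def test_proximal_fraction_planted(self, toy_genome, sim_config):
        repeats, genes, truth = toy_genome
        expected = round(sim_config.genes.fraction_near_mt2
                         * sim_config.genes.n_genes)
        assert len(truth.proximal_gene_ids) == expected

    def test_outputs_parse_through_readers(self, tmp_path):
        cfg = default_config(seed=5)
        run_simulation(cfg, tmp_path)
        repeats = read_repeat_annotation(tmp_path / "repeats.bed", "bed6")
        genes = read_gene_models(tmp_path / "genes.gtf", "gtf")
        assert len(repeats) > 0 and len(genes) == cfg.genes.n_genes
        reads = read_sam(tmp_path / "rnaseq_wt.sam")
        assert len(reads) > 0

    def test_yaml_config_round_trip(self, tmp_path):
        cfg = default_config(seed=9)
        cfg.to_yaml(tmp_path / "c.yaml")
        back = SimConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg


class TestDeterminism:
    def test_byte_identical_runs(self, tmp_path):
        cfg = rnaseq_test_config(seed=13)
        a, b = tmp_path / "a", tmp_path / "b"
        run_simulation(cfg, a)
        run_simulation(rnaseq_test_config(seed=13), b)
        names = sorted(p.name for p in a.iterdir())
        assert names == sorted(p.name for p in b.iterdir())
        for name in names:
            assert (a / name).read_bytes() == (b / name).read_bytes(), name

    def test_seed_changes_output(self, tmp_path):
        truth_a = generate_toy_genome(rnaseq_test_config(seed=1))[2]
        truth_b = generate_toy_genome(rnaseq_test_config(seed=1))[2]
        reads_a = simulate_rnaseq_pairs(truth_a, truth_a.config, "wt")
        reads_b = simulate_rnaseq_pairs(truth_b, truth_b.config, "wt")
        assert reads_a == reads_b
        truth_c = generate_toy_genome(rnaseq_test_config(seed=2))[2]
        reads_c = simulate_rnaseq_pairs(truth_c, truth_c.config, "wt")
        assert reads_a != reads_c


class TestSimulateRnaseq:
    def test_zero_expected_no_records(self):
        cfg = one_element_config(0, expected_pairs=0.0)
        _, _, truth = generate_toy_genome(cfg)
        assert simulate_rnaseq_pairs(truth, cfg, "wt") == []

    def test_unknown_sample(self):
        cfg = one_element_config(0)
        _, _, truth = generate_toy_genome(cfg)
        with pytest.raises(KeyError):
            simulate_rnaseq_pairs(truth, cfg, "nope")

    def test_conservation(self):
        cfg = rnaseq_test_config(seed=3, chimera_supports=(7, 4))
        _, _, truth = generate_toy_genome(cfg)
        reads = simulate_rnaseq_pairs(truth, cfg, "wt")
        planted = sum(truth.rnaseq_counts["wt"].values())
        chimeric = sum(truth.chimera_support.values())
        assert len(reads) == 2 * (planted + chimeric)

    def test_planted_chimera_support_round_trip(self):
        cfg = rnaseq_test_config(seed=21, chimera_supports=(7,))
        repeats, genes, truth = generate_toy_genome(cfg)
        reads = simulate_rnaseq_pairs(truth, cfg, "wt")
        pairs = build_mate_pairs(reads)
        stats = FragmentStats(cfg.fragments.mean, cfg.fragments.sd, len(pairs))
        cands = detect_chimeric_candidates(pairs, stats, repeats, genes)
        ((gid, eid), support) = next(iter(truth.chimera_support.items()))
        match = [c for c in cands if c.gene_id == gid]
        assert len(match) == 1
        assert match[0].erv_element_id == eid
        assert match[0].support == 7

    def test_poisson_mean_recovery(self):
        # replicate-seed oracle: mean planted count ~ expected within 3 SE
        expected, n_seeds = 30.0, 200
        counts = []
        for seed in range(n_seeds):
            cfg = one_element_config(seed, expected_pairs=expected)
            _, _, truth = generate_toy_genome(cfg)
            simulate_rnaseq_pairs(truth, cfg, "wt")
            counts.append(sum(truth.rnaseq_counts["wt"].values()))
        se = np.sqrt(expected / n_seeds)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_mapq_unique_fraction(self):
        cfg = one_element_config(8, expected_pairs=500.0)
        cfg.unique_fraction = 0.5
        _, _, truth = generate_toy_genome(cfg)
        reads = simulate_rnaseq_pairs(truth, cfg, "wt")
        frac = np.mean([r.mapq >= 10 for r in reads])
        assert 0.4 < frac < 0.6


class TestSimulateChip:
    def test_flank_decay_half_length_recovery(self, pooled_chip_profiles):
        # fit log2(density - background) ~ distance over the seed-averaged
        # profile; planted half-length 500 bp, tolerance 20%
        pooled, _ = pooled_chip_profiles
        background = np.concatenate([pooled[:30], pooled[-30:]]).mean()
        dist = np.arange(120) * 50 + 25
        for side in (pooled[120:], pooled[:120][::-1]):
            mask = (dist >= 350) & (dist <= 1_600)  # beyond extension spill
            y = side[mask] - background
            keep = y > 0
            slope, _ = np.polyfit(dist[mask][keep], np.log2(y[keep]), 1)
            assert -1.0 / slope == pytest.approx(500.0, rel=0.20)

    def test_zero_reads(self):
        cfg = one_element_config(0)
        cfg.chip.background_per_kb = 0.0
        _, _, truth = generate_toy_genome(cfg)
        assert simulate_chip_reads(truth, cfg, "ab") == []

    def test_read_count_recorded(self):
        cfg = one_element_config(0)
        _, _, truth = generate_toy_genome(cfg)
        reads = simulate_chip_reads(truth, cfg, "ab")
        assert truth.chip_read_counts["ab"] == len(reads)


class TestStageTable:
    def test_exact_recovery_no_noise(self):
        cfg = rnaseq_test_config(seed=17)
        _, _, truth = generate_toy_genome(cfg)
        table = simulate_stage_table(truth, cfg)
        assert classify_2c_specific(table) == truth.two_c_gene_ids
        assert len(truth.two_c_gene_ids) == cfg.stage.n_2c_specific

    def test_empty_planted_set(self):
        cfg = one_element_config(0)
        _, _, truth = generate_toy_genome(cfg)
        table = simulate_stage_table(truth, cfg)
        assert classify_2c_specific(table) == set()

    def test_fixed_seed_identical_bytes(self, tmp_path):
        for sub in ("x", "y"):
            cfg = rnaseq_test_config(seed=5)
            cfg.stage.noise_sigma = 0.1
            _, _, truth = generate_toy_genome(cfg)
            table = simulate_stage_table(truth, cfg)
            table.to_csv(tmp_path / f"{sub}.tsv", sep="\t", index=False)
        assert (tmp_path / "x.tsv").read_bytes() == (tmp_path / "y.tsv").read_bytes()

    def test_noisy_recovery(self):
        hits = 0
        trials = 25
        for seed in range(trials):
            cfg = rnaseq_test_config(seed=seed)
            cfg.stage.noise_sigma = 0.2
            _, _, truth = generate_toy_genome(cfg)
            table = simulate_stage_table(truth, cfg)
            got = classify_2c_specific(table)
            hits += len(got & truth.two_c_gene_ids)
        total = trials * len(truth.two_c_gene_ids)
        assert hits / total >= 0.95  # sensitivity under moderate noise
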