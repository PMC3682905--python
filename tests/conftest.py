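import pytest

from ervkit.genome_model import (
    FamilySpec,
    FullLengthElement,
    GeneModel,
    GenomicInterval,
    RepeatElement,
)
from ervkit.synthetic_data import (
    ChimeraPlan,
    FamilySim,
    GeneSim,
    SimConfig,
    StageSim,
    default_config,
    generate_toy_genome,
)


def make_repeat(chrom, start, end, family, strand="+", part="LTR"):
    return RepeatElement(
        element_id=f"{family}|{chrom}:{start}-{end}",
        family=family,
        part=part,
        interval=GenomicInterval(chrom, start, end, strand),
    )


def make_full_length(chrom, start, end, strand="+", family="MERVL",
                     ltr_family="MT2_Mm", ltr_len=500):
    ltr_a = make_repeat(chrom, start, start + ltr_len, ltr_family, strand)
    internal = make_repeat(chrom, start + ltr_len, end - ltr_len,
                           "MERVL-int", strand, part="internal")
    ltr_b = make_repeat(chrom, end - ltr_len, end, ltr_family, strand)
    five, three = (ltr_a, ltr_b) if strand == "+" else (ltr_b, ltr_a)
    return FullLengthElement(
        element_id=f"{family}|{chrom}:{start}-{end}",
        family=family,
        ltr5=five,
        internal=[internal],
        ltr3=three,
        interval=GenomicInterval(chrom, start, end, strand),
        strand=strand,
    )


def make_gene(gene_id, chrom, exon_coords, strand="+", **flags):
    exons = [GenomicInterval(chrom, s, e, strand) for s, e in exon_coords]
    if strand == "-":
        exons = sorted(exons, key=lambda e: e.start, reverse=True)
    return GeneModel(gene_id, gene_id, chrom, strand, exons, **flags)


@pytest.fixture
def mervl_spec():
    return FamilySpec("MERVL", "MT2_Mm", "MERVL-int", 5_000, 8_000)


@pytest.fixture(scope="session")
def sim_config():
    return default_config(seed=11)


@pytest.fixture(scope="session")
def toy_genome(sim_config):
    return generate_toy_genome(sim_config)


def chip_test_config(seed: int, spreading_enrichment: float = 50.0,
                     half_length: float = 500.0) -> SimConfig:
    """Small two-family config for flank-profile recovery loops."""
    return SimConfig(
        seed=seed,
        genome={"chr1": 160_000},
        families=[
            FamilySim("IAPEz", "IAPLTR1_Mm", "IAPEz-int", erv_class="II",
                      n_full_length=3, n_solo_ltr=0,
                      chip_enrichment=spreading_enrichment,
                      chip_mode="spreading", chip_half_length=half_length),
            FamilySim("MERVL", "MT2_Mm", "MERVL-int", erv_class="III",
                      n_full_length=3, n_solo_ltr=0,
                      chip_enrichment=1.0, chip_mode="absent"),
        ],
        genes=GeneSim(n_genes=0, fraction_near_mt2=0.0),
        stage=StageSim(n_2c_specific=0),
        samples={},
    )


@pytest.fixture(scope="session")
def pooled_chip_profiles():
    """Seed-averaged spreading-family profile and heatmap row means.

    100 replicate simulations at 50x enrichment, 500 bp half-length,
    10 reads/kb background.
    """
    import numpy as np

    from ervkit.chip_flank_profiler import (
        aggregate_flank_profile,
        build_coverage,
        flank_heatmap,
    )
    from ervkit.synthetic_data import generate_toy_genome, simulate_chip_reads

    n_seeds = 100
    pooled = np.zeros(240)
    row_means = np.zeros(240)
    for seed in range(n_seeds):
        cfg = chip_test_config(seed, spreading_enrichment=50.0, half_length=500.0)
        cfg.chip.background_per_kb = 10.0
        _, _, truth = generate_toy_genome(cfg)
        reads = simulate_chip_reads(truth, cfg, "chip")
        track = build_coverage(reads, cfg.genome)
        els = truth.full_length["IAPEz"]
        pooled += aggregate_flank_profile(track, els).densities
        row_means += flank_heatmap(track, els).matrix.mean(axis=0)
    return pooled / n_seeds, row_means / n_seeds


def rnaseq_test_config(seed: int, chimera_supports=(7,)) -> SimConfig:
    """Small one-family + genes config for RNA-seq and chimera loops."""
    return SimConfig(
        seed=seed,
        genome={"chr1": 300_000},
        families=[
            FamilySim("MERVL", "MT2_Mm", "MERVL-int", erv_class="III",
                      n_full_length=2, n_solo_ltr=1, expected_pairs=60.0),
        ],
        genes=GeneSim(n_genes=6, fraction_near_mt2=0.5),
        stage=StageSim(n_2c_specific=2),
        chimeras=[ChimeraPlan(i, s) for i, s in enumerate(chimera_supports)],
        samples={"wt": {"MERVL": 1.0, "genes": 1.0}},
    )
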