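"""Deterministic simulators for toy genomes, alignments and stage tables.

Every generator takes an explicit config and derives an independent
random substream from the single global seed, so a fixed seed makes all
outputs byte-reproducible. Ground truth (planted counts, planted
chimeras, planted 2C-specific genes) is recorded alongside the emitted
files for parameter-recovery tests.

Noise models: read/pair counts are Poisson, fragment sizes Normal.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .alignments import AlignedRead, write_alignments_tsv, write_sam
from .genome_model import (
    FamilySpec,
    FullLengthElement,
    GeneModel,
    GenomicInterval,
    RepeatElement,
    assemble_full_length_elements,
    write_gene_models_gtf,
    write_repeat_bed6,
)

# fixed substream tags so generators are independent of call order
_STREAM_GENOME = 1
_STREAM_RNA = 2
_STREAM_CHIP = 3
_STREAM_STAGE = 4


class PlacementError(RuntimeError):
    """Raised when the configured features cannot fit in the genome."""


@dataclass
class FamilySim:
    """Simulation parameters for one ERV family."""

    name: str
    ltr_family: str
    internal_family: str
    ltr_length: int = 500
    internal_length: int = 5_000
    n_full_length: int = 4
    n_solo_ltr: int = 2
    erv_class: str = "other"
    expected_pairs: float = 50.0        # RNA-seq pairs per full-length element
    chip_enrichment: float = 1.0        # body density as multiple of background
    chip_mode: str = "absent"           # "spreading" | "focal" | "absent"
    chip_half_length: float = 500.0     # bp decay half-length for spreading

    @property
    def full_span(self) -> int:
        return 2 * self.ltr_length + self.internal_length


@dataclass
class GeneSim:
    n_genes: int = 20
    n_exons: int = 3
    exon_length: int = 600
    intron_length: int = 800
    fraction_near_mt2: float = 0.25     # genes with TSS within 5 kb of an MT2 LTR
    near_distance: int = 2_000          # planted TSS-to-LTR gap
    expected_pairs: float = 20.0

    @property
    def span(self) -> int:
        return self.n_exons * self.exon_length + (self.n_exons - 1) * self.intron_length


@dataclass
class FragmentSim:
    mean: float = 200.0
    sd: float = 30.0
    read_length: int = 75

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("fragment SD must be positive")


@dataclass
class ChipSim:
    background_per_kb: float = 5.0      # expected reads per kb outside elements


@dataclass
class StageSim:
    n_2c_specific: int = 5
    baseline_rpm: float = 5.0
    fold_2c: float = 10.0
    noise_sigma: float = 0.0            # lognormal sigma on every RPM


@dataclass
class ChimeraPlan:
    """Planted LTR-gene chimera: attaches to the i-th MT2-proximal gene."""

    proximal_gene_index: int
    support: int


@dataclass
class SimConfig:
    seed: int = 0
    genome: dict[str, int] = field(default_factory=lambda: {"chr1": 700_000,
                                                            "chr2": 600_000})
    families: list[FamilySim] = field(default_factory=list)
    genes: GeneSim = field(default_factory=GeneSim)
    fragments: FragmentSim = field(default_factory=FragmentSim)
    chip: ChipSim = field(default_factory=ChipSim)
    stage: StageSim = field(default_factory=StageSim)
    chimeras: list[ChimeraPlan] = field(default_factory=list)
    #: per-sample expression fold factors, keyed by family name or "genes"
    samples: dict[str, dict[str, float]] = field(default_factory=dict)
    unique_fraction: float = 1.0        # fraction of reads with mapq >= 10
    spacing: int = 15_000               # clearance between planted features

    def family_specs(self) -> list[FamilySpec]:
        """Assembly specs consistent with the simulated element geometry."""
        return [
            FamilySpec(f.name, f.ltr_family, f.internal_family,
                       min_span=f.full_span - 200, max_span=f.full_span + 200)
            for f in self.families
        ]

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        data = dict(data)
        data["families"] = [FamilySim(**f) for f in data.get("families", [])]
        data["chimeras"] = [ChimeraPlan(**c) for c in data.get("chimeras", [])]
        for key, typ in (("genes", GeneSim), ("fragments", FragmentSim),
                         ("chip", ChipSim), ("stage", StageSim)):
            if key in data and isinstance(data[key], dict):
                data[key] = typ(**data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def default_config(seed: int = 0) -> SimConfig:
    """A three-family config exercising every analysis stage."""
    families = [
        FamilySim("MERVL", "MT2_Mm", "MERVL-int", erv_class="III",
                  n_full_length=4, n_solo_ltr=2, expected_pairs=40.0,
                  chip_enrichment=1.0, chip_mode="absent"),
        FamilySim("IAPEz", "IAPLTR1_Mm", "IAPEz-int", erv_class="II",
                  n_full_length=4, n_solo_ltr=2, expected_pairs=40.0,
                  chip_enrichment=50.0, chip_mode="spreading",
                  chip_half_length=500.0),
        FamilySim("MMERVK10C", "RLTR10C", "MMERVK10C-int", erv_class="II",
                  n_full_length=3, n_solo_ltr=1, expected_pairs=40.0,
                  chip_enrichment=10.0, chip_mode="focal"),
    ]
    samples = {
        "wt": {"MERVL": 1.0, "IAPEz": 1.0, "MMERVK10C": 1.0, "genes": 1.0},
        "ko": {"MERVL": 27.0, "IAPEz": 4.0, "MMERVK10C": 1.0, "genes": 1.0},
    }
    return SimConfig(
        seed=seed,
        families=families,
        chimeras=[ChimeraPlan(0, 7), ChimeraPlan(1, 9), ChimeraPlan(2, 3)],
        samples=samples,
    )


@dataclass
class SimTruth:
    """Ground truth for one simulated genome."""

    config: SimConfig
    repeats: list[RepeatElement] = field(default_factory=list)
    genes: list[GeneModel] = field(default_factory=list)
    full_length: dict[str, list[FullLengthElement]] = field(default_factory=dict)
    solo_ltrs: dict[str, list[RepeatElement]] = field(default_factory=dict)
    proximal_gene_ids: list[str] = field(default_factory=list)
    chimera_elements: dict[str, str] = field(default_factory=dict)   # gene -> element
    chimera_support: dict[tuple[str, str], int] = field(default_factory=dict)
    two_c_gene_ids: set[str] = field(default_factory=set)
    #: filled by simulate_rnaseq_pairs: sample -> region_id -> emitted pairs
    rnaseq_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    #: filled by simulate_chip_reads: antibody -> emitted read count
    chip_read_counts: dict[str, int] = field(default_factory=dict)


def _rng(config: SimConfig, stream: int, tag: str = "") -> np.random.Generator:
    return np.random.default_rng(
        [config.seed, stream, zlib.crc32(tag.encode()) & 0xFFFFFFFF]
    )


class _Placer:
    """First-fit sequential feature placement with fixed clearance."""

    def __init__(self, genome: dict[str, int], spacing: int):
        self.genome = genome
        self.spacing = spacing
        self.cursor = {c: spacing for c in genome}

    def place(self, length: int, what: str) -> tuple[str, int]:
        for chrom, clen in self.genome.items():
            start = self.cursor[chrom]
            if start + length + self.spacing <= clen:
                self.cursor[chrom] = start + length + self.spacing
                return chrom, start
        raise PlacementError(
            f"cannot place {what} (length {length}): genome too small for the "
            f"configured feature set"
        )


def generate_toy_genome(config: SimConfig) -> tuple[list[RepeatElement],
                                                    list[GeneModel], SimTruth]:
    """Place full-length elements, solo LTRs and genes on the toy genome.

    Full-length elements are LTR-internal-LTR with identical LTR family
    annotations and zero inter-component gaps; the configured fraction of
    genes receives a solo MT2-family LTR ``near_distance`` bp upstream of
    its TSS. Features never overlap (clearance ``spacing``).
    """
    rng = _rng(config, _STREAM_GENOME)
    placer = _Placer(config.genome, config.spacing)
    truth = SimTruth(config=config)
    repeats: list[RepeatElement] = []

    def add_repeat(chrom: str, start: int, end: int, strand: str,
                   family: str, part: str, erv_class: str) -> RepeatElement:
        el = RepeatElement(
            element_id=f"{family}|{chrom}:{start}-{end}",
            family=family, part=part,
            interval=GenomicInterval(chrom, start, end, strand),
            erv_class=erv_class,
        )
        repeats.append(el)
        return el

    mt2_family: Optional[str] = None
    for fam in config.families:
        if fam.ltr_family.startswith("MT2"):
            mt2_family = fam.ltr_family
        components: list[RepeatElement] = []
        for i in range(fam.n_full_length):
            strand = "+" if i % 2 == 0 else "-"
            chrom, start = placer.place(fam.full_span, f"{fam.name} element")
            p = start
            components.append(add_repeat(chrom, p, p + fam.ltr_length, strand,
                                         fam.ltr_family, "LTR", fam.erv_class))
            p += fam.ltr_length
            components.append(add_repeat(chrom, p, p + fam.internal_length, strand,
                                         fam.internal_family, "internal",
                                         fam.erv_class))
            p += fam.internal_length
            components.append(add_repeat(chrom, p, p + fam.ltr_length, strand,
                                         fam.ltr_family, "LTR", fam.erv_class))
        solos = []
        for _ in range(fam.n_solo_ltr):
            chrom, start = placer.place(fam.ltr_length, f"{fam.name} solo LTR")
            solos.append(add_repeat(chrom, start, start + fam.ltr_length, "+",
                                    fam.ltr_family, "LTR", fam.erv_class))
        truth.solo_ltrs[fam.name] = solos
        truth.full_length[fam.name] = assemble_full_length_elements(
            sorted(components, key=lambda e: (e.interval.chrom, e.interval.start)),
            config.family_specs(),
        )
        if len(truth.full_length[fam.name]) != fam.n_full_length:
            raise PlacementError(
                f"planted {fam.n_full_length} {fam.name} elements but assembled "
                f"{len(truth.full_length[fam.name])}"
            )

    gs = config.genes
    n_proximal = round(gs.fraction_near_mt2 * gs.n_genes)
    if n_proximal > 0 and mt2_family is None:
        raise PlacementError("proximal genes requested but no MT2-family LTR "
                             "configured")
    if config.chimeras and max(c.proximal_gene_index for c in config.chimeras) \
            >= max(n_proximal, 0):
        raise PlacementError("chimera plan refers to a proximal gene index "
                             "beyond the planted proximal gene count")
    genes: list[GeneModel] = []
    for gi in range(gs.n_genes):
        proximal = gi < n_proximal
        extra = (gs.near_distance + 600) if proximal else 0
        chrom, start = placer.place(gs.span + extra, f"gene g{gi:04d}")
        gene_start = start + extra
        exons = []
        p = gene_start
        for _ in range(gs.n_exons):
            exons.append(GenomicInterval(chrom, p, p + gs.exon_length, "+"))
            p += gs.exon_length + gs.intron_length
        gene = GeneModel(f"g{gi:04d}", f"g{gi:04d}", chrom, "+", exons)
        genes.append(gene)
        if proximal:
            # solo MT2 LTR ending near_distance bp upstream of the TSS
            fam = next(f for f in config.families if f.ltr_family == mt2_family)
            ltr_end = gene_start - gs.near_distance
            ltr = add_repeat(chrom, ltr_end - fam.ltr_length, ltr_end, "+",
                             mt2_family, "LTR", fam.erv_class)
            truth.proximal_gene_ids.append(gene.gene_id)
            truth.solo_ltrs.setdefault(fam.name, []).append(ltr)

    for plan in config.chimeras:
        gid = truth.proximal_gene_ids[plan.proximal_gene_index]
        gene = next(g for g in genes if g.gene_id == gid)
        ltr = next(
            el for el in repeats
            if el.family == mt2_family and el.part == "LTR"
            and el.interval.chrom == gene.chrom
            and el.interval.end == gene.first_exon.start - gs.near_distance
        )
        truth.chimera_elements[gid] = ltr.element_id
        truth.chimera_support[(gid, ltr.element_id)] = plan.support

    # planted 2C-specific genes: drawn from the non-proximal tail plus any
    # proximal genes, biased toward proximal ones (as in the biology)
    n2c = min(config.stage.n_2c_specific, gs.n_genes)
    ranked = truth.proximal_gene_ids + [g.gene_id for g in genes
                                        if g.gene_id not in truth.proximal_gene_ids]
    truth.two_c_gene_ids = set(ranked[:n2c])

    repeats.sort(key=lambda e: (e.interval.chrom, e.interval.start))
    truth.repeats = repeats
    truth.genes = genes
    return repeats, genes, truth


# ---------------------------------------------------------------------------
# RNA-seq


def _mapq(rng: np.random.Generator, unique_fraction: float) -> int:
    return 60 if rng.random() < unique_fraction else 0


def _pair_in_interval(
    rng: np.random.Generator,
    name: str,
    iv: GenomicInterval,
    frag_cfg: FragmentSim,
    mapq: int,
) -> tuple[AlignedRead, AlignedRead]:
    """A concordant mate pair fully inside ``iv`` with ~Normal fragment size."""
    rl = frag_cfg.read_length
    min_frag, max_frag = 2 * rl, iv.length
    frag = int(round(rng.normal(frag_cfg.mean, frag_cfg.sd)))
    frag = max(min_frag, min(frag, max_frag))
    start = int(rng.integers(iv.start, iv.end - frag + 1))
    r1 = AlignedRead(name, iv.chrom, start, start + rl, "+", mapq, mate=1,
                     fragment_size=frag)
    r2 = AlignedRead(name, iv.chrom, start + frag - rl, start + frag, "-", mapq,
                     mate=2, fragment_size=frag)
    return r1, r2


def simulate_rnaseq_pairs(
    truth: SimTruth,
    config: SimConfig,
    sample: str,
) -> list[AlignedRead]:
    """Paired-end reads for one sample; counts Poisson, fragments Normal.

    Expression regions are full-length element bodies (per family) and
    gene exons; expected pair counts are baseline x per-sample fold.
    Planted chimeras are emitted exactly at their planted support with one
    mate in the LTR and one in a genic exon, which makes their outer
    distance far exceed mean + SD. Records the emitted pair count per
    region in ``truth.rnaseq_counts[sample]``.
    """
    if sample not in config.samples:
        raise KeyError(f"no expression fold factors for sample {sample!r}")
    folds = config.samples[sample]
    rng = _rng(config, _STREAM_RNA, sample)
    reads: list[AlignedRead] = []
    counts: dict[str, int] = {}
    serial = 0

    def emit_pairs(region_id: str, iv: GenomicInterval, expected: float) -> None:
        nonlocal serial
        n = int(rng.poisson(expected)) if expected > 0 else 0
        counts[region_id] = n
        for _ in range(n):
            name = f"{sample}:r{serial:07d}"
            serial += 1
            mapq = _mapq(rng, config.unique_fraction)
            reads.extend(_pair_in_interval(rng, name, iv, config.fragments, mapq))

    for fam in config.families:
        fold = folds.get(fam.name, 1.0)
        for el in truth.full_length[fam.name]:
            emit_pairs(el.element_id, el.interval, fam.expected_pairs * fold)
    gene_fold = folds.get("genes", 1.0)
    for gene in truth.genes:
        # pairs confined to the first exon so exon-overlap counting is exact
        emit_pairs(gene.gene_id, gene.first_exon,
                   config.genes.expected_pairs * gene_fold)

    rl = config.fragments.read_length
    for (gid, eid), support in sorted(truth.chimera_support.items()):
        gene = next(g for g in truth.genes if g.gene_id == gid)
        ltr = next(e for e in truth.repeats if e.element_id == eid)
        exon = gene.exons[1] if len(gene.exons) > 1 else gene.exons[0]
        for j in range(support):
            name = f"{sample}:chim:{gid}:{j}"
            # jitter keeps pair start coordinates distinct (unique support)
            off1 = j % max(ltr.interval.length - rl, 1)
            s1 = ltr.interval.start + off1
            s2 = exon.start + (j % max(exon.length - rl, 1))
            frag = (s2 + rl) - s1
            reads.append(AlignedRead(name, ltr.interval.chrom, s1, s1 + rl, "+",
                                     60, mate=1, fragment_size=frag))
            reads.append(AlignedRead(name, gene.chrom, s2, s2 + rl, "-",
                                     60, mate=2, fragment_size=frag))
    truth.rnaseq_counts[sample] = counts
    return reads


# ---------------------------------------------------------------------------
# ChIP


def _sample_flank_reads(
    rng: np.random.Generator,
    boundary: int,
    direction: int,  # +1: flank extends to higher coordinates
    rate_per_bp: float,
    half_length: float,
    span: int,
    chrom: str,
    chrom_len: int,
    read_length: int,
    name_prefix: str,
    unique_fraction: float,
) -> list[AlignedRead]:
    """Reads with intensity rate * 2^(-d/h) over one flank of width span."""
    h = half_length
    mass = rate_per_bp * h / math.log(2) * (1.0 - 2.0 ** (-span / h))
    n = int(rng.poisson(mass))
    out = []
    for i in range(n):
        u = rng.random()
        d = -h * math.log2(1.0 - u * (1.0 - 2.0 ** (-span / h)))
        pos = boundary + direction * int(d)
        pos = max(0, min(pos, chrom_len - read_length))
        strand = "+" if rng.random() < 0.5 else "-"
        out.append(AlignedRead(f"{name_prefix}:{i}", chrom, pos,
                               pos + read_length, strand,
                               _mapq(rng, unique_fraction)))
    return out


def simulate_chip_reads(
    truth: SimTruth,
    config: SimConfig,
    antibody: str = "chip",
) -> list[AlignedRead]:
    """Single-end ChIP reads: uniform background plus per-family signal.

    "spreading" families get element-body enrichment that continues into
    the flanks with an exponential decay of the configured half-length;
    "focal" families get body-only enrichment; "absent" families get
    background everywhere.
    """
    rng = _rng(config, _STREAM_CHIP, antibody)
    rl = config.fragments.read_length
    bg_per_bp = config.chip.background_per_kb / 1_000
    reads: list[AlignedRead] = []
    serial = 0

    def uniform_reads(chrom: str, start: int, end: int, rate: float,
                      tag: str) -> None:
        nonlocal serial
        n = int(rng.poisson(rate * (end - start)))
        clen = config.genome[chrom]
        for _ in range(n):
            pos = int(rng.integers(start, end))
            pos = max(0, min(pos, clen - rl))
            strand = "+" if rng.random() < 0.5 else "-"
            reads.append(AlignedRead(f"{antibody}:{tag}:{serial:07d}", chrom,
                                     pos, pos + rl, strand,
                                     _mapq(rng, config.unique_fraction)))
            serial += 1

    for chrom, clen in config.genome.items():
        uniform_reads(chrom, 0, clen, bg_per_bp, "bg")

    span = 6_000
    for fam in config.families:
        extra = fam.chip_enrichment - 1.0
        if extra <= 0 or fam.chip_mode == "absent":
            continue
        for el in truth.full_length[fam.name]:
            iv = el.interval
            uniform_reads(iv.chrom, iv.start, iv.end, bg_per_bp * extra,
                          f"{fam.name}:body")
            if fam.chip_mode == "spreading":
                clen = config.genome[iv.chrom]
                for boundary, direction in ((iv.start - 1, -1), (iv.end, +1)):
                    reads.extend(
                        _sample_flank_reads(
                            rng, boundary, direction, bg_per_bp * extra,
                            fam.chip_half_length, span, iv.chrom, clen, rl,
                            f"{antibody}:{fam.name}:flank:{len(reads)}",
                            config.unique_fraction,
                        )
                    )
    truth.chip_read_counts[antibody] = len(reads)
    return reads


# ---------------------------------------------------------------------------
# stage-expression table


def simulate_stage_table(truth: SimTruth, config: SimConfig) -> pd.DataFrame:
    """Blastomere-style RPM table with planted 2C-specific genes.

    Planted genes get 2C RPM ``fold_2c`` times the baseline; every other
    gene sits at baseline across all stages, so at zero noise the
    4-fold classifier recovers the planted set exactly.
    """
    rng = _rng(config, _STREAM_STAGE)
    st = config.stage
    rows = []
    for gene in truth.genes:
        planted = gene.gene_id in truth.two_c_gene_ids
        base = st.baseline_rpm

        def noisy(x: float) -> float:
            if st.noise_sigma <= 0:
                return x
            return float(x * rng.lognormal(0.0, st.noise_sigma))

        rows.append({
            "gene_id": gene.gene_id,
            "rpm_oocyte": noisy(base),
            "rpm_2c": noisy(base * st.fold_2c if planted else base),
            "rpm_8c": noisy(base),
            "transcript_length": gene.transcript_length,
        })
    columns = ["gene_id", "rpm_oocyte", "rpm_2c", "rpm_8c", "transcript_length"]
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# run directory


def run_simulation(config: SimConfig, outdir: str | Path,
                   antibodies: Sequence[str] = ("chip",)) -> SimTruth:
    """Generate every output under one directory with a manifest.

    Writes repeats.bed, genes.gtf, full_length.bed, per-sample RNA-seq
    SAM + TSV mirrors, per-antibody ChIP SAM + TSV, stage_table.tsv,
    truth.json and manifest.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    repeats, genes, truth = generate_toy_genome(config)
    write_repeat_bed6(repeats, outdir / "repeats.bed")
    write_gene_models_gtf(genes, outdir / "genes.gtf")
    from .genome_model import write_full_length_bed6
    write_full_length_bed6(
        [el for fam in truth.full_length.values() for el in fam],
        outdir / "full_length.bed",
    )
    files = ["repeats.bed", "genes.gtf", "full_length.bed"]
    for sample in config.samples:
        reads = simulate_rnaseq_pairs(truth, config, sample)
        write_sam(reads, outdir / f"rnaseq_{sample}.sam", config.genome)
        write_alignments_tsv(reads, outdir / f"rnaseq_{sample}.tsv")
        files += [f"rnaseq_{sample}.sam", f"rnaseq_{sample}.tsv"]
    for antibody in antibodies:
        reads = simulate_chip_reads(truth, config, antibody)
        write_sam(reads, outdir / f"chip_{antibody}.sam", config.genome)
        write_alignments_tsv(reads, outdir / f"chip_{antibody}.tsv")
        files += [f"chip_{antibody}.sam", f"chip_{antibody}.tsv"]
    stage = simulate_stage_table(truth, config)
    stage.to_csv(outdir / "stage_table.tsv", sep="\t", index=False)
    files.append("stage_table.tsv")
    truth_dict = {
        "proximal_gene_ids": truth.proximal_gene_ids,
        "two_c_gene_ids": sorted(truth.two_c_gene_ids),
        "chimera_support": {f"{g}\t{e}": s
                            for (g, e), s in truth.chimera_support.items()},
        "rnaseq_counts": truth.rnaseq_counts,
        "chip_read_counts": truth.chip_read_counts,
        "full_length_counts": {f: len(v) for f, v in truth.full_length.items()},
    }
    (outdir / "truth.json").write_text(json.dumps(truth_dict, indent=1,
                                                  sort_keys=True))
    files.append("truth.json")
    manifest = {"seed": config.seed, "files": sorted(files),
                "genome": config.genome}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     sort_keys=True))
    config.to_yaml(outdir / "config.yaml")
    return truth
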