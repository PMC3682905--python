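"""Run configuration, pipeline orchestration and report writing."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .alignments import AlignedRead, build_mate_pairs, read_alignments
from .chimeric_transcripts import (
    detect_chimeric_candidates,
    estimate_fragment_stats,
    filter_and_summarize,
    mt2_first_exon_genes,
)
from .chip_flank_profiler import (
    aggregate_flank_profile,
    build_coverage,
    flank_heatmap,
    threshold_coverage,
    write_wig,
)
from .genome_model import (
    assemble_full_length_elements,
    read_gene_models,
    read_repeat_annotation,
)
from .repeat_expression import (
    compare_expression,
    family_expression,
    per_element_expression,
    RegionExpression,
)
from .stage_specificity import (
    DEFAULT_MT2_FAMILIES,
    classify_2c_specific,
    proximity_enrichment,
)
from .synthetic_data import SimConfig, run_simulation

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline thresholds, at their standard defaults."""

    run_dir: str = "."
    seed: int = 0
    mapq_min: int = 10
    extension: int = 300
    peak_height: int = 10
    bin_width: int = 50
    span: int = 6_000
    sd_multiplier: float = 1.0
    min_support: int = 5
    stage_fold: float = 4.0
    ko_fold: float = 4.0
    proximity_bp: int = 5_000
    pseudocount: float = 0.1
    use_thresholded_track: bool = True
    samples: list[str] = field(default_factory=list)
    antibodies: list[str] = field(default_factory=list)


@dataclass
class ReportBundle:
    """Outputs of one pipeline run plus the manifest to reproduce it."""

    run_dir: Path
    outputs: dict[str, str] = field(default_factory=dict)  # label -> filename
    summary: list[str] = field(default_factory=list)

    def add(self, label: str, path: Path) -> None:
        self.outputs[label] = path.name


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_annotations(run_dir: Path):
    repeats = read_repeat_annotation(run_dir / "repeats.bed", "bed6")
    genes = read_gene_models(run_dir / "genes.gtf", "gtf")
    return repeats, genes


def _genome_from_manifest(run_dir: Path) -> dict[str, int]:
    manifest = json.loads((run_dir / "manifest.json").read_text())
    return manifest["genome"]


def _load_sim_config(run_dir: Path) -> SimConfig:
    return SimConfig.from_yaml(run_dir / "config.yaml")


def stage_quantify(config: RunConfig, sample: str,
                   bundle: ReportBundle) -> pd.DataFrame:
    """Per-element and per-family RPKM for one RNA-seq sample.

    Mate pairs are counted once, as their fragment interval.
    """
    run_dir = Path(config.run_dir)
    sam = run_dir / f"rnaseq_{sample}.sam"
    if not sam.exists():
        raise FileNotFoundError(f"missing alignment file: {sam}")
    repeats, _ = _load_annotations(run_dir)
    sim = _load_sim_config(run_dir)
    full = assemble_full_length_elements(repeats, sim.family_specs())
    pairs = build_mate_pairs(read_alignments(sam))
    fragments = [
        AlignedRead(p.read1.read_name, p.read1.chrom,
                    min(p.read1.start, p.read2.start),
                    max(p.read1.end, p.read2.end), p.read1.strand,
                    min(p.read1.mapq, p.read2.mapq))
        for p in pairs if p.same_chrom
    ]
    expr = per_element_expression(fragments, full, mapq_min=config.mapq_min)
    library_total = sum(1 for f in fragments if f.mapq >= config.mapq_min)
    fam_expr = family_expression(
        {eid: (e.read_count, e.length_bp) for eid, e in expr.items()},
        {el.element_id: el.family for el in full},
        library_total,
    )
    rows = [
        {"region_id": e.region_id, "level": "element", "count": e.read_count,
         "length": e.length_bp, "rpkm": e.rpkm, "library_total": library_total}
        for e in expr.values()
    ] + [
        {"region_id": e.region_id, "level": "family", "count": e.read_count,
         "length": e.length_bp, "rpkm": e.rpkm, "library_total": library_total}
        for e in fam_expr.values()
    ]
    df = pd.DataFrame(rows).sort_values(["level", "region_id"]).reset_index(drop=True)
    out = run_dir / f"expression_{sample}.tsv"
    df.to_csv(out, sep="\t", index=False)
    bundle.add(f"expression_{sample}", out)
    return df


def stage_compare(config: RunConfig, sample_a: str, sample_b: str,
                  bundle: ReportBundle) -> pd.DataFrame:
    run_dir = Path(config.run_dir)
    frames = {}
    totals = {}
    for s in (sample_a, sample_b):
        path = run_dir / f"expression_{s}.tsv"
        if not path.exists():
            raise FileNotFoundError(
                f"expression output for sample {s!r} not found; run quantify first"
            )
        df = pd.read_csv(path, sep="\t")
        frames[s] = df
        totals[s] = int(df["library_total"].iloc[0])
    out_rows = []
    for level in ("element", "family"):
        a = frames[sample_a].query("level == @level").set_index("region_id")
        b = frames[sample_b].query("level == @level").set_index("region_id")
        expr_a = {rid: RegionExpression(rid, int(r["count"]), int(r["length"]),
                                        float(r["rpkm"]))
                  for rid, r in a.iterrows()}
        expr_b = {rid: RegionExpression(rid, int(r["count"]), int(r["length"]),
                                        float(r["rpkm"]))
                  for rid, r in b.iterrows()}
        for cmp_ in compare_expression(expr_a, expr_b, totals[sample_a],
                                       totals[sample_b], config.pseudocount):
            out_rows.append({
                "region_id": cmp_.region_id, "level": level,
                "rpkm_a": cmp_.rpkm_a, "rpkm_b": cmp_.rpkm_b,
                "n_a": cmp_.n_a, "n_b": cmp_.n_b,
                "z": cmp_.z, "fold_change": cmp_.fold_change,
            })
    df = pd.DataFrame(out_rows)
    out = run_dir / f"comparison_{sample_a}_vs_{sample_b}.tsv"
    df.to_csv(out, sep="\t", index=False)
    bundle.add(f"comparison_{sample_a}_vs_{sample_b}", out)
    return df


def stage_profile(config: RunConfig, antibody: str,
                  bundle: ReportBundle) -> dict[str, pd.DataFrame]:
    run_dir = Path(config.run_dir)
    sam = run_dir / f"chip_{antibody}.sam"
    if not sam.exists():
        raise FileNotFoundError(f"missing alignment file: {sam}")
    repeats, _ = _load_annotations(run_dir)
    sim = _load_sim_config(run_dir)
    full = assemble_full_length_elements(repeats, sim.family_specs())
    genome = _genome_from_manifest(run_dir)
    reads = read_alignments(sam)
    track = build_coverage(reads, genome, mapq_min=config.mapq_min,
                           extension=config.extension)
    regions, thresholded = threshold_coverage(track, config.peak_height)
    write_wig(track, run_dir / f"coverage_{antibody}.wig", f"{antibody} raw")
    write_wig(thresholded, run_dir / f"coverage_{antibody}_thresholded.wig",
              f"{antibody} thresholded")
    with open(run_dir / f"enriched_{antibody}.bed", "w") as fh:
        for chrom, start, end, height in regions:
            fh.write(f"{chrom}\t{start}\t{end}\tpeak\t{height}\t.\n")
    bundle.add(f"coverage_{antibody}", run_dir / f"coverage_{antibody}.wig")
    bundle.add(f"enriched_{antibody}", run_dir / f"enriched_{antibody}.bed")
    use = thresholded if config.use_thresholded_track else track
    profiles = {}
    by_family: dict[str, list] = {}
    for el in full:
        by_family.setdefault(el.family, []).append(el)
    for family, elements in sorted(by_family.items()):
        prof = aggregate_flank_profile(use, elements, span=config.span,
                                       bin_width=config.bin_width)
        heat = flank_heatmap(use, elements, span=config.span,
                             bin_width=config.bin_width)
        n_bins = config.span // config.bin_width
        offsets = [(-n_bins + i) * config.bin_width + config.bin_width // 2
                   if i < n_bins else
                   (i - n_bins) * config.bin_width + config.bin_width // 2
                   for i in range(2 * n_bins)]
        pdf = pd.DataFrame({
            "bin": range(2 * n_bins),
            "offset_bp": offsets,
            "side": ["5prime"] * n_bins + ["3prime"] * n_bins,
            "density": prof.densities,
        })
        ppath = run_dir / f"profile_{antibody}_{family}.tsv"
        pdf.to_csv(ppath, sep="\t", index=False)
        hdf = pd.DataFrame(heat.matrix, index=heat.element_ids)
        hpath = run_dir / f"heatmap_{antibody}_{family}.tsv"
        hdf.to_csv(hpath, sep="\t", index_label="element_id")
        bundle.add(f"profile_{antibody}_{family}", ppath)
        bundle.add(f"heatmap_{antibody}_{family}", hpath)
        profiles[family] = pdf
    return profiles


def stage_chimera(config: RunConfig, sample: str,
                  bundle: ReportBundle) -> pd.DataFrame:
    run_dir = Path(config.run_dir)
    sam = run_dir / f"rnaseq_{sample}.sam"
    if not sam.exists():
        raise FileNotFoundError(f"missing alignment file: {sam}")
    repeats, genes = _load_annotations(run_dir)
    pairs = build_mate_pairs(read_alignments(sam))
    stats = estimate_fragment_stats(pairs)
    candidates = detect_chimeric_candidates(
        pairs, stats, repeats, genes, mapq_min=config.mapq_min
    )
    valid, breakdown = filter_and_summarize(candidates, config.min_support)
    calls = pd.DataFrame(
        [{"gene_id": c.gene_id, "element_id": c.erv_element_id,
          "family": c.erv_family, "support": c.support, "valid": c.valid}
         for c in candidates],
        columns=["gene_id", "element_id", "family", "support", "valid"],
    )
    cpath = run_dir / f"chimera_calls_{sample}.tsv"
    calls.to_csv(cpath, sep="\t", index=False)
    bpath = run_dir / f"chimera_breakdown_{sample}.tsv"
    breakdown.to_csv(bpath, sep="\t", index=False)
    bundle.add(f"chimera_calls_{sample}", cpath)
    bundle.add(f"chimera_breakdown_{sample}", bpath)
    annotated = mt2_first_exon_genes(genes, repeats)
    apath = run_dir / "mt2_exon1_genes.tsv"
    pd.DataFrame({"gene_id": [g.gene_id for g in annotated]}).to_csv(
        apath, sep="\t", index=False
    )
    bundle.add("mt2_exon1_genes", apath)
    bundle.summary.append(
        f"chimera[{sample}]: {len(valid)} valid of {len(candidates)} candidates; "
        + "; ".join(f"{r.family} {r.percentage}%"
                    for r in breakdown.itertuples())
    )
    return calls


def stage_twocell(config: RunConfig, bundle: ReportBundle) -> pd.DataFrame:
    run_dir = Path(config.run_dir)
    table_path = run_dir / "stage_table.tsv"
    if not table_path.exists():
        raise FileNotFoundError(f"missing stage table: {table_path}")
    repeats, genes = _load_annotations(run_dir)
    table = pd.read_csv(table_path, sep="\t")
    two_c = classify_2c_specific(table, fold=config.stage_fold)
    result = proximity_enrichment(
        two_c, genes, repeats, families=DEFAULT_MT2_FAMILIES,
        max_dist=config.proximity_bp,
    )
    genes_df = pd.DataFrame({"gene_id": sorted(two_c)})
    gpath = run_dir / "two_cell_specific.tsv"
    genes_df.to_csv(gpath, sep="\t", index=False)
    enr = pd.DataFrame([{
        "overlap": result.overlap_count, "set_size": result.set_size,
        "background_count": result.background_count,
        "population": result.population,
        "percentage": result.percentage,
        "background_fraction": result.background_fraction,
        "p_value": result.p_value,
    }])
    epath = run_dir / "two_cell_enrichment.tsv"
    enr.to_csv(epath, sep="\t", index=False)
    bundle.add("two_cell_specific", gpath)
    bundle.add("two_cell_enrichment", epath)
    bundle.summary.append(
        f"twocell: {len(two_c)} 2C-specific genes; MT2-proximal "
        f"{result.overlap_count}/{result.set_size} "
        f"(background {100 * result.background_fraction:.1f}%), "
        f"p={result.p_value:.3g}"
    )
    return enr


STAGE_ORDER = ("quantify", "compare", "profile", "chimera", "twocell")


def run_pipeline(config: RunConfig,
                 stages: Optional[Sequence[str]] = None) -> ReportBundle:
    """Execute the requested stages in dependency order and write reports."""
    run_dir = Path(config.run_dir)
    bundle = ReportBundle(run_dir=run_dir)
    wanted = list(stages) if stages else list(STAGE_ORDER)
    unknown = set(wanted) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    samples = config.samples or sorted(
        p.stem.removeprefix("rnaseq_") for p in run_dir.glob("rnaseq_*.sam")
    )
    antibodies = config.antibodies or sorted(
        p.stem.removeprefix("chip_") for p in run_dir.glob("chip_*.sam")
    )
    for stage in STAGE_ORDER:
        if stage not in wanted:
            continue
        t0 = time.monotonic()
        if stage == "quantify":
            for s in samples:
                stage_quantify(config, s, bundle)
        elif stage == "compare":
            for a, b in zip(samples, samples[1:]):
                stage_compare(config, a, b, bundle)
        elif stage == "profile":
            for ab in antibodies:
                stage_profile(config, ab, bundle)
        elif stage == "chimera":
            for s in samples:
                stage_chimera(config, s, bundle)
        elif stage == "twocell":
            stage_twocell(config, bundle)
        logger.info("stage %s finished in %.2fs", stage, time.monotonic() - t0)
    write_manifest(config, bundle)
    return bundle


def write_manifest(config: RunConfig, bundle: ReportBundle) -> Path:
    run_dir = Path(config.run_dir)
    digests = {
        name: _sha256(run_dir / fname)
        for name, fname in sorted(bundle.outputs.items())
        if (run_dir / fname).exists()
    }
    manifest = {
        "version": __version__,
        "parameters": asdict(config),
        "outputs": bundle.outputs,
        "digests": digests,
        "summary": bundle.summary,
    }
    path = run_dir / "pipeline_manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path
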