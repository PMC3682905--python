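"""Detection of LTR-gene chimeric transcripts from discordant mate pairs.

A mate pair supports a chimera when its fragment size deviates from the
library mean by strictly more than one standard deviation, one mate lies
in an ERV element upstream (in gene orientation) of the gene's first
exon, and the other mate lies in an annotated exon of that gene.
Transcripts with strictly more than ``min_support`` unique supporting
pairs are scored valid.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .alignments import MatePair
from .genome_model import GeneModel, GenomicInterval, IntervalIndex, RepeatElement

DEFAULT_MIN_SUPPORT = 5
DEFAULT_MAX_UPSTREAM = 10_000
DEFAULT_MAPQ_MIN = 10
DEFAULT_TRIM = 0.005


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class FragmentStats:
    """Trimmed mean/SD of the concordant fragment-size distribution."""

    mean: float
    sd: float
    n_pairs_used: int

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("fragment-size SD must be positive")


@dataclass
class ChimericCandidate:
    gene_id: str
    erv_element_id: str
    erv_family: str
    support: int
    valid: bool = False


def estimate_fragment_stats(
    pairs: Iterable[MatePair],
    trim: float = DEFAULT_TRIM,
    min_pairs: int = 50,
) -> FragmentStats:
    """Mean/SD of fragment sizes over same-chromosome pairs.

    Sizes outside the central 1 - 2*trim quantile range are discarded
    before estimating, so grossly discordant pairs do not inflate the SD.
    """
    sizes = np.array(
        [p.fragment_size for p in pairs if p.fragment_size is not None], dtype=float
    )
    if len(sizes) < min_pairs:
        raise ValueError(
            f"need >= {min_pairs} same-chromosome pairs, got {len(sizes)}"
        )
    lo, hi = np.quantile(sizes, [trim, 1.0 - trim])
    kept = sizes[(sizes >= lo) & (sizes <= hi)]
    sd = float(kept.std(ddof=1))
    if sd <= 0:
        raise ValueError("degenerate fragment-size distribution (SD = 0)")
    return FragmentStats(mean=float(kept.mean()), sd=sd, n_pairs_used=int(len(kept)))


def _upstream_window(gene: GeneModel, max_upstream: int) -> tuple[int, int]:
    """Genomic window upstream of the first exon, in gene orientation.

    The window also covers the first exon itself, since an ERV overlapping
    exon 1 qualifies.
    """
    fe = gene.first_exon
    if gene.strand == "+":
        return max(fe.start - max_upstream, 0), fe.end
    return fe.start, fe.end + max_upstream


def detect_chimeric_candidates(
    pairs: Sequence[MatePair],
    stats: FragmentStats,
    erv_elements: Sequence[RepeatElement],
    genes: Sequence[GeneModel],
    max_upstream: int = DEFAULT_MAX_UPSTREAM,
    mapq_min: int = DEFAULT_MAPQ_MIN,
    mode: str = "methods",
) -> list[ChimericCandidate]:
    """Enumerate ERV-gene chimeric candidates from discordant pairs.

    mode "methods": one mate in an ERV upstream of (or overlapping) the
    gene's first exon, the other mate in an annotated exon of that gene.
    mode "results": one mate in any LTR-part element and the other in any
    exon of the gene (no upstream constraint on the element).

    Support counts unique pairs only: both mates mapq >= mapq_min and
    distinct pair start coordinates. Qualifying pairs are grouped by
    (gene, element); the order of the input pairs does not matter.
    """
    if mode not in ("methods", "results"):
        raise ValueError(f"unknown mode {mode!r}")

    element_index = IntervalIndex(
        (el.interval, el)
        for el in erv_elements
        if mode == "methods" or el.part == "LTR"
    )
    exon_index = IntervalIndex(
        (ex, gene) for gene in genes for ex in gene.exons
    )
    upstream = {g.gene_id: _upstream_window(g, max_upstream) for g in genes}

    support_keys: dict[tuple[str, str], set] = defaultdict(set)
    families: dict[str, str] = {}
    for pair in pairs:
        frag = pair.fragment_size
        if frag is None or abs(frag - stats.mean) <= stats.sd:  # strict ">"
            continue
        if pair.read1.mapq < mapq_min or pair.read2.mapq < mapq_min:
            continue
        for erv_mate, gene_mate in ((pair.read1, pair.read2), (pair.read2, pair.read1)):
            hit_elements = element_index.overlapping(
                erv_mate.chrom, erv_mate.start, erv_mate.end
            )
            if not hit_elements:
                continue
            hit_genes = {
                g.gene_id: g
                for g in exon_index.overlapping(
                    gene_mate.chrom, gene_mate.start, gene_mate.end
                )
            }
            for el in hit_elements:
                for gid, gene in hit_genes.items():
                    if gene.chrom != el.interval.chrom:
                        continue
                    if mode == "methods":
                        lo, hi = upstream[gid]
                        if not (el.interval.start < hi and lo < el.interval.end):
                            continue
                    support_keys[(gid, el.element_id)].add(pair.start_key)
                    families[el.element_id] = el.family
    candidates = [
        ChimericCandidate(gene_id=gid, erv_element_id=eid,
                          erv_family=families[eid], support=len(keys))
        for (gid, eid), keys in sorted(support_keys.items())
    ]
    return candidates


def filter_and_summarize(
    candidates: Sequence[ChimericCandidate],
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> tuple[list[ChimericCandidate], pd.DataFrame]:
    """Score valid chimeric transcripts and break them down by LTR family.

    A transcript (gene) is valid when its summed support across elements
    is strictly greater than ``min_support``. The breakdown reports, per
    ERV family, the number of valid calls and their percentage of all
    valid calls (rounded half-up to the nearest integer); raw fractions
    are kept alongside.
    """
    gene_support: dict[str, int] = defaultdict(int)
    for c in candidates:
        gene_support[c.gene_id] += c.support
    valid = []
    for c in candidates:
        c.valid = gene_support[c.gene_id] > min_support
        if c.valid:
            valid.append(c)
    fam_counts: dict[str, int] = defaultdict(int)
    for c in valid:
        fam_counts[c.erv_family] += 1
    total = sum(fam_counts.values())
    rows = [
        {
            "family": fam,
            "count": n,
            "total": total,
            "fraction": n / total if total else 0.0,
            "percentage": _round_half_up(100.0 * n / total) if total else 0,
        }
        for fam, n in sorted(fam_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    breakdown = pd.DataFrame(
        rows, columns=["family", "count", "total", "fraction", "percentage"]
    )
    return valid, breakdown


def mt2_first_exon_genes(
    genes: Sequence[GeneModel],
    erv_elements: Sequence[RepeatElement],
    family_prefix: str = "MT2",
) -> list[GeneModel]:
    """Genes in both RefSeq and Ensembl whose first exon overlaps an MT2 LTR."""
    index = IntervalIndex(
        (el.interval, el)
        for el in erv_elements
        if el.family.startswith(family_prefix) and el.part == "LTR"
    )
    out = []
    for gene in genes:
        if not (gene.in_refseq and gene.in_ensembl):
            continue
        fe = gene.first_exon
        if index.overlapping(gene.chrom, fe.start, fe.end):
            out.append(gene)
    return out
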