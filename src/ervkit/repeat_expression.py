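"""RPKM quantification and pairwise deregulation scoring.

The pairwise statistic treats each sample's RPKM as Poisson-like
(variance proportional to mean) and scales sample B by the library-size
ratio r_AB = N_A / N_B:

    z = (RPKM_A - RPKM_B) / sqrt(RPKM_A + r_AB * RPKM_B)

z is defined as 0 when both RPKMs are 0. Fold changes use a configurable
pseudocount so zero-reference regions stay defined.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .alignments import AlignedRead
from .genome_model import FullLengthElement, GenomicInterval, IntervalIndex

DEFAULT_MAPQ_MIN = 10
DEFAULT_PSEUDOCOUNT = 0.1


@dataclass(frozen=True)
class RegionExpression:
    """Read count, summed length and RPKM for one region."""

    region_id: str
    read_count: int
    length_bp: int
    rpkm: float


@dataclass(frozen=True)
class PairwiseComparison:
    region_id: str
    rpkm_a: float
    rpkm_b: float
    n_a: int
    n_b: int
    z: float
    fold_change: float

    @property
    def r_ab(self) -> float:
        return self.n_a / self.n_b


def count_reads_in_regions(
    alignments: Iterable[AlignedRead],
    regions: Mapping[str, Sequence[GenomicInterval]],
    mapq_min: int = DEFAULT_MAPQ_MIN,
    unique_only: bool = True,
) -> tuple[dict[str, int], int]:
    """Count reads per region and return (counts, library_total).

    A read is counted once per region it overlaps by >=1 bp (a read
    overlapping two regions increments both; no fractional assignment).
    When ``unique_only`` is set, reads with mapq < mapq_min are dropped
    from both the counts and the library total.
    """
    if not isinstance(regions, Mapping):
        pairs = list(regions)
        ids = [rid for rid, _ in pairs]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate region ids: {dupes}")
        regions = dict(pairs)
    if not regions:
        raise ValueError("regions must be non-empty")
    index = IntervalIndex(
        (iv, rid) for rid, ivs in regions.items() for iv in ivs
    )
    counts: dict[str, int] = {rid: 0 for rid in regions}
    library_total = 0
    for read in alignments:
        if unique_only and read.mapq < mapq_min:
            continue
        library_total += 1
        hits = set(index.overlapping(read.chrom, read.start, read.end))
        for rid in hits:
            counts[rid] += 1
    return counts, library_total


def compute_rpkm(read_count: int, length_bp: int, total_reads: int) -> float:
    """Reads per kilobase of region per million mapped reads."""
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    if total_reads <= 0:
        raise ValueError("total_reads must be positive (normalization undefined)")
    return read_count / (length_bp / 1_000) / (total_reads / 1_000_000)


def family_expression(
    element_expression: Mapping[str, tuple[int, int]],
    family_map: Mapping[str, str],
    library_total: int,
) -> dict[str, RegionExpression]:
    """Aggregate per-element (count, length) to per-family RPKM.

    Every element id must map to exactly one family; families without
    members are absent from the output.
    """
    unmapped = [eid for eid in element_expression if eid not in family_map]
    if unmapped:
        raise ValueError(f"elements not mapped to a family: {sorted(unmapped)}")
    counts: dict[str, int] = defaultdict(int)
    lengths: dict[str, int] = defaultdict(int)
    for eid, (count, length) in element_expression.items():
        fam = family_map[eid]
        counts[fam] += count
        lengths[fam] += length
    return {
        fam: RegionExpression(fam, counts[fam], lengths[fam],
                              compute_rpkm(counts[fam], lengths[fam], library_total))
        for fam in counts
    }


def poisson_zscore(rpkm_a: float, rpkm_b: float, n_a: int, n_b: int) -> float:
    if rpkm_a < 0 or rpkm_b < 0:
        raise ValueError("RPKM values must be non-negative")
    if n_a <= 0 or n_b <= 0:
        raise ValueError("library totals must be positive")
    if rpkm_a + rpkm_b == 0:
        return 0.0
    r_ab = n_a / n_b
    return (rpkm_a - rpkm_b) / math.sqrt(rpkm_a + r_ab * rpkm_b)


def fold_change(rpkm_test: float, rpkm_ref: float,
                pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    if rpkm_test < 0 or rpkm_ref < 0:
        raise ValueError("RPKM values must be non-negative")
    if pseudocount == 0 and rpkm_ref == 0:
        raise ValueError("fold change undefined: zero reference and no pseudocount")
    return (rpkm_test + pseudocount) / (rpkm_ref + pseudocount)


def compare_expression(
    expr_a: Mapping[str, RegionExpression],
    expr_b: Mapping[str, RegionExpression],
    n_a: int,
    n_b: int,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[PairwiseComparison]:
    """Pairwise Z-score + fold change for every region shared by A and B."""
    shared = sorted(set(expr_a) & set(expr_b))
    out = []
    for rid in shared:
        a, b = expr_a[rid].rpkm, expr_b[rid].rpkm
        out.append(
            PairwiseComparison(
                region_id=rid, rpkm_a=a, rpkm_b=b, n_a=n_a, n_b=n_b,
                z=poisson_zscore(a, b, n_a, n_b),
                fold_change=fold_change(a, b, pseudocount),
            )
        )
    return out


def per_element_expression(
    alignments: Iterable[AlignedRead],
    full_length_elements: Sequence[FullLengthElement],
    mapq_min: int = DEFAULT_MAPQ_MIN,
    library_total: Optional[int] = None,
) -> dict[str, RegionExpression]:
    """Unique-read expression of individual full-length elements.

    Only reads passing the mapq filter that overlap exactly one element
    are counted (reads straddling two elements are ambiguous and dropped).
    ``library_total`` defaults to the number of mapq-passing reads seen.
    """
    index = IntervalIndex((el.interval, el.element_id) for el in full_length_elements)
    counts: dict[str, int] = {el.element_id: 0 for el in full_length_elements}
    retained = 0
    for read in alignments:
        if read.mapq < mapq_min:
            continue
        retained += 1
        hits = set(index.overlapping(read.chrom, read.start, read.end))
        if len(hits) == 1:
            counts[hits.pop()] += 1
    total = library_total if library_total is not None else retained
    out = {}
    for el in full_length_elements:
        length = el.interval.length
        rpkm = compute_rpkm(counts[el.element_id], length, total) if total > 0 else 0.0
        out[el.element_id] = RegionExpression(el.element_id, counts[el.element_id],
                                              length, rpkm)
    return out
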