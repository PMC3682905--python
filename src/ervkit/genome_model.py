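"""Domain types and annotation handling for repeat-centric genome analyses.

All coordinates are 0-based, half-open. RepeatMasker ``.out`` records
(1-based, inclusive) are converted on read; BED is native.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")


class AnnotationParseError(ValueError):
    """Raised when an annotation file cannot be parsed; names the line."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class RepeatElement:
    """One annotated repeat segment (an LTR or an internal region)."""

    element_id: str
    family: str
    part: str  # "LTR" | "internal"
    interval: GenomicInterval
    erv_class: str = "other"  # "I" | "II" | "III" | "other"

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError("family must be nonempty")
        if self.part not in ("LTR", "internal"):
            raise ValueError(f"invalid part {self.part!r}")


@dataclass
class FullLengthElement:
    """An intact LTR-internal-LTR provirus assembled from repeat segments."""

    element_id: str
    family: str  # superfamily, e.g. MERVL
    ltr5: RepeatElement
    internal: list[RepeatElement]
    ltr3: RepeatElement
    interval: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        if self.ltr5.family != self.ltr3.family:
            raise ValueError("5' and 3' LTR families differ")
        if not self.internal:
            raise ValueError("full-length element needs >=1 internal segment")


@dataclass
class GeneModel:
    """A gene with exon structure; exons ordered 5'->3' in transcript sense."""

    gene_id: str
    name: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    in_refseq: bool = True
    in_ensembl: bool = True

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError("gene needs >=1 exon")
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise ValueError(f"overlapping exons in {self.gene_id}")
        want = genomic if self.strand == "+" else genomic[::-1]
        if list(self.exons) != want:
            raise ValueError(f"exons of {self.gene_id} not in transcript order")

    @property
    def tss(self) -> int:
        first = self.exons[0]
        return first.start if self.strand == "+" else first.end - 1

    @property
    def first_exon(self) -> GenomicInterval:
        return self.exons[0]

    @property
    def transcript_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        start = min(e.start for e in self.exons)
        end = max(e.end for e in self.exons)
        return GenomicInterval(self.chrom, start, end, self.strand)


@dataclass(frozen=True)
class FlankBin:
    """One fixed-width bin in an element flank, strand-oriented.

    ``bin_index`` 0 is adjacent to the element boundary; the 5' side of a
    minus-strand element lies at higher genomic coordinates. A bin clipped
    at a chromosome edge keeps its nominal width in ``bin_index`` terms but
    carries a truncated ``interval`` (``None`` when fully off-chromosome)
    and ``truncated=True``.
    """

    element_id: str
    side: str  # "5prime" | "3prime"
    bin_index: int
    interval: Optional[GenomicInterval]
    truncated: bool = False


@dataclass(frozen=True)
class FamilySpec:
    """Assembly rules for one ERV superfamily."""

    name: str
    ltr_family: str
    internal_family: str
    min_span: int
    max_span: int
    gap_tolerance: int = 100


#: Length windows are configurable placeholders (no authoritative values).
DEFAULT_FAMILY_SPECS: tuple[FamilySpec, ...] = (
    FamilySpec("MERVL", "MT2_Mm", "MERVL-int", 5_000, 8_000),
    FamilySpec("IAPEz", "IAPLTR1_Mm", "IAPEz-int", 6_000, 9_000),
    FamilySpec("MMERVK10C", "RLTR10C", "MMERVK10C-int", 5_000, 10_000),
)

#: family name -> ERV class for the families this artifact cares about.
DEFAULT_CLASS_TABLE: Mapping[str, str] = {
    "MT2_Mm": "III",
    "MT2A": "III",
    "MT2B": "III",
    "MT2C": "III",
    "MERVL-int": "III",
    "ORR1A3-int": "III",
    "IAPLTR1_Mm": "II",
    "IAPEz-int": "II",
    "RLTR10C": "II",
    "MMERVK10C-int": "II",
}


def infer_part(family: str, part_table: Optional[Mapping[str, str]] = None,
               strict: bool = False) -> str:
    """Classify a repeat family name as LTR or internal segment."""
    if part_table and family in part_table:
        return part_table[family]
    if family.endswith("-int") or family.endswith("_I"):
        return "internal"
    if family.startswith(("MT2", "IAPLTR", "RLTR", "LTR")):
        return "LTR"
    if strict:
        raise ValueError(f"unknown repeat family {family!r} (strict mode)")
    logger.warning("unknown family %r: assuming internal segment", family)
    return "internal"


def read_repeat_annotation(
    path: str | Path,
    dialect: str = "bed6",
    part_table: Optional[Mapping[str, str]] = None,
    class_table: Optional[Mapping[str, str]] = None,
    strict: bool = False,
) -> list[RepeatElement]:
    """Read repeat annotations from BED6 or RepeatMasker ``.out``.

    RepeatMasker coordinates (1-based inclusive) are converted to 0-based
    half-open. The segment part (LTR vs internal) is inferred from the
    family name via ``part_table`` / naming conventions.
    """
    if dialect not in ("bed6", "repeatmasker"):
        raise ValueError(f"unknown dialect {dialect!r}")
    class_table = class_table if class_table is not None else DEFAULT_CLASS_TABLE
    out: list[RepeatElement] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            if dialect == "repeatmasker" and (
                line.lstrip().startswith(("SW", "score")) or lineno <= 3
                and not line.split()[0].isdigit()
            ):
                continue  # header block
            try:
                if dialect == "bed6":
                    fields = line.split("\t") if "\t" in line else line.split()
                    chrom, start, end, family = fields[0], int(fields[1]), int(fields[2]), fields[3]
                    strand = fields[5] if len(fields) > 5 else "+"
                else:
                    fields = line.split()
                    chrom = fields[4]
                    start = int(fields[5]) - 1  # 1-based inclusive -> 0-based
                    end = int(fields[6])
                    strand = "-" if fields[8] in ("C", "-") else "+"
                    family = fields[9]
                interval = GenomicInterval(chrom, start, end, strand)
            except (IndexError, ValueError) as exc:
                raise AnnotationParseError(
                    f"{path}: malformed {dialect} record at line {lineno}: {exc}"
                ) from exc
            part = infer_part(family, part_table, strict=strict)
            out.append(
                RepeatElement(
                    element_id=f"{family}|{chrom}:{start}-{end}",
                    family=family,
                    part=part,
                    interval=interval,
                    erv_class=class_table.get(family, "other"),
                )
            )
    return out


def write_repeat_bed6(elements: Iterable[RepeatElement], path: str | Path) -> None:
    with open(path, "w") as fh:
        for el in elements:
            iv = el.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{el.family}\t0\t{iv.strand}\n")


def write_full_length_bed6(elements: Iterable[FullLengthElement], path: str | Path) -> None:
    """Write assembled elements as BED6 with the superfamily in the name field."""
    with open(path, "w") as fh:
        for el in elements:
            iv = el.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{el.family}\t0\t{el.strand}\n")


# ---------------------------------------------------------------------------
# gene models


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gene_models(path: str | Path, fmt: str = "gtf") -> list[GeneModel]:
    """Read gene models from GTF (exon features) or BED12.

    GTF attributes ``in_refseq`` / ``in_ensembl`` ("0"/"1") set the source
    flags; both default to true when absent (as for BED12 input).
    """
    if fmt == "gtf":
        return _read_gtf(path)
    if fmt == "bed12":
        return _read_bed12(path)
    raise ValueError(f"unknown gene model format {fmt!r}")


def _read_gtf(path: str | Path) -> list[GeneModel]:
    exons: dict[str, list[GenomicInterval]] = defaultdict(list)
    meta: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            if not raw.strip() or raw.startswith("#"):
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise AnnotationParseError(f"{path}: malformed GTF at line {lineno}")
            if fields[2] != "exon":
                continue
            chrom, start, end, strand = fields[0], int(fields[3]) - 1, int(fields[4]), fields[6]
            attrs = _parse_gtf_attributes(fields[8])
            gid = attrs.get("gene_id")
            if gid is None:
                raise AnnotationParseError(f"{path}: exon without gene_id at line {lineno}")
            exons[gid].append(GenomicInterval(chrom, start, end, strand))
            meta.setdefault(gid, {
                "name": attrs.get("gene_name", gid),
                "chrom": chrom,
                "strand": strand,
                "in_refseq": attrs.get("in_refseq", "1") != "0",
                "in_ensembl": attrs.get("in_ensembl", "1") != "0",
            })
    genes = []
    for gid, ivs in exons.items():
        m = meta[gid]
        ordered = sorted(ivs, key=lambda e: e.start, reverse=m["strand"] == "-")
        genes.append(GeneModel(gid, m["name"], m["chrom"], m["strand"], ordered,
                               in_refseq=m["in_refseq"], in_ensembl=m["in_ensembl"]))
    genes.sort(key=lambda g: (g.chrom, g.span.start, g.gene_id))
    return genes


def _read_bed12(path: str | Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            if not raw.strip() or raw.startswith(("#", "track", "browser")):
                continue
            f = raw.rstrip("\n").split("\t")
            if len(f) < 12:
                raise AnnotationParseError(f"{path}: malformed BED12 at line {lineno}")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            ivs = [GenomicInterval(chrom, start + o, start + o + s, strand)
                   for o, s in zip(offsets, sizes)]
            if strand == "-":
                ivs = ivs[::-1]
            genes.append(GeneModel(name, name, chrom, strand, ivs))
    return genes


def write_gene_models_gtf(genes: Iterable[GeneModel], path: str | Path,
                          source: str = "ervkit") -> None:
    with open(path, "w") as fh:
        for g in genes:
            for i, ex in enumerate(g.exons, 1):
                attrs = (
                    f'gene_id "{g.gene_id}"; gene_name "{g.name}"; '
                    f'exon_number "{i}"; '
                    f'in_refseq "{int(g.in_refseq)}"; in_ensembl "{int(g.in_ensembl)}";'
                )
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# intact-element assembly


def assemble_full_length_elements(
    elements: Sequence[RepeatElement],
    family_specs: Sequence[FamilySpec] = DEFAULT_FAMILY_SPECS,
) -> list[FullLengthElement]:
    """Assemble intact LTR-internal(s)-LTR proviruses from repeat segments.

    A run qualifies when both LTRs carry the identical family annotation,
    internal segments belong to the spec'd internal family, adjacent
    components are separated by at most the gap tolerance, and the total
    span falls inside the family length window. Segments consumed by one
    element are not reused; non-qualifying runs are skipped (counted in a
    debug log).
    """
    by_ltr = {spec.ltr_family: spec for spec in family_specs}
    skipped: dict[str, int] = defaultdict(int)
    out: list[FullLengthElement] = []
    groups: dict[tuple[str, str], list[RepeatElement]] = defaultdict(list)
    for el in elements:
        groups[(el.interval.chrom, el.interval.strand)].append(el)

    for (chrom, strand), group in sorted(groups.items()):
        group = sorted(group, key=lambda e: (e.interval.start, e.interval.end))
        consumed = [False] * len(group)
        i = 0
        while i < len(group):
            el = group[i]
            spec = by_ltr.get(el.family)
            if consumed[i] or spec is None:
                i += 1
                continue
            internal: list[RepeatElement] = []
            closing: Optional[int] = None
            prev_end = el.interval.end
            j = i + 1
            taken: list[int] = []
            while j < len(group):
                nxt = group[j]
                if consumed[j]:
                    j += 1
                    continue
                if nxt.interval.start - prev_end > spec.gap_tolerance:
                    break
                if nxt.family == spec.internal_family:
                    internal.append(nxt)
                    taken.append(j)
                elif nxt.family == el.family and internal:
                    closing = j
                    break
                else:
                    break  # foreign segment interrupts the run
                prev_end = nxt.interval.end
                j += 1
            if closing is None or not internal:
                skipped[spec.name] += 1
                i += 1
                continue
            ltr3 = group[closing]
            span = ltr3.interval.end - el.interval.start
            if not (spec.min_span <= span <= spec.max_span):
                skipped[spec.name] += 1
                i += 1
                continue
            interval = GenomicInterval(chrom, el.interval.start, ltr3.interval.end, strand)
            out.append(
                FullLengthElement(
                    element_id=f"{spec.name}|{chrom}:{interval.start}-{interval.end}",
                    family=spec.name,
                    ltr5=el if strand == "+" else ltr3,
                    internal=list(internal),
                    ltr3=ltr3 if strand == "+" else el,
                    interval=interval,
                    strand=strand,
                )
            )
            consumed[i] = True
            consumed[closing] = True
            for k in taken:
                consumed[k] = True
            i = closing + 1
    for fam, n in sorted(skipped.items()):
        logger.debug("assembly skipped %d non-qualifying %s run(s)", n, fam)
    out.sort(key=lambda e: (e.interval.chrom, e.interval.start))
    return out


# ---------------------------------------------------------------------------
# flank geometry


def flank_bins(
    element: FullLengthElement,
    span: int = 6_000,
    bin_width: int = 50,
    chrom_length: Optional[int] = None,
) -> list[FlankBin]:
    """Fixed-width bins over both flanks of an element, strand-oriented.

    Returns 2 * span/bin_width bins, the 5' side first. Bin index 0 abuts
    the element boundary. For minus-strand elements the 5' side lies at
    higher genomic coordinates. Bins crossing a chromosome edge are
    truncated and flagged.
    """
    if span <= 0 or bin_width <= 0:
        raise ValueError("span and bin_width must be positive")
    if span % bin_width != 0:
        raise ValueError("span must be divisible by bin_width")
    n_bins = span // bin_width
    iv = element.interval
    chrom_end = chrom_length if chrom_length is not None else None

    def clip(start: int, end: int) -> tuple[Optional[GenomicInterval], bool]:
        cs, ce = max(start, 0), end
        if chrom_end is not None:
            ce = min(ce, chrom_end)
        truncated = (cs, ce) != (start, end)
        if cs >= ce:
            return None, True
        return GenomicInterval(iv.chrom, cs, ce, iv.strand), truncated

    bins: list[FlankBin] = []
    for side in ("5prime", "3prime"):
        # "left" = lower genomic coordinates relative to the element
        left = (side == "5prime") == (element.strand == "+")
        for k in range(n_bins):
            if left:
                start = iv.start - (k + 1) * bin_width
                end = iv.start - k * bin_width
            else:
                start = iv.end + k * bin_width
                end = iv.end + (k + 1) * bin_width
            clipped, truncated = clip(start, end)
            bins.append(FlankBin(element.element_id, side, k, clipped, truncated))
    return bins


# ---------------------------------------------------------------------------
# TSS-to-LTR distance


def nearest_ltr_distance(
    gene: GeneModel,
    ltr_families: Iterable[str],
    elements: Sequence[RepeatElement],
) -> Optional[int]:
    """Distance in bp from a gene's TSS to the nearest listed LTR element.

    0 when the TSS falls inside such an element; ``None`` when no listed
    element exists on the gene's chromosome. Ties go to the element with
    the lower genomic coordinate (affects identity only, not distance).
    """
    fams = set(ltr_families)
    tss = gene.tss
    best: Optional[int] = None
    for el in elements:
        if el.family not in fams or el.interval.chrom != gene.chrom:
            continue
        iv = el.interval
        if iv.contains_point(tss):
            d = 0
        elif tss < iv.start:
            d = iv.start - tss
        else:
            d = tss - iv.end
        if best is None or d < best:
            best = d
    return best


# ---------------------------------------------------------------------------
# simple per-chromosome interval index (small-scale, sorted-scan)


class IntervalIndex:
    """Overlap queries over a static interval set, grouped by chromosome.

    Sorted-start scan bounded by the running maximum end; adequate for the
    annotation scales this toolkit targets.
    """

    def __init__(self, intervals: Iterable[tuple[GenomicInterval, object]]):
        per_chrom: dict[str, list[tuple[int, int, object]]] = defaultdict(list)
        for iv, payload in intervals:
            per_chrom[iv.chrom].append((iv.start, iv.end, payload))
        self._starts: dict[str, list[int]] = {}
        self._recs: dict[str, list[tuple[int, int, object]]] = {}
        for chrom, recs in per_chrom.items():
            recs.sort(key=lambda r: (r[0], r[1]))
            self._recs[chrom] = recs
            self._starts[chrom] = [r[0] for r in recs]

    def overlapping(self, chrom: str, start: int, end: int) -> list[object]:
        """Payloads of intervals overlapping [start, end) by >=1 bp."""
        recs = self._recs.get(chrom)
        if not recs:
            return []
        hi = bisect_left(self._starts[chrom], end)
        out = []
        for s, e, payload in recs[:hi]:
            if e > start:
                out.append(payload)
        return out
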