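"""ChIP coverage tracks and per-family flank metaprofiles.

Coverage construction collapses duplicate reads (identical chromosome,
5' position and strand), keeps reads with mapq >= 10 and extends each
retained read 300 bp downstream of its 5' end in read orientation.
Profiles report mean per-base coverage per element per million retained
reads, in 50 bp bins over +/-6 kb flanks oriented by element strand:
vector positions run from the 5'-distal bin through the element boundary
to the 3'-distal bin, so reversing every element's strand reverses the
vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .alignments import AlignedRead
from .genome_model import FlankBin, FullLengthElement, GenomicInterval, flank_bins

DEFAULT_EXTENSION = 300
DEFAULT_MAPQ_MIN = 10
DEFAULT_MIN_HEIGHT = 10
DEFAULT_SPAN = 6_000
DEFAULT_BIN_WIDTH = 50


@dataclass
class CoverageTrack:
    """Per-base coverage arrays keyed by chromosome."""

    coverage: dict[str, np.ndarray]
    chrom_lengths: dict[str, int]
    library_total: int
    parameters: dict = field(default_factory=dict)

    def region_sum(self, chrom: str, start: int, end: int) -> float:
        arr = self.coverage.get(chrom)
        if arr is None:
            return 0.0
        s, e = max(start, 0), min(end, len(arr))
        if s >= e:
            return 0.0
        return float(arr[s:e].sum())


@dataclass
class FlankProfile:
    """Per-family mean binned flank density (5'-distal ... 3'-distal)."""

    family: str
    densities: np.ndarray  # length 2 * span / bin_width
    n_elements: int
    library_total: int
    span: int = DEFAULT_SPAN
    bin_width: int = DEFAULT_BIN_WIDTH
    neighbor_flags: Optional[np.ndarray] = None  # bins overlapping other elements


@dataclass
class FlankHeatmap:
    family: str
    matrix: np.ndarray  # elements x bins
    element_ids: list[str]
    library_total: int
    span: int = DEFAULT_SPAN
    bin_width: int = DEFAULT_BIN_WIDTH


def build_coverage(
    alignments: Iterable[AlignedRead],
    chrom_lengths: dict[str, int],
    mapq_min: int = DEFAULT_MAPQ_MIN,
    extension: int = DEFAULT_EXTENSION,
    dedup: bool = True,
) -> CoverageTrack:
    """Directionally-extended, duplicate-collapsed read coverage.

    A plus-strand read with 5' end p covers [p, p+extension); a
    minus-strand read with 5' end q covers [q-extension+1, q+1].
    Extension is truncated at chromosome bounds.
    """
    if extension <= 0:
        raise ValueError("extension must be positive")
    cov = {c: np.zeros(n, dtype=np.int32) for c, n in chrom_lengths.items()}
    seen: set[tuple[str, int, str]] = set()
    retained = 0
    for read in alignments:
        if read.mapq < mapq_min:
            continue
        p5 = read.five_prime
        if dedup:
            key = (read.chrom, p5, read.strand)
            if key in seen:
                continue
            seen.add(key)
        arr = cov.get(read.chrom)
        if arr is None:
            continue
        retained += 1
        if read.strand == "+":
            s, e = p5, p5 + extension
        else:
            s, e = p5 - extension + 1, p5 + 1
        s, e = max(s, 0), min(e, len(arr))
        if s < e:
            arr[s:e] += 1
    return CoverageTrack(
        coverage=cov,
        chrom_lengths=dict(chrom_lengths),
        library_total=retained,
        parameters={"extension": extension, "mapq_min": mapq_min,
                    "dedup": dedup, "threshold": None},
    )


def threshold_coverage(
    track: CoverageTrack, min_height: int = DEFAULT_MIN_HEIGHT
) -> tuple[list[tuple[str, int, int, int]], CoverageTrack]:
    """Maximal intervals with coverage >= min_height, plus a zeroed track.

    Returns ``(regions, thresholded)`` where each region is
    (chrom, start, end, max_height) and the thresholded track zeroes
    every position below min_height.
    """
    regions: list[tuple[str, int, int, int]] = []
    new_cov: dict[str, np.ndarray] = {}
    for chrom in sorted(track.coverage):
        arr = track.coverage[chrom]
        mask = arr >= min_height
        out = np.where(mask, arr, 0)
        new_cov[chrom] = out
        if mask.any():
            edges = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False]))))
            for s, e in zip(edges[::2], edges[1::2]):
                regions.append((chrom, int(s), int(e), int(arr[s:e].max())))
    params = dict(track.parameters)
    params["threshold"] = min_height
    thresholded = CoverageTrack(new_cov, dict(track.chrom_lengths),
                                track.library_total, params)
    return regions, thresholded


def _oriented_positions(n_bins: int) -> dict[tuple[str, int], int]:
    """Map (side, bin_index) -> position in the 2*n_bins oriented vector."""
    pos = {}
    for k in range(n_bins):
        pos[("5prime", k)] = n_bins - 1 - k
        pos[("3prime", k)] = n_bins + k
    return pos


def _element_bin_sums(
    track: CoverageTrack,
    element: FullLengthElement,
    span: int,
    bin_width: int,
) -> tuple[np.ndarray, list[Optional[FlankBin]]]:
    n_bins = span // bin_width
    sums = np.zeros(2 * n_bins)
    placed: list[Optional[FlankBin]] = [None] * (2 * n_bins)
    chrom_len = track.chrom_lengths.get(element.interval.chrom)
    pos = _oriented_positions(n_bins)
    for fb in flank_bins(element, span=span, bin_width=bin_width,
                         chrom_length=chrom_len):
        p = pos[(fb.side, fb.bin_index)]
        placed[p] = fb
        if fb.interval is not None:
            sums[p] = track.region_sum(fb.interval.chrom, fb.interval.start,
                                       fb.interval.end)
    return sums, placed


def aggregate_flank_profile(
    track: CoverageTrack,
    elements: Sequence[FullLengthElement],
    span: int = DEFAULT_SPAN,
    bin_width: int = DEFAULT_BIN_WIDTH,
    family: Optional[str] = None,
    annotated_intervals: Optional[Sequence[GenomicInterval]] = None,
) -> FlankProfile:
    """Aggregate binned flank density over all elements of one family.

    density(bin) = sum of per-base coverage inside the strand-oriented bin
    over all elements / (bin_width * n_elements * library_total / 1e6).

    ``annotated_intervals``, when given, marks bins that overlap any other
    annotated element (the confound is flagged, not masked).
    """
    if not elements:
        raise ValueError("need at least one element")
    if track.library_total <= 0:
        raise ValueError("track has no retained reads")
    fam = family or elements[0].family
    n_bins = span // bin_width
    total = np.zeros(2 * n_bins)
    flags = np.zeros(2 * n_bins, dtype=bool)
    for el in elements:
        sums, placed = _element_bin_sums(track, el, span, bin_width)
        total += sums
        if annotated_intervals is not None:
            for p, fb in enumerate(placed):
                if fb is None or fb.interval is None:
                    continue
                for iv in annotated_intervals:
                    if iv.overlaps(fb.interval) and not (
                        iv.start == el.interval.start and iv.end == el.interval.end
                        and iv.chrom == el.interval.chrom
                    ):
                        flags[p] = True
                        break
    denom = bin_width * len(elements) * track.library_total / 1_000_000
    return FlankProfile(
        family=fam,
        densities=total / denom,
        n_elements=len(elements),
        library_total=track.library_total,
        span=span,
        bin_width=bin_width,
        neighbor_flags=flags if annotated_intervals is not None else None,
    )


def flank_heatmap(
    track: CoverageTrack,
    elements: Sequence[FullLengthElement],
    span: int = DEFAULT_SPAN,
    bin_width: int = DEFAULT_BIN_WIDTH,
    family: Optional[str] = None,
) -> FlankHeatmap:
    """Per-element flank density matrix; column means equal the aggregate."""
    if not elements:
        raise ValueError("need at least one element")
    if track.library_total <= 0:
        raise ValueError("track has no retained reads")
    n_bins = span // bin_width
    mat = np.zeros((len(elements), 2 * n_bins))
    denom = bin_width * track.library_total / 1_000_000
    for i, el in enumerate(elements):
        sums, _ = _element_bin_sums(track, el, span, bin_width)
        mat[i] = sums / denom
    return FlankHeatmap(
        family=family or elements[0].family,
        matrix=mat,
        element_ids=[el.element_id for el in elements],
        library_total=track.library_total,
        span=span,
        bin_width=bin_width,
    )


# ---------------------------------------------------------------------------
# WIG export / import (fixedStep, step=1)


def write_wig(track: CoverageTrack, path: str | Path, name: str = "coverage") -> None:
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{name}"\n')
        for chrom in sorted(track.coverage):
            arr = track.coverage[chrom]
            fh.write(f"fixedStep chrom={chrom} start=1 step=1 span=1\n")
            fh.write("\n".join(str(int(v)) for v in arr))
            fh.write("\n")


def read_wig(path: str | Path, chrom_lengths: dict[str, int],
             library_total: int = 0) -> CoverageTrack:
    cov = {c: np.zeros(n, dtype=np.int32) for c, n in chrom_lengths.items()}
    chrom, offset = None, 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("track"):
                continue
            if line.startswith("fixedStep"):
                kv = dict(tok.split("=") for tok in line.split()[1:])
                chrom = kv["chrom"]
                offset = int(kv["start"]) - 1
                continue
            cov[chrom][offset] = int(line)
            offset += 1
    return CoverageTrack(cov, dict(chrom_lengths), library_total, {})
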