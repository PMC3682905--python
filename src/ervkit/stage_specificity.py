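"""2C-specific gene classification and MT2-LTR proximity enrichment.

Stage expression arrives as reads-per-million (RPM) per gene for the
oocyte, two-cell (2C) and eight-cell (8C) stages; RPKM is RPM divided by
transcript length in kb. A gene is 2C-specific when its 2C RPKM is at
least ``fold`` times both the oocyte and 8C RPKMs (inclusive thresholds)
and clears a small expression floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .genome_model import GeneModel, RepeatElement, nearest_ltr_distance
from .repeat_expression import DEFAULT_PSEUDOCOUNT, fold_change

DEFAULT_FOLD = 4.0
DEFAULT_MIN_RPKM_2C = 0.5
DEFAULT_MAX_DIST = 5_000
DEFAULT_MT2_FAMILIES = frozenset({"MT2", "MT2_Mm", "MT2A", "MT2C"})

STAGES = ("oocyte", "2c", "8c")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric upper-tail enrichment of proximal genes in a set."""

    overlap_count: int
    set_size: int
    background_count: int
    population: int
    percentage: float
    background_fraction: float
    p_value: float


def rpm_to_rpkm(rpm: float, transcript_length_bp: int) -> float:
    if transcript_length_bp <= 0:
        raise ValueError("transcript length must be positive")
    return rpm / (transcript_length_bp / 1_000)


def build_stage_table(df: pd.DataFrame) -> pd.DataFrame:
    """Add rpkm_{oocyte,2c,8c} columns to an RPM stage table."""
    required = ["gene_id", "rpm_oocyte", "rpm_2c", "rpm_8c", "transcript_length"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"stage table missing columns: {missing}")
    out = df.copy()
    for stage in STAGES:
        out[f"rpkm_{stage}"] = out[f"rpm_{stage}"] / (out["transcript_length"] / 1_000)
    return out


def classify_2c_specific(
    table: pd.DataFrame,
    fold: float = DEFAULT_FOLD,
    min_rpkm_2c: float = DEFAULT_MIN_RPKM_2C,
) -> set[str]:
    """Genes with 2C RPKM >= fold x oocyte RPKM and >= fold x 8C RPKM.

    Thresholds are inclusive; the ``min_rpkm_2c`` floor excludes genes
    whose 2C expression is itself negligible.
    """
    if not all(f"rpkm_{s}" in table.columns for s in STAGES):
        table = build_stage_table(table)
    mask = (
        (table["rpkm_2c"] >= fold * table["rpkm_oocyte"])
        & (table["rpkm_2c"] >= fold * table["rpkm_8c"])
        & (table["rpkm_2c"] >= min_rpkm_2c)
    )
    return set(table.loc[mask, "gene_id"])


def upregulated_genes(
    ko_rpkm: Mapping[str, float],
    wt_rpkm: Mapping[str, float],
    fold: float = DEFAULT_FOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> set[str]:
    """Genes whose pseudocounted KO/wt RPKM ratio is >= fold (inclusive)."""
    if set(ko_rpkm) != set(wt_rpkm):
        raise ValueError("KO and wt samples must share one gene universe")
    return {
        gid
        for gid in ko_rpkm
        if fold_change(ko_rpkm[gid], wt_rpkm[gid], pseudocount) >= fold
    }


def overlap_summary(
    two_cell_set: set[str],
    upregulated_sets: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Overlap of the 2C-specific set with each KO-upregulated set.

    Reports one row per KO line plus a "union" row (genes upregulated in
    at least one line) and an "intersection" row (upregulated in all
    lines). Percentages are 100 * |overlap| / |two_cell_set|, rounded
    half-up; raw fractions are kept alongside.
    """
    rows = []
    n2c = len(two_cell_set)

    def add_row(label: str, other: set[str]) -> None:
        overlap = two_cell_set & other
        frac = len(overlap) / n2c if n2c else 0.0
        rows.append({
            "line": label,
            "set_size": len(other),
            "two_cell_size": n2c,
            "overlap": len(overlap),
            "fraction": frac,
            "percentage": _round_half_up(100.0 * frac),
        })

    for label in sorted(upregulated_sets):
        add_row(label, upregulated_sets[label])
    if upregulated_sets:
        union = set.union(*upregulated_sets.values())
        inter = set.intersection(*upregulated_sets.values())
        add_row("union", union)
        add_row("intersection", inter)
    return pd.DataFrame(
        rows,
        columns=["line", "set_size", "two_cell_size", "overlap",
                 "fraction", "percentage"],
    )


def proximity_enrichment(
    gene_set: Iterable[str],
    all_genes: Sequence[GeneModel],
    elements: Sequence[RepeatElement],
    families: frozenset[str] | set[str] = DEFAULT_MT2_FAMILIES,
    max_dist: int = DEFAULT_MAX_DIST,
    distances: Optional[Mapping[str, Optional[int]]] = None,
) -> EnrichmentResult:
    """Enrichment of TSS-proximal-to-LTR genes inside a gene set.

    A gene is proximal when its TSS lies inside a listed element or
    within ``max_dist`` bp of one (inclusive). The p-value is the
    hypergeometric upper tail P(X >= k) with population N = |all_genes|,
    K = proximal genes overall, n = |gene_set| draws. ``distances`` may
    supply precomputed TSS-to-LTR distances keyed by gene id.
    """
    gene_ids = set(gene_set)
    if distances is None:
        distances = {
            g.gene_id: nearest_ltr_distance(g, families, elements) for g in all_genes
        }
    proximal = {
        gid for gid, d in distances.items() if d is not None and d <= max_dist
    }
    universe = {g.gene_id for g in all_genes}
    unknown = gene_ids - universe
    if unknown:
        raise ValueError(f"gene_set not contained in all_genes: {sorted(unknown)[:5]}")
    N = len(universe)
    K = len(proximal & universe)
    n = len(gene_ids)
    k = len(gene_ids & proximal)
    if n == 0:
        p = 1.0
    else:
        p = float(hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(
        overlap_count=k,
        set_size=n,
        background_count=K,
        population=N,
        percentage=100.0 * k / n if n else 0.0,
        background_fraction=K / N if N else 0.0,
        p_value=min(max(p, 0.0), 1.0),
    )
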