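"""Cis-target assignment: genes within a 10 kb window of a lncRNA.

The gap between two features on the same chromosome is the number of
bases strictly between their spans (1-based inclusive coordinates):
``gap = max(0, max(startA, startB) - min(endA, endB) - 1)``; overlapping
spans have gap 0. A pair is emitted iff the gap is <= the window
(inclusive, default 10 000 bp). Strand is ignored for eligibility and
only annotates the lncRNA's position relative to the gene on the gene's
strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .annotation import Interval

__all__ = ["CisPair", "gap_bp", "assign_cis_targets", "de_cis_network"]


@dataclass(frozen=True)
class CisPair:
    lncrna_id: str
    gene_id: str
    gap: int
    relpos: str  # upstream | downstream | overlapping (w.r.t. the gene's strand)


def gap_bp(a: Interval, b: Interval) -> int:
    """Bases strictly between two spans; 0 if they touch or overlap."""
    return max(0, max(a.start, b.start) - min(a.end, b.end) - 1)


def _relpos(lnc: Interval, gene: Interval) -> str:
    if lnc.start <= gene.end and gene.start <= lnc.end:
        return "overlapping"
    before = lnc.end < gene.start  # lncRNA on the lower-coordinate side
    if gene.strand == "-":
        before = not before
    return "upstream" if before else "downstream"


def assign_cis_targets(
    lncrnas: Sequence[Interval],
    genes: Sequence[Interval],
    window_bp: int = 10_000,
) -> list[CisPair]:
    """All (lncRNA, gene) pairs on the same chromosome with gap <= window.

    Uses an interval tree of window-padded gene spans per chromosome;
    output is sorted by (lncRNA id, gap, gene id) with each pair emitted
    once. lncRNA chromosomes matching no gene chromosome produce a single
    warning with a count, not an error.
    """
    trees: dict[str, IntervalTree] = {}
    by_id: dict[str, Interval] = {}
    for g in genes:
        # half-open tree coordinates; padding by window+1 makes tree overlap
        # equivalent to gap <= window
        trees.setdefault(g.chrom, IntervalTree()).addi(
            g.start - window_bp - 1, g.end + window_bp + 2, g.id
        )
        by_id[g.id] = g

    pairs: list[CisPair] = []
    n_unmatched = 0
    for lnc in lncrnas:
        tree = trees.get(lnc.chrom)
        if tree is None:
            n_unmatched += 1
            continue
        seen: set[str] = set()
        for hit in tree.overlap(lnc.start, lnc.end + 1):
            gid = hit.data
            if gid in seen or gid == lnc.id:
                continue
            seen.add(gid)
            gene = by_id[gid]
            gap = gap_bp(lnc, gene)
            if gap <= window_bp:
                pairs.append(CisPair(lnc.id, gid, gap, _relpos(lnc, gene)))
    if n_unmatched:
        warnings.warn(
            f"{n_unmatched} lncRNA(s) on chromosomes with no genes", stacklevel=2
        )
    pairs.sort(key=lambda p: (p.lncrna_id, p.gap, p.gene_id))
    return pairs


def de_cis_network(
    cis_pairs: Iterable[CisPair],
    de_lnc: dict[str, list[str]],
    de_mrna: dict[str, list[str]],
) -> list[dict[str, object]]:
    """Restrict cis pairs to edges where both endpoints are significant.

    ``de_lnc`` / ``de_mrna`` are the up/down/not_de partitions from
    :func:`cernaforge.expression.filter_de`. Each edge carries the
    up/down direction of both endpoints as categorical attributes.
    """
    lnc_dir = {f: d for d in ("up", "down") for f in de_lnc.get(d, [])}
    gene_dir = {f: d for d in ("up", "down") for f in de_mrna.get(d, [])}
    edges = []
    for p in cis_pairs:
        if p.lncrna_id in lnc_dir and p.gene_id in gene_dir:
            edges.append(
                {
                    "lncrna_id": p.lncrna_id,
                    "gene_id": p.gene_id,
                    "gap_bp": p.gap,
                    "relpos": p.relpos,
                    "lncrna_direction": lnc_dir[p.lncrna_id],
                    "gene_direction": gene_dir[p.gene_id],
                }
            )
    return edges


def write_cis_pairs(pairs: Iterable[CisPair], path: str | Path) -> None:
    pd.DataFrame(
        [(p.lncrna_id, p.gene_id, p.gap, p.relpos) for p in pairs],
        columns=["lncrna_id", "gene_id", "gap_bp", "relpos"],
    ).to_csv(path, sep="\t", index=False)
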