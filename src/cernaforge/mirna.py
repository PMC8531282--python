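"""miRNA-target edges: imported tables and canonical seed-site prediction.

Seed matching follows the canonical site vocabulary: with the miRNA given
5'->3', a 7mer-m8 site is an exact match of the reverse complement of
miRNA positions 2-8 on the target sense strand; 6mer uses positions 2-7;
7mer-A1 is the 6mer site followed by an A opposite position 1; 8mer is
the 7mer-m8 site followed by that A. U and T are equivalent on input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import SchemaError

TARGET_CLASSES = ("mRNA", "lncRNA", "circRNA")
SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")
# evidence strength, weakest first; canonical site hierarchy
EVIDENCE_ORDER = ("imported", "6mer", "7mer-A1", "7mer-m8", "8mer")

_RC = str.maketrans("ACGT", "TGCA")


@dataclass
class TargetEdge:
    mirna_id: str
    target_id: str
    target_class: str
    evidence: str = "imported"
    positions: list[int] = field(default_factory=list)

    def key(self) -> tuple[str, str]:
        return (self.mirna_id, self.target_id)


def _clean_seq(seq: str, name: str, alphabet: str) -> str:
    s = seq.upper().replace("U", "T")
    for i, ch in enumerate(s):
        if ch not in alphabet:
            raise SchemaError(
                f"non-IUPAC character {ch!r} at position {i} in sequence {name}"
            )
    return s


def _site_patterns(mirna_dna: str, site_types: Iterable[str]) -> list[tuple[str, str]]:
    """(evidence, pattern) for each requested site type, strongest first."""
    rc7 = mirna_dna[1:8].translate(_RC)[::-1]  # positions 2-8
    rc6 = mirna_dna[1:7].translate(_RC)[::-1]  # positions 2-7
    table = {
        "8mer": rc7 + "A",
        "7mer-m8": rc7,
        "7mer-A1": rc6 + "A",
        "6mer": rc6,
    }
    unknown = set(site_types) - set(table)
    if unknown:
        raise SchemaError(f"unknown site type(s): {sorted(unknown)}")
    order = [t for t in ("8mer", "7mer-m8", "7mer-A1", "6mer") if t in set(site_types)]
    return [(t, table[t]) for t in order]


def seed_match(
    mirna_seqs: Mapping[str, str],
    target_seqs: Mapping[str, str],
    site_types: Iterable[str] = ("7mer-m8",),
    target_classes: Mapping[str, str] | str = "mRNA",
) -> list[TargetEdge]:
    """Scan every target for seed sites of every miRNA.

    All non-overlapping occurrences are reported left to right; when a
    pair has sites of several types, the edge carries the strongest
    site's evidence label. ``target_classes`` is either one class for all
    targets or a per-target mapping.
    """
    edges: list[TargetEdge] = []
    targets = {
        t: _clean_seq(target_seqs[t], t, "ACGTN") for t in sorted(target_seqs)
    }
    for m in sorted(mirna_seqs):
        mseq = _clean_seq(mirna_seqs[m], m, "ACGT")
        if len(mseq) < 8:
            raise SchemaError(f"miRNA {m} shorter than 8 nt")
        patterns = _site_patterns(mseq, site_types)
        for t, tseq in targets.items():
            positions: list[int] = []
            evidence: str | None = None
            blocked: list[tuple[int, int]] = []
            for ev, pat in patterns:  # strongest type claims sites first
                start = 0
                while True:
                    i = tseq.find(pat, start)
                    if i < 0:
                        break
                    span = (i, i + len(pat) - 1)
                    if all(span[1] < s or span[0] > e for s, e in blocked):
                        positions.append(i)
                        blocked.append(span)
                        if evidence is None:
                            evidence = ev
                        start = i + len(pat)
                    else:
                        start = i + 1
            if positions:
                cls = (
                    target_classes
                    if isinstance(target_classes, str)
                    else target_classes[t]
                )
                edges.append(TargetEdge(m, t, cls, evidence, sorted(positions)))
    return edges


def load_target_table(path: str | Path) -> list[TargetEdge]:
    """Read a (mirna_id, target_id, target_class) TSV; deduplicated, imported."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"mirna_id", "target_id", "target_class"}
    if not need.issubset(df.columns):
        raise SchemaError(f"target table {path} needs columns {sorted(need)}")
    edges: dict[tuple[str, str], TargetEdge] = {}
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        if row.target_class not in TARGET_CLASSES:
            raise SchemaError(
                f"{path}:{lineno}: unknown target class {row.target_class!r} "
                f"(expected one of {TARGET_CLASSES})"
            )
        edges.setdefault(
            (row.mirna_id, row.target_id),
            TargetEdge(row.mirna_id, row.target_id, row.target_class),
        )
    return [edges[k] for k in sorted(edges)]


def merge_edges(*edge_lists: Sequence[TargetEdge]) -> list[TargetEdge]:
    """Union of edge lists, keeping the strongest evidence per pair.

    Predicted site evidence outranks imported; among site types the
    canonical hierarchy 8mer > 7mer-m8 > 7mer-A1 > 6mer applies. Site
    positions from the winning record are kept.
    """
    rank = {ev: i for i, ev in enumerate(EVIDENCE_ORDER)}
    best: dict[tuple[str, str], TargetEdge] = {}
    for edges in edge_lists:
        for e in edges:
            cur = best.get(e.key())
            if cur is None or rank[e.evidence] > rank[cur.evidence]:
                best[e.key()] = e
    return [best[k] for k in sorted(best)]


def edges_to_frame(edges: Sequence[TargetEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (e.mirna_id, e.target_id, e.target_class, e.evidence,
             len(e.positions), ",".join(map(str, e.positions)))
            for e in edges
        ],
        columns=["mirna_id", "target_id", "target_class", "evidence",
                 "n_sites", "positions"],
    )
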