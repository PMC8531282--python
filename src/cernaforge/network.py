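"""ceRNA network inference and export.

A ceRNA triad (regulator, miRNA, mRNA) — the regulator being a lncRNA or
circRNA — is emitted when, over the pooled samples:

* the miRNA is a predicted/imported target partner of both the regulator
  and the mRNA, with Spearman correlation < -0.7 (strict) against each
  on log2(expression + 1);
* the regulator and the mRNA have Pearson correlation > 0.9 (strict);
* the two share significantly more targeting miRNAs than chance under
  the upper-tail hypergeometric sponge test (p < 0.05) within the
  DE-miRNA universe.

All participating features are expected to be differentially expressed;
the caller restricts the expression matrices and edge set accordingly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core import DesignError, DomainError, SchemaError
from .enrichment import HypergeomResult, hypergeom_sf
from .mirna import TargetEdge

__all__ = [
    "CorrEdge",
    "CeRNATriad",
    "negative_pairs",
    "coexpressed_pairs",
    "sponge_test",
    "build_triads",
    "export_network",
    "read_network",
]


@dataclass(frozen=True)
class CorrEdge:
    id_a: str
    id_b: str
    coefficient: float
    method: str  # SCC | PCC
    n_samples: int


@dataclass
class CeRNATriad:
    regulator_id: str
    mirna_id: str
    mrna_id: str
    scc_mir_regulator: float
    scc_mir_mrna: float
    pcc_regulator_mrna: float
    sponge_k: int
    sponge_K: int
    sponge_n: int
    sponge_N: int
    sponge_p: float
    direction_consistent: bool | None = None


def _aligned(a: pd.DataFrame, b: pd.DataFrame) -> list[str]:
    shared = [s for s in a.columns if s in set(b.columns)]
    if len(shared) < 3:
        raise DesignError(
            f"correlation needs >= 3 shared samples, found {len(shared)}"
        )
    return shared


def _corr_pairs(
    expr_a: pd.DataFrame,
    expr_b: pd.DataFrame,
    pairs: Iterable[tuple[str, str]],
    method: str,
    keep,
    log_transform: bool,
) -> list[CorrEdge]:
    samples = _aligned(expr_a, expr_b)
    xa = np.log2(expr_a[samples] + 1.0) if log_transform else expr_a[samples]
    xb = np.log2(expr_b[samples] + 1.0) if log_transform else expr_b[samples]
    out: list[CorrEdge] = []
    skipped = 0
    for a, b in pairs:
        if a not in xa.index or b not in xb.index:
            continue
        va = xa.loc[a].to_numpy(dtype=float)
        vb = xb.loc[b].to_numpy(dtype=float)
        if np.ptp(va) == 0 or np.ptp(vb) == 0:
            skipped += 1
            continue
        if method == "SCC":
            r = float(stats.spearmanr(va, vb).statistic)
        else:
            r = float(stats.pearsonr(va, vb).statistic)
        if keep(r):
            out.append(CorrEdge(a, b, r, method, len(samples)))
    if skipped:
        warnings.warn(
            f"{skipped} pair(s) skipped: constant expression vector", stacklevel=3
        )
    return out


def negative_pairs(
    expr_mirna: pd.DataFrame,
    expr_target: pd.DataFrame,
    target_edges: Sequence[TargetEdge],
    scc_threshold: float = -0.7,
    log_transform: bool = True,
) -> list[CorrEdge]:
    """Anti-correlated miRNA-target pairs among the target edges.

    Spearman rank correlation (average ranks on ties) on log2(expr+1);
    a pair is kept iff it is a target edge and SCC < threshold, strictly.
    """
    pairs = sorted({(e.mirna_id, e.target_id) for e in target_edges})
    return _corr_pairs(
        expr_mirna, expr_target, pairs, "SCC",
        keep=lambda r: r < scc_threshold, log_transform=log_transform,
    )


def coexpressed_pairs(
    expr_regulator: pd.DataFrame,
    expr_mrna: pd.DataFrame,
    candidate_pairs: Iterable[tuple[str, str]] | None = None,
    pcc_threshold: float = 0.9,
    log_transform: bool = True,
) -> list[CorrEdge]:
    """Positively co-expressed regulator-mRNA pairs (PCC > threshold, strict)."""
    if candidate_pairs is None:
        candidate_pairs = [
            (a, b)
            for a in expr_regulator.index
            for b in expr_mrna.index
            if a != b
        ]
    return _corr_pairs(
        expr_regulator, expr_mrna, sorted(set(candidate_pairs)), "PCC",
        keep=lambda r: r > pcc_threshold, log_transform=log_transform,
    )


def sponge_test(
    regulator_id: str,
    mrna_id: str,
    target_edges: Sequence[TargetEdge],
    mirna_universe: Iterable[str],
) -> HypergeomResult:
    """Hypergeometric test of shared targeting miRNAs between two transcripts.

    N is the miRNA universe size, K the miRNAs targeting the regulator,
    n the miRNAs targeting the mRNA, k the shared ones; p = P(X >= k).
    """
    universe = set(mirna_universe)
    if not universe:
        raise DomainError("empty miRNA universe")
    t_reg: set[str] = set()
    t_mrna: set[str] = set()
    for e in target_edges:
        if e.mirna_id not in universe:
            continue
        if e.target_id == regulator_id:
            t_reg.add(e.mirna_id)
        if e.target_id == mrna_id:
            t_mrna.add(e.mirna_id)
    N, K, n = len(universe), len(t_reg), len(t_mrna)
    k = len(t_reg & t_mrna)
    return HypergeomResult(
        term_id=f"{regulator_id}~{mrna_id}",
        term_name="shared miRNA sponges",
        category="sponge",
        k=k, n=n, K=K, N=N,
        p=hypergeom_sf(k, N, K, n),
    )


def build_triads(
    neg_edges: Sequence[CorrEdge],
    coexp_edges: Sequence[CorrEdge],
    target_edges: Sequence[TargetEdge],
    mirna_universe: Iterable[str],
    p_threshold: float = 0.05,
    directions: Mapping[str, str] | None = None,
) -> list[CeRNATriad]:
    """Assemble triads passing all three gates.

    For every co-expressed (regulator, mRNA) pair with sponge p <
    threshold, one triad row is emitted per miRNA that is anti-correlated
    with both members. Rows are ordered by (regulator, mRNA, miRNA).
    ``directions`` (feature -> up/down) fills the descriptive
    ``direction_consistent`` flag: regulator and mRNA moving together,
    opposite to the miRNA.
    """
    universe = set(mirna_universe)
    neg = {(e.id_a, e.id_b): e.coefficient for e in neg_edges}
    targeted: dict[str, set[str]] = {}
    for e in target_edges:
        if e.mirna_id in universe:
            targeted.setdefault(e.target_id, set()).add(e.mirna_id)

    triads: list[CeRNATriad] = []
    for ce in sorted(coexp_edges, key=lambda e: (e.id_a, e.id_b)):
        reg, g = ce.id_a, ce.id_b
        shared = sorted(targeted.get(reg, set()) & targeted.get(g, set()))
        mirs = [m for m in shared if (m, reg) in neg and (m, g) in neg]
        if not mirs:
            continue
        hg = sponge_test(reg, g, target_edges, universe)
        if not hg.p < p_threshold:
            continue
        for m in mirs:
            consistent = None
            if directions is not None:
                dr, dm, dg = (directions.get(x) for x in (reg, m, g))
                if None not in (dr, dm, dg):
                    consistent = (dr == dg) and (dr != dm)
            triads.append(
                CeRNATriad(
                    regulator_id=reg, mirna_id=m, mrna_id=g,
                    scc_mir_regulator=neg[(m, reg)],
                    scc_mir_mrna=neg[(m, g)],
                    pcc_regulator_mrna=ce.coefficient,
                    sponge_k=hg.k, sponge_K=hg.K, sponge_n=hg.n,
                    sponge_N=hg.N, sponge_p=hg.p,
                    direction_consistent=consistent,
                )
            )
    return triads


def triads_to_frame(triads: Sequence[CeRNATriad]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (t.regulator_id, t.mirna_id, t.mrna_id, t.scc_mir_regulator,
             t.scc_mir_mrna, t.pcc_regulator_mrna, t.sponge_k, t.sponge_K,
             t.sponge_n, t.sponge_N, t.sponge_p, t.direction_consistent)
            for t in triads
        ],
        columns=["regulator_id", "mirna_id", "mrna_id", "scc_mir_regulator",
                 "scc_mir_mrna", "pcc_regulator_mrna", "sponge_k", "sponge_K",
                 "sponge_n", "sponge_N", "sponge_p", "direction_consistent"],
    )


# ---------------------------------------------------------------------------
# network assembly and export
# ---------------------------------------------------------------------------

RELATIONS = ("targets", "cis", "coexpressed", "sponges")


def triads_to_network(
    triads: Sequence[CeRNATriad],
    node_attrs: Mapping[str, Mapping[str, str]] | None = None,
) -> tuple[dict[str, dict], list[dict]]:
    """Nodes and typed edges for a set of triads."""
    nodes: dict[str, dict] = {}
    edges: list[dict] = []
    seen: set[tuple[str, str, str]] = set()

    def add_node(nid: str, cls: str) -> None:
        if nid not in nodes:
            attrs = dict(node_attrs.get(nid, {})) if node_attrs else {}
            attrs.setdefault("node_class", cls)
            nodes[nid] = attrs

    def add_edge(u: str, rel: str, v: str, **attrs) -> None:
        if (u, rel, v) not in seen:
            seen.add((u, rel, v))
            edges.append({"source": u, "target": v, "relation": rel, **attrs})

    for t in triads:
        add_node(t.regulator_id, "regulator")
        add_node(t.mirna_id, "miRNA")
        add_node(t.mrna_id, "mRNA")
        add_edge(t.mirna_id, "targets", t.regulator_id,
                 scc=t.scc_mir_regulator)
        add_edge(t.mirna_id, "targets", t.mrna_id, scc=t.scc_mir_mrna)
        add_edge(t.regulator_id, "coexpressed", t.mrna_id,
                 pcc=t.pcc_regulator_mrna)
        add_edge(t.regulator_id, "sponges", t.mrna_id, p=t.sponge_p)
    return nodes, edges


def to_graph(nodes: Mapping[str, dict], edges: Sequence[dict]) -> nx.MultiDiGraph:
    g = nx.MultiDiGraph()
    for nid in sorted(nodes):
        g.add_node(nid, **nodes[nid])
    for e in edges:
        attrs = {k: v for k, v in e.items() if k not in ("source", "target")}
        g.add_edge(e["source"], e["target"], **attrs)
    return g


def export_network(
    nodes: Mapping[str, dict],
    edges: Sequence[dict],
    path: str | Path,
    fmt: str,
) -> Path:
    """Write the network as SIF, GraphML or a flat edge TSV."""
    path = Path(path)
    order = sorted(edges, key=lambda e: (e["source"], e["relation"], e["target"]))
    if fmt == "SIF":
        lines = [f'{e["source"]}\t{e["relation"]}\t{e["target"]}' for e in order]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "GraphML":
        nx.write_graphml(to_graph(nodes, edges), str(path))
    elif fmt == "TSV":
        keys = sorted({k for e in edges for k in e} - {"source", "target", "relation"})
        rows = [
            [e["source"], e["relation"], e["target"]] + [e.get(k, "") for k in keys]
            for e in order
        ]
        pd.DataFrame(rows, columns=["source", "relation", "target"] + keys).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise SchemaError(f"unknown network format {fmt!r} (SIF, GraphML, TSV)")
    return path


def read_network(path: str | Path, fmt: str) -> tuple[dict[str, dict], list[dict]]:
    """Re-import a written network (inverse of :func:`export_network`)."""
    path = Path(path)
    if fmt == "SIF":
        nodes: dict[str, dict] = {}
        edges = []
        text = path.read_text()
        for line in text.splitlines():
            if not line.strip():
                continue
            u, rel, v = line.split("\t")
            nodes.setdefault(u, {})
            nodes.setdefault(v, {})
            edges.append({"source": u, "target": v, "relation": rel})
        return nodes, edges
    if fmt == "GraphML":
        g = nx.read_graphml(str(path), force_multigraph=True)
        nodes = {n: dict(g.nodes[n]) for n in g.nodes}
        edges = [
            {"source": u, "target": v, **d} for u, v, d in g.edges(data=True)
        ]
        return nodes, edges
    if fmt == "TSV":
        df = pd.read_csv(path, sep="\t")
        nodes = {}
        edges = []
        for row in df.to_dict("records"):
            nodes.setdefault(str(row["source"]), {})
            nodes.setdefault(str(row["target"]), {})
            edges.append(
                {"source": str(row["source"]), "target": str(row["target"]),
                 "relation": str(row["relation"]),
                 **{k: v for k, v in row.items()
                    if k not in ("source", "target", "relation") and v == v and v != ""}}
            )
        return nodes, edges
    raise SchemaError(f"unknown network format {fmt!r} (SIF, GraphML, TSV)")
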