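"""Correlation gates, sponge test, triad assembly and network export."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cernaforge import (
    DomainError,
    build_triads,
    coexpressed_pairs,
    export_network,
    negative_pairs,
    read_network,
    sponge_test,
)
from cernaforge.mirna import TargetEdge
from cernaforge.network import CorrEdge, triads_to_network


def expr_row(name: str, values) -> pd.DataFrame:
    return pd.DataFrame([values], index=[name],
                        columns=[f"s{i}" for i in range(len(values))])


EDGE = [TargetEdge("m", "t", "mRNA")]


class TestNegativePairs:
    def test_perfect_rank_reversal_kept(self):
        mir = expr_row("m", [1, 2, 3, 4, 5, 6, 7, 8])
        tgt = expr_row("t", [8, 7, 6, 5, 4, 3, 2, 1])
        (e,) = negative_pairs(mir, tgt, EDGE, log_transform=False)
        assert e.coefficient == pytest.approx(-1.0)

    def test_threshold_is_strict(self):
        """A pair whose SCC equals the threshold exactly is dropped."""
        mir = expr_row("m", [1, 2, 3, 4, 5])
        tgt = expr_row("t", [5, 3, 2, 4, 1])
        scc = stats.spearmanr(mir.iloc[0], tgt.iloc[0]).statistic
        assert scc == pytest.approx(-0.7)
        assert negative_pairs(mir, tgt, EDGE, scc_threshold=scc,
                              log_transform=False) == []
        kept = negative_pairs(mir, tgt, EDGE, scc_threshold=scc + 1e-9,
                              log_transform=False)
        assert len(kept) == 1

    def test_average_ranks_on_ties(self):
        mir = expr_row("m", [1, 2, 2, 3])
        tgt = expr_row("t", [3, 2, 2, 1])
        (e,) = negative_pairs(mir, tgt, EDGE, log_transform=False)
        assert e.coefficient == pytest.approx(-1.0)

    def test_non_target_pairs_ignored(self):
        mir = expr_row("m", [1, 2, 3, 4])
        tgt = expr_row("x", [4, 3, 2, 1])
        assert negative_pairs(mir, tgt, EDGE, log_transform=False) == []

    def test_constant_vector_warns_and_skips(self):
        mir = expr_row("m", [2, 2, 2, 2])
        tgt = expr_row("t", [4, 3, 2, 1])
        with pytest.warns(UserWarning, match="constant"):
            assert negative_pairs(mir, tgt, EDGE, log_transform=False) == []

    def test_too_few_shared_samples(self):
        from cernaforge import DesignError

        with pytest.raises(DesignError, match="3"):
            negative_pairs(expr_row("m", [1, 2]), expr_row("t", [2, 1]), EDGE)


class TestCoexpressedPairs:
    def test_identical_vectors_kept(self):
        a = expr_row("l", [1, 5, 2, 8])
        b = expr_row("g", [1, 5, 2, 8])
        (e,) = coexpressed_pairs(a, b, log_transform=False)
        assert e.coefficient == pytest.approx(1.0)

    def test_threshold_is_strict(self):
        rng = np.random.default_rng(3)
        x = rng.random(8)
        y = x + 0.3 * rng.random(8)
        a, b = expr_row("l", x), expr_row("g", y)
        r = stats.pearsonr(x, y).statistic
        assert coexpressed_pairs(a, b, pcc_threshold=r, log_transform=False) == []
        assert len(coexpressed_pairs(a, b, pcc_threshold=r - 1e-9,
                                     log_transform=False)) == 1

    def test_anticorrelated_dropped(self):
        a = expr_row("l", [1, 2, 3, 4])
        b = expr_row("g", [9, 7, 5, 3][::-1])
        a2 = expr_row("g", list(reversed([1, 2, 3, 4])))
        assert coexpressed_pairs(a, a2, log_transform=False) == []


def sponge_oracle(k: int, N: int, K: int, n: int) -> float:
    """Exhaustive draw enumeration: fraction of n-subsets sharing >= k."""
    universe = list(range(N))
    hits = sum(
        1 for draw in combinations(universe, n) if len(set(draw) & set(range(K))) >= k
    )
    from math import comb

    return hits / comb(N, n)


class TestSpongeTest:
    def edges(self, reg_mirs, mrna_mirs):
        out = [TargetEdge(m, "L", "lncRNA") for m in reg_mirs]
        out += [TargetEdge(m, "G", "mRNA") for m in mrna_mirs]
        return out

    def test_counts_and_p(self):
        universe = [f"m{i}" for i in range(10)]
        shared = universe[:5]
        hg = sponge_test("L", "G", self.edges(shared, shared), universe)
        assert (hg.k, hg.K, hg.n, hg.N) == (5, 5, 5, 10)
        assert hg.p == pytest.approx(1 / 252, rel=1e-12)

    def test_partial_overlap(self):
        universe = [f"m{i}" for i in range(10)]
        hg = sponge_test(
            "L", "G", self.edges(universe[:4], universe[1:6]), universe
        )
        assert (hg.k, hg.K, hg.n) == (3, 4, 5)
        assert hg.p == pytest.approx(66 / 252, rel=1e-12)

    def test_no_shared_mirnas_never_significant(self):
        universe = [f"m{i}" for i in range(10)]
        hg = sponge_test("L", "G", self.edges(universe[:3], universe[5:8]), universe)
        assert hg.k == 0 and hg.p == 1.0

    def test_empty_universe_rejected(self):
        with pytest.raises(DomainError):
            sponge_test("L", "G", [], [])

    def test_matches_exhaustive_subset_enumeration(self):
        rng = np.random.default_rng(43)
        for _ in range(25):
            N = int(rng.integers(2, 13))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            universe = [f"m{i}" for i in range(N)]
            edges = self.edges(universe[:K], universe[:n])
            k = min(K, n)
            hg = sponge_test("L", "G", edges, universe)
            assert hg.p == pytest.approx(sponge_oracle(k, N, K, n), rel=1e-10)


class TestBuildTriads:
    UNIVERSE = [f"m{i}" for i in range(10)]

    def make_edges(self):
        edges = [TargetEdge(m, "L", "lncRNA") for m in self.UNIVERSE[:5]]
        edges += [TargetEdge(m, "G", "mRNA") for m in self.UNIVERSE[:5]]
        return edges

    def test_qualifying_triad_emitted_per_mirna(self):
        neg = [
            CorrEdge("m0", "L", -0.9, "SCC", 8), CorrEdge("m0", "G", -0.8, "SCC", 8),
            CorrEdge("m1", "L", -0.95, "SCC", 8), CorrEdge("m1", "G", -0.85, "SCC", 8),
        ]
        coexp = [CorrEdge("L", "G", 0.95, "PCC", 8)]
        triads = build_triads(
            neg, coexp, self.make_edges(), self.UNIVERSE,
            directions={"L": "up", "G": "up", "m0": "down", "m1": "up"},
        )
        assert [(t.regulator_id, t.mirna_id, t.mrna_id) for t in triads] == [
            ("L", "m0", "G"), ("L", "m1", "G"),
        ]
        assert triads[0].direction_consistent is True
        assert triads[1].direction_consistent is False
        assert all(t.sponge_p < 0.05 for t in triads)

    def test_failed_sponge_gate_excludes_pair(self):
        # only one shared miRNA in a universe of 10: p = 1 - C(9,1)... > 0.05
        edges = [TargetEdge("m0", "L", "lncRNA"), TargetEdge("m0", "G", "mRNA")]
        neg = [CorrEdge("m0", "L", -0.9, "SCC", 8), CorrEdge("m0", "G", -0.9, "SCC", 8)]
        coexp = [CorrEdge("L", "G", 0.95, "PCC", 8)]
        assert build_triads(neg, coexp, edges, self.UNIVERSE) == []

    def test_missing_negative_edge_excludes_mirna(self):
        neg = [CorrEdge("m0", "L", -0.9, "SCC", 8)]  # no (m0, G) edge
        coexp = [CorrEdge("L", "G", 0.95, "PCC", 8)]
        assert build_triads(neg, coexp, self.make_edges(), self.UNIVERSE) == []


class TestExport:
    def triad_network(self):
        from cernaforge.network import CeRNATriad

        t = CeRNATriad("L", "m", "G", -0.9, -0.8, 0.95, 3, 3, 3, 10, 0.008, True)
        return triads_to_network([t])

    def test_sif_stable_three_node_triad(self, tmp_path):
        nodes, edges = self.triad_network()
        p = export_network(nodes, edges, tmp_path / "n.sif", "SIF")
        lines = p.read_text().splitlines()
        assert lines == sorted(lines)
        assert "m\ttargets\tL" in lines and "L\tsponges\tG" in lines
        assert len(lines) == 4

    def test_graphml_round_trip_lossless(self, tmp_path):
        nodes, edges = self.triad_network()
        for nid in nodes:
            nodes[nid]["direction"] = "up"
        p = export_network(nodes, edges, tmp_path / "n.graphml", "GraphML")
        nodes2, edges2 = read_network(p, "GraphML")
        assert nodes2 == nodes

        def norm(es):
            return sorted(
                (e["source"], e["target"], e["relation"],
                 tuple(sorted((k, v) for k, v in e.items()
                              if k not in ("source", "target", "relation"))))
                for e in es
            )

        assert norm(edges2) == norm(edges)

    def test_tsv_round_trip(self, tmp_path):
        nodes, edges = self.triad_network()
        p = export_network(nodes, edges, tmp_path / "n.tsv", "TSV")
        _nodes2, edges2 = read_network(p, "TSV")
        assert {(e["source"], e["relation"], e["target"]) for e in edges2} == {
            (e["source"], e["relation"], e["target"]) for e in edges
        }

    def test_empty_network_valid(self, tmp_path):
        for fmt, name in (("SIF", "e.sif"), ("GraphML", "e.graphml"), ("TSV", "e.tsv")):
            p = export_network({}, [], tmp_path / name, fmt)
            nodes, edges = read_network(p, fmt)
            assert nodes == {} and edges == []

    def test_unknown_format_rejected(self, tmp_path):
        from cernaforge import SchemaError

        with pytest.raises(SchemaError, match="xml"):
            export_network({}, [], tmp_path / "x", "xml")
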