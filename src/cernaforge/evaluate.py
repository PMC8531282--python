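"""Planted-truth benchmarks for the synthetic study.

These routines re-run the analysis on generated data and score it
against the generator's truth ledger: DE sensitivity/FDR, type-I error
of the exact NB test on null data, cis-window oracle agreement, ceRNA
triad recovery, and a permutation null for false triads. They are what
the acceptance checks and the run report's recovery block are built on.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from . import network as net
from .cis import assign_cis_targets
from .core import CountMatrix
from .expression import cpm_normalize, exact_nb_test, filter_de, fpkm_normalize
from .mirna import TargetEdge
from .synthetic import SimConfig, SimulatedStudy


def type_i_error_rate(
    n_features: int = 2000,
    phi: float = 0.1,
    n_per_group: int = 4,
    seed: int = 11,
    alpha: float = 0.05,
) -> tuple[float, int]:
    """Fraction of null NB features with p < alpha under the exact test."""
    rng = np.random.default_rng(seed)
    n_s = 2 * n_per_group
    mu = np.exp(rng.normal(5, 1, size=n_features))[:, None] * np.ones(n_s)
    lam = rng.gamma(1.0 / phi, mu * phi) if phi > 0 else mu
    counts = rng.poisson(lam)
    samples = [f"A_{i}" for i in range(n_per_group)] + [
        f"B_{i}" for i in range(n_per_group)
    ]
    cm = CountMatrix(
        pd.DataFrame(counts, columns=samples,
                     index=[f"F{i}" for i in range(n_features)]),
        {s: s[0] for s in samples},
        ("A", "B"),
    )
    res = exact_nb_test(cm)
    return float((res["pvalue"] < alpha).mean()), n_features


def de_recovery(
    study: SimulatedStudy, rna_class: str = "mRNA"
) -> dict[str, float | int]:
    """Sensitivity and empirical FDR of the DE call against planted truth."""
    cm = study.counts[rna_class]
    _ann, part = filter_de(exact_nb_test(cm))
    called = set(part["up"]) | set(part["down"])
    planted = {
        f for f in study.truth.de_features if f in set(cm.values.index)
    }
    tp = len(called & planted)
    return {
        "sensitivity": tp / len(planted) if planted else float("nan"),
        "fdr": (len(called) - tp) / len(called) if called else 0.0,
        "planted": len(planted),
        "called": len(called),
    }


def cis_oracle_mismatches(n_annotations: int = 50, seed: int = 23) -> tuple[int, int]:
    """Interval-tree assignment vs brute-force all-pairs gaps.

    Returns (number of annotations with any disagreement, annotations checked).
    """
    from .annotation import Interval

    rng = np.random.default_rng(seed)
    bad = 0
    for _ in range(n_annotations):
        feats = []
        for prefix, n in (("L", int(rng.integers(5, 60))),
                          ("G", int(rng.integers(5, 140)))):
            for i in range(n):
                chrom = f"chr{int(rng.integers(1, 4))}"
                start = int(rng.integers(1, 200_000))
                feats.append(
                    Interval(f"{prefix}{i}", chrom, start,
                             start + int(rng.integers(100, 8000)))
                )
        lncs = [f for f in feats if f.id.startswith("L")]
        genes = [f for f in feats if f.id.startswith("G")]
        got = {
            (p.lncrna_id, p.gene_id, p.gap) for p in assign_cis_targets(lncs, genes)
        }
        expect = set()
        for l in lncs:
            for g in genes:
                if l.chrom != g.chrom:
                    continue
                gap = max(0, max(l.start, g.start) - min(l.end, g.end) - 1)
                if gap <= 10_000:
                    expect.add((l.id, g.id, gap))
        if got != expect:
            bad += 1
    return bad, n_annotations


def planted_cis_recovered_exactly(study: SimulatedStudy) -> bool:
    ann = study.annotation
    found = {
        (p.lncrna_id, p.gene_id, p.gap)
        for p in assign_cis_targets(
            ann.transcript_intervals("lncRNA"), ann.gene_intervals(), 10_000
        )
    }
    return found == set(study.truth.cis_pairs)


def fpkm_conservation_error(study: SimulatedStudy) -> float:
    """Max relative error of the FPKM read-count conservation identity."""
    cm = study.counts["mRNA"]
    f = fpkm_normalize(cm)
    T = cm.values.sum(axis=0).to_numpy(dtype=float)
    L = cm.lengths.to_numpy()
    recon = (f.to_numpy() * L[:, None] * T[None, :] / 1e9).sum(axis=0)
    return float(np.max(np.abs(recon - T) / T))


def cerna_triads_from_counts(
    counts: Mapping[str, CountMatrix],
    truth_edges: list[tuple[str, str, str]],
) -> set[tuple[str, str, str]]:
    """Run the DE -> correlation -> sponge chain on count matrices.

    The miRNA universe is the set of DE-called miRNAs, matching the
    pipeline default.
    """
    parts = {}
    for cls in ("mRNA", "lncRNA", "miRNA"):
        _ann, parts[cls] = filter_de(exact_nb_test(counts[cls]))
    de = {cls: set(p["up"]) | set(p["down"]) for cls, p in parts.items()}
    universe = de["miRNA"]
    if not universe:
        return set()
    expr = {
        "mRNA": fpkm_normalize(counts["mRNA"]),
        "lncRNA": fpkm_normalize(counts["lncRNA"]),
        "miRNA": cpm_normalize(counts["miRNA"]),
    }
    edges = [
        TargetEdge(m, t, c)
        for m, t, c in truth_edges
        if m in universe and t in de.get(c, set())
    ]
    if not edges:
        return set()
    mir_expr = expr["miRNA"].loc[sorted(universe)]
    neg = []
    for cls in ("lncRNA", "mRNA"):
        ids = sorted(de[cls])
        if not ids:
            return set()
        neg += net.negative_pairs(
            mir_expr, expr[cls].loc[ids],
            [e for e in edges if e.target_class == cls],
        )
    targeted: dict[str, set[str]] = {}
    for e in edges:
        targeted.setdefault(e.target_id, set()).add(e.mirna_id)
    regs = expr["lncRNA"].loc[sorted(de["lncRNA"])]
    mrna = expr["mRNA"].loc[sorted(de["mRNA"])]
    candidates = [
        (r, g)
        for r in regs.index
        for g in mrna.index
        if targeted.get(r, set()) & targeted.get(g, set())
    ]
    if not candidates:
        return set()
    coexp = net.coexpressed_pairs(regs, mrna, candidates)
    triads = net.build_triads(neg, coexp, edges, universe)
    return {(t.regulator_id, t.mirna_id, t.mrna_id) for t in triads}


def triad_recovery(study: SimulatedStudy) -> dict[str, float | int]:
    emitted = cerna_triads_from_counts(study.counts, study.truth.target_edges)
    planted = set(study.truth.triads)
    rec = len(emitted & planted)
    return {
        "planted": len(planted),
        "emitted": len(emitted),
        "recovered": rec,
        "fraction": rec / len(planted) if planted else float("nan"),
    }


def permutation_false_triads(
    study: SimulatedStudy, n_permutations: int = 10, seed: int = 7
) -> int:
    """Total triads emitted across group-label permutations of the fixture."""
    rng = np.random.default_rng(seed)
    base = study.counts["mRNA"]
    samples = list(base.values.columns)
    total = 0
    for _ in range(n_permutations):
        perm = rng.permutation(samples)
        groups = {s: base.groups[p] for s, p in zip(samples, perm)}
        counts = {
            cls: CountMatrix(cm.values, groups, cm.group_order, cm.lengths)
            for cls, cm in study.counts.items()
            if cls in ("mRNA", "lncRNA", "miRNA")
        }
        total += len(
            cerna_triads_from_counts(counts, study.truth.target_edges)
        )
    return total


def null_study(seed: int = 1) -> SimulatedStudy:
    """The default study conditions with a given seed (convenience)."""
    from .synthetic import simulate_study

    return simulate_study(SimConfig(seed=seed))
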