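"""End-to-end pipeline: filters -> normalization -> DE -> cis -> enrichment
-> target edges -> ceRNA network, from a single YAML configuration.

Every intermediate table is written as TSV next to a machine-readable
``report.json`` holding stage counts and the exact thresholds used. The
run is deterministic: re-running on unchanged inputs reproduces
byte-identical outputs (no timestamps enter any output file; timings go
to stderr logging only).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import cis as cis_mod
from . import expression as expr_mod
from . import filters as filt_mod
from . import mirna as mirna_mod
from . import network as net_mod
from .annotation import AnnotationSet
from .core import CountMatrix, PipelineError, read_sample_table
from .enrichment import enrich, read_term_map, results_to_frame
from .synthetic import TruthSet

log = logging.getLogger("cernaforge")

REPORT_VERSION = 1
CLASS_KEYS = ("mRNA", "lncRNA", "circRNA", "miRNA")


class ConfigValidationError(PipelineError, ValueError):
    """Raised with the complete list of configuration violations."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid configuration:\n" + "\n".join(f"- {v}" for v in violations))


class StageError(PipelineError, RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    base_dir: Path
    gtf: Path
    counts: dict[str, Path]
    samples: Path
    coding_labels: Path
    term_map: Path
    target_edges: Path | None = None
    mirna_fasta: Path | None = None
    target_fasta: Path | None = None
    truth: Path | None = None
    mirna_universe: Path | None = None
    group1: str = "PMM"
    group2: str = "SART"
    p_de: float = 0.05
    lfc: float = 1.0
    cis_window: int = 10_000
    scc: float = -0.7
    pcc: float = 0.9
    sponge_p: float = 0.05
    enrich_p: float = 0.05
    dispersion: float | str = "estimate"
    adjust: str = "none"
    circ_triads: bool = True
    corr_scope: str = "pooled"  # pooled | group1 | group2
    seed: int = 0


_THRESHOLD_DOMAINS = {
    "p_de": (lambda v: 0 < v <= 1, "p_de must be in (0, 1]"),
    "lfc": (lambda v: v >= 0, "lfc must be >= 0"),
    "cis_window": (lambda v: v >= 0, "cis_window must be >= 0"),
    "scc": (lambda v: -1 <= v < 0, "scc threshold must be in [-1, 0)"),
    "pcc": (lambda v: 0 < v <= 1, "pcc threshold must be in (0, 1]"),
    "sponge_p": (lambda v: 0 < v <= 1, "sponge_p must be in (0, 1]"),
    "enrich_p": (lambda v: 0 < v <= 1, "enrich_p must be in (0, 1]"),
}


def validate_config(path: str | Path, **overrides: Any) -> PipelineConfig:
    """Load and fully validate a YAML pipeline configuration.

    All violations are collected and reported together rather than
    failing on the first one.
    """
    path = Path(path)
    violations: list[str] = []
    if not path.exists():
        raise ConfigValidationError([f"config file not found: {path}"])
    doc = yaml.safe_load(path.read_text()) or {}
    base = path.parent
    inputs = doc.get("inputs", {})
    thresholds = doc.get("thresholds", {})
    groups = doc.get("groups", {})

    def resolve(key: str, required: bool) -> Path | None:
        rel = inputs.get(key)
        if rel is None:
            if required:
                violations.append(f"missing required input path: {key}")
            return None
        p = base / rel
        if not p.exists():
            violations.append(f"input file does not exist: {key} = {p}")
        return p

    gtf = resolve("gtf", True)
    samples = resolve("samples", True)
    coding = resolve("coding_labels", True)
    term_map = resolve("term_map", True)
    counts_doc = inputs.get("counts", {})
    counts: dict[str, Path] = {}
    for cls in CLASS_KEYS:
        rel = counts_doc.get(cls)
        if rel is None:
            violations.append(f"missing count table for class {cls}")
            continue
        p = base / rel
        if not p.exists():
            violations.append(f"count table does not exist: {cls} = {p}")
        counts[cls] = p
    optional = {
        k: (base / inputs[k] if inputs.get(k) else None)
        for k in ("target_edges", "mirna_fasta", "target_fasta", "truth",
                  "mirna_universe")
    }
    for k, p in optional.items():
        if p is not None and not p.exists():
            violations.append(f"input file does not exist: {k} = {p}")
    if optional["target_edges"] is None and (
        optional["mirna_fasta"] is None or optional["target_fasta"] is None
    ):
        violations.append(
            "either target_edges or both mirna_fasta and target_fasta are required"
        )

    kwargs: dict[str, Any] = {}
    for key, (ok, msg) in _THRESHOLD_DOMAINS.items():
        v = overrides.get(key, thresholds.get(key))
        if v is None:
            continue
        if not ok(v):
            violations.append(f"{msg} (got {v})")
        else:
            kwargs[key] = v
    disp = overrides.get("dispersion", doc.get("dispersion", "estimate"))
    if disp != "estimate":
        try:
            disp = float(disp)
            if disp < 0:
                violations.append(f"dispersion must be >= 0 (got {disp})")
        except (TypeError, ValueError):
            violations.append(f"dispersion must be a number or 'estimate' (got {disp!r})")
    kwargs["dispersion"] = disp

    g1 = groups.get("group1")
    g2 = groups.get("group2")
    if not g1 or not g2 or g1 == g2:
        violations.append("groups must name two distinct labels group1 and group2")
    if samples is not None and samples.exists() and g1 and g2:
        mapping = read_sample_table(samples)
        bad = sorted({g for g in mapping.values() if g not in (g1, g2)})
        if bad:
            violations.append(f"sample table contains unknown group label(s): {bad}")
        for cls, p in counts.items():
            if p is not None and p.exists():
                header = pd.read_csv(p, sep="\t", nrows=0).columns[1:]
                missing = [s for s in header if s not in mapping]
                if missing:
                    violations.append(
                        f"samples in {cls} counts absent from sample table: {missing}"
                    )
    scope = overrides.get("corr_scope", doc.get("corr_scope", "pooled"))
    if scope not in ("pooled", "group1", "group2"):
        violations.append(f"corr_scope must be pooled|group1|group2 (got {scope!r})")

    if violations:
        raise ConfigValidationError(violations)
    return PipelineConfig(
        base_dir=base, gtf=gtf, counts=counts, samples=samples,
        coding_labels=coding, term_map=term_map,
        target_edges=optional["target_edges"],
        mirna_fasta=optional["mirna_fasta"],
        target_fasta=optional["target_fasta"],
        truth=optional["truth"], mirna_universe=optional["mirna_universe"],
        group1=g1, group2=g2,
        circ_triads=bool(overrides.get("circ_triads", doc.get("circ_triads", True))),
        corr_scope=scope,
        seed=int(overrides.get("seed", doc.get("seed", 0))),
        **kwargs,
    )


def _read_fasta(path: Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute all stages; returns the run report (also written as JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stale = out / "STALE"
    stale.write_text("run in progress; outputs incomplete\n")
    report: dict[str, Any] = {
        "version": REPORT_VERSION,
        "thresholds": {
            "p_de": cfg.p_de, "lfc": cfg.lfc, "cis_window": cfg.cis_window,
            "scc": cfg.scc, "pcc": cfg.pcc, "sponge_p": cfg.sponge_p,
            "enrich_p": cfg.enrich_p, "dispersion": cfg.dispersion,
        },
        "stages": {},
        "validation_qpcr": None,  # slot for user-supplied qRT-PCR values
    }
    stages = report["stages"]
    state: dict[str, Any] = {}

    def stage(name: str):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                stale.write_text(f"failed at stage {name}\n")
                raise StageError(name, exc) from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)

        return deco

    @stage("load")
    def _load() -> None:
        ann = AnnotationSet.from_gtf(cfg.gtf)
        groups = read_sample_table(cfg.samples)
        order = (cfg.group1, cfg.group2)
        counts = {}
        for cls, path in cfg.counts.items():
            lengths = pd.Series(
                {t.transcript_id: float(t.length)
                 for t in ann.by_biotype(cls)}
            )
            counts[cls] = CountMatrix.from_tsv(path, groups, order, lengths)
        state.update(ann=ann, counts=counts)

    @stage("filters")
    def _filters() -> None:
        ann: AnnotationSet = state["ann"]
        labels = filt_mod.read_coding_labels(cfg.coding_labels)
        tally = filt_mod.filter_lncrna_candidates(ann.by_biotype("lncRNA"), labels)
        tally.to_frame().to_csv(out / "lncrna_filter.tsv", sep="\t", index=False)
        retained_circ = filt_mod.filter_circrna(state["counts"]["circRNA"])
        pd.Series(retained_circ, name="circrna_id").to_csv(
            out / "circrna_retained.tsv", sep="\t", index=False
        )
        counts = state["counts"]
        counts["lncRNA"] = counts["lncRNA"].subset_features(tally.accepted)
        counts["circRNA"] = counts["circRNA"].subset_features(retained_circ)
        state.update(lnc_tally=tally, retained_circ=retained_circ)
        stages["filters"] = {
            "lncrna_in": tally.n_input,
            "lncrna_accepted": len(tally.accepted),
            "lncrna_rejected": {k: len(v) for k, v in tally.rejected.items()},
            "circrna_in": len(
                pd.read_csv(cfg.counts["circRNA"], sep="\t", index_col=0)
            ),
            "circrna_retained": len(retained_circ),
        }

    @stage("normalize")
    def _normalize() -> None:
        counts = state["counts"]
        expr = {
            "mRNA": expr_mod.fpkm_normalize(counts["mRNA"]),
            "lncRNA": expr_mod.fpkm_normalize(counts["lncRNA"]),
            # junction/short classes are library-size scaled, not length-normalized
            "circRNA": expr_mod.cpm_normalize(counts["circRNA"]),
            "miRNA": expr_mod.cpm_normalize(counts["miRNA"]),
        }
        for cls, df in expr.items():
            df.to_csv(out / f"expr_{cls.lower()}.tsv", sep="\t")
        corr = expr_mod.sample_correlation(expr["mRNA"], "pearson")
        corr.to_csv(out / "sample_correlation.tsv", sep="\t")
        n = corr.shape[0]
        offdiag = (corr.to_numpy().sum() - n) / (n * (n - 1))
        stages["correlation"] = {"mean_offdiag": float(offdiag)}
        state["expr"] = expr

    @stage("differential_expression")
    def _de() -> None:
        de: dict[str, pd.DataFrame] = {}
        parts: dict[str, dict[str, list[str]]] = {}
        stages["de"] = {}
        for cls in CLASS_KEYS:
            cm = state["counts"][cls]
            res = expr_mod.exact_nb_test(cm, cfg.dispersion)
            annotated, part = expr_mod.filter_de(
                res, cfg.p_de, cfg.lfc, adjust=cfg.adjust
            )
            annotated.index.name = "feature_id"
            annotated.to_csv(out / f"de_{cls.lower()}.tsv", sep="\t")
            de[cls] = annotated
            parts[cls] = part
            stages["de"][cls] = {
                "tested": len(annotated),
                "up": len(part["up"]),
                "down": len(part["down"]),
                "not_de": len(part["not_de"]),
                "dispersion_used": res.attrs.get("dispersion"),
            }
        state.update(de=de, parts=parts)

    @stage("presence")
    def _presence() -> None:
        stages["presence"] = {}
        for cls in CLASS_KEYS:
            part = expr_mod.presence_partition(state["counts"][cls])
            stages["presence"][cls] = {
                "group1_specific": len(part["group1_specific"]),
                "group2_specific": len(part["group2_specific"]),
                "shared": len(part["shared"]),
                "unexpressed": len(part["unexpressed"]),
            }
            if cls == "mRNA":
                state["expressed_genes"] = (
                    part["group1_specific"] | part["group2_specific"] | part["shared"]
                )

    @stage("cis_targets")
    def _cis() -> None:
        ann: AnnotationSet = state["ann"]
        parts = state["parts"]
        de_lnc = set(parts["lncRNA"]["up"]) | set(parts["lncRNA"]["down"])
        lnc_iv = [iv for iv in ann.transcript_intervals("lncRNA") if iv.id in de_lnc]
        pairs = cis_mod.assign_cis_targets(lnc_iv, ann.gene_intervals(), cfg.cis_window)
        cis_mod.write_cis_pairs(pairs, out / "cis_pairs.tsv")
        edges = cis_mod.de_cis_network(pairs, parts["lncRNA"], parts["mRNA"])
        pd.DataFrame(edges).to_csv(out / "cis_de_network.tsv", sep="\t", index=False)
        state.update(cis_pairs=pairs, cis_edges=edges)
        stages["cis"] = {
            "de_lncrnas": len(de_lnc),
            "lncrnas_with_cis_target": len({p.lncrna_id for p in pairs}),
            "cis_pairs": len(pairs),
            "de_cis_edges": len(edges),
        }

    @stage("enrichment")
    def _enrich() -> None:
        ann: AnnotationSet = state["ann"]
        term_map = read_term_map(cfg.term_map)
        background = state["expressed_genes"]
        stages["enrichment"] = {}

        def run(name: str, study: set[str]) -> None:
            study = study & background
            res = enrich(study, background, term_map, cfg.enrich_p, adjust="none")
            results_to_frame(res).to_csv(out / f"enrich_{name}.tsv", sep="\t", index=False)
            stages["enrichment"][name] = {
                "study_size": len(study),
                "terms_tested": len(res),
                "significant": sum(r.significant for r in res),
            }

        run("cis_targets", {p.gene_id for p in state["cis_pairs"]})
        parts = state["parts"]
        de_circ = set(parts["circRNA"]["up"]) | set(parts["circRNA"]["down"])
        hosts = {
            ann.transcripts[c].host_gene_id
            for c in de_circ
            if c in ann.transcripts and ann.transcripts[c].host_gene_id
        }
        run("circ_hosts", hosts)

    @stage("target_edges")
    def _targets() -> None:
        ann: AnnotationSet = state["ann"]
        collected = []
        source = []
        if cfg.target_edges is not None:
            collected.append(mirna_mod.load_target_table(cfg.target_edges))
            source.append("imported")
        if cfg.mirna_fasta is not None and cfg.target_fasta is not None:
            mir = _read_fasta(cfg.mirna_fasta)
            tgt = _read_fasta(cfg.target_fasta)
            classes = {
                t.transcript_id: t.biotype
                for t in ann.transcripts.values()
                if t.biotype in mirna_mod.TARGET_CLASSES
            }
            tgt = {k: v for k, v in tgt.items() if k in classes}
            collected.append(
                mirna_mod.seed_match(mir, tgt, target_classes=classes)
            )
            source.append("seed_match")
        edges = mirna_mod.merge_edges(*collected)
        mirna_mod.edges_to_frame(edges).to_csv(
            out / "target_edges.tsv", sep="\t", index=False
        )
        state["edges"] = edges
        stages["targets"] = {"edges": len(edges), "source": "+".join(source)}

    @stage("cerna_network")
    def _cerna() -> None:
        parts = state["parts"]
        expr = state["expr"]
        if cfg.mirna_universe is not None:
            ids = [
                line.strip()
                for line in Path(cfg.mirna_universe).read_text().splitlines()
            ]
            universe = {i for i in ids if i}
        else:
            universe = set(parts["miRNA"]["up"]) | set(parts["miRNA"]["down"])
        if not universe:
            stages["cerna"] = {"skipped": True, "reason": "empty miRNA universe"}
            state["triads"] = []
            return
        samples = None
        if cfg.corr_scope != "pooled":
            grp = cfg.group1 if cfg.corr_scope == "group1" else cfg.group2
            samples = state["counts"]["miRNA"].samples_in(grp)

        def scoped(df: pd.DataFrame) -> pd.DataFrame:
            return df[samples] if samples is not None else df

        de_sets = {
            cls: set(parts[cls]["up"]) | set(parts[cls]["down"])
            for cls in CLASS_KEYS
        }
        edges = [
            e for e in state["edges"]
            if e.mirna_id in universe and e.target_id in de_sets[e.target_class]
        ]
        mir_expr = scoped(expr["miRNA"].loc[sorted(universe & set(expr["miRNA"].index))])
        reg_classes = ["lncRNA"] + (["circRNA"] if cfg.circ_triads else [])
        neg: list[net_mod.CorrEdge] = []
        for cls in ("lncRNA", "mRNA", "circRNA"):
            cls_edges = [e for e in edges if e.target_class == cls]
            tgt_expr = scoped(expr[cls].loc[sorted(de_sets[cls] & set(expr[cls].index))])
            neg += net_mod.negative_pairs(mir_expr, tgt_expr, cls_edges, cfg.scc)
        targeted: dict[str, set[str]] = {}
        for e in edges:
            targeted.setdefault(e.target_id, set()).add(e.mirna_id)
        directions = {
            f: d for cls in CLASS_KEYS for d in ("up", "down")
            for f in parts[cls][d]
        }
        all_triads: list[net_mod.CeRNATriad] = []
        stages["cerna"] = {
            "skipped": False, "universe_size": len(universe),
            "negative_pairs": len(neg),
        }
        for cls in reg_classes:
            reg_expr = scoped(expr[cls].loc[sorted(de_sets[cls] & set(expr[cls].index))])
            mrna_expr = scoped(
                expr["mRNA"].loc[sorted(de_sets["mRNA"] & set(expr["mRNA"].index))]
            )
            candidates = [
                (r, g)
                for r in reg_expr.index
                for g in mrna_expr.index
                if targeted.get(r, set()) & targeted.get(g, set())
            ]
            coexp = net_mod.coexpressed_pairs(reg_expr, mrna_expr, candidates, cfg.pcc)
            triads = net_mod.build_triads(
                neg, coexp, edges, universe, cfg.sponge_p, directions
            )
            stages["cerna"][f"coexpressed_pairs_{cls}"] = len(coexp)
            stages["cerna"][f"triads_{cls}"] = len(triads)
            all_triads += triads
        net_mod.triads_to_frame(all_triads).to_csv(
            out / "cerna_triads.tsv", sep="\t", index=False
        )
        state["triads"] = all_triads
        stages["cerna"]["triads"] = len(all_triads)

    @stage("export")
    def _export() -> None:
        ann: AnnotationSet = state["ann"]
        directions = {
            f: d for cls in CLASS_KEYS for d in ("up", "down")
            for f in state["parts"][cls][d]
        }
        classes = {t.transcript_id: t.biotype for t in ann.transcripts.values()}
        node_attrs = {}
        nodes, edges = net_mod.triads_to_network(state["triads"])
        for e in state["cis_edges"]:
            for nid in (e["lncrna_id"], e["gene_id"]):
                nodes.setdefault(nid, {"node_class": classes.get(nid, "gene")})
            edges.append(
                {"source": e["lncrna_id"], "target": e["gene_id"],
                 "relation": "cis", "gap_bp": e["gap_bp"]}
            )
        for nid, attrs in nodes.items():
            attrs["node_class"] = classes.get(nid, attrs.get("node_class", "gene"))
            attrs["direction"] = directions.get(nid, "none")
        for fmt, suffix in (("SIF", "sif"), ("GraphML", "graphml"), ("TSV", "tsv")):
            net_mod.export_network(nodes, edges, out / f"network.{suffix}", fmt)
        stages["export"] = {"nodes": len(nodes), "edges": len(edges)}

    @stage("recovery")
    def _recovery() -> None:
        if cfg.truth is None:
            return
        truth = TruthSet.from_json(cfg.truth)
        parts = state["parts"]
        ann: AnnotationSet = state["ann"]
        rec: dict[str, Any] = {}
        de_called = {
            cls: set(parts[cls]["up"]) | set(parts[cls]["down"]) for cls in CLASS_KEYS
        }
        for cls in CLASS_KEYS:
            planted = {
                f for f in truth.de_features if f in set(state["de"][cls].index)
            }
            called = de_called[cls]
            tp = len(planted & called)
            fp = len(called - planted)
            rec[f"de_{cls}"] = {
                "planted": len(planted),
                "called": len(called),
                "sensitivity": tp / len(planted) if planted else None,
                "fdr": fp / len(called) if called else 0.0,
            }
        all_pairs = cis_mod.assign_cis_targets(
            ann.transcript_intervals("lncRNA"), ann.gene_intervals(), cfg.cis_window
        )
        found = {(p.lncrna_id, p.gene_id) for p in all_pairs}
        planted_cis = {(l, g) for l, g, _gap in truth.cis_pairs}
        rec["cis"] = {
            "planted": len(planted_cis),
            "found": len(found),
            "exact_match": found == planted_cis,
        }
        emitted = {
            (t.regulator_id, t.mirna_id, t.mrna_id) for t in state["triads"]
        }
        planted_triads = set(truth.triads)
        rec["triads"] = {
            "planted": len(planted_triads),
            "emitted": len(emitted),
            "recovered": len(planted_triads & emitted),
            "recovery_fraction": (
                len(planted_triads & emitted) / len(planted_triads)
                if planted_triads else None
            ),
        }
        report["recovery"] = rec

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    stale.unlink()
    return report
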