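"""Synthetic two-muscle RNA-seq study generator.

Emulates the data layout of a 4-vs-4 glycolytic (PMM-like) vs oxidative
(SART-like) muscle profiling experiment: annotated mRNA genes, lncRNAs,
circRNAs and miRNAs on synthetic chromosomes; grouped negative-binomial
count matrices with planted differential expression; planted lncRNA-gene
cis placements that deliberately avoid the 10 kb decision boundary;
planted ceRNA triads (lncRNA/miRNA/mRNA) whose members share a
group-aligned latent factor; and miRNA/target sequences with embedded
seed sites. Everything is reproducible from a single seed, and a
:class:`TruthSet` records every planted signal so downstream stages can
be scored without external data.

Count model
-----------
Counts are Gamma-Poisson (negative binomial) with mean ``mu_fs`` and
dispersion ``phi``: ``Var = mu + phi * mu**2``. Baseline feature means are
log-normal. Planted DE features have their group-2 mean multiplied by
``2**(+/- de_log2fc)``. Triad members instead draw their group contrast
from a shared per-triad latent factor ``z_s = (+/-1 by group) + jitter``;
the factor enters the miRNA log-mean with negative sign and the
regulator/mRNA log-means with positive sign, scaled by
``triad_corr_strength * latent_scale``. Aligning the factor with the group
contrast makes triad members simultaneously strongly differential and
strongly rank-correlated across the pooled samples — the behaviour of
fiber-type program genes (e.g. myosin isoform switches), which differ by
orders of magnitude between red and white muscle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import AnnotationSet, Interval, TranscriptRecord
from .core import CountMatrix, ConsistencyError, SizingError, write_sample_table

GROUP1 = "PMM"   # glycolytic analogue (reference group)
GROUP2 = "SART"  # oxidative analogue (fold changes are group2 over group1)

CLASS_ORDER = ("mRNA", "lncRNA", "circRNA", "miRNA")

# gap bands for planted cis placements: the generator never places a lncRNA
# with a gene gap inside (9_500, 15_000) bp, so a ``<= 10 kb`` and a
# ``< 10 kb`` windowing convention label every planted pair identically.
CIS_GAP_MAX = 9_500
NONCIS_GAP_MIN = 15_000


@dataclass
class SimConfig:
    """Parameters of the synthetic study. Defaults are the study conditions."""

    n_mrna: int = 2000
    n_lncrna: int = 400
    n_circrna: int = 300
    n_mirna: int = 150
    n_per_group: int = 4
    frac_de: float = 0.10
    de_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    mean_log_expr_mu: float = 5.0
    mean_log_expr_sigma: float = 1.0
    n_triads: int = 30
    triad_corr_strength: float = 0.9
    cis_fraction: float = 0.15
    library_size_range: tuple[int, int] = (800_000, 1_200_000)
    seed: int = 0
    # genome layout
    n_chromosomes: int = 5
    chrom_length_bp: int = 40_000_000
    # triad latent factor: amplitude (natural-log units) and within-group jitter
    latent_scale: float = 2.2
    latent_jitter: float = 0.25
    # structural-filter decoys (all zero by default: a clean study)
    n_decoy_short: int = 0
    n_decoy_monoexonic: int = 0
    n_decoy_coding: int = 0
    # target-edge structure
    n_shared_decoy_mirnas: int = 2
    background_edges_per_mirna: int = 3
    target_seq_len: int = 500
    mirna_len: int = 22
    # term map
    n_terms: int = 40
    term_size_range: tuple[int, int] = (10, 40)
    # circRNAs are lowly expressed relative to linear RNAs
    circ_log_expr_shift: float = -2.0

    def __post_init__(self) -> None:
        for name in ("n_mrna", "n_lncrna", "n_circrna", "n_mirna", "n_per_group"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must be in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if not 0.0 <= self.cis_fraction <= 1.0:
            raise ValueError("cis_fraction must be in [0, 1]")
        if not 0.0 <= self.triad_corr_strength <= 1.0:
            raise ValueError("triad_corr_strength must be in [0, 1]")
        if self.n_triads > min(self.n_lncrna, self.n_mirna, self.n_mrna):
            raise ValueError(
                "n_triads must be <= min(n_lncrna, n_mirna, n_mrna)"
            )
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("library_size_range must be a positive ordered pair")


@dataclass
class TruthSet:
    """Ledger of every planted signal, re-derivable from the emitted files."""

    de_features: dict[str, str] = field(default_factory=dict)
    cis_pairs: list[tuple[str, str, int]] = field(default_factory=list)
    triads: list[tuple[str, str, str]] = field(default_factory=list)
    target_edges: list[tuple[str, str, str]] = field(default_factory=list)
    seed_sites: dict[tuple[str, str], list[int]] = field(default_factory=dict)
    features: dict[str, list[str]] = field(default_factory=dict)
    decoys: dict[str, list[str]] = field(default_factory=dict)
    enriched_term: str = ""
    term_map: list[tuple[str, str, str, str]] = field(default_factory=list)

    @property
    def triad_members(self) -> set[str]:
        out: set[str] = set()
        for reg, mir, mrna in self.triads:
            out.update((reg, mir, mrna))
        return out

    def validate(self) -> None:
        edge_pairs = {(m, t) for m, t, _c in self.target_edges}
        for reg, mir, mrna in self.triads:
            if (mir, reg) not in edge_pairs or (mir, mrna) not in edge_pairs:
                raise ConsistencyError(
                    f"triad ({reg},{mir},{mrna}) lacks its target edges"
                )

    def to_json(self, path: str | Path) -> None:
        doc = {
            "de_features": self.de_features,
            "cis_pairs": [list(p) for p in self.cis_pairs],
            "triads": [list(t) for t in self.triads],
            "target_edges": [list(e) for e in self.target_edges],
            "seed_sites": [
                [m, t, pos] for (m, t), pos in sorted(self.seed_sites.items())
            ],
            "features": self.features,
            "decoys": self.decoys,
            "enriched_term": self.enriched_term,
            "term_map": [list(r) for r in self.term_map],
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        doc = json.loads(Path(path).read_text())
        return cls(
            de_features=dict(doc["de_features"]),
            cis_pairs=[tuple(p) for p in doc["cis_pairs"]],
            triads=[tuple(t) for t in doc["triads"]],
            target_edges=[tuple(e) for e in doc["target_edges"]],
            seed_sites={(m, t): list(pos) for m, t, pos in doc["seed_sites"]},
            features={k: list(v) for k, v in doc["features"].items()},
            decoys={k: list(v) for k, v in doc["decoys"].items()},
            enriched_term=doc["enriched_term"],
            term_map=[tuple(r) for r in doc["term_map"]],
        )


# ---------------------------------------------------------------------------
# annotation generation
# ---------------------------------------------------------------------------

def _make_exons(rng: np.random.Generator, start: int, n_exons: int,
                exon_rng: tuple[int, int], intron_rng: tuple[int, int]
                ) -> list[tuple[int, int]]:
    exons = []
    pos = start
    for i in range(n_exons):
        elen = int(rng.integers(exon_rng[0], exon_rng[1] + 1))
        exons.append((pos, pos + elen - 1))
        pos += elen
        if i < n_exons - 1:
            pos += int(rng.integers(intron_rng[0], intron_rng[1] + 1))
    return exons


def generate_annotation(cfg: SimConfig) -> tuple[AnnotationSet, TruthSet]:
    """Lay out all features on synthetic chromosomes and plant the truth.

    Genes never overlap; consecutive layout entities are separated by at
    least 20 kb, so a lncRNA is within the cis window only of the gene it
    was planted next to. Planted cis gaps fall in [0, 9 500] bp; every
    other lncRNA is >= 15 000 bp from any gene.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    ann = AnnotationSet()
    truth = TruthSet()

    gene_ids = [f"G{i:04d}" for i in range(1, cfg.n_mrna + 1)]
    lnc_total = (cfg.n_lncrna + cfg.n_decoy_short + cfg.n_decoy_monoexonic
                 + cfg.n_decoy_coding)
    lnc_ids = [f"LNC{i:04d}" for i in range(1, lnc_total + 1)]
    circ_ids = [f"CIRC{i:04d}" for i in range(1, cfg.n_circrna + 1)]
    mir_ids = [f"MIR{i:04d}" for i in range(1, cfg.n_mirna + 1)]

    valid_lnc = lnc_ids[: cfg.n_lncrna]
    decoy_short = lnc_ids[cfg.n_lncrna: cfg.n_lncrna + cfg.n_decoy_short]
    decoy_mono = lnc_ids[cfg.n_lncrna + cfg.n_decoy_short:
                         cfg.n_lncrna + cfg.n_decoy_short + cfg.n_decoy_monoexonic]
    decoy_coding = lnc_ids[cfg.n_lncrna + cfg.n_decoy_short + cfg.n_decoy_monoexonic:]
    truth.decoys = {
        "short": list(decoy_short),
        "monoexonic": list(decoy_mono),
        "coding": list(decoy_coding),
    }

    # plant cis assignments: each chosen lncRNA sits next to a distinct gene
    n_cis = int(round(cfg.cis_fraction * cfg.n_lncrna))
    cis_lncs = [valid_lnc[i] for i in sorted(
        rng.choice(cfg.n_lncrna, size=n_cis, replace=False))]
    cis_hosts = [gene_ids[i] for i in sorted(
        rng.choice(cfg.n_mrna, size=n_cis, replace=False))]
    host_of = dict(zip(cis_hosts, cis_lncs))

    def build_lnc(lid: str, start: int) -> TranscriptRecord:
        if lid in decoy_short:
            exons = _make_exons(rng, start, 2, (60, 90), (100, 300))
        elif lid in decoy_mono:
            exons = _make_exons(rng, start, 1, (250, 600), (0, 0))
        else:
            exons = _make_exons(rng, start, int(rng.integers(2, 5)),
                                (120, 400), (100, 500))
        return TranscriptRecord(
            transcript_id=lid, gene_id=lid, biotype="lncRNA",
            chrom="", strand="+" if rng.random() < 0.5 else "-",
            start=exons[0][0], end=exons[-1][1], exons=exons,
        )

    # layout entities in a fixed order; each entity carries its own spacer
    entities: list[tuple[str, str]] = [("gene", g) for g in gene_ids]
    standalone = [l for l in lnc_ids if l not in set(cis_lncs)]
    entities += [("lnc", l) for l in standalone]
    entities += [("mir", m) for m in mir_ids]

    chrom_i, cursor = 0, 1

    def ensure_room(extent: int, what: str) -> None:
        nonlocal chrom_i, cursor
        while cursor + extent > cfg.chrom_length_bp:
            chrom_i += 1
            cursor = 1
            if chrom_i >= cfg.n_chromosomes:
                raise SizingError(
                    f"cannot place {what}: n_chromosomes={cfg.n_chromosomes} x "
                    f"chrom_length_bp={cfg.chrom_length_bp} is too small for the "
                    "requested feature counts"
                )

    for kind, fid in entities:
        spacer = int(rng.integers(20_000, 30_001))
        if kind == "gene":
            strand = "+" if rng.random() < 0.5 else "-"
            # build at a provisional origin, then shift into place
            exons = _make_exons(rng, 1, int(rng.integers(3, 9)),
                                (100, 400), (200, 1_000))
            glen = exons[-1][1]
            attached = host_of.get(fid)
            lnc_rec = None
            gap = 0
            side = "down"
            if attached is not None:
                gap = int(rng.integers(0, CIS_GAP_MAX + 1))
                side = "up" if rng.random() < 0.5 else "down"
                lnc_rec = build_lnc(attached, 1)
            llen = (lnc_rec.end - lnc_rec.start + 1) if lnc_rec else 0
            extent = glen + (llen + gap + 1 if lnc_rec else 0) + spacer
            ensure_room(extent, fid)
            chrom = f"chr{chrom_i + 1}"
            if lnc_rec is not None and side == "up":
                lshift = cursor - lnc_rec.start
                gstart = cursor + llen + gap
            else:
                gstart = cursor
                lshift = (gstart + glen + gap - lnc_rec.start) if lnc_rec else 0
            gexons = [(s + gstart - 1, e + gstart - 1) for s, e in exons]
            ann.genes[fid] = Interval(fid, chrom, gexons[0][0], gexons[-1][1], strand)
            ann.add(TranscriptRecord(
                transcript_id=fid, gene_id=fid, biotype="mRNA",
                chrom=chrom, strand=strand,
                start=gexons[0][0], end=gexons[-1][1], exons=gexons,
            ))
            if lnc_rec is not None:
                lexons = [(s + lshift, e + lshift) for s, e in lnc_rec.exons]
                ann.add(TranscriptRecord(
                    transcript_id=lnc_rec.transcript_id,
                    gene_id=lnc_rec.gene_id, biotype="lncRNA",
                    chrom=chrom, strand=lnc_rec.strand,
                    start=lexons[0][0], end=lexons[-1][1], exons=lexons,
                ))
                truth.cis_pairs.append((lnc_rec.transcript_id, fid, gap))
            cursor = cursor + extent
        elif kind == "lnc":
            rec = build_lnc(fid, 1)
            llen = rec.end - rec.start + 1
            ensure_room(llen + spacer, fid)
            chrom = f"chr{chrom_i + 1}"
            shift = cursor - rec.start
            exons = [(s + shift, e + shift) for s, e in rec.exons]
            ann.add(TranscriptRecord(
                transcript_id=fid, gene_id=fid, biotype="lncRNA",
                chrom=chrom, strand=rec.strand,
                start=exons[0][0], end=exons[-1][1], exons=exons,
            ))
            cursor += llen + spacer
        else:  # miRNA locus
            ensure_room(cfg.mirna_len + spacer, fid)
            chrom = f"chr{chrom_i + 1}"
            ann.add(TranscriptRecord(
                transcript_id=fid, gene_id=fid, biotype="miRNA",
                chrom=chrom, strand="+",
                start=cursor, end=cursor + cfg.mirna_len - 1,
                exons=[(cursor, cursor + cfg.mirna_len - 1)],
            ))
            cursor += cfg.mirna_len + spacer

    # circRNAs: back-spliced from 1-3 consecutive exons of a random host gene
    for cid in circ_ids:
        host = gene_ids[int(rng.integers(0, cfg.n_mrna))]
        hrec = ann.transcripts[host]
        n_ex = int(rng.integers(1, min(3, hrec.n_exons) + 1))
        first = int(rng.integers(0, hrec.n_exons - n_ex + 1))
        exons = hrec.exons[first: first + n_ex]
        ann.add(TranscriptRecord(
            transcript_id=cid, gene_id=host, biotype="circRNA",
            chrom=hrec.chrom, strand=hrec.strand,
            start=exons[0][0], end=exons[-1][1], exons=list(exons),
            host_gene_id=host,
        ))

    truth.features = {
        "mRNA": list(gene_ids),
        "lncRNA": list(lnc_ids),
        "circRNA": list(circ_ids),
        "miRNA": list(mir_ids),
    }

    _plant_signals(cfg, rng, truth, gene_ids, valid_lnc, circ_ids, mir_ids)
    truth.validate()
    return ann, truth


def _plant_signals(cfg: SimConfig, rng: np.random.Generator, truth: TruthSet,
                   gene_ids: list[str], valid_lnc: list[str],
                   circ_ids: list[str], mir_ids: list[str]) -> None:
    """Choose DE features, triads, target edges and the term map."""
    # triad members are distinct within and across triads
    regs = [valid_lnc[i] for i in rng.choice(len(valid_lnc), cfg.n_triads, replace=False)]
    mirs = [mir_ids[i] for i in rng.choice(len(mir_ids), cfg.n_triads, replace=False)]
    mrnas = [gene_ids[i] for i in rng.choice(len(gene_ids), cfg.n_triads, replace=False)]
    flips = rng.random(cfg.n_triads) < 0.5
    for reg, mir, mrna, flip in zip(regs, mirs, mrnas, flips):
        truth.triads.append((reg, mir, mrna))
        up, down = ("up", "down") if not flip else ("down", "up")
        truth.de_features[reg] = up
        truth.de_features[mrna] = up
        truth.de_features[mir] = down

    # ordinary planted DE features, outside the triads
    members = truth.triad_members
    for ids in (gene_ids, valid_lnc, circ_ids, mir_ids):
        pool = [f for f in ids if f not in members]
        n_de = int(round(cfg.frac_de * len(ids)))
        n_de = min(n_de, len(pool))
        chosen = [pool[i] for i in sorted(rng.choice(len(pool), n_de, replace=False))]
        for f in chosen:
            truth.de_features[f] = "up" if rng.random() < 0.5 else "down"

    # target edges: triad edges, decoy shared sponges, random background
    edges: dict[tuple[str, str], str] = {}
    class_of = {f: "mRNA" for f in gene_ids}
    class_of.update({f: "lncRNA" for f in valid_lnc})
    class_of.update({f: "circRNA" for f in circ_ids})
    de_mirs_nontriad = [m for m in mir_ids
                        if m in truth.de_features and m not in members]
    for i, (reg, mir, mrna) in enumerate(truth.triads):
        edges[(mir, reg)] = "lncRNA"
        edges[(mir, mrna)] = "mRNA"
        # extra miRNAs that sponge-link the pair but carry no correlation signal
        pool = [m for m in de_mirs_nontriad if m != mir]
        k = min(cfg.n_shared_decoy_mirnas, len(pool))
        if k:
            decoy = [pool[j] for j in rng.choice(len(pool), k, replace=False)]
            for m in decoy:
                edges[(m, reg)] = "lncRNA"
                edges[(m, mrna)] = "mRNA"
    all_targets = gene_ids + valid_lnc + circ_ids
    for mir in mir_ids:
        for _ in range(cfg.background_edges_per_mirna):
            t = all_targets[int(rng.integers(0, len(all_targets)))]
            edges.setdefault((mir, t), class_of[t])
    truth.target_edges = sorted((m, t, c) for (m, t), c in edges.items())

    # term map: one term enriched in planted DE genes, the rest random
    de_genes = [g for g in gene_ids if g in truth.de_features]
    truth.enriched_term = "T0000"
    n_hit = min(30, len(de_genes))
    hit = [de_genes[i] for i in sorted(rng.choice(len(de_genes), n_hit, replace=False))]
    pad = [g for g in gene_ids if g not in set(hit)]
    pad = [pad[i] for i in sorted(rng.choice(len(pad), 10, replace=False))]
    rows = [(g, "T0000", "planted muscle program term", "BP") for g in hit + pad]
    lo, hi = cfg.term_size_range
    for ti in range(1, cfg.n_terms):
        term = f"T{ti:04d}"
        cat = "BP" if ti % 2 else "pathway"
        size = int(rng.integers(lo, hi + 1))
        genes = [gene_ids[i] for i in sorted(rng.choice(len(gene_ids), size, replace=False))]
        rows += [(g, term, f"synthetic term {ti}", cat) for g in genes]
    truth.term_map = rows


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------

def sample_names(cfg: SimConfig) -> tuple[list[str], dict[str, str]]:
    samples = [f"{GROUP1}_{i}" for i in range(1, cfg.n_per_group + 1)] + \
              [f"{GROUP2}_{i}" for i in range(1, cfg.n_per_group + 1)]
    groups = {s: (GROUP1 if s.startswith(GROUP1) else GROUP2) for s in samples}
    return samples, groups


def simulate_counts(
    annotation: AnnotationSet, truth: TruthSet, cfg: SimConfig
) -> dict[str, CountMatrix]:
    """Draw one NB count matrix per RNA class; see the module docstring."""
    for cls, ids in truth.features.items():
        for f in ids:
            if f not in annotation.transcripts:
                raise ConsistencyError(
                    f"truth feature {f} ({cls}) absent from annotation"
                )
    rng = np.random.default_rng([cfg.seed, 2])
    samples, groups = sample_names(cfg)
    n_s = len(samples)
    group2 = np.array([groups[s] == GROUP2 for s in samples])

    lib = rng.integers(cfg.library_size_range[0], cfg.library_size_range[1] + 1,
                       size=n_s).astype(float)
    log_lib_factor = np.log(lib / lib.mean())

    # one shared latent factor per triad: group contrast plus jitter
    sign = np.where(group2, 1.0, -1.0)
    latent = sign[None, :] + cfg.latent_jitter * rng.normal(size=(len(truth.triads), n_s))
    amp = cfg.triad_corr_strength * cfg.latent_scale
    role: dict[str, tuple[int, float]] = {}
    for ti, (reg, mir, mrna) in enumerate(truth.triads):
        flip = -1.0 if truth.de_features[reg] == "down" else 1.0
        role[reg] = (ti, +flip)
        role[mir] = (ti, -flip)
        role[mrna] = (ti, +flip)

    lfc_nat = cfg.de_log2fc * np.log(2.0)
    out: dict[str, CountMatrix] = {}
    for cls in CLASS_ORDER:
        ids = truth.features[cls]
        mu0 = cfg.mean_log_expr_mu + (cfg.circ_log_expr_shift if cls == "circRNA" else 0.0)
        base = rng.normal(mu0, cfg.mean_log_expr_sigma, size=len(ids))
        logmu = base[:, None] + log_lib_factor[None, :]
        for fi, f in enumerate(ids):
            if f in role:
                ti, s = role[f]
                logmu[fi] += s * amp * latent[ti]
            elif f in truth.de_features:
                shift = lfc_nat if truth.de_features[f] == "up" else -lfc_nat
                logmu[fi, group2] += shift
        mu = np.exp(logmu)
        if cfg.nb_dispersion == 0:
            counts = rng.poisson(mu)
        else:
            lam = rng.gamma(shape=1.0 / cfg.nb_dispersion,
                            scale=mu * cfg.nb_dispersion)
            counts = rng.poisson(lam)
        lengths = pd.Series(
            {f: annotation.transcripts[f].length for f in ids}, dtype=float
        )
        df = pd.DataFrame(counts, index=ids, columns=samples, dtype=np.int64)
        out[cls] = CountMatrix(df, groups, (GROUP1, GROUP2), lengths)
    return out


# ---------------------------------------------------------------------------
# sequence simulation
# ---------------------------------------------------------------------------

_DNA = np.array(list("ACGT"))
_RNA = np.array(list("ACGU"))
_RC = str.maketrans("ACGU", "TGCA")


def seed7_site(mirna_seq: str) -> str:
    """DNA reverse complement of miRNA positions 2-8 (the 7mer-m8 site)."""
    seed = mirna_seq.upper().replace("T", "U")[1:8]
    return seed.translate(_RC)[::-1]


def simulate_sequences(
    truth: TruthSet, cfg: SimConfig
) -> tuple[dict[str, str], dict[str, str]]:
    """Random sequences with one exact 7mer-m8 site per planted target edge.

    Unintended occurrences of a planted miRNA's seed site elsewhere in that
    miRNA's target are scrubbed by point mutation, so seed scanning recovers
    exactly the planted positions plus only cross-pair chance matches.
    """
    rng = np.random.default_rng([cfg.seed, 3])
    mirna_seqs = {
        m: "".join(rng.choice(_RNA, size=cfg.mirna_len))
        for m in sorted(truth.features.get("miRNA", []))
    }
    edges_by_target: dict[str, list[str]] = {}
    for m, t, _c in truth.target_edges:
        edges_by_target.setdefault(t, []).append(m)

    target_seqs: dict[str, str] = {}
    truth.seed_sites = {}
    for t in sorted(edges_by_target):
        seq = rng.choice(_DNA, size=cfg.target_seq_len)
        planted: list[tuple[int, int]] = []  # closed [start, end] windows
        for m in sorted(edges_by_target[t]):
            site = seed7_site(mirna_seqs[m])
            pos = None
            for _try in range(200):
                cand = int(rng.integers(0, cfg.target_seq_len - 7 + 1))
                if all(cand + 6 < s or cand > e for s, e in planted):
                    pos = cand
                    break
            if pos is None:
                raise SizingError(
                    f"target_seq_len={cfg.target_seq_len} too short to host "
                    f"{len(edges_by_target[t])} sites in {t}"
                )
            seq[pos: pos + 7] = list(site)
            planted.append((pos, pos + 6))
            truth.seed_sites[(m, t)] = [pos]
        # scrub unintended copies of each planted seed
        s = "".join(seq)
        for _pass in range(50):
            dirty = False
            for m in sorted(edges_by_target[t]):
                site = seed7_site(mirna_seqs[m])
                start = 0
                while True:
                    i = s.find(site, start)
                    if i < 0:
                        break
                    if i not in truth.seed_sites[(m, t)]:
                        # mutate one base of this copy outside all planted windows
                        for off in range(7):
                            j = i + off
                            if all(j < ps or j > pe for ps, pe in planted):
                                alt = [b for b in "ACGT" if b != s[j]]
                                s = s[:j] + alt[int(rng.integers(0, 3))] + s[j + 1:]
                                dirty = True
                                break
                        else:
                            start = i + 1
                            continue
                    start = i + 1
            if not dirty:
                break
        target_seqs[t] = s
    return mirna_seqs, target_seqs


# ---------------------------------------------------------------------------
# fixture writing
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    cfg: SimConfig
    annotation: AnnotationSet
    truth: TruthSet
    counts: dict[str, CountMatrix]
    mirna_seqs: dict[str, str]
    target_seqs: dict[str, str]


def simulate_study(cfg: SimConfig) -> SimulatedStudy:
    """Run annotation, count and sequence generation from one seed."""
    annotation, truth = generate_annotation(cfg)
    counts = simulate_counts(annotation, truth, cfg)
    mirna_seqs, target_seqs = simulate_sequences(truth, cfg)
    return SimulatedStudy(cfg, annotation, truth, counts, mirna_seqs, target_seqs)


def _write_fasta(seqs: Mapping[str, str], path: Path) -> None:
    records = [SeqRecord(Seq(seqs[k]), id=k, description="") for k in sorted(seqs)]
    SeqIO.write(records, str(path), "fasta")


def write_fixture(study: SimulatedStudy, dir_path: str | Path) -> dict[str, Path]:
    """Write the complete study as plain-text files; returns name -> path."""
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["gtf"] = d / "annotation.gtf"
    study.annotation.to_gtf(paths["gtf"])

    for cls, cm in study.counts.items():
        key = f"counts_{cls.lower()}"
        paths[key] = d / f"{key}.tsv"
        cm.to_tsv(paths[key])

    any_cm = next(iter(study.counts.values()))
    paths["samples"] = d / "samples.tsv"
    write_sample_table(any_cm.groups, paths["samples"])

    paths["mirna_fasta"] = d / "mirna.fasta"
    _write_fasta(study.mirna_seqs, paths["mirna_fasta"])
    paths["target_fasta"] = d / "targets.fasta"
    _write_fasta(study.target_seqs, paths["target_fasta"])

    paths["target_edges"] = d / "target_edges.tsv"
    pd.DataFrame(
        study.truth.target_edges, columns=["mirna_id", "target_id", "target_class"]
    ).to_csv(paths["target_edges"], sep="\t", index=False)

    paths["coding_labels"] = d / "coding_labels.tsv"
    rows = []
    coding_decoys = set(study.truth.decoys.get("coding", []))
    for t in sorted(study.annotation.transcripts):
        rec = study.annotation.transcripts[t]
        if rec.biotype != "lncRNA":
            continue
        rows.append((t, "cnci", "coding" if t in coding_decoys else "noncoding"))
        rows.append((t, "cpc", "noncoding"))
    pd.DataFrame(rows, columns=["transcript_id", "predictor", "label"]).to_csv(
        paths["coding_labels"], sep="\t", index=False
    )

    paths["term_map"] = d / "term_map.tsv"
    pd.DataFrame(
        study.truth.term_map,
        columns=["gene_id", "term_id", "term_name", "category"],
    ).to_csv(paths["term_map"], sep="\t", index=False)

    paths["truth"] = d / "truth.json"
    study.truth.to_json(paths["truth"])

    paths["config"] = d / "pipeline_config.yaml"
    _write_pipeline_config(study.cfg, d, paths["config"])
    return paths


def _write_pipeline_config(cfg: SimConfig, d: Path, path: Path) -> None:
    import yaml

    doc = {
        "inputs": {
            "gtf": "annotation.gtf",
            "counts": {
                "mRNA": "counts_mrna.tsv",
                "lncRNA": "counts_lncrna.tsv",
                "circRNA": "counts_circrna.tsv",
                "miRNA": "counts_mirna.tsv",
            },
            "samples": "samples.tsv",
            "coding_labels": "coding_labels.tsv",
            "target_edges": "target_edges.tsv",
            "mirna_fasta": "mirna.fasta",
            "target_fasta": "targets.fasta",
            "term_map": "term_map.tsv",
            "truth": "truth.json",
        },
        "groups": {"group1": GROUP1, "group2": GROUP2},
        "thresholds": {
            "p_de": 0.05,
            "lfc": 1.0,
            "cis_window": 10_000,
            "scc": -0.7,
            "pcc": 0.9,
            "sponge_p": 0.05,
            "enrich_p": 0.05,
        },
        "dispersion": "estimate",
        "circ_triads": True,
        "seed": cfg.seed,
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
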