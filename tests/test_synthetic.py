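"""Generator behaviour: determinism, planted structure, count model moments."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from cernaforge import (
    SimConfig,
    SizingError,
    TruthSet,
    assign_cis_targets,
    generate_annotation,
    seed_match,
    simulate_counts,
    simulate_sequences,
    simulate_study,
    write_fixture,
)
from cernaforge.annotation import AnnotationSet
from cernaforge.core import CountMatrix
from cernaforge.synthetic import CIS_GAP_MAX, NONCIS_GAP_MIN, GROUP2

SMALL = dict(n_mrna=80, n_lncrna=30, n_circrna=10, n_mirna=20, n_triads=4)


def test_same_seed_gives_byte_identical_fixture(tmp_path):
    d1, d2 = tmp_path / "a", tmp_path / "b"
    cfg = SimConfig(**SMALL, seed=3)
    write_fixture(simulate_study(cfg), d1)
    write_fixture(simulate_study(SimConfig(**SMALL, seed=3)), d2)
    files = sorted(p.name for p in d1.iterdir())
    assert files == sorted(p.name for p in d2.iterdir())
    for name in files:
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name


def test_different_seed_changes_counts():
    a = simulate_study(SimConfig(**SMALL, seed=1))
    b = simulate_study(SimConfig(**SMALL, seed=2))
    assert not a.counts["mRNA"].values.equals(b.counts["mRNA"].values)


def test_cis_fraction_one_places_every_lncrna_within_band():
    ann, truth = generate_annotation(SimConfig(**SMALL, cis_fraction=1.0, seed=5))
    assert len(truth.cis_pairs) == SMALL["n_lncrna"]
    assert all(0 <= gap <= CIS_GAP_MAX for _l, _g, gap in truth.cis_pairs)


def test_cis_fraction_zero_yields_no_pairs_within_window():
    ann, truth = generate_annotation(SimConfig(**SMALL, cis_fraction=0.0, seed=5))
    assert truth.cis_pairs == []
    pairs = assign_cis_targets(
        ann.transcript_intervals("lncRNA"), ann.gene_intervals(), 10_000
    )
    assert pairs == []
    # and indeed every lncRNA is beyond the exclusion band from every gene
    assert NONCIS_GAP_MIN > 10_000


def test_planted_cis_gaps_rederivable_from_annotation():
    ann, truth = generate_annotation(SimConfig(**SMALL, seed=9))
    found = {
        (p.lncrna_id, p.gene_id): p.gap
        for p in assign_cis_targets(
            ann.transcript_intervals("lncRNA"), ann.gene_intervals(), 10_000
        )
    }
    assert found == {(l, g): gap for l, g, gap in truth.cis_pairs}


def test_lncrna_structure_and_decoys():
    cfg = SimConfig(**SMALL, n_decoy_short=3, n_decoy_monoexonic=2, seed=4)
    ann, truth = generate_annotation(cfg)
    for t in ann.by_biotype("lncRNA"):
        if t.transcript_id in truth.decoys["short"]:
            assert t.length < 200
        elif t.transcript_id in truth.decoys["monoexonic"]:
            assert t.n_exons < 2
        else:
            assert t.length >= 200 and t.n_exons >= 2
    for c in ann.by_biotype("circRNA"):
        assert c.host_gene_id in ann.genes


def test_insufficient_chromosome_capacity_names_parameters():
    cfg = SimConfig(**SMALL, n_chromosomes=1, chrom_length_bp=100_000, seed=1)
    with pytest.raises(SizingError, match="chrom_length_bp"):
        generate_annotation(cfg)


def test_unknown_truth_feature_raises_consistency_error():
    from cernaforge import ConsistencyError

    cfg = SimConfig(**SMALL, seed=2)
    ann, truth = generate_annotation(cfg)
    truth.features["mRNA"] = truth.features["mRNA"] + ["GHOST"]
    with pytest.raises(ConsistencyError, match="GHOST"):
        simulate_counts(ann, truth, cfg)


def test_poisson_limit_variance_matches_mean():
    """phi = 0 and constant library sizes give Poisson counts."""
    cfg = SimConfig(
        n_mrna=60, n_lncrna=10, n_circrna=5, n_mirna=5, n_triads=0,
        frac_de=0.0, nb_dispersion=0.0, n_per_group=50,
        library_size_range=(1_000_000, 1_000_000), seed=11,
    )
    ann, truth = generate_annotation(cfg)
    cm = simulate_counts(ann, truth, cfg)["mRNA"]
    vals = cm.values.to_numpy(dtype=float)
    m = vals.mean(axis=1)
    v = vals.var(axis=1, ddof=1)
    ratio = v[m > 5] / m[m > 5]
    assert np.all(ratio > 0.5) and np.all(ratio < 2.0)


def test_nb_marginal_moments():
    """Empirical variance tracks mu + phi mu^2 within 20% per mean stratum."""
    cfg = SimConfig(
        n_mrna=300, n_lncrna=10, n_circrna=5, n_mirna=5, n_triads=0,
        frac_de=0.0, nb_dispersion=0.1, n_per_group=150,
        library_size_range=(1_000_000, 1_000_000), seed=13,
    )
    ann, truth = generate_annotation(cfg)
    vals = simulate_counts(ann, truth, cfg)["mRNA"].values.to_numpy(dtype=float)
    m = vals.mean(axis=1)
    v = vals.var(axis=1, ddof=1)
    expect = m + 0.1 * m**2
    for lo, hi in ((50, 200), (200, 1000), (1000, np.inf)):
        sel = (m >= lo) & (m < hi)
        if sel.sum() < 10:
            continue
        rel = np.median(v[sel] / expect[sel])
        assert 0.8 < rel < 1.2, (lo, hi, rel)


def test_planted_de_effect_size_recovered():
    """A planted up feature shows an empirical log2 ratio near de_log2fc."""
    cfg = SimConfig(
        n_mrna=100, n_lncrna=10, n_circrna=5, n_mirna=5, n_triads=0,
        frac_de=0.2, de_log2fc=2.0, n_per_group=50, seed=17,
    )
    ann, truth = generate_annotation(cfg)
    cm = simulate_counts(ann, truth, cfg)["mRNA"]
    g2 = cm.samples_in(GROUP2)
    g1 = [s for s in cm.sample_ids if s not in g2]
    ups = [f for f, d in truth.de_features.items()
           if d == "up" and f.startswith("G")]
    assert ups
    lfcs = [
        np.log2(cm.values.loc[f, g2].mean() / cm.values.loc[f, g1].mean())
        for f in ups
    ]
    assert all(1.5 <= x <= 2.5 for x in lfcs)


def test_triad_members_anticorrelated_at_large_n():
    """miRNA vs mRNA Spearman is negative for >= 90% of planted triads."""
    cfg = SimConfig(
        n_mrna=100, n_lncrna=40, n_circrna=5, n_mirna=40, n_triads=20,
        triad_corr_strength=0.9, n_per_group=25, seed=19,
    )
    ann, truth = generate_annotation(cfg)
    counts = simulate_counts(ann, truth, cfg)
    neg = 0
    for _reg, mir, mrna in truth.triads:
        x = counts["miRNA"].values.loc[mir].to_numpy(dtype=float)
        y = counts["mRNA"].values.loc[mrna].to_numpy(dtype=float)
        if stats.spearmanr(x, y).statistic < 0:
            neg += 1
    assert neg >= 0.9 * len(truth.triads)


def test_every_planted_edge_has_a_recoverable_seed_site(small_study):
    edges = seed_match(
        small_study.mirna_seqs, small_study.target_seqs,
        target_classes={t: c for _m, t, c in small_study.truth.target_edges},
    )
    hit = {(e.mirna_id, e.target_id) for e in edges}
    for m, t, _c in small_study.truth.target_edges:
        assert (m, t) in hit
        pos = small_study.truth.seed_sites[(m, t)]
        found = next(e for e in edges if e.key() == (m, t))
        assert set(pos) <= set(found.positions)


def test_fixture_round_trips(small_study, tmp_path):
    paths = write_fixture(small_study, tmp_path)
    # counts round trip element-wise
    cm = small_study.counts["mRNA"]
    back = CountMatrix.from_tsv(paths["counts_mrna"], cm.groups, cm.group_order)
    assert back.values.equals(cm.values)
    # GTF round trip preserves exon structure
    ann2 = AnnotationSet.from_gtf(paths["gtf"])
    assert set(ann2.transcripts) == set(small_study.annotation.transcripts)
    for tid, t in small_study.annotation.transcripts.items():
        t2 = ann2.transcripts[tid]
        assert t2.exons == t.exons and t2.biotype == t.biotype
        assert t2.host_gene_id == t.host_gene_id
    # truth JSON round trip is lossless
    assert TruthSet.from_json(paths["truth"]) == small_study.truth
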