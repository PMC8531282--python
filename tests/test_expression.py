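"""FPKM, sample correlation, the exact NB test and the DE filter."""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from cernaforge import (
    DegenerateSampleError,
    DesignError,
    DomainError,
    SchemaError,
    exact_nb_test,
    filter_de,
    fpkm_normalize,
    presence_partition,
    sample_correlation,
)
from conftest import toy_counts


def binomial_two_sided(a: int, s: int, n1: int, n2: int) -> Fraction:
    """Exact minimum-likelihood two-sided binomial p, in rational arithmetic."""
    denom = (n1 + n2) ** s
    probs = [Fraction(comb(s, i) * n1**i * n2 ** (s - i), denom) for i in range(s + 1)]
    return sum(p for p in probs if p <= probs[a])


class TestFPKM:
    def test_formula(self):
        cm = toy_counts([[10, 10], [999_990, 999_990]], n1=1, n2=1,
                        lengths=[1000, 1000])
        f = fpkm_normalize(cm)
        assert f.iloc[0, 0] == pytest.approx(10.0, abs=0)

    def test_all_zero_feature_row_stays_zero(self):
        cm = toy_counts([[0, 0], [5, 7]], lengths=[500, 500])
        assert (fpkm_normalize(cm).iloc[0] == 0).all()

    def test_conservation_identity(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 500, size=(50, 8))
        counts[0] += 1  # no all-zero column
        cm = toy_counts(counts, n1=4, n2=4,
                        lengths=list(rng.integers(200, 5000, size=50)))
        f = fpkm_normalize(cm)
        T = cm.values.sum(axis=0).to_numpy(dtype=float)
        L = cm.lengths.to_numpy()
        recon = (f.to_numpy() * L[:, None] * T[None, :] / 1e9).sum(axis=0)
        assert np.allclose(recon, T, rtol=1e-9)

    def test_zero_total_sample_named(self):
        cm = toy_counts([[5, 0]], lengths=[100])
        with pytest.raises(DegenerateSampleError, match="B0"):
            fpkm_normalize(cm)

    def test_missing_lengths_rejected(self):
        with pytest.raises(SchemaError, match="lengths"):
            fpkm_normalize(toy_counts([[1, 1]]))


class TestSampleCorrelation:
    def test_duplicated_columns_correlate_perfectly(self):
        rng = np.random.default_rng(1)
        x = rng.random(20) * 100
        df = pd.DataFrame({"a": x, "b": x, "c": rng.random(20)})
        corr = sample_correlation(df)
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_negated_centered_sample_gives_minus_one(self):
        x = np.array([3.0, -1.0, 2.0, -4.0, 0.0])
        df = pd.DataFrame({"a": x, "b": -x})
        corr = sample_correlation(df, "pearson", log_transform=False)
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.random((30, 3)) * 50, columns=list("abc"))
        for method in ("pearson", "spearman"):
            corr = sample_correlation(df, method)
            assert np.array_equal(corr.values, corr.values.T)
            assert np.all(np.diag(corr) == 1.0)
            assert np.all(np.abs(corr.values) <= 1.0)

    def test_constant_sample_warns_not_crashes(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="constant"):
            corr = sample_correlation(df, log_transform=False)
        assert np.isnan(corr.loc["a", "b"])
        assert corr.loc["b", "b"] == 1.0

    def test_single_sample_rejected(self):
        with pytest.raises(DesignError):
            sample_correlation(pd.DataFrame({"a": [1.0, 2.0]}))


class TestExactNBTest:
    def test_identical_groups_give_null_result(self):
        cm = toy_counts([[7, 7], [30, 30]], n1=1, n2=1)
        res = exact_nb_test(cm, dispersion=0.0)
        assert np.allclose(res["log2fc"], 0.0)
        assert np.allclose(res["pvalue"], 1.0)

    def test_ten_versus_zero_matches_binomial(self):
        """Group sums 10 vs 0 at dispersion 0: p = 2/1024."""
        cm = toy_counts([[10, 0]], n1=1, n2=1)
        lib = pd.Series([100.0, 100.0], index=cm.values.columns)
        res = exact_nb_test(cm, dispersion=0.0, library_sizes=lib)
        assert res["pvalue"].iloc[0] == pytest.approx(2 / 1024, abs=1e-12)

    @pytest.mark.parametrize("n1,n2", [(1, 1), (2, 2), (1, 3)])
    def test_dispersion_zero_equals_binomial_oracle(self, n1, n2):
        """At phi=0 the conditional test is exactly binomial (sums <= 30)."""
        for a in range(0, 16):
            for b in range(0, 16):
                counts = np.zeros((1, n1 + n2))
                counts[0, 0] = a
                counts[0, n1] = b
                cm = toy_counts(counts, n1=n1, n2=n2)
                lib = pd.Series(1000.0, index=cm.values.columns)
                p = exact_nb_test(cm, 0.0, library_sizes=lib)["pvalue"].iloc[0]
                expect = float(binomial_two_sided(a, a + b, n1, n2))
                assert abs(p - expect) < 1e-10, (a, b, n1, n2)

    def test_group_label_swap_negates_lfc_keeps_p(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 200, size=(40, 8))
        cm = toy_counts(counts, n1=4, n2=4)
        cm_sw = toy_counts(counts, n1=4, n2=4)
        cm_sw.group_order = ("B", "A")
        r1 = exact_nb_test(cm, 0.05)
        r2 = exact_nb_test(cm_sw, 0.05)
        assert np.allclose(r1["pvalue"], r2["pvalue"], atol=1e-12)
        assert np.allclose(r1["log2fc"], -r2["log2fc"], atol=1e-12)

    def test_negative_dispersion_rejected(self):
        with pytest.raises(DomainError):
            exact_nb_test(toy_counts([[1, 2]]), dispersion=-0.5)

    def test_estimate_needs_replicates(self):
        with pytest.raises(DesignError, match="2 samples"):
            exact_nb_test(toy_counts([[1, 2]]), dispersion="estimate")

    def test_dispersion_estimate_recovers_truth(self):
        rng = np.random.default_rng(8)
        mu = np.exp(rng.normal(5, 1, size=1000))[:, None] * np.ones(8)
        counts = rng.poisson(rng.gamma(1 / 0.15, mu * 0.15))
        res = exact_nb_test(toy_counts(counts, n1=4, n2=4))
        assert 0.10 < res.attrs["dispersion"] < 0.20


class TestFilterDE:
    @pytest.mark.parametrize(
        "p,lfc,expected",
        [
            (0.05, 2.0, "not_de"),   # p threshold is strict
            (0.01, 1.0, "up"),       # lfc threshold is inclusive
            (0.01, -0.99, "not_de"), # below lfc magnitude
            (0.01, -1.0, "down"),
            (0.049999, 1.5, "up"),
        ],
    )
    def test_boundary_semantics(self, p, lfc, expected):
        df = pd.DataFrame({"log2fc": [lfc], "pvalue": [p],
                           "mean1": [1.0], "mean2": [1.0]}, index=["f"])
        _ann, part = filter_de(df)
        assert ("f" in part[expected]) and all(
            "f" not in part[k] for k in part if k != expected
        )

    def test_partition_is_disjoint_and_exhaustive(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(
            {"log2fc": rng.normal(0, 2, 200), "pvalue": rng.random(200)},
            index=[f"f{i}" for i in range(200)],
        )
        _ann, part = filter_de(df)
        ids = part["up"] + part["down"] + part["not_de"]
        assert sorted(ids) == sorted(df.index)
        assert len(set(ids)) == len(ids)

    def test_bh_adjustment_is_more_conservative(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(
            {"log2fc": np.full(100, 2.0), "pvalue": rng.random(100) * 0.2},
            index=[f"f{i}" for i in range(100)],
        )
        _a1, raw = filter_de(df)
        _a2, bh = filter_de(df, adjust="BH")
        assert set(bh["up"]) <= set(raw["up"])


class TestPresencePartition:
    def test_examples_and_conservation(self):
        cm = toy_counts(
            [[3, 0, 0, 0],   # group1 specific
             [0, 0, 1, 0],   # group2 specific
             [1, 0, 2, 0],   # shared
             [0, 0, 0, 0]],  # unexpressed
            n1=2, n2=2,
        )
        part = presence_partition(cm)
        assert part["group1_specific"] == {"f0"}
        assert part["group2_specific"] == {"f1"}
        assert part["shared"] == {"f2"}
        assert part["unexpressed"] == {"f3"}
        n_expr = sum(len(part[k]) for k in
                     ("group1_specific", "group2_specific", "shared"))
        assert n_expr + len(part["unexpressed"]) == 4
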