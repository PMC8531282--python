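"""Normalization, sample correlation and two-group differential expression.

The DE test is a conditional exact negative-binomial test for a two-group
design: counts are scaled to a common effective library size and rounded,
a common dispersion is estimated by method of moments (or supplied), and
each feature's group-1 sum is tested against its conditional distribution
given the total, with a two-sided minimum-likelihood rejection rule. At
dispersion zero the conditional distribution is exactly binomial.

Significance follows the study's filter: p < 0.05 (raw, strict) and
|log2 fold change| >= 1 (inclusive), fold changes oriented group2 over
group1 with a 0.5 pseudocount on scaled group means.
"""

from __future__ import annotations

import warnings
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    CountMatrix,
    DegenerateSampleError,
    DesignError,
    DomainError,
    SchemaError,
)

__all__ = [
    "fpkm_normalize",
    "cpm_normalize",
    "sample_correlation",
    "exact_nb_test",
    "filter_de",
    "presence_partition",
]


def fpkm_normalize(counts: CountMatrix) -> pd.DataFrame:
    """FPKM_fs = c_fs * 1e9 / (L_f * T_s), with T_s the sample's total counts."""
    if counts.lengths is None:
        raise SchemaError("FPKM requires feature lengths")
    totals = counts.values.sum(axis=0).astype(float)
    zero = totals[totals == 0]
    if len(zero):
        raise DegenerateSampleError(
            f"sample(s) with zero total counts: {list(zero.index)}"
        )
    c = counts.values.to_numpy(dtype=float)
    L = counts.lengths.to_numpy(dtype=float)[:, None]
    T = totals.to_numpy()[None, :]
    return pd.DataFrame(
        c * 1e9 / (L * T), index=counts.values.index, columns=counts.values.columns
    )


def cpm_normalize(counts: CountMatrix) -> pd.DataFrame:
    """Counts per million, for classes without a meaningful length (circRNA, miRNA)."""
    totals = counts.values.sum(axis=0).astype(float)
    zero = totals[totals == 0]
    if len(zero):
        raise DegenerateSampleError(
            f"sample(s) with zero total counts: {list(zero.index)}"
        )
    return counts.values.div(totals, axis=1) * 1e6


def sample_correlation(
    expr: pd.DataFrame,
    method: Literal["pearson", "spearman"] = "pearson",
    log_transform: bool = True,
) -> pd.DataFrame:
    """Sample-by-sample correlation matrix on log2(expr + 1).

    Constant sample vectors yield missing values off-diagonal (with a
    warning); the diagonal is forced to 1.
    """
    if expr.shape[1] < 2:
        raise DesignError("sample correlation requires >= 2 samples")
    if method not in ("pearson", "spearman"):
        raise DomainError(f"unknown correlation method {method!r}")
    x = np.log2(expr + 1.0) if log_transform else expr
    constant = [s for s in x.columns if x[s].nunique() <= 1]
    if constant:
        warnings.warn(
            f"constant sample vector(s), correlation undefined: {constant}",
            stacklevel=2,
        )
    corr = x.corr(method=method)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def _common_dispersion(scaled: np.ndarray, idx1: np.ndarray, idx2: np.ndarray) -> float:
    """Method-of-moments common NB dispersion across features, floored at 0.

    Pools the per-feature, per-group excess variance: phi = sum(v - m) / sum(m^2)
    over both groups, using unbiased within-group variances.
    """
    num = 0.0
    den = 0.0
    for idx in (idx1, idx2):
        sub = scaled[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        keep = m > 0
        num += float((v[keep] - m[keep]).sum())
        den += float((m[keep] ** 2).sum())
    if den == 0:
        return 0.0
    return max(0.0, num / den)


def _conditional_exact_p(s1: int, total: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided minimum-likelihood p for the observed group-1 sum.

    Conditional on the total, the group-1 sum of NB counts with common mean
    and dispersion follows a distribution proportional to
    ``NB(a; n1/phi, .) * NB(total-a; n2/phi, .)``; at phi = 0 this is exactly
    ``Binomial(total, n1/(n1+n2))``. The p-value sums the probabilities of
    all outcomes no more likely than the observed one.
    """
    if total == 0:
        return 1.0
    a = np.arange(total + 1)
    if phi == 0.0:
        logp = stats.binom.logpmf(a, total, n1 / (n1 + n2))
    else:
        mu = total / (n1 + n2)
        r1, m1 = n1 / phi, n1 * mu
        r2, m2 = n2 / phi, n2 * mu
        logp = stats.nbinom.logpmf(a, r1, r1 / (r1 + m1)) + stats.nbinom.logpmf(
            a[::-1], r2, r2 / (r2 + m2)
        )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    p_obs = prob[s1]
    return float(min(1.0, prob[prob <= p_obs * (1.0 + 1e-12)].sum()))


def exact_nb_test(
    counts: CountMatrix,
    dispersion: float | Literal["estimate"] = "estimate",
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Exact two-group NB test per feature.

    Parameters
    ----------
    counts
        Count matrix with a two-group design.
    dispersion
        Common NB dispersion phi >= 0, or ``"estimate"`` for the
        method-of-moments estimate (requires >= 2 samples per group).
    library_sizes
        Effective library size per sample; defaults to column totals.

    Returns
    -------
    DataFrame indexed by feature with columns mean1, mean2, log2fc, pvalue.
    """
    g1, g2 = counts.group_order
    s1_ids = counts.samples_in(g1)
    s2_ids = counts.samples_in(g2)
    if not s1_ids or not s2_ids:
        raise DesignError("both groups need at least one sample")

    raw = counts.values.to_numpy(dtype=float)
    if library_sizes is None:
        lib = raw.sum(axis=0)
    else:
        lib = library_sizes.reindex(counts.values.columns).to_numpy(dtype=float)
    dead = [s for s, t in zip(counts.values.columns, lib) if not t > 0]
    if dead:
        raise DegenerateSampleError(f"sample(s) with zero library size: {dead}")

    scaled = np.rint(raw * (lib.mean() / lib)[None, :])
    cols = list(counts.values.columns)
    idx1 = np.array([cols.index(s) for s in s1_ids])
    idx2 = np.array([cols.index(s) for s in s2_ids])

    if dispersion == "estimate":
        if len(s1_ids) < 2 or len(s2_ids) < 2:
            raise DesignError(
                "dispersion estimation needs >= 2 samples per group; "
                "pass an explicit dispersion"
            )
        phi = _common_dispersion(scaled, idx1, idx2)
    else:
        phi = float(dispersion)
        if phi < 0:
            raise DomainError(f"dispersion must be >= 0, got {phi}")

    n1, n2 = len(idx1), len(idx2)
    sum1 = scaled[:, idx1].sum(axis=1)
    sum2 = scaled[:, idx2].sum(axis=1)
    mean1 = sum1 / n1
    mean2 = sum2 / n2
    log2fc = np.log2((mean2 + 0.5) / (mean1 + 0.5))
    pvals = np.array(
        [
            _conditional_exact_p(int(a), int(a + b), n1, n2, phi)
            for a, b in zip(sum1, sum2)
        ]
    )
    out = pd.DataFrame(
        {"mean1": mean1, "mean2": mean2, "log2fc": log2fc, "pvalue": pvals},
        index=counts.values.index,
    )
    out.attrs["dispersion"] = phi
    return out


def filter_de(
    records: pd.DataFrame,
    p_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
    adjust: Literal["none", "BH"] = "none",
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Apply the significance filter and partition features.

    Significant iff p < p_threshold (strict) AND |log2fc| >= lfc_threshold
    (inclusive). ``adjust="BH"`` tests Benjamini-Hochberg adjusted p-values
    against the same threshold instead of raw ones.

    Returns the annotated record table (direction, significant columns
    added) and the partition ``{"up": [...], "down": [...], "not_de": [...]}``.
    """
    out = records.copy()
    p = out["pvalue"].to_numpy(dtype=float)
    if adjust == "BH":
        p = stats.false_discovery_control(p, method="bh")
        out["padj"] = p
    elif adjust != "none":
        raise DomainError(f"unknown adjust method {adjust!r}")
    sig = (p < p_threshold) & (np.abs(out["log2fc"].to_numpy()) >= lfc_threshold)
    direction = np.where(~sig, "none", np.where(out["log2fc"] > 0, "up", "down"))
    out["direction"] = direction
    out["significant"] = sig
    partition = {
        "up": list(out.index[(out["direction"] == "up")]),
        "down": list(out.index[(out["direction"] == "down")]),
        "not_de": list(out.index[~sig]),
    }
    return out, partition


def presence_partition(counts: CountMatrix) -> dict[str, set[str]]:
    """Group-specific / shared presence sets (the Venn-diagram partition).

    A feature is expressed in a group iff its raw count is >= 1 in at least
    one sample of that group. All-zero features land in ``unexpressed``;
    ``group1_specific + group2_specific + shared`` equals the number of
    expressed features.
    """
    g1, g2 = counts.group_order
    in1 = (counts.values[counts.samples_in(g1)] >= 1).any(axis=1)
    in2 = (counts.values[counts.samples_in(g2)] >= 1).any(axis=1)
    idx = counts.values.index
    return {
        "group1_specific": set(idx[in1 & ~in2]),
        "group2_specific": set(idx[in2 & ~in1]),
        "shared": set(idx[in1 & in2]),
        "unexpressed": set(idx[~in1 & ~in2]),
    }
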