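"""Hypergeometric over-representation analysis.

Both the functional-term enrichment and the ceRNA shared-sponge test use
the upper-tail hypergeometric probability

    P(X >= k) = sum_{i=k}^{min(K, n)} C(K, i) C(N-K, n-i) / C(N, n)

for a study set of size n drawn from a background of size N of which K
carry the property. The sum is evaluated in log space (log-gamma terms
combined with logsumexp), which keeps it exact to well beyond 10
significant digits for backgrounds up to 1e4.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import false_discovery_control

from .core import DomainError, SchemaError

__all__ = ["HypergeomResult", "hypergeom_sf", "enrich", "read_term_map"]


@dataclass
class HypergeomResult:
    term_id: str
    term_name: str
    category: str
    k: int  # study genes carrying the term
    n: int  # study size
    K: int  # background genes carrying the term
    N: int  # background size
    p: float
    padj: float | None = None
    significant: bool = False


def _log_comb(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k)."""
    for name, v in (("k", k), ("N", N), ("K", K), ("n", n)):
        if int(v) != v or v < 0:
            raise DomainError(f"{name} must be a non-negative integer, got {v}")
    k, N, K, n = int(k), int(N), int(K), int(n)
    if K > N or n > N:
        raise DomainError(f"K={K} and n={n} must not exceed N={N}")
    if k > min(K, n):
        raise DomainError(f"k={k} exceeds min(K, n)={min(K, n)}")
    if k <= max(0, n + K - N):
        return 1.0
    i = np.arange(k, min(K, n) + 1)
    log_terms = _log_comb(K, i) + _log_comb(N - K, n - i) - _log_comb(N, n)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def read_term_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "term_id"}.issubset(df.columns):
        raise SchemaError("term map needs at least columns gene_id, term_id")
    for col, default in (("term_name", ""), ("category", "")):
        if col not in df.columns:
            df[col] = default
    return df[["gene_id", "term_id", "term_name", "category"]]


def enrich(
    study_set: Iterable[str],
    background_set: Iterable[str],
    term_map: pd.DataFrame,
    p_threshold: float = 0.05,
    adjust: Literal["none", "BH"] = "none",
    drop_unannotated: bool = False,
) -> list[HypergeomResult]:
    """Over-representation of terms in a study gene set.

    The study set must be a subset of the background. Genes without any
    term annotation stay in the background size N unless
    ``drop_unannotated`` restricts N (and the study) to annotated genes.
    Significance is raw p < threshold by default; ``adjust="BH"`` tests
    BH-adjusted p-values instead. Results are sorted ascending by p with
    a stable term-id tiebreak.
    """
    study = set(study_set)
    background = set(background_set)
    outside = sorted(study - background)
    if outside:
        raise SchemaError(f"study genes outside the background: {outside}")

    ann = term_map[term_map["gene_id"].isin(background)]
    if drop_unannotated:
        annotated = set(ann["gene_id"])
        background = background & annotated
        study = study & annotated
    N = len(background)
    n = len(study)

    meta: dict[str, tuple[str, str]] = {}
    members: dict[str, set[str]] = {}
    for g, t, name, cat in ann.itertuples(index=False):
        members.setdefault(t, set()).add(g)
        meta.setdefault(t, (name, cat))

    results: list[HypergeomResult] = []
    for t in sorted(members):
        K = len(members[t])
        k = len(members[t] & study)
        if k == 0:
            continue
        name, cat = meta[t]
        results.append(
            HypergeomResult(t, name, cat, k, n, K, N, hypergeom_sf(k, N, K, n))
        )
    if adjust == "BH" and results:
        padj = false_discovery_control([r.p for r in results], method="bh")
        for r, q in zip(results, padj):
            r.padj = float(q)
    elif adjust not in ("none", "BH"):
        raise DomainError(f"unknown adjust method {adjust!r}")
    for r in results:
        r.significant = (r.padj if adjust == "BH" else r.p) < p_threshold
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def results_to_frame(results: Sequence[HypergeomResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.term_id, r.term_name, r.category, r.k, r.n, r.K, r.N, r.p,
             r.padj if r.padj is not None else "", r.significant)
            for r in results
        ],
        columns=["term_id", "term_name", "category", "k", "n", "K", "N",
                 "pvalue", "padj", "significant"],
    )
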