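"""Structural and evidence filters defining the lncRNA and circRNA candidate sets.

A lncRNA candidate is accepted iff its spliced length is >= 200 bp, it has
>= 2 exons, and both coding-potential predictors call it noncoding. A
circRNA is retained iff its back-splice junction count is >= 1 in at least
two distinct samples, regardless of group.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .annotation import TranscriptRecord
from .core import CountMatrix, SchemaError

REJECTION_ORDER = ("length", "exons", "coding")


@dataclass
class FilterTally:
    accepted: list[str]
    rejected: dict[str, list[str]]  # rule -> ids, first-failing-rule attribution

    @property
    def n_input(self) -> int:
        return len(self.accepted) + sum(len(v) for v in self.rejected.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [("accepted", t) for t in self.accepted]
        for rule in REJECTION_ORDER:
            rows += [(f"rejected_{rule}", t) for t in self.rejected[rule]]
        return pd.DataFrame(rows, columns=["status", "transcript_id"])


def read_coding_labels(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a (transcript_id, predictor, label) TSV into a nested mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"transcript_id", "predictor", "label"}
    if not need.issubset(df.columns):
        raise SchemaError(f"coding label table needs columns {sorted(need)}")
    out: dict[str, dict[str, str]] = {}
    for t, p, l in df.itertuples(index=False):
        out.setdefault(t, {})[p] = l
    return out


def filter_lncrna_candidates(
    transcripts: Iterable[TranscriptRecord],
    coding_labels: Mapping[str, Mapping[str, str]],
    min_length: int = 200,
    min_exons: int = 2,
) -> FilterTally:
    """Apply the structural + two-predictor noncoding filter.

    Rejections are attributed to the first failing rule in the fixed order
    length -> exons -> coding, so tallies are deterministic.
    """
    candidates = sorted(transcripts, key=lambda t: t.transcript_id)
    missing = [
        t.transcript_id
        for t in candidates
        if len(coding_labels.get(t.transcript_id, {})) < 2
    ]
    if missing:
        raise SchemaError(
            f"candidates missing coding-potential labels from two predictors: {missing}"
        )
    accepted: list[str] = []
    rejected: dict[str, list[str]] = {r: [] for r in REJECTION_ORDER}
    for t in candidates:
        if t.length < min_length:
            rejected["length"].append(t.transcript_id)
        elif t.n_exons < min_exons:
            rejected["exons"].append(t.transcript_id)
        elif any(
            label != "noncoding" for label in coding_labels[t.transcript_id].values()
        ):
            rejected["coding"].append(t.transcript_id)
        else:
            accepted.append(t.transcript_id)
    return FilterTally(accepted=accepted, rejected=rejected)


def filter_circrna(circ_counts: CountMatrix, min_samples: int = 2) -> list[str]:
    """Retain circRNAs with a count >= 1 in at least ``min_samples`` samples."""
    if circ_counts.values.shape[1] < min_samples:
        raise SchemaError(
            f"circRNA filter needs >= {min_samples} samples, "
            f"got {circ_counts.values.shape[1]}"
        )
    n_expressed = (circ_counts.values >= 1).sum(axis=1)
    return list(circ_counts.values.index[n_expressed >= min_samples])
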