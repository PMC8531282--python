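"""Shared containers and error types.

The pipeline passes expression data around as a :class:`CountMatrix`
(features x samples integer counts plus a two-group sample design) and
plain :class:`pandas.DataFrame` objects for normalized expression, which
keep the same axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class PipelineError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(PipelineError, ValueError):
    """Input table or annotation violates the expected schema."""


class SizingError(PipelineError, ValueError):
    """A simulation request does not fit the configured capacity."""


class ConsistencyError(PipelineError, ValueError):
    """Two inputs that must agree (e.g. annotation and truth) do not."""


class DegenerateSampleError(PipelineError, ValueError):
    """A sample is unusable for the requested normalization (e.g. zero total)."""


class DesignError(PipelineError, ValueError):
    """The sample design does not support the requested test."""


class DomainError(PipelineError, ValueError):
    """A numeric argument is outside its mathematical domain."""


@dataclass
class CountMatrix:
    """Integer read counts for one RNA class with a two-group design.

    Parameters
    ----------
    values
        features x samples DataFrame of non-negative integers. The index
        holds feature ids, the columns sample ids; both must be unique.
    groups
        Mapping sample id -> group label. Exactly two labels must occur and
        every sample column must be labelled.
    group_order
        The (group1, group2) orientation used for fold changes
        (group2 over group1). Defaults to the sorted pair of labels.
    lengths
        Optional per-feature transcript length in bp, required for FPKM.
    """

    values: pd.DataFrame
    groups: Mapping[str, str]
    group_order: tuple[str, str] | None = None
    lengths: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise SchemaError("duplicate feature ids in count matrix")
        if v.columns.has_duplicates:
            raise SchemaError("duplicate sample ids in count matrix")
        arr = v.to_numpy()
        if arr.size and arr.min() < 0:
            raise SchemaError("negative entries in count matrix")
        missing = [s for s in v.columns if s not in self.groups]
        if missing:
            raise SchemaError(f"samples without a group label: {missing}")
        labels = sorted({self.groups[s] for s in v.columns})
        if len(labels) != 2:
            raise DesignError(
                f"expected exactly two groups among samples, found {labels}"
            )
        if self.group_order is None:
            self.group_order = (labels[0], labels[1])
        elif sorted(self.group_order) != labels:
            raise DesignError(
                f"group_order {self.group_order} does not match labels {labels}"
            )
        if self.lengths is not None:
            absent = v.index.difference(self.lengths.index)
            if len(absent):
                raise SchemaError(
                    f"lengths missing for {len(absent)} features, e.g. {list(absent[:3])}"
                )
            self.lengths = self.lengths.reindex(v.index).astype(float)
            if (self.lengths <= 0).any():
                raise SchemaError("feature lengths must be positive")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    def subset_features(self, ids: Sequence[str]) -> "CountMatrix":
        keep = [i for i in self.values.index if i in set(ids)]
        lengths = self.lengths.loc[keep] if self.lengths is not None else None
        return CountMatrix(
            self.values.loc[keep].copy(), dict(self.groups), self.group_order, lengths
        )

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        groups: Mapping[str, str],
        group_order: tuple[str, str] | None = None,
        lengths: pd.Series | None = None,
    ) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        if not np.issubdtype(df.to_numpy().dtype, np.number):
            raise SchemaError(f"non-numeric entries in count table {path}")
        return cls(df.astype(np.int64), dict(groups), group_order, lengths)


def read_sample_table(path: str | Path) -> dict[str, str]:
    """Read a two-column sample table (sample_id, group) as a group mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"sample_id", "group"}
    if not need.issubset(df.columns):
        raise SchemaError(f"sample table {path} must have columns {sorted(need)}")
    return dict(zip(df["sample_id"], df["group"]))


def write_sample_table(groups: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(groups), "group": [groups[s] for s in groups]}
    ).to_csv(path, sep="\t", index=False)
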