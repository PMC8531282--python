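"""Shared fixtures: a default synthetic study, its on-disk form, and one
full pipeline run, all session-scoped so the expensive work happens once."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cernaforge import CountMatrix, SimConfig, simulate_study, write_fixture
from cernaforge.pipeline import run_pipeline, validate_config


@pytest.fixture(scope="session")
def default_study():
    """The default study conditions (2000 mRNAs, 4 vs 4, 30 triads), seed 1."""
    return simulate_study(SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_study():
    """A small study for structural tests (fast to regenerate)."""
    return simulate_study(
        SimConfig(
            n_mrna=120, n_lncrna=40, n_circrna=20, n_mirna=30, n_triads=5,
            n_decoy_short=3, n_decoy_monoexonic=2, n_decoy_coding=2, seed=7,
        )
    )


@pytest.fixture(scope="session")
def fixture_dir(default_study, tmp_path_factory):
    d = tmp_path_factory.mktemp("fixture")
    write_fixture(default_study, d)
    return d


@pytest.fixture(scope="session")
def pipeline_run(fixture_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("run")
    cfg = validate_config(fixture_dir / "pipeline_config.yaml")
    report = run_pipeline(cfg, out)
    return report, out


def toy_counts(
    values: np.ndarray | list,
    n1: int = 1,
    n2: int = 1,
    lengths: list | None = None,
) -> CountMatrix:
    """Small count matrix helper: first n1 columns group A, rest group B."""
    arr = np.asarray(values)
    samples = [f"A{i}" for i in range(n1)] + [f"B{i}" for i in range(n2)]
    groups = {s: s[0] for s in samples}
    df = pd.DataFrame(
        arr, index=[f"f{i}" for i in range(arr.shape[0])], columns=samples
    )
    lser = (
        pd.Series(lengths, index=df.index, dtype=float)
        if lengths is not None
        else None
    )
    return CountMatrix(df, groups, ("A", "B"), lser)
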