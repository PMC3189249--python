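"""Shared fixtures: small and full-scale simulated studies.

Everything is generated at test time from fixed seeds; session scope keeps
the expensive full-scale pipeline run shared across the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from promethylome import PipelineConfig, SimulationConfig, run_pipeline
from promethylome.simulate import simulate_study

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_study():
    """Small simulated study (400 genes) for unit-level checks."""
    return simulate_study(SimulationConfig(n_genes=400, seed=7))


@pytest.fixture(scope="session")
def small_result():
    """Full pipeline on a small study (800 genes)."""
    cfg = PipelineConfig(sim=SimulationConfig(n_genes=800, seed=3), seed=3, n_perm=200)
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def full_result():
    """Full pipeline at the default study scale (5000 genes, seed 1)."""
    cfg = PipelineConfig(sim=SimulationConfig(n_genes=5000, seed=1), seed=1, n_perm=1000)
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def null_study():
    """Study with no planted methylation at all (pure null arrays)."""
    cfg = SimulationConfig(
        n_genes=1200,
        seed=21,
        frac_common_germline=0.0,
        frac_tdmr=0.0,
        frac_imprinted=0.0,
        frac_cluster_mosaic=0.0,
        frac_es_somatic=0.0,
        frac_low_cpg_constitutive=0.0,
    )
    return simulate_study(cfg)


def toy_matrix(values: dict[str, np.ndarray], positions: np.ndarray, chrom: str = "chr1"):
    """Build a small IntensityMatrix from named array columns."""
    from promethylome.scoring import IntensityMatrix

    n = len(positions)
    probes = pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(n)],
            "chrom": chrom,
            "start": positions,
            "end": positions + 50,
        }
    )
    meta = []
    cols = []
    for name, col in values.items():
        sample, channel, rep = name.split(".")
        meta.append((name, sample, channel, int(rep)))
        cols.append(np.asarray(col, dtype=float))
    arrays = pd.DataFrame(meta, columns=["name", "sample", "channel", "replicate"])
    return IntensityMatrix(probes=probes, values=np.column_stack(cols), arrays=arrays)
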