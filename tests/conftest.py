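"""Shared fixtures: small simulated datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from fgm import simulate
from fgm.pipeline import RunConfig, run_pipeline


def random_dna(n: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def small_genome() -> simulate.Genome:
    return simulate.generate_genome(1_000_000, 0.0, 42)


@pytest.fixture(scope="session")
def desk_library(small_genome):
    """Eight ~50 kb clones on the 1 Mb genome (a <0.5X desk-scale library)."""
    model = simulate.LibraryModel().scaled(50_000, n_clones=8)
    return simulate.simulate_library(small_genome, model, seed=7)


@pytest.fixture(scope="session")
def toy_run():
    """Error-free end-to-end pipeline run on a 300 kb genome (truth-checked).

    A 4X library of 48 x 25 kb clones in 6D/16-pool solid pools at 10X
    per-pool depth; four prefix motifs give enough landmark density for
    25 kb clones.  The frequency filter is off (error-free reads create no
    false elements) and the candidate bound m_max exceeds the local clone
    multiplicity of a 4X library.
    """
    cfg = RunConfig(
        genome_length=300_000, n_clones=48, mean_insert=25_000,
        dimension=6, pools_per_dim=16, depth=10, with_errors=False,
        filter_freq=0, m_max=14, seed=3, marker_spacing=12_000,
        seq_mean_len=5_000, min_frac=0.3,
        prefixes=("GGATCC", "GAATTC", "TCTAGA", "CTCGAG"),
    )
    return run_pipeline(cfg)
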