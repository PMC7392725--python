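import numpy as np
import pandas as pd
import pytest

from medipdiff import SimulationConfig, simulate_experiment
from medipdiff.demo import demo_pfms


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A fast simulation: 400 kb genome, ~60 reads/bin/condition."""
    params = dict(
        genome_length=400_000,
        n_chromosomes=2,
        n_rfm_peaks=15,
        n_mfr_peaks=15,
        flank_size=2_000,
        n_snps=150,
        n_reads_ct=120_000,
        n_reads_kd=120_000,
        n_tfbs_planted=50,
        n_background_motifs_per_tf=20,
        seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture(scope="session")
def pfms():
    return demo_pfms()


@pytest.fixture(scope="session")
def small_experiment(pfms):
    """One simulated experiment shared by read-only tests."""
    config = small_config(seed=0)
    sequences, gt, reads = simulate_experiment(config, pfms)
    return config, sequences, gt, reads


def reads_frame(rows):
    """Helper: build a read DataFrame from (chrom, start, end) tuples."""
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["name"] = [f"r{i}" for i in range(len(df))]
    df["score"] = 0
    df["strand"] = "."
    return df
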