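import numpy as np
import pandas as pd
import pytest

from barclean import ReadCountTable, SampleMeta, SimulationConfig, simulate_experiment


def make_table(rows: dict[str, list[int]], lane_id: str = "lane1",
               pair_replicates: bool = True) -> ReadCountTable:
    """Build a small count table from {barcode: per-sample counts}."""
    n_samples = len(next(iter(rows.values())))
    samples = []
    for i in range(n_samples):
        group = f"g{i // 2}" if pair_replicates else f"g{i}"
        samples.append(SampleMeta(sample_id=f"s{i}", lane_id=lane_id,
                                  replicate_group=group))
    frame = pd.DataFrame(
        {s.sample_id: [rows[b][i] for b in rows] for i, s in enumerate(samples)},
        index=list(rows),
        dtype=np.int64,
    )
    return ReadCountTable(frame, samples)


@pytest.fixture(scope="session")
def default_lane():
    """One default-condition simulated lane (20-clone two-fold training mix)."""
    tables, truth = simulate_experiment(SimulationConfig(seed=1))
    return tables["lane1"], truth


@pytest.fixture(scope="session")
def small_sim_config():
    """A miniature configuration for fast end-to-end tests."""
    return SimulationConfig(
        n_mothers=5,
        smallest_clone=4.0,
        n_replicate_groups=3,
        errors_per_mother=2,
        noise_variants_per_mother=5,
        contaminant_count=1,
        pcr_error_rate=0.0,
        reads_per_sample=20_000,
        seed=7,
    )
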