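import numpy as np
import pandas as pd
import pytest

from txquant import InfReps, QuantResult, SimConfig, simulate_truth


def tx_result_from_truth(truth, with_reps=False):
    """Assemble an in-memory transcript-level QuantResult from a SimTruth."""
    reps = None
    if with_reps and truth.bootstraps is not None:
        reps = InfReps(
            n_reps=truth.bootstraps.shape[0],
            per_sample=[truth.bootstraps[:, :, j]
                        for j in range(truth.n_samples)],
        )
    return QuantResult(
        abundance=pd.DataFrame(truth.abundance, index=truth.tx_ids,
                               columns=truth.sample_ids),
        counts=pd.DataFrame(truth.counts, index=truth.tx_ids,
                            columns=truth.sample_ids),
        length=pd.DataFrame(truth.eff_length, index=truth.tx_ids,
                            columns=truth.sample_ids),
        level="transcript",
        inf_reps=reps,
    )


def max_rel_err(a, b, floor=1e-12):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.max(np.abs(a - b) / np.maximum(np.abs(b), floor)))


@pytest.fixture(scope="session")
def small_truth():
    return simulate_truth(SimConfig(n_genes=30, n_samples=4, seed=42,
                                    n_bootstraps=5))


@pytest.fixture(scope="session")
def desk_truth():
    """Desk-scale default configuration: 250 genes, 1-4 tx/gene, 6 samples."""
    return simulate_truth(SimConfig(seed=7, n_bootstraps=20))
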