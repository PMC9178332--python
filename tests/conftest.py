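import numpy as np
import pandas as pd
import pytest

from herbdissect import synthetic_data
from herbdissect.synthetic_data import SimConfig


@pytest.fixture(scope="session")
def default_sim():
    """One full-size simulated experiment (seed 7), shared across tests."""
    cfg = SimConfig(seed=7)
    counts, samples, lengths, ann, truth = synthetic_data.simulate_experiment(cfg)
    return {
        "config": cfg,
        "counts": counts,
        "samples": samples,
        "lengths": lengths,
        "annotation": ann,
        "truth": truth,
    }


@pytest.fixture()
def small_counts():
    """Tiny deterministic two-treatment count matrix."""
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(50)]
    samples = ["control_r1", "control_r2", "control_r3", "trt_r1", "trt_r2", "trt_r3"]
    counts = pd.DataFrame(
        rng.poisson(100, size=(50, 6)), index=pd.Index(genes, name="gene_id"), columns=samples
    )
    meta = pd.DataFrame(
        {
            "sample_id": samples,
            "treatment": ["control"] * 3 + ["trt"] * 3,
            "replicate": [1, 2, 3, 1, 2, 3],
        }
    )
    return counts, meta
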