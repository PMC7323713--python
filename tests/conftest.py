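import numpy as np
import pytest

from somakit.sv import classify_all, filter_svs
from somakit.synthetic import SimulationConfig, simulate_cohort, synthetic_genes


@pytest.fixture(scope="session")
def cohort():
    """One default 20-sample synthetic cohort with ground truth."""
    cfg = SimulationConfig(seed=1)
    snvs, svs, segments, clinical, truth = simulate_cohort(cfg)
    kept, _ = filter_svs(classify_all(svs))
    return {"config": cfg, "snvs": snvs, "svs": svs, "kept": kept,
            "segments": segments, "clinical": clinical, "truth": truth,
            "genes": synthetic_genes(cfg)}


@pytest.fixture
def rng():
    return np.random.default_rng(42)
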