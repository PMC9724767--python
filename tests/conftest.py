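import numpy as np
import pandas as pd
import pytest

from episig import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale planted-signature cohort shared by read-only tests."""
    cfg = SimulationConfig(
        n_probes=2000, n_signature_probes=60, delta_beta=0.2,
        n_cases=8, n_controls=80, n_reference=40, noise_sd=0.4,
        n_age_probes=100, n_sex_probes=50, n_batch_probes=50, seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def tiny_beta():
    """Deterministic 6-probe x 6-sample beta matrix with clean values."""
    rng = np.random.default_rng(5)
    values = rng.uniform(0.05, 0.95, (6, 6))
    return pd.DataFrame(
        values,
        index=pd.Index([f"cg{i:05d}" for i in range(6)], name="probe_id"),
        columns=[f"s{i}" for i in range(6)],
    )
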