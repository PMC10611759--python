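import numpy as np
import pytest

from domaincoupling import synthetic_data as sim
from domaincoupling.types import PeptideRecord, UptakeSeries


@pytest.fixture
def peptide():
    return PeptideRecord(protein_state="WT", start=505, end=511,
                         sequence="YGIFLYG")


@pytest.fixture
def noiseless_mono_series():
    """Exact mono-exponential uptake series (A0=10, A=60, k=0.01/s)."""
    spec = sim.UptakeSimSpec(a0=10.0, amplitudes=(60.0,), rates=(0.01,),
                             noise_sd=0.0, timepoints=(10, 60, 240, 1200),
                             n_replicates=1)
    return sim.simulate_uptake(spec)


def make_uptake(seed, rates=(5e-3,), amplitudes=(70.0,), a0=5.0,
                noise_sd=1.5, timepoints=sim.DEFAULT_TIMEPOINTS,
                n_replicates=3, state="sim"):
    spec = sim.UptakeSimSpec(a0=a0, amplitudes=amplitudes, rates=rates,
                             noise_sd=noise_sd, timepoints=timepoints,
                             n_replicates=n_replicates, seed=seed)
    return sim.simulate_uptake(spec, state=state), spec
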