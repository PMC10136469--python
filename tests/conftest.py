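import numpy as np
import pytest
from hypothesis import settings

import hyperdyad as hd
from hyperdyad.preprocess import preprocess_cohort
from hyperdyad.session import small_layout

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=40)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config():
    return hd.AnalysisConfig()


@pytest.fixture(scope="session")
def timeline():
    return hd.gen_timeline(0)


def make_cohort(n_couples, n_controls, seed, *, amplitudes=None, hrf=0.02,
                n_channels=3, pair=(1, 2), lag=0.0):
    """Reduced-montage cohort on the fast direct-HbO path at the 1 Hz
    analysis rate (cardiac oscillator dropped: above that Nyquist)."""
    coupling = hd.CouplingSpec(channel_pair=pair, lag_s=lag)
    if amplitudes is not None:
        coupling.amplitude_by_group_block = {
            (g, b): amplitudes[g][b - 1]
            for g in ("couple", "control") for b in (1, 2)}
    noise = hd.NoiseSpec(cardiac_amp=0.0, hrf_amplitude=hrf)
    return hd.gen_cohort(n_couples, n_controls, layout=small_layout(n_channels),
                         coupling=coupling, noise=noise, fs_hz=1.0,
                         emit="hbo", seed=seed)


NULL_AMPS = {"couple": (0.0, 0.0), "control": (0.0, 0.0)}


@pytest.fixture(scope="session")
def coupled_cohort(config):
    """12-dyad default-coupling cohort, preprocessed, with IBS computed."""
    from hyperdyad.ibs import compute_cohort_ibs
    sessions = make_cohort(6, 6, seed=42)
    kept, pairs, reports = preprocess_cohort(sessions, config)
    ibs = compute_cohort_ibs(kept, pairs, config)
    return {"sessions": kept, "pairs": pairs, "reports": reports, "ibs": ibs}
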