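import numpy as np
import pytest

from rhythmkit import synthetic


@pytest.fixture
def clean_trace():
    """Noiseless, undamped 24 h oscillation with peaks at 12, 36, 60, ... h."""
    spec = synthetic.EnsembleSpec(noise_sd=0.0, damping_rate=0.0,
                                  duration_h=240.0)
    return synthetic.gen_ensemble_trace(spec)


@pytest.fixture
def treated_trace():
    """Noisy trace with a planted -4 h delay at hour 106 (CT10)."""
    spec = synthetic.EnsembleSpec(noise_sd=10.0, treatment_time_h=106.0,
                                  d_phase_h=-4.0, duration_h=240.0, seed=7)
    return synthetic.gen_ensemble_trace(spec)


@pytest.fixture
def disc_stack():
    """5x5 grid of noiseless oscillating discs with a 45 deg phase wave."""
    cell = synthetic.EnsembleSpec(noise_sd=0.0, baseline=20.0, duration_h=120.0)
    spec = synthetic.WaveFieldSpec(seed=5, cell=cell, phase_scatter_sd_h=0.0)
    return synthetic.gen_image_stack(spec)
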