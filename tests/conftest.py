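"""Shared fixtures: noise-free and noisy synthetic trace factories."""

from dataclasses import replace

import numpy as np
import pytest

from sparsegate.detection import DetectionParams
from sparsegate.synthetic import STUDY_GROUPS, AcquisitionConfig, generate_trace


@pytest.fixture
def control_profile():
    return STUDY_GROUPS["control"]


@pytest.fixture
def clean_profile(control_profile):
    """Control profile with deterministic amplitude (5.2% ΔF/F₀) and latency."""
    return replace(control_profile, amplitude_dispersion=0.0, latency_sd=0.0)


@pytest.fixture
def noise_free_trace(clean_profile):
    """Single noise-free transient of amplitude exactly 5.2% ΔF/F₀."""
    acq = AcquisitionConfig(noise_sd=0.0)
    trace, events = generate_trace(clean_profile, acq, [True], np.random.default_rng(1))
    return trace, events


@pytest.fixture
def raw_char_params():
    """Detection params characterizing on the raw ΔF/F trace (noise-free data)."""
    return DetectionParams(characterize_on_smoothed=False)
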