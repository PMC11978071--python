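import numpy as np
import pytest

from whiskthal.synthetic import SyntheticConfig, NeuronParams, generate_session
from whiskthal import whisking


def decompose_session(session):
    """Two-pass stationary normalization + decomposition (pipeline path)."""
    angle = whisking.normalize_angle(session.whisker_angle)
    trace0 = whisking.decompose(angle, session.whisker_time)
    angle = whisking.normalize_angle(session.whisker_angle, ~trace0.whisking_mask)
    return whisking.decompose(angle, session.whisker_time)


@pytest.fixture(scope="session")
def vpm_session():
    cfg = SyntheticConfig(duration=300.0)
    return generate_session(cfg, NeuronParams.vpm_like(), 1,
                            neuron_id="fix-vpm", nucleus_label="VPM")


@pytest.fixture(scope="session")
def pom_session():
    cfg = SyntheticConfig(duration=300.0)
    return generate_session(cfg, NeuronParams.pom_like(), 2,
                            neuron_id="fix-pom", nucleus_label="POm")


@pytest.fixture(scope="session")
def vpm_trace(vpm_session):
    session, _ = vpm_session
    return decompose_session(session)


@pytest.fixture(scope="session")
def free_whisking_session():
    """Free whisking only (no deflections), for state/phase statistics."""
    cfg = SyntheticConfig(duration=300.0, block_cycle=("free",))
    return generate_session(cfg, NeuronParams.vpm_like(), 5,
                            neuron_id="fix-free", nucleus_label="VPM")
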