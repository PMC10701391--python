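import numpy as np
import pytest

from seegdecode import Recording, SessionConfig, generate_session

# scaled study conditions used throughout the suite: the full 30-cues-per-hand
# protocol on a smaller montage and 256 Hz sampling keeps runtimes short while
# preserving every statistical property the pipeline relies on
SCALED = dict(n_channels=24, sampling_rate_hz=256.0, tasks=("executed",))


@pytest.fixture(scope="session")
def high_snr_session():
    """One scaled session with the default planted class difference."""
    config = SessionConfig(seed=7, **SCALED)
    return (config, *generate_session(config))


@pytest.fixture(scope="session")
def null_session():
    """One scaled session with no class difference (snr_move=0)."""
    config = SessionConfig(seed=7, snr_move=0.0, **SCALED)
    return (config, *generate_session(config))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_spd(rng: np.random.Generator, k: int, scale: float = 1.0) -> np.ndarray:
    a = rng.standard_normal((k, k))
    return scale * (a @ a.T) + 0.5 * np.eye(k)


def white_recording(rng: np.random.Generator, n_channels: int = 20,
                    fs: float = 512.0, duration_s: float = 30.0) -> Recording:
    n = int(fs * duration_s)
    return Recording(
        data=rng.standard_normal((n_channels, n)),
        sampling_rate_hz=fs,
        channel_names=[f"ch{i}" for i in range(n_channels)],
        anatomical_labels=["S_temporal_sup"] * n_channels,
    )
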