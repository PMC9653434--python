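"""Shared fixtures: scaled-down synthetic recordings for fast unit tests.

The scaled protocol keeps the trial anatomy (baseline / stimulation / ITI,
PMT shutter around light) but shortens every segment so movies stay small;
the full-timing presets are exercised in the synthetic-data and acceptance
tests.
"""

import numpy as np
import pytest

from obfeedback import imaging, synth


@pytest.fixture(scope="session")
def scaled_spec() -> synth.ProtocolSpec:
    return synth.ProtocolSpec(
        modality="two_photon",
        conditions=("light", "shutter"),
        baseline_s=2.0,
        stim_s=1.0,
        iti_s=2.0,
        trials_per_block=12,
    )


@pytest.fixture(scope="session")
def scaled_protocol(scaled_spec):
    return synth.generate_protocol(scaled_spec, n_blocks=1, seed=7)


@pytest.fixture(scope="session")
def movie_params() -> synth.MovieParams:
    return synth.MovieParams(shape=(64, 64), n_cells=12, min_separation_px=9)


@pytest.fixture(scope="session")
def small_movie(scaled_protocol, movie_params):
    """Clean movie (no drift, no out-of-plane frames) with ground truth."""
    return synth.generate_movie(scaled_protocol, movie_params, seed=7)


@pytest.fixture(scope="session")
def corrupted_movie(scaled_protocol, movie_params):
    """Same preset with injected drift and out-of-plane frames."""
    import dataclasses

    params = dataclasses.replace(
        movie_params, drift_shift=(3, -2), out_of_plane_frames=(10, 11, 12)
    )
    return synth.generate_movie(scaled_protocol, params, seed=7)


@pytest.fixture()
def textured_frame() -> np.ndarray:
    rng = np.random.default_rng(0)
    yy, xx = np.mgrid[:32, :32]
    return 100 + 10 * np.sin(yy / 3.0) * np.cos(xx / 5.0) + rng.normal(0, 1, (32, 32))


def make_movie(frames: np.ndarray, rate: float = 15.0) -> imaging.Movie:
    return imaging.Movie(frames=np.asarray(frames, dtype=float), frame_rate=rate)
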