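"""Ground-truth-labelled synthetic data for every pipeline in the package.

The generator emulates the statistical structure the analyses assume —
trial protocols with the study's timing, calcium movies with slow-indicator
kinetics on a noisy background (with optional lateral drift and out-of-plane
frames), per-trial window-mean fixtures for statistic calibration, and
two-channel photometry sessions with known light-evoked suppression — so
every analysis module can be tested against known truth without any
recording.

Protocol presets carry the experimental timing: two-photon trials are 8 s
baseline, 2 s stimulation and 10 s inter-trial interval in blocks of 20
trials at 15 Hz; photometry trials are 5-s odors every 60 s with a 1-s light
pulse 3.5 s after odor onset, 10 repetitions per condition at 5 kHz.

Indicator kinetics, cell counts, noise levels and effect sizes are fixture
choices (documented in the methods note), not measured values. Everything is
deterministic under a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InvalidParameterError
from .imaging import Movie, RoiSet
from .photometry import PhotometrySession
from .trials import TRIAL_COLUMNS, validate_trial_table

logger = logging.getLogger(__name__)

__all__ = [
    "ProtocolSpec",
    "GroundTruth",
    "MovieParams",
    "generate_protocol",
    "generate_movie",
    "generate_trace_set",
    "generate_photometry_session",
    "DEFAULT_EXCITED_EFFECT",
    "DEFAULT_INHIBITED_EFFECT",
    "DEFAULT_TRIALS_PER_CONDITION",
]

#: Default per-cell window-mean effect sizes for the trace-set fixture, in
#: units of the window-mean noise SD. With 20 paired trials these give a
#: theoretical paired-t power of ~0.96 at alpha = 0.01 (noncentral t).
DEFAULT_EXCITED_EFFECT = 1.5
DEFAULT_INHIBITED_EFFECT = -1.5
DEFAULT_TRIALS_PER_CONDITION = 20


@dataclass(frozen=True)
class ProtocolSpec:
    """Timing constants for one recording modality."""

    modality: str                        # "two_photon" | "photometry"
    conditions: tuple[str, ...]
    baseline_s: float = 8.0              # two-photon pre-stimulus baseline
    stim_s: float = 2.0                  # two-photon stimulation duration
    iti_s: float = 10.0                  # two-photon inter-trial interval
    trials_per_block: int = 20
    frame_rate: float = 15.0
    frame_shape: tuple[int, int] = (512, 512)
    odor_duration_s: float = 5.0         # photometry odor pulse
    trial_period_s: float = 60.0         # photometry odor spacing
    light_delay_s: float = 3.5           # photometry light onset after odor
    light_duration_s: float = 1.0
    repeats_per_condition: int = 10
    sample_rate: float = 5000.0
    shutter_margin_s: float = 0.05       # shutter closes/reopens 50 ms around light

    def __post_init__(self) -> None:
        if self.modality not in ("two_photon", "photometry"):
            raise InvalidParameterError(f"unknown modality {self.modality!r}")
        for name in ("baseline_s", "stim_s", "iti_s", "odor_duration_s",
                     "trial_period_s", "light_duration_s"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")
        if self.modality == "photometry" and (
            self.light_delay_s + self.light_duration_s > self.trial_period_s
        ):
            raise InvalidParameterError("light window exceeds the trial period")

    @classmethod
    def two_photon_default(
        cls,
        conditions: tuple[str, ...] = ("odorA", "odorB", "light", "odorA+light", "odorB+light"),
    ) -> "ProtocolSpec":
        return cls(modality="two_photon", conditions=conditions)

    @classmethod
    def photometry_default(
        cls, conditions: tuple[str, ...] = ("odor", "odor+light", "light")
    ) -> "ProtocolSpec":
        return cls(modality="photometry", conditions=conditions)

    @property
    def trial_duration_s(self) -> float:
        return self.baseline_s + self.stim_s + self.iti_s


@dataclass
class GroundTruth:
    """Everything the generator injected, for recovery tests."""

    seed: int
    cell_positions: np.ndarray | None = None       # (n, 2) row/col centres
    cell_radii: np.ndarray | None = None
    cell_labels: list[str] = field(default_factory=list)
    effect_sizes: np.ndarray | None = None
    event_times: list[np.ndarray] = field(default_factory=list)
    clean_traces: np.ndarray | None = None         # (n_cells, T) noiseless
    injected_shifts: np.ndarray | None = None      # (T, 2) applied (dy, dx)
    out_of_plane_frames: np.ndarray | None = None
    noise_sigma: float = 0.0
    trial_suppression: np.ndarray | None = None    # photometry: per trial
    artifact_percent: float = 0.0


# --------------------------------------------------------------------------- #
# protocols
# --------------------------------------------------------------------------- #

def generate_protocol(spec: ProtocolSpec, n_blocks: int = 1, seed: int = 0) -> pd.DataFrame:
    """Trial table following the preset's timing, stimulus order randomised
    within each block.

    Two-photon blocks hold ``trials_per_block`` trials of ``trial_duration_s``
    each; light-involving and shutter-control trials get shutter close/open
    times 50 ms around the stimulation window. Photometry blocks hold one
    repeat of each condition at ``trial_period_s`` spacing, with the light
    pulse ``light_delay_s`` after odor onset on light trials.
    """
    if n_blocks < 1:
        raise InvalidParameterError(f"n_blocks must be >= 1, got {n_blocks}")
    rng = np.random.default_rng(seed)
    rows = []
    if spec.modality == "two_photon":
        reps = int(np.ceil(spec.trials_per_block / len(spec.conditions)))
        for block in range(n_blocks):
            order = np.tile(spec.conditions, reps)[: spec.trials_per_block]
            rng.shuffle(order)
            for k, stim in enumerate(order):
                start = (block * spec.trials_per_block + k) * spec.trial_duration_s
                onset = start + spec.baseline_s
                shuttered = "light" in stim or stim == "shutter"
                rows.append(
                    {
                        "onset_s": onset,
                        "stimulus": stim,
                        "block": block,
                        "shutter_close_s": onset - spec.shutter_margin_s if shuttered else np.nan,
                        "shutter_open_s": onset + spec.stim_s + spec.shutter_margin_s if shuttered else np.nan,
                        "light_onset_s": onset if "light" in stim else np.nan,
                    }
                )
    else:
        trial = 0
        for block in range(n_blocks * spec.repeats_per_condition):
            order = np.array(spec.conditions, dtype=object)
            rng.shuffle(order)
            for stim in order:
                onset = 30.0 + trial * spec.trial_period_s
                has_light = "light" in stim
                rows.append(
                    {
                        "onset_s": onset,
                        "stimulus": stim,
                        "block": block,
                        "shutter_close_s": np.nan,
                        "shutter_open_s": np.nan,
                        "light_onset_s": onset + spec.light_delay_s if has_light else np.nan,
                    }
                )
                trial += 1
    table = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return validate_trial_table(table)


# --------------------------------------------------------------------------- #
# calcium movies
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class MovieParams:
    """Fixture parameters for synthetic calcium movies.

    The defaults emulate a 128x128-px field (scaled down from the 512-px
    acquisition) with ~30 somata, a GCaMP6s-like kernel (0.1-s rise, 1-s
    decay) and shot-noise-like Gaussian pixel noise.
    """

    shape: tuple[int, int] = (128, 128)
    n_cells: int = 30
    frame_rate: float = 15.0
    background: float = 100.0
    # static smooth neuropil-like texture: amplitude (intensity units) and
    # spatial correlation length (px); keeps frame-to-average correlation
    # robust to small lateral drift, as in real recordings
    bg_texture_amp: float = 8.0
    bg_texture_scale_px: float = 12.0
    noise_sigma: float = 3.0
    tonic_range: tuple[float, float] = (20.0, 40.0)
    spont_rate_hz: float = 0.06
    spont_amp_range: tuple[float, float] = (8.0, 20.0)
    # stimulus-locked transient amplitude; only its decay tail is visible
    # after the shutter reopens, so the peak must be comfortably large
    excited_amp: float = 40.0
    inhibited_suppression: float = 0.6
    fraction_excited: float = 0.3
    fraction_inhibited: float = 0.3
    effect_stimulus: str = "light"
    kernel_rise_s: float = 0.1
    kernel_decay_s: float = 1.0
    radius_range: tuple[float, float] = (2.5, 4.0)
    min_separation_px: float = 10.0
    # (dy, dx) applied to the trailing frames; the default start fraction keeps
    # the undrifted position in the majority so the stack average is a
    # well-posed registration reference
    drift_shift: tuple[int, int] | None = None
    drift_start_fraction: float = 0.6
    out_of_plane_frames: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise InvalidParameterError("n_cells must be >= 1")
        if self.noise_sigma < 0:
            raise InvalidParameterError("noise_sigma must be >= 0")
        if not 0 <= self.inhibited_suppression <= 1:
            raise InvalidParameterError("inhibited_suppression must be in [0, 1]")
        if self.fraction_excited + self.fraction_inhibited > 1:
            raise InvalidParameterError("effect fractions sum above 1")


def _indicator_kernel(rise_s: float, decay_s: float, rate: float) -> np.ndarray:
    """Double-exponential calcium-indicator kernel, peak-normalised."""
    t = np.arange(0, 6 * decay_s, 1.0 / rate)
    k = (1 - np.exp(-t / rise_s)) * np.exp(-t / decay_s)
    peak = k.max()
    return k / peak if peak > 0 else k


def _place_cells(
    rng: np.random.Generator, params: MovieParams
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample non-crowded cell centres; warn if separation relaxed."""
    h, w = params.shape
    margin = params.radius_range[1] * 2
    positions = []
    min_sep = params.min_separation_px
    attempts = 0
    while len(positions) < params.n_cells:
        cand = rng.uniform([margin, margin], [h - margin, w - margin])
        if all(np.hypot(*(cand - p)) >= min_sep for p in positions):
            positions.append(cand)
        attempts += 1
        if attempts > 200 * params.n_cells:
            min_sep *= 0.8
            attempts = 0
            logger.warning("_place_cells: relaxing minimum separation to %.1f px", min_sep)
    radii = rng.uniform(*params.radius_range, size=params.n_cells)
    return np.array(positions), radii


def _disc(shape: tuple[int, int], centre: np.ndarray, radius: float) -> np.ndarray:
    """Hard-edged Gaussian soma profile: indicator-filled cell bodies have
    fairly crisp boundaries, so the tail below 0.3 of the peak is cut."""
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    r2 = (yy - centre[0]) ** 2 + (xx - centre[1]) ** 2
    sigma = radius / 1.5
    profile = np.exp(-r2 / (2 * sigma**2))
    profile[profile < 0.3] = 0.0
    return profile


def generate_movie(
    protocol: pd.DataFrame, params: MovieParams = MovieParams(), seed: int = 0
) -> tuple[Movie, RoiSet, GroundTruth]:
    """Synthetic trial-structured calcium movie with known cells and effects.

    Cells are Gaussian discs with tonic fluorescence plus spontaneous
    indicator transients. On trials whose stimulus contains
    ``params.effect_stimulus``, "excited" cells fire a stimulus-locked
    transient and "inhibited" cells lose ``inhibited_suppression`` of their
    tonic component during the stimulation and the following second. The
    movie is background + cells + i.i.d. Gaussian noise; injected lateral
    drift and replaced out-of-plane frames are recorded in the ground truth.
    Returns the movie, the true ROI masks and the GroundTruth record.
    """
    rng = np.random.default_rng(seed)
    rate = params.frame_rate
    last_onset = protocol["onset_s"].max()
    duration = last_onset + 12.0
    n_frames = int(round(duration * rate))
    h, w = params.shape

    positions, radii = _place_cells(rng, params)
    n = params.n_cells
    labels = ["null"] * n
    n_exc = int(round(params.fraction_excited * n))
    n_inh = int(round(params.fraction_inhibited * n))
    order = rng.permutation(n)
    for i in order[:n_exc]:
        labels[i] = "excited"
    for i in order[n_exc : n_exc + n_inh]:
        labels[i] = "inhibited"

    kernel = _indicator_kernel(params.kernel_rise_s, params.kernel_decay_s, rate)
    times = (np.arange(n_frames) + 0.5) / rate
    effect_trials = protocol[
        protocol["stimulus"].str.contains(params.effect_stimulus, regex=False)
    ]

    clean = np.zeros((n, n_frames))
    event_times: list[np.ndarray] = []
    effect_sizes = np.zeros(n)
    for i in range(n):
        tonic = rng.uniform(*params.tonic_range)
        # at least a few transients per cell so every trace has temporal structure
        n_spont = max(3, rng.poisson(params.spont_rate_hz * duration))
        spont_t = np.sort(rng.uniform(0, duration, size=n_spont))
        events = np.zeros(n_frames)
        for t_ev in spont_t:
            idx = int(t_ev * rate)
            if idx < n_frames:
                events[idx] += rng.uniform(*params.spont_amp_range)
        cell_events = list(spont_t)
        gate = np.ones(n_frames)
        if labels[i] == "excited":
            effect_sizes[i] = params.excited_amp
            for onset in effect_trials["onset_s"]:
                idx = int(onset * rate)
                if idx < n_frames:
                    events[idx] += params.excited_amp
                    cell_events.append(onset)
        elif labels[i] == "inhibited":
            effect_sizes[i] = -params.inhibited_suppression
            for onset in effect_trials["onset_s"]:
                window = (times >= onset) & (times < onset + 3.0)
                gate[window] = 1.0 - params.inhibited_suppression
        transient = np.convolve(events, kernel)[:n_frames]
        clean[i] = (tonic + transient) * gate
        event_times.append(np.array(sorted(cell_events)))

    texture = ndimage.gaussian_filter(
        rng.normal(size=(h, w)), params.bg_texture_scale_px / 2.0
    )
    tex_sd = texture.std()
    if tex_sd > 0:
        texture *= params.bg_texture_amp / tex_sd
    movie = np.full((n_frames, h, w), params.background, dtype=float)
    movie += texture[None, :, :]
    masks = np.zeros((h, w), dtype=int)
    for i in range(n):
        profile = _disc(params.shape, positions[i], radii[i])
        ys, xs = np.nonzero(profile > 0)
        masks[ys, xs] = i + 1
        movie += profile[None, :, :] * clean[i][:, None, None]
    movie += rng.normal(0, params.noise_sigma, size=movie.shape)

    shifts = np.zeros((n_frames, 2), dtype=int)
    if params.drift_shift is not None:
        start = int(params.drift_start_fraction * n_frames)
        dy, dx = params.drift_shift
        shifts[start:] = (dy, dx)
        movie[start:] = np.roll(movie[start:], (dy, dx), axis=(1, 2))

    oop = np.array(sorted(params.out_of_plane_frames), dtype=int)
    if oop.size:
        if oop.max() >= n_frames:
            raise InvalidParameterError("out_of_plane_frames beyond movie length")
        movie[oop] = rng.normal(
            params.background, params.background * 0.3, size=(oop.size, h, w)
        )

    truth = GroundTruth(
        seed=seed,
        cell_positions=positions,
        cell_radii=radii,
        cell_labels=labels,
        effect_sizes=effect_sizes,
        event_times=event_times,
        clean_traces=clean,
        injected_shifts=shifts,
        out_of_plane_frames=oop,
        noise_sigma=params.noise_sigma,
    )
    return (
        Movie(frames=movie, frame_rate=rate),
        RoiSet(masks=masks),
        truth,
    )


# --------------------------------------------------------------------------- #
# trial-window fixtures
# --------------------------------------------------------------------------- #

def generate_trace_set(
    n_cells: int,
    n_trials: int = DEFAULT_TRIALS_PER_CONDITION,
    effect_map: dict[str, tuple[int, float]] | None = None,
    noise_sigma: float = 1.0,
    baseline_mean: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[str], np.ndarray]:
    """Per-trial baseline/response window means with known per-cell effects.

    ``effect_map`` assigns cells to labels: ``{"inhibited": (200, -1.5)}``
    means 200 cells whose response-window mean is shifted by -1.5; remaining
    cells are "null" with zero shift. Window means are independent normal
    draws with SD ``noise_sigma``. Returns
    ``(base_means, resp_means, labels, effects)`` with arrays shaped
    (n_cells, n_trials).
    """
    if n_trials < 2:
        raise InvalidParameterError(f"need n_trials >= 2, got {n_trials}")
    if noise_sigma < 0:
        raise InvalidParameterError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    effect_map = effect_map or {}
    labels: list[str] = []
    effects = np.zeros(n_cells)
    cursor = 0
    for label, (count, effect) in effect_map.items():
        if cursor + count > n_cells:
            raise InvalidParameterError("effect_map assigns more cells than n_cells")
        labels.extend([label] * count)
        effects[cursor : cursor + count] = effect
        cursor += count
    labels.extend(["null"] * (n_cells - cursor))

    base = rng.normal(baseline_mean, noise_sigma, size=(n_cells, n_trials))
    resp = rng.normal(
        baseline_mean + effects[:, None], noise_sigma, size=(n_cells, n_trials)
    )
    return base, resp, labels, effects


# --------------------------------------------------------------------------- #
# photometry sessions
# --------------------------------------------------------------------------- #

def generate_photometry_session(
    protocol: pd.DataFrame,
    suppression_levels: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4),
    artifact_percent: float = 0.0,
    rate: float = 5000.0,
    baseline_f: float = 100.0,
    odor_amplitude: float = 0.05,
    noise_sigma: float = 0.05,
    light_duration_s: float = 1.0,
    seed: int = 0,
) -> tuple[PhotometrySession, GroundTruth]:
    """Two-channel photometry session with known light-evoked suppression.

    Odor trials evoke a plateau ΔF/F transient of ``odor_amplitude`` (rise
    tau 0.5 s, decay tau 1 s after odor offset). On light trials the
    odor-evoked component is multiplied by (1 - s) during the light window,
    with s cycling through ``suppression_levels`` across odor+light trials
    (recorded per trial in the ground truth). The reflection channel is flat
    except for an injected step of ``artifact_percent`` % during light
    windows, for QC testing.
    """
    if any(not 0 <= s <= 1 for s in suppression_levels):
        raise InvalidParameterError("suppression levels must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    duration = protocol["onset_s"].max() + 30.0
    n = int(round(duration * rate))
    t = np.arange(n) / rate

    dff = np.zeros(n)
    suppression = np.full(len(protocol), np.nan)
    light_trial_counter = 0
    odor_len = 5.0
    for row_i, (_, row) in enumerate(protocol.iterrows()):
        stim = str(row["stimulus"])
        onset = row["onset_s"]
        if "odor" in stim:
            rel = t - onset
            rise = (1 - np.exp(-np.clip(rel, 0, None) / 0.5)) * (rel >= 0)
            plateau = rise * (rel < odor_len)
            decay = np.exp(-np.clip(rel - odor_len, 0.0, None) / 1.0) * (rel >= odor_len)
            shape = np.clip(plateau + decay * (1 - np.exp(-odor_len / 0.5)), 0, None)
            shape[rel > odor_len + 8] = 0.0
            transient = odor_amplitude * shape
            if pd.notna(row["light_onset_s"]):
                s = suppression_levels[light_trial_counter % len(suppression_levels)]
                suppression[row_i] = s
                light_trial_counter += 1
                in_light = (t >= row["light_onset_s"]) & (
                    t < row["light_onset_s"] + light_duration_s
                )
                transient[in_light] *= 1.0 - s
            dff += transient
    fluorescence = baseline_f * (1.0 + dff) + rng.normal(0, noise_sigma, size=n)

    reflection = np.full(n, 50.0) + rng.normal(0, 0.005, size=n)
    if artifact_percent:
        for _, row in protocol.iterrows():
            if pd.notna(row["light_onset_s"]):
                in_light = (t >= row["light_onset_s"]) & (
                    t < row["light_onset_s"] + light_duration_s
                )
                reflection[in_light] *= 1.0 + artifact_percent / 100.0

    session = PhotometrySession(
        fluorescence=fluorescence,
        reflection=reflection,
        rate=rate,
        trials=protocol.copy(),
    )
    truth = GroundTruth(
        seed=seed,
        trial_suppression=suppression,
        artifact_percent=artifact_percent,
        noise_sigma=noise_sigma,
    )
    return session, truth
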