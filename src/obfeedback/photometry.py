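"""Fiber-photometry trial analysis.

Bulk GCaMP fluorescence and the co-recorded reflected excitation light are
acquired at 5 kHz, smoothed with a 0.02-s boxcar, and downsampled to 500 Hz
by bin averaging. Each trial is normalised to its own 2-s pre-onset baseline
(ΔF/F). Sessions whose reflected-light channel changes by more than 1% ΔF/F
during stimulation are discarded: such changes indicate fiber-coupling or
excitation artifacts rather than calcium signals. The net impact of a 1-s
optogenetic light pulse on the odor-evoked response is the difference between
the mean ΔF/F during the pulse and during the preceding 1 s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, InvalidParameterError
from .imaging import moving_average

logger = logging.getLogger(__name__)

__all__ = [
    "PhotometrySession",
    "TrialMatrix",
    "preprocess_signal",
    "qc_reflection",
    "reflection_change",
    "trial_dff",
    "net_light_impact",
]


@dataclass
class PhotometrySession:
    """Two-channel photometry recording plus its trial schedule."""

    fluorescence: np.ndarray
    reflection: np.ndarray | None
    rate: float
    trials: pd.DataFrame

    def __post_init__(self) -> None:
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.reflection is not None:
            self.reflection = np.asarray(self.reflection, dtype=float)
            if self.reflection.shape != self.fluorescence.shape:
                raise InvalidParameterError(
                    "fluorescence and reflection channels must have the same length"
                )
        if self.rate <= 0:
            raise InvalidParameterError(f"rate must be positive, got {self.rate}")
        dur = self.fluorescence.size / self.rate
        onsets = self.trials["onset_s"].to_numpy(dtype=float)
        if onsets.size and (onsets.min() < 0 or onsets.max() > dur):
            raise InvalidParameterError(
                f"trial onsets outside recording span [0, {dur:.1f}] s"
            )

    @property
    def duration_s(self) -> float:
        return self.fluorescence.size / self.rate


@dataclass
class TrialMatrix:
    """Trial-aligned ΔF/F rows with a common time axis relative to onset."""

    dff: np.ndarray                 # (n_trials, n_samples)
    time_s: np.ndarray              # relative to trial onset
    conditions: list[str]
    rate: float
    trial_index: np.ndarray = field(default=None)  # type: ignore[assignment]
    light_onset_s: np.ndarray | None = None        # relative to onset, NaN if none

    def __post_init__(self) -> None:
        if self.trial_index is None:
            self.trial_index = np.arange(self.dff.shape[0])

    def rows_for(self, condition: str) -> np.ndarray:
        sel = [i for i, c in enumerate(self.conditions) if c == condition]
        return self.dff[sel]


def preprocess_signal(
    raw: np.ndarray,
    rate: float,
    smooth_window_s: float = 0.02,
    target_rate: float = 500.0,
) -> np.ndarray:
    """Boxcar-smooth then downsample a raw photometry channel.

    Smoothing uses a centred moving average over ``smooth_window_s`` seconds;
    decimation averages each output bin. A non-integer rate ratio is handled
    by averaging over rounded bin edges (with a logged note).
    """
    raw = np.asarray(raw, dtype=float)
    if rate < target_rate:
        raise InvalidParameterError(
            f"acquisition rate {rate} below target rate {target_rate}"
        )
    window = max(1, int(round(smooth_window_s * rate)))
    smoothed = moving_average(raw, window)
    ratio = rate / target_rate
    if float(ratio).is_integer():
        factor = int(ratio)
        n_out = raw.size // factor
        return smoothed[: n_out * factor].reshape(n_out, factor).mean(axis=1)
    logger.info(
        "preprocess_signal: rate %.1f not an integer multiple of %.1f; "
        "bin-averaging over rounded edges", rate, target_rate,
    )
    n_out = int(np.floor(raw.size / ratio))
    edges = np.round(np.arange(n_out + 1) * ratio).astype(int)
    return np.array([smoothed[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])


def reflection_change(
    session: PhotometrySession,
    light_column: str = "light_onset_s",
    light_duration_s: float = 1.0,
    f0_window_s: float = 2.0,
    processed_rate: float = 500.0,
) -> float:
    """Mean |ΔF/F| of the reflected-light channel during stimulation windows.

    Returns NaN when the session has no reflection channel or no light trials.
    """
    if session.reflection is None:
        return np.nan
    refl = preprocess_signal(session.reflection, session.rate, target_rate=processed_rate)
    changes = []
    for _, row in session.trials.iterrows():
        t_light = row.get(light_column)
        if pd.isna(t_light):
            continue
        onset = row["onset_s"]
        i0 = int((onset - f0_window_s) * processed_rate)
        i1 = int(onset * processed_rate)
        j0 = int(t_light * processed_rate)
        j1 = int((t_light + light_duration_s) * processed_rate)
        if i0 < 0 or j1 > refl.size:
            raise AlignmentError(f"light window for trial at {onset:.1f} s out of range")
        f0 = refl[i0:i1].mean()
        if f0 <= 0:
            continue
        changes.append(abs(refl[j0:j1].mean() - f0) / f0)
    if not changes:
        return np.nan
    return float(np.mean(changes))


def qc_reflection(reflection_dff: float, threshold: float = 0.01) -> str:
    """Session QC on the reflected excitation light.

    ``reflection_dff`` is the session's mean |ΔF/F| change of the reflected
    channel during stimulation (see :func:`reflection_change`). Returns
    ``"discard"`` when it strictly exceeds ``threshold`` (1% by default),
    ``"keep"`` otherwise, and ``"unverified"`` when the channel was missing.
    """
    if np.isnan(reflection_dff):
        logger.warning("qc_reflection: no reflection measurement; session unverified")
        return "unverified"
    return "discard" if reflection_dff > threshold else "keep"


def trial_dff(
    session: PhotometrySession,
    pre_s: float = 2.0,
    post_s: float = 10.0,
    processed_rate: float = 500.0,
) -> TrialMatrix:
    """Per-trial ΔF/F aligned to odor onset.

    The raw fluorescence is preprocessed (smooth + downsample), then each
    trial is cut from ``pre_s`` before to ``post_s`` after onset and
    normalised by F0 = mean fluorescence over the 2 s before onset. Trials
    with F0 <= 0 are dropped with a log message.
    """
    f = preprocess_signal(session.fluorescence, session.rate, target_rate=processed_rate)
    n_pre = int(round(pre_s * processed_rate))
    n_post = int(round(post_s * processed_rate))
    time_s = (np.arange(n_pre + n_post) - n_pre) / processed_rate
    rows, conds, kept_idx, light_rel = [], [], [], []
    for idx, row in session.trials.iterrows():
        onset = row["onset_s"]
        i_on = int(round(onset * processed_rate))
        i0, i1 = i_on - n_pre, i_on + n_post
        if i0 < 0 or i1 > f.size:
            raise AlignmentError(
                f"trial at {onset:.1f} s needs [{-pre_s}, {post_s}] s around onset"
            )
        f0 = f[i_on - n_pre : i_on].mean()
        if f0 <= 0:
            logger.warning("trial_dff: trial %s has F0=%.3g <= 0; dropped", idx, f0)
            continue
        rows.append((f[i0:i1] - f0) / f0)
        conds.append(str(row["stimulus"]))
        kept_idx.append(idx)
        t_light = row.get("light_onset_s")
        light_rel.append(float(t_light) - onset if pd.notna(t_light) else np.nan)
    if not rows:
        raise InvalidParameterError("no usable trials (all baselines non-positive)")
    return TrialMatrix(
        dff=np.vstack(rows),
        time_s=time_s,
        conditions=conds,
        rate=processed_rate,
        trial_index=np.asarray(kept_idx),
        light_onset_s=np.asarray(light_rel),
    )


def net_light_impact(
    trial_matrix: TrialMatrix,
    light_onset_s: float,
    window_s: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Net impact of light on the odor-evoked response.

    impact = mean ΔF/F during [light_onset, light_onset + window) minus the
    mean over the ``window_s`` immediately before light onset, computed per
    trial (times relative to odor onset). For "odor only" trials the same
    latencies give the comparable no-light impact. Returns
    ``(per_trial_impacts, mean_impact)``.
    """
    t = trial_matrix.time_s
    pre = (t >= light_onset_s - window_s) & (t < light_onset_s)
    dur = (t >= light_onset_s) & (t < light_onset_s + window_s)
    if not pre.any() or not dur.any():
        raise AlignmentError(
            f"light window [{light_onset_s - window_s}, {light_onset_s + window_s}) s "
            "outside the aligned trace"
        )
    impacts = trial_matrix.dff[:, dur].mean(axis=1) - trial_matrix.dff[:, pre].mean(axis=1)
    return impacts, float(impacts.mean())
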