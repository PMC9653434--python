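"""Two-photon calcium-movie pipeline: frame QC, registration, PCA denoising,
ROI refinement, trace extraction and trial-based response statistics.

The processing order mirrors the acquisition logic: out-of-plane (z) frames
are flagged first on the raw stack, lateral translation is then corrected,
and a 10-component PCA reconstruction denoises the movie before ROIs are
refined and traces extracted. Responses are quantified per trial in 1-s
windows (baseline before the PMT shutter closes, response after it reopens)
with a z statistic over trial-window means and a two-sided paired t-test for
significance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.registration import phase_cross_correlation
from sklearn.decomposition import PCA

from .errors import (
    AlignmentError,
    BaselineError,
    InvalidParameterError,
    PairingError,
    RoiError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Movie",
    "RoiSet",
    "TraceSet",
    "ResponseStat",
    "flag_z_frames",
    "correct_lateral_motion",
    "pca_reconstruct",
    "refine_rois",
    "extract_traces",
    "smooth_traces",
    "moving_average",
    "compute_dff",
    "compute_zscore",
    "classify_response",
    "trial_window_means",
]


@dataclass
class Movie:
    """An image stack (time x height x width) with per-frame QC flags."""

    frames: np.ndarray
    frame_rate: float
    kept_frames: np.ndarray = None  # type: ignore[assignment]
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise InvalidParameterError(
                f"movie frames must be 3-D (time, height, width), got {self.frames.shape}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise InvalidParameterError("movie contains non-finite intensities")
        if self.frame_rate <= 0:
            raise InvalidParameterError(f"frame_rate must be positive, got {self.frame_rate}")
        if self.kept_frames is None:
            self.kept_frames = np.ones(self.n_frames, dtype=bool)
        else:
            self.kept_frames = np.asarray(self.kept_frames, dtype=bool)
            if self.kept_frames.shape != (self.n_frames,):
                raise InvalidParameterError("kept_frames length must equal frame count")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    def frame_times(self) -> np.ndarray:
        """Frame-centre times: (index + 0.5) / rate."""
        return (np.arange(self.n_frames) + 0.5) / self.frame_rate


@dataclass
class RoiSet:
    """Labelled ROI masks (0 = background, k = ROI k) with provenance."""

    masks: np.ndarray
    provenance: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks)
        if self.masks.ndim != 2:
            raise InvalidParameterError("ROI masks must be a 2-D labelled image")
        labels = self.labels
        if labels.size and not np.array_equal(labels, np.arange(1, labels.size + 1)):
            raise InvalidParameterError(
                f"ROI labels must be contiguous positive integers, got {labels}"
            )
        for lab in labels:
            self.provenance.setdefault(int(lab), "manual")

    @property
    def labels(self) -> np.ndarray:
        labs = np.unique(self.masks)
        return labs[labs > 0]

    def pixels(self, label: int) -> tuple[np.ndarray, np.ndarray]:
        return np.nonzero(self.masks == label)


@dataclass
class TraceSet:
    """Per-ROI fluorescence traces (cell x time) at the movie frame rate."""

    traces: np.ndarray
    frame_rate: float
    roi_labels: np.ndarray = None  # type: ignore[assignment]
    interpolated_frames: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        if self.roi_labels is None:
            self.roi_labels = np.arange(1, self.traces.shape[0] + 1)

    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    def frame_times(self) -> np.ndarray:
        return (np.arange(self.n_frames) + 0.5) / self.frame_rate


@dataclass
class ResponseStat:
    """Per cell-stimulus response quantification.

    ``z`` is (mu_resp - mu_base) / sqrt(s_resp^2/n - s_base^2/n) with sample
    standard deviations; when the radicand is non-positive ``z`` is NaN and
    ``z_pooled`` (the conventional + form) is the usable fallback. The label
    comes from a two-sided paired t-test on per-trial differences, not from z.
    """

    z: float
    z_pooled: float
    mu_resp: float
    mu_baseline: float
    sigma_resp: float
    sigma_baseline: float
    n: int
    p_value: float
    label: str


# --------------------------------------------------------------------------- #
# frame QC and registration
# --------------------------------------------------------------------------- #

def _pearson_vs_reference(frame: np.ndarray, reference: np.ndarray) -> float:
    """Zero-lag Pearson correlation of a frame with a reference image."""
    a = frame.ravel().astype(float)
    b = reference.ravel().astype(float)
    sa = a.std()
    sb = b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(np.dot(a - a.mean(), b - b.mean()) / (a.size * sa * sb))


def flag_z_frames(movie: Movie, r_threshold: float = 0.65) -> Movie:
    """Flag out-of-plane (z-movement) frames by correlation with the stack average.

    Each frame's zero-lag Pearson correlation with the average projection of
    the entire stack is computed; frames with r <= ``r_threshold`` are marked
    not-kept. Constant (zero-variance) frames have undefined correlation and
    are flagged as well.
    """
    if movie.n_frames < 2:
        raise InvalidParameterError("need at least 2 frames to QC against the stack average")
    if not -1.0 <= r_threshold <= 1.0:
        raise InvalidParameterError(f"r_threshold must be in [-1, 1], got {r_threshold}")
    reference = movie.frames.mean(axis=0)
    r = np.array([_pearson_vs_reference(f, reference) for f in movie.frames])
    undefined = ~np.isfinite(r)
    if undefined.any():
        logger.warning(
            "flag_z_frames: %d zero-variance frame(s) flagged (correlation undefined)",
            int(undefined.sum()),
        )
    kept = movie.kept_frames & np.where(undefined, False, r > r_threshold)
    return replace(movie, kept_frames=kept)


def correct_lateral_motion(
    movie: Movie, max_shift_fraction: float = 0.10
) -> tuple[Movie, np.ndarray]:
    """Rigid translational registration against the average of kept frames.

    Per-frame integer (dy, dx) shifts are estimated by Fourier-domain
    cross-correlation and applied with zero fill at the edges. A frame whose
    estimated shift exceeds ``max_shift_fraction`` of the frame size is
    flagged not-kept instead of being shifted.
    """
    if not movie.kept_frames.any():
        raise InvalidParameterError("no kept frames to register")
    if movie.n_frames == 1:
        return replace(movie, frames=movie.frames.copy()), np.zeros((1, 2))

    reference = movie.frames[movie.kept_frames].mean(axis=0)
    max_dy = max_shift_fraction * movie.shape[1]
    max_dx = max_shift_fraction * movie.shape[2]
    shifts = np.zeros((movie.n_frames, 2))
    out = np.empty_like(movie.frames)
    kept = movie.kept_frames.copy()
    for i, frame in enumerate(movie.frames):
        if not kept[i]:
            out[i] = frame
            continue
        # plain FFT cross-correlation (no phase whitening): far more robust
        # than the phase-normalised variant at calcium-imaging noise levels
        shift, _, _ = phase_cross_correlation(
            reference, frame, upsample_factor=1, normalization=None
        )
        dy, dx = int(round(shift[0])), int(round(shift[1]))
        if abs(dy) > max_dy or abs(dx) > max_dx:
            logger.warning(
                "correct_lateral_motion: frame %d shift (%d, %d) exceeds bound; flagged",
                i, dy, dx,
            )
            kept[i] = False
            out[i] = frame
            continue
        shifts[i] = (dy, dx)
        if dy == 0 and dx == 0:
            out[i] = frame
        else:
            out[i] = ndimage.shift(frame, (dy, dx), order=0, mode="constant", cval=0.0)
    return replace(movie, frames=out, kept_frames=kept), shifts


# --------------------------------------------------------------------------- #
# PCA denoising and ROI refinement
# --------------------------------------------------------------------------- #

def pca_reconstruct(movie: Movie, n_components: int = 10) -> Movie:
    """Reconstruct the movie from its first ``n_components`` principal components.

    The stack is reshaped to (time x pixels) and mean-centred per pixel; the
    PCA basis is fitted on kept frames and every frame is reconstructed as
    scores @ components + pixel means. Output shape equals input shape.
    """
    n_kept = int(movie.kept_frames.sum())
    if n_components <= 0:
        raise InvalidParameterError(f"n_components must be positive, got {n_components}")
    if n_kept <= n_components:
        raise InvalidParameterError(
            f"need more kept frames ({n_kept}) than components ({n_components})"
        )
    t, h, w = movie.shape
    x = movie.frames.reshape(t, h * w).astype(float)
    pca = PCA(n_components=n_components, svd_solver="randomized", random_state=0)
    pca.fit(x[movie.kept_frames])
    recon = pca.inverse_transform(pca.transform(x))
    return replace(movie, frames=recon.reshape(t, h, w))


def refine_rois(
    movie: Movie,
    rois: RoiSet,
    n_components: int = 3,
    coefficient_threshold: float = 0.25,
) -> RoiSet:
    """Redefine each ROI's outer bounds from a PCA inside the ROI.

    For every ROI a PCA is run over its pixels' time courses (kept frames,
    samples = time, features = pixels). Pixels whose variance-weighted loading
    magnitude on PCs 1-3 falls below ``coefficient_threshold`` times the ROI's
    maximum loading are removed — these are neuropil/background pixels that do
    not share the cell's dominant temporal modes. Fluorescence data are never
    modified, only mask membership. An ROI that would shrink below 3 pixels
    keeps its original mask (with a warning).
    """
    if not 0 <= coefficient_threshold <= 1:
        raise InvalidParameterError(
            f"coefficient_threshold must be in [0, 1], got {coefficient_threshold}"
        )
    new_masks = np.zeros_like(rois.masks)
    provenance: dict[int, str] = {}
    kept_frames = movie.kept_frames
    for lab in rois.labels:
        ys, xs = rois.pixels(int(lab))
        n_pix = ys.size
        if n_pix <= n_components:
            raise InvalidParameterError(
                f"ROI {lab} has {n_pix} pixels; needs more than {n_components}"
            )
        x = movie.frames[kept_frames][:, ys, xs].astype(float)  # (time, pixels)
        k = min(n_components, x.shape[0] - 1, n_pix - 1)
        pca = PCA(svd_solver="full")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pca.fit(x)
        # weight each component's loadings by its signal variance above the
        # noise floor (median singular value over all components), so pure
        # noise directions contribute nothing to the pixel's loading magnitude
        s = pca.singular_values_
        noise_floor = np.median(s)
        # degenerate ROI: no temporal mode rises clearly above the noise floor
        if noise_floor == 0 or s[0] ** 2 < 4.0 * noise_floor**2:
            logger.warning(
                "refine_rois: ROI %d has no coherent temporal mode; keeping original mask",
                lab,
            )
            new_masks[ys, xs] = lab
            provenance[int(lab)] = "manual"
            continue
        weights = np.sqrt(np.maximum(0.0, s[:k] ** 2 - noise_floor**2))
        weighted = weights[:, None] * pca.components_[:k]
        loading = np.sqrt((weighted**2).sum(axis=0))
        max_loading = loading.max()
        keep = loading >= coefficient_threshold * max_loading
        if keep.sum() < 3:
            logger.warning(
                "refine_rois: ROI %d would shrink to %d px; keeping original mask",
                lab, int(keep.sum()),
            )
            new_masks[ys, xs] = lab
            provenance[int(lab)] = "manual"
            continue
        new_masks[ys[keep], xs[keep]] = lab
        provenance[int(lab)] = "refined"
    return RoiSet(masks=new_masks, provenance=provenance)


# --------------------------------------------------------------------------- #
# traces
# --------------------------------------------------------------------------- #

def extract_traces(movie: Movie, rois: RoiSet) -> TraceSet:
    """Mean intensity over each ROI mask per frame.

    Values on not-kept frames are replaced by linear interpolation between the
    neighbouring kept frames, so trial windows keep fixed sample counts.
    """
    labels = rois.labels
    if labels.size == 0:
        raise RoiError("ROI set is empty")
    t = movie.n_frames
    traces = np.empty((labels.size, t))
    for row, lab in enumerate(labels):
        ys, xs = rois.pixels(int(lab))
        if ys.size == 0:
            raise RoiError(f"ROI {lab} has an empty mask")
        traces[row] = movie.frames[:, ys, xs].mean(axis=1)
    interpolated = ~movie.kept_frames
    if interpolated.any() and movie.kept_frames.any():
        idx = np.arange(t)
        kept_idx = idx[movie.kept_frames]
        for row in range(traces.shape[0]):
            traces[row, interpolated] = np.interp(
                idx[interpolated], kept_idx, traces[row, kept_idx]
            )
        logger.info(
            "extract_traces: interpolated %d not-kept frame(s) in %d trace(s)",
            int(interpolated.sum()), traces.shape[0],
        )
    return TraceSet(
        traces=traces,
        frame_rate=movie.frame_rate,
        roi_labels=labels.copy(),
        interpolated_frames=interpolated,
    )


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with shrinking windows at the edges."""
    if window == 1:
        return np.asarray(x, dtype=float).copy()
    x = np.asarray(x, dtype=float)
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def smooth_traces(traces: TraceSet, window: int = 5) -> TraceSet:
    """Centred moving-average smoothing of every trace (default 5 frames)."""
    if window < 1 or window % 2 == 0:
        raise InvalidParameterError(f"window must be odd and >= 1, got {window}")
    if window > traces.n_frames:
        raise InvalidParameterError(
            f"window {window} exceeds trace length {traces.n_frames}"
        )
    smoothed = np.vstack([moving_average(row, window) for row in traces.traces])
    return replace(traces, traces=smoothed)


def compute_dff(trace: np.ndarray, f0_window: tuple[int, int]) -> np.ndarray:
    """Delta-F-over-F: (F - F0)/F0 with F0 the mean over ``f0_window`` samples."""
    trace = np.asarray(trace, dtype=float)
    start, stop = f0_window
    if not (0 <= start < stop <= trace.size):
        raise InvalidParameterError(
            f"f0_window {f0_window} outside trace of length {trace.size}"
        )
    f0 = trace[start:stop].mean()
    if f0 <= 0:
        raise BaselineError(f"non-positive baseline F0 = {f0}; pathological trace")
    return (trace - f0) / f0


# --------------------------------------------------------------------------- #
# response statistics
# --------------------------------------------------------------------------- #

def _paired_t(resp: np.ndarray, base: np.ndarray) -> float:
    """Two-sided paired t-test p-value with degenerate-case conventions."""
    diff = resp - base
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff.mean(), 0.0):
            return 1.0
        logger.warning("paired t-test: zero-variance nonzero-mean differences; p set to 0")
        return 0.0
    return float(stats.ttest_rel(resp, base).pvalue)


def compute_zscore(
    trial_resp_means: np.ndarray,
    trial_base_means: np.ndarray,
    alpha: float = 0.05,
) -> ResponseStat:
    """Per-cell response z statistic over paired trial-window means.

    z = (mu_resp - mu_base) / sqrt(s_resp^2/n - s_base^2/n), with s the sample
    standard deviation (n-1 denominator). When the radicand is non-positive
    the statistic is undefined (NaN) and only the pooled fallback
    z_pooled = (mu_resp - mu_base) / sqrt(s_resp^2/n + s_base^2/n) is finite.
    A zero numerator reports z = 0 regardless of the radicand. Significance
    labelling uses the paired t-test at ``alpha``, never z itself.
    """
    resp = np.asarray(trial_resp_means, dtype=float)
    base = np.asarray(trial_base_means, dtype=float)
    if resp.shape != base.shape or resp.ndim != 1:
        raise PairingError(
            f"paired trial means must be equal-length 1-D vectors, got {resp.shape} vs {base.shape}"
        )
    n = resp.size
    if n < 2:
        raise InvalidParameterError(f"need at least 2 trials, got {n}")
    mu_r, mu_b = resp.mean(), base.mean()
    s_r, s_b = resp.std(ddof=1), base.std(ddof=1)
    numerator = mu_r - mu_b
    radicand = s_r**2 / n - s_b**2 / n
    pooled = np.sqrt(s_r**2 / n + s_b**2 / n)
    z_pooled = numerator / pooled if pooled > 0 else (0.0 if numerator == 0 else np.inf * np.sign(numerator))
    if numerator == 0:
        z = 0.0
    elif radicand > 0:
        z = numerator / np.sqrt(radicand)
    else:
        z = np.nan
    p = _paired_t(resp, base)
    label = _label_from(p, numerator, alpha)
    return ResponseStat(
        z=float(z),
        z_pooled=float(z_pooled),
        mu_resp=float(mu_r),
        mu_baseline=float(mu_b),
        sigma_resp=float(s_r),
        sigma_baseline=float(s_b),
        n=n,
        p_value=p,
        label=label,
    )


def _label_from(p: float, mean_diff: float, alpha: float) -> str:
    if p < alpha and mean_diff > 0:
        return "excited"
    if p < alpha and mean_diff < 0:
        return "inhibited"
    return "nonresponsive"


def classify_response(
    trial_resp_means: np.ndarray,
    trial_base_means: np.ndarray,
    alpha: float = 0.01,
) -> tuple[str, float]:
    """Label a cell excited/inhibited/nonresponsive by a two-sided paired t-test.

    Significant (p < alpha) with positive mean trial difference -> excited;
    significant with negative mean -> inhibited; otherwise nonresponsive.
    Returns ``(label, p_value)``.
    """
    resp = np.asarray(trial_resp_means, dtype=float)
    base = np.asarray(trial_base_means, dtype=float)
    if resp.shape != base.shape or resp.ndim != 1:
        raise PairingError(f"unpaired trial vectors: {resp.shape} vs {base.shape}")
    if resp.size < 2:
        raise InvalidParameterError(f"need at least 2 paired trials, got {resp.size}")
    p = _paired_t(resp, base)
    return _label_from(p, float(resp.mean() - base.mean()), alpha), p


def trial_window_means(
    traces: TraceSet,
    trials: pd.DataFrame,
    window_s: float = 1.0,
    reopen_delay_s: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial baseline/response window means for every cell.

    The baseline window is the ``window_s`` seconds before the shutter closes
    and the response window starts ``reopen_delay_s`` after the shutter
    reopens (scan realignment time), lasting ``window_s``. Trials without
    shutter times use the stimulus onset/offset implied by ``onset_s`` and the
    2-s stimulation (baseline before onset, response after offset). Windows
    are half-open [start, start + window) over frame-centre times.

    Returns ``(base_means, resp_means)`` shaped (n_cells, n_trials).
    """
    times = traces.frame_times()
    n_trials = len(trials)
    base = np.empty((traces.n_cells, n_trials))
    resp = np.empty((traces.n_cells, n_trials))
    for j, (_, row) in enumerate(trials.iterrows()):
        close = row.get("shutter_close_s")
        reopen = row.get("shutter_open_s")
        if pd.isna(close) or pd.isna(reopen):
            close = row["onset_s"]
            reopen = row["onset_s"] + 2.0
        b0 = close - window_s
        r0 = reopen + reopen_delay_s
        b_mask = (times >= b0) & (times < b0 + window_s)
        r_mask = (times >= r0) & (times < r0 + window_s)
        if not b_mask.any() or not r_mask.any():
            raise AlignmentError(
                f"trial {j} windows [{b0}, {b0 + window_s}) / [{r0}, {r0 + window_s}) "
                "contain no frames"
            )
        base[:, j] = traces.traces[:, b_mask].mean(axis=1)
        resp[:, j] = traces.traces[:, r_mask].mean(axis=1)
    return base, resp
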