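"""Two-population firing-rate model of the olfactory bulb under cortical GABAergic feedback.

The excitatory population lumps mitral and tufted cells (MC/TC); the inhibitory
population is the granule cells (GC). Deep short-axon cells (dSAC) are not
modelled explicitly — they enter as a constant inhibitory drive onto GC that is
shunted by the feedback. The dynamics (unit time constants) are

    dMC/dt = -MC + I - w_mc_gc * GC - w_fb_mc * FB
    dGC/dt = -GC + w_mc_gc * MC - w_sac_gc * SAC - 2 * w_fb_mc * FB

with FB = 1 when the long-range GABAergic feedback is stimulated (0 otherwise)
and SAC = 0.1 / w_fb_mc under feedback (1 otherwise), capturing the shunting of
the dSAC→GC input. Feedback is twice as strong on GC as on MC/TC. GC rates are
rectified at zero; MC/TC rates are left unconstrained (a warning is emitted if
they go negative).

The linear subsystem has Jacobian [[-1, -w], [w, -1]] with eigenvalues
-1 ± i·w, so every real-weight configuration is stable and the steady state is
unique: either the unconstrained linear solution, or — when that solution has
GC < 0 — the rectified branch GC = 0, MC = I - w_fb_mc·FB.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DegenerateNullclineError, DivergenceError, InvalidParameterError

__all__ = [
    "NetworkParams",
    "PopulationState",
    "FixedPoint",
    "SweepResult",
    "integrate_dynamics",
    "mc_nullcline",
    "gc_nullcline",
    "solve_fixed_point",
    "feedback_delta",
    "sweep_parameter_grid",
    "jacobian_eigenvalues",
]

#: dSAC drive constant: under feedback the residual dSAC→GC input is 0.1/w_fb_mc.
SAC_SHUNT_CONSTANT = 0.1


@dataclass(frozen=True)
class NetworkParams:
    """Parameters of the MC/TC–GC rate model.

    Parameters
    ----------
    odor_input : float
        External excitatory drive ``I`` onto MC/TC (rate units, >= 0).
    w_mc_gc : float
        Reciprocal MC/TC<->GC coupling strength (>= 0).
    w_sac_gc : float
        dSAC->GC inhibition strength (>= 0).
    w_fb_mc : float
        Cortical GABAergic feedback strength onto MC/TC; the feedback onto GC
        is always ``2 * w_fb_mc`` and is never an independent parameter.
    feedback_on : bool
        Whether the feedback is being stimulated (FB = 1).
    """

    odor_input: float = 10.0
    w_mc_gc: float = 0.3
    w_sac_gc: float = 1.0
    w_fb_mc: float = 0.0
    feedback_on: bool = False

    def __post_init__(self) -> None:
        vals = (self.odor_input, self.w_mc_gc, self.w_sac_gc, self.w_fb_mc)
        if not all(np.isfinite(v) for v in vals):
            raise InvalidParameterError(f"non-finite model parameter in {vals}")
        if any(v < 0 for v in vals):
            raise InvalidParameterError("rates and coupling weights must be >= 0")
        if self.feedback_on and self.w_fb_mc <= 0:
            raise InvalidParameterError(
                "feedback_on requires w_fb_mc > 0 (SAC = 0.1/w_fb_mc is undefined at 0)"
            )

    @property
    def fb(self) -> float:
        """Feedback indicator FB (1.0 under stimulation, else 0.0)."""
        return 1.0 if self.feedback_on else 0.0

    @property
    def sac_drive(self) -> float:
        """dSAC drive: 0.1 / w_fb_mc under feedback (shunted), 1 otherwise."""
        if self.feedback_on:
            return SAC_SHUNT_CONSTANT / self.w_fb_mc
        return 1.0

    def with_feedback(self, w_fb_mc: float) -> "NetworkParams":
        """Return a copy with the feedback stimulated at strength ``w_fb_mc``."""
        return replace(self, w_fb_mc=w_fb_mc, feedback_on=True)


@dataclass(frozen=True)
class PopulationState:
    """Instantaneous (MC/TC, GC) population rates."""

    mc_rate: float
    gc_rate: float

    def as_array(self) -> np.ndarray:
        return np.array([self.mc_rate, self.gc_rate], dtype=float)


@dataclass(frozen=True)
class FixedPoint:
    """A steady state of the network.

    ``rectified_branch`` is True when the GC >= 0 constraint is active, i.e.
    the unconstrained linear solution had negative GC and the network settles
    at GC = 0, MC = I - w_fb_mc*FB.
    """

    state: PopulationState
    rectified_branch: bool
    converged: bool = True


@dataclass
class SweepResult:
    """Fixed-point rates over a (w_mc_gc, w_fb) grid.

    ``baseline_*`` hold the no-feedback fixed point (constant along the w_fb
    axis); ``delta_*`` hold the with-feedback minus without-feedback change.
    """

    w_mc_gc_axis: np.ndarray
    w_fb_axis: np.ndarray
    baseline_mc: np.ndarray
    baseline_gc: np.ndarray
    delta_mc: np.ndarray
    delta_gc: np.ndarray
    rectified: np.ndarray = field(default=None)  # type: ignore[assignment]


def _derivatives(mc: float, gc: float, p: NetworkParams) -> tuple[float, float]:
    d_mc = -mc + p.odor_input - p.w_mc_gc * gc - p.w_fb_mc * p.fb
    d_gc = -gc + p.w_mc_gc * mc - p.w_sac_gc * p.sac_drive - 2.0 * p.w_fb_mc * p.fb
    return d_mc, d_gc


def jacobian_eigenvalues(params: NetworkParams) -> np.ndarray:
    """Eigenvalues of the linearised system: -1 ± i·w_mc_gc (always stable)."""
    w = params.w_mc_gc
    return np.array([-1 + 1j * w, -1 - 1j * w])


def integrate_dynamics(
    params: NetworkParams,
    init: PopulationState,
    dt: float = 0.01,
    t_end: float = 100.0,
    divergence_bound: float = 1e6,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-Euler integration of the rate equations with GC rectification.

    Returns ``(times, states)`` where ``states`` has shape ``(n_steps + 1, 2)``
    with columns (MC, GC); row 0 is the initial condition. GC is clamped at 0
    after every step.

    Raises
    ------
    InvalidParameterError
        If ``dt <= 0``, ``t_end < dt`` or the initial state is non-finite.
    DivergenceError
        If either rate magnitude exceeds ``divergence_bound``.
    """
    if dt <= 0 or t_end < dt:
        raise InvalidParameterError(f"need dt > 0 and t_end >= dt, got dt={dt}, t_end={t_end}")
    s0 = init.as_array()
    if not np.all(np.isfinite(s0)):
        raise InvalidParameterError(f"non-finite initial state {init}")

    n_steps = int(round(t_end / dt))
    times = np.arange(n_steps + 1) * dt
    states = np.empty((n_steps + 1, 2))
    states[0] = s0
    mc, gc = float(s0[0]), max(0.0, float(s0[1]))
    mc_went_negative = False
    for k in range(1, n_steps + 1):
        d_mc, d_gc = _derivatives(mc, gc, params)
        mc = mc + dt * d_mc
        gc = max(0.0, gc + dt * d_gc)
        if abs(mc) > divergence_bound or gc > divergence_bound:
            raise DivergenceError(
                f"integration diverged at t={k * dt:.3f} "
                f"(MC={mc:.3g}, GC={gc:.3g}); unstable regime for {params}"
            )
        if mc < 0:
            mc_went_negative = True
        states[k] = (mc, gc)
    if mc_went_negative:
        warnings.warn(
            "MC/TC rate went negative during integration (MC is not rectified)",
            RuntimeWarning,
            stacklevel=2,
        )
    return times, states


def mc_nullcline(params: NetworkParams, mc_values: np.ndarray) -> np.ndarray:
    """GC values on the MC nullcline: GC = (I - MC - w_fb_mc*FB) / w_mc_gc.

    Raises
    ------
    DegenerateNullclineError
        If ``w_mc_gc == 0`` (the nullcline is the vertical line MC = I - w_fb*FB).
    """
    if params.w_mc_gc == 0:
        raise DegenerateNullclineError(
            "w_mc_gc = 0: MC nullcline is vertical and cannot be written as GC(MC)"
        )
    mc = np.asarray(mc_values, dtype=float)
    return (params.odor_input - mc - params.w_fb_mc * params.fb) / params.w_mc_gc


def gc_nullcline(params: NetworkParams, mc_values: np.ndarray) -> np.ndarray:
    """GC values on the (rectified) GC nullcline.

    GC = max(0, w_mc_gc*MC - w_sac_gc*SAC - 2*w_fb_mc*FB). The sign of the MC
    term is the one implied by the GC rate equation (the nullcline rises with
    MC), and the curve is clipped at zero because GC rates are rectified.
    """
    mc = np.asarray(mc_values, dtype=float)
    gc = params.w_mc_gc * mc - params.w_sac_gc * params.sac_drive - 2.0 * params.w_fb_mc * params.fb
    return np.maximum(0.0, gc)


def solve_fixed_point(params: NetworkParams, rectify: bool = True) -> FixedPoint:
    """Analytic steady state of the 2x2 linear system, with optional rectification.

    Substituting the MC steady state into the GC steady state gives

        GC* = (w*(I - w_fb*FB) - w_sac*SAC - 2*w_fb*FB) / (1 + w^2)
        MC* = I - w*GC* - w_fb*FB

    If ``rectify`` and GC* < 0 the network settles on the constrained branch
    GC = 0, MC = I - w_fb*FB (``rectified_branch`` is set on the result).
    """
    w = params.w_mc_gc
    drive_fb = params.w_fb_mc * params.fb
    gc = (
        w * (params.odor_input - drive_fb)
        - params.w_sac_gc * params.sac_drive
        - 2.0 * drive_fb
    ) / (1.0 + w * w)
    if rectify and gc < 0:
        return FixedPoint(
            state=PopulationState(mc_rate=params.odor_input - drive_fb, gc_rate=0.0),
            rectified_branch=True,
        )
    mc = params.odor_input - w * gc - drive_fb
    return FixedPoint(state=PopulationState(mc_rate=mc, gc_rate=gc), rectified_branch=False)


def feedback_delta(
    params_without_fb: NetworkParams,
    w_fb_mc: float,
    rectify: bool = True,
) -> tuple[float, float]:
    """Fixed-point rate change caused by stimulating the feedback at ``w_fb_mc``.

    Returns ``(delta_mc, delta_gc)`` = with-feedback minus without-feedback
    fixed-point rates. ``w_fb_mc = 0`` returns ``(0, 0)`` by convention (no
    stimulation); negative strengths are invalid.
    """
    if params_without_fb.feedback_on:
        raise InvalidParameterError("params_without_fb must have feedback_on=False")
    if w_fb_mc < 0 or not np.isfinite(w_fb_mc):
        raise InvalidParameterError(f"invalid feedback strength {w_fb_mc}")
    if w_fb_mc == 0:
        return 0.0, 0.0
    base = solve_fixed_point(params_without_fb, rectify=rectify).state
    stim = solve_fixed_point(params_without_fb.with_feedback(w_fb_mc), rectify=rectify).state
    return stim.mc_rate - base.mc_rate, stim.gc_rate - base.gc_rate


def sweep_parameter_grid(
    odor_input: float,
    w_sac_gc: float,
    w_mc_gc_axis: np.ndarray,
    w_fb_axis: np.ndarray,
    rectify: bool = True,
) -> SweepResult:
    """Baseline fixed points and feedback-induced changes over a parameter grid.

    Matrices are shaped ``(len(w_mc_gc_axis), len(w_fb_axis))``. Baselines are
    (by construction) constant along the feedback axis.
    """
    w_axis = np.asarray(w_mc_gc_axis, dtype=float)
    fb_axis = np.asarray(w_fb_axis, dtype=float)
    for name, ax in (("w_mc_gc_axis", w_axis), ("w_fb_axis", fb_axis)):
        if ax.size == 0:
            raise InvalidParameterError(f"{name} is empty")
        if ax.size > 1 and not np.all(np.diff(ax) > 0):
            raise InvalidParameterError(f"{name} must be strictly increasing")

    shape = (w_axis.size, fb_axis.size)
    baseline_mc = np.empty(shape)
    baseline_gc = np.empty(shape)
    delta_mc = np.empty(shape)
    delta_gc = np.empty(shape)
    rectified = np.zeros(shape, dtype=bool)
    for i, w in enumerate(w_axis):
        base_params = NetworkParams(
            odor_input=odor_input, w_mc_gc=w, w_sac_gc=w_sac_gc, feedback_on=False
        )
        base = solve_fixed_point(base_params, rectify=rectify)
        baseline_mc[i, :] = base.state.mc_rate
        baseline_gc[i, :] = base.state.gc_rate
        for j, w_fb in enumerate(fb_axis):
            try:
                d_mc, d_gc = feedback_delta(base_params, w_fb, rectify=rectify)
                if w_fb > 0:
                    stim = solve_fixed_point(
                        base_params.with_feedback(w_fb), rectify=rectify
                    )
                    rectified[i, j] = stim.rectified_branch
            except (InvalidParameterError, DivergenceError) as exc:
                raise type(exc)(
                    f"{exc} [at grid cell w_mc_gc={w}, w_fb={w_fb}]"
                ) from exc
            delta_mc[i, j] = d_mc
            delta_gc[i, j] = d_gc
    return SweepResult(
        w_mc_gc_axis=w_axis,
        w_fb_axis=fb_axis,
        baseline_mc=baseline_mc,
        baseline_gc=baseline_gc,
        delta_mc=delta_mc,
        delta_gc=delta_gc,
        rectified=rectified,
    )
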