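"""Numerical integration of the HCO and the phased-pulse protocol.

The integrator is an adaptive Dormand-Prince 5(4) scheme (numba-compiled)
run at tight tolerances (atol 1e-8, rel 1e-9 by default); a hard cap on the
step size is available through ``SolverOptions.max_step``.  The square
conductance pulse is handled by splitting the integration at the pulse
onset and offset so every segment has a smooth right-hand side and the
state at pulse offset is obtained exactly (not from the sampling grid).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks

from . import _kernels as K
from .model import ModelParameters, HCOState, NeuronState, PulseSpec

__all__ = [
    "SolverOptions",
    "Trajectory",
    "AttractorReference",
    "IntegrationError",
    "RegimeError",
    "integrate_trajectory",
    "settle_to_attractor",
    "run_pulse_protocol",
    "detect_spike_peaks",
]

log = logging.getLogger(__name__)

#: cycle periods shorter than this are paw-shake-like ("fast")
FAST_CP_LIMIT = 0.210


class IntegrationError(RuntimeError):
    """Solver failure; carries the last successfully reached time."""

    def __init__(self, msg, t_last):
        super().__init__(f"{msg} (last good time t={t_last:.6f} s)")
        self.t_last = t_last


class RegimeError(RuntimeError):
    """No rhythm of the requested class was found."""


@dataclass(frozen=True)
class SolverOptions:
    rtol: float = 1e-9
    atol: float = 1e-8
    max_step: float = 0.0      # 0 disables the hard cap
    dt_out: float = 1e-4       # output sampling interval (s)

    def replace(self, **kw) -> "SolverOptions":
        return replace(self, **kw)


@dataclass
class Trajectory:
    """Densely sampled solution with run metadata.

    ``y`` has one row per time sample; 16 columns for the full model,
    14 for the reduced (constant-hCaS) model.
    """

    t: np.ndarray
    y: np.ndarray
    params: ModelParameters
    pulse: PulseSpec | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_vars(self) -> int:
        return self.y.shape[1]

    def V(self, neuron: int) -> np.ndarray:
        off = (8 if self.n_vars == 16 else 7) * (neuron - 1)
        return self.y[:, off]

    def var(self, neuron: int, name: str) -> np.ndarray:
        names = (["V", "h_NaF", "m_NaS", "h_NaS", "m_K", "m_CaS", "h_CaS",
                  "m_Syn"] if self.n_vars == 16 else
                 ["V", "h_NaF", "m_NaS", "h_NaS", "m_K", "m_CaS", "m_Syn"])
        per = len(names)
        return self.y[:, per * (neuron - 1) + names.index(name)]

    def final_state(self) -> HCOState:
        if self.n_vars != 16:
            raise ValueError("final_state is defined for the full model only")
        return HCOState.from_array(self.y[-1], t=float(self.t[-1]))


def _segments(t0, t_end, pulse: PulseSpec | None):
    """(t_start, t_stop, g_E) pieces with a smooth RHS on each."""
    if pulse is None or pulse.g_E == 0.0 or pulse.t_pul is None:
        return [(t0, t_end, 0.0)]
    t_on = max(t0, pulse.t_pul)
    t_off = min(t_end, pulse.t_pul + pulse.d_pul)
    segs = []
    if t_on > t0:
        segs.append((t0, t_on, 0.0))
    if t_off > t_on:
        segs.append((t_on, t_off, pulse.g_E))
    if t_end > t_off:
        segs.append((t_off, t_end, 0.0))
    return segs or [(t0, t_end, 0.0)]


def integrate_trajectory(initial, params: ModelParameters,
                         pulse: PulseSpec | None, t_end: float,
                         options: SolverOptions = SolverOptions()) -> Trajectory:
    """Integrate the full 16-variable HCO from ``initial`` up to ``t_end``.

    ``initial`` is an :class:`HCOState` or a 16-vector (then taken at t=0).
    Deterministic for fixed inputs and options.
    """
    if isinstance(initial, HCOState):
        y0, t0 = initial.as_array(), initial.t
    else:
        y0, t0 = np.asarray(initial, dtype=float), 0.0
    if t_end <= t0:
        raise ValueError("t_end must exceed the initial time")
    p = params.as_array()
    EE = pulse.E_E if pulse is not None else 0.0

    ts_parts = [np.array([t0])]
    ys_parts = [y0[None, :]]
    meta = {}
    for (ta, tb, gE) in _segments(t0, t_end, pulse):
        ts, ys, yfin, ok = K.integrate_segment(
            ys_parts[-1][-1].copy(), ta, tb, p, gE, EE,
            options.rtol, options.atol, options.max_step, options.dt_out,
            0, 0.0, 0.0)
        if not ok:
            t_last = ts[-1] if len(ts) else ta
            raise IntegrationError("integration failed", t_last)
        ts_parts.append(ts)
        ys_parts.append(ys)
        if len(ts) == 0 or ts[-1] < tb - 1e-12:
            ts_parts.append(np.array([tb]))
            ys_parts.append(yfin[None, :])
        if pulse is not None and gE > 0.0:
            meta["offset_state"] = yfin.copy()
            meta["t_off"] = tb
            meta["t_pul"] = ta
    t = np.concatenate(ts_parts)
    y = np.vstack(ys_parts)
    keep = np.concatenate([[True], np.diff(t) > 1e-13])
    return Trajectory(t[keep], y[keep], params, pulse, meta)


def detect_spike_peaks(traj: Trajectory, neuron: int, threshold: float = 0.0,
                       refractory: float = 0.001) -> np.ndarray:
    """Times of spike peaks: strict local maxima of V above ``threshold``,
    separated by at least ``refractory`` seconds."""
    V = traj.V(neuron)
    if len(traj.t) < 3:
        return np.empty(0)
    dt = float(np.median(np.diff(traj.t)))
    idx, _ = find_peaks(V, height=threshold,
                        distance=max(1, int(round(refractory / dt))))
    return traj.t[idx]


@dataclass
class AttractorReference:
    """A settled rhythm: regime class, its period, and a phase reference.

    Phase 0% is the first spike peak of a burst of neuron #2;
    ``cycle_start_state`` is the state vector captured at such an instant,
    so protocol runs can start at a known phase.
    """

    regime: str
    cycle_period: float
    phase_zero_times: np.ndarray
    cycle_start_state: np.ndarray
    params: ModelParameters
    options: SolverOptions
    burst_duration: float = np.nan
    interburst_interval: float = np.nan

    @property
    def frequency(self) -> float:
        return 1.0 / self.cycle_period


def _default_initial(regime: str = "slow") -> np.ndarray:
    """Asymmetric standard start (V1 = -20, V2 = -60 mV, every gate at its
    own steady state); relaxes onto the slow rhythm."""
    n1 = NeuronState.at_rest(-20.0)
    n2 = NeuronState.at_rest(-60.0)
    return HCOState(n1, n2).as_array()


def _fast_seed(params: ModelParameters,
               options: SolverOptions) -> np.ndarray:
    """A state inside the fast rhythm's basin: run the constant-hCaS
    (14-variable) system at a nearly inactivated level until it bursts
    fast, then restore hCaS as a dynamic variable at that level.  (A cold
    asymmetric start drifts into the slow basin because hCaS deinactivates
    during the initial long silent phases.)"""
    y16 = _default_initial()
    y14 = np.concatenate([np.delete(y16[:8], 6), np.delete(y16[8:], 6)])
    h0 = 0.01
    _, _, yfin, ok = K.integrate_segment(
        y14, 0.0, 6.0, params.as_array(), 0.0, 0.0,
        options.rtol, options.atol, options.max_step, -1.0, 1, h0, h0)
    if not ok:
        raise IntegrationError("fast-seed pre-run failed", 0.0)
    y = np.empty(16)
    y[:6] = yfin[:6]
    y[6] = h0
    y[7] = yfin[6]
    y[8:14] = yfin[7:13]
    y[14] = h0
    y[15] = yfin[13]
    return y


def settle_to_attractor(params: ModelParameters = ModelParameters(),
                        regime: str = "slow",
                        options: SolverOptions = SolverOptions(),
                        initial=None, t_max: float = 60.0,
                        chunk: float = 10.0, cp_rtol: float = 1e-3,
                        spike_threshold: float = 0.0) -> AttractorReference:
    """Integrate until consecutive cycle periods agree to ``cp_rtol``.

    The regime is classified by the settled CP against 210 ms and must
    match the request, else :class:`RegimeError` is raised.
    """
    from .bursts import segment_bursts

    if regime not in ("slow", "fast"):
        raise ValueError("regime must be 'slow' or 'fast'")
    if initial is not None:
        y = np.asarray(initial, dtype=float)
    elif regime == "fast":
        y = _fast_seed(params, options)
    else:
        y = _default_initial()
    t_acc = 0.0
    while t_acc < t_max:
        # the system is autonomous: integrate one chunk at a time from the
        # reached state and look for period convergence within the chunk
        traj = integrate_trajectory(y, params, None, chunk, options=options)
        y = traj.y[-1].copy()
        t_acc += chunk
        spikes = detect_spike_peaks(traj, 2, threshold=spike_threshold)
        gap = 0.050 if regime == "fast" else 0.150
        bursts = segment_bursts(spikes, gap_threshold=gap)
        onsets = np.array([b.first_spike for b in bursts])
        if len(onsets) >= 4:
            cps = np.diff(onsets)
            if abs(cps[-1] - cps[-2]) < cp_rtol * cps[-1]:
                cp = float(cps[-1])
                found = "fast" if cp < FAST_CP_LIMIT else "slow"
                if found != regime:
                    raise RegimeError(
                        f"settled on a {found} rhythm (CP={cp:.4f} s) "
                        f"while {regime} was requested")
                # state snapshot at the last complete phase-zero instant
                i0 = int(np.searchsorted(traj.t, onsets[-2]))
                bd = np.array([b.last_spike - b.first_spike
                               for b in bursts[:-1]])
                log.info("settled %s rhythm: CP=%.4f s after %.1f s",
                         regime, cp, t_acc)
                return AttractorReference(
                    regime=regime, cycle_period=cp,
                    phase_zero_times=onsets,
                    cycle_start_state=traj.y[i0].copy(),
                    params=params, options=options,
                    burst_duration=float(bd[-1]),
                    interburst_interval=float(cp - bd[-1]))
    raise RegimeError(f"no settled {regime} rhythm within {t_max} s")


def run_pulse_protocol(ref: AttractorReference, p_pul: float, d_pul: float,
                       g_E: float = 1.0, E_E: float = 0.0,
                       post_horizon: float = 15.0,
                       options: SolverOptions | None = None,
                       spike_threshold: float = 0.0,
                       gap_threshold: float = 0.050) -> Trajectory:
    """Apply the phased square pulse to both neurons from the slow rhythm.

    Time 0 of the returned trajectory is the phase-zero instant (first
    spike peak of a burst of neuron #2); the pulse starts at
    ``p_pul/100 * cycle_period`` and lasts ``d_pul`` seconds.  Integration
    continues after pulse offset until the rhythm slows back down (first
    completed cycle with CP >= 210 ms) or ``post_horizon`` elapses — the
    latter case is flagged ``stable_fast`` in the metadata rather than
    raised, since a switch to the coexisting fast attractor is a valid
    protocol outcome.
    """
    from .bursts import segment_bursts

    if ref.regime != "slow":
        raise ValueError("pulse protocol starts from the slow rhythm")
    if not 0 <= p_pul < 100:
        raise ValueError("p_pul must lie in [0, 100)")
    options = options or ref.options
    t_pul = p_pul / 100.0 * ref.cycle_period
    pulse = PulseSpec(g_E=g_E, d_pul=d_pul, t_pul=t_pul, p_pul=p_pul, E_E=E_E)
    t_off = t_pul + d_pul

    traj = integrate_trajectory(ref.cycle_start_state, ref.params, pulse,
                                t_off, options=options)
    meta = dict(traj.meta)
    meta.update(p_pul=p_pul, d_pul=d_pul, g_E=g_E,
                cycle_period=ref.cycle_period, returned=False,
                stable_fast=False, t_return=np.nan)
    if g_E == 0.0:
        meta.update(t_pul=t_pul, t_off=t_off,
                    offset_state=traj.y[-1].copy())

    # post-pulse continuation in chunks until return to the slow rhythm
    t_parts = [traj.t]
    y_parts = [traj.y]
    t_now = t_off
    while t_now < t_off + post_horizon:
        t_next = min(t_now + 2.0, t_off + post_horizon)
        seg = integrate_trajectory(y_parts[-1][-1], ref.params, None,
                                   t_next - t_now, options=options)
        t_parts.append(seg.t[1:] + t_now)
        y_parts.append(seg.y[1:])
        t_now = t_next
        post = Trajectory(np.concatenate(t_parts), np.vstack(y_parts),
                          ref.params)
        spikes = detect_spike_peaks(post, 2, threshold=spike_threshold)
        spikes = spikes[spikes >= t_off]
        bursts = segment_bursts(spikes, gap_threshold=gap_threshold)
        onsets = np.array([b.first_spike for b in bursts])
        if len(onsets) >= 2:
            cps = np.diff(onsets)
            slow = np.nonzero(cps >= FAST_CP_LIMIT)[0]
            if len(slow):
                meta["returned"] = True
                meta["t_return"] = float(onsets[slow[0]])
                log.info("returned to slow rhythm at t=%.3f s "
                         "(%.3f s after pulse offset)",
                         meta["t_return"], meta["t_return"] - t_off)
                break
    else:
        meta["stable_fast"] = True
        log.info("no return within %.1f s after offset: stable fast rhythm",
                 post_horizon)
    return Trajectory(np.concatenate(t_parts), np.vstack(y_parts),
                      ref.params, pulse, meta)
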