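"""The constant-hCaS reduced model and hCaS-freezing experiments.

Holding the slow calcium inactivation constant removes the slowest
timescale from each neuron: the 16-variable HCO becomes a 14-variable
system whose hCaS levels are parameters.  The reduced model isolates the
mechanism of the transient asymmetry: the duty-cycle difference between
the neurons is controlled by the difference in their hCaS levels, and
clamping hCaS at pulse offset freezes the burst metrics at asymmetric
baselines with (near-)zero trends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import _kernels as K
from .model import ModelParameters, NeuronState, HCOState
from .simulate import (SolverOptions, Trajectory, AttractorReference,
                       detect_spike_peaks, run_pulse_protocol,
                       IntegrationError)
from .bursts import segment_bursts, cycle_metrics, extract_transient_episode

__all__ = ["ReducedModelConfig", "run_constant_hcas", "constant_hcas_grid",
           "dc_difference_regression", "freeze_hcas_experiment"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReducedModelConfig:
    """Fixed inactivation levels and averaging window for a reduced run."""

    h_CaS1: float = 0.01
    h_CaS2: float = 0.01
    run_time: float = 1000.0
    n_tail_bursts: int = 20

    def __post_init__(self):
        if not (0 <= self.h_CaS1 <= 1 and 0 <= self.h_CaS2 <= 1):
            raise ValueError("hCaS levels must lie in [0, 1]")
        if self.run_time <= 0 or self.n_tail_bursts < 1:
            raise ValueError("invalid run_time / n_tail_bursts")


def reduced_initial() -> np.ndarray:
    """Standard asymmetric start for the 14-variable reduced system."""
    y16 = HCOState(NeuronState.at_rest(-20.0),
                   NeuronState.at_rest(-60.0)).as_array()
    return np.concatenate([np.delete(y16[:8], 6), np.delete(y16[8:], 6)])


def integrate_reduced(y0, t_end, h1, h2,
                      params: ModelParameters = ModelParameters(),
                      g_E: float = 0.0, E_E: float = 0.0,
                      options: SolverOptions = SolverOptions(),
                      dense: bool = True):
    """Integrate the 14-variable system; returns (Trajectory|None, yfinal)."""
    dt_out = options.dt_out if dense else -1.0
    ts, ys, yfin, ok = K.integrate_segment(
        np.asarray(y0, dtype=float).copy(), 0.0, t_end, params.as_array(),
        g_E, E_E, options.rtol, options.atol, options.max_step, dt_out,
        1, h1, h2)
    if not ok:
        raise IntegrationError("reduced-model integration failed",
                               ts[-1] if len(ts) else 0.0)
    traj = None
    if dense:
        traj = Trajectory(np.concatenate([ts, [t_end]]),
                          np.vstack([ys, yfin[None, :]]), params,
                          meta={"h_CaS1": h1, "h_CaS2": h2})
    return traj, yfin


def run_constant_hcas(cfg: ReducedModelConfig,
                      params: ModelParameters = ModelParameters(),
                      options: SolverOptions = SolverOptions(),
                      gap_threshold: float = 0.050,
                      tail_window: float = 10.0) -> dict:
    """Steady bursting metrics of the reduced model at fixed hCaS levels.

    Integrates for ``cfg.run_time`` (only the final ``tail_window`` is
    stored densely), then averages CP/BD/IBI/DC over the last
    ``cfg.n_tail_bursts`` bursts of each neuron.  Returns a flat dict;
    ``rhythmic`` is False when either neuron shows too few bursts.
    """
    y0 = reduced_initial()
    settle = max(cfg.run_time - tail_window, 0.0)
    if settle > 0:
        _, y0 = integrate_reduced(y0, settle, cfg.h_CaS1, cfg.h_CaS2,
                                  params, options=options, dense=False)
    traj, _ = integrate_reduced(y0, min(tail_window, cfg.run_time),
                                cfg.h_CaS1, cfg.h_CaS2, params,
                                options=options, dense=True)
    out = {"h_CaS1": cfg.h_CaS1, "h_CaS2": cfg.h_CaS2, "rhythmic": True}
    for neuron in (1, 2):
        spikes = detect_spike_peaks(traj, neuron)
        df = cycle_metrics(segment_bursts(spikes, gap_threshold))
        if df is None or len(df) < cfg.n_tail_bursts:
            out["rhythmic"] = False
            for m in ("CP", "BD", "IBI", "DC"):
                out[f"{m}{neuron}"] = np.nan
            continue
        tail = df.iloc[-cfg.n_tail_bursts:]
        for m in ("CP", "BD", "IBI", "DC"):
            out[f"{m}{neuron}"] = float(tail[m].mean())
    return out


def constant_hcas_grid(levels=None, params: ModelParameters = ModelParameters(),
                       run_time: float = 1000.0, n_tail_bursts: int = 20,
                       options: SolverOptions = SolverOptions()) -> pd.DataFrame:
    """Grid of reduced-model runs over all (hCaS1, hCaS2) combinations.

    The canonical grid varies both levels from 0.0075 to 0.02 in steps of
    0.0005 (26 x 26 = 676 runs).
    """
    if levels is None:
        levels = np.round(np.arange(0.0075, 0.02 + 1e-9, 0.0005), 5)
    levels = np.asarray(levels, dtype=float)
    rows = []
    for h1 in levels:
        for h2 in levels:
            cfg = ReducedModelConfig(h_CaS1=float(h1), h_CaS2=float(h2),
                                     run_time=run_time,
                                     n_tail_bursts=n_tail_bursts)
            rows.append(run_constant_hcas(cfg, params, options=options))
    return pd.DataFrame(rows)


def dc_difference_regression(grid: pd.DataFrame) -> dict:
    """OLS of (DC2 - DC1) against (hCaS2 - hCaS1) over rhythmic grid cells.

    Non-rhythmic cells are excluded (their count is reported).  By the
    neuron-exchange symmetry the intercept is ~0 and the diagonal
    (equal levels) sits exactly at the origin.
    """
    ok = grid[grid["rhythmic"]]
    n_excluded = int(len(grid) - len(ok))
    if n_excluded:
        log.info("excluding %d non-rhythmic cells", n_excluded)
    dh = (ok["h_CaS2"] - ok["h_CaS1"]).to_numpy()
    ddc = (ok["DC2"] - ok["DC1"]).to_numpy()
    res = stats.linregress(dh, ddc)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r_squared": float(res.rvalue ** 2), "n": int(len(ok)),
            "n_excluded": n_excluded}


def _full_to_reduced(y16):
    return np.concatenate([np.delete(y16[:8], 6), np.delete(y16[8:], 6)])


def freeze_hcas_experiment(ref: AttractorReference, p_pul: float,
                           d_pul: float, g_E: float = 1.0,
                           mode: str = "asymmetric",
                           post_horizon: float = 8.0,
                           options: SolverOptions | None = None):
    """Clamp hCaS in both neurons at pulse offset and follow the bursting.

    ``asymmetric`` clamps each neuron at the level it reached at pulse
    offset; ``symmetric`` clamps both at the mean of those levels.  The
    clamped system bursts indefinitely (no hCaS drift, hence no return to
    the slow rhythm); the analysis window and the number of regressed
    bursts are matched to the corresponding unclamped transient episode.

    Returns (episode, unclamped_episode, clamp_levels).
    """
    if mode not in ("asymmetric", "symmetric"):
        raise ValueError("mode must be 'asymmetric' or 'symmetric'")
    options = options or ref.options
    traj = run_pulse_protocol(ref, p_pul, d_pul, g_E,
                              post_horizon=post_horizon, options=options)
    unclamped = extract_transient_episode(traj)
    off16 = traj.meta["offset_state"]
    t_off = traj.meta["t_off"]
    h1, h2 = float(off16[6]), float(off16[14])
    if mode == "symmetric":
        h1 = h2 = 0.5 * (h1 + h2)

    # follow the clamped system for the span of the unclamped episode
    n_keep = max(unclamped.n_cycles, 3)
    span = max(traj.meta.get("t_return", t_off + post_horizon) - t_off, 2.0)
    red, _ = integrate_reduced(_full_to_reduced(off16), span + 1.0, h1, h2,
                               ref.params, options=options, dense=True)
    cycles = {}
    counts = {}
    for neuron in (1, 2):
        spikes = detect_spike_peaks(red, neuron)
        df = cycle_metrics(segment_bursts(spikes, 0.050))
        if df is None:
            df = pd.DataFrame(columns=["onset", "CP", "BD", "IBI", "DC"])
        df = df.iloc[:n_keep].reset_index(drop=True)
        cycles[neuron] = df
        counts[neuron] = len(df)
    from .bursts import TransientEpisode
    ep = TransientEpisode(cycles=cycles, pulse=traj.pulse,
                          n_cycles=counts[2], n_cycles_per_neuron=counts,
                          stable_fast=False, qualifies=unclamped.qualifies,
                          t_off=0.0,
                          meta={"mode": mode, "h_CaS1": h1, "h_CaS2": h2,
                                "n_keep": n_keep})
    return ep, unclamped, (h1, h2)
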