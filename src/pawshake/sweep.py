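"""Phase x duration sweep of the pulse protocol and aggregate statistics.

One pulse protocol is run per grid cell from a single converged slow-rhythm
reference (the slow attractor is unique, so re-settling per cell would only
repeat work).  Each cell yields the transient episode's cycle count, the
hCaS values at pulse offset, a stable-fast flag, and per-neuron OLS slopes
of BD/IBI/DC against burst-onset time.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy import stats

from .simulate import AttractorReference, run_pulse_protocol
from .bursts import extract_transient_episode, regress_episode

__all__ = ["phase_duration_sweep", "select_episodes", "aggregate_slopes",
           "default_grid"]

log = logging.getLogger(__name__)

#: the full protocol grid: 0-100% in 0.25% steps, 200-1200 ms in 5 ms steps
def default_grid():
    return (np.arange(0.0, 100.0, 0.25),
            np.round(np.arange(0.200, 1.200 + 1e-9, 0.005), 3))


def _cell_key(phase, duration, g_E, params):
    h = hashlib.sha1()
    h.update(json.dumps([round(phase, 6), round(duration, 6), round(g_E, 6),
                         sorted(params.__dict__.items())],
                        default=str).encode())
    return h.hexdigest()[:16]


def _run_cell(ref, phase, duration, g_E, post_horizon, min_cycles,
              max_cycles):
    row = {"phase": phase, "duration": duration, "g_E": g_E}
    try:
        traj = run_pulse_protocol(ref, phase, duration, g_E,
                                  post_horizon=post_horizon)
        ep = extract_transient_episode(traj, min_cycles=min_cycles,
                                       max_cycles=max_cycles)
        off = traj.meta.get("offset_state")
        row.update(n_cycles=ep.n_cycles,
                   n_cycles_1=ep.n_cycles_per_neuron[1],
                   n_cycles_2=ep.n_cycles_per_neuron[2],
                   stable_fast=ep.stable_fast, qualifies=ep.qualifies,
                   hcas1_off=float(off[6]), hcas2_off=float(off[14]),
                   t_return=traj.meta.get("t_return", np.nan),
                   failed=False)
        for metric in ("BD", "IBI", "DC"):
            for neuron in (1, 2):
                res = regress_episode(ep, metric, neuron)
                row[f"slope_{metric}_{neuron}"] = (
                    np.nan if res is None else res.slope)
                row[f"r_{metric}_{neuron}"] = (
                    np.nan if res is None else res.pearson_r)
    except Exception as exc:  # record, never abort the sweep
        log.warning("cell (%.2f%%, %.3f s) failed: %s", phase, duration, exc)
        row.update(n_cycles=0, n_cycles_1=0, n_cycles_2=0, stable_fast=False,
                   qualifies=False, hcas1_off=np.nan, hcas2_off=np.nan,
                   t_return=np.nan, failed=True)
    return row


def phase_duration_sweep(ref: AttractorReference, phases=None, durations=None,
                         g_E: float = 1.0, post_horizon: float = 8.0,
                         min_cycles: int = 5, max_cycles: int = 9,
                         n_jobs: int = 1,
                         cache_dir=None) -> pd.DataFrame:
    """Run the pulse protocol over a rectangular phase x duration grid.

    Deterministic per cell; cells are cached by a key over (phase,
    duration, g_E, parameters) when ``cache_dir`` is given, so interrupted
    sweeps resume where they stopped.
    """
    if phases is None or durations is None:
        dphases, ddur = default_grid()
        phases = dphases if phases is None else phases
        durations = ddur if durations is None else durations
    phases = np.asarray(phases, dtype=float)
    durations = np.asarray(durations, dtype=float)
    cache = Path(cache_dir) if cache_dir else None
    if cache:
        cache.mkdir(parents=True, exist_ok=True)

    cells = [(p, d) for p in phases for d in durations]
    rows = [None] * len(cells)
    todo = []
    for i, (p, d) in enumerate(cells):
        if cache:
            f = cache / (_cell_key(p, d, g_E, ref.params) + ".json")
            if f.exists():
                rows[i] = json.loads(f.read_text())
                continue
        todo.append(i)

    computed = Parallel(n_jobs=n_jobs)(
        delayed(_run_cell)(ref, cells[i][0], cells[i][1], g_E, post_horizon,
                           min_cycles, max_cycles)
        for i in todo)
    for i, row in zip(todo, computed):
        rows[i] = row
        if cache:
            f = cache / (_cell_key(*cells[i], g_E, ref.params) + ".json")
            f.write_text(json.dumps(row, default=float))
    return pd.DataFrame(rows)


def select_episodes(grid: pd.DataFrame, min_cycles: int = 5,
                    max_cycles: int = 9, phase_range=None,
                    duration_range=None) -> pd.DataFrame:
    """Episodes used for aggregate statistics: within the cycle-count band,
    not switched to the stable fast rhythm, optionally windowed."""
    m = (grid["n_cycles"].between(min_cycles, max_cycles)
         & ~grid["stable_fast"] & ~grid["failed"])
    if phase_range is not None:
        m &= grid["phase"].between(*phase_range)
    if duration_range is not None:
        m &= grid["duration"].between(*duration_range)
    out = grid[m].copy()
    log.info("selected %d of %d episodes", len(out), len(grid))
    return out


def aggregate_slopes(episodes: pd.DataFrame, metric: str,
                     neuron: int) -> dict:
    """Median/quartiles/mean of per-episode slopes plus a two-sided
    one-sample Wilcoxon signed-rank test of the median against zero."""
    col = f"slope_{metric}_{neuron}"
    s = episodes[col].dropna().to_numpy()
    if len(s) == 0:
        raise ValueError("no episodes to aggregate")
    if np.allclose(s, 0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(s).pvalue) if len(s) > 1 else np.nan
    return {"metric": metric, "neuron": neuron, "n": int(len(s)),
            "median": float(np.median(s)),
            "q1": float(np.percentile(s, 25)),
            "q3": float(np.percentile(s, 75)),
            "mean": float(np.mean(s)),
            "wilcoxon_p": p}
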