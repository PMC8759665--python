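"""Burst segmentation, per-cycle metrics and episode regression.

Definitions (all times from spike peaks):
  CP  — first spike peak of a burst to first spike peak of the next burst
  BD  — first to last spike peak of the same burst
  IBI — CP - BD
  DC  — 100 * BD / CP
Paw-shake-like cycles are cycles with CP < 210 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import PulseSpec
from .simulate import Trajectory, detect_spike_peaks, FAST_CP_LIMIT

__all__ = [
    "Burst",
    "RegressionResult",
    "TransientEpisode",
    "segment_bursts",
    "cycle_metrics",
    "extract_transient_episode",
    "regress_episode",
    "phase_sliding_average",
]

#: default intra-burst gap threshold for model spike trains (s)
DEFAULT_GAP = 0.050


@dataclass(frozen=True)
class Burst:
    first_spike: float
    last_spike: float
    n_spikes: int

    def __post_init__(self):
        if self.last_spike < self.first_spike or self.n_spikes < 1:
            raise ValueError("invalid burst")

    @property
    def duration(self) -> float:
        return self.last_spike - self.first_spike


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    pearson_r: float
    n_points: int


def segment_bursts(spikes, gap_threshold: float = DEFAULT_GAP) -> list[Burst]:
    """Group an ordered spike train into bursts: consecutive spikes with
    inter-spike interval <= gap_threshold share a burst."""
    spikes = np.asarray(spikes, dtype=float)
    if len(spikes) == 0:
        return []
    if np.any(np.diff(spikes) <= 0):
        raise ValueError("spike times must be strictly increasing")
    breaks = np.nonzero(np.diff(spikes) > gap_threshold)[0]
    starts = np.concatenate([[0], breaks + 1])
    stops = np.concatenate([breaks, [len(spikes) - 1]])
    return [Burst(float(spikes[a]), float(spikes[b]), int(b - a + 1))
            for a, b in zip(starts, stops)]


def cycle_metrics(bursts: list[Burst]) -> pd.DataFrame | None:
    """Per-cycle metrics table with columns onset, CP, BD, IBI, DC.

    The final burst starts no complete cycle and contributes no row.
    Returns None when fewer than two bursts are available (CP needs the
    next burst), as an insufficient-data signal rather than an error.
    """
    if len(bursts) < 2:
        return None
    onsets = np.array([b.first_spike for b in bursts])
    bd = np.array([b.duration for b in bursts])
    cp = np.diff(onsets)
    bd = bd[:-1]
    ibi = cp - bd
    df = pd.DataFrame({"onset": onsets[:-1], "CP": cp, "BD": bd,
                       "IBI": ibi, "DC": 100.0 * bd / cp})
    df.index.name = "cycle"
    return df


@dataclass
class TransientEpisode:
    """Post-pulse paw-shake-like cycles of both neurons.

    ``cycles[n]`` holds the fast-cycle (CP < 210 ms) metrics of neuron n
    with onsets measured from pulse offset.  ``n_cycles`` counts the fast
    cycles of neuron #2 (the phase-reference neuron); per-neuron counts
    are kept alongside.  Episodes that switched to the stable fast rhythm
    are flagged and excluded from aggregate statistics downstream.
    """

    cycles: dict
    pulse: PulseSpec | None
    n_cycles: int
    n_cycles_per_neuron: dict
    stable_fast: bool
    qualifies: bool
    t_off: float
    meta: dict = field(default_factory=dict)

    def regress(self, metric: str, neuron: int,
                exclude_first: bool = True) -> RegressionResult | None:
        return regress_episode(self, metric, neuron,
                               exclude_first=exclude_first)


def extract_transient_episode(traj: Trajectory,
                              pulse: PulseSpec | None = None,
                              gap_threshold: float = DEFAULT_GAP,
                              spike_threshold: float = 0.0,
                              min_cycles: int = 5,
                              max_cycles: int = 9) -> TransientEpisode:
    """Pull the transient fast-burst episode out of a protocol trajectory.

    Only cycles whose burst onset lies at/after pulse offset and whose CP
    is below 210 ms are counted.  ``qualifies`` records the 5-9-cycle
    selection used for aggregate statistics.
    """
    pulse = pulse or traj.pulse
    meta = traj.meta or {}
    t_off = meta.get("t_off")
    if t_off is None:
        if pulse is not None and pulse.t_pul is not None:
            t_off = pulse.t_pul + pulse.d_pul
        else:
            t_off = float(traj.t[0])
    stable_fast = bool(meta.get("stable_fast", False))

    cycles = {}
    counts = {}
    for neuron in (1, 2):
        spikes = detect_spike_peaks(traj, neuron, threshold=spike_threshold)
        spikes = spikes[spikes >= t_off]
        df = cycle_metrics(segment_bursts(spikes, gap_threshold))
        if df is None:
            df = pd.DataFrame(columns=["onset", "CP", "BD", "IBI", "DC"])
        fast = df[df["CP"] < FAST_CP_LIMIT].copy()
        fast["onset"] -= t_off  # episode clock starts at pulse offset
        fast.reset_index(drop=True, inplace=True)
        cycles[neuron] = fast
        counts[neuron] = len(fast)

    n_cycles = counts[2]
    qualifies = (min_cycles <= n_cycles <= max_cycles) and not stable_fast
    return TransientEpisode(cycles=cycles, pulse=pulse, n_cycles=n_cycles,
                            n_cycles_per_neuron=counts,
                            stable_fast=stable_fast, qualifies=qualifies,
                            t_off=float(t_off), meta=dict(meta))


def regress_episode(ep: TransientEpisode, metric: str, neuron: int,
                    exclude_first: bool = True) -> RegressionResult | None:
    """OLS of a cycle metric against burst onset time.

    The first post-pulse burst is excluded by default (it is often
    degenerate, only a few spikes long).  Returns None when fewer than
    three cycles remain.
    """
    if metric not in ("CP", "BD", "IBI", "DC"):
        raise ValueError(f"unknown metric {metric!r}")
    df = ep.cycles[neuron]
    if exclude_first:
        df = df.iloc[1:]
    if len(df) < 3:
        return None
    res = stats.linregress(df["onset"].to_numpy(), df[metric].to_numpy())
    return RegressionResult(slope=float(res.slope),
                            intercept=float(res.intercept),
                            pearson_r=float(res.rvalue),
                            n_points=int(len(df)))


def phase_sliding_average(phases, slopes, window: float = 1.25,
                          grid=None) -> pd.DataFrame:
    """Sliding mean of per-episode slopes along pulse-onset phase.

    For each grid phase the mean of all slopes whose phase lies within
    +/- window/2 is reported; empty windows yield NaN (a gap, not zero).
    """
    phases = np.asarray(phases, dtype=float)
    slopes = np.asarray(slopes, dtype=float)
    if grid is None:
        grid = np.unique(phases)
    grid = np.asarray(grid, dtype=float)
    half = window / 2.0
    out = np.full(len(grid), np.nan)
    for i, g in enumerate(grid):
        m = np.abs(phases - g) <= half + 1e-12
        if m.any():
            out[i] = slopes[m].mean()
    return pd.DataFrame({"phase": grid, "slope": out})
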