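"""EMG burst analysis for paw-shake episodes.

Pipeline: full-wave rectification -> zero-lag 8-ms moving average ->
noise floor (mean/SD over a quiet interval of at least 200 ms) -> burst
detection at 3 x SD threshold -> per-cycle CP/BD/IBI/DC (onset-based:
CP is burst onset to next burst onset, BD onset to offset, IBI offset to
next onset) -> per-episode OLS slopes and Pearson R of each metric
against time (first burst excluded) -> per-muscle medians/quartiles and
a two-sided one-sample Wilcoxon signed-rank test of slopes against zero.

Recordings follow a plain-text dialect: a header line of muscle
abbreviations (MG, SO, BFA, IP, TA, VA) and whitespace-separated numeric
columns of band-pass-filtered EMG in mV sampled at 3000 Hz.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KNOWN_MUSCLES",
    "EMGRecording",
    "EMGFormatError",
    "read_s1_recording",
    "write_s1_recording",
    "preprocess_emg",
    "find_quiet_interval",
    "estimate_noise_floor",
    "detect_emg_bursts",
    "emg_cycle_metrics",
    "analyze_episode",
    "muscle_group_stats",
]

log = logging.getLogger(__name__)

#: flexors (swing-related) and extensors (stance-related)
KNOWN_MUSCLES = ("MG", "SO", "VA", "BFA", "IP", "TA")
FLEXORS = ("IP", "TA")
EXTENSORS = ("MG", "SO", "VA", "BFA")


class EMGFormatError(ValueError):
    """Malformed EMG text file (ragged columns, empty body, ...)."""


@dataclass
class EMGRecording:
    """Multi-channel EMG container; channels keyed by muscle name (mV)."""

    channels: dict
    sampling_rate: float = 3000.0
    session: str = ""
    animal: str = ""
    episode: str = ""

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise EMGFormatError(f"unequal channel lengths: {lengths}")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


def read_s1_recording(path, sampling_rate: float = 3000.0) -> EMGRecording:
    """Read a plain-text EMG file: header of muscle abbreviations, then
    whitespace-delimited numeric columns (one per muscle)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().split()
        if not header:
            raise EMGFormatError(f"{path}: empty file")
        for name in header:
            if name not in KNOWN_MUSCLES:
                warnings.warn(f"{path}: unknown muscle abbreviation "
                              f"{name!r}; keeping it as-is")
        try:
            data = pd.read_csv(fh, sep=r"\s+", header=None,
                               names=header, dtype=float)
        except Exception as exc:
            raise EMGFormatError(f"{path}: malformed numeric body: {exc}") \
                from None
    if data.isna().any().any():
        raise EMGFormatError(f"{path}: ragged columns / missing values")
    if len(data) == 0:
        raise EMGFormatError(f"{path}: header but no samples")
    # filename dialect: Number_Data_Session_Animal_Episode.txt
    parts = path.stem.split("_")
    ids = dict(zip(("session", "animal", "episode"), parts[2:5])) \
        if len(parts) >= 5 else {}
    return EMGRecording(channels={c: data[c].to_numpy() for c in header},
                        sampling_rate=sampling_rate, **ids)


def write_s1_recording(rec: EMGRecording, path) -> None:
    names = list(rec.channels)
    arr = np.column_stack([rec.channels[n] for n in names])
    header = " ".join(names)
    np.savetxt(path, arr, fmt="%.6f", header=header, comments="")


def preprocess_emg(x, sampling_rate: float = 3000.0,
                   window: float = 0.008) -> np.ndarray:
    """Full-wave rectify and smooth with a zero-lag centered moving
    average (window rounded to samples and forced odd); edges are
    reflect-padded."""
    x = np.abs(np.asarray(x, dtype=float))
    n = int(round(window * sampling_rate))
    n = max(1, n | 1)  # odd
    if n == 1:
        return x
    pad = n // 2
    xp = np.pad(x, pad, mode="reflect")
    kern = np.ones(n) / n
    return np.convolve(xp, kern, mode="valid")


def find_quiet_interval(x, sampling_rate: float = 3000.0,
                        width: float = 0.200) -> tuple[float, float]:
    """Deterministic stand-in for a hand-picked quiet stretch: the
    minimum-variance window of the requested width."""
    x = np.asarray(x, dtype=float)
    n = int(round(width * sampling_rate))
    if n > len(x):
        raise ValueError("recording shorter than the quiet-window width")
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    s1 = c1[n:] - c1[:-n]
    s2 = c2[n:] - c2[:-n]
    var = s2 / n - (s1 / n) ** 2
    i = int(np.argmin(var))
    return i / sampling_rate, (i + n) / sampling_rate


def estimate_noise_floor(x, sampling_rate: float = 3000.0,
                         quiet_interval=None) -> tuple[float, float]:
    """Mean and SD over a quiet interval of at least 200 ms.

    Pass the *raw* signal: its SD is the noise level sigma whose 3x
    multiple is the burst threshold applied to the rectified-smoothed
    envelope.  (The SD of the smoothed envelope itself would be shrunk by
    the averaging window and sit below the envelope's own baseline.)"""
    x = np.asarray(x, dtype=float)
    if quiet_interval is None:
        quiet_interval = find_quiet_interval(x, sampling_rate)
    t0, t1 = quiet_interval
    if t1 - t0 < 0.200 - 1e-9:
        raise ValueError("quiet interval must be at least 200 ms wide")
    i0, i1 = int(round(t0 * sampling_rate)), int(round(t1 * sampling_rate))
    if i0 < 0 or i1 > len(x):
        raise ValueError("quiet interval outside the recording")
    seg = x[i0:i1]
    return float(seg.mean()), float(seg.std())


def detect_emg_bursts(x, sampling_rate: float = 3000.0,
                      threshold: float | None = None,
                      noise_sd: float | None = None,
                      threshold_mult: float = 3.0,
                      min_burst: float = 0.010,
                      min_gap: float = 0.005) -> pd.DataFrame:
    """Burst onsets/offsets from threshold crossings of a preprocessed
    signal.

    ``threshold`` may be given directly or derived as
    ``threshold_mult * noise_sd``.  Gaps shorter than ``min_gap`` are
    merged first, then bursts shorter than ``min_burst`` are dropped.
    Returns a DataFrame with columns onset, offset (s).
    """
    x = np.asarray(x, dtype=float)
    if threshold is None:
        if noise_sd is None:
            raise ValueError("provide threshold or noise_sd")
        threshold = threshold_mult * noise_sd
    if threshold <= 0:
        raise ValueError("degenerate (non-positive) burst threshold; "
                         "is the noise estimate flat zero?")
    above = x > threshold
    edges = np.diff(above.astype(np.int8))
    onsets = np.nonzero(edges == 1)[0] + 1
    offsets = np.nonzero(edges == -1)[0] + 1
    if above[0]:
        onsets = np.concatenate([[0], onsets])
    if above[-1]:
        offsets = np.concatenate([offsets, [len(x)]])
    if len(onsets) == 0:
        return pd.DataFrame(columns=["onset", "offset"])
    on = onsets / sampling_rate
    off = offsets / sampling_rate
    # merge short gaps, then drop short bursts
    m_on, m_off = [on[0]], [off[0]]
    for a, b in zip(on[1:], off[1:]):
        if a - m_off[-1] < min_gap:
            m_off[-1] = b
        else:
            m_on.append(a)
            m_off.append(b)
    rows = [(a, b) for a, b in zip(m_on, m_off) if b - a >= min_burst]
    return pd.DataFrame(rows, columns=["onset", "offset"])


def emg_cycle_metrics(bursts: pd.DataFrame) -> pd.DataFrame | None:
    """Onset-based cycle metrics: CP onset-to-onset, BD onset-to-offset,
    IBI offset-to-next-onset; the final burst contributes no cycle."""
    if bursts is None or len(bursts) < 2:
        return None
    on = bursts["onset"].to_numpy()
    off = bursts["offset"].to_numpy()
    cp = np.diff(on)
    bd = (off - on)[:-1]
    ibi = cp - bd
    return pd.DataFrame({"onset": on[:-1], "CP": cp, "BD": bd, "IBI": ibi,
                         "DC": 100.0 * bd / cp})


def analyze_episode(rec: EMGRecording, quiet_interval=None,
                    threshold_mult: float = 3.0, min_burst: float = 0.010,
                    min_gap: float = 0.005) -> dict:
    """Full per-episode pipeline: returns {muscle: cycle-metrics frame}."""
    out = {}
    for name, raw in rec.channels.items():
        env = preprocess_emg(raw, rec.sampling_rate)
        qi = quiet_interval
        if qi is None:
            qi = find_quiet_interval(env, rec.sampling_rate)
        _, sd = estimate_noise_floor(raw, rec.sampling_rate, qi)
        bursts = detect_emg_bursts(env, rec.sampling_rate, noise_sd=sd,
                                   threshold_mult=threshold_mult,
                                   min_burst=min_burst, min_gap=min_gap)
        out[name] = emg_cycle_metrics(bursts)
    return out


def _episode_regressions(df: pd.DataFrame, exclude_first: bool = True):
    """Per-episode slope and Pearson R of BD/IBI/DC against burst onset
    time (clock zeroed at the first burst onset)."""
    if exclude_first:
        df = df.iloc[1:]
    if len(df) < 3:
        return None
    t = df["onset"].to_numpy() - df["onset"].to_numpy()[0]
    out = {}
    for m in ("BD", "IBI", "DC"):
        res = stats.linregress(t, df[m].to_numpy())
        out[f"slope_{m}"] = float(res.slope)
        out[f"r_{m}"] = float(res.rvalue)
    out["n_cycles"] = int(len(df))
    return out


def muscle_group_stats(episode_tables: dict,
                       exclude_first: bool = True) -> pd.DataFrame:
    """Aggregate per-muscle statistics over episodes.

    ``episode_tables`` maps muscle -> list of per-episode cycle-metric
    frames.  Returns one row per muscle and metric with the median/
    quartile slope, median Pearson R, episode count, and the two-sided
    one-sample Wilcoxon signed-rank p-value of the slopes against zero
    (exact distribution for n <= 25).
    """
    rows = []
    for muscle, tables in episode_tables.items():
        regs = []
        for df in tables:
            if df is None:
                continue
            r = _episode_regressions(df, exclude_first=exclude_first)
            if r is not None:
                regs.append(r)
        if not regs:
            log.warning("muscle %s: no usable episodes", muscle)
            continue
        if len(regs) < 6:
            warnings.warn(f"muscle {muscle}: only {len(regs)} episodes; "
                          "Wilcoxon test is weakly powered")
        rdf = pd.DataFrame(regs)
        for m in ("BD", "IBI", "DC"):
            s = rdf[f"slope_{m}"].to_numpy()
            method = "exact" if len(s) <= 25 else "approx"
            p = (float(stats.wilcoxon(s, method=method).pvalue)
                 if not np.allclose(s, 0) else 1.0)
            rows.append({
                "muscle": muscle, "metric": m, "n_episodes": len(s),
                "median_slope": float(np.median(s)),
                "q1_slope": float(np.percentile(s, 25)),
                "q3_slope": float(np.percentile(s, 75)),
                "median_r": float(rdf[f"r_{m}"].median()),
                "wilcoxon_p": p,
            })
    return pd.DataFrame(rows)
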