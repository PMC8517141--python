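"""Spike detection and frequency/conductance readouts.

The frequency statistic used throughout is the reciprocal of the mean
interspike interval between the 3rd and 6th detected spikes, i.e.
``f = 3000 / (t6 - t3)`` spikes/s.  Discarding the first two spikes skips the
settling transient after the trigger pulse; a run with fewer than six spikes
yields an *invalid* (not exceptional) result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpikeTrain",
    "FrequencyResult",
    "detect_spikes",
    "frequency_3to6",
    "ap_duration",
    "conductance_drop",
    "ConductanceDrop",
    "synchrony_check",
    "SynchronyResult",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Strictly increasing spike times (ms) for one cell."""

    times: np.ndarray
    cell: int | str | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1:
            raise ValueError("spike times must be 1-D")
        if len(times) > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class FrequencyResult:
    """3rd-to-6th-spike frequency; ``valid`` is False with < 6 spikes."""

    frequency: float
    valid: bool
    times_used: np.ndarray = field(default_factory=lambda: np.empty(0))


def detect_spikes(
    t: np.ndarray,
    v: np.ndarray,
    threshold: float = 0.0,
    min_interval: float = 1.0,
    cell: int | str | None = None,
) -> SpikeTrain:
    """Detect spikes as upward threshold crossings on a uniform time base.

    The spike time is the first sample at or above ``threshold`` of each
    crossing; crossings closer than ``min_interval`` ms to the previous
    accepted spike are ignored (refractory lockout).
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if len(t) != len(v):
        raise ValueError("time and voltage arrays differ in length")
    if len(t) > 2:
        dts = np.diff(t)
        if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
            raise ValueError("spike detection requires a uniform time base")
    above = v >= threshold
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if len(t) and above[0]:
        crossings = np.concatenate(([0], crossings))
    times = []
    last = -np.inf
    for i in crossings:
        if t[i] - last >= min_interval:
            times.append(t[i])
            last = t[i]
    return SpikeTrain(np.asarray(times), cell=cell)


def frequency_3to6(train: SpikeTrain) -> FrequencyResult:
    """Frequency from the mean of the three ISIs spanning spikes 3..6.

    ``f = 1000 * 3 / (t6 - t3)`` spikes/s; only the 3rd and 6th spike times
    enter.  Invalid result when fewer than six spikes were detected.
    """
    if len(train) < 6:
        return FrequencyResult(frequency=0.0, valid=False)
    t3, t6 = train.times[2], train.times[5]
    return FrequencyResult(
        frequency=3000.0 / (t6 - t3), valid=True, times_used=train.times[2:6]
    )


def ap_duration(t: np.ndarray, v: np.ndarray, level: float = -20.0) -> float | None:
    """Duration of a single AP as the time between the upward and downward
    crossings of ``level`` (mV), with linear interpolation between samples.

    Returns None when the trace never crosses the level (e.g. level above the
    AP peak).  The window is assumed to contain exactly one AP.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    above = v >= level
    if not above.any() or above.all():
        return None
    up = np.flatnonzero(above[1:] & ~above[:-1])
    down = np.flatnonzero(~above[1:] & above[:-1])
    if len(up) == 0 or len(down) == 0:
        return None

    def _interp(i: int, rising: bool) -> float:
        v0, v1 = v[i], v[i + 1]
        if v1 == v0:
            return t[i]
        return t[i] + (level - v0) / (v1 - v0) * (t[i + 1] - t[i])

    t_up = _interp(up[0], True)
    later_down = down[down >= up[0]]
    if len(later_down) == 0:
        return None
    t_down = _interp(later_down[0], False)
    return t_down - t_up


@dataclass(frozen=True)
class ConductanceDrop:
    """Fractional fall of a junction-conductance trace (percent) and the time
    at which the running mean first settles within 1% of the plateau."""

    percent: float
    g_start: float
    g_plateau: float
    time_to_plateau: float | None


def conductance_drop(t: np.ndarray, g: np.ndarray) -> ConductanceDrop:
    """Percentage fall from the first sample to the late-run plateau.

    The plateau is the mean over the final 10% of the trace; the drop is
    ``100 * (g_start - g_plateau) / g_start``.  Also reports the first time
    the running (moving-window) mean of ``g`` comes within 1% of the plateau;
    the window spans 10% of the trace, long enough to average out the
    per-spike conductance ripple.
    """
    t = np.asarray(t, dtype=float)
    g = np.asarray(g, dtype=float)
    if len(g) == 0:
        raise ValueError("empty conductance trace")
    g_start = float(g[0])
    if g_start == 0.0:
        raise ValueError("initial conductance is zero; drop undefined")
    win = max(1, len(g) // 10)
    g_plateau = float(np.mean(g[-win:]))
    csum = np.concatenate(([0.0], np.cumsum(g)))
    running = (csum[win:] - csum[:-win]) / win   # mean of g[i-win+1 .. i]
    tol = 0.01 * abs(g_plateau) if g_plateau != 0 else 0.01 * g_start
    close = np.abs(running - g_plateau) <= tol
    t_plateau = float(t[win - 1 + np.argmax(close)]) if close.any() else None
    return ConductanceDrop(
        percent=100.0 * (g_start - g_plateau) / g_start,
        g_start=g_start,
        g_plateau=g_plateau,
        time_to_plateau=t_plateau,
    )


@dataclass(frozen=True)
class SynchronyResult:
    frequencies: dict
    common_frequency: float
    max_relative_deviation: float
    excluded: tuple


def synchrony_check(trains: list[SpikeTrain]) -> SynchronyResult:
    """Per-cell 3-to-6 frequencies and their maximum pairwise relative spread.

    Trains with fewer than six spikes are excluded and reported.  The common
    frequency is the mean over valid trains; the deviation statistic is
    ``(f_max - f_min) / f_min``.
    """
    if len(trains) < 2:
        raise ValueError("synchrony check needs at least two spike trains")
    freqs, excluded = {}, []
    for i, tr in enumerate(trains):
        key = tr.cell if tr.cell is not None else i
        res = frequency_3to6(tr)
        if res.valid:
            freqs[key] = res.frequency
        else:
            excluded.append(key)
    if len(freqs) < 2:
        raise ValueError("fewer than two valid trains; cannot assess synchrony")
    values = np.array(list(freqs.values()))
    return SynchronyResult(
        frequencies=freqs,
        common_frequency=float(values.mean()),
        max_relative_deviation=float((values.max() - values.min()) / values.min()),
        excluded=tuple(excluded),
    )
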