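"""Core containers shared across the analysis stages.

The atomic unit of analysis is one well of a multi-well MEA plate at one
recording day (DIV, days in vitro): a set of per-electrode spike trains plus
the exposure condition of that well.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = ["SpikeTrain", "Condition", "WellRecording"]


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times of one electrode inside an observation window.

    Times are seconds, strictly increasing, and lie inside ``window``.
    The window is the observation period, not the span of the spikes; the
    train's mean rate is ``n_spikes / window_length``.
    """

    electrode: int
    spike_times: np.ndarray
    window: tuple[float, float]

    def __post_init__(self):
        t = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", t)
        if t.ndim != 1:
            raise ValueError("spike_times must be 1-D")
        if t.size and not np.all(np.diff(t) > 0):
            raise ValueError("spike times must be strictly increasing")
        lo, hi = self.window
        if hi <= lo:
            raise ValueError("window must have positive length")
        if t.size and (t[0] < lo or t[-1] > hi):
            raise ValueError("spike times must lie inside the window")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def window_length(self) -> float:
        return float(self.window[1] - self.window[0])

    @property
    def mean_rate(self) -> float:
        """Mean firing rate over the observation window (Hz)."""
        return self.n_spikes / self.window_length


@dataclass(frozen=True)
class Condition:
    """Exposure condition of a well: one compound at one concentration.

    Solvent controls use ``compound="DMSO"`` with ``concentration_um=0.0``
    (the 0.1% DMSO vehicle is a label, not a covariate).
    """

    compound: str = "DMSO"
    concentration_um: float = 0.0
    sex: str = "female"
    experiment: str = "exp1"


@dataclass(frozen=True)
class WellRecording:
    """One well at one DIV: 16 (or fewer) per-electrode spike trains.

    Each well carries exactly one condition for the whole experiment.
    ``duration_s`` is the recording length; trains share the same window.
    """

    well: str
    div: int
    condition: Condition
    trains: Mapping[int, SpikeTrain]
    duration_s: float
    n_electrodes: int
    plate: int = 0

    @property
    def electrodes(self) -> list[int]:
        return sorted(self.trains)

    @property
    def n_spikes(self) -> int:
        return sum(tr.n_spikes for tr in self.trains.values())

    def pooled_spikes(self) -> tuple[np.ndarray, np.ndarray]:
        """All spikes of the well merged into one time-sorted sequence.

        Returns (times, electrode_ids), both sorted by time with a stable
        sort so electrode order breaks exact ties deterministically.
        """
        if not self.trains:
            return np.empty(0), np.empty(0, dtype=int)
        times = np.concatenate([self.trains[e].spike_times for e in self.electrodes])
        elecs = np.concatenate(
            [np.full(self.trains[e].n_spikes, e, dtype=int) for e in self.electrodes]
        )
        order = np.argsort(times, kind="stable")
        return times[order], elecs[order]

    def subset(self, electrodes) -> "WellRecording":
        """Restrict to a subset of electrodes (e.g. after activity filtering)."""
        keep = {e: tr for e, tr in self.trains.items() if e in set(electrodes)}
        return replace(self, trains=keep)
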