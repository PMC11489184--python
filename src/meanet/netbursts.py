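"""Well-level network-burst detection.

A network burst is a coordinated cluster of spiking pooled across a well's
electrodes: a maximal run of pooled spikes in which every consecutive gap
is below a well-adaptive maximum interval, subject to two hard floors —
at least ``min_spikes`` pooled spikes (default 40) and participation of at
least ``ceil(min_electrode_fraction * n_electrodes)`` distinct electrodes
(default 15%, i.e. 3 of 16).

The adaptive maximum interval scales inversely with the well's pooled mean
spike rate, ``C / r_well``, clamped to ``isi_bounds``; the inverse-rate
form with C = 0.25 and 5-300 ms bounds is this package's documented
dialect of the rate-adaptive rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import WellRecording

__all__ = ["NetworkBurst", "NetworkBurstConfig", "well_max_isi", "detect_network_bursts"]


@dataclass(frozen=True)
class NetworkBurst:
    well: str
    start_s: float
    end_s: float
    n_spikes: int
    participating_electrodes: frozenset[int]
    # per-electrode spike times inside the event
    spikes_by_electrode: dict[int, np.ndarray]

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def n_electrodes(self) -> int:
        return len(self.participating_electrodes)


@dataclass(frozen=True)
class NetworkBurstConfig:
    min_spikes: int = 40
    min_electrode_fraction: float = 0.15
    adaptive_isi_constant: float = 0.25
    isi_bounds: tuple[float, float] = (0.005, 0.3)
    # if True, the participation floor is computed from the electrodes that
    # passed the activity filter; if False, from the physical electrode count
    fraction_of_included: bool = True

    def __post_init__(self):
        if self.min_spikes < 1:
            raise ValueError("min_spikes must be >= 1")
        if not (0 < self.min_electrode_fraction <= 1):
            raise ValueError("min_electrode_fraction must be in (0, 1]")


def well_max_isi(rec: WellRecording, cfg: NetworkBurstConfig = NetworkBurstConfig()) -> float | None:
    """Well-adaptive maximum pooled inter-spike interval, in seconds.

    clamp(C / r_well, isi_bounds) with r_well the pooled spike rate across
    the well's (included) electrodes.  Returns None for a silent well, which
    signals that network-burst analysis is not applicable.
    """
    total = rec.n_spikes
    if total == 0:
        return None
    r_well = total / rec.duration_s
    lo, hi = cfg.isi_bounds
    return float(min(max(cfg.adaptive_isi_constant / r_well, lo), hi))


def detect_network_bursts(
    rec: WellRecording, cfg: NetworkBurstConfig = NetworkBurstConfig()
) -> list[NetworkBurst]:
    """Detect network bursts in one well.

    Pools all spikes of the recording's electrodes, splits the pooled
    sequence at gaps above the well-adaptive maximum interval, and accepts
    each maximal run iff it meets both the pooled-spike floor and the
    distinct-electrode participation floor.  Deterministic.
    """
    max_isi = well_max_isi(rec, cfg)
    if max_isi is None:
        return []
    times, elecs = rec.pooled_spikes()
    n_ref = len(rec.trains) if cfg.fraction_of_included else rec.n_electrodes
    min_elec = math.ceil(cfg.min_electrode_fraction * n_ref)
    # maximal runs: break wherever the pooled gap exceeds max_isi
    breaks = np.flatnonzero(np.diff(times) > max_isi)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [times.size - 1]))
    out: list[NetworkBurst] = []
    for a, b in zip(starts, ends):
        n = int(b - a + 1)
        if n < cfg.min_spikes:
            continue
        seg_e = elecs[a : b + 1]
        participants = frozenset(int(e) for e in np.unique(seg_e))
        if len(participants) < min_elec:
            continue
        seg_t = times[a : b + 1]
        by_e = {int(e): seg_t[seg_e == e] for e in participants}
        out.append(
            NetworkBurst(
                well=rec.well,
                start_s=float(seg_t[0]),
                end_s=float(seg_t[-1]),
                n_spikes=n,
                participating_electrodes=participants,
                spikes_by_electrode=by_e,
            )
        )
    return out
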