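"""The ten per-well activity parameters.

Computed on the last 20 minutes of each 30-minute recording (the most
stable timeframe).  Counts are pooled sums over the well's included
electrodes; means over empty sets are undefined (NaN), never zero — a well
with no network bursts has an undefined network-burst duration rather than
a fabricated hypo-active one.  Undefined values propagate as missing into
the normalization stage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np

from .bursts import Burst
from .core import SpikeTrain, WellRecording
from .netbursts import NetworkBurst

__all__ = ["WellMetrics", "analysis_window", "compute_metrics", "synchrony_auc", "PARAMETERS"]

log = logging.getLogger(__name__)

#: the ten reported parameters, in table order
PARAMETERS = (
    "n_spikes",
    "n_bursts",
    "n_network_bursts",
    "burst_duration_s",
    "network_burst_duration_s",
    "inter_burst_interval_s",
    "spikes_per_burst",
    "spikes_per_network_burst",
    "mean_isi_within_network_bursts_s",
    "synchrony_auc",
)

ANALYSIS_WINDOW_S = 1200.0  # last 20 min of the 30-min recording


@dataclass(frozen=True)
class WellMetrics:
    """The ten activity parameters of one well at one DIV.

    Means over empty sets are NaN ("undefined"), with ``defined`` flags
    derivable via ``numpy.isnan``.  ``n_bursting_electrodes`` is carried for
    the well-inclusion rule and is not one of the ten parameters.
    """

    n_spikes: int
    n_bursts: int
    n_network_bursts: int
    burst_duration_s: float
    network_burst_duration_s: float
    inter_burst_interval_s: float
    spikes_per_burst: float
    spikes_per_network_burst: float
    mean_isi_within_network_bursts_s: float
    synchrony_auc: float
    n_bursting_electrodes: int
    n_included_electrodes: int

    def as_dict(self) -> dict[str, float]:
        return {p: getattr(self, p) for p in PARAMETERS} | {
            "n_bursting_electrodes": self.n_bursting_electrodes,
            "n_included_electrodes": self.n_included_electrodes,
        }


def analysis_window(rec: WellRecording, window_s: float = ANALYSIS_WINDOW_S) -> WellRecording:
    """Restrict a recording to its final ``window_s`` seconds.

    Spikes before ``duration - window_s`` are dropped and the trains are
    re-anchored to the new window.  Recordings shorter than the window are
    used in full, with a logged warning.
    """
    if rec.duration_s < window_s:
        log.warning(
            "well %s DIV %d: recording (%.0f s) shorter than analysis window (%.0f s); using full duration",
            rec.well, rec.div, rec.duration_s, window_s,
        )
        return rec
    cut = rec.duration_s - window_s
    new_trains = {}
    for e, tr in rec.trains.items():
        t = tr.spike_times[tr.spike_times >= cut]
        new_trains[e] = SpikeTrain(electrode=e, spike_times=t, window=(cut, rec.duration_s))
    return replace(rec, trains=new_trains)


def _mean(values) -> float:
    vals = list(values)
    return float(np.mean(vals)) if vals else math.nan


def synchrony_auc(
    rec: WellRecording,
    bin_s: float = 0.005,
    max_lag_s: float = 0.100,
    min_spikes: int = 10,
) -> float:
    """Area under the pairwise spike cross-correlation, a synchrony score in [0, 1].

    For each unordered electrode pair the spike trains are binned at
    ``bin_s``; the cross-correlogram over lags |tau| <= ``max_lag_s`` is
    normalized by sqrt(N_i * N_j) so that two identical trains produce a
    zero-lag peak of 1.  The pair score is the normalized correlogram area
    over the lag window, the well score the mean over pairs, clamped to
    [0, 1].  Undefined (NaN) with fewer than two electrodes carrying at
    least ``min_spikes`` spikes.
    """
    eligible = [tr for tr in rec.trains.values() if tr.n_spikes >= min_spikes]
    if len(eligible) < 2:
        return math.nan
    lags = int(round(max_lag_s / bin_s))
    t0 = min(tr.window[0] for tr in eligible)
    binned = [np.floor((tr.spike_times - t0) / bin_s).astype(np.int64) for tr in eligible]
    scores = []
    for bi, bj in combinations(binned, 2):
        # correlogram area over |lag| <= lags = number of spike pairs whose
        # bin indices differ by at most `lags` (bin arrays are sorted)
        lo = np.searchsorted(bj, bi - lags)
        hi = np.searchsorted(bj, bi + lags + 1)
        area = float(np.sum(hi - lo))
        scores.append(area / math.sqrt(bi.size * bj.size))
    return float(min(max(np.mean(scores), 0.0), 1.0))


def compute_metrics(
    rec: WellRecording,
    bursts: list[Burst],
    network_bursts: list[NetworkBurst],
) -> WellMetrics:
    """Assemble the ten parameters from detection output on the analysis window.

    ``rec`` must be the (activity-filtered) recording the detectors ran on.
    Inter-burst interval is the gap from the end of one burst to the start
    of the next on the same electrode, pooled across electrodes; the mean
    ISI within network bursts averages, over network bursts, the mean
    consecutive pooled-spike interval inside each event.
    """
    n_spikes = rec.n_spikes
    n_bursts = len(bursts)
    n_nb = len(network_bursts)

    burst_dur = _mean(b.end_s - b.start_s for b in bursts)
    spb = _mean(b.n_spikes for b in bursts)

    ibis: list[float] = []
    by_elec: dict[int, list[Burst]] = {}
    for b in bursts:
        by_elec.setdefault(b.electrode, []).append(b)
    for bs in by_elec.values():
        bs = sorted(bs, key=lambda b: b.start_s)
        ibis.extend(b2.start_s - b1.end_s for b1, b2 in zip(bs, bs[1:]))
    ibi = _mean(ibis)

    nb_dur = _mean(nb.duration_s for nb in network_bursts)
    spnb = _mean(nb.n_spikes for nb in network_bursts)
    nb_isis = []
    for nb in network_bursts:
        pooled = np.sort(np.concatenate(list(nb.spikes_by_electrode.values())))
        if pooled.size >= 2:
            nb_isis.append(float(np.mean(np.diff(pooled))))
    isi_in_nb = _mean(nb_isis)

    return WellMetrics(
        n_spikes=n_spikes,
        n_bursts=n_bursts,
        n_network_bursts=n_nb,
        burst_duration_s=burst_dur,
        network_burst_duration_s=nb_dur,
        inter_burst_interval_s=ibi,
        spikes_per_burst=spb,
        spikes_per_network_burst=spnb,
        mean_isi_within_network_bursts_s=isi_in_nb,
        synchrony_auc=synchrony_auc(rec),
        n_bursting_electrodes=len(by_elec),
        n_included_electrodes=len(rec.trains),
    )
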