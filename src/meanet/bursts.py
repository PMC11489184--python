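"""Single-electrode burst detection by the Poisson surprise method.

A burst is a cluster of spikes on one electrode that is improbably dense
under a homogeneous Poisson null at the electrode's mean rate.  The
surprise statistic is

    S = -ln P(X >= n),   X ~ Poisson(rate * interval),

in natural-log units (nats); bursts are accepted at S >= 10 by default.
The search follows the classic seed / extend / trim scheme: candidate
bursts are seeded on runs of short inter-spike intervals, extended forward
while S increases (with a bounded look-ahead), then trimmed from the start
while S does not decrease.

``brute_force_bursts`` is an exhaustive reference detector used for
equivalence testing on short trains; it is not meant for production data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp, pdtrc

from .core import SpikeTrain

__all__ = ["Burst", "BurstConfig", "surprise", "detect_bursts", "brute_force_bursts"]

# below this the upper tail probability is evaluated fully in the log domain
_UNDERFLOW = 1e-290


@dataclass(frozen=True)
class Burst:
    """A detected burst: an inclusive index range of spikes on one electrode."""

    electrode: int
    first_spike_index: int
    last_spike_index: int
    start_s: float
    end_s: float
    n_spikes: int
    surprise: float


@dataclass(frozen=True)
class BurstConfig:
    """Knobs of the surprise burst detector.

    S_min is the acceptance threshold in nats.  Candidate bursts are seeded
    where at least two consecutive ISIs fall below ``seed_isi_factor`` times
    the train's mean ISI.  ``extension_lookahead`` bounds how many spikes
    past the current end are tried in one extension step.
    """

    S_min: float = 10.0
    min_spikes_per_burst: int = 3
    seed_isi_factor: float = 0.5
    extension_lookahead: int = 10

    def __post_init__(self):
        if self.S_min <= 0:
            raise ValueError("S_min must be positive")
        if self.min_spikes_per_burst < 2:
            raise ValueError("min_spikes_per_burst must be >= 2")


def _log_tail_deep(n: float, mu: float) -> float:
    """log P(X >= n) by log-domain pmf summation; for tails below underflow."""
    if mu == 0.0:
        return -np.inf
    # terms decay geometrically once k > mu; here n >> mu by construction
    width = int(200 + 4 * math.sqrt(mu))
    k = np.arange(n, n + width)
    return float(logsumexp(k * np.log(mu) - mu - gammaln(k + 1)))


def _surprise_mu(n: float, mu: float) -> float:
    """S = -log P(X >= n), X ~ Poisson(mu); scalar fast path."""
    if n <= 0:
        return 0.0
    sf = pdtrc(n - 1, mu)
    if sf > _UNDERFLOW:
        return -math.log(sf)
    return -_log_tail_deep(n, mu)


def _surprise_mu_vec(n: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Vectorized S over arrays of counts and Poisson means."""
    n = np.asarray(n, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sf = pdtrc(np.maximum(n - 1, 0), mu)
    deep = sf <= _UNDERFLOW
    s = -np.log(np.where(deep, 1.0, sf))
    if deep.any():
        mu_b = np.broadcast_to(mu, n.shape)
        idx = np.flatnonzero(deep.ravel())
        s.ravel()[idx] = [
            -_log_tail_deep(ni, mi) if ni > 0 else 0.0
            for ni, mi in zip(n.ravel()[idx], mu_b.ravel()[idx])
        ]
    if np.any(n <= 0):
        s = np.where(n <= 0, 0.0, s)
    return s


def surprise(n_spikes, interval_s, rate_hz) -> float | np.ndarray:
    """Poisson surprise S = -ln P(X >= n) with X ~ Poisson(rate * interval).

    Accepts scalars or arrays (broadcast).  ``rate_hz`` must be positive:
    an inactive train has no Poisson null to be surprised against.
    """
    if np.any(np.asarray(rate_hz) <= 0):
        raise ValueError("rate_hz must be positive")
    if np.any(np.asarray(n_spikes) < 0) or np.any(np.asarray(interval_s) < 0):
        raise ValueError("n_spikes and interval_s must be non-negative")
    if np.isscalar(n_spikes) and np.isscalar(interval_s) and np.isscalar(rate_hz):
        return _surprise_mu(float(n_spikes), float(rate_hz) * float(interval_s))
    n, mu = np.broadcast_arrays(np.asarray(n_spikes, dtype=float),
                                np.asarray(interval_s, dtype=float) * np.asarray(rate_hz, dtype=float))
    return _surprise_mu_vec(n, mu.copy())


def detect_bursts(train: SpikeTrain, cfg: BurstConfig = BurstConfig()) -> list[Burst]:
    """Detect bursts on one electrode by the surprise seed/extend/trim search.

    Returns disjoint bursts in time order.  Empty or near-empty trains yield
    an empty list.  Deterministic for fixed input.
    """
    t = train.spike_times
    n = t.size
    if n < cfg.min_spikes_per_burst:
        return []
    rate = train.mean_rate
    if rate <= 0:
        return []
    mean_isi = 1.0 / rate
    isi = np.diff(t)
    short = isi < cfg.seed_isi_factor * mean_isi
    # candidate seeds: two consecutive short ISIs
    seed_idx = np.flatnonzero(short[:-1] & short[1:])

    bursts: list[Burst] = []
    pos = 0
    while pos < n - 2:
        # first seed at or after the scan position
        k0 = int(np.searchsorted(seed_idx, pos))
        if k0 >= seed_idx.size:
            break
        seed = int(seed_idx[k0])
        start, end = seed, seed + 2
        s = _surprise_mu(3, rate * (t[end] - t[start]))
        # extend forward: try up to `lookahead` additional spikes, keep the
        # best extension as long as it raises S
        while end < n - 1:
            m = min(cfg.extension_lookahead, n - 1 - end)
            lengths = np.arange(end - start + 2, end - start + 2 + m)
            sf = pdtrc(lengths - 1, rate * (t[end + 1 : end + 1 + m] - t[start]))
            k = int(sf.argmin())  # smallest tail probability = largest S
            s_k = -math.log(sf[k]) if sf[k] > _UNDERFLOW else -_log_tail_deep(
                lengths[k], rate * (t[end + 1 + k] - t[start])
            )
            if s_k > s:
                end = end + 1 + k
                s = s_k
            else:
                break
        # trim from the start while S does not decrease (ties -> shorter burst)
        while end - start + 1 > cfg.min_spikes_per_burst:
            s2 = _surprise_mu(end - start, rate * (t[end] - t[start + 1]))
            if s2 >= s:
                start += 1
                s = s2
            else:
                break
        if s >= cfg.S_min and end - start + 1 >= cfg.min_spikes_per_burst:
            bursts.append(
                Burst(
                    electrode=train.electrode,
                    first_spike_index=start,
                    last_spike_index=end,
                    start_s=float(t[start]),
                    end_s=float(t[end]),
                    n_spikes=end - start + 1,
                    surprise=s,
                )
            )
            pos = end + 1
        else:
            pos = seed + 1
    return bursts


def brute_force_bursts(train: SpikeTrain, cfg: BurstConfig = BurstConfig()) -> list[Burst]:
    """Exhaustive reference detector (test oracle) for trains of <= 200 spikes.

    Scores every contiguous spike subsequence of length >= min_spikes, then
    greedily accepts non-overlapping subsequences in order of descending S
    until none with S >= S_min remain.  Returned in time order.
    """
    t = train.spike_times
    n = t.size
    if n > 200:
        raise ValueError("brute_force_bursts is limited to trains of <= 200 spikes")
    if n < cfg.min_spikes_per_burst:
        return []
    rate = train.mean_rate
    if rate <= 0:
        return []
    ii, jj = np.triu_indices(n, k=cfg.min_spikes_per_burst - 1)
    s = _surprise_mu_vec(jj - ii + 1, rate * (t[jj] - t[ii]))
    order = np.argsort(-s, kind="stable")
    taken = np.zeros(n, dtype=bool)
    accepted: list[tuple[int, int, float]] = []
    for k in order:
        if s[k] < cfg.S_min:
            break
        i, j = int(ii[k]), int(jj[k])
        if taken[i : j + 1].any():
            continue
        taken[i : j + 1] = True
        accepted.append((i, j, float(s[k])))
    accepted.sort()
    return [
        Burst(
            electrode=train.electrode,
            first_spike_index=i,
            last_spike_index=j,
            start_s=float(t[i]),
            end_s=float(t[j]),
            n_spikes=j - i + 1,
            surprise=sv,
        )
        for i, j, sv in accepted
    ]
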