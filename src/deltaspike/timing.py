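"""Autocorrelation-histogram construction and the 8 spike-timing features.

The ACH counts all ordered spike pairs with |Δt| <= 1000 ms (zero-lag
self-pairs excluded) into 0.5 ms bins. Positive and negative lags are
averaged into a single-sided 0-1000 ms histogram (the ACH is an even
function; averaging removes any edge asymmetry) and the result is upsampled
eightfold by polyphase filtering, giving 16000 bins of 62.5 μs.

Features come in three families: high-frequency (0-50 ms window:
uniform-distance, short-window Kullback-Leibler divergence, rise time),
low-frequency (50-1000 ms: jump index, long-window D_KL), and wide-band
(PSD centroid, PSD-derivative centroid, firing rate). Windowed features are
computed on the mass-normalized window; D_KL uses base-2 logarithms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import resample_poly

from .registry import TIMING_FEATURES

WINDOW_MS = 1000.0
BIN_MS = 0.5
ACH_UPSAMPLE = 8
N_BINS = int(WINDOW_MS / BIN_MS)  # 2000 single-sided bins pre-upsampling
UP_BIN_MS = BIN_MS / ACH_UPSAMPLE
SHORT_MS = 50.0  # high-frequency window


@dataclass
class ACH:
    """Single-sided autocorrelation histogram of one unit or chunk."""

    counts: np.ndarray  # raw symmetrized single-sided counts (2000 bins)
    upsampled: np.ndarray  # 8x polyphase-upsampled counts (16000 bins)
    n_spikes: int

    @property
    def bin_ms(self) -> float:
        return BIN_MS


def _upsample_counts(counts: np.ndarray) -> np.ndarray:
    up = resample_poly(counts, ACH_UPSAMPLE, 1)
    # Polyphase ringing can produce small negative values; counts are
    # non-negative by definition.
    return np.clip(up, 0.0, None)


def _pair_counts(
    spike_times: np.ndarray, reference: np.ndarray
) -> np.ndarray:
    """Symmetrized single-sided histogram of lags from ``reference`` spikes
    to all spikes in ``spike_times`` within the ±1 s window."""
    window_s = WINDOW_MS / 1000.0
    lo = np.searchsorted(spike_times, reference - window_s, side="left")
    hi = np.searchsorted(spike_times, reference + window_s, side="right")
    chunks = [
        (spike_times[a:b] - t) * 1000.0 for t, a, b in zip(reference, lo, hi)
    ]
    if not chunks:
        return np.zeros(N_BINS)
    lags_ms = np.concatenate(chunks)
    lags_ms = lags_ms[lags_ms != 0.0]  # exclude zero-lag self-pairs
    pos = np.minimum((lags_ms[lags_ms > 0] / BIN_MS).astype(int), N_BINS - 1)
    neg = np.minimum((-lags_ms[lags_ms < 0] / BIN_MS).astype(int), N_BINS - 1)
    counts = np.bincount(pos, minlength=N_BINS) + np.bincount(neg, minlength=N_BINS)
    return counts / 2.0


def compute_ach(spike_times: np.ndarray) -> ACH:
    """ACH of a whole spike train. Trains with <2 spikes give an all-zero ACH."""
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size < 2:
        counts = np.zeros(N_BINS)
    else:
        counts = _pair_counts(spike_times, spike_times)
    return ACH(counts=counts, upsampled=_upsample_counts(counts), n_spikes=spike_times.size)


def single_spike_ach(spike_times: np.ndarray, reference_index: int) -> np.ndarray:
    """Raw single-sided ACH contribution of one reference spike.

    Counts all spikes within ±1000 ms of the reference; summing the
    contributions of every spike of a train reproduces the full pairwise ACH.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if not 0 <= reference_index < spike_times.size:
        raise IndexError("reference index out of range")
    return _pair_counts(spike_times, spike_times[reference_index : reference_index + 1])


def chunk_ach(spike_times: np.ndarray, member_indices: np.ndarray) -> ACH:
    """ACH of a chunk: the sum of its members' single-spike ACHs.

    Each member's neighborhood spans the full train, so the chunk ACH keeps
    the unit's timing statistics while weighting them by chunk membership.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    member_indices = np.asarray(member_indices)
    counts = _pair_counts(spike_times, spike_times[np.sort(member_indices)])
    return ACH(counts=counts, upsampled=_upsample_counts(counts), n_spikes=member_indices.size)


def per_spike_rates(spike_times: np.ndarray) -> np.ndarray:
    """Single-spike firing rate: mean of the inverse pre- and post-ISIs.

    Boundary spikes use their single available ISI.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    n = spike_times.size
    if n < 2:
        return np.zeros(n)
    inv = 1.0 / np.diff(spike_times)
    rates = np.empty(n)
    rates[0] = inv[0]
    rates[-1] = inv[-1]
    if n > 2:
        rates[1:-1] = (inv[:-1] + inv[1:]) / 2.0
    return rates


def _cdf_features(window: np.ndarray) -> tuple[float, float]:
    """(mean |CDF - uniform CDF|, base-2 D_KL vs uniform) for one window."""
    mass = window.sum()
    if mass <= 0:
        return 0.0, 0.0
    p = window / mass
    n = p.size
    cdf = np.cumsum(p)
    uniform_cdf = np.arange(1, n + 1) / n
    dist = float(np.abs(cdf - uniform_cdf).mean())
    nz = p > 0
    dkl = float((p[nz] * np.log2(p[nz] * n)).sum())
    return dist, dkl


def _rise_time_ms(window: np.ndarray, bin_ms: float) -> float:
    """Time at which the window CDF first exceeds 1/e (ms from window start)."""
    mass = window.sum()
    if mass <= 0:
        return 0.0
    cdf = np.cumsum(window) / mass
    idx = int(np.searchsorted(cdf, 1.0 / np.e, side="right"))
    return (idx + 1) * bin_ms


def _psd_centroids(upsampled: np.ndarray, bin_ms: float) -> tuple[float, float]:
    """Centroids (Hz) of the PSD and of |dPSD/df| of the full-band ACH.

    The PSD is the squared FFT magnitude of the single-sided 0-1000 ms ACH.
    The DC bin is excluded (it only reflects total pair count); the
    derivative is the adjacent-bin difference, whose signed sum is ~0, so
    the centroid of its absolute value is used.
    """
    psd = np.abs(np.fft.rfft(upsampled)) ** 2
    freqs = np.fft.rfftfreq(upsampled.size, d=bin_ms / 1000.0)
    psd, freqs = psd[1:], freqs[1:]  # drop DC
    total = psd.sum()
    psd_center = float((freqs * psd).sum() / total) if total > 0 else 0.0
    dpsd = np.abs(np.diff(psd))
    dtotal = dpsd.sum()
    psd_prime_center = float((freqs[:-1] * dpsd).sum() / dtotal) if dtotal > 0 else 0.0
    return psd_center, psd_prime_center


def mean_firing_rate(spike_times: np.ndarray) -> float:
    """Average firing rate over the train span: (n-1) / (t_last - t_first)."""
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size < 2:
        return 0.0
    span = spike_times[-1] - spike_times[0]
    return float((spike_times.size - 1) / span) if span > 0 else 0.0


def extract_timing_features(
    ach: ACH,
    spike_times: np.ndarray | None = None,
    chunk_rates: np.ndarray | None = None,
) -> dict[str, float]:
    """The 8 spike-timing features of one ACH.

    The firing-rate feature is the whole-train rate when ``spike_times`` is
    given, or the mean of per-spike rates (inverse pre/post ISIs) in chunk
    mode when ``chunk_rates`` is given.
    """
    up = ach.upsampled
    n_short = int(SHORT_MS / UP_BIN_MS)
    short = up[:n_short]
    long_ = up[n_short:]

    uniform_distance, dkl_short = _cdf_features(short)
    rise_time = _rise_time_ms(short, UP_BIN_MS)
    jump_index, dkl_long = _cdf_features(long_)
    psd_center, psd_prime_center = _psd_centroids(up, UP_BIN_MS)

    if chunk_rates is not None:
        firing_rate = float(np.mean(chunk_rates)) if len(chunk_rates) else 0.0
    elif spike_times is not None:
        firing_rate = mean_firing_rate(spike_times)
    else:
        firing_rate = 0.0

    return dict(
        zip(
            TIMING_FEATURES,
            [
                uniform_distance,
                dkl_short,
                rise_time,
                jump_index,
                dkl_long,
                psd_center,
                psd_prime_center,
                firing_rate,
            ],
        )
    )
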