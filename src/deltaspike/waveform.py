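"""Single-channel waveform processing and the 8 waveform-based features.

The mean multichannel waveform is upsampled eightfold by Fourier
interpolation (32 -> 256 samples per channel, 6.25 μs per sample at 20 kHz).
The channel with the largest trough-to-peak (TTP) magnitude is the "main"
channel; its waveform is polarity-corrected and scaled so the trough sits at
exactly -1, and eight features are extracted: four from the waveform itself
(TTP duration, TTP magnitude, FWHM, rise coefficient), one from the first
temporal derivative (maximum speed), and three from the second derivative
(break measure, smile-cry, acceleration). Derivatives are adjacent-sample
differences with no smoothing.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import resample

from .core_data import DT_US, MeanWaveform, UPSAMPLED_LENGTH, UnitRecording
from .registry import WAVEFORM_FEATURES

#: Tolerance band for the maximum-speed feature: the post-trough first
#: derivative counts as "the same change rate" while within this relative
#: distance of its post-trough maximum.
MAX_SPEED_TOL = 0.05

# Second-derivative windows, in upsampled samples relative to the trough.
# Boundaries are snapped to the 6.25 μs grid toward the trough; each window is
# closed on the side nearer the trough and half-open on the far side.
_BREAK_WINDOW = (-47, -12)  # 0.3-0.08 ms before the trough
_ACCEL_WINDOW = (12, 39)  # 0.08-0.25 ms after the trough
_SMILE_WINDOW = (41, 120)  # 0.26-0.76 ms after the trough


def mean_and_upsample(
    unit: UnitRecording, spike_subset: np.ndarray | None = None
) -> MeanWaveform:
    """Average snippets over spikes and Fourier-interpolate eightfold.

    Averaging and interpolation are both linear, so their order is
    irrelevant; averaging first is cheaper.
    """
    if spike_subset is None:
        snippets = unit.snippets
    else:
        spike_subset = np.asarray(spike_subset)
        if spike_subset.size == 0:
            raise ValueError("spike subset is empty")
        snippets = unit.snippets[spike_subset]
    if snippets.shape[0] == 0:
        raise ValueError("unit has no spikes to average")
    mean = snippets.mean(axis=0)
    up = resample(mean, UPSAMPLED_LENGTH, axis=1)
    return MeanWaveform(values=up)


def select_main_channel(w: MeanWaveform) -> int:
    """Channel with the largest trough-to-peak magnitude (ties: lowest index)."""
    ttp = w.values.max(axis=1) - w.values.min(axis=1)
    return int(np.argmax(ttp))


def scale_align(w: MeanWaveform) -> MeanWaveform:
    """Polarity-correct and scale a mean waveform by its main-channel trough.

    The polarity decision is taken once, on the main channel: when the
    absolute value at the trough is smaller than at the peak the whole
    multichannel waveform is inverted, preserving inter-channel sign
    relations. All channels are then divided by the absolute main-channel
    minimum, which maps the main-channel trough to exactly -1 and bounds the
    main channel to [-1, 1]. Idempotent.
    """
    main = select_main_channel(w)
    values = w.values.copy()
    inverted = False
    if abs(values[main].min()) < abs(values[main].max()):
        values = -values
        inverted = True
    depth = abs(values[main].min())
    if depth == 0:
        raise ValueError("all-zero waveform cannot be scaled")
    values = values / depth
    return MeanWaveform(
        values=values,
        main_channel=main,
        polarity_inverted=inverted ^ w.polarity_inverted,
    )


def _fwhm_ms(v: np.ndarray, trough: int, dt_us: float) -> float:
    """Duration of the contiguous sub-half-trough region around the trough."""
    below = v <= -0.5
    lo = trough
    while lo > 0 and below[lo - 1]:
        lo -= 1
    hi = trough
    while hi < v.size - 1 and below[hi + 1]:
        hi += 1
    return (hi - lo) * dt_us / 1000.0


def _window_sum(d2: np.ndarray, trough: int, window: tuple[int, int]) -> float:
    lo = max(trough + window[0], 0)
    hi = min(trough + window[1], d2.size - 1)
    if hi < lo:
        return 0.0
    return float(d2[lo : hi + 1].sum())


def extract_waveform_features(
    v: np.ndarray, dt_us: float = DT_US, speed_tol: float = MAX_SPEED_TOL
) -> dict[str, float]:
    """The 8 waveform features of a scaled, polarity-corrected main channel.

    ``v`` must satisfy the :func:`scale_align` contract (256 samples in
    [-1, 1] with minimum exactly -1). Durations are in ms; the
    second-derivative sums are reported on the printed unit scales
    (break measure in 1e-1 AU, smile-cry in 1e-2 AU, acceleration in 1e-6 AU).
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size != UPSAMPLED_LENGTH:
        raise ValueError(f"expected a {UPSAMPLED_LENGTH}-sample vector")
    trough = int(np.argmin(v))

    # Trough-to-peak: the ensuing maximal positivity. If no sample after the
    # trough is positive, the global post-trough maximum is used regardless.
    if trough < v.size - 1:
        peak = trough + 1 + int(np.argmax(v[trough + 1 :]))
    else:
        peak = trough
    ttp_duration = (peak - trough) * dt_us / 1000.0
    ttp_magnitude = float(v[peak] - v[trough])

    fwhm = _fwhm_ms(v, trough, dt_us)

    # Rise coefficient: time from the trough to the point of maximal absolute
    # distance from the straight line connecting the trough and the last sample.
    last = v.size - 1
    if last > trough:
        ts = np.arange(trough, last + 1)
        line = v[trough] + (v[last] - v[trough]) * (ts - trough) / (last - trough)
        rise_idx = int(np.argmax(np.abs(v[trough : last + 1] - line)))
    else:
        rise_idx = 0
    rise_coefficient = rise_idx * dt_us / 1000.0

    # Maximum speed: longest contiguous post-trough stretch over which the
    # first derivative stays within ``speed_tol`` of its post-trough maximum.
    d1 = np.diff(v)
    post = d1[trough:]
    if post.size:
        dmax = post.max()
        in_band = np.abs(post - dmax) <= abs(speed_tol * dmax)
        best = run = 0
        for flag in in_band:
            run = run + 1 if flag else 0
            best = max(best, run)
        maximum_speed = best * dt_us / 1000.0
    else:
        maximum_speed = 0.0

    # Second derivative, adjacent differences applied twice; d2[i] is aligned
    # with sample i.
    d2 = np.diff(v, n=2)
    break_measure = _window_sum(d2, trough, _BREAK_WINDOW) / 1e-1
    smile_cry = _window_sum(d2, trough, _SMILE_WINDOW) / 1e-2
    lo = max(trough + _ACCEL_WINDOW[0], 0)
    hi = min(trough + _ACCEL_WINDOW[1], d2.size - 1)
    accel_sum = float((d2[lo : hi + 1] ** 2).sum()) if hi >= lo else 0.0
    acceleration = accel_sum / 1e-6

    return dict(
        zip(
            WAVEFORM_FEATURES,
            [
                ttp_duration,
                ttp_magnitude,
                fwhm,
                rise_coefficient,
                maximum_speed,
                break_measure,
                smile_cry,
                acceleration,
            ],
        )
    )


def unit_waveform_features(
    unit: UnitRecording, spike_subset: np.ndarray | None = None
) -> dict[str, float]:
    """Convenience: mean -> upsample -> scale -> extract for one unit."""
    scaled = scale_align(mean_and_upsample(unit, spike_subset))
    return extract_waveform_features(scaled.values[scaled.main_channel])
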