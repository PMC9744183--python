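"""Event-based delta-transformation: stripping single-channel waveform shape.

Three per-channel events are detected on the polarity-corrected mean
multichannel waveform: NEG, the time of maximal negativity; FMC, the first
median crossing before NEG; and SMC, the first median crossing after NEG.
The "median" is one global level, the median voltage over all channels and
all samples. Each channel's waveform is then replaced by a delta-like
function holding the channel's maximal negativity (scaled by the absolute
global minimum over channels) at the single event time, and all channels are
shifted together so the main-channel event sits at sample index 128 (the
129th sample, 1-based). The result carries purely spatial information:
per-channel event times and amplitudes, with no waveform shape left.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_data import MeanWaveform, UPSAMPLED_LENGTH
from .waveform import select_main_channel

#: Channels whose trough-to-peak magnitude falls below this fraction of the
#: per-unit maximum are ignored by time- and graph-based spatial features.
MASK_THRESHOLD = 0.25

#: 0-based index of the centralization target (the 129th sample).
CENTER_INDEX = 128

EVENT_NAMES = ("FMC", "NEG", "SMC")


@dataclass
class EventSet:
    """Per-channel FMC/NEG/SMC event times plus amplitudes and masks.

    Times are upsampled sample indices (6.25 μs grid). ``valid[event]`` marks
    channels on which the event was actually detected; a channel that never
    crosses the median before (after) NEG gets its FMC (SMC) pinned to the
    window edge and is flagged invalid for that event. ``mask`` is the
    25%-TTP channel mask used by time- and graph-based features.
    """

    fmc: np.ndarray
    neg: np.ndarray
    smc: np.ndarray
    neg_amplitude: np.ndarray  # pre-scaling per-channel maximal negativity
    global_median: float
    mask: np.ndarray  # bool, 25%-TTP threshold
    valid: dict = field(default_factory=dict)  # event name -> bool array
    main_channel: int = -1

    def times(self, event: str) -> np.ndarray:
        return {"FMC": self.fmc, "NEG": self.neg, "SMC": self.smc}[event]

    @property
    def n_points(self) -> int:
        return 3 * self.fmc.size


@dataclass
class DeltaWaveform:
    """Delta-transformed multichannel waveform (one impulse per channel)."""

    values: np.ndarray  # (n_channels, 256)
    event: str
    scale: float  # absolute global minimum used for scaling
    main_channel: int
    dropped: np.ndarray  # channels whose event was shifted out of the window


def channel_mask(w: MeanWaveform, threshold: float = MASK_THRESHOLD) -> np.ndarray:
    """Boolean mask of channels whose TTP magnitude reaches ``threshold`` of
    the per-unit maximum (>=, ties included). The main channel always passes."""
    ttp = w.values.max(axis=1) - w.values.min(axis=1)
    return ttp >= threshold * ttp.max()


def _fix_polarity(w: MeanWaveform) -> tuple[np.ndarray, int]:
    """Invert the whole multichannel waveform if the main channel is
    positive-dominant; the decision is taken once per unit."""
    main = select_main_channel(w)
    values = w.values
    if abs(values[main].min()) < abs(values[main].max()):
        values = -values
    return values, main


def detect_events(w: MeanWaveform) -> EventSet:
    """Detect the FMC, NEG, and SMC events on every channel.

    A crossing is the first sample strictly above the global median scanning
    outward from NEG; a sample sitting exactly on the median is not a
    crossing. Missing crossings are pinned to the window edge and flagged.
    """
    values, main = _fix_polarity(w)
    n_channels, n = values.shape
    median = float(np.median(values))

    neg = values.argmin(axis=1)
    fmc = np.zeros(n_channels, dtype=int)
    smc = np.full(n_channels, n - 1, dtype=int)
    fmc_ok = np.zeros(n_channels, dtype=bool)
    smc_ok = np.zeros(n_channels, dtype=bool)
    for c in range(n_channels):
        above = values[c] > median
        before = np.nonzero(above[: neg[c]])[0]
        if before.size:
            fmc[c] = before[-1]
            fmc_ok[c] = True
        after = np.nonzero(above[neg[c] + 1 :])[0]
        if after.size:
            smc[c] = neg[c] + 1 + after[0]
            smc_ok[c] = True

    return EventSet(
        fmc=fmc,
        neg=neg,
        smc=smc,
        neg_amplitude=values.min(axis=1),
        global_median=median,
        mask=channel_mask(MeanWaveform(values=values)),
        valid={"FMC": fmc_ok, "NEG": np.ones(n_channels, bool), "SMC": smc_ok},
        main_channel=main,
    )


def delta_transform(w: MeanWaveform, ev: EventSet, event: str) -> DeltaWaveform:
    """Replace each channel by a scaled impulse at its event time, shifted so
    the main-channel event sits at sample 128.

    Impulse values are the channel's maximal negativity divided by the
    absolute global minimum over channels, hence in [-1, 0). Channels whose
    shifted event falls outside the 256-sample window are dropped (all-zero)
    and reported in ``dropped``.
    """
    if event not in EVENT_NAMES:
        raise ValueError(f"event must be one of {EVENT_NAMES}")
    values, _ = _fix_polarity(w)
    n_channels = values.shape[0]
    scale = abs(float(values.min()))
    if scale == 0:
        raise ValueError("all-zero waveform cannot be delta-transformed")
    times = ev.times(event)
    shift = CENTER_INDEX - int(times[ev.main_channel])
    out = np.zeros((n_channels, UPSAMPLED_LENGTH))
    dropped = []
    for c in range(n_channels):
        t = int(times[c]) + shift
        if 0 <= t < UPSAMPLED_LENGTH:
            out[c, t] = ev.neg_amplitude[c] / scale
        else:
            dropped.append(c)
    return DeltaWaveform(
        values=out,
        event=event,
        scale=scale,
        main_channel=ev.main_channel,
        dropped=np.asarray(dropped, dtype=int),
    )
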