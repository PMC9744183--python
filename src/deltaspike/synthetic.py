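"""Ground-truth-labeled synthetic populations of PYR and PV units.

The generator emulates the statistics that separate the two classes in
recorded data, without any biophysical modelling:

* **Waveform**: each channel's spike is a smooth monotone-cubic template
  with a small positive pre-hump, a negative trough, a median up-crossing,
  and a late positive peak. The trough-to-peak duration and trough width
  are class parameters (wide for PYR, narrow for PV).
* **Timing**: PYR trains are bursty (a Poisson process of burst onsets, each
  onset spawning a geometric number of short-ISI spikes); PV trains are
  near-renewal Poisson at a much higher rate. Both respect an absolute
  refractory period.
* **Space**: amplitudes attenuate exponentially with distance from a soma
  channel, and each channel's FMC / NEG / SMC event times carry independent
  per-channel offsets whose SDs are the class jitters. Offsets of the soma
  (main) channel are pinned to zero so the configured jitters are directly
  the SDs of the offsets relative to the main channel. Per-spike jitter
  (``intraunit_drift`` times the event jitter) creates across-chunk
  variability, larger for PV units.

The soma channel has both the largest trough-to-peak magnitude and the
largest negativity, so the delta-transformation's centralization removes the
main-channel event time exactly. Everything is bit-reproducible for a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_data import (
    DEFAULT_SAMPLING_RATE,
    ProbeGeometry,
    SAMPLES_PER_SPIKE,
    UnitRecording,
    default_probe,
)

#: Time of the trough within the 1.6 ms snippet (ms).
TROUGH_MS = 0.5
#: Positive peak amplitude relative to the trough depth.
PEAK_RATIO = 0.35
#: Pre-trough positive hump amplitude relative to the trough depth.
HUMP_RATIO = 0.12


@dataclass(frozen=True)
class ClassParams:
    """Generative parameters of one cell class."""

    label: str
    rate_hz: float  # mean firing rate (spikes/s)
    burst_fraction: float  # P(a spike extends a burst); 0 -> renewal train
    burst_isi_ms: float  # intra-burst ISI scale beyond the refractory period
    refractory_ms: float  # absolute refractory period
    ttp_ms: float  # template trough-to-peak duration
    trough_width_ms: float  # template trough half-width (sets FWHM)
    amp_decay_per_um: float  # exponential amplitude attenuation rate
    fmc_jitter_us: float  # SD of per-channel FMC time offsets
    neg_jitter_us: float  # SD of per-channel NEG time offsets
    smc_jitter_us: float  # SD of per-channel SMC time offsets
    noise_sd: float  # additive per-sample noise, relative to trough depth
    n_spikes_range: tuple[int, int] = (25, 600)
    intraunit_drift: float = 0.5  # per-spike jitter, relative to event jitter

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.refractory_ms <= 0:
            raise ValueError("refractory_ms must be positive")
        if not 0 <= self.burst_fraction < 1:
            raise ValueError("burst_fraction must be in [0, 1)")
        if min(self.fmc_jitter_us, self.neg_jitter_us, self.smc_jitter_us) < 0:
            raise ValueError("jitters must be non-negative")


def pyr_defaults() -> ClassParams:
    """Pyramidal-cell parameters: slow bursty firing, wide spikes, tight FMC."""
    return ClassParams(
        label="PYR",
        rate_hz=0.69,
        burst_fraction=0.5,
        burst_isi_ms=4.0,
        refractory_ms=2.0,
        ttp_ms=0.77,
        trough_width_ms=0.21,
        amp_decay_per_um=0.022,
        fmc_jitter_us=15.9,
        neg_jitter_us=13.5,
        smc_jitter_us=26.0,
        noise_sd=0.05,
        intraunit_drift=0.2,
    )


def pv_defaults() -> ClassParams:
    """PV interneuron parameters: fast regular firing, narrow spikes,
    dispersed FMC, tight NEG, larger intraunit variability."""
    return ClassParams(
        label="PV",
        rate_hz=8.95,
        burst_fraction=0.0,
        burst_isi_ms=4.0,
        refractory_ms=1.5,
        ttp_ms=0.29,
        trough_width_ms=0.16,
        amp_decay_per_um=0.022,
        fmc_jitter_us=40.6,
        neg_jitter_us=9.4,
        smc_jitter_us=24.0,
        noise_sd=0.05,
        intraunit_drift=0.5,
    )


def null_params(label: str) -> ClassParams:
    """Class-independent parameters: both classes share one generative model,
    so no feature carries label information (chance-level classification)."""
    return ClassParams(
        label=label,
        rate_hz=3.0,
        burst_fraction=0.25,
        burst_isi_ms=4.0,
        refractory_ms=2.0,
        ttp_ms=0.5,
        trough_width_ms=0.18,
        amp_decay_per_um=0.022,
        fmc_jitter_us=25.0,
        neg_jitter_us=12.0,
        smc_jitter_us=25.0,
        noise_sd=0.05,
        intraunit_drift=0.35,
    )


@dataclass(frozen=True)
class PopulationSpec:
    """Population layout: unit counts, recording duration, seed, geometry."""

    n_pyr: int
    n_pv: int
    duration_s: float = 600.0
    seed: int = 0
    geometry: ProbeGeometry | None = None
    fraction_ca1: float = 0.877  # region tag imbalance of the source dataset

    def __post_init__(self) -> None:
        if self.n_pyr < 0 or self.n_pv < 0:
            raise ValueError("unit counts must be non-negative")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")


# ---------------------------------------------------------------------------
# Spike trains
# ---------------------------------------------------------------------------

def generate_spike_train(
    params: ClassParams, duration_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Strictly increasing spike times (s) with the class firing statistics.

    Burst onsets follow a Poisson process at ``rate * (1 - burst_fraction)``;
    each onset spawns a geometric number of extra spikes at short ISIs
    (refractory + exponential of scale ``burst_isi_ms``), so the overall rate
    stays at ``rate_hz``. ISIs below the refractory period are discarded.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    b = params.burst_fraction
    onset_rate = params.rate_hz * (1.0 - b)
    refr_s = params.refractory_ms / 1000.0
    mean_isi = 1.0 / onset_rate
    exp_mean = max(mean_isi - refr_s, 1e-6)

    spikes: list[float] = []
    t = float(rng.exponential(exp_mean))
    while t < duration_s:
        spikes.append(t)
        # burst extensions
        tb = t
        while b > 0 and rng.random() < b:
            tb = tb + refr_s + rng.exponential(params.burst_isi_ms / 1000.0)
            if tb >= duration_s:
                break
            spikes.append(tb)
        t = max(t, tb) + refr_s + rng.exponential(exp_mean)

    times = np.sort(np.asarray(spikes))
    if times.size > 1:
        keep = np.concatenate([[True], np.diff(times) > refr_s])
        times = times[keep]
    return times


# ---------------------------------------------------------------------------
# Snippets
# ---------------------------------------------------------------------------

def _unit_anchor_times(params: ClassParams) -> tuple[float, float, float]:
    """(FMC, NEG, SMC) template anchor times in ms.

    The down- and up-crossing lags are set from the trough width so the
    extracted FWHM approximates ``trough_width_ms``; the FMC lag is widened
    when the configured FMC jitter would otherwise collide with the trough.
    """
    w = params.trough_width_ms
    t_neg = TROUGH_MS
    fmc_lag = max(0.8 * w, 0.045 + 2.6 * params.fmc_jitter_us / 1000.0 + 0.005)
    return t_neg - fmc_lag, t_neg, t_neg + 1.2 * w


def _channel_amplitudes(
    params: ClassParams, geometry: ProbeGeometry, soma: int
) -> np.ndarray:
    d = np.linalg.norm(geometry.coords_um - geometry.coords_um[soma], axis=1)
    return np.exp(-params.amp_decay_per_um * d)


def _base_template(params: ClassParams) -> tuple[np.ndarray, np.ndarray]:
    """Smooth (C1) unit-amplitude template on a fine time grid.

    A monotone cubic (PCHIP) passes through: flat baseline, a small positive
    pre-hump, a zero crossing at the FMC anchor, the trough (-1) at the NEG
    anchor, a zero crossing at the SMC anchor, the positive peak one TTP
    after the trough, and a decay back to baseline. Smoothness matters: the
    snippets are sampled at 20 kHz and later Fourier-interpolated, and a
    kink-free template keeps the reconstructed event times faithful to the
    anchors.
    """
    t_fmc, t_neg, t_smc = _unit_anchor_times(params)
    sample_ms = 1000.0 / DEFAULT_SAMPLING_RATE
    t_end = (SAMPLES_PER_SPIKE - 1) * sample_ms
    t_peak = t_neg + params.ttp_ms
    knots_t = np.array(
        [
            0.0,
            t_fmc - 0.18,
            t_fmc - 0.07,
            t_fmc,
            t_neg,
            t_smc,
            t_peak,
            min(t_peak + 0.35, t_end - 0.01),
            t_end,
        ]
    )
    knots_t = np.maximum.accumulate(knots_t + np.arange(knots_t.size) * 1e-6)
    knots_v = np.array(
        [0.0, 0.0, HUMP_RATIO, 0.0, -1.0, 0.0, PEAK_RATIO, 0.0, 0.0]
    )
    from scipy.interpolate import PchipInterpolator

    fine_t = np.arange(0.0, t_end + 0.002, 0.002)  # 2 μs resolution
    fine_v = PchipInterpolator(knots_t, knots_v)(fine_t)
    return fine_t, fine_v


def _spike_waveforms(
    params: ClassParams,
    geometry: ProbeGeometry,
    soma: int,
    base_offsets_us: np.ndarray,  # (3, n_channels) per-unit event offsets
    n_spikes: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_spikes, n_channels, 32) waveforms: warped templates plus noise.

    Per-channel event offsets are realized as a piecewise-linear time warp
    anchored at the FMC, NEG, and SMC template times, so each event moves
    independently by its offset while the waveform stays smooth.
    """
    n_ch = geometry.n_channels
    amps = _channel_amplitudes(params, geometry, soma)
    t_fmc0, t_neg0, t_smc0 = _unit_anchor_times(params)
    sample_ms = 1000.0 / DEFAULT_SAMPLING_RATE
    grid = np.arange(SAMPLES_PER_SPIKE) * sample_ms
    t_end = (SAMPLES_PER_SPIKE - 1) * sample_ms
    fine_t, fine_v = _base_template(params)
    # The trough translates rigidly within ±h so its local shape stays
    # symmetric under NEG offsets (an asymmetric warp would bias the
    # band-limited minimum toward the wider flank).
    h = 0.035
    anchors = np.array(
        [0.0, t_fmc0, t_neg0 - h, t_neg0, t_neg0 + h, t_smc0, t_end]
    )

    jitters = np.array(
        [params.fmc_jitter_us, params.neg_jitter_us, params.smc_jitter_us]
    )
    drift_sd = params.intraunit_drift * jitters

    out = np.empty((n_spikes, n_ch, SAMPLES_PER_SPIKE))
    for s in range(n_spikes):
        # per-spike wander of the event offsets (zero on the soma channel)
        off = base_offsets_us + drift_sd[:, None] * rng.standard_normal((3, n_ch))
        off[:, soma] = 0.0
        off_ms = off / 1000.0
        for c in range(n_ch):
            warped = anchors.copy()
            warped[1] += off_ms[0, c]
            warped[2:5] += off_ms[1, c]
            warped[5] += off_ms[2, c]
            warped = np.maximum.accumulate(warped + np.arange(7) * 1e-6)
            tau = np.interp(grid, warped, anchors)
            out[s, c] = amps[c] * np.interp(tau, fine_t, fine_v)
    if params.noise_sd > 0:
        out += params.noise_sd * rng.standard_normal(out.shape)
    return out


def generate_snippets(
    params: ClassParams,
    spike_times: np.ndarray,
    geometry: ProbeGeometry,
    rng: np.random.Generator,
    unit_id: str = "unit",
    region: str = "CA1",
    soma: int | None = None,
) -> UnitRecording:
    """A :class:`UnitRecording` whose snippets realize the class parameters.

    With all jitters, drift, and noise at zero every snippet is identical.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    n_ch = geometry.n_channels
    if soma is None:
        lo, hi = max(1, n_ch // 4), max(2, 3 * n_ch // 4)
        soma = int(rng.integers(lo, hi))
    elif not 0 <= soma < n_ch:
        raise ValueError("soma channel outside geometry")

    jitters = np.array(
        [params.fmc_jitter_us, params.neg_jitter_us, params.smc_jitter_us]
    )
    base_offsets = jitters[:, None] * rng.standard_normal((3, n_ch))
    # Truncate at 2.6 SD: extreme draws would collide with the neighboring
    # event anchors and saturate, biasing the realized dispersion.
    base_offsets = np.clip(base_offsets, -2.6 * jitters[:, None], 2.6 * jitters[:, None])
    base_offsets[:, soma] = 0.0

    snippets = _spike_waveforms(
        params, geometry, soma, base_offsets, spike_times.size, rng
    )
    return UnitRecording(
        unit_id=unit_id,
        spike_times=spike_times,
        snippets=snippets,
        label=params.label,
        region=region,
    )


def generate_population(
    spec: PopulationSpec,
    pyr: ClassParams | None = None,
    pv: ClassParams | None = None,
) -> list[UnitRecording]:
    """``n_pyr + n_pv`` labeled units, bit-reproducible for a fixed seed."""
    pyr = pyr or pyr_defaults()
    pv = pv or pv_defaults()
    geometry = spec.geometry or default_probe()
    rng = np.random.default_rng(spec.seed)
    units: list[UnitRecording] = []
    plan = [("PYR", pyr, i) for i in range(spec.n_pyr)] + [
        ("PV", pv, i) for i in range(spec.n_pv)
    ]
    for label, params, i in plan:
        times = generate_spike_train(params, spec.duration_s, rng)
        lo, hi = params.n_spikes_range
        duration = spec.duration_s
        while times.size < lo and duration < 16 * spec.duration_s:
            duration *= 2
            times = generate_spike_train(params, duration, rng)
        if times.size > hi:
            times = times[:hi]
        region = "CA1" if rng.random() < spec.fraction_ca1 else "nCX"
        units.append(
            generate_snippets(
                params,
                times,
                geometry,
                rng,
                unit_id=f"{label}{i:03d}",
                region=region,
            )
        )
    return units


def with_seeded_regions(
    units: list[UnitRecording], n_ncx_per_label: dict[str, int]
) -> list[UnitRecording]:
    """Deterministically retag the first ``n`` units of each label as nCX.

    Convenience for generalization experiments that need guaranteed region
    counts.
    """
    seen: dict[str, int] = {}
    out = []
    for u in units:
        k = seen.get(u.label, 0)
        region = "nCX" if k < n_ncx_per_label.get(u.label, 0) else "CA1"
        seen[u.label] = k + 1
        out.append(replace_region(u, region))
    return out


def replace_region(u: UnitRecording, region: str) -> UnitRecording:
    return UnitRecording(
        unit_id=u.unit_id,
        spike_times=u.spike_times,
        snippets=u.snippets,
        label=u.label,
        region=region,
        sampling_rate=u.sampling_rate,
    )
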