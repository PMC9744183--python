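"""Domain containers and readers/writers shared by all pipeline stages.

Units are held in memory as :class:`UnitRecording` objects (spike times plus
per-spike multichannel snippets) and on disk either in a single hierarchical
HDF5 container (one group per unit) or in the classic Neurosuite triplet
(``.spk``/``.res``/``.clu``). Feature tables are plain pandas DataFrames
serialized as CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .registry import META_COLUMNS

#: Raw snippet length in samples; 32 samples at 20 kHz span 1.6 ms.
SAMPLES_PER_SPIKE = 32
#: Fourier-interpolation factor applied to mean waveforms.
UPSAMPLE_FACTOR = 8
#: Length of an upsampled mean waveform.
UPSAMPLED_LENGTH = SAMPLES_PER_SPIKE * UPSAMPLE_FACTOR
#: Default sampling rate (Hz).
DEFAULT_SAMPLING_RATE = 20000.0
#: Time step of one upsampled sample (microseconds).
DT_US = 1e6 / (DEFAULT_SAMPLING_RATE * UPSAMPLE_FACTOR)

#: Permitted chunk sizes (spikes per chunk); ``None`` means no chunking.
CHUNK_SIZES = (None, 25, 50, 100, 200, 400, 800, 1600)

LABELS = ("PYR", "PV", "unknown")
REGIONS = ("CA1", "nCX")


class FormatError(ValueError):
    """Raised when an on-disk container violates the expected format."""


@dataclass(frozen=True)
class ProbeGeometry:
    """Electrode layout: channel identifiers and (x, y) positions in μm."""

    channel_ids: tuple[int, ...]
    coords_um: np.ndarray  # (n_channels, 2)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords_um, dtype=float)
        object.__setattr__(self, "coords_um", coords)
        if len(self.channel_ids) < 2:
            raise ValueError("a probe needs at least 2 channels")
        if coords.shape != (len(self.channel_ids), 2):
            raise ValueError("coords_um must be (n_channels, 2)")
        if len({tuple(row) for row in coords.tolist()}) != len(self.channel_ids):
            raise ValueError("channel positions must be pairwise distinct")

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    def distances_mm(self) -> np.ndarray:
        """Pairwise Euclidean distances between channels, in millimetres."""
        diff = self.coords_um[:, None, :] - self.coords_um[None, :, :]
        return np.sqrt((diff**2).sum(-1)) / 1000.0


def default_probe(n_channels: int = 8, pitch_um: float = 20.0) -> ProbeGeometry:
    """A single-shank linear probe with ``pitch_um`` vertical spacing."""
    coords = np.stack(
        [np.zeros(n_channels), np.arange(n_channels) * pitch_um], axis=1
    )
    return ProbeGeometry(tuple(range(n_channels)), coords)


@dataclass
class UnitRecording:
    """One unit: spike times (s), per-spike multichannel snippets, metadata."""

    unit_id: str
    spike_times: np.ndarray  # (n_spikes,) seconds, strictly increasing
    snippets: np.ndarray  # (n_spikes, n_channels, 32)
    label: str = "unknown"
    region: str = "CA1"
    sampling_rate: float = DEFAULT_SAMPLING_RATE

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        self.snippets = np.asarray(self.snippets, dtype=float)
        if self.snippets.ndim != 3 or self.snippets.shape[2] != SAMPLES_PER_SPIKE:
            raise ValueError(
                f"snippets must be (n_spikes, n_channels, {SAMPLES_PER_SPIKE})"
            )
        if self.snippets.shape[0] != self.spike_times.shape[0]:
            raise ValueError("n_spikes mismatch between snippets and spike_times")
        if self.spike_times.size > 1 and not np.all(np.diff(self.spike_times) > 0):
            raise ValueError("spike_times must be strictly increasing")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}")

    @property
    def n_spikes(self) -> int:
        return self.spike_times.shape[0]

    @property
    def n_channels(self) -> int:
        return self.snippets.shape[1]


@dataclass
class MeanWaveform:
    """Per-channel mean waveform after 8x Fourier interpolation.

    ``values`` is (n_channels, 256); one upsampled sample spans 6.25 μs at the
    default 20 kHz acquisition rate. ``main_channel`` is the channel with the
    largest trough-to-peak magnitude; ``polarity_inverted`` records whether the
    unit was multiplied by -1 before scaling.
    """

    values: np.ndarray
    main_channel: int = -1
    polarity_inverted: bool = False
    upsample_factor: int = UPSAMPLE_FACTOR
    dt_us: float = DT_US

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != UPSAMPLED_LENGTH:
            raise ValueError(f"waveforms must have {UPSAMPLED_LENGTH} samples")


@dataclass(frozen=True)
class DatasetManifest:
    """Bookkeeping for one generated or loaded dataset."""

    n_per_label: dict = field(default_factory=dict)
    n_per_region: dict = field(default_factory=dict)
    chunk_size: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.n_per_label.values()):
            raise ValueError("counts must be non-negative")
        if self.chunk_size not in CHUNK_SIZES:
            raise ValueError(f"chunk_size must be one of {CHUNK_SIZES}")


# ---------------------------------------------------------------------------
# Native HDF5 container
# ---------------------------------------------------------------------------

def write_units(path: str | Path, units: Sequence[UnitRecording]) -> None:
    """Write units to a single hierarchical HDF5 container (one group each)."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "deltaspike-units"
        f.attrs["sampling_rate"] = units[0].sampling_rate if units else DEFAULT_SAMPLING_RATE
        f.attrs["n_channels"] = units[0].n_channels if units else 0
        order = []
        for u in units:
            g = f.create_group(f"units/{u.unit_id}")
            g.create_dataset("spike_times", data=u.spike_times)
            g.create_dataset("snippets", data=u.snippets)
            g.attrs["label"] = u.label
            g.attrs["region"] = u.region
            order.append(u.unit_id)
        f.attrs["unit_order"] = order


def read_units(path: str | Path, geometry: ProbeGeometry | None = None) -> list[UnitRecording]:
    """Read units from the native container, in stable (written) order.

    Raises :class:`FormatError` when the container lacks a sampling rate or
    the channel count disagrees with ``geometry``; non-monotonic spike times
    surface as a validation error from :class:`UnitRecording`.
    """
    units: list[UnitRecording] = []
    with h5py.File(path, "r") as f:
        if "sampling_rate" not in f.attrs:
            raise FormatError(f"{path}: container does not declare a sampling rate")
        rate = float(f.attrs["sampling_rate"])
        n_channels = int(f.attrs.get("n_channels", 0))
        if geometry is not None and n_channels != geometry.n_channels:
            raise FormatError(
                f"{path}: container has {n_channels} channels, "
                f"geometry expects {geometry.n_channels}"
            )
        order = [str(s) for s in f.attrs.get("unit_order", list(f["units"]))]
        for uid in order:
            g = f[f"units/{uid}"]
            units.append(
                UnitRecording(
                    unit_id=uid,
                    spike_times=g["spike_times"][()],
                    snippets=g["snippets"][()],
                    label=str(g.attrs["label"]),
                    region=str(g.attrs["region"]),
                    sampling_rate=rate,
                )
            )
    return units


# ---------------------------------------------------------------------------
# Neurosuite (.spk / .res / .clu) reader
# ---------------------------------------------------------------------------

def read_neurosuite(
    spk_path: str | Path,
    res_path: str | Path,
    clu_path: str | Path,
    n_channels: int,
    samples_per_spike: int = SAMPLES_PER_SPIKE,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
) -> list[UnitRecording]:
    """Read a Neurosuite triplet into one :class:`UnitRecording` per cluster.

    ``.spk`` holds interleaved int16 snippets (spike-major, channel-major,
    sample-minor), ``.res`` spike times in samples, ``.clu`` cluster ids with a
    leading cluster count. Clusters 0 and 1 (noise/artifact by convention) are
    skipped. Spike times are sorted ascending within each cluster.
    """
    res = np.loadtxt(res_path, dtype=np.int64, ndmin=1)
    clu = np.loadtxt(clu_path, dtype=np.int64, ndmin=1)
    if clu.size < 1:
        raise FormatError(f"{clu_path}: empty .clu file")
    clu = clu[1:]  # leading entry is the number of clusters
    if clu.shape[0] != res.shape[0]:
        raise FormatError(".clu and .res length mismatch")
    spk = np.fromfile(spk_path, dtype=np.int16)
    expected = res.shape[0] * n_channels * samples_per_spike
    if spk.size != expected:
        raise FormatError(
            f".spk holds {spk.size} samples, expected {expected} "
            f"({res.shape[0]} spikes x {n_channels} ch x {samples_per_spike})"
        )
    spk = spk.reshape(res.shape[0], n_channels, samples_per_spike).astype(float)

    units = []
    for cid in sorted(set(clu.tolist())):
        if cid <= 1:
            continue
        idx = np.nonzero(clu == cid)[0]
        order = np.argsort(res[idx], kind="stable")
        idx = idx[order]
        units.append(
            UnitRecording(
                unit_id=str(cid),
                spike_times=res[idx] / sampling_rate,
                snippets=spk[idx],
                sampling_rate=sampling_rate,
            )
        )
    return units


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table as CSV (UTF-8, '.' decimal, 12 significant digits)."""
    if table.columns.duplicated().any():
        dupes = table.columns[table.columns.duplicated()].tolist()
        raise ValueError(f"duplicate column names: {dupes}")
    table.to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def feature_columns(table: pd.DataFrame) -> list[str]:
    """All non-metadata columns of a feature table, in table order."""
    return [c for c in table.columns if c not in META_COLUMNS]


# ---------------------------------------------------------------------------
# Plain-text configuration
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "channels",
    "coords_um",
    "sampling_rate",
    "chunk_size",
    "seed",
    "n_partitions",
    "grids",
}


def write_config(config: dict, path: str | Path) -> None:
    unknown = set(config) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(config, fh, indent=1)


def read_config(path: str | Path) -> dict:
    """Read a pipeline configuration (JSON) and materialize the geometry.

    Recognized keys: channels, coords_um, sampling_rate, chunk_size, seed,
    n_partitions, grids. When channels/coords_um are present, a
    ``ProbeGeometry`` is returned under the key ``geometry``.
    """
    with open(path, encoding="utf-8") as fh:
        config = json.load(fh)
    unknown = set(config) - _CONFIG_KEYS
    if unknown:
        raise FormatError(f"{path}: unknown config keys: {sorted(unknown)}")
    if config.get("chunk_size", None) not in CHUNK_SIZES:
        raise FormatError(f"{path}: chunk_size must be one of {CHUNK_SIZES}")
    if "channels" in config and "coords_um" in config:
        config["geometry"] = ProbeGeometry(
            tuple(config["channels"]), np.asarray(config["coords_um"], float)
        )
    return config
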