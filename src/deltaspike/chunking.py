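"""Chunking augmentation: partitioning spikes, per-chunk features, vote pooling.

A unit with N spikes and chunk size C is randomly split into floor(N/C)
chunks whose sizes all lie in [C, 2C-1] and differ by at most one spike;
units with N < C contribute a single chunk of N spikes. Every chunk receives
the label of its source unit. Per-chunk features use the chunk-mean waveform
(waveform and spatial modalities) and the summed single-spike ACHs of the
chunk members (timing modality). Five across-chunk statistics per base
feature (mean, SD, 25/50/75% quantiles) are appended to every row, a sixfold
feature expansion; the no-chunking table carries the same statistics
computed from its single chunk so the column set is identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import MeanWaveform, ProbeGeometry, UnitRecording
from .delta import detect_events
from .registry import BASE_FEATURES, CHUNK_STATS, META_COLUMNS
from .spatial import extract_spatial_features
from .timing import chunk_ach, extract_timing_features, per_spike_rates
from .waveform import extract_waveform_features, mean_and_upsample, scale_align


@dataclass(frozen=True)
class ChunkAssignment:
    """Random disjoint partition of one unit's spikes into chunks."""

    unit_id: str
    chunk_size: int
    chunks: tuple[np.ndarray, ...]
    seed: int | None = None


def make_chunks(
    n_spikes: int, chunk_size: int, rng: np.random.Generator | int | None = None
) -> list[np.ndarray]:
    """Randomly partition ``n_spikes`` spike indices into balanced chunks.

    Returns floor(N/C) index arrays with sizes in [C, 2C-1] differing by at
    most one; a single chunk of all N spikes when N < C.
    """
    if n_spikes < 1 or chunk_size < 1:
        raise ValueError("n_spikes and chunk_size must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    perm = rng.permutation(n_spikes)
    k = n_spikes // chunk_size
    if k <= 1:
        return [np.sort(perm)]
    base, extra = divmod(n_spikes, k)
    sizes = [base + 1] * extra + [base] * (k - extra)
    chunks, start = [], 0
    for size in sizes:
        chunks.append(np.sort(perm[start : start + size]))
        start += size
    return chunks


def _chunk_features(
    unit: UnitRecording,
    member_idx: np.ndarray,
    geometry: ProbeGeometry,
    rates: np.ndarray,
    single_chunk: bool,
) -> dict[str, float]:
    """All 34 base features of one chunk of a unit."""
    mean_wf = mean_and_upsample(unit, member_idx)
    scaled = scale_align(mean_wf)
    feats = extract_waveform_features(scaled.values[scaled.main_channel])

    ach = chunk_ach(unit.spike_times, member_idx)
    if single_chunk:
        feats.update(extract_timing_features(ach, spike_times=unit.spike_times))
    else:
        feats.update(extract_timing_features(ach, chunk_rates=rates[member_idx]))

    ev = detect_events(mean_wf)
    feats.update(extract_spatial_features(ev, geometry))
    return feats


def _append_chunk_stats(rows: list[dict[str, float]]) -> None:
    """Append across-chunk statistics (identical for all chunks of a unit)."""
    block = pd.DataFrame(rows, columns=list(BASE_FEATURES))
    stats = {}
    for name in BASE_FEATURES:
        col = block[name]
        stats[f"{name}_mean"] = float(col.mean())
        stats[f"{name}_sd"] = float(col.std(ddof=0)) if col.notna().any() else np.nan
        q25, q50, q75 = col.quantile([0.25, 0.5, 0.75])
        stats[f"{name}_q25"] = float(q25)
        stats[f"{name}_q50"] = float(q50)
        stats[f"{name}_q75"] = float(q75)
    for row in rows:
        row.update(stats)


def chunk_feature_table(
    units: list[UnitRecording],
    chunk_size: int | None,
    geometry: ProbeGeometry,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Feature table with one row per chunk (or per unit when ``chunk_size``
    is None), chunk statistics appended: 6 x 34 feature columns plus
    unit_id / label / region metadata."""
    rng = np.random.default_rng(seed)
    all_rows: list[dict] = []
    for unit in units:
        if unit.n_spikes == 0:
            warnings.warn(f"unit {unit.unit_id} has no spikes; skipped")
            continue
        if chunk_size is None:
            chunks = [np.arange(unit.n_spikes)]
        else:
            chunks = make_chunks(unit.n_spikes, chunk_size, rng)
        rates = per_spike_rates(unit.spike_times)
        single = len(chunks) == 1 and chunk_size is None
        rows = [
            _chunk_features(unit, idx, geometry, rates, single) for idx in chunks
        ]
        _append_chunk_stats(rows)
        for row in rows:
            row["unit_id"] = unit.unit_id
            row["label"] = unit.label
            row["region"] = unit.region
        all_rows.extend(rows)
    columns = list(META_COLUMNS) + list(BASE_FEATURES) + [
        f"{name}_{stat}" for name in BASE_FEATURES for stat in CHUNK_STATS
    ]
    return pd.DataFrame(all_rows, columns=columns)


def unit_feature_table(
    units: list[UnitRecording], geometry: ProbeGeometry
) -> pd.DataFrame:
    """No-chunking table: one row per unit, chunk statistics from itself."""
    return chunk_feature_table(units, None, geometry)


def delta_waveform_table(
    units: list[UnitRecording], event: str = "NEG"
) -> pd.DataFrame:
    """Waveform features extracted from delta-transformed mean waveforms.

    This is the control analysis that demonstrates information destruction:
    when the max-TTP channel coincides with the max-negativity channel, the
    transformed main channel is identical across units, so all eight
    waveform features are constant and any classifier is at chance.
    """
    from .delta import delta_transform

    rows = []
    for unit in units:
        w = mean_and_upsample(unit)
        ev = detect_events(w)
        dw = delta_transform(w, ev, event)
        scaled = scale_align(MeanWaveform(values=dw.values))
        feats = extract_waveform_features(scaled.values[scaled.main_channel])
        feats.update(
            {"unit_id": unit.unit_id, "label": unit.label, "region": unit.region}
        )
        rows.append(feats)
    from .registry import WAVEFORM_FEATURES

    return pd.DataFrame(
        rows, columns=list(META_COLUMNS) + list(WAVEFORM_FEATURES)
    )


def pool_votes(chunk_predictions: np.ndarray) -> tuple[str, float]:
    """Majority vote over one unit's chunk predictions.

    ``chunk_predictions`` holds predicted labels ("PYR"/"PV"). Returns the
    majority label (ties break toward the positive class, PV) and the unit
    score: the fraction of chunks predicted PV, used for unit-level ROC.
    """
    preds = np.asarray(chunk_predictions)
    if preds.size == 0:
        raise ValueError("need at least one chunk prediction")
    score = float((preds == "PV").mean())
    return ("PV" if score >= 0.5 else "PYR"), score
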