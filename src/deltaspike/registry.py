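"""Canonical feature registry: names, modalities, and chunk-statistic layout.

The pipeline extracts 34 base features per sample, partitioned into three
modalities: 8 waveform-based, 8 spike-timing, and 18 purely spatial features.
When chunking is used, five across-chunk statistics (mean, SD, and the
25/50/75% quantiles) are appended per base feature, a sixfold expansion.
"""

from __future__ import annotations

WAVEFORM_FEATURES: tuple[str, ...] = (
    "TTP-duration",
    "TTP-magnitude",
    "FWHM",
    "Rise-coefficient",
    "Maximum-speed",
    "Break-measure",
    "Smile-cry",
    "Acceleration",
)

TIMING_FEATURES: tuple[str, ...] = (
    "Uniform-distance",
    "DKL-short",
    "Rise-time",
    "Jump-index",
    "DKL-long",
    "PSD-center",
    "PSD-prime-center",
    "Firing-rate",
)

EVENTS: tuple[str, ...] = ("FMC", "NEG", "SMC")

_EVENT_FEATURES: tuple[str, ...] = (
    "Time-lag-SS",
    "Time-lag-SD",
    "Average-weight",
    "Longest-path",
    "Shortest-path",
)

SPATIAL_FEATURES: tuple[str, ...] = tuple(
    f"{ev}-{feat}" for feat in _EVENT_FEATURES for ev in EVENTS
) + ("SPD-Count", "SPD-SD", "SPD-Area")

BASE_FEATURES: tuple[str, ...] = WAVEFORM_FEATURES + TIMING_FEATURES + SPATIAL_FEATURES

MODALITIES: dict[str, tuple[str, ...]] = {
    "waveform": WAVEFORM_FEATURES,
    "timing": TIMING_FEATURES,
    "spatial": SPATIAL_FEATURES,
}

#: Across-chunk statistics appended to every base feature.
CHUNK_STATS: tuple[str, ...] = ("mean", "sd", "q25", "q50", "q75")

#: Non-feature columns of a feature table.
META_COLUMNS: tuple[str, ...] = ("unit_id", "label", "region")


def chunk_stat_columns(features: tuple[str, ...] | list[str]) -> list[str]:
    """Column names for the chunk statistics of ``features`` (5 per feature)."""
    return [f"{name}_{stat}" for name in features for stat in CHUNK_STATS]


def base_feature_of(column: str) -> str:
    """Map a feature-table column (base or chunk-statistic) to its base feature.

    Used when folding chunk-statistic attributions back onto the 34 base
    features for importance reports.
    """
    for stat in CHUNK_STATS:
        suffix = f"_{stat}"
        if column.endswith(suffix) and column[: -len(suffix)] in BASE_FEATURES:
            return column[: -len(suffix)]
    if column in BASE_FEATURES:
        return column
    raise KeyError(f"unknown feature column: {column!r}")


assert len(WAVEFORM_FEATURES) == 8
assert len(TIMING_FEATURES) == 8
assert len(SPATIAL_FEATURES) == 18
assert len(BASE_FEATURES) == 34
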