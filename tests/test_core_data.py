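"""Containers, readers/writers, and the feature registry."""

import numpy as np
import pandas as pd
import pytest

from deltaspike import (
    ProbeGeometry,
    UnitRecording,
    default_probe,
    read_neurosuite,
    read_units,
    write_feature_table,
    write_units,
)
from deltaspike.core_data import FormatError, read_feature_table
from deltaspike.registry import (
    BASE_FEATURES,
    CHUNK_STATS,
    SPATIAL_FEATURES,
    TIMING_FEATURES,
    WAVEFORM_FEATURES,
    base_feature_of,
    chunk_stat_columns,
)


class TestRegistry:
    def test_feature_census_partition(self):
        """34 base features, partitioned 8 waveform / 8 timing / 18 spatial."""
        assert len(BASE_FEATURES) == 34
        assert len(WAVEFORM_FEATURES) == 8
        assert len(TIMING_FEATURES) == 8
        assert len(SPATIAL_FEATURES) == 18
        assert len(set(BASE_FEATURES)) == 34

    def test_chunk_stat_expansion_is_sixfold(self):
        cols = list(BASE_FEATURES) + chunk_stat_columns(BASE_FEATURES)
        assert len(cols) == 6 * 34
        assert len(set(cols)) == len(cols)

    def test_stat_columns_fold_back_to_base(self):
        for col in chunk_stat_columns(BASE_FEATURES):
            assert base_feature_of(col) in BASE_FEATURES
        with pytest.raises(KeyError):
            base_feature_of("not-a-feature_mean")


class TestProbeGeometry:
    def test_rejects_single_channel_and_duplicate_positions(self):
        with pytest.raises(ValueError):
            ProbeGeometry((0,), np.zeros((1, 2)))
        with pytest.raises(ValueError):
            ProbeGeometry((0, 1), np.zeros((2, 2)))

    def test_default_probe_pitch(self, geometry):
        assert geometry.n_channels == 8
        d = geometry.distances_mm()
        assert d[0, 1] == pytest.approx(0.020)  # 20 μm pitch in mm


class TestUnitValidation:
    def test_rejects_non_monotonic_spike_times(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            UnitRecording("u", np.array([0.2, 0.1]), np.zeros((2, 8, 32)))

    def test_rejects_wrong_snippet_length(self):
        with pytest.raises(ValueError):
            UnitRecording("u", np.array([0.1]), np.zeros((1, 8, 31)))


class TestNativeContainer:
    def test_round_trip_identity(self, small_population, geometry, tmp_path):
        path = tmp_path / "units.h5"
        write_units(path, small_population)
        back = read_units(path, geometry)
        assert len(back) == len(small_population)
        for a, b in zip(small_population, back):
            assert a.unit_id == b.unit_id
            assert a.label == b.label and a.region == b.region
            np.testing.assert_array_equal(a.spike_times, b.spike_times)
            np.testing.assert_array_equal(a.snippets, b.snippets)

    def test_missing_sampling_rate_is_format_error(self, tmp_path):
        import h5py

        path = tmp_path / "bad.h5"
        with h5py.File(path, "w") as f:
            f.create_group("units")
        with pytest.raises(FormatError, match="sampling rate"):
            read_units(path)

    def test_channel_count_mismatch_is_format_error(
        self, small_population, tmp_path
    ):
        path = tmp_path / "units.h5"
        write_units(path, small_population)
        wrong = default_probe(n_channels=4)
        with pytest.raises(FormatError, match="channels"):
            read_units(path, wrong)


class TestNeurosuite:
    @staticmethod
    def _write_triplet(tmp_path, res, clu, snippets):
        spk = tmp_path / "f.spk.1"
        resf = tmp_path / "f.res.1"
        cluf = tmp_path / "f.clu.1"
        snippets.astype(np.int16).tofile(spk)
        np.savetxt(resf, res, fmt="%d")
        np.savetxt(cluf, np.concatenate([[len(set(clu))], clu]), fmt="%d")
        return spk, resf, cluf

    def test_two_clusters_round_trip(self, tmp_path, rng):
        n = 20
        res = np.sort(rng.integers(0, 10**6, n))
        clu = np.array([2, 3] * 10)
        snippets = rng.integers(-1000, 1000, (n, 8, 32))
        paths = self._write_triplet(tmp_path, res, clu, snippets)
        units = read_neurosuite(*paths, n_channels=8)
        assert [u.unit_id for u in units] == ["2", "3"]
        assert all(u.n_spikes == 10 for u in units)
        got = units[0].snippets[0]
        np.testing.assert_array_equal(got, snippets[clu == 2][0])

    def test_reserved_clusters_excluded(self, tmp_path, rng):
        res = np.sort(rng.integers(0, 10**6, 10))
        clu = np.zeros(10, dtype=int)
        snippets = rng.integers(-100, 100, (10, 8, 32))
        paths = self._write_triplet(tmp_path, res, clu, snippets)
        assert read_neurosuite(*paths, n_channels=8) == []

    def test_unsorted_res_sorted_on_load(self, tmp_path, rng):
        res = np.array([500, 100, 300, 200])
        clu = np.full(4, 2)
        snippets = rng.integers(-100, 100, (4, 8, 32))
        paths = self._write_triplet(tmp_path, res, clu, snippets)
        (unit,) = read_neurosuite(*paths, n_channels=8)
        assert np.all(np.diff(unit.spike_times) > 0)

    def test_length_mismatch_is_format_error(self, tmp_path, rng):
        res = np.sort(rng.integers(0, 10**6, 5))
        clu = np.full(5, 2)
        snippets = rng.integers(-100, 100, (4, 8, 32))  # one spike short
        paths = self._write_triplet(tmp_path, res, clu, snippets)
        with pytest.raises(FormatError, match=".spk"):
            read_neurosuite(*paths, n_channels=8)


class TestConfig:
    def test_round_trip_with_geometry(self, tmp_path):
        from deltaspike.core_data import read_config, write_config

        cfg = {
            "channels": [0, 1, 2],
            "coords_um": [[0, 0], [0, 20], [0, 40]],
            "sampling_rate": 20000,
            "chunk_size": 25,
            "seed": 7,
            "n_partitions": 50,
        }
        path = tmp_path / "pipeline.json"
        write_config(cfg, path)
        back = read_config(path)
        assert back["geometry"].n_channels == 3
        assert back["chunk_size"] == 25

    def test_invalid_chunk_size_rejected(self, tmp_path):
        from deltaspike.core_data import FormatError, read_config, write_config

        path = tmp_path / "bad.json"
        write_config({"chunk_size": 33}, path)
        with pytest.raises(FormatError, match="chunk_size"):
            read_config(path)

    def test_unknown_keys_rejected(self, tmp_path):
        from deltaspike.core_data import write_config

        with pytest.raises(ValueError, match="unknown"):
            write_config({"bogus": 1}, tmp_path / "x.json")


class TestDatasetManifest:
    def test_invariants(self):
        from deltaspike import DatasetManifest

        m = DatasetManifest(n_per_label={"PYR": 40, "PV": 10}, chunk_size=25, seed=0)
        assert m.chunk_size == 25
        with pytest.raises(ValueError):
            DatasetManifest(n_per_label={"PYR": -1})
        with pytest.raises(ValueError):
            DatasetManifest(chunk_size=33)


class TestFeatureTableIO:
    def test_round_trip_to_12_digits(self, tmp_path, rng):
        table = pd.DataFrame(
            {
                "unit_id": ["a", "b"],
                "label": ["PYR", "PV"],
                "region": ["CA1", "nCX"],
                **{name: rng.normal(size=2) for name in BASE_FEATURES},
            }
        )
        path = tmp_path / "feat.csv"
        write_feature_table(table, path)
        back = read_feature_table(path)
        assert list(back.columns) == list(table.columns)
        for name in BASE_FEATURES:
            np.testing.assert_allclose(back[name], table[name], rtol=1e-11)

    def test_duplicate_columns_rejected(self, tmp_path):
        table = pd.DataFrame(np.zeros((1, 2)), columns=["x", "x"])
        with pytest.raises(ValueError, match="duplicate"):
            write_feature_table(table, tmp_path / "dup.csv")

    def test_empty_table_writes_header_only(self, tmp_path):
        table = pd.DataFrame(columns=["unit_id", "label", "region", "f1"])
        path = tmp_path / "empty.csv"
        write_feature_table(table, path)
        assert read_feature_table(path).shape[0] == 0
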