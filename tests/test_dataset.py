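import numpy as np
import pandas as pd
import pytest

from edred.dataset import (Dataset, H5Stack, QueryError, SchemaError, load_dataset,
                           read_list, write_list)
from edred.geometry import Geometry
from edred.peaks import PeakList
from edred.synthdata import make_ground_truth, simulate_dataset

GEOM = Geometry(camera_length=1000.0, detector_shape=(96, 96))


@pytest.fixture(scope="module")
def two_files(tmp_path_factory):
    """Two small simulated region files (5 crystals x 2 frames each)."""
    d = tmp_path_factory.mktemp("data")
    paths = []
    for i in range(2):
        truth = make_ground_truth(geometry=GEOM, n_crystals=5, n_frames=2,
                                  seed=10 + i, dmin=6.0)
        p = d / f"region{i}.h5"
        ds = simulate_dataset(truth, GEOM, out_path=p)
        with_region = p  # one acquisition run per file
        paths.append(str(p))
    lst = d / "files.lst"
    write_list(paths, lst)
    return paths, str(lst)


class TestLoading:
    def test_list_file_concatenates_in_order(self, two_files):
        paths, lst = two_files
        ds = load_dataset(lst)
        assert ds.n_shots == 20
        assert list(ds.shots["file"][:10].unique()) == [paths[0]]

    def test_single_file_and_wildcard(self, two_files):
        paths, _ = two_files
        assert load_dataset(paths[0]).n_shots == 10
        pattern = paths[0].rsplit("/", 1)[0] + "/region*.h5"
        assert load_dataset(pattern).n_shots == 20

    def test_empty_wildcard_is_explicit_error(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_dataset(str(tmp_path / "nothing*.h5"))

    def test_stacks_are_lazy(self, two_files):
        _, lst = two_files
        ds = load_dataset(lst)
        assert isinstance(ds.stacks["data"], H5Stack)
        assert ds.stacks["data"].shape == (20, 96, 96)

    def test_roundtrip_shot_table(self, two_files, tmp_path):
        paths, _ = two_files
        ds = load_dataset(paths[0])
        out = tmp_path / "rt.h5"
        ds.write(out)
        back = load_dataset(str(out))
        skip = {"file"}
        for col in ds.shots.columns:
            if col in skip:
                continue
            assert list(back.shots[col]) == list(ds.shots[col]), col
        assert np.array_equal(back.stacks["data"].compute(),
                              ds.stacks["data"].compute())


class TestSelection:
    def make_ds(self, num_peaks):
        n = len(num_peaks)
        shots = pd.DataFrame({
            "file": ["f"] * n, "entry_index": range(n), "sample": ["s"] * n,
            "region_id": [0] * n, "crystal_id": range(n), "frame": [0] * n,
            "selected": [True] * n, "num_peaks": num_peaks,
        })
        return Dataset(shots=shots, stacks={"data": np.arange(n * 4.0).reshape(n, 2, 2)})

    def test_threshold_query_inclusive(self):
        ds = self.make_ds([10, 20, 15])
        sel = ds.get_selection("num_peaks >= 15")
        assert sel.n_shots == 2
        assert list(sel.shots["num_peaks"]) == [20, 15]

    def test_frame_query(self, two_files):
        ds = load_dataset(two_files[0][0])
        assert ds.get_selection("frame == 0").n_shots == 5

    def test_matches_boolean_mask_oracle(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 40, 25)
        ds = self.make_ds(list(counts))
        sel = ds.get_selection("num_peaks >= 15 and num_peaks < 35")
        mask = (counts >= 15) & (counts < 35)
        assert list(sel.shots["crystal_id"]) == list(np.flatnonzero(mask))

    def test_chained_equals_conjunction(self):
        rng = np.random.default_rng(1)
        ds = self.make_ds(list(rng.integers(0, 30, 40)))
        a = ds.get_selection("num_peaks >= 10").get_selection("num_peaks < 20")
        b = ds.get_selection("num_peaks >= 10 and num_peaks < 20")
        assert list(a.shots["crystal_id"]) == list(b.shots["crystal_id"])

    def test_unknown_column_raises(self):
        ds = self.make_ds([1, 2])
        with pytest.raises(QueryError):
            ds.get_selection("no_such_column > 3")

    def test_original_unmodified_and_stacks_aligned(self):
        ds = self.make_ds([5, 25, 30])
        sel = ds.get_selection("num_peaks > 10")
        assert ds.n_shots == 3
        assert sel.stacks["data"].shape[0] == sel.n_shots
        assert np.array_equal(sel.stacks["data"][0], ds.stacks["data"][1])


class TestAggregation:
    def test_sum_of_two_frames(self, two_files):
        ds = load_dataset(two_files[0][0])
        agg = ds.aggregate(by=["crystal_id"], how="sum", frame_range=(0, 2))
        assert agg.n_shots == 5
        raw = ds.stacks["data"].compute().astype(float)
        assert np.allclose(np.asarray(agg.stacks["data"][0], float), raw[0] + raw[1])

    def test_counts_conserved_under_sum(self, two_files):
        ds = load_dataset(two_files[0][0])
        agg = ds.aggregate(by=["crystal_id"], how="sum")
        assert np.isclose(np.asarray(agg.stacks["data"], float).sum(),
                          ds.stacks["data"].compute().astype(float).sum())

    def test_single_frame_range_is_identity(self, two_files):
        ds = load_dataset(two_files[0][0])
        agg = ds.aggregate(by=["crystal_id"], how="sum", frame_range=(0, 1))
        sel = ds.get_selection("frame == 0")
        assert np.array_equal(np.asarray(agg.stacks["data"]),
                              sel.stacks["data"].compute())

    def test_four_frame_aggregate_shrinks_dim0(self, tmp_path):
        truth = make_ground_truth(geometry=GEOM, n_crystals=3, n_frames=4,
                                  seed=3, dmin=6.0)
        ds = simulate_dataset(truth, GEOM)
        agg = ds.aggregate(by=["crystal_id"], how="sum", frame_range=(0, 4))
        assert ds.n_shots == 12 and agg.n_shots == 3
        assert agg.shots["frame_from"].iloc[0] == 0
        assert agg.shots["frame_to"].iloc[0] == 4

    def test_query_applied_before_grouping(self, two_files):
        ds = load_dataset(two_files[0][0])
        agg = ds.aggregate(query="frame == 1", by=["crystal_id"], how="first")
        assert agg.n_shots == 5
        sel = ds.get_selection("frame == 1")
        assert np.array_equal(np.asarray(agg.stacks["data"]),
                              sel.stacks["data"].compute())


class TestWriting:
    def test_refuse_overwrite_without_flag(self, two_files, tmp_path):
        ds = load_dataset(two_files[0][0])
        out = tmp_path / "x.h5"
        ds.write(out)
        with pytest.raises(FileExistsError):
            ds.write(out)
        ds.write(out, overwrite=True)

    def test_empty_dataset_refused(self):
        with pytest.raises(ValueError):
            Dataset().write("nowhere.h5")

    def test_split_by_region(self, tmp_path):
        truth = make_ground_truth(geometry=GEOM, n_crystals=4, seed=4, dmin=6.0)
        ds = simulate_dataset(truth, GEOM)
        ds.shots["region_id"] = [0, 0, 1, 1]
        paths = ds.write(tmp_path / "split.h5", split_by="region_id")
        assert len(paths) == 2
        assert load_dataset(paths[0]).n_shots == 2

    def test_list_file_roundtrip(self, tmp_path):
        paths = ["a.h5", "b.h5"]
        lst = tmp_path / "f.lst"
        write_list(paths, lst)
        assert read_list(lst) == paths


class TestVirtualFile:
    def make_ds_with_peaks(self, centers, peaks_x):
        n = len(centers)
        shots = pd.DataFrame({
            "file": ["f"] * n, "entry_index": range(n), "sample": ["s"] * n,
            "region_id": [0] * n, "crystal_id": range(n), "frame": [0] * n,
            "selected": [True] * n,
            "center_x": [c[0] for c in centers],
            "center_y": [c[1] for c in centers],
        })
        ds = Dataset(shots=shots,
                     stacks={"data": np.zeros((n, 1024, 1024), dtype=np.uint8)})
        pls = [PeakList(x=np.array([px]), y=np.array([510.0]),
                        intensity=np.array([9.0]), snr=np.array([3.0]))
               for px in peaks_x]
        ds.set_peaks(pls)
        return ds

    def test_shift_rule(self, tmp_path):
        ds = self.make_ds_with_peaks([(520.0, 510.0)], [600.0])
        path = ds.write_virtual_file(tmp_path / "v.h5")
        v = load_dataset(path)
        pk = v.get_peaks()[0]
        assert pk.x[0] == pytest.approx(592.0)
        assert pk.y[0] == pytest.approx(512.0)
        assert "data" not in v.stacks
        assert v.shots["orig_entry_index"].iloc[0] == 0

    def test_center_already_at_detector_center(self, tmp_path):
        ds = self.make_ds_with_peaks([(512.0, 512.0)], [600.0])
        v = load_dataset(ds.write_virtual_file(tmp_path / "v2.h5"))
        pk = v.get_peaks()[0]
        assert pk.x[0] == pytest.approx(600.0)
        assert pk.y[0] == pytest.approx(510.0)

    def test_shot_count_preserved(self, tmp_path):
        ds = self.make_ds_with_peaks([(520.0, 510.0), (500.0, 515.0)], [600.0, 400.0])
        v = load_dataset(ds.write_virtual_file(tmp_path / "v3.h5"))
        assert v.n_shots == 2

    def test_missing_centers_rejected(self, tmp_path):
        ds = self.make_ds_with_peaks([(520.0, np.nan)], [600.0])
        with pytest.raises(ValueError, match="center"):
            ds.write_virtual_file(tmp_path / "v4.h5")


def test_alignment_invariant_enforced():
    shots = pd.DataFrame({
        "file": ["f"], "entry_index": [0], "sample": ["s"], "region_id": [0],
        "crystal_id": [0], "frame": [0], "selected": [True]})
    with pytest.raises(SchemaError):
        Dataset(shots=shots, stacks={"data": np.zeros((2, 4, 4))})
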