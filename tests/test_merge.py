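import numpy as np
import pandas as pd
import pytest

from edred.cell import UnitCell
from edred.merge import (PointGroup, cc_half, cc_star, completeness_redundancy,
                         expected_uniques, make_shells, map_to_asu, mean_i_over_sigma,
                         merge_mc, r_split, read_hkl, split_half_sets, write_hkl)


def brute_force_asu(hkl, pg):
    """Oracle: explicit orbit enumeration, lexicographically maximal image."""
    best = tuple(hkl)
    for op in pg.operators:
        img = tuple(np.asarray(hkl) @ op)
        if img > best:
            best = img
    return best


class TestPointGroup:
    @pytest.mark.parametrize("name,order", [("1", 1), ("2", 2), ("222", 4),
                                            ("4", 4), ("422", 8), ("622", 12),
                                            ("23", 12), ("432", 24)])
    def test_group_orders(self, name, order):
        pg = PointGroup(name, friedel=False)
        assert pg.order == order
        assert PointGroup(name, friedel=True).order == 2 * order

    def test_closed_under_composition_and_has_identity(self):
        pg = PointGroup("422", friedel=True)
        ops = {tuple(o.ravel()) for o in pg.operators}
        assert tuple(np.eye(3, dtype=int).ravel()) in ops
        for a in pg.operators:
            for b in pg.operators:
                assert tuple((a @ b).ravel()) in ops

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            PointGroup("17")


class TestMapToAsu:
    @pytest.mark.parametrize("name", ["1", "2", "422"])
    def test_matches_bruteforce_orbit_oracle(self, name):
        pg = PointGroup(name, friedel=True)
        rng = np.random.default_rng(0)
        hkl = rng.integers(-8, 9, size=(500, 3))
        got = map_to_asu(hkl, pg)
        for row, rep in zip(hkl, got):
            assert tuple(rep) == brute_force_asu(row, pg)

    def test_identity_group_without_friedel_is_noop(self):
        pg = PointGroup("1", friedel=False)
        hkl = np.array([[1, -2, 3], [0, 0, 5]])
        assert np.array_equal(map_to_asu(hkl, pg), hkl)

    def test_symmetry_mates_share_representative(self):
        pg = PointGroup("422", friedel=True)
        assert np.array_equal(map_to_asu([1, 2, 3], pg), map_to_asu([-2, -1, -3], pg))

    def test_idempotent(self):
        pg = PointGroup("422", friedel=True)
        rng = np.random.default_rng(1)
        hkl = rng.integers(-10, 11, size=(1000, 3))
        once = map_to_asu(hkl, pg)
        assert np.array_equal(map_to_asu(once, pg), once)


def obs_frame(rows):
    return pd.DataFrame(rows, columns=["h", "k", "l", "intensity", "sigma",
                                       "crystal"])


class TestMergeMC:
    def test_unweighted_mean(self):
        obs = obs_frame([(1, 2, 3, 10.0, 1.0, 0), (1, 2, 3, 20.0, 1.0, 1)])
        m = merge_mc(obs, PointGroup("1", friedel=False))
        assert len(m) == 1
        assert m["intensity"].iloc[0] == 15.0
        assert m["n_obs"].iloc[0] == 2

    def test_friedel_mates_merged(self):
        obs = obs_frame([(1, 2, 3, 10.0, 1.0, 0), (-1, -2, -3, 30.0, 1.0, 1)])
        m = merge_mc(obs, PointGroup("1", friedel=True))
        assert len(m) == 1 and m["intensity"].iloc[0] == 20.0
        m2 = merge_mc(obs, PointGroup("1", friedel=False))
        assert len(m2) == 2

    def test_n_obs_conserved(self):
        rng = np.random.default_rng(2)
        obs = obs_frame([(int(h), int(k), int(l), float(i), 1.0, int(c))
                         for h, k, l, i, c in zip(
                             rng.integers(-4, 5, 200), rng.integers(-4, 5, 200),
                             rng.integers(-4, 5, 200), rng.exponential(10, 200),
                             rng.integers(0, 10, 200))])
        obs = obs[(obs.h != 0) | (obs.k != 0) | (obs.l != 0)]
        m = merge_mc(obs, PointGroup("422", friedel=True))
        assert m["n_obs"].sum() == len(obs)

    def test_sigma_is_standard_error(self):
        obs = obs_frame([(1, 0, 0, 10.0, 1.0, 0), (1, 0, 0, 14.0, 1.0, 1)])
        m = merge_mc(obs, PointGroup("1", friedel=False))
        assert m["sigma"].iloc[0] == pytest.approx(np.std([10, 14], ddof=1) / np.sqrt(2))
        single = merge_mc(obs_frame([(1, 0, 0, 10.0, 2.5, 0)]),
                          PointGroup("1", friedel=False))
        assert single["sigma"].iloc[0] == 2.5   # falls back to integration sigma

    def test_global_scaling_recovers_truth(self):
        rng = np.random.default_rng(0)
        pg = PointGroup("422", friedel=True)
        hkl = rng.integers(-5, 6, size=(400, 3))
        hkl = hkl[np.any(hkl != 0, axis=1)]
        asu = sorted(set(map(tuple, map_to_asu(hkl, pg))))
        truth = {h: float(rng.exponential(100)) for h in asu}
        rows = []
        for c in range(20):
            k_c = rng.uniform(0.5, 2.0)
            for i in rng.choice(len(asu), size=60, replace=False):
                h = asu[i]
                rows.append((h[0], h[1], h[2], truth[h] * k_c, 1.0, c))
        obs = obs_frame(rows)
        merged = merge_mc(obs, pg, scaling="global", n_cycles=5)
        tv = np.array([truth[(r.h, r.k, r.l)] for r in merged.itertuples()])
        assert np.corrcoef(merged["intensity"], tv)[0, 1] >= 0.999

    def test_single_crystal_scaling_is_noop(self):
        obs = obs_frame([(1, 0, 0, 10.0, 1.0, 0), (2, 0, 0, 30.0, 1.0, 0)])
        pg = PointGroup("1", friedel=False)
        a = merge_mc(obs, pg, scaling="none")
        b = merge_mc(obs, pg, scaling="global")
        assert np.allclose(a["intensity"], b["intensity"], rtol=1e-9)

    def test_empty_observations_rejected(self):
        with pytest.raises(ValueError):
            merge_mc(obs_frame([]), PointGroup("1"))


class TestCCHalf:
    def test_duplicated_half_sets_give_unity(self):
        rng = np.random.default_rng(3)
        cell = UnitCell("tP", a=78.9, c=37.9)
        rows = []
        for c in range(4):  # two identical pairs of crystals
            for _ in range(30):
                h, k, l = rng.integers(1, 6, 3)
                rows.append((int(h), int(k), int(l), float(50 + 10 * h), 1.0, c))
        obs = obs_frame(rows)
        stats = cc_half(obs, PointGroup("1", friedel=False), cell, shells=2,
                        split_seed=0)
        assert stats.attrs["overall_cc_half"] == pytest.approx(1.0, abs=1e-12)
        assert stats.attrs["overall_cc_star"] == pytest.approx(1.0, abs=1e-12)

    def test_threshold_value(self):
        assert cc_star(0.143) == pytest.approx(0.5, abs=5e-4)

    def test_cc_star_monotone_and_anchored(self):
        cc = np.linspace(-0.3, 1.0, 200)
        vals = cc_star(cc)
        assert np.all(np.diff(vals) > 0)
        assert cc_star(0.0) == 0.0
        assert cc_star(1.0) == 1.0
        assert np.isnan(cc_star(-0.5))

    def test_split_is_seeded_and_by_crystal(self):
        rng = np.random.default_rng(4)
        rows = [(int(h), int(k), int(l), 10.0, 1.0, int(c))
                for h, k, l, c in zip(rng.integers(1, 5, 100), rng.integers(1, 5, 100),
                                      rng.integers(1, 5, 100), rng.integers(0, 8, 100))]
        obs = obs_frame(rows)
        a1, b1 = split_half_sets(obs, split_seed=7)
        a2, _ = split_half_sets(obs, split_seed=7)
        assert set(a1["crystal"]) == set(a2["crystal"])
        assert set(a1["crystal"]).isdisjoint(set(b1["crystal"]))


class TestShellStats:
    def test_completeness_full_and_half(self):
        cell = UnitCell("cP", a=10.0)
        pg = PointGroup("432", friedel=True)
        exp = expected_uniques(cell, pg, dmin=3.0)
        full = pd.DataFrame({"h": exp[:, 0], "k": exp[:, 1], "l": exp[:, 2],
                             "intensity": 1.0, "sigma": 1.0,
                             "n_obs": 2})
        stats = completeness_redundancy(full, cell, pg, dmin=3.0, shells=3)
        assert stats.attrs["overall_completeness"] == pytest.approx(100.0)
        assert stats.attrs["overall_redundancy"] == pytest.approx(2.0)
        half = full.iloc[: len(full) // 2]
        stats2 = completeness_redundancy(half, cell, pg, dmin=3.0, shells=3)
        expected = 100.0 * len(half) / len(full)
        assert stats2.attrs["overall_completeness"] == pytest.approx(expected, abs=0.5)

    def test_shells_partition_range(self):
        q = np.random.default_rng(5).uniform(0.05, 0.3, 500)
        edges = make_shells(q, 10)
        counts, _ = np.histogram(q, bins=edges)
        assert counts.sum() == 500
        assert counts.min() >= 30   # roughly equal occupation

    def test_r_split_examples(self):
        a = pd.DataFrame({"h": [1, 2], "k": [0, 0], "l": [0, 0],
                          "intensity": [10.0, 20.0]})
        b = pd.DataFrame({"h": [1, 2], "k": [0, 0], "l": [0, 0],
                          "intensity": [20.0, 10.0]})
        assert r_split(a, a) == 0.0
        assert r_split(a, b) == pytest.approx(20.0 / (np.sqrt(2) * 30.0))

    def test_mean_i_over_sigma(self):
        m = pd.DataFrame({"intensity": [30.0, 30.0], "sigma": [10.0, 10.0]})
        assert mean_i_over_sigma(m) == pytest.approx(3.0)


class TestHklFile:
    def test_roundtrip(self, tmp_path):
        m = pd.DataFrame({"h": [1, 2, -3], "k": [0, 1, 2], "l": [4, 5, 6],
                          "intensity": [100.25, -3.5, 7.0],
                          "sigma": [1.5, 0.7, 2.0], "n_obs": [12, 3, 1]})
        path = tmp_path / "m.hkl"
        write_hkl(m, path, symmetry="4/mmm")
        back = read_hkl(path)
        merged = m.sort_values(["h", "k", "l"]).reset_index(drop=True)
        assert np.allclose(back[["intensity", "sigma"]],
                           merged[["intensity", "sigma"]], atol=0.005)
        assert list(back["n_obs"]) == list(merged["n_obs"])

    def test_terminated_and_formatted(self):
        m = pd.DataFrame({"h": [1], "k": [2], "l": [3], "intensity": [9.0],
                          "sigma": [1.0], "n_obs": [4]})
        text = write_hkl(m)
        assert text.rstrip().endswith("End of reflections")
        assert "Symmetry:" in text

    def test_empty_refused(self):
        with pytest.raises(ValueError):
            write_hkl(pd.DataFrame(columns=["h", "k", "l", "intensity",
                                            "sigma", "n_obs"]))
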