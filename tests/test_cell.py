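import numpy as np
import pytest

import gemmi

from edred.cell import (SpacingHistogram, UnitCell, enumerate_lattice, export_cell,
                        pairwise_histogram, parse_cell, powder_histogram,
                        predict_spacings, refine_cell)
from edred.geometry import Geometry
from edred.peaks import PeakList
from edred.synthdata import simulate_peak_lists


class TestUnitCell:
    def test_constraints_filled(self):
        c = UnitCell("tP", a=78.9, c=37.9)
        assert c.b == 78.9 and c.alpha == c.beta == c.gamma == 90.0
        h = UnitCell("hP", a=50.0, c=30.0)
        assert h.gamma == 120.0

    def test_invalid_symbols_rejected(self):
        with pytest.raises(ValueError):
            UnitCell("xP", a=10, b=10, c=10)
        with pytest.raises(ValueError):
            UnitCell("tZ", a=10, c=10)
        with pytest.raises(ValueError):
            UnitCell("cP", a=-5.0)

    def test_one_over_d_tetragonal_closed_form(self):
        c = UnitCell("tP", a=78.9, c=37.9)
        assert c.one_over_d([(1, 1, 0)])[0] == pytest.approx(np.sqrt(2) / 78.9, rel=1e-12)
        assert c.one_over_d([(0, 0, 1)])[0] == pytest.approx(1 / 37.9, rel=1e-12)


class TestPredictSpacings:
    def test_cubic_closed_form(self):
        sp = predict_spacings(UnitCell("cP", a=10.0), dmin=5.0)
        got = [q for _, q in sp[:3]]
        assert got == pytest.approx([0.1, np.sqrt(2) / 10, np.sqrt(3) / 10], rel=1e-9)

    def test_body_centered_cubic_100_absent(self):
        sp = predict_spacings(UnitCell("cI", a=10.0), dmin=5.0)
        qs = np.array([q for _, q in sp])
        assert not np.any(np.isclose(qs, 0.1, atol=1e-9))     # (100) extinct
        assert np.any(np.isclose(qs, np.sqrt(2) / 10, atol=1e-9))  # (110) present

    CELLS = [
        UnitCell("aP", a=8.3, b=9.1, c=10.7, alpha=95.0, beta=88.0, gamma=101.0),
        UnitCell("mP", a=9.0, b=11.0, c=8.0, beta=102.0),
        UnitCell("oC", a=8.0, b=12.0, c=9.5),
        UnitCell("oF", a=10.0, b=11.0, c=12.0),
        UnitCell("oI", a=9.0, b=10.0, c=11.0),
        UnitCell("tP", a=10.5, c=7.7),
        UnitCell("tI", a=10.5, c=7.7),
        UnitCell("hP", a=9.8, c=6.4),
        UnitCell("cP", a=9.0),
        UnitCell("cF", a=13.0),
    ]

    @pytest.mark.parametrize("cell", CELLS, ids=[c.bravais for c in CELLS])
    def test_against_bruteforce_enumeration(self, cell):
        """Independent oracle: gemmi d-spacings over an index box, extinction
        rules written out explicitly, deduplicated."""
        dmin = 3.0
        g = gemmi.UnitCell(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)
        rules = {
            "P": lambda h, k, l: True,
            "I": lambda h, k, l: (h + k + l) % 2 == 0,
            "F": lambda h, k, l: h % 2 == k % 2 == l % 2,
            "A": lambda h, k, l: (k + l) % 2 == 0,
            "B": lambda h, k, l: (h + l) % 2 == 0,
            "C": lambda h, k, l: (h + k) % 2 == 0,
            "R": lambda h, k, l: (-h + k + l) % 3 == 0,
        }[cell.centering]
        qs = set()
        n = 14
        for h in range(-n, n + 1):
            for k in range(-n, n + 1):
                for l in range(-n, n + 1):
                    if (h, k, l) == (0, 0, 0) or not rules(h, k, l):
                        continue
                    d = g.calculate_d([h, k, l])
                    if d >= dmin:
                        qs.add(round(1.0 / d, 6))
        expected = np.array(sorted(qs))
        got = np.array([q for _, q in predict_spacings(cell, dmin)])
        assert len(got) == len(expected)
        assert np.allclose(got, expected, atol=2e-6)


def exact_histograms(cell, dmin=10.0, bw=2e-4):
    """Histograms with a parabolic 3-bin bump centered exactly at each
    well-separated predicted spacing (sub-bin maxima recover positions
    exactly, so the true cell is a zero-residual fixed point)."""
    spacings = np.array([q for _, q in predict_spacings(cell, dmin)])
    keep = []
    for q in spacings:
        others = spacings[spacings != q]
        if others.size == 0 or np.min(np.abs(others - q)) > 8 * bw:
            keep.append(q)
    edges = np.arange(0.0, spacings.max() + 20 * bw, bw)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.zeros(len(centers))
    for q in keep:
        j = int(np.argmin(np.abs(centers - q)))
        for off in (-1, 0, 1):
            x = centers[j + off]
            counts[j + off] += max(100.0 - 30.0 / bw**2 * (x - q) ** 2, 0.0)
    h = SpacingHistogram(bin_edges=edges, counts=counts, source="powder")
    return h


class TestRefineCell:
    def test_truth_is_fixed_point_on_exact_histograms(self):
        cell = UnitCell("tP", a=78.9, c=37.9)
        hist = exact_histograms(cell)
        refined, report = refine_cell(cell, hist, None, dmin=10.0)
        assert report.converged
        assert abs(refined.a - 78.9) < 1e-6
        assert abs(refined.c - 37.9) < 1e-6

    def test_recovery_from_perturbed_start_exact_histograms(self):
        cell = UnitCell("tP", a=78.9, c=37.9)
        hist = exact_histograms(cell)
        start = UnitCell("tP", a=80.5, c=37.0)
        refined, report = refine_cell(start, hist, None, dmin=10.0)
        assert abs(refined.a - 78.9) < 0.05
        assert abs(refined.c - 37.9) < 0.05

    def test_cubic_constrained_recovery(self):
        geom = Geometry()
        cell = UnitCell("cP", a=10.0)
        pls, ctrs = simulate_peak_lists(cell, 100, geom, dmin=3.0, noise_px=0.3, seed=5)
        powder = powder_histogram(pls, ctrs, geom, bin_width=2e-4)
        pairs = pairwise_histogram(pls, geom, bin_width=2e-4)
        refined, _ = refine_cell(UnitCell("cP", a=10.3), powder, pairs, dmin=3.0)
        assert refined.a == pytest.approx(10.0, abs=0.01)

    def test_monotone_residual_and_report(self):
        cell = UnitCell("tP", a=78.9, c=37.9)
        hist = exact_histograms(cell)
        _, report = refine_cell(UnitCell("tP", a=80.0, c=37.3), hist, None, dmin=10.0)
        finals = [r for _, r in report.history[-3:]]
        assert finals[-1] <= finals[0] + 1e-9

    def test_underdetermined_refused(self):
        edges = np.arange(0.0, 0.05, 2e-4)
        empty = SpacingHistogram(bin_edges=edges, counts=np.zeros(len(edges) - 1))
        with pytest.raises(ValueError):
            refine_cell(UnitCell("tP", a=78.9, c=37.9), empty, None, dmin=10.0)

    def test_random_tetragonal_recovery_median(self):
        """Noisy synthetic histograms, 3% perturbed starts: median error small."""
        rng = np.random.default_rng(3)
        geom = Geometry()
        errs = []
        for trial in range(6):
            a, c = rng.uniform(40, 120), rng.uniform(20, 60)
            cell = UnitCell("tP", a=a, c=c)
            pls, ctrs = simulate_peak_lists(cell, 150, geom, dmin=10.0,
                                            noise_px=0.3, seed=100 + trial)
            powder = powder_histogram(pls, ctrs, geom, bin_width=2e-4)
            pairs = pairwise_histogram(pls, geom, bin_width=2e-4)
            start = UnitCell("tP", a=a * (1 + 0.03 * rng.choice([-1, 1])),
                             c=c * (1 + 0.03 * rng.choice([-1, 1])))
            refined, _ = refine_cell(start, powder, pairs, dmin=10.0)
            errs.append(abs(refined.a - a))
        assert np.median(errs) < 0.1


class TestHistograms:
    def test_powder_single_peak_lands_in_bin(self, geom):
        pk = PeakList(x=np.array([256.0 + geom.q_to_r(0.05)]), y=np.array([256.0]),
                      intensity=np.ones(1), snr=np.ones(1))
        h = powder_histogram([pk], [(256.0, 256.0)], geom, bin_width=2e-4)
        j = np.argmax(h.counts)
        assert h.counts.sum() == 1
        assert abs(h.bin_centers[j] - 0.05) <= h.bin_width

    def test_powder_linear_in_data(self, geom):
        rng = np.random.default_rng(0)
        pls = [PeakList(x=rng.uniform(100, 400, 20), y=rng.uniform(100, 400, 20),
                        intensity=np.ones(20), snr=np.ones(20)) for _ in range(3)]
        ctrs = [(256.0, 256.0)] * 3
        h1 = powder_histogram(pls, ctrs, geom, bin_width=2e-4, qmax=0.3)
        h2 = powder_histogram(pls + pls, ctrs + ctrs, geom, bin_width=2e-4, qmax=0.3)
        assert np.array_equal(h2.counts, 2 * h1.counts)

    def test_pairwise_collinear_counting(self, geom):
        # 3 collinear equally spaced peaks: two pairs at s, one at 2s
        s_px = 30.0
        pk = PeakList(x=np.array([100.0, 130.0, 160.0]), y=np.full(3, 200.0),
                      intensity=np.ones(3), snr=np.ones(3))
        h = pairwise_histogram([pk], geom, bin_width=2e-4)
        q1, q2 = geom.r_to_q(s_px), geom.r_to_q(2 * s_px)
        j1 = np.argmin(np.abs(h.bin_centers - q1))
        j2 = np.argmin(np.abs(h.bin_centers - q2))
        assert h.counts.sum() == 3
        assert h.counts[j1 - 1:j1 + 2].sum() == 2
        assert h.counts[j2 - 1:j2 + 2].sum() == 1

    def test_single_peak_shots_contribute_nothing(self, geom):
        pk = PeakList(x=np.array([100.0]), y=np.array([100.0]),
                      intensity=np.ones(1), snr=np.ones(1))
        h = pairwise_histogram([pk], geom)
        assert h.counts.sum() == 0

    def test_pairwise_maxima_near_primitive_basis(self, geom):
        cell = UnitCell("tP", a=78.9, c=37.9)
        g2 = Geometry()  # wide camera for powder statistics
        pls, _ = simulate_peak_lists(cell, 150, g2, dmin=10.0, noise_px=0.3, seed=9)
        h = pairwise_histogram(pls, g2, bin_width=2e-4)
        from scipy.signal import find_peaks as sp_find_peaks
        idx, _ = sp_find_peaks(h.counts, prominence=0.05 * h.counts.max())
        maxima = h.bin_centers[idx]
        # the primitive in-plane basis length |a*| must appear as a
        # pronounced pairwise maximum
        assert np.min(np.abs(maxima - 1 / 78.9)) <= 3 * h.bin_width


class TestCellFile:
    def test_export_contains_required_fields(self):
        text = export_cell(UnitCell("tP", a=78.9, c=37.9))
        assert "lattice_type = tetragonal" in text
        assert "centering = P" in text

    @pytest.mark.parametrize("cell", [
        UnitCell("tP", a=78.9, c=37.9),
        UnitCell("mP", a=9.0, b=11.0, c=8.0, beta=102.0),
        UnitCell("cF", a=13.0),
    ], ids=["tP", "mP", "cF"])
    @pytest.mark.parametrize("unit", ["A", "nm"])
    def test_roundtrip(self, cell, unit, tmp_path):
        path = tmp_path / "c.cell"
        export_cell(cell, path, unit=unit)
        back = parse_cell(path)
        assert back.bravais == cell.bravais
        assert back.a == pytest.approx(cell.a, abs=1e-3)
        assert back.c == pytest.approx(cell.c, abs=1e-3)
        assert back.beta == pytest.approx(cell.beta, abs=1e-6)
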