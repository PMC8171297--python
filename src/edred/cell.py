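"""Bravais unit cells, layer-spacing prediction and histogram-based refinement.

Still electron diffraction patterns carry almost no three-dimensional
information, so per-pattern cell determination (as in serial X-ray pipelines)
is not possible.  Instead, starting from a reasonable estimate of the cell
parameters, the cell is refined against *pooled* radial statistics of all
found Bragg peaks: the virtual powder pattern (histogram of peak radii,
converted to 1/d) and the pairwise-distance histogram (all peak-pair distance
vectors within each pattern, whose lengths in the paraxial regime also match
inverse layer spacings and show pronounced maxima near the primitive-cell
basis vectors).  Predicted layer spacings are matched to observed histogram
maxima and the free cell parameters fitted by weighted least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, signal

import gemmi

#: lattice system -> (free parameter names, constraint filler)
_SYSTEMS = {
    "a": ("triclinic", ("a", "b", "c", "alpha", "beta", "gamma")),
    "m": ("monoclinic", ("a", "b", "c", "beta")),
    "o": ("orthorhombic", ("a", "b", "c")),
    "t": ("tetragonal", ("a", "c")),
    "h": ("hexagonal", ("a", "c")),
    "c": ("cubic", ("a",)),
}

_CENTERINGS = set("PABCIFR")


@dataclass(frozen=True)
class UnitCell:
    """A Bravais unit cell (parameters in Angstrom / degrees).

    ``bravais`` is a two-letter Pearson-style symbol, e.g. ``tP`` for a
    primitive tetragonal lattice; the first letter sets the lattice system
    (and hence parameter constraints), the second the centering (which
    determines systematic absences).
    """

    bravais: str
    a: float
    b: float | None = None
    c: float | None = None
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if len(self.bravais) != 2 or self.bravais[0] not in _SYSTEMS or self.bravais[1] not in _CENTERINGS:
            raise ValueError(f"unknown Bravais symbol {self.bravais!r}")
        sys = self.bravais[0]
        # fill implied parameters, then enforce constraints
        b = self.b
        c = self.c
        alpha, beta, gamma = self.alpha, self.beta, self.gamma
        if sys in ("t", "h"):
            b = self.a
        if sys == "c":
            b = c = self.a
        if b is None or c is None:
            raise ValueError("b and c must be given for this lattice system")
        if sys == "h":
            gamma = 120.0
        if sys in ("m",):
            alpha = gamma = 90.0
        if sys in ("o", "t", "c"):
            alpha = beta = gamma = 90.0
        object.__setattr__(self, "b", float(b))
        object.__setattr__(self, "c", float(c))
        object.__setattr__(self, "alpha", float(alpha))
        object.__setattr__(self, "beta", float(beta))
        object.__setattr__(self, "gamma", float(gamma))
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        if self.volume <= 0:
            raise ValueError("cell volume must be positive")

    # ------------------------------------------------------------------

    @property
    def lattice_system(self) -> str:
        return _SYSTEMS[self.bravais[0]][0]

    @property
    def centering(self) -> str:
        return self.bravais[1]

    @property
    def volume(self) -> float:
        return float(gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma).volume)

    @property
    def free_parameter_names(self) -> tuple[str, ...]:
        return _SYSTEMS[self.bravais[0]][1]

    @property
    def free_parameters(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.free_parameter_names])

    def with_parameters(self, values) -> "UnitCell":
        kw = dict(zip(self.free_parameter_names, (float(v) for v in values)))
        return replace(self, **kw)

    def reciprocal_basis(self) -> np.ndarray:
        """3x3 matrix whose rows are a*, b*, c* in 1/A (crystallographic,
        no 2 pi), in a Cartesian crystal-fixed frame."""
        g = gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)
        frac = np.array(g.frac.mat.tolist())
        return frac  # rows of the fractionalization matrix are a*, b*, c*

    def one_over_d(self, hkl) -> np.ndarray:
        """|g| = 1/d for one or many Miller triples."""
        hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
        bstar = self.reciprocal_basis()
        return np.linalg.norm(hkl @ bstar, axis=1)

    # ------------------------------------------------------------------

    def allowed(self, h, k, l) -> np.ndarray:
        """Reflection conditions of the centering (systematic absences)."""
        h, k, l = (np.asarray(v, dtype=int) for v in (h, k, l))
        cent = self.centering
        if cent == "P":
            return np.ones(np.broadcast(h, k, l).shape, dtype=bool)
        if cent == "I":
            return (h + k + l) % 2 == 0
        if cent == "F":
            return ((h % 2) == (k % 2)) & ((k % 2) == (l % 2))
        if cent == "A":
            return (k + l) % 2 == 0
        if cent == "B":
            return (h + l) % 2 == 0
        if cent == "C":
            return (h + k) % 2 == 0
        if cent == "R":  # obverse hexagonal setting
            return (-h + k + l) % 3 == 0
        raise AssertionError(cent)


def enumerate_lattice(cell: UnitCell, dmin: float) -> tuple[np.ndarray, np.ndarray]:
    """All non-zero lattice points with 1/d <= 1/dmin, absences removed.

    Returns ``(hkl, one_over_d)`` arrays.
    """
    qmax = 1.0 / dmin
    hmax = int(np.ceil(qmax * cell.a)) + 1
    kmax = int(np.ceil(qmax * cell.b)) + 1
    lmax = int(np.ceil(qmax * cell.c)) + 1
    h, k, l = np.meshgrid(
        np.arange(-hmax, hmax + 1), np.arange(-kmax, kmax + 1), np.arange(-lmax, lmax + 1),
        indexing="ij",
    )
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    hkl = hkl[np.any(hkl != 0, axis=1)]
    hkl = hkl[cell.allowed(hkl[:, 0], hkl[:, 1], hkl[:, 2])]
    q = cell.one_over_d(hkl)
    keep = q <= qmax + 1e-12
    return hkl[keep], q[keep]


def predict_spacings(cell: UnitCell, dmin: float, tol: float = 1e-6):
    """Distinct inverse layer spacings 1/d <= 1/dmin for the cell.

    Returns a list of ``(hkl, one_over_d)`` with one representative Miller
    triple per spacing, deduplicated within ``tol`` (1/A) and sorted by 1/d.
    """
    hkl, q = enumerate_lattice(cell, dmin)
    order = np.argsort(q)
    hkl, q = hkl[order], q[order]
    out: list[tuple[tuple[int, int, int], float]] = []
    for trip, qi in zip(hkl, q):
        if out and abs(qi - out[-1][1]) < tol:
            continue
        out.append((tuple(int(v) for v in trip), float(qi)))
    return out


# ----------------------------------------------------------------------
# spacing histograms


@dataclass
class SpacingHistogram:
    """1-D histogram of inverse layer spacings (1/d in 1/A)."""

    bin_edges: np.ndarray
    counts: np.ndarray
    source: str = "powder"

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_text(self) -> str:
        lines = [f"# 1/d(1/A)  counts  ({self.source})"]
        for x, n in zip(self.bin_centers, self.counts):
            lines.append(f"{x:.6e} {n:g}")
        return "\n".join(lines) + "\n"


def _histogram(values: np.ndarray, bin_width: float, qmax: float, source: str) -> SpacingHistogram:
    edges = np.arange(0.0, qmax + bin_width, bin_width)
    counts, _ = np.histogram(values, bins=edges)
    return SpacingHistogram(bin_edges=edges, counts=counts.astype(float), source=source)


def powder_histogram(peak_lists, centers, geometry, bin_width: float = 2e-4,
                     qmax: float | None = None) -> SpacingHistogram:
    """Virtual powder pattern: histogram of per-peak 1/d over all shots.

    ``peak_lists`` is an iterable of PeakList (or (x, y) arrays),
    ``centers`` the per-shot beam centers.  Peak radii are measured from
    each shot's own center, which makes this a super-resolution powder
    measurement unaffected by beam-center jitter.
    """
    qs = []
    for pk, ctr in zip(peak_lists, centers):
        x, y = _peak_xy(pk)
        if len(x) == 0:
            continue
        r = np.hypot(x - ctr[0], y - ctr[1])
        qs.append(geometry.r_to_q(r))
    allq = np.concatenate(qs) if qs else np.empty(0)
    if qmax is None:
        qmax = float(allq.max()) + 10 * bin_width if allq.size else 0.1
    return _histogram(allq, bin_width, qmax, "powder")


def pairwise_histogram(peak_lists, geometry, bin_width: float = 2e-4,
                       qmax: float | None = None) -> SpacingHistogram:
    """Histogram of all within-shot peak-pair distances, converted to 1/d.

    In the paraxial regime the difference vector of two reflections in one
    still is itself close to a reciprocal-lattice vector, so pair distances
    also accumulate at inverse layer spacings — including the primitive
    basis-vector lengths that centering absences hide from the powder
    histogram.  Pairs are never formed across shots.
    """
    qs = []
    for pk in peak_lists:
        x, y = _peak_xy(pk)
        n = len(x)
        if n < 2:
            continue
        dx = x[:, None] - x[None, :]
        dy = y[:, None] - y[None, :]
        iu = np.triu_indices(n, k=1)
        d = np.hypot(dx[iu], dy[iu])
        qs.append(geometry.r_to_q(d))
    allq = np.concatenate(qs) if qs else np.empty(0)
    if qmax is None:
        qmax = float(allq.max()) + 10 * bin_width if allq.size else 0.1
    return _histogram(allq, bin_width, qmax, "pairwise")


def _peak_xy(pk):
    if hasattr(pk, "x"):
        return np.asarray(pk.x, dtype=float), np.asarray(pk.y, dtype=float)
    arr = np.asarray(pk, dtype=float)
    return arr[:, 0], arr[:, 1]


# ----------------------------------------------------------------------
# refinement


def _observed_maxima(hist: SpacingHistogram, prominence_frac: float):
    """Local maxima of the histogram with sub-bin position by parabolic
    interpolation; returns (positions 1/A, weights=counts)."""
    c = hist.counts
    if c.max() <= 0:
        return np.empty(0), np.empty(0)
    idx, _ = signal.find_peaks(c, prominence=prominence_frac * c.max())
    pos, wt = [], []
    centers = hist.bin_centers
    for i in idx:
        if 0 < i < len(c) - 1:
            denom = c[i - 1] - 2 * c[i] + c[i + 1]
            shift = 0.0 if denom == 0 else 0.5 * (c[i - 1] - c[i + 1]) / denom
            shift = float(np.clip(shift, -0.5, 0.5))
        else:
            shift = 0.0
        pos.append(centers[i] + shift * hist.bin_width)
        wt.append(c[i])
    return np.array(pos), np.array(wt)


def _prescan_scale(cell0: UnitCell, hists, dmin: float,
                   span: float = 0.06, step: float = 1e-3) -> UnitCell:
    """Scan an overall length-scale factor against the histograms.

    Scores each candidate scale by the smoothed histogram counts at the
    scaled predicted spacings; lengths are rescaled by the best factor.
    Leaves angles untouched.
    """
    q_pred = np.array([q for _, q in predict_spacings(cell0, dmin)])
    if q_pred.size < 3:
        return cell0
    scales = np.arange(1.0 - span, 1.0 + span + step / 2, step)
    score = np.zeros(len(scales))
    for h, w in hists:
        c = h.counts
        if c.max() <= 0:
            continue
        sm = np.convolve(c, np.ones(3) / 3.0, mode="same") / c.max()
        centers = h.bin_centers
        for i, s in enumerate(scales):
            score[i] += w * np.interp(q_pred * s, centers, sm, left=0, right=0).sum()
    best = float(scales[np.argmax(score)])
    names = cell0.free_parameter_names
    vals = [getattr(cell0, n) / best if n in ("a", "b", "c") else getattr(cell0, n)
            for n in names]
    cell = cell0.with_parameters(vals)

    # coordinate-wise scans remove anti-correlated start errors the common
    # scale cannot reach
    def hist_score(c):
        qp = np.array([q for _, q in predict_spacings(c, dmin)])
        total = 0.0
        for h, w in hists:
            cnt = h.counts
            if cnt.max() <= 0:
                continue
            sm = np.convolve(cnt, np.ones(3) / 3.0, mode="same") / cnt.max()
            total += w * np.interp(qp, h.bin_centers, sm, left=0, right=0).sum() / max(len(qp), 1)
        return total

    length_names = [n for n in names if n in ("a", "b", "c")]
    for _ in range(2 if len(length_names) > 1 else 0):
        for pname in length_names:
            base = getattr(cell, pname)
            cands = base * np.arange(0.97, 1.03 + 1e-9, 2e-3)
            scores = []
            for v in cands:
                trial = cell.with_parameters(
                    [v if n == pname else getattr(cell, n) for n in names])
                scores.append(hist_score(trial))
            cell = cell.with_parameters(
                [float(cands[int(np.argmax(scores))]) if n == pname
                 else getattr(cell, n) for n in names])
    return cell


@dataclass
class CellFitReport:
    converged: bool
    n_iter: int
    n_assigned: int
    residual: float
    history: list


def refine_cell(cell0: UnitCell, powder: SpacingHistogram | None,
                pairs: SpacingHistogram | None, dmin: float = 10.0,
                tol_bins: float = 1.5, start_tol_bins: float = 8.0,
                min_sep_bins: float = 6.0, prominence_frac: float = 0.02,
                weight_ratio: float = 0.3, max_iter: int = 20,
                param_tol: float = 1e-3) -> tuple[UnitCell, CellFitReport]:
    """Refine free cell parameters against spacing-histogram maxima.

    Iterates: predict spacings from the current cell -> assign each
    prediction to the nearest observed histogram maximum within the current
    tolerance (unassigned predictions dropped, degenerate assignments
    allowed) -> weighted least squares on
    ``sum w (1/d_pred - 1/d_obs)^2`` over the free parameters -> repeat
    until the parameter change falls below ``param_tol`` (A / degree).

    The assignment tolerance is annealed from ``start_tol_bins`` down to
    ``tol_bins`` (factor 0.6 per iteration): a start estimate a few percent
    off shifts predicted spacings by several bins, so early iterations must
    accept wider matches, while the final iterations use the tight
    tolerance that rejects accidental assignments.  Predicted spacings
    closer than ``min_sep_bins`` bins to another prediction are excluded
    from the fit: the histograms cannot resolve them, and their blended
    maxima sit systematically off either constituent.  ``weight_ratio``
    scales the pairwise-histogram weights relative to the powder ones; the
    default down-weights the pairwise histogram in the least-squares stage
    because the excitation-error band smears pair distances asymmetrically
    toward low 1/d, while powder radii are unbiased sub-bin measurements —
    the pairwise maxima still drive the assignment of primitive-basis
    spacings that centering absences hide from the powder pattern.
    Requires at least 3 assigned spacings.
    """
    hists = []
    if powder is not None:
        hists.append((powder, 1.0))
    if pairs is not None:
        hists.append((pairs, weight_ratio))
    if not hists:
        raise ValueError("at least one histogram required")

    obs = []
    for h, w in hists:
        pos, wt = _observed_maxima(h, prominence_frac)
        obs.append((pos, wt * w, h.bin_width))

    # global scale pre-scan: a start estimate off by an overall factor locks
    # the assignment onto wrong maxima, so first find the scale s maximizing
    # the histogram counts sitting under the (scaled) predicted spacings
    cell = _prescan_scale(cell0, hists, dmin)
    history = []
    converged = False
    n_assigned = 0
    res_val = np.nan
    tol_now = max(start_tol_bins, tol_bins)
    bw_min = min(h.bin_width for h, _ in hists)
    for it in range(1, max_iter + 1):
        spac = predict_spacings(cell, dmin)
        pred_hkl = np.array([s[0] for s in spac])
        q_pred = np.array([s[1] for s in spac])
        # keep only spacings the histograms can resolve
        if len(q_pred) > 1 and min_sep_bins > 0:
            gap_lo = np.diff(q_pred, prepend=-np.inf)
            gap_hi = np.diff(q_pred, append=np.inf)
            resolved = np.minimum(gap_lo, gap_hi) >= min_sep_bins * bw_min
            if resolved.sum() >= 3:
                pred_hkl, q_pred = pred_hkl[resolved], q_pred[resolved]
        # assignment under current cell
        targets, weights, hkls = [], [], []
        for pos, wt, bw in obs:
            if pos.size == 0:
                continue
            j = np.argmin(np.abs(q_pred[:, None] - pos[None, :]), axis=1)
            ok = np.abs(q_pred - pos[j]) <= tol_now * bw
            targets.append(pos[j[ok]])
            weights.append(wt[j[ok]])
            hkls.append(pred_hkl[ok])
        if not targets or sum(len(t) for t in targets) < 3:
            raise ValueError("fewer than 3 predicted spacings assigned to observed maxima; "
                             "refinement under-determined")
        t_obs = np.concatenate(targets)
        w = np.concatenate(weights)
        hkl_fit = np.concatenate(hkls)
        n_assigned = len(t_obs)
        sw = np.sqrt(w)

        p0 = cell.free_parameters

        def resid(p):
            c = cell.with_parameters(p)
            return sw * (c.one_over_d(hkl_fit) - t_obs)

        sol = optimize.least_squares(resid, p0, method="lm")
        new_cell = cell.with_parameters(sol.x)
        res_val = float(np.sum(sol.fun**2))
        history.append((new_cell.free_parameters.copy(), res_val))
        dp = np.max(np.abs(new_cell.free_parameters - cell.free_parameters))
        cell = new_cell
        if dp < param_tol and tol_now <= tol_bins:
            converged = True
            break
        tol_now = max(tol_now * 0.6, tol_bins)
    return cell, CellFitReport(converged=converged, n_iter=it, n_assigned=n_assigned,
                               residual=res_val, history=history)


# ----------------------------------------------------------------------
# .cell interop (CrystFEL dialect)

_LATTICE_NAMES = {s: name for s, (name, _) in _SYSTEMS.items()}
_LATTICE_FROM_NAME = {name: s for s, (name, _) in _SYSTEMS.items()}
# rhombohedral cells in the hexagonal setting carry centering R
_LATTICE_FROM_NAME["rhombohedral"] = "h"


def export_cell(cell: UnitCell, path=None, unit: str = "A") -> str:
    """Write a CrystFEL-style .cell file; returns the text.

    ``unit`` is ``"A"`` (Angstrom) or ``"nm"``.
    """
    if unit not in ("A", "nm"):
        raise ValueError("unit must be 'A' or 'nm'")
    scale = 1.0 if unit == "A" else 0.1
    name = _LATTICE_NAMES[cell.bravais[0]]
    if cell.centering == "R":
        name = "rhombohedral"
    lines = [
        "CrystFEL unit cell file version 1.0",
        "",
        f"lattice_type = {name}",
        f"centering = {cell.centering}",
    ]
    if cell.lattice_system in ("tetragonal", "hexagonal"):
        lines.append("unique_axis = c")
    elif cell.lattice_system == "monoclinic":
        lines.append("unique_axis = b")
    lines += [
        f"a = {cell.a * scale:.5f} {unit}",
        f"b = {cell.b * scale:.5f} {unit}",
        f"c = {cell.c * scale:.5f} {unit}",
        f"al = {cell.alpha:.5f} deg",
        f"be = {cell.beta:.5f} deg",
        f"ga = {cell.gamma:.5f} deg",
    ]
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as f:
            f.write(text)
    return text


def parse_cell(text_or_path) -> UnitCell:
    """Read a .cell file written by :func:`export_cell` (or CrystFEL)."""
    try:
        with open(text_or_path) as f:
            text = f.read()
    except (OSError, TypeError):
        text = text_or_path
    kv = {}
    for line in text.splitlines():
        line = line.split(";")[0].strip()
        if "=" not in line:
            continue
        key, val = (s.strip() for s in line.split("=", 1))
        kv[key] = val

    def length(key):
        tok = kv[key].split()
        v = float(tok[0])
        if len(tok) > 1 and tok[1] == "nm":
            v *= 10.0
        return v

    name = kv["lattice_type"]
    sys = _LATTICE_FROM_NAME[name]
    cent = kv.get("centering", "P")
    angles = {}
    for short, full in (("al", "alpha"), ("be", "beta"), ("ga", "gamma")):
        if short in kv:
            angles[full] = float(kv[short].split()[0])
    return UnitCell(bravais=sys + cent, a=length("a"), b=length("b"), c=length("c"), **angles)
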