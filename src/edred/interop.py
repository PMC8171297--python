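"""File-format bridges to the serial-crystallography ecosystem.

Covers the CrystFEL-interop formats around indexing and integration:
geometry files (.geom), plain-text indexing-solution files (.sol, one line
per shot: file identifier, event identifier, nine reciprocal-basis
components in 1/A, two beam-shift components in px), a minimal .stream
parser (found peaks, crystal reciprocal bases, cells, integrated
reflections), and broadcasting of indexing solutions between datasets with
different dose-fraction aggregation.  All files are text, UTF-8, unix
newlines; every writer is exactly inverted by its reader.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Geometry

_SOL_HEADER = ("# edred solution file\n"
               "# columns: file event  a*x a*y a*z  b*x b*y b*z  c*x c*y c*z  "
               "shift_x shift_y   (basis 1/A lab frame, shift px)\n")


@dataclass
class IndexingSolution:
    """Reciprocal basis + beam shift of one indexed crystal.

    ``basis`` rows are a*, b*, c* in 1/A, laboratory frame (beam along +z);
    ``shift`` is the beam offset from the detector center in px.
    """

    file: str
    event: object
    basis: np.ndarray
    shift: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.basis = np.asarray(self.basis, dtype=float).reshape(3, 3)
        if abs(np.linalg.det(self.basis)) < 1e-15:
            raise ValueError("reciprocal basis is singular")
        if not np.all(np.isfinite(self.shift)):
            raise ValueError("beam shift must be finite")


# ----------------------------------------------------------------------
# .geom


def write_geom(geometry: Geometry, path=None, detector_meta: dict | None = None) -> str:
    """Write a single-panel CrystFEL-style geometry file.

    The panel corner places the beam at the detector center; ``res`` is
    1/pixel_size in 1/m, ``clen`` the camera length in m, the wavelength in
    Angstrom.  The elliptical distortion model is folded into the fs/ss
    axis vectors (isotropic axes for axis ratio 1).
    """
    ny, nx = geometry.detector_shape
    eta, theta = geometry.ellipticity
    ct, st = np.cos(theta), np.sin(theta)
    rot = np.array([[ct, -st], [st, ct]])
    s = np.sqrt(eta)
    m = rot @ np.diag([1 / s, s]) @ rot.T      # coordinate-correction tensor
    lines = ["; geometry generated by edred",
             f"wavelength = {geometry.wavelength!r} A",
             f"clen = {geometry.camera_length / 1000.0!r} m",
             f"res = {1.0 / (geometry.pixel_size * 1e-3)!r}",
             "",
             "panel0/min_fs = 0",
             f"panel0/max_fs = {nx - 1}",
             "panel0/min_ss = 0",
             f"panel0/max_ss = {ny - 1}",
             f"panel0/corner_x = {-nx / 2.0:.9g}",
             f"panel0/corner_y = {-ny / 2.0:.9g}",
             f"panel0/fs = {m[0, 0]:+.9g}x {m[1, 0]:+.9g}y",
             f"panel0/ss = {m[0, 1]:+.9g}x {m[1, 1]:+.9g}y",
             ""]
    if detector_meta:
        for k, v in detector_meta.items():
            lines.insert(1, f"; {k} = {v}")
    text = "\n".join(lines)
    if path is not None:
        with open(path, "w") as f:
            f.write(text)
    return text


def parse_geom(text_or_path) -> Geometry:
    """Read a geometry file written by :func:`write_geom`."""
    try:
        with open(text_or_path) as f:
            text = f.read()
    except (OSError, TypeError):
        text = text_or_path
    kv = {}
    for line in text.splitlines():
        line = line.split(";")[0].strip()
        if "=" in line:
            k, v = (s.strip() for s in line.split("=", 1))
            kv[k] = v
    wavelength = float(kv["wavelength"].split()[0])
    clen = float(kv["clen"].split()[0]) * 1000.0
    pixel = 1.0 / float(kv["res"]) * 1e3
    nx = int(kv["panel0/max_fs"]) + 1
    ny = int(kv["panel0/max_ss"]) + 1

    def axis(spec):
        vec = [0.0, 0.0]
        for tok in spec.split():
            if tok.endswith("x"):
                vec[0] = float(tok[:-1])
            elif tok.endswith("y"):
                vec[1] = float(tok[:-1])
        return vec

    m = np.array([axis(kv["panel0/fs"]), axis(kv["panel0/ss"])]).T
    sym = 0.5 * (m + m.T)
    w, v = np.linalg.eigh(sym)
    eta = float(w[1] / w[0]) if w[0] > 0 else 1.0
    theta = float(np.arctan2(v[1, 0], v[0, 0]))
    if theta <= -np.pi / 2:
        theta += np.pi
    elif theta > np.pi / 2:
        theta -= np.pi
    if abs(eta - 1.0) < 1e-12:
        eta, theta = 1.0, 0.0
    return Geometry(camera_length=clen, pixel_size=pixel, wavelength=wavelength,
                    detector_shape=(ny, nx), ellipticity=(eta, theta))


# ----------------------------------------------------------------------
# .sol


def write_sol(solutions, path=None) -> str:
    """Write indexing solutions to a .sol text file."""
    lines = [_SOL_HEADER.rstrip("\n")]
    for s in solutions:
        b = s.basis.ravel()
        comp = " ".join(f"{v:.9e}" for v in b)
        lines.append(f"{s.file} {s.event} {comp} {s.shift[0]:.6f} {s.shift[1]:.6f}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as f:
            f.write(text)
    return text


def read_sol(text_or_path) -> list[IndexingSolution]:
    """Read a .sol file; tolerant of extra whitespace and # comments."""
    try:
        with open(text_or_path) as f:
            text = f.read()
    except (OSError, TypeError):
        text = text_or_path
    out = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#")[0].strip()
        if not line:
            continue
        tok = line.split()
        if len(tok) != 13:
            raise ValueError(f".sol line {lineno}: expected 13 fields "
                             f"(file event 9 basis 2 shift), got {len(tok)}")
        basis = np.array([float(v) for v in tok[2:11]]).reshape(3, 3)
        shift = (float(tok[11]), float(tok[12]))
        out.append(IndexingSolution(file=tok[0], event=_coerce_event(tok[1]),
                                    basis=basis, shift=shift))
    return out


def _coerce_event(tok: str):
    try:
        return int(tok)
    except ValueError:
        return tok


# ----------------------------------------------------------------------
# .stream (minimal)


@dataclass
class StreamChunk:
    """One chunk of a CrystFEL stream: a shot plus any indexed crystals."""

    filename: str = ""
    event: object = None
    peaks: np.ndarray = field(default_factory=lambda: np.empty((0, 4)))  # fs ss 1/d I
    crystals: list = field(default_factory=list)
    extra: list = field(default_factory=list)   # unknown lines, preserved verbatim


@dataclass
class StreamCrystal:
    basis: np.ndarray | None = None             # rows a*,b*,c* 1/A
    cell: tuple | None = None                   # a b c (A), al be ga (deg)
    reflections: np.ndarray = field(default_factory=lambda: np.empty((0, 9)))
    # columns: h k l I sigma peak background fs ss


def parse_stream(text_or_path) -> list[StreamChunk]:
    """Parse the subset of a .stream needed for solutions and validation."""
    try:
        with open(text_or_path) as f:
            text = f.read()
    except (OSError, TypeError, ValueError):
        text = text_or_path
    lines = text.splitlines()
    chunks: list[StreamChunk] = []
    i = 0
    n = len(lines)
    while i < n:
        if "Begin chunk" not in lines[i]:
            i += 1
            continue
        chunk = StreamChunk()
        i += 1
        closed = False
        while i < n:
            line = lines[i]
            if "End chunk" in line:
                closed = True
                i += 1
                break
            if line.startswith("Image filename:"):
                chunk.filename = line.split(":", 1)[1].strip()
            elif line.startswith("Event:"):
                chunk.event = _coerce_event(line.split(":", 1)[1].strip().lstrip("/"))
            elif line.startswith("Peaks from peak search"):
                i += 1
                rows = []
                while i < n and "End of peak list" not in lines[i]:
                    tok = lines[i].split()
                    if len(tok) >= 4 and _is_float(tok[0]):
                        rows.append([float(tok[0]), float(tok[1]),
                                     float(tok[2]), float(tok[3])])
                    i += 1
                chunk.peaks = np.array(rows) if rows else np.empty((0, 4))
            elif "Begin crystal" in line:
                crystal = StreamCrystal()
                basis_rows = {}
                i += 1
                while i < n and "End crystal" not in lines[i]:
                    cl = lines[i]
                    if cl.startswith("Cell parameters"):
                        tok = cl.replace("Cell parameters", "").split()
                        nums = [float(t) for t in tok if _is_float(t)]
                        # CrystFEL prints lengths in nm
                        crystal.cell = (nums[0] * 10, nums[1] * 10, nums[2] * 10,
                                        nums[3], nums[4], nums[5])
                    elif cl.split("=")[0].strip() in ("astar", "bstar", "cstar"):
                        name = cl.split("=")[0].strip()
                        nums = [float(t) for t in cl.split("=")[1].split()
                                if _is_float(t)]
                        basis_rows[name] = np.array(nums[:3]) / 10.0  # nm^-1 -> A^-1
                    elif "Reflections measured after indexing" in cl:
                        i += 1
                        rows = []
                        while i < n and "End of reflections" not in lines[i]:
                            tok = lines[i].split()
                            if len(tok) >= 9 and _is_int(tok[0]):
                                rows.append([float(t) for t in tok[:9]])
                            i += 1
                        crystal.reflections = np.array(rows) if rows else np.empty((0, 9))
                    i += 1
                if len(basis_rows) == 3:
                    crystal.basis = np.stack([basis_rows["astar"], basis_rows["bstar"],
                                              basis_rows["cstar"]])
                chunk.crystals.append(crystal)
            else:
                chunk.extra.append(line)
            i += 1
        if not closed:
            raise ValueError(f"truncated stream chunk (index {len(chunks)})")
        chunks.append(chunk)
    return chunks


def _is_float(t):
    try:
        float(t)
        return True
    except ValueError:
        return False


def _is_int(t):
    try:
        int(t)
        return True
    except ValueError:
        return False


def write_stream(chunks, path=None) -> str:
    """Write a minimal .stream (used for fixtures and round-trip tests)."""
    lines = ["CrystFEL stream format 2.3"]
    for ch in chunks:
        lines.append("----- Begin chunk -----")
        lines.append(f"Image filename: {ch.filename}")
        if ch.event is not None:
            lines.append(f"Event: //{ch.event}")
        lines.append("Peaks from peak search")
        lines.append("  fs/px   ss/px (1/d)/nm^-1   Intensity  Panel")
        for fs, ss, invd, inten in ch.peaks:
            lines.append(f" {fs:7.2f} {ss:7.2f} {invd:11.3f} {inten:11.2f}  panel0")
        lines.append("End of peak list")
        for cr in ch.crystals:
            lines.append("--- Begin crystal")
            if cr.cell is not None:
                a, b, c, al, be, ga = cr.cell
                lines.append(f"Cell parameters {a / 10:.5f} {b / 10:.5f} {c / 10:.5f} nm,"
                             f" {al:.2f} {be:.2f} {ga:.2f} deg")
            if cr.basis is not None:
                for name, row in zip(("astar", "bstar", "cstar"), cr.basis):
                    lines.append(f"{name} = {row[0] * 10:+.7f} {row[1] * 10:+.7f} "
                                 f"{row[2] * 10:+.7f} nm^-1")
            lines.append("Reflections measured after indexing")
            lines.append("   h    k    l          I   sigma(I)       peak background"
                         "  fs/px  ss/px panel")
            for r in cr.reflections:
                lines.append(f"{int(r[0]):4d} {int(r[1]):4d} {int(r[2]):4d} "
                             f"{r[3]:10.2f} {r[4]:10.2f} {r[5]:10.2f} {r[6]:10.2f} "
                             f"{r[7]:7.1f} {r[8]:7.1f} panel0")
            lines.append("End of reflections")
            lines.append("--- End crystal")
        lines.append("----- End chunk -----")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as f:
            f.write(text)
    return text


def stream_to_sol(stream, shot_table=None, path=None) -> list[IndexingSolution]:
    """Extract indexing solutions from a stream; optionally write a .sol.

    The beam shift is taken from ``center_x``/``center_y`` columns of the
    matching shot-table row (offset from the detector center) when a shot
    table with ``det_center_x/y`` attrs is given, else 0.
    """
    chunks = parse_stream(stream)
    sols = []
    for ch in chunks:
        for cr in ch.crystals:
            if cr.basis is None:
                continue
            shift = (0.0, 0.0)
            if shot_table is not None and {"center_x", "center_y"} <= set(shot_table.columns):
                sel = shot_table[(shot_table["file"] == ch.filename)
                                 & (shot_table["entry_index"] == ch.event)]
                if len(sel):
                    cx0 = shot_table.attrs.get("det_center_x", 0.0) \
                        if hasattr(shot_table, "attrs") else 0.0
                    cy0 = shot_table.attrs.get("det_center_y", 0.0) \
                        if hasattr(shot_table, "attrs") else 0.0
                    shift = (float(sel.iloc[0]["center_x"]) - cx0,
                             float(sel.iloc[0]["center_y"]) - cy0)
            sols.append(IndexingSolution(file=ch.filename, event=ch.event,
                                         basis=cr.basis, shift=shift))
    if path is not None:
        write_sol(sols, path)
    return sols


# ----------------------------------------------------------------------
# solution broadcasting


def broadcast_solutions(solutions, from_ds, to_ds,
                        keys=("sample", "region_id", "crystal_id")):
    """Assign each target shot the solution of its crystal.

    ``solutions`` must be aligned with ``from_ds`` shots (same order/length,
    as produced by indexing the aggregated dataset).  Matching is by the
    crystal key columns, so the target may use any dose-fraction
    aggregation.  Returns ``(per_target_solutions, unmatched_keys)`` where
    unmatched target shots get ``None``.  Duplicate solutions for one
    crystal are an error.
    """
    keys = list(keys)
    from_keys = list(map(tuple, from_ds.shots[keys].itertuples(index=False, name=None)))
    if len(from_keys) != len(solutions):
        raise ValueError("solutions must align with from_ds shots")
    lookup = {}
    for key, sol in zip(from_keys, solutions):
        if sol is None:
            continue
        if key in lookup and lookup[key] is not sol:
            raise ValueError(f"duplicate solution for crystal key {key}")
        lookup[key] = sol
    out, unmatched = [], []
    for key in map(tuple, to_ds.shots[keys].itertuples(index=False, name=None)):
        sol = lookup.get(key)
        if sol is None:
            unmatched.append(key)
        out.append(sol)
    return out, sorted(set(unmatched))
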