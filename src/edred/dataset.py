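"""Consistent management of image stacks plus shot/crystal/global metadata.

A :class:`Dataset` bundles a *shot table* (one row per detector exposure), a
*feature table* (one row per crystal), an arbitrary number of named N-D data
*stacks* whose dimension 0 is always the shot axis, and hierarchical global
metadata.  Every operation (selection, aggregation, I/O) preserves the
row/stack alignment invariant.  Image stacks can be larger than memory:
stacks loaded from HDF5 are exposed through a lazy h5py-backed wrapper that
reads rows on demand and only materializes on explicit ``compute``/write.

On disk the NeXus-style layout is used, everything under ``/entry``:
``/entry/shots/<column>`` (1-D datasets per shot-table column),
``/entry/map/features/<column>`` (feature table), ``/entry/sample`` and
``/entry/instrument`` metadata trees, ``/entry/data/<stack>`` (N-D, dim 0 =
shots).  Found peaks are stored in CXI style: ``peakXPosRaw``,
``peakYPosRaw``, ``peakTotalIntensity`` (shots x max_peaks, zero-padded) and
``nPeaks``.  List files (.lst) hold one HDF5 path per line, ``#`` comments
allowed.
"""

from __future__ import annotations

import glob as _glob
import os
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .peaks import PeakList

_MANDATORY_SHOT_COLUMNS = ("file", "entry_index", "sample", "region_id",
                           "crystal_id", "frame", "selected")

_ENTRY = "entry"


class SchemaError(ValueError):
    """A file or table violates the dataset schema."""


class QueryError(ValueError):
    """A selection query failed to parse or referenced unknown columns."""


# ----------------------------------------------------------------------
# lazy stacks


class H5Stack:
    """Lazy view onto one or more HDF5 datasets stacked along dim 0.

    Holds ``(path, dataset_name)`` sources and a row map; nothing is read
    until rows are indexed or :meth:`compute` is called.  Row selection
    returns a new lazy view.
    """

    def __init__(self, sources, row_map=None):
        self.sources = list(sources)
        self._shapes = []
        dtype = None
        for path, name in self.sources:
            with h5py.File(path, "r") as f:
                if name not in f:
                    raise SchemaError(f"{path}: missing dataset {name}")
                ds = f[name]
                self._shapes.append(ds.shape)
                dtype = ds.dtype
        inners = {s[1:] for s in self._shapes}
        ndims = {len(s) for s in inners}
        if len(ndims) > 1:
            raise SchemaError(f"inconsistent stack ranks across files: {sorted(inners)}")
        # ragged inner dims (e.g. per-file CXI padding width) are padded with
        # zeros up to the common maximum
        self._inner = tuple(max(s[d] for s in inners)
                            for d in range(ndims.pop())) if inners else ()
        self.dtype = dtype
        if row_map is None:
            rows = []
            for i, s in enumerate(self._shapes):
                rows.append(np.stack([np.full(s[0], i), np.arange(s[0])], axis=1))
            row_map = np.concatenate(rows) if rows else np.empty((0, 2), dtype=int)
        self.row_map = np.asarray(row_map, dtype=int)

    @property
    def shape(self):
        return (len(self.row_map),) + tuple(self._inner)

    def __len__(self):
        return len(self.row_map)

    def select(self, rows) -> "H5Stack":
        return H5Stack(self.sources, row_map=self.row_map[np.asarray(rows)])

    def _place(self, out_row, value):
        if value.shape == out_row.shape:
            out_row[...] = value
        else:
            out_row[...] = 0
            out_row[tuple(slice(0, s) for s in value.shape)] = value

    def compute(self) -> np.ndarray:
        out = np.empty(self.shape, dtype=self.dtype)
        scalar_rows = self._inner == ()
        handles = {}
        try:
            for i, (src, local) in enumerate(self.row_map):
                if src not in handles:
                    handles[src] = h5py.File(self.sources[src][0], "r")
                val = handles[src][self.sources[src][1]][local]
                if scalar_rows:
                    out[i] = val
                else:
                    self._place(out[i], val)
        finally:
            for h in handles.values():
                h.close()
        return out

    def __getitem__(self, item):
        if isinstance(item, (int, np.integer)):
            src, local = self.row_map[item]
            with h5py.File(self.sources[src][0], "r") as f:
                val = f[self.sources[src][1]][local]
            if self._inner == ():
                return val
            out = np.empty(self._inner, dtype=self.dtype)
            self._place(out, val)
            return out
        if isinstance(item, slice):
            return self.select(np.arange(len(self))[item]).compute()
        return self.select(np.asarray(item)).compute()


def _stack_rows(stack, rows):
    if isinstance(stack, H5Stack):
        return stack.select(rows)
    return np.asarray(stack)[np.asarray(rows)]


def _stack_len(stack) -> int:
    return stack.shape[0]


def compute_stack(stack) -> np.ndarray:
    return stack.compute() if isinstance(stack, H5Stack) else np.asarray(stack)


# ----------------------------------------------------------------------


@dataclass
class Dataset:
    """Image stacks + aligned shot/feature metadata tables."""

    shots: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        {c: pd.Series(dtype=object) for c in _MANDATORY_SHOT_COLUMNS}))
    features: pd.DataFrame = field(default_factory=pd.DataFrame)
    stacks: dict = field(default_factory=dict)
    global_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    # -- invariants ----------------------------------------------------

    def validate(self):
        missing = [c for c in _MANDATORY_SHOT_COLUMNS if c not in self.shots.columns]
        if missing:
            raise SchemaError(f"shot table missing mandatory column(s): {missing}")
        n = len(self.shots)
        for name, st in self.stacks.items():
            if _stack_len(st) != n:
                raise SchemaError(
                    f"stack {name!r} has {_stack_len(st)} rows, shot table has {n}")
        if len(self.shots):
            dup = self.shots.duplicated(subset=["file", "entry_index"]).any()
            if dup:
                raise SchemaError("duplicate (file, entry_index) in shot table")

    @property
    def n_shots(self) -> int:
        return len(self.shots)

    def add_stack(self, name: str, data):
        if _stack_len(data) != len(self.shots):
            raise SchemaError(f"stack {name!r} row count does not match shot table")
        self.stacks[name] = data

    # -- selection -----------------------------------------------------

    def get_selection(self, query: str) -> "Dataset":
        """New Dataset with the shots satisfying the query string.

        The grammar is column comparisons (==, !=, <, <=, >, >=) combined
        with and/or and parentheses, evaluated against shot-table columns.
        """
        try:
            sel = self.shots.query(query)
        except Exception as exc:
            raise QueryError(f"cannot evaluate query {query!r}: {exc}") from exc
        rows = self.shots.index.get_indexer(sel.index)
        return self._take(rows)

    def _take(self, rows) -> "Dataset":
        rows = np.asarray(rows)
        shots = self.shots.iloc[rows].reset_index(drop=True)
        stacks = {k: _stack_rows(v, rows) for k, v in self.stacks.items()}
        return Dataset(shots=shots, features=self.features.copy(),
                       stacks=stacks, global_meta=dict(self.global_meta))

    # -- aggregation ---------------------------------------------------

    def aggregate(self, query: str | None = None, by=("sample", "region_id", "crystal_id"),
                  how: str = "sum", frame_range: tuple[int, int] | None = None,
                  stacks: list[str] | None = None) -> "Dataset":
        """Group shots (default: per crystal) and aggregate stacks over frames.

        The query (if any) is applied first, then frames outside
        ``frame_range = [i, j)`` are dropped, then one output shot per group
        is produced with the element-wise ``sum``/``mean``/``first`` of the
        group's stack rows.  Group-constant shot columns are kept; the frame
        range is recorded in ``frame_from``/``frame_to``.  Summing conserves
        total counts.  Empty groups (after the query) are simply absent; a
        ``dropped_groups`` attribute records how many groups vanished.
        """
        if how not in ("sum", "mean", "first"):
            raise ValueError(f"unknown aggregation {how!r}")
        by = list(by)
        for c in by:
            if c not in self.shots.columns:
                raise QueryError(f"unknown grouping column {c!r}")
        ds = self.get_selection(query) if query else self._take(np.arange(self.n_shots))
        groups_before = ds.shots.groupby(by, sort=False).ngroups if len(ds.shots) else 0
        if frame_range is not None:
            i, j = frame_range
            keep = (ds.shots["frame"] >= i) & (ds.shots["frame"] < j)
            ds = ds._take(np.flatnonzero(keep.to_numpy()))
        else:
            i, j = (int(ds.shots["frame"].min()), int(ds.shots["frame"].max()) + 1) \
                if len(ds.shots) else (0, 0)
        if len(ds.shots) == 0:
            raise ValueError("no shots left to aggregate")
        grouped = ds.shots.groupby(by, sort=False)
        dropped = groups_before - grouped.ngroups

        rows_out = []
        stack_rows = []
        for _, idx in grouped.indices.items():
            first = ds.shots.iloc[idx[0]].copy()
            rows_out.append(first)
            stack_rows.append(np.asarray(idx))
        shots = pd.DataFrame(rows_out).reset_index(drop=True)
        shots["frame"] = 0
        shots["frame_from"] = i
        shots["frame_to"] = j
        shots["n_frames_agg"] = [len(r) for r in stack_rows]
        # re-key entries so (file, entry_index) stays unique
        shots["entry_index"] = np.arange(len(shots))

        names = stacks if stacks is not None else list(ds.stacks)
        new_stacks = {}
        for name in names:
            st = ds.stacks[name]
            arrs = []
            for rows in stack_rows:
                block = compute_stack(_stack_rows(st, rows))
                if how == "sum":
                    if block.dtype.kind not in "iufb":
                        raise ValueError(f"cannot sum stack {name!r} of dtype {block.dtype}")
                    arrs.append(block.sum(axis=0))
                elif how == "mean":
                    arrs.append(block.mean(axis=0))
                else:
                    arrs.append(block[0])
            new_stacks[name] = np.stack(arrs)
        out = Dataset(shots=shots, features=self.features.copy(),
                      stacks=new_stacks, global_meta=dict(self.global_meta))
        out.dropped_groups = dropped
        return out

    # -- peak-list helpers --------------------------------------------

    def set_peaks(self, peak_lists, max_peaks: int | None = None):
        """Store per-shot PeakLists as padded CXI stacks."""
        x, y, inten, npk = peaklists_to_cxi(peak_lists, max_peaks=max_peaks)
        self.add_stack("peakXPosRaw", x)
        self.add_stack("peakYPosRaw", y)
        self.add_stack("peakTotalIntensity", inten)
        self.add_stack("nPeaks", npk)

    def get_peaks(self) -> list[PeakList]:
        needed = ("peakXPosRaw", "peakYPosRaw", "peakTotalIntensity", "nPeaks")
        if any(n not in self.stacks for n in needed):
            raise SchemaError("dataset carries no CXI peak stacks")
        return cxi_to_peaklists(*(compute_stack(self.stacks[n]) for n in needed))

    # -- I/O -----------------------------------------------------------

    def write(self, path, split_by: str | None = None, overwrite: bool = False):
        """Write the dataset to HDF5 file(s); returns the list of paths.

        With ``split_by`` (a shot-table column, e.g. ``region_id``) one file
        per distinct value is written, ``<stem>_<value>.h5``.
        """
        if self.n_shots == 0:
            raise ValueError("refusing to write an empty dataset")
        if split_by is None:
            _write_single(self, path, overwrite)
            return [os.fspath(path)]
        paths = []
        stem, ext = os.path.splitext(os.fspath(path))
        for val, idx in self.shots.groupby(split_by, sort=True).indices.items():
            sub = self._take(np.asarray(idx))
            p = f"{stem}_{val}{ext or '.h5'}"
            _write_single(sub, p, overwrite)
            paths.append(p)
        return paths

    def write_virtual_file(self, path, overwrite: bool = False):
        """Write an image-free *virtual* file for indexing.

        Contains only the shot table and the CXI peak arrays, with each
        shot's peaks translated by (detector_center - shot_center) so the
        zero-order beam sits at the detector center for every pattern;
        bookkeeping columns link each virtual entry back to the actual
        (file, entry_index).  Requires ``center_x``/``center_y`` columns and
        peak stacks; shots lacking centers are reported in the error.
        """
        for c in ("center_x", "center_y"):
            if c not in self.shots.columns:
                raise SchemaError(f"virtual file needs shot column {c!r}")
        bad = self.shots.index[~np.isfinite(self.shots["center_x"].to_numpy(float))
                               | ~np.isfinite(self.shots["center_y"].to_numpy(float))]
        if len(bad):
            raise ValueError(f"shots without a valid center: {list(bad[:20])}")
        peaks = self.get_peaks()
        det_shape = self._detector_shape()
        cx0, cy0 = det_shape[1] / 2.0, det_shape[0] / 2.0
        shifted = []
        for pk, (_, row) in zip(peaks, self.shots.iterrows()):
            dx = cx0 - float(row["center_x"])
            dy = cy0 - float(row["center_y"])
            shifted.append(PeakList(x=pk.x + dx, y=pk.y + dy,
                                    intensity=pk.intensity, snr=pk.snr))
        shots = self.shots.copy().reset_index(drop=True)
        shots["orig_file"] = shots["file"]
        shots["orig_entry_index"] = shots["entry_index"]
        shots["entry_index"] = np.arange(len(shots))
        vds = Dataset(shots=shots, features=self.features.copy(),
                      stacks={}, global_meta=dict(self.global_meta))
        vds.set_peaks(shifted)
        _write_single(vds, path, overwrite)
        return os.fspath(path)

    def _detector_shape(self):
        for name in ("data", "raw_counts", "corrected"):
            if name in self.stacks:
                return self.stacks[name].shape[1:]
        meta = next(iter(self.global_meta.values()), {})
        shape = meta.get("instrument/detector/shape")
        if shape is not None:
            return tuple(int(v) for v in shape)
        raise SchemaError("cannot infer detector shape (no image stack)")


# ----------------------------------------------------------------------
# HDF5 writing / loading


def _write_table(group: h5py.Group, df: pd.DataFrame):
    for col in df.columns:
        vals = df[col].to_numpy()
        if vals.dtype == object or vals.dtype.kind in "US":
            data = np.array([str(v) for v in vals], dtype=h5py.string_dtype("utf-8"))
            group.create_dataset(col, data=data)
        else:
            group.create_dataset(col, data=vals)


def _read_table(group: h5py.Group) -> pd.DataFrame:
    cols = {}
    for name, ds in group.items():
        arr = ds[()]
        if arr.dtype.kind in ("O", "S"):
            arr = np.array([v.decode() if isinstance(v, bytes) else str(v) for v in arr])
        cols[name] = arr
    return pd.DataFrame(cols)


def _write_meta(group: h5py.Group, meta: dict):
    for key, val in meta.items():
        parts = key.split("/")
        g = group
        for p in parts[:-1]:
            g = g.require_group(p)
        if isinstance(val, str):
            g.create_dataset(parts[-1], data=np.array(val, dtype=h5py.string_dtype("utf-8")))
        else:
            g.create_dataset(parts[-1], data=val)


def _read_meta(group: h5py.Group, prefix: str = "") -> dict:
    out = {}
    for name, item in group.items():
        key = f"{prefix}{name}"
        if isinstance(item, h5py.Group):
            out.update(_read_meta(item, prefix=key + "/"))
        else:
            val = item[()]
            if isinstance(val, bytes):
                val = val.decode()
            out[key] = val
    return out


def _write_single(ds: Dataset, path, overwrite: bool):
    path = os.fspath(path)
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    shots = ds.shots.copy().reset_index(drop=True)
    shots["file"] = path
    shots["entry_index"] = np.arange(len(shots))
    with h5py.File(path, "w") as f:
        entry = f.create_group(_ENTRY)
        entry.attrs["NX_class"] = "NXentry"
        _write_table(entry.create_group("shots"), shots)
        if len(ds.features):
            _write_table(entry.require_group("map").create_group("features"), ds.features)
        data = entry.create_group("data")
        data.attrs["NX_class"] = "NXdata"
        for name, st in ds.stacks.items():
            data.create_dataset(name, data=compute_stack(st))
        meta = next(iter(ds.global_meta.values()), {}) if ds.global_meta else {}
        inst = {k.split("instrument/", 1)[1]: v for k, v in meta.items()
                if k.startswith("instrument/")}
        samp = {k.split("sample/", 1)[1]: v for k, v in meta.items()
                if k.startswith("sample/")}
        if inst:
            _write_meta(entry.create_group("instrument"), inst)
        if samp:
            _write_meta(entry.create_group("sample"), samp)


def write_list(paths, list_path):
    """Write a .lst file: one HDF5 path per line."""
    with open(list_path, "w") as f:
        f.write("# edred file list\n")
        for p in paths:
            f.write(os.fspath(p) + "\n")
    return os.fspath(list_path)


def read_list(list_path) -> list[str]:
    out = []
    with open(list_path) as f:
        for line in f:
            line = line.split("#")[0].strip()
            if line:
                out.append(line)
    return out


def load_dataset(source) -> Dataset:
    """Load a Dataset from a file path, a .lst file, or a wildcard pattern.

    Tables are concatenated in listed order; image stacks are exposed
    lazily (no pixel data is read here).  Per-file global metadata is kept
    under ``global_meta[path]``.
    """
    if isinstance(source, (list, tuple)):
        files = [os.fspath(p) for p in source]
    else:
        source = os.fspath(source)
        if source.endswith(".lst"):
            files = read_list(source)
        elif any(ch in source for ch in "*?["):
            files = sorted(_glob.glob(source))
        else:
            files = [source]
    if not files:
        raise FileNotFoundError(f"no input files match {source!r}")
    for p in files:
        if not os.path.exists(p):
            raise FileNotFoundError(p)

    tables, feats, metas = [], [], {}
    stack_names = None
    for p in files:
        with h5py.File(p, "r") as f:
            if _ENTRY not in f or "shots" not in f[_ENTRY]:
                raise SchemaError(f"{p}: missing /entry/shots group")
            t = _read_table(f[f"{_ENTRY}/shots"])
            missing = [c for c in _MANDATORY_SHOT_COLUMNS if c not in t.columns]
            if missing:
                raise SchemaError(f"{p}: shot table missing column(s) {missing}")
            t["file"] = p
            tables.append(t)
            if f"{_ENTRY}/map/features" in f:
                feats.append(_read_table(f[f"{_ENTRY}/map/features"]))
            meta = {}
            for top in ("instrument", "sample"):
                if f"{_ENTRY}/{top}" in f:
                    meta.update(_read_meta(f[f"{_ENTRY}/{top}"], prefix=top + "/"))
            metas[p] = meta
            names = set(f[f"{_ENTRY}/data"].keys()) if f"{_ENTRY}/data" in f else set()
        if stack_names is None:
            stack_names = names
        elif names != stack_names:
            raise SchemaError(f"{p}: stack names differ from first file")

    shots = pd.concat(tables, ignore_index=True)
    features = pd.concat(feats, ignore_index=True).drop_duplicates() if feats else pd.DataFrame()
    stacks = {name: H5Stack([(p, f"{_ENTRY}/data/{name}") for p in files])
              for name in (stack_names or ())}
    for name, st in stacks.items():
        if len(st) != len(shots):
            raise SchemaError(f"stack {name!r} rows ({len(st)}) != shot rows ({len(shots)})")
    if "selected" in shots.columns:
        shots["selected"] = shots["selected"].astype(bool)
    return Dataset(shots=shots, features=features, stacks=stacks, global_meta=metas)


# ----------------------------------------------------------------------
# CXI peak arrays


def peaklists_to_cxi(peak_lists, max_peaks: int | None = None):
    n = len(peak_lists)
    if max_peaks is None:
        max_peaks = max((len(p) for p in peak_lists), default=0) or 1
    x = np.zeros((n, max_peaks))
    y = np.zeros((n, max_peaks))
    inten = np.zeros((n, max_peaks))
    npk = np.zeros(n, dtype=int)
    for i, p in enumerate(peak_lists):
        m = min(len(p), max_peaks)
        x[i, :m] = p.x[:m]
        y[i, :m] = p.y[:m]
        inten[i, :m] = p.intensity[:m]
        npk[i] = m
    return x, y, inten, npk


def cxi_to_peaklists(x, y, intensity, n_peaks) -> list[PeakList]:
    out = []
    for i in range(len(n_peaks)):
        m = int(n_peaks[i])
        out.append(PeakList(x=x[i, :m], y=y[i, :m], intensity=intensity[i, :m],
                            snr=np.zeros(m)))
    return out
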