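"""Symmetry reduction, Monte-Carlo merging and validation statistics.

The many observations of each Bragg reflection collected over hundreds of
crystals are combined per symmetry-unique reflection — in the simplest case
by plain unweighted averaging (the "Monte-Carlo" method), optionally after
iterative global or resolution-dependent per-crystal scaling.  Data quality
is validated with the half-set correlation CC1/2 (crystals split into two
random halves, merged independently, Pearson-correlated per resolution
shell), its estimate of correlation to the true signal
CC* = sqrt(2 CC1/2 / (1 + CC1/2)), completeness against the expected
symmetry-unique reflection count, redundancy, R_split and mean I/sigma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cell import UnitCell, enumerate_lattice

# ----------------------------------------------------------------------
# point groups

_R4Z = np.array([[0, 1, 0], [-1, 0, 0], [0, 0, 1]])
_R2Z = np.diag([-1, -1, 1])
_R2X = np.diag([1, -1, -1])
_R2Y = np.diag([-1, 1, -1])
_R3_111 = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]])
_R3Z_HEX = np.array([[0, 1, 0], [-1, -1, 0], [0, 0, 1]])
_R2_110_HEX = np.array([[0, 1, 0], [1, 0, 0], [0, 0, -1]])

_GENERATORS: dict[str, list[np.ndarray]] = {
    "1": [],
    "2": [_R2Z],
    "222": [_R2Z, _R2X],
    "4": [_R4Z],
    "422": [_R4Z, _R2X],
    "3": [_R3Z_HEX],
    "32": [_R3Z_HEX, _R2_110_HEX],
    "6": [_R3Z_HEX, _R2Z],
    "622": [_R3Z_HEX, _R2Z, _R2_110_HEX],
    "23": [_R2Z, _R2Y, _R3_111],
    "432": [_R2Z, _R2Y, _R3_111, _R4Z],
}


@dataclass
class PointGroup:
    """A (rotational) point group acting on Miller indices.

    Operators are integer 3x3 matrices acting on (h, k, l) row vectors;
    the set is generated by closure from the named generators and always
    contains the identity.  ``friedel=True`` adds the inversion, i.e. the
    Laue group used for merging (the default for still electron data).
    """

    name: str
    friedel: bool = True
    operators: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if self.name not in _GENERATORS:
            raise ValueError(f"unknown point group {self.name!r}; "
                             f"known: {sorted(_GENERATORS)}")
        gens = [np.eye(3, dtype=int)] + [g.astype(int) for g in _GENERATORS[self.name]]
        if self.friedel:
            gens.append(-np.eye(3, dtype=int))
        ops = {tuple(np.eye(3, dtype=int).ravel())}
        frontier = list(ops)
        # closure under composition
        changed = True
        mats = [np.array(t).reshape(3, 3) for t in ops]
        while changed:
            changed = False
            for g in gens:
                for m in list(mats):
                    prod = m @ g
                    key = tuple(prod.ravel())
                    if key not in ops:
                        ops.add(key)
                        mats.append(prod)
                        changed = True
        self.operators = np.array(mats)

    @property
    def order(self) -> int:
        return len(self.operators)

    def orbit(self, hkl) -> np.ndarray:
        """All distinct images of one Miller triple."""
        hkl = np.asarray(hkl, dtype=int)
        images = np.einsum("j,njk->nk", hkl, self.operators)
        return np.unique(images, axis=0)


def map_to_asu(hkl, pg: PointGroup) -> np.ndarray:
    """Map Miller indices to their asymmetric-unit representative.

    The representative is the lexicographically maximal image of (h, k, l)
    under all point-group operators (plus inversion if the Friedel flag is
    set) — deterministic and idempotent by construction.
    """
    hkl = np.atleast_2d(np.asarray(hkl, dtype=int))
    images = np.einsum("mj,njk->nmk", hkl, pg.operators)  # (n_ops, n_hkl, 3)
    # lexicographic maximum over the operator axis
    best = images[0]
    for i in range(1, images.shape[0]):
        cand = images[i]
        better = (
            (cand[:, 0] > best[:, 0])
            | ((cand[:, 0] == best[:, 0]) & (cand[:, 1] > best[:, 1]))
            | ((cand[:, 0] == best[:, 0]) & (cand[:, 1] == best[:, 1]) & (cand[:, 2] > best[:, 2]))
        )
        best = np.where(better[:, None], cand, best)
    return best


# ----------------------------------------------------------------------
# merging


def _asu_frame(observations: pd.DataFrame, pg: PointGroup) -> pd.DataFrame:
    df = observations.copy()
    asu = map_to_asu(df[["h", "k", "l"]].to_numpy(), pg)
    df[["h", "k", "l"]] = asu
    return df


def _plain_merge(df: pd.DataFrame) -> pd.DataFrame:
    grp = df.groupby(["h", "k", "l"], sort=True)
    merged = grp.agg(intensity=("intensity", "mean"),
                     n_obs=("intensity", "size"),
                     _std=("intensity", "std"),
                     _sig1=("sigma", "first")).reset_index()
    sem = merged["_std"] / np.sqrt(merged["n_obs"])
    merged["sigma"] = np.where(merged["n_obs"] >= 2, sem.fillna(0.0), merged["_sig1"])
    return merged.drop(columns=["_std", "_sig1"])


def merge_mc(observations: pd.DataFrame, pg: PointGroup, scaling: str = "none",
             n_cycles: int = 3, cell: UnitCell | None = None) -> pd.DataFrame:
    """Monte-Carlo merging with optional per-crystal scaling.

    ``observations`` needs columns h, k, l, intensity, sigma and (for
    scaling) crystal.  ``scaling`` is ``"none"`` (unweighted mean per unique
    reflection), ``"global"`` (iterate: per-crystal scale
    ``k_c = sum(I_ref I_obs) / sum(I_obs^2)`` against the current merged
    reference, re-merge) or ``"resolution"`` (per-crystal (k_c, B_c) from the
    log-linear model ``log(I_ref / I_obs) = log k_c + B_c q^2 / 2``, which
    needs ``cell`` for q = 1/d).  Returns a frame with one row per unique
    hkl: intensity (mean), sigma (standard error; for n=1 the integration
    sigma), n_obs.
    """
    if len(observations) == 0:
        raise ValueError("no observations to merge")
    if scaling not in ("none", "global", "resolution"):
        raise ValueError(f"unknown scaling mode {scaling!r}")
    df = _asu_frame(observations, pg)
    if scaling == "none":
        return _plain_merge(df)
    if "crystal" not in df.columns:
        raise ValueError("scaling requires a 'crystal' column")
    if scaling == "resolution":
        if cell is None:
            raise ValueError("resolution-dependent scaling requires the unit cell")
        df["_q"] = cell.one_over_d(df[["h", "k", "l"]].to_numpy())

    work = df.copy()
    for _ in range(n_cycles):
        ref = _plain_merge(work).set_index(["h", "k", "l"])["intensity"]
        iref = ref.reindex(pd.MultiIndex.from_frame(work[["h", "k", "l"]])).to_numpy()
        scales = np.ones(len(work))
        for cid, idx in work.groupby("crystal").groups.items():
            sub = work.loc[idx]
            ir = iref[work.index.get_indexer(idx)]
            ok = np.isfinite(ir)
            if scaling == "global":
                denom = float(np.sum(sub["intensity"].to_numpy()[ok] ** 2))
                if denom <= 0:
                    continue
                k_c = float(np.sum(ir[ok] * sub["intensity"].to_numpy()[ok])) / denom
                if k_c > 0:
                    scales[work.index.get_indexer(idx)] = k_c
            else:
                iobs = sub["intensity"].to_numpy()
                pos = ok & (ir > 0) & (iobs > 0)
                if pos.sum() < 3:
                    continue
                yv = np.log(ir[pos] / iobs[pos])
                x = sub["_q"].to_numpy()[pos] ** 2 / 2.0
                design = np.column_stack([np.ones_like(x), x])
                coef, *_ = np.linalg.lstsq(design, yv, rcond=None)
                logk, b_c = coef
                scales[work.index.get_indexer(idx)] = np.exp(
                    logk + b_c * sub["_q"].to_numpy() ** 2 / 2.0)
        work = work.copy()
        work["intensity"] = work["intensity"] * scales
        work["sigma"] = work["sigma"] * scales
        # fix the overall scale: mean crystal scale -> 1
        norm = float(np.mean(scales))
        if norm > 0:
            work["intensity"] /= norm
            work["sigma"] /= norm
    out = _plain_merge(work.drop(columns=[c for c in ("_q",) if c in work]))
    return out


# ----------------------------------------------------------------------
# shells and statistics


def make_shells(q_values: np.ndarray, n_shells: int = 10) -> np.ndarray:
    """Shell edges in 1/d with (approximately) equal unique counts per shell."""
    q = np.sort(np.asarray(q_values, dtype=float))
    if q.size == 0:
        raise ValueError("no reflections to shell")
    quantiles = np.linspace(0, 1, n_shells + 1)
    edges = np.quantile(q, quantiles)
    edges[0] = max(edges[0] - 1e-9, 0.0)
    edges[-1] += 1e-9
    return np.unique(edges)


def cc_star(cc_half_value):
    """CC* = sqrt(2 CC1/2 / (1 + CC1/2)); defined for CC1/2 > -1/3."""
    cc = np.asarray(cc_half_value, dtype=float)
    valid = cc > -1.0 / 3.0
    with np.errstate(invalid="ignore", divide="ignore"):
        arg = 2 * cc / (1 + cc)
        # signed extension for slightly negative CC1/2 (argument negative there)
        out = np.sign(arg) * np.sqrt(np.abs(arg))
    out = np.where(valid, out, np.nan)
    return out if out.shape else float(out)


def split_half_sets(observations: pd.DataFrame, split_seed: int = 0):
    """Split observations into two halves by *crystal* (seeded)."""
    crystals = observations["crystal"].unique()
    if len(crystals) < 2:
        raise ValueError("need at least 2 crystals for a half-set split")
    rng = np.random.default_rng(split_seed)
    perm = rng.permutation(len(crystals))
    half_a = set(crystals[perm[: len(crystals) // 2]])
    in_a = observations["crystal"].isin(half_a)
    return observations[in_a], observations[~in_a]


def cc_half(observations: pd.DataFrame, pg: PointGroup, cell: UnitCell,
            shells: np.ndarray | int = 10, split_seed: int = 0,
            scaling: str = "none") -> pd.DataFrame:
    """Per-shell and overall half-set correlation CC1/2 (and CC*).

    Crystals are split randomly into two halves, each half merged
    independently (unscaled by default), and the Pearson correlation of the
    two merged intensity sets computed over the unique reflections common to
    both, per resolution shell.  Shells with fewer than 3 common uniques are
    flagged with NaN.
    """
    a, b = split_half_sets(observations, split_seed)
    ma = merge_mc(a, pg, scaling=scaling, cell=cell).set_index(["h", "k", "l"])
    mb = merge_mc(b, pg, scaling=scaling, cell=cell).set_index(["h", "k", "l"])
    common = ma.index.intersection(mb.index)
    ia = ma.loc[common, "intensity"].to_numpy()
    ib = mb.loc[common, "intensity"].to_numpy()
    q = cell.one_over_d(np.array(list(common)))
    if isinstance(shells, int):
        shells = make_shells(q, shells)
    rows = []
    for lo, hi in zip(shells[:-1], shells[1:]):
        sel = (q >= lo) & (q < hi)
        if sel.sum() < 3:
            cc = np.nan
        else:
            cc = float(np.corrcoef(ia[sel], ib[sel])[0, 1])
        rows.append({"q_lo": lo, "q_hi": hi, "n_common": int(sel.sum()),
                     "cc_half": cc, "cc_star": cc_star(cc) if np.isfinite(cc) else np.nan})
    overall = float(np.corrcoef(ia, ib)[0, 1]) if len(common) >= 3 else np.nan
    stats = pd.DataFrame(rows)
    stats.attrs["overall_cc_half"] = overall
    stats.attrs["overall_cc_star"] = cc_star(overall) if np.isfinite(overall) else np.nan
    stats.attrs["split_seed"] = split_seed
    return stats


def r_split(half_a: pd.DataFrame, half_b: pd.DataFrame) -> float:
    """R_split = 2^-1/2 sum|I1 - I2| / (1/2 sum(I1 + I2)) over common uniques."""
    a = half_a.set_index(["h", "k", "l"])["intensity"]
    b = half_b.set_index(["h", "k", "l"])["intensity"]
    common = a.index.intersection(b.index)
    i1, i2 = a.loc[common].to_numpy(), b.loc[common].to_numpy()
    denom = 0.5 * np.sum(i1 + i2)
    if denom == 0:
        return np.nan
    return float(np.sum(np.abs(i1 - i2)) / (np.sqrt(2.0) * denom))


def mean_i_over_sigma(merged: pd.DataFrame) -> float:
    sig = merged["sigma"].to_numpy()
    ok = sig > 0
    if not ok.any():
        return np.nan
    return float(np.mean(merged["intensity"].to_numpy()[ok] / sig[ok]))


def expected_uniques(cell: UnitCell, pg: PointGroup, dmin: float,
                     qmin: float = 0.0) -> np.ndarray:
    """All expected asymmetric-unit reflections with qmin < 1/d <= 1/dmin."""
    hkl, q = enumerate_lattice(cell, dmin)
    sel = q > qmin
    asu = map_to_asu(hkl[sel], pg)
    return np.unique(asu, axis=0)


def completeness_redundancy(merged: pd.DataFrame, cell: UnitCell, pg: PointGroup,
                            dmin: float, qmin: float = 0.0,
                            shells: np.ndarray | int = 10) -> pd.DataFrame:
    """Per-shell and overall completeness (%) and redundancy.

    Expected uniques come from brute-force lattice enumeration (centering
    absences removed) mapped to the asymmetric unit; completeness is
    100 x observed / expected, redundancy the mean n_obs over observed
    uniques in the shell.
    """
    exp = expected_uniques(cell, pg, dmin, qmin=qmin)
    q_exp = cell.one_over_d(exp)
    obs_idx = pd.MultiIndex.from_frame(merged[["h", "k", "l"]])
    exp_idx = pd.MultiIndex.from_arrays([exp[:, 0], exp[:, 1], exp[:, 2]])
    n_obs = merged.set_index(["h", "k", "l"])["n_obs"]
    if isinstance(shells, int):
        shells = make_shells(q_exp, shells)
    rows = []
    observed_mask = exp_idx.isin(obs_idx)
    for lo, hi in zip(shells[:-1], shells[1:]):
        sel = (q_exp >= lo) & (q_exp < hi)
        n_exp = int(sel.sum())
        got = exp_idx[sel & observed_mask]
        n_got = len(got)
        red = float(n_obs.loc[got].mean()) if n_got else np.nan
        rows.append({"q_lo": lo, "q_hi": hi, "n_expected": n_exp, "n_observed": n_got,
                     "completeness": 100.0 * n_got / n_exp if n_exp else np.nan,
                     "redundancy": red})
    stats = pd.DataFrame(rows)
    n_exp_all = len(exp_idx)
    n_got_all = int(observed_mask.sum())
    stats.attrs["overall_completeness"] = 100.0 * n_got_all / n_exp_all if n_exp_all else np.nan
    got_all = exp_idx[observed_mask]
    stats.attrs["overall_redundancy"] = float(n_obs.loc[got_all].mean()) if n_got_all else np.nan
    return stats


# ----------------------------------------------------------------------
# .hkl interop (CrystFEL-style reflection list)


def write_hkl(merged: pd.DataFrame, path=None, symmetry: str = "unknown") -> str:
    """Write merged intensities as a CrystFEL-style .hkl reflection list."""
    if len(merged) == 0:
        raise ValueError("refusing to write an empty reflection list")
    df = merged.sort_values(["h", "k", "l"])
    lines = ["CrystFEL reflection list version 2.0",
             f"Symmetry: {symmetry}",
             "   h    k    l          I    phase   sigma(I)   nmeas"]
    for _, row in df.iterrows():
        lines.append(f"{int(row.h):4d} {int(row.k):4d} {int(row.l):4d} "
                     f"{row.intensity:10.2f}        - {row.sigma:10.2f} {int(row.n_obs):8d}")
    lines.append("End of reflections")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as f:
            f.write(text)
    return text


def read_hkl(text_or_path) -> pd.DataFrame:
    """Read a .hkl file written by :func:`write_hkl`."""
    try:
        with open(text_or_path) as f:
            text = f.read()
    except (OSError, TypeError):
        text = text_or_path
    rows = []
    in_body = False
    for line in text.splitlines():
        if line.startswith("   h "):
            in_body = True
            continue
        if line.startswith("End of reflections"):
            break
        if not in_body or not line.strip():
            continue
        tok = line.split()
        rows.append({"h": int(tok[0]), "k": int(tok[1]), "l": int(tok[2]),
                     "intensity": float(tok[3]), "sigma": float(tok[5]),
                     "n_obs": int(tok[6])})
    return pd.DataFrame(rows)
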