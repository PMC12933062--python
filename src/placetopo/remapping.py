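"""Global remapping across environments and pairwise-relation survival.

Hippocampal place cells re-randomize their firing locations between
distinct environments (global remapping) while re-expressing the same
map on re-exposure (A–A′). These operations quantify that at the cell
level (map correlation, center-of-mass shift, vs random-cell controls)
and at the pair level (the change Δd in pairwise field distance between
environments, Levene's variance test across A–A′ / A–B / A–RandomA′),
and ask whether any pairwise relation that survives remapping is
anatomically organized.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist

from .core import DataError, ParameterError
from . import topography as tp
from . import tuning as tn

__all__ = [
    "cross_session_cell_stats",
    "rotation_control",
    "pairwise_distance_difference",
    "remap_vs_anatomy",
]


def cross_session_cell_stats(
    maps_a: list,
    maps_b: list,
    maps_a2: list | None = None,
    *,
    cell_ids: np.ndarray | None = None,
    n_ctrl: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-cell cross-session map correlation and center-of-mass shift.

    Rows are cells qualifying in both environments (the caller passes
    matched map lists). Controls pair each cell's A map with the map of
    a random *other* cell, ``n_ctrl`` iterations; columns ``r_ab``,
    ``r_aa2``, ``r_ctrl_a`` (mean over iterations), ``com_shift_ab``,
    ``com_shift_aa2`` (cm), ``com_shift_ctrl``.
    """
    n = len(maps_a)
    if len(maps_b) != n or (maps_a2 is not None and len(maps_a2) != n):
        raise DataError("map lists must be matched per cell")
    if n == 0:
        return pd.DataFrame()
    if cell_ids is None:
        cell_ids = np.arange(n)
    rng = np.random.default_rng(seed)

    def safe_corr(m1, m2):
        try:
            return tn.map_correlation(m1, m2)
        except DataError:
            return np.nan

    coms_a = np.array([tn.center_of_mass(m) for m in maps_a])
    coms_b = np.array([tn.center_of_mass(m) for m in maps_b])
    coms_a2 = np.array([tn.center_of_mass(m) for m in maps_a2]) if maps_a2 else None

    rows = []
    for i in range(n):
        r_ab = safe_corr(maps_a[i], maps_b[i])
        row = {
            "cell_id": cell_ids[i],
            "r_ab": r_ab,
            "com_shift_ab": float(np.hypot(*(coms_a[i] - coms_b[i]))),
        }
        if maps_a2 is not None:
            row["r_aa2"] = safe_corr(maps_a[i], maps_a2[i])
            row["com_shift_aa2"] = float(np.hypot(*(coms_a[i] - coms_a2[i])))
        if n > 1:
            others = [j for j in range(n) if j != i]
            picks = rng.choice(others, size=n_ctrl, replace=True)
            rs = [safe_corr(maps_a[i], maps_a[j]) for j in picks]
            row["r_ctrl_a"] = float(np.nanmean(rs))
            row["com_shift_ctrl"] = float(
                np.mean([np.hypot(*(coms_a[i] - coms_a[j])) for j in picks])
            )
        rows.append(row)
    return pd.DataFrame(rows)


def rotation_control(map_a: tn.TuningMap, map_b: tn.TuningMap) -> pd.DataFrame:
    """Correlation of A against B rotated by 0°, 90°, 180°, 270°.

    Guards against 'remapping' that is a mere rigid rotation of the same
    map. Returns one row per rotation with the argmax flagged.
    """
    if map_a.rate.shape[0] != map_a.rate.shape[1]:
        raise DataError("rotation control needs square maps")
    if map_a.rate.shape != map_b.rate.shape:
        raise DataError("maps must share geometry")
    rows = []
    for k, deg in enumerate((0, 90, 180, 270)):
        rot = tn.TuningMap(
            rate=np.rot90(map_b.rate, k),
            occupancy=np.rot90(map_b.occupancy, k),
            visited_mask=np.rot90(map_b.visited_mask, k),
            bin_size=map_b.bin_size,
            smoothing_sigma=map_b.smoothing_sigma,
        )
        try:
            r = tn.map_correlation(map_a, rot)
        except DataError:
            r = np.nan
        rows.append({"rotation_deg": deg, "r": r})
    df = pd.DataFrame(rows)
    df["is_best"] = df["r"] == df["r"].max()
    return df


def pairwise_distance_difference(
    fields_a: np.ndarray,
    fields_b: np.ndarray,
    fields_a2: np.ndarray,
    *,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Signed per-pair change in main-field distance across sessions.

    For every unordered cell pair (cells with a main field in all three
    sessions), Δd(A,X) = d_A(i,j) − d_X(i,j). The A–RandomA′ group
    shuffles the A′ cell identities before recomputing pair distances.
    Returns the pair table and a Brown–Forsythe (median-centered Levene)
    test across the three groups.
    """
    fields_a = np.asarray(fields_a, dtype=float)
    fields_b = np.asarray(fields_b, dtype=float)
    fields_a2 = np.asarray(fields_a2, dtype=float)
    n = len(fields_a)
    if n < 2:
        raise ParameterError("need at least 2 cells with fields in all sessions")
    rng = np.random.default_rng(seed)
    d_a = pdist(fields_a)
    d_b = pdist(fields_b)
    d_a2 = pdist(fields_a2)
    d_rand = pdist(fields_a2[rng.permutation(n)])
    table = pd.DataFrame(
        {
            "dd_aa2": d_a - d_a2,
            "dd_ab": d_a - d_b,
            "dd_a_rand": d_a - d_rand,
        }
    )
    stat, p = sps.levene(
        table["dd_aa2"], table["dd_ab"], table["dd_a_rand"], center="median"
    )
    test = {
        "levene_F": float(stat),
        "p_value": float(p),
        "var_aa2": float(np.var(table["dd_aa2"], ddof=1)),
        "var_ab": float(np.var(table["dd_ab"], ddof=1)),
        "var_a_rand": float(np.var(table["dd_a_rand"], ddof=1)),
    }
    return table, test


def remap_vs_anatomy(
    anatomical_xy: np.ndarray,
    dd_ab: np.ndarray,
    *,
    radii: np.ndarray | None = None,
    n_iter: int = 200,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> dict:
    """Is the pairwise remapping change anatomically organized?

    ``dd_ab`` is the signed per-pair Δd(A,B) in condensed (pdist) order
    over the same cells as ``anatomical_xy``. Computes the kNN MI
    between anatomical distance and |Δd|, and an expanding-circle
    profile of |Δd| with size-matched controls.
    """
    anatomical_xy = np.asarray(anatomical_xy, dtype=float)
    dd_ab = np.asarray(dd_ab, dtype=float)
    ad = pdist(anatomical_xy)
    if dd_ab.shape != ad.shape:
        raise DataError("dd_ab must be in condensed pair order over the same cells")
    abs_dd = np.abs(dd_ab)
    mi = tp.mutual_information_continuous(ad, abs_dd, seed=seed)
    n = len(anatomical_xy)
    from scipy.spatial.distance import squareform

    profile = tp.expanding_circle_profile(
        anatomical_xy,
        squareform(abs_dd),
        radii,
        n_iter=n_iter,
        n_boot=n_boot,
        seed=seed,
    )
    return {"mi": mi, "profile": profile}
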