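"""The anatomical-clustering test battery.

Given classified place cells with soma centroids (µm, FOV coordinates)
and main-field centroids (cm, arena coordinates), these operations ask
one question from several angles: are anatomically nearby cells more
functionally similar than chance?

* pairwise tables of anatomical distance vs field distance / map
  correlation, plus a continuous mutual-information estimate;
* ~45 µm anatomical binning with size-matched random controls and
  bootstrap confidence intervals;
* global and local Moran's I with permutation nulls;
* expanding-circle neighborhood profiles (anatomy → function and
  function → anatomy);
* Cliff's delta effect sizes and nearest-neighbor comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core import DataError, DegenerateInputError, ParameterError

__all__ = [
    "MoranResult",
    "build_pair_table",
    "mutual_information_continuous",
    "assign_anatomical_bins",
    "within_bin_similarity",
    "size_matched_control",
    "bootstrap_median_ci",
    "spatial_weights",
    "global_morans_i",
    "local_morans_i",
    "expanding_circle_profile",
    "fieldspace_profile",
    "cliffs_delta",
    "nearest_neighbor_analysis",
]


# ---------------------------------------------------------------------------
# pair tables
# ---------------------------------------------------------------------------

def build_pair_table(
    anatomical_xy: np.ndarray,
    field_xy: np.ndarray,
    maps: list | None = None,
    *,
    cell_ids: np.ndarray | None = None,
    dff: np.ndarray | None = None,
) -> pd.DataFrame:
    """All unordered cell pairs with distances in both spaces.

    Columns: cell_i, cell_j, anatomical_distance (µm), field_distance
    (cm), and map_correlation / dff_correlation when maps or traces are
    supplied. Pooling across environments is a row-wise concat by the
    caller.
    """
    anatomical_xy = np.asarray(anatomical_xy, dtype=float)
    field_xy = np.asarray(field_xy, dtype=float)
    n = len(anatomical_xy)
    if cell_ids is None:
        cell_ids = np.arange(n)
    if n < 2:
        return pd.DataFrame(
            columns=["cell_i", "cell_j", "anatomical_distance", "field_distance"]
        )
    ii, jj = np.triu_indices(n, k=1)
    out = pd.DataFrame(
        {
            "cell_i": np.asarray(cell_ids)[ii],
            "cell_j": np.asarray(cell_ids)[jj],
            "anatomical_distance": pdist(anatomical_xy),
            "field_distance": pdist(field_xy),
        }
    )
    if maps is not None:
        out["map_correlation"] = pairwise_map_correlations(maps)[ii, jj]
    if dff is not None:
        out["dff_correlation"] = np.corrcoef(np.asarray(dff))[ii, jj]
    return out


def pairwise_map_correlations(maps: list) -> np.ndarray:
    """Dense matrix of pairwise tuning-map Pearson correlations.

    Fast path: when every map shares one visited mask the correlations
    reduce to ``np.corrcoef`` of the flattened rate vectors; otherwise
    falls back to per-pair common-mask correlation.
    """
    from . import tuning as tn

    masks = [m.visited_mask for m in maps]
    if all(np.array_equal(masks[0], mk) for mk in masks[1:]):
        flat = np.array([m.rate[masks[0]] for m in maps])
        with np.errstate(invalid="ignore"):
            return np.corrcoef(flat)
    n = len(maps)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                r = tn.map_correlation(maps[i], maps[j])
            except DataError:
                r = np.nan
            out[i, j] = out[j, i] = r
    return out


# ---------------------------------------------------------------------------
# mutual information
# ---------------------------------------------------------------------------

def mutual_information_continuous(
    x: np.ndarray,
    y: np.ndarray,
    *,
    k: int = 3,
    seed: int | None = 0,
) -> float:
    """Kraskov k-nearest-neighbor MI estimate (nats) for two continuous
    variables. Negative estimates are clamped to 0; constant input gives
    0 (degenerate)."""
    from sklearn.feature_selection import mutual_info_regression

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be equal-length 1D samples")
    if x.size < 100:
        raise ParameterError("MI estimation needs n >= 100 paired samples")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return 0.0
    mi = mutual_info_regression(
        x.reshape(-1, 1), y, n_neighbors=k, random_state=seed
    )[0]
    return float(max(mi, 0.0))


def mutual_information_binned(x, y, bins: int = 16) -> float:
    """Equal-frequency binned MI (nats); cross-check for the kNN path."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    qx = np.quantile(x, np.linspace(0, 1, bins + 1))
    qy = np.quantile(y, np.linspace(0, 1, bins + 1))
    cx = np.clip(np.searchsorted(qx[1:-1], x), 0, bins - 1)
    cy = np.clip(np.searchsorted(qy[1:-1], y), 0, bins - 1)
    joint = np.zeros((bins, bins))
    np.add.at(joint, (cx, cy), 1.0)
    joint /= joint.sum()
    px = joint.sum(1, keepdims=True)
    py = joint.sum(0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / (px @ py)[nz])).sum())


# ---------------------------------------------------------------------------
# anatomical binning + size-matched controls
# ---------------------------------------------------------------------------

def assign_anatomical_bins(
    anatomical_xy: np.ndarray,
    fov_width: float = 350.0,
    fov_height: float = 350.0,
    n_per_axis: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """Assign each cell to one square bin of a grid anchored at (0, 0).

    'Approximately 45 µm' bins are realized as FOV/8 per axis. Returns
    (bin_index per cell, bin_center (µm) per bin index).
    """
    xy = np.asarray(anatomical_xy, dtype=float)
    bw = fov_width / n_per_axis
    bh = fov_height / n_per_axis
    ix = np.clip((xy[:, 0] / bw).astype(int), 0, n_per_axis - 1)
    iy = np.clip((xy[:, 1] / bh).astype(int), 0, n_per_axis - 1)
    flat = ix * n_per_axis + iy
    gx = (np.arange(n_per_axis) + 0.5) * bw
    gy = (np.arange(n_per_axis) + 0.5) * bh
    centers = np.array([(gx[i], gy[j]) for i in range(n_per_axis) for j in range(n_per_axis)])
    return flat, centers


def _mean_pairwise(stat_matrix, members, anat_xy, exclusion):
    """Mean of the pairwise statistic over a cell set, dropping pairs
    closer than ``exclusion`` µm; NaN if no valid pair remains."""
    vals = []
    for a in range(len(members)):
        for b in range(a + 1, len(members)):
            i, j = members[a], members[b]
            if exclusion and np.hypot(*(anat_xy[i] - anat_xy[j])) < exclusion:
                continue
            v = stat_matrix[i, j]
            if np.isfinite(v):
                vals.append(v)
    return float(np.mean(vals)) if vals else float("nan")


def within_bin_similarity(
    anatomical_xy: np.ndarray,
    stat_matrix: np.ndarray,
    *,
    fov_width: float = 350.0,
    fov_height: float = 350.0,
    n_per_axis: int = 8,
    min_cells: int = 3,
    exclusion: float = 15.0,
) -> pd.DataFrame:
    """Per-anatomical-bin mean pairwise statistic (map or ΔF/F
    correlation).

    Only bins holding at least ``min_cells`` place cells qualify; pairs
    closer than ``exclusion`` µm are dropped (soma-overlap guard); bins
    left without a valid pair are dropped.
    """
    anatomical_xy = np.asarray(anatomical_xy, dtype=float)
    flat, centers = assign_anatomical_bins(
        anatomical_xy, fov_width, fov_height, n_per_axis
    )
    rows = []
    for b in np.unique(flat):
        members = np.flatnonzero(flat == b)
        if members.size < min_cells:
            continue
        v = _mean_pairwise(stat_matrix, members, anatomical_xy, exclusion)
        if np.isfinite(v):
            rows.append(
                {
                    "bin": int(b),
                    "bin_x": centers[b][0],
                    "bin_y": centers[b][1],
                    "n_cells": int(members.size),
                    "mean_stat": v,
                }
            )
    return pd.DataFrame(rows, columns=["bin", "bin_x", "bin_y", "n_cells", "mean_stat"])


def size_matched_control(
    anatomical_xy: np.ndarray,
    stat_matrix: np.ndarray,
    bin_sizes: list[int],
    n_iter: int = 200,
    *,
    exclusion: float = 15.0,
    seed: int | None = None,
) -> np.ndarray:
    """Control distribution for within-bin similarity.

    For each observed bin size, draws ``n_iter`` random cell sets of
    that size (without replacement within a draw) from the full session
    roster and computes the same mean-pairwise statistic. Returns an
    array of shape (n_iter, n_bins) of control values.
    """
    anatomical_xy = np.asarray(anatomical_xy, dtype=float)
    n = len(anatomical_xy)
    if max(bin_sizes, default=0) > n:
        raise ParameterError("bin size exceeds session roster")
    rng = np.random.default_rng(seed)
    out = np.full((n_iter, len(bin_sizes)), np.nan)
    for j, size in enumerate(bin_sizes):
        for it in range(n_iter):
            members = rng.choice(n, size=size, replace=False)
            out[it, j] = _mean_pairwise(stat_matrix, members, anatomical_xy, exclusion)
    return out


def bootstrap_median_ci(
    values: np.ndarray,
    n_boot: int = 10_000,
    level: float = 99.0,
    *,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Percentile bootstrap CI of the median: (median, lo, hi)."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise ParameterError("bootstrap needs at least 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    meds = np.median(values[idx], axis=1)
    alpha = (100.0 - level) / 2.0
    lo, hi = np.percentile(meds, [alpha, 100.0 - alpha])
    return float(np.median(values)), float(lo), float(hi)


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------

@dataclass
class MoranResult:
    """Global (and optionally local) Moran's I with a permutation null."""

    I: float
    null: np.ndarray
    p95: float
    significant: bool
    p_value: float
    weights_spec: str
    local: pd.DataFrame | None = None


def spatial_weights(
    positions: np.ndarray,
    *,
    style: str = "idw",
    cutoff: float | None = None,
    bin_size: float = 45.0,
    row_standardize: bool = True,
) -> np.ndarray:
    """Spatial weight matrix between analysis units.

    style='idw': inverse-distance weights with a cutoff (default 2×
    ``bin_size``), zero diagonal, optionally row-standardized.
    style='queen': contiguity on a square grid inferred from positions
    (units within 1.5× bin size in Chebyshev distance are neighbors).
    """
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    d = squareform(pdist(positions))
    if style == "idw":
        if cutoff is None:
            cutoff = 2.0 * bin_size
        with np.errstate(divide="ignore"):
            w = np.where((d > 0) & (d <= cutoff), 1.0 / np.maximum(d, 1e-12), 0.0)
    elif style == "queen":
        cheb = np.maximum(
            np.abs(positions[:, None, 0] - positions[None, :, 0]),
            np.abs(positions[:, None, 1] - positions[None, :, 1]),
        )
        w = ((cheb > 0) & (cheb <= 1.5 * bin_size)).astype(float)
    else:
        raise ParameterError(f"unknown weight style: {style!r}")
    np.fill_diagonal(w, 0.0)
    if row_standardize:
        rs = w.sum(1, keepdims=True)
        nz = rs[:, 0] > 0
        w[nz] = w[nz] / rs[nz]
    return w


def _moran_stat(z: np.ndarray, w: np.ndarray) -> float:
    s0 = w.sum()
    return float(len(z) / s0 * (z @ w @ z) / (z @ z))


def global_morans_i(
    positions: np.ndarray,
    values: np.ndarray,
    *,
    weights: np.ndarray | None = None,
    weights_spec: str = "idw,row-standardized,cutoff=2x45µm",
    n_perm: int = 1000,
    seed: int | None = None,
    **weight_kw,
) -> MoranResult:
    """Global Moran's I with a permutation null.

    I = (n/ΣΣw) · (ΣΣ w_ij z_i z_j)/(Σ z_i²) with z the centered
    values. The null randomly reassigns the values across units and
    recomputes I (default 1,000 iterations); the observation is
    'significant clustering' iff I exceeds the null's 95th percentile.
    """
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    positions, values = positions[ok], values[ok]
    n = len(values)
    if n < 8:
        raise ParameterError("Moran's I needs at least 8 units")
    if np.std(values) == 0.0:
        raise DegenerateInputError("zero variance in values")
    if weights is None:
        weights = spatial_weights(positions, **weight_kw)
    if weights.sum() == 0:
        raise DataError("weight matrix is all zero (cutoff too small?)")
    z = values - values.mean()
    i_obs = _moran_stat(z, weights)

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    zp = z[perms]  # (n_perm, n)
    denom = float(z @ z)
    s0 = weights.sum()
    null = (n / s0) * np.einsum("ij,jk,ik->i", zp, weights, zp) / denom
    p95 = float(np.percentile(null, 95))
    p_value = float((np.sum(null >= i_obs) + 1) / (n_perm + 1))
    return MoranResult(
        I=i_obs,
        null=null,
        p95=p95,
        significant=bool(i_obs > p95),
        p_value=p_value,
        weights_spec=weights_spec,
    )


def local_morans_i(
    positions: np.ndarray,
    values: np.ndarray,
    *,
    weights: np.ndarray | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    bonferroni: bool = True,
    seed: int | None = None,
    **weight_kw,
) -> pd.DataFrame:
    """Local Moran's I per unit with conditional-permutation p-values.

    I_i = z_i · Σ_j w_ij z_j / (Σ z²/n). For each unit the null holds
    its own value fixed and draws its neighbors' values from the
    remaining units. Significance defaults to Bonferroni-corrected
    α = 0.05 across units.
    """
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 8:
        raise ParameterError("Moran's I needs at least 8 units")
    if np.std(values) == 0.0:
        raise DegenerateInputError("zero variance in values")
    if weights is None:
        weights = spatial_weights(positions, **weight_kw)
    z = values - values.mean()
    m2 = float(z @ z) / n
    lag = weights @ z
    local_i = z * lag / m2

    rng = np.random.default_rng(seed)
    p = np.empty(n)
    for i in range(n):
        others = np.delete(z, i)
        wrow = np.delete(weights[i], i)
        nz = wrow > 0
        k = int(nz.sum())
        if k == 0:
            p[i] = 1.0
            continue
        draws = rng.choice(others, size=(n_perm, k), replace=True)
        null_i = z[i] * (draws @ wrow[nz]) / m2
        # two-comparable one-sided p in the direction of the observation
        if local_i[i] >= 0:
            p[i] = (np.sum(null_i >= local_i[i]) + 1) / (n_perm + 1)
        else:
            p[i] = (np.sum(null_i <= local_i[i]) + 1) / (n_perm + 1)
    thresh = alpha / n if bonferroni else alpha
    return pd.DataFrame(
        {
            "unit": np.arange(n),
            "local_I": local_i,
            "p_value": p,
            "significant": p < thresh,
        }
    )


# ---------------------------------------------------------------------------
# expanding-circle profiles
# ---------------------------------------------------------------------------

def _profile(
    ref_space_d: np.ndarray,
    stat: np.ndarray,
    radii: np.ndarray,
    *,
    n_iter: int,
    n_boot: int,
    level: float,
    seed,
) -> pd.DataFrame:
    """Shared engine: ``ref_space_d``/``stat`` are condensed pair vectors
    of the radius-defining distance and the pooled statistic."""
    radii = np.asarray(radii, dtype=float)
    if np.any(np.diff(radii) <= 0):
        raise ParameterError("radii must be strictly increasing")
    rng = np.random.default_rng(seed)
    finite = np.isfinite(stat)
    all_stat = stat[finite]
    rows = []
    for r in radii:
        sel = (ref_space_d <= r) & finite
        vals = stat[sel]
        if vals.size < 2:
            rows.append(
                {"radius": r, "n_pairs": int(vals.size), "median": np.nan,
                 "ci_lo": np.nan, "ci_hi": np.nan, "control_median": np.nan}
            )
            continue
        med, lo, hi = bootstrap_median_ci(
            vals, n_boot=n_boot, level=level, seed=int(rng.integers(2**31))
        )
        ctrl = np.median(
            [
                np.median(rng.choice(all_stat, size=vals.size, replace=False))
                for _ in range(n_iter)
            ]
        )
        rows.append(
            {"radius": r, "n_pairs": int(vals.size), "median": med,
             "ci_lo": lo, "ci_hi": hi, "control_median": float(ctrl)}
        )
    return pd.DataFrame(rows)


def expanding_circle_profile(
    anatomical_xy: np.ndarray,
    stat_matrix: np.ndarray,
    radii: np.ndarray | None = None,
    *,
    n_iter: int = 200,
    n_boot: int = 10_000,
    level: float = 99.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Reference-cell neighborhood profile over expanding anatomical circles.

    At each radius (default 15–60 µm in 5 µm steps) all reference–
    neighbor pairs with anatomical distance ≤ radius (closed boundary)
    are pooled; reports the pooled median with a bootstrap CI and the
    median of ``n_iter`` size-matched random draws from pairs at all
    distances. ``stat_matrix`` holds the pairwise statistic (map
    correlation, field distance, |Δd|, circular angle difference, ...).
    """
    if radii is None:
        radii = np.arange(15.0, 60.1, 5.0)
    anatomical_xy = np.asarray(anatomical_xy, dtype=float)
    d = pdist(anatomical_xy)
    ii, jj = np.triu_indices(len(anatomical_xy), k=1)
    stat = np.asarray(stat_matrix)[ii, jj]
    return _profile(
        d, stat, radii, n_iter=n_iter, n_boot=n_boot, level=level, seed=seed
    )


def fieldspace_profile(
    field_xy: np.ndarray,
    anatomical_xy: np.ndarray,
    radii: np.ndarray | None = None,
    *,
    n_iter: int = 200,
    n_boot: int = 10_000,
    level: float = 99.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mirror profile: expanding circles in place-field space.

    Neighbors are cells whose main-field centroid lies within the field
    radius (default 5–50 cm in 5 cm steps) of the reference cell's
    field; the pooled statistic is the anatomical distance (µm).
    """
    if radii is None:
        radii = np.arange(5.0, 50.1, 5.0)
    fd = pdist(np.asarray(field_xy, dtype=float))
    ad = pdist(np.asarray(anatomical_xy, dtype=float))
    return _profile(
        fd, ad, np.asarray(radii, dtype=float),
        n_iter=n_iter, n_boot=n_boot, level=level, seed=seed,
    )


def profile_control_within_ci(profile: pd.DataFrame) -> float:
    """Fraction of radii at which the random-control median falls inside
    the observed bootstrap CI (NaN rows skipped)."""
    ok = profile.dropna(subset=["median", "control_median"])
    if len(ok) == 0:
        return float("nan")
    inside = (ok["control_median"] >= ok["ci_lo"]) & (ok["control_median"] <= ok["ci_hi"])
    return float(inside.mean())


# ---------------------------------------------------------------------------
# effect size + nearest neighbors
# ---------------------------------------------------------------------------

def cliffs_delta(x: np.ndarray, y: np.ndarray) -> float:
    """Cliff's delta: (#{x_i > y_j} − #{x_i < y_j}) / (n_x n_y) ∈ [−1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("Cliff's delta needs non-empty samples")
    ys = np.sort(y)
    greater = np.searchsorted(ys, x, side="left").sum()  # y < x
    less = (y.size - np.searchsorted(ys, x, side="right")).sum()  # y > x
    return float((greater - less) / (x.size * y.size))


def nearest_neighbor_analysis(
    anatomical_xy: np.ndarray,
    stat_matrix: np.ndarray,
    *,
    cell_ids: np.ndarray | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
    **weight_kw,
) -> tuple[pd.DataFrame, MoranResult]:
    """Per-cell nearest-neighbor statistic vs a random-partner control.

    For each place cell the anatomically nearest other place cell is
    found (ties broken by lowest cell id); the per-cell statistic (map
    correlation or field distance to that neighbor) is compared with the
    same statistic for a uniformly drawn random partner. A global
    Moran's I over the per-cell nearest-neighbor statistic at the cell
    positions tests whether the statistic itself is spatially clustered.
    """
    anatomical_xy = np.asarray(anatomical_xy, dtype=float)
    n = len(anatomical_xy)
    if n < 2:
        raise ParameterError("need at least 2 cells")
    if cell_ids is None:
        cell_ids = np.arange(n)
    d = squareform(pdist(anatomical_xy))
    np.fill_diagonal(d, np.inf)
    # argmin breaks ties by lowest index == lowest cell_id under sorted ids
    nn = np.argmin(d, axis=1)
    rng = np.random.default_rng(seed)
    partners = np.array(
        [rng.choice([j for j in range(n) if j != i]) for i in range(n)]
    )
    stat = np.asarray(stat_matrix, dtype=float)
    table = pd.DataFrame(
        {
            "cell_id": np.asarray(cell_ids),
            "neighbor_id": np.asarray(cell_ids)[nn],
            "neighbor_distance": d[np.arange(n), nn],
            "observed": stat[np.arange(n), nn],
            "random_partner": stat[np.arange(n), partners],
        }
    )
    moran = global_morans_i(
        anatomical_xy,
        table["observed"].to_numpy(),
        n_perm=n_perm,
        seed=seed,
        **weight_kw,
    )
    return table, moran
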