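"""Object-tuned (landmark-vector) cell classification and topography.

In the four-session object protocol (baseline → object → object moved →
post), an object-tuned cell develops a new, stable activity field at a
similar distance and allocentric direction from the object in both
object sessions — the field follows the object when it moves. The
module extracts each cell's preferred (distance, angle) vector from its
allocentric object-tuning map, classifies object-tuned cells, tests the
population's angular coverage (Rayleigh), and reuses the clustering
battery on circular angle differences to ask whether similarly tuned
object cells sit near each other anatomically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DegenerateInputError, ParameterError
from . import topography as tp
from . import tuning as tn

__all__ = [
    "ObjectTuning",
    "object_vector",
    "object_map_stability",
    "classify_object_tuned",
    "rayleigh_uniformity",
    "circular_difference_deg",
    "object_topography",
]


@dataclass
class ObjectTuning:
    preferred_distance: float  # cm
    preferred_angle: float  # deg in [0, 360)
    consistency: float  # cm distance between session vectors (lower = better)


def object_vector(obj_map: tn.ObjectTuningMap) -> tuple[float, float]:
    """Preferred (distance cm, angle deg): the smoothed object-map peak."""
    if not obj_map.visited_mask.any():
        raise DegenerateInputError("empty object map")
    return obj_map.peak_location()


def object_map_candidate_peaks(
    obj_map: tn.ObjectTuningMap,
    k: int = 3,
    min_fraction: float = 0.5,
    contrast_min: float = 3.0,
    min_occupancy_s: float = 0.5,
) -> list[tuple[float, float]]:
    """Up to ``k`` candidate (distance, angle) vectors: local maxima of
    the smoothed object map, strongest first, at ≥ ``min_fraction`` of
    the global peak and ≥ ``contrast_min`` × the map's median level.

    A cell that is simultaneously a place cell shows two bumps in object
    coordinates — its arena field and (if object-tuned) the
    object-locked field; cross-session consistency decides which one is
    object-locked, so classification must see more than the single
    global peak. The contrast floor keeps background-only maps (whose
    local maxima are smoothed noise) from yielding candidates, and the
    occupancy floor excludes bins visited too briefly for a reliable
    rate estimate (the small innermost distance rings in particular).
    """
    from scipy.ndimage import maximum_filter

    if not obj_map.visited_mask.any():
        raise DegenerateInputError("empty object map")
    reliable = obj_map.visited_mask & (obj_map.occupancy >= min_occupancy_s)
    if not reliable.any():
        reliable = obj_map.visited_mask
    rate = np.where(reliable, np.nan_to_num(obj_map.rate), -np.inf)
    local_max = (maximum_filter(rate, size=3, mode=("nearest", "wrap")) == rate) & (
        rate > -np.inf
    )
    ii, jj = np.nonzero(local_max)
    order = np.argsort(rate[ii, jj])[::-1]
    peak = rate[ii, jj].max()
    med = float(np.median(np.nan_to_num(obj_map.rate)[reliable]))
    floor = contrast_min * max(med, 1e-12)
    out = []
    for idx in order:
        if rate[ii[idx], jj[idx]] < min_fraction * peak:
            break
        if rate[ii[idx], jj[idx]] < floor:
            break
        d = (ii[idx] + 0.5) * obj_map.dist_bin_size
        a = (jj[idx] + 0.5) * obj_map.angle_bin_size
        # suppress secondary maxima of the same bump: keep candidates
        # mutually separated by >= 8 cm in object-vector space
        xy = _vector_to_xy(d, a)
        if any(np.hypot(*(xy - _vector_to_xy(dp, ap))) < 8.0 for dp, ap in out):
            continue
        out.append((d, a))
        if len(out) == k:
            break
    return out


def object_map_stability(
    map_obj1: tn.ObjectTuningMap,
    map_obj2: tn.ObjectTuningMap,
    *,
    min_occupancy_s: float = 0.5,
    min_common_bins: int = 50,
) -> float:
    """Pearson correlation of two object-centred maps over bins that are
    reliably sampled (≥ ``min_occupancy_s``) in both sessions.

    High for responses locked to the object across sessions; ≈ 0 for
    background activity and for arena-fixed fields (which move in
    object coordinates when the object moves). NaN when fewer than
    ``min_common_bins`` reliable bins are shared or either map is flat.
    """
    common = (
        map_obj1.visited_mask
        & map_obj2.visited_mask
        & (map_obj1.occupancy >= min_occupancy_s)
        & (map_obj2.occupancy >= min_occupancy_s)
    )
    if common.sum() < min_common_bins:
        return float("nan")
    a = np.nan_to_num(map_obj1.rate[common])
    b = np.nan_to_num(map_obj2.rate[common])
    if a.std() == 0.0 or b.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def _vector_to_xy(dist: float, ang_deg: float) -> np.ndarray:
    a = np.deg2rad(ang_deg)
    return np.array([dist * np.cos(a), dist * np.sin(a)])


def circular_difference_deg(a: float | np.ndarray, b: float | np.ndarray) -> np.ndarray:
    """Absolute circular angle difference in degrees, in [0, 180]."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return np.where(d > 180.0, 360.0 - d, d)


def classify_object_tuned(
    map_obj1: tn.ObjectTuningMap,
    map_obj2: tn.ObjectTuningMap,
    baseline_map: tn.TuningMap,
    object_xy_1: tuple[float, float],
    object_xy_2: tuple[float, float] | None = None,
    *,
    d_tol: float = 10.0,
    a_tol: float = 45.0,
    new_field_radius: float = 6.0,
    follow_min_fraction: float = 0.5,
    r_obj_min: float = 0.2,
    min_common_bins: int = 50,
    peak_rate_min: float = 0.0,
) -> tuple[bool, ObjectTuning]:
    """Object-tuned iff the object-referenced field is stable and new.

    (i) the two object-session object-centred maps are correlated
    (Pearson r ≥ ``r_obj_min`` over jointly reliable bins): a field
    locked to the object occupies the same object-map location in both
    sessions even though the object moved, while an arena-fixed place
    field moves in object coordinates and decorrelates — this is the
    'stable activity field at similar distance and direction' core of
    the definition, and it holds equally for cells firing at the object
    itself,
    (ii) a matched pair of candidate map peaks agrees across sessions:
    |Δdistance| ≤ ``d_tol`` cm and circular |Δangle| ≤ ``a_tol``°
    (the angle criterion is waived when both preferred distances are
    < ``d_tol`` — direction is ill-defined near the object),
    (iii) the field is new: the baseline (empty-arena) map's maximum
    rate within ``new_field_radius`` cm of the object-referenced arena
    location, expressed as an elevation above the baseline background
    (median rate) relative to the baseline peak elevation, stays below
    50% — i.e. the cell was not already firing there before the object
    appeared. The elevation ratio is scale-free, so the test is
    insensitive to the different normalizations of spatial and
    object-centred maps,
    (iv) the field follows the object: when both object positions are
    known, the matched field's arena locations in the two sessions must
    differ by at least ``follow_min_fraction`` of the object
    displacement.
    """
    cands1 = object_map_candidate_peaks(map_obj1)
    cands2 = object_map_candidate_peaks(map_obj2)
    peak1 = float(np.nanmax(np.where(map_obj1.visited_mask, map_obj1.rate, np.nan)))
    peak2 = float(np.nanmax(np.where(map_obj2.visited_mask, map_obj2.rate, np.nan)))
    has_field = peak1 > peak_rate_min and peak2 > peak_rate_min

    r_obj = object_map_stability(map_obj1, map_obj2, min_common_bins=min_common_bins)
    object_locked = bool(np.isfinite(r_obj) and r_obj >= r_obj_min)

    base_rate = np.where(baseline_map.visited_mask, baseline_map.rate, np.nan)
    base_bg = float(np.nanmedian(base_rate))
    base_peak = float(np.nanmax(base_rate))
    centers = baseline_map.bin_centers()
    bx, by = np.meshgrid(centers, centers, indexing="ij")

    def baseline_elevation_at(loc) -> float:
        """Max baseline elevation near loc, relative to the baseline
        peak elevation; 0 when the baseline map holds no real field
        (peak < 3× background — its 'peak' is then itself noise and
        cannot meaningfully veto newness)."""
        if base_peak < 3.0 * max(base_bg, 1e-12):
            return 0.0
        near = np.hypot(bx - loc[0], by - loc[1]) <= new_field_radius
        vals = base_rate[near]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            return 0.0
        return float((vals.max() - base_bg) / (base_peak - base_bg))

    best: tuple[float, float, float] | None = None  # (consistency, d, a)
    for d1, a1 in cands1:
        for d2, a2 in cands2:
            dd = abs(d1 - d2)
            da = float(circular_difference_deg(a1, a2))
            near_object = d1 < d_tol and d2 < d_tol
            if not (dd <= d_tol and (near_object or da <= a_tol)):
                continue
            # 'new': no baseline place field at the object-referenced spot
            locs = [np.asarray(object_xy_1) + _vector_to_xy(d1, a1)]
            if object_xy_2 is not None:
                locs.append(np.asarray(object_xy_2) + _vector_to_xy(d2, a2))
                displacement = float(
                    np.hypot(*(np.asarray(object_xy_2) - np.asarray(object_xy_1)))
                )
                if displacement > 0:
                    moved = float(np.hypot(*(locs[1] - locs[0])))
                    if moved < follow_min_fraction * displacement:
                        continue
            # a field is 'pre-existing' only if the baseline was already
            # active at every reconstructed location: with a moved
            # object the two locations are far apart, so one arena-fixed
            # baseline field cannot legitimately explain both
            if all(baseline_elevation_at(loc) >= 0.5 for loc in locs):
                continue
            cons = float(np.hypot(*(_vector_to_xy(d1, a1) - _vector_to_xy(d2, a2))))
            if best is None or cons < best[0]:
                best = (cons, (d1 + d2) / 2, a1)

    if best is not None:
        tuning = ObjectTuning(
            preferred_distance=float(best[1]),
            preferred_angle=float(best[2]),
            consistency=best[0],
        )
        return bool(has_field and object_locked), tuning

    d1, a1 = object_vector(map_obj1)
    d2, a2 = object_vector(map_obj2)
    tuning = ObjectTuning(
        preferred_distance=float((d1 + d2) / 2),
        preferred_angle=float(a1),
        consistency=float(np.hypot(*(_vector_to_xy(d1, a1) - _vector_to_xy(d2, a2)))),
    )
    return False, tuning


def rayleigh_uniformity(angles_deg: np.ndarray) -> tuple[float, float]:
    """Rayleigh test of circular uniformity: (Z, p).

    Z = n·R̄² with R̄ the mean resultant length; p from the standard
    series approximation (Zar). Requires n ≥ 5.
    """
    angles = np.deg2rad(np.asarray(angles_deg, dtype=float))
    n = angles.size
    if n < 5:
        raise ParameterError("Rayleigh test needs n >= 5 angles")
    c = np.cos(angles).sum()
    s = np.sin(angles).sum()
    r_bar = np.hypot(c, s) / n
    z = n * r_bar**2
    p = np.exp(np.sqrt(1 + 4 * n + 4 * (n**2 - (n * r_bar) ** 2)) - (1 + 2 * n))
    return float(z), float(min(max(p, 0.0), 1.0))


def object_topography(
    anatomical_xy: np.ndarray,
    preferred_angles_deg: np.ndarray,
    *,
    preferred_distances: np.ndarray | None = None,
    radii: np.ndarray | None = None,
    n_iter: int = 200,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> dict:
    """Anatomical organization of object-cell angular tuning.

    Builds the pairwise circular angle-difference matrix (Δθ ∈ [0°,
    180°]), estimates its MI with anatomical distance, and runs the
    expanding-circle profile with Δθ as the pooled statistic. When
    preferred distances are given, the same MI is reported for
    field-distance-from-object differences.
    """
    anatomical_xy = np.asarray(anatomical_xy, dtype=float)
    ang = np.asarray(preferred_angles_deg, dtype=float)
    n = len(ang)
    if n < 2:
        raise ParameterError("need at least 2 object-tuned cells")
    dtheta = circular_difference_deg(ang[:, None], ang[None, :])
    np.fill_diagonal(dtheta, 0.0)
    from scipy.spatial.distance import pdist, squareform

    ad = pdist(anatomical_xy)
    dth = squareform(dtheta, checks=False)
    out: dict = {}
    if ad.size >= 100:
        out["mi_angle"] = tp.mutual_information_continuous(ad, dth, seed=seed)
        if preferred_distances is not None:
            od = np.abs(
                np.asarray(preferred_distances)[:, None]
                - np.asarray(preferred_distances)[None, :]
            )
            out["mi_distance"] = tp.mutual_information_continuous(
                ad, squareform(od, checks=False), seed=seed
            )
    out["profile"] = tp.expanding_circle_profile(
        anatomical_xy, dtheta, radii, n_iter=n_iter, n_boot=n_boot, seed=seed
    )
    out["pair_table"] = pd.DataFrame(
        {"anatomical_distance": ad, "angle_difference": dth}
    )
    return out
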