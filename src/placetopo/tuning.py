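"""Spatial tuning maps and allocentric object-tuning maps.

A spatial tuning map divides the arena into 2.5 cm × 2.5 cm bins, sums
the deconvolved event amplitudes falling in each bin, divides by the
time spent there, and smooths the result with a Gaussian kernel
(σ = 2.5 bins by default). Occupancy and events are speed-filtered
first; bins the animal never visited are masked, not imputed. Object
maps use the same normalization on a (distance-from-object ×
angle-to-object) grid with circular smoothing along the angle axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import DataError, DegenerateInputError, ParameterError, Trajectory
from .synthetic import ArenaSpec

__all__ = [
    "TuningMap",
    "ObjectTuningMap",
    "PlaceField",
    "speed_filter",
    "compute_tuning_map",
    "compute_object_map",
    "map_correlation",
    "detect_fields",
    "field_centroid",
    "main_field",
    "center_of_mass",
    "spatial_information",
    "smooth_masked",
]


@dataclass
class TuningMap:
    """Binned, occupancy-normalized, smoothed event-rate map.

    ``rate`` is indexed [ix, iy] (x varies along axis 0) and is defined
    only where ``visited_mask`` is True; elsewhere it is NaN.
    """

    rate: np.ndarray
    occupancy: np.ndarray  # seconds per bin
    visited_mask: np.ndarray
    bin_size: float  # cm
    smoothing_sigma: float  # bins
    raw_rate: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return self.rate.shape[0]

    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_size


@dataclass
class ObjectTuningMap:
    """Event-rate map over (distance-from-object, angle-to-object) bins.

    Angle bins tile [0°, 360°) exactly; angle 0° points arena-east,
    counter-clockwise positive (allocentric).
    """

    rate: np.ndarray  # [i_dist, i_angle]
    occupancy: np.ndarray
    visited_mask: np.ndarray
    dist_bin_size: float  # cm
    angle_bin_size: float  # deg

    def peak_location(self) -> tuple[float, float]:
        """(distance cm, angle deg) of the map peak over visited bins."""
        masked = np.where(self.visited_mask, self.rate, -np.inf)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        return ((i + 0.5) * self.dist_bin_size, (j + 0.5) * self.angle_bin_size)


@dataclass
class PlaceField:
    """One detected place field (a connected component of hot bins)."""

    bins: np.ndarray  # (k, 2) int array of (ix, iy)
    centroid: tuple[float, float]  # cm
    peak_rate: float
    area: float  # cm²


def speed_filter(
    traj: Trajectory,
    events_t: np.ndarray,
    v_min: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Frame mask and event mask for samples at speed ≥ v_min cm/s.

    Returns (frame_keep, event_keep) boolean arrays; events are assigned
    to the trajectory frame they fall in.
    """
    events_t = np.asarray(events_t, dtype=float)
    if v_min < 0:
        raise ParameterError("v_min must be >= 0")
    if v_min == 0:
        return np.ones(traj.n_samples, bool), np.ones(events_t.size, bool)
    keep = traj.speed() >= v_min
    if not keep.any():
        raise DegenerateInputError("all samples below the speed threshold")
    frames = assign_frames(traj, events_t)
    return keep, keep[frames]


def assign_frames(traj: Trajectory, events_t: np.ndarray) -> np.ndarray:
    """Index of the trajectory frame containing each event time."""
    idx = np.searchsorted(traj.t, np.asarray(events_t, dtype=float), side="right") - 1
    return np.clip(idx, 0, traj.n_samples - 1)


def bin_indices(traj: Trajectory, arena: ArenaSpec, bin_size: float = 2.5) -> np.ndarray:
    """Flat arena-bin index per trajectory frame."""
    n_bins = int(np.ceil(arena.side_length / bin_size))
    ix = np.clip((traj.x / bin_size).astype(int), 0, n_bins - 1)
    iy = np.clip((traj.y / bin_size).astype(int), 0, n_bins - 1)
    return ix * n_bins + iy


def smooth_masked(raw: np.ndarray, mask: np.ndarray, sigma: float, *, wrap_axis: int | None = None) -> np.ndarray:
    """Gaussian smoothing under a validity mask (normalized convolution).

    The raw values (zeros outside the mask) and the mask itself are
    smoothed separately and divided, so unvisited bins neither receive
    nor dilute rate mass. ``wrap_axis`` selects one circular axis.
    """
    if sigma <= 0:
        return np.where(mask, raw, np.nan)
    mode: tuple[str, str] = ("reflect", "reflect")
    if wrap_axis is not None:
        mode = tuple("wrap" if ax == wrap_axis else "reflect" for ax in (0, 1))
    num = ndimage.gaussian_filter(np.where(mask, raw, 0.0), sigma, mode=mode)
    den = ndimage.gaussian_filter(mask.astype(float), sigma, mode=mode)
    out = np.full(raw.shape, np.nan)
    ok = den > 1e-12
    out[ok] = num[ok] / den[ok]
    return np.where(mask, out, np.nan)


def compute_tuning_map(
    traj: Trajectory,
    events_t: np.ndarray,
    events_amp: np.ndarray,
    arena: ArenaSpec = ArenaSpec(),
    bin_size: float = 2.5,
    smoothing_sigma: float = 2.5,
    *,
    sigma_units: str = "bins",
    v_min: float = 2.0,
) -> TuningMap:
    """Occupancy-normalized, smoothed event-amplitude rate map.

    Unsmoothed rate in each visited bin is (Σ event amplitudes)/(seconds
    of occupancy); smoothing is mask-normalized Gaussian with σ given in
    ``sigma_units`` ('bins' or 'cm').
    """
    events_t = np.asarray(events_t, dtype=float)
    events_amp = np.asarray(events_amp, dtype=float)
    if events_t.shape != events_amp.shape:
        raise DataError("event times and amplitudes must align")
    if sigma_units not in ("bins", "cm"):
        raise ParameterError("sigma_units must be 'bins' or 'cm'")
    sigma_bins = smoothing_sigma if sigma_units == "bins" else smoothing_sigma / bin_size

    n_bins = int(np.ceil(arena.side_length / bin_size))
    frame_keep, event_keep = speed_filter(traj, events_t, v_min)

    flat = bin_indices(traj, arena, bin_size)
    dt = traj.dt if traj.n_samples > 1 else 1.0
    occ = np.bincount(flat[frame_keep], minlength=n_bins * n_bins).astype(float) * dt
    if occ.sum() == 0:
        raise DegenerateInputError("zero total occupancy after filtering")

    ev_frames = assign_frames(traj, events_t[event_keep])
    amp = np.bincount(
        flat[ev_frames], weights=events_amp[event_keep], minlength=n_bins * n_bins
    )
    occ = occ.reshape(n_bins, n_bins)
    amp = amp.reshape(n_bins, n_bins)
    visited = occ > 0
    raw = np.full((n_bins, n_bins), np.nan)
    raw[visited] = amp[visited] / occ[visited]
    rate = smooth_masked(np.nan_to_num(raw), visited, sigma_bins)
    return TuningMap(
        rate=rate,
        occupancy=occ,
        visited_mask=visited,
        bin_size=bin_size,
        smoothing_sigma=sigma_bins,
        raw_rate=raw,
    )


def compute_object_map(
    traj: Trajectory,
    events_t: np.ndarray,
    events_amp: np.ndarray,
    object_xy: tuple[float, float],
    *,
    dist_bin_size: float = 2.0,
    angle_bin_size: float = 6.0,
    max_distance: float | None = None,
    smoothing_sigma: float = 2.5,
    v_min: float = 2.0,
    arena: ArenaSpec = ArenaSpec(),
) -> ObjectTuningMap:
    """Allocentric object-tuning map: rate over (distance, angle) bins.

    Distance from the object in 2 cm bins, angle to the object in 6°
    bins (60 bins covering the full circle); the same sum/occupancy
    normalization as spatial maps, smoothed with circular wrap along the
    angle axis.
    """
    events_t = np.asarray(events_t, dtype=float)
    events_amp = np.asarray(events_amp, dtype=float)
    if max_distance is None:
        max_distance = arena.side_length * np.sqrt(2.0)
    n_dist = int(np.ceil(max_distance / dist_bin_size))
    n_ang = int(round(360.0 / angle_bin_size))

    dx = traj.x - object_xy[0]
    dy = traj.y - object_xy[1]
    dist = np.hypot(dx, dy)
    ang = np.degrees(np.arctan2(dy, dx)) % 360.0
    i_dist = np.clip((dist / dist_bin_size).astype(int), 0, n_dist - 1)
    i_ang = np.clip((ang / angle_bin_size).astype(int), 0, n_ang - 1)
    flat = i_dist * n_ang + i_ang

    frame_keep, event_keep = speed_filter(traj, events_t, v_min)
    dt = traj.dt if traj.n_samples > 1 else 1.0
    occ = np.bincount(flat[frame_keep], minlength=n_dist * n_ang).astype(float) * dt
    if occ.sum() == 0:
        raise DegenerateInputError("zero occupancy on the object grid")
    ev_frames = assign_frames(traj, events_t[event_keep])
    amp = np.bincount(flat[ev_frames], weights=events_amp[event_keep], minlength=n_dist * n_ang)

    occ = occ.reshape(n_dist, n_ang)
    amp = amp.reshape(n_dist, n_ang)
    visited = occ > 0
    raw = np.zeros((n_dist, n_ang))
    raw[visited] = amp[visited] / occ[visited]
    rate = smooth_masked(raw, visited, smoothing_sigma, wrap_axis=1)
    return ObjectTuningMap(
        rate=rate,
        occupancy=occ,
        visited_mask=visited,
        dist_bin_size=dist_bin_size,
        angle_bin_size=angle_bin_size,
    )


def map_correlation(map_a: TuningMap, map_b: TuningMap) -> float:
    """Pearson correlation of two maps over jointly visited bins.

    Returns NaN (undefined) when either map has zero variance on the
    common support; raises on disjoint visited masks.
    """
    if map_a.rate.shape != map_b.rate.shape:
        raise DataError("maps must share grid geometry")
    common = map_a.visited_mask & map_b.visited_mask
    if not common.any():
        raise DataError("maps have disjoint visited masks")
    a = map_a.rate[common]
    b = map_b.rate[common]
    if a.size < 2 or np.std(a) == 0.0 or np.std(b) == 0.0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def detect_fields(
    tmap: TuningMap,
    *,
    threshold_fraction: float = 0.3,
    min_area_bins: int = 4,
    max_area_fraction: float = 0.5,
) -> list[PlaceField]:
    """Connected components of elevated bins.

    A bin is 'hot' when its rate exceeds background + threshold_fraction
    × (peak − background), background being the median rate over visited
    bins; thresholding the *elevation* keeps a uniform event background
    from merging a field with the rest of the arena. Components smaller
    than ``min_area_bins`` bins or larger than ``max_area_fraction`` of
    the arena are rejected. Fields are sorted by peak rate (desc), ties
    by area (desc) then lowest (row, col) of their peak bin.
    """
    rate = np.where(tmap.visited_mask, tmap.rate, np.nan)
    if not np.any(np.nan_to_num(rate) > 0):
        return []
    peak = np.nanmax(rate)
    background = float(np.nanmedian(rate))
    if peak <= background:
        return []
    hot = np.nan_to_num(rate) >= background + threshold_fraction * (peak - background)
    labels, n_lab = ndimage.label(hot)
    max_bins = max_area_fraction * tmap.visited_mask.size
    fields = []
    for lab in range(1, n_lab + 1):
        sel = labels == lab
        k = int(sel.sum())
        if k < min_area_bins or k > max_bins:
            continue
        ii, jj = np.nonzero(sel)
        w = np.nan_to_num(rate[sel])
        tot = w.sum()
        cx = float(((ii + 0.5) * tmap.bin_size * w).sum() / tot)
        cy = float(((jj + 0.5) * tmap.bin_size * w).sum() / tot)
        p = float(np.nanmax(rate[sel]))
        fields.append(
            PlaceField(
                bins=np.column_stack([ii, jj]),
                centroid=(cx, cy),
                peak_rate=p,
                area=k * tmap.bin_size**2,
            )
        )
    def sort_key(f: PlaceField):
        i_pk = int(np.argmax([tmap.rate[i, j] for i, j in f.bins]))
        pi, pj = f.bins[i_pk]
        return (-f.peak_rate, -f.area, int(pi), int(pj))
    fields.sort(key=sort_key)
    return fields


def field_centroid(field: PlaceField) -> tuple[float, float]:
    return field.centroid


def main_field(fields: list[PlaceField]) -> PlaceField | None:
    """Highest-peak field (ties: larger area, then lowest (row, col))."""
    return fields[0] if fields else None


def center_of_mass(tmap: TuningMap) -> tuple[float, float]:
    """Rate-weighted mean position over the whole visited map (cm)."""
    rate = np.where(tmap.visited_mask, np.nan_to_num(tmap.rate), 0.0)
    tot = rate.sum()
    if tot == 0:
        raise DegenerateInputError("all-zero map has no center of mass")
    ii, jj = np.meshgrid(
        np.arange(tmap.n_bins), np.arange(tmap.n_bins), indexing="ij"
    )
    cx = ((ii + 0.5) * tmap.bin_size * rate).sum() / tot
    cy = ((jj + 0.5) * tmap.bin_size * rate).sum() / tot
    return float(cx), float(cy)


def spatial_information(tmap: TuningMap, *, use_raw: bool = False) -> float:
    """Spatial information in bits per event (Skaggs-style).

    SI = Σ_i p_i (λ_i/λ̄) log2(λ_i/λ̄) with p_i the occupancy share of
    bin i and λ̄ the occupancy-weighted mean rate; zero-rate bins
    contribute nothing.
    """
    rate = tmap.raw_rate if (use_raw and tmap.raw_rate is not None) else tmap.rate
    m = tmap.visited_mask
    occ = tmap.occupancy[m]
    lam = np.nan_to_num(rate[m])
    p = occ / occ.sum()
    lam_bar = float((p * lam).sum())
    if lam_bar <= 0:
        raise DegenerateInputError("mean rate is zero; SI undefined")
    pos = lam > 0
    ratio = lam[pos] / lam_bar
    return float((p[pos] * ratio * np.log2(ratio)).sum())
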