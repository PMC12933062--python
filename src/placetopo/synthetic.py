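"""Synthetic place-cell and object-cell session generator.

The generator emulates the ingredients of a miniaturized two-photon
recording from hippocampal CA1 during free foraging: an animal trajectory
in a square arena, a population of cells with Gaussian place fields and
anatomical soma positions inside a ~350 µm field of view, deconvolved
calcium event trains driven by position (inhomogeneous Poisson), a
surrogate ΔF/F trace (events convolved with a GCaMP-like exponential
kernel plus white noise), remapping session pairs, and object sessions
with vector-tuned cells.

A single knob — :class:`ClusteringConfig` — injects an optional coupling
between anatomical distance and place-field distance. With
``coupling_lambda = 0`` the anatomical and functional layouts are
statistically independent (the null every clustering test should fail to
reject); with strong coupling nearby somata acquire nearby fields
(the positive control the tests must detect).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import CellRecording, ParameterError, Trajectory

__all__ = [
    "ArenaSpec",
    "FovSpec",
    "ClusteringConfig",
    "SyntheticCellSpec",
    "simulate_trajectory",
    "place_field_population",
    "generate_events",
    "expected_rate_map",
    "generate_remapping_pair",
    "generate_object_session",
]


@dataclass(frozen=True)
class ArenaSpec:
    """Square open-field arena (default 80 cm × 80 cm, 50 cm walls)."""

    side_length: float = 80.0  # cm
    wall_height: float = 50.0  # cm, metadata only

    def __post_init__(self) -> None:
        if self.side_length <= 0:
            raise ParameterError("arena side_length must be positive")


@dataclass(frozen=True)
class FovSpec:
    """Imaging field of view (default 350 µm × 350 µm)."""

    width: float = 350.0  # µm
    height: float = 350.0  # µm

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ParameterError("FOV extents must be positive")


@dataclass(frozen=True)
class ClusteringConfig:
    """Anatomy→field coupling (the alternative hypothesis).

    coupling_lambda : float in [0, 1]
        0 yields fully distributed (independent) field positions; 1 makes
        each cell's field fully determined by its anatomical neighbourhood.
    cluster_scale : float, µm
        Anatomical range over which the coupling acts.
    """

    coupling_lambda: float = 0.0
    cluster_scale: float = 100.0

    def __post_init__(self) -> None:
        if self.coupling_lambda < 0:
            raise ParameterError("coupling_lambda must be >= 0")
        if self.cluster_scale <= 0:
            raise ParameterError("cluster_scale must be positive")


@dataclass
class SyntheticCellSpec:
    """Generative description of one synthetic cell.

    ``field_centroids`` lists 1–2 Gaussian place-field centres in arena
    cm; the first entry is the main field. ``object_vector`` holds an
    optional (preferred_distance cm, preferred_angle deg) landmark-vector
    tuning; angle is allocentric, 0° = arena east, counter-clockwise.
    """

    cell_id: int
    anatomical_centroid: tuple[float, float]  # µm in FOV
    field_centroids: list[tuple[float, float]] = field(default_factory=list)
    field_width_sigma: float = 7.0  # cm
    peak_event_rate: float = 2.0  # events/s
    active: bool = True
    object_vector: tuple[float, float] | None = None
    object_peak_rate: float = 2.0  # events/s of the object-vector bump

    def __post_init__(self) -> None:
        if self.field_width_sigma <= 0:
            raise ParameterError("field_width_sigma must be positive")
        if self.peak_event_rate < 0:
            raise ParameterError("peak_event_rate must be >= 0")


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------

def simulate_trajectory(
    arena: ArenaSpec,
    duration: float,
    mean_speed: float = 10.0,
    *,
    frame_rate: float = 15.0,
    theta: float = 0.5,
    seed: int | None = None,
) -> Trajectory:
    """Simulate free foraging as a smoothed random walk.

    Velocity follows a 2D Ornstein–Uhlenbeck process (relaxation rate
    ``theta`` per second) whose stationary distribution is tuned so the
    mean scalar speed equals ``mean_speed``; positions reflect off the
    arena walls. Sampled at ``frame_rate`` Hz.

    With the defaults, a 35-min session visits >95% of the 2.5 cm bins
    of an 80 cm arena.
    """
    if duration <= 0:
        raise ParameterError("duration must be positive")
    if mean_speed <= 0:
        raise ParameterError("mean_speed must be positive")
    rng = np.random.default_rng(seed)
    dt = 1.0 / frame_rate
    n = int(round(duration * frame_rate)) + 1
    side = arena.side_length

    # mean of a 2D Gaussian speed (Rayleigh) is sigma_v * sqrt(pi/2)
    sigma_v = mean_speed / np.sqrt(np.pi / 2)
    diff = sigma_v * np.sqrt(2.0 * theta)

    # pre-draw all noise, then integrate with wall reflection
    noise = rng.normal(0.0, diff * np.sqrt(dt), size=(n - 1, 2))
    v = rng.normal(0.0, sigma_v, size=2)
    p = rng.uniform(0.0, side, size=2)
    pos = np.empty((n, 2))
    pos[0] = p
    for i in range(1, n):
        v = v - theta * v * dt + noise[i - 1]
        p = p + v * dt
        for k in (0, 1):
            if p[k] < 0.0:
                p[k] = -p[k]
                v[k] = -v[k]
            elif p[k] > side:
                p[k] = 2.0 * side - p[k]
                v[k] = -v[k]
            # a huge step could still escape; clamp defensively
            p[k] = min(max(p[k], 0.0), side)
        pos[i] = p
    t = np.arange(n) * dt
    return Trajectory(t=t, x=pos[:, 0], y=pos[:, 1])


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def _dart_throw(rng, n, width, height, min_spacing, max_tries=20000):
    pts: list[np.ndarray] = []
    arr = np.empty((0, 2))
    tries = 0
    while len(pts) < n:
        c = rng.uniform((0.0, 0.0), (width, height))
        if arr.size == 0 or np.min(np.hypot(*(arr - c).T)) >= min_spacing:
            pts.append(c)
            arr = np.asarray(pts)
        tries += 1
        if tries > max_tries:
            raise ParameterError(
                f"cannot place {n} somata with {min_spacing} µm spacing "
                f"in a {width}×{height} µm FOV"
            )
    return arr


def place_field_population(
    n_cells: int,
    arena: ArenaSpec = ArenaSpec(),
    fov: FovSpec = FovSpec(),
    active_fraction: float = 0.35,
    clustering: ClusteringConfig = ClusteringConfig(),
    *,
    min_spacing: float = 10.0,
    two_field_prob: float = 0.2,
    field_sigma: float = 7.0,
    peak_rate: float = 1.2,
    peak_rate_sigma: float = 0.7,
    seed: int | None = None,
) -> list[SyntheticCellSpec]:
    """Draw a population of synthetic cells.

    Somata are placed uniformly in the FOV with a hard minimum spacing
    (soma scale, default 10 µm). Main place-field centroids are uniform
    over the arena when ``clustering.coupling_lambda == 0``. With
    coupling λ > 0, topography is injected as anatomical patches:
    cluster anchors are scattered over the FOV (≈ one per
    (2·cluster_scale)² µm²), each with its own uniformly drawn field
    anchor; a cell within ``cluster_scale`` of its nearest anchor draws
    its field as the convex mixture

        λ · (anchor_field + g · (own_soma − anchor_soma)) + (1 − λ) · uniform,

    where g maps FOV µm onto arena cm, while cells outside every patch
    draw uniformly. Inside a patch the gradient term makes expected
    field distance grow with anatomical distance, so λ is a single
    monotone clustering knob and the patchwork makes functional
    similarity spatially heterogeneous — the 'local clusters of
    similarly tuned cells' alternative.
    """
    if not (0.0 < active_fraction <= 1.0):
        raise ParameterError("active_fraction must be in (0, 1]")
    if n_cells < 1:
        raise ParameterError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    anat = _dart_throw(rng, n_cells, fov.width, fov.height, min_spacing)

    side = arena.side_length
    lam = min(clustering.coupling_lambda, 1.0)
    scale = clustering.cluster_scale
    grad = side / max(fov.width, fov.height)

    fields_main = rng.uniform(0.0, side, size=(n_cells, 2))
    if lam > 0.0:
        n_anchors = max(1, int(round(fov.width * fov.height / (2.0 * scale) ** 2)))
        anchor_xy = rng.uniform((0.0, 0.0), (fov.width, fov.height), size=(n_anchors, 2))
        anchor_field = rng.uniform(0.0, side, size=(n_anchors, 2))
        d = np.linalg.norm(anat[:, None, :] - anchor_xy[None, :, :], axis=2)
        nearest = d.argmin(1)
        in_patch = d[np.arange(n_cells), nearest] <= scale
        tgt = anchor_field[nearest] + grad * (anat - anchor_xy[nearest])
        fields_main[in_patch] = np.clip(
            lam * tgt[in_patch] + (1.0 - lam) * fields_main[in_patch], 0.0, side
        )

    active = rng.random(n_cells) < active_fraction
    n_two = rng.random(n_cells) < two_field_prob
    # per-cell rate heterogeneity: lognormal with median `peak_rate`
    rates = (
        rng.lognormal(np.log(peak_rate), peak_rate_sigma, size=n_cells)
        if peak_rate_sigma > 0
        else np.full(n_cells, peak_rate)
    )
    cells = []
    for i in range(n_cells):
        centers = [tuple(fields_main[i])]
        if n_two[i]:
            centers.append(tuple(rng.uniform(0.0, side, size=2)))
        cells.append(
            SyntheticCellSpec(
                cell_id=i,
                anatomical_centroid=tuple(anat[i]),
                field_centroids=centers,
                field_width_sigma=field_sigma,
                peak_event_rate=float(rates[i]),
                active=bool(active[i]),
            )
        )
    return cells


# ---------------------------------------------------------------------------
# events / traces
# ---------------------------------------------------------------------------

def _field_intensity(cell: SyntheticCellSpec, x, y, object_xy=None):
    """Event intensity (events/s) at positions (x, y), excluding noise.

    Place fields scale with the cell's ``peak_event_rate``; the
    object-vector bump (present only when an object is in the arena) has
    its own ``object_peak_rate`` — an object-tuned cell responds to the
    object regardless of how active its place fields are.
    """
    x = np.asarray(x, dtype=float)
    s2 = 2.0 * cell.field_width_sigma**2
    lam = np.zeros_like(x)
    if cell.active:
        for cx, cy in cell.field_centroids:
            lam = lam + cell.peak_event_rate * np.exp(
                -((x - cx) ** 2 + (y - cy) ** 2) / s2
            )
    if object_xy is not None and cell.object_vector is not None:
        d, ang = cell.object_vector
        a = np.deg2rad(ang)
        cx = object_xy[0] + d * np.cos(a)
        cy = object_xy[1] + d * np.sin(a)
        lam = lam + cell.object_peak_rate * np.exp(
            -((x - cx) ** 2 + (y - cy) ** 2) / s2
        )
    return lam


def generate_events(
    cell: SyntheticCellSpec,
    traj: Trajectory,
    noise_rate: float = 0.2,
    *,
    object_xy: tuple[float, float] | None = None,
    calcium_tau: float = 1.5,
    dff_noise_sigma: float = 0.1,
    dff_gain: float = 0.2,
    seed: int | None = None,
) -> CellRecording:
    """Draw a deconvolved event train and a surrogate ΔF/F trace.

    Events follow an inhomogeneous Poisson process whose intensity is the
    sum of Gaussian bumps over the cell's fields (scaled by
    ``peak_event_rate``) plus a position-independent ``noise_rate``.
    Event amplitudes are exponential with mean 1. The surrogate ΔF/F is
    the amplitude train convolved with a single-exponential calcium
    kernel (τ default 1.5 s, GCaMP6s scale) plus white noise.
    """
    if traj.n_samples == 0:
        raise ParameterError("trajectory must be non-empty")
    if noise_rate < 0:
        raise ParameterError("noise_rate must be >= 0")
    rng = np.random.default_rng(seed)
    dt = traj.dt if traj.n_samples > 1 else 1.0

    lam = _field_intensity(cell, traj.x, traj.y, object_xy=object_xy) + noise_rate
    counts = rng.poisson(lam * dt)
    frames = np.repeat(np.arange(traj.n_samples), counts)
    n_ev = frames.size
    events_t = traj.t[frames] + rng.uniform(0.0, dt, size=n_ev)
    # keep timestamps inside the session
    events_t = np.minimum(events_t, traj.t[-1])
    order = np.argsort(events_t, kind="stable")
    events_t = events_t[order]
    frames = frames[order]
    events_amp = rng.exponential(1.0, size=n_ev)

    # surrogate ΔF/F: amplitude train * exp kernel + white noise
    amp_per_frame = np.zeros(traj.n_samples)
    np.add.at(amp_per_frame, frames, events_amp)
    k_len = int(np.ceil(5 * calcium_tau / dt)) + 1
    kernel = dff_gain * np.exp(-np.arange(k_len) * dt / calcium_tau)
    dff = np.convolve(amp_per_frame, kernel)[: traj.n_samples]
    dff = dff + rng.normal(0.0, dff_noise_sigma, size=traj.n_samples)

    return CellRecording(
        cell_id=cell.cell_id,
        dff=dff,
        events_t=events_t,
        events_amp=events_amp,
        centroid=cell.anatomical_centroid,
    )


def expected_rate_map(
    cell: SyntheticCellSpec,
    arena: ArenaSpec = ArenaSpec(),
    bin_size: float = 2.5,
    *,
    noise_rate: float = 0.0,
    object_xy: tuple[float, float] | None = None,
) -> np.ndarray:
    """Noise-free expected event-rate map of a cell on the arena grid.

    Evaluates the generative intensity at bin centres — the map an
    infinitely long session would converge to. Useful for fast,
    simulation-free calibration of map-level statistics.
    """
    n_bins = int(np.ceil(arena.side_length / bin_size))
    centers = (np.arange(n_bins) + 0.5) * bin_size
    gx, gy = np.meshgrid(centers, centers, indexing="ij")
    return _field_intensity(cell, gx, gy, object_xy=object_xy) + noise_rate


# ---------------------------------------------------------------------------
# remapping & objects
# ---------------------------------------------------------------------------

def generate_remapping_pair(
    base_population: list[SyntheticCellSpec],
    mode: str,
    arena: ArenaSpec = ArenaSpec(),
    active_fraction: float | None = None,
    *,
    seed: int | None = None,
) -> tuple[list[SyntheticCellSpec], list[SyntheticCellSpec]]:
    """Derive an (A, B) session pair from a base population.

    mode='orthogonal' models global remapping: B redraws every field
    centroid uniformly and redraws the active subset, independent of A.
    mode='preserved' models re-exposure to the same environment (A–A′):
    identical field layout and active flags; only event noise differs
    when events are regenerated.
    """
    if mode not in ("orthogonal", "preserved"):
        raise ParameterError(f"unknown remapping mode: {mode!r}")
    a = [replace(c, field_centroids=list(c.field_centroids)) for c in base_population]
    if mode == "preserved":
        b = [replace(c, field_centroids=list(c.field_centroids)) for c in base_population]
        return a, b
    rng = np.random.default_rng(seed)
    if active_fraction is None:
        active_fraction = float(np.mean([c.active for c in base_population]))
    b = []
    for c in base_population:
        centers = [tuple(rng.uniform(0.0, arena.side_length, 2)) for _ in c.field_centroids]
        b.append(
            replace(
                c,
                field_centroids=centers,
                active=bool(rng.random() < active_fraction),
            )
        )
    return a, b


def generate_object_session(
    base_population: list[SyntheticCellSpec],
    object_xy: tuple[float, float],
    object_fraction: float = 0.1,
    arena: ArenaSpec = ArenaSpec(),
    *,
    distance_scale: float = 12.0,
    object_peak_rate: float = 2.0,
    seed: int | None = None,
) -> list[SyntheticCellSpec]:
    """Inject landmark-vector tuning into a fraction of cells.

    A ``object_fraction`` subset of cells gains an additive intensity
    bump at ``object_xy + preferred_vector``. Preferred angles are drawn
    uniformly on the circle and preferred distances from an exponential
    (scale ``distance_scale`` cm, matching the skew of empirical
    object-field distances). The vector is stored on the spec, so moving
    the object moves the bump coherently; non-object cells are returned
    unchanged (copies).
    """
    side = arena.side_length
    if not (0.0 <= object_xy[0] <= side and 0.0 <= object_xy[1] <= side):
        raise ParameterError("object position outside arena")
    if not (0.0 <= object_fraction <= 1.0):
        raise ParameterError("object_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    n = len(base_population)
    is_obj = rng.random(n) < object_fraction
    for c, flag in zip(base_population, is_obj):
        c2 = replace(c, field_centroids=list(c.field_centroids))
        if flag:
            ang = rng.uniform(0.0, 360.0)
            dist = min(rng.exponential(distance_scale), side / 2)
            c2.object_vector = (float(dist), float(ang))
            c2.object_peak_rate = object_peak_rate
        out.append(c2)
    return out
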