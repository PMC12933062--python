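"""Place-cell classification.

A cell is a place cell in an environment when (i) the spatial
information of its tuning map exceeds the 95th percentile of maps built
from circularly time-shifted event trains, (ii) its within-session
split-half stability (odd vs even 1-min blocks) exceeds a threshold,
and (iii) it has at least one detected place field. Cells must already
have passed the SNR/event-count inclusion filters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CellRecording, DegenerateInputError, ParameterError, Trajectory
from .synthetic import ArenaSpec
from . import tuning as tn

__all__ = [
    "PlaceCellRecord",
    "shuffle_events",
    "shuffle_si_distribution",
    "split_half_stability",
    "classify_place_cell",
    "stable_in_both",
    "classification_table",
]


@dataclass
class PlaceCellRecord:
    cell_id: int
    is_place_cell: bool
    si_value: float
    si_shuffle_threshold: float
    stability_r: float
    n_fields: int
    main_field_centroid: tuple[float, float] | None
    tmap: "tn.TuningMap | None" = None


def shuffle_events(
    events_t: np.ndarray,
    traj: Trajectory,
    n_shuffles: int = 1000,
    min_shift: float = 30.0,
    seed: int | None = None,
) -> np.ndarray:
    """Circularly shift event times; one row per shuffle.

    Shifts are uniform in [min_shift, duration − min_shift], so no
    shuffle reproduces the original alignment while inter-event
    structure is preserved.
    """
    events_t = np.asarray(events_t, dtype=float)
    dur = traj.duration
    if dur <= 2 * min_shift:
        raise ParameterError("session shorter than twice the minimum shift")
    rng = np.random.default_rng(seed)
    shifts = rng.uniform(min_shift, dur - min_shift, size=n_shuffles)
    t0 = traj.t[0]
    return (events_t[None, :] - t0 + shifts[:, None]) % dur + t0


def shuffle_si_distribution(
    traj: Trajectory,
    events_t: np.ndarray,
    events_amp: np.ndarray,
    arena: ArenaSpec = ArenaSpec(),
    *,
    bin_size: float = 2.5,
    smoothing_sigma: float = 2.5,
    v_min: float = 2.0,
    n_shuffles: int = 1000,
    min_shift: float = 30.0,
    seed: int | None = None,
) -> tuple[float, np.ndarray]:
    """Observed SI and its circular-shift null distribution.

    Implemented on pre-binned frame indices so the full shuffle loop
    costs one bincount + one smoothing pass per shuffle. SI is computed
    on the smoothed maps, matching :func:`placetopo.tuning.spatial_information`.
    """
    from scipy.ndimage import gaussian_filter

    events_t = np.asarray(events_t, dtype=float)
    events_amp = np.asarray(events_amp, dtype=float)
    n_bins = int(np.ceil(arena.side_length / bin_size))
    frame_keep, _ = tn.speed_filter(traj, events_t, v_min)
    flat = tn.bin_indices(traj, arena, bin_size)
    dt = traj.dt
    occ = np.bincount(flat[frame_keep], minlength=n_bins * n_bins).astype(float) * dt
    visited = (occ > 0).reshape(n_bins, n_bins)
    m = occ > 0
    p = occ[m] / occ[m].sum()
    # smoothing denominator is shuffle-invariant: precompute once
    den = gaussian_filter(visited.astype(float), smoothing_sigma, mode="reflect")

    def si_for(times: np.ndarray) -> float:
        frames = tn.assign_frames(traj, times)
        keep = frame_keep[frames]
        amp = np.bincount(
            flat[frames[keep]], weights=events_amp[keep], minlength=n_bins * n_bins
        )
        raw = np.zeros(n_bins * n_bins)
        raw[m] = amp[m] / occ[m]
        num = gaussian_filter(raw.reshape(n_bins, n_bins), smoothing_sigma, mode="reflect")
        lam = (num / np.maximum(den, 1e-12)).reshape(-1)[m]
        lam_bar = float((p * lam).sum())
        if lam_bar <= 0:
            return 0.0
        pos = lam > 0
        ratio = lam[pos] / lam_bar
        return float((p[pos] * ratio * np.log2(ratio)).sum())

    observed = si_for(events_t)
    shuffled = shuffle_events(events_t, traj, n_shuffles, min_shift, seed)
    null = np.array([si_for(row) for row in shuffled])
    return observed, null


def split_half_stability(
    traj: Trajectory,
    events_t: np.ndarray,
    events_amp: np.ndarray,
    arena: ArenaSpec = ArenaSpec(),
    *,
    block_s: float = 60.0,
    **map_kw,
) -> float:
    """Pearson correlation of tuning maps from interleaved 1-min blocks.

    Odd-numbered blocks form one half-session, even-numbered the other;
    NaN when either half lacks coverage or variance.
    """
    if traj.duration < 600.0:
        raise ParameterError("split-half stability needs a session of >= 10 min")
    events_t = np.asarray(events_t, dtype=float)
    events_amp = np.asarray(events_amp, dtype=float)
    block_of_frame = ((traj.t - traj.t[0]) // block_s).astype(int)
    ev_blocks = ((events_t - traj.t[0]) // block_s).astype(int)

    maps = []
    for parity in (0, 1):
        fsel = block_of_frame % 2 == parity
        esel = ev_blocks % 2 == parity
        sub = Trajectory(t=traj.t[fsel], x=traj.x[fsel], y=traj.y[fsel])
        try:
            maps.append(
                tn.compute_tuning_map(
                    sub, events_t[esel], events_amp[esel], arena, **map_kw
                )
            )
        except DegenerateInputError:
            return float("nan")
    try:
        return tn.map_correlation(maps[0], maps[1])
    except Exception:
        return float("nan")


def classify_place_cell(
    cell: CellRecording,
    traj: Trajectory,
    arena: ArenaSpec = ArenaSpec(),
    *,
    n_shuffles: int = 1000,
    min_shift: float = 30.0,
    si_percentile: float = 95.0,
    r_min: float = 0.3,
    v_min: float = 2.0,
    bin_size: float = 2.5,
    smoothing_sigma: float = 2.5,
    seed: int | None = None,
) -> PlaceCellRecord:
    """Full three-criterion place-cell test for one cell.

    The caller is responsible for applying the SNR/min-event inclusion
    filters first; this function evaluates spatial information against
    its shuffle threshold, split-half stability, and field existence.
    """
    tmap = tn.compute_tuning_map(
        traj, cell.events_t, cell.events_amp, arena,
        bin_size=bin_size, smoothing_sigma=smoothing_sigma, v_min=v_min,
    )
    si, null = shuffle_si_distribution(
        traj, cell.events_t, cell.events_amp, arena,
        bin_size=bin_size, smoothing_sigma=smoothing_sigma, v_min=v_min,
        n_shuffles=n_shuffles, min_shift=min_shift, seed=seed,
    )
    thresh = float(np.percentile(null, si_percentile))
    stab = split_half_stability(
        traj, cell.events_t, cell.events_amp, arena,
        bin_size=bin_size, smoothing_sigma=smoothing_sigma, v_min=v_min,
    )
    fields = tn.detect_fields(tmap)
    mf = tn.main_field(fields)
    is_pc = bool(si > thresh and np.isfinite(stab) and stab > r_min and fields)
    return PlaceCellRecord(
        cell_id=cell.cell_id,
        is_place_cell=is_pc,
        si_value=si,
        si_shuffle_threshold=thresh,
        stability_r=float(stab) if np.isfinite(stab) else float("nan"),
        n_fields=len(fields),
        main_field_centroid=mf.centroid if mf else None,
        tmap=tmap,
    )


def stable_in_both(record_a: PlaceCellRecord, record_b: PlaceCellRecord) -> bool:
    """Cell qualifies for cross-environment analyses iff it is a
    classified place cell in both environments."""
    return bool(record_a.is_place_cell and record_b.is_place_cell)


def classification_table(records: dict[str, list[PlaceCellRecord]]) -> pd.DataFrame:
    """Tidy table of classification results keyed by environment label."""
    rows = []
    for env, recs in records.items():
        for r in recs:
            rows.append(
                {
                    "cell_id": r.cell_id,
                    "environment": env,
                    "si": r.si_value,
                    "si_threshold": r.si_shuffle_threshold,
                    "stability": r.stability_r,
                    "n_fields": r.n_fields,
                    "is_place_cell": r.is_place_cell,
                }
            )
    return pd.DataFrame(rows)
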