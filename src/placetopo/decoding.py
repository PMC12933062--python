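"""Bayesian position decoding from deconvolved events.

A naive-Bayes (Poisson) decoder: the session is cut into temporal bins
(default 0.5 s) that alternate train/test; per-cell expected event
rates per spatial bin are fit on the training bins only, and each test
bin's position is decoded as the posterior argmax over spatial bins,

    log P(bin | k) = log prior(bin) + Σ_cells [k_c log(λ_c Δt) − λ_c Δt],

with k_c the summed deconvolved event amplitude of cell c in the test
bin (a non-negative real, used via the continuous extension of the
Poisson log-likelihood; the k-dependent Stirling term is constant
across spatial bins and dropped). The clustering question enters
through :func:`local_vs_random_decoding`: if nearby cells were
functionally redundant, anatomically local subsets would decode worse
than size-matched random subsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DataError, ParameterError, Trajectory
from .synthetic import ArenaSpec
from . import tuning as tn

__all__ = [
    "DecoderModel",
    "DecodingResult",
    "fit_decoder",
    "decode",
    "decoding_error_for_subset",
    "local_vs_random_decoding",
    "similar_tuning_subset_control",
    "chance_distance",
]

RATE_FLOOR = 1e-3  # events/s per spatial bin, avoids log(0)


@dataclass
class DecoderModel:
    rates: np.ndarray  # (n_cells, n_bins) expected event rate per spatial bin
    prior: np.ndarray  # (n_bins,) training-occupancy prior, sums to 1
    bin_width: float  # s, temporal
    bin_size: float  # cm, spatial
    n_bins_axis: int
    train_mask: np.ndarray  # per temporal bin
    temporal_edges: np.ndarray
    true_xy: np.ndarray  # (n_temporal_bins, 2) mean position per bin
    valid_bins: np.ndarray  # temporal bins passing the speed filter


@dataclass
class DecodingResult:
    decoded_xy: np.ndarray
    true_xy: np.ndarray
    errors: np.ndarray  # cm
    median_error: float
    n_cells: int


def _temporal_binning(traj: Trajectory, bin_width: float, v_min: float):
    edges = np.arange(traj.t[0], traj.t[-1] + bin_width, bin_width)
    n_tb = len(edges) - 1
    frame_bin = np.clip(
        np.searchsorted(edges, traj.t, side="right") - 1, 0, n_tb - 1
    )
    speed_ok = traj.speed() >= v_min if v_min > 0 else np.ones(traj.n_samples, bool)
    true_xy = np.full((n_tb, 2), np.nan)
    valid = np.zeros(n_tb, bool)
    for b in range(n_tb):
        sel = (frame_bin == b) & speed_ok
        if sel.any():
            true_xy[b] = (traj.x[sel].mean(), traj.y[sel].mean())
            valid[b] = True
    return edges, frame_bin, speed_ok, true_xy, valid


def fit_decoder(
    cells: list,
    traj: Trajectory,
    arena: ArenaSpec = ArenaSpec(),
    *,
    bin_width: float = 0.5,
    bin_size: float = 2.5,
    smoothing_sigma: float = 2.5,
    v_min: float = 2.0,
) -> DecoderModel:
    """Fit per-cell rate maps and the occupancy prior on alternate
    temporal bins (even-index bins train, odd-index bins test).

    ``cells`` are :class:`placetopo.core.CellRecording` objects. The
    speed filter applies to training and test frames alike.
    """
    edges, frame_bin, speed_ok, true_xy, valid = _temporal_binning(
        traj, bin_width, v_min
    )
    n_tb = len(edges) - 1
    train_mask = np.arange(n_tb) % 2 == 0
    if train_mask.sum() < 100:
        raise ParameterError("session too short: need >= 100 training bins")

    train_frames = train_mask[frame_bin] & speed_ok
    if not train_frames.any():
        raise DataError("no usable training frames")
    sub = Trajectory(t=traj.t[train_frames], x=traj.x[train_frames], y=traj.y[train_frames])

    n_axis = int(np.ceil(arena.side_length / bin_size))
    rates = np.empty((len(cells), n_axis * n_axis))
    flat = tn.bin_indices(sub, arena, bin_size)
    dt = traj.dt
    occ = np.bincount(flat, minlength=n_axis * n_axis).astype(float) * dt
    visited = (occ > 0).reshape(n_axis, n_axis)
    for c_idx, cell in enumerate(cells):
        frames_all = tn.assign_frames(traj, cell.events_t)
        keep = train_frames[frames_all]
        sub_frames = tn.assign_frames(sub, cell.events_t[keep])
        amp = np.bincount(
            flat[sub_frames], weights=cell.events_amp[keep], minlength=n_axis * n_axis
        )
        raw = np.zeros(n_axis * n_axis)
        m = occ > 0
        raw[m] = amp[m] / occ[m]
        sm = tn.smooth_masked(raw.reshape(n_axis, n_axis), visited, smoothing_sigma)
        rates[c_idx] = np.maximum(np.nan_to_num(sm.reshape(-1)), RATE_FLOOR)
    # unvisited bins get the floor rate and zero prior
    prior = occ / occ.sum()
    return DecoderModel(
        rates=rates,
        prior=prior,
        bin_width=bin_width,
        bin_size=bin_size,
        n_bins_axis=n_axis,
        train_mask=train_mask,
        temporal_edges=edges,
        true_xy=true_xy,
        valid_bins=valid,
    )


def _event_counts_per_temporal_bin(cells, edges) -> np.ndarray:
    """(n_cells, n_temporal_bins) summed event amplitudes."""
    n_tb = len(edges) - 1
    counts = np.zeros((len(cells), n_tb))
    for i, cell in enumerate(cells):
        tb = np.clip(np.searchsorted(edges, cell.events_t, side="right") - 1, 0, n_tb - 1)
        np.add.at(counts[i], tb, cell.events_amp)
    return counts


def decode(
    model: DecoderModel,
    cells: list,
    *,
    cell_subset: np.ndarray | None = None,
    return_posterior: bool = False,
) -> DecodingResult:
    """Decode position in every valid test bin.

    Posterior per test bin ∝ prior × Π_c Poisson(k_c; λ_c Δt); decoded
    position is the argmax bin center (ties resolved to the lowest
    (row, col) index by C-order argmax). Log-domain computation.
    """
    if cell_subset is None:
        cell_subset = np.arange(len(cells))
    cell_subset = np.asarray(cell_subset, dtype=int)
    if cell_subset.size == 0:
        raise ParameterError("empty cell subset")
    test_bins = np.flatnonzero(~model.train_mask & model.valid_bins)
    if test_bins.size == 0:
        raise DataError("no valid test bins")
    counts = _event_counts_per_temporal_bin(
        [cells[i] for i in cell_subset], model.temporal_edges
    )[:, test_bins]
    lam = model.rates[cell_subset] * model.bin_width  # (n_sub, n_bins)
    log_lam = np.log(lam)
    with np.errstate(divide="ignore"):
        log_prior = np.where(model.prior > 0, np.log(model.prior), -np.inf)
    # (n_test, n_bins)
    log_post = counts.T @ log_lam - lam.sum(0)[None, :] + log_prior[None, :]
    best = np.argmax(log_post, axis=1)
    n_axis = model.n_bins_axis
    bx = (best // n_axis + 0.5) * model.bin_size
    by = (best % n_axis + 0.5) * model.bin_size
    decoded = np.column_stack([bx, by])
    true = model.true_xy[test_bins]
    errors = np.hypot(*(decoded - true).T)
    result = DecodingResult(
        decoded_xy=decoded,
        true_xy=true,
        errors=errors,
        median_error=float(np.median(errors)),
        n_cells=int(cell_subset.size),
    )
    if return_posterior:
        post = np.exp(log_post - log_post.max(axis=1, keepdims=True))
        result.posterior = post / post.sum(axis=1, keepdims=True)  # type: ignore[attr-defined]
    return result


def decoding_error_for_subset(model, cells, subset) -> float:
    return decode(model, cells, cell_subset=np.asarray(subset)).median_error


def local_vs_random_decoding(
    model: DecoderModel,
    cells: list,
    anatomical_xy: np.ndarray,
    *,
    n_ref: int = 200,
    radii: np.ndarray | None = None,
    n_random: int = 25,
    min_cells: int = 2,
    seed: int | None = None,
) -> pd.DataFrame:
    """Decoding error of anatomically local vs size-matched random subsets.

    For each of ``n_ref`` reference cells (sampled without replacement
    if the roster is smaller) and each anatomical radius, decodes from
    the cells within the radius of the reference soma and from
    ``n_random`` random subsets of equal size. Radius entries with fewer
    than ``min_cells`` members are skipped.
    """
    if radii is None:
        radii = np.array([25.0, 50.0, 75.0, 100.0, 125.0])
    anatomical_xy = np.asarray(anatomical_xy, dtype=float)
    n = len(cells)
    rng = np.random.default_rng(seed)
    refs = rng.choice(n, size=min(n_ref, n), replace=False)
    rows = []
    for ref in refs:
        d = np.hypot(*(anatomical_xy - anatomical_xy[ref]).T)
        for r in radii:
            local = np.flatnonzero(d <= r)
            if local.size < min_cells:
                continue
            err_local = decoding_error_for_subset(model, cells, local)
            errs_rand = [
                decoding_error_for_subset(
                    model, cells, rng.choice(n, size=local.size, replace=False)
                )
                for _ in range(n_random)
            ]
            rows.append(
                {
                    "reference_cell": int(ref),
                    "radius": float(r),
                    "n_cells": int(local.size),
                    "median_error_local": err_local,
                    "median_error_random_mean": float(np.mean(errs_rand)),
                }
            )
    return pd.DataFrame(rows)


def similar_tuning_subset_control(
    field_xy: np.ndarray,
    k: int,
    *,
    anchor: tuple[float, float] | None = None,
    arena: ArenaSpec = ArenaSpec(),
    seed: int | None = None,
) -> np.ndarray:
    """Indices of the k cells whose main-field centroids are closest to
    a (random) anchor location — a functionally homogeneous subset.

    Decoding from such a subset should be worse than from k random
    cells, because its fields cover only part of the arena.
    """
    field_xy = np.asarray(field_xy, dtype=float)
    if k > len(field_xy):
        raise ParameterError("k exceeds the cell roster")
    if anchor is None:
        rng = np.random.default_rng(seed)
        anchor = tuple(rng.uniform(0.0, arena.side_length, 2))
    d = np.hypot(field_xy[:, 0] - anchor[0], field_xy[:, 1] - anchor[1])
    return np.argsort(d, kind="stable")[:k]


def chance_distance(
    arena: ArenaSpec = ArenaSpec(), n: int = 100_000, seed: int | None = 0
) -> float:
    """Monte-Carlo mean distance between two uniform points in the arena
    (the no-information decoding baseline, ≈ 0.52 × side)."""
    rng = np.random.default_rng(seed)
    a = rng.uniform(0, arena.side_length, (n, 2))
    b = rng.uniform(0, arena.side_length, (n, 2))
    return float(np.mean(np.hypot(*(a - b).T)))
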