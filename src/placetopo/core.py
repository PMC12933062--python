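"""Shared containers and exceptions.

All analyses operate on two primitive records: an animal :class:`Trajectory`
(time-stamped path through the arena) and a :class:`CellRecording` (one
cell's fluorescence trace, deconvolved event train, and anatomical soma
position within the imaging field of view).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ParameterError(ValueError):
    """A caller-supplied parameter violates a precondition."""


class DataError(ValueError):
    """Input data are structurally invalid for the requested operation."""


class DegenerateInputError(DataError):
    """Input is formally valid but carries no usable signal (e.g. a
    constant trace, an all-unvisited map)."""


@dataclass
class Trajectory:
    """Time-stamped 2D path of the animal inside the arena.

    Attributes
    ----------
    t : ndarray
        Sample times in seconds, strictly increasing, uniform spacing.
    x, y : ndarray
        Position in cm.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise DataError("t, x, y must have identical shapes")
        if self.t.ndim != 1 or self.t.size == 0:
            raise DataError("trajectory must be a non-empty 1D time series")

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def dt(self) -> float:
        if self.t.size < 2:
            return 0.0
        return float(np.median(np.diff(self.t)))

    def speed(self, smooth_sigma_s: float = 0.25) -> np.ndarray:
        """Instantaneous speed (cm/s) from Gaussian-smoothed positions.

        Position is smoothed before differentiation so that tracking jitter
        does not inflate speed; the returned array has one entry per sample
        (forward difference, last value repeated).
        """
        from scipy.ndimage import gaussian_filter1d

        if self.t.size < 2:
            return np.zeros_like(self.t)
        dt = self.dt
        sigma_frames = max(smooth_sigma_s / dt, 1e-9)
        xs = gaussian_filter1d(self.x, sigma_frames, mode="nearest")
        ys = gaussian_filter1d(self.y, sigma_frames, mode="nearest")
        v = np.hypot(np.diff(xs), np.diff(ys)) / np.diff(self.t)
        return np.append(v, v[-1])


@dataclass
class CellRecording:
    """One cell's activity within a session.

    Attributes
    ----------
    cell_id : int
    dff : ndarray
        ΔF/F trace, one value per trajectory frame (unitless).
    events_t : ndarray
        Times of deconvolved calcium events, seconds.
    events_amp : ndarray
        Non-negative deconvolved event amplitudes (a.u.).
    centroid : tuple of float
        Anatomical soma centroid (x, y) in µm within the FOV.
    """

    cell_id: int
    dff: np.ndarray
    events_t: np.ndarray
    events_amp: np.ndarray
    centroid: tuple[float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        self.events_t = np.asarray(self.events_t, dtype=float)
        self.events_amp = np.asarray(self.events_amp, dtype=float)
        if self.events_t.shape != self.events_amp.shape:
            raise DataError("event times and amplitudes must align")
        if self.events_amp.size and np.any(self.events_amp < 0):
            raise DataError("event amplitudes must be non-negative")

    @property
    def n_events(self) -> int:
        return self.events_t.size


def derive_seed(master_seed: int, *labels) -> int:
    """Stable per-task seed derived from a master seed and string labels.

    Uses numpy's SeedSequence spawn-key machinery indirectly: labels are
    hashed with a stable (non-salted) scheme so the same (seed, labels)
    always yields the same child seed across processes.
    """
    import zlib

    key = "/".join(str(c) for c in labels).encode()
    mix = zlib.crc32(key) & 0xFFFFFFFF
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, mix])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)
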