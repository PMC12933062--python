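"""Per-cell signal quality control.

SNR is defined on the ΔF/F trace as the mean, over significant calcium
transients, of each transient's 90th-percentile ΔF/F, divided by the
noise level — the mean absolute frame-to-frame difference of ΔF/F
outside transients. Cells enter downstream analyses only with SNR
strictly above 3 and at least 40 deconvolved events per environment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CellRecording, DegenerateInputError

__all__ = [
    "SnrResult",
    "detect_significant_transients",
    "compute_snr",
    "apply_inclusion_filters",
    "qc_report",
]


@dataclass
class SnrResult:
    snr: float
    signal_level: float
    noise_level: float
    transient_mask: np.ndarray
    no_transients: bool = False


def _contiguous_runs(mask: np.ndarray):
    """(start, stop) index pairs of True runs; stop exclusive."""
    if not mask.any():
        return []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def detect_significant_transients(
    dff: np.ndarray,
    *,
    frame_rate: float = 15.0,
    k: float = 3.0,
    min_duration_s: float = 0.5,
    merge_gap_s: float = 0.2,
) -> np.ndarray:
    """Mark contiguous epochs where ΔF/F exceeds k robust-SD of the trace.

    The robust SD is 1.4826×MAD around the median (falling back to the
    plain SD if the MAD is zero). Epochs shorter than ``min_duration_s``
    are dropped; epochs separated by less than ``merge_gap_s`` are merged
    first. The complement of the returned mask defines the noise epochs.
    """
    dff = np.asarray(dff, dtype=float)
    if dff.size < 100:
        raise DegenerateInputError("trace too short for transient detection")
    med = np.median(dff)
    mad = np.median(np.abs(dff - med))
    sigma = 1.4826 * mad
    if sigma == 0.0:
        sigma = float(np.std(dff))
    if sigma == 0.0:
        raise DegenerateInputError("constant trace: no noise scale")

    mask = dff > med + k * sigma

    # merge runs separated by short gaps
    gap = int(round(merge_gap_s * frame_rate))
    runs = _contiguous_runs(mask)
    merged = []
    for start, stop in runs:
        if merged and start - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], stop)
        else:
            merged.append((start, stop))

    min_len = max(int(round(min_duration_s * frame_rate)), 1)
    out = np.zeros(dff.size, dtype=bool)
    for start, stop in merged:
        if stop - start >= min_len:
            out[start:stop] = True
    return out


def compute_snr(dff: np.ndarray, transient_mask: np.ndarray | None = None, **kw) -> SnrResult:
    """SNR = mean per-transient 90th-percentile ΔF/F / noise level.

    The noise level is the mean absolute first difference of ΔF/F over
    frame pairs that both lie outside transients. A cell without any
    detected transient gets SNR 0 and ``no_transients=True`` (it will
    fail the inclusion filter downstream).
    """
    dff = np.asarray(dff, dtype=float)
    if transient_mask is None:
        transient_mask = detect_significant_transients(dff, **kw)
    transient_mask = np.asarray(transient_mask, dtype=bool)

    outside = ~transient_mask
    pair_ok = outside[:-1] & outside[1:]
    if not pair_ok.any():
        raise DegenerateInputError("no noise epochs outside transients")
    noise = float(np.mean(np.abs(np.diff(dff))[pair_ok]))
    if noise == 0.0:
        raise DegenerateInputError("zero noise level outside transients")

    runs = _contiguous_runs(transient_mask)
    if not runs:
        return SnrResult(0.0, 0.0, noise, transient_mask, no_transients=True)
    signal = float(np.mean([np.percentile(dff[a:b], 90) for a, b in runs]))
    return SnrResult(signal / noise, signal, noise, transient_mask)


def apply_inclusion_filters(
    cells: list[CellRecording],
    snr: dict[int, float] | list[float],
    *,
    snr_min: float = 3.0,
    min_events: int = 40,
) -> list[CellRecording]:
    """Keep cells with SNR strictly above ``snr_min`` and at least
    ``min_events`` deconvolved events in the environment."""
    if not isinstance(snr, dict):
        snr = {c.cell_id: s for c, s in zip(cells, snr)}
    return [
        c
        for c in cells
        if snr[c.cell_id] > snr_min and c.n_events >= min_events
    ]


def qc_report(cells: list[CellRecording], **snr_kw) -> pd.DataFrame:
    """Per-cell QC table: cell_id, snr, n_events, included flag."""
    rows = []
    for c in cells:
        try:
            res = compute_snr(c.dff, **snr_kw)
            snr_val = res.snr
        except DegenerateInputError:
            snr_val = 0.0
        rows.append(
            {
                "cell_id": c.cell_id,
                "snr": snr_val,
                "n_events": c.n_events,
                "included": snr_val > 3.0 and c.n_events >= 40,
            }
        )
    return pd.DataFrame(rows)
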