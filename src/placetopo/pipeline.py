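"""End-to-end orchestration and report arithmetic.

:func:`run_pipeline` takes a :class:`placetopo.config.RunConfig`,
generates (or loads) an A/B/A′ session set, runs QC, place-cell
classification, and the clustering battery, and emits CSV/JSON outputs
plus a summary verdict. :func:`simulate_session_set` and
:func:`analyze_population` are the reusable building blocks; both are
deterministic under a fixed master seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as cl
from . import decoding as dec
from . import qc
from . import topography as tp
from . import tuning as tn
from .config import RunConfig
from .core import DataError, ParameterError, derive_seed
from .session import SessionContainer, write_sessions
from . import synthetic as syn

log = logging.getLogger("placetopo")

__all__ = [
    "report_cohort_fractions",
    "simulate_session_set",
    "analyze_population",
    "run_pipeline",
]


def report_cohort_fractions(counts: list[tuple[str, int, int]], decimals: int = 2) -> pd.DataFrame:
    """Percentage table from (label, numerator, denominator) counts."""
    rows = []
    for label, num, den in counts:
        if den <= 0:
            raise ParameterError(f"{label}: zero or negative denominator")
        if num < 0:
            raise ParameterError(f"{label}: negative numerator")
        rows.append(
            {
                "label": label,
                "numerator": num,
                "denominator": den,
                "percent": round(100.0 * num / den, decimals),
            }
        )
    return pd.DataFrame(rows)


def simulate_session_set(cfg: RunConfig, *, mode: str = "orthogonal") -> list[SessionContainer]:
    """Generate an A/B/A′ synthetic session triplet under one config."""
    arena = syn.ArenaSpec(cfg.arena_side)
    fov = syn.FovSpec(cfg.fov_width, cfg.fov_height)
    clustering = syn.ClusteringConfig(cfg.coupling_lambda, cfg.cluster_scale)
    pop_a = syn.place_field_population(
        cfg.n_cells, arena, fov, cfg.active_fraction, clustering,
        min_spacing=cfg.min_spacing, two_field_prob=cfg.two_field_prob,
        field_sigma=cfg.field_sigma, peak_rate=cfg.peak_rate, peak_rate_sigma=cfg.peak_rate_sigma,
        seed=derive_seed(cfg.master_seed, "population"),
    )
    _, pop_b = syn.generate_remapping_pair(
        pop_a, mode, arena, cfg.active_fraction,
        seed=derive_seed(cfg.master_seed, "remap"),
    )
    _, pop_a2 = syn.generate_remapping_pair(pop_a, "preserved", arena)
    sessions = []
    for label, pop in (("A", pop_a), ("B", pop_b), ("A2", pop_a2)):
        traj = syn.simulate_trajectory(
            arena, cfg.duration_s, cfg.mean_speed, frame_rate=cfg.frame_rate,
            seed=derive_seed(cfg.master_seed, "traj", label),
        )
        cells = [
            syn.generate_events(
                c, traj, cfg.noise_rate, calcium_tau=cfg.calcium_tau,
                seed=derive_seed(cfg.master_seed, "events", label, c.cell_id),
            )
            for c in pop
        ]
        sessions.append(
            SessionContainer(
                label=label, traj=traj, cells=cells, arena=arena, fov=fov,
                meta={"config_hash": cfg.hash(), "master_seed": cfg.master_seed},
            )
        )
    return sessions


def analyze_population(
    session: SessionContainer,
    cfg: RunConfig,
    *,
    records: list[cl.PlaceCellRecord] | None = None,
) -> dict:
    """QC → classification → clustering battery for one session.

    Returns a dict with the QC table, classification records, pair
    table, within-bin similarity + size-matched control, global Moran's
    I, expanding-circle profile, and nearest-neighbor comparison.
    """
    out: dict = {}
    report = qc.qc_report(session.cells, frame_rate=cfg.frame_rate)
    out["qc"] = report
    included = [
        c for c in session.cells
        if report.set_index("cell_id").loc[c.cell_id, "included"]
    ]
    log.info("session %s: %d/%d cells pass QC", session.label, len(included), session.n_cells)

    if records is None:
        records = [
            cl.classify_place_cell(
                c, session.traj, session.arena,
                n_shuffles=cfg.n_shuffles, min_shift=cfg.min_shift_s,
                si_percentile=cfg.si_percentile, r_min=cfg.stability_r_min,
                v_min=cfg.v_min, bin_size=cfg.bin_size,
                smoothing_sigma=cfg.smoothing_sigma,
                seed=derive_seed(cfg.master_seed, "shuffle", session.label, c.cell_id),
            )
            for c in included
        ]
    out["records"] = records
    pcs = [r for r in records if r.is_place_cell]
    log.info("session %s: %d place cells", session.label, len(pcs))
    if len(pcs) < 8:
        out["note"] = "too few place cells for the clustering battery"
        return out

    id2cell = {c.cell_id: c for c in session.cells}
    anat = np.array([id2cell[r.cell_id].centroid for r in pcs])
    fields = np.array([r.main_field_centroid for r in pcs])
    maps = [r.tmap for r in pcs]
    corr = tp.pairwise_map_correlations(maps)
    out["pair_table"] = tp.build_pair_table(
        anat, fields, maps, cell_ids=np.array([r.cell_id for r in pcs])
    )
    wb = tp.within_bin_similarity(
        anat, corr, fov_width=session.fov.width, fov_height=session.fov.height,
        n_per_axis=cfg.anat_bins_per_axis, min_cells=cfg.bin_min_cells,
        exclusion=cfg.pair_exclusion_um,
    )
    out["within_bin"] = wb
    if len(wb) >= 8:
        moran = tp.global_morans_i(
            wb[["bin_x", "bin_y"]].to_numpy(), wb["mean_stat"].to_numpy(),
            n_perm=cfg.moran_permutations,
            seed=derive_seed(cfg.master_seed, "moran", session.label),
            style=cfg.moran_weight_style,
            bin_size=session.fov.width / cfg.anat_bins_per_axis,
        )
        out["moran"] = moran
    out["profile"] = tp.expanding_circle_profile(
        anat, corr, n_iter=cfg.control_iterations, n_boot=cfg.n_boot,
        level=cfg.ci_level, seed=derive_seed(cfg.master_seed, "profile", session.label),
    )
    out["nn_table"], out["nn_moran"] = tp.nearest_neighbor_analysis(
        anat, corr, n_perm=cfg.moran_permutations,
        seed=derive_seed(cfg.master_seed, "nn", session.label),
        bin_size=session.fov.width / cfg.anat_bins_per_axis,
    )
    return out


def clustering_verdict(analysis: dict) -> dict:
    """Summarize one session's battery into a clustering verdict."""
    moran_sig = bool(analysis.get("moran") and analysis["moran"].significant)
    prof = analysis.get("profile")
    frac_inside = tp.profile_control_within_ci(prof) if prof is not None else float("nan")
    profile_flag = bool(np.isfinite(frac_inside) and frac_inside < 0.5)
    return {
        "moran_significant": moran_sig,
        "profile_control_within_ci_fraction": frac_inside,
        "clustering_detected": bool(moran_sig and profile_flag),
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Full synthetic-session pipeline; writes outputs under cfg.output_dir."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    sessions = simulate_session_set(cfg)
    write_sessions(outdir / "sessions.h5", sessions)

    summary: dict = {"config_hash": cfg.hash(), "sessions": {}}
    analyses = {}
    for s in sessions:
        try:
            res = analyze_population(s, cfg)
        except (DataError, ParameterError) as exc:
            log.error("session %s failed: %s", s.label, exc)
            summary["sessions"][s.label] = {"error": str(exc)}
            continue
        analyses[s.label] = res
        res["qc"].to_csv(outdir / f"qc_{s.label}.csv", index=False)
        if "pair_table" in res:
            res["pair_table"].to_csv(outdir / f"pairs_{s.label}.csv", index=False)
            res["profile"].to_csv(outdir / f"profile_{s.label}.csv", index=False)
        verdict = clustering_verdict(res)
        if "moran" in res:
            verdict["moran_I"] = res["moran"].I
            verdict["moran_p95"] = res["moran"].p95
        summary["sessions"][s.label] = verdict

    detected = [v.get("clustering_detected", False) for v in summary["sessions"].values()]
    summary["verdict"] = "clustering detected" if any(detected) else "no clustering"

    # decoding comparison on session A place cells
    if "A" in analyses and "pair_table" in analyses["A"]:
        a = sessions[0]
        pcs = [r for r in analyses["A"]["records"] if r.is_place_cell]
        id2cell = {c.cell_id: c for c in a.cells}
        cells = [id2cell[r.cell_id] for r in pcs]
        if len(cells) >= 10:
            model = dec.fit_decoder(
                cells, a.traj, a.arena, bin_width=cfg.decoder_bin_width_s,
                bin_size=cfg.bin_size, smoothing_sigma=cfg.smoothing_sigma,
                v_min=cfg.v_min,
            )
            full = dec.decode(model, cells)
            summary["decoding_median_error_cm"] = full.median_error
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return {"summary": summary, "analyses": analyses, "sessions": sessions}
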