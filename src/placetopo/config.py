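"""Run configuration: every tunable default in one serializable place."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field


@dataclass
class RunConfig:
    """Defaults for a full pipeline run.

    Units: lengths in cm (arena) or µm (FOV), times in s, rates in
    events/s, angles in degrees.
    """

    master_seed: int = 0
    output_dir: str = "placetopo_out"

    # synthetic generation
    n_cells: int = 300
    duration_s: float = 2100.0
    mean_speed: float = 10.0
    frame_rate: float = 15.0
    arena_side: float = 80.0
    fov_width: float = 350.0
    fov_height: float = 350.0
    active_fraction: float = 0.35
    coupling_lambda: float = 0.0
    cluster_scale: float = 100.0
    min_spacing: float = 10.0
    field_sigma: float = 7.0
    peak_rate: float = 1.2
    peak_rate_sigma: float = 0.7
    noise_rate: float = 0.2
    two_field_prob: float = 0.2
    calcium_tau: float = 1.5

    # QC
    snr_min: float = 3.0
    min_events: int = 40
    transient_k: float = 3.0
    transient_min_duration_s: float = 0.5
    transient_merge_gap_s: float = 0.2

    # tuning maps
    bin_size: float = 2.5
    smoothing_sigma: float = 2.5
    sigma_units: str = "bins"
    v_min: float = 2.0
    field_threshold_fraction: float = 0.3
    field_min_area_bins: int = 4
    field_max_area_fraction: float = 0.5

    # classification
    n_shuffles: int = 1000
    min_shift_s: float = 30.0
    si_percentile: float = 95.0
    stability_r_min: float = 0.3

    # clustering battery
    anat_bins_per_axis: int = 8
    bin_min_cells: int = 3
    pair_exclusion_um: float = 15.0
    control_iterations: int = 200
    n_boot: int = 10_000
    ci_level: float = 99.0
    moran_permutations: int = 1000
    moran_weight_style: str = "idw"

    # decoding
    decoder_bin_width_s: float = 0.5
    decoder_n_ref: int = 200
    decoder_n_random: int = 25
    decoder_radii_um: tuple = (25.0, 50.0, 75.0, 100.0, 125.0)

    # object cells
    object_fraction: float = 0.1
    object_d_tol: float = 10.0
    object_a_tol: float = 45.0

    extra: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=list)

    def hash(self) -> str:
        return hashlib.sha1(self.to_json().encode()).hexdigest()[:12]
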