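# Methods

`placetopo` asks one scientific question from several statistical
angles: **are spatially tuned hippocampal neurons anatomically
clustered by their functional tuning?** Every analysis stage is
verifiable end-to-end against a synthetic-data generator whose null
(zero anatomy→field coupling) and alternative (injected topography)
are known by construction.

## The synthetic session model

**Trajectory.** Free foraging in a square arena (default 80 cm × 80 cm)
is modelled as a 2D Ornstein–Uhlenbeck velocity process (relaxation
rate θ = 0.5 s⁻¹) integrated at 15 Hz with reflecting walls. The
stationary speed distribution is Rayleigh; its scale is set so the mean
speed equals the requested value (default 10 cm/s). A 35-min session
visits > 95% of the 1024 2.5-cm bins. θ and the frame rate are
behavioural-realism choices, not fits to any dataset.

**Cells.** Somata are placed uniformly at random in a 350 µm × 350 µm
field of view with a hard 10 µm minimum spacing (soma scale — so the
15 µm pair-exclusion rule downstream is actually exercised). Each cell
carries 1–2 Gaussian place fields (σ = 7 cm; a second field with
probability 0.2), a per-environment active flag (default 35% active,
the empirical range for 80-cm arenas), and a peak event rate drawn
lognormally (median 1.2 events/s, σ_ln = 0.7). The rate heterogeneity
plus a uniform background event rate of 0.2 events/s are what make the
place-cell classifier's yield realistic (~60–90% of field-bearing
cells, rather than 100%).

**Events and traces.** Deconvolved events are an inhomogeneous Poisson
process: intensity = Σ field bumps × peak rate + background. Amplitudes
are exponential with mean 1. The surrogate ΔF/F is the amplitude train
convolved with a single-exponential calcium kernel (τ = 1.5 s, GCaMP6s
scale; gain 0.2) plus white noise (σ = 0.1); these values put the
population mean SNR near 5.8, inside the empirically reported regime.

**Topography injection.** The clustering knob is
`ClusteringConfig(coupling_lambda, cluster_scale)`. With λ = 0,
anatomical and field layouts are independent — the null. With λ > 0
the generator scatters *cluster anchors* over the FOV (≈ one per
(2·cluster_scale)² µm²), each holding a uniformly drawn field anchor;
a cell within `cluster_scale` of its nearest anchor draws its main
field as

    λ · (anchor_field + g · (soma − anchor_soma)) + (1 − λ) · uniform,

with g the FOV→arena scale. Two properties motivated this patch-based
design over a smooth global gradient. First, within a patch the
gradient term makes expected field distance grow with anatomical
distance, so λ is a single monotone knob (λ = 0.9 at
cluster_scale = 350 µm gives r ≈ 0.87 between anatomical and field
distance within the scale). Second — and decisive — a *homogeneous*
smooth topography leaves the within-bin-correlation variable spatially
constant, which Moran's I is structurally blind to; patches are the
actual "local clusters of similarly tuned cells" hypothesis and make
the variable spatially heterogeneous, so the Moran test has power
against them (λ = 0.9, cluster_scale = 100 µm: joint Moran + profile
detection in ≥ 90% of sessions, with the median nearest-neighbor field
distance at ~44% of the random-pair median).

**Remapping and objects.** `generate_remapping_pair` models global
remapping ('orthogonal': fields and active flags redrawn
independently) and re-exposure ('preserved': identical layout, fresh
event noise). `generate_object_session` gives a chosen fraction of
cells a landmark vector (angle uniform on the circle, distance
exponential with 12 cm scale, capped at half the arena); the
object-locked bump has its own response rate (2 events/s) — an
object-tuned cell is defined by a robust object response regardless of
how active its place fields are — and follows the object when it moves.

## Analysis pipeline

**QC.** SNR = (mean over significant transients of each transient's
90th-percentile ΔF/F) / (mean |frame-to-frame ΔF/F difference| outside
transients). Transients are epochs above 3 robust SD (1.4826·MAD) of
the trace lasting ≥ 0.5 s, merged across < 0.2 s gaps; the detection
criterion and the absolute-difference reading of the noise level are
conventional choices, config-exposed. A signed mean of differences
would be ≈ 0 by construction and cannot serve as a noise level.
Inclusion requires SNR strictly > 3 and ≥ 40 events per environment.

**Tuning maps.** 2.5-cm bins; summed event amplitudes (not counts —
amplitude carries the signal in deconvolved data) divided by occupancy
seconds; speed filter at 2 cm/s (on positions smoothed with a 0.25-s
Gaussian); Gaussian smoothing with σ = 2.5 *bins* (= 6.25 cm; a σ
quoted next to a bin size conventionally means bin units — 'cm' is a
config switch). Smoothing is mask-normalized (smooth rate·mask and
mask separately, divide) with reflecting boundaries, so unvisited bins
neither receive nor dilute rate mass; on a fully visited grid total
rate mass is conserved exactly. Unvisited bins stay NaN. Object maps
use 2-cm distance × 6° angle bins with circular wrap along the angle
axis; angle 0° is arena-east, counter-clockwise, allocentric.

**Place-cell classification** is a conjunction: (i) spatial
information (Skaggs, bits/event, computed on the smoothed map) above
the 95th percentile of 1,000 circular event-time shifts (shift ≥ 30 s
from either session edge); (ii) split-half stability r > 0.3 across
interleaved 1-min blocks; (iii) ≥ 1 detected field (connected
component of bins elevated ≥ 30% of the peak elevation above the
background median, 4–512 bins). All thresholds are
config-exposed; n_shuffles is reduced in test harnesses (≥ 200 keeps
the 95th percentile stable). "Stable in both environments" =
classified place cell in both.

**Clustering battery.**
* *Pair tables*: all unordered place-cell pairs; anatomical distance,
  main-field distance, map correlation (Pearson over jointly visited
  bins). Mutual information between pair variables uses the Kraskov
  kNN estimator (k = 3, via scikit-learn) with an equal-frequency
  binned estimator as cross-check; estimates are clamped at 0.
* *Anatomical binning*: FOV/8 per axis (≈ 45 µm); bins need ≥ 3 place
  cells; pairs closer than 15 µm are excluded (soma overlap). The
  size-matched control redraws equal-size cell sets from the session
  roster (200 iterations). Medians carry 99% percentile-bootstrap CIs
  (10,000 resamples by default; 2,000 in the large calibration runs).
* *Moran's I*: I = (n/ΣΣw)·(ΣΣ w_ij z_i z_j)/(Σ z_i²) on the per-bin
  mean pairwise correlation at bin centres, with row-standardized
  inverse-distance weights cut off at 2× bin size (queen contiguity
  available). Significance by permuting values across units (1,000
  iterations); "clustered" iff I > the null's 95th percentile. Local
  Moran's I uses conditional permutation per unit and Bonferroni
  correction across units. The implementation is matched to a direct
  double-loop formula to 1e-10 in the test suite.
* *Expanding-circle profiles*: pooled reference–neighbor statistics at
  radii 15–60 µm (5 µm steps, closed boundary, cumulative), median +
  bootstrap CI vs the median of 200 size-matched random draws from
  all-distance pairs; the mirrored field-space profile (5–50 cm) pools
  anatomical distance. Cliff's delta quantifies small-vs-large-radius
  effect sizes.
* *Nearest neighbors*: per-cell statistic against its anatomically
  nearest place cell (ties to the lowest cell id) vs a uniformly drawn
  random partner, plus Moran's I of the per-cell statistic.

**Remapping.** Per-cell cross-session map correlation and
center-of-mass shift with random-cell controls (100 iterations);
right-angle rotation controls; per-pair signed Δd = d_env1 − d_env2 of
main-field distances with a Brown–Forsythe (median-centred Levene)
test across A–A′ / A–B / A–RandomA′ (the random group shuffles A′
cell identities); MI and |Δd| profiles against anatomical distance.

**Decoding.** Poisson naive Bayes on alternating 0.5-s temporal bins
(even train / odd test), per-cell rate maps and occupancy prior fit on
training bins only, speed filter applied throughout. Summed event
amplitudes act as a continuous "count" via k·log(λΔt) − λΔt (the
Stirling term is constant over spatial bins; thresholding to integer
counts is a config switch). Rates are floored at 1e-3 events/s.
Decoded position = posterior argmax bin centre, ties to the lowest
(row, col). Local-vs-random comparisons decode from cells within an
anatomical radius of a reference cell against 25 size-matched random
subsets; the similar-tuning control takes the k cells with fields
nearest a random anchor.

**Object cells.** Classification demands a *stable, new,
object-following* field, established by four jointly necessary tests.
(1) The two object-session object-centred maps must correlate
(Pearson r ≥ 0.2 over bins reliably sampled in both sessions): a
response locked to the object occupies the same object-map location in
both sessions even though the object moved, while arena-fixed fields
and background decorrelate — and the test holds equally for cells
firing at the object itself, whose preferred angle is ill-defined.
(2) A pair of candidate map peaks must agree across sessions within
10 cm / 45° (angle waived when both distances are < 10 cm); candidates
are object-map local maxima at ≥ 50% of the peak and ≥ 3× the map
median, on bins with ≥ 0.5 s occupancy, with an 8 cm non-maximum
suppression so one bump cannot fill all three slots — several
candidates are needed because most object cells are simultaneously
place cells, whose arena field hijacks a single global peak.
(3) The matched field must follow the object: its reconstructed arena
locations in the two sessions must move by ≥ 50% of the object
displacement. (4) The field must be new: when the baseline map holds a
real field (peak ≥ 3× its background median), its elevation within
6 cm of *every* reconstructed location must stay below 50% of the peak
elevation — a single arena-fixed baseline field near one location does
not veto, because criterion (3) already excludes fixed fields. The
Rayleigh uniformity test (Z = nR̄², Zar's approximation) is
cross-checked against pingouin. Place-field detection itself
thresholds the *elevation* above the background median, so a uniform
background event rate cannot merge a field with the rest of the
arena.

## Calibration suite and problem sizes

`placetopo.calibration` runs the battery over many generated
populations using each cell's *expected* rate map (the generative
intensity on the grid) instead of event realizations: the clustering
statistics act on map correlations and field centroids, and under
either hypothesis the anatomical layout is (in)dependent of the
functional layout identically with or without Poisson noise, so the
permutation calibration is unchanged while a session costs
milliseconds. The shipped verification suite uses 500 null sessions
(≈ 300 cells; Moran rejection rate must sit in the binomial 95% band
around 5% at 500 permutations) with profiles on 100 of them, 100
strong-coupling sessions for power, a 400-cell 35-min session for
decoding, and 150-cell protocols for remapping and object recovery;
`scripts/acceptance.py` re-runs the same computations at moderately
reduced session counts. These sizes are the package's chosen
verification conditions; all counts are arguments.

## What the synthetic data do and do not establish

The generator reproduces the *statistical skeleton* the analyses
assume: position-driven Poisson events, Gaussian fields, remapping
orthogonality, vector-tuned object responses, and a controllable
anatomy–function coupling. It does not emulate imaging physics,
neuropil contamination, deconvolution artifacts, non-Gaussian or
boundary-anchored fields, behavioural biases (thigmotaxis, reward
hotspots), or rate remapping. Passing the suite therefore shows the
*statistics* are calibrated and powerful against the stated
alternative — not that any particular empirical dataset is clustered
or not.

## Numerical conventions and degenerate inputs

Zero-variance maps give NaN correlations (flagged, never imputed);
all-constant traces, zero-occupancy sessions and sub-minimum samples
raise typed errors (`ParameterError` for caller mistakes,
`DegenerateInputError` for signal-free input). Every stochastic
operation takes an explicit seed; session-level seeds derive from a
master seed by stable hashing of the task labels, so full runs are
bit-reproducible under a fixed configuration.
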