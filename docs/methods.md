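# Methods

This note documents the models behind `metkit`: what the synthetic-data
generator simulates, what each analysis estimates, the numerical choices
involved, and what the package's validation does and does not demonstrate
about real recordings.

## Transducer model and MET current simulation

The mechanoelectrical transducer is modeled as `n_channels` identical
two-state channels with single-channel conductance `g_single` (pS) and a
common reversal potential `e_rev` (mV, default 0 — the MET channel is a
nonselective cation channel). Open probability follows a single
Boltzmann of bundle displacement `x` (nm, positive toward the tallest
stereocilia row, i.e. excitatory):

    P_open(x) = 1 / (1 + exp(−(x − x_half) / λ))

with slope `λ = lambda_slope` (default 20 nm). This is deliberately the
minimal gating model that yields a tunable resting open probability; no
claim of kinetic fidelity is made (fast/slow adaptation kinetics are a
non-goal, as are hydrodynamic jet models and optical PSF modeling).

The simulated current is

    I(t) = n_channels · g_single · (V − e_rev) · P_open(x(t)) / 1000
           + i_leak + ε(t),      ε ~ N(0, noise_sd²)   [pA]

Inward current is negative. Defaults `n_channels = 160`,
`g_single = 50 pS` give a ≈1 nA peak-to-peak current at −124 mV, the
order of magnitude of a healthy outer hair cell; `noise_sd = 15 pA` is a
typical whole-cell noise floor at this bandwidth.

**Ca²⁺-dependent adaptation** is a static set-point shift: at membrane
potential `V` the half-activation point becomes

    x_half(V) = x_half + adapt_gain · max(0, E_Ca − V),    E_Ca = +40 mV

Calcium influx through resting channels (large at hyperpolarized
potentials) partially closes the transducer, lowering the resting open
probability; at potentials positive to `E_Ca` the shift vanishes and
`P_open` at rest returns to the buffer-free set point. Under the
`BAPTA_5mM` buffer label the gain is zeroed — fast Ca²⁺ chelation removes
adaptation, reproducing the large resting MET current seen with high
BAPTA. `p_rest` (default 0.5) is the shift-free set point and fixes
`x_half = λ·ln(1/p_rest − 1)`; `adapt_gain = 0.35 nm/mV` puts the 1 mM
EGTA resting open probability at −84 mV near 0.10. These two defaults
were chosen once so that the generator's BAPTA/EGTA contrast has the
qualitative shape seen in real hair cells (small resting current in EGTA,
large in BAPTA); kinetic time constants are intentionally absent.

**Stimulus and mechanics.** The fluid-jet force is
`F(t) = dv_gain · DV_lp(t)` where `DV` is the driver voltage (positive DV
excitatory) low-passed with `tau_jet` (default 0.5 ms). The published
jet-calibration procedure is not part of this package; the linear
`dv_gain` (default 100 nN/V) is a configuration constant standing in for
a per-rig calibration. The bundle is an overdamped Hookean spring:
displacement is the first-order response of `1000·F/k_true` (nm) with
time constant `c_drag/k_true` ms (`k_true` in mN/m, `c_drag` in µN·s/m;
1 mN/m = 10⁻³ nN/nm, hence the factor 1000). Steady state is exactly
`F/k` — Hooke's law — which anchors the stiffness-recovery tests. The
default protocol is a 10-cycle, 50 Hz sinusoid with 20 ms of pre-stimulus
baseline, sampled at 50 kHz, across the −124, −84, −64, … +96 mV series.

## MET current analysis

`cycle_average` detects the driver period from its autocorrelation within
the stimulus window (the stimulus annotation, when present, anchors cycle
boundaries at onset) and averages complete cycles; a non-periodic driver
raises an error directing the caller to step-mode analysis.

`peak_to_peak_current` takes phase extrema of the averaged cycle, with
phases assigned by driver sign (DV = 0 belongs to neither phase). Two
numerical choices matter:

* The averaged cycle is smoothed with a short **circular boxcar**
  (~1/16 cycle) before the extrema are read. A raw extremum of a noisy
  average is biased outward by order statistics of the residual noise
  (≈3σ at these cycle lengths, i.e. tens of pA), which would corrupt the
  open-probability estimate; a boxcar removes that bias and — unlike
  polynomial smoothing — can never overshoot the data range at the
  saturated plateaus.
* The transduction direction (inward vs outward on opening) is chosen
  from the data as the pairing of excitatory/inhibitory extrema with the
  larger magnitude, so the analysis never consults the generator.

`resting_open_probability` returns `(i_hold − i_inhib)/i_max` with
`i_hold` the mean over the annotated pre-stimulus window (first 10 ms if
unannotated). "Maximal MET current" is read as the peak-to-peak
(excitatory-minus-inhibitory) current, which makes `P_open = 1`
attainable when the channels are fully open at rest. The value is
reported raw; quality flags mark values outside [−0.05, 1.05] and
currents below 5× the baseline noise SD (a P_open without a measurable
MET current is meaningless). The reversal potential is linearly
interpolated between the two voltages bracketing the sign change of the
signed peak-to-peak current and is reported absent — never extrapolated —
without a sign change. `detect_saturation` declares a gradually increased
stimulus series saturated when the final increment grows |i_max| by less
than 5% (the protocol's published description states only that stimuli
were increased "until the maximal current was achieved"; 5% is this
package's operational criterion, configurable).

## Bundle tracking and stiffness

Kymograph rows are per-frame intensity profiles along a measurement line
orthogonal to the bundle edge (an integer row index, or an arbitrary line
sampled by `skimage.measure.profile_line`). Each profile is min-max
normalized (`(v − min)/(max − min)`) — the published analyses plot
"normalized gray values", and min-max is invariant to camera gain and
offset — and fitted with a Gaussian amplitude function by least squares
(`scipy.optimize.curve_fit`), initialized at the intensity-weighted
centroid with σ = 2 pixels, warm-started from the previous frame during
tracking. A fit is rejected (flagged, never raised) when the solver
fails, the center leaves the profile support, or σ < 0.5 pixel; a trace
with > 20% failed rows is flagged unusable. Displacement is referenced to
the mean pre-stimulus center.

Stiffness uses the final 20% of the force step as the steady-state
window: `k = F/x̄ · 1000` (F in nN, x̄ in nm, k in mN/m). The force on
the bundle is taken equal to the calibrated jet force (no series
compliance) — the "apparent overall" steady-state stiffness of the lumped
bundle. `quality` is the coefficient of variation of the tracked position
within the window. A zero force step is an error; a displacement within
3× the pre-stimulus SD leaves k undefined with a flag.

The movie generator draws pixel counts as Poisson with `photon_scale`
counts per gray unit (default 2; `inf` = noise-free), an 8×64-pixel field
at 50 nm/pixel, 5 kHz, 900 frames — small enough that the full recovery
suite runs in seconds per movie, large enough that the tracker's
precision, not the movie length, limits the stiffness estimate.

## Confocal ratiometry

Weights at a landmark are a separable anisotropic Gaussian with SDs
(σ_xy, σ_xy, σ_z), truncated at ±4σ per axis and at the stack boundary,
then renormalized to sum exactly 1 (truncation at 4σ discards < 10⁻⁴ of
the mass; the constant-field invariant holds to 10⁻⁹ by construction).
Default SDs follow the anatomical convention: (250, 500) nm for both
stereocilia landmarks, (1 µm, 500 nm) for the cuticular plate, (1 µm,
1 µm) for the cytoplasmic positions. Landmarks are supplied as JSON
annotations — automated landmark detection is out of scope — and the
"stereocilia tips" placement guidance (toward the tips of the tallest
row, above the middle row) is annotation advice, not enforced geometry.

The ratio divides the MYO7A weighted average by the F-actin weighted
average computed with the identical weight field, cancelling any gain
applied to both channels. Ratios with an actin average below 1% of the
channel maximum are flagged invalid rather than divided. Background
subtraction is off by default (an optional constant offset per channel
can be applied upstream); bleed-through correction is not modeled.
Group summaries are mean ± SD (population SD) with n per (genotype, age,
landmark); percent reduction is reported both per landmark and from the
across-landmark mean, since a published summary range may use either
aggregation.

The stack generator assigns each voxel the actin level and MYO7A/actin
ratio of its nearest landmark (a Voronoi partition) plus independent
Gaussian noise. Because a landmark's 4σ volume overlaps neighboring
compartments slightly, absolute recovered ratios carry a ≲3% bleed bias;
the knockout/control *ratio of ratios* — hence percent reduction — is
unaffected, which is what the validation asserts.

## Gene-set arithmetic

Thresholds are applied with strict inequalities and the fold-change
threshold on the magnitude (both up- and downregulated genes are
reported in the source analyses, so a signed reading would discard the
downregulated half; this choice is flagged here because the original
analysis does not state it). Missing adjusted p-values exclude the row
and are counted. Identifiers are trimmed and case-folded only. Integer
percentages use round-half-up with the raw value always retained —
printed percentages in the literature round inconsistently, so both forms
are kept. The table generator makes every non-member fail at least one
threshold strictly (occasionally sitting exactly on a boundary to
exercise strictness) so that `filter_degs` must recover the ground-truth
membership exactly. Exact overlap construction supports one or two
overlapping sets (the Venn comparisons implemented here are pairwise);
more than two mutually overlapping sets raise `NotImplementedError`.

## Statistics

`compare_groups` reports mean ± SD and n per group with either Welch's t
(scipy) or the two-sided Mann–Whitney U. For combined n ≤ 20 the
Mann–Whitney p-value is exact: all C(n, n₁) assignments of the pooled
midranks are enumerated and the two-sided p is
P(|U − n₁n₂/2| ≥ |u_obs − n₁n₂/2|), which handles ties without
approximation and gives p = 1 for identical groups. Larger samples use
the normal approximation with tie and continuity correction (scipy). The
tie/continuity policy of published Mann–Whitney values is rarely stated;
exact enumeration sidesteps the question wherever feasible and this note
documents the convention otherwise. Omnibus designs (two-way ANOVA with
Šídák post tests) are deliberately delegated to standard statistical
software; this package implements the two-group tests and summaries its
own pipeline needs.

## Pipeline and reproducibility

`run_pipeline` derives one child seed per stage from the top-level seed
(via `numpy.random.SeedSequence` keyed on the stage name's CRC-32), logs
it, and records it in the manifest together with the config, package
version and per-stage status; reruns with the same config and seed
produce byte-identical CSV outputs. Stage failures are recorded and do
not stop independent stages. All randomness in the package flows through
explicit integer seeds — there is no hidden global state.

The package is presented as a library with narrative `examples/` scripts
rather than a console command; the pipeline entry point and the per-stage
functions are the scripting interface.

## Problem sizes used in validation

Recovery checks run at the generator defaults: 20 seeded replicates per
condition for open-probability (4 set points × 20), BAPTA/EGTA ordering
(20), reversal (20 × 11 voltages) and stiffness (3 stiffnesses × 20
movies of 900 frames); 100 sub-pixel offsets and 500 shot-noise draws for
localization (against a dense grid-search template-MLE oracle); 4 cells
per genotype × 5 landmarks for the confocal chain; 1,000 null replicates
for Welch calibration; and full enumeration for every Mann–Whitney group
size with combined n ≤ 12.

## Known limitations

* The gating model is static; adaptation kinetics, gating compliance and
  channel-noise analysis are out of scope.
* The jet calibration is a linear stand-in constant; absolute forces in
  the generator are arbitrary up to that constant (stiffness recovery is
  self-consistent regardless).
* The confocal generator uses piecewise-constant compartments and
  Gaussian noise, not a full optical model; passing tests demonstrate the
  correctness of the measurement arithmetic, not robustness to real PSFs,
  bleed-through or chromatic misregistration.
* Percent-reduction recovery on synthetic stacks says nothing about
  antibody linearity in real immunostaining.
* Gene tables are generated directly at the DEG-table level; read
  alignment, quantification and the differential-expression model itself
  are upstream of this package.
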