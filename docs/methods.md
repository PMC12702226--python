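# Methods

This note records the models implemented in `asldyn`, the parameters that
matter, what the synthetic data does and does not emulate, and the design
choices made where more than one defensible convention exists.

## CBF quantification (single-PLD model)

The perfusion-weighted signal is the mean of the pairwise control−label
differences, ΔM (8 pairs by default). CBF in ml/100 g/min follows the
standard single-PLD closed form for PCASL:

    CBF = 6000 · λ · ΔM · exp(PLD/T1b) / (2 · α · T1b[s] · M0 · (1 − exp(−τ/T1b)))

with defaults λ = 0.9 ml/g (blood–brain partition coefficient),
T1b = 1350 ms (arterial blood T1 at 1.5 T), τ = 1800 ms (label duration),
PLD = 2000 ms, and labelling efficiency α ∈ (0, 1]. All constants are
config-exposed. The closed form was chosen over a Bayesian kinetic fitter
deliberately: it is the community-standard estimator for single-PLD data
and is *exactly invertible*, which makes zero-noise round-trip recovery a
machine-precision test of the whole simulate→quantify chain rather than a
tolerance judgement.

CBF is inversely proportional to α, so `rescale_alpha` converts a map
fitted at one labelling efficiency to another by the scalar α_old/α_new;
this identity (rescaled map ≡ directly fitted map) is asserted exactly in
the tests. Voxels with M0 below 0.1 × the 99th percentile of M0 are marked
invalid and set to 0 — a deterministic guard against background division
blow-ups. No partial-volume correction is applied.

## Labelling-efficiency estimation

The carotid difference signal at post-label time t is modelled as a
mixture over a discrete velocity grid (5–40 cm/s in 5 cm/s steps):

    s(t)/M0b = 2 α Σ_j w_j · 1[Δt_j ≤ t ≤ Δt_j + τ] · exp(−t/T1b),   Δt_j = D/v_j

Each velocity component leaves the labelling plane (D = 40 mm below the
imaging slice by default), arrives after its transit delay, is present for
the bolus duration τ, and the inversion label relaxes with age at 1/T1b.
Freshly inflowing spins are assumed unsaturated by prior readout pulses
(inflow-refresh assumption). This concrete form is this package's own
fixed stand-in for velocity-dependent carotid inflow models in the
literature, whose exact saturation handling varies; all validation here is
therefore *recovery-based* (the generator and fitter share the model, an
acknowledged inverse crime), and passing tests demonstrate internal
consistency and noise robustness, not robustness to model misfit.

The default time grid is 45 samples spanning 20–2042 ms (≈46 ms spacing;
the endpoints and a strict 46 ms step cannot both hold, and the grid keeps
the printed endpoints). The fit window starts at the first raw
negative-difference sample and extends 450 ms (10 samples on this grid);
an optional moving-average slope detector exists but is off by default so
window selection is literal and deterministic.

Because the signal is linear in c_j = α·w_j with c_j ≥ 0 and α = Σ c_j,
the joint least-squares fit over (α, w on the simplex) is a nonnegative
linear least-squares problem, solved globally by NNLS. This replaces any
iterative simplex-constrained optimisation: no initialisation, no local
minima, and exact α recovery on noiseless data even when several velocity
components are indistinguishable inside the window (their coefficient
*sum* — which is all α needs — remains identified). Per-subject α is the
arithmetic mean of the left and right internal-carotid fits; the cohort
value is the across-subject median. Estimates above 1.05 are flagged
rather than clipped.

The simulator's default velocity mixture is triangular over 15–40 cm/s
(typical internal-carotid speeds). This also keeps every transit delay
≤ 267 ms, so all components have support inside any fit window the
negative-slope rule can select, keeping α identifiable under noise.

## Synthetic phantom and acquisitions

The phantom is an ellipsoidal brain (GM shell, WM core, central CSF
ventricles) split into hemispheres at the mid-sagittal plane, on a
48×48×24 grid of 4×4×8 mm³ voxels by default. A spherical tumour in one
hemisphere contains a cavity, a rim, and a high-CBF ("hot") subvolume; the
hot sphere is displaced along a seed-dependent ray until the requested
fraction of its voxels lies outside the GTV (bisection on the voxelised
fraction, so the realised fraction is quantization-exact). The planning
CTV is the GTV plus baseline hot subvolume dilated by a metric 5 mm margin
(distance transform), held fixed over a patient's longitudinal series;
contralateral grey matter is the GM of the opposite hemisphere minus the
CTV.

Mean tissue CBF defaults: GM 45, WM 22, tumour rim 55, hot tumour 100,
cavity 3, CSF 2 ml/100 g/min. Voxelwise heterogeneity is multiplicative
Gaussian per tissue (clipped at 0); the GM spread of 0.45 places the GM
95 % quantile near 1.74 × the mean, i.e. in the ~79 ml/100 g/min regime
for a 45 ml/100 g/min mean, so the cohort threshold sits between normal
GM and hot tumour as intended. The default true α is 0.59, the regime of
measured MRI-linac labelling efficiencies, with 0.85 as the consensus
comparison value.

Acquisition noise is additive Gaussian on each control and label frame
(Rician magnitude behaviour is ignored: at realistic tissue SNR the
subtraction signal is well approximated as Gaussian, and the additive
model keeps recovery tests analytic). The default frame noise SD is 0.002
of the GM M0 — chosen once as a plausible per-voxel SNR for large
(4×4×8 mm³) voxels; no measured noise level exists for this acquisition
class, so it is a free simulation parameter. Note that noise inflates the
GM 95 % quantile (order statistics of a widened distribution), so the
demo-pipeline threshold lands above the noise-free ~79; this is expected
behaviour, not a calibration target.

The forward ASL simulator writes control = M0 (+noise) and
label = M0 − ΔM_true (+noise) with ΔM_true the exact inverse of the
quantification formula at the true CBF and true α, so zero-noise recovery
is exact to floating-point rounding (asserted at ≤1e-9 relative). What the
phantom does **not** emulate: motion, background-suppression timing,
readout distortion, partial volume, registration error, or physiological
CBF fluctuation — so passing tests validate the analysis chain, not
scanner physics.

## High-CBF regions and dynamics

The cohort threshold is the across-patient median of each patient's
baseline contralateral-GM 95 % quantile (baseline = earliest scan during
treatment). Quantiles use linear interpolation between order statistics
(config-exposed). Segmentation keeps CTV voxels with CBF strictly above
the threshold, labels connected components at 26-connectivity (the
permissive 3D default; 6/18 available), keeps the largest, breaking size
ties by smallest linear voxel index for determinism, and applies the
> 1 cm³ inclusion rule to that component. Volumes are voxel count ×
voxel volume / 1000 (cm³).

Overlap metrics: %GTV occupied = 100·|hCBF∩GTV|/|GTV| and
%outside = 100·|hCBF∩¬GTV|/|hCBF| (undefined and flagged for an empty
region). Scan days map to weeks as week = floor((day−1)/7)+1; weekly
volumes are averaged within a week, and the dynamics series is
%Δ_k = 100·(V_k − V_1)/V_1 with week 1 ≡ 0. The cohort summary includes
only patients whose first scan fell in week 1 and who have ≥ 2 scans
(exclusions are logged per patient with the reason), reports per-week
medians, and tests each post-baseline week against zero change with a
two-sided one-sample t-test (p < 0.05 convention, no multiplicity
adjustment).

## Repeatability

Repeated grey-matter CBF values per subject follow a one-way
random-effects model y_ij = μ + b_i + ε_ij. REML estimation is implemented
by profiling the restricted likelihood down to the variance ratio
θ = σ_b²/σ_w² and solving the score equation dℓ_R/dθ = 0 by bracketed
root-finding (the envelope theorem removes the μ̂(θ) dependence from the
derivative), with θ = 0 taken when the score is nonnegative at the
boundary. This is deterministic, runs in microseconds, and matches the
balanced-design ANOVA closed forms to ~1e-9 (a flat-criterion scalar
*minimiser* could not reach that accuracy, which is why the root-finding
form is used); statsmodels' general mixed-model fitter serves as an
independent cross-check in the tests, not as the implementation. Only
subjects with ≥ 2 scans inform the fit, and ≥ 2 such subjects are
required.

Derived summaries: wSD = σ_w, wCV = 100·σ_w/μ (arithmetic, not
log-based), and the repeatability coefficient RC = 2.77·wSD
(1.96·√2, the Bland–Altman convention). A longitudinal change is flagged
significant only when its magnitude *strictly* exceeds RC; under
within-subject noise alone this flags ~5 % of scan pairs, verified by
seeded simulation. Degenerate inputs: identical repeats give wSD = 0;
zero-variance samples in the t-test helper return p = 1 at the null and
p = 0 off it, flagged as non-stochastic.

## Pipeline and problem sizes

The demo pipeline simulates 6 patients × 4 weekly scans on a 40×40×20
grid, estimates α from simulated carotid series per patient, fits maps at
the consensus α = 0.85 and rescales them to the measured cohort median
(numerically identical to fitting at the measured α, and it exercises the
correction path), then runs the region, dynamics and repeatability stages.
One patient per group of six is scheduled with a week-2 baseline to
exercise the dynamics exclusion filter. Everything derives from the config
seed; two runs with the same seed produce byte-identical cohort tables.
The acceptance script uses 200 replicates for noise-robustness and
segmentation-oracle checks and 250 for variance-component recovery —
enough for sub-percent Monte-Carlo error on the reported means while the
whole script stays in the seconds range.

## Known limitations

- The Look-Locker generator and fitter share one forward model; no claim
  is made about agreement with any specific published carotid inflow model.
- The phantom's piecewise-constant-plus-jitter CBF field has no spatial
  correlation, vascular territories, or arterial-transit heterogeneity.
- The negative-slope window rule is literal; on very low-SNR series the
  window can start before the inflow peak (the model still fits the rising
  portion, but slow velocity components arriving after the window would be
  unidentifiable there).
- wCV is reported on the arithmetic scale; a log-scale variant is not
  implemented.
- No registration: all volumes of a patient are assumed voxel-aligned,
  which the synthetic generator guarantees but real data would not.
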