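# asldyn

Quantitative perfusion analysis for single-PLD pseudo-continuous arterial
spin labelling (PCASL), aimed at low-SNR acquisitions such as those from an
MRI-linac, with a focus on glioblastoma during radiotherapy.

ASL measures cerebral blood flow (CBF, ml/100 g/min) without contrast
agents by magnetically inverting arterial water spins at the neck and
imaging after a post-label delay. On hybrid MRI + linear-accelerator
scanners the labelling efficiency α (the fraction of spins actually
inverted) can be well below the consensus value of 0.85, and because
measured CBF scales as 1/α this biases every number downstream. This
package implements the full analysis chain needed to do the job properly:

- **CBF quantification** via the standard single-PLD closed form
  `CBF = 6000 λ ΔM e^{PLD/T1b} / (2 α T1b M0 (1 − e^{−τ/T1b}))`,
  with exact rescaling between labelling efficiencies;
- **labelling-efficiency estimation** from dynamic Look-Locker signals in
  the internal carotid arteries, using a velocity-dependent inflow model
  (boxcar bolus per velocity component, transit delay `D/v`, T1 decay of
  the label) fitted by nonnegative least squares;
- **high-CBF tumour subvolume analysis**: cohort threshold = across-patient
  median of the grey-matter 95 % CBF quantile, largest connected component
  above threshold within the planning CTV, overlap percentages against the
  enhancing GTV, and weekly volume dynamics relative to week 1;
- **test–retest repeatability**: REML variance components of a one-way
  random-effects model (wSD, wCV, repeatability coefficient 2.77·wSD) and
  change detection against the repeatability coefficient;
- **a synthetic patient generator** (seeded, fully deterministic): a
  digital head phantom with GM/WM/CSF compartments, a tumour whose high-CBF
  subvolume straddles the GTV boundary and shrinks week by week, simulated
  control/label acquisitions that exactly invert the quantification model,
  and simulated carotid Look-Locker series.

Intended users: medical-physics and imaging researchers who want a tested,
scriptable reference implementation of this analysis chain, or a synthetic
test bed for their own ASL pipelines.

## Worked example

```python
from asldyn import (PhantomSpec, build_phantom, QuantParams,
                    simulate_asl_acquisition, simulate_look_locker,
                    perfusion_difference, quantify_cbf, gm_cbf_stats,
                    RegionSet, segment_high_cbf, overlap_metrics,
                    fit_labelling_efficiency)

spec = PhantomSpec(seed=42)                      # 48x48x24 grid, 4x4x8 mm voxels
truth = build_phantom(spec)
quant = QuantParams(alpha=0.59)                  # measured labelling efficiency
acq = simulate_asl_acquisition(truth, quant, alpha_true=0.59,
                               noise_sd=spec.noise_sd * spec.m0_scale, seed=42)
cbf = quantify_cbf(perfusion_difference(acq), acq.m0, quant)

gm_med, gm_q95 = gm_cbf_stats(cbf, truth.contralateral_gm_mask)
regions = RegionSet(gtv=truth.gtv_mask, ctv=truth.ctv_mask,
                    contralateral_gm=truth.contralateral_gm_mask)
hcbf = segment_high_cbf(cbf, regions, threshold=gm_q95)
ov = overlap_metrics(hcbf, truth.gtv_mask)

est = fit_labelling_efficiency(simulate_look_locker(0.59, noise_sd=10.0, seed=42))
```

Printed output for this seed:

```
GM median CBF: 45.0 ml/100 g/min
GM 95% quantile: 98.5 ml/100 g/min
high-CBF volume: 4.35 cm^3 (included: True)
%GTV occupied: 4.9%  %outside GTV: 50.0%
alpha: left 0.588, right 0.589, mean 0.589
```

The contralateral grey-matter median lands on the simulated 45 ml/100 g/min
ground truth; the 95 % quantile is inflated above the noise-free value
(~79) by the acquisition noise at this SNR. The high-CBF region exceeds the
1 cm³ inclusion cut, and half of it lies outside the enhancing GTV — the
phantom was built with 47 % of the hot subvolume outside the GTV. The
fitted labelling efficiency recovers the simulated α = 0.59 to three
decimals from noisy carotid signals.

## Command line

`asldyn` exposes the stages as subcommands over NIfTI/CSV/JSON files:

```bash
asldyn simulate --out-dir scratch/patient1 --seed 1
asldyn quantify --series scratch/patient1/asl.nii.gz --m0 scratch/patient1/m0.nii.gz \
                --alpha 0.59 --out scratch/patient1/cbf.nii.gz
asldyn regions  --cbf scratch/patient1/cbf.nii.gz --gtv scratch/patient1/gtv_mask.nii.gz \
                --ctv scratch/patient1/ctv_mask.nii.gz \
                --gm scratch/patient1/contralateral_gm_mask.nii.gz \
                --out scratch/patient1/regions.json
asldyn run --config examples/demo_config.yaml    # full 6-patient synthetic cohort
```

## Layout

```
src/asldyn/
  phantom.py        synthetic head/tumour ground truth (PhantomSpec, build_phantom)
  simulate.py       forward ASL + Look-Locker + longitudinal/repeat simulators
  quantify.py       single-PLD CBF model, alpha rescaling
  labeff.py         velocity-model labelling-efficiency fit
  regions.py        thresholding, connected components, overlap, dynamics
  repeatability.py  REML variance components, RC-based change detection, t-tests
  io.py / config.py / pipeline.py / cli.py   formats, YAML config, orchestration
docs/methods.md     model and design notes
```
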