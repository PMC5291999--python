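# footkin

Static foot-deformity assessment versus multi-segment foot kinematics, as a
reproducible software pipeline.

Clinical foot models in the Root tradition classify a foot from static
measures — neutral and relaxed calcaneal stance position (NCSP/RCSP), ankle
dorsiflexion with the knee extended, first-MPJ dorsiflexion, first-ray and
forefoot alignment — and assume those deformities shape how the foot moves.
`footkin` implements the full chain needed to test that assumption on
three-dimensional gait data from a six-segment foot model (leg, calcaneus,
midfoot, medial forefoot, lateral forefoot, hallux):

- **Kinematics** — rigid marker-cluster pose fitting (SVD/Kabsch), an
  anatomically calibrated leg coordinate system, Cardan x-y-z joint angles
  with an explicit gimbal policy, and zero-phase Butterworth filtering with a
  documented dual-pass cutoff correction.
- **Events and variables** — force-plate stance detection, heel-lift
  detection from the sagittal rearfoot velocity, and the six scalar gait
  variables (mid-stance eversion/dorsiflexion peaks, sagittal angle at heel
  lift, mid-stance sagittal range, propulsive hallux dorsiflexion and
  rearfoot eversion).
- **Deformity classification** — Root-model categories (rearfoot varus,
  ankle equinus, hallux limitus, first-ray and forefoot alignment) with
  strict, configurable thresholds, plus the subtalar-neutral (STN)
  pass-through analysis: does the rearfoot frontal curve cross the foot's
  own neutral position during stance, and when?
- **Statistics** — a normality-gated two/three-group comparison grid
  (t / Mann-Whitney, ANOVA+LSD / Kruskal-Wallis with Bonferroni-corrected
  pairwise tests) and static-dynamic correlations (Pearson/Spearman),
  wrapped in a `CohortAnalysis -> fit() -> CohortResults` model.
- **Synthetic cohorts** — a generator that produces marker-level walking,
  standing and STN trials from ground-truth harmonic angle waveforms, with
  configurable deformity prevalences, static-dynamic correlations, group
  effects, marker noise and trial-to-trial jitter. Every generated
  participant carries its exact ground truth, so the whole pipeline can be
  validated end to end.

## Worked example

```python
import footkin as fk

cfg = fk.CohortConfig(n=12, trial_count=2, seed=7)
cohort = fk.generate_cohort(cfg)               # marker-level synthetic data
results = fk.process_synthetic_cohort(cohort)  # the measurement pipeline

r = results[0]
print(f"{r.participant_id}: deformity count {r.profile.count}, "
      f"STN neutral {r.stn_angle_deg:+.2f} deg, "
      f"passed through neutral: {r.stn.passed}")
for name, value in r.variables.as_dict().items():
    print(f"  {name:38s} {value:+7.2f} deg")
```

Output:

```
P001: deformity count 4, STN neutral +4.62 deg, passed through neutral: False
  peak_rearfoot_eversion_midstance         -2.50 deg
  peak_rearfoot_dorsiflexion_midstance     +5.16 deg
  rearfoot_sagittal_at_heel_lift           +5.16 deg
  rearfoot_sagittal_range_midstance       +10.59 deg
  peak_hallux_dorsiflexion_propulsion     +49.38 deg
  peak_rearfoot_eversion_propulsion        -2.53 deg
```

Cohort-level statistics use the analysis model (here on the generator's fast
truth-only path; `CohortAnalysis.from_results(...)` does the same from
processed marker data):

```python
from footkin.analysis import truth_frame, run_full_analysis

cohort = fk.generate_cohort(fk.CohortConfig(n=100, seed=1),
                            include_markers=False)
df, profiles, stn = truth_frame(cohort)
results = run_full_analysis(df, profiles, stn)
print(results.summary())
```

Output (abridged):

```
Cohort analysis of 100 feet
==================================
...
Deformity counts (0-5): 0:0, 1:0, 2:5, 3:28, 4:62, 5:5
Prevalence: rearfoot_varus 97%, ankle_equinus 88%, hallux_limited 8%, ...
Subtalar neutral: 42% passed through; crossing/closest at 51.4% (47.2 - 55.6) of the gait cycle

Group comparisons:
  rearfoot_varus peak_rearfoot_eversion_midstance       skipped (insufficient comparator group)
  ankle_equinus  peak_rearfoot_dorsiflexion_midstance   t                      p=0.025
  ...
Correlations:
  ncsp_deg                   ~ peak_rearfoot_eversion_midstance       pearson  r=+0.47 p=0.000
  ...
```

### Classifying a single static assessment

```python
from footkin.io_formats import StaticAssessment

static = StaticAssessment(ncsp_deg=9.2, rcsp_deg=0.5,
                          ankle_dorsiflexion_deg=4.8,
                          first_mpj_dorsiflexion_deg=70.0,
                          first_ray="normal", forefoot="normal", fpi=4)
profile = fk.classify_deformities(static)
# profile.rearfoot_varus == True   (9.2 deg NCSP inversion)
# profile.ankle_equinus  == True   (4.8 deg < 10 deg dorsiflexion)
# profile.count          == 2
```

An assessment of 0 deg NCSP, 11.9 deg ankle dorsiflexion, 70 deg first-MPJ
dorsiflexion and normal first-ray/forefoot alignment classifies as zero
deformities. Classification is deterministic: identical inputs always
produce byte-identical profiles.

## Command line

```
footkin simulate --config run.yaml --out out/        # write a synthetic cohort
footkin process  --manifest out/cohort/manifest.csv --out out/processed
footkin analyse  --manifest out/cohort/manifest.csv --out out/analysis
footkin run-all  --config run.yaml --out out/        # all of the above
```

`run.yaml` holds `cohort:` (any `CohortConfig` field), `pipeline:` and
`stats:` sections; unknown keys are rejected.

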