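# Methods

This note documents the models, numerical conventions and deliberate
simplifications behind `footkin`. Nothing here makes empirical claims about
real feet; every number refers to the package's own definitions and synthetic
data.

## Segment model and coordinate systems

The model (`footkin-6seg-1`) comprises six segments — leg, calcaneus,
midfoot, medial forefoot, lateral forefoot, hallux — linked by five joints:

| joint | proximal | distal |
| --- | --- | --- |
| rearfoot | leg | calcaneus |
| midfoot_calcaneus | calcaneus | midfoot |
| medial_forefoot_midfoot | midfoot | medial forefoot |
| lateral_forefoot_midfoot | midfoot | lateral forefoot |
| hallux_medial_forefoot | medial forefoot | hallux |

Each foot segment carries a rigid four-marker cluster plate; the leg carries
four markers. Cluster plates have 30–45 mm marker baselines in two
directions: cluster geometry directly sets how marker noise propagates into
orientation, and these baselines keep the filtered joint-angle noise from
0.5 mm marker noise below 0.5° per channel (verified by simulation — smaller
or near-collinear triads do not meet that budget).

The leg's anatomical coordinate system is built from medial/lateral
malleolus and knee markers present only in the standing reference trial:
origin at the inter-malleolar midpoint, z along the malleoli→knee axis, x as
the malleolar axis orthogonalised against z, y = z × x (forward). A
configurable walking-direction vector resolves the forward sense. In the
reference posture this LCS is the identity, so standing calibration maps
every joint to zero rotation — all angles are relative to each foot's own
standing posture.

## Pose fitting and joint angles

Per frame, each segment's pose is the least-squares rigid transform (SVD /
Kabsch, det +1 enforced) from its standing-reference cluster to the current
frame. Frames missing any cluster marker are excluded (NaN) rather than
interpolated. The relative rotation of distal in proximal is expressed in
the anatomical basis and decomposed with the Cardan x-y-z sequence
(R = Rx·Ry·Rz; x ≈ sagittal, y ≈ frontal, z ≈ transverse). Near gimbal lock
(|frontal| → 90°) the transverse angle is set to 0 and a `GimbalWarning` is
emitted — never a silent wrong answer. Foot joints operate far from ±90°, so
the fallback is a guard, not an operating mode.

The independent verification route for the pose fit is Horn's quaternion
absolute-orientation method (eigendecomposition of the 4×4 profile matrix),
implemented separately in the tests and the acceptance script; both solve
the same least-squares problem, so agreement to 1e-6 is required.

## Filtering

Angle curves are filtered with a zero-phase (forward–backward) Butterworth
low-pass, overall order 4 (order-2 per pass), cutoff 6 Hz at a 100 Hz marker
rate. The per-pass cutoff is pre-warped by (√2−1)^(−1/4) so the dual-pass
response is −3 dB at the nominal cutoff. DC gain is exactly 1 and phase is
identically zero. The analytic dual-pass amplitude response
1/(1+(f/f_d)^4) is exposed as `butterworth_expected_gain`; the digital
filter matches it within 0.01 absolute gain over the tested band (the
bilinear transform's frequency warping grows toward the Nyquist frequency,
which is why the contract is stated as an absolute-gain tolerance).
Filtering is applied per contiguous run of valid frames; runs shorter than
the filter warm-up length stay missing.

## Events and variables

Stance is the longest force-plate contact above 20 N lasting at least
0.2 s; heel strike and toe off are the threshold crossings. Curves are
linearly resampled to 101 points over stance (and over a nominal cycle,
stance / 0.62). Heel lift is the first instant from 40% of stance where the
sagittal rearfoot velocity stays negative for 5% of stance, with a 60%
fallback when no sustained drop exists; its resolution is 1% of stance. The
mean of a participant's trials is taken pointwise on the normalised bases
before variables are read off. The six variables are signed extrema (or a
value/range) in the mid-stance window (15% of stance to heel lift) and the
propulsive window (heel lift to toe off).

## Deformity classification and STN pass-through

Root-style categories with strict inequalities: rearfoot varus when NCSP
inversion > 0°, ankle equinus when ankle dorsiflexion < 10°, hallux limitus
when first-MPJ dorsiflexion < 65°, first-ray and forefoot categories taken
as recorded. Thresholds are configurable; boundary values classify as
normal. The deformity count is the number of affected categories (0–5).

The STN analysis compares each foot's subtalar-neutral standing angle (mean
frontal rearfoot angle of the STN trial) with its frontal rearfoot gait
curve on the cycle base. The foot "passes through neutral" when the
difference curve changes sign — or touches zero within a small tolerance —
within the stance window; crossing instants are linearly interpolated
between samples, and non-passing feet report the minimum difference and its
time.

## Statistics

Each comparison family groups feet by one deformity and compares the
affected dynamic variables. A Kolmogorov–Smirnov normality gate (per group,
any failure → nonparametric) selects t vs Mann–Whitney for two groups, and
one-way ANOVA with Fisher's LSD (pairwise pooled-MSE t-tests, only after a
significant omnibus, uncorrected by design) vs Kruskal–Wallis with pairwise
Mann–Whitney at Bonferroni-corrected α/3 for three. Groups below 5 feet
skip the test but keep descriptives. Correlations are Pearson when both
variables pass the gate, Spearman otherwise. α = 0.05 throughout.

## Synthetic cohort generator: scope and construction

The generator exists to validate the pipeline, not to imitate any particular
dataset. Per participant it draws statics (NCSP, RCSP, ankle and hallux
dorsiflexion as truncated-normal mixtures over configured prevalences,
categorical first-ray/forefoot, FPI), dynamic targets correlated with the
statics at configured ρ (via shared standard-normal scores), and harmonic
ground-truth angle waveforms over the gait cycle:

- The rearfoot frontal curve is a two-harmonic curve solved through three
  constraints — heel-strike inversion, a mid-stance trough, toe-off
  re-inversion. The trough constraint is adjusted by secant iteration until
  the realised mid-stance window minimum equals the drawn dynamic target, so
  the configured static–dynamic correlations hold exactly for the realised
  curves (the window minimum can sit on a side lobe of the two-harmonic
  curve, where a naive fixed point converges too slowly).
- Other channels are one- or two-harmonic curves whose window extrema hit
  the remaining targets.
- Marker trials are produced by forward kinematics: joint rotations
  propagated down the chain about fixed joint centres, cluster markers
  rigidly transported, Gaussian marker noise added, a smooth double-hump
  force trace generated for stance. Trials differ by noise and small
  (< 1°) amplitude jitter. Standing and STN trials are constant-posture.
- Ground truth (six variables, heel lift, STN crossing) is always computed
  from dense scans of the realised curves, never copied from the drawn
  targets.

Scope limits: harmonic waveforms cannot represent every gait shape; the
model is left-foot shaped with a fixed reference posture; soft-tissue
artefact, marker occlusion patterns and force-plate noise are not modelled
(missing frames are supported by the pipeline but not produced by the
generator); group effects are additive constants on the affected variable.

## Numerical choices

- Angles in degrees everywhere; positions in mm; rates in Hz.
- 101-point normalised bases (0–100% inclusive), linear interpolation.
- Dense-grid scans (≥ 20001 points) define ground-truth extrema and
  crossings in tests; tolerances: 0.01° (noise-free round trip), 1e-9
  (rotation identity), 1e-6 (pose-fit cross-validation), 0.1°
  (variable-extraction vs sampled curves — the 1% sampling of a harmonic
  curve biases window extrema by well under that).
- TSV/CSV files store numbers at 9 decimal places; JSON reports convert
  numpy scalars/arrays to native types.
- All stochastic APIs take explicit seeds; derived seeds are drawn below
  2^31.

## Limitations

- The pipeline estimates the gait cycle from stance via a fixed stance
  fraction (0.62) rather than contralateral events.
- Mid-stance onset is a fixed 15% of stance (a foot-flat proxy), not an
  event detected from data.
- The statistics are scalar-variable tests; no curve-level inference
  (e.g., statistical parametric mapping) is provided.
- Classification thresholds implement one published convention; boundary
  behaviour (strict inequalities) is a package decision and configurable.
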