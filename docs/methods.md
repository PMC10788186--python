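# Methods

## The two eligibility rules

**Hypoperfusion-hypodensity mismatch (HHM).** Intravenous thrombolysis is
licensed up to 4.5 h after stroke onset, but for as many as a quarter of
patients (wake-up strokes, aphasia) the onset time is unknown. The HHM rule
substitutes a *tissue clock*: after arterial occlusion, ischemic tissue
takes up water at a roughly constant rate, which reads on non-contrast CT
as a slowly deepening hypodensity relative to the mirror-image healthy
tissue. A patient whose perfusion maps show a core lesion that is *not yet*
hypodense on NCCT was therefore probably occluded recently. The rule is:

1. Find the total ischemic area on the bolus-delay maps (MTT/TTD/Tmax).
2. Within it, find the core on CBV (below 2 mL/100 mL absolute or 30 % of
   the contralateral value), falling back to CBF (below 30 mL/100 mL/min or
   60 % relative) when no CBV lesion exists. The reading protocol does not
   state whether its raters required the absolute and relative criteria
   jointly or alternatively; we default to the alternative ("OR") reading
   and expose an "AND" switch (`core_rule_logic`).
3. Judge the corresponding NCCT region for a clear hypodensity,
   slice by slice. HHM is positive iff a core exists and no clear
   hypodensity accompanies it.

The human judgement in step 3 is operationalised as the core's net water
uptake, `NWU = (1 − meanHU_core / meanHU_mirror) × 100 %`, exceeding a
threshold δ (default **5 %**). The protocol's tie-break — "in case of
doubt, rate as absence" — maps to a strict inequality: `NWU > δ`, never
`≥`. δ is a calibration choice, not a published constant: no study
quantifies the HU deficit a rater perceives as "clearly hypodense", so the
default was chosen once so that, under the default NWU dynamics below, the
phantom's hypodensity becomes detectable near the 4.5 h window edge
(5 / 1.3 ≈ 3.8 h), matching the clinical premise that hypoperfusion and
hypodensity usually match beyond 4.5 h. A second judgement mode
(`ALL_SLICES`) requires every core-bearing axial slice to exceed δ
individually, mirroring the protocol's requirement that a
hypoperfusion-hypodensity *match* encompass all slices; on noise-free
phantoms the two modes coincide.

**Automated perfusion mismatch (EXTEND).** Core = relative CBF < 30 % of
the mirrored value; penumbra = Tmax > 6 s; positive iff core < 70 mL,
penumbra/core ratio > 1.2 and absolute mismatch > 10 mL. The published
phrasing chains the clauses with an ambiguous "or"; the default is the
CONJUNCTIVE reading (the trial's own rule, all three clauses), with the
literal DISJUNCTIVE reading (core cap AND (ratio OR absolute)) available —
the ambiguity is preserved as a switch, never silently resolved. Edge
conventions: empty core with non-empty penumbra has infinite ratio (counts
toward positive); both empty is negative (nothing to salvage); a core
larger than the Tmax lesion gives a negative mismatch volume, legal and
flagged. Ground-truth eligibility for a known-onset cohort is
`onset < 4.5 h OR extend_positive`, with a strict boundary (exactly 4.5 h
is outside the window).

## The phantom generator

The generator exists to exercise every downstream rule against a known
truth; it is a geometric idealisation, not a realistic scan.

- **Geometry.** Ellipsoidal brain (mirror-symmetric about the central plane
  of axis 0, the midsagittal plane; grid default 64×64×16 at 2×2×5 mm —
  small enough for seconds-scale tests, large enough for multi-mL lesions).
  The lesion is an ellipsoidal penumbra (default radii 20×24×20 mm ≈ 40 mL)
  with a concentric core (10×12×10 mm ≈ 5 mL), required to lie inside the
  brain and within one hemisphere.
- **Physiology.** Healthy baselines are conventional gray-matter values:
  33 HU, CBF 50 mL/100 mL/min, CBV 4 mL/100 mL, MTT 4 s, TTD 6 s, Tmax
  0.5 s. Penumbra: Tmax 8 s (> 6), CBF 50 % of baseline (hypoperfused but
  above the 30 % core cut), MTT/TTD doubled (> 145 % of mirror), CBV
  preserved. Core: CBF 20 % of baseline, CBV 1 mL/100 mL (below both core
  criteria). The penumbra-tissue values (CBF fraction 0.5, delay factor
  2.0) are the generator's own choices — the reading protocol constrains
  only the thresholds, so any values respecting the threshold ordering
  would do; these are conventional penumbra physiology.
- **Tissue clock.** NCCT in the true core is
  `baseline_HU × (1 − NWU(t)/100)` with `NWU(t) = min(rate·t, cap)`,
  defaults **1.3 %/h** capped at **12 %**. No quantitative NWU trajectory
  is published for this protocol; the linear-with-saturation form is a
  deliberate stand-in (kept swappable via the `PhantomSpec` fields) whose defaults
  place the δ = 5 % detection point near 3.8 h. Noise: additive Gaussian,
  1 HU on NCCT and 1 % of baseline on the perfusion maps by default.
- **Cohorts.** Three strata — within-window, late-with-mismatch (eligible),
  late-without-mismatch (not eligible) — with onset times drawn from
  normals truncated at 0 (resampling), means/SDs 2.70/2.30 h (eligible) and
  8.27/6.10 h (non-eligible), resampled into each stratum's onset range.
  Late-mismatch patients get the favourable geometry above (±10 % radius
  jitter); late-no-mismatch patients get a *matched* lesion (core filling
  the penumbra), which fails the automated criteria by construction
  (ratio ≈ 1, mismatch ≈ 0). Within-window patients carry a favourable
  profile with probability 88/197, the observed within-window automated-
  mismatch rate. Baseline covariates (age, sex, hypertension, NIHSS) are
  sampled per group from the reference cohort's marginals with ~8 %
  missingness, so the summary-table machinery sees realistic input.

**What the phantom does not emulate** — and hence what passing tests do
not show about real data: skull/CSF and tissue heterogeneity, deconvolution
artefacts, partial-volume and beam-hardening effects, motion, inter-rater
variability, and any biological variability in the NWU rate (every
synthetic patient shares one tissue clock, so the synthetic HHM call is a
deterministic function of onset time, unlike the 96.4 % / 22.7 % stratum
rates of the real cohort). Results on phantoms validate the *rules and
statistics*, not clinical performance.

## Statistics

- **Exact binomial CIs** (Clopper–Pearson) via the beta-quantile
  construction (statsmodels `proportion_confint(method="beta")`), degenerate
  bounds fixed at 0/1. These intervals are conservative: coverage ≥ the
  nominal 95 % for every true proportion.
- **Accuracy metrics** from 2×2 counts: sensitivity tp/(tp+fn), specificity
  tn/(tn+fp), PPV tp/(tp+fp), NPV tn/(tn+fn); each CI is the exact interval
  on its own numerator/denominator. A metric with a zero denominator is
  reported as undefined, never fabricated. For a binary test the AUC equals
  (sensitivity + specificity)/2, an identity that holds exactly for every
  table. The AUC CI uses the Hanley–McNeil standard-error formula with a
  normal approximation clipped to [0, 1]; no exact construction exists
  here, and published AUC intervals computed with unnamed methods are not
  expected to match it.
- **Group comparisons.** Pearson chi-square without continuity correction
  (the SPSS "Pearson Chi-Square" convention; Fisher's exact by flag;
  empty-margin tables raise). Student's t (equal variances; zero pooled
  variance raises) and Mann–Whitney U with the tie-corrected normal
  approximation and *no* continuity correction, so identical samples give
  exactly p = 1.
- **Rounding.** Percentages print at 1 decimal with half-up rounding
  (`round_half_up`), matching clinical-table convention rather than
  banker's rounding.
- The complement of NPV (here 100 − 45.5 = 54.5 % for HHM) is exposed as
  `false_omission_rate`; clinical texts sometimes label this quantity a
  "false negative rate", which conventionally means 100 − sensitivity
  instead, hence the unambiguous name.

## Numerical and design choices

- The midsagittal plane is the central plane of axis 0; mirroring is index
  reversal (`i → N−1−i`), an involution that never leaves the grid. No
  registration stage exists — phantoms are generated pre-aligned.
- Relative perfusion comparisons are undefined where the mirrored value is
  0; such voxels use the absolute criterion only.
- The ischemic area keeps only its largest 26-connected component by
  default (a rater ignores speckle); the cleanup has an off-switch and is
  disabled when comparing against the brute-force per-voxel oracle.
- "No CBV lesion present" (the CBF-fallback trigger) means fewer than
  `min_core_voxels` (default 1) voxels, configurable because raters may
  ignore tiny lesions.
- Determinism is contractual: `generate_phantom` requires a seed and the
  same (`PhantomSpec`, seed) pair is bit-identical; cohort generation derives per-patient
  seeds from the cohort seed; `run_pipeline` reports embed the config hash,
  seed and package version.
- Problem sizes: the default test and acceptance runs use the 64×64×16
  grid and the full 247-patient synthetic cohort (a few seconds per run);
  the coverage property uses 2 000 binomial draws at n = 28, p = 0.7, and
  the CI oracle a 10⁻⁴ probability grid over 20 random (k, n) pairs.

## Known limitations

- The phantom's single-rate tissue clock makes synthetic HHM sensitivity
  within the window higher than any real cohort's (all synthetic
  within-window patients with onset < 3.8 h are HHM-positive and all
  later ones negative).
- Only the stated threshold criteria of the automated software are
  reproduced; its proprietary smoothing, deconvolution and segmentation
  post-processing are out of scope, as are DICOM ingestion, skull
  stripping, registration and outcome modelling.
- `cohort_summary` infers binary vs continuous covariates from the data;
  ordinal scales with few levels (e.g. a heavily tied NIHSS) are treated
  as continuous and compared by Mann–Whitney.
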