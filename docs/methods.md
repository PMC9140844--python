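# Methods

## The correction model

A pure ground-glass nodule is modelled as a homogeneous two-compartment
mixture of solid tissue and air. Linear mixing of CT attenuation gives the
tissue fraction

    k = (HU_ggn − HU_air) / (HU_tissue − HU_air),

and, since FDG occupies only the tissue compartment, the corrected uptake
is SUVmaxTF = SUVmax / k. The model's assumptions, in decreasing order of
consequence:

1. **Homogeneity.** Density (and hence `k`) is uniform within the nodule.
   The correction is only meaningful for *pure* GGNs; part-solid nodules
   violate it.
2. **Two compartments.** Everything that is not air is solid tissue at a
   single reference attenuation. `HU_tissue = 50` (liver-like) is a
   convention, not a measured constant; it is exposed as configuration
   precisely because the appropriate value is uncertain. With defaults the
   correction factor is `1050 / (HU_ggn + 1000)`.
3. **No resolution modelling.** PET partial-volume effects are *not*
   corrected; the phantom quantifies the resulting residual
   underestimation instead (below).

Parameters (all `CorrectionParams` fields): `hu_tissue` (default 50 HU),
`hu_air` (default −1000 HU), `suv_cutoff` (default 2.5, dimensionless,
applied inclusively — "≥ cutoff" is positive).

Edge handling: `hu_ggn ≤ hu_air` is an error (k ≤ 0, correction
undefined — division by zero or sign flip downstream); `hu_ggn ≥ hu_tissue`
clamps k to 1 with a warning rather than extrapolating, because a "nodule"
denser than the tissue reference breaks the mixing premise and clamping
degrades gracefully to a no-op. Internal arithmetic is full precision;
2-decimal values are a separate display convention (`*_display`
properties), matching how such values are reported clinically.

## Phantom

`generate_phantom` builds co-registered attenuation and activity volumes:
an isotropic grid (default 64³ voxels at 2 mm) holding a spherical nodule
(voxel-center-in-sphere membership, 0-based indices) of uniform tissue
fraction `k` in a lung background (default −850 HU, SUV 0.4). Inside the
nodule, `hu = k·hu_tissue + (1−k)·hu_air` and `activity = k·tissue_suv` —
the generative counterpart of the correction, so a VOI measurement
followed by `correct_suv` recovers `tissue_suv` exactly (to 1e−9 in tests)
when blur and noise are off. That exact-recovery property is the package's
constructive demonstration that the correction inverts its own model.

PET resolution is emulated by a Gaussian blur of the **activity volume
only** (CT resolution effects are out of scope), parameterized by FWHM in
mm; blur can only lower the measured maximum, monotonically in the FWHM,
so the corrected value then *under*-recovers the truth — a quantitative
handle on the partial-volume underestimation that remains after
tissue-fraction correction. Noise is additive Gaussian on activity, applied
after blur and clipped at zero: a minimal stochastic stress test, not a
physics simulation (no sinograms, no reconstruction, no misregistration).

VOI statistics: SUVmax is the voxel **maximum** of activity (PET
convention); the HU reading is the voxel **mean** over the same sphere — a
max over HU would be biased upward by discretization, and a mean best
matches how a single ROI attenuation value is reported in practice. The
VOI is assumed spherical and concentric with the nodule; neither choice is
dictated by the underlying study protocol, which leaves the VOI shape and
the HU statistic unstated.

## Cohort generator

`simulate_cohort` emulates a 40-nodule cohort in three pathological groups
— 25 invasive adenocarcinomas, 9 minimally invasive adenocarcinomas (MIA),
6 adenocarcinomas in situ (AIS) — from a calibration of per-group
median (Q1–Q3) summaries and visual-positivity rates (packaged in
`ggn_tfc/data/table2_calibration.yaml`). Families:

* **SUVmax — log-normal**, location `ln median`, scale
  `(ln Q3 − ln Q1)/(2 z_0.75)`. Positive and right-skewed; the minimal
  family compatible with a median/IQR summary. Two parameters cannot honor
  three constraints, so asymmetric quartiles are reconciled symmetrically
  in log space with the median pinned — the median is the headline
  statistic and is reproduced exactly (tests check 2% at n = 10,000);
  the quartiles land on the fitted law's, not necessarily the inputs.
* **HU and size — normal**, location at the median, scale `IQR/1.349`,
  truncated to the admissible range: HU to (−1000, 50), size to ≥ 10 mm
  (the inclusion criterion). Truncation is negligible for HU (bounds are
  several SDs out) but *not* for the MIA size row, whose Q1 sits on the
  10 mm bound: the simulated MIA size median is ~2–3 mm above its target.
  Size recovery is therefore not asserted; HU and SUV recovery are.
* **Visual read — Bernoulli** at the group rate, drawn independently of
  SUVmax.

Seeding: one master seed spawns an independent child stream per group
(`numpy.random.SeedSequence`), so appending a group never perturbs
existing groups' draws; identical seeds give identical cohorts,
bit-exactly, including through the CSV round trip (`%.17g` floats,
round-trip float parsing).

### What the generator does not emulate

* **SUV–HU independence.** Within a group, SUVmax and HU are independent;
  no joint distribution is reported to calibrate against. The real cohort
  plainly has SUV–HU coupling: its printed corrected-SUV quartiles are
  *narrower* (in log terms) than its raw-SUV quartiles, whereas under
  independence the ratio SUVmax/k is necessarily *more* dispersed than
  SUVmax. Consequence, measured: the across-group Kruskal–Wallis on
  corrected SUV rejects at 0.05 in only ~35% of 500 simulated cohorts at
  the real group sizes (25/9/6), versus ~92% for raw SUVmax — the
  generator under-states the corrected-SUV group separation seen in the
  real data. Passing pipeline tests on simulated cohorts therefore
  demonstrate correctness of the computation, not the real-data effect
  size for corrected SUV.
* **Within-patient correlation** (two patients contributed two nodules
  each in the real cohort; nodules are simulated independently, as the
  original analysis also assumed).
* **Benign nodules and clinical covariates** (the source cohort contained
  no benign lesions; age/sex/smoking are not simulated).

## Statistical battery

All categorical tests are exact, sized for n ≈ 40:

* **Fisher / Freeman–Halton** (r×c, r,c ≤ 4, total ≤ 200): full
  enumeration of tables with the observed margins; two-sided p is the sum
  of probabilities of tables no more probable than the observed one
  (probability ordering), which reduces to the classic two-sided Fisher
  test on 2×2. Probabilities are compared with a 1e−7 relative tie
  tolerance to absorb float round-off. Larger tables are rejected with a
  pointer to chi-square methods (out of scope).
* **McNemar**, exact binomial: p = 2·BinTail(min(b,c); b+c, ½) capped at 1
  while b + c ≤ 25; continuity-corrected chi-square above. b + c = 0
  returns p = 1 with a degenerate-data note.
* **Wilcoxon signed-rank**: zero differences dropped; up to 20 non-zero
  pairs the exact sign-flip distribution of the positive-rank sum is
  computed by dynamic programming over doubled (hence integer) average
  ranks, and the smaller tail is doubled; above 20, normal approximation
  with tie and continuity corrections.
* **Mann–Whitney U**: exact by enumeration of all rank splits when both
  samples ≤ 10 (handles ties); tie-corrected normal approximation
  otherwise; doubled smaller tail.
* **Kruskal–Wallis**: tie-corrected H against chi-square (scipy); an
  all-identical pooled sample short-circuits to H = 0, p = 1.
* **Bonferroni post-hoc**: p times the number of comparisons, capped at 1.
  Pairwise post-hoc results carry *both* the raw and the adjusted p,
  labelled, since small-sample reports commonly print the unadjusted
  value.

The exact/approximate switch points (25 discordant pairs, 20 signed-rank
pairs, 10/10 for Mann–Whitney) are module constants, chosen so the exact
branch covers every size this pipeline produces while staying effectively
instant; the approximations exist for out-of-range reuse, not for the
study-scale analysis. Every exact procedure is verified in the test suite
against an independent naive full-enumeration oracle (exhaustively for all
2×2 and 2×3 tables with total ≤ 12 and all discordant splits ≤ 12, to
1e−12) and cross-checked against scipy/statsmodels where those implement
the same convention.

Quantiles everywhere use the weighted-average percentile definition
(positions at (n+1)p; numpy's "weibull" method), the default of mainstream
clinical statistics software, so summary rows are comparable with
published tables.

## Pipeline and report

`run_pipeline` validates every record (size ≥ 10 mm, HU within the mixing
range, SUVmax > 0 — failures abort naming the nodule), fills the corrected
value and both positivity flags, then computes per-group and pooled
summaries, the across-group tests for each summary row, pairwise post-hoc
exact tests on visual positivity (all three pairs, raw + Bonferroni), the
paired Wilcoxon (SUVmax shift) and exact McNemar (positivity change), and
the percent change of the pooled median SUVmax (exact value in JSON,
integer-rounded for display). Missing visual reads are permitted and
excluded pairwise from visual-analysis rows only; the semiquantitative
analysis never blocks on them. The machine surface is JSON; the plain-text
table is a display layer.

Structural invariants tested end-to-end: positives-after ⊇
positives-before in every report; group ns and count rows sum to the
pooled column; re-running the pipeline on its own output changes nothing.

## Problem sizes

Default test and verification scales, chosen to make Monte-Carlo error
negligible relative to the tolerances while keeping the full suite fast:
calibration recovery at 10,000 records per group (median tolerance 2%,
rate tolerance 1 percentage point); detection-power estimation over 500
seeds at the real group sizes; the amplification invariant fuzzed over
10,000 random records; oracle equivalence exhaustive to total count 12.
The full suite runs in well under a minute on one CPU.
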