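# Methods

`chronophase` analyzes circadian rhythms in the three data modalities of a
mouse chronotype study — binned locomotor/wheel-running activity, 4-h-sampled
gene-expression time courses, and urinary corticosterone profiles — and ships
a synthetic-data generator that produces all three with the statistical
structure the analysis assumes. Recovery of known simulation parameters is
the package's primary validation: the genotype presets carry the published
cohort estimates for wild-type, *Cry1*⁻/⁻ (short-period, "lark"-like) and
*Cry2*⁻/⁻ (long-period, "owl"-like) mice, and the test suite checks that the
analysis chain run on simulated cohorts returns those values.

## Activity model

The expected activity rate is a rectangular bout of duration α hours riding
on a low baseline. Under an LD cycle the bout starts each day at dark onset
minus the genotype's onset offset (in minutes; positive = onset precedes
darkness); during lights-on the activity component is multiplied by a masking
factor m ∈ [0, 1], representing negative masking by light. Under constant
darkness the bout phase of the last LD day carries over and then drifts by
(τ − 24) h per cycle, where τ is the genotype's free-running period. Counts
per bin are Poisson with the analytic per-bin expectation (bout overlap is
integrated exactly over each bin, so sub-bin onset offsets such as 19.4 min
are represented without rounding). No overdispersion is modeled.

Defaults where the source cohorts report none (chosen once as realistic for
C57BL/6 mice, stated here as the package's own choices): α = 10 h; active
rates 40 counts/min in both modalities (≈ 24 000 wheel revolutions per night,
typical for young C57BL/6); baselines 0.2 (wheel) and 1.0 (locomotor)
counts/min; m = 0.8. A rectangular bout keeps the onset ground truth exact;
an optional smooth edge was considered and rejected because it would blur the
quantity the onset rule estimates.

## Onset detection and phase angle

Onset is the first bin of a 24-h scan window with count ≥ 30% of the window's
single-bin peak, confirmed by at least 3 of the following 6 bins reaching the
same threshold (confirmation may look past the window edge). Scan windows are
anchored at ZT6 — six hours before dark onset — so nocturnal onsets sit
mid-window and never wrap. No smoothing is applied to the counts before
scanning (a boxcar option exists but defaults to off). The phase angle of
entrainment is (dark onset − onset) × 60 minutes, wrapped to (−720, 720];
days without a qualifying onset are excluded, and a subject needs at least 3
valid days to be scored.

Because onsets are quantized to bin edges, a phase-angle estimate is biased
upward by up to one bin width (e.g. the 28-min locomotor offset reads as
30 min at 15-min bins); this discretization is inherent to the rule and well
inside the acceptance tolerances.

## Chi-square periodogram

For each integer bin-period P between 20 h and 28 h the N-bin series is
folded modulo P into columns with counts n_h and means M_h, and

  Q_P = N · Σ_h n_h (M_h − M̄)² / Σ_i (x_i − M̄)²

is compared with the χ²(1 − α, P − 1) critical value (pointwise, α = 0.05, no
multiplicity correction by default; the classical Sokolove–Bushell statistic
and its distribution theory). The period estimate is the significant P with
the largest Q_P, converted to hours; the grid is integer bin-periods only, so
the resolution equals the bin width (2-min bins → 1/30 h). Q_P is invariant
under affine transforms of the counts. The standard analysis window is
12 full DD days commencing one day after release into darkness. Free-running
periods that fall between grid points (22.59 h → nearest grid 22.600 h) incur
a quantization error below half a grid step, which dominates the residual
bias seen in period recovery (≤ 0.04 h, tolerance 0.1 h).

## Expression and hormone generators

Expression at ZT t follows a truncated Fourier profile
μ(t) = mesor + Σ_k A_k cos(2πk(t − φ)/24) with A₁/mesor = 0.9 by default
(clock genes are high-amplitude), multiplied per observation by a lognormal
factor with mean 1 and CV 0.2 (each observation is an independent animal,
matching a sacrifice design of 6 time points × 3–4 animals). Values are
strictly positive by construction.

Corticosterone uses the same profile shape (mesor 40 ng/ml, amplitude 30)
passed through the reported immunoassay error model: mean recovery 97.3%,
duplicate wells with intra-assay CV 3.1%, a shared lognormal batch factor per
collection time with inter-assay CV 11.1% (urine was collected once per
time point, so one batch per time), and a 0.29 ng/ml detection limit below
which replicates are flagged. Two animal-level terms create between-animal
variation: a lognormal level factor (CV 0.25) and a Gaussian peak-time offset
with SD 1.0 h. The phase SD is derived once from the published group ANOVA —
F(2,23) = 13.47 with group peaks 14.53/12.04/14.12 ZT h and n = 8 implies a
within-group phase SD near one hour — and makes the simulated significance
pattern (Cry1 vs Cry2 significant, wt vs Cry2 not) reproducible; without it
every between-group gap would be declared significant.

What the generators do **not** emulate: ultradian activity structure,
light-intensity-dependent masking, inter-individual τ variation, circadian
waveform asymmetry in expression profiles (single-harmonic default), feeding-
driven components of liver gene expression, or assay drift within a batch.
Passing recovery tests therefore show the analysis chain is correct and
well-calibrated under the assumed structure, not that it is robust to every
feature of real recordings.

## Wave fit and center of gravity

The "wave curve" is ordinary least squares on a Fourier basis of fixed period
T = 24 h. Harmonics are added by forward selection (partial F-test, α = 0.05)
up to H = 2; two harmonics capture the asymmetric peaks seen in peripheral
tissues while keeping 6-time-point designs identifiable. Rhythmicity is the
F-test of the one-harmonic model against the intercept-only model,
F = ((SS_flat − SS_res)/2)/(SS_res/(n − 3)). The period is fixed because the
data are entrained; free-running period estimation belongs to the
periodogram.

The phase marker is the center of gravity: the fitted curve is sampled at
0.1-h steps over one period, weighted by its height above the curve minimum
(a floor at the minimum rather than the mesor keeps weights non-negative for
asymmetric waves), and the weighted circular mean is reported. Dispersion is
the Mardia circular SD √(−2 ln R) · 24/2π hours, R being the mean resultant
length; this convention is stated explicitly because several exist. For
per-animal phases (needed for the corticosterone one-way ANOVA) the same
computation runs on the raw samples of one animal, with duplicate assay wells
averaged first. Group-level panels use the fitted-curve COG; per-animal
comparisons use the sample-level COG. For a pure cosine sampled uniformly the
sample-level COG is exact at any acrophase, on or off the sampling grid.

## qPCR quantification

Triplicate Cq values are collapsed by a conservative QC rule: a replicate
deviating more than 0.5 cycles from the replicate median is dropped (at most
one); mutually discordant replicates are an error. Primer efficiency comes
from the standard-curve slope, E = 10^(−1/slope) (E = 2 is perfect doubling);
relative expression is the efficiency-corrected two-gene ratio
E_t^(−Cq_t)/E_ref^(−Cq_ref) normalized to *β2m* without a calibrator sample —
time courses are subsequently rescaled to percent of peak (largest per-time
group mean = 100, within genotype), which makes a calibrator redundant.
With E = 2 throughout the ratio reduces to 2^(−ΔCq).

## Group statistics

Two-way genotype × time ANOVA with interaction uses the classical balanced
decomposition when cell counts are equal and Type II sums of squares (OLS)
for the mildly unbalanced 4-vs-3 design. One-way ANOVA on circular phases
first unwraps all phases to the linear branch nearest the circular grand
mean (shifting by ±24 h), which makes linear ANOVA defensible for
concentrated phase samples; pairwise comparisons are two-sample t-tests with
Bonferroni adjustment (p × m, capped at 1). Onset comparisons use the
Mann-Whitney U test, exact for small untied samples (n₁·n₂ ≤ 400), otherwise
the tie-corrected normal approximation, reporting min(U₁, U₂). All tests are
two-tailed at α = 0.05. The interaction term's type-I error is verified at
5% ± 2% over 2000 null simulations.

## Problem sizes and determinism

Validation uses the study's own cohort sizes: 6 wheel-running animals per
genotype over 13 DD days at 2-min bins for period estimation; 10–12 animals
over 5 LD scan windows for onsets; 8 animals × 6 collection times × duplicate
wells for corticosterone (averaged over 5 seeds); 6 time points × 3–4 animals
for expression panels (averaged over 10 seeds). Every generator takes an
explicit seed; cohort member i uses stream seed + i, and the replay pipeline
derives disjoint seed blocks per genotype and stage, so every reported
estimate is reproducible from the master seed and the config hash recorded in
the report.

## Known limitations

- The periodogram's grid resolution equals the bin width; no interpolation
  between grid periods is attempted.
- The onset rule's bin-edge quantization biases phase angles by up to one
  bin width.
- Circular phases are compared with linear ANOVA after unwrapping, not with
  a circular ANOVA (Watson–Williams); the unwrapping is only defensible for
  concentrated samples (circular SD ≪ period/4).
- The reported "± circular SD" of a fitted-curve COG measures the waveform's
  mass dispersion, not between-animal variability; the two are not
  interchangeable and are computed by separate functions.
- Survival analysis and body-weight trajectories are out of scope.
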