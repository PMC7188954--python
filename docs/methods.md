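# Methods

## The assay and its data model

Allele-specific qPCR separates the two alleles of a SNP into two wells: in
each, an allele-specific primer amplifies only templates carrying its
allele, and a gene-specific hydrolysis probe reports amplification on one
detection channel. Indel targets use a single presence/absence reaction
(named `GENE_+`) placed in both wells of the pair. A control gene is
amplified in every well to verify DNA load. The plate layout is encoded
entirely in the sample and target names: wells of one sample share one
sample name; target names follow `GENENAME_ALLELENAME` with the allele
after the *last* underscore; a name without a suffix is a bare marker (the
control gene); wells with identical marker sets form a *kit*; no-template
controls carry the NTC sample type.

One imported file holds one or more plates; each well carries one reaction
(fluorescence trace) per channel. Analysis is strictly per plate with
shared settings, and multi-file batches are concatenations of per-plate
results — this batch invariance is asserted by a test.

## Curve processing

1. **Baseline.** An ordinary least-squares line is fitted to the trace over
   the background cycle range (default cycles 5–15, the flat region before
   exponential growth) and subtracted across all cycles.
2. **Model fit.** Nonlinear least squares (`scipy.optimize.curve_fit`,
   trust-region reflective) of one of four sigmoid models, x = cycle:

   * `b5`: F(x) = c + (d − c)/(1 + exp(b (x − e)))^f
   * `b4`: `b5` with f ≡ 1 (then e is exactly the inflection point)
   * `l5`: F(x) = c + (d − c)/(1 + exp(b (ln x − ln e)))^f
   * `l4`: `l5` with f ≡ 1

   Starting values come from the data (c = min, d = max, e = half-rise
   crossing, b from the steepest observed rise; the maximum slope of a
   4-parameter logistic is −b(d−c)/4). Optimizer failure is encoded as
   `converged = False`, never an exception. For symmetric (f = 1) models
   the mirrored solution (−b, d, c) describes the same curve and is folded
   back so fits report rising orientation; orientation in general is the
   sign of b·(d − c).
3. **Cq.** Five methods on the fitted curve: `cpD1` (first-derivative
   maximum), `cpD2` (second-derivative maximum), `maxE` (maximum of the
   cycle-efficiency proxy E(x) = F(x)/F(x−1)), `expR` (first cycle where
   F′ reaches 5% of its maximum — "exponential region start" needs an
   explicit definition and this is ours), and `Cy20` (the cycle where F
   crosses 20% of the rise reached at cpD2, measured from the departing
   asymptote). Maxima are located on a 0.01-cycle grid and refined by
   parabolic interpolation; analytic first derivatives are used, second
   derivatives by central differences of the analytic first derivative.
   The search grid extends half a span past the last recorded cycle so a
   fit whose transition lies beyond the data reports it there instead of
   clamping to the boundary. For noise-free logistics, cpD1 = e and
   cpD2 = e − ln(2 + √3)/k reproduce the closed forms to < 1e-4 cycles.
4. **Amplification detection.** A reaction is amplified when (a) a Cq
   exists, (b) it lies within the recorded cycle span, (c) the amplitude —
   the smallest of the fitted d − c, the fitted rise over the span, and the
   observed data rise — clears a noise floor of max(10 RFU, 6 × the
   baseline residual SD), and (d) the sigmoid beats a straight line in a
   nested-model F-test at α = 1e-5. Check (d) exists because baseline
   subtraction extrapolates an 11-point line across 40 cycles: negative
   reactions keep a residual tilt of tens of RFU that a sigmoid fit happily
   absorbs, and the lack-of-fit test is the statistically standard way to
   reject it. Cq-range and RFU-threshold checks are deliberately *not*
   part of detection — they are separate QC codes.
5. **Endpoint.** Mean of the last three corrected readings (robust to
   final-cycle jitter). When preprocessing is off, traces are taken as the
   instrument software produced them and the file's Cq values are used.

Flat traces whose observed rise is below the detection noise floor skip
the sigmoid fit; the screen uses the same floor as detection, so it only
saves time and cannot change an outcome.

## Quality control and calling

Seven per-reaction codes: `RFU_QC` (endpoint below the RFU threshold),
`ampStatus_QC` (no amplification), `replicateMatch_QC` (Cq spread across
replicate wells beyond Cq Δ), `noAmpNTC_QC` (an NTC well of the kit
amplified; contamination invalidates the whole kit on that plate),
`ctrlMarker_QC` (control gene dead in a well; the paired well is excluded
with it), `allelesDeltaCq_QC` (control-adjusted allele ΔCq beyond Cq Δ;
the adjustment subtracts the control-gene ΔCq of the same wells and so
cancels per-well load offsets — a deliberate asymmetry: replicate matching
is *not* control-adjusted), and `kit_QC` (the sample's wells for the kit
could not be paired).

Calling gates on `kit_QC`, `replicateMatch_QC`, `ctrlMarker_QC` and
`noAmpNTC_QC` → `NA`. Each allele reaction is then *positive* (amplified,
Cq in range, endpoint ≥ threshold), *cleanly negative* (no amplification
and endpoint < threshold) or *uncertain* (the mixed states: Cq in range
with low endpoint, or out-of-range Cq with high endpoint — and any other
conflicting combination). Two positives with a passing ΔCq check →
heterozygote (alleles reported alphabetically); positive + clean negative →
homozygote; two negatives → `NA` ("no signal"); anything uncertain → the
pair is `Uncertain`. Requiring the negative side of a homozygote to be
*cleanly* negative is a safety choice: an ambiguous negative degrades to
`Uncertain` rather than risking a wrong definite call. Indels follow the
same state logic: both positive → `Insertion`, both cleanly negative →
`Deletion`, else `Uncertain`. Replicate pairs must agree or the marker is
`NA` ("replicate mismatch"). The whole decision table is checked cell by
cell against an independently written brute-force enumeration, plus a
monotone-safety property: worsening any single QC code never upgrades a
non-definite call to a definite genotype.

## The simulator

The default design is the production panel geometry: 96 samples on 12
plates, 8 samples/plate, five kits of four targets each (19 SNPs + 1
indel) plus the B2m control gene in every well, five channels, 40 cycles.
That yields 400 reactions per plate and 4,800 per study, with 1,920
possible target calls and a 480-reaction fully-loaded-plate capacity. NTC
wells (one pair per kit, columns 11–12) are optional because the counting
identities above describe sample wells only.

Curves are 4-parameter logistics (k = 0.8, amplitude 1000 ± 10% RFU) on a
baseline of 50 RFU with 0.5 RFU/cycle linear drift and i.i.d. Gaussian
noise (default σ = 20 RFU, i.e. 2% of amplitude). Genotypes are drawn
under Hardy–Weinberg proportions at allele frequency 0.5 (deletion-allele
frequency 0.5 for the indel, so one sample in four is a homozygous
deletion). Marker base Cqs are uniform on 18–21 cycles so that, after the
offsets below, every true Cq stays inside the default 15–25 window.
DNA-load variation has two layers: a per-sample offset (SD 0.5, clipped at
±1.2 cycles) shared by all the sample's reactions, and a per-well
pipetting jitter (SD 0.15, clipped at ±0.4) shared by all reactions *in
that well* — the latter is exactly what the control-gene ΔCq adjustment
must cancel. Heterozygous alleles run one cycle later than homozygous ones
(half the template per allele). Positive reactions carry their true
inflection cycle as the file Cq, so the no-preprocessing path is testable.

Defect injection mutates labeled reactions in place and records the scope
of calls each defect may legitimately change: `low_rfu` rescales one
positive target reaction to half the RFU threshold; `ntc_contamination`
turns one NTC target reaction positive; `missing_control` kills one well's
control reaction; `evaporation` drifts one well's Cqs unevenly across
channels (targets +6–9 cycles, control +0–1 — the channel-uneven signature
that the control-adjusted ΔCq check catches); `load_imbalance` shifts one
well uniformly by +1 cycle (which calling must absorb); `late_rise` moves
one positive reaction's transition two cycles past the last recorded
cycle. Defect-sensitivity experiments run on noise-free studies so every
flip is causally attributable to its defect rather than to noise.

What the simulator does *not* model: multiplicative or periodic instrument
artifacts, channel cross-talk, probe chemistry, pipetting failures other
than load offsets, or realistic allele-frequency spectra. Passing recovery
tests therefore demonstrates the correctness of the pipeline's logic and
numerics under the stated noise model, not calling performance on degraded
real-world DNA.

## Problem sizes and numerical choices

The test suite and the acceptance script analyze full 4,800-reaction
studies (about 15 s each with noise) plus small two-kit designs for unit
tests. Tolerances: Cq oracles at ±0.01 cycles; fitted inflection recovery
at ±0.1 cycles over 100 replicates at σ = 0.5% of amplitude; noise-free
end-to-end concordance must be exact, noisy (2%) concordance ≥ 99%.
Degenerate inputs (constant traces, single wells, empty call lists) flow
through as non-converged fits, unpaired samples and header-only reports
rather than exceptions. Well positions are normalized to zero-padded form
("A1" → "A01"); kit identifiers are the sorted marker names joined with
"|", so batches merge deterministically; heterozygote allele order is
alphabetical.

## Known limitations

* The efficiency-curve Cq (`maxE`) uses the F(x)/F(x−1) proxy; on a
  baseline-corrected curve with c ≈ 0 the proxy is nearly flat before the
  transition and its maximum is poorly localized. `cpD1`/`cpD2` are the
  recommended methods.
* Replicates beyond two wells per sample and kit are paired only when the
  well count is even and allele layouts split cleanly; anything else is
  flagged unpaired rather than guessed.
* RDML ingestion reads the subset needed for calling (samples, targets,
  dyes, amplification data points, Cq); other document content is ignored.
  Writing RDML is supported only for the simulator's own output.
* xlsx as an *input* format is not supported (no defined plate schema);
  use RDML or the CSV/JSON fixture dialect.
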