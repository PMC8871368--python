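# Methods

This note documents the models behind each pipeline, the parameters that
matter, the synthetic-data generators and what they do and do not emulate,
and the numerical choices made where the analysis conventions were open.

## 1. Gamma waiting-time burst detection

**Model.** A unit's spontaneous discharge is referenced against a homogeneous
Poisson process with rate λ̂ = n_spikes / T (the whole-recording estimate; a
`rate_estimator` hook exists for alternatives). Under that null, the waiting
time for *k* consecutive ISIs is gamma(k, λ) distributed, so the probability
of seeing *k* ISIs inside a window τ is the regularized lower incomplete
gamma function

    p(k, τ, λ) = P(k, λτ) = P(Poisson(λτ) ≥ k),

which is small exactly when firing is locally much faster than the unit's
overall rate. `scipy.special.gammainc` evaluates it; the Poisson tail sum is
kept as an independent oracle in the tests (agreement to 1e-10 over
k ≤ 50, λτ ≤ 100).

**Detector.** For every spike index j ≥ k_min the probability
p_j = P(k_min, λ̂ · (t_j − t_{j−k_min})) is computed over the k_min most
recent ISIs. A burst is a maximal run of at least k_min consecutive indices
with p_j < α; it covers spikes j_first − k_min through j_last. Defaults:
α = 0.01, k_min = 10. Runs are disjoint; if a run's backward window would
reach into the previous burst the overlap is clipped deterministically.

The sliding-window form was chosen over a start-anchored cumulative scan
after analysis of the alternatives: a cumulative statistic that must stay
below α from k = 1 can never start at physiological within-burst ISIs
(p(1, τ) < 0.01 needs τ < −ln(0.99)/λ ≈ 1.6 ms at 6 Hz), while a cumulative
statistic tested only from k = k_min has a per-start null rate of exactly α
by the probability integral transform (≈5 false bursts per 100 s at 5 Hz)
and, once triggered, absorbs several seconds of trailing background before
the accumulated evidence decays. The sliding window with a persistence
requirement detects bursts at realistic rates, terminates at the first
sizeable gap, and has a measured null rate of ~0.01 bursts per 100 s train
at 5 Hz (requirement: ≤ 0.05). Consequences: a detectable burst needs at
least 2·k_min ISIs, and one or two background spikes adjacent to a burst
(gaps ≲ 0.4 s at λ ≈ 6 Hz) may be absorbed into it.

**Other ISI statistics.** CV uses the sample (n−1) standard deviation.
Pooled ISI comparisons draw n ISIs per unit without replacement
(n = smallest per-unit count) so high-rate units do not dominate; the pooled
samples are compared with the two-sample KS test and a chi-square test on
shared log₁₀ histograms (5 bins/decade over 1 ms–100 s, sparse bins merged
rightward until expected counts reach 5). Duplicate spike times are rejected
at load; edge-truncated runs still count if they reach k_min ISIs.

## 2. Imaging event detection

**Procedure.** For Fura-2 data the 340/380 ratio is formed pixelwise
(denominators ≤ 1 count are masked). Each frame F_n is reduced to
Δ_n = F_n − mean(F_{n−1}…F_{n−5}); the first five frames carry no valid Δ
and are excluded. A scalar baseline is the spatio-temporal mean of a quiet
ROI (default: a 20 µm strip along the top of the field, outside the ISC
band). Pixels with Δ > 0.10 × baseline are active; per-frame 8-connected
components are linked across frames by ≥ 1 px spatial overlap, bridging
single-frame gaps (near-threshold events flicker). An event is kept iff its
maximum instantaneous component area reaches the one-ISC minimum
(default 50 µm², configurable); its reported area is that maximum, its
centroid is taken at the peak frame, and it belongs to the analysis ROI
(an axis-aligned 10,000 µm² square centered on the field) iff that centroid
falls inside. Frequency = events/s over the stack duration.

Thresholding is pixelwise on the Δ image against the scalar baseline, and
event area is the maximal instantaneous extent rather than the
spatio-temporal union — the conservative readings of an
ImageJ-macro-plus-manual-counting workflow.

## 3. FRA tuning metrics

Rates are counts/(reps × 100 ms window). A bin is significant when its rate
exceeds spontaneous + 3·SD, both estimated from the lowest-level row unless
supplied. Threshold is the lowest level with a significant bin whose
frequency remains significant one level higher (the vertical-support rule:
a genuine V-shaped response region grows with level, an isolated Poisson
fluctuation does not — without it a single noise bin among ~400 regularly
hijacks CF at c = 3; the rule is configurable). CF is that bin's frequency,
ties broken by larger response then lower frequency. BW_n is the width of
the significant span containing CF at threshold + n dB, reported **at grid
resolution** (outer significant columns; rows linearly interpolated when
threshold + n falls between level rows; islands not touching the CF span are
ignored with a warning). Sub-column edge interpolation was deliberately
omitted: at the sharp response edges produced by a thresholded rate surface
it systematically drags the edge to the first non-significant column, and
grid-resolution reporting keeps noiseless recovery exact. Q_n = CF/BW_n;
a single-column span leaves BW undefined (reported missing).

## 4. Input maps

PSP amplitude is the peak depolarization from the pre-onset baseline (mean
of the 50 ms before laser onset) within a 20 ms post-onset window; a site is
an action-potential site when the trace overshoots 0 mV. Classes use strict
inequalities (> 2 mV, > 10 mV); AP sites count as strong. Input area =
100 × n_responsive × 400 µm² / MNTB polygon area — responsive sites slightly
outside the outline are counted. Input width = the maximal **x-projected**
separation of strong sites (the mediolateral/tonotopic axis is x by
convention; a `swap_axes` flag handles unrotated maps), normalized to the
polygon's x extent; zero or one strong site gives width 0. Polygon geometry
uses shapely.

## 5. Synthetic-data generators

One root seed drives everything; per-unit/per-stack streams derive from
(seed, index) via `numpy.random.SeedSequence`. Calibration constants live in
`src/prehear/presets.yaml` and were fixed once by simulating cohorts at the
study sizes and matching the pipeline outputs to the target group
statistics; they are not tuned per run.

**Spike trains.** Background spikes are homogeneous Poisson (WT 0.6 Hz,
cKO 1.0 Hz). Burst epochs contain lognormal numbers of mini-bursts
(WT median 15, σ = 1.05, floor 8; cKO median 7, σ = 0.7, floor 2) at
100 ± 15 ms intervals; each mini-burst holds 1 + Poisson spikes (per-burst
density lognormally spread) at 25 ± 6 ms ISIs. Burst onsets are
quasi-periodic — sub-Poisson count dispersion (≈ gamma-renewal shape 3) with
stratified onset times — reflecting the recurring Ca²⁺-wave drive; this also
stabilizes 14-unit cohort medians. Per-unit lognormal jitter (σ = 0.4)
spreads rates across units. Burst counts and event counts invert the
relevant CDF on the stream's first uniform so that, for matched seeds, the
WT preset never produces less burst/event load than cKO. Known limitation:
the cKO preset prioritizes the regular-firing (low-CV) phenotype; its
overall rate (~2 Hz) sits below the WT rate rather than matching it, so
"overall rate does not differ" is not a property of these presets.

**Imaging stacks.** Events are discs (lognormal areas; WT Ca²⁺ median
3250 µm², cKO 640 µm²; DIC WT 7350 µm²) placed in a horizontal band standing
in for Kölliker's organ, with a linear rise (6 frames), hold (2) and decay
(6) of amplitude 0.30–0.35 × baseline; the steady rise keeps every footprint
pixel above the Δ threshold simultaneously, so the detected instantaneous
area matches the footprint. WT discs drift along the tonotopic axis at
3 µm/s (a phenomenological wave — the within-event growth law is not
constrained by data and no Cl⁻/ATP biophysics is modeled); cKO events are
stationary. Fura stacks emit 16-bit 340/380 channels with the event signal
multiplicative on the 340 channel only and 1.2% multiplicative noise per
channel; fields are 256 × 256 µm at 2 µm/px. Concurrent events may merge
during detection, which is why detected mean areas exceed the generative
median; the calibration absorbs this.

**FRAs.** V-shaped threshold curves with constant dB/octave flanks
(WT 70/90, cKO 40/55, per-unit lognormal sharpness spread σ = 0.25), rate
ramping from spontaneous (5 AP/s) to max (WT 260, cKO 220 AP/s) over 15 dB,
switching on exactly at local threshold; counts are Poisson over
20 reps × 100 ms. Frequency grid: 61 log-spaced points 4–40 kHz; levels
0–80 dB in 5 dB steps; cohort CFs are snapped to the grid.

**Maps.** The MNTB outline is an ellipse (WT 63,000 µm², cKO 55,000 µm²,
aspect 1.4, lognormal area jitter σ = 0.07). The PSP profile is an
anisotropic Gaussian whose 2 mV contour covers the target fraction of the
outline (WT 10%, cKO 20%) and whose 10 mV contour spans the target fraction
of the mediolateral extent (WT 18%, cKO 36%, plus a 25 µm pad compensating
the ~one-grid-cell downward bias of sampling a continuous span every 20 µm);
amplitude noise is 0.5 mV; the grid has a random sub-spacing origin offset,
which makes expected site counts exactly area/spacing².

**What passing tests show.** The generators emulate the *statistics* the
pipelines measure — they contain no biophysics, no optics, no motion or
bleaching artifacts, no electrode drift, and no spike-sorting ambiguity.
Recovery results therefore validate the analysis code and its calibration,
not the experimental robustness of the methods on real recordings.

## 6. Statistics and reporting

Summaries are mean ± SEM (sample SD/√n) or median with 25/75% quartiles
(linear interpolation). The test per metric is fixed by configuration
(Mann–Whitney for skewed burst/tuning metrics, unpaired t for rates and
areas, paired t for within-preparation designs, KS/chi-square for pooled ISI
distributions, two-way ANOVA via statsmodels for rate-level functions);
normality screening is deliberately not automated, so the reported table is
reproducible. Stars: * < 0.05, ** < 0.01, *** < 0.001.

## 7. Problem sizes

Default runs use the study's cohort sizes: 14/15 spike-train units at 100 s,
14/16 Fura ratio stacks (400 frames, 1 fps), 7/9 DIC stacks (1200 frames),
25/32 FRAs, 10/10 maps. Imaging fields are 128 × 128 px at 2 µm/px, which
keeps a full run at a few minutes on one CPU while leaving event footprints
tens to thousands of pixels in size.
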