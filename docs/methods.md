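# Methods

## Data model and conventions

All times are seconds in double precision. Intervals are half-open
`[start, end)`; histogram bins are half-open on the left and closed on the
right, `(low, high]`, so the bin "containing 2.0 ms" is (1.5, 2.0] and the
causal region of interest 0 < τ ≤ 5 ms is exactly ten 0.5-ms bins. Lag is
always target minus reference: positive lags mean the target (postsynaptic)
spike follows the reference (presynaptic) spike. Symmetric lag grids have
edges aligned at zero (an even number of bins); the one exception is the
CCH-difference grid used for classification, which is offset by half a bin
so that a zero-centered bin exists and the ±10-ms window holds exactly 21
one-millisecond elements. Sessions are read and written as three TSV files
(spikes, events, epochs) with times serialized at six decimal places, which
makes write∘read the identity and whole pipeline runs byte-reproducible.

## Spike transmission curve and STG

The count CCH of a pair mixes three components: the monosynaptic excess,
slow co-modulation (behavioral state, rate covariations), and the imprint
of the presynaptic autocorrelation (bursts, refractoriness) on both. The
transmission curve is obtained by (1) deconvolving the presynaptic ACH from
the raw count CCH and (2) subtracting a slow baseline estimated by hollowed
median filtering of the deconvolved curve.

The deconvolution solves `cch[i] = Σ_d K[d]·c[i−d]` on the finite ±30-ms
lag window, where `K[0] = n_ref` (each reference spike co-occurs with
itself) and `K[d≠0]` is read off the measured ACH at lag `d·Δ` (average of
the two straddling bins, zero outside the window). The Toeplitz system is
solved by least squares with Tikhonov regularization,
`λ = 10⁻⁶·trace(AᵀA)/n`; the factorization is cached so permutation
replicates cost one triangular solve each. For a Poisson reference the
kernel is diagonal-dominated and the curve collapses to
`cch_excess/(n_ref·Δ)` — this flat-ACH equivalence is asserted in the tests
to 1% RMS, and a forward-convolution round trip with a bursty (doublet)
ACH is recovered to 5% RMS over the interior of the window. Edge bins of
the window carry known residuals from the finite-lag truncation and are not
part of the contract.

Order of operations matters: subtracting the baseline *before*
deconvolution removes the flat excess contributed by neighboring
presynaptic spikes' transmission once via the median and again via the ACH
kernel, deflating the STG by roughly (presynaptic rate × lag window) —
about 12% at 2 spk/s. Deconvolving first and subtracting a hollowed median
of the deconvolved curve avoids the double subtraction.

The baseline half-width is 5 ms where the corresponding PSTH/synchrony
analyses specify it (CLE, light response, synchrony predictor). For the
transmission curve itself the half-width is 15 ms (61-bin window at 0.5-ms
bins): the monosynaptic peak spans up to 10 bins, and with a 21-bin window
those elevated bins push the hollowed median to the ~70th percentile of the
background, biasing the STG low by 8–20% depending on coupling strength.
Ground-truth recovery on synthetic pairs (45-min epochs, 2 spk/s → 10
spk/s) is within ~5% of the injected transmission probability across
p ∈ {0.01, 0.05, 0.1} with the 61-bin window. Both half-widths are
configurable.

The STG is the area under the causal peak: the maximal bin within
0 < τ ≤ 5 ms, extended left (bounded by lag 0) and right until the curve
first drops to ≤ 0 or the window ends, times the bin width. A pair with no
positive bin in the region has STG 0. Because the statistic selects a
maximum, its null distribution is positively biased (~0.005 at 10-minute
epochs); uncoupled pairs are screened out by the detection test rather than
by the STG value itself.

## Permutation test for STG-change consistency

Rows of a binary matrix are presynaptic spikes from Before∪After, columns
are 0.5-ms lag bins on (−30, 30] ms (120 bins), and entries mark whether a
postsynaptic spike occupies the bin. The observed change and all 2000
shuffled changes flow through the same path: column sums per partition →
deconvolution → hollowed-median subtraction → peak area → log₂ ratio. The
deconvolution kernels are label-invariant across shuffles: the
combined-epoch ACH scaled by (n_part/n_total)² — the expected pair-survival
fraction of a random row subset — with the zero-displacement term set to
the partition's row count. Recomputing the presynaptic ACH per shuffle is
not meaningful here because the row labels do not alter the presynaptic
train. Two-sided p-values use |shuffled| ≥ |observed| with ties counted as
extreme and the add-one correction, so the minimal attainable p is
1/(n_shuffles+1). Shuffles in which either partition yields a non-positive
STG leave the log-ratio undefined; they are redrawn (up to 3× the shuffle
budget) and any still-unresolved draws are counted as extreme, which is
conservative. Calibration on 200 simulated null pairs gives a
flagged-increase rate statistically indistinguishable from the 2.5%
per-direction chance level and uniform p-values.

## Closed-loop feedback metrics

The CLE divides the PSTH excess in −5 ≤ τ < 0 ms (1-ms bins, hollowed
median baseline at 5-ms half-width) by the unit's total spike count in the
analyzed period — per-spike, not per-event, so it reads as "the fraction of
this unit's spikes that generated stimuli" — and clips to [0, 1]. With
sparse triggers it recovers the simulator's detection probability; at high
trigger rates it recovers the *realized* efficiency, which is lower because
spikes arriving during the 50-ms stimulus-plus-dead-time blanking cannot
trigger. The light gain divides the mean PSTH rate in 10 ≤ τ < 30 ms by the
mean in −30 ≤ τ < −15 ms; a zero-count baseline flags the gain undefined
rather than dividing by zero.

## Synthetic sessions

The generator reproduces the study conditions: Before/Experience/After
epochs (defaults 45/55/45 min), PYR rates 0.5–5 spk/s, PV rates 5–30 spk/s,
transmission probabilities drawn log-uniformly from 0.005–0.2, a 3-ms
detection delay, 30-ms stimuli with a 20-ms dead time, Bernoulli spike
detection, and a light-induced PV rate gain defaulting to 1.56. Presynaptic
trains are renewal processes — exponential intervals plus a 2-ms absolute
refractory period, with the hazard corrected so the mean rate is exactly
nominal. The postsynaptic intensity is
`λ(t) = base·g(t) + Σ_pairs Σ_s k(t−s)` with a rectangular causal kernel on
(0.5, 3.5] ms; it is sampled exactly by superposition (piecewise-constant
baseline process plus at most one evoked spike per presynaptic spike with
probability p and uniform latency over the kernel), after which
refractoriness is imposed on the merged train. Bernoulli rather than
Poisson-count transmission matches the meaning of a monosynaptic
transmission probability and avoids self-collision losses that would make
the injected p unrecoverable under refractoriness. Injected plasticity
multiplies p from the Experience epoch onward (the measured contrast is
Before vs After); factors can be fixed per assembly, drawn per assembly
(coherent changes), or drawn per pair (independent changes).

What the generator does **not** emulate: bursting and theta/ripple
structure in PYR trains, common drive within assemblies (PYRs are
independent given their rates), recurrent or divergent connectivity,
short-term synaptic dynamics, waveform-level detection errors, and
nonstationarity of rates within epochs. Passing recovery tests therefore
demonstrates estimator correctness under the stated point-process model,
not robustness to every property of in vivo data.

### Classifier cohorts

The timing/rate dissociation uses 122 Experience-only assemblies whose
binary label (plasticity direction) is encoded in exactly one information
channel. In the **latency** cohort, presynaptic spikes during a stimulus
recruit an extra transmission kernel of fixed integral (0.1) whose latency
depends on the label (0.5–3.5 vs 5.5–8.5 ms); the class-conditional added
rate is equal, so only millisecond timing separates the classes. In the
**gain** cohort the PV rate gain differs by label (≈2.1 vs ≈1.3) with spike
timing untouched. A genuinely rate-only condition needs care: with 30-ms
stimuli, the probability that a lagged bin is still inside the stimulus
falls off with |τ| across a ±10-ms window, imprinting a label-scaled
triangular shape on the CCH difference — timing-like information that
survives Z-scoring. The gain cohort therefore uses 100-ms stimuli and
applies the gain envelope with a ±10.5-ms margin around each stimulus, so
the rate modulation is constant across the analysis window of every
in-stimulus reference spike. With that construction the Z-scored (timing
only) classifier is at chance on the gain cohort and near-perfect on the
latency cohort, while the bin-shuffled (rate only) classifier shows the
reverse.

## Cross-validated learners

SVR uses an RBF kernel with C = 1 and the kernel width set by the median
heuristic of pairwise distances on the standardized training folds; the SVM
is linear with C = 1. Features are standardized on training folds only;
out-of-fold predictions are pooled within a repeat before computing the
single R² or AUC of that repeat. Fold schemes: row-level random folds;
entire-assembly folds (greedy size-balanced allocation of whole assemblies,
so no assembly spans train and test); and one-pair-per-assembly
subsampling, repeated until every pair holds the requested number of
predictions. Label-shuffled controls reshuffle independently per repeat.
One calibration caveat is worth stating: the null distribution of a
cross-validated AUC at n = 122 has SD ≈ 0.05–0.07 (the binomial
Hanley–McNeil floor plus overdispersion from classifiers partially fitting
the shuffled labels), so individual null repeats fall outside [0.4, 0.6]
several percent of the time; chance-level conclusions should rest on the
mean over repeats, not on single draws.

The virtual closed loop draws a target CLE per assembly from a log-normal
matched to the real trigger-unit quantiles (median 0.054, IQR 0.013–0.184),
tags that fraction of a randomly chosen presynaptic unit's Experience
spikes, and derives onsets with the 3-ms delay and dead-time blanking; no
spike train is modified, and recomputing the CLE from the sham events
closes over the drawn value.

## Problem sizes

Default analysis sizes are chosen so a full run completes in minutes on one
CPU: recovery tests use 45-min epochs (the study schedule) for single
pairs, 10–20-min epochs for cohorts of 20–200 pairs; permutation tests use
1000–2000 shuffles; classifier cohorts use 122 assemblies at 300 s of
Experience each; the demo pipeline session uses 10/12/10-min epochs with
three assemblies. All sizes are parameters.

## Known limitations

- The STG estimator retains a small negative bias (2–5%) from postsynaptic
  refractory collisions and peak truncation at the zero crossings; it is
  within the recovery tolerance but not removed.
- The deconvolution contract covers the interior of the lag window; edge
  bins are best-effort.
- The "between stimuli" intervals of the CCH difference apply no guard
  period after stimulus offset; slow opsin tails would leak into the
  between-CCH (configurable window, not modeled by the generator).
- Single-session non-peer means are an affine function of the own-assembly
  mean (the session total is fixed), which induces a spurious negative
  pair-vs-non-peer association; non-peer statistics are therefore only
  meaningful pooled across several sessions, as done in
  `assembly_signature`.
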