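# Methods

This note documents the models, conventions and design choices behind the
package, in the spirit of a methods appendix: what each stage computes,
which knobs matter, what the synthetic generator does and does not
emulate, and where genuinely open choices were settled.

## Time conventions

All times are milliseconds. Each trial lives on a peristimulus clock with
cue onset at 0; the default layout places `trial_start` at −500 ms.
Windows and bins are half-open `[a, b)` everywhere, so a spike at an exact
boundary belongs to the later bin and nothing is counted twice. On disk,
times are absolute session milliseconds at 1 µs resolution (three
decimals), which makes the write→read round trip exact. Channels are
1-based; channel 60 is the ground, carries no spikes, and contributes the
constant 1 element of every feature vector.

## Burst segmentation

Single-stimulus trials: a burst is declared when the pooled spike count in
the first 590 ms of the trial strictly exceeds 20 ("more than 20" is read
as strict, so 20 spikes is not a burst and 21 is). The 590 ms window is
anchored at `trial_start`, i.e. it covers −500 to +90 ms peristimulus
under the default layout; the anchor is configurable because alternative
anchorings are defensible.

Sequential trials are classified with temporal precedence — cue, delay,
probe, then control — and every trial receives exactly one class:

1. **cue burst**: pooled count in the first 590 ms ≥ half the session
   mean spikes per trial ("whenever half the mean … occurred" is read as
   ≥). The session mean is taken over *all* trials, the only estimator
   available before classification.
2. **delay burst**: pooled count between cue offset and probe onset
   reaches the same threshold, *and* the gap from the last pre-probe
   spike to probe onset lies within 100–300 ms. The upper bound matters:
   it is what keeps quiet control trials (whose last spike is typically
   much earlier) from matching.
3. **probe burst**: ≥ 20 pooled spikes in a 300 ms window anchored
   100 ms before probe onset, i.e. `[probe−100, probe+200)`. The verbal
   description of this window in the source protocol is internally
   inconsistent (its endpoints span 200 ms but it is named a 300 ms
   window); the stated duration is honored and both endpoints are
   configuration fields.
4. otherwise **control**, unless any spike falls in the final 200 ms of
   the delay, in which case the trial is flagged
   `excluded_delay_activity`: it cannot serve as a hidden-memory control
   because spiking could have carried the information across the delay.

All thresholds and windows live in `SegmentationParams`.

## Features

Spike-count vectors are 60-dimensional per 100 ms bin: 59 electrode
counts plus the ground element fixed at 1 (the constant element also
protects downstream normalizations from all-zero vectors). Binary
activity vectors use 250 ms bins with a 550 ms first bin spanning −500 to
+50 ms, so subsequent bins fall at `[50, 300)`, `[300, 550)`, …,
separating the initial evoked response from the later bursting response.
A unit is active when its rate in the bin strictly exceeds its inter-trial
baseline mean + 3 SD. Baseline statistics are computed per unit from
non-overlapping 250 ms windows tiling the inter-trial segments (sample SD,
`ddof=1`); non-overlapping windows match the statistics of the analysis
bins and avoid the correlations a sliding window would introduce. With a
degenerate SD of 0 (silent or single-window baselines) the rule collapses
to "any rate above the mean counts", which is the sensible limit. Sessions
without inter-trial data raise an explicit error rather than guessing a
baseline.

## Decoding

One independent soft-margin linear SVM per time bin, fed raw spike-count
vectors (no scaling — classification is an inner product with the learned
boundary). Multiclass problems use one-vs-one voting with ties resolved
toward the lowest class label; the penalty C defaults to 1 and the
qualitative acceptance behavior is insensitive to ±10× around it on
synthetic data. Train/test follows repeated random subsampling: a
stratified 70/30 partition redrawn 50 times (stratification guarantees
every class in both partitions, which unstratified draws cannot at small
n), reporting per-bin mean accuracy ± SEM over repeats. Significance
comes from 200 label permutations, each with one fresh stratified split
and one train/test pass per bin; the per-bin 5th/95th percentiles form
the null band (the source protocol states 5th/95th in one place and
90th/10th in another; the former is the default and both are
configurable). Cross-condition tests apply every repeat's trained
machines, unchanged, to an independent trial set — this is how
"control-trained, burst-tested" generalization is measured. Stored
per-repeat predictions make every reported accuracy recountable, and the
test suite recounts them.

## Entropy and correlations

Pattern entropy per bin is the plug-in Shannon entropy of the tallies of
identical binary vectors, `H = log2 N − (1/N) Σ nᵢ log2 nᵢ`, always
finite because every observed class has `nᵢ ≥ 1`; `N = 1` gives `H = 0`.
It is reported alongside the equivalent number `2^H`, which is bounded by
the trial count — 46 all-distinct vectors give exactly 46. No
bias-corrected estimator is used; the plug-in form is the measure of
record here. "Normalized entropy", used when pooling across sessions of
unequal size, is defined as `H / log2 N` (a z-scored alternative is
config-exposed; the term is otherwise undefined in the source protocol).

Groups of unequal size are compared by subsampling the larger group
without replacement to the smaller size 300 times; the per-bin mean and
the 0.5th/99.5th percentiles of the resampled values form the band
(two-sided reading of "99th percentile extremes"; a one-sided option
exists). Cross-network comparisons z-score each variable within its
network (`ddof=1`) and pool all (network, bin) points into one Pearson r
with a two-sided t-test p-value; a variable with zero variance within a
network is flagged and that network excluded from the affected pairs.

## Clustering

Trial similarity in a bin is the Pearson correlation of 60-element binary
vectors. An all-ones vector (possible once the ground bit is included)
has zero variance; its correlation is defined as 1 against an identical
vector and 0 otherwise, and the trial is flagged. Clusters come from
average-linkage agglomerative clustering on `1 − r` cut at a distance
threshold (default 0.5) — the simplest method consistent with the
red-block diagonal structure such matrices show; linkage and threshold
are parameters because no stronger constraint exists. Output order is
deterministic: clusters by decreasing size (ties toward the lowest trial
id), trials within a cluster sorted by stimulus then id. Cluster
stimulus selectivity is the Shannon entropy of the cluster's label
distribution, through the same kernel as pattern entropy.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
not the biophysics. Units are inhomogeneous Poisson processes without
refractoriness — the simplest process carrying every statistic the
pipeline measures. Its defaults describe a plausible quiet dissociated
culture between bursts and are the conditions under which the acceptance
properties are demonstrated:

- 59 units, baseline 0.02 Hz per unit (sparse inter-burst firing; quiet
  enough that most sequential trials have silent delay tails).
- Stimuli: random-dot patterns, 18–22 dots on a 10×10 grid, pairwise
  distinct. 16 responsive units carry receptive fields of 4 grid cells;
  a unit's evoked rate is `gain × |field ∩ dots|` with gain 3.5 Hz per
  dot. These numbers put the pooled evoked response near 45 Hz — strong
  enough for reliable decoding, and safely below the 20-spike probe-rule
  threshold within its 300 ms window.
- Stimulus duration 150 ms; after offset the evoked rate decays
  exponentially with τ = 200 ms (reverberation, the "active memory"
  carrier: information decays over roughly a second).
- Sequential trials: 1050 ms cue-offset→probe-onset delay, fixed probe
  pattern. Hidden memory is a per (cue, unit) multiplicative factor on
  probe-evoked rates, drawn equiprobably from {0.15, 1.85}: each unit is
  either strongly depressed or facilitated depending on the preceding
  cue. The bimodal form encodes the cue as a *recruitment pattern* while
  leaving the mean probe rate unchanged, mirroring how paired-pulse
  adaptation redistributes rather than scales responses. There is no
  delay-period spiking from the memory itself.
- Bursts: a fixed core of 15 units fires at `excitability × 60 Hz` for
  300 ms; every other unit is recruited independently with probability
  `min(1, excitability × 0.3)`. One burst at most per trial, with
  per-phase probabilities defaulting to 1% each (bursts interrupt a few
  percent of trials; tests raise this). Past
  `excitability ≈ 3.3` recruitment saturates: every burst recruits every
  unit and the binary burst pattern becomes identical across trials —
  the descending branch of the excitability/entropy inverted U.
- Burst–information interaction: a burst at or before a stimulus
  replaces that stimulus's evoked recruitment profile with the
  stimulus-averaged profile (activity without identity), and any burst
  erases the cue-specific adaptation, so the probe response is drawn
  cue-independently. This is the "overwrite" mechanism the decoding
  analysis detects; a purely additive burst would leave early-burst
  trials' stimulus responses intact.
- Burst timing is uniform within its phase window, except delay bursts,
  which end 100–300 ms before probe onset — the characteristic pre-probe
  pause by which delay bursts are defined; the gap range is a
  configuration field.

What the generator does *not* emulate: refractoriness and spike-sorting
artifacts, electrode cross-talk, burst propagation structure and
within-burst rate profiles (flat rate, fixed duration — neither is
quantified in the source protocol), slow nonstationarities across a
session, and any mechanistic synaptic model of adaptation. Passing tests
therefore certify the *analysis chain* — that the rules, decoders and
entropy statistics recover what was injected under the assumed
statistics — not that real cultures satisfy those statistics.

## Problem sizes and numerics

Test and acceptance runs use sessions of 40–240 trials (e.g. 4×40 for
null calibration, 2×120 for the burst-destruction pattern, 6 excitability
levels × 80 trials for the saturation sweep), sizes chosen so shuffle
bands are stable and the whole suite completes in minutes on one CPU.
The 46-vector entropy ceiling and the 0.9-bit → 1.87-stimuli transform
are exact. Stage seeds are derived deterministically from one master
seed; identical configurations give byte-identical reports. Tolerances:
null-mean calibration ±2 percentage points around 1/K; Poisson-rate
recoveries within 3 standard errors; entropy identities to 1e−12.

## Known limitations

- The segmentation thresholds are the protocol's fixed rules, not
  adaptive burst detectors; sessions with very different firing regimes
  need re-tuned `SegmentationParams`.
- The half-mean cue/delay rules depend on the session composition (the
  mean includes burst trials), so burst prevalence shifts the effective
  threshold; this mirrors the original rules.
- Plug-in entropy is biased low at small trial counts; comparisons are
  therefore always made at equalized N.
- With very small burst groups, cross-condition accuracies are coarse
  (multiples of 1/n); conclusions should rest on whether accuracy
  exceeds the null band, not on its exact value.
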