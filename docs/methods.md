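# Methods

## The assay and its statistical model

`barsense` analyses a multiplexed transcriptional-reporter ("pathway
sensor") assay. Each sensor is a synthetic transcription-factor-binding-site
cluster or a human promoter driving a transcribed RNA barcode; sequencing
read counts of the barcode proxy the activity of the signaling pathway
feeding that sensor. The default panel has 22 pathway sensors, each on two
barcoded constructs, plus a minimal-promoter control reporter (MLPmin) on
four constructs — 48 barcodes in all. The control carries no response
element, so its counts reflect only sequencing depth and cell number and
anchor the normalization.

### Counts

The count of sensor *i* in well *j* is modeled as negative binomial,

    K_ij ~ NB(mean = s_j · μ_ij,  var = μ + α_i μ²)

with per-well size factor `s_j`, per-sensor dispersion `α_i`, and condition
effects entering as log2 fold changes on `μ`. This NB-with-size-factors
formulation is the standard one for count-based differential expression;
the package implements the fit itself rather than delegating it, because
the two-group structure admits a fast closed-form Fisher-scoring solution
(below).

### Size factors

`s_j` = geometric mean of the well's four control-tag counts (a +0.5
pseudocount applied to zero counts only), divided by the grand geometric
mean across wells, so `geomean_j(s_j) = 1`. Geometric means are robust to a
single tag dropping out; a well whose control tags are all zero is an
error, not a guess. Note an intrinsic accuracy limit: with four control
tags of dispersion α, the per-well relative RMS error of `s_j` has the
depth-independent floor `sqrt(α/4)`. Size-factor accuracy statements at a
given depth therefore refer to the counting-noise-limited regime (small
technical α); biological overdispersion of the control cannot be averaged
away by sequencing deeper.

### Dispersion

Per sensor, a method-of-moments estimate on normalized counts `y = k/s`:
pooled within-stratum variance (Bessel-corrected sums over replicate groups
defined by genotype × treatment × dose × timepoint) and pooled mean give

    α_i = max(floor, (var − mean) / mean²),   floor = 1e-8.

No empirical-Bayes shrinkage or mean-dispersion trend is applied: with a
~23-sensor panel such priors are poorly identified, and the trend machinery
of full RNA-seq pipelines is deliberately out of scope. Two consequences
are documented rather than hidden:

* Under Poisson truth the estimator is centered at zero, so roughly half
  the estimates land at the floor and half slightly above it — "no
  overdispersion" manifests as *negligible* estimates, not as all-floored.
* The plug-in estimate makes the Wald statistic slightly heavy-tailed
  (t-like with the pooled residual df). At the default simulation settings
  the p ≤ 0.05 mass stays calibrated (~0.05), but far-tail p values are
  inflated ~2×, so the probability of at least one Benjamini-Hochberg
  rejection per all-null panel is ~0.09 rather than 0.05. Dispersion should
  be estimated from as many strata as the experiment offers; the package's
  calibration checks estimate it from a 12-stratum design (~36 residual
  df), mirroring how a full assay run is analysed.

### Wald test

For a contrast (numerator vs. denominator well sets) the model has group
means `s_j·q` and `s_j·q·2^L`. The two group parameters decouple, so each
is a one-dimensional MLE solved by Newton iteration on ln q with the score

    Σ_j [ k_j − μ_j (k_j + r)/(μ_j + r) ],   r = 1/α,

and `SE(L)` comes from the observed Fisher information of the two-parameter
model on the log2 scale: with observed weights
`w_j = μ_j r (k_j + r)/(μ_j + r)²`, `Var(L) = A/(ln2² · B · C)` where `B`,
`C` are the numerator/denominator weight sums and `A = B + C`. `z = L/SE`
is referred to a standard normal, two-sided. A +0.5 pseudocount is added to
a sensor's counts (both groups) only when one group is entirely zero; it is
never silently applied elsewhere. Non-convergence yields an NA row, never a
crash.

One property worth stating precisely: rescaling one well's counts together
with its size factor changes the fit only through the NB weights
`μ/(1+αμ)`. In the Poisson limit the MLE is the depth-weighted ratio
estimator `Σk/Σs` and legitimately moves with a well's depth; as `αμ` grows
the weights saturate at `1/α` and the estimate becomes exactly
scaling-invariant. At the assay's operating point (`αμ` ≈ 25) the residual
sensitivity is ~10⁻³ in log2 units.

### Multiplicity and gating

Benjamini-Hochberg runs within a user-defined family — by default all
sensor × contrast cells of one run, the scope of one results heatmap
(delegated to `statsmodels.stats.multitest`). Significance stars
(`*` … `****` at adjusted p ≤ 0.05 / 0.01 / 0.001 / 0.0001) are displayed
only where |log2FC| strictly exceeds the fold-change gate, default 1.5.
BH itself covers all cells by default; restricting it to gated cells is
available behind a flag (`bh_on_gated_only`) since the family boundary of
the original analysis is not stated.

### Low-baseline filtering

Sensors whose mean normalized count over vehicle wells falls below
`min_baseline_mean` (default 10; the original threshold is unpublished) are
dropped before testing; the control is never dropped. The default synthetic
baselines give one immune-response sensor (IL6p) a vehicle mean of ~2
precisely so this filter is exercised.

## Read simulation and quantification

Reads are rigid amplicons `sample_index + flank_5p + tag + flank_3p` (the
true read architecture of the assay is not published; the layout is
declared in the panel header so simulation and quantification always
agree). Errors are i.i.d. per-base substitutions. Quantification is
dictionary lookup, not alignment: demultiplexing on the sample index
(Hamming ≤ 1; indices kept at pairwise distance ≥ 3), anchor located at its
expected offset with ≤ 1 mismatch, tag matched against the whitelist at
Hamming ≤ 1. Because tags sit at pairwise distance ≥ 3, a single
substitution always has a unique nearest tag; distance-1 matches are
tallied as "corrected". Ambiguous and unassigned reads are reported per
category and never redistributed. At error rate 0 the whole loop is
exactly lossless, a property the suite asserts over 20 seeded matrices.

## Synthetic-data generator: what it emulates and what it does not

* **Counts**: NB tag counts with log-normal size factors (sd 0.3 on the log
  scale — enough depth variation to make normalization matter), equal tag
  weights within a sensor, and Hill-type dose responses
  `LFC = γ^[cKO] · Lmax · d^h/(EC50^h + d^h)`, zeroed for vehicle and (for
  all stimuli except forskolin) at the 24 h timepoint. Knockout attenuation
  γ multiplies Lmax. Default magnitudes (Lmax 3, EC50 1, γ 0.4) are
  illustrative: the published per-sensor amplitudes exist only as heatmap
  colors, so no numerical calibration to them is attempted.
* **Not emulated**: PCR amplification bias, UMI structure, quality-score
  variation, optical duplicates. Passing tests therefore demonstrate
  correctness of the analysis on data satisfying the stated model, not
  robustness to those artifacts.
* Because each sensor's two tags are drawn independently and then summed,
  the sensor-level effective dispersion is α/2 of the tag-level value —
  the variance-halving of technical replicates. Recovery statements say
  which level they refer to.
* **Behavior**: the open-field agent is a reflected correlated random walk
  whose heading blends persistence with a pull toward the nearest wall
  (`wall_attraction` ∈ [0,1]); it reproduces thigmotaxis-like occupancy
  statistics, not mouse locomotion. IntelliCage visits are Bernoulli with
  success probability rising from chance p0 toward a ceiling as
  `p(k) = ceiling − (ceiling − p0)·exp(−rate·k)`. Y-maze sequences are the
  two-state Markov rule "novel arm with probability a, else return".
  Calcium traces are baseline + shared slow drift + exponential transient +
  Gaussian noise; the five background ROIs carry the same drift, so
  subtractive background correction removes it exactly in the noise-free
  case.

## Phenotype metrics: conventions and tie-breaks

* **Zones**: three concentric 5 cm wall strips (strip 1 = periphery), a
  20 × 20 cm center and four 10 × 10 cm corners in a 50 × 50 cm arena,
  scored from the body center. Boundary ties resolve to the more peripheral
  zone (closed outer boundaries), matching the thigmotaxis emphasis; the
  center square is open, corner squares closed. Time in a zone is the sum
  of frame intervals of frames in the zone (the final frame owns one median
  interval); each path segment's distance belongs to the zone of its
  starting frame; an entry is an outside→inside transition, with initial
  presence counting as the first entry. All of this is pinned by an
  independent per-frame point-in-rectangle oracle in the tests.
* **Preference score**: exactly
  `(choicesA·pA − choicesB·pB)/(choicesA·pA + choicesB·pB)`, the chance
  weights being 0.5/0.5 for two bottles and day/night duration fractions
  for nocturnality. Undefined (error) when both counts are zero.
* **Spontaneous alternation**: percent of sliding visit triads whose three
  arms are all distinct, out of visits − 2, computed after entry/exit
  hysteresis (enter at ≥ 85 % body area, exit below 75 %).
* **SPRT learning time**: cumulative Bernoulli log-likelihood ratio of
  H1: p = p0 + 0.10 against H0: p = p0 (chance; 0.25 for one of four
  corners), declared "learned" at the first crossing of
  `ln((1−β)/α)` with α = 0.05 and β = 0.05 (β is unstated in the original
  description; the symmetric default is used). Both the crossing visit
  index and its wall-clock timestamp are reported; crossing the lower
  boundary or exhausting the log is a censored outcome with its reason.
  For an all-correct stream the crossing index is
  `ceil(ln((1−β)/α) / ln(p1/p0))` = 9 under the defaults.
* **ΔF**: subtractive background correction (`F_corr = F_cell − mean of
  the five background ROIs`), then `ΔF = F_corr − F_baseline` with the
  baseline the pre-stimulus mean of `F_corr`. Subtractive rather than
  divisive correction matches the printed difference formula.

## Problem sizes used by the checks

The calibration and recovery checks are sized to run on a single CPU in a
few minutes: 1,000 all-null panels (48-well design) for type-I error;
500 seeds × 22 sensors (16-well design, n = 4+4 contrast) for log2FC
recovery at baseline 500 / tag dispersion 0.05; 20 seeded matrices for the
lossless round trip; 100 + 100 agents (120 s at 10 Hz) for the thigmotaxis
direction check; 100 random trajectories against the zone oracle. The
dose-response monotonicity demonstration runs at tag dispersion 0.01
because near-saturating doses of a Hill curve differ by less than replicate
noise at dispersion 0.05, making strict monotonicity of noisy means the
wrong check at that noise level.

## Known limitations

* No empirical-Bayes dispersion shrinkage: far-tail p values are modestly
  anti-conservative at small replicate numbers (quantified above).
* The exact read architecture, barcode sequences and full sensor roster of
  the original assay are not public; placeholder sensors and synthetic
  barcodes stand in, clearly labeled.
* The Wald contrast machinery tests two-group comparisons; dose-trend
  models and interaction tests are out of scope (the contrast file makes
  the comparison explicit instead).
* Behavioral statistics (ANOVA and the like) are out of scope; the package
  emits tidy per-animal/per-cell tables for downstream tools.
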