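# Methods

## Generative model

Each simulated pollen mother cell carries 12 bivalents whose relative SC
lengths are proportional to the assembled rice chromosome sizes,
normalised to mean 1 (chromosome 9 is the shortest, ~0.74). Two
independent point processes place crossover sites on each bivalent, in
units of its own SC length:

* **Class I (interference-sensitive).** A renewal process whose
  inter-event gaps are Gamma(shape ν, scale 1/(νμ)), so the mean gap is
  1/μ and μ is the event intensity per unit SC length. By default the
  process is *stationary*: the first event is drawn from the equilibrium
  residual-life distribution, sampled exactly as U·X* with U uniform and
  X* a size-biased gap (the size-biased version of Gamma(ν, θ) is
  Gamma(ν+1, θ)). Stationarity makes interior gaps exactly gamma and the
  expected count exactly μ × length, both of which the tests verify. An
  "ordinary" (non-stationary) start is available via
  `SimConfig(stationary=False)`.
* **Class II (interference-insensitive).** A homogeneous Poisson process
  with rate per unit SC length.

A bivalent's metaphase I shape is a deterministic function of its total
event count: 0 → univalent pair, 1 → rod, ≥ 2 → ring. No obligate-chiasma
constraint is imposed; bivalents with no events become univalent pairs,
which is exactly the mutant phenotype the shape scoring needs to express.
The bright-focus channel records the class I positions, because prominent
pro-crossover foci mark interference-sensitive CO sites.

### Genotype presets and calibration

| genotype  | ν    | class I μ | class II rate | rationale |
|-----------|------|-----------|---------------|-----------|
| WT        | 8.39 | 24.3/12   | 4.0/12        | 24.3 bright foci/cell; 28.3 total COs/cell |
| hei10     | —    | 0         | 6.5/12        | class I knockout; residual chiasma mean 6.5 |
| mer3      | —    | 0         | 5.8/12        | ~28% of the WT chiasma frequency retained |
| mer3hei10 | —    | 0         | 2.1/12        | double-mutant chiasma mean 2.1 |
| zep1      | 8.39 | 36.2/12   | 4.0/12        | bright foci elevated ~1.5-fold |
| pair3     | —    | 0         | 0             | asynaptic: no bivalents, no chiasmata |

These defaults are fixed once from the observed per-cell means; they are
config values, not constants baked into the analyses. Rates are per unit
SC length, so with mean relative length 1 a cell total is 12× the rate.

Shape scoring caps each bivalent at two chiasmata, so the scored WT mean
under the focus-matched preset is ~22.0/cell rather than the observed
~20.7 — real cytological scoring loses more than the cap (e.g. two
chiasmata in the same arm can look rod-shaped), and the generator keeps
raw event counts in the output so this underestimate is itself
measurable. For analyses of the *scored-count distribution* a separately
documented class I density `WT_CHIASMA_CALIBRATED_MU = 1.76` reproduces a
scored mean of ~20.7 with SD ~1.4. The residual class II rates are raw
event rates; capping trims the hei10 scored mean slightly (to ~6.26).

### Dual-channel staining

Both channels derive from the same site set. Each site is detected per
channel unless dropped (independent Bernoulli; defaults 0.025 and 0.069),
detected positions receive Gaussian jitter (SD 0.002 of SC length,
truncated to [0, 1]), and Poisson-distributed spurious foci can be added
(default rate 0). With threshold matching at tolerance 0.01, the default
asymmetric dropouts reproduce directional colocalization fractions of
~93.1% and ~97.5%: the fraction of A foci with a B partner is governed by
B's dropout rate, and vice versa.

## Statistical procedures

**Poisson goodness of fit.** λ̂ is the sample mean; expected frequencies
are Poisson(λ̂) over integer categories 0..max with an open upper tail;
adjacent categories are pooled inward from both ends until each expected
frequency reaches `min_expected` (default 1, configurable); χ² is
Pearson's statistic and df = categories − 2 (total and estimated rate).
The default pooling threshold of 1 keeps many categories at cytological
sample sizes (n ≈ 130); simulation shows the null rejection rate is
0.048–0.054 at α = 0.05 for n from 130 to 10,000, so the statistic is
well calibrated despite the low threshold. Published χ² values for these
data cannot be reproduced exactly because the underlying per-cell count
tables (and hence the exact binning) are not available; the tests instead
verify calibration under the null and power against interference-driven
underdispersion.

**Two-sample comparison.** The pooled-variance t-test (df = n₁ + n₂ − 2)
is the default because it matches the reported degrees of freedom; Welch's
test is deliberately not the default. From the published rounded summaries
(6.5 ± 2.1, n = 130 vs 2.1 ± 1.3, n = 121) the pooled t is 19.786; the
published 19.9 evidently came from unrounded raw data, and the package's
value agrees with it to ~0.6%.

**Gamma fitting.** The default estimator is maximum likelihood on raw
distances with location fixed at 0 (`scipy.stats.gamma.fit(floc=0)`); the
shape SE is the Fisher-information form
√(ν̂ / (n(ν̂ψ′(ν̂) − 1))), and a seeded nonparametric bootstrap SE is
available. The binned least-squares fit (equal-width bins over the
observed range, gamma probability mass integrated per bin, Nelder–Mead
with multistart from the method-of-moments estimate) exists for fidelity
to the histogram-fitting tradition; it is less efficient and carries no SE.
Degenerate inputs (constant distances) return an infinite shape with a
warning rather than crashing.

**Distance extraction.** Consecutive gaps are taken per chromosome after
sorting, divided by SC length and scaled to percent; chromosomes with
fewer than two foci contribute nothing, and end segments are excluded
rather than treated as censored — under the stationary generator interior
gaps are exactly gamma, so exclusion is unbiased *per gap*.

## Known limitations

* **Window bias on short chromosomes.** A gap is observable only if both
  of its foci fall inside the chromosome, so when the mean gap is
  comparable to the SC length (e.g. ~2 foci per chromosome) the observable
  gaps are length-biased toward small values and the fitted shape is
  biased (the demo pipeline's fit on the shortest chromosome, n ≈ 70 gaps,
  scatters well above/below the generating 8.39). Validation of the
  extraction convention therefore uses long simulated SCs; pooled
  small-window estimates should be read with this caveat, which applies
  equally to real cytological data.
* The simulator assumes spatial Poisson placement for class II events; the
  mutant observations constrain only the per-cell counts, not the spatial
  law.
* No 3D geometry, image synthesis, SC dynamics or stage-resolved focus
  turnover: stage differences are representable only as parameter choices.
* Colocalization uses threshold matching, not one-to-one assignment; the
  tolerance (default 0.01 of SC length) is the most consequential free
  parameter and is printed in every report. The real scoring criterion
  behind the published fractions is unknown, so the dual-channel noise
  parameters are calibrations, not measurements.
* Synthetic data do not emulate antibody background structure, optical
  resolution limits, or segmentation errors beyond Gaussian jitter and
  uniform extras — passing tests show the statistics behave correctly
  under the stated model, not that the model captures every feature of
  slides.

## Problem sizes

Default test and acceptance runs use 5,000 gaps for fitting experiments,
130–250 cells per genotype (the cytological sample sizes), and 500
replicates for rejection-rate calibration; these sizes give Monte Carlo
errors comfortably below the tolerances asserted.
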