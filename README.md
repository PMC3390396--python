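# meiocross

Simulation and statistics of meiotic crossover interference for cytological
data, modelled on rice pollen mother cells (PMCs).

During meiosis, crossovers (COs) between homologous chromosomes appear
cytologically as chiasmata and are marked earlier by immunofluorescent foci
of pro-crossover proteins on the synaptonemal complex (SC). `meiocross` is a
library for people who analyse such data — or who need realistic synthetic
versions of it: it simulates per-cell crossover placement, scores chiasmata
from metaphase I bivalent shapes, tests count distributions, estimates
interference strength, and quantifies focus colocalization.

## The models

**Chiasma scoring.** A rod-shaped bivalent is scored as one chiasma, a
ring-shaped bivalent as two, a pair of univalents as zero; the per-cell
count is the sum over the 12 rice bivalents. Per-genotype counts are
summarised as mean ± SD and tested against a Poisson distribution with a
Pearson χ² goodness-of-fit test (rate estimated by the sample mean, tail
categories pooled, df = categories − 2). Genotypes are compared with the
classical pooled-variance two-sample t-test from summary statistics.

**Interference (gamma model).** Distances *d* between adjacent crossover
foci along an SC are modelled as *d* ~ Gamma(ν, θ). The shape ν is the
interference parameter: ν = 1 corresponds to a Poisson process (no
interference); larger ν means more even spacing, with CV(d) = 1/√ν. ν is
estimated by maximum likelihood (with a Fisher-information SE), by the
method of moments (mean/sd)², and by least squares on binned relative
frequencies.

**Simulation.** Class I (interference-sensitive) CO sites follow a
stationary gamma renewal process with shape ν and intensity μ per unit SC
length; class II (interference-insensitive) sites follow a homogeneous
Poisson process. Genotype presets encode pathway knockouts: ZMM mutants
(`hei10`, `mer3`, `mer3hei10`) lose class I entirely and keep a calibrated
residual class II rate. Dual-channel immunostaining is emulated with
per-channel dropout, positional jitter and spurious extra foci.

## Worked example

```sh
$ python examples/02_chiasma_statistics.py
    WT: mean 20.84, chi2[14] =  329.3, p = 8.75e-62  -> deviates from Poisson
 hei10: mean  6.06, chi2[11] =   10.9, p = 0.451  -> consistent with Poisson

hei10 vs mer3hei10 (published summaries): t[249] = 19.8, p = 5.3e-53
chiasma retention in hei10: 31.4% of wild type
class I share of all crossovers: 85.9%
```

Wild-type chiasma counts are strongly underdispersed relative to Poisson —
the signature of interference — while the residual chiasmata of the
pathway mutant fit a Poisson, meaning they are distributed at random among
cells. The t-test shows the double mutant retains significantly fewer
chiasmata than the single mutant; ~31% of wild-type chiasmata survive in
`hei10`, and ~86% of all COs come from the interference-sensitive pathway.

The other examples cover genotype simulation (`01`), interference fitting
(`03` — ML, moments and binned fits all recover a generating ν of 8.39),
and colocalization (`04` — asymmetric dropout yields ~93%/~97.5%
directional fractions). The full pipeline runs from a flat config file:

```sh
meiocross all examples/demo.cfg --out-dir demo_run
```

which simulates three genotypes, writes the cells/foci tables and a
consolidated report (chiasma summaries, goodness-of-fit, pairwise t-tests,
interference fits, colocalization), deterministically for a given seed.

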