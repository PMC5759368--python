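# Methods

`dsense` is a simulation-and-inference package for asking a practical
question about the ABBA-BABA framework: *given a four-taxon phylogeny with
known divergence times, population size and gene-flow time, how much gene
flow does the D-statistic need before it reliably fires, and how well do the
f̂ estimators recover the gene-flow fraction?*  Everything below is computed
by the package itself; no empirical claim here goes beyond what the test
suite and `scripts/acceptance.py` actually measure.

## Model

### Species tree and units

The fixed species tree has tips H1, H2, H3, H4 (outgroup) with splits at
`T2` (H1–H2), `T3` ((H1,H2)–H3) and `T4` (ingroup–outgroup), plus two
*introgressed lineages*: H3f branches from the H3 population at the
gene-flow time `Tgf` and stands in for H2's sequence at loci that received
H3→H2 gene flow; H2f symmetrically for H2→H3 flow.  Two samples H3a, H3b
are taken from H3 (needed by f̂G).  Setting the quartet per locus —
(H1,H2,H3a,H4), (H1,H3f,H3a,H4) or (H1,H2,H2f,H4) — turns one simulated
gene tree into the no-flow or either introgressed reading of that locus, so
a single simulation serves every analysis.

All times and the population size are stored pre-multiplied by the
substitution rate μ (`k = T·μ`), so branch lengths are expected
substitutions per site and every result is μ-free.  A scenario is
summarised by dimensionless ratios: the **relative population size**
`Ne/T3`, `Tgf/T2`, `T2/T3`, `T4/T3`.

### Coalescent

Gene trees follow a structured Kingman coalescent constrained by the
species tree: within any population holding `k` lineages, coalescence at
rate `k(k−1)/2 · 1/Ne` per generation, with constant `Ne` on every branch
and no bound above `T4`.  Two conventions matter:

- **`Ne` counts gene copies** (haploid convention, pair rate `1/Ne`): one
  coalescent time unit is `Ne` generations, i.e. the reciprocal of the
  relative population size.  This choice is forced by the package's own
  measurements: the simulated f̂hom slope matches
  `(1−Tgf/T3)/(1+Ne/T3)` only under this convention (see below).  The
  background closed form `E(D)` is quoted from the literature in its
  original diploid-`N` parameterisation and takes explicit arguments, so
  the two conventions never mix silently.
- Exponential waiting times replace discrete Wright–Fisher generations; at
  every grid value `(1−1/2N)^t` and `e^(−t/2N)` differ by `< 1e−3`
  (asserted in tests), so the approximation is immaterial.

Between the present and `Tgf` an introgressed lineage sits alone in its own
population of size `Ne`; with one sample per lineage nothing can coalesce
there, and in diploid mode (two samples) the two introgressed copies may
coalesce within it; under the 100%-replacement model the effect of this
choice on pattern counts is second-order.

Validation: triplet discordance frequencies match `(2/3)e^(−t)` with
`t = (T3−T2)/Ne` at `t ∈ {0.5, 1, 2}` (binomial 99% band, 10,000 trees),
an independent discrete-generation Wright–Fisher sampler agrees, and
pairwise MRCA times match their closed-form means.

### Sequences

Each locus evolves under HKY85 with κ = 3.6 (rate-matrix
transition/transversion parameter, the usual simulator input convention),
GC = 40% split symmetrically (πA = πT = 0.30, πC = πG = 0.20), and
continuous Gamma(α = 1, mean 1) site rates drawn once per site and shared
across branches.  The rate matrix is normalised to one expected
substitution per site per unit branch length.

Two exact, distribution-identical simulators are provided and cross-checked
against each other and against the analytic HKY+Γ expected p-distance
(Gauss–Laguerre integration of the matrix exponential over the rate
density):

- `uniformization` (default): substitution events per branch are Poisson
  with rate `Λ·b·r_site` (`Λ` the maximal leave rate), thinned onto sites
  by rate, each event applying one jump of `I + Q/Λ`.  Cost scales with the
  number of events, which is tiny in this study's regime (branch lengths
  ≪ 1), giving ~1 ms per 7-taxon, 1-kb locus.
- `spectral`: per-site sampling from `P(d) = Σ_k A_k e^{λ_k d}`.

No indels, no selection, no recombination within loci; loci are unlinked.

## Statistics

`D = (nABBA − nBABA)/(nABBA + nBABA)` with site patterns counted on exactly
biallelic sites (the pattern definitions imply exactly two alleles;
three- and four-allele sites count toward neither).
Sites containing any non-ACGT symbol are skipped.  In diploid mode a site
heterozygous in any of the four analysed taxa is excluded before the
haploid rule is applied.  `S` denotes the numerator summed over loci;
`f̂G = S(H1,H2,H3a,H4)/S(H1,H3a,H3b,H4)` and
`f̂hom = S(H1,H2,H3,H4)/S(H1,H3,H3,H4)` (denominator an ABBA count, never
negative; the f̂G denominator is a difference and can be ≤ 0).

### Weighted block jackknife

Standard errors come from a delete-one-block jackknife over consecutive
locus blocks, block weight = the statistic's denominator in that block,
using the delete-m estimator of Busing, Meijer & van der Leeden (1999,
*Statistics and Computing* 9:3–8):

    θ̃ = G·θ̂ − Σ_j (1 − m_j/n)·θ̂₍ⱼ₎
    var = (1/G) Σ_j (h_j θ̂ − (h_j−1) θ̂₍ⱼ₎ − θ̃)² / (h_j − 1),  h_j = n/m_j

The estimator is isolated in one function
(`stats.weighted_block_jackknife`) so an alternative weighting can be
swapped in easily.  Negative f̂G
block weights can drive the variance negative; such results are flagged
`valid = False` (CI treated as missing) rather than clamped.  Zero-weight
blocks are dropped; a trailing partial block is kept with its smaller
weight.  `Z = θ̂/SE`; sensitivity scans use one-sided `Z > 3` (the
simulated direction predicts ABBA excess), null audits two-sided
`|Z| > 3`/`|Z| > 1.96`.

Default block size is 250 loci (5 Mb at the full-scale 20-kb loci).
Reduced-scale runs here use 50-locus blocks so that a 2,000-locus dataset
still has ~40 blocks: with only 8 blocks the Z statistic is visibly
t-distributed and its |Z| > 1.96 tail is inflated well above the nominal
rate, which would confound the specificity calibration.  Since loci are
unlinked, block span carries no linkage meaning in simulation.

## Power analysis (MF80)

An *introgression test* at fraction `f` draws `round(f·n_loci)` loci
(banker's rounding) without replacement to carry the introgressed reading,
computes D (and f̂s) on the mixture and applies the jackknife.  MF80 — the
minimal `f` detected with ≥ 80% probability — is found in two stages:

1. **Coarse scan** over the basic f list (0, 0.001…0.009, 0.01, 0.015,
   0.02, 0.03…0.09, 0.1, 0.15, 0.2, 0.3, 0.4, 0.5), three tests per f;
   `f0` = smallest f with 3/3 significant, bracket `[f_min, f_max]` = two
   list places before to one after (clamped: f0 ≤ 0.002 → f_min = 0.001;
   f0 = 0.5 → f_max = 0.5).
2. **Fine scan** at 0.001 steps inside the bracket, many tests per point
   (500 at full scale; 100 in the reduced test runs), followed by a
   binomial logistic GLM of significance on f; MF80 = `(ln 4 − β0)/β1`.

Conventions: no qualifying `f0`, a fitted curve still below 80% at
`f = 0.5`, or an all-negative scan ⇒ MF80 := 0.501 ("unusable", kept
numeric so correlations can use it); an all-positive (saturated) scan
reports the scan floor; perfect separation falls back to the empirical 80%
crossing.  The fit accepts aggregated binomial counts (identical likelihood
to per-replicate Bernoulli).  Coarse and fine scans reuse the same
simulated locus pool with fresh mixture draws, so repeated tests probe
mixing noise on a fixed dataset.

## Robustness analysis

f̂ linearity: OLS of the statistic on true f over the basic f list; the
slope estimates f̂/f.  Package-measured slopes at desk scale (10,000 × 1 kb,
`Tgf = 0.25·T3`, `Ne = T3`) reproduce the closed-form predictors: f̂G
0.767 vs 0.75 predicted, f̂hom 0.376 vs 0.375, with r > 0.99.

Bootstrap: replicates draw `n_draw` loci without replacement from the
pooled replicate datasets (without replacement), assign `f·n_draw` to gene flow, and attach CI = value ±
2 × jackknife SD.  Pairwise comparison of replicate sets records the
proportions numerically ordered, significantly ordered (non-overlapping
CIs) and — on the diagonal — not significantly different.  Replicates with
missing CIs (negative f̂G variance) are excluded from the significance
denominators; this choice (exclusion rather than counting them as
non-significant) is isolated in `pairwise_compare`.  f̂G under H2→H3 flow raises `UnsupportedCombination`.

## Reduced problem sizes

Full scale is 50,000 × 20 kb = 1 Gb per dataset across the 789 datasets of
the four scheme grids — cluster territory.  The package's own test and acceptance runs use, as their study
conditions: 2,000 × 1 kb datasets (specificity calibration, 100–200
independent nulls), 10,000 × 1 kb (slopes, bootstrap diagonal), 3,000 ×
1 kb per grid point (relative-population-size trend), 100–500 fine-scan
replicates, and 50-locus blocks throughout.  Noise in pooled statistics
grows as the square root of the total-bp ratio, so thresholds stated at
1 Gb are relaxed by that factor where applicable (e.g. |f̂hom| at f = 0:
0.01 at 1 Gb → 0.1 at 10 Mb).

## What the generator does and does not emulate

The simulator *is* the study's data-generating process (coalescent gene
trees + substitution-only sequences), so passing tests validate the
statistics under exactly those assumptions.  Real data add alignment and
mapping error, indels, selection, recombination within loci, varying
population sizes and mutation-rate variation among lineages — none of which
are modelled, so the measured sensitivities are best-case.  The diploid
mode brackets reality between its "same loci" and "random loci" extremes
rather than modelling segregating introgressed alleles.

## Known limitations

- MF80 at reduced scale is systematically larger than at 1 Gb (less data);
  orderings and correlations, not absolute MF80 values, are the
  transferable results.
- The jackknife weighting is a reconstruction (see above); alternative
  weightings change SEs by small amounts.
- `expected_d` uses the literature's diploid-`N` convention while the
  simulator's `Ne` counts gene copies; convert (`N = Ne/2`) when comparing
  the two directly.
- With very sparse data (short loci at low divergence) statistics degrade
  to explicit undefined/invalid results rather than numbers; scans treat
  them as non-significant.
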