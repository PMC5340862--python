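# Methods

`consortium-coupling` reimplements, as a tested pipeline, the
species-resolved steady-state analysis of a binary consortium in which
a thermophilic unicellular cyanobacterium (the primary producer)
supports an obligate aerobic heterotroph through excreted carbon and
nitrogen. The experimental platform is a turbidostat held at 52 °C
across five steady states arranged on two treatment axes that share
one corner condition (highest irradiance at the lowest oxygen
tension):

* an **irradiance axis** — 197, 1,190 and 1,995 µmol photons m⁻² s⁻¹
  at pO₂ = 0 atm;
* a **pO₂ axis** — 0, 0.30 and 0.59 atm O₂ in the inlet gas at
  1,995 µmol photons m⁻² s⁻¹.

Transcriptomes are sampled in biological duplicate, except the shared
corner condition of the binary culture (quadruplicate).

## Expression normalization and filtering

Raw gene counts are depth-normalized with **median-of-ratios size
factors**: for every gene with nonzero counts in all samples, the
ratio of its count to its across-sample geometric mean is formed, and
a sample's factor is the median of these ratios. Factors of this kind
are defined only up to a common constant; the invariant that matters —
and the one the tests assert — is that per-million-scaled expression
is invariant to multiplying any sample's counts by a constant. If no
gene is positive in every sample the computation refuses rather than
falling back to a pseudo-reference, because such a matrix signals a
corrupt input.

Normalized counts are divided by gene length in kilobases. Two
variants are exposed because "RPKM after size-factor normalization" is
ambiguous about per-million scaling, and downstream thresholds are
scale-dependent:

* `scaled` (default): per-kb values × 10⁶ / (sum of size-factor
  normalized counts in the sample) — the familiar RPKM scale. The
  per-million denominator uses the joint two-species library by
  default (mirroring alignment against a concatenated reference); a
  per-species option is available because the ~90/10 community
  composition shifts per-million scaling materially.
* `per-kb`: normalized counts per kilobase with no further scaling.

Three gene-level filters are applied:

1. **Zero-count rule** — remove any gene whose replicate-mean raw
   count is zero in at least one condition.
2. **Low-expression rule** — remove any gene whose mean expression
   over *all* samples is strictly below 15 (one number per gene; a
   per-condition reading would duplicate the zero-count rule's role).
   The rule runs on normalized expression, after size factors.
3. **Variance mask** (before clustering only) — drop the
   ⌊0.30 · n⌋ genes with the smallest profile variance ("flat
   profiles"), computed on reference-scaled profiles so the mask
   responds to shape rather than magnitude. Ties break by gene id, so
   the mask is deterministic.

Profile transforms: **reference scaling** divides each per-condition
mean profile by its lowest-treatment value (the display transform for
relative-abundance figures), and **log-mean centering** maps a profile
to log₂(value / profile mean) (the transform used to display cluster
patterns). Both reject nonpositive inputs rather than imputing.

## Responsive genes and differential expression

A gene is **responsive** on an axis when its replicate-mean expression
changes at least two-fold between the lowest- and highest-treatment
conditions; interior conditions are ignored. A pseudocount of ε = 0.5
expression units is added to numerator and denominator so marginal
genes cannot divide by zero; the threshold is inclusive and symmetric
(max(fold, 1/fold) ≥ 2), with the direction given by which extreme is
larger.

Pairwise **differential expression** keeps the published decision rule
— |log₂ fold change| > 1 with Benjamini–Hochberg adjusted p < 0.05 —
on top of a moderated t-statistic computed on log₂(value + ε)
replicates: each gene's pooled residual variance is shrunk toward the
median genewise variance with 10 prior degrees of freedom, and p
derives from a t distribution with prior + residual df. With
duplicate-level designs, raw genewise variances carry so few degrees
of freedom that an unmoderated test has essentially no power at
genome-wide FDR control; variance moderation is the standard
empirical-Bayes remedy for exactly this regime and is the package's
stand-in for the reference count-model machinery, which is out of
scope. The contract (fold + adjusted-p rule) is unchanged.

## Correlation K-means with eigen-gene centroids

Binary-culture profiles of both species are co-clustered per axis with
K-means in correlation distance, d(x, c) = 1 − Pearson r. Profiles
are standardized (mean 0, SD 1) before clustering — correlation
distance implies scale invariance, and standardization makes the
arithmetic centroid mean consistent with the metric. Centroids
("eigen-genes") are member means, re-standardized. Lloyd iterations
run to an assignment fixpoint (or 300 iterations), empty clusters are
re-seeded with the farthest profile, and the best of 50 random
initializations by total within-cluster distance is kept; the whole
procedure is a pure function of (profiles, k, seed, n_init). K = 4
per axis, matching the four archetypal patterns along an ordered
treatment series: **tent** (extremum at the midpoint — the midpoint
irradiance is the theoretical saturating irradiance), **inverse
tent**, **decreasing**, and **increasing**. Recovered centroids are
labeled against these templates by maximum-weight matching
(linear-sum assignment on the centroid–template correlation matrix),
so the four labels are always distinct.

## Functional enrichment

For a gene set, each category's enrichment ratio is
(k/n) / (K/N): the category's share of the set over its share of
the universe. The default universe is all genes of the set's species
("the genome as a whole"); a filtered universe can be supplied where
statistically preferable. Significance is the one-sided exact
hypergeometric tail, summed directly in log space (lgamma + logsumexp)
and verified in the tests against a rational-arithmetic oracle
(exhaustively for N ≤ 26) and against an independent library
implementation for random tables up to N = 200, to 10⁻¹². The
significance flag uses the raw p < 0.05 rule of the original analysis
(which did not adjust across categories); BH-adjusted values are
always reported alongside.

## Turbidostat physiology

At steady state the turbidostat identity µ = D holds, so the specific
growth rate is read as the mean dilution rate over a **steady-state
window**: the maximal trailing stretch of the 1-min log in which
dilution rate, OD₇₃₀ and dissolved O₂ each vary by less than 10 % of
the window mean — "variation" implemented as maximum absolute
deviation over the mean, the stricter of the plausible readings — for
at least three residence times (τ = 1/D; at the fastest τ of 3.36 h
this is ⌊3 · 3.36 · 60⌋ = 604 one-minute rows).

Derived quantities:

* **Doubling time** ln 2 / µ (0.289 h⁻¹ ↦ 2.4 h).
* **Cmol growth rate** µ_Cmol = µ · 1000 / M_X, with M_X the formula
  weight of the elemental biomass composition (default CH₁.₈O₀.₅N₀.₂,
  24.63 g Cmol⁻¹) — units Cmmol h⁻¹ g⁻¹ CDW.
* **Net O₂ production** from a two-route export balance out of the
  well-mixed reactor: q_O₂ = [F_gas (y_out − y_in) P/(RT) · 10³ +
  D · C_dissolved · V · 10⁻³] / (X · V) in mmol O₂ h⁻¹ g⁻¹ CDW, with
  off-gas molar flow by the ideal gas law at 298.15 K. The balance is
  artifact-defined (the original instrument-level derivation is not
  public); the simulator inverts the same balance, so noise-free
  round-trips recover configured rates to machine precision, which is
  what the closure suite asserts.
* **O₂ sensitivity** — the absolute OLS slope of µ against pO₂ (h⁻¹
  atm⁻¹) with its standard error; larger values mean more growth
  inhibition per atm O₂.
* **Photosynthetic quotient** — the OLS slope of µ_Cmol against q_O₂
  across steady states (Cmol biomass per mol O₂).
* **Gas conversions** — dissolved O₂ concentration and percent air
  saturation are Henry-law proportional to pO₂:
  C = C_air-sat · pO₂ / 0.21 and % = 100 · pO₂ / 0.21. The
  air-saturation concentration at 52 °C defaults to 130.3 µM,
  back-calibrated together with the 0.21 atmospheric fraction so that
  the 0.59 atm treatment reports the printed pair 366 µM / 281 % under
  nearest-integer rounding; both constants are configuration-exposed.

**Flow cytometry**: events are assigned by pairwise-disjoint
rectangular gates in (forward scatter, side scatter), optionally
refined by fluorescence thresholds; composition is the percentage of
total events per gate plus the ungated remainder. **ROS-RNS plates**:
the corrected value is treated − control per matched replicate
(removing nonspecific fluorescence); group means ± SD are compared
all-pairs by Tukey's HSD on the studentized range (Tukey–Kramer for
unequal group sizes) at α = 0.01.

## The synthetic-data generator

The generator produces every input the pipeline consumes, with
ground-truth records, calibrated to the study's printed quantities.

**Transcriptomes.** The catalog holds 2,476 cyanobacterial and 2,016
heterotroph genes (the latter chosen so the default jointly analyzed
set is ≈ 4,492), lengths uniform on 300–3,000 bp, 0–2 categories from
a 20-label vocabulary. Per axis, every gene carries one archetype
shape. Responsive genes — planted at the study counts: 354/339
light-responsive and 105/60 O₂-responsive cyanobacterial genes under
axenic/binary growth, plus heterotroph counts of realistic magnitude
(300/200) — are geometric monotone ramps spanning a 4-fold change
between the axis extremes. All non-responsive genes are tent, inverse
tent (amplitude 1.5, extremes equal) or flat, so their extreme-
condition ratio is exactly 1. Responsive sets are disjoint across
axes within a species, and a gene responsive on one axis carries a
ratio-1 shape on the other. Gene baselines are lognormal around 200
expected counts (σ = 0.3) with a floor at 60 % of that mean; the
heterotroph's baselines are rescaled so its library share is 10 %.
Replicate counts draw from a negative binomial whose dispersion
parameter is the extra-Poisson coefficient of variation (NB size =
dispersion⁻², default 0.05, i.e. ≈ 5 % biological CV on top of
Poisson noise), plus a lognormal per-sample depth factor (σ = 0.15)
that exercises the size-factor stage.

This design makes the planted truth *exact*: the set of genes whose
noise-free extreme ratio reaches 2-fold equals the planted responsive
set by construction, and the ≥ 4σ margins on both sides of the
threshold keep the noisy caller's counts at the planted values. Three
things real data have are deliberately absent — weak monotone trends
below the 2-fold threshold (real clusters of increasing/decreasing
genes are much larger than the responsive sets), a low-expression tail
(the RPKM < 15 filter is exercised by dedicated unit fixtures
instead), and any correlation structure beyond the planted shapes.
Passing recovery tests therefore demonstrates the pipeline's
correctness on separable ground truth, not its behavior on marginal
real-world genes.

**Turbidostat logs.** µ(Iᵢ, pO₂) = µ(Iᵢ) − s · pO₂, with µ(Iᵢ)
piecewise-linear through (197, 0.08), (1,190, 0.18), (1,995, 0.289)
h⁻¹ and sensitivity s = 0.127 (axenic) or 0.086 (binary) h⁻¹ atm⁻¹.
Only the top-irradiance value is anchored to a measured number (the
≈ 2.4-h doubling time); the low/mid-irradiance defaults are plausible
placeholders and not study values. Photosynthetic quotients default
to 0.30 (axenic) and 0.40 (binary) Cmol mol⁻¹ — free parameters whose
slope recovery, not value, is tested. Each 1-min channel sits at its
model value with 2 % relative Gaussian noise; off-gas fractions are
derived by inverting the analyzer's own gas balance.

**FACS.** Population fractions 90.2 % / 9.1 % / 0.7 %
(cyanobacterium / heterotroph / debris, the last absorbing the
percentages not summing to 100). Channels are Gaussian with scatter
means separated by ≥ 4 pooled SDs — enforced as a config invariant —
so the default mean ± 4 SD rectangular gates are unambiguous and
assign ≥ 99.9 % of events to their true population.

**ROS plates.** Triplicate treated/control wells per group; default
treated means are ≈ 520–540 (axenic) and ≈ 920–940 (binary) against a
200-unit control with SD 40 — chosen to reproduce the qualitative
finding that intracellular ROS-RNS rises under heterotrophic
partnership and is insensitive to pO₂.

## Numerical and degenerate-input choices

* Pseudocount ε = 0.5 for ratios and logs (configurable).
* Strict inequalities follow the published wording: "< 15" removes
  14.99 and keeps 15.0; the 2-fold calling threshold is inclusive.
* Variance-mask and K-means tie-breaks are deterministic (gene-id
  order; fixed-seed generator; linear-sum assignment).
* K-means raises on constant profiles (standardization is undefined;
  apply the variance mask first) and on fewer distinct profiles than k.
* Missing table cells are errors, never zeros; counts must be
  integers ≥ 0.
* Steady-state detection treats an all-zero channel as stable and a
  zero-mean varying channel as unstable.

## Problem sizes used in the checks

The acceptance-style checks run the generators at full study scale
(4,492-gene transcriptomes, 50,000-event FACS runs, 604+-row logs) —
a few seconds each. Unit and property suites use scaled-down configs
(≈ 500 genes, 10⁴ events) plus exhaustive small-table sweeps for the
exact test (all tables N ≤ 26, random tables to N = 200).

## Known limitations

* The original count-model DE engine and instrument-level gas balance
  are replaced by documented stand-ins (moderated t; two-route export
  balance); contracts, not internals, are preserved.
* Enrichment categories are opaque labels; no ontology semantics.
* The growth model has no light saturation or photoinhibition beyond
  the piecewise-linear µ(Iᵢ), and no carbonate-system chemistry.
* Cluster-size realism is traded for exact responsive-gene ground
  truth (see the generator section); do not compare synthetic cluster
  sizes against published ones.
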