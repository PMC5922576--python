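# Methods

## Detection-sensitivity model

A somatic mutation is called at a base in one library replicate when the
mutant read count reaches `k0 = max(c, ceil(r*n))`, where `n` is the
coverage, `c` is the minimum mutant read count and `r` the minimum mutant
read proportion.  The mutant read count is modeled as Binomial(n, m), with
`m` the expected mutant allele frequency; the per-replicate sensitivity is
the binomial upper tail `P(X >= k0)`.

`m` defaults to half the tumor-nuclei fraction — a heterozygous clonal
mutation in a diploid background, with tumor purity measured by a
pathologist on the H&E slide.  That assumption fails for amplified loci,
copy-neutral LOH, subclonal events and non-diploid genomes; `m` can be
overridden per call (`TumorContext(purity, m=...)`).

When every read over a base is wild type, a sharper bound is available:
assuming a mutation present at frequency `r`, the false-negative probability
is `(1-r)^n`, giving sensitivity `1-(1-r)^n`.  The bound uses the extra
information (all reads WT) and therefore dominates the standard power
calculation at the same `r`; it is selected per replicate exactly when that
replicate observed zero mutant reads, and is invalid otherwise (misuse
raises).

Replicate combination: variants are reported only when called in **both**
duplicate libraries (concordance — consistent with treating
singleton-replicate variants as sequencing error), so combined sensitivity
is the product of per-replicate sensitivities under an independence
assumption.  The alternative "either" policy (complement product) is
available but not the default.  Any replicate count >= 1 is supported; a
base observed in fewer replicates than expected falls back to what is
available and is flagged.

Gene-level sensitivity is the weighted mean of combined base sensitivities,
with per-base weights standing in for catalog-derived somatic-mutation
priors, normalized within each gene (rescaling a gene's weights is a
no-op).  Zero-weight bases are excluded rather than zeroing the gene —
mutation catalogs are sparse.  A gene below the 99% reporting threshold is
classified low coverage and reported as indeterminate.

Numerics: the binomial tail is computed via the survival function
(regularized incomplete beta), stable beyond n = 10^6; `(1-r)^n` is
evaluated in log space (`expm1`/`log1p`).  `ceil(r*n)` carries a 1e-9
relative snap-to-integer guard: in binary floating point `0.02 * 1000`
exceeds 20 by 4 ulp, and an unguarded ceiling would demand 21 mutant reads
where the rule means 20.

A note on shape: sensitivity is monotone in `m`, and non-increasing in `c`
and `r`, but it is **not** globally monotone in coverage `n` — each time
`ceil(r*n)` increments, the required mutant count jumps by a whole read and
the sensitivity can drop (e.g. c=5, r=0.02, m=0.025: 0.7505 at n=250,
0.5999 at n=251).  Property tests therefore assert monotonicity in `n` only
within constant-threshold segments.

## QC gates

* **Copy number** — per-gene coefficient of variation of repeated reads
  (sample sd / mean; genes with mean zero excluded and logged), averaged
  across genes; an average above 30% rejects all copy-number results.  The
  gate is applied to the average, not to any single gene's CV.
* **mRNA** — per-gene replicate variance compared with the reference-range
  variance through the pooled statistic `sum_g (n_g - 1) s_g^2 / sigma_g^2`,
  referred to chi-squared with `sum_g (n_g - 1)` degrees of freedom,
  two-sided at alpha = 0.05 (suspiciously tiny variance also fails).  This
  is one reasonable construction of an otherwise under-specified test and is
  kept pluggable; with replicates truly drawn from the reference
  distribution it passes 95% of cases by construction, which the
  calibration suite verifies empirically.
* **Sequencing error** — the singleton rate is the fraction of candidate
  variants observed in exactly one replicate.  The per-variant
  false-positive estimate defaults to half that rate (a singleton is an
  error in one of two libraries); the case-level probability that at least
  one reported (concordant) variant is a false positive is `1-(1-fp)^k`.

## Drug-association rules

Rules are conjunctive if-then statements over (analyte, target) findings —
mutation, copy number, mRNA, IHC — serialized as YAML and round-tripping
losslessly.  Predicates: presence/absence, equality, numeric comparisons,
set membership.  Each matched rule is one drug association; one drug can
accrue several associations through distinct rules (the configurable
alternative counts satisfied criteria instead).  Indeterminate findings
(e.g. mutation status on a low-coverage gene) never satisfy a criterion,
including "absent": an indeterminate result is not evidence of absence.  A
finding missing from the profile also satisfies nothing — profiles are
treated as complete panel outputs.

## Geometry

Area is the accessioning measurement: longest dimension, the perpendicular,
and a visual fill-fraction estimate of the bounding rectangle (pi/4 = 79%
for a perfect circle).  Depth is deliberately not modeled — it cannot be
measured non-destructively at accessioning — so curl availability is a
configured cap, not an inference.  Curls: `ceil(500 mm^2 / area)` per
nucleic-acid type, 10 um thick.  FNA passes: a pass is modeled as a
longitudinal core section, inner diameter x core length (default 10 mm,
configurable), and the pass count is `ceil(required_area / per-pass area)`
with required area defaulting to 10 mm^2.  The gauge -> inner-diameter
table ships the standard regular-wall chart for 14-25G; finer gauges are
omitted because published inner diameters stop decreasing strictly there.
The per-pass geometric model is a stated assumption: pass counts are
monotone in gauge by construction, but absolute counts depend on the core
length a site actually achieves.  Adequacy verdicts use inclusive floors:
adequate at >= 10 mm^2 **and** >= 5% tumor nuclei; marginal when either the
5 mm^2 area floor or the 3% tumor floor is met; otherwise inadequate.

## Synthetic cohort generator

The generator draws the study conditions, not a convenient fixture:

* 2,000 specimens by default (2,723 for full-series accounting), with a
  0.88% pre-sequencing cancellation rate and a 6.4% overall QNS rate
  (cancellations included).
* Tumor-nuclei percentage and tissue area drawn uniformly within bins
  (1-3 / 3-5 / 5-10 / 10-25 / 25-100 % and 1-5 / 5-10 / 10-20 / 20-30 /
  >30 mm^2) under configurable bin probabilities weighted toward the higher
  ranges, as in a real consecutive series.
* Coverage per base: negative binomial (dispersion 8) around a mean depth
  of 13,656x scaled by the recoverable input mass
  `min(1, area * curls / 500)`, curls capped at 40 — small blocks yield
  shallower libraries.  Error mutant reads at 5e-4 per base; true mutations
  at the hotspot (highest-prior) base of 10% of genes per specimen, with
  allele frequency `purity/2`.  Calling defaults c=5, r=0.02.
* Low-coverage counts are **not injected**: they emerge from the sensitivity
  model as `m = purity/2` crosses the calling proportion `r` (the crossover
  sits near 4-5% tumor at these defaults).  The coverage "effect knob" is
  therefore a null switch: `coverage_effects=False` fixes `m` and removes
  the mass->depth coupling.
* Drug associations follow per-bin mean counts — 21 at baseline, 3 in the
  <=5 mm^2 area bin, 10 in the 1-3% tumor bin, combined across axes by
  `min()` — realized as Bernoulli findings over a generated 30-rule,
  single-criterion rule library, so the rule engine recovers the generated
  count exactly.  The 21 -> 3 area drop is anchored to the emulated series;
  the 1-3% tumor value is a package choice (only the direction and
  significance of that drop are anchored).  `association_effects=False`
  flattens the means.
* mRNA replicate reads are drawn from the reference distribution itself
  (pass rate ~95% regardless of bin — mRNA QC is insensitive to specimen
  size and tumor content by construction); copy-number replicates are tight
  (CV 10%) with a 2% failure mode at CV 50%.
* Ground truth (true association counts, true mutant genes, mass factors)
  is retained on every record and excluded from the public export, which a
  side file carries instead.

What the generator does **not** emulate: FFPE artifact chemistry
(deamination), panel-specific coverage unevenness, correlated multi-analyte
biology (findings are independent given the bin means), pathologist
purity-estimation error, and any coupling between QNS and geometry beyond
the configured rates.  Passing recovery tests therefore demonstrate that the
pipeline detects the modeled effect structure at realistic sizes and noise
— not that real cohorts have that structure.

## Cohort statistics

Bins are left-open/right-closed with a closed lowest edge.  Count outcomes
use one-way ANOVA, then Tukey's HSD (Tukey-Kramer for unequal n) against
the highest range only when the omnibus test is significant; proportion
outcomes use chi-squared homogeneity plus pairwise 2x2 chi-squared (no
continuity correction) against the highest range, with exact
Clopper-Pearson intervals per bin.  Alpha = 0.05 everywhere; no
multiple-testing correction beyond Tukey's family-wise control.  QNS rows
and rows with missing outcomes are excluded from comparisons.  QNS
accounting adds pre-sequencing cancellations to both numerator and
denominator, since they never appear as dataset rows.

## Problem sizes and seeds

Parameter recovery runs 100 replications of 2,000-specimen cohorts
(~1.5 s each); Tukey calibration uses 1,000 equal-mean simulations (the
family-wise error band of 7.5% covers the ~0.7% simulation sd around the
nominal 5%); Clopper-Pearson coverage uses 10,000 draws at four (n, p)
settings; the mRNA gate calibration uses 1,000 cases.  All randomness flows
from `numpy.random.default_rng` / `SeedSequence` children of a single seed,
kept below 2^31.

## Known limitations

* The replicate-independence assumption in the product combination ignores
  shared pre-library artifacts (both replicates sequence the same extract).
* The mRNA chi-squared construction and the per-variant false-positive
  model are reasonable conventions, flagged as such and configurable.
* The FNA pass counts are model-dependent (core length); only their
  monotone shape in gauge is asserted.
* Bin edges for intermediate ranges are defaults, overridable via
  `BinScheme`; results near edges depend on the boundary convention.
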