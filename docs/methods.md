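# Methods

## The coalescent model for a converting gene-duplicate pair

The simulator (`paraconv.coalsim`) runs an event-driven structured
coalescent backwards in time for two homologous loci of `L` discrete
sites sampled from one panmictic population.  Each ancestral lineage
carries a set of material segments (intervals of sites with the set of
descendant samples) and resides at one locus.

* **Coalescence.** Two lineages at the same locus coalesce at rate 1 per
  pair.  Time is measured internally in units of 2N generations (N =
  current population size); user-facing times are in 4N units and
  converted on entry.
* **Gene conversion.** `C = 4Nc` is the per-site rate at which a site is
  covered by a conversion tract.  Tract initiations therefore occur at
  rate `C/(2*lambda_tract)` per site per lineage; tract lengths are
  geometric with mean `lambda_tract` (≥ 1 bp), truncated at the locus
  boundary; the covered material splits off as a new lineage residing at
  the other locus.  With this parameterization the marginal process at a
  single site is exactly a two-island migration model with rate `C`,
  which yields the analytic pair-time oracle `E[T_same] = 2`,
  `E[T_diff] = 2 + 1/C` used in the tests.  As an optimisation,
  initiations whose tract cannot intersect a lineage's ancestral
  material are integrated out analytically (the closed-form geometric
  tail mass to the left of the material span); such events have no
  genealogical effect, so the optimisation is exact.
* **Duplication.** At `t_dup` the younger locus ceases to exist: all its
  material is relabelled to the ancestral locus and conversion stops.
  The duplication is treated as fixed; segregation of the copy number
  itself is not modelled (the data motivating the model show copy-number
  variation, but no parameters for a segregating-duplication model are
  identifiable from a single population sample of this size).
* **Demography.** A stepwise expansion: for `t > t_exp` the population
  was smaller by factor `f ≥ 1`, implemented by multiplying the
  coalescence rate by `f`.  Mutation and conversion rates are per
  generation and therefore unaffected by the size change.
* **Mutation.** Infinite sites mapped onto the `L` discrete homologous
  positions: mutations fall on branches as a Poisson process at rate
  θ/2 per site per lineage (2N-unit clock), each assigned a uniform site
  within the lineage's material and resampled on collision.  This
  calibrates a constant-size single locus to `E[S] = theta*L*a_n`.
  Intralocus crossing-over is not modelled (rate 0): recombination
  between the paralogs is represented by conversion only.

Mutations attached to segments whose descendant set spans the full
sample are fixed in everything and dropped; sets spanning exactly one
locus's samples produce fixed differences between the paralogs.  The
replicate output is a binary haplotype matrix over homologous 1-based
positions with ancestral state 0, plus the per-site grand-MRCA times.

The simulator was cross-checked against msprime under the expansion
demography (mean Tajima's D and E[S] via branch lengths agree within
Monte-Carlo error); msprime appears in the test extra only, never in the
implementation path.

## Summary statistics

All statistics follow the classic sequence-based definitions with
pairwise deletion of missing data (gaps and N): per column, pair
differences are averaged over pairs with both members present, and
per-site denominators count columns with at least two non-missing
alleles.  π is reported uncorrected for multiple hits.  Tajima's D uses
the 1989 variance constants and is flagged undefined (NaN) when S = 0 or
n = 2.  Fu & Li's D uses the outgroup-polarized 1993 form with total
mutations η and derived singletons η_e; columns with a missing outgroup
state are excluded, and the outgroup-free D* variant is out of scope.
F_ST between two groups is Hudson's 1 − H_w/H_b with H_w pooled over
both groups' pairs; it is 0 by convention when H_b = 0.  Cross-locus
columns are classified as shared (segregating in both paralogs), private
(segregating in exactly one) or fixed (monomorphic for different
states), with derived-allele-frequency spectra per class (pooled counts
for shared columns, per-locus counts for private ones).

## ABC

Rejection with SD-standardized statistics and Euclidean distance,
retaining the best k of n simulations, followed by local-linear
regression adjustment (weighted least squares of parameter on
standardized statistics, Epanechnikov weights on the distance with
bandwidth equal to the largest retained distance; adjusted draws are
clamped to the prior support).  Posterior point estimates are the argmax
of a Gaussian KDE (Silverman bandwidth, 512-point grid over the prior
support); intervals are central 95% quantiles of the adjusted draws.

The statistic set is (S_A, S_B, π_A, π_B, D_A, D_B, n_shared, n_fixed,
n_private): the shared/fixed counts carry most of the information about
interlocus conversion, while the per-locus statistics anchor θ and the
duplication age.  Model choice pools the conversion and no-conversion
reference tables, standardizes jointly, retains the overall best k, and
reports the acceptance-ratio Bayes factor; when no no-conversion
simulation is retained the value k is reported as a lower bound.

Priors (uniform throughout): `C ~ U(0, 20)` per site, `lambda_tract ~
U(50, 2000)` bp, `t_dup ~ U(0.05, 2)` in 4N generations; θ is fixed to
the panel's Watterson estimate.  The production recipe retains the best
500 of 100,000 simulations; the package's default profile is the scaled
version (best 200 of 20,000), which the recovery tests show covers a
true conversion rate of 1 in ≈ 95% of repetitions.  Simulated replicates
with an undefined statistic (S = 0 at a locus) are resampled.

Demographic calibration uses a panel of independent single-copy loci;
the observed vector is the across-locus mean and variance of (S, π per
site, Tajima's D), and each prior draw simulates a panel of the same
size.  Conversion can be included in or excluded from the estimation
model independently of the neutrality nulls; the default estimates the
conversion rate with demography held constant and uses both the fitted
demography and the estimated conversion rate when building the
Tajima's-D null for the coding region.

## Neutrality tests

Null distributions of Tajima's D are simulated (default 2,000
replicates) under the fitted expansion demography, with conversion and
the paralog's sample size included for coding-region nulls.  Empirical
p-values use an add-one pseudo-count, `p = (1 + #{null ≥ obs})/(reps +
1)`, so finite simulation never yields p = 0.  Because the directional
convention is question-dependent, upper, lower and two-sided values are
all reported; the default is the upper tail (balancing selection
predicts positive D).

## Association scan

Each biallelic marker with minor-allele frequency strictly above 0.25 is
tested by OLS of the binary phenotype on the 0/1 genotype; R² is the
model sum of squares over the total and p comes from F(1, n−2).
Phenotype contrasts: protease-inhibitor sensitivity codes class II
against classes III + IV; response strength codes III against IV; class
I (no protein, pseudogenes) is always excluded.  Raw p-values are
reported alongside Bonferroni-corrected ones (m = markers tested) with
flags at corrected 0.05 and 0.01.  No population-structure covariates
are used.  The 25% filter is exposed as a parameter because biologically
interesting variants can sit below it in small panels.

## The synthetic data generator

`paraconv.synthetic_data` produces panels with the structure the
analysis assumes: 14 + 9 alleles of a 1,000-site gene (two exons of 100
and 200 codons around a 100 bp intron, valid reading frame, terminal
stop), simulated under θ = 0.0085 per site and conversion at C = 1.08
per site with 500 bp mean tracts and a duplication at 1.0 (4N
generations) — the rates estimated for the motivating system; the
reference-locus panel uses θ = 0.014 under a five-fold expansion at 0.5
(4N generations).  The intron dimorphism (5% per-site divergence, 50%
frequency within each locus) is overlaid deterministically on the
simulated genealogy rather than arising from simulated selection:
forward simulation of balancing selection is out of scope, and the
downstream analyses only require data shaped like the observation.
Pseudogene alleles receive alternating premature-stop and 1-bp-deletion
(frameshift) lesions; the outgroup carries the ancestral states.  Causal
phenotype SNPs are planted at monomorphic exonic columns with carrier
frequency 0.35 drawn among expressed alleles, which makes the causal
pattern unlinked to the genealogy and keeps the planted marker the
unique perfect association under full penetrance.

Because the overlay and planted sites add intermediate-frequency
variants, the panel's observed diversity exceeds the generating θ; the
ABC is unaffected (observed and simulated data are summarised
identically), but per-type π values are higher than at a neutral
single-copy locus.  What passing tests show is that the machinery
recovers known generating parameters and planted signals under this
emulation; they do not validate biological features the generator omits
(selection, recombination within loci, sequencing error, alignment
ambiguity).

## Numerical choices and edge cases

Sequence typing is deterministic complete-linkage 2-clustering of
pairwise intron distances (a tree-free stand-in for manual clade
assignment); label 1 is the larger group, ties broken by the smallest
member id, and a monomorphic intron yields "untyped" rather than an
error.  Pseudogene flagging translates the degapped, intron-removed
frame and reports "frameshift" (length not divisible by 3) before
"premature stop".  SNP calling keeps strictly biallelic columns, treats
gaps as missing, and breaks 50/50 frequency ties alphabetically.
Zero-variance statistics are dropped from ABC distances with a warning;
singular regression designs fall back to unadjusted draws; rejection
ties are broken by row index for determinism.  All stochastic entry
points accept either a seed or a NumPy Generator, and every analysis
script and the acceptance script derive their streams from a single
`--seed`.

## Known limitations

The duplication is fixed rather than segregating; only two paralogs are
modelled; there is no intralocus crossing-over, no selection, and no
sequencing/alignment noise model.  Tract-length and conversion-rate
priors are weakly identified by a single panel (the tract posterior is
typically close to its prior).  The association scan is a plain GLM: in
structured panels it will pick up stratification that a mixed model
would absorb.
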