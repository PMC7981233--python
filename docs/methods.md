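# Methods

This note documents the models and procedures implemented in `anole_spatgen`,
the choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Spatial model

All analyses live in a planar park frame (metres, origin at the southwest
fence corner). Capture locations are always coarsened to the centroid of the
bush of capture: field GPS at this scale (±1–2 m) cannot resolve positions
within a bush, so the bush is the spatial unit. Raw coordinates, when
supplied, are retained but unused.

**Distance metrics.** Bush-to-bush distances come in two flavours.
`euclidean` is the straight line between centroids. `perimeter` (the
default) projects each centroid perpendicularly onto the fence polyline and
takes the shorter of the two along-fence arcs — appropriate because the open
park interior is lawn that the lizards do not cross, so movement follows the
fence-line vegetation. Which of the two a field study's hand-measured
distance matrix corresponds to is generally not determinable, so both are
exposed and the choice is a flag. Males captured in the same bush are 0 m
apart; this floor effect of bush coarsening is accepted and documented.

**Home ranges.** A single distinct capture bush yields that bush's polygon
(areas at the 10–20 m² scale); two or more yield the convex hull of the
union of the capture-bush polygons — the minimal deterministic region
containing the distal capture points and all area between them. Hand-drawn
polygon tools used in GIS workflows are not reproducible; the hull is, and
it naturally accommodates ranges that cut across the park interior.
Single-capture individuals are flagged and can be excluded by argument
(`exclude_single_capture`), since their "range" is just one bush.

## Population-genetic machinery

**Locus summaries.** Allele frequencies by gene counting over non-missing
calls; observed heterozygosity is the fraction of heterozygous genotypes;
expected heterozygosity uses Nei's unbiased correction (2n/(2n−1))(1−Σp²).

**HWE.** A Monte-Carlo exact test: conditional on the observed allele
counts, alleles are re-paired at random (default 10,000 pairings) and the
p-value is the fraction of pairings whose conditional probability is no
larger than the observed configuration's, with the +1 correction. The
conditional probability is evaluated in log space from the genotype-count
factorials and the 2^heterozygotes factor.

**Linkage disequilibrium.** A permutation test of genotypic association:
the statistic is the G (log-likelihood-ratio) statistic of the two-locus
genotype contingency table; the null permutes one locus's genotypes across
individuals (default 1,000 permutations).

**Multiple testing.** Holm's sequentially rejective correction; with eight
loci the first threshold is α/8 ≈ 0.0065 at the conventional 5% level.

**Kinship.** The Loiselle correlation-type estimator with its small-sample
correction term p̄(1−p̄)/(nₗ−1) per allele, where nₗ counts reference *gene
copies* (twice the genotyped individuals). With the correction on the
gene-copy scale the estimator's mean over all dyads within its own reference
sample is slightly negative, its documented finite-sample property, while
parent–offspring and full-sib dyads centre on 0.25 and half sibs on 0.125.
Reference allele frequencies are computed per cohort by default (IBD is a
within-cohort question); a whole-dataset baseline is available by argument.

**Autocorrelograms.** Five equal-frequency (quantile) distance classes —
robust to the clumped perimeter geometry of the bushes, and the default
behaviour of standard spatial-genetics software; per class, the mean pairwise
kinship and a 95% envelope from permuting individuals among their occupied
positions (default 999 permutations). A class mean outside the envelope is
significant at that scale.

**Mantel tests.** Pearson correlation of off-diagonal elements under joint
row/column permutation of one matrix, one-tailed with the +1 correction.
For IBD the test is run one-tailed toward negative correlation (relatedness
declining with distance).

**Neighbour contrasts.** For a focal heavyweight, neighbours are the cohort
males captured in any bush intersecting his home-range polygon. The package
reports the classical t-test on the per-focal (neighbour mean − non-neighbour
mean) differences *and* a permutation test that reshuffles neighbour labels
within each focal's scored partners. The t-test ignores the non-independence
of dyads sharing a focal; the permutation test is the recommended inference
and both are labelled in the output.

## Parentage engine

The likelihood is a trio/pairwise categorical allocation: the offspring
genotype arises by Mendelian transmission from a candidate sire and/or dam,
with population allele frequencies standing in for an unsampled parent, and
each observed offspring allele independently mistyped with probability ε
(replaced by a uniformly drawn different allele of the locus pool).
Candidate genotypes are taken at face value; loci missing in the offspring
are skipped and a candidate's missing locus contributes the unknown-parent
term, keeping configurations comparable. Full-pedigree sibship likelihoods
(as in full-likelihood pedigree software) are deliberately **not**
replicated: the procedure-level structure — sequential cohort stacking,
replicate consensus, retention threshold — is the object of interest here,
and a pairwise engine keeps it transparent and testable. This is a
documented fidelity gap: sibship information among parentless offspring is
ignored.

Per offspring, four configurations are weighted: no sampled parent, sire
only, dam only, sire+dam, with priors (1−π)², π(1−π), (1−π)π, π² from the
parent-sampled probability π (default 0.5). The sire+dam configuration is
found by a joint search over the `pair_top_k` (default 5) marginally best
candidates of each sex — the true trio often dominates jointly even when a
relative wins a marginal ranking. A link from the maximum-posterior
configuration is retained when a likelihood-ratio test against the same
configuration without that parent is significant (χ², 1 df, default
α = 0.05). Ties between equally likely candidates are refused — no link —
which is conservative and deterministic; a replicate-seeded random tie-break
is available by configuration.

**Sequential procedure.** Cohorts are processed chronologically; at step k
the candidates are all individuals seen in cohorts 1..k (males as sires,
females as dams), the offspring are the step-k newcomers, and accepted links
are frozen as known-parentage priors, never revised. Links that would close
a parentage cycle (possible when same-cohort individuals are mutually
eligible) are refused. The whole procedure runs in replicate (default 3,
one seed each) and the consensus keeps links present in every replicate.
Because the default engine is deterministic given the data, the replicates
coincide and the consensus equals a single run; the replicate machinery
matters when random tie-breaking or data perturbation is enabled.

**Inbreeding.** F of an individual is the pedigree kinship of its two
parents by the recursive tabular method; unknown parents are unrelated
founders. The trajectory report gives, after each sequential step, the mean
F over individuals with both parents assigned — a *pedigree-depth-limited*
quantity: early cohorts are founders by construction, so the trajectory
starts at zero and grows as the known pedigree deepens.

## The synthetic park

The generator is an individual-based seasonal model of the study system it
emulates: a one-hectare fenced square park, 38 rectangular bushes of 2 m
depth placed with random lengths and gaps along the fence (corners kept
clear), ten seasonal cohorts (spring/fall over five years), eight
microsatellite loci with 13–33 alleles each (symmetric-Dirichlet founder
frequencies, which reproduce high polymorphism without extra parameters),
polygynous mating, and a 1% per-allele genotyping error applied to the
*observed* genotype table only.

Season cycle: (1) females and lightweight males may shift to one of the
`move_k_nearest` bushes (p = 0.25 and 0.15 per season); moving females head
for the nearest heavyweight-held bush with probability 0.7 — the
female-defence structure of the mating system; (2) heavyweights (males
≥ 64 mm) claim one bush each, largest SVL winning contested bushes (ties by
id), displaced males taking the nearest free bush; (3) every living
individual is captured with probability `capture_prob` (default 0.55);
(4) each mature female (SVL ≥ 42 mm) produces Poisson(2.1) recruits, sired
by her bush's resident heavyweight with probability `p_resident_sire`
(default 0.8), otherwise by a random lightweight; (5) individuals survive
with probability 0.65 and grow by a truncated-normal SVL increment
(mean 10 mm, sd 2) toward a sex-specific asymptote, so the
lightweight-to-heavyweight transition emerges from growth; (6) recruits
enter the next season at the dam's bush, daughters staying with probability
`p_female_philopatry` (default 0.8), sons with probability
`p_male_natal_stay` (default 0).

**Male kin exclusion.** Under the default male-dispersal regime
(`male_avoids_sire_range=True`), a male never settles in, and never expands
his own occupied hull over, any bush intersecting the convex hull of his
sire's occupied bushes — and symmetrically a sire's moves never engulf a
son's recorded bushes. This mutual exclusion encodes the agonistic
expulsion of male offspring from paternal territories as a mechanism, and
makes "no son is ever captured inside his father's range" a *generative
property* of the regime, which the end-to-end tests then verify the analysis
pipeline recovers from the observable data alone. Setting the flag false
(and `p_male_natal_stay = p_female_philopatry`) gives the sex-symmetric
control regime.

Demographic rates (survival 0.65/season, Poisson(2.1) recruits per mature
female, founder n = 110, capture probability 0.55) are **assumptions, not
estimates**: no demographic rates are available for the emulated system, so
defaults were chosen once to yield a realistic population of roughly 850
unique captured individuals across the ten cohorts, and are documented here
rather than tuned per analysis.

What the generator does *not* emulate: within-season movement and multiple
captures per season; mortality structure (predation, winter die-off);
density-dependent fecundity; immigration through the fence; null alleles,
stutter or allele-binning artefacts (the error model is pure mistyping);
three-dimensional perch structure. Passing recovery tests on this generator
therefore demonstrates that the estimators and procedures are correct under
Mendelian inheritance, territorial polygyny and sex-biased dispersal — not
that any particular field dataset satisfies those assumptions.

## Numerical choices

- All Monte-Carlo procedures take explicit `rng`/seed arguments; defaults
  are documented at each call site and every pipeline entry point threads a
  single seed.
- Permutation p-values use the +1 correction in numerator and denominator,
  so p ∈ (0, 1] and the smallest attainable p is 1/(n_perm+1).
- Likelihood ties (< 1e-9 in log-likelihood) refuse assignment; Mendelian
  exclusions at ε = 0 produce −inf log-likelihoods handled explicitly.
- Monomorphic loci report He = Ho = 0 and are skipped by the kinship
  denominator; dyads with no co-genotyped locus are NaN and excluded.
- Degenerate inputs (one-bush cohorts, constant matrices, empty tables) are
  flagged in the output rather than raising, except where the input violates
  a domain invariant (unknown bush ids, duplicate cohort records, cyclic
  pedigrees), which is an error naming the offending row.

## Problem sizes used by the test suite and acceptance script

Estimator-recovery experiments use 8 loci × 20 alleles with a 200-individual
reference and 500 dyads per relationship class. Calibration experiments use
1,000 null replicates per test, with 399 Monte-Carlo pairings (HWE, n = 100,
8 alleles) or 199 permutations (LD, n = 40; Mantel, n = 15) per replicate —
sample sizes chosen so the tests' discreteness does not dominate the
rejection rate at α = 0.05. Parentage recovery runs on the full default park
(~850 captured individuals, 10 cohorts, triplicate). The end-to-end
dispersal experiments use 20 replicate parks of 8 cohorts with ~40 founders
and perfect detection, the smallest configuration in which inheritance
tables have stable counts in every run.

## Known limitations

- The parentage engine ignores sibship structure; precision and recall
  (~0.85–0.93 on the default park) would improve with full-pedigree
  likelihoods at considerable complexity cost.
- Home-range hulls from bush polygons cannot shrink below one bush, and
  single-capture individuals carry no range information beyond it.
- The perimeter metric assumes the fence line is the only corridor; a
  partially permeable interior would need a cost surface, which is out of
  scope.
- Heterozygosities in the default synthetic park (~0.89) are higher than
  typical field values for the same allele counts because founder
  frequencies are drawn flat-Dirichlet and drift has only ten seasons to
  act; kinship and parentage results are insensitive to this, but absolute
  QC numbers from synthetic runs should not be compared to field tables.
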