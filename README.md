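# anole-spatgen

Spatial and genetic analysis of territorial lizard populations in enclosed
habitats: home-range geometry from mark–recapture snapshots, microsatellite
kinship and isolation-by-distance, sequential-cohort parentage inference,
and tests of sex-biased dispersal and home-range inheritance — together with
an individual-based park simulator that provides ground truth for every
stage.

## The problem

Green anoles (*Anolis carolinensis*) in an urban park live almost entirely in
the bushes fringing the perimeter fence. Males come in two size morphs split
at a snout–vent length (SVL) of 64 mm: *heavyweights* (≥ 64 mm), which defend
single-bush territories, and *lightweights*, non-territorial "sneaker" males.
Seasonal (spring/fall) mark–recapture samples give each individual a series
of capture bushes; eight hypervariable microsatellite loci give each a
multilocus genotype. From these two data streams the package asks what
structures male spatial distribution — body size, relatedness, or neither —
and whether offspring inherit parental ranges.

## The statistics at its core

* **Home range**: with captures coarsened to bush centroids, an individual's
  home range is its single capture bush, or the convex hull of all its
  capture-bush polygons; areas are log-transformed for analysis.
* **Average distance**: for a focal male in a cohort of *n* males,
  d′ = (d₁ + … + d₍ₙ₋₁₎)/(n − 1), the mean bush-to-bush distance to every
  other male. Distances follow the fence perimeter by default (the open park
  centre is not a dispersal corridor); straight-line distances are available
  by flag.
* **Kinship**: the Loiselle correlation-type estimator,
  k̂ᵢⱼ = Σₗ Σₐ [(pᵢₐ − p̄ₐ)(pⱼₐ − p̄ₐ) + p̄ₐ(1 − p̄ₐ)/(nₗ − 1)] / Σₗ Σₐ p̄ₐ(1 − p̄ₐ),
  with allele dosages pᵢₐ ∈ {0, ½, 1} and nₗ reference gene copies; expected
  ≈ 0.25 for parent–offspring and full sibs, 0.125 for half sibs.
* **IBD**: five-distance-class spatial autocorrelograms of kinship with
  permutation envelopes, plus Mantel tests (999 permutations, +1 corrected).
* **Parentage**: a genotyping-error-aware categorical-allocation likelihood
  (per-allele mistyping rate ε = 0.01, parent-sampled prior 0.5), run under a
  sequential cohort-stacking procedure in triplicate; only links recovered in
  all replicates and passing a likelihood-ratio retention test (p < 0.05)
  enter the consensus pedigree. Pedigree inbreeding coefficients F follow
  from the recursive tabular kinship of each individual's parents.
* **Inheritance**: per parent role, 2×2 inside/outside × offspring-sex tables
  with the Yates-corrected chi-square Σ(|O − E| − 0.5)²/E.

## Worked example

```python
from anole_spatgen.simulate import SimConfig, simulate_population
from anole_spatgen.io import build_individuals, cohort_members
from anole_spatgen.spatial import home_ranges
from anole_spatgen.pedigree import ParentageConfig, sequential_pedigree
from anole_spatgen.analysis import h1_home_range_by_sex, h4_inheritance

res = simulate_population(SimConfig(seed=42))
inds = build_individuals(res.records)
ranges = home_ranges(inds.values(), res.habitat)
h1 = h1_home_range_by_sex(ranges, {i: x.sex for i, x in inds.items()})
seq = sequential_pedigree(cohort_members(res.records), res.truth.sexes,
                          res.genotypes, ParentageConfig(), seeds=[1, 2, 3])
h4 = h4_inheritance(seq.consensus, ranges, inds, res.habitat)
```

prints (via the accompanying formatting, exactly as run):

```
captured 868 individuals in 10 cohorts
home range, males:   15.6 m2 (n=421)
home range, females: 16.0 m2 (n=447)
log-area ~ sex: F=0.01, p=0.918
consensus pedigree: 1441 parent-offspring links
sons inside sire range:      0.0% (n=346)
daughters inside sire range: 27.3% (n=366)
Yates chi-square = 107.73, p = 0.0000
```

Reading the numbers: 868 marked lizards over ten seasonal cohorts; home-range
areas are small and sex-symmetric (most individuals are recaptured in one or
two bushes, so the sex model finds nothing, F ≈ 0). The triplicate-consensus
pedigree links offspring to parents, and the inheritance table shows the
simulated male-biased dispersal exactly: not one son was ever captured inside
his father's range while a quarter of daughters were, and the sire-table
chi-square rejects random space use decisively.

The same pipeline runs from files:

```sh
anole-spatgen simulate --seed 42 --out data/
anole-spatgen run --captures data/capture.csv --genotypes data/genotypes.gen \
    --habitat data/habitat.geojson --seed 1 --out report/
```

Real datasets are supplied as a capture CSV
(`id,year,season,sex,svl_mm,mass_g,bush_id`), a GenePop genotype file and a
GeoJSON habitat map (bush polygons with integer `bush_id`, one fence
LineString).

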