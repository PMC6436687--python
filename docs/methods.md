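# Methods

## Disease model and filtering semantics

The package targets a fully penetrant-to-moderately-penetrant autosomal
dominant disease segregating in a single family.  Genotypes are collapsed
to a dominant-model carrier state (any alternate allele ⇒ carrier);
zygosity is retained only as the dosage matrix for allele-count
bookkeeping.  All variants are keyed by a normalized biallelic
(chrom, pos, ref, alt): multiallelic records are decomposed per alternate
allele, shared suffix/prefix bases are trimmed, and indels are left-aligned
when a reference window is available.  Normalization is idempotent and is
applied to every frequency table on load, so family, control and public
resources join on the same identity.

Every filter is a per-variant predicate, which makes the final candidate
set the intersection of the individual filters and therefore invariant to
application order; only the reported step waterfall depends on the fixed
order (quality → public MAF → local control → segregation → unknown
status).  Count thresholds are uniformly "maximal allowed": a variant
survives when its count is ≤ the threshold.  Control-cohort carriers are
counted as individuals, not alleles, because the relaxation they model is
"an unaffected cohort member may carry the causal variant".

Two deliberate conventions:

* **MAF comparison.**  "MAF > t" is evaluated on the plain alternate-allele
  frequency by default; for the rare variants this pipeline cares about,
  catalogue MAF and alt-AF coincide.  A folded `min(af, 1-af)` switch
  exists for resources that report major alleles.
* **Missing genotypes in affected members** count as non-carriers, so they
  consume phenocopy allowance.  This is the conservative reading of
  "conditioned to exist in all affected individuals"; it is configurable.

The phenocopy × control-carrier relaxation matrix counts, for each (p, c),
variants with ≤ p affected non-carriers and ≤ c control carriers; rows and
columns are cumulative by construction.

## Expected shared fraction

For a member set S with designated reference r, the statistic is the
probability that every member of S carries a specific founder allele,
*conditioned on r carrying it*: `f = 2^-(m-d)`, where m is the number of
meioses in the union of founder→member transmission paths (the Steiner
transmission tree) and d the founder→r path length.  The conditional form
is used because it anchors correctly at 50% for a sibling pair and is the
quantity that predicts shared candidate counts relative to the reference's
own count.  The closed form requires unique transmission paths; pedigrees
with inbreeding loops are rejected and handled by the gene-dropping
Monte-Carlo (`shared_fraction` falls back automatically).  Gene dropping
transmits one founder allele Bernoulli(1/2) per meiosis and supports
children of two carriers.

## Reduction per halving

A sharing curve records, for nested member prefixes, the expected shared
fraction and the count of variants carried by all prefix members.  The
summary statistic is the geometric mean of per-halving survival:
with `h = log2(f_first / f_last)` halvings, the reduction is
`100 × (1 − (N_last / N_first)^(1/h))`.  The geometric mean is chosen
because the quantity of interest is a multiplicative decay rate; an
arithmetic mean across successive segments is available behind
`method="arithmetic"`.  Trailing zero-count points carry no geometric
information and are dropped with a `truncated` flag.

## Synthetic data: what it emulates and what it does not

The generator reproduces the population structure the method exploits:

* **Three AF classes.**  Globally common variants (alt AF U(0.05, 0.5))
  appear in all six emulated public catalogues with ±20% frequency jitter,
  clipped above the 1% threshold; locally common variants (U(0.02, 0.2))
  and rare variants (U(1e-4, 1e-3)) are absent from every public
  catalogue.  Class proportions default to 50,000 / 5,000 / 20,000 —
  illustrative of a catalogue-dominated genome with a substantial local
  excess, not a calibrated genome-wide count.
* **Transmission.**  Founders draw two Bernoulli(AF) haplotypes
  (Hardy–Weinberg); each meiosis transmits one parental haplotype, chosen
  independently per variant (default; sufficient for all count statistics)
  or once per chromosome ("segment" mode, a zero-recombination
  approximation that makes co-founder variants travel as a haplotype
  block, used for clustering demonstrations).
* **Phenotypes.**  Carriers of the planted causal variant become affected
  with probability π (default 0.9 — high but incomplete penetrance, as
  expected for a dominant cancer syndrome); non-carriers with the sporadic
  rate 0.045, a lifetime-risk-scale phenocopy probability for colorectal
  cancer.  The control cohort defaults to n = 300.

Not emulated: linkage disequilibrium within chromosomes (outside segment
mode), recombination maps, coalescent founder genealogies, genotyping
error, and VQSR-style quality structure (the quality filter is exercised
with synthetic FILTER/QUAL columns).  Passing tests therefore demonstrate
the *logic* of the filters and the *scaling* of sharing statistics, not
calling-pipeline robustness on real data.

## Cohort design

Per municipality × gender stratum, numeric survey variables are imputed to
the stratum mean, standardized, and projected onto the top two principal
components (full SVD; signs fixed so each component's largest-magnitude
loading is positive, making scores deterministic).  Selection targets are
a 2-level full factorial with center point (5 points) or the reinforced
design that adds a half-level factorial around each corner plus four
center replicates (25 points).  The design level defaults to 1.5 stratum
score SDs with sub-designs at half that — a spread that keeps corners
inside the observed score cloud for Gaussian-like strata; it is
configurable because the choice is a design convention, not an estimate.
Samples are assigned greedily in point order, nearest Euclidean sample
first, ties broken by sample id.  The quota allocator gives every stratum
a fixed baseline per gender and distributes the remaining budget over
designated high-population strata by largest-remainder apportionment,
keeping genders balanced exactly.

## Candidate reporting

Context classification is pure interval logic with precedence exonic >
intron > upstream > intergenic; upstream means within 5 kb 5' of a
transcript start, strand-aware (5 kb is a conventional annotation-tool
default).  Coordinates are 1-based inclusive throughout; BED12 input is
converted on load.  Clustering is single-linkage on position with a 3 Mb
default gap — the smallest round value that keeps the packaged chr20
candidate block (largest internal gap ≈ 2.59 Mb) in one cluster.  Cluster
spans are reported variant-to-variant; a phased haplotype's physical
extent can only be larger and is not inferred.

The packaged table `famsieve/data/crc1_candidates.tsv` lists the 26
candidates surviving the full analysis of family CRC1 (2 phenocopies, 1
control carrier allowed), with rsID and catalogue-frequency columns as
printed in the original report, including one row carrying an rsID with a
listed European alt-AF of 0.

## Problem sizes and numerical checks

The test suite and the acceptance driver use desk-scale simulations chosen
to keep Monte-Carlo error well inside the asserted tolerances: the
sharing-law experiment uses 20,000 founder-het rare variants on an
8-member chain (six halvings) averaged over 10 replicate seeds, giving a
standard error of ≈ 0.4 percentage points on the ~50% statistic; the
gene-drop cross-checks use 1e5 replicates (binomial/χ² agreement at fixed
seeds); the planted-variant recovery sweep runs 100 seeds on a
~650-variant, 40-control scenario.  PC scores are checked against an
independent eigendecomposition at 1e-8.

## Known limitations

* The closed-form shared fraction rejects multi-path (inbred) pedigrees;
  the Monte-Carlo fallback is unbiased but adds sampling noise.
* `max_carriers` filtering from a frequency table (rather than genotypes)
  approximates carrier counts by allele counts, exact only when all
  carriers are heterozygous — safe for the rare variants the mode targets.
* The unknown-status filter treats missing genotypes in unknown-status
  members as non-carriers (they cannot push a variant over the cap).
* X-linked and recessive/compound-het models, somatic filtering and
  multi-family joint analysis are out of scope.
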