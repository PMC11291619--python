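# Methods

`sdom` infers S-locus genotypes and pollen dominance phenotypes from bulk
flower-bud RNA-seq over a reference panel of S-allele sequences, predicts
self-compatibility of hybrids carrying a non-functional S-haplotype, and
tests the association of those predictions with autonomous seed set. This
note records the models, the defaults and why they were chosen, the
numerical conventions, and what the synthetic-data validation does and does
not establish.

## The biological model

Sporophytic SI in Brassicaceae is controlled by *SRK* (pistil receptor) and
*SCR* (pollen ligand) at the S-locus. Two expression regularities carry all
of the signal the pipeline uses:

* *SRK* alleles are codominantly expressed in pistil tissue, so flower-bud
  RNA-seq depth over *SRK* references reveals which alleles a plant
  carries, with roughly balanced depth between the alleles of a
  heterozygote.
* *SCR* transcription of recessive haplotypes is silenced by small RNAs
  from dominant haplotypes, so the share of *SCR* read depth attributable
  to one allele identifies the phenotypically dominant haplotype — in
  practice one allele carries >99% of *SCR* transcripts in a heterozygote.

A hybrid between a selfing species (non-functional S-haplotype, default
focal allele H4004n) and an outcrossing one is self-compatible exactly when
the non-functional haplotype silences every functional haplotype present.

## Genotyping stage

* **k-mer filter.** Reads sharing no k-mer (either strand) with the
  reference set are dropped before alignment. Defaults k = 20 for *SRK*
  and k = 15 for *SCR*; the smaller *SCR* value accommodates the higher
  divergence of *SCR* alleles. k < 8 is refused: at k = 8 a random 100-mer
  already matches a small reference set with non-negligible probability,
  so the filter would stop filtering.
* **Read assignment.** Each read is aligned locally (soft clipping
  allowed) against every allele on both strands with match +2, mismatch
  −3, gap open −5, gap extend −2 (standard short-read nucleotide scoring;
  configurable). A read is assigned to the top allele when its score
  reaches 80% of the perfect-match score and beats the runner-up by ≥5
  score units; ties and weak hits are discarded rather than fractionally
  split, which is conservative given that cross-mapping between such
  divergent alleles is negligible. A strand-aware prescreen restricts the
  candidate alleles/orientations per read to those sharing a k-mer with
  it; reads matching no k-mer fall back to the full all-vs-all alignment.
  The prescreen is verified in tests to leave depth profiles bit-identical.
* **Depth.** `mean_depth(a)` = reference bases covered by reads assigned
  to `a`, divided by `a`'s reference length — alleles of different lengths
  are therefore comparable.
* **Presence calls.** An allele is present at depth ≥5× absolute *and*
  ≥5% of the strongest allele. The absolute floor suppresses error-driven
  stray assignments near zero; the relative floor suppresses residual
  cross-mapping that scales with signal. Both are exposed. Diploids:
  1 allele ⇒ homozygote, 2 ⇒ heterozygote, more ⇒ flagged unconfident.
  Tetraploids: identities only; copy numbers are reported unknown unless
  four distinct alleles are seen (RNA depth cannot resolve dosage
  reliably, so the pipeline never guesses it).

## Dominance inference

Relative *SCR* expression is computed over the alleles the genotype call
contains (depth on other references is ignored as noise):
`r_a = depth(a) / Σ_b depth(b)`. The arg-max allele is the putative
dominant; shares within 1e−6 of the maximum are flagged co-dominant. Each
individual contributes one "winner beats loser" observation per other
allele present; per pair, the strict-majority direction is kept (e.g. an
11-vs-2 split resolves to the majority), exact ties stay unresolved, and
no class prior ever forces a direction. The resulting digraph is checked
for acyclicity (cycles are reported, never broken silently); when its
transitive closure makes all pairs comparable, the unique topological
order is the linear hierarchy. A consistency report lists any edge where a
lower-class allele dominates a higher-class one; dominance classes are
used only for this report.

An open reading in the statistic's definition: the focal allele's
expression can be expressed as a share of the total (focal included in the
denominator) or as a ratio to the other alleles' sum. Both are computed
(`relative_depth` and `focal_vs_others_ratio`); the share-of-total version
drives the prediction rule because that is the quantity the 0.5 threshold
is defined on.

## Prediction rules and their boundary conventions

* Rule 1 (genotype): SC iff the focal allele is carried and no
  co-occurring allele dominates it. If the hierarchy cannot compare the
  focal allele with some co-occurring allele the call is NA, not SI — the
  rule refuses to guess. The call depends only on the distinct-allele set,
  never on copy numbers, so tetraploids with unknown dosage are handled
  identically.
* Rule 2 (expression): SC iff the focal share is **strictly** greater than
  0.5. A share of exactly 0.5 is SI. A plant not carrying the focal allele
  has share 0 ⇒ SI; a plant with no *SCR* expression at all is NA.
* A secondary descriptive threshold of 0.25 is sometimes useful when
  examining seed-set patterns; it is exposed as a parameter but never used
  in calls.

## Association stage

Seed counts from autonomous selfing are categorized as almost none (<10),
few (10–300, both endpoints inclusive — the interval notation leaves
endpoints implicit, so the convention is documented here) and plenty
(>300); the low cutoff absorbs occasional pollen contamination.

**Fisher's exact test** is implemented by full enumeration of the 2×r
tables with the observed margins, summing the multivariate hypergeometric
probability of every table as probable or less probable than the observed
one (Freeman–Halton criterion, which reduces to the classical two-sided
test for 2×2). Probabilities are compared as exact integers
(`∏ C(col_j, x_j)` against the observed product), so there is no
floating-point tie tolerance; the p-value is returned as an exact rational
converted to float. Enumeration is refused above a configurable total
(default n = 200). Both the full 2×3 test and a collapsed 2×2 (plenty vs
rest) are reported, since either tabulation is defensible.

**Kruskal–Wallis H** (mid-ranks, tie-corrected, chi-square tail with k−1
df) compares the focal allele's relative expression across the populated
seed categories; the all-values-identical degenerate case is defined as
H = 0, p = 1. The implementation delegates to scipy and is checked in the
tests against the hand rank-sum formula.

## Synthetic-data generator

The generator emulates exactly the features the inference relies on:

* **References**: each allele's gene sequence is a common random ancestor
  mutated at 25% of sites (expected pairwise divergence ≈ 44%, floor 25%),
  rejection-resampled until every *SCR* 15-mer and *SRK* 20-mer is
  diagnostic of a single allele on either strand. The divergence default
  is deliberately generous: real S-haplotypes are ancient and highly
  diverged, and the analysis assumes negligible cross-mapping.
* **Expression**: *SRK* shares are near-equal per distinct allele with
  log-normal jitter (sd 0.25 on the log scale — 2-fold imbalance is ~2.8
  sd, matching "approximately balanced"); *SCR* gives the top-ranked
  allele share 1 − ε and splits ε among the silenced alleles by copy
  number, with co-dominant maxima splitting the top share equally.
  ε defaults to 0.01, calibrated to the >99% dominant share observed in
  real heterozygotes; it is the simplest model reproducing that skew.
* **Reads**: single-end, uniform start positions, random strand,
  substitution errors only, fixed quality. Depth ratios — not variant
  calls — are the downstream signal, so fragment-size and quality-model
  realism would add nothing the pipeline consumes. Read count per gene is
  `target_depth × Σ L_a / read_length` over distinct alleles (so an
  equal split gives each allele the target fold-coverage).
* **Seed set**: SC plants draw Poisson(mean 400); SI plants set 0 seeds
  except with probability 0.1, when a uniform count on [1, 300] models
  pollen contamination. The real data constrain only the categories and
  the bimodality, so these distributions are the package's own choice,
  exposed as parameters; the mixture puts <5% mass between 50 and 300,
  reproducing the observed bimodal gap.
* **Panels**: `hybrid_panel` mirrors the study design (27 diploid + 26
  tetraploid hybrids, every hybrid carrying the focal allele, outcrosser
  alleles drawn uniformly from the four present in the cross);
  `pair_coverage_panel` covers all 15 allele pairs for hierarchy
  reconstruction studies.

Two simulation depths are provided. The FASTQ path exercises the full
filter → align → call chain and is used where the measurement itself is
the object (dominant-share and genotype-recovery checks, at 50 individuals
and 200 individuals respectively). The depth-level path converts the same
multinomial read allocation directly into depth profiles and is used for
replicated panel-scale Monte-Carlo (100 hierarchy-recovery panels, 200-
hybrid congruence, 500-replicate null calibration); read allocation is the
dominant stochastic term at these depths, and the full-path tests confirm
the alignment stage adds essentially no further noise at 0.2% error.

**What passing tests do not show.** The generator draws reads from the
reference sequences themselves, so it cannot probe reference/sample
sequence mismatch, unknown alleles absent from the database, paralogous
S-locus-unlinked genes, expression leakage between tissues, indel or
quality-structured errors, or library-preparation biases. Results on real
data depend on those factors; the tests establish correctness of the
inference chain under its own stated assumptions, not robustness beyond
them.

## Numerical and degenerate-case conventions

* Same seed ⇒ byte-identical outputs end to end; every stochastic unit
  (individual × gene × purpose) gets an independent counter-based
  substream, so per-individual results do not depend on panel order.
* Expression shares sum to 1 up to float rounding; the co-dominance
  tolerance is 1e−6 on shares.
* Zero total *SCR* depth yields a `no_expression` status (rule 2 NA), not
  an exception; an all-zero *SRK* profile yields an explicit no-call.
* The exact-test enumeration compares integer weights, so ties in table
  probability are included deterministically.

## Null calibration: a known, expected deviation

Under prediction-independent seed counts the Fisher p-values are valid but
conservative: with 53 individuals and discrete 2×3 tables, the exact
conditional p-value has an atom at 1 (the observed table is the
conditional mode in ~12% of null replicates) and P(p ≤ α) ≤ α throughout.
A two-sided Kolmogorov–Smirnov test against the uniform distribution over
500 replicates therefore rejects (D ≈ 0.13, driven almost entirely by the
p = 1 atom) — as it must for *any* exact discrete test at this sample
size. The test suite asserts the attainable form of calibration (the
type-I error rate at nominal 0.05 is not inflated) and retains the strict
KS uniformity check as a documented, expected failure rather than
weakening it.

## Known limitations

* No de novo assembly: only alleles present in the reference database can
  be genotyped or quantified.
* Best-hit assignment cannot separate a true allele from an unmodeled
  close paralog; paralog discrimination is out of scope.
* Tetraploid dosage is never inferred from RNA depth.
* The enumeration-based Fisher test is exact but bounded (default
  n ≤ 200); larger panels need a different testing strategy.
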