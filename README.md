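# sdom

**S-locus genotyping, SCR dominance inference and mating-system prediction
from short-read RNA-seq data.**

In Brassicaceae, sporophytic self-incompatibility (SI) is controlled by two
tightly linked genes at the S-locus: *SRK* (the stigma receptor) and *SCR*
(the pollen-coat ligand). S-haplotypes are highly divergent and form a
linear dominance hierarchy in pollen: small non-coding RNAs encoded by
dominant haplotypes transcriptionally silence the *SCR* gene of recessive
ones, so a heterozygote usually expresses essentially a single *SCR*
allele. This has a striking consequence for hybrids and neo-allopolyploids
between a self-compatible (SC) species carrying a *non-functional*
S-haplotype and a self-incompatible relative: whenever the non-functional
haplotype is dominant over every functional haplotype the plant carries, no
functional SCR is presented and the plant is instantly self-compatible.

`sdom` implements the full inference chain needed to test this from bulk
flower-bud RNA-seq, for *Capsella orientalis* × *C. grandiflora*-style
crosses (the default allele panel is H4035, H4015, H4004n, H2022, H2008,
H1001, with H4004n the non-functional focal allele):

1. **Genotyping** (`sdom.genotyping`) — reads are screened against a
   dictionary of reference k-mers (k = 20 for *SRK*, k = 15 for the more
   divergent *SCR*), locally aligned against every allele sequence on both
   strands, and assigned to the best-scoring allele (weak and ambiguous
   hits are discarded). Alleles are called present from length-normalized
   mean read depth (absolute floor 5×, relative floor 5% of the strongest
   allele). Diploids get full copy numbers; tetraploids get allele
   identities with copy numbers reported unknown.
2. **Expression & dominance** (`sdom.expression`) — each allele's relative
   *SCR* expression is its share of the summed mean depth over the alleles
   the plant carries, `r_a = depth(a) / Σ_b depth(b)`. Per individual the
   arg-max allele "beats" every other allele present; pairwise majority
   directions across a panel are assembled into a directed dominance graph
   and, when acyclic and total, a linear hierarchy.
3. **Phenotype prediction** (`sdom.prediction`) — rule 1: SC iff the plant
   carries the focal non-functional allele and nothing above it in the
   hierarchy; rule 2: SC iff the focal allele's *SCR* share exceeds 0.5
   (strict). The two rules are cross-tabulated for congruence.
4. **Association** (`sdom.stats`) — autonomous-selfing seed counts are
   categorized (<10, 10–300, >300 seeds); predicted phenotype vs category
   is tested with an exact Fisher test (full enumeration, Freeman–Halton
   criterion, so 2×3 tables need no chi-square approximation), and the
   focal allele's expression across categories with Kruskal–Wallis H.
5. **Synthetic data** (`sdom.simulate`) — a generator producing divergent
   allele databases (every *SCR* 15-mer and *SRK* 20-mer diagnostic of one
   allele), genotypes, allele-specific reads (balanced *SRK*; *SCR*
   dominated by the top allele, share 1 − ε with ε = 0.01 by default) and
   bimodal seed counts, with a ground-truth ledger for validating every
   stage.

## Worked example

```python
from sdom import (make_allele_db, default_scenario, run_simulated_pipeline)

db = make_allele_db(seed=3)                 # six divergent S-alleles
scenario = default_scenario(seed=3)         # 27 diploid + 26 tetraploid hybrids
result = run_simulated_pipeline(scenario, db=db, read_level=True)

print(result.congruence.agreement)
print(result.association.table)
print(round(result.association.fisher_p_2x3, 20))
kw = result.association.kruskal
print(round(kw.H_statistic, 2), kw.p_value)
```

Output from this exact run:

```
1.0
    almost_none  few  plenty
SC            0    0      18
SI           34    1       0
1.547567e-14
35.29 2.1731123070179685e-08
```

Reading it: the genotype-based and expression-based SC/SI predictions agree
on all 53 hybrids (`agreement = 1.0`); all 18 predicted-SC plants set
plenty of seed (>300) while the 35 predicted-SI plants set almost none
(one SI plant shows a low contamination-range count), giving an exact
Fisher p of ~1.5e-14; and the focal allele's relative *SCR* expression
differs strongly across seed categories (H = 35.3, p ≈ 2e-8).

The same pipeline is available from the shell:

```bash
sdom simulate --out sim/ --seed 42          # FASTAs + FASTQs + sample sheet
sdom type --srk-db sim/srk.fasta --scr-db sim/scr.fasta --gene SRK \
     --reads sim/F-01_SRK.fastq --ploidy 2 --out profile.tsv
sdom run --config run.yaml --out-dir results/
```

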