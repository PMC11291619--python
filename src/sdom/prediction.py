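"""SC/SI phenotype prediction for hybrids carrying a non-functional S-allele.

A hybrid between a self-compatible species (contributing a non-functional
S-haplotype, here H4004n by default) and a self-incompatible one is predicted
self-compatible exactly when the non-functional haplotype dominates every
functional haplotype it co-occurs with, so that no functional SCR ligand is
presented on pollen.  Two independent rules implement this:

* **rule 1 (genotype-based)** — SC iff the individual carries the focal
  non-functional allele and none of the co-occurring alleles sits above it
  in the dominance hierarchy.
* **rule 2 (expression-based)** — SC iff the focal allele's share of total
  SCR read depth exceeds a threshold (default 0.5, strict).

The module also provides the congruence summary between the two rules and
the qualitative lookup of the expected instantaneous effect of polyploidy on
self-compatibility for the three main SI system / polyploidy combinations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .expression import DominanceGraph, ExpressionProfile
from .genotyping import GenotypeCall

DEFAULT_FOCAL = "H4004n"
DEFAULT_RULE2_THRESHOLD = 0.5

SC, SI, NA = "SC", "SI", "NA"


@dataclass
class PredictionRecord:
    """Per-individual SC/SI calls under both rules."""

    individual: str
    rule1_call: str
    rule2_call: str
    focal_allele: str = DEFAULT_FOCAL
    rule2_statistic: float = float("nan")
    congruent: bool | None = None
    rule1_reason: str = ""

    def __post_init__(self) -> None:
        if self.rule1_call in (SC, SI) and self.rule2_call in (SC, SI):
            self.congruent = self.rule1_call == self.rule2_call
        else:
            self.congruent = None


def predict_rule1(
    genotype: GenotypeCall,
    hierarchy: DominanceGraph,
    focal: str = DEFAULT_FOCAL,
) -> tuple[str, str]:
    """Genotype-based SC/SI call; returns ``(call, reason)``.

    SC iff the focal allele is present and no co-occurring allele dominates
    it.  NA when the hierarchy cannot compare the focal allele with some
    co-occurring allele (the call would be a guess).  Copy numbers are
    irrelevant: the rule is a pure function of the distinct-allele set.
    """
    present = set(genotype.alleles_present)
    if not present:
        return NA, "no alleles called"
    if focal not in hierarchy.graph:
        return NA, f"focal allele {focal} absent from hierarchy"
    if focal not in present:
        return SI, "focal allele not carried"
    for other in sorted(present - {focal}):
        if not hierarchy.comparable(focal, other):
            return NA, f"hierarchy does not resolve {focal} vs {other}"
    dominated_by = [o for o in present - {focal} if hierarchy.dominates(o, focal)]
    if dominated_by:
        return SI, f"dominated by {','.join(sorted(dominated_by))}"
    return SC, "focal allele dominant"


def predict_rule2(
    expr: ExpressionProfile,
    focal: str = DEFAULT_FOCAL,
    threshold: float = DEFAULT_RULE2_THRESHOLD,
) -> tuple[str, float]:
    """Expression-based SC/SI call; returns ``(call, focal share)``.

    SC iff the focal allele's share of total SCR depth over the alleles
    present is strictly greater than ``threshold``.  An individual not
    carrying the focal allele has share 0 and is SI.  NA when no SCR
    expression was observed at all.
    """
    if expr.status == "no_expression":
        return NA, float("nan")
    share = expr.relative_depth.get(focal, 0.0)
    return (SC if share > threshold else SI), share


def predict_panel(
    panel: Sequence[tuple[GenotypeCall, ExpressionProfile]],
    hierarchy: DominanceGraph,
    focal: str = DEFAULT_FOCAL,
    threshold: float = DEFAULT_RULE2_THRESHOLD,
) -> list[PredictionRecord]:
    """Apply both rules to every individual of a panel."""
    records = []
    for genotype, expr in panel:
        r1, reason = predict_rule1(genotype, hierarchy, focal)
        r2, stat = predict_rule2(expr, focal, threshold)
        records.append(
            PredictionRecord(
                individual=genotype.individual,
                rule1_call=r1,
                rule2_call=r2,
                focal_allele=focal,
                rule2_statistic=stat,
                rule1_reason=reason,
            )
        )
    return records


@dataclass
class CongruenceResult:
    """2x2 cross-tabulation of rule-1 vs rule-2 calls."""

    counts: dict[tuple[str, str], int]
    agreement: float | None
    n_used: int
    n_excluded: int


def congruence_table(records: Iterable[PredictionRecord]) -> CongruenceResult:
    """Cross-tabulate the two rules over records where both calls are made.

    Records with an NA call are excluded from the table and counted
    separately; agreement is the fraction of concordant (SC,SC)+(SI,SI)
    records, or ``None`` when no record is usable.
    """
    counts = {(a, b): 0 for a in (SC, SI) for b in (SC, SI)}
    n_excluded = 0
    for rec in records:
        if rec.rule1_call in (SC, SI) and rec.rule2_call in (SC, SI):
            counts[(rec.rule1_call, rec.rule2_call)] += 1
        else:
            n_excluded += 1
    n_used = sum(counts.values())
    agreement = (
        (counts[(SC, SC)] + counts[(SI, SI)]) / n_used if n_used else None
    )
    return CongruenceResult(counts, agreement, n_used, n_excluded)


SI_SYSTEMS = ("gametophytic_nonself", "gametophytic_self", "sporophytic")
POLYPLOIDY_TYPES = ("auto", "allo_SIxSI", "allo_SCxSI")

#: Expected instantaneous effect of polyploidy on self-compatibility.
#: Gametophytic SI with non-self-recognition breaks down mechanically in
#: heteroallelic diploid pollen; self-recognition gametophytic and
#: sporophytic systems stay SI under autopolyploidy and SI x SI
#: allopolyploidy; with one SC parent the outcome depends on the SC mutation
#: (gametophytic) or on the relative dominance of the SI and SC alleles
#: (sporophytic).
_NEOPOLYPLOID_TABLE = {
    ("gametophytic_nonself", "auto"): "SC",
    ("gametophytic_nonself", "allo_SIxSI"): "SC",
    ("gametophytic_nonself", "allo_SCxSI"): "depends",
    ("gametophytic_self", "auto"): "SI",
    ("gametophytic_self", "allo_SIxSI"): "SI",
    ("gametophytic_self", "allo_SCxSI"): "depends",
    ("sporophytic", "auto"): "SI",
    ("sporophytic", "allo_SIxSI"): "SI",
    ("sporophytic", "allo_SCxSI"): "depends",
}


def expected_neopolyploid_phenotype(si_system: str, polyploidy: str) -> str:
    """Qualitative SC/SI/depends expectation for a neopolyploid."""
    if si_system not in SI_SYSTEMS:
        raise ValueError(f"unknown SI system {si_system!r}; expected {SI_SYSTEMS}")
    if polyploidy not in POLYPLOIDY_TYPES:
        raise ValueError(
            f"unknown polyploidy type {polyploidy!r}; expected {POLYPLOIDY_TYPES}"
        )
    return _NEOPOLYPLOID_TABLE[(si_system, polyploidy)]
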