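"""Synthetic S-locus data with the statistical structure the pipeline assumes.

The generator emulates the features of flower-bud RNA-seq data over a small
panel of S-alleles that the downstream inference relies on:

* **divergent allele references** — allele sequences are produced by mutating
  a common random ancestor far enough (default 25% per-site divergence per
  allele) that every 15-mer of every SCR sequence, and every 20-mer of every
  SRK sequence, is diagnostic of a single allele; candidate databases are
  rejection-resampled until this holds exactly.
* **codominant SRK expression** — in a heterozygote both SRK alleles are
  expressed at near-equal levels (log-normal jitter around equality).
* **dominant SCR silencing** — small-RNA silencing by the most dominant
  S-haplotype present leaves only a residual fraction ``silencing_epsilon``
  of SCR transcripts to the silenced alleles, so the dominant allele
  contributes a share ``1 - epsilon`` (over 99% at the default 0.01).
  Co-dominant maxima (no order between them) split the top share equally.
* **bimodal autonomous seed set** — self-compatible individuals draw seed
  counts from a high-mean Poisson; self-incompatible individuals set no seed
  except for rare low counts from pollen contamination.

Every simulated individual is recorded in a :class:`TruthLedger` so each
downstream stage can be scored against its generating truth.
"""

from __future__ import annotations

import zlib
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alleles import Allele, AlleleDB, revcomp
from .genotyping import DEFAULT_K, DepthProfile
from .io import Read

#: The six-allele study panel: five C. grandiflora alleles spanning dominance
#: classes I, II and IV, plus the non-functional C. orientalis allele H4004n.
DEFAULT_ALLELE_NAMES = ("H4035", "H4015", "H4004n", "H2022", "H2008", "H1001")

#: Generating dominance order, most dominant first.  H4004n sits between the
#: two functional class-IV alleles and the class-II alleles.
DEFAULT_HIERARCHY = ("H4035", "H4015", "H4004n", "H2022", "H2008", "H1001")

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class Individual:
    """One simulated plant: an identifier, ploidy and S-locus genotype.

    ``genotype`` is a multiset of allele names of size equal to the ploidy.
    """

    id: str
    ploidy: int
    genotype: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.ploidy not in (2, 4):
            raise ValueError(f"{self.id}: ploidy must be 2 or 4")
        if len(self.genotype) != self.ploidy:
            raise ValueError(
                f"{self.id}: genotype size {len(self.genotype)} != ploidy {self.ploidy}"
            )


@dataclass(frozen=True)
class SimScenario:
    """Parameters of one simulation run.

    ``hierarchy`` is a linear dominance order (most dominant first); entries
    may be tuples of names to express co-dominant ties.  ``silencing_epsilon``
    is the residual SCR expression share left to silenced alleles;
    ``srk_imbalance_sd`` the log-scale jitter of SRK allelic shares;
    ``target_depth`` the mean fold-coverage per expressed allele.
    """

    individuals: tuple[Individual, ...] = ()
    hierarchy: tuple = DEFAULT_HIERARCHY
    silencing_epsilon: float = 0.01
    srk_imbalance_sd: float = 0.25
    read_length: int = 100
    target_depth: float = 50.0
    error_rate: float = 0.002
    seed: int = 0
    sc_seed_mean: float = 400.0
    si_contamination_prob: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 <= self.silencing_epsilon < 0.5):
            raise ValueError("silencing_epsilon must be in [0, 0.5)")
        if self.srk_imbalance_sd < 0:
            raise ValueError("srk_imbalance_sd must be nonnegative")


def rank_map(hierarchy: Sequence) -> dict[str, int]:
    """Map allele name -> dominance rank (larger = more dominant).

    ``hierarchy`` lists alleles from most to least dominant; an entry may be
    a tuple/set of names sharing a rank (co-dominant tie).
    """
    ranks: dict[str, int] = {}
    n = len(hierarchy)
    for i, entry in enumerate(hierarchy):
        rank = n - i
        if isinstance(entry, str):
            ranks[entry] = rank
        else:
            for name in entry:
                ranks[name] = rank
    return ranks


def _sub_rng(seed: int, *labels) -> np.random.Generator:
    """Independent, reproducible stream for one (individual, gene, ...) unit."""
    tag = zlib.crc32(":".join(str(x) for x in labels).encode())
    return np.random.default_rng([seed & 0x7FFFFFFF, tag])


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(rng: np.random.Generator, ancestor: np.ndarray, rate: float) -> str:
    seq = ancestor.copy()
    sites = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in sites:
        choices = _BASES[_BASES != seq[i]]
        seq[i] = rng.choice(choices)
    return seq.tobytes().decode()


def _colliding_pairs(seqs: Mapping[str, str], k: int) -> list[tuple[str, str]]:
    from .alleles import canonical_kmers

    sets = {n: canonical_kmers(s, k) for n, s in seqs.items()}
    names = list(seqs)
    bad = []
    for i, ni in enumerate(names):
        for nj in names[i + 1 :]:
            if sets[ni] & sets[nj]:
                bad.append((ni, nj))
    return bad


def make_allele_db(
    names: Sequence[str] = DEFAULT_ALLELE_NAMES,
    seq_length: int = 400,
    seed: int = 0,
    divergence: float = 0.25,
    max_rounds: int = 50,
) -> AlleleDB:
    """Generate a reference database of divergent SRK/SCR allele sequences.

    Each allele's gene sequence is the random ancestral sequence mutated at a
    fraction ``divergence`` of sites (expected pairwise difference roughly
    ``2*divergence*(1 - divergence) + divergence**2`` under the 3-state
    substitution model, well above the per-allele rate).  Candidate databases
    are resampled until every SCR 15-mer and every SRK 20-mer (either strand)
    occurs in exactly one allele; generation is deterministic given ``seed``.

    Raises ``RuntimeError`` naming the offending allele pair if the
    diagnostic-k-mer property cannot be achieved in ``max_rounds`` rounds.
    """
    if seq_length < 300:
        raise ValueError("seq_length must be at least 300")
    if len(set(names)) != len(names):
        raise ValueError("allele names must be unique")
    rng = _sub_rng(seed, "make_allele_db", seq_length, divergence)
    gene_seqs: dict[str, dict[str, str]] = {}
    for gene in ("SRK", "SCR"):
        ancestor = _random_seq(rng, seq_length)
        seqs = {name: _mutate(rng, ancestor, divergence) for name in names}
        k = DEFAULT_K[gene]
        last_bad: tuple[str, str] | None = None
        for _ in range(max_rounds):
            bad = _colliding_pairs(seqs, k)
            if not bad:
                break
            last_bad = bad[0]
            # resample one member of the first colliding pair
            seqs[bad[0][0]] = _mutate(rng, ancestor, divergence)
        else:
            raise RuntimeError(
                f"could not make {gene} {k}-mers diagnostic after "
                f"{max_rounds} rounds; offending pair {last_bad}"
            )
        gene_seqs[gene] = dict(seqs)
    return AlleleDB(
        [
            Allele.from_name(n, gene_seqs["SRK"][n], gene_seqs["SCR"][n])
            for n in names
        ]
    )


def true_scr_proportions(
    genotype: Sequence[str],
    hierarchy: Sequence | Mapping[str, int],
    silencing_epsilon: float = 0.01,
) -> dict[str, float]:
    """Expected share of SCR transcripts contributed by each allele.

    The unique most-dominant allele present receives share ``1 - epsilon``;
    the remaining ``epsilon`` is split among the other distinct alleles in
    proportion to copy number.  Two (or more) co-dominant maxima split the
    top share equally.  A genotype with a single distinct allele expresses it
    fully.  Shares sum to 1 exactly.
    """
    if not genotype:
        raise ValueError("empty genotype")
    if not (0.0 <= silencing_epsilon < 0.5):
        raise ValueError("silencing_epsilon must be in [0, 0.5)")
    ranks = dict(hierarchy) if isinstance(hierarchy, Mapping) else rank_map(hierarchy)
    counts = Counter(genotype)
    missing = [a for a in counts if a not in ranks]
    if missing:
        raise ValueError(f"alleles not in hierarchy: {missing}")
    distinct = list(counts)
    if len(distinct) == 1:
        return {distinct[0]: 1.0}
    top = max(ranks[a] for a in distinct)
    maxima = [a for a in distinct if ranks[a] == top]
    others = [a for a in distinct if ranks[a] < top]
    props: dict[str, float] = {}
    top_share = (1.0 - silencing_epsilon) if others else 1.0
    for m in maxima:
        props[m] = top_share / len(maxima)
    if others:
        total_copies = sum(counts[o] for o in others)
        for o in others:
            props[o] = silencing_epsilon * counts[o] / total_copies
    return props


def _expression_proportions(
    individual: Individual,
    scenario: SimScenario,
    gene: str,
    mode: str,
    rng: np.random.Generator,
) -> dict[str, float]:
    counts = Counter(individual.genotype)
    if mode == "dna":
        total = sum(counts.values())
        return {a: c / total for a, c in counts.items()}
    if mode != "rna":
        raise ValueError(f"unknown simulation mode {mode!r}")
    if gene == "SCR":
        return true_scr_proportions(
            individual.genotype, scenario.hierarchy, scenario.silencing_epsilon
        )
    # SRK: near-equal expression per distinct allele with log-normal jitter
    names = list(counts)
    weights = np.exp(rng.normal(0.0, scenario.srk_imbalance_sd, size=len(names)))
    weights /= weights.sum()
    return dict(zip(names, weights.tolist()))


def _read_counts(
    individual: Individual,
    db: AlleleDB,
    scenario: SimScenario,
    gene: str,
    props: dict[str, float],
    rng: np.random.Generator,
) -> dict[str, int]:
    names = list(props)
    lengths = [db.gene_length(a, gene) for a in names]
    if scenario.target_depth <= 0:
        raise ValueError("target_depth must be positive")
    if scenario.read_length > min(lengths):
        raise ValueError(
            f"read_length {scenario.read_length} exceeds shortest {gene} "
            f"sequence among genotype alleles"
        )
    n_total = int(round(scenario.target_depth * sum(lengths) / scenario.read_length))
    p = np.array([props[a] for a in names])
    counts = rng.multinomial(n_total, p / p.sum())
    return dict(zip(names, counts.tolist()))


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    sites = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in sites:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_reads(
    individual: Individual,
    db: AlleleDB,
    scenario: SimScenario,
    gene: str,
    mode: str = "rna",
) -> tuple[list[Read], dict[str, int]]:
    """Simulate single-end reads for one individual and one gene.

    Reads are uniform-start substrings of the expressed alleles' gene
    sequences on a random strand, with per-base substitution errors at
    ``scenario.error_rate``.  Read counts per allele are multinomial with
    proportions given by the expression model (``mode="rna"``) or by copy
    number (``mode="dna"``, genomic-like coverage).  Read names carry no
    truth.  Deterministic given the scenario seed.

    Returns ``(reads, true_read_counts_per_allele)``.
    """
    for a in individual.genotype:
        if a not in db:
            raise KeyError(f"{individual.id}: genotype allele {a!r} not in database")
    rng = _sub_rng(scenario.seed, "reads", individual.id, gene, mode)
    props = _expression_proportions(individual, scenario, gene, mode, rng)
    counts = _read_counts(individual, db, scenario, gene, props, rng)
    rl = scenario.read_length
    reads: list[Read] = []
    for allele_name in sorted(counts):
        n = counts[allele_name]
        if n == 0:
            continue
        ref = db.get(allele_name).gene_seq(gene)
        starts = rng.integers(0, len(ref) - rl + 1, size=n)
        strands = rng.random(n) < 0.5
        for start, minus in zip(starts.tolist(), strands.tolist()):
            frag = ref[start : start + rl]
            if minus:
                frag = revcomp(frag)
            reads.append(Read("", _apply_errors(rng, frag, scenario.error_rate)))
    order = rng.permutation(len(reads))
    shuffled = [
        Read(f"{individual.id}|{gene}|{i:06d}", reads[j].seq)
        for i, j in enumerate(order.tolist())
    ]
    return shuffled, counts


def simulate_depth_profile(
    individual: Individual,
    db: AlleleDB,
    scenario: SimScenario,
    gene: str,
    mode: str = "rna",
) -> DepthProfile:
    """Idealized depth profile: multinomial read counts converted directly to
    mean depths, bypassing read synthesis and alignment.

    Captures the sampling noise of read allocation (the dominant stochastic
    term at the depths simulated) while running orders of magnitude faster
    than the full FASTQ path; used for panel-scale Monte-Carlo studies.
    """
    rng = _sub_rng(scenario.seed, "depths", individual.id, gene, mode)
    props = _expression_proportions(individual, scenario, gene, mode, rng)
    counts = _read_counts(individual, db, scenario, gene, props, rng)
    mean_depth = {a.name: 0.0 for a in db}
    total = 0
    for name, n in counts.items():
        mean_depth[name] = n * scenario.read_length / db.gene_length(name, gene)
        total += n
    return DepthProfile(
        individual=individual.id,
        gene=gene,
        mean_depth=mean_depth,
        n_reads_assigned=total,
    )


def true_dominant_alleles(
    genotype: Sequence[str], hierarchy: Sequence | Mapping[str, int]
) -> tuple[str, ...]:
    """Most-dominant distinct allele(s) of a genotype under the hierarchy."""
    ranks = dict(hierarchy) if isinstance(hierarchy, Mapping) else rank_map(hierarchy)
    distinct = set(genotype)
    top = max(ranks[a] for a in distinct)
    return tuple(sorted(a for a in distinct if ranks[a] == top))


def true_phenotype(
    genotype: Sequence[str], hierarchy: Sequence | Mapping[str, int]
) -> str:
    """SC/SI phenotype implied by the generating dominance order.

    The pollen phenotype is set by the expressed (dominant) SCR allele(s):
    the individual is self-compatible only when every dominant allele is
    non-functional (name ending in ``n``), so no functional SCR is presented.
    """
    dominant = true_dominant_alleles(genotype, hierarchy)
    return "SC" if all(a.endswith("n") for a in dominant) else "SI"


def simulate_seed_set(
    phenotype: str, scenario: SimScenario, rng: np.random.Generator
) -> int:
    """Autonomous-selfing seed count for one individual.

    SC individuals draw from Poisson(``sc_seed_mean``); SI individuals set 0
    seeds except with probability ``si_contamination_prob``, in which case a
    small count uniform on [1, 300] models pollen contamination.
    """
    if phenotype == "SC":
        return int(rng.poisson(scenario.sc_seed_mean))
    if phenotype == "SI":
        if rng.random() < scenario.si_contamination_prob:
            return int(rng.integers(1, 301))
        return 0
    raise ValueError(f"unknown phenotype {phenotype!r}")


@dataclass
class TruthEntry:
    individual: str
    ploidy: int
    genotype: tuple[str, ...]
    dominant_scr: tuple[str, ...]
    scr_proportions: dict[str, float]
    phenotype: str
    seed_count: int


@dataclass
class TruthLedger:
    """Ground truth for every simulated individual, one entry per plant."""

    entries: list[TruthEntry] = field(default_factory=list)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, individual: str) -> TruthEntry:
        for e in self.entries:
            if e.individual == individual:
                return e
        raise KeyError(individual)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            rows.append(
                {
                    "individual": e.individual,
                    "ploidy": e.ploidy,
                    "genotype": ";".join(e.genotype),
                    "dominant_scr": ";".join(e.dominant_scr),
                    "phenotype": e.phenotype,
                    "seed_count": e.seed_count,
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        from .io import write_tsv

        write_tsv(self.to_dataframe(), path)


def build_truth(scenario: SimScenario) -> TruthLedger:
    """Per-individual ground truth (dominance, phenotype, seed counts)."""
    ledger = TruthLedger()
    for ind in scenario.individuals:
        props = true_scr_proportions(
            ind.genotype, scenario.hierarchy, scenario.silencing_epsilon
        )
        pheno = true_phenotype(ind.genotype, scenario.hierarchy)
        rng = _sub_rng(scenario.seed, "seeds", ind.id)
        seeds = simulate_seed_set(pheno, scenario, rng)
        ledger.entries.append(
            TruthEntry(
                individual=ind.id,
                ploidy=ind.ploidy,
                genotype=tuple(ind.genotype),
                dominant_scr=true_dominant_alleles(ind.genotype, scenario.hierarchy),
                scr_proportions=props,
                phenotype=pheno,
                seed_count=seeds,
            )
        )
    return ledger


# ---------------------------------------------------------------------------
# panel builders


def hybrid_panel(
    seed: int = 0,
    n_diploid: int = 27,
    n_tetraploid: int = 26,
    focal: str = "H4004n",
    cg_alleles: Sequence[str] = ("H4035", "H4015", "H2022", "H2008"),
) -> tuple[Individual, ...]:
    """Hybrid panel mimicking the study's crossing design.

    Every hybrid inherits the non-functional ``focal`` allele from the
    selfing parent; diploids carry one outcrosser allele, tetraploids two
    focal copies plus two outcrosser alleles (drawn with replacement).
    Default sizes mirror the 27 diploid + 26 tetraploid panel.
    """
    rng = _sub_rng(seed, "hybrid_panel", n_diploid, n_tetraploid)
    individuals = []
    for i in range(n_diploid):
        other = rng.choice(list(cg_alleles))
        individuals.append(Individual(f"F-{i + 1:02d}", 2, (focal, str(other))))
    for i in range(n_tetraploid):
        others = rng.choice(list(cg_alleles), size=2, replace=True)
        individuals.append(
            Individual(
                f"S-{i + 1:02d}", 4, (focal, focal, str(others[0]), str(others[1]))
            )
        )
    return tuple(individuals)


def pair_coverage_panel(
    allele_names: Sequence[str] = DEFAULT_ALLELE_NAMES, per_pair: int = 3
) -> tuple[Individual, ...]:
    """Diploid heterozygotes covering every unordered allele pair
    ``per_pair`` times (for dominance-hierarchy reconstruction studies)."""
    individuals = []
    names = list(allele_names)
    idx = 0
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            for _ in range(per_pair):
                idx += 1
                individuals.append(Individual(f"P-{idx:03d}", 2, (a, b)))
    return tuple(individuals)
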