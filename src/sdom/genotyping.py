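"""S-locus genotype calling from short reads.

The genotyping stage mirrors the read-depth profiling strategy used for
S-allele typing from RNA-seq or genomic reads against a database of highly
divergent allele sequences:

1. **k-mer filtering** — raw reads are screened against a dictionary of all
   k-mers (both strands) from the reference alleles; only reads sharing at
   least one k-mer with the database are kept.  Because SCR alleles are more
   divergent than SRK alleles, a smaller k is used for SCR (default 15) than
   for SRK (default 20).
2. **per-allele local alignment** — each surviving read is aligned locally
   (soft clipping allowed) against every allele sequence on both strands and
   assigned to the best-scoring allele, provided the score clears a minimum
   and beats the runner-up by a margin; ambiguous reads are discarded.
3. **depth summary** — the mean read depth of each allele is the total number
   of reference bases covered by its assigned reads divided by the allele
   sequence length, so alleles of different lengths are comparable.
4. **genotype calling** — alleles whose mean depth clears an absolute floor
   and a floor relative to the strongest allele are called present.  Diploids
   with one or two alleles get full copy numbers; for tetraploids only allele
   identity is called and copy numbers are reported unknown unless four
   distinct alleles are seen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from Bio import Align

from .alleles import AlleleDB, kmers, revcomp
from .io import Read

DEFAULT_K = {"SRK": 20, "SCR": 15}
MIN_K = 8  # below this, random reads start passing the filter


@dataclass(frozen=True)
class AlignmentScoring:
    """Local-alignment scoring used for read assignment."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = self.match
        aligner.mismatch_score = self.mismatch
        aligner.open_gap_score = self.gap_open
        aligner.extend_gap_score = self.gap_extend
        return aligner


@dataclass
class KmerIndex:
    """Exact-match dictionary of reference k-mers (both strands).

    ``kmer_to_alleles`` maps each k-mer to the allele names containing it on
    either strand; ``kmer_to_hits`` additionally records the strand ("+" for
    the forward reference sequence, "-" for its reverse complement), which
    lets the read-assignment stage align each read in the right orientation
    only.
    """

    k: int
    gene: str
    kmer_to_alleles: dict[str, frozenset[str]]
    kmer_to_hits: dict[str, frozenset[tuple[str, str]]] | None = None

    def lookup(self, kmer: str) -> frozenset[str]:
        return self.kmer_to_alleles.get(kmer, frozenset())

    def lookup_hits(self, kmer: str) -> frozenset[tuple[str, str]]:
        if self.kmer_to_hits is None:
            return frozenset()
        return self.kmer_to_hits.get(kmer, frozenset())

    def __len__(self) -> int:
        return len(self.kmer_to_alleles)


@dataclass
class DepthProfile:
    """Per-allele mean read depth for one individual and one gene."""

    individual: str
    gene: str
    mean_depth: dict[str, float]
    n_reads_assigned: int = 0
    n_reads_unassigned: int = 0
    n_reads_filtered_out: int = 0

    def total_depth(self) -> float:
        return sum(self.mean_depth.values())


#: Sentinel used in copy-number maps when only allele identity is known.
UNKNOWN = None


@dataclass
class GenotypeCall:
    """Alleles (and, where determinable, copy numbers) of one individual.

    ``copy_numbers`` maps each present allele to an integer copy number or to
    ``None`` (UNKNOWN) when only the identity could be established, as is the
    case for tetraploids with fewer than four distinct alleles.
    """

    individual: str
    ploidy: int
    alleles_present: frozenset[str]
    copy_numbers: dict[str, int | None] = field(default_factory=dict)
    confident: bool = True
    status: str = "ok"

    @property
    def distinct_alleles(self) -> frozenset[str]:
        return self.alleles_present


def build_kmer_index(db: AlleleDB, gene: str, k: int | None = None) -> KmerIndex:
    """Index every k-mer of every allele's gene sequence and its reverse
    complement.

    Raises ``ValueError`` when ``k`` is below :data:`MIN_K` (the filter would
    pass essentially random reads) or exceeds the shortest reference.
    """
    if k is None:
        k = DEFAULT_K[gene]
    if k < MIN_K:
        raise ValueError(f"k={k} is too small to be selective (minimum {MIN_K})")
    shortest = min(len(a.gene_seq(gene)) for a in db)
    if k > shortest:
        raise ValueError(
            f"k={k} exceeds the shortest {gene} reference sequence ({shortest} bp)"
        )
    index: dict[str, set[str]] = {}
    hits: dict[str, set[tuple[str, str]]] = {}
    for allele in db:
        seq = allele.gene_seq(gene)
        for strand, strand_seq in (("+", seq), ("-", revcomp(seq))):
            for km in kmers(strand_seq, k):
                index.setdefault(km, set()).add(allele.name)
                hits.setdefault(km, set()).add((allele.name, strand))
    return KmerIndex(
        k=k,
        gene=gene,
        kmer_to_alleles={km: frozenset(v) for km, v in index.items()},
        kmer_to_hits={km: frozenset(v) for km, v in hits.items()},
    )


def filter_reads(reads: Iterable[Read], index: KmerIndex) -> tuple[list[Read], int]:
    """Keep reads sharing at least one k-mer (either strand) with the index.

    Returns ``(kept_reads, n_filtered_out)``; input order is preserved.
    Reads shorter than k carry no k-mer and are filtered out.
    """
    kept: list[Read] = []
    n_filtered = 0
    k = index.k
    table = index.kmer_to_alleles
    for read in reads:
        # reference k-mers are indexed on both strands, so scanning the
        # forward read sequence alone covers both orientations
        hit = any(km in table for km in kmers(read.seq, k))
        if hit:
            kept.append(read)
        else:
            n_filtered += 1
    return kept, n_filtered


def assign_reads(
    reads: Iterable[Read],
    db: AlleleDB,
    gene: str,
    individual: str = "",
    scoring: AlignmentScoring = AlignmentScoring(),
    min_match_frac: float = 0.8,
    margin: float = 5.0,
    n_filtered: int = 0,
    index: KmerIndex | None = None,
    prescreen: bool = True,
) -> DepthProfile:
    """Assign each read to its best-matching allele by local alignment.

    A read is assigned to the allele with the highest local alignment score
    (best strand) when that score is at least ``min_match_frac * read length
    * match score`` — the score of an alignment matching that fraction of the
    read with no penalties — and exceeds the runner-up allele's score by at
    least ``margin``.  Ties and weak hits are discarded rather than split.

    With ``prescreen`` (default), shared k-mers restrict the alleles a read
    is aligned against; because reference k-mers are allele-diagnostic this
    prunes only alleles that could not win, and reads matching no k-mer fall
    back to alignment against the full database.

    ``mean_depth`` of an allele is the total number of its reference bases
    covered by assigned reads, divided by the reference length.
    """
    allele_list = list(db)
    if not allele_list:
        raise ValueError("empty allele database")
    aligner = scoring.make_aligner()
    refs = {a.name: a.gene_seq(gene) for a in allele_list}
    if prescreen and index is None:
        index = build_kmer_index(db, gene)
    covered_bases = {name: 0.0 for name in refs}
    n_assigned = 0
    n_unassigned = 0
    both = ("+", "-")
    for read in reads:
        read_rc = revcomp(read.seq)
        oriented_seq = {"+": read.seq, "-": read_rc}
        # candidate alleles (and orientations) from shared diagnostic k-mers;
        # a read matching no k-mer is aligned against everything
        candidates: dict[str, tuple[str, ...]] = {}
        if prescreen and index is not None:
            strand_votes: dict[str, set[str]] = {}
            for km in kmers(read.seq, index.k):
                for name, strand in index.lookup_hits(km):
                    strand_votes.setdefault(name, set()).add(strand)
            candidates = {n: tuple(sorted(s)) for n, s in strand_votes.items()}
        if not candidates:
            candidates = {name: both for name in refs}
        best_name = ""
        best_score = float("-inf")
        best_oriented = read.seq
        second_score = float("-inf")
        for name, strands in candidates.items():
            ref = refs[name]
            score = float("-inf")
            oriented = read.seq
            for strand in strands:
                s = aligner.score(ref, oriented_seq[strand])
                if s > score:
                    score, oriented = s, oriented_seq[strand]
            if score > best_score:
                second_score = best_score
                best_score, best_name, best_oriented = score, name, oriented
            elif score > second_score:
                second_score = score
        min_score = min_match_frac * len(read.seq) * scoring.match
        if best_score < min_score or best_score - second_score < margin:
            n_unassigned += 1
            continue
        if best_score == len(read.seq) * scoring.match:
            covered = float(len(read.seq))  # perfect full-length match
        else:
            alignment = aligner.align(refs[best_name], best_oriented)[0]
            target_segments = alignment.aligned[0]
            covered = float(sum(end - start for start, end in target_segments))
        covered_bases[best_name] += covered
        n_assigned += 1
    mean_depth = {name: covered_bases[name] / len(refs[name]) for name in refs}
    return DepthProfile(
        individual=individual,
        gene=gene,
        mean_depth=mean_depth,
        n_reads_assigned=n_assigned,
        n_reads_unassigned=n_unassigned,
        n_reads_filtered_out=n_filtered,
    )


def call_genotype(
    profile: DepthProfile,
    ploidy: int,
    abs_floor: float = 5.0,
    rel_floor: float = 0.05,
) -> GenotypeCall:
    """Call which alleles are present from an SRK depth profile.

    An allele is present when its mean depth is at least ``abs_floor`` and at
    least ``rel_floor`` times the depth of the strongest allele.  For
    diploids, one present allele is a homozygote (2 copies) and two a
    heterozygote (1+1); more than two yields an unconfident call.  For
    tetraploids, copy numbers are unknown unless exactly four distinct
    alleles are present.
    """
    if ploidy not in (2, 4):
        raise ValueError(f"unsupported ploidy {ploidy}")
    depths = profile.mean_depth
    top = max(depths.values(), default=0.0)
    if top <= 0.0:
        return GenotypeCall(
            individual=profile.individual,
            ploidy=ploidy,
            alleles_present=frozenset(),
            copy_numbers={},
            confident=False,
            status="no_call",
        )
    present = frozenset(
        name
        for name, d in depths.items()
        if d >= abs_floor and d >= rel_floor * top
    )
    if not present:
        return GenotypeCall(
            individual=profile.individual,
            ploidy=ploidy,
            alleles_present=frozenset(),
            copy_numbers={},
            confident=False,
            status="no_call",
        )
    if ploidy == 2:
        if len(present) == 1:
            (only,) = present
            return GenotypeCall(
                profile.individual, 2, present, {only: 2}, True, "ok"
            )
        if len(present) == 2:
            return GenotypeCall(
                profile.individual, 2, present, {n: 1 for n in present}, True, "ok"
            )
        return GenotypeCall(
            profile.individual,
            2,
            present,
            {n: UNKNOWN for n in present},
            False,
            "too_many_alleles",
        )
    # tetraploid
    if len(present) == 4:
        return GenotypeCall(
            profile.individual, 4, present, {n: 1 for n in present}, True, "ok"
        )
    if len(present) > 4:
        return GenotypeCall(
            profile.individual,
            4,
            present,
            {n: UNKNOWN for n in present},
            False,
            "too_many_alleles",
        )
    return GenotypeCall(
        profile.individual, 4, present, {n: UNKNOWN for n in present}, True, "ok"
    )
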