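"""S-allele records and reference databases.

In Brassicaceae, sporophytic self-incompatibility (SI) is controlled by two
tightly linked genes at the S-locus: *SRK*, the stigma receptor kinase, and
*SCR*, the pollen-coat ligand.  Each S-haplotype ("S-allele") carries its own
highly divergent copy of both genes, and haplotypes fall into four dominance
classes (class I most recessive, class IV most dominant).  The high nucleotide
divergence between alleles is what makes short-read genotyping by k-mer
filtering and per-allele read mapping possible: for sufficiently divergent
sequences, every k-mer is diagnostic of a single allele and cross-mapping of
reads between alleles is negligible.

This module defines the :class:`Allele` record, the :class:`AlleleDB`
container (a small reference database of SRK/SCR sequences), and FASTA
round-trip helpers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_GENES = ("SRK", "SCR")

#: Allele naming convention: ``H<class digit><3 digits>`` with an optional
#: trailing ``n`` marking a non-functional allele (e.g. ``H4004n``).
ALLELE_NAME_RE = re.compile(r"^H([1-4])(\d{3})(n?)$")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_VALID_SEQ_RE = re.compile(r"^[ACGT]+$")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    return seq.translate(_COMPLEMENT)[::-1]


def kmers(seq: str, k: int) -> Iterator[str]:
    """All overlapping substrings of length ``k`` (empty if ``len(seq) < k``)."""
    for i in range(len(seq) - k + 1):
        yield seq[i : i + k]


def canonical_kmers(seq: str, k: int) -> set[str]:
    """Strand-canonical k-mer set: min(kmer, revcomp(kmer)) for each window."""
    out = set()
    for km in kmers(seq, k):
        rc = revcomp(km)
        out.add(km if km <= rc else rc)
    return out


def parse_allele_name(name: str) -> tuple[int, bool]:
    """Return ``(dominance_class, functional)`` encoded in an allele name.

    Raises ``ValueError`` for names not matching the ``H<class><3 digits>[n]``
    convention.
    """
    m = ALLELE_NAME_RE.match(name)
    if m is None:
        raise ValueError(
            f"invalid allele name {name!r}: expected H<class digit><3 digits> "
            "with optional trailing 'n'"
        )
    return int(m.group(1)), m.group(3) != "n"


@dataclass(frozen=True)
class Allele:
    """One S-haplotype: a name, dominance class, and SRK/SCR sequences.

    The name encodes the dominance class (first digit) and functionality
    (trailing ``n`` = non-functional); both redundant fields are validated
    against the name on construction.
    """

    name: str
    dominance_class: int
    functional: bool
    srk_seq: str
    scr_seq: str

    def __post_init__(self) -> None:
        cls, func = parse_allele_name(self.name)
        if cls != self.dominance_class:
            raise ValueError(
                f"{self.name}: dominance_class {self.dominance_class} "
                f"contradicts name (class {cls})"
            )
        if func != self.functional:
            raise ValueError(
                f"{self.name}: functional={self.functional} contradicts name "
                f"(trailing 'n' means non-functional)"
            )
        for gene, seq in (("SRK", self.srk_seq), ("SCR", self.scr_seq)):
            if not seq or not _VALID_SEQ_RE.match(seq):
                raise ValueError(
                    f"{self.name}: {gene} sequence must be a non-empty "
                    "uppercase A/C/G/T string"
                )

    @classmethod
    def from_name(cls, name: str, srk_seq: str, scr_seq: str) -> "Allele":
        """Build an allele deriving class and functionality from the name."""
        dom, func = parse_allele_name(name)
        return cls(name, dom, func, srk_seq, scr_seq)

    def gene_seq(self, gene: str) -> str:
        if gene == "SRK":
            return self.srk_seq
        if gene == "SCR":
            return self.scr_seq
        raise ValueError(f"unknown gene {gene!r}; expected one of {VALID_GENES}")


@dataclass
class AlleleDB:
    """A reference database of S-alleles with unique names.

    Iterating yields :class:`Allele` records in insertion order.
    """

    alleles: list[Allele]
    _by_name: dict[str, Allele] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_name = {}
        for a in self.alleles:
            if a.name in self._by_name:
                raise ValueError(f"duplicate allele name {a.name!r}")
            self._by_name[a.name] = a

    def __iter__(self) -> Iterator[Allele]:
        return iter(self.alleles)

    def __len__(self) -> int:
        return len(self.alleles)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.alleles]

    def get(self, name: str) -> Allele:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"allele {name!r} not in database") from None

    def gene_length(self, name: str, gene: str) -> int:
        return len(self.get(name).gene_seq(gene))

    def colliding_kmer_pairs(self, gene: str, k: int) -> list[tuple[str, str]]:
        """Allele pairs sharing at least one strand-canonical k-mer.

        An empty list means every k-mer of every allele (on either strand) is
        diagnostic of exactly one allele, the property the read filter and
        the per-allele read assignment both rely on.
        """
        sets = {a.name: canonical_kmers(a.gene_seq(gene), k) for a in self.alleles}
        names = self.names
        bad = []
        for i, ni in enumerate(names):
            for nj in names[i + 1 :]:
                if sets[ni] & sets[nj]:
                    bad.append((ni, nj))
        return bad

    def is_kmer_diagnostic(self, gene: str, k: int) -> bool:
        return not self.colliding_kmer_pairs(gene, k)

    def min_pairwise_divergence(self, gene: str) -> float | None:
        """Minimum pairwise per-site difference (Hamming), equal-length only.

        Returns ``None`` when sequences differ in length or fewer than two
        alleles are present.
        """
        seqs = [a.gene_seq(gene) for a in self.alleles]
        if len(seqs) < 2 or len({len(s) for s in seqs}) != 1:
            return None
        best = 1.0
        for i, si in enumerate(seqs):
            for sj in seqs[i + 1 :]:
                d = sum(x != y for x, y in zip(si, sj)) / len(si)
                best = min(best, d)
        return best

    def write_fasta(self, path: str | Path, gene: str) -> None:
        """Write one gene's sequences as FASTA.

        Headers follow ``><name> class=<1-4> functional=<0|1> gene=<SRK|SCR>``.
        """
        if gene not in VALID_GENES:
            raise ValueError(f"unknown gene {gene!r}")
        records = [
            SeqRecord(
                Seq(a.gene_seq(gene)),
                id=a.name,
                description=(
                    f"class={a.dominance_class} "
                    f"functional={int(a.functional)} gene={gene}"
                ),
            )
            for a in self.alleles
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, srk_path: str | Path, scr_path: str | Path) -> "AlleleDB":
        """Load a database from paired SRK and SCR FASTA files.

        The two files must contain the same allele names; class and
        functionality are re-derived from the names.
        """
        srk = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(srk_path), "fasta")}
        scr = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(scr_path), "fasta")}
        if set(srk) != set(scr):
            raise ValueError(
                "SRK and SCR FASTA files name different alleles: "
                f"{sorted(set(srk) ^ set(scr))}"
            )
        alleles = [Allele.from_name(n, srk[n], scr[n]) for n in srk]
        return cls(alleles)
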