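"""k-mer filtering, read assignment and genotype calling."""

import numpy as np
import pytest

from sdom.alleles import Allele, AlleleDB, kmers, revcomp
from sdom.genotyping import (
    assign_reads,
    build_kmer_index,
    call_genotype,
    filter_reads,
)
from sdom.io import Read
from sdom.simulate import Individual, SimScenario, simulate_reads


@pytest.fixture(scope="module")
def het_reads(db):
    """Error-free SCR reads from a diploid H4004n/H2022 heterozygote."""
    ind = Individual("het", 2, ("H4004n", "H2022"))
    sc = SimScenario(individuals=(ind,), error_rate=0.0, seed=21)
    reads, counts = simulate_reads(ind, db, sc, "SCR")
    return reads, counts


class TestBuildKmerIndex:
    def test_window_count_single_short_allele(self):
        # 20 bp sequence, k=15: L-k+1 = 6 windows per strand
        seq = "ACGTAACCGGTTAGCATGAC"
        mini = AlleleDB([Allele.from_name("H1001", seq, seq)])
        idx = build_kmer_index(mini, "SCR", 15)
        expected = set(kmers(seq, 15)) | set(kmers(revcomp(seq), 15))
        assert set(idx.kmer_to_alleles) == expected
        assert len(idx) == 12  # all 6+6 windows distinct for this sequence

    def test_k_equal_to_sequence_length(self):
        seq = "ACGTAACCGGTTAGCATGAC"
        mini = AlleleDB([Allele.from_name("H1001", seq, seq)])
        idx = build_kmer_index(mini, "SCR", 20)
        assert set(idx.kmer_to_alleles) == {seq, revcomp(seq)}

    def test_default_fixture_keys_map_to_single_allele(self, db):
        idx = build_kmer_index(db, "SCR", 15)
        assert all(len(v) == 1 for v in idx.kmer_to_alleles.values())

    def test_too_small_or_too_large_k_refused(self, db):
        with pytest.raises(ValueError):
            build_kmer_index(db, "SCR", 7)
        with pytest.raises(ValueError):
            build_kmer_index(db, "SCR", 10_000)


class TestFilterReads:
    def test_error_free_reads_all_kept(self, db, het_reads):
        reads, _ = het_reads
        idx = build_kmer_index(db, "SCR", 15)
        kept, n_filtered = filter_reads(reads, idx)
        assert n_filtered == 0
        assert [r.id for r in kept] == [r.id for r in reads]  # order preserved

    def test_read_shorter_than_k_filtered(self, db):
        idx = build_kmer_index(db, "SCR", 15)
        kept, n_filtered = filter_reads([Read("tiny", "ACGTACGTAC")], idx)
        assert kept == [] and n_filtered == 1

    def test_random_reads_essentially_never_pass(self, db):
        # collision bound: <= 2*L*6 reference 15-mers out of 4^15 (~1e9)
        # possibilities; per 100 bp read the expected hit count is ~4e-4
        rng = np.random.default_rng(0)
        bases = np.frombuffer(b"ACGT", dtype="S1")
        reads = [
            Read(f"r{i}", bases[rng.integers(0, 4, 100)].tobytes().decode())
            for i in range(500)
        ]
        idx = build_kmer_index(db, "SCR", 15)
        kept, n_filtered = filter_reads(reads, idx)
        assert len(kept) <= 1
        assert n_filtered >= 499

    def test_empty_input_gives_empty_output(self, db):
        idx = build_kmer_index(db, "SCR", 15)
        assert filter_reads([], idx) == ([], 0)


class TestAssignReads:
    def test_single_source_allele_gets_all_depth(self, db):
        ind = Individual("homo", 2, ("H2008", "H2008"))
        sc = SimScenario(individuals=(ind,), error_rate=0.0, seed=5)
        reads, _ = simulate_reads(ind, db, sc, "SCR")
        prof = assign_reads(reads[:100], db, "SCR", individual="homo")
        assert prof.mean_depth["H2008"] > 0
        assert all(v == 0 for a, v in prof.mean_depth.items() if a != "H2008")
        assert prof.n_reads_assigned == 100

    def test_depth_is_length_normalized_for_perfect_coverage(self, db):
        ind = Individual("homo", 2, ("H2008", "H2008"))
        sc = SimScenario(individuals=(ind,), error_rate=0.0, seed=5)
        reads, _ = simulate_reads(ind, db, sc, "SCR")
        prof = assign_reads(reads, db, "SCR")
        L = db.gene_length("H2008", "SCR")
        expected = len(reads) * 100 / L  # every read aligns full-length
        assert prof.mean_depth["H2008"] == pytest.approx(expected)

    def test_srk_heterozygote_depths_within_twofold(self, db, het_reads):
        ind = Individual("het", 2, ("H4004n", "H2022"))
        sc = SimScenario(individuals=(ind,), seed=21)
        reads, _ = simulate_reads(ind, db, sc, "SRK")
        prof = assign_reads(reads, db, "SRK")
        d1, d2 = prof.mean_depth["H4004n"], prof.mean_depth["H2022"]
        assert d1 > 0 and d2 > 0
        assert max(d1, d2) / min(d1, d2) < 2.0

    def test_engineered_chimera_discarded_by_margin(self, db):
        a = db.get("H4004n").scr_seq
        b = db.get("H2022").scr_seq
        chimera = Read("chimera", a[:50] + b[50:100])
        prof = assign_reads([chimera], db, "SCR", prescreen=False)
        assert prof.n_reads_assigned == 0
        assert prof.n_reads_unassigned == 1
        assert all(v == 0 for v in prof.mean_depth.values())

    def test_junk_read_fails_min_score(self, db):
        prof = assign_reads([Read("junk", "AC" * 50)], db, "SCR", prescreen=False)
        assert prof.n_reads_assigned == 0

    def test_mean_depth_invariant_under_read_order(self, db, het_reads):
        reads, _ = het_reads
        prof1 = assign_reads(reads, db, "SCR")
        prof2 = assign_reads(list(reversed(reads)), db, "SCR")
        assert prof1.mean_depth == prof2.mean_depth

    def test_prescreen_does_not_change_profiles(self, db):
        ind = Individual("het", 2, ("H4004n", "H2022"))
        sc = SimScenario(individuals=(ind,), seed=13)
        reads, _ = simulate_reads(ind, db, sc, "SCR")
        with_screen = assign_reads(reads[:150], db, "SCR", prescreen=True)
        without = assign_reads(reads[:150], db, "SCR", prescreen=False)
        for allele in db.names:
            assert with_screen.mean_depth[allele] == pytest.approx(
                without.mean_depth[allele]
            )

    def test_empty_db_rejected(self):
        with pytest.raises(ValueError):
            assign_reads([], AlleleDB([]), "SCR")


class TestCallGenotype:
    def _profile(self, depths, individual="x", gene="SRK"):
        from sdom.genotyping import DepthProfile

        return DepthProfile(individual=individual, gene=gene, mean_depth=depths)

    def test_diploid_homozygote(self):
        g = call_genotype(self._profile({"H4004n": 52.0, "H2022": 0.4}), 2)
        assert g.alleles_present == frozenset({"H4004n"})
        assert g.copy_numbers == {"H4004n": 2}
        assert g.confident

    def test_diploid_heterozygote(self):
        g = call_genotype(self._profile({"H4004n": 50.0, "H2022": 48.0}), 2)
        assert g.alleles_present == frozenset({"H4004n", "H2022"})
        assert g.copy_numbers == {"H4004n": 1, "H2022": 1}
        assert sum(g.copy_numbers.values()) == 2

    def test_diploid_three_alleles_not_confident(self):
        g = call_genotype(
            self._profile({"H4004n": 50.0, "H2022": 40.0, "H2008": 30.0}), 2
        )
        assert len(g.alleles_present) == 3
        assert not g.confident
        assert g.status == "too_many_alleles"

    def test_tetraploid_three_alleles_copy_numbers_unknown(self):
        g = call_genotype(
            self._profile({"H4004n": 80.0, "H2022": 30.0, "H2008": 28.0}), 4
        )
        assert g.alleles_present == frozenset({"H4004n", "H2022", "H2008"})
        assert all(v is None for v in g.copy_numbers.values())
        assert g.confident

    def test_tetraploid_four_distinct_alleles_single_copies(self):
        g = call_genotype(
            self._profile(
                {"H4035": 30.0, "H4015": 28.0, "H2022": 25.0, "H2008": 26.0}
            ),
            4,
        )
        assert g.copy_numbers == {n: 1 for n in g.alleles_present}

    def test_absolute_and_relative_floors(self):
        # 4.9 < absolute floor; 4.0 < 5% of 100
        g = call_genotype(self._profile({"H4004n": 100.0, "H2022": 4.9}), 2)
        assert g.alleles_present == frozenset({"H4004n"})
        g = call_genotype(self._profile({"H4004n": 200.0, "H2022": 9.0}), 2)
        assert g.alleles_present == frozenset({"H4004n"})

    def test_all_zero_depth_is_explicit_no_call(self):
        g = call_genotype(self._profile({"H4004n": 0.0, "H2022": 0.0}), 2)
        assert g.status == "no_call"
        assert not g.confident
        assert g.alleles_present == frozenset()

    def test_invalid_ploidy_rejected(self):
        with pytest.raises(ValueError):
            call_genotype(self._profile({"H4004n": 50.0}), 3)


def test_genomic_and_flower_bud_reads_give_identical_genotypes(db):
    """Calls from genomic-like (per-copy) and RNA (balanced-SRK) coverage
    agree on the same individuals, mirroring the DNA/RNA concordance check."""
    from sdom.simulate import hybrid_panel, simulate_depth_profile

    inds = hybrid_panel(seed=17, n_diploid=10, n_tetraploid=10)
    sc = SimScenario(individuals=inds, seed=17)
    for ind in inds:
        g_rna = call_genotype(
            simulate_depth_profile(ind, db, sc, "SRK", mode="rna"), ind.ploidy
        )
        g_dna = call_genotype(
            simulate_depth_profile(ind, db, sc, "SRK", mode="dna"), ind.ploidy
        )
        assert g_rna.alleles_present == g_dna.alleles_present


def test_filter_never_changes_calls_on_error_free_reads(db):
    """The k-mer filter is a pure speedup for clean reads."""
    ind = Individual("het", 2, ("H4015", "H1001"))
    sc = SimScenario(individuals=(ind,), error_rate=0.0, seed=31)
    reads, _ = simulate_reads(ind, db, sc, "SRK")
    idx = build_kmer_index(db, "SRK", 20)
    filtered, n_out = filter_reads(reads, idx)
    assert n_out == 0
    direct = assign_reads(reads, db, "SRK")
    via_filter = assign_reads(filtered, db, "SRK")
    assert direct.mean_depth == via_filter.mean_depth
    assert call_genotype(direct, 2).alleles_present == call_genotype(
        via_filter, 2
    ).alleles_present
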