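"""Synthetic-data generator: expression model, reads, seed sets, truth."""

import io as stdio

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from sdom.io import write_fastq
from sdom.simulate import (
    DEFAULT_ALLELE_NAMES,
    DEFAULT_HIERARCHY,
    Individual,
    SimScenario,
    build_truth,
    hybrid_panel,
    pair_coverage_panel,
    simulate_depth_profile,
    simulate_reads,
    simulate_seed_set,
    true_phenotype,
    true_scr_proportions,
    _sub_rng,
)


class TestTrueScrProportions:
    def test_diploid_heterozygote_silencing_split(self):
        p = true_scr_proportions(("H4004n", "H2022"), DEFAULT_HIERARCHY, 0.01)
        assert p == {"H4004n": pytest.approx(0.99), "H2022": pytest.approx(0.01)}

    def test_homozygote_expresses_fully(self):
        p = true_scr_proportions(("H4004n", "H4004n"), DEFAULT_HIERARCHY, 0.3)
        assert p == {"H4004n": 1.0}

    def test_tetraploid_split_hand_arithmetic(self):
        # dominant H4035 gets 0.98; the remaining 0.02 splits over 3 single
        # copies: 0.02/3 each
        p = true_scr_proportions(
            ("H4035", "H4015", "H4004n", "H2022"), DEFAULT_HIERARCHY, 0.02
        )
        assert p["H4035"] == pytest.approx(0.98)
        for other in ("H4015", "H4004n", "H2022"):
            assert p[other] == pytest.approx(0.02 / 3)
        assert sum(p.values()) == pytest.approx(1.0)

    def test_copy_number_weighting_of_silenced_alleles(self):
        p = true_scr_proportions(
            ("H4035", "H2022", "H2022", "H2008"), DEFAULT_HIERARCHY, 0.03
        )
        assert p["H2022"] == pytest.approx(0.02)
        assert p["H2008"] == pytest.approx(0.01)

    def test_codominant_maxima_split_top_share(self):
        hierarchy = (("H4035", "H4015"), "H2022")  # tied class-IV pair
        p = true_scr_proportions(("H4035", "H4015", "H2022", "H2022"), hierarchy, 0.02)
        assert p["H4035"] == pytest.approx(0.49)
        assert p["H4015"] == pytest.approx(0.49)
        assert p["H2022"] == pytest.approx(0.02)

    def test_empty_genotype_rejected(self):
        with pytest.raises(ValueError):
            true_scr_proportions((), DEFAULT_HIERARCHY)

    @given(
        genotype=st.lists(
            st.sampled_from(DEFAULT_ALLELE_NAMES), min_size=1, max_size=4
        ),
        eps=st.floats(0.0, 0.49),
    )
    @settings(max_examples=200, deadline=None)
    def test_proportions_sum_to_one(self, genotype, eps):
        p = true_scr_proportions(tuple(genotype), DEFAULT_HIERARCHY, eps)
        assert sum(p.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(v >= 0 for v in p.values())
        assert set(p) == set(genotype)


class TestSimulateReads:
    def test_error_free_reads_are_exact_substrings(self, db):
        ind = Individual("h", 2, ("H2008", "H2008"))
        sc = SimScenario(individuals=(ind,), error_rate=0.0, seed=4)
        reads, counts = simulate_reads(ind, db, sc, "SCR")
        ref = db.get("H2008").scr_seq
        from sdom.alleles import revcomp

        assert counts == {"H2008": len(reads)}
        for r in reads:
            assert r.seq in ref or revcomp(r.seq) in ref

    def test_dominant_allele_provides_most_scr_reads(self, db):
        ind = Individual("h", 2, ("H4004n", "H1001"))
        sc = SimScenario(individuals=(ind,), seed=4)
        _, counts = simulate_reads(ind, db, sc, "SCR")
        total = sum(counts.values())
        # expected share 0.99; binomial 5-sigma band at n=400
        assert counts["H4004n"] / total > 0.99 - 5 * np.sqrt(0.99 * 0.01 / total)

    def test_fixed_seed_gives_byte_identical_fastq(self, db):
        ind = Individual("h", 2, ("H4004n", "H2022"))
        sc = SimScenario(individuals=(ind,), seed=9)
        out = []
        for _ in range(2):
            reads, _ = simulate_reads(ind, db, sc, "SCR")
            buf = stdio.StringIO()
            from Bio import SeqIO
            from Bio.Seq import Seq
            from Bio.SeqRecord import SeqRecord

            recs = []
            for r in reads:
                rec = SeqRecord(Seq(r.seq), id=r.id, description="")
                rec.letter_annotations["phred_quality"] = [40] * len(r.seq)
                recs.append(rec)
            SeqIO.write(recs, buf, "fastq")
            out.append(buf.getvalue())
        assert out[0] == out[1]

    def test_headers_carry_no_truth(self, db):
        ind = Individual("h", 2, ("H4004n", "H2022"))
        sc = SimScenario(individuals=(ind,), seed=9)
        reads, _ = simulate_reads(ind, db, sc, "SCR")
        assert not any("H4004n" in r.id or "H2022" in r.id for r in reads)

    def test_genomic_mode_proportional_to_copy_number(self, db):
        ind = Individual("t", 4, ("H4004n", "H4004n", "H4004n", "H2022"))
        sc = SimScenario(individuals=(ind,), seed=2)
        _, counts = simulate_reads(ind, db, sc, "SRK", mode="dna")
        total = sum(counts.values())
        assert counts["H4004n"] / total == pytest.approx(0.75, abs=0.06)

    def test_bad_parameters_rejected(self, db):
        ind = Individual("h", 2, ("H4004n", "H2022"))
        with pytest.raises(ValueError):
            sc = SimScenario(individuals=(ind,), target_depth=0.0)
            simulate_reads(ind, db, sc, "SCR")
        with pytest.raises(ValueError):
            sc = SimScenario(individuals=(ind,), read_length=10_000)
            simulate_reads(ind, db, sc, "SCR")
        bad = Individual("h", 2, ("H4004n", "H3999"))
        sc = SimScenario(individuals=(bad,), seed=0)
        with pytest.raises(KeyError):
            simulate_reads(bad, db, sc, "SCR")


def test_srk_shares_balanced_in_expectation(db):
    """Diploid heterozygote SRK shares average 0.5 per allele."""
    shares = []
    for i in range(200):
        ind = Individual(f"h{i}", 2, ("H4004n", "H2022"))
        sc = SimScenario(individuals=(ind,), seed=100 + i)
        prof = simulate_depth_profile(ind, db, sc, "SRK")
        total = prof.mean_depth["H4004n"] + prof.mean_depth["H2022"]
        shares.append(prof.mean_depth["H4004n"] / total)
    mean = float(np.mean(shares))
    # sd of one share is ~0.12 at jitter sd 0.25 -> SE over 200 ~ 0.01
    assert mean == pytest.approx(0.5, abs=0.04)


class TestSeedSet:
    def test_si_without_contamination_sets_no_seed(self):
        sc = SimScenario(si_contamination_prob=0.0)
        rng = np.random.default_rng(0)
        assert all(simulate_seed_set("SI", sc, rng) == 0 for _ in range(50))

    def test_sc_tail_matches_poisson(self):
        sc = SimScenario()
        rng = np.random.default_rng(1)
        draws = np.array([simulate_seed_set("SC", sc, rng) for _ in range(10_000)])
        frac_over_300 = (draws > 300).mean()
        expected = float(sps.poisson.sf(300, 400))  # closed-form tail oracle
        assert frac_over_300 == pytest.approx(expected, abs=0.01)

    def test_bimodality_little_mass_between_modes(self):
        # closed-form mixture: half SC, half SI ->
        # P(50..300) = 0.5*P(Po(400) in [50,300]) + 0.5*c*P(U{1..300} >= 50)
        sc = SimScenario()
        rng = np.random.default_rng(2)
        draws = []
        for i in range(500):
            pheno = "SC" if i % 2 == 0 else "SI"
            draws.append(simulate_seed_set(pheno, sc, rng))
        draws = np.array(draws)
        mid = ((draws >= 50) & (draws <= 300)).mean()
        closed_form = 0.5 * float(
            sps.poisson.cdf(300, 400) - sps.poisson.cdf(49, 400)
        ) + 0.5 * 0.1 * (251 / 300)
        assert closed_form < 0.05
        assert mid < 0.05
        assert mid == pytest.approx(closed_form, abs=0.03)

    def test_unknown_phenotype_rejected(self):
        with pytest.raises(ValueError):
            simulate_seed_set("??", SimScenario(), np.random.default_rng(0))


class TestTruthLedger:
    def test_phenotype_follows_dominant_allele_functionality(self):
        assert true_phenotype(("H4004n", "H2022"), DEFAULT_HIERARCHY) == "SC"
        assert true_phenotype(("H4004n", "H4015"), DEFAULT_HIERARCHY) == "SI"
        assert true_phenotype(("H2008", "H2022"), DEFAULT_HIERARCHY) == "SI"

    def test_ledger_covers_panel_and_proportions_sum_to_one(self):
        inds = hybrid_panel(seed=3, n_diploid=5, n_tetraploid=5)
        sc = SimScenario(individuals=inds, seed=3)
        ledger = build_truth(sc)
        assert len(ledger) == 10
        for entry in ledger:
            assert sum(entry.scr_proportions.values()) == pytest.approx(1.0)
            assert entry.seed_count >= 0
            assert entry.phenotype in ("SC", "SI")
        df = ledger.to_dataframe()
        assert list(df.columns) == [
            "individual", "ploidy", "genotype", "dominant_scr",
            "phenotype", "seed_count",
        ]


def test_panel_builders_shapes():
    inds = hybrid_panel(seed=0)
    assert len(inds) == 53
    assert sum(1 for i in inds if i.ploidy == 2) == 27
    assert all("H4004n" in i.genotype for i in inds)
    pairs = pair_coverage_panel(per_pair=3)
    assert len(pairs) == 15 * 3
    seen = {frozenset(i.genotype) for i in pairs}
    assert len(seen) == 15
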