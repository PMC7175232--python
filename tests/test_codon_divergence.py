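import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import oracle_ng86, oracle_path_counts, oracle_syn_sites
from conftest import random_codon_alignment
from paralogkit._genetics import SENSE_CODONS
from paralogkit.codon_divergence import (
    CodonAlignment,
    SaturationError,
    classify_age,
    divergence_profile,
    fourDTv,
    identify_4d_sites,
    k2p_transversion_correction,
    ng86_kaks,
    pairwise_identity,
    thread_codon_alignment,
)
from paralogkit.io_formats import SequenceRecord
from paralogkit.synthetic_data import PairEvolutionConfig, evolve_codon_pair


def nt(ident, seq):
    return SequenceRecord(id=ident, seq=seq, moltype="nt", is_cds=True)


class TestThreading:
    def test_identity_case(self):
        aln = thread_codon_alignment(["MA", "MA"], nt("a", "ATGGCT"), nt("b", "ATGGCA"))
        assert (aln.seq_a, aln.seq_b) == ("ATGGCT", "ATGGCA")

    def test_gap_becomes_gap_codon(self):
        aln = thread_codon_alignment(
            ["M-A", "MKA"], nt("a", "ATGGCT"), nt("b", "ATGAAAGCA")
        )
        assert aln.seq_a == "ATG---GCT"
        assert aln.seq_b == "ATGAAAGCA"

    def test_terminal_stop_trimmed(self):
        aln = thread_codon_alignment(
            ["MA", "MA"], nt("a", "ATGGCTTAA"), nt("b", "ATGGCA")
        )
        assert aln.seq_a == "ATGGCT"

    def test_translation_mismatch_names_residue(self):
        with pytest.raises(ValueError, match="residue 2"):
            thread_codon_alignment(["MA", "MA"], nt("a", "ATGGTT"), nt("b", "ATGGCA"))

    def test_partial_codon_gap_rejected(self):
        with pytest.raises(ValueError, match="partial gap"):
            CodonAlignment("ATG-CT", "ATGGCT")


class TestFourfoldSites:
    def test_all_three_codons_fourfold(self):
        aln = CodonAlignment("GCTCGTGGA", "GCACGTGGG")
        assert identify_4d_sites(aln) == [2, 5, 8]

    def test_non_degenerate_prefix_excluded(self):
        aln = CodonAlignment("ATGATG", "ATGATG")
        assert identify_4d_sites(aln) == []

    def test_differing_prefixes_excluded(self):
        aln = CodonAlignment("GCTATG", "ACTATG")
        assert identify_4d_sites(aln) == []

    def test_gapped_and_ambiguous_codons_excluded(self):
        aln = CodonAlignment("GCT---", "GCAGCA")
        assert identify_4d_sites(aln) == [2]


class TestFourDTv:
    def test_hand_counted_example(self):
        # GCT/GCA: T<->A transversion; CGT/CGT equal; GGA/GGG transition
        result = fourDTv(CodonAlignment("GCTCGTGGA", "GCACGTGGG"))
        assert result.n_4d_sites == 3
        assert result.raw == pytest.approx(1 / 3)
        assert result.corrected == pytest.approx(-0.5 * math.log(1 / 3))

    def test_identical_sequences(self):
        result = fourDTv(CodonAlignment("GCTCGTGGA", "GCTCGTGGA"))
        assert result.raw == 0.0 and result.corrected == 0.0

    def test_saturation_flag_at_half(self):
        # both fourfold sites differ by a transversion -> raw = 1.0
        result = fourDTv(CodonAlignment("GGAGCT", "GGTGCA"))
        assert result.raw >= 0.5 and result.saturated and result.corrected is None

    def test_no_fourfold_sites_raises(self):
        with pytest.raises(ValueError, match="fourfold"):
            fourDTv(CodonAlignment("ATGATG", "ATGATG"))

    def test_correction_monotone_and_above_raw(self):
        qs = np.linspace(0.01, 0.49, 40)
        corrected = [k2p_transversion_correction(q) for q in qs]
        assert all(c >= q for c, q in zip(corrected, qs))
        assert all(b > a for a, b in zip(corrected, corrected[1:]))

    def test_row_swap_invariance(self, rng):
        for _ in range(20):
            ra, rb = random_codon_alignment(rng, 30)
            try:
                fwd = fourDTv(CodonAlignment(ra, rb))
                rev = fourDTv(CodonAlignment(rb, ra))
            except ValueError:
                continue
            assert fwd.raw == rev.raw and fwd.n_4d_sites == rev.n_4d_sites


class TestNg86:
    def test_identical_sequences(self):
        r = ng86_kaks(CodonAlignment("ATGGCTAAA", "ATGGCTAAA"))
        assert r.Ka == r.Ks == 0.0 and r.omega is None

    def test_hand_computed_site_fractions(self):
        # codons AAA (s=1/3), AAT/AAC (s=1/3), GGG (s=1): S=5/3, N=22/3
        r = ng86_kaks(CodonAlignment("AAAAATGGG", "AAAAACGGG"))
        assert r.S == pytest.approx(5 / 3)
        assert r.N == pytest.approx(22 / 3)
        assert (r.Sd, r.Nd) == (1.0, 0.0)
        assert r.ps == pytest.approx(0.6)
        assert r.Ks == pytest.approx(-0.75 * math.log(0.2))
        assert r.Ka == 0.0 and r.omega == 0.0

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            ng86_kaks(CodonAlignment("TTATTATTA", "CTGCTGCTG"))

    @pytest.mark.parametrize("codon", SENSE_CODONS)
    def test_site_fractions_match_enumeration_oracle(self, codon):
        from paralogkit.codon_divergence import _SYN_FRACTION

        assert _SYN_FRACTION[codon] == pytest.approx(oracle_syn_sites(codon))

    def test_pathway_counts_match_oracle_exhaustively(self):
        from paralogkit.codon_divergence import _PATHWAY

        checked = 0
        for a in SENSE_CODONS:
            for b in SENSE_CODONS:
                diffs = sum(x != y for x, y in zip(a, b))
                if diffs <= 2:
                    assert _PATHWAY[(a, b)] == pytest.approx(oracle_path_counts(a, b))
                    checked += 1
        assert checked > 1000

    def test_random_alignments_match_oracle(self, rng):
        for _ in range(25):
            ra, rb = random_codon_alignment(rng, 50)
            mine = ng86_kaks(CodonAlignment(ra, rb))
            ref = oracle_ng86(ra, rb)
            for field in ("S", "N", "Sd", "Nd", "Ka", "Ks"):
                assert getattr(mine, field) == pytest.approx(ref[field]), field

    def test_parameter_recovery_neutral(self):
        omegas = []
        for rep in range(20):
            a, b, _ = evolve_codon_pair(
                PairEvolutionConfig(n_codons=2000, d=0.3, kappa=1.0, omega_true=1.0, seed=500 + rep)
            )
            omegas.append(ng86_kaks(CodonAlignment(a.seq, b.seq)).omega)
        assert 0.9 <= np.mean(omegas) <= 1.1

    def test_purifying_selection_drives_ka_to_zero(self):
        a, b, _ = evolve_codon_pair(
            PairEvolutionConfig(n_codons=2000, d=0.3, kappa=2.0, omega_true=0.0, seed=42)
        )
        r = ng86_kaks(CodonAlignment(a.seq, b.seq))
        assert r.Ka < 0.005 and r.Ks > 0.1


class TestIdentity:
    @pytest.mark.parametrize(
        "a,b,expected",
        [("ACGT", "ACGA", 75.0), ("ACGT", "ACGT", 100.0), ("AC-T", "ACGT", 100.0)],
    )
    def test_examples(self, a, b, expected):
        assert pairwise_identity(a, b) == expected

    def test_all_gap_columns_raise(self):
        with pytest.raises(ValueError, match="comparable"):
            pairwise_identity("--", "AA")

    @given(st.text(alphabet="ACGT", min_size=1, max_size=60))
    def test_self_identity_is_100(self, seq):
        assert pairwise_identity(seq, seq) == 100.0


class TestDivergenceProfile:
    def test_threshold_classification(self):
        assert classify_age_value(0.6) == "ancient"
        assert classify_age_value(0.005) == "recent"
        assert classify_age_value(0.2) == "intermediate"

    def test_simulated_cohort_class_counts(self):
        alns = []
        expected = {"recent": 0, "intermediate": 0, "ancient": 0, "saturated": 0}
        for rep, d in enumerate([0.0, 0.0, 0.3, 0.3, 2.5]):
            a, b, _ = evolve_codon_pair(
                PairEvolutionConfig(n_codons=3000, d=d, kappa=2.0, omega_true=1.0, seed=900 + rep)
            )
            aln = CodonAlignment(a.seq, b.seq)
            alns.append(aln)
            expected[classify_age(fourDTv(aln))] += 1
        _, counts = divergence_profile(alns)
        assert counts == expected
        assert counts["recent"] == 2  # d=0 pairs are exactly identical


def classify_age_value(corrected):
    from paralogkit.codon_divergence import FourDTvResult

    return classify_age(FourDTvResult(10, 0, 0.1, corrected, False))
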