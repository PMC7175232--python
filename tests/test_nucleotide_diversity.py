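import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import oracle_pairwise_diversity
from paralogkit.io_formats import VariantSite
from paralogkit.nucleotide_diversity import (
    AccessionGenotypeMatrix,
    effect_summary,
    filter_by_impact,
    pi_gene,
    read_genotype_matrix,
    shared_deleterious,
    site_heterozygosity,
)
from paralogkit.synthetic_data import (
    PanelConfig,
    assign_effects,
    simulate_snp_panel,
    write_panel_vcf,
)


def site(pos, counts, impact="unknown", effect="", deleterious=None):
    n = sum(counts.values())
    return VariantSite("chr4", pos, "A", "T", counts, n, impact, effect, deleterious)


class TestSiteHeterozygosity:
    def test_balanced_four_samples(self):
        assert site_heterozygosity(site(1, {"A": 2, "T": 2})) == pytest.approx(2 / 3)

    def test_monomorphic_site_is_zero(self):
        assert site_heterozygosity(site(1, {"A": 4, "T": 0})) == pytest.approx(0.0)

    def test_smallest_sample(self):
        assert site_heterozygosity(site(1, {"A": 1, "T": 1})) == pytest.approx(1.0)

    def test_n_below_two_raises(self):
        with pytest.raises(ValueError):
            site_heterozygosity(site(1, {"A": 1}))

    @given(i=st.integers(1, 19), n=st.integers(2, 20))
    def test_equals_pairwise_difference_fraction(self, i, n):
        # (n/(n-1))(1 - sum p^2) == i(n-i) / C(n,2): same quantity, two routes
        if i >= n:
            return
        h = site_heterozygosity(site(1, {"A": n - i, "T": i}))
        assert h == pytest.approx(i * (n - i) / (n * (n - 1) / 2))


class TestPiGene:
    def test_per_segregating_site_mean(self):
        sites = [site(1, {"A": 2, "T": 2}), site(2, {"A": 3, "T": 1})]
        r = pi_gene(sites, 100, "per_segregating_site")
        assert r.pi == pytest.approx((2 / 3 + 1 / 2) / 2)

    def test_per_site_sum_over_length(self):
        sites = [site(1, {"A": 2, "T": 2}), site(2, {"A": 3, "T": 1})]
        r = pi_gene(sites, 100, "per_site")
        assert r.pi == pytest.approx((2 / 3 + 1 / 2) / 100)

    def test_zero_sites(self):
        assert pi_gene([], 100, "per_site").pi == 0.0
        assert pi_gene([], 100, "per_segregating_site").pi is None

    def test_bad_length_raises(self):
        with pytest.raises(ValueError):
            pi_gene([], 0, "per_site")

    def test_normalization_is_mandatory_and_checked(self):
        with pytest.raises(ValueError, match="normalization"):
            pi_gene([], 100, "per_bp")

    def test_decomposed_multiallelic_counted_once(self):
        counts = {"A": 2, "T": 1, "G": 1}
        duplicated = [
            VariantSite("chr4", 5, "A", "T", counts, 4),
            VariantSite("chr4", 5, "A", "G", counts, 4),
        ]
        r = pi_gene(duplicated, 100, "per_site")
        assert r.n_snps == 1
        assert r.pi == pytest.approx(site_heterozygosity(duplicated[0]) / 100)

    def test_site_order_permutation_invariant(self):
        sites = [site(p, {"A": 3, "T": 1}) for p in range(1, 6)]
        fwd = pi_gene(sites, 50, "per_site").pi
        rev = pi_gene(sites[::-1], 50, "per_site").pi
        assert fwd == rev

    def test_low_n_sites_excluded_and_counted(self):
        sites = [site(1, {"A": 2, "T": 2}), site(2, {"A": 1})]
        r = pi_gene(sites, 100, "per_site")
        assert r.n_snps == 1 and r.n_low_n_excluded == 1

    @pytest.mark.parametrize("n,theta", [(5, 0.02), (12, 0.01), (20, 0.02)])
    def test_sum_h_matches_all_pairs_brute_force(self, n, theta):
        sites, _ = simulate_snp_panel(PanelConfig(n_accessions=n, L=500, theta=theta, seed=n))
        if not sites:
            pytest.skip("empty draw")
        # explicit allele matrix: accessions x sites, derived carried by the first i
        matrix = [
            [1 if a < s.allele_counts[s.alt] else 0 for s in sites] for a in range(n)
        ]
        h_sum = sum(site_heterozygosity(s) for s in sites)
        assert h_sum == pytest.approx(oracle_pairwise_diversity(matrix), rel=1e-12)

    def test_matches_generator_truth_exactly(self):
        sites, truth_pi = simulate_snp_panel(
            PanelConfig(n_accessions=100, L=10_000, theta=0.005, seed=77)
        )
        assert pi_gene(sites, 10_000, "per_site").pi == pytest.approx(truth_pi, rel=1e-12)


class TestImpactFilter:
    def make_panel(self):
        return [
            site(1, {"A": 3, "T": 1}, "MODERATE", "missense_variant"),
            site(2, {"A": 3, "T": 1}, "LOW", "synonymous_variant"),
            site(3, {"A": 3, "T": 1}, "HIGH", "stop_gained"),
            site(4, {"A": 3, "T": 1}, "MODIFIER", "intron_variant"),
            site(5, {"A": 3, "T": 1}, "unknown", ""),
        ]

    def test_default_keeps_moderate_and_high(self):
        kept = filter_by_impact(self.make_panel())
        assert [s.pos for s in kept] == [1, 3]

    def test_keep_all_classes_is_identity(self):
        panel = self.make_panel()
        kept = filter_by_impact(
            panel, keep={"HIGH", "MODERATE", "LOW", "MODIFIER", "unknown"}
        )
        assert kept == panel

    def test_effect_summary_counts(self):
        panel = self.make_panel()
        panel[0].deleterious = True
        s = effect_summary(panel, "g1")
        assert s.n_nonsynonymous == 1
        assert s.n_nonsense_or_frameshift == 1
        assert s.n_deleterious == 1
        assert sum(s.impact_counts.values()) == len(panel)

    def test_planted_annotation_answer_key(self):
        sites, _ = simulate_snp_panel(PanelConfig(n_accessions=30, L=3000, theta=0.02, seed=3))
        key = assign_effects(sites, "g1", seed=3)
        s = effect_summary(sites, "g1")
        assert s.n_nonsynonymous == key["missense"]
        assert s.n_nonsense_or_frameshift == key["nonsense"]
        assert s.impact_counts.get("LOW", 0) == key["synonymous"]


class TestSharedDeleterious:
    def mat(self, gene, accessions, carrier_cols):
        keys = [("c", i + 1, "T") for i in range(len(carrier_cols[0]) if carrier_cols else 0)]
        m = np.array(carrier_cols, dtype=np.int8).reshape(len(accessions), -1)
        return AccessionGenotypeMatrix(gene, accessions, keys[: m.shape[1]], m)

    def test_disjoint_carriers(self):
        a = self.mat("g1", ["x", "y"], [[1, 0], [0, 0]])
        b = self.mat("g2", ["x", "y"], [[0, 0], [1, 0]])
        assert shared_deleterious(a, b) == (False, [])

    def test_shared_carrier_listed(self):
        a = self.mat("g1", ["x", "y"], [[1, 0], [0, 0]])
        b = self.mat("g2", ["x", "y"], [[0, 1], [1, 0]])
        assert shared_deleterious(a, b) == (True, ["x"])

    def test_empty_variant_sets(self):
        a = AccessionGenotypeMatrix("g1", ["x"], [], np.zeros((1, 0), dtype=np.int8))
        b = AccessionGenotypeMatrix("g2", ["x"], [], np.zeros((1, 0), dtype=np.int8))
        assert shared_deleterious(a, b) == (False, [])

    def test_mismatched_accessions_raise(self):
        a = AccessionGenotypeMatrix("g1", ["x"], [], np.zeros((1, 0), dtype=np.int8))
        b = AccessionGenotypeMatrix("g2", ["y"], [], np.zeros((1, 0), dtype=np.int8))
        with pytest.raises(ValueError):
            shared_deleterious(a, b)

    def test_matrix_from_synthetic_vcf_matches_carrier_key(self, tmp_path):
        sites, _ = simulate_snp_panel(PanelConfig(n_accessions=8, L=1000, theta=0.03, seed=4))
        assert sites
        vcf = tmp_path / "p.vcf"
        carriers = write_panel_vcf(sites, vcf, gene_id="g1", contig_length=1000, seed=4)
        m = read_genotype_matrix(vcf, "1", 1, 1000, "g1")
        expected_carriers = {acc for acc, keys in carriers.items() if keys}
        assert m.carriers() == expected_carriers
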