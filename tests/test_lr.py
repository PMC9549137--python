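"""Likelihood-ratio indices: spec cases, exact identities, matrix agreement."""

import itertools
import math

import numpy as np
import pytest

from microkin import AlleleFrequencySet
from microkin.lr import (
    INDEX_HYPOTHESES,
    conditional_genotype_prob,
    genotype_prob,
    lr_index,
    lr_matrix,
    panel_log10_lr,
    transmission_prob,
)
from microkin.sim import GenotypePair, MutationModel, NO_MUTATION, n_genotypes
from oracles import pair_distribution


def _genotypes(alleles):
    return [tuple(sorted((a, b))) for a, b in itertools.combinations_with_replacement(alleles, 2)]


class TestConditionalGenotypeProb:
    def test_unrelated_is_marginal(self, toy_freqs3):
        for g1 in _genotypes(toy_freqs3.alleles):
            for g2 in _genotypes(toy_freqs3.alleles):
                assert conditional_genotype_prob(g2, g1, (1, 0, 0), toy_freqs3) == pytest.approx(
                    genotype_prob(g2, toy_freqs3)
                )

    def test_full_ibd_is_identity(self, toy_freqs3):
        for g1 in _genotypes(toy_freqs3.alleles):
            for g2 in _genotypes(toy_freqs3.alleles):
                expect = 1.0 if g1 == g2 else 0.0
                assert conditional_genotype_prob(g2, g1, (0, 0, 1), toy_freqs3) == expect

    def test_parent_child_transmission_enumeration(self, toy_freqs2):
        # g1 = AA at p = q = 0.5: child is AA or AB each with probability 0.5
        probs = {
            g2: conditional_genotype_prob(g2, ("A", "A"), (0, 1, 0), toy_freqs2)
            for g2 in _genotypes("AB")
        }
        assert probs[("A", "A")] == pytest.approx(0.5)
        assert probs[("A", "B")] == pytest.approx(0.5)
        assert probs[("B", "B")] == 0.0

    @pytest.mark.parametrize("label", ["unrelated", "parent_child", "full_sibling", "half_sibling", "first_cousin"])
    def test_sums_to_one(self, toy_freqs3, label):
        for g1 in _genotypes(toy_freqs3.alleles):
            total = sum(
                conditional_genotype_prob(g2, g1, label, toy_freqs3)
                for g2 in _genotypes(toy_freqs3.alleles)
            )
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_matches_pedigree_enumeration(self, toy_freqs3):
        # P(g1) * P(g2 | g1, k) must equal the exact pedigree-derived joint law
        for label in ("full_sibling", "half_sibling", "first_cousin"):
            dist = pair_distribution(dict(zip(toy_freqs3.alleles, toy_freqs3.vector())), label)
            for g1 in _genotypes(toy_freqs3.alleles):
                for g2 in _genotypes(toy_freqs3.alleles):
                    joint = genotype_prob(g1, toy_freqs3) * conditional_genotype_prob(
                        g2, g1, label, toy_freqs3
                    )
                    assert joint == pytest.approx(dist.get((g1, g2), 0.0), abs=1e-12), (label, g1, g2)

    def test_unknown_allele_errors(self, toy_freqs2):
        with pytest.raises(KeyError):
            conditional_genotype_prob(("A", "Z"), ("A", "A"), (1, 0, 0), toy_freqs2)


class TestLrIndex:
    def test_pi_compatible_pair(self, toy_freqs2):
        # PI(aa -> ab) = 1/(2p) = 1 at p = 0.5
        assert lr_index(("A", "A"), ("A", "B"), "PI", toy_freqs2) == pytest.approx(0.0)

    def test_pi_exclusion_is_minus_inf(self, toy_freqs2):
        assert lr_index(("A", "A"), ("B", "B"), "PI", toy_freqs2) == -math.inf

    def test_fsi_shared_homozygote(self, toy_freqs2):
        # FSI(aa, aa; p = 0.5) = 1/4 + 1/2 * (p/ p^2)/2 ... = 2.25 by enumeration
        assert 10 ** lr_index(("A", "A"), ("A", "A"), "FSI", toy_freqs2) == pytest.approx(2.25)

    def test_mutation_adjusted_pi_finite(self, toy_freqs2):
        mut = MutationModel("equal_probability", 1e-8)
        val = lr_index(("A", "A"), ("B", "B"), "PI", toy_freqs2, mut)
        assert -12 < val < -6

    def test_mu_to_zero_converges_to_classical(self, toy_freqs3):
        mut = MutationModel("equal_probability", 1e-8)
        for g1 in _genotypes(toy_freqs3.alleles):
            for g2 in _genotypes(toy_freqs3.alleles):
                classical = lr_index(g1, g2, "PI", toy_freqs3)
                adjusted = lr_index(g1, g2, "PI", toy_freqs3, mut)
                if math.isfinite(classical):
                    # relative error < 1e-6 on the LR itself
                    assert 10 ** adjusted == pytest.approx(10 ** classical, rel=1e-6)

    def test_fhsi_is_fsi_minus_hsi(self, toy_freqs3):
        for g1 in _genotypes(toy_freqs3.alleles):
            for g2 in _genotypes(toy_freqs3.alleles):
                fhsi = lr_index(g1, g2, "FHSI", toy_freqs3)
                fsi = lr_index(g1, g2, "FSI", toy_freqs3)
                hsi = lr_index(g1, g2, "HSI", toy_freqs3)
                assert fhsi == pytest.approx(fsi - hsi, abs=1e-12)

    @pytest.mark.parametrize("index_name", sorted(INDEX_HYPOTHESES))
    def test_expected_lr_under_hd_is_one(self, toy_freqs3, index_name):
        # sum over all ordered pairs of P(pair | Hd) * LR(pair) = 1 exactly
        hp, hd = INDEX_HYPOTHESES[index_name]
        mut = MutationModel("equal_probability", 1e-8) if index_name == "PI" else NO_MUTATION
        hd_dist = pair_distribution(dict(zip(toy_freqs3.alleles, toy_freqs3.vector())), hd)
        total = sum(
            w * 10 ** lr_index(g1, g2, index_name, toy_freqs3, mut)
            for (g1, g2), w in hd_dist.items()
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("index_name", sorted(INDEX_HYPOTHESES))
    def test_hp_distribution_normalised(self, toy_freqs3, index_name):
        hp, _ = INDEX_HYPOTHESES[index_name]
        hp_dist = pair_distribution(dict(zip(toy_freqs3.alleles, toy_freqs3.vector())), hp)
        assert sum(hp_dist.values()) == pytest.approx(1.0, abs=1e-12)

    def test_unknown_index(self, toy_freqs2):
        with pytest.raises(ValueError):
            lr_index(("A", "A"), ("A", "A"), "XYZ", toy_freqs2)


class TestPanelLr:
    def test_additivity(self, toy_panel):
        pair = GenotypePair(
            {"L1": ("A", "A"), "L2": ("A", "A")},
            {"L1": ("A", "B"), "L2": ("A", "A")},
            "parent_child",
        )
        total = panel_log10_lr(pair, "FSI", toy_panel)
        parts = sum(
            lr_index(pair.genotypes_a[l], pair.genotypes_b[l], "FSI", toy_panel[l])
            for l in toy_panel
        )
        assert total == pytest.approx(parts)

    def test_minus_inf_propagates(self, toy_panel):
        pair = GenotypePair(
            {"L1": ("A", "A"), "L2": ("A", "A")},
            {"L1": ("B", "B"), "L2": ("A", "A")},
            "parent_child",
        )
        assert panel_log10_lr(pair, "PI", toy_panel) == -math.inf

    def test_locus_mismatch_errors(self, toy_panel):
        pair = GenotypePair({"L1": ("A", "A")}, {"L1": ("A", "A")}, "unrelated")
        with pytest.raises(KeyError):
            panel_log10_lr(pair, "PI", toy_panel)


class TestLrMatrix:
    @pytest.mark.parametrize("index_name", sorted(INDEX_HYPOTHESES))
    def test_matrix_agrees_with_scalar(self, toy_freqs3, index_name):
        mut = MutationModel("equal_probability", 1e-8)
        mat = lr_matrix(index_name, toy_freqs3, mut)
        alleles = toy_freqs3.alleles
        genos = [(alleles[i], alleles[j]) for j in range(3) for i in range(j + 1)]
        assert mat.shape == (n_genotypes(3), n_genotypes(3))
        for gi, g1 in enumerate(genos):
            for gj, g2 in enumerate(genos):
                assert mat[gi, gj] == pytest.approx(
                    lr_index(g1, g2, index_name, toy_freqs3, mut), abs=1e-12
                )

    def test_reference_panel_matrices_finite_with_mutation(self, ref_freqs):
        mut = MutationModel("equal_probability", 1e-8)
        fs = ref_freqs["mh04zha032a"]  # the most allele-rich locus
        mat = lr_matrix("PI", fs, mut)
        assert np.isfinite(mat).all()
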