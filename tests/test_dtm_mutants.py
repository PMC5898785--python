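"""Decoding-time measure and synonymous variant design, with an exhaustive
enumeration oracle on short ORFs."""

import itertools

import numpy as np
import pytest

from rfmnet import (
    DTMWeights,
    GeneRecord,
    VariantRule,
    default_weights,
    design_variant,
    dtm,
    rates_from_orf,
    steady_state_chain,
)
from rfmnet.dtm_mutants import VARIANT_NAMES, _pick
from rfmnet.synthetic_genome import SYNONYMOUS_GROUPS


class TestDTM:
    def test_all_fastest_orf_scores_zero(self, toy_table):
        orf = [min(g, key=toy_table.tau) for g in SYNONYMOUS_GROUPS.values()] * 3
        assert dtm(orf, toy_table, default_weights(len(orf))) == 0.0

    def test_hand_computed_two_codon_example(self, toy_table):
        # eta = sum (tau_i - psi_i) w_i / K on a Leu codon (6 synonyms) and
        # a Met codon (single-codon group, zero excess)
        leu = max(SYNONYMOUS_GROUPS["L"], key=toy_table.tau)
        excess = toy_table.tau(leu) - min(toy_table.tau(c) for c in SYNONYMOUS_GROUPS["L"])
        orf = [leu, "ATG"]
        assert dtm(orf, toy_table, default_weights(2)) == pytest.approx(excess / 2)

    def test_linearity_in_weights(self, toy_table, reporter):
        w = default_weights(239)
        eta1 = dtm(reporter.orf, toy_table, w)
        eta2 = dtm(reporter.orf, toy_table, DTMWeights(2 * w.w))
        assert eta2 == pytest.approx(2 * eta1)

    def test_weight_length_mismatch_rejected(self, toy_table, reporter):
        with pytest.raises(ValueError):
            dtm(reporter.orf, toy_table, default_weights(10))


class TestWeights:
    def test_homogeneous_all_ones(self):
        assert default_weights(3).w == pytest.approx([1, 1, 1])

    def test_increasing_ramp_mean_one(self):
        w = default_weights(3, "increasing").w
        assert w == pytest.approx([0.5, 1.0, 1.5])
        for K in (2, 7, 100):
            ramp = default_weights(K, "increasing").w
            assert ramp.mean() == pytest.approx(1.0)
            assert np.all(np.diff(ramp) > 0)


class TestVariantDesign:
    def test_spd_tr_scores_zero_under_any_weights(self, toy_table, reporter):
        rule = VariantRule.built_in("SPD_TR", 239)
        fast = design_variant(reporter.orf, toy_table, rule)
        assert dtm(fast, toy_table, default_weights(239)) == 0.0
        assert dtm(fast, toy_table, default_weights(239, "increasing")) == 0.0

    def test_slw_tr_maximizes_dtm_by_exhaustive_enumeration(self, toy_table):
        """Brute force over all synonymous recodings of a 5-codon ORF."""
        orf = ["CTA", "GCA", "CGT", "ATG", "GGG"]
        slow = design_variant(orf, toy_table, VariantRule.built_in("SLW_TR", 5))
        w = default_weights(5)
        eta_slow = dtm(slow, toy_table, w)
        best = max(
            dtm(list(cand), toy_table, w)
            for cand in itertools.product(*(toy_table.synonyms(c) for c in orf))
        )
        assert eta_slow == pytest.approx(best)

    def test_eta_ordering_spd_le_any_le_slw(self, toy_table, reporter, rng):
        w = default_weights(239)
        spd = dtm(design_variant(reporter.orf, toy_table, VariantRule.built_in("SPD_TR", 239)), toy_table, w)
        slw = dtm(design_variant(reporter.orf, toy_table, VariantRule.built_in("SLW_TR", 239)), toy_table, w)
        assert spd == 0.0
        for name in ("HIGH_RD", "LOW_RD", "MDN_RD"):
            v = design_variant(reporter.orf, toy_table, VariantRule.built_in(name, 239))
            assert spd <= dtm(v, toy_table, w) <= slw

    def test_protein_sequence_preserved_and_idempotent(self, toy_table, reporter):
        from Bio.Data.CodonTable import standard_dna_table

        aa = [standard_dna_table.forward_table[c] for c in reporter.orf]
        for name in VARIANT_NAMES:
            rule = VariantRule.built_in(name, 239)
            v = design_variant(reporter.orf, toy_table, rule)
            assert [standard_dna_table.forward_table[c] for c in v] == aa
            assert design_variant(v, toy_table, rule) == v

    def test_high_rd_boundaries_match_chain_sites_for_239(self, toy_table, reporter):
        """Region split 1-119 fast / 120-239 slow; codon 120 is the first
        codon of the piece feeding lambda_12 in the q=10 partition."""
        rule = VariantRule.built_in("HIGH_RD", 239)
        assert rule.region_map[0][0] == (1, 119)
        assert rule.region_map[1][0] == (120, 239)
        # partition: first piece 9 codons (lambda_0), pieces of 10 after;
        # codons 120.. fall in piece index 12 onward -> lambda_12..lambda_23
        from rfmnet import partition_orf

        part = partition_orf(239)
        slices = part.codon_slices()
        assert slices[12].start == 119  # 0-based codon 119 == 1-based codon 120
        assert part.n == 23

    def test_median_pick_uses_lower_middle_for_even_groups(self, toy_table):
        codon = SYNONYMOUS_GROUPS["A"][0]  # alanine: 4 synonyms
        group = sorted(toy_table.synonyms(codon), key=toy_table.tau)
        assert _pick(toy_table, codon, "median") == group[1]

    def test_rule_length_mismatch_rejected(self, toy_table, reporter):
        with pytest.raises(ValueError):
            design_variant(reporter.orf, toy_table, VariantRule.built_in("SPD_TR", 100))


class TestSteadyStateOrdering:
    def test_density_and_rate_orderings_on_shared_chassis(self, toy_table, reporter):
        """Traffic-jam design binds more ribosomes than traffic-flow design;
        all-fast translates faster than all-slow (same protein, alpha=0.8)."""
        results = {}
        for name in ("HIGH_RD", "LOW_RD", "SPD_TR", "SLW_TR"):
            orf = design_variant(reporter.orf, toy_table, VariantRule.built_in(name, 239))
            gene = GeneRecord("v", orf, 1.0, 0.8)
            _, R, rho = steady_state_chain(rates_from_orf(gene, toy_table), u=1.0)
            results[name] = (R, rho)
        assert results["HIGH_RD"][1] > results["LOW_RD"][1]
        assert results["SPD_TR"][0] > results["SLW_TR"][0]
        assert results["SPD_TR"][0] == max(r for r, _ in results.values())
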