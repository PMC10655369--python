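"""Instrument selection, clumping, strength and harmonization rules."""

import numpy as np
import pytest

from mrscreen import estimators
from mrscreen.instruments import (
    compute_strength,
    filter_strength,
    harmonize_pair,
    ld_clump,
    NoInstrumentsError,
    select_by_significance,
)
from mrscreen.summary_io import LDReference

from conftest import iset_from_pair, make_trait, make_variant


class TestSelection:
    def test_locus_wide_threshold_keeps_only_sub_threshold_records(self):
        trait = make_trait(
            [make_variant("rs1", p=1e-6), make_variant("rs2", pos=2_000_000, p=2e-5)]
        )
        kept = select_by_significance(trait, 1e-5)
        assert [r.variant_id for r in kept] == ["rs1"]

    def test_threshold_one_keeps_everything(self):
        trait = make_trait([make_variant("rs1", p=0.5), make_variant("rs2", p=0.99)])
        assert len(select_by_significance(trait, 1.0)) == 2

    def test_equal_p_ties_break_on_variant_id(self):
        trait = make_trait([make_variant("rsB", p=1e-6), make_variant("rsA", p=1e-6)])
        assert [r.variant_id for r in select_by_significance(trait, 1e-5)] == ["rsA", "rsB"]


class TestClumping:
    def test_greedy_rule_hand_trace(self):
        # v1 most significant; v2 correlated and within the window; v3 far away
        v1 = make_variant("v1", pos=100_000, p=1e-8)
        v2 = make_variant("v2", pos=200_000, p=1e-6)
        v3 = make_variant("v3", pos=9_000_000, p=1e-7)
        ld = LDReference()
        ld.set_r2("v1", "v2", 0.5)
        kept = ld_clump([v1, v3, v2], ld, r2_max=0.01, window_kb=5000)
        assert [v.variant_id for v in kept] == ["v1", "v3"]

    def test_independent_variants_all_kept(self):
        vs = [make_variant(f"v{i}", pos=i * 100_000, p=10**-(8 - i)) for i in range(3)]
        assert len(ld_clump(vs, LDReference(), 0.01, 5000)) == 3

    def test_perfect_proxy_of_index_removed_and_logged(self):
        v1 = make_variant("v1", pos=100_000, p=1e-8)
        v2 = make_variant("v2", pos=100_100, p=1e-7)
        ld = LDReference()
        ld.set_r2("v1", "v2", 1.0)
        log = []
        kept = ld_clump([v1, v2], ld, 0.01, 5000, log=log)
        assert [v.variant_id for v in kept] == ["v1"]
        assert log[0].reason == "clumped_with:v1"

    def test_window_is_chromosome_local(self):
        v1 = make_variant("v1", chrom="1", pos=100_000, p=1e-8)
        v2 = make_variant("v2", chrom="2", pos=100_000, p=1e-7)
        ld = LDReference()
        ld.set_r2("v1", "v2", 0.9)  # high r2 but different chromosome
        assert len(ld_clump([v1, v2], ld, 0.01, 5000)) == 2


class TestStrength:
    def test_f_formula_at_printed_anchor(self):
        # R2 = 0.01, N = 7824 -> F = 0.01 * 7822 / 0.99 = 79.01
        v = make_variant(eaf=0.5, beta=np.sqrt(0.02))  # R2 = 2*0.25*0.02 = 0.01
        r2, f, method = compute_strength([v], 7824)
        assert r2[0] == pytest.approx(0.01)
        assert f[0] == pytest.approx(79.01, abs=0.005)
        assert method[0] == "eaf"

    def test_eaf_convention(self):
        v = make_variant(eaf=0.5, beta=0.1)
        r2, _, _ = compute_strength([v], 7824)
        assert r2[0] == pytest.approx(0.005)

    def test_zero_beta_gives_zero_r2_and_f(self):
        v = make_variant(beta=0.0)
        r2, f, _ = compute_strength([v], 7824)
        assert r2[0] == 0.0 and f[0] == 0.0

    def test_zscore_fallback_when_eaf_missing(self):
        v = make_variant(eaf=None, beta=0.1, se=0.02)
        r2, _, method = compute_strength([v], 7824)
        z2 = 25.0
        assert r2[0] == pytest.approx(z2 / (z2 + 7822))
        assert method[0] == "zscore"

    def test_f_monotone_in_r2(self):
        vs = [make_variant(f"v{i}", eaf=0.5, beta=b) for i, b in enumerate([0.05, 0.1, 0.2])]
        _, f, _ = compute_strength(vs, 7824)
        assert np.all(np.diff(f) > 0)

    def test_weak_instruments_filtered_at_f_threshold(self):
        strong = make_variant("v1", eaf=0.5, beta=np.sqrt(0.02))  # F = 79
        weak = make_variant("v2", eaf=0.5, beta=0.04)  # R2 = 8e-4 -> F ~ 6.3
        log = []
        kept = filter_strength([strong, weak], 7824, 10.0, log=log)
        assert [v.variant_id for v in kept] == ["v1"]
        assert log[0].reason == "weak_instrument"

    def test_f_min_zero_keeps_all(self):
        vs = [make_variant("v1", beta=0.01), make_variant("v2", beta=0.02)]
        assert len(filter_strength(vs, 7824, 0.0)) == 2


class TestHarmonization:
    def _outcome(self, **kw):
        return make_trait([make_variant(**kw)], trait_id="stroke")

    def test_swapped_alleles_negate_outcome_beta(self):
        exp = make_variant(ea="A", oa="G", beta=0.1)
        out = self._outcome(ea="G", oa="A", beta=0.05, eaf=0.3)
        iset = harmonize_pair([exp], out, 7824)
        assert iset.beta_out[0] == pytest.approx(-0.05)

    def test_strand_flip_complements_then_aligns(self):
        exp = make_variant(ea="A", oa="G", beta=0.1)
        out = self._outcome(ea="T", oa="C", beta=0.05)
        iset = harmonize_pair([exp], out, 7824)
        assert iset.beta_out[0] == pytest.approx(+0.05)

    def test_strand_flip_with_swap_negates(self):
        exp = make_variant(ea="A", oa="G", beta=0.1)
        out = self._outcome(ea="C", oa="T", beta=0.05)
        iset = harmonize_pair([exp], out, 7824)
        assert iset.beta_out[0] == pytest.approx(-0.05)

    @pytest.mark.parametrize("ea,oa", [("A", "T"), ("C", "G")])
    def test_palindromic_variants_dropped_unconditionally(self, ea, oa):
        exp = make_variant(ea=ea, oa=oa)
        out = self._outcome(ea=ea, oa=oa)
        with pytest.raises(NoInstrumentsError):
            harmonize_pair([exp], out, 7824)

    def test_exclusion_reasons_partition_removals(self):
        exps = [
            make_variant("rs1", ea="A", oa="G"),
            make_variant("rs2", ea="A", oa="T"),  # palindromic
            make_variant("rs3", ea="A", oa="G"),  # missing in outcome
            make_variant("rs4", ea="A", oa="G"),  # confounder list
            make_variant("rs5", ea="A", oa="G"),  # allele mismatch
        ]
        out = make_trait(
            [
                make_variant("rs1", ea="A", oa="G", beta=0.02),
                make_variant("rs2", ea="A", oa="T", beta=0.02),
                make_variant("rs5", ea="A", oa="C", beta=0.02),
            ],
            trait_id="stroke",
        )
        iset = harmonize_pair(exps, out, 7824, exclusion_list={"rs4"})
        assert list(iset.variant_id) == ["rs1"]
        reasons = {e.variant_id: e.reason for e in iset.exclusions}
        assert reasons == {
            "rs2": "palindromic",
            "rs3": "missing_in_outcome",
            "rs4": "confounder_associated",
            "rs5": "allele_mismatch",
        }
        # partition: each input either kept or logged exactly once
        assert len(iset.exclusions) + iset.n_snps == len(exps)

    def test_harmonization_is_idempotent(self):
        exps = [
            make_variant("rs1", ea="A", oa="G", beta=0.1),
            make_variant("rs2", ea="C", oa="T", beta=-0.2, pos=2_000_000),
        ]
        out = make_trait(
            [
                make_variant("rs1", ea="G", oa="A", beta=0.05, eaf=0.7),
                make_variant("rs2", ea="C", oa="T", beta=0.03, pos=2_000_000),
            ],
            trait_id="stroke",
        )
        first = harmonize_pair(exps, out, 7824)
        # rebuild an outcome table from the harmonized effects and redo
        harmonized_out = make_trait(
            [
                make_variant(
                    str(v),
                    ea=e.effect_allele,
                    oa=e.other_allele,
                    beta=float(b),
                    se=float(s),
                    pos=e.position,
                )
                for v, b, s, e in zip(
                    first.variant_id, first.beta_out, first.se_out, exps
                )
            ],
            trait_id="stroke",
        )
        second = harmonize_pair(exps, harmonized_out, 7824)
        np.testing.assert_allclose(second.beta_out, first.beta_out)
        np.testing.assert_allclose(second.beta_exp, first.beta_exp)

    def test_exposure_allele_recoding_leaves_estimates_unchanged(self):
        from mrscreen.synthetic import SimulationScenario, simulate_pair

        scen = SimulationScenario(n_snps=12, true_theta=0.3, seed=21)
        exp, out, _, _ = simulate_pair(scen)
        base = iset_from_pair(exp, out)
        # recode half the exposure variants: swap alleles, flip beta, 1-eaf
        recoded = []
        for i, rec in enumerate(exp.records.values()):
            if i % 2 == 0:
                rec = make_variant(
                    rec.variant_id,
                    chrom=rec.chromosome,
                    pos=rec.position,
                    ea=rec.other_allele,
                    oa=rec.effect_allele,
                    eaf=1 - rec.eaf,
                    beta=-rec.beta,
                    se=rec.se,
                    p=rec.p_value,
                    n=rec.n,
                )
            recoded.append(rec)
        flipped = harmonize_pair(recoded, out, 7824)
        for fn in (estimators.ivw, estimators.egger):
            assert fn(base).beta == pytest.approx(fn(flipped).beta, rel=1e-12)
        wm_a = estimators.weighted_median(base, n_boot=50, seed=1)
        wm_b = estimators.weighted_median(flipped, n_boot=50, seed=1)
        assert wm_a.beta == pytest.approx(wm_b.beta, rel=1e-12)
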