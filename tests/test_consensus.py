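"""Caller-consensus rules, background subtraction, homozygosity test,
recurrence, and pairwise overlap."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats

from mutscape.consensus import (
    ConsensusSet, binomial_screen, homozygosity_binomial_test,
    intersect_callers, pairwise_overlap, recurrence_table, remove_homozygous,
    subtract_background,
)
from mutscape.core_io import VariantCall, VariantKey


def _call(pos, ref="A", alt="G", zyg="het", caller="c1", plant="p1"):
    return VariantCall(plant, caller, "chr1", pos, ref, alt, zyg, (10, 10))


def _cset(plant, *positions, zyg="het"):
    calls = [_call(p, zyg=zyg, caller=None, plant=plant) for p in positions]
    return ConsensusSet(plant, calls, {c.key(): frozenset() for c in calls})


class TestIntersect:
    def test_snv_requires_all_three_callers(self):
        callsets = {"c1": [_call(100, caller="c1"), _call(200, caller="c1")],
                    "c2": [_call(100, caller="c2"), _call(200, caller="c2")],
                    "c3": [_call(100, caller="c3")]}
        cons = intersect_callers(callsets)
        assert [v.pos for v in cons.variants] == [100]
        assert cons.provenance[VariantKey("chr1", 100, "A", "G")] == \
               frozenset({"c1", "c2", "c3"})

    def test_indel_requires_two_callers(self):
        callsets = {"c1": [_call(50, "AT", "A", caller="c1")],
                    "c2": [],
                    "c3": [_call(50, "AT", "A", caller="c3")]}
        cons = intersect_callers(callsets)
        assert len(cons) == 1 and cons.variants[0].vtype == "indel"

    def test_disjoint_callsets_empty(self):
        callsets = {"c1": [_call(1, caller="c1")], "c2": [_call(2, caller="c2")],
                    "c3": [_call(3, caller="c3")]}
        assert len(intersect_callers(callsets)) == 0

    def test_zygosity_majority_vote_tie_is_het(self):
        callsets = {"c1": [_call(9, zyg="hom", caller="c1"),
                           _call(7, "AT", "A", zyg="hom", caller="c1")],
                    "c2": [_call(9, zyg="hom", caller="c2")],
                    "c3": [_call(9, zyg="het", caller="c3"),
                           _call(7, "AT", "A", zyg="het", caller="c3")]}
        cons = intersect_callers(callsets)
        by_pos = {v.pos: v.zygosity for v in cons.variants}
        assert by_pos[9] == "hom"   # 2-1 majority
        assert by_pos[7] == "het"   # 1-1 tie resolved het

    def test_duplicate_keys_deduplicated_with_warning(self, caplog):
        dup = [_call(5, caller="c1"), _call(5, caller="c1")]
        callsets = {"c1": dup, "c2": [_call(5, caller="c2")],
                    "c3": [_call(5, caller="c3")]}
        with caplog.at_level("WARNING"):
            cons = intersect_callers(callsets)
        assert len(cons) == 1
        assert any("duplicate" in r.message for r in caplog.records)

    def test_order_independent_and_idempotent(self):
        base = {"c1": [_call(1, caller="c1"), _call(2, caller="c1")],
                "c2": [_call(1, caller="c2"), _call(2, caller="c2")],
                "c3": [_call(2, caller="c3")]}
        a = intersect_callers(base)
        b = intersect_callers(dict(reversed(list(base.items()))))
        assert a.keys() == b.keys()

    def test_dialect_differences_reconciled_by_normalization(self):
        # the same deletion spelled three ways intersects to one key
        callsets = {"c1": [_call(10, "AT", "A", caller="c1")],
                    "c2": [_call(10, "ATT", "AT", caller="c2")],
                    "c3": []}
        cons = intersect_callers(callsets)
        assert len(cons) == 1


class TestBackground:
    def test_variant_in_any_background_plant_removed(self):
        target = _cset("p1", 100, 200)
        bg = [_cset(f"wt{i}", 999) for i in range(9)] + [_cset("wt9", 100)]
        out = subtract_background(target, bg)
        assert {v.pos for v in out.variants} == {200}

    def test_removal_ignores_zygosity(self):
        target = _cset("p1", 100, zyg="hom")
        out = subtract_background(target, [_cset("wt", 100, zyg="het")])
        assert len(out) == 0

    def test_self_subtraction_empty_and_empty_background_identity(self, caplog):
        target = _cset("p1", 1, 2, 3)
        assert len(subtract_background(target, [target])) == 0
        with caplog.at_level("WARNING"):
            out = subtract_background(target, [])
        assert out.keys() == target.keys()


class TestRecurrenceAndHom:
    def test_remove_homozygous(self):
        cs = ConsensusSet("p", [_call(1), _call(2, zyg="hom"), _call(3)])
        assert [v.pos for v in remove_homozygous(cs).variants] == [1, 3]

    def test_recurrence_counts(self):
        sets = {"a": _cset("a", 10, 20), "b": _cset("b", 10),
                "c": _cset("c", 10, 30)}
        tab = recurrence_table(sets).set_index("pos")
        assert tab.loc[10, "n_plants"] == 3
        assert tab.loc[20, "n_plants"] == 1
        assert tab.loc[30, "n_het"] == 1

    def test_shared_background_recurs_in_every_plant(self, noise_free_cohort):
        from mutscape.consensus import intersect_callers
        co = noise_free_cohort
        sets = {p: intersect_callers(co.dna_calls[p], genome=co.genome)
                for p in list(co.truth.entries)[:5]}
        tab = recurrence_table(sets)
        bg = co.truth.keys_for(list(co.truth.entries)[0], origins=["background"])
        hits = tab[tab.apply(lambda r: VariantKey(r["chrom"], r["pos"], r["ref"],
                                                  r["alt"]) in bg, axis=1)]
        assert (hits["n_plants"] == len(sets)).all()


class TestBinomialTest:
    def test_genotype_probabilities_at_half(self):
        # p = 0.5 -> P(hom) 0.25, P(het) 0.5, P(wt) 0.25; carriers see 1/3 hom
        res = homozygosity_binomial_test(25, 50, 25)
        assert res.p_hat == pytest.approx(0.5)
        q = res.p_hat / (2 - res.p_hat)
        assert q == pytest.approx(1 / 3)

    def test_hom_only_shared_locus_is_flagged(self):
        # 3 hom, 0 het among 57 plants: manual exact-tail oracle
        res = homozygosity_binomial_test(3, 0, 54)
        p_hat = (2 * 3) / (2 * 57)
        q = p_hat / (2 - p_hat)
        manual = sum(math.comb(3, k) * q**k * (1 - q) ** (3 - k)
                     for k in range(3, 4))
        assert res.pvalue == pytest.approx(manual)
        assert res.pvalue < 0.01

    def test_exact_tail_matches_summation_oracle(self):
        res = homozygosity_binomial_test(4, 6, 40)
        q = res.p_hat / (2 - res.p_hat)
        manual = sum(math.comb(10, k) * q**k * (1 - q) ** (10 - k)
                     for k in range(4, 11))
        assert res.pvalue == pytest.approx(manual, rel=1e-12)

    def test_no_carriers_rejected(self):
        with pytest.raises(ValueError):
            homozygosity_binomial_test(0, 0, 10)

    def test_type_one_error_controlled_under_null(self):
        # genotypes drawn from the null p^2 / 2p(1-p) / (1-p)^2 model
        rng = np.random.default_rng(42)
        p, n_plants, n_loci, alpha = 0.15, 57, 2000, 0.05
        probs = [p * p, 2 * p * (1 - p), (1 - p) ** 2]
        draws = rng.multinomial(n_plants, probs, size=n_loci)
        rejections = trials = 0
        for n_hom, n_het, n_wt in draws:
            if n_hom < 1:
                continue
            trials += 1
            if homozygosity_binomial_test(n_hom, n_het, n_wt).pvalue < alpha:
                rejections += 1
        rate = rejections / trials
        mc_sd = math.sqrt(alpha * (1 - alpha) / trials)
        assert rate <= alpha + 3 * mc_sd


class TestOverlap:
    def test_fifty_seven_plants_give_1596_comparisons(self):
        sets = {f"p{i:02d}": _cset(f"p{i:02d}", i + 1) for i in range(57)}
        _, n_cmp = pairwise_overlap(sets)
        assert n_cmp == 1596

    def test_disjoint_sets_share_nothing(self):
        sets = {"a": _cset("a", 1), "b": _cset("b", 2), "c": _cset("c", 3)}
        mat, _ = pairwise_overlap(sets)
        off = mat.values[~np.eye(3, dtype=bool)]
        assert (off == 0).all()

    def test_matrix_symmetric_and_counts_shared(self):
        sets = {"a": _cset("a", 1, 2, 3), "b": _cset("b", 2, 3, 4)}
        mat, n_cmp = pairwise_overlap(sets)
        assert n_cmp == 1
        assert mat.loc["a", "b"] == mat.loc["b", "a"] == 2
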