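"""Inference: descents, two-increasing splits, explanation enumeration,
reduction of recent duplications, and the brute-force oracle."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drrl import (
    InversionError,
    GeneContentError,
    brute_force_explanations,
    descents,
    explain_drrl,
    explain_tdrl,
    is_drrl_derivable,
    reduce_recent_duplications,
    samariscus_latus_order,
    simulate_drrl,
    simulate_tdrl,
    two_increasing_split,
)
from drrl.orders import GeneElement, GeneOrder
from drrl.simulate import COPY1, COPY2

from conftest import toy_order

# the rearranged segment of the observed order (ancestral indices between
# the CR and trnP), scanned top to bottom of the genome
SLATUS_BLOCK_ARRANGEMENT = [14, 15, 17, 20, 26, 30, 32, 33, 34, 35, 36,
                            9, 10, 11, 12, 13, 16, 18, 19, 21, 22, 23, 24,
                            25, 27, 28, 29, 31]


class TestDescents:
    def test_slatus_block_has_unique_descent(self):
        assert descents(SLATUS_BLOCK_ARRANGEMENT) == [10]

    def test_increasing_sequence_has_none(self):
        assert descents([1, 2, 3, 9]) == []

    def test_decreasing_sequence(self):
        assert descents([3, 2, 1]) == [0, 1]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 50), unique=True, max_size=12))
    def test_split_positions_agree_with_brute_force(self, seq):
        def increasing(s):
            return all(a < b for a, b in zip(s, s[1:]))

        expected = [i for i in range(len(seq) + 1)
                    if increasing(seq[:i]) and increasing(seq[i:])]
        assert two_increasing_split(seq) == expected


class TestTwoIncreasingSplit:
    def test_slatus_block_splits_into_11_and_17(self):
        splits = two_increasing_split(SLATUS_BLOCK_ARRANGEMENT)
        assert splits == [11]
        left = SLATUS_BLOCK_ARRANGEMENT[:11]
        right = SLATUS_BLOCK_ARRANGEMENT[11:]
        assert len(left) == 11 and len(right) == 17

    def test_increasing_admits_every_split(self):
        assert two_increasing_split([1, 2, 3]) == [0, 1, 2, 3]

    def test_no_split_with_two_descents(self):
        assert two_increasing_split([2, 1, 3, 2]) == []


class TestExplainDrrl:
    def test_stage_e_unique_remnant_supported_explanation(self, canon, stages):
        exps = explain_drrl(canon, stages["E"])
        assert exps
        supported = [e for e in exps if e.remnant_support]
        assert len(supported) == 1
        e = supported[0]
        assert e.event.insertion_edge == (("trnQ", None), ("trnM", None))
        assert e.event.duplicated_block[0] == "trnM"
        assert len(e.event.duplicated_block) == 29
        assert e.event.copy1_survivors == {
            "trnC", "trnY", "trnS1", "trnK", "trnR", "trnS2",
            "ND5", "ND6", "trnE", "CYTB", "trnT"}

    def test_stage_e_cluster_sizes(self, canon, stages):
        e = [x for x in explain_drrl(canon, stages["E"]) if x.remnant_support][0]
        assert e.cluster_sizes() == (11, 18)
        assert e.cluster_sizes(exclude_trailing=True) == (11, 17)
        assert e.trailing_typical == 1  # trnP retains the typical position

    def test_identity_is_trivially_derivable_without_support(self, canon):
        exps = explain_drrl(canon, canon)
        edges = {e.event.insertion_edge for e in exps}
        assert len(edges) == 38  # every edge of the ancestral circle
        assert not any(e.remnant_support for e in exps)

    def test_inversion_flagged_not_explained(self, canon):
        els = list(canon.elements)
        i = canon.index_of("trnD")
        els[i] = GeneElement(label="trnD", strand="L", element_class="tRNA",
                             ancestral_index=18)
        with pytest.raises(InversionError, match="trnD"):
            explain_drrl(canon, GeneOrder(tuple(els)))

    def test_gene_content_mismatch_lists_labels(self, canon):
        truncated = GeneOrder(canon.elements[:-2])
        with pytest.raises(GeneContentError, match="trnP"):
            explain_drrl(canon, truncated)

    def test_round_trip_recovery_with_remnants(self, canon):
        derived, event = simulate_drrl(canon, (("trnI", None), ("trnQ", None)),
                                       seed=5)
        exps = explain_drrl(canon, derived, require_remnants=True)
        keys = {(e.event.insertion_edge, e.event.copy1_survivors) for e in exps}
        assert (event.insertion_edge, event.copy1_survivors) in keys


class TestExplainTdrl:
    def test_matches_forward_tdrl_simulation(self):
        toy = toy_order(6, with_cr=False)
        assignment = {f"g{i}": (COPY1 if i in (1, 3, 5) else COPY2)
                      for i in range(1, 7)}
        derived = simulate_tdrl(toy, [(f"g{i}", None) for i in range(1, 7)],
                                assignment)
        exps = explain_tdrl(toy, derived)
        full = [e for e in exps
                if e.event.block == ("g1", "g2", "g3", "g4", "g5", "g6")]
        assert any(e.event.copy1_survivors == {"g1", "g3", "g5"} for e in full)

    def test_stage_e_admits_tdrl_without_remnant_support(self, canon, stages):
        # TDRL can reproduce the same split structure, but carries no CR
        # bookkeeping, so it never gains remnant support
        exps = explain_tdrl(canon, stages["E"])
        assert exps
        assert not any(e.remnant_support for e in exps)

    def test_full_reversal_has_no_one_step_explanation(self):
        toy = toy_order(4, with_cr=False)
        rev = GeneOrder(tuple(reversed(toy.elements)))
        assert explain_tdrl(toy, rev) == []


class TestReduceRecentDuplications:
    def test_slatus_two_candidates(self, slatus):
        reductions = reduce_recent_duplications(slatus)
        assert len(reductions) == 2
        removed = {tuple(el.identity for el in seg) for seg, _ in reductions}
        assert (("CR", None), ("trnC", None), ("trnY", None)) in removed
        assert (("CR", "'"), ("trnC", "'"), ("trnY", "'")) in removed

    def test_no_repeats_yields_empty(self, canon):
        assert reduce_recent_duplications(canon) == []

    def test_exactly_one_reduction_is_derivable(self, canon, slatus, stages):
        derivable = []
        for seg, reduced in reduce_recent_duplications(slatus):
            derivable.append(is_drrl_derivable(canon, reduced))
        assert sorted(derivable) == [False, True]

    def test_derivable_reduction_is_stage_e_without_cr_remnant(
            self, canon, slatus, stages):
        good = next(red for seg, red in reduce_recent_duplications(slatus)
                    if is_drrl_derivable(canon, red))
        stage_e_genes = [el.identity for el in stages["E"].genes()]
        assert [el.identity for el in good.genes()] == stage_e_genes


class TestBruteForceOracle:
    def test_contains_generating_event(self):
        toy = toy_order(4)
        derived, event = simulate_drrl(toy, (("g2", None), ("g3", None)),
                                       seed=9)
        exps = brute_force_explanations(toy, derived, max_block=4)
        keys = {(e.event.insertion_edge, e.event.copy1_survivors) for e in exps}
        assert (event.insertion_edge, event.copy1_survivors) in keys

    def test_unreachable_order_yields_empty(self):
        # three descents in ancestral rank cannot come from one event
        toy = toy_order(6)
        els = [toy.elements[i] for i in (1, 0, 3, 2, 5, 4, 6)]
        shuffled = GeneOrder(tuple(els))
        assert brute_force_explanations(toy, shuffled, max_block=6) == []
        assert explain_drrl(toy, shuffled) == []

    def test_max_block_guard(self):
        toy = toy_order(8)
        with pytest.raises(ValueError, match="max_block"):
            brute_force_explanations(toy, toy, max_block=4)

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_exhaustive_agreement_on_all_permutations(self, n):
        """Fast enumeration and brute-force replay agree on every observed
        arrangement of a small circle, reachable or not."""
        import itertools

        toy = toy_order(n)
        for perm in itertools.permutations(range(n)):
            els = tuple(toy.elements[i] for i in perm) + (toy.elements[n],)
            observed = GeneOrder(els)
            fast = {e.key() for e in explain_drrl(toy, observed)}
            slow = {e.key() for e in
                    brute_force_explanations(toy, observed, max_block=n)}
            assert fast == slow
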