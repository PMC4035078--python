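"""Forward simulators: duplication/translocation, double replication,
random loss, and classic TDRL."""

import pytest

from drrl import (
    double_replication,
    duplicate_translocate,
    random_loss,
    samariscus_latus_order,
    simulate_drrl,
    simulate_tdrl,
)
from drrl.infer import slatus_loss_assignment
from drrl.orders import PRIME
from drrl.simulate import COPY1, COPY2, DEFAULT_CR_FATES

from conftest import toy_order

EDGE_QM = (("trnQ", None), ("trnM", None))


class TestDuplicateTranslocate:
    def test_cr_copy_between_q_and_m(self, canon):
        out = duplicate_translocate(canon, [("CR", None)], EDGE_QM)
        assert len(out) == 39
        i = out.index_of("trnQ")
        assert out.elements[i + 1].identity == ("CR", PRIME)
        assert out.elements[i + 2].label == "trnM"
        # the original CR is untouched at the typical position
        assert out.elements[out.index_of("trnP") + 1].identity == ("CR", None)

    def test_edge_inside_segment_rejected(self, canon):
        with pytest.raises(ValueError, match="inside"):
            duplicate_translocate(canon, [("trnF", None), ("rrnS", None)],
                                  (("trnF", None), ("rrnS", None)))

    def test_tandem_placement_at_segment_end(self, toy6):
        out = duplicate_translocate(toy6, [("g2", None)],
                                    (("g2", None), ("g3", None)))
        assert out.labels()[:4] == ("g1", "g2", "g2", "g3")

    def test_non_adjacent_edge_rejected(self, canon):
        with pytest.raises(ValueError, match="adjacency"):
            duplicate_translocate(canon, [("CR", None)],
                                  (("trnQ", None), ("trnW", None)))


class TestDoubleReplication:
    def test_29_gene_block_and_three_crs(self, canon):
        with_cri = duplicate_translocate(canon, [("CR", None)], EDGE_QM)
        state = double_replication(with_cri)
        assert len(state.block) == 29
        assert state.block[0] == "trnM" and state.block[-1] == "trnP"
        crs = [el for el in state.order if el.element_class == "CR"]
        assert [c.copy_tag for c in crs] == ["I", "II", "III"]
        assert len(state.order) == 8 + 1 + 29 + 1 + 29 + 1

    def test_each_block_gene_twice_same_relative_order(self, canon):
        with_cri = duplicate_translocate(canon, [("CR", None)], EDGE_QM)
        state = double_replication(with_cri)
        copy1 = [el.label for el in state.order if el.copy_tag == "1"]
        copy2 = [el.label for el in state.order if el.copy_tag == "2"]
        assert copy1 == copy2 == list(state.block)

    def test_empty_block_when_crs_adjacent(self, toy6):
        adjacent = duplicate_translocate(toy6, [("CR", None)],
                                         (("g6", None), ("CR", None)))
        state = double_replication(adjacent)
        assert state.block == ()
        assert sum(1 for el in state.order if el.element_class == "CR") == 3

    def test_toy_block_after_gene2(self):
        # hand simulation: CRI after g2 duplicates g3,g4,g5
        toy = toy_order(5)
        with_cri = duplicate_translocate(toy, [("CR", None)],
                                         (("g2", None), ("g3", None)))
        state = double_replication(with_cri)
        assert state.block == ("g3", "g4", "g5")
        assert state.upstream == ("g1", "g2")

    def test_wrong_cr_count_rejected(self, canon):
        with pytest.raises(ValueError, match="2 CRs"):
            double_replication(canon)


class TestRandomLoss:
    def test_slatus_assignment_reproduces_cluster_structure(self, canon):
        with_cri = duplicate_translocate(canon, [("CR", None)], EDGE_QM)
        state = double_replication(with_cri)
        out, event = random_loss(state, slatus_loss_assignment(),
                                 cr_fates=dict(DEFAULT_CR_FATES))
        labels = out.labels()
        i = out.index_of("CR")
        cluster1 = labels[i + 1:i + 12]
        assert cluster1 == ("trnC", "trnY", "trnS1", "trnK", "trnR", "trnS2",
                            "ND5", "ND6", "trnE", "CYTB", "trnT")
        assert labels[i + 12] == "CRII-remnant"
        assert labels[-1] == "NC"

    def test_identity_loss_restores_pre_duplication_order(self, canon):
        with_cri = duplicate_translocate(canon, [("CR", None)], EDGE_QM)
        state = double_replication(with_cri)
        assignment = {g: COPY1 for g in state.block}
        out, _ = random_loss(state, assignment,
                             cr_fates={"CRI": "functional", "CRII": "lost",
                                       "CRIII": "lost"})
        # CRI keeps the translocated position; gene arrangement is unchanged
        expected = duplicate_translocate(canon, [("CR", None)], EDGE_QM)
        kept = [el for el in expected.elements if el.identity != ("CR", None)]
        assert [el.label for el in out] == [el.label for el in kept]

    def test_seeded_draw_is_reproducible(self, canon):
        with_cri = duplicate_translocate(canon, [("CR", None)], EDGE_QM)
        state = double_replication(with_cri)
        out1, ev1 = random_loss(state, seed=11)
        out2, ev2 = random_loss(state, seed=11)
        assert out1 == out2 and ev1.loss_assignment == ev2.loss_assignment
        out3, _ = random_loss(state, seed=12)
        assert out1 != out3  # overwhelmingly likely over 29 coins

    def test_incomplete_assignment_rejected(self, canon):
        with_cri = duplicate_translocate(canon, [("CR", None)], EDGE_QM)
        state = double_replication(with_cri)
        with pytest.raises(ValueError, match="missing"):
            random_loss(state, {"trnM": COPY1})


class TestSimulateDrrl:
    def test_paper_parameters_reach_stage_e(self, canon, stages):
        out, event = simulate_drrl(canon, EDGE_QM, slatus_loss_assignment())
        assert out == stages["E"]
        assert event.insertion_edge == EDGE_QM
        assert len(event.duplicated_block) == 29

    def test_all_copy2_keeps_gene_content(self, canon):
        out, _ = simulate_drrl(
            canon, EDGE_QM,
            {g: COPY2 for g in
             simulate_drrl(canon, EDGE_QM, seed=0)[1].duplicated_block})
        assert {el.identity for el in out.genes()} \
            == {el.identity for el in canon.genes()}

    def test_gene_content_conservation_and_strands(self, canon):
        for seed in range(10):
            out, _ = simulate_drrl(canon, EDGE_QM, seed=seed)
            obs = {el.identity: el.strand for el in out.genes()}
            anc = {el.identity: el.strand for el in canon.genes()}
            assert obs == anc  # each gene exactly once, strand untouched

    def test_survivor_clusters_strictly_increasing(self, canon):
        rank = {el.label: i for i, el in enumerate(canon.genes())}
        for seed in range(10):
            out, event = simulate_drrl(canon, EDGE_QM, seed=seed)
            labels = out.labels()
            i = labels.index("CR")
            j = labels.index("CRII-remnant")
            k = labels.index("NC")
            run1 = [rank[x] for x in labels[i + 1:j]]
            run2 = [rank[x] for x in labels[j + 1:k]]
            assert run1 == sorted(run1) and run2 == sorted(run2)
            assert sorted(labels[i + 1:j] + labels[j + 1:k]) \
                == sorted(event.duplicated_block)


class TestSimulateTdrl:
    def test_hand_simulated_tandem_array(self):
        toy = toy_order(6, with_cr=False)
        assignment = {f"g{i}": (COPY1 if i in (1, 3, 5) else COPY2)
                      for i in range(1, 7)}
        out = simulate_tdrl(toy, [(f"g{i}", None) for i in range(1, 7)],
                            assignment)
        assert out.labels() == ("g1", "g3", "g5", "g2", "g4", "g6")

    def test_all_copy1_is_identity(self, toy6):
        block = [(f"g{i}", None) for i in range(1, 7)]
        out = simulate_tdrl(toy6, block, {f"g{i}": COPY1 for i in range(1, 7)})
        assert out == toy6

    @pytest.mark.parametrize("copy", [COPY1, COPY2])
    def test_single_gene_block_is_identity(self, toy6, copy):
        out = simulate_tdrl(toy6, [("g3", None)], {"g3": copy})
        assert out == toy6

    def test_incomplete_assignment_rejected(self, toy6):
        with pytest.raises(ValueError, match="incomplete"):
            simulate_tdrl(toy6, [("g1", None), ("g2", None)], {"g1": COPY1})


def test_slatus_reconstruction_stages(stages, slatus):
    assert len(stages) == 6
    assert len(stages["A"]) == 38
    assert len(stages["B"]) == 39
    assert len(stages["D"]) == 69
    assert stages["F"] == slatus
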