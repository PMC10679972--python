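"""Parsimony trees, branch classification and trunk enrichment."""

from __future__ import annotations

import numpy as np
import pytest

from spatial_ith import phylogeny as ph
from spatial_ith import variant_core as vc

from oracles import parsimony_score_bruteforce


def _matrix(values, taxa=None):
    values = np.asarray(values, dtype=np.uint8)
    if taxa is None:
        taxa = list(vc.REGIONS)[: values.shape[0] - 1] + ["normal"]
    chars = [("1", j + 1, "C", "T") for j in range(values.shape[1])]
    return vc.BinaryCharacterMatrix(taxa=taxa, characters=chars, values=values)


class TestClassifyBranches:
    def test_basic_classes(self):
        m = _matrix(
            [
                [1, 1, 0],  # PT_sup
                [1, 0, 0],  # PT_deep
                [1, 1, 1],  # LN_met
                [0, 0, 0],  # normal
            ]
        )
        br = ph.classify_branches(m)
        assert br.classes[("1", 1, "C", "T")] == "trunk"
        assert br.classes[("1", 2, "C", "T")] == "shared"
        assert br.classes[("1", 3, "C", "T")] == "private"

    def test_planted_counts_recovered(self, genomics_result):
        frame = genomics_result.mutations
        records = [
            vc._record_from_row(row, line=i)
            for i, row in enumerate(frame.to_dict("records"))
        ]
        kept, _ = vc.filter_somatic(records)
        for patient in ("P000", "P007"):
            m = vc.build_presence_matrix(
                [r for r in kept if r.patient_id == patient]
            )
            counts = ph.classify_branches(m).counts
            planted = genomics_result.truth["planted_counts"]
            assert counts == planted
            # trunk count equals the all-ones-row count, tree-free
            tumor = m.values[:-1, :]
            assert counts["trunk"] == int((tumor.sum(axis=0) == 3).sum())


class TestWagnerParsimony:
    def test_perfect_phylogeny_score_and_trunk_length(self):
        # 4 trunk + 2 private(PT_sup) + 1 private(LN_met): no homoplasy
        values = np.zeros((4, 7), dtype=np.uint8)
        values[:3, :4] = 1
        values[0, 4:6] = 1
        values[2, 6] = 1
        tree = ph.wagner_parsimony(_matrix(values))
        assert tree.score == 7
        lengths = {
            tuple(sorted(l.taxon.label for l in e.head_node.leaf_iter())): e.length
            for e in tree.tree.preorder_edge_iter()
            if e.head_node is not tree.tree.seed_node
        }
        assert lengths[("LN_met", "PT_deep", "PT_sup")] == 4  # trunk
        assert lengths[("PT_sup",)] == 2
        assert lengths[("LN_met",)] == 1
        assert lengths[("normal",)] == 0

    def test_single_trunk_character(self):
        values = np.array([[1], [1], [1], [0]], dtype=np.uint8)
        tree = ph.wagner_parsimony(_matrix(values))
        assert tree.score == 1
        assert tree.branch_length_sum() == 1

    def test_matches_bruteforce_oracle_on_random_matrices(self, rng):
        for _ in range(30):
            n_taxa = int(rng.integers(3, 6))  # tumor taxa
            n_chars = int(rng.integers(5, 31))
            values = rng.integers(0, 2, size=(n_taxa, n_chars)).astype(np.uint8)
            values[0, values.sum(axis=0) == 0] = 1
            full = np.vstack([values, np.zeros((1, n_chars), dtype=np.uint8)])
            taxa = [f"R{i}" for i in range(n_taxa)] + ["normal"]
            m = _matrix(full, taxa=taxa)
            tree = ph.wagner_parsimony(m)
            oracle = parsimony_score_bruteforce(full, outgroup_index=n_taxa)
            assert tree.score == oracle
            assert tree.branch_length_sum() == tree.score

    def test_too_many_taxa_rejected(self):
        values = np.zeros((9, 1), dtype=np.uint8)
        values[:8, 0] = 1
        taxa = [f"R{i}" for i in range(8)] + ["normal"]
        with pytest.raises(ValueError, match="infeasible"):
            ph.wagner_parsimony(_matrix(values, taxa=taxa))


class TestNewick:
    def test_outgroup_first_and_round_trip(self):
        values = np.zeros((4, 5), dtype=np.uint8)
        values[:3, :3] = 1
        values[0, 3] = 1
        values[2, 4] = 1
        tree = ph.wagner_parsimony(_matrix(values))
        nwk = tree.newick
        assert nwk.startswith("(normal:0,")
        parsed = ph.parse_newick(nwk)
        assert {l.taxon.label for l in parsed.leaf_node_iter()} == {
            "normal",
            "PT_sup",
            "PT_deep",
            "LN_met",
        }
        total = sum(
            e.length
            for e in parsed.preorder_edge_iter()
            if e.length is not None
        )
        assert total == tree.score

    def test_branch_length_conservation_on_random_trees(self, rng):
        for _ in range(10):
            values = rng.integers(0, 2, size=(3, 20)).astype(np.uint8)
            values[0, values.sum(axis=0) == 0] = 1
            full = np.vstack([values, np.zeros((1, 20), dtype=np.uint8)])
            tree = ph.wagner_parsimony(_matrix(full))
            assert tree.branch_length_sum() == tree.score


class TestDriverTrunkEnrichment:
    @staticmethod
    def _branches(n_dt, n_db, n_ot, n_ob):
        classes = {}
        flags = {}
        i = 0
        for n, cls, drv in [
            (n_dt, "trunk", True),
            (n_db, "private", True),
            (n_ot, "trunk", False),
            (n_ob, "private", False),
        ]:
            for _ in range(n):
                key = ("1", i + 1, "C", "T")
                classes[key] = cls
                flags[key] = drv
                i += 1
        return (
            ph.BranchAssignment(classes=classes, subsets={}),
            flags,
        )

    def test_balanced_table_p_one(self):
        branches, flags = self._branches(10, 10, 10, 10)
        props, p = ph.driver_trunk_enrichment(branches, flags)
        assert props["driver_trunk_proportion"] == pytest.approx(0.5)
        assert p == pytest.approx(1.0)

    def test_enriched_table_matches_enumeration(self):
        from oracles import fisher_2x2_exact_fraction

        branches, flags = self._branches(8, 2, 1, 5)
        _, p = ph.driver_trunk_enrichment(branches, flags)
        assert p == pytest.approx(
            fisher_2x2_exact_fraction([[8, 2], [1, 5]]), rel=1e-9
        )
        assert 0 < p <= 1

    def test_planted_trunk_bias_detected(self, genomics_result):
        """Pooled across the cohort, the planted driver truncal bias is significant."""
        truth = genomics_result.truth
        table = np.zeros((2, 2), dtype=int)
        classes_all = truth["branch_class"]
        for patient, flags in truth["driver"].items():
            for key, is_driver in flags.items():
                cls = classes_all[patient][key]
                table[0 if is_driver else 1, 0 if cls == "trunk" else 1] += 1
        from spatial_ith.stats import fisher_exact_2x2

        assert fisher_exact_2x2(table) < 0.05
        # and the driver trunk proportion exceeds the non-driver one
        assert table[0, 0] / table[0].sum() > table[1, 0] / table[1].sum()
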