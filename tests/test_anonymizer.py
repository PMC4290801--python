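import numpy as np
import pytest
from scipy import stats

from dpgenome import (
    Cut,
    PrivacyParams,
    StateError,
    ValidationError,
    anonymize,
    build_flat_taxonomy,
    initialize_root,
    laplace_noise,
    make_blocks,
    postprocess_counts,
    random_trace,
    select_candidate,
)
from dpgenome.errors import CoverageError

from conftest import (
    WORKED_FORCED_TRACE,
    WORKED_PARTITION,
    random_table,
    table_from_rows,
)


class TestPrivacyParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"epsilon": 0.0, "h": 1},
            {"epsilon": -1.0, "h": 1},
            {"epsilon": 1.0, "h": -1},
            {"epsilon": 1.0, "h": 1, "sensitivity": 2.0},
            {"epsilon": 1.0, "h": 1, "rounding": "weird"},
        ],
    )
    def test_invalid_params(self, kwargs):
        with pytest.raises(ValidationError):
            PrivacyParams(**kwargs)


class TestInitializeRoot:
    def test_single_partition_with_all_records(self, worked_table, flat_forest):
        tree = initialize_root(worked_table, flat_forest)
        items = tree.leaf_items()
        assert len(items) == 1
        labels, members = items[0]
        assert labels == ("Any", "Any", "Any", "Any")
        assert members.tolist() == list(range(10))
        assert tree.cut.is_valid()

    def test_empty_table_allowed(self, worked_table, flat_forest):
        empty = worked_table
        for rid in list(empty.record_ids):
            empty = empty.drop_record(rid)
        tree = initialize_root(empty, flat_forest)
        assert tree.leaf_items()[0][1].size == 0

    def test_coverage_failure_lists_values(self, worked_table, blocks4):
        other = table_from_rows(["TT GG TT GG TT GG TT GG"])
        forest = build_flat_taxonomy(other, blocks4)
        with pytest.raises(CoverageError) as exc:
            initialize_root(worked_table, forest)
        assert (0, "AG CC") in exc.value.uncovered


class TestSelectCandidate:
    def test_uniform_over_cut(self, flat_forest):
        """Each of the four roots drawn ~uniformly (chi-square GOF)."""
        rng = np.random.default_rng(123)
        counts = np.zeros(4)
        for _ in range(10_000):
            block, node = select_candidate(Cut(flat_forest), rng)
            counts[block] += 1
        _, p = stats.chisquare(counts)
        assert p > 0.001

    def test_exhausted_cut_returns_none(self, flat_forest):
        cut = Cut(flat_forest)
        for b, tree in enumerate(flat_forest.trees):
            cut.specialize(b, tree)
        assert select_candidate(cut, np.random.default_rng(0)) is None

    def test_seeded_selection_sequence_reproduces(self, flat_forest):
        t1 = random_trace(flat_forest, 4, 99)
        t2 = random_trace(flat_forest, 4, 99)
        assert t1 == t2 and len(t1) == 4


class TestSpecialize:
    def test_example_first_step_splits_root_in_two(self, worked_table, example_forest):
        tree = initialize_root(worked_table, example_forest)
        tree.specialize(1, "Any_2")
        items = dict(
            (labels, set(members.tolist())) for labels, members in tree.leaf_items()
        )
        # "CC GG" category covers {CC GG, CT GG}; "CT AG" covers {CT AG, TT AG}
        assert items[("Any", "CC GG", "Any", "Any")] == {0, 1, 2, 5, 7, 9}
        assert items[("Any", "CT AG", "Any", "Any")] == {3, 4, 6, 8}

    def test_forced_trace_reproduces_hand_partition(self, worked_table, flat_forest):
        tree = initialize_root(worked_table, flat_forest)
        for block, label in WORKED_FORCED_TRACE:
            tree.specialize(block, label)
        labels, counts = tree.counts()
        nonzero = {
            lab: int(c) for lab, c in zip(labels, counts) if c > 0
        }
        assert nonzero == WORKED_PARTITION
        assert len(labels) == 8  # full 4 x 2 product, empties retained

    def test_node_not_in_cut_is_a_state_error(self, worked_table, example_forest):
        tree = initialize_root(worked_table, example_forest)
        with pytest.raises(StateError):
            tree.specialize(1, "CC GG")  # child of an unspecialized root

    def test_disjoint_cover_after_every_specialization(self):
        """Leaf partitions always partition the record set exactly."""
        rng = np.random.default_rng(7)
        for trial in range(8):
            n = int(rng.integers(5, 300))
            m = int(rng.integers(2, 13))
            table = random_table(rng, n, m)
            blocks = make_blocks(m, int(rng.integers(1, m + 1)))
            forest = build_flat_taxonomy(table, blocks)
            keep_empty = bool(trial % 2)
            tree = initialize_root(table, forest, keep_empty=keep_empty)
            for _ in range(3):
                cand = select_candidate(tree.cut, rng)
                if cand is None:
                    break
                tree.specialize(*cand)
                members = np.concatenate([m for _, m in tree.leaf_items()])
                assert sorted(members.tolist()) == list(range(n))

    def test_membership_matches_group_by_oracle(self):
        """Leaf membership equals a brute-force group-by of records on
        their generalized labels under the cut."""
        from dpgenome import leaves_under

        rng = np.random.default_rng(21)
        for _ in range(10):
            n = int(rng.integers(2, 50))
            table = random_table(rng, n, 8)
            blocks = make_blocks(8, 2)
            forest = build_flat_taxonomy(table, blocks)
            trace = random_trace(forest, int(rng.integers(0, 5)), int(rng.integers(1000)))
            tree = initialize_root(table, forest)
            for b, lab in trace:
                tree.specialize(b, lab)
            # oracle: generalize each record independently via leaf->cut ancestor
            cut_nodes = [tree.cut.nodes(b) for b in range(blocks.n_blocks)]
            def generalized(i):
                out = []
                for b, (s, e) in enumerate(blocks.intervals):
                    value = " ".join(table.genotypes[i, s:e])
                    hits = [
                        nd for nd in cut_nodes[b] if value in set(leaves_under(nd))
                    ]
                    assert len(hits) == 1
                    out.append(hits[0].rendered)
                return tuple(out)
            expected = {}
            for i in range(n):
                expected.setdefault(generalized(i), set()).add(i)
            got = {
                lab: set(mem.tolist())
                for lab, mem in tree.leaf_items()
                if mem.size
            }
            assert got == expected


class TestLaplaceNoise:
    def test_moments_at_unit_scale(self):
        rng = np.random.default_rng(11)
        draws = laplace_noise(1.0, rng, size=100_000)
        assert abs(draws.mean()) < 0.02
        assert 1.9 < draws.var() < 2.1
        assert abs((draws < 0).mean() - 0.5) < 0.01  # symmetry

    def test_variance_scales_with_epsilon(self):
        rng = np.random.default_rng(12)
        draws = laplace_noise(1 / 10, rng, size=100_000)
        assert 0.02 * 0.8 < draws.var() < 0.02 * 1.2

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValidationError):
            laplace_noise(0.0, np.random.default_rng(0))


class TestAnonymize:
    def test_release_structure_matches_worked_example(self, worked_table,
                                                      example_forest):
        rel = anonymize(
            worked_table, example_forest,
            PrivacyParams(epsilon=1.0, h=2, seed=0),
            trace=[(1, "Any_2"), (3, "Any_4")],
        )
        assert [" ".join(r.generalized_values) for r in rel.rows] == [
            "Any CC GG Any AA CC",
            "Any CC GG Any AG CT",
            "Any CT AG Any AA CC",
            "Any CT AG Any AG CT",
        ]

    def test_near_zero_noise_recovers_true_counts(self, worked_table, flat_forest):
        rel = anonymize(
            worked_table, flat_forest,
            PrivacyParams(epsilon=1e6, h=2, seed=4, rounding="rounded_nonnegative"),
            trace=WORKED_FORCED_TRACE,
        )
        got = {
            r.generalized_values: r.rounded for r in rel.rows if r.rounded
        }
        assert got == WORKED_PARTITION

    def test_h0_single_row_expected_count_is_n(self, worked_table, flat_forest):
        rels = [
            anonymize(worked_table, flat_forest, PrivacyParams(epsilon=1.0, h=0, seed=s))
            for s in range(200)
        ]
        assert all(len(r.rows) == 1 for r in rels)
        mean = np.mean([r.rows[0].noisy_count for r in rels])
        # Laplace(1) noise: SE of the mean over 200 draws is 0.1
        assert abs(mean - worked_table.n_records) < 0.5

    def test_budget_ledger(self, worked_table, flat_forest):
        rel = anonymize(worked_table, flat_forest, PrivacyParams(epsilon=0.7, h=2, seed=0))
        budget = rel.metadata["budget"]
        assert budget["blocking"] == budget["taxonomy"] == budget["specialization"] == 0
        assert budget["noisy_counts"] == budget["total"] == 0.7

    def test_deterministic_given_seed(self, worked_table, flat_forest):
        params = PrivacyParams(epsilon=1.0, h=3, seed=77)
        assert anonymize(worked_table, flat_forest, params) == anonymize(
            worked_table, flat_forest, params
        )

    def test_leaf_count_lower_bound_with_binary_trees(self):
        """With all-binary trees and no early stop, rows >= 2^h."""
        rng = np.random.default_rng(3)
        gen = np.array(["AA", "AG"])[rng.integers(2, size=(40, 6))]
        table = table_from_rows([" ".join(row) for row in gen])
        forest = build_flat_taxonomy(table, make_blocks(6, 1))
        for h in range(1, 5):
            rel = anonymize(table, forest, PrivacyParams(epsilon=1.0, h=h, seed=h))
            assert not rel.metadata["early_stop"]
            assert len(rel.rows) >= 2**h

    def test_early_stop_when_candidates_exhausted(self, worked_table, flat_forest):
        rel = anonymize(worked_table, flat_forest, PrivacyParams(epsilon=1.0, h=10, seed=0))
        assert rel.metadata["early_stop"]
        assert rel.metadata["h_performed"] == 4  # flat forest: one step per block

    def test_data_derived_taxonomy_is_stamped_non_private(self, worked_table,
                                                          flat_forest, example_forest):
        rel_flat = anonymize(worked_table, flat_forest, PrivacyParams(epsilon=1, h=0, seed=0))
        rel_user = anonymize(worked_table, example_forest, PrivacyParams(epsilon=1, h=0, seed=0))
        assert rel_flat.metadata["taxonomy_private"] is False
        assert rel_user.metadata["taxonomy_private"] is True


class TestPostprocessCounts:
    def test_rounding_rules(self, worked_table, flat_forest):
        rel = anonymize(worked_table, flat_forest, PrivacyParams(epsilon=1, h=1, seed=1))
        rel.rows[0] = type(rel.rows[0])(rel.rows[0].generalized_values, -0.7)
        rel.rows[1] = type(rel.rows[1])(rel.rows[1].generalized_values, 2.5)
        out = postprocess_counts(rel, "rounded_nonnegative")
        assert out.rows[0].rounded == 0  # clamped
        assert out.rows[1].rounded == 2  # round-half-to-even
        assert out.rows[0].noisy_count == -0.7  # raw counts left intact

    def test_raw_mode_is_identity(self, worked_table, flat_forest):
        rel = anonymize(worked_table, flat_forest, PrivacyParams(epsilon=1, h=1, seed=1))
        assert postprocess_counts(rel, "raw") == rel

    def test_unknown_mode_rejected(self, worked_table, flat_forest):
        rel = anonymize(worked_table, flat_forest, PrivacyParams(epsilon=1, h=0, seed=0))
        with pytest.raises(ValidationError):
            postprocess_counts(rel, "ceil")
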