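import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lncwalk as lw
from lncwalk.networks import (
    PROV_BOTH,
    CoexpressionSource,
    read_coexpression,
    write_coexpression,
)

from _oracles import aggregate_direct, pcc_direct


def expr(rows, ids=None):
    rows = np.asarray(rows, dtype=float)
    ids = ids or [f"e{i}" for i in range(rows.shape[0])]
    conds = [f"c{j}" for j in range(rows.shape[1])]
    return lw.ExpressionProfiles(ids, conds, rows)


class TestPearsonSimilarity:
    def test_affine_copy_scores_one(self):
        base = [1.0, 2.0, 5.0, 3.0]
        net = lw.pearson_similarity(expr([base, [2 * x + 7 for x in base]]), top_k=None)
        assert net.matrix[0, 1] == pytest.approx(1.0)

    def test_negation_clamped_to_zero(self):
        base = [1.0, 2.0, 5.0, 3.0]
        net = lw.pearson_similarity(expr([base, [-x for x in base]]), top_k=None)
        assert net.matrix[0, 1] == 0.0

    def test_abs_mode_keeps_negative_magnitude(self):
        base = [1.0, 2.0, 5.0, 3.0]
        net = lw.pearson_similarity(
            expr([base, [-x for x in base]]), negative="abs", top_k=None
        )
        assert net.matrix[0, 1] == pytest.approx(1.0)

    def test_zero_variance_row_scores_zero(self):
        net = lw.pearson_similarity(
            expr([[1, 2, 3, 4], [5, 5, 5, 5], [2, 1, 4, 3]]), top_k=None
        )
        assert np.all(net.matrix[1] == 0) and np.all(net.matrix[:, 1] == 0)

    def test_matches_direct_covariance_oracle(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((4, 8))
        net = lw.pearson_similarity(expr(X), top_k=None)
        for i in range(4):
            for j in range(4):
                expected = 0.0 if i == j else max(0.0, pcc_direct(X[i], X[j]))
                assert abs(net.matrix[i, j] - expected) < 1e-12

    def test_affine_invariance_positive_slope(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((5, 7))
        scale = rng.uniform(0.5, 3.0, size=5)[:, None]
        shift = rng.uniform(-4, 4, size=5)[:, None]
        a = lw.pearson_similarity(expr(X), top_k=None)
        b = lw.pearson_similarity(expr(scale * X + shift), top_k=None)
        np.testing.assert_allclose(a.matrix, b.matrix, atol=1e-12)

    def test_top_k_sparsifies_and_stays_symmetric(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((10, 12))
        dense = lw.pearson_similarity(expr(X), top_k=None)
        sparse = lw.pearson_similarity(expr(X), top_k=2)
        assert np.allclose(sparse.matrix, sparse.matrix.T)
        assert (sparse.matrix > 0).sum() <= (dense.matrix > 0).sum()
        # surviving entries are unchanged
        mask = sparse.matrix > 0
        np.testing.assert_allclose(sparse.matrix[mask], dense.matrix[mask])

    def test_too_few_conditions_rejected(self):
        with pytest.raises(ValueError, match="conditions"):
            lw.pearson_similarity(expr([[1, 2], [2, 1]]))

    def test_single_entity_rejected(self):
        with pytest.raises(ValueError, match="2 entities"):
            lw.pearson_similarity(expr([[1, 2, 3, 4]]))


def src(label, **pairs):
    return CoexpressionSource(label, {("e", k): v for k, v in pairs.items()})


class TestAggregateCoexpression:
    def test_two_halves_give_three_quarters(self):
        agg = lw.aggregate_coexpression([src("a", p=0.5), src("b", p=0.5)])
        assert agg[("e", "p")] == pytest.approx(0.75)

    def test_negative_only_pair_is_absent(self):
        agg = lw.aggregate_coexpression([src("a", p=-0.3)])
        assert ("e", "p") not in agg

    def test_perfect_correlation_absorbs(self):
        agg = lw.aggregate_coexpression([src("a", p=1.0), src("b", p=0.4)])
        assert agg[("e", "p")] == pytest.approx(1.0)

    def test_out_of_range_names_source_and_pair(self):
        with pytest.raises(ValueError, match="bad.*'e'"):
            lw.aggregate_coexpression([src("bad", p=1.5)])

    def test_no_sources_rejected(self):
        with pytest.raises(ValueError):
            lw.aggregate_coexpression([])

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(
            # rounding keeps positive scores away from the underflow regime
            # where 1 - (1 - c) evaluates to exactly 0 in floats
            st.floats(min_value=-1, max_value=1, allow_nan=False).map(
                lambda v: round(v, 6)
            ),
            min_size=1,
            max_size=6,
        )
    )
    def test_matches_direct_product_and_stays_in_unit_interval(self, values):
        sources = [src(f"s{i}", p=v) for i, v in enumerate(values)]
        agg = lw.aggregate_coexpression(sources)
        expected = aggregate_direct(values)
        if expected is None:
            assert ("e", "p") not in agg
        else:
            assert agg[("e", "p")] == pytest.approx(expected, abs=1e-12)
            assert 0.0 < agg[("e", "p")] <= 1.0

    def test_order_invariant_and_monotone(self):
        base = [src("a", p=0.3), src("b", p=0.6)]
        fwd = lw.aggregate_coexpression(base)
        rev = lw.aggregate_coexpression(base[::-1])
        assert fwd == rev
        more = lw.aggregate_coexpression(base + [src("c", p=0.2)])
        assert more[("e", "p")] >= fwd[("e", "p")]


class TestAssembleAssociations:
    ids = (["e1", "e2"], ["p1", "p2"])

    def test_overlap_takes_max_and_flags_both(self):
        A = lw.assemble_associations(
            lw.EdgeList([("e1", "p1", 1.0)]),
            {("e1", "p1"): 0.8},
            *self.ids,
        )
        assert A.A[0, 0] == 1.0
        assert A.provenance[0, 0] == PROV_BOTH

    def test_threshold_excludes_weak_coexpression(self):
        A = lw.assemble_associations(
            lw.EdgeList([("e1", "p1", 1.0)]),
            {("e2", "p2"): 0.4},
            *self.ids,
            coexpr_threshold=0.5,
        )
        assert A.A[1, 1] == 0.0

    def test_weighted_mode_passes_through(self):
        A = lw.assemble_associations(
            lw.EdgeList([("e1", "p1", 1.0)]),
            {("e2", "p2"): 0.75},
            *self.ids,
            mode="weighted",
        )
        assert A.A[1, 1] == pytest.approx(0.75)

    def test_binary_mode_yields_zero_one_matrix(self):
        A = lw.assemble_associations(
            lw.EdgeList([("e1", "p2", 1.0)]),
            {("e2", "p1"): 0.9, ("e1", "p1"): 0.55},
            *self.ids,
        )
        assert set(np.unique(A.A)) <= {0.0, 1.0}

    def test_unknown_ids_skipped(self, caplog):
        with caplog.at_level("INFO"):
            A = lw.assemble_associations(
                lw.EdgeList([("e1", "p1", 1.0), ("ghost", "p1", 1.0)]),
                {},
                *self.ids,
            )
        assert A.A.sum() == 1.0

    def test_all_zero_is_an_error(self):
        with pytest.raises(ValueError, match="no nonzero"):
            lw.assemble_associations(
                lw.EdgeList([("ghost", "p1", 1.0)]), {}, *self.ids
            )


class TestBuildPartnerNet:
    def test_confidence_rescaling(self):
        net = lw.build_partner_net(
            lw.EdgeList([("p1", "p2", 900.0), ("p2", "p3", 450.0)]),
            confidence_cutoff=0.4,
        )
        i = {p: k for k, p in enumerate(net.ids)}
        assert net.matrix[i["p1"], i["p2"]] == pytest.approx(1.0)
        assert net.matrix[i["p2"], i["p3"]] == pytest.approx(0.5)

    def test_cutoff_removes_weak_edges(self):
        net = lw.build_partner_net(
            lw.EdgeList([("p1", "p2", 900.0), ("p2", "p3", 450.0)]),
            confidence_cutoff=0.6,
        )
        i = {p: k for k, p in enumerate(net.ids)}
        assert net.matrix[i["p2"], i["p3"]] == 0.0

    def test_binary_mode_sets_survivors_to_one(self):
        net = lw.build_partner_net(
            lw.EdgeList([("p1", "p2", 900.0), ("p2", "p3", 450.0)]),
            weight_mode="binary",
            confidence_cutoff=0.4,
        )
        assert set(np.unique(net.matrix)) <= {0.0, 1.0}
        assert net.matrix.sum() == 4.0  # two undirected edges

    def test_conflicting_duplicate_edge_rejected(self):
        with pytest.raises(ValueError, match="conflicting"):
            lw.build_partner_net(
                lw.EdgeList([("p1", "p2", 900.0), ("p2", "p1", 800.0)])
            )

    def test_empty_edge_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            lw.build_partner_net(lw.EdgeList([]))

    def test_extended_partner_universe_keeps_isolates(self):
        net = lw.build_partner_net(
            lw.EdgeList([("p1", "p2", 1.0)]), partner_ids=["p1", "p2", "p3"]
        )
        assert net.ids == ["p1", "p2", "p3"]
        assert np.all(net.matrix[2] == 0)


class TestCoexpressionIO:
    def test_round_trip(self, tmp_path):
        source = CoexpressionSource("s1", {("e1", "p1"): 0.5, ("e2", "p1"): -0.25})
        path = tmp_path / "s1.tsv"
        write_coexpression(source, path)
        back = read_coexpression(path, "s1")
        assert back.scores == pytest.approx(source.scores)

    def test_duplicate_pair_rejected(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("e1\tp1\t0.5\ne1\tp1\t0.6\n")
        with pytest.raises(ValueError, match="duplicate pair"):
            read_coexpression(path)
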