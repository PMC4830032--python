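import numpy as np
import pytest

from metapath_dti.features import (
    MetaPathFeaturizer,
    brute_force_commuting,
    brute_force_walk_count,
    compute_commuting,
    extract_features,
    rw_normalize,
)
from metapath_dti.metapaths import MetaPath, MetaPathStep, similarity_free
from metapath_dti.synthetic import random_hetnet

from conftest import net_from_rows


def mp(*tokens, mp_id="m"):
    return MetaPath(mp_id, tuple(MetaPathStep.parse(t) for t in tokens))


class TestCommuting:
    def test_similar_then_binds_counts(self, schema, catalog):
        """c1 reaches p1/p2 only through its similar neighbor c2."""
        net = net_from_rows(
            schema, [("A11", "c1", "c2"), ("A2", "c2", "p1"), ("A2", "c2", "p2")]
        )
        pc = compute_commuting(net, catalog["C1"]).toarray()
        c1, c2 = (net.registries["compound"].index(c) for c in ("c1", "c2"))
        p1, p2 = (net.registries["protein"].index(p) for p in ("p1", "p2"))
        assert pc[c1, p1] == 1 and pc[c1, p2] == 1
        # c2's only similar neighbor is c1, which binds nothing
        assert pc[c2, p1] == 0 and pc[c2, p2] == 0

    def test_shared_target_walks_allow_revisiting_the_start_link(self, schema, catalog):
        """Walk semantics: c1-p1-c1-p1 is a valid walk, so PC(c1,p1) = 2."""
        net = net_from_rows(
            schema, [("A2", "c1", "p1"), ("A2", "c2", "p1"), ("A2", "c2", "p2")]
        )
        c7 = catalog["C7"]
        pc = compute_commuting(net, c7).toarray()
        idx_c = net.registries["compound"].index
        idx_p = net.registries["protein"].index
        assert pc[idx_c("c1"), idx_p("p2")] == 1  # c1-p1-c2-p2
        assert pc[idx_c("c1"), idx_p("p1")] == 2  # c1-p1-c1-p1 and c1-p1-c2-p1
        assert pc[idx_c("c1"), idx_p("p1")] == brute_force_walk_count(net, c7, "c1", "p1")

    def test_zero_adjacency_annihilates(self, schema, catalog):
        net = net_from_rows(schema, [("A11", "c1", "c2")], preregister={"protein": ["p1"]})
        assert compute_commuting(net, catalog["C1"]).nnz == 0

    def test_length_one_path_equals_adjacency(self, toy_net):
        pc = compute_commuting(toy_net, mp("A2"))
        np.testing.assert_array_equal(pc.toarray(), toy_net.adjacency("A2").toarray())

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_walk_enumeration_oracle(self, schema, catalog, seed):
        """Sparse products equal explicit walk counting for all 51 meta-paths."""
        net = random_hetnet(seed=seed, n_per_type=8, density=0.2, schema=schema)
        for m in catalog:
            np.testing.assert_array_equal(
                compute_commuting(net, m).toarray(),
                brute_force_commuting(net, m).toarray(),
                err_msg=f"meta-path {m.id}",
            )

    def test_concatenation_decomposes_into_product(self, schema):
        net = random_hetnet(seed=3, n_per_type=10, density=0.25, schema=schema)
        whole = compute_commuting(net, mp("A2", "A2_rev", "A11", "A2"))
        left = compute_commuting(net, mp("A2", "A2_rev"))
        right = compute_commuting(net, mp("A11", "A2"))
        np.testing.assert_array_equal(whole.toarray(), (left @ right).toarray())

    def test_reversal_transposes(self, schema, catalog):
        net = random_hetnet(seed=4, n_per_type=8, density=0.2, schema=schema)
        for m in (catalog["C1"], catalog["C7"], catalog["C39"]):
            fwd = compute_commuting(net, m).toarray()
            rev = compute_commuting(net, m.reversed()).toarray()
            np.testing.assert_array_equal(fwd, rev.T, err_msg=m.id)

    def test_removing_a_link_never_increases_counts(self, schema, catalog):
        net = random_hetnet(seed=6, n_per_type=8, density=0.25, schema=schema)
        a2 = net.adjacency("A2").tocoo()
        c = net.registries["compound"].ids[a2.row[0]]
        p = net.registries["protein"].ids[a2.col[0]]
        smaller = net.remove_links("A2", [(c, p)])
        for m in catalog:
            before = compute_commuting(net, m).toarray()
            after = compute_commuting(smaller, m).toarray()
            assert (after <= before).all(), m.id


class TestRwNormalize:
    def test_rows_sum_to_one_or_zero(self, schema, catalog):
        net = random_hetnet(seed=7, n_per_type=10, density=0.2, schema=schema)
        rw = rw_normalize(compute_commuting(net, catalog["C1"]))
        sums = np.asarray(rw.sum(axis=1)).ravel()
        assert np.all((np.abs(sums - 1) < 1e-12) | (sums == 0))

    def test_example_row(self):
        import scipy.sparse as sp

        rw = rw_normalize(sp.csr_matrix(np.array([[3, 1, 0], [0, 0, 0], [0, 5, 0]])))
        np.testing.assert_allclose(
            rw.toarray(), [[0.75, 0.25, 0], [0, 0, 0], [0, 1.0, 0]]
        )

    def test_invariant_to_row_scaling(self, schema, catalog):
        net = random_hetnet(seed=8, n_per_type=8, density=0.2, schema=schema)
        pc = compute_commuting(net, catalog["C1"]).toarray()
        scaled = pc.copy()
        scaled[0] *= 7
        import scipy.sparse as sp

        np.testing.assert_allclose(
            rw_normalize(sp.csr_matrix(pc)).toarray(),
            rw_normalize(sp.csr_matrix(scaled)).toarray(),
        )


class TestExtractFeatures:
    @pytest.mark.parametrize(
        "simfree,measures,expected",
        [(False, ("PC", "RW"), 102), (False, ("PC",), 51), (True, ("PC",), 29)],
    )
    def test_feature_set_column_counts(self, schema, catalog, simfree, measures, expected):
        net = random_hetnet(seed=9, n_per_type=8, density=0.2, schema=schema)
        cat = similarity_free(catalog, schema) if simfree else catalog
        pairs = [("co0", "pr0"), ("co1", "pr2")]
        table = extract_features(net, cat, pairs, measures=measures)
        assert table.shape == (2, expected)

    def test_values_read_from_commuting_matrices(self, schema, catalog):
        net = random_hetnet(seed=10, n_per_type=8, density=0.2, schema=schema)
        table = extract_features(net, catalog, [("co0", "pr1")], measures=("PC",))
        for m in catalog:
            pc = compute_commuting(net, m)
            assert table.iloc[0][f"{m.id}_PC"] == pc[0, 1]

    def test_unregistered_pair_lists_offenders(self, schema, catalog):
        net = random_hetnet(seed=11, n_per_type=6, density=0.2, schema=schema)
        with pytest.raises(KeyError, match="ghost"):
            extract_features(net, catalog, [("ghost", "pr0")])

    def test_empty_pair_list(self, schema, catalog):
        net = random_hetnet(seed=11, n_per_type=6, density=0.2, schema=schema)
        table = extract_features(net, catalog, [], measures=("PC",))
        assert table.shape == (0, 51)


class TestFeaturizer:
    def test_transform_matches_extract(self, schema, catalog):
        net = random_hetnet(seed=12, n_per_type=8, density=0.2, schema=schema)
        pairs = [("co0", "pr0"), ("co3", "pr4")]
        fz = MetaPathFeaturizer(net, catalog, measures=("PC", "RW")).fit()
        arr = fz.transform(pairs)
        table = extract_features(net, catalog, pairs, measures=("PC", "RW"))
        np.testing.assert_allclose(arr, table.to_numpy())
        assert list(fz.get_feature_names_out()) == list(table.columns)

    def test_sklearn_param_protocol(self, schema, catalog):
        from sklearn.base import clone

        net = random_hetnet(seed=13, n_per_type=6, density=0.2, schema=schema)
        fz = MetaPathFeaturizer(net, catalog, measures=("PC",))
        cloned = clone(fz)
        assert cloned.get_params()["measures"] == ("PC",)
        with pytest.raises(RuntimeError):
            cloned.transform([("co0", "pr0")])
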