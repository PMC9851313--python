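"""Meta-path enumeration, restriction/sampling and tensorization."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, strategies as st

from muthene.autodiff import Tensor
from muthene.hetnet import HetNet
from muthene.metapath import (MetaPathInstance, Schema, TypeTransform,
                              enumerate_instances, export_instances,
                              restrict_and_sample_dtttd, tensorize)
from tests.conftest import random_hetnet


def brute_force_instances(net: HetNet, schema: Schema, end_drug: int):
    """Test every node tuple of the schema's length against the edge
    constraints — the independent oracle for enumerate_instances."""
    def dti(d, t):
        return (d, t) in net.dti_edges

    def ppi(a, b):
        return tuple(sorted((a, b))) in net.ppi_edges

    def dd(a, b):
        return tuple(sorted((a, b))) in net.dd_edges

    D, T = range(net.n_drugs), range(net.n_targets)
    e = end_drug
    found = set()
    if schema is Schema.DD:
        for s in D:
            if s != e and dd(s, e):
                found.add((s, e))
    elif schema is Schema.DTD:
        for s, t in product(D, T):
            if s != e and dti(s, t) and dti(e, t):
                found.add((s, t, e))
    elif schema is Schema.DTTD:
        for s, t1, t2 in product(D, T, T):
            if s != e and t1 != t2 and dti(s, t1) and ppi(t1, t2) and dti(e, t2):
                found.add((s, t1, t2, e))
    elif schema is Schema.DTTTD:
        for s, t1, t2, t3 in product(D, T, T, T):
            if (s != e and len({t1, t2, t3}) == 3 and dti(s, t1)
                    and ppi(t1, t2) and ppi(t2, t3) and dti(e, t3)):
                found.add((s, t1, t2, t3, e))
    return found


class TestEnumerate:
    def test_shared_target_example(self):
        net = HetNet(2, 1, dti_edges=frozenset({(0, 0), (1, 0)}),
                     ppi_edges=frozenset(), dd_edges=frozenset())
        inst = enumerate_instances(net, Schema.DTD, end_drug=1)
        assert [i.nodes for i in inst] == [(0, 0, 1)]

    def test_no_shared_targets_means_no_dtd(self):
        net = HetNet(2, 2, dti_edges=frozenset({(0, 0), (1, 1)}),
                     ppi_edges=frozenset(), dd_edges=frozenset())
        for e in range(2):
            assert enumerate_instances(net, Schema.DTD, e) == []

    def test_dd_instances_are_te_neighbors(self):
        net = HetNet(3, 1, dti_edges=frozenset(), ppi_edges=frozenset(),
                     dd_edges=frozenset({(1, 2)}))
        inst = enumerate_instances(net, Schema.DD, end_drug=2)
        assert [i.nodes for i in inst] == [(1, 2)]

    @pytest.mark.parametrize("schema", list(Schema))
    def test_matches_brute_force_oracle_on_random_networks(self, schema):
        rng = np.random.default_rng(42)
        for _ in range(15):
            net = random_hetnet(rng, n_drugs=6, n_targets=8, p=0.3)
            for e in range(net.n_drugs):
                got = {i.nodes for i in enumerate_instances(net, schema, e)}
                assert got == brute_force_instances(net, schema, e)

    def test_deterministic_lexicographic_order(self):
        rng = np.random.default_rng(5)
        net = random_hetnet(rng)
        inst = enumerate_instances(net, Schema.DTTD, 0)
        assert [i.nodes for i in inst] == sorted(i.nodes for i in inst)

    @given(st.integers(0, 10_000))
    def test_symmetric_schema_counts(self, seed):
        """DTD instances from a to b match those from b to a in count."""
        rng = np.random.default_rng(seed)
        net = random_hetnet(rng, n_drugs=5, n_targets=6, p=0.35)
        for a in range(net.n_drugs):
            for b in range(net.n_drugs):
                if a == b:
                    continue
                ab = sum(1 for i in enumerate_instances(net, Schema.DTD, b)
                         if i.start_drug == a)
                ba = sum(1 for i in enumerate_instances(net, Schema.DTD, a)
                         if i.start_drug == b)
                assert ab == ba


class TestRestrictAndSample:
    # random net with 10 DTTTD instances ending at drug 3, of which 7 pass
    # the middle-target restriction and 3 are removed
    def _net(self):
        return random_hetnet(np.random.default_rng(7), n_drugs=5,
                             n_targets=6, p=0.3)

    def test_middle_target_restriction(self):
        net = self._net()
        inst = enumerate_instances(net, Schema.DTTTD, 3)
        targeted = {t for (_, t) in net.dti_edges}
        assert any(i.nodes[2] not in targeted for i in inst)
        kept = restrict_and_sample_dtttd(inst, net, ratio=1.0, rng_seed=0)
        assert kept == [i for i in inst if i.nodes[2] in targeted]

    def test_ratio_one_is_pure_order_preserving_filter(self):
        net = self._net()
        inst = enumerate_instances(net, Schema.DTTTD, 3)
        kept = restrict_and_sample_dtttd(inst, net, 1.0, rng_seed=99)
        assert set(kept) <= set(inst)
        positions = [inst.index(i) for i in kept]
        assert positions == sorted(positions)

    def test_ceiling_count_and_seed_determinism(self):
        net = self._net()
        inst = [i for i in enumerate_instances(net, Schema.DTTTD, 3)
                if i.nodes[2] in {t for (_, t) in net.dti_edges}][:4]
        assert len(inst) == 4
        a = restrict_and_sample_dtttd(inst, net, 0.5, rng_seed=123)
        b = restrict_and_sample_dtttd(inst, net, 0.5, rng_seed=123)
        assert len(a) == 2  # ceil(0.5 * 4)
        assert a == b

    def test_single_instance_never_discarded(self):
        net = self._net()
        one = [i for i in enumerate_instances(net, Schema.DTTTD, 3)
               if i.nodes[2] in {t for (_, t) in net.dti_edges}][:1]
        assert len(one) == 1
        kept = restrict_and_sample_dtttd(one, net, 0.5, rng_seed=0)
        assert len(kept) == 1  # ceil(0.5 * 1)

    def test_wrong_schema_rejected(self):
        net = self._net()
        with pytest.raises(ValueError, match="DTTTD"):
            restrict_and_sample_dtttd(
                [MetaPathInstance(Schema.DTD, (0, 0, 1))], net, 1.0, 0)


class TestTensorize:
    def _transforms(self, n_drugs=3, n_targets=2, d=4, identity=False):
        rng = np.random.default_rng(0)
        tr = TypeTransform.create(n_drugs, n_targets, d, rng)
        if identity:
            tr.w_drug.data = np.eye(n_drugs, d)
            tr.w_target.data = np.eye(n_targets, d)
        return tr

    def test_identity_transform_recovers_one_hots(self):
        tr = self._transforms(identity=True)
        inst = [MetaPathInstance(Schema.DTD, (0, 1, 2))]
        t = tensorize(inst, tr)
        np.testing.assert_array_equal(t.values.data[0, 0], [1, 0, 0, 0])
        np.testing.assert_array_equal(t.values.data[0, 1], [0, 1, 0, 0])
        np.testing.assert_array_equal(t.values.data[0, 2], [0, 0, 1, 0])

    def test_shape_contract(self):
        tr = self._transforms()
        t = tensorize([MetaPathInstance(Schema.DTD, (0, 0, 1))], tr)
        assert t.values.shape == (1, 3, 4)

    def test_shared_nodes_give_identical_rows(self):
        tr = self._transforms()
        t = tensorize([MetaPathInstance(Schema.DTD, (0, 1, 2)),
                       MetaPathInstance(Schema.DTD, (1, 1, 2))], tr)
        np.testing.assert_array_equal(t.values.data[0, 1], t.values.data[1, 1])

    def test_permutation_equivariance(self):
        tr = self._transforms()
        insts = [MetaPathInstance(Schema.DTD, (0, 0, 2)),
                 MetaPathInstance(Schema.DTD, (0, 1, 2)),
                 MetaPathInstance(Schema.DTD, (1, 0, 2))]
        fwd = tensorize(insts, tr).values.data
        rev = tensorize(insts[::-1], tr).values.data
        np.testing.assert_array_equal(fwd, rev[::-1])

    def test_mixed_schema_or_empty_rejected(self):
        tr = self._transforms()
        with pytest.raises(ValueError):
            tensorize([], tr)
        with pytest.raises(ValueError, match="share"):
            tensorize([MetaPathInstance(Schema.DTD, (0, 0, 1)),
                       MetaPathInstance(Schema.DD, (0, 1))], tr)

    def test_index_exceeding_one_hot_length_rejected(self):
        tr = self._transforms(n_drugs=2)
        with pytest.raises(ValueError, match="one-hot"):
            tensorize([MetaPathInstance(Schema.DTD, (0, 0, 5))], tr)


def test_export_instances_writes_node_names(tmp_path):
    inst = [MetaPathInstance(Schema.DTD, (0, 1, 2))]
    out = tmp_path / "dtd.tsv"
    export_instances(inst, out, drug_names=["aspirin", "x", "ibuprofen"],
                     target_names=["COX1", "COX2"])
    assert out.read_text() == "aspirin\tCOX2\tibuprofen\n"
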