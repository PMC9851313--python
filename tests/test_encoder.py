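"""Aggregators, attention extractor, combiner and fingerprints."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from muthene.autodiff import Tensor
from muthene.encoder import (Aggregator, AggregatorOutput, CombinerParams,
                             GATParams, combine_metapaths, compute_ecfp6,
                             gat_attention_weights, gat_extract,
                             gat_extract_batch)
from muthene.metapath import InstanceTensor, Schema


def _tensor(data, schema=Schema.DTD):
    data = np.asarray(data, dtype=float)
    return InstanceTensor(values=Tensor(data),
                          instance_index=[None] * data.shape[0],
                          central_drug=0, schema=schema)


class TestAggregators:
    def test_bigru_dimensional_contract(self):
        rng = np.random.default_rng(0)
        agg = Aggregator("bigru", d_in=6, hidden=16, rng=rng)
        out = agg(_tensor(rng.standard_normal((5, 3, 6))))
        assert out.h_f.shape == (5, 32)
        assert out.h_l.shape == (5, 32)

    def test_identical_instances_get_identical_rows(self):
        rng = np.random.default_rng(1)
        agg = Aggregator("bigru", d_in=4, hidden=8, rng=rng)
        row = rng.standard_normal((3, 4))
        out = agg(_tensor(np.stack([row, row])))
        np.testing.assert_array_equal(out.h_f.data[0], out.h_f.data[1])

    def test_gru_variant_dims(self):
        rng = np.random.default_rng(2)
        agg = Aggregator("gru", d_in=4, hidden=8, rng=rng)
        out = agg(_tensor(rng.standard_normal((2, 3, 4))))
        assert out.h_f.shape == (2, 8)
        np.testing.assert_array_equal(out.h_f.data, out.h_l.data)

    def test_mean_variant_closed_form(self):
        rng = np.random.default_rng(3)
        agg = Aggregator("mean", d_in=4, hidden=8, rng=rng)
        v = np.array([1.0, -2.0, 0.5, 3.0])
        data = np.stack([np.tile(v, (3, 1))])  # all rows equal v
        out = agg(_tensor(data))
        np.testing.assert_allclose(out.h_f.data[0], v)   # mean of identical rows
        np.testing.assert_allclose(out.h_l.data[0], v)   # central node feature

    def test_mean_h_l_is_central_node_feature(self):
        rng = np.random.default_rng(4)
        agg = Aggregator("mean", d_in=2, hidden=4, rng=rng)
        data = np.array([[[1.0, 0.0], [0.0, 1.0], [5.0, 5.0]]])
        out = agg(_tensor(data))
        np.testing.assert_array_equal(out.h_l.data[0], [5.0, 5.0])

    def test_empty_set_signals_caller(self):
        rng = np.random.default_rng(5)
        agg = Aggregator("bigru", d_in=4, hidden=8, rng=rng)
        with pytest.raises(ValueError, match="no instances"):
            agg(_tensor(np.zeros((0, 3, 4))))

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            Aggregator("lstm", 4, 8, np.random.default_rng(0))


class TestGATExtract:
    def _agg(self, n, dim=10, seed=0):
        rng = np.random.default_rng(seed)
        return AggregatorOutput(h_f=Tensor(rng.standard_normal((n, dim))),
                                h_l=Tensor(rng.standard_normal((n, dim))))

    def test_single_instance_attention_is_one(self):
        agg = self._agg(1)
        gat = GATParams.create(10, 10, n_heads=2, d_head=4,
                               rng=np.random.default_rng(1))
        np.testing.assert_allclose(gat_attention_weights(agg, gat).data, [1.0])

    def test_equal_logits_give_uniform_weights(self):
        agg = self._agg(4)
        gat = GATParams.create(10, 10, 2, 4, np.random.default_rng(1))
        gat.a_m.data[:] = 0.0  # every logit 0
        np.testing.assert_allclose(gat_attention_weights(agg, gat).data,
                                   np.full(4, 0.25))

    def test_weights_sum_to_one(self):
        for seed in range(5):
            agg = self._agg(7, seed=seed)
            gat = GATParams.create(10, 10, 2, 4, np.random.default_rng(seed))
            assert abs(gat_attention_weights(agg, gat).data.sum() - 1.0) < 1e-6

    def test_head_concatenation_length(self):
        agg = self._agg(3)
        gat = GATParams.create(10, 10, n_heads=2, d_head=8,
                               rng=np.random.default_rng(1))
        assert gat_extract(agg, gat).shape == (16,)

    def test_permutation_invariance(self):
        agg = self._agg(5)
        gat = GATParams.create(10, 10, 2, 4, np.random.default_rng(1))
        base = gat_extract(agg, gat).data
        perm = np.array([3, 1, 4, 0, 2])
        shuffled = AggregatorOutput(h_f=Tensor(agg.h_f.data[perm]),
                                    h_l=Tensor(agg.h_l.data[perm]))
        np.testing.assert_allclose(gat_extract(shuffled, gat).data, base,
                                   atol=1e-12)

    def test_batch_matches_per_drug_composition(self):
        rng = np.random.default_rng(9)
        h_f = rng.standard_normal((6, 10))
        h_l = rng.standard_normal((6, 10))
        gat = GATParams.create(10, 10, 2, 4, np.random.default_rng(2))
        segs = [(0, 2), (2, 6)]
        batch = gat_extract_batch(
            AggregatorOutput(h_f=Tensor(h_f), h_l=Tensor(h_l)), gat, segs)
        for k, (lo, hi) in enumerate(segs):
            single = gat_extract(AggregatorOutput(h_f=Tensor(h_f[lo:hi]),
                                                  h_l=Tensor(h_l[lo:hi])), gat)
            np.testing.assert_allclose(batch.data[k], single.data, atol=1e-12)

    def test_single_instance_reduces_to_projected_feature(self):
        # with one instance the attention is trivially 1, so the output is
        # elu(h_f @ W) — checkable in closed form
        agg = self._agg(1)
        gat = GATParams.create(10, 10, 2, 4, np.random.default_rng(3))
        expect = agg.h_f.data[0] @ gat.w_heads.data
        expect = np.where(expect > 0, expect, np.exp(expect) - 1)
        np.testing.assert_allclose(gat_extract(agg, gat).data, expect,
                                   atol=1e-12)


class TestCombiner:
    def _embeddings(self, n_drugs=5, dim=8, seed=0, identical=False):
        rng = np.random.default_rng(seed)
        if identical:
            h = rng.standard_normal((n_drugs, dim))
            return {s: Tensor(h.copy()) for s in Schema}
        return {s: Tensor(rng.standard_normal((n_drugs, dim))) for s in Schema}

    def test_equal_importances_give_quarter_weights(self):
        emb = self._embeddings(identical=True)
        params = CombinerParams.create(8, d_attn=6, d_out=8,
                                       rng=np.random.default_rng(1))
        _, beta = combine_metapaths(emb, params, return_beta=True)
        np.testing.assert_allclose(beta.data, np.full(4, 0.25), atol=1e-12)

    def test_identical_embeddings_pass_through_convexly(self):
        emb = self._embeddings(identical=True)
        params = CombinerParams.create(8, 6, 8, np.random.default_rng(1))
        params.w_proj.data = np.eye(8)
        z = combine_metapaths(emb, params)
        common = emb[Schema.DTD].data
        np.testing.assert_allclose(z.data, np.maximum(common, 0.0), atol=1e-10)

    def test_beta_sums_to_one(self):
        for seed in range(10):
            emb = self._embeddings(seed=seed)
            params = CombinerParams.create(8, 6, 8, np.random.default_rng(seed))
            _, beta = combine_metapaths(emb, params, return_beta=True)
            assert abs(beta.data.sum() - 1.0) < 1e-6

    def test_missing_schema_rejected(self):
        emb = self._embeddings()
        del emb[Schema.DD]
        params = CombinerParams.create(8, 6, 8, np.random.default_rng(0))
        with pytest.raises(ValueError, match="missing"):
            combine_metapaths(emb, params)

    @given(st.integers(0, 1000))
    def test_outputs_finite_for_bounded_inputs(self, seed):
        rng = np.random.default_rng(seed)
        emb = {s: Tensor(rng.uniform(-10, 10, size=(4, 8))) for s in Schema}
        params = CombinerParams.create(8, 6, 8, rng)
        z = combine_metapaths(emb, params)
        assert np.all(np.isfinite(z.data))


class TestECFP6:
    def test_deterministic_and_correct_length(self):
        a = compute_ecfp6("CCO", n_bits=256)
        b = compute_ecfp6("CCO", n_bits=256)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (256,)
        assert set(np.unique(a)) <= {0, 1}

    def test_on_bits_match_toolkit_oracle(self):
        from rdkit import Chem
        from rdkit.Chem import AllChem
        mol = Chem.MolFromSmiles("CCO")
        ref = AllChem.GetMorganFingerprintAsBitVect(mol, 3, nBits=1024)
        ours = compute_ecfp6("CCO", n_bits=1024)
        assert set(np.flatnonzero(ours)) == set(ref.GetOnBits())

    def test_unparsable_smiles_names_the_drug(self):
        with pytest.raises(ValueError, match="thingamycin"):
            compute_ecfp6("not_a_molecule((", n_bits=64, drug="thingamycin")
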