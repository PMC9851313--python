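"""End-to-end model: encoder + AE head + TE head over a fixed network.

The model owns the trainable state (type transforms, per-schema
aggregators and attention extractors, the combiner, the cell projection
and both heads) and knows the static structure it operates on: the
meta-path instance sets of every drug, the chemical fingerprint matrix and
the cell-line expression matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, stack
from .encoder import Aggregator, AggregatorOutput, CombinerParams, GATParams, \
    combine_metapaths, gat_extract, gat_extract_batch
from .heads import AEHead, CellProjection, TEHead, bce_loss, mse_loss, total_loss
from .metapath import InstanceTensor, MetaPathInstance, Schema, TypeTransform

__all__ = ["ModelConfig", "MutheneModel"]


@dataclass
class ModelConfig:
    """Architecture and objective hyper-parameters.

    Dimensions follow the conventional desk-scale defaults; the loss
    weight ``alpha`` combines the synergy MSE and the AE BCE as
    alpha*MSE + (1-alpha)*BCE, with R = alpha/(1-alpha) the ratio swept on
    validation.  ``use_ae=False`` removes the AE head entirely (no BCE
    term, no AE input block to the regressor) — the single-task variant.
    """

    aggregator: str = "bigru"      # bigru | gru | mean
    d_prime: int = 64              # shared transformed node-feature dim
    hidden: int = 64               # GRU hidden size H
    n_heads: int = 8               # attention heads K
    d_head: int = 8                # per-head output dim
    d_attn: int = 32               # combiner attention dim
    d_drug: int | None = None      # z_drug dim; default K*d_head
    d_cell: int = 32               # cell-line embedding dim
    dnn_base_width: int = 2048     # first conic hidden layer width
    dnn_depth: int = 3             # number of conic hidden layers
    dropout: float = 0.5
    alpha: float = 0.5
    use_ae: bool = True
    leaky_slope: float = 0.01
    dd_threshold: float = 0.0      # synergy score cut for DD edges
    dtttd_ratio: float = 0.5       # DTTTD uniform sampling ratio
    score_type: str = "loewe"

    @property
    def emb_dim(self) -> int:
        return self.n_heads * self.d_head

    @property
    def z_drug_dim(self) -> int:
        return self.d_drug if self.d_drug is not None else self.emb_dim


class MutheneModel:
    """Trainable multi-task model bound to one network's instance sets."""

    def __init__(self, config: ModelConfig, n_drugs: int, n_targets: int,
                 instance_sets: dict[Schema, list[list[MetaPathInstance]]],
                 chem: np.ndarray, expression: np.ndarray, n_ae: int,
                 seed: int = 0):
        self.config = config
        self.n_drugs = n_drugs
        self.n_targets = n_targets
        self.n_ae = n_ae
        self.chem = Tensor(np.asarray(chem, dtype=float))
        self.expression = Tensor(np.asarray(expression, dtype=float))
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(seed + 1)

        c = config
        self.transforms = TypeTransform.create(n_drugs, n_targets, c.d_prime, rng)
        self.aggregators = {s: Aggregator(c.aggregator, c.d_prime, c.hidden, rng)
                            for s in Schema}
        self.gat = {s: GATParams.create(self.aggregators[s].dim_f,
                                        self.aggregators[s].dim_l,
                                        c.n_heads, c.d_head, rng, c.leaky_slope)
                    for s in Schema}
        self.combiner = CombinerParams.create(c.emb_dim, c.d_attn,
                                              c.z_drug_dim, rng)
        n_bits = chem.shape[1]
        d_int = c.z_drug_dim + n_bits
        self.d_integrated = d_int
        self.cell_proj = CellProjection.create(expression.shape[1], c.d_cell, rng)
        self.ae_head = AEHead.create(d_int, n_ae, rng) if c.use_ae else None
        te_in = 2 * d_int + c.d_cell + (n_ae if c.use_ae else 0)
        self.te_head = TEHead(te_in, c.dnn_base_width, c.dnn_depth,
                              c.dropout, rng)

        # static per-schema instance structure: stacked node-id arrays and
        # per-drug row segments into them
        self._segments: dict[Schema, list[tuple[int, int]]] = {}
        self._node_ids: dict[Schema, np.ndarray] = {}
        for s in Schema:
            per_drug = instance_sets[s]
            if len(per_drug) != n_drugs:
                raise ValueError("instance_sets must cover every drug")
            rows, segs, pos = [], [], 0
            for d, insts in enumerate(per_drug):
                for inst in insts:
                    if inst.end_drug != d:
                        raise ValueError("instance filed under wrong drug")
                rows.extend(inst.nodes for inst in insts)
                segs.append((pos, pos + len(insts)))
                pos += len(insts)
            self._segments[s] = segs
            self._node_ids[s] = (np.array(rows, dtype=int) if rows
                                 else np.zeros((0, len(s)), dtype=int))
        self.instance_sets = instance_sets

    # -- parameters ------------------------------------------------------

    def parameters(self) -> list[Tensor]:
        ps = self.transforms.params()
        for s in Schema:
            ps += self.aggregators[s].params() + self.gat[s].params()
        ps += self.combiner.params() + self.cell_proj.params()
        if self.ae_head is not None:
            ps += self.ae_head.params()
        ps += self.te_head.params()
        return ps

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state size mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch")
            p.data = np.asarray(a, dtype=float).copy()

    # -- forward ---------------------------------------------------------

    def _schema_tensor(self, schema: Schema) -> Tensor:
        """Stacked (N_total, L, d') feature tensor for all drugs' instances
        of one schema (embedding-lookup through the type transforms)."""
        from .hetnet import NodeType
        ids = self._node_ids[schema]
        cols = []
        for pos, nt in enumerate(schema.node_types):
            w = self.transforms.w_drug if nt is NodeType.DRUG else self.transforms.w_target
            cols.append(w[ids[:, pos]])
        return stack(cols, axis=1)

    def drug_embeddings(self, return_beta: bool = False):
        """Meta-path embeddings z_drug for every drug, (n_drugs, z_dim)."""
        schema_emb: dict[Schema, Tensor] = {}
        for s in Schema:
            segs = self._segments[s]
            null = self.combiner.null_embeddings[s]
            if self._node_ids[s].shape[0] == 0:
                schema_emb[s] = stack([null] * self.n_drugs, axis=0)
                continue
            feats = self._schema_tensor(s)  # (N, L, d')
            agg_all = self.aggregators[s].aggregate(
                InstanceTensor(values=feats, instance_index=[None] * feats.shape[0],
                               central_drug=-1, schema=s))
            occupied = [(d, seg) for d, seg in enumerate(segs) if seg[1] > seg[0]]
            emb = gat_extract_batch(agg_all, self.gat[s],
                                    [seg for _, seg in occupied])
            rows: list = [null] * self.n_drugs
            for k, (d, _) in enumerate(occupied):
                rows[d] = emb[k]
            schema_emb[s] = stack(rows, axis=0)
        return combine_metapaths(schema_emb, self.combiner,
                                 return_beta=return_beta)

    def integrated_embeddings(self) -> Tensor:
        """[z_drug ‖ z_chem] for every drug, (n_drugs, z_dim + n_bits)."""
        return concat([self.drug_embeddings(), self.chem], axis=1)

    def forward(self, drug_i: np.ndarray, drug_j: np.ndarray,
                cell: np.ndarray, training: bool = False,
                z_int: Tensor | None = None):
        """Predictions for a batch of (i, j, cell) triples.

        Returns ``(te_pred, p_ae)`` with ``p_ae=None`` for the no-AE
        variant.  ``z_int`` can carry precomputed integrated embeddings to
        share the encoder pass across uses.
        """
        if z_int is None:
            z_int = self.integrated_embeddings()
        z_i = z_int[np.asarray(drug_i, dtype=int)]
        z_j = z_int[np.asarray(drug_j, dtype=int)]
        z_cell = self.cell_proj(self.expression[np.asarray(cell, dtype=int)])
        p_ae = None
        if self.ae_head is not None:
            p_ae = self.ae_head.predict(z_i, z_j)
        te = self.te_head.predict(z_i, z_j, z_cell, p_ae,
                                  self._dropout_rng, training=training)
        return te, p_ae

    def loss(self, drug_i, drug_j, cell, targets, ae_labels,
             training: bool = True):
        """(l_total, l_mse, l_bce) on a batch; l_bce is None without AE head.

        With alpha == 1 the BCE term is dropped from the graph entirely,
        so the AE decoder receives no gradient at all (its probabilities
        still feed the regressor, as a constant).
        """
        te, p_ae = self.forward(drug_i, drug_j, cell, training=training)
        l_mse = mse_loss(te, np.asarray(targets, dtype=float))
        alpha = self.config.alpha
        if self.ae_head is None:
            return l_mse, l_mse, None
        if alpha >= 1.0:
            return l_mse, l_mse, None
        l_bce = bce_loss(p_ae, np.asarray(ae_labels, dtype=float))
        return total_loss(l_mse, l_bce, alpha), l_mse, l_bce
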