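"""Drug meta-path embedding: aggregation, attention extraction, combination.

For each schema the instance tensor is aggregated per instance by a
meta-path-specific sequence model (BiGRU by default); a graph-attention
extractor then softmax-weights the instances of each central drug and
produces a multi-head meta-path-specific embedding; a type-level attention
combiner fuses the four schema embeddings into the drug's meta-path
embedding, which is finally concatenated with its chemical fingerprint.

Aggregator variants
-------------------
``bigru``
    h_f = [forward final state ‖ backward final state] (dimension 2H);
    h_l = the BiGRU per-position output at the final (central-node)
    position.
``gru``
    Unidirectional: h_f = final state (dimension H); h_l = output at the
    final position (for a plain GRU these coincide).
``mean``
    Non-directional: h_f = position-wise mean of the instance's node
    features; h_l = the central node's own transformed feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, glorot, segment_attention, softmax, stack
from .metapath import InstanceTensor, Schema

__all__ = [
    "GRULayer", "Aggregator", "AggregatorOutput", "GATParams", "gat_extract",
    "gat_extract_batch", "gat_attention_weights", "CombinerParams",
    "combine_metapaths", "compute_ecfp6",
]


@dataclass
class AggregatorOutput:
    """Per-instance representations: h_f summarises the whole instance,
    h_l is the updated representation of its end/central node."""

    h_f: Tensor  # (n_instances, dim_f)
    h_l: Tensor  # (n_instances, dim_l)


class GRULayer:
    """Single-direction GRU scanned over the path positions."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.wx = glorot(rng, d_in, 3 * hidden)   # input -> [z | r | n]
        self.wh = glorot(rng, hidden, 3 * hidden)
        self.b = Tensor(np.zeros(3 * hidden), requires_grad=True)

    def params(self) -> list[Tensor]:
        return [self.wx, self.wh, self.b]

    def scan(self, xs: list[Tensor]) -> list[Tensor]:
        """xs: per-position feature matrices (n, d_in); returns the state
        after each position (the GRU's per-position outputs)."""
        H = self.hidden
        n = xs[0].shape[0]
        h = Tensor(np.zeros((n, H)))
        outs = []
        for x in xs:
            gx = x @ self.wx + self.b
            gh = h @ self.wh
            z = (gx[:, :H] + gh[:, :H]).sigmoid()
            r = (gx[:, H:2 * H] + gh[:, H:2 * H]).sigmoid()
            nn = (gx[:, 2 * H:] + r * gh[:, 2 * H:]).tanh()
            h = (1.0 - z) * nn + z * h
            outs.append(h)
        return outs


class Aggregator:
    """Meta-path-specific instance aggregator (one per schema)."""

    def __init__(self, variant: str, d_in: int, hidden: int,
                 rng: np.random.Generator):
        if variant not in ("bigru", "gru", "mean"):
            raise ValueError(f"unknown aggregator variant {variant!r}")
        self.variant = variant
        self.d_in = d_in
        self.hidden = hidden
        if variant == "bigru":
            self.fwd = GRULayer(d_in, hidden, rng)
            self.bwd = GRULayer(d_in, hidden, rng)
            self.dim_f = self.dim_l = 2 * hidden
        elif variant == "gru":
            self.fwd = GRULayer(d_in, hidden, rng)
            self.dim_f = self.dim_l = hidden
        else:
            self.dim_f = self.dim_l = d_in

    def params(self) -> list[Tensor]:
        if self.variant == "bigru":
            return self.fwd.params() + self.bwd.params()
        if self.variant == "gru":
            return self.fwd.params()
        return []

    def __call__(self, tensor: InstanceTensor) -> AggregatorOutput:
        return self.aggregate(tensor)

    def aggregate(self, tensor: InstanceTensor) -> AggregatorOutput:
        """Produce (h_f, h_l) for every instance in the tensor.

        Raises ``ValueError`` on an empty set — the caller substitutes the
        schema's null embedding for drugs without instances.
        """
        if tensor.n_instances == 0:
            raise ValueError("no instances to aggregate")
        vals = tensor.values  # (n, L, d')
        L = vals.shape[1]
        xs = [vals[:, t, :] for t in range(L)]
        if self.variant == "mean":
            h_f = vals.mean(axis=1)
            h_l = xs[-1]
            return AggregatorOutput(h_f=h_f, h_l=h_l)
        fwd_outs = self.fwd.scan(xs)
        if self.variant == "gru":
            return AggregatorOutput(h_f=fwd_outs[-1], h_l=fwd_outs[-1])
        bwd_outs = self.bwd.scan(xs[::-1])
        # final hidden state of each direction summarises the full path
        h_f = concat([fwd_outs[-1], bwd_outs[-1]], axis=1)
        # per-position output at the final position: the backward direction
        # has read only the central node there (its first step)
        h_l = concat([fwd_outs[-1], bwd_outs[0]], axis=1)
        return AggregatorOutput(h_f=h_f, h_l=h_l)


@dataclass
class GATParams:
    """Attention vector and multi-head projections for one schema."""

    a_m: Tensor        # (dim_l + dim_f,)
    w_heads: Tensor    # (dim_f, K * d_head)
    n_heads: int
    d_head: int
    leaky_slope: float = 0.01

    @classmethod
    def create(cls, dim_f: int, dim_l: int, n_heads: int, d_head: int,
               rng: np.random.Generator, leaky_slope: float = 0.01) -> "GATParams":
        return cls(a_m=glorot(rng, dim_l + dim_f),
                   w_heads=glorot(rng, dim_f, n_heads * d_head),
                   n_heads=n_heads, d_head=d_head, leaky_slope=leaky_slope)

    def params(self) -> list[Tensor]:
        return [self.a_m, self.w_heads]


def gat_extract(agg: AggregatorOutput, gat: GATParams) -> Tensor:
    """Meta-path-specific embedding of one central drug.

    The attention logit of instance i is LeakyReLU(a_m · [h_l,i ‖ h_f,i]);
    the weights are the softmax over the central drug's instances (its
    meta-path-based neighbours).  Each of the K heads projects h_f and
    sums it under those weights; the head outputs pass an ELU and are
    concatenated, giving a vector of length K·d_head.
    """
    if agg.h_f.shape[0] == 0:
        raise ValueError("gat_extract needs at least one instance")
    logits = concat([agg.h_l, agg.h_f], axis=1) @ gat.a_m  # (n,)
    alpha = softmax(logits.leaky_relu(gat.leaky_slope), axis=0)  # (n,)
    proj = agg.h_f @ gat.w_heads                  # (n, K*d_head)
    return (alpha @ proj).elu()                   # (K*d_head,)


def gat_attention_weights(agg: AggregatorOutput, gat: GATParams) -> Tensor:
    """The softmax attention weights over one central drug's instances
    (meta-path-based neighbours); sums to 1 by construction."""
    logits = concat([agg.h_l, agg.h_f], axis=1) @ gat.a_m
    return softmax(logits.leaky_relu(gat.leaky_slope), axis=0)


def gat_extract_batch(agg: AggregatorOutput, gat: GATParams,
                      segments) -> Tensor:
    """Meta-path-specific embeddings for many central drugs at once.

    ``segments`` lists the non-empty (lo, hi) instance-row ranges, one per
    central drug, into ``agg``.  Row k of the output equals
    :func:`gat_extract` applied to the k-th segment (the softmax is taken
    within each segment); the fused path exists because the per-drug
    composition dominates the training profile.
    """
    logits = (concat([agg.h_l, agg.h_f], axis=1) @ gat.a_m).leaky_relu(gat.leaky_slope)
    proj = agg.h_f @ gat.w_heads
    return segment_attention(logits, proj, segments).elu()


@dataclass
class CombinerParams:
    """Type-level semantic attention over the four schema embeddings."""

    q: Tensor                 # (d_attn,)
    w: Tensor                 # (emb_dim, d_attn)
    b: Tensor                 # (d_attn,)
    w_proj: Tensor            # (emb_dim, d_out)
    null_embeddings: dict = field(default_factory=dict)  # Schema -> (emb_dim,)

    @classmethod
    def create(cls, emb_dim: int, d_attn: int, d_out: int,
               rng: np.random.Generator) -> "CombinerParams":
        nulls = {s: glorot(rng, emb_dim) for s in Schema}
        return cls(q=glorot(rng, d_attn), w=glorot(rng, emb_dim, d_attn),
                   b=Tensor(np.zeros(d_attn), requires_grad=True),
                   w_proj=glorot(rng, emb_dim, d_out), null_embeddings=nulls)

    def params(self) -> list[Tensor]:
        return [self.q, self.w, self.b, self.w_proj,
                *self.null_embeddings.values()]


def combine_metapaths(embeddings: dict[Schema, Tensor],
                      params: CombinerParams,
                      return_beta: bool = False):
    """Fuse the four meta-path-specific embedding matrices into z_drug.

    ``embeddings`` maps every schema to an (n_drugs, emb_dim) matrix (rows
    of drugs without instances already hold the schema's null embedding).
    The importance of schema m is the mean over drug nodes of
    q · tanh(W h_i^m + b); a softmax over the four schemas yields weights
    β shared by all drugs (type-level attention); the weighted sum passes a
    ReLU projection.  Returns an (n_drugs, d_out) matrix.
    """
    missing = [s for s in Schema if s not in embeddings]
    if missing:
        raise ValueError(f"missing schema embeddings: {[s.value for s in missing]}")
    order = list(Schema)
    omegas = []
    for m in order:
        h = embeddings[m]                           # (n, emb_dim)
        scores = (h @ params.w + params.b).tanh() @ params.q  # (n,)
        omegas.append(scores.mean())
    beta = softmax(stack(omegas), axis=0)           # (4,)
    fused = None
    for k, m in enumerate(order):
        term = beta[k] * embeddings[m]
        fused = term if fused is None else fused + term
    z = (fused @ params.w_proj).relu()
    if return_beta:
        return z, beta
    return z


def compute_ecfp6(smiles: str, n_bits: int = 1024, drug: str | None = None) -> np.ndarray:
    """Morgan circular fingerprint of radius 3 as a dense 0/1 vector."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        who = f" for drug {drug!r}" if drug else ""
        raise ValueError(f"unparsable SMILES{who}: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=3, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.int64)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr
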