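"""Meta-path schemas, instance enumeration, sampling and tensorization.

Four schemas describe drug–drug interaction pathways over the
heterogeneous network:

* ``DTD``   — the start drug shares a protein target with the end drug;
* ``DTTD``  — the two drugs bind two targets that interact (PPI);
* ``DTTTD`` — the two targets are bridged by a third protein;
* ``DD``    — a direct therapeutic-effect relationship.

An *instance* is a concrete node sequence conforming to a schema and ending
at a given central drug.  Enumeration is exhaustive and deterministic
(lexicographic in node indices); instances never repeat a target node and
never start and end at the same drug.  DTTTD sets are first restricted —
the middle protein must itself be a drug target somewhere in the network —
and then uniformly subsampled, mirroring the heuristic that keeps the
exponential growth of length-5 paths in check.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor, stack
from .hetnet import HetNet, NodeType

__all__ = [
    "Schema", "MetaPathInstance", "InstanceTensor", "TypeTransform",
    "enumerate_instances", "restrict_and_sample_dtttd", "tensorize",
    "instances_for_all_drugs", "export_instances",
]


class Schema(enum.Enum):
    DTD = "DTD"
    DTTD = "DTTD"
    DTTTD = "DTTTD"
    DD = "DD"

    @property
    def node_types(self) -> tuple[NodeType, ...]:
        D, T = NodeType.DRUG, NodeType.TARGET
        return {
            Schema.DTD: (D, T, D),
            Schema.DTTD: (D, T, T, D),
            Schema.DTTTD: (D, T, T, T, D),
            Schema.DD: (D, D),
        }[self]

    @property
    def edge_types(self) -> tuple[str, ...]:
        return {
            Schema.DTD: ("dti", "dti"),
            Schema.DTTD: ("dti", "ppi", "dti"),
            Schema.DTTTD: ("dti", "ppi", "ppi", "dti"),
            Schema.DD: ("dd",),
        }[self]

    def __len__(self) -> int:
        return len(self.node_types)


@dataclass(frozen=True)
class MetaPathInstance:
    """One node sequence conforming to a schema; node types follow the
    schema position-wise, so ``nodes`` stores bare per-type indices."""

    schema: Schema
    nodes: tuple[int, ...]

    def __post_init__(self):
        if len(self.nodes) != len(self.schema):
            raise ValueError(
                f"{self.schema.value} instance needs {len(self.schema)} nodes, "
                f"got {len(self.nodes)}")

    @property
    def start_drug(self) -> int:
        return self.nodes[0]

    @property
    def end_drug(self) -> int:
        return self.nodes[-1]


def _adjacency(net: HetNet):
    drug_targets: dict[int, set[int]] = {d: set() for d in range(net.n_drugs)}
    target_drugs: dict[int, set[int]] = {t: set() for t in range(net.n_targets)}
    for d, t in net.dti_edges:
        drug_targets[d].add(t)
        target_drugs[t].add(d)
    ppi_nbrs: dict[int, set[int]] = {t: set() for t in range(net.n_targets)}
    for a, b in net.ppi_edges:
        ppi_nbrs[a].add(b)
        ppi_nbrs[b].add(a)
    dd_nbrs: dict[int, set[int]] = {d: set() for d in range(net.n_drugs)}
    for a, b in net.dd_edges:
        dd_nbrs[a].add(b)
        dd_nbrs[b].add(a)
    return drug_targets, target_drugs, ppi_nbrs, dd_nbrs


def enumerate_instances(net: HetNet, schema: Schema,
                        end_drug: int) -> list[MetaPathInstance]:
    """All instances of ``schema`` ending at ``end_drug``.

    Returns every conforming node sequence with distinct endpoint drugs and
    no repeated target node, sorted lexicographically by node indices.  An
    empty list is a valid result.
    """
    if not (0 <= end_drug < net.n_drugs):
        raise ValueError(f"end drug {end_drug} not in network")
    drug_targets, target_drugs, ppi_nbrs, dd_nbrs = _adjacency(net)
    e = end_drug
    out: list[tuple[int, ...]] = []
    if schema is Schema.DD:
        out = [(s, e) for s in dd_nbrs[e]]
    elif schema is Schema.DTD:
        for t in drug_targets[e]:
            for s in target_drugs[t]:
                if s != e:
                    out.append((s, t, e))
    elif schema is Schema.DTTD:
        for t2 in drug_targets[e]:
            for t1 in ppi_nbrs[t2]:
                if t1 == t2:
                    continue
                for s in target_drugs[t1]:
                    if s != e:
                        out.append((s, t1, t2, e))
    elif schema is Schema.DTTTD:
        for t3 in drug_targets[e]:
            for t2 in ppi_nbrs[t3]:
                if t2 == t3:
                    continue
                for t1 in ppi_nbrs[t2]:
                    if t1 in (t2, t3):
                        continue
                    for s in target_drugs[t1]:
                        if s != e:
                            out.append((s, t1, t2, t3, e))
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unknown schema {schema}")
    return [MetaPathInstance(schema, nodes) for nodes in sorted(out)]


def restrict_and_sample_dtttd(instances: list[MetaPathInstance], net: HetNet,
                              ratio: float, rng_seed: int) -> list[MetaPathInstance]:
    """Apply the DTTTD restriction, then uniform subsampling.

    The middle protein (position 3 of 5) must appear in at least one DTI
    edge — i.e. be a target of some drug in the network.  From the
    surviving instances, ``ceil(ratio * n)`` are drawn uniformly without
    replacement with a generator seeded by ``rng_seed``; the original
    (lexicographic) order is preserved in the output, so ``ratio=1.0`` is a
    pure filter.
    """
    if not 0.0 < ratio <= 1.0:
        raise ValueError(f"sampling ratio must be in (0, 1], got {ratio}")
    for inst in instances:
        if inst.schema is not Schema.DTTTD:
            raise ValueError(f"expected DTTTD instances, got {inst.schema.value}")
    targeted = {t for (_, t) in net.dti_edges}
    kept = [inst for inst in instances if inst.nodes[2] in targeted]
    if ratio >= 1.0 or not kept:
        return kept
    n_keep = int(np.ceil(ratio * len(kept)))
    rng = np.random.default_rng(rng_seed)
    chosen = np.sort(rng.choice(len(kept), size=n_keep, replace=False))
    return [kept[k] for k in chosen]


@dataclass
class TypeTransform:
    """Node-type-specific projections of one-hot features to a shared
    dimension d': row i of ``w_drug``/``w_target`` is the transformed
    feature of node i of that type (one-hot times the trainable matrix)."""

    w_drug: Tensor    # (n_drugs, d_prime)
    w_target: Tensor  # (n_targets, d_prime)

    @classmethod
    def create(cls, n_drugs: int, n_targets: int, d_prime: int,
               rng: np.random.Generator) -> "TypeTransform":
        from .autodiff import glorot
        return cls(w_drug=glorot(rng, n_drugs, d_prime),
                   w_target=glorot(rng, n_targets, d_prime))

    @property
    def d_prime(self) -> int:
        return self.w_drug.shape[1]

    def params(self) -> list[Tensor]:
        return [self.w_drug, self.w_target]


@dataclass
class InstanceTensor:
    """3-D feature array for one drug's instance set of one schema: axes
    (instance, position-in-path, shared feature dimension d')."""

    values: Tensor
    instance_index: list[MetaPathInstance]
    central_drug: int
    schema: Schema

    @property
    def n_instances(self) -> int:
        return len(self.instance_index)


def tensorize(instances: list[MetaPathInstance],
              transforms: TypeTransform) -> InstanceTensor:
    """Turn an instance set into its (n, L, d') feature tensor.

    Each node contributes its type-specific transformed one-hot feature; a
    node appearing in several instances contributes identical rows.  All
    instances must share one schema and one central drug.  An empty input
    yields an empty tensor (shape (0, L, d') is unrepresentable without a
    schema, so empties are rejected here and handled by the caller's null
    embedding path).
    """
    if not instances:
        raise ValueError("cannot tensorize an empty instance set")
    schema = instances[0].schema
    central = instances[0].end_drug
    for inst in instances:
        if inst.schema is not schema or inst.end_drug != central:
            raise ValueError("instances must share one schema and central drug")
    node_ids = np.array([inst.nodes for inst in instances], dtype=int)  # (n, L)
    per_type = {NodeType.DRUG: transforms.w_drug, NodeType.TARGET: transforms.w_target}
    for pos, nt in enumerate(schema.node_types):
        n_avail = per_type[nt].shape[0]
        if node_ids[:, pos].max() >= n_avail:
            raise ValueError(
                f"node index {node_ids[:, pos].max()} exceeds one-hot length "
                f"{n_avail} for type {nt.name}")
    cols = [per_type[nt][node_ids[:, pos]]
            for pos, nt in enumerate(schema.node_types)]  # each (n, d')
    values = stack(cols, axis=1)  # (n, L, d')
    return InstanceTensor(values=values, instance_index=list(instances),
                          central_drug=central, schema=schema)


def instances_for_all_drugs(net: HetNet, dtttd_ratio: float = 0.5,
                            rng_seed: int = 0) -> dict[Schema, list[list[MetaPathInstance]]]:
    """Enumerate (and, for DTTTD, restrict+sample) all four instance sets
    for every drug.  The DTTTD draw is fixed once per call, seeded per drug
    (``rng_seed + drug``) so results are independent of enumeration order."""
    sets: dict[Schema, list[list[MetaPathInstance]]] = {}
    for schema in Schema:
        per_drug = []
        for d in range(net.n_drugs):
            inst = enumerate_instances(net, schema, d)
            if schema is Schema.DTTTD:
                inst = restrict_and_sample_dtttd(inst, net, dtttd_ratio,
                                                 rng_seed + d)
            per_drug.append(inst)
        sets[schema] = per_drug
    return sets


def export_instances(instances: list[MetaPathInstance], path,
                     drug_names=None, target_names=None) -> None:
    """Write one instance per row as tab-separated node names (TSV)."""
    path = Path(path)

    def label(idx: int, nt: NodeType) -> str:
        if nt is NodeType.DRUG:
            return drug_names[idx] if drug_names is not None else f"D{idx}"
        return target_names[idx] if target_names is not None else f"T{idx}"

    with path.open("w", encoding="utf-8") as fh:
        for inst in instances:
            fh.write("\t".join(label(i, nt) for i, nt
                               in zip(inst.nodes, inst.schema.node_types)) + "\n")
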