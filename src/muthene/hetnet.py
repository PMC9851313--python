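"""Heterogeneous therapeutic-effect network construction.

The network G = (V, E, R) has two node types — drugs (D) and protein
targets (T) — and three binary edge relations: drug–target interactions
(DTI), protein–protein interactions (PPI), and drug–drug therapeutic-effect
(TE) edges obtained by thresholding real-valued synergy scores.

External names are arbitrary strings; internally every node type gets dense
integer indices starting at 0 (see :class:`IdMap`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "NodeType", "NodeId", "IdMap", "HetNet", "Dataset",
    "build_hetnet", "load_tables", "TableError",
]

SCORE_TYPES = ("loewe", "bliss", "hsa", "zip")


class TableError(ValueError):
    """Raised when an input table violates the expected dialect."""


class NodeType(enum.Enum):
    DRUG = "D"
    TARGET = "T"


@dataclass(frozen=True)
class NodeId:
    node_type: NodeType
    index: int

    def __post_init__(self):
        if self.index < 0:
            raise ValueError(f"negative node index: {self.index}")


class IdMap:
    """Bijection between external string names and dense integer indices."""

    def __init__(self, names):
        self._names = list(names)
        self._index = {n: i for i, n in enumerate(self._names)}
        if len(self._index) != len(self._names):
            raise TableError("duplicate identifier in vocabulary")

    def __len__(self):
        return len(self._names)

    def __contains__(self, name):
        return name in self._index

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise TableError(f"unknown identifier: {name!r}") from None

    def name(self, index: int) -> str:
        return self._names[index]

    @property
    def names(self) -> list[str]:
        return list(self._names)


@dataclass
class HetNet:
    """Binary-presence heterogeneous network over drug and target nodes."""

    n_drugs: int
    n_targets: int
    dti_edges: frozenset  # of (drug, target) pairs
    ppi_edges: frozenset  # of unordered (target, target) pairs, stored sorted
    dd_edges: frozenset   # of unordered (drug, drug) pairs, stored sorted

    def drug_targets(self, d: int) -> list[int]:
        return sorted(t for (dd, t) in self.dti_edges if dd == d)

    def has_dd(self, i: int, j: int) -> bool:
        return tuple(sorted((i, j))) in self.dd_edges


@dataclass
class Dataset:
    """In-memory view of the six input tables with integer-indexed rows.

    ``triples`` holds one row per drug–drug–cell-line synergy sample with
    all four score columns; ``ae_labels`` is aligned with ``ae_pairs``.
    """

    drugs: IdMap
    targets: IdMap
    cell_lines: IdMap
    genes: list[str]
    dti: pd.DataFrame           # columns: drug, target (int)
    ppi: pd.DataFrame           # columns: target_a, target_b (int)
    triples: pd.DataFrame       # columns: drug_a, drug_b, cell_line, loewe, bliss, hsa, zip
    ae_pairs: np.ndarray        # (n_pairs, 2) int, unordered pairs stored sorted
    ae_labels: np.ndarray       # (n_pairs, n_ae) in {0,1}
    chem: np.ndarray            # (n_drugs, n_bits) in {0,1}
    expression: np.ndarray      # (n_cell_lines, n_genes) in [0,1]
    extras: dict = field(default_factory=dict)

    @property
    def n_ae(self) -> int:
        return self.ae_labels.shape[1]

    def ae_for_pair(self, i: int, j: int) -> np.ndarray:
        key = tuple(sorted((i, j)))
        hit = self.extras.setdefault("_ae_index", {
            tuple(p): k for k, p in enumerate(self.ae_pairs.tolist())
        })
        return self.ae_labels[hit[key]]


def build_hetnet(dti_table: pd.DataFrame, ppi_table: pd.DataFrame,
                 synergy_samples: pd.DataFrame, threshold: float = 0.0,
                 dd_source_pairs=None, *, n_drugs: int, n_targets: int) -> HetNet:
    """Assemble the heterogeneous network from integer-indexed edge tables.

    A drug pair (i, j) receives a TE (DD) edge iff any of its synergy
    samples *among the in-scope pairs* has score strictly greater than
    ``threshold``.  Restricting ``dd_source_pairs`` to the training-split
    pairs guarantees no DD edge encodes a held-out label.

    Parameters
    ----------
    dti_table
        Columns ``drug``, ``target`` (dense integer indices).
    ppi_table
        Columns ``target_a``, ``target_b``.
    synergy_samples
        Columns ``drug_a``, ``drug_b``, ``score`` — one row per
        drug–drug–cell-line sample with the score type already selected.
    threshold
        DD binarization cut; the edge requires ``score > threshold``
        (strict), so a score exactly at the threshold does not create an
        edge and the default 0 places the cut at the synergy/antagonism
        boundary.
    dd_source_pairs
        Iterable of unordered drug pairs allowed to contribute DD edges;
        ``None`` means all pairs present in ``synergy_samples``.
    """
    def _check(col, n, what, df):
        bad = df[(col < 0) | (col >= n)]
        if len(bad):
            raise TableError(f"unknown {what} index in row: {bad.iloc[0].to_dict()}")

    _check(dti_table["drug"], n_drugs, "drug", dti_table)
    _check(dti_table["target"], n_targets, "target", dti_table)
    _check(ppi_table["target_a"], n_targets, "target", ppi_table)
    _check(ppi_table["target_b"], n_targets, "target", ppi_table)
    _check(synergy_samples["drug_a"], n_drugs, "drug", synergy_samples)
    _check(synergy_samples["drug_b"], n_drugs, "drug", synergy_samples)
    scores = synergy_samples["score"].to_numpy(dtype=float)
    if not np.all(np.isfinite(scores)):
        row = synergy_samples[~np.isfinite(scores)].iloc[0]
        raise TableError(f"non-finite synergy score in row: {row.to_dict()}")

    dti = frozenset(zip(dti_table["drug"].astype(int), dti_table["target"].astype(int)))
    ppi = frozenset(
        tuple(sorted((int(a), int(b))))
        for a, b in zip(ppi_table["target_a"], ppi_table["target_b"])
        if int(a) != int(b)
    )

    allowed = None
    if dd_source_pairs is not None:
        allowed = {tuple(sorted(map(int, p))) for p in dd_source_pairs}
    dd = set()
    for a, b, s in zip(synergy_samples["drug_a"], synergy_samples["drug_b"], scores):
        a, b = int(a), int(b)
        if a == b:
            continue
        pair = tuple(sorted((a, b)))
        if allowed is not None and pair not in allowed:
            continue
        if s > threshold:
            dd.add(pair)
    return HetNet(n_drugs=n_drugs, n_targets=n_targets,
                  dti_edges=dti, ppi_edges=ppi, dd_edges=frozenset(dd))


def _read(path: Path, required: list[str], name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableError(f"{name}: missing column(s) {missing}; found {list(df.columns)}")
    return df


def load_tables(data_dir) -> Dataset:
    """Load the six TSV tables of a data directory into a :class:`Dataset`.

    Expected files (tab-delimited, header line, UTF-8): ``dti.tsv``
    (drug, target), ``ppi.tsv`` (target_a, target_b), ``synergy.tsv``
    (drug_a, drug_b, cell_line, loewe, bliss, hsa, zip), ``ae.tsv``
    (drug_a, drug_b, ae_1..ae_K with 0/1 entries), ``expression.tsv``
    (cell_line + one column per gene, values in [0,1]) and ``chem.tsv``
    (drug + one column per fingerprint bit).

    String identifiers are mapped to contiguous integer indices per node
    type (sorted order, so the mapping is reproducible); the maps are
    retained on the returned dataset for reporting.
    """
    d = Path(data_dir)
    dti_raw = _read(d / "dti.tsv", ["drug", "target"], "dti.tsv")
    ppi_raw = _read(d / "ppi.tsv", ["target_a", "target_b"], "ppi.tsv")
    syn_raw = _read(d / "synergy.tsv",
                    ["drug_a", "drug_b", "cell_line", *SCORE_TYPES], "synergy.tsv")
    ae_raw = pd.read_csv(d / "ae.tsv", sep="\t", dtype=str)
    for c in ("drug_a", "drug_b"):
        if c not in ae_raw.columns:
            raise TableError(f"ae.tsv: missing column(s) ['{c}']")
    ae_cols = [c for c in ae_raw.columns if c.startswith("ae_")]
    if not ae_cols:
        raise TableError("ae.tsv: no ae_* label columns found")
    expr_raw = pd.read_csv(d / "expression.tsv", sep="\t", dtype=str)
    if "cell_line" not in expr_raw.columns:
        raise TableError("expression.tsv: missing column(s) ['cell_line']")
    chem_raw = pd.read_csv(d / "chem.tsv", sep="\t", dtype=str)
    if "drug" not in chem_raw.columns:
        raise TableError("chem.tsv: missing column(s) ['drug']")

    drugs = IdMap(sorted(set(dti_raw["drug"]) | set(syn_raw["drug_a"])
                         | set(syn_raw["drug_b"]) | set(ae_raw["drug_a"])
                         | set(ae_raw["drug_b"]) | set(chem_raw["drug"])))
    targets = IdMap(sorted(set(dti_raw["target"]) | set(ppi_raw["target_a"])
                           | set(ppi_raw["target_b"])))
    cells = IdMap(sorted(set(syn_raw["cell_line"]) | set(expr_raw["cell_line"])))

    missing_chem = [n for n in drugs.names if n not in set(chem_raw["drug"])]
    if missing_chem:
        raise TableError(f"chem.tsv: no fingerprint row for drug(s) {missing_chem[:5]}")
    missing_expr = [n for n in cells.names if n not in set(expr_raw["cell_line"])]
    if missing_expr:
        raise TableError(f"expression.tsv: no row for cell line(s) {missing_expr[:5]}")

    dti = pd.DataFrame({
        "drug": [drugs.index(x) for x in dti_raw["drug"]],
        "target": [targets.index(x) for x in dti_raw["target"]],
    }).drop_duplicates(ignore_index=True)
    ppi = pd.DataFrame({
        "target_a": [targets.index(x) for x in ppi_raw["target_a"]],
        "target_b": [targets.index(x) for x in ppi_raw["target_b"]],
    }).drop_duplicates(ignore_index=True)

    triples = pd.DataFrame({
        "drug_a": [drugs.index(x) for x in syn_raw["drug_a"]],
        "drug_b": [drugs.index(x) for x in syn_raw["drug_b"]],
        "cell_line": [cells.index(x) for x in syn_raw["cell_line"]],
    })
    for s in SCORE_TYPES:
        vals = pd.to_numeric(syn_raw[s], errors="coerce").to_numpy()
        if np.any(~np.isfinite(vals)):
            bad = int(np.flatnonzero(~np.isfinite(vals))[0])
            raise TableError(f"synergy.tsv row {bad}: non-finite {s} score "
                             f"({syn_raw.iloc[bad].to_dict()})")
        triples[s] = vals
    if np.any(triples["drug_a"].to_numpy() == triples["drug_b"].to_numpy()):
        bad = triples[triples["drug_a"] == triples["drug_b"]].index[0]
        raise TableError(f"synergy.tsv row {bad}: drug paired with itself")
    key = pd.DataFrame({
        "lo": np.minimum(triples["drug_a"], triples["drug_b"]),
        "hi": np.maximum(triples["drug_a"], triples["drug_b"]),
        "c": triples["cell_line"],
    })
    dup = key.duplicated()
    if dup.any():
        bad = int(np.flatnonzero(dup.to_numpy())[0])
        raise TableError(f"synergy.tsv row {bad}: duplicate (drug_a, drug_b, "
                         f"cell_line) sample ({syn_raw.iloc[bad].to_dict()})")

    ae_pairs, ae_rows, seen = [], [], set()
    for ridx, row in ae_raw.iterrows():
        pair = tuple(sorted((drugs.index(row["drug_a"]), drugs.index(row["drug_b"]))))
        if pair[0] == pair[1]:
            raise TableError(f"ae.tsv row {ridx}: drug paired with itself")
        if pair in seen:
            raise TableError(f"ae.tsv row {ridx}: duplicate drug pair")
        seen.add(pair)
        try:
            labels = np.array([int(row[c]) for c in ae_cols])
        except (TypeError, ValueError):
            raise TableError(f"ae.tsv row {ridx}: malformed AE label vector "
                             f"(expected {len(ae_cols)} 0/1 entries)") from None
        if np.any(~np.isin(labels, (0, 1))):
            raise TableError(f"ae.tsv row {ridx}: AE labels must be 0/1")
        ae_pairs.append(pair)
        ae_rows.append(labels)

    gene_cols = [c for c in expr_raw.columns if c != "cell_line"]
    expr = np.zeros((len(cells), len(gene_cols)))
    for _, row in expr_raw.iterrows():
        expr[cells.index(row["cell_line"])] = [float(row[c]) for c in gene_cols]
    if expr.min() < 0.0 or expr.max() > 1.0:
        raise TableError("expression.tsv: values outside [0, 1]")

    bit_cols = [c for c in chem_raw.columns if c != "drug"]
    chem = np.zeros((len(drugs), len(bit_cols)))
    for _, row in chem_raw.iterrows():
        chem[drugs.index(row["drug"])] = [int(row[c]) for c in bit_cols]
    if np.any(~np.isin(chem, (0, 1))):
        raise TableError("chem.tsv: fingerprint bits must be 0/1")

    return Dataset(
        drugs=drugs, targets=targets, cell_lines=cells, genes=gene_cols,
        dti=dti, ppi=ppi, triples=triples,
        ae_pairs=np.array(ae_pairs, dtype=int).reshape(-1, 2),
        ae_labels=np.array(ae_rows, dtype=int).reshape(len(ae_rows), -1),
        chem=chem, expression=expr,
    )
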