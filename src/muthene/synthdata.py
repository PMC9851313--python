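"""Desk-scale synthetic datasets with a planted shared mechanism.

The generator emulates the statistical structure the multi-task model
assumes: drugs bind protein targets (DTI), targets interact (PPI), and a
latent per-pair factor — built from the drugs' latent vectors *and* their
shared-target count in the generated network — drives both the
adverse-effect labels and the synergy scores.  Because the same factor
underlies both signals, AE supervision carries information about synergy,
which is exactly the planted structure a multi-task learner can exploit
and a single-task learner cannot.

What it does not emulate: realistic chemistry (fingerprints are random
bits correlated with the drug latents, not molecules) or the marginal
distributions of any public synergy/AE database.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .hetnet import Dataset, IdMap, load_tables

__all__ = ["SynthConfig", "SynthDataset", "generate", "write_fixture"]

_SCORE_SCALE = {"loewe": 10.0, "bliss": 5.0, "hsa": 4.0, "zip": 4.0}


@dataclass
class SynthConfig:
    """Knobs of the generator.

    ``shared_effect`` scales how strongly the latent pair factor (the one
    the AE labels read out) enters the synergy scores; ``noise_sd`` is the
    standard deviation of the additive Gaussian noise on the latent score
    scale (scores are then multiplied by a per-score-type scale so the
    four columns live on plausibly different ranges).
    """

    n_drugs: int = 20
    n_targets: int = 30
    n_cell_lines: int = 5
    n_ae: int = 8
    n_genes: int = 50
    n_bits: int = 64
    p_dti: float = 0.15
    p_ppi: float = 0.10
    latent_dim: int = 4
    shared_effect: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_drugs", "n_targets", "n_cell_lines", "n_ae",
                     "n_genes", "n_bits"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        for name in ("p_dti", "p_ppi"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.shared_effect < 0:
            raise ValueError("shared_effect must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


@dataclass
class SynthDataset:
    """Generated tables plus the ground-truth latents behind them."""

    dti: pd.DataFrame          # string columns drug, target
    ppi: pd.DataFrame          # target_a, target_b
    synergy: pd.DataFrame      # drug_a, drug_b, cell_line, loewe, bliss, hsa, zip
    ae: pd.DataFrame           # drug_a, drug_b, ae_1..ae_K
    chem: pd.DataFrame         # drug + bit columns
    expression: pd.DataFrame   # cell_line + gene columns
    latents: dict = field(default_factory=dict)  # u (drug), v (cell), s (pair factor)
    config: SynthConfig | None = None


def _drug_name(i): return f"DRUG{i:03d}"
def _target_name(i): return f"TGT{i:03d}"
def _cell_name(i): return f"CELL{i:02d}"
def _gene_name(i): return f"GENE{i:03d}"


def generate(config: SynthConfig) -> SynthDataset:
    """Draw a full dataset from the seeded generator.

    Steps: (a) DTI/PPI edges are independent Bernoulli draws (drugs left
    without any target are re-wired to one random target so meta-path sets
    are non-trivial whenever p_dti*n_targets >= 3); (b) each drug gets a
    latent u_d and each cell line a latent v_c; (c) each unordered drug
    pair gets the shared factor s_ij combining u_i·u_j with the pair's
    shared-target count; (d) AE label k fires with probability
    logistic(w_k*s_ij + bias_k); (e) the synergy of (i,j,c) is
    shared_effect*s_ij plus a pair–cell interaction plus Gaussian noise,
    scaled per score type; (f) fingerprint bits are Bernoulli draws whose
    log-odds are linear in u_d; (g) expression rows are affine images of
    v_c clipped to [0,1].
    """
    config.validate()
    c = config
    rng = np.random.default_rng(c.seed)

    # (a) network edges
    dti_mask = rng.random((c.n_drugs, c.n_targets)) < c.p_dti
    if c.p_dti * c.n_targets >= 3:
        for d in range(c.n_drugs):
            if not dti_mask[d].any():
                dti_mask[d, rng.integers(c.n_targets)] = True
    dti_rows = [( _drug_name(d), _target_name(t))
                for d in range(c.n_drugs) for t in range(c.n_targets)
                if dti_mask[d, t]]
    ppi_rows = [(_target_name(a), _target_name(b))
                for a, b in combinations(range(c.n_targets), 2)
                if rng.random() < c.p_ppi]

    # (b) latents
    u = rng.standard_normal((c.n_drugs, c.latent_dim))
    v = rng.standard_normal((c.n_cell_lines, c.latent_dim))

    # (c) pair factor coupled to the network
    pairs = list(combinations(range(c.n_drugs), 2))
    shared_targets = np.array([np.sum(dti_mask[i] & dti_mask[j])
                               for i, j in pairs], dtype=float)
    raw = np.array([u[i] @ u[j] for i, j in pairs]) / np.sqrt(c.latent_dim)
    raw = raw + 0.5 * shared_targets
    s = (raw - raw.mean()) / (raw.std() + 1e-12)  # standardized pair factor

    # (d) AE labels
    w_ae = 2.0 * rng.standard_normal(c.n_ae)
    b_ae = 0.5 * rng.standard_normal(c.n_ae)
    logits = np.outer(s, w_ae) + b_ae
    ae_labels = (rng.random((len(pairs), c.n_ae)) < 1.0 / (1.0 + np.exp(-logits))).astype(int)
    ae_df = pd.DataFrame({
        "drug_a": [_drug_name(i) for i, _ in pairs],
        "drug_b": [_drug_name(j) for _, j in pairs],
        **{f"ae_{k + 1}": ae_labels[:, k] for k in range(c.n_ae)},
    })

    # (e) synergy scores: latent mean, independent per-type noise + scale
    w_cell = rng.standard_normal(c.latent_dim)
    rows = []
    for p, (i, j) in enumerate(pairs):
        for k in range(c.n_cell_lines):
            interact = (u[i] + u[j]) @ (v[k] * w_cell) / np.sqrt(2 * c.latent_dim)
            mu = c.shared_effect * s[p] + interact
            rec = {"drug_a": _drug_name(i), "drug_b": _drug_name(j),
                   "cell_line": _cell_name(k)}
            for score, scale in _SCORE_SCALE.items():
                rec[score] = round(scale * (mu + c.noise_sd * rng.standard_normal()), 6)
            rows.append(rec)
    synergy = pd.DataFrame(rows)

    # (f) fingerprints correlated with u
    proj = rng.standard_normal((c.latent_dim, c.n_bits))
    bit_logits = 1.5 * (u @ proj) - 1.0          # ~25% on-bit density
    chem_bits = (rng.random((c.n_drugs, c.n_bits))
                 < 1.0 / (1.0 + np.exp(-bit_logits))).astype(int)
    chem = pd.DataFrame({"drug": [_drug_name(d) for d in range(c.n_drugs)],
                         **{f"bit_{b + 1}": chem_bits[:, b] for b in range(c.n_bits)}})

    # (g) expression from cell latents, clipped to [0, 1]
    m = rng.standard_normal((c.latent_dim, c.n_genes))
    expr_vals = np.clip(0.5 + 0.2 * (v @ m), 0.0, 1.0)
    expression = pd.DataFrame({"cell_line": [_cell_name(k) for k in range(c.n_cell_lines)],
                               **{_gene_name(g): np.round(expr_vals[:, g], 6)
                                  for g in range(c.n_genes)}})

    if not dti_rows:
        import warnings
        warnings.warn("degenerate config: no DTI edges; meta-path sets will be empty")

    return SynthDataset(
        dti=pd.DataFrame(dti_rows, columns=["drug", "target"]),
        ppi=pd.DataFrame(ppi_rows, columns=["target_a", "target_b"]),
        synergy=synergy, ae=ae_df, chem=chem, expression=expression,
        latents={"u": u, "v": v, "s": s, "pairs": pairs,
                 "shared_targets": shared_targets},
        config=c,
    )


def write_fixture(dataset: SynthDataset, out_dir) -> Path:
    """Emit the TSV dialect consumed by :func:`muthene.hetnet.load_tables`."""
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    for name, df in (("dti", dataset.dti), ("ppi", dataset.ppi),
                     ("synergy", dataset.synergy), ("ae", dataset.ae),
                     ("chem", dataset.chem), ("expression", dataset.expression)):
        df.to_csv(d / f"{name}.tsv", sep="\t", index=False)
    return d


def as_dataset(synth: SynthDataset) -> Dataset:
    """Index a generated dataset without a filesystem round trip.

    Equivalent to ``load_tables(write_fixture(synth, tmp))`` up to float
    formatting; used by tests and the acceptance driver.
    """
    import tempfile
    with tempfile.TemporaryDirectory() as td:
        return load_tables(write_fixture(synth, td))
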