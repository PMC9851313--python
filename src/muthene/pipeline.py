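"""Leakage-free evaluation protocol: splitting, training, metrics.

Drug–drug–cell-line samples are split *by drug pair* — all samples sharing
an unordered drug pair land in the same partition — so a test pair is never
seen during training under any cell line.  The DD (therapeutic-effect)
edges of the network are, by default, built from training-split pairs only,
so held-out synergy labels cannot leak into the graph either.

Training symmetrizes the sample list (each triple appears in both drug
orders); validation/test predictions average the two orderings.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .autodiff import Adam
from .hetnet import Dataset, HetNet, build_hetnet
from .heads import alpha_from_ratio
from .metapath import Schema, instances_for_all_drugs
from .model import ModelConfig, MutheneModel

__all__ = [
    "SplitSpec", "TrainConfig", "EvalReport", "split_by_pair",
    "symmetrize_training", "predict_symmetric", "build_model", "train",
    "evaluate", "regression_metrics", "run_single", "run_repeats",
    "sweep_alpha", "R_GRID",
]

# validation search range for the loss weight ratio R = alpha/(1-alpha)
R_GRID = (0.01, 0.05, 0.1, 0.5, 1.0, 5.0, 10.0)


@dataclass
class SplitSpec:
    """Assignment of unordered drug pairs (and hence all their triples) to
    train/validation/test."""

    train_pairs: frozenset
    val_pairs: frozenset
    test_pairs: frozenset

    def __post_init__(self):
        for a, b in ((self.train_pairs, self.val_pairs),
                     (self.train_pairs, self.test_pairs),
                     (self.val_pairs, self.test_pairs)):
            if a & b:
                raise ValueError("split pair sets overlap")

    def of_pair(self, i: int, j: int) -> str:
        key = tuple(sorted((int(i), int(j))))
        if key in self.train_pairs:
            return "train"
        if key in self.val_pairs:
            return "val"
        if key in self.test_pairs:
            return "test"
        raise KeyError(f"pair {key} not in split")

    def triples_of(self, triples: pd.DataFrame, part: str) -> pd.DataFrame:
        pairs = {"train": self.train_pairs, "val": self.val_pairs,
                 "test": self.test_pairs}[part]
        keys = [tuple(sorted((int(a), int(b))))
                for a, b in zip(triples["drug_a"], triples["drug_b"])]
        mask = np.array([k in pairs for k in keys])
        return triples[mask].reset_index(drop=True)


def _largest_remainder(n: int, ratios) -> list[int]:
    quotas = [r * n for r in ratios]
    counts = [int(np.floor(q)) for q in quotas]
    rem = n - sum(counts)
    order = sorted(range(len(ratios)), key=lambda k: (-(quotas[k] - counts[k]), k))
    for k in order[:rem]:
        counts[k] += 1
    return counts


def split_by_pair(triples: pd.DataFrame, ratios=(0.6, 0.2, 0.2),
                  rng_seed: int = 0) -> SplitSpec:
    """Shuffle unordered drug pairs and partition them 6:2:2 by count
    (largest-remainder rounding); every triple follows its pair."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    pairs = sorted({tuple(sorted((int(a), int(b))))
                    for a, b in zip(triples["drug_a"], triples["drug_b"])})
    if len(pairs) < len(ratios):
        raise ValueError(f"need at least {len(ratios)} distinct pairs, "
                         f"got {len(pairs)}")
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(len(pairs))
    shuffled = [pairs[k] for k in perm]
    n_tr, n_va, n_te = _largest_remainder(len(pairs), ratios)
    return SplitSpec(
        train_pairs=frozenset(shuffled[:n_tr]),
        val_pairs=frozenset(shuffled[n_tr:n_tr + n_va]),
        test_pairs=frozenset(shuffled[n_tr + n_va:]),
    )


def symmetrize_training(triples: pd.DataFrame) -> pd.DataFrame:
    """Duplicate every training triple with the drug order swapped
    (identical labels); applies to the training set only by contract."""
    swapped = triples.copy()
    swapped["drug_a"] = triples["drug_b"].to_numpy()
    swapped["drug_b"] = triples["drug_a"].to_numpy()
    return pd.concat([triples, swapped], ignore_index=True)


def predict_symmetric(model: MutheneModel, drug_i, drug_j, cell,
                      z_int=None) -> np.ndarray:
    """Order-invariant prediction: mean of f(i,j,k) and f(j,i,k)."""
    if z_int is None:
        z_int = model.integrated_embeddings()
    a, _ = model.forward(drug_i, drug_j, cell, training=False, z_int=z_int)
    b, _ = model.forward(drug_j, drug_i, cell, training=False, z_int=z_int)
    return (a.data + b.data) / 2.0


@dataclass
class TrainConfig:
    """Optimization settings (Adam; early stopping on validation MSE)."""

    lr: float = 1e-3
    weight_decay: float = 1e-5
    batch_size: int = 256
    max_epochs: int = 100
    patience: int = 20
    seed: int = 0
    verbose: bool = False


@dataclass
class EvalReport:
    """Per-repeat and averaged test metrics plus run provenance."""

    per_repeat: list = field(default_factory=list)  # dicts with mse/mae/pearson/seed
    mse: float = float("nan")
    mae: float = float("nan")
    pearson: float = float("nan")
    config: dict = field(default_factory=dict)

    def finalize(self) -> "EvalReport":
        for key in ("mse", "mae", "pearson"):
            vals = [r[key] for r in self.per_repeat if np.isfinite(r[key])]
            setattr(self, key, float(np.mean(vals)) if vals else float("nan"))
        return self

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"per_repeat": self.per_repeat, "mse": self.mse,
                       "mae": self.mae, "pearson": self.pearson,
                       "config": self.config}, fh, indent=2)


def _triple_arrays(dataset: Dataset, triples: pd.DataFrame, score_type: str):
    i = triples["drug_a"].to_numpy(dtype=int)
    j = triples["drug_b"].to_numpy(dtype=int)
    c = triples["cell_line"].to_numpy(dtype=int)
    y = triples[score_type].to_numpy(dtype=float)
    ae = np.stack([dataset.ae_for_pair(a, b) for a, b in zip(i, j)])
    return i, j, c, y, ae


def build_model(dataset: Dataset, config: ModelConfig, split: SplitSpec,
                seed: int = 0, dd_all_pairs: bool = False) -> MutheneModel:
    """Construct the network + instance sets for a split and bind a model.

    DD edges come from training-split pairs unless ``dd_all_pairs`` is set
    (which reproduces the leaky all-pairs behaviour for comparison).
    """
    syn = dataset.triples.rename(columns={config.score_type: "score"})
    syn = syn[["drug_a", "drug_b", "score"]]
    net = build_hetnet(
        dataset.dti, dataset.ppi, syn, threshold=config.dd_threshold,
        dd_source_pairs=None if dd_all_pairs else split.train_pairs,
        n_drugs=len(dataset.drugs), n_targets=len(dataset.targets))
    sets = instances_for_all_drugs(net, dtttd_ratio=config.dtttd_ratio,
                                   rng_seed=seed)
    return MutheneModel(config, net.n_drugs, net.n_targets, sets,
                        dataset.chem, dataset.expression, dataset.n_ae,
                        seed=seed)


def train(model: MutheneModel, dataset: Dataset, split: SplitSpec,
          tc: TrainConfig) -> pd.DataFrame:
    """End-to-end training minimising the alpha-weighted objective.

    Mini-batch Adam over the symmetrized training triples with early
    stopping on validation MSE (symmetric predictions).  Returns the
    per-epoch log (l_total / l_mse / l_bce / val_mse); the model is left
    at the best-validation parameters.
    """
    score = model.config.score_type
    tr = symmetrize_training(split.triples_of(dataset.triples, "train"))
    va = split.triples_of(dataset.triples, "val")
    ti, tj, tcell, ty, tae = _triple_arrays(dataset, tr, score)
    vi, vj, vcell, vy, _ = _triple_arrays(dataset, va, score)

    opt = Adam(model.parameters(), lr=tc.lr, weight_decay=tc.weight_decay)
    rng = np.random.default_rng(tc.seed)
    log_rows = []
    best_val = np.inf
    best_state = [a.copy() for a in model.state_arrays()]
    stale = 0
    n = len(ty)
    for epoch in range(1, tc.max_epochs + 1):
        order = rng.permutation(n)
        tot_l = tot_m = tot_b = 0.0
        nb = 0
        for lo in range(0, n, tc.batch_size):
            idx = order[lo:lo + tc.batch_size]
            opt.zero_grad()
            l_total, l_mse, l_bce = model.loss(ti[idx], tj[idx], tcell[idx],
                                               ty[idx], tae[idx], training=True)
            if not np.isfinite(l_total.data):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            l_total.backward()
            opt.step()
            tot_l += float(l_total.data)
            tot_m += float(l_mse.data)
            tot_b += float(l_bce.data) if l_bce is not None else 0.0
            nb += 1
        val_pred = predict_symmetric(model, vi, vj, vcell) if len(vy) else np.array([])
        val_mse = float(np.mean((val_pred - vy) ** 2)) if len(vy) else np.nan
        log_rows.append({"epoch": epoch, "l_total": tot_l / nb,
                         "l_mse": tot_m / nb, "l_bce": tot_b / nb,
                         "val_mse": val_mse})
        if tc.verbose:
            print(f"epoch {epoch:3d}  l_total {tot_l / nb:10.4f}  "
                  f"val_mse {val_mse:10.4f}")
        if np.isfinite(val_mse) and val_mse < best_val - 1e-12:
            best_val = val_mse
            best_state = [a.copy() for a in model.state_arrays()]
            stale = 0
        else:
            stale += 1
            if stale > tc.patience:
                break
    model.load_state_arrays(best_state)
    return pd.DataFrame(log_rows)


def regression_metrics(pred: np.ndarray, y: np.ndarray) -> dict:
    """MSE, MAE and Pearson correlation of a prediction vector.

    A constant vector leaves Pearson undefined; it is reported as NaN with
    a warning (repeat averaging excludes NaNs).
    """
    pred = np.asarray(pred, dtype=float)
    y = np.asarray(y, dtype=float)
    mse = float(np.mean((pred - y) ** 2))
    mae = float(np.mean(np.abs(pred - y)))
    if np.std(pred) == 0.0 or np.std(y) == 0.0:
        warnings.warn("constant predictions or targets: Pearson undefined")
        r = float("nan")
    else:
        r = float(stats.pearsonr(pred, y)[0])
    return {"mse": mse, "mae": mae, "pearson": r, "n": int(len(y))}


def evaluate(model: MutheneModel, dataset: Dataset, split: SplitSpec,
             part: str = "test") -> dict:
    """MSE / MAE / Pearson over a partition using symmetric predictions."""
    score = model.config.score_type
    te = split.triples_of(dataset.triples, part)
    i, j, c, y, _ = _triple_arrays(dataset, te, score)
    return regression_metrics(predict_symmetric(model, i, j, c), y)


def run_single(dataset: Dataset, config: ModelConfig, tc: TrainConfig,
               seed: int) -> tuple[MutheneModel, SplitSpec, dict, pd.DataFrame]:
    """One split → train → evaluate cycle with every stage seeded."""
    split = split_by_pair(dataset.triples, rng_seed=seed)
    model = build_model(dataset, config, split, seed=seed)
    tc_run = TrainConfig(**{**tc.__dict__, "seed": seed})
    log = train(model, dataset, split, tc_run)
    metrics = evaluate(model, dataset, split, "test")
    return model, split, metrics, log


def run_repeats(dataset: Dataset, config: ModelConfig, tc: TrainConfig,
                n_repeats: int = 5, base_seed: int = 0) -> EvalReport:
    """Repeat split→train→evaluate with fresh shuffles; report means."""
    report = EvalReport(config={"model": config.__dict__.copy(),
                                "train": tc.__dict__.copy(),
                                "n_repeats": n_repeats,
                                "base_seed": base_seed})
    for rep in range(n_repeats):
        seed = base_seed + rep
        _, _, metrics, _ = run_single(dataset, config, tc, seed)
        metrics["seed"] = seed
        report.per_repeat.append(metrics)
    return report.finalize()


def sweep_alpha(dataset: Dataset, config: ModelConfig, tc: TrainConfig,
                seed: int, grid=R_GRID) -> dict:
    """Pick the loss weight ratio R by validation MSE on one split.

    Trains one model per R in the grid on the same split/seed, selects the
    ratio with the lowest validation MSE, and reports that model's test
    metrics.
    """
    split = split_by_pair(dataset.triples, rng_seed=seed)
    results = []
    best = None
    for R in grid:
        cfg = ModelConfig(**{**config.__dict__, "alpha": alpha_from_ratio(R)})
        model = build_model(dataset, cfg, split, seed=seed)
        tc_run = TrainConfig(**{**tc.__dict__, "seed": seed})
        log = train(model, dataset, split, tc_run)
        val = evaluate(model, dataset, split, "val")
        entry = {"R": R, "alpha": cfg.alpha, "val_mse": val["mse"]}
        results.append(entry)
        if best is None or val["mse"] < best["val_mse"]:
            best = {**entry, "model": model}
    test = evaluate(best["model"], dataset, split, "test")
    return {"grid": results, "best_R": best["R"], "best_alpha": best["alpha"],
            "best_val_mse": best["val_mse"], "test": test,
            "model": best["model"], "split": split}
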