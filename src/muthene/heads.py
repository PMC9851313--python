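"""Prediction heads and losses.

Two heads sit on top of the drug integrated embeddings:

* an adverse-effect (AE) decoder — a linear map over the concatenated pair
  embeddings followed by an element-wise logistic, trained with binary
  cross-entropy over the AE label vector of the pair;
* a therapeutic-effect (TE) regressor — a conic feed-forward network (each
  hidden layer half the width of the previous, ReLU + dropout) over the
  pair embeddings, the cell-line expression embedding and the AE
  probability vector.  The AE probabilities enter as a *constant*
  (stop-gradient), so the regression loss can never update the AE decoder
  or, through this path, the encoder.

The two losses combine as l_total = alpha * l_MSE + (1 - alpha) * l_BCE;
the weight ratio R = alpha / (1 - alpha) is the quantity swept during
validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, dropout, glorot

__all__ = [
    "AEHead", "CellProjection", "TEHead", "conic_widths",
    "bce_loss", "mse_loss", "total_loss", "alpha_from_ratio", "EPS",
]

EPS = 1e-7  # probability clamp before logs


@dataclass
class AEHead:
    """Linear decoder + logistic over [z_i_drug, z_i_chem, z_j_drug, z_j_chem]."""

    w: Tensor  # (2 * d_int, n_ae)
    b: Tensor  # (n_ae,)

    @classmethod
    def create(cls, d_integrated: int, n_ae: int,
               rng: np.random.Generator) -> "AEHead":
        return cls(w=glorot(rng, 2 * d_integrated, n_ae),
                   b=Tensor(np.zeros(n_ae), requires_grad=True))

    def params(self) -> list[Tensor]:
        return [self.w, self.b]

    def predict(self, z_i: Tensor, z_j: Tensor) -> Tensor:
        """AE occurrence probabilities, shape (batch, n_ae), entries in (0,1).

        ``z_i``/``z_j`` are the drugs' integrated embeddings (meta-path
        embedding with the chemical fingerprint already concatenated), so
        their concatenation realises the four-block input ordering.
        """
        x = concat([z_i, z_j], axis=1)
        if x.shape[1] != self.w.shape[0]:
            raise ValueError(f"AE head expects input dim {self.w.shape[0]}, "
                             f"got {x.shape[1]}")
        return (x @ self.w + self.b).sigmoid()


@dataclass
class CellProjection:
    """Single trainable affine map from raw expression (G) to d_cell."""

    w: Tensor
    b: Tensor

    @classmethod
    def create(cls, n_genes: int, d_cell: int,
               rng: np.random.Generator) -> "CellProjection":
        if d_cell > n_genes:
            raise ValueError(f"d_cell={d_cell} exceeds expression dim {n_genes}")
        return cls(w=glorot(rng, n_genes, d_cell),
                   b=Tensor(np.zeros(d_cell), requires_grad=True))

    def params(self) -> list[Tensor]:
        return [self.w, self.b]

    def __call__(self, expr: Tensor) -> Tensor:
        return expr @ self.w + self.b


def conic_widths(base_width: int, depth: int) -> list[int]:
    """Hidden-layer widths: each layer half the units of its predecessor."""
    if depth < 1 or base_width < 1:
        raise ValueError("depth and base width must be positive")
    widths = [base_width]
    for _ in range(depth - 1):
        widths.append(max(widths[-1] // 2, 1))
    return widths


class TEHead:
    """Conic DNN regressor over [z_i, z_j, z_cell, p_ae_const]."""

    def __init__(self, d_in: int, base_width: int, depth: int,
                 dropout_rate: float, rng: np.random.Generator):
        self.d_in = d_in
        self.dropout_rate = dropout_rate
        self.widths = conic_widths(base_width, depth)
        dims = [d_in] + self.widths + [1]
        self.layers = [(glorot(rng, a, b), Tensor(np.zeros(b), requires_grad=True))
                       for a, b in zip(dims[:-1], dims[1:])]

    def params(self) -> list[Tensor]:
        return [t for pair in self.layers for t in pair]

    def predict(self, z_i: Tensor, z_j: Tensor, z_cell: Tensor,
                p_ae_const: Tensor | None, rng: np.random.Generator,
                training: bool = False) -> Tensor:
        """Synergy predictions, shape (batch,).

        ``p_ae_const`` must already be detached by the caller (it is
        re-detached here for safety); pass ``None`` for the no-AE variant,
        whose input layer was sized without the AE block.
        """
        blocks = [z_i, z_j, z_cell]
        if p_ae_const is not None:
            blocks.append(p_ae_const.detach())
        x = concat(blocks, axis=1)
        if x.shape[1] != self.d_in:
            raise ValueError(f"TE head expects input dim {self.d_in}, got {x.shape[1]}")
        for k, (w, b) in enumerate(self.layers):
            x = x @ w + b
            if k < len(self.layers) - 1:
                x = x.relu()
                x = dropout(x, self.dropout_rate, rng, training)
        return x.reshape(-1)


def bce_loss(preds: Tensor, labels) -> Tensor:
    """Mean binary cross-entropy over all elements.

    Predictions are clamped to [EPS, 1-EPS] before the logs; labels must
    be 0/1.
    """
    y = labels.data if isinstance(labels, Tensor) else np.asarray(labels, dtype=float)
    if preds.shape != y.shape:
        raise ValueError(f"shape mismatch: preds {preds.shape} vs labels {y.shape}")
    if np.any(~np.isin(y, (0.0, 1.0))):
        raise ValueError("labels must be binary")
    x = preds.clip(EPS, 1.0 - EPS)
    y = Tensor(y)
    return (-(y * x.log() + (1.0 - y) * (1.0 - x).log())).mean()


def mse_loss(preds: Tensor, targets) -> Tensor:
    """Mean squared error."""
    t = targets.data if isinstance(targets, Tensor) else np.asarray(targets, dtype=float)
    if preds.data.size == 0:
        raise ValueError("empty input to mse_loss")
    if preds.shape != t.shape:
        raise ValueError(f"shape mismatch: preds {preds.shape} vs targets {t.shape}")
    d = preds - Tensor(t)
    return (d * d).mean()


def total_loss(l_mse: Tensor, l_bce: Tensor, alpha: float) -> Tensor:
    """alpha-weighted multi-task objective: alpha*MSE + (1-alpha)*BCE."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    return alpha * l_mse + (1.0 - alpha) * l_bce


def alpha_from_ratio(R: float) -> float:
    """Convert the loss weight ratio R = alpha/(1-alpha) to alpha."""
    if R < 0:
        raise ValueError("R must be non-negative")
    if np.isinf(R):
        return 1.0
    return R / (1.0 + R)
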