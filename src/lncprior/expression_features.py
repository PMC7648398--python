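"""Expression transforms and the autoencoder expression representation.

The expression feature block is built in three steps: log2(RPKM+1)
transform, unsupervised compression of the per-gene expression profile
with a single-hidden-layer autoencoder (ReLU encoder and decoder, MSE
loss, RMSprop optimizer), and min-max scaling of the final combined
feature set. The autoencoder is trained once on the full gene set
(labeled and unlabeled together) so candidate lncRNAs can be encoded in
the same space; this is a transductive step and is documented as such.

The code dimension is chosen by grid search: for each candidate size an
autoencoder is trained, genes are encoded, and the mean ROC AUC of a
classifier under repeated stratified cross-validation is recorded; the
argmax wins (ties to the smaller size).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, LabelSet

logger = logging.getLogger("lncprior")


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Replace every RPKM value v by log2(v + 1).

    Requires a raw (``rpkm``) matrix with non-negative values; the
    result is tagged ``log2``. Strictly monotone, so within-column
    orderings are preserved; exactly inverted by ``2**y - 1``.
    """
    if matrix.transform_state != "rpkm":
        raise ValueError(f"log_transform expects an rpkm matrix, got {matrix.transform_state}")
    if (matrix.values < 0).any():
        raise ValueError("negative value in RPKM matrix")
    return ExpressionMatrix(np.log2(matrix.data + 1.0), transform_state="log2")


def minmax_normalize(
    data: pd.DataFrame,
    fit_stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[pd.DataFrame, tuple[np.ndarray, np.ndarray]]:
    """Scale each column to (v - min) / (max - min).

    With ``fit_stats=None`` the per-column min and max are computed from
    ``data`` itself (output then lies in [0,1]); otherwise the supplied
    training-fold stats are used, so held-out values may fall outside
    [0,1]. Constant columns (max == min) map to 0. Returns the scaled
    frame and the stats used.
    """
    values = data.to_numpy(dtype=float)
    if fit_stats is None:
        col_min, col_max = values.min(axis=0), values.max(axis=0)
    else:
        col_min, col_max = (np.asarray(s, dtype=float) for s in fit_stats)
        if col_min.shape[0] != values.shape[1]:
            raise ValueError(
                f"fit_stats cover {col_min.shape[0]} features, data has {values.shape[1]}"
            )
    span = col_max - col_min
    safe_span = np.where(span > 0, span, 1.0)
    scaled = (values - col_min) / safe_span
    scaled[:, span == 0] = 0.0
    return (
        pd.DataFrame(scaled, index=data.index, columns=data.columns),
        (col_min, col_max),
    )


# ---------------------------------------------------------------------------
# Autoencoder
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AutoencoderSpec:
    """Architecture and training protocol of the expression autoencoder.

    One fully connected encoder layer (input_dim -> code_dim) and one
    decoder layer (code_dim -> input_dim), ReLU on both; MSE loss;
    RMSprop. Defaults: 100 epochs, batch size 64, learning rate 1e-3.
    """

    input_dim: int
    code_dim: int
    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0

    activation = "ReLU"
    loss = "MSE"
    optimizer = "RMSprop"

    def __post_init__(self) -> None:
        if not 1 <= self.code_dim < self.input_dim:
            raise ValueError(
                f"code_dim must satisfy 1 <= code_dim < input_dim "
                f"(got {self.code_dim} vs {self.input_dim})"
            )
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class EncodedFeatures:
    """Per-gene autoencoder codes; all entries >= 0 (ReLU outputs)."""

    gene_ids: list
    codes: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        cols = [f"code_{j:03d}" for j in range(self.codes.shape[1])]
        return pd.DataFrame(self.codes, index=self.gene_ids, columns=cols)


class Autoencoder:
    """Single-hidden-layer ReLU autoencoder trained with RMSprop on MSE.

    Encoder weights are initialized uniformly on +/- 1/sqrt(fan_in)
    from the spec's seed; decoder weights are initialized uniformly on
    [0, 1/sqrt(fan_in)]. The non-negative decoder start matters: with a
    ReLU output reconstructing non-negative data, an output unit whose
    pre-activation begins negative for every gene receives zero gradient
    and stays dead, so a symmetric decoder init strands roughly half the
    output dimensions. Mini-batches are reshuffled every epoch from the
    same generator, so training is fully deterministic given the seed.
    ``loss_trace_`` holds the mean per-batch MSE of each epoch.
    """

    _RHO = 0.9       # RMSprop decay
    _EPS = 1e-8      # RMSprop denominator floor

    def __init__(self, spec: AutoencoderSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        d, c = spec.input_dim, spec.code_dim
        self.W1 = rng.uniform(-1, 1, size=(d, c)) / np.sqrt(d)
        self.b1 = np.zeros(c)
        self.W2 = rng.uniform(0, 1, size=(c, d)) / np.sqrt(c)
        self.b2 = np.zeros(d)
        self._rng = rng
        self._cache = {name: np.zeros_like(getattr(self, name))
                       for name in ("W1", "b1", "W2", "b2")}
        self.loss_trace_: list[float] = []

    # forward pieces -------------------------------------------------------
    def encode(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.spec.input_dim:
            raise ValueError(
                f"expected {self.spec.input_dim} input features, got {X.shape[1]}"
            )
        return np.maximum(X @ self.W1 + self.b1, 0.0)

    def decode(self, codes: np.ndarray) -> np.ndarray:
        return np.maximum(np.asarray(codes, dtype=float) @ self.W2 + self.b2, 0.0)

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self.decode(self.encode(X))

    # training -------------------------------------------------------------
    def _step(self, X: np.ndarray) -> float:
        Z1 = X @ self.W1 + self.b1
        H = np.maximum(Z1, 0.0)
        Z2 = H @ self.W2 + self.b2
        R = np.maximum(Z2, 0.0)
        diff = R - X
        loss = float(np.mean(diff * diff))

        n = X.size
        dZ2 = (2.0 / n) * diff * (Z2 > 0)
        grads = {
            "W2": H.T @ dZ2,
            "b2": dZ2.sum(axis=0),
        }
        dH = dZ2 @ self.W2.T
        dZ1 = dH * (Z1 > 0)
        grads["W1"] = X.T @ dZ1
        grads["b1"] = dZ1.sum(axis=0)

        lr = self.spec.learning_rate
        for name, grad in grads.items():
            cache = self._cache[name]
            cache *= self._RHO
            cache += (1 - self._RHO) * grad * grad
            getattr(self, name).__isub__(lr * grad / (np.sqrt(cache) + self._EPS))
        return loss

    def fit(self, X: np.ndarray) -> "Autoencoder":
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.spec.input_dim:
            raise ValueError(
                f"expected {self.spec.input_dim} input features, got {X.shape[1]}"
            )
        n = X.shape[0]
        for _ in range(self.spec.epochs):
            order = self._rng.permutation(n)
            batch_losses = []
            for start in range(0, n, self.spec.batch_size):
                batch = X[order[start : start + self.spec.batch_size]]
                batch_losses.append(self._step(batch))
            self.loss_trace_.append(float(np.mean(batch_losses)))
        return self


def train_autoencoder(matrix: ExpressionMatrix, spec: AutoencoderSpec) -> Autoencoder:
    """Fit the autoencoder on a log2 (or minmax) expression matrix.

    Rows are genes (training examples), columns the input features.
    Returns the trained model with its per-epoch loss trace.
    """
    if matrix.transform_state == "rpkm":
        raise ValueError("train on a log2 or minmax matrix, not raw RPKM")
    if spec.input_dim != len(matrix.sample_ids):
        raise ValueError(
            f"spec.input_dim={spec.input_dim} but matrix has {len(matrix.sample_ids)} samples"
        )
    return Autoencoder(spec).fit(matrix.values)


def encode_expression(model: Autoencoder, matrix: ExpressionMatrix) -> EncodedFeatures:
    """Encode every gene: x_code = ReLU(W_enc x_in + b_enc)."""
    return EncodedFeatures(gene_ids=matrix.gene_ids, codes=model.encode(matrix.values))


def select_code_dimension(
    matrix: ExpressionMatrix,
    labels: LabelSet,
    grid: list[int],
    cv_config,
    epochs: int = 100,
    batch_size: int = 64,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Choose the code dimension by repeated-CV ROC AUC over a size grid.

    For each candidate size: train an autoencoder on the full matrix,
    encode, run repeated stratified CV with ``cv_config`` (an
    :class:`evaluation.CVConfig`), and record the mean ROC AUC. Returns
    the argmax size (ties to the smaller) and the per-size AUC table.
    """
    from .evaluation import repeated_cv  # local import to avoid a cycle

    if not grid:
        raise ValueError("empty code-dimension grid")
    input_dim = len(matrix.sample_ids)
    rows = []
    for code_dim in sorted(grid):
        spec = AutoencoderSpec(input_dim=input_dim, code_dim=code_dim,
                               epochs=epochs, batch_size=batch_size, seed=seed)
        model = train_autoencoder(matrix, spec)
        codes = encode_expression(model, matrix).to_frame()
        report = repeated_cv(codes, labels, cv_config)
        auc = report.summary.loc["roc_auc", "mean"]
        rows.append({"code_dim": code_dim, "mean_roc_auc": auc})
        logger.info("code_dim=%d mean ROC AUC=%.4f", code_dim, auc)
    table = pd.DataFrame(rows).set_index("code_dim")
    best = int(table["mean_roc_auc"].idxmax())  # idxmax takes first (smallest) on ties
    return best, table
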