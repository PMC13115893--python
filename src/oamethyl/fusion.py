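"""Dual-branch gated-fusion diagnostic model for CpG methylation profiles.

A sample's beta-value vector is embedded one token per CpG (scalar value
through a learned per-site affine map plus a learned position embedding in
genomic order) and processed by two parallel branches:

* a Transformer encoder capturing long-range dependency structure across
  the genome-ordered CpG tokens, and
* a stack of 1-D convolutions capturing local methylation patterns among
  neighbouring sites.

Each branch is global-average-pooled and linearly projected to a common
``fusion_dim``-wide vector (``p_a`` from attention, ``p_b`` from
convolution).  A gating network produces per-dimension weights

    Z = [p_a ; p_b]
    g = sigmoid(W2 . relu(W1 . Z + b1) + b2)
    fused = g * p_a + (1 - g) * p_b

so every fused coordinate is a convex combination of the two branch
features, and the mean of ``g`` measures the attention branch's share of
the decision.  A small feed-forward head maps the fused vector to two
class logits (osteoarthritis = 1, control = 0).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from .nn.autograd import Tensor, concat, no_grad, softmax, logsumexp
from .nn.layers import (
    Adam,
    Conv1d,
    CpGEmbedding,
    GatedFusion,
    Linear,
    Module,
    TransformerEncoderLayer,
    dropout,
)

FUSION_MODES = ("gated", "concat", "transformer", "cnn")


@dataclass
class FusionModelConfig:
    """Architecture and training hyperparameters.

    The three feature widths default to 64, matching the published
    architecture; remaining values are small-sample tabular defaults and
    are all overridable.
    """

    d_model: int = 64
    cnn_out: int = 64
    fusion_dim: int = 64
    n_heads: int = 4
    n_layers: int = 2
    ff_dim: int = 128
    kernel_sizes: tuple[int, ...] = (7, 3)
    cnn_channels: tuple[int, ...] = (32,)
    dropout: float = 0.1
    lr: float = 1e-3
    batch_size: int = 16
    max_epochs: int = 200
    patience: int = 20
    class_weighting: bool = True
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        for name in ("d_model", "cnn_out", "fusion_dim", "n_heads",
                     "n_layers", "ff_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.d_model % self.n_heads != 0:
            raise ValueError("n_heads must divide d_model")


@dataclass
class GateRecord:
    """Gating matrix over samples plus branch-level mean contributions.

    ``mean_transformer_weight + mean_cnn_weight == 1`` exactly: the CNN
    share is computed as the complement of the attention share.
    """

    g: np.ndarray
    mean_transformer_weight: float
    mean_cnn_weight: float


@dataclass
class Metrics:
    acc: float
    f1: float
    auc: float | None


class TransCNN(Module):
    """The dual-branch model; ``mode`` selects the fusion variant used by
    the ablation study (gated, plain concatenation, or a single branch)."""

    def __init__(self, n_features: int, config: FusionModelConfig,
                 mode: str = "gated"):
        if mode not in FUSION_MODES:
            raise ValueError(f"unknown mode {mode!r}; use one of {FUSION_MODES}")
        cfg = config
        rng = np.random.default_rng(cfg.seed)
        self.config = cfg
        self.mode = mode
        self.n_features = n_features
        self.is_trained = False

        self.embedding = CpGEmbedding(n_features, cfg.d_model, rng)
        self.encoder_layers = [
            TransformerEncoderLayer(cfg.d_model, cfg.n_heads, cfg.ff_dim,
                                    cfg.dropout, rng)
            for _ in range(cfg.n_layers)
        ]
        self.attn_proj = Linear(cfg.d_model, cfg.fusion_dim, rng)

        chans = (cfg.d_model,) + tuple(cfg.cnn_channels) + (cfg.cnn_out,)
        if len(cfg.kernel_sizes) != len(chans) - 1:
            raise ValueError("kernel_sizes must have one entry per conv layer")
        self.conv_layers = [
            Conv1d(chans[i], chans[i + 1], k, rng)
            for i, k in enumerate(cfg.kernel_sizes)
        ]
        self.conv_proj = Linear(cfg.cnn_out, cfg.fusion_dim, rng)

        self.fusion = GatedFusion(cfg.fusion_dim, cfg.fusion_dim, rng)
        head_in = 2 * cfg.fusion_dim if mode == "concat" else cfg.fusion_dim
        self.head1 = Linear(head_in, cfg.fusion_dim, rng)
        self.head2 = Linear(cfg.fusion_dim, 2, rng)

        self.last_gate: np.ndarray | None = None

    # -- branches ----------------------------------------------------------
    def embed(self, x: Tensor) -> Tensor:
        return self.embedding(x)

    def attention_branch(self, tokens: Tensor, rng=None,
                         training: bool = False) -> Tensor:
        h = tokens
        for layer in self.encoder_layers:
            h = layer(h, rng=rng, training=training)
        pooled = h.mean(axis=1)
        return self.attn_proj(pooled)

    def convolution_branch(self, tokens: Tensor, rng=None,
                           training: bool = False) -> Tensor:
        h = tokens
        for conv in self.conv_layers:
            h = dropout(conv(h).relu(), self.config.dropout, rng, training)
        pooled = h.mean(axis=1)
        return self.conv_proj(pooled)

    def forward(self, x: Tensor, rng=None, training: bool = False) -> Tensor:
        tokens = self.embed(x)
        if self.mode == "transformer":
            feat = self.attention_branch(tokens, rng, training)
        elif self.mode == "cnn":
            feat = self.convolution_branch(tokens, rng, training)
        else:
            p_a = self.attention_branch(tokens, rng, training)
            p_b = self.convolution_branch(tokens, rng, training)
            if self.mode == "concat":
                feat = concat([p_a, p_b], axis=-1)
            else:
                feat, g = self.fusion(p_a, p_b)
                self.last_gate = g.data
        h = dropout(self.head1(feat).relu(), self.config.dropout, rng, training)
        return self.head2(h)

    __call__ = forward

    # -- inference ---------------------------------------------------------
    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Positive-class (osteoarthritis) probability per sample."""
        with no_grad():
            logits = self.forward(Tensor(np.asarray(X, dtype=float)))
            probs = softmax(logits, axis=-1).data
        return probs[:, 1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)


def gated_fusion(p_a: np.ndarray, p_b: np.ndarray, W1: np.ndarray,
                 b1: np.ndarray, W2: np.ndarray, b2: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Standalone evaluation of the gating equations on raw arrays.

    ``W1`` maps the concatenation [p_a; p_b] (width 2F) to the hidden
    layer; ``W2`` maps the hidden layer to the F gate logits.
    """
    p_a = np.atleast_2d(p_a)
    p_b = np.atleast_2d(p_b)
    if p_a.shape != p_b.shape:
        raise ValueError("branch features must have equal width")
    z = np.concatenate([p_a, p_b], axis=-1)
    hidden = np.maximum(z @ W1 + b1, 0.0)
    g = 1.0 / (1.0 + np.exp(-(hidden @ W2 + b2)))
    fused = g * p_a + (1.0 - g) * p_b
    return fused, g


# -- training ---------------------------------------------------------------

def _class_weights(y: np.ndarray) -> np.ndarray:
    counts = np.bincount(y, minlength=2)
    return y.size / (2.0 * np.maximum(counts, 1))


def _cross_entropy(logits: Tensor, y: np.ndarray,
                   sample_weights: np.ndarray) -> Tensor:
    logp = logits - logsumexp(logits, axis=-1)
    onehot = np.zeros(logits.shape)
    onehot[np.arange(y.size), y] = sample_weights
    nll = -(logp * Tensor(onehot)).sum()
    return nll * (1.0 / sample_weights.sum())


def train_model(X: np.ndarray, y: np.ndarray, config: FusionModelConfig,
                mode: str = "gated") -> tuple[TransCNN, dict]:
    """Train the fusion classifier with early stopping on validation ACC.

    A stratified validation split of ``config.val_fraction`` is carved off
    internally; the best-validation-accuracy weights are restored before
    returning.  Fully seeded from ``config.seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for training")

    X_tr, X_val, y_tr, y_val = train_test_split(
        X, y, test_size=config.val_fraction, stratify=y,
        random_state=config.seed % (2**32))

    model = TransCNN(X.shape[1], config, mode=mode)
    opt = Adam(list(model.parameters()), lr=config.lr)
    rng = np.random.default_rng(config.seed + 1)
    weights = (_class_weights(y_tr) if config.class_weighting
               else np.ones(2))

    history: dict = {"train_loss": [], "val_acc": []}
    best_acc, best_state, best_epoch, stale = -1.0, None, -1, 0
    n = y_tr.size
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = model.forward(Tensor(X_tr[idx]), rng=rng, training=True)
            loss = _cross_entropy(logits, y_tr[idx], weights[y_tr[idx]])
            if not np.isfinite(loss.item()):
                raise ArithmeticError(
                    f"training diverged (non-finite loss) at epoch {epoch}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item() * idx.size
        val_acc = float(np.mean(model.predict(X_val) == y_val))
        history["train_loss"].append(epoch_loss / n)
        history["val_acc"].append(val_acc)
        if val_acc > best_acc:
            best_acc, best_state, best_epoch = val_acc, model.state(), epoch
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    if best_state is not None:
        model.load_state(best_state)
    history["best_epoch"] = best_epoch
    history["best_val_acc"] = best_acc
    model.is_trained = True
    return model, history


# -- evaluation --------------------------------------------------------------

def _f1_positive(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = np.sum((y_pred == 1) & (y_true == 1))
    fp = np.sum((y_pred == 1) & (y_true == 0))
    fn = np.sum((y_pred == 0) & (y_true == 1))
    denom = 2 * tp + fp + fn
    return float(2 * tp / denom) if denom else 0.0


def evaluate(model: TransCNN, X: np.ndarray, y: np.ndarray) -> Metrics:
    """ACC, positive-class F1, and AUC (rank statistic over scores).

    AUC is undefined on a single-class set and reported as None.
    """
    y = np.asarray(y, dtype=int)
    scores = model.predict_proba(X)
    preds = (scores >= 0.5).astype(int)
    acc = float(np.mean(preds == y))
    f1 = _f1_positive(y, preds)
    if len(np.unique(y)) < 2:
        import warnings
        warnings.warn("AUC undefined on single-class data; reported as None")
        auc = None
    else:
        auc = float(roc_auc_score(y, scores))
    return Metrics(acc=acc, f1=f1, auc=auc)


def positive_only_accuracy(n_correct: int, n_total: int) -> float:
    """Accuracy on an all-positive cohort, rounded half-to-even to 4 dp."""
    if n_total <= 0:
        raise ValueError("empty positive-only cohort")
    if not 0 <= n_correct <= n_total:
        raise ValueError("n_correct must lie in [0, n_total]")
    return float(np.round(n_correct / n_total, 4))


def evaluate_positive_only(model: TransCNN, X_positive: np.ndarray
                           ) -> tuple[int, int, float]:
    """Sensitivity-style check on a cohort of known cases only.

    Specificity is unassessable here (no controls); only the fraction of
    cases called positive is reported.
    """
    X_positive = np.asarray(X_positive, dtype=float)
    if X_positive.shape[0] == 0:
        raise ValueError("empty positive-only cohort")
    preds = model.predict(X_positive)
    n_total = int(preds.size)
    n_correct = int(np.sum(preds == 1))
    return n_correct, n_total, positive_only_accuracy(n_correct, n_total)


def gate_contribution(model: TransCNN, X: np.ndarray) -> GateRecord:
    """Distribution of the gating vector over a cohort.

    The attention branch's mean share is mean(g) over samples and fused
    dimensions; the convolution share is its exact complement.
    """
    if not getattr(model, "is_trained", False):
        raise ValueError("gate_contribution requires a trained model")
    if model.mode != "gated":
        raise ValueError("gate statistics only exist for the gated model")
    with no_grad():
        model.forward(Tensor(np.asarray(X, dtype=float)))
    g = model.last_gate
    mean_t = float(np.mean(g))
    return GateRecord(g=g, mean_transformer_weight=mean_t,
                      mean_cnn_weight=1.0 - mean_t)


def ablation_compare(X: np.ndarray, y: np.ndarray, config: FusionModelConfig,
                     modes: tuple[str, ...] = FUSION_MODES) -> dict[str, Metrics]:
    """Train each fusion variant under identical seeds and splits and
    evaluate on the shared validation split."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _, X_val, _, y_val = train_test_split(
        X, y, test_size=config.val_fraction, stratify=y,
        random_state=config.seed % (2**32))
    results: dict[str, Metrics] = {}
    for mode in modes:
        model, _ = train_model(X, y, config, mode=mode)
        results[mode] = evaluate(model, X_val, y_val)
    return results


def gradient_importance(model: TransCNN, X: np.ndarray) -> np.ndarray:
    """Mean absolute gradient of the positive-class logit w.r.t. each input.

    importance(j) = mean over samples of |d logit_1 / d beta_j|; the
    saliency used to rank CpGs for the biomarker panel sweep.
    """
    if not getattr(model, "is_trained", False):
        raise ValueError("gradient_importance requires a trained model")
    x = Tensor(np.asarray(X, dtype=float), requires_grad=True)
    logits = model.forward(x)
    # each sample's logit depends only on its own row, so the summed
    # positive logit yields per-sample input gradients in one pass
    logits[:, 1].sum().backward()
    return np.mean(np.abs(x.grad), axis=0)
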