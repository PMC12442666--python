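"""Per-read origin model: CNN -> multi-head attention -> biLSTM -> sigmoid.

The model maps an encoded read (L x 5 one-hot with an mC channel) to the
probability that the read is of maternal (cumulus) origin.  High scores are
maternal, low scores embryonic; the embryo-enriched subset used for CNV
reconstruction is obtained by keeping low-score reads.

:class:`ReadOriginClassifier` is a scikit-learn style estimator (``fit`` /
``predict_proba`` / ``get_params``); :func:`build_model`, :func:`train` and
:func:`score_reads` are thin functional wrappers kept for pipeline use.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import auc as _auc
from sklearn.metrics import precision_recall_curve, roc_auc_score, roc_curve

from .encoder import encode_batch
from .nn import Adam, BiLSTM, Conv1d, Linear, MultiHeadAttention, Tensor
from .readio import ReadSet
from .scores import ScoreSet

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "ReadOriginClassifier",
    "build_model",
    "train",
    "score_reads",
    "evaluate",
    "save_model",
    "load_model",
]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    100 convolution filters of width 10 over the 5 input channels; the
    attention embedding equals the filter count, split across ``n_heads``
    heads (d_k = d_model / n_heads).  Module toggles support ablations;
    a disabled module is replaced by the identity (the LSTM ablation
    mean-pools over positions instead).
    """

    n_filters: int = 100
    kernel_size: int = 10
    in_channels: int = 5
    n_heads: int = 4
    lstm_hidden: int = 32
    bidirectional: bool = True
    use_cnn: bool = True
    use_attention: bool = True
    use_lstm: bool = True
    read_length: int = 66

    def __post_init__(self) -> None:
        for name in ("n_filters", "kernel_size", "in_channels", "n_heads", "lstm_hidden", "read_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        d_model = self.n_filters if self.use_cnn else self.in_channels
        if self.use_attention and d_model % self.n_heads:
            raise ValueError(f"n_heads={self.n_heads} must divide the embedding dim {d_model}")
        if self.kernel_size > self.read_length:
            raise ValueError("kernel wider than the read")


@dataclass
class TrainConfig:
    """Optimization settings: binary cross-entropy loss, Adam, an 80/20
    train/validation split with no overlap, and 1:1 class balancing by
    down-sampling the majority class."""

    epochs: int = 30
    validation_fraction: float = 0.2
    batch_size: int = 128
    learning_rate: float = 1e-3
    seed: int = 0
    balance_classes: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must lie in (0, 1)")
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs/batch_size/learning_rate must be positive")


class _Net:
    """The assembled network; forward returns logits."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        self.conv = (
            Conv1d(config.in_channels, config.n_filters, config.kernel_size, rng)
            if config.use_cnn
            else None
        )
        d_model = config.n_filters if config.use_cnn else config.in_channels
        self.attn = MultiHeadAttention(d_model, config.n_heads, rng) if config.use_attention else None
        self.lstm = (
            BiLSTM(d_model, config.lstm_hidden, rng, config.bidirectional)
            if config.use_lstm
            else None
        )
        head_in = self.lstm.out_dim if self.lstm is not None else d_model
        self.head = Linear(head_in, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = x
        if self.conv is not None:
            h = self.conv(h).relu()
        if self.attn is not None:
            h = h + self.attn(h)  # residual connection stabilizes optimization
        if self.lstm is not None:
            h = self.lstm(h)
        else:
            h = h.mean(axis=1)
        return self.head(h).reshape(-1)

    def logits(self, x: np.ndarray) -> np.ndarray:
        return self.forward(Tensor(x)).data

    def conv_activations(self, x: np.ndarray) -> np.ndarray:
        """Post-ReLU first-layer filter activations, (B, L-k+1, n_filters)."""
        if self.conv is None:
            raise ValueError("model was built without a convolution module")
        return self.conv(Tensor(x)).relu().data

    def parameters(self):
        params = []
        for mod in (self.conv, self.attn, self.lstm, self.head):
            if mod is not None:
                params += mod.parameters()
        return params

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights):
            p.data = w.astype(np.float32).copy()


def _scores_in_batches(net: _Net, X: np.ndarray, batch_size: int = 1024) -> np.ndarray:
    out = np.empty(len(X))
    for i in range(0, len(X), batch_size):
        z = net.logits(X[i : i + batch_size])
        out[i : i + batch_size] = 1.0 / (1.0 + np.exp(-z))
    return out


class ReadOriginClassifier(BaseEstimator, ClassifierMixin):
    """CNN + multi-head attention + biLSTM read-origin classifier.

    ``fit`` expects ``X`` of shape (N, L, 5) — encoded reads — and binary
    labels ``y`` (0 = embryonic, 1 = maternal).  ``predict_proba`` follows
    the sklearn convention of one column per class; the maternal
    probability (the per-read "score") is column 1 and is also returned by
    :meth:`decision_scores`.

    Attributes after fitting include ``net_`` (the underlying network),
    ``history_`` (per-epoch train/validation loss and validation AUC) and
    ``best_epoch_``; the retained weights are the best-validation-AUC
    checkpoint.
    """

    def __init__(
        self,
        n_filters: int = 100,
        kernel_size: int = 10,
        n_heads: int = 4,
        lstm_hidden: int = 32,
        bidirectional: bool = True,
        use_cnn: bool = True,
        use_attention: bool = True,
        use_lstm: bool = True,
        epochs: int = 30,
        validation_fraction: float = 0.2,
        batch_size: int = 128,
        learning_rate: float = 1e-3,
        balance_classes: bool = True,
        random_state: int = 0,
    ):
        self.n_filters = n_filters
        self.kernel_size = kernel_size
        self.n_heads = n_heads
        self.lstm_hidden = lstm_hidden
        self.bidirectional = bidirectional
        self.use_cnn = use_cnn
        self.use_attention = use_attention
        self.use_lstm = use_lstm
        self.epochs = epochs
        self.validation_fraction = validation_fraction
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.balance_classes = balance_classes
        self.random_state = random_state

    # -- config plumbing ----------------------------------------------------

    def _model_config(self, read_length: int) -> ModelConfig:
        return ModelConfig(
            n_filters=self.n_filters,
            kernel_size=self.kernel_size,
            n_heads=self.n_heads,
            lstm_hidden=self.lstm_hidden,
            bidirectional=self.bidirectional,
            use_cnn=self.use_cnn,
            use_attention=self.use_attention,
            use_lstm=self.use_lstm,
            read_length=read_length,
        )

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs,
            validation_fraction=self.validation_fraction,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            seed=self.random_state,
            balance_classes=self.balance_classes,
        )

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if X.ndim != 3 or X.shape[2] != 5:
            raise ValueError("X must have shape (n_reads, read_length, 5)")
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("both classes must be present in the training data")
        self.classes_ = classes
        y_bin = (y == classes[1]).astype(np.float32)

        tc = self._train_config()
        mc = self._model_config(read_length=X.shape[1])
        rng = np.random.default_rng(tc.seed)
        net = _Net(mc, rng)
        history = _train_loop(net, X, y_bin, tc, rng)
        self.net_ = net
        self.history_ = history
        self.best_epoch_ = history["best_epoch"]
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def decision_scores(self, X) -> np.ndarray:
        """P(maternal) for each encoded read."""
        X = np.asarray(X, dtype=np.float32)
        if len(X) == 0:
            return np.empty(0)
        return _scores_in_batches(self.net_, X)

    def predict_proba(self, X) -> np.ndarray:
        s = self.decision_scores(X)
        return np.column_stack([1.0 - s, s])

    def predict(self, X) -> np.ndarray:
        s = self.decision_scores(X)
        return self.classes_[(s > 0.5).astype(int)]

    def score_reads(self, readset: ReadSet, batch_size: int = 1024) -> ScoreSet:
        """Score a ReadSet; reads whose length does not match the model are
        rejected (the rejection count is recorded in provenance)."""
        L = self.net_.config.read_length
        ok = np.array([len(s) == L for s in readset.seq], dtype=bool)
        usable = readset[ok]
        X = encode_batch(usable.seq, usable.meth, L) if len(usable) else np.zeros((0, L, 5))
        s = self.decision_scores(X)
        labels = usable.labels_array()
        out = ScoreSet(s, labels if (labels >= 0).all() and len(usable) else None)
        out.provenance["n_rejected_length"] = int((~ok).sum())
        return out


def _train_loop(net: _Net, X: np.ndarray, y: np.ndarray, tc: TrainConfig, rng) -> dict:
    # 1:1 class balance by down-sampling the majority class
    if tc.balance_classes:
        idx0 = np.flatnonzero(y == 0)
        idx1 = np.flatnonzero(y == 1)
        k = min(idx0.size, idx1.size)
        keep = np.concatenate([rng.choice(idx0, k, replace=False), rng.choice(idx1, k, replace=False)])
        X, y = X[keep], y[keep]

    # disjoint train/validation split
    order = rng.permutation(len(X))
    n_val = max(1, int(round(tc.validation_fraction * len(X))))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    X_tr, y_tr = X[tr_idx], y[tr_idx]
    X_val, y_val = X[val_idx], y[val_idx]

    opt = Adam(net.parameters(), lr=tc.learning_rate)
    history = {"train_loss": [], "val_loss": [], "val_auc": []}
    best_auc, best_weights, best_epoch = -np.inf, None, -1
    for epoch in range(tc.epochs):
        perm = rng.permutation(len(X_tr))
        total, count = 0.0, 0
        for i in range(0, len(perm), tc.batch_size):
            sel = perm[i : i + tc.batch_size]
            xb = Tensor(X_tr[sel])
            z = net.forward(xb)
            # stable BCE on logits: mean(softplus(z) - y*z)
            loss = (z.softplus() - Tensor(y_tr[sel]) * z).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * sel.size
            count += sel.size
        s_val = _scores_in_batches(net, X_val)
        eps = 1e-7
        val_loss = float(
            -np.mean(y_val * np.log(s_val + eps) + (1 - y_val) * np.log(1 - s_val + eps))
        )
        val_auc = float(roc_auc_score(y_val, s_val)) if len(np.unique(y_val)) == 2 else float("nan")
        history["train_loss"].append(total / max(count, 1))
        history["val_loss"].append(val_loss)
        history["val_auc"].append(val_auc)
        if np.isnan(val_auc):
            metric = -val_loss
        else:
            metric = val_auc
        if metric > best_auc:
            best_auc, best_weights, best_epoch = metric, net.get_weights(), epoch
    if best_weights is not None:
        net.set_weights(best_weights)
    history["best_epoch"] = best_epoch
    history["n_train"] = len(X_tr)
    history["n_val"] = len(X_val)
    return history


# ---------------------------------------------------------------------------
# Functional wrappers


def build_model(config: ModelConfig, seed: int = 0) -> _Net:
    return _Net(config, np.random.default_rng(seed))


def train(X, y, train_config: TrainConfig | None = None, model_config: ModelConfig | None = None):
    """Fit a classifier from encoded reads and labels; returns the fitted
    :class:`ReadOriginClassifier` (its ``history_`` holds the loss/AUC
    trajectory and the best-validation checkpoint is retained)."""
    tc = train_config or TrainConfig()
    mc = model_config or ModelConfig()
    clf = ReadOriginClassifier(
        n_filters=mc.n_filters,
        kernel_size=mc.kernel_size,
        n_heads=mc.n_heads,
        lstm_hidden=mc.lstm_hidden,
        bidirectional=mc.bidirectional,
        use_cnn=mc.use_cnn,
        use_attention=mc.use_attention,
        use_lstm=mc.use_lstm,
        epochs=tc.epochs,
        validation_fraction=tc.validation_fraction,
        batch_size=tc.batch_size,
        learning_rate=tc.learning_rate,
        balance_classes=tc.balance_classes,
        random_state=tc.seed,
    )
    return clf.fit(X, y)


def score_reads(clf: ReadOriginClassifier, readset: ReadSet) -> ScoreSet:
    return clf.score_reads(readset)


def evaluate(scores: ScoreSet, exclusion: tuple[float, float] | None = None) -> dict:
    """ROC/PR evaluation with embryonic reads as the positive class.

    ``exclusion=(c, d)`` removes ambiguous reads with score strictly inside
    (c, d) before computing the curves — the reads the model cannot commit
    on — which raises the AUC of what remains.
    """
    if scores.labels is None:
        raise ValueError("labels are required for evaluation")
    s, y = scores.scores, scores.labels
    if exclusion is not None:
        c, d = exclusion
        keep = (s <= c) | (s >= d)
        s, y = s[keep], y[keep]
        if s.size == 0:
            raise ValueError("no reads remain after score-range exclusion")
    # embryonic (label 0) is positive; its score is 1 - s
    y_pos = (y == 0).astype(int)
    s_pos = 1.0 - s
    fpr, tpr, roc_thr = roc_curve(y_pos, s_pos)
    precision, recall, pr_thr = precision_recall_curve(y_pos, s_pos)
    return {
        "auc": float(_auc(fpr, tpr)),
        "roc_points": {"fpr": fpr, "tpr": tpr, "threshold": roc_thr},
        "pr_points": {"precision": precision, "recall": recall, "threshold": pr_thr},
        "n_used": int(s.size),
        "exclusion": exclusion,
    }


# ---------------------------------------------------------------------------
# Checkpoints: npz of weights plus a JSON sidecar with the configuration


def save_model(clf: ReadOriginClassifier, path) -> None:
    path = Path(path)
    weights = clf.net_.get_weights()
    np.savez(path.with_suffix(".npz"), *weights)
    sidecar = {
        "model_config": asdict(clf.net_.config),
        "params": clf.get_params(),
        "classes": np.asarray(clf.classes_).tolist(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path) -> ReadOriginClassifier:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    clf = ReadOriginClassifier(**sidecar["params"])
    mc = ModelConfig(**sidecar["model_config"])
    net = _Net(mc, np.random.default_rng(0))
    with np.load(path.with_suffix(".npz")) as data:
        net.set_weights([data[f"arr_{i}"] for i in range(len(data.files))])
    clf.net_ = net
    clf.classes_ = np.array(sidecar["classes"])
    clf.history_ = {}
    return clf
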