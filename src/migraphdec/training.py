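"""Training loop, split protocols and evaluation metrics.

Optimisation follows the decoder's published recipe: Adam with learning
rate 1e-3 and weight decay 1e-3, cross-entropy loss, dropout 0.1, and a
max-norm projection capping each spatial filter's L2 norm at 2 after every
step.  Splits support the three standard motor-imagery protocols:
session-dependent (stratified 9:1 within session 1), session-independent
(train session 1 / test session 2) and leave-one-subject-out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import accuracy_score, confusion_matrix, f1_score
from scipy.stats import wilcoxon as _wilcoxon

from .autodiff import Tensor
from .connectivity import build_graph
from .eeg_data import FilterBankSpec, TrialSet, filter_bank_batch
from .network import MIGraphNet, ModelConfig


@dataclass
class TrainConfig:
    lr: float = 1e-3
    weight_decay: float = 1e-3
    epochs: int = 500
    batch_size: int = 64
    seed: int = 0
    max_norm: float = 2.0

    def __post_init__(self):
        for name in ("lr", "weight_decay", "epochs", "batch_size", "max_norm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SplitPlan:
    mode: str
    train_idx: np.ndarray
    test_idx: np.ndarray

    def __post_init__(self):
        if set(np.asarray(self.train_idx)) & set(np.asarray(self.test_idx)):
            raise ValueError("train and test indices overlap")


class Adam:
    """Adam with uniform decoupled-from-nothing L2 weight decay (added to
    the gradient, as in classic Adam+L2)."""

    def __init__(self, params: list[Tensor], lr: float, weight_decay: float = 0.0,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p.data, dtype=np.float64) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = np.zeros_like(p.data, dtype=np.float64) if p.grad is None \
                else p.grad.astype(np.float64)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = (p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
                      ).astype(p.data.dtype)


def apply_max_norm(weights: np.ndarray, c: float) -> np.ndarray:
    """Project each row (one spatial filter) onto the L2 ball of radius c."""
    if c <= 0:
        raise ValueError("max-norm cap must be positive")
    norms = np.linalg.norm(weights, axis=-1, keepdims=True)
    scale = np.minimum(1.0, c / np.maximum(norms, 1e-12))
    return weights * scale


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy from raw logits (log-softmax inside)."""
    shift = Tensor(logits.data.max(axis=-1, keepdims=True))
    z = logits - shift
    logsumexp = z.exp().sum(axis=-1, keepdims=True).log()
    logp = z - logsumexp
    picked = logp[np.arange(len(labels)), labels]
    return -picked.mean()


def bank_for_model(config: ModelConfig) -> FilterBankSpec:
    """A 4-Hz filter bank with as many views as the model expects."""
    from .eeg_data import DEFAULT_BANDS

    if config.n_bands > len(DEFAULT_BANDS):
        raise ValueError(
            f"no default bank with {config.n_bands} views; pass one explicitly")
    return FilterBankSpec(bands=DEFAULT_BANDS[: config.n_bands])


def prepare_inputs(
    tset: TrialSet,
    bank: FilterBankSpec | None = None,
    edge_budget: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Precompute filter-bank views and per-trial PLV-graph masks.

    Returns ``x_fb`` (n, N_b, C, T) float32 and ``masks`` (n, C, C) —
    adjacency with self-loops, ready for the network.
    """
    bank = bank or FilterBankSpec()
    x_fb = filter_bank_batch(tset.signals, tset.fs, bank)
    C = tset.n_channels
    masks = np.empty((tset.n_trials, C, C), dtype=np.float32)
    eye = np.eye(C, dtype=np.float32)
    for i in range(tset.n_trials):
        masks[i] = build_graph(tset.signals[i], k=edge_budget).matrix + eye
    return x_fb, masks


@dataclass
class TrainResult:
    model: MIGraphNet
    loss_history: list[float] = field(default_factory=list)
    train_accuracy: float = float("nan")


def train(
    model: MIGraphNet,
    trainset: TrialSet,
    cfg: TrainConfig,
    bank: FilterBankSpec | None = None,
    inputs: tuple[np.ndarray, np.ndarray] | None = None,
    log=None,
) -> TrainResult:
    """Fit the decoder on a TrialSet; fully seeded and deterministic."""
    if len(np.unique(trainset.labels)) < 2:
        raise ValueError("training set must contain at least two classes")

    if inputs is None:
        bank = bank or bank_for_model(model.config)
        inputs = prepare_inputs(trainset, bank, model.config.edge_budget)
    x_fb, masks = inputs
    labels = trainset.labels
    n = len(labels)

    rng = np.random.default_rng(cfg.seed)
    model._dropout_rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    history: list[float] = []

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            opt.zero_grad()
            out = model._forward(x_fb[idx], masks[idx], training=True)
            loss = cross_entropy(out["logits"], labels[idx])
            loss.backward()
            opt.step()
            model.spatial_w.data = apply_max_norm(
                model.spatial_w.data, cfg.max_norm
            )
            epoch_loss += float(loss.data) * len(idx)
        epoch_loss /= n
        history.append(epoch_loss)
        if log is not None:
            log({"epoch": epoch, "loss": epoch_loss, "lr": cfg.lr,
                 "spatial_norm_max": float(
                     np.linalg.norm(model.spatial_w.data, axis=1).max())})

    preds = predict(model, trainset, inputs=inputs)
    acc = float(accuracy_score(labels, preds))
    return TrainResult(model=model, loss_history=history, train_accuracy=acc)


def predict(
    model: MIGraphNet,
    tset: TrialSet,
    bank: FilterBankSpec | None = None,
    inputs: tuple[np.ndarray, np.ndarray] | None = None,
    batch_size: int = 64,
) -> np.ndarray:
    if inputs is None:
        bank = bank or bank_for_model(model.config)
        inputs = prepare_inputs(tset, bank, model.config.edge_budget)
    x_fb, masks = inputs
    preds = []
    for start in range(0, len(x_fb), batch_size):
        logits = model.predict_logits(x_fb[start : start + batch_size],
                                      masks[start : start + batch_size])
        preds.append(np.argmax(logits, axis=-1))
    return np.concatenate(preds)


def evaluate(
    model: MIGraphNet,
    testset: TrialSet,
    bank: FilterBankSpec | None = None,
    inputs: tuple[np.ndarray, np.ndarray] | None = None,
) -> dict:
    """Accuracy, macro-F1 and confusion matrix (rows = true classes)."""
    if testset.n_trials == 0:
        raise ValueError("empty test set")
    preds = predict(model, testset, bank, inputs)
    all_labels = np.arange(testset.n_classes)
    return {
        "accuracy": float(accuracy_score(testset.labels, preds)),
        "macro_f1": float(f1_score(testset.labels, preds, labels=all_labels,
                                   average="macro", zero_division=0)),
        "confusion": confusion_matrix(testset.labels, preds, labels=all_labels),
        "predictions": preds,
    }


# ---------------------------------------------------------------------------
# split protocols

def make_splits(tset: TrialSet, mode: str, seed: int = 0) -> SplitPlan | list[SplitPlan]:
    """Build the index split(s) for one of the three evaluation protocols."""
    if mode == "session_dependent":
        if tset.session is None:
            raise ValueError("session metadata required for session_dependent")
        return _stratified_within_session(tset, seed)
    if mode == "session_independent":
        if tset.session is None:
            raise ValueError("session metadata required for session_independent")
        train_idx = np.nonzero(tset.session == 1)[0]
        test_idx = np.nonzero(tset.session == 2)[0]
        return SplitPlan(mode, train_idx, test_idx)
    if mode == "subject_independent":
        if tset.subject is None:
            raise ValueError("subject metadata required for subject_independent")
        plans = []
        for subj in np.unique(tset.subject):
            test_idx = np.nonzero(tset.subject == subj)[0]
            train_idx = np.nonzero(tset.subject != subj)[0]
            plans.append(SplitPlan(mode, train_idx, test_idx))
        return plans
    raise ValueError(f"unknown split mode {mode!r}")


def _stratified_within_session(tset: TrialSet, seed: int) -> SplitPlan:
    """Stratified 9:1 inside session 1; per-class test count is
    floor(n_class/10), remainder stays in training."""
    rng = np.random.default_rng(seed)
    sess1 = np.nonzero(tset.session == 1)[0]
    test: list[int] = []
    train: list[int] = []
    for cls in np.unique(tset.labels[sess1]):
        idx = sess1[tset.labels[sess1] == cls]
        idx = rng.permutation(idx)
        n_test = len(idx) // 10
        test.extend(idx[:n_test])
        train.extend(idx[n_test:])
    return SplitPlan("session_dependent", np.sort(train), np.sort(test))


def wilcoxon_signed_rank(a, b) -> dict:
    """Thin paired-comparison wrapper (subject-level score vectors)."""
    stat, p = _wilcoxon(a, b)
    return {"statistic": float(stat), "p_value": float(p)}


def edge_budget_sweep(
    budgets: list[int],
    train_set: TrialSet,
    test_set: TrialSet,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
) -> dict[int, float]:
    """Sensitivity of decoding accuracy to the PLV-graph edge budget.

    Trains one model per budget (sharing the filter-bank views, which do
    not depend on the graph) and returns {budget: test accuracy}.
    """
    tc = train_config or TrainConfig(epochs=50)
    results: dict[int, float] = {}
    bank = FilterBankSpec()
    x_tr = filter_bank_batch(train_set.signals, train_set.fs, bank)
    x_te = filter_bank_batch(test_set.signals, test_set.fs, bank)
    for k in budgets:
        mc = ModelConfig(**{**(model_config or ModelConfig()).to_dict(),
                            "edge_budget": k})
        masks_tr = _graph_masks(train_set, k)
        masks_te = _graph_masks(test_set, k)
        model = MIGraphNet(mc, seed=tc.seed)
        train(model, train_set, tc, inputs=(x_tr, masks_tr))
        metrics = evaluate(model, test_set, inputs=(x_te, masks_te))
        results[k] = metrics["accuracy"]
    return results


def _graph_masks(tset: TrialSet, k: int) -> np.ndarray:
    C = tset.n_channels
    masks = np.empty((tset.n_trials, C, C), dtype=np.float32)
    eye = np.eye(C, dtype=np.float32)
    for i in range(tset.n_trials):
        masks[i] = build_graph(tset.signals[i], k=k).matrix + eye
    return masks
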