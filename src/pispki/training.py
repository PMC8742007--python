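"""Training loop with bootstrapped turns and early stopping, plus baselines.

Every epoch draws a fresh class-balanced bootstrap *turn* from the training
and validation partitions (2048 and 256 samples per class by default), so
the heavily imbalanced per-atom data is seen through balanced resamples.
Validation accuracy drives early stopping: training halts after `patience`
(default 5) consecutive epochs without a new best, and the recorded
accuracy is the one from the last improving epoch — the sixth-to-last
validation when the stop triggers.

Loss is binary cross-entropy on the logit; the optimiser is Adam at 1e-3.
Both are standard choices exposed in :class:`TrainConfig`.

Baselines: an RBF-kernel SVM and a small two-convolution network, both on
feature matrices zero-padded to the dataset's maximum atom count, with the
best of `repeats` runs reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .dataset import Dataset, Split, bootstrap_turn, shuffle_labels
from .model import PISPKIModel


@dataclass
class TrainConfig:
    batch_size: int = 16
    turn_train: int = 2048   # per class
    turn_val: int = 256      # per class
    patience: int = 5
    max_epochs: int = 200
    lr: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.batch_size > 2 * self.turn_train:
            raise ValueError("batch size cannot exceed the turn size")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    stop_epoch: int | None = None   # 1-based epoch at which patience ran out
    best_epoch: int = 0             # 1-based epoch of the recorded accuracy
    recorded_accuracy: float = 0.0


def early_stop_epoch(accuracies, patience: int = 5) -> int | None:
    """First 1-based epoch with `patience` consecutive non-improvements
    over the running best; None if the sequence never triggers."""
    best = -np.inf
    since = 0
    for e, a in enumerate(accuracies, start=1):
        if a > best:
            best = a
            since = 0
        else:
            since += 1
            if since == patience:
                return e
    return None


def evaluate(model: PISPKIModel, ds: Dataset) -> float:
    """Accuracy at threshold 0.5, dropout off."""
    y = ds.labels()
    pred = np.array([model.predict(s) for s in ds.samples])
    return float((pred == y).mean())


def evaluate_detailed(model: PISPKIModel, ds: Dataset) -> dict[str, float]:
    y = ds.labels()
    pred = np.array([model.predict(s) for s in ds.samples])
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return {
        "accuracy": float((pred == y).mean()),
        "precision": tp / (tp + fp) if tp + fp else 0.0,
        "recall": tp / (tp + fn) if tp + fn else 0.0,
    }


def train(model: PISPKIModel, split: Split, cfg: TrainConfig
          ) -> tuple[PISPKIModel, TrainHistory]:
    """Train with per-epoch bootstrap turns until early stopping or max epochs.

    All randomness (turn resampling, batch dropout) derives from cfg.seed,
    so identical configs replay identical histories on CPU.
    """
    if len(split.train) == 0 or len(split.validation) == 0:
        raise ValueError("train and validation partitions must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    opt = ad.Adam(model.parameters(), lr=cfg.lr)
    hist = TrainHistory()
    best = -np.inf
    since = 0
    best_state = [p.data.copy() for p in model.parameters()]
    for epoch in range(1, cfg.max_epochs + 1):
        turn = bootstrap_turn(split.train, cfg.turn_train, seed=rng)
        val_turn = bootstrap_turn(split.validation, cfg.turn_val, seed=rng)
        losses = []
        for lo in range(0, len(turn), cfg.batch_size):
            batch = turn.samples[lo : lo + cfg.batch_size]
            opt.zero_grad()
            for s in batch:
                z = model.forward_logit(s, train=True, rng=rng)
                loss = ad.bce_with_logits(z, float(s.label))
                loss.backward()
                losses.append(float(loss.data[0]))
            opt.step(grad_scale=1.0 / len(batch))
        hist.train_loss.append(float(np.mean(losses)))
        acc = evaluate(model, val_turn)
        hist.val_accuracy.append(acc)
        if acc > best:
            best = acc
            since = 0
            hist.best_epoch = epoch
            best_state = [p.data.copy() for p in model.parameters()]
        else:
            since += 1
            if since == cfg.patience:
                hist.stop_epoch = epoch
                break
    hist.recorded_accuracy = float(best)
    for p, s in zip(model.parameters(), best_state):
        p.data[...] = s
    return model, hist


def shuffled_control(model: PISPKIModel, val: Dataset, seed=0,
                     subset: int | None = None) -> tuple[float, float]:
    """Evaluate on a validation subset and its label-shuffled twin.

    A model that learned the real signal scores well on the former and
    near 50% (chance, balanced classes) on the latter.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    ds = val
    if subset is not None and subset < len(val):
        ds = val.subset(rng.choice(len(val), size=subset, replace=False))
    acc_real = evaluate(model, ds)
    acc_shuffled = evaluate(model, shuffle_labels(ds, seed=rng))
    return acc_real, acc_shuffled


# -- baselines -------------------------------------------------------------

def _padded_features(ds: Dataset, n_max: int) -> np.ndarray:
    w = ds.samples[0].F_marked.shape[1]
    out = np.zeros((len(ds), n_max, w))
    for i, s in enumerate(ds.samples):
        out[i, : s.n_atoms] = s.F_marked
    return out


def max_atoms(*parts: Dataset) -> int:
    return max(s.n_atoms for p in parts for s in p.samples)


def baseline_svm(split: Split, repeats: int = 10, seed: int = 0,
                 train_cap: int | None = None) -> float:
    """RBF-kernel SVM on zero-padded, flattened feature matrices.

    Reports the best test accuracy over `repeats` runs (each run reshuffles
    the training subsample and the SVC random state).
    """
    from sklearn.svm import SVC

    n_max = max_atoms(split.train, split.validation, split.test)
    x_test = _padded_features(split.test, n_max).reshape(len(split.test), -1)
    y_test = split.test.labels()
    x_train_full = _padded_features(split.train, n_max).reshape(len(split.train), -1)
    y_train_full = split.train.labels()
    rng = np.random.default_rng(seed)
    best = 0.0
    for _ in range(repeats):
        idx = rng.permutation(len(y_train_full))
        if train_cap is not None:
            idx = idx[:train_cap]
        clf = SVC(kernel="rbf", random_state=int(rng.integers(2**31)))
        clf.fit(x_train_full[idx], y_train_full[idx])
        best = max(best, float((clf.predict(x_test) == y_test).mean()))
    return best


class _ConvNetBaseline:
    """Two convolution stages + one dense layer on padded feature matrices."""

    def __init__(self, n_max: int, width: int, rng: np.random.Generator,
                 slope: float = 0.01):
        self.slope = slope
        self.n_max = n_max
        self.width = width

        def conv(cin, cout):
            lim = 1.0 / np.sqrt(cin * 9)
            return (ad.Tensor(rng.uniform(-lim, lim, (cout, cin, 3, 3)),
                              requires_grad=True),
                    ad.Tensor(np.zeros(cout), requires_grad=True))

        self.c1w, self.c1b = conv(1, 2)
        self.c2w, self.c2b = conv(2, 5)
        d = 5 * n_max * width
        lim = 1.0 / np.sqrt(d)
        self.w = ad.Tensor(rng.uniform(-lim, lim, (1, d)), requires_grad=True)
        self.b = ad.Tensor(np.zeros(1), requires_grad=True)

    def parameters(self):
        return [self.c1w, self.c1b, self.c2w, self.c2b, self.w, self.b]

    def logit(self, x: np.ndarray) -> ad.Tensor:
        t = ad.Tensor(x[None, :, :])
        t = ad.leaky_relu(ad.conv2d_same(t, self.c1w, self.c1b), self.slope)
        t = ad.leaky_relu(ad.conv2d_same(t, self.c2w, self.c2b), self.slope)
        return self.w @ t.reshape(-1) + self.b

    def predict(self, x: np.ndarray) -> int:
        with ad.no_grad():
            return int(self.logit(x).data[0] >= 0.0)


def baseline_convnet(split: Split, repeats: int = 10, seed: int = 0,
                     epochs: int = 10, batch_size: int = 16,
                     turn_per_class: int = 256, lr: float = 1e-3) -> float:
    """Conv-Net baseline: trained on balanced turns, best of `repeats`."""
    n_max = max_atoms(split.train, split.validation, split.test)
    width = split.train.samples[0].F_marked.shape[1]
    x_test = _padded_features(split.test, n_max)
    y_test = split.test.labels()
    rng = np.random.default_rng(seed)
    best = 0.0
    for _ in range(repeats):
        net = _ConvNetBaseline(n_max, width, rng)
        opt = ad.Adam(net.parameters(), lr=lr)
        for _epoch in range(epochs):
            turn = bootstrap_turn(split.train, turn_per_class, seed=rng)
            xs = _padded_features(turn, n_max)
            ys = turn.labels()
            for lo in range(0, len(ys), batch_size):
                opt.zero_grad()
                for x, y in zip(xs[lo : lo + batch_size], ys[lo : lo + batch_size]):
                    loss = ad.bce_with_logits(net.logit(x), float(y))
                    loss.backward()
                opt.step(grad_scale=1.0 / len(ys[lo : lo + batch_size]))
        acc = float(np.mean([net.predict(x) == y for x, y in zip(x_test, y_test)]))
        best = max(best, acc)
    return best
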