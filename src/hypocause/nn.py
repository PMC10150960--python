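"""A compact NumPy feed-forward classifier with dropout.

Architecture: three fully connected hidden layers of equal width (set to the
number of input features), ReLU activations, inverted dropout (default rate
0.6) after each hidden layer, and either a single sigmoid unit (binary) or a
3-way softmax output. Trained full-batch with Adam on observation-weighted
cross-entropy.

Model selection is objective-driven: 20% of the training data (grouped by
subject) is held out internally; the parameter checkpoint — and, for binary
models, the decision threshold — maximizing the requested objective
(F1, recall or precision) on that split is kept. Early stopping uses the
same internal objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import f1_recall_precision

__all__ = ["NNConfig", "NeuralClassifier"]


@dataclass(frozen=True)
class NNConfig:
    dropout: float = 0.6
    learning_rate: float = 1e-2
    batch_size: int = 64
    max_epochs: int = 600
    #: epochs without internal-objective improvement before stopping; with
    #: 60% dropout the internal score is noisy early on, so the patience
    #: window spans 30 evaluation checks
    patience: int = 150
    eval_every: int = 5  # epochs between internal-objective evaluations
    internal_holdout: float = 0.2
    objective: str = "f1"  # 'f1' | 'recall' | 'precision'

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.objective not in ("f1", "recall", "precision"):
            raise ValueError(f"unknown objective {self.objective!r}")


def _relu(x):
    return np.maximum(x, 0.0)


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class NeuralClassifier:
    """3-hidden-layer dropout MLP; hidden width equals the input dimension."""

    def __init__(self, n_classes: int, config: NNConfig = NNConfig(), seed: int = 0) -> None:
        if n_classes not in (2, 3):
            raise ValueError("supports binary (2) or 3-class problems")
        self.n_classes = n_classes
        self.config = config
        self.seed = seed
        self.threshold = 0.5  # binary decision threshold (objective-selected)
        self.params: list[np.ndarray] | None = None

    # -- forward ---------------------------------------------------------

    def _init_params(self, d: int, rng: np.random.Generator) -> list[np.ndarray]:
        out_dim = 1 if self.n_classes == 2 else 3
        dims = [d, d, d, d, out_dim]
        params = []
        for a, b in zip(dims[:-1], dims[1:]):
            params.append(rng.normal(0.0, np.sqrt(2.0 / a), size=(a, b)))
            params.append(np.zeros(b))
        return params

    def _forward(self, X, params, rng=None, dropout=0.0):
        h = X
        cache = [h]
        masks = []
        for layer in range(3):
            W, b = params[2 * layer], params[2 * layer + 1]
            h = _relu(h @ W + b)
            if dropout > 0.0 and rng is not None:
                m = (rng.random(h.shape) >= dropout) / (1.0 - dropout)
                h = h * m
                masks.append(m)
            else:
                masks.append(None)
            cache.append(h)
        W, b = params[6], params[7]
        logits = h @ W + b
        return logits, cache, masks

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.params is None:
            raise RuntimeError("classifier is not fitted")
        logits, _, _ = self._forward(np.asarray(X, dtype=float), self.params)
        if self.n_classes == 2:
            p1 = 1.0 / (1.0 + np.exp(-np.clip(logits[:, 0], -500, 500)))
            return np.column_stack([1.0 - p1, p1])
        return _softmax(logits)

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(X)
        if self.n_classes == 2:
            return (proba[:, 1] >= self.threshold).astype(int)
        return np.argmax(proba, axis=1)

    # -- training --------------------------------------------------------

    def _objective_score(self, y_true, proba, threshold=None) -> float:
        """The configured objective on labels derived from ``proba``; for
        multiclass problems the class-average (macro) of the metric."""
        obj = self.config.objective
        if self.n_classes == 2:
            thr = self.threshold if threshold is None else threshold
            y_pred = (proba[:, 1] >= thr).astype(int)
            scores = f1_recall_precision(y_true, y_pred, classes=[0, 1])
            return scores[1][obj]
        y_pred = np.argmax(proba, axis=1)
        per_class = f1_recall_precision(y_true, y_pred, classes=list(range(3)))
        return float(np.mean([per_class[c][obj] for c in per_class]))

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        sample_weight: np.ndarray | None = None,
        groups: np.ndarray | None = None,
    ) -> "NeuralClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        n, d = X.shape
        if len(np.unique(y)) < 2:
            raise ValueError("training fold contains a single class")
        w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=float)
        rng = np.random.default_rng(self.seed)

        # internal grouped 20% holdout for objective-based model selection
        if groups is None:
            groups = np.arange(n)
        uniq = np.unique(groups)
        perm = rng.permutation(len(uniq))
        n_hold = max(1, int(round(self.config.internal_holdout * len(uniq))))
        hold_groups = set(uniq[perm[:n_hold]])
        hold = np.array([g in hold_groups for g in groups])
        if hold.all() or len(np.unique(y[~hold])) < 2:
            # degenerate split: train on everything, select on training data
            hold = np.zeros(n, dtype=bool)
        Xt, yt, wt = X[~hold], y[~hold], w[~hold]
        Xv, yv = (X[hold], y[hold]) if hold.any() else (Xt, yt)

        params = self._init_params(d, rng)
        m_adam = [np.zeros_like(p) for p in params]
        v_adam = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        lr = self.config.learning_rate
        wt_norm = wt / wt.sum()

        onehot = None
        if self.n_classes == 3:
            onehot = np.zeros((len(yt), 3))
            onehot[np.arange(len(yt)), yt] = 1.0

        best_score, best_params, best_epoch = -np.inf, [p.copy() for p in params], 0
        step = 0
        n_train = len(yt)
        batch = min(self.config.batch_size, n_train)
        for epoch in range(1, self.config.max_epochs + 1):
            order = rng.permutation(n_train)
            for start in range(0, n_train, batch):
                idx = order[start : start + batch]
                Xb, yb, wb = Xt[idx], yt[idx], wt[idx]
                logits, cache, masks = self._forward(
                    Xb, params, rng=rng, dropout=self.config.dropout
                )
                wb_norm = wb / wb.sum()
                if self.n_classes == 2:
                    p1 = 1.0 / (1.0 + np.exp(-np.clip(logits[:, 0], -500, 500)))
                    dlogits = ((p1 - yb) * wb_norm)[:, None]
                else:
                    probs = _softmax(logits)
                    dlogits = (probs - onehot[idx]) * wb_norm[:, None]

                grads = [np.zeros_like(p) for p in params]
                delta = dlogits
                grads[6] = cache[3].T @ delta
                grads[7] = delta.sum(axis=0)
                delta = delta @ params[6].T
                for layer in (2, 1, 0):
                    h = cache[layer + 1]
                    if masks[layer] is not None:
                        delta = delta * masks[layer]
                    delta = delta * (h > 0)
                    grads[2 * layer] = cache[layer].T @ delta
                    grads[2 * layer + 1] = delta.sum(axis=0)
                    if layer > 0:
                        delta = delta @ params[2 * layer].T

                step += 1
                for i in range(len(params)):
                    m_adam[i] = beta1 * m_adam[i] + (1 - beta1) * grads[i]
                    v_adam[i] = beta2 * v_adam[i] + (1 - beta2) * grads[i] ** 2
                    mhat = m_adam[i] / (1 - beta1**step)
                    vhat = v_adam[i] / (1 - beta2**step)
                    params[i] -= lr * mhat / (np.sqrt(vhat) + eps)

            if epoch % self.config.eval_every == 0 or epoch == self.config.max_epochs:
                self.params = params
                score = self._objective_score(yv, self.predict_proba(Xv), threshold=0.5)
                if score > best_score + 1e-12:
                    best_score, best_epoch = score, epoch
                    best_params = [p.copy() for p in params]
                elif epoch - best_epoch >= self.config.patience:
                    break

        self.params = best_params
        # objective-driven decision threshold (binary only)
        if self.n_classes == 2:
            proba = self.predict_proba(Xv)
            grid = np.linspace(0.05, 0.95, 19)
            scores = [self._objective_score(yv, proba, threshold=t) for t in grid]
            self.threshold = float(grid[int(np.argmax(scores))])
        return self
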