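"""Feed-forward patch scorer with nested cross-validated ensemble training.

The scorer is a small fully connected network — two hidden layers of 25
sigmoid units and a single sigmoid output — trained with Adam on the overlap
target in [0, 1]. Training follows a nested 5-partition / 10-fold scheme: for
each outer partition, the remaining four partitions are split into 10
sub-partitions that keep complexes of the same cluster together; ten networks
are trained, each early-stopped on its own validation sub-partition, and
their mean output scores the held-out partition. Inputs are z-scored with
parameters fitted on each member's training folds only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .dataset import TrainingExample
from .features import FeatureLayout, PatchDescriptor, assemble_feature_vector

__all__ = [
    "TrainingParams",
    "FeedForwardNet",
    "ScorerEnsemble",
    "train_nested_cv",
    "score_pair",
    "examples_to_matrix",
]


@dataclass
class TrainingParams:
    """Optimizer and early-stopping settings."""

    hidden: tuple[int, int] = (25, 25)
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    batch_size: int = 32
    max_epochs: int = 500
    patience: int = 10
    loss: str = "bce"  # "bce" | "mse"


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class FeedForwardNet:
    """2-hidden-layer sigmoid network trained with Adam."""

    def __init__(self, n_in: int, params: TrainingParams, seed: int = 0):
        self.params = params
        rng = np.random.default_rng(seed)
        sizes = [n_in, *params.hidden, 1]
        self.weights = []
        self.biases = []
        for a, b in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / (a + b))  # Glorot uniform
            self.weights.append(rng.uniform(-limit, limit, size=(a, b)))
            self.biases.append(np.zeros(b))

    # -- forward / backward -------------------------------------------------
    def _forward(self, x: np.ndarray) -> list[np.ndarray]:
        acts = [x]
        for w, b in zip(self.weights, self.biases):
            acts.append(_sigmoid(acts[-1] @ w + b))
        return acts

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self._forward(np.asarray(x, dtype=float))[-1][:, 0]

    def _loss(self, p: np.ndarray, y: np.ndarray) -> float:
        if self.params.loss == "bce":
            p = np.clip(p, 1e-12, 1 - 1e-12)
            return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
        return float(np.mean((p - y) ** 2))

    def _output_delta(self, p: np.ndarray, y: np.ndarray) -> np.ndarray:
        if self.params.loss == "bce":
            return (p - y) / len(y)  # sigmoid + BCE
        return 2.0 * (p - y) * p * (1 - p) / len(y)

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        x_val: np.ndarray,
        y_val: np.ndarray,
        seed: int = 0,
    ) -> dict:
        """Adam minibatch training with early stopping on validation loss."""
        pr = self.params
        rng = np.random.default_rng(seed)
        m = [np.zeros_like(w) for w in self.weights] + [np.zeros_like(b) for b in self.biases]
        v = [np.zeros_like(g) for g in m]
        t = 0
        best_val = np.inf
        best_state = None
        stale = 0
        epochs_run = 0
        for epoch in range(pr.max_epochs):
            order = rng.permutation(len(x))
            for lo in range(0, len(x), pr.batch_size):
                batch = order[lo:lo + pr.batch_size]
                xb, yb = x[batch], y[batch]
                acts = self._forward(xb)
                delta = self._output_delta(acts[-1][:, 0], yb)[:, None]
                grads_w, grads_b = [], []
                for layer in range(len(self.weights) - 1, -1, -1):
                    a_prev = acts[layer]
                    grads_w.append(a_prev.T @ delta)
                    grads_b.append(delta.sum(axis=0))
                    if layer > 0:
                        delta = (delta @ self.weights[layer].T) * acts[layer] * (1 - acts[layer])
                grads = list(reversed(grads_w)) + list(reversed(grads_b))
                t += 1
                params = self.weights + self.biases
                for k, (p_arr, g) in enumerate(zip(params, grads)):
                    m[k] = pr.beta1 * m[k] + (1 - pr.beta1) * g
                    v[k] = pr.beta2 * v[k] + (1 - pr.beta2) * g * g
                    mhat = m[k] / (1 - pr.beta1 ** t)
                    vhat = v[k] / (1 - pr.beta2 ** t)
                    p_arr -= pr.learning_rate * mhat / (np.sqrt(vhat) + pr.eps)
            epochs_run = epoch + 1
            val_loss = self._loss(self.predict(x_val), y_val)
            if val_loss < best_val - 1e-9:
                best_val = val_loss
                best_state = ([w.copy() for w in self.weights],
                              [b.copy() for b in self.biases])
                stale = 0
            else:
                stale += 1
                if stale >= pr.patience:
                    break
        if best_state is not None:
            self.weights, self.biases = best_state
        return {"epochs": epochs_run, "val_loss": best_val}


@dataclass
class _Member:
    net: FeedForwardNet
    mean: np.ndarray
    std: np.ndarray

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.net.predict((x - self.mean) / self.std)


@dataclass
class ScorerEnsemble:
    """Ten networks sharing a feature layout; prediction is the member mean."""

    members: list[_Member]
    layout: FeatureLayout
    metadata: dict = field(default_factory=dict)

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.layout.length:
            raise ValueError(
                f"layout mismatch: expected {self.layout.length} features, got {x.shape[1]}")
        return np.mean([m.predict(x) for m in self.members], axis=0)

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for i, m in enumerate(self.members):
            np.savez(path / f"member_{i}.npz",
                     mean=m.mean, std=m.std,
                     **{f"w{j}": w for j, w in enumerate(m.net.weights)},
                     **{f"b{j}": b for j, b in enumerate(m.net.biases)})
        (path / "metadata.json").write_text(json.dumps(
            {"layout": self.layout.kind, "n_members": len(self.members),
             **self.metadata}, indent=2))

    @classmethod
    def load(cls, path) -> "ScorerEnsemble":
        path = Path(path)
        meta = json.loads((path / "metadata.json").read_text())
        layout = FeatureLayout(meta["layout"])
        members = []
        for i in range(meta["n_members"]):
            data = np.load(path / f"member_{i}.npz")
            n_layers = len([k for k in data.files if k.startswith("w")])
            net = FeedForwardNet(data["w0"].shape[0], TrainingParams())
            net.weights = [data[f"w{j}"] for j in range(n_layers)]
            net.biases = [data[f"b{j}"] for j in range(n_layers)]
            members.append(_Member(net=net, mean=data["mean"], std=data["std"]))
        return cls(members=members, layout=layout,
                   metadata={k: v for k, v in meta.items()
                             if k not in ("layout", "n_members")})


# ---------------------------------------------------------------------------
# training orchestration
# ---------------------------------------------------------------------------

def examples_to_matrix(
    examples: Sequence[TrainingExample], layout: FeatureLayout | str
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix and target vector for a set of training examples."""
    kind = layout.kind if isinstance(layout, FeatureLayout) else layout
    x = np.array([
        assemble_feature_vector(
            ex.antigen_desc,
            None if kind == "antigen" else ex.paratope_desc,
            kind,
        )
        for ex in examples
    ])
    y = np.array([ex.target for ex in examples])
    return x, y


def _subpartition_folds(
    examples: Sequence[TrainingExample],
    cluster_of: dict[str, int],
    n_folds: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Assign each example a sub-partition, keeping clusters together."""
    clusters = sorted({cluster_of[ex.complex_id] for ex in examples})
    shuffled = list(rng.permutation(clusters))
    fold_of_cluster = {c: i % n_folds for i, c in enumerate(shuffled)}
    return np.array([fold_of_cluster[cluster_of[ex.complex_id]] for ex in examples])


def train_nested_cv(
    examples: Sequence[TrainingExample],
    cluster_of: dict[str, int],
    layout: FeatureLayout | str = "full",
    params: TrainingParams | None = None,
    seed: int = 0,
    n_inner_folds: int = 10,
) -> dict[int, ScorerEnsemble]:
    """Nested cross-validation: one 10-member ensemble per outer partition.

    The ensemble returned for partition ``p`` never saw any example from
    ``p``; each member is early-stopped on one inner sub-partition of the
    remaining partitions, split along cluster boundaries.
    """
    if isinstance(layout, str):
        layout = FeatureLayout(layout)
    params = params or TrainingParams()
    partitions = sorted({ex.partition for ex in examples})
    if len(partitions) < 2:
        raise ValueError("nested cross-validation needs >= 2 partitions")
    for p in partitions:
        if not any(ex.partition == p for ex in examples):  # pragma: no cover
            raise ValueError(f"partition {p} has no examples")

    root = np.random.default_rng(seed)
    ensembles: dict[int, ScorerEnsemble] = {}
    for p in partitions:
        train_ex = [ex for ex in examples if ex.partition != p]
        if not train_ex:
            raise ValueError(f"no training examples outside partition {p}")
        x, y = examples_to_matrix(train_ex, layout)
        rng = np.random.default_rng(root.integers(2**31 - 1))
        folds = _subpartition_folds(train_ex, cluster_of, n_inner_folds, rng)
        members = []
        for fold in range(n_inner_folds):
            val_mask = folds == fold
            if not val_mask.any() or val_mask.all():
                # inner fold empty (few clusters): fall back to a random split
                val_mask = rng.random(len(train_ex)) < 0.1
                if not val_mask.any():
                    val_mask[rng.integers(len(train_ex))] = True
            tr = ~val_mask
            mean = x[tr].mean(axis=0)
            std = x[tr].std(axis=0)
            std[std < 1e-8] = 1.0
            xs = (x - mean) / std
            net = FeedForwardNet(layout.length, params,
                                 seed=int(rng.integers(2**31 - 1)))
            net.fit(xs[tr], y[tr], xs[val_mask], y[val_mask],
                    seed=int(rng.integers(2**31 - 1)))
            members.append(_Member(net=net, mean=mean, std=std))
        ensembles[p] = ScorerEnsemble(
            members=members, layout=layout,
            metadata={"held_out_partition": p, "seed": seed,
                      "n_train_examples": len(train_ex)},
        )
    return ensembles


def score_pair(
    ensemble: ScorerEnsemble,
    antigen_desc: PatchDescriptor,
    paratope_desc: PatchDescriptor | None = None,
) -> float:
    """Ensemble score of one antigen patch / paratope pair, in (0, 1)."""
    kind = ensemble.layout.kind
    vec = assemble_feature_vector(
        antigen_desc, None if kind == "antigen" else paratope_desc, kind)
    return float(ensemble.predict(vec[None, :])[0])
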