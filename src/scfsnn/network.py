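"""Fully connected softmax classifier with manual backpropagation.

Architecture: input -> 256 -> 128 -> K, ReLU hidden units, batch
normalization and dropout (rate 0.5) on each hidden layer, cross-entropy
loss, Adam optimizer (lr 0.001), minibatches of 32.  Implemented directly on
NumPy arrays so that the exact gradient of each per-sample loss with respect
to each input coordinate is available in closed form — that gradient is the
feature-importance primitive of the selection procedure.

Evaluation mode freezes batch-norm at its running statistics and disables
dropout, so prediction and input-gradient computation are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NetConfig", "DenseClassifier", "build_model", "train", "predict", "accuracy"]


@dataclass
class NetConfig:
    hidden_sizes: tuple[int, ...] = (256, 128)
    dropout_rate: float = 0.5
    learning_rate: float = 1e-3
    batch_size: int = 32
    init_epochs: int = 30
    step_epochs: int = 3
    bn_eps: float = 1e-5
    bn_momentum: float = 0.1  # update weight of batch stats in running stats
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    dtype: str = "float32"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if min(self.hidden_sizes) <= 0 or self.batch_size <= 0 or self.learning_rate <= 0:
            raise ValueError("hidden sizes, batch size and learning rate must be positive")
        if self.init_epochs < 0 or self.step_epochs < 0:
            raise ValueError("epoch counts must be >= 0")


class DenseClassifier:
    """MLP classifier whose first-layer width can shrink as features are eliminated."""

    def __init__(
        self,
        n_features: int,
        n_classes: int,
        cfg: NetConfig,
        rng: np.random.Generator,
    ) -> None:
        if n_features < 1 or n_classes < 2:
            raise ValueError("need n_features >= 1 and n_classes >= 2")
        self.cfg = cfg
        self.n_features = n_features
        self.n_classes = n_classes
        self.dtype = np.dtype(cfg.dtype)
        self._rng = rng  # owns init and all training stochasticity
        sizes = [n_features, *cfg.hidden_sizes, n_classes]
        self.params: dict[str, np.ndarray] = {}
        self.n_hidden = len(cfg.hidden_sizes)
        for layer, (fan_in, fan_out) in enumerate(zip(sizes[:-1], sizes[1:])):
            # He initialisation for the ReLU layers, Glorot-like scale for the head
            std = np.sqrt(2.0 / fan_in)
            self.params[f"W{layer}"] = (rng.standard_normal((fan_in, fan_out)) * std).astype(self.dtype)
            self.params[f"b{layer}"] = np.zeros(fan_out, dtype=self.dtype)
        self.bn: dict[str, np.ndarray] = {}
        for layer, width in enumerate(cfg.hidden_sizes):
            self.bn[f"gamma{layer}"] = np.ones(width, dtype=self.dtype)
            self.bn[f"beta{layer}"] = np.zeros(width, dtype=self.dtype)
            self.bn[f"rmean{layer}"] = np.zeros(width, dtype=self.dtype)
            self.bn[f"rvar{layer}"] = np.ones(width, dtype=self.dtype)
        # Adam state over trainable parameters (weights, biases, bn affine)
        self._adam_t = 0
        self._adam_m = {k: np.zeros_like(v) for k, v in self._trainables().items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self._trainables().items()}
        self.loss_history: list[float] = []

    # -- parameter bookkeeping -------------------------------------------------

    def _trainables(self) -> dict[str, np.ndarray]:
        out = dict(self.params)
        for layer in range(self.n_hidden):
            out[f"gamma{layer}"] = self.bn[f"gamma{layer}"]
            out[f"beta{layer}"] = self.bn[f"beta{layer}"]
        return out

    def _set_trainable(self, key: str, value: np.ndarray) -> None:
        if key in self.params:
            self.params[key] = value
        else:
            self.bn[key] = value

    def drop_features(self, keep: np.ndarray) -> None:
        """Restrict the input layer to the given feature positions.

        Equivalent to zero-masking the eliminated input columns and freezing
        their first-layer weights (a zeroed column contributes nothing to the
        forward pass and receives zero gradient); slicing keeps later steps
        cheap.  Adam moments of the kept rows are retained.
        """
        keep = np.asarray(keep)
        self.params["W0"] = self.params["W0"][keep]
        self._adam_m["W0"] = self._adam_m["W0"][keep]
        self._adam_v["W0"] = self._adam_v["W0"][keep]
        self.n_features = int(keep.size) if keep.dtype != bool else int(keep.sum())

    # -- forward / backward ----------------------------------------------------

    @staticmethod
    def _softmax(z: np.ndarray) -> np.ndarray:
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def _forward_train(self, X: np.ndarray) -> tuple[np.ndarray, list[dict]]:
        cfg = self.cfg
        keep_p = 1.0 - cfg.dropout_rate
        h = X
        caches: list[dict] = []
        for layer in range(self.n_hidden):
            z = h @ self.params[f"W{layer}"] + self.params[f"b{layer}"]
            mu = z.mean(axis=0)
            var = z.var(axis=0)
            istd = 1.0 / np.sqrt(var + cfg.bn_eps)
            xhat = (z - mu) * istd
            a_bn = self.bn[f"gamma{layer}"] * xhat + self.bn[f"beta{layer}"]
            m = cfg.bn_momentum
            self.bn[f"rmean{layer}"] = ((1 - m) * self.bn[f"rmean{layer}"] + m * mu).astype(self.dtype)
            self.bn[f"rvar{layer}"] = ((1 - m) * self.bn[f"rvar{layer}"] + m * var).astype(self.dtype)
            relu_mask = a_bn > 0
            a = a_bn * relu_mask
            if cfg.dropout_rate > 0:
                drop = (self._rng.random(a.shape) < keep_p).astype(self.dtype) / keep_p
                a = a * drop
            else:
                drop = None
            caches.append(
                {"h_in": h, "xhat": xhat, "istd": istd, "relu": relu_mask, "drop": drop}
            )
            h = a
        logits = h @ self.params[f"W{self.n_hidden}"] + self.params[f"b{self.n_hidden}"]
        caches.append({"h_in": h})
        return logits, caches

    def _forward_eval(self, X: np.ndarray, need_cache: bool = False):
        cfg = self.cfg
        h = np.asarray(X, dtype=self.dtype)
        caches: list[dict] = []
        for layer in range(self.n_hidden):
            z = h @ self.params[f"W{layer}"] + self.params[f"b{layer}"]
            istd = 1.0 / np.sqrt(self.bn[f"rvar{layer}"] + cfg.bn_eps)
            a_bn = self.bn[f"gamma{layer}"] * (z - self.bn[f"rmean{layer}"]) * istd + self.bn[f"beta{layer}"]
            relu_mask = a_bn > 0
            if need_cache:
                caches.append({"istd": istd, "relu": relu_mask})
            h = a_bn * relu_mask
        logits = h @ self.params[f"W{self.n_hidden}"] + self.params[f"b{self.n_hidden}"]
        return (logits, caches) if need_cache else logits

    def _backward(
        self, caches: list[dict], probs: np.ndarray, y: np.ndarray
    ) -> dict[str, np.ndarray]:
        B = probs.shape[0]
        grads: dict[str, np.ndarray] = {}
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        head = self.n_hidden
        grads[f"W{head}"] = caches[head]["h_in"].T @ dlogits
        grads[f"b{head}"] = dlogits.sum(axis=0)
        dh = dlogits @ self.params[f"W{head}"].T
        for layer in range(self.n_hidden - 1, -1, -1):
            c = caches[layer]
            if c["drop"] is not None:
                dh = dh * c["drop"]
            d_abn = dh * c["relu"]
            grads[f"gamma{layer}"] = (d_abn * c["xhat"]).sum(axis=0)
            grads[f"beta{layer}"] = d_abn.sum(axis=0)
            dxhat = d_abn * self.bn[f"gamma{layer}"]
            # batch-norm backward, fused form
            dz = (c["istd"] / B) * (
                B * dxhat - dxhat.sum(axis=0) - c["xhat"] * (dxhat * c["xhat"]).sum(axis=0)
            )
            grads[f"W{layer}"] = c["h_in"].T @ dz
            grads[f"b{layer}"] = dz.sum(axis=0)
            dh = dz @ self.params[f"W{layer}"].T
        return grads

    def _adam_step(self, grads: dict[str, np.ndarray]) -> None:
        cfg = self.cfg
        self._adam_t += 1
        t = self._adam_t
        b1, b2 = cfg.adam_beta1, cfg.adam_beta2
        corr1 = 1.0 - b1**t
        corr2 = 1.0 - b2**t
        for key, g in grads.items():
            m = self._adam_m[key] = b1 * self._adam_m[key] + (1 - b1) * g
            v = self._adam_v[key] = b2 * self._adam_v[key] + (1 - b2) * g * g
            update = (cfg.learning_rate * (m / corr1) / (np.sqrt(v / corr2) + cfg.adam_eps)).astype(self.dtype)
            cur = self._trainables()[key]
            self._set_trainable(key, cur - update)

    # -- public API ------------------------------------------------------------

    def fit_epochs(self, X: np.ndarray, y: np.ndarray, epochs: int) -> list[float]:
        """Run minibatch Adam for the given number of epochs; returns per-epoch losses."""
        X = np.asarray(X, dtype=self.dtype)
        y = np.asarray(y, dtype=np.int64)
        if X.shape[0] != y.shape[0]:
            raise ValueError("row count of X must match labels")
        n = X.shape[0]
        losses: list[float] = []
        for _ in range(epochs):
            order = self._rng.permutation(n)
            batch_losses = []
            for start in range(0, n, self.cfg.batch_size):
                idx = order[start : start + self.cfg.batch_size]
                logits, caches = self._forward_train(X[idx])
                probs = self._softmax(logits.astype(np.float64)).astype(self.dtype)
                loss = -float(
                    np.mean(np.log(np.maximum(probs[np.arange(len(idx)), y[idx]], 1e-12)))
                )
                if not np.isfinite(loss):
                    raise FloatingPointError(f"non-finite training loss {loss} at step {self._adam_t}")
                batch_losses.append(loss)
                grads = self._backward(caches, probs, y[idx])
                self._adam_step(grads)
            losses.append(float(np.mean(batch_losses)))
        self.loss_history.extend(losses)
        return losses

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Deterministic class probabilities (evaluation mode)."""
        return self._softmax(self._forward_eval(X).astype(np.float64))

    def input_gradients(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Per-sample gradient of the cross-entropy loss w.r.t. each input.

        Evaluation mode: batch-norm frozen at running statistics, no dropout,
        so rows are independent and the result is reproducible.
        """
        X = np.asarray(X, dtype=self.dtype)
        y = np.asarray(y, dtype=np.int64)
        logits, caches = self._forward_eval(X, need_cache=True)
        probs = self._softmax(logits.astype(np.float64)).astype(self.dtype)
        dlogits = probs.copy()
        dlogits[np.arange(X.shape[0]), y] -= 1.0  # per-sample loss, no batch averaging
        dh = dlogits @ self.params[f"W{self.n_hidden}"].T
        for layer in range(self.n_hidden - 1, -1, -1):
            c = caches[layer]
            dz = dh * c["relu"] * (self.bn[f"gamma{layer}"] * c["istd"])
            dh = dz @ self.params[f"W{layer}"].T
        if not np.all(np.isfinite(dh)):
            bad = int(np.flatnonzero(~np.isfinite(dh).all(axis=0))[0])
            raise FloatingPointError(f"non-finite input gradient for feature index {bad}")
        return dh

    def mean_loss(self, X: np.ndarray, y: np.ndarray) -> float:
        probs = self.predict_proba(X)
        return -float(np.mean(np.log(np.maximum(probs[np.arange(len(y)), y], 1e-300))))

    # -- persistence -----------------------------------------------------------

    def save(self, path) -> None:
        """Checkpoint config, weights and batch-norm state to an .npz file."""
        import json

        cfg_json = json.dumps(self.cfg.__dict__)
        arrays = {f"param_{k}": v for k, v in self.params.items()}
        arrays.update({f"bn_{k}": v for k, v in self.bn.items()})
        np.savez(
            path,
            config=np.array(cfg_json),
            n_features=np.array(self.n_features),
            n_classes=np.array(self.n_classes),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "DenseClassifier":
        import json

        data = np.load(path, allow_pickle=False)
        raw = json.loads(str(data["config"]))
        raw["hidden_sizes"] = tuple(raw["hidden_sizes"])
        cfg = NetConfig(**raw)
        model = cls(int(data["n_features"]), int(data["n_classes"]), cfg, np.random.default_rng(0))
        for k in model.params:
            model.params[k] = data[f"param_{k}"]
        for k in model.bn:
            model.bn[k] = data[f"bn_{k}"]
        return model


# -- functional wrappers matching the procedural surface ------------------------


def build_model(
    n_features: int, n_classes: int, cfg: NetConfig, seed: int | np.random.Generator | None = None
) -> DenseClassifier:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        cfg.seed if seed is None else seed
    )
    return DenseClassifier(n_features, n_classes, cfg, rng)


def train(model: DenseClassifier, X: np.ndarray, y: np.ndarray, epochs: int) -> DenseClassifier:
    model.fit_epochs(X, y, epochs)
    return model


def predict(model: DenseClassifier, X: np.ndarray) -> np.ndarray:
    return model.predict_proba(X)


def accuracy(model: DenseClassifier, X: np.ndarray, y: np.ndarray) -> float:
    pred = model.predict_proba(X).argmax(axis=1)
    return float(np.mean(pred == np.asarray(y)))
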