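"""Shared-trunk multi-head network and the transfer-learning freeze.

The trunk is four blocks of fully-connected layer -> batch normalization ->
ReLU; three linear+softmax heads share it:

* ``iic``        — two-class contrastive head,
* ``iic_oc``     — overclustering head (more classes than expected, absorbs
                   noise and latent subtypes),
* ``classifier`` — two-class supervised head trained in the transfer phase.

After contrastive prior learning the trunk and the two IIC heads are frozen
(including batch-norm running statistics); only the classifier head's linear
map remains trainable — a linear probe on the learned representation.

Everything is plain numpy with handwritten forward/backward passes and an
Adam optimizer; at the feature dimensions involved (thousands of inputs,
narrow hidden layers) dense matrix products are all that is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NetworkSpec", "EiicModel", "build_network", "forward", "freeze_trunk", "Adam"]

HEADS = ("iic", "iic_oc", "classifier")
BN_EPS = 1e-5
BN_MOMENTUM = 0.1


@dataclass
class NetworkSpec:
    """Architecture description: exactly four hidden FC+BN+ReLU blocks."""

    input_dim: int
    hidden_dims: tuple[int, ...] = (1024, 512, 256, 128)
    c_main: int = 2
    c_oc: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        self.hidden_dims = tuple(int(d) for d in self.hidden_dims)
        if len(self.hidden_dims) != 4:
            raise ValueError(
                f"the trunk has exactly four hidden layers, got {len(self.hidden_dims)}"
            )
        dims = (self.input_dim, *self.hidden_dims, self.c_main, self.c_oc)
        if any(d < 1 for d in dims):
            raise ValueError("all layer widths must be >= 1")
        if self.c_main != 2:
            raise ValueError("the main and classifier heads are two-class")


def _softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def softmax_backward(probs: np.ndarray, d_probs: np.ndarray) -> np.ndarray:
    """Gradient w.r.t. logits given gradient w.r.t. softmax output."""
    inner = np.sum(d_probs * probs, axis=1, keepdims=True)
    return probs * (d_probs - inner)


class EiicModel:
    """Parameter container with explicit forward/backward passes."""

    def __init__(self, spec: NetworkSpec):
        self.spec = spec
        self.frozen = False
        rng = np.random.default_rng(spec.seed)
        self.params: dict[str, np.ndarray] = {}
        self.bn_running: list[dict[str, np.ndarray]] = []
        dims = (spec.input_dim, *spec.hidden_dims)
        for i in range(4):
            fan_in, fan_out = dims[i], dims[i + 1]
            # He initialization for the ReLU blocks
            self.params[f"fc{i}_W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, fan_out))
            self.params[f"fc{i}_b"] = np.zeros(fan_out)
            self.params[f"bn{i}_gamma"] = np.ones(fan_out)
            self.params[f"bn{i}_beta"] = np.zeros(fan_out)
            self.bn_running.append({"mean": np.zeros(fan_out), "var": np.ones(fan_out)})
        d_last = dims[-1]
        head_widths = {"iic": spec.c_main, "iic_oc": spec.c_oc, "classifier": 2}
        for name, width in head_widths.items():
            self.params[f"head_{name}_W"] = rng.normal(
                0.0, np.sqrt(1.0 / d_last), (d_last, width)
            )
            self.params[f"head_{name}_b"] = np.zeros(width)

    # -- parameter bookkeeping ------------------------------------------------

    def trainable_names(self) -> set[str]:
        if self.frozen:
            return {"head_classifier_W", "head_classifier_b"}
        return set(self.params)

    def snapshot(self) -> dict:
        return {
            "params": {k: v.copy() for k, v in self.params.items()},
            "bn": [{k: v.copy() for k, v in s.items()} for s in self.bn_running],
        }

    def load_snapshot(self, snap: dict) -> None:
        for k, v in snap["params"].items():
            self.params[k][...] = v
        for stats, saved in zip(self.bn_running, snap["bn"]):
            for k, v in saved.items():
                stats[k][...] = v

    # -- forward / backward ---------------------------------------------------

    def _forward_trunk(self, x: np.ndarray, training: bool):
        """Returns trunk output and the per-layer cache for backward."""
        if x.ndim != 2 or x.shape[1] != self.spec.input_dim:
            raise ValueError(
                f"expected input of shape (n, {self.spec.input_dim}), got {x.shape}"
            )
        training = training and not self.frozen
        if training and x.shape[0] < 2:
            raise ValueError("batch normalization in training mode needs a batch of >= 2")
        cache = {"training": training, "layers": []}
        h = x
        for i in range(4):
            w, b = self.params[f"fc{i}_W"], self.params[f"fc{i}_b"]
            gamma, beta = self.params[f"bn{i}_gamma"], self.params[f"bn{i}_beta"]
            z = h @ w + b
            if training:
                mu = z.mean(axis=0)
                var = z.var(axis=0)
                run = self.bn_running[i]
                run["mean"] *= 1.0 - BN_MOMENTUM
                run["mean"] += BN_MOMENTUM * mu
                run["var"] *= 1.0 - BN_MOMENTUM
                run["var"] += BN_MOMENTUM * var
            else:
                mu = self.bn_running[i]["mean"]
                var = self.bn_running[i]["var"]
            inv_std = 1.0 / np.sqrt(var + BN_EPS)
            xhat = (z - mu) * inv_std
            pre_act = gamma * xhat + beta
            a = np.maximum(pre_act, 0.0)
            cache["layers"].append(
                {"x": h, "xhat": xhat, "inv_std": inv_std, "mask": pre_act > 0}
            )
            h = a
        cache["h_out"] = h
        return h, cache

    def forward_all(self, x: np.ndarray, training: bool = False, heads=HEADS):
        """Forward through the trunk and the requested heads.

        Returns ``(probs_by_head, cache)``; the cache feeds :meth:`backward`.
        """
        h, cache = self._forward_trunk(np.asarray(x, dtype=float), training)
        probs = {}
        for name in heads:
            logits = h @ self.params[f"head_{name}_W"] + self.params[f"head_{name}_b"]
            probs[name] = _softmax(logits)
        cache["head_probs"] = probs
        return probs, cache

    def forward(self, x: np.ndarray, head: str, training: bool = False) -> np.ndarray:
        """Softmax output of one head; eval mode (running BN stats) by default."""
        if head not in HEADS:
            raise ValueError(f"unknown head {head!r}; choose from {HEADS}")
        probs, _ = self.forward_all(x, training=training, heads=(head,))
        return probs[head]

    def backward(self, cache: dict, d_logits_by_head: dict[str, np.ndarray]):
        """Backprop from per-head logit gradients to parameter gradients."""
        h = cache["h_out"]
        grads: dict[str, np.ndarray] = {}
        dh = np.zeros_like(h)
        for name, d_logits in d_logits_by_head.items():
            w = self.params[f"head_{name}_W"]
            grads[f"head_{name}_W"] = h.T @ d_logits
            grads[f"head_{name}_b"] = d_logits.sum(axis=0)
            dh += d_logits @ w.T
        da = dh
        for i in reversed(range(4)):
            layer = cache["layers"][i]
            gamma = self.params[f"bn{i}_gamma"]
            d_pre = da * layer["mask"]
            grads[f"bn{i}_gamma"] = (d_pre * layer["xhat"]).sum(axis=0)
            grads[f"bn{i}_beta"] = d_pre.sum(axis=0)
            d_xhat = d_pre * gamma
            if cache["training"]:
                n = d_xhat.shape[0]
                dz = (
                    layer["inv_std"]
                    / n
                    * (
                        n * d_xhat
                        - d_xhat.sum(axis=0)
                        - layer["xhat"] * (d_xhat * layer["xhat"]).sum(axis=0)
                    )
                )
            else:
                dz = d_xhat * layer["inv_std"]
            grads[f"fc{i}_W"] = layer["x"].T @ dz
            grads[f"fc{i}_b"] = dz.sum(axis=0)
            da = dz @ self.params[f"fc{i}_W"].T
        return grads


def build_network(spec: NetworkSpec) -> EiicModel:
    """Deterministically initialize the model from ``spec.seed``."""
    return EiicModel(spec)


def forward(model: EiicModel, x: np.ndarray, head: str) -> np.ndarray:
    """Evaluation-mode forward of a feature batch through one head."""
    return model.forward(x, head, training=False)


def freeze_trunk(model: EiicModel) -> EiicModel:
    """Mark everything but the classifier head's linear map non-trainable.

    Batch-norm running statistics stop updating: forward passes through a
    frozen trunk always use the statistics accumulated during prior learning.
    """
    model.frozen = True
    return model


@dataclass
class Adam:
    """Adam optimizer over the model's parameter dict (trainable subset only)."""

    model: EiicModel
    lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    _m: dict = field(default_factory=dict, repr=False)
    _v: dict = field(default_factory=dict, repr=False)
    _t: int = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        if self.lr == 0.0:
            return
        self._t += 1
        trainable = self.model.trainable_names()
        for name, g in grads.items():
            if name not in trainable:
                continue
            if name not in self._m:
                self._m[name] = np.zeros_like(g)
                self._v[name] = np.zeros_like(g)
            m, v = self._m[name], self._v[name]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            m_hat = m / (1 - self.beta1**self._t)
            v_hat = v / (1 - self.beta2**self._t)
            self.model.params[name] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
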