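"""Permutation-invariant set classifier (atom encoder / shared MLP / pooling
/ output head), implemented directly on NumPy with hand-written backprop.

The architecture mirrors the DeepSets pattern: a per-atom encoder MLP
(input -> hidden -> latent), a shared per-atom MLP (latent -> hidden), a
symmetric pooling step over the atom axis (sum, mean, max, or additive
attention), and an MLP head (hidden -> hidden/2 -> 2 logits).  Because every
per-atom layer acts identically on each atom and pooling is symmetric, the
logits are invariant to atom order by construction.

Batches hold variable-cardinality samples packed as one flat atom matrix
plus per-sample offsets, so sets of 1..100 atoms mix freely.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

__all__ = ["ModelConfig", "DeepSetsClassifier", "attention_pool", "pack_batch"]

POOLINGS = ("mean", "max", "attention", "sum")
REGULARIZATIONS = ("None", "LayerNorm", "BatchNorm")

_BN_MOMENTUM = 0.1
_EPS = 1e-5


@dataclass
class ModelConfig:
    input_dim: int
    latent_dim: int = 64
    hidden_dim: int = 64
    pooling: str = "mean"
    dropout_rate: float = 0.0
    regularization: str = "None"
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self):
        if not (4 <= self.latent_dim <= 512 and 4 <= self.hidden_dim <= 512):
            raise ValueError("latent_dim and hidden_dim must lie in [4, 512]")
        if not (0.0 <= self.dropout_rate <= 0.5):
            raise ValueError("dropout_rate must lie in [0, 0.5]")
        if self.pooling not in POOLINGS:
            raise ValueError(f"pooling must be one of {POOLINGS}")
        if self.regularization not in REGULARIZATIONS:
            raise ValueError(f"regularization must be one of {REGULARIZATIONS}")


def pack_batch(feature_sets: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate variable-size atom sets; returns (flat atoms, offsets).

    ``offsets`` has length n_samples + 1; sample i owns rows
    ``offsets[i]:offsets[i+1]``.
    """
    counts = [len(f) for f in feature_sets]
    if any(c == 0 for c in counts):
        raise ValueError("empty atom set in batch")
    offsets = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    flat = np.concatenate([np.asarray(f, dtype=np.float64) for f in feature_sets], axis=0)
    return flat, offsets


def attention_pool(
    vectors: np.ndarray, weight: np.ndarray, bias: float
) -> tuple[np.ndarray, np.ndarray]:
    """Additive attention pooling of one set: softmax(v @ w + b)-weighted sum.

    Returns (pooled vector, attention weights); the weights sum to 1.
    """
    scores = vectors @ weight + bias
    scores = scores - scores.max()
    alpha = np.exp(scores)
    alpha /= alpha.sum()
    return alpha @ vectors, alpha


class _Norm:
    """LayerNorm / BatchNorm / identity with learnable gain and shift."""

    def __init__(self, kind: str, dim: int):
        self.kind = kind
        self.gamma = np.ones(dim)
        self.beta = np.zeros(dim)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)

    def forward(self, x, train):
        if self.kind == "None":
            self.cache = None
            return x
        if self.kind == "LayerNorm":
            mu = x.mean(axis=1, keepdims=True)
            var = x.var(axis=1, keepdims=True)
            xhat = (x - mu) / np.sqrt(var + _EPS)
        else:  # BatchNorm over the flattened atom (or batch) axis
            if train:
                mu = x.mean(axis=0)
                var = x.var(axis=0)
                self.running_mean = (1 - _BN_MOMENTUM) * self.running_mean + _BN_MOMENTUM * mu
                self.running_var = (1 - _BN_MOMENTUM) * self.running_var + _BN_MOMENTUM * var
            else:
                mu, var = self.running_mean, self.running_var
            xhat = (x - mu) / np.sqrt(var + _EPS)
        self.cache = (xhat, var)
        return self.gamma * xhat + self.beta

    def backward(self, dout, train):
        if self.kind == "None":
            return dout, {}
        xhat, var = self.cache
        dgamma = (dout * xhat).sum(axis=0)
        dbeta = dout.sum(axis=0)
        dxhat = dout * self.gamma
        inv = 1.0 / np.sqrt(var + _EPS)
        if self.kind == "LayerNorm":
            n = xhat.shape[1]
            dx = inv * (dxhat - dxhat.mean(axis=1, keepdims=True)
                        - xhat * (dxhat * xhat).mean(axis=1, keepdims=True))
        elif train:
            n = xhat.shape[0]
            dx = inv * (dxhat - dxhat.mean(axis=0) - xhat * (dxhat * xhat).mean(axis=0))
        else:
            dx = dxhat * inv
        return dx, {"gamma": dgamma, "beta": dbeta}


class DeepSetsClassifier:
    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, h, z = config.input_dim, config.hidden_dim, config.latent_dim
        h2 = max(1, h // 2)
        self.params = {
            "enc_W1": _he(rng, d, h), "enc_b1": np.zeros(h),
            "enc_W2": _he(rng, h, z), "enc_b2": np.zeros(z),
            "shr_W": _he(rng, z, h), "shr_b": np.zeros(h),
            "head_W1": _he(rng, h, h2), "head_b1": np.zeros(h2),
            "head_W2": _he(rng, h2, config.n_classes), "head_b2": np.zeros(config.n_classes),
        }
        if config.pooling == "attention":
            self.params["att_w"] = rng.normal(0.0, 1.0 / np.sqrt(h), h)
            self.params["att_b"] = np.zeros(1)
        reg = config.regularization
        self.norms = {
            "enc": _Norm(reg, h),
            "shr": _Norm(reg, h),
            "head": _Norm(reg, h2),
        }
        self._dropout_rng = np.random.default_rng(config.seed + 1)

    # -- forward ----------------------------------------------------------
    def forward(
        self,
        flat: np.ndarray,
        offsets: np.ndarray,
        train: bool = False,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Logits (n_samples, n_classes) and per-atom latents (n_atoms, z)."""
        if not np.all(np.isfinite(flat)):
            raise ValueError("non-finite values in features")
        logits, latents, _ = self._forward_full(flat, offsets, train)
        return logits, latents

    def _forward_full(self, flat, offsets, train):
        p = self.params
        cache = {"flat": flat, "offsets": offsets, "train": train}
        drop = self.config.dropout_rate if train else 0.0

        a1 = flat @ p["enc_W1"] + p["enc_b1"]
        n1 = self.norms["enc"].forward(a1, train)
        r1 = np.maximum(n1, 0.0)
        d1, m1 = self._dropout(r1, drop)
        latents = d1 @ p["enc_W2"] + p["enc_b2"]

        a3 = latents @ p["shr_W"] + p["shr_b"]
        n3 = self.norms["shr"].forward(a3, train)
        h_atom = np.maximum(n3, 0.0)

        pooled, pool_cache = self._pool(h_atom, offsets)

        a4 = pooled @ p["head_W1"] + p["head_b1"]
        n4 = self.norms["head"].forward(a4, train)
        r4 = np.maximum(n4, 0.0)
        d4, m4 = self._dropout(r4, drop)
        logits = d4 @ p["head_W2"] + p["head_b2"]

        cache.update(
            a1=a1, n1=n1, r1=r1, d1=d1, m1=m1, latents=latents, a3=a3, n3=n3,
            h_atom=h_atom, pooled=pooled, pool=pool_cache, a4=a4, n4=n4,
            r4=r4, d4=d4, m4=m4, logits=logits, drop=drop,
        )
        return logits, latents, cache

    def _dropout(self, x, rate):
        if rate <= 0.0:
            return x, None
        mask = self._dropout_rng.random(x.shape) >= rate
        return x * mask / (1.0 - rate), mask

    def _pool(self, h_atom, offsets):
        mode = self.config.pooling
        n_samp = len(offsets) - 1
        hdim = h_atom.shape[1]
        pooled = np.zeros((n_samp, hdim))
        cache = {"mode": mode}
        if mode in ("sum", "mean"):
            sums = np.add.reduceat(h_atom, offsets[:-1], axis=0)
            counts = np.diff(offsets)[:, None]
            pooled = sums if mode == "sum" else sums / counts
            cache["counts"] = counts
        elif mode == "max":
            argmaxes = np.zeros((n_samp, hdim), dtype=np.int64)
            for i in range(n_samp):
                block = h_atom[offsets[i] : offsets[i + 1]]
                idx = np.argmax(block, axis=0)
                argmaxes[i] = offsets[i] + idx
                pooled[i] = block[idx, np.arange(hdim)]
            cache["argmaxes"] = argmaxes
        else:  # attention
            w, b = self.params["att_w"], self.params["att_b"][0]
            alphas = np.zeros(len(h_atom))
            for i in range(n_samp):
                block = h_atom[offsets[i] : offsets[i + 1]]
                pooled[i], alpha = attention_pool(block, w, b)
                alphas[offsets[i] : offsets[i + 1]] = alpha
            cache["alphas"] = alphas
        return pooled, cache

    # -- loss / gradients -------------------------------------------------
    def loss_and_grads(self, flat, offsets, labels, train=True):
        logits, _, cache = self._forward_full(flat, offsets, train)
        n = logits.shape[0]
        shifted = logits - logits.max(axis=1, keepdims=True)
        expz = np.exp(shifted)
        probs = expz / expz.sum(axis=1, keepdims=True)
        loss = -float(np.mean(np.log(probs[np.arange(n), labels] + 1e-300)))
        dlogits = probs.copy()
        dlogits[np.arange(n), labels] -= 1.0
        dlogits /= n
        grads = self._backward(dlogits, cache)
        return loss, grads, probs

    def _backward(self, dlogits, cache):
        p = self.params
        g = {}
        train = cache["train"]

        g["head_W2"] = cache["d4"].T @ dlogits
        g["head_b2"] = dlogits.sum(axis=0)
        dd4 = dlogits @ p["head_W2"].T
        if cache["m4"] is not None:
            dd4 = dd4 * cache["m4"] / (1.0 - cache["drop"])
        dn4 = dd4 * (cache["n4"] > 0)
        dn4, norm_g = self.norms["head"].backward(dn4, train)
        _merge(g, "head_norm", norm_g)
        g["head_W1"] = cache["pooled"].T @ dn4
        g["head_b1"] = dn4.sum(axis=0)
        dpooled = dn4 @ p["head_W1"].T

        dh_atom = self._pool_backward(dpooled, cache)

        dn3 = dh_atom * (cache["n3"] > 0)
        dn3, norm_g = self.norms["shr"].backward(dn3, train)
        _merge(g, "shr_norm", norm_g)
        g["shr_W"] = cache["latents"].T @ dn3
        g["shr_b"] = dn3.sum(axis=0)
        dlat = dn3 @ p["shr_W"].T

        g["enc_W2"] = cache["d1"].T @ dlat
        g["enc_b2"] = dlat.sum(axis=0)
        dd1 = dlat @ p["enc_W2"].T
        if cache["m1"] is not None:
            dd1 = dd1 * cache["m1"] / (1.0 - cache["drop"])
        dn1 = dd1 * (cache["n1"] > 0)
        dn1, norm_g = self.norms["enc"].backward(dn1, train)
        _merge(g, "enc_norm", norm_g)
        g["enc_W1"] = cache["flat"].T @ dn1
        g["enc_b1"] = dn1.sum(axis=0)
        return g

    def _pool_backward(self, dpooled, cache):
        offsets = cache["offsets"]
        h_atom = cache["h_atom"]
        pc = cache["pool"]
        mode = pc["mode"]
        dh = np.zeros_like(h_atom)
        n_samp = len(offsets) - 1
        if mode in ("sum", "mean"):
            scale = dpooled if mode == "sum" else dpooled / pc["counts"]
            for i in range(n_samp):
                dh[offsets[i] : offsets[i + 1]] = scale[i]
        elif mode == "max":
            hdim = h_atom.shape[1]
            for i in range(n_samp):
                dh[pc["argmaxes"][i], np.arange(hdim)] += dpooled[i]
        else:
            w = self.params["att_w"]
            alphas = pc["alphas"]
            dw = np.zeros_like(w)
            db = 0.0
            for i in range(n_samp):
                sl = slice(offsets[i], offsets[i + 1])
                block = h_atom[sl]
                alpha = alphas[sl]
                dp = dpooled[i]
                dh[sl] += alpha[:, None] * dp
                dalpha = block @ dp
                ds = alpha * (dalpha - float(alpha @ dalpha))
                dw += ds @ block
                db += ds.sum()
                dh[sl] += np.outer(ds, w)
            self._att_grads = {"att_w": dw, "att_b": np.array([db])}
        return dh

    # -- parameter access -------------------------------------------------
    def trainable(self):
        """Flat dict of all trainable arrays (params + norm gains/shifts)."""
        out = dict(self.params)
        for name, norm in self.norms.items():
            if norm.kind != "None":
                out[f"{name}_norm_gamma"] = norm.gamma
                out[f"{name}_norm_beta"] = norm.beta
        return out

    def gradients_from(self, grads):
        """Match ``trainable`` layout from a raw gradient dict."""
        out = {k: v for k, v in grads.items() if not k.endswith("_norm")}
        for name in ("enc", "shr", "head"):
            key = f"{name}_norm"
            if key in grads and grads[key]:
                out[f"{key}_gamma"] = grads[key]["gamma"]
                out[f"{key}_beta"] = grads[key]["beta"]
        if self.config.pooling == "attention" and hasattr(self, "_att_grads"):
            out.update(self._att_grads)
        return out

    def get_state(self):
        state = {k: v.copy() for k, v in self.params.items()}
        for name, norm in self.norms.items():
            state[f"_norm_{name}_gamma"] = norm.gamma.copy()
            state[f"_norm_{name}_beta"] = norm.beta.copy()
            state[f"_norm_{name}_rmean"] = norm.running_mean.copy()
            state[f"_norm_{name}_rvar"] = norm.running_var.copy()
        return state

    def set_state(self, state):
        for k in self.params:
            self.params[k] = state[k].copy()
        for name, norm in self.norms.items():
            norm.gamma = state[f"_norm_{name}_gamma"].copy()
            norm.beta = state[f"_norm_{name}_beta"].copy()
            norm.running_mean = state[f"_norm_{name}_rmean"].copy()
            norm.running_var = state[f"_norm_{name}_rvar"].copy()

    # -- persistence ------------------------------------------------------
    def save(self, path: str) -> None:
        import json

        state = self.get_state()
        np.savez(path, _config=np.frombuffer(json.dumps(asdict(self.config)).encode(), dtype=np.uint8), **state)

    @classmethod
    def load(cls, path: str) -> "DeepSetsClassifier":
        import json

        data = np.load(path if str(path).endswith(".npz") else str(path) + ".npz")
        config = ModelConfig(**json.loads(bytes(data["_config"]).decode()))
        model = cls(config)
        model.set_state({k: data[k] for k in data.files if k != "_config"})
        return model


def _he(rng, fan_in, fan_out):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, fan_out))


def _merge(grads, key, norm_grads):
    grads[key] = norm_grads
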