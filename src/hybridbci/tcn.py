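"""A compact 1-D temporal convolutional network (TCN) with center loss.

Implemented directly on numpy (forward, backward, Adam) so the classifier
has no heavyweight runtime dependency.  Architecture, matching the shape
contract of the PLR pipeline:

* input ``(B, F, T)`` wavelet-power tensor, default ``F=122, T=139``;
* a depthwise smoothing convolution along the frequency axis (kernel 3);
* three TCN blocks (default filters 512, 512, 64).  Each block stacks four
  causal convolutions (kernel 2, dilations 1, 2, 4, 8) with ReLU, plus a
  1x1-projected residual connection;
* max-pool over time (size 2, stride 2): ``T=139 -> 69``, flatten to
  ``64 * 69 = 4416`` features;
* dropout 0.5, dense layer to 4 classes, softmax.

Loss = sparse categorical cross-entropy + ``0.7 x`` center loss, where the
center loss pulls the 4416-d flattened features toward online-updated
per-class centroids, sharpening class clusters before the linear readout.
Training is fully deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["TCNSpec", "TCNClassifier", "train_tcn", "classify_plr"]


@dataclass(frozen=True)
class TCNSpec:
    """Hyper-parameters of the PLR classifier network."""

    input_shape: tuple[int, int] = (122, 139)
    filters: tuple[int, int, int] = (512, 512, 64)
    kernel: int = 2
    dilations: tuple[int, ...] = (1, 2, 4, 8)
    pool: int = 2
    dropout: float = 0.5
    n_classes: int = 4
    learning_rate: float = 1e-3
    center_weight: float = 0.7
    center_alpha: float = 0.5
    batch_size: int = 32

    @property
    def pooled_t(self) -> int:
        return self.input_shape[1] // self.pool

    @property
    def flat_dim(self) -> int:
        return self.filters[-1] * self.pooled_t


def _he(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float) -> None:
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps)


def _causal_conv(x: np.ndarray, w0: np.ndarray, w1: np.ndarray,
                 b: np.ndarray, d: int) -> np.ndarray:
    """y[:, :, t] = w0 @ x[:, :, t-d] + w1 @ x[:, :, t] + b  (zero past)."""
    y = np.einsum("oi,bit->bot", w1, x, optimize=True)
    y[:, :, d:] += np.einsum("oi,bit->bot", w0, x[:, :, :-d], optimize=True)
    return y + b[None, :, None]


def _causal_conv_back(x: np.ndarray, dy: np.ndarray, w0: np.ndarray,
                      w1: np.ndarray, d: int):
    dw1 = np.einsum("bot,bit->oi", dy, x, optimize=True)
    dw0 = np.einsum("bot,bit->oi", dy[:, :, d:], x[:, :, :-d], optimize=True)
    db = dy.sum(axis=(0, 2))
    dx = np.einsum("oi,bot->bit", w1, dy, optimize=True)
    dx[:, :, :-d] += np.einsum("oi,bot->bit", w0, dy[:, :, d:], optimize=True)
    return dx, dw0, dw1, db


class TCNClassifier:
    """Trainable TCN; see module docstring for the architecture."""

    def __init__(self, spec: TCNSpec = TCNSpec(), seed: int = 0) -> None:
        self.spec = spec
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        self.centers = np.zeros((spec.n_classes, spec.flat_dim), dtype=np.float32)
        self.trained = False
        self.history: list[float] = []
        self._init_params()
        self.opt = _Adam(self.params, spec.learning_rate)

    # -- parameters ---------------------------------------------------------

    def _init_params(self) -> None:
        sp, rng = self.spec, self.rng
        f_dim, _ = sp.input_shape
        p = self.params
        p["dw_w"] = _he(rng, (3, f_dim), 3)
        p["dw_w"][1, :] += 1.0  # start near identity
        p["dw_b"] = np.zeros(f_dim, dtype=np.float32)
        in_ch = f_dim
        for bi, out_ch in enumerate(sp.filters):
            ch = in_ch
            for li, _d in enumerate(sp.dilations):
                oc = out_ch
                p[f"b{bi}c{li}_w0"] = _he(rng, (oc, ch), ch * sp.kernel)
                p[f"b{bi}c{li}_w1"] = _he(rng, (oc, ch), ch * sp.kernel)
                p[f"b{bi}c{li}_b"] = np.zeros(oc, dtype=np.float32)
                ch = oc
            p[f"b{bi}_proj"] = _he(rng, (out_ch, in_ch), in_ch)
            in_ch = out_ch
        p["fc_w"] = _he(rng, (sp.n_classes, sp.flat_dim), sp.flat_dim)
        p["fc_b"] = np.zeros(sp.n_classes, dtype=np.float32)

    # -- forward / backward -------------------------------------------------

    def _forward(self, x: np.ndarray, train: bool,
                 drop_rng: np.random.Generator | None = None):
        sp, p = self.spec, self.params
        cache: dict = {"x": x}
        # depthwise frequency smoothing
        xpad = np.pad(x, ((0, 0), (1, 1), (0, 0)))
        h = (p["dw_w"][0][None, :, None] * xpad[:, :-2]
             + p["dw_w"][1][None, :, None] * xpad[:, 1:-1]
             + p["dw_w"][2][None, :, None] * xpad[:, 2:]
             + p["dw_b"][None, :, None])
        cache["dw_out"] = h
        for bi in range(len(sp.filters)):
            block_in = h
            cache[f"b{bi}_in"] = block_in
            for li, d in enumerate(sp.dilations):
                pre = _causal_conv(h, p[f"b{bi}c{li}_w0"], p[f"b{bi}c{li}_w1"],
                                   p[f"b{bi}c{li}_b"], d)
                cache[f"b{bi}c{li}_in"] = h
                cache[f"b{bi}c{li}_pre"] = pre
                h = np.maximum(pre, 0.0)
            res = np.einsum("oi,bit->bot", p[f"b{bi}_proj"], block_in,
                            optimize=True)
            cache[f"b{bi}_sum"] = h + res
            h = np.maximum(cache[f"b{bi}_sum"], 0.0)
        # max-pool over time (size = stride = sp.pool), truncating the tail
        tp = sp.pooled_t
        hp = h[:, :, : tp * sp.pool].reshape(h.shape[0], h.shape[1], tp, sp.pool)
        am = hp.argmax(axis=3)
        pooled = np.take_along_axis(hp, am[..., None], axis=3)[..., 0]
        cache["pool_arg"] = am
        cache["pre_pool_shape"] = h.shape
        feats = pooled.reshape(h.shape[0], -1)
        cache["feats"] = feats
        if train and sp.dropout > 0:
            mask = (drop_rng.random(feats.shape) >= sp.dropout).astype(
                np.float32) / (1.0 - sp.dropout)
        else:
            mask = np.ones_like(feats, dtype=np.float32)
        cache["drop_mask"] = mask
        dropped = feats * mask
        cache["dropped"] = dropped
        logits = dropped @ p["fc_w"].T + p["fc_b"]
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=1, keepdims=True)
        return probs, cache

    def _backward(self, probs: np.ndarray, y: np.ndarray, cache: dict
                  ) -> dict[str, np.ndarray]:
        sp, p = self.spec, self.params
        bsz = y.size
        grads: dict[str, np.ndarray] = {}
        dlogits = probs.copy()
        dlogits[np.arange(bsz), y] -= 1.0
        dlogits /= bsz
        grads["fc_w"] = dlogits.T @ cache["dropped"]
        grads["fc_b"] = dlogits.sum(axis=0)
        dfeat = dlogits @ p["fc_w"] * cache["drop_mask"]
        # center loss gradient on the pre-dropout features
        if sp.center_weight > 0:
            dfeat = dfeat + sp.center_weight * (
                cache["feats"] - self.centers[y]) / bsz
        b, c, t = cache["pre_pool_shape"]
        tp = sp.pooled_t
        dpool = dfeat.reshape(b, c, tp)
        dh = np.zeros((b, c, tp, sp.pool), dtype=dpool.dtype)
        np.put_along_axis(dh, cache["pool_arg"][..., None],
                          dpool[..., None], axis=3)
        dhf = np.zeros((b, c, t), dtype=dpool.dtype)
        dhf[:, :, : tp * sp.pool] = dh.reshape(b, c, tp * sp.pool)
        dh = dhf
        for bi in reversed(range(len(sp.filters))):
            dsum = dh * (cache[f"b{bi}_sum"] > 0)
            block_in = cache[f"b{bi}_in"]
            grads[f"b{bi}_proj"] = np.einsum("bot,bit->oi", dsum, block_in,
                                             optimize=True)
            dblock_in = np.einsum("oi,bot->bit", p[f"b{bi}_proj"], dsum,
                                  optimize=True)
            dcur = dsum
            for li in reversed(range(len(sp.dilations))):
                d = sp.dilations[li]
                dpre = dcur * (cache[f"b{bi}c{li}_pre"] > 0)
                xin = cache[f"b{bi}c{li}_in"]
                dx, dw0, dw1, db = _causal_conv_back(
                    xin, dpre, p[f"b{bi}c{li}_w0"], p[f"b{bi}c{li}_w1"], d)
                grads[f"b{bi}c{li}_w0"] = dw0
                grads[f"b{bi}c{li}_w1"] = dw1
                grads[f"b{bi}c{li}_b"] = db
                dcur = dx
            dh = dcur + dblock_in
        # depthwise layer
        x = cache["x"]
        xpad = np.pad(x, ((0, 0), (1, 1), (0, 0)))
        grads["dw_w"] = np.stack([
            np.einsum("bft,bft->f", dh, xpad[:, :-2], optimize=True),
            np.einsum("bft,bft->f", dh, xpad[:, 1:-1], optimize=True),
            np.einsum("bft,bft->f", dh, xpad[:, 2:], optimize=True),
        ])
        grads["dw_b"] = dh.sum(axis=(0, 2))
        return grads

    # -- losses -------------------------------------------------------------

    def _loss_terms(self, probs: np.ndarray, feats: np.ndarray,
                    y: np.ndarray) -> tuple[float, float]:
        bsz = y.size
        ce = float(-np.log(np.clip(probs[np.arange(bsz), y], 1e-12, None)).mean())
        center = float(0.5 * np.sum((feats - self.centers[y]) ** 2) / bsz)
        return ce, center

    def _update_centers(self, feats: np.ndarray, y: np.ndarray) -> None:
        for j in np.unique(y):
            fj = feats[y == j]
            delta = (self.centers[j] - fj).sum(axis=0) / (1.0 + fj.shape[0])
            self.centers[j] -= self.spec.center_alpha * delta

    # -- public API ---------------------------------------------------------

    def fit(self, tensors: np.ndarray, labels: np.ndarray,
            epochs: int = 100, verbose: bool = False) -> "TCNClassifier":
        """Train on ``tensors`` (N, F, T) with integer ``labels`` in [0, K)."""
        sp = self.spec
        x = np.asarray(tensors, dtype=np.float32)
        y = np.asarray(labels, dtype=int)
        if x.ndim != 3 or x.shape[1:] != sp.input_shape:
            raise ValueError(
                f"expected tensors of shape (N, {sp.input_shape[0]}, "
                f"{sp.input_shape[1]}), got {x.shape}")
        if np.unique(y).size < 2:
            raise ValueError("need at least 2 classes to train")
        # per-feature log-scaling keeps the wavelet powers in a trainable range
        x = np.log1p(x)
        self._norm_mean = x.mean(axis=(0, 2), keepdims=True)
        self._norm_sd = x.std(axis=(0, 2), keepdims=True) + 1e-6
        x = (x - self._norm_mean) / self._norm_sd
        shuffle_rng = np.random.default_rng(self.seed + 1)
        drop_rng = np.random.default_rng(self.seed + 2)
        n = x.shape[0]
        for ep in range(epochs):
            order = shuffle_rng.permutation(n)
            ep_loss = 0.0
            for start in range(0, n, sp.batch_size):
                idx = order[start:start + sp.batch_size]
                xb, yb = x[idx], y[idx]
                probs, cache = self._forward(xb, train=True, drop_rng=drop_rng)
                ce, center = self._loss_terms(probs, cache["feats"], yb)
                ep_loss += (ce + sp.center_weight * center) * idx.size
                grads = self._backward(probs, yb, cache)
                self.opt.step(self.params, grads)
                self._update_centers(cache["feats"], yb)
            self.history.append(ep_loss / n)
            if verbose:
                print(f"epoch {ep + 1}/{epochs}  loss {self.history[-1]:.4f}")
        self.trained = True
        return self

    def predict_proba(self, tensors: np.ndarray) -> np.ndarray:
        if not self.trained:
            raise RuntimeError("model has not been trained")
        x = np.asarray(tensors, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        x = np.log1p(x)
        x = (x - self._norm_mean) / self._norm_sd
        probs, _ = self._forward(x, train=False)
        return probs

    def predict(self, tensors: np.ndarray) -> np.ndarray:
        return self.predict_proba(tensors).argmax(axis=1)

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        meta = {"spec": self.spec.__dict__, "seed": self.seed}
        arrays = dict(self.params)
        arrays["_centers"] = self.centers
        arrays["_norm_mean"] = self._norm_mean
        arrays["_norm_sd"] = self._norm_sd
        np.savez(path, _meta=json.dumps(meta, default=list), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TCNClassifier":
        data = np.load(Path(path).with_suffix(".npz") if not str(path).endswith(".npz") else path,
                       allow_pickle=False)
        meta = json.loads(str(data["_meta"]))
        spec_d = meta["spec"]
        for k in ("input_shape", "filters", "dilations"):
            spec_d[k] = tuple(spec_d[k])
        model = cls(TCNSpec(**spec_d), seed=meta["seed"])
        for k in model.params:
            model.params[k] = data[k]
        model.centers = data["_centers"]
        model._norm_mean = data["_norm_mean"]
        model._norm_sd = data["_norm_sd"]
        model.trained = True
        return model


def train_tcn(tensors: np.ndarray, labels: np.ndarray,
              spec: TCNSpec = TCNSpec(), epochs: int = 100,
              seed: int = 0) -> TCNClassifier:
    """Convenience wrapper: build and fit a :class:`TCNClassifier`."""
    return TCNClassifier(spec, seed=seed).fit(tensors, labels, epochs=epochs)


def classify_plr(model: TCNClassifier, tensor: np.ndarray
                 ) -> tuple[int, np.ndarray]:
    """Predicted LED (1-4) and class probabilities for one tensor."""
    probs = model.predict_proba(tensor)[0]
    return int(probs.argmax()) + 1, probs
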