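"""A compact convolutional network on 32x32 EEG windows, in plain numpy.

Each classifier column of the voting ensemble is an instance of this
network: a stack of convolution stages with ReLU, 2x2 average pooling
between stages, average pooling over the time axis (the coarse channel
axis is kept — scalp position carries meaning), optional dropout, and two
independent 2-way softmax heads (valence low/high, arousal low/high).
Kernels may be rectangular — wider along the time axis than the channel
axis — so the earliest filters can resolve oscillation frequency, the
feature the synthetic corpus (and spectral EEG analysis generally) encodes
emotion in.  Training is mini-batch Adam on the summed cross-entropy of
the two heads with early stopping on validation loss.

The implementation is deliberately small and fully deterministic given a
seed: convolutions are im2col matrix products, and all state lives in a
flat dict of float32 arrays so checkpoints are plain ``.npz`` files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = ["SmallConvNet", "Adam", "fit", "FitResult"]


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N, C, H, W), zero-padded to "same" -> (N*H*W, C*kh*kw) patch matrix."""
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    n, c, h, w = x.shape
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * kh * kw)
    return np.ascontiguousarray(cols)


def _col2im(dcols: np.ndarray, shape: tuple[int, int, int, int], kh: int, kw: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter patch gradients back onto the image."""
    n, c, h, w = shape
    ph, pw = kh // 2, kw // 2
    dxp = np.zeros((n, c, h + 2 * ph, w + 2 * pw), dtype=dcols.dtype)
    d6 = dcols.reshape(n, h, w, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + h, j:j + w] += d6[:, :, :, :, i, j]
    return dxp[:, :, ph:ph + h, pw:pw + w]


def _avgpool2(x: np.ndarray) -> np.ndarray:
    n, c, h, w = x.shape
    return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def _avgpool2_back(d: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(d, 2, axis=2), 2, axis=3) * np.float32(0.25)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _normalize_kernels(kernels, n_stages: int) -> tuple[tuple[int, int], ...]:
    if kernels is None:
        return tuple((3, 3) for _ in range(n_stages))
    out = []
    for k in kernels:
        kh, kw = (k, k) if np.isscalar(k) else tuple(k)
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError("kernel sides must be odd for 'same' padding")
        out.append((int(kh), int(kw)))
    if len(out) != n_stages:
        raise ValueError("one kernel per conv stage required")
    return tuple(out)


class SmallConvNet:
    """Conv stages with inter-stage 2x2 average pooling and two binary heads.

    ``conv_channels`` gives the feature-map count of each stage; pooling
    follows every stage except the last, so ``len(conv_channels)`` also
    fixes the spatial reduction.  ``kernels`` optionally gives one
    (height, width) kernel per stage (default 3x3 everywhere).
    """

    INPUT_SIZE = 32

    def __init__(self, conv_channels: Sequence[int] = (8, 16, 16, 16),
                 kernels: Optional[Sequence] = ((3, 7), (3, 5), (3, 3), (3, 3)),
                 dropout: float = 0.0, seed: int = 0):
        if len(conv_channels) < 1 or any(c < 1 for c in conv_channels):
            raise ValueError("conv_channels must be positive counts")
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        self.conv_channels = tuple(int(c) for c in conv_channels)
        self.kernels = _normalize_kernels(kernels, len(self.conv_channels))
        self.dropout = float(dropout)
        self.seed = int(seed)
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        self.params: dict[str, np.ndarray] = {}
        c_in = 1
        for s, (c_out, (kh, kw)) in enumerate(zip(self.conv_channels, self.kernels), 1):
            fan_in = c_in * kh * kw
            self.params[f"W{s}"] = _he_init(rng, (fan_in, c_out), fan_in)
            self.params[f"b{s}"] = np.zeros(c_out, dtype=np.float32)
            c_in = c_out
        # feature dim after time-pooling: channels x remaining channel positions
        feat_dim = c_in * (self.INPUT_SIZE // 2 ** (self.n_stages - 1))
        for head in ("v", "a"):
            self.params[f"W{head}"] = _he_init(rng, (feat_dim, 2), feat_dim)
            self.params[f"b{head}"] = np.zeros(2, dtype=np.float32)

    @property
    def n_stages(self) -> int:
        return len(self.conv_channels)

    # -- forward ----------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False,
                drop_rng: Optional[np.random.Generator] = None):
        """Return (valence logits, arousal logits), shape (N, 2) each.

        With ``train=True`` also returns the backprop cache, and applies
        dropout (if configured) to the pooled features using ``drop_rng``.
        """
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, None, :, :]
        p = self.params
        cache: dict = {"cols": [], "z": [], "shapes": []}
        h = x
        for s, (kh, kw) in enumerate(self.kernels, 1):
            cols = _im2col(h, kh, kw)
            n, _, hh, ww = h.shape
            z = (cols @ p[f"W{s}"] + p[f"b{s}"]).reshape(n, hh, ww, -1).transpose(0, 3, 1, 2)
            if train:
                cache["cols"].append(cols)
                cache["shapes"].append(h.shape)
                cache["z"].append(z)
            h = np.maximum(z, 0)
            if s < self.n_stages:
                h = _avgpool2(h)
        # pool over time only: EEG channel position carries meaning (which
        # scalp region a feature came from), so the coarse channel axis is
        # kept and flattened instead of averaged away
        feat = h.mean(axis=3).reshape(h.shape[0], -1)  # (N, C_last * H_last)

        mask = None
        if train and self.dropout > 0.0:
            if drop_rng is None:
                raise ValueError("dropout during training needs drop_rng")
            mask = (drop_rng.uniform(size=feat.shape) >= self.dropout).astype(
                np.float32
            ) / np.float32(1.0 - self.dropout)
            feat = feat * mask

        logit_v = feat @ p["Wv"] + p["bv"]
        logit_a = feat @ p["Wa"] + p["ba"]
        if not train:
            return logit_v, logit_a
        cache.update(last_shape=h.shape, feat=feat, mask=mask)
        return (logit_v, logit_a), cache

    # -- loss / backward --------------------------------------------------

    def loss_and_grads(self, x: np.ndarray, y_val: np.ndarray, y_aro: np.ndarray,
                       drop_rng: Optional[np.random.Generator] = None):
        """Summed two-head cross-entropy and parameter gradients for a batch."""
        (lv, la), cache = self.forward(x, train=True, drop_rng=drop_rng)
        n = x.shape[0]
        pv, pa = _softmax(lv), _softmax(la)
        eps = 1e-12
        loss = float(
            -np.log(pv[np.arange(n), y_val] + eps).mean()
            - np.log(pa[np.arange(n), y_aro] + eps).mean()
        )
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite training loss; aborting")

        dv = pv.copy()
        dv[np.arange(n), y_val] -= 1.0
        dv /= n
        da = pa.copy()
        da[np.arange(n), y_aro] -= 1.0
        da /= n

        p = self.params
        feat = cache["feat"]
        grads = {
            "Wv": feat.T @ dv, "bv": dv.sum(0),
            "Wa": feat.T @ da, "ba": da.sum(0),
        }
        dfeat = dv @ p["Wv"].T + da @ p["Wa"].T
        if cache["mask"] is not None:
            dfeat = dfeat * cache["mask"]

        n_, c_last, hh, ww = cache["last_shape"]
        dh = np.broadcast_to(
            (dfeat.reshape(n_, c_last, hh) / ww)[:, :, :, None], (n_, c_last, hh, ww)
        ).astype(np.float32)
        for s in range(self.n_stages, 0, -1):
            if s < self.n_stages:
                dh = _avgpool2_back(dh)
            z = cache["z"][s - 1]
            dz = dh * (z > 0)
            kh, kw = self.kernels[s - 1]
            nb, f, zh, zw = dz.shape
            dflat = dz.transpose(0, 2, 3, 1).reshape(nb * zh * zw, f)
            grads[f"W{s}"] = cache["cols"][s - 1].T @ dflat
            grads[f"b{s}"] = dflat.sum(0)
            if s > 1:
                dcols = dflat @ p[f"W{s}"].T
                dh = _col2im(dcols, cache["shapes"][s - 1], kh, kw)
        return loss, grads

    # -- inference --------------------------------------------------------

    def predict_proba(self, x: np.ndarray, batch: int = 2048):
        """Per-head class probabilities (N, 2), computed in batches."""
        outs_v, outs_a = [], []
        for i in range(0, x.shape[0], batch):
            lv, la = self.forward(x[i:i + batch])
            outs_v.append(_softmax(lv))
            outs_a.append(_softmax(la))
        return np.concatenate(outs_v), np.concatenate(outs_a)

    def predict_classes(self, x: np.ndarray, batch: int = 2048):
        pv, pa = self.predict_proba(x, batch=batch)
        return pv.argmax(1), pa.argmax(1)

    # -- state ------------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=np.float32)


class Adam:
    """Standard Adam with bias correction, float32 state."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for k, g in grads.items():
            g = g.astype(np.float32)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            self.params[k] -= lr_t * self.m[k] / (np.sqrt(self.v[k]) + self.eps)


@dataclass
class FitResult:
    epochs_run: int
    best_epoch: int
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)


def _eval_loss(net: SmallConvNet, x, y_val, y_aro, batch: int = 2048) -> float:
    pv, pa = net.predict_proba(x, batch=batch)
    n = x.shape[0]
    eps = 1e-12
    return float(
        -np.log(pv[np.arange(n), y_val] + eps).mean()
        - np.log(pa[np.arange(n), y_aro] + eps).mean()
    )


def fit(net: SmallConvNet, x_train, y_train_val, y_train_aro,
        x_val, y_val_val, y_val_aro, *,
        lr: float = 1e-3, batch_size: int = 256, max_epochs: int = 30,
        patience: int = 3, seed: int = 0, verbose: bool = False) -> FitResult:
    """Mini-batch Adam with early stopping on validation loss.

    The best-validation parameters are restored before returning, so the
    network never ends on an overfit epoch.  All shuffling and dropout
    randomness derives from ``seed``.
    """
    if x_train.shape[0] == 0 or x_val.shape[0] == 0:
        raise ValueError("training and validation sets must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xF17)))
    opt = Adam(net.params, lr=lr)
    hist = FitResult(epochs_run=0, best_epoch=0)
    best_loss = np.inf
    best_state = net.state_dict()
    bad = 0
    n = x_train.shape[0]
    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, batch_size):
            idx = order[i:i + batch_size]
            loss, grads = net.loss_and_grads(
                x_train[idx], y_train_val[idx], y_train_aro[idx], drop_rng=rng
            )
            opt.step(grads)
            losses.append(loss)
        vloss = _eval_loss(net, x_val, y_val_val, y_val_aro)
        hist.train_loss.append(float(np.mean(losses)))
        hist.val_loss.append(vloss)
        hist.epochs_run = epoch
        if verbose:
            print(f"epoch {epoch:3d}  train {hist.train_loss[-1]:.4f}  val {vloss:.4f}")
        if vloss < best_loss - 1e-5:
            best_loss = vloss
            best_state = net.state_dict()
            hist.best_epoch = epoch
            bad = 0
        else:
            bad += 1
            if bad > patience:
                break
    net.load_state_dict(best_state)
    return hist
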