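"""A miniature 3D U-Net in pure numpy with hand-written gradients.

One encoder level, a bottleneck, one decoder level with a skip
connection, and three output heads: sigmoid mask and border
probabilities plus a linear distance-transform regression (clipped to
[0, 32] at prediction time).  It is trained with the composite
Dice + log-MSE loss and plain SGD.

This is a testing vehicle for the label-prediction contract — small
enough to train on a phantom in seconds on one CPU — not a production
segmentation network; the oracle predictor is the canonical path.
"""

from __future__ import annotations

import numpy as np

from .errors import TrainingError
from .labels import DT_SATURATION, LabelTriplet, LossWeights
from .volume import Volume

__all__ = ["TinyUnet"]


def _pad_same(x: np.ndarray, r: int) -> np.ndarray:
    return np.pad(x, ((0, 0), (r, r), (r, r), (r, r)), mode="edge")


def _conv3(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padded 3D convolution; x (C,Z,Y,X), w (O,C,k,k,k), b (O,)."""
    k = w.shape[2]
    r = k // 2
    xp = _pad_same(x, r)
    out = np.zeros((w.shape[0],) + x.shape[1:], dtype=x.dtype)
    nz, ny, nx = x.shape[1:]
    for dz in range(k):
        for dy in range(k):
            for dx in range(k):
                patch = xp[:, dz:dz + nz, dy:dy + ny, dx:dx + nx]
                out += np.einsum("oc,czyx->ozyx", w[:, :, dz, dy, dx], patch)
    return out + b[:, None, None, None]


def _conv3_grads(x, w, dout):
    """Gradients of _conv3 w.r.t. w, b and x."""
    k = w.shape[2]
    r = k // 2
    xp = _pad_same(x, r)
    nz, ny, nx = x.shape[1:]
    dw = np.zeros_like(w)
    for dz in range(k):
        for dy in range(k):
            for dx in range(k):
                patch = xp[:, dz:dz + nz, dy:dy + ny, dx:dx + nx]
                dw[:, :, dz, dy, dx] = np.einsum("ozyx,czyx->oc", dout, patch)
    db = dout.sum(axis=(1, 2, 3))
    # input gradient: correlate dout with flipped kernels, zero padding
    dxp = np.zeros((x.shape[0], nz + 2 * r, ny + 2 * r, nx + 2 * r), dtype=x.dtype)
    for dz in range(k):
        for dy in range(k):
            for dx in range(k):
                dxp[:, dz:dz + nz, dy:dy + ny, dx:dx + nx] += np.einsum(
                    "oc,ozyx->czyx", w[:, :, dz, dy, dx], dout)
    # fold edge padding back (edge mode reuses border cells), one axis at a time
    t = dxp
    if r:
        t[:, r] += t[:, :r].sum(axis=1)
        t[:, r + nz - 1] += t[:, r + nz:].sum(axis=1)
        t = t[:, r:r + nz]
        t[:, :, r] += t[:, :, :r].sum(axis=2)
        t[:, :, r + ny - 1] += t[:, :, r + ny:].sum(axis=2)
        t = t[:, :, r:r + ny]
        t[:, :, :, r] += t[:, :, :, :r].sum(axis=3)
        t[:, :, :, r + nx - 1] += t[:, :, :, r + nx:].sum(axis=3)
        t = t[:, :, :, r:r + nx]
    return dw, db, t.copy()


def _pool2(x):
    c, z, y, xx = x.shape
    return x[:, :z - z % 2, :y - y % 2, :xx - xx % 2].reshape(
        c, z // 2, 2, y // 2, 2, xx // 2, 2).mean(axis=(2, 4, 6))


def _unpool2(x, shape):
    up = np.repeat(np.repeat(np.repeat(x, 2, axis=1), 2, axis=2), 2, axis=3)
    out = np.zeros((x.shape[0],) + shape, dtype=x.dtype)
    z, y, xx = (min(a, b) for a, b in zip(up.shape[1:], shape))
    out[:, :z, :y, :xx] = up[:, :z, :y, :xx]
    return out


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class TinyUnet:
    """3-head miniature U-Net; see the module docstring."""

    def __init__(self, base_filters: int = 4, seed: int = 0):
        rng = np.random.default_rng(seed)
        c = base_filters
        self.c = c

        def w(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        k3 = 27
        self.params = {
            "w_enc": w((c, 1, 3, 3, 3), k3), "b_enc": np.zeros(c),
            "w_bot": w((2 * c, c, 3, 3, 3), c * k3), "b_bot": np.zeros(2 * c),
            "w_dec": w((c, 3 * c, 3, 3, 3), 3 * c * k3), "b_dec": np.zeros(c),
            "w_mask": w((1, c, 1, 1, 1), c), "b_mask": np.zeros(1),
            "w_bord": w((1, c, 1, 1, 1), c), "b_bord": np.zeros(1),
            "w_dt": w((1, c, 1, 1, 1), c), "b_dt": np.zeros(1),
        }

    # -- forward -------------------------------------------------------

    def _forward(self, img: np.ndarray):
        p = self.params
        x0 = img[None].astype(np.float64)
        a_enc = _conv3(x0, p["w_enc"], p["b_enc"])
        h_enc = np.maximum(a_enc, 0.0)
        pooled = _pool2(h_enc)
        a_bot = _conv3(pooled, p["w_bot"], p["b_bot"])
        h_bot = np.maximum(a_bot, 0.0)
        up = _unpool2(h_bot, h_enc.shape[1:])
        cat = np.concatenate([h_enc, up], axis=0)
        a_dec = _conv3(cat, p["w_dec"], p["b_dec"])
        h_dec = np.maximum(a_dec, 0.0)
        z_mask = _conv3(h_dec, p["w_mask"], p["b_mask"])[0]
        z_bord = _conv3(h_dec, p["w_bord"], p["b_bord"])[0]
        z_dt = _conv3(h_dec, p["w_dt"], p["b_dt"])[0]
        cache = dict(x0=x0, a_enc=a_enc, h_enc=h_enc, pooled=pooled, a_bot=a_bot,
                     h_bot=h_bot, up=up, cat=cat, a_dec=a_dec, h_dec=h_dec)
        return z_mask, z_bord, z_dt, cache

    def predict(self, img: Volume) -> LabelTriplet:
        z_mask, z_bord, z_dt, _ = self._forward(np.asarray(img.data, dtype=float))
        return LabelTriplet(
            mask=img.like(_sigmoid(z_mask)),
            border=img.like(_sigmoid(z_bord)),
            dt=img.like(np.clip(z_dt, 0.0, float(DT_SATURATION))),
        )

    # -- loss and training --------------------------------------------

    @staticmethod
    def _dice_and_grad(t, p):
        inter = float((t * p).sum())
        s = float(t.sum() + p.sum()) + 1.0
        loss = (inter + 1.0) / s
        grad = t / s - (inter + 1.0) / s ** 2
        return loss, grad

    @staticmethod
    def _logmse_and_grad(t, p, eps=1e-8):
        resid = p - t
        m = float((resid ** 2).mean())
        loss = np.log(m + eps)
        grad = (2.0 * resid / resid.size) / (m + eps)
        return loss, grad

    def loss_and_grads(self, img: np.ndarray, truth: LabelTriplet,
                       weights: LossWeights):
        z_mask, z_bord, z_dt, cache = self._forward(img)
        p_mask, p_bord = _sigmoid(z_mask), _sigmoid(z_bord)
        t_mask = truth.mask.data.astype(float)
        t_bord = truth.border.data.astype(float)
        t_dt = truth.dt.data.astype(float)

        l_k, g_mask = self._dice_and_grad(t_mask, p_mask)
        l_e, g_bord = self._dice_and_grad(t_bord, p_bord)
        l_d, g_dt = self._logmse_and_grad(t_dt, z_dt)
        loss = weights.w_e * l_e + weights.w_k * l_k + weights.w_d * l_d

        dz_mask = weights.w_k * g_mask * p_mask * (1 - p_mask)
        dz_bord = weights.w_e * g_bord * p_bord * (1 - p_bord)
        dz_dt = weights.w_d * g_dt

        p = self.params
        grads = {}
        dh_dec = np.zeros_like(cache["h_dec"])
        for name, dz in (("mask", dz_mask), ("bord", dz_bord), ("dt", dz_dt)):
            dw, db, dx = _conv3_grads(cache["h_dec"], p[f"w_{name}"], dz[None])
            grads[f"w_{name}"], grads[f"b_{name}"] = dw, db
            dh_dec += dx
        da_dec = dh_dec * (cache["a_dec"] > 0)
        grads["w_dec"], grads["b_dec"], dcat = _conv3_grads(cache["cat"], p["w_dec"], da_dec)
        c = self.c
        dh_enc = dcat[:c].copy()
        dup = dcat[c:]
        # unpool gradient: sum each 2x2x2 block back to the coarse cell
        hb = cache["h_bot"]
        dh_bot = np.zeros_like(hb)
        z2, y2, x2 = hb.shape[1:]
        for dz_ in range(2):
            for dy_ in range(2):
                for dx_ in range(2):
                    sl = dup[:, dz_:2 * z2:2, dy_:2 * y2:2, dx_:2 * x2:2]
                    dh_bot[:, :sl.shape[1], :sl.shape[2], :sl.shape[3]] += sl
        da_bot = dh_bot * (cache["a_bot"] > 0)
        grads["w_bot"], grads["b_bot"], dpooled = _conv3_grads(cache["pooled"], p["w_bot"], da_bot)
        # pool gradient: spread evenly over the 2x2x2 block
        dh_enc_pool = np.zeros_like(cache["h_enc"])
        zp, yp, xp_ = dpooled.shape[1:]
        up8 = np.repeat(np.repeat(np.repeat(dpooled / 8.0, 2, axis=1), 2, axis=2), 2, axis=3)
        dh_enc_pool[:, :2 * zp, :2 * yp, :2 * xp_] += up8
        dh_enc += dh_enc_pool
        da_enc = dh_enc * (cache["a_enc"] > 0)
        grads["w_enc"], grads["b_enc"], _ = _conv3_grads(cache["x0"], p["w_enc"], da_enc)
        return loss, grads

    def fit(self, pairs: list[tuple[Volume, LabelTriplet]], epochs: int = 10,
            lr: float = 0.05, weights: LossWeights | None = None) -> list[float]:
        """Full-volume SGD; returns the per-epoch mean loss curve."""
        if not pairs:
            raise ValueError("need at least one training pair")
        weights = weights or LossWeights()
        curve = []
        for _ in range(epochs):
            total = 0.0
            for img, truth in pairs:
                loss, grads = self.loss_and_grads(np.asarray(img.data, dtype=float),
                                                  truth, weights)
                if not np.isfinite(loss):
                    raise TrainingError("training diverged (non-finite loss)")
                total += loss
                for k, gval in grads.items():
                    self.params[k] -= lr * gval
            curve.append(total / len(pairs))
        return curve
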