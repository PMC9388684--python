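"""NumPy forward/backward execution of a :class:`~endoseg.nn.graph.ModelGraph`.

The engine interprets the layer DAG on NCHW float32 tensors.  Convolutions
are lowered to BLAS matrix products (shift-and-add for 3x3, block reshapes
for the non-overlapping 2x2 stride-2 kernels).  Normalization layers use
batch statistics during training (tracking moving mean/variance/stddev) and
the tracked statistics at inference.  Gradients are accumulated by a manual
reverse pass over the same DAG.
"""

from __future__ import annotations

import numpy as np

from endoseg.nn.graph import LayerSpec, ModelGraph

__all__ = ["Network", "softmax_cross_entropy"]

EPS = 1e-5
BN_MOMENTUM = 0.99


def _he_std(fan_in: int) -> float:
    return float(np.sqrt(2.0 / max(fan_in, 1)))


class Network:
    """Executable network: parameters + forward/backward over a ModelGraph."""

    def __init__(self, graph: ModelGraph, seed: int = 0):
        self.graph = graph
        self.params: dict[str, dict[str, np.ndarray]] = {}
        self.stats: dict[str, dict[str, np.ndarray]] = {}
        rng = np.random.default_rng(seed)
        for l in graph.layers:
            if l.op == "conv":
                fan_in = l.kernel * l.kernel * l.in_channels
                w = rng.normal(0.0, _he_std(fan_in), (l.out_channels, l.in_channels, l.kernel, l.kernel))
                self.params[l.name] = {"W": w.astype(np.float32),
                                       "b": np.zeros(l.out_channels, np.float32)}
            elif l.op == "convT":
                fan_in = l.in_channels  # each output pixel sees one input pixel
                w = rng.normal(0.0, _he_std(fan_in), (l.in_channels, l.out_channels, 2, 2))
                self.params[l.name] = {"W": w.astype(np.float32),
                                       "b": np.zeros(l.out_channels, np.float32)}
            elif l.op == "bn":
                c = l.out_channels
                self.params[l.name] = {"gamma": np.ones(c, np.float32),
                                       "beta": np.zeros(c, np.float32)}
                self.stats[l.name] = {"mean": np.zeros(c, np.float32),
                                      "var": np.ones(c, np.float32),
                                      "stddev": np.ones(c, np.float32)}

    # ------------------------------------------------------------------ ops

    @staticmethod
    def _conv1x1(x, w2):
        n, c, h, wdt = x.shape
        y = np.matmul(w2, x.reshape(n, c, h * wdt))
        return y.reshape(n, w2.shape[0], h, wdt)

    def _conv_fwd(self, l: LayerSpec, x):
        w, b = self.params[l.name]["W"], self.params[l.name]["b"]
        if l.kernel == 1:
            y = self._conv1x1(x, w[:, :, 0, 0])
        elif l.kernel == 3:
            n, c, h, wd = x.shape
            xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
            y = np.zeros((n, l.out_channels, h, wd), np.float32)
            for i in range(3):
                for j in range(3):
                    y += self._conv1x1(xp[:, :, i:i + h, j:j + wd], w[:, :, i, j])
        elif l.kernel == 2 and l.stride == 2:
            n, c, h, wd = x.shape
            xb = x.reshape(n, c, h // 2, 2, wd // 2, 2).transpose(0, 2, 4, 1, 3, 5)
            xb = np.ascontiguousarray(xb).reshape(n, h // 2, wd // 2, c * 4)
            y = xb @ w.reshape(l.out_channels, c * 4).T
            y = np.ascontiguousarray(y.transpose(0, 3, 1, 2))
        else:  # pragma: no cover
            raise NotImplementedError(f"conv kernel {l.kernel} stride {l.stride}")
        return y + b[None, :, None, None]

    def _conv_bwd(self, l: LayerSpec, x, dy, grads):
        w = self.params[l.name]["W"]
        g = grads.setdefault(l.name, {})
        g["b"] = dy.sum(axis=(0, 2, 3))
        n = x.shape[0]
        if l.kernel == 1:
            c = x.shape[1]
            hw = x.shape[2] * x.shape[3]
            dyf = dy.reshape(n, l.out_channels, hw)
            xf = x.reshape(n, c, hw)
            g["W"] = np.einsum("noh,nch->oc", dyf, xf, optimize=True)[:, :, None, None]
            dx = np.matmul(w[:, :, 0, 0].T, dyf).reshape(x.shape)
        elif l.kernel == 3:
            h, wd = x.shape[2], x.shape[3]
            xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
            dxp = np.zeros_like(xp)
            dw = np.zeros_like(w)
            dyf = dy.reshape(n, l.out_channels, h * wd)
            for i in range(3):
                for j in range(3):
                    xs = xp[:, :, i:i + h, j:j + wd].reshape(n, x.shape[1], h * wd)
                    dw[:, :, i, j] = np.einsum("noh,nch->oc", dyf, xs, optimize=True)
                    dxp[:, :, i:i + h, j:j + wd] += np.matmul(
                        w[:, :, i, j].T, dyf).reshape(n, x.shape[1], h, wd)
            g["W"] = dw
            dx = dxp[:, :, 1:-1, 1:-1]
        else:  # 2x2 stride 2
            c, h, wd = x.shape[1], x.shape[2], x.shape[3]
            xb = x.reshape(n, c, h // 2, 2, wd // 2, 2).transpose(0, 2, 4, 1, 3, 5)
            xb = np.ascontiguousarray(xb).reshape(-1, c * 4)
            dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, l.out_channels)
            g["W"] = (dyf.T @ xb).reshape(w.shape)
            dxb = dyf @ w.reshape(l.out_channels, c * 4)
            dx = dxb.reshape(n, h // 2, wd // 2, c, 2, 2).transpose(0, 3, 1, 4, 2, 5)
            dx = np.ascontiguousarray(dx).reshape(x.shape)
        return dx

    def _convT_fwd(self, l: LayerSpec, x):
        w, b = self.params[l.name]["W"], self.params[l.name]["b"]
        n, c, h, wd = x.shape
        xf = np.ascontiguousarray(x.transpose(0, 2, 3, 1)).reshape(-1, c)
        yb = xf @ w.reshape(c, l.out_channels * 4)
        y = yb.reshape(n, h, wd, l.out_channels, 2, 2).transpose(0, 3, 1, 4, 2, 5)
        y = np.ascontiguousarray(y).reshape(n, l.out_channels, 2 * h, 2 * wd)
        return y + b[None, :, None, None]

    def _convT_bwd(self, l: LayerSpec, x, dy, grads):
        w = self.params[l.name]["W"]
        g = grads.setdefault(l.name, {})
        g["b"] = dy.sum(axis=(0, 2, 3))
        n, c, h, wd = x.shape
        o = l.out_channels
        dyb = dy.reshape(n, o, h, 2, wd, 2).transpose(0, 2, 4, 1, 3, 5)
        dyb = np.ascontiguousarray(dyb).reshape(-1, o * 4)
        xf = np.ascontiguousarray(x.transpose(0, 2, 3, 1)).reshape(-1, c)
        g["W"] = (xf.T @ dyb).reshape(w.shape)
        dx = (dyb @ w.reshape(c, o * 4).T).reshape(n, h, wd, c).transpose(0, 3, 1, 2)
        return np.ascontiguousarray(dx)

    def _bn_fwd(self, l: LayerSpec, x, training, cache):
        p, s = self.params[l.name], self.stats[l.name]
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = BN_MOMENTUM
            s["mean"] = m * s["mean"] + (1 - m) * mean
            s["var"] = m * s["var"] + (1 - m) * var
            s["stddev"] = m * s["stddev"] + (1 - m) * np.sqrt(var + EPS)
        else:
            mean, var = s["mean"], s["var"]
        ivar = 1.0 / np.sqrt(var + EPS)
        xhat = (x - mean[None, :, None, None]) * ivar[None, :, None, None]
        cache[l.name] = (xhat, ivar, training)
        return p["gamma"][None, :, None, None] * xhat + p["beta"][None, :, None, None]

    def _bn_bwd(self, l: LayerSpec, dy, cache, grads):
        xhat, ivar, training = cache[l.name]
        p = self.params[l.name]
        g = grads.setdefault(l.name, {})
        g["gamma"] = (dy * xhat).sum(axis=(0, 2, 3))
        g["beta"] = dy.sum(axis=(0, 2, 3))
        dxhat = dy * p["gamma"][None, :, None, None]
        if not training:
            return dxhat * ivar[None, :, None, None]
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        term = dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True) \
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / m
        return term * ivar[None, :, None, None]

    @staticmethod
    def _attn_chunk(npix: int) -> int:
        # keep each (chunk, npix) score block around ~128 MB of float32
        return max(64, min(npix, int(3.2e7 / max(npix, 1))))

    @classmethod
    def _attend_fwd(cls, l: LayerSpec, q, k, v, cache):
        """Scaled dot-product attention over all spatial positions.

        The (npix x npix) attention matrix is never materialized in full:
        rows are processed per image in chunks (and recomputed likewise in
        backward), so memory stays linear in the number of positions.  The
        softmax normalization is applied after the value product, on the
        narrow side.
        """
        n, c8, h, w = q.shape
        npix = h * w
        qm = np.ascontiguousarray(q.reshape(n, c8, npix).transpose(0, 2, 1))
        km = np.ascontiguousarray(k.reshape(n, c8, npix))
        vm = np.ascontiguousarray(v.reshape(n, c8, npix).transpose(0, 2, 1))
        z = np.empty((n, npix, c8), np.float32)
        step = cls._attn_chunk(npix)
        inv_scale = np.float32(1.0 / np.sqrt(c8))
        for b in range(n):
            for i in range(0, npix, step):
                s = np.dot(qm[b, i:i + step], km[b])
                s *= inv_scale
                s -= s.max(axis=-1, keepdims=True)
                np.exp(s, out=s)
                zc = np.dot(s, vm[b])
                zc /= s.sum(axis=-1)[:, None]
                z[b, i:i + step] = zc
        cache[l.name] = (qm, km, vm, (n, c8, h, w))
        return np.ascontiguousarray(z.transpose(0, 2, 1)).reshape(n, c8, h, w)

    @classmethod
    def _attend_bwd(cls, l: LayerSpec, dy, cache):
        qm, km, vm, (n, c8, h, w) = cache[l.name]
        npix = h * w
        dz = np.ascontiguousarray(dy.reshape(n, c8, npix).transpose(0, 2, 1))
        dqm = np.empty_like(qm)
        dkm = np.zeros_like(km)
        dvm = np.zeros_like(vm)
        step = cls._attn_chunk(npix)
        inv_scale = np.float32(1.0 / np.sqrt(c8))
        for b in range(n):
            kmT = km[b].T
            vmT = vm[b].T
            for i in range(0, npix, step):
                e = np.dot(qm[b, i:i + step], km[b])
                e *= inv_scale
                e -= e.max(axis=-1, keepdims=True)
                np.exp(e, out=e)
                denom = e.sum(axis=-1)[:, None]
                dzc = dz[b, i:i + step]
                dattn = np.dot(dzc, vmT)                     # (chunk, npix)
                dvm[b] += np.dot(e.T, dzc / denom)
                t = (dattn * e).sum(axis=-1)[:, None] / denom
                dattn -= t
                dattn *= inv_scale / denom
                e *= dattn                                   # now d(scores)*...
                dqm[b, i:i + step] = np.dot(e, kmT)
                dkm[b] += np.dot(qm[b, i:i + step].T, e)
        dq = np.ascontiguousarray(dqm.transpose(0, 2, 1)).reshape(n, c8, h, w)
        dk = dkm.reshape(n, c8, h, w)
        dv = np.ascontiguousarray(dvm.transpose(0, 2, 1)).reshape(n, c8, h, w)
        return dq, dk, dv

    # ------------------------------------------------------------ execution

    def forward(self, x: np.ndarray, training: bool = False,
                dropout_rng: np.random.Generator | None = None) -> dict[str, np.ndarray]:
        """Run the graph; returns the activation cache (includes 'output')."""
        x = np.asarray(x, np.float32)
        if x.ndim == 3:
            x = x[:, None]
        h, w = x.shape[2], x.shape[3]
        factor = 2 ** (self.graph.config.stages - 1)
        if h % factor or w % factor:
            raise ValueError(f"spatial dims {h}x{w} must be divisible by {factor}")
        acts: dict[str, np.ndarray] = {}
        self._cache: dict = {}
        for l in self.graph.layers:
            if l.op == "input":
                acts[l.name] = x
            elif l.op == "conv":
                acts[l.name] = self._conv_fwd(l, acts[l.inputs[0]])
            elif l.op == "convT":
                acts[l.name] = self._convT_fwd(l, acts[l.inputs[0]])
            elif l.op == "bn":
                acts[l.name] = self._bn_fwd(l, acts[l.inputs[0]], training, self._cache)
            elif l.op == "elu":
                xi = acts[l.inputs[0]]
                acts[l.name] = np.where(xi > 0, xi, np.expm1(np.minimum(xi, 0.0)))
            elif l.op == "relu":
                acts[l.name] = np.maximum(acts[l.inputs[0]], 0.0)
            elif l.op == "sigmoid":
                acts[l.name] = 1.0 / (1.0 + np.exp(-acts[l.inputs[0]]))
            elif l.op == "dropout":
                xi = acts[l.inputs[0]]
                if training and l.rate > 0:
                    rng = dropout_rng or np.random.default_rng(0)
                    mask = (rng.random(xi.shape, np.float32) >= l.rate)
                    self._cache[l.name] = mask
                    acts[l.name] = xi * mask / (1.0 - l.rate)
                else:
                    acts[l.name] = xi
            elif l.op == "concat":
                acts[l.name] = np.concatenate([acts[i] for i in l.inputs], axis=1)
            elif l.op == "add":
                s = acts[l.inputs[0]].copy()
                for i in l.inputs[1:]:
                    s += acts[i]
                acts[l.name] = s
            elif l.op == "mul":
                acts[l.name] = acts[l.inputs[0]] * acts[l.inputs[1]]
            elif l.op == "attend":
                q, k, v = (acts[i] for i in l.inputs)
                if k.shape[2:] != q.shape[2:]:
                    raise ValueError("attention key/value spatial size must match query")
                acts[l.name] = self._attend_fwd(l, q, k, v, self._cache)
            elif l.op == "softmax":
                z = acts[l.inputs[0]]
                z = z - z.max(axis=1, keepdims=True)
                e = np.exp(z)
                acts[l.name] = e / e.sum(axis=1, keepdims=True)
            else:  # pragma: no cover
                raise NotImplementedError(l.op)
        self._acts = acts
        return acts

    def backward(self, d_logits: np.ndarray) -> dict[str, dict[str, np.ndarray]]:
        """Reverse pass from the gradient at the 'logits' layer output."""
        acts = self._acts
        grads: dict[str, dict[str, np.ndarray]] = {}
        dacts: dict[str, np.ndarray] = {"logits": np.asarray(d_logits, np.float32)}

        def accum(name, g):
            if name in dacts:
                dacts[name] = dacts[name] + g
            else:
                dacts[name] = g

        for l in reversed(self.graph.layers):
            if l.name not in dacts or l.op in ("input", "softmax"):
                continue
            dy = dacts.pop(l.name)
            if l.op == "conv":
                accum(l.inputs[0], self._conv_bwd(l, acts[l.inputs[0]], dy, grads))
            elif l.op == "convT":
                accum(l.inputs[0], self._convT_bwd(l, acts[l.inputs[0]], dy, grads))
            elif l.op == "bn":
                accum(l.inputs[0], self._bn_bwd(l, dy, self._cache, grads))
            elif l.op == "elu":
                y = acts[l.name]
                accum(l.inputs[0], dy * np.where(acts[l.inputs[0]] > 0, 1.0, y + 1.0))
            elif l.op == "relu":
                accum(l.inputs[0], dy * (acts[l.inputs[0]] > 0))
            elif l.op == "sigmoid":
                y = acts[l.name]
                accum(l.inputs[0], dy * y * (1.0 - y))
            elif l.op == "dropout":
                mask = self._cache.get(l.name)
                accum(l.inputs[0], dy if mask is None else dy * mask / (1.0 - l.rate))
            elif l.op == "concat":
                ofs = 0
                for i in l.inputs:
                    c = acts[i].shape[1]
                    accum(i, dy[:, ofs:ofs + c])
                    ofs += c
            elif l.op == "add":
                for i in l.inputs:
                    accum(i, dy)
            elif l.op == "mul":
                xi, gate = acts[l.inputs[0]], acts[l.inputs[1]]
                accum(l.inputs[0], dy * gate)
                dg = dy * xi
                if gate.shape[1] == 1 and xi.shape[1] > 1:
                    dg = dg.sum(axis=1, keepdims=True)
                accum(l.inputs[1], dg)
            elif l.op == "attend":
                dq, dk, dv = self._attend_bwd(l, dy, self._cache)
                accum(l.inputs[0], dq)
                accum(l.inputs[1], dk)
                accum(l.inputs[2], dv)
        return grads

    # ---------------------------------------------------------- persistence

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for name, p in self.params.items():
            for key, arr in p.items():
                out[f"{name}::{key}"] = arr
        for name, s in self.stats.items():
            for key, arr in s.items():
                out[f"{name}::stat::{key}"] = arr
        return out

    def save(self, path) -> None:
        np.savez_compressed(path, **self.state_arrays())

    def load(self, path) -> None:
        data = np.load(path)
        for full, arr in data.items():
            if "::stat::" in full:
                name, key = full.split("::stat::")
                self.stats[name][key] = arr
            else:
                name, key = full.split("::")
                self.params[name][key] = arr.astype(np.float32)


def softmax_cross_entropy(logits: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Categorical cross-entropy over the channel axis with soft targets.

    Targets are per-pixel class probabilities (e.g. (p, 1-p)); returns the
    mean per-pixel loss and the gradient w.r.t. the logits.  A uniform
    predictor against any normalized target scores ln 2 per pixel for two
    classes.
    """
    z = logits - logits.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    npix = logits.shape[0] * logits.shape[2] * logits.shape[3]
    loss = float(-(target * logp).sum() / npix)
    grad = (np.exp(logp) - target) / npix
    return loss, grad.astype(np.float32)
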