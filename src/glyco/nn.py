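"""Minimal, deterministic NumPy neural-network layers with manual
backpropagation, sized for small sequence-classification models.

Implements exactly what the event detectors need: dense, 1-D
convolution, max-pooling, LSTM, bidirectional LSTM, a ConvLSTM cell for
1x1 spatial grids, dropout (plain and recurrent/variational), masking,
softmax cross-entropy with per-sample weights, L1 weight/bias
penalties, and Adam.  Everything is driven by explicit
``numpy.random.Generator`` seeds, so training is bitwise reproducible
on a fixed platform.

Recurrent cells use the conventional sigmoid/tanh gate activations;
ReLU is used in the convolutional and dense layers.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class Layer:
    """Base layer: ``params``/``grads`` are parallel lists of arrays."""

    params: list
    grads: list

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x, training=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, d_in, units, activation="linear", rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / d_in) if activation == "relu" else np.sqrt(1.0 / d_in)
        self.W = rng.standard_normal((d_in, units)) * scale
        self.b = np.zeros(units)
        self.activation = activation
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, training=False):
        self._x = x
        z = x @ self.W + self.b
        if self.activation == "relu":
            self._mask = z > 0
            return z * self._mask
        return z

    def backward(self, dy):
        if self.activation == "relu":
            dy = dy * self._mask
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.W.T


class Dropout(Layer):
    def __init__(self, rate, rng=None):
        super().__init__()
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, training=False):
        if not training or self.rate <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Conv1D(Layer):
    """Valid 1-D convolution along the lag axis, features as channels.

    Input (B, T, C) -> output (B, T - k + 1, filters), ReLU activation.
    """

    def __init__(self, c_in, filters, kernel=3, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.kernel = kernel
        self.W = rng.standard_normal((kernel, c_in, filters)) * np.sqrt(2.0 / (kernel * c_in))
        self.b = np.zeros(filters)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, training=False):
        self._x = x
        B, T, C = x.shape
        To = T - self.kernel + 1
        z = np.broadcast_to(self.b, (B, To, self.W.shape[2])).copy()
        for i in range(self.kernel):
            z += x[:, i:i + To] @ self.W[i]
        self._mask = z > 0
        return z * self._mask

    def backward(self, dy):
        dy = dy * self._mask
        x = self._x
        B, T, C = x.shape
        To = dy.shape[1]
        dx = np.zeros_like(x)
        for i in range(self.kernel):
            self.grads[0][i] = np.einsum("btc,btf->cf", x[:, i:i + To], dy)
            dx[:, i:i + To] += dy @ self.W[i].T
        self.grads[1][...] = dy.sum(axis=(0, 1))
        return dx


class MaxPool1D(Layer):
    def __init__(self, pool=2):
        super().__init__()
        self.pool = pool

    def forward(self, x, training=False):
        B, T, C = x.shape
        To = T // self.pool
        xr = x[:, :To * self.pool].reshape(B, To, self.pool, C)
        self._argmax = xr.argmax(axis=2)
        self._in_shape = x.shape
        return xr.max(axis=2)

    def backward(self, dy):
        B, To, C = dy.shape
        dx = np.zeros(self._in_shape)
        b, t, c = np.meshgrid(np.arange(B), np.arange(To), np.arange(C),
                              indexing="ij")
        dx[b, t * self.pool + self._argmax, c] = dy
        return dx


class Masking(Layer):
    """Flags timesteps where every feature equals ``mask_value``; the
    following recurrent layer carries its state through flagged steps."""

    def __init__(self, mask_value=0.0):
        super().__init__()
        self.mask_value = mask_value

    def forward(self, x, training=False):
        self.mask = ~np.all(x == self.mask_value, axis=-1)  # (B, T)
        return x

    def backward(self, dy):
        return dy


class LSTM(Layer):
    """Standard LSTM returning the final hidden state.

    Supports a per-timestep validity mask (state held where invalid) and
    variational recurrent dropout (one dropout mask on the recurrent
    input, shared across timesteps).
    """

    def __init__(self, d_in, units, recurrent_dropout=0.0, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        u = units
        self.units = u
        self.Wx = rng.standard_normal((d_in, 4 * u)) * np.sqrt(1.0 / d_in)
        self.Wh = rng.standard_normal((u, 4 * u)) * np.sqrt(1.0 / u)
        self.b = np.zeros(4 * u)
        self.b[u:2 * u] = 1.0  # forget-gate bias
        self.recurrent_dropout = recurrent_dropout
        self.rng = rng
        self.params = [self.Wx, self.Wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, training=False, mask=None):
        B, T, D = x.shape
        u = self.units
        if training and self.recurrent_dropout > 0:
            rd = (self.rng.random((B, u)) >= self.recurrent_dropout) \
                / (1.0 - self.recurrent_dropout)
        else:
            rd = np.ones((B, u))
        h = np.zeros((B, u))
        c = np.zeros((B, u))
        self._cache = []
        self._x, self._mask_seq, self._rd = x, mask, rd
        for t in range(T):
            hd = h * rd
            a = x[:, t] @ self.Wx + hd @ self.Wh + self.b
            i = _sigmoid(a[:, :u])
            f = _sigmoid(a[:, u:2 * u])
            g = np.tanh(a[:, 2 * u:3 * u])
            o = _sigmoid(a[:, 3 * u:])
            c_new = f * c + i * g
            hc = np.tanh(c_new)
            h_new = o * hc
            if mask is not None:
                m = mask[:, t:t + 1]
                c_out = np.where(m, c_new, c)
                h_out = np.where(m, h_new, h)
            else:
                c_out, h_out = c_new, h_new
            self._cache.append((h.copy(), c.copy(), hd, i, f, g, o, c_new, hc))
            h, c = h_out, c_out
        return h

    def backward(self, dh):
        x, mask, rd = self._x, self._mask_seq, self._rd
        B, T, D = x.shape
        u = self.units
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dx = np.zeros_like(x)
        dc = np.zeros((B, u))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, hd, i, f, g, o, c_new, hc = self._cache[t]
            if mask is not None:
                m = mask[:, t:t + 1].astype(float)
            else:
                m = 1.0
            dh_step = dh * m if mask is not None else dh
            dc_step = dc * m if mask is not None else dc
            do = dh_step * hc
            dc_new = dc_step + dh_step * o * (1 - hc ** 2)
            di = dc_new * g
            df = dc_new * c_prev
            dg = dc_new * i
            da = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                                 dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
            dWx += x[:, t].T @ da
            dWh += hd.T @ da
            db += da.sum(axis=0)
            dx[:, t] = da @ self.Wx.T
            dh_prev = (da @ self.Wh.T) * rd
            dc_prev = dc_new * f
            if mask is not None:
                inv = 1.0 - m
                dh = dh_prev + dh * inv
                dc = dc_prev + dc * inv
            else:
                dh = dh_prev
                dc = dc_prev
        self.grads[0][...] = dWx
        self.grads[1][...] = dWh
        self.grads[2][...] = db
        return dx


class BiLSTM(Layer):
    """Bidirectional LSTM: concatenated final states of a forward pass
    and a pass over the time-reversed sequence."""

    def __init__(self, d_in, units, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.fwd = LSTM(d_in, units, rng=rng)
        self.bwd = LSTM(d_in, units, rng=rng)
        self.params = self.fwd.params + self.bwd.params
        self.grads = self.fwd.grads + self.bwd.grads

    def forward(self, x, training=False, mask=None):
        hf = self.fwd.forward(x, training, mask)
        mrev = mask[:, ::-1] if mask is not None else None
        hb = self.bwd.forward(x[:, ::-1], training, mrev)
        return np.concatenate([hf, hb], axis=1)

    def backward(self, dy):
        u = self.fwd.units
        dxf = self.fwd.backward(dy[:, :u])
        dxb = self.bwd.backward(dy[:, u:])
        return dxf + dxb[:, ::-1]


class ConvLSTM(LSTM):
    """Convolutional LSTM cell on a 1x1 spatial grid.

    The detectors feed tensors of shape (B, T, 1, 1, C); on a 1x1 grid
    the input-to-state and state-to-state convolutions reduce exactly to
    the dense transforms of a standard LSTM, which this class reuses.
    Accepts either (B, T, 1, 1, C) or (B, T, C) input.
    """

    def forward(self, x, training=False, mask=None):
        if x.ndim == 5:
            assert x.shape[2] == 1 and x.shape[3] == 1, "spatial grid must be 1x1"
            x = x.reshape(x.shape[0], x.shape[1], x.shape[4])
        return super().forward(x, training, mask)


class Sequential:
    """A feed-forward stack ending in 4-class logits, trained with
    weighted softmax cross-entropy + L1 penalties via Adam."""

    def __init__(self, layers, l1=1e-4):
        self.layers = layers
        self.l1 = l1
        self._adam_m = None
        self._adam_v = None
        self._adam_t = 0

    @property
    def params(self):
        return [p for lay in self.layers for p in lay.params]

    @property
    def grads(self):
        return [g for lay in self.layers for g in lay.grads]

    def n_params(self) -> int:
        return sum(p.size for p in self.params)

    def forward(self, x, training=False):
        mask = None
        for lay in self.layers:
            if isinstance(lay, Masking):
                x = lay.forward(x, training)
                mask = lay.mask
            elif isinstance(lay, (LSTM, BiLSTM)):
                x = lay.forward(x, training, mask=mask)
                mask = None
            else:
                x = lay.forward(x, training)
        return x

    def predict_proba(self, x, batch=512):
        out = []
        for i in range(0, len(x), batch):
            logits = self.forward(x[i:i + batch], training=False)
            z = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(z)
            out.append(e / e.sum(axis=1, keepdims=True))
        return np.concatenate(out, axis=0)

    def loss_and_grad(self, x, y_onehot, sample_weight, training=True):
        logits = self.forward(x, training=training)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=1, keepdims=True)
        w = sample_weight / sample_weight.sum()
        ce = float(-(w * np.log((p * y_onehot).sum(axis=1) + 1e-300)).sum())
        reg = self.l1 * sum(np.abs(par).sum() for par in self.params)
        dlogits = (p - y_onehot) * w[:, None]
        # backprop
        dy = dlogits
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return ce + reg, ce

    def adam_step(self, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        if self._adam_m is None:
            self._adam_m = [np.zeros_like(p) for p in self.params]
            self._adam_v = [np.zeros_like(p) for p in self.params]
        self._adam_t += 1
        t = self._adam_t
        for p, g, m, v in zip(self.params, self.grads, self._adam_m, self._adam_v):
            g = g + self.l1 * np.sign(p)
            m[...] = beta1 * m + (1 - beta1) * g
            v[...] = beta2 * v + (1 - beta2) * g * g
            mh = m / (1 - beta1 ** t)
            vh = v / (1 - beta2 ** t)
            p -= lr * mh / (np.sqrt(vh) + eps)

    def fit(self, x, y, sample_weight=None, epochs=50, batch_size=32,
            lr=1e-3, seed=0, x_val=None, y_val=None, patience=10,
            verbose=False):
        """Mini-batch Adam training; early stopping on validation loss
        (training loss when no validation split is given).  Returns the
        per-epoch loss history."""
        n = len(x)
        y = np.asarray(y)
        if y.ndim == 1:
            y = np.eye(4)[y]
        if sample_weight is None:
            sample_weight = np.ones(n)
        rng = np.random.default_rng(seed)
        history = []
        best = np.inf
        best_params = None
        wait = 0
        for epoch in range(epochs):
            order = rng.permutation(n)
            ep_loss = 0.0
            nb = 0
            for i in range(0, n, batch_size):
                sel = order[i:i + batch_size]
                loss, _ = self.loss_and_grad(x[sel], y[sel], sample_weight[sel])
                self.adam_step(lr)
                ep_loss += loss
                nb += 1
            ep_loss /= max(nb, 1)
            if x_val is not None and len(x_val):
                yv = y_val if y_val.ndim == 2 else np.eye(4)[y_val]
                pv = self.predict_proba(x_val)
                monitor = float(-np.mean(np.log((pv * yv).sum(axis=1) + 1e-300)))
            else:
                monitor = ep_loss
            history.append((ep_loss, monitor))
            if verbose:
                print(f"epoch {epoch}: loss {ep_loss:.4f} monitor {monitor:.4f}")
            if monitor < best - 1e-6:
                best = monitor
                best_params = [p.copy() for p in self.params]
                wait = 0
            else:
                wait += 1
                if wait >= patience:
                    break
        if best_params is not None:
            for p, bp in zip(self.params, best_params):
                p[...] = bp
        return history
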