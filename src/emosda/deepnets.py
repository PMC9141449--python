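"""Denoising autoencoders, their stacking, and reference deep baselines.

Everything is implemented directly on numpy with hand-written gradients
and an Adam-style optimizer:

* :class:`DAELayer` — one denoising autoencoder (sigmoid encoder, linear
  decoder, untied weights) trained to reconstruct the clean input from a
  corrupted version (a fixed random proportion of coordinates zeroed).
* :class:`SDAStack` — greedy layer-wise unsupervised pre-training followed
  by supervised fine-tuning of a softmax head on the top code, with an
  L1/L2/misclassification-cost regularized cross-entropy loss.
* :class:`RBMLayer` — restricted Boltzmann machine with CD-1 updates
  (binary or Gaussian visible units), the building block of deep belief
  networks.
* :func:`build_baseline` — the DNN (affine/batch-norm/ReLU/dropout) and
  CNN (stride-2 valid convolutions, max-pooling on the last two modules)
  reference architectures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from emosda.features import FeatureTable


class DivergenceError(RuntimeError):
    pass


class UntrainedStackError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# optimizer

class Adam:
    """Adaptive-moment mini-batch gradient descent."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[int, np.ndarray] = {}
        self.v: dict[int, np.ndarray] = {}

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            if i not in self.m:
                self.m[i] = np.zeros_like(p)
                self.v[i] = np.zeros_like(p)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# corruption

def corrupt_input(x: np.ndarray, q: float, seed: int) -> np.ndarray:
    """Zero exactly round(q * d) uniformly chosen coordinates of a vector.

    Uncorrupted coordinates are preserved exactly; q = 0 is the identity
    and q = 1 returns the zero vector.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must be in [0, 1]")
    x = np.asarray(x, dtype=np.float64)
    d = x.size
    m = int(round(q * d))
    out = x.copy()
    if m:
        idx = np.random.default_rng(seed).choice(d, size=m, replace=False)
        out[idx] = 0.0
    return out


def _corrupt_batch(X: np.ndarray, q: float, rng: np.random.Generator) -> np.ndarray:
    """Row-wise fixed-count corruption (round(q*d) zeros per row)."""
    m = int(round(q * X.shape[1]))
    if m == 0:
        return X
    out = X.copy()
    order = rng.random(X.shape).argsort(axis=1)[:, :m]
    np.put_along_axis(out, order, 0.0, axis=1)
    return out


# ---------------------------------------------------------------------------
# denoising autoencoder layer

@dataclass
class DAELayer:
    """One denoising autoencoder: h = s_f(W x~ + b), z = W' h + b'."""

    W: np.ndarray        # (d', d)
    b: np.ndarray        # (d',)
    Wp: np.ndarray       # (d, d')
    bp: np.ndarray       # (d,)
    corruption: float = 0.2
    encoder_activation: str = "sigmoid"   # 'sigmoid' or 'identity'
    loss_trace: list[float] = field(default_factory=list)
    pretrained: bool = False

    @classmethod
    def create(cls, d_in: int, d_out: int, corruption: float = 0.2,
               seed: int = 0, encoder_activation: str = "sigmoid") -> "DAELayer":
        rng = np.random.default_rng(seed)
        scale = np.sqrt(6.0 / (d_in + d_out))
        return cls(W=rng.uniform(-scale, scale, size=(d_out, d_in)),
                   b=np.zeros(d_out),
                   Wp=rng.uniform(-scale, scale, size=(d_in, d_out)),
                   bp=np.zeros(d_in), corruption=corruption,
                   encoder_activation=encoder_activation)

    def encode(self, X: np.ndarray) -> np.ndarray:
        pre = X @ self.W.T + self.b
        return _sigmoid(pre) if self.encoder_activation == "sigmoid" else pre

    def decode(self, H: np.ndarray) -> np.ndarray:
        return H @ self.Wp.T + self.bp


def dae_pretrain_layer(layer: DAELayer, inputs: np.ndarray, epochs: int = 200,
                       seed: int = 0, lr: float = 1e-3,
                       batch_size: int = 128) -> DAELayer:
    """Train one layer to reconstruct clean inputs from corrupted inputs.

    Mini-batch Adam on the mean squared reconstruction error; the per-epoch
    loss trace is recorded on the layer.  Deterministic under the seed.
    """
    X = np.asarray(inputs, dtype=np.float64)
    if X.shape[1] != layer.W.shape[1]:
        raise ValueError("input dimension does not match layer")
    rng = np.random.default_rng(seed)
    opt = Adam(lr=lr)
    n = X.shape[0]
    layer.loss_trace = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            xb = X[order[start:start + batch_size]]
            xt = _corrupt_batch(xb, layer.corruption, rng)
            pre = xt @ layer.W.T + layer.b
            h = _sigmoid(pre) if layer.encoder_activation == "sigmoid" else pre
            z = h @ layer.Wp.T + layer.bp
            diff = z - xb
            loss = float(np.mean(diff ** 2))
            if not np.isfinite(loss):
                raise DivergenceError(f"NaN loss at epoch {epoch}")
            losses.append(loss)
            m = xb.shape[0]
            dz = 2.0 * diff / diff.size
            dWp = dz.T @ h
            dbp = dz.sum(axis=0)
            dh = dz @ layer.Wp
            if layer.encoder_activation == "sigmoid":
                dpre = dh * h * (1.0 - h)
            else:
                dpre = dh
            dW = dpre.T @ xt
            db = dpre.sum(axis=0)
            opt.step([layer.W, layer.b, layer.Wp, layer.bp],
                     [dW, db, dWp, dbp])
        layer.loss_trace.append(float(np.mean(losses)))
    layer.pretrained = True
    return layer


# ---------------------------------------------------------------------------
# stacked denoising autoencoder

@dataclass
class LossSpec:
    """Coefficients of the regularized fine-tuning loss.

    total = lam0 * cross-entropy + lam1 * L1 + lam2 * L2 + lam3 * C,
    where C is the class-imbalance misclassification cost with entries
    c01 (true 0 predicted 1) and c10 (true 1 predicted 0).
    """

    lam0: float = 1.0
    lam1: float = 1e-4
    lam2: float = 1e-4
    lam3: float = 0.5
    c01: float | None = None   # None -> inverse class frequency
    c10: float | None = None


@dataclass
class SDAStack:
    """Ordered denoising-autoencoder layers plus a supervised softmax head.

    The fine-tuning output layer takes input only from the top hidden
    layer.  Default architecture 3840-1000-200-40 with a 2-class head.
    """

    layers: list[DAELayer]
    W_out: np.ndarray
    b_out: np.ndarray
    fine_tuned: bool = False
    history: dict[str, list[float]] = field(default_factory=dict)

    @classmethod
    def create(cls, dims: tuple[int, ...] = (3840, 1000, 200, 40),
               n_classes: int = 2, corruption: float = 0.2,
               seed: int = 0) -> "SDAStack":
        rng = np.random.default_rng(seed)
        layers = [DAELayer.create(dims[i], dims[i + 1], corruption=corruption,
                                  seed=int(rng.integers(2 ** 31)))
                  for i in range(len(dims) - 1)]
        scale = np.sqrt(6.0 / (dims[-1] + n_classes))
        return cls(layers=layers,
                   W_out=rng.uniform(-scale, scale, size=(n_classes, dims[-1])),
                   b_out=np.zeros(n_classes))

    @property
    def pretrained(self) -> bool:
        return all(l.pretrained for l in self.layers)

    def encode(self, X: np.ndarray) -> np.ndarray:
        H = np.asarray(X, dtype=np.float64)
        for layer in self.layers:
            H = layer.encode(H)
        return H

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        H = self.encode(X)
        for layer in reversed(self.layers):
            H = layer.decode(H)
        return H

    def reconstruction_error(self, X: np.ndarray) -> float:
        """Mean squared encode-decode reconstruction error per element."""
        X = np.asarray(X, dtype=np.float64)
        return float(np.mean((self.reconstruct(X) - X) ** 2))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _softmax(self.encode(X) @ self.W_out.T + self.b_out)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)


def sda_pretrain(stack: SDAStack, data: np.ndarray,
                 epochs_per_layer: int = 200, seed: int = 0,
                 lr: float = 1e-3, batch_size: int = 128) -> SDAStack:
    """Greedy bottom-up pre-training.

    Each layer is trained on the clean codes of the layer below and applies
    its own corruption to its own input.
    """
    H = np.asarray(data, dtype=np.float64)
    rng = np.random.default_rng(seed)
    for layer in stack.layers:
        dae_pretrain_layer(layer, H, epochs=epochs_per_layer,
                           seed=int(rng.integers(2 ** 31)), lr=lr,
                           batch_size=batch_size)
        H = layer.encode(H)
    return stack


def _cost_weights(y: np.ndarray, loss: LossSpec) -> tuple[float, float]:
    n = y.size
    n1 = int(y.sum())
    n0 = n - n1
    c01 = loss.c01 if loss.c01 is not None else n / (2.0 * max(n0, 1))
    c10 = loss.c10 if loss.c10 is not None else n / (2.0 * max(n1, 1))
    return float(c01), float(c10)


def sda_loss(stack: SDAStack, X: np.ndarray, y: np.ndarray,
             loss: LossSpec) -> float:
    """Evaluate the regularized loss.

    The misclassification-cost term uses hard prediction error counts, so
    it is exactly zero when every prediction is correct.
    """
    p = stack.predict_proba(X)
    n = y.size
    ce = float(-np.mean(np.log(p[np.arange(n), y] + 1e-12)))
    weights = [stack.W_out] + [l.W for l in stack.layers]
    l1 = float(sum(np.abs(w).sum() for w in weights))
    l2 = float(sum((w ** 2).sum() for w in weights))
    c01, c10 = _cost_weights(y, loss)
    pred = p.argmax(axis=1)
    n_fp = int(np.sum((y == 0) & (pred == 1)))
    n_fn = int(np.sum((y == 1) & (pred == 0)))
    cost = (c01 * n_fp + c10 * n_fn) / n
    return loss.lam0 * ce + loss.lam1 * l1 + loss.lam2 * l2 + loss.lam3 * cost


def fine_tune(stack: SDAStack, data: np.ndarray, labels: np.ndarray,
              loss: LossSpec | None = None, epochs: int = 50, seed: int = 0,
              lr: float = 1e-3, batch_size: int = 128,
              validation: tuple[np.ndarray, np.ndarray] | None = None,
              restore_best: bool = False) -> SDAStack:
    """End-to-end supervised gradient descent on the regularized loss.

    The gradient uses the smooth surrogate of the misclassification-cost
    term (expected cost under the softmax probabilities); the reported loss
    uses hard error counts.  Records per-epoch train loss/accuracy and
    validation accuracy when provided.  With ``restore_best`` (and a
    validation set) the parameters of the best-validation-accuracy epoch
    are restored at the end, i.e. the epoch count is selected on the
    validation set.
    """
    loss = loss or LossSpec()
    X = np.asarray(data, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    if X.shape[0] != y.size:
        raise ValueError("data and labels are misaligned")
    rng = np.random.default_rng(seed)
    opt = Adam(lr=lr)
    c01, c10 = _cost_weights(y, loss)
    n = X.shape[0]
    hist: dict[str, list[float]] = {"loss": [], "train_acc": [], "val_acc": []}
    params = []
    for l in stack.layers:
        params += [l.W, l.b]
    params += [stack.W_out, stack.b_out]

    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb, yb = X[idx], y[idx]
            m = xb.shape[0]
            acts = [xb]
            for l in stack.layers:
                acts.append(l.encode(acts[-1]))
            p = _softmax(acts[-1] @ stack.W_out.T + stack.b_out)
            onehot = np.zeros_like(p)
            onehot[np.arange(m), yb] = 1.0
            dz = loss.lam0 * (p - onehot) / m
            # smooth class-cost surrogate: expected cost of the wrong class
            kappa = np.where(yb == 0, c01, c10)
            wrong = 1 - yb
            e_wrong = np.zeros_like(p)
            e_wrong[np.arange(m), wrong] = 1.0
            p_wrong = p[np.arange(m), wrong][:, None]
            dz += loss.lam3 * kappa[:, None] * p_wrong * (e_wrong - p) / m
            grads = []
            dW_out = dz.T @ acts[-1] + loss.lam1 * np.sign(stack.W_out) \
                + 2.0 * loss.lam2 * stack.W_out
            db_out = dz.sum(axis=0)
            dh = dz @ stack.W_out
            for li in range(len(stack.layers) - 1, -1, -1):
                l = stack.layers[li]
                h = acts[li + 1]
                dpre = dh * h * (1.0 - h) if l.encoder_activation == "sigmoid" else dh
                dW = dpre.T @ acts[li] + loss.lam1 * np.sign(l.W) \
                    + 2.0 * loss.lam2 * l.W
                db = dpre.sum(axis=0)
                dh = dpre @ l.W
                grads = [dW, db] + grads
            grads += [dW_out, db_out]
            opt.step(params, grads)
        hist["loss"].append(sda_loss(stack, X, y, loss))
        hist["train_acc"].append(float(np.mean(stack.predict(X) == y)))
        if validation is not None:
            val_acc = float(np.mean(stack.predict(validation[0]) == validation[1]))
            hist["val_acc"].append(val_acc)
            if restore_best and val_acc >= max(hist["val_acc"]):
                best_params = [p.copy() for p in params]
    stack.fine_tuned = True
    stack.history = hist
    if restore_best and validation is not None:
        for p, bp in zip(params, best_params):
            p[...] = bp
    return stack


def sda_autoencoder_finetune(stack: SDAStack, data: np.ndarray,
                             epochs: int = 20, seed: int = 0, lr: float = 1e-3,
                             batch_size: int = 128) -> list[float]:
    """End-to-end reconstruction fine-tuning of the unrolled autoencoder.

    Minimizes the mean squared error between the input and the full
    encode-decode chain by gradient descent over every encoder and decoder
    parameter.  Returns the per-epoch reconstruction-error trace on the
    training data (the epoch-0 entry is the error of the initial
    parameters, i.e. of pre-training or of random initialization).
    """
    X = np.asarray(data, dtype=np.float64)
    rng = np.random.default_rng(seed)
    opt = Adam(lr=lr)
    n = X.shape[0]
    params: list[np.ndarray] = []
    for l in stack.layers:
        params += [l.W, l.b, l.Wp, l.bp]
    trace = [stack.reconstruction_error(X)]
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            xb = X[order[start:start + batch_size]]
            acts = [xb]
            for l in stack.layers:
                acts.append(l.encode(acts[-1]))
            dec = [acts[-1]]
            for l in reversed(stack.layers):
                dec.append(l.decode(dec[-1]))
            z = dec[-1]
            diff = z - xb
            if not np.isfinite(diff).all():
                raise DivergenceError("NaN in autoencoder fine-tuning")
            grads = [np.zeros_like(p) for p in params]
            d = 2.0 * diff / diff.size
            # decoder chain (top layer decoded last in dec, so walk back)
            n_l = len(stack.layers)
            for k, l in enumerate(stack.layers):  # l decodes dec[n_l-1-k] -> dec[n_l-k]
                h_in = dec[n_l - 1 - k]
                gi = 4 * k
                grads[gi + 2] += d.T @ h_in          # dWp
                grads[gi + 3] += d.sum(axis=0)       # dbp
                d = d @ l.Wp
                if k < n_l - 1:
                    pass  # decoders are linear; no activation derivative
            # d is now the gradient w.r.t. the top code; encoder chain
            for li in range(n_l - 1, -1, -1):
                l = stack.layers[li]
                h = acts[li + 1]
                dpre = d * h * (1.0 - h) if l.encoder_activation == "sigmoid" else d
                gi = 4 * li
                grads[gi] += dpre.T @ acts[li]       # dW
                grads[gi + 1] += dpre.sum(axis=0)    # db
                d = dpre @ l.W
            opt.step(params, grads)
        trace.append(stack.reconstruction_error(X))
    return trace


def encode_features(stack: SDAStack, data: np.ndarray) -> FeatureTable:
    """Top-layer codes as a feature table for external classifiers."""
    if not (stack.pretrained or stack.fine_tuned):
        raise UntrainedStackError("stack has not been trained")
    codes = stack.encode(np.asarray(data, dtype=np.float64))
    d = codes.shape[1]
    return FeatureTable(codes, [f"sda.code{i}" for i in range(d)],
                        ["code"] * d)


# ---------------------------------------------------------------------------
# restricted Boltzmann machine

@dataclass
class RBMLayer:
    """RBM with binary hidden units and binary or Gaussian visible units."""

    W: np.ndarray        # (d_visible, d_hidden)
    b: np.ndarray        # hidden biases (d_hidden,)
    c: np.ndarray        # visible biases (d_visible,)
    visible_kind: str = "binary"

    @classmethod
    def create(cls, d_visible: int, d_hidden: int,
               visible_kind: str = "binary", seed: int = 0) -> "RBMLayer":
        rng = np.random.default_rng(seed)
        return cls(W=rng.normal(0.0, 0.01, size=(d_visible, d_hidden)),
                   b=np.zeros(d_hidden), c=np.zeros(d_visible),
                   visible_kind=visible_kind)

    def hidden_prob(self, v: np.ndarray) -> np.ndarray:
        return _sigmoid(v @ self.W + self.b)

    def visible_mean(self, h: np.ndarray) -> np.ndarray:
        pre = h @ self.W.T + self.c
        return _sigmoid(pre) if self.visible_kind == "binary" else pre

    def energy(self, v: np.ndarray, h: np.ndarray) -> float:
        """Joint energy of one (v, h) configuration."""
        v = np.asarray(v, dtype=np.float64)
        h = np.asarray(h, dtype=np.float64)
        interaction = float(v @ self.W @ h)
        if self.visible_kind == "binary":
            return -interaction - float(self.b @ h) - float(self.c @ v)
        return float(np.sum((v - self.c) ** 2) / 2.0) - interaction - float(self.b @ h)


def rbm_cd_update(rbm: RBMLayer, batch: np.ndarray, lr: float = 1e-2,
                  seed: int = 0) -> RBMLayer:
    """One CD-1 contrastive-divergence step on a mini-batch."""
    v0 = np.asarray(batch, dtype=np.float64)
    if v0.shape[1] != rbm.W.shape[0]:
        raise ValueError("batch dimension does not match visible units")
    rng = np.random.default_rng(seed)
    p_h0 = rbm.hidden_prob(v0)
    h0 = (rng.random(p_h0.shape) < p_h0).astype(np.float64)
    v1 = rbm.visible_mean(h0)
    p_h1 = rbm.hidden_prob(v1)
    m = v0.shape[0]
    rbm.W += lr * (v0.T @ p_h0 - v1.T @ p_h1) / m
    rbm.b += lr * (p_h0.mean(axis=0) - p_h1.mean(axis=0))
    rbm.c += lr * (v0.mean(axis=0) - v1.mean(axis=0))
    return rbm


def rbm_reconstruction_error(rbm: RBMLayer, X: np.ndarray) -> float:
    v1 = rbm.visible_mean(rbm.hidden_prob(X))
    return float(np.mean((v1 - X) ** 2))


@dataclass
class DBN:
    """Deep-belief reference: greedily trained RBMs plus a logistic head.

    Each RBM's hidden probabilities become the visible data of the next
    (the first layer is Gaussian-visible for real-valued input); after
    pre-training, a softmax output layer is fit on the top activations.
    """

    rbms: list[RBMLayer]
    W_out: np.ndarray | None = None
    b_out: np.ndarray | None = None

    @classmethod
    def create(cls, dims: tuple[int, ...], seed: int = 0) -> "DBN":
        rng = np.random.default_rng(seed)
        rbms = [RBMLayer.create(dims[i], dims[i + 1],
                                visible_kind="gaussian" if i == 0 else "binary",
                                seed=int(rng.integers(2 ** 31)))
                for i in range(len(dims) - 1)]
        return cls(rbms=rbms)

    def transform(self, X: np.ndarray) -> np.ndarray:
        H = np.asarray(X, dtype=np.float64)
        for rbm in self.rbms:
            H = rbm.hidden_prob(H)
        return H

    def pretrain(self, X: np.ndarray, epochs_per_layer: int = 20,
                 lr: float = 1e-2, batch_size: int = 128,
                 seed: int = 0) -> "DBN":
        rng = np.random.default_rng(seed)
        H = np.asarray(X, dtype=np.float64)
        for rbm in self.rbms:
            n = H.shape[0]
            for _ in range(epochs_per_layer):
                order = rng.permutation(n)
                for start in range(0, n, batch_size):
                    rbm_cd_update(rbm, H[order[start:start + batch_size]],
                                  lr=lr, seed=int(rng.integers(2 ** 31)))
            H = rbm.hidden_prob(H)
        return self

    def fit_head(self, X: np.ndarray, y: np.ndarray, epochs: int = 50,
                 lr: float = 1e-2, seed: int = 0) -> "DBN":
        """Multinomial logistic regression on the top-layer activations."""
        H = self.transform(X)
        y = np.asarray(y, dtype=np.int64)
        rng = np.random.default_rng(seed)
        d, k = H.shape[1], int(y.max()) + 1
        self.W_out = rng.normal(0, 0.01, size=(k, d))
        self.b_out = np.zeros(k)
        opt = Adam(lr=lr)
        onehot = np.zeros((y.size, k))
        onehot[np.arange(y.size), y] = 1.0
        for _ in range(epochs):
            p = _softmax(H @ self.W_out.T + self.b_out)
            dz = (p - onehot) / y.size
            opt.step([self.W_out, self.b_out], [dz.T @ H, dz.sum(axis=0)])
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.W_out is None:
            raise UntrainedStackError("output head has not been fit")
        return _softmax(self.transform(X) @ self.W_out.T + self.b_out)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)


# ---------------------------------------------------------------------------
# DNN / CNN baselines

class _BatchNorm:
    def __init__(self, d: int, momentum: float = 0.9) -> None:
        self.gamma = np.ones(d)
        self.beta = np.zeros(d)
        self.run_mean = np.zeros(d)
        self.run_var = np.ones(d)
        self.momentum = momentum
        self.eps = 1e-5
        self.cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mu
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mu, var = self.run_mean, self.run_var
        xhat = (x - mu) / np.sqrt(var + self.eps)
        if train:
            self.cache = (xhat, var)
        return self.gamma * xhat + self.beta

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, var = self.cache
        m = dout.shape[0]
        self.dgamma = (dout * xhat).sum(axis=0)
        self.dbeta = dout.sum(axis=0)
        dxhat = dout * self.gamma
        inv_std = 1.0 / np.sqrt(var + self.eps)
        return inv_std * (dxhat - dxhat.mean(axis=0)
                          - xhat * (dxhat * xhat).mean(axis=0))


class DNNBaseline:
    """Fully connected 3840-800-200-20-2 network.

    Three hidden blocks of affine -> batch-norm -> ReLU -> dropout
    (probabilities 0.45, 0.5, 0.25), then a 2-way softmax output.
    """

    WIDTHS = (3840, 800, 200, 20, 2)
    DROPOUT = (0.45, 0.5, 0.25)

    def __init__(self, input_dim: int = 3840, seed: int = 0) -> None:
        if input_dim != self.WIDTHS[0]:
            raise ValueError(f"input_dim must be {self.WIDTHS[0]}")
        rng = np.random.default_rng(seed)
        self.W, self.b, self.bn = [], [], []
        for i in range(len(self.WIDTHS) - 1):
            d_in, d_out = self.WIDTHS[i], self.WIDTHS[i + 1]
            self.W.append(rng.normal(0, np.sqrt(2.0 / d_in), size=(d_out, d_in)))
            self.b.append(np.zeros(d_out))
            if i < len(self.WIDTHS) - 2:
                self.bn.append(_BatchNorm(d_out))
        self.rng = rng

    @property
    def layer_widths(self) -> tuple[int, ...]:
        return self.WIDTHS

    def _forward(self, X: np.ndarray, train: bool):
        cache = []
        h = X
        for i in range(3):
            a = h @ self.W[i].T + self.b[i]
            bn = self.bn[i].forward(a, train)
            relu_mask = bn > 0
            r = bn * relu_mask
            if train:
                keep = 1.0 - self.DROPOUT[i]
                drop_mask = (self.rng.random(r.shape) < keep) / keep
                out = r * drop_mask
            else:
                drop_mask = None
                out = r
            cache.append((h, relu_mask, drop_mask))
            h = out
        logits = h @ self.W[3].T + self.b[3]
        return logits, h, cache

    def fit(self, X: np.ndarray, y: np.ndarray, epochs: int = 30,
            batch_size: int = 128, lr: float = 1e-3) -> "DNNBaseline":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        opt = Adam(lr=lr)
        n = X.shape[0]
        for _ in range(epochs):
            order = self.rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                xb, yb = X[idx], y[idx]
                m = xb.shape[0]
                logits, h_top, cache = self._forward(xb, train=True)
                p = _softmax(logits)
                onehot = np.zeros_like(p)
                onehot[np.arange(m), yb] = 1.0
                dz = (p - onehot) / m
                grads_W = [None] * 4
                grads_b = [None] * 4
                grads_W[3] = dz.T @ h_top
                grads_b[3] = dz.sum(axis=0)
                dh = dz @ self.W[3]
                for i in range(2, -1, -1):
                    h_in, relu_mask, drop_mask = cache[i]
                    if drop_mask is not None:
                        dh = dh * drop_mask
                    dr = dh * relu_mask
                    da = self.bn[i].backward(dr)
                    grads_W[i] = da.T @ h_in
                    grads_b[i] = da.sum(axis=0)
                    dh = da @ self.W[i]
                params = self.W + self.b + [bn.gamma for bn in self.bn] \
                    + [bn.beta for bn in self.bn]
                grads = grads_W + grads_b + [bn.dgamma for bn in self.bn] \
                    + [bn.dbeta for bn in self.bn]
                opt.step(params, grads)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits, _, _ = self._forward(np.asarray(X, dtype=np.float64), train=False)
        return _softmax(logits)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)


class _Conv2D:
    """Valid convolution, kernel 3, stride 2."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 k: int = 3, stride: int = 2) -> None:
        self.k, self.stride = k, stride
        self.W = rng.normal(0, np.sqrt(2.0 / (c_in * k * k)),
                            size=(c_out, c_in, k, k))
        self.b = np.zeros(c_out)
        self.cache = None

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        return ((h - self.k) // self.stride + 1, (w - self.k) // self.stride + 1)

    def forward(self, X: np.ndarray) -> np.ndarray:
        X = np.ascontiguousarray(X)
        n, c, h, w = X.shape
        oh, ow = self.out_shape(h, w)
        s = X.strides
        patches = np.lib.stride_tricks.as_strided(
            X, shape=(n, c, oh, ow, self.k, self.k),
            strides=(s[0], s[1], s[2] * self.stride, s[3] * self.stride, s[2], s[3]))
        out = np.einsum("nchwij,ocij->nohw", patches, self.W) \
            + self.b[None, :, None, None]
        self.cache = (X, patches)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        X, patches = self.cache
        self.dW = np.einsum("nohw,nchwij->ocij", dout, patches)
        self.db = dout.sum(axis=(0, 2, 3))
        dX = np.zeros_like(X)
        n, c, h, w = X.shape
        oh, ow = dout.shape[2], dout.shape[3]
        for i in range(self.k):
            for j in range(self.k):
                # positions hit by kernel element (i, j)
                contrib = np.einsum("nohw,oc->nchw", dout, self.W[:, :, i, j])
                dX[:, :, i:i + oh * self.stride:self.stride,
                   j:j + ow * self.stride:self.stride] += contrib
        return dX


class CNNBaseline:
    """Four convolutional modules (kernel 3, stride 2, no padding), batch
    norm and ReLU after each, max-pooling after the last two, then a
    fully connected softmax head with 0.85 dropout.

    Each 3840-sample instance is reshaped to a 60 x 64 single-channel image.
    """

    IMAGE_SHAPE = (60, 64)
    CHANNELS = (1, 8, 16, 32, 32)

    def __init__(self, input_dim: int = 3840, seed: int = 0) -> None:
        if input_dim != self.IMAGE_SHAPE[0] * self.IMAGE_SHAPE[1]:
            raise ValueError(f"input_dim must be {self.IMAGE_SHAPE[0] * self.IMAGE_SHAPE[1]}")
        rng = np.random.default_rng(seed)
        self.convs = [_Conv2D(self.CHANNELS[i], self.CHANNELS[i + 1], rng)
                      for i in range(4)]
        h, w = self.IMAGE_SHAPE
        shapes = []
        for i, conv in enumerate(self.convs):
            h, w = conv.out_shape(h, w)
            if i >= 2:  # max-pool 2x2 when the map is large enough
                h, w = max(h // 2, 1), max(w // 2, 1)
            shapes.append((h, w))
        self.flat_dim = self.CHANNELS[-1] * h * w
        self.bn = [_BatchNorm(self.CHANNELS[i + 1]) for i in range(4)]
        self.W_fc = rng.normal(0, np.sqrt(2.0 / self.flat_dim),
                               size=(2, self.flat_dim))
        self.b_fc = np.zeros(2)
        self.dropout_fc = 0.85
        self.rng = rng

    @staticmethod
    def _pool(x: np.ndarray):
        n, c, h, w = x.shape
        if h < 2 or w < 2:
            return x, None
        h2, w2 = h // 2, w // 2
        xc = x[:, :, :h2 * 2, :w2 * 2].reshape(n, c, h2, 2, w2, 2)
        out = xc.max(axis=(3, 5))
        mask = (xc == out[:, :, :, None, :, None])
        return out, (mask, x.shape)

    @staticmethod
    def _pool_backward(dout: np.ndarray, cache) -> np.ndarray:
        if cache is None:
            return dout
        mask, shape = cache
        n, c, h, w = shape
        h2, w2 = mask.shape[2], mask.shape[4]
        dx = np.zeros(shape)
        expanded = mask * dout[:, :, :, None, :, None]
        dx[:, :, :h2 * 2, :w2 * 2] = expanded.reshape(n, c, h2 * 2, w2 * 2)
        return dx

    def _bn_forward(self, i: int, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        flat = x.transpose(0, 2, 3, 1).reshape(-1, c)
        out = self.bn[i].forward(flat, train)
        return out.reshape(n, h, w, c).transpose(0, 3, 1, 2)

    def _bn_backward(self, i: int, d: np.ndarray) -> np.ndarray:
        n, c, h, w = d.shape
        flat = d.transpose(0, 2, 3, 1).reshape(-1, c)
        out = self.bn[i].backward(flat)
        return out.reshape(n, h, w, c).transpose(0, 3, 1, 2)

    def _forward(self, X: np.ndarray, train: bool):
        n = X.shape[0]
        h = X.reshape(n, 1, *self.IMAGE_SHAPE)
        cache = []
        for i, conv in enumerate(self.convs):
            a = conv.forward(h)
            bn = self._bn_forward(i, a, train)
            relu_mask = bn > 0
            r = bn * relu_mask
            pooled, pool_cache = (self._pool(r) if i >= 2 else (r, None))
            cache.append((relu_mask, pool_cache))
            h = pooled
        flat = h.reshape(n, -1)
        if train:
            keep = 1.0 - self.dropout_fc
            drop_mask = (self.rng.random(flat.shape) < keep) / keep
            flat_d = flat * drop_mask
        else:
            drop_mask = None
            flat_d = flat
        logits = flat_d @ self.W_fc.T + self.b_fc
        return logits, flat_d, drop_mask, h.shape, cache

    def fit(self, X: np.ndarray, y: np.ndarray, epochs: int = 20,
            batch_size: int = 64, lr: float = 1e-3) -> "CNNBaseline":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        opt = Adam(lr=lr)
        n = X.shape[0]
        for _ in range(epochs):
            order = self.rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                xb, yb = X[idx], y[idx]
                m = xb.shape[0]
                logits, flat_d, drop_mask, top_shape, cache = \
                    self._forward(xb, train=True)
                p = _softmax(logits)
                onehot = np.zeros_like(p)
                onehot[np.arange(m), yb] = 1.0
                dz = (p - onehot) / m
                dW_fc = dz.T @ flat_d
                db_fc = dz.sum(axis=0)
                dflat = dz @ self.W_fc
                if drop_mask is not None:
                    dflat = dflat * drop_mask
                dh = dflat.reshape(top_shape)
                conv_grads = []
                for i in range(3, -1, -1):
                    relu_mask, pool_cache = cache[i]
                    if i >= 2:
                        dh = self._pool_backward(dh, pool_cache)
                    dr = dh * relu_mask
                    da = self._bn_backward(i, dr)
                    dh = self.convs[i].backward(da)
                    conv_grads = [(self.convs[i].dW, self.convs[i].db,
                                   self.bn[i].dgamma, self.bn[i].dbeta)] + conv_grads
                params = [self.W_fc, self.b_fc]
                grads = [dW_fc, db_fc]
                for i, (dW, db, dg, dbeta) in enumerate(conv_grads):
                    params += [self.convs[i].W, self.convs[i].b,
                               self.bn[i].gamma, self.bn[i].beta]
                    grads += [dW, db, dg, dbeta]
                opt.step(params, grads)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits, *_ = self._forward(np.asarray(X, dtype=np.float64), train=False)
        return _softmax(logits)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)


def build_baseline(model: str, input_dim: int = 3840, seed: int = 0):
    """Construct a reference discriminative baseline ('dnn' or 'cnn')."""
    if model == "dnn":
        return DNNBaseline(input_dim=input_dim, seed=seed)
    if model == "cnn":
        return CNNBaseline(input_dim=input_dim, seed=seed)
    raise ValueError(f"unknown baseline {model!r}")
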