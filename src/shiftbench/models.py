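"""The four benchmarked classifier constructions sharing one architecture.

A single residual feed-forward network underlies all four variants:
an input affine layer projecting to the hidden width, then three residual
hidden blocks ``U(l) = g(BN(U(l-1) W + b)) + U(l-1)`` with Mish activations,
batch normalisation and dropout after each block's activation; on top of the
last hidden representation sit a linear mean head producing K logits and a
data-dependent variance head (softplus-positive) defining a heteroscedastic
Gaussian in logit space.

The variants differ only by canonical extensions:

* **pointwise** — dropout and the Gaussian head disabled at inference; a
  single deterministic softmax of the mean logits;
* **MC-dropout** — dropout kept active at inference; each of T stochastic
  passes samples the logit-space Gaussian once and the T softmax draws are
  averaged (Monte Carlo integration);
* **bi-Lipschitz** — MC-dropout plus spectral normalisation of every affine
  weight after each optimisation step, bounding the largest singular value;
  together with the residual connections this keeps the map bi-Lipschitz;
* **deep ensemble** — several independently initialised and trained
  bi-Lipschitz members whose MC draws are pooled.

Everything is NumPy; training uses Adam on the negative log likelihood with
early stopping on validation NLL, and is deterministic given a seed.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np

__all__ = [
    "ModelSpec",
    "PredictiveOutput",
    "TrainingHistory",
    "ResidualClassifier",
    "build_network",
    "predict_pointwise",
    "predict_mcd",
    "predict_ensemble",
    "spectral_normalise",
    "train",
    "architecture_hash",
    "save_network",
    "load_network",
]


@dataclass
class ModelSpec:
    """Shared architecture/hyperparameter bundle for all four model variants.

    `width` defaults to a desk-scale 128 (the full-scale setting is 1024);
    `mc_samples` T is the Monte Carlo draw budget for single Bayesian models
    and `per_member_samples` = T/10 the per-member budget of the
    `ensemble_size`-member deep ensemble, so the pooled ensemble draw count
    roughly matches the single-model budget.
    """

    n_hidden_layers: int = 4
    width: int = 128
    activation: str = "mish"
    batch_norm: bool = True
    dropout_rate: float = 0.1
    spectral_bound: float = 1.0
    mc_samples: int = 250
    ensemble_size: int = 8
    per_member_samples: int = 25
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.spectral_bound <= 0:
            raise ValueError("spectral_bound must be positive")
        if self.n_hidden_layers < 2:
            raise ValueError("need at least an input layer and one residual block")
        if self.activation != "mish":
            raise ValueError("only the mish activation is supported")


@dataclass
class PredictiveOutput:
    """MC-averaged predictive probabilities, optionally with per-draw values."""

    mean_probs: np.ndarray
    n_draws: int
    raw_draws: np.ndarray | None = None


@dataclass
class TrainingHistory:
    train_nll: list = field(default_factory=list)
    val_nll: list = field(default_factory=list)
    val_f1: list = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0


# ---------------------------------------------------------------------------
# numerics


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _mish(x: np.ndarray) -> np.ndarray:
    return x * np.tanh(_softplus(x))


def _mish_grad(x: np.ndarray) -> np.ndarray:
    t = np.tanh(_softplus(x))
    return t + x * (1.0 - t * t) * _sigmoid(x)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def spectral_normalise(weight: np.ndarray, bound: float) -> np.ndarray:
    """Rescale a weight matrix so its largest singular value is at most `bound`.

    Matrices already inside the bound are returned unchanged (same object).
    """
    if bound <= 0:
        raise ValueError("spectral bound must be positive")
    weight = np.asarray(weight, dtype=float)
    if not np.all(np.isfinite(weight)):
        raise ValueError("non-finite entries in weight matrix")
    sigma = np.linalg.svd(weight, compute_uv=False)[0]
    if sigma > bound:
        return weight * (bound / sigma)
    return weight


class _BatchNorm:
    """Plain batch normalisation with running statistics frozen at inference."""

    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(dim)
        self.beta = np.zeros(dim)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if training:
            self._cache = (xhat, inv_std)
        return self.gamma * xhat + self.beta

    def backward(self, dout: np.ndarray):
        xhat, inv_std = self._cache
        m = dout.shape[0]
        dgamma = (dout * xhat).sum(axis=0)
        dbeta = dout.sum(axis=0)
        dxhat = dout * self.gamma
        dx = (inv_std / m) * (
            m * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        )
        return dx, dgamma, dbeta


class ResidualClassifier:
    """Residual feed-forward classifier with mean and variance logit heads."""

    def __init__(self, spec: ModelSpec, n_features: int, n_classes: int):
        if n_features < 2 or n_classes < 2:
            raise ValueError("need n_features >= 2 and n_classes >= 2")
        self.spec = spec
        self.n_features = n_features
        self.n_classes = n_classes
        h = spec.width
        self.n_blocks = spec.n_hidden_layers - 1  # residual blocks after input layer
        rng = np.random.default_rng(spec.seed)

        def he(fan_in, shape):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        self.W = [he(n_features, (n_features, h))]
        self.b = [np.zeros(h)]
        for _ in range(self.n_blocks):
            self.W.append(he(h, (h, h)))
            self.b.append(np.zeros(h))
        self.bn = [_BatchNorm(h) for _ in range(self.n_blocks + 1)]
        self.W_mu = he(h, (h, n_classes))
        self.b_mu = np.zeros(n_classes)
        self.W_sigma = he(h, (h, n_classes))
        self.b_sigma = np.zeros(n_classes)
        self._cache = None

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        params = []
        for i in range(self.n_blocks + 1):
            params += [self.W[i], self.b[i], self.bn[i].gamma, self.bn[i].beta]
        params += [self.W_mu, self.b_mu, self.W_sigma, self.b_sigma]
        return params

    def weight_matrices(self) -> list[np.ndarray]:
        return list(self.W) + [self.W_mu, self.W_sigma]

    def set_weight_matrices(self, mats: list[np.ndarray]) -> None:
        k = len(self.W)
        self.W = [np.asarray(m) for m in mats[:k]]
        self.W_mu = np.asarray(mats[k])
        self.W_sigma = np.asarray(mats[k + 1])

    def n_parameters(self) -> int:
        """Trainable parameter count (affine weights/biases + batch-norm scale/shift)."""
        return sum(p.size for p in self.parameters())

    # -- forward / backward -------------------------------------------------

    def forward(
        self,
        X: np.ndarray,
        training: bool = False,
        dropout_rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Return mean logits f(X) and logit variances s²(X).

        Dropout is applied only when `dropout_rng` is given (training or MC
        inference); batch statistics are used only when `training` is True.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected (n, {self.n_features}) features, got {X.shape}"
            )
        rate = self.spec.dropout_rate
        keep = 1.0 - rate
        cache = {"X": X, "A": [], "H": [], "mask": [], "U": []}
        u = None
        for i in range(self.n_blocks + 1):
            inp = X if i == 0 else u
            a = inp @ self.W[i] + self.b[i]
            bnorm = self.bn[i].forward(a, training) if self.spec.batch_norm else a
            hidden = _mish(bnorm)
            if dropout_rng is not None and rate > 0.0:
                mask = (dropout_rng.random(hidden.shape) < keep) / keep
            else:
                mask = None
            dropped = hidden * mask if mask is not None else hidden
            u = dropped if i == 0 else dropped + u  # residual skip for blocks
            if training:
                cache["A"].append(bnorm)
                cache["H"].append(hidden)
                cache["mask"].append(mask)
                cache["U"].append(u)
        f = u @ self.W_mu + self.b_mu
        s_raw = u @ self.W_sigma + self.b_sigma
        if training:
            cache["u_last"] = u
            cache["s_raw"] = s_raw
            self._cache = cache
        return f, _softplus(s_raw)

    def backward(self, df: np.ndarray, ds_raw: np.ndarray | None):
        """Gradients of the loss w.r.t. every parameter, in parameters() order."""
        cache = self._cache
        u_last = cache["u_last"]
        gW_mu = u_last.T @ df
        gb_mu = df.sum(axis=0)
        du = df @ self.W_mu.T
        if ds_raw is not None:
            gW_sigma = u_last.T @ ds_raw
            gb_sigma = ds_raw.sum(axis=0)
            du = du + ds_raw @ self.W_sigma.T
        else:
            gW_sigma = np.zeros_like(self.W_sigma)
            gb_sigma = np.zeros_like(self.b_sigma)
        grads_blocks = [None] * (self.n_blocks + 1)
        for i in range(self.n_blocks, -1, -1):
            mask = cache["mask"][i]
            d_dropped = du
            d_hidden = d_dropped * mask if mask is not None else d_dropped
            d_bn = d_hidden * _mish_grad(cache["A"][i])
            if self.spec.batch_norm:
                d_a, dgamma, dbeta = self.bn[i].backward(d_bn)
            else:
                d_a, dgamma, dbeta = d_bn, np.zeros_like(self.bn[i].gamma), np.zeros_like(self.bn[i].beta)
            inp = cache["X"] if i == 0 else cache["U"][i - 1]
            gW = inp.T @ d_a
            gb = d_a.sum(axis=0)
            grads_blocks[i] = [gW, gb, dgamma, dbeta]
            if i > 0:
                du = d_a @ self.W[i].T + du  # residual skip passes gradient through
        grads: list[np.ndarray] = []
        for g in grads_blocks:
            grads += g
        grads += [gW_mu, gb_mu, gW_sigma, gb_sigma]
        return grads


def build_network(spec: ModelSpec, n_features: int, n_classes: int) -> ResidualClassifier:
    """Construct the shared architecture for a given input/output size."""
    return ResidualClassifier(spec, n_features, n_classes)


def architecture_hash(network: ResidualClassifier) -> str:
    """Hash of the structural architecture: layer shapes, activation, norm.

    Identical across the four variants built from one ModelSpec — the
    controlled-benchmark contract.
    """
    desc = {
        "layers": [list(w.shape) for w in network.weight_matrices()],
        "activation": network.spec.activation,
        "batch_norm": network.spec.batch_norm,
        "n_hidden_layers": network.spec.n_hidden_layers,
        "width": network.spec.width,
    }
    return hashlib.sha256(json.dumps(desc, sort_keys=True).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# training


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _one_hot(y_idx: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((y_idx.size, k))
    out[np.arange(y_idx.size), y_idx] = 1.0
    return out


def _nll(probs: np.ndarray, y_idx: np.ndarray) -> float:
    p = np.clip(probs[np.arange(y_idx.size), y_idx], 1e-12, None)
    return float(-np.mean(np.log(p)))


def _snapshot(network: ResidualClassifier) -> list[np.ndarray]:
    state = [p.copy() for p in network.parameters()]
    state += [np.concatenate([bn.running_mean, bn.running_var]) for bn in network.bn]
    return state


def _restore(network: ResidualClassifier, state: list[np.ndarray]) -> None:
    params = network.parameters()
    for p, s in zip(params, state[: len(params)]):
        p[...] = s
    for bn, s in zip(network.bn, state[len(params):]):
        d = s.size // 2
        bn.running_mean = s[:d].copy()
        bn.running_var = s[d:].copy()


def train(
    network: ResidualClassifier,
    X_train: np.ndarray,
    y_train_idx: np.ndarray,
    X_val: np.ndarray,
    y_val_idx: np.ndarray,
    heteroscedastic: bool = False,
    spectral_bound: float | None = None,
    seed: int | None = None,
    target_val_nll: float | None = None,
) -> TrainingHistory:
    """Minimise the negative log likelihood with Adam and early stopping.

    `heteroscedastic` trains via one reparameterised Gaussian logit sample per
    forward pass (mean head + softplus variance head); otherwise plain
    cross-entropy on the mean logits. `spectral_bound` (bi-Lipschitz variant)
    rescales every affine weight after each optimisation step so its largest
    singular value stays within the bound.

    Early stopping: halt after `spec.patience` epochs without validation NLL
    improvement and restore the best weights; if `target_val_nll` is given,
    additionally stop at the first epoch reaching it (so every variant can be
    stopped at a shared validation loss).
    """
    spec = network.spec
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    k = network.n_classes
    n = X_train.shape[0]
    opt = _Adam(network.parameters(), spec.learning_rate)
    history = TrainingHistory()
    best_nll = np.inf
    best_state = _snapshot(network)
    since_best = 0
    if spectral_bound is not None:
        network.set_weight_matrices(
            [spectral_normalise(w, spectral_bound) for w in network.weight_matrices()]
        )
        opt.params = network.parameters()
    for epoch in range(spec.max_epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            if idx.size < 2:
                continue  # batch norm needs at least two samples
            xb, yb = X_train[idx], y_train_idx[idx]
            yb_hot = _one_hot(yb, k)
            f, s = network.forward(xb, training=True, dropout_rng=rng)
            if heteroscedastic:
                eps = rng.standard_normal(f.shape)
                logits = f + s * eps
                probs = _softmax(logits)
                dlogits = (probs - yb_hot) / idx.size
                df = dlogits
                ds_raw = dlogits * eps * _sigmoid(network._cache["s_raw"])
            else:
                probs = _softmax(f)
                df = (probs - yb_hot) / idx.size
                ds_raw = None
            loss = _nll(probs, yb)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: diverged"
                )
            grads = network.backward(df, ds_raw)
            opt.step(grads)
            if spectral_bound is not None:
                mats = network.weight_matrices()
                normed = [spectral_normalise(w, spectral_bound) for w in mats]
                network.set_weight_matrices(normed)
                # keep optimiser state attached to the (possibly new) arrays
                opt.params = network.parameters()
                # batch norm can undo the weight constraint through its scale:
                # clip gamma so the effective per-feature scale
                # |gamma| / sqrt(var + eps) also respects the bound
                for bn in network.bn:
                    cap = spectral_bound * np.sqrt(bn.running_var + bn.eps)
                    np.clip(bn.gamma, -cap, cap, out=bn.gamma)
            epoch_losses.append(loss)
        f_val, _ = network.forward(X_val, training=False)
        val_probs = _softmax(f_val)
        val_nll = _nll(val_probs, y_val_idx)
        val_f1 = float(np.mean(val_probs.argmax(axis=1) == y_val_idx))
        history.train_nll.append(float(np.mean(epoch_losses)))
        history.val_nll.append(val_nll)
        history.val_f1.append(val_f1)
        if val_nll < best_nll - 1e-12:
            best_nll = val_nll
            best_state = _snapshot(network)
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
        history.stopped_epoch = epoch
        if target_val_nll is not None and val_nll <= target_val_nll:
            break
        if since_best >= spec.patience:
            break
    _restore(network, best_state)
    return history


# ---------------------------------------------------------------------------
# prediction


def predict_pointwise(network: ResidualClassifier, X: np.ndarray) -> PredictiveOutput:
    """Single deterministic pass: softmax of the mean logits, no dropout."""
    f, _ = network.forward(X, training=False)
    probs = _softmax(f)
    return PredictiveOutput(mean_probs=probs, n_draws=1, raw_draws=probs[None])


def predict_mcd(
    network: ResidualClassifier,
    X: np.ndarray,
    n_draws: int | None = None,
    seed: int | None = None,
    return_draws: bool = False,
) -> PredictiveOutput:
    """Monte Carlo dropout prediction with a heteroscedastic Gaussian head.

    Each draw runs a dropout-masked pass giving mean logits f_t and variances
    s_t², samples the Gaussian once (u_t ~ N(f_t, diag s_t²)), applies the
    softmax, and the draws are averaged.
    """
    t_draws = network.spec.mc_samples if n_draws is None else n_draws
    if t_draws < 1:
        raise ValueError("need at least one MC draw")
    rng = np.random.default_rng(network.spec.seed if seed is None else seed)
    total = np.zeros((X.shape[0], network.n_classes))
    draws = [] if return_draws else None
    for _ in range(t_draws):
        f, s = network.forward(X, training=False, dropout_rng=rng)
        u = f + s * rng.standard_normal(f.shape)
        p = _softmax(u)
        total += p
        if draws is not None:
            draws.append(p)
    mean = total / t_draws
    return PredictiveOutput(
        mean_probs=mean,
        n_draws=t_draws,
        raw_draws=np.stack(draws) if draws is not None else None,
    )


def predict_ensemble(
    members: list[ResidualClassifier],
    X: np.ndarray,
    per_member_draws: int | None = None,
    seed: int | None = None,
) -> PredictiveOutput:
    """Pool MC draws across independently trained members and average.

    With the default spec (8 members × 25 draws) the pooled draw count is 200,
    roughly matching the single-model Monte Carlo budget.
    """
    if len(members) < 2:
        raise ValueError("an ensemble needs at least two members")
    k = members[0].n_classes
    if any(m.n_classes != k for m in members):
        raise ValueError("ensemble members disagree on the class count")
    t_pm = members[0].spec.per_member_samples if per_member_draws is None else per_member_draws
    if t_pm < 1:
        raise ValueError("need at least one draw per member")
    base = members[0].spec.seed if seed is None else seed
    total = np.zeros((X.shape[0], k))
    for j, member in enumerate(members):
        out = predict_mcd(member, X, n_draws=t_pm, seed=base + 7919 * (j + 1))
        total += out.mean_probs * t_pm
    n_total = t_pm * len(members)
    return PredictiveOutput(mean_probs=total / n_total, n_draws=n_total)


# ---------------------------------------------------------------------------
# checkpoints


def save_network(network: ResidualClassifier, path, classes: list[str] | None = None) -> None:
    """Single-file checkpoint embedding the ModelSpec and class order."""
    arrays = {}
    for i, (w, b) in enumerate(zip(network.W, network.b)):
        arrays[f"W{i}"] = w
        arrays[f"b{i}"] = b
    for i, bn in enumerate(network.bn):
        arrays[f"bn{i}_gamma"] = bn.gamma
        arrays[f"bn{i}_beta"] = bn.beta
        arrays[f"bn{i}_mean"] = bn.running_mean
        arrays[f"bn{i}_var"] = bn.running_var
    arrays["W_mu"] = network.W_mu
    arrays["b_mu"] = network.b_mu
    arrays["W_sigma"] = network.W_sigma
    arrays["b_sigma"] = network.b_sigma
    meta = {
        "spec": asdict(network.spec),
        "n_features": network.n_features,
        "n_classes": network.n_classes,
        "classes": classes,
    }
    buf = io.BytesIO()
    np.savez(buf, **arrays)
    with open(path, "wb") as fh:
        header = json.dumps(meta).encode()
        fh.write(len(header).to_bytes(8, "little"))
        fh.write(header)
        fh.write(buf.getvalue())


def load_network(path) -> tuple[ResidualClassifier, list[str] | None]:
    with open(path, "rb") as fh:
        hlen = int.from_bytes(fh.read(8), "little")
        meta = json.loads(fh.read(hlen).decode())
        data = np.load(io.BytesIO(fh.read()))
    spec = ModelSpec(**meta["spec"])
    net = ResidualClassifier(spec, meta["n_features"], meta["n_classes"])
    net.W = [data[f"W{i}"] for i in range(net.n_blocks + 1)]
    net.b = [data[f"b{i}"] for i in range(net.n_blocks + 1)]
    for i, bn in enumerate(net.bn):
        bn.gamma = data[f"bn{i}_gamma"]
        bn.beta = data[f"bn{i}_beta"]
        bn.running_mean = data[f"bn{i}_mean"]
        bn.running_var = data[f"bn{i}_var"]
    net.W_mu = data["W_mu"]
    net.b_mu = data["b_mu"]
    net.W_sigma = data["W_sigma"]
    net.b_sigma = data["b_sigma"]
    return net, meta.get("classes")
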