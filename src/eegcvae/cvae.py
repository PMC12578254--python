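"""Label-conditioned variational autoencoder on per-window feature vectors.

The model follows a *dual concatenation* protocol: the binary health label y
is appended to the feature vector at the encoder input (x' = [x; y], width
89) and again to the latent sample at the decoder input (z' = [z; y], width
33).  The encoder is an MLP 89 -> 64 -> 32 with two linear 32-unit heads for
mu and log sigma^2; the decoder is 33 -> 32 -> 64 -> 88 with a linear output;
a linear classifier head on z emits 2-class logits.  With the default sizes
the model has exactly 18,938 trainable parameters.

Training minimizes

    J = MSE_per_feature(x, xhat) + lambda_div * beta * D(q(z|x,y) || N(0,I))
        + lambda_clf * CE(y, p(y|z)),

where D is either the closed-form diagonal-Gaussian KL or an unbiased
Gaussian-kernel MMD estimator with median-heuristic bandwidth.  Optimization
is Adam (1e-3, betas 0.9/0.999), batch 128, 50 epochs, no annealing, no
weight decay, all in plain numpy with hand-written gradients (the model is a
few-thousand-parameter MLP; the gradients are verified by finite differences
in the test suite).

The classifier consumes the sampled z during training (so its gradient flows
through the reparameterization) and the posterior mean mu at evaluation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .preprocess import ClassWeights


@dataclass(frozen=True)
class CVAEConfig:
    d_feat: int = 88
    d_z: int = 32
    encoder_widths: tuple[int, int] = (64, 32)
    decoder_widths: tuple[int, int] = (32, 64)
    beta: float = 4.0
    lambda_div: float = 2.5e-4
    lambda_clf: float = 1.0
    divergence: str = "kl"  # "kl" or "mmd"
    mmd_prior_samples: int | None = None  # default: match the batch size
    mmd_multi_kernel: bool = False
    mmd_kernel_scales: tuple[float, ...] = (0.5, 1.0, 2.0)
    learning_rate: float = 1e-3
    adam_betas: tuple[float, float] = (0.9, 0.999)
    batch_size: int = 128
    epochs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.divergence not in ("kl", "mmd"):
            raise ValueError("divergence must be 'kl' or 'mmd'")


@dataclass
class LatentStats:
    """Diagonal-Gaussian posterior parameters: mu and s = log sigma^2."""

    mu: np.ndarray
    log_var: np.ndarray


_LAYERS = ("enc1", "enc2", "mu", "log_var", "dec1", "dec2", "dec3", "clf")


def _layer_dims(cfg: CVAEConfig) -> dict[str, tuple[int, int]]:
    e1, e2 = cfg.encoder_widths
    d1, d2 = cfg.decoder_widths
    return {
        "enc1": (cfg.d_feat + 1, e1),
        "enc2": (e1, e2),
        "mu": (e2, cfg.d_z),
        "log_var": (e2, cfg.d_z),
        "dec1": (cfg.d_z + 1, d1),
        "dec2": (d1, d2),
        "dec3": (d2, cfg.d_feat),
        "clf": (cfg.d_z, 2),
    }


@dataclass
class CVAEModel:
    """Named parameter arrays; weights are (fan_in, fan_out), biases (fan_out,)."""

    config: CVAEConfig
    params: dict[str, np.ndarray] = field(default_factory=dict)


def init_model(cfg: CVAEConfig, rng: np.random.Generator | None = None) -> CVAEModel:
    """Fan-in-scaled uniform initialization, U(-1/sqrt(fan_in), 1/sqrt(fan_in)),
    for both weights and biases; fully determined by the config seed."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    params: dict[str, np.ndarray] = {}
    for name, (fi, fo) in _layer_dims(cfg).items():
        bound = 1.0 / np.sqrt(fi)
        params[f"{name}.W"] = rng.uniform(-bound, bound, size=(fi, fo))
        params[f"{name}.b"] = rng.uniform(-bound, bound, size=fo)
    return CVAEModel(config=cfg, params=params)


def count_parameters(model: CVAEModel) -> int:
    return int(sum(p.size for p in model.params.values()))


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary in {0, 1}")
    return y.astype(np.float64)


def _relu(a: np.ndarray) -> np.ndarray:
    return np.maximum(a, 0.0)


def encode(model: CVAEModel, x: np.ndarray, y: np.ndarray) -> LatentStats:
    """Posterior parameters for a batch; x is (B, d_feat), y binary (B,)."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    yf = _check_labels(np.atleast_1d(y))
    p = model.params
    xp = np.concatenate([x, yf[:, None]], axis=1)
    h1 = _relu(xp @ p["enc1.W"] + p["enc1.b"])
    h2 = _relu(h1 @ p["enc2.W"] + p["enc2.b"])
    return LatentStats(mu=h2 @ p["mu.W"] + p["mu.b"],
                       log_var=h2 @ p["log_var.W"] + p["log_var.b"])


def reparameterize(ls: LatentStats, eps: np.ndarray) -> np.ndarray:
    """z = mu + sigma * eps with sigma = exp(log_var / 2)."""
    return ls.mu + np.exp(0.5 * ls.log_var) * eps


def decode(model: CVAEModel, z: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Reconstruction xhat from [z; y]; linear output layer."""
    z = np.atleast_2d(np.asarray(z, dtype=np.float64))
    yf = _check_labels(np.atleast_1d(y))
    p = model.params
    zp = np.concatenate([z, yf[:, None]], axis=1)
    g1 = _relu(zp @ p["dec1.W"] + p["dec1.b"])
    g2 = _relu(g1 @ p["dec2.W"] + p["dec2.b"])
    return g2 @ p["dec3.W"] + p["dec3.b"]


def classify_logits(model: CVAEModel, z: np.ndarray) -> np.ndarray:
    z = np.atleast_2d(np.asarray(z, dtype=np.float64))
    return z @ model.params["clf.W"] + model.params["clf.b"]


def _softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def classify(model: CVAEModel, z: np.ndarray) -> np.ndarray:
    """Class probabilities p(y|z) = softmax(W z + b)."""
    return _softmax(classify_logits(model, z))


def kl_divergence(ls: LatentStats) -> float:
    """Closed-form KL(N(mu, diag sigma^2) || N(0, I)), batch mean:
    (1/2) sum_i (mu_i^2 + sigma_i^2 - log sigma_i^2 - 1)."""
    mu, lv = np.atleast_2d(ls.mu), np.atleast_2d(ls.log_var)
    per_sample = 0.5 * (mu ** 2 + np.exp(lv) - lv - 1.0).sum(axis=1)
    return float(per_sample.mean())


def median_heuristic(z: np.ndarray, z_tilde: np.ndarray) -> float:
    """Kernel bandwidth sigma^2 = median of squared pairwise distances over
    the pooled sample."""
    pool = np.concatenate([np.atleast_2d(z), np.atleast_2d(z_tilde)], axis=0)
    sq = ((pool[:, None, :] - pool[None, :, :]) ** 2).sum(-1)
    iu = np.triu_indices(len(pool), k=1)
    med = float(np.median(sq[iu]))
    return med if med > 0 else 1.0


def _kernel_sums(z: np.ndarray, z_tilde: np.ndarray, sigma_sq: float):
    kzz = np.exp(-((z[:, None, :] - z[None, :, :]) ** 2).sum(-1) / (2 * sigma_sq))
    kpp = np.exp(-((z_tilde[:, None, :] - z_tilde[None, :, :]) ** 2).sum(-1) / (2 * sigma_sq))
    kzp = np.exp(-((z[:, None, :] - z_tilde[None, :, :]) ** 2).sum(-1) / (2 * sigma_sq))
    return kzz, kpp, kzp


def mmd_unbiased(z: np.ndarray, z_tilde: np.ndarray,
                 bandwidth: float | None = None) -> float:
    """Unbiased squared maximum mean discrepancy with a Gaussian kernel
    k(u, v) = exp(-||u - v||^2 / (2 sigma^2)).

    Diagonal terms are excluded, so the estimator can be negative.  When
    ``bandwidth`` (sigma^2) is not supplied it is set by the median heuristic
    on the pooled sample.  Requires n, m >= 2.
    """
    z = np.atleast_2d(np.asarray(z, dtype=np.float64))
    z_tilde = np.atleast_2d(np.asarray(z_tilde, dtype=np.float64))
    n, m = len(z), len(z_tilde)
    if n < 2 or m < 2:
        raise ValueError("mmd_unbiased requires at least 2 samples per set")
    if bandwidth is None:
        bandwidth = median_heuristic(z, z_tilde)
    kzz, kpp, kzp = _kernel_sums(z, z_tilde, bandwidth)
    term1 = (kzz.sum() - np.trace(kzz)) / (n * (n - 1))
    term2 = (kpp.sum() - np.trace(kpp)) / (m * (m - 1))
    term3 = 2.0 * kzp.sum() / (n * m)
    return float(term1 + term2 - term3)


def _mmd_value_and_grad(z: np.ndarray, z_tilde: np.ndarray,
                        sigma_sq: float) -> tuple[float, np.ndarray]:
    """MMD^2 and its gradient w.r.t. z (bandwidth treated as a constant)."""
    n, m = len(z), len(z_tilde)
    kzz, kpp, kzp = _kernel_sums(z, z_tilde, sigma_sq)
    np.fill_diagonal(kzz, 0.0)
    value = (kzz.sum() / (n * (n - 1)) + (kpp.sum() - np.trace(kpp)) / (m * (m - 1))
             - 2.0 * kzp.sum() / (n * m))
    # z_i appears in 2(n-1) ordered pairs of the first sum; the factor 2
    # relative to a single row-sum is already included below
    diff_zz = z[:, None, :] - z[None, :, :]
    grad = (-2.0 / (n * (n - 1) * sigma_sq)) * (kzz[:, :, None] * diff_zz).sum(axis=1)
    diff_zp = z[:, None, :] - z_tilde[None, :, :]
    grad += (2.0 / (n * m * sigma_sq)) * (kzp[:, :, None] * diff_zp).sum(axis=1)
    return float(value), grad


def weighted_cross_entropy(logits: np.ndarray, y: np.ndarray,
                           weights: ClassWeights | None = None
                           ) -> tuple[float, np.ndarray]:
    """Class-weighted CE, normalized by the summed weights (so unit weights
    reduce to the plain mean); returns (loss, d loss / d logits)."""
    y = np.asarray(y, dtype=int)
    w = (weights.as_array() if weights is not None else np.ones(2))[y]
    logp = logits - logits.max(axis=1, keepdims=True)
    logp = logp - np.log(np.exp(logp).sum(axis=1, keepdims=True))
    nll = -logp[np.arange(len(y)), y]
    wsum = w.sum()
    loss = float((w * nll).sum() / wsum)
    probs = np.exp(logp)
    onehot = np.eye(2)[y]
    dlogits = (probs - onehot) * (w / wsum)[:, None]
    return loss, dlogits


@dataclass
class ObjectiveValue:
    total: float
    recon: float
    div: float
    clf: float


def objective(model: CVAEModel, x: np.ndarray, y: np.ndarray,
              eps: np.ndarray | None = None,
              weights: ClassWeights | None = None,
              rng: np.random.Generator | None = None) -> ObjectiveValue:
    """Evaluate the training objective on a batch (no gradients).

    recon is the mean squared error per feature dimension; the divergence is
    weighted by lambda_div * beta (1e-3 at the defaults); the classifier term
    by lambda_clf.
    """
    cfg = model.config
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    y = np.atleast_1d(y)
    ls = encode(model, x, y)
    if eps is None:
        eps = (rng or np.random.default_rng(cfg.seed)).standard_normal(ls.mu.shape)
    z = reparameterize(ls, eps)
    xhat = decode(model, z, y)
    recon = float(((x - xhat) ** 2).mean(axis=1).mean())
    if cfg.divergence == "kl":
        div = kl_divergence(ls)
    else:
        m = cfg.mmd_prior_samples or len(z)
        z_prior = (rng or np.random.default_rng(cfg.seed + 1)).standard_normal((m, cfg.d_z))
        div = mmd_unbiased(z, z_prior)
    clf, _ = weighted_cross_entropy(classify_logits(model, z), y, weights)
    total = recon + cfg.lambda_div * cfg.beta * div + cfg.lambda_clf * clf
    return ObjectiveValue(total=total, recon=recon, div=div, clf=clf)


def _forward_backward(model: CVAEModel, x: np.ndarray, y: np.ndarray,
                      eps: np.ndarray, weights: ClassWeights | None,
                      z_prior: np.ndarray | None
                      ) -> tuple[ObjectiveValue, dict[str, np.ndarray]]:
    """One full forward pass plus hand-written backward pass.

    Returns the loss components and the gradient of the total objective with
    respect to every parameter array.
    """
    cfg = model.config
    p = model.params
    B = len(x)
    yf = y.astype(np.float64)
    lam_div = cfg.lambda_div * cfg.beta

    # ---- forward ----
    xp = np.concatenate([x, yf[:, None]], axis=1)
    a1 = xp @ p["enc1.W"] + p["enc1.b"]; h1 = _relu(a1)
    a2 = h1 @ p["enc2.W"] + p["enc2.b"]; h2 = _relu(a2)
    mu = h2 @ p["mu.W"] + p["mu.b"]
    lv = h2 @ p["log_var.W"] + p["log_var.b"]
    sigma = np.exp(0.5 * lv)
    z = mu + sigma * eps
    zp = np.concatenate([z, yf[:, None]], axis=1)
    c1 = zp @ p["dec1.W"] + p["dec1.b"]; g1 = _relu(c1)
    c2 = g1 @ p["dec2.W"] + p["dec2.b"]; g2 = _relu(c2)
    xhat = g2 @ p["dec3.W"] + p["dec3.b"]
    logits = z @ p["clf.W"] + p["clf.b"]

    recon = float(((x - xhat) ** 2).mean(axis=1).mean())
    clf_loss, dlogits = weighted_cross_entropy(logits, y.astype(int), weights)
    if cfg.divergence == "kl":
        div = 0.5 * float((mu ** 2 + np.exp(lv) - lv - 1.0).sum(axis=1).mean())
        dmu_div = lam_div * mu / B
        dlv_div = lam_div * 0.5 * (np.exp(lv) - 1.0) / B
        dz_div = 0.0
    else:
        sigma_sq = median_heuristic(z, z_prior)
        div, dz_mmd = _mmd_value_and_grad(z, z_prior, sigma_sq)
        dmu_div = 0.0
        dlv_div = 0.0
        dz_div = lam_div * dz_mmd
    total = recon + lam_div * div + cfg.lambda_clf * clf_loss

    # ---- backward ----
    grads: dict[str, np.ndarray] = {}
    dxhat = 2.0 * (xhat - x) / (B * cfg.d_feat)
    grads["dec3.W"] = g2.T @ dxhat
    grads["dec3.b"] = dxhat.sum(axis=0)
    dg2 = dxhat @ p["dec3.W"].T * (c2 > 0)
    grads["dec2.W"] = g1.T @ dg2
    grads["dec2.b"] = dg2.sum(axis=0)
    dg1 = dg2 @ p["dec2.W"].T * (c1 > 0)
    grads["dec1.W"] = zp.T @ dg1
    grads["dec1.b"] = dg1.sum(axis=0)
    dz = (dg1 @ p["dec1.W"].T)[:, : cfg.d_z]

    dlogits = cfg.lambda_clf * dlogits
    grads["clf.W"] = z.T @ dlogits
    grads["clf.b"] = dlogits.sum(axis=0)
    dz = dz + dlogits @ p["clf.W"].T + dz_div

    dmu = dz + dmu_div
    dlv = dz * eps * 0.5 * sigma + dlv_div
    grads["mu.W"] = h2.T @ dmu
    grads["mu.b"] = dmu.sum(axis=0)
    grads["log_var.W"] = h2.T @ dlv
    grads["log_var.b"] = dlv.sum(axis=0)
    dh2 = (dmu @ p["mu.W"].T + dlv @ p["log_var.W"].T) * (a2 > 0)
    grads["enc2.W"] = h1.T @ dh2
    grads["enc2.b"] = dh2.sum(axis=0)
    dh1 = dh2 @ p["enc2.W"].T * (a1 > 0)
    grads["enc1.W"] = xp.T @ dh1
    grads["enc1.b"] = dh1.sum(axis=0)

    return ObjectiveValue(total=total, recon=recon, div=float(div), clf=clf_loss), grads


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float, betas: tuple[float, float]):
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def evaluate_accuracy(model: CVAEModel, x: np.ndarray, y: np.ndarray) -> float:
    """Classification accuracy of :func:`predict` against true labels."""
    preds = predict(model, x)
    return float((preds == np.asarray(y)).mean())


def _encode_mu_raw(model: CVAEModel, x: np.ndarray, y_value: float) -> np.ndarray:
    """Posterior mean with an arbitrary (possibly non-binary) label input."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    p = model.params
    xp = np.concatenate([x, np.full((len(x), 1), y_value)], axis=1)
    h1 = _relu(xp @ p["enc1.W"] + p["enc1.b"])
    h2 = _relu(h1 @ p["enc2.W"] + p["enc2.b"])
    return h2 @ p["mu.W"] + p["mu.b"]


def predict(model: CVAEModel, x: np.ndarray) -> np.ndarray:
    """Predicted labels from the classifier head applied to the latent mean.

    The label is unknown at prediction time, so the encoder's conditioning
    input is fixed to the neutral midpoint 0.5 for every window: the
    prediction then derives from the feature content alone and cannot leak
    the true label through the conditioning channel.  The posterior mean
    (rather than a sample) removes reparameterization noise at test time.
    """
    mu = _encode_mu_raw(model, x, 0.5)
    return np.argmax(classify(model, mu), axis=1)


def train(x: np.ndarray, y: np.ndarray, cfg: CVAEConfig,
          weights: ClassWeights | None = None,
          x_val: np.ndarray | None = None, y_val: np.ndarray | None = None
          ) -> tuple[CVAEModel, pd.DataFrame]:
    """Train the CVAE; fully deterministic given the config seed.

    Data order, reparameterization draws, prior draws (for MMD) and the
    initialization all derive from one seeded generator.  Returns the trained
    model and per-epoch traces (mean/std of the batch losses, training
    accuracy on mu, and held-out accuracy when a validation set is given).
    A non-finite loss aborts with diagnostics.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    if x.ndim != 2 or x.shape[1] != cfg.d_feat:
        raise ValueError(f"expected (n, {cfg.d_feat}) features, got {x.shape}")
    rng = np.random.default_rng(cfg.seed)
    model = init_model(cfg, rng)
    opt = _Adam(model.params, cfg.learning_rate, cfg.adam_betas)
    n = len(x)
    rows = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            eps = rng.standard_normal((len(idx), cfg.d_z))
            z_prior = None
            if cfg.divergence == "mmd":
                m = cfg.mmd_prior_samples or len(idx)
                z_prior = rng.standard_normal((m, cfg.d_z))
            val, grads = _forward_backward(model, xb, yb, eps, weights, z_prior)
            if not np.isfinite(val.total):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: recon={val.recon} "
                    f"div={val.div} clf={val.clf}")
            opt.step(model.params, grads)
            batch_losses.append((val.total, val.recon, val.div, val.clf))
        arr = np.array(batch_losses)
        row = {
            "epoch": epoch,
            "total": arr[:, 0].mean(), "recon": arr[:, 1].mean(),
            "div": arr[:, 2].mean(), "clf": arr[:, 3].mean(),
            "clf_std_batch": arr[:, 3].std(),
            "total_std_batch": arr[:, 0].std(),
            "train_acc": evaluate_accuracy(model, x, y),
        }
        if x_val is not None:
            row["val_acc"] = evaluate_accuracy(model, x_val, y_val)
        rows.append(row)
    return model, pd.DataFrame(rows)


def generate(model: CVAEModel, y_star: int, n: int,
             seed: int | None = None,
             rng: np.random.Generator | None = None) -> np.ndarray:
    """Label-controlled synthesis: z ~ N(0, I), xhat = decoder([z; y*])."""
    if y_star not in (0, 1):
        raise ValueError("y_star must be 0 or 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, model.config.d_z))
    return decode(model, z, np.full(n, y_star))


def save_model(model: CVAEModel, path) -> None:
    """Checkpoint: named parameter arrays plus a JSON config echo."""
    np.savez(path, __config__=json.dumps(asdict(model.config)), **model.params)


def load_model(path) -> CVAEModel:
    with np.load(path, allow_pickle=False) as data:
        raw = json.loads(str(data["__config__"]))
        for key in ("encoder_widths", "decoder_widths", "adam_betas",
                    "mmd_kernel_scales"):
            raw[key] = tuple(raw[key])
        cfg = CVAEConfig(**raw)
        params = {k: data[k] for k in data.files if k != "__config__"}
    return CVAEModel(config=cfg, params=params)
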