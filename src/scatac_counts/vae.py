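"""Poisson and Bernoulli variational autoencoders for cell-by-peak counts.

Generative model (Poisson likelihood)::

    z_c   ~ Normal(f_mu(x_c), f_sigma(x_c))
    rho_cp = g_p(z_c, s_c)
    w_cp  = softmax_p(rho_cp + r_p)
    lam_cp = exp(l_c) * w_cp
    x_cp  ~ Poisson(lam_cp)

with s_c the batch covariate (one-hot, decoder only), r_p a learned
region bias, and l_c = log(sum_p x_cp) the per-cell depth offset,
precomputed from the data rather than learned. The softmax ties the model
mass to the observed depth: sum_p lam_cp = exp(l_c) exactly.

Bernoulli likelihood on the binarized matrix y::

    theta_cp = sigmoid(rho_cp + r_p + ltilde_c),
    ltilde_c = logit(mean_p y_cp)

so that theta equals the cell's mean accessibility when rho = r = 0.

Encoder and decoder are two blocks of [affine -> dropout -> layer norm ->
leaky ReLU] with hidden width round(sqrt(P)); the encoder ends in affine
heads for the posterior mean and log standard deviation. The implementation
is pure NumPy with hand-written backpropagation and an Adam optimizer whose
weight-decay term is added to the gradient (L2 coupling); gradients are
validated against finite differences in the test suite.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.sparse as sp
from scipy.special import gammaln

from .core import CountKind, CountMatrix, CellTable

logger = logging.getLogger(__name__)

__all__ = [
    "VAEConfig", "VAEModel", "TrainingLog", "train", "encode",
    "decode_poisson", "decode_binary", "elbo_loss", "get_latent",
    "predict_theta", "poisson_rate_to_bernoulli", "normalized_accessibility",
    "sweep_latent_dims", "save_model", "load_model",
]

_LEAK = 0.01
_LN_EPS = 1e-5


@dataclass
class VAEConfig:
    """Hyperparameters; defaults follow standard practice for this model.

    ``n_hidden=None`` resolves to round(sqrt(P)) at build time. The KL weight
    is fixed at 1 with no annealing (configurable). ``f_sigma`` is defined to
    output the posterior standard deviation.
    """

    n_latent: int = 10
    n_hidden: int | None = None
    dropout_rate: float = 0.1
    learning_rate: float = 1e-4
    weight_decay: float = 1e-3
    minibatch_size: int = 128
    max_epochs: int = 500
    patience: int = 20
    min_delta: float = 0.0
    seed: int = 0
    likelihood: str = "poisson"
    kl_weight: float = 1.0
    batch_to_encoder: bool = False

    def __post_init__(self) -> None:
        if self.n_latent < 1:
            raise ValueError("n_latent must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.likelihood not in ("poisson", "bernoulli"):
            raise ValueError("likelihood must be 'poisson' or 'bernoulli'")


@dataclass
class TrainingLog:
    train_loss: list[float] = field(default_factory=list)
    val_recon_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    n_dropped_cells: int = 0
    train_idx: np.ndarray | None = None
    val_idx: np.ndarray | None = None
    test_idx: np.ndarray | None = None


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


class VAEModel:
    """Parameter container plus forward/backward machinery."""

    def __init__(self, n_peaks: int, batch_categories: list,
                 config: VAEConfig) -> None:
        self.n_peaks = int(n_peaks)
        self.batch_categories = list(batch_categories)
        self.config = config
        self.n_hidden = (config.n_hidden if config.n_hidden is not None
                         else max(2, int(round(np.sqrt(n_peaks)))))
        self.params = self._init_params()
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- construction -----------------------------------------------------
    @property
    def n_batches(self) -> int:
        return len(self.batch_categories)

    def _init_params(self) -> dict[str, np.ndarray]:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        P, H, D, B = self.n_peaks, self.n_hidden, cfg.n_latent, len(self.batch_categories)
        enc_in = P + (B if cfg.batch_to_encoder else 0)
        dec_in = D + B
        p: dict[str, np.ndarray] = {}

        def block(name: str, fi: int, fo: int) -> None:
            p[f"{name}.W"] = _glorot(rng, fi, fo)
            p[f"{name}.b"] = np.zeros(fo)
            p[f"{name}.gamma"] = np.ones(fo)
            p[f"{name}.beta"] = np.zeros(fo)

        block("enc1", enc_in, H)
        block("enc2", H, H)
        p["mu.W"] = _glorot(rng, H, D)
        p["mu.b"] = np.zeros(D)
        p["logsig.W"] = _glorot(rng, H, D)
        p["logsig.b"] = np.zeros(D)
        block("dec1", dec_in, H)
        block("dec2", H, H)
        p["out.W"] = _glorot(rng, H, P)
        p["out.b"] = np.zeros(P)
        p["r"] = np.zeros(P)
        return p

    def batch_code(self, label) -> int:
        try:
            return self.batch_categories.index(label)
        except ValueError:
            raise KeyError(f"unknown batch label {label!r}") from None

    def one_hot(self, codes: np.ndarray) -> np.ndarray:
        codes = np.asarray(codes, dtype=np.int64)
        if codes.size and (codes.min() < 0 or codes.max() >= self.n_batches):
            raise KeyError(f"batch code out of range 0..{self.n_batches - 1}")
        S = np.zeros((codes.size, self.n_batches))
        S[np.arange(codes.size), codes] = 1.0
        return S

    # -- layers -----------------------------------------------------------
    def _block_fwd(self, x, name, train, rng):
        p = self.params
        a = x @ p[f"{name}.W"] + p[f"{name}.b"]
        rate = self.config.dropout_rate
        if train and rate > 0:
            mask = (rng.random(a.shape) >= rate) / (1.0 - rate)
        else:
            mask = None
        d = a * mask if mask is not None else a
        mu = d.mean(axis=1, keepdims=True)
        var = d.var(axis=1, keepdims=True)
        inv_std = 1.0 / np.sqrt(var + _LN_EPS)
        xhat = (d - mu) * inv_std
        ln = p[f"{name}.gamma"] * xhat + p[f"{name}.beta"]
        h = np.where(ln > 0, ln, _LEAK * ln)
        cache = (x, a, mask, xhat, inv_std, ln)
        return h, cache

    def _block_bwd(self, dh, name, cache, grads):
        p = self.params
        x, a, mask, xhat, inv_std, ln = cache
        dln = dh * np.where(ln > 0, 1.0, _LEAK)
        grads[f"{name}.gamma"] += (dln * xhat).sum(axis=0)
        grads[f"{name}.beta"] += dln.sum(axis=0)
        dxhat = dln * p[f"{name}.gamma"]
        H = xhat.shape[1]
        # layer-norm backward, per row
        dd = (inv_std / H) * (
            H * dxhat
            - dxhat.sum(axis=1, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=1, keepdims=True)
        )
        da = dd * mask if mask is not None else dd
        grads[f"{name}.W"] += x.T @ da
        grads[f"{name}.b"] += da.sum(axis=0)
        return da @ p[f"{name}.W"].T

    # -- encoder / decoder ------------------------------------------------
    def encode_forward(self, X, S=None, train=False, rng=None):
        enc_in = X
        if self.config.batch_to_encoder:
            if S is None:
                raise ValueError("batch one-hot required when batch_to_encoder")
            enc_in = np.concatenate([X, S], axis=1)
        h1, c1 = self._block_fwd(enc_in, "enc1", train, rng)
        h2, c2 = self._block_fwd(h1, "enc2", train, rng)
        p = self.params
        mu = h2 @ p["mu.W"] + p["mu.b"]
        logsig = np.clip(h2 @ p["logsig.W"] + p["logsig.b"], -10.0, 10.0)
        return mu, logsig, (c1, c2, h2)

    def decode_forward(self, z, S, train=False, rng=None):
        dec_in = np.concatenate([z, S], axis=1)
        h1, c1 = self._block_fwd(dec_in, "dec1", train, rng)
        h2, c2 = self._block_fwd(h1, "dec2", train, rng)
        p = self.params
        rho = h2 @ p["out.W"] + p["out.b"]
        return rho, (dec_in, c1, c2, h2)

    def decode_backward(self, drho, cache, grads):
        dec_in, c1, c2, h2 = cache
        p = self.params
        grads["out.W"] += h2.T @ drho
        grads["out.b"] += drho.sum(axis=0)
        dh2 = drho @ p["out.W"].T
        dh1 = self._block_bwd(dh2, "dec2", c2, grads)
        ddec_in = self._block_bwd(dh1, "dec1", c1, grads)
        return ddec_in[:, : self.config.n_latent]  # dz; batch one-hot has no grad

    def encode_backward(self, dmu, dlogsig, cache, grads):
        c1, c2, h2 = cache
        p = self.params
        grads["mu.W"] += h2.T @ dmu
        grads["mu.b"] += dmu.sum(axis=0)
        grads["logsig.W"] += h2.T @ dlogsig
        grads["logsig.b"] += dlogsig.sum(axis=0)
        dh2 = dmu @ p["mu.W"].T + dlogsig @ p["logsig.W"].T
        dh1 = self._block_bwd(dh2, "enc2", c2, grads)
        self._block_bwd(dh1, "enc1", c1, grads)

    # -- optimizer --------------------------------------------------------
    def adam_step(self, grads: dict[str, np.ndarray]) -> None:
        cfg = self.config
        b1, b2, eps = 0.9, 0.999, 1e-8
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            if cfg.weight_decay > 0:
                g = g + cfg.weight_decay * self.params[k]
            m = self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            v = self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g * g
            mhat = m / (1 - b1**t)
            vhat = v / (1 - b2**t)
            self.params[k] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}


# -- offsets ----------------------------------------------------------------

def poisson_offset(totals: np.ndarray) -> np.ndarray:
    """l_c = log total fragment count; requires totals > 0."""
    totals = np.asarray(totals, dtype=float)
    if np.any(totals <= 0):
        raise ValueError("Poisson offset undefined for cells with zero total")
    return np.log(totals)


def bernoulli_offset(y: sp.spmatrix) -> np.ndarray:
    """ltilde_c = logit of the cell's mean accessibility (fraction nonzero)."""
    frac = np.asarray((y > 0).sum(axis=1)).ravel() / y.shape[1]
    if np.any(frac <= 0) or np.any(frac >= 1):
        raise ValueError("logit offset undefined for all-zero or all-one cells")
    return np.log(frac / (1 - frac))


# -- losses -----------------------------------------------------------------

def _poisson_nll_and_grad(u, X, l_c, want_grad=True):
    """Per-cell Poisson NLL with lam = exp(l) * softmax(u); grad wrt u."""
    umax = u.max(axis=1, keepdims=True)
    lse = umax[:, 0] + np.log(np.exp(u - umax).sum(axis=1))
    log_w = u - lse[:, None]
    T = X.sum(axis=1)
    nll = np.exp(l_c) - (X * (l_c[:, None] + log_w)).sum(axis=1) \
        + gammaln(X + 1.0).sum(axis=1)
    grad = np.exp(log_w) * T[:, None] - X if want_grad else None
    return nll, grad


def _bernoulli_nll_and_grad(u, Y, ltilde, want_grad=True):
    """Per-cell Bernoulli NLL with theta = sigmoid(u + ltilde); grad wrt u."""
    a = u + ltilde[:, None]
    softplus = np.where(a > 0, a + np.log1p(np.exp(-a)), np.log1p(np.exp(a)))
    nll = (softplus - Y * a).sum(axis=1)
    if want_grad:
        theta = 1.0 / (1.0 + np.exp(-a))
        grad = theta - Y
    else:
        grad = None
    return nll, grad


def _kl_gaussian(mu, logsig):
    """KL(N(mu, sigma) || N(0, 1)) per cell, sigma = exp(logsig)."""
    sig2 = np.exp(2.0 * logsig)
    return (0.5 * (mu**2 + sig2 - 1.0) - logsig).sum(axis=1)


# -- public functional surface ----------------------------------------------

def encode(x_row: np.ndarray, model: VAEModel,
           batch_code: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Posterior parameters (mu, sigma) for one cell; deterministic."""
    x = np.asarray(x_row, dtype=float).reshape(1, -1)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite encoder input")
    S = model.one_hot(np.array([batch_code])) if model.config.batch_to_encoder else None
    mu, logsig, _ = model.encode_forward(x, S, train=False)
    return mu[0], np.exp(logsig[0])


def decode_poisson(z: np.ndarray, batch_code: int, model: VAEModel,
                   l_c: float) -> np.ndarray:
    """Poisson rates lam for one cell; sums to exp(l_c) by construction."""
    if not np.isfinite(l_c):
        raise ValueError("l_c must be finite")
    z = np.asarray(z, dtype=float).reshape(1, -1)
    S = model.one_hot(np.array([batch_code]))
    rho, _ = model.decode_forward(z, S, train=False)
    u = rho[0] + model.params["r"]
    u = u - u.max()
    w = np.exp(u)
    w /= w.sum()
    return np.exp(l_c) * w


def decode_binary(z: np.ndarray, batch_code: int, model: VAEModel,
                  l_tilde: float) -> np.ndarray:
    """Bernoulli probabilities theta for one cell."""
    if not np.isfinite(l_tilde):
        raise ValueError("l_tilde must be finite")
    z = np.asarray(z, dtype=float).reshape(1, -1)
    S = model.one_hot(np.array([batch_code]))
    rho, _ = model.decode_forward(z, S, train=False)
    a = rho[0] + model.params["r"] + l_tilde
    return 1.0 / (1.0 + np.exp(-a))


def poisson_rate_to_bernoulli(lam: np.ndarray) -> np.ndarray:
    """P(count > 0) under Poisson(lam): theta = 1 - exp(-lam)."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 0):
        raise ValueError("Poisson rate must be non-negative")
    return -np.expm1(-lam)


def elbo_loss(model: VAEModel, X: np.ndarray, batch_codes: np.ndarray,
              offsets: np.ndarray, sample: bool = False,
              rng: np.random.Generator | None = None,
              train: bool = False) -> float:
    """Mean per-cell negative ELBO of a minibatch.

    With ``sample=False`` the latent is the posterior mean, making the value
    deterministic; the minibatch loss then equals the mean of singleton
    losses exactly.
    """
    loss, _, _ = _loss_forward(model, np.asarray(X, dtype=float),
                               model.one_hot(batch_codes),
                               np.asarray(offsets, dtype=float),
                               sample=sample, rng=rng, train=train,
                               want_grad=False)
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite ELBO loss")
    return float(loss)


def _loss_forward(model, X, S, offsets, sample, rng, train, want_grad):
    cfg = model.config
    enc_S = S if cfg.batch_to_encoder else None
    mu, logsig, enc_cache = model.encode_forward(X, enc_S, train=train, rng=rng)
    sigma = np.exp(logsig)
    if sample:
        eps = rng.standard_normal(mu.shape)
        z = mu + sigma * eps
    else:
        eps = np.zeros_like(mu)
        z = mu
    rho, dec_cache = model.decode_forward(z, S, train=train, rng=rng)
    u = rho + model.params["r"]
    if cfg.likelihood == "poisson":
        nll, du = _poisson_nll_and_grad(u, X, offsets, want_grad)
    else:
        nll, du = _bernoulli_nll_and_grad(u, X, offsets, want_grad)
    kl = _kl_gaussian(mu, logsig)
    loss = float(np.mean(nll + cfg.kl_weight * kl))
    if not want_grad:
        return loss, None, float(np.mean(nll))
    n = X.shape[0]
    grads = {k: np.zeros_like(v) for k, v in model.params.items()}
    du = du / n
    grads["r"] += du.sum(axis=0)
    dz = model.decode_backward(du, dec_cache, grads)
    dmu = dz + cfg.kl_weight * mu / n
    dlogsig = dz * eps * sigma + cfg.kl_weight * (sigma**2 - 1.0) / n
    model.encode_backward(dmu, dlogsig, enc_cache, grads)
    return loss, grads, float(np.mean(nll))


def _prepare_inputs(matrix: CountMatrix, config: VAEConfig):
    """Validate kind vs likelihood, drop offset-degenerate cells."""
    kind = matrix.kind
    if kind is CountKind.reads:
        raise ValueError(
            "read-count matrix rejected: fragment counts, but not read "
            "counts, should instead be modeled — run reads_to_fragments first"
        )
    if config.likelihood == "poisson":
        if kind is not CountKind.fragments:
            raise ValueError("poisson likelihood requires a fragments-kind matrix")
        values = matrix.values
        totals = np.asarray(values.sum(axis=1)).ravel()
        keep = totals > 0
        offsets_all = np.where(keep, np.log(np.maximum(totals, 1)), 0.0)
    else:
        values = matrix.values if kind is CountKind.binary else matrix.binarize().values
        frac = np.asarray((values > 0).sum(axis=1)).ravel() / values.shape[1]
        keep = (frac > 0) & (frac < 1)
        safe = np.clip(frac, 1e-12, 1 - 1e-12)
        offsets_all = np.log(safe / (1 - safe))
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropping %d cells with undefined depth offset", dropped)
    return values, keep, offsets_all, dropped


def train(matrix: CountMatrix, config: VAEConfig,
          cell_table: CellTable | None = None) -> tuple[VAEModel, TrainingLog]:
    """Fit a VAE with an 80/10/10 split and early stopping.

    Early stopping monitors the validation reconstruction loss (per-cell
    NLL, posterior-mean latent, dropout off); the best-epoch weights are
    restored. A single seed controls the split, the weight initialization,
    dropout masks, reparameterization noise and minibatch order.
    """
    cells = cell_table if cell_table is not None else matrix.cells
    if len(cells) != matrix.n_cells:
        raise ValueError("cell table length does not match matrix")
    values, keep, offsets_all, dropped = _prepare_inputs(matrix, config)

    model = VAEModel(matrix.n_peaks, cells.batch_categories, config)
    codes_all = np.array([model.batch_code(b) for b in cells.batch])

    kept = np.flatnonzero(keep)
    rng = np.random.default_rng(config.seed)
    perm = kept[rng.permutation(kept.size)]
    n = perm.size
    n_train = int(round(0.8 * n))
    n_val = int(round(0.1 * n))
    train_idx = perm[:n_train]
    val_idx = perm[n_train:n_train + n_val]
    test_idx = perm[n_train + n_val:]
    if n_train == 0 or n_val == 0:
        raise ValueError("too few cells for an 80/10/10 split")

    log = TrainingLog(n_dropped_cells=dropped, train_idx=train_idx,
                      val_idx=val_idx, test_idx=test_idx)

    Xval = np.asarray(values[val_idx].todense(), dtype=float)
    Sval = model.one_hot(codes_all[val_idx])
    off_val = offsets_all[val_idx]

    best_val = np.inf
    best_params = model.copy_params()
    best_epoch = -1
    bad_epochs = 0
    bs = config.minibatch_size

    for epoch in range(config.max_epochs):
        order = train_idx[rng.permutation(train_idx.size)]
        epoch_loss = 0.0
        n_seen = 0
        for start in range(0, order.size, bs):
            idx = order[start:start + bs]
            X = np.asarray(values[idx].todense(), dtype=float)
            S = model.one_hot(codes_all[idx])
            loss, grads, _ = _loss_forward(
                model, X, S, offsets_all[idx], sample=True, rng=rng,
                train=True, want_grad=True)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            model.adam_step(grads)
            epoch_loss += loss * idx.size
            n_seen += idx.size
        log.train_loss.append(epoch_loss / n_seen)

        _, _, val_recon = _loss_forward(model, Xval, Sval, off_val,
                                        sample=False, rng=None, train=False,
                                        want_grad=False)
        log.val_recon_loss.append(val_recon)
        if val_recon < best_val - config.min_delta:
            best_val = val_recon
            best_params = model.copy_params()
            best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                break

    model.params = best_params
    log.best_epoch = best_epoch
    return model, log


def _eval_forward(model: VAEModel, matrix: CountMatrix,
                  cell_idx: np.ndarray | None = None,
                  chunk: int = 1024):
    """Posterior means and decoder logits u = rho + r in eval mode."""
    values, keep, offsets_all, _ = _prepare_inputs(matrix, model.config)
    codes_all = np.array([model.batch_code(b) for b in matrix.cells.batch])
    idx = np.arange(matrix.n_cells) if cell_idx is None else np.asarray(cell_idx)
    mus, us = [], []
    for start in range(0, idx.size, chunk):
        sub = idx[start:start + chunk]
        X = np.asarray(values[sub].todense(), dtype=float)
        S = model.one_hot(codes_all[sub])
        enc_S = S if model.config.batch_to_encoder else None
        mu, _, _ = model.encode_forward(X, enc_S, train=False)
        rho, _ = model.decode_forward(mu, S, train=False)
        mus.append(mu)
        us.append(rho + model.params["r"])
    return (np.concatenate(mus), np.concatenate(us),
            offsets_all[idx], keep[idx])


def get_latent(model: VAEModel, matrix: CountMatrix) -> np.ndarray:
    """Cells x n_latent matrix of posterior means (deterministic)."""
    if matrix.n_peaks != model.n_peaks:
        raise ValueError(
            f"matrix has {matrix.n_peaks} peaks, model expects {model.n_peaks}")
    mu, _, _, _ = _eval_forward(model, matrix)
    return mu


def predict_rates(model: VAEModel, matrix: CountMatrix,
                  cell_idx: np.ndarray | None = None) -> np.ndarray:
    """Poisson rates lam_cp at the observed depth offsets (denoised counts).

    By the softmax construction every row sums to the cell's observed total
    fragment count.
    """
    if model.config.likelihood != "poisson":
        raise ValueError("rates are defined for the Poisson model only")
    _, u, offsets, _ = _eval_forward(model, matrix, cell_idx)
    umax = u.max(axis=1, keepdims=True)
    w = np.exp(u - umax)
    w /= w.sum(axis=1, keepdims=True)
    return np.exp(offsets)[:, None] * w


def predict_theta(model: VAEModel, matrix: CountMatrix,
                  cell_idx: np.ndarray | None = None) -> np.ndarray:
    """Probability of observing >= 1 count per (cell, peak).

    Poisson model: theta = 1 - exp(-lam) with the observed depth offset.
    Bernoulli model: theta directly.
    """
    if model.config.likelihood == "poisson":
        return poisson_rate_to_bernoulli(predict_rates(model, matrix, cell_idx))
    _, u, offsets, _ = _eval_forward(model, matrix, cell_idx)
    return 1.0 / (1.0 + np.exp(-(u + offsets[:, None])))


def normalized_accessibility(model: VAEModel, matrix: CountMatrix,
                             peak_subset: np.ndarray | None = None) -> np.ndarray:
    """Model-denoised accessibility at a common (median) depth.

    Every cell's depth offset is replaced by the median across cells —
    median total fragment count for the Poisson model, logit of the median
    mean-accessibility for the Bernoulli model — so cells become comparable.
    """
    _, u, _, _ = _eval_forward(model, matrix)
    if model.config.likelihood == "poisson":
        med = float(np.median(matrix.row_totals()))
        if med <= 0:
            raise ValueError("median total fragment count is zero")
        umax = u.max(axis=1, keepdims=True)
        w = np.exp(u - umax)
        w /= w.sum(axis=1, keepdims=True)
        out = med * w
    else:
        frac = np.asarray((matrix.values > 0).sum(axis=1)).ravel() / matrix.n_peaks
        med = float(np.median(frac))
        if med <= 0 or med >= 1:
            raise ValueError("median mean accessibility is degenerate")
        ltilde = np.log(med / (1 - med))
        out = 1.0 / (1.0 + np.exp(-(u + ltilde)))
    if peak_subset is not None:
        out = out[:, np.asarray(peak_subset)]
    return out


def sweep_latent_dims(matrix: CountMatrix, config: VAEConfig,
                      grid: list[int] | None = None) -> tuple[int, dict[int, float]]:
    """Select n_latent by validation-set average precision on binarized data.

    Trains one model per grid value (default 10..100 in steps of 10) and
    returns the argmax; ties go to the smallest dimension.
    """
    from .evaluation import average_precision

    if grid is None:
        grid = list(range(10, 101, 10))
    if not grid:
        raise ValueError("grid must be non-empty")
    scores: dict[int, float] = {}
    for d in grid:
        cfg = VAEConfig(**{**asdict(config), "n_latent": int(d)})
        model, log = train(matrix, cfg)
        theta = predict_theta(model, matrix, log.val_idx)
        y = np.asarray((matrix.values[log.val_idx] > 0).todense()).ravel()
        scores[int(d)] = average_precision(theta.ravel(), y)
    best = max(sorted(scores), key=lambda d: scores[d])
    return best, scores


# -- persistence -------------------------------------------------------------

def save_model(model: VAEModel, path: str, barcodes=None, peak_ids=None) -> None:
    """Write a single-file bundle: weights + config + optional manifests."""
    meta = {
        "config": asdict(model.config),
        "batch_categories": list(map(str, model.batch_categories)),
        "n_peaks": model.n_peaks,
        "n_hidden": model.n_hidden,
        "barcodes": list(barcodes) if barcodes is not None else None,
        "peak_ids": list(peak_ids) if peak_ids is not None else None,
    }
    arrays = {f"param:{k}": v for k, v in model.params.items()}
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_model(path: str) -> VAEModel:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(bytes(z["meta_json"]).decode())
        model = VAEModel(meta["n_peaks"], meta["batch_categories"],
                         VAEConfig(**meta["config"]))
        for k in model.params:
            model.params[k] = z[f"param:{k}"]
    return model
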