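"""Conditional Gaussian-mixture density network (numpy core).

Conditional density estimator q(theta | x) = sum_k pi_k(x) N(theta;
mu_k(x), diag(sigma_k(x)^2)).  A fully connected embedding network (three
tanh layers of 50 units by default) maps the observation x to an
embedding, and a linear head maps the embedding to mixture logits, means
and log-STDs.  Trained by maximum likelihood (minimizing the negative
mean log q over simulated pairs) with Adam and early stopping on a
held-out validation split.

Inputs are expected to be standardized (z-scored); the mixture lives in
standardized parameter space.  Everything is plain float64 numpy with a
seeded Generator, so training is exactly reproducible.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = ["MDN", "TrainingHistory"]

_LOG_2PI = float(np.log(2.0 * np.pi))
_LOG_SIG_MIN, _LOG_SIG_MAX = -9.0, 5.0


@dataclass
class TrainingHistory:
    train_loss: list = field(default_factory=list)
    val_logprob: list = field(default_factory=list)
    best_epoch: int = -1
    init_val_logprob: float = float("nan")


def _xavier(rng, fan_in, fan_out):
    return rng.standard_normal((fan_in, fan_out)) / np.sqrt(fan_in)


class MDN:
    """Mixture density network with manual backprop (see module docstring)."""

    def __init__(
        self,
        x_dim: int,
        theta_dim: int,
        n_components: int = 8,
        hidden_units: int = 50,
        n_hidden_layers: int = 3,
        mean_skip: bool = False,
        seed: int = 0,
    ):
        self.x_dim = x_dim
        self.theta_dim = theta_dim
        self.n_components = n_components
        self.hidden_units = hidden_units
        self.n_hidden_layers = n_hidden_layers
        self.mean_skip = mean_skip
        rng = np.random.default_rng(seed)
        sizes = [x_dim] + [hidden_units] * n_hidden_layers
        self.W = [_xavier(rng, sizes[i], sizes[i + 1]) for i in range(n_hidden_layers)]
        self.b = [np.zeros(sizes[i + 1]) for i in range(n_hidden_layers)]
        head_dim = n_components * (1 + 2 * theta_dim)
        self.W.append(_xavier(rng, hidden_units, head_dim) * 0.1)
        hb = np.zeros(head_dim)
        # spread initial component means over standardized parameter space
        K, D = n_components, theta_dim
        hb[K : K + K * D] = 0.5 * rng.standard_normal(K * D)
        self.b.append(hb)
        # optional linear readout x -> component means (shared across components);
        # reduces smoothing bias of the conditional mean on sharp posteriors
        self.W_skip = np.zeros((x_dim, theta_dim)) if mean_skip else None

    # -- forward -----------------------------------------------------------

    def _split_head(self, out):
        K, D = self.n_components, self.theta_dim
        logits = out[:, :K]
        mu = out[:, K : K + K * D].reshape(-1, K, D)
        log_sig = np.clip(out[:, K + K * D :].reshape(-1, K, D), _LOG_SIG_MIN, _LOG_SIG_MAX)
        return logits, mu, log_sig

    def forward(self, X):
        """Mixture parameters for each row of X; returns (logits, mu, log_sig, cache)."""
        h = np.asarray(X, dtype=float)
        cache = [h]
        for W, b in zip(self.W[:-1], self.b[:-1]):
            h = np.tanh(h @ W + b)
            cache.append(h)
        out = h @ self.W[-1] + self.b[-1]
        logits, mu, log_sig = self._split_head(out)
        if self.W_skip is not None:
            mu = mu + (cache[0] @ self.W_skip)[:, None, :]
        return logits, mu, log_sig, cache

    def log_prob(self, X, Y):
        """Elementwise log q(y | x) for matched rows of X and Y."""
        logits, mu, log_sig, _ = self.forward(X)
        return self._log_prob_from_params(logits, mu, log_sig, np.asarray(Y, float))

    @staticmethod
    def _log_prob_from_params(logits, mu, log_sig, Y):
        log_pi = logits - logsumexp(logits, axis=1, keepdims=True)
        z = (Y[:, None, :] - mu) / np.exp(log_sig)
        comp = -0.5 * np.sum(z**2 + _LOG_2PI, axis=2) - np.sum(log_sig, axis=2)
        return logsumexp(log_pi + comp, axis=1)

    def mixture_params(self, x):
        """Mixture (pi, mu, sig) conditioned on a single observation x."""
        logits, mu, log_sig, _ = self.forward(np.asarray(x, float)[None, :])
        pi = np.exp(logits[0] - logsumexp(logits[0]))
        return pi, mu[0], np.exp(log_sig[0])

    # -- gradients ---------------------------------------------------------

    def _loss_and_grads(self, X, Y):
        B = X.shape[0]
        logits, mu, log_sig, cache = self.forward(X)
        log_pi = logits - logsumexp(logits, axis=1, keepdims=True)
        sig = np.exp(log_sig)
        z = (Y[:, None, :] - mu) / sig
        comp = -0.5 * np.sum(z**2 + _LOG_2PI, axis=2) - np.sum(log_sig, axis=2)
        a = log_pi + comp
        logq = logsumexp(a, axis=1)
        loss = -float(np.mean(logq))
        r = np.exp(a - logq[:, None])  # responsibilities
        pi = np.exp(log_pi)
        # gradients of the mean NLL w.r.t. head outputs
        d_logits = (pi - r) / B
        d_mu = (r[:, :, None] * (mu - Y[:, None, :]) / sig**2) / B
        d_log_sig = (r[:, :, None] * (1.0 - z**2)) / B
        d_out = np.concatenate(
            [d_logits, d_mu.reshape(B, -1), d_log_sig.reshape(B, -1)], axis=1
        )
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        h_last = cache[-1]
        gW[-1] = h_last.T @ d_out
        gb[-1] = d_out.sum(axis=0)
        dh = d_out @ self.W[-1].T
        for i in range(self.n_hidden_layers - 1, -1, -1):
            dh = dh * (1.0 - cache[i + 1] ** 2)  # through tanh
            gW[i] = cache[i].T @ dh
            gb[i] = dh.sum(axis=0)
            if i > 0:
                dh = dh @ self.W[i].T
        g_skip = None
        if self.W_skip is not None:
            g_skip = cache[0].T @ d_mu.sum(axis=1)
        return loss, gW, gb, g_skip

    # -- training ----------------------------------------------------------

    def fit(
        self,
        X,
        Y,
        lr: float = 5e-4,
        batch_size: int = 200,
        max_epochs: int = 500,
        patience: int = 20,
        val_fraction: float = 0.1,
        seed: int = 0,
        lr_decay: float = 0.5,
        min_lr: float = 2e-5,
    ) -> TrainingHistory:
        """Maximum-likelihood training with Adam and early stopping.

        Splits off a validation fraction (seeded permutation), restores
        the best-validation weights at the end, and records the score of
        the untrained initialization for the learning-happened contract.
        When the validation log-density plateaus for half the patience
        window the learning rate is multiplied by ``lr_decay`` (down to
        ``min_lr``) and training resumes from the best weights so far;
        early stopping triggers once the full patience window passes
        without improvement.
        """
        X = np.asarray(X, float)
        Y = np.asarray(Y, float)
        n = X.shape[0]
        if n < 2:
            raise ValueError("need at least 2 training pairs")
        if not 0 < val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        n_val = max(1, int(round(n * val_fraction)))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xt, Yt, Xv, Yv = X[tr_idx], Y[tr_idx], X[val_idx], Y[val_idx]
        bs = min(batch_size, Xt.shape[0])

        hist = TrainingHistory()
        hist.init_val_logprob = float(np.mean(self.log_prob(Xv, Yv)))
        all_params = self.W + self.b + ([self.W_skip] if self.W_skip is not None else [])
        m = [np.zeros_like(p) for p in all_params]
        v = [np.zeros_like(p) for p in all_params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        best_val = -np.inf
        best_weights = None
        bad_epochs = 0
        cur_lr = lr
        decay_window = max(1, patience // 2)
        for epoch in range(max_epochs):
            order = rng.permutation(Xt.shape[0])
            ep_loss = 0.0
            nb = 0
            for start in range(0, Xt.shape[0], bs):
                idx = order[start : start + bs]
                loss, gW, gb, g_skip = self._loss_and_grads(Xt[idx], Yt[idx])
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}; "
                        "check input standardization"
                    )
                ep_loss += loss
                nb += 1
                t += 1
                grads = gW + gb
                params = self.W + self.b
                if self.W_skip is not None:
                    grads = grads + [g_skip]
                    params = params + [self.W_skip]
                for j, (p, g) in enumerate(zip(params, grads)):
                    m[j] = beta1 * m[j] + (1 - beta1) * g
                    v[j] = beta2 * v[j] + (1 - beta2) * g**2
                    mh = m[j] / (1 - beta1**t)
                    vh = v[j] / (1 - beta2**t)
                    p -= cur_lr * mh / (np.sqrt(vh) + eps)
            val = float(np.mean(self.log_prob(Xv, Yv)))
            hist.train_loss.append(ep_loss / nb)
            hist.val_logprob.append(val)
            if val > best_val:
                best_val = val
                hist.best_epoch = epoch
                best_weights = (copy.deepcopy(self.W), copy.deepcopy(self.b),
                                copy.deepcopy(self.W_skip))
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs > patience:
                    break
                if bad_epochs % decay_window == 0 and cur_lr > min_lr:
                    cur_lr = max(cur_lr * lr_decay, min_lr)
                    if best_weights is not None:
                        self.W = copy.deepcopy(best_weights[0])
                        self.b = copy.deepcopy(best_weights[1])
                        self.W_skip = copy.deepcopy(best_weights[2])
        if best_weights is not None:
            self.W, self.b, self.W_skip = best_weights
        return hist

    # -- sampling ----------------------------------------------------------

    def sample(self, x, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n samples from q(. | x) in standardized parameter space."""
        pi, mu, sig = self.mixture_params(x)
        ks = rng.choice(self.n_components, size=n, p=pi)
        eps = rng.standard_normal((n, self.theta_dim))
        return mu[ks] + sig[ks] * eps

    def log_prob_single(self, thetas, x) -> np.ndarray:
        """log q(theta | x) for many thetas and one observation x."""
        logits, mu, log_sig, _ = self.forward(np.asarray(x, float)[None, :])
        thetas = np.atleast_2d(np.asarray(thetas, float))
        # note: forward already applied the mean-skip term to mu
        log_pi = logits[0] - logsumexp(logits[0])
        sig = np.exp(log_sig[0])
        z = (thetas[:, None, :] - mu[0]) / sig
        comp = -0.5 * np.sum(z**2 + _LOG_2PI, axis=2) - np.sum(log_sig[0], axis=1)
        return logsumexp(log_pi + comp, axis=1)

    def grad_log_prob_single(self, theta, x) -> np.ndarray:
        """d log q(theta | x) / d theta for one theta and one x."""
        logits, mu, log_sig, _ = self.forward(np.asarray(x, float)[None, :])
        theta = np.asarray(theta, float)
        log_pi = logits[0] - logsumexp(logits[0])
        sig = np.exp(log_sig[0])
        z = (theta[None, :] - mu[0]) / sig
        comp = -0.5 * np.sum(z**2 + _LOG_2PI, axis=1) - np.sum(log_sig[0], axis=1)
        a = log_pi + comp
        r = np.exp(a - logsumexp(a))
        return np.sum(r[:, None] * (mu[0] - theta[None, :]) / sig**2, axis=0)

    # -- (de)serialization -------------------------------------------------

    def get_weights(self) -> dict:
        out = {"meta": np.array([self.x_dim, self.theta_dim, self.n_components,
                                 self.hidden_units, self.n_hidden_layers,
                                 int(self.mean_skip)])}
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            out[f"W{i}"] = W
            out[f"b{i}"] = b
        if self.W_skip is not None:
            out["W_skip"] = self.W_skip
        return out

    @classmethod
    def from_weights(cls, d: dict) -> "MDN":
        meta = [int(v) for v in np.asarray(d["meta"]).ravel()]
        net = cls(*meta[:5], mean_skip=bool(meta[5]) if len(meta) > 5 else False, seed=0)
        n_layers = meta[4] + 1
        net.W = [np.asarray(d[f"W{i}"], float) for i in range(n_layers)]
        net.b = [np.asarray(d[f"b{i}"], float) for i in range(n_layers)]
        if net.mean_skip:
            net.W_skip = np.asarray(d["W_skip"], float)
        return net
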