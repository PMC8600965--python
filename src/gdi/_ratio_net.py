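"""Internal numerics for the likelihood-ratio classifier.

The classifier separating dependent (p) from permuted (q) samples is a
small multilayer perceptron over standardized inputs, augmented with one
engineered input: the closed-form Gaussian discriminant

    g(x) = log N(x; mu, S) - log N(x_A; mu_A, S_A) - log N(x_B; mu_B, S_B)

computed from the training rows of p (S_A, S_B are the diagonal blocks of
the ridge-regularized covariance S; the A block may be augmented with its
element-wise squares so that quadratic-in-A interactions are visible to
the linear part).  For jointly Gaussian data g is, up to calibration, the
exact log likelihood ratio, so the network only has to learn the residual
non-Gaussian structure.  Training is minibatch Adam on the binary
cross-entropy with early stopping on a held-out slice, followed by Platt
recalibration of the logit, which keeps the Donsker-Varadhan plug-in
stable.

Everything here is float32 full-numpy and deterministic given a Generator.
"""

from __future__ import annotations

import numpy as np

__all__ = ["GaussianFeature", "MLPRatioNet", "platt_fit"]


class GaussianFeature:
    """Closed-form Gaussian discriminant g(x) between a joint density and
    the product of its A-block and B-block marginals."""

    def __init__(self, X_p: np.ndarray, a_cols: np.ndarray, ridge: float = 1e-2,
                 square_a: bool = True):
        X_p = np.asarray(X_p, dtype=np.float64)
        a_cols = np.asarray(a_cols, dtype=int)
        d0 = X_p.shape[1]
        self._d0 = d0
        self._a_cols = a_cols
        self._square_a = square_a
        b_cols = np.setdiff1d(np.arange(d0), a_cols)
        self._b_cols = b_cols

        F = self._feats(X_p)
        self._mu = F.mean(axis=0)
        na = len(a_cols) * (2 if square_a else 1)
        ai = np.arange(na)
        bi = np.arange(na, F.shape[1])
        S = np.cov((F - self._mu).T)
        S = np.atleast_2d(S)
        lam = ridge * np.trace(S) / S.shape[0]
        S = S + lam * np.eye(S.shape[0])
        Sa = S[np.ix_(ai, ai)]
        Sb = S[np.ix_(bi, bi)]
        self._ai, self._bi = ai, bi
        self._Si = np.linalg.inv(S)
        self._Sai = np.linalg.inv(Sa)
        self._Sbi = np.linalg.inv(Sb)
        self._const = -0.5 * (np.linalg.slogdet(S)[1]
                              - np.linalg.slogdet(Sa)[1]
                              - np.linalg.slogdet(Sb)[1])

    def _feats(self, X: np.ndarray) -> np.ndarray:
        A = X[:, self._a_cols]
        if self._square_a:
            return np.hstack([A, A ** 2, X[:, self._b_cols]])
        return np.hstack([A, X[:, self._b_cols]])

    def __call__(self, X: np.ndarray) -> np.ndarray:
        F = self._feats(np.asarray(X, dtype=np.float64)) - self._mu
        qf = np.einsum("ni,ij,nj->n", F, self._Si, F)
        qa = np.einsum("ni,ij,nj->n", F[:, self._ai], self._Sai, F[:, self._ai])
        qb = np.einsum("ni,ij,nj->n", F[:, self._bi], self._Sbi, F[:, self._bi])
        return (-0.5 * (qf - qa - qb) + self._const).astype(np.float32)


def platt_fit(z: np.ndarray, y: np.ndarray, max_iter: int = 50) -> tuple[float, float]:
    """Newton fit of sigmoid(a*z + c) to labels y; returns (a, c).

    Targets are smoothed (Platt 1999) so the MLE stays finite even when
    the scores separate the classes perfectly.
    """
    a, c = 1.0, 0.0
    z = np.asarray(z, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n_pos = y.sum()
    n_neg = len(y) - n_pos
    y = np.where(y > 0.5, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def loss(a_, c_):
        u = a_ * z + c_
        return float(np.mean(np.logaddexp(0.0, u) - y * u))

    cur = loss(a, c)
    for _ in range(max_iter):
        u = a * z + c
        p = 1.0 / (1.0 + np.exp(-np.clip(u, -700, 700)))
        w = p * (1 - p) + 1e-12
        ga = np.mean((p - y) * z)
        gc = np.mean(p - y)
        haa = np.mean(w * z * z)
        hac = np.mean(w * z)
        hcc = np.mean(w)
        det = haa * hcc - hac * hac
        if det <= 1e-14:
            break
        da = (hcc * ga - hac * gc) / det
        dc = (-hac * ga + haa * gc) / det
        step = 1.0
        for _bt in range(25):  # backtracking keeps the concave ascent safe
            new = loss(a - step * da, c - step * dc)
            if new <= cur + 1e-12:
                break
            step *= 0.5
        else:
            break
        a -= step * da
        c -= step * dc
        if cur - new < 1e-10:
            cur = new
            break
        cur = new
    return a, c


class MLPRatioNet:
    """MLP with a Gaussian-discriminant skip feature, trained on BCE.

    The logit is ``a0 * g(x) + MLP(x) + c`` where g is the closed-form
    discriminant (absent when no block structure is supplied, in which
    case a plain MLP is trained).
    """

    def __init__(self, hidden_layers, learning_rate, batch_size, max_epochs,
                 val_fraction, patience, ridge, use_gaussian_feature, square_a):
        self.hidden_layers = tuple(hidden_layers)
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.val_fraction = val_fraction
        self.patience = patience
        self.ridge = ridge
        self.use_gaussian_feature = use_gaussian_feature
        self.square_a = square_a
        self._params = None
        self._gfun = None

    # -- forward pieces -------------------------------------------------
    def _mlp_logit(self, params, X):
        *hidden, (W_out, b_out) = params
        a = X
        for W, b in hidden:
            a = np.maximum(a @ W + b, 0)
        return a @ W_out + b_out

    def logit(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        z = self._mlp_logit(self._mlp_params, X).ravel()
        if self._gfun is not None:
            z = z + self._a0 * self._gfun(X)
        return z

    # -- training -------------------------------------------------------
    def fit(self, X_p, X_q, rng: np.random.Generator, a_cols=None):
        X_p = np.asarray(X_p, dtype=np.float32)
        X_q = np.asarray(X_q, dtype=np.float32)
        n_p = X_p.shape[0]
        d = X_p.shape[1]

        # held-out slice for early stopping and calibration
        nv_p = max(1, int(n_p * self.val_fraction))
        perm_p = rng.permutation(n_p)
        perm_q = rng.permutation(X_q.shape[0])
        vp, tp = perm_p[:nv_p], perm_p[nv_p:]
        nv_q = max(1, int(X_q.shape[0] * self.val_fraction))
        vq, tq = perm_q[:nv_q], perm_q[nv_q:]

        if self.use_gaussian_feature and a_cols is not None and d > len(np.atleast_1d(a_cols)):
            self._gfun = GaussianFeature(X_p[tp], np.atleast_1d(a_cols),
                                         ridge=self.ridge, square_a=self.square_a)
        else:
            self._gfun = None

        X = np.vstack([X_p[tp], X_q[tq]])
        y = np.r_[np.ones(len(tp)), np.zeros(len(tq))].astype(np.float32)[:, None]
        Xv = np.vstack([X_p[vp], X_q[vq]])
        yv = np.r_[np.ones(len(vp)), np.zeros(len(vq))].astype(np.float32)[:, None]
        G = (self._gfun(X)[:, None] if self._gfun is not None
             else np.zeros((len(X), 1), dtype=np.float32))
        Gv = (self._gfun(Xv)[:, None] if self._gfun is not None
              else np.zeros((len(Xv), 1), dtype=np.float32))

        sizes = [d, *self.hidden_layers, 1]
        params = []
        for i in range(len(sizes) - 1):
            W = rng.normal(0, np.sqrt(2.0 / sizes[i]),
                           size=(sizes[i], sizes[i + 1])).astype(np.float32)
            if i == len(sizes) - 2 and self._gfun is not None:
                W = np.zeros_like(W)  # let the discriminant carry the start
            params.append((W, np.zeros(sizes[i + 1], dtype=np.float32)))
        a0 = np.ones(1, dtype=np.float32)

        flat = [arr for Wb in params for arr in Wb] + [a0]
        m = [np.zeros_like(p) for p in flat]
        v = [np.zeros_like(p) for p in flat]
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = 0
        n = len(X)
        best = np.inf
        best_state = None
        bad = 0

        for _epoch in range(self.max_epochs):
            order = rng.permutation(n)
            for s in range(0, n, self.batch_size):
                t += 1
                bi = order[s: s + self.batch_size]
                xb, gb, yb = X[bi], G[bi], y[bi]
                acts = [xb]
                a = xb
                for W, b in params[:-1]:
                    a = np.maximum(a @ W + b, 0)
                    acts.append(a)
                W_out, b_out = params[-1]
                z = acts[-1] @ W_out + b_out + a0 * gb
                p = 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))
                gz = (p - yb) / len(bi)
                grads = []
                g_back = gz
                for i in range(len(params) - 1, -1, -1):
                    W, b = params[i]
                    grads.append((acts[i].T @ g_back, g_back.sum(0)))
                    if i > 0:
                        g_back = (g_back @ W.T) * (acts[i] > 0)
                grads = [gr for pair in reversed(grads) for gr in pair]
                grads.append(np.array([float(np.sum(gz * gb))], dtype=np.float32))
                for pi, (P, Gd) in enumerate(zip(flat, grads)):
                    m[pi] = b1 * m[pi] + (1 - b1) * Gd
                    v[pi] = b2 * v[pi] + (1 - b2) * Gd * Gd
                    P -= self.learning_rate * (m[pi] / (1 - b1 ** t)) / (
                        np.sqrt(v[pi] / (1 - b2 ** t)) + eps)
            # validation loss
            self._mlp_params = params
            self._a0 = float(a0[0])
            zv = self._mlp_logit(params, Xv) + a0 * Gv
            loss = float(np.mean(np.logaddexp(0, zv) - yv * zv))
            if loss < best - 1e-4:
                best = loss
                best_state = ([(W.copy(), b.copy()) for W, b in params], float(a0[0]))
                bad = 0
            else:
                bad += 1
                if bad >= self.patience:
                    break

        if best_state is not None:
            params, a0_val = best_state
        else:
            a0_val = float(a0[0])
        self._mlp_params = params
        self._a0 = a0_val

        # Platt recalibration on the held-out slice
        zv = self._mlp_logit(params, Xv).ravel() + self._a0 * (
            Gv.ravel() if self._gfun is not None else 0.0)
        self._cal_a, self._cal_c = platt_fit(zv, yv.ravel())
        return self

    def calibrated_logit(self, X: np.ndarray) -> np.ndarray:
        return self._cal_a * self.logit(X) + self._cal_c
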