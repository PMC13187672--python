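"""Univariate Gaussian-mixture fitting by EM with BIC model selection.

Unequal component variances; E-step responsibilities and M-step weighted
moments in log-space for stability. A variance floor (``1e-4 * var(x)``)
guards against component collapse; initialization spreads component means
over sample quantiles and perturbs them across seeded restarts.

On heavily rounded data (many exact ties) the unequal-variance likelihood
rewards components shrunk onto tie clusters; the floor bounds but does not
remove those spurious maxima, so BIC selection on such data should be read
together with the KDE mode structure (see the package methods note).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class GmmFit:
    k: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    log_likelihood: float
    bic: float
    n_iter: int
    converged: bool
    ll_trace: np.ndarray = field(repr=False, default=None)

    def n_substantive(self, min_weight: float = 0.05) -> int:
        """Number of components with non-negligible weight."""
        return int((self.weights >= min_weight).sum())


def _em_once(
    xs: np.ndarray,
    mu: np.ndarray,
    var: np.ndarray,
    w: np.ndarray,
    var_floor: float,
    tol: float,
    max_iter: int,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, int, bool, np.ndarray]:
    n = xs.size
    ll_old = -np.inf
    trace = []
    converged = False
    for it in range(max_iter):
        logp = (
            -0.5 * (_LOG2PI + np.log(var))[None, :]
            - 0.5 * (xs[:, None] - mu[None, :]) ** 2 / var[None, :]
            + np.log(np.maximum(w, 1e-300))[None, :]
        )
        m = logp.max(axis=1, keepdims=True)
        p = np.exp(logp - m)
        s = p.sum(axis=1, keepdims=True)
        ll = float((np.log(s) + m).sum())
        trace.append(ll)
        resp = p / s
        nk = resp.sum(axis=0) + 1e-12
        w = nk / n
        mu = (resp * xs[:, None]).sum(axis=0) / nk
        var = np.maximum(
            (resp * (xs[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk, var_floor
        )
        if ll - ll_old < tol:
            converged = True
            break
        ll_old = ll
    return ll, w, mu, var, it + 1, converged, np.asarray(trace)


def gmm_fit_em(
    x,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> GmmFit:
    """Fit a k-component univariate Gaussian mixture, best of seeded restarts.

    Restart 0 starts from quantile-spread means; later restarts perturb them.
    The reported log-likelihood trace is non-decreasing (EM guarantee, up to
    the variance-floor projection).
    """
    xs = np.asarray(x, dtype=float)
    n = xs.size
    if k < 1:
        raise ValueError("k must be >= 1")
    if n <= 3 * k:
        raise ValueError(f"need n > 3k (= {3 * k}), got n = {n}")
    if np.ptp(xs) == 0:
        raise ValueError("degenerate sample (zero variance)")
    rng = np.random.default_rng(seed)
    gvar = xs.var()
    var_floor = 1e-4 * gvar
    sd = np.sqrt(gvar)
    base_mu = np.quantile(xs, (np.arange(k) + 0.5) / k)

    best = None
    for r in range(n_restarts):
        mu = base_mu.copy()
        if r > 0:
            mu = np.sort(mu + rng.normal(0.0, 0.25 * sd / max(k - 1, 1), k))
        var = np.full(k, gvar / k)
        w = np.full(k, 1.0 / k)
        ll, w2, mu2, var2, n_iter, conv, trace = _em_once(
            xs, mu, var, w, var_floor, tol, max_iter
        )
        if best is None or ll > best[0]:
            best = (ll, w2, mu2, var2, n_iter, conv, trace)

    ll, w, mu, var, n_iter, conv, trace = best
    order = np.argsort(mu)
    n_params = 3 * k - 1
    bic = -2.0 * ll + n_params * np.log(n)
    return GmmFit(
        k=k,
        weights=w[order],
        means=mu[order],
        variances=var[order],
        log_likelihood=ll,
        bic=bic,
        n_iter=n_iter,
        converged=conv,
        ll_trace=trace,
    )


def select_k_bic(
    x,
    k_max: int = 8,
    seed: int = 0,
    n_restarts: int = 10,
    tol: float = 1e-8,
) -> tuple[int, list[GmmFit]]:
    """Fit k = 1..k_max and return the BIC-minimizing k with all fits.

    ``BIC = -2*logL + (3k - 1)*ln(n)``; ks whose fit is infeasible
    (``n <= 3k``) are skipped.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    fits: list[GmmFit] = []
    for k in range(1, k_max + 1):
        try:
            fits.append(gmm_fit_em(x, k, seed=seed + k, n_restarts=n_restarts, tol=tol))
        except ValueError:
            break
    if not fits:
        raise ValueError("no feasible mixture size")
    best = min(fits, key=lambda f: f.bic)
    return best.k, fits
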