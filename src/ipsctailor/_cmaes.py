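"""Covariance Matrix Adaptation Evolution Strategy (CMA-ES).

A compact implementation of the standard (mu/mu_w, lambda)-CMA-ES with
cumulative step-size adaptation and rank-one plus rank-mu covariance
updates, following Hansen's tutorial formulation. Written for
low-dimensional, cheap objectives (here: the sum-of-squares current
decomposition, which is an exact quadratic), where running the strategy to
tight function tolerances is inexpensive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CMAESResult", "minimize_cmaes"]


@dataclass
class CMAESResult:
    x: np.ndarray  # distribution mean at termination
    fun: float  # objective at x
    x_best: np.ndarray  # best sampled point
    fun_best: float
    n_iter: int
    n_evals: int
    converged: bool
    message: str


def minimize_cmaes(
    fun,
    x0,
    sigma0: float,
    seed: int,
    *,
    max_iter: int = 3000,
    tol_fun: float = 1e-13,
    tol_x: float = 1e-13,
    popsize: int | None = None,
    param_transform=None,
    tol_params: float | None = None,
):
    """Minimize ``fun`` starting from ``x0`` with initial step ``sigma0``.

    Termination: the range of the best objective values over a trailing
    window falls below ``tol_fun * max(1, |f_best|)`` (function-value
    stagnation), or the search distribution collapses below ``tol_x``
    relative to the parameter scale, or — when ``param_transform`` and
    ``tol_params`` are given — the transformed mean stagnates: every
    coordinate of ``param_transform(xmean)`` moves by less than
    ``tol_params * max(1, |coord|)`` over the trailing window. The last
    criterion suits transformed parameterizations (e.g. log-scales) where
    coordinates pushed toward a boundary never satisfy tol_x.
    """
    rng = np.random.default_rng(seed)
    xmean = np.asarray(x0, dtype=float).copy()
    n = xmean.size
    sigma = float(sigma0)

    lam = popsize or 4 + int(3 * np.log(n))
    mu = lam // 2
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mueff = 1.0 / np.sum(w ** 2)

    cc = (4 + mueff / n) / (n + 4 + 2 * mueff / n)
    cs = (mueff + 2) / (n + mueff + 5)
    c1 = 2 / ((n + 1.3) ** 2 + mueff)
    cmu = min(1 - c1, 2 * (mueff - 2 + 1 / mueff) / ((n + 2) ** 2 + mueff))
    damps = 1 + 2 * max(0.0, np.sqrt((mueff - 1) / (n + 1)) - 1) + cs
    chiN = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n ** 2))

    pc = np.zeros(n)
    ps = np.zeros(n)
    C = np.eye(n)
    B = np.eye(n)
    D = np.ones(n)
    invsqrtC = np.eye(n)

    x_best = xmean.copy()
    f_best = np.inf
    hist_len = 20 + int(np.ceil(30.0 * n / lam))
    f_hist: list[float] = []
    p_hist: list[np.ndarray] = []
    n_evals = 0
    message = "max_iter reached"
    converged = False

    for it in range(1, max_iter + 1):
        Z = rng.standard_normal((lam, n))
        Y = Z * D  # N(0, D^2)
        X = xmean + sigma * (Y @ B.T)
        f = np.array([fun(x) for x in X])
        n_evals += lam
        order = np.argsort(f)
        f = f[order]
        X = X[order]

        if f[0] < f_best:
            f_best = float(f[0])
            x_best = X[0].copy()
        f_hist.append(float(f[0]))
        if len(f_hist) > hist_len:
            f_hist.pop(0)

        xold = xmean
        xmean = w @ X[:mu]
        y_w = (xmean - xold) / sigma

        ps = (1 - cs) * ps + np.sqrt(cs * (2 - cs) * mueff) * (invsqrtC @ y_w)
        hsig = (
            np.linalg.norm(ps)
            / np.sqrt(1 - (1 - cs) ** (2 * it))
            / chiN
            < 1.4 + 2 / (n + 1)
        )
        pc = (1 - cc) * pc + hsig * np.sqrt(cc * (2 - cc) * mueff) * y_w

        artmp = (X[:mu] - xold) / sigma
        C = (
            (1 - c1 - cmu) * C
            + c1 * (np.outer(pc, pc) + (not hsig) * cc * (2 - cc) * C)
            + cmu * artmp.T @ (w[:, None] * artmp)
        )
        sigma *= np.exp((cs / damps) * (np.linalg.norm(ps) / chiN - 1))

        C = np.triu(C) + np.triu(C, 1).T
        D2, B = np.linalg.eigh(C)
        D = np.sqrt(np.maximum(D2, 1e-40))
        invsqrtC = B @ np.diag(1.0 / D) @ B.T

        scale = max(1.0, float(np.max(np.abs(xmean))))
        if len(f_hist) >= hist_len:
            f_range = max(f_hist) - min(f_hist)
            if tol_fun > 0 and f_range <= tol_fun * max(1.0, abs(f_best)):
                message = "tol_fun"
                converged = True
                break
        if tol_x > 0 and sigma * float(np.max(D)) < tol_x * scale:
            message = "tol_x"
            converged = True
            break
        if param_transform is not None and tol_params is not None:
            p_hist.append(np.asarray(param_transform(xmean), dtype=float))
            if len(p_hist) > hist_len:
                p_hist.pop(0)
            if len(p_hist) >= hist_len:
                P = np.asarray(p_hist)
                rng_per_coord = P.max(axis=0) - P.min(axis=0)
                bound = tol_params * max(1.0, float(np.max(np.abs(P[-1]))))
                if np.all(rng_per_coord <= bound):
                    message = "tol_params"
                    converged = True
                    break

    f_mean = float(fun(xmean))
    n_evals += 1
    if f_mean > f_best:
        # mean is usually the most reliable point on smooth problems, but
        # never return something worse than the best sample
        xmean, f_mean = x_best.copy(), f_best
    return CMAESResult(
        x=xmean,
        fun=f_mean,
        x_best=x_best,
        fun_best=f_best,
        n_iter=it,
        n_evals=n_evals,
        converged=converged,
        message=message,
    )
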