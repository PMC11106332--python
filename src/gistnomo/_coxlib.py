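"""Breslow-tie Cox partial-likelihood primitives.

Shared numerical core: log partial likelihood, its gradient and Hessian,
a Newton solver for the (optionally ridge-penalized) objective, and the
Breslow baseline cumulative-hazard estimator.  Everything works on plain
arrays and is vectorized over tied-time groups; the model-facing wrappers
live in :mod:`gistnomo.models`.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "breslow_loglik",
    "breslow_gradient",
    "breslow_hessian",
    "newton_cox",
    "breslow_baseline",
]


def _prep(X, time, event):
    """Sort descending by time and locate tied-time run boundaries.

    Returns (Xs, ts, ds, starts, ends): ``starts[k]``/``ends[k]`` delimit
    run k (inclusive); the risk set at run k's time is rows 0..ends[k].
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    order = np.argsort(-time, kind="stable")
    Xs, ts, ds = X[order], time[order], event[order]
    change = np.flatnonzero(np.diff(ts))
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [len(ts) - 1]))
    return Xs, ts, ds, starts, ends


def breslow_loglik(beta, X, time, event) -> float:
    """Breslow-approximation log partial likelihood."""
    Xs, ts, ds, starts, ends = _prep(X, time, event)
    beta = np.asarray(beta, dtype=float)
    eta = Xs @ beta
    c = eta.max() if eta.size else 0.0
    S0 = np.cumsum(np.exp(eta - c))[ends]
    d = np.add.reduceat(ds, starts)
    eta_ev = np.add.reduceat(ds * eta, starts)
    ev = d > 0
    return float(np.sum(eta_ev[ev] - d[ev] * (np.log(S0[ev]) + c)))


def breslow_gradient(beta, X, time, event) -> np.ndarray:
    Xs, ts, ds, starts, ends = _prep(X, time, event)
    beta = np.asarray(beta, dtype=float)
    eta = Xs @ beta
    c = eta.max() if eta.size else 0.0
    w = np.exp(eta - c)
    S0 = np.cumsum(w)[ends]
    S1 = np.cumsum(w[:, None] * Xs, axis=0)[ends]
    d = np.add.reduceat(ds, starts)
    x_ev = np.add.reduceat(ds[:, None] * Xs, starts, axis=0)
    ev = d > 0
    return x_ev[ev].sum(axis=0) - (d[ev] / S0[ev]) @ S1[ev]


def breslow_hessian(beta, X, time, event) -> np.ndarray:
    Xs, ts, ds, starts, ends = _prep(X, time, event)
    beta = np.asarray(beta, dtype=float)
    eta = Xs @ beta
    c = eta.max() if eta.size else 0.0
    w = np.exp(eta - c)
    S0 = np.cumsum(w)[ends]
    S1 = np.cumsum(w[:, None] * Xs, axis=0)[ends]
    d = np.add.reduceat(ds, starts)
    ev = d > 0
    # sum_k (d_k/S0_k) S2_k == X^T diag(w * a) X, where a_i accumulates
    # d/S0 over the event runs whose risk set contains row i — avoids ever
    # materializing the per-run p x p second moments
    r = np.where(ev, d / S0, 0.0)
    suffix = np.cumsum(r[::-1])[::-1]
    run_of_row = np.repeat(np.arange(len(starts)), ends - starts + 1)
    a = suffix[run_of_row]
    H = -(Xs * (w * a)[:, None]).T @ Xs
    m = S1[ev] / S0[ev][:, None]
    H += np.einsum("k,ki,kj->ij", d[ev], m, m)
    return H


def newton_cox(X, time, event, ridge: float = 0.0, max_iter: int = 100,
               tol: float = 1e-10, beta0=None) -> np.ndarray:
    """Newton-Raphson maximizer of the Breslow partial likelihood.

    With ``ridge`` > 0 the objective is the glmnet-scale penalized one,
    ``-loglik/n + ridge * ||beta||^2 / 2``; with ridge = 0 it is the plain
    partial likelihood.  Step-halving guards each update.  Raises on
    non-convergence (e.g. monotone likelihood).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()

    def objective(b):
        return -breslow_loglik(b, X, time, event) / n + 0.5 * ridge * float(b @ b)

    f = objective(beta)
    for _ in range(max_iter):
        g = -breslow_gradient(beta, X, time, event) / n + ridge * beta
        H = -breslow_hessian(beta, X, time, event) / n + ridge * np.eye(p)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        if not np.all(np.isfinite(step)):
            raise RuntimeError("Cox Newton step not finite (monotone likelihood?)")
        t = 1.0
        for _ in range(30):
            cand = beta - t * step
            f_new = objective(cand)
            if f_new <= f + 1e-12:
                break
            t /= 2
        else:
            break  # no descent possible: at optimum within line-search resolution
        moved = float(np.max(np.abs(t * step)))
        beta, f = cand, f_new
        if moved < tol:
            break
    else:
        raise RuntimeError("Cox Newton failed to converge")
    gfin = -breslow_gradient(beta, X, time, event) / n + ridge * beta
    if np.max(np.abs(gfin)) > 1e-4 * max(1.0, float(np.max(np.abs(beta)))):
        feat = int(np.argmax(np.abs(gfin)))
        raise RuntimeError(
            f"Cox fit did not converge (score residual on feature index {feat}); "
            "possible monotone likelihood"
        )
    return beta


def breslow_baseline(beta, X, time, event) -> tuple[np.ndarray, np.ndarray]:
    """Breslow baseline cumulative hazard on the event-time grid.

    Returns (unique event times ascending, H0 at those times), with the
    baseline referring to the all-zero covariate vector.
    """
    Xs, ts, ds, starts, ends = _prep(X, time, event)
    beta = np.asarray(beta, dtype=float)
    eta = Xs @ beta
    c = eta.max() if eta.size else 0.0
    S0 = np.cumsum(np.exp(eta - c))[ends]
    d = np.add.reduceat(ds, starts)
    ev = d > 0
    incr = d[ev] / (S0[ev] * np.exp(c))
    times = ts[ends][ev]
    # runs are in descending time order
    return times[::-1].copy(), np.cumsum(incr[::-1])
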