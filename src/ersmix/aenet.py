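"""Adaptive elastic net logistic regression, written as a from-scratch solver.

The estimator minimizes

    (1/n) * sum_i [log(1 + exp(eta_i)) - y_i * eta_i]
        + lambda * sum_j w_j * (mix * |beta_j| + (1 - mix)/2 * beta_j^2)

with an unpenalized intercept, by cyclic coordinate descent on a quadratic
majorization of the logistic loss (curvature bounded by 1/4), with active-set
sweeps and warm starts along a decreasing lambda path.

The adaptive ("two-stage") procedure fits a plain elastic net first, turns
its coefficient magnitudes into penalty weights w_j = (|b_j| + 1/n)^(-gamma),
and refits.  Weighting the L1 penalty by inverse first-stage magnitudes is
what buys selection consistency under the collinearity a metal panel shows;
the 1/n offset keeps every candidate eligible in stage two instead of hard
screening.  Model choice along the (mix, lambda) grid is by minimum mean
10-fold cross-validated binomial deviance with outcome-stratified folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .expansion import TermSet

__all__ = [
    "AENETFit",
    "ConvergenceError",
    "enet_logistic",
    "adaptive_weights",
    "lambda_max",
    "lambda_grid",
    "kkt_violation",
    "cv_fit",
]

DEFAULT_ALPHA_GRID = (0.1, 0.3, 0.5, 0.7, 0.9)


class ConvergenceError(RuntimeError):
    """Coordinate descent exhausted its sweep budget without converging."""


# ---------------------------------------------------------------- numba core
#
# Majorize-minimize solver with a Gram-cached quadratic.  At each refresh the
# logistic loss is replaced by the quadratic model
#
#     g'(beta - beta_hat) + (s/2) (beta - beta_hat)' G (beta - beta_hat)
#
# with g the exact gradient at the refresh point, G = X'X/n precomputed once
# per design (BLAS), and s a scalar curvature bound adapted to
# max_i mu_i(1-mu_i) (capped at the global logistic bound 1/4, with an
# objective-decrease safeguard that falls back to 1/4).  Cyclic coordinate
# descent on this quadratic costs O(active set) per coordinate — the data
# matrix is touched only in the O(n*p) gradient refresh — which is what makes
# dense, collinear candidate sets affordable.  Convergence is declared when a
# full pass over all coordinates at a freshly refreshed quadratic moves no
# coefficient (nor the intercept) by more than ``tol``.


@njit(cache=False, fastmath=True)
def _resid_refresh(y, eta, resid, W, n):
    """Residuals mu - y and weights mu(1-mu) at eta.

    Returns (g0, mean loss, mean weight, max weight).
    """
    g0 = 0.0
    loss = 0.0
    wsum = 0.0
    wmax = 0.0
    for i in range(n):
        e = eta[i]
        if e > 0.0:
            loss += e + np.log(1.0 + np.exp(-e)) - y[i] * e
        else:
            loss += np.log(1.0 + np.exp(e)) - y[i] * e
        ec = min(max(e, -30.0), 30.0)
        mu = 1.0 / (1.0 + np.exp(-ec))
        wi = mu * (1.0 - mu)
        if wi < 1e-6:
            wi = 1e-6
        W[i] = wi
        wsum += wi
        if wi > wmax:
            wmax = wi
        resid[i] = mu - y[i]
        g0 += resid[i]
    g0 /= n
    return g0, loss / n, wsum / n, wmax


@njit(cache=False, fastmath=True)
def _grad_cols(X, resid, g, cols, n):
    """Gradient entries g_j = (1/n) x_j'resid for the listed columns only."""
    for idx in range(cols.shape[0]):
        j = cols[idx]
        acc = 0.0
        for i in range(n):
            acc += X[i, j] * resid[i]
        g[j] = acc / n


@njit(cache=False, fastmath=True)
def _quad_pass(G, xmean, g, g0, s, w, l1, l2, beta, beta0, v, v0, db0, active_only):
    """One cyclic CD pass on the current quadratic model.

    ``v = G (beta - beta_refresh)`` and ``v0`` (its intercept analogue) are
    maintained incrementally; ``db0`` is beta0 - beta0_refresh.  Returns
    (maxd, beta0, v0, db0).
    """
    p = beta.shape[0]
    maxd = 0.0
    # intercept: curvature s, gradient g0 + s*(v0 + db0)
    # intercept effect on the j-th gradient is carried by db0 * xmean[j]
    d0 = -(g0 + s * (v0 + db0)) / s
    if d0 != 0.0:
        beta0 += d0
        db0 += d0
        if abs(d0) > maxd:
            maxd = abs(d0)
    for j in range(p):
        bj = beta[j]
        if active_only and bj == 0.0:
            continue
        aj = s * G[j, j] + l2 * w[j]
        if aj <= 0.0:
            continue
        rho = s * G[j, j] * bj - (g[j] + s * (v[j] + db0 * xmean[j]))
        thr = l1 * w[j]
        if rho > thr:
            bnew = (rho - thr) / aj
        elif rho < -thr:
            bnew = (rho + thr) / aj
        else:
            bnew = 0.0
        d = bnew - bj
        if d != 0.0:
            beta[j] = bnew
            for k in range(p):
                v[k] += d * G[k, j]
            v0 += d * xmean[j]
            if abs(d) > maxd:
                maxd = abs(d)
    return maxd, beta0, v0, db0


@njit(cache=False, fastmath=True)
def _penalty(beta, w, l1, l2):
    pen = 0.0
    for j in range(beta.shape[0]):
        b = beta[j]
        if b != 0.0:
            pen += w[j] * (l1 * abs(b) + 0.5 * l2 * b * b)
    return pen


@njit(cache=False, fastmath=True)
def _recompute_eta(X, beta, beta0, eta, n, p):
    for i in range(n):
        eta[i] = beta0
    for j in range(p):
        b = beta[j]
        if b != 0.0:
            for i in range(n):
                eta[i] += b * X[i, j]


@njit(cache=False, fastmath=True)
def _loss_only(y, eta, n):
    loss = 0.0
    for i in range(n):
        e = eta[i]
        if e > 0.0:
            loss += e + np.log(1.0 + np.exp(-e)) - y[i] * e
        else:
            loss += np.log(1.0 + np.exp(e)) - y[i] * e
    return loss / n


@njit(cache=False, fastmath=True)
def _fit_single(X, G, xmean, y, w, mix, lam, beta, beta0, eta, tol, max_sweeps):
    """Solve one (lambda, mix) problem in place; returns (beta0, sweeps, ok).

    ``beta`` and ``eta`` (the linear predictor) are updated in place so the
    caller can warm-start the next path point.
    """
    n, p = X.shape
    l1 = lam * mix
    l2 = lam * (1.0 - mix)
    sweeps = 0
    converged = False
    g = np.empty(p)
    v = np.empty(p)
    resid = np.empty(n)
    W = np.empty(n)
    beta_save = np.empty(p)
    all_cols = np.arange(p)
    active = np.empty(p, dtype=np.int64)
    Ga = np.empty((p, p))
    ga = np.empty(p)
    gwa = np.empty(p)
    va = np.empty(p)
    force_quarter = False
    irls_ok = True
    while sweeps < max_sweeps:
        # ---- outer: certification cycle with the full gradient ----
        g0, loss, wmean, wmax = _resid_refresh(y, eta, resid, W, n)
        _grad_cols(X, resid, g, all_cols, n)
        obj = loss + _penalty(beta, w, l1, l2)
        s = 0.25 if force_quarter else min(0.25, max(1.5 * wmean, 1e-3))
        for j in range(p):
            v[j] = 0.0
            beta_save[j] = beta[j]
        beta0_save = beta0
        v0 = 0.0
        db0 = 0.0
        maxd_full, beta0, v0, db0 = _quad_pass(
            G, xmean, g, g0, s, w, l1, l2, beta, beta0, v, v0, db0, False)
        sweeps += 1
        maxd = maxd_full
        inner_tol = max(tol, 0.1 * maxd_full)
        while maxd >= inner_tol and sweeps < max_sweeps:
            maxd, beta0, v0, db0 = _quad_pass(
                G, xmean, g, g0, s, w, l1, l2, beta, beta0, v, v0, db0, True)
            sweeps += 1
        _recompute_eta(X, beta, beta0, eta, n, p)
        if maxd_full < tol:
            converged = True
            break
        # safeguard: s < 1/4 is not a global majorizer; redo on ascent
        if not force_quarter and s < 0.25:
            new_obj = _loss_only(y, eta, n) + _penalty(beta, w, l1, l2)
            if new_obj > obj + 1e-12:
                for j in range(p):
                    beta[j] = beta_save[j]
                beta0 = beta0_save
                _recompute_eta(X, beta, beta0, eta, n, p)
                force_quarter = True
                continue
        # ---- middle: exact IRLS on the active set (weighted Gram) ----
        if not irls_ok:
            continue  # IRLS misbehaved for this problem; outer-only MM
        for _mid in range(100):
            na = 0
            for j in range(p):
                if beta[j] != 0.0:
                    active[na] = j
                    na += 1
            if na == 0 or na > 64:
                # dense active set: the O(n*na^2) weighted Gram rebuild is
                # no longer worth it; let the outer MM loop iterate instead
                break
            g0, loss, wmean, wmax = _resid_refresh(y, eta, resid, W, n)
            obj = loss + _penalty(beta, w, l1, l2)
            # weighted Gram, gradient, and intercept couplings on active cols
            w0 = 0.0
            for i in range(n):
                w0 += W[i]
            w0 /= n
            for a in range(na):
                j = active[a]
                acc_g = 0.0
                acc_w = 0.0
                for i in range(n):
                    acc_g += X[i, j] * resid[i]
                    acc_w += W[i] * X[i, j]
                ga[a] = acc_g / n
                gwa[a] = acc_w / n
                for b in range(a, na):
                    k = active[b]
                    acc = 0.0
                    for i in range(n):
                        acc += W[i] * X[i, j] * X[i, k]
                    Ga[a, b] = acc / n
                    Ga[b, a] = Ga[a, b]
            for j in range(p):
                beta_save[j] = beta[j]
            beta0_save = beta0
            for a in range(na):
                va[a] = 0.0
            v0a = 0.0
            db0 = 0.0
            maxd1 = -1.0
            maxd = 1e30
            inner_tol = tol
            while maxd >= inner_tol and sweeps < max_sweeps:
                maxd = 0.0
                d0 = -(g0 + v0a + w0 * db0) / w0
                if d0 != 0.0:
                    beta0 += d0
                    db0 += d0
                    if abs(d0) > maxd:
                        maxd = abs(d0)
                for a in range(na):
                    j = active[a]
                    bj = beta[j]
                    ajj = Ga[a, a] + l2 * w[j]
                    if ajj <= 0.0:
                        continue
                    rho = Ga[a, a] * bj - (ga[a] + va[a] + db0 * gwa[a])
                    thr = l1 * w[j]
                    if rho > thr:
                        bnew = (rho - thr) / ajj
                    elif rho < -thr:
                        bnew = (rho + thr) / ajj
                    else:
                        bnew = 0.0
                    d = bnew - bj
                    if d != 0.0:
                        beta[j] = bnew
                        for b in range(na):
                            va[b] += d * Ga[b, a]
                        v0a += d * gwa[a]
                        if abs(d) > maxd:
                            maxd = abs(d)
                sweeps += 1
                if maxd1 < 0.0:
                    maxd1 = maxd
                    inner_tol = max(tol, 0.1 * maxd1)
            _recompute_eta(X, beta, beta0, eta, n, p)
            if maxd1 < tol or sweeps >= max_sweeps:
                break
            new_obj = _loss_only(y, eta, n) + _penalty(beta, w, l1, l2)
            if new_obj > obj + 1e-12:
                # Newton overshoot: revert and fall back to safeguarded MM
                for j in range(p):
                    beta[j] = beta_save[j]
                beta0 = beta0_save
                _recompute_eta(X, beta, beta0, eta, n, p)
                irls_ok = False
                break
    return beta0, sweeps, converged


@njit(cache=False)
def _fit_path(X, G, xmean, y, w, mix, lambdas, tol, max_sweeps):
    """Warm-started solution path over a decreasing lambda grid."""
    n, p = X.shape
    K = lambdas.shape[0]
    B = np.zeros((K, p))
    b0s = np.empty(K)
    ok = np.zeros(K, np.int64)
    sweeps = np.zeros(K, np.int64)
    beta = np.zeros(p)
    ybar = 0.0
    for i in range(n):
        ybar += y[i]
    ybar /= n
    beta0 = np.log(ybar / (1.0 - ybar))
    eta = np.full(n, beta0)
    for k in range(K):
        beta0, used, conv = _fit_single(
            X, G, xmean, y, w, mix, lambdas[k], beta, beta0, eta, tol, max_sweeps)
        B[k, :] = beta
        b0s[k] = beta0
        ok[k] = 1 if conv else 0
        sweeps[k] = used
    return b0s, B, ok, sweeps


def _gram(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """G = X'X/n (BLAS) and per-column means, precomputed once per design."""
    n = X.shape[0]
    return np.ascontiguousarray(X.T @ X / n), X.mean(axis=0)


# ------------------------------------------------------------- python layer

def _validate(X, y, lam, mix, weights):
    X = np.asfortranarray(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X and y shapes disagree")
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, [0.0, 1.0])) or len(uniq) < 2:
        raise ValueError("y must be binary with both classes present")
    if lam is not None and lam < 0:
        raise ValueError("lambda must be >= 0")
    if mix is not None and not (0.0 <= mix <= 1.0):
        raise ValueError("mix must lie in [0, 1]")
    if weights is None:
        weights = np.ones(X.shape[1])
    weights = np.asarray(weights, dtype=np.float64).ravel()
    if weights.shape[0] != X.shape[1]:
        raise ValueError("one penalty weight per column required")
    if np.any(weights <= 0) or not np.all(np.isfinite(weights)):
        raise ValueError("penalty weights must be finite and > 0")
    return X, y, weights


def lambda_max(X, y, weights=None, mix: float = 1.0) -> float:
    """Smallest lambda that zeroes every coefficient: max_j |<x_j, y-ybar>|/(n*mix*w_j)."""
    X, y, weights = _validate(X, y, 0.0, mix, weights)
    n = len(y)
    score = np.abs(X.T @ (y - y.mean())) / (n * max(mix, 1e-3) * weights)
    return float(score.max())


def lambda_grid(lmax: float, count: int = 100, min_ratio: float = 1e-3) -> np.ndarray:
    """Log-spaced decreasing grid from lambda_max down to min_ratio * lambda_max."""
    return np.geomspace(lmax, lmax * min_ratio, count)


def enet_logistic(X, y, lam: float, mix: float, term_weights=None,
                  tol: float = 1e-7, max_sweeps: int = 10_000,
                  warm=None) -> tuple[float, np.ndarray]:
    """Weighted elastic net logistic fit at a single (lambda, mix) point.

    Returns (intercept, coefficients).  Raises :class:`ConvergenceError` if
    the sweep budget is exhausted before the max coefficient change per full
    cycle drops below ``tol``.
    """
    X, y, w = _validate(X, y, lam, mix, term_weights)
    n, p = X.shape
    G, xmean = _gram(X)
    if warm is not None:
        beta = np.array(warm[1], dtype=np.float64).copy()
        beta0 = float(warm[0])
    else:
        beta = np.zeros(p)
        ybar = y.mean()
        beta0 = float(np.log(ybar / (1 - ybar)))
    eta = beta0 + X @ beta
    beta0, used, conv = _fit_single(X, G, xmean, y, w, mix, lam, beta, beta0, eta,
                                    tol, max_sweeps)
    if not conv:
        raise ConvergenceError(
            f"coordinate descent did not converge in {used} sweeps "
            f"(lambda={lam:.4g}, mix={mix}, n={n}, p={p})")
    return float(beta0), beta


def adaptive_weights(stage1_coefficients, gamma: float = 1.0, n: int | None = None) -> np.ndarray:
    """Penalty weights w_j = (|b_j| + 1/n)^(-gamma) from a first-stage fit.

    The 1/n offset keeps weights finite for zero first-stage coefficients so
    every candidate remains eligible in stage two.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    if n is None or n < 1:
        raise ValueError("n (sample size for the 1/n offset) must be >= 1")
    b = np.abs(np.asarray(stage1_coefficients, dtype=float))
    return (b + 1.0 / n) ** (-gamma)


def kkt_violation(X, y, intercept: float, beta, lam: float, mix: float,
                  term_weights=None) -> float:
    """Max violation of the penalized-logistic KKT conditions at a solution.

    For active coordinates the subgradient must vanish; for inactive ones the
    plain gradient must sit inside the L1 threshold.  Used as the solver's
    correctness certificate.
    """
    X, y, w = _validate(X, y, lam, mix, term_weights)
    n = len(y)
    eta = intercept + X @ np.asarray(beta, dtype=float)
    mu = 1.0 / (1.0 + np.exp(-eta))
    g = X.T @ (mu - y) / n
    viol = abs(float(np.mean(mu - y)))  # intercept stationarity
    beta = np.asarray(beta, dtype=float)
    for j in range(X.shape[1]):
        if beta[j] != 0.0:
            sub = g[j] + lam * w[j] * ((1 - mix) * beta[j] + mix * np.sign(beta[j]))
            viol = max(viol, abs(sub))
        else:
            viol = max(viol, max(0.0, abs(g[j]) - lam * w[j] * mix))
    return viol


def binomial_deviance(eta: np.ndarray, y: np.ndarray) -> float:
    """Mean binomial deviance, -2 * mean(y*eta - log(1 + e^eta))."""
    return float(-2.0 * np.mean(y * eta - np.logaddexp(0.0, eta)))


def stratified_folds(y, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Outcome-stratified fold assignment; re-stratifies once, then errors."""
    y = np.asarray(y, dtype=int)
    for attempt in range(2):
        fold = np.empty(len(y), dtype=int)
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            fold[idx] = np.arange(len(idx)) % n_folds
        ok = all(len(np.unique(y[fold != f])) == 2 for f in range(n_folds))
        if ok:
            return fold
    raise ValueError(
        "could not stratify folds with both outcome classes in every "
        "training split; reduce the number of folds")


@dataclass
class AENETFit:
    """Everything the two-stage fit produced, for audit and reuse."""

    term_labels: list[str]
    stage1_intercept: float
    stage1_coefficients: np.ndarray
    stage1_alpha: float
    stage1_lambda: float
    adaptive_weights: np.ndarray
    cv_deviance: pd.DataFrame          # stage, alpha, lambda, mean_dev, se_dev
    selected_alpha: float
    selected_lambda: float
    intercept: float
    final_coefficients: np.ndarray
    fold_assignments: np.ndarray = field(repr=False)
    gamma: float = 1.0
    stage1_path: dict = field(default=None, repr=False)
    stage2_path: dict = field(default=None, repr=False)

    @property
    def selected_terms(self) -> list[str]:
        return [lab for lab, b in zip(self.term_labels, self.final_coefficients)
                if b != 0.0]

    @property
    def coefficients(self) -> pd.Series:
        return pd.Series(self.final_coefficients, index=self.term_labels)

    def to_dict(self) -> dict:
        return {
            "term_labels": self.term_labels,
            "stage1": {
                "intercept": self.stage1_intercept,
                "coefficients": self.stage1_coefficients.tolist(),
                "alpha": self.stage1_alpha,
                "lambda": self.stage1_lambda,
            },
            "adaptive_weights": self.adaptive_weights.tolist(),
            "gamma": self.gamma,
            "cv_deviance": self.cv_deviance.to_dict(orient="records"),
            "selected_alpha": self.selected_alpha,
            "selected_lambda": self.selected_lambda,
            "intercept": self.intercept,
            "final_coefficients": self.final_coefficients.tolist(),
            "selected_terms": self.selected_terms,
            "fold_assignments": self.fold_assignments.tolist(),
        }


def _prepare_folds(X, y, fold):
    """Per-fold training designs with their Gram matrices, computed once."""
    n_folds = int(fold.max()) + 1
    out = []
    for f in range(n_folds):
        tr = fold != f
        Xtr = np.asfortranarray(X[tr])
        G, xm = _gram(Xtr)
        out.append((tr, Xtr, G, xm, y[tr]))
    return out


#: CV early stop: abandon an alpha's lambda descent once this many grid
#: points have passed without a new mean-deviance minimum (the dense
#: overfitting tail is never competitive).
_CV_STOP_PATIENCE = 15


def _cv_stage(X, G_full, xmean_full, y, weights, fold_designs, alpha_grid,
              lambda_count, lambda_min_ratio, tol, cv_tol, max_sweeps,
              stage_name, early_stop=True, rule="min"):
    """CV over the (alpha, lambda) grid for fixed penalty weights.

    Folds advance down each alpha's lambda path in lockstep (warm-started);
    the descent stops early once the mean deviance is clearly past its
    minimum.  Grid points after the stop carry the last deviance forward and
    are flagged ``evaluated=False``.  ``rule`` picks the reported solution:
    ``"min"`` = minimum mean CV deviance; ``"1se"`` = the largest lambda (in
    the winning alpha's curve) within one SE of that minimum.  Returns
    (intercept, coefficients, best_alpha, best_lambda, cv_table, full_path).
    """
    n, p = X.shape
    n_folds = len(fold_designs)
    records = []
    best = (np.inf, None, None)
    for alpha in alpha_grid:
        lmax = lambda_max(X, y, weights, alpha)
        grid = lambda_grid(lmax, lambda_count, lambda_min_ratio)
        states = []
        for (tr, Xtr, Gtr, xmtr, ytr) in fold_designs:
            ybar = ytr.mean()
            b0 = float(np.log(ybar / (1 - ybar)))
            states.append([np.zeros(p), b0, np.full(len(ytr), b0)])
        mean_dev = np.full(len(grid), np.nan)
        se_dev = np.full(len(grid), np.nan)
        evaluated = np.zeros(len(grid), dtype=bool)
        run_min = np.inf
        worse = 0
        for k, lam in enumerate(grid):
            dev_f = np.empty(n_folds)
            for f, (tr, Xtr, Gtr, xmtr, ytr) in enumerate(fold_designs):
                beta, b0, eta = states[f]
                b0, used, conv = _fit_single(Xtr, Gtr, xmtr, ytr, weights,
                                             alpha, lam, beta, b0, eta,
                                             cv_tol, max_sweeps)
                if not conv:
                    raise ConvergenceError(
                        f"{stage_name}: fold {f} alpha {alpha} did not "
                        f"converge at lambda {lam:.4g} after {used} sweeps")
                states[f][1] = b0
                eta_val = b0 + X[~tr] @ beta
                yv = y[~tr]
                dev_f[f] = -2.0 * np.mean(yv * eta_val - np.logaddexp(0.0, eta_val))
            mean_dev[k] = dev_f.mean()
            se_dev[k] = dev_f.std(ddof=1) / np.sqrt(n_folds)
            evaluated[k] = True
            if mean_dev[k] < run_min:
                run_min = mean_dev[k]
                worse = 0
            else:
                worse += 1
                if early_stop and worse >= _CV_STOP_PATIENCE:
                    break
        # carry the last evaluated deviance forward for unvisited points
        last = int(np.flatnonzero(evaluated)[-1])
        mean_dev[last + 1:] = mean_dev[last]
        se_dev[last + 1:] = se_dev[last]
        for k in range(len(grid)):
            records.append((stage_name, alpha, grid[k], mean_dev[k], se_dev[k],
                            bool(evaluated[k])))
        ev_idx = np.flatnonzero(evaluated)
        k_min = int(ev_idx[np.argmin(mean_dev[ev_idx])])
        if rule == "1se":
            thresh = mean_dev[k_min] + se_dev[k_min]
            k_sel = int(ev_idx[np.flatnonzero(mean_dev[ev_idx] <= thresh)[0]])
        else:
            k_sel = k_min
        if mean_dev[k_min] < best[0]:
            best = (mean_dev[k_min], alpha, grid[:k_sel + 1])
    _, best_alpha, path_to_best = best
    b0s, B, ok, _ = _fit_path(X, G_full, xmean_full, y, weights, best_alpha,
                              path_to_best, tol, max_sweeps)
    if not ok.all():
        raise ConvergenceError(f"{stage_name}: full-data path failed to converge")
    table = pd.DataFrame(records,
                         columns=["stage", "alpha", "lambda", "mean_deviance",
                                  "se_deviance", "evaluated"])
    full_path = {"lambdas": path_to_best, "intercepts": b0s, "coefficients": B,
                 "alpha": float(best_alpha)}
    return (float(b0s[-1]), B[-1].copy(), float(best_alpha),
            float(path_to_best[-1]), table, full_path)


def cv_fit(termset, y, folds: int = 10, alpha_grid=DEFAULT_ALPHA_GRID,
           lambda_count: int = 100, lambda_min_ratio: float = 1e-3,
           gamma: float = 1.0, seed: int = 0, tol: float = 1e-7,
           cv_tol: float = 1e-4, max_sweeps: int = 10_000,
           early_stop: bool = True, selection_rule: str = "min") -> AENETFit:
    """Two-stage adaptive elastic net selection with stratified 10-fold CV.

    Stage 1 is a plain elastic net at its own CV-selected (alpha, lambda);
    its coefficients become adaptive penalty weights for the stage-2 search,
    whose minimum-deviance solution defines the selected term set.  Fold fits
    converge at ``cv_tol`` (a model-selection device); all full-data solutions
    use the tight ``tol`` and satisfy the KKT conditions.
    """
    if isinstance(termset, TermSet):
        labels = termset.labels
        X = termset.values.to_numpy(dtype=np.float64)
    elif isinstance(termset, pd.DataFrame):
        labels = list(termset.columns)
        X = termset.to_numpy(dtype=np.float64)
    else:
        X = np.asarray(termset, dtype=np.float64)
        labels = [f"x{j}" for j in range(X.shape[1])]
    X = np.asfortranarray(X)
    y = np.asarray(y, dtype=np.float64).ravel()
    _validate(X, y, 0.0, 0.5, None)
    n = len(y)
    if n < folds:
        raise ValueError("need at least as many subjects as folds")
    rng = np.random.default_rng(seed)
    fold = stratified_folds(y, folds, rng)
    G_full, xmean_full = _gram(X)
    fold_designs = _prepare_folds(X, y, fold)

    ones = np.ones(X.shape[1])
    # stage 1 supplies weight information, not parsimony: always lambda-min
    s1_b0, s1_beta, s1_alpha, s1_lambda, s1_table, s1_path = _cv_stage(
        X, G_full, xmean_full, y, ones, fold_designs, alpha_grid,
        lambda_count, lambda_min_ratio, tol, cv_tol, max_sweeps, "stage1",
        early_stop, rule="min")

    w = adaptive_weights(s1_beta, gamma=gamma, n=n)
    s2_b0, s2_beta, s2_alpha, s2_lambda, s2_table, s2_path = _cv_stage(
        X, G_full, xmean_full, y, w, fold_designs, alpha_grid,
        lambda_count, lambda_min_ratio, tol, cv_tol, max_sweeps, "stage2",
        early_stop, rule=selection_rule)

    return AENETFit(
        term_labels=labels,
        stage1_intercept=s1_b0,
        stage1_coefficients=s1_beta,
        stage1_alpha=s1_alpha,
        stage1_lambda=s1_lambda,
        adaptive_weights=w,
        cv_deviance=pd.concat([s1_table, s2_table], ignore_index=True),
        selected_alpha=s2_alpha,
        selected_lambda=s2_lambda,
        intercept=s2_b0,
        final_coefficients=s2_beta,
        fold_assignments=fold,
        gamma=gamma,
        stage1_path=s1_path,
        stage2_path=s2_path,
    )
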