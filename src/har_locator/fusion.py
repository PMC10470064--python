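"""Feature fusion and stepwise discriminant analysis with Wilks' lambda.

Wilks' lambda of a feature subset S is det(W_S)/det(T_S) with W the pooled
within-class scatter and T the total scatter; small lambda means strong
between-class separation.  Selection is classic forward stepwise with
backward checks: the candidate minimizing the partial lambda enters when
its partial F exceeds ``f_enter``; any included feature whose partial F
falls below ``f_remove`` leaves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ConfigurationError(ValueError):
    pass


@dataclass
class SdaResult:
    """Ordered selected indices with the lambda value after each step."""

    selected: list
    lambda_trace: list
    f_enter: float
    f_remove: float


def concat_features(abstract, shallow) -> np.ndarray:
    """Concatenate abstract-block-first feature vector (validates finiteness).

    ``shallow`` may be a :class:`~har_locator.shallow.ShallowVector` or a
    plain array; an empty abstract block returns the shallow vector alone.
    """
    sh = getattr(shallow, "vector", shallow)
    sh = np.asarray(sh, dtype=float)
    ab = np.asarray(abstract, dtype=float).ravel()
    out = np.concatenate([ab, sh])
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite feature value")
    return out


def _scatter(X, y):
    """Within-class and total scatter matrices (ridge-free)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    mean = X.mean(axis=0)
    Xc = X - mean
    T = Xc.T @ Xc
    W = np.zeros_like(T)
    for cls in np.unique(y):
        Z = X[y == cls] - X[y == cls].mean(axis=0)
        W += Z.T @ Z
    return W, T


def wilks_lambda(X, y, ridge=None) -> float:
    """Wilks' lambda det(W)/det(T) in (0, 1].

    ``ridge=None`` applies the default guard eps = 1e-8 * trace(T)/p to both
    scatter matrices when T is singular.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    n, p = X.shape
    if n <= len(np.unique(y)):
        raise ValueError("need more samples than classes")
    W, T = _scatter(X, y)
    sign_t, logdet_t = np.linalg.slogdet(T)
    if sign_t <= 0:
        eps = (1e-8 * np.trace(T) / p) if ridge is None else ridge
        eps = max(eps, 1e-12)
        W = W + eps * np.eye(p)
        T = T + eps * np.eye(p)
        sign_t, logdet_t = np.linalg.slogdet(T)
    sign_w, logdet_w = np.linalg.slogdet(W)
    if sign_w <= 0:
        return 0.0
    return float(min(1.0, np.exp(logdet_w - logdet_t)))


def _schur_all(M, sel, cand):
    """Schur complements M_jj - M_jS M_SS^{-1} M_Sj for all candidates j."""
    if not sel:
        return np.diag(M)[cand].copy()
    Mss = M[np.ix_(sel, sel)]
    Msc = M[np.ix_(sel, cand)]
    try:
        sol = np.linalg.solve(Mss, Msc)
    except np.linalg.LinAlgError:
        sol = np.linalg.lstsq(Mss, Msc, rcond=None)[0]
    return np.diag(M)[cand] - np.einsum("ij,ij->j", Msc, sol)


def _lambda_of(W, T, sel, ridge_eps):
    if not sel:
        return 1.0
    idx = np.ix_(sel, sel)
    Ws, Ts = W[idx], T[idx]
    sign_t, ld_t = np.linalg.slogdet(Ts)
    if sign_t <= 0:
        k = len(sel)
        Ws = Ws + ridge_eps * np.eye(k)
        Ts = Ts + ridge_eps * np.eye(k)
        sign_t, ld_t = np.linalg.slogdet(Ts)
    sign_w, ld_w = np.linalg.slogdet(Ws)
    if sign_w <= 0:
        return 0.0
    return float(min(1.0, np.exp(ld_w - ld_t)))


def sda_select(X, y, f_enter=3.84, f_remove=2.71, max_features=None) -> SdaResult:
    """Forward-stepwise Wilks'-lambda selection with backward elimination.

    Ties on the partial lambda break toward the lowest column index.  The
    selected subset size never exceeds min(p, max_features, n - g - 1).
    """
    if f_remove >= f_enter:
        raise ConfigurationError("f_remove must be < f_enter (oscillation risk)")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    g = len(np.unique(y))
    cap = min(p, n - g - 1)
    if max_features is not None:
        cap = min(cap, max_features)
    W, T = _scatter(X, y)
    ridge_eps = max(1e-8 * np.trace(T) / p, 1e-12)
    tol = 1e-10 * max(np.trace(T) / p, 1.0)

    selected: list = []
    trace: list = []
    lam = 1.0
    changed = True
    while changed and len(selected) < cap:
        changed = False
        cand = [j for j in range(p) if j not in selected]
        if cand:
            sw = _schur_all(W, selected, cand)
            st = _schur_all(T, selected, cand)
            valid = st > tol
            if valid.any():
                ratio = np.full(len(cand), np.inf)
                ratio[valid] = np.maximum(sw[valid], 0.0) / st[valid]
                best = int(np.argmin(ratio))  # argmin takes lowest index on ties
                lam_new = lam * min(ratio[best], 1.0)
                k = len(selected)
                if lam_new <= 0:
                    f_stat = np.inf
                else:
                    f_stat = ((n - g - k) / (g - 1)) * (lam / lam_new - 1.0)
                if f_stat > f_enter and (n - g - k) > 0:
                    selected.append(cand[best])
                    lam = _lambda_of(W, T, selected, ridge_eps)
                    trace.append(lam)
                    changed = True
        # backward checks
        while len(selected) > 1:
            k = len(selected)
            fr = []
            for i, feat in enumerate(selected):
                rest = selected[:i] + selected[i + 1 :]
                lam_wo = _lambda_of(W, T, rest, ridge_eps)
                if lam <= 0:
                    fr.append(np.inf)
                else:
                    fr.append(((n - g - k + 1) / (g - 1)) * (lam_wo / lam - 1.0))
            worst = int(np.argmin(fr))
            if fr[worst] < f_remove:
                selected.pop(worst)
                lam = _lambda_of(W, T, selected, ridge_eps)
                trace.append(lam)
                changed = True
            else:
                break
    return SdaResult(selected=selected, lambda_trace=trace, f_enter=f_enter, f_remove=f_remove)
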