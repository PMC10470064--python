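"""Independent brute-force oracles used across the test suite.

Every function here is a from-scratch transcription of the relevant
definition (double loops, exhaustive enumeration, closed forms) sharing no
code with the package implementation it checks.
"""

import numpy as np


def glcm_bruteforce(quantized, offset, levels):
    """Symmetric normalized co-occurrence by explicit double loop."""
    dr, dc = offset
    h, w = quantized.shape
    m = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                i, j = quantized[r, c], quantized[r2, c2]
                m[i, j] += 1
                m[j, i] += 1
    s = m.sum()
    return m / s if s else m


def haralick_bruteforce(p):
    """Second independent transcription of the 13 Haralick statistics.

    Same conventions as the implementation: natural log, 0*log0 = 0,
    correlation-type statistics 0 on zero marginal variance, sum variance
    about the sum mean.
    """
    L = p.shape[0]
    out = {}
    px = [sum(p[i, j] for j in range(L)) for i in range(L)]
    py = [sum(p[i, j] for i in range(L)) for j in range(L)]
    mx = sum(i * px[i] for i in range(L))
    my = sum(j * py[j] for j in range(L))
    vx = sum((i - mx) ** 2 * px[i] for i in range(L))
    vy = sum((j - my) ** 2 * py[j] for j in range(L))

    def xlogx(v):
        return v * np.log(v) if v > 0 else 0.0

    out["energy"] = sum(p[i, j] ** 2 for i in range(L) for j in range(L))
    out["contrast"] = sum((i - j) ** 2 * p[i, j] for i in range(L) for j in range(L))
    if vx > 0 and vy > 0:
        out["correlation"] = (
            sum(i * j * p[i, j] for i in range(L) for j in range(L)) - mx * my
        ) / np.sqrt(vx * vy)
    else:
        out["correlation"] = 0.0
    out["variance"] = sum((i - mx) ** 2 * p[i, j] for i in range(L) for j in range(L))
    out["inverse_difference_moment"] = sum(
        p[i, j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L)
    )
    psum = [0.0] * (2 * L - 1)
    pdiff = [0.0] * L
    for i in range(L):
        for j in range(L):
            psum[i + j] += p[i, j]
            pdiff[abs(i - j)] += p[i, j]
    out["sum_average"] = sum(k * psum[k] for k in range(2 * L - 1))
    out["sum_variance"] = sum(
        (k - out["sum_average"]) ** 2 * psum[k] for k in range(2 * L - 1)
    )
    out["sum_entropy"] = -sum(xlogx(v) for v in psum)
    out["entropy"] = -sum(xlogx(p[i, j]) for i in range(L) for j in range(L))
    dmean = sum(k * pdiff[k] for k in range(L))
    out["difference_variance"] = sum((k - dmean) ** 2 * pdiff[k] for k in range(L))
    out["difference_entropy"] = -sum(xlogx(v) for v in pdiff)
    hxy = out["entropy"]
    hxy1 = -sum(
        p[i, j] * np.log(px[i] * py[j])
        for i in range(L)
        for j in range(L)
        if p[i, j] > 0 and px[i] * py[j] > 0
    )
    hxy2 = -sum(xlogx(px[i] * py[j]) for i in range(L) for j in range(L))
    hx = -sum(xlogx(v) for v in px)
    hy = -sum(xlogx(v) for v in py)
    denom = max(hx, hy)
    out["info_correlation_1"] = (hxy - hxy1) / denom if denom > 0 else 0.0
    out["info_correlation_2"] = np.sqrt(max(0.0, 1 - np.exp(-2 * (hxy2 - hxy))))
    order = (
        "energy",
        "contrast",
        "correlation",
        "variance",
        "inverse_difference_moment",
        "sum_average",
        "sum_variance",
        "sum_entropy",
        "entropy",
        "difference_variance",
        "difference_entropy",
        "info_correlation_1",
        "info_correlation_2",
    )
    return np.array([out[k] for k in order])


def lbp_code_bruteforce(patch):
    """LBP code of the center of a 3x3 patch by explicit bit assembly."""
    c = patch[1, 1]
    clockwise = [
        patch[0, 0],
        patch[0, 1],
        patch[0, 2],
        patch[1, 2],
        patch[2, 2],
        patch[2, 1],
        patch[2, 0],
        patch[1, 0],
    ]
    code = 0
    for bit, nb in enumerate(clockwise):
        if nb >= c:
            code += 2 ** bit
    return code


def wilks_lambda_eigen(X, y):
    """Wilks' lambda as prod 1/(1+theta_i), theta_i eigenvalues of W^-1 B."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    mean = X.mean(axis=0)
    W = np.zeros((X.shape[1], X.shape[1]))
    B = np.zeros_like(W)
    for cls in np.unique(y):
        Xc = X[y == cls]
        mc = Xc.mean(axis=0)
        W += (Xc - mc).T @ (Xc - mc)
        B += len(Xc) * np.outer(mc - mean, mc - mean)
    theta = np.linalg.eigvals(np.linalg.solve(W, B))
    return float(np.prod(1.0 / (1.0 + theta.real)))


def attention_h3_bruteforce(x, p11w, p11b, p21w, p21b, p12w, p12b, p22w, p22b):
    """Straight-line transcription of the hybrid-attention equations for the
    identity bottom branch on a single-sample (C, H, W) input.

    P = p21(relu(p11(X))), G = p22(relu(p12(gap(X)))) broadcast,
    X' = sigmoid(P + G) * X.  Pointwise convs are per-pixel matrix products.
    """
    C, H, W = x.shape
    cmid = p11w.shape[0]
    P = np.zeros_like(x)
    for r in range(H):
        for c in range(W):
            v = x[:, r, c]
            h1 = np.maximum(p11w @ v + p11b, 0.0)
            P[:, r, c] = p21w @ h1 + p21b
    gap = np.array([x[ch].mean() for ch in range(C)])
    h2 = np.maximum(p12w @ gap + p12b, 0.0)
    G = p22w @ h2 + p22b
    out = np.zeros_like(x)
    for r in range(H):
        for c in range(W):
            gate = 1.0 / (1.0 + np.exp(-(P[:, r, c] + G)))
            out[:, r, c] = gate * x[:, r, c]
    return out


def auc_mann_whitney(y_bin, scores):
    """AUC by exhaustive positive/negative pair counting (ties = 1/2)."""
    pos = scores[y_bin == 1]
    neg = scores[y_bin == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def sda_greedy_bruteforce(X, y, f_enter, f_remove, max_features=None):
    """Forward-stepwise path by exhaustive per-step candidate scan.

    Recomputes full Wilks' lambda (via the eigen formulation when possible,
    determinants otherwise) for every candidate subset at every step.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    g = len(np.unique(y))

    def lam(subset):
        Xs = X[:, subset]
        mean = Xs.mean(axis=0)
        W = np.zeros((len(subset), len(subset)))
        for cls in np.unique(y):
            Z = Xs[y == cls] - Xs[y == cls].mean(axis=0)
            W += Z.T @ Z
        T = (Xs - mean).T @ (Xs - mean)
        return np.linalg.det(W) / np.linalg.det(T)

    cap = min(p, n - g - 1, max_features if max_features else p)
    selected = []
    lam_cur = 1.0
    while len(selected) < cap:
        cands = [j for j in range(p) if j not in selected]
        lams = []
        for j in cands:
            try:
                lams.append(lam(selected + [j]))
            except np.linalg.LinAlgError:
                lams.append(np.inf)
        best = int(np.argmin(lams))
        lam_new = lams[best]
        k = len(selected)
        if lam_new <= 0:
            f = np.inf
        else:
            f = ((n - g - k) / (g - 1)) * (lam_cur / lam_new - 1)
        if f > f_enter and (n - g - k) > 0:
            selected.append(cands[best])
            lam_cur = lam_new
        else:
            break
        # backward check
        while len(selected) > 1:
            k = len(selected)
            frs = []
            for i in range(len(selected)):
                rest = selected[:i] + selected[i + 1 :]
                frs.append(((n - g - k + 1) / (g - 1)) * (lam(rest) / lam_cur - 1))
            worst = int(np.argmin(frs))
            if frs[worst] < f_remove:
                selected.pop(worst)
                lam_cur = lam(selected)
            else:
                break
    return selected
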