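"""Linear max-margin (C-SVC) solver.

Sequential minimal optimization on the standard C-SVC dual

    min  1/2 sum_ij a_i a_j y_i y_j K_ij - sum_i a_i
    s.t. 0 <= a_i <= C,   sum_i a_i y_i = 0

with maximal-violating-pair working-set selection and the usual
(m + M)/2 intercept.  This is the same problem libsvm solves for
``SVC(kernel='linear')``; agreement with sklearn is asserted in the test
suite.  The solver is written here (numba-jitted) because the
permutation stages of the pipeline refit the classifier millions of
times on very small problems (tens of trials, tens to ~100 voxels),
where per-call overhead dominates everything else.

Deterministic: ties in working-set selection go to the lowest index and
no randomness is used, so repeated fits on identical input are
bit-identical.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["fit_linear_svm", "smo_solve"]


@njit(cache=True)
def smo_solve(K, y, C, tol, max_iter):  # pragma: no cover - exercised via wrapper
    """Solve the C-SVC dual for Gram matrix K and labels y in {-1,+1}.

    Returns (alpha, b, n_iter).
    """
    n = K.shape[0]
    alpha = np.zeros(n)
    # f_t = sum_j alpha_j y_j K_tj ; gradient bookkeeping
    f = np.zeros(n)
    b = 0.0
    it = 0
    while it < max_iter:
        it += 1
        # maximal violating pair over  gneg_t = y_t - f_t
        m = -1e300
        M = 1e300
        i = -1
        j = -1
        for t in range(n):
            g = y[t] - f[t]
            up = (y[t] > 0.0 and alpha[t] < C) or (y[t] < 0.0 and alpha[t] > 0.0)
            lo = (y[t] < 0.0 and alpha[t] < C) or (y[t] > 0.0 and alpha[t] > 0.0)
            if up and g > m:
                m = g
                i = t
            if lo and g < M:
                M = g
                j = t
        if i < 0 or j < 0 or m - M < tol:
            b = 0.5 * (m + M)
            break
        # two-variable analytic step (Platt), E_t = f_t - y_t
        Ei = f[i] - y[i]
        Ej = f[j] - y[j]
        eta = K[i, i] + K[j, j] - 2.0 * K[i, j]
        if eta < 1e-12:
            eta = 1e-12
        aj_old = alpha[j]
        ai_old = alpha[i]
        aj_new = aj_old + y[j] * (Ei - Ej) / eta
        if y[i] == y[j]:
            L = max(0.0, ai_old + aj_old - C)
            H = min(C, ai_old + aj_old)
        else:
            L = max(0.0, aj_old - ai_old)
            H = min(C, C + aj_old - ai_old)
        if aj_new < L:
            aj_new = L
        elif aj_new > H:
            aj_new = H
        d_j = aj_new - aj_old
        if abs(d_j) < 1e-14:
            # numerically stuck violating pair: accept current iterate
            b = 0.5 * (m + M)
            break
        ai_new = ai_old + y[i] * y[j] * (aj_old - aj_new)
        # snap to the box so float dirt cannot keep a bound variable in
        # the working set (stalls selection one ulp from the bound)
        if ai_new < 1e-12:
            ai_new = 0.0
        elif ai_new > C - 1e-12:
            ai_new = C
        if aj_new < 1e-12:
            aj_new = 0.0
        elif aj_new > C - 1e-12:
            aj_new = C
        alpha[i] = ai_new
        alpha[j] = aj_new
        d_i = ai_new - ai_old
        d_j = aj_new - aj_old
        for t in range(n):
            f[t] += d_i * y[i] * K[t, i] + d_j * y[j] * K[t, j]
    else:
        # hit max_iter: compute intercept from current gradient
        m = -1e300
        M = 1e300
        for t in range(n):
            g = y[t] - f[t]
            up = (y[t] > 0.0 and alpha[t] < C) or (y[t] < 0.0 and alpha[t] > 0.0)
            lo = (y[t] < 0.0 and alpha[t] < C) or (y[t] > 0.0 and alpha[t] > 0.0)
            if up and g > m:
                m = g
            if lo and g < M:
                M = g
        b = 0.5 * (m + M)
    return alpha, b, it


def fit_linear_svm(X: np.ndarray, y: np.ndarray, C: float = 1.0,
                   tol: float = 1e-4, max_iter: int = 100_000):
    """Fit a linear C-SVC; return (w, b) of the decision rule w.x + b.

    Parameters
    ----------
    X : (n_samples, n_features) float array.
    y : (n_samples,) array of +1/-1 labels.
    C : box constraint (regularization), must be > 0.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    K = X @ X.T
    alpha, b, _ = smo_solve(K, y, float(C), float(tol), int(max_iter))
    w = X.T @ (alpha * y)
    return w, b
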