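"""Fast linear soft-margin SVM on a precomputed Gram matrix.

Dual coordinate descent on the hinge-loss dual (the Hsieh et al. 2008
algorithm used by liblinear: randomly permuted sweeps, active-set
shrinking, projected-gradient stopping rule) with the bias handled as an
augmented kernel constant, plus one-vs-one voting for multi-class
problems. This is the package's default decoding engine: permutation
inference reruns thousands of cross-validations on a fixed Gram matrix,
where the generic libsvm QP solver is orders of magnitude too slow on
permuted (non-separable) labels. Predictions agree with sklearn.svm.SVC,
which the test suite keeps as an independent reference engine.
"""

from __future__ import annotations

import numpy as np
from numba import njit

DEFAULT_TOL = 0.1  # liblinear's default projected-gradient tolerance
MAX_EPOCHS = 150  # sweep cap; solutions are prediction-stable well before this
_BIG = 1e30


@njit(cache=True)
def _dcd_fit(Kb: np.ndarray, y: np.ndarray, C: float, eps: float, max_epochs: int):
    """Solve min 0.5 a'Qa - e'a, 0 <= a <= C, Q_ij = y_i y_j Kb_ij."""
    n = Kb.shape[0]
    alpha = np.zeros(n)
    s = np.zeros(n)  # s_j = sum_i alpha_i y_i Kb_ij
    idx = np.arange(n)
    active = n
    proj_max_old = _BIG
    proj_min_old = -_BIG
    state = np.uint64(88172645463325252)
    for _ in range(max_epochs):
        proj_max = -_BIG
        proj_min = _BIG
        # Fisher-Yates shuffle of the active slice (xorshift64)
        for t in range(active - 1, 0, -1):
            state ^= state << np.uint64(13)
            state ^= state >> np.uint64(7)
            state ^= state << np.uint64(17)
            j = int(state % np.uint64(t + 1))
            idx[t], idx[j] = idx[j], idx[t]
        pos = 0
        while pos < active:
            i = idx[pos]
            G = y[i] * s[i] - 1.0
            a = alpha[i]
            PG = 0.0
            if a == 0.0:
                if G > proj_max_old:
                    active -= 1
                    idx[pos], idx[active] = idx[active], idx[pos]
                    continue
                if G < 0.0:
                    PG = G
            elif a >= C:
                if G < proj_min_old:
                    active -= 1
                    idx[pos], idx[active] = idx[active], idx[pos]
                    continue
                if G > 0.0:
                    PG = G
            else:
                PG = G
            if PG > proj_max:
                proj_max = PG
            if PG < proj_min:
                proj_min = PG
            if PG != 0.0:
                qii = Kb[i, i]
                if qii > 0.0:
                    anew = a - G / qii
                    if anew < 0.0:
                        anew = 0.0
                    elif anew > C:
                        anew = C
                    d = anew - a
                    if d != 0.0:
                        alpha[i] = anew
                        yi = y[i]
                        for jj in range(n):
                            s[jj] += d * yi * Kb[i, jj]
            pos += 1
        if proj_max - proj_min < eps:
            if active == n:
                break
            # converged on the shrunk set: re-activate everything, final pass
            active = n
            proj_max_old = _BIG
            proj_min_old = -_BIG
        else:
            proj_max_old = proj_max if proj_max > 0.0 else _BIG
            proj_min_old = proj_min if proj_min < 0.0 else -_BIG
    return alpha


@njit(cache=True)
def _ovo_predict_votes(
    K_tr: np.ndarray,
    K_te_tr: np.ndarray,
    ytr: np.ndarray,
    n_classes: int,
    C: float,
    eps: float,
    max_epochs: int,
) -> np.ndarray:
    """One-vs-one vote matrix for test samples; kernel rows exclude the bias.

    The bias is an augmented kernel constant scaled to the mean kernel
    diagonal, which leaves the intercept effectively unregularized at the
    data's own scale (predictions then match the free-intercept libsvm
    solution).
    """
    n_te = K_te_tr.shape[0]
    n_tr = K_tr.shape[0]
    bias = 0.0
    for i in range(n_tr):
        bias += K_tr[i, i]
    bias = bias / n_tr if n_tr > 0 else 1.0
    if bias <= 0.0:
        bias = 1.0
    votes = np.zeros((n_te, n_classes))
    for a in range(n_classes):
        for b in range(a + 1, n_classes):
            idx = np.flatnonzero((ytr == a) | (ytr == b))
            m = len(idx)
            Kb = np.empty((m, m))
            for p in range(m):
                for q in range(m):
                    Kb[p, q] = K_tr[idx[p], idx[q]] + bias
            ypm = np.empty(m)
            for p in range(m):
                ypm[p] = 1.0 if ytr[idx[p]] == a else -1.0
            alpha = _dcd_fit(Kb, ypm, C, eps, max_epochs)
            coef = alpha * ypm
            for t in range(n_te):
                f = 0.0
                for p in range(m):
                    f += coef[p] * (K_te_tr[t, idx[p]] + bias)
                if f > 0.0:
                    votes[t, a] += 1.0
                else:
                    votes[t, b] += 1.0
    return votes


def ovo_svm_predict(
    K_tr: np.ndarray,
    K_te_tr: np.ndarray,
    ytr: np.ndarray,
    n_classes: int,
    C: float = 1.0,
    tol: float = DEFAULT_TOL,
    max_epochs: int = MAX_EPOCHS,
) -> np.ndarray:
    """Predicted class labels for test samples given a precomputed kernel."""
    votes = _ovo_predict_votes(
        np.ascontiguousarray(K_tr, dtype=np.float64),
        np.ascontiguousarray(K_te_tr, dtype=np.float64),
        np.ascontiguousarray(ytr, dtype=np.int64),
        n_classes,
        float(C),
        float(tol),
        int(max_epochs),
    )
    return votes.argmax(axis=1)
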