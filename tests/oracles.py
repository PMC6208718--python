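"""Independent reference implementations used only to check the package.

Every oracle here computes its answer by a route disjoint from the code
under test: direct textbook formulas, closed forms via eigen/SVD
decompositions with scalar root finding, scikit-learn's coordinate
descent (for the penalized regressions, after an algebraic parameter
conversion), and an explicit a-trous filter cascade with hand-written
db2 taps (for the stationary wavelet transform).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from sklearn.linear_model import ElasticNet, MultiTaskElasticNet

# Analytic Daubechies-2 filter taps, laid out in the pywt/Matlab filter-bank
# order (dec_lo); the highpass is the quadrature mirror hi[k] = (-1)^(k+1) lo[L-1-k].
_S3 = np.sqrt(3.0)
DB2_LO = np.array([1.0 - _S3, 3.0 - _S3, 3.0 + _S3, 1.0 + _S3]) / (4.0 * np.sqrt(2.0))
DB2_HI = np.array([(-1.0) ** (k + 1) * DB2_LO[len(DB2_LO) - 1 - k]
                   for k in range(len(DB2_LO))])


def pearson_direct(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook covariance / (sd * sd) Pearson correlation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    cov = np.sum((x - x.mean()) * (y - y.mean())) / n
    sx = np.sqrt(np.sum((x - x.mean()) ** 2) / n)
    sy = np.sqrt(np.sum((y - y.mean()) ** 2) / n)
    return float(cov / (sx * sy))


def ridge_normal_equations(A: np.ndarray, B: np.ndarray, lam: float) -> np.ndarray:
    """min ||A P - B||_F^2 + lam ||P||_F^2 via the normal equations."""
    q = A.shape[1]
    return np.linalg.solve(A.T @ A + lam * np.eye(q), A.T @ B)


def elastic_net_objective(A, P, B, lam, alpha) -> float:
    """Columnwise elastic-net objective summed over columns."""
    P = np.atleast_2d(P)
    B = np.atleast_2d(B)
    return float(
        np.sum((A @ P - B) ** 2)
        + lam * ((1 - alpha) / 2 * np.sum(P**2) + alpha * np.abs(P).sum())
    )


def sklearn_columnwise_en(A, B, lam, alpha) -> np.ndarray:
    """Decoupled elastic net via scikit-learn's coordinate descent.

    Our objective carries no 1/(2n) loss factor, so
    ``alpha_sklearn = lam / (2 r)`` and ``l1_ratio = alpha``.
    """
    r = A.shape[0]
    est = ElasticNet(alpha=lam / (2.0 * r), l1_ratio=alpha,
                     fit_intercept=False, tol=1e-12, max_iter=1000000)
    est.fit(A, B)
    return np.atleast_2d(est.coef_).T if B.ndim > 1 else est.coef_


def sklearn_multitask_en(A, B, lam, alpha) -> np.ndarray:
    """Row-grouped (multitask) elastic net via scikit-learn (alpha > 0)."""
    r = A.shape[0]
    est = MultiTaskElasticNet(alpha=lam / (2.0 * r), l1_ratio=alpha,
                              fit_intercept=False, tol=1e-14, max_iter=1000000)
    est.fit(A, B)
    return est.coef_.T


def single_group_elastic_net(A: np.ndarray, b: np.ndarray,
                             lam: float, alpha: float) -> np.ndarray:
    """Closed-form solve of ``min ||A w - b||^2 + lam[(1-a)/2 |w|^2 + a |w|_2]``.

    The whole vector is one group.  Optimality: w = 0 iff
    ``||2 A^T b||_2 <= lam * alpha``; otherwise w solves
    ``(2 A^T A + lam(1-a) I + lam a / t I) w = 2 A^T b`` with t = ||w||_2,
    found by scalar root finding on the eigenbasis of the quadratic.
    """
    q = A.shape[1]
    c = 2.0 * A.T @ b
    la = lam * alpha
    if np.linalg.norm(c) <= la:
        return np.zeros(q)
    M = 2.0 * A.T @ A + lam * (1.0 - alpha) * np.eye(q)
    d, Q = np.linalg.eigh(M)
    ct = Q.T @ c
    # c lies in the row space of A, so null-space components of ct are
    # exact zeros up to rounding; discard them before bracketing
    mask = d > d.max() * 1e-12
    ct = np.where(mask, ct, 0.0)
    if la == 0.0:
        return Q @ np.where(mask, ct / np.where(mask, d, 1.0), 0.0)
    nc = np.linalg.norm(ct)
    if nc <= la:
        return np.zeros(q)

    def gap(t):
        return np.sqrt(np.sum((ct * t / (d * t + la)) ** 2)) - t

    # at the root t* = ||w||: (nc - la)/d_max <= t* <= (nc - la)/d_min,
    # with d_min over components carrying coefficient mass
    d_min = d[mask].min()
    lo = 0.5 * (nc - la) / d.max()
    hi = 2.0 * (nc - la) / d_min + 1.0
    t = brentq(gap, lo, hi, xtol=5e-16, rtol=8.9e-16, maxiter=500)
    return Q @ (ct * t / (d * t + la))


def columns_group_elastic_net(A, B, lam, alpha) -> np.ndarray:
    """Column-grouped multitask EN: separable, solved column by column."""
    B = np.atleast_2d(B)
    return np.column_stack([
        single_group_elastic_net(A, B[:, k], lam, alpha)
        for k in range(B.shape[1])
    ])


# ---------------------------------------------------------------------------
# Stationary wavelet transform: a-trous cascade and average-of-shifts inverse
# ---------------------------------------------------------------------------

def _circ_conv(x: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Circular convolution: out[i] = sum_k f[k] x[i-k]."""
    out = np.zeros_like(x, dtype=float)
    for k, fk in enumerate(f):
        out += fk * np.roll(x, k)
    return out


def swt_atrous(x: np.ndarray, levels: int) -> list[np.ndarray]:
    """Undecimated db2 transform by the a-trous cascade, periodic borders.

    Level-j filters are the base taps upsampled by ``2**(j-1)``; each
    stage's output is advanced by two base-tap positions (the periodized
    anti-causal alignment used by the standard SWT coefficient layout).
    Returns ``[approx_N, detail_N, ..., detail_1]``.
    """
    a = np.asarray(x, dtype=float)
    details = []
    for j in range(1, levels + 1):
        u = 2 ** (j - 1)
        lo = np.zeros(len(DB2_LO) * u)
        lo[::u] = DB2_LO
        hi = np.zeros(len(DB2_HI) * u)
        hi[::u] = DB2_HI
        details.append(np.roll(_circ_conv(a, hi), -2 * u))
        a = np.roll(_circ_conv(a, lo), -2 * u)
    return [a] + details[::-1]


def _conv_matrix(n: int, f: np.ndarray, advance: int) -> np.ndarray:
    C = np.zeros((n, n))
    for k, fk in enumerate(f):
        C += fk * np.roll(np.eye(n), k, axis=0)
    return np.roll(C, -advance, axis=0)


def _level1_avg_inverse(a: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Average the two decimated-phase orthogonal reconstructions."""
    n = len(a)
    C_lo = _conv_matrix(n, DB2_LO, 2)
    C_hi = _conv_matrix(n, DB2_HI, 2)
    even = np.vstack([C_lo[0::2], C_hi[0::2]])
    odd = np.vstack([C_lo[1::2], C_hi[1::2]])
    x_even = even.T @ np.concatenate([a[0::2], d[0::2]])
    x_odd = odd.T @ np.concatenate([a[1::2], d[1::2]])
    return 0.5 * (x_even + x_odd)


def iswt_avg_shifts(bands: list[np.ndarray]) -> np.ndarray:
    """Average-of-shifts inverse SWT for arbitrary (modified) coefficients.

    ``bands = [approx_N, detail_N, ..., detail_1]``.  At level j the
    coefficient streams decompose into ``2**(j-1)`` interleaved phases,
    each a valid one-level undecimated pair, inverted independently and
    reassembled.
    """
    a = np.array(bands[0], dtype=float)
    levels = len(bands) - 1
    for idx, j in enumerate(range(levels, 0, -1)):
        d = np.asarray(bands[1 + idx], dtype=float)
        step = 2 ** (j - 1)
        out = np.empty_like(a)
        for p in range(step):
            out[p::step] = _level1_avg_inverse(a[p::step], d[p::step])
        a = out
    return a
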