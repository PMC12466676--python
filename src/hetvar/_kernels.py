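"""Numba kernels for the single-site Gibbs sweeps.

The coefficient structures are CSR arrays of W'W (W = [X Z]) and of the
sparse A-inverse; a sweep updates every location effect in place from its
scalar normal full conditional, Gauss-Seidel style, then the callers draw
the variance components in Python.  Keeping only these hot loops in numba
leaves all bookkeeping, RNG seeding and prior logic in plain NumPy.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def sweep_single(C_indptr, C_indices, C_data, rhs,
                 A_indptr, A_indices, A_data,
                 theta, p, lam, sigma2_e, normals):
    """One Gauss-Seidel Gibbs pass over all effects of a single-trait model.

    ``theta`` holds the p fixed effects followed by q breeding values;
    ``lam = sigma2_e / sigma2_a``.  Each effect is replaced by a draw from
    N((rhs_i - sum_{j!=i} Chat_ij theta_j) / Chat_ii, sigma2_e / Chat_ii)
    with Chat = W'W + lam * diag(0, Ainv).
    """
    m = theta.shape[0]
    for i in range(m):
        off = 0.0
        dii = 0.0
        for k in range(C_indptr[i], C_indptr[i + 1]):
            j = C_indices[k]
            if j == i:
                dii += C_data[k]
            else:
                off += C_data[k] * theta[j]
        if i >= p:
            ai = i - p
            for k in range(A_indptr[ai], A_indptr[ai + 1]):
                j = A_indices[k]
                if j == ai:
                    dii += lam * A_data[k]
                else:
                    off += lam * A_data[k] * theta[p + j]
        mean = (rhs[i] - off) / dii
        theta[i] = mean + normals[i] * np.sqrt(sigma2_e / dii)


@njit(cache=True)
def sweep_bivariate_trait(C_indptr, C_indices, C_data, rhs,
                          A_indptr, A_indices, A_data,
                          theta_t, a_other, p, inv_se,
                          gtt, gtu, normals):
    """One pass over the effects of one trait of the bivariate model.

    ``inv_se`` is 1/sigma2_e of this trait; ``gtt``/``gtu`` are the
    within-trait and cross-trait entries of G0^{-1}; ``a_other`` is the
    current breeding-value vector of the other trait.  The prior precision
    of the breeding-value pair is G0^{-1} (Kronecker) Ainv, which adds the
    cross-trait adjustment to each animal's conditional.
    """
    m = theta_t.shape[0]
    for i in range(m):
        off = 0.0
        dii = 0.0
        for k in range(C_indptr[i], C_indptr[i + 1]):
            j = C_indices[k]
            if j == i:
                dii += C_data[k]
            else:
                off += C_data[k] * theta_t[j]
        prec = dii * inv_se
        num = (rhs[i] - off) * inv_se
        if i >= p:
            ai = i - p
            prior_own = 0.0
            prior_cross = 0.0
            for k in range(A_indptr[ai], A_indptr[ai + 1]):
                j = A_indices[k]
                if j == ai:
                    prec += gtt * A_data[k]
                else:
                    prior_own += A_data[k] * theta_t[p + j]
                prior_cross += A_data[k] * a_other[j]
            num -= gtt * prior_own + gtu * prior_cross
        theta_t[i] = num / prec + normals[i] * np.sqrt(1.0 / prec)


@njit(cache=True)
def quad_form(A_indptr, A_indices, A_data, x, y):
    """x' Ainv y for CSR Ainv."""
    total = 0.0
    for i in range(x.shape[0]):
        row = 0.0
        for k in range(A_indptr[i], A_indptr[i + 1]):
            row += A_data[k] * y[A_indices[k]]
        total += x[i] * row
    return total


@njit(cache=True)
def residual_sse(W_indptr, W_indices, W_data, y, theta):
    """Sum of squared residuals y - W theta for CSR W (records x effects)."""
    sse = 0.0
    for r in range(y.shape[0]):
        fit = 0.0
        for k in range(W_indptr[r], W_indptr[r + 1]):
            fit += W_data[k] * theta[W_indices[k]]
        e = y[r] - fit
        sse += e * e
    return sse
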