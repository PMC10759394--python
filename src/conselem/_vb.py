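"""Compiled coordinate-ascent kernel for the spike-and-slab variational fit.

The summary-statistic likelihood reduces, up to hyper-parameter-free
constants, to a quadratic form in beta with "X'y" vector
``b_j = betahat_j / se_j^2`` and "X'X" matrix ``A = D^-1 R D^-1`` (D the
diagonal of SEs, R the block-diagonal reference LD).  Because the constants
do not depend on the hyper-parameters, the ELBO computed here can be compared
across grid points and across models on the same data.

LD blocks are passed as a single flattened array of per-block dense matrices
(row-major, concatenated) with offset bookkeeping, which keeps the kernel a
single easily-compiled function.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _block_elbo(a_flat, a_off, s_off, nb, b, d, logodds, s2, v, alpha, mu):
    total = 0.0
    for k in range(nb):
        p0 = s_off[k]
        p1 = s_off[k + 1]
        m = p1 - p0
        base = a_off[k]
        # m̄' A m̄ and linear term
        quad = 0.0
        lin = 0.0
        for i in range(m):
            gi = p0 + i
            mi = alpha[gi] * mu[gi]
            lin += b[gi] * mi
            row = base + i * m
            acc = 0.0
            for j in range(m):
                acc += a_flat[row + j] * alpha[p0 + j] * mu[p0 + j]
            quad += mi * acc
        total += lin - 0.5 * quad
        for i in range(m):
            gi = p0 + i
            ai = alpha[gi]
            mi = mu[gi]
            mbar = ai * mi
            total -= 0.5 * d[gi] * (ai * (mi * mi + v[gi]) - mbar * mbar)
            # KL terms
            pi_log = logodds[gi]
            # log pi and log(1-pi) from the log-odds, numerically stable
            if pi_log > 0.0:
                log_pi = -np.log1p(np.exp(-pi_log))
                log_1mpi = -pi_log - np.log1p(np.exp(-pi_log))
            else:
                log_pi = pi_log - np.log1p(np.exp(pi_log))
                log_1mpi = -np.log1p(np.exp(pi_log))
            eps = 1e-300
            total += ai * (log_pi - np.log(ai + eps))
            total += (1.0 - ai) * (log_1mpi - np.log(1.0 - ai + eps))
            total += 0.5 * ai * (
                1.0 + np.log(v[gi] / s2[gi]) - (mi * mi + v[gi]) / s2[gi]
            )
    return total


@njit(cache=True)
def coordinate_ascent(
    a_flat, a_off, s_off, b, d, logodds, s2, order, alpha, mu, tol, max_iter
):
    """Run block-wise coordinate ascent; returns (elbo_trace, n_iter).

    ``alpha`` and ``mu`` are updated in place.  ``order`` holds, per block,
    the within-block update order as global SNP indices.
    """
    nb = len(s_off) - 1
    p = len(b)
    v = np.empty(p)
    for j in range(p):
        v[j] = 1.0 / (d[j] + 1.0 / s2[j])
    # cached A m̄ per block for fast residual updates
    mbar = np.empty(p)
    for j in range(p):
        mbar[j] = alpha[j] * mu[j]
    amb = np.zeros(p)
    for k in range(nb):
        p0 = s_off[k]
        m = s_off[k + 1] - p0
        base = a_off[k]
        for i in range(m):
            row = base + i * m
            acc = 0.0
            for j in range(m):
                acc += a_flat[row + j] * mbar[p0 + j]
            amb[p0 + i] = acc
    trace = np.empty(max_iter)
    last = -1.0e300
    it = 0
    for it in range(max_iter):
        for k in range(nb):
            p0 = s_off[k]
            p1 = s_off[k + 1]
            m = p1 - p0
            base = a_off[k]
            for oi in range(p0, p1):
                gj = order[oi]
                lj = gj - p0
                r = b[gj] - (amb[gj] - d[gj] * mbar[gj])
                mu_new = v[gj] * r
                lo = logodds[gj] + 0.5 * np.log(v[gj] / s2[gj]) + 0.5 * mu_new * mu_new / v[gj]
                if lo > 0.0:
                    a_new = 1.0 / (1.0 + np.exp(-lo))
                else:
                    ex = np.exp(lo)
                    a_new = ex / (1.0 + ex)
                delta = a_new * mu_new - mbar[gj]
                if delta != 0.0:
                    col = base + lj  # column lj of the block, stride m
                    for i in range(m):
                        amb[p0 + i] += a_flat[col + i * m] * delta
                alpha[gj] = a_new
                mu[gj] = mu_new
                mbar[gj] = a_new * mu_new
        elbo = _block_elbo(a_flat, a_off, s_off, nb, b, d, logodds, s2, v, alpha, mu)
        trace[it] = elbo
        if np.abs(elbo - last) < tol * (1.0 + np.abs(elbo)):
            last = elbo
            break
        last = elbo
    return trace[: it + 1], it + 1
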