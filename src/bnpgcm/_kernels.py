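"""Numba inner loops for the Gibbs sweep.

Each kernel is a pure function of pre-drawn random variates, so the
NumPy reference implementations in :mod:`bnpgcm.sampler` consume the
identical random stream and produce identical chains — a property the
test suite exploits.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def alloc_kernel(e, precisions, logdets, logp, uniforms):
    """Categorical allocation by inverse-CDF over log-space weights.

    For each subject computes log w_ij = log p_j - 0.5 log|Phi_j|
    - 0.5 e_i' P_j e_i, normalizes against the row maximum (safe against
    underflow), and inverts the CDF at ``uniforms[i]``.
    """
    n, t = e.shape
    c = precisions.shape[0]
    z = np.empty(n, dtype=np.int64)
    logw = np.empty(c)
    for i in range(n):
        best = -1e300
        for j in range(c):
            q = 0.0
            for a in range(t):
                row = 0.0
                for b in range(t):
                    row += precisions[j, a, b] * e[i, b]
                q += e[i, a] * row
            v = logp[j] - 0.5 * logdets[j] - 0.5 * q
            logw[j] = v
            if v > best:
                best = v
        total = 0.0
        for j in range(c):
            total += np.exp(logw[j] - best)
        target = uniforms[i] * total
        acc = 0.0
        zi = c - 1
        for j in range(c):
            acc += np.exp(logw[j] - best)
            if acc >= target:
                zi = j
                break
        z[i] = zi
    return z


@njit(cache=True)
def scatter_kernel(e, z, c):
    """Per-component residual scatter matrices sum_{i: z_i=j} e_i e_i'."""
    n, t = e.shape
    out = np.zeros((c, t, t))
    for i in range(n):
        j = z[i]
        for a in range(t):
            for b in range(t):
                out[j, a, b] += e[i, a] * e[i, b]
    return out


@njit(cache=True)
def inv_wishart_kernel(scales, chi, norms):
    """Batched inverse-Wishart draws from pre-drawn variates.

    ``chi[j, i]`` are chi-square draws with df_j - i degrees of freedom and
    ``norms[j]`` the below-diagonal normals of the Bartlett factor.  Returns
    (covariances, precisions, log-determinants of the covariances).
    """
    c, t, _ = scales.shape
    covs = np.empty((c, t, t))
    precs = np.empty((c, t, t))
    logdets = np.empty(c)
    for j in range(c):
        s_inv = np.linalg.inv(scales[j])
        s_inv = 0.5 * (s_inv + s_inv.T)
        chol = np.linalg.cholesky(s_inv)
        a = np.zeros((t, t))
        idx = 0
        for i in range(t):
            a[i, i] = np.sqrt(chi[j, i])
            for k in range(i):
                a[i, k] = norms[j, idx]
                idx += 1
        m = chol @ a
        w = m @ m.T
        precs[j] = 0.5 * (w + w.T)
        ld = 0.0
        for i in range(t):
            ld += np.log(np.abs(m[i, i]))
        logdets[j] = -2.0 * ld
        cov = np.linalg.inv(precs[j])
        covs[j] = 0.5 * (cov + cov.T)
    return covs, precs, logdets
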