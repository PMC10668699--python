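"""Numba inner loops for the Gibbs sampler.

The breeding-value update is a sequential (Gauss-Seidel) sweep over animals:
each animal's T-vector full conditional depends on the *current* values of
its pedigree neighbours through A-inverse, so the loop cannot be vectorised
without colouring the pedigree graph.  T is small (<= 6), so the per-animal
Cholesky is hand-rolled to avoid LAPACK call overhead.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def gauss_seidel_u(u, indptr, indices, data, Ginv, Rinv, ry, has_rec, z):
    """One in-place Gauss-Seidel sampling sweep over all animals.

    Full conditional of animal ``a``:
      precision  P = has_rec[a] * Rinv + Ainv[a,a] * Ginv
      rhs        r = has_rec[a] * ry[a] - Ginv @ (sum_b Ainv[a,b] u[b])
      draw       u[a] ~ N(P^-1 r, P^-1)  via  u = mu + L^-T z  with P = L L^T.

    ``ry`` is Rinv @ (liability - X b) per animal (zeros if unphenotyped);
    ``z`` holds pre-drawn standard normals, keeping all randomness in the
    caller's generator.
    """
    n, T = u.shape
    P = np.empty((T, T))
    L = np.empty((T, T))
    s = np.empty(T)
    rhs = np.empty(T)
    w = np.empty(T)
    mu = np.empty(T)
    x = np.empty(T)
    for a in range(n):
        for t in range(T):
            s[t] = 0.0
        diag = 0.0
        for ptr in range(indptr[a], indptr[a + 1]):
            b = indices[ptr]
            v = data[ptr]
            if b == a:
                diag += v
            else:
                for t in range(T):
                    s[t] += v * u[b, t]
        hr = has_rec[a]
        for i in range(T):
            acc = 0.0
            for j in range(T):
                acc += Ginv[i, j] * s[j]
            rhs[i] = -acc
            if hr:
                rhs[i] += ry[a, i]
            for j in range(T):
                pij = diag * Ginv[i, j]
                if hr:
                    pij += Rinv[i, j]
                P[i, j] = pij
        # Cholesky P = L L^T
        for i in range(T):
            for j in range(i + 1):
                acc = P[i, j]
                for k in range(j):
                    acc -= L[i, k] * L[j, k]
                if i == j:
                    L[i, i] = np.sqrt(acc)
                else:
                    L[i, j] = acc / L[j, j]
        # forward: L w = rhs
        for i in range(T):
            acc = rhs[i]
            for k in range(i):
                acc -= L[i, k] * w[k]
            w[i] = acc / L[i, i]
        # backward: L^T mu = w  and  L^T x = z[a]
        for i in range(T - 1, -1, -1):
            am = w[i]
            ax = z[a, i]
            for k in range(i + 1, T):
                am -= L[k, i] * mu[k]
                ax -= L[k, i] * x[k]
            mu[i] = am / L[i, i]
            x[i] = ax / L[i, i]
        for t in range(T):
            u[a, t] = mu[t] + x[t]
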