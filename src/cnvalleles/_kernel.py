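"""Compiled VB-EM inner loops.

One full restart (outer EM loop with the per-sample inner fixed point) runs
inside a single numba-compiled function; the pure-numpy implementations of the
individual steps live in :mod:`cnvalleles.inference` and serve as the readable
reference the kernel is tested against.

The per-iteration lower bound uses the collapsed identity: with
``w[n,c,k] = phi[c,k] * g[n,k] / S[n,c]`` (g the exponentiated Dirichlet
expectation, S the normaliser), the emission + assignment + entropy terms of
the bound reduce to ``sum_{n,c} counts[n,c] * log S[n,c]`` evaluated at the r
that produced w, plus an O(N*K) correction for the subsequent r update and the
per-sample Dirichlet KL term.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=False)
def _digamma(x: float) -> float:
    # Recurrence to x >= 10, then the standard asymptotic series; agrees with
    # scipy.special.digamma to ~1e-13 on the positive axis used here.
    res = 0.0
    while x < 10.0:
        res -= 1.0 / x
        x += 1.0
    inv = 1.0 / x
    inv2 = inv * inv
    res += math.log(x) - 0.5 * inv
    res -= inv2 * (1.0 / 12.0 - inv2 * (1.0 / 120.0 - inv2 * (
        1.0 / 252.0 - inv2 * (1.0 / 240.0 - inv2 * (1.0 / 132.0)))))
    return res


@njit(cache=False)
def vb_em_run(c2, phi0, alpha, r0, inner_tol, max_inner, max_iter, tol,
              phi_floor):
    """One VB-EM restart on flattened arrays.

    c2: (N, C) float64 counts with C = 4 * n_sites; phi0: (C, K) emission
    probabilities; r0: (N, K) initial Dirichlet parameters.  Returns
    (w, r, phi, trace, n_iter, converged).
    """
    n_samples, n_cells = c2.shape
    n_alleles = alpha.shape[0]
    n_sites = n_cells // 4

    phi = phi0.copy()
    r = r0.copy()
    w = np.zeros((n_samples, n_cells, n_alleles))
    trace = np.zeros(max_iter)
    phinum = np.zeros((n_cells, n_alleles))
    phi_new = np.zeros((n_cells, n_alleles))
    g = np.zeros(n_alleles)
    rnew = np.zeros(n_alleles)
    rprev = np.zeros(n_alleles)
    tmp4 = np.zeros(4)

    alpha_sum = 0.0
    lg_alpha = 0.0
    for k in range(n_alleles):
        alpha_sum += alpha[k]
        lg_alpha += math.lgamma(alpha[k])
    log_c_alpha = math.lgamma(alpha_sum) - lg_alpha

    converged = False
    n_iter = 0
    prev = 0.0
    for it in range(max_iter):
        value = 0.0

        # ---- E step: per-sample inner fixed point (samples independent) ----
        for n in range(n_samples):
            for k in range(n_alleles):
                rnew[k] = r[n, k]
            for _inner in range(max_inner):
                rs = 0.0
                for k in range(n_alleles):
                    rprev[k] = rnew[k]
                    rs += rnew[k]
                psis = _digamma(rs)
                for k in range(n_alleles):
                    g[k] = math.exp(_digamma(rprev[k]) - psis)
                for k in range(n_alleles):
                    rnew[k] = alpha[k]
                for c in range(n_cells):
                    if c2[n, c] > 0.0:
                        s = 0.0
                        for k in range(n_alleles):
                            s += phi[c, k] * g[k]
                        f = c2[n, c] / s
                        for k in range(n_alleles):
                            rnew[k] += f * phi[c, k] * g[k]
                delta = 0.0
                for k in range(n_alleles):
                    d = abs(rnew[k] - rprev[k])
                    if d > delta:
                        delta = d
                if delta < inner_tol:
                    break

            # final responsibilities from the r (rprev) that produced rnew,
            # accumulating the collapsed data term sum c * log S
            for c in range(n_cells):
                s = 0.0
                for k in range(n_alleles):
                    s += phi[c, k] * g[k]
                for k in range(n_alleles):
                    w[n, c, k] = phi[c, k] * g[k] / s
                if c2[n, c] > 0.0:
                    value += c2[n, c] * math.log(s)

            rs_new = 0.0
            rs_prev = 0.0
            for k in range(n_alleles):
                rs_new += rnew[k]
                rs_prev += rprev[k]
            psis_new = _digamma(rs_new)
            psis_prev = _digamma(rs_prev)
            lg_r = 0.0
            for k in range(n_alleles):
                elog_new = _digamma(rnew[k]) - psis_new
                elog_prev = _digamma(rprev[k]) - psis_prev
                # assignment term correction: state r moved from rprev to rnew
                value += (rnew[k] - alpha[k]) * (elog_new - elog_prev)
                # -KL(Dir(rnew) || Dir(alpha)) pieces
                value += (alpha[k] - rnew[k]) * elog_new
                lg_r += math.lgamma(rnew[k])
            value += log_c_alpha - (math.lgamma(rs_new) - lg_r)
            for k in range(n_alleles):
                r[n, k] = rnew[k]

        # ---- M step: phi[k, x, b] proportional to weighted counts ----
        for c in range(n_cells):
            for k in range(n_alleles):
                phinum[c, k] = 0.0
        for n in range(n_samples):
            for c in range(n_cells):
                if c2[n, c] > 0.0:
                    for k in range(n_alleles):
                        phinum[c, k] += c2[n, c] * w[n, c, k]
        for k in range(n_alleles):
            for x in range(n_sites):
                tot = 0.0
                for b in range(4):
                    tot += phinum[x * 4 + b, k]
                s2 = 0.0
                for b in range(4):
                    v = phinum[x * 4 + b, k] / tot if tot > 0.0 else 0.25
                    if v < phi_floor:
                        v = phi_floor
                    tmp4[b] = v
                    s2 += v
                for b in range(4):
                    phi_new[x * 4 + b, k] = tmp4[b] / s2

        # emission term correction: bound evaluated at the updated phi
        for c in range(n_cells):
            for k in range(n_alleles):
                if phinum[c, k] > 0.0:
                    value += phinum[c, k] * (
                        math.log(phi_new[c, k]) - math.log(phi[c, k]))
        for c in range(n_cells):
            for k in range(n_alleles):
                phi[c, k] = phi_new[c, k]

        trace[it] = value
        n_iter = it + 1
        bound = tol * (abs(prev) if abs(prev) > 1.0 else 1.0)
        if it > 0 and abs(value - prev) <= bound:
            converged = True
            break
        prev = value

    return w, r, phi, trace[:n_iter], n_iter, converged
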