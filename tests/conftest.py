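"""Shared fixtures and independent oracles for the test suite.

The oracles here intentionally re-derive everything with plain loops and
exhaustive enumeration, independent of the package's vectorised/compiled
implementations.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.special import digamma, gammaln, logsumexp

from cnvalleles import BaseCountTensor


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_counts(array, sample_ids=None, positions=None) -> BaseCountTensor:
    a = np.asarray(array)
    n, m, _ = a.shape
    return BaseCountTensor(
        a,
        sample_ids or tuple(f"s{i}" for i in range(n)),
        positions or tuple(range(1, m + 1)),
    )


def e_step_oracle(counts: np.ndarray, phi: np.ndarray, alpha: np.ndarray,
                  r_init: np.ndarray, tol: float = 1e-12,
                  max_iter: int = 100000):
    """Brute-force alternation of the responsibility and Dirichlet updates.

    Plain-loop implementation of
        w[n,x,b,k] ∝ phi[k,x,b] * exp(psi(r_nk) - psi(sum_k r_nk))
        r[n,k]    = sum_{x,b} counts[n,x,b] * w[n,x,b,k] + alpha[k]
    run to |delta r| < tol.
    """
    n_s, m, _ = counts.shape
    k_n = phi.shape[0]
    r = r_init.astype(float).copy()
    w = np.zeros((n_s, m, 4, k_n))
    for _ in range(max_iter):
        for n in range(n_s):
            for x in range(m):
                for b in range(4):
                    raw = [phi[k, x, b] * np.exp(digamma(r[n, k]) - digamma(r[n].sum()))
                           for k in range(k_n)]
                    w[n, x, b] = np.array(raw) / sum(raw)
        r_new = np.zeros_like(r)
        for n in range(n_s):
            for k in range(k_n):
                acc = alpha[k]
                for x in range(m):
                    for b in range(4):
                        acc += counts[n, x, b] * w[n, x, b, k]
                r_new[n, k] = acc
        if np.abs(r_new - r).max() < tol:
            r = r_new
            break
        r = r_new
    return w, r


def m_step_oracle(counts: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Direct summation of the emission update, unnormalised then normalised."""
    n_s, m, _, k_n = w.shape
    phi = np.zeros((k_n, m, 4))
    for k in range(k_n):
        for x in range(m):
            for b in range(4):
                phi[k, x, b] = sum(counts[n, x, b] * w[n, x, b, k]
                                   for n in range(n_s))
            tot = phi[k, x].sum()
            phi[k, x] = phi[k, x] / tot if tot > 0 else 0.25
    return phi


def exact_log_marginal(counts: np.ndarray, phi: np.ndarray,
                       alpha: np.ndarray) -> float:
    """Exact log P(b | alpha, phi) by enumerating every allele assignment.

    Each observed base is a token; for each joint assignment z of tokens to
    alleles the Dirichlet integral over theta is analytic (a ratio of
    multivariate beta functions).  Samples are independent.  Feasible only
    for K^depth small.
    """
    k_n = phi.shape[0]
    log_b_alpha = gammaln(alpha).sum() - gammaln(alpha.sum())
    total = 0.0
    for n in range(counts.shape[0]):
        tokens = [(x, b)
                  for x in range(counts.shape[1])
                  for b in range(4)
                  for _ in range(int(counts[n, x, b]))]
        terms = []
        for z in itertools.product(range(k_n), repeat=len(tokens)):
            logp = sum(np.log(phi[k, x, b]) for k, (x, b) in zip(z, tokens))
            m = np.bincount(np.array(z, dtype=int), minlength=k_n) \
                if z else np.zeros(k_n)
            log_b_post = (gammaln(alpha + m).sum()
                          - gammaln(alpha.sum() + len(tokens)))
            terms.append(logp + log_b_post - log_b_alpha)
        total += logsumexp(terms)
    return float(total)
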