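"""Variational Bayes EM for the copy-unit allele mixture model.

The generative model treats every observed base at a variable site of a CNV
locus as drawn from one of K latent copy-unit alleles.  Sample ``n`` carries
the alleles in proportions ``theta_n`` (a point on the K-simplex with a
Dirichlet(alpha) prior), and allele ``k`` emits base ``b`` at site ``x`` with
probability ``phi[k, x, b]``.  This is the latent-Dirichlet-allocation
structure with sites/bases playing the role of words: the posterior over the
per-base allele assignments and per-sample proportions is approximated with a
fully factorised distribution ``Q(z) Q(theta)`` and optimised coordinate-wise,
alternating with maximum-likelihood updates of ``phi``.

Because the per-read update depends on a read only through its base, all reads
with the same (sample, site, base) share a responsibility vector; the state is
therefore stored per base count, not per read, giving O(N*M*K*|bases|) work
per iteration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln, xlogy

from ._kernel import vb_em_run

logger = logging.getLogger(__name__)

#: Fixed base order; ties in argmax operations resolve to the earliest base.
BASES: tuple[str, ...] = ("A", "C", "G", "T")
N_BASES = len(BASES)
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Absolute ELBO gap under which a smaller K wins model selection.
K_TIE_TOL = 1e-6

#: Floor applied to phi entries before renormalisation (prevents log(0)).
PHI_FLOOR = 1e-10


@dataclass(frozen=True)
class Alphabet:
    """The nucleotide alphabet, with a fixed order used for tie-breaking."""

    bases: tuple[str, ...] = BASES

    def __post_init__(self) -> None:
        if len(self.bases) != 4 or len(set(self.bases)) != 4:
            raise ValueError("alphabet must hold exactly 4 unique symbols")

    def index(self, base: str) -> int:
        return self.bases.index(base)

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class BaseCountTensor:
    """Observed base counts ``counts[n, x, b]`` per sample, site and base.

    This is the sufficient statistic of the read data: the model never needs
    individual reads, only how many times each base was seen at each variable
    site of each sample.  A row summing to zero is an uncovered site and
    contributes nothing to inference.
    """

    counts: np.ndarray
    sample_ids: tuple[str, ...]
    site_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3 or self.counts.shape[2] != N_BASES:
            raise ValueError(
                f"counts must be (N, M, {N_BASES}), got {self.counts.shape}"
            )
        n, m, _ = self.counts.shape
        if n < 1 or m < 1:
            raise ValueError("need at least one sample and one site")
        if (self.counts < 0).any():
            raise ValueError("negative base count")
        self.sample_ids = tuple(str(s) for s in self.sample_ids)
        self.site_positions = tuple(int(p) for p in self.site_positions)
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match counts")
        if len(self.site_positions) != m:
            raise ValueError("site_positions length does not match counts")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_sites(self) -> int:
        return self.counts.shape[1]

    @property
    def site_depths(self) -> np.ndarray:
        """d[n, x]: total bases observed at site x of sample n."""
        return self.counts.sum(axis=2)

    @property
    def sample_depths(self) -> np.ndarray:
        """Total observed bases per sample, summed over sites."""
        return self.counts.sum(axis=(1, 2))

    def drop_sample(self, index: int) -> "BaseCountTensor":
        keep = [i for i in range(self.n_samples) if i != index]
        return BaseCountTensor(
            self.counts[keep],
            tuple(self.sample_ids[i] for i in keep),
            self.site_positions,
        )


@dataclass
class ModelParams:
    """Emission probabilities phi[k, x, b] and Dirichlet hyperparameters alpha."""

    phi: np.ndarray
    alpha: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.phi.ndim != 3 or self.phi.shape[2] != N_BASES:
            raise ValueError(f"phi must be (K, M, {N_BASES}), got {self.phi.shape}")
        if self.alpha.shape != (self.phi.shape[0],):
            raise ValueError("alpha length must equal K")
        if (self.alpha <= 0).any():
            raise ValueError("alpha entries must be positive")
        if not np.isfinite(self.phi).all():
            bad = np.argwhere(~np.isfinite(self.phi))[0]
            raise FloatingPointError(f"non-finite phi at (k, x, b)={tuple(bad)}")
        sums = self.phi.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("phi rows must sum to 1 over bases")

    @property
    def n_alleles(self) -> int:
        return self.phi.shape[0]

    @property
    def n_sites(self) -> int:
        return self.phi.shape[1]


@dataclass
class VariationalState:
    """Factorised posterior: responsibilities w[n, x, b, k] and Dirichlet r[n, k].

    ``w[n, x, b, :]`` is the posterior probability, shared by every read with
    base b at site x of sample n, that the read came from each allele.
    ``r[n]`` parametrises the Dirichlet posterior over theta_n.
    """

    w: np.ndarray
    r: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.w.ndim != 4 or self.w.shape[2] != N_BASES:
            raise ValueError(f"w must be (N, M, {N_BASES}, K), got {self.w.shape}")
        if self.r.shape != (self.w.shape[0], self.w.shape[3]):
            raise ValueError("r must be (N, K) matching w")
        if (self.r <= 0).any():
            raise ValueError("r entries must be positive")
        sums = self.w.sum(axis=3)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("w must sum to 1 over alleles")

    @property
    def theta_hat(self) -> np.ndarray:
        """Posterior-mean allele proportions r_n / sum_k r_nk, shape (N, K)."""
        return self.r / self.r.sum(axis=1, keepdims=True)


@dataclass
class FitResult:
    """One converged VB-EM run (best restart)."""

    params: ModelParams
    state: VariationalState
    elbo_trace: list[float]
    K: int
    n_restarts: int
    seed: int
    converged: bool
    n_iterations: int

    @property
    def elbo(self) -> float:
        return self.elbo_trace[-1]

    @property
    def theta_hat(self) -> np.ndarray:
        return self.state.theta_hat


@dataclass
class SelectKResult:
    """Model selection over a range of K by the variational lower bound."""

    best: FitResult
    elbo_by_k: dict[int, float]
    fits: dict[int, FitResult] = field(repr=False, default_factory=dict)

    @property
    def selected_k(self) -> int:
        return self.best.K


def _check_dims(counts: BaseCountTensor, params: ModelParams,
                state: VariationalState | None = None) -> None:
    if params.n_sites != counts.n_sites:
        raise ValueError(
            f"params cover {params.n_sites} sites but counts have {counts.n_sites}"
        )
    if state is not None:
        if state.w.shape != (counts.n_samples, counts.n_sites, N_BASES,
                             params.n_alleles):
            raise ValueError("state w shape inconsistent with counts/params")


def _e_kernel(c2: np.ndarray, phi2: np.ndarray, alpha: np.ndarray,
              r0: np.ndarray, inner_tol: float,
              max_inner: int) -> tuple[np.ndarray, np.ndarray]:
    """Raw E-step on flattened arrays: c2 (N, M*B), phi2 (M*B, K).

    Responsibilities are formed multiplicatively, ``w ∝ phi * exp(E[log
    theta])``; the exponentiated Dirichlet expectation lies in (e^-psi-range,
    1] and phi is floored, so no log-space stabilisation is needed.
    """
    r = r0
    n_samples = c2.shape[0]
    w_out = np.empty((n_samples, c2.shape[1], phi2.shape[1]))
    r_out = r.copy()
    active = np.ones(n_samples, dtype=bool)
    for _ in range(max_inner):
        g = np.exp(digamma(r) - digamma(r.sum(axis=1, keepdims=True)))
        w = phi2[None, :, :] * g[:, None, :]
        w /= w.sum(axis=2, keepdims=True)
        r_new = alpha[None, :] + (c2[:, None, :] @ w)[:, 0, :]
        w_out[active] = w[active]
        r_out[active] = r_new[active]
        delta = np.abs(r_new - r).max(axis=1)
        active &= delta >= inner_tol
        r = r_new
        if not active.any():
            break
    return w_out, r_out


def _m_kernel(c2: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Raw M-step: returns phi2 (M*B grouped per site, K) -> (K, M, B)."""
    num = np.einsum("nc,nck->ck", c2, w)  # (M*B, K)
    m = c2.shape[1] // N_BASES
    phi = num.T.reshape(-1, m, N_BASES)
    tot = phi.sum(axis=2, keepdims=True)
    phi = np.where(tot > 0, phi / np.where(tot > 0, tot, 1.0), 1.0 / N_BASES)
    phi = np.maximum(phi, PHI_FLOOR)
    phi /= phi.sum(axis=2, keepdims=True)
    return phi


def _elbo_kernel(c2: np.ndarray, log_phi2: np.ndarray, alpha: np.ndarray,
                 w: np.ndarray, r: np.ndarray) -> dict[str, float]:
    elog = digamma(r) - digamma(r.sum(axis=1, keepdims=True))
    cw = c2[:, :, None] * w
    terms = {
        "emission": float(np.sum(cw * log_phi2[None])),
        "assignment": float(np.sum(cw.sum(axis=1) * elog)),
        "entropy_z": float(-np.sum(c2[:, :, None] * xlogy(w, w))),
    }

    def log_beta_norm(a: np.ndarray) -> np.ndarray:
        return gammaln(a.sum(axis=-1)) - gammaln(a).sum(axis=-1)

    terms["theta_kl"] = float(
        c2.shape[0] * log_beta_norm(alpha)
        - log_beta_norm(r).sum()
        + ((alpha[None, :] - r) * elog).sum()
    )
    return terms


def _flatten(counts: BaseCountTensor) -> np.ndarray:
    return counts.counts.reshape(counts.n_samples, -1).astype(float)


def _log_phi2(params: ModelParams) -> np.ndarray:
    if not np.isfinite(params.phi).all():
        bad = tuple(int(i) for i in np.argwhere(~np.isfinite(params.phi))[0])
        raise FloatingPointError(f"non-finite phi at (k, x, b)={bad}")
    return np.log(params.phi).transpose(1, 2, 0).reshape(-1, params.n_alleles)


def e_step(counts: BaseCountTensor, params: ModelParams,
           state: VariationalState, *, inner_tol: float = 1e-4,
           max_inner: int = 100) -> VariationalState:
    """Inner fixed point of the alternating responsibility/Dirichlet updates.

    Alternates ``w[n,x,b,k] ∝ phi[k,x,b] * exp(psi(r_nk) - psi(sum_k r_nk))``
    and ``r[n,k] = sum_{x,b} counts[n,x,b] * w[n,x,b,k] + alpha[k]`` until each
    sample's r stops moving by more than ``inner_tol`` (max-norm).  A sample is
    frozen the iteration it converges, so its result never depends on which
    other samples are present in ``counts``.
    """
    _check_dims(counts, params, state)
    if not np.isfinite(params.phi).all():
        bad = tuple(int(i) for i in np.argwhere(~np.isfinite(params.phi))[0])
        raise FloatingPointError(f"non-finite phi at (k, x, b)={bad}")
    phi2 = params.phi.transpose(1, 2, 0).reshape(-1, params.n_alleles)
    w, r = _e_kernel(_flatten(counts), phi2, params.alpha,
                     state.r.copy(), inner_tol, max_inner)
    k = params.n_alleles
    return VariationalState(
        w=w.reshape(counts.n_samples, counts.n_sites, N_BASES, k), r=r)


def m_step(counts: BaseCountTensor, state: VariationalState,
           alpha: np.ndarray) -> ModelParams:
    """Update emissions: phi[k,x,b] ∝ sum_n counts[n,x,b] * w[n,x,b,k].

    A (k, x) cell with no weighted observations falls back to a uniform
    distribution over bases.  Entries are floored at a small epsilon and
    renormalised so downstream logs stay finite.
    """
    c2 = _flatten(counts)
    w = state.w.reshape(counts.n_samples, -1, state.w.shape[3])
    n_empty = int((np.einsum("nc,nck->ck", c2, w)
                   .reshape(counts.n_sites, N_BASES, -1)
                   .sum(axis=1) <= 0).sum())
    if n_empty:
        logger.info("m_step: uniform fallback at %d (allele, site) cells",
                    n_empty)
    phi = _m_kernel(c2, w)
    return ModelParams(phi=phi, alpha=np.asarray(alpha, dtype=float))


def elbo(counts: BaseCountTensor, params: ModelParams,
         state: VariationalState) -> float:
    """Variational lower bound on the marginal log likelihood.

    Standard mean-field decomposition
    ``E_Q[log P(b, z, theta | alpha, phi)] - E_Q[log Q(z, theta)]`` with the
    Dirichlet expectation ``E[log theta_nk] = psi(r_nk) - psi(sum_k r_nk)``:

    * data term      sum c*w*log phi
    * assignment     sum c*w*E[log theta]  minus entropy  sum c*w*log w
    * theta term     -KL(Dir(r_n) || Dir(alpha)) per sample.

    Zero data gives exactly 0 at the optimum r = alpha.
    """
    _check_dims(counts, params, state)
    w = state.w.reshape(counts.n_samples, -1, state.w.shape[3])
    terms = _elbo_kernel(_flatten(counts), _log_phi2(params), params.alpha,
                         w, state.r)
    for name, value in terms.items():
        if not np.isfinite(value):
            raise FloatingPointError(f"non-finite ELBO term: {name}")
    return float(sum(terms.values()))


def _log_n_consistent_sequences(counts: BaseCountTensor) -> float:
    """log of the number of allele sequences drawable from observed bases."""
    per_site = (counts.counts.sum(axis=0) > 0).sum(axis=1)
    return float(np.log(np.maximum(per_site, 1)).sum())


def _init_restart(counts: BaseCountTensor, K: int, alpha: np.ndarray,
                  rng: np.random.Generator) -> tuple[ModelParams, VariationalState]:
    # phi rows: blend of pooled empirical base frequencies and a Dirichlet(1)
    # draw — breaks allele-label symmetry while starting near the data.
    pooled = counts.counts.sum(axis=0).astype(float)
    tot = pooled.sum(axis=1, keepdims=True)
    emp = np.where(tot > 0, pooled / np.where(tot > 0, tot, 1.0), 1.0 / N_BASES)
    noise = rng.dirichlet(np.ones(N_BASES), size=(K, counts.n_sites))
    phi = 0.5 * emp[None] + 0.5 * noise
    phi = np.maximum(phi, PHI_FLOOR)
    phi /= phi.sum(axis=2, keepdims=True)
    params = ModelParams(phi=phi, alpha=alpha)

    r0 = alpha[None, :] + counts.sample_depths[:, None] / K
    w0 = np.full((counts.n_samples, counts.n_sites, N_BASES, K), 1.0 / K)
    return params, VariationalState(w=w0, r=r0)


def fit(counts: BaseCountTensor, K: int, *, max_iter: int = 500,
        tol: float = 1e-6, n_restarts: int = 10, seed: int = 0,
        alpha: np.ndarray | None = None, inner_tol: float = 1e-4,
        max_inner: int = 1) -> FitResult:
    """Run VB-EM with random restarts and return the best run by final ELBO.

    Each restart alternates the E step with the M step for phi, tracking the
    lower bound; the run stops when the relative ELBO change drops below
    ``tol``.  By default each outer iteration applies a *single* pass of the
    responsibility and Dirichlet updates rather than iterating them to their
    inner fixed point (``max_inner=1``): every individual coordinate update
    increases the bound, so monotonicity is preserved either way, and the
    gentler path is markedly less prone to committing to poor local optima
    early.  Set ``max_inner`` higher to run the inner fixed point.  Restart
    ``i`` for a given ``(seed, K)`` is seeded deterministically, so results
    are reproducible bit-for-bit.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if counts.sample_depths.sum() == 0:
        warnings.warn("counts tensor has no observed bases")
    if alpha is None:
        alpha = np.ones(K)
    alpha = np.asarray(alpha, dtype=float)
    if np.log(K) > _log_n_consistent_sequences(counts):
        warnings.warn(
            f"K={K} exceeds the number of allele sequences consistent with the "
            "observed bases; surplus alleles will converge to duplicates"
        )

    c2 = np.ascontiguousarray(_flatten(counts))
    best: FitResult | None = None
    for restart in range(n_restarts):
        rng = np.random.default_rng([seed, K, restart])
        params, state = _init_restart(counts, K, alpha, rng)
        phi2 = np.ascontiguousarray(
            params.phi.transpose(1, 2, 0).reshape(-1, K))
        w, r, phi2, trace_arr, n_iter, converged = vb_em_run(
            c2, phi2, alpha, state.r, inner_tol, max_inner, max_iter, tol,
            PHI_FLOOR)
        phi = phi2.reshape(counts.n_sites, N_BASES, K).transpose(2, 0, 1)
        candidate = FitResult(
            params=ModelParams(phi=phi, alpha=alpha),
            state=VariationalState(
                w=w.reshape(counts.n_samples, counts.n_sites, N_BASES, K), r=r),
            elbo_trace=[float(v) for v in trace_arr],
            K=K, n_restarts=n_restarts, seed=seed,
            converged=bool(converged), n_iterations=int(n_iter))
        if best is None or candidate.elbo > best.elbo:
            best = candidate
    assert best is not None
    return best


def select_k(counts: BaseCountTensor, k_min: int, k_max: int,
             **config) -> SelectKResult:
    """Fit every K in [k_min, k_max] and select the K maximising the ELBO.

    The lower bound serves as the model-selection score for the number of
    copy-unit alleles; ties within a small absolute slack go to the smaller K
    (parsimony).  The full ELBO-by-K table is returned for inspection.
    """
    if not (1 <= k_min <= k_max):
        raise ValueError("need 1 <= k_min <= k_max")
    fits: dict[int, FitResult] = {}
    elbo_by_k: dict[int, float] = {}
    best: FitResult | None = None
    for K in range(k_min, k_max + 1):
        result = fit(counts, K, **config)
        fits[K] = result
        elbo_by_k[K] = result.elbo
        if best is None or result.elbo > best.elbo + K_TIE_TOL:
            best = result
    assert best is not None
    return SelectKResult(best=best, elbo_by_k=elbo_by_k, fits=fits)
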