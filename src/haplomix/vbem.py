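"""Variational Bayes EM for the fragment mixture model.

The posterior over haplotype origins H, per-fragment phase assignments Psi
and phase probabilities Theta is approximated by a factorised distribution
Q(H, Psi) * Q(Theta), with Q(Theta) a product of per-site Dirichlet
distributions Dir(theta_j | lambda_j).  Coordinate ascent alternates:

E step
    log beta_{ihj,nu} = mu_{ihj,nu} + psi(lambda_{j,nu}) - psi(sum_nu' lambda_{j,nu'})
    q_{ih}   proportional to p_m(h) * prod_{j in X(f_i)} sum_nu beta_{ihj,nu}
    rho_{ihj,nu} proportional to beta_{ihj,nu}

M step (conjugate Dirichlet update)
    lambda_{j,nu} = lambda0_{j,nu} + sum_i sum_h q_{ih} rho_{ihj,nu}

where mu_{ihj,nu} = log p_e(f_{ij} | nu_h) and psi is the digamma function.
The evidence lower bound (ELBO) after an E step reduces to
sum_i log Z_i - sum_j KL(Dir(lambda_j) || Dir(lambda0_j)), with Z_i the
per-fragment normaliser; it is non-decreasing over iterations.

Plain VBEM converges readily to configurations containing switch errors --
a switched suffix is locally stable because no single-site change can repair
it.  :func:`optimize` therefore wraps VBEM in a twist-restart loop: after
each convergence, the Dirichlet state is *twisted* (phase hyperparameters
flipped for all sites at or beyond a low-connectivity site) and VBEM is
re-run; the twist is kept only if the data log-likelihood at the posterior
mean improves.  The accepted log-likelihood is thus monotone across the
loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numba
import numpy as np
from scipy.special import digamma, gammaln

from . import scoring
from .fragments import FragmentSet, PhaseVector
from .model import DEFAULT_ALPHA, LOG_HALF, PhaseParams, data_loglik, twist_array

log = logging.getLogger(__name__)

DEFAULT_PRIOR = 1.0
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 500
DEFAULT_MAX_TWISTS = 100
DEFAULT_RESTARTS = 3
ACCEPT_TOL = 1e-6  # minimum data-loglik gain for accepting a twist
INIT_JITTER = 0.1


@dataclass
class DirichletState:
    """Variational Dirichlet posterior over phase probabilities.

    ``lam[j-1, nu]`` are the per-site hyperparameters; ``lam0`` the prior.
    """

    lam: np.ndarray
    lam0: np.ndarray

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=np.float64)
        self.lam0 = np.asarray(self.lam0, dtype=np.float64)
        if self.lam.shape != self.lam0.shape or self.lam.ndim != 2 or self.lam.shape[1] != 2:
            raise ValueError("lam and lam0 must share shape (M, 2)")
        if np.any(self.lam <= 0) or np.any(self.lam0 <= 0):
            raise ValueError("Dirichlet hyperparameters must be strictly positive")

    @property
    def num_sites(self) -> int:
        return self.lam.shape[0]

    def posterior_mean(self, alpha: float = DEFAULT_ALPHA) -> PhaseParams:
        """Posterior-mean phase probabilities lambda_nu / sum lambda."""
        theta = self.lam / self.lam.sum(axis=1, keepdims=True)
        return PhaseParams(theta, alpha)

    def twisted(self, j0: int) -> "DirichletState":
        """Hyperparameters flipped for all sites >= j0 (prior untouched)."""
        return DirichletState(twist_array(self.lam, j0), self.lam0)


@dataclass
class FragmentPosterior:
    """Variational posterior over fragment origins and phase assignments.

    ``q[i, h]`` is the responsibility of haplotype h for fragment i;
    ``rho[k, h, nu]`` the phase posterior at the k-th (fragment, site) entry
    of the flat layout given origin h.  ``log_z[i]`` is the per-fragment
    normaliser entering the ELBO.
    """

    q: np.ndarray
    rho: np.ndarray
    log_z: np.ndarray


@dataclass
class FitResult:
    """Outcome of a VBEM run or of the full twist-restart optimisation."""

    state: DirichletState
    params: PhaseParams
    elbo_trace: list[float]
    loglik: float
    n_iter: int
    converged: bool
    twist_trace: list[tuple[int, float, bool, float]] = field(default_factory=list)
    """Per twist attempt: (site, connectivity there, accepted, resulting loglik)."""


# ---------------------------------------------------------------------------
# Workspace: per-dataset constants shared across iterations
# ---------------------------------------------------------------------------


class _Workspace:
    """Precomputed flat arrays for one (FragmentSet, alpha) pair."""

    def __init__(self, fs: FragmentSet, alpha: float) -> None:
        self.fs = fs
        self.alpha = alpha
        self.offsets, self.sites0, alleles, self.frag_index = fs._flat
        self.n_frag = len(fs)
        k = len(self.sites0)
        # mu[k, h, nu] = log p_e(f_k | allele h XOR nu); match iff nu == f XOR h
        self.mu = np.empty((k, 2, 2))
        la, l1a = np.log(max(alpha, 1e-300)), np.log1p(-alpha)
        for h in (0, 1):
            m = alleles ^ h
            self.mu[:, h, 0] = np.where(m == 0, l1a, la)
            self.mu[:, h, 1] = np.where(m == 1, l1a, la)
        self.pe = np.exp(self.mu)  # emission probabilities, used by the kernel


def e_step(fs: FragmentSet, state: DirichletState, alpha: float = DEFAULT_ALPHA) -> FragmentPosterior:
    """Mean-field update of the fragment posterior given the Dirichlet state."""
    return _e_step(_Workspace(fs, alpha), state)


def _e_step(ws: _Workspace, state: DirichletState) -> FragmentPosterior:
    if np.any(state.lam <= 0):
        raise ValueError("Dirichlet hyperparameters must be strictly positive")
    elog = digamma(state.lam) - digamma(state.lam.sum(axis=1))[:, None]  # (M, 2)
    logb = ws.mu + elog[ws.sites0][:, None, :]  # (K, 2, 2)
    s = np.logaddexp(logb[:, :, 0], logb[:, :, 1])  # (K, 2)
    if ws.n_frag:
        frag_sums = np.add.reduceat(s, ws.offsets[:-1], axis=0)  # (N, 2)
    else:
        frag_sums = np.zeros((0, 2))
    frag_sums = frag_sums + LOG_HALF
    log_z = np.logaddexp(frag_sums[:, 0], frag_sums[:, 1])
    q = np.exp(frag_sums - log_z[:, None])
    rho = np.exp(logb - s[:, :, None])
    return FragmentPosterior(q=q, rho=rho, log_z=log_z)


def m_step(fs: FragmentSet, post: FragmentPosterior, lam0: np.ndarray) -> DirichletState:
    """Conjugate update: add each fragment-site's expected phase counts."""
    ws = _Workspace(fs, DEFAULT_ALPHA)  # alpha unused here
    return _m_step(ws, post, np.asarray(lam0, dtype=np.float64))


def _m_step(ws: _Workspace, post: FragmentPosterior, lam0: np.ndarray) -> DirichletState:
    m = lam0.shape[0]
    qk = post.q[ws.frag_index]  # (K, 2)
    w = np.einsum("kh,khv->kv", qk, post.rho)  # (K, 2)
    lam = lam0.copy()
    for nu in (0, 1):
        lam[:, nu] += np.bincount(ws.sites0, weights=w[:, nu], minlength=m)
    return DirichletState(lam, lam0)


def _dirichlet_kl(lam: np.ndarray, lam0: np.ndarray) -> float:
    """Sum over sites of KL(Dir(lam_j) || Dir(lam0_j))."""
    s, s0 = lam.sum(axis=1), lam0.sum(axis=1)
    t = (
        gammaln(s)
        - gammaln(lam).sum(axis=1)
        - gammaln(s0)
        + gammaln(lam0).sum(axis=1)
        + ((lam - lam0) * (digamma(lam) - digamma(s)[:, None])).sum(axis=1)
    )
    return float(t.sum())


def elbo(fs: FragmentSet, state: DirichletState, post: FragmentPosterior) -> float:
    """Evidence lower bound for a posterior freshly produced by the E step."""
    return float(post.log_z.sum()) - _dirichlet_kl(state.lam, state.lam0)


@numba.njit(cache=False)
def _cycle_kernel(
    offsets: np.ndarray,
    sites0: np.ndarray,
    pe: np.ndarray,
    g: np.ndarray,
    lam_new: np.ndarray,
) -> float:
    """One fused E+M cycle; returns sum_i log Z_i and fills ``lam_new``.

    ``g`` is exp(E[log theta]) per site and phase; ``lam_new`` must be
    pre-filled with the prior.  Numerically identical to e_step followed
    by m_step: per-fragment products are accumulated in log space.
    """
    log_half = np.log(0.5)
    total = 0.0
    n = len(offsets) - 1
    for i in range(n):
        lo, hi = offsets[i], offsets[i + 1]
        lp0 = 0.0
        lp1 = 0.0
        for k in range(lo, hi):
            s = sites0[k]
            ts0 = pe[k, 0, 0] * g[s, 0] + pe[k, 0, 1] * g[s, 1]
            ts1 = pe[k, 1, 0] * g[s, 0] + pe[k, 1, 1] * g[s, 1]
            lp0 += np.log(ts0)
            lp1 += np.log(ts1)
        m = lp0 if lp0 > lp1 else lp1
        log_z = m + np.log(np.exp(lp0 - m) + np.exp(lp1 - m)) + log_half
        total += log_z
        q0 = np.exp(log_half + lp0 - log_z)
        q1 = 1.0 - q0
        for k in range(lo, hi):
            s = sites0[k]
            t00 = pe[k, 0, 0] * g[s, 0]
            t01 = pe[k, 0, 1] * g[s, 1]
            t10 = pe[k, 1, 0] * g[s, 0]
            t11 = pe[k, 1, 1] * g[s, 1]
            ts0 = t00 + t01
            ts1 = t10 + t11
            lam_new[s, 0] += q0 * t00 / ts0 + q1 * t10 / ts1
            lam_new[s, 1] += q0 * t01 / ts0 + q1 * t11 / ts1
    return total


def _cycle(ws: _Workspace, lam: np.ndarray, lam0: np.ndarray) -> tuple[float, np.ndarray]:
    """E step at ``lam`` + conjugate M step; returns (ELBO, next lam)."""
    g = np.exp(digamma(lam) - digamma(lam.sum(axis=1))[:, None])
    lam_new = lam0.copy()
    log_z_total = _cycle_kernel(ws.offsets, ws.sites0, ws.pe, g, lam_new)
    return log_z_total - _dirichlet_kl(lam, lam0), lam_new


# ---------------------------------------------------------------------------
# Initialisation
# ---------------------------------------------------------------------------


def uniform_prior(num_sites: int, prior: float = DEFAULT_PRIOR) -> np.ndarray:
    return np.full((num_sites, 2), float(prior))


def init_state(
    num_sites: int,
    rng: np.random.Generator,
    prior: float = DEFAULT_PRIOR,
    jitter: float = INIT_JITTER,
) -> DirichletState:
    """Prior plus small positive jitter; the symmetric point is a saddle."""
    lam0 = uniform_prior(num_sites, prior)
    lam = lam0 + jitter * rng.random((num_sites, 2))
    return DirichletState(lam, lam0)


def truth_seeded_state(
    truth: PhaseVector, num_sites: int, prior: float = DEFAULT_PRIOR
) -> DirichletState:
    """Initial state biased one unit toward the true phase at every site.

    Used as an approximate-global-optimum reference when benchmarking the
    twist-restart heuristic on simulated data.
    """
    lam0 = uniform_prior(num_sites, prior)
    lam = lam0.copy()
    for j in truth.sites():
        if j <= num_sites:
            lam[j - 1, truth[j]] += 1.0
    return DirichletState(lam, lam0)


# ---------------------------------------------------------------------------
# VBEM loop and twist-restart optimisation
# ---------------------------------------------------------------------------


def run_vbem(
    fs: FragmentSet,
    init: DirichletState,
    alpha: float = DEFAULT_ALPHA,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> FitResult:
    """Alternate E/M steps until the ELBO gain drops below ``tol``."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    ws = _Workspace(fs, alpha)
    return _run_vbem(ws, init, tol, max_iter)


def _run_vbem(ws: _Workspace, init: DirichletState, tol: float, max_iter: int) -> FitResult:
    lam, lam0 = init.lam, init.lam0
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        cur_elbo, lam_new = _cycle(ws, lam, lam0)
        trace.append(cur_elbo)
        if len(trace) >= 2 and trace[-1] - trace[-2] < tol:
            converged = True
            break
        lam = lam_new
    state = DirichletState(lam, lam0)
    params = state.posterior_mean(ws.alpha)
    return FitResult(
        state=state,
        params=params,
        elbo_trace=trace,
        loglik=data_loglik(ws.fs, params),
        n_iter=len(trace),
        converged=converged,
    )


def optimize(
    fs: FragmentSet,
    seed: int | None = 0,
    alpha: float = DEFAULT_ALPHA,
    prior: float = DEFAULT_PRIOR,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    max_twists: int = DEFAULT_MAX_TWISTS,
    restarts: int = DEFAULT_RESTARTS,
    init: DirichletState | None = None,
) -> FitResult:
    """Full fit: restarted VBEM followed by the twist-restart loop.

    Candidate twist sites are visited in ascending order of connectivity
    (computed from the current posterior-mean parameters); a twist is
    accepted iff the data log-likelihood at the posterior mean improves,
    which makes the accepted log-likelihood monotone non-decreasing.
    Sites already tried since the last accepted twist are skipped.  The
    loop stops when no candidate improves or after ``max_twists`` VBEM
    re-runs.
    """
    rng = np.random.default_rng(seed)
    ws = _Workspace(fs, alpha)
    m = fs.num_sites

    if init is not None:
        best = _run_vbem(ws, init, tol, max_iter)
    else:
        best = None
        for _ in range(max(1, restarts)):
            fit = _run_vbem(ws, init_state(m, rng, prior), tol, max_iter)
            if best is None or fit.elbo_trace[-1] > best.elbo_trace[-1]:
                best = fit
    best_ll = best.loglik

    twist_trace: list[tuple[int, float, bool, float]] = []
    # sites whose cut no fragment covers can never change the likelihood
    coverable = np.zeros(m, dtype=bool)
    for f in fs:
        coverable[int(f.sites[0]) : int(f.sites[-1])] = True  # cuts at j=site0+2..site-1+1
    attempts = 0
    tried: set[int] = set()
    while attempts < max_twists:
        conn = scoring.compute_connectivities(fs, best.params)
        order = np.argsort(conn, kind="stable")
        improved = False
        for j0_idx in order:
            j0 = int(j0_idx) + 1
            if j0 in tried or not coverable[j0 - 1]:
                continue
            if attempts >= max_twists:
                break
            attempts += 1
            tried.add(j0)
            fit2 = _run_vbem(ws, best.state.twisted(j0), tol, max_iter)
            accept = fit2.loglik > best_ll + ACCEPT_TOL
            twist_trace.append((j0, float(conn[j0 - 1]), accept, fit2.loglik))
            if accept:
                best, best_ll = fit2, fit2.loglik
                tried.clear()
                improved = True
                break
        if not improved:
            break

    log.info(
        "optimize: loglik=%.4f after %d twist attempt(s), %d accepted",
        best_ll,
        len(twist_trace),
        sum(1 for t in twist_trace if t[2]),
    )
    return FitResult(
        state=best.state,
        params=best.params,
        elbo_trace=best.elbo_trace,
        loglik=best_ll,
        n_iter=best.n_iter,
        converged=best.converged,
        twist_trace=twist_trace,
    )
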