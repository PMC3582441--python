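"""Mixture likelihood for binary SNP fragments.

Each fragment is emitted independently from one of two equiprobable
haplotypes.  Given phase probabilities theta_{j,nu} over the two phases
nu in {(0,1), (1,0)} at every site j, and a constant per-allele error rate
alpha, the marginal probability of a fragment f spanning sites X(f) is

    P(f | Theta) = sum_h 0.5 * prod_{j in X(f)} sum_nu theta_{j,nu} p_e(f_j | nu_h)

where nu_h is the allele phase nu places on haplotype h and
p_e(s | s') = 1 - alpha if s == s' else alpha.  Fragments are independent,
so the data log-likelihood is the sum of fragment log-likelihoods.

The model is symmetric under the global exchange of haplotype labels:
flipping every phase (theta -> theta-bar) leaves every likelihood
unchanged.  *Twisting* at site j0 flips the phases of all sites >= j0
only; the likelihood drop under a twist is the basis of the connectivity
score (see :mod:`haplomix.scoring`).

All arithmetic is carried out in natural-log space, so likelihood ratios,
connectivities and chimerity scores throughout the package are in nats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fragments import FragmentSet, SNPFragment

LOG_HALF = float(np.log(0.5))

DEFAULT_ALPHA = 0.1
"""Default per-allele sequencing/mapping error rate."""


@dataclass
class PhaseParams:
    """Point parameters Theta: per-site phase probabilities plus error rate.

    ``theta[j-1, 0]`` is the probability of phase (0, 1) at site j and
    ``theta[j-1, 1]`` of phase (1, 0); each row sums to one.  ``alpha`` is
    held fixed (it is better estimated from read data at large than from
    the heterozygous sites alone).
    """

    theta: np.ndarray
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=np.float64)
        if self.theta.ndim != 2 or self.theta.shape[1] != 2:
            raise ValueError("theta must have shape (M, 2)")
        if np.any(self.theta < 0):
            raise ValueError("theta must be nonnegative")
        if not np.allclose(self.theta.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("theta rows must sum to 1")
        if not 0.0 <= self.alpha < 0.5:
            raise ValueError("alpha must lie in [0, 0.5)")

    @property
    def num_sites(self) -> int:
        return self.theta.shape[0]

    @classmethod
    def from_phase_codes(
        cls, codes: np.ndarray, alpha: float = DEFAULT_ALPHA
    ) -> "PhaseParams":
        """Deterministic parameters concentrated on given phase codes."""
        codes = np.asarray(codes, dtype=np.int64)
        theta = np.zeros((len(codes), 2))
        theta[np.arange(len(codes)), codes] = 1.0
        return cls(theta, alpha)

    def switched(self) -> "PhaseParams":
        """Theta-bar: every phase flipped (an equivalent parameter set)."""
        return PhaseParams(self.theta[:, ::-1].copy(), self.alpha)


def emission_prob(sigma: int, sigma_true: int, alpha: float) -> float:
    """P(observe ``sigma`` | true allele ``sigma_true``) under error rate alpha."""
    if sigma not in (0, 1) or sigma_true not in (0, 1):
        raise ValueError("alleles must be 0 or 1")
    return 1.0 - alpha if sigma == sigma_true else alpha


def twist_array(arr: np.ndarray, j0: int) -> np.ndarray:
    """Flip the phase axis of ``arr`` (shape (M, 2)) for all sites >= j0.

    Twisting twice at the same site is the identity; j0 = 1 flips every
    site and j0 > M leaves the array unchanged.
    """
    if j0 < 1:
        raise ValueError("j0 must be >= 1")
    out = arr.copy()
    out[j0 - 1 :] = out[j0 - 1 :, ::-1]
    return out


def twist_params(params: PhaseParams, j0: int) -> PhaseParams:
    """Theta twisted at site j0: phases flipped for all j >= j0."""
    if not 1 <= j0 <= params.num_sites + 1:
        raise ValueError(f"j0={j0} outside 1..{params.num_sites + 1}")
    return PhaseParams(twist_array(params.theta, j0), params.alpha)


# ---------------------------------------------------------------------------
# Likelihood kernels
# ---------------------------------------------------------------------------
#
# With binary alleles the emission simplifies: phase nu (coded 0/1) places
# allele h XOR nu on haplotype h, so the observed allele matches iff
# nu == f_j XOR h.  The per-site factor for haplotype h is therefore
#
#     a[k, h] = log( theta[s_k, m] * (1 - alpha) + theta[s_k, 1 - m] * alpha ),
#     m = f_k XOR h,
#
# and the fragment log-likelihood is logsumexp_h( log 0.5 + sum_k a[k, h] ).


def _site_logterms(sites0: np.ndarray, alleles: np.ndarray, params: PhaseParams) -> np.ndarray:
    """Per-(fragment-site, haplotype) log factors, shape (K, 2)."""
    theta = params.theta
    a = np.empty((len(sites0), 2))
    for h in (0, 1):
        m = alleles ^ h
        a[:, h] = np.log(
            theta[sites0, m] * (1.0 - params.alpha) + theta[sites0, 1 - m] * params.alpha
        )
    return a


def _fragment_logliks(fs: FragmentSet, params: PhaseParams) -> np.ndarray:
    """Log-likelihood of every fragment in ``fs``, shape (N,)."""
    if params.num_sites < fs.num_sites:
        raise ValueError("params cover fewer sites than the fragment set")
    offsets, sites0, alleles, _ = fs._flat
    if len(sites0) == 0:
        return np.zeros(0)
    a = _site_logterms(sites0, alleles, params)
    sums = np.add.reduceat(a, offsets[:-1], axis=0)  # (N, 2)
    return np.logaddexp(LOG_HALF + sums[:, 0], LOG_HALF + sums[:, 1])


def fragment_loglik(f: SNPFragment, params: PhaseParams) -> float:
    """Marginal log-likelihood of one fragment under point parameters."""
    if len(f) == 0:
        raise ValueError("fragment spans no site")
    if f.sites[-1] > params.num_sites:
        raise ValueError(
            f"fragment {f.fragment_id!r} spans site {int(f.sites[-1])} "
            f"outside 1..{params.num_sites}"
        )
    a = _site_logterms(f.sites - 1, f.alleles.astype(np.int64), params)
    sums = a.sum(axis=0)
    return float(np.logaddexp(LOG_HALF + sums[0], LOG_HALF + sums[1]))


def data_loglik(fs: FragmentSet, params: PhaseParams) -> float:
    """Marginal log-likelihood of the whole fragment set (fragments independent)."""
    return float(_fragment_logliks(fs, params).sum())
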