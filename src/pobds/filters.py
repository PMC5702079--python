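"""Exact MMSE state estimation: Boolean Kalman filter and smoother.

Because the hidden state lives in the finite set {0,1}^d, the optimal
(minimum mean-squared-error) estimator is computable exactly by a normalized
forward recursion over all 2^d states — the Boolean Kalman Filter (BKF).  The
posterior distribution vector (PDV) pi_k over states is propagated as

    predict:  pi_k^- = M pi_{k-1}
    update:   pi_k(i) ∝ P(y_k | s_i) * pi_k^-(i)

and the MMSE Boolean estimate sets gene j to 1 whenever its posterior
marginal P(X_k(j)=1 | y_{1:k}) exceeds 1/2 (exactly 1/2 rounds to 1; any
fixed tie rule is MMSE-optimal and a deterministic one keeps runs
reproducible).  The Boolean Kalman Smoother (BKS) adds a backward
likelihood-message pass, conditioning every instant on the whole series.

The per-step normalizers are the predictive likelihoods
P(y_k | y_{1:k-1}); their logs summed give the log marginal likelihood of
the series, which is what the multiple-model estimator ranks models by.

Exact filtering is refused above d = 12 (dense 2^d x 2^d algebra); use the
SIR particle filter from :mod:`pobds.particle` for larger networks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import ObservationModel, TransitionModel, build_transition_matrix, loglik_all_states
from .network import BooleanNetwork, StateIndexCodec

__all__ = ["FilterResult", "ZeroLikelihoodError", "bkf_step", "run_bkf", "run_bks", "mmse_from_pdv"]

_MAX_EXACT_D = 12

_PDV_TOL = 1e-10


class ZeroLikelihoodError(RuntimeError):
    """Every state has likelihood zero under an observation (q=0 contradictions)."""


@dataclass
class FilterResult:
    """Output of a filtering or smoothing pass.

    Attributes
    ----------
    Xhat : (n, d) int array
        Per-step MMSE Boolean state estimates.
    pdvs : (n, 2^d) array
        Filtered (BKF) or smoothed (BKS) posterior distribution vectors.
    log_normalizers : (n,) array
        Per-step log predictive likelihoods log P(y_k | y_{1:k-1}); their sum
        is the log marginal likelihood of the observation sequence.
    gene_names : tuple of str
    """

    Xhat: np.ndarray
    pdvs: np.ndarray
    log_normalizers: np.ndarray
    gene_names: tuple[str, ...]

    @property
    def log_marginal_likelihood(self) -> float:
        return float(self.log_normalizers.sum())

    def marginals(self) -> np.ndarray:
        """(n, d) posterior activation probabilities P(X_k(j)=1 | data)."""
        d = len(self.gene_names)
        states = StateIndexCodec(d).all_states()
        return self.pdvs @ states


def _check_pdv(pdv: np.ndarray) -> np.ndarray:
    pdv = np.asarray(pdv, dtype=float)
    if pdv.ndim != 1 or np.any(pdv < -1e-15) or abs(pdv.sum() - 1.0) > _PDV_TOL:
        raise ValueError("prior must be a normalized probability vector over states")
    return np.clip(pdv, 0.0, None)


def mmse_from_pdv(pdv: np.ndarray, codec: StateIndexCodec) -> np.ndarray:
    """MMSE Boolean estimate: per-gene marginal thresholded at 1/2 (ties -> 1)."""
    marg = np.asarray(pdv) @ codec.all_states()
    return (marg >= 0.5).astype(np.int8)


def bkf_step(
    prior: np.ndarray,
    M: np.ndarray,
    spec: ObservationModel,
    y,
    states: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """One predict/update step of the Boolean Kalman filter.

    Returns the posterior PDV and the log normalizer (log predictive
    likelihood of ``y``).  Likelihoods are handled in log space with a
    max-shift before exponentiation, so count observations far in the tails
    do not underflow.
    """
    prior = _check_pdv(prior)
    if states is None:
        d = int(np.round(np.log2(M.shape[0])))
        states = StateIndexCodec(d).all_states()
    pred = M @ prior
    logl = loglik_all_states(spec, np.asarray(y, dtype=float), states)
    finite = np.isfinite(logl) & (pred > 0)
    if not np.any(finite):
        raise ZeroLikelihoodError("zero-likelihood observation: no state can produce y")
    shift = logl[finite].max()
    w = np.where(np.isfinite(logl), np.exp(np.clip(logl - shift, -745, 0)), 0.0)
    unnorm = w * pred
    c = unnorm.sum()
    if c <= 0:
        raise ZeroLikelihoodError("zero-likelihood observation: no state can produce y")
    return unnorm / c, float(shift + np.log(c))


def _prepare(net: BooleanNetwork, p: float, Y, prior0):
    if net.d > _MAX_EXACT_D:
        raise ValueError(
            f"exact filtering over 2^{net.d} states refused (limit d <= {_MAX_EXACT_D}); "
            "use the SIR particle filter for large networks")
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[1] != net.d:
        raise ValueError(f"observations have {Y.shape[1]} columns, network has {net.d} genes")
    tm = build_transition_matrix(net, p)
    codec = tm.codec
    if prior0 is None:
        prior0 = np.full(codec.n_states, 1.0 / codec.n_states)
    else:
        prior0 = _check_pdv(prior0)
    return Y, tm, codec, prior0


def run_bkf(
    net: BooleanNetwork,
    p: float,
    spec: ObservationModel,
    Y,
    prior0: np.ndarray | None = None,
) -> FilterResult:
    """Boolean Kalman filter over an (n, d) observation matrix.

    ``prior0`` defaults to the uniform distribution over all 2^d states.
    """
    Y, tm, codec, prior = _prepare(net, p, Y, prior0)
    states = codec.all_states()
    n = Y.shape[0]
    pdvs = np.empty((n, codec.n_states))
    lognorm = np.empty(n)
    for k in range(n):
        prior, lognorm[k] = bkf_step(prior, tm.M, spec, Y[k], states)
        pdvs[k] = prior
    Xhat = (pdvs @ states >= 0.5).astype(np.int8)
    return FilterResult(Xhat=Xhat, pdvs=pdvs, log_normalizers=lognorm, gene_names=net.genes)


def run_bks(
    net: BooleanNetwork,
    p: float,
    spec: ObservationModel,
    Y,
    prior0: np.ndarray | None = None,
) -> FilterResult:
    """Boolean Kalman smoother: fixed-interval smoothing over the whole series.

    Forward pass identical to :func:`run_bkf`; the backward pass propagates
    likelihood messages beta_k(i) = P(y_{k+1:n} | X_k = s_i) (renormalized
    each step for stability), and the smoothed PDV at k is proportional to
    the filtered PDV times beta_k.  At k = n the smoothed and filtered PDVs
    coincide.  ``log_normalizers`` are those of the forward pass.
    """
    Y, tm, codec, prior = _prepare(net, p, Y, prior0)
    states = codec.all_states()
    n = Y.shape[0]
    filt = np.empty((n, codec.n_states))
    lognorm = np.empty(n)
    logliks = np.empty((n, codec.n_states))
    for k in range(n):
        logliks[k] = loglik_all_states(spec, Y[k], states)
        prior, lognorm[k] = bkf_step(prior, tm.M, spec, Y[k], states)
        filt[k] = prior
    smoothed = np.empty_like(filt)
    beta = np.ones(codec.n_states)
    smoothed[n - 1] = filt[n - 1]
    for k in range(n - 2, -1, -1):
        ll = logliks[k + 1]
        finite = np.isfinite(ll)
        w = np.zeros_like(beta)
        if np.any(finite):
            shift = ll[finite].max()
            w = np.where(finite, np.exp(np.clip(ll - shift, -745, 0)), 0.0)
        # beta_k(i) = sum_j P(s_j | s_i) P(y_{k+1} | s_j) beta_{k+1}(j)
        beta = tm.M.T @ (w * beta)
        tot = beta.sum()
        if tot <= 0:
            raise ZeroLikelihoodError("zero-likelihood observation in backward pass")
        beta = beta / tot
        post = filt[k] * beta
        smoothed[k] = post / post.sum()
    Xhat = (smoothed @ states >= 0.5).astype(np.int8)
    return FilterResult(Xhat=Xhat, pdvs=smoothed, log_normalizers=lognorm, gene_names=net.genes)
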