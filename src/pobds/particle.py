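"""Sequential importance resampling (SIR) approximation of the BKF.

For networks with many genes the 2^d state enumeration behind the exact
filter is intractable, so the posterior is approximated by N weighted
particles.  Each step is a bootstrap filter move: particles are propagated
through the noisy network transition (the proposal is the transition kernel),
reweighted by the observation likelihood, and — when the effective sample
size 1/sum(w_i^2) drops below ``alpha * N`` — resampled back to equal weights
with systematic resampling (a single uniform draw and stratified positions,
the lowest-variance of the simple schemes).  ``alpha = 0`` never resamples
(pure sequential importance sampling); ``alpha = 1`` resamples every step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .filters import FilterResult, ZeroLikelihoodError
from .models import ObservationModel, loglik_all_states
from .network import BooleanNetwork, StateIndexCodec, state_map_indices

__all__ = ["ParticleEnsemble", "ess", "systematic_resample", "sir_step", "run_sir_bkf"]


def _logsumexp(v: np.ndarray) -> float:
    m = v.max()
    if not np.isfinite(m):
        return -np.inf
    return float(m + np.log(np.exp(v - m).sum()))


@dataclass
class ParticleEnsemble:
    """N Boolean particles with log-weights (normalized on demand).

    ``log_increment`` records the log mean incremental weight of the step
    that produced the ensemble (a consistent estimate of the per-step log
    predictive likelihood); it is None for a freshly initialized ensemble.
    """

    particles: np.ndarray  # (N, d) Boolean
    log_weights: np.ndarray  # (N,)
    log_increment: float | None = field(default=None, compare=False)

    def __post_init__(self):
        self.particles = np.asarray(self.particles, dtype=np.int8)
        self.log_weights = np.asarray(self.log_weights, dtype=float)
        if self.particles.ndim != 2 or self.particles.shape[0] != self.log_weights.shape[0]:
            raise ValueError("particles must be (N, d) with one log-weight per particle")
        if self.particles.shape[0] < 1:
            raise ValueError("at least one particle is required")

    @property
    def n_particles(self) -> int:
        return self.particles.shape[0]

    def weights(self) -> np.ndarray:
        """Normalized weights (log-sum-exp stabilized)."""
        lw = self.log_weights - self.log_weights.max()
        w = np.exp(lw)
        return w / w.sum()

    def marginals(self) -> np.ndarray:
        """Weighted per-gene activation probabilities, length d."""
        return self.weights() @ self.particles

    def state_distribution(self, codec: StateIndexCodec) -> np.ndarray:
        """Weighted empirical distribution over the 2^d states (small d only)."""
        shifts = np.arange(codec.d - 1, -1, -1)
        idx = (self.particles.astype(np.int64) << shifts[None, :]).sum(axis=1)
        return np.bincount(idx, weights=self.weights(), minlength=codec.n_states)


def ess(ensemble: ParticleEnsemble) -> float:
    """Effective sample size 1/sum(w_i^2) of the normalized weights; in [1, N]."""
    w = ensemble.weights()
    return float(1.0 / np.sum(w**2))


def systematic_resample(weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Systematic resampling: indices drawn at positions (u + i)/N, one uniform u."""
    n = weights.shape[0]
    positions = (rng.random() + np.arange(n)) / n
    return np.searchsorted(np.cumsum(weights), positions).clip(max=n - 1)


def _apply_network(net: BooleanNetwork, X: np.ndarray) -> np.ndarray:
    """Synchronous network update applied row-wise to an (N, d) particle matrix."""
    from .network import _eval_ast  # vectorized AST evaluation

    env = {g: X[:, j].astype(np.uint8) for j, g in enumerate(net.genes)}
    cols = [np.broadcast_to(_eval_ast(rule, env) & 1, (X.shape[0],)) for rule in net.rules]
    return np.column_stack(cols).astype(np.int8)


def sir_step(
    ensemble: ParticleEnsemble,
    net: BooleanNetwork,
    p: float,
    spec: ObservationModel,
    y,
    alpha: float,
    rng: np.random.Generator,
    _fidx: np.ndarray | None = None,
) -> ParticleEnsemble:
    """One SIR step: propagate every particle through the noisy transition,
    multiply its weight by the observation likelihood, and resample
    systematically (weights reset to exactly 1/N) when ESS < alpha * N."""
    if not 0 <= alpha <= 1:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    if not 0 <= p <= 0.5:
        raise ValueError(f"process noise p must lie in [0, 0.5], got {p}")
    X = ensemble.particles
    n, d = X.shape
    if _fidx is not None:  # small-d fast path: precomputed state index map
        shifts = np.arange(d - 1, -1, -1)
        idx = (X.astype(np.int64) << shifts[None, :]).sum(axis=1)
        fX = ((_fidx[idx][:, None] >> shifts[None, :]) & 1).astype(np.int8)
    else:  # evaluate rules on particle columns; no 2^d enumeration
        fX = _apply_network(net, X)
    noise = (rng.random((n, d)) < p).astype(np.int8)
    Xnew = fX ^ noise
    logl = loglik_all_states(spec, np.asarray(y, dtype=float), Xnew)
    lw = ensemble.log_weights + logl
    if not np.any(np.isfinite(lw)):
        raise ZeroLikelihoodError("particle degeneracy: all weights zero under observation y")
    increment = _logsumexp(lw) - _logsumexp(ensemble.log_weights)
    new = ParticleEnsemble(particles=Xnew, log_weights=lw, log_increment=increment)
    if ess(new) < alpha * n:
        keep = systematic_resample(new.weights(), rng)
        new = ParticleEnsemble(particles=Xnew[keep],
                               log_weights=np.full(n, -np.log(n)),
                               log_increment=increment)
    return new


def run_sir_bkf(
    net: BooleanNetwork,
    p: float,
    spec: ObservationModel,
    Y,
    n_particles: int,
    alpha: float,
    rng: np.random.Generator | int,
) -> FilterResult:
    """SIR particle approximation of the Boolean Kalman filter.

    Particles start uniform over the 2^d states.  For d <= 12 the returned
    ``pdvs`` hold the weighted empirical state distributions so results are
    directly comparable with :func:`pobds.filters.run_bkf` (for larger d they
    hold the (n, d) per-gene marginals instead); ``Xhat`` uses the same
    marginal-threshold MMSE rule (ties -> 1).
    """
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[1] != net.d:
        raise ValueError(f"observations have {Y.shape[1]} columns, network has {net.d} genes")
    d = net.d
    codec = StateIndexCodec(d)
    fidx = state_map_indices(net) if d <= 12 else None
    particles = rng.integers(0, 2, size=(n_particles, d)).astype(np.int8)
    ens = ParticleEnsemble(particles=particles, log_weights=np.full(n_particles, -np.log(n_particles)))
    n = Y.shape[0]
    small = d <= 12
    Xhat = np.empty((n, d), dtype=np.int8)
    pdvs = np.empty((n, codec.n_states if small else d))
    lognorm = np.empty(n)
    for k in range(n):
        ens = sir_step(ens, net, p, spec, Y[k], alpha, rng, _fidx=fidx)
        lognorm[k] = ens.log_increment
        marg = ens.marginals()
        Xhat[k] = (marg >= 0.5).astype(np.int8)
        pdvs[k] = ens.state_distribution(codec) if small else marg
    return FilterResult(Xhat=Xhat, pdvs=pdvs, log_normalizers=lognorm, gene_names=net.genes)
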