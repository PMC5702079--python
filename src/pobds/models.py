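"""Stochastic transition and observation models for POBDS.

The hidden state follows ``X_k = f(X_{k-1}) XOR n_k`` where the components of
the transition noise ``n_k`` are i.i.d. Bernoulli(p).  On the enumerated state
space this induces a 2^d x 2^d column-stochastic matrix

    M[j, i] = p^h (1-p)^(d-h),   h = Hamming(s_j, f(s_i)),

used by the exact filters.  Observations are conditionally independent across
genes given the state; four measurement channels are provided:

* ``BernoulliObs(q)``        — Boolean read-out with flip probability q
* ``GaussianObs(mu0, sigma0, mu1, sigma1)`` — continuous (microarray/imaging)
* ``PoissonObs(s, mu, delta)``              — RNA-seq counts
* ``NegBinomialObs(s, mu, delta, phi)``     — overdispersed RNA-seq counts

The count models use the log-linear mean lambda_j(x) = s * exp(mu + delta_j *
x_j): ``s`` is the sequencing depth, ``mu`` the baseline log-expression of an
inactivated gene, ``delta_j > 0`` the differential expression of gene j, and
``phi_j > 0`` the inverse dispersion (variance = lambda + lambda^2 / phi).

All likelihood evaluation is done in log space; NaN entries in an observation
vector are treated as missing and contribute nothing to the log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .network import BooleanNetwork, StateIndexCodec, network_step, state_map_indices

__all__ = [
    "BernoulliObs",
    "GaussianObs",
    "PoissonObs",
    "NegBinomialObs",
    "ObservationModel",
    "observation_model_from_config",
    "TransitionModel",
    "build_transition_matrix",
    "sample_transition",
    "obs_loglik",
    "sample_observation",
    "loglik_all_states",
]


def _as_pos_vector(v, d: int, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim == 0:
        v = np.full(d, float(v))
    if v.shape != (d,):
        raise ValueError(f"{name} must be a scalar or length-{d} vector, got shape {v.shape}")
    if not np.all(v > 0):
        raise ValueError(f"all entries of {name} must be > 0")
    return v


@dataclass(frozen=True)
class BernoulliObs:
    """Boolean observations: each gene read-out flips with probability q."""

    q: float

    def __post_init__(self):
        # q = 0 (noiseless read-out) is allowed; a contradictory observation
        # then has likelihood exactly zero and the filters raise.
        if not 0 <= self.q <= 0.5:
            raise ValueError(f"q must be in [0, 0.5], got {self.q}")

    name = "Bernoulli"

    def loglik_gene(self, y, x: int) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if not np.all(np.isin(y, (0.0, 1.0))):
            raise ValueError("Bernoulli observations must be 0/1")
        with np.errstate(divide="ignore"):
            return np.where(y != x, np.log(self.q), np.log1p(-self.q))

    def sample_gene(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        flips = rng.random(x.shape) < self.q
        return np.where(flips, 1 - x, x).astype(np.int8)


@dataclass(frozen=True)
class GaussianObs:
    """Continuous observations: N(mu0, sigma0^2) when inactive, N(mu1, sigma1^2) when active."""

    mu0: float
    sigma0: float
    mu1: float
    sigma1: float

    def __post_init__(self):
        if self.sigma0 <= 0 or self.sigma1 <= 0:
            raise ValueError("sigma0 and sigma1 must be > 0")

    name = "Gaussian"

    def loglik_gene(self, y, x):
        mu = self.mu1 if x else self.mu0
        sd = self.sigma1 if x else self.sigma0
        y = np.asarray(y, dtype=float)
        return -0.5 * np.log(2 * np.pi * sd**2) - 0.5 * ((y - mu) / sd) ** 2

    def sample_gene(self, x, rng):
        mu = np.where(x == 1, self.mu1, self.mu0)
        sd = np.where(x == 1, self.sigma1, self.sigma0)
        return rng.normal(mu, sd)


@dataclass(frozen=True)
class PoissonObs:
    """RNA-seq counts: y_j ~ Poisson(s * exp(mu + delta_j * x_j))."""

    s: float
    mu: float
    delta: tuple

    def __post_init__(self):
        if self.s <= 0:
            raise ValueError("sequencing depth s must be > 0")
        object.__setattr__(self, "delta", tuple(np.atleast_1d(np.asarray(self.delta, dtype=float))))
        if not all(dj > 0 for dj in self.delta):
            raise ValueError("all entries of delta must be > 0")

    name = "Poisson"

    def mean(self, j: int, x: int) -> float:
        return self.s * np.exp(self.mu + self.delta[j] * x)

    def loglik_gene_j(self, j, y, x):
        y = np.asarray(y, dtype=float)
        if np.any((y < 0) | (y != np.floor(y))):
            raise ValueError("Poisson observations must be non-negative integers")
        return stats.poisson.logpmf(y.astype(np.int64), self.mean(j, x))

    def sample_gene_j(self, j, x, rng):
        return rng.poisson(self.mean(j, np.asarray(x)))


@dataclass(frozen=True)
class NegBinomialObs:
    """Overdispersed RNA-seq counts with inverse dispersion phi.

    Mean lambda_j(x) = s * exp(mu + delta_j * x_j), variance
    lambda + lambda^2 / phi_j; phi_j -> inf recovers the Poisson model.
    """

    s: float
    mu: float
    delta: tuple
    phi: tuple

    def __post_init__(self):
        if self.s <= 0:
            raise ValueError("sequencing depth s must be > 0")
        object.__setattr__(self, "delta", tuple(np.atleast_1d(np.asarray(self.delta, dtype=float))))
        object.__setattr__(self, "phi", tuple(np.atleast_1d(np.asarray(self.phi, dtype=float))))
        if not all(dj > 0 for dj in self.delta):
            raise ValueError("all entries of delta must be > 0")
        if not all(pj > 0 for pj in self.phi):
            raise ValueError("all entries of phi must be > 0")

    name = "NegBinomial"

    def mean(self, j: int, x: int) -> float:
        return self.s * np.exp(self.mu + self.delta[j] * x)

    def _nb_params(self, j, x):
        lam = self.mean(j, x)
        n = self.phi[j]
        return n, n / (n + lam)

    def loglik_gene_j(self, j, y, x):
        y = np.asarray(y, dtype=float)
        if np.any((y < 0) | (y != np.floor(y))):
            raise ValueError("negative binomial observations must be non-negative integers")
        n, pp = self._nb_params(j, x)
        return stats.nbinom.logpmf(y.astype(np.int64), n, pp)

    def sample_gene_j(self, j, x, rng):
        n, pp = self._nb_params(j, int(x))
        return rng.negative_binomial(n, pp)


ObservationModel = BernoulliObs | GaussianObs | PoissonObs | NegBinomialObs

_COUNT_MODELS = (PoissonObs, NegBinomialObs)


def observation_model_from_config(name: str, params: dict) -> ObservationModel:
    """Build an observation model from a (name, parameters) configuration.

    Mirrors the ``("Bernoulli", q)``-style configuration convention: ``name``
    is one of Bernoulli/Gaussian/Poisson/NegBinomial (case-insensitive) and
    ``params`` supplies that model's parameters by keyword.
    """
    table = {"bernoulli": BernoulliObs, "gaussian": GaussianObs,
             "poisson": PoissonObs, "negbinomial": NegBinomialObs, "nb": NegBinomialObs}
    key = name.strip().lower()
    if key not in table:
        raise ValueError(f"unknown observation model {name!r}; expected one of "
                         "Bernoulli, Gaussian, Poisson, NegBinomial")
    return table[key](**params)


def _check_spec_dim(spec: ObservationModel, d: int):
    for attr in ("delta", "phi"):
        v = getattr(spec, attr, None)
        if v is not None and len(v) != d:
            raise ValueError(f"{attr} has length {len(v)}, expected {d}")


def obs_loglik(spec: ObservationModel, y, x) -> float:
    """Log-likelihood log P(y | x): sum of per-gene terms; NaN entries of y are
    treated as missing genes and dropped."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x)
    if y.shape != x.shape:
        raise ValueError(f"observation shape {y.shape} != state shape {x.shape}")
    d = x.shape[0]
    _check_spec_dim(spec, d)
    total = 0.0
    for j in range(d):
        if np.isnan(y[j]):
            continue
        if isinstance(spec, _COUNT_MODELS):
            total += float(spec.loglik_gene_j(j, y[j], int(x[j])))
        else:
            total += float(spec.loglik_gene(np.asarray(y[j]), int(x[j])))
    return total


def loglik_all_states(spec: ObservationModel, y, states: np.ndarray) -> np.ndarray:
    """Vector of log P(y | s_i) for every row s_i of ``states`` (2^d x d).

    Exploits conditional independence across genes: for each gene only the two
    per-gene log-likelihood values (x_j = 0 and 1) are evaluated, then summed
    over genes according to each state's bits.  NaN observations are skipped.
    """
    y = np.asarray(y, dtype=float)
    n_states, d = states.shape
    _check_spec_dim(spec, d)
    out = np.zeros(n_states)
    for j in range(d):
        if np.isnan(y[j]):
            continue
        if isinstance(spec, _COUNT_MODELS):
            l0 = float(spec.loglik_gene_j(j, y[j], 0))
            l1 = float(spec.loglik_gene_j(j, y[j], 1))
        else:
            l0 = float(spec.loglik_gene(np.asarray(y[j]), 0))
            l1 = float(spec.loglik_gene(np.asarray(y[j]), 1))
        out += np.where(states[:, j] == 1, l1, l0)
    return out


def sample_observation(spec: ObservationModel, x, rng: np.random.Generator) -> np.ndarray:
    """Draw one observation vector y ~ P(. | x)."""
    x = np.asarray(x)
    d = x.shape[0]
    _check_spec_dim(spec, d)
    if isinstance(spec, _COUNT_MODELS):
        return np.array([spec.sample_gene_j(j, x[j], rng) for j in range(d)], dtype=np.int64)
    if isinstance(spec, BernoulliObs):
        return spec.sample_gene(x, rng)
    return spec.sample_gene(x, rng)


@dataclass(frozen=True)
class TransitionModel:
    """Markov transition structure of a POBDS on the enumerated state space."""

    net: BooleanNetwork
    p: float
    M: np.ndarray  # (2^d, 2^d), column-stochastic: M[j, i] = P(X_k = s_j | X_{k-1} = s_i)

    @property
    def codec(self) -> StateIndexCodec:
        return StateIndexCodec(self.net.d)


def build_transition_matrix(net: BooleanNetwork, p: float) -> TransitionModel:
    """Transition matrix M[j, i] = p^h (1-p)^(d-h) with h = Hamming(s_j, f(s_i)).

    p = 0 gives the deterministic network map; p = 0.5 the uniform matrix.
    """
    if not 0 <= p <= 0.5:
        raise ValueError(f"process noise p must lie in [0, 0.5], got {p}")
    d = net.d
    fidx = state_map_indices(net)
    n = 1 << d
    idx = np.arange(n, dtype=np.int64)
    # Hamming distance between every target state j and every image f(s_i)
    xor = idx[:, None] ^ fidx[None, :]
    h = np.zeros((n, n), dtype=np.int64)
    for b in range(d):
        h += (xor >> b) & 1
    if p == 0.0:
        M = (h == 0).astype(float)
    else:
        M = np.exp(h * np.log(p) + (d - h) * np.log1p(-p))
    return TransitionModel(net=net, p=p, M=M)


def sample_transition(net: BooleanNetwork, p: float, x, rng: np.random.Generator) -> np.ndarray:
    """One draw of X_k = f(x) XOR n, with n ~ iid Bernoulli(p)."""
    if not 0 <= p <= 0.5:
        raise ValueError(f"process noise p must lie in [0, 0.5], got {p}")
    fx = network_step(net, x)
    noise = (rng.random(net.d) < p).astype(np.int8)
    return fx ^ noise
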