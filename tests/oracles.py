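"""Independent reference implementations used only by the tests.

Everything here is deliberately written from first principles — plain loops,
log-densities from math formulas, exhaustive enumeration — and never calls
into the filtering code paths it is used to check.
"""

from __future__ import annotations

import math

import numpy as np

from pobds.models import (
    BernoulliObs,
    GaussianObs,
    NegBinomialObs,
    PoissonObs,
)
from pobds.network import BooleanNetwork, StateIndexCodec


# ---------------------------------------------------------------------------
# independent per-state observation log-likelihoods (math module formulas)
# ---------------------------------------------------------------------------

def ref_obs_loglik(spec, y, x) -> float:
    total = 0.0
    for j, (yj, xj) in enumerate(zip(np.asarray(y, dtype=float), np.asarray(x))):
        if math.isnan(yj):
            continue
        xj = int(xj)
        if isinstance(spec, BernoulliObs):
            pr = spec.q if yj != xj else 1.0 - spec.q
            total += math.log(pr) if pr > 0 else -math.inf
        elif isinstance(spec, GaussianObs):
            mu = spec.mu1 if xj else spec.mu0
            sd = spec.sigma1 if xj else spec.sigma0
            total += -0.5 * math.log(2 * math.pi * sd * sd) - (yj - mu) ** 2 / (2 * sd * sd)
        elif isinstance(spec, PoissonObs):
            lam = spec.s * math.exp(spec.mu + spec.delta[j] * xj)
            total += yj * math.log(lam) - lam - math.lgamma(yj + 1)
        elif isinstance(spec, NegBinomialObs):
            lam = spec.s * math.exp(spec.mu + spec.delta[j] * xj)
            r = spec.phi[j]
            pp = r / (r + lam)
            total += (math.lgamma(yj + r) - math.lgamma(r) - math.lgamma(yj + 1)
                      + r * math.log(pp) + yj * math.log(1 - pp))
        else:  # pragma: no cover
            raise TypeError(f"unknown spec {spec!r}")
    return total


# ---------------------------------------------------------------------------
# transition structure from first principles
# ---------------------------------------------------------------------------

def ref_transition_matrix(net: BooleanNetwork, p: float) -> np.ndarray:
    """M[j, i] built state by state with explicit Hamming-distance loops."""
    from pobds.network import network_step

    codec = StateIndexCodec(net.d)
    n = codec.n_states
    M = np.zeros((n, n))
    for i in range(n):
        fx = network_step(net, codec.decode(i))
        for j in range(n):
            sj = codec.decode(j)
            h = int(sum(int(a != b) for a, b in zip(sj, fx)))
            M[j, i] = (p**h) * ((1 - p) ** (net.d - h))
    return M


# ---------------------------------------------------------------------------
# brute-force HMM forward recursion (the BKF oracle)
# ---------------------------------------------------------------------------

def hmm_forward(net: BooleanNetwork, p: float, spec, Y, prior=None):
    """Normalized forward recursion with independent likelihoods.

    Returns (pdvs, log_normalizers).  Matrix-vector products use numpy but
    the likelihood evaluation and recursion are written here from scratch.
    """
    codec = StateIndexCodec(net.d)
    n_states = codec.n_states
    M = ref_transition_matrix(net, p)
    states = [codec.decode(i) for i in range(n_states)]
    pi = np.full(n_states, 1.0 / n_states) if prior is None else np.asarray(prior, float)
    pdvs, logns = [], []
    for y in np.atleast_2d(np.asarray(Y, dtype=float)):
        pred = M @ pi
        w = np.array([math.exp(ref_obs_loglik(spec, y, s)) for s in states])
        unnorm = w * pred
        c = unnorm.sum()
        pi = unnorm / c
        pdvs.append(pi.copy())
        logns.append(math.log(c))
    return np.array(pdvs), np.array(logns)


def enumerate_smoother(net: BooleanNetwork, p: float, spec, Y):
    """Smoothed marginals P(X_k = s | Y_{1:n}) by summing over ALL state paths.

    Exponential in n * d — intended for d = 2, n <= 6.  The hidden path is
    (X_1, ..., X_n); X_0 is marginalized over the uniform initial prior with
    one transition before the first observation, matching the filters' time
    convention.
    """
    codec = StateIndexCodec(net.d)
    n_states = codec.n_states
    M = ref_transition_matrix(net, p)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n = Y.shape[0]
    states = [codec.decode(i) for i in range(n_states)]
    loglik = np.array([[ref_obs_loglik(spec, Y[k], states[i]) for i in range(n_states)]
                       for k in range(n)])
    post = np.zeros((n, n_states))
    total = 0.0
    for path in np.ndindex(*([n_states] * n)):
        # marginalize the latent initial state x0 (uniform, one transition
        # before the first observation — the filters' time convention)
        prob = sum((1.0 / n_states) * M[path[0], i0] for i0 in range(n_states))
        lp = math.log(prob)
        for k in range(1, n):
            lp += math.log(M[path[k], path[k - 1]])
        lp += loglik[:, list(path)].diagonal().sum()
        w = math.exp(lp)
        total += w
        for k in range(n):
            post[k, path[k]] += w
    return post / total


def enumerate_log_evidence(net: BooleanNetwork, p: float, spec, Y) -> float:
    """log P(Y_{1:n}) by direct joint enumeration over all paths."""
    codec = StateIndexCodec(net.d)
    n_states = codec.n_states
    M = ref_transition_matrix(net, p)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n = Y.shape[0]
    states = [codec.decode(i) for i in range(n_states)]
    total = 0.0
    for path in np.ndindex(*([n_states] * n)):
        prob = sum((1.0 / n_states) * M[path[0], i0] for i0 in range(n_states))
        lp = math.log(prob)
        for k in range(1, n):
            lp += math.log(M[path[k], path[k - 1]])
        for k in range(n):
            lp += ref_obs_loglik(spec, Y[k], states[path[k]])
        total += math.exp(lp)
    return math.log(total)


# ---------------------------------------------------------------------------
# random small networks for property tests
# ---------------------------------------------------------------------------

def random_network(d: int, rng: np.random.Generator) -> BooleanNetwork:
    """Random d-gene network with rules of random shape (depth <= 2)."""
    genes = [f"g{i}" for i in range(d)]

    def leaf():
        if rng.random() < 0.15:
            return ("const", int(rng.integers(2)))
        return ("var", genes[int(rng.integers(d))])

    def expr(depth):
        r = rng.random()
        if depth == 0 or r < 0.3:
            node = leaf()
        elif r < 0.65:
            node = ("and", expr(depth - 1), expr(depth - 1))
        else:
            node = ("or", expr(depth - 1), expr(depth - 1))
        if rng.random() < 0.3:
            node = ("not", node)
        return node

    return BooleanNetwork(genes=tuple(genes), rules=tuple(expr(2) for _ in genes))


def random_obs_model(kind: str, d: int, rng: np.random.Generator):
    if kind == "bernoulli":
        return BernoulliObs(q=float(rng.uniform(0.02, 0.3)))
    if kind == "gaussian":
        return GaussianObs(mu0=float(rng.uniform(0, 2)), sigma0=float(rng.uniform(0.5, 2)),
                           mu1=float(rng.uniform(3, 6)), sigma1=float(rng.uniform(0.5, 2)))
    if kind == "poisson":
        return PoissonObs(s=float(rng.uniform(5, 20)), mu=float(rng.uniform(0.1, 1)),
                          delta=tuple(rng.uniform(0.5, 2, size=d)))
    if kind == "negbinomial":
        return NegBinomialObs(s=float(rng.uniform(5, 20)), mu=float(rng.uniform(0.1, 1)),
                              delta=tuple(rng.uniform(0.5, 2, size=d)),
                              phi=tuple(rng.uniform(2, 8, size=d)))
    raise ValueError(kind)
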