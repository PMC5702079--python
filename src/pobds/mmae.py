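"""Multiple Model Adaptive Estimation: Bayesian selection of the network
and/or process-noise intensity from an observation series.

A bank of candidate models (network function, process-noise intensity)
each runs its own Boolean Kalman filter.  At every time step each model's
posterior probability is multiplied by that filter's predictive likelihood
P(y_k | y_{1:k-1}, model) and the bank is renormalized — all in log space,
since per-step likelihoods on count data span many orders of magnitude.
The procedure stops at the first step where some model's posterior reaches
the stopping threshold; if no model ever crosses, the full series is
processed and the final argmax is reported without declaring a selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .filters import bkf_step
from .models import ObservationModel, build_transition_matrix
from .network import BooleanNetwork, StateIndexCodec

__all__ = ["ModelBank", "MMAEResult", "make_model_bank", "run_mmae"]


@dataclass(frozen=True)
class ModelBank:
    """Ordered candidate (network, p) pairs with a prior over models."""

    models: tuple  # tuple of (BooleanNetwork, float)
    prior: np.ndarray

    def __post_init__(self):
        if len(self.models) < 1:
            raise ValueError("model bank must contain at least one model")
        prior = np.asarray(self.prior, dtype=float)
        if prior.shape != (len(self.models),):
            raise ValueError(f"prior has length {prior.shape}, expected {len(self.models)}")
        if np.any(prior < 0) or abs(prior.sum() - 1.0) > 1e-10:
            raise ValueError("prior must be non-negative and sum to 1")
        object.__setattr__(self, "prior", prior)

    @property
    def n_models(self) -> int:
        return len(self.models)

    def labels(self) -> list[str]:
        return [f"net{i_net}:p={p:g}" for (i_net, p) in self._axes()]

    def _axes(self):
        seen: dict[int, int] = {}
        out = []
        for net, p in self.models:
            key = id(net)
            if key not in seen:
                seen[key] = len(seen)
            out.append((seen[key], p))
        return out


def make_model_bank(
    nets: list[BooleanNetwork],
    ps: list[float],
    prior: np.ndarray | None = None,
) -> ModelBank:
    """Cartesian product bank: networks on the outer axis, noise values inner.

    With 2 networks and 3 noise intensities the bank holds 6 models in
    row-major order (net1 x p1, net1 x p2, ..., net2 x p3).  ``prior=None``
    gives the uniform prior.
    """
    if not nets or not ps:
        raise ValueError("need at least one network and one noise intensity")
    genes0 = nets[0].genes
    for net in nets[1:]:
        if net.genes != genes0:
            raise ValueError("all candidate networks must share the same gene set and order")
    models = tuple((net, float(p)) for net in nets for p in ps)
    if prior is None:
        prior = np.full(len(models), 1.0 / len(models))
    return ModelBank(models=models, prior=np.asarray(prior, dtype=float))


@dataclass
class MMAEResult:
    """Posterior model-probability history and the stopping decision.

    ``posterior_history`` has one row per processed time step (rows sum
    to 1).  ``selected_model`` is the index whose posterior first reached
    the threshold, or None if the threshold was never crossed — then
    ``argmax_model`` still reports the a-posteriori most probable model
    after the full series.
    """

    posterior_history: np.ndarray  # (T_stop, M)
    selected_model: int | None
    stop_time: int | None  # 1-based step at which the threshold was crossed
    argmax_model: int
    threshold: float
    labels: list[str]


def run_mmae(
    bank: ModelBank,
    spec: ObservationModel,
    Y,
    threshold: float,
    prior: np.ndarray | None = None,
) -> MMAEResult:
    """Run the filter bank over ``Y`` until a model's posterior reaches
    ``threshold`` (checked after each update; ties broken toward the lowest
    model index), or to the end of the series."""
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] < 1:
        raise ValueError("observation sequence is empty")
    d = bank.models[0][0].d
    if Y.shape[1] != d:
        raise ValueError(f"observations have {Y.shape[1]} columns, networks have {d} genes")
    log_prior = _log_prior(bank, prior)

    codec = StateIndexCodec(d)
    states = codec.all_states()
    tms = [build_transition_matrix(net, p).M for net, p in bank.models]
    pdvs = [np.full(codec.n_states, 1.0 / codec.n_states) for _ in bank.models]

    log_post = log_prior.copy()
    history = []
    selected, stop = None, None
    for k in range(Y.shape[0]):
        for m in range(bank.n_models):
            pdvs[m], log_inc = bkf_step(pdvs[m], tms[m], spec, Y[k], states)
            log_post[m] += log_inc
        shift = log_post.max()
        post = np.exp(log_post - shift)
        post /= post.sum()
        history.append(post.copy())
        if post.max() >= threshold:
            selected = int(np.argmax(post))  # argmax takes lowest index on ties
            stop = k + 1
            break
    history = np.asarray(history)
    return MMAEResult(
        posterior_history=history,
        selected_model=selected,
        stop_time=stop,
        argmax_model=int(np.argmax(history[-1])),
        threshold=threshold,
        labels=bank.labels(),
    )


def _log_prior(bank: ModelBank, prior) -> np.ndarray:
    if prior is None:
        prior = bank.prior
    else:
        prior = np.asarray(prior, dtype=float)
        if prior.shape != (bank.n_models,):
            raise ValueError(f"prior must have length {bank.n_models}")
        if np.any(prior < 0) or abs(prior.sum() - 1.0) > 1e-10:
            raise ValueError("prior must be non-negative and sum to 1")
    with np.errstate(divide="ignore"):
        return np.log(prior)
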