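"""Model/Results interface over the filtering and identification machinery.

Two model classes follow the familiar construct-then-fit pattern:

* :class:`BooleanStateFilter` — built from an observation matrix and one
  candidate POBDS (network, process noise, observation model); ``fit()``
  runs the exact Boolean Kalman filter, the smoother, or the SIR particle
  approximation and returns a :class:`StateFilterResults` with the MMSE
  state estimates, posterior marginals, per-step predictive likelihoods,
  and a ``summary()`` table.

* :class:`ModelSelector` — built from an observation matrix and a bank of
  candidate (network, p) models; ``fit()`` runs the MMAE filter bank and
  returns :class:`ModelSelectionResults` with the posterior model
  probabilities over time and the stopping decision.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import filters, mmae, particle
from .models import ObservationModel
from .network import BooleanNetwork

__all__ = [
    "BooleanStateFilter",
    "StateFilterResults",
    "ModelSelector",
    "ModelSelectionResults",
]


class BooleanStateFilter:
    """MMSE estimation of hidden Boolean gene states from noisy expression data.

    Parameters
    ----------
    endog : (n, d) array-like
        Observation time series, one row per time point, one column per gene.
    network : BooleanNetwork
        The Boolean network driving the hidden state process.
    p : float
        Bernoulli process-noise intensity in [0, 0.5].
    obs_model : ObservationModel
        Measurement channel (Bernoulli/Gaussian/Poisson/NegBinomial).
    """

    def __init__(self, endog, network: BooleanNetwork, p: float, obs_model: ObservationModel):
        self.endog = np.atleast_2d(np.asarray(endog, dtype=float))
        self.network = network
        self.p = float(p)
        self.obs_model = obs_model
        if self.endog.shape[1] != network.d:
            raise ValueError(
                f"endog has {self.endog.shape[1]} columns but the network has {network.d} genes")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, network: BooleanNetwork, p: float,
                       obs_model: ObservationModel) -> "BooleanStateFilter":
        """Build from a DataFrame whose columns are (a superset of) the gene names."""
        missing = [g for g in network.genes if g not in df.columns]
        if missing:
            raise ValueError(f"data frame lacks gene column(s): {', '.join(missing)}")
        return cls(df.loc[:, list(network.genes)].to_numpy(), network, p, obs_model)

    def fit(self, method: str = "exact", smooth: bool = False,
            n_particles: int = 5000, alpha: float = 0.5,
            seed: int | np.random.Generator | None = None) -> "StateFilterResults":
        """Run the requested estimator.

        method="exact" runs the BKF (or the BKS when ``smooth=True``);
        method="particle" runs the SIR approximation with ``n_particles``
        particles and resampling threshold ``alpha``.
        """
        if method == "exact":
            runner = filters.run_bks if smooth else filters.run_bkf
            raw = runner(self.network, self.p, self.obs_model, self.endog)
            used = "BKS" if smooth else "BKF"
        elif method == "particle":
            if smooth:
                raise ValueError("smoothing is only available with method='exact'")
            rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
            raw = particle.run_sir_bkf(self.network, self.p, self.obs_model, self.endog,
                                       n_particles, alpha, rng)
            used = f"SIR({n_particles})"
        else:
            raise ValueError(f"unknown method {method!r}; expected 'exact' or 'particle'")
        return StateFilterResults(self, raw, used)


class StateFilterResults:
    """Results of a state-filtering fit.

    Attributes
    ----------
    states : (n, d) int array
        MMSE Boolean state estimates.
    marginals : (n, d) array
        Posterior per-gene activation probabilities.
    log_marginal_likelihood : float
        Log-likelihood of the observation series under the model.
    """

    def __init__(self, model: BooleanStateFilter, raw: filters.FilterResult, method: str):
        self.model = model
        self.raw = raw
        self.method = method
        self.states = raw.Xhat
        self.log_normalizers = raw.log_normalizers
        self.log_marginal_likelihood = raw.log_marginal_likelihood
        if raw.pdvs is not None and raw.pdvs.shape[1] == 2 ** model.network.d:
            self.marginals = raw.marginals()
        else:
            self.marginals = raw.pdvs

    def states_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.states, columns=list(self.model.network.genes))

    def accuracy(self, X_true) -> pd.Series:
        """Per-gene fraction of time points where the estimate equals X_true."""
        X_true = np.asarray(X_true)
        if X_true.shape != self.states.shape:
            raise ValueError("X_true shape does not match the estimates")
        acc = (X_true == self.states).mean(axis=0)
        return pd.Series(acc, index=list(self.model.network.genes), name="accuracy")

    def summary(self) -> str:
        g = self.model.network.genes
        lines = [
            "Boolean state estimation results",
            "=" * 48,
            f"estimator:               {self.method}",
            f"genes (d):               {len(g)}",
            f"time points (n):         {self.states.shape[0]}",
            f"process noise p:         {self.model.p:g}",
            f"observation model:       {self.model.obs_model.name}",
            f"log marginal likelihood: {self.log_marginal_likelihood:.4f}",
            "-" * 48,
            "gene      frac. time active   mean posterior",
        ]
        act = self.states.mean(axis=0)
        mp = self.marginals.mean(axis=0)
        for j, gene in enumerate(g):
            lines.append(f"{gene:<12}{act[j]:>12.3f}{mp[j]:>17.3f}")
        return "\n".join(lines)

    def plot(self, X_true=None, genes=None, path=None):
        """Step-function plot of estimated (and optionally true) trajectories."""
        from .plotting import plot_trajectory

        series = {"estimated": self.states}
        if X_true is not None:
            series = {"original": np.asarray(X_true), "estimated": self.states}
        return plot_trajectory(series, gene_names=self.model.network.genes,
                               gene_subset=genes, path=path)


class ModelSelector:
    """Bayesian identification of the network / process noise from data.

    Parameters
    ----------
    endog : (n, d) array-like
        Observation time series.
    networks : list of BooleanNetwork
        Candidate network functions (shared gene set and order).
    ps : list of float
        Candidate process-noise intensities; the bank is the Cartesian
        product networks x ps.
    obs_model : ObservationModel
    prior : optional probability vector over the bank (default uniform).
    """

    def __init__(self, endog, networks, ps, obs_model: ObservationModel, prior=None):
        self.endog = np.atleast_2d(np.asarray(endog, dtype=float))
        self.bank = mmae.make_model_bank(list(networks), list(ps), prior)
        self.obs_model = obs_model
        self.networks = list(networks)
        self.ps = [float(p) for p in ps]

    def fit(self, threshold: float = 0.8) -> "ModelSelectionResults":
        raw = mmae.run_mmae(self.bank, self.obs_model, self.endog, threshold)
        return ModelSelectionResults(self, raw)


class ModelSelectionResults:
    """Results of an MMAE fit: posterior model probabilities and the decision."""

    def __init__(self, model: ModelSelector, raw: mmae.MMAEResult):
        self.model = model
        self.raw = raw
        self.posterior_history = raw.posterior_history
        self.selected_model = raw.selected_model
        self.stop_time = raw.stop_time
        self.argmax_model = raw.argmax_model
        self.threshold = raw.threshold

    def selected_pair(self):
        """(network, p) of the selected (or a-posteriori most probable) model."""
        idx = self.selected_model if self.selected_model is not None else self.argmax_model
        return self.model.bank.models[idx]

    def posterior_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.posterior_history, columns=self.raw.labels,
                            index=pd.RangeIndex(1, self.posterior_history.shape[0] + 1,
                                                name="step"))

    def summary(self) -> str:
        final = self.posterior_history[-1]
        lines = [
            "Multiple-model adaptive estimation results",
            "=" * 48,
            f"candidate models:   {len(final)}",
            f"threshold:          {self.threshold:g}",
            f"stopped at step:    {self.stop_time if self.stop_time else '— (never crossed)'}",
            f"selected model:     "
            + (self.raw.labels[self.selected_model] if self.selected_model is not None
               else f"none (argmax: {self.raw.labels[self.argmax_model]})"),
            "-" * 48,
            "model           final posterior",
        ]
        for lbl, pr in zip(self.raw.labels, final):
            lines.append(f"{lbl:<18}{pr:>12.4f}")
        return "\n".join(lines)

    def plot(self, model_index=None, path=None):
        from .plotting import plot_mmae_posterior

        return plot_mmae_posterior(self.raw, true_model_index=model_index, path=path)
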