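"""Simulation of paired state/observation time series and their text I/O.

A :class:`Trajectory` holds the hidden Boolean state matrix ``X`` (n x d) and
the observation matrix ``Y`` (n x d) produced by one run of the POBDS.  One
seed drives three independent RNG sub-streams (initial state, process noise,
observation noise), so e.g. swapping the observation model leaves the hidden
state path untouched.

Trajectories round-trip through tab-separated text: ``<prefix>.states.tsv``
and ``<prefix>.obs.tsv`` (header row of gene names, one row per time point)
plus a small ``<prefix>.meta.json`` sidecar recording model parameters and
seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .models import ObservationModel, sample_observation, sample_transition
from .network import BooleanNetwork, StateIndexCodec

__all__ = ["Trajectory", "simulate_network", "write_trajectory", "read_trajectory"]


def _p(prefix, suffix: str) -> Path:
    # append, never replace, so dots in the prefix survive
    return Path(str(prefix) + suffix)


@dataclass
class Trajectory:
    """Paired hidden-state / observation time series from one POBDS run."""

    X: np.ndarray  # (n, d) Boolean states
    Y: np.ndarray  # (n, d) observations (Boolean, real, or count)
    gene_names: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.X = np.asarray(self.X)
        self.Y = np.asarray(self.Y)
        if self.X.shape != self.Y.shape:
            raise ValueError(f"X shape {self.X.shape} != Y shape {self.Y.shape}")
        if self.X.ndim != 2 or self.X.shape[1] != len(self.gene_names):
            raise ValueError("X must be (n, d) with one column per gene name")
        if not np.all(np.isin(self.X, (0, 1))):
            raise ValueError("X must be Boolean")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]


def _spec_meta(spec: ObservationModel) -> dict:
    out = {"name": spec.name}
    for k, v in vars(spec).items():
        out[k] = list(v) if isinstance(v, tuple) else v
    return out


def simulate_network(
    net: BooleanNetwork,
    n_data: int,
    p: float,
    spec: ObservationModel,
    rng: np.random.Generator | int,
    x0=None,
) -> Trajectory:
    """Simulate ``n_data`` steps of hidden states and observations.

    The initial state is ``x0`` if given, otherwise uniform over all 2^d
    states.  Each subsequent state is ``f(X_{k-1}) XOR Bernoulli(p)`` noise;
    each observation row is drawn from the observation model at the current
    state.  Passing the same seed reproduces the trajectory bitwise.
    """
    if n_data < 1:
        raise ValueError(f"n_data must be >= 1, got {n_data}")
    if isinstance(rng, (int, np.integer)):
        seed: int | None = int(rng)
        ss = np.random.SeedSequence(seed)
    elif isinstance(rng, np.random.SeedSequence):
        seed = None
        ss = rng
    else:
        seed = None
        ss = np.random.SeedSequence(rng.integers(2**31))
    rng_init, rng_proc, rng_obs = (np.random.default_rng(s) for s in ss.spawn(3))

    d = net.d
    codec = StateIndexCodec(d)
    if x0 is None:
        x = codec.decode(int(rng_init.integers(codec.n_states)))
    else:
        x = np.asarray(x0, dtype=np.int8)
        if x.shape != (d,):
            raise ValueError(f"x0 must have length {d}, got shape {x.shape}")

    X = np.empty((n_data, d), dtype=np.int8)
    Y_rows = []
    for k in range(n_data):
        if k > 0:
            x = sample_transition(net, p, x, rng_proc)
        X[k] = x
        Y_rows.append(sample_observation(spec, x, rng_obs))
    Y = np.asarray(Y_rows)
    meta = {
        "genes": list(net.genes),
        "p": p,
        "obs_model": _spec_meta(spec),
        "seed": seed,
        "n_data": n_data,
    }
    return Trajectory(X=X, Y=Y, gene_names=net.genes, meta=meta)


def write_trajectory(traj: Trajectory, prefix) -> None:
    """Write ``<prefix>.states.tsv``, ``<prefix>.obs.tsv`` and ``<prefix>.meta.json``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    cols = list(traj.gene_names)
    pd.DataFrame(traj.X.astype(int), columns=cols).to_csv(
        _p(prefix, ".states.tsv"), sep="\t", index=False)
    ydf = pd.DataFrame(traj.Y, columns=cols)
    float_fmt = None if np.issubdtype(traj.Y.dtype, np.integer) else "%.17g"
    ydf.to_csv(_p(prefix, ".obs.tsv"), sep="\t", index=False, float_format=float_fmt)
    with open(_p(prefix, ".meta.json"), "w", encoding="utf-8") as fh:
        json.dump(traj.meta, fh, indent=1)


def read_trajectory(prefix) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory`."""
    prefix = Path(prefix)
    xdf = pd.read_csv(_p(prefix, ".states.tsv"), sep="\t")
    ydf = pd.read_csv(_p(prefix, ".obs.tsv"), sep="\t", float_precision="round_trip")
    if list(xdf.columns) != list(ydf.columns):
        raise ValueError("state and observation files disagree on gene columns")
    if xdf.shape != ydf.shape:
        raise ValueError(f"state shape {xdf.shape} != observation shape {ydf.shape}")
    meta_path = _p(prefix, ".meta.json")
    meta = {}
    if meta_path.exists():
        with open(meta_path, encoding="utf-8") as fh:
            meta = json.load(fh)
    Y = ydf.to_numpy()
    if np.allclose(Y, np.round(Y), equal_nan=True) and not np.isnan(Y).any():
        as_int = np.round(Y).astype(np.int64)
        if np.array_equal(as_int.astype(Y.dtype), Y):
            Y = as_int
    return Trajectory(X=xdf.to_numpy(dtype=np.int8), Y=Y,
                      gene_names=tuple(xdf.columns), meta=meta)
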