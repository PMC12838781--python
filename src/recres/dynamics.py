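"""Stochastic tanh recurrent network simulation, binarization and encoding.

The network state u ∈ [−1, 1]^n evolves as

    u_i(t+1) = tanh( Σ_j w_ij u_j(t) + r η_i(t) ),   η_i(t) ~ N(0, 1) i.i.d.,

with noise strength r ≥ 0.  The symbolic dynamics are obtained post hoc by
thresholding at zero (u ≤ 0 → 0, u > 0 → 1) and encoding each binary vector
as an integer z = Σ_k s_k 2^{k−1} with neuron 1 as the least-significant bit,
so the 5-neuron all-off/all-on states are 0 and 31.

The initial state is drawn uniformly from [−1, 1]^n (the zero state is a
deterministic fixed point at r = 0, so a fixed zero start would be
degenerate), and no burn-in is discarded by default: all recorded steps enter
the statistics.  Both choices are configurable.

``simulate`` runs a single trajectory and keeps the continuous states;
``simulate_ensemble`` advances many independent trials in lock-step (one
shared noise stream, one column per trial) and records only the encoded
symbol sequences, which is what the noise scans consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "step",
    "binarize",
    "encode",
    "decode",
    "simulate",
    "simulate_ensemble",
    "raster",
    "DEFAULT_NOISE_GRID",
    "TE_NOISE_GRID",
]

# default scan grid: unit-spaced noise strengths 0–18, the sampling at which
# the resonance peaks are reported (peak values are grid-resolution sensitive)
DEFAULT_NOISE_GRID: tuple[float, ...] = tuple(float(r) for r in range(19))
# transfer-entropy comparisons span noise strengths 0–6, refined where the
# resonance lives
TE_NOISE_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.0, 3.01, 0.25), 10)) + (4.0, 5.0, 6.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Run length, noise strength and reproducibility contract for one run."""

    steps: int
    noise_strength: float = 0.0
    seed: int | None = None
    initial_state: np.ndarray | str = "uniform"  # "uniform", "zero", or explicit vector
    burn_in: int = 0
    keep_continuous: bool = True

    def __post_init__(self) -> None:
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.noise_strength < 0:
            raise ValueError("noise strength must be >= 0")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")


@dataclass
class Trajectory:
    """T recorded steps: continuous states, binary states and encoded symbols."""

    continuous: np.ndarray | None  # (T, n) floats in (−1, 1), or None if not kept
    binary: np.ndarray  # (T, n) uint8
    encoded: np.ndarray  # (T,) integers in [0, 2^n)

    @property
    def steps(self) -> int:
        return self.binary.shape[0]

    @property
    def n(self) -> int:
        return self.binary.shape[1]


def _weights_array(weights) -> np.ndarray:
    w = getattr(weights, "weights", weights)
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weights must be a square matrix")
    return w


def step(u: np.ndarray, weights, r: float, rng: np.random.Generator | None = None) -> np.ndarray:
    """One synchronous update u ← tanh(W u + r η)."""
    w = _weights_array(weights)
    u = np.asarray(u, dtype=float)
    if u.shape[-1] != w.shape[0]:
        raise ValueError(f"state of length {u.shape[-1]} incompatible with {w.shape[0]} neurons")
    drive = u @ w.T
    if r > 0:
        if rng is None:
            raise ValueError("a generator is required when r > 0")
        drive = drive + r * rng.standard_normal(u.shape)
    return np.tanh(drive)


def binarize(u: np.ndarray) -> np.ndarray:
    """Threshold at zero; ties (u = 0) map to 0."""
    return (np.asarray(u) > 0).astype(np.uint8)


def encode(s: np.ndarray) -> np.ndarray | int:
    """Binary vector(s) → integer(s); neuron 1 is the least-significant bit."""
    s = np.asarray(s)
    if not np.isin(s, (0, 1)).all():
        raise ValueError("encode expects a binary vector")
    pow2 = 1 << np.arange(s.shape[-1], dtype=np.int64)
    out = s.astype(np.int64) @ pow2
    return int(out) if out.ndim == 0 else out


def decode(z: int, m: int) -> np.ndarray:
    """Inverse of :func:`encode` for an m-bit state."""
    return (np.asarray(z, dtype=np.int64)[..., None] >> np.arange(m) & 1).astype(np.uint8)


def _initial_state(config: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    init = config.initial_state
    if isinstance(init, str):
        if init == "uniform":
            return rng.uniform(-1.0, 1.0, n)
        if init == "zero":
            return np.zeros(n)
        raise ValueError(f"unknown initial state rule {init!r}")
    init = np.asarray(init, dtype=float)
    if init.shape != (n,):
        raise ValueError("explicit initial state has wrong shape")
    return init


def simulate(weights, config: SimulationConfig) -> Trajectory:
    """Run the network for ``burn_in + steps`` updates, recording the last ``steps``."""
    w = _weights_array(weights)
    n = w.shape[0]
    rng = np.random.default_rng(config.seed)
    u = _initial_state(config, n, rng)
    r = config.noise_strength
    total = config.burn_in + config.steps
    cont = np.empty((config.steps, n)) if config.keep_continuous else None
    binary = np.empty((config.steps, n), dtype=np.uint8)
    wT = w.T.copy()
    for t in range(total):
        drive = u @ wT
        if r > 0:
            drive += r * rng.standard_normal(n)
        u = np.tanh(drive)
        k = t - config.burn_in
        if k >= 0:
            if cont is not None:
                cont[k] = u
            binary[k] = u > 0
    return Trajectory(cont, binary, encode(binary))


def simulate_ensemble(
    weight_stack: Sequence[np.ndarray] | np.ndarray,
    steps: int,
    r: float,
    seed,
    burn_in: int = 0,
    chunk: int = 2048,
) -> np.ndarray:
    """Advance k independent trials in lock-step; returns encoded (steps, k).

    ``weight_stack`` is a (k, n, n) array (one effective weight matrix per
    trial).  All trials share one noise stream: trial t consumes column t of
    each (k, n) standard-normal draw, so the block of trials is reproducible
    as a whole from ``seed``.
    """
    w = np.asarray(weight_stack, dtype=float)
    if w.ndim == 2:
        w = w[None]
    k, n, _ = w.shape
    rng = np.random.default_rng(seed)
    u = rng.uniform(-1.0, 1.0, (k, n))
    pow2 = 1 << np.arange(n, dtype=np.int64)
    dtype = np.int16 if n < 15 else np.int32
    enc = np.empty((steps, k), dtype=dtype)
    total = burn_in + steps
    done = 0
    while done < total:
        m = min(chunk, total - done)
        eta = rng.standard_normal((m, k, n)) if r > 0 else None
        for t in range(m):
            drive = np.matmul(w, u[..., None])[..., 0]
            if eta is not None:
                drive += r * eta[t]
            u = np.tanh(drive)
            rec = done + t - burn_in
            if rec >= 0:
                enc[rec] = (u > 0).astype(np.int64) @ pow2
        done += m
    return enc


def raster(traj: Trajectory | np.ndarray, interval: int = 1) -> np.ndarray:
    """Subsample the binary matrix at rows 0, Δt, 2Δt, …; values unchanged."""
    if interval < 1:
        raise ValueError("interval must be >= 1")
    binary = traj.binary if isinstance(traj, Trajectory) else np.asarray(traj)
    return binary[::interval]
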