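"""State-transition matrices, attractor classification and energy landscapes.

The empirical state-transition matrix (STM) over the 2^m encoded states has
entries T_xy = N_xy / Σ_k N_xk estimated from consecutive pairs of a symbol
series.  From the transition counts we derive the visitation marginal
P_x = Σ_y N_xy / Σ N, the relative probability gain G(x) = P_x / P_uni
against the uniform baseline P_uni = 1/2^m, and the diagonal stability T_xx.

States are classified operationally:

* transient noise:  G(x) ≤ 1 — at or below the uniform-randomness floor;
* strong attractor: G(x) > 2 and T_xx > 1.5 × baseline, the baseline being
  the mean diagonal entry over visited states;
* weak attractor:   everything else above the noise floor, split into
  high-stability traps (T_xx ≥ baseline) and low-stability "structural
  hubs" (T_xx < baseline).

Rows of unvisited states are left all-zero and flagged rather than filled
uniformly: the normalization N_xy/ΣN_xk is undefined there and a uniform
fill would fabricate transitions.

The energy landscape E(s) = −½ Σ_{i≠j} w_ij s_i s_j over binary states
provides the deterministic backdrop: strict local minima in Hamming-1
neighborhoods are the candidate deep wells that the stochastic dynamics
visit as strong attractors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TransitionModel",
    "Thresholds",
    "AttractorClassification",
    "EnergyLandscape",
    "build_stm",
    "gain",
    "classify",
    "energy",
    "local_minima",
    "classification_table",
]

MAX_ENERGY_N = 20  # local_minima enumerates 2^n states


@dataclass
class TransitionModel:
    """Empirical first-order Markov model over 2^m encoded states."""

    counts: np.ndarray  # (2^m, 2^m) transition counts N_xy
    m: int

    stm: np.ndarray = field(init=False)  # row-stochastic where visited, else zero
    marginal: np.ndarray = field(init=False)  # P_x from transition counts
    visited: np.ndarray = field(init=False)  # rows with at least one outgoing count

    def __post_init__(self) -> None:
        row = self.counts.sum(axis=1)
        self.visited = row > 0
        self.stm = np.zeros_like(self.counts, dtype=float)
        self.stm[self.visited] = self.counts[self.visited] / row[self.visited, None]
        self.marginal = row / row.sum()

    @property
    def n_states(self) -> int:
        return 1 << self.m

    @property
    def gain(self) -> np.ndarray:
        """G(x) = P_x / P_uni = P_x · 2^m."""
        return self.marginal * self.n_states

    @property
    def diag(self) -> np.ndarray:
        return np.diagonal(self.stm)

    @property
    def baseline(self) -> float:
        """Mean diagonal entry of the STM over visited states."""
        return float(self.diag[self.visited].mean())


def build_stm(encoded, m: int) -> TransitionModel:
    """Count consecutive-pair transitions of an encoded series."""
    z = np.asarray(getattr(encoded, "encoded", getattr(encoded, "symbols", encoded)), dtype=np.int64)
    if z.size < 2:
        raise ValueError("need at least two symbols")
    k = 1 << m
    if z.min() < 0 or z.max() >= k:
        raise ValueError(f"symbols outside [0, 2^{m})")
    counts = np.bincount(z[:-1] * k + z[1:], minlength=k * k).reshape(k, k)
    return TransitionModel(counts, m)


def gain(model: TransitionModel) -> np.ndarray:
    return model.gain


@dataclass(frozen=True)
class Thresholds:
    """Operational classification thresholds (recorded for provenance)."""

    transient_gain: float = 1.0  # G ≤ this → transient noise
    strong_gain: float = 2.0  # G > this (and stability) → strong
    strong_stability_factor: float = 1.5  # T_xx > factor × baseline


@dataclass
class AttractorClassification:
    labels: np.ndarray  # per-state: "strong" | "weak" | "transient"
    subtypes: np.ndarray  # weak states: "high_stability" | "structural_hub"; else ""
    thresholds: Thresholds
    baseline: float
    states: np.ndarray  # indices actually classified

    def states_with(self, label: str) -> np.ndarray:
        return self.states[self.labels[self.states] == label]


def classify(
    model: TransitionModel,
    thresholds: Thresholds = Thresholds(),
    visited_only: bool = True,
) -> AttractorClassification:
    """Exhaustive, exclusive labeling of states by gain and diagonal stability."""
    g = model.gain
    d = model.diag
    base = model.baseline
    n = model.n_states
    labels = np.full(n, "transient", dtype=object)
    strong = (g > thresholds.strong_gain) & (d > thresholds.strong_stability_factor * base)
    weak = (g > thresholds.transient_gain) & ~strong
    labels[weak] = "weak"
    labels[strong] = "strong"
    subtypes = np.full(n, "", dtype=object)
    subtypes[weak & (d >= base)] = "high_stability"
    subtypes[weak & (d < base)] = "structural_hub"
    states = np.flatnonzero(model.visited) if visited_only else np.arange(n)
    return AttractorClassification(labels, subtypes, thresholds, base, states)


def classification_table(model: TransitionModel, cls: AttractorClassification) -> pd.DataFrame:
    """Tidy per-state export: state, P_x, G, T_xx, label, subtype."""
    s = cls.states
    return pd.DataFrame(
        {
            "state": s,
            "P": model.marginal[s],
            "G": model.gain[s],
            "Txx": model.diag[s],
            "label": cls.labels[s],
            "subtype": cls.subtypes[s],
        }
    )


# ---------------------------------------------------------------------------
# energy landscape


def _weights_array(weights) -> np.ndarray:
    w = getattr(weights, "weights", weights)
    return np.asarray(w, dtype=float)


def energy(s, weights) -> float:
    """E(s) = −½ Σ_{i≠j} w_ij s_i s_j for a binary state s (self-terms excluded)."""
    w = _weights_array(weights)
    s = np.asarray(s, dtype=float)
    if not np.isin(s, (0.0, 1.0)).all():
        raise ValueError("state must be binary")
    return float(-0.5 * (s @ w @ s - np.diag(w) @ (s * s)))


@dataclass
class EnergyLandscape:
    energies: np.ndarray  # (2^n,) E for every binary state, encoded LSB-first
    minima: np.ndarray  # encoded indices of strict Hamming-1 local minima
    barriers: np.ndarray  # per-minimum smallest neighbor excess min_s' E(s')−E(s*)
    n: int


def local_minima(weights) -> EnergyLandscape:
    """Exhaustive strict local minima of E over 1-bit neighborhoods."""
    w = _weights_array(weights)
    n = w.shape[0]
    if n > MAX_ENERGY_N:
        raise ValueError(f"n={n} too large for 2^n enumeration")
    states = (np.arange(1 << n)[:, None] >> np.arange(n) & 1).astype(float)
    off = w - np.diag(np.diag(w))
    energies = -0.5 * np.einsum("si,ij,sj->s", states, off, states)
    idx = np.arange(1 << n)
    neighbor_e = np.stack([energies[idx ^ (1 << b)] for b in range(n)], axis=1)
    strict = (energies[:, None] < neighbor_e).all(axis=1)
    minima = np.flatnonzero(strict)
    barriers = (neighbor_e[minima] - energies[minima, None]).min(axis=1)
    return EnergyLandscape(energies, minima, barriers, n)
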