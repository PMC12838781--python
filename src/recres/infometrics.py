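"""Plugin (maximum-likelihood) information estimators and noise scans.

All estimators are plugin estimates over empirical frequencies with base-2
logarithms and the convention 0·log 0 = 0.  No bias correction is applied
anywhere: the elevated mutual-information floor of large state spaces at
finite run length (≈3.6 bits for a 10-neuron system over 10^5 steps) is a
finite-sample plugin artifact that the analysis deliberately retains, since
resonance is read off the *shape* of the curve, not its offset.

Mutual information of a trajectory means the temporal pairing I(z_t; z_{t+1})
between consecutive encoded states — the quantity whose interior maximum at
intermediate noise, with entropy still rising, signals recurrence resonance.
Transfer entropy is first-order: the joint of (target_{t+1}, target_t,
source_t).
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .connectivity import ConditionSpec, build_weight_matrix
from .dynamics import simulate_ensemble

__all__ = [
    "SymbolSeries",
    "ScanResult",
    "entropy",
    "mutual_information",
    "temporal_mi",
    "transfer_entropy",
    "subsystem_series",
    "noise_scan",
    "find_peak",
    "per_trial_values",
    "shuffle_surrogate",
    "trial_weight_stack",
]


@dataclass(frozen=True)
class SymbolSeries:
    """A length-T integer series over the alphabet [0, 2^m)."""

    symbols: np.ndarray
    m: int
    label: str = "global"

    def __post_init__(self) -> None:
        s = np.asarray(self.symbols)
        if s.size and (s.min() < 0 or s.max() >= 1 << self.m):
            raise ValueError(f"symbols outside [0, 2^{self.m})")


def _as_symbols(x) -> np.ndarray:
    s = x.symbols if isinstance(x, SymbolSeries) else x
    return np.asarray(s, dtype=np.int64)


def _plugin_bits(counts: np.ndarray) -> float:
    n = counts.sum()
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def entropy(series) -> float:
    """Plugin entropy H(X) = −Σ P(x) log2 P(x) in bits."""
    s = _as_symbols(series)
    if s.size == 0:
        raise ValueError("empty series")
    return _plugin_bits(np.bincount(s))


def mutual_information(x, y) -> float:
    """Plugin mutual information I(X;Y) in bits from the empirical joint."""
    xs, ys = _as_symbols(x), _as_symbols(y)
    if xs.shape != ys.shape:
        raise ValueError("series must have equal length")
    if xs.size == 0:
        raise ValueError("empty series")
    ky = int(ys.max()) + 1
    joint = np.bincount(xs * ky + ys)
    return entropy(xs) + entropy(ys) - _plugin_bits(joint)


def temporal_mi(series) -> float:
    """I(z_t; z_{t+1}) over the T−1 consecutive pairs of one series."""
    s = _as_symbols(series)
    if s.size < 2:
        raise ValueError("need at least two symbols")
    return mutual_information(s[:-1], s[1:])


def transfer_entropy(source, target) -> float:
    """First-order plugin transfer entropy TE(source → target) in bits.

    TE = H(B_{t+1} | B_t) − H(B_{t+1} | B_t, A_t), estimated from the
    empirical joint of (B_{t+1}, B_t, A_t) over the T−1 transitions.
    """
    a, b = _as_symbols(source), _as_symbols(target)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    if a.size < 2:
        raise ValueError("need at least two symbols")
    b_next, b_now, a_now = b[1:], b[:-1], a[:-1]
    ka = int(a_now.max()) + 1
    kb = int(max(b_next.max(), b_now.max())) + 1
    h_bb = _plugin_bits(np.bincount(b_next * kb + b_now))
    h_b = _plugin_bits(np.bincount(b_now))
    h_ba = _plugin_bits(np.bincount(b_now * ka + a_now))
    h_bba = _plugin_bits(np.bincount((b_next * kb + b_now) * ka + a_now))
    return h_bb - h_b - h_bba + h_ba


def shuffle_surrogate(source, target, rng: np.random.Generator) -> float:
    """TE with a time-shuffled source: isolates the plugin-bias floor."""
    a = _as_symbols(source)
    return transfer_entropy(rng.permutation(a), target)


def subsystem_series(encoded, bits: tuple[int, int], label: str | None = None) -> SymbolSeries:
    """Project encoded global states onto the bit range [lo, hi) of neurons."""
    lo, hi = bits
    if not 0 <= lo < hi:
        raise ValueError("bad bit range")
    s = (_as_symbols(encoded) >> lo) & ((1 << (hi - lo)) - 1)
    return SymbolSeries(s, hi - lo, label or f"neurons {lo + 1}-{hi}")


# ---------------------------------------------------------------------------
# ensemble noise scans


@dataclass
class ScanResult:
    """Tidy per-(noise, trial, observable) values for one condition and W."""

    condition: str
    W: float
    grid: tuple[float, ...]
    trials: int
    steps: int
    data: pd.DataFrame  # columns: condition, W, r, trial, observable, value

    def summary(self) -> pd.DataFrame:
        g = self.data.groupby(["observable", "r"])["value"]
        out = g.agg(mean="mean", sd="std").reset_index()
        out["sd"] = out["sd"].fillna(0.0)
        return out


# standard partition of the 10-neuron system
SUBSYSTEM_A = (0, 5)
SUBSYSTEM_B = (5, 10)


def _stack_from_seedseqs(spec: ConditionSpec, W: float, seedseqs) -> np.ndarray:
    mats = []
    for ss in seedseqs:
        wseed = int(ss.generate_state(1)[0])
        wm = build_weight_matrix(_dc_replace(spec, seed=wseed))
        mats.append(W * wm.values)
    return np.asarray(mats)


def trial_weight_stack(spec: ConditionSpec, W: float, trials: int, seed) -> np.ndarray:
    """The (trials, n, n) effective weight matrices a ``noise_scan`` with this
    seed draws — one matrix per trial, held fixed across the grid."""
    return _stack_from_seedseqs(spec, W, np.random.SeedSequence(seed).spawn(trials))


def _observable_values(enc_col: np.ndarray, m: int, observables: Iterable[str]) -> dict[str, float]:
    out: dict[str, float] = {}
    cache: dict[str, np.ndarray] = {"global": enc_col}
    half = m // 2

    def series(tag: str) -> np.ndarray:
        if tag not in cache:
            bits = (0, half) if tag == "A" else (half, m)
            cache[tag] = subsystem_series(enc_col, bits).symbols
        return cache[tag]

    for obs in observables:
        if obs == "entropy":
            out[obs] = entropy(enc_col)
        elif obs == "mi":
            out[obs] = temporal_mi(enc_col)
        elif obs in ("entropy_A", "entropy_B"):
            out[obs] = entropy(series(obs[-1]))
        elif obs in ("mi_A", "mi_B"):
            out[obs] = temporal_mi(series(obs[-1]))
        elif obs == "te_AB":
            out[obs] = transfer_entropy(series("A"), series("B"))
        elif obs == "te_BA":
            out[obs] = transfer_entropy(series("B"), series("A"))
        else:
            raise ValueError(f"unknown observable {obs!r}")
    return out


def noise_scan(
    spec: ConditionSpec,
    W: float,
    grid: Sequence[float],
    trials: int,
    steps: int,
    observables: Sequence[str] = ("entropy", "mi"),
    seed: int | None = None,
    redraw_per_point: bool = False,
) -> ScanResult:
    """Ensemble scan over noise strengths.

    One weight matrix per trial, drawn from the trial's seed and held fixed
    across the whole grid (``redraw_per_point`` redraws instead); the noise
    realization is independent per grid point.  All randomness derives from
    ``seed`` via a SeedSequence, so identical calls give identical results.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    root = np.random.SeedSequence(seed)
    children = root.spawn(trials + len(grid))
    grid_ss = children[trials:]

    stack = None if redraw_per_point else _stack_from_seedseqs(spec, W, children[:trials])
    rows = []
    for gi, r in enumerate(grid):
        if redraw_per_point:
            stack = _stack_from_seedseqs(spec, W, grid_ss[gi].spawn(trials))
        enc = simulate_ensemble(stack, steps, float(r), grid_ss[gi])
        for t in range(trials):
            vals = _observable_values(enc[:, t].astype(np.int64), spec.n, observables)
            for obs, v in vals.items():
                rows.append((spec.name or spec.condition, W, float(r), t, obs, v))
    data = pd.DataFrame(rows, columns=["condition", "W", "r", "trial", "observable", "value"])
    return ScanResult(spec.name or spec.condition, W, tuple(float(r) for r in grid), trials, steps, data)


def find_peak(scan: ScanResult, observable: str = "mi") -> tuple[float, float, float]:
    """(r*, peak mean, SD at peak) of the trial-mean curve; ties → smaller r."""
    sub = scan.data[scan.data["observable"] == observable]
    if sub.empty:
        raise ValueError(f"observable {observable!r} not in scan")
    means = sub.groupby("r")["value"].mean().reindex(scan.grid)
    sds = sub.groupby("r")["value"].std().reindex(scan.grid).fillna(0.0)
    i = int(np.argmax(means.to_numpy()))
    r_star = scan.grid[i]
    return float(r_star), float(means.iloc[i]), float(sds.iloc[i])


def per_trial_values(scan: ScanResult, observable: str, r: float) -> np.ndarray:
    """Per-trial values of one observable at one grid point (sorted by trial)."""
    sub = scan.data[(scan.data["observable"] == observable) & (scan.data["r"] == r)]
    if sub.empty:
        raise ValueError(f"no values for {observable!r} at r={r}")
    return sub.sort_values("trial")["value"].to_numpy()
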