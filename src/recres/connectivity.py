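"""Weight-matrix generators for the experimental connectivity conditions.

Each condition draws an n×n coupling matrix from per-class truncated normal
distributions.  A class is an interval [p, q]; samples come from
N(μ=(p+q)/2, σ) truncated to [p, q] with σ = (q−p)/4 by default, so ≈95% of
the untruncated mass already lies inside the interval.

Conditions
----------
quantum_logic
    The cell layout mirrors the pasted-lattice relation (diagonal
    sub-relations bounded by cross-block pairs): strong excitatory weights on
    the *diagonal* (self-coupling), one class on the within-block
    off-diagonal cells (the Boolean-algebra block squares; blocks 3+2 for
    5 neurons, 2+5+3 for 10) and another on the cross-block background.
    In the excitatory 5-neuron variant the block squares are weak/negligible
    and the cross-block background carries the intermediate coupling; in the
    inhibitory variants the block squares become inhibitory and the
    background is attenuated to negligible.  This is the reconstruction that
    jointly satisfies the reported constraints — thresholding recovers the
    pasted relation, the resonance sits near r = 1, within-block E/I balance
    prevents freezing — and it is recorded in the methods note as the
    package's declared reading of the figure-only layout.

diagonal
    Strong self-coupling only; all off-diagonal cells share one background
    class (possibly eliminated entirely, i.e. exactly zero).

broken_quantum_logic
    A quantum-logic matrix whose background entries (every cell outside the
    strong diagonal) are randomly permuted among those positions, preserving
    the per-class cell counts (connectivity density) while destroying the
    block topology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "WeightClassSpec",
    "ConditionSpec",
    "WeightMatrix",
    "sample_truncated_normal",
    "category_matrix",
    "build_weight_matrix",
    "break_background",
    "scale",
    "condition_spec",
    "CONDITIONS",
    "save_weights",
    "load_weights",
]


@dataclass(frozen=True)
class WeightClassSpec:
    """A named weight class: samples live in [low, high], centred at the midpoint."""

    name: str
    low: float
    high: float
    sigma: float | None = None  # defaults to (high − low)/4

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"class {self.name!r}: require low < high")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError(f"class {self.name!r}: sigma must be positive")

    @property
    def mu(self) -> float:
        return (self.low + self.high) / 2

    @property
    def scale_(self) -> float:
        return self.sigma if self.sigma is not None else (self.high - self.low) / 4


def sample_truncated_normal(spec: WeightClassSpec, count: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``count`` values from N(μ, σ) truncated (exactly) to [low, high]."""
    if count < 0:
        raise ValueError("count must be non-negative")
    if count == 0:
        return np.empty(0)
    a = (spec.low - spec.mu) / spec.scale_
    b = (spec.high - spec.mu) / spec.scale_
    return stats.truncnorm.rvs(a, b, loc=spec.mu, scale=spec.scale_, size=count, random_state=rng)


# ---------------------------------------------------------------------------
# condition specification


@dataclass(frozen=True)
class ConditionSpec:
    """Everything needed to regenerate one weight matrix exactly.

    ``class_assignment`` maps cell categories to weight classes.  Categories
    are ``self`` (the diagonal), plus ``within_block``/``cross_block`` for
    lattice conditions or ``background`` for diagonal conditions.  A ``None``
    class means the cells are eliminated (exactly zero).
    """

    n: int
    condition: str  # quantum_logic | diagonal | broken_quantum_logic
    variant: str  # excitatory | inhibitory
    class_assignment: dict[str, WeightClassSpec | None]
    blocks: tuple[int, ...] | None = None
    seed: int | None = None
    symmetric: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if self.condition not in ("quantum_logic", "diagonal", "broken_quantum_logic"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.condition != "diagonal":
            if self.blocks is None or sum(self.blocks) != self.n:
                raise ValueError("block sizes must sum to n for lattice conditions")
        for cat in self._categories():
            if cat not in self.class_assignment:
                raise ValueError(f"no weight class assigned to category {cat!r}")

    def _categories(self) -> tuple[str, ...]:
        if self.condition == "diagonal":
            return ("self", "background")
        return ("self", "within_block", "cross_block")


def category_matrix(spec: ConditionSpec) -> np.ndarray:
    """n×n array of category names for every cell of the condition."""
    n = spec.n
    cats = np.empty((n, n), dtype=object)
    if spec.condition == "diagonal":
        cats[:] = "background"
        np.fill_diagonal(cats, "self")
        return cats
    ids = np.repeat(np.arange(len(spec.blocks)), spec.blocks)
    same = ids[:, None] == ids[None, :]
    cats[:] = "cross_block"
    cats[same] = "within_block"
    np.fill_diagonal(cats, "self")
    return cats


@dataclass
class WeightMatrix:
    """An n×n coupling matrix with per-cell class labels and a scaling factor W.

    ``values`` holds the unscaled draws (each inside its class interval);
    ``weights`` — what the dynamics consume — is ``scale × values``.
    """

    values: np.ndarray
    classes: np.ndarray
    scale: float = 1.0
    spec: ConditionSpec | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def weights(self) -> np.ndarray:
        return self.scale * self.values

    @property
    def class_specs(self) -> dict[str, WeightClassSpec]:
        if self.spec is None:
            return {}
        return {
            cls.name: cls
            for cls in self.spec.class_assignment.values()
            if cls is not None
        }

    def strong_mask(self) -> np.ndarray:
        """Boolean mask of the strong (signal-pathway) cells."""
        return self.classes == "strong"


def build_weight_matrix(spec: ConditionSpec) -> WeightMatrix:
    """Sample the condition's matrix; bit-reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    base = spec if spec.condition != "broken_quantum_logic" else replace(spec, condition="quantum_logic")
    cats = category_matrix(base)
    n = spec.n
    values = np.zeros((n, n))
    classes = np.empty((n, n), dtype=object)
    for cat in base._categories():
        cls = spec.class_assignment[cat]
        mask = cats == cat
        if cls is None:
            classes[mask] = "none"
            continue
        values[mask] = sample_truncated_normal(cls, int(mask.sum()), rng)
        classes[mask] = cls.name
    if spec.symmetric:
        iu = np.triu_indices(n, k=1)
        values[(iu[1], iu[0])] = values[iu]
        classes[(iu[1], iu[0])] = classes[iu]
    wm = WeightMatrix(values, classes, 1.0, spec)
    if spec.condition == "broken_quantum_logic":
        wm.spec = replace(spec, condition="quantum_logic")
        wm = break_background(wm, rng)
        wm.spec = spec
    return wm


def break_background(matrix: WeightMatrix, rng: np.random.Generator) -> WeightMatrix:
    """Permute background entries (values and labels jointly).

    The strong signal-pathway cells are untouched; every other cell is
    shuffled among those positions, so the sorted multiset of entries —
    hence the per-class cell counts and connectivity density — is preserved
    while the block topology is destroyed.
    """
    if matrix.spec is None or matrix.spec.condition != "quantum_logic":
        raise ValueError("break_background applies only to quantum_logic matrices")
    off = ~matrix.strong_mask()
    idx = np.flatnonzero(off.ravel())
    perm = rng.permutation(len(idx))
    values = matrix.values.copy().ravel()
    classes = matrix.classes.copy().ravel()
    values[idx] = values[idx[perm]]
    classes[idx] = classes[idx[perm]]
    n = matrix.n
    return WeightMatrix(values.reshape(n, n), classes.reshape(n, n), matrix.scale, matrix.spec)


def scale(matrix: WeightMatrix, W: float) -> WeightMatrix:
    """Apply the weight scaling factor W (the experiment grid uses W ∈ {1, 2, 5, 10})."""
    if W <= 0:
        raise ValueError("W must be positive")
    return WeightMatrix(matrix.values, matrix.classes, matrix.scale * W, matrix.spec)


# ---------------------------------------------------------------------------
# the named experimental conditions

_FIVE_STRONG = WeightClassSpec("strong", 0.7, 1.0)
_FIVE_INTERMEDIATE = WeightClassSpec("intermediate", 0.2, 0.3)
_FIVE_WEAK = WeightClassSpec("weak", 0.0, 0.05)
_FIVE_INHIBITORY = WeightClassSpec("inhibitory", -0.8, -0.4)
_FIVE_DIAG_INHIBITORY = WeightClassSpec("inhibitory", -0.26, -0.16)
_TEN_STRONG = WeightClassSpec("strong", 0.95, 1.05)
_TEN_NEGLIGIBLE = WeightClassSpec("weak", 0.02, 0.08)
_TEN_INHIBITORY = WeightClassSpec("inhibitory", -0.75, -0.55)


def _five_ql_excitatory(seed):
    return ConditionSpec(
        5, "quantum_logic", "excitatory",
        {"self": _FIVE_STRONG, "within_block": _FIVE_WEAK, "cross_block": _FIVE_INTERMEDIATE},
        blocks=(3, 2), seed=seed, name="five_ql_excitatory",
    )


def _five_ql_inhibitory(seed):
    # the formerly negligible block squares become inhibitory and the
    # formerly intermediate cross-block background is attenuated to weak
    return ConditionSpec(
        5, "quantum_logic", "inhibitory",
        {"self": _FIVE_STRONG, "within_block": _FIVE_INHIBITORY, "cross_block": _FIVE_WEAK},
        blocks=(3, 2), seed=seed, name="five_ql_inhibitory",
    )


def _five_diagonal_excitatory(seed):
    return ConditionSpec(
        5, "diagonal", "excitatory",
        {"self": _FIVE_STRONG, "background": _FIVE_WEAK},
        seed=seed, name="five_diagonal_excitatory",
    )


def _five_diagonal_inhibitory(seed):
    return ConditionSpec(
        5, "diagonal", "inhibitory",
        {"self": _FIVE_STRONG, "background": _FIVE_DIAG_INHIBITORY},
        seed=seed, name="five_diagonal_inhibitory",
    )


def _ten_ql(seed):
    return ConditionSpec(
        10, "quantum_logic", "inhibitory",
        {"self": _TEN_STRONG, "within_block": _TEN_INHIBITORY, "cross_block": _TEN_NEGLIGIBLE},
        blocks=(2, 5, 3), seed=seed, name="ten_ql",
    )


def _ten_broken(seed):
    return replace(_ten_ql(seed), condition="broken_quantum_logic", name="ten_broken")


def _ten_diagonal(seed):
    return ConditionSpec(
        10, "diagonal", "excitatory",
        {"self": _TEN_STRONG, "background": None},
        seed=seed, name="ten_diagonal",
    )


CONDITIONS: dict[str, Callable[[int | None], ConditionSpec]] = {
    "five_ql_excitatory": _five_ql_excitatory,
    "five_ql_inhibitory": _five_ql_inhibitory,
    "five_diagonal_excitatory": _five_diagonal_excitatory,
    "five_diagonal_inhibitory": _five_diagonal_inhibitory,
    "ten_ql": _ten_ql,
    "ten_broken": _ten_broken,
    "ten_diagonal": _ten_diagonal,
}


def condition_spec(name: str, seed: int | None = None) -> ConditionSpec:
    """Look up a named experimental condition, binding the seed."""
    try:
        return CONDITIONS[name](seed)
    except KeyError:
        raise KeyError(f"unknown condition {name!r}; known: {sorted(CONDITIONS)}") from None


# ---------------------------------------------------------------------------
# I/O: CSV values + JSON sidecar (classes, spec, scale); round-trip exact


def _spec_to_dict(spec: ConditionSpec) -> dict:
    def cls_dict(c):
        return None if c is None else {"name": c.name, "low": c.low, "high": c.high, "sigma": c.sigma}

    return {
        "n": spec.n,
        "condition": spec.condition,
        "variant": spec.variant,
        "class_assignment": {k: cls_dict(v) for k, v in spec.class_assignment.items()},
        "blocks": list(spec.blocks) if spec.blocks else None,
        "seed": spec.seed,
        "symmetric": spec.symmetric,
        "name": spec.name,
    }


def _spec_from_dict(d: dict) -> ConditionSpec:
    def cls(c):
        return None if c is None else WeightClassSpec(c["name"], c["low"], c["high"], c["sigma"])

    return ConditionSpec(
        d["n"], d["condition"], d["variant"],
        {k: cls(v) for k, v in d["class_assignment"].items()},
        blocks=tuple(d["blocks"]) if d["blocks"] else None,
        seed=d["seed"], symmetric=d["symmetric"], name=d["name"],
    )


def save_weights(matrix: WeightMatrix, csv_path: str | Path) -> None:
    csv_path = Path(csv_path)
    np.savetxt(csv_path, matrix.values, delimiter=",", fmt="%.17g")
    sidecar = {
        "classes": matrix.classes.tolist(),
        "scale": matrix.scale,
        "spec": _spec_to_dict(matrix.spec) if matrix.spec else None,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_weights(csv_path: str | Path) -> WeightMatrix:
    csv_path = Path(csv_path)
    values = np.loadtxt(csv_path, delimiter=",", ndmin=2)
    sidecar = json.loads(csv_path.with_suffix(".json").read_text())
    classes = np.array(sidecar["classes"], dtype=object)
    spec = _spec_from_dict(sidecar["spec"]) if sidecar["spec"] else None
    return WeightMatrix(values, classes, sidecar["scale"], spec)
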