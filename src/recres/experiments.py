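"""End-to-end replication protocols and condition comparisons.

A :class:`Protocol` bundles everything one analysis figure needs — the
connectivity condition(s), weight scaling factors, run lengths (20,000 steps
for 5-neuron systems and subsystem observations, 100,000 for the 10-neuron
global state space), the noise grid, trial count (20) and requested
artifacts.  ``run_protocol`` executes it and writes tables, figures and a
manifest with full provenance; every protocol replays bit-identically from
its master seed, with all per-trial randomness derived through a documented
SeedSequence tree.

``compare_conditions`` reproduces the peak-transfer-entropy statistics:
per-trial peak TE values per connectivity condition, a one-way ANOVA across
conditions, and pairwise independent t-tests (classic pooled-variance by
default; Welch optional).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, replace
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .attractors import build_stm, classification_table, classify
from .connectivity import build_weight_matrix, condition_spec
from .dynamics import (DEFAULT_NOISE_GRID, TE_NOISE_GRID, SimulationConfig,
                       raster, simulate)
from .infometrics import ScanResult, find_peak, noise_scan, per_trial_values
from .plotting import (plot_classification, plot_raster, plot_scan, plot_stm,
                       plot_te_comparison)

__all__ = [
    "Protocol",
    "PROTOCOLS",
    "run_protocol",
    "compare_conditions",
    "ComparisonReport",
    "replicate_figure",
    "peak_te_per_trial",
]

# standard trial count for ensemble statistics
N_TRIALS = 20
# run lengths: 5-neuron / subsystem state spaces vs the 10-neuron global one
STEPS_SMALL = 20_000
STEPS_GLOBAL = 100_000


@dataclass(frozen=True)
class Protocol:
    """A fully serializable description of one replication experiment."""

    name: str
    conditions: tuple[str, ...]
    W_list: tuple[float, ...] = (1.0, 2.0, 5.0, 10.0)
    steps: int = STEPS_SMALL
    trials: int = N_TRIALS
    grid: tuple[float, ...] = DEFAULT_NOISE_GRID
    observables: tuple[str, ...] = ("entropy", "mi")
    local_W: tuple[float, ...] = ()  # W values for subsystem scans (20k steps)
    stm_W: tuple[float, ...] = ()  # W values for single-trial STMs at the MI peak
    stm_noise_levels: tuple[float, ...] = ()  # explicit extra STM noise levels (first W)
    classify_states: bool = False
    raster_W: tuple[float, ...] = ()
    te_compare: bool = False


PROTOCOLS: dict[str, Protocol] = {
    p.name: p
    for p in [
        Protocol("fig2_ql_excitatory_5n", ("five_ql_excitatory",)),
        Protocol("fig3_stm_5n", ("five_ql_excitatory",), stm_W=(1.0, 2.0, 5.0, 10.0),
                 stm_noise_levels=(0.0, 1.0, 3.0, 18.0)),
        Protocol("fig4_ql_inhibitory_5n", ("five_ql_inhibitory",)),
        Protocol("fig5_stm_inhibitory_5n", ("five_ql_inhibitory",), stm_W=(1.0, 2.0, 5.0, 10.0)),
        Protocol("fig6_diagonal_5n", ("five_diagonal_excitatory", "five_diagonal_inhibitory"),
                 stm_W=(1.0,)),
        Protocol("fig7_ql_inhibitory_10n", ("ten_ql",), steps=STEPS_GLOBAL),
        Protocol("fig8_stm_10n", ("ten_ql",), steps=STEPS_GLOBAL, stm_W=(1.0, 2.0)),
        Protocol("fig9_classification_10n", ("ten_ql",), steps=STEPS_GLOBAL,
                 stm_W=(1.0, 2.0), classify_states=True),
        Protocol("fig10_raster_10n", ("ten_ql",), steps=STEPS_GLOBAL, raster_W=(1.0, 2.0)),
        Protocol("fig11_subsystems_10n", ("ten_ql",), steps=STEPS_GLOBAL,
                 local_W=(1.0, 2.0)),
        Protocol("fig12_diagonal_10n", ("ten_diagonal",), steps=STEPS_GLOBAL,
                 local_W=(1.0, 2.0), stm_W=(2.0,)),
        Protocol("fig13_raster_diagonal_10n", ("ten_diagonal",), steps=STEPS_GLOBAL,
                 raster_W=(2.0,)),
        Protocol("fig14_broken_10n", ("ten_broken",), steps=STEPS_GLOBAL,
                 local_W=(1.0, 2.0), stm_W=(2.0,)),
        Protocol("fig15_raster_broken_10n", ("ten_broken",), steps=STEPS_GLOBAL,
                 raster_W=(2.0,)),
        Protocol("fig16_te_comparison", ("ten_ql", "ten_diagonal", "ten_broken"),
                 W_list=(1.0, 2.0), steps=STEPS_GLOBAL, grid=TE_NOISE_GRID,
                 observables=("entropy", "mi", "te_AB"), te_compare=True),
    ]
}


def _seed_for(master_seed: int, *path: str) -> np.random.SeedSequence:
    """Deterministic per-stage seed derivation (documented provenance)."""
    digest = [zlib.crc32(p.encode()) for p in path]
    return np.random.SeedSequence([int(master_seed) % (1 << 31)] + digest)


def _scan_seed(master_seed: int, *path: str) -> int:
    return int(_seed_for(master_seed, *path).generate_state(1)[0] % (1 << 31))


def run_protocol(p: Protocol | str, outdir: str | Path, master_seed: int = 0) -> dict:
    """Execute a protocol and write all requested artifacts under ``outdir``."""
    if isinstance(p, str):
        if p not in PROTOCOLS:
            raise KeyError(f"unknown protocol {p!r}; known: {sorted(PROTOCOLS)}")
        p = PROTOCOLS[p]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"protocol": p, "scans": {}, "local_scans": {}, "stms": {},
                    "classifications": {}, "rasters": {}, "comparison": None}

    all_rows = []
    for cond in p.conditions:
        spec = condition_spec(cond)
        for W in p.W_list:
            scan = noise_scan(spec, W, p.grid, p.trials, p.steps, p.observables,
                              seed=_scan_seed(master_seed, p.name, cond, f"W{W}"))
            bundle["scans"][(cond, W)] = scan
            all_rows.append(scan.data)
        for W in p.local_W:
            scan = noise_scan(spec, W, p.grid, p.trials, STEPS_SMALL,
                              ("entropy_A", "mi_A", "entropy_B", "mi_B"),
                              seed=_scan_seed(master_seed, p.name, cond, f"local W{W}"))
            bundle["local_scans"][(cond, W)] = scan
            all_rows.append(scan.data)
    if all_rows:
        tidy = pd.concat(all_rows, ignore_index=True)
        tidy.to_csv(outdir / "scan.csv", index=False)
        summ = (tidy.groupby(["condition", "W", "observable", "r"])["value"]
                .agg(mean="mean", sd="std").reset_index())
        summ.to_csv(outdir / "summary.csv", index=False)

    for cond in p.conditions:
        spec = condition_spec(cond)
        peak_r = {
            W: find_peak(bundle["scans"][(cond, W)], "mi")[0]
            for W in p.W_list if (cond, W) in bundle["scans"]
        }
        stm_jobs = [(W, peak_r.get(W)) for W in p.stm_W]
        if p.stm_noise_levels and p.stm_W:
            stm_jobs += [(p.stm_W[0], r) for r in p.stm_noise_levels]
        for W, r in stm_jobs:
            if r is None:
                continue
            model, cls = _single_trial_stm(spec, W, r, p.steps, master_seed, p.name)
            bundle["stms"][(cond, W, r)] = model
            tag = f"{cond}_W{W:g}_r{r:g}"
            np.savetxt(outdir / f"stm_{tag}.csv", model.stm, delimiter=",", fmt="%.10g")
            if p.classify_states:
                bundle["classifications"][(cond, W, r)] = cls
                classification_table(model, cls).to_csv(outdir / f"classification_{tag}.csv", index=False)
        for W in p.raster_W:
            r = peak_r.get(W, 1.0)
            traj = _single_trial_trajectory(spec, W, r, p.steps, master_seed, p.name)
            bundle["rasters"][(cond, W)] = traj

    if p.te_compare:
        reports = {}
        for W in p.W_list:
            groups_w = {c: peak_te_per_trial(bundle["scans"][(c, W)]) for c in p.conditions}
            rep = compare_conditions(groups_w)
            reports[W] = rep
            (outdir / f"te_stats_W{W:g}.json").write_text(rep.to_json())
        bundle["comparison"] = reports

    manifest = {
        "protocol": {**asdict(p)},
        "master_seed": int(master_seed),
        "version": __version__,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=list))
    return bundle


def _single_trial_weights(spec, W, master_seed, tag):
    wseed = _scan_seed(master_seed, tag, spec.name, "stm-weights")
    from .connectivity import scale as _scale

    return _scale(build_weight_matrix(replace(spec, seed=wseed)), W)


def _single_trial_trajectory(spec, W, r, steps, master_seed, tag):
    wm = _single_trial_weights(spec, W, master_seed, tag)
    cfg = SimulationConfig(steps=steps, noise_strength=r,
                           seed=_scan_seed(master_seed, tag, spec.name, f"stm r{r}"),
                           keep_continuous=False)
    return simulate(wm, cfg)


def _single_trial_stm(spec, W, r, steps, master_seed, tag):
    traj = _single_trial_trajectory(spec, W, r, steps, master_seed, tag)
    model = build_stm(traj.encoded, spec.n)
    return model, classify(model)


def peak_te_per_trial(scan: ScanResult, observable: str = "te_AB") -> np.ndarray:
    """Per-trial TE at the grid point maximizing the ensemble-mean curve.

    All trials are read at the shared r* so the groups entering the
    statistics are comparable.
    """
    r_star, _, _ = find_peak(scan, observable)
    return per_trial_values(scan, observable, r_star)


@dataclass
class ComparisonReport:
    groups: dict[str, list[float]]
    anova_F: float
    anova_p: float
    pairwise: list[dict]  # {a, b, t, p}
    degenerate: bool = False
    welch: bool = False

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def compare_conditions(groups: dict[str, Sequence[float]], welch: bool = False) -> ComparisonReport:
    """One-way ANOVA across conditions plus pairwise two-sample t-tests."""
    if len(groups) < 2:
        raise ValueError("need at least two conditions")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"condition {k!r} has fewer than 2 trials")
    degenerate = all(np.ptp(v) == 0 for v in arrays.values())
    if degenerate:
        anova_F, anova_p = float("nan"), float("nan")
    else:
        anova_F, anova_p = stats.f_oneway(*arrays.values())
    pairwise = []
    for a, b in combinations(arrays, 2):
        if np.ptp(arrays[a]) == 0 and np.ptp(arrays[b]) == 0:
            t, pval = float("nan"), float("nan")
        else:
            t, pval = stats.ttest_ind(arrays[a], arrays[b], equal_var=not welch)
        pairwise.append({"a": a, "b": b, "t": float(t), "p": float(pval)})
    return ComparisonReport({k: v.tolist() for k, v in arrays.items()},
                            float(anova_F), float(anova_p), pairwise, degenerate, welch)


# ---------------------------------------------------------------------------
# figure replication

_FIGURE_PROTOCOL = {
    "fig2": "fig2_ql_excitatory_5n",
    "fig3": "fig3_stm_5n",
    "fig4": "fig4_ql_inhibitory_5n",
    "fig5": "fig5_stm_inhibitory_5n",
    "fig6": "fig6_diagonal_5n",
    "fig7": "fig7_ql_inhibitory_10n",
    "fig8": "fig8_stm_10n",
    "fig9": "fig9_classification_10n",
    "fig10": "fig10_raster_10n",
    "fig11": "fig11_subsystems_10n",
    "fig12": "fig12_diagonal_10n",
    "fig13": "fig13_raster_diagonal_10n",
    "fig14": "fig14_broken_10n",
    "fig15": "fig15_raster_broken_10n",
    "fig16": "fig16_te_comparison",
}


def replicate_figure(name: str, outdir: str | Path, master_seed: int = 0,
                     bundle: dict | None = None) -> list[Path]:
    """Run the protocol behind a named figure and render its panels."""
    if name not in _FIGURE_PROTOCOL:
        raise KeyError(f"unknown figure {name!r}; known: {sorted(_FIGURE_PROTOCOL)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if bundle is None:
        bundle = run_protocol(_FIGURE_PROTOCOL[name], outdir, master_seed)
    if not any((bundle["scans"], bundle["stms"], bundle["rasters"], bundle["local_scans"])):
        raise IOError("empty protocol bundle: nothing to draw")
    written: list[Path] = []

    def emit(path: Path) -> Path:
        written.append(path)
        return path

    p: Protocol = bundle["protocol"]
    by_cond: dict[str, list[ScanResult]] = {}
    for (cond, W), scan in bundle["scans"].items():
        by_cond.setdefault(cond, []).append(scan)
    if name == "fig16":
        for W in p.W_list:
            scans = {c: bundle["scans"][(c, W)] for c in p.conditions}
            plot_te_comparison(scans, emit(outdir / f"{name}_W{W:g}.png"),
                               title=f"TE A->B, W={W:g}")
    elif by_cond and not (bundle["stms"] or bundle["rasters"]):
        for cond, scans in by_cond.items():
            plot_scan(scans, emit(outdir / f"{name}_{cond}.png"), title=cond)
        for (cond, W), scan in bundle["local_scans"].items():
            plot_scan([scan], emit(outdir / f"{name}_{cond}_local_W{W:g}.png"),
                      observables=("entropy_A", "mi_A"), title=f"{cond} subsystems W={W:g}")
    for (cond, W, r), model in bundle["stms"].items():
        inset = (250, 500) if name == "fig8" else None
        fig = plot_stm(model, inset=inset, title=f"{cond} W={W:g} r={r:g}")
        fig.savefig(emit(outdir / f"{name}_stm_{cond}_W{W:g}_r{r:g}.png"), dpi=150)
        import matplotlib.pyplot as plt

        plt.close(fig)
        if (cond, W, r) in bundle["classifications"]:
            plot_classification(model, bundle["classifications"][(cond, W, r)],
                                emit(outdir / f"{name}_classification_{cond}_W{W:g}.png"),
                                title=f"{cond} W={W:g}")
    for (cond, W), traj in bundle["rasters"].items():
        plot_raster(raster(traj, 1)[:300].copy(),
                    emit(outdir / f"{name}_raster_{cond}_W{W:g}_dt1.png"),
                    title=f"{cond} W={W:g}, Δt=1 (first 300 steps)")
        plot_raster(raster(traj, 200),
                    emit(outdir / f"{name}_raster_{cond}_W{W:g}_dt200.png"),
                    title=f"{cond} W={W:g}, Δt=200 (full run)")
    return written
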