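"""End-to-end pipeline: fixed points -> branch -> potential -> prefactor ->
mixture -> truncated CME (-> optional SSA), with delimited-text outputs and a
machine-readable run manifest."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import model_to_dict
from .mixture import MixtureApprox, build_mixture, marginal_X, marginal_s
from .model import ModelSpec
from .potential import PotentialBranch, potential, prefactor, trace_branch
from .presets import Preset, load_preset
from .qss import FixedPoint, find_fixed_points
from .solvers import LatticeDistribution, cme_steady_state, default_Xmax, ssa_simulate
from .util import total_variation

__all__ = ["PipelineResult", "run_pipeline", "branch_table"]


@dataclass
class PipelineResult:
    model: ModelSpec
    fixed_points: list[FixedPoint]
    branch: PotentialBranch
    mixture: MixtureApprox
    cme: LatticeDistribution
    metrics: dict
    ssa_histogram: np.ndarray | None = None


def branch_table(branch: PotentialBranch) -> pd.DataFrame:
    """Tabular view of the traced branch (x, theta, phi, k, w_0..w_smax)."""
    data = {"x": branch.grid, "theta": branch.theta}
    data["phi"] = branch.phi if branch.phi is not None else np.nan
    data["k"] = branch.prefactor if branch.prefactor is not None else np.nan
    for s in range(branch.w.shape[1]):
        data[f"w_{s}"] = branch.w[:, s]
    return pd.DataFrame(data)


def _write_two_column(path: Path, states, probs) -> None:
    with open(path, "w") as fh:
        fh.write("state\tprobability\n")
        for st, pr in zip(states, probs):
            fh.write(f"{st}\t{pr:.17g}\n")


def run_pipeline(
    source: str | Preset | ModelSpec,
    epsilon: float | None = None,
    out_dir: str | Path | None = None,
    seed: int = 0,
    n_grid: int = 2001,
    run_ssa: bool = False,
    ssa_events: int = 1_000_000,
) -> PipelineResult:
    """Run the full analysis for a preset name, Preset, or ModelSpec.

    Writes (when ``out_dir`` is given): ``branch.tsv``, ``mixture.json``,
    ``cme_marginal_X.tsv``, ``cme_marginal_s.tsv``, ``metrics.json`` and a
    ``run.json`` manifest.  Identical inputs and seed give byte-identical
    outputs.
    """
    if isinstance(source, str):
        source = load_preset(source)
    if isinstance(source, Preset):
        if epsilon is None:
            epsilon = source.epsilon_list[0]
        model = source.model(epsilon)
        name = source.name
    else:
        model = source if epsilon is None else source.with_epsilon(epsilon)
        name = "custom"

    fps = find_fixed_points(model)
    branch = trace_branch(model, fps, n_grid=n_grid)
    potential(branch)
    prefactor(model, branch)
    mix = build_mixture(model, branch)

    x_max = default_Xmax(model, fps)
    cme = cme_steady_state(model, x_max)

    grid_X, mix_X = marginal_X(mix, model, np.arange(x_max + 1))
    mix_s = marginal_s(mix, model)
    metrics = {
        "tv_marginal_X_mixture_vs_cme": total_variation(mix_X, cme.marginal_X()),
        "tv_marginal_s_mixture_vs_cme": total_variation(mix_s, cme.marginal_s()),
        "cme_boundary_mass": cme.boundary_mass,
    }

    ssa_hist = None
    if run_ssa:
        # pilot run to size t_end for the requested number of events
        pilot_t = 50.0 * model.epsilon
        pilot, _ = ssa_simulate(model, pilot_t, seed=seed + 1, record_trace=False)
        rate = max(pilot.total_events / pilot_t, 1.0)
        t_end = 1.1 * ssa_events / rate
        _, ssa_hist = ssa_simulate(
            model,
            t_end,
            seed=seed,
            burn_in=min(10.0, 0.05 * t_end),
            max_events=2 * ssa_events,
            record_trace=False,
        )
        metrics["tv_joint_ssa_vs_cme"] = total_variation(
            np.pad(ssa_hist, ((0, max(0, x_max + 1 - ssa_hist.shape[0])), (0, 0)))[
                : x_max + 1
            ],
            cme.probs,
        )

    result = PipelineResult(
        model=model,
        fixed_points=fps,
        branch=branch,
        mixture=mix,
        cme=cme,
        metrics=metrics,
        ssa_histogram=ssa_hist,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        branch_table(branch).to_csv(
            out / "branch.tsv", sep="\t", index=False, float_format="%.17g"
        )
        with open(out / "mixture.json", "w") as fh:
            json.dump(
                {
                    "epsilon": mix.epsilon,
                    "C": mix.C,
                    "modes": [asdict(m) for m in mix.modes],
                },
                fh,
                indent=2,
            )
        _write_two_column(out / "cme_marginal_X.tsv", grid_X, cme.marginal_X())
        _write_two_column(
            out / "cme_marginal_s.tsv", np.arange(model.s_max + 1), cme.marginal_s()
        )
        with open(out / "metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=2)
        manifest = {
            "version": __version__,
            "source": name,
            "seed": seed,
            "n_grid": n_grid,
            "X_max": x_max,
            "model": model_to_dict(model),
            "fixed_points": [asdict(fp) for fp in fps],
        }
        with open(out / "run.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    return result
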