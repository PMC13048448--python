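"""Orchestration: staged analysis runs from a single configuration.

A run configuration (dict or YAML file) names a registered model, its
parameters, and the stages to execute — any of ``gradient``, ``singular``,
``jacobian``, ``hessian`` and ``simulate`` — in dependency order.  Each
stage writes tidy CSV/JSON artifacts into the output directory and logs the
tolerances, grid sizes and seeds it used, so a run is reproducible from its
manifest alone.  Plots (optional) are regenerated from the written CSVs,
never from in-memory state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .directional import (convergence_stability, find_singular_strategy,
                          selection_gradient)
from .model import get_model
from .quadratic import classify_second_order, hessian
from .sexual_niche import SexualNicheParams

__all__ = ["AnalysisRun", "run"]

_STAGES = ("gradient", "singular", "jacobian", "hessian", "simulate")


@dataclass
class AnalysisRun:
    """Outcome of a staged analysis: outputs written and settings used."""

    model: str
    stages: tuple[str, ...]
    manifest: dict = field(default_factory=dict)  # stage -> list of paths
    log: dict = field(default_factory=dict)  # stage -> settings/tolerances
    results: dict = field(default_factory=dict)  # stage -> key numbers


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _build(cfg: dict):
    name = cfg.get("model", "sexual_niche")
    kwargs = {}
    if name == "sexual_niche":
        pblock = cfg.get("params", {}) or {}
        kwargs["params"] = (SexualNicheParams(**pblock)
                            if isinstance(pblock, dict)
                            else SexualNicheParams.from_yaml(pblock))
        kwargs["shared_trait"] = bool(cfg.get("shared_trait", False))
        if cfg.get("genetics"):
            from .genetics import make_genetic_system

            kwargs["genetics"] = make_genetic_system(
                cfg["genetics"], kwargs["params"].c)
    return name, get_model(name, **kwargs)


def _as_float_list(x):
    return [float(t) for t in np.asarray(x, dtype=float).reshape(-1)]


def run(config, out_dir: str | Path | None = None) -> AnalysisRun:
    """Execute the requested stages and write their artifacts.

    Raises on config schema violations (unknown stages, a ``hessian`` stage
    without a singular value from config or a prior ``singular`` stage).
    """
    cfg = _load_config(config)
    stages = tuple(cfg.get("stages", ()))
    unknown = [s for s in stages if s not in _STAGES]
    if unknown:
        raise ValueError(f"unknown stages {unknown}; valid: {_STAGES}")
    out_dir = Path(out_dir or cfg.get("out_dir", "ontosel_run"))
    name, model = _build(cfg)
    runrec = AnalysisRun(model=name, stages=stages)
    if stages:
        out_dir.mkdir(parents=True, exist_ok=True)
    solver = {
        "tol": float(cfg.get("tol", 1e-9)),
        "n_grid": int(cfg.get("n_grid", 801)),
    }
    v = cfg.get("v")
    v_star = cfg.get("v_star")

    def _write_json(stage, payload):
        path = out_dir / f"{stage}.json"
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
        runrec.manifest.setdefault(stage, []).append(str(path))

    def _write_csv(stage, frame: pd.DataFrame, suffix=""):
        path = out_dir / f"{stage}{suffix}.csv"
        frame.to_csv(path, index=False)
        runrec.manifest.setdefault(stage, []).append(str(path))

    for stage in stages:
        if stage == "gradient":
            if v is None:
                raise ValueError("gradient stage requires 'v' in the config")
            grad = selection_gradient(model, v, **solver)
            _write_csv(stage, grad.to_frame())
            payload = {"v": _as_float_list(v),
                       "totals": _as_float_list(grad.totals)}
            if grad.constrained_totals:
                payload["constrained_totals"] = {
                    str(k): float(val)
                    for k, val in grad.constrained_totals.items()}
            _write_json(stage, payload)
            runrec.results[stage] = payload
            runrec.log[stage] = dict(solver)
        elif stage == "singular":
            guess = cfg.get("guess", v if v is not None else
                            [0.5] * model.n_classes * model.n_traits)
            ss = find_singular_strategy(model, guess, **solver)
            v_star = ss.v_star
            payload = {
                "v_star": _as_float_list(ss.v_star),
                "gradient_norm": ss.gradient_norm,
                "converged": ss.converged,
                "boundary_pinned": [list(map(list, ss.boundary_pinned))
                                    if ss.boundary_pinned else []][0],
                "n_evaluations": ss.n_evaluations,
            }
            _write_json(stage, payload)
            runrec.results[stage] = payload
            runrec.log[stage] = dict(solver, guess=_as_float_list(guess))
        elif stage == "jacobian":
            if v_star is None:
                raise ValueError(
                    "jacobian requires v*: provide 'v_star' or run the "
                    "'singular' stage first")
            rep = convergence_stability(model, v_star, **solver)
            payload = {
                "v_star": _as_float_list(v_star),
                "J": [list(map(float, row)) for row in rep.J],
                "leading_symmetric_eigenvalue": rep.leading_eigenvalue,
                "label": rep.label,
            }
            _write_json(stage, payload)
            runrec.results[stage] = payload
            runrec.log[stage] = dict(solver, fd_step=rep.step)
        elif stage == "hessian":
            if v_star is None:
                raise ValueError(
                    "hessian requires v*: provide 'v_star' or run the "
                    "'singular' stage first")
            rep = hessian(model, v_star, **solver)
            _write_csv(stage, rep.to_frame(), suffix="_components")
            cls = classify_second_order(rep)
            payload = {
                "v_star": _as_float_list(v_star),
                "H": [list(map(float, row)) for row in rep.H],
                "eigenvalues": _as_float_list(rep.eigenvalues),
                "net": cls["net"],
                "per_trait": {str(k): lab
                              for k, lab in cls["per_trait"].items()},
            }
            if rep.constrained:
                payload["constrained"] = {
                    str(k): float(val) for k, val in rep.constrained.items()}
            _write_json(stage, payload)
            runrec.results[stage] = payload
            runrec.log[stage] = dict(solver)
        elif stage == "simulate":
            from .simulate import SimConfig, simulate, summarize

            sim_cfg = dict(cfg.get("sim", {}))
            sim_cfg.setdefault("seed", int(cfg.get("seed", 0)))
            sim = SimConfig(params=model.params,
                            shared_trait=bool(cfg.get("shared_trait", False)),
                            **sim_cfg)
            trace = simulate(sim)
            summary = summarize(trace)
            traits = pd.DataFrame({
                "time": trace.times,
                "pop_size": trace.pop_size,
                "mean_trait_f": trace.mean_trait[0],
                "mean_trait_m": trace.mean_trait[1],
            })
            _write_csv(stage, traits, suffix="_traits")
            f_hist, m_hist = trace.size_histograms()
            hist = pd.DataFrame({
                "bin_left": trace.hist_bins[:-1],
                "bin_right": trace.hist_bins[1:],
                "female_density": f_hist,
                "male_density": m_hist,
            })
            _write_csv(stage, hist, suffix="_histograms")
            payload = {
                "kl_male_female": summary["kl_male_female"],
                "branching": {k: (bool(val) if isinstance(val, (bool, np.bool_))
                                  else float(val))
                              for k, val in summary["branching"].items()},
                "extinct": bool(trace.extinct),
                "final_mean_traits": _as_float_list(
                    summary["mean_final_traits"]),
                "seed": sim.seed,
            }
            _write_json(stage, payload)
            runrec.results[stage] = payload
            runrec.log[stage] = {"dt": sim.dt, "duration": sim.duration,
                                 "seed": sim.seed,
                                 "mutation_prob": sim.mutation_prob,
                                 "mutation_sd": sim.mutation_sd}
    if cfg.get("plots") and stages:
        _regenerate_plots(runrec, out_dir)
    return runrec


def _regenerate_plots(runrec: AnalysisRun, out_dir: Path) -> None:
    """Rebuild figures from the CSVs written by the stages."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for stage, paths in list(runrec.manifest.items()):
        for path in list(paths):
            if not path.endswith(".csv"):
                continue
            df = pd.read_csv(path)
            fig, ax = plt.subplots(figsize=(6, 4))
            if stage == "gradient":
                for (j, l), grp in df.groupby(["class", "trait"]):
                    ax.plot(grp["age"], grp["kernel"], label=f"class {j}")
                ax.axhline(0.0, color="k", lw=0.5)
                ax.set_xlabel("age")
                ax.set_ylabel("age-specific selection")
                ax.legend()
            elif stage == "simulate" and "mean_trait_f" in df.columns:
                ax.plot(df["time"], df["mean_trait_f"], label="female")
                ax.plot(df["time"], df["mean_trait_m"], label="male")
                ax.set_xlabel("time")
                ax.set_ylabel("mean trait")
                ax.legend()
            elif "female_density" in df.columns:
                mid = 0.5 * (df["bin_left"] + df["bin_right"])
                ax.step(mid, df["female_density"], label="female")
                ax.step(mid, df["male_density"], label="male")
                ax.set_xlabel("size")
                ax.set_ylabel("density")
                ax.legend()
            else:
                plt.close(fig)
                continue
            png = Path(path).with_suffix(".png")
            fig.tight_layout()
            fig.savefig(png, dpi=120)
            plt.close(fig)
            runrec.manifest[stage].append(str(png))
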