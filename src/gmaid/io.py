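"""Experiment file formats, run configuration and the pipeline driver.

Time series travel as tidy (long-format) CSV with columns
``experiment_id,replicate,time,metabolite,value``; a wide layout with a
``time`` column followed by one column per metabolite is auto-detected on
input.  A sidecar JSON (``<data>.meta.json``) optionally carries the true
initial state, the noise level and the seed of each series.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import estimation, network as netmod, reference, search
from .collocation import make_mesh
from .signs import SignAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "load_experiments",
    "save_experiments",
    "load_sign_pattern",
    "save_sign_pattern",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# experiments


def save_experiments(path, experiments) -> None:
    rows = []
    meta = {}
    for exp in experiments:
        names = [f"X{i + 1}" for i in range(exp.observations.shape[0])]
        for i, name in enumerate(names):
            for u, t in enumerate(exp.times):
                rows.append(
                    {
                        "experiment_id": exp.experiment_id,
                        "replicate": exp.replicate_id,
                        "time": float(t),
                        "metabolite": name,
                        "value": float(exp.observations[i, u]),
                    }
                )
        meta[f"{exp.experiment_id}/{exp.replicate_id}"] = {
            "x0": exp.x0.tolist(),
            "noise_sd_fraction": exp.noise_sd_fraction,
            "seed": exp.seed,
        }
    pd.DataFrame(rows).to_csv(path, index=False)
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2))


def _wide_to_long(df: pd.DataFrame) -> pd.DataFrame:
    value_cols = [c for c in df.columns if c != "time"]
    long = df.melt(id_vars="time", value_vars=value_cols,
                   var_name="metabolite", value_name="value")
    long["experiment_id"] = "exp"
    long["replicate"] = 0
    return long


def load_experiments(path) -> list:
    """Read experiments from tidy or wide CSV, with validation."""
    df = pd.read_csv(path)
    if "metabolite" not in df.columns and "time" in df.columns:
        df = _wide_to_long(df)
    required = {"experiment_id", "replicate", "time", "metabolite", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"experiment file missing columns: {sorted(missing)}")
    if (df["value"] <= 0).any():
        bad = df.index[df["value"] <= 0][0]
        raise ValueError(
            f"non-positive concentration at row {bad}: {df.loc[bad].to_dict()}"
        )
    meta_path = Path(str(path) + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}

    experiments = []
    for (exp_id, rep), grp in df.groupby(["experiment_id", "replicate"], sort=True):
        if grp.duplicated(["time", "metabolite"]).any():
            raise ValueError(
                f"duplicate (time, metabolite) pair in experiment {exp_id}/{rep}"
            )
        pivot = grp.pivot(index="metabolite", columns="time", values="value")
        pivot = pivot.reindex(sorted(pivot.index), axis=0)
        times = np.asarray(sorted(pivot.columns), dtype=float)
        obs = pivot[sorted(pivot.columns)].to_numpy()
        if np.isnan(obs).any():
            raise ValueError(
                f"experiment {exp_id}/{rep}: incomplete metabolite/time grid"
            )
        info = meta.get(f"{exp_id}/{rep}", {})
        x0 = np.asarray(info.get("x0", obs[:, 0]), dtype=float)
        experiments.append(
            reference.Experiment(
                times=times,
                observations=obs,
                x0=x0,
                noise_sd_fraction=float(info.get("noise_sd_fraction", 0.0)),
                replicate_id=int(rep),
                seed=info.get("seed"),
                experiment_id=str(exp_id),
            )
        )
    return experiments


# ---------------------------------------------------------------------------
# sign patterns


def save_sign_pattern(path, assignment: SignAssignment) -> None:
    Path(path).write_text(json.dumps(assignment.to_records(), indent=2))


def load_sign_pattern(path, network) -> SignAssignment:
    """Read sign records; unlisted entries default to the baseline pattern."""
    records = json.loads(Path(path).read_text())
    signs = np.array(SignAssignment.baseline(network).signs)
    for rec in records:
        signs[int(rec["reaction"]), int(rec["metabolite"])] = int(rec["sign"])
    assignment = SignAssignment(signs=signs)
    assignment.validate_against(network)
    return assignment


# ---------------------------------------------------------------------------
# configuration and pipeline


@dataclass
class RunConfig:
    """Settings for one pipeline run; every output embeds this config's hash."""

    mode: str  # simulate | generate | estimate | profile | identify
    network_path: str | None = None
    data_paths: list[str] = field(default_factory=list)
    signs_path: str | None = None
    out_dir: str = "."
    elements: int = 20
    points: int = 4
    scheme: str = "radau"
    grading: float = 1.15
    starts: int = 10
    seed: int = 0
    max_modifiers: int = 1
    topologies: int = 5
    node_limit: int = 400
    x3_init: float = 1.2
    noise_sd: float = 0.0
    replicates: int = 1
    k_samples: int = reference.DEFAULT_K_SAMPLES
    t_final: float = reference.DEFAULT_T_FINAL
    target: str | None = None
    values: list[float] = field(default_factory=list)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        colloc = doc.pop("collocation", {})
        for key, name in (("elements", "elements"), ("points", "points"),
                          ("scheme", "scheme"), ("grading", "grading")):
            if key in colloc:
                doc[name] = colloc[key]
        return cls(**doc)

    def digest(self) -> str:
        doc = dataclasses.asdict(self)
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True).encode()
        ).hexdigest()[:12]


def _resolve_network(config: RunConfig):
    if config.network_path:
        net, params = netmod.load_network(config.network_path)
        return net, params
    return reference.reference_network()


def _mesh_for(config, experiments):
    t0 = min(float(e.times[0]) for e in experiments)
    tf = max(float(e.times[-1]) for e in experiments)
    return make_mesh(t0, tf, config.elements, config.points,
                     scheme=config.scheme, grading=config.grading)


def _fit_payload(fit, config):
    return {
        "config_hash": config.digest(),
        "seed": config.seed,
        "rss": fit.rss,
        "status": fit.status,
        "n_starts_used": fit.n_starts_used,
        "gamma": fit.params.gamma.tolist(),
        "f": fit.params.f.tolist(),
        "sign_pattern": fit.sign_pattern.to_records(),
        "trajectories": [t.tolist() for t in fit.trajectories],
        "start_log": fit.start_log,
    }


def run_pipeline(config: RunConfig) -> int:
    """Execute one pipeline stage; returns 0 on success.

    Artifacts are written under ``config.out_dir``; every payload embeds the
    config hash and seed for provenance.
    """
    if config.mode not in ("simulate", "generate", "estimate", "profile", "identify"):
        raise ValueError(f"unknown mode {config.mode!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net, params = _resolve_network(config)

    if config.mode == "simulate":
        if params is None:
            raise ValueError("simulate requires parameters in the network file")
        times = np.linspace(0.0, config.t_final, config.k_samples)
        x0 = np.array(reference.DEFAULT_X0)
        if net.n_dependent == 4:
            x0[2] = config.x3_init
        else:
            x0 = np.ones(net.n_dependent)
        traj = netmod.simulate(net, params, x0, times)
        df = pd.DataFrame(traj.states, columns=[
            f"X{i + 1}" for i in range(net.n_dependent)])
        df.insert(0, "time", traj.times)
        df.to_csv(out / "trajectory.csv", index=False)
        logger.info("wrote %s", out / "trajectory.csv")
        return 0

    if config.mode == "generate":
        exps = []
        for i in range(config.replicates):
            exps.append(
                reference.generate_experiment(
                    x3_init=config.x3_init,
                    noise_sd_fraction=config.noise_sd,
                    k_samples=config.k_samples,
                    t_final=config.t_final,
                    seed=config.seed + i,
                    replicate_id=i,
                )
            )
        save_experiments(out / "experiments.csv", exps)
        logger.info("wrote %s", out / "experiments.csv")
        return 0

    experiments = []
    for p in config.data_paths:
        experiments.extend(load_experiments(p))
    if not experiments:
        raise ValueError(f"mode {config.mode} requires data_paths")
    mesh = _mesh_for(config, experiments)

    if config.mode == "estimate":
        if config.signs_path:
            signs = load_sign_pattern(config.signs_path, net)
        elif params is not None:
            signs = SignAssignment.from_parameters(net, params)
        else:
            signs = SignAssignment.baseline(net)
        fit = estimation.multistart_fit(
            net, experiments, signs, mesh=mesh,
            n_starts=config.starts, seed=config.seed,
        )
        (out / "fit.json").write_text(json.dumps(_fit_payload(fit, config), indent=2))
        logger.info("estimate: rss=%.4g -> %s", fit.rss, out / "fit.json")
        return 0

    if config.mode == "profile":
        if not config.target or not config.values:
            raise ValueError("profile requires target and values")
        signs = (
            load_sign_pattern(config.signs_path, net)
            if config.signs_path
            else SignAssignment.from_parameters(net, params)
        )
        results = estimation.profile_parameter(
            net, experiments, signs, config.target, config.values,
            mesh=mesh, n_starts=config.starts, seed=config.seed,
        )
        payload = {
            "config_hash": config.digest(),
            "target": config.target,
            "values": list(config.values),
            "rss": [r.rss for r in results],
        }
        (out / "profile.json").write_text(json.dumps(payload, indent=2))
        return 0

    if config.mode == "identify":
        ranking = search.identify_topologies(
            net, experiments, mesh=None,
            max_modifiers_per_reaction=config.max_modifiers,
            n_topologies=config.topologies, seed=config.seed,
            node_limit=config.node_limit,
        )
        payload = {
            "config_hash": config.digest(),
            "seed": config.seed,
            "exhausted": ranking.exhausted,
            "topologies": [
                {
                    "iteration": e.iteration,
                    "aic": e.aic,
                    "rss": e.fit.rss,
                    "signs": e.sign_pattern.to_records(),
                    "gamma": e.fit.params.gamma.tolist(),
                    "f": e.fit.params.f.tolist(),
                }
                for e in ranking.entries
            ],
        }
        (out / "ranking.json").write_text(json.dumps(payload, indent=2))
        # companion CSV: one row per topology, kinetic parameters + AIC + rss
        rows = []
        for e in ranking.entries:
            row = {"iteration": e.iteration, "aic": e.aic, "rss": e.fit.rss}
            for r in range(net.n_reactions):
                row[f"gamma_{r + 1}"] = e.fit.params.gamma[r]
                for j in range(net.n_dependent):
                    if e.fit.params.f[r, j] != 0:
                        row[f"f_{r + 1}{j + 1}"] = e.fit.params.f[r, j]
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "ranking.csv", index=False)
        logger.info("identify: %d topologies -> %s", len(rows), out / "ranking.json")
        return 0

    raise ValueError(f"unknown mode {config.mode!r}")
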