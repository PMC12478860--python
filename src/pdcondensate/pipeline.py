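"""Configuration-driven build -> simulate -> analyze pipeline.

A run is described by one YAML file with four sections (system,
forcefield, dynamics, analysis) whose defaults are the published study
conditions: 5000 protein beads + 5000 DNA beads as chains of length 250
in a 2000 Å periodic cube, Langevin dynamics at 300 K with t_damp =
1000 ps and dt = 10 fs.  Unknown keys are rejected.  Re-running the
analysis stage on a stored trajectory is bit-for-bit deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chain_metrics import mean_chain_rg
from .condensate import (BlockScheme, block_average, bound_protein_fraction,
                         cluster_beads, default_bound_cutoff,
                         default_cluster_cutoff, largest_cluster_fractions)
from .diffusion import displacement_distribution, fit_diffusion_modes, \
    select_mode_count
from .dynamics import LangevinParams, Trajectory, run
from .forcefield import ForceFieldParams
from .profiles import coexistence_concentrations
from .system import build_mixture

__all__ = ["RunConfig", "run_pipeline", "analyze", "interaction_regime"]

_SYSTEM_DEFAULTS = dict(n_protein=5000, dna_length=250, dna_bead_budget=5000,
                        box_edge=2000.0, placement_radius=None, seed=0)
_DYNAMICS_DEFAULTS = dict(temperature=300.0, t_damp=1000.0, dt=10.0,
                          n_steps=1000, sample_every=100, neighbor_skin=10.0)
_ANALYSIS_DEFAULTS = dict(cluster_cutoff=None, cluster_per_pair=True,
                          bound_cutoff=None, bin_width=10.0, n_blocks=5,
                          n_discard=1, lags=[], diffusion_n_max=6,
                          diffusion_bins=300)


def _merge(defaults: dict, given: dict, section: str) -> dict:
    unknown = set(given) - set(defaults)
    if unknown:
        raise ValueError(f"unknown keys in [{section}]: {sorted(unknown)}")
    out = dict(defaults)
    out.update(given)
    return out


@dataclass
class RunConfig:
    """Validated pipeline configuration (all defaults = study conditions)."""

    system: dict = field(default_factory=lambda: dict(_SYSTEM_DEFAULTS))
    forcefield: dict = field(default_factory=dict)
    dynamics: dict = field(default_factory=lambda: dict(_DYNAMICS_DEFAULTS))
    analysis: dict = field(default_factory=lambda: dict(_ANALYSIS_DEFAULTS))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - {"system", "forcefield", "dynamics", "analysis"}
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        ff_given = dict(d.get("forcefield", {}))
        ForceFieldParams.from_dict(ff_given)  # validates keys/values
        return cls(
            system=_merge(_SYSTEM_DEFAULTS, d.get("system", {}), "system"),
            forcefield=ff_given,
            dynamics=_merge(_DYNAMICS_DEFAULTS, d.get("dynamics", {}),
                            "dynamics"),
            analysis=_merge(_ANALYSIS_DEFAULTS, d.get("analysis", {}),
                            "analysis"),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {"system": self.system, "forcefield": self.forcefield,
                "dynamics": self.dynamics, "analysis": self.analysis}

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()

    def forcefield_params(self) -> ForceFieldParams:
        return ForceFieldParams.from_dict(self.forcefield)

    def langevin_params(self, seed: int | None = None) -> LangevinParams:
        d = dict(self.dynamics)
        return LangevinParams(seed=self.system["seed"] if seed is None
                              else seed, **d)


def interaction_regime(ff: ForceFieldParams) -> dict:
    """Published interaction-regime bands, attached as metadata.

    Heterotypic: weak (lambda_PD < 0.5), moderate (0.5-1.0), strong
    (> 1.0).  Homotypic: weak (lambda_PP < 3), strong (>= 3).
    """
    lpd = ff.lambda_PD
    het = "weak" if lpd < 0.5 else ("moderate" if lpd <= 1.0 else "strong")
    hom = "weak" if ff.lambda_PP < 3.0 else "strong"
    return {"heterotypic": het, "homotypic": hom}


def analyze(traj: Trajectory, topo, ff: ForceFieldParams,
            analysis: dict, outdir: Path) -> dict:
    """Run the analysis stage on a trajectory; returns the summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scheme = BlockScheme(analysis["n_blocks"], analysis["n_discard"])
    cluster_cutoff = analysis["cluster_cutoff"] or default_cluster_cutoff(ff)
    bound_cutoff = analysis["bound_cutoff"] or default_bound_cutoff(ff)

    per_pair = bool(analysis.get("cluster_per_pair", True)) \
        and analysis["cluster_cutoff"] is None

    rows = []
    for f in range(traj.n_frames):
        pos = traj.positions[f]
        if per_pair:
            cl = cluster_beads(pos, traj.box_edge, per_pair=True,
                               species=traj.species, ff=ff)
        else:
            cl = cluster_beads(pos, traj.box_edge, cluster_cutoff)
        f_p, f_d = largest_cluster_fractions(cl, topo, traj.species)
        in_largest = cl.labels == cl.largest_id
        try:
            bound = bound_protein_fraction(pos, traj.species, traj.box_edge,
                                           bound_cutoff,
                                           restrict_to=in_largest)
        except ValueError:
            bound = float("nan")
        rows.append(dict(time_fs=traj.times_fs[f], f_P=f_p, f_D=f_d,
                         bound_fraction=bound,
                         largest_size=int(np.sum(in_largest))))
    frames = pd.DataFrame(rows)
    frames.to_csv(outdir / "cluster_timeseries.csv", index=False)

    summary: dict = {"regime": interaction_regime(ff)}
    for col in ("f_P", "f_D", "bound_fraction"):
        try:
            if frames[col].isna().all():
                m, s = float("nan"), float("nan")
            else:
                m, s = block_average(frames[col].to_numpy(), scheme)
        except ValueError:
            m, s = float(frames[col].mean()), 0.0
        summary[col] = {"mean": m, "stderr": s}

    if topo.dna_chains():
        try:
            rg = mean_chain_rg(traj, topo, scheme)
            summary["dna_rg"] = {"mean": rg.mean, "stderr": rg.stderr,
                                 "units": rg.units}
            pd.DataFrame(rg.per_chain_values,
                         columns=["molecule_id", "rg"]).to_csv(
                outdir / "chain_rg.csv", index=False)
        except ValueError:
            pass

    try:
        coex = coexistence_concentrations(
            traj, topo, scheme, bin_width=analysis["bin_width"],
            cluster_cutoff=cluster_cutoff)
        summary["coexistence"] = {
            "c_dilute": list(coex["c_dilute"]),
            "c_dense": (list(coex["c_dense"])
                        if coex["c_dense"] is not None else None),
            "multiphasic_fraction": coex["multiphasic_fraction"],
        }
    except ValueError:
        pass

    lags = analysis.get("lags") or []
    if lags:
        dists = [displacement_distribution(traj, lag,
                                           n_bins=analysis["diffusion_bins"])
                 for lag in lags]
        n_sel = select_mode_count(dists, n_max=analysis["diffusion_n_max"])
        fit = fit_diffusion_modes(dists, n_sel)
        summary["diffusion"] = {
            "n_modes": n_sel,
            "p": fit.p.tolist(),
            "D_A2_per_ns": fit.D.tolist(),
            "per_lag_D": {str(k): v.tolist()
                          for k, v in fit.per_lag_D.items()},
        }

    with open(outdir / "analysis_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary


def run_pipeline(config: RunConfig, outdir, seed: int | None = None,
                 log=print) -> dict:
    """Execute build -> simulate -> analyze, writing all artifacts.

    A stored trajectory (trajectory.npz) in ``outdir`` is reused instead
    of re-simulating, which makes analysis re-runs deterministic and
    provides coarse resume behavior.  The manifest records the config
    hash, seed and package version.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ff = config.forcefield_params()
    sysc = config.system
    seed = sysc["seed"] if seed is None else seed

    system, topo = build_mixture(
        n_protein=sysc["n_protein"], dna_length=sysc["dna_length"],
        dna_bead_budget=sysc["dna_bead_budget"], box_edge=sysc["box_edge"],
        placement_radius=sysc["placement_radius"], seed=seed, ff=ff)
    log(f"built {system.n_beads} beads "
        f"({len(topo.dna_chains())} DNA chains)")

    traj_path = outdir / "trajectory.npz"
    resumed = traj_path.exists()
    if resumed:
        traj = Trajectory.load_npz(traj_path)
        log("reusing stored trajectory")
    else:
        lp = config.langevin_params(seed=seed)
        traj = run(system, topo, ff, lp)
        traj.save_npz(traj_path)
        traj.write_xyz(outdir / "trajectory.xyz")
        log(f"simulated {lp.n_steps} steps, {traj.n_frames} frames")

    summary = analyze(traj, topo, ff, config.analysis, outdir)

    manifest = {
        "config": config.to_dict(),
        "config_sha256": config.digest(),
        "seed": seed,
        "version": __version__,
        "resumed_from_trajectory": resumed,
        "n_frames": traj.n_frames,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    return summary
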