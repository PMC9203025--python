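"""Reproduction driver: figure-level experiments run from a config.

Each experiment writes the tables needed to re-plot the corresponding result
(CSV) plus a JSON manifest with the package version, seeds and a hash of the
resolved configuration, so any output file is reproducible from its manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import hashlib
import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .lif_analytics import build_phase_diagram
from .neuron_sim import IntegrationConfig, simulate_eif_kir
from .noisy_rate import NoiseModel, build_phase_diagram_noisy
from .params import EIFKirParams, LIFParams
from .population_analysis import spn_vs_fsi_curve, vm_distribution_sd, vm_histogram
from .striatal_network import (
    NetworkSpec,
    calibrate_drive,
    fsi_rate_sweep,
    simulate_network,
)

__all__ = ["ExperimentConfig", "run_experiment", "EXPERIMENTS"]

EXPERIMENTS = (
    "phase_deterministic",
    "phase_constant_noise",
    "phase_conductance_noise",
    "eif_kir_sweep",
    "network_baseline",
    "network_fsi_sweep",
)


@dataclass
class ExperimentConfig:
    """Named experiment plus overrides.

    ``options`` carries experiment-specific knobs (grids, sigma/a lists,
    durations, realization counts); unknown keys are rejected by the runner.
    ``lif_overrides`` patches the LIF parameter set.
    """

    experiment: str
    outdir: Union[str, Path] = "."
    seed: int = 0
    lif_overrides: dict = field(default_factory=dict)
    options: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: Union[str, Path], **overrides) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        return cls(**data)

    def resolved(self) -> dict:
        d = asdict(self)
        d["outdir"] = str(d["outdir"])
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _axis(spec, default):
    """Parse a 'lo:hi:step' string or a [lo, hi, step] triple into a grid."""
    if spec is None:
        return default
    if isinstance(spec, str):
        lo, hi, step = (float(x) for x in spec.split(":"))
    else:
        lo, hi, step = (float(x) for x in spec)
    return np.arange(lo, hi + step * 1e-6, step)


def _check_options(options: dict, allowed: set) -> None:
    unknown = set(options) - allowed
    if unknown:
        raise ValueError(f"unknown experiment options: {sorted(unknown)}")


def _write_manifest(cfg: ExperimentConfig, outdir: Path, files: list) -> None:
    manifest = {
        "experiment": cfg.experiment,
        "package_version": __version__,
        "seed": cfg.seed,
        "config": cfg.resolved(),
        "config_hash": cfg.config_hash(),
        "outputs": files,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def run_experiment(cfg: ExperimentConfig) -> Path:
    """Execute one named experiment; returns the output directory."""
    if cfg.experiment not in EXPERIMENTS:
        raise ValueError(
            f"unknown experiment {cfg.experiment!r}; choose from {EXPERIMENTS}"
        )
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = LIFParams(**{**{}, **cfg.lif_overrides}) if cfg.lif_overrides else LIFParams()
    opts = cfg.options
    files: list[str] = []

    if cfg.experiment == "phase_deterministic":
        _check_options(opts, {"grid_egaba", "grid_gglu", "summaries"})
        E_ax = _axis(opts.get("grid_egaba"), None)
        g_ax = _axis(opts.get("grid_gglu"), None)
        pd_ = build_phase_diagram(
            params, E_ax, g_ax, compute_summaries=opts.get("summaries", True)
        )
        pd_.save(outdir / "phase_deterministic.csv")
        files += ["phase_deterministic.csv", "phase_deterministic.json"]

    elif cfg.experiment in ("phase_constant_noise", "phase_conductance_noise"):
        _check_options(opts, {"grid_egaba", "grid_gglu", "sigmas", "a_values", "summaries"})
        # coarser default grids: each point needs quadrature
        E_ax = _axis(opts.get("grid_egaba"), np.arange(-80.0, -50.0 + 1e-9, 1.0))
        g_ax = _axis(opts.get("grid_gglu"), np.arange(0.0, 2.0 + 1e-9, 0.1))
        if cfg.experiment == "phase_constant_noise":
            levels = [("sigma", s, NoiseModel.constant(s))
                      for s in opts.get("sigmas", [1.0, 3.0, 6.0])]
        else:
            levels = [("a", a, NoiseModel.conductance(a))
                      for a in opts.get("a_values", [0.01, 0.05, 0.1])]
        for name, value, noise in levels:
            diag = build_phase_diagram_noisy(
                params, noise, E_ax, g_ax,
                compute_summaries=opts.get("summaries", False),
            )
            stem = f"phase_{name}_{value:g}"
            diag.save(outdir / f"{stem}.csv")
            files += [f"{stem}.csv", f"{stem}.json"]

    elif cfg.experiment == "eif_kir_sweep":
        _check_options(opts, {"g_glu", "e_gaba_values", "g_gaba_max", "n_points",
                              "duration_ms"})
        eif = EIFKirParams()
        g_glu = float(opts.get("g_glu", 0.8))
        e_gaba_values = opts.get("e_gaba_values", [-70.0, -64.0, -62.0, -55.0])
        g_grid = np.linspace(0.0, float(opts.get("g_gaba_max", 6.0)),
                             int(opts.get("n_points", 25)))
        sim_cfg = IntegrationConfig(
            dt=0.01, duration=float(opts.get("duration_ms", 3000.0)),
            transient=100.0, seed=cfg.seed,
        )
        rows = []
        from .params import SynapticDrive

        for EG in e_gaba_values:
            for g in g_grid:
                res = simulate_eif_kir(
                    eif, SynapticDrive(g_Glu=g_glu, g_GABA=float(g), E_GABA=float(EG)),
                    cfg=sim_cfg, record_stride=1000,
                )
                rows.append({"E_GABA_mV": EG, "g_GABA": g, "rate_Hz": res.rate})
        pd.DataFrame(rows).to_csv(outdir / "eif_kir_rates.csv", index=False)
        files.append("eif_kir_rates.csv")

    elif cfg.experiment == "network_baseline":
        _check_options(opts, {"duration_ms", "targets", "e_gaba_spn", "calib_duration_ms",
                              "n_neurons"})
        spec = NetworkSpec(N=int(opts.get("n_neurons", 1000)),
                           E_GABA_SPN=float(opts.get("e_gaba_spn", -61.0)))
        realization = spec.sample_realization(seed=cfg.seed)
        calib_cfg = IntegrationConfig(
            dt=0.05, duration=float(opts.get("calib_duration_ms", 10_100.0)),
            transient=100.0, seed=cfg.seed,
        )
        calib = calibrate_drive(
            spec, realization, tuple(opts.get("targets", (10.0, 1.0, 1.0))),
            cfg=calib_cfg,
        )
        run_cfg = IntegrationConfig(
            dt=0.05, duration=float(opts.get("duration_ms", 10_100.0)),
            transient=100.0, seed=cfg.seed + 1,
        )
        out = simulate_network(spec, realization, calib.amplitudes, run_cfg,
                               record_vm=True)
        calib.save_json(outdir / "calibration.json")
        out.save_spikes_csv(outdir / "spikes.csv")
        out.save_rates_csv(outdir / "rates.csv")
        vm_histogram(out).to_csv(outdir / "vm_histogram.csv", index=False)
        summary = {
            "pop_rates_Hz": out.pop_rates,
            "vm_sd_mV": vm_distribution_sd(out),
            "amplitudes": list(map(float, calib.amplitudes)),
        }
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        files += ["calibration.json", "spikes.csv", "rates.csv",
                  "vm_histogram.csv", "summary.json"]

    elif cfg.experiment == "network_fsi_sweep":
        _check_options(opts, {"duration_ms", "targets", "fsi_targets", "e_gaba_spn",
                              "n_realizations", "calib_duration_ms", "n_neurons"})
        spec = NetworkSpec(N=int(opts.get("n_neurons", 1000)),
                           E_GABA_SPN=float(opts.get("e_gaba_spn", -61.0)))
        calib_cfg = IntegrationConfig(
            dt=0.05, duration=float(opts.get("calib_duration_ms", 10_100.0)),
            transient=100.0, seed=cfg.seed,
        )
        fsi_targets = list(opts.get("fsi_targets", [0.0, 5.0, 10.0, 17.0, 25.0]))
        n_real = int(opts.get("n_realizations", 5))
        run_cfg = IntegrationConfig(
            dt=0.05, duration=float(opts.get("duration_ms", 20_100.0)),
            transient=100.0, seed=cfg.seed,
        )
        realization0 = spec.sample_realization(seed=cfg.seed)
        calib = calibrate_drive(
            spec, realization0, tuple(opts.get("targets", (10.0, 1.0, 1.0))),
            cfg=calib_cfg,
        )
        sweeps = []
        for r in range(n_real):
            realization = spec.sample_realization(seed=cfg.seed + 1000 + r)
            sweeps.append(
                fsi_rate_sweep(
                    spec, realization, calib.amplitudes, fsi_targets,
                    cfg=IntegrationConfig(
                        dt=0.05, duration=run_cfg.duration, transient=100.0,
                        seed=cfg.seed + 2000 + r,
                    ),
                    calib_cfg=calib_cfg,
                )
            )
        curve = spn_vs_fsi_curve(sweeps)
        curve.to_csv(outdir / "spn_vs_fsi.csv", index=False)
        calib.save_json(outdir / "calibration.json")
        files += ["spn_vs_fsi.csv", "calibration.json"]

    _write_manifest(cfg, outdir, files)
    return outdir
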