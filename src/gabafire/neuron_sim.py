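"""Time-stepped simulation of single LIF and EIF-Kir neurons.

Euler–Maruyama integration in ms units; the white-noise term enters the
voltage update as sigma*sqrt(dt/tau)*N(0,1) per step, matching the
I_noise = sigma*sqrt(tau)*zeta(t) convention of the current-balance equation.
These simulators are the brute-force cross-check for the closed-form rates and
the primary tool for the EIF-Kir model, whose Kir current makes the V-I curve
nonlinear and whose exponential term generates spikes without a hard
threshold (the voltage runs away and is reset from a numeric ceiling V_cut).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import _kernels
from .params import LIFParams, EIFKirParams, SynapticDrive, NoiseModel

__all__ = [
    "IntegrationConfig",
    "SpikeTrain",
    "SingleNeuronResult",
    "simulate_lif",
    "simulate_eif_kir",
    "vi_curve",
    "fi_curve",
    "save_trace_csv",
    "save_trace_hdf5",
]


@dataclass(frozen=True)
class IntegrationConfig:
    """Numerical integration settings.

    The first ``transient`` ms are discarded from all rate estimates (100 ms by
    default). ``V_cut`` is the spike-detection ceiling of the EIF-Kir model:
    beyond -30 mV the exponential current dominates and the spike time is
    insensitive to the exact cutoff. ``V_init`` defaults to the leak reversal.
    """

    dt: float = 0.05            # step, ms
    duration: float = 1000.0    # total simulated time, ms
    transient: float = 100.0    # discarded initial window, ms
    seed: int = 0
    V_cut: float = -30.0        # EIF spike-detection ceiling, mV
    V_init: float | None = None # initial voltage; leak reversal when None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (self.duration > self.transient >= 0):
            raise ValueError("need duration > transient >= 0")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times (ms) of one neuron."""

    times: np.ndarray
    neuron_id: int = 0

    def rate(self, t_start: float, t_stop: float) -> float:
        """Mean rate in Hz over [t_start, t_stop)."""
        n = np.count_nonzero((self.times >= t_start) & (self.times < t_stop))
        return 1000.0 * n / (t_stop - t_start)


@dataclass(frozen=True)
class SingleNeuronResult:
    spikes: SpikeTrain
    t: np.ndarray            # sample times of the voltage trace, ms
    v: np.ndarray            # membrane potential, mV
    rate: float              # post-transient mean rate, Hz
    cfg: IntegrationConfig


def _finish(spike_steps: np.ndarray, trace: np.ndarray, cfg: IntegrationConfig,
            record_stride: int) -> SingleNeuronResult:
    times = (spike_steps + 1) * cfg.dt
    rate = 1000.0 * np.count_nonzero(times >= cfg.transient) / (cfg.duration - cfg.transient)
    t = np.arange(len(trace)) * (record_stride * cfg.dt)
    return SingleNeuronResult(
        spikes=SpikeTrain(times=times), t=t, v=trace, rate=float(rate), cfg=cfg
    )


def simulate_lif(
    params: LIFParams,
    drive: SynapticDrive,
    noise: NoiseModel = NoiseModel.none(),
    cfg: IntegrationConfig = IntegrationConfig(),
    record_stride: int = 1,
) -> SingleNeuronResult:
    """Simulate the LIF neuron; spike at v >= E_thr, instantaneous reset.

    Only ``none`` and ``constant`` noise kinds are meaningful here (the
    conductance-kind diffusion model resolves to a constant sigma at the mean
    conductances and should be converted by the caller).
    """
    if noise.kind == "conductance":
        raise ValueError(
            "convert conductance-kind noise to an effective constant sigma first "
            "(noisy_rate.conductance_noise_sigma)"
        )
    sigma = noise.sigma if noise.kind == "constant" else 0.0
    v0 = params.E_L if cfg.V_init is None else cfg.V_init
    spike_steps, _, trace = _kernels.lif_run(
        params.tau, params.E_L, params.E_thr, params.E_reset, params.E_Glu,
        drive.g_Glu, drive.g_GABA, drive.E_GABA, sigma,
        cfg.dt, cfg.n_steps, cfg.seed, v0, record_stride,
    )
    return _finish(spike_steps, trace, cfg, record_stride)


def simulate_eif_kir(
    params: EIFKirParams,
    drive: SynapticDrive = SynapticDrive(),
    I_const_pA: float = 0.0,
    cfg: IntegrationConfig = IntegrationConfig(dt=0.01),
    noise: NoiseModel = NoiseModel.none(),
    record_stride: int = 1,
) -> SingleNeuronResult:
    """Simulate the EIF-Kir neuron with an optional constant current (pA).

    The injected current is converted to voltage units as I/g_L_abs. Raises if
    the voltage jumps more than 20 mV beyond V_cut within a single step, which
    indicates dt is too large for the exponential term.
    """
    base = params.base
    sigma = noise.sigma if noise.kind == "constant" else 0.0
    v0 = base.E_L if cfg.V_init is None else cfg.V_init
    spike_steps, _, trace, overshoot = _kernels.eif_kir_run(
        base.tau, base.E_L, base.E_reset, base.E_Glu,
        params.Delta_T, params.V_T, params.g_K, params.K, params.V_P, params.E_K,
        drive.g_Glu, drive.g_GABA, drive.E_GABA, I_const_pA / params.g_L_abs, sigma,
        cfg.dt, cfg.n_steps, cfg.seed, v0, cfg.V_cut, record_stride,
    )
    if overshoot > cfg.V_cut + 20.0:
        raise RuntimeError(
            f"voltage overshot to {overshoot:.1f} mV past V_cut; decrease dt "
            "(exponential term diverges within one step)"
        )
    return _finish(spike_steps, trace, cfg, record_stride)


def _eif_current_balance(params: EIFKirParams, drive: SynapticDrive, I_const: float):
    """RHS of the EIF-Kir voltage equation (mV units) as a function of v."""
    base = params.base

    def f(v: float) -> float:
        I_exp = params.Delta_T * np.exp((v - params.V_T) / params.Delta_T)
        kir = params.g_K / (1.0 + np.exp((v - params.V_P) / params.K)) * (v - params.E_K)
        return (
            -(v - base.E_L)
            - drive.g_GABA * (v - drive.E_GABA)
            - drive.g_Glu * (v - base.E_Glu)
            + I_exp
            - kir
            + I_const
        )

    return f


def vi_curve(
    params: EIFKirParams,
    I_values_pA: Sequence[float],
    drive: SynapticDrive = SynapticDrive(),
) -> pd.DataFrame:
    """Steady-state membrane potential vs injected current (sub-rheobase).

    Solves the current-balance equation for the stable fixed point below the
    exponential-term threshold; supra-rheobase currents (no sub-threshold
    fixed point) are flagged with ``converged=False`` and V = NaN. The Kir
    current makes this curve nonlinear.
    """
    rows = []
    lo = min(params.E_K, params.base.E_L) - 40.0
    hi = params.V_T
    for I in I_values_pA:
        f = _eif_current_balance(params, drive, I / params.g_L_abs)
        if f(lo) * f(hi) > 0:
            rows.append({"I_pA": I, "V_mV": np.nan, "converged": False})
            continue
        V = brentq(f, lo, hi, xtol=1e-10)
        rows.append({"I_pA": I, "V_mV": float(V), "converged": True})
    return pd.DataFrame(rows)


def fi_curve(
    params: EIFKirParams,
    I_values_pA: Sequence[float],
    cfg: IntegrationConfig = IntegrationConfig(dt=0.01, duration=2000.0),
) -> pd.DataFrame:
    """Firing rate vs injected current from spike counts after the transient."""
    rows = []
    for I in I_values_pA:
        res = simulate_eif_kir(params, I_const_pA=I, cfg=cfg, record_stride=100)
        rows.append({"I_pA": I, "rate_Hz": res.rate})
    return pd.DataFrame(rows)


def save_trace_csv(result: SingleNeuronResult, path: Union[str, Path]) -> None:
    pd.DataFrame({"time_ms": result.t, "v_mV": result.v}).to_csv(path, index=False)


def save_trace_hdf5(result: SingleNeuronResult, path: Union[str, Path]) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("time_ms", data=result.t)
        fh.create_dataset("v_mV", data=result.v)
        fh.create_dataset("spike_times_ms", data=result.spikes.times)
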