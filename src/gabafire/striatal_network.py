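"""Striatal microcircuit model: FSI, dSPN and iSPN populations of LIF neurons.

N = 1000 neurons (2% fast-spiking interneurons, 49% direct- and 49%
indirect-pathway spiny projection neurons) connected by GABAergic synapses
with the block connectivity of `synthetic_inputs.DEFAULT_P`/`DEFAULT_G` and a
difference-of-exponentials conductance kernel. Every neuron receives an
independent 1000 Hz filtered-Poisson glutamatergic drive; the per-population
drive amplitudes are free parameters calibrated so the populations fire at
target rates (in vivo-like defaults: FSI 10 Hz, SPNs 1 Hz). FSIs have a
hyperpolarized GABA reversal (-80 mV) while SPNs carry a depolarized reversal
(default 1 mV below threshold), which is what makes the feedforward FSI->SPN
pathway capable of non-monotonic population effects.

Because SPNs do not project to FSIs, the FSI drive is calibrated on the
20-neuron FSI subnetwork alone; the two SPN drives are then calibrated
jointly on the full network.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import json
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from . import _kernels
from .lif_analytics import firing_onset_gGlu
from .neuron_sim import IntegrationConfig
from .params import LIFParams
from .synthetic_inputs import (
    ConnectivityRealization,
    DEFAULT_G,
    DEFAULT_P,
    POPULATIONS,
    PSCKernel,
    sample_connectivity,
)

__all__ = [
    "NetworkSpec",
    "SimOutput",
    "CalibrationResult",
    "simulate_network",
    "calibrate_drive",
    "fsi_rate_sweep",
    "fsi_subnetwork",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Structural and biophysical description of the striatal network."""

    N: int = 1000
    fractions: tuple = (0.02, 0.49, 0.49)       # FSI, dSPN, iSPN
    P: np.ndarray = field(default_factory=lambda: DEFAULT_P.copy())
    G: np.ndarray = field(default_factory=lambda: DEFAULT_G.copy())
    E_GABA_FSI: float = -80.0
    E_GABA_SPN: float = -61.0                   # E_thr - 1 mV by default
    neuron: LIFParams = field(default_factory=LIFParams)
    kernel: PSCKernel = field(default_factory=PSCKernel)
    drive_rate: float = 1000.0                  # Poisson event rate, Hz
    drive_tau: float = 5.6                      # drive kernel decay, ms

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("population fractions must sum to 1")
        for E in (self.E_GABA_FSI, self.E_GABA_SPN):
            if not (-90.0 <= E <= -50.0):
                raise ValueError("GABA reversal potentials must lie in [-90, -50] mV")

    @property
    def pop_sizes(self) -> tuple:
        sizes = [int(round(self.N * f)) for f in self.fractions]
        sizes[-1] = self.N - sum(sizes[:-1])
        return tuple(sizes)

    def E_GABA_per_neuron(self) -> np.ndarray:
        """Per-neuron GABA reversal, set by the postsynaptic population."""
        pop = np.repeat(np.arange(3), self.pop_sizes)
        return np.where(pop == 0, self.E_GABA_FSI, self.E_GABA_SPN)

    def sample_realization(self, seed: int = 0) -> ConnectivityRealization:
        return sample_connectivity(self.pop_sizes, self.P, self.G, seed=seed)


@dataclass(frozen=True)
class SimOutput:
    """Result of one network run (times in ms, rates in Hz)."""

    spike_times: np.ndarray      # recorded spike times (may be truncated)
    spike_ids: np.ndarray
    spikes_truncated: bool
    rates: np.ndarray            # per-neuron post-transient rate, Hz
    pop_rates: dict              # population name -> mean member rate, Hz
    vm: np.ndarray | None        # (n_samples, N) float32, post-transient
    vm_times: np.ndarray | None  # sample times, ms
    mean_g_gaba: np.ndarray      # per-neuron time-averaged GABA conductance
    mean_g_glu: np.ndarray       # per-neuron time-averaged drive conductance
    population_of: np.ndarray
    amplitudes: np.ndarray       # per-population drive amplitudes used
    cfg: IntegrationConfig

    def spike_times_of(self, neuron: int) -> np.ndarray:
        return self.spike_times[self.spike_ids == neuron]

    def rates_of(self, pop: int) -> np.ndarray:
        return self.rates[self.population_of == pop]

    def save_spikes_csv(self, path: Union[str, Path]) -> None:
        pd.DataFrame(
            {"neuron_id": self.spike_ids, "time_ms": self.spike_times}
        ).to_csv(path, index=False)

    def save_rates_csv(self, path: Union[str, Path]) -> None:
        pd.DataFrame(
            {
                "neuron_id": np.arange(len(self.rates)),
                "population": [POPULATIONS[p] for p in self.population_of],
                "rate_Hz": self.rates,
            }
        ).to_csv(path, index=False)


def _mix_seed(seed: int, salt: int) -> int:
    """Derive a stream seed below 2^31 from (seed, salt)."""
    return int((seed * 1000003 + salt * 7919 + 12345) % (2**31 - 1))


def simulate_network(
    spec: NetworkSpec,
    realization: ConnectivityRealization,
    amplitudes: Sequence[float],
    cfg: IntegrationConfig,
    record_vm: bool = False,
    vm_stride_ms: float = 1.0,
    max_rate_hint: float = 100.0,
) -> SimOutput:
    """Integrate the network with per-population drive amplitudes.

    Initial voltages are independent uniform draws on [E_L, E_thr] (spurious
    synchrony is avoided and the 100 ms transient is discarded anyway).
    ``max_rate_hint`` (Hz, network mean) sizes the spike-recording buffer;
    per-neuron counts and rates are exact even if the buffer fills.
    """
    if realization.pop_sizes != spec.pop_sizes:
        raise ValueError("connectivity realization does not match the network spec")
    amplitudes = np.asarray(amplitudes, dtype=float)
    if amplitudes.shape != (3,) or np.any(amplitudes < 0):
        raise ValueError("need three non-negative drive amplitudes (FSI, dSPN, iSPN)")
    n = spec.N
    neuron = spec.neuron
    pop = realization.population_of
    amp_arr = amplitudes[pop]
    E_GABA_arr = spec.E_GABA_per_neuron()

    rng = np.random.default_rng(_mix_seed(cfg.seed, 1))
    v0 = rng.uniform(neuron.E_L, neuron.E_thr, size=n)

    n_steps = cfg.n_steps
    transient_steps = int(round(cfg.transient / cfg.dt))
    vm_stride = max(int(round(vm_stride_ms / cfg.dt)), 1)
    max_spikes = max(int(n * (cfg.duration / 1000.0) * max_rate_hint), 200_000)

    out = _kernels.network_run(
        neuron.tau, neuron.E_L, neuron.E_thr, neuron.E_reset, neuron.E_Glu,
        E_GABA_arr.astype(np.float64), amp_arr.astype(np.float64), v0,
        spec.drive_rate / 1000.0, spec.drive_tau,
        spec.kernel.tau1, spec.kernel.tau2,
        realization.indptr, realization.post_idx, realization.weights,
        cfg.dt, n_steps, transient_steps, _mix_seed(cfg.seed, 2),
        vm_stride, record_vm, max_spikes,
    )
    spike_t, spike_id, n_rec, counts, vm, mean_gaba, mean_glu = out
    window_s = (cfg.duration - cfg.transient) / 1000.0
    rates = counts / window_s
    pop_rates = {
        name: (float(rates[pop == k].mean()) if np.any(pop == k) else float("nan"))
        for k, name in enumerate(POPULATIONS)
    }
    if record_vm:
        vm_times = cfg.transient + np.arange(vm.shape[0]) * vm_stride * cfg.dt
    else:
        vm, vm_times = None, None
    return SimOutput(
        spike_times=spike_t, spike_ids=spike_id,
        spikes_truncated=bool(n_rec >= max_spikes),
        rates=rates, pop_rates=pop_rates,
        vm=vm, vm_times=vm_times,
        mean_g_gaba=mean_gaba, mean_g_glu=mean_glu,
        population_of=pop, amplitudes=amplitudes, cfg=cfg,
    )


def fsi_subnetwork(
    spec: NetworkSpec, realization: ConnectivityRealization
) -> tuple[NetworkSpec, ConnectivityRealization]:
    """Restrict spec and realization to the FSI population.

    Valid because FSIs receive GABA only from other FSIs, so their dynamics
    are independent of the SPN populations.
    """
    n_fsi = spec.pop_sizes[0]
    sub_spec = replace(spec, N=n_fsi, fractions=(1.0, 0.0, 0.0))
    # FSI neurons are indices [0, n_fsi); keep edges among them
    indptr = np.zeros(n_fsi + 1, dtype=np.int64)
    posts, wts = [], []
    for j in range(n_fsi):
        lo, hi = realization.indptr[j], realization.indptr[j + 1]
        tgt = realization.post_idx[lo:hi]
        keep = tgt < n_fsi
        posts.append(tgt[keep])
        wts.append(realization.weights[lo:hi][keep])
        indptr[j + 1] = indptr[j] + keep.sum()
    sub = ConnectivityRealization(
        indptr=indptr,
        post_idx=np.concatenate(posts) if posts else np.empty(0, np.int32),
        weights=np.concatenate(wts) if wts else np.empty(0, np.float64),
        population_of=np.zeros(n_fsi, dtype=np.int64),
        pop_sizes=(n_fsi, 0, 0),
        P=realization.P, G=realization.G, seed=realization.seed,
    )
    return sub_spec, sub


@dataclass(frozen=True)
class CalibrationResult:
    amplitudes: np.ndarray       # per-population drive amplitudes (FSI, dSPN, iSPN)
    achieved_rates: dict         # population name -> Hz, from the final evaluation
    targets: tuple
    n_evaluations: int
    converged: bool

    def save_json(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "amplitudes": list(map(float, self.amplitudes)),
                    "achieved_rates_Hz": self.achieved_rates,
                    "targets_Hz": list(self.targets),
                    "n_evaluations": self.n_evaluations,
                    "converged": self.converged,
                },
                fh, indent=2,
            )


def _initial_amplitude(spec: NetworkSpec) -> float:
    """Drive amplitude whose mean conductance sits at the deterministic firing
    onset — a natural starting scale for low-rate operating points."""
    g_onset = firing_onset_gGlu(spec.neuron)
    return g_onset / ((spec.drive_rate / 1000.0) * spec.drive_tau)


def _calibrate_fsi(
    spec: NetworkSpec,
    realization: ConnectivityRealization,
    target: float,
    cfg: IntegrationConfig,
    rel_tol: float,
    max_iter: int,
) -> tuple[float, float, int]:
    """Bisection on the FSI drive amplitude using the FSI subnetwork.

    Returns (amplitude, achieved rate, n_evaluations).
    """
    sub_spec, sub = fsi_subnetwork(spec, realization)

    n_eval = 0

    def fsi_rate(a: float) -> float:
        nonlocal n_eval
        n_eval += 1
        out = simulate_network(
            sub_spec, sub, [a, 0.0, 0.0],
            replace(cfg, seed=_mix_seed(cfg.seed, 100 + n_eval)),
        )
        return out.pop_rates["FSI"]

    a0 = _initial_amplitude(spec)
    lo, hi = a0 / 4.0, a0 * 4.0
    r_lo, r_hi = fsi_rate(lo), fsi_rate(hi)
    expansions = 0
    while r_lo > target and expansions < 8:
        hi, r_hi = lo, r_lo
        lo /= 2.0
        r_lo = fsi_rate(lo)
        expansions += 1
    while r_hi < target and expansions < 8:
        lo, r_lo = hi, r_hi
        hi *= 2.0
        r_hi = fsi_rate(hi)
        expansions += 1
    if not (r_lo <= target <= r_hi):
        raise RuntimeError("could not bracket the FSI target rate")
    a, r = hi, r_hi
    for _ in range(max_iter):
        a = 0.5 * (lo + hi)
        r = fsi_rate(a)
        if abs(r - target) <= rel_tol * target:
            break
        if r < target:
            lo = a
        else:
            hi = a
    return a, r, n_eval


def calibrate_drive(
    spec: NetworkSpec,
    realization: ConnectivityRealization,
    targets: Sequence[float] = (10.0, 1.0, 1.0),
    cfg: IntegrationConfig | None = None,
    rel_tol: float = 0.05,
    max_iter: int = 12,
) -> CalibrationResult:
    """Find per-population drive amplitudes reproducing target mean rates.

    Stage 1 calibrates the FSI amplitude on the FSI subnetwork (bisection).
    Stage 2 fixes it and adjusts the dSPN and iSPN amplitudes jointly on the
    full network: both brackets are bisected against the same evaluation runs,
    which the weak dSPN<->iSPN coupling permits. Evaluation runs default to
    10 s (after a 100 ms transient) per the calibration design.
    """
    targets = tuple(float(t) for t in targets)
    if any(t < 0 for t in targets) or any(t >= 100 for t in targets):
        raise ValueError("target rates must lie in [0, 100) Hz")
    if cfg is None:
        cfg = IntegrationConfig(dt=0.05, duration=10_100.0, transient=100.0, seed=0)

    if targets[0] > 0:
        a_fsi, r_fsi, n_eval = _calibrate_fsi(
            spec, realization, targets[0], cfg, rel_tol, max_iter
        )
    else:
        a_fsi, r_fsi, n_eval = 0.0, 0.0, 0

    a0 = _initial_amplitude(spec)
    lo = np.array([a0 / 4.0, a0 / 4.0])
    hi = np.array([a0 * 4.0, a0 * 4.0])

    def spn_rates(a_d: float, a_i: float) -> tuple[float, float]:
        nonlocal n_eval
        n_eval += 1
        out = simulate_network(
            spec, realization, [a_fsi, a_d, a_i],
            replace(cfg, seed=_mix_seed(cfg.seed, 200 + n_eval)),
        )
        return out.pop_rates["dSPN"], out.pop_rates["iSPN"]

    # establish brackets for both SPN populations with shared runs
    tgt = np.array(targets[1:])
    r_lo = np.array(spn_rates(*lo))
    r_hi = np.array(spn_rates(*hi))
    for _ in range(8):
        moved = False
        if np.any(r_lo > tgt):
            hi = np.where(r_lo > tgt, lo, hi)
            lo = np.where(r_lo > tgt, lo / 2.0, lo)
            moved = True
        if np.any(r_hi < tgt):
            lo = np.where(r_hi < tgt, hi, lo)
            hi = np.where(r_hi < tgt, hi * 2.0, hi)
            moved = True
        if not moved:
            break
        r_lo = np.array(spn_rates(*lo))
        r_hi = np.array(spn_rates(*hi))
    if np.any(r_lo > tgt) or np.any(r_hi < tgt):
        raise RuntimeError("could not bracket the SPN target rates")

    converged = False
    a = hi.copy()
    r = r_hi.copy()
    for _ in range(max_iter):
        a = 0.5 * (lo + hi)
        r = np.array(spn_rates(*a))
        if np.all(np.abs(r - tgt) <= rel_tol * np.maximum(tgt, 1e-9)):
            converged = True
            break
        lo = np.where(r < tgt, a, lo)
        hi = np.where(r >= tgt, a, hi)

    fsi_ok = targets[0] == 0 or abs(r_fsi - targets[0]) <= rel_tol * targets[0]
    amplitudes = np.array([a_fsi, a[0], a[1]])
    return CalibrationResult(
        amplitudes=amplitudes,
        achieved_rates={"FSI": float(r_fsi), "dSPN": float(r[0]), "iSPN": float(r[1])},
        targets=targets,
        n_evaluations=n_eval,
        converged=bool(converged and fsi_ok),
    )


def fsi_rate_sweep(
    spec: NetworkSpec,
    realization: ConnectivityRealization,
    baseline_amplitudes: Sequence[float],
    fsi_targets: Sequence[float],
    cfg: IntegrationConfig,
    calib_cfg: IntegrationConfig | None = None,
    rel_tol: float = 0.05,
    record_vm: bool = False,
) -> list[tuple[float, SimOutput]]:
    """Run the network at a series of FSI mean-rate targets, SPN drive fixed.

    The FSI drive is re-calibrated (on the FSI subnetwork) for each non-zero
    target, modelling optogenetic-like gain modulation of the FSI population
    while preserving its spike statistics; target 0 silences the FSIs.
    Returns (target, SimOutput) pairs.
    """
    baseline_amplitudes = np.asarray(baseline_amplitudes, dtype=float)
    if calib_cfg is None:
        calib_cfg = IntegrationConfig(dt=cfg.dt, duration=10_100.0, transient=100.0,
                                      seed=cfg.seed)
    results = []
    for k, target in enumerate(fsi_targets):
        if target == 0:
            a_fsi = 0.0
        else:
            a_fsi, _, _ = _calibrate_fsi(
                spec, realization, float(target),
                replace(calib_cfg, seed=_mix_seed(calib_cfg.seed, 300 + k)),
                rel_tol, max_iter=12,
            )
        amps = np.array([a_fsi, baseline_amplitudes[1], baseline_amplitudes[2]])
        out = simulate_network(
            spec, realization, amps,
            replace(cfg, seed=_mix_seed(cfg.seed, 400 + k)),
            record_vm=record_vm,
        )
        results.append((float(target), out))
    return results
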