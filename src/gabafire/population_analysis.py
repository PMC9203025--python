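"""Population statistics over network simulations.

Covers the quantities used to characterize the calibrated striatal model:
the Gaussian width of the pooled sub-threshold SPN membrane-potential
distribution, the width of the per-SPN firing-rate distribution under
different FSI conditions, per-neuron rate changes between two FSI conditions
and their correlation with the FSI in-degree, and the population
rate-vs-FSI-rate curve across realizations.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .striatal_network import SimOutput
from .synthetic_inputs import ConnectivityRealization, POPULATIONS

__all__ = [
    "vm_distribution_sd",
    "pooled_spn_vm",
    "rate_distribution_sd",
    "delta_rate_vs_indegree",
    "spn_vs_fsi_curve",
    "vm_histogram",
]

#: samples within this window (ms) of a spike are excluded from the
#: sub-threshold membrane-potential distribution (threshold/reset artifacts)
SPIKE_EXCLUSION_MS = 1.0


def pooled_spn_vm(out: SimOutput, exclusion_ms: float = SPIKE_EXCLUSION_MS) -> np.ndarray:
    """Pool post-transient membrane-potential samples over all SPNs.

    Samples within ``exclusion_ms`` before a spike or after the following
    reset are discarded, so the pooled distribution describes the
    sub-threshold fluctuations only. Requires a run with ``record_vm=True``
    whose spike record was not truncated.
    """
    if out.vm is None:
        raise ValueError("run was executed without record_vm=True")
    if out.spikes_truncated:
        raise ValueError("spike record truncated; cannot apply spike exclusions")
    spn = np.nonzero(out.population_of != 0)[0]
    t = out.vm_times
    pooled = []
    for idx, i in enumerate(spn):
        v = out.vm[:, i].astype(float)
        st = np.sort(out.spike_times_of(i))
        if len(st):
            # sample k is dropped if some spike lies in (t_k - excl, t_k + excl]
            left = np.searchsorted(st, t - exclusion_ms, side="left")
            right = np.searchsorted(st, t + exclusion_ms, side="right")
            keep = left == right
            v = v[keep]
        pooled.append(v)
    pooled = np.concatenate(pooled)
    if len(pooled) < 100:
        raise ValueError(f"too few vm samples ({len(pooled)}) for a stable fit")
    return pooled


def vm_distribution_sd(out: SimOutput, exclusion_ms: float = SPIKE_EXCLUSION_MS) -> float:
    """Gaussian-fit SD (mV) of the pooled sub-threshold SPN membrane potential.

    The maximum-likelihood Gaussian fit of a sample is its mean and standard
    deviation, so this is the sample SD of the pooled, spike-excluded samples.
    """
    return float(np.std(pooled_spn_vm(out, exclusion_ms)))


def vm_histogram(out: SimOutput, bins: int = 80) -> pd.DataFrame:
    """Histogram (density) of the pooled sub-threshold SPN membrane potential."""
    pooled = pooled_spn_vm(out)
    density, edges = np.histogram(pooled, bins=bins, density=True)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "density": density}
    )


def rate_distribution_sd(out: SimOutput, population: Union[int, str, None] = None) -> float:
    """Sample SD (Hz) of per-neuron rates; SPNs pooled when population is None."""
    if population is None:
        rates = out.rates[out.population_of != 0]
    else:
        if isinstance(population, str):
            population = POPULATIONS.index(population)
        rates = out.rates[out.population_of == population]
    return float(np.std(rates, ddof=1))


def delta_rate_vs_indegree(
    out0: SimOutput,
    out1: SimOutput,
    realization: ConnectivityRealization,
) -> pd.DataFrame:
    """Per-SPN rate change between two FSI conditions vs FSI in-degree.

    Delta = rate(out1) - rate(out0) per SPN; the two runs must share the
    connectivity realization and SPN drive amplitudes. Returns a frame with
    columns (neuron_id, population, fsi_indegree, delta_rate_Hz) carrying the
    Pearson and Spearman correlations in ``df.attrs``. Identical conditions
    (all deltas zero) make the correlation undefined and raise.
    """
    if out0.population_of.shape != out1.population_of.shape or np.any(
        out0.population_of != out1.population_of
    ):
        raise ValueError("runs come from different network layouts")
    if not np.allclose(out0.amplitudes[1:], out1.amplitudes[1:]):
        raise ValueError("SPN drive amplitudes differ between the two runs")
    if realization.pop_sizes[0] + 0 != int(np.count_nonzero(out0.population_of == 0)):
        raise ValueError("realization does not match the runs")
    spn = np.nonzero(out0.population_of != 0)[0]
    delta = out1.rates[spn] - out0.rates[spn]
    indeg_all = realization.indegree(source_pop=0)
    indeg = indeg_all[spn]
    if np.allclose(delta, 0.0):
        raise ValueError("rate changes are identically zero; correlation undefined")
    pearson_r, pearson_p = stats.pearsonr(delta, indeg)
    spearman_r, spearman_p = stats.spearmanr(delta, indeg)
    df = pd.DataFrame(
        {
            "neuron_id": spn,
            "population": [POPULATIONS[p] for p in out0.population_of[spn]],
            "fsi_indegree": indeg,
            "delta_rate_Hz": delta,
        }
    )
    df.attrs["pearson_r"] = float(pearson_r)
    df.attrs["pearson_p"] = float(pearson_p)
    df.attrs["spearman_r"] = float(spearman_r)
    df.attrs["spearman_p"] = float(spearman_p)
    return df


def spn_vs_fsi_curve(
    sweeps: Sequence[Sequence[tuple[float, SimOutput]]],
) -> pd.DataFrame:
    """Population rate vs FSI rate, averaged over network realizations.

    ``sweeps`` holds one (fsi_target, SimOutput) list per realization, all
    with the same targets. Returns per-target mean rates for dSPN and iSPN
    with the standard deviation of the mean over realizations (NaN for a
    single realization), plus the realized FSI rate.
    """
    if not sweeps:
        raise ValueError("need at least one realization sweep")
    targets = [t for t, _ in sweeps[0]]
    for sw in sweeps:
        if [t for t, _ in sw] != targets:
            raise ValueError("all sweeps must share the same FSI targets")
    rows = []
    n_real = len(sweeps)
    for k, target in enumerate(targets):
        fsi = np.array([sw[k][1].pop_rates["FSI"] for sw in sweeps])
        d = np.array([sw[k][1].pop_rates["dSPN"] for sw in sweeps])
        i = np.array([sw[k][1].pop_rates["iSPN"] for sw in sweeps])
        spn = 0.5 * (d + i)
        def sdm(x):
            return float(np.std(x, ddof=1) / np.sqrt(n_real)) if n_real > 1 else float("nan")
        rows.append(
            {
                "fsi_target_Hz": target,
                "fsi_rate_Hz": float(fsi.mean()),
                "dSPN_rate_Hz": float(d.mean()),
                "dSPN_sdm_Hz": sdm(d),
                "iSPN_rate_Hz": float(i.mean()),
                "iSPN_sdm_Hz": sdm(i),
                "SPN_rate_Hz": float(spn.mean()),
                "SPN_sdm_Hz": sdm(spn),
                "n_realizations": n_real,
            }
        )
    return pd.DataFrame(rows)
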