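"""Synthetic input generators for the striatal network model.

Everything the network consumes is generated here: independent
filtered-Poisson conductance trains standing in for the total cortical
glutamatergic input (1000 Hz event rate, exponential kernel with 5.6 ms
decay), the difference-of-exponentials GABAergic PSC kernel
g(t) = g0 (e^{-t/tau1} - e^{-t/tau2}) with 20 ms decay and 1.5 ms rise, and
Bernoulli realizations of the block-structured FSI/dSPN/iSPN connectivity.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "PoissonDriveSpec",
    "PSCKernel",
    "ConnectivityRealization",
    "generate_poisson_drive",
    "save_drive_hdf5",
    "psc_kernel_eval",
    "sample_connectivity",
    "expected_total_conductance",
    "DEFAULT_P",
    "DEFAULT_G",
    "POPULATIONS",
]

#: population order used by all 3x3 matrices (row = target, column = source)
POPULATIONS = ("FSI", "dSPN", "iSPN")

#: connection probabilities, source population j (column) -> target i (row)
DEFAULT_P = np.array([
    [0.58, 0.00, 0.00],
    [0.53, 0.26, 0.27],
    [0.36, 0.06, 0.36],
])

#: synaptic strengths (normalized by leak) for present connections
DEFAULT_G = np.array([
    [0.06, 0.00, 0.00],
    [0.50, 0.04, 0.13],
    [0.50, 0.11, 0.11],
])


@dataclass(frozen=True)
class PoissonDriveSpec:
    """Filtered-Poisson conductance drive: event rate (Hz), exponential kernel
    decay (ms) and per-event conductance jump (dimensionless)."""

    rate: float = 1000.0
    tau_kernel: float = 5.6
    amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate <= 0 or self.tau_kernel <= 0:
            raise ValueError("rate and tau_kernel must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    @property
    def mean_conductance(self) -> float:
        """Stationary mean, amplitude * rate * tau_kernel (Campbell's theorem)."""
        return self.amplitude * (self.rate / 1000.0) * self.tau_kernel


@dataclass(frozen=True)
class PSCKernel:
    """GABAergic post-synaptic conductance kernel g0(e^{-t/tau1} - e^{-t/tau2}).

    ``g0`` is identified with the connection-strength matrix entry; the kernel
    starts at zero, peaks at tau1*tau2/(tau1-tau2)*ln(tau1/tau2) and integrates
    to g0*(tau1 - tau2).
    """

    g0: float = 1.0
    tau1: float = 20.0   # decay, ms
    tau2: float = 1.5    # rise, ms

    def __post_init__(self) -> None:
        if not (self.tau1 > self.tau2 > 0):
            raise ValueError("need tau1 > tau2 > 0")

    @property
    def peak_time(self) -> float:
        return self.tau1 * self.tau2 / (self.tau1 - self.tau2) * np.log(self.tau1 / self.tau2)

    @property
    def integral(self) -> float:
        return self.g0 * (self.tau1 - self.tau2)


def psc_kernel_eval(kernel: PSCKernel, t) -> np.ndarray:
    """Evaluate the PSC kernel; zero for t < 0 (causality)."""
    t = np.asarray(t, dtype=float)
    out = kernel.g0 * (np.exp(-t / kernel.tau1) - np.exp(-t / kernel.tau2))
    return np.where(t >= 0, out, 0.0)


def generate_poisson_drive(
    spec: PoissonDriveSpec, duration: float, dt: float
) -> np.ndarray:
    """One realization of the filtered-Poisson conductance trace.

    Event counts per bin are Poisson(rate*dt); the trace follows the exact
    discrete update g[n+1] = g[n]*exp(-dt/tau_kernel) + amplitude*counts[n],
    started from the stationary mean to avoid an onset transient.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    rng = np.random.default_rng(spec.seed)
    n = int(round(duration / dt))
    rate_ms = spec.rate / 1000.0
    counts = rng.poisson(rate_ms * dt, size=n)
    decay = np.exp(-dt / spec.tau_kernel)
    from scipy.signal import lfilter

    g, _ = lfilter(
        [spec.amplitude], [1.0, -decay], counts.astype(float),
        zi=[decay * spec.mean_conductance],
    )
    return g


def save_drive_hdf5(
    path: Union[str, Path], trace: np.ndarray, spec: PoissonDriveSpec, dt: float
) -> None:
    """Write a drive conductance trace with its generating parameters."""
    import h5py

    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("g_drive", data=trace)
        ds.attrs.update(
            {"rate_Hz": spec.rate, "tau_kernel_ms": spec.tau_kernel,
             "amplitude": spec.amplitude, "seed": spec.seed, "dt_ms": dt}
        )


@dataclass(frozen=True)
class ConnectivityRealization:
    """One Bernoulli draw of the directed network, CSR by presynaptic neuron.

    Edges from neuron j are ``post_idx[indptr[j]:indptr[j+1]]`` with strengths
    ``weights[...]``; ``population_of`` maps neuron index to population index
    (0=FSI, 1=dSPN, 2=iSPN) and ``pop_sizes`` gives the population sizes.
    """

    indptr: np.ndarray
    post_idx: np.ndarray
    weights: np.ndarray
    population_of: np.ndarray
    pop_sizes: tuple
    P: np.ndarray
    G: np.ndarray
    seed: int

    @property
    def n_neurons(self) -> int:
        return len(self.indptr) - 1

    @property
    def n_edges(self) -> int:
        return len(self.post_idx)

    def indegree(self, target_pop: int | None = None, source_pop: int | None = None) -> np.ndarray:
        """Afferent edge count per neuron, optionally restricted by population."""
        deg = np.zeros(self.n_neurons, dtype=np.int64)
        src_of_edge = np.repeat(
            np.arange(self.n_neurons), np.diff(self.indptr)
        )
        mask = np.ones(self.n_edges, dtype=bool)
        if source_pop is not None:
            mask &= self.population_of[src_of_edge] == source_pop
        np.add.at(deg, self.post_idx[mask], 1)
        if target_pop is not None:
            return deg[self.population_of == target_pop]
        return deg

    def block_edge_count(self, target_pop: int, source_pop: int) -> int:
        src_of_edge = np.repeat(np.arange(self.n_neurons), np.diff(self.indptr))
        return int(np.count_nonzero(
            (self.population_of[src_of_edge] == source_pop)
            & (self.population_of[self.post_idx] == target_pop)
        ))

    def to_edge_list(self) -> pd.DataFrame:
        src = np.repeat(np.arange(self.n_neurons), np.diff(self.indptr))
        return pd.DataFrame(
            {"pre_id": src, "post_id": self.post_idx, "strength": self.weights}
        )

    def save_csv(self, path: Union[str, Path]) -> None:
        self.to_edge_list().to_csv(path, index=False)


def sample_connectivity(
    pop_sizes: Sequence[int],
    P: np.ndarray = DEFAULT_P,
    G: np.ndarray = DEFAULT_G,
    seed: int = 0,
) -> ConnectivityRealization:
    """Draw independent Bernoulli edges with block probabilities P[i, j].

    Every present edge from population j to population i carries strength
    G[i, j]; self-connections are excluded.
    """
    P = np.asarray(P, dtype=float)
    G = np.asarray(G, dtype=float)
    if P.shape != G.shape or P.shape[0] != P.shape[1]:
        raise ValueError("P and G must be square matrices of equal shape")
    if np.any((P < 0) | (P > 1)):
        raise ValueError("P entries must lie in [0, 1]")
    if len(pop_sizes) != P.shape[0]:
        raise ValueError("pop_sizes length must match P")
    rng = np.random.default_rng(seed)
    N = int(np.sum(pop_sizes))
    population_of = np.repeat(np.arange(len(pop_sizes)), pop_sizes)

    # adjacency[j, i] True when j -> i; drawn block-wise
    adj = np.zeros((N, N), dtype=bool)
    starts = np.concatenate(([0], np.cumsum(pop_sizes)))
    for jp in range(len(pop_sizes)):
        for ip in range(len(pop_sizes)):
            p = P[ip, jp]
            if p == 0:
                continue
            block = rng.random((pop_sizes[jp], pop_sizes[ip])) < p
            adj[starts[jp]:starts[jp + 1], starts[ip]:starts[ip + 1]] = block
    np.fill_diagonal(adj, False)

    counts = adj.sum(axis=1)
    indptr = np.concatenate(([0], np.cumsum(counts))).astype(np.int64)
    post_idx = np.nonzero(adj)[1].astype(np.int32)
    src_of_edge = np.repeat(np.arange(N), counts)
    weights = G[population_of[post_idx], population_of[src_of_edge]].astype(np.float64)
    return ConnectivityRealization(
        indptr=indptr, post_idx=post_idx, weights=weights,
        population_of=population_of, pop_sizes=tuple(int(s) for s in pop_sizes),
        P=P, G=G, seed=seed,
    )


def expected_total_conductance(
    G_ij: float, P_ij: float, N_j: int, nu_j_Hz: float, kernel: PSCKernel | None = None
) -> float:
    """Mean summed GABA conductance from population j onto one target neuron:
    G_ij * P_ij * N_j * nu_j * (tau1 - tau2), with the rate in ms^-1."""
    if nu_j_Hz < 0:
        raise ValueError("rate must be non-negative")
    kernel = kernel or PSCKernel()
    return G_ij * P_ij * N_j * (nu_j_Hz / 1000.0) * (kernel.tau1 - kernel.tau2)
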