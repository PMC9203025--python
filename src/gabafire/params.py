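"""Model parameter containers.

All conductances are dimensionless (normalized by the leak conductance g_L),
voltages are in mV and times in ms. Firing rates on public surfaces are in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Union

import yaml


@dataclass(frozen=True)
class LIFParams:
    """Membrane constants of the conductance-based leaky integrate-and-fire neuron.

    Defaults are the standard operating point used throughout: a 20 ms membrane,
    leak reversal at -80 mV, hard spike threshold at -60 mV with instantaneous
    reset to -70 mV, and glutamatergic reversal at 0 mV.
    """

    tau: float = 20.0        # membrane time constant, ms
    E_L: float = -80.0       # leak reversal potential, mV
    E_thr: float = -60.0     # spike threshold, mV
    E_reset: float = -70.0   # reset potential, mV
    E_Glu: float = 0.0       # glutamate reversal potential, mV

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.E_reset >= self.E_thr:
            raise ValueError("E_reset must lie below E_thr")
        if self.E_Glu <= self.E_thr:
            raise ValueError("E_Glu must lie above E_thr")


@dataclass(frozen=True)
class SynapticDrive:
    """Constant synaptic operating point (g_Glu, g_GABA, E_GABA).

    Conductances are normalized by the leak conductance and therefore
    dimensionless; ``E_GABA`` is the GABA reversal potential in mV.
    """

    g_Glu: float = 0.0
    g_GABA: float = 0.0
    E_GABA: float = -80.0

    def __post_init__(self) -> None:
        if self.g_Glu < 0:
            raise ValueError("g_Glu must be non-negative")
        if self.g_GABA < 0:
            raise ValueError("g_GABA must be non-negative")


@dataclass(frozen=True)
class EffectiveInput:
    """Derived single-compartment input: g_eff, E_eff and tau_eff = tau/g_eff."""

    g_eff: float      # total conductance relative to leak, >= 1
    E_eff: float      # effective reversal potential, mV
    tau_eff: float    # effective membrane time constant, ms


@dataclass(frozen=True)
class NoiseModel:
    """Input-noise description for the stochastic membrane equation.

    kind
        ``"none"`` — deterministic dynamics;
        ``"constant"`` — additive white noise of fixed amplitude ``sigma`` (mV),
        entering the current balance as sigma*sqrt(tau)*zeta(t);
        ``"conductance"`` — diffusion approximation of Poisson synaptic
        bombardment, where the variance is a_s * g_s * (v - E_s)^2 summed over
        the two synapse types, evaluated at v = E_eff. ``a_Glu``/``a_GABA`` are
        the unitary (single-event) synaptic strengths.
    """

    kind: str = "constant"
    sigma: float = 0.0
    a_Glu: float = 0.0
    a_GABA: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "constant", "conductance"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0 or self.a_Glu < 0 or self.a_GABA < 0:
            raise ValueError("noise amplitudes must be non-negative")

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls(kind="none")

    @classmethod
    def constant(cls, sigma: float) -> "NoiseModel":
        return cls(kind="constant", sigma=sigma)

    @classmethod
    def conductance(cls, a: float, a_GABA: float | None = None) -> "NoiseModel":
        """Conductance-dependent noise; by default a_Glu = a_GABA = a."""
        return cls(kind="conductance", a_Glu=a, a_GABA=a if a_GABA is None else a_GABA)


@dataclass(frozen=True)
class EIFKirParams:
    """Exponential integrate-and-fire neuron with an inward-rectifier K+ current.

    The exponential term Delta_T * exp((v - V_T)/Delta_T) models the sodium
    spike-generating current; the Kir term -g_K/(1 + exp((v - V_P)/K)) * (v - E_K)
    has a conductance that decreases sigmoidally with depolarization (half its
    maximum at V_P). Parameters reproduce sub- and supra-threshold properties of
    a striatal spiny projection neuron. ``g_L_abs`` converts injected currents
    in pA to the normalized units used by the voltage equation (I/g_L in mV).
    """

    base: LIFParams = field(default_factory=LIFParams)
    Delta_T: float = 2.0    # spike slope factor, mV
    V_T: float = -60.0      # exponential-term threshold, mV
    g_K: float = 5.0        # Kir maximal conductance, normalized by leak
    K: float = 16.0         # Kir inactivation slope factor, mV
    V_P: float = -80.0      # Kir half-conductance potential, mV
    E_K: float = -80.0      # Kir reversal potential, mV
    g_L_abs: float = 5.0    # absolute leak conductance, nS

    def __post_init__(self) -> None:
        if self.Delta_T <= 0 or self.K <= 0:
            raise ValueError("Delta_T and K must be positive")
        if self.g_K < 0:
            raise ValueError("g_K must be non-negative")
        if self.g_L_abs <= 0:
            raise ValueError("g_L_abs must be positive")


def _lif_from_dict(d: dict) -> LIFParams:
    return LIFParams(**d)


def load_lif_params(path: Union[str, Path]) -> LIFParams:
    """Read LIF parameters from a YAML file; missing keys keep defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    base = asdict(LIFParams())
    unknown = set(data) - set(base)
    if unknown:
        raise ValueError(f"unknown LIF parameter keys: {sorted(unknown)}")
    base.update(data)
    return _lif_from_dict(base)


def load_eif_kir_params(path: Union[str, Path]) -> EIFKirParams:
    """Read EIF-Kir parameters from a YAML file (LIF fields under ``base``)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    base = data.pop("base", {})
    lif_defaults = asdict(LIFParams())
    unknown = set(base) - set(lif_defaults)
    if unknown:
        raise ValueError(f"unknown LIF parameter keys: {sorted(unknown)}")
    lif_defaults.update(base)
    defaults = {
        f: v for f, v in asdict(EIFKirParams()).items() if f != "base"
    }
    unknown = set(data) - set(defaults)
    if unknown:
        raise ValueError(f"unknown EIF-Kir parameter keys: {sorted(unknown)}")
    defaults.update(data)
    return EIFKirParams(base=_lif_from_dict(lif_defaults), **defaults)
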