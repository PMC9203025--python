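"""Closed-form theory of the deterministic conductance-based LIF neuron.

With constant synaptic conductances the membrane equation collapses to a
one-dimensional relaxation towards an effective reversal potential

    tau dv/dt = -g_eff (v - E_eff),
    g_eff = 1 + g_GABA + g_Glu,
    E_eff = (E_L + g_GABA E_GABA + g_Glu E_Glu) / g_eff,

and the firing rate, time to integrate from reset to threshold, is

    nu = g_eff / (tau * ln((E_eff - E_reset) / (E_eff - E_thr)))     [ms^-1]

whenever E_eff > E_thr, and zero otherwise (no refractory period). GABA enters
twice: it shortens the effective time constant tau/g_eff (speeding firing) and
pulls E_eff towards E_GABA (raising or lowering it depending on where E_GABA
sits). The competition produces three firing regimes as a function of E_GABA —
inhibitory, non-monotonic in g_GABA, and excitatory — plus two silent-at-rest
regimes at sub-threshold glutamatergic drive. This module provides the closed
forms, the regime classification, and phase-diagram construction over the
(E_GABA, g_Glu) plane.

Rates are computed internally in ms^-1 and reported in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
import json
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .params import LIFParams, SynapticDrive, EffectiveInput

__all__ = [
    "RegimeLabel",
    "RegimeSummary",
    "PhaseDiagram",
    "effective_input",
    "deterministic_rate",
    "firing_onset_gGlu",
    "silencing_conductance",
    "rate_derivative_gGABA",
    "critical_EGABA",
    "regime_summary",
    "classify_regime",
    "build_phase_diagram",
]

#: tolerance below which the initial slope is treated as zero when classifying
SLOPE_TOL = 1e-9


class RegimeLabel(str, Enum):
    """Qualitative effect of GABAergic conductance on the firing rate."""

    SILENT = "SILENT"                    # sub-threshold drive, E_GABA <= E_thr
    INHIBITORY = "INHIBITORY"            # rate monotonically decreasing in g_GABA
    NON_MONOTONIC = "NON_MONOTONIC"      # interior maximum of rate vs g_GABA
    EXCITATORY = "EXCITATORY"            # rate monotonically increasing in g_GABA
    GABA_ACTIVATED = "GABA_ACTIVATED"    # silent at g_GABA=0, fires beyond a critical g_GABA


@dataclass(frozen=True)
class RegimeSummary:
    """Shape descriptors of the rate-vs-g_GABA curve at one (g_Glu, E_GABA) point.

    ``strength_ratio`` = nu_max/nu_init measures the strength of the
    non-monotonic effect; it is +inf when the neuron is silent without GABA but
    activated by it, and 1.0 on monotonically decreasing (inhibitory) curves.
    """

    nu_init: float          # rate at g_GABA = 0, Hz
    nu_max: float           # maximum rate over g_GABA in [0, g_GABA_max], Hz
    g_star: float           # argmax GABA conductance, dimensionless
    g_silence: float        # silencing conductance (inf if E_GABA >= E_thr)
    strength_ratio: float   # nu_max / nu_init


def effective_input(params: LIFParams, drive: SynapticDrive) -> EffectiveInput:
    """Effective conductance, reversal potential and time constant."""
    g_eff = 1.0 + drive.g_GABA + drive.g_Glu
    E_eff = (
        params.E_L + drive.g_GABA * drive.E_GABA + drive.g_Glu * params.E_Glu
    ) / g_eff
    return EffectiveInput(g_eff=g_eff, E_eff=E_eff, tau_eff=params.tau / g_eff)


def _rate_hz(params: LIFParams, g_eff, E_eff):
    """Vectorized deterministic rate in Hz from (g_eff, E_eff). Zero below onset."""
    g_eff = np.asarray(g_eff, dtype=float)
    E_eff = np.asarray(E_eff, dtype=float)
    firing = E_eff > params.E_thr
    log_arg = np.where(
        firing,
        (E_eff - params.E_reset) / np.where(firing, E_eff - params.E_thr, 1.0),
        np.e,
    )
    rate = np.where(firing, g_eff / (params.tau * np.log(log_arg)), 0.0)
    return 1000.0 * rate


def deterministic_rate(params: LIFParams, drive: SynapticDrive) -> float:
    """Noise-free firing rate in Hz; exactly zero when E_eff <= E_thr."""
    eff = effective_input(params, drive)
    return float(_rate_hz(params, eff.g_eff, eff.E_eff))


def _rate_vs_gGABA(params: LIFParams, g_Glu: float, E_GABA: float, g_GABA):
    """Vectorized rate over an array of GABA conductances (Hz)."""
    g_GABA = np.asarray(g_GABA, dtype=float)
    g_eff = 1.0 + g_GABA + g_Glu
    E_eff = (params.E_L + g_GABA * E_GABA + g_Glu * params.E_Glu) / g_eff
    return _rate_hz(params, g_eff, E_eff)


def firing_onset_gGlu(params: LIFParams) -> float:
    """Minimal glutamatergic conductance for deterministic firing at g_GABA = 0.

    Solves E_eff(g_Glu) = E_thr, giving (E_thr - E_L)/(E_Glu - E_thr).
    """
    return (params.E_thr - params.E_L) / (params.E_Glu - params.E_thr)


def silencing_conductance(params: LIFParams, g_Glu: float, E_GABA: float) -> float:
    """GABA conductance at which firing stops (E_eff pulled down to E_thr).

    For E_GABA < E_thr this is
    [(E_thr - E_L) + g_Glu (E_thr - E_Glu)] / (E_GABA - E_thr), clamped at 0
    when the drive is already sub-threshold. For E_GABA > E_thr GABA can never
    silence the neuron and +inf is returned; E_GABA = E_thr is divergent.
    """
    if E_GABA == params.E_thr:
        raise ValueError("silencing conductance diverges at E_GABA = E_thr")
    if E_GABA > params.E_thr:
        return float("inf")
    num = (params.E_thr - params.E_L) + g_Glu * (params.E_thr - params.E_Glu)
    return max(num / (E_GABA - params.E_thr), 0.0)


def rate_derivative_gGABA(params: LIFParams, drive: SynapticDrive) -> float:
    """d(nu)/d(g_GABA) at the given operating point, in Hz per unit conductance.

    The two terms inside the bracket are the conductance effect (shorter
    tau_eff, always positive) and the reversal-potential effect (sign set by
    E_GABA - E_eff). Requires a firing point (E_eff > E_thr).
    """
    eff = effective_input(params, drive)
    if eff.E_eff <= params.E_thr:
        raise ValueError("rate derivative undefined at a non-firing point (E_eff <= E_thr)")
    nu_ms = _rate_hz(params, eff.g_eff, eff.E_eff) / 1000.0
    bracket = 1.0 + (
        (drive.E_GABA - eff.E_eff)
        * (params.E_thr - params.E_reset)
        / ((eff.E_eff - params.E_reset) * (eff.E_eff - params.E_thr))
        * params.tau
        * nu_ms
        / eff.g_eff
    )
    return float(1000.0 * nu_ms / eff.g_eff * bracket)


def critical_EGABA(params: LIFParams, g_Glu: float) -> float:
    """GABA reversal separating the inhibitory and non-monotonic regimes (mV).

    Root of d(nu)/d(g_GABA) = 0 at g_GABA = 0, in closed form:

        E* = E_eff - (E_eff - E_reset)(E_eff - E_thr)/(E_thr - E_reset)
                   * ln((E_eff - E_reset)/(E_eff - E_thr))

    with E_eff evaluated at g_GABA = 0. Approaches E_thr at the firing onset
    and decreases towards (E_reset + E_thr)/2 for strong glutamatergic drive.
    """
    eff = effective_input(params, SynapticDrive(g_Glu=g_Glu))
    E = eff.E_eff
    if E <= params.E_thr:
        raise ValueError("critical E_GABA requires supra-threshold g_Glu")
    span = params.E_thr - params.E_reset
    return float(
        E
        - (E - params.E_reset) * (E - params.E_thr) / span
        * np.log((E - params.E_reset) / (E - params.E_thr))
    )


def default_gGABA_max(params: LIFParams, g_Glu: float, E_GABA: float) -> float:
    """Search ceiling for the rate maximum: 2x the silencing conductance when
    finite, else 50 (guarantees an interior maximum in the regimes of interest)."""
    if E_GABA < params.E_thr:
        gs = silencing_conductance(params, g_Glu, E_GABA)
        if np.isfinite(gs) and gs > 0:
            return 2.0 * gs
    return 50.0


def regime_summary(
    params: LIFParams,
    g_Glu: float,
    E_GABA: float,
    g_GABA_max: float | None = None,
) -> RegimeSummary:
    """Characterize the rate-vs-g_GABA curve by bounded maximization.

    A coarse log-spaced grid (512 points) locates the maximum, which is then
    refined by bounded scalar minimization to ~1e-6 in g_GABA.
    """
    if g_GABA_max is None:
        g_GABA_max = default_gGABA_max(params, g_Glu, E_GABA)
    if g_GABA_max <= 0:
        raise ValueError("g_GABA_max must be positive")
    grid = np.concatenate(
        ([0.0], np.geomspace(1e-3, g_GABA_max, 511))
    )
    rates = _rate_vs_gGABA(params, g_Glu, E_GABA, grid)
    nu_init = float(rates[0])
    k = int(np.argmax(rates))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    if hi > lo:
        res = minimize_scalar(
            lambda g: -_rate_vs_gGABA(params, g_Glu, E_GABA, g),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-6},
        )
        g_star, nu_max = float(res.x), float(-res.fun)
    else:  # pragma: no cover - degenerate bracket at the boundary
        g_star, nu_max = float(grid[k]), float(rates[k])
    if nu_max < nu_init:  # refinement can only improve; guard rounding
        g_star, nu_max = 0.0, nu_init
    if nu_init > 0:
        ratio = nu_max / nu_init
    else:
        ratio = float("inf") if nu_max > 0 else float("nan")
    if E_GABA < params.E_thr:
        g_sil = silencing_conductance(params, g_Glu, E_GABA)
    else:
        g_sil = float("inf")
    return RegimeSummary(
        nu_init=nu_init,
        nu_max=nu_max,
        g_star=g_star,
        g_silence=g_sil,
        strength_ratio=ratio,
    )


def classify_regime(params: LIFParams, g_Glu: float, E_GABA: float) -> RegimeLabel:
    """Deterministic regime label at one (g_Glu, E_GABA) point.

    Sub-threshold drive gives SILENT (E_GABA <= E_thr: GABA can never lift
    E_eff above threshold) or GABA_ACTIVATED (E_GABA > E_thr: the neuron starts
    firing beyond a critical g_GABA). Supra-threshold drive gives EXCITATORY
    when E_GABA >= E_thr, otherwise NON_MONOTONIC when the initial slope of the
    rate curve is positive and INHIBITORY when it is non-positive (boundary
    ties resolved towards EXCITATORY / INHIBITORY).
    """
    eff0 = effective_input(params, SynapticDrive(g_Glu=g_Glu))
    if eff0.E_eff <= params.E_thr:
        return RegimeLabel.GABA_ACTIVATED if E_GABA > params.E_thr else RegimeLabel.SILENT
    if E_GABA >= params.E_thr:
        return RegimeLabel.EXCITATORY
    slope0 = rate_derivative_gGABA(
        params, SynapticDrive(g_Glu=g_Glu, E_GABA=E_GABA)
    )
    return RegimeLabel.NON_MONOTONIC if slope0 > SLOPE_TOL else RegimeLabel.INHIBITORY


@dataclass(frozen=True)
class PhaseDiagram:
    """Regime map over a (E_GABA, g_Glu) grid.

    Arrays are indexed ``[i_gGlu, j_EGABA]``. ``slope0`` is d(nu)/d(g_GABA) at
    g_GABA = 0 (Hz per unit conductance; NaN at non-firing points), and the
    summary arrays describe the rate-vs-g_GABA curve at each point.
    """

    E_GABA_axis: np.ndarray
    g_Glu_axis: np.ndarray
    labels: np.ndarray          # dtype object of RegimeLabel
    slope0: np.ndarray
    nu_init: np.ndarray
    nu_max: np.ndarray
    g_star: np.ndarray
    strength_ratio: np.ndarray
    meta: dict

    def to_frame(self) -> pd.DataFrame:
        """Long-format table, one row per grid point."""
        gg, ee = np.meshgrid(self.g_Glu_axis, self.E_GABA_axis, indexing="ij")
        return pd.DataFrame(
            {
                "E_GABA_mV": ee.ravel(),
                "g_Glu": gg.ravel(),
                "label": [lab.value for lab in self.labels.ravel()],
                "slope0_Hz": self.slope0.ravel(),
                "g_star": self.g_star.ravel(),
                "nu_init_Hz": self.nu_init.ravel(),
                "nu_max_Hz": self.nu_max.ravel(),
                "strength_ratio": self.strength_ratio.ravel(),
            }
        )

    def save(self, csv_path: Union[str, Path], json_path: Union[str, Path] | None = None) -> None:
        """Write the long-format CSV and a JSON metadata sidecar."""
        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index=False)
        if json_path is None:
            json_path = csv_path.with_suffix(".json")
        meta = dict(self.meta)
        meta["grid"] = {
            "E_GABA_mV": [float(self.E_GABA_axis[0]), float(self.E_GABA_axis[-1]),
                          int(len(self.E_GABA_axis))],
            "g_Glu": [float(self.g_Glu_axis[0]), float(self.g_Glu_axis[-1]),
                      int(len(self.g_Glu_axis))],
        }
        with open(json_path, "w") as fh:
            json.dump(meta, fh, indent=2)


def default_axes() -> tuple[np.ndarray, np.ndarray]:
    """Default phase-diagram grid: E_GABA -80..-50 mV step 0.1, g_Glu 0..2 step 0.01."""
    return np.arange(-80.0, -50.0 + 1e-9, 0.1), np.arange(0.0, 2.0 + 1e-9, 0.01)


def build_phase_diagram(
    params: LIFParams,
    E_GABA_axis: Sequence[float] | None = None,
    g_Glu_axis: Sequence[float] | None = None,
    compute_summaries: bool = True,
) -> PhaseDiagram:
    """Label every grid point and (optionally) summarize its rate curve.

    ``compute_summaries=False`` skips the per-point maximization (labels and
    initial slopes only), which is much faster on fine grids.
    """
    if E_GABA_axis is None or g_Glu_axis is None:
        dflt_E, dflt_g = default_axes()
        E_GABA_axis = dflt_E if E_GABA_axis is None else np.asarray(E_GABA_axis, float)
        g_Glu_axis = dflt_g if g_Glu_axis is None else np.asarray(g_Glu_axis, float)
    else:
        E_GABA_axis = np.asarray(E_GABA_axis, float)
        g_Glu_axis = np.asarray(g_Glu_axis, float)
    for ax in (E_GABA_axis, g_Glu_axis):
        if len(ax) < 2 or np.any(np.diff(ax) <= 0):
            raise ValueError("axes must be strictly increasing with >= 2 points")

    shape = (len(g_Glu_axis), len(E_GABA_axis))
    labels = np.empty(shape, dtype=object)
    slope0 = np.full(shape, np.nan)
    nu_init = np.zeros(shape)
    nu_max = np.zeros(shape)
    g_star = np.zeros(shape)
    ratio = np.full(shape, np.nan)

    for i, gE in enumerate(g_Glu_axis):
        firing = effective_input(params, SynapticDrive(g_Glu=gE)).E_eff > params.E_thr
        for j, EG in enumerate(E_GABA_axis):
            lab = classify_regime(params, gE, EG)
            labels[i, j] = lab
            if firing:
                slope0[i, j] = rate_derivative_gGABA(
                    params, SynapticDrive(g_Glu=gE, E_GABA=EG)
                )
            if compute_summaries:
                if EG == params.E_thr:
                    # silencing conductance (and hence the default search
                    # ceiling) is undefined exactly at threshold
                    summ = regime_summary(params, gE, EG, g_GABA_max=50.0)
                else:
                    summ = regime_summary(params, gE, EG)
                nu_init[i, j] = summ.nu_init
                nu_max[i, j] = summ.nu_max
                g_star[i, j] = summ.g_star
                ratio[i, j] = summ.strength_ratio

    from . import __version__

    meta = {
        "model": "deterministic LIF",
        "params": {
            "tau_ms": params.tau, "E_L_mV": params.E_L, "E_thr_mV": params.E_thr,
            "E_reset_mV": params.E_reset, "E_Glu_mV": params.E_Glu,
        },
        "package_version": __version__,
    }
    return PhaseDiagram(
        E_GABA_axis=E_GABA_axis, g_Glu_axis=g_Glu_axis, labels=labels,
        slope0=slope0, nu_init=nu_init, nu_max=nu_max, g_star=g_star,
        strength_ratio=ratio, meta=meta,
    )
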