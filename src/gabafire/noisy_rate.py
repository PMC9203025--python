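"""Firing rate of the conductance-based LIF neuron under white-noise input.

The mean first-passage-time (Ricciardi) formula gives the stationary rate

    nu = [ tau_eff * sqrt(pi) * Int_{x_min}^{x_max} e^{x^2}(1 + erf x) dx ]^-1,
    x_min = (E_reset - E_eff)/sigma_eff,  x_max = (E_thr - E_eff)/sigma_eff,
    tau_eff = tau/g_eff,  sigma_eff = sigma/sqrt(g_eff),

where sigma is the white-noise amplitude of the current-balance equation
(I_noise = sigma*sqrt(tau)*zeta(t)). Two noise models are supported: a constant
sigma, and a conductance-dependent sigma from the diffusion approximation of
Poisson synaptic input, sigma^2(v) = sum_s a_s g_s (v - E_s)^2 evaluated at
v = E_eff.

Numerics: the integrand e^{x^2}(1 + erf x) equals erfcx(-x), the scaled
complementary error function, which scipy evaluates stably on the whole real
axis; adaptive quadrature then covers every regime without overflow. Points
where x_max > 26 (rate below ~1e-290) return exactly 0.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import erfcx

from .params import LIFParams, SynapticDrive, NoiseModel
from .lif_analytics import (
    PhaseDiagram,
    RegimeLabel,
    SLOPE_TOL,
    critical_EGABA,
    default_axes,
    deterministic_rate,
    effective_input,
)

__all__ = [
    "ricciardi_rate",
    "high_noise_rate",
    "conductance_noise_sigma",
    "slope0_noisy",
    "boundary_inhibitory_nonmonotonic",
    "build_phase_diagram_noisy",
]

#: central-difference step in g_GABA for the initial slope under noise
SLOPE_H = 1e-4
#: x_max beyond which the first-passage rate underflows to zero
_X_OVERFLOW = 26.0


def conductance_noise_sigma(
    params: LIFParams,
    drive: SynapticDrive,
    a_Glu: float,
    a_GABA: float | None = None,
) -> float:
    """Effective noise amplitude (mV) of the diffusion approximation.

    sigma = sqrt( a_Glu g_Glu (E_eff - E_Glu)^2 + a_GABA g_GABA (E_eff - E_GABA)^2 )
    with E_eff from the mean conductances; vanishes with the conductances.
    By default the two unitary strengths are equal (a_GABA = a_Glu).
    """
    if a_GABA is None:
        a_GABA = a_Glu
    if a_Glu < 0 or a_GABA < 0:
        raise ValueError("unitary synaptic strengths must be non-negative")
    E_eff = effective_input(params, drive).E_eff
    var = a_Glu * drive.g_Glu * (E_eff - params.E_Glu) ** 2
    var += a_GABA * drive.g_GABA * (E_eff - drive.E_GABA) ** 2
    return float(np.sqrt(var))


def _effective_sigma(params: LIFParams, drive: SynapticDrive, noise: NoiseModel) -> float:
    if noise.kind == "none":
        return 0.0
    if noise.kind == "constant":
        return noise.sigma
    if noise.kind == "conductance":
        return conductance_noise_sigma(params, drive, noise.a_Glu, noise.a_GABA)
    raise ValueError(f"unknown noise kind {noise.kind!r}")  # pragma: no cover


def _ricciardi_raw(
    params: LIFParams, g_GABA: float, g_Glu: float, E_GABA: float, sigma: float
) -> float:
    """Rate in Hz from the bare algebra; accepts slightly negative g_GABA for
    finite-difference derivatives (the formula is analytic in g_GABA)."""
    g_eff = 1.0 + g_GABA + g_Glu
    E_eff = (params.E_L + g_GABA * E_GABA + g_Glu * params.E_Glu) / g_eff
    sigma_eff = sigma / np.sqrt(g_eff)
    tau_eff = params.tau / g_eff
    x_min = (params.E_reset - E_eff) / sigma_eff
    x_max = (params.E_thr - E_eff) / sigma_eff
    if x_max > _X_OVERFLOW:
        return 0.0
    pts = [0.0] if x_min < 0.0 < x_max else None
    integral, _ = quad(
        lambda x: erfcx(-x), x_min, x_max,
        epsabs=1e-12, epsrel=1e-10, limit=500, points=pts,
    )
    return 1000.0 / (tau_eff * np.sqrt(np.pi) * integral)


def ricciardi_rate(params: LIFParams, drive: SynapticDrive, noise: NoiseModel) -> float:
    """Stationary firing rate in Hz under white-noise input.

    Dispatches to the deterministic closed form when the effective noise is
    zero. For conductance-kind noise sigma is recomputed at each operating
    point from the mean conductances.
    """
    sigma = _effective_sigma(params, drive, noise)
    if sigma == 0.0:
        return deterministic_rate(params, drive)
    return _ricciardi_raw(params, drive.g_GABA, drive.g_Glu, drive.E_GABA, sigma)


def high_noise_rate(params: LIFParams, drive: SynapticDrive, noise: NoiseModel) -> float:
    """Large-sigma closed form: integrand ~ 1 between the (small) bounds, so

        nu ~ sigma * sqrt(g_eff) / (tau * sqrt(pi) * (E_thr - E_reset)),

    in Hz, growing as sqrt(1 + g_GABA) with the GABA conductance. Accurate only
    when sigma_eff >> both |E_thr - E_eff| and |E_reset - E_eff|.
    """
    if noise.kind != "constant":
        raise ValueError("high-noise limit is defined for constant-amplitude noise")
    g_eff = 1.0 + drive.g_GABA + drive.g_Glu
    return float(
        1000.0 * noise.sigma * np.sqrt(g_eff)
        / (params.tau * np.sqrt(np.pi) * (params.E_thr - params.E_reset))
    )


def slope0_noisy(
    params: LIFParams, g_Glu: float, E_GABA: float, noise: NoiseModel, h: float = SLOPE_H
) -> float:
    """d(nu)/d(g_GABA) at g_GABA = 0 by central difference (Hz per conductance).

    The formula is analytic in g_GABA, so the stencil may dip to g_GABA = -h.
    """
    rates = []
    for g in (-h, +h):
        if noise.kind == "conductance":
            # the variance term a_GABA * g * (E_eff - E_GABA)^2 continues
            # linearly through g = 0; rebuild sigma from the raw algebra
            g_eff = 1.0 + g + g_Glu
            E_eff = (params.E_L + g * E_GABA + g_Glu * params.E_Glu) / g_eff
            var = noise.a_Glu * g_Glu * (E_eff - params.E_Glu) ** 2
            var += noise.a_GABA * g * (E_eff - E_GABA) ** 2
            sigma = float(np.sqrt(max(var, 0.0)))
        else:
            sigma = _effective_sigma(
                params, SynapticDrive(g_Glu=g_Glu, E_GABA=E_GABA), noise
            )
        if sigma == 0.0:
            raise ValueError("slope under noise requires a non-zero noise model")
        rates.append(_ricciardi_raw(params, g, g_Glu, E_GABA, sigma))
    return float((rates[1] - rates[0]) / (2 * h))


def boundary_inhibitory_nonmonotonic(
    params: LIFParams, noise: NoiseModel, g_Glu: float, xtol: float = 0.01
) -> float:
    """E_GABA at which the initial slope of the rate curve crosses zero (mV).

    Bisection over [E_reset, E_thr]; as sigma -> 0 this converges to the
    deterministic critical reversal potential, and noise moves the boundary
    down (the non-monotonic region expands). Raises if the slope does not
    change sign over the bracket.
    """
    lo, hi = params.E_reset, params.E_thr - 1e-6
    f_lo = slope0_noisy(params, g_Glu, lo, noise)
    f_hi = slope0_noisy(params, g_Glu, hi, noise)
    if f_lo * f_hi > 0:
        raise ValueError(
            "initial slope does not change sign over [E_reset, E_thr]; "
            "boundary outside the bracket"
        )
    return float(
        brentq(lambda E: slope0_noisy(params, g_Glu, E, noise), lo, hi, xtol=xtol)
    )


def build_phase_diagram_noisy(
    params: LIFParams,
    noise: NoiseModel,
    E_GABA_axis: Sequence[float] | None = None,
    g_Glu_axis: Sequence[float] | None = None,
    compute_summaries: bool = False,
    g_GABA_grid: Sequence[float] | None = None,
) -> PhaseDiagram:
    """Regime map under noise over a (E_GABA, g_Glu) grid.

    Noise removes the silent region (the rate is positive everywhere), leaves
    the excitatory boundary fixed at E_GABA = E_thr, and moves the
    inhibitory/non-monotonic boundary to lower E_GABA. Summaries (optional,
    they dominate the cost) maximize the Ricciardi rate over ``g_GABA_grid``
    (default: 0 plus 128 log-spaced points up to 50).
    """
    if noise.kind == "none":
        raise ValueError("use build_phase_diagram for the deterministic model")
    if E_GABA_axis is None or g_Glu_axis is None:
        dflt_E, dflt_g = default_axes()
        E_GABA_axis = dflt_E if E_GABA_axis is None else np.asarray(E_GABA_axis, float)
        g_Glu_axis = dflt_g if g_Glu_axis is None else np.asarray(g_Glu_axis, float)
    else:
        E_GABA_axis = np.asarray(E_GABA_axis, float)
        g_Glu_axis = np.asarray(g_Glu_axis, float)
    if g_GABA_grid is None:
        g_GABA_grid = np.concatenate(([0.0], np.geomspace(1e-3, 50.0, 128)))
    else:
        g_GABA_grid = np.asarray(g_GABA_grid, float)

    shape = (len(g_Glu_axis), len(E_GABA_axis))
    labels = np.empty(shape, dtype=object)
    slope0 = np.full(shape, np.nan)
    nu_init = np.zeros(shape)
    nu_max = np.zeros(shape)
    g_star = np.zeros(shape)
    ratio = np.full(shape, np.nan)

    for i, gE in enumerate(g_Glu_axis):
        for j, EG in enumerate(E_GABA_axis):
            s = slope0_noisy(params, gE, EG, noise)
            slope0[i, j] = s
            if EG >= params.E_thr:
                labels[i, j] = RegimeLabel.EXCITATORY
            elif s > SLOPE_TOL:
                labels[i, j] = RegimeLabel.NON_MONOTONIC
            else:
                labels[i, j] = RegimeLabel.INHIBITORY
            if compute_summaries:
                rates = np.array([
                    ricciardi_rate(
                        params, SynapticDrive(g_Glu=gE, g_GABA=g, E_GABA=EG), noise
                    )
                    for g in g_GABA_grid
                ])
                k = int(np.argmax(rates))
                nu_init[i, j] = rates[0]
                nu_max[i, j] = rates[k]
                g_star[i, j] = g_GABA_grid[k]
                ratio[i, j] = rates[k] / rates[0] if rates[0] > 0 else float("inf")

    from . import __version__

    meta = {
        "model": "LIF with white-noise input (first-passage-time rate)",
        "noise": {"kind": noise.kind, "sigma_mV": noise.sigma,
                  "a_Glu": noise.a_Glu, "a_GABA": noise.a_GABA},
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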