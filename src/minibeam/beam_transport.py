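"""Proton beam transport in water: range-energy, lateral spread, ctc planning.

Range follows the Bragg-Kleeman power law R = alpha * E^p (R in cm of
water, E in MeV; defaults alpha = 0.0022, p = 1.77).  Lateral growth of a
pencil beam with depth is modelled by Fermi-Eyges integration of the
Highland multiple-Coulomb-scattering formula over the residual energy
along the track,

    sigma_mcs^2(d) = f_H(d)^2 * int_0^d [E_s / (p(z) v(z))]^2 (d - z)^2 / X0 dz

with E_s = 14.1 MeV, X0 the radiation length of water, pv the
kinematic momentum-velocity product from the residual kinetic energy, and
f_H(d) = 1 + 0.038 ln(d / X0) the Highland logarithmic correction applied
to the whole path.  The initial spot size adds in quadrature:
sigma(d) = sqrt(sigma0^2 + sigma_mcs(d)^2).

For lattice planning, the largest center-to-center spacing whose
peak-to-valley dose ratio at the proximal edge of the target stays below a
homogeneity cap is found by bisection on the monotone sigma/ctc -> PVDR map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .grid_dose import InvalidGeometryError, pvdr_of_ratio

__all__ = [
    "PROTON_MASS_MEV",
    "TransportParams",
    "DepthSigmaCurve",
    "OutOfRangeError",
    "range_from_energy",
    "energy_from_range",
    "sigma_at_depth",
    "depth_sigma_curve",
    "depth_for_sigma",
    "plan_ctc",
]

PROTON_MASS_MEV = 938.272
_ES_MEV = 14.1  # Highland characteristic scattering energy
_HIGHLAND_LOG = 0.038


class OutOfRangeError(ValueError):
    """Depth at or beyond the proton range."""


@dataclass(frozen=True)
class TransportParams:
    """Entry energy, initial spot size and medium constants (water)."""

    energy_mev: float
    sigma0_um: float = 0.0
    radiation_length_g_cm2: float = 36.08
    density_g_cm3: float = 1.0
    bragg_kleeman_alpha: float = 0.0022  # cm * MeV^-p
    bragg_kleeman_p: float = 1.77

    def __post_init__(self) -> None:
        if self.energy_mev <= 0:
            raise ValueError("energy must be positive")
        if self.sigma0_um < 0:
            raise ValueError("sigma0 must be non-negative")

    @property
    def x0_cm(self) -> float:
        return self.radiation_length_g_cm2 / self.density_g_cm3

    @property
    def range_cm(self) -> float:
        return range_from_energy(
            self.energy_mev, self.bragg_kleeman_alpha, self.bragg_kleeman_p
        )


@dataclass(frozen=True)
class DepthSigmaCurve:
    """Beam standard deviation versus depth in water."""

    depths_cm: np.ndarray
    sigmas_um: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.sigmas_um, dtype=float)
        if np.any(np.diff(s) < -1e-9 * max(float(s.max()), 1.0)):
            raise ValueError("sigma must be non-decreasing with depth")


def range_from_energy(energy_mev: float, alpha: float = 0.0022, p: float = 1.77) -> float:
    """Bragg-Kleeman range in water, cm: R = alpha * E^p."""
    if energy_mev <= 0:
        raise ValueError("energy must be positive")
    return alpha * energy_mev**p


def energy_from_range(range_cm: float, alpha: float = 0.0022, p: float = 1.77) -> float:
    """Exact inverse of :func:`range_from_energy`: E = (R / alpha)^(1/p)."""
    if range_cm <= 0:
        raise ValueError("range must be positive")
    return (range_cm / alpha) ** (1.0 / p)


def _pv_mev(kinetic_mev: np.ndarray) -> np.ndarray:
    """Momentum times velocity, MeV, from proton kinetic energy."""
    t = np.asarray(kinetic_mev, dtype=float)
    return t * (t + 2.0 * PROTON_MASS_MEV) / (t + PROTON_MASS_MEV)


def _residual_energy(params: TransportParams, z: np.ndarray) -> np.ndarray:
    """Kinetic energy after depth z, from the residual Bragg-Kleeman range."""
    r_res = params.range_cm - np.asarray(z, dtype=float)
    return (r_res / params.bragg_kleeman_alpha) ** (1.0 / params.bragg_kleeman_p)


def sigma_at_depth(
    params: TransportParams,
    depth_cm: float,
    rel_tol: float = 1e-4,
    n_steps: int | None = None,
) -> float:
    """Beam standard deviation (μm) after a water depth.

    Composite-Simpson Fermi-Eyges quadrature; the step count doubles from
    64 until successive estimates of sigma_mcs agree to ``rel_tol``
    relative (or use exactly ``n_steps`` panels when given, for
    convergence studies).
    """
    if depth_cm < 0:
        raise OutOfRangeError("depth must be non-negative")
    if depth_cm >= params.range_cm:
        raise OutOfRangeError(
            f"depth {depth_cm} cm at or beyond the {params.range_cm:.3f} cm range"
        )
    if depth_cm == 0.0:
        return params.sigma0_um
    var_cm2 = _mcs_variance_cm2(params, depth_cm, rel_tol, n_steps)
    sigma_mcs_um = math.sqrt(var_cm2) * 1.0e4
    return math.hypot(params.sigma0_um, sigma_mcs_um)


def _mcs_variance_cm2(
    params: TransportParams,
    depth_cm: float,
    rel_tol: float,
    n_steps: int | None,
) -> float:
    def integral(n: int) -> float:
        z = np.linspace(0.0, depth_cm, n + 1)
        e = _residual_energy(params, z)
        g = (_ES_MEV / _pv_mev(e)) ** 2 * (depth_cm - z) ** 2 / params.x0_cm
        # composite Simpson (n even)
        h = depth_cm / n
        return float(h / 3.0 * (g[0] + g[-1] + 4.0 * g[1:-1:2].sum() + 2.0 * g[2:-1:2].sum()))

    if n_steps is not None:
        n = n_steps + (n_steps % 2)
        val = integral(n)
    else:
        n = 64
        val = integral(n)
        while n < 65536:
            n *= 2
            new = integral(n)
            if abs(new - val) <= rel_tol * abs(new):
                val = new
                break
            val = new
    f_h = 1.0 + _HIGHLAND_LOG * math.log(depth_cm / params.x0_cm)
    f_h = max(f_h, 0.25)  # guard the log at unphysically shallow depths
    return f_h**2 * val


def depth_sigma_curve(params: TransportParams, depths_cm) -> DepthSigmaCurve:
    """Evaluate sigma(d) on a grid of depths."""
    depths = np.asarray(depths_cm, dtype=float)
    sigmas = np.array([sigma_at_depth(params, float(d)) for d in depths])
    return DepthSigmaCurve(depths_cm=depths, sigmas_um=sigmas)


def depth_for_sigma(params: TransportParams, sigma_target_um: float) -> float:
    """Depth (cm) at which the beam reaches a target standard deviation.

    Monotone root-find (Brent) on :func:`sigma_at_depth`; raises
    :class:`OutOfRangeError` when the target is not reached before the
    end of range (sampled at 99.9% of the range).
    """
    if sigma_target_um < params.sigma0_um:
        raise ValueError("sigma_target below the initial beam size")
    if sigma_target_um == params.sigma0_um:
        return 0.0
    d_max = 0.999 * params.range_cm
    if sigma_at_depth(params, d_max) < sigma_target_um:
        raise OutOfRangeError(
            f"sigma {sigma_target_um} μm not reached before end of range"
        )
    return float(
        optimize.brentq(
            lambda d: sigma_at_depth(params, d) - sigma_target_um,
            0.0,
            d_max,
            xtol=1e-6,
        )
    )


def plan_ctc(
    sigma_proximal_um: float, pvdr_max: float, tol: float = 1e-6
) -> tuple[float, float]:
    """Largest lattice spacing keeping the proximal PVDR within a cap.

    Homogeneous tumor coverage requires the minibeams to have merged at
    the proximal target edge; expressed as PVDR(sigma/ctc) <= pvdr_max,
    the PVDR being strictly decreasing in sigma/ctc, the largest
    admissible ctc is sigma / r* with r* the root of
    PVDR(r) = pvdr_max.  Returns (ctc_um, achieved_pvdr).
    """
    if sigma_proximal_um <= 0:
        raise InvalidGeometryError("sigma_proximal must be positive")
    if pvdr_max <= 1.0:
        raise InvalidGeometryError("pvdr_max must exceed 1 (infeasible otherwise)")
    lo, hi = 1e-3, 10.0  # sigma/ctc bracket: PVDR(lo) huge, PVDR(hi) -> 1
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if pvdr_of_ratio(mid) > pvdr_max:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * hi:
            break
    r_star = hi
    ctc = sigma_proximal_um / r_star
    return ctc, pvdr_of_ratio(r_star)
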