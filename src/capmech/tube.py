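"""Semi-analytic inflation of an incompressible thick-walled cylinder.

This is the validation oracle for the finite-element solver: for a tube of
reference radii Ri < Ro, axial stretch lambda_z and internal pressure p, the
exactly incompressible reduction gives a one-dimensional pressure-radius
relation

    p = \\int_{ri}^{ro} (sigma_theta - sigma_r) / r  dr ,

with the deformed radius field r(R)^2 = ri^2 + (R^2 - Ri^2)/lambda_z.  The
integral is evaluated by quadrature and the deformed inner radius ri found
by bracketing root search.  Circumferential fibers (I4 = lambda_theta^2)
are supported, so the vessel material can be checked as well as the
isotropic tissues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq

from .materials import MaterialParams

__all__ = ["TubeSolution", "analytic_tube_inflation"]


@dataclass(frozen=True)
class TubeSolution:
    """Deformed geometry and transmural stress profile of the inflated tube."""

    ri: float  # deformed inner radius, mm
    ro: float  # deformed outer radius, mm
    r: np.ndarray  # deformed radial stations, mm
    hoop_stress: np.ndarray  # sigma_theta(r), kPa
    radial_stress: np.ndarray  # sigma_r(r), kPa
    pressure: float  # kPa
    axial_stretch: float


def _stress_difference(mat: MaterialParams, lam_t: np.ndarray, lam_z: float) -> np.ndarray:
    """sigma_theta - sigma_r at circumferential stretch lam_t (incompressible)."""
    lam_r = 1.0 / (lam_t * lam_z)
    i1 = lam_r**2 + lam_t**2 + lam_z**2
    w1 = mat.c1 + mat.D1 * mat.D2 * np.exp(mat.D2 * (i1 - 3.0))
    w2 = mat.c2
    dtheta = 2.0 * lam_t**2 * (w1 + (lam_r**2 + lam_z**2) * w2)
    dr = 2.0 * lam_r**2 * (w1 + (lam_t**2 + lam_z**2) * w2)
    if mat.anisotropic:
        i4 = lam_t**2
        w4 = 2.0 * mat.K1 * (i4 - 1.0) * np.exp(mat.K2 * (i4 - 1.0) ** 2)
        dtheta = dtheta + 2.0 * lam_t**2 * w4
    return dtheta - dr


def _pressure_of_ri(
    mat: MaterialParams, Ri: float, Ro: float, ri: float, lam_z: float, n: int
) -> tuple[float, np.ndarray, np.ndarray]:
    """Quadrature of the pressure integral; returns (p, r grid, integrand)."""
    R = np.linspace(Ri, Ro, n)
    r = np.sqrt(ri**2 + (R**2 - Ri**2) / lam_z)
    lam_t = r / R
    integrand = _stress_difference(mat, lam_t, lam_z) / r
    p = float(np.trapezoid(integrand, r))
    return p, r, integrand


def analytic_tube_inflation(
    mat: MaterialParams,
    Ri: float,
    Ro: float,
    pressure: float,
    axial_stretch: float = 1.0,
    n_quad: int = 2000,
) -> TubeSolution:
    """Solve the incompressible tube-inflation problem.

    Parameters are reference radii in mm, internal pressure in kPa and the
    prescribed axial stretch.  Returns the deformed radii and the radial /
    hoop Cauchy stress profiles across the wall (sigma_r(ri) = -p,
    sigma_r(ro) = 0).
    """
    if not 0 < Ri < Ro:
        raise ValueError("need 0 < Ri < Ro")
    if pressure < 0:
        raise ValueError("pressure must be >= 0")

    def f(ri: float) -> float:
        return _pressure_of_ri(mat, Ri, Ro, ri, axial_stretch, n_quad)[0] - pressure

    # bracket: start near the pure-axial-stretch radius, expand outwards
    lo = Ri / np.sqrt(axial_stretch) * 0.5
    hi = Ri / np.sqrt(axial_stretch)
    flo = f(lo)
    for _ in range(60):
        if f(hi) > 0 >= flo:
            break
        hi *= 1.1
    else:
        raise RuntimeError("no root in physical range for deformed inner radius")
    ri = brentq(f, lo, hi, xtol=1e-12, rtol=1e-13)

    _, r, integrand = _pressure_of_ri(mat, Ri, Ro, ri, axial_stretch, n_quad)
    # sigma_r(r) = -p + int_{ri}^{r} (sig_t - sig_r)/r' dr'
    sig_r = -pressure + np.concatenate(
        [[0.0], cumulative_trapezoid(integrand, r)]
    )
    sig_t = sig_r + integrand * r
    return TubeSolution(
        ri=float(r[0]),
        ro=float(r[-1]),
        r=r,
        hoop_stress=sig_t,
        radial_stress=sig_r,
        pressure=pressure,
        axial_stretch=axial_stretch,
    )
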