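"""Zero-load geometry recovery by axial + circumferential pre-shrink.

In-vivo contours are imaged under blood pressure and axial stretch; FE
models must start from the unloaded state.  The unloaded slice is obtained
by (i) shrinking the lumen contour circumferentially by a per-slice factor
and (ii) rescaling the outer contour so the unloaded wall area equals the
in-vivo wall area divided by (1 - axial_shrink) — wall volume conservation
under the assumed 5% axial shortening.  The circumferential shrink is found
by bisection: a candidate zero-load slice is meshed coarsely, pressurized to
the imaging pressure with the matching axial stretch, and its lumen area is
compared with the in-vivo lumen area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from .contours import (
    ContourValidationError,
    SliceContours,
    polygon_area,
    polygon_centroid,
)
from .materials import MaterialParams
from .mesh import build_mesh

__all__ = ["ShrinkResult", "apply_shrink", "find_circ_shrink"]

AXIAL_SHRINK = 0.05


@dataclass
class ShrinkResult:
    shrunk: SliceContours
    axial_shrink: float
    circ_shrink: float
    achieved_lumen_area_error: float  # relative, at the matching pressure
    iterations: int


def _radius_along(centroid: np.ndarray, direction: np.ndarray, poly: np.ndarray) -> float:
    """Distance from centroid to the polygon boundary along a unit ray."""
    from shapely.geometry import LineString

    reach = 10.0 * np.max(np.linalg.norm(poly - centroid, axis=1))
    ray = LineString([centroid, centroid + direction * reach])
    ring = LineString(np.vstack([poly, poly[:1]]))
    inter = ray.intersection(ring)
    if inter.is_empty:
        raise ContourValidationError("ray misses contour during shrink mapping")
    pts = [inter] if inter.geom_type == "Point" else list(inter.geoms)
    coords = np.vstack([np.asarray(g.coords) for g in pts])
    return float(np.max(np.linalg.norm(coords - centroid, axis=1)))


def apply_shrink(
    slc: SliceContours, circ_shrink: float, axial_shrink: float = AXIAL_SHRINK
) -> SliceContours:
    """Map an in-vivo slice to a candidate zero-load slice.

    The lumen scales about its centroid by (1 - circ_shrink); the outer
    contour rescales so the zero-load wall area is the in-vivo wall area
    divided by (1 - axial_shrink); internal pools follow a radial blend of
    the two scalings.
    """
    if not 0 <= circ_shrink < 1:
        raise ValueError("need 0 <= circ_shrink < 1")
    if not 0 <= axial_shrink < 1:
        raise ValueError("need 0 <= axial_shrink < 1")
    centroid = polygon_centroid(slc.lumen)
    la = polygon_area(slc.lumen)
    oa = polygon_area(slc.outer)
    s_lumen = 1.0 - circ_shrink
    wall_target = (oa - la) / (1.0 - axial_shrink)
    s_outer = np.sqrt((wall_target + s_lumen**2 * la) / oa)

    def scale(poly: np.ndarray, k: float) -> np.ndarray:
        return centroid + k * (poly - centroid)

    new_lumen = scale(slc.lumen, s_lumen)
    new_outer = scale(slc.outer, s_outer)
    if not Polygon(new_outer).contains(Polygon(new_lumen)):
        raise ContourValidationError("shrink produced outer inside lumen")

    def blend(poly: np.ndarray) -> np.ndarray:
        out = np.empty_like(poly)
        for i, v in enumerate(poly):
            d = v - centroid
            r = np.linalg.norm(d)
            if r < 1e-12:
                out[i] = v
                continue
            u = d / r
            r_l = _radius_along(centroid, u, slc.lumen)
            r_o = _radius_along(centroid, u, slc.outer)
            t = np.clip((r - r_l) / max(r_o - r_l, 1e-9), 0.0, 1.0)
            k = s_lumen * (1.0 - t) + s_outer * t
            out[i] = centroid + k * d
        return out

    return slc.with_contours(
        lumen=new_lumen,
        outer=new_outer,
        lipids=[blend(p) for p in slc.lipids],
        calcifications=[blend(p) for p in slc.calcifications],
    )


def estimate_circ_shrink_annulus(
    slc: SliceContours,
    pressure: float,
    axial_shrink: float = AXIAL_SHRINK,
    material: MaterialParams | None = None,
) -> float:
    """Fast shrink estimate from the area-equivalent incompressible tube.

    Replaces the slice by the annulus with the same lumen/outer areas and
    inverts the semi-analytic inflation relation; used to warm-start the FE
    bisection.
    """
    from scipy.optimize import brentq

    from .materials import VESSEL
    from .tube import analytic_tube_inflation

    mat = material or VESSEL
    Ri = np.sqrt(polygon_area(slc.lumen) / np.pi)
    Ro = np.sqrt(polygon_area(slc.outer) / np.pi)
    lam_z = 1.0 / (1.0 - axial_shrink)

    def err(s: float) -> float:
        ri0 = Ri * (1.0 - s)
        wall0 = np.pi * (Ro**2 - Ri**2) / (1.0 - axial_shrink)
        ro0 = np.sqrt(ri0**2 + wall0 / np.pi)
        sol = analytic_tube_inflation(mat, ri0, ro0, pressure, lam_z, n_quad=400)
        return sol.ri - Ri

    if err(0.0) <= 0:
        return 0.0
    try:
        return float(brentq(err, 0.0, 0.45, xtol=1e-4))
    except ValueError:
        return 0.15  # mid-bracket fallback


def find_circ_shrink(
    slc: SliceContours,
    materials: dict[str, MaterialParams],
    pressure: float,
    tol: float = 0.01,
    coarse_mesh_size: float = 0.35,
    axial_shrink: float = AXIAL_SHRINK,
    bracket: tuple[float, float] = (0.0, 0.3),
    max_iter: int = 40,
    n_increments: int = 6,
    initial_guess: float | None = None,
) -> ShrinkResult:
    """Bisect the circumferential shrink so pressurization recovers the
    in-vivo lumen area within relative tolerance ``tol``.

    The candidate zero-load slice is solved at the target pressure (kPa)
    with axial stretch 1/(1 - axial_shrink) on a coarse mesh.
    """
    from . import fem

    if tol <= 0:
        raise ValueError("tol must be positive")
    la_target = polygon_area(slc.lumen)
    lam_z = 1.0 / (1.0 - axial_shrink)

    def pressurized_area(s: float) -> float:
        shrunk = apply_shrink(slc, s, axial_shrink)
        mesh = build_mesh(shrunk, coarse_mesh_size)
        try:
            sol = fem.solve(mesh, materials, pressure, lam_z,
                            n_increments=n_increments)
        except fem.NonConvergenceError:
            return np.nan
        # correct the polygonization deficit of the coarse lumen ring so the
        # comparison with the (finely sampled) in-vivo contour is unbiased
        ring0 = mesh.nodes[mesh.lumen_edges[:, 0]]
        x, y = ring0[:, 0], ring0[:, 1]
        a_ring0 = abs(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        return sol.lumen_area() * polygon_area(shrunk.lumen) / a_ring0

    lo, hi = bracket
    if initial_guess is not None:
        lo = float(np.clip(initial_guess - 0.03, bracket[0], bracket[1]))
        hi = float(np.clip(initial_guess + 0.03, bracket[0], bracket[1]))
    iterations = 0

    def err(s: float) -> float:
        nonlocal iterations
        iterations += 1
        a = pressurized_area(s)
        if np.isnan(a):
            import warnings

            warnings.warn(f"FE non-convergence at circ_shrink={s:.4f}; skipped",
                          stacklevel=2)
            return np.nan
        return (a - la_target) / la_target

    def probe(s: float, direction: float) -> tuple[float, float]:
        """Evaluate err(s), nudging past FE-non-convergent candidates."""
        v = err(s)
        for _ in range(4):
            if np.isfinite(v):
                return s, v
            s = float(np.clip(s + direction * 0.015, bracket[0], bracket[1]))
            v = err(s)
        return s, v

    lo, f_lo = probe(lo, +1.0)
    if np.isfinite(f_lo) and abs(f_lo) <= tol:
        return ShrinkResult(apply_shrink(slc, lo, axial_shrink), axial_shrink,
                            lo, abs(f_lo), iterations)
    # pressurized lumen area decreases with shrink: need f_lo > 0; widen a
    # warm-started bracket toward the full one if the sign is wrong
    while np.isfinite(f_lo) and f_lo < 0 and lo > bracket[0] + 1e-12:
        lo, f_lo = probe(max(bracket[0], lo - 0.06), +1.0)
        if np.isfinite(f_lo) and abs(f_lo) <= tol:
            return ShrinkResult(apply_shrink(slc, lo, axial_shrink),
                                axial_shrink, lo, abs(f_lo), iterations)
    hi, f_hi = probe(hi, -1.0)
    while np.isfinite(f_hi) and f_hi > 0 and hi < bracket[1] - 1e-12:
        hi, f_hi = probe(min(bracket[1], hi + 0.06), -1.0)
        if np.isfinite(f_hi) and abs(f_hi) <= tol:
            return ShrinkResult(apply_shrink(slc, hi, axial_shrink),
                                axial_shrink, hi, abs(f_hi), iterations)
    if not (np.isfinite(f_lo) and np.isfinite(f_hi)) or f_lo < 0 or f_hi > 0:
        raise RuntimeError(
            f"no sign change on [{lo}, {hi}]: rel. errors ({f_lo:.4g}, {f_hi:.4g})"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = err(mid)
        if np.isnan(f_mid):
            # skip the failed candidate by nudging the bracket inward
            hi = 0.5 * (mid + hi)
            continue
        if abs(f_mid) <= tol:
            return ShrinkResult(apply_shrink(slc, mid, axial_shrink),
                                axial_shrink, mid, abs(f_mid), iterations)
        if f_mid > 0:
            lo = mid
        else:
            hi = mid
    raise RuntimeError(
        f"bisection did not reach tol={tol} in {max_iter} iterations "
        f"(bracket [{lo:.5f}, {hi:.5f}])"
    )
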