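"""Seeded synthetic cohorts of matched baseline/follow-up vessel slices.

Patient contour data behind this kind of analysis are not publicly
deposited, so the pipeline is exercised on a generator that emulates the
statistical structure the analysis assumes:

* matched baseline/follow-up cross-sections for each slice;
* a heavily right-skewed fibrous-cap-thickness distribution (most slices in
  the thickest-cap category), drawn log-normal;
* eccentric single-pool lipid plaques whose cap subtends a uniform arc;
* morphology-linked progression: the log change in cap thickness depends on
  baseline plaque burden and baseline cap thickness plus noise, so
  follow-up vulnerability-category changes are rare (class-imbalanced) but
  carry learnable signal;
* per-patient diastolic/systolic arm pressures.

Geometry is a perturbed-ellipse lumen with an offset outer wall thickened
over the plaque arc; every generated slice passes the contour validator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np

from .contours import ContourValidationError, SliceContours

__all__ = ["CohortSpec", "ProgressionModel", "SlicePair", "generate_cohort",
           "generate_cylinder_fixture"]


@dataclass(frozen=True)
class ProgressionModel:
    """Log-scale drift of cap thickness and lumen area, baseline→follow-up.

    log(capT_fu / capT_bl) = intercept + pb_coef*(PB - pb_ref)
                             + capt_coef*(log capT - log capt_ref) + N(0, sd)
    log(LA_fu / LA_bl)     = la_intercept + N(0, la_sd)
    """

    intercept: float = -0.04
    pb_coef: float = -1.2
    capt_coef: float = -0.15
    pb_ref: float = 0.62
    capt_ref: float = 0.45
    noise_sd: float = 0.18
    la_intercept: float = -0.01
    la_sd: float = 0.05

    def null(self) -> "ProgressionModel":
        """Zeroed drift: follow-up differs from baseline by noise only."""
        return ProgressionModel(0.0, 0.0, 0.0, self.pb_ref, self.capt_ref,
                                self.noise_sd, 0.0, self.la_sd)

    def strong(self) -> "ProgressionModel":
        """Large, low-noise morphology-linked progression (signal check)."""
        return ProgressionModel(-0.10, -4.0, -0.9, self.pb_ref, self.capt_ref,
                                0.05, -0.02, 0.03)


@dataclass(frozen=True)
class CohortSpec:
    """Statistical laws of the synthetic cohort (lengths mm, angles degrees).

    Defaults emulate the analysed study conditions: 114 matched slice pairs
    from 10 patients, ~69% of baseline slices in the thickest-cap category
    and roughly one positive vulnerability-change outcome per seven slices.
    """

    n_patients: int = 10
    slices_per_patient: int = 12
    n_pairs: int = 114  # total matched pairs (truncates the patient grid)
    seed: int = 0
    # log-normal cap thickness: median exp(mu)=0.48 mm, sigma on log scale
    cap_thickness_law: tuple[float, float] = (-0.7374, 0.564)
    lipid_arc_law: tuple[float, float] = (60.0, 150.0)
    lumen_radius_law: tuple[float, float] = (1.5, 0.22)
    wall_thickness_law: tuple[float, float] = (1.0, 0.15)
    pressure_dia_law: tuple[float, float] = (72.0, 10.0)
    pressure_sys_law: tuple[float, float] = (140.0, 14.0)
    progression: ProgressionModel = field(default_factory=ProgressionModel)
    n_contour_points: int = 96

    def __post_init__(self):
        for name in ("cap_thickness_law", "lumen_radius_law", "wall_thickness_law"):
            if getattr(self, name)[1] <= 0:
                raise ValueError(f"{name}: scale must be positive")
        if self.slices_per_patient < 1:
            raise ValueError("slices_per_patient >= 1")
        if self.n_pairs > self.n_patients * self.slices_per_patient:
            raise ValueError("n_pairs exceeds patient grid capacity")


@dataclass
class SlicePair:
    baseline: SliceContours
    followup: SliceContours
    true_cap_thickness: tuple[float, float]  # drawn (baseline, follow-up) mm


# ---------------------------------------------------------------------------

def _smooth_bump(theta: np.ndarray, center: float, half_width: float) -> np.ndarray:
    """C1 bump: 1 at center, 0 outside |dtheta| > half_width; flat middle."""
    d = np.angle(np.exp(1j * (theta - center)))
    x = np.abs(d) / half_width
    w = np.where(x < 0.5, 1.0, np.where(x < 1.0, 0.5 * (1 + np.cos(2 * np.pi * (x - 0.5))), 0.0))
    return w


def _build_slice(
    rng: np.random.Generator,
    slice_id: str,
    patient_id: str,
    timepoint: str,
    lumen_r: float,
    wall_h: float,
    cap_t: float,
    lipid_arc_deg: float,
    lipid_angle: float,
    shape: dict,
    pressure: dict,
    n_pts: int,
) -> SliceContours:
    theta = np.linspace(0, 2 * np.pi, n_pts, endpoint=False)
    r_lumen = lumen_r * (
        1.0
        + shape["e2"] * np.cos(2 * theta + shape["p2"])
        + shape["e3"] * np.cos(3 * theta + shape["p3"])
    )
    lumen = np.stack([r_lumen * np.cos(theta), r_lumen * np.sin(theta)], axis=1)

    half = math.radians(lipid_arc_deg) / 2.0
    w = _smooth_bump(theta, lipid_angle, half)
    # wall bulges over the plaque so cap + lipid always fit inside it
    bulge = max(0.35, cap_t + 0.50 - wall_h)
    h = wall_h + bulge * w
    r_outer = r_lumen + h
    outer = np.stack([r_outer * np.cos(theta), r_outer * np.sin(theta)], axis=1)

    # lipid pool: inner border one cap thickness outside the lumen over the
    # arc (flat over the central half, shouldering up at the edges)
    n_arc = max(24, int(n_pts * lipid_arc_deg / 360.0))
    th = np.linspace(lipid_angle - half, lipid_angle + half, n_arc)
    wl = _smooth_bump(th, lipid_angle, half)
    r_l = lumen_r * (
        1.0
        + shape["e2"] * np.cos(2 * th + shape["p2"])
        + shape["e3"] * np.cos(3 * th + shape["p3"])
    )
    cap_prof = cap_t * (1.0 + 0.8 * (1.0 - wl))
    h_arc = wall_h + bulge * wl
    lip_th = np.maximum((h_arc - cap_prof - 0.15) * 0.8 * wl, 0.03)
    ri = r_l + cap_prof
    ro = ri + lip_th
    inner_arc = np.stack([ri * np.cos(th), ri * np.sin(th)], axis=1)
    outer_arc = np.stack([ro * np.cos(th), ro * np.sin(th)], axis=1)
    lipid = np.vstack([inner_arc, outer_arc[::-1]])

    return SliceContours(
        slice_id=slice_id,
        patient_id=patient_id,
        timepoint=timepoint,
        lumen=lumen,
        outer=outer,
        lipids=[lipid],
        pressure_mmHg=pressure,
    )


def _draw_shape(rng: np.random.Generator) -> dict:
    return {
        "e2": rng.uniform(0.0, 0.07),
        "e3": rng.uniform(0.0, 0.04),
        "p2": rng.uniform(0, 2 * np.pi),
        "p3": rng.uniform(0, 2 * np.pi),
    }


def generate_cohort(spec: CohortSpec) -> list[SlicePair]:
    """Generate the matched baseline/follow-up cohort, deterministic in seed."""
    rng = np.random.default_rng(spec.seed)
    pairs: list[SlicePair] = []
    made = 0
    for p in range(spec.n_patients):
        patient_id = f"P{p + 1:02d}"
        dia = float(np.clip(rng.normal(*spec.pressure_dia_law), 50, 100))
        sys_p = float(np.clip(rng.normal(*spec.pressure_sys_law), dia + 25, 200))
        pressure = {"dia": dia, "sys": sys_p}
        for s in range(spec.slices_per_patient):
            if made >= spec.n_pairs:
                break
            slice_id = f"{patient_id}S{s + 1:02d}"
            for attempt in range(100):
                try:
                    pair = _make_pair(rng, spec, slice_id, patient_id, pressure)
                    break
                except ContourValidationError:
                    continue
            else:
                raise RuntimeError(f"{slice_id}: no valid geometry in 100 attempts")
            pairs.append(pair)
            made += 1
    return pairs


def _make_pair(rng, spec: CohortSpec, slice_id: str, patient_id: str,
               pressure: dict) -> SlicePair:
    prog = spec.progression
    lumen_r = float(np.clip(rng.normal(*spec.lumen_radius_law), 0.8, 2.6))
    wall_h = float(np.clip(rng.normal(*spec.wall_thickness_law), 0.6, 1.8))
    cap_t = float(np.clip(rng.lognormal(*spec.cap_thickness_law), 0.06, 1.8))
    arc = float(rng.uniform(*spec.lipid_arc_law))
    angle = float(rng.uniform(0, 2 * np.pi))
    shape = _draw_shape(rng)
    n = spec.n_contour_points

    baseline = _build_slice(rng, slice_id, patient_id, "baseline", lumen_r,
                            wall_h, cap_t, arc, angle, shape, pressure, n)

    # progression drives cap thinning/thickening and lumen-area change from
    # baseline morphology; plaque burden proxy from the drawn geometry
    la = math.pi * lumen_r**2
    outer_a = math.pi * (lumen_r + wall_h) ** 2
    pb = (outer_a - la) / outer_a
    dlog_cap = (
        prog.intercept
        + prog.pb_coef * (pb - prog.pb_ref)
        + prog.capt_coef * (math.log(cap_t) - math.log(prog.capt_ref))
        + rng.normal(0.0, prog.noise_sd)
    )
    cap_fu = float(np.clip(cap_t * math.exp(dlog_cap), 0.05, 1.9))
    la_factor = math.exp(prog.la_intercept + rng.normal(0.0, prog.la_sd))
    lumen_r_fu = lumen_r * math.sqrt(la_factor)
    wall_fu = wall_h * float(np.clip(1.0 + 0.5 * (1.0 - la_factor), 0.9, 1.1))

    followup = _build_slice(
        rng, slice_id, patient_id, "followup", lumen_r_fu, wall_fu, cap_fu,
        arc, angle, shape, pressure, n)
    return SlicePair(baseline, followup, (cap_t, cap_fu))


def generate_cylinder_fixture(
    Ri: float, Ro: float, n_vertices: int = 360,
    slice_id: str = "cylinder", pressure: dict | None = None
) -> SliceContours:
    """Concentric regular-polygon annulus — the FE validation geometry."""
    if not 0 < Ri < Ro:
        raise ValueError("need 0 < Ri < Ro")
    if n_vertices < 8:
        raise ValueError("need at least 8 vertices")
    if n_vertices < 32:
        import warnings

        warnings.warn("coarse cylinder fixture (< 32 vertices)", stacklevel=2)
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    ring = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    return SliceContours(
        slice_id=slice_id,
        patient_id="fixture",
        timepoint="baseline",
        lumen=Ri * ring,
        outer=Ro * ring,
        pressure_mmHg=pressure or {"dia": 75.0, "sys": 100.0},
    )
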