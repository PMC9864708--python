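"""Hyperelastic material parameters for vessel wall, lipid and calcification.

The constitutive model is a modified Mooney-Rivlin solid with exponential
stiffening,

    W_iso   = c1 (I1b - 3) + c2 (I2b - 3) + D1 [exp(D2 (I1b - 3)) - 1]
    W_aniso = W_iso + K1/K2 { exp[K2 (I4b - 1)^2] - 1 }

written on the isochoric invariants I1b = J^(-2/3) I1, I2b = J^(-4/3) I2 and
I4b = J^(-2/3) I4, where I4 = C : (nc x nc) for the unit circumferential
fiber direction nc.  Near-incompressibility is enforced by a volumetric
penalty kappa/2 (J-1)^2 with kappa a large multiple of the tissue's initial
shear modulus mu0 = 2 (c1 + c2 + D1 D2).

The vessel/fibrous-tissue constants carry a negative c1; the combined model
is nevertheless stable over the physiological strain range because the
exponential I1 term dominates (mu0 = 24.2 kPa > 0).  A convexity scan over
the working stretch range is available and warns if the shear response ever
softens to non-positive slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MaterialParams",
    "VESSEL",
    "LIPID",
    "CALCIFICATION",
    "DEFAULT_MATERIALS",
    "check_stability",
]

PENALTY_FACTOR = 1000.0  # kappa = PENALTY_FACTOR * mu0


@dataclass(frozen=True)
class MaterialParams:
    """Mooney-Rivlin constants; stress-like parameters in kPa.

    K1/K2 (the circumferential fiber terms) are present only for vessel
    tissue; lipid and calcification are isotropic.
    """

    tissue: str  # vessel | lipid | calcification
    c1: float
    c2: float
    D1: float
    D2: float
    K1: float | None = None
    K2: float | None = None

    def __post_init__(self) -> None:
        if self.D2 <= 0:
            raise ValueError("D2 must be positive")
        has_fiber = self.K1 is not None and self.K2 is not None
        if (self.tissue == "vessel") != has_fiber:
            raise ValueError("K1/K2 must be present iff tissue is vessel")

    @property
    def anisotropic(self) -> bool:
        return self.K1 is not None

    @property
    def shear_modulus(self) -> float:
        """Initial (small-strain) shear modulus 2(c1 + c2 + D1*D2), kPa."""
        return 2.0 * (self.c1 + self.c2 + self.D1 * self.D2)

    @property
    def kappa(self) -> float:
        """Volumetric penalty stiffness, kPa."""
        return PENALTY_FACTOR * abs(self.shear_modulus)


VESSEL = MaterialParams("vessel", c1=-262.6, c2=22.9, D1=125.9, D2=2.0, K1=7.19, K2=23.5)
LIPID = MaterialParams("lipid", c1=0.5, c2=0.0, D1=0.5, D2=1.5)
CALCIFICATION = MaterialParams("calcification", c1=92.0, c2=0.0, D1=36.0, D2=2.0)

DEFAULT_MATERIALS: dict[str, MaterialParams] = {
    "vessel": VESSEL,
    "lipid": LIPID,
    "calcification": CALCIFICATION,
}


def check_stability(mat: MaterialParams, max_stretch: float = 1.5, n: int = 200) -> bool:
    """Scan incompressible equibiaxial response for softening.

    Returns True when the in-plane stress is strictly increasing in stretch
    over [1, max_stretch]; warns and returns False otherwise.
    """
    lam = np.linspace(1.0, max_stretch, n)
    i1 = 2 * lam**2 + lam**-4
    w1 = mat.c1 + mat.D1 * mat.D2 * np.exp(mat.D2 * (i1 - 3.0))
    w2 = mat.c2
    # incompressible equibiaxial membrane stress
    sig = 2.0 * (lam**2 - lam**-4) * (w1 + lam**2 * w2)
    ok = bool(np.all(np.diff(sig) > -1e-12))
    if not ok:
        warnings.warn(
            f"{mat.tissue}: equibiaxial response non-monotone below stretch "
            f"{max_stretch}; check parameters",
            stacklevel=2,
        )
    return ok
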