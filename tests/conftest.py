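"""Shared fixtures: canonical geometries and a small synthetic cohort."""

from __future__ import annotations

import numpy as np
import pytest

from _geometry import circle
from capmech.contours import SliceContours
from capmech.synthetic import CohortSpec, generate_cohort, generate_cylinder_fixture


@pytest.fixture(scope="session")
def cylinder():
    """Annulus Ri=1.5, Ro=3.0 mm — the FE validation fixture."""
    return generate_cylinder_fixture(1.5, 3.0, 360)


@pytest.fixture(scope="session")
def lipid_slice():
    """Eccentric plaque slice with one lipid pool (cap ~0.25 mm)."""
    pairs = generate_cohort(CohortSpec(seed=11, n_pairs=1))
    return pairs[0].baseline


@pytest.fixture(scope="session")
def small_cohort():
    """Twelve matched pairs, default progression."""
    return generate_cohort(CohortSpec(seed=7, n_pairs=12))


@pytest.fixture
def annular_lipid_slice():
    """Circular lumen r=1 with an annular lipid 0.2 mm away over ~90 deg."""
    lumen = circle(1.0, 180)
    outer = circle(2.2, 180)
    th = np.linspace(-np.pi / 4, np.pi / 4, 60)
    inner = np.stack([1.2 * np.cos(th), 1.2 * np.sin(th)], axis=1)
    outer_arc = np.stack([1.7 * np.cos(th), 1.7 * np.sin(th)], axis=1)
    lipid = np.vstack([inner, outer_arc[::-1]])
    return SliceContours(
        slice_id="annular",
        patient_id="T",
        timepoint="baseline",
        lumen=lumen,
        outer=outer,
        lipids=[lipid],
    )
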