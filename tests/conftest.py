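"""Shared fixtures: tiny hand-built plans and a session-scoped phantom."""

from __future__ import annotations

import numpy as np
import pytest

from sbrtqa import (
    DoseGrid,
    PhantomConfig,
    Plan,
    Prescription,
    StructureMask,
    StructureSet,
    load_criteria,
    make_phantom,
    reference_cohort,
)


def build_plan(
    dose: np.ndarray,
    masks: dict,
    spacing=(10.0, 10.0, 10.0),
    total_dose=50.0,
    n_fractions=5,
    isocenter=(0.0, 0.0, 0.0),
    patient_id="test",
) -> Plan:
    """Assemble a plan from raw arrays on a shared frame."""
    frame = "test-frame"
    grid = DoseGrid(np.zeros(3), np.asarray(spacing, float), dose, frame)
    sset = StructureSet(
        {name: StructureMask(name, occ, frame) for name, occ in masks.items()},
        np.asarray(isocenter, float),
    )
    return Plan(grid, sset, Prescription(total_dose, n_fractions), patient_id)


@pytest.fixture(scope="session")
def criteria():
    return load_criteria()


@pytest.fixture(scope="session")
def cohort():
    return reference_cohort()


@pytest.fixture(scope="session")
def sphere_phantom_plan():
    """A 2 mm spherical phantom with analytically known metrics."""
    cfg = PhantomConfig(
        ptv_semiaxes_mm=(15.0, 15.0, 15.0),
        r100_scale=1.08,
        g50_mm=10.0,
        iso_to_rib_mm=30.0,
        patient_id="fixture-phantom",
    )
    return make_phantom(cfg), cfg
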