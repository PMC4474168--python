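"""Shared fixtures.

The full scenario grid takes a couple of minutes to simulate, so it runs once
per session and is shared between the scenario-property tests and the
acceptance checks.
"""

from __future__ import annotations

import numpy as np
import pytest

import pedtmdd as pt


@pytest.fixture(scope="session")
def ref_params() -> pt.TMDDParameters:
    """Adult reference parameter set (anchored R0 / Vmax / Km, surrogate disposition)."""
    return pt.make_reference_params()


@pytest.fixture(scope="session")
def spolicy() -> pt.ScalingPolicy:
    return pt.ScalingPolicy()


@pytest.fixture(scope="session")
def full_table(ref_params):
    """The complete default scenario grid (560 cells x 2 model kinds)."""
    return pt.run_grid(pt.default_grid(), ref_params)


@pytest.fixture()
def adult_regimen(ref_params):
    """A 2 mg/kg IV bolus for the 18-year reference subject."""
    return pt.build_regimen(2.0, "per_kg", pt.Subject.from_age("18y"))


def two_compartment_reference(dose, kel, v1, v2, q, times):
    """Independent bi-exponential oracle for the linear two-compartment model.

    Solves the characteristic quadratic of the 2x2 amount system by hand
    (macro-constant route, no linear-algebra shortcuts shared with the
    package) and returns the central concentration.
    """
    k10 = kel
    k12 = q / v1
    k21 = q / v2
    s = k10 + k12 + k21
    disc = np.sqrt(s**2 - 4.0 * k10 * k21)
    lam1 = (s + disc) / 2.0
    lam2 = (s - disc) / 2.0
    c0 = dose / v1
    a = c0 * (lam1 - k21) / (lam1 - lam2)
    b = c0 * (k21 - lam2) / (lam1 - lam2)
    times = np.asarray(times, dtype=float)
    return a * np.exp(-lam1 * times) + b * np.exp(-lam2 * times)
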