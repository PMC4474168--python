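"""Core target-mediated drug disposition (TMDD) model and its Michaelis-Menten reduction.

The full model is the Mager–Jusko scheme for an IV-dosed monoclonal antibody:
free drug distributes between a central (plasma) and a peripheral compartment,
is eliminated linearly (catabolic clearance ``kel * V1``) and binds 1:1 to a
target that turns over with zero-order synthesis ``ksyn`` and first-order
degradation ``kdeg``.  The drug-target complex is internalized with rate
constant ``kint``, which constitutes the target-mediated elimination route.
Binding occurs in the central compartment only; target feedback is not
modelled.

State convention (package-wide units: day, nmol, l, nmol/l):

* ``A1`` — free drug amount in the central compartment (nmol)
* ``A2`` — free drug amount in the peripheral compartment (nmol)
* ``R``  — free target concentration (nmol/l, referenced to ``V1``)
* ``DR`` — drug-target complex concentration (nmol/l)

The quasi-steady-state reduction collapses the binding/turnover dynamics into
Michaelis-Menten elimination of free drug with ``Vmax = kint * R0`` and
``Km = (koff + kint) / kon``, where ``R0 = ksyn / kdeg`` is the pre-dose
target concentration.  The reduction assumes total target stays near ``R0``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "TMDDParameters",
    "MMParameters",
    "tmdd_rhs",
    "tmdd_jacobian",
    "mm_rhs",
    "steady_state_target",
    "mm_from_micro",
    "occupancy",
    "cl_total_model",
    "linear_disposition_profile",
]


@dataclass(frozen=True)
class TMDDParameters:
    """Micro-parameterization of the full TMDD model.

    Parameters
    ----------
    kel : float
        First-order catabolic elimination rate constant of free drug (1/day).
    kon : float
        Second-order binding association rate constant (1/(nmol/l)/day).
    koff : float
        First-order dissociation rate constant (1/day).
    kint : float
        First-order internalization rate constant of the complex (1/day).
    ksyn : float
        Zero-order target synthesis rate (nmol/l/day, central-volume units).
    kdeg : float
        First-order free-target degradation rate constant (1/day).
    v1, v2 : float
        Central and peripheral volumes of distribution (l).
    q : float
        Distributional clearance between the compartments (l/day).
    """

    kel: float
    kon: float
    koff: float
    kint: float
    ksyn: float
    kdeg: float
    v1: float
    v2: float
    q: float

    def __post_init__(self) -> None:
        # Rate constants may be zero (limiting cases: kon=0 is the linear
        # two-compartment model, kint=0 removes target-mediated elimination);
        # volumes and the distributional clearance must be strictly positive.
        for name in ("kel", "kon", "koff", "kint", "ksyn", "kdeg"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0.0:
                raise ValueError(f"TMDD parameter {name!r} must be finite and >= 0, got {value!r}")
        for name in ("v1", "v2", "q"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0.0:
                raise ValueError(f"TMDD parameter {name!r} must be finite and > 0, got {value!r}")

    @property
    def cl_linear(self) -> float:
        """Linear (catabolic) clearance, ``kel * V1`` (l/day)."""
        return self.kel * self.v1

    @property
    def r0(self) -> float:
        """Pre-dose steady-state free target concentration, ``ksyn / kdeg`` (nmol/l)."""
        return self.ksyn / self.kdeg

    def with_(self, **changes: float) -> "TMDDParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass(frozen=True)
class MMParameters:
    """Michaelis-Menten reduced parameterization (drug species only).

    ``vmax`` is the maximal target-mediated elimination rate (nmol/l/day) and
    ``km`` the Michaelis constant (nmol/l); the remaining fields retain the
    two-compartment disposition of the full model.
    """

    kel: float
    vmax: float
    km: float
    v1: float
    v2: float
    q: float

    def __post_init__(self) -> None:
        for name in ("kel", "vmax"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0.0:
                raise ValueError(f"MM parameter {name!r} must be finite and >= 0, got {value!r}")
        for name in ("km", "v1", "v2", "q"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0.0:
                raise ValueError(f"MM parameter {name!r} must be finite and > 0, got {value!r}")

    @property
    def cl_linear(self) -> float:
        return self.kel * self.v1


def tmdd_rhs(t: float, y: np.ndarray, p: TMDDParameters) -> np.ndarray:
    """Right-hand side of the full TMDD system, d/dt of ``[A1, A2, R, DR]``.

    Drug species are amounts (nmol); target species are concentrations
    (nmol/l).  Binding converts between the two through the central volume.
    """
    a1, a2, r, dr = y
    if not np.all(np.isfinite(y)):
        raise FloatingPointError(f"non-finite TMDD state at t={t}: {y}")
    c = a1 / p.v1
    transfer = p.q * (a1 / p.v1 - a2 / p.v2)
    binding = p.kon * c * r
    da1 = -p.kel * a1 - transfer - binding * p.v1 + p.koff * dr * p.v1
    da2 = transfer
    dr_free = p.ksyn - p.kdeg * r - binding + p.koff * dr
    ddr = binding - (p.koff + p.kint) * dr
    return np.array([da1, da2, dr_free, ddr])


def tmdd_jacobian(t: float, y: np.ndarray, p: TMDDParameters) -> np.ndarray:
    """Analytic Jacobian of :func:`tmdd_rhs`; the binding terms make the system stiff."""
    a1, _a2, r, _dr = y
    c = a1 / p.v1
    j = np.zeros((4, 4))
    # dA1/dt row
    j[0, 0] = -p.kel - p.q / p.v1 - p.kon * r
    j[0, 1] = p.q / p.v2
    j[0, 2] = -p.kon * a1
    j[0, 3] = p.koff * p.v1
    # dA2/dt row
    j[1, 0] = p.q / p.v1
    j[1, 1] = -p.q / p.v2
    # dR/dt row
    j[2, 0] = -p.kon * r / p.v1
    j[2, 2] = -p.kdeg - p.kon * c
    j[2, 3] = p.koff
    # dDR/dt row
    j[3, 0] = p.kon * r / p.v1
    j[3, 2] = p.kon * c
    j[3, 3] = -(p.koff + p.kint)
    return j


def mm_rhs(t: float, y: np.ndarray, p: MMParameters) -> np.ndarray:
    """Right-hand side of the Michaelis-Menten approximation, d/dt of ``[A1, A2]``."""
    a1, a2 = y
    if not np.all(np.isfinite(y)):
        raise FloatingPointError(f"non-finite MM state at t={t}: {y}")
    c = a1 / p.v1
    transfer = p.q * (a1 / p.v1 - a2 / p.v2)
    da1 = -p.kel * a1 - transfer - p.vmax * c / (p.km + c) * p.v1
    da2 = transfer
    return np.array([da1, da2])


def steady_state_target(p: TMDDParameters) -> float:
    """Pre-dose free target concentration ``R0 = ksyn / kdeg`` (nmol/l)."""
    if p.kdeg <= 0.0:
        raise ValueError("steady-state target requires kdeg > 0")
    return p.ksyn / p.kdeg


def mm_from_micro(p: TMDDParameters) -> MMParameters:
    """Quasi-steady-state reduction of the micro-parameterization.

    ``Vmax = kint * R0`` and ``Km = (koff + kint) / kon``; disposition
    parameters carry over unchanged.  Because ``Vmax`` depends on the
    subject's ``R0``, the reduction must be applied after any scaling or
    target-level policy has been applied to the micro parameters.
    """
    if p.kon <= 0.0:
        raise ValueError("the quasi-steady-state reduction requires kon > 0")
    r0 = steady_state_target(p)
    return MMParameters(
        kel=p.kel,
        vmax=p.kint * r0,
        km=(p.koff + p.kint) / p.kon,
        v1=p.v1,
        v2=p.v2,
        q=p.q,
    )


def occupancy(r, dr):
    """Target occupancy ``DR / (R + DR)``, elementwise.

    Returns NaN where total target ``R + DR`` is zero (the ratio is undefined;
    this only arises in synthesis-free edge cases).
    """
    r = np.asarray(r, dtype=float)
    dr = np.asarray(dr, dtype=float)
    if np.any(r < 0) or np.any(dr < 0):
        raise ValueError("occupancy requires non-negative R and DR")
    total = r + dr
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0.0, dr / np.where(total > 0.0, total, 1.0), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def cl_total_model(c, p: TMDDParameters):
    """Model-predicted total clearance at free drug concentration ``c``.

    Decomposes total clearance into the linear catabolic part and a
    concentration-dependent target-mediated part,

    ``CL_TOT(C) = kel*V1 + kint * R0 * V1 / (Km + C)``

    with total target held at its baseline ``R0`` (the same assumption as the
    Michaelis-Menten reduction).  The nonlinear part saturates away as C grows
    large, recovering the linear clearance, and is maximal as C -> 0.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    km = (p.koff + p.kint) / p.kon
    out = p.kel * p.v1 + p.kint * steady_state_target(p) * p.v1 / (km + c)
    if out.ndim == 0:
        return float(out)
    return out


def linear_disposition_profile(
    dose: float, kel: float, v1: float, v2: float, q: float, times: np.ndarray
) -> np.ndarray:
    """Closed-form central concentration of the linear two-compartment IV-bolus model.

    Eigen-decomposition of the 2x2 amount system

    ``d/dt [A1, A2] = [[-kel - q/v1, q/v2], [q/v1, -q/v2]] [A1, A2]``

    with ``A1(0) = dose``, ``A2(0) = 0``.  This is the exact solution of the
    full TMDD model in the no-binding limit (``kon = 0``) and of the MM model
    with ``vmax = 0``; it serves as an analytic cross-check for the numerical
    integrator.  Its exact AUC from zero to infinity is ``dose / (kel * v1)``.
    """
    m = np.array([[-kel - q / v1, q / v2], [q / v1, -q / v2]])
    eigvals, eigvecs = np.linalg.eig(m)
    coef = np.linalg.solve(eigvecs, np.array([dose, 0.0]))
    times = np.asarray(times, dtype=float)
    a1 = (eigvecs[0, :] * coef) @ np.exp(np.outer(eigvals, times))
    return np.real(a1) / v1
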