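"""Allometric scaling from the 70-kg adult reference and dose/target construction.

Clearances scale with body weight to the 0.75 power and volumes linearly
(``Y = Y_adult * (BW / 70)^b``).  Binding micro-constants (``kon``, ``koff``,
``kint``) and target turnover (``kdeg``) are held age-invariant; the target
level itself is set by a policy that anchors either the target concentration
(same nmol/l in every age group) or the whole-body target amount (same nmol,
converted through an allometrically scaled plasma volume).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .model import TMDDParameters

__all__ = [
    "AGE_GROUP_WEIGHTS",
    "DEFAULT_MOLECULAR_WEIGHT",
    "Subject",
    "ScalingPolicy",
    "TargetPolicy",
    "DoseRegimen",
    "allometric_scale",
    "scale_parameters",
    "plasma_volume",
    "apply_target_policy",
    "target_amount_from_concentration",
    "build_regimen",
]

#: Mean body weights (kg) of the four canonical age groups (CDC growth charts).
AGE_GROUP_WEIGHTS: dict[str, float] = {
    "2y": 12.8,
    "6y": 21.3,
    "12y": 43.5,
    "18y": 66.1,
}

#: Default monoclonal antibody molecular weight (g/mol) for mg -> nmol conversion.
DEFAULT_MOLECULAR_WEIGHT = 150_000.0


@dataclass(frozen=True)
class Subject:
    """A simulated individual: an age-group label and a body weight in kg."""

    age_label: str
    bw: float

    def __post_init__(self) -> None:
        if self.bw <= 0:
            raise ValueError(f"body weight must be > 0 kg, got {self.bw!r}")

    @classmethod
    def from_age(cls, age_label: str) -> "Subject":
        """Subject at the canonical mean body weight of an age group."""
        try:
            return cls(age_label, AGE_GROUP_WEIGHTS[age_label])
        except KeyError:
            raise KeyError(
                f"unknown age label {age_label!r}; known: {sorted(AGE_GROUP_WEIGHTS)}"
            ) from None


@dataclass(frozen=True)
class ScalingPolicy:
    """Allometric exponents and adult reference anchors."""

    cl_exponent: float = 0.75
    v_exponent: float = 1.0
    reference_bw: float = 70.0
    reference_plasma_volume: float = 2.8

    def __post_init__(self) -> None:
        for name in ("cl_exponent", "v_exponent"):
            b = getattr(self, name)
            if not 0.0 < b < 2.0:
                raise ValueError(f"{name} must lie in (0, 2), got {b!r}")
        if self.reference_bw <= 0 or self.reference_plasma_volume <= 0:
            raise ValueError("reference body weight and plasma volume must be > 0")


@dataclass(frozen=True)
class TargetPolicy:
    """How the target level is carried from adults to children.

    ``same_concentration`` fixes the baseline target concentration ``R0``
    (nmol/l) across ages; ``same_amount`` fixes the whole-body target amount
    (nmol), so smaller children see a proportionally higher concentration.
    Exactly one anchor quantity must be supplied.
    """

    mode: str
    adult_r0: Optional[float] = None
    adult_amount: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode not in ("same_concentration", "same_amount"):
            raise ValueError(f"unknown target policy mode {self.mode!r}")
        if self.mode == "same_concentration":
            if self.adult_r0 is None or self.adult_amount is not None:
                raise ValueError("same_concentration requires adult_r0 only")
            if self.adult_r0 <= 0:
                raise ValueError("adult_r0 must be > 0")
        else:
            if self.adult_amount is None or self.adult_r0 is not None:
                raise ValueError("same_amount requires adult_amount only")
            if self.adult_amount <= 0:
                raise ValueError("adult_amount must be > 0")

    @property
    def level(self) -> float:
        """The anchor value (nmol/l or nmol depending on mode)."""
        return self.adult_r0 if self.mode == "same_concentration" else self.adult_amount


@dataclass(frozen=True)
class DoseRegimen:
    """A single IV bolus at time zero, carried in molar units with provenance.

    ``nominal`` is the prescribed dose in mg/kg (``mode='per_kg'``) or mg
    (``mode='fixed'``); ``molar_dose`` is the total administered amount in
    nmol for a given subject.
    """

    mode: str
    nominal: float
    molar_dose: float
    molecular_weight: float = DEFAULT_MOLECULAR_WEIGHT
    route: str = "iv_bolus"
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("per_kg", "fixed"):
            raise ValueError(f"unknown dose mode {self.mode!r}")
        if self.nominal < 0 or self.molar_dose < 0:
            raise ValueError("doses must be >= 0")
        if self.molecular_weight <= 0:
            raise ValueError("molecular weight must be > 0")


def allometric_scale(value_adult: float, bw: float, exponent: float, policy: ScalingPolicy) -> float:
    """Scale an adult parameter value to body weight ``bw``: ``value * (BW/ref)^b``."""
    if bw <= 0:
        raise ValueError("body weight must be > 0")
    return value_adult * (bw / policy.reference_bw) ** exponent


def scale_parameters(
    adult: TMDDParameters, subject: Subject, policy: ScalingPolicy
) -> TMDDParameters:
    """Allometric scaling of a full adult parameter set to one subject.

    Volumes scale with ``v_exponent``; linear clearance ``kel*V1`` and the
    distributional clearance ``Q`` scale with ``cl_exponent`` (``kel`` is then
    recomputed as scaled clearance over scaled volume).  Binding and turnover
    rate constants are cell-level quantities and are left unchanged, so the
    subject's baseline target concentration equals the adult's until a
    :class:`TargetPolicy` is applied.
    """
    v1 = allometric_scale(adult.v1, subject.bw, policy.v_exponent, policy)
    v2 = allometric_scale(adult.v2, subject.bw, policy.v_exponent, policy)
    cl = allometric_scale(adult.cl_linear, subject.bw, policy.cl_exponent, policy)
    q = allometric_scale(adult.q, subject.bw, policy.cl_exponent, policy)
    return adult.with_(v1=v1, v2=v2, q=q, kel=cl / v1)


def plasma_volume(bw: float, policy: ScalingPolicy) -> float:
    """Plasma volume (l) at body weight ``bw``, linear in BW from the adult anchor."""
    if bw <= 0:
        raise ValueError("body weight must be > 0")
    return policy.reference_plasma_volume * (bw / policy.reference_bw)


def apply_target_policy(
    params: TMDDParameters,
    subject: Subject,
    tpolicy: TargetPolicy,
    spolicy: ScalingPolicy,
) -> TMDDParameters:
    """Set the subject's baseline target level according to the policy.

    The policy fixes ``R0``; ``ksyn`` is then re-derived as ``R0 * kdeg`` so
    the drug-free system starts at steady state.  ``kdeg`` is age-invariant.
    """
    if tpolicy.mode == "same_concentration":
        r0 = tpolicy.adult_r0
    else:
        r0 = tpolicy.adult_amount / plasma_volume(subject.bw, spolicy)
    return params.with_(ksyn=r0 * params.kdeg)


def target_amount_from_concentration(r0: float, bw: float, spolicy: ScalingPolicy) -> float:
    """Whole-body target amount (nmol) equivalent to concentration ``r0`` at weight ``bw``."""
    if r0 < 0:
        raise ValueError("target concentration must be >= 0")
    return r0 * plasma_volume(bw, spolicy)


def build_regimen(
    nominal: float,
    mode: str,
    subject: Subject,
    molecular_weight: float = DEFAULT_MOLECULAR_WEIGHT,
) -> DoseRegimen:
    """Construct a single IV-bolus regimen in molar units.

    ``per_kg``: total nmol = mg/kg * BW * 1e6 / MW; ``fixed``: mg * 1e6 / MW.
    (1 mg = 1e-3 g = 1e6/MW nmol at molecular weight MW g/mol.)  A zero dose
    is admitted as a degenerate regimen (all-zero profile downstream).
    """
    if nominal < 0:
        raise ValueError("nominal dose must be >= 0")
    if mode == "per_kg":
        molar = nominal * subject.bw * 1e6 / molecular_weight
    elif mode == "fixed":
        molar = nominal * 1e6 / molecular_weight
    else:
        raise ValueError(f"unknown dose mode {mode!r}")
    return DoseRegimen(mode=mode, nominal=nominal, molar_dose=molar, molecular_weight=molecular_weight)
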