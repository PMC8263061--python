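"""Dependent-variable parametrisations of partner age and their Jacobians.

A reported partnership carries the respondent's age ``a`` (15-64 years),
the respondent's sex ``s`` (1 = female) and the partner's age ``p``. Four
outcome parametrisations of ``p`` are modelled:

==============  =====================  ==========================
name            forward y = f(p, a)    log |dy/dp|
==============  =====================  ==========================
linear_age      p                      0
age_difference  p - a                  0
log_age         log p                  -log p
log_ratio       log(p / a)             -log p
==============  =====================  ==========================

Two additional support transforms adapt partner age to restricted-domain
families: a horizontal reflection ``150 - p`` applied to male respondents'
reports so the gamma family (always right-skewed) can represent the
left-skew of men's partner ages, and a rescaling ``p / 150`` onto the
open unit interval for the beta family.

``density_on_age_scale`` converts a model's log-density of y into the
log-density of p itself by adding log |dy/dp|, which is what makes
ELPD comparable across outcome parametrisations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "PartnershipRecord",
    "OutcomeSpec",
    "SupportTransform",
    "OUTCOMES",
    "SUPPORT_TRANSFORMS",
    "get_outcome",
    "get_support_transform",
    "transform_outcome",
    "density_on_age_scale",
    "apply_support_transform",
]


@dataclass(frozen=True)
class PartnershipRecord:
    """One reported partnership: respondent age/sex and partner age."""

    respondent_age: float
    respondent_sex: int
    partner_age: float

    def __post_init__(self) -> None:
        if not 15 <= self.respondent_age <= 64:
            raise ValueError("respondent age must be in [15, 64]")
        if self.respondent_sex not in (0, 1):
            raise ValueError("respondent sex must be 0 (male) or 1 (female)")
        if self.partner_age <= 0:
            raise ValueError("partner age must be positive")


@dataclass(frozen=True)
class OutcomeSpec:
    """An outcome parametrisation with its inverse and log-Jacobian."""

    name: str
    forward: Callable
    inverse: Callable
    log_jacobian: Callable  # log |dy/dp| as a function of (p, a)


def _requires_positive(p):
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0):
        raise ValueError("partner age must be positive under log transforms")
    return p


OUTCOMES = {
    "linear_age": OutcomeSpec(
        "linear_age",
        forward=lambda p, a: np.asarray(p, dtype=float),
        inverse=lambda y, a: np.asarray(y, dtype=float),
        log_jacobian=lambda p, a: np.zeros_like(np.asarray(p, dtype=float)),
    ),
    "age_difference": OutcomeSpec(
        "age_difference",
        forward=lambda p, a: np.asarray(p, dtype=float) - a,
        inverse=lambda y, a: np.asarray(y, dtype=float) + a,
        log_jacobian=lambda p, a: np.zeros_like(np.asarray(p, dtype=float)),
    ),
    "log_age": OutcomeSpec(
        "log_age",
        forward=lambda p, a: np.log(_requires_positive(p)),
        inverse=lambda y, a: np.exp(np.asarray(y, dtype=float)),
        log_jacobian=lambda p, a: -np.log(_requires_positive(p)),
    ),
    "log_ratio": OutcomeSpec(
        "log_ratio",
        forward=lambda p, a: np.log(_requires_positive(p) / a),
        inverse=lambda y, a: a * np.exp(np.asarray(y, dtype=float)),
        log_jacobian=lambda p, a: -np.log(_requires_positive(p)),
    ),
}


@dataclass(frozen=True)
class SupportTransform:
    """Maps partner age onto a restricted family's support.

    ``forward``/``inverse``/``log_jacobian`` take (value, sex) so the
    male-only gamma reflection can condition on respondent sex.
    """

    name: str
    forward: Callable
    inverse: Callable
    log_jacobian: Callable


_UPPER_BOUND = 150.0


def _gamma_reflect(p, sex):
    # male respondents (s=0) report younger partners: reflect to right-skew
    p = np.asarray(p, dtype=float)
    sex = np.asarray(sex)
    return np.where(sex == 0, _UPPER_BOUND - p, p)


def _beta_scale(p, sex):
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= _UPPER_BOUND)):
        raise ValueError("beta scaling requires 0 < p < 150")
    return p / _UPPER_BOUND


SUPPORT_TRANSFORMS = {
    "identity": SupportTransform(
        "identity",
        forward=lambda p, sex: np.asarray(p, dtype=float),
        inverse=lambda x, sex: np.asarray(x, dtype=float),
        log_jacobian=lambda p, sex: np.zeros_like(np.asarray(p, dtype=float)),
    ),
    "gamma_male_reflection": SupportTransform(
        "gamma_male_reflection",
        forward=_gamma_reflect,
        inverse=_gamma_reflect,  # the reflection is an involution
        log_jacobian=lambda p, sex: np.zeros_like(np.asarray(p, dtype=float)),
    ),
    "beta_unit_scaling": SupportTransform(
        "beta_unit_scaling",
        forward=_beta_scale,
        inverse=lambda x, sex: np.asarray(x, dtype=float) * _UPPER_BOUND,
        log_jacobian=lambda p, sex: np.full_like(
            np.asarray(p, dtype=float), -np.log(_UPPER_BOUND)
        ),
    ),
}


def get_outcome(name) -> OutcomeSpec:
    if isinstance(name, OutcomeSpec):
        return name
    try:
        return OUTCOMES[name]
    except KeyError:
        raise ValueError(f"unknown outcome {name!r}") from None


def get_support_transform(name) -> SupportTransform:
    if isinstance(name, SupportTransform):
        return name
    try:
        return SUPPORT_TRANSFORMS[name]
    except KeyError:
        raise ValueError(f"unknown support transform {name!r}") from None


def transform_outcome(rec: PartnershipRecord, spec) -> float:
    """Evaluate y = f(p, a) for one record."""
    spec = get_outcome(spec)
    return float(spec.forward(rec.partner_age, rec.respondent_age))


def density_on_age_scale(logpdf_y, rec_or_p, spec, respondent_age=None):
    """Convert a log-density of y into the log-density of partner age p.

    Adds log |dy/dp|: for the log transforms this subtracts log p; the
    linear transforms have unit Jacobian and pass through unchanged.
    Accepts either a PartnershipRecord or (p, a) arrays.
    """
    spec = get_outcome(spec)
    if isinstance(rec_or_p, PartnershipRecord):
        p, a = rec_or_p.partner_age, rec_or_p.respondent_age
    else:
        p, a = rec_or_p, respondent_age
    return np.asarray(logpdf_y, dtype=float) + spec.log_jacobian(p, a)


def apply_support_transform(p, sex, transform):
    """Map partner age onto a restricted family's support (see module doc)."""
    t = get_support_transform(transform)
    return t.forward(p, sex)
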