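"""Closed-form linear-quadratic (LQ) radiobiology for combined-modality dosing.

Two irradiation regimes are covered:

* fractionated low-LET external beam radiotherapy (EBRT), where the
  biologically effective dose is ``BED = D (1 + d / (alpha/beta))`` with
  ``d = D / n_f`` the dose per fraction; and
* continuous, exponentially decaying irradiation by a high-LET alpha-emitter
  mixture (the Ra-223 decay chain), using the permanent-implant
  (brachytherapy) form of the LQ model generalised to a mixture of
  radionuclides sharing a single effective decay constant, with the alpha
  linear term weighted by the low-dose-limit relative biological
  effectiveness ``RBE_max``.

Both BEDs convert to EQD2 (the equieffective dose in 2 Gy fractions) by
dividing by ``1 + d_ref/(alpha/beta)``.

All doses are in Gy at the API boundary; per-nuclide dose coefficients are
mGy/MBq (converted internally), rates in h^-1, activities in MBq.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "LQParameters",
    "EBRTSchedule",
    "RNDoseModel",
    "bed_ebrt",
    "eqd2_from_bed",
    "rbe_max",
    "dose_rate",
    "bed_rn",
    "bed_rn_double_loop",
    "eqd2_rn",
    "residence_time",
    "effective_half_life",
    "decay_constant_from_half_life",
    "round_half_up",
    "RA223_PHYSICAL_HALF_LIFE_H",
    "RA223_DECAY_CONSTANT_H",
]

#: Physical half-life of Ra-223, hours (11.43 days).
RA223_PHYSICAL_HALF_LIFE_H = 11.43 * 24.0

#: Physical decay constant of Ra-223, h^-1. Used as the default effective
#: rate when no patient-specific kinetics are supplied.
RA223_DECAY_CONSTANT_H = math.log(2.0) / RA223_PHYSICAL_HALF_LIFE_H


class ParameterDomainError(ValueError):
    """A radiobiological parameter or input is outside its physical domain."""


@dataclass(frozen=True)
class LQParameters:
    """Radiobiological constants of the LQ model.

    Parameters
    ----------
    alpha_beta : float
        alpha/beta ratio in Gy (fractionation sensitivity). Default 10 Gy,
        appropriate for tumours and acute effects.
    mu : float
        First-order sublethal-damage repair rate constant, h^-1.
    rbe_exp : float
        Experimental RBE of the alpha component relative to low-LET
        reference radiation (dimensionless).
    rbe_photon : float
        RBE assigned to photon/electron (gamma/beta) emissions. Default 1.
    d_ref : float
        Reference dose per fraction for EQD2 conversion, Gy. Default 2.
    """

    alpha_beta: float = 10.0
    mu: float = 1.4
    rbe_exp: float = 5.0
    rbe_photon: float = 1.0
    d_ref: float = 2.0

    def __post_init__(self) -> None:
        if self.alpha_beta <= 0:
            raise ParameterDomainError(f"alpha_beta must be > 0, got {self.alpha_beta}")
        if self.mu <= 0:
            raise ParameterDomainError(f"mu must be > 0, got {self.mu}")
        if self.rbe_exp < 1:
            raise ParameterDomainError(f"rbe_exp must be >= 1, got {self.rbe_exp}")
        if self.d_ref <= 0:
            raise ParameterDomainError(f"d_ref must be > 0, got {self.d_ref}")


@dataclass(frozen=True)
class EBRTSchedule:
    """A fractionated EBRT prescription: total dose D in n_f fractions."""

    total_dose: float
    n_fractions: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.total_dose < 0:
            raise ParameterDomainError(f"total_dose must be >= 0, got {self.total_dose}")
        if self.n_fractions < 1:
            raise ParameterDomainError(f"n_fractions must be >= 1, got {self.n_fractions}")

    @property
    def dose_per_fraction(self) -> float:
        return self.total_dose / self.n_fractions


@dataclass(frozen=True)
class RNDoseModel:
    """Dose model for one radionuclide-therapy course.

    Parameters
    ----------
    dose_coefficients : mapping
        Per-nuclide mean absorbed dose per unit injected activity, mGy/MBq.
        Keys are nuclide names (e.g. ``"Ra-223"``).
    decay_constant : float
        Effective clearance rate lambda shared by parent and daughters, h^-1.
    injected_activity : float
        Injected activity per cycle, MBq.
    n_cycles : int
        Number of therapy cycles.
    """

    dose_coefficients: Mapping[str, float]
    decay_constant: float = RA223_DECAY_CONSTANT_H
    injected_activity: float = 0.0
    n_cycles: int = 1

    def __post_init__(self) -> None:
        for name, c in self.dose_coefficients.items():
            if c < 0:
                raise ParameterDomainError(f"dose coefficient for {name} is negative: {c}")
        if self.decay_constant <= 0:
            raise ParameterDomainError(
                f"decay_constant must be > 0, got {self.decay_constant}"
            )
        if self.injected_activity < 0:
            raise ParameterDomainError(
                f"injected_activity must be >= 0, got {self.injected_activity}"
            )
        if self.n_cycles < 0:
            raise ParameterDomainError(f"n_cycles must be >= 0, got {self.n_cycles}")

    @property
    def total_dose_per_cycle_gy(self) -> float:
        """Total physical absorbed dose per cycle over the chain, Gy."""
        return sum(self.dose_coefficients.values()) * self.injected_activity / 1000.0


def bed_ebrt(schedule: EBRTSchedule, params: LQParameters) -> float:
    """BED of a fractionated EBRT schedule: ``D (1 + (D/n_f)/(alpha/beta))``."""
    d = schedule.dose_per_fraction
    return schedule.total_dose * (1.0 + d / params.alpha_beta)


def eqd2_from_bed(bed: float, params: LQParameters) -> float:
    """Convert a BED to EQD2: ``BED / (1 + d_ref/(alpha/beta))``."""
    if bed < 0:
        raise ParameterDomainError(f"bed must be >= 0, got {bed}")
    return bed / (1.0 + params.d_ref / params.alpha_beta)


def rbe_max(params: LQParameters) -> float:
    """Low-dose-limit RBE weighting the alpha linear term.

    ``RBE_max = RBE_exp + d/(alpha/beta) * (RBE_exp^2 - 1)/RBE_exp`` with d
    the reference dose per fraction. With RBE_exp = 5, d = 2 Gy and
    alpha/beta = 10 Gy this evaluates to 5.96.
    """
    if params.rbe_exp == 0:
        raise ParameterDomainError("rbe_exp must be nonzero")
    r = params.rbe_exp
    return r + (params.d_ref / params.alpha_beta) * (r * r - 1.0) / r


def dose_rate(dose_coefficient: float, injected_activity: float, decay_constant: float) -> float:
    """Initial dose rate of one nuclide, mGy/h.

    ``R_i = D_i [mGy/MBq] * A_inj [MBq] * lambda [1/h]`` — the rate at t=0
    of an exponentially decaying delivery whose time-integral is D_i * A_inj.
    """
    if dose_coefficient < 0 or injected_activity < 0 or decay_constant < 0:
        raise ParameterDomainError("dose_rate arguments must all be >= 0")
    return dose_coefficient * injected_activity * decay_constant


def _rbe_weighted_linear_dose(
    model: RNDoseModel,
    params: LQParameters,
    emission_by_nuclide: Mapping[str, str] | None,
) -> float:
    """Linear-term dose (Gy) with per-emission RBE weighting.

    By default every nuclide is weighted by RBE_max (the chain's dose is
    alpha-dominated). When an emission map is supplied, beta/gamma emitters
    are weighted by ``rbe_photon`` instead.
    """
    rmax = rbe_max(params)
    a = model.injected_activity / 1000.0  # mGy -> Gy
    total = 0.0
    for name, coeff in model.dose_coefficients.items():
        if emission_by_nuclide is not None and emission_by_nuclide.get(name) in ("beta", "gamma"):
            total += params.rbe_photon * coeff * a
        else:
            total += rmax * coeff * a
    return total


def bed_rn(
    model: RNDoseModel,
    params: LQParameters,
    emission_by_nuclide: Mapping[str, str] | None = None,
) -> float:
    """BED of the decaying alpha-mixture course, Gy.

    Closed form of the permanent-implant mixture BED with a single shared
    effective decay constant:

        BED = n_c [ RBE_max * D_tot + lambda * D_tot^2 / ((alpha/beta)(mu+lambda)) ]

    where ``D_tot = sum_i D_i * A_inj`` is the total physical dose per cycle.
    The mixture double sum ``sum_i sum_j R_i R_j`` collapses to
    ``(sum_i R_i)^2``; :func:`bed_rn_double_loop` keeps the explicit loops.
    Exactly linear in ``n_cycles``.

    When ``emission_by_nuclide`` is given, photon/electron emitters enter
    the linear term with weight ``rbe_photon`` instead of RBE_max.
    """
    if not model.dose_coefficients or all(
        c == 0 for c in model.dose_coefficients.values()
    ):
        if model.n_cycles > 0 and not model.dose_coefficients:
            warnings.warn("empty decay chain: BED_RN is 0", stacklevel=2)
        return 0.0
    d_tot = model.total_dose_per_cycle_gy
    lam = model.decay_constant
    linear = _rbe_weighted_linear_dose(model, params, emission_by_nuclide)
    quad = lam * d_tot * d_tot / (params.alpha_beta * (params.mu + lam))
    return model.n_cycles * (linear + quad)


def bed_rn_double_loop(model: RNDoseModel, params: LQParameters) -> float:
    """BED_RN evaluated with the explicit nested mixture double sum.

    Reference implementation of

        BED = n_c (1/lambda sum_i R_i) { RBE_max
              + sum_i sum_j R_i R_j / ((alpha/beta)(mu+lambda) sum_i R_i) }

    kept alongside the closed form so the algebraic identity
    ``sum_i sum_j R_i R_j = (sum_i R_i)^2`` is testable, not assumed.
    """
    lam = model.decay_constant
    rates = [
        dose_rate(c / 1000.0, model.injected_activity, lam)  # Gy/h
        for c in model.dose_coefficients.values()
    ]
    r_sum = sum(rates)
    if r_sum == 0.0:
        return 0.0
    double = 0.0
    for ri in rates:
        for rj in rates:
            double += ri * rj
    brace = rbe_max(params) + double / (
        params.alpha_beta * (params.mu + lam) * r_sum
    )
    return model.n_cycles * (r_sum / lam) * brace


def eqd2_rn(
    model: RNDoseModel,
    params: LQParameters,
    emission_by_nuclide: Mapping[str, str] | None = None,
) -> float:
    """EQD2 of the radionuclide course: ``BED_RN / (1 + d_ref/(alpha/beta))``."""
    return eqd2_from_bed(bed_rn(model, params, emission_by_nuclide), params)


def residence_time(uptake_fraction: float, decay_constant: float) -> float:
    """Residence time tau (h) under single-phase (mono-exponential) kinetics.

    tau = uptake_fraction / lambda: the time-integrated activity in the
    source region per unit injected activity, assuming instantaneous uptake
    of the given fraction followed by clearance at the effective rate.
    """
    if not 0.0 <= uptake_fraction <= 1.0:
        raise ParameterDomainError(
            f"uptake_fraction must be in [0, 1], got {uptake_fraction}"
        )
    if decay_constant <= 0:
        raise ParameterDomainError(f"decay_constant must be > 0, got {decay_constant}")
    return uptake_fraction / decay_constant


def effective_half_life(decay_constant: float) -> float:
    """Half-life (h) corresponding to a rate constant (h^-1)."""
    if decay_constant <= 0:
        raise ParameterDomainError(f"decay_constant must be > 0, got {decay_constant}")
    return math.log(2.0) / decay_constant


def decay_constant_from_half_life(half_life_h: float) -> float:
    """Rate constant (h^-1) corresponding to a half-life (h)."""
    if half_life_h <= 0:
        raise ParameterDomainError(f"half_life must be > 0, got {half_life_h}")
    return math.log(2.0) / half_life_h


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, the convention of printed dose tables."""
    factor = 10.0 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)
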