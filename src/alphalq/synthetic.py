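"""Synthetic inputs for the whole pipeline: lesions, doses, outcomes.

Three generators cover the data the published pipeline consumed but never
deposited:

* a lesion-level dosimetry set emulating the planar-image MIRD evaluation
  of 24 bone-metastasis lesions in 9 patients that the virtual cohort was
  derived from: absorbed dose per unit injected activity falls
  exponentially with lesion mass, ``a * exp(-b * mass)``, with
  multiplicative lognormal noise;
* the inverse operation, a nonlinear least-squares refit of the
  exponential dose-mass curve; and
* arm-level binomial outcomes drawn from a known logistic dose-response,
  for parameter-recovery experiments on the outcome models.

Every generator is a pure function of its parameters and seed. Default
curve parameters are placeholders with realistic orders of magnitude —
the source lesion table was never published.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, special

from .cohort import DoseSummary
from .outcomes import OutcomeDataset
from .radiobio import RA223_DECAY_CONSTANT_H, residence_time

__all__ = [
    "LesionRecord",
    "SyntheticTruth",
    "DoseMassFit",
    "generate_lesion_set",
    "fit_dose_mass_curve",
    "simulate_cohort_outcomes",
]


@dataclass(frozen=True)
class LesionRecord:
    """One lesion's dosimetry: mass (g), dose coefficient (Gy/MBq), tau (h)."""

    patient_id: str
    lesion_id: str
    mass: float
    dose_per_activity: float
    residence_time: float

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.dose_per_activity <= 0 or self.residence_time < 0:
            raise ValueError(f"invalid lesion record: {self}")


@dataclass(frozen=True)
class SyntheticTruth:
    """A known logistic dose-response used to generate outcomes."""

    intercept: float
    slope: float
    seed: int


@dataclass(frozen=True)
class DoseMassFit:
    a: float
    b: float
    residual_sd_log: float
    n_records: int


def generate_lesion_set(
    n_patients: int = 9,
    n_lesions: int = 24,
    mass_range: tuple[float, float] = (1.0, 60.0),
    curve_params: tuple[float, float] = (2.0, 0.05),
    noise_cv: float = 0.2,
    seed: int = 0,
    uptake_fraction: float = 0.5,
    decay_constant: float = RA223_DECAY_CONSTANT_H,
) -> list[LesionRecord]:
    """Draw a lesion-level dosimetry set.

    Masses are log-uniform over ``mass_range`` (g); the dose coefficient is
    ``a * exp(-b * mass)`` (Gy/MBq) times lognormal noise with coefficient
    of variation ``noise_cv``; lesions are dealt round-robin over patients
    (every patient gets at least one). Residence time is the single-phase
    value ``uptake_fraction / decay_constant``, shared across lesions.
    """
    if n_patients <= 0 or n_lesions <= 0:
        raise ValueError("counts must be positive")
    if n_lesions < n_patients:
        raise ValueError(f"n_lesions ({n_lesions}) < n_patients ({n_patients})")
    a, b = curve_params
    if a <= 0 or b <= 0:
        raise ValueError("curve parameters must be positive")
    if not 0.0 <= noise_cv < 1.0:
        raise ValueError(f"noise_cv must be in [0, 1), got {noise_cv}")
    lo, hi = mass_range
    if not 0 < lo < hi:
        raise ValueError(f"invalid mass_range {mass_range}")
    rng = np.random.default_rng(seed)
    masses = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_lesions))
    sigma = np.sqrt(np.log1p(noise_cv**2))
    noise = np.exp(rng.normal(0.0, sigma, size=n_lesions)) if noise_cv > 0 else np.ones(n_lesions)
    tau = residence_time(uptake_fraction, decay_constant)
    return [
        LesionRecord(
            patient_id=f"P{(i % n_patients) + 1:02d}",
            lesion_id=f"L{i + 1:02d}",
            mass=float(m),
            dose_per_activity=float(a * np.exp(-b * m) * w),
            residence_time=tau,
        )
        for i, (m, w) in enumerate(zip(masses, noise))
    ]


def fit_dose_mass_curve(records: Sequence[LesionRecord]) -> DoseMassFit:
    """Nonlinear least-squares fit of ``dose = a * exp(-b * mass)``.

    Started from the log-linear regression estimate; residual summary is
    the SD of log-residuals (the noise model is multiplicative).
    """
    if len(records) < 3:
        raise ValueError(f"need at least 3 records, got {len(records)}")
    m = np.array([r.mass for r in records])
    d = np.array([r.dose_per_activity for r in records])
    if np.ptp(m) == 0:
        raise ValueError("degenerate masses: all lesions have the same mass")
    # log-linear start: log d = log a - b m
    slope, logint = np.polyfit(m, np.log(d), 1)
    p0 = (float(np.exp(logint)), float(max(-slope, 1e-6)))
    popt, _ = optimize.curve_fit(
        lambda x, a, b: a * np.exp(-b * x), m, d, p0=p0, maxfev=20000
    )
    a, b = float(popt[0]), float(popt[1])
    resid = np.log(d) - np.log(a * np.exp(-b * m))
    return DoseMassFit(a=a, b=b, residual_sd_log=float(np.std(resid, ddof=2)), n_records=len(records))


def simulate_cohort_outcomes(
    truth: SyntheticTruth,
    dose_table: Sequence[DoseSummary],
    n_per_arm: Sequence[int] | None = None,
    endpoint: str = "os_2y",
) -> OutcomeDataset:
    """Draw per-arm binomial outcomes from a known logistic truth.

    ``events_i ~ Binomial(n_i, expit(b0 + b1 * EQD2_TOT_i))`` independently
    per arm, deterministic given ``truth.seed``.
    """
    if n_per_arm is None:
        n_per_arm = [s.n_patients for s in dose_table]
    if len(n_per_arm) != len(dose_table):
        raise ValueError("n_per_arm length does not match dose table")
    if any(n <= 0 for n in n_per_arm):
        raise ValueError("n_per_arm must be positive")
    doses = np.array([s.eqd2_tot for s in dose_table])
    if not np.isfinite(doses).all():
        raise ValueError("non-finite dose in table")
    rng = np.random.default_rng(truth.seed)
    p = special.expit(truth.intercept + truth.slope * doses)
    events = rng.binomial(list(n_per_arm), p)
    return OutcomeDataset(
        study_ids=tuple(s.study_id for s in dose_table),
        doses=tuple(float(x) for x in doses),
        events=tuple(int(e) for e in events),
        n=tuple(int(n) for n in n_per_arm),
        endpoint=endpoint,
    )
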