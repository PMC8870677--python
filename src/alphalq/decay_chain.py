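"""Registry of the Ra-223 decay chain with emission metadata.

Ra-223 decays through six short-lived daughters (Rn-219, Po-215, Pb-211,
Bi-211, Po-211, Tl-207) to stable Pb-207. Because every daughter half-life
is minutes or less against the 11.43-day parent, the chain is treated in
secular equilibrium: one effective decay constant and one residence time,
taken from the parent, apply to all members. The rare Po-215 beta branch
(branching ratio < 0.001%) is dropped and full alpha decay to Pb-211 is
assumed; the omission is recorded on the chain object so reports can state
it.

No Bateman solver is provided — under the equilibrium assumption the
mixture BED needs only the per-nuclide dose coefficients and the shared
rate, aggregated by :func:`total_initial_dose_rate`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

from .radiobio import dose_rate

__all__ = [
    "Nuclide",
    "DecayChain",
    "ChainConfigurationError",
    "default_chain",
    "total_initial_dose_rate",
]


class ChainConfigurationError(ValueError):
    """A coefficient map or chain definition is inconsistent."""


@dataclass(frozen=True)
class Nuclide:
    name: str
    primary_emission: str  # "alpha" | "beta" | "gamma"
    notes: str = ""

    def __post_init__(self) -> None:
        if self.primary_emission not in ("alpha", "beta", "gamma"):
            raise ChainConfigurationError(
                f"unknown emission type {self.primary_emission!r} for {self.name}"
            )


@dataclass(frozen=True)
class DecayChain:
    """An ordered set of nuclides plus any decay branches excluded from dose."""

    nuclides: tuple[Nuclide, ...]
    omitted_branches: tuple[tuple[str, str, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [n.name for n in self.nuclides]
        if len(names) != len(set(names)):
            raise ChainConfigurationError(f"duplicate nuclide names in chain: {names}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.nuclides)

    def emission_map(self) -> dict[str, str]:
        """Nuclide name -> primary emission type, for RBE weighting."""
        return {n.name: n.primary_emission for n in self.nuclides}

    def to_json(self) -> str:
        return json.dumps(
            {
                "nuclides": [
                    {"name": n.name, "primary_emission": n.primary_emission, "notes": n.notes}
                    for n in self.nuclides
                ],
                "omitted_branches": [list(b) for b in self.omitted_branches],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "DecayChain":
        obj = json.loads(text)
        return cls(
            nuclides=tuple(
                Nuclide(d["name"], d["primary_emission"], d.get("notes", ""))
                for d in obj["nuclides"]
            ),
            omitted_branches=tuple(tuple(b) for b in obj.get("omitted_branches", [])),
        )


def default_chain() -> DecayChain:
    """The seven-member Ra-223 chain used for mixture dosimetry."""
    return DecayChain(
        nuclides=(
            Nuclide("Ra-223", "alpha", "parent, T1/2 = 11.43 d"),
            Nuclide("Rn-219", "alpha", "T1/2 = 3.96 s"),
            Nuclide("Po-215", "alpha", "T1/2 = 1.78 ms"),
            Nuclide("Pb-211", "beta", "T1/2 = 36.1 min"),
            Nuclide("Bi-211", "alpha", "T1/2 = 2.14 min"),
            Nuclide("Po-211", "alpha", "T1/2 = 0.52 s; 0.28% branch of Bi-211"),
            Nuclide("Tl-207", "beta", "T1/2 = 4.77 min"),
        ),
        omitted_branches=(
            (
                "Po-215",
                "beta",
                "branching ratio < 0.001%; full alpha decay to Pb-211 assumed",
            ),
        ),
    )


def total_initial_dose_rate(
    chain: DecayChain,
    coefficients: Mapping[str, float],
    injected_activity: float,
    decay_constant: float,
) -> float:
    """Summed initial dose rate over the chain, mGy/h.

    ``sum_i D_i * A_inj * lambda`` over the supplied per-nuclide dose
    coefficients (mGy/MBq). Nuclides without a coefficient contribute zero;
    a coefficient for a nuclide outside the chain is a configuration error.
    """
    unknown = set(coefficients) - set(chain.names)
    if unknown:
        raise ChainConfigurationError(
            f"coefficients given for nuclides not in chain: {sorted(unknown)}"
        )
    return sum(
        dose_rate(c, injected_activity, decay_constant) for c in coefficients.values()
    )
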