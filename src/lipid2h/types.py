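"""Shared domain types for the lipid ²H/¹H reduction pipeline.

Delta notation convention: all user-facing δ²H values are in permil (‰)
relative to a named reference; all chained isotope arithmetic inside the
package happens on the dimensionless fractional deviation (δ/1000), which
keeps the multiplicative α algebra exact.  Conversion happens only at the
boundaries of each operation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence


class DomainError(ValueError):
    """A value outside the physical domain of an isotope or growth quantity."""


def permil_to_fraction(value_permil: float) -> float:
    """Convert a δ value in ‰ to a dimensionless ratio deviation.

    Raises
    ------
    DomainError
        If ``value_permil`` ≤ −1000‰ (the isotope ratio would be ≤ 0).
    """
    if value_permil <= -1000.0:
        raise DomainError(
            f"delta value {value_permil}‰ implies a non-positive isotope ratio"
        )
    return value_permil / 1000.0


def fraction_to_permil(fraction: float) -> float:
    """Inverse of :func:`permil_to_fraction` (exact to floating precision)."""
    return fraction * 1000.0


class Strain(str, Enum):
    WILD_TYPE = "wild-type"
    NFNA2 = "nfnA-2"
    NFNB2 = "nfnB-2"


class Donor(str, Enum):
    PYRUVATE = "pyruvate"
    MALATE = "malate"
    FUMARATE = "fumarate"
    LACTATE = "lactate"


class InjectionRole(str, Enum):
    SAMPLE = "sample"
    FAME_MIX_STANDARD = "fame_mix_standard"
    ALKANE_LADDER = "alkane_ladder"


@dataclass(frozen=True)
class DeltaValue:
    """A δ²H value in ‰ versus a named reference, with uncertainty.

    Parameters
    ----------
    value : float
        δ²H in ‰ relative to ``reference``.  Must exceed −1000‰.
    reference : str
        Name of the reference frame, e.g. ``"V-SMOW"``, ``"coinjected-ref"``
        or ``"media-water"``.
    sem : float
        Standard error of the mean, in ‰ (≥ 0).
    n : int
        Number of replicate measurements contributing (≥ 1).
    """

    value: float
    reference: str = "V-SMOW"
    sem: float = 0.0
    n: int = 1

    def __post_init__(self) -> None:
        if not math.isfinite(self.value) or self.value <= -1000.0:
            raise DomainError(f"delta value must be finite and > -1000‰, got {self.value}")
        if self.sem < 0:
            raise DomainError(f"sem must be >= 0, got {self.sem}")
        if self.n < 1:
            raise DomainError(f"replicate count must be >= 1, got {self.n}")

    @property
    def fraction(self) -> float:
        """The value as a dimensionless ratio deviation (δ/1000)."""
        return self.value / 1000.0

    @property
    def sem_fraction(self) -> float:
        return self.sem / 1000.0

    def with_reference(self, reference: str) -> "DeltaValue":
        return replace(self, reference=reference)


@dataclass(frozen=True, order=True)
class SampleCondition:
    """One experimental cell: strain × electron donor × sulfate level.

    ``sulfate_mM == 0`` denotes fermentative growth (donor alone); the
    respiration experiments used 40 mM sulfate.
    """

    strain: Strain
    donor: Donor
    sulfate_mM: float
    bio_replicate: int = 1

    def __post_init__(self) -> None:
        if self.sulfate_mM < 0:
            raise DomainError("sulfate concentration cannot be negative")
        if self.bio_replicate < 1:
            raise DomainError("biological replicate index starts at 1")

    @property
    def treatment(self) -> str:
        """Human-readable treatment label, e.g. ``"malate/sulfate"``."""
        if self.sulfate_mM > 0:
            return f"{self.donor.value}/sulfate"
        return f"{self.donor.value} fermentation"

    def cell_key(self) -> tuple:
        """(strain, donor, sulfate) key identifying the cell, ignoring replicate."""
        return (self.strain.value, self.donor.value, self.sulfate_mM)


#: The five donor × sulfate treatments of the study design.
STUDY_TREATMENTS: tuple[tuple[Donor, float], ...] = (
    (Donor.PYRUVATE, 40.0),
    (Donor.MALATE, 40.0),
    (Donor.FUMARATE, 40.0),
    (Donor.FUMARATE, 0.0),
    (Donor.PYRUVATE, 0.0),
)

#: All 15 strain × treatment cells.
STUDY_CELLS: tuple[tuple[Strain, Donor, float], ...] = tuple(
    (s, d, so) for d, so in STUDY_TREATMENTS for s in Strain
)


@dataclass
class PeakRecord:
    """One chromatographic peak in one injection."""

    compound_label: str
    retention_time: float
    area: float
    raw_delta: Optional[DeltaValue] = None
    amplitude: Optional[float] = None

    def __post_init__(self) -> None:
        if self.retention_time <= 0:
            raise DomainError(f"retention time must be positive, got {self.retention_time}")
        if self.area < 0:
            raise DomainError(f"peak area cannot be negative, got {self.area}")


@dataclass
class Injection:
    """One chromatographic run: a role-tagged, run-ordered set of peaks.

    ``h3_factor`` is the instrument H₃⁺ correction coefficient (ppm/nA); it is
    carried as metadata only — input δ values are taken as already corrected.
    """

    injection_id: str
    run_order: int
    role: InjectionRole
    peaks: list[PeakRecord] = field(default_factory=list)
    h3_factor: Optional[float] = None
    sample_link: Optional[SampleCondition] = None

    def peak(self, compound_label: str) -> Optional[PeakRecord]:
        for p in self.peaks:
            if p.compound_label == compound_label:
                return p
        return None


@dataclass
class StudyResult:
    """Final per-cell result: profile, per-lipid ε, pool ε, growth rate."""

    condition: SampleCondition
    profile: dict[str, float]            # compound -> % of total
    eps_lipid: dict[str, "object"]       # compound -> FractionationResult
    eps_total: float                     # ‰ vs media water
    eps_total_sem: float
    delta_total: DeltaValue              # vs V-SMOW
    mu_avg: Optional[float] = None       # 1/h
    mu_sem: Optional[float] = None

    def __post_init__(self) -> None:
        if self.profile:
            total = sum(self.profile.values())
            if abs(total - 100.0) > 1e-6:
                raise DomainError(f"profile must sum to 100%, got {total}")
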