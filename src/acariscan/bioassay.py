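"""Containers for dose-mortality bioassay data.

An assay is a set of vials, each coated with a known surface dose of one
acaricide and loaded with a known number of mites; mortality is scored
after a fixed exposure (8 h for the residual contact vial method).
Dose 0 rows are solvent-only controls and are kept out of the probit
design matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = ["BioassayObservation", "BioassayDataset"]

#: recognised dose-unit tags
DOSE_UNITS = ("ug/cm2", "ppm")


@dataclass(frozen=True)
class BioassayObservation:
    """One vial (or one replicate) of a dose-mortality assay.

    Parameters
    ----------
    dose : float
        Surface dose or concentration. Must be positive for treated
        vials; 0 marks a control vial.
    n_treated : int
        Number of mites placed in the vial (positive).
    n_dead : int
        Number scored dead at the end of exposure; ``0 <= n_dead <=
        n_treated``.
    exposure_h : float, default 8
        Exposure time in hours.
    replicate : int, optional
        Replicate index, informational only.
    """

    dose: float
    n_treated: int
    n_dead: int
    exposure_h: float = 8.0
    replicate: int | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.dose) or self.dose < 0:
            raise ValueError(f"dose must be finite and >= 0, got {self.dose}")
        if self.n_treated <= 0:
            raise ValueError(f"n_treated must be positive, got {self.n_treated}")
        if not 0 <= self.n_dead <= self.n_treated:
            raise ValueError(
                f"n_dead must lie in [0, n_treated], got {self.n_dead}/{self.n_treated}"
            )
        if self.exposure_h <= 0:
            raise ValueError(f"exposure_h must be positive, got {self.exposure_h}")

    @property
    def is_control(self) -> bool:
        return self.dose == 0

    @property
    def mortality(self) -> float:
        """Observed mortality as a fraction in [0, 1]."""
        return self.n_dead / self.n_treated


@dataclass
class BioassayDataset:
    """All observations for one strain x acaricide assay."""

    strain: str
    acaricide: str
    observations: list[BioassayObservation] = field(default_factory=list)
    dose_unit: str = "ug/cm2"

    def __post_init__(self) -> None:
        if self.dose_unit not in DOSE_UNITS:
            raise ValueError(
                f"dose_unit must be one of {DOSE_UNITS}, got {self.dose_unit!r}"
            )
        self.observations = list(self.observations)

    # -- accessors -------------------------------------------------------
    @property
    def treated(self) -> list[BioassayObservation]:
        return [o for o in self.observations if not o.is_control]

    @property
    def controls(self) -> list[BioassayObservation]:
        return [o for o in self.observations if o.is_control]

    @property
    def n_distinct_doses(self) -> int:
        return len({o.dose for o in self.treated})

    @property
    def total_treated(self) -> int:
        return sum(o.n_treated for o in self.treated)

    @property
    def total_dead(self) -> int:
        return sum(o.n_dead for o in self.treated)

    def validate_for_fit(self) -> None:
        """Raise ``ValueError`` unless the dataset supports a probit fit."""
        if self.n_distinct_doses < 3:
            raise ValueError(
                f"{self.strain}/{self.acaricide}: probit fitting needs >=3 "
                f"distinct positive doses, got {self.n_distinct_doses}"
            )

    def append(self, obs: BioassayObservation) -> None:
        self.observations.append(obs)

    def __len__(self) -> int:
        return len(self.observations)

    def __iter__(self) -> Iterable[BioassayObservation]:
        return iter(self.observations)


def pool_by_dose(observations: Sequence[BioassayObservation]) -> list[tuple[float, int, int]]:
    """Aggregate replicate vials to ``(dose, n_treated, n_dead)`` per distinct dose."""
    acc: dict[float, list[int]] = {}
    for o in observations:
        bucket = acc.setdefault(o.dose, [0, 0])
        bucket[0] += o.n_treated
        bucket[1] += o.n_dead
    return [(d, n, y) for d, (n, y) in sorted(acc.items())]
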