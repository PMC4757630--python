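"""Core domain types: haplotypes, STR profiles, molecular clocks, skylines.

The package analyses two haploid marker systems:

* mtDNA HVS-I haplotypes, encoded as sets of derived variants over a fixed
  1-based coordinate range of the control region (default 16,051-16,400,
  closed on both ends);
* Y-chromosome STR profiles, encoded as per-locus repeat counts over a
  fixed 19-locus panel (DYS426 is excluded because of unreliable typing).

Molecular clocks convert mutation counts to years.  Sequence clocks carry
``years_per_mutation``; STR clocks carry ``rate_per_locus_per_year``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Closed 1-based coordinate interval of the HVS-I segment analysed.
HVS1_RANGE: tuple[int, int] = (16051, 16400)

#: Symbol used for a deleted base in a variant's derived state.
DELETION = "-"

_BASES = ("A", "C", "G", "T")

#: Canonical 19-locus Y-STR panel (DYS426 deliberately absent).
CANONICAL_STR_PANEL: tuple[str, ...] = (
    "DYS388", "DYS393", "DYS392", "DYS19", "DYS390", "DYS391", "DYS425",
    "DYS389I", "DYS389II", "DYS460", "DYS461", "DYS438", "DYS448",
    "DYS458", "DYS437", "DYS439", "H4", "A10", "DYS635",
)

#: Loci rejected by default by the STR reader.
EXCLUDED_STR_LOCI: frozenset[str] = frozenset({"DYS426"})

VALID_ROLES = ("source", "sink", "excluded")


@dataclass(frozen=True)
class HVSIHaplotype:
    """One sampled HVS-I sequence, stored as its derived-variant set.

    ``variants`` holds ``(position, derived_state)`` pairs where
    ``derived_state`` is a base A/C/G/T or :data:`DELETION`.  The role
    (source / sink / excluded) always comes from sample metadata, never
    from the sequence itself.
    """

    sample_id: str
    population: str
    role: str
    variants: frozenset[tuple[int, str]]
    haplogroup_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.role not in VALID_ROLES:
            raise ValueError(
                f"invalid role {self.role!r} for sample {self.sample_id!r}; "
                f"expected one of {VALID_ROLES}"
            )
        positions = [p for p, _ in self.variants]
        if len(positions) != len(set(positions)):
            raise ValueError(
                f"duplicate variant positions in sample {self.sample_id!r}"
            )
        for pos, state in self.variants:
            if state not in _BASES and state != DELETION:
                raise ValueError(
                    f"invalid derived state {state!r} at {pos} "
                    f"in sample {self.sample_id!r}"
                )

    def variant_tokens(self) -> list[str]:
        """Variants as sorted standard tokens, e.g. ``['16189C', '16217C']``."""
        return [
            f"{pos}{'d' if state == DELETION else state}"
            for pos, state in sorted(self.variants)
        ]


@dataclass(frozen=True)
class STRProfile:
    """One sampled Y-STR profile: repeat counts over a fixed locus panel."""

    sample_id: str
    population: str
    role: str
    repeats: dict[str, int]
    snp_haplogroup: str = ""

    def __post_init__(self) -> None:
        if self.role not in VALID_ROLES:
            raise ValueError(
                f"invalid role {self.role!r} for sample {self.sample_id!r}; "
                f"expected one of {VALID_ROLES}"
            )
        for locus, count in self.repeats.items():
            if not isinstance(count, (int, np.integer)) or count <= 0:
                raise ValueError(
                    f"repeat count for {locus} in sample {self.sample_id!r} "
                    f"must be a positive integer, got {count!r}"
                )

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(sorted(self.repeats))


@dataclass(frozen=True)
class ClockSpec:
    """A molecular clock: exactly one of the two rate encodings is set.

    Sequence clocks give the expected waiting time between mutations on one
    lineage over the scored range (years per mutation).  STR clocks give a
    per-locus, per-year mutation rate; ages additionally need the number of
    loci in the panel.
    """

    name: str
    years_per_mutation: Optional[float] = None
    rate_per_locus_per_year: Optional[float] = None
    applicable_range: str = ""

    def __post_init__(self) -> None:
        set_fields = [
            v for v in (self.years_per_mutation, self.rate_per_locus_per_year)
            if v is not None
        ]
        if len(set_fields) != 1:
            raise ValueError(
                f"clock {self.name!r}: exactly one of years_per_mutation and "
                "rate_per_locus_per_year must be set"
            )
        if set_fields[0] <= 0:
            raise ValueError(f"clock {self.name!r}: rate must be positive")

    @property
    def is_sequence_clock(self) -> bool:
        return self.years_per_mutation is not None

    @property
    def is_str_clock(self) -> bool:
        return self.rate_per_locus_per_year is not None


def zhivotovsky_rate_per_year(
    rate_per_generation: float = 6.9e-4, generation_years: float = 25.0
) -> float:
    """Convert an effective STR rate per generation to a per-year rate.

    The widely used evolutionary (effective) Y-STR rate of 6.9e-4
    mutations per 25 years per locus converts exactly to 2.76e-5
    mutations per locus per year.
    """
    return rate_per_generation / generation_years


#: Built-in clock presets.
CLOCKS: dict[str, ClockSpec] = {
    # HVS-I transitions over 16,051-16,400: one mutation every 16,677 years.
    "hvs1": ClockSpec(
        "hvs1", years_per_mutation=16677.0, applicable_range="16051-16400"
    ),
    # Whole-mtDNA time-dependent clock corrected for purifying selection,
    # anchored on the long-term phylogenetic rate of one mutation / 3624 y.
    "mtdna_phylogenetic": ClockSpec(
        "mtdna_phylogenetic", years_per_mutation=3624.0,
        applicable_range="whole-mtDNA",
    ),
    # Synonymous substitutions only: one substitution every 7884 years.
    "synonymous": ClockSpec(
        "synonymous", years_per_mutation=7884.0,
        applicable_range="whole-mtDNA coding, synonymous",
    ),
    # 19-locus average Y-STR rate calibrated on the settlement of Remote
    # Oceania (3000-year-old star clade).
    "ystr_calibrated": ClockSpec(
        "ystr_calibrated", rate_per_locus_per_year=4.08e-5,
        applicable_range="19 Y-STR panel",
    ),
    # Zhivotovsky evolutionary rate, 6.9e-4 per 25-year generation.
    "ystr_zhivotovsky": ClockSpec(
        "ystr_zhivotovsky",
        rate_per_locus_per_year=zhivotovsky_rate_per_year(),
        applicable_range="Y-STR, evolutionary effective rate",
    ),
}


@dataclass
class SkylineTrajectory:
    """An effective-population-size trajectory (e.g. from a Bayesian skyline).

    Times are years before present, strictly increasing; sizes are the
    (median) effective population sizes at those times, with optional
    credible bounds.
    """

    times: np.ndarray
    sizes: np.ndarray
    lower: Optional[np.ndarray] = None
    upper: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.sizes = np.asarray(self.sizes, dtype=float)
        if self.times.shape != self.sizes.shape or self.times.ndim != 1:
            raise ValueError("times and sizes must be 1-D arrays of equal length")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("skyline times must be strictly increasing")
        if np.any(self.sizes <= 0):
            raise ValueError("skyline sizes must be positive")
        for name in ("lower", "upper"):
            bound = getattr(self, name)
            if bound is not None:
                bound = np.asarray(bound, dtype=float)
                if bound.shape != self.times.shape:
                    raise ValueError(f"{name} bound length mismatch")
                setattr(self, name, bound)
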