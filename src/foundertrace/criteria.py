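"""The five-point "out-of-Taiwan" marker test and skyline post-processing.

A clear-cut marker of a mid-Holocene dispersal from Taiwan into Island
Southeast Asia (ISEA) should satisfy five phylogeographic expectations:

(a) its arrival in Taiwan (with rice agriculturists from South China,
    ~6-8 ka) is bracketed by the age of the mainland ancestral clade
    (upper bound) and the insular, Austronesian-specific subclade (lower
    bound);
(b) the insular subclade dates between the arrival of rice agriculturists
    (~5.5 ka) and the out-of-Taiwan migration (~4.5 ka);
(c) its founder age into ISEA is ~4.5 ka;
(d) its founder age from Taiwan+Philippines into the rest of ISEA is below
    the out-of-Taiwan date, ~4 ka;
(e) its demographic expansion in Taiwan predates the expansion in ISEA.

Expansion onsets/peaks for (e) are read off Bayesian skyline trajectories
after differencing them into expansion increments (effective population
size change per 100 individuals per 100 years).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .types import SkylineTrajectory


@dataclass
class MarkerAges:
    """Age estimates (in ka) feeding the five-criterion test.

    Intervals are optional (lo, hi) pairs; criteria use point estimates by
    default.
    """

    clade_age: float
    ancestor_age: float
    founder_age_sink: float
    founder_age_extended_source: float
    expansion_onset_source: float
    expansion_onset_sink: float
    clade_interval: Optional[tuple[float, float]] = None
    ancestor_interval: Optional[tuple[float, float]] = None
    founder_sink_interval: Optional[tuple[float, float]] = None
    founder_extended_interval: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        fields = {
            "clade_age": self.clade_age,
            "ancestor_age": self.ancestor_age,
            "founder_age_sink": self.founder_age_sink,
            "founder_age_extended_source": self.founder_age_extended_source,
            "expansion_onset_source": self.expansion_onset_source,
            "expansion_onset_sink": self.expansion_onset_sink,
        }
        blocked = {
            "clade_age": "a/b", "ancestor_age": "a",
            "founder_age_sink": "c", "founder_age_extended_source": "d",
            "expansion_onset_source": "e", "expansion_onset_sink": "e",
        }
        for name, value in fields.items():
            if value is None:
                raise ValueError(
                    f"missing {name}: blocks criterion ({blocked[name]})")
            if value < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class CriteriaConfig:
    """Windows and tolerances for the five criteria (all in ka).

    The defaults encode the narrative expectations: carriage into Taiwan
    ~6-8 ka, insular subclade origin 4.5-5.5 ka, founder age target 4.5 ka,
    extended-source founder bound 4 ka, with a symmetric 0.5 ka tolerance
    on the point comparisons and a 0.5 ka margin on the expansion-order
    test.
    """

    arrival_window: tuple[float, float] = (6.0, 8.0)
    clade_window: tuple[float, float] = (4.5, 5.5)
    founder_target: float = 4.5
    extended_founder_bound: float = 4.0
    tolerance: float = 0.5
    onset_margin: float = 0.5

    def __post_init__(self) -> None:
        if self.arrival_window[0] > self.arrival_window[1] \
                or self.clade_window[0] > self.clade_window[1]:
            raise ValueError("criteria windows must be ordered (lo, hi)")
        if self.tolerance < 0 or self.onset_margin < 0:
            raise ValueError("tolerance and onset margin must be >= 0")

    def rescaled(self, factor: float) -> "CriteriaConfig":
        """Same config with every quantity multiplied by ``factor`` (e.g.
        1000 for ka -> years)."""
        return CriteriaConfig(
            tuple(x * factor for x in self.arrival_window),
            tuple(x * factor for x in self.clade_window),
            self.founder_target * factor,
            self.extended_founder_bound * factor,
            self.tolerance * factor,
            self.onset_margin * factor,
        )


@dataclass
class CriteriaVerdict:
    verdicts: dict[str, bool]

    @property
    def n_passed(self) -> int:
        return sum(self.verdicts.values())

    def __getitem__(self, key: str) -> bool:
        return self.verdicts[key]


def evaluate_criteria(ages: MarkerAges,
                      config: Optional[CriteriaConfig] = None
                      ) -> CriteriaVerdict:
    """Evaluate the five out-of-Taiwan criteria for one candidate marker.

    (a) passes iff [clade_age, ancestor_age] contains the whole arrival
    window; (b) iff the clade age lies in the clade window; (c) iff the
    sink founder age is within ``tolerance`` of the founder target;
    (d) iff the extended-source founder age is at most the bound plus
    tolerance; (e) iff the source expansion onset predates the sink onset
    by at least ``onset_margin``.
    """
    cfg = config or CriteriaConfig()
    v = {
        "a": (ages.clade_age <= cfg.arrival_window[0]
              and ages.ancestor_age >= cfg.arrival_window[1]),
        "b": cfg.clade_window[0] <= ages.clade_age <= cfg.clade_window[1],
        "c": abs(ages.founder_age_sink - cfg.founder_target)
        <= cfg.tolerance,
        "d": ages.founder_age_extended_source
        <= cfg.extended_founder_bound + cfg.tolerance,
        "e": ages.expansion_onset_source
        >= ages.expansion_onset_sink + cfg.onset_margin,
    }
    return CriteriaVerdict(v)


# ---------------------------------------------------------------------------
# skyline post-processing


@dataclass
class IncrementSeries:
    """Expansion increments on a regular (default 100-year) grid.

    ``increments[i]`` is the effective-size change between ``times[i]`` and
    ``times[i] + time_step``, in units of ``size_unit`` individuals
    (positive = growth toward the present).
    """

    times: np.ndarray
    increments: np.ndarray
    time_step: float = 100.0
    size_unit: float = 100.0


def expansion_increments(traj: SkylineTrajectory, time_step: float = 100.0,
                         size_unit: float = 100.0) -> IncrementSeries:
    """Difference a skyline trajectory into expansion increments.

    The trajectory is linearly interpolated onto a regular grid; the
    increment at time t is (N(t) - N(t + step)) / size_unit, i.e. growth
    per ``size_unit`` individuals per ``time_step`` years going forward in
    time.
    """
    if len(traj.times) < 2:
        raise ValueError("need at least two skyline points")
    grid = np.arange(traj.times[0], traj.times[-1] + time_step / 2.0,
                     time_step)
    sizes = np.interp(grid, traj.times, traj.sizes)
    increments = (sizes[:-1] - sizes[1:]) / size_unit
    return IncrementSeries(grid[:-1], increments, time_step, size_unit)


@dataclass
class ExpansionSignal:
    """Onset and peak of an expansion read off an increment series."""

    onset_years: Optional[float]
    peak_years: Optional[float]
    local_maxima_years: list[float] = field(default_factory=list)

    @property
    def defined(self) -> bool:
        return self.peak_years is not None


def detect_expansion(series: IncrementSeries,
                     onset_fraction: float = 0.1) -> ExpansionSignal:
    """Locate the expansion peak and onset in an increment series.

    The peak is the grid time of the maximum increment; the onset is the
    oldest time on the contiguous rise toward the peak at which the
    increment still exceeds ``onset_fraction`` of the peak value. All
    positive local maxima are reported; the primary peak is the global one.
    A flat (all-zero) series yields an undefined signal.
    """
    inc = series.increments
    if len(inc) == 0 or np.all(inc <= 0):
        return ExpansionSignal(None, None)
    peak_idx = int(np.argmax(inc))
    peak_val = inc[peak_idx]
    threshold = onset_fraction * peak_val
    onset_idx = peak_idx
    # walk toward older times while the rise stays above threshold
    for i in range(peak_idx, len(inc)):
        if inc[i] > threshold:
            onset_idx = i
        else:
            break
    maxima = []
    for i in range(len(inc)):
        left = inc[i - 1] if i > 0 else -np.inf
        right = inc[i + 1] if i < len(inc) - 1 else -np.inf
        if inc[i] > 0 and inc[i] >= left and inc[i] >= right:
            maxima.append(float(series.times[i]))
    return ExpansionSignal(float(series.times[onset_idx]),
                           float(series.times[peak_idx]), maxima)
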