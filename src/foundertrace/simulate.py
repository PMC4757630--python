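"""Two-deme migration simulator with known founder truth.

Generates matched source/sink datasets in which every sink lineage descends
from a known source founder type via a migration pulse at a known time, so
that founder identification, rho dating, the migration scan and the
partition model can all be validated against ground truth.

Model
-----
* The source genealogy is clade-structured: a root haplotype gives rise to
  ``n_clades`` clade centres at random founding times (backbone branches
  accumulate mutations), and each clade centre persists to the present as a
  modal type while sampled source lineages branch off it at recent-skewed
  times and mutate privately. This mimics the expansion-cluster structure
  of real source pools (frequent ancestral types surrounded by derived
  variation) that founder analysis relies on; a plain
  birth-only (comb-like) genealogy would leave pulse-time ancestral states
  unobserved in any finite modern sample.
* Each migration pulse at time T draws founder types from the states of
  source lineages at T, frequency-weighted and restricted to states carried
  by at least two sampled lineages: migrations that leave a detectable
  founder cluster are founded by types segregating at appreciable
  frequency, which is also the premise of the f1/f2 founder criteria (a
  founder type must show derived diversity on the source side). Each
  migrating sink lineage then mutates independently for T years.
* HVS-I mutation is finite-sites: Poisson(T/Q) events placed uniformly over
  the segment, recurrent and back mutation allowed. STR mutation is
  strictly single-step: per-locus symmetric +/-1 events at rate r per
  locus-year (reflected at a repeat count of 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .dating import FounderCluster
from .types import CLOCKS, HVS1_RANGE, ClockSpec, HVSIHaplotype, STRProfile

_BASES = np.array(list("ACGT"))


@dataclass
class SimScenario:
    """Study conditions for a two-deme simulation.

    ``pulses`` is a list of (time in years BP, fraction of sink lineages)
    whose fractions sum to 1. The seed is mandatory: identical scenarios
    produce byte-identical datasets.
    """

    pulses: Sequence[tuple[float, float]]
    seed: int
    clock: ClockSpec = field(default_factory=lambda: CLOCKS["hvs1"])
    n_source: int = 300
    n_sink: int = 200
    n_sites: int = 350
    n_loci: int = 19
    source_depth_years: float = 50000.0
    n_clades: int = 8
    founders_per_pulse: int = 3

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        if not self.pulses:
            raise ValueError("at least one migration pulse is required")
        times = [t for t, _ in self.pulses]
        fracs = [f for _, f in self.pulses]
        if any(t <= 0 for t in times):
            raise ValueError("pulse times must be positive")
        if not np.isclose(sum(fracs), 1.0):
            raise ValueError(
                f"pulse fractions must sum to 1, got {sum(fracs)}")

    @property
    def marker(self) -> str:
        return "hvs1" if self.clock.is_sequence_clock else "str"

    @property
    def rate_per_lineage_year(self) -> float:
        if self.clock.is_sequence_clock:
            return 1.0 / self.clock.years_per_mutation
        return self.clock.rate_per_locus_per_year * self.n_loci


@dataclass
class SimTruth:
    """Ground truth emitted next to a simulated dataset."""

    sample_founder: dict[str, str]
    sample_entry_time: dict[str, float]
    founder_states: dict[str, str]
    founder_times: dict[str, float]

    def members_of(self, founder_id: str) -> list[str]:
        return sorted(s for s, f in self.sample_founder.items()
                      if f == founder_id)


# ---------------------------------------------------------------------------
# mutation processes


def _mutate_hvs1(state: dict[int, str], n_events: int, rng, ref: str,
                 start: int, n_sites: int) -> dict[int, str]:
    state = dict(state)
    for _ in range(n_events):
        pos = start + int(rng.integers(n_sites))
        cur = state.get(pos, ref[pos - start])
        new = str(rng.choice(_BASES[_BASES != cur]))
        if new == ref[pos - start]:
            state.pop(pos, None)
        else:
            state[pos] = new
    return state


def _mutate_str(state: np.ndarray, n_events: int, rng) -> np.ndarray:
    state = state.copy()
    for _ in range(n_events):
        locus = int(rng.integers(len(state)))
        step = int(rng.choice((-1, 1)))
        if state[locus] + step < 1:
            step = 1  # reflect: repeat counts stay positive
        state[locus] += step
    return state


class _Lineage:
    """A sampled source lineage with its full mutation history.

    ``events`` are (time BP, payload) tuples sorted oldest-first along the
    path from the root to the tip; the state at any time T is obtained by
    replaying events older than T onto the root state.
    """

    def __init__(self, events: list[tuple[float, tuple]]):
        self.events = sorted(events, key=lambda e: -e[0])

    def state_at(self, time_bp: float, root_state, ref, start, n_sites,
                 marker: str):
        if marker == "hvs1":
            state = dict(root_state)
            for t, (pos, off) in self.events:
                if t < time_bp:
                    break
                cur = state.get(pos, ref[pos - start])
                new = _BASES[(int(np.where(_BASES == cur)[0][0]) + off) % 4]
                if new == ref[pos - start]:
                    state.pop(pos, None)
                else:
                    state[pos] = new
            return state
        state = np.array(root_state, copy=True)
        for t, (locus, step) in self.events:
            if t < time_bp:
                break
            if state[locus] + step < 1:
                step = 1
            state[locus] += step
        return state


def _hvs1_label(state: dict[int, str]) -> str:
    return " ".join(f"{p}{b}" for p, b in sorted(state.items())) or "ref"


def _str_label(state: np.ndarray) -> str:
    return "-".join(str(int(x)) for x in state)


def _draw_events(rng, rate: float, t_new: float, t_old: float,
                 payload_fn) -> list[tuple[float, tuple]]:
    """Poisson mutation events on a branch spanning [t_new, t_old] years BP."""
    n = rng.poisson(rate * (t_old - t_new))
    times = rng.uniform(t_new, t_old, size=n)
    return [(float(t), payload_fn()) for t in np.sort(times)[::-1]]


def simulate_two_deme(scenario: SimScenario):
    """Simulate a source/sink dataset under a known migration history.

    Returns ``(samples, truth)``: samples are HVSIHaplotype or STRProfile
    records (roles assigned), truth a :class:`SimTruth`.
    """
    rng = np.random.default_rng(scenario.seed)
    marker = scenario.marker
    rate = scenario.rate_per_lineage_year
    depth = scenario.source_depth_years
    start, n_sites = HVS1_RANGE[0], scenario.n_sites
    if marker == "hvs1":
        from .io import load_reference_segment
        _, ref_full = load_reference_segment()
        ref = (ref_full * (n_sites // len(ref_full) + 1))[:n_sites]
        root_state: Union[dict, np.ndarray] = {}
        # payload: (position, base offset 1..3) so a replayed event always
        # changes the current base, whatever it is
        payload = lambda: (start + int(rng.integers(n_sites)),
                           int(rng.integers(1, 4)))
    else:
        ref = ""
        root_state = rng.integers(10, 20, size=scenario.n_loci)
        payload = lambda: (int(rng.integers(scenario.n_loci)),
                           int(rng.choice((-1, 1))))

    # clade-structured source genealogy
    clade_tau = rng.uniform(0.3 * depth, 0.9 * depth, size=scenario.n_clades)
    clade_backbone = [
        _draw_events(rng, rate, tau, depth, payload) for tau in clade_tau
    ]
    clade_of_tip = rng.integers(scenario.n_clades, size=scenario.n_source)
    lineages = []
    for i in range(scenario.n_source):
        k = int(clade_of_tip[i])
        u = clade_tau[k] * rng.beta(1.0, 4.0)  # recent-skewed branch-off
        branch = _draw_events(rng, rate, 0.0, u, payload)
        lineages.append(_Lineage(clade_backbone[k] + branch))

    samples: list = []
    for i, lin in enumerate(lineages):
        state = lin.state_at(0.0, root_state, ref, start, n_sites, marker)
        sid = f"src{i:04d}"
        if marker == "hvs1":
            samples.append(HVSIHaplotype(
                sid, "SOURCE", "source",
                frozenset((p, b) for p, b in state.items())))
        else:
            samples.append(STRProfile(
                sid, "SOURCE", "source",
                {f"L{j:02d}": int(state[j])
                 for j in range(scenario.n_loci)}))

    # founder types per pulse, then sink lineages
    truth = SimTruth({}, {}, {}, {})
    pulse_counts = _allocate(scenario.n_sink, [f for _, f in scenario.pulses])
    sink_i = 0
    for p_idx, ((t_pulse, _), count) in enumerate(
            zip(scenario.pulses, pulse_counts)):
        # candidate founder types: lineage states at the pulse time carried
        # by >= 2 sampled source lineages, drawn frequency-weighted
        states_at_t = [lin.state_at(t_pulse, root_state, ref, start,
                                    n_sites, marker) for lin in lineages]
        labels_at_t = [(_hvs1_label(s) if marker == "hvs1"
                        else _str_label(s)) for s in states_at_t]
        mult: dict[str, int] = {}
        for lbl in labels_at_t:
            mult[lbl] = mult.get(lbl, 0) + 1
        eligible = [i for i, lbl in enumerate(labels_at_t) if mult[lbl] >= 2]
        if not eligible:
            top = max(mult.values())
            eligible = [i for i, lbl in enumerate(labels_at_t)
                        if mult[lbl] == top]
        founder_ids = []
        founder_states = []
        for j in range(scenario.founders_per_pulse):
            tip = int(eligible[int(rng.integers(len(eligible)))])
            state = states_at_t[tip]
            fid = f"pulse{p_idx}_f{j}"
            founder_ids.append(fid)
            founder_states.append(state)
            truth.founder_states[fid] = (_hvs1_label(state)
                                         if marker == "hvs1"
                                         else _str_label(state))
            truth.founder_times[fid] = float(t_pulse)
        for _ in range(count):
            j = int(rng.integers(scenario.founders_per_pulse))
            n_mut = rng.poisson(rate * t_pulse)
            if marker == "hvs1":
                state = _mutate_hvs1(founder_states[j], n_mut, rng, ref,
                                     start, n_sites)
            else:
                state = _mutate_str(founder_states[j], n_mut, rng)
            sid = f"sink{sink_i:04d}"
            sink_i += 1
            if marker == "hvs1":
                samples.append(HVSIHaplotype(
                    sid, "SINK", "sink",
                    frozenset((p, b) for p, b in state.items())))
            else:
                samples.append(STRProfile(
                    sid, "SINK", "sink",
                    {f"L{k:02d}": int(state[k])
                     for k in range(scenario.n_loci)}))
            truth.sample_founder[sid] = founder_ids[j]
            truth.sample_entry_time[sid] = float(t_pulse)
    return samples, truth


def _allocate(total: int, fractions: Sequence[float]) -> list[int]:
    raw = [f * total for f in fractions]
    counts = [int(np.floor(x)) for x in raw]
    remainders = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i],
                        reverse=True)
    for i in remainders[: total - sum(counts)]:
        counts[i] += 1
    return counts


# ---------------------------------------------------------------------------
# star clades


@dataclass
class StarCladeSim:
    """A simulated star clade: n lineages mutated independently from one
    founder for a fixed time."""

    founder_label: str
    members: list
    distances: list[int]

    def cluster(self) -> FounderCluster:
        members = [(m.sample_id, m.sample_id, d)
                   for m, d in zip(self.members, self.distances)]
        branches = [(d, 1) for d in self.distances if d > 0]
        return FounderCluster(self.founder_label, members, branches)


def simulate_star_clade(n: int, age_years: float, clock: ClockSpec,
                        n_loci: int = 19, n_sites: int = 350,
                        seed: int = 0) -> StarCladeSim:
    """Simulate ``n`` lineages radiating from one founder for ``age_years``.

    The expected rho (mutational distance to the founder) is
    age * total mutation rate per lineage: T/Q for a sequence clock,
    T * r * n_loci for an STR clock (up to random-walk cancellation of
    opposite repeat steps).
    """
    if n < 2:
        raise ValueError("a star clade needs at least two lineages")
    rng = np.random.default_rng(seed)
    start = HVS1_RANGE[0]
    members: list = []
    distances = []
    if clock.is_sequence_clock:
        from .io import load_reference_segment
        _, ref_full = load_reference_segment()
        ref = (ref_full * (n_sites // len(ref_full) + 1))[:n_sites]
        rate = 1.0 / clock.years_per_mutation
        founder: dict[int, str] = {}
        for i in range(n):
            state = _mutate_hvs1(founder, rng.poisson(rate * age_years),
                                 rng, ref, start, n_sites)
            members.append(HVSIHaplotype(
                f"m{i:04d}", "CLADE", "sink",
                frozenset((p, b) for p, b in state.items())))
            distances.append(len(set(state.items())
                                 ^ set(founder.items())))
        label = _hvs1_label(founder)
    else:
        rate = clock.rate_per_locus_per_year * n_loci
        founder_arr = rng.integers(10, 20, size=n_loci)
        for i in range(n):
            state = _mutate_str(founder_arr,
                                rng.poisson(rate * age_years), rng)
            members.append(STRProfile(
                f"m{i:04d}", "CLADE", "sink",
                {f"L{j:02d}": int(state[j]) for j in range(n_loci)}))
            distances.append(int(np.abs(state - founder_arr).sum()))
        label = _str_label(founder_arr)
    return StarCladeSim(label, members, distances)
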