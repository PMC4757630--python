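"""Founder identification and Bayesian migration-time inference.

Founder analysis assigns every sink sample to the nearest ancestral node of
the rooted haplotype tree whose state is observed in the source region and
which shows derived diversity on the source side (the f1 criterion demands
at least one source-side derived branch at the candidate node, f2 at least
two -- a guard against sink-to-source back-migration masquerading as a
founder). Candidates failing the criterion are dissolved and their sink
members climb to the next surviving candidate, so every sink sample ends up
in exactly one founder cluster.

Each cluster is then dated probabilistically against a set of candidate
migration times. With an effective (star-equivalent) number of lineages
n_eff and effective mutation count m = n_eff * rho, the likelihood of a
migration at time T is the continuous-Poisson form

    L(T) proportional to lambda^m * exp(-lambda),
    lambda = n_eff * T / Q            (sequence clock, Q years/mutation)
    lambda = n_eff * T * r * n_loci   (STR clock, rate r per locus-year)

evaluated either on a fine regular grid (the migration-time scan, default
200-year intervals from 0 to 70 ka) or on a small set of archaeologically
motivated event times (the partition model; mtDNA preset 0.5/4.5/8/50 ka,
Y-STR preset 0.5/4.5/8/20 ka). Posteriors are normalised per founder;
aggregate curves and partition fractions weight founders by their sink
sample counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import networkx as nx
import numpy as np
from scipy.special import logsumexp

from .dating import FounderCluster
from .network import RootedTree
from .types import ClockSpec

logger = logging.getLogger(__name__)

#: Partition event presets (years before present).
MTDNA_EVENT_TIMES: tuple[float, ...] = (500.0, 4500.0, 8000.0, 50000.0)
Y_EVENT_TIMES: tuple[float, ...] = (500.0, 4500.0, 8000.0, 20000.0)


@dataclass
class MigrationModel:
    """Candidate migration event times with a prior over them."""

    event_times: Sequence[float]
    prior: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        times = np.asarray(self.event_times, dtype=float)
        if np.any(times <= 0):
            raise ValueError("event times must be positive")
        if np.any(np.diff(times) <= 0):
            raise ValueError("event times must be strictly increasing")
        self.event_times = times
        if self.prior is None:
            self.prior = np.full(len(times), 1.0 / len(times))
        else:
            prior = np.asarray(self.prior, dtype=float)
            if prior.shape != times.shape or np.any(prior < 0):
                raise ValueError("prior must be a matching nonnegative vector")
            if not np.isclose(prior.sum(), 1.0):
                raise ValueError("prior must sum to 1")
            self.prior = prior


@dataclass
class ScanResult:
    """Per-founder and aggregate posteriors over a regular time grid."""

    grid: np.ndarray
    founders: list[str]
    sink_counts: np.ndarray
    per_founder_posterior: np.ndarray  # founders x grid
    aggregate: np.ndarray

    def mode_years(self) -> float:
        """Grid time of the aggregate posterior maximum."""
        return float(self.grid[int(np.argmax(self.aggregate))])


@dataclass
class PartitionResult:
    """Per-founder event probabilities and overall migration fractions."""

    event_times: np.ndarray
    founders: list[str]
    sink_counts: np.ndarray
    per_founder_probs: np.ndarray  # founders x events
    fractions: np.ndarray
    criterion: str = ""


# ---------------------------------------------------------------------------
# founder identification


def identify_founders(tree: RootedTree, criterion: str = "f1"
                      ) -> list[FounderCluster]:
    """Partition the sink samples of a rooted tree into founder clusters.

    Candidate founder nodes are states observed in the source; a candidate
    survives under f1 (f2) if at least one (two) of its child subtrees
    contains source samples. Each sink sample is assigned to the nearest
    surviving candidate on its path to the root; samples with none are
    assigned to the root with a warning.
    """
    if criterion not in ("f1", "f2"):
        raise ValueError(f"unknown founder criterion {criterion!r}")
    need = 1 if criterion == "f1" else 2
    G = tree.graph

    def roles(node):
        return [r for _, r, *_ in G.nodes[node].get("samples", ())]

    # postorder: which subtrees contain source samples
    has_source: dict[str, bool] = {}
    for node in nx.dfs_postorder_nodes(G, tree.root):
        own = "source" in roles(node)
        has_source[node] = own or any(
            has_source[c] for c in G.successors(node))

    def passes(node: str) -> bool:
        if "source" not in roles(node):
            return False
        derived = sum(1 for c in G.successors(node) if has_source[c])
        return derived >= need

    parent = {v: u for u, v in nx.bfs_edges(G, tree.root)}

    assignment: dict[str, str] = {}  # sink node -> founder node
    orphaned = False
    for node in G.nodes:
        n_sink = sum(1 for r in roles(node) if r == "sink")
        if n_sink == 0:
            continue
        cur: Optional[str] = node
        founder = None
        while cur is not None:
            if passes(cur):
                founder = cur
                break
            cur = parent.get(cur)
        if founder is None:
            founder = tree.root
            orphaned = True
        assignment[node] = founder
    if orphaned:
        logger.warning(
            "some sink samples had no source-observed ancestor passing %s; "
            "they were assigned to the root", criterion)

    clusters = []
    for founder in sorted(set(assignment.values())):
        nodes = sorted(n for n, f in assignment.items() if f == founder)
        members = []
        edge_load: dict[tuple[str, str], int] = {}
        for node in nodes:
            n_sink_here = sum(1 for r in roles(node) if r == "sink")
            dist = tree.depth_steps(node) - tree.depth_steps(founder)
            for sid, role, *_ in G.nodes[node].get("samples", ()):
                if role == "sink":
                    members.append((sid, node, dist))
            # accumulate member load on each edge of the path to the founder
            cur = node
            while cur != founder:
                up = parent[cur]
                edge_load[(up, cur)] = edge_load.get((up, cur), 0) \
                    + n_sink_here
                cur = up
        branches = [(1, b) for _, b in sorted(edge_load.items())]
        clusters.append(FounderCluster(founder, members, branches,
                                       label=founder))
    return clusters


# ---------------------------------------------------------------------------
# migration-time likelihood


def _lambda_scale(n_eff: float, clock: ClockSpec,
                  n_loci: Optional[int]) -> float:
    """lambda(T) = scale * T for one cluster."""
    if clock.is_sequence_clock:
        return n_eff / clock.years_per_mutation
    if n_loci is None:
        raise ValueError(f"STR clock {clock.name!r} needs n_loci")
    return n_eff * clock.rate_per_locus_per_year * n_loci


def migration_posterior(cluster: FounderCluster, times: Sequence[float],
                        clock: ClockSpec,
                        prior: Optional[Sequence[float]] = None,
                        n_loci: Optional[int] = None) -> np.ndarray:
    """Posterior probability of each candidate migration time for a cluster.

    Uses the continuous-Poisson likelihood with effective counts
    (m = n_eff * rho), computed in log space. A cluster with m = 0 carries
    zero post-migration mutations and resolves exactly to the youngest
    candidate time.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("need a non-empty 1-D vector of candidate times")
    if prior is None:
        prior = np.full(len(times), 1.0 / len(times))
    else:
        prior = np.asarray(prior, dtype=float)
        prior = prior / prior.sum()
    r = cluster.rho
    n_eff = cluster.n_eff
    m_tilde = n_eff * r
    if m_tilde == 0:
        post = np.zeros(len(times))
        post[int(np.argmin(times))] = 1.0
        return post
    scale = _lambda_scale(n_eff, clock, n_loci)
    lam = scale * times
    with np.errstate(divide="ignore"):
        loglik = m_tilde * np.log(lam) - lam
        logpost = np.log(prior) + loglik
    logpost -= logsumexp(logpost)
    post = np.exp(logpost)
    return post / post.sum()


def scan_migrations(founders: Sequence[FounderCluster], clock: ClockSpec,
                    grid_start: float = 0.0, grid_end: float = 70000.0,
                    step: float = 200.0,
                    n_loci: Optional[int] = None) -> ScanResult:
    """Scan migration times on a regular grid (default 0-70 ka by 200 y)."""
    if not founders:
        raise ValueError("no founder clusters to scan")
    grid = np.arange(grid_start, grid_end + step / 2.0, step)
    rows = np.stack([
        migration_posterior(f, grid, clock, n_loci=n_loci) for f in founders
    ])
    counts = np.array([f.n for f in founders], dtype=float)
    weights = counts / counts.sum()
    aggregate = weights @ rows
    return ScanResult(grid, [f.label or f.founder_node for f in founders],
                      counts, rows, aggregate)


def partition_migrations(founders: Sequence[FounderCluster],
                         model: MigrationModel, clock: ClockSpec,
                         n_loci: Optional[int] = None,
                         criterion: str = "") -> PartitionResult:
    """Partition founder clusters among a fixed set of migration events."""
    if not founders:
        raise ValueError("no founder clusters to partition")
    times = np.asarray(model.event_times, dtype=float)
    rows = np.stack([
        migration_posterior(f, times, clock, prior=model.prior,
                            n_loci=n_loci)
        for f in founders
    ])
    counts = np.array([f.n for f in founders], dtype=float)
    weights = counts / counts.sum()
    fractions = weights @ rows
    return PartitionResult(times, [f.label or f.founder_node
                                   for f in founders],
                           counts, rows, fractions, criterion=criterion)


# ---------------------------------------------------------------------------
# end-to-end convenience pipeline


@dataclass
class FounderAnalysisResult:
    network: object
    tree: RootedTree
    clusters: list[FounderCluster]
    scan: Optional[ScanResult] = None
    partition: Optional[PartitionResult] = None


def run_founder_analysis(data, clock: ClockSpec, criterion: str = "f1",
                         network_method: str = "mj",
                         weights=None,
                         root_method: str = "outgroup_consensus",
                         outgroup=None,
                         model: Optional[MigrationModel] = None,
                         scan: bool = True,
                         n_loci: Optional[int] = None
                         ) -> FounderAnalysisResult:
    """Run the full founder pipeline on combined source+sink data.

    Builds the haplotype network (median-joining by default, reduced-median
    for binary data on request), roots it, identifies founder clusters
    under the chosen criterion, and optionally runs the 200-year scan and
    the event partition.
    """
    from .network import (median_joining_network, reduced_median_network,
                          root_network)

    if network_method == "mj":
        net = median_joining_network(data, weights=weights)
    elif network_method == "rm":
        net = reduced_median_network(data, weights=weights)
    else:
        raise ValueError(f"unknown network method {network_method!r}")
    tree = root_network(net, method=root_method, outgroup=outgroup)
    clusters = identify_founders(tree, criterion=criterion)
    result = FounderAnalysisResult(net, tree, clusters)
    if clusters and scan:
        result.scan = scan_migrations(clusters, clock, n_loci=n_loci)
    if clusters and model is not None:
        result.partition = partition_migrations(clusters, model, clock,
                                                n_loci=n_loci,
                                                criterion=criterion)
    return result
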