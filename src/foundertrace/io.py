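"""Readers and writers for haplotype tables, networks, trees and results.

Formats:

* HVS-I input as a variant table (TSV; one sample per row with
  whitespace-separated tokens like ``16189C``, ``16166d``) or as aligned
  FASTA over the configured control-region segment, converted to variant
  sets against a reference segment;
* Y-STR input as a TSV of per-locus repeat counts;
* networks as GraphML, extracted trees as Newick, scan/partition results
  as TSV tables, and a JSON run report carrying inputs, seed and a config
  digest.

The bundled reference segment is a synthetic stand-in for the rCRS
HVS-I region (see ``data/hvs1_reference_synthetic.fasta``); supply
``reference=`` to score real data against the actual rCRS.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO

from .analysis import PartitionResult, ScanResult
from .network import HaplotypeNetwork, RootedTree
from .types import (DELETION, EXCLUDED_STR_LOCI, HVS1_RANGE, HVSIHaplotype,
                    STRProfile, SkylineTrajectory)

logger = logging.getLogger(__name__)

_VARIANT_TOKEN = re.compile(r"^(\d{1,6})([ACGTacgt]|d|D|del)$")

_META_COLUMNS = ("sample_id", "population", "role")


def load_reference_segment(path: Optional[Union[str, Path]] = None,
                           ) -> tuple[int, str]:
    """Load the reference segment used to call FASTA variants.

    Returns (start position, sequence). The bundled default is a synthetic
    stand-in sequence over positions 16,051-16,400, not the rCRS itself.
    """
    if path is None:
        ref = resources.files("foundertrace.data") \
            .joinpath("hvs1_reference_synthetic.fasta")
        with resources.as_file(ref) as p:
            record = next(SeqIO.parse(str(p), "fasta"))
    else:
        record = next(SeqIO.parse(str(path), "fasta"))
    return HVS1_RANGE[0], str(record.seq).upper()


def _parse_token(token: str, line_no: int) -> tuple[int, str]:
    m = _VARIANT_TOKEN.match(token)
    if not m:
        raise ValueError(
            f"malformed variant token {token!r} on line {line_no}")
    pos = int(m.group(1))
    state = m.group(2).upper()
    if state in ("D", "DEL"):
        state = DELETION
    return pos, state


def read_hvs1(path: Union[str, Path], format: str = "variant_table",
              position_range: tuple[int, int] = HVS1_RANGE,
              reference: Optional[Union[str, Path]] = None,
              metadata: Optional[dict] = None) -> list[HVSIHaplotype]:
    """Read HVS-I haplotypes from a variant table or aligned FASTA.

    Variants outside ``position_range`` (closed interval) are dropped with
    a logged count. FASTA sequences must cover the full segment (no
    ambiguity codes); they are converted to variant sets by comparison
    against the reference segment.
    """
    lo, hi = position_range
    if format == "variant_table":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        missing = [c for c in _META_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"variant table lacks columns {missing}")
        haps = []
        dropped = 0
        for row_i, row in enumerate(df.itertuples(index=False), start=2):
            tokens = getattr(row, "variants", "").split()
            variants = set()
            for tok in tokens:
                pos, state = _parse_token(tok, row_i)
                if lo <= pos <= hi:
                    variants.add((pos, state))
                else:
                    dropped += 1
            haps.append(HVSIHaplotype(
                sample_id=row.sample_id, population=row.population,
                role=row.role, variants=frozenset(variants),
                haplogroup_label=getattr(row, "haplogroup", None) or None))
        if dropped:
            logger.info("dropped %d variants outside [%d, %d]",
                        dropped, lo, hi)
    elif format == "fasta":
        start, ref = load_reference_segment(reference)
        if start != lo:
            raise ValueError("reference segment does not start at the "
                             "configured range")
        haps = []
        for record in SeqIO.parse(str(path), "fasta"):
            fields = record.description.split("|")
            sid = fields[0].strip()
            if metadata and sid in metadata:
                pop, role = metadata[sid][:2]
                hg = metadata[sid][2] if len(metadata[sid]) > 2 else None
            elif len(fields) >= 3:
                pop, role = fields[1].strip(), fields[2].strip()
                hg = fields[3].strip() if len(fields) > 3 else None
            else:
                raise ValueError(
                    f"no metadata for FASTA record {sid!r}: use "
                    "'id|population|role' headers or pass metadata=")
            seq = str(record.seq).upper()
            if len(seq) != hi - lo + 1:
                raise ValueError(
                    f"sequence {sid!r} length {len(seq)} does not cover "
                    f"the segment [{lo}, {hi}]")
            bad = set(seq) - set("ACGT-")
            if bad:
                raise ValueError(
                    f"sequence {sid!r} contains unsupported symbols {bad}; "
                    "complete unambiguous coverage of the range is required")
            variants = set()
            for i, base in enumerate(seq):
                if base != ref[i]:
                    variants.add((lo + i, DELETION if base == "-" else base))
            haps.append(HVSIHaplotype(sid, pop, role, frozenset(variants),
                                      haplogroup_label=hg))
    else:
        raise ValueError(f"unknown HVS-I format {format!r}")
    ids = [h.sample_id for h in haps]
    dupes = {s for s in ids if ids.count(s) > 1}
    if dupes:
        raise ValueError(f"duplicate sample ids: {sorted(dupes)}")
    return haps


def write_hvs1_variant_table(haps: Sequence[HVSIHaplotype],
                             path: Union[str, Path]) -> None:
    rows = [{
        "sample_id": h.sample_id, "population": h.population,
        "role": h.role, "haplogroup": h.haplogroup_label or "",
        "variants": " ".join(h.variant_tokens()),
    } for h in haps]
    pd.DataFrame(rows, columns=["sample_id", "population", "role",
                                "haplogroup", "variants"]) \
        .to_csv(path, sep="\t", index=False)


def read_str_profiles(path: Union[str, Path],
                      allow_excluded: bool = False) -> list[STRProfile]:
    """Read Y-STR repeat profiles from a TSV table.

    All non-metadata columns are treated as loci; every profile must carry
    the same locus set, repeat counts must be integers, and columns for
    excluded loci (DYS426) are rejected unless ``allow_excluded``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"STR table lacks columns {missing}")
    meta_cols = set(_META_COLUMNS) | {"snp_haplogroup"}
    loci = [c for c in df.columns if c not in meta_cols]
    banned = sorted(set(loci) & EXCLUDED_STR_LOCI)
    if banned and not allow_excluded:
        raise ValueError(
            f"table contains excluded locus column(s) {banned}; these loci "
            "gave inconsistent typing and are rejected by default "
            "(allow_excluded=True to override)")
    profiles = []
    for row in df.itertuples(index=False):
        repeats = {}
        for locus in loci:
            raw = getattr(row, locus)
            try:
                value = int(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-integer repeat value {raw!r} at sample "
                    f"{row.sample_id!r}, locus {locus}") from None
            repeats[locus] = value
        profiles.append(STRProfile(
            sample_id=row.sample_id, population=row.population,
            role=row.role, repeats=repeats,
            snp_haplogroup=getattr(row, "snp_haplogroup", "")))
    ids = [p.sample_id for p in profiles]
    dupes = {s for s in ids if ids.count(s) > 1}
    if dupes:
        raise ValueError(f"duplicate sample ids: {sorted(dupes)}")
    return profiles


def write_str_profiles(profiles: Sequence[STRProfile],
                       path: Union[str, Path]) -> None:
    loci = sorted(profiles[0].repeats) if profiles else []
    rows = []
    for p in profiles:
        row = {"sample_id": p.sample_id, "population": p.population,
               "role": p.role, "snp_haplogroup": p.snp_haplogroup}
        row.update({l: p.repeats[l] for l in loci})
        rows.append(row)
    pd.DataFrame(rows, columns=list(_META_COLUMNS) + ["snp_haplogroup"]
                 + loci).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# networks / trees / results


def network_to_graphml(net: HaplotypeNetwork, path: Union[str, Path]) -> None:
    G = nx.Graph()
    G.graph["marker"] = net.marker
    G.graph["characters"] = json.dumps(net.characters)
    G.graph["weights"] = json.dumps(net.character_weights)
    G.graph["core_edges"] = json.dumps(net.core_edges)
    for n, d in net.graph.nodes(data=True):
        G.add_node(n, kind=d.get("kind", "observed"),
                   count=int(d.get("count", 0)),
                   samples=";".join("|".join(s)
                                    for s in d.get("samples", ())),
                   state=",".join(str(int(x)) for x in net.states[n]))
    for u, v, d in net.graph.edges(data=True):
        G.add_edge(u, v, character=d["character"], weight=float(d["weight"]))
    nx.write_graphml(G, str(path))


def network_from_graphml(path: Union[str, Path]) -> HaplotypeNetwork:
    G = nx.read_graphml(str(path))
    marker = G.graph["marker"]
    characters = json.loads(G.graph["characters"])
    weights = json.loads(G.graph["weights"])
    core_edges = [tuple(e) for e in json.loads(G.graph["core_edges"])]
    H = nx.Graph()
    states = {}
    for n, d in G.nodes(data=True):
        samples = [tuple(s.split("|")) for s in d["samples"].split(";")
                   if s]
        H.add_node(n, kind=d["kind"], count=int(d["count"]), samples=samples)
        raw = d.get("state", "")
        states[n] = np.array([int(x) for x in raw.split(",") if x != ""],
                             dtype=np.int16)
    for u, v, d in G.edges(data=True):
        H.add_edge(u, v, character=d["character"], weight=float(d["weight"]))
    return HaplotypeNetwork(H, characters, weights, marker, states,
                            core_edges)


def scan_to_frame(scan: ScanResult) -> pd.DataFrame:
    df = pd.DataFrame({"time_years": scan.grid,
                       "aggregate": scan.aggregate})
    for i, name in enumerate(scan.founders):
        df[name] = scan.per_founder_posterior[i]
    return df


def partition_to_frame(result: PartitionResult) -> pd.DataFrame:
    cols = [f"{int(t)}y" for t in result.event_times]
    df = pd.DataFrame(result.per_founder_probs, columns=cols,
                      index=result.founders)
    df.index.name = "founder"
    df.insert(0, "sink_count", result.sink_counts.astype(int))
    df.loc["fractions"] = [np.nan] + list(result.fractions)
    return df


def read_skyline(path: Union[str, Path]) -> SkylineTrajectory:
    """Read a skyline trajectory TSV (time, median[, lower, upper])."""
    df = pd.read_csv(path, sep="\t")
    return SkylineTrajectory(
        df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float),
        df.iloc[:, 2].to_numpy(float) if df.shape[1] > 2 else None,
        df.iloc[:, 3].to_numpy(float) if df.shape[1] > 3 else None)


def config_digest(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_report(inputs: Sequence[str], seed: Optional[int],
               config: dict) -> dict:
    return {"inputs": list(inputs), "seed": seed,
            "config": config, "config_digest": config_digest(config)}


def write_results(result, path: Union[str, Path], kind: str) -> None:
    """Serialise a pipeline result.

    ``kind`` selects the format: ``network_graphml`` (HaplotypeNetwork),
    ``tree_newick`` (RootedTree), ``table`` (scan/partition/DataFrame as
    TSV), ``report`` (dict as JSON).
    """
    path = Path(path)
    if kind == "network_graphml":
        network_to_graphml(result, path)
    elif kind == "tree_newick":
        path.write_text(result.to_newick() + "\n")
    elif kind == "table":
        if isinstance(result, ScanResult):
            df = scan_to_frame(result)
            df.to_csv(path, sep="\t", index=False)
        elif isinstance(result, PartitionResult):
            partition_to_frame(result).to_csv(path, sep="\t")
        elif isinstance(result, pd.DataFrame):
            result.to_csv(path, sep="\t", index=False)
        else:
            raise ValueError(f"cannot write {type(result).__name__} as table")
    elif kind == "report":
        path.write_text(json.dumps(result, indent=2, default=str) + "\n")
    else:
        raise ValueError(f"unknown result kind {kind!r}")
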