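"""Co-prescription network: build, sparsify, detect groups.

Co-prescription is the prescription of agents from two or more different
pharmaceutical families (PFs) within the same booked consultation.  The
PF-level network has one node per family (sized by its total prescription
events) and one edge per co-prescribed family pair (weighted by the number
of consultations in which the pair co-occurred).

Sparsification drops rarely prescribed families (below a fraction of total
prescriptions, default 0.5%) and then edges whose weight does not exceed
the mean weight of the surviving edges; families left without edges are
retained as isolates rather than removed.  Group structure is then detected
by asynchronous label propagation — each node repeatedly adopts its
neighbours' (weighted) majority label until densely connected regions agree
on one label — repeated over several seeded runs with the modal partition
returned, since single label-propagation runs are order-dependent.
"""

from __future__ import annotations

import logging
from itertools import combinations
from pathlib import Path
from typing import Optional, Union

import networkx as nx
import pandas as pd

from .errors import UndefinedResultError
from .taxonomy import UNRESOLVED

logger = logging.getLogger(__name__)


def consult_pf_sets(events: pd.DataFrame) -> pd.Series:
    """Distinct families prescribed per consultation, as frozensets.

    A family appears at most once per set no matter how many of its agents
    were prescribed in the consultation.
    """
    return events.groupby("consultation_id", sort=True)["pf"].agg(
        lambda s: frozenset(s)
    )


def coprescription_rate(sets) -> float:
    """Fraction of prescribing consultations involving >= 2 distinct families."""
    sets = list(sets)
    if not sets:
        raise UndefinedResultError("no prescribing consultations")
    return sum(1 for s in sets if len(s) >= 2) / len(sets)


def build_network(events: pd.DataFrame) -> nx.Graph:
    """PF-level co-prescription graph from mapped prescription events.

    Node attribute ``count`` is the family's total prescription events (one
    per event row, so several agents of one family in one consultation all
    count); each consultation prescribing ``m`` distinct families adds +1
    weight to each of its C(m, 2) unordered pairs.
    """
    g = nx.Graph()
    for pf, count in events["pf"].value_counts().items():
        g.add_node(pf, count=int(count))
    for pf_set in consult_pf_sets(events):
        for a, b in combinations(sorted(pf_set), 2):
            if g.has_edge(a, b):
                g[a][b]["weight"] += 1
            else:
                g.add_edge(a, b, weight=1)
    return g


def build_pc_network(events: pd.DataFrame) -> nx.Graph:
    """Class-level analogue of :func:`build_network` (export only; group
    detection runs at family level)."""
    ev = events[events["agent"] != UNRESOLVED].copy()
    ev = ev.rename(columns={"pf": "_pf", "pc": "pf"})
    return build_network(ev)


def sparsify(g: nx.Graph, node_frac: float = 0.005) -> nx.Graph:
    """Drop rare nodes, then edges at or below the mean surviving weight.

    Nodes contributing less than ``node_frac`` of total prescriptions are
    removed first; the edge-weight mean is computed over the edges remaining
    after node removal, and only edges strictly exceeding it survive.
    Nodes left edgeless are kept as isolates.
    """
    total = sum(d["count"] for _, d in g.nodes(data=True))
    keep = [n for n, d in g.nodes(data=True) if d["count"] >= node_frac * total]
    out = g.subgraph(keep).copy()
    if not keep:
        logger.warning("sparsification removed every node")
        return out
    weights = [d["weight"] for _, _, d in out.edges(data=True)]
    if weights:
        mean_w = sum(weights) / len(weights)
        drop = [
            (a, b) for a, b, d in out.edges(data=True) if d["weight"] <= mean_w
        ]
        out.remove_edges_from(drop)
    return out


def _canonical(partition) -> frozenset:
    return frozenset(frozenset(c) for c in partition)


def detect_groups(
    g: nx.Graph, seed: int = 0, n_runs: int = 20
) -> dict[str, int]:
    """Consensus label-propagation grouping.

    Runs weighted asynchronous label propagation ``n_runs`` times with
    seeds ``seed, seed+1, ...`` and returns the modal partition (ties go to
    the earliest run).  Isolated nodes always form singleton groups.  Group
    labels are integers from 1, ordered by decreasing group size then by
    the smallest member name.
    """
    if len(g) == 0:
        return {}
    partitions = []
    for r in range(n_runs):
        comms = nx.community.asyn_lpa_communities(
            g, weight="weight", seed=(seed + r) % (2**31)
        )
        partitions.append(_canonical(comms))
    counts: dict[frozenset, int] = {}
    first_seen: dict[frozenset, int] = {}
    for i, p in enumerate(partitions):
        counts[p] = counts.get(p, 0) + 1
        first_seen.setdefault(p, i)
    best = max(counts, key=lambda p: (counts[p], -first_seen[p]))

    groups = sorted(best, key=lambda c: (-len(c), min(c)))
    labels: dict[str, int] = {}
    for label, members in enumerate(groups, start=1):
        for node in members:
            labels[node] = label
    return labels


def partition_from_labels(labels: dict[str, int]) -> frozenset:
    """Partition (set of frozensets) induced by a node -> label mapping."""
    by_label: dict[int, set] = {}
    for node, lab in labels.items():
        by_label.setdefault(lab, set()).add(node)
    return frozenset(frozenset(v) for v in by_label.values())


def write_network(
    g: nx.Graph,
    outdir: Union[str, Path],
    groups: Optional[dict[str, int]] = None,
    prefix: str = "network",
) -> dict[str, Path]:
    """Export GraphML + weighted edge list CSV (+ groups CSV when given)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "graphml": outdir / f"{prefix}.graphml",
        "edges": outdir / f"{prefix}_edges.csv",
    }
    nx.write_graphml(g, paths["graphml"])
    edges = pd.DataFrame(
        [
            {"source": a, "target": b, "weight": d["weight"]}
            for a, b, d in sorted(g.edges(data=True))
        ],
        columns=["source", "target", "weight"],
    )
    edges.to_csv(paths["edges"], index=False)
    if groups is not None:
        paths["groups"] = outdir / f"{prefix}_groups.csv"
        pd.DataFrame(
            sorted(groups.items()), columns=["pf", "group"]
        ).to_csv(paths["groups"], index=False)
    return paths
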