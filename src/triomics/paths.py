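"""Candidate mediation pathway extraction.

From the least-penalized estimated network, all shortest directed paths
from a maternal feature node (SNP, fasting/1-hr metabolite, or
phenotype) to a newborn outcome node are collected as purported
mediation pathways.  Paths that are contiguous subpaths of a longer
candidate are removed, and only paths with at least ``min_nodes``
nodes (default 3: exposure, >=1 mediator, outcome) are kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import networkx as nx
import pandas as pd

from .dag import DAGResults
from .nodes import NodeMeta

MATERNAL_SOURCE_TYPES = ("MG", "MM", "MP")


@dataclass(frozen=True)
class MediationPath:
    """An ordered maternal-exposure-to-newborn-outcome path."""

    node_ids: Tuple[str, ...]
    source_type: str
    outcome: str

    @property
    def length(self) -> int:
        return len(self.node_ids)


def _as_digraph(dag) -> nx.DiGraph:
    if isinstance(dag, DAGResults):
        return dag.to_networkx()
    if isinstance(dag, nx.DiGraph):
        return dag
    raise TypeError("dag must be DAGResults or networkx.DiGraph")


def shortest_directed_paths(dag, source: str, target: str) -> List[List[str]]:
    """All minimal-edge-count directed paths from source to target.

    Returns an empty list when the target is unreachable; output is
    sorted lexicographically by node-id sequence.
    """
    g = _as_digraph(dag)
    if source == target:
        raise ValueError("source and target must differ")
    for node in (source, target):
        if node not in g:
            raise KeyError(f"node {node!r} not in graph")
    try:
        paths = [list(p) for p in nx.all_shortest_paths(g, source, target)]
    except nx.NetworkXNoPath:
        return []
    return sorted(paths)


def is_subpath(short: Sequence[str], long: Sequence[str]) -> bool:
    """True iff ``short`` occurs as a contiguous ordered slice of ``long``."""
    if len(short) < 2 or len(long) < 2:
        raise ValueError("both paths need at least two nodes")
    s, l = tuple(short), tuple(long)
    k = len(s)
    return any(l[i : i + k] == s for i in range(len(l) - k + 1))


def extract_candidates(
    dag,
    meta: Sequence[NodeMeta],
    min_nodes: int = 3,
) -> List[MediationPath]:
    """Pooled shortest-path candidates with subpath exclusion.

    Sources are maternal feature nodes (MG/MM/MP); targets are newborn
    phenotype nodes with role "outcome".  Shortest directed paths are
    pooled over all source/target pairs; any path that is a contiguous
    subpath of a longer pooled path is excluded, as are paths shorter
    than ``min_nodes``.  Output order is deterministic (by length,
    then node-id sequence).
    """
    g = _as_digraph(dag)
    by_id = {m.node_id: m for m in meta}
    sources = [m.node_id for m in meta if m.node_type in MATERNAL_SOURCE_TYPES and m.node_id in g]
    targets = [
        m.node_id
        for m in meta
        if m.node_type == "NP" and m.role == "outcome" and m.node_id in g
    ]
    pool: List[Tuple[str, ...]] = []
    for s in sources:
        for t in targets:
            for p in shortest_directed_paths(g, s, t):
                if len(p) >= min_nodes:
                    pool.append(tuple(p))
    pool = sorted(set(pool))
    kept = [
        p
        for p in pool
        if not any(len(q) > len(p) and is_subpath(p, q) for q in pool)
    ]
    kept.sort(key=lambda p: (len(p), p))
    return [
        MediationPath(node_ids=p, source_type=by_id[p[0]].node_type, outcome=p[-1])
        for p in kept
    ]


def paths_to_frame(paths: Sequence[MediationPath]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "path": [";".join(p.node_ids) for p in paths],
            "length": [p.length for p in paths],
            "source_type": [p.source_type for p in paths],
            "outcome": [p.outcome for p in paths],
        }
    )


def paths_from_frame(df: pd.DataFrame) -> List[MediationPath]:
    return [
        MediationPath(
            node_ids=tuple(row.path.split(";")),
            source_type=row.source_type,
            outcome=row.outcome,
        )
        for row in df.itertuples(index=False)
    ]
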