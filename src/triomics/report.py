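"""Solution-path summaries, growth-frame export and light preprocessing.

Mirrors the way the study is reported: edge tallies by ordered
node-type pair at each penalty value, the first-occurrence penalty of
notable edge classes (e.g. the first genotype-to-non-genotype edge),
per-penalty GraphML plus static plot frames for animation, and the
metabolite missingness filter with minimum-value imputation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .dag import DAGResults, SolutionPathResults
from .nodes import Blocklist, NodeMeta, NODE_TYPES, build_blocklist


@dataclass
class EdgeTally:
    """Edge counts (and percent of total) by ordered node-type pair."""

    lambda_value: float
    rows: pd.DataFrame  # columns: from_type, to_type, count, percent

    @property
    def total_edges(self) -> int:
        return int(self.rows["count"].sum())


def _ordered_type_pairs(blocklist: Optional[Blocklist]) -> List[Tuple[str, str]]:
    pairs = []
    for a in NODE_TYPES:
        for b in NODE_TYPES:
            if blocklist is not None and blocklist.is_type_pair_forbidden(a, b):
                continue
            pairs.append((a, b))
    return pairs


def tally_edges_by_type(
    dag: DAGResults,
    meta: Optional[Sequence[NodeMeta]] = None,
    blocklist: Optional[Blocklist] = None,
) -> EdgeTally:
    """Count edges per ordered (parent type, child type) pair.

    Rows cover exactly the type pairs not forbidden outright by the
    blocklist (the published tally's 21-row layout when the standard
    rules are used); percents are count/total*100, reported as 0 for an
    empty graph.
    """
    meta = list(meta) if meta is not None else dag.meta
    if blocklist is None:
        blocklist = build_blocklist(meta)
    by_id = {m.node_id: m for m in meta}
    counts: Dict[Tuple[str, str], int] = {p: 0 for p in _ordered_type_pairs(blocklist)}
    for u, v, _ in dag.edges():
        key = (by_id[u].node_type, by_id[v].node_type)
        if key not in counts:  # defensive: blocklisted pair should not occur
            counts[key] = 0
        counts[key] += 1
    total = sum(counts.values())
    rows = pd.DataFrame(
        {
            "from_type": [k[0] for k in counts],
            "to_type": [k[1] for k in counts],
            "count": list(counts.values()),
        }
    )
    rows["percent"] = 100.0 * rows["count"] / total if total else 0.0
    return EdgeTally(lambda_value=dag.lambda_value, rows=rows)


def first_occurrence(
    path: SolutionPathResults,
    edge_class: Callable[[NodeMeta, NodeMeta, float], bool],
) -> Optional[float]:
    """Largest (most stringent) lambda at which any matching edge is present.

    Scans the grid from the largest lambda down; ``edge_class`` is a
    predicate on (parent meta, child meta, weight).  Returns None if no
    model on the path contains a matching edge.
    """
    if not path.lambdas:
        raise ValueError("empty solution path")
    for lam in sorted(path.lambdas, reverse=True):
        res = path.models[lam]
        by_id = {m.node_id: m for m in res.meta}
        for u, v, w in res.edges():
            if edge_class(by_id[u], by_id[v], w):
                return lam
    return None


def genotype_to_nongenotype(parent: NodeMeta, child: NodeMeta, weight: float) -> bool:
    """Edge-class predicate: SNP node into a metabolite/phenotype node."""
    return parent.is_genotype and not child.is_genotype


# stable class-keyed palette for frames (outcomes grey, genotypes green)
_CLASS_COLORS = {
    "AA": "#1f77b4",
    "AC": "#ff7f0e",
    "CHO": "#9467bd",
    "FA": "#8c564b",
    "GC/TCA": "#e377c2",
    "OA": "#17becf",
    "PUR/PYR": "#bcbd22",
    "other": "#7f7f7f",
}


def _node_color(m: NodeMeta) -> str:
    if m.is_genotype:
        return "#2ca02c"
    if m.node_type == "NP":
        return "#999999"
    if m.node_type == "MP":
        return "#d62728"
    return _CLASS_COLORS.get(m.metabolite_class or "other", "#7f7f7f")


def export_growth_frames(
    path: SolutionPathResults,
    meta: Optional[Sequence[NodeMeta]] = None,
    out_dir: str | Path = ".",
    plot: bool = True,
) -> List[Path]:
    """One GraphML (and optionally one PNG) per lambda, largest first.

    Frame index 1 corresponds to the largest lambda on the grid (the
    sparsest network), so with the default 15..1 grid frame_01 is
    lambda=15 and frame_15 is lambda=1.  Node colors key on type and
    metabolite class; maternal nodes are squares, offspring circles.
    Layout is computed once on the union graph so frames are stable.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lambdas = sorted(path.lambdas, reverse=True)
    files: List[Path] = []

    pos = None
    if plot:
        union = nx.DiGraph()
        for lam in lambdas:
            union = nx.compose(union, path.models[lam].to_networkx())
        pos = nx.spring_layout(union, seed=0)

    for k, lam in enumerate(lambdas, start=1):
        res = path.models[lam]
        g = res.to_networkx()
        gml = out_dir / f"frame_{k:02d}_lambda{lam:g}.graphml"
        nx.write_graphml(g, gml)
        files.append(gml)
        if plot:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(7, 7))
            nmeta = {m.node_id: m for m in res.meta}
            for shape, members in (
                ("s", [n for n in g if nmeta[n].is_maternal]),
                ("o", [n for n in g if not nmeta[n].is_maternal]),
            ):
                nx.draw_networkx_nodes(
                    g, pos, nodelist=members, node_shape=shape, ax=ax,
                    node_color=[_node_color(nmeta[n]) for n in members],
                    node_size=120,
                )
            nx.draw_networkx_edges(g, pos, ax=ax, arrowsize=8, width=0.8)
            nx.draw_networkx_labels(g, pos, ax=ax, font_size=5)
            ax.set_title(f"frame {k} (lambda = {lam:g}), {res.n_edges} edges")
            ax.set_axis_off()
            png = out_dir / f"frame_{k:02d}_lambda{lam:g}.png"
            try:
                fig.savefig(png, dpi=100)
            except OSError as exc:
                raise OSError(f"failed writing {png}: {exc}") from exc
            finally:
                plt.close(fig)
            files.append(png)
    return files


def read_graphml_dag(path: str | Path) -> nx.DiGraph:
    """Re-read an exported frame (edge weights as floats)."""
    g = nx.read_graphml(path)
    return nx.DiGraph(g)


def preprocess_metabolites(
    matrix: pd.DataFrame,
    max_missing_fraction: float = 0.2,
    impute: bool = True,
) -> pd.DataFrame:
    """Missingness filter with metabolite-specific minimum imputation.

    Columns with a missing fraction strictly greater than the threshold
    are dropped (0.1 for targeted assays, 0.2 for non-targeted in the
    motivating study); remaining missing entries are set to the column
    minimum when ``impute`` is on, reflecting that low-abundance
    features go undetected.
    """
    if not (0.0 <= max_missing_fraction <= 1.0):
        raise ValueError("max_missing_fraction must lie in [0, 1]")
    frac = matrix.isna().mean(axis=0)
    out = matrix.loc[:, frac[frac <= max_missing_fraction].index].copy()
    if impute:
        for col in out.columns:
            if out[col].isna().any():
                out[col] = out[col].fillna(out[col].min())
    return out


def tally_path_to_frame(
    path: SolutionPathResults,
    meta: Optional[Sequence[NodeMeta]] = None,
    blocklist: Optional[Blocklist] = None,
) -> pd.DataFrame:
    """Long-format tally over the whole solution path."""
    frames = []
    for lam in path.lambdas:
        t = tally_edges_by_type(path.models[lam], meta, blocklist)
        df = t.rows.copy()
        df.insert(0, "lambda", lam)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
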