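"""Typed node catalog and the directed-edge blocklist.

Nodes in the maternal-offspring network carry a type code:

====  =========================================
MG    maternal genotype (SNP dosage)
MM    maternal metabolite (fasting or 1-hr)
MP    maternal phenotype (e.g. BMI, glucose)
NG    newborn genotype (SNP dosage)
NM    newborn (cord blood) metabolite
NP    newborn phenotype / outcome
====  =========================================

The blocklist encodes a priori biological ordering: metabolites cannot
cause genotypes, offspring features cannot cause maternal genotypes, and
SNP-to-SNP edges are only allowed within a chromosome.  Structure search
never proposes a blocklisted edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import pandas as pd

NODE_TYPES = ("MG", "MM", "MP", "NG", "NM", "NP")
GENOTYPE_TYPES = ("MG", "NG")
MATERNAL_TYPES = ("MG", "MM", "MP")
TIMEPOINTS = ("fasting", "1hr", "cord", "none")
METABOLITE_CLASSES = ("AA", "AC", "CHO", "FA", "GC/TCA", "OA", "PUR/PYR", "other")
ROLES = ("exposure", "outcome", "intermediate")


@dataclass(frozen=True)
class NodeMeta:
    """Metadata for one network node."""

    node_id: str
    node_type: str
    timepoint: str = "none"
    chromosome: Optional[str] = None
    metabolite_class: Optional[str] = None
    role: str = "intermediate"

    def __post_init__(self) -> None:
        if self.node_type not in NODE_TYPES:
            raise ValueError(f"unknown node_type {self.node_type!r} for {self.node_id}")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r} for {self.node_id}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for {self.node_id}")
        if self.node_type in GENOTYPE_TYPES and self.chromosome is None:
            raise ValueError(f"SNP node {self.node_id} must have a chromosome")

    @property
    def is_genotype(self) -> bool:
        return self.node_type in GENOTYPE_TYPES

    @property
    def is_maternal(self) -> bool:
        return self.node_type in MATERNAL_TYPES


def check_node_meta(meta: Sequence[NodeMeta]) -> None:
    """Validate a node catalog: nonempty, unique ids."""
    if not meta:
        raise ValueError("node catalog is empty")
    ids = [m.node_id for m in meta]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate node ids: {dupes}")


def meta_to_frame(meta: Sequence[NodeMeta]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "node_id": [m.node_id for m in meta],
            "node_type": [m.node_type for m in meta],
            "timepoint": [m.timepoint for m in meta],
            "chromosome": [m.chromosome if m.chromosome is not None else "" for m in meta],
            "metabolite_class": [
                m.metabolite_class if m.metabolite_class is not None else "" for m in meta
            ],
            "role": [m.role for m in meta],
        }
    )


def meta_from_frame(df: pd.DataFrame) -> list[NodeMeta]:
    meta = []
    for row in df.itertuples(index=False):
        chrom = getattr(row, "chromosome", "") or None
        if isinstance(chrom, float):  # pandas reads empty strings as NaN
            chrom = None
        mclass = getattr(row, "metabolite_class", "") or None
        if isinstance(mclass, float):
            mclass = None
        meta.append(
            NodeMeta(
                node_id=str(row.node_id),
                node_type=str(row.node_type),
                timepoint=str(getattr(row, "timepoint", "none") or "none"),
                chromosome=str(chrom) if chrom is not None else None,
                metabolite_class=str(mclass) if mclass is not None else None,
                role=str(getattr(row, "role", "intermediate") or "intermediate"),
            )
        )
    check_node_meta(meta)
    return meta


# The ten forbidden ordered type pairs.  Together with the
# cross-chromosome SNP rule below these are the eleven ordering
# constraints imposed on structure search.
FORBIDDEN_TYPE_PAIRS: frozenset[tuple[str, str]] = frozenset(
    {
        ("NG", "MG"),  # offspring SNP -> maternal SNP
        ("NP", "MG"),  # newborn outcome -> maternal SNP
        ("NM", "MG"),  # cord metabolite -> maternal SNP
        ("NG", "MP"),  # offspring SNP -> maternal phenotype
        ("NG", "MM"),  # offspring SNP -> maternal fasting/1-hr metabolite
        ("NP", "NG"),  # newborn outcome -> offspring SNP
        ("NM", "NG"),  # cord metabolite -> offspring SNP
        ("MP", "NG"),  # maternal phenotype -> offspring SNP
        ("MM", "MG"),  # maternal metabolite -> maternal SNP
        ("MM", "NG"),  # maternal metabolite -> offspring SNP
    }
)


def _cross_chromosome(parent: NodeMeta, child: NodeMeta) -> bool:
    """Forbid SNP->SNP edges between different chromosomes."""
    return (
        parent.is_genotype
        and child.is_genotype
        and parent.chromosome != child.chromosome
    )


EdgePredicate = Callable[[NodeMeta, NodeMeta], bool]


@dataclass
class Blocklist:
    """Direction-specific forbidden-edge rules.

    ``forbidden_type_rules`` forbids every edge whose (parent type,
    child type) pair is listed; ``extra_predicates`` are named callables
    returning True when a specific (parent, child) edge is forbidden.
    """

    forbidden_type_rules: frozenset[tuple[str, str]] = FORBIDDEN_TYPE_PAIRS
    extra_predicates: tuple[tuple[str, EdgePredicate], ...] = (
        ("cross_chromosome_snp", _cross_chromosome),
    )

    def is_forbidden(self, parent: NodeMeta, child: NodeMeta) -> bool:
        if (parent.node_type, child.node_type) in self.forbidden_type_rules:
            return True
        return any(pred(parent, child) for _, pred in self.extra_predicates)

    def is_type_pair_forbidden(self, parent_type: str, child_type: str) -> bool:
        """True when the ordered type pair is forbidden outright."""
        return (parent_type, child_type) in self.forbidden_type_rules

    def forbidden_matrix(self, meta: Sequence[NodeMeta]):
        """Boolean p x p matrix, entry [i, j] True when edge i->j is forbidden."""
        import numpy as np

        p = len(meta)
        out = np.zeros((p, p), dtype=bool)
        for i, mi in enumerate(meta):
            for j, mj in enumerate(meta):
                if i == j:
                    continue
                out[i, j] = self.is_forbidden(mi, mj)
        return out


def build_blocklist(meta: Sequence[NodeMeta]) -> Blocklist:
    """Construct the standard maternal-offspring blocklist.

    The rule set does not depend on the catalog contents, but the
    catalog is validated so that downstream queries are well defined.
    """
    check_node_meta(meta)
    return Blocklist()


def empty_blocklist() -> Blocklist:
    """A blocklist that permits every directed edge (for benchmarks)."""
    return Blocklist(forbidden_type_rules=frozenset(), extra_predicates=())


def blocklist_from_yaml(path) -> Blocklist:
    """Load blocklist overrides from YAML.

    Recognized keys: ``extra_forbidden`` (list of [from_type, to_type]
    pairs added to the standard rules), ``allow`` (list of pairs removed
    from them), and ``cross_chromosome_snp`` (bool, default true).
    """
    import yaml

    data = yaml.safe_load(open(path)) or {}
    rules = set(FORBIDDEN_TYPE_PAIRS)
    for pair in data.get("extra_forbidden", []):
        rules.add((str(pair[0]), str(pair[1])))
    for pair in data.get("allow", []):
        rules.discard((str(pair[0]), str(pair[1])))
    preds: tuple = (
        (("cross_chromosome_snp", _cross_chromosome),)
        if data.get("cross_chromosome_snp", True)
        else ()
    )
    return Blocklist(forbidden_type_rules=frozenset(rules), extra_predicates=preds)
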