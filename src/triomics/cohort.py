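"""Synthetic maternal-offspring multi-omics cohorts with known ground truth.

The generator emulates the dependency structure the network model
assumes: Mendelian transmission of maternal alleles to offspring,
SNP -> metabolite effects, maternal -> cord metabolite transfer, and
metabolite -> phenotype effects, all linear-Gaussian with known
coefficients.  Because the truth is known, indirect effects along any
path and the full implied covariance matrix are available in closed
form, which is what makes every downstream stage testable.

Genotype dosages are additive 0/1/2 counts.  A transmission edge
MG -> NG is generated mechanistically (one maternal allele drawn
uniformly, one paternal allele from the population frequency); its
implied linear coefficient is exactly 0.5, since
cov(mother, child) = p(1-p) = var(mother)/2 under Hardy-Weinberg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .nodes import Blocklist, NodeMeta, build_blocklist, check_node_meta

TRANSMISSION_COEF = 0.5  # implied linear effect of a Mendelian MG->NG edge


class StructureError(ValueError):
    """Raised when a graph violates acyclicity or path/edge structure."""


def _topological_order(nodes: Sequence[str], edges: Mapping[Tuple[str, str], float]) -> List[str]:
    """Kahn's algorithm; raises StructureError on a cycle."""
    indeg = {n: 0 for n in nodes}
    children: Dict[str, List[str]] = {n: [] for n in nodes}
    for (u, v) in edges:
        children[u].append(v)
        indeg[v] += 1
    frontier = sorted(n for n in nodes if indeg[n] == 0)
    order: List[str] = []
    while frontier:
        n = frontier.pop(0)
        order.append(n)
        for c in sorted(children[n]):
            indeg[c] -= 1
            if indeg[c] == 0:
                frontier.append(c)
        frontier.sort()
    if len(order) != len(nodes):
        raise StructureError("model graph contains a cycle")
    return order


@dataclass
class TrueModel:
    """Ground-truth linear-Gaussian generative model over typed nodes.

    ``coefficients`` maps (parent, child) to the linear effect on the
    child, in the child's units.  Transmission edges (MG -> NG pairs at
    the same locus) are listed in ``transmission`` and simulated
    mechanistically; their entry in :meth:`coefficient` is 0.5.
    """

    meta: List[NodeMeta]
    coefficients: Dict[Tuple[str, str], float]
    noise_sd: Dict[str, float]
    intercepts: Dict[str, float] = field(default_factory=dict)
    maf: Dict[str, float] = field(default_factory=dict)
    transmission: Dict[str, str] = field(default_factory=dict)  # NG node -> MG node

    def __post_init__(self) -> None:
        check_node_meta(self.meta)
        self._by_id = {m.node_id: m for m in self.meta}
        for child, mother in self.transmission.items():
            if self._by_id[child].node_type != "NG" or self._by_id[mother].node_type != "MG":
                raise ValueError("transmission must map NG -> MG node ids")
        for snp in self.genotype_nodes():
            p = self.maf.get(snp)
            if p is None or not (0.0 < p <= 0.5):
                raise ValueError(f"SNP node {snp} needs maf in (0, 0.5]")
        blocklist = build_blocklist(self.meta)
        for (u, v) in self.dag_edges():
            if blocklist.is_forbidden(self._by_id[u], self._by_id[v]):
                raise ValueError(f"ground-truth edge {u}->{v} violates the blocklist")
        order = _topological_order([m.node_id for m in self.meta], dict.fromkeys(self.dag_edges(), 0.0))
        self._order = order
        for n in self.non_genotype_nodes():
            if self.noise_sd.get(n, -1.0) < 0.0:
                raise ValueError(f"node {n} needs noise_sd >= 0")
            if self.parents(n) == [] and self.noise_sd[n] <= 0.0:
                raise ValueError(f"root node {n} needs noise_sd > 0")

    # -- structure accessors -------------------------------------------------
    def node_ids(self) -> List[str]:
        return [m.node_id for m in self.meta]

    def genotype_nodes(self) -> List[str]:
        return [m.node_id for m in self.meta if m.is_genotype]

    def non_genotype_nodes(self) -> List[str]:
        return [m.node_id for m in self.meta if not m.is_genotype]

    def dag_edges(self) -> List[Tuple[str, str]]:
        edges = list(self.coefficients)
        edges += [(mom, child) for child, mom in self.transmission.items()]
        return edges

    def coefficient(self, parent: str, child: str) -> float:
        if self.transmission.get(child) == parent:
            return TRANSMISSION_COEF
        try:
            return self.coefficients[(parent, child)]
        except KeyError:
            raise StructureError(f"{parent}->{child} is not an edge of the model") from None

    def parents(self, node: str) -> List[str]:
        out = [u for (u, v) in self.coefficients if v == node]
        if node in self.transmission:
            out.append(self.transmission[node])
        return sorted(out)

    def topological_order(self) -> List[str]:
        return list(self._order)

    # -- closed-form moments -------------------------------------------------
    def implied_covariance(self) -> pd.DataFrame:
        """Population covariance (I-B)^-T Omega (I-B)^-1 over all nodes.

        B[i, j] is the effect of node i on node j (0.5 for transmission
        edges); Omega holds marginal variances 2p(1-p) for maternal
        SNPs, residual variances 1.5p(1-p) for transmitted offspring
        SNPs, and noise_sd**2 for all other nodes.
        """
        ids = self.node_ids()
        idx = {n: k for k, n in enumerate(ids)}
        p = len(ids)
        B = np.zeros((p, p))
        omega = np.zeros(p)
        for (u, v), c in self.coefficients.items():
            B[idx[u], idx[v]] = c
        for child, mom in self.transmission.items():
            B[idx[mom], idx[child]] = TRANSMISSION_COEF
        for n in ids:
            m = self._by_id[n]
            if m.is_genotype:
                q = self.maf[n]
                pq = q * (1.0 - q)
                if n in self.transmission:
                    omega[idx[n]] = 1.5 * pq  # 2pq - 0.25 * 2pq
                else:
                    omega[idx[n]] = 2.0 * pq
            else:
                omega[idx[n]] = self.noise_sd[n] ** 2
        inv = np.linalg.inv(np.eye(p) - B)
        cov = inv.T @ np.diag(omega) @ inv
        return pd.DataFrame(cov, index=ids, columns=ids)


@dataclass
class Cohort:
    """Aligned per-pair matrices for a maternal-offspring cohort."""

    pair_ids: List[str]
    maternal_genotypes: pd.DataFrame
    offspring_genotypes: pd.DataFrame
    maternal_metabolites_fasting: pd.DataFrame
    maternal_metabolites_1hr: pd.DataFrame
    cord_metabolites: pd.DataFrame
    phenotypes: pd.DataFrame
    covariates: pd.DataFrame
    strata: pd.Series
    meta: Optional[List[NodeMeta]] = None

    def __post_init__(self) -> None:
        n = len(self.pair_ids)
        for name in (
            "maternal_genotypes",
            "offspring_genotypes",
            "maternal_metabolites_fasting",
            "maternal_metabolites_1hr",
            "cord_metabolites",
            "phenotypes",
            "covariates",
        ):
            df = getattr(self, name)
            if len(df) != n:
                raise ValueError(f"{name} has {len(df)} rows, expected {n}")
        if len(self.strata) != n:
            raise ValueError("strata length mismatch")

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)

    def _blocks(self) -> List[pd.DataFrame]:
        return [
            self.maternal_genotypes,
            self.offspring_genotypes,
            self.maternal_metabolites_fasting,
            self.maternal_metabolites_1hr,
            self.cord_metabolites,
            self.phenotypes,
        ]

    def analysis_frame(self, timepoint: str = "fasting") -> pd.DataFrame:
        """All node columns for one analysis family (fasting or 1hr).

        Genotypes, cord metabolites and phenotypes are shared across
        families; maternal metabolites are restricted to the requested
        timepoint, mirroring the separate fasting and 1-hr networks.
        """
        if timepoint not in ("fasting", "1hr"):
            raise ValueError("timepoint must be 'fasting' or '1hr'")
        mm = (
            self.maternal_metabolites_fasting
            if timepoint == "fasting"
            else self.maternal_metabolites_1hr
        )
        return pd.concat(
            [self.maternal_genotypes, self.offspring_genotypes, mm,
             self.cord_metabolites, self.phenotypes],
            axis=1,
        )

    def subset(self, rows: Sequence[int]) -> "Cohort":
        rows = list(rows)
        return Cohort(
            pair_ids=[self.pair_ids[i] for i in rows],
            maternal_genotypes=self.maternal_genotypes.iloc[rows].reset_index(drop=True),
            offspring_genotypes=self.offspring_genotypes.iloc[rows].reset_index(drop=True),
            maternal_metabolites_fasting=self.maternal_metabolites_fasting.iloc[rows].reset_index(drop=True),
            maternal_metabolites_1hr=self.maternal_metabolites_1hr.iloc[rows].reset_index(drop=True),
            cord_metabolites=self.cord_metabolites.iloc[rows].reset_index(drop=True),
            phenotypes=self.phenotypes.iloc[rows].reset_index(drop=True),
            covariates=self.covariates.iloc[rows].reset_index(drop=True),
            strata=self.strata.iloc[rows].reset_index(drop=True),
            meta=self.meta,
        )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_trio_genotypes(
    n_pairs: int,
    mafs: Sequence[float],
    seed: int,
) -> Tuple[np.ndarray, np.ndarray]:
    """Simulate maternal and offspring additive dosages at unlinked SNPs.

    Maternal genotypes are Binomial(2, maf) under Hardy-Weinberg; the
    offspring inherits one allele drawn uniformly from the mother's two
    plus one paternal allele drawn from the population frequency.  The
    parent-offspring dosage correlation is therefore exactly 1/2.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    mafs = np.asarray(mafs, dtype=float)
    if np.any((mafs <= 0.0) | (mafs > 0.5)):
        raise ValueError("every maf must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)
    m = len(mafs)
    a1 = rng.random((n_pairs, m)) < mafs
    a2 = rng.random((n_pairs, m)) < mafs
    maternal = a1.astype(np.int64) + a2.astype(np.int64)
    pick_first = rng.random((n_pairs, m)) < 0.5
    transmitted = np.where(pick_first, a1, a2)
    paternal = rng.random((n_pairs, m)) < mafs
    offspring = transmitted.astype(np.int64) + paternal.astype(np.int64)
    return maternal, offspring


def simulate_cohort(
    model: TrueModel,
    n_pairs: int,
    seed: int,
    n_covariates: int = 3,
    n_strata: int = 4,
    covariate_effects: Optional[Mapping[Tuple[str, str], float]] = None,
) -> Cohort:
    """Draw a cohort from the generative model.

    Genotype nodes come from :func:`simulate_trio_genotypes`; every
    other node is generated in topological order as
    ``intercept + sum(coef * parent) + Normal(0, noise_sd)``.
    Covariates are independent standard normals unless
    ``covariate_effects`` maps (covariate, node) pairs to confounding
    coefficients.  Ancestry strata are Dirichlet-proportioned labels,
    independent of the omics nodes.
    """
    rng = np.random.default_rng(seed)
    ids = model.node_ids()
    values: Dict[str, np.ndarray] = {}

    # genotypes: maternal nodes first, then transmitted / unpaired offspring
    mg_nodes = [n for n in ids if model._by_id[n].node_type == "MG"]
    ng_nodes = [n for n in ids if model._by_id[n].node_type == "NG"]
    geno_seed = int(rng.integers(0, 2**31 - 1))
    if mg_nodes:
        # allele-level draw (same scheme as simulate_trio_genotypes) so
        # transmitted offspring SNPs reuse the maternal alleles
        grng = np.random.default_rng(geno_seed)
        m = len(mg_nodes)
        mafs = np.array([model.maf[n] for n in mg_nodes])
        a1 = grng.random((n_pairs, m)) < mafs
        a2 = grng.random((n_pairs, m)) < mafs
        pick_first = grng.random((n_pairs, m)) < 0.5
        transmitted = np.where(pick_first, a1, a2)
        for k, n in enumerate(mg_nodes):
            values[n] = (a1[:, k].astype(np.int64) + a2[:, k].astype(np.int64)).astype(float)
        for child in ng_nodes:
            mom = model.transmission.get(child)
            if mom is not None:
                k = mg_nodes.index(mom)
                paternal = rng.random(n_pairs) < model.maf[child]
                values[child] = transmitted[:, k].astype(float) + paternal.astype(float)
    for child in ng_nodes:
        if child not in values:  # unpaired offspring SNP: plain HWE draw
            values[child] = rng.binomial(2, model.maf[child], size=n_pairs).astype(float)

    covar_names = [f"cov{k + 1}" for k in range(n_covariates)]
    covars = pd.DataFrame(
        rng.normal(size=(n_pairs, n_covariates)), columns=covar_names
    )
    confounding: Dict[str, np.ndarray] = {}
    if covariate_effects:
        for (cov, node), coef in covariate_effects.items():
            confounding[node] = confounding.get(node, 0.0) + coef * covars[cov].to_numpy()

    for node in model.topological_order():
        if node in values:
            continue
        mu = np.full(n_pairs, model.intercepts.get(node, 0.0))
        for parent in model.parents(node):
            mu = mu + model.coefficient(parent, node) * values[parent]
        if node in confounding:
            mu = mu + confounding[node]
        sd = model.noise_sd[node]
        values[node] = mu + (rng.normal(0.0, sd, size=n_pairs) if sd > 0 else 0.0)

    pair_ids = [f"pair{i:05d}" for i in range(n_pairs)]

    def frame(node_filter) -> pd.DataFrame:
        cols = [n for n in ids if node_filter(model._by_id[n])]
        return pd.DataFrame({c: values[c] for c in cols}, index=range(n_pairs))

    props = rng.dirichlet(np.ones(n_strata) * 5.0)
    strata = pd.Series(
        rng.choice([f"grp{k + 1}" for k in range(n_strata)], size=n_pairs, p=props),
        name="stratum",
    )

    cohort = Cohort(
        pair_ids=pair_ids,
        maternal_genotypes=frame(lambda m: m.node_type == "MG"),
        offspring_genotypes=frame(lambda m: m.node_type == "NG"),
        maternal_metabolites_fasting=frame(
            lambda m: m.node_type == "MM" and m.timepoint == "fasting"
        ),
        maternal_metabolites_1hr=frame(
            lambda m: m.node_type == "MM" and m.timepoint == "1hr"
        ),
        cord_metabolites=frame(lambda m: m.node_type == "NM"),
        phenotypes=frame(lambda m: m.node_type in ("MP", "NP")),
        covariates=covars,
        strata=strata,
        meta=list(model.meta),
    )
    return cohort


def split_train_validation(
    cohort: Cohort,
    train_fraction: float,
    seed: int,
) -> Tuple[Cohort, Cohort]:
    """Stratified train/validation split.

    Within each ancestry stratum, ``round(train_fraction * size)`` pairs
    (half rounded up) go to training after a seeded shuffle; the two
    cohorts partition the input.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train_rows: List[int] = []
    valid_rows: List[int] = []
    labels = cohort.strata.to_numpy()
    for label in sorted(pd.unique(labels)):
        rows = np.flatnonzero(labels == label)
        if rows.size == 0:
            continue
        rows = rng.permutation(rows)
        n_train = int(np.floor(train_fraction * rows.size + 0.5))
        train_rows.extend(rows[:n_train].tolist())
        valid_rows.extend(rows[n_train:].tolist())
    if not train_rows or not valid_rows:
        raise ValueError("train_fraction produces an empty split")
    return cohort.subset(sorted(train_rows)), cohort.subset(sorted(valid_rows))


def true_serial_ide(model: TrueModel, path: Sequence[str]) -> float:
    """Ground-truth indirect effect: product of coefficients along the path."""
    if len(path) < 2:
        raise StructureError("path needs at least two nodes")
    out = 1.0
    for u, v in zip(path[:-1], path[1:]):
        out *= model.coefficient(u, v)
    return out


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

def seven_node_example_model(coef: float = 0.8) -> TrueModel:
    """Seven-node illustrative trio model.

    Two maternal genotypes (MG1, MG2), one fetal genotype at the MG1
    locus (FG1), two maternal metabolites (MMa, MMb) and two fetal
    metabolites (FMc, FMd); the joint density factors as a product of
    per-node conditionals.  Every drawn (non-transmission) edge has the
    stated coefficient.
    """
    meta = [
        NodeMeta("MG1", "MG", chromosome="2"),
        NodeMeta("MG2", "MG", chromosome="11"),
        NodeMeta("FG1", "NG", chromosome="2"),
        NodeMeta("MMa", "MM", timepoint="fasting", metabolite_class="AA"),
        NodeMeta("MMb", "MM", timepoint="fasting", metabolite_class="AC"),
        NodeMeta("FMc", "NM", timepoint="cord", metabolite_class="AA"),
        NodeMeta("FMd", "NM", timepoint="cord", metabolite_class="AC"),
    ]
    coefficients = {
        ("MG1", "MMa"): coef,
        ("MG2", "MMb"): coef,
        ("MMa", "FMc"): coef,
        ("MMb", "FMd"): coef,
        ("FMc", "FMd"): coef,
    }
    return TrueModel(
        meta=meta,
        coefficients=coefficients,
        noise_sd={n: 1.0 for n in ("MMa", "MMb", "FMc", "FMd")},
        intercepts={},
        maf={"MG1": 0.3, "MG2": 0.4, "FG1": 0.3},
        transmission={"FG1": "MG1"},
    )


def structure_recovery_model(coef: float = 0.8) -> TrueModel:
    """Twelve-node typed benchmark graph for structure recovery.

    Designed so that every true edge's reverse is either blocklisted
    (genotype ordering rules) or oriented by a collider, which is what
    makes exact orientation recoverable from observational Gaussian
    data.  All linear coefficients have magnitude ``coef``.
    """
    meta = [
        NodeMeta("mg1", "MG", chromosome="1"),
        NodeMeta("mg2", "MG", chromosome="2"),
        NodeMeta("mg3", "MG", chromosome="3"),
        NodeMeta("ng1", "NG", chromosome="1"),
        NodeMeta("ng2", "NG", chromosome="2"),
        NodeMeta("ng3", "NG", chromosome="3"),
        NodeMeta("mm1", "MM", timepoint="fasting", metabolite_class="AA"),
        NodeMeta("mm2", "MM", timepoint="fasting", metabolite_class="AC"),
        NodeMeta("nm1", "NM", timepoint="cord", metabolite_class="AA"),
        NodeMeta("nm2", "NM", timepoint="cord", metabolite_class="AC"),
        NodeMeta("np1", "NP", role="outcome"),
        NodeMeta("np2", "NP", role="outcome"),
    ]
    s = [1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0]
    coefficients = {
        ("mg1", "mm1"): s[0] * coef,
        ("mg2", "mm2"): s[1] * coef,
        ("ng1", "nm1"): s[2] * coef,
        ("ng2", "nm2"): s[3] * coef,
        ("mm1", "nm1"): s[4] * coef,
        ("mm2", "nm2"): s[5] * coef,
        ("nm1", "np1"): s[6] * coef,
        ("nm2", "np1"): s[7] * coef,
        ("nm1", "np2"): s[8] * coef,
        ("mm2", "np2"): s[9] * coef,
    }
    noise = {n: 1.0 for n in ("mm1", "mm2", "nm1", "nm2", "np1", "np2")}
    maf = {n: 0.3 for n in ("mg1", "mg2", "mg3", "ng1", "ng2", "ng3")}
    return TrueModel(
        meta=meta,
        coefficients=coefficients,
        noise_sd=noise,
        maf=maf,
        transmission={"ng1": "mg1", "ng2": "mg2", "ng3": "mg3"},
    )


def study_model(
    n_snp_pairs: int = 4,
    n_fasting: int = 6,
    n_1hr: int = 6,
    n_cord: int = 5,
    seed: int = 424242,
) -> TrueModel:
    """Small study-shaped model used by the pipeline demo.

    Maternal/offspring SNP pairs, fasting and 1-hr maternal
    metabolites, cord metabolites, two maternal exposure phenotypes and
    two newborn outcomes.  One serial mediation pathway per family is
    planted: SNP -> maternal metabolite -> cord metabolite -> outcome,
    alongside metabolite-metabolite dependencies of the kind that
    dominate the estimated networks.
    """
    rng = np.random.default_rng(seed)
    meta: List[NodeMeta] = []
    coefficients: Dict[Tuple[str, str], float] = {}
    noise: Dict[str, float] = {}
    maf: Dict[str, float] = {}
    transmission: Dict[str, str] = {}

    classes = ["AA", "AC", "CHO", "FA", "GC/TCA", "OA"]
    for k in range(n_snp_pairs):
        chrom = str(2 * k + 1)
        mg, ng = f"mg_snp{k + 1}", f"ng_snp{k + 1}"
        meta.append(NodeMeta(mg, "MG", chromosome=chrom))
        meta.append(NodeMeta(ng, "NG", chromosome=chrom))
        maf[mg] = maf[ng] = float(rng.uniform(0.2, 0.45))
        transmission[ng] = mg
    for k in range(n_fasting):
        n = f"mm_f{k + 1}"
        meta.append(NodeMeta(n, "MM", timepoint="fasting", metabolite_class=classes[k % len(classes)]))
        noise[n] = 1.0
    for k in range(n_1hr):
        n = f"mm_h{k + 1}"
        meta.append(NodeMeta(n, "MM", timepoint="1hr", metabolite_class=classes[k % len(classes)]))
        noise[n] = 1.0
    for k in range(n_cord):
        n = f"nm_c{k + 1}"
        meta.append(NodeMeta(n, "NM", timepoint="cord", metabolite_class=classes[k % len(classes)]))
        noise[n] = 1.0
    meta.append(NodeMeta("mp_bmi", "MP", role="exposure"))
    meta.append(NodeMeta("mp_glucose", "MP", role="exposure"))
    meta.append(NodeMeta("np_birthweight", "NP", role="outcome"))
    meta.append(NodeMeta("np_ssf", "NP", role="outcome"))
    noise.update({"mp_bmi": 1.0, "mp_glucose": 1.0, "np_birthweight": 1.0, "np_ssf": 1.0})

    # planted mediation pathways (one per metabolite family)
    coefficients[("mg_snp1", "mm_f1")] = 0.9
    coefficients[("mm_f1", "nm_c1")] = 0.6
    coefficients[("nm_c1", "np_birthweight")] = 0.6
    coefficients[("mg_snp2", "mm_h1")] = 0.9
    coefficients[("mm_h1", "nm_c2")] = 0.6
    coefficients[("nm_c2", "np_ssf")] = 0.6
    # within-class metabolite chains (fasting, 1hr, cord)
    for k in range(1, n_fasting):
        coefficients[(f"mm_f{k}", f"mm_f{k + 1}")] = 0.5
    for k in range(1, n_1hr):
        coefficients[(f"mm_h{k}", f"mm_h{k + 1}")] = 0.5
    for k in range(1, n_cord):
        coefficients[(f"nm_c{k}", f"nm_c{k + 1}")] = 0.5
    # maternal exposure phenotype into cord metabolism
    coefficients[("mp_glucose", "nm_c3")] = 0.5
    coefficients[("mp_bmi", "mp_glucose")] = 0.4
    return TrueModel(
        meta=meta,
        coefficients=coefficients,
        noise_sd=noise,
        maf=maf,
        transmission=transmission,
    )
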