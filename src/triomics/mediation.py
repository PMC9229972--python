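"""Serial mediation modeling with bootstrap inference.

For a candidate path X -> M1 -> ... -> Mk -> Y the serial mediator
model (PROCESS "Model 6" style, by ordinary least squares with
covariates in every equation) fits

    M_j = a-path:  M_j ~ X + M_1 .. M_{j-1} + covariates
    Y   = b-path:  Y   ~ X + M_1 .. M_k     + covariates
    Y   = reduced: Y   ~ X                  + covariates

The serial indirect effect (IDE) is the product of the chained
coefficients a1 * d21 * ... * b_k; the direct effect (DE) is the X
coefficient in the full outcome equation; the total effect (TE) is the
X coefficient of the reduced form; the proportion mediated is
PM = IDE / TE (which can exceed 1 or be negative).  Standard errors,
percentile confidence intervals and normal-approximation p-values for
the IDE come from resampling individuals with replacement.

Discovery/replication protocol: candidate paths are screened on the
training cohort (Benjamini-Hochberg adjusted IDE p < alpha within each
analysis family, positive PM) and survivors are refit on the held-out
validation cohort (nominal p < alpha, positive PM).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .paths import MediationPath


class SingularDesignError(ValueError):
    pass


class SampleSizeError(ValueError):
    pass


class UnstableFitError(RuntimeError):
    """More than the tolerated fraction of bootstrap replicates failed."""


# ---------------------------------------------------------------------------
# core chain fitting (single Gram matrix, all equations)
# ---------------------------------------------------------------------------

def _solve_eq(G: np.ndarray, pred: Sequence[int], resp: int) -> np.ndarray:
    """OLS coefficients for one equation from the full Gram matrix.

    An exactly singular design is tolerated only when the equation is
    deterministic (zero least-squares residual); the shared variance is
    then attributed to the rightmost independent predictors (mediator
    priority), which matches the full-mediation reading of a noiseless
    serial chain.  Otherwise numpy's LinAlgError propagates.
    """
    A = G[np.ix_(pred, pred)]
    b = G[pred, resp]
    scale = max(float(np.abs(A).max()), 1.0)
    try:
        beta = np.linalg.solve(A, b)
        if np.all(np.isfinite(beta)) and np.abs(A @ beta - b).max() <= 1e-6 * scale * max(
            1.0, float(np.abs(beta).max())
        ):
            return beta
    except np.linalg.LinAlgError:
        pass
    beta_mn = np.linalg.lstsq(A, b, rcond=None)[0]
    rss = float(G[resp, resp] - 2.0 * beta_mn @ b + beta_mn @ A @ beta_mn)
    if rss > 1e-8 * max(float(G[resp, resp]), 1.0):
        raise np.linalg.LinAlgError("singular design with nonzero residual")
    keep: List[int] = []
    for col in range(len(pred) - 1, -1, -1):  # rightmost first
        trial = keep + [col]
        if np.linalg.matrix_rank(A[np.ix_(trial, trial)]) == len(trial):
            keep = trial
    beta = np.zeros(len(pred))
    beta[keep] = np.linalg.solve(A[np.ix_(keep, keep)], b[keep])
    return beta


def _chain_from_gram(
    G: np.ndarray, k: int, q: int
) -> Tuple[np.ndarray, float, float]:
    """Chain coefficients, DE and TE from the Gram matrix of Z.

    Z columns are ordered [1, X, covariates (q), M_1..M_k, Y].  Raises
    LinAlgError on singular subdesigns.
    """
    x_col = 1
    med0 = 2 + q
    y_col = med0 + k
    chain = np.empty(k + 1)
    for j in range(k):
        pred = list(range(med0 + j))  # 1, X, covars, M_1..M_{j-1}
        beta = _solve_eq(G, pred, med0 + j)
        chain[j] = beta[x_col] if j == 0 else beta[med0 + j - 1]
    pred = list(range(med0 + k))
    beta = _solve_eq(G, pred, y_col)
    chain[k] = beta[med0 + k - 1]  # b_k
    de = float(beta[x_col])
    beta_red = _solve_eq(G, list(range(med0)), y_col)
    te = float(beta_red[x_col])
    return chain, de, te


def _design(
    path: Sequence[str], data: pd.DataFrame, covariates: Optional[pd.DataFrame]
) -> Tuple[np.ndarray, int, int]:
    """Assemble Z = [1, X, covars, mediators, Y] as a dense array."""
    nodes = list(path)
    if len(nodes) < 3:
        raise ValueError("a mediation path needs at least 3 nodes")
    missing = [c for c in nodes if c not in data.columns]
    if missing:
        raise KeyError(f"path nodes missing from data: {missing}")
    k = len(nodes) - 2
    n = len(data)
    if covariates is not None and covariates.shape[1] > 0:
        C = covariates.to_numpy(dtype=float)
        q = C.shape[1]
    else:
        C = np.empty((n, 0))
        q = 0
    X = data[nodes[0]].to_numpy(dtype=float)
    M = data[nodes[1:-1]].to_numpy(dtype=float)
    Y = data[nodes[-1]].to_numpy(dtype=float)
    Z = np.column_stack([np.ones(n), X, C, M, Y])
    n_params = 2 + q + k  # largest equation
    if n <= n_params:
        raise SampleSizeError(f"n={n} too small for {n_params} parameters")
    return Z, k, q


def fit_serial_chain(
    path: Sequence[str],
    data: pd.DataFrame,
    covariates: Optional[pd.DataFrame] = None,
) -> Tuple[List[float], float, float]:
    """Fit the serial chain; returns ([a1, d21, ..., b_k], de, te)."""
    Z, k, q = _design(path, data, covariates)
    G = Z.T @ Z
    try:
        chain, de, te = _chain_from_gram(G, k, q)
    except np.linalg.LinAlgError as exc:
        raise SingularDesignError(str(exc)) from exc
    return chain.tolist(), de, te


def serial_ide(coefficients: Sequence[float]) -> float:
    """Serial indirect effect: product of the chained coefficients."""
    if len(coefficients) == 0:
        raise ValueError("empty coefficient chain")
    return float(np.prod(np.asarray(coefficients, dtype=float)))


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------

@dataclass
class SMMResult:
    """Serial mediation estimates for one path with bootstrap inference."""

    path: MediationPath
    chain: List[float]
    ide: float
    de: float
    te: float
    pm: float
    pm_defined: bool
    ide_se: float
    ide_ci: Tuple[float, float]
    p_ide: float
    n_boot: int
    n_boot_failed: int
    seed: int
    p_adjusted: Optional[float] = None

    def summary(self) -> str:
        lo, hi = self.ide_ci
        pm_txt = f"{100 * self.pm:.2f}%" if self.pm_defined else "undefined (TE=0)"
        lines = [
            "Serial mediation: " + " -> ".join(self.path.node_ids),
            f"  IDE {self.ide:+.4e}  (95% CI {lo:+.4e} .. {hi:+.4e})",
            f"  DE  {self.de:+.4e}   TE {self.te:+.4e}   PM {pm_txt}",
            f"  bootstrap SE {self.ide_se:.4e}  p {self.p_ide:.4g}"
            + (f"  adj. p {self.p_adjusted:.4g}" if self.p_adjusted is not None else ""),
            f"  n_boot {self.n_boot} ({self.n_boot_failed} failed)  seed {self.seed}",
        ]
        return "\n".join(lines)


class SerialMediationModel:
    """Statsmodels-style wrapper: build from data, ``fit`` to bootstrap."""

    def __init__(
        self,
        data: pd.DataFrame,
        path: Sequence[str] | MediationPath,
        covariates: Optional[pd.DataFrame] = None,
    ):
        if isinstance(path, MediationPath):
            self.path = path
        else:
            self.path = MediationPath(tuple(path), source_type="", outcome=path[-1])
        self.data = data
        self.covariates = covariates

    def fit(
        self,
        n_boot: int = 1000,
        seed: int = 0,
        max_failed_fraction: float = 0.1,
    ) -> SMMResult:
        return bootstrap_smm(
            self.path,
            self.data,
            self.covariates,
            n_boot=n_boot,
            seed=seed,
            max_failed_fraction=max_failed_fraction,
        )


def bootstrap_smm(
    path: Sequence[str] | MediationPath,
    data: pd.DataFrame,
    covariates: Optional[pd.DataFrame] = None,
    n_boot: int = 1000,
    seed: int = 0,
    max_failed_fraction: float = 0.1,
) -> SMMResult:
    """Point estimates from the full sample; inference from resampling.

    The IDE point estimate does not depend on ``n_boot``; the bootstrap
    supplies its SE (replicate standard deviation), a 2.5/97.5
    percentile CI, and a two-sided normal-approximation p-value
    ``2 * Phi(-|ide| / se)``.  Replicates with singular designs are
    dropped; more than ``max_failed_fraction`` failures raises
    :class:`UnstableFitError`.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    mpath = path if isinstance(path, MediationPath) else MediationPath(
        tuple(path), source_type="", outcome=path[-1]
    )
    Z, k, q = _design(mpath.node_ids, data, covariates)
    n = Z.shape[0]
    try:
        chain, de, te = _chain_from_gram(Z.T @ Z, k, q)
    except np.linalg.LinAlgError as exc:
        raise SingularDesignError(str(exc)) from exc
    ide = serial_ide(chain)
    pm_defined = te != 0.0
    pm = ide / te if pm_defined else float("nan")

    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    failed = 0
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        Zb = Z[idx]
        try:
            chain_b, _, _ = _chain_from_gram(Zb.T @ Zb, k, q)
        except np.linalg.LinAlgError:
            reps[b] = np.nan
            failed += 1
            continue
        reps[b] = serial_ide(chain_b)
    if failed > max_failed_fraction * n_boot:
        raise UnstableFitError(f"{failed}/{n_boot} bootstrap replicates failed")
    good = reps[~np.isnan(reps)]
    se = float(np.std(good, ddof=1))
    lo, hi = (float(v) for v in np.percentile(good, [2.5, 97.5]))
    if se > 0:
        p = float(2.0 * stats.norm.sf(abs(ide) / se))
    else:
        p = 1.0 if ide == 0 else 5e-324
    p = min(max(p, 5e-324), 1.0)
    return SMMResult(
        path=mpath,
        chain=list(chain),
        ide=float(ide),
        de=float(de),
        te=float(te),
        pm=float(pm),
        pm_defined=pm_defined,
        ide_se=se,
        ide_ci=(lo, hi),
        p_ide=p,
        n_boot=n_boot,
        n_boot_failed=failed,
        seed=seed,
    )


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# discovery / replication
# ---------------------------------------------------------------------------

@dataclass
class MediationReport:
    """Two-stage discovery/replication results."""

    train_results: List[SMMResult]
    discovered: List[MediationPath]
    validation_results: List[SMMResult]
    validated: List[MediationPath]
    alpha_fdr: float
    alpha_nominal: float

    def to_frame(self) -> pd.DataFrame:
        """Table-style layout: training stats for all paths, validation for survivors."""
        vmap = {r.path.node_ids: r for r in self.validation_results}
        rows = []
        for r in self.train_results:
            v = vmap.get(r.path.node_ids)
            rows.append(
                {
                    "path": " -> ".join(r.path.node_ids),
                    "train_ide": r.ide,
                    "train_ci_low": r.ide_ci[0],
                    "train_ci_high": r.ide_ci[1],
                    "train_p_adj": r.p_adjusted,
                    "train_pm_pct": 100.0 * r.pm if r.pm_defined else np.nan,
                    "discovered": r.path in self.discovered,
                    "valid_ide": v.ide if v else np.nan,
                    "valid_ci_low": v.ide_ci[0] if v else np.nan,
                    "valid_ci_high": v.ide_ci[1] if v else np.nan,
                    "valid_p": v.p_ide if v else np.nan,
                    "valid_pm_pct": (100.0 * v.pm if v.pm_defined else np.nan) if v else np.nan,
                    "validated": r.path in self.validated,
                }
            )
        return pd.DataFrame(rows)


def discover_and_validate(
    paths: Sequence[MediationPath],
    train: pd.DataFrame,
    valid: pd.DataFrame,
    covariates_train: Optional[pd.DataFrame] = None,
    covariates_valid: Optional[pd.DataFrame] = None,
    alpha_fdr: float = 0.05,
    alpha_nominal: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
    families: Optional[Mapping[Tuple[str, ...], str]] = None,
    require_positive_pm: bool = True,
) -> MediationReport:
    """Training discovery then held-out replication.

    Stage 1 bootstraps every path on the training cohort and adjusts
    IDE p-values by Benjamini-Hochberg within each analysis family
    (e.g. fasting vs 1-hr networks; single family by default); paths
    with adjusted p < ``alpha_fdr`` and positive PM are discovered.
    Stage 2 refits survivors on the validation cohort; a path is
    validated iff its nominal p < ``alpha_nominal`` (and PM > 0 unless
    ``require_positive_pm`` is off).
    """
    paths = list(paths)
    if not paths:
        return MediationReport([], [], [], [], alpha_fdr, alpha_nominal)
    seeds = np.random.SeedSequence(seed).spawn(2 * len(paths))
    train_results: List[SMMResult] = []
    for i, p in enumerate(paths):
        train_results.append(
            bootstrap_smm(
                p, train, covariates_train, n_boot=n_boot,
                seed=int(seeds[i].generate_state(1)[0] % (2**31 - 1)),
            )
        )
    fam = {p.node_ids: (families[p.node_ids] if families else "all") for p in paths}
    for label in sorted(set(fam.values())):
        members = [r for r in train_results if fam[r.path.node_ids] == label]
        adj = bh_adjust([r.p_ide for r in members])
        for r, a in zip(members, adj):
            r.p_adjusted = float(a)
    discovered = [
        r.path
        for r in train_results
        if r.p_adjusted is not None
        and r.p_adjusted < alpha_fdr
        and (not require_positive_pm or (r.pm_defined and r.pm > 0))
    ]
    validation_results: List[SMMResult] = []
    validated: List[MediationPath] = []
    disc_set = {p.node_ids for p in discovered}
    for i, p in enumerate(paths):
        if p.node_ids not in disc_set:
            continue
        res = bootstrap_smm(
            p, valid, covariates_valid, n_boot=n_boot,
            seed=int(seeds[len(paths) + i].generate_state(1)[0] % (2**31 - 1)),
        )
        validation_results.append(res)
        if res.p_ide < alpha_nominal and (
            not require_positive_pm or (res.pm_defined and res.pm > 0)
        ):
            validated.append(p)
    return MediationReport(
        train_results=train_results,
        discovered=discovered,
        validation_results=validation_results,
        validated=validated,
        alpha_fdr=alpha_fdr,
        alpha_nominal=alpha_nominal,
    )
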