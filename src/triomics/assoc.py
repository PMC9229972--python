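"""Per-metabolite SNP association scan ("metabotyping") and LD trimming.

Each SNP is tested against each metabolite with an ordinary
least-squares regression of the (log/normalized) metabolite on additive
dosage plus covariates.  SNP x metabolite pairs passing a genome-wide
threshold (default p < 10^-7.5, slightly more inclusive than the usual
10^-8 because the downstream penalized network does its own selection)
are then LD-trimmed greedily per metabolite so the network stage
receives approximately independent signals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

DEFAULT_P_THRESHOLD = 10.0 ** -7.5

_TINY_P = 5e-324  # smallest positive float; keeps p in (0, 1] for exact fits


class MonomorphicSNPError(ValueError):
    """Dosage column is constant; the additive effect is not estimable."""


class SingularDesignError(ValueError):
    """Design matrix is rank deficient."""

    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(f"rank-deficient design; collinear columns: {self.columns}")


@dataclass(frozen=True)
class AssocRecord:
    """One SNP-metabolite association test."""

    snp_id: str
    metabolite_id: str
    beta: float
    se: float
    statistic: float
    p: float
    n_used: int


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> List[str]:
    """Names of columns with (near-)zero pivots in a pivoted QR."""
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    bad = [names[piv[k]] for k in range(len(diag)) if diag[k] <= tol]
    bad += [names[j] for j in piv[len(diag):]]
    return sorted(bad)


def fit_snp_metabolite(
    dosages: Sequence[float],
    metabolite: Sequence[float],
    covariates: Optional[pd.DataFrame] = None,
    snp_id: str = "snp",
    metabolite_id: str = "metabolite",
) -> AssocRecord:
    """OLS fit of metabolite on intercept + dosage + covariates.

    Rows with a missing metabolite value are dropped.  ``beta`` is the
    per-allele dosage coefficient and ``p`` the two-sided t-test
    p-value at residual degrees of freedom.
    """
    g = np.asarray(dosages, dtype=float)
    y = np.asarray(metabolite, dtype=float)
    if covariates is not None and len(covariates.columns) > 0:
        C = covariates.to_numpy(dtype=float)
        names = ["const", "dosage"] + list(covariates.columns)
    else:
        C = np.empty((len(g), 0))
        names = ["const", "dosage"]
    if not (len(g) == len(y) == len(C)):
        raise ValueError("dosages, metabolite and covariates must share length")
    keep = ~np.isnan(y)
    g, y, C = g[keep], y[keep], C[keep]
    if g.size == 0 or np.ptp(g) == 0.0:
        raise MonomorphicSNPError(f"{snp_id}: constant dosage")
    X = np.column_stack([np.ones(g.size), g, C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError(_collinear_columns(X, names))
    res = sm.OLS(y, X).fit()
    beta = float(res.params[1])
    se = float(res.bse[1])
    stat = beta / se if se > 0 else math.copysign(math.inf, beta)
    p = float(res.pvalues[1]) if se > 0 else 0.0
    return AssocRecord(
        snp_id=snp_id,
        metabolite_id=metabolite_id,
        beta=beta,
        se=max(se, 0.0),
        statistic=stat,
        p=max(p, _TINY_P),
        n_used=int(res.nobs),
    )


def run_metabotype_scan(
    genotypes: pd.DataFrame,
    metabolites: pd.DataFrame,
    covariates: Optional[pd.DataFrame] = None,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    keep_all: bool = False,
) -> List[AssocRecord]:
    """Scan every SNP x metabolite pair; keep tests with p < threshold.

    Per-fit failures (monomorphic SNPs, singular designs) are skipped
    with a logged warning.  With ``keep_all`` the complete scan is
    returned regardless of significance (for persistence/QQ review).
    """
    out: List[AssocRecord] = []
    for metab in metabolites.columns:
        y = metabolites[metab]
        for snp in genotypes.columns:
            try:
                rec = fit_snp_metabolite(
                    genotypes[snp], y, covariates, snp_id=snp, metabolite_id=metab
                )
            except (MonomorphicSNPError, SingularDesignError) as exc:
                logger.warning("skipping %s x %s: %s", snp, metab, exc)
                continue
            if keep_all or rec.p < p_threshold:
                out.append(rec)
    return out


def scan_to_frame(records: Sequence[AssocRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp": [r.snp_id for r in records],
            "metabolite": [r.metabolite_id for r in records],
            "beta": [r.beta for r in records],
            "se": [r.se for r in records],
            "stat": [r.statistic for r in records],
            "p": [r.p for r in records],
            "n": [r.n_used for r in records],
        }
    )


def ld_trim(
    snp_ids: Sequence[str],
    genotypes: pd.DataFrame,
    assoc: Sequence[AssocRecord],
    r2_threshold: float = 0.5,
) -> List[str]:
    """Greedy LD trim of one metabolite's significant SNPs.

    SNPs are visited in ascending p order (strongest signal first); a
    SNP is kept iff its squared dosage correlation with every
    already-kept SNP is below ``r2_threshold``.  The result is sorted
    by p.
    """
    if not (0.0 < r2_threshold <= 1.0):
        raise ValueError("r2_threshold must lie in (0, 1]")
    if not snp_ids:
        return []
    pmap = {r.snp_id: r.p for r in assoc}
    missing = [s for s in snp_ids if s not in pmap]
    if missing:
        raise ValueError(f"no association record for SNPs: {missing}")
    order = sorted(snp_ids, key=lambda s: (pmap[s], s))
    kept: List[str] = []
    for snp in order:
        x = genotypes[snp].to_numpy(dtype=float)
        ok = True
        for other in kept:
            r = np.corrcoef(x, genotypes[other].to_numpy(dtype=float))[0, 1]
            if r * r >= r2_threshold:
                ok = False
                break
        if ok:
            kept.append(snp)
    return kept
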