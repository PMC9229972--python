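"""End-to-end reproducible pipeline: simulate -> scan -> learn -> paths -> mediate -> report.

The pipeline runs the fasting and 1-hr metabolite families as separate
network analyses sharing genotype, cord-metabolite and phenotype
nodes.  All randomness flows from named per-stage seeds in the config;
a manifest (package version, config, seeds, output hashes) makes
reruns bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assoc import DEFAULT_P_THRESHOLD, ld_trim, run_metabotype_scan, scan_to_frame
from .cohort import Cohort, simulate_cohort, split_train_validation, study_model
from .dag import DEFAULT_LAMBDAS, GaussianDAGModel
from .io import write_cohort, write_edge_list, write_table, write_true_model
from .mediation import discover_and_validate
from .paths import extract_candidates, paths_to_frame
from .report import export_growth_frames, tally_path_to_frame

logger = logging.getLogger(__name__)

TRANSFORMS = {
    "identity": lambda x: x,
    "log10": np.log10,
    "sqrt": np.sqrt,
}


@dataclass
class PipelineConfig:
    """All tunable settings with the study's stated defaults."""

    n_pairs: int = 600
    train_fraction: float = 2.0 / 3.0
    p_threshold: float = DEFAULT_P_THRESHOLD
    ld_r2: float = 0.5
    lambdas: List[float] = field(default_factory=lambda: list(DEFAULT_LAMBDAS))
    penalty: str = "mcp"
    gamma: float = 2.0
    min_nodes: int = 3
    n_boot: int = 200
    alpha_fdr: float = 0.05
    alpha_nominal: float = 0.05
    seeds: Dict[str, int] = field(
        default_factory=lambda: {"simulate": 1, "split": 2, "mediate": 3}
    )
    covariate_columns: List[str] = field(default_factory=lambda: ["cov1", "cov2", "cov3"])
    transform_table: Dict[str, str] = field(default_factory=dict)
    export_plots: bool = False

    def validate(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must lie in (0, 1)")
        if any(b >= a for a, b in zip(self.lambdas, self.lambdas[1:])):
            raise ValueError("lambdas must be strictly decreasing")
        bad = [t for t in self.transform_table.values() if t not in TRANSFORMS]
        if bad:
            raise ValueError(f"unknown transforms: {bad}")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        cfg = cls(**data)
        cfg.validate()
        return cfg


def apply_transforms(df: pd.DataFrame, table: Dict[str, str]) -> pd.DataFrame:
    """Apply the configured phenotype transforms (identity/log10/sqrt)."""
    out = df.copy()
    for col, name in table.items():
        if col in out.columns:
            out[col] = TRANSFORMS[name](out[col])
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    cohort: Optional[Cohort] = None,
) -> Path:
    """Execute all stages; returns the artifact directory.

    When ``cohort`` is omitted, a study-shaped synthetic cohort is
    simulated from the packaged generative model.  Outputs: cohort
    TSVs, full scan + trimmed-hit TSVs, per-lambda edge lists and
    GraphML frames for both metabolite families, candidate-path TSVs,
    the two-stage mediation report, tally tables, and manifest.json.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    # stage log to file alongside stderr; excluded from the manifest
    # since log lines carry timestamps
    file_handler = logging.FileHandler(out_dir / "pipeline.log", mode="w")
    file_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(file_handler)
    written: List[Path] = []
    stage = "simulate"
    try:
        model = None
        if cohort is None:
            model = study_model()
            cohort = simulate_cohort(model, config.n_pairs, seed=config.seeds["simulate"])
            written += write_true_model(model, out_dir / "truth")
        written += write_cohort(cohort, out_dir / "cohort")
        meta = cohort.meta
        if meta is None:
            raise ValueError("cohort lacks node metadata")
        by_id = {m.node_id: m for m in meta}

        stage = "split"
        logger.info("stage: split (seeds=%s)", config.seeds)
        train, valid = split_train_validation(
            cohort, config.train_fraction, seed=config.seeds["split"]
        )

        stage = "scan"
        logger.info("stage: scan")
        covars = cohort.covariates[config.covariate_columns]
        scan_frames = []
        hits_by_family: Dict[str, List[str]] = {}
        for family, geno, metab, gmeta in (
            ("maternal_fasting", cohort.maternal_genotypes,
             cohort.maternal_metabolites_fasting, "MG"),
            ("maternal_1hr", cohort.maternal_genotypes,
             cohort.maternal_metabolites_1hr, "MG"),
            ("cord", cohort.offspring_genotypes, cohort.cord_metabolites, "NG"),
        ):
            if geno.shape[1] == 0 or metab.shape[1] == 0:
                continue
            records = run_metabotype_scan(
                geno, metab, covars, p_threshold=config.p_threshold, keep_all=True
            )
            df = scan_to_frame(records)
            df.insert(0, "family", family)
            scan_frames.append(df)
            sig = [r for r in records if r.p < config.p_threshold]
            kept: List[str] = []
            for metab_id in sorted({r.metabolite_id for r in sig}):
                snps = [r.snp_id for r in sig if r.metabolite_id == metab_id]
                kept += ld_trim(snps, geno, [r for r in sig if r.metabolite_id == metab_id],
                                r2_threshold=config.ld_r2)
            hits_by_family[family] = sorted(set(kept))
        scan_df = pd.concat(scan_frames, ignore_index=True) if scan_frames else pd.DataFrame()
        written.append(write_table(scan_df, out_dir / "scan_full.tsv"))
        selected_snps = sorted(set(sum(hits_by_family.values(), [])))
        written.append(
            write_table(pd.DataFrame({"snp": selected_snps}), out_dir / "scan_selected_snps.tsv")
        )

        stage = "learn"
        logger.info("stage: learn")
        reports = {}
        for timepoint in ("fasting", "1hr"):
            frame = train.analysis_frame(timepoint)
            frame = apply_transforms(frame, config.transform_table)
            fam_meta = [
                m for m in meta
                if m.node_id in frame.columns
                and (not m.is_genotype or m.node_id in selected_snps or not selected_snps)
            ]
            frame = frame[[m.node_id for m in fam_meta]]
            dag_model = GaussianDAGModel(
                frame, fam_meta, penalty=config.penalty, gamma=config.gamma
            )
            path_res = dag_model.fit_path(config.lambdas)
            fam_dir = out_dir / f"network_{timepoint}"
            fam_dir.mkdir(exist_ok=True)
            for lam in path_res.lambdas:
                written.append(
                    write_edge_list(path_res.models[lam], fam_dir / f"edges_lambda{lam:g}.tsv")
                )
            written += export_growth_frames(
                path_res, fam_meta, fam_dir / "frames", plot=config.export_plots
            )
            written.append(
                write_table(tally_path_to_frame(path_res, fam_meta), fam_dir / "edge_tally.tsv")
            )
            written.append(
                write_table(path_res.summary_frame(), fam_dir / "summary.tsv")
            )
            summary_json = fam_dir / "summary.json"
            summary_json.write_text(
                json.dumps(
                    path_res.summary_frame().to_dict(orient="records"), indent=2
                )
            )
            written.append(summary_json)

            stage = "paths"
            lowest = path_res.models[min(path_res.lambdas)]
            candidates = extract_candidates(lowest, fam_meta, min_nodes=config.min_nodes)
            written.append(
                write_table(paths_to_frame(candidates), fam_dir / "candidate_paths.tsv")
            )
            reports[timepoint] = (fam_meta, candidates)

        stage = "mediate"
        logger.info("stage: mediate")
        all_paths = []
        families = {}
        for timepoint, (_, candidates) in reports.items():
            for p in candidates:
                all_paths.append(p)
                families[p.node_ids] = timepoint
        train_covars = train.covariates[config.covariate_columns]
        valid_covars = valid.covariates[config.covariate_columns]
        tr_frames = {tp: apply_transforms(train.analysis_frame(tp), config.transform_table)
                     for tp in ("fasting", "1hr")}
        va_frames = {tp: apply_transforms(valid.analysis_frame(tp), config.transform_table)
                     for tp in ("fasting", "1hr")}
        # all node columns exist in both family frames' union; mediate on a merged frame
        tr_all = pd.concat(
            [tr_frames["fasting"],
             tr_frames["1hr"].drop(columns=tr_frames["fasting"].columns, errors="ignore")],
            axis=1,
        )
        va_all = pd.concat(
            [va_frames["fasting"],
             va_frames["1hr"].drop(columns=va_frames["fasting"].columns, errors="ignore")],
            axis=1,
        )
        report = discover_and_validate(
            all_paths, tr_all, va_all,
            covariates_train=train_covars, covariates_valid=valid_covars,
            alpha_fdr=config.alpha_fdr, alpha_nominal=config.alpha_nominal,
            n_boot=config.n_boot, seed=config.seeds["mediate"],
            families=families,
        )
        written.append(write_table(report.to_frame(), out_dir / "mediation_report.tsv"))

        stage = "manifest"
        logger.info("stage: manifest")
        manifest = {
            "triomics_version": __version__,
            "config": dataclasses.asdict(config),
            "outputs": {
                str(p.relative_to(out_dir)): _sha256(p)
                for p in sorted(written)
                if p.suffix != ".png"
            },
        }
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
    except Exception as exc:
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(file_handler)
        file_handler.close()
    logger.info("pipeline complete: %d outputs in %s", len(written), out_dir)
    return out_dir
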