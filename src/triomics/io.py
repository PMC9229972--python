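"""Readers and writers for the pipeline's standard formats.

Genotypes: TSV sample x SNP dosage matrices, or VCF with a DS FORMAT
field (GT hard calls summed when DS is absent; parsed with cyvcf2).
Everything else is plain TSV; networks are GraphML via networkx.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import Cohort, TrueModel
from .nodes import NodeMeta, meta_from_frame, meta_to_frame

FLOAT_FMT = "%.10g"  # stable text representation for reproducible reruns


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_node_meta(meta: Sequence[NodeMeta], path: str | Path) -> Path:
    return write_table(meta_to_frame(meta), path)


def read_node_meta(path: str | Path) -> List[NodeMeta]:
    return meta_from_frame(pd.read_csv(path, sep="\t", keep_default_na=False))


def write_vcf_dosages(
    genotypes: pd.DataFrame,
    chromosomes: Sequence[str],
    path: str | Path,
) -> Path:
    """Minimal single-sample-per-column VCF with GT+DS fields.

    ``genotypes`` is sample x SNP; dosages in [0, 2].  Positions are
    synthetic (1-based SNP order); hard-call GT is derived by rounding.
    """
    path = Path(path)
    snps = list(genotypes.columns)
    if len(chromosomes) != len(snps):
        raise ValueError("need one chromosome per SNP column")
    samples = [str(s) for s in genotypes.index]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted(set(str(c) for c in chromosomes)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for k, snp in enumerate(snps):
            ds = genotypes[snp].to_numpy(dtype=float)
            fields = []
            for d in ds:
                hard = int(round(d))
                gt = {0: "0/0", 1: "0/1", 2: "1/1"}.get(hard, "./.")
                fields.append(f"{gt}:{d:g}")
            fh.write(
                f"{chromosomes[k]}\t{k + 1}\t{snp}\tA\tG\t.\tPASS\t.\tGT:DS\t" + "\t".join(fields) + "\n"
            )
    return path


def read_genotypes(
    path: str | Path, fmt: Optional[str] = None
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Read a genotype matrix; returns (sample x SNP dosages, SNP metadata).

    ``fmt`` is "vcf" or "tsv"; inferred from the suffix when omitted.
    VCF uses the DS field when present, otherwise summed GT alleles.
    TSV must have samples as rows and SNPs as columns; a ``sample``
    first column is used as the index when present.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix in (".vcf", ".gz", ".bcf") else "tsv"
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t")
        if df.columns[0].lower() in ("sample", "sample_id", "pair_id"):
            df = df.set_index(df.columns[0])
        snp_meta = pd.DataFrame({"snp": df.columns, "chromosome": ""})
        return df, snp_meta
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    dosages = {}
    chroms = []
    for var in vcf:
        snp = var.ID or f"{var.CHROM}:{var.POS}"
        ds_arr = var.format("DS")
        if ds_arr is not None:
            ds = np.asarray(ds_arr, dtype=float).ravel()
        else:
            ds = np.array([g[0] + g[1] for g in var.genotypes], dtype=float)
        dosages[snp] = ds
        chroms.append(str(var.CHROM))
    df = pd.DataFrame(dosages, index=samples)
    snp_meta = pd.DataFrame({"snp": list(dosages), "chromosome": chroms})
    return df, snp_meta


def write_cohort(cohort: Cohort, out_dir: str | Path, vcf: bool = False) -> List[Path]:
    """Write all cohort matrices as TSVs (plus optional genotype VCFs)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    def _write(df: pd.DataFrame, name: str) -> None:
        out = df.copy()
        out.insert(0, "pair_id", cohort.pair_ids)
        written.append(write_table(out, out_dir / name))

    _write(cohort.maternal_genotypes, "maternal_genotypes.tsv")
    _write(cohort.offspring_genotypes, "offspring_genotypes.tsv")
    _write(cohort.maternal_metabolites_fasting, "maternal_metabolites_fasting.tsv")
    _write(cohort.maternal_metabolites_1hr, "maternal_metabolites_1hr.tsv")
    _write(cohort.cord_metabolites, "cord_metabolites.tsv")
    _write(cohort.phenotypes, "phenotypes.tsv")
    _write(cohort.covariates, "covariates.tsv")
    _write(cohort.strata.to_frame(), "strata.tsv")
    if cohort.meta is not None:
        written.append(write_node_meta(cohort.meta, out_dir / "node_meta.tsv"))
    if vcf and cohort.meta is not None:
        by_id = {m.node_id: m for m in cohort.meta}
        for name, df in (
            ("maternal_genotypes.vcf", cohort.maternal_genotypes),
            ("offspring_genotypes.vcf", cohort.offspring_genotypes),
        ):
            if df.shape[1]:
                gm = df.copy()
                gm.index = cohort.pair_ids
                chroms = [by_id[c].chromosome or "1" for c in df.columns]
                written.append(write_vcf_dosages(gm, chroms, out_dir / name))
    return written


def write_true_model(model: TrueModel, out_dir: str | Path) -> List[Path]:
    """Ground truth as GraphML (structure) + JSON (coefficients etc.)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    g = nx.DiGraph()
    for m in model.meta:
        g.add_node(m.node_id, node_type=m.node_type, timepoint=m.timepoint)
    for (u, v) in model.dag_edges():
        g.add_edge(u, v, weight=model.coefficient(u, v))
    gml = out_dir / "true_model.graphml"
    nx.write_graphml(g, gml)
    payload = {
        "coefficients": {f"{u}->{v}": c for (u, v), c in model.coefficients.items()},
        "transmission": model.transmission,
        "noise_sd": model.noise_sd,
        "intercepts": model.intercepts,
        "maf": model.maf,
    }
    js = out_dir / "true_model.json"
    js.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return [gml, js]


def write_edge_list(dag_results, path: str | Path) -> Path:
    rows = pd.DataFrame(
        [(u, v, w) for u, v, w in dag_results.edges()],
        columns=["parent", "child", "weight"],
    )
    return write_table(rows, path)
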