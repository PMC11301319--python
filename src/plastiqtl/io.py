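"""Readers and writers for the pipeline's external formats.

Genotypes come in as VCF v4.x with a GT field (RIL homozygotes 0/0 and
1/1, residual heterozygote 0/1, missing ./.), phenotypes as a long CSV
(ril_id, treatment, replicate, week, leaf_number).  Scan results and
module tables go out as TSV, module member SNPs as 0-based half-open
BED.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .cofunmap import ScanResult
from .growth import LogisticParams, TimeGrid
from .plasticity import TREATMENTS
from .simdata import MISSING, RILGenotypes

logger = logging.getLogger("plastiqtl")

__all__ = [
    "read_genotypes",
    "read_phenotypes",
    "scan_table_with_params",
    "write_scan_tsv",
    "gsd_matrix_from_scan_table",
    "write_members_bed",
]


def read_genotypes(path) -> RILGenotypes:
    """Read a biallelic-SNP VCF into the coded genotype matrix.

    GT calls map 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2, ./. -> -9.
    Multi-allelic records are skipped (count recorded on the result);
    positions stay 1-based as in the file.
    """
    vcf = VCF(str(path))
    ril_ids = list(vcf.samples)
    chroms, poss, rows = [], [], []
    n_skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_skipped += 1
            continue
        if "GT" not in variant.FORMAT:
            raise ValueError(f"record {variant.CHROM}:{variant.POS} lacks GT")
        codes = np.empty(len(ril_ids), dtype=np.int8)
        for i, g in enumerate(variant.genotypes):
            a, b = g[0], g[1]
            codes[i] = MISSING if (a < 0 or b < 0) else a + b
        chroms.append(variant.CHROM)
        poss.append(variant.POS)
        rows.append(codes)
    vcf.close()
    if not rows:
        raise ValueError(f"no usable biallelic records in {path}")
    if n_skipped:
        logger.info("skipped %d multi-allelic records in %s", n_skipped, path)
    return RILGenotypes(
        codes=np.stack(rows),
        chrom=np.asarray(chroms),
        pos=np.asarray(poss, dtype=float),
        ril_ids=ril_ids,
        n_skipped_multiallelic=n_skipped,
    )


def read_phenotypes(path, grid: TimeGrid) -> pd.DataFrame:
    """Read and validate the long phenotype CSV.

    Rejects unknown treatment labels, week values off the configured
    grid, duplicated (ril, treatment, replicate, week) rows and empty
    files.
    """
    raw = pd.read_csv(path)
    if raw.empty:
        raise ValueError(f"phenotype file {path} is empty")
    required = ["ril_id", "treatment", "replicate", "week", "leaf_number"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValueError(f"phenotype file lacks columns {missing}")
    bad_treat = set(raw["treatment"].unique()) - set(TREATMENTS)
    if bad_treat:
        raise ValueError(f"unknown treatment labels {sorted(bad_treat)}")
    weeks = raw["week"]
    if not np.issubdtype(weeks.dtype, np.number) or (weeks != weeks.astype(int)).any():
        raise ValueError("week column must hold integers")
    allowed = {int(w) for w in grid.values}
    off_grid = set(weeks.astype(int).unique()) - allowed
    if off_grid:
        raise ValueError(f"week values {sorted(off_grid)} outside the grid {sorted(allowed)}")
    dup = raw.duplicated(subset=["ril_id", "treatment", "replicate", "week"])
    if dup.any():
        raise ValueError(f"{int(dup.sum())} duplicated (ril, treatment, replicate, week) rows")
    return raw


_CLASS_COLS = ("a_x", "b_x", "r_x", "a_y", "b_y", "r_y")


def scan_table_with_params(result: ScanResult) -> pd.DataFrame:
    """Scan table augmented with fitted per-genotype curve and SAD(1) params."""
    table = result.table.copy()
    theta = result.theta
    table["phi_x"] = np.tanh(theta[:, 0])
    table["nu2_x"] = np.exp(theta[:, 1])
    table["phi_y"] = np.tanh(theta[:, 2])
    table["nu2_y"] = np.exp(theta[:, 3])
    for c in range(3):
        table[f"n_g{c}"] = result.class_counts[:, c]
        params = np.exp(result.curve_logparams[:, c, :])
        for k, name in enumerate(_CLASS_COLS):
            table[f"{name}_g{c}"] = params[:, k]
    return table


def write_scan_tsv(result: ScanResult, path) -> pd.DataFrame:
    table = scan_table_with_params(result)
    table.to_csv(path, sep="\t", index=False, float_format="%.8g")
    return table


def gsd_matrix_from_scan_table(table: pd.DataFrame, grid: TimeGrid) -> tuple:
    """Rebuild GSD curves from a (filtered) scan TSV with fitted params.

    Returns (curves (S, T) array, snp ids).  Rows whose per-class
    parameters are absent (J < 2) get zero curves.
    """
    t = grid.values
    curves, ids = [], []
    for row in table.itertuples():
        mus, ws = [], []
        for c in range(3):
            n_c = getattr(row, f"n_g{c}")
            ax = getattr(row, f"a_x_g{c}")
            if n_c <= 0 or not np.isfinite(ax):
                continue
            px = LogisticParams(ax, getattr(row, f"b_x_g{c}"), getattr(row, f"r_x_g{c}"))
            py = LogisticParams(
                getattr(row, f"a_y_g{c}"), getattr(row, f"b_y_g{c}"), getattr(row, f"r_y_g{c}")
            )
            fx = px.a / (1 + px.b * np.exp(-px.r * t))
            fy = py.a / (1 + py.b * np.exp(-py.r * t))
            mus.append(fx - fy)
            ws.append(float(n_c))
        if len(mus) < 2:
            curves.append(np.zeros(len(grid)))
        else:
            mus = np.stack(mus)
            w = np.asarray(ws) / np.sum(ws)
            var = np.clip(w @ mus**2 - (w @ mus) ** 2, 0.0, None)
            curves.append(np.sqrt(var))
        ids.append(row.snp)
    return np.stack(curves), ids


def write_members_bed(table: pd.DataFrame, assignments, snp_ids, path) -> None:
    """0-based half-open BED of module member SNPs (name = snp, score = module)."""
    lookup = table.set_index("snp")
    with open(path, "w") as fh:
        for sid, module in zip(snp_ids, assignments):
            row = lookup.loc[sid]
            pos = int(row["pos"])
            fh.write(f"{row['chrom']}\t{pos - 1}\t{pos}\tsnp{sid}\t{int(module)}\n")
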