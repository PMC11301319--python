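"""Pipeline configuration and orchestration.

Binds the stages end to end: read genotypes and phenotypes, average
replicates, fit treatment mean curves, build the requested plasticity
contrasts, scan each contrast with permutation calibration, cluster the
significant QTLs of each contrast into modules, and write a report
bundle (TSV tables, BED exports, run-metadata JSON).

All stochastic stages take seeds derived from a single master seed by
fixed offsets; permutation maxima are cached under the output directory
keyed by a content hash of their inputs so an interrupted run can
resume without redoing permutations.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cofunmap import ScanConfig, ScanResult, permutation_threshold, scan
from .funclust import module_effect_summary, select_modules
from .growth import TimeGrid, fit_treatment_mean_curves
from .io import (
    gsd_matrix_from_scan_table,
    read_genotypes,
    read_phenotypes,
    scan_table_with_params,
    write_members_bed,
)
from .plasticity import (
    CONTRASTS,
    asymptotic_summary,
    average_replicates,
    compute_plasticity,
    test_contrasts,
)

logger = logging.getLogger("plastiqtl")

__all__ = ["PipelineConfig", "run_pipeline"]

# fixed per-stage seed offsets derived from the master seed
_SEED_SCAN = 1_000
_SEED_CLUSTER = 2_000


@dataclass
class PipelineConfig:
    vcf: str
    phenotypes: str
    outdir: str
    weeks: int = 8
    contrasts: list = field(default_factory=lambda: list(CONTRASTS))
    comparisons: list | None = None  # pairwise Welch family; None = defaults
    alpha: float = 0.05
    n_perm: int = 100
    n_min: int = 5
    seed: int = 1
    cluster_L_range: list = field(default_factory=lambda: [1, 2, 3, 4, 5, 6])
    cluster_order: int = 4
    cluster_starts: int = 10

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 20:
            raise ValueError("n_perm must be >= 20")
        unknown = set(self.contrasts) - set(CONTRASTS)
        if unknown:
            raise ValueError(f"unknown contrast names {sorted(unknown)}")
        if self.comparisons is not None:
            self.comparisons = [tuple(pair) for pair in self.comparisons]
            bad = [p for p in self.comparisons
                   if len(p) != 2 or not set(p) <= set(self.contrasts)]
            if bad:
                raise ValueError(f"invalid comparison pairs {bad}")
        if self.seed < 0 or self.seed >= 2**30:
            raise ValueError("seed must be in [0, 2^30)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    @property
    def grid(self) -> TimeGrid:
        return TimeGrid.weekly(self.weeks)


def _content_hash(*parts) -> str:
    h = hashlib.sha256()
    for p in parts:
        if isinstance(p, np.ndarray):
            h.update(np.ascontiguousarray(p).tobytes())
        else:
            h.update(str(p).encode())
    return h.hexdigest()[:24]


def cached_permutation_maxima(
    trait, genotypes, grid, cfg: ScanConfig, cache_dir: Path
) -> np.ndarray:
    """Permutation maxima for one contrast, cached by content hash."""
    key = _content_hash(
        np.asarray(genotypes.codes),
        trait.values,
        trait.name,
        cfg.alpha,
        cfg.n_perm,
        cfg.n_min,
        cfg.seed,
        cfg.settings,
    )
    cache_dir.mkdir(parents=True, exist_ok=True)
    path = cache_dir / f"perm_{key}.npz"
    if path.exists():
        logger.info("reusing cached permutation maxima %s", path.name)
        return np.load(path)["maxima"]
    record = permutation_threshold(
        trait,
        genotypes,
        grid,
        n_perm=cfg.n_perm,
        alpha=cfg.alpha,
        seed=cfg.seed,
        settings=cfg.settings,
    )
    np.savez(path, maxima=record.maxima)
    return record.maxima


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns result objects.

    Deterministic given the config seeds: identical configs produce
    byte-identical TSV outputs.  Every dropped SNP or RIL is logged with
    a machine-readable reason code in the metadata JSON.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = config.grid
    exclusions: list[dict] = []

    genotypes = read_genotypes(config.vcf)
    if genotypes.n_skipped_multiallelic:
        exclusions.append(
            {
                "stage": "read_genotypes",
                "reason": "multiallelic_record",
                "count": genotypes.n_skipped_multiallelic,
            }
        )
    raw = read_phenotypes(config.phenotypes, grid)
    panels = average_replicates(raw, grid)
    for treatment, panel in panels.items():
        dropped = sorted(set(raw[raw.treatment == treatment].ril_id) - set(panel.ril_ids))
        for r in dropped:
            exclusions.append(
                {
                    "stage": "average_replicates",
                    "reason": "ril_missing_week",
                    "treatment": treatment,
                    "ril_id": str(r),
                }
            )

    mean_fits = fit_treatment_mean_curves(panels, grid)
    pd.DataFrame(
        [
            {
                "treatment": tr,
                "a": fit.params.a,
                "b": fit.params.b,
                "r": fit.params.r,
                "rss": fit.rss,
                "converged": fit.success,
            }
            for tr, fit in mean_fits.items()
        ]
    ).to_csv(outdir / "treatment_mean_curves.tsv", sep="\t", index=False,
             float_format="%.8g")

    asymptotic_summary(panels, grid).to_csv(
        outdir / "asymptotic_summary.tsv", sep="\t", index=False, float_format="%.8g"
    )

    traits = {name: compute_plasticity(name, panels) for name in config.contrasts}
    test_contrasts(traits, grid, comparisons=config.comparisons).to_csv(
        outdir / "contrast_tests.tsv", sep="\t", index=False, float_format="%.8g"
    )

    scans: dict[str, ScanResult] = {}
    modules: dict[str, dict] = {}
    for name, trait in traits.items():
        scan_cfg = ScanConfig(
            alpha=config.alpha,
            n_perm=config.n_perm,
            n_min=config.n_min,
            seed=config.seed + _SEED_SCAN,
        )
        maxima = cached_permutation_maxima(
            trait, genotypes, grid, scan_cfg, outdir / "cache"
        )
        result = scan(trait, genotypes, grid, scan_cfg, maxima=maxima)
        scans[name] = result
        table = scan_table_with_params(result)
        table.to_csv(outdir / f"scan_{name}.tsv", sep="\t", index=False,
                     float_format="%.8g")
        result.manhattan().to_csv(
            outdir / f"manhattan_{name}.tsv", sep="\t", index=False,
            float_format="%.8g"
        )
        for row in result.table[~result.table["usable"]].itertuples():
            exclusions.append(
                {
                    "stage": "scan",
                    "contrast": name,
                    "reason": "no_class_passes_n_min",
                    "snp": int(row.snp),
                }
            )

        sig = table[table["significant"] & table["usable"]]
        if len(sig) < 2:
            logger.info("contrast %s: %d significant SNPs, skipping clustering",
                        name, len(sig))
            continue
        curves, ids = gsd_matrix_from_scan_table(sig, grid)
        L_range = [L for L in config.cluster_L_range if L <= len(ids)]
        best_L, solutions, bic_table = select_modules(
            curves,
            L_range,
            seed=config.seed + _SEED_CLUSTER,
            order=config.cluster_order,
            n_starts=config.cluster_starts,
        )
        sol = solutions[best_L]
        modules[name] = {"best_L": best_L, "solution": sol, "bic": bic_table}
        bic_table.to_csv(outdir / f"bic_{name}.tsv", sep="\t", index=False,
                         float_format="%.8g")
        assign = pd.DataFrame({"snp": ids, "module": sol.assignments})
        assign.to_csv(outdir / f"modules_{name}.tsv", sep="\t", index=False)
        module_effect_summary(sol, curves).assign(contrast=name).to_csv(
            outdir / f"module_curves_{name}.tsv", sep="\t", index=False,
            float_format="%.8g"
        )
        write_members_bed(table, sol.assignments, ids, outdir / f"modules_{name}.bed")

    meta = {
        "package": "plastiqtl",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": asdict(config),
        "threshold": {
            name: {
                "threshold": scans[name].threshold.threshold,
                "alpha": scans[name].threshold.alpha,
                "n_perm": scans[name].threshold.n_perm,
            }
            for name in scans
        },
        "n_significant": {
            name: int(scans[name].table["significant"].sum()) for name in scans
        },
        "best_modules": {name: modules[name]["best_L"] for name in modules},
        "exclusions": exclusions,
        "decisions": [
            "pairwise tests: Welch t with Benjamini-Hochberg adjustment",
            "asymptote estimator: fitted logistic a, final-week fallback",
            "permutation unit: whole RIL phenotype vector",
            "threshold: empirical upper quantile of genome-wide max LR",
        ],
    }
    with open(outdir / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
    return {"panels": panels, "traits": traits, "scans": scans, "modules": modules}
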