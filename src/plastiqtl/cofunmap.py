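"""Functional mapping of plasticity QTLs (the coFunMap scan).

A plasticity trait z_i is a T-vector per RIL (difference of two
trajectories).  At SNP s with J_s observed genotype classes, the trait is
modelled as multivariate normal with

* class mean = difference of two logistic curves (six parameters per
  class, one logistic per source environment), and
* a single shared residual covariance Sigma_s = SAD(1) + SAD(1), one
  antedependence block per source environment, the two environments
  being treated as independent.

The no-QTL null collapses all classes onto one mean curve.  The test
statistic is LR = 2(logL1 - logL0); genome-wide significance is
calibrated by permutation: whole RIL phenotype vectors are reshuffled
against genotype rows, the scan re-run, and the genome-wide maximum LR
recorded, with the threshold taken as the upper quantile of those
maxima (Churchill–Doerge style).  Per-SNP asymptotic chi-square P values
are deliberately not used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._engine import (
    EngineSettings,
    ScanEngine,
    composite_sigma,
    difflog6_eval,
)
from .growth import LogisticParams, TimeGrid
from .plasticity import PlasticityTrait
from .sad import SAD1Params, sad1_covariance

__all__ = [
    "SAD1Params",
    "CompositeCovariance",
    "composite_covariance",
    "GenotypeClassFit",
    "GenotypeModel",
    "NullFit",
    "ScanConfig",
    "ScanResult",
    "ThresholdRecord",
    "fit_null",
    "fit_alternative",
    "lr_statistic",
    "permutation_threshold",
    "quantile_threshold",
    "scan",
    "gaussian_loglik",
]

_POLISH = EngineSettings(h0_rounds=4, h0_adam=300, h1_rounds=4, h1_adam=200, gn_iters=60)


@dataclass(frozen=True)
class CompositeCovariance:
    """Sigma = SAD(1; x-environment) + SAD(1; y-environment)."""

    params_x: SAD1Params
    params_y: SAD1Params
    matrix: np.ndarray

    @property
    def n_times(self) -> int:
        return self.matrix.shape[0]


def composite_covariance(px: SAD1Params, py: SAD1Params, grid) -> CompositeCovariance:
    """Elementwise sum of the two environment SAD(1) covariance matrices."""
    mat = sad1_covariance(px, grid) + sad1_covariance(py, grid)
    return CompositeCovariance(px, py, mat)


@dataclass(frozen=True)
class GenotypeClassFit:
    code: int
    n: int
    params_x: LogisticParams
    params_y: LogisticParams

    def mean_curve(self, grid: TimeGrid) -> np.ndarray:
        """Fitted plasticity mean curve of the class over the grid."""
        t = grid.values
        fx = self.params_x.a / (1 + self.params_x.b * np.exp(-self.params_x.r * t))
        fy = self.params_y.a / (1 + self.params_y.b * np.exp(-self.params_y.r * t))
        return fx - fy


@dataclass
class GenotypeModel:
    """Fitted per-genotype mean curves and the shared composite covariance."""

    snp_index: int
    classes: list[GenotypeClassFit]
    covariance: CompositeCovariance

    @property
    def n(self) -> int:
        return sum(c.n for c in self.classes)

    @property
    def J(self) -> int:
        return len(self.classes)


@dataclass
class NullFit:
    params_x: LogisticParams
    params_y: LogisticParams
    covariance: CompositeCovariance
    loglik: float

    def mean_curve(self, grid: TimeGrid) -> np.ndarray:
        t = grid.values
        fx = self.params_x.a / (1 + self.params_x.b * np.exp(-self.params_x.r * t))
        fy = self.params_y.a / (1 + self.params_y.b * np.exp(-self.params_y.r * t))
        return fx - fy


@dataclass(frozen=True)
class ScanConfig:
    alpha: float = 0.05
    n_perm: int = 100
    n_min: int = 5
    seed: int = 0
    settings: EngineSettings = field(default_factory=EngineSettings)

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 20:
            raise ValueError("n_perm must be at least 20")
        if int(np.floor(self.alpha * self.n_perm)) < 1:
            raise ValueError(
                f"n_perm={self.n_perm} too small to estimate the "
                f"{1 - self.alpha:.3f} quantile; increase n_perm or alpha"
            )


@dataclass
class ThresholdRecord:
    threshold: float
    maxima: np.ndarray
    alpha: float
    n_perm: int
    seed: int


@dataclass
class ScanResult:
    table: pd.DataFrame
    grid: TimeGrid
    threshold: ThresholdRecord
    curve_logparams: np.ndarray  # (M, 3, 6)
    theta: np.ndarray            # (M, 4)
    class_counts: np.ndarray     # (M, 3)

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def genotype_model(self, snp_index: int) -> GenotypeModel:
        """Reconstruct the fitted per-genotype model for one SNP."""
        counts = self.class_counts[snp_index]
        classes = []
        for c in range(3):
            if counts[c] <= 0 or not np.isfinite(self.curve_logparams[snp_index, c, 0]):
                continue
            ax, bx, rx, ay, by, ry = np.exp(self.curve_logparams[snp_index, c])
            classes.append(
                GenotypeClassFit(
                    c,
                    int(counts[c]),
                    LogisticParams(ax, bx, rx),
                    LogisticParams(ay, by, ry),
                )
            )
        cov = _theta_to_cov(self.theta[snp_index], len(self.grid))
        return GenotypeModel(snp_index, classes, cov)

    def manhattan(self) -> pd.DataFrame:
        """Manhattan-ready export: chrom, pos, -log10 empirical P."""
        eps = 0.5 / max(self.threshold.n_perm, 1)
        out = self.table[["chrom", "pos"]].copy()
        out["neglog10_p"] = -np.log10(np.clip(self.table["p_emp"], eps, 1.0))
        return out


def _theta_to_cov(theta: np.ndarray, T: int) -> CompositeCovariance:
    px = SAD1Params(float(np.tanh(theta[0])), float(np.exp(theta[1])))
    py = SAD1Params(float(np.tanh(theta[2])), float(np.exp(theta[3])))
    return composite_covariance(px, py, T)


def gaussian_loglik(Z: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> float:
    """Sum of T-variate normal log densities of rows of Z around mu.

    ``mu`` may be one curve (T,) or one per row (n, T).  Used for
    optimality spot checks against the fitted likelihoods.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    resid = Z - np.atleast_2d(mu)
    T = Z.shape[1]
    chol = np.linalg.cholesky(sigma)
    logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
    w = np.linalg.solve(chol, resid.T)
    quad = float(np.sum(w * w))
    return -0.5 * (Z.shape[0] * (T * np.log(2 * np.pi) + logdet) + quad)


def _aligned_arrays(trait: PlasticityTrait, genotypes) -> tuple:
    geno_index = {r: i for i, r in enumerate(genotypes.ril_ids)}
    shared = [r for r in trait.ril_ids if r in geno_index]
    if not shared:
        raise ValueError("no RILs shared between trait and genotypes")
    t_idx = [trait.ril_ids.index(r) for r in shared]
    g_idx = [geno_index[r] for r in shared]
    Z = trait.values[t_idx]
    X = trait.x_values[t_idx] if trait.x_values is not None else Z
    Y = trait.y_values[t_idx] if trait.y_values is not None else np.zeros_like(Z)
    G = np.asarray(genotypes.codes)[:, g_idx]
    return Z, X, Y, G, shared


def fit_null(trait: PlasticityTrait, grid: TimeGrid) -> NullFit:
    """Maximum likelihood no-QTL fit: one mean curve, composite covariance.

    The mean is the difference of two logistic curves whose components
    are initialised from per-environment fits to the paired source
    panels; the covariance search is nested around generalized
    least-squares curve updates.
    """
    if trait.n_ril < 2:
        raise ValueError("need at least 2 RILs")
    Z = trait.values
    X = trait.x_values if trait.x_values is not None else Z
    Y = trait.y_values if trait.y_values is not None else np.zeros_like(Z)
    G = np.zeros((1, trait.n_ril), dtype=int)
    engine = ScanEngine(Z, X, Y, G, settings=_POLISH)
    ZZ = np.einsum("nt,nu->ntu", Z, Z).reshape(trait.n_ril, -1)
    (h0,) = engine._fit_h0_batch(
        np.ones((1, trait.n_ril), dtype=bool), Z, X, Y, ZZ
    )
    ax, bx, rx, ay, by, ry = np.exp(h0.p0)
    cov = _theta_to_cov(h0.theta0, len(grid))
    return NullFit(
        LogisticParams(ax, bx, rx), LogisticParams(ay, by, ry), cov, h0.loglik
    )


def fit_alternative(
    trait: PlasticityTrait,
    snp_codes: np.ndarray,
    grid: TimeGrid,
    n_min: int = 5,
) -> tuple[GenotypeModel, float]:
    """Per-genotype model at one SNP; returns (model, maximised logL1).

    ``snp_codes`` are genotype codes aligned with ``trait.ril_ids``.
    Classes with fewer than ``n_min`` RILs are dropped and their RILs
    excluded for this SNP; with a single retained class the model
    coincides with the null fit.
    """
    codes = np.asarray(snp_codes)
    if codes.shape != (trait.n_ril,):
        raise ValueError("snp_codes must align with trait.ril_ids")
    Z = trait.values
    X = trait.x_values if trait.x_values is not None else Z
    Y = trait.y_values if trait.y_values is not None else np.zeros_like(Z)
    settings = EngineSettings(
        n_min=n_min,
        h0_rounds=_POLISH.h0_rounds,
        h0_adam=_POLISH.h0_adam,
        h1_rounds=_POLISH.h1_rounds,
        h1_adam=_POLISH.h1_adam,
        gn_iters=_POLISH.gn_iters,
    )
    engine = ScanEngine(Z, X, Y, codes[None, :], settings=settings)
    res = engine.lr_scan(keep_fits=True)
    if not res["usable"][0]:
        raise ValueError("no genotype class passes the n_min filter at this SNP")
    result = ScanResult(
        table=pd.DataFrame(),
        grid=grid,
        threshold=ThresholdRecord(np.nan, np.zeros(0), np.nan, 0, 0),
        curve_logparams=res["curve_logparams"],
        theta=res["theta"],
        class_counts=res["class_counts"],
    )
    if res["J"][0] < 2:
        # single class: models coincide; report the null curve for the class
        null = fit_null(trait, grid)
        cls = [
            GenotypeClassFit(
                int(c), int(n), null.params_x, null.params_y
            )
            for c, n in zip(range(3), res["class_counts"][0])
            if n > 0
        ]
        return GenotypeModel(0, cls, null.covariance), float(res["loglik1"][0])
    return result.genotype_model(0), float(res["loglik1"][0])


def lr_statistic(loglik0: float, loglik1: float, tol: float = 1e-6) -> float:
    """LR = 2(logL1 - logL0), clipped at zero.

    The null is nested in the alternative, so a negative value beyond
    tolerance can only be optimiser noise; it is clipped with a warning.
    """
    lr = 2.0 * (loglik1 - loglik0)
    if lr < -tol:
        import warnings

        warnings.warn(
            f"negative LR {lr:.3g} clipped to 0 (optimizer noise)", stacklevel=2
        )
    return max(lr, 0.0)


def quantile_threshold(maxima: np.ndarray, alpha: float) -> float:
    """Empirical upper-(1-alpha) quantile of permutation maxima."""
    maxima = np.asarray(maxima, dtype=float)
    return float(np.quantile(maxima, 1.0 - alpha, method="higher"))


def _perm_maxima(engine: ScanEngine, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    maxima = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(engine.n)
        res = engine.lr_scan(perm=perm)
        lrs = res["lr"][res["usable"]]
        maxima[k] = float(np.max(lrs)) if lrs.size else 0.0
    return maxima


def permutation_threshold(
    trait: PlasticityTrait,
    genotypes,
    grid: TimeGrid,
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    settings: EngineSettings = EngineSettings(),
) -> ThresholdRecord:
    """Genome-wide LR threshold from whole-vector phenotype permutations.

    Each permutation reshuffles RIL phenotype vectors against genotype
    rows (preserving the trait's temporal covariance while breaking all
    SNP-trait association), re-runs the full scan and records the
    genome-wide maximum LR; the threshold is the empirical (1 - alpha)
    quantile of those maxima.
    """
    ScanConfig(alpha=alpha, n_perm=n_perm, seed=seed)  # validates
    Z, X, Y, G, _ = _aligned_arrays(trait, genotypes)
    engine = ScanEngine(Z, X, Y, G, settings=settings)
    engine.lr_scan()  # warm the permutation-invariant null cache
    rng = np.random.default_rng(seed)
    maxima = _perm_maxima(engine, n_perm, rng)
    return ThresholdRecord(quantile_threshold(maxima, alpha), maxima, alpha, n_perm, seed)


def scan(
    trait: PlasticityTrait,
    genotypes,
    grid: TimeGrid,
    config: ScanConfig = ScanConfig(),
    maxima: np.ndarray | None = None,
) -> ScanResult:
    """Genome scan of one plasticity trait: LR per SNP + permutation calibration.

    Empirical per-SNP P = fraction of permutation genome-wide maxima at or
    above the SNP's LR; the significant set is {LR >= threshold}.
    Deterministic given ``config.seed``.  Precomputed permutation maxima
    (e.g. from a cached ``permutation_threshold`` run with the same seed
    and settings) can be passed to skip the permutation loop.
    """
    settings = EngineSettings(
        n_min=config.n_min,
        h0_rounds=config.settings.h0_rounds,
        h0_adam=config.settings.h0_adam,
        h1_rounds=config.settings.h1_rounds,
        h1_adam=config.settings.h1_adam,
        gn_iters=config.settings.gn_iters,
        adam_lr=config.settings.adam_lr,
    )
    Z, X, Y, G, shared = _aligned_arrays(trait, genotypes)
    engine = ScanEngine(Z, X, Y, G, settings=settings)
    res = engine.lr_scan(keep_fits=True)
    if not np.any(res["usable"]):
        raise ValueError("no usable SNPs after genotype-class filtering")

    if maxima is None:
        rng = np.random.default_rng(config.seed)
        maxima = _perm_maxima(engine, config.n_perm, rng)
    else:
        maxima = np.asarray(maxima, dtype=float)
        if maxima.size != config.n_perm:
            raise ValueError("supplied maxima length differs from config.n_perm")
    threshold = quantile_threshold(maxima, config.alpha)

    lr = res["lr"]
    with np.errstate(invalid="ignore"):
        p_emp = np.array(
            [
                float(np.mean(maxima >= x)) if np.isfinite(x) else np.nan
                for x in lr
            ]
        )
    significant = np.where(np.isfinite(lr), lr >= threshold, False)

    table = pd.DataFrame(
        {
            "snp": np.arange(engine.M),
            "chrom": np.asarray(genotypes.chrom),
            "pos": np.asarray(genotypes.pos),
            "J": res["J"],
            "n": res["n"],
            "LR": lr,
            "p_emp": p_emp,
            "significant": significant,
            "usable": res["usable"],
        }
    )
    record = ThresholdRecord(threshold, maxima, config.alpha, config.n_perm, config.seed)
    return ScanResult(
        table=table,
        grid=grid,
        threshold=record,
        curve_logparams=res["curve_logparams"],
        theta=res["theta"],
        class_counts=res["class_counts"],
    )
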