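"""Synthetic RIL panel and six-treatment growth trajectories.

Emulates the study system: ~100 recombinant inbred lines derived from
two inbred founders by ten generations of selfing, genotyped at SNPs on
five chromosomes, grown under six light treatments (H, L and the four
maternal x offspring combinations HH, HL, LH, LL) with 20 replicates per
RIL per treatment and leaf number recorded weekly for eight weeks.

Gametes are formed by a Markov walk along each chromosome using the
Haldane map function (no crossover interference); selfing is iterated
from a uniformly heterozygous F1, so residual heterozygotes survive at
rate (1/2)^(k-1) in generation F_k and are retained with code 1.

Trajectories are logistic means plus multivariate normal noise with
SAD(1) covariance per final light environment.  Maternal effects are
encoded entirely through treatment-specific baseline curves (the four
offspring baselines differ from the parental ones and from each other);
planted QTLs perturb the baseline with genotype- and treatment-specific
logistic parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .growth import LogisticParams, TimeGrid, logistic_mean
from .plasticity import TREATMENTS, TrajectoryPanel, average_replicates
from .sad import SAD1Params, sad1_covariance

__all__ = [
    "GeneticMap",
    "RILGenotypes",
    "QTLSpec",
    "NoiseSpec",
    "SimulatedExperiment",
    "default_map",
    "default_baselines",
    "default_noise",
    "simulate_ril_genotypes",
    "simulate_trajectories",
    "write_fixture",
]

MISSING = -9


@dataclass(frozen=True)
class GeneticMap:
    """Marker map: list of (chromosome id, positions in centiMorgans)."""

    chromosomes: tuple

    def __init__(self, chromosomes) -> None:
        chroms = []
        for chrom_id, pos in chromosomes:
            pos = np.asarray(pos, dtype=float)
            if pos.size == 0:
                raise ValueError(f"chromosome {chrom_id} has no markers")
            if np.any(pos < 0) or np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions on {chrom_id} must be non-negative, strictly increasing"
                )
            chroms.append((str(chrom_id), pos))
        if not chroms:
            raise ValueError("map needs at least one chromosome")
        object.__setattr__(self, "chromosomes", tuple(chroms))

    @property
    def n_markers(self) -> int:
        return sum(p.size for _, p in self.chromosomes)


@dataclass
class RILGenotypes:
    """SNP x RIL genotype matrix, codes {0, 1, 2, -9}.

    0/2 are the founder homozygotes, 1 a residual heterozygote, -9
    missing.  Marker metadata (chrom, pos) runs parallel to the rows.
    """

    codes: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ril_ids: list
    n_skipped_multiallelic: int = 0

    def __post_init__(self):
        self.codes = np.asarray(self.codes)
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes restricted to {0, 1, 2, -9}")
        if self.codes.shape != (len(self.chrom), len(self.ril_ids)):
            raise ValueError("codes must be (n_markers, n_ril)")

    @property
    def n_markers(self) -> int:
        return self.codes.shape[0]

    @property
    def n_ril(self) -> int:
        return self.codes.shape[1]


@dataclass(frozen=True)
class QTLSpec:
    """A planted QTL: marker index + per-(treatment, genotype) curve params.

    ``params[treatment][genotype_code]`` holds the LogisticParams of the
    genotype's mean curve in that treatment.  Codes 0 and 2 are required
    for every listed treatment; the residual-heterozygote curve defaults
    to the parameter-wise midpoint.
    """

    marker_index: int
    params: dict

    def __post_init__(self):
        for tr, by_geno in self.params.items():
            if tr not in TREATMENTS:
                raise ValueError(f"unknown treatment {tr!r} in QTLSpec")
            for g in (0, 2):
                if g not in by_geno:
                    raise ValueError(f"QTLSpec treatment {tr}: genotype {g} missing")

    def curve_params(self, treatment: str, genotype: int) -> LogisticParams | None:
        by_geno = self.params.get(treatment)
        if by_geno is None:
            return None
        if genotype in by_geno:
            return by_geno[genotype]
        p0, p2 = by_geno[0], by_geno[2]
        return LogisticParams(
            0.5 * (p0.a + p2.a), 0.5 * (p0.b + p2.b), 0.5 * (p0.r + p2.r)
        )


@dataclass(frozen=True)
class NoiseSpec:
    """Residual SAD(1) parameters per final light environment (H or L)."""

    env_params: dict

    def __post_init__(self):
        for env, p in self.env_params.items():
            if env not in ("H", "L"):
                raise ValueError("noise environments are 'H' and 'L'")
            if not isinstance(p, SAD1Params):
                raise TypeError("env_params values must be SAD1Params")

    def for_treatment(self, treatment: str) -> SAD1Params:
        return self.env_params[treatment[-1]]


@dataclass
class SimulatedExperiment:
    """Replicate-level long table + replicate-averaged panels + truth record."""

    long_table: pd.DataFrame
    panels: dict
    grid: TimeGrid
    truth: dict = field(default_factory=dict)


def default_map(
    n_chrom: int = 5, markers_per_chrom: int = 400, spacing_cm: float = 0.25
) -> GeneticMap:
    """Desk-scale map: 5 chromosomes x 400 markers, 0.25 cM spacing."""
    return GeneticMap(
        [
            (f"chr{c + 1}", np.arange(markers_per_chrom) * spacing_cm)
            for c in range(n_chrom)
        ]
    )


def default_baselines() -> dict:
    """Treatment-level baseline logistic curves.

    Asymptotes follow the qualitative pattern of the experiment: low
    light yields roughly seven more leaves than high light in the
    parental generation, about four more for offspring of low-light
    mothers and about three more for offspring of high-light mothers,
    with offspring curves pulled toward their maternal environment.
    """
    return {
        "H": LogisticParams(10.0, 8.0, 0.9),
        "L": LogisticParams(17.0, 10.0, 0.7),
        "HH": LogisticParams(11.0, 8.0, 0.85),
        "HL": LogisticParams(14.0, 9.0, 0.75),
        "LH": LogisticParams(12.0, 8.0, 0.85),
        "LL": LogisticParams(16.0, 10.0, 0.7),
    }


def default_noise() -> NoiseSpec:
    """Replicate-level residual SAD(1) noise; low light slightly noisier."""
    return NoiseSpec(
        {
            "H": SAD1Params(0.70, 0.8),
            "L": SAD1Params(0.75, 1.0),
        }
    )


def simulate_ril_genotypes(
    gmap: GeneticMap,
    n_ril: int = 100,
    n_generations: int = 10,
    seed: int = 0,
) -> RILGenotypes:
    """Simulate a selfed RIL panel by Haldane-model meiosis.

    Starting from a uniformly heterozygous F1, each of ``n_generations - 1``
    selfing rounds draws two independent gametes per line; a gamete
    follows a Markov walk along each chromosome, switching parental
    haplotype between adjacent markers with the Haldane recombination
    fraction r = (1 - exp(-2 d / 100)) / 2 for map distance d cM.
    Genotype codes count founder-B alleles (0, 1, 2).
    """
    if n_ril < 2:
        raise ValueError("n_ril must be >= 2")
    if n_generations < 2:
        raise ValueError("n_generations must be >= 2")
    rng = np.random.default_rng(seed)

    chrom_codes = []
    chrom_names = []
    chrom_pos = []
    for chrom_id, pos in gmap.chromosomes:
        n_mark = pos.size
        rec = 0.5 * (1.0 - np.exp(-2.0 * np.diff(pos) / 100.0))
        # F1: haplotype A all founder-A (0), haplotype B all founder-B (1)
        hap1 = np.zeros((n_ril, n_mark), dtype=np.int8)
        hap2 = np.ones((n_ril, n_mark), dtype=np.int8)
        for _ in range(n_generations - 1):
            hap1, hap2 = (
                _gamete(hap1, hap2, rec, rng),
                _gamete(hap1, hap2, rec, rng),
            )
        chrom_codes.append((hap1 + hap2).astype(np.int8))
        chrom_names.append(np.repeat(chrom_id, n_mark))
        chrom_pos.append(pos)

    codes = np.concatenate(chrom_codes, axis=1).T  # (n_markers, n_ril)
    return RILGenotypes(
        codes=codes,
        chrom=np.concatenate(chrom_names),
        pos=np.concatenate(chrom_pos),
        ril_ids=[f"RIL{i + 1:03d}" for i in range(n_ril)],
    )


def _gamete(hap1, hap2, rec, rng) -> np.ndarray:
    """One gamete per line: Markov haplotype walk with switch probs ``rec``."""
    n_ril, n_mark = hap1.shape
    switches = rng.random((n_ril, n_mark)) < np.concatenate([[0.5], rec])[None, :]
    # cumulative XOR of switches gives which haplotype is copied at each marker
    state = np.cumsum(switches, axis=1) % 2
    return np.where(state == 0, hap1, hap2).astype(np.int8)


def simulate_trajectories(
    genotypes: RILGenotypes,
    qtls: list,
    baselines: dict | None = None,
    noise: NoiseSpec | None = None,
    grid: TimeGrid | None = None,
    n_replicates: int = 20,
    seed: int = 0,
) -> SimulatedExperiment:
    """Six-treatment replicate trajectories with planted plasticity QTLs.

    Each replicate trajectory is the RIL x treatment logistic mean plus an
    independent multivariate normal draw with the environment's SAD(1)
    covariance.  A planted QTL shifts the mean additively by the
    difference between its genotype-specific curve and the treatment
    baseline, so a single planted QTL with baseline parameters for one
    genotype reproduces that genotype's curve exactly.
    """
    if baselines is None:
        baselines = default_baselines()
    if noise is None:
        noise = default_noise()
    if grid is None:
        grid = TimeGrid.weekly(8)
    if len(grid) < 3:
        raise ValueError("grid needs at least 3 time points")
    if n_replicates < 1:
        raise ValueError("need at least 1 replicate")
    for q in qtls:
        if not 0 <= q.marker_index < genotypes.n_markers:
            raise ValueError(f"QTL marker index {q.marker_index} out of range")
    missing_baseline = set(TREATMENTS) - set(baselines)
    if missing_baseline:
        raise ValueError(f"baselines missing treatments {sorted(missing_baseline)}")

    rng = np.random.default_rng(seed)
    t = grid.values
    weeks = [int(w) for w in t]
    n_ril = genotypes.n_ril
    T = len(grid)

    frames = []
    for treatment in TREATMENTS:
        base_curve = logistic_mean(t, baselines[treatment])
        means = np.tile(base_curve, (n_ril, 1))
        for q in qtls:
            geno = genotypes.codes[q.marker_index]
            for g in (0, 1, 2):
                p = q.curve_params(treatment, g)
                if p is None:
                    continue
                rows = geno == g
                if rows.any():
                    means[rows] += logistic_mean(t, p) - base_curve
        sad = noise.for_treatment(treatment)
        chol = np.linalg.cholesky(sad1_covariance(sad, T))
        eps = rng.standard_normal((n_replicates * n_ril, T)) @ chol.T
        values = np.repeat(means, n_replicates, axis=0) + eps

        frames.append(
            pd.DataFrame(
                {
                    "ril_id": np.repeat(genotypes.ril_ids, n_replicates * T),
                    "treatment": treatment,
                    "replicate": np.tile(
                        np.repeat(np.arange(1, n_replicates + 1), T), n_ril
                    ),
                    "week": np.tile(weeks, n_ril * n_replicates),
                    "leaf_number": values.reshape(-1),
                }
            )
        )
    long_table = pd.concat(frames, ignore_index=True)
    panels = average_replicates(long_table, grid)
    truth = {
        "seed": int(seed),
        "n_replicates": int(n_replicates),
        "weeks": weeks,
        "baselines": {
            tr: [p.a, p.b, p.r] for tr, p in baselines.items()
        },
        "noise": {
            env: {"phi": p.phi, "nu2": p.nu2} for env, p in noise.env_params.items()
        },
        "qtls": [
            {
                "marker_index": int(q.marker_index),
                "chrom": str(genotypes.chrom[q.marker_index]),
                "pos_cm": float(genotypes.pos[q.marker_index]),
                "params": {
                    tr: {int(g): [p.a, p.b, p.r] for g, p in by_geno.items()}
                    for tr, by_geno in q.params.items()
                },
            }
            for q in qtls
        ],
    }
    return SimulatedExperiment(long_table, panels, grid, truth)


# ---------------------------------------------------------------------------
# fixture writing
# ---------------------------------------------------------------------------

def _vcf_positions(chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Map cM positions to unique, increasing integer bp per chromosome."""
    bp = np.zeros(pos.size, dtype=np.int64)
    for c in np.unique(chrom):
        idx = np.nonzero(chrom == c)[0]
        raw = np.round(pos[idx] * 10_000).astype(np.int64) + 1
        bp[idx] = np.maximum.accumulate(raw)
        # enforce strict increase in case of rounding collisions
        for k in range(1, idx.size):
            if bp[idx[k]] <= bp[idx[k - 1]]:
                bp[idx[k]] = bp[idx[k - 1]] + 1
    return bp

_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_fixture(
    genotypes: RILGenotypes, experiment: SimulatedExperiment, outdir
) -> dict:
    """Write VCF (genotypes), long CSV (phenotypes) and truth YAML.

    Returns the paths written.  The VCF stores the map position in an
    INFO field ``CM`` alongside the integer POS used for the file format.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vcf_path = outdir / "genotypes.vcf"
    csv_path = outdir / "phenotypes.csv"
    truth_path = outdir / "truth.yaml"

    bp = _vcf_positions(genotypes.chrom, genotypes.pos)
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=CM,Number=1,Type=Float,Description="Map position (cM)">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(genotypes.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.ril_ids)
            + "\n"
        )
        for m in range(genotypes.n_markers):
            gts = "\t".join(_GT[int(g)] for g in genotypes.codes[m])
            fh.write(
                f"{genotypes.chrom[m]}\t{bp[m]}\tm{m}\tA\tT\t.\tPASS\t"
                f"CM={genotypes.pos[m]:.4f}\tGT\t{gts}\n"
            )

    experiment.long_table.to_csv(csv_path, index=False, float_format="%.10g")
    with open(truth_path, "w") as fh:
        yaml.safe_dump(experiment.truth, fh, sort_keys=True)
    return {"vcf": vcf_path, "phenotypes": csv_path, "truth": truth_path}
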