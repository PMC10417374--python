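"""Synthetic backcross and human case-control cohorts with recorded truth.

Mouse cohorts follow the mediation structure under study: ipQTLs set IMP
levels, IMPs feed the fibrosis pathophenotype together with direct cdaQTL
effects, an arm-specific age slope and noise. Human cohorts draw SNV
dosages under Hardy-Weinberg equilibrium and a logistic outcome with
configured odds ratios. Every generator is a pure function of
(config, seed) and the truth record is returned alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetics_core import MISSING, BackcrossGenotypes, GeneticMap, map_to_recomb
from .human_genetics import HumanCohort
from .imp_association import IMPPanel

__all__ = [
    "QTLEffect",
    "HumanConfig",
    "SimulationConfig",
    "default_genetic_map",
    "simulate_backcross_genotypes",
    "simulate_imp_levels",
    "simulate_cda_phenotypes",
    "simulate_human_cohort",
    "simulate_mouse_cohort",
]


@dataclass(frozen=True)
class QTLEffect:
    """One genetic effect: a locus acting on an IMP or on a phenotype.

    ``effect`` is the heterozygote-minus-homozygote shift in trait SD units
    of the residual scale; on a backcross the genotype indicator has
    variance 1/4, so the locus contributes effect^2 / 4 genetic variance.
    """

    chromosome: str
    position: float
    target: str
    effect: float


@dataclass
class HumanConfig:
    n: int = 420
    n_snvs: int = 200
    maf: float | list[float] = 0.3
    causal: dict[int, float] = field(default_factory=dict)  # SNV index -> odds ratio
    prevalence: float = 0.35
    r2_low: float = 0.5
    r2_high: float = 1.0
    tag: str = "breast"

    def maf_vector(self, rng: np.random.Generator) -> np.ndarray:
        if np.isscalar(self.maf):
            m = np.full(self.n_snvs, float(self.maf))
        else:
            m = np.asarray(self.maf, dtype=float)
        if np.any((m <= 0) | (m > 0.5)):
            raise ValueError("MAF must lie in (0, 0.5]")
        return m


@dataclass
class SimulationConfig:
    """Full specification of one synthetic study; ``seed`` is mandatory."""

    seed: int
    n_autosomes: int = 19
    chrom_length_cM: float = 70.0
    n_markers_total: int = 1499
    n_mice: int = 130
    arm_sizes: tuple[int, int] = (70, 60)  # (doxorubicin, combined)
    age_range: tuple[float, float] = (51.0, 114.0)
    missing_rate: float = 0.02
    qtl_effects: list[QTLEffect] = field(default_factory=list)
    mediation: dict[str, float] = field(default_factory=dict)  # IMP -> beta into fibrosis
    imp_noise_sd: float = 1.0
    fibrosis_noise_sd: float = 5.0
    fibrosis_baseline: float = 20.0
    fibrosis_scale: float = 5.0  # multiplies SD-unit genetic/mediated effects
    age_slope_combined: float = 0.15  # % fibrosis per week, combined arm only
    age_slope_dox: float = 0.0
    arm_offset_combined: float = 3.0
    human: HumanConfig = field(default_factory=HumanConfig)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if sum(self.arm_sizes) != self.n_mice:
            raise ValueError("arm sizes must sum to n_mice")


def default_genetic_map(
    n_autosomes: int = 19, chrom_length_cM: float = 70.0, n_markers_total: int = 1499
) -> GeneticMap:
    """Equally spaced markers on equal-length autosomes.

    Markers are distributed as evenly as possible so the total is exact
    (with the defaults: 17 chromosomes carry 79 markers and 2 carry 78).
    """
    base = n_markers_total // n_autosomes
    extra = n_markers_total - base * n_autosomes
    chroms = [str(i + 1) for i in range(n_autosomes)]
    names: dict[str, list[str]] = {}
    pos: dict[str, np.ndarray] = {}
    for i, c in enumerate(chroms):
        k = base + (1 if i < extra else 0)
        names[c] = [f"c{c}m{j + 1}" for j in range(k)]
        pos[c] = np.linspace(0.0, chrom_length_cM, k)
    return GeneticMap(chromosomes=chroms, marker_names=names, positions=pos)


def simulate_backcross_genotypes(
    gmap: GeneticMap,
    n: int,
    seed_or_rng,
    missing_rate: float = 0.0,
    map_function: str = "haldane",
) -> BackcrossGenotypes:
    """Markov-chain backcross genotypes along each chromosome.

    The first marker of each chromosome is heterozygous with probability
    1/2; each subsequent marker switches state with the recombination
    fraction of the inter-marker distance. Missingness is applied uniformly.
    """
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) else np.random.default_rng(seed_or_rng)
    blocks = []
    for c in gmap.chromosomes:
        pos = gmap.positions[c]
        m = len(pos)
        g = np.empty((n, m), dtype=np.int8)
        g[:, 0] = rng.random(n) < 0.5
        r = map_to_recomb(np.diff(pos), map_function=map_function)
        r = np.atleast_1d(r)
        for j in range(1, m):
            switch = rng.random(n) < r[j - 1]
            g[:, j] = np.where(switch, 1 - g[:, j - 1], g[:, j - 1])
        blocks.append(g)
    mat = np.concatenate(blocks, axis=1)
    if missing_rate > 0:
        mask = rng.random(mat.shape) < missing_rate
        mat[mask] = MISSING
    return BackcrossGenotypes(map=gmap, matrix=mat)


def _true_genotype_column(
    geno: BackcrossGenotypes, chrom: str, position: float
) -> np.ndarray:
    """Genotype indicator at the marker nearest a requested locus.

    Missing genotypes are replaced by the 0.5 backcross expectation so
    effect sizes stay interpretable.
    """
    gmap = geno.map
    sl = gmap.chrom_slices()[chrom]
    pos = gmap.positions[chrom]
    j = int(np.argmin(np.abs(pos - position)))
    col = geno.matrix[:, sl][:, j].astype(float)
    col[col == MISSING] = 0.5
    return col


def simulate_imp_levels(
    geno: BackcrossGenotypes, config: SimulationConfig, rng: np.random.Generator
) -> IMPPanel:
    """IMP levels: sum of ipQTL effects plus normal noise (SD units)."""
    imp_names: list[str] = []
    for e in config.qtl_effects:
        if e.target not in ("fibrosis", "cardiomyocyte_area") and e.target not in imp_names:
            imp_names.append(e.target)
    for m in config.mediation:
        if m not in imp_names:
            imp_names.append(m)
    n = geno.n_individuals
    levels = pd.DataFrame(0.0, index=range(n), columns=imp_names)
    for e in config.qtl_effects:
        if e.target in imp_names:
            levels[e.target] += e.effect * _true_genotype_column(geno, e.chromosome, e.position)
    for m in imp_names:
        levels[m] += rng.normal(0.0, config.imp_noise_sd, n)
    classes = {m: "protein" for m in imp_names}
    return IMPPanel(levels=levels, molecule_class=classes)


def simulate_cda_phenotypes(
    geno: BackcrossGenotypes,
    imps: IMPPanel,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Pathophenotype table: fibrosis, cardiomyocyte area, age, arm.

    fibrosis = baseline + scale * (direct cdaQTL effects + mediated IMP
    contributions) + arm-specific age slope + arm offset + noise, truncated
    to [0, 100].
    """
    n = geno.n_individuals
    n_dox, n_comb = config.arm_sizes
    arm = np.array(["doxorubicin"] * n_dox + ["combined"] * n_comb)[:n]
    age = rng.uniform(config.age_range[0], config.age_range[1], n)

    genetic = np.zeros(n)
    for e in config.qtl_effects:
        if e.target == "fibrosis":
            genetic += e.effect * _true_genotype_column(geno, e.chromosome, e.position)
    mediated = np.zeros(n)
    for imp, beta in config.mediation.items():
        mediated += beta * imps.levels[imp].to_numpy(float)

    slope = np.where(arm == "combined", config.age_slope_combined, config.age_slope_dox)
    offset = np.where(arm == "combined", config.arm_offset_combined, 0.0)
    fibrosis = (
        config.fibrosis_baseline
        + config.fibrosis_scale * (genetic + mediated)
        + slope * (age - age.mean())
        + offset
        + rng.normal(0.0, config.fibrosis_noise_sd, n)
    )
    fibrosis = np.clip(fibrosis, 0.0, 100.0)

    area_genetic = np.zeros(n)
    for e in config.qtl_effects:
        if e.target == "cardiomyocyte_area":
            area_genetic += e.effect * _true_genotype_column(geno, e.chromosome, e.position)
    area = 300.0 + 30.0 * area_genetic + rng.normal(0.0, 25.0, n)
    area = np.maximum(area, 1.0)

    return pd.DataFrame(
        {
            "fibrosis": fibrosis,
            "cardiomyocyte_area": area,
            "age_weeks": age,
            "therapy_arm": arm,
        }
    )


def simulate_mouse_cohort(config: SimulationConfig) -> dict:
    """Full mouse cohort: map, genotypes, IMP panel, phenotypes, truth."""
    rng = np.random.default_rng(config.seed)
    gmap = default_genetic_map(config.n_autosomes, config.chrom_length_cM, config.n_markers_total)
    geno = simulate_backcross_genotypes(gmap, config.n_mice, rng, config.missing_rate)
    imps = simulate_imp_levels(geno, config, rng)
    pheno = simulate_cda_phenotypes(geno, imps, config, rng)
    truth = {
        "qtl_effects": [
            {"chromosome": e.chromosome, "position": e.position, "target": e.target, "effect": e.effect}
            for e in config.qtl_effects
        ],
        "mediation": dict(config.mediation),
        "seed": config.seed,
    }
    return {"map": gmap, "genotypes": geno, "imps": imps, "phenotypes": pheno, "truth": truth}


def _calibrate_intercept(eta: np.ndarray, prevalence: float) -> float:
    """Intercept making mean(sigmoid(b0 + eta)) equal the target prevalence."""
    lo, hi = -20.0, 20.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        p = 1.0 / (1.0 + np.exp(-(mid + eta)))
        if p.mean() < prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_human_cohort(config: HumanConfig, seed: int) -> tuple[HumanCohort, dict]:
    """HWE SNV dosages with a logistic CDA outcome.

    Dosages are Binomial(2, MAF) per SNV; the linear predictor adds
    log(OR) * dosage for each causal SNV with the intercept calibrated to
    the configured baseline prevalence. Imputation R^2 values are drawn
    uniformly on [r2_low, r2_high] so the quality filter is exercisable.
    """
    rng = np.random.default_rng(seed)
    maf = config.maf_vector(rng)
    G = rng.binomial(2, maf[None, :], size=(config.n, config.n_snvs)).astype(float)
    snv_ids = [f"snv{j + 1}" for j in range(config.n_snvs)]

    eta = np.zeros(config.n)
    for j, orr in config.causal.items():
        eta += np.log(orr) * G[:, j]
    b0 = _calibrate_intercept(eta - eta.mean(), config.prevalence)
    p = 1.0 / (1.0 + np.exp(-(b0 + eta - eta.mean())))
    y = (rng.random(config.n) < p).astype(int)

    r2 = rng.uniform(config.r2_low, config.r2_high, config.n_snvs)
    cohort = HumanCohort(
        dosages=pd.DataFrame(G, columns=snv_ids),
        imputation_r2=pd.Series(r2, index=snv_ids),
        outcome=y,
        tag=config.tag,
    )
    truth = {
        "causal": {snv_ids[j]: float(orr) for j, orr in config.causal.items()},
        "prevalence": config.prevalence,
        "intercept": float(b0),
        "seed": seed,
    }
    return cohort, truth
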