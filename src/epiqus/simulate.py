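"""Synthetic cohort generator with the statistical structure the scan assumes.

Emulates a young-adult bone-phenotype study: ~575 individuals genotyped on a
32-SNP candidate panel, with genotypes drawn in Hardy-Weinberg proportions at
the panel minor-allele frequencies, optional pairwise LD blocks, a covariate
profile (sex, age, BMI, physical activity, dietary calcium) and a Gaussian
broadband-ultrasound-attenuation (BUA) phenotype that is linear in covariates,
genotype terms and planted pairwise interactions.

LD between a marker pair is induced by a Gaussian copula on the two allele
draws: each of an individual's two allele copies at the pair is thresholded
from a shared latent bivariate normal whose correlation is calibrated by
bisection so the realized genotype r² matches the requested target (within
about ±0.03 at n >= 5,000).  Because each copy is an independent draw, every
marker stays in HWE marginally.

One root seed drives independent substreams for genotypes, missingness,
covariates and phenotype noise, so the genotype draw is invariant to, say, a
change of phenotype parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .io_panel import (
    COVARIATE_COLUMNS,
    CovariateTable,
    GenotypeMatrix,
    PhenotypeVector,
    SnpMarker,
    load_reference_panel,
    write_covariates,
    write_genotypes,
    write_phenotype,
)

__all__ = [
    "ConfigError",
    "UnattainableLdError",
    "MainEffect",
    "InteractionEffect",
    "SimulationConfig",
    "REDUNDANT_PAIRS",
    "max_attainable_r2",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_phenotype",
    "generate_cohort",
    "Cohort",
]


class ConfigError(ValueError):
    """The simulation configuration is internally inconsistent."""


class UnattainableLdError(ConfigError):
    """Requested genotype r² exceeds what the two MAFs permit."""


@dataclass(frozen=True)
class MainEffect:
    rsid: str
    beta: float  # dB/MHz per carrier (carrier coding) or per allele (additive)
    coding: str = "carrier"


@dataclass(frozen=True)
class InteractionEffect:
    rsid1: str
    rsid2: str
    beta: float  # dB/MHz of departure from additivity on the stated scale
    coding: str = "carrier"


# The panel's two redundant same-locus marker pairs, held in near-perfect LD so
# pruning at r² > 0.90 drops one member of each (the later-listed, by the
# greedy panel-order rule) and 30 of the 32 markers remain.
REDUNDANT_PAIRS: tuple[tuple[str, str, float], ...] = (
    ("rs2908004", "rs2707466", 0.95),
    ("rs2148073", "rs7988338", 0.95),
)


@dataclass
class SimulationConfig:
    """Everything the generator needs; defaults mirror the emulated study.

    Cohort: 575 individuals, 400/575 female, age 20.41 ± 2.36 y.  BMI,
    IPAQ-style activity score and dietary calcium moments are plausible
    young-adult values (they are adjustment variables, not targets).  The
    default phenotype has active covariate effects, no genetic effects and
    residual SD 16 dB/MHz, giving a mean BUA near 80 dB/MHz.
    """

    n_samples: int = 575
    sex_split: float = 400 / 575
    age_mean: float = 20.41
    age_sd: float = 2.36
    bmi_mean: float = 22.0
    bmi_sd: float = 3.0
    activity_mean: float = 2500.0   # MET-min/week
    activity_sd: float = 1500.0
    calcium_mean: float = 900.0     # mg/day
    calcium_sd: float = 300.0
    panel: list[SnpMarker] | None = None  # None -> packaged 32-SNP panel
    ld_pairs: list[tuple[str, str, float]] = field(
        default_factory=lambda: list(REDUNDANT_PAIRS)
    )
    missing_rate: float = 0.01
    intercept: float = 35.0         # dB/MHz
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {
            "sex": -6.0,            # females lower BUA
            "age": 0.9,             # per year
            "bmi": 1.1,             # per kg/m²
            "physical_activity": 0.0015,
            "calcium_intake": 0.004,
        }
    )
    snp_effects: list[MainEffect] = field(default_factory=list)
    interaction_effects: list[InteractionEffect] = field(default_factory=list)
    noise_sd: float = 16.0          # dB/MHz
    seed: int = 0

    # calibration slack for LD targets; also the tolerance within which a
    # target above the attainable maximum is clamped to the boundary
    ld_tolerance: float = 0.03

    def resolved_panel(self) -> list[SnpMarker]:
        return list(self.panel) if self.panel is not None else load_reference_panel()

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ConfigError("n_samples must be positive")
        for name in ("sex_split", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")
        panel = self.resolved_panel()
        rsids = {m.rsid for m in panel}
        in_ld: set[str] = set()
        for a, b, r2 in self.ld_pairs:
            if a not in rsids or b not in rsids:
                raise ConfigError(f"ld_pairs references unknown marker {a!r}/{b!r}")
            if not 0.0 <= r2 <= 1.0:
                raise ConfigError(f"ld_pairs target r²={r2} outside [0, 1]")
            if a in in_ld or b in in_ld or a == b:
                raise ConfigError("each marker may appear in at most one ld_pair")
            in_ld.update((a, b))
        for eff in self.snp_effects:
            if eff.rsid not in rsids:
                raise ConfigError(f"snp_effects references unknown marker {eff.rsid!r}")
        for eff in self.interaction_effects:
            for r in (eff.rsid1, eff.rsid2):
                if r not in rsids:
                    raise ConfigError(
                        f"interaction_effects references unknown marker {r!r}"
                    )
        for key in self.covariate_effects:
            if key not in COVARIATE_COLUMNS:
                raise ConfigError(f"unknown covariate {key!r} in covariate_effects")


class Cohort(NamedTuple):
    genotypes: GenotypeMatrix
    covariates: CovariateTable
    phenotype: PhenotypeVector


# ---------------------------------------------------------------------------
# LD copula calibration


def _allele_corr(rho: float, t1: float, t2: float, p1: float, p2: float) -> float:
    """Correlation of two thresholded-allele indicators at latent correlation rho."""
    if rho == 0.0:
        return 0.0
    p11 = float(
        stats.multivariate_normal(cov=[[1.0, rho], [rho, 1.0]]).cdf([t1, t2])
    )
    denom = np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    return (p11 - p1 * p2) / denom


def max_attainable_r2(maf1: float, maf2: float) -> float:
    """Upper bound on genotype r² between loci with these allele frequencies.

    At the comonotonic limit the rarer allele is nested inside the commoner
    one, so the joint allele probability is min(maf1, maf2).
    """
    if maf1 in (0.0, 1.0) or maf2 in (0.0, 1.0):
        return 0.0
    r = (min(maf1, maf2) - maf1 * maf2) / np.sqrt(
        maf1 * (1 - maf1) * maf2 * (1 - maf2)
    )
    return float(r * r)


def _calibrate_rho(maf1: float, maf2: float, target_r2: float, tol: float) -> float:
    """Latent correlation whose implied allele correlation hits sqrt(target_r2).

    Clamps to the comonotonic boundary when the target exceeds the attainable
    maximum by no more than ``tol`` (the generator's calibration slack);
    beyond that the request is reported as unattainable.
    """
    if target_r2 == 0.0:
        return 0.0
    r2_max = max_attainable_r2(maf1, maf2)
    if target_r2 > r2_max + tol:
        raise UnattainableLdError(
            f"target r²={target_r2} unattainable for MAFs {maf1}/{maf2}; "
            f"maximum achievable is {r2_max:.4f}"
        )
    target_r = np.sqrt(target_r2)
    t1, t2 = stats.norm.ppf(maf1), stats.norm.ppf(maf2)
    lo, hi = 0.0, 1.0 - 1e-9
    if _allele_corr(hi, t1, t2, maf1, maf2) <= target_r:
        return hi
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _allele_corr(mid, t1, t2, maf1, maf2) < target_r:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-10:
            break
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# simulators


def _rng_streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("genotypes", "missingness", "covariates", "phenotype")
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _simulate_complete_genotypes(
    config: SimulationConfig, rng: np.random.Generator
) -> GenotypeMatrix:
    panel = config.resolved_panel()
    n = config.n_samples
    maf_of = {}
    for m in panel:
        if m.panel_maf is None:
            raise ConfigError(f"marker {m.rsid} has no panel MAF to simulate from")
        maf_of[m.rsid] = m.panel_maf
    in_pair = {r for a, b, _ in config.ld_pairs for r in (a, b)}
    cols: dict[str, np.ndarray] = {}
    # independent markers: two Bernoulli(MAF) allele draws summed -> HWE
    for m in panel:
        if m.rsid not in in_pair:
            cols[m.rsid] = rng.binomial(2, maf_of[m.rsid], size=n).astype(float)
    # LD pairs: shared latent bivariate normal per allele copy
    for a, b, target_r2 in config.ld_pairs:
        pa, pb = maf_of[a], maf_of[b]
        if pa in (0.0, 1.0) or pb in (0.0, 1.0):
            if target_r2 > 0.0:
                raise UnattainableLdError(
                    f"{a}/{b}: monomorphic marker cannot carry LD"
                )
            cols[a] = np.full(n, 2.0 * pa)
            cols[b] = np.full(n, 2.0 * pb)
            continue
        rho = _calibrate_rho(pa, pb, target_r2, config.ld_tolerance)
        ta, tb = stats.norm.ppf(pa), stats.norm.ppf(pb)
        da = np.zeros(n)
        db = np.zeros(n)
        for _copy in range(2):
            za = rng.standard_normal(n)
            zb = rho * za + np.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
            da += za < ta
            db += zb < tb
        cols[a], cols[b] = da, db
    dosages = np.column_stack([cols[m.rsid] for m in panel])
    sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    return GenotypeMatrix(sample_ids=sample_ids, markers=panel, dosages=dosages)


def _apply_missingness(
    genotypes: GenotypeMatrix, rate: float, rng: np.random.Generator
) -> GenotypeMatrix:
    if rate == 0.0:
        return genotypes
    mask = rng.random(genotypes.dosages.shape) < rate
    dos = genotypes.dosages.copy()
    dos[mask] = np.nan
    return GenotypeMatrix(
        sample_ids=list(genotypes.sample_ids),
        markers=list(genotypes.markers),
        dosages=dos,
    )


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """HWE genotypes at the panel MAFs, with LD pairs and uniform missingness."""
    config.validate()
    streams = _rng_streams(config.seed)
    complete = _simulate_complete_genotypes(config, streams["genotypes"])
    return _apply_missingness(complete, config.missing_rate, streams["missingness"])


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, low: float, n: int
) -> np.ndarray:
    """Normal draws resampled above ``low``; degenerate sd gives a constant."""
    if sd == 0.0:
        return np.full(n, mean)
    out = rng.normal(mean, sd, size=n)
    bad = out <= low
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= low
    return out


def simulate_covariates(config: SimulationConfig) -> CovariateTable:
    """Sex, age, BMI, activity and calcium at the configured moments."""
    config.validate()
    rng = _rng_streams(config.seed)["covariates"]
    n = config.n_samples
    data = pd.DataFrame(
        {
            "sex": (rng.random(n) < config.sex_split).astype(float),
            "age": _truncated_normal(rng, config.age_mean, config.age_sd, 0.0, n),
            "bmi": _truncated_normal(rng, config.bmi_mean, config.bmi_sd, 10.0, n),
            "physical_activity": _truncated_normal(
                rng, config.activity_mean, config.activity_sd, -1e-12, n
            ),
            "calcium_intake": _truncated_normal(
                rng, config.calcium_mean, config.calcium_sd, -1e-12, n
            ),
        }
    )
    sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    return CovariateTable(sample_ids=sample_ids, data=data)


def _coded(dosage: np.ndarray, coding: str) -> np.ndarray:
    if coding == "carrier":
        return (dosage >= 1).astype(float)
    if coding == "additive":
        return dosage
    raise ConfigError(f"unknown effect coding {coding!r}")


def simulate_phenotype(
    genotypes: GenotypeMatrix,
    covariates: CovariateTable,
    config: SimulationConfig,
) -> PhenotypeVector:
    """BUA = intercept + covariate terms + genotype terms + Gaussian noise.

    Each planted effect is applied on its own coding scale: a carrier-scale
    interaction of beta adds exactly beta to the both-carriers class over the
    additive prediction.  Effect markers must be complete (simulate the
    phenotype before applying missingness, as :func:`generate_cohort` does).
    """
    config.validate()
    if genotypes.sample_ids != covariates.sample_ids:
        raise ConfigError("genotypes and covariates are not aligned")
    rng = _rng_streams(config.seed)["phenotype"]
    n = len(genotypes.sample_ids)
    y = np.full(n, config.intercept, dtype=float)
    cov = covariates.as_array()
    for j, name in enumerate(COVARIATE_COLUMNS):
        beta = config.covariate_effects.get(name, 0.0)
        if beta:
            y += beta * cov[:, j]
    for eff in config.snp_effects:
        d = genotypes.column(eff.rsid)
        if np.isnan(d).any():
            raise ConfigError(
                f"effect marker {eff.rsid} has missing calls; simulate the "
                "phenotype from complete genotypes"
            )
        y += eff.beta * _coded(d, eff.coding)
    for eff in config.interaction_effects:
        d1, d2 = genotypes.column(eff.rsid1), genotypes.column(eff.rsid2)
        if np.isnan(d1).any() or np.isnan(d2).any():
            raise ConfigError(
                f"effect pair {eff.rsid1}/{eff.rsid2} has missing calls"
            )
        if eff.coding == "carrier":
            term = ((d1 >= 1) & (d2 >= 1)).astype(float)
        else:
            term = d1 * d2
        y += eff.beta * term
    if config.noise_sd > 0:
        y += rng.normal(0.0, config.noise_sd, size=n)
    return PhenotypeVector(sample_ids=list(genotypes.sample_ids), bua=y)


def generate_cohort(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> Cohort:
    """Compose the three simulators under one seed stream.

    The phenotype is computed from the complete genotypes; missingness is then
    applied to the released genotype matrix, so planted effects are exact.
    Optionally writes genotypes.tsv, covariates.tsv and phenotype.tsv.
    """
    config.validate()
    streams = _rng_streams(config.seed)
    complete = _simulate_complete_genotypes(config, streams["genotypes"])
    covariates = simulate_covariates(config)
    phenotype = simulate_phenotype(complete, covariates, config)
    genotypes = _apply_missingness(
        complete, config.missing_rate, streams["missingness"]
    )
    cohort = Cohort(genotypes, covariates, phenotype)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_genotypes(genotypes, out / "genotypes.tsv")
        write_covariates(covariates, out / "covariates.tsv")
        write_phenotype(phenotype, out / "phenotype.tsv")
    return cohort
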