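"""Synthetic pedigree, genotype, weather and phenotype generator.

The generator emulates the data-generating process assumed by the
reaction-norm model so that every downstream stage can be tested against
known truth: a sire-structured multi-generation pedigree, founder
genotypes at Hardy-Weinberg proportions dropped through the pedigree by
Mendelian inheritance, a sinusoidal seasonal weather series with daily
noise, and phenotypes assembled record by record as

    y = alpha*phi0 + beta*phi1(x) + CG + parity + a0*phi0 + a1*phi1(x)
        + pe + e(class)

with breeding values (a0, a1) drawn jointly from N(0, A (x) G) by the
pedigree-recursive rule, a permanent-environment effect per sow, and a
residual variance chosen by the record's covariate quintile class.  The
environmental covariate x is computed from the simulated weather through
the same interval/standardization code used at fitting time.

Conception dates are spread uniformly over the calendar so every
covariate quintile is populated; gestation is fixed at 114 days.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from heatnorm import env as env_mod
from heatnorm.basis import legendre_basis
from heatnorm.components import VarianceComponents
from heatnorm.relationship import GenotypeSet, build_A

_GESTATION = env_mod.GESTATION_DAYS


@dataclass
class WeatherParams:
    """Sinusoidal season + daily noise, North-American temperate defaults."""

    mean_temp: float = 15.0  # deg C
    seasonal_amplitude: float = 12.0  # deg C
    rh_mean: float = 70.0  # %
    rh_amplitude: float = 15.0  # %
    daily_noise_sd: float = 3.0
    diurnal_spread: float = 8.0  # t_max - t_min, deg C
    start_date: str = "2010-01-01"


@dataclass
class EnvSpec:
    """Which covariate column carries the simulated GxE signal."""

    variable: str = "THI"
    interval: int = 10

    @property
    def column(self) -> str:
        return env_mod.covariate_name(self.variable, self.interval)


@dataclass
class FixedEffects:
    """True fixed effects on the phenotype scale."""

    intercept: float = 50.0
    slope: float = -1.5  # fixed regression on phi1 (decline under heat load)
    parity_effects: tuple = (0.0, 1.5, 2.0, 1.5, 0.5)
    year_trend: float = 0.3  # per sow birth year


def _default_varcomp() -> VarianceComponents:
    return VarianceComponents(
        G=np.array([[9.0, 0.6], [0.6, 6.5]]),
        sigma2_pe=15.0,
        sigma2_e=np.array([30.0, 32.0, 34.0, 36.0, 38.0]),
    )


@dataclass
class SimConfig:
    """Study conditions for the synthetic dataset.

    Defaults produce roughly 500 recorded sows in 50 sire families with
    about 5,000 farrowing records and 2,000 SNPs; the true variance
    components sit at the magnitudes reported for sow litter traits on a
    percent-of-phenotypic-variance scale.
    """

    n_founders: int = 120
    n_generations: int = 3
    n_sires_per_gen: int = 25
    n_daughters_per_sire: int = 10
    n_sons_per_sire: int = 2
    n_snps: int = 2000
    n_chromosomes: int = 10
    maf_range: tuple = (0.10, 0.50)
    weather_params: WeatherParams = field(default_factory=WeatherParams)
    n_weather_days: int = 1461  # four years
    true_varcomp: VarianceComponents = field(default_factory=_default_varcomp)
    fixed_effects: FixedEffects = field(default_factory=FixedEffects)
    env_spec: EnvSpec = field(default_factory=EnvSpec)
    trait: str = "tnb"
    parities_range: tuple = (8, 12)
    base_year: int = 2008
    seed: int = 0

    def __post_init__(self):
        for name in (
            "n_founders", "n_generations", "n_sires_per_gen",
            "n_daughters_per_sire", "n_snps", "n_chromosomes",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent, reproducible stream per operation
    return np.random.default_rng([stream, config.seed])


# ---------------------------------------------------------------------------


def simulate_pedigree(config: SimConfig) -> pd.DataFrame:
    """Multi-generation sire-structured pedigree.

    Generation 1 animals are founders (both parents unknown, coded 0).
    In each later generation, ``n_sires_per_gen`` sires drawn from the
    previous generation's males each produce ``n_daughters_per_sire``
    daughters and ``n_sons_per_sire`` sons out of dams sampled from the
    previous generation's females.
    """
    rng = _rng(config, 1)
    n_male = max(config.n_sires_per_gen, config.n_founders // 4)
    if n_male >= config.n_founders and config.n_generations > 1:
        raise ValueError("not enough founders to provide both sexes")
    rows = []
    next_id = 1
    for i in range(config.n_founders):
        rows.append((next_id, 0, 0, "M" if i < n_male else "F", 1))
        next_id += 1
    for gen in range(2, config.n_generations + 1):
        prev = [r for r in rows if r[4] == gen - 1]
        males = [r[0] for r in prev if r[3] == "M"]
        females = [r[0] for r in prev if r[3] == "F"]
        if len(males) < config.n_sires_per_gen or not females:
            raise ValueError(
                f"generation {gen - 1} has too few breeding animals "
                f"({len(males)} males, {len(females)} females)"
            )
        sires = rng.choice(males, size=config.n_sires_per_gen, replace=False)
        for sire in sires:
            n_off = config.n_daughters_per_sire + config.n_sons_per_sire
            dams = rng.choice(females, size=n_off, replace=True)
            for k in range(n_off):
                sex = "F" if k < config.n_daughters_per_sire else "M"
                rows.append((next_id, int(sire), int(dams[k]), sex, gen))
                next_id += 1
    return pd.DataFrame(rows, columns=["animal", "sire", "dam", "sex", "generation"])


def simulate_genotypes(pedigree: pd.DataFrame, config: SimConfig) -> GenotypeSet:
    """Founders at HWE, descendants by Mendelian gene dropping.

    Each locus segregates independently (no linkage disequilibrium): the
    allele transmitted by a parent with dosage ``d`` is Bernoulli(d/2).
    """
    rng = _rng(config, 2)
    m = config.n_snps
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=m)

    per_chrom = np.full(config.n_chromosomes, m // config.n_chromosomes)
    per_chrom[: m % config.n_chromosomes] += 1
    chrom = np.repeat(np.arange(1, config.n_chromosomes + 1), per_chrom)
    pos = np.concatenate(
        [np.cumsum(rng.integers(5_000, 60_000, size=c)) for c in per_chrom]
    )
    snp_ids = np.array([f"SNP{c}_{p}" for c, p in zip(chrom, pos)])

    ids = pedigree["animal"].to_numpy()
    lookup = {a: i for i, a in enumerate(ids.tolist())}
    dosages = np.zeros((len(ids), m), dtype=np.int8)
    for i, row in enumerate(pedigree.itertuples(index=False)):
        if row.sire == 0 and row.dam == 0:
            dosages[i] = rng.binomial(2, maf, size=m)
        else:
            s = dosages[lookup[row.sire]]
            d = dosages[lookup[row.dam]]
            dosages[i] = rng.binomial(1, s / 2.0) + rng.binomial(1, d / 2.0)
    return GenotypeSet(ids=ids.copy(), snp_ids=snp_ids, chrom=chrom, pos=pos,
                       dosages=dosages)


def simulate_weather(n_days: int, config: SimConfig) -> pd.DataFrame:
    """Daily weather: seasonal sinusoid plus noise, RH clipped to [0, 100]."""
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = _rng(config, 3)
    wp = config.weather_params
    t = np.arange(n_days)
    season = np.sin(2.0 * np.pi * (t - 80.0) / 365.25)
    t_mean = (
        wp.mean_temp
        + wp.seasonal_amplitude * season
        + rng.normal(0.0, wp.daily_noise_sd, size=n_days)
    )
    # humidity peaks offset by a season quarter relative to temperature
    rh_season = np.sin(2.0 * np.pi * (t - 80.0) / 365.25 + np.pi / 2.0)
    rh = np.clip(
        wp.rh_mean
        + wp.rh_amplitude * rh_season
        + rng.normal(0.0, wp.daily_noise_sd, size=n_days),
        0.0,
        100.0,
    )
    half = 0.5 * wp.diurnal_spread
    t_max = t_mean + half + np.abs(rng.normal(0.0, 1.0, size=n_days))
    t_min = t_mean - half - np.abs(rng.normal(0.0, 1.0, size=n_days))
    dates = pd.date_range(wp.start_date, periods=n_days, freq="D")
    return pd.DataFrame(
        {"date": dates, "t_mean": t_mean, "t_min": t_min, "t_max": t_max, "rh": rh}
    )


def _sample_breeding_values(
    pedigree: pd.DataFrame, G: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Joint (a0, a1) ~ N(0, A (x) G) by the pedigree-recursive rule.

    bv_offspring = (bv_sire + bv_dam)/2 + Mendelian deviation with
    covariance G * (0.5 - 0.25 (F_s + F_d)); exact and linear in pedigree
    size, avoiding an explicit factorization of A (x) G.
    """
    amat = build_A(pedigree, max_generations=10**9)
    order = {a: i for i, a in enumerate(amat.ids.tolist())}
    F = amat.inbreeding
    L_full = np.linalg.cholesky(G + 1e-12 * np.eye(2))
    bv = np.zeros((len(amat.ids), 2))
    for row in pedigree.itertuples(index=False):
        i = order[row.animal]
        s = order.get(row.sire) if row.sire != 0 else None
        d = order.get(row.dam) if row.dam != 0 else None
        if s is None and d is None:
            mean, factor = np.zeros(2), 1.0
        elif s is not None and d is not None:
            mean = 0.5 * (bv[s] + bv[d])
            factor = 0.5 - 0.25 * (F[s] + F[d])
        else:
            p = s if s is not None else d
            mean = 0.5 * bv[p]
            factor = 0.75 - 0.25 * F[p]
        bv[i] = mean + np.sqrt(factor) * (L_full @ rng.standard_normal(2))
    # reorder to pedigree row order
    idx = np.array([order[a] for a in pedigree["animal"]], dtype=int)
    return bv[idx]


def simulate_phenotypes(
    pedigree: pd.DataFrame,
    weather: pd.DataFrame,
    env_spec: EnvSpec,
    config: SimConfig,
):
    """Farrowing records assembled exactly per the reaction-norm model.

    Every non-founder female becomes a recorded sow with a uniformly
    spread series of conception dates.  Returns the record table and a
    truth dict (breeding values, permanent-environment effects, record
    covariate values/classes, standardization stats and fixed effects)
    for recovery testing.
    """
    vc = config.true_varcomp
    if np.linalg.eigvalsh(vc.G).min() < -1e-10:
        raise ValueError("true G must be positive semidefinite")
    rng = _rng(config, 4)
    fx = config.fixed_effects

    sows = pedigree.loc[
        (pedigree["sex"] == "F") & (pedigree["generation"] > 1)
    ]
    if sows.empty:
        raise ValueError("pedigree has no non-founder females to record")

    lo_day = -env_mod.CYCLE_START  # need 21 days of weather before conception
    hi_day = len(weather) - (_GESTATION + 1)
    if hi_day <= lo_day:
        raise ValueError("weather series too short for a reproductive cycle")

    rows = []
    start = pd.to_datetime(weather["date"].iloc[0])
    pmin, pmax = config.parities_range
    for sow in sows.itertuples(index=False):
        n_par = int(rng.integers(pmin, pmax + 1))
        days = np.sort(rng.integers(lo_day, hi_day, size=n_par))
        for parity, day in enumerate(days, start=1):
            conception = start + pd.Timedelta(days=int(day))
            rows.append(
                (
                    sow.animal,
                    parity,
                    min(parity, 5),
                    config.base_year + int(sow.generation),
                    conception,
                    conception + pd.Timedelta(days=_GESTATION),
                )
            )
    records = pd.DataFrame(
        rows,
        columns=["sow", "parity", "parity_class", "birth_year", "conception",
                 "farrowing"],
    )

    # covariate through the same code path the fitting module uses
    spec = [s for s in env_mod.interval_specs() if s.index == env_spec.interval]
    table = env_mod.build_interval_covariates(
        weather, records, variables=(env_spec.variable,), intervals=spec
    )
    raw = table.data[env_spec.column].to_numpy()
    x, stats = env_mod.standardize_env(raw)
    boundaries = env_mod.quintile_boundaries(x)
    classes = env_mod.assign_residual_class(x, boundaries)
    phi0, phi1 = legendre_basis(x)

    bv = _sample_breeding_values(pedigree, vc.G, rng)
    animal_ids = pedigree["animal"].to_numpy()
    bv_idx = {a: i for i, a in enumerate(animal_ids.tolist())}
    sow_ids = records["sow"].to_numpy()
    rec_bv = bv[[bv_idx[s] for s in sow_ids]]

    unique_sows = np.unique(sow_ids)
    pe_map = dict(
        zip(unique_sows, rng.normal(0.0, np.sqrt(vc.sigma2_pe), len(unique_sows)))
    )
    pe = np.array([pe_map[s] for s in sow_ids])

    years = records["birth_year"].to_numpy()
    cg = fx.year_trend * (years - years.min())
    par = np.asarray(fx.parity_effects)[records["parity_class"].to_numpy() - 1]
    resid_sd = np.sqrt(vc.sigma2_e[classes - 1])
    e = rng.normal(0.0, resid_sd)

    y = (
        fx.intercept * phi0
        + fx.slope * phi1
        + cg
        + par
        + rec_bv[:, 0] * phi0
        + rec_bv[:, 1] * phi1
        + pe
        + e
    )
    records[config.trait] = y
    if config.trait == "tnb":
        records["nba"] = y - np.abs(rng.normal(1.0, 0.5, size=len(y)))
        records["abw"] = rng.normal(1.55, 0.26, size=len(y))
    else:
        # secondary traits only need plausible marginals
        records["tnb"] = rng.normal(11.5, 3.5, size=len(y))
        records["nba"] = records["tnb"] - np.abs(rng.normal(1.0, 0.5, size=len(y)))
        if "abw" not in records:
            records["abw"] = rng.normal(1.55, 0.26, size=len(y))

    truth = {
        "a": pd.DataFrame({"animal": animal_ids, "a0": bv[:, 0], "a1": bv[:, 1]}),
        "pe": pd.Series(pe_map),
        "x": x,
        "raw_env": raw,
        "class": classes,
        "env_stats": stats,
        "class_boundaries": boundaries,
        "env_column": env_spec.column,
        "fixed": {
            "intercept": fx.intercept,
            "slope": fx.slope,
            "parity_effects": list(fx.parity_effects),
            "year_trend": fx.year_trend,
        },
        "varcomp": vc,
    }
    return records, truth


@dataclass
class SimData:
    """Bundle of all simulated tables plus the generating truth."""

    config: SimConfig
    pedigree: pd.DataFrame
    genotypes: GenotypeSet
    weather: pd.DataFrame
    records: pd.DataFrame
    truth: dict


def simulate_dataset(config: SimConfig) -> SimData:
    """Run the full generator: pedigree, genotypes, weather, phenotypes."""
    pedigree = simulate_pedigree(config)
    genotypes = simulate_genotypes(pedigree, config)
    weather = simulate_weather(config.n_weather_days, config)
    records, truth = simulate_phenotypes(pedigree, weather, config.env_spec, config)
    return SimData(
        config=config,
        pedigree=pedigree,
        genotypes=genotypes,
        weather=weather,
        records=records,
        truth=truth,
    )
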