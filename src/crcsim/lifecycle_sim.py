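"""Discrete-generation island-model metapopulation with an auto-pseudogamous
life cycle.

Each generation, every deme of constant size ``deme_size`` is refilled by
offspring of its current members.  A mother (sampled with probability
proportional to fitness) produces each offspring either

* by **automixis** (probability ``sigma``): a diploid daughter via the
  modified meiosis of :mod:`crcsim.genome_meiosis` with cosegregation bias
  ``b`` -- the sperm activates the oocyte but contributes no DNA; or
* by **amphimixis** (probability ``1 - sigma``): a haploid maternal gamete
  fuses with the gamete of a fitness-sampled male of the same deme; the
  offspring is female with probability ``phi`` and male otherwise.

Males are required in a deme for any reproduction (sperm-dependent
parthenogenesis); a deme lacking males (or females) produces nothing that
generation and is refilled by offspring of the other demes (logged as a
failure).  Offspring migrate to a uniformly chosen other deme with
probability ``m``; reversible symmetric mutation acts on neutral loci at
rate ``mu_neutral`` per allele per generation; deme sizes are regulated
back to ``deme_size``.

Three fitness regimes are available: ``neutral`` (w = 1),
``phenomenological_delta`` (automictic offspring pay a cost proportional to
the genomic tract their conceiving meiosis rendered homozygous, normalised
so that random segregation, beta = 1/2, costs ``delta`` on average and full
CRC costs nothing; the underlying recessive load is treated as a constant
population property, so the cost is not purgeable by prior LOH) and
``explicit_deleterious`` (recessive-leaning deleterious mutations at rate
``U`` per diploid genome per generation, multiplicative fitness
``(1-h*s)`` per heterozygous and ``(1-s)`` per homozygous deleterious
locus -- LOH exposes them, an emergent inbreeding depression).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome_meiosis import (
    DiploidGenome,
    LocusMap,
    MeiosisConfig,
    automixis_batch,
    gamete_batch,
)
from .sumstats import GenotypeTable, fis_global

__all__ = [
    "Individual",
    "LifeCycleConfig",
    "Metapopulation",
    "SimulationResult",
    "init_population",
    "fitness_of",
    "generation_step",
    "run_simulation",
]

FITNESS_REGIMES = ("neutral", "phenomenological_delta", "explicit_deleterious")
SEX_RATIO_MODES = ("fixed_phi", "fixed_male_fraction")

ORIGIN_AUTOMICTIC = 0
ORIGIN_SEXUAL_FEMALE = 1
ORIGIN_MALE = 2


@dataclass
class Individual:
    """Single-individual view used by the per-individual API and tests."""

    genome: DiploidGenome
    sex: str                      # "female" | "male"
    origin: str                   # "automictic" | "sexual_female" | "male"
    loh_fraction: float = 0.0     # realized marker-LOH fraction at conception
    loh_tract_fraction: float = 0.0  # genome fraction homozygosed at conception
    deleterious: DiploidGenome | None = None
    sigma_alleles: tuple[float, float] | None = None
    bias_alleles: tuple[float, float] | None = None


@dataclass
class LifeCycleConfig:
    """Parameters of the metapopulation life cycle.

    Defaults follow the modelled natural conditions: total census 1000
    (10 demes of 100), migration m = 5e-4, 90% automictic daughters and no
    sexual females (so ~10% males), one obligate crossover per chromosome,
    10 chromosome pairs.
    """

    n_demes: int = 10
    deme_size: int = 100
    m: float = 5e-4
    sigma: float = 0.9
    phi: float = 0.0
    b: float = 1.0
    non_loh_mode: str = "recombinants_only"
    n_chromosomes: int = 10
    loci_per_chromosome: int = 10
    mu_neutral: float = 1e-3
    init_het: float = 1.0
    fitness_regime: str = "neutral"
    delta: float = 0.0
    U: float = 0.0
    s_del: float = 0.2
    h_del: float = 0.1
    del_loci_per_chromosome: int = 0
    generations: int = 200
    seed: int | None = None
    sperm_dependent: bool = True
    sex_ratio_mode: str = "fixed_phi"
    target_male_fraction: float = 0.1
    # modifier evolution (used by crcsim.modifier_evolution)
    evolvable_sigma: bool = False
    evolvable_bias: bool = False
    modifier_mut_rate: float = 0.01
    modifier_effect_sd: float = 0.2
    sigma_max: float = 0.9

    def __post_init__(self):
        for name in ("sigma", "phi", "m", "init_het", "mu_neutral"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        MeiosisConfig(b=self.b, non_loh_mode=self.non_loh_mode)  # validates
        if self.deme_size < 2:
            raise ValueError("deme_size must be at least 2")
        if self.n_demes < 1:
            raise ValueError("need at least one deme")
        if self.fitness_regime not in FITNESS_REGIMES:
            raise ValueError(f"fitness_regime must be one of {FITNESS_REGIMES}")
        if self.sex_ratio_mode not in SEX_RATIO_MODES:
            raise ValueError(f"sex_ratio_mode must be one of {SEX_RATIO_MODES}")
        if self.sperm_dependent:
            if self.sigma >= 1.0 and not self.evolvable_sigma:
                raise ValueError(
                    "sigma = 1 is not viable: males are needed to activate oocytes"
                )
            if self.male_fraction <= 0.0 and not self.evolvable_sigma:
                raise ValueError(
                    "the configured sigma/phi produce no males, but sperm is required"
                )
        if self.fitness_regime == "explicit_deleterious" and self.del_loci_per_chromosome < 1:
            raise ValueError("explicit_deleterious regime needs del_loci_per_chromosome >= 1")

    @property
    def male_fraction(self) -> float:
        """Expected male fraction rho = (1 - sigma) * (1 - phi)."""
        return (1.0 - self.sigma) * (1.0 - self.phi)

    @property
    def total_size(self) -> int:
        return self.n_demes * self.deme_size


@dataclass
class Metapopulation:
    """Array-of-individuals state; one row per individual."""

    config: LifeCycleConfig
    locus_map: LocusMap
    hap0: np.ndarray              # (N, L) int8, neutral loci
    hap1: np.ndarray
    male: np.ndarray              # (N,) bool
    deme: np.ndarray              # (N,) int
    origin: np.ndarray            # (N,) int8
    loh_fraction: np.ndarray      # (N,) float, marker LOH at conception
    loh_tract: np.ndarray | None = None   # (N,) genome fraction homozygosed
    fitness: np.ndarray = None    # (N,) float
    del_map: LocusMap | None = None
    del0: np.ndarray | None = None
    del1: np.ndarray | None = None
    sigma_alleles: np.ndarray | None = None   # (N, 2) float
    bias_alleles: np.ndarray | None = None    # (N, 2) float
    generation: int = 0
    extinct: bool = False
    deme_failures: list = field(default_factory=list)

    @property
    def size(self) -> int:
        return self.hap0.shape[0]

    # -- effective (possibly evolvable) life-cycle parameters -------------
    def sigma_of(self) -> np.ndarray:
        if self.sigma_alleles is None:
            return np.full(self.size, self.config.sigma)
        return np.clip(self.sigma_alleles.sum(axis=1), 0.0, self.config.sigma_max)

    def bias_of(self) -> np.ndarray:
        if self.bias_alleles is None:
            return np.full(self.size, self.config.b)
        return np.clip(self.bias_alleles.sum(axis=1), -1.0, 1.0)

    def phi_now(self) -> float:
        """Sexual-female rate, possibly adjusted to hold the male fraction."""
        cfg = self.config
        if cfg.sex_ratio_mode == "fixed_male_fraction":
            sbar = float(self.sigma_of()[~self.male].mean()) if (~self.male).any() else cfg.sigma
            amphi = max(1e-12, 1.0 - sbar)
            return float(np.clip(1.0 - cfg.target_male_fraction / amphi, 0.0, 1.0))
        return cfg.phi

    def het_mask(self) -> np.ndarray:
        return self.hap0 != self.hap1

    def mean_heterozygosity(self) -> float:
        return float(self.het_mask().mean())

    def genotype_table(self, max_individuals: int | None = None) -> GenotypeTable:
        sel = np.arange(self.size)
        if max_individuals is not None and max_individuals < self.size:
            sel = sel[:: max(1, self.size // max_individuals)][:max_individuals]
        return GenotypeTable.from_haplotypes(
            self.hap0[sel], self.hap1[sel], self.locus_map, groups=self.deme[sel]
        )

    def individual(self, i: int) -> Individual:
        genome = DiploidGenome(self.locus_map, self.hap0[i].copy(), self.hap1[i].copy())
        deleterious = None
        if self.del0 is not None:
            deleterious = DiploidGenome(self.del_map, self.del0[i].copy(), self.del1[i].copy())
        origin = {ORIGIN_AUTOMICTIC: "automictic", ORIGIN_SEXUAL_FEMALE: "sexual_female",
                  ORIGIN_MALE: "male"}[int(self.origin[i])]
        return Individual(
            genome=genome,
            sex="male" if self.male[i] else "female",
            origin=origin,
            loh_fraction=float(self.loh_fraction[i]),
            loh_tract_fraction=float(self.loh_tract[i]) if self.loh_tract is not None else 0.0,
            deleterious=deleterious,
            sigma_alleles=tuple(self.sigma_alleles[i]) if self.sigma_alleles is not None else None,
            bias_alleles=tuple(self.bias_alleles[i]) if self.bias_alleles is not None else None,
        )


# Expected genome fraction homozygosed by one automictic meiosis at random
# segregation (beta = 1/2): each chromosome loses its distal tract 1 - x
# (x ~ Uniform) with probability 1/2, so E = 1/2 * 1/2 = 1/4.  Normalises
# the phenomenological cost so that beta = 1/2 costs exactly delta on
# average and full CRC (b = 1) costs nothing.
EXPECTED_TRACT_RANDOM = 0.25


def expected_loh_fraction_random(locus_map: LocusMap) -> float:
    """E[marker LOH fraction] at beta = 1/2 with one uniform CO.

    A heterozygous locus at position p is distal to a Uniform(0,1) crossover
    with probability p, so the genome-mean LOH fraction at beta is
    beta * mean(p); at beta = 1/2 and loci centred on the chromosome this is
    1/4 (matching :data:`EXPECTED_TRACT_RANDOM`).
    """
    return 0.5 * float(locus_map.position.mean())


def init_population(
    config: LifeCycleConfig,
    init_het: float | None = None,
    rng: np.random.Generator | None = None,
) -> Metapopulation:
    """Initial metapopulation.

    Each neutral locus is heterozygous with probability ``init_het`` per
    individual (random phase; homozygous loci get a fair-coin allele), sexes
    match the expected male fraction, and every deme is guaranteed one
    individual of each sex.  Deleterious loci start empty.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    het = config.init_het if init_het is None else init_het
    if not 0.0 <= het <= 1.0:
        raise ValueError("init_het must lie in [0, 1]")
    N = config.total_size
    lm = LocusMap.even(config.n_chromosomes, config.loci_per_chromosome)
    L = lm.n_loci
    is_het = rng.random((N, L)) < het
    base = rng.integers(0, 2, (N, L)).astype(np.int8)
    phase = rng.integers(0, 2, (N, L)).astype(np.int8)
    hap0 = np.where(is_het, phase, base).astype(np.int8)
    hap1 = np.where(is_het, 1 - phase, base).astype(np.int8)

    male = rng.random(N) < config.male_fraction
    deme = np.repeat(np.arange(config.n_demes), config.deme_size)
    # guarantee both sexes per deme
    for d in range(config.n_demes):
        rows = np.flatnonzero(deme == d)
        if not male[rows].any():
            male[rng.choice(rows)] = True
        if male[rows].all():
            male[rng.choice(rows)] = False

    # founding females labelled by the reproduction mode that would have
    # produced them at the configured sigma
    female_auto = rng.random(N) < config.sigma
    origin = np.where(
        male, ORIGIN_MALE, np.where(female_auto, ORIGIN_AUTOMICTIC, ORIGIN_SEXUAL_FEMALE)
    ).astype(np.int8)

    del_map = del0 = del1 = None
    if config.del_loci_per_chromosome > 0:
        del_map = LocusMap.even(config.n_chromosomes, config.del_loci_per_chromosome)
        del0 = np.zeros((N, del_map.n_loci), np.int8)
        del1 = np.zeros((N, del_map.n_loci), np.int8)

    sigma_alleles = None
    if config.evolvable_sigma:
        sigma_alleles = np.full((N, 2), config.sigma / 2.0)
    bias_alleles = None
    if config.evolvable_bias:
        bias_alleles = np.full((N, 2), config.b / 2.0)

    pop = Metapopulation(
        config=config,
        locus_map=lm,
        hap0=hap0,
        hap1=hap1,
        male=male,
        deme=deme,
        origin=origin,
        loh_fraction=np.zeros(N),
        loh_tract=np.zeros(N),
        fitness=np.ones(N),
        del_map=del_map,
        del0=del0,
        del1=del1,
        sigma_alleles=sigma_alleles,
        bias_alleles=bias_alleles,
    )
    pop.fitness = _population_fitness(pop)
    return pop


def _population_fitness(pop: Metapopulation) -> np.ndarray:
    cfg = pop.config
    if cfg.fitness_regime == "neutral":
        return np.ones(pop.size)
    if cfg.fitness_regime == "phenomenological_delta":
        w = np.ones(pop.size)
        auto = pop.origin == ORIGIN_AUTOMICTIC
        w[auto] = 1.0 - cfg.delta * pop.loh_tract[auto] / EXPECTED_TRACT_RANDOM
        return np.clip(w, 0.0, None)
    # explicit deleterious
    het = (pop.del0 != pop.del1).sum(axis=1)
    hom = ((pop.del0 == 1) & (pop.del1 == 1)).sum(axis=1)
    return (1.0 - cfg.h_del * cfg.s_del) ** het * (1.0 - cfg.s_del) ** hom


def fitness_of(individual: Individual, config: LifeCycleConfig) -> float:
    """Fitness of a single individual under the configured regime."""
    if config.fitness_regime == "neutral":
        return 1.0
    if config.fitness_regime == "phenomenological_delta":
        if individual.origin != "automictic":
            return 1.0
        w = 1.0 - config.delta * individual.loh_tract_fraction / EXPECTED_TRACT_RANDOM
        if w < 0.0:
            warnings.warn("negative fitness clamped to 0")
            return 0.0
        return w
    if individual.deleterious is None:
        return 1.0
    d = individual.deleterious
    het = int((d.hap0 != d.hap1).sum())
    hom = int(((d.hap0 == 1) & (d.hap1 == 1)).sum())
    return (1.0 - config.h_del * config.s_del) ** het * (1.0 - config.s_del) ** hom


def _mutate_modifier_alleles(alleles, rate, sd, rng):
    if alleles is None or rate <= 0:
        return alleles
    hit = rng.random(alleles.shape) < rate
    alleles[hit] += rng.normal(0.0, sd, int(hit.sum()))
    return alleles


def generation_step(
    pop: Metapopulation, config: LifeCycleConfig | None = None,
    rng: np.random.Generator | None = None,
) -> Metapopulation:
    """Advance one non-overlapping generation; returns the new population."""
    cfg = config if config is not None else pop.config
    if rng is None:
        raise ValueError("rng is required")
    if pop.extinct:
        return pop

    N, L = pop.hap0.shape
    lm = pop.locus_map
    has_del = pop.del0 is not None
    phi = pop.phi_now()
    sigma_i = pop.sigma_of()
    bias_i = pop.bias_of()

    new_hap0 = np.empty((N, L), np.int8)
    new_hap1 = np.empty((N, L), np.int8)
    new_del0 = np.empty_like(pop.del0) if has_del else None
    new_del1 = np.empty_like(pop.del1) if has_del else None
    new_male = np.zeros(N, bool)
    new_deme = np.empty(N, np.int64)
    new_origin = np.empty(N, np.int8)
    new_loh = np.zeros(N)
    new_tract = np.zeros(N)
    new_sig = np.zeros((N, 2)) if pop.sigma_alleles is not None else None
    new_bias = np.zeros((N, 2)) if pop.bias_alleles is not None else None

    filled = np.zeros(N, bool)
    cursor = 0
    failures = []

    for d in range(cfg.n_demes):
        rows = np.flatnonzero(pop.deme == d)
        females = rows[~pop.male[rows]]
        males = rows[pop.male[rows]]
        needs_males = cfg.sperm_dependent or (sigma_i[females].mean() < 1.0 if females.size else True)
        if females.size == 0 or (needs_males and males.size == 0):
            failures.append((pop.generation + 1, d, "missing sex"))
            continue
        wf = pop.fitness[females]
        if wf.sum() <= 0:
            failures.append((pop.generation + 1, d, "zero female fitness"))
            continue
        k = cfg.deme_size
        mothers = rng.choice(females, size=k, p=wf / wf.sum())
        auto = rng.random(k) < sigma_i[mothers]
        if males.size == 0:
            # only reachable without sperm dependence: no fathers available
            auto[:] = True
        n_auto = int(auto.sum())
        n_amph = k - n_auto
        sl = slice(cursor, cursor + k)
        idx_auto = np.flatnonzero(auto) + cursor
        idx_amph = np.flatnonzero(~auto) + cursor

        if n_auto:
            am = mothers[auto]
            blocks = [(pop.hap0[am], pop.hap1[am])]
            maps = [lm]
            if has_del:
                blocks.append((pop.del0[am], pop.del1[am]))
                maps.append(pop.del_map)
            beta = 0.5 * (1.0 - bias_i[am])
            out, loh_count, het_count, tract = automixis_batch(
                blocks, maps, beta, rng, non_loh_mode=cfg.non_loh_mode
            )
            new_hap0[idx_auto], new_hap1[idx_auto] = out[0]
            if has_del:
                new_del0[idx_auto], new_del1[idx_auto] = out[1]
            with np.errstate(invalid="ignore"):
                lf = np.where(het_count > 0, loh_count / np.maximum(het_count, 1), 0.0)
            new_loh[idx_auto] = lf
            new_tract[idx_auto] = tract
            new_origin[idx_auto] = ORIGIN_AUTOMICTIC
            # modifier inheritance: both maternal alleles; LOH at an unlinked
            # modifier locus with probability beta/2 homozygoses a random allele
            for alleles, store in ((pop.sigma_alleles, new_sig), (pop.bias_alleles, new_bias)):
                if alleles is None:
                    continue
                inherited = alleles[am].copy()
                loh_mod = rng.random(n_auto) < 0.5 * beta
                pick = rng.integers(0, 2, n_auto)
                fix = inherited[np.arange(n_auto), pick]
                inherited[loh_mod, 0] = fix[loh_mod]
                inherited[loh_mod, 1] = fix[loh_mod]
                store[idx_auto] = inherited

        if n_amph:
            wm = pop.fitness[males]
            if wm.sum() <= 0:
                wm = np.ones(males.size)
            fathers = rng.choice(males, size=n_amph, p=wm / wm.sum())
            sm = mothers[~auto]
            blocks_m = [(pop.hap0[sm], pop.hap1[sm])]
            blocks_f = [(pop.hap0[fathers], pop.hap1[fathers])]
            maps = [lm]
            if has_del:
                blocks_m.append((pop.del0[sm], pop.del1[sm]))
                blocks_f.append((pop.del0[fathers], pop.del1[fathers]))
                maps.append(pop.del_map)
            gm = gamete_batch(blocks_m, maps, rng)
            gf = gamete_batch(blocks_f, maps, rng)
            new_hap0[idx_amph], new_hap1[idx_amph] = gm[0], gf[0]
            if has_del:
                new_del0[idx_amph], new_del1[idx_amph] = gm[1], gf[1]
            is_female = rng.random(n_amph) < phi
            new_male[idx_amph] = ~is_female
            new_origin[idx_amph] = np.where(is_female, ORIGIN_SEXUAL_FEMALE, ORIGIN_MALE)
            for alleles, store in ((pop.sigma_alleles, new_sig), (pop.bias_alleles, new_bias)):
                if alleles is None:
                    continue
                store[idx_amph, 0] = alleles[sm, rng.integers(0, 2, n_amph)]
                store[idx_amph, 1] = alleles[fathers, rng.integers(0, 2, n_amph)]

        new_deme[sl] = d
        filled[sl] = True
        cursor += k

    if cursor == 0:
        pop.extinct = True
        pop.deme_failures.extend(failures)
        return pop

    # trim to the offspring actually produced
    prod = slice(0, cursor)
    hap0, hap1 = new_hap0[prod], new_hap1[prod]
    male, deme = new_male[prod], new_deme[prod]
    origin, loh = new_origin[prod], new_loh[prod]
    tract = new_tract[prod]
    d0 = new_del0[prod] if has_del else None
    d1 = new_del1[prod] if has_del else None
    sig = new_sig[prod] if new_sig is not None else None
    bia = new_bias[prod] if new_bias is not None else None
    n = cursor

    # migration: each offspring moves to a uniform other deme w.p. m
    if cfg.m > 0 and cfg.n_demes > 1:
        mig = rng.random(n) < cfg.m
        if mig.any():
            shift = rng.integers(1, cfg.n_demes, int(mig.sum()))
            deme[mig] = (deme[mig] + shift) % cfg.n_demes

    # regulation back to deme_size per deme; empty demes are recolonised
    # from the pooled offspring (logged), keeping the census constant
    keep = []
    for d in range(cfg.n_demes):
        rows = np.flatnonzero(deme == d)
        if rows.size == 0:
            failures.append((pop.generation + 1, d, "recolonised"))
            rows = rng.choice(n, size=cfg.deme_size, replace=True)
            keep.append((d, rows))
        elif rows.size > cfg.deme_size:
            keep.append((d, rng.choice(rows, size=cfg.deme_size, replace=False)))
        elif rows.size < cfg.deme_size:
            extra = rng.choice(rows, size=cfg.deme_size - rows.size, replace=True)
            keep.append((d, np.concatenate([rows, extra])))
        else:
            keep.append((d, rows))
    order = np.concatenate([r for _, r in keep])
    deme_final = np.repeat([d for d, _ in keep], cfg.deme_size)

    hap0, hap1 = hap0[order], hap1[order]
    male, origin, loh = male[order], origin[order], loh[order]
    tract = tract[order]
    if has_del:
        d0, d1 = d0[order], d1[order]
    if sig is not None:
        sig = sig[order]
    if bia is not None:
        bia = bia[order]

    # neutral mutation: symmetric reversible flips
    if cfg.mu_neutral > 0:
        for h in (hap0, hap1):
            flip = rng.random(h.shape) < cfg.mu_neutral
            h ^= flip.astype(np.int8)

    # deleterious mutation: Poisson(U) new mutations per diploid genome
    if has_del and cfg.U > 0:
        n_mut = rng.poisson(cfg.U, N)
        hit = np.flatnonzero(n_mut)
        for i in hit:
            loci = rng.integers(0, pop.del_map.n_loci, n_mut[i])
            which = rng.integers(0, 2, n_mut[i])
            d0[i, loci[which == 0]] = 1
            d1[i, loci[which == 1]] = 1

    # modifier mutation
    sig = _mutate_modifier_alleles(sig, cfg.modifier_mut_rate if cfg.evolvable_sigma else 0.0,
                                   cfg.modifier_effect_sd, rng)
    bia = _mutate_modifier_alleles(bia, cfg.modifier_mut_rate if cfg.evolvable_bias else 0.0,
                                   cfg.modifier_effect_sd, rng)

    child = Metapopulation(
        config=cfg,
        locus_map=lm,
        hap0=hap0,
        hap1=hap1,
        male=male,
        deme=deme_final,
        origin=origin,
        loh_fraction=loh,
        loh_tract=tract,
        fitness=np.ones(N),
        del_map=pop.del_map,
        del0=d0,
        del1=d1,
        sigma_alleles=sig,
        bias_alleles=bia,
        generation=pop.generation + 1,
        deme_failures=pop.deme_failures + failures,
    )
    child.fitness = _population_fitness(child)
    return child


@dataclass
class SimulationResult:
    """Per-generation records plus the final population."""

    records: pd.DataFrame
    final: Metapopulation
    extinct: bool = False

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def _record(pop: Metapopulation, compute_fis: bool) -> dict:
    females = ~pop.male
    rec = {
        "generation": pop.generation,
        "mean_het": pop.mean_heterozygosity(),
        "male_fraction": float(pop.male.mean()),
        "mean_fitness": float(pop.fitness.mean()),
        "mean_sigma": float(pop.sigma_of()[females].mean()) if females.any() else np.nan,
        "mean_b": float(pop.bias_of()[females].mean()) if females.any() else np.nan,
        "pseudogamous_female_fraction": float(
            (pop.origin[females] == ORIGIN_AUTOMICTIC).mean()
        ) if females.any() else np.nan,
    }
    if compute_fis:
        rec["fis"] = fis_global(pop.genotype_table())
    else:
        rec["fis"] = np.nan
    return rec


def run_simulation(
    config: LifeCycleConfig,
    rng: np.random.Generator | None = None,
    record_every: int = 1,
    fis_every: int = 10,
    stop_when=None,
) -> SimulationResult:
    """Run the life cycle for ``config.generations`` generations.

    Deterministic given the config seed (or a supplied generator).
    ``stop_when(pop) -> bool`` allows early stopping (e.g. fixation of an
    invading modifier); extinction is reported in the result, not raised.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pop = init_population(config, rng=rng)
    records = [_record(pop, compute_fis=True)]
    for _ in range(config.generations):
        pop = generation_step(pop, rng=rng)
        if pop.extinct:
            break
        if pop.generation % record_every == 0:
            records.append(_record(pop, compute_fis=pop.generation % fis_every == 0))
        if stop_when is not None and stop_when(pop):
            break
    return SimulationResult(pd.DataFrame(records), pop, extinct=pop.extinct)
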