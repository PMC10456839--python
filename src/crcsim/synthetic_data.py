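"""Synthetic-data generators for every analysis stage.

Three generators emulate the statistical structure of the study's inputs
with no external data:

* :func:`gen_trio_readcounts` -- per-site, per-sister base read counts for a
  three-sister trio, under a pseudogamous-CRC, pseudogamous-random or sexual
  inheritance mode, with dispersed coverage and uniform base-miscall error;
  truth genotypes are returned for exact scoring of the caller and screen.
* :func:`gen_metapop_genotypes` -- diploid genotypes (with truth phase) from
  a life-cycle simulation, or from a Hardy-Weinberg shortcut used to
  calibrate the F_IS estimator.
* :func:`gen_embryo_paints` -- EdU chromatid-paint embryo tables.

Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome_meiosis import LocusMap
from .lifecycle_sim import LifeCycleConfig, run_simulation
from .parity_test import simulate_paints
from .sibhet_lrt import BASES, N_SISTERS, ReadCountMatrix
from .sumstats import GenotypeTable

__all__ = [
    "TrioSpec",
    "MetapopSpec",
    "PaintSpec",
    "gen_trio_readcounts",
    "gen_metapop_genotypes",
    "gen_embryo_paints",
]

TRIO_MODES = ("pseudogamous_crc", "pseudogamous_random", "sexual")


@dataclass(frozen=True)
class TrioSpec:
    """Three sisters, read counts at polymorphic candidate sites.

    ``mode`` fixes the daughter-genotype law: under ``pseudogamous_crc``
    daughters copy the mother's heterozygous genotype at every site; under
    ``pseudogamous_random`` each daughter independently loses heterozygosity
    at a site with probability beta * p_distal = 1/4 (random segregation,
    marginal distal probability 1/2); under ``sexual`` daughters are
    Mendelian offspring of two heterozygous parents.  Coverage per site and
    sister is negative-binomial around ``coverage_mean`` (gamma-Poisson,
    shape ``coverage_shape``); sequencing errors scatter uniformly to the
    three other bases at rate ``error_rate``.
    """

    mode: str = "pseudogamous_crc"
    n_sites: int = 2000
    n_contigs: int = 40
    coverage_mean: float = 30.0
    coverage_shape: float = 10.0
    error_rate: float = 0.005
    maternal_het: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.mode not in TRIO_MODES:
            raise ValueError(f"mode must be one of {TRIO_MODES}")
        if self.n_sites < 1 or self.n_contigs < 1:
            raise ValueError("need at least one site and one contig")
        if not 0.0 <= self.error_rate < 0.75:
            raise ValueError("error_rate must be a small probability")


def _draw_coverage(rng, spec: TrioSpec, shape) -> np.ndarray:
    lam = rng.gamma(spec.coverage_shape, spec.coverage_mean / spec.coverage_shape, shape)
    return rng.poisson(lam)


def gen_trio_readcounts(spec: TrioSpec) -> tuple[ReadCountMatrix, pd.DataFrame]:
    """Read counts plus a truth table of the underlying genotypes.

    Each site carries two alleles drawn among A,C,G,T; truth genotypes are
    coded per sister as ``het`` or ``hom0``/``hom1`` (first/second allele).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_sites
    # two distinct bases per site
    first = rng.integers(0, 4, n)
    second = (first + rng.integers(1, 4, n)) % 4

    mother_het = rng.random(n) < spec.maternal_het
    # daughter genotype codes: 0 = hom first allele, 1 = het, 2 = hom second
    geno = np.ones((N_SISTERS, n), np.int8)
    if spec.mode == "pseudogamous_crc":
        geno[:, ~mother_het] = 0
    elif spec.mode == "pseudogamous_random":
        geno[:, ~mother_het] = 0
        loh = rng.random((N_SISTERS, n)) < 0.25
        side = rng.integers(0, 2, (N_SISTERS, n)).astype(np.int8) * 2
        m = loh & mother_het[None, :]
        geno[m] = side[m]
    else:  # sexual: het x het cross per polymorphic site
        alleles = rng.integers(0, 2, (N_SISTERS, n, 2)).sum(axis=2).astype(np.int8)
        geno = alleles  # 0,1,2 copies of the second allele -> hom0/het/hom2
        geno[:, ~mother_het] = 0

    contig = np.repeat(
        [f"contig{c:04d}" for c in range(spec.n_contigs)],
        int(np.ceil(n / spec.n_contigs)),
    )[:n]
    pos = np.concatenate(
        [np.arange(int((contig == c).sum())) * 37 + 11 for c in pd.unique(contig)]
    )

    cov = _draw_coverage(rng, spec, (n, N_SISTERS))
    counts = np.zeros((n, N_SISTERS, 4), np.int64)
    e = spec.error_rate
    for s in range(N_SISTERS):
        for code in (0, 1, 2):
            m = np.flatnonzero(geno[s] == code)
            if m.size == 0:
                continue
            # per-read base probabilities for each site in this genotype class
            p = np.full((m.size, 4), e / 3.0)
            rows = np.arange(m.size)
            if code == 1:
                p[rows, first[m]] = 0.5 * (1 - e) + 0.5 * e / 3.0
                p[rows, second[m]] = 0.5 * (1 - e) + 0.5 * e / 3.0
            else:
                hom = first[m] if code == 0 else second[m]
                p[rows, hom] = 1.0 - e
            for j, i in enumerate(m):
                counts[i, s] = rng.multinomial(cov[i, s], p[j])

    matrix = ReadCountMatrix(counts, contig, pos)
    truth = pd.DataFrame(
        {
            "contig": contig,
            "pos": pos,
            "allele0": [BASES[i] for i in first],
            "allele1": [BASES[i] for i in second],
            "mother_het": mother_het,
            **{f"sister{s}_genotype": np.select(
                [geno[s] == 0, geno[s] == 1, geno[s] == 2],
                ["hom0", "het", "hom1"],
                default="hom0",
            ) for s in range(N_SISTERS)},
        }
    )
    return matrix, truth


@dataclass(frozen=True)
class MetapopSpec:
    """Genotype-table generator: life-cycle simulation or HW shortcut."""

    config: LifeCycleConfig = field(default_factory=LifeCycleConfig)
    generations: int | None = None
    n_sampled: int | None = None
    hw_shortcut: bool = False
    hw_n_individuals: int = 100
    hw_n_loci: int = 200
    hw_allele_freq: float = 0.5
    seed: int = 0
    max_retries: int = 3


def gen_metapop_genotypes(spec: MetapopSpec) -> GenotypeTable:
    """Genotype table (with truth phase) for the heterozygosity/F_IS stages.

    With ``hw_shortcut`` genotypes are drawn directly at Hardy-Weinberg
    proportions (no simulation) -- the calibration input for which F_IS = 0
    by construction.  Otherwise the life-cycle simulation is run and its
    final population exported; extinct runs are re-seeded up to
    ``max_retries`` times (logged on the returned table as ``retries``).
    """
    rng = np.random.default_rng(spec.seed)
    if spec.hw_shortcut:
        n, L = spec.hw_n_individuals, spec.hw_n_loci
        hap0 = (rng.random((n, L)) < spec.hw_allele_freq).astype(np.int8)
        hap1 = (rng.random((n, L)) < spec.hw_allele_freq).astype(np.int8)
        lm = LocusMap.even(1, L)
        return GenotypeTable.from_haplotypes(hap0, hap1, lm)

    cfg = spec.config
    if spec.generations is not None:
        cfg = replace(cfg, generations=spec.generations)
    retries = 0
    while True:
        result = run_simulation(replace(cfg, seed=int(rng.integers(2**31))))
        if not result.extinct:
            break
        retries += 1
        if retries > spec.max_retries:
            raise RuntimeError("simulation went extinct in every retry")
    pop = result.final
    sel = np.arange(pop.size)
    if spec.n_sampled is not None and spec.n_sampled < pop.size:
        sel = np.sort(rng.choice(pop.size, spec.n_sampled, replace=False))
    table = GenotypeTable.from_haplotypes(
        pop.hap0[sel], pop.hap1[sel], pop.locus_map, groups=pop.deme[sel]
    )
    table.retries = retries
    return table


@dataclass(frozen=True)
class PaintSpec:
    """EdU chromatid-paint embryo table generator."""

    b: float = 1.0
    n_embryos: int = 11
    n_pairs: int = 10
    visibility: float = 0.5
    non_loh_mode: str = "recombinants_only"
    seed: int = 0


def gen_embryo_paints(spec: PaintSpec) -> pd.DataFrame:
    """Per-embryo bicolor-chromatid counts in the parity CLI's TSV schema."""
    rng = np.random.default_rng(spec.seed)
    embryos = simulate_paints(
        spec.b,
        spec.n_embryos,
        n_pairs=spec.n_pairs,
        visibility=spec.visibility,
        rng=rng,
        non_loh_mode=spec.non_loh_mode,
    )
    return pd.DataFrame(
        {
            "embryo": np.arange(len(embryos)),
            "bicolor_count": [e.bicolor_count for e in embryos],
            "recombinant_count": [e.recombinant_count for e in embryos],
            "is_even": [e.is_even for e in embryos],
        }
    )
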