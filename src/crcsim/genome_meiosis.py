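"""Genome representation and the three transmission modes of a recombining
auto-pseudogamous nematode.

The organism is diploid with ``C`` holocentric chromosome pairs.  Female
meiosis comes in two flavours:

* **amphimixis** -- canonical meiosis.  One obligate crossover (CO) per
  chromosome, then one of the four chromatids is transmitted to a haploid
  gamete.
* **automixis** -- meiosis I aborts after recombination; a single equational
  division retains two *nonsister* chromatids (one per homolog) in the
  diploid oocyte.  Which nonsister pair is retained is governed by the
  cosegregation bias ``b``: with probability ``1 - beta`` (where
  ``beta = (1 - b) / 2``) a heterozygosity-conserving pair is kept (the two
  recombinants, or optionally the two nonrecombinants), and with probability
  ``beta`` a {recombinant, nonrecombinant} pair is kept, which renders every
  maternally heterozygous locus distal to the crossover homozygous (loss of
  heterozygosity, LOH).

``b = 1`` is full cosegregation of recombinant chromatids (CRC; no LOH),
``b = 0`` is random nonsister assortment (beta = 1/2), and ``b = -1`` is
complete anti-cosegregation (beta = 1, every distal locus loses
heterozygosity).

Loci live at real-valued positions in [0, 1) along each chromosome; "distal"
means position greater than the crossover coordinate (orientation can be
flipped per configuration).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LocusMap",
    "DiploidGenome",
    "Tetrad",
    "MeiosisConfig",
    "place_crossover",
    "form_tetrad",
    "automictic_oocyte",
    "amphimictic_gamete",
    "realized_loh_fraction",
]

NON_LOH_MODES = ("recombinants_only", "rec_or_nonrec_equal")


@dataclass(frozen=True)
class LocusMap:
    """Positions of biallelic loci on ``n_chromosomes`` chromosomes.

    Stored flat: ``chromosome[i]`` and ``position[i]`` give the chromosome
    index and the relative coordinate (in [0, 1)) of locus ``i``.  Positions
    are strictly increasing within a chromosome.
    """

    chromosome: np.ndarray
    position: np.ndarray

    def __post_init__(self):
        chrom = np.asarray(self.chromosome, dtype=np.int64)
        pos = np.asarray(self.position, dtype=np.float64)
        if chrom.shape != pos.shape or chrom.ndim != 1 or chrom.size < 1:
            raise ValueError("chromosome and position must be equal-length 1-D arrays")
        if np.any(np.diff(chrom) < 0):
            raise ValueError("loci must be grouped by chromosome in ascending order")
        if np.any(pos < 0.0) or np.any(pos > 1.0):
            raise ValueError("locus positions must lie in [0, 1]")
        for c in np.unique(chrom):
            p = pos[chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions on chromosome {c} must be strictly increasing")
        object.__setattr__(self, "chromosome", chrom)
        object.__setattr__(self, "position", pos)

    @property
    def n_loci(self) -> int:
        return self.position.size

    @property
    def n_chromosomes(self) -> int:
        return int(self.chromosome.max()) + 1

    def loci_of(self, chromosome_index: int) -> np.ndarray:
        """Indices of the loci on one chromosome."""
        return np.flatnonzero(self.chromosome == chromosome_index)

    def chromosome_slices(self) -> list[slice]:
        """Per-chromosome contiguous slices into the flat locus arrays."""
        out = []
        for c in range(self.n_chromosomes):
            idx = np.flatnonzero(self.chromosome == c)
            if idx.size:
                out.append(slice(int(idx[0]), int(idx[-1]) + 1))
            else:
                out.append(slice(0, 0))
        return out

    @classmethod
    def even(cls, n_chromosomes: int, loci_per_chromosome: int) -> "LocusMap":
        """Evenly spaced loci: positions (k+1)/(L+1), k = 0..L-1, per chromosome."""
        if n_chromosomes < 1 or loci_per_chromosome < 1:
            raise ValueError("need at least one chromosome and one locus")
        chrom = np.repeat(np.arange(n_chromosomes), loci_per_chromosome)
        pos = np.tile(
            (np.arange(loci_per_chromosome) + 1.0) / (loci_per_chromosome + 1.0),
            n_chromosomes,
        )
        return cls(chrom, pos)

    @classmethod
    def random(cls, n_chromosomes: int, loci_per_chromosome: int, rng: np.random.Generator) -> "LocusMap":
        """Uniformly scattered loci (sorted within chromosomes)."""
        chrom = np.repeat(np.arange(n_chromosomes), loci_per_chromosome)
        pos = np.sort(
            rng.random((n_chromosomes, loci_per_chromosome)), axis=1
        ).ravel()
        return cls(chrom, pos)


@dataclass
class DiploidGenome:
    """Two haplotypes of 0/1 alleles indexed by a :class:`LocusMap`."""

    locus_map: LocusMap
    hap0: np.ndarray
    hap1: np.ndarray

    def __post_init__(self):
        self.hap0 = np.asarray(self.hap0, dtype=np.int8)
        self.hap1 = np.asarray(self.hap1, dtype=np.int8)
        if self.hap0.shape != (self.locus_map.n_loci,) or self.hap1.shape != self.hap0.shape:
            raise ValueError("haplotypes must match the locus map length")

    @property
    def het_mask(self) -> np.ndarray:
        return self.hap0 != self.hap1

    @property
    def heterozygosity(self) -> float:
        return float(np.mean(self.het_mask))

    @classmethod
    def fully_heterozygous(cls, locus_map: LocusMap) -> "DiploidGenome":
        n = locus_map.n_loci
        return cls(locus_map, np.zeros(n, np.int8), np.ones(n, np.int8))

    @classmethod
    def homozygous(cls, locus_map: LocusMap, allele: int = 0) -> "DiploidGenome":
        n = locus_map.n_loci
        return cls(locus_map, np.full(n, allele, np.int8), np.full(n, allele, np.int8))


@dataclass
class Tetrad:
    """Four chromatids of one chromosome after replication and one crossover.

    ``chromatids[0:2]`` descend from homolog 0, ``chromatids[2:4]`` from
    homolog 1.  Exactly one chromatid per homolog is recombinant: its alleles
    distal to ``co_position`` come from the other homolog.
    """

    chromosome_index: int
    co_position: float
    chromatids: np.ndarray          # (4, L_c) int8
    recombinant_flags: np.ndarray   # (4,) bool; exactly two True, one per homolog

    def __post_init__(self):
        if int(self.recombinant_flags[:2].sum()) != 1 or int(self.recombinant_flags[2:].sum()) != 1:
            raise ValueError("exactly one recombinant chromatid per homolog")


@dataclass(frozen=True)
class MeiosisConfig:
    """Automictic segregation parameters.

    Parameters
    ----------
    b : cosegregation bias of recombinant chromatids in [-1, 1].
        The per-chromosome LOH probability is ``beta = (1 - b) / 2``.
    non_loh_mode : which heterozygosity-conserving nonsister pair is retained
        in a non-LOH event: ``"recombinants_only"`` keeps the two recombinant
        chromatids; ``"rec_or_nonrec_equal"`` keeps either the two recombinants
        or the two nonrecombinants with equal odds (both conserve per-locus
        heterozygosity; they differ only in haplotype phase).
    distal_high : if True (default) loci *above* the crossover coordinate are
        distal (lose heterozygosity in LOH events); if False the orientation
        is flipped.
    """

    b: float = 1.0
    non_loh_mode: str = "recombinants_only"
    distal_high: bool = True

    def __post_init__(self):
        if not -1.0 <= self.b <= 1.0:
            raise ValueError(f"cosegregation bias b must be in [-1, 1], got {self.b}")
        if self.non_loh_mode not in NON_LOH_MODES:
            raise ValueError(f"non_loh_mode must be one of {NON_LOH_MODES}")

    @property
    def beta(self) -> float:
        """Per-meiosis, per-chromosome LOH probability, beta = (1 - b)/2."""
        return 0.5 * (1.0 - self.b)


def place_crossover(chromosome_index: int, locus_map: LocusMap, rng: np.random.Generator) -> float:
    """Draw the single obligate crossover coordinate, uniform on (0, 1).

    One mandatory CO per chromosome per meiosis; its position law is uniform
    (recombination is not restricted to chromosome ends in this species).
    """
    if not 0 <= chromosome_index < locus_map.n_chromosomes:
        raise IndexError(f"chromosome index {chromosome_index} out of range")
    x = float(rng.random())
    # open interval: a CO exactly at 0 or 1 would be a no-op / degenerate
    while x == 0.0:  # pragma: no cover - probability zero in practice
        x = float(rng.random())
    return x


def form_tetrad(
    genome: DiploidGenome,
    chromosome_index: int,
    co_position: float,
    rng: np.random.Generator,
    distal_high: bool = True,
) -> Tetrad:
    """Replicate one chromosome and apply the crossover.

    One sister chromatid of each homolog (chosen uniformly) participates in
    the CO; the two recombinants swap their distal segments.
    """
    if not 0.0 < co_position < 1.0:
        raise ValueError("co_position must lie strictly inside (0, 1)")
    loci = genome.locus_map.loci_of(chromosome_index)
    pos = genome.locus_map.position[loci]
    a = genome.hap0[loci]
    b = genome.hap1[loci]
    distal = pos > co_position if distal_high else pos < co_position

    chromatids = np.stack([a, a, b, b]).astype(np.int8)
    rec0 = int(rng.integers(2))        # which sister of homolog 0 recombines
    rec1 = 2 + int(rng.integers(2))    # which sister of homolog 1
    chromatids[rec0, distal] = b[distal]
    chromatids[rec1, distal] = a[distal]
    flags = np.zeros(4, bool)
    flags[[rec0, rec1]] = True
    return Tetrad(chromosome_index, co_position, chromatids, flags)


def _automictic_chromosome(
    a: np.ndarray,
    b: np.ndarray,
    distal: np.ndarray,
    config: MeiosisConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Retained nonsister pair for one chromosome. Returns (hapA, hapB, loh)."""
    if rng.random() < config.beta:
        # LOH assortment: one recombinant with the nonrecombinant of the
        # other homolog; distal segment becomes homozygous.
        if rng.integers(2) == 0:
            # keep {recombinant of homolog 0, nonrecombinant homolog 1}:
            # distal alleles both from homolog 1
            hapA = np.where(distal, b, a)
            hapB = b.copy()
        else:
            hapA = np.where(distal, a, b)
            hapB = a.copy()
        return hapA.astype(np.int8), hapB.astype(np.int8), True
    # heterozygosity-conserving assortment
    if config.non_loh_mode == "rec_or_nonrec_equal" and rng.integers(2) == 0:
        return a.copy(), b.copy(), False            # both nonrecombinants
    # both recombinants: phase switches at the CO, genotype conserved
    hapA = np.where(distal, b, a).astype(np.int8)
    hapB = np.where(distal, a, b).astype(np.int8)
    return hapA, hapB, False


def automictic_oocyte(
    genome: DiploidGenome,
    config: MeiosisConfig,
    rng: np.random.Generator,
) -> tuple[DiploidGenome, np.ndarray]:
    """One automictic meiosis: diploid oocyte plus realized-LOH mask.

    Per chromosome, independently: one uniform CO, then retention of one
    nonsister chromatid pair according to the cosegregation bias (see module
    docstring).  The returned boolean mask marks loci that were heterozygous
    in the mother and are homozygous in the oocyte.
    """
    lm = genome.locus_map
    hap0 = np.empty_like(genome.hap0)
    hap1 = np.empty_like(genome.hap1)
    loh_mask = np.zeros(lm.n_loci, bool)
    for c, sl in enumerate(lm.chromosome_slices()):
        if sl.start == sl.stop:
            continue
        x = place_crossover(c, lm, rng)
        pos = lm.position[sl]
        distal = pos > x if config.distal_high else pos < x
        a, b = genome.hap0[sl], genome.hap1[sl]
        hA, hB, loh = _automictic_chromosome(a, b, distal, config, rng)
        hap0[sl], hap1[sl] = hA, hB
        if loh:
            loh_mask[sl] = distal & (a != b)
    return DiploidGenome(lm, hap0, hap1), loh_mask


def amphimictic_gamete(
    genome: DiploidGenome,
    locus_map: LocusMap | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Canonical meiosis: one CO per chromosome, one of four chromatids kept.

    The marginal transmission probability of each maternal allele is 1/2 at
    every locus; loci on different chromosomes segregate independently.
    """
    if rng is None:
        raise ValueError("rng is required")
    lm = locus_map if locus_map is not None else genome.locus_map
    gamete = np.empty(lm.n_loci, np.int8)
    for c, sl in enumerate(lm.chromosome_slices()):
        if sl.start == sl.stop:
            continue
        x = place_crossover(c, lm, rng)
        pos = lm.position[sl]
        distal = pos > x
        a, b = genome.hap0[sl], genome.hap1[sl]
        which = int(rng.integers(4))
        if which == 0:
            gamete[sl] = a
        elif which == 1:
            gamete[sl] = b
        elif which == 2:
            gamete[sl] = np.where(distal, b, a)
        else:
            gamete[sl] = np.where(distal, a, b)
    return gamete


def realized_loh_fraction(mother: DiploidGenome, offspring: DiploidGenome) -> float:
    """Fraction of maternally heterozygous loci homozygous in the offspring.

    Defined as 0 (with a warning) when the mother has no heterozygous locus.
    """
    if mother.locus_map.n_loci != offspring.locus_map.n_loci:
        raise ValueError("mother and offspring must share a locus map")
    het = mother.het_mask
    n_het = int(het.sum())
    if n_het == 0:
        warnings.warn("mother has no heterozygous locus; LOH fraction defined as 0")
        return 0.0
    lost = het & (offspring.hap0 == offspring.hap1)
    return float(lost.sum() / n_het)


# ---------------------------------------------------------------------------
# Vectorised batch engines used by the life-cycle simulator.  Semantics are
# identical to automictic_oocyte / amphimictic_gamete applied row by row; the
# batch forms share the CO position and assortment draw across any number of
# linked locus blocks (e.g. neutral and deleterious loci on the same
# chromosome).
# ---------------------------------------------------------------------------

def automixis_batch(
    haps: list[tuple[np.ndarray, np.ndarray]],
    locus_maps: list[LocusMap],
    beta: np.ndarray,
    rng: np.random.Generator,
    non_loh_mode: str = "recombinants_only",
) -> tuple[list[tuple[np.ndarray, np.ndarray]], np.ndarray, np.ndarray]:
    """Automictic meiosis for ``n`` mothers at once.

    Parameters
    ----------
    haps : list of (hap0, hap1) pairs, each of shape (n, L_k); all blocks
        share chromosomes (block k's locus map must have the same
        n_chromosomes).  Block 0 is the one whose LOH is reported.
    locus_maps : locus map per block.
    beta : per-mother LOH probability, shape (n,).
    Returns (offspring blocks, loh_count, het_count, tract_fraction):
    loh_count / het_count refer to block 0 and give per-mother counts of
    lost and of maternally heterozygous loci; tract_fraction is the
    fraction of the genome (chromosome-length weighted) rendered
    homozygous by this meiosis -- the distal tract 1 - x of each LOH
    chromosome, averaged over chromosomes -- independent of how much
    marker heterozygosity the mother still segregates.
    """
    n = haps[0][0].shape[0]
    n_chrom = locus_maps[0].n_chromosomes
    out = [(h0.copy(), h1.copy()) for h0, h1 in haps]
    slices = [lm.chromosome_slices() for lm in locus_maps]

    het0 = haps[0][0] != haps[0][1]
    het_count = het0.sum(axis=1)
    loh_count = np.zeros(n, np.int64)
    tract_fraction = np.zeros(n)

    for c in range(n_chrom):
        x = rng.random(n)
        u = rng.random(n)
        loh = u < beta
        tract_fraction += np.where(loh, 1.0 - x, 0.0) / n_chrom
        # among non-LOH events, optionally keep the nonrecombinant pair
        keep_parental = np.zeros(n, bool)
        if non_loh_mode == "rec_or_nonrec_equal":
            keep_parental = (~loh) & (rng.random(n) < 0.5)
        side = rng.integers(0, 2, n)  # which homolog's allele fixes distally on LOH

        for k, ((a, b), sl) in enumerate(zip(haps, [s[c] for s in slices])):
            if sl.start == sl.stop:
                continue
            pos = locus_maps[k].position[sl]
            distal = pos[None, :] > x[:, None]          # (n, L_c)
            a_c, b_c = a[:, sl], b[:, sl]
            swap = distal.copy()
            swap[keep_parental] = False                  # parental pair: no phase swap
            new0 = np.where(swap, b_c, a_c)
            new1 = np.where(swap, a_c, b_c)
            # LOH rows: distal segment homozygous for one homolog's alleles
            fix_b = loh & (side == 0)
            fix_a = loh & (side == 1)
            m = distal & fix_b[:, None]
            new0[m] = b_c[m]
            new1[m] = b_c[m]
            m = distal & fix_a[:, None]
            new0[m] = a_c[m]
            new1[m] = a_c[m]
            out[k][0][:, sl] = new0
            out[k][1][:, sl] = new1
            if k == 0:
                loh_count += (distal & loh[:, None] & het0[:, sl]).sum(axis=1)
    return out, loh_count, het_count, tract_fraction


def gamete_batch(
    haps: list[tuple[np.ndarray, np.ndarray]],
    locus_maps: list[LocusMap],
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Amphimictic gametes for ``n`` parents at once (one CO, 1-of-4 chromatid).

    The CO coordinate and retained-chromatid draw are shared across blocks
    (linked loci); returns one (n, L_k) haploid array per block.
    """
    n = haps[0][0].shape[0]
    n_chrom = locus_maps[0].n_chromosomes
    out = [np.empty_like(h0) for h0, _ in haps]
    slices = [lm.chromosome_slices() for lm in locus_maps]

    for c in range(n_chrom):
        x = rng.random(n)
        which = rng.integers(0, 4, n)
        for k, ((a, b), sl) in enumerate(zip(haps, [s[c] for s in slices])):
            if sl.start == sl.stop:
                continue
            pos = locus_maps[k].position[sl]
            distal = pos[None, :] > x[:, None]
            a_c, b_c = a[:, sl], b[:, sl]
            r0 = np.where(distal, b_c, a_c)
            r1 = np.where(distal, a_c, b_c)
            g = np.where((which == 0)[:, None], a_c,
                np.where((which == 1)[:, None], b_c,
                np.where((which == 2)[:, None], r0, r1)))
            out[k][:, sl] = g
    return out
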