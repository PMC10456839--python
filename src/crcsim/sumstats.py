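"""Genomic summary statistics on simulated or synthetic genotypes.

Heterozygosity, F_IS profiles along chromosomes, linkage-disequilibrium
decay on phased haplotypes, sibling genotype-class tables and LOH-tract
detection.  Sign convention for F_IS: positive means a deficit of
heterozygotes relative to Hardy-Weinberg (as in selfers), negative an
excess (as in clonal lineages diverging under the Meselson effect).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .genome_meiosis import DiploidGenome, LocusMap

__all__ = [
    "GenotypeTable",
    "SibClassTable",
    "obs_exp_het",
    "fis_global",
    "fis_profile",
    "r2_decay",
    "sib_class_table",
    "loh_tracts",
]

SIB_CLASSES = ("one_heterozygote", "two_heterozygote", "three_heterozygote", "other")


@dataclass
class GenotypeTable:
    """Individuals x loci genotypes coded 0 (hom ref), 1 (het), 2 (hom alt).

    ``groups`` optionally assigns each individual to a subpopulation (deme);
    when present, expected heterozygosity is computed within groups, so the
    inbreeding statistics measure F_IS proper rather than Wahlund-inflated
    totals.  ``haplotypes`` (2n x L, 0/1) carry truth phase when available.
    """

    genotypes: np.ndarray
    locus_map: LocusMap
    groups: np.ndarray | None = None
    haplotypes: np.ndarray | None = None

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2 or self.genotypes.shape[1] != self.locus_map.n_loci:
            raise ValueError("genotypes must be (n_individuals, n_loci)")
        if not np.isin(self.genotypes, [0, 1, 2]).all():
            raise ValueError("genotype codes must be 0, 1 or 2")
        if self.groups is not None:
            self.groups = np.asarray(self.groups)
            if self.groups.shape != (self.genotypes.shape[0],):
                raise ValueError("groups must have one label per individual")
        if self.haplotypes is not None:
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
            if self.haplotypes.shape != (2 * self.genotypes.shape[0], self.locus_map.n_loci):
                raise ValueError("haplotypes must be (2 n_individuals, n_loci)")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @classmethod
    def from_haplotypes(cls, hap0, hap1, locus_map, groups=None) -> "GenotypeTable":
        hap0 = np.asarray(hap0, np.int8)
        hap1 = np.asarray(hap1, np.int8)
        geno = (hap0 + hap1).astype(np.int8)
        haps = np.empty((2 * hap0.shape[0], hap0.shape[1]), np.int8)
        haps[0::2] = hap0
        haps[1::2] = hap1
        return cls(geno, locus_map, groups=groups, haplotypes=haps)


def _site_het_components(table: GenotypeTable) -> tuple[np.ndarray, np.ndarray]:
    """Per-site observed and expected heterozygosity.

    H_obs is the fraction of heterozygous individuals.  H_exp is
    ``2 p (1-p) * n/(n-1)`` from the sample allele frequency (the
    small-sample correction makes E[H_exp] unbiased).  With groups, both are
    computed within each group and averaged weighted by group size.
    """
    g = table.genotypes
    n, L = g.shape
    if table.groups is None:
        labels = np.zeros(n, np.int64)
    else:
        _, labels = np.unique(table.groups, return_inverse=True)
    hobs = np.zeros(L)
    hexp = np.zeros(L)
    for k in np.unique(labels):
        sub = g[labels == k]
        m = sub.shape[0]
        w = m / n
        hobs += w * (sub == 1).mean(axis=0)
        p = sub.mean(axis=0) / 2.0
        corr = m / (m - 1.0) if m > 1 else 0.0
        hexp += w * 2.0 * p * (1.0 - p) * corr
    return hobs, hexp


def obs_exp_het(table: GenotypeTable, per: str = "site") -> pd.DataFrame:
    """Observed and expected heterozygosity.

    ``per="site"``: one row per locus with H_obs, allele frequency and
    H_exp (monomorphic sites get H_exp = 0 and are excluded from F_IS
    downstream).  ``per="individual"``: one row per individual with its
    fraction of heterozygous loci.  ``per="window"``: window means of the
    per-site quantities (20 loci per window).
    """
    if per == "individual":
        frac = (table.genotypes == 1).mean(axis=1)
        return pd.DataFrame({"individual": np.arange(table.n_individuals), "h_obs": frac})
    hobs, hexp = _site_het_components(table)
    df = pd.DataFrame(
        {
            "chromosome": table.locus_map.chromosome,
            "position": table.locus_map.position,
            "h_obs": hobs,
            "h_exp": hexp,
            "p": table.genotypes.mean(axis=0) / 2.0,
        }
    )
    if per == "site":
        return df
    if per == "window":
        prof = fis_profile(table, loci_per_window=20)
        return prof
    raise ValueError("per must be 'site', 'individual' or 'window'")


def fis_global(table: GenotypeTable) -> float:
    """Ratio-of-sums F_IS = 1 - sum(H_obs)/sum(H_exp) over polymorphic sites."""
    hobs, hexp = _site_het_components(table)
    poly = hexp > 0
    if not poly.any():
        return float("nan")
    return float(1.0 - hobs[poly].sum() / hexp[poly].sum())


def fis_profile(table: GenotypeTable, loci_per_window: int = 20) -> pd.DataFrame:
    """Windowed F_IS along each chromosome.

    Windows are consecutive blocks of ``loci_per_window`` loci; within a
    window F_IS is the ratio of sums 1 - sum(H_obs)/sum(H_exp) over its
    polymorphic sites (NaN when a window has none).
    """
    if table.n_individuals < 2:
        raise ValueError("F_IS needs at least two individuals")
    hobs, hexp = _site_het_components(table)
    lm = table.locus_map
    rows = []
    for c, sl in enumerate(lm.chromosome_slices()):
        idx = np.arange(sl.start, sl.stop)
        for w0 in range(0, idx.size, loci_per_window):
            win = idx[w0 : w0 + loci_per_window]
            poly = hexp[win] > 0
            if poly.any():
                fis = 1.0 - hobs[win][poly].sum() / hexp[win][poly].sum()
            else:
                fis = np.nan
            rows.append(
                (
                    c,
                    w0 // loci_per_window,
                    lm.position[win[0]],
                    lm.position[win[-1]],
                    float(np.mean(lm.position[win])),
                    fis,
                    int(poly.sum()),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["chromosome", "window", "start", "end", "mid", "fis", "n_polymorphic"],
    )


def r2_decay(
    haplotypes: np.ndarray,
    locus_map: LocusMap,
    distance_bins: np.ndarray | None = None,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Mean r^2 between site pairs, binned by position distance.

    ``haplotypes`` is (2n, L) phased 0/1.  r^2 is the squared Pearson
    correlation of allele indicators across haplotypes; monomorphic sites
    are excluded.  Within-chromosome pairs are binned by |pos_i - pos_j|;
    pairs on different chromosomes are pooled into an ``unlinked`` row whose
    null expectation is ~1/(2n).  Bins with fewer than ``min_pairs`` pairs
    are flagged low-confidence.
    """
    H = np.asarray(haplotypes, np.float64)
    if distance_bins is None:
        distance_bins = np.linspace(0.0, 1.0, 11)
    poly = (H.var(axis=0) > 0)
    idx = np.flatnonzero(poly)
    if idx.size < 2:
        return pd.DataFrame(columns=["bin_low", "bin_high", "mean_r2", "n_pairs", "low_confidence"])
    Hs = H[:, idx]
    r = np.corrcoef(Hs, rowvar=False)
    r2 = r ** 2
    chrom = locus_map.chromosome[idx]
    pos = locus_map.position[idx]
    iu, ju = np.triu_indices(idx.size, k=1)
    same = chrom[iu] == chrom[ju]
    dist = np.abs(pos[iu] - pos[ju])
    vals = r2[iu, ju]

    rows = []
    for lo, hi in zip(distance_bins[:-1], distance_bins[1:]):
        m = same & (dist >= lo) & (dist < hi)
        n_pairs = int(m.sum())
        rows.append(
            (lo, hi, float(vals[m].mean()) if n_pairs else np.nan, n_pairs, n_pairs < min_pairs)
        )
    m = ~same
    n_pairs = int(m.sum())
    if n_pairs:
        rows.append((np.nan, np.nan, float(vals[m].mean()), n_pairs, n_pairs < min_pairs))
    df = pd.DataFrame(rows, columns=["bin_low", "bin_high", "mean_r2", "n_pairs", "low_confidence"])
    df["unlinked"] = df["bin_low"].isna()
    return df


@dataclass
class SibClassTable:
    """Counts of polymorphic sites by shared-heterozygosity class among 3 sisters."""

    counts: dict
    n_excluded_missing: int = 0

    @property
    def n_sites(self) -> int:
        return sum(self.counts.values())

    @property
    def proportions(self) -> dict:
        n = self.n_sites
        return {k: (v / n if n else float("nan")) for k, v in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        props = self.proportions
        return pd.DataFrame(
            {
                "class": list(self.counts),
                "count": list(self.counts.values()),
                "proportion": [props[k] for k in self.counts],
            }
        )


def sib_class_table(genotypes: np.ndarray) -> SibClassTable:
    """Classify polymorphic sites by how many of three sisters are heterozygous.

    ``genotypes`` is (3, L) coded 0/1/2, with -1 for missing.  Classes:
    one/two/three-heterozygote by het count; ``other`` = no heterozygote but
    conflicting homozygotes (both hom-ref and hom-alt present).  Sites where
    all three sisters share one homozygous genotype are monomorphic among
    sisters and excluded, as are sites with missing calls (counted).
    """
    g = np.asarray(genotypes)
    if g.shape[0] != 3:
        raise ValueError("sib_class_table needs exactly three sisters")
    missing = (g < 0).any(axis=0)
    g = g[:, ~missing]
    n_het = (g == 1).sum(axis=0)
    has0 = (g == 0).any(axis=0)
    has2 = (g == 2).any(axis=0)
    counts = {
        "one_heterozygote": int((n_het == 1).sum()),
        "two_heterozygote": int((n_het == 2).sum()),
        "three_heterozygote": int((n_het == 3).sum()),
        "other": int(((n_het == 0) & has0 & has2).sum()),
    }
    return SibClassTable(counts, n_excluded_missing=int(missing.sum()))


def loh_tracts(
    mother: DiploidGenome, offspring: DiploidGenome, locus_map: LocusMap | None = None
) -> list[tuple[int, float, float, int]]:
    """Maximal runs of loci heterozygous in the mother, homozygous in offspring.

    Runs are computed over the mother's heterozygous loci only (maternally
    homozygous loci are uninformative and do not interrupt a run).  Returns
    ``(chromosome, start_position, end_position, n_loci)`` per run; under
    the automictic model each LOH chromosome yields exactly one run from
    the crossover to the distal end.
    """
    lm = locus_map if locus_map is not None else mother.locus_map
    het = mother.het_mask
    lost = het & (offspring.hap0 == offspring.hap1)
    tracts = []
    for c, sl in enumerate(lm.chromosome_slices()):
        idx = np.arange(sl.start, sl.stop)
        informative = idx[het[idx]]
        if informative.size == 0:
            continue
        state = lost[informative]
        start = None
        for j, (i, s) in enumerate(zip(informative, state)):
            if s and start is None:
                start = j
            if (not s or j == informative.size - 1) and start is not None:
                end = j if s else j - 1
                tracts.append(
                    (
                        c,
                        float(lm.position[informative[start]]),
                        float(lm.position[informative[end]]),
                        int(end - start + 1),
                    )
                )
                start = None
    return tracts
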