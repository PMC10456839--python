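"""Multinomial likelihood-ratio screen on per-sister base read counts.

For each candidate site, read counts of A, C, G, T are available for three
sister individuals.  Two nested multinomial models are fitted:

* **M0** (3 free parameters): the three sisters share a common base-frequency
  vector;
* **M1** (9 free parameters): each sister has her own frequency vector.

The statistic ``2 * (logL1 - logL0)`` is referred to a chi-square with
``9 - 3 = 6`` degrees of freedom, and only sites where M0 is rejected at a
stringent threshold (default p < 1e-8) are retained — this removes sites
whose apparent genotype differences among sisters could be genotype-calling
noise, keeping only sites with genuinely heterogeneous read frequencies.

Genotypes are then called per sister with a maximum-likelihood diploid
caller under a symmetric sequencing-error model (a stand-in for an external
caller; the screen itself is the statistic of interest).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BASES",
    "ReadCountMatrix",
    "LRTResult",
    "filter_coverage",
    "fit_m0",
    "fit_m1",
    "lrt_site",
    "lrt_screen",
    "call_genotypes",
    "classify_site",
]

BASES = ("A", "C", "G", "T")
N_SISTERS = 3
LRT_DF = 9 - 3


@dataclass
class ReadCountMatrix:
    """Per-site, per-sister base read counts.

    ``counts`` has shape (n_sites, 3, 4): sites x sisters x bases (A,C,G,T).
    ``contig`` and ``pos`` locate each site.
    """

    counts: np.ndarray
    contig: np.ndarray
    pos: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.contig = np.asarray(self.contig)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.counts.ndim != 3 or self.counts.shape[1:] != (N_SISTERS, len(BASES)):
            raise ValueError("counts must have shape (n_sites, 3, 4)")
        if np.any(self.counts < 0):
            raise ValueError("read counts must be non-negative")
        if self.contig.shape != (self.counts.shape[0],) or self.pos.shape != self.contig.shape:
            raise ValueError("contig/pos must have one entry per site")

    @property
    def n_sites(self) -> int:
        return self.counts.shape[0]

    @property
    def site_coverage(self) -> np.ndarray:
        """Per-site per-sister total reads, shape (n_sites, 3)."""
        return self.counts.sum(axis=2)

    def contig_mean_coverage(self) -> dict:
        """Mean per-site per-sister coverage of each contig."""
        cov = self.site_coverage.mean(axis=1)
        out = {}
        for c in pd.unique(self.contig):
            out[c] = float(cov[self.contig == c].mean())
        return out

    def subset(self, mask: np.ndarray) -> "ReadCountMatrix":
        return ReadCountMatrix(self.counts[mask], self.contig[mask], self.pos[mask])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n_sites):
            for s in range(N_SISTERS):
                rows.append(
                    (self.contig[i], int(self.pos[i]), s)
                    + tuple(int(x) for x in self.counts[i, s])
                )
        return pd.DataFrame(rows, columns=["contig", "pos", "sister", *BASES])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReadCountMatrix":
        df = df.sort_values(["contig", "pos", "sister"], kind="stable")
        key = df[["contig", "pos"]].drop_duplicates()
        n = len(key)
        counts = np.zeros((n, N_SISTERS, len(BASES)), np.int64)
        idx = {tuple(r): i for i, r in enumerate(key.itertuples(index=False))}
        for r in df.itertuples(index=False):
            i = idx[(r.contig, r.pos)]
            counts[i, int(r.sister)] = [getattr(r, b) for b in BASES]
        return cls(counts, key["contig"].to_numpy(), key["pos"].to_numpy())


@dataclass
class LRTResult:
    """Outcome of the M0-vs-M1 likelihood-ratio test at one site."""

    logl0: float
    logl1: float
    df: int = LRT_DF
    alpha: float = 1e-8

    @property
    def statistic(self) -> float:
        # nesting guarantees logl1 >= logl0; clip away float jitter
        return max(0.0, 2.0 * (self.logl1 - self.logl0))

    @property
    def p_value(self) -> float:
        return float(stats.chi2.sf(self.statistic, self.df))

    @property
    def passes(self) -> bool:
        return self.p_value < self.alpha


def filter_coverage(
    matrix: ReadCountMatrix,
    min_contig_mean: float = 15.0,
    min_site: int = 20,
) -> np.ndarray:
    """Coverage filter: boolean mask of retained sites.

    A site is retained when its contig's mean coverage is at least
    ``min_contig_mean`` and *each* of the three sisters has at least
    ``min_site`` reads at the site (the per-sister reading: a site
    unobserved in one sister cannot enter a three-sister test).
    """
    cmeans = matrix.contig_mean_coverage()
    contig_ok = np.array([cmeans[c] >= min_contig_mean for c in matrix.contig])
    site_ok = (matrix.site_coverage >= min_site).all(axis=1)
    return contig_ok & site_ok


def _xlogy(x, y):
    from scipy.special import xlogy
    return xlogy(x, y)


def fit_m0(site_counts: np.ndarray) -> tuple[np.ndarray, float]:
    """MLE of the shared-frequency model at one site.

    Returns the pooled base proportions and the multinomial log-likelihood
    summed over sisters (multinomial coefficients dropped; they are dropped
    identically in M1, so the LRT statistic is unaffected).
    """
    site_counts = np.asarray(site_counts, dtype=np.float64)
    total = site_counts.sum()
    if total <= 0:
        raise ValueError("site has zero total read count")
    p = site_counts.sum(axis=0) / total
    logl = float(np.sum(_xlogy(site_counts, p)))
    return p, logl


def fit_m1(site_counts: np.ndarray) -> tuple[np.ndarray, float]:
    """MLE of the per-sister-frequency model at one site."""
    site_counts = np.asarray(site_counts, dtype=np.float64)
    totals = site_counts.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("every sister needs at least one read at a retained site")
    p = site_counts / totals
    logl = float(np.sum(_xlogy(site_counts, p)))
    return p, logl


def lrt_site(site_counts: np.ndarray, alpha: float = 1e-8) -> LRTResult:
    """Fit M0 and M1 at one site and form the likelihood-ratio test."""
    _, l0 = fit_m0(site_counts)
    _, l1 = fit_m1(site_counts)
    return LRTResult(l0, l1, alpha=alpha)


def lrt_screen(matrix: ReadCountMatrix, alpha: float = 1e-8) -> pd.DataFrame:
    """Run the LRT at every site of a (filtered) matrix.

    Vectorised across sites; returns a tidy frame with the statistic, the
    chi-square(6) p-value and the pass flag (p < alpha).
    """
    counts = matrix.counts.astype(np.float64)
    pooled = counts.sum(axis=1)                                  # (n, 4)
    p0 = pooled / pooled.sum(axis=1, keepdims=True)
    l0 = _xlogy(counts, p0[:, None, :]).sum(axis=(1, 2))
    totals = counts.sum(axis=2, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(totals > 0, counts / np.where(totals == 0, 1, totals), 0.0)
    l1 = _xlogy(counts, p1).sum(axis=(1, 2))
    statistic = np.maximum(0.0, 2.0 * (l1 - l0))
    p = stats.chi2.sf(statistic, LRT_DF)
    return pd.DataFrame(
        {
            "contig": matrix.contig,
            "pos": matrix.pos,
            "statistic": statistic,
            "p_value": p,
            "passes": p < alpha,
        }
    )


_GENOTYPES = [("hom", b) for b in range(4)] + [
    ("het", pair) for pair in itertools.combinations(range(4), 2)
]


def _genotype_base_probs(error_rate: float) -> np.ndarray:
    """Per-read base distribution of the 10 diploid genotypes, shape (10, 4).

    A read is drawn from one of the genotype's alleles (equally for a het),
    then miscalled with probability ``error_rate``, scattering uniformly to
    the three other bases.
    """
    e = error_rate
    probs = np.empty((len(_GENOTYPES), 4))
    for g, (kind, which) in enumerate(_GENOTYPES):
        row = np.full(4, e / 3.0)
        if kind == "hom":
            row[which] = 1.0 - e
        else:
            i, j = which
            row[i] = 0.5 * (1.0 - e) + 0.5 * (e / 3.0)
            row[j] = row[i]
        probs[g] = row
    return probs


def call_genotypes(
    site_counts: np.ndarray,
    error_rate: float = 0.01,
    tie_break: str = "het",
    multi_support_frac: float = 0.05,
) -> list[tuple]:
    """Maximum-likelihood diploid genotype for each sister at one site.

    Returns one tuple per sister: ``("hom", base_index)``,
    ``("het", (base_i, base_j))`` or ``("other", None)`` when more than two
    bases have substantial support (count >= max(2, multi_support_frac *
    coverage)).  Exact likelihood ties are broken toward the heterozygote
    when ``tie_break == "het"``.
    """
    site_counts = np.asarray(site_counts, dtype=np.float64)
    probs = _genotype_base_probs(error_rate)
    calls = []
    for s in range(site_counts.shape[0]):
        c = site_counts[s]
        support = c >= max(2.0, multi_support_frac * c.sum())
        if support.sum() > 2:
            calls.append(("other", None))
            continue
        logl = _xlogy(c[None, :], probs).sum(axis=1)
        best = np.flatnonzero(logl >= logl.max() - 1e-9)
        if len(best) > 1 and tie_break == "het":
            het = [g for g in best if _GENOTYPES[g][0] == "het"]
            g = het[0] if het else int(best[0])
        else:
            g = int(best[0])
        calls.append(_GENOTYPES[g])
    return calls


def classify_site(calls: list[tuple]) -> str:
    """Table-1 style class of one site from the three sister calls.

    ``one``/``two``/``three``-heterozygote by the number of het calls;
    ``other`` for sites with no het call but conflicting homozygotes, or any
    multiallelic call; ``monomorphic`` when all three share one homozygous
    genotype (such sites are not polymorphic among sisters).
    """
    if any(kind == "other" for kind, _ in calls):
        return "other"
    n_het = sum(1 for kind, _ in calls if kind == "het")
    if n_het == 3:
        return "three_heterozygote"
    if n_het == 2:
        return "two_heterozygote"
    if n_het == 1:
        return "one_heterozygote"
    homs = {which for kind, which in calls if kind == "hom"}
    return "other" if len(homs) > 1 else "monomorphic"
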