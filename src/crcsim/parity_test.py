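"""The EdU chromatid-paint parity statistic.

A pulse/chase EdU labelling leaves one labelled chromatid per chromosome.
A crossover between one labelled and one unlabelled chromatid (probability
1/2 under uniform chromatid choice) produces visibly "bicolor" recombinant
chromatids.  If the two recombinant chromatids of every bivalent cosegregate
into the oocyte (CRC), each of the 10 chromosome pairs contributes 0 or 2
recombinant chromatids, so the bicolor count in a one-cell embryo is always
even.  Under random nonsister assortment the per-pair retained-recombinant
count is 0, 1 or 2 with probabilities 1/4, 1/2, 1/4, and the total is even
with probability exactly 1/2.  Observing an even count in each of n embryos
therefore has tail probability 0.5**n under the random null.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genome_meiosis import MeiosisConfig

__all__ = [
    "EmbryoPaint",
    "parity_prob_random",
    "all_even_pvalue",
    "simulate_paints",
]

# The four equiprobable nonsister assortments of a bivalent (one chromatid
# retained per homolog) and how many recombinant chromatids each retains:
# {rec0, rec1} -> 2, {rec0, nonrec1} -> 1, {rec1, nonrec0} -> 1,
# {nonrec0, nonrec1} -> 0.
_ASSORTMENT_REC_COUNTS = (2, 1, 1, 0)


@dataclass
class EmbryoPaint:
    """Per-chromosome-pair paint record of one embryo.

    ``rec_retained[c]`` is the number of recombinant chromatids retained for
    pair ``c`` (0, 1 or 2); ``visible[c]`` is True when the crossover of pair
    ``c`` involved exactly one EdU-labelled chromatid, which is what renders
    its recombinants bicolor.
    """

    rec_retained: np.ndarray   # (n_pairs,) int
    visible: np.ndarray        # (n_pairs,) bool

    @property
    def bicolor_count(self) -> int:
        return int(np.sum(self.rec_retained * self.visible))

    @property
    def recombinant_count(self) -> int:
        return int(np.sum(self.rec_retained))

    @property
    def is_even(self) -> bool:
        return self.bicolor_count % 2 == 0


def parity_prob_random(n_pairs: int) -> float:
    """P(even total retained-recombinant count) under random assortment.

    Exhaustive enumeration over all ``4**n_pairs`` equiprobable per-pair
    nonsister assortments.  The value is exactly 1/2 for every ``n_pairs``
    because each pair contributes an odd count with probability 1/2.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    even = 0
    for combo in itertools.product(_ASSORTMENT_REC_COUNTS, repeat=n_pairs):
        if sum(combo) % 2 == 0:
            even += 1
    return even / 4 ** n_pairs


def all_even_pvalue(observed_even_count: int, n_embryos: int, p_even: float = 0.5) -> float:
    """Binomial upper tail P(X >= observed | n_embryos, p_even).

    For ``observed = n`` this is simply ``p_even ** n`` (e.g. 11 even counts
    out of 11 embryos under the random null: 0.5**11 = 4.88e-4).
    """
    if not 0 <= observed_even_count <= n_embryos:
        raise ValueError("observed count must lie in [0, n_embryos]")
    return float(stats.binom.sf(observed_even_count - 1, n_embryos, p_even))


def simulate_paints(
    b: float,
    n_embryos: int,
    n_pairs: int = 10,
    visibility: float = 0.5,
    rng: np.random.Generator | None = None,
    non_loh_mode: str = "recombinants_only",
) -> list[EmbryoPaint]:
    """Simulate EdU-painted one-cell embryos at cosegregation bias ``b``.

    Per chromosome pair the retained assortment follows the automictic law:
    with probability ``1 - beta`` a conserving pair is retained (both
    recombinants under ``recombinants_only``; both recombinants or both
    nonrecombinants with equal odds under ``rec_or_nonrec_equal``), with
    probability ``beta`` one {recombinant, nonrecombinant} pair.  A pair's
    recombinants are bicolor only when its crossover was EdU-visible
    (probability ``visibility``, 1/2 in the experimental design).
    """
    if rng is None:
        raise ValueError("rng is required")
    config = MeiosisConfig(b=b, non_loh_mode=non_loh_mode)
    beta = config.beta
    embryos = []
    for _ in range(n_embryos):
        u = rng.random(n_pairs)
        rec = np.empty(n_pairs, np.int64)
        loh = u < beta
        # LOH assortment retains exactly one recombinant
        rec[loh] = 1
        if non_loh_mode == "rec_or_nonrec_equal":
            both_rec = rng.random(n_pairs) < 0.5
            rec[~loh] = np.where(both_rec[~loh], 2, 0)
        else:
            rec[~loh] = 2
        visible = rng.random(n_pairs) < visibility
        embryos.append(EmbryoPaint(rec, visible))
    return embryos
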