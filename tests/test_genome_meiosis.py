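"""Meiosis engine: crossover placement, tetrads, automixis, gametes."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crcsim import (
    DiploidGenome,
    LocusMap,
    MeiosisConfig,
    amphimictic_gamete,
    automictic_oocyte,
    form_tetrad,
    place_crossover,
    realized_loh_fraction,
)


class TestLocusMap:
    def test_even_map_is_sorted_and_unit_interval(self):
        lm = LocusMap.even(3, 5)
        assert lm.n_loci == 15 and lm.n_chromosomes == 3
        for c in range(3):
            p = lm.position[lm.loci_of(c)]
            assert np.all(np.diff(p) > 0)
            assert np.all((p > 0) & (p < 1))

    @pytest.mark.parametrize(
        "chrom,pos",
        [
            ([0, 0], [0.5, 0.5]),        # duplicate position
            ([0, 0], [0.7, 0.3]),        # not increasing
            ([1, 0], [0.3, 0.7]),        # chromosomes out of order
            ([0, 0], [0.3, 1.5]),        # outside unit interval
        ],
    )
    def test_invalid_maps_rejected(self, chrom, pos):
        with pytest.raises(ValueError):
            LocusMap(np.array(chrom), np.array(pos))


class TestPlaceCrossover:
    def test_coordinate_in_open_unit_interval(self, locus_map_10x2, rng):
        xs = [place_crossover(0, locus_map_10x2, rng) for _ in range(100)]
        assert all(0.0 < x < 1.0 for x in xs)

    def test_uniform_mean(self, locus_map_10x2):
        rng = np.random.default_rng(1)
        xs = np.array([place_crossover(3, locus_map_10x2, rng) for _ in range(100_000)])
        # mean of Uniform(0,1): 1/2, MC standard error = 1/sqrt(12 n)
        assert abs(xs.mean() - 0.5) < 3.0 / np.sqrt(12 * xs.size)

    def test_seeds_give_different_sequences(self, locus_map_10x2):
        a = [place_crossover(0, locus_map_10x2, np.random.default_rng(1)) for _ in range(1)]
        b = [place_crossover(0, locus_map_10x2, np.random.default_rng(2)) for _ in range(1)]
        assert a != b

    def test_bad_chromosome_index(self, locus_map_10x2, rng):
        with pytest.raises(IndexError):
            place_crossover(10, locus_map_10x2, rng)


class TestFormTetrad:
    def test_homozygous_mother_gives_identical_chromatids(self, rng):
        lm = LocusMap.even(1, 8)
        g = DiploidGenome.homozygous(lm, allele=1)
        t = form_tetrad(g, 0, 0.5, rng)
        assert np.all(t.chromatids == 1)

    def test_recombinants_are_bicolor_at_midpoint(self, rng):
        # a fully heterozygous mother: recombinants carry own-homolog alleles
        # proximally and the other homolog's distally
        lm = LocusMap.even(1, 10)
        g = DiploidGenome.fully_heterozygous(lm)
        t = form_tetrad(g, 0, 0.5, rng)
        prox = lm.position < 0.5
        rec = np.flatnonzero(t.recombinant_flags)
        r0 = rec[rec < 2][0]
        r1 = rec[rec >= 2][0]
        assert np.array_equal(t.chromatids[r0, prox], g.hap0[prox])
        assert np.array_equal(t.chromatids[r0, ~prox], g.hap1[~prox])
        assert np.array_equal(t.chromatids[r1, prox], g.hap1[prox])
        assert np.array_equal(t.chromatids[r1, ~prox], g.hap0[~prox])

    def test_exactly_two_recombinants_one_per_homolog(self, rng):
        lm = LocusMap.even(1, 4)
        g = DiploidGenome.fully_heterozygous(lm)
        for _ in range(20):
            t = form_tetrad(g, 0, float(rng.uniform(0.05, 0.95)), rng)
            assert t.recombinant_flags.sum() == 2
            assert t.recombinant_flags[:2].sum() == 1

    def test_co_near_one_makes_recombinants_trivial(self, rng):
        lm = LocusMap.even(1, 6)
        g = DiploidGenome.fully_heterozygous(lm)
        t = form_tetrad(g, 0, 0.999, rng)
        # all loci proximal: recombinants equal the nonrecombinant sisters
        assert np.array_equal(t.chromatids[0], t.chromatids[1])
        assert np.array_equal(t.chromatids[2], t.chromatids[3])

    def test_proximal_sisters_identical_property(self, rng):
        lm = LocusMap.even(1, 12)
        for _ in range(10):
            hap0 = rng.integers(0, 2, 12).astype(np.int8)
            hap1 = rng.integers(0, 2, 12).astype(np.int8)
            g = DiploidGenome(lm, hap0, hap1)
            x = float(rng.uniform(0.05, 0.95))
            t = form_tetrad(g, 0, x, rng)
            prox = lm.position < x
            assert np.array_equal(t.chromatids[0, prox], t.chromatids[1, prox])
            assert np.array_equal(t.chromatids[2, prox], t.chromatids[3, prox])


class TestAutomicticOocyte:
    def test_full_bias_conserves_heterozygosity_exactly(self, het_mother, rng):
        cfg = MeiosisConfig(b=1.0)
        for _ in range(200):
            child, mask = automictic_oocyte(het_mother, cfg, rng)
            assert np.array_equal(child.het_mask, het_mother.het_mask)
            assert not mask.any()

    def test_full_bias_conserves_het_pattern_of_arbitrary_mothers(self, rng):
        lm = LocusMap.even(4, 6)
        cfg = MeiosisConfig(b=1.0)
        for _ in range(50):
            g = DiploidGenome(
                lm, rng.integers(0, 2, 24).astype(np.int8), rng.integers(0, 2, 24).astype(np.int8)
            )
            child, _ = automictic_oocyte(g, cfg, rng)
            assert np.array_equal(child.het_mask, g.het_mask)

    def test_invalid_bias_rejected(self):
        with pytest.raises(ValueError):
            MeiosisConfig(b=1.5)

    @pytest.mark.parametrize("b", [-1.0, -0.5, 0.0, 0.5, 1.0])
    def test_beta_recovered_at_fully_distal_locus(self, b):
        # single locus at the far end of its chromosome: always distal, so
        # the MC LOH rate estimates beta = (1 - b)/2 directly
        rng = np.random.default_rng(42)
        lm = LocusMap(np.array([0]), np.array([1.0]))
        mother = DiploidGenome.fully_heterozygous(lm)
        cfg = MeiosisConfig(b=b)
        n = 10_000
        lost = 0
        for _ in range(n):
            child, _ = automictic_oocyte(mother, cfg, rng)
            lost += int(child.hap0[0] == child.hap1[0])
        beta = 0.5 * (1.0 - b)
        sd = np.sqrt(max(beta * (1 - beta), 1e-12) / n)
        assert abs(lost / n - beta) <= 3 * sd + 1e-9

    def test_anti_cosegregation_always_loses_distal_locus(self):
        rng = np.random.default_rng(7)
        lm = LocusMap(np.array([0]), np.array([1.0]))
        mother = DiploidGenome.fully_heterozygous(lm)
        cfg = MeiosisConfig(b=-1.0)
        for _ in range(500):
            child, mask = automictic_oocyte(mother, cfg, rng)
            assert child.hap0[0] == child.hap1[0]
            assert mask[0]

    def test_marginal_distribution_matches_exhaustive_enumeration(self):
        """One chromosome, two loci: MC genotype-class frequencies match the
        exact law from enumerating CO region x assortment x retained side."""
        p1, p2 = 0.3, 0.8
        beta = 0.5  # b = 0
        # exact: per locus i, P(LOH at locus i) = beta * P(CO proximal of i)
        # joint classes: (het,het), (het,hom), (hom,hom); a LOH event fixes
        # every distal locus, so (hom at 1 => hom at 2)
        p_lohevent = beta
        p_both = p_lohevent * p1               # CO before locus 1: both lost
        p_only2 = p_lohevent * (p2 - p1)       # CO between loci: locus 2 lost
        p_none = 1 - p_both - p_only2
        rng = np.random.default_rng(3)
        lm = LocusMap(np.array([0, 0]), np.array([p1, p2]))
        mother = DiploidGenome.fully_heterozygous(lm)
        cfg = MeiosisConfig(b=0.0)
        n = 20_000
        counts = {"none": 0, "only2": 0, "both": 0}
        for _ in range(n):
            child, _ = automictic_oocyte(mother, cfg, rng)
            h = child.het_mask
            if h.all():
                counts["none"] += 1
            elif h[0] and not h[1]:
                counts["only2"] += 1
            elif not h.any():
                counts["both"] += 1
            else:  # hom proximal but het distal cannot occur
                raise AssertionError("impossible genotype class")
        for key, p in [("none", p_none), ("only2", p_only2), ("both", p_both)]:
            sd = np.sqrt(p * (1 - p) / n)
            assert abs(counts[key] / n - p) <= 4 * sd

    def test_rec_or_nonrec_mode_also_conserves_heterozygosity(self, het_mother, rng):
        cfg = MeiosisConfig(b=1.0, non_loh_mode="rec_or_nonrec_equal")
        for _ in range(100):
            child, mask = automictic_oocyte(het_mother, cfg, rng)
            assert np.array_equal(child.het_mask, het_mother.het_mask)
            assert not mask.any()


class TestAmphimicticGamete:
    def test_homozygous_mother_transmits_her_haplotype(self, rng):
        lm = LocusMap.even(2, 5)
        g = DiploidGenome.homozygous(lm, allele=1)
        gam = amphimictic_gamete(g, rng=rng)
        assert np.array_equal(gam, g.hap0)

    def test_mendelian_marginal_transmission(self):
        rng = np.random.default_rng(5)
        lm = LocusMap.even(1, 1)
        g = DiploidGenome.fully_heterozygous(lm)
        n = 10_000
        zeros = sum(int(amphimictic_gamete(g, rng=rng)[0] == 0) for _ in range(n))
        sd = np.sqrt(0.25 / n)
        assert abs(zeros / n - 0.5) <= 3 * sd

    def test_chromosomes_segregate_independently(self):
        rng = np.random.default_rng(6)
        lm = LocusMap.even(2, 1)  # one locus on each of two chromosomes
        g = DiploidGenome.fully_heterozygous(lm)
        gams = np.array([amphimictic_gamete(g, rng=rng) for _ in range(5_000)])
        r = np.corrcoef(gams[:, 0], gams[:, 1])[0, 1]
        assert r ** 2 < 9.0 / gams.shape[0]  # ~3 SD of null r^2 ~ 1/n


class TestRealizedLohFraction:
    def test_identical_offspring_gives_zero(self, het_mother):
        assert realized_loh_fraction(het_mother, het_mother) == 0.0

    def test_full_bias_automixis_gives_zero(self, het_mother, rng):
        cfg = MeiosisConfig(b=1.0)
        child, _ = automictic_oocyte(het_mother, cfg, rng)
        assert realized_loh_fraction(het_mother, child) == 0.0

    def test_homozygous_mother_warns_and_returns_zero(self, rng):
        lm = LocusMap.even(1, 3)
        m = DiploidGenome.homozygous(lm)
        with pytest.warns(UserWarning):
            assert realized_loh_fraction(m, m) == 0.0

    def test_random_segregation_mean_quarter(self, het_mother):
        # beta * E[P(locus distal)] = 1/2 * 1/2 = 1/4 for loci centred on
        # chromosomes under a uniform CO
        rng = np.random.default_rng(8)
        cfg = MeiosisConfig(b=0.0)
        fracs = []
        for _ in range(3_000):
            child, _ = automictic_oocyte(het_mother, cfg, rng)
            fracs.append(realized_loh_fraction(het_mother, child))
        assert abs(np.mean(fracs) - 0.25) < 0.01


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    b=st.floats(min_value=-1.0, max_value=1.0),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_oocyte_heterozygosity_never_increases(b, seed):
    """Automixis can only conserve or lose heterozygosity, never create it."""
    rng = np.random.default_rng(seed)
    lm = LocusMap.even(3, 4)
    g = DiploidGenome(
        lm, rng.integers(0, 2, 12).astype(np.int8), rng.integers(0, 2, 12).astype(np.int8)
    )
    child, mask = automictic_oocyte(g, MeiosisConfig(b=b), rng)
    assert not (child.het_mask & ~g.het_mask).any()
    assert np.array_equal(mask, g.het_mask & ~child.het_mask)
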