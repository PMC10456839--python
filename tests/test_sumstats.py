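"""Heterozygosity, F_IS, LD decay, sib classes and LOH tracts."""

import itertools

import numpy as np
import pytest

from crcsim import (
    DiploidGenome,
    GenotypeTable,
    LocusMap,
    MeiosisConfig,
    MetapopSpec,
    LifeCycleConfig,
    automictic_oocyte,
    fis_global,
    fis_profile,
    gen_metapop_genotypes,
    loh_tracts,
    obs_exp_het,
    r2_decay,
    run_simulation,
    sib_class_table,
)


def _hw_table(n=1000, L=100, p=0.5, seed=0, groups=None):
    rng = np.random.default_rng(seed)
    hap0 = (rng.random((n, L)) < p).astype(np.int8)
    hap1 = (rng.random((n, L)) < p).astype(np.int8)
    return GenotypeTable.from_haplotypes(hap0, hap1, LocusMap.even(1, L), groups=groups)


class TestObsExpHet:
    def test_all_heterozygous_site(self):
        lm = LocusMap.even(1, 2)
        table = GenotypeTable(np.array([[1, 0], [1, 0], [1, 2]], np.int8), lm)
        df = obs_exp_het(table)
        assert df["h_obs"].iloc[0] == 1.0

    def test_hardy_weinberg_site_heterozygosity(self):
        df = obs_exp_het(_hw_table())
        # 2 p (1-p) = 0.5 at p = 0.5
        assert df["h_obs"].mean() == pytest.approx(0.5, abs=0.01)
        assert df["h_exp"].mean() == pytest.approx(0.5, abs=0.01)

    def test_single_individual_het_fraction(self):
        # one heterozygous residue among 75 positions
        lm = LocusMap.even(1, 75)
        g = np.zeros((1, 75), np.int8)
        g[0, 10] = 1
        table = GenotypeTable(g, lm)
        df = obs_exp_het(table, per="individual")
        assert df["h_obs"].iloc[0] == pytest.approx(1 / 75)

    def test_monomorphic_sites_have_zero_expected_het(self):
        lm = LocusMap.even(1, 3)
        table = GenotypeTable(np.zeros((4, 3), np.int8), lm)
        df = obs_exp_het(table)
        assert (df["h_exp"] == 0).all()
        assert np.isnan(fis_global(table))


class TestFis:
    def test_hardy_weinberg_population_near_zero(self):
        fis = fis_global(_hw_table(seed=1))
        # permutation-free null: sd(F_IS) ~ 1/sqrt(n_sites * n) is tiny;
        # use a conservative 3-sd-style band
        assert abs(fis) < 0.01

    def test_everyone_heterozygous_is_negative(self):
        lm = LocusMap.even(1, 10)
        table = GenotypeTable(np.ones((20, 10), np.int8), lm)
        assert fis_global(table) < 0

    def test_selfing_like_excess_homozygosity_positive(self):
        rng = np.random.default_rng(2)
        lm = LocusMap.even(1, 50)
        # half hom-ref, half hom-alt individuals: maximal homozygote excess
        g = np.where(rng.random((40, 50)) < 0.5, 0, 2).astype(np.int8)
        table = GenotypeTable(g, lm)
        assert fis_global(table) > 0.9

    def test_profile_window_layout(self):
        table = _hw_table(n=50, L=100)
        prof = fis_profile(table, loci_per_window=20)
        assert len(prof) == 5
        assert (prof["n_polymorphic"] > 0).all()

    def test_needs_two_individuals(self):
        lm = LocusMap.even(1, 5)
        with pytest.raises(ValueError):
            fis_profile(GenotypeTable(np.zeros((1, 5), np.int8), lm))

    def test_loh_inflates_fis_away_from_proximal_end(self):
        """Random segregation (b = 0) makes LOH probability grow with the
        position's distance from the proximal end, so windowed F_IS rises
        along the chromosome."""
        cfg = LifeCycleConfig(
            n_demes=2, deme_size=100, m=0.01, sigma=0.9, phi=0.0, b=0.0,
            n_chromosomes=1, loci_per_chromosome=60, mu_neutral=0.01,
            generations=150, seed=21,
        )
        res = run_simulation(cfg)
        table = res.final.genotype_table()
        prof = fis_profile(table, loci_per_window=20)
        fis = prof["fis"].to_numpy()
        assert np.nanmean(fis) > 0
        assert fis[-1] > fis[0]


class TestR2Decay:
    def test_duplicated_site_pair_is_one(self):
        rng = np.random.default_rng(3)
        col = rng.integers(0, 2, 40)
        H = np.stack([col, col], axis=1)
        lm = LocusMap.even(1, 2)
        df = r2_decay(H, lm)
        linked = df[~df["unlinked"]]
        assert linked["mean_r2"].dropna().iloc[0] == pytest.approx(1.0)

    def test_unlinked_null_expectation(self):
        rng = np.random.default_rng(4)
        n_hap, L = 100, 40
        H = rng.integers(0, 2, (n_hap, L)).astype(np.int8)
        lm = LocusMap.even(4, 10)
        df = r2_decay(H, lm)
        null = df[df["unlinked"]]["mean_r2"].iloc[0]
        # E[r^2] ~ 1/n_hap for independent sites
        assert null == pytest.approx(1.0 / n_hap, rel=0.5)

    def test_low_confidence_flagging(self):
        rng = np.random.default_rng(5)
        H = rng.integers(0, 2, (20, 4)).astype(np.int8)
        df = r2_decay(H, LocusMap.even(1, 4), min_pairs=10)
        assert df[~df["unlinked"]]["low_confidence"].all()

    def test_decay_with_distance_in_sexual_population(self):
        """At mutation-recombination-drift equilibrium r^2 declines with
        inter-locus distance (Spearman rank test on bin means)."""
        cfg = LifeCycleConfig(
            n_demes=1, deme_size=200, m=0.0, sigma=0.0, phi=0.5, b=0.0,
            n_chromosomes=2, loci_per_chromosome=40, mu_neutral=0.005,
            generations=300, seed=31,
        )
        res = run_simulation(cfg)
        pop = res.final
        haps = np.vstack([pop.hap0, pop.hap1])
        df = r2_decay(haps, pop.locus_map, distance_bins=np.linspace(0, 1, 6))
        linked = df[~df["unlinked"]].dropna(subset=["mean_r2"])
        from scipy.stats import spearmanr
        rho, _ = spearmanr(linked["bin_low"], linked["mean_r2"])
        assert rho < 0


class TestSibClassTable:
    def test_crc_trio_all_three_heterozygote(self):
        g = np.ones((3, 200), np.int8)
        t = sib_class_table(g)
        assert t.proportions["three_heterozygote"] == 1.0
        assert sum(t.proportions.values()) == pytest.approx(1.0)

    def test_mendelian_trio_matches_enumeration(self):
        """Daughters of a het x het cross: per-site class probabilities from
        exhaustive enumeration of the 3-daughter genotype combinations."""
        # enumerate: each daughter hom0 w.p. 1/4, het 1/2, hom1 1/4
        probs = {"one": 0.0, "two": 0.0, "three": 0.0, "other": 0.0, "mono": 0.0}
        for combo in itertools.product([0, 1, 2], repeat=3):
            p = 1.0
            for gt in combo:
                p *= 0.5 if gt == 1 else 0.25
            n_het = sum(1 for gt in combo if gt == 1)
            if n_het == 3:
                probs["three"] += p
            elif n_het == 2:
                probs["two"] += p
            elif n_het == 1:
                probs["one"] += p
            elif {0, 2} <= set(combo):
                probs["other"] += p
            else:
                probs["mono"] += p
        assert probs["three"] == pytest.approx(0.125)
        rng = np.random.default_rng(6)
        n = 40_000
        g = (rng.integers(0, 2, (3, n)) + rng.integers(0, 2, (3, n))).astype(np.int8)
        t = sib_class_table(g)
        scale = 1.0 - probs["mono"]  # monomorphic-in-trio sites are excluded
        for key, name in [("one", "one_heterozygote"), ("two", "two_heterozygote"),
                          ("three", "three_heterozygote"), ("other", "other")]:
            expected = probs[key] / scale
            sd = np.sqrt(expected * (1 - expected) / t.n_sites)
            assert abs(t.proportions[name] - expected) <= 4 * sd

    def test_missing_genotypes_excluded_and_counted(self):
        g = np.array([[1, -1], [1, 1], [1, 1]], np.int8)
        t = sib_class_table(g)
        assert t.n_sites == 1 and t.n_excluded_missing == 1

    def test_requires_three_sisters(self):
        with pytest.raises(ValueError):
            sib_class_table(np.ones((2, 5), np.int8))


class TestLohTracts:
    def test_identical_offspring_no_tracts(self, het_mother):
        assert loh_tracts(het_mother, het_mother) == []

    def test_full_bias_no_tracts(self, het_mother, rng):
        child, _ = automictic_oocyte(het_mother, MeiosisConfig(b=1.0), rng)
        assert loh_tracts(het_mother, child) == []

    def test_forced_loh_yields_single_distal_run(self):
        lm = LocusMap.even(1, 10)
        mother = DiploidGenome.fully_heterozygous(lm)
        child_h0 = mother.hap0.copy()
        child_h1 = mother.hap1.copy()
        distal = lm.position > 0.3
        child_h1[distal] = child_h0[distal]  # LOH with CO at 0.3
        child = DiploidGenome(lm, child_h0, child_h1)
        tracts = loh_tracts(mother, child)
        assert len(tracts) == 1
        c, start, end, n = tracts[0]
        assert c == 0 and n == int(distal.sum())
        assert start == pytest.approx(lm.position[distal][0])
        assert end == pytest.approx(lm.position[-1])

    def test_automictic_loh_chromosomes_have_one_distal_run_each(self):
        rng = np.random.default_rng(9)
        lm = LocusMap.even(5, 20)
        mother = DiploidGenome.fully_heterozygous(lm)
        child, mask = automictic_oocyte(mother, MeiosisConfig(b=-1.0), rng)
        tracts = loh_tracts(mother, child)
        chroms_hit = {c for c, *_ in tracts}
        # b = -1: every chromosome undergoes LOH; chromosomes whose CO fell
        # beyond the last locus leave no marker run
        assert len(tracts) == len(chroms_hit)
        for c, start, end, n in tracts:
            sl = lm.loci_of(c)
            assert end == pytest.approx(lm.position[sl][-1])


class TestHetTrajectoryClosedForm:
    @pytest.mark.parametrize("t_check", [1, 5, 10])
    def test_pure_automixis_geometric_decay(self, t_check):
        """Under obligate automixis at b = 0 the expected heterozygosity of a
        locus with distal probability p decays as H0 (1 - beta p)^t."""
        cfg = LifeCycleConfig(
            n_demes=1, deme_size=500, m=0.0, sigma=1.0, phi=0.0, b=0.0,
            n_chromosomes=1, loci_per_chromosome=9, mu_neutral=0.0,
            generations=t_check, seed=41, sperm_dependent=False,
        )
        res = run_simulation(cfg)
        pop = res.final
        lm = pop.locus_map
        het = (pop.hap0 != pop.hap1).mean(axis=0)
        expected = (1.0 - 0.5 * lm.position) ** t_check
        sd = np.sqrt(expected * (1 - expected) / pop.size)
        assert np.all(np.abs(het - expected) <= 4 * sd + 0.01)


class TestHwShortcutGenerator:
    def test_fis_calibration_input(self):
        table = gen_metapop_genotypes(MetapopSpec(hw_shortcut=True, seed=3,
                                                  hw_n_individuals=500, hw_n_loci=200))
        assert abs(fis_global(table)) < 0.02
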