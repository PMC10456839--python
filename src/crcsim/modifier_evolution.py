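"""Evolution experiments on the pseudogamy and cosegregation modifiers.

Two unlinked diploid modifier loci act maternally (in the carrier's own
meiosis): the *sigma* locus sets the fraction of her offspring produced by
automixis, the *bias* locus sets her cosegregation bias ``b``.  Effects are
additive across the two alleles, clamped to the legal ranges
(``sigma in [0, 0.9]`` -- sperm dependence caps pseudogamy at the species'
observed 90% -- and ``b in [-1, 1]``).  Mutations perturb single alleles by
Gaussian steps, in both directions.

The invasion experiment starts from a fully sexual population (all modifier
alleles at zero) with Mendelian sex determination in the amphimictic
pathway (phi = 1/2, so the sexual resident has ~50% males); this is what
gives automixis its classic twofold transmission advantage and places the
invasion threshold at an inbreeding-depression cost of 1/2.  As pseudogamy
spreads the male fraction falls toward the ~10% observed in natural
populations of the modelled species.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .lifecycle_sim import (
    LifeCycleConfig,
    Metapopulation,
    generation_step,
    init_population,
)

__all__ = [
    "ModifierGenotype",
    "InvasionConfig",
    "mutate_modifiers",
    "invasion_experiment",
    "crc_selection_experiment",
    "estimate_invasion_threshold",
]


@dataclass
class ModifierGenotype:
    """Additive diploid modifier genotype of one individual."""

    sigma_alleles: tuple[float, float] = (0.0, 0.0)
    bias_alleles: tuple[float, float] = (0.0, 0.0)
    sigma_max: float = 0.9

    @property
    def sigma(self) -> float:
        return float(np.clip(sum(self.sigma_alleles), 0.0, self.sigma_max))

    @property
    def b(self) -> float:
        return float(np.clip(sum(self.bias_alleles), -1.0, 1.0))


@dataclass
class InvasionConfig:
    """An invasion / modifier-evolution experiment.

    ``base`` supplies the life cycle; ``evolvable`` lists which modifier
    loci mutate ({"sigma"}, {"bias"} or both); ``delta`` the
    phenomenological LOH cost; 20 replicates of up to 2000 generations at a
    census of 200 with 20 neutral loci reproduce the threshold behaviour at
    the scaled-down size used throughout the test-suite.
    """

    base: LifeCycleConfig = field(default_factory=LifeCycleConfig)
    evolvable: frozenset = frozenset({"sigma"})
    delta: float = 0.0
    mutation_rate: float = 0.01
    effect_sd: float = 0.2
    max_generations: int = 2000
    replicates: int = 20
    seed: int = 0
    success_sigma: float = 0.45     # invaded when final mean sigma exceeds this
    stop_sigma: float = 0.8         # early stop once pseudogamy clearly fixed
    stop_bias: float = 0.95

    def lifecycle_config(self) -> LifeCycleConfig:
        return replace(
            self.base,
            evolvable_sigma="sigma" in self.evolvable,
            evolvable_bias="bias" in self.evolvable,
            modifier_mut_rate=self.mutation_rate,
            modifier_effect_sd=self.effect_sd,
            fitness_regime="phenomenological_delta"
            if self.base.fitness_regime == "neutral" and self.delta > 0
            else self.base.fitness_regime,
            delta=self.delta,
            generations=self.max_generations,
        )


def mutate_modifiers(
    genotype: ModifierGenotype,
    config: InvasionConfig,
    rng: np.random.Generator,
) -> ModifierGenotype:
    """Mutate one individual's modifier genotype.

    With probability ``mutation_rate`` per allele, perturb it by a
    ``Normal(0, effect_sd)`` step (both signs occur); expressed values are
    clamped to the legal ranges, not the alleles themselves.
    """
    sig = list(genotype.sigma_alleles)
    bia = list(genotype.bias_alleles)
    if "sigma" in config.evolvable:
        for i in range(2):
            if rng.random() < config.mutation_rate:
                sig[i] += rng.normal(0.0, config.effect_sd)
    if "bias" in config.evolvable:
        for i in range(2):
            if rng.random() < config.mutation_rate:
                bia[i] += rng.normal(0.0, config.effect_sd)
    return ModifierGenotype(tuple(sig), tuple(bia), genotype.sigma_max)


@dataclass
class ReplicateOutcome:
    replicate: int
    outcome: str                  # "invaded" | "resisted" | "extinct"
    final_sigma: float
    final_b: float
    generations: int
    negative_bias_fixed: bool
    trajectory: pd.DataFrame


def _run_replicate(
    cfg: LifeCycleConfig,
    seed: int,
    max_generations: int,
    stop_rule,
    record_every: int = 10,
) -> tuple[Metapopulation, pd.DataFrame, bool]:
    rng = np.random.default_rng(seed)
    pop = init_population(cfg, rng=rng)
    rows = []
    neg_fixed = False

    def snap(p):
        females = ~p.male
        rows.append(
            {
                "generation": p.generation,
                "mean_sigma": float(p.sigma_of()[females].mean()) if females.any() else np.nan,
                "mean_b": float(p.bias_of()[females].mean()) if females.any() else np.nan,
                "pseudogamous_female_fraction": float(
                    (p.origin[females] == 0).mean()
                ) if females.any() else np.nan,
                "male_fraction": float(p.male.mean()),
                "mean_het": p.mean_heterozygosity(),
            }
        )

    snap(pop)
    for _ in range(max_generations):
        pop = generation_step(pop, rng=rng)
        if pop.extinct:
            break
        if pop.bias_alleles is not None:
            alleles = pop.bias_alleles
            if (alleles < 0).all() and alleles.mean() < -0.05:
                neg_fixed = True
        if pop.generation % record_every == 0:
            snap(pop)
        if stop_rule is not None and stop_rule(pop):
            snap(pop)
            break
    if rows and rows[-1]["generation"] != pop.generation and not pop.extinct:
        snap(pop)
    return pop, pd.DataFrame(rows), neg_fixed


def invasion_experiment(config: InvasionConfig) -> list[ReplicateOutcome]:
    """Invasion of pseudogamy into an initially sexual population.

    The resident has all modifier alleles at zero (sigma = 0, b = 0).  Per
    replicate, returns the trajectory of the pseudogamous-female fraction
    and modifier means, and whether pseudogamy invaded (final mean sigma
    above ``success_sigma``), the population resisted, or went extinct.
    Deterministic per (config, seed).
    """
    if config.replicates < 1:
        raise ValueError("replicates must be >= 1")
    cfg = config.lifecycle_config()
    seeds = np.random.SeedSequence(config.seed).generate_state(config.replicates)
    out = []
    for r in range(config.replicates):
        stop = (lambda p: float(p.sigma_of()[~p.male].mean()) >= config.stop_sigma) \
            if "sigma" in config.evolvable else None
        pop, traj, neg_fixed = _run_replicate(
            cfg, int(seeds[r]) % (2**31), config.max_generations, stop
        )
        if pop.extinct:
            outcome = "extinct"
            fs = fb = float("nan")
        else:
            females = ~pop.male
            fs = float(pop.sigma_of()[females].mean())
            fb = float(pop.bias_of()[females].mean())
            outcome = "invaded" if fs >= config.success_sigma else "resisted"
        out.append(
            ReplicateOutcome(r, outcome, fs, fb, pop.generation, neg_fixed, traj)
        )
    return out


def crc_selection_experiment(config: InvasionConfig) -> list[ReplicateOutcome]:
    """Evolution of the cosegregation bias in an already pseudogamous population.

    sigma is fixed at the base config's value (0.9 by default); only the
    bias locus mutates, starting from b = 0 (random segregation).  With any
    positive LOH cost, positive-bias mutants are favoured and mean b climbs
    toward 1; negative-bias mutants (increasing LOH) arise but are never
    selected to fixation.
    """
    cfg = replace(config.lifecycle_config(), evolvable_sigma=False, b=0.0)
    seeds = np.random.SeedSequence(config.seed).generate_state(config.replicates)
    out = []
    for r in range(config.replicates):
        stop = lambda p: float(p.bias_of()[~p.male].mean()) >= config.stop_bias
        pop, traj, neg_fixed = _run_replicate(
            cfg, int(seeds[r]) % (2**31), config.max_generations, stop
        )
        if pop.extinct:
            outcome, fs, fb = "extinct", float("nan"), float("nan")
        else:
            females = ~pop.male
            fs = float(pop.sigma_of()[females].mean())
            fb = float(pop.bias_of()[females].mean())
            outcome = "evolved_crc" if fb >= 0.8 else "no_crc"
        out.append(ReplicateOutcome(r, outcome, fs, fb, pop.generation, neg_fixed, traj))
    return out


def estimate_invasion_threshold(
    deltas: tuple[float, float],
    base: LifeCycleConfig,
    replicates: int = 20,
    max_generations: int = 2000,
    seed: int = 0,
) -> dict:
    """Bracket the critical inbreeding depression for pseudogamy invasion.

    Runs ``replicates`` invasion replicates at each delta with beta fixed at
    1/2 (b = 0, bias not evolvable).  When the majority outcome flips
    between the two deltas, the critical value is reported as their
    midpoint.
    """
    lo, hi = sorted(deltas)
    results = {}
    for i, d in enumerate((lo, hi)):
        cfg = InvasionConfig(
            base=replace(base, b=0.0, fitness_regime="phenomenological_delta"),
            evolvable=frozenset({"sigma"}),
            delta=d,
            replicates=replicates,
            max_generations=max_generations,
            seed=seed + i,
        )
        outs = invasion_experiment(cfg)
        results[d] = sum(1 for o in outs if o.outcome == "invaded")
    invaded_lo, invaded_hi = results[lo], results[hi]
    flipped = invaded_lo > replicates / 2 and invaded_hi <= replicates / 2
    return {
        "deltas": (lo, hi),
        "invaded": (invaded_lo, invaded_hi),
        "replicates": replicates,
        "flipped": flipped,
        "critical_delta": 0.5 * (lo + hi) if flipped else float("nan"),
    }
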