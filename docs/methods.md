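# Methods

## The meiosis model

Each individual is diploid with C chromosome pairs (default C = 10,
matching the 2n = 20 karyotype of the modelled species). Loci sit at
real-valued positions in (0, 1) along each chromosome. Every meiosis
places exactly one crossover (CO) per chromosome at a Uniform(0, 1)
coordinate: the species shows one obligate chiasma per bivalent, and its
recombination is not confined to chromosome ends, so a uniform position
law is the natural default. One sister chromatid per homolog, chosen
uniformly, participates in the CO; the two recombinants swap the segment
*distal* to the CO (positions above the coordinate; the orientation can be
flipped per chromosome via `MeiosisConfig.distal_high`).

**Amphimixis** completes both divisions and transmits one of the four
chromatids uniformly: each maternal allele has marginal transmission
probability ½ and chromosomes segregate independently.

**Automixis** aborts anaphase I; the single equational division retains
one nonsister chromatid pair (one chromatid per homolog). The
cosegregation bias b ∈ [−1, 1] sets the per-chromosome loss-of-
heterozygosity probability β = ½(1 − b):

* with probability 1 − β a heterozygosity-conserving pair is retained —
  by default both recombinants (`non_loh_mode="recombinants_only"`, the
  titular mechanism, consistent with the even bicolor counts); the
  alternative `rec_or_nonrec_equal` keeps both recombinants or both
  nonrecombinants with equal odds. Both conserve per-locus genotype and
  differ only in haplotype phase (hence in LD, not in heterozygosity or
  F_IS). The cytological parity data cannot distinguish them, so both are
  kept as options and neither is asserted to be the biological truth.
* with probability β one {recombinant, nonrecombinant} pair is retained
  (equal odds between the two such pairs): every maternally heterozygous
  locus distal to the CO becomes homozygous, for the homolog whose
  nonrecombinant chromatid was kept.

Enumerating the four equiprobable nonsister pairs shows two conserve and
two lose heterozygosity, giving β = ½ at b = 0; restricting to the two
mixed pairs gives β = 1 at b = −1; b = 1 conserves the mother's genotype
at every locus, every meiosis, exactly.

## Life cycle and metapopulation

Generations are discrete and non-overlapping. An island model of
`n_demes` demes of constant size `deme_size` emulates the strong
consanguinity of natural populations (small demes, low migration).
Per offspring slot in a deme, a mother is sampled among the deme's
females with probability proportional to fitness; with probability σ
(her own modifier value, if evolvable) the offspring is an automictic
daughter (the activating sperm contributes no DNA); otherwise a male of
the deme is sampled fitness-proportionally and a Mendelian offspring is
formed, female with probability ϕ, male otherwise. Offspring migrate to
a uniform other deme with probability m; symmetric reversible mutation
flips neutral alleles at rate μ per allele per generation (the paper-free
choice that sustains polymorphism for the F_IS profiles); deme sizes are
regulated back to `deme_size` by resampling.

Sperm dependence: a deme with no males (or no females) produces nothing
that generation. To keep the census constant, an emptied deme is refilled
from the pooled offspring of the other demes (a recolonisation event,
logged on the population); if no deme can reproduce the metapopulation is
extinct, reported rather than raised. σ = 1 is rejected at configuration
time unless sperm dependence is explicitly disabled (a hypothetical
allowed in unit tests of the pure-automixis decay law).

Defaults mirror the modelled natural conditions: total census 1000
(10 × 100), m = 5 × 10⁻⁴, σ = 0.9, ϕ = 0 (so ~10% males), C = 10.

## Fitness regimes

* `neutral` — w = 1.
* `explicit_deleterious` — deleterious mutations arrive at rate U per
  diploid genome per generation (Poisson) on a dedicated locus set sharing
  the chromosomes (and therefore the COs and assortments) of the neutral
  loci; fitness is multiplicative, (1 − h s) per heterozygous and (1 − s)
  per homozygous deleterious locus. Defaults s = 0.2, h = 0.1: strongly
  recessive-leaning, so LOH exposes the load — inbreeding depression as an
  emergent property.
* `phenomenological_delta` — an automictic offspring pays
  w = 1 − δ · T / 0.25 (clamped at 0), where T is the fraction of the
  genome its conceiving meiosis rendered homozygous: the distal tract
  1 − x of each chromosome that drew an LOH assortment, averaged over
  chromosomes. E[T] = β · ½, so at β = ½ the expected cost is exactly δ
  and at b = 1 it is zero; in expectation the cost is δ(1 − b). The cost
  is deliberately attached to the *meiotic event*, not to the mother's
  remaining marker heterozygosity: δ phenomenologically stands for a
  standing recessive load, as in classic models of inbreeding depression
  where selfed offspring pay δ regardless of pedigree. (Tying the cost to
  the markers would let a lineage purge its ~20 marker loci within a few
  generations and then invade cost-free at any δ, abolishing the
  threshold; the explicit-deleterious regime is the mechanistic
  counterpart in which purging and its limits are real.)

## Modifier evolution

Two unlinked diploid loci act maternally: one sets σ, one sets b.
Effects are additive across alleles and clamped at expression
(σ ∈ [0, 0.9] — sperm dependence makes σ → 1 suicidal and natural
populations plateau at 90% asexual females; b ∈ [−1, 1]). Mutations hit
each allele at rate 0.01 per generation with Normal(0, 0.2) effects —
small Gaussian steps in both directions rather than jump-to-extreme
alleles. Under automixis a modifier locus undergoes LOH with probability
β/2 (the marginal for a locus at the centre of its own chromosome with a
uniform CO — equivalent in distribution to running the chromatid
machinery on a dedicated chromosome); under amphimixis each parent
transmits a random allele.

The invasion experiment starts fully sexual (all modifier alleles 0) with
ϕ = ½ (Mendelian X/Y sex determination in the amphimictic pathway, ~50%
males initially). This is what gives automixis its classic twofold
transmission advantage — an automictic daughter carries both maternal
alleles, an amphimictic offspring one, and with equal sex ratio a random
sexual offspring has reproductive value 1 — so pseudogamy invades exactly
when 2(1 − δ) > 1, i.e. δ < ½. Reproductive-value accounting shows that
holding the male fraction at 10% throughout instead (available as
`sex_ratio_mode="fixed_male_fraction"`) shrinks the advantage to
1/(1 − 0.1) ≈ 1.11 and would move the threshold to δ ≈ 0.1; the Mendelian
sexual ancestor is therefore the default for the threshold experiment,
and the male fraction falls toward the observed ~10% as σ → 0.9.
Invasion is scored as final mean σ ≥ 0.45 (half the cap); runs stop early
once mean σ ≥ 0.8. The CRC experiment fixes σ = 0.9 and lets only b
evolve from 0; negative-bias fixation is monitored as all bias-allele
copies simultaneously negative.

## Read-count screen

For each site with A/C/G/T read counts in three sisters, model M0 (one
shared frequency vector, 3 free parameters) and M1 (per-sister vectors,
9) are fitted by maximum likelihood (pooled and per-sister proportions);
multinomial coefficients are dropped identically in both, leaving the
statistic 2(logL₁ − logL₀) unchanged. The statistic is referred to
χ²(6 = 9 − 3) and sites with p < 10⁻⁸ are retained. Coverage filters:
contig mean ≥ 15×, and ≥ 20 reads at the site *in each sister* (the
stricter per-sister reading — a site unobserved in one sister cannot
enter a three-sister test). Genotypes are called per sister by comparing
the ten diploid genotype likelihoods under a symmetric error model
(error ε scatters uniformly to the three other bases; a heterozygote
emits each allele's base at (1 − ε)/2 + ε/6); exact ties break toward the
heterozygote, and sites with more than two substantially supported bases
(count ≥ max(2, 5% of coverage)) are flagged multiallelic. The caller is
a documented stand-in for an external genotyper; the LRT screen is the
statistic of interest and is implemented exactly.

Calibration: with all four bases segregating at 40× per sister the
χ²(6) screen rejects within 1.5 percentage points of the nominal 5%
(expected cell counts of 10 leave the chi-square approximation mildly
anticonservative); with structurally absent bases the statistic carries
fewer effective degrees of freedom and the screen is conservative —
appropriate for its gate-keeping role.

## Summary statistics

Observed heterozygosity is the fraction of heterozygous calls; expected
heterozygosity is 2p(1 − p) · n/(n − 1) from sample allele frequencies,
computed within demes when group labels are present (so the statistic is
F_IS proper, not Wahlund-inflated). F_IS = 1 − ΣH_obs/ΣH_exp as a ratio
of sums over polymorphic sites — a deliberate, documented estimator
choice (swappable; Weir–Cockerham would serve equally). Windows are
fixed blocks of 20 loci along each chromosome. LD is r² between allele
indicators on truth-phased haplotypes, binned by position distance
within chromosomes, with cross-chromosome pairs pooled as the unlinked
null (≈ 1/(2n)); bins with < 10 pairs are flagged. Sibling sites are
classed one/two/three-heterozygote by the number of heterozygous
sisters; "other" covers sites with conflicting homozygotes and no
heterozygote, plus multiallelic calls — the exact footnote rule of the
original tabulation is not recoverable, so this definition is fixed
here. LOH tracts are maximal runs over maternally heterozygous loci that
are homozygous in the offspring (maternally homozygous loci are
uninformative and do not interrupt a run).

## Synthetic data

The trio generator conditions on candidate polymorphic sites: the mother
is heterozygous at a configurable fraction (two distinct bases per
site); daughters follow the mode law (CRC: copy the mother; random
automixis: per-site LOH at β · ½ = ¼; sexual: offspring of a het × het
cross — conditioning on parental heterozygosity at analysed sites rather
than drawing from a frequency spectrum). Coverage is gamma-Poisson
(negative-binomial-like, mean 30×, shape 10) per site and sister; errors
are uniform base miscalls. What passing tests show is therefore that the
*statistical machinery* discriminates the inheritance modes at realistic
coverage and error — not that real RNA-seq artefacts (allele-specific
expression, mapping bias, indels, assembly collapse) are handled; those
are outside the generator's scope, as are FASTQ/BAM-level features
(counts are the entry point). The genotype generator either runs the
life cycle or draws Hardy–Weinberg genotypes directly (the F_IS
calibration input); the paint generator delegates to the parity
simulator with EdU visibility ½ per pair (a crossover is visible when it
involves exactly one labelled chromatid), exposed as a free parameter.

## Problem sizes and numerical choices

Tests and the acceptance script use the scaled-down study design: census
200 (2 demes × 100), 20 neutral loci (10 chromosomes × 2), up to 2000
generations, 20 replicates per condition for the invasion threshold and
10 for CRC evolution; the F_IS contrasts use 2 demes × 150 with 40 loci
and 250 generations, U = 0.5, s = 0.3, h = 0.05. Monte-Carlo assertions
use 10⁴ draws with 3–4 binomial SD bands. Enumeration (4¹⁰ assortments,
tetrad pair sets, the 27 trio genotype combinations) backs every exact
expected value. All randomness flows from `numpy.random.default_rng`
seeds; replicate seeds are spawned via `SeedSequence` and kept below
2³¹. Simulations are vectorised across individuals per chromosome; a
200-individual, 2000-generation run takes ~2 s on one CPU.

## Known limitations

No sequence-level simulation (no nucleotides on the simulator side, no
indels), no aneuploidy or kinetochore mechanics, no overlapping
generations or age structure, no evolvable sex ratio, no estimation of
the population recombination rate ρ; the analytical recursions of the
original theory are represented only through their qualitative
conclusions, which are encoded as property tests.
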