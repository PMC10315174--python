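# Methods

## Model

Each haploid individual carries a Boolean selector-gene genotype **v**
(length L, completely linked) and, optionally, a 3-bit robustness-modifier
locus. Development is a single-layer threshold network over a fixed ternary
interaction table **T** (K traits × L genes) with per-trait thresholds
**h**:

    z_i = σ(γ Σ_j t_ij v_j − h_i),   σ(y) = 1 iff y > 0  (ties are OFF).

The table and thresholds never evolve; only **v** (and the modifier) do.
Fitness against an environment vector **b** is W = 1 − D(**b**, **z**)/K.
Each generation applies mutation (Poisson(μLN) uniformly placed bit flips;
symmetric, so a second hit restores the founder state), optional
recombination of the modifier locus (Poisson(2rN) pair swaps), and
multinomial Wright–Fisher resampling with class probabilities proportional
to count × W.

### Random initialization

Maps are drawn with P(t_ij = ±1) = c/2 and h_i ~ N(0, acL); the founder has
exactly round(aL) ON genes at uniform positions (a Bernoulli(a) variant is
available). By the CLT, Σ_j t_ij v_j ~ N(0, acL) for the founder, and the
pre-threshold input y_i ~ N(0, (1+γ²)acL). Environments: `opt` sets **b**
to the founder phenotype (founder W = 1 exactly); `random` draws i.i.d.
Bernoulli(0.5) bits (expected naive fitness 0.5); `attainable` develops a
freshly drawn random genotype under the same map and uses its phenotype,
guaranteeing the optimum lies in the map's image (the genotype is then
discarded).

### Robustness control

Robustness R — the probability a single flip leaves a trait unchanged —
follows from the crossing probability of y_i under a ±γ (or ±α) shift:

* γ family: R = 1 − c[0.5 − Φ(−γ/√((1+γ²)acL))], spanning only (≈0.996, 1]
  at the standard parameters;
* α family: y_i = α Σ t_ij v_j − h′_i with
  h′_i = (α−1)·(Σ_j t_ij v⁰_j) + h_i anchored at the *founding* genotype
  v⁰, giving R = 1 − c[0.5 − Φ(−α/√(2acL))], spanning (0.75, 1].

The denominator √(2acL) is the standard deviation of y at γ = 1 (variance
acL from the interaction sum plus acL from the threshold). Anchoring h′ at
the founder is essential: if the compensation tracked the current genotype,
α would cancel identically; anchoring preserves the founder phenotype
exactly for every α while later mutations shift y by ±α per flipped gene.
With an evolving modifier, each individual's decoded α is applied against
the shared population-wide anchor. The modifier's 3 bits, read as a binary
integer (MSB first), index the ascending α list (0.5, 1, 2, 2.5, 3, 3.5, 4,
8); any bijection is behaviourally equivalent, so the canonical one is
fixed and documented here.

## Implementation choices

* **Genotype classes.** The population is stored as distinct
  (genotype, modifier) classes with multiplicities, not N individual rows;
  fitness is cached per class, and a mutant's regulatory scores are updated
  incrementally from its parent (O(K) per event instead of a K×L product).
  Within a generation, individuals are fixed labels 0..N−1 assigned to
  classes by the generation-start counts, so repeated hits on one label
  chain onto its already-mutated class (exact double-mutant handling).
  Modifier swaps during recombination may duplicate a class rather than
  merge; resampling over duplicates is statistically identical and class
  number stays ≤ N after compaction.
* **Mutation count.** Poisson(μLN) per generation ("on average" reading and
  standard forward-simulator convention); an exact-count mode exists for
  sensitivity checks. The modifier mutates per individual with probability
  μ_r, flipping one uniformly chosen bit; v mutates before the modifier, and
  the modifier is decoded before development.
* **Fixations.** A site scores one fixation each time the entire population
  comes to carry the non-founder state there, checked every generation;
  reversion ends the episode and a later re-fixation scores again (finite
  sites make back mutation possible). Fixation rates are reported per 1000
  generations over an early window (default the first 10⁶ generations) and
  the remainder.
* **Heterozygosity** is the unweighted mean over sites of 2p(1−p), p the
  derived-allele frequency — equivalently the expected per-site mismatch of
  two individuals drawn with replacement (no N/(N−1) correction).
* **Selection coefficients** of prospective mutations are relative:
  s = W_mut/W_parent − 1 (scale-free in K); a parent at W = 0 yields NaN and
  is excluded from summaries.
* **Degenerate cases.** If every individual has W = 0 (possible under a
  random environment at small K), resampling falls back to neutral and
  records a warning instead of aborting. σ(0) = 0 exactly; no tie jitter.
  acL = 0 is a domain error for the analytic formulas.
* **Randomness.** One root seed spawns named, independent generator streams
  (founder, map, environment, mutation, recombination, resampling,
  observers), so identical configurations reproduce outputs byte-for-byte
  and observer sampling cannot perturb trajectories.

## Calibration of the analytic formulas

`calibrate_robustness` draws random (map, founder) pairs, flips every bit of
the founder exhaustively, and compares the mean fraction of unchanged
(trait, flip) pairs with the closed forms. Traits are i.i.d. across rows of
**T**, so each drawn map uses K = 50 traits at otherwise standard
parameters (a = c = 0.5, L = 10⁴); 500 maps per control value give standard
errors of ~1–3 × 10⁻⁴, and the test suite requires agreement within three
standard errors for every γ ∈ {0.1, 1, 10} and all eight modifier α levels.

## Desk-scale study conditions

The full-scale simulations (N = L = 10⁴, K = 10³, μ = 10⁻⁶, 8×10⁶–1.6×10⁷
generations) are far beyond a desk run, so the suite replicates the
qualitative regularities at reduced scale. Problem sizes were fixed ahead
of time by standard forward-simulation rescaling arguments:

* **Fixed-robustness arms** (constant vs shifted environment): N = 100,
  L = 100, K = 20, 2×10⁴ generations, 20 seeds per arm, with μ = 10⁻⁴
  preserving the full-scale per-individual genomic mutation rate
  μL = 0.01 (and per-site Nμ = 0.01; N/K stays within a factor two of the
  full-scale ratio). Across seeds, the equilibrium (trailing-quarter) mean
  fitness at γ = 0.1 exceeds that at γ = 10 under the optimal environment,
  and the ordering reverses after a random environmental shift (one-sided
  two-sample tests at α = 0.01). Seeds are paired across arms (shared map
  and founder), which only reduces comparison variance.
* **Evolving-robustness arm**: N = 200, L = 200, K = 40, 5000 generations,
  10 seeds, with μ = 2.5×10⁻³ preserving the full-scale population-level
  influx μLN = 100 mutations per generation and μ_r = 5×10⁻⁴ preserving
  Nμ_r = 0.1. Indirect selection on the modifier scales with the
  population-level deleterious-mutation flux (N·ΔU); preserving
  per-individual rates instead would put N·s near 1 at this N and leave the
  sweep drift-dominated. Under these conditions the highest-robustness
  allele (α = 0.5) starts at frequency 0.125 and sweeps above 0.5 (usually
  to fixation) in a constant environment, matching the full-scale
  behaviour; 5000 generations comfortably cover the sweep timescale.

What the desk runs do *not* show: the quantitative equilibrium fitness
values of the full-scale runs (W̄ = 0.99929 at γ = 0.1 vs 0.95869 at γ = 10
under the optimal environment), the bifurcation of outcomes at intermediate
α, or long-term fixation-rate contrasts over 10⁷ generations — those depend
on the full N, K, L and generation counts.

## What the generator emulates — and what it does not

The synthetic maps and populations realize the model's own assumptions:
i.i.d. ternary interactions, Gaussian thresholds, complete linkage of
selector genes, discrete non-overlapping generations, and a static
environment vector. Real regulatory systems differ in ways the model
deliberately coarse-grains: graded expression rather than Boolean states,
structured (non-i.i.d.) network topology, evolution of the effector network
itself, diploidy and dominance, recombination within the genome,
environmental plasticity, and developmental time. Passing tests therefore
validate the model's internal logic and its analytic robustness theory, not
quantitative predictions about any real organism.

## Known limitations

* The engine targets desk-scale parameter ranges; full-scale runs
  (N = L = 10⁴ for 10⁷ generations) would need hours-to-days per replicate.
* Phenotype-space enumeration is exact but capped at L ≤ 22 (2^L growth).
* The analytic R formulas are CLT approximations; they are excellent at
  L = 10⁴ but visibly approximate for L below a few hundred.
* The modifier-to-α bit assignment is one fixed bijection among the 8!
  possibilities; dynamics are invariant to the choice.
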