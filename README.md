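# canevo

Canalization and evolvability in a Boolean model of multicellular evolution:
a perceptron genotype–phenotype map with analytically tunable mutational
robustness, haploid Wright–Fisher dynamics under explicit environments, and
an evolvable robustness-modifier locus.

## The model

An individual is a Boolean vector of *selector genes* **v** (length *L*,
completely linked). A fixed K×L ternary table **T** of *effector alleles*
(t<sub>ij</sub> ∈ {−1, 0, +1}) maps the genotype onto a Boolean phenotype
**z** of K cell-type traits through a single-layer threshold network:

    z_i = σ( γ Σ_j t_ij v_j − h_i ),        σ(y) = 1 iff y > 0.

Fitness against an environment **b** (the optimal state of each trait) is
the fraction of matching traits, W = 1 − D(b, z)/K with D the Hamming
distance. Populations of N haploids evolve by mutation (Poisson(μLN)
single-bit flips per generation) and fitness-proportional multinomial
resampling.

Mutational robustness R — the probability that one bit flip leaves a trait
unchanged — is an emergent property of the map. For maps initialized with
P(t<sub>ij</sub> ≠ 0) = c and a proportion *a* of ON genes
(h<sub>i</sub> ~ N(0, acL)), it has closed forms under two controls:

* interaction strength γ:  R = 1 − c·[0.5 − Φ(−γ/√((1+γ²)acL))]
* rescaling α with an anchor-compensated threshold
  h′<sub>i</sub> = (α−1)Σ<sub>j</sub>t<sub>ij</sub>v⁰<sub>j</sub> + h<sub>i</sub>
  (which leaves the current phenotype untouched):
  R = 1 − c·[0.5 − Φ(−α/√(2acL))]

At the standard parameters (a = c = 0.5, L = 10⁴) these give R = 0.9996,
0.9972, 0.9960 for γ = 0.1, 1, 10 (floor 0.996 as γ→∞) and R = 0.9944,
0.9929, 0.9915, 0.9887, 0.9775 for α = 2, 2.5, 3, 4, 8 (limit 0.75 as
α→∞). A 3-bit modifier locus can encode eight α levels (0.5–8), mutate at
rate μ<sub>r</sub>, and optionally recombine with **v** (Poisson(2rN) pair
swaps per generation), letting robustness itself evolve.

## Worked example

Adaptation of a low-robustness population (γ = 10) to a randomly shifted
environment, at desk scale:

```sh
canevo simulate --N 100 --L 100 --K 20 --mu 1e-4 --generations 20000 \
    --record-every 2000 --env random --mode gamma --gamma 10 --seed 1 --out ex
```

prints

```
simulating 20000 generations (N=100, L=100, K=20, mode=gamma, env=random, seed=1)
done: final mean fitness 0.79700, 3106 fixations, 19935 mutation events
```

and writes `ex.trajectory.tsv`, whose head and tail show mean fitness rising
from the random-environment baseline of 0.5 towards its plateau as
beneficial mutations fix:

```
generation  mean_fitness  fitness_var  heterozygosity  cum_fixations
0           0.5           0.0          0.0             0
2000        0.6995        2.47e-05     0.01305         107
...
20000       0.797         2.91e-04     0.00783         3106
```

Re-running the same command with `--gamma 0.1` (high robustness) leaves mean
fitness near 0.45: strongly canalized populations cannot reach the random
optimum because their realizable phenotype space is small. The `enumerate`
subcommand shows that space directly — over 20 random 6-gene, 6-trait maps:

```
$ canevo enumerate --L 6 --K 6 --n-maps 20 --seed 0
mean counts: count_gamma_0.1=1.60  count_gamma_1=9.55  count_gamma_10=12.70
```

and `canevo robustness` tabulates the Monte-Carlo calibration of the
analytic R formulas:

```
$ canevo robustness --mode gamma --n-maps 200 --seed 0
  value  analytic  empirical_mean  empirical_se  n_maps
0.10000   0.99960         0.99968       0.00010     200
1.00000   0.99718         0.99696       0.00028     200
10.0000   0.99603         0.99598       0.00031     200
```

The same machinery is available as a library: `SimParams` + `run()` return a
`SimulationRecord` with fitness, heterozygosity, fixation and
robustness-allele-frequency series (see `docs/methods.md`).

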