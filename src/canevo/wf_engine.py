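"""Haploid Wright–Fisher forward simulation over the perceptron map.

The population is stored as genotype classes: rows of a class matrix hold the
selector genotype ``v`` (completely linked), an optional 3-bit robustness
locus, and cached regulatory scores and fitness; a count vector holds class
multiplicities summing to N. Each generation applies, in order,

1. mutation — a Poisson(mu * L * N) number of uniformly placed single-bit
   flips in ``v`` (plus, with per-individual probability mu_r, one random bit
   flip of the robustness locus when robustness evolves),
2. optional recombination — Poisson(2 * rec * N) haploid pairs exchange
   robustness loci,
3. Wright–Fisher resampling — the next generation of N individuals is drawn
   multinomially with class probabilities proportional to count * W.

Fixation bookkeeping is per episode: a site scores one fixation each time the
whole population comes to carry a state different from the founder's bit
there, and can score again after reverting. All randomness flows through
named generator streams derived from a single root seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .environments import Environment, env_attainable, env_opt, env_random
from .gpmap import ALPHA_LEVELS, GPMap, InitParams, init_map, random_founder

__all__ = [
    "SimParams",
    "Population",
    "mutate",
    "recombine",
    "resample",
    "run",
]

_ALPHA_ARR = np.array(ALPHA_LEVELS)


@dataclass(frozen=True)
class SimParams:
    """Simulation parameters (defaults follow the standard parameter set)."""

    N: int = 10_000
    L: int = 10_000
    K: int = 1_000
    a: float = 0.5
    c: float = 0.5
    mu: float = 1e-6
    mu_r: float = 1e-5
    rec: float = 0.0
    generations: int = 0
    record_every: int = 1_000
    env: str = "opt"          # opt | random | attainable
    mode: str = "gamma"       # gamma | alpha | evolve
    gamma: float = 1.0
    alpha: float = 1.0
    fixed_mutation_count: bool = False
    bernoulli_founder: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be at least 2")
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError("mu must lie in [0, 1]")
        if not (0.0 <= self.mu_r <= 1.0):
            raise ValueError("mu_r must lie in [0, 1]")
        if not (0.0 <= self.rec <= 0.5):
            raise ValueError("rec must lie in [0, 0.5]")
        if self.generations < 0:
            raise ValueError("generations must be non-negative")
        if self.record_every < 1:
            raise ValueError("record_every must be positive")
        if self.env not in ("opt", "random", "attainable"):
            raise ValueError(f"unknown environment kind {self.env!r}")
        if self.mode not in ("gamma", "alpha", "evolve"):
            raise ValueError(f"unknown mode {self.mode!r}")


class Population:
    """Genotype-class representation of a haploid population of size N.

    Classes live in parallel arrays; ``counts`` sums to N at every generation
    boundary. Fitness is cached per class against the fixed environment.
    """

    def __init__(
        self,
        gpmap: GPMap,
        env: Environment,
        founder: np.ndarray,
        N: int,
        rloc_counts: np.ndarray | None = None,
    ) -> None:
        self.gpmap = gpmap
        self.env = env
        self.founder = np.ascontiguousarray(founder, dtype=np.uint8)
        self.N = int(N)
        self.generation = 0
        self.evolving = rloc_counts is not None
        self.fix_count = 0
        self.fix_events: list[tuple[int, int]] = []  # (generation, site)
        self.mutation_events = 0
        self.zero_fitness_generations = 0

        s0 = gpmap.scores(self.founder)
        if self.evolving:
            if rloc_counts.shape != (8,) or rloc_counts.sum() != N:
                raise ValueError("rloc_counts must be 8 counts summing to N")
            keep = np.flatnonzero(rloc_counts)
            C = keep.size
            self._rloc = keep.astype(np.int16)
            self.counts = rloc_counts[keep].astype(np.int64)
        else:
            C = 1
            self._rloc = None
            self.counts = np.array([N], dtype=np.int64)
        self._V = np.tile(self.founder, (C, 1))
        self._D = np.zeros((C, self.gpmap.L), dtype=np.int8)
        self._scores = np.tile(s0, (C, 1))
        self.w = np.array(
            [self._fitness_of(self._scores[i],
                              self._rloc[i] if self.evolving else None)
             for i in range(C)]
        )
        self._diverged = np.zeros(self.gpmap.L, dtype=bool)
        self._clear_pending()

    # -- class bookkeeping -------------------------------------------------
    #
    # Classes spawned within a generation are buffered in python lists and
    # concatenated onto the main arrays once per step (appending rows one by
    # one would cost O(n_classes * L) per mutation event).

    def _clear_pending(self) -> None:
        self._pV: list = []
        self._pD: list = []
        self._pS: list = []
        self._pw: list = []
        self._prloc: list = []
        self._pcounts: list = []

    def _flush(self) -> None:
        if not self._pV:
            return
        self._V = np.vstack([self._V, np.array(self._pV, dtype=np.uint8)])
        self._D = np.vstack([self._D, np.array(self._pD, dtype=np.int8)])
        self._scores = np.vstack([self._scores, np.array(self._pS)])
        self.counts = np.concatenate([self.counts,
                                      np.array(self._pcounts, dtype=np.int64)])
        self.w = np.concatenate([self.w, np.array(self._pw)])
        if self.evolving:
            self._rloc = np.concatenate([self._rloc,
                                         np.array(self._prloc, dtype=np.int16)])
        self._clear_pending()

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0] + len(self._pV)

    def genotypes(self) -> np.ndarray:
        """Class genotype matrix (n_classes, L); rows are views."""
        return self._V

    def rloci(self) -> np.ndarray | None:
        return self._rloc

    def class_alpha(self, ci: int) -> float:
        if self.evolving:
            return float(_ALPHA_ARR[self._rloc[ci]])
        return self.gpmap.alpha

    def _fitness_of(self, scores: np.ndarray, rloc: int | None) -> float:
        m = self.gpmap
        if m.mode == "gamma":
            y = m.gamma * scores - m.h
        else:
            a = m.alpha if rloc is None else float(_ALPHA_ARR[rloc])
            y = a * scores - ((a - 1.0) * m.anchor_sums + m.h)
        z = y > 0.0
        return 1.0 - np.count_nonzero(z != self.env.b) / m.K

    def _spawn(self, ci: int, flip_site: int | None = None,
               new_rloc: int | None = None) -> int:
        """Split one individual off class ``ci`` into a new derived class."""
        base = self.counts.shape[0]
        if ci < base:
            v, d, s = self._V[ci].copy(), self._D[ci].copy(), self._scores[ci].copy()
            rl = int(self._rloc[ci]) if self.evolving else None
            self.counts[ci] -= 1
        else:
            k = ci - base
            v, d, s = self._pV[k].copy(), self._pD[k].copy(), self._pS[k].copy()
            rl = self._prloc[k] if self.evolving else None
            self._pcounts[k] -= 1
        if flip_site is not None:
            old = v[flip_site]
            v[flip_site] = 1 - old
            d[flip_site] = 1 - d[flip_site]
            s += self.gpmap.T[:, flip_site].astype(np.float64) * (1.0 - 2.0 * old)
        if new_rloc is not None:
            rl = int(new_rloc)
        self._pV.append(v)
        self._pD.append(d)
        self._pS.append(s)
        self._pw.append(self._fitness_of(s, rl))
        self._pcounts.append(1)
        if self.evolving:
            self._prloc.append(rl)
        return self.n_classes - 1

    def _rloc_of(self, ci: int) -> int:
        base = self.counts.shape[0]
        return int(self._rloc[ci]) if ci < base else int(self._prloc[ci - base])

    def _compact(self) -> None:
        keep = self.counts > 0
        if keep.all():
            return
        self._V = self._V[keep]
        self._D = self._D[keep]
        self._scores = self._scores[keep]
        self.counts = self.counts[keep]
        self.w = self.w[keep]
        if self.evolving:
            self._rloc = self._rloc[keep]

    def _class_of_label(self, label: int, cum: np.ndarray,
                        touched: dict[int, int]) -> int:
        """Class of individual ``label`` (0..N-1) under generation-start
        assignment, following any within-generation moves of that label."""
        ci = touched.get(label)
        if ci is None:
            ci = int(np.searchsorted(cum, label, side="right"))
        return ci

    # -- summaries ---------------------------------------------------------

    def derived_counts(self) -> np.ndarray:
        """Per-site number of individuals carrying the non-founder state."""
        self._flush()
        return self.counts @ self._D.astype(np.int64)

    def update_fixations(self) -> None:
        diverged = self.derived_counts() == self.N
        new = diverged & ~self._diverged
        if new.any():
            for site in np.flatnonzero(new):
                self.fix_events.append((self.generation, int(site)))
            self.fix_count += int(new.sum())
        self._diverged = diverged


# ---------------------------------------------------------------------------
# generation steps


def mutate(pop: Population, params: SimParams, rng: np.random.Generator) -> Population:
    """Introduce Poisson(mu * L * N) single-bit flips into the population.

    Each event hits a uniformly chosen individual and site. In evolving mode
    each individual additionally mutates its robustness locus with
    probability mu_r, flipping one uniformly chosen bit of the three.
    Repeated hits on one individual within a generation chain correctly.
    """
    mean_events = params.mu * pop.gpmap.L * pop.N
    if params.fixed_mutation_count:
        n = int(round(mean_events))
    else:
        n = int(rng.poisson(mean_events))
    cum = np.cumsum(pop.counts)
    touched: dict[int, int] = {}
    if n > 0:
        labels = rng.integers(pop.N, size=n)
        sites = rng.integers(pop.gpmap.L, size=n)
        for label, site in zip(labels, sites):
            ci = pop._class_of_label(int(label), cum, touched)
            touched[int(label)] = pop._spawn(ci, flip_site=int(site))
        pop.mutation_events += n
    if pop.evolving and params.mu_r > 0:
        n_r = int(rng.binomial(pop.N, params.mu_r))
        if n_r > 0:
            labels = rng.choice(pop.N, size=n_r, replace=False)
            bits = rng.integers(3, size=n_r)
            for label, bit in zip(labels, bits):
                ci = pop._class_of_label(int(label), cum, touched)
                rl = pop._rloc_of(ci) ^ (1 << (2 - int(bit)))
                touched[int(label)] = pop._spawn(ci, new_rloc=rl)
    pop._flush()
    return pop


def recombine(pop: Population, params: SimParams, rng: np.random.Generator) -> Population:
    """Exchange robustness loci between Poisson(2 * rec * N) haploid pairs.

    Each pair consists of two distinct uniformly chosen individuals; their
    selector genotypes are untouched. Only meaningful when robustness
    evolves.
    """
    if not pop.evolving:
        raise ValueError("recombination requires an evolving robustness locus")
    n_pairs = int(rng.poisson(2.0 * params.rec * pop.N))
    if n_pairs == 0:
        return pop
    cum = np.cumsum(pop.counts)
    touched: dict[int, int] = {}
    for _ in range(n_pairs):
        i = int(rng.integers(pop.N))
        j = int(rng.integers(pop.N - 1))
        if j >= i:
            j += 1
        ci = pop._class_of_label(i, cum, touched)
        cj = pop._class_of_label(j, cum, touched)
        ri, rj = pop._rloc_of(ci), pop._rloc_of(cj)
        if ri == rj:
            continue
        touched[i] = pop._spawn(ci, new_rloc=rj)
        touched[j] = pop._spawn(cj, new_rloc=ri)
    pop._flush()
    return pop


def resample(pop: Population, rng: np.random.Generator) -> Population:
    """Wright–Fisher resampling proportional to count * W.

    If every individual has W = 0 (possible under a random environment at
    small K), the generation is resampled neutrally and a warning is
    recorded rather than aborting the run.
    """
    pop._flush()
    weights = pop.counts * pop.w
    total = weights.sum()
    if total <= 0.0:
        pop.zero_fitness_generations += 1
        warnings.warn(
            "all individuals have zero fitness; resampling neutrally",
            RuntimeWarning,
            stacklevel=2,
        )
        probs = pop.counts / pop.counts.sum()
    else:
        probs = weights / total
    pop.counts = rng.multinomial(pop.N, probs).astype(np.int64)
    pop._compact()
    pop.generation += 1
    return pop


# ---------------------------------------------------------------------------
# full simulation


def _init_population(params: SimParams, streams: dict[str, np.random.Generator]):
    founder = random_founder(params.L, params.a, streams["founder"],
                             bernoulli=params.bernoulli_founder)
    map_mode = "alpha" if params.mode in ("alpha", "evolve") else "gamma"
    ip = InitParams(K=params.K, L=params.L, a=params.a, c=params.c,
                    gamma=params.gamma, alpha=params.alpha, mode=map_mode)
    gpmap = init_map(ip, founder, streams["map"])
    if params.env == "opt":
        env = env_opt(gpmap, founder)
    elif params.env == "random":
        env = env_random(params.K, streams["environment"])
    else:
        env = env_attainable(gpmap, streams["environment"], a=params.a)
    rloc_counts = None
    if params.mode == "evolve":
        base, extra = divmod(params.N, 8)
        rloc_counts = np.full(8, base, dtype=np.int64)
        rloc_counts[:extra] += 1
    return Population(gpmap, env, founder, params.N, rloc_counts=rloc_counts)


def run(params: SimParams, progress_every: int | None = None):
    """Run a full simulation and return its :class:`~canevo.observers.SimulationRecord`.

    Initializes the founder genotype, map and environment from the root seed,
    starts the population homogeneous at the founder (in evolving mode with
    the eight robustness alleles at equal frequencies), then iterates
    mutate -> [recombine] -> resample for ``params.generations`` generations,
    sampling observers every ``record_every`` generations. Fully reproducible
    from ``params.seed``.
    """
    from .observers import SimulationRecord, heterozygosity, mean_fitness, rlocus_frequencies

    ss = np.random.SeedSequence(params.seed)
    names = ("founder", "map", "environment", "mutation", "recombination",
             "resample", "observer")
    streams = dict(zip(names, map(np.random.default_rng, ss.spawn(len(names)))))

    pop = _init_population(params, streams)
    record = SimulationRecord(params=params)

    def sample() -> None:
        mw, vw = mean_fitness(pop)
        rfreq = rlocus_frequencies(pop) if pop.evolving else None
        record.append(pop.generation, mw, vw, heterozygosity(pop),
                      pop.fix_count, rfreq)

    sample()
    do_rec = params.mode == "evolve" and params.rec > 0.0
    for _ in range(params.generations):
        mutate(pop, params, streams["mutation"])
        if do_rec:
            recombine(pop, params, streams["recombination"])
        resample(pop, streams["resample"])
        pop.update_fixations()
        if pop.generation % params.record_every == 0 or pop.generation == params.generations:
            sample()
        if progress_every and pop.generation % progress_every == 0:
            import sys
            print(f"generation {pop.generation}/{params.generations} "
                  f"mean_fitness={record.mean_fitness[-1]:.5f}", file=sys.stderr)
    record.finalize(pop)
    return record
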