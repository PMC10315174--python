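"""Summary statistics over a running population and its time series.

Covers mean fitness and its variance, episode-counted fixations and
windowed fixation rates, per-site heterozygosity, sampled selection
coefficients of prospective single-bit mutations, and the frequencies of the
eight robustness-locus alleles when robustness evolves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gpmap import ALPHA_LEVELS

__all__ = [
    "SimulationRecord",
    "mean_fitness",
    "count_fixations",
    "fixation_rate",
    "heterozygosity",
    "selection_coefficients",
    "rlocus_frequencies",
    "equilibrium_mean_fitness",
]

_ALPHA_ARR = np.array(ALPHA_LEVELS)


@dataclass
class SimulationRecord:
    """Time series sampled during a simulation.

    All series share the ``generations`` index; ``cum_fixations`` is
    non-decreasing and ``rloc_frequencies`` rows (evolving mode) sum to 1.
    ``fixation_events`` lists every (generation, site) fixation episode start.
    """

    params: object = None
    generations: list = field(default_factory=list)
    mean_fitness: list = field(default_factory=list)
    fitness_variance: list = field(default_factory=list)
    heterozygosity: list = field(default_factory=list)
    cum_fixations: list = field(default_factory=list)
    rloc_frequencies: list = field(default_factory=list)
    fixation_events: list = field(default_factory=list)
    total_mutation_events: int = 0
    zero_fitness_generations: int = 0
    final_population: object = None

    def append(self, gen, mw, vw, het, fix, rfreq=None) -> None:
        self.generations.append(int(gen))
        self.mean_fitness.append(float(mw))
        self.fitness_variance.append(float(vw))
        self.heterozygosity.append(float(het))
        self.cum_fixations.append(int(fix))
        if rfreq is not None:
            self.rloc_frequencies.append(np.asarray(rfreq))

    def finalize(self, pop) -> None:
        self.final_population = pop
        self.fixation_events = list(pop.fix_events)
        self.total_mutation_events = pop.mutation_events
        self.zero_fitness_generations = pop.zero_fitness_generations

    @property
    def span(self) -> int:
        """Number of generations the record covers."""
        return self.generations[-1] if self.generations else 0

    def trajectory_frame(self):
        """Trajectory as a pandas DataFrame (one row per sampled generation)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "generation": self.generations,
                "mean_fitness": self.mean_fitness,
                "fitness_var": self.fitness_variance,
                "heterozygosity": self.heterozygosity,
                "cum_fixations": self.cum_fixations,
            }
        )

    def rfreq_frame(self):
        """Robustness-allele frequencies as a DataFrame (evolving mode)."""
        import pandas as pd

        if not self.rloc_frequencies:
            raise ValueError("no robustness-locus frequencies were recorded")
        cols = {f"alpha_{a:g}": np.array(self.rloc_frequencies)[:, i]
                for i, a in enumerate(ALPHA_LEVELS)}
        return pd.DataFrame({"generation": self.generations, **cols})


def mean_fitness(pop, env=None, gpmap=None) -> tuple[float, float]:
    """Count-weighted mean and variance of absolute fitness W.

    Uses the population's cached per-class fitnesses; pass ``env`` (and
    optionally ``gpmap``) to evaluate against a different environment.
    """
    if env is None:
        w = pop.w
    else:
        m = gpmap if gpmap is not None else pop.gpmap
        w = np.array([
            1.0 - np.count_nonzero(_class_phenotype(pop, m, ci) != env.b) / m.K
            for ci in range(pop.n_classes)
        ])
    mean = float(np.average(w, weights=pop.counts))
    var = float(np.average((w - mean) ** 2, weights=pop.counts))
    return mean, var


def _class_phenotype(pop, m, ci: int) -> np.ndarray:
    s = pop._scores[ci]
    if m.mode == "gamma":
        y = m.gamma * s - m.h
    else:
        a = pop.class_alpha(ci)
        y = a * s - ((a - 1.0) * m.anchor_sums + m.h)
    return (y > 0.0).astype(np.uint8)


def count_fixations(pop) -> int:
    """Cumulative number of fixation episodes relative to the founder.

    A site scores one event each time the whole population comes to carry
    the non-founder state there; a site that reverts and later re-fixes
    scores again.
    """
    return pop.fix_count


def fixation_rate(record: SimulationRecord, early_span: int = 1_000_000,
                  late_span: int | None = None) -> tuple[float, float]:
    """Average fixations per 1000 generations in an early and a late window.

    The early window is the first ``early_span`` generations; the late window
    is the remainder of the record (or ``late_span`` generations after it).
    """
    total = record.span
    if late_span is None:
        late_span = total - early_span
    if early_span <= 0 or late_span <= 0 or early_span + late_span > total:
        raise ValueError("record does not span both fixation-rate windows")
    gens = np.array([g for g, _ in record.fixation_events], dtype=np.int64)
    early = int(np.count_nonzero(gens <= early_span))
    late = int(np.count_nonzero((gens > early_span)
                                & (gens <= early_span + late_span)))
    return early / (early_span / 1000.0), late / (late_span / 1000.0)


def heterozygosity(pop) -> float:
    """Mean over sites of 2 p (1 - p), p the derived-bit frequency."""
    p = pop.derived_counts() / pop.N
    return float(np.mean(2.0 * p * (1.0 - p)))


def selection_coefficients(pop, n_mutants: int, rng: np.random.Generator) -> np.ndarray:
    """Selection coefficients of prospective random single-bit mutations.

    Draws ``n_mutants`` (individual, site) pairs uniformly, computes
    s = W_mutant / W_parent - 1 without modifying the population, and
    returns them; a parent with W = 0 yields NaN (excluded from summaries).
    """
    if n_mutants < 1:
        raise ValueError("n_mutants must be at least 1")
    m = pop.gpmap
    cum = np.cumsum(pop.counts)
    labels = rng.integers(pop.N, size=n_mutants)
    sites = rng.integers(m.L, size=n_mutants)
    out = np.empty(n_mutants)
    for k, (label, site) in enumerate(zip(labels, sites)):
        ci = int(np.searchsorted(cum, label, side="right"))
        w_parent = pop.w[ci]
        if w_parent == 0.0:
            out[k] = np.nan
            continue
        old = pop._V[ci, site]
        s_mut = pop._scores[ci] + m.T[:, site].astype(np.float64) * (1.0 - 2.0 * old)
        if m.mode == "gamma":
            y = m.gamma * s_mut - m.h
        else:
            a = pop.class_alpha(ci)
            y = a * s_mut - ((a - 1.0) * m.anchor_sums + m.h)
        w_mut = 1.0 - np.count_nonzero((y > 0.0) != pop.env.b.astype(bool)) / m.K
        out[k] = w_mut / w_parent - 1.0
    return out


def rlocus_frequencies(pop) -> np.ndarray:
    """Frequencies of the eight robustness alleles, indexed by locus value.

    Index b (0-7) corresponds to alpha level ``ALPHA_LEVELS[b]``; the
    frequencies sum to 1.
    """
    if not pop.evolving:
        raise ValueError("population has no evolving robustness locus")
    freqs = np.zeros(8)
    np.add.at(freqs, pop._rloc, pop.counts)
    return freqs / pop.N


def equilibrium_mean_fitness(record: SimulationRecord, frac: float = 0.25) -> float:
    """Mean fitness averaged over the trailing ``frac`` of sampled points.

    A plateau summary that is less noisy than the single final sample.
    """
    w = np.asarray(record.mean_fitness)
    n = max(1, int(round(frac * w.size)))
    return float(w[-n:].mean())
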