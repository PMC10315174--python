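"""Environments and the phenotype-to-fitness map.

An environment is a Boolean vector ``b`` of optimal trait states. Absolute
fitness is the fraction of matching traits,

    W = 1 - D(b, z) / K,

with D the Hamming distance. Three constructions are provided: the optimal
environment (b equals the founder phenotype, so the founder has W = 1), a
random environment b* (i.i.d. Bernoulli(0.5) bits, expected naive fitness
0.5), and an attainable random environment b** (the phenotype developed from
a freshly drawn random genotype under the same map, guaranteeing that some
genotype reaches W = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gpmap import GPMap, develop, random_founder

__all__ = [
    "Environment",
    "env_opt",
    "env_random",
    "env_attainable",
    "fitness",
    "save_environment",
    "load_environment",
]


@dataclass(frozen=True)
class Environment:
    b: np.ndarray
    kind: str  # "opt" | "random" | "attainable"

    def __post_init__(self) -> None:
        b = np.ascontiguousarray(self.b, dtype=np.uint8)
        if b.ndim != 1:
            raise ValueError("environment vector must be one-dimensional")
        if not np.isin(b, (0, 1)).all():
            raise ValueError("environment bits must be 0 or 1")
        object.__setattr__(self, "b", b)
        self.b.setflags(write=False)

    @property
    def K(self) -> int:
        return self.b.shape[0]


def env_opt(gpmap: GPMap, founder: np.ndarray) -> Environment:
    """Optimal environment: b is the founder's phenotype, so founder W = 1."""
    return Environment(b=develop(gpmap, founder), kind="opt")


def env_random(K: int, rng: np.random.Generator) -> Environment:
    """Random environment b*: i.i.d. Bernoulli(0.5) optimal trait states."""
    if K < 1:
        raise ValueError("K must be positive")
    return Environment(b=(rng.random(K) < 0.5).astype(np.uint8), kind="random")


def env_attainable(
    gpmap: GPMap, rng: np.random.Generator, a: float = 0.5
) -> Environment:
    """Attainable random environment b**.

    Develops a freshly drawn random genotype (proportion ``a`` of ON genes)
    under the same map and uses its phenotype as the optimum; the genotype is
    discarded and is *not* the simulation founder. Some genotype therefore
    attains W = 1 by construction.
    """
    v_rand = random_founder(gpmap.L, a, rng)
    return Environment(b=develop(gpmap, v_rand), kind="attainable")


def fitness(z: np.ndarray, env: Environment | np.ndarray) -> float:
    """Absolute fitness W = 1 - HammingDistance(b, z) / K."""
    b = env.b if isinstance(env, Environment) else np.asarray(env)
    z = np.asarray(z)
    if z.shape != b.shape:
        raise ValueError(
            f"phenotype length {z.shape} does not match environment {b.shape}"
        )
    return 1.0 - np.count_nonzero(z != b) / b.shape[0]


def save_environment(env: Environment, path) -> None:
    with open(path, "w") as fh:
        fh.write(env.kind + " " + " ".join(str(int(x)) for x in env.b) + "\n")


def load_environment(path) -> Environment:
    with open(path) as fh:
        parts = fh.readline().split()
    return Environment(b=np.array([int(x) for x in parts[1:]], dtype=np.uint8),
                       kind=parts[0])
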