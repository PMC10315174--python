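"""Exhaustive phenotype-space enumeration for small genomes.

For small L the full set of 2^L genotypes can be developed under a fixed map
to measure the realized phenotype space — the number of distinct phenotype
vectors reachable by any genotype. Comparing that size across interaction
strengths gamma (equivalently, scaling T to gamma * T) shows how robustness
constrains the reachable space: high robustness collapses many genotypes
onto few phenotypes.
"""

from __future__ import annotations

import numpy as np

from .gpmap import GPMap, InitParams, init_map, random_founder

__all__ = ["enumerate_space", "space_size_vs_robustness", "MAX_ENUM_L"]

#: Guard against 2^L blow-up; enumeration refuses larger genomes.
MAX_ENUM_L = 22

_CHUNK = 1 << 16


def enumerate_space(gpmap: GPMap, gamma: float | None = None):
    """Develop every genotype and collect the distinct phenotypes.

    Returns ``(count, phenotypes)`` where ``phenotypes`` is a (count, K)
    array of the unique phenotype bit vectors. ``gamma`` overrides the map's
    interaction strength (the map's T and h are shared across strengths; the
    scalar multiplies T, which is identical to scaling the sum). Only gamma
    mode is enumerated; alpha-compensated maps have the same image as the
    gamma = 1 map restricted to their anchor by construction.
    """
    L, K = gpmap.L, gpmap.K
    if L > MAX_ENUM_L:
        raise ValueError(f"L={L} exceeds the enumeration guard of {MAX_ENUM_L}")
    if gpmap.mode != "gamma":
        raise ValueError("phenotype-space enumeration is defined for gamma mode")
    g = gpmap.gamma if gamma is None else gamma
    bit_idx = np.arange(L, dtype=np.uint32)
    Tf = gpmap.T.astype(np.float64)
    seen: set[bytes] = set()
    for start in range(0, 1 << L, _CHUNK):
        stop = min(start + _CHUNK, 1 << L)
        ints = np.arange(start, stop, dtype=np.uint32)
        V = ((ints[:, None] >> bit_idx) & 1).astype(np.float64)
        y = g * (V @ Tf.T) - gpmap.h
        Z = np.packbits(y > 0.0, axis=1)
        seen.update(row.tobytes() for row in Z)
    packed = np.frombuffer(b"".join(sorted(seen)), dtype=np.uint8)
    packed = packed.reshape(len(seen), -1)
    phenos = np.unpackbits(packed, axis=1)[:, :K]
    return len(seen), phenos


def space_size_vs_robustness(
    gamma_list,
    n_maps: int,
    *,
    K: int = 6,
    L: int = 6,
    a: float = 0.5,
    c: float = 0.5,
    rng: np.random.Generator | None = None,
):
    """Phenotype-space sizes across interaction strengths on shared maps.

    Draws ``n_maps`` random maps; for each, enumerates the phenotype space at
    every gamma in ``gamma_list`` with T and h shared (only the strength
    varies). Returns a pandas DataFrame with one row per map and one
    ``count_gamma_<g>`` column per strength, plus a mean row accessor via
    ``df.mean()``.
    """
    import pandas as pd

    if rng is None:
        rng = np.random.default_rng()
    gamma_list = list(gamma_list)
    rows = []
    params = InitParams(K=K, L=L, a=a, c=c, mode="gamma")
    for m in range(n_maps):
        founder = random_founder(L, a, rng)
        gpmap = init_map(params, founder, rng)
        row = {"map": m}
        for g in gamma_list:
            row[f"count_gamma_{g:g}"] = enumerate_space(gpmap, gamma=g)[0]
        rows.append(row)
    cols = ["map"] + [f"count_gamma_{g:g}" for g in gamma_list]
    return pd.DataFrame(rows, columns=cols)
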