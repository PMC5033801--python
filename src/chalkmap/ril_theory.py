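"""Exact two-locus theory for selfed recombinant inbred lines.

A single selfing lineage is a Markov chain on two-locus diploid states:
haplotypes over two loci are coded 0..3 as (origin at locus 1, origin at
locus 2) bits, and each generation replaces the diploid with two
independent gametes drawn with per-meiosis recombination ``r``.  From the
state distribution after g selfings (generation F(g+1)) follow the
quantities the simulator and the map estimator need:

* the per-Morgan density of homozygous A|B junctions,
* the density and mean length of residual heterozygous tracts,
* the observable recombination fraction between homozygous calls,
  ``R_hom(r; g) = P(discordant | both loci homozygous)``, whose g -> inf
  limit is the classic Haldane-Waddington relation R = 2r/(1+2r).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


def two_locus_distribution(r: float, generations: int) -> np.ndarray:
    """Distribution over the 16 ordered diploid states after selfing."""
    P = np.zeros(16)
    P[0 * 4 + 3] = 1.0  # F1: AB / ab
    for _ in range(generations):
        nxt = np.zeros(16)
        for s in np.flatnonzero(P > 0):
            h1, h2 = divmod(int(s), 4)
            a1, b1 = divmod(h1, 2)
            a2, b2 = divmod(h2, 2)
            gametes: dict[int, float] = {}
            for h, p in ((h1, (1 - r) / 2), (h2, (1 - r) / 2),
                         (a1 * 2 + b2, r / 2), (a2 * 2 + b1, r / 2)):
                gametes[h] = gametes.get(h, 0.0) + p
            for g1, p1 in gametes.items():
                for g2, p2 in gametes.items():
                    nxt[g1 * 4 + g2] += P[s] * p1 * p2
        P = nxt
    return P


def _state_classes(P: np.ndarray) -> tuple[float, float, float]:
    """(P both hom & different, P exactly one het, P both hom)."""
    p_hom_diff = p_one_het = p_both_hom = 0.0
    for s in range(16):
        h1, h2 = divmod(s, 4)
        a1, b1 = divmod(h1, 2)
        a2, b2 = divmod(h2, 2)
        het1 = (a1 + a2) == 1
        het2 = (b1 + b2) == 1
        if het1 != het2:
            p_one_het += P[s]
        elif not het1:
            p_both_hom += P[s]
            if (a1 + a2) != (b1 + b2):
                p_hom_diff += P[s]
    return p_hom_diff, p_one_het, p_both_hom


@lru_cache(maxsize=None)
def junction_densities(generations: int) -> tuple[float, float, float]:
    """Per-Morgan mosaic densities at generation F(generations+1).

    Returns (homozygous-junction density, heterozygous-tract start
    density, mean heterozygous tract length in Morgans), obtained by
    linearising the chain at a small inter-locus distance; the marginal
    heterozygosity (1/2)^generations fixes the mean tract length.
    """
    r = 1e-6
    p_hom_diff, p_one_het, _ = _state_classes(
        two_locus_distribution(r, generations))
    lam_hom = p_hom_diff / r
    tract_start = (p_one_het / r) / 2.0
    p_het = 0.5 ** generations
    mean_tract = p_het / tract_start if tract_start > 0 else 0.0
    return lam_hom, tract_start, mean_tract


def hom_recombination(r: float, generations: int) -> float:
    """Observable RIL recombination fraction between homozygous calls."""
    p_hom_diff, _, p_both_hom = _state_classes(
        two_locus_distribution(r, generations))
    return p_hom_diff / p_both_hom if p_both_hom > 0 else 0.5


@lru_cache(maxsize=None)
def _hom_recombination_table(generations: int
                             ) -> tuple[np.ndarray, np.ndarray]:
    rs = np.linspace(0.0, 0.4999, 200)
    Rs = np.array([hom_recombination(float(r), generations) for r in rs])
    return rs, Rs


def invert_hom_recombination(R: float, generations: int) -> float:
    """Meiotic r from an observed homozygote recombination fraction.

    Numeric inversion of the exact finite-generation relation (the table
    is monotone in r); values beyond the attainable range are clamped.
    """
    rs, Rs = _hom_recombination_table(generations)
    R = min(max(R, 0.0), float(Rs[-1]))
    return float(np.interp(R, Rs, rs))
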