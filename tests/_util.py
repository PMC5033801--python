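"""Shared test helpers: independent oracles and small builders.

The gamete-dropping simulator here is the reference implementation of the
selfing process (one meiosis at a time); the package's direct mosaic
sampler is checked against it.  It deliberately shares no code with the
package.
"""

from __future__ import annotations

import numpy as np

from chalkmap.core import BinMarkerMatrix


def _meiosis(hap_a, hap_b, L, rng):
    """One gamete from a diploid; haplotype = (break positions, origins)."""
    n_co = rng.poisson(L)
    xs = np.sort(rng.uniform(0.0, L, n_co))

    def origin_at(hap, x):
        b, o = hap
        return o[np.searchsorted(b, x, side="right")]

    pts = np.unique(np.concatenate([hap_a[0], hap_b[0], xs]))
    src = rng.integers(2)
    xs_set = set(xs.tolist())
    prev = 0.0
    out_b, out_o = [], []
    for x in list(pts) + [L]:
        mid = (prev + x) / 2.0
        h = hap_a if src == 0 else hap_b
        out_b.append(x)
        out_o.append(origin_at(h, mid))
        if x in xs_set:
            src = 1 - src
        prev = x
    bb, oo = [], [out_o[0]]
    for i in range(1, len(out_o)):
        if out_o[i] != oo[-1]:
            bb.append(out_b[i - 1])
            oo.append(out_o[i])
    return np.array(bb), np.array(oo)


def gamete_drop_line(L_morgans, generations, rng):
    """Genotype-class junction count of one selfed line (oracle).

    Returns (junction count, het fraction) of the diploid mosaic after
    ``generations`` selfings from the F1.
    """
    h1 = (np.array([]), np.array([0]))
    h2 = (np.array([]), np.array([1]))
    for _ in range(generations):
        g1 = _meiosis(h1, h2, L_morgans, rng)
        g2 = _meiosis(h1, h2, L_morgans, rng)
        h1, h2 = g1, g2
    pts = np.unique(np.concatenate([h1[0], h2[0]]))

    def orig(h, x):
        return h[1][np.searchsorted(h[0], x, side="right")]

    prev = 0.0
    classes, lengths = [], []
    for x in list(pts) + [L_morgans]:
        mid = (prev + x) / 2.0
        classes.append(int(orig(h1, mid)) + int(orig(h2, mid)))
        lengths.append(x - prev)
        prev = x
    n_j = sum(1 for a, b in zip(classes, classes[1:]) if a != b)
    het = sum(ln for c, ln in zip(classes, lengths) if c == 1)
    return n_j, het / L_morgans if L_morgans > 0 else 0.0


def truth_marker_matrix(genomes, spacing_cm=1.25) -> BinMarkerMatrix:
    """Error-free marker matrix read off the true genomes at an even
    genetic spacing (for isolating map/QTL estimators from GBS noise)."""
    ids, chroms, start, geno = [], [], [], []
    k = 0
    for ch in genomes.config.chromosomes:
        n_mk = max(int(ch.length_cm / spacing_cm), 2)
        pos_bp = np.linspace(1, ch.length_bp, n_mk).astype(np.int64)
        for p in pos_bp:
            k += 1
            ids.append(f"mk{k}")
            chroms.append(ch.name)
            start.append(int(p))
            geno.append(np.array(
                [m.genotype_at(np.array([p]))[0]
                 for m in genomes.mosaics[ch.name]], dtype=np.int8))
    start = np.array(start, dtype=np.int64)
    return BinMarkerMatrix(
        ids=ids, chroms=np.array(chroms, dtype=object),
        start=start, end=start.copy(),
        genotypes=np.vstack(geno), lines=genomes.lines)


def bh_brute_force(p):
    """Literal BH definition: q_i = min_{j: p_j >= p_i} p_j * m / rank_j,
    computed by brute force on the sorted vector."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    sorted_p = p[order]
    for i in range(m):
        q[i] = min(min(sorted_p[j] * m / (j + 1) for j in range(i, m)), 1.0)
    out = np.empty(m)
    out[order] = q
    return out
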