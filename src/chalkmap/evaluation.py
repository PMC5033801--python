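"""Truth-channel scoring utilities.

These helpers compare analysis output against the synthetic truth channel
(true junctions, placed QTLs, planted DE genes).  They are used by tests
and by the acceptance script only; no analysis module imports them, so the
truth channel never leaks into the method itself.
"""

from __future__ import annotations

import numpy as np

from .bin_genotyping import GenotypeSegment
from .synthetic_data import TrueGenome


def recovered_breakpoints(segments: list[GenotypeSegment],
                          chrom: str, chrom_length: int) -> np.ndarray:
    """Internal segment boundaries of one line on one chromosome (bp)."""
    ends = sorted(s.end for s in segments
                  if s.chrom == chrom and s.end < chrom_length)
    return np.array(ends, dtype=np.int64)


def junction_recovery(genomes: TrueGenome,
                      segments_by_line: dict[str, list[GenotypeSegment]],
                      tol_bp: int = 300_000) -> tuple[float, int, int]:
    """Fraction of true junctions with a recovered breakpoint within
    ``tol_bp`` on the same line and chromosome.

    Returns (fraction, n_recovered, n_true).
    """
    n_true = 0
    n_hit = 0
    lines = genomes.lines
    for ch in genomes.config.chromosomes:
        for j, line in enumerate(lines):
            truth = genomes.junctions(ch.name, j)
            if len(truth) == 0:
                continue
            rec = recovered_breakpoints(segments_by_line[line], ch.name,
                                        ch.length_bp)
            n_true += len(truth)
            if len(rec) == 0:
                continue
            idx = np.searchsorted(rec, truth)
            left = rec[np.clip(idx - 1, 0, len(rec) - 1)]
            right = rec[np.clip(idx, 0, len(rec) - 1)]
            dist = np.minimum(np.abs(truth - left), np.abs(right - truth))
            n_hit += int((dist <= tol_bp).sum())
    return (n_hit / n_true if n_true else float("nan")), n_hit, n_true


def oracle_bin_count(genomes: TrueGenome) -> int:
    """Brute-force bin count implied by the union of true junctions."""
    total = 0
    for ch in genomes.config.chromosomes:
        union: set[int] = set()
        for m in genomes.mosaics[ch.name]:
            union.update(int(b) for b in m.breaks)
        total += len(union) + 1
    return total


def spurious_breakpoints(genomes: TrueGenome,
                         segments_by_line: dict[str, list[GenotypeSegment]],
                         tol_bp: int = 300_000) -> tuple[int, int]:
    """Recovered breakpoints with no true junction within ``tol_bp``.

    Returns (n_spurious, n_recovered).
    """
    n_rec = 0
    n_spur = 0
    for ch in genomes.config.chromosomes:
        for j, line in enumerate(genomes.lines):
            truth = genomes.junctions(ch.name, j)
            rec = recovered_breakpoints(segments_by_line[line], ch.name,
                                        ch.length_bp)
            n_rec += len(rec)
            if len(rec) == 0:
                continue
            if len(truth) == 0:
                n_spur += len(rec)
                continue
            idx = np.searchsorted(truth, rec)
            left = truth[np.clip(idx - 1, 0, len(truth) - 1)]
            right = truth[np.clip(idx, 0, len(truth) - 1)]
            dist = np.minimum(np.abs(rec - left), np.abs(right - rec))
            n_spur += int((dist > tol_bp).sum())
    return n_spur, n_rec
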