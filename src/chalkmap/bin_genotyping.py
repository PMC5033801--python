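"""Sliding-window genotyping and recombination-bin construction.

Low-coverage GBS calls are too noisy and too sparse to read recombination
breakpoints off single SNPs.  Instead, a window of 15 consecutive observed
SNPs is slid along each line, one SNP at a time; each SNP receives its
window's consensus genotype, maximal runs of equal consensus become
genotype segments, and the transition between two different segments is a
breakpoint placed midway between the bounding SNPs.  Short low-support
segments (< 300 kb and < 5 SNPs) are masked as missing to avoid false
double recombinants, and the population's breakpoint union defines the
recombination-bin markers.

Windows run over each line's *observed* sites: GBS leaves most sites
unobserved in any given individual, so fixed-size windows over the
population site list would almost never contain enough calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import GENO_A, GENO_B, GENO_H, MISSING, BinMarkerMatrix, \
    GENO_CHARS, VariantMatrix

log = logging.getLogger(__name__)


@dataclass
class WindowConfig:
    window_size: int = 15          # SNPs per window
    hom_min: int = 11              # calls of one parent to declare homozygous
    min_called_in_window: int = 5  # fewer called -> window missing
    mask_max_len: int = 300_000    # bp, strict <
    mask_max_snps: int = 5         # strict <

    def validate(self) -> None:
        if self.hom_min > self.window_size:
            raise ValueError("hom_min must be <= window_size")
        if self.mask_max_len <= 0:
            raise ValueError("mask_max_len must be > 0")
        if self.window_size < 1 or self.min_called_in_window < 1:
            raise ValueError("window sizes must be >= 1")


@dataclass
class GenotypeSegment:
    """A maximal constant-genotype interval of one line (1-based
    inclusive)."""

    line: str
    chrom: str
    start: int
    end: int
    genotype: int          # GENO_A / GENO_H / GENO_B / MISSING
    n_snps: int            # observed SNPs of this line supporting it

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def genotype_char(self) -> str:
        return GENO_CHARS[self.genotype]


def window_genotype(calls: np.ndarray, cfg: WindowConfig | None = None) -> int:
    """Consensus genotype of one window of parental-origin calls.

    Missing if fewer than ``min_called_in_window`` calls are present;
    homozygous for a parent if at least ``hom_min`` calls support it;
    heterozygous otherwise.
    """
    cfg = cfg or WindowConfig()
    calls = np.asarray(calls)
    called = calls[calls != MISSING]
    if len(called) < cfg.min_called_in_window:
        return MISSING
    n_a = int((called == GENO_A).sum())
    n_b = int((called == GENO_B).sum())
    if n_a >= cfg.hom_min:
        return GENO_A
    if n_b >= cfg.hom_min:
        return GENO_B
    return GENO_H


def _window_calls(calls: np.ndarray, cfg: WindowConfig) -> np.ndarray:
    """Per-SNP consensus over centred windows (vectorised).

    Windows are truncated at chromosome ends; the homozygosity threshold
    scales with the truncated width so end windows are judged by the same
    majority ratio as interior ones.
    """
    n = len(calls)
    half = cfg.window_size // 2
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    ca = np.concatenate(([0], np.cumsum(calls == GENO_A)))
    cb = np.concatenate(([0], np.cumsum(calls == GENO_B)))
    n_a = ca[hi] - ca[lo]
    n_b = cb[hi] - cb[lo]
    w = hi - lo
    hom_min_w = np.ceil(cfg.hom_min * w / cfg.window_size).astype(int)
    out = np.full(n, GENO_H, dtype=np.int8)
    out[n_a >= hom_min_w] = GENO_A
    out[n_b >= hom_min_w] = GENO_B
    out[w < cfg.min_called_in_window] = MISSING
    return out


def segment_line(positions: np.ndarray, calls: np.ndarray, chrom_length: int,
                 cfg: WindowConfig | None = None, line: str = "",
                 chrom: str = "") -> list[GenotypeSegment]:
    """Segment one line's ordered observed calls on one chromosome.

    Runs of equal window consensus become segments; the breakpoint between
    two runs is the midpoint between the last SNP of one and the first SNP
    of the next.  A short heterozygous run (< window_size SNPs) sandwiched
    between discordant homozygous runs is the window's transition zone
    around a single breakpoint, not a real segment: it is collapsed into
    one A|B breakpoint at the centre of the zone.
    """
    cfg = cfg or WindowConfig()
    cfg.validate()
    positions = np.asarray(positions, dtype=np.int64)
    calls = np.asarray(calls, dtype=np.int8)
    keep = calls != MISSING
    positions, calls = positions[keep], calls[keep]
    n = len(positions)
    if n == 0:
        return [GenotypeSegment(line, chrom, 1, chrom_length, MISSING, 0)]
    if n < cfg.window_size:
        log.warning("%s %s: only %d SNPs (< window); single segment by "
                    "majority", line, chrom, n)
        g = window_genotype(calls, cfg) if n >= cfg.min_called_in_window \
            else MISSING
        if g == GENO_H:
            n_a = int((calls == GENO_A).sum())
            n_b = int((calls == GENO_B).sum())
            if n_a != n_b:
                g = GENO_A if n_a > n_b else GENO_B
        return [GenotypeSegment(line, chrom, 1, chrom_length, g, n)]

    wcalls = _window_calls(calls, cfg)
    # runs over window consensus
    change = np.flatnonzero(np.diff(wcalls)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change - 1, [n - 1]))
    runs = [(int(s), int(e), int(wcalls[s])) for s, e in zip(starts, ends)]

    # Collapse heterozygous transition zones between discordant
    # homozygotes.  Around a genuine A|B breakpoint the straddling windows
    # report H over a band of up to ~window_size SNPs; such a band is an
    # artefact of the consensus, not a segment.  It is told apart from a
    # real residual-heterozygosity tract by its raw calls: a transition
    # band is an A/B mixture with almost no per-SNP H calls, a true het
    # tract is mostly H calls.
    homs = (GENO_A, GENO_B)
    collapsed: list[tuple[int, int, int]] = []
    i = 0
    while i < len(runs):
        s, e, g = runs[i]
        if (g == GENO_H and collapsed and i + 1 < len(runs)
                and collapsed[-1][2] in homs and runs[i + 1][2] in homs
                and collapsed[-1][2] != runs[i + 1][2]
                and (e - s + 1) < 3 * cfg.window_size
                and float((calls[s:e + 1] == GENO_H).mean()) < 0.5):
            i += 1
            continue
        collapsed.append((s, e, g))
        i += 1
    runs = collapsed

    # Re-call the remaining H runs from their own supporting SNPs.  A
    # short homozygous segment (a double recombinant spanning ~5-12 SNPs)
    # is diluted to H by the windows straddling its ends, so the H run
    # mixes the core's calls with contamination from the flanking
    # genotype.  The flanks identify the contaminant: the core must carry
    # the opposite allele.  A true heterozygous tract keeps an H-call
    # majority and is left alone; isolated call errors cannot assemble
    # the required core support (min_called_in_window same-parent calls).
    recalled: list[tuple[int, int, int]] = []
    for i, (s, e, gcode) in enumerate(runs):
        pieces = [(s, e, gcode)]
        if gcode == GENO_H:
            seg_calls = calls[s:e + 1]
            lf = runs[i - 1][2] if i > 0 else None
            rf = runs[i + 1][2] if i + 1 < len(runs) else None
            flanks = {f for f in (lf, rf) if f in homs}
            if (float((seg_calls == GENO_H).mean()) < 0.5
                    and len(flanks) == 1):
                target = GENO_B if flanks == {GENO_A} else GENO_A
                hits = np.flatnonzero(seg_calls == target)
                if len(hits) >= cfg.min_called_in_window:
                    flank_code = flanks.pop()
                    s2, e2 = s + int(hits[0]), s + int(hits[-1])
                    pieces = []
                    if s2 > s:
                        pieces.append((s, s2 - 1, flank_code))
                    pieces.append((s2, e2, target))
                    if e2 < e:
                        pieces.append((e2 + 1, e, flank_code))
        for piece in pieces:
            if recalled and recalled[-1][2] == piece[2]:
                recalled[-1] = (recalled[-1][0], piece[1], piece[2])
            else:
                recalled.append(piece)
    runs = recalled

    # breakpoints midway between the bounding SNPs of consecutive runs
    breaks = []
    for (s1, e1, _), (s2, e2, _) in zip(runs[:-1], runs[1:]):
        breaks.append((int(positions[e1]) + int(positions[s2])) // 2)
    bounds = [0] + breaks + [chrom_length]
    segs = []
    for k, (_, _, g) in enumerate(runs):
        start, end = bounds[k] + 1, bounds[k + 1]
        n_snps = int(np.searchsorted(positions, end, side="right")
                     - np.searchsorted(positions, start, side="left"))
        segs.append(GenotypeSegment(line, chrom, start, end, g, n_snps))
    return segs


def mask_segments(segments: list[GenotypeSegment],
                  cfg: WindowConfig | None = None) -> list[GenotypeSegment]:
    """Mask short, weakly supported segments as missing.

    A segment is masked only when both conditions hold: physical span
    < ``mask_max_len`` AND supporting SNPs < ``mask_max_snps``.  Neighbours
    are not merged across the masked gap.
    """
    cfg = cfg or WindowConfig()
    out = []
    for s in segments:
        if (s.genotype != MISSING and s.length < cfg.mask_max_len
                and s.n_snps < cfg.mask_max_snps):
            out.append(GenotypeSegment(s.line, s.chrom, s.start, s.end,
                                       MISSING, s.n_snps))
        else:
            out.append(s)
    return out


def build_bin_markers(segments_by_line: dict[str, list[GenotypeSegment]],
                      chrom_lengths: dict[str, int],
                      lines: list[str] | None = None) -> BinMarkerMatrix:
    """Population bin markers from all lines' masked segments.

    Candidate boundaries are the union of all lines' retained breakpoints;
    each inter-boundary interval is genotyped per line from its covering
    segment, and adjacent intervals with identical genotype vectors across
    the population are merged.  Ids are assigned in genome order.
    """
    lines = lines or sorted(segments_by_line)
    all_chroms, all_start, all_end, all_geno = [], [], [], []
    for chrom, length in chrom_lengths.items():
        bset: set[int] = set()
        for line in lines:
            for seg in segments_by_line[line]:
                if seg.chrom == chrom and seg.end < length:
                    bset.add(seg.end)
        bounds = np.array(sorted(bset), dtype=np.int64)
        starts = np.concatenate(([1], bounds + 1))
        ends = np.concatenate((bounds, [length]))
        mids = (starts + ends) // 2
        geno = np.full((len(starts), len(lines)), MISSING, dtype=np.int8)
        for j, line in enumerate(lines):
            segs = [s for s in segments_by_line[line] if s.chrom == chrom]
            if not segs:
                continue
            seg_ends = np.array([s.end for s in segs])
            seg_gen = np.array([s.genotype for s in segs], dtype=np.int8)
            geno[:, j] = seg_gen[np.clip(np.searchsorted(seg_ends, mids),
                                         0, len(segs) - 1)]
        # merge adjacent intervals with identical genotype vectors, and
        # fold fully-missing intervals into their left neighbour
        m_start, m_end, m_geno = [], [], []
        n_empty = 0
        for i in range(len(starts)):
            row = geno[i]
            all_missing = bool((row == MISSING).all())
            if m_geno and (np.array_equal(row, m_geno[-1]) or all_missing):
                if all_missing:
                    n_empty += 1
                m_end[-1] = ends[i]
                continue
            m_start.append(starts[i])
            m_end.append(ends[i])
            m_geno.append(row)
        if n_empty:
            log.info("%s: %d uninformative intervals merged", chrom, n_empty)
        all_chroms.extend([chrom] * len(m_start))
        all_start.extend(m_start)
        all_end.extend(m_end)
        all_geno.extend(m_geno)
    ids = [f"mk{i + 1}" for i in range(len(all_start))]
    return BinMarkerMatrix(
        ids=ids,
        chroms=np.array(all_chroms, dtype=object),
        start=np.array(all_start, dtype=np.int64),
        end=np.array(all_end, dtype=np.int64),
        genotypes=np.vstack(all_geno) if all_geno else
        np.empty((0, len(lines)), dtype=np.int8),
        lines=list(lines),
    )


def bin_population(vm: VariantMatrix, cfg: WindowConfig | None = None,
                   chrom_lengths: dict[str, int] | None = None
                   ) -> tuple[BinMarkerMatrix, dict[str, list[GenotypeSegment]]]:
    """Full bin-genotyping pass over a filtered variant matrix."""
    cfg = cfg or WindowConfig()
    cfg.validate()
    if chrom_lengths is None:
        chrom_lengths = {}
        for c in dict.fromkeys(vm.chroms):
            chrom_lengths[c] = int(vm.pos[vm.chroms == c].max())
    segments_by_line: dict[str, list[GenotypeSegment]] = {}
    chrom_masks = {c: vm.chroms == c for c in chrom_lengths}
    for j, line in enumerate(vm.lines):
        segs: list[GenotypeSegment] = []
        for chrom, length in chrom_lengths.items():
            m = chrom_masks[chrom]
            pos = vm.pos[m]
            calls = vm.calls[m, j]
            s = segment_line(pos, calls, length, cfg, line=line, chrom=chrom)
            segs.extend(mask_segments(s, cfg))
        segments_by_line[line] = segs
    bins = build_bin_markers(segments_by_line, chrom_lengths, list(vm.lines))
    return bins, segments_by_line
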