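"""Ground-truthed simulation of a biparental rice RIL study.

This module emulates the experimental design the rest of the package
analyses: 192 F7 recombinant inbred lines (RILs) from a cross between two
fully homozygous parents, genotyped by reduced-representation sequencing
(GBS) that observes ~7% of SNP sites per individual at a mean depth of
~11.76x, phenotyped for eight grain-appearance traits in four environments,
and profiled for gene expression in the two parents plus two bulked RIL
pools.

Every simulated dataset carries a *truth channel* (true recombination
junctions, placed QTLs, flagged DE genes) that downstream analysis modules
never read; it exists so that recovery can be measured in tests.

Model
-----
RIL genomes are drawn directly at the target selfing generation rather than
meiosis-by-meiosis.  A two-locus Markov chain for a selfing lineage gives
the exact per-Morgan density of genotype junctions at generation F(g+1):
the homozygous A|B junction density, the density of residual heterozygous
tract boundaries and the marginal heterozygosity (1/2)^g.  Genomes are then
composed as a two-state (A/B) Markov mosaic with Poisson junctions at the
homozygous density, overlaid with stationary exponential heterozygous
tracts matching the tract-start density and mean tract length.  A
per-meiosis gamete-dropping simulator is kept in the test suite as an
independent oracle for this shortcut.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import GENO_A, GENO_B, GENO_H, MISSING, VariantMatrix, geno_to_score
from .ril_theory import junction_densities as selfing_junction_densities

TRAITS = ["GW", "GL", "LWR", "CS", "AS", "PL", "PGWC", "DEC"]
ENVIRONMENTS = ["G-DS", "Z-DS", "G-WS", "Z-WS"]
RNA_SAMPLES = ["PYZX", "P02428", "H-Pool", "L-Pool"]


@dataclass(frozen=True)
class ChromosomeSpec:
    """One chromosome: physical length in bp, meiotic map length in cM."""

    name: str
    length_bp: int
    length_cm: float


def rice_chromosomes() -> list[ChromosomeSpec]:
    """Default 12-chromosome rice genome.

    Physical lengths approximate the Nipponbare reference assembly; meiotic
    map lengths are half the RIL-scale bin-map lengths reported for this
    cross (selfed-RIL maps expand roughly twofold relative to the meiotic
    map).
    """
    bp = [43.27, 35.94, 36.41, 35.50, 29.96, 31.25,
          29.70, 28.44, 23.01, 23.21, 29.02, 27.53]
    cm = [116.1, 110.8, 113.2, 111.6, 97.5, 99.8,
          90.4, 83.7, 89.3, 59.4, 106.9, 93.1]
    return [
        ChromosomeSpec(f"Chr{i + 1:02d}", int(b * 1e6), c)
        for i, (b, c) in enumerate(zip(bp, cm))
    ]


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic population."""

    n_lines: int = 192
    chromosomes: list[ChromosomeSpec] = field(default_factory=rice_chromosomes)
    snp_density: float = 330.0          # aa x bb SNP sites per Mb
    capture_fraction: float = 0.07      # P(site observed) per individual
    mean_depth: float = 11.76           # mean reads at an observed site
    genotyping_error: float = 0.01      # per-call flip probability
    selfing_generations: int = 6        # 6 selfings after F1 -> F7
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.capture_fraction <= 1.0):
            raise ValueError("capture_fraction must be in (0, 1]")
        if self.n_lines <= 0:
            raise ValueError("n_lines must be positive")
        if self.snp_density <= 0:
            raise ValueError("snp_density must be positive")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not (0.0 <= self.genotyping_error < 0.5):
            raise ValueError("genotyping_error must be in [0, 0.5)")
        if self.selfing_generations < 1:
            raise ValueError("selfing_generations must be >= 1")
        for ch in self.chromosomes:
            if ch.length_bp <= 0:
                raise ValueError(f"{ch.name}: physical length must be > 0")
            if ch.length_cm < 0:
                raise ValueError(f"{ch.name}: genetic length must be >= 0")


@dataclass
class QTLSpec:
    """A placed additive QTL.

    ``additive`` follows the field's sign convention: positive means the
    parent-1 (A) allele increases the trait, negative means the parent-2
    allele does.  ``env_multiplier`` scales the effect per environment and
    ``resid_sd`` is the residual standard deviation per environment.
    """

    trait: str
    chrom: str
    pos_cm: float
    additive: float
    env_multiplier: dict[str, float] = field(default_factory=dict)
    resid_sd: dict[str, float] = field(default_factory=dict)

    def effect_in(self, env: str) -> float:
        return self.additive * self.env_multiplier.get(env, 1.0)


@dataclass
class DEGSpec:
    """A simulated gene for the expression stage.

    ``log2fc`` applies in ``affected_samples`` relative to the baseline
    mean; genes with log2fc == 0 (or no affected samples) are nulls.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    baseline_mean: float
    log2fc: float = 0.0
    dispersion: float = 0.01
    affected_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.baseline_mean <= 0:
            raise ValueError("baseline mean must be > 0")

    @property
    def is_deg(self) -> bool:
        return bool(self.affected_samples) and self.log2fc != 0.0


# ---------------------------------------------------------------------------
# true genomes
# ---------------------------------------------------------------------------

@dataclass
class LineMosaic:
    """Genotype mosaic of one line on one chromosome.

    ``breaks`` are junction positions in bp (sorted); segment ``i`` spans
    (breaks[i-1], breaks[i]] with genotype ``genos[i]`` (1-based inclusive
    coordinates; the first segment starts at 1, the last ends at the
    chromosome length).
    """

    breaks: np.ndarray   # int64, strictly increasing, inside (1, length)
    genos: np.ndarray    # int8, len(breaks) + 1, no equal neighbours

    def genotype_at(self, pos: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.breaks, np.asarray(pos), side="left")
        return self.genos[idx]

    def segments(self, length_bp: int) -> list[tuple[int, int, int]]:
        starts = np.concatenate(([1], self.breaks + 1))
        ends = np.concatenate((self.breaks, [length_bp]))
        return [(int(s), int(e), int(g))
                for s, e, g in zip(starts, ends, self.genos)]


@dataclass
class TrueGenome:
    """Truth channel: per-line, per-chromosome genotype mosaics."""

    config: SimConfig
    mosaics: dict[str, list[LineMosaic]]   # chrom -> one mosaic per line

    @property
    def lines(self) -> list[str]:
        return [f"RIL{i + 1:03d}" for i in range(self.config.n_lines)]

    def junctions(self, chrom: str, line_idx: int) -> np.ndarray:
        return self.mosaics[chrom][line_idx].breaks

    def het_fraction(self) -> float:
        tot = 0.0
        het = 0.0
        for ch in self.config.chromosomes:
            for m in self.mosaics[ch.name]:
                segs = m.segments(ch.length_bp)
                for s, e, g in segs:
                    tot += e - s + 1
                    if g == GENO_H:
                        het += e - s + 1
        return het / tot

    def truth_dict(self) -> dict:
        out: dict = {"junctions": {}}
        for ch in self.config.chromosomes:
            out["junctions"][ch.name] = [
                [int(b) for b in m.breaks] for m in self.mosaics[ch.name]
            ]
        return out


def _simulate_mosaic(chrom: ChromosomeSpec, lam_hom: float, tract_start: float,
                     mean_tract: float, rng: np.random.Generator) -> LineMosaic:
    L = chrom.length_cm / 100.0  # Morgans
    if L == 0.0:
        g = GENO_A if rng.random() < 0.5 else GENO_B
        return LineMosaic(breaks=np.empty(0, dtype=np.int64),
                          genos=np.array([g], dtype=np.int8))
    # homozygous backbone: Poisson junctions, alternating A/B
    n_j = rng.poisson(lam_hom * L)
    jpos = np.sort(rng.uniform(0.0, L, size=n_j))
    first = GENO_A if rng.random() < 0.5 else GENO_B
    # heterozygous tracts: stationary process of exponential tracts
    pad = 12.0 * mean_tract if mean_tract > 0 else 0.0
    n_t = rng.poisson(tract_start * (L + pad)) if tract_start > 0 else 0
    t_start = rng.uniform(-pad, L, size=n_t)
    t_len = rng.exponential(mean_tract, size=n_t) if n_t else np.empty(0)
    t_end = t_start + t_len

    # assemble piecewise genotype over [0, L] in genetic coordinates
    cuts = [0.0, L]
    cuts.extend(jpos.tolist())
    for a, b in zip(t_start, t_end):
        if b > 0.0 and a < L:
            cuts.append(max(a, 0.0))
            cuts.append(min(b, L))
    cuts = np.unique(np.asarray(cuts))
    mids = (cuts[:-1] + cuts[1:]) / 2.0
    backbone_idx = np.searchsorted(jpos, mids)
    genos = np.where((backbone_idx + (0 if first == GENO_A else 1)) % 2 == 0,
                     GENO_A, GENO_B).astype(np.int8)
    if n_t:
        in_het = np.zeros(len(mids), dtype=bool)
        for a, b in zip(t_start, t_end):
            in_het |= (mids > a) & (mids < b)
        genos[in_het] = GENO_H
    # genetic -> physical, merge equal neighbours / zero-length segments
    bp_cuts = np.rint(cuts / L * chrom.length_bp).astype(np.int64)
    keep = [0]
    for i in range(1, len(bp_cuts) - 1):
        if bp_cuts[i] > bp_cuts[keep[-1]] and genos[i] != genos[keep[-1]]:
            keep.append(i)
    breaks = bp_cuts[keep[1:]]
    out_genos = genos[keep]
    # clamp away degenerate first/last cuts
    ok = (breaks >= 1) & (breaks < chrom.length_bp)
    if not ok.all():
        out_genos = np.concatenate((out_genos[:1], out_genos[1:][ok]))
        breaks = breaks[ok]
    return LineMosaic(breaks=breaks, genos=out_genos)


def simulate_ril_genomes(config: SimConfig,
                         rng: np.random.Generator | None = None) -> TrueGenome:
    """Draw one genotype mosaic per line and chromosome.

    Junction and heterozygous-tract densities are the exact
    finite-generation values from the two-locus selfing chain, so the
    output matches a per-meiosis gamete-dropping simulation in
    distribution (checked in the test suite).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lam_hom, tract_start, mean_tract = selfing_junction_densities(
        config.selfing_generations)
    mosaics: dict[str, list[LineMosaic]] = {}
    for ch in config.chromosomes:
        mosaics[ch.name] = [
            _simulate_mosaic(ch, lam_hom, tract_start, mean_tract, rng)
            for _ in range(config.n_lines)
        ]
    return TrueGenome(config=config, mosaics=mosaics)


# ---------------------------------------------------------------------------
# GBS observations
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _truncated_poisson(mean: float, size: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Poisson conditioned on >= 1 via inverse CDF."""
    lo = np.exp(-mean)
    u = rng.uniform(lo, 1.0, size=size)
    return stats.poisson.ppf(u, mean).astype(np.int32)


def simulate_gbs_observations(genomes: TrueGenome, config: SimConfig,
                              rng: np.random.Generator | None = None
                              ) -> VariantMatrix:
    """Observe the true genomes through a GBS-like channel.

    SNP sites are placed uniformly at ``snp_density`` per Mb; each
    individual observes each site independently with probability
    ``capture_fraction`` at a depth drawn from a Poisson truncated at 1;
    observed calls flip away from the truth with probability
    ``genotyping_error`` (heterozygous truths flip to either homozygote).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    chroms_out = []
    pos_out = []
    calls_out = []
    n = config.n_lines
    for ch in config.chromosomes:
        n_sites = int(round(ch.length_bp / 1e6 * config.snp_density))
        pos = np.sort(rng.choice(ch.length_bp, size=n_sites, replace=False)) + 1
        truth = np.empty((n_sites, n), dtype=np.int8)
        for j in range(n):
            truth[:, j] = genomes.mosaics[ch.name][j].genotype_at(pos)
        chroms_out.append(np.full(n_sites, ch.name, dtype=object))
        pos_out.append(pos.astype(np.int64))
        calls_out.append(truth)
    chroms = np.concatenate(chroms_out)
    pos = np.concatenate(pos_out)
    truth = np.concatenate(calls_out, axis=0)
    n_sites = len(pos)

    observed = rng.random((n_sites, n)) < config.capture_fraction
    depth = np.zeros((n_sites, n), dtype=np.int32)
    n_obs = int(observed.sum())
    depth[observed] = _truncated_poisson(config.mean_depth, n_obs, rng)

    calls = truth.copy()
    if config.genotyping_error > 0:
        flip = (rng.random((n_sites, n)) < config.genotyping_error) & observed
        r = rng.random((n_sites, n))
        flipped = np.where(calls == GENO_A, GENO_B,
                           np.where(calls == GENO_B, GENO_A,
                                    np.where(r < 0.5, GENO_A, GENO_B)))
        calls = np.where(flip, flipped, calls).astype(np.int8)
    calls[~observed] = MISSING

    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_shift = rng.integers(1, 4, size=n_sites)
    ref = _BASES[ref_idx]
    alt = _BASES[(ref_idx + alt_shift) % 4]
    # mapping quality: mostly high, a small low-quality tail
    mq = rng.normal(55.0, 5.0, size=n_sites)
    low = rng.random(n_sites) < 0.03
    mq[low] = rng.uniform(0.0, 30.0, size=int(low.sum()))
    mq = np.clip(mq, 0.0, 60.0)

    p1 = np.array([f"{a}/{a}" for a in ref], dtype=object)
    p2 = np.array([f"{a}/{a}" for a in alt], dtype=object)
    return VariantMatrix(
        chroms=chroms, pos=pos, ref=ref, alt=alt,
        parent1_call=p1, parent2_call=p2, mapping_quality=mq,
        calls=calls, depth=depth, lines=genomes.lines,
    )


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def genotype_scores_at(genomes: TrueGenome, chrom: str,
                       pos_cm: float) -> np.ndarray:
    """Additive scores x in {+1,0,-1} of all lines at a map position."""
    spec = {c.name: c for c in genomes.config.chromosomes}[chrom]
    if spec.length_cm > 0:
        bp = int(round(pos_cm / spec.length_cm * spec.length_bp))
    else:
        bp = 1
    bp = min(max(bp, 1), spec.length_bp)
    codes = np.array([m.genotype_at(np.array([bp]))[0]
                      for m in genomes.mosaics[chrom]])
    return geno_to_score(codes)


def simulate_phenotypes(genomes: TrueGenome, qtls: list[QTLSpec],
                        environments: list[str],
                        rng: np.random.Generator | None = None,
                        default_resid_sd: float = 1.0,
                        trait_means: dict[str, float] | None = None
                        ) -> pd.DataFrame:
    """Multi-environment trait table: y = sum_q a_q m_env x_q + noise.

    Returns one row per (line, environment) with one column per trait.
    """
    if rng is None:
        rng = np.random.default_rng(genomes.config.seed + 2)
    chrom_names = {c.name for c in genomes.config.chromosomes}
    for q in qtls:
        if q.chrom not in chrom_names:
            raise ValueError(f"QTL on unknown chromosome {q.chrom}")
    traits = sorted({q.trait for q in qtls}) or list(TRAITS)
    trait_means = trait_means or {}
    scores = {id(q): genotype_scores_at(genomes, q.chrom, q.pos_cm)
              for q in qtls}
    n = genomes.config.n_lines
    rows = []
    for env in environments:
        block = {}
        for t in traits:
            y = np.full(n, trait_means.get(t, 0.0))
            sds = [default_resid_sd]
            for q in qtls:
                if q.trait != t:
                    continue
                x = np.nan_to_num(scores[id(q)], nan=0.0)
                y = y + q.effect_in(env) * x
                if env in q.resid_sd:
                    sds.append(q.resid_sd[env])
            sd = sds[-1]
            y = y + rng.normal(0.0, sd, size=n)
            block[t] = y
        for i, line in enumerate(genomes.lines):
            rows.append({"line": line, "environment": env,
                         **{t: block[t][i] for t in traits}})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression counts
# ---------------------------------------------------------------------------

def simulate_counts(degspecs: list[DEGSpec], samples: list[str],
                    library_sizes: dict[str, float] | None = None,
                    rng: np.random.Generator | int | None = None
                    ) -> pd.DataFrame:
    """Raw NB counts, genes by samples.

    The NB mean for gene g in sample s is ``baseline * 2**log2fc`` if s is
    an affected sample (else baseline), scaled by the sample's library-size
    factor; variance is mean + dispersion * mean^2 (dispersion 0 gives
    Poisson).
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(0 if rng is None else rng)
    if library_sizes is None:
        library_sizes = {s: 1.0 for s in samples}
    for s in samples:
        if library_sizes[s] <= 0:
            raise ValueError("library sizes must be > 0")
    mean_lib = float(np.mean([library_sizes[s] for s in samples]))
    counts = np.zeros((len(degspecs), len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        factor = library_sizes[s] / mean_lib
        mu = np.array([
            g.baseline_mean * (2.0 ** g.log2fc if s in g.affected_samples
                               else 1.0) * factor
            for g in degspecs
        ])
        phi = np.array([g.dispersion for g in degspecs])
        lam = mu.copy()
        nb = phi > 0
        if nb.any():
            shape = 1.0 / phi[nb]
            lam[nb] = rng.gamma(shape, mu[nb] * phi[nb])
        counts[:, j] = rng.poisson(lam)
    return pd.DataFrame(counts, index=[g.gene_id for g in degspecs],
                        columns=samples)


# ---------------------------------------------------------------------------
# study-condition defaults and truth serialization
# ---------------------------------------------------------------------------

def example_qtl_specs() -> list[QTLSpec]:
    """Default placed QTLs echoing the study's trait architecture.

    Chalkiness (PGWC/DEC) loci sit on chromosomes 5, 7 and 8 with the
    increasing allele from parent 2 (negative additive effect); grain-shape
    loci sit on chromosomes 3, 5 and 7.  Residual SDs give single-QTL PVEs
    of roughly 8-15%.
    """
    envs = {e: 1.0 for e in ENVIRONMENTS}
    qtls = [
        QTLSpec("GW", "Chr05", 40.0, -0.10, dict(envs), {}),
        QTLSpec("GL", "Chr03", 55.0, 0.55, dict(envs), {}),
        QTLSpec("GL", "Chr07", 62.0, 0.40, dict(envs), {}),
        QTLSpec("LWR", "Chr03", 55.0, 0.35, dict(envs), {}),
        QTLSpec("CS", "Chr05", 40.0, -0.012, dict(envs), {}),
        QTLSpec("AS", "Chr10", 30.0, -0.60, dict(envs), {}),
        QTLSpec("PL", "Chr03", 55.0, 0.90, dict(envs), {}),
        QTLSpec("PGWC", "Chr05", 40.0, -9.0, dict(envs), {}),
        QTLSpec("PGWC", "Chr07", 65.0, -7.0, dict(envs), {}),
        QTLSpec("PGWC", "Chr08", 8.0, -8.0, dict(envs), {}),
        QTLSpec("DEC", "Chr05", 40.0, -5.0, dict(envs), {}),
        QTLSpec("DEC", "Chr08", 8.0, -4.5, dict(envs), {}),
    ]
    sd = {"GW": 0.22, "GL": 1.1, "LWR": 0.8, "CS": 0.028, "AS": 1.4,
          "PL": 2.0, "PGWC": 18.0, "DEC": 10.0}
    for q in qtls:
        q.resid_sd = {e: sd[q.trait] for e in ENVIRONMENTS}
    return qtls


def phenotype_resid_sds() -> dict[str, float]:
    return {"GW": 0.22, "GL": 1.1, "LWR": 0.8, "CS": 0.028, "AS": 1.4,
            "PL": 2.0, "PGWC": 18.0, "DEC": 10.0}


def trait_baselines() -> dict[str, float]:
    """RIL-population trait means on the scale of the study's Table 1."""
    return {"GW": 2.743, "GL": 9.404, "LWR": 3.461, "CS": 0.516,
            "AS": 19.650, "PL": 21.950, "PGWC": 28.26, "DEC": 19.43}


def simulate_genes(config: SimConfig, n_genes: int,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Uniformly placed non-overlapping-ish gene models for the GFF3."""
    rows = []
    total_bp = sum(c.length_bp for c in config.chromosomes)
    per_chrom = [max(1, int(round(n_genes * c.length_bp / total_bp)))
                 for c in config.chromosomes]
    k = 0
    for ch, m in zip(config.chromosomes, per_chrom):
        starts = np.sort(rng.choice(max(ch.length_bp - 5000, m), size=m,
                                    replace=False)) + 1
        lengths = rng.integers(1000, 5000, size=m)
        for s, ln in zip(starts, lengths):
            k += 1
            rows.append({
                "gene_id": f"Gene{k:05d}", "chrom": ch.name,
                "start": int(s), "end": int(min(s + ln, ch.length_bp)),
                "strand": "+" if rng.random() < 0.5 else "-",
            })
    return pd.DataFrame(rows)


def plant_degs(genes: pd.DataFrame, qtl_windows: list[tuple[str, int, int]],
               rng: np.random.Generator, n_inside: int = 3,
               n_outside: int = 30, baseline_mean: float = 100.0,
               log2fc: float = 3.0, dispersion: float = 0.01
               ) -> list[DEGSpec]:
    """Turn gene models into DEGSpecs with DE genes planted in and out of
    QTL windows.

    ``n_inside`` DE genes are placed within each QTL window (up in the
    high-chalk samples), ``n_outside`` elsewhere; all remaining genes are
    nulls.
    """
    specs: dict[str, DEGSpec] = {}
    for _, g in genes.iterrows():
        specs[g.gene_id] = DEGSpec(
            gene_id=g.gene_id, chrom=g.chrom, start=int(g.start),
            end=int(g.end), baseline_mean=baseline_mean,
            dispersion=dispersion)
    affected = ["P02428", "H-Pool"]
    window_ids: set[str] = set()
    for chrom, lo, hi in qtl_windows:
        hit = genes[(genes.chrom == chrom) & (genes.end >= lo)
                    & (genes.start <= hi)]
        window_ids.update(hit.gene_id)
        for gid in hit.gene_id.tolist()[:n_inside]:
            specs[gid].log2fc = log2fc
            specs[gid].affected_samples = list(affected)
    outside = genes[~genes.gene_id.isin(window_ids)]
    pick = rng.choice(outside.gene_id.to_numpy(), size=min(n_outside,
                                                           len(outside)),
                      replace=False)
    for gid in pick:
        specs[gid].log2fc = log2fc * (1 if rng.random() < 0.5 else -1)
        specs[gid].affected_samples = list(affected)
    return list(specs.values())


def write_truth_json(path, genomes: TrueGenome, qtls: list[QTLSpec],
                     degspecs: list[DEGSpec]) -> None:
    truth = genomes.truth_dict()
    truth["qtls"] = [
        {"trait": q.trait, "chrom": q.chrom, "pos_cm": q.pos_cm,
         "additive": q.additive, "env_multiplier": q.env_multiplier,
         "resid_sd": q.resid_sd}
        for q in qtls
    ]
    truth["degs"] = [
        {"gene_id": d.gene_id, "chrom": d.chrom, "start": d.start,
         "end": d.end, "log2fc": d.log2fc,
         "affected_samples": d.affected_samples}
        for d in degspecs if d.is_deg
    ]
    with open(path, "w") as fh:
        json.dump(truth, fh)
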