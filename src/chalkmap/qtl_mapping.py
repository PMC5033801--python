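"""Additive inclusive composite interval mapping (ICIM-ADD).

The scan follows the two-step inclusive composite interval mapping recipe:
(1) stepwise linear regression picks a sparse set of background markers per
trait and environment (entry p <= p_in, removal p > p_out); (2) walking a
1 cM grid, the phenotype is adjusted by the selected markers *excluding*
the two markers flanking the current interval, and a normal-mixture model
with per-line QTL-genotype probabilities is fitted by EM at each position.
LOD is the log10 likelihood ratio against a single-normal null; peaks at
LOD >= 2.5 are reported with their flanking bin markers, percent variance
explained and signed additive effect (positive: the parent-1/A allele
increases the trait; negative: the parent-2/B allele does).

Heterozygous lines enter as their own mixture component constrained to the
midparent mean (no dominance parameter in the ADD model).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import GENO_A, GENO_B, GENO_H, MISSING, BinMarkerMatrix, \
    geno_to_score
from .linkage_map import GeneticMap, kosambi_inv, meiotic_to_ril

log = logging.getLogger(__name__)

LN10 = np.log(10.0)


@dataclass
class ScanConfig:
    step: float = 1.0               # cM
    p_in: float = 0.001             # stepwise entry probability
    p_out: float | None = None      # removal probability (default 2 * p_in)
    lod_threshold: float = 2.5
    em_tol: float = 1e-6
    em_max_iter: int = 100
    peak_valley: float = 1.0        # LOD drop separating adjacent peaks

    def __post_init__(self) -> None:
        if self.p_out is None:
            self.p_out = 2.0 * self.p_in

    def validate(self) -> None:
        if not (0.0 < self.p_in <= self.p_out < 1.0):
            raise ValueError("need 0 < p_in <= p_out < 1")
        if self.step <= 0:
            raise ValueError("step must be > 0")


@dataclass
class QTLRecord:
    trait: str
    environment: str
    chrom: str
    pos_cm: float
    left_marker: str
    right_marker: str
    lod: float
    pve: float                     # percent
    additive: float
    left_pos_cm: float = 0.0
    right_pos_cm: float = 0.0
    left_start_bp: int = 0
    right_end_bp: int = 0
    stable: bool = False
    group_id: int = -1


@dataclass
class QTLCluster:
    cluster_id: str
    chrom: str
    left_marker: str
    right_marker: str
    start_bp: int
    end_bp: int
    traits: list[str] = field(default_factory=list)
    members: list[QTLRecord] = field(default_factory=list)


# ---------------------------------------------------------------------------
# stepwise marker selection
# ---------------------------------------------------------------------------

def _impute(X: np.ndarray) -> np.ndarray:
    """Column-mean imputation of missing genotype scores (regression
    only)."""
    X = np.array(X, dtype=float)
    mu = np.nanmean(X, axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    idx = np.where(np.isnan(X))
    X[idx] = mu[idx[1]]
    return X


def stepwise_select(y: np.ndarray, X: np.ndarray,
                    cfg: ScanConfig | None = None
                    ) -> tuple[list[int], dict[int, float], float]:
    """Forward-backward stepwise regression.

    ``X`` is the imputed marker-score matrix (lines x markers).  Returns
    (selected marker indices in genome order, {index: coefficient},
    intercept) from the final OLS fit.  Collinear duplicates of already
    selected markers are never entered (first in genome order wins).
    """
    cfg = cfg or ScanConfig()
    cfg.validate()
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    if np.std(y) == 0.0:
        return [], {}, float(y.mean())

    selected: list[int] = []
    max_terms = max(n - 3, 1)

    def ols(sel: list[int]):
        Z = np.column_stack([np.ones(n)] + [X[:, k] for k in sel])
        beta, _, _, _ = np.linalg.lstsq(Z, y, rcond=None)
        resid = y - Z @ beta
        return Z, beta, resid

    while True:
        changed = False
        # forward: best candidate by partial F given current model
        Z, beta, resid = ols(selected)
        Q, _ = np.linalg.qr(Z)
        Xr = X - Q @ (Q.T @ X)
        yr = resid
        ssx = np.einsum("ij,ij->j", Xr, Xr)
        ok = ssx > 1e-10 * n          # excludes selected + their duplicates
        sy = float(yr @ yr)
        if sy > 0 and ok.any() and len(selected) < max_terms:
            cxy = Xr.T @ yr
            ssr = np.zeros(m)
            ssr[ok] = cxy[ok] ** 2 / ssx[ok]
            dof = n - len(selected) - 2
            denom = np.maximum(sy - ssr, 1e-300)
            F = np.where(ok, ssr * dof / denom, 0.0)
            j = int(np.argmax(np.where(ok, F, -np.inf)))
            p_enter = float(stats.f.sf(F[j], 1, dof))
            if p_enter <= cfg.p_in:
                selected.append(j)
                selected.sort()
                changed = True
        # backward: drop the worst term while p > p_out
        while selected:
            Z, beta, resid = ols(selected)
            dof = n - len(selected) - 1
            sse = float(resid @ resid)
            XtXinv = np.linalg.pinv(Z.T @ Z)
            se = np.sqrt(np.maximum(np.diag(XtXinv), 0.0)
                         * sse / max(dof, 1))
            with np.errstate(divide="ignore", invalid="ignore"):
                tstat = np.where(se > 0, beta / se, np.inf)
            pvals = 2.0 * stats.t.sf(np.abs(tstat[1:]), max(dof, 1))
            worst = int(np.argmax(pvals))
            if pvals[worst] > cfg.p_out:
                selected.pop(worst)
                changed = True
            else:
                break
        if not changed:
            break

    _, beta, _ = ols(selected)
    coefs = {k: float(beta[i + 1]) for i, k in enumerate(selected)}
    return selected, coefs, float(beta[0])


def adjust_phenotype(y: np.ndarray, X: np.ndarray,
                     coefs: dict[int, float],
                     exclude: set[int] | None = None) -> np.ndarray:
    """Remove the fitted background-marker effects from the phenotype.

    Coefficients are fixed from the full stepwise fit (no refit); markers
    in ``exclude`` (the current interval's flanks) are left in.
    """
    exclude = exclude or set()
    dy = np.asarray(y, dtype=float).copy()
    for k, b in coefs.items():
        if k in exclude:
            continue
        dy -= b * X[:, k]
    return dy


# ---------------------------------------------------------------------------
# interval genotype probabilities and the EM mixture
# ---------------------------------------------------------------------------

def qtl_genotype_prob(left: np.ndarray, right: np.ndarray,
                      R_left: float, R_right: float
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """P(QTL genotype | flanking marker genotypes) per line.

    The RIL genotype process is treated as Markov along the chromosome
    with RIL-scale recombination ``R`` per sub-interval.  Heterozygous
    flanks: both-H lines are assigned to the het component; a single H
    flank is treated as uninformative and the line is conditioned on the
    other flank only.  Returns (pA, pH, pB) arrays.
    """
    left = np.asarray(left)
    right = np.asarray(right)
    n = len(left)
    RL = min(max(R_left, 0.0), 0.5)
    RR = min(max(R_right, 0.0), 0.5)
    pA = np.full(n, 0.5)
    pH = np.zeros(n)

    l_hom = np.isin(left, (GENO_A, GENO_B))
    r_hom = np.isin(right, (GENO_A, GENO_B))
    both = l_hom & r_hom
    lA = left == GENO_A
    rA = right == GENO_A
    # both flanks homozygous: condition on both
    num = np.where(lA, 1.0 - RL, RL) * np.where(rA, 1.0 - RR, RR)
    den = num + np.where(lA, RL, 1.0 - RL) * np.where(rA, RR, 1.0 - RR)
    with np.errstate(invalid="ignore", divide="ignore"):
        pA[both] = (num / den)[both]
    # single informative flank
    only_l = l_hom & ~r_hom
    only_r = r_hom & ~l_hom
    pA[only_l] = np.where(lA, 1.0 - RL, RL)[only_l]
    pA[only_r] = np.where(rA, 1.0 - RR, RR)[only_r]
    # both heterozygous: own component at the midparent mean
    hh = (left == GENO_H) & (right == GENO_H)
    pH[hh] = 1.0
    pA[hh] = 0.0
    pB = 1.0 - pA - pH
    return pA, pH, np.clip(pB, 0.0, 1.0)


def em_scan_position(dy: np.ndarray, pA: np.ndarray, pH: np.ndarray,
                     pB: np.ndarray, cfg: ScanConfig | None = None
                     ) -> tuple[float, float, tuple[float, float], float,
                                np.ndarray]:
    """Fit the additive normal mixture at one scan position.

    Components are A, H, B with means m+a, m, m-a and a common sigma;
    per-line mixing probabilities come from the flanking markers.  Returns
    (LOD, additive, (mu_A, mu_B), sigma, posterior expected score).
    """
    cfg = cfg or ScanConfig()
    y = np.asarray(dy, dtype=float)
    n = len(y)
    # null: single normal
    mu0 = y.mean()
    s20 = max(y.var(), 1e-12)
    ll0 = -0.5 * n * (np.log(2.0 * np.pi * s20) + 1.0)

    wa = pA + 1e-12
    wb = pB + 1e-12
    mu_a = float((wa * y).sum() / wa.sum())
    mu_b = float((wb * y).sum() / wb.sum())
    m = 0.5 * (mu_a + mu_b)
    a = 0.5 * (mu_a - mu_b)
    s2 = s20
    ll = -np.inf
    P = np.column_stack([pA, pH, pB])
    t = np.array([1.0, 0.0, -1.0])
    wA = wB = None
    for _ in range(cfg.em_max_iter):
        mus = m + a * t
        dens = P * np.exp(-0.5 * (y[:, None] - mus[None, :]) ** 2 / s2) \
            / np.sqrt(2.0 * np.pi * s2)
        tot = dens.sum(axis=1)
        tot = np.maximum(tot, 1e-300)
        ll_new = float(np.log(tot).sum())
        if ll_new < ll - 1e-8:
            raise RuntimeError("EM log-likelihood decreased")
        W = dens / tot[:, None]
        wA, wB = W[:, 0], W[:, 2]
        st = float((wA - wB).sum())
        st2 = float((wA + wB).sum())
        sy = float(y.sum())
        sty = float(((wA - wB) * y).sum())
        det = n * st2 - st * st
        if st2 < 1e-12 or abs(det) < 1e-12:
            m, a = y.mean(), 0.0
        else:
            m = (st2 * sy - st * sty) / det
            a = (n * sty - st * sy) / det
        mus = m + a * t
        s2 = float((W * (y[:, None] - mus[None, :]) ** 2).sum() / n)
        s2 = max(s2, 1e-12)
        if ll_new - ll < cfg.em_tol:
            ll = ll_new
            break
        ll = ll_new
    lod = (ll - ll0) / LN10
    xhat = wA - wB if wA is not None else np.zeros(n)
    return float(lod), float(a), (m + a, m - a), float(np.sqrt(s2)), xhat


# ---------------------------------------------------------------------------
# genome scan
# ---------------------------------------------------------------------------

def _find_peaks(grid: np.ndarray, lods: np.ndarray, threshold: float,
                valley: float) -> list[int]:
    """Indices of local maxima >= threshold separated by >= valley drops."""
    n = len(lods)
    if n == 0:
        return []
    cand = [i for i in range(n)
            if lods[i] >= threshold
            and (i == 0 or lods[i] >= lods[i - 1])
            and (i == n - 1 or lods[i] > lods[i + 1])]
    cand.sort(key=lambda i: -lods[i])
    kept: list[int] = []
    for i in cand:
        ok = True
        for j in kept:
            lo, hi = min(i, j), max(i, j)
            vmin = lods[lo:hi + 1].min()
            if vmin > min(lods[i], lods[j]) - valley:
                ok = False
                break
        if ok:
            kept.append(i)
    return sorted(kept)


def scan_genome(y: np.ndarray, bins: BinMarkerMatrix, gmap: GeneticMap,
                cfg: ScanConfig | None = None, trait: str = "",
                environment: str = "") -> tuple[list[QTLRecord],
                                                pd.DataFrame]:
    """ICIM-ADD scan of one trait in one environment.

    ``y`` is ordered like ``bins.lines``; NaN phenotypes drop the line for
    this scan.  Returns QTL records (peaks at LOD >= threshold) and the
    full LOD-profile table.
    """
    cfg = cfg or ScanConfig()
    cfg.validate()
    y = np.asarray(y, dtype=float)
    valid = ~np.isnan(y)
    if valid.mean() <= 0.5:
        log.warning("%s/%s: >50%% missing phenotypes; scan skipped",
                    trait, environment)
        return [], pd.DataFrame()
    yv = y[valid]
    var_y = float(yv.var())
    codes = bins.genotypes[:, valid]
    X = _impute(geno_to_score(codes).T)        # lines x markers
    selected, coefs, _ = stepwise_select(yv, X, cfg)

    mtab = gmap.table.reset_index(drop=True)
    marker_pos = {m: (c, p) for m, c, p in
                  zip(mtab["marker"], mtab["chrom"], mtab["pos_cm"])}
    records: list[QTLRecord] = []
    prof_rows = []
    for chrom in gmap.chromosomes():
        ct = mtab[mtab["chrom"] == chrom]
        gidx = np.array([bins.marker_index(m) for m in ct["marker"]])
        mpos = ct["pos_cm"].to_numpy()
        if len(gidx) == 0:
            continue
        chrom_len = mpos[-1]
        grid = np.arange(0.0, chrom_len + cfg.step / 2, cfg.step)
        if len(grid) == 0:
            grid = np.array([0.0])
        lods = np.zeros(len(grid))
        adds = np.zeros(len(grid))
        xhats: list[np.ndarray] = []
        for gi, t_cm in enumerate(grid):
            iright = int(np.searchsorted(mpos, t_cm, side="left"))
            ileft = iright - 1
            if iright >= len(mpos):
                ileft, iright = len(mpos) - 1, len(mpos) - 1
            if ileft < 0:
                ileft = iright
            kl, kr = int(gidx[ileft]), int(gidx[iright])
            dl = max(t_cm - mpos[ileft], 0.0)
            dr = max(mpos[iright] - t_cm, 0.0)
            RL = meiotic_to_ril(kosambi_inv(dl))
            RR = meiotic_to_ril(kosambi_inv(dr))
            left = codes[kl] if kl != kr else codes[kl]
            right = codes[kr] if kl != kr else \
                np.full(codes.shape[1], MISSING, dtype=np.int8)
            dy = adjust_phenotype(yv, X, coefs, exclude={kl, kr})
            pA, pH, pB = qtl_genotype_prob(left, right, RL, RR)
            lod, a, _, _, xhat = em_scan_position(dy, pA, pH, pB, cfg)
            lods[gi], adds[gi] = lod, a
            xhats.append(xhat)
            prof_rows.append({"trait": trait, "environment": environment,
                              "chrom": chrom, "pos_cm": t_cm, "lod": lod,
                              "additive": a})
        for pi in _find_peaks(grid, lods, cfg.lod_threshold, cfg.peak_valley):
            t_cm = grid[pi]
            # 1-LOD support interval around the peak, then the markers
            # bracketing it (the reported confidence interval)
            lo = pi
            while lo > 0 and lods[lo - 1] > lods[pi] - 1.0:
                lo -= 1
            hi = pi
            while hi < len(grid) - 1 and lods[hi + 1] > lods[pi] - 1.0:
                hi += 1
            ileft = int(np.searchsorted(mpos, grid[lo], side="right")) - 1
            ileft = max(ileft, 0)
            iright = int(np.searchsorted(mpos, grid[hi], side="left"))
            iright = min(iright, len(mpos) - 1)
            a = adds[pi]
            pve = 100.0 * float(np.var(a * xhats[pi])) / max(var_y, 1e-12)
            li, ri = int(gidx[ileft]), int(gidx[iright])
            records.append(QTLRecord(
                trait=trait, environment=environment, chrom=chrom,
                pos_cm=float(t_cm),
                left_marker=bins.ids[li], right_marker=bins.ids[ri],
                lod=float(lods[pi]), pve=pve, additive=float(a),
                left_pos_cm=float(mpos[ileft]),
                right_pos_cm=float(mpos[iright]),
                left_start_bp=int(bins.start[li]),
                right_end_bp=int(bins.end[ri]),
            ))
    return records, pd.DataFrame(prof_rows)


def scan_all(pheno: pd.DataFrame, bins: BinMarkerMatrix, gmap: GeneticMap,
             cfg: ScanConfig | None = None,
             traits: list[str] | None = None,
             environments: list[str] | None = None
             ) -> tuple[list[QTLRecord], pd.DataFrame]:
    """Scan every trait in every environment of a phenotype table."""
    cfg = cfg or ScanConfig()
    meta_cols = {"line", "environment"}
    traits = traits or [c for c in pheno.columns if c not in meta_cols]
    environments = environments or list(dict.fromkeys(pheno["environment"]))
    records: list[QTLRecord] = []
    profiles = []
    for env in environments:
        sub = pheno[pheno["environment"] == env].set_index("line")
        if sub.empty:
            raise ValueError(f"unknown environment: {env}")
        for trait in traits:
            y = np.array([sub[trait].get(line, np.nan)
                          for line in bins.lines], dtype=float)
            recs, prof = scan_genome(y, bins, gmap, cfg, trait=trait,
                                     environment=env)
            records.extend(recs)
            profiles.append(prof)
    prof_df = pd.concat([p for p in profiles if len(p)],
                        ignore_index=True) if profiles else pd.DataFrame()
    return records, prof_df


# ---------------------------------------------------------------------------
# stability and clustering
# ---------------------------------------------------------------------------

def _overlap(a: QTLRecord, b: QTLRecord) -> bool:
    return (a.chrom == b.chrom
            and a.left_start_bp <= b.right_end_bp
            and b.left_start_bp <= a.right_end_bp)


def _single_linkage(records: list[QTLRecord]) -> list[list[int]]:
    n = len(records)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _overlap(records[i], records[j]):
                pi, pj = find(i), find(j)
                if pi != pj:
                    parent[pi] = pj
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def classify_stable(records: list[QTLRecord]) -> list[QTLRecord]:
    """Flag stable QTLs: same trait, overlapping confidence intervals,
    detected in three or more distinct environments."""
    by_trait: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        by_trait.setdefault(r.trait, []).append(i)
    gid = 0
    for trait, idxs in by_trait.items():
        sub = [records[i] for i in idxs]
        for group in _single_linkage(sub):
            envs = {sub[k].environment for k in group}
            stable = len(envs) >= 3
            for k in group:
                sub[k].stable = stable
                sub[k].group_id = gid
            gid += 1
    return records


def cluster_qtls(records: list[QTLRecord]) -> list[QTLCluster]:
    """Group QTLs (across traits) with overlapping marker intervals into
    clusters; the cluster interval is the union of member intervals."""
    clusters: list[QTLCluster] = []
    groups = _single_linkage(records)
    groups.sort(key=lambda g: (records[g[0]].chrom,
                               min(records[k].left_start_bp for k in g)))
    for ci, group in enumerate(groups):
        members = [records[k] for k in group]
        start = min(m.left_start_bp for m in members)
        end = max(m.right_end_bp for m in members)
        left = min(members, key=lambda m: m.left_start_bp).left_marker
        right = max(members, key=lambda m: m.right_end_bp).right_marker
        traits = sorted({m.trait for m in members})
        clusters.append(QTLCluster(
            cluster_id=f"cluster{ci + 1}", chrom=members[0].chrom,
            left_marker=left, right_marker=right, start_bp=int(start),
            end_bp=int(end), traits=traits, members=members,
        ))
    return clusters


def records_to_frame(records: list[QTLRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "trait": r.trait, "environment": r.environment, "chrom": r.chrom,
        "peak_cm": round(r.pos_cm, 2),
        "interval_cm": f"{r.left_pos_cm:.2f}-{r.right_pos_cm:.2f}",
        "left_marker": r.left_marker, "right_marker": r.right_marker,
        "lod": round(r.lod, 3), "pve_pct": round(r.pve, 3),
        "additive": round(r.additive, 3), "stable": r.stable,
    } for r in records])


def clusters_to_frame(clusters: list[QTLCluster]) -> pd.DataFrame:
    return pd.DataFrame([{
        "cluster": c.cluster_id, "chrom": c.chrom,
        "marker_interval": f"{c.left_marker}-{c.right_marker}",
        "start_bp": c.start_bp, "end_bp": c.end_bp,
        "traits": ",".join(c.traits),
        "n_qtls": len(c.members),
        "lod_range": f"{min(m.lod for m in c.members):.3f}-"
                     f"{max(m.lod for m in c.members):.3f}",
        "pve_range": f"{min(m.pve for m in c.members):.3f}-"
                     f"{max(m.pve for m in c.members):.3f}",
    } for c in clusters])
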