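"""Exact negative-binomial differential expression for unreplicated pairs.

The design contrasts single samples (parent vs parent; high-chalk pool vs
low-chalk pool), so gene-wise dispersion cannot be estimated and a fixed
dispersion is used instead (default biological CV 0.1, i.e. dispersion
0.01, a common choice for genetically near-identical material).  The test
conditions on the two-sample sum: with dispersion 0 it degenerates to the
exact binomial test; otherwise the conditional distribution of the first
count given the sum of two NB variables is enumerated.  Multiple testing
is controlled by Benjamini-Hochberg FDR, and a gene is called DE at
FDR <= 0.05 and |log2 fold change| >= 1 (both thresholds inclusive).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

DEFAULT_DISPERSION = 0.01  # BCV 0.1 squared
PRIOR_COUNT = 0.5


def normalize_cpm(counts: pd.DataFrame,
                  library_sizes: dict[str, float] | None = None
                  ) -> pd.DataFrame:
    """Counts per million; library sizes default to column sums."""
    if library_sizes is None:
        library_sizes = counts.sum(axis=0).to_dict()
    out = counts.astype(float).copy()
    for c in out.columns:
        ls = library_sizes[c]
        if ls <= 0:
            raise ValueError(f"library size for {c} must be > 0")
        out[c] = out[c] * 1e6 / ls
    return out


def nb_exact_test(count_a: int, count_b: int, libsize_a: float,
                  libsize_b: float,
                  dispersion: float = DEFAULT_DISPERSION) -> float:
    """Two-sided exact test of equal expression, conditioning on the sum.

    Under the null the two counts share one underlying expression level;
    given the total t, the conditional probabilities of each split (k,
    t - k) are computed from NB (or Poisson when dispersion is 0) masses
    with means proportional to the library sizes, and the two-sided p is
    the total mass of splits no more probable than the observed one.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if libsize_a <= 0 or libsize_b <= 0:
        raise ValueError("library sizes must be > 0")
    t = int(count_a) + int(count_b)
    if t == 0:
        return 1.0
    k = np.arange(t + 1)
    mu = t / (libsize_a + libsize_b)
    mu_a, mu_b = mu * libsize_a, mu * libsize_b
    if dispersion == 0.0:
        la = stats.poisson.logpmf(k, mu_a)
        lb = stats.poisson.logpmf(k[::-1], mu_b)
    else:
        size = 1.0 / dispersion
        pa = size / (size + mu_a)
        pb = size / (size + mu_b)
        la = stats.nbinom.logpmf(k, size, pa)
        lb = stats.nbinom.logpmf(k[::-1], size, pb)
    logp = la + lb
    logp = logp - logsumexp(logp)
    p_obs = logp[int(count_a)]
    p = float(np.exp(logp[logp <= p_obs + 1e-10]).sum())
    return min(p, 1.0)


def fdr_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def report_log2fc(fold_change: float, direction: str) -> float:
    """Signed log2 of a direction-annotated fold change, 3 decimals.

    ``direction`` is "+" (up relative to baseline) or "-" (down).
    """
    if fold_change <= 0:
        raise ValueError("fold change must be > 0")
    sign = {"+": 1.0, "-": -1.0}[direction]
    return round(sign * float(np.log2(fold_change)), 3)


def de_table(counts: pd.DataFrame, baseline: str, contrast: str,
             dispersion: float = DEFAULT_DISPERSION,
             library_sizes: dict[str, float] | None = None) -> pd.DataFrame:
    """Per-gene DE results for one contrast against a baseline sample.

    Fold changes are reported on CPM with a prior count of 0.5 and a
    direction sign: "+" means higher in the contrast sample than in the
    baseline.
    """
    for s in (baseline, contrast):
        if s not in counts.columns:
            raise ValueError(f"sample {s} not in count matrix")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0).to_dict()
    cpm = normalize_cpm(counts[[baseline, contrast]],
                        {k: library_sizes[k] for k in (baseline, contrast)})
    scale = 1e6 / np.mean([library_sizes[baseline],
                           library_sizes[contrast]])
    prior = PRIOR_COUNT * scale
    ratio = (cpm[contrast] + prior) / (cpm[baseline] + prior)
    up = ratio >= 1.0
    fc = np.where(up, ratio, 1.0 / ratio)
    direction = np.where(up, "+", "-")
    log2fc = np.where(up, np.log2(ratio), -np.log2(1.0 / ratio))
    pvals = np.array([
        nb_exact_test(int(counts.at[g, contrast]), int(counts.at[g, baseline]),
                      library_sizes[contrast], library_sizes[baseline],
                      dispersion)
        for g in counts.index
    ])
    fdr = fdr_bh(pvals)
    out = pd.DataFrame({
        "gene_id": counts.index,
        "baseline": baseline,
        "contrast": contrast,
        "fold_change": fc,
        "direction": direction,
        "log2fc": log2fc,
        "p": pvals,
        "fdr": fdr,
    }).set_index("gene_id")
    return call_degs(out)


def call_degs(results: pd.DataFrame, max_fdr: float = 0.05,
              min_abs_log2fc: float = 1.0) -> pd.DataFrame:
    """Apply the significance rule: FDR <= 0.05 AND |log2FC| >= 1."""
    out = results.copy()
    out["significant"] = (out["fdr"] <= max_fdr) \
        & (out["log2fc"].abs() >= min_abs_log2fc)
    return out


def deg_summary(results: pd.DataFrame) -> dict[str, int]:
    sig = results[results["significant"]]
    return {
        "up": int((sig["direction"] == "+").sum()),
        "down": int((sig["direction"] == "-").sum()),
        "total": int(len(sig)),
    }
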