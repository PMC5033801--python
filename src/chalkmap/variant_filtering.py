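"""Reduction of raw biallelic variant calls to informative markers.

A site is useful in a RIL cross only if it is of the "aa x bb" type: both
parents homozygous for different alleles.  Retained sites are additionally
filtered on mapping quality (strict > threshold), per-call depth (strict >
threshold, failing calls set missing) and, for finished markers, on
segregation distortion against the 1:1 Mendelian expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import GENO_A, GENO_B, MISSING, BinMarkerMatrix, VariantMatrix

SITE_AA_BB = "aa_bb"
SITE_REJECTED = "rejected"


@dataclass
class FilterConfig:
    min_mapping_quality: float = 20.0   # strict: keep sites with MQ > this
    min_depth: int = 4                  # strict: keep calls with DP > this
    distortion_alpha: float = 0.01

    def validate(self) -> None:
        if self.min_mapping_quality < 0 or self.min_depth < 0:
            raise ValueError("thresholds must be >= 0")
        if not (0.0 < self.distortion_alpha < 1.0):
            raise ValueError("distortion_alpha must be in (0, 1)")


def classify_parental_site(parent1_call: str, parent2_call: str
                           ) -> tuple[str, str]:
    """Classify one site from the two parental diploid genotypes.

    Returns (site_class, reason); class is "aa_bb" iff both parents are
    homozygous for different alleles.
    """
    def alleles(call: str) -> list[str] | None:
        if not call or "." in call:
            return None
        parts = call.replace("|", "/").split("/")
        return parts if len(parts) == 2 else None

    a1 = alleles(parent1_call)
    a2 = alleles(parent2_call)
    if a1 is None or a2 is None:
        return SITE_REJECTED, "parent_missing"
    if a1[0] != a1[1] or a2[0] != a2[1]:
        return SITE_REJECTED, "parent_heterozygous"
    if a1[0] == a2[0]:
        return SITE_REJECTED, "monomorphic"
    return SITE_AA_BB, ""


def classify_sites(vm: VariantMatrix) -> VariantMatrix:
    """Fill ``site_class`` for every site from the parental calls."""
    cls = np.array([classify_parental_site(p1, p2)[0]
                    for p1, p2 in zip(vm.parent1_call, vm.parent2_call)],
                   dtype=object)
    vm.site_class = cls
    return vm


def filter_calls(vm: VariantMatrix, cfg: FilterConfig | None = None
                 ) -> tuple[VariantMatrix, pd.DataFrame]:
    """Apply the site/call quality filters.

    Order: keep aa x bb sites only; drop sites with mapping quality <=
    threshold; set calls with depth <= threshold missing; drop sites left
    with no called individual.  Returns the filtered matrix and a
    stage-by-stage report of site counts.
    """
    cfg = cfg or FilterConfig()
    cfg.validate()
    if vm.n_sites == 0:
        raise ValueError("no_sites")
    if vm.site_class is None:
        vm = classify_sites(vm)
    report_rows = [("input", vm.n_sites)]

    keep = vm.site_class == SITE_AA_BB
    vm = vm.subset_sites(keep)
    vm.site_class = np.full(vm.n_sites, SITE_AA_BB, dtype=object)
    report_rows.append(("aa_bb", vm.n_sites))

    keep = vm.mapping_quality > cfg.min_mapping_quality
    vm = vm.subset_sites(keep)
    report_rows.append(("mapping_quality", vm.n_sites))

    vm.calls = np.where(vm.depth > cfg.min_depth, vm.calls,
                        MISSING).astype(np.int8)
    vm.depth = np.where(vm.depth > cfg.min_depth, vm.depth, 0)

    keep = (vm.calls != MISSING).any(axis=1)
    vm = vm.subset_sites(keep)
    report_rows.append(("any_call", vm.n_sites))

    report = pd.DataFrame(report_rows, columns=["stage", "sites"])
    return vm, report


def segregation_distortion_test(n_a: int, n_b: int) -> tuple[float, float]:
    """Chi-square test of the homozygote counts against 1:1 (df = 1).

    Heterozygous and missing calls must already be excluded from the
    counts.  Returns (chi2, p).
    """
    n = n_a + n_b
    if n == 0:
        raise ValueError("no informative calls")
    exp = n / 2.0
    chi2 = (n_a - exp) ** 2 / exp + (n_b - exp) ** 2 / exp
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def distortion_scan(genotypes: np.ndarray) -> pd.DataFrame:
    """Per-marker distortion test over a genotype code matrix
    (markers x lines)."""
    rows = []
    for i in range(genotypes.shape[0]):
        g = genotypes[i]
        n_a = int((g == GENO_A).sum())
        n_b = int((g == GENO_B).sum())
        if n_a + n_b == 0:
            rows.append((n_a, n_b, np.nan, np.nan))
            continue
        chi2, p = segregation_distortion_test(n_a, n_b)
        rows.append((n_a, n_b, chi2, p))
    return pd.DataFrame(rows, columns=["n_A", "n_B", "chi2", "p"])


def drop_distorted_markers(bins: BinMarkerMatrix, alpha: float = 0.01
                           ) -> tuple[BinMarkerMatrix, pd.DataFrame]:
    """Discard bin markers with distorted segregation (p < alpha).

    Markers with no informative homozygous calls are kept untested.
    """
    tab = distortion_scan(bins.genotypes)
    discard = (tab["p"] < alpha).fillna(False).to_numpy()
    tab["discarded"] = discard
    return bins.subset(~discard), tab
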