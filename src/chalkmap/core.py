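"""Shared genotype codes and in-memory containers.

Genotypes are coded as small integers throughout the package:
``A`` (0) for the parent-1 (PYZX-type) homozygote, ``H`` (1) for
heterozygous, ``B`` (2) for the parent-2 (P02428-type) homozygote and
``MISSING`` (-1) for no call.  The additive coding used in QTL models maps
A/H/B to +1/0/-1 so that a negative additive effect means the parent-2
allele increases the trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENO_A: int = 0
GENO_H: int = 1
GENO_B: int = 2
MISSING: int = -1

#: single-character representation used in text output
GENO_CHARS = {GENO_A: "A", GENO_H: "H", GENO_B: "B", MISSING: "-"}
CHAR_GENOS = {v: k for k, v in GENO_CHARS.items()}


def geno_to_score(codes: np.ndarray) -> np.ndarray:
    """Map genotype codes to the additive score x in {+1, 0, -1}.

    Missing codes map to NaN.
    """
    codes = np.asarray(codes)
    out = np.full(codes.shape, np.nan)
    out[codes == GENO_A] = 1.0
    out[codes == GENO_H] = 0.0
    out[codes == GENO_B] = -1.0
    return out


@dataclass
class VariantMatrix:
    """Per-site, per-individual parental-origin calls with read depth.

    Sites are rows (1-based positions), individuals are columns.  ``calls``
    holds genotype codes, ``depth`` the supporting read count (0 where
    unobserved).  ``site_class`` is filled by the variant-filtering stage
    ("aa_bb" / "rejected" / "" before classification).
    """

    chroms: np.ndarray            # str, per site
    pos: np.ndarray               # int64, 1-based
    ref: np.ndarray               # str
    alt: np.ndarray               # str
    parent1_call: np.ndarray      # diploid genotype string, e.g. "A/A"
    parent2_call: np.ndarray
    mapping_quality: np.ndarray   # float
    calls: np.ndarray             # int8 (n_sites, n_lines)
    depth: np.ndarray             # int32 (n_sites, n_lines)
    lines: list[str] = field(default_factory=list)
    site_class: np.ndarray | None = None

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    def subset_sites(self, mask: np.ndarray) -> "VariantMatrix":
        return VariantMatrix(
            chroms=self.chroms[mask],
            pos=self.pos[mask],
            ref=self.ref[mask],
            alt=self.alt[mask],
            parent1_call=self.parent1_call[mask],
            parent2_call=self.parent2_call[mask],
            mapping_quality=self.mapping_quality[mask],
            calls=self.calls[mask],
            depth=self.depth[mask],
            lines=list(self.lines),
            site_class=None if self.site_class is None else self.site_class[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        chars = np.array([GENO_CHARS[GENO_A], GENO_CHARS[GENO_H],
                          GENO_CHARS[GENO_B]])
        cols = {"chrom": self.chroms, "pos": self.pos}
        for j, line in enumerate(self.lines):
            cols[line] = np.where(self.calls[:, j] >= 0,
                                  chars[np.clip(self.calls[:, j], 0, 2)],
                                  GENO_CHARS[MISSING])
        return pd.DataFrame(cols)


@dataclass
class BinMarkerMatrix:
    """Ordered recombination-bin markers by individuals.

    Bins are physical intervals (1-based inclusive) within which no
    recombination is observed in any line; each is one genetic marker.
    """

    ids: list[str]                # "mk<i>" in genome order
    chroms: np.ndarray            # str per marker
    start: np.ndarray             # int64
    end: np.ndarray               # int64
    genotypes: np.ndarray         # int8 (n_markers, n_lines)
    lines: list[str] = field(default_factory=list)

    @property
    def n_markers(self) -> int:
        return len(self.ids)

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    def chromosome_names(self) -> list[str]:
        seen: list[str] = []
        for c in self.chroms:
            if c not in seen:
                seen.append(c)
        return seen

    def marker_index(self, marker_id: str) -> int:
        try:
            return self.ids.index(marker_id)
        except ValueError:
            raise KeyError(f"unknown marker id: {marker_id}") from None

    def subset(self, mask: np.ndarray) -> "BinMarkerMatrix":
        idx = np.flatnonzero(mask)
        return BinMarkerMatrix(
            ids=[self.ids[i] for i in idx],
            chroms=self.chroms[idx],
            start=self.start[idx],
            end=self.end[idx],
            genotypes=self.genotypes[idx],
            lines=list(self.lines),
        )

    def to_frame(self) -> pd.DataFrame:
        chars = np.array(["A", "H", "B"])
        cols = {
            "marker": self.ids,
            "chrom": self.chroms,
            "start": self.start,
            "end": self.end,
        }
        for j, line in enumerate(self.lines):
            g = self.genotypes[:, j]
            cols[line] = np.where(g >= 0, chars[np.clip(g, 0, 2)], "-")
        return pd.DataFrame(cols)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BinMarkerMatrix":
        lines = [c for c in df.columns
                 if c not in ("marker", "chrom", "start", "end")]
        geno = np.full((len(df), len(lines)), MISSING, dtype=np.int8)
        for j, line in enumerate(lines):
            col = df[line].to_numpy()
            for ch, code in CHAR_GENOS.items():
                geno[col == ch, j] = code
        return cls(
            ids=[str(m) for m in df["marker"]],
            chroms=df["chrom"].to_numpy(dtype=object),
            start=df["start"].to_numpy(dtype=np.int64),
            end=df["end"].to_numpy(dtype=np.int64),
            genotypes=geno,
            lines=lines,
        )

    @classmethod
    def read_tsv(cls, path) -> "BinMarkerMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype={"chrom": str}))
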