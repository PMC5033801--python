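"""Readers and writers for the standard interchange formats.

VCF v4.2 (GT:DP), tab-separated phenotype/count tables and GFF3 gene
annotation.  VCF reading goes through cyvcf2, GFF3 reading through
gffutils; all coordinates are 1-based inclusive in memory (BED output is
converted explicitly at the boundary).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import GENO_A, GENO_B, GENO_H, MISSING, VariantMatrix


def write_vcf(vm: VariantMatrix, path, parent1: str = "PYZX",
              parent2: str = "P02428", parent_depth: int = 25) -> None:
    """Write parents + RILs as a VCF v4.2 with GT:DP fields.

    Parent 1 carries the REF allele, parent 2 the ALT allele; RIL calls are
    emitted on the same allele scale (A -> 0/0, H -> 0/1, B -> 1/1).
    """
    gt = {GENO_A: "0/0", GENO_H: "0/1", GENO_B: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">\n')
        seen = []
        for c in vm.chroms:
            if c not in seen:
                seen.append(c)
        for c in seen:
            fh.write(f"##contig=<ID={c}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER",
                "INFO", "FORMAT", parent1, parent2] + list(vm.lines)
        fh.write("\t".join(cols) + "\n")
        for i in range(vm.n_sites):
            row = [str(vm.chroms[i]), str(int(vm.pos[i])), ".",
                   str(vm.ref[i]), str(vm.alt[i]), ".", "PASS",
                   f"MQ={vm.mapping_quality[i]:.2f}", "GT:DP",
                   f"0/0:{parent_depth}", f"1/1:{parent_depth}"]
            for j in range(vm.n_lines):
                code = int(vm.calls[i, j])
                dp = int(vm.depth[i, j])
                row.append(f"{gt[code]}:{dp}" if code != MISSING
                           else f"./.:{dp}")
            fh.write("\t".join(row) + "\n")


def read_vcf(path, parent1: str, parent2: str) -> VariantMatrix:
    """Load a biallelic-SNP VCF into a VariantMatrix.

    Calls are re-expressed as parental origin using the two parents'
    genotypes at each site; sites where either parent is missing keep the
    parents' raw calls so the classification stage can reject them.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    for p in (parent1, parent2):
        if p not in samples:
            raise ValueError(f"parent {p} not in VCF samples")
    i1, i2 = samples.index(parent1), samples.index(parent2)
    ril_idx = [k for k, s in enumerate(samples) if s not in (parent1, parent2)]
    lines = [samples[k] for k in ril_idx]

    chroms, pos, ref, alt, mq = [], [], [], [], []
    p1c, p2c = [], []
    calls_rows, depth_rows = [], []
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            continue
        gts = var.gt_types  # 0=hom-ref, 1=het, 2=hom-alt, 3=missing
        a_ref, a_alt = var.REF, var.ALT[0]

        def diploid(g):
            return {0: f"{a_ref}/{a_ref}", 1: f"{a_ref}/{a_alt}",
                    2: f"{a_alt}/{a_alt}", 3: "./."}[int(g)]

        chroms.append(var.CHROM)
        pos.append(var.POS)
        ref.append(a_ref)
        alt.append(a_alt)
        m = var.INFO.get("MQ")
        mq.append(float(m) if m is not None else 60.0)
        p1c.append(diploid(gts[i1]))
        p2c.append(diploid(gts[i2]))
        # parental-origin coding relative to the two parent alleles: the
        # parent-1 allele is A.  Only meaningful for aa x bb sites; others
        # are rejected downstream.
        p1_is_ref = gts[i1] == 0
        conv = {0: GENO_A if p1_is_ref else GENO_B, 1: GENO_H,
                2: GENO_B if p1_is_ref else GENO_A, 3: MISSING}
        calls_rows.append(np.array([conv[int(gts[k])] for k in ril_idx],
                                   dtype=np.int8))
        dp = var.format("DP")
        if dp is None:
            depth_rows.append(np.zeros(len(ril_idx), dtype=np.int32))
        else:
            d = dp.reshape(-1)
            depth_rows.append(np.array([max(int(d[k]), 0) for k in ril_idx],
                                       dtype=np.int32))
    return VariantMatrix(
        chroms=np.array(chroms, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        parent1_call=np.array(p1c, dtype=object),
        parent2_call=np.array(p2c, dtype=object),
        mapping_quality=np.array(mq, dtype=float),
        calls=np.vstack(calls_rows) if calls_rows else
        np.empty((0, len(ril_idx)), dtype=np.int8),
        depth=np.vstack(depth_rows) if depth_rows else
        np.empty((0, len(ril_idx)), dtype=np.int32),
        lines=lines,
    )


def write_phenotypes_tsv(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index=False)


def read_phenotypes_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_gff3(genes: pd.DataFrame, path,
               source: str = "chalkmap-sim") -> None:
    """Write gene models (1-based inclusive, as GFF3 requires)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            attrs = f"ID={g.gene_id};Name={g.gene_id}"
            fh.write("\t".join([
                str(g.chrom), source, "gene", str(int(g.start)),
                str(int(g.end)), ".", str(g.strand), ".", attrs,
            ]) + "\n")


def read_gff3_genes(path) -> pd.DataFrame:
    """Gene models from a GFF3 via gffutils (in-memory database)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    rows = []
    for feat in db.features_of_type("gene"):
        rows.append({
            "gene_id": feat.id, "chrom": feat.seqid,
            "start": int(feat.start), "end": int(feat.end),
            "strand": feat.strand,
        })
    return pd.DataFrame(rows)


def write_segments_bed(segments_by_line: dict, path) -> None:
    """Per-line genotype segments as BED (0-based half-open on output)."""
    with open(path, "w") as fh:
        for line, segs in segments_by_line.items():
            for s in segs:
                fh.write(f"{s.chrom}\t{s.start - 1}\t{s.end}\t"
                         f"{line}:{s.genotype_char}\t{s.n_snps}\n")
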