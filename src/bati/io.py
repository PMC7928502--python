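"""Cohort file formats: multi-sample VCF, annotation and phenotype TSV.

Reading goes through :mod:`cyvcf2`; multi-allelic records are split
into one biallelic record per alternate allele at load, with dosages
counting that allele only.  Writing emits minimal uncompressed VCF
v4.2 (GT-only) plus plain TSV tables so generated cohorts round-trip
through standard tooling.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import MISSING, Cohort

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}

VCF_NAME = "cohort.vcf"
ANNOTATION_NAME = "annotations.tsv"
PHENOTYPE_NAME = "phenotypes.tsv"


def write_vcf(cohort: Cohort, path) -> None:
    """Write biallelic genotypes as uncompressed VCF v4.2."""
    path = Path(path)
    samples = list(cohort.sample_ids)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=bati-simulator\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(cohort.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        V = cohort.variants
        G = cohort.genotypes
        for j in range(cohort.n_variants):
            gts = "\t".join(_GT_STRINGS[int(g)] for g in G[:, j])
            fh.write(
                f"{V['chrom'].iloc[j]}\t{V['pos'].iloc[j]}\t.\t"
                f"{V['ref'].iloc[j]}\t{V['alt'].iloc[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_annotations(cohort: Cohort, path) -> None:
    cohort.variants.to_csv(path, sep="\t", index=False)


def write_phenotypes(cohort: Cohort, path) -> None:
    cohort.samples.reset_index().to_csv(path, sep="\t", index=False)


def write_cohort(cohort: Cohort, out_dir) -> dict:
    """Write VCF + annotation TSV + phenotype TSV into a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out_dir / VCF_NAME,
        "annotations": out_dir / ANNOTATION_NAME,
        "phenotypes": out_dir / PHENOTYPE_NAME,
    }
    write_vcf(cohort, paths["vcf"])
    write_annotations(cohort, paths["annotations"])
    write_phenotypes(cohort, paths["phenotypes"])
    return {k: str(v) for k, v in paths.items()}


def _read_vcf(path) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    rows, cols = [], []
    for rec in vcf:
        alts = rec.ALT or []
        genos = rec.genotypes  # [a1, a2, phased] per sample
        for alt_idx, alt in enumerate(alts):
            allele = alt_idx + 1
            dos = np.empty(len(samples), dtype=np.int8)
            for si, g in enumerate(genos):
                a = g[:-1]
                if any(x < 0 for x in a):
                    dos[si] = MISSING
                else:
                    dos[si] = sum(1 for x in a if x == allele)
            rows.append((rec.CHROM, rec.POS, rec.REF, alt))
            cols.append(dos)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    G = (np.stack(cols, axis=1) if cols
         else np.empty((len(samples), 0), dtype=np.int8))
    return variants, G, samples


def load_cohort(vcf_path, annotation_path, phenotype_path) -> Cohort:
    """Assemble a :class:`Cohort` from VCF + annotation + phenotype files.

    Annotations are joined by (chrom, pos, ref, alt); a variant without
    an annotation row is an error naming the variant.  Samples present
    in the VCF but missing from the phenotype table are dropped with a
    warning; phenotype rows without a genotyped sample are an error.
    """
    variants, G, samples = _read_vcf(vcf_path)

    ann = pd.read_csv(annotation_path, sep="\t", dtype={"chrom": str})
    key = ["chrom", "pos", "ref", "alt"]
    for col in key:
        if col not in ann.columns:
            raise ValueError(f"annotation table lacks key column '{col}'")
    variants["chrom"] = variants["chrom"].astype(str)
    merged = variants.merge(ann, on=key, how="left", validate="one_to_one")
    if "gene" not in merged.columns:
        raise ValueError("annotation table lacks a 'gene' column")
    missing = merged.index[merged["gene"].isna()]
    if len(missing):
        names = [
            f"{merged['chrom'].iloc[i]}:{merged['pos'].iloc[i]}:"
            f"{merged['ref'].iloc[i]}:{merged['alt'].iloc[i]}"
            for i in missing[:5]
        ]
        raise ValueError(f"no annotation for variant(s): {names}")

    pheno = pd.read_csv(phenotype_path, sep="\t")
    if "sample" not in pheno.columns or "status" not in pheno.columns:
        raise ValueError("phenotype table needs 'sample' and 'status' columns")
    pheno = pheno.set_index("sample")
    unknown = [s for s in pheno.index if s not in samples]
    if unknown:
        raise ValueError(f"phenotype rows for unknown sample id(s): {unknown[:5]}")
    keep = [s for s in samples if s in pheno.index]
    dropped = [s for s in samples if s not in pheno.index]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} sample(s) without phenotype: {dropped[:5]}",
            RuntimeWarning,
        )
    idx = [samples.index(s) for s in keep]
    return Cohort(
        samples=pheno.loc[keep],
        variants=merged,
        genotypes=G[idx],
    )


def load_cohort_dir(directory) -> Cohort:
    d = Path(directory)
    return load_cohort(d / VCF_NAME, d / ANNOTATION_NAME, d / PHENOTYPE_NAME)
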