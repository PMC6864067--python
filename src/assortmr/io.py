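"""Cohort serialisation: minimal VCF + TSV dosage + CSV phenotype tables.

Genotypes are written twice — as a minimal VCF v4.2 (GT only, one sample per
individual, ALT = effect allele) and as a TSV dosage matrix (rows =
individuals, columns = variants, entries 0/1/2 effect-allele counts, empty
for missing).  ``read_cohort(write_cohort(c))`` reproduces every analysed
field exactly.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import pysam

from .errors import DataError
from .simulate import Cohort

FILENAMES = {
    "vcf": "genotypes.vcf",
    "dosage": "dosages.tsv",
    "phenotypes": "phenotypes.csv",
    "variants": "variants.tsv",
    "truth": "truth.csv",
}

_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(genotypes: pd.DataFrame, variants: pd.DataFrame, path) -> None:
    """Write a minimal VCF v4.2 with GT = count of ALT (= effect allele)."""
    samples = list(genotypes.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        order = variants.sort_values(["chrom", "pos"]).index
        for vid in order:
            v = variants.loc[vid]
            dos = genotypes[vid].to_numpy()
            gts = "\t".join("./." if np.isnan(d) else _GT[float(d)] for d in dos)
            fh.write(f"{v['chrom']}\t{int(v['pos'])}\t{vid}\t{v['ref']}\t{v['alt']}"
                     f"\t.\t.\t.\tGT\t{gts}\n")


def read_vcf(path) -> tuple:
    """Read a (possibly plain-text) VCF into (dosage DataFrame, variant meta).

    Dosage = ALT allele count; ``./.`` becomes NaN.  Malformed files raise
    :class:`DataError` carrying pysam's diagnostic.
    """
    try:
        vf = pysam.VariantFile(os.fspath(path))
        samples = list(vf.header.samples)
        rows, meta = [], []
        for rec in vf:
            dos = []
            for s in samples:
                alleles = rec.samples[s].allele_indices
                if alleles is None or any(a is None for a in alleles):
                    dos.append(np.nan)
                else:
                    dos.append(float(sum(alleles)))
            rows.append(dos)
            meta.append({
                "variant": rec.id,
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alts[0] if rec.alts else ".",
            })
    except (ValueError, OSError, NotImplementedError) as exc:
        raise DataError(f"malformed VCF {path}: {exc}") from exc
    if not rows:
        raise DataError(f"VCF {path} contains no variant records")
    meta_df = pd.DataFrame(meta).set_index("variant")
    dosage = pd.DataFrame(
        np.array(rows, dtype=float).T,
        index=pd.Index(samples, name="id"),
        columns=meta_df.index,
    )
    return dosage, meta_df


def write_dosage_tsv(genotypes: pd.DataFrame, path) -> None:
    out = genotypes.copy()
    out.index.name = "id"
    out.to_csv(path, sep="\t", na_rep="")


def read_dosage_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="id")
    arr = df.to_numpy(dtype=float)
    ok = np.isnan(arr) | np.isin(arr, (0.0, 1.0, 2.0))
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise DataError(
            f"invalid dosage {arr[i, j]!r} at line {i + 2} (individual {df.index[i]!r}, "
            f"variant {df.columns[j]!r}) in {path}: dosages must be 0/1/2 or missing"
        )
    return df.astype(float)


def write_cohort(cohort: Cohort, directory) -> dict:
    """Write a cohort to ``directory``; returns a name -> path mapping."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {k: directory / v for k, v in FILENAMES.items()}
    write_vcf(cohort.genotypes, cohort.variants, paths["vcf"])
    write_dosage_tsv(cohort.genotypes, paths["dosage"])
    cohort.individuals.to_csv(paths["phenotypes"])
    cohort.variants.to_csv(paths["variants"], sep="\t")
    if cohort.truth is not None and len(cohort.truth):
        cohort.truth.to_csv(paths["truth"], index=False)
    else:
        paths.pop("truth")
    return paths


def read_phenotypes(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, index_col="id")
    except (ValueError, pd.errors.ParserError) as exc:
        raise DataError(f"malformed phenotype CSV {path}: {exc}") from exc
    return df


def read_cohort(directory, genotypes_from: str = "vcf") -> Cohort:
    """Read a cohort written by :func:`write_cohort`.

    ``genotypes_from`` selects the VCF ("vcf") or the dosage TSV ("tsv") as
    the genotype source; both carry identical information.
    """
    directory = Path(directory)
    individuals = read_phenotypes(directory / FILENAMES["phenotypes"])
    variants = pd.read_csv(directory / FILENAMES["variants"], sep="\t",
                           index_col="variant", dtype={"chrom": str})
    if genotypes_from == "tsv":
        genotypes = read_dosage_tsv(directory / FILENAMES["dosage"])
    elif genotypes_from == "vcf":
        genotypes, _ = read_vcf(directory / FILENAMES["vcf"])
        genotypes = genotypes[list(variants.index)]
    else:
        raise DataError(f"genotypes_from must be 'vcf' or 'tsv', got {genotypes_from!r}")
    genotypes = genotypes.loc[individuals.index]
    truth_path = directory / FILENAMES["truth"]
    truth: Optional[pd.DataFrame] = None
    if truth_path.exists():
        truth = pd.read_csv(truth_path)
    else:
        truth = pd.DataFrame(columns=["couple_id", "id_a", "id_b", "mechanism",
                                      "duration", "dissolved", "decoy_class"])
    return Cohort(individuals=individuals, genotypes=genotypes,
                  variants=variants, truth=truth)
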