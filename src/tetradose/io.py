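"""Reading and writing the pipeline's tabular formats.

Canonical interchange is TSV: genotype matrices as samples (rows) x loci
(columns) with NA for missing, GRMs with a sample-id header row and column,
phenotypes as sample_id plus one column per trait.  VCF (with per-sample AD
allele-depth FORMAT fields, 1-based positions) is supported as ingest and as
an export of simulated read counts.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .genotyping import GenotypeMatrix, ReadCountMatrix
from .grm import GRM

__all__ = [
    "read_vcf_allele_depths",
    "write_vcf",
    "write_genotype_tsv",
    "read_genotype_tsv",
    "write_grm_tsv",
    "read_grm_tsv",
    "write_phenotypes_tsv",
    "read_phenotypes_tsv",
    "write_truth_tsv",
]

log = logging.getLogger("tetradose")


def read_vcf_allele_depths(path) -> tuple[ReadCountMatrix, int]:
    """Read per-sample ref/alt allele depths from a VCF.

    Only biallelic records are kept; multi-allelic records are skipped and
    counted (the count is returned and logged).  A missing AD entry ('.')
    yields counts (0, 0), which downstream code treats as missing depth.
    Raises if a biallelic record carries no AD field at all.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    loci, refs, alts = [], [], []
    chroms, poss = [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        ad = var.format("AD")
        if ad is None:
            raise ValueError(
                f"record {var.CHROM}:{var.POS} has no AD FORMAT field")
        ad = np.asarray(ad)
        ad = np.where(ad < 0, 0, ad)  # negative sentinels mark missing
        refs.append(ad[:, 0])
        alts.append(ad[:, 1])
        chroms.append(var.CHROM)
        poss.append(var.POS)
        loci.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
    vcf.close()
    if n_skipped:
        log.info("skipped %d non-biallelic VCF records", n_skipped)
    if not loci:
        raise ValueError(f"no biallelic records with AD found in {path}")
    locus_map = pd.DataFrame(
        {"chrom": [c for c, *_ in loci],
         "pos": [p for _, p, *_ in loci],
         "ref": [r for _, _, r, _ in loci],
         "alt": [a for *_, a in loci]},
        index=[f"{c}_{p}" for c, p, *_ in loci],
    )
    rcm = ReadCountMatrix(
        sample_ids=samples,
        locus_map=locus_map,
        ref_count=np.column_stack(refs).astype(np.int32),
        alt_count=np.column_stack(alts).astype(np.int32),
    )
    return rcm, n_skipped


def write_vcf(counts: ReadCountMatrix, path) -> Path:
    """Write read counts as a minimal VCF 4.2 with AD FORMAT fields.

    Genotype calls are left undetermined ('./.'); zero total depth is
    written as a missing AD entry ('.').
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lm = counts.locus_map
    valid = {"A", "C", "G", "T"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in pd.unique(lm["chrom"]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths (ref,alt)">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(counts.sample_ids) + "\n")
        depth = counts.depth
        for k, (locus, row) in enumerate(lm.iterrows()):
            ref = str(row["ref"]) if "ref" in lm.columns else "A"
            alt = str(row["alt"]) if "alt" in lm.columns else "T"
            # synthetic placeholders may not be valid bases
            if ref not in valid:
                ref = "A"
            if alt not in valid or alt == ref:
                alt = "T" if ref != "T" else "C"
            cells = []
            for i in range(counts.n_samples):
                if depth[i, k] == 0:
                    cells.append("./.:.")
                else:
                    cells.append(f"./.:{counts.ref_count[i, k]},{counts.alt_count[i, k]}")
            fh.write(f"{row['chrom']}\t{row['pos']}\t{locus}\t{ref}\t{alt}"
                     f"\t.\tPASS\t.\tGT:AD\t" + "\t".join(cells) + "\n")
    return path


def write_genotype_tsv(geno: GenotypeMatrix, path) -> Path:
    """Samples (rows) x loci (columns), NA for missing."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    geno.to_frame().to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")
    return path


def read_genotype_tsv(path, locus_map: pd.DataFrame | None = None,
                      encoding: str = "continuous") -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
    if locus_map is None:
        chrom = [c.split("_")[0] for c in df.columns]
        pos = [int(c.split("_")[1]) for c in df.columns]
        locus_map = pd.DataFrame({"chrom": chrom, "pos": pos}, index=df.columns)
    else:
        locus_map = locus_map.loc[df.columns]
    return GenotypeMatrix(
        sample_ids=list(df.index), locus_map=locus_map,
        values=df.to_numpy(dtype=float), encoding=encoding,
    )


def write_grm_tsv(grm: GRM, path) -> Path:
    """Symmetric matrix with a sample-id header row and column."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(grm.values, index=grm.sample_ids, columns=grm.sample_ids
                 ).to_csv(path, sep="\t", float_format="%.10g")
    return path


def read_grm_tsv(path, excluded_chromosome: str | None = None) -> GRM:
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy(dtype=float)
    # symmetrize away round-trip formatting error
    values = 0.5 * (values + values.T)
    return GRM(sample_ids=list(df.index), values=values,
               excluded_chromosome=excluded_chromosome)


def write_phenotypes_tsv(values: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    values.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")
    return path


def read_phenotypes_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values="NA")


def write_truth_tsv(truth, path) -> Path:
    """Long-format truth table: sample, locus, copy_number, alt_copies."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    S, L = truth.copy_number.shape
    df = pd.DataFrame({
        "sample_id": np.repeat(truth.sample_ids, L),
        "locus": np.tile(truth.locus_map.index.to_numpy(), S),
        "copy_number": truth.copy_number.ravel(),
        "alt_copies": truth.alt_copies.ravel(),
    })
    df.to_csv(path, sep="\t", index=False)
    return path
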