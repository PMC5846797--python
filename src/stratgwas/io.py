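"""File formats: dosage VCF/TSV, sample tables, summary stats, BED, config.

Internal coordinates are 1-based inclusive everywhere; conversion to BED's
0-based half-open convention happens only on write (and back on read), so a
round trip is the identity. Dosages travel either as a VCF 4.2 file with a
per-sample ``DS`` FORMAT field (read back through cyvcf2) or as a plain
variants-by-samples TSV matrix.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "write_dosage_vcf",
    "read_dosage_vcf",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_sample_table",
    "read_sample_table",
    "read_known_loci",
    "read_gene_table",
    "write_bed",
    "read_bed",
]

SAMPLE_COLUMNS = ["sample_id", "status", "age", "sex", "pc1", "pc2", "wga"]

_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">
##INFO=<ID=EAF,Number=1,Type=Float,Description="Effect (ALT) allele frequency">
"""


def write_dosage_vcf(
    path: str | Path,
    variants: pd.DataFrame,
    dosages: np.ndarray,
    sample_ids: list[str],
) -> None:
    """Write a VCF 4.2 with the effect allele as ALT and a DS FORMAT field."""
    path = Path(path)
    n_var, n_samp = dosages.shape
    if len(sample_ids) != n_samp:
        raise ValueError("sample ids do not match dosage matrix columns")
    with path.open("w") as fh:
        fh.write(_VCF_HEADER)
        contigs = variants["chr"].astype(str).unique()
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for i, row in enumerate(variants.itertuples()):
            eaf = float(dosages[i].mean() / 2.0)
            ds = "\t".join(f"{d:.3f}" for d in dosages[i])
            fh.write(
                f"{row.chr}\t{row.pos}\t{row.variant_id}\t{row.oa}\t{row.ea}\t.\t.\t"
                f"EAF={eaf:.4f}\tDS\t{ds}\n"
            )


def read_dosage_vcf(path: str | Path) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Read a dosage VCF (DS FORMAT field; ALT is the effect allele).

    Unsorted input is accepted and sorted internally with a warning.
    Returns (variants frame, dosage matrix, sample ids).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    recs, doses = [], []
    for var in vcf:
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is None:
            raise ValueError(f"record {var.ID or var.POS} lacks a DS FORMAT field")
        recs.append(
            (var.ID, str(var.CHROM), int(var.POS), var.ALT[0], var.REF)
        )
        doses.append(np.asarray(ds, dtype=float).ravel())
    vcf.close()
    variants = pd.DataFrame(recs, columns=["variant_id", "chr", "pos", "ea", "oa"])
    dosages = np.vstack(doses) if doses else np.empty((0, len(sample_ids)))
    order = variants.sort_values(["chr", "pos"], kind="mergesort").index.to_numpy()
    if not np.array_equal(order, np.arange(len(variants))):
        logger.warning("VCF %s was not coordinate-sorted; sorting internally", path)
        variants = variants.iloc[order].reset_index(drop=True)
        dosages = dosages[order]
    return variants, dosages, sample_ids


def write_dosage_tsv(
    path: str | Path,
    variants: pd.DataFrame,
    dosages: np.ndarray,
    sample_ids: list[str],
) -> None:
    """Write a variants-by-samples dosage matrix as TSV."""
    meta = variants[["variant_id", "chr", "pos", "ea", "oa"]].reset_index(drop=True)
    mat = pd.DataFrame(np.asarray(dosages, dtype=float), columns=sample_ids)
    pd.concat([meta, mat], axis=1).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_dosage_tsv(path: str | Path) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Read a TSV dosage matrix written by :func:`write_dosage_tsv`."""
    df = pd.read_csv(path, sep="\t", dtype={"chr": str})
    meta_cols = ["variant_id", "chr", "pos", "ea", "oa"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise ValueError(f"dosage TSV {path} lacks columns {missing}")
    sample_ids = [c for c in df.columns if c not in meta_cols]
    variants = df[meta_cols].copy()
    dosages = df[sample_ids].to_numpy(dtype=float)
    return variants, dosages, sample_ids


def write_sample_table(path: str | Path, samples: pd.DataFrame) -> None:
    """Write the sample/phenotype table (fixed 7-column schema)."""
    samples[SAMPLE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Read a sample table; validates the schema and status coding."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "sex": str})
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample table {path} lacks columns {missing}")
    if not set(df["status"].unique()) <= {0, 1}:
        raise ValueError("status must be coded 0 (control) / 1 (case)")
    return df


def align_samples(
    dosages: np.ndarray, geno_ids: list[str], samples: pd.DataFrame
) -> tuple[np.ndarray, pd.DataFrame]:
    """Align dosage columns with the sample table by id.

    Errors list the symmetric difference when the two sources disagree.
    """
    pheno_ids = samples["sample_id"].tolist()
    only_g = sorted(set(geno_ids) - set(pheno_ids))
    only_p = sorted(set(pheno_ids) - set(geno_ids))
    if only_g or only_p:
        raise ValueError(
            "genotype/phenotype sample mismatch; only in genotypes: "
            f"{only_g[:5]}{'...' if len(only_g) > 5 else ''}, only in phenotypes: "
            f"{only_p[:5]}{'...' if len(only_p) > 5 else ''}"
        )
    order = [geno_ids.index(s) for s in pheno_ids]
    return dosages[:, order], samples.reset_index(drop=True)


def read_known_loci(path: str | Path) -> pd.DataFrame:
    """Read the known-loci table: TSV with ``rsid, chr, pos`` (1-based)."""
    df = pd.read_csv(path, sep="\t", dtype={"chr": str})
    missing = [c for c in ("rsid", "chr", "pos") if c not in df.columns]
    if missing:
        raise ValueError(f"known-loci table {path} lacks columns {missing}")
    return df


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Read gene annotation: TSV with ``gene, chr, start, end`` (1-based)."""
    df = pd.read_csv(path, sep="\t", dtype={"chr": str})
    missing = [c for c in ("gene", "chr", "start", "end") if c not in df.columns]
    if missing:
        raise ValueError(f"gene table {path} lacks columns {missing}")
    return df


def write_bed(path: str | Path, intervals: pd.DataFrame) -> None:
    """Write 1-based inclusive intervals (chr, start, end, name) as BED.

    BED is 0-based half-open, so start becomes ``start - 1``.
    """
    out = intervals.copy()
    out["start"] = out["start"].astype(int) - 1
    out["end"] = out["end"].astype(int)
    cols = ["chr", "start", "end"] + (["name"] if "name" in out.columns else [])
    out[cols].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED back into 1-based inclusive intervals."""
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    df = df.rename(columns={0: "chr", 1: "start", 2: "end", 3: "name"})
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    return df
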