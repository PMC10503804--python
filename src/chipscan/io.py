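"""Readers and writers for the pipeline's on-disk formats.

Everything is tab-delimited text except genotypes, which can also be VCF
(read through :mod:`cyvcf2`, using the ``DS`` FORMAT field when present and
falling back to hard-call genotypes).  Column contracts:

summary statistics
    ``gene_id chrom pos effect_allele other_allele eaf beta se pvalue n tss``
dosage TSV
    header ``sample_id <variant_id> ...`` plus four leading metadata rows
    (``#chrom``, ``#pos``, ``#counted_allele``, ``#other_allele``)
expression TSV
    ``sample_id <gene_id> ...``
CHIP calls TSV
    ``sample_id gene protein_change vaf``
phenotypes TSV
    ``sample_id age sex ancestry bmi smoker t2d pc1..pc10 follow_time event``
    (plus any quantitative-trait columns)
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .containers import DosageMatrix

SUMSTAT_COLUMNS = [
    "gene_id", "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n", "tss",
]


# ---------------------------------------------------------------- summary stats

def write_sumstats(df: pd.DataFrame, path: str) -> None:
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary statistics missing columns: {missing}")
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_sumstats(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary statistics at {path} missing columns: {missing}")
    return df


# ---------------------------------------------------------------------- dosages

def write_dosage_tsv(dm: DosageMatrix, path: str) -> None:
    """Dosage TSV: 4 commented metadata rows, then one row per sample."""
    with open(path, "w") as fh:
        ids = dm.variants["variant_id"].tolist()
        fh.write("sample_id\t" + "\t".join(ids) + "\n")
        for key in ("chrom", "pos", "counted_allele", "other_allele"):
            vals = dm.variants[key].astype(str).tolist()
            fh.write(f"#{key}\t" + "\t".join(vals) + "\n")
        for i, sid in enumerate(dm.sample_ids):
            row = dm.values[i]
            fh.write(sid + "\t" + "\t".join(
                "NA" if np.isnan(x) else format(x, ".6g") for x in row) + "\n")


def read_dosage_tsv(path: str) -> DosageMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        variant_ids = header[1:]
        meta = {}
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            fields = line.rstrip("\n").split("\t")
            meta[fields[0][1:]] = fields[1:]
            pos = fh.tell()
        body = pd.read_csv(fh, sep="\t", header=None, na_values=["NA"])
    sample_ids = body.iloc[:, 0].astype(str).tolist()
    values = body.iloc[:, 1:].to_numpy(dtype=float)
    variants = pd.DataFrame({
        "variant_id": variant_ids,
        "chrom": meta.get("chrom", ["1"] * len(variant_ids)),
        "pos": [int(p) for p in meta["pos"]],
        "counted_allele": meta["counted_allele"],
        "other_allele": meta["other_allele"],
    })
    return DosageMatrix(sample_ids=sample_ids, variants=variants, values=values)


def write_vcf(dm: DosageMatrix, path: str) -> None:
    """Minimal VCF 4.2 with GT (rounded dosage) and DS FORMAT fields.

    1-based positions; REF is the non-counted allele, ALT the counted allele,
    so that DS counts ALT copies (the usual dosage convention).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        chroms = dict.fromkeys(dm.variants["chrom"].astype(str))
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(dm.sample_ids) + "\n")
        for j, rec in dm.variants.iterrows():
            ds = dm.values[:, j]
            cells = []
            for x in ds:
                if np.isnan(x):
                    cells.append("./.:.")
                else:
                    g = int(round(x))
                    gt = ("0/0", "0/1", "1/1")[min(max(g, 0), 2)]
                    cells.append(f"{gt}:{x:.3f}")
            fh.write(f"{rec['chrom']}\t{rec['pos']}\t{rec['variant_id']}\t"
                     f"{rec['other_allele']}\t{rec['counted_allele']}\t.\t.\t.\t"
                     "GT:DS\t" + "\t".join(cells) + "\n")


def read_vcf(path: str) -> DosageMatrix:
    """Read genotypes from VCF via cyvcf2; ALT is the counted allele."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    rows, meta = [], []
    for var in vcf:
        alt = var.ALT[0] if var.ALT else "."
        vid = var.ID or f"{var.CHROM}:{var.POS}:{var.REF}:{alt}"
        try:
            ds = np.asarray(var.format("DS"), dtype=float).reshape(-1)
        except (KeyError, TypeError, ValueError):
            gts = np.asarray(var.gt_types)  # 0=hom ref,1=het,2=hom alt,3=missing
            ds = np.where(gts == 3, np.nan, np.where(gts == 2, 2.0, gts)).astype(float)
        rows.append(ds)
        meta.append((vid, var.CHROM, var.POS, alt, var.REF))
    variants = pd.DataFrame(meta, columns=["variant_id", "chrom", "pos",
                                           "counted_allele", "other_allele"])
    return DosageMatrix(sample_ids=sample_ids, variants=variants,
                        values=np.column_stack(rows) if rows else np.empty((len(sample_ids), 0)))


def read_genotypes(path: str) -> DosageMatrix:
    """Dispatch on extension: ``.vcf``/``.vcf.gz`` via cyvcf2, else dosage TSV."""
    base = path.lower()
    if base.endswith(".vcf") or base.endswith(".vcf.gz"):
        return read_vcf(path)
    return read_dosage_tsv(path)


# --------------------------------------------------------------- simple tables

def write_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
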