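"""Reading and writing cohort files.

Genotypes travel as uncompressed VCF 4.2 (FORMAT: GT, DP, GQ, AD) written
and read with pysam; annotations, phenotypes and the truth table are TSVs
with headers. X-male alternate calls are written hemizygous (a single
allele in GT) and read back as dosage 2.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .simulate import GenotypeMatrix, SimulatedCohort

_INFO_FLOAT_FIELDS = (
    ("FS", "Fisher strand bias score"),
    ("MQ", "RMS mapping quality"),
    ("RPRS", "Read position rank sum"),
    ("MQRS", "Mapping quality rank sum"),
)

_INFO_KEY_TO_COLUMN = {"FS": "fs", "MQ": "mq", "RPRS": "rprs", "MQRS": "mqrs"}


def write_cohort(
    samples: pd.DataFrame,
    variants: pd.DataFrame,
    genotypes: GenotypeMatrix,
    out_prefix: str | Path,
    truth: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Emit VCF + annotation TSV + phenotype TSV (+ truth TSV).

    Returns the written paths keyed ``vcf`` / ``annotations`` /
    ``phenotypes`` / ``truth``. A round-trip read reproduces dosages
    exactly.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out_prefix.with_suffix(".vcf"),
        "annotations": Path(str(out_prefix) + ".annotations.tsv"),
        "phenotypes": Path(str(out_prefix) + ".phenotypes.tsv"),
    }
    try:
        write_vcf(paths["vcf"], samples, variants, genotypes)
    except OSError as exc:
        raise OSError(f"failed writing VCF to {paths['vcf']}: {exc}") from exc
    variants.to_csv(paths["annotations"], sep="\t", index=False)
    samples.to_csv(paths["phenotypes"], sep="\t", index=False)
    if truth is not None:
        paths["truth"] = Path(str(out_prefix) + ".truth.tsv")
        truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def write_vcf(path, samples: pd.DataFrame, variants: pd.DataFrame, genotypes: GenotypeMatrix) -> None:
    header = pysam.VariantHeader()
    for chrom in pd.unique(variants["chrom"].astype(str)):
        header.contigs.add(chrom)
    for key, desc in _INFO_FLOAT_FIELDS:
        header.info.add(key, 1, "Float", desc)
    header.info.add("GENE", 1, "String", "Gene symbol")
    header.info.add("CSQ", 1, "String", "Consequence term")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    sample_ids = samples["sample_id"].tolist()
    for sid in sample_ids:
        header.add_sample(sid)

    is_male = (samples["sex"] == "male").to_numpy()
    on_x = variants["chrom"].astype(str).str.upper().isin(["X", "CHRX"]).to_numpy()
    dosage = genotypes.dosage
    have_metrics = genotypes.dp is not None

    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j in range(len(variants)):
            row = variants.iloc[j]
            rec = vcf.new_record(
                contig=str(row["chrom"]),
                start=int(row["pos"]) - 1,
                stop=int(row["pos"]) - 1 + len(str(row["ref"])),
                alleles=(str(row["ref"]), str(row["alt"])),
            )
            rec.id = f"{row['chrom']}-{row['pos']}-{row['ref']}-{row['alt']}"
            qual = row.get("qual")
            rec.qual = None if qual is None or (isinstance(qual, float) and math.isnan(qual)) else float(qual)
            status = row.get("filter_status", "PASS")
            rec.filter.add(str(status) if status else "PASS")
            for key, col in _INFO_KEY_TO_COLUMN.items():
                value = row.get(col)
                if value is not None and not (isinstance(value, float) and math.isnan(value)):
                    rec.info[key] = round(float(value), 4)
            rec.info["GENE"] = str(row["gene"])
            rec.info["CSQ"] = str(row["consequence"])
            hemi_col = on_x[j] & is_male
            for i, sid in enumerate(sample_ids):
                d = int(dosage[i, j])
                call = rec.samples[sid]
                if d < 0:
                    call["GT"] = (None,) if hemi_col[i] else (None, None)
                elif hemi_col[i]:
                    call["GT"] = (1,) if d == 2 else (0,)
                else:
                    call["GT"] = (1, 1) if d == 2 else ((0, 1) if d == 1 else (0, 0))
                if have_metrics:
                    dp = int(genotypes.dp[i, j])
                    ad_alt = int(genotypes.ad_alt[i, j])
                    call["DP"] = dp
                    call["GQ"] = int(genotypes.gq[i, j])
                    call["AD"] = (dp - ad_alt, ad_alt)
            vcf.write(rec)


def read_vcf(path, sex: pd.Series | np.ndarray | None = None):
    """Read a cohort VCF back into arrays.

    Returns ``(variants, genotypes)`` where ``variants`` carries the
    columns stored in the VCF (chrom, pos, ref, alt, gene, consequence,
    qual, filter_status, fs, mq, rprs, mqrs) and ``genotypes`` is a
    :class:`GenotypeMatrix` (phased truth unavailable: ``a1``/``a2`` are
    zeros). A single-allele GT (hemizygous) maps to dosage 0 or 2.
    """
    rows = []
    dosage_cols, dp_cols, gq_cols, ad_cols = [], [], [], []
    with pysam.VariantFile(str(path)) as vcf:
        sample_ids = list(vcf.header.samples)
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            rows.append(
                {
                    "chrom": rec.contig,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0] if rec.alts else ".",
                    "gene": rec.info.get("GENE", ""),
                    "consequence": rec.info.get("CSQ", ""),
                    "qual": rec.qual,
                    "filter_status": next(iter(rec.filter), "PASS"),
                    "fs": rec.info.get("FS"),
                    "mq": rec.info.get("MQ"),
                    "rprs": rec.info.get("RPRS"),
                    "mqrs": rec.info.get("MQRS"),
                }
            )
            dos = np.empty(len(sample_ids), dtype=np.int8)
            dp = np.zeros(len(sample_ids), dtype=np.int16)
            gq = np.zeros(len(sample_ids), dtype=np.int16)
            ad = np.zeros(len(sample_ids), dtype=np.int16)
            for i, sid in enumerate(sample_ids):
                call = rec.samples[sid]
                gt = call.get("GT")
                if gt is None or all(a is None for a in gt):
                    dos[i] = -1
                elif len(gt) == 1:
                    dos[i] = 2 if gt[0] else 0  # hemizygous
                else:
                    dos[i] = sum(1 for a in gt if a)
                if call.get("DP") is not None:
                    dp[i] = call["DP"]
                if call.get("GQ") is not None:
                    gq[i] = call["GQ"]
                advals = call.get("AD")
                if advals is not None and len(advals) == 2 and advals[1] is not None:
                    ad[i] = advals[1]
            dosage_cols.append(dos)
            dp_cols.append(dp)
            gq_cols.append(gq)
            ad_cols.append(ad)
    variants = pd.DataFrame(rows)
    n, m = len(sample_ids), len(rows)
    dosage = np.column_stack(dosage_cols) if m else np.zeros((n, 0), dtype=np.int8)
    genotypes = GenotypeMatrix(
        dosage=dosage.astype(np.int8),
        a1=np.zeros_like(dosage, dtype=np.int8),
        a2=np.zeros_like(dosage, dtype=np.int8),
        dp=np.column_stack(dp_cols) if m else None,
        gq=np.column_stack(gq_cols) if m else None,
        ad_alt=np.column_stack(ad_cols) if m else None,
    )
    return variants, genotypes, sample_ids


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


__all__ = ["read_table", "read_vcf", "write_cohort", "write_vcf"]
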