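"""Reading and writing the pipeline's file formats.

Per-sample variant calls travel as single-sample VCF 4.2 with a
``GT:AD:DP:GQ`` FORMAT; manifests, diagnoses, truth and driver-candidate
tables are tab-separated with headers.  VCF parsing goes through cyvcf2;
multiallelic records are decomposed into one row per ALT allele.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

log = logging.getLogger(__name__)

__all__ = [
    "write_sample_vcf",
    "write_cohort",
    "read_sample_vcf",
    "read_cohort",
    "read_manifest",
    "read_diagnoses",
]

_VCF_HEADER = """\
##fileformat=VCFv4.2
##FILTER=<ID=Low_QD,Description="Low quality by depth">
##FILTER=<ID=LowQual,Description="Low quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
"""


def write_sample_vcf(sample_table: pd.DataFrame, sample_id: str, path) -> Path:
    """Write one sample's variant rows as a sorted single-sample VCF."""
    path = Path(path)
    tab = sample_table.sort_values(["chrom", "pos"], kind="mergesort")
    contigs = pd.unique(tab["chrom"].astype(str))
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample_id}\n")
        cols = zip(tab["chrom"].astype(str), tab["pos"], tab["ref"].astype(str),
                   tab["alt"].astype(str), tab["filter"].astype(str),
                   tab["depth"], tab["alt_reads"], tab["gq"])
        for chrom, pos, ref, alt, filt, dp, ad, gq in cols:
            ref_reads = int(dp) - int(ad)
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t{filt}\t.\t"
                     f"GT:AD:DP:GQ\t0/1:{ref_reads},{int(ad)}:{int(dp)}:{int(gq)}\n")
    return path


def write_cohort(cohort, out_dir) -> Path:
    """Write a SimulatedCohort: one VCF per sample plus the TSV side tables."""
    out = Path(out_dir)
    vcf_dir = out / "vcf"
    vcf_dir.mkdir(parents=True, exist_ok=True)
    for sid, grp in cohort.variants.groupby("sample_id", observed=True):
        write_sample_vcf(grp, str(sid), vcf_dir / f"{sid}.vcf")
    cohort.manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    cohort.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    cohort.diagnoses.to_csv(out / "diagnoses.tsv", sep="\t", index=False)
    cohort.drivers.to_csv(out / "drivers.tsv", sep="\t", index=False)
    return out


def read_sample_vcf(path) -> pd.DataFrame:
    """Parse one single-sample VCF into variant rows.

    Multiallelic records are decomposed: one row per ALT allele, with that
    allele's AD as alt_reads.  Records missing AD, DP or GQ are kept but
    flagged (``flagged=True``) and are excluded from filtering downstream,
    with a logged count.
    """
    vcf = VCF(str(path))
    if len(vcf.samples) != 1:
        raise ValueError(f"{path}: expected a single-sample VCF, "
                         f"got samples {vcf.samples}")
    sample_id = vcf.samples[0]
    rows = []
    n_flagged = 0
    for rec in vcf:
        try:
            ad = rec.format("AD")
            dp = rec.format("DP")
            gq = rec.format("GQ")
        except KeyError:
            ad = dp = gq = None
        missing = ad is None or dp is None or gq is None
        depth = int(dp[0][0]) if not missing else 0
        gq_val = float(gq[0][0]) if not missing else -1.0
        if not missing and (depth < 0 or gq_val < 0):
            missing = True
        filt = rec.FILTER or "PASS"  # cyvcf2 reports PASS as None
        for i, alt in enumerate(rec.ALT):
            if missing or ad.shape[1] < i + 2:
                n_flagged += 1
                rows.append((sample_id, rec.CHROM, rec.POS, rec.REF, alt,
                             max(depth, 1), 0, -1.0, filt, True))
                continue
            rows.append((sample_id, rec.CHROM, rec.POS, rec.REF, alt,
                         depth, int(ad[0][i + 1]), gq_val, filt, False))
    if n_flagged:
        log.warning("%s: %d ALT records missing AD/DP/GQ were flagged", path, n_flagged)
    return pd.DataFrame(rows, columns=[
        "sample_id", "chrom", "pos", "ref", "alt", "depth", "alt_reads",
        "gq", "filter", "flagged"])


def read_cohort(paths, manifest: pd.DataFrame) -> pd.DataFrame:
    """Read and concatenate per-sample VCFs; every sample must be in the manifest."""
    known = set(manifest["sample_id"])
    frames = []
    for path in paths:
        tab = read_sample_vcf(path)
        if len(tab):
            sid = tab["sample_id"].iloc[0]
            if sid not in known:
                raise ValueError(f"sample {sid!r} from {path} absent from manifest")
        frames.append(tab)
    if not frames:
        return pd.DataFrame(columns=[
            "sample_id", "chrom", "pos", "ref", "alt", "depth", "alt_reads",
            "gq", "filter", "flagged"])
    return pd.concat(frames, ignore_index=True)


def read_manifest(path) -> pd.DataFrame:
    manifest = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "center", "platform"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return manifest


def read_diagnoses(path) -> pd.DataFrame:
    dx = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "icd10": str})
    required = {"sample_id", "icd10", "date_offset_days"}
    missing = required - set(dx.columns)
    if missing:
        raise ValueError(f"diagnoses table missing columns: {sorted(missing)}")
    return dx
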