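"""Readers and writers for the pipeline's file formats.

Conventions:

* VCF v4.2 (via pysam): diploid GT "0/0"/"0/1"/"1/1", hemizygous calls as
  haploid GT "0"/"1", missing "./.".  SV alleles are symbolic ALTs; the
  custom INFO key ``GCN`` carries the per-allele gene->haploid-copy map as
  ``ALLELE:gene=copies,gene=copies|ALLELE:...`` (reference allele included);
  ``VARCLASS`` carries the variant class, ``END`` the SV span end.
* AIRR Rearrangement TSV: sequence_id, sample_id, c_call, v_call, d_call,
  j_call, junction_length, duplicate_count, clone_id.
* Covariates CSV: sample_id, age, platform.
* Features BED: chrom, start, end, name (name = feature class label).
* GWAS TSV: NHGRI-EBI export column names by default.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .enrichment import FeatureInterval
from .variants import HEMI, MISSING, GenotypeMatrix, VariantRecord

AIRR_REQUIRED = ("sequence_id", "sample_id", "c_call", "v_call", "d_call", "j_call", "clone_id")
AIRR_COLUMNS = AIRR_REQUIRED[:6] + ("junction_length", "duplicate_count", "clone_id")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _gcn_encode(gene_cn: dict[str, dict[str, int]]) -> str:
    return "|".join(
        f"{allele}:" + ",".join(f"{g}={c}" for g, c in sorted(cn.items()))
        for allele, cn in gene_cn.items()
    )


def _gcn_decode(s: str) -> dict[str, dict[str, int]]:
    out: dict[str, dict[str, int]] = {}
    for part in s.split("|"):
        allele, _, body = part.partition(":")
        out[allele] = {
            g: int(c) for g, c in (kv.split("=") for kv in body.split(",") if kv)
        }
    return out


def write_vcf(matrix: GenotypeMatrix, path, contig: str = "igh", contig_length: int = 1_300_000):
    hdr = pysam.VariantHeader()
    hdr.add_line(f"##contig=<ID={contig},length={contig_length}>")
    hdr.add_line('##INFO=<ID=VARCLASS,Number=1,Type=String,Description="Variant class">')
    hdr.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="SV span end">')
    hdr.add_line(
        '##INFO=<ID=GCN,Number=1,Type=String,'
        'Description="Per-allele gene to haploid copy number map">'
    )
    hdr.add_line('##INFO=<ID=CSV,Number=1,Type=String,Description="Containing SV id">')
    hdr.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in matrix.samples:
        hdr.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=hdr) as vf:
        for j, v in enumerate(matrix.variants):
            stop = v.span[1] if v.span else v.position
            rec = vf.new_record(
                contig=contig, start=v.position - 1, stop=stop, alleles=v.alleles, id=v.id
            )
            rec.info["VARCLASS"] = v.var_class
            if v.gene_cn is not None:
                rec.info["GCN"] = _gcn_encode(v.gene_cn)
            if v.containing_sv is not None:
                rec.info["CSV"] = v.containing_sv
            for i, s in enumerate(matrix.samples):
                a1, a2 = int(matrix.a1[i, j]), int(matrix.a2[i, j])
                if a1 == MISSING:
                    rec.samples[s]["GT"] = (None, None)
                elif a2 == HEMI:
                    rec.samples[s]["GT"] = (a1,)
                else:
                    rec.samples[s]["GT"] = (a1, a2)
            vf.write(rec)


def read_vcf(path) -> GenotypeMatrix:
    """Read a locus VCF back into a genotype matrix.  Haploid GT -> hemizygous;
    ./. -> missing; malformed rows are collected and reported together."""
    errors = []
    records: list[VariantRecord] = []
    a1_rows, a2_rows = [], []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            try:
                var_class = rec.info.get("VARCLASS", "SNV")
                gcn = rec.info.get("GCN")
                span = None
                if var_class in ("SV", "COMPLEX_SV", "MSV") and rec.stop > rec.start + 1:
                    span = (rec.start + 1, rec.stop)
                if rec.id is None:
                    raise ValueError("missing variant id")
                records.append(
                    VariantRecord(
                        id=rec.id,
                        position=rec.start + 1,
                        var_class=var_class,
                        alleles=tuple(rec.alleles),
                        containing_sv=rec.info.get("CSV"),
                        span=span,
                        gene_cn=_gcn_decode(gcn) if gcn else None,
                    )
                )
            except Exception as exc:  # collected, not silently dropped
                errors.append(f"{rec.contig}:{rec.pos}: {exc}")
                continue
            a1 = np.full(len(samples), MISSING, dtype=np.int16)
            a2 = np.full(len(samples), MISSING, dtype=np.int16)
            for i, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is None or all(g is None for g in gt):
                    continue
                gt = tuple(g for g in gt if g is not None)
                if len(gt) == 1:
                    a1[i], a2[i] = gt[0], HEMI
                else:
                    a1[i], a2[i] = gt[0], gt[1]
            a1_rows.append(a1)
            a2_rows.append(a2)
    if errors:
        raise ValueError("malformed VCF rows:\n" + "\n".join(errors))
    return GenotypeMatrix(
        samples=samples,
        variants=records,
        a1=np.column_stack(a1_rows) if a1_rows else np.zeros((len(samples), 0), np.int16),
        a2=np.column_stack(a2_rows) if a2_rows else np.zeros((len(samples), 0), np.int16),
    )


# ---------------------------------------------------------------------------
# AIRR Rearrangement TSV
# ---------------------------------------------------------------------------


def write_airr(clones: pd.DataFrame, path):
    cols = [c for c in AIRR_COLUMNS if c in clones.columns]
    clones[cols].to_csv(path, sep="\t", index=False)


def read_airr(path, log: list | None = None) -> pd.DataFrame:
    """Read an AIRR Rearrangement TSV.  Rows lacking v_call or clone_id are
    dropped (counted into ``log``); a missing duplicate_count column defaults
    to 1 per row with a warning entry."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = [c for c in AIRR_REQUIRED if c not in df.columns and c != "clone_id"]
    if "clone_id" not in df.columns:
        missing_cols.append("clone_id")
    if missing_cols:
        raise ValueError(f"AIRR file {path} lacks required columns: {missing_cols}")
    n0 = len(df)
    df = df[df["v_call"].notna() & (df["v_call"] != "")]
    df = df[df["clone_id"].notna() & (df["clone_id"] != "")]
    dropped = n0 - len(df)
    if log is not None and dropped:
        log.append(f"{path}: dropped {dropped} rows with empty v_call/clone_id")
    if "duplicate_count" not in df.columns:
        if log is not None:
            log.append(f"{path}: no duplicate_count column; defaulting to 1")
        df["duplicate_count"] = 1
    df["duplicate_count"] = pd.to_numeric(df["duplicate_count"]).astype(int)
    if "junction_length" in df.columns:
        df["junction_length"] = pd.to_numeric(df["junction_length"]).astype(int)
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Covariates, BED, GWAS
# ---------------------------------------------------------------------------


def write_covariates(cov: pd.DataFrame, path):
    cov.to_csv(path, index=True)


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="sample_id")
    for col in ("age", "platform"):
        if col not in df.columns:
            raise ValueError(f"covariates file lacks column {col!r}")
    df["age"] = pd.to_numeric(df["age"])
    return df


def read_bed(path, source: str = "") -> list[FeatureInterval]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: BED needs chrom/start/end/name")
            out.append(
                FeatureInterval(
                    chrom=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    feature_class=parts[3],
                    source=source,
                )
            )
    return out


def read_gwas(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


# ---------------------------------------------------------------------------
# Cohort bundle
# ---------------------------------------------------------------------------


def write_cohort(cohort, out_dir, clones: pd.DataFrame | None = None):
    """Write a simulated cohort: VCF, per-sample AIRR TSVs, covariates CSV and
    the ground-truth registry JSON.  Files round-trip through the readers."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_vcf(
        cohort.genotypes, out / "cohort.vcf",
        contig=cohort.model.contig, contig_length=cohort.model.locus_length,
    )
    write_covariates(cohort.covariates, out / "covariates.csv")
    with open(out / "truth.json", "w") as fh:
        json.dump(cohort.truth_registry(), fh, indent=1)
    if clones is not None:
        airr_dir = out / "airr"
        airr_dir.mkdir(exist_ok=True)
        for sample, sub in clones.groupby("sample_id", sort=False):
            write_airr(sub, airr_dir / f"{sample}.tsv")
    return out


def read_cohort_clones(out_dir) -> pd.DataFrame:
    airr_dir = Path(out_dir) / "airr"
    frames = [read_airr(p) for p in sorted(airr_dir.glob("*.tsv"))]
    if not frames:
        raise FileNotFoundError(f"no AIRR tables under {airr_dir}")
    return pd.concat(frames, ignore_index=True)
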