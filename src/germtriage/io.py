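"""Readers and writers for the pipeline's file dialects.

Formats: VCF v4.x for per-patient variant calls (via pysam), flat TSVs
for annotations, transcripts, phenotypes, control summaries, and the
classified output. Empty TSV cells encode absent evidence. Write/read
round-trips reproduce records exactly.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
import pysam

from .models import (
    NOT_LISTED,
    ControlSummary,
    EvidenceBundle,
    GenomicVariant,
    PatientRecord,
    TranscriptModel,
)


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class VcfParseError(ValueError):
    """A VCF header or record could not be parsed."""


class SampleMappingError(KeyError):
    """A VCF sample is not present in the supplied sample map."""


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _opt_float(value, column: str, row: int) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if s == "":
        return None
    try:
        return float(s)
    except ValueError:
        raise ValueError(f"row {row}: unparseable numeric {value!r} in column {column}")


# ---------------------------------------------------------------------------
# VCF

def read_vcf(
    path, sample_map: Optional[Dict[str, str]] = None
) -> List[Tuple[str, GenomicVariant]]:
    """Read per-patient alternate alleles from a VCF.

    Returns one ``(patient_id, GenomicVariant)`` entry for every sample
    genotype that contains the alternate allele; multi-allelic records
    are split per alternate. ``sample_map`` optionally renames VCF sample
    IDs to patient IDs and must then cover every emitted sample.
    """
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"{path}: malformed VCF header ({exc})") from exc
    out: List[Tuple[str, GenomicVariant]] = []
    with vcf:
        for i, rec in enumerate(vcf, start=1):
            try:
                alts = rec.alts or ()
                for sample, call in rec.samples.items():
                    gt = call.get("GT") or ()
                    carried = sorted({a for a in gt if a not in (None, 0)})
                    if not carried:
                        continue
                    if sample_map is not None:
                        if sample not in sample_map:
                            raise SampleMappingError(
                                f"{path}: sample {sample!r} not in sample map"
                            )
                        patient = sample_map[sample]
                    else:
                        patient = sample
                    for allele_idx in carried:
                        alt = alts[allele_idx - 1]
                        out.append(
                            (patient, GenomicVariant(rec.chrom, rec.pos, rec.ref, alt))
                        )
            except SampleMappingError:
                raise
            except (VcfParseError, IndexError, TypeError, ValueError) as exc:
                raise VcfParseError(f"{path}: bad record at line ~{i}: {exc}") from exc
    return out


def write_vcf(
    entries: List[Tuple[str, GenomicVariant]], path, contigs: Optional[List[str]] = None
) -> None:
    """Write (patient, variant) pairs as a minimal multi-sample VCF."""
    samples = sorted({p for p, _ in entries})
    by_variant: Dict[tuple, set] = {}
    for patient, v in entries:
        by_variant.setdefault(v.key, set()).add(patient)
    variants = {v.key: v for _, v in entries}
    if contigs is None:
        contigs = sorted({k[0] for k in by_variant}, key=str)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for key in sorted(by_variant, key=lambda k: (str(k[0]), k[1], k[2], k[3])):
            v = variants[key]
            carriers = by_variant[key]
            gts = ["0/1" if s in carriers else "0/0" for s in samples]
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Annotation table

_ANNOTATION_COLS = [
    "chrom", "pos", "ref", "alt",
    "clinvar", "maf", "esm1b", "alphamissense", "splice_ref", "splice_alt",
]


def read_annotation_table(path) -> Dict[tuple, EvidenceBundle]:
    """Read the per-variant evidence TSV keyed by (chrom, pos, ref, alt)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, _ANNOTATION_COLS, path)
    out: Dict[tuple, EvidenceBundle] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            pos = int(row.pos)
        except ValueError:
            raise ValueError(f"row {i}: unparseable position {row.pos!r}")
        key = (str(row.chrom), pos, row.ref, row.alt)
        out[key] = EvidenceBundle(
            clinvar=row.clinvar if row.clinvar.strip() else NOT_LISTED,
            maf=_opt_float(row.maf, "maf", i),
            esm1b=_opt_float(row.esm1b, "esm1b", i),
            alphamissense=_opt_float(row.alphamissense, "alphamissense", i),
            splice_ref=_opt_float(row.splice_ref, "splice_ref", i),
            splice_alt=_opt_float(row.splice_alt, "splice_alt", i),
        )
    return out


def write_annotation_table(bundles: Dict[tuple, EvidenceBundle], path) -> None:
    rows = []
    for (chrom, pos, ref, alt), e in bundles.items():
        rows.append(
            {
                "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                "clinvar": e.clinvar,
                "maf": "" if e.maf is None else repr(e.maf),
                "esm1b": "" if e.esm1b is None else repr(e.esm1b),
                "alphamissense": "" if e.alphamissense is None else repr(e.alphamissense),
                "splice_ref": "" if e.splice_ref is None else repr(e.splice_ref),
                "splice_alt": "" if e.splice_alt is None else repr(e.splice_alt),
            }
        )
    pd.DataFrame(rows, columns=_ANNOTATION_COLS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Transcripts (flat TSV, one row per exon; 1-based inclusive coordinates
# in the file, converted to 0-based half-open here and nowhere else)

_TRANSCRIPT_COLS = [
    "gene", "transcript_id", "strand", "exon_start", "exon_end", "cds_start", "cds_end",
]
_TRANSCRIPT_COLS_OUT = _TRANSCRIPT_COLS + ["chrom"]


def read_transcripts(path) -> List[TranscriptModel]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, _TRANSCRIPT_COLS, path)
    models: List[TranscriptModel] = []
    for tid, grp in df.groupby("transcript_id", sort=False):
        exons = sorted(
            (int(r.exon_start) - 1, int(r.exon_end)) for r in grp.itertuples()
        )
        first = grp.iloc[0]
        models.append(
            TranscriptModel(
                gene=first.gene,
                transcript_id=tid,
                strand=first.strand,
                exons=tuple(exons),
                cds_start=int(first.cds_start) - 1,
                cds_end=int(first.cds_end),
                chrom=first["chrom"] if "chrom" in grp.columns else "",
            )
        )
    return models


def write_transcripts(models: List[TranscriptModel], path) -> None:
    rows = []
    for t in models:
        for s, e in t.exons:
            rows.append(
                {
                    "gene": t.gene,
                    "transcript_id": t.transcript_id,
                    "strand": t.strand,
                    "exon_start": s + 1,
                    "exon_end": e,
                    "cds_start": t.cds_start + 1,
                    "cds_end": t.cds_end,
                    "chrom": t.chrom,
                }
            )
    pd.DataFrame(rows, columns=_TRANSCRIPT_COLS_OUT).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Phenotypes

_PHENOTYPE_COLS = ["patient_id", "age", "histology", "hpv", "stage", "variants"]


def read_phenotypes(path) -> List[PatientRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, _PHENOTYPE_COLS[:5], path)
    has_variants = "variants" in df.columns
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        age = _opt_float(row.age, "age", i)
        if age is None:
            raise ValueError(f"row {i}: missing age")
        variants = []
        if has_variants and row.variants.strip():
            variants = row.variants.split(",")
        out.append(
            PatientRecord(
                patient_id=row.patient_id,
                age=age,
                histology=row.histology,
                hpv=row.hpv,
                stage=row.stage,
                variants=variants,
            )
        )
    return out


def write_phenotypes(patients: List[PatientRecord], path) -> None:
    rows = [
        {
            "patient_id": p.patient_id,
            "age": repr(p.age) if isinstance(p.age, float) else p.age,
            "histology": p.histology.value,
            "hpv": p.hpv.value,
            "stage": p.stage.value,
            "variants": ",".join(p.variants),
        }
        for p in patients
    ]
    pd.DataFrame(rows, columns=_PHENOTYPE_COLS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Control summaries

_CONTROL_COLS = ["gene", "carriers", "total"]


def read_control_summary(path) -> List[ControlSummary]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, _CONTROL_COLS, path)
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            carriers, total = int(row.carriers), int(row.total)
        except ValueError:
            raise ValueError(f"row {i}: unparseable counts {row.carriers!r}/{row.total!r}")
        out.append(ControlSummary(gene=row.gene, carriers=carriers, total=total))
    return out


def write_control_summary(controls: List[ControlSummary], path) -> None:
    rows = [{"gene": c.gene, "carriers": c.carriers, "total": c.total} for c in controls]
    pd.DataFrame(rows, columns=_CONTROL_COLS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Classified output

def write_classified_table(df: pd.DataFrame, path) -> None:
    """Write the classified variant table (annotation columns plus
    consequence, classification, rule_trace)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_classified_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)
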