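"""Orchestration: file-level classify and associate runs, plus the run
manifest used to make every run reproducible and auditable."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd

from . import __version__
from . import io as gio
from .consequence import (
    IntegrityError,
    OutOfTranscriptError,
    call_consequence,
)
from .models import EvidenceBundle, GenomicVariant, ReferenceWindow, TranscriptModel
from .normalize import ReferenceMismatchError, normalize_variant
from .simulate import read_reference_windows
from .triage import CohortClassification, TriageConfig, classify_cohort


def variant_id(gene: str, v: GenomicVariant) -> str:
    return f"{gene}:{v.chrom}:{v.pos}:{v.ref}>{v.alt}"


@dataclass
class RunManifest:
    tool_version: str
    command: str
    config: dict
    inputs: Dict[str, str]  # path -> sha256
    seed: Optional[int]
    started: str
    finished: str = ""
    stage_counts: Dict[str, int] = field(default_factory=dict)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def new_manifest(command: str, config: dict, inputs: Dict[str, str], seed=None) -> RunManifest:
    digests = {str(p): sha256_of(p) for p in inputs.values() if p and Path(p).exists()}
    return RunManifest(
        tool_version=__version__,
        command=command,
        config=config,
        inputs=digests,
        seed=seed,
        started=datetime.now(timezone.utc).isoformat(),
    )


def classify_files(
    vcf_path,
    annotations_path,
    transcripts_path,
    reference_path,
    cfg: TriageConfig = None,
) -> Tuple[CohortClassification, Dict[str, List[str]], Dict[str, int]]:
    """Classify every distinct variant seen in a VCF.

    Returns the cohort classification, the patient → variant-id carriage
    map, and per-stage record counts. Variants that cannot be projected
    onto a transcript are listed under ``skipped``, never dropped.
    """
    cfg = cfg or TriageConfig()
    entries = gio.read_vcf(vcf_path)
    evidence = gio.read_annotation_table(annotations_path)
    transcripts = gio.read_transcripts(transcripts_path)
    windows = read_reference_windows(reference_path)

    unique: Dict[tuple, GenomicVariant] = {}
    carriage: Dict[str, List[str]] = {}
    raw_to_norm: Dict[tuple, GenomicVariant] = {}
    for patient, v in entries:
        if v.key not in raw_to_norm:
            w = windows.get(v.chrom)
            nv = v
            if w is not None:
                try:
                    nv = normalize_variant(v, w)
                except (ReferenceMismatchError, IndexError):
                    nv = v
            raw_to_norm[v.key] = nv
            unique[nv.key] = nv
        carriage.setdefault(patient, [])

    # one canonical transcript per contig
    tx_for: Dict[str, TranscriptModel] = {t.chrom: t for t in transcripts if t.chrom}

    records = []
    for key, v in unique.items():
        w = windows.get(v.chrom)
        t = tx_for.get(v.chrom)
        cons = None
        gene = t.gene if t is not None else ""
        if t is not None and w is not None:
            try:
                cons = call_consequence(v, t, w)
            except (IntegrityError, OutOfTranscriptError):
                cons = None
        e = evidence.get(v.key, EvidenceBundle())
        records.append(
            {
                "variant_id": variant_id(gene, v),
                "gene": gene,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "consequence": cons,
                "evidence": e,
            }
        )
    result = classify_cohort(records, cfg)

    id_of = {}
    for key, v in unique.items():
        t = tx_for.get(v.chrom)
        id_of[key] = variant_id(t.gene if t else "", v)
    for patient, v in entries:
        nv = raw_to_norm[v.key]
        vid = id_of[nv.key]
        if vid not in carriage[patient]:
            carriage[patient].append(vid)
    counts = {
        "vcf_entries": len(entries),
        "unique_variants": len(unique),
        "classified": int(len(result.table)),
        "skipped": len(result.skipped),
        "patients_in_vcf": len(carriage),
    }
    return result, carriage, counts


def classified_lookup(table: pd.DataFrame) -> Dict[str, dict]:
    """Variant-id keyed lookup used by carrier aggregation."""
    out = {}
    for row in table.itertuples(index=False):
        out[row.variant_id] = {
            "gene": row.gene,
            "classification": row.classification,
            "consequence": row.consequence,
            "in_last_exon": getattr(row, "in_last_exon", ""),
        }
    return out
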