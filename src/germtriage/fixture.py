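"""Packaged study fixture: the published rare-variant table of a
728-patient cervical cancer HDR/MMR panel screen, with helpers that wire
it into the pipeline.

The TSV carries, per variant: gene, GRCh37 position, HGVS g./c./p.
descriptions, dbSNP id, the number of carrier patients, the reported
molecular consequence, the ClinVar assertion string, and the table
section the variant was reported under. The section label encodes which
evidence tier decided the variant (e.g. concordant in-silico pathogenic
vs. ambiguous); :func:`synthesize_evidence` converts it into
threshold-consistent score pairs so the triage engine can be run on the
fixture. The classifier itself never reads the section label.

In-silico scores are synthetic stand-ins consistent with the reported
concordance category, not the original predictor outputs (which the
source table does not print); the splice-variant MaxEnt scores (10.57 →
8.38) are the published values.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, List, Tuple

import pandas as pd

from .consequence import Consequence, ConsequenceKind
from .models import (
    EvidenceBundle,
    Histology,
    HpvStatus,
    NOT_LISTED,
    PatientRecord,
    Stage,
)

FIXTURE_NAME = "cervical_panel_variants.tsv"

#: Synthetic in-silico scores per concordance category (ESM1b more
#: negative = damaging, threshold −10; AlphaMissense higher = damaging,
#: threshold 0.8).
_CONCORDANT_PATHOGENIC = {"esm1b": -15.0, "alphamissense": 0.95}
_DISCORDANT = {"esm1b": -15.0, "alphamissense": 0.30}
_CONCORDANT_BENIGN = {"esm1b": -5.0, "alphamissense": 0.30}

_CONSEQUENCE_MAP = {
    "Stop gained": (ConsequenceKind.STOP_GAINED, False),
    "Frameshift": (ConsequenceKind.FRAMESHIFT, False),
    "Frameshift (last exon)": (ConsequenceKind.FRAMESHIFT, True),
    "Missense": (ConsequenceKind.MISSENSE, None),
    "In frame deletion": (ConsequenceKind.INFRAME_DELETION, None),
    "Donor splice-site variant": (ConsequenceKind.SPLICE_REGION, None),
}


def load_panel_table() -> pd.DataFrame:
    """Load the packaged variant table fixture."""
    with resources.files("germtriage.data").joinpath(FIXTURE_NAME).open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    df["pos"] = df["pos"].astype(int)
    df["n_patients"] = df["n_patients"].astype(int)
    return df


def parse_consequence(label: str) -> Consequence:
    """Map a reported consequence label to a :class:`Consequence`."""
    kind, last_exon = _CONSEQUENCE_MAP[label]
    return Consequence(kind=kind, in_last_exon=last_exon)


def synthesize_evidence(row) -> EvidenceBundle:
    """Evidence bundle for one fixture row.

    Scores are drawn from the variant's reported concordance category so
    that the triage thresholds reproduce the reported tier; in-frame
    deletions receive an ESM1b score only (AlphaMissense covers
    substitutions, not indels); the splice variant carries the published
    MaxEnt reference/alternate scores. MAF is left unknown — every row
    of the table already passed the rarity filter.
    """
    section: str = row.section
    clinvar = row.clinvar if row.clinvar.strip() else NOT_LISTED
    kind, _ = _CONSEQUENCE_MAP[row.consequence]
    kwargs: Dict[str, float] = {}
    if section.endswith("_splice_benign"):
        kwargs = {"splice_ref": 10.57, "splice_alt": 8.38}
    elif section.endswith("_insilico_pathogenic"):
        kwargs = dict(_CONCORDANT_PATHOGENIC)
    elif section.endswith("_insilico_ambiguous"):
        kwargs = dict(_DISCORDANT)
    elif section.endswith("_insilico_benign") and kind in (
        ConsequenceKind.MISSENSE,
        ConsequenceKind.INFRAME_DELETION,
    ):
        kwargs = dict(_CONCORDANT_BENIGN)
        if kind is ConsequenceKind.INFRAME_DELETION:
            kwargs.pop("alphamissense")
    return EvidenceBundle(clinvar=clinvar, **kwargs)


def panel_records(df: pd.DataFrame = None) -> List[dict]:
    """Fixture rows as joined records for the triage engine."""
    if df is None:
        df = load_panel_table()
    records = []
    for row in df.itertuples(index=False):
        records.append(
            {
                "variant_id": row.hgvs_c,
                "gene": row.gene,
                "chrom": row.chrom,
                "pos": row.pos,
                "n_patients": row.n_patients,
                "section": row.section,
                "consequence": parse_consequence(row.consequence),
                "evidence": synthesize_evidence(row),
            }
        )
    return records


def build_cohort(
    df: pd.DataFrame = None, n_patients: int = 728
) -> Tuple[List[PatientRecord], Dict[str, int]]:
    """Wire the fixture's per-variant carrier counts to a synthetic cohort.

    Each variant's reported carrier count is assigned to that many
    distinct fresh patients (no patient carries two variants, matching
    the reported totals); the remaining patients carry nothing.
    Phenotype fields are deterministic placeholders — only carrier
    wiring is meaningful here. Returns the patient list and the variant
    id → carrier count map.
    """
    if df is None:
        df = load_panel_table()
    total_carrier_slots = int(df["n_patients"].sum())
    if total_carrier_slots > n_patients:
        raise ValueError("more carrier slots than patients")
    patients: List[PatientRecord] = []
    counts: Dict[str, int] = {}
    i = 0
    for row in df.itertuples(index=False):
        counts[row.hgvs_c] = row.n_patients
        for _ in range(row.n_patients):
            i += 1
            patients.append(
                PatientRecord(
                    patient_id=f"P{i:04d}",
                    age=47.0,
                    histology=Histology.SQUAMOUS,
                    hpv=HpvStatus.HPV16,
                    stage=Stage.INVASIVE,
                    variants=[row.hgvs_c],
                )
            )
    while i < n_patients:
        i += 1
        patients.append(
            PatientRecord(
                patient_id=f"P{i:04d}",
                age=47.0,
                histology=Histology.SQUAMOUS,
                hpv=HpvStatus.HPV16,
                stage=Stage.INVASIVE,
                variants=[],
            )
        )
    return patients, counts
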