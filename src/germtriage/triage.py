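"""Tiered germline variant triage.

The decision sequence, applied in strict precedence order:

1. **Rarity filter** — variants with a known population minor allele
   frequency at or above the threshold (default 0.005) are excluded as
   common polymorphisms; unknown MAF is treated as rare.
2. **ClinVar precedence** — a concordant pathogenic (or benign) ClinVar
   assertion decides the class outright. Assertions containing
   "uncertain significance" or mixing pathogenic with benign components
   are treated as unresolved and fall through to the rule tiers.
3. **Truncation rule** — stop-gained and frameshift variants are
   pathogenic unless the first affected codon lies in the last coding
   exon (presumed escape from nonsense-mediated decay), in which case
   they are likely benign.
4. **Splice rule** — donor/acceptor-window variants are judged on the
   reference vs. alternate maximum-entropy splice scores: likely
   pathogenic when the alternate score drops below zero or loses at
   least half of the reference score, otherwise likely benign; without
   scores the variant stays ambiguous.
5. **In-silico concordance rule** — protein-altering variants are likely
   pathogenic when ESM1b (≤ −10) and AlphaMissense (> 0.8) concur on a
   damaging prediction, likely benign when both concur on a tolerated
   one, and ambiguous when they disagree. If only one predictor covers
   the variant (AlphaMissense scores substitutions only), that predictor
   decides alone and the rule trace records single-predictor evidence.
6. **Silent fallback** — synonymous and intronic variants are likely
   benign.

Every classification carries an ordered rule trace for audit.
"""

from __future__ import annotations

import enum
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd

from .consequence import Consequence, ConsequenceKind, TRUNCATING_KINDS
from .models import EvidenceBundle, NOT_LISTED, pathway_of


class ClinVarCall(str, enum.Enum):
    PATHOGENIC = "PATHOGENIC"
    BENIGN = "BENIGN"
    VUS_OR_CONFLICTING = "VUS_OR_CONFLICTING"
    NOT_LISTED = "NOT_LISTED"


class Klass(str, enum.Enum):
    EXCLUDED_COMMON = "excluded_common"
    BENIGN = "benign"
    LIKELY_BENIGN = "likely_benign"
    AMBIGUOUS = "ambiguous"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    PATHOGENIC = "pathogenic"


#: Severity order used for carrier aggregation floors.
SEVERITY_ORDER: Tuple[Klass, ...] = (
    Klass.EXCLUDED_COMMON,
    Klass.BENIGN,
    Klass.LIKELY_BENIGN,
    Klass.AMBIGUOUS,
    Klass.LIKELY_PATHOGENIC,
    Klass.PATHOGENIC,
)


def severity_rank(k: Klass) -> int:
    return SEVERITY_ORDER.index(Klass(k))


@dataclass(frozen=True)
class Classification:
    klass: Klass
    rule_trace: Tuple[str, ...]
    evidence_used: frozenset

    def __post_init__(self) -> None:
        if not self.rule_trace:
            raise ValueError("rule_trace must be non-empty")


@dataclass(frozen=True)
class SpliceRule:
    """Splice-score criterion: damaging when the alternate score falls
    below ``abs_floor`` or drops by at least ``rel_drop`` of the
    reference score."""

    abs_floor: float = 0.0
    rel_drop: float = 0.5


@dataclass(frozen=True)
class TriageConfig:
    maf_threshold: float = 0.005
    esm1b_threshold: float = -10.0
    alphamissense_threshold: float = 0.8
    splice_rule: SpliceRule = field(default_factory=SpliceRule)
    last_exon_exemption: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.maf_threshold < 1.0:
            raise ValueError("maf_threshold must be in (0,1)")


DEFAULT_CONFIG = TriageConfig()

_PATHOGENIC_TERMS = {"pathogenic", "likely pathogenic"}
_BENIGN_TERMS = {"benign", "likely benign"}


def parse_clinvar_assertion(s: Optional[str]) -> ClinVarCall:
    """Collapse a free-text, slash-joined ClinVar assertion to one call.

    All components pathogenic/likely-pathogenic → PATHOGENIC; all
    benign/likely-benign → BENIGN; any "uncertain significance" or a
    pathogenic/benign mixture → VUS_OR_CONFLICTING; empty or
    unrecognized → NOT_LISTED. Case-insensitive, total.
    """
    if s is None:
        return ClinVarCall.NOT_LISTED
    text = s.strip().lower()
    if not text or text == NOT_LISTED.lower():
        return ClinVarCall.NOT_LISTED
    parts = [p.strip() for p in re.split(r"[/;|]", text) if p.strip()]
    if not parts:
        return ClinVarCall.NOT_LISTED
    known = [p for p in parts if p in _PATHOGENIC_TERMS | _BENIGN_TERMS
             or p == "uncertain significance"]
    if len(known) != len(parts) or not known:
        return ClinVarCall.NOT_LISTED
    if any(p == "uncertain significance" for p in parts):
        return ClinVarCall.VUS_OR_CONFLICTING
    has_path = any(p in _PATHOGENIC_TERMS for p in parts)
    has_ben = any(p in _BENIGN_TERMS for p in parts)
    if has_path and has_ben:
        return ClinVarCall.VUS_OR_CONFLICTING
    return ClinVarCall.PATHOGENIC if has_path else ClinVarCall.BENIGN


_PROTEIN_ALTERING = frozenset(
    {
        ConsequenceKind.MISSENSE,
        ConsequenceKind.INFRAME_DELETION,
        ConsequenceKind.INFRAME_INSERTION,
        ConsequenceKind.STOP_LOST,
        ConsequenceKind.START_LOST,
    }
)


def classify_variant(
    c: Consequence, e: EvidenceBundle, cfg: TriageConfig = DEFAULT_CONFIG
) -> Classification:
    """Apply the tiered decision sequence to one variant. Total function."""
    trace: List[str] = []
    used = set()

    # (1) rarity filter
    if e.maf is not None and e.maf >= cfg.maf_threshold:
        return Classification(
            Klass.EXCLUDED_COMMON, ("MAF_COMMON",), frozenset({"MAF"})
        )
    trace.append("MAF_RARE")
    used.add("MAF")

    # (2) ClinVar precedence
    call = parse_clinvar_assertion(e.clinvar)
    if call is ClinVarCall.PATHOGENIC:
        trace.append("CLINVAR_PATHOGENIC")
        return Classification(Klass.PATHOGENIC, tuple(trace), frozenset(used | {"CLINVAR"}))
    if call is ClinVarCall.BENIGN:
        trace.append("CLINVAR_BENIGN")
        return Classification(Klass.BENIGN, tuple(trace), frozenset(used | {"CLINVAR"}))
    if call is ClinVarCall.VUS_OR_CONFLICTING:
        trace.append("CLINVAR_UNRESOLVED")
        used.add("CLINVAR")

    # (3) truncation rule with last-exon exemption
    if c.kind in TRUNCATING_KINDS:
        used.add("TRUNCATION")
        if cfg.last_exon_exemption and c.in_last_exon:
            trace.append("TRUNCATING_LAST_EXON")
            return Classification(Klass.LIKELY_BENIGN, tuple(trace), frozenset(used))
        trace.append("TRUNCATING_NON_LAST_EXON")
        return Classification(Klass.PATHOGENIC, tuple(trace), frozenset(used))

    # (4) splice rule
    if c.kind is ConsequenceKind.SPLICE_REGION:
        used.add("SPLICE")
        if e.splice_ref is None or e.splice_alt is None:
            trace.append("SPLICE_SCORES_ABSENT")
            return Classification(Klass.AMBIGUOUS, tuple(trace), frozenset(used))
        damaging = e.splice_alt < cfg.splice_rule.abs_floor
        if not damaging and e.splice_ref > 0:
            drop = (e.splice_ref - e.splice_alt) / e.splice_ref
            damaging = drop >= cfg.splice_rule.rel_drop
        if damaging:
            trace.append("SPLICE_SCORE_LOSS")
            return Classification(Klass.LIKELY_PATHOGENIC, tuple(trace), frozenset(used))
        trace.append("SPLICE_SCORE_RETAINED")
        return Classification(Klass.LIKELY_BENIGN, tuple(trace), frozenset(used))

    # (5) in-silico concordance rule
    if c.kind in _PROTEIN_ALTERING:
        used.add("INSILICO")
        esm_path = None if e.esm1b is None else e.esm1b <= cfg.esm1b_threshold
        am_path = (
            None
            if e.alphamissense is None
            else e.alphamissense > cfg.alphamissense_threshold
        )
        if esm_path is None and am_path is None:
            trace.append("INSILICO_ABSENT")
            return Classification(Klass.AMBIGUOUS, tuple(trace), frozenset(used))
        if esm_path is None or am_path is None:
            verdict = esm_path if am_path is None else am_path
            trace.append(
                "INSILICO_SINGLE_ESM1B" if am_path is None else "INSILICO_SINGLE_ALPHAMISSENSE"
            )
            klass = Klass.LIKELY_PATHOGENIC if verdict else Klass.LIKELY_BENIGN
            return Classification(klass, tuple(trace), frozenset(used))
        if esm_path and am_path:
            trace.append("INSILICO_CONCORDANT_PATHOGENIC")
            return Classification(Klass.LIKELY_PATHOGENIC, tuple(trace), frozenset(used))
        if not esm_path and not am_path:
            trace.append("INSILICO_CONCORDANT_BENIGN")
            return Classification(Klass.LIKELY_BENIGN, tuple(trace), frozenset(used))
        trace.append("INSILICO_DISCORDANT")
        return Classification(Klass.AMBIGUOUS, tuple(trace), frozenset(used))

    # (6) silent fallback
    trace.append("SILENT_CONSEQUENCE")
    return Classification(Klass.LIKELY_BENIGN, tuple(trace), frozenset(used))


@dataclass
class CohortClassification:
    """Classified variant table plus tallies."""

    table: pd.DataFrame
    class_counts: Dict[str, int]
    gene_counts: Dict[str, Dict[str, int]]
    pathway_counts: Dict[str, Dict[str, int]]
    skipped: List[dict] = field(default_factory=list)


def classify_cohort(
    records: Iterable[dict], cfg: TriageConfig = DEFAULT_CONFIG
) -> CohortClassification:
    """Classify joined variant records.

    Each record is a mapping with keys ``variant_id``, ``gene``,
    ``consequence`` (:class:`~germtriage.consequence.Consequence` or
    None) and ``evidence`` (:class:`~germtriage.models.EvidenceBundle`);
    extra keys are carried through to the output table. Records without
    a consequence are reported under ``skipped``, never dropped
    silently.
    """
    rows = []
    skipped = []
    class_counts: Counter = Counter({k.value: 0 for k in Klass})
    gene_counts: Dict[str, Counter] = {}
    pathway_counts: Dict[str, Counter] = {}
    for rec in records:
        cons: Optional[Consequence] = rec.get("consequence")
        if cons is None:
            skipped.append(
                {"variant_id": rec.get("variant_id"), "reason": "no consequence"}
            )
            continue
        result = classify_variant(cons, rec["evidence"], cfg)
        gene = rec.get("gene", "")
        row = {
            k: v for k, v in rec.items() if k not in ("consequence", "evidence")
        }
        row.update(
            {
                "gene": gene,
                "consequence": cons.kind.value,
                "in_last_exon": "" if cons.in_last_exon is None else cons.in_last_exon,
                "protein_change": cons.protein_change or "",
                "classification": result.klass.value,
                "rule_trace": ";".join(result.rule_trace),
            }
        )
        rows.append(row)
        class_counts[result.klass.value] += 1
        gene_counts.setdefault(gene, Counter())[result.klass.value] += 1
        pathway_counts.setdefault(pathway_of(gene), Counter())[result.klass.value] += 1
    table = pd.DataFrame(rows)
    return CohortClassification(
        table=table,
        class_counts=dict(class_counts),
        gene_counts={g: dict(c) for g, c in gene_counts.items()},
        pathway_counts={p: dict(c) for p, c in pathway_counts.items()},
        skipped=skipped,
    )
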