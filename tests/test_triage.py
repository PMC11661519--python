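"""Triage rule tests: ClinVar assertion folding, the tiered decision
sequence, rule exhaustiveness/monotonicity properties, and the packaged
cohort table."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from germtriage.consequence import Consequence, ConsequenceKind
from germtriage.models import EvidenceBundle, HDR_GENES
from germtriage.triage import (
    ClinVarCall,
    DEFAULT_CONFIG,
    Klass,
    TriageConfig,
    classify_cohort,
    classify_variant,
    parse_clinvar_assertion,
)


@pytest.mark.parametrize(
    "text,expected",
    [
        ("Pathogenic/likely pathogenic", ClinVarCall.PATHOGENIC),
        ("pathogenic", ClinVarCall.PATHOGENIC),
        ("Benign/likely benign", ClinVarCall.BENIGN),
        ("Likely benign", ClinVarCall.BENIGN),
        ("Uncertain significance/likely pathogenic", ClinVarCall.VUS_OR_CONFLICTING),
        ("Uncertain significance/benign/likely benign", ClinVarCall.VUS_OR_CONFLICTING),
        ("Pathogenic/benign", ClinVarCall.VUS_OR_CONFLICTING),
        ("UNCERTAIN SIGNIFICANCE", ClinVarCall.VUS_OR_CONFLICTING),
        ("", ClinVarCall.NOT_LISTED),
        ("Not listed", ClinVarCall.NOT_LISTED),
        ("drug response", ClinVarCall.NOT_LISTED),
        (None, ClinVarCall.NOT_LISTED),
    ],
)
def test_parse_clinvar_assertion(text, expected):
    assert parse_clinvar_assertion(text) is expected


MISSENSE = Consequence(ConsequenceKind.MISSENSE, protein_change="Ala1Val")
STOP = Consequence(ConsequenceKind.STOP_GAINED, in_last_exon=False,
                   protein_change="Gln1Ter")
STOP_LAST = Consequence(ConsequenceKind.FRAMESHIFT, in_last_exon=True,
                        protein_change="Ser1fs")
SPLICE = Consequence(ConsequenceKind.SPLICE_REGION)


def test_maf_exclusion_dominates_everything():
    result = classify_variant(STOP, EvidenceBundle(clinvar="Pathogenic", maf=0.01))
    assert result.klass is Klass.EXCLUDED_COMMON
    assert result.rule_trace == ("MAF_COMMON",)
    # unknown MAF passes the rarity filter
    assert classify_variant(STOP, EvidenceBundle()).klass is Klass.PATHOGENIC


def test_clinvar_precedence_over_insilico():
    benign_scores = EvidenceBundle(clinvar="Pathogenic", esm1b=-2.0, alphamissense=0.1)
    assert classify_variant(MISSENSE, benign_scores).klass is Klass.PATHOGENIC
    assert (
        classify_variant(MISSENSE, EvidenceBundle(clinvar="Benign")).klass
        is Klass.BENIGN
    )


def test_truncation_rule_and_last_exon_exemption():
    novel = EvidenceBundle()  # not listed anywhere
    assert classify_variant(STOP, novel).klass is Klass.PATHOGENIC
    r = classify_variant(STOP_LAST, novel)
    assert r.klass is Klass.LIKELY_BENIGN
    # exemption can be switched off
    cfg = TriageConfig(last_exon_exemption=False)
    assert classify_variant(STOP_LAST, novel, cfg).klass is Klass.PATHOGENIC


def test_splice_rule_thresholds():
    mild = EvidenceBundle(splice_ref=10.57, splice_alt=8.38)  # 21% drop
    assert classify_variant(SPLICE, mild).klass is Klass.LIKELY_BENIGN
    severe = EvidenceBundle(splice_ref=10.0, splice_alt=4.9)  # 51% drop
    assert classify_variant(SPLICE, severe).klass is Klass.LIKELY_PATHOGENIC
    negative = EvidenceBundle(splice_ref=3.0, splice_alt=-1.0)
    assert classify_variant(SPLICE, negative).klass is Klass.LIKELY_PATHOGENIC
    assert classify_variant(SPLICE, EvidenceBundle()).klass is Klass.AMBIGUOUS


def test_insilico_concordance_rule():
    vus = "Uncertain significance"
    lp = classify_variant(MISSENSE, EvidenceBundle(clinvar=vus, esm1b=-12.0,
                                                   alphamissense=0.95))
    assert lp.klass is Klass.LIKELY_PATHOGENIC
    amb = classify_variant(MISSENSE, EvidenceBundle(clinvar=vus, esm1b=-12.0,
                                                    alphamissense=0.30))
    assert amb.klass is Klass.AMBIGUOUS
    lb = classify_variant(MISSENSE, EvidenceBundle(clinvar=vus, esm1b=-5.0,
                                                   alphamissense=0.30))
    assert lb.klass is Klass.LIKELY_BENIGN
    # one predictor only: it decides, and the trace says so
    single = classify_variant(
        Consequence(ConsequenceKind.INFRAME_DELETION, protein_change="Asn1del"),
        EvidenceBundle(clinvar=vus, esm1b=-5.0),
    )
    assert single.klass is Klass.LIKELY_BENIGN
    assert "INSILICO_SINGLE_ESM1B" in single.rule_trace
    both_absent = classify_variant(MISSENSE, EvidenceBundle(clinvar=vus))
    assert both_absent.klass is Klass.AMBIGUOUS


def test_silent_fallback():
    syn = Consequence(ConsequenceKind.SYNONYMOUS, protein_change="Leu5=")
    assert classify_variant(syn, EvidenceBundle()).klass is Klass.LIKELY_BENIGN
    intronic = Consequence(ConsequenceKind.INTRONIC)
    assert classify_variant(intronic, EvidenceBundle()).klass is Klass.LIKELY_BENIGN


# --- property tests over randomized inputs ---

_consequences = st.builds(
    Consequence,
    kind=st.sampled_from(list(ConsequenceKind)),
    in_last_exon=st.one_of(st.none(), st.booleans()),
    protein_change=st.just("Xaa1Xaa"),
)
_scores = st.one_of(st.none(), st.floats(-30, 10))
_evidence = st.builds(
    EvidenceBundle,
    clinvar=st.sampled_from(
        ["Pathogenic", "Benign", "Likely benign", "Uncertain significance",
         "Pathogenic/likely pathogenic", "Uncertain significance/likely pathogenic",
         "Not listed", ""]
    ),
    maf=st.one_of(st.none(), st.floats(0, 0.5)),
    esm1b=_scores,
    alphamissense=st.one_of(st.none(), st.floats(0, 1)),
    splice_ref=st.one_of(st.none(), st.floats(-5, 15)),
    splice_alt=st.one_of(st.none(), st.floats(-5, 15)),
)


@settings(max_examples=300, derandomize=True)
@given(c=_consequences, e=_evidence)
def test_rules_are_exhaustive_and_exclusive(c, e):
    """Every consequence/evidence pair maps to exactly one class with a
    non-empty rule trace, and MAF exclusion fires iff it fired first."""
    r = classify_variant(c, e)
    assert r.klass in Klass
    assert len(r.rule_trace) >= 1
    assert (r.klass is Klass.EXCLUDED_COMMON) == (r.rule_trace[0] == "MAF_COMMON")


_SEVERITY = {Klass.LIKELY_BENIGN: 0, Klass.AMBIGUOUS: 1, Klass.LIKELY_PATHOGENIC: 2}


@settings(max_examples=200, derandomize=True)
@given(
    esm=st.floats(-30, 5), am=st.floats(0, 1),
    d_esm=st.floats(0, 10), d_am=st.floats(0, 1),
)
def test_missense_monotonicity(esm, am, d_esm, d_am):
    """More damaging scores never move a missense variant to a less severe
    class, holding the other predictor fixed."""
    vus = "Uncertain significance"
    base = classify_variant(MISSENSE, EvidenceBundle(clinvar=vus, esm1b=esm,
                                                     alphamissense=am))
    lower_esm = classify_variant(
        MISSENSE, EvidenceBundle(clinvar=vus, esm1b=esm - d_esm, alphamissense=am)
    )
    higher_am = classify_variant(
        MISSENSE,
        EvidenceBundle(clinvar=vus, esm1b=esm, alphamissense=min(1.0, am + d_am)),
    )
    assert _SEVERITY[lower_esm.klass] >= _SEVERITY[base.klass]
    assert _SEVERITY[higher_am.klass] >= _SEVERITY[base.klass]


# --- independent decision-table oracle ---

def oracle_class(c: Consequence, e: EvidenceBundle, cfg=DEFAULT_CONFIG) -> Klass:
    """Row-wise re-implementation of the decision table, written as a flat
    lookup rather than the engine's sequential rules."""
    known_path = {"pathogenic", "likely pathogenic"}
    known_ben = {"benign", "likely benign"}
    parts = [p.strip().lower() for p in (e.clinvar or "").replace(";", "/").split("/")
             if p.strip()]
    recognized = all(p in known_path | known_ben | {"uncertain significance"}
                     for p in parts) and bool(parts)
    if e.maf is not None and e.maf >= cfg.maf_threshold:
        return Klass.EXCLUDED_COMMON
    if recognized and "uncertain significance" not in parts:
        if set(parts) <= known_path:
            return Klass.PATHOGENIC
        if set(parts) <= known_ben:
            return Klass.BENIGN
    truncating = c.kind in (ConsequenceKind.STOP_GAINED, ConsequenceKind.FRAMESHIFT)
    if truncating:
        return Klass.LIKELY_BENIGN if (c.in_last_exon and cfg.last_exon_exemption) \
            else Klass.PATHOGENIC
    if c.kind is ConsequenceKind.SPLICE_REGION:
        if e.splice_ref is None or e.splice_alt is None:
            return Klass.AMBIGUOUS
        bad = e.splice_alt < cfg.splice_rule.abs_floor or (
            e.splice_ref > 0
            and (e.splice_ref - e.splice_alt) / e.splice_ref >= cfg.splice_rule.rel_drop
        )
        return Klass.LIKELY_PATHOGENIC if bad else Klass.LIKELY_BENIGN
    if c.kind in (ConsequenceKind.SYNONYMOUS, ConsequenceKind.INTRONIC):
        return Klass.LIKELY_BENIGN
    votes = []
    if e.esm1b is not None:
        votes.append(e.esm1b <= cfg.esm1b_threshold)
    if e.alphamissense is not None:
        votes.append(e.alphamissense > cfg.alphamissense_threshold)
    if not votes:
        return Klass.AMBIGUOUS
    if all(votes):
        return Klass.LIKELY_PATHOGENIC
    if not any(votes):
        return Klass.LIKELY_BENIGN
    return Klass.AMBIGUOUS


@settings(max_examples=500, derandomize=True)
@given(c=_consequences, e=_evidence)
def test_classifier_matches_decision_table_oracle(c, e):
    assert classify_variant(c, e).klass is oracle_class(c, e)


# --- cohort-level behaviour ---

def test_empty_cohort():
    result = classify_cohort([])
    assert all(v == 0 for v in result.class_counts.values())
    assert result.skipped == []


def test_missing_consequence_is_reported_not_dropped():
    records = [
        {"variant_id": "v1", "gene": "BRCA1", "consequence": None,
         "evidence": EvidenceBundle()},
        {"variant_id": "v2", "gene": "BRCA1", "consequence": STOP,
         "evidence": EvidenceBundle()},
    ]
    result = classify_cohort(records)
    assert len(result.table) == 1
    assert result.skipped == [{"variant_id": "v1", "reason": "no consequence"}]


def test_panel_fixture_classification_counts(panel_classification):
    """The packaged cohort table reproduces the reported class spectrum."""
    counts = panel_classification.class_counts
    assert counts["pathogenic"] + counts["likely_pathogenic"] == 23
    hdr = panel_classification.pathway_counts["HDR"]
    assert hdr.get("pathogenic", 0) + hdr.get("likely_pathogenic", 0) == 17
    assert hdr.get("ambiguous", 0) == 7
    table = panel_classification.table
    brca2_last = table[table.variant_id.str.contains("c.10095", regex=False)]
    assert list(brca2_last.classification) == ["likely_benign"]
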