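"""Consequence engine tests: published stop-gain/frameshift/splice
examples rebuilt on synthetic transcripts, plus a brute-force oracle that
re-translates the whole mutant coding sequence."""

import numpy as np
import pytest
from Bio.Seq import Seq

from germtriage.consequence import (
    Consequence,
    ConsequenceKind,
    IntegrityError,
    OutOfTranscriptError,
    call_consequence,
    cds_sequence,
    genomic_position_of_cds,
    project_to_cds,
    revcomp,
)
from germtriage.models import EvidenceBundle, GenomicVariant, ReferenceWindow
from germtriage.triage import Klass, classify_variant

from conftest import make_transcript, random_cds


def _cds_with_codon(rng, n_codons, codon_idx, codon_seq):
    cds = random_cds(rng, n_codons)
    i = 3 * codon_idx
    return cds[:i] + codon_seq + cds[i + 3 :]


def _snv_at_cds(t, window, c, alt_transcript_base):
    g0 = genomic_position_of_cds(t, c)
    ref = window.base_at(g0 + 1)
    alt = alt_transcript_base if t.strand == "+" else revcomp(alt_transcript_base)
    return GenomicVariant(window.chrom, g0 + 1, ref, alt)


# --- published truncating substitutions, rebuilt on synthetic transcripts ---
# (codon number, reference codon, base index within codon, alternate base on
#  the transcript strand, transcript strand, expected protein change)
TRUNCATING_SNVS = [
    ("BARD1", 564, "CAG", 0, "T", "-", "Gln564Ter"),
    ("BRCA1", 655, "TAC", 2, "A", "-", "Tyr655Ter"),
    ("BRIP1", 162, "CGA", 0, "T", "-", "Arg162Ter"),
    ("FANCM", 1701, "CAA", 0, "T", "+", "Gln1701Ter"),
    ("FANCM", 658, "CGA", 0, "T", "+", "Arg658Ter"),
    ("RAD51D", 253, "CGA", 0, "T", "-", "Arg253Ter"),
    ("SLX4", 795, "TCA", 1, "G", "-", "Ser795Ter"),
]


@pytest.mark.parametrize(
    "gene,codon_num,codon,within,alt_base,strand,expected", TRUNCATING_SNVS
)
def test_reported_stop_gains_reproduced(gene, codon_num, codon, within, alt_base,
                                        strand, expected):
    rng = np.random.default_rng(sum(ord(c) for c in gene) + codon_num)
    n_codons = codon_num + 10
    cds = _cds_with_codon(rng, n_codons, codon_num - 1, codon)
    # two coding exons, the target codon in the first (non-last) exon
    split = 3 * (codon_num + 3)
    t, window = make_transcript(cds, strand=strand,
                                exon_sizes=[split, len(cds) - split], rng=rng)
    c = 3 * (codon_num - 1) + within + 1
    v = _snv_at_cds(t, window, c, alt_base)
    placement = project_to_cds(v, t)
    assert placement.kind == "coding" and placement.cds_pos == c
    cons = call_consequence(v, t, window)
    assert cons.kind is ConsequenceKind.STOP_GAINED
    assert cons.protein_change == expected
    assert cons.in_last_exon is False


def test_minus_strand_stop_gain_at_reported_genomic_coordinate():
    # c.1965 C>A on a minus-strand transcript anchored so the variant falls
    # at its reported build-37 position, read as G>T on the forward strand
    rng = np.random.default_rng(17)
    cds = _cds_with_codon(rng, 665, 654, "TAC")
    sizes = [3 * 660, len(cds) - 3 * 660]
    t0, w0 = make_transcript(cds, strand="-", exon_sizes=sizes, rng=np.random.default_rng(5))
    g1 = genomic_position_of_cds(t0, 1965) + 1
    delta = 41245583 - g1
    t, window = make_transcript(cds, strand="-", exon_sizes=sizes,
                                chrom="17", start=1001 + delta,
                                rng=np.random.default_rng(5))
    v = _snv_at_cds(t, window, 1965, "A")
    assert v.pos == 41245583
    assert (v.ref, v.alt) == ("G", "T")
    assert project_to_cds(v, t).cds_pos == 1965
    cons = call_consequence(v, t, window)
    assert cons.kind is ConsequenceKind.STOP_GAINED
    assert cons.protein_change == "Tyr655Ter"
    assert cons.in_last_exon is False


def test_cds_start_boundary():
    rng = np.random.default_rng(3)
    cds = random_cds(rng, 40)
    t, window = make_transcript(cds, strand="+", exon_sizes=[60, 60], rng=rng)
    v = _snv_at_cds(t, window, 1, "C")  # A of ATG
    assert project_to_cds(v, t).cds_pos == 1
    assert call_consequence(v, t, window).kind is ConsequenceKind.START_LOST


def test_donor_splice_offset_five_and_default_splice_rule():
    # donor +5 variant after the exon ending at c.1036: splice placement,
    # and the reported MaxEnt pair 10.57 -> 8.38 stays below the damage rule
    rng = np.random.default_rng(11)
    cds = random_cds(rng, 400)
    t, window = make_transcript(cds, strand="+", exon_sizes=[1036, len(cds) - 1036],
                                intron_len=120, rng=rng)
    e1_end = t.exons[0][1]  # 0-based half-open
    pos = e1_end + 5  # 1-based intron +5
    ref = window.base_at(pos)
    alt = "A" if ref != "A" else "G"
    v = GenomicVariant(window.chrom, pos, ref, alt)
    placement = project_to_cds(v, t)
    assert placement.kind == "splice"
    assert placement.splice_site == "donor" and placement.splice_offset == 5
    cons = call_consequence(v, t, window)
    assert cons.kind is ConsequenceKind.SPLICE_REGION
    result = classify_variant(
        cons,
        EvidenceBundle(clinvar="Uncertain significance",
                       splice_ref=10.57, splice_alt=8.38),
    )
    assert result.klass is not Klass.PATHOGENIC
    assert result.klass is Klass.LIKELY_BENIGN


def test_acceptor_and_deep_intron_placement():
    rng = np.random.default_rng(13)
    cds = random_cds(rng, 60)
    t, window = make_transcript(cds, strand="+", exon_sizes=[90, 90],
                                intron_len=100, rng=rng)
    e1_end, e2_start = t.exons[0][1], t.exons[1][0]
    acc = GenomicVariant(window.chrom, e2_start, window.base_at(e2_start),
                         "A" if window.base_at(e2_start) != "A" else "C")
    p = project_to_cds(acc, t)
    assert p.kind == "splice" and p.splice_site == "acceptor" and p.splice_offset == -1
    mid = e1_end + 50
    deep = GenomicVariant(window.chrom, mid, window.base_at(mid),
                          "A" if window.base_at(mid) != "A" else "C")
    assert project_to_cds(deep, t).kind == "intronic"
    assert call_consequence(deep, t, window).kind is ConsequenceKind.INTRONIC


def test_last_exon_frameshift_delins_naming():
    # a 1->11 base replacement whose first touched codon is silent in the
    # mutant frame: the frameshift is named at the first diverging residue
    rng = np.random.default_rng(19)
    cds = _cds_with_codon(rng, 3380, 3364, "TCT")
    cds = cds[: 3 * 3365] + "AGC" + cds[3 * 3365 + 3 :]  # codon 3366 = Ser
    t, window = make_transcript(cds, strand="+",
                                exon_sizes=[9000, len(cds) - 9000], rng=rng)
    g0 = genomic_position_of_cds(t, 10095)
    v = GenomicVariant(window.chrom, g0 + 1, window.base_at(g0 + 1), "GAATTATATCT")
    cons = call_consequence(v, t, window)
    assert cons.kind is ConsequenceKind.FRAMESHIFT
    assert cons.in_last_exon is True
    assert cons.protein_change == "Ser3366fs"
    result = classify_variant(
        cons, EvidenceBundle(clinvar="Uncertain significance/benign/likely benign")
    )
    assert result.klass is Klass.LIKELY_BENIGN
    assert "TRUNCATING_LAST_EXON" in result.rule_trace


def test_error_contracts():
    rng = np.random.default_rng(23)
    cds = random_cds(rng, 40)
    t, window = make_transcript(cds, strand="+", exon_sizes=[120], rng=rng)
    with pytest.raises(OutOfTranscriptError):
        project_to_cds(GenomicVariant(window.chrom, window.end + 500, "A", "T"), t)
    g0 = genomic_position_of_cds(t, 10)
    wrong_ref = "A" if window.base_at(g0 + 1) != "A" else "C"
    alt = "G" if wrong_ref != "G" else "T"
    with pytest.raises(IntegrityError):
        call_consequence(GenomicVariant(window.chrom, g0 + 1, wrong_ref, alt), t, window)


# --- brute-force full-translation oracle ---

def oracle_snv_kind(v, t, window):
    mutated = (
        window.seq[: v.pos - window.start]
        + v.alt
        + window.seq[v.pos - window.start + 1 :]
    )
    w2 = ReferenceWindow(window.chrom, window.start, mutated)
    p_ref = str(Seq(cds_sequence(t, window)).translate())
    p_alt = str(Seq(cds_sequence(t, w2)).translate())
    if p_ref == p_alt:
        return ConsequenceKind.SYNONYMOUS
    i = next(k for k in range(len(p_ref)) if p_ref[k] != p_alt[k])
    if i == 0 and p_ref[0] == "M":
        return ConsequenceKind.START_LOST
    if p_alt[i] == "*":
        return ConsequenceKind.STOP_GAINED
    if p_ref[i] == "*":
        return ConsequenceKind.STOP_LOST
    return ConsequenceKind.MISSENSE


def _exonic_snvs(t, window, rng, limit=None):
    out = []
    for s, e in t.coding_intervals:
        for g0 in range(s, e):
            ref = window.base_at(g0 + 1)
            for alt in "ACGT":
                if alt != ref:
                    out.append(GenomicVariant(window.chrom, g0 + 1, ref, alt))
    if limit is not None and len(out) > limit:
        idx = rng.choice(len(out), size=limit, replace=False)
        out = [out[i] for i in sorted(idx)]
    return out


def test_snv_consequences_match_full_translation_oracle():
    from germtriage.simulate import simulate_transcripts

    rng = np.random.default_rng(101)
    for t, window in simulate_transcripts(6, seed=101):
        for v in _exonic_snvs(t, window, rng, limit=300):
            got = call_consequence(v, t, window)
            want = oracle_snv_kind(v, t, window)
            assert got.kind is want, (t.gene, t.strand, v)
            assert got.kind in {
                ConsequenceKind.STOP_GAINED, ConsequenceKind.MISSENSE,
                ConsequenceKind.SYNONYMOUS, ConsequenceKind.STOP_LOST,
                ConsequenceKind.START_LOST,
            }


def _mirror(t, window):
    """Reverse-complement the whole window and mirror the transcript."""
    from germtriage.models import TranscriptModel

    L = len(window.seq)
    s0 = window.start - 1  # 0-based window origin
    def flip(g):  # 0-based coordinate mirror within the window
        return s0 + (L - (g - s0))
    exons = tuple(sorted((flip(e), flip(s)) for s, e in t.exons))
    mt = TranscriptModel(
        gene=t.gene, transcript_id=t.transcript_id + "m",
        strand="-" if t.strand == "+" else "+",
        exons=exons, cds_start=flip(t.cds_end), cds_end=flip(t.cds_start),
        chrom=t.chrom,
    )
    mw = ReferenceWindow(window.chrom, window.start, revcomp(window.seq))
    return mt, mw


def test_strand_symmetry_under_mirroring():
    from germtriage.simulate import simulate_transcripts

    rng = np.random.default_rng(55)
    for t, window in simulate_transcripts(3, seed=55):
        mt, mw = _mirror(t, window)
        assert cds_sequence(mt, mw) == cds_sequence(t, window)
        for v in _exonic_snvs(t, window, rng, limit=60):
            g0 = v.pos - 1
            mpos = (window.start - 1) + (len(window.seq) - 1 - (g0 - (window.start - 1))) + 1
            mv = GenomicVariant(v.chrom, mpos, revcomp(v.ref), revcomp(v.alt))
            a = call_consequence(v, t, window)
            b = call_consequence(mv, mt, mw)
            assert a == b, (v, mv, a, b)
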