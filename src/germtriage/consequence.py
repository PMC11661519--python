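"""Transcript consequence engine.

Projects a genomic variant onto its gene's canonical transcript and
derives the molecular consequence (stop gained, frameshift, missense,
splice region, ...), including the last-coding-exon flag that the triage
rules need: truncating alleles confined to the final coding exon often
escape nonsense-mediated decay, so they are exempt from the automatic
pathogenic call.

Coordinate conventions: variants are 1-based genomic; CDS positions are
1-based in transcript (5'→3') orientation; exon intervals are 0-based
half-open genomic. For minus-strand transcripts alleles are
reverse-complemented during projection.

Protein descriptions are minimal HGVS-like names (three-letter residues,
``Ter`` for stops, ``fs`` for frameshifts). Frameshift names report the
first residue at which the mutant translation diverges from the
reference. Full HGVS grammar (3'-shifted protein names, extension
variants) is out of scope.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .models import GenomicVariant, ReferenceWindow, TranscriptModel


class IntegrityError(ValueError):
    """Reference sequence, transcript model and variant disagree."""


class OutOfTranscriptError(ValueError):
    """The variant does not overlap the transcript span."""


class ConsequenceKind(str, enum.Enum):
    STOP_GAINED = "stop_gained"
    FRAMESHIFT = "frameshift"
    INFRAME_DELETION = "inframe_deletion"
    INFRAME_INSERTION = "inframe_insertion"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    SPLICE_REGION = "splice_region"
    INTRONIC = "intronic"
    STOP_LOST = "stop_lost"
    START_LOST = "start_lost"


TRUNCATING_KINDS = frozenset({ConsequenceKind.STOP_GAINED, ConsequenceKind.FRAMESHIFT})


@dataclass(frozen=True)
class Consequence:
    kind: ConsequenceKind
    in_last_exon: Optional[bool] = None  # defined for stop_gained/frameshift only
    protein_change: Optional[str] = None
    cds_position: Optional[int] = None


@dataclass(frozen=True)
class Placement:
    """Where a variant lands on a transcript.

    ``kind`` is one of ``coding`` (``cds_pos`` set), ``splice``
    (``splice_site``/``splice_offset`` set; offsets are in transcript
    orientation, +1..+6 after a donor, −1/−2 before an acceptor),
    ``intronic`` or ``noncoding`` (exonic UTR).
    """

    kind: str
    cds_pos: Optional[int] = None
    splice_site: Optional[str] = None
    splice_offset: Optional[int] = None


_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# Donor window: intronic +1..+6 (captures the +5 position scored by
# maximum-entropy splice models); acceptor window: intronic −1..−2.
DONOR_INTRON_WINDOW = 6
ACCEPTOR_INTRON_WINDOW = 2


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _aa3(aa: str) -> str:
    return "Ter" if aa == "*" else seq3(aa)


def cds_position_of(t: TranscriptModel, g0: int) -> Optional[int]:
    """1-based CDS coordinate of 0-based genomic position ``g0``, or None."""
    consumed = 0
    intervals = t.coding_intervals
    if t.strand == "+":
        for s, e in intervals:
            if s <= g0 < e:
                return consumed + (g0 - s) + 1
            consumed += e - s
    else:
        for s, e in reversed(intervals):
            if s <= g0 < e:
                return consumed + (e - 1 - g0) + 1
            consumed += e - s
    return None


def genomic_position_of_cds(t: TranscriptModel, c: int) -> int:
    """0-based genomic position of 1-based CDS coordinate ``c``."""
    rem = c - 1
    intervals = t.coding_intervals
    if t.strand == "+":
        for s, e in intervals:
            if rem < e - s:
                return s + rem
            rem -= e - s
    else:
        for s, e in reversed(intervals):
            if rem < e - s:
                return e - 1 - rem
            rem -= e - s
    raise OutOfTranscriptError(f"CDS position {c} beyond CDS length {t.cds_len}")


def cds_sequence(t: TranscriptModel, window: ReferenceWindow) -> str:
    """Spliced coding sequence in transcript orientation."""
    parts = [window.slice(s + 1, e) for s, e in t.coding_intervals]
    seq = "".join(parts)
    return revcomp(seq) if t.strand == "-" else seq


def _is_exonic(t: TranscriptModel, g0: int) -> bool:
    return any(s <= g0 < e for s, e in t.exons)


def _splice_placement(t: TranscriptModel, g0: int) -> Optional[Placement]:
    """Splice placement for an intronic 0-based position, if in window."""
    for (s_prev, e_prev), (s_next, _) in zip(t.exons, t.exons[1:]):
        if e_prev <= g0 < s_next:
            if t.strand == "+":
                donor_off = g0 - e_prev + 1
                acceptor_off = g0 - s_next  # negative
            else:
                donor_off = s_next - g0
                acceptor_off = -(g0 - e_prev + 1)
            if 1 <= donor_off <= DONOR_INTRON_WINDOW:
                return Placement("splice", splice_site="donor", splice_offset=donor_off)
            if -ACCEPTOR_INTRON_WINDOW <= acceptor_off <= -1:
                return Placement(
                    "splice", splice_site="acceptor", splice_offset=acceptor_off
                )
            return None
    return None


def _affected_g0(v: GenomicVariant) -> range:
    """0-based genomic positions whose reference base is substituted/removed."""
    if len(v.ref) == 1 and len(v.alt) == 1:
        return range(v.pos - 1, v.pos)
    if v.ref[0] == v.alt[0]:
        if len(v.ref) > len(v.alt):  # anchored deletion
            return range(v.pos, v.end)
        # anchored insertion: no reference base substituted; use the anchor
        return range(v.pos - 1, v.pos)
    return range(v.pos - 1, v.end)  # delins


def project_to_cds(v: GenomicVariant, t: TranscriptModel) -> Placement:
    """Place a variant on the transcript: coding CDS coordinate, splice
    window with offset, plain intronic, or exonic-noncoding (UTR)."""
    span_s, span_e = t.span
    if v.end - 1 < span_s or v.pos - 1 >= span_e:
        raise OutOfTranscriptError(
            f"{v.chrom}:{v.pos} outside transcript {t.transcript_id}"
        )
    affected = list(_affected_g0(v))
    cds_hits = [cds_position_of(t, g) for g in affected]
    if all(c is not None for c in cds_hits):
        first = min(cds_hits)
        if len(v.ref) != len(v.alt) and v.ref[0] == v.alt[0] and len(v.alt) < len(v.ref):
            pass  # deletion: first is the first deleted base
        return Placement("coding", cds_pos=first)
    # not (fully) coding: check splice windows over affected positions
    splice = None
    for g in affected:
        if not _is_exonic(t, g):
            hit = _splice_placement(t, g)
            if hit is not None and (
                splice is None
                or abs(hit.splice_offset) < abs(splice.splice_offset)
            ):
                splice = hit
    if splice is not None:
        return splice
    if any(c is not None for c in cds_hits):
        # partially coding but outside any splice window: treat as splice
        # region conservatively (exon/intron boundary disruption)
        return Placement("splice", splice_site="donor", splice_offset=0)
    if all(_is_exonic(t, g) for g in affected):
        return Placement("noncoding")
    return Placement("intronic")


def _replacement_in_cds(v: GenomicVariant, t: TranscriptModel):
    """Express the variant as: replace CDS interval [c1, c2] by S (transcript
    orientation). Insertions use an empty interval (c1 = c2 + 1)."""
    minus = t.strand == "-"
    if len(v.ref) == 1 and len(v.alt) == 1:
        c = cds_position_of(t, v.pos - 1)
        s = revcomp(v.alt) if minus else v.alt
        return c, c, s
    if v.ref[0] == v.alt[0] and len(v.ref) > len(v.alt) == 1:  # anchored deletion
        cs = [cds_position_of(t, g) for g in range(v.pos, v.end)]
        if any(c is None for c in cs):
            raise IntegrityError("deletion extends outside the CDS")
        c1, c2 = min(cs), max(cs)
        if c2 - c1 + 1 != len(cs):
            raise IntegrityError("deletion spans an intron")
        return c1, c2, ""
    if v.ref[0] == v.alt[0] and len(v.alt) > len(v.ref) == 1:  # anchored insertion
        ins = v.alt[1:]
        if minus:
            anchor = cds_position_of(t, v.pos)  # genomic pos+1 precedes pos
            ins = revcomp(ins)
        else:
            anchor = cds_position_of(t, v.pos - 1)
        if anchor is None:
            raise IntegrityError("insertion anchor outside the CDS")
        return anchor + 1, anchor, ins
    # delins
    cs = [cds_position_of(t, g) for g in range(v.pos - 1, v.end)]
    if any(c is None for c in cs):
        raise IntegrityError("delins extends outside the CDS")
    c1, c2 = min(cs), max(cs)
    if c2 - c1 + 1 != len(cs):
        raise IntegrityError("delins spans an intron")
    s = revcomp(v.alt) if minus else v.alt
    return c1, c2, s


def _in_last_coding_exon(t: TranscriptModel, cds_pos: int) -> bool:
    """True when the first base of the codon containing ``cds_pos`` lies in
    the final coding exon (transcript orientation)."""
    codon_first = 3 * ((cds_pos - 1) // 3) + 1
    g0 = genomic_position_of_cds(t, codon_first)
    s, e = t.last_coding_interval()
    return s <= g0 < e


def _translate(seq: str) -> str:
    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate())


def call_consequence(
    v: GenomicVariant, t: TranscriptModel, window: ReferenceWindow
) -> Consequence:
    """Derive the molecular consequence of ``v`` on transcript ``t``.

    ``window`` must cover the transcript span with the reference
    sequence; a disagreement between the variant's ref allele and the
    window raises :class:`IntegrityError`.
    """
    observed = window.slice(v.pos, v.end)
    if observed != v.ref:
        raise IntegrityError(
            f"ref allele {v.ref!r} at {v.chrom}:{v.pos} does not match reference"
        )
    placement = project_to_cds(v, t)
    if placement.kind == "splice":
        return Consequence(ConsequenceKind.SPLICE_REGION)
    if placement.kind in ("intronic", "noncoding"):
        return Consequence(ConsequenceKind.INTRONIC)

    cds = cds_sequence(t, window)
    c1, c2, s = _replacement_in_cds(v, t)
    first_cds = min(c1, c2 + 1)
    net = len(s) - (c2 - c1 + 1)

    if len(v.ref) == 1 and len(v.alt) == 1:
        codon_idx = (c1 - 1) // 3
        offset = (c1 - 1) % 3
        codon = cds[3 * codon_idx : 3 * codon_idx + 3]
        if codon[offset] != s:
            mutant = codon[:offset] + s + codon[offset + 1 :]
        else:  # pragma: no cover - guarded by the ref check above
            raise IntegrityError("transcript/window inconsistency")
        ref_aa = _translate(codon)
        alt_aa = _translate(mutant)
        n = codon_idx + 1
        if codon_idx == 0 and codon == "ATG" and alt_aa != "M":
            return Consequence(
                ConsequenceKind.START_LOST, protein_change="Met1?", cds_position=c1
            )
        if ref_aa == alt_aa:
            return Consequence(
                ConsequenceKind.SYNONYMOUS,
                protein_change=f"{_aa3(ref_aa)}{n}=",
                cds_position=c1,
            )
        if alt_aa == "*":
            return Consequence(
                ConsequenceKind.STOP_GAINED,
                in_last_exon=_in_last_coding_exon(t, c1),
                protein_change=f"{_aa3(ref_aa)}{n}{_aa3(alt_aa)}",
                cds_position=c1,
            )
        if ref_aa == "*":
            return Consequence(
                ConsequenceKind.STOP_LOST,
                protein_change=f"Ter{n}{_aa3(alt_aa)}",
                cds_position=c1,
            )
        return Consequence(
            ConsequenceKind.MISSENSE,
            protein_change=f"{_aa3(ref_aa)}{n}{_aa3(alt_aa)}",
            cds_position=c1,
        )

    # indel / delins
    mutant_cds = cds[: c1 - 1] + s + cds[c2:]
    if net % 3 != 0:
        ref_protein = _translate(cds)
        mut_protein = _translate(mutant_cds)
        name_idx = (first_cds - 1) // 3
        for i, (ra, ma) in enumerate(zip(ref_protein, mut_protein)):
            if ra != ma:
                name_idx = i
                break
        ref_aa = ref_protein[name_idx] if name_idx < len(ref_protein) else "*"
        return Consequence(
            ConsequenceKind.FRAMESHIFT,
            in_last_exon=_in_last_coding_exon(t, first_cds),
            protein_change=f"{_aa3(ref_aa)}{name_idx + 1}fs",
            cds_position=first_cds,
        )
    if net < 0:
        ref_protein = _translate(cds)
        i1 = (c1 - 1) // 3
        i2 = (c2 - 1) // 3
        a1 = ref_protein[i1] if i1 < len(ref_protein) else "*"
        a2 = ref_protein[i2] if i2 < len(ref_protein) else "*"
        if i1 == i2:
            name = f"{_aa3(a1)}{i1 + 1}del"
        else:
            name = f"{_aa3(a1)}{i1 + 1}_{_aa3(a2)}{i2 + 1}del"
        return Consequence(
            ConsequenceKind.INFRAME_DELETION, protein_change=name, cds_position=first_cds
        )
    if net > 0:
        ref_protein = _translate(cds)
        i1 = (first_cds - 1) // 3
        a1 = ref_protein[i1] if i1 < len(ref_protein) else "*"
        name = f"{_aa3(a1)}{i1 + 1}ins"
        return Consequence(
            ConsequenceKind.INFRAME_INSERTION, protein_change=name, cds_position=first_cds
        )
    # length-preserving multi-base substitution
    ref_protein = _translate(cds)
    mut_protein = _translate(mutant_cds)
    if mut_protein == ref_protein:
        i1 = (c1 - 1) // 3
        return Consequence(
            ConsequenceKind.SYNONYMOUS,
            protein_change=f"{_aa3(ref_protein[i1])}{i1 + 1}=",
            cds_position=c1,
        )
    for i, (ra, ma) in enumerate(zip(ref_protein, mut_protein)):
        if ra != ma:
            if ma == "*":
                return Consequence(
                    ConsequenceKind.STOP_GAINED,
                    in_last_exon=_in_last_coding_exon(t, 3 * i + 1),
                    protein_change=f"{_aa3(ra)}{i + 1}Ter",
                    cds_position=c1,
                )
            return Consequence(
                ConsequenceKind.MISSENSE,
                protein_change=f"{_aa3(ra)}{i + 1}{_aa3(ma)}",
                cds_position=c1,
            )
    return Consequence(  # pragma: no cover - differences only past CDS end
        ConsequenceKind.SYNONYMOUS, protein_change=None, cds_position=c1
    )
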