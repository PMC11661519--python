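"""Core domain types for the panel triage pipeline.

All variant coordinates are 1-based GRCh37 positions (VCF convention);
exon intervals inside :class:`TranscriptModel` are 0-based half-open.
Conversion from 1-based interval files happens in the readers.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

_BASES = frozenset("ACGT")

# Fixed panel vocabulary: 12 homology-directed-repair genes and the
# mismatch-repair(-related) genes screened alongside them.
HDR_GENES = frozenset(
    {
        "BARD1", "BRCA1", "BRCA2", "BRIP1", "ERCC4", "FANCM",
        "PALB2", "RAD51", "RAD51B", "RAD51C", "RAD51D", "SLX4",
    }
)
MMR_GENES = frozenset({"MLH1", "MSH2", "MSH6", "PMS2", "MUTYH"})
PANEL_GENES = HDR_GENES | MMR_GENES


def pathway_of(gene: str) -> str:
    """Map a panel gene symbol to its repair pathway label."""
    if gene in HDR_GENES:
        return "HDR"
    if gene in MMR_GENES:
        return "MMR"
    return "other"


class VariantClass(str, enum.Enum):
    SNV = "SNV"
    INSERTION = "insertion"
    DELETION = "deletion"
    DELINS = "delins"


def infer_variant_class(ref: str, alt: str) -> VariantClass:
    if len(ref) == 1 and len(alt) == 1:
        return VariantClass.SNV
    if len(ref) < len(alt) and alt.startswith(ref):
        return VariantClass.INSERTION
    if len(ref) > len(alt) and ref.startswith(alt):
        return VariantClass.DELETION
    return VariantClass.DELINS


@dataclass(frozen=True)
class GenomicVariant:
    """One allele substitution or indel on the forward genomic strand."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    variant_class: VariantClass = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        for allele in (self.ref, self.alt):
            if not set(allele) <= _BASES:
                raise ValueError(f"allele {allele!r} not over ACGT")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.variant_class is None:
            object.__setattr__(
                self, "variant_class", infer_variant_class(self.ref, self.alt)
            )

    @property
    def key(self) -> tuple:
        """Join key used to match annotation rows: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def end(self) -> int:
        """Last reference base touched (1-based inclusive)."""
        return self.pos + len(self.ref) - 1


@dataclass(frozen=True)
class ReferenceWindow:
    """A slice of reference sequence anchored at a 1-based genomic start."""

    chrom: str
    start: int  # 1-based position of seq[0]
    seq: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError("window start must be >= 1")
        if not set(self.seq) <= _BASES:
            raise ValueError("window sequence must be over ACGT")

    @property
    def end(self) -> int:
        return self.start + len(self.seq) - 1

    def base_at(self, pos: int) -> str:
        if not self.start <= pos <= self.end:
            raise IndexError(f"position {pos} outside window {self.start}-{self.end}")
        return self.seq[pos - self.start]

    def slice(self, start: int, end: int) -> str:
        """Sequence for 1-based inclusive [start, end]."""
        if not (self.start <= start and end <= self.end and start <= end + 1):
            raise IndexError(f"[{start},{end}] outside window {self.start}-{self.end}")
        return self.seq[start - self.start : end - self.start + 1]


@dataclass(frozen=True)
class TranscriptModel:
    """Canonical transcript: stranded exon/CDS structure on the genome.

    ``exons`` are 0-based half-open genomic intervals sorted by position;
    ``cds_start``/``cds_end`` bound the translated region (half-open) and
    must fall inside exons. One canonical transcript per gene.
    """

    gene: str
    transcript_id: str
    strand: str
    exons: tuple
    cds_start: int
    cds_end: int
    chrom: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = -1
        for s, e in exons:
            if s >= e:
                raise ValueError(f"empty/inverted exon ({s},{e})")
            if s < prev_end:
                raise ValueError("exons overlap or are unsorted")
            prev_end = e
        if not (self.cds_start < self.cds_end):
            raise ValueError("cds_start must be < cds_end")
        if not any(s <= self.cds_start < e for s, e in exons):
            raise ValueError("cds_start not inside an exon")
        if not any(s < self.cds_end <= e for s, e in exons):
            raise ValueError("cds_end not inside an exon")
        if self.cds_len % 3 != 0:
            raise ValueError(f"CDS length {self.cds_len} not divisible by 3")

    @property
    def coding_intervals(self) -> tuple:
        """Exon intervals clipped to the CDS, in genomic order (0-based half-open)."""
        out = []
        for s, e in self.exons:
            cs, ce = max(s, self.cds_start), min(e, self.cds_end)
            if cs < ce:
                out.append((cs, ce))
        return tuple(out)

    @property
    def cds_len(self) -> int:
        return sum(e - s for s, e in self.coding_intervals)

    @property
    def span(self) -> tuple:
        """Genomic transcript span, 0-based half-open."""
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def n_coding_exons(self) -> int:
        return len(self.coding_intervals)

    def last_coding_interval(self) -> tuple:
        """The final coding exon in transcript (5'→3') orientation."""
        ivals = self.coding_intervals
        return ivals[-1] if self.strand == "+" else ivals[0]


NOT_LISTED = "Not listed"


@dataclass(frozen=True)
class EvidenceBundle:
    """Per-variant evidence consumed by the triage rules.

    ``esm1b`` is a log-likelihood-ratio-style score where more negative
    means more damaging; ``alphamissense`` is a pathogenicity probability
    in [0, 1]; ``splice_ref``/``splice_alt`` are maximum-entropy splice
    model scores for the reference and alternate alleles. ``None`` marks
    evidence that is absent for the variant (e.g. AlphaMissense for
    indels). An unknown MAF is treated downstream as rare.
    """

    clinvar: str = NOT_LISTED
    maf: Optional[float] = None
    esm1b: Optional[float] = None
    alphamissense: Optional[float] = None
    splice_ref: Optional[float] = None
    splice_alt: Optional[float] = None

    def __post_init__(self) -> None:
        if self.maf is not None and not 0.0 <= self.maf <= 1.0:
            raise ValueError(f"maf {self.maf} outside [0,1]")
        if self.alphamissense is not None and not 0.0 <= self.alphamissense <= 1.0:
            raise ValueError(f"alphamissense {self.alphamissense} outside [0,1]")


class Histology(str, enum.Enum):
    SQUAMOUS = "squamous"
    ADENOCARCINOMA = "adenocarcinoma"
    OTHER = "other"


class HpvStatus(str, enum.Enum):
    HPV16 = "HPV16"
    HPV18 = "HPV18"
    OTHER_POSITIVE = "other_positive"
    NEGATIVE = "negative"


class Stage(str, enum.Enum):
    DYSPLASIA = "dysplasia"
    INVASIVE = "invasive"


@dataclass
class PatientRecord:
    """One phenotype row plus the identifiers of variants the patient carries."""

    patient_id: str
    age: float
    histology: Histology
    hpv: HpvStatus
    stage: Stage
    variants: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError(f"age must be positive, got {self.age}")
        self.histology = Histology(self.histology)
        self.hpv = HpvStatus(self.hpv)
        self.stage = Stage(self.stage)


@dataclass(frozen=True)
class ControlSummary:
    """Carrier count for one gene in an external control population."""

    gene: str
    carriers: int
    total: int

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError("control total must be positive")
        if not 0 <= self.carriers <= self.total:
            raise ValueError("carriers must be in [0, total]")
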