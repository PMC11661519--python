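"""Seeded synthetic-data generator for the whole pipeline.

Emulates the study's five inputs — transcript models with reference
sequence, variant calls, per-variant evidence, patient phenotypes, and
external control carrier summaries — with planted statistical structure:
a configurable baseline carrier rate, an odds ratio linking
homology-directed-repair (HDR) carrier status to HPV18-positive disease,
and an odds ratio linking mismatch-repair (MMR) carrier status to
adenocarcinoma. Carrier phenotypes follow a logistic model whose
intercept is solved numerically so the marginal carrier frequency equals
the configured rate.

All randomness flows through one seed; each stage draws from its own
labelled substream, so adding a stage never perturbs the draws of
earlier stages. A fixed seed reproduces every output byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from . import io as gio
from .consequence import (
    ConsequenceKind,
    IntegrityError,
    OutOfTranscriptError,
    call_consequence,
    cds_sequence,
    genomic_position_of_cds,
    revcomp,
)
from .normalize import normalize_variant
from .models import (
    EvidenceBundle,
    GenomicVariant,
    Histology,
    HpvStatus,
    PatientRecord,
    ReferenceWindow,
    Stage,
    TranscriptModel,
    HDR_GENES,
    MMR_GENES,
)
from .triage import DEFAULT_CONFIG, Klass, classify_variant

_STAGE_SUBSTREAM = {"transcripts": 1, "variants": 2, "patients": 3, "controls": 4}

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"

# Default class mix mirrors the study's rare-variant spectrum: ~65 rare
# variants of which 23 pathogenic/likely pathogenic, 10 ambiguous and
# the rest benign/likely benign.
DEFAULT_CLASS_MIX: Dict[str, float] = {
    "pathogenic": 16 / 65,
    "likely_pathogenic": 7 / 65,
    "ambiguous": 10 / 65,
    "likely_benign": 28 / 65,
    "benign": 2 / 65,
    "excluded_common": 2 / 65,
}


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STAGE_SUBSTREAM[stage]])


@dataclass
class SimulationConfig:
    """Study-scale defaults: 728 patients, 4.0% overall carrier rate split
    2.6% HDR / 1.4% MMR, an invasive-enriched stage mix, and HPV/histology
    distributions typical of a European cervical cancer series."""

    n_patients: int = 728
    histology_probs: Dict[str, float] = field(
        default_factory=lambda: {"squamous": 0.76, "adenocarcinoma": 0.19, "other": 0.05}
    )
    hpv_probs: Dict[str, float] = field(
        default_factory=lambda: {
            "HPV16": 0.55, "HPV18": 0.15, "other_positive": 0.22, "negative": 0.08,
        }
    )
    stage_probs: Dict[str, float] = field(
        default_factory=lambda: {"dysplasia": 0.25, "invasive": 0.75}
    )
    hdr_carrier_rate: float = 0.026
    mmr_carrier_rate: float = 0.014
    planted_or_hpv18: float = 3.0
    planted_or_adeno_mmr: float = 4.0
    age_carrier: Tuple[float, float] = (44.0, 11.0)
    age_noncarrier: Tuple[float, float] = (47.3, 11.0)
    class_mix: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    n_variants: int = 65
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("histology_probs", "hpv_probs", "stage_probs"):
            probs = getattr(self, name)
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if self.planted_or_hpv18 <= 0 or self.planted_or_adeno_mmr <= 0:
            raise ValueError("planted odds ratios must be positive")


# ---------------------------------------------------------------------------
# Transcripts

def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random internal codons (no stops) + one stop codon."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(list(_BASES), size=3))
        if c not in _STOPS:
            codons.append(c)
    codons.append(str(rng.choice(sorted(_STOPS))))
    return "".join(codons)


def simulate_transcripts(
    n_genes: int,
    exon_count_range: Tuple[int, int] = (2, 5),
    seed: int = 0,
    n_codons_range: Tuple[int, int] = (60, 200),
    gene_names: Optional[Sequence[str]] = None,
) -> List[Tuple[TranscriptModel, ReferenceWindow]]:
    """Generate valid transcript models (both strands, CDS divisible by 3,
    no internal stop) together with consistent reference windows. Each
    gene sits on its own synthetic contig."""
    rng = _stage_rng(seed, "transcripts")
    out = []
    for gi in range(n_genes):
        gene = gene_names[gi] if gene_names else f"GENE{gi + 1:02d}"
        chrom = f"sim{gi + 1}"
        n_exons = int(rng.integers(exon_count_range[0], exon_count_range[1] + 1))
        n_codons = int(rng.integers(n_codons_range[0], n_codons_range[1] + 1))
        cds = _random_cds(rng, n_codons)
        # split the CDS into n_exons chunks, each at least 12 bases
        L = len(cds)
        while True:
            cuts = sorted(rng.integers(12, L - 12, size=n_exons - 1).tolist()) if n_exons > 1 else []
            sizes = np.diff([0] + cuts + [L])
            if (sizes >= 12).all():
                break
        chunks = []
        off = 0
        for sz in sizes:
            chunks.append(cds[off : off + int(sz)])
            off += int(sz)
        strand = "+" if rng.random() < 0.5 else "-"
        genomic_chunks = chunks if strand == "+" else [revcomp(c) for c in reversed(chunks)]
        start0 = 1000  # arbitrary genomic anchor
        pieces = []
        exons = []
        cursor = start0
        for i, chunk in enumerate(genomic_chunks):
            if i > 0:
                intron_len = int(rng.integers(20, 200))
                intron = "".join(rng.choice(list(_BASES), size=intron_len))
                pieces.append(intron)
                cursor += intron_len
            exons.append((cursor, cursor + len(chunk)))
            pieces.append(chunk)
            cursor += len(chunk)
        seq = "".join(pieces)
        t = TranscriptModel(
            gene=gene,
            transcript_id=f"SIM_{gene}.1",
            strand=strand,
            exons=tuple(exons),
            cds_start=exons[0][0],
            cds_end=exons[-1][1],
            chrom=chrom,
        )
        window = ReferenceWindow(chrom=chrom, start=start0 + 1, seq=seq)
        assert cds_sequence(t, window) == cds
        out.append((t, window))
    return out


# ---------------------------------------------------------------------------
# Variants with intended triage classes

def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, low=-np.inf, high=np.inf
) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if low < x <= high:
            return float(x)
    return float(min(max(mean, low + sd * 1e-3), high))


def _pathogenic_scores(rng) -> Dict[str, float]:
    return {
        "esm1b": _truncated_normal(rng, -15.0, 2.0, high=-10.0),
        "alphamissense": _truncated_normal(rng, 0.92, 0.04, low=0.8, high=1.0),
    }


def _benign_scores(rng) -> Dict[str, float]:
    return {
        "esm1b": _truncated_normal(rng, -5.0, 2.0, low=-10.0 + 1e-9, high=np.inf),
        "alphamissense": _truncated_normal(rng, 0.3, 0.15, low=0.0, high=0.8),
    }


def _variant_at_cds(
    t: TranscriptModel, window: ReferenceWindow, c: int, alt_transcript_base: str
) -> GenomicVariant:
    """SNV at CDS position ``c`` whose transcript-strand alt base is given."""
    g0 = genomic_position_of_cds(t, c)
    ref = window.base_at(g0 + 1)
    alt = alt_transcript_base if t.strand == "+" else revcomp(alt_transcript_base)
    return GenomicVariant(window.chrom, g0 + 1, ref, alt)


def _single_base_deletion(
    t: TranscriptModel, window: ReferenceWindow, c: int
) -> GenomicVariant:
    """Anchored deletion of the single genomic base at CDS position ``c``."""
    g0 = genomic_position_of_cds(t, c)
    anchor = window.base_at(g0)  # genomic base before the deleted one
    deleted = window.base_at(g0 + 1)
    return GenomicVariant(window.chrom, g0, anchor + deleted, anchor)


def _codon_exon_index(t: TranscriptModel, codon_idx: int) -> int:
    """Index (transcript orientation) of the coding exon holding the codon start."""
    g0 = genomic_position_of_cds(t, 3 * codon_idx + 1)
    ivals = t.coding_intervals if t.strand == "+" else tuple(reversed(t.coding_intervals))
    for i, (s, e) in enumerate(ivals):
        if s <= g0 < e:
            return i
    raise ValueError("codon outside coding intervals")


def _pick_stop_snv(t, window, rng, want_last_exon: bool):
    cds = cds_sequence(t, window)
    n_codons = len(cds) // 3
    last = t.n_coding_exons - 1
    order = rng.permutation(np.arange(1, n_codons - 1))
    for ci in order:
        in_last = _codon_exon_index(t, int(ci)) == last
        if in_last != want_last_exon:
            continue
        codon = cds[3 * ci : 3 * ci + 3]
        for stop in sorted(_STOPS):
            diff = [k for k in range(3) if codon[k] != stop[k]]
            if len(diff) == 1:
                c = 3 * int(ci) + diff[0] + 1
                return _variant_at_cds(t, window, c, stop[diff[0]])
    return None


def _pick_frameshift(t, window, rng, want_last_exon: bool):
    cds = cds_sequence(t, window)
    n_codons = len(cds) // 3
    last = t.n_coding_exons - 1
    order = rng.permutation(np.arange(2, n_codons - 1))
    for ci in order:
        if (_codon_exon_index(t, int(ci)) == last) != want_last_exon:
            continue
        c = 3 * int(ci) + 1
        g0 = genomic_position_of_cds(t, c)
        if g0 < window.start:  # need an anchor base
            continue
        # the anchor must not sit beyond the window or inside an intron gap
        # for identity purposes; a genomic-anchor deletion is always valid
        v = _single_base_deletion(t, window, c)
        # ensure the deletion does not silently shift out of the CDS when
        # normalized; accept as-is (classification uses raw placement)
        return v
    return None


def _pick_coding_snv(t, window, rng, want: str):
    """want: 'missense' or 'synonymous'."""
    from Bio.Seq import Seq

    cds = cds_sequence(t, window)
    n_codons = len(cds) // 3
    order = rng.permutation(np.arange(1, n_codons - 1))
    for ci in order:
        codon = cds[3 * ci : 3 * ci + 3]
        ref_aa = str(Seq(codon).translate())
        for k in rng.permutation(3):
            for b in _BASES:
                if b == codon[k]:
                    continue
                mut = codon[:k] + b + codon[k + 1 :]
                if mut in _STOPS:
                    continue
                alt_aa = str(Seq(mut).translate())
                if want == "missense" and alt_aa != ref_aa:
                    return _variant_at_cds(t, window, 3 * int(ci) + int(k) + 1, b)
                if want == "synonymous" and alt_aa == ref_aa:
                    return _variant_at_cds(t, window, 3 * int(ci) + int(k) + 1, b)
    return None


def _pick_donor_splice(t, window, rng, offset: int = 5):
    """SNV at intron position +``offset`` after a random donor site."""
    if len(t.exons) < 2:
        return None
    pairs = list(zip(t.exons, t.exons[1:]))
    for idx in rng.permutation(len(pairs)):
        (s_prev, e_prev), (s_next, _) = pairs[idx]
        if s_next - e_prev <= offset + 1:
            continue
        g0 = (e_prev + offset - 1) if t.strand == "+" else (s_next - offset)
        ref = window.base_at(g0 + 1)
        alt = next(b for b in _BASES if b != ref)
        return GenomicVariant(window.chrom, g0 + 1, ref, alt)
    return None


def simulate_variants(
    transcripts: List[Tuple[TranscriptModel, ReferenceWindow]],
    class_mix: Optional[Dict[str, float]] = None,
    seed: int = 0,
    n_variants: int = 65,
) -> List[dict]:
    """Generate variants + evidence whose triage classes realize ``class_mix``.

    Returns records with keys ``variant_id``, ``gene``, ``variant``
    (:class:`GenomicVariant`), ``evidence``, ``consequence`` (computed
    by the consequence engine) and ``intended_class`` (hidden truth).
    Generated evidence is consistent with the intended class under the
    default triage configuration.
    """
    if class_mix is None:
        class_mix = dict(DEFAULT_CLASS_MIX)
    total = sum(class_mix.values())
    rng = _stage_rng(seed, "variants")
    # integer allocation by largest remainder
    raw = {k: v / total * n_variants for k, v in class_mix.items()}
    alloc = {k: int(np.floor(r)) for k, r in raw.items()}
    rem = n_variants - sum(alloc.values())
    for k in sorted(raw, key=lambda k: raw[k] - alloc[k], reverse=True)[:rem]:
        alloc[k] += 1

    seen = set()
    records: List[dict] = []
    for intended, count in alloc.items():
        made = 0
        attempts = 0
        while made < count and attempts < 200 * max(count, 1):
            attempts += 1
            t, window = transcripts[int(rng.integers(len(transcripts)))]
            v = None
            kwargs: Dict[str, object] = {}
            if intended == "pathogenic":
                if rng.random() < 0.5:
                    v = _pick_stop_snv(t, window, rng, want_last_exon=False)
                else:
                    v = _pick_frameshift(t, window, rng, want_last_exon=False)
                if v is not None and rng.random() < 0.5:
                    kwargs["clinvar"] = "Pathogenic"
            elif intended == "likely_pathogenic":
                if rng.random() < 0.2:
                    v = _pick_donor_splice(t, window, rng)
                    if v is not None:
                        ref_score = _truncated_normal(rng, 10.0, 1.5, low=5.0)
                        kwargs.update(
                            splice_ref=ref_score,
                            splice_alt=_truncated_normal(rng, -3.0, 2.0, high=-0.01),
                            clinvar="Uncertain significance",
                        )
                else:
                    v = _pick_coding_snv(t, window, rng, "missense")
                    if v is not None:
                        kwargs.update(_pathogenic_scores(rng))
                        kwargs["clinvar"] = (
                            "Uncertain significance" if rng.random() < 0.5 else ""
                        )
            elif intended == "ambiguous":
                v = _pick_coding_snv(t, window, rng, "missense")
                if v is not None:
                    if rng.random() < 0.5:
                        kwargs["esm1b"] = _truncated_normal(rng, -15.0, 2.0, high=-10.0)
                        kwargs["alphamissense"] = _truncated_normal(rng, 0.3, 0.15, 0.0, 0.8)
                    else:
                        kwargs["esm1b"] = _truncated_normal(rng, -5.0, 2.0, low=-10.0 + 1e-9)
                        kwargs["alphamissense"] = _truncated_normal(rng, 0.92, 0.04, 0.8, 1.0)
                    kwargs["clinvar"] = "Uncertain significance"
            elif intended == "likely_benign":
                u = rng.random()
                if u < 0.15:
                    v = _pick_coding_snv(t, window, rng, "synonymous")
                elif u < 0.3:
                    v = _pick_frameshift(t, window, rng, want_last_exon=True)
                elif u < 0.4:
                    v = _pick_donor_splice(t, window, rng)
                    if v is not None:
                        ref_score = _truncated_normal(rng, 10.0, 1.5, low=5.0)
                        kwargs.update(
                            splice_ref=ref_score,
                            splice_alt=ref_score * float(rng.uniform(0.6, 0.95)),
                        )
                else:
                    v = _pick_coding_snv(t, window, rng, "missense")
                    if v is not None:
                        kwargs.update(_benign_scores(rng))
                        kwargs["clinvar"] = "Uncertain significance"
            elif intended == "benign":
                v = _pick_coding_snv(t, window, rng, "missense")
                if v is not None:
                    kwargs["clinvar"] = "Benign/likely benign"
            elif intended == "excluded_common":
                v = _pick_coding_snv(t, window, rng, "missense")
                if v is not None:
                    kwargs["maf"] = float(rng.uniform(0.005, 0.05))
            else:
                raise ValueError(f"unknown intended class {intended!r}")
            if v is None:
                continue
            try:  # keep identities in minimal left-aligned form
                v = normalize_variant(v, window)
            except (ValueError, IndexError):
                continue
            if v.key in seen:
                continue
            evidence = EvidenceBundle(**kwargs)  # type: ignore[arg-type]
            try:
                cons = call_consequence(v, t, window)
            except (IntegrityError, OutOfTranscriptError):
                continue
            got = classify_variant(cons, evidence, DEFAULT_CONFIG).klass
            if got.value != intended:
                continue  # retry with a fresh draw
            seen.add(v.key)
            records.append(
                {
                    "variant_id": f"{t.gene}:{v.chrom}:{v.pos}:{v.ref}>{v.alt}",
                    "gene": t.gene,
                    "variant": v,
                    "evidence": evidence,
                    "consequence": cons,
                    "intended_class": intended,
                }
            )
            made += 1
        if made < count:
            raise RuntimeError(
                f"could not realize {count} variants of class {intended!r}"
            )
    return records


# ---------------------------------------------------------------------------
# Patients

def _solve_intercept(x: np.ndarray, log_or: float, target_rate: float) -> float:
    """Intercept of logit P(carrier) = b0 + log_or * x with the requested
    marginal carrier frequency over the realized covariates."""

    def gap(b0: float) -> float:
        return float(np.mean(expit(b0 + log_or * x))) - target_rate

    return float(brentq(gap, -30.0, 10.0))


def simulate_patients(
    cfg: SimulationConfig, variants: List[dict], seed: Optional[int] = None
) -> Tuple[List[PatientRecord], Dict[str, dict]]:
    """Draw phenotypes and carrier assignments with the planted structure.

    HDR carrier status follows a logistic model on HPV18 positivity with
    odds ratio ``planted_or_hpv18``; MMR carrier status follows one on
    adenocarcinoma histology with ``planted_or_adeno_mmr``. Intercepts
    are solved so marginal carrier rates match the configured ones. Each
    carrier receives one pathogenic/likely-pathogenic variant from the
    matching pathway; remaining variants are scattered on random
    patients. Returns patients and a truth record.
    """
    if seed is None:
        seed = cfg.seed
    rng = _stage_rng(seed, "patients")
    n = cfg.n_patients
    if n == 0:
        return [], {"hdr_carriers": [], "mmr_carriers": []}

    def draw(probs: Dict[str, float]) -> np.ndarray:
        keys = list(probs)
        return rng.choice(keys, size=n, p=[probs[k] for k in keys])

    histology = draw(cfg.histology_probs)
    hpv = draw(cfg.hpv_probs)
    stage = draw(cfg.stage_probs)

    plp = {"pathogenic", "likely_pathogenic"}
    hdr_vars = [r for r in variants if r["gene"].split(":")[0] and r["intended_class"] in plp
                and _pathway(r["gene"]) == "HDR"]
    mmr_vars = [r for r in variants if r["intended_class"] in plp
                and _pathway(r["gene"]) == "MMR"]

    carriers: Dict[str, np.ndarray] = {}
    for label, rate, log_or, x in (
        ("hdr", cfg.hdr_carrier_rate, np.log(cfg.planted_or_hpv18), (hpv == "HPV18").astype(float)),
        ("mmr", cfg.mmr_carrier_rate, np.log(cfg.planted_or_adeno_mmr), (histology == "adenocarcinoma").astype(float)),
    ):
        if rate <= 0:
            carriers[label] = np.zeros(n, bool)
            continue
        b0 = _solve_intercept(x, log_or, rate)
        carriers[label] = rng.random(n) < expit(b0 + log_or * x)

    assignments: Dict[int, List[str]] = {}
    for label, pool in (("hdr", hdr_vars), ("mmr", mmr_vars)):
        idx = np.flatnonzero(carriers[label])
        if len(idx) and not pool:
            raise RuntimeError(f"no {label.upper()} pathogenic variants to assign")
        for i in idx:
            rec = pool[int(rng.integers(len(pool)))]
            assignments.setdefault(int(i), []).append(rec["variant_id"])
    # scatter non-pathogenic variants one patient each (background carriage)
    for rec in variants:
        if rec["intended_class"] not in plp:
            i = int(rng.integers(n))
            assignments.setdefault(i, []).append(rec["variant_id"])

    any_carrier = carriers["hdr"] | carriers["mmr"]
    mu_c, sd_c = cfg.age_carrier
    mu_n, sd_n = cfg.age_noncarrier
    ages = np.where(any_carrier, rng.normal(mu_c, sd_c, n), rng.normal(mu_n, sd_n, n))
    ages = np.clip(ages, 18.0, 95.0).round(1)

    patients = [
        PatientRecord(
            patient_id=f"S{i + 1:04d}",
            age=float(ages[i]),
            histology=Histology(histology[i]),
            hpv=HpvStatus(hpv[i]),
            stage=Stage(stage[i]),
            variants=assignments.get(i, []),
        )
        for i in range(n)
    ]
    truth = {
        "hdr_carriers": [f"S{i + 1:04d}" for i in np.flatnonzero(carriers["hdr"])],
        "mmr_carriers": [f"S{i + 1:04d}" for i in np.flatnonzero(carriers["mmr"])],
    }
    return patients, truth


def _pathway(gene: str) -> str:
    if gene in HDR_GENES:
        return "HDR"
    if gene in MMR_GENES:
        return "MMR"
    # synthetic genes alternate pathways by their numeric suffix
    digits = "".join(ch for ch in gene if ch.isdigit())
    return "HDR" if not digits or int(digits) % 3 else "MMR"


# ---------------------------------------------------------------------------
# Controls

def simulate_control_summary(
    genes: Sequence[str],
    carrier_freqs: Dict[str, float],
    n_controls: int,
    seed: int = 0,
):
    """Binomial carrier counts per gene for a control population."""
    from .models import ControlSummary

    rng = _stage_rng(seed, "controls")
    out = []
    for g in genes:
        f = carrier_freqs.get(g, 0.0)
        carriers = int(rng.binomial(n_controls, f))
        out.append(ControlSummary(gene=g, carriers=carriers, total=n_controls))
    return out


# ---------------------------------------------------------------------------
# Full bundle

def simulate_bundle(cfg: SimulationConfig, out_dir) -> Dict[str, str]:
    """Write a complete synthetic input bundle in the pipeline's dialects.

    Emits: ``calls.vcf``, ``transcripts.tsv``, ``annotations.tsv``,
    ``phenotypes.tsv``, ``controls.tsv``, ``reference.tsv`` (per-contig
    reference windows) and ``truth.json`` (hidden labels, for tests
    only). Deterministic for a fixed config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_genes = max(4, min(12, cfg.n_variants // 6 + 2))
    transcripts = simulate_transcripts(n_genes, seed=cfg.seed)
    variants = simulate_variants(
        transcripts, cfg.class_mix, seed=cfg.seed, n_variants=cfg.n_variants
    )
    patients, truth = simulate_patients(cfg, variants)

    by_id = {r["variant_id"]: r for r in variants}
    entries = []
    for p in patients:
        for vid in p.variants:
            entries.append((p.patient_id, by_id[vid]["variant"]))
    gio.write_vcf(entries, out / "calls.vcf")
    gio.write_transcripts([t for t, _ in transcripts], out / "transcripts.tsv")
    gio.write_annotation_table(
        {r["variant"].key: r["evidence"] for r in variants}, out / "annotations.tsv"
    )
    gio.write_phenotypes(patients, out / "phenotypes.tsv")
    freqs = {t.gene: 0.002 for t, _ in transcripts}
    gio.write_control_summary(
        simulate_control_summary([t.gene for t, _ in transcripts], freqs, 100_000, cfg.seed),
        out / "controls.tsv",
    )
    ref_rows = ["chrom\tstart\tseq"]
    for _, w in transcripts:
        ref_rows.append(f"{w.chrom}\t{w.start}\t{w.seq}")
    (out / "reference.tsv").write_text("\n".join(ref_rows) + "\n")
    truth_full = {
        **truth,
        "intended_classes": {r["variant_id"]: r["intended_class"] for r in variants},
    }
    (out / "truth.json").write_text(json.dumps(truth_full, indent=1, sort_keys=True))
    return {name: str(out / name) for name in (
        "calls.vcf", "transcripts.tsv", "annotations.tsv", "phenotypes.tsv",
        "controls.tsv", "reference.tsv", "truth.json",
    )}


def read_reference_windows(path) -> Dict[str, ReferenceWindow]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    return {
        r.chrom: ReferenceWindow(r.chrom, int(r.start), r.seq)
        for r in df.itertuples(index=False)
    }
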