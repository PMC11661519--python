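# Methods

## Scope and data model

The package models a targeted-panel germline study downstream of variant
calling: inputs are per-patient calls (VCF, GRCh37), a per-variant
evidence table (ClinVar assertion string, population minor allele
frequency, ESM1b score, AlphaMissense score, reference/alternate splice
scores), one canonical transcript per gene (flat TSV with exon/CDS
coordinates; an optional `chrom` column ties a transcript to its
contig), a phenotype table (age at diagnosis, histology, HPV type,
dysplasia vs. invasive), and per-gene control carrier summaries
emulating biobank-scale populations. Alignment, genotype calling,
build liftover, multi-transcript annotation and PMS2 pseudogene
disambiguation (beyond the frequency filter) are out of scope.

Variants are stored 1-based (VCF convention) with alleles on the
forward genomic strand; exon intervals are 0-based half-open and the
conversion is confined to the transcript reader. The join key between
calls and evidence is the normalized tuple (chrom, pos, ref, alt):
variants are reduced to minimal left-aligned form by the standard
trim-and-shift algorithm (as in `vt normalize`), which is idempotent and
never shifts a representation rightward. Genotypes are used only for
allele presence; zygosity is not modelled (het/hom distinctions carry no
weight in any downstream rule).

## Consequence engine

A variant is projected onto its gene's canonical transcript:
coding positions map to 1-based CDS coordinates (alleles are
reverse-complemented for minus-strand transcripts); intronic positions
within +1..+6 of a donor or −1..−2 of an acceptor are splice placements
with a signed offset; other intronic or exonic-noncoding positions fall
back to an intronic call. The donor window extends to +6 so that
positions routinely scored by maximum-entropy splice models (such as a
+5 substitution) are captured; exonic bases near junctions keep their
coding consequence, since the classification tiers treat coding evidence
as primary.

Coding SNVs are judged on the affected codon: stop gained, stop lost,
start lost (a disrupted ATG at codon 1), synonymous, or missense.
Indels are frameshift when the net length change is not a multiple of
three, otherwise in-frame deletion/insertion; length-preserving
multi-base substitutions are translated and compared. The
`in_last_exon` flag — defined only for stop-gained and frameshift
variants — is true when the first base of the first affected codon lies
in the final coding exon in transcript orientation. The 50-bp
penultimate-exon NMD-escape refinement is deliberately not applied: the
procedure modelled here uses the last-exon criterion only.

Protein descriptions are minimal HGVS-like names (`Gln564Ter`,
`Ser3366fs`, `Asn1322del`). Frameshifts are named at the first residue
where the mutant translation diverges from the reference (so an indel
whose first touched codon is preserved in the new frame is named one
residue downstream); full HGVS grammar (3'-shifted protein names,
extension variants) is out of scope. Correctness of the consequence
kinds is checked against an independent brute-force oracle that rebuilds
the mutant genome, re-extracts and translates the whole CDS, and
classifies by the first differing residue; the two routes agree on every
exonic SNV of 50 random synthetic transcripts, and consequences are
invariant under mirroring a transcript to the opposite strand.

## Triage rules

Applied in strict precedence; every decision carries an ordered rule
trace naming the rules that fired.

| Tier | Rule | Default |
|---|---|---|
| 1 | Rarity filter: known MAF ≥ threshold → `excluded_common`; unknown MAF passes | 0.005 |
| 2 | ClinVar precedence: all components pathogenic → `pathogenic`; all benign → `benign`; any *Uncertain significance* or mixed components → fall through | — |
| 3 | Truncation: stop-gained/frameshift → `pathogenic`; in the last coding exon → `likely_benign` | exemption on |
| 4 | Splice: damaging iff alternate score < 0 or relative drop ≥ `rel_drop` → `likely_pathogenic`/`likely_benign`; missing scores → `ambiguous` | floor 0, drop 0.5 |
| 5 | In-silico concordance: ESM1b ≤ −10 and AlphaMissense > 0.8 → `likely_pathogenic`; both on the tolerated side → `likely_benign`; discordant → `ambiguous`; single predictor decides alone (trace-flagged); none → `ambiguous` | −10 / 0.8 |
| 6 | Synonymous / intronic → `likely_benign` | — |

Design notes on the open points:

- **Conflicting ClinVar strings** (e.g. *Uncertain
  significance/likely pathogenic*) are not trusted as assertions; they
  route to the computational tiers. This matches the observed placement
  of such variants in the ambiguous and benign tiers of the study
  cohort.
- **Last-exon truncations** default to `likely_benign`, not
  `ambiguous` — again matching the cohort's placement of a last-exon
  frameshift in the benign tier.
- **The splice damage threshold** is the package's own choice: the
  procedure being modelled cites no numeric criterion but treats a 21%
  MaxEnt drop as non-pathogenic, so the relative-drop threshold must
  exceed 21%; 50% is used and exposed in `TriageConfig`.
- **In-frame indels** are decided by ESM1b alone when AlphaMissense is
  absent (AlphaMissense scores substitutions only); the single-predictor
  path is recorded in the rule trace.
- **Benign thresholds mirror the pathogenic ones** (a binary split at
  −10 / 0.8); no separate benign cutoffs are defined.
- **stop_lost / start_lost** are not covered by rules 3–6 as literally
  stated; they are routed through the in-silico tier as protein-altering
  so that the rule set is total. Rule exhaustiveness and missense
  monotonicity (more damaging scores never yield a less severe class)
  are property-tested over randomized inputs.

Gene→pathway vocabulary is fixed: HDR = {BARD1, BRCA1, BRCA2, BRIP1,
ERCC4, FANCM, PALB2, RAD51, RAD51B, RAD51C, RAD51D, SLX4};
MMR-related = {MLH1, MSH2, MSH6, PMS2, MUTYH}.

## Association statistics

- **Exact 2×2 test**: two-sided p by the probability method (sum of
  hypergeometric probabilities of tables no more probable than
  observed), computed in exact integer arithmetic, so the nominal 1e−7
  tie tolerance is trivially satisfied. Degenerate margins raise an
  explicit error.
- **2×K Freeman–Halton test** (K ≤ 6): enumerates all tables with the
  observed margins over the smaller row margin, in log-gamma arithmetic
  with a 1e−7 relative tie tolerance; all-zero columns are dropped; an
  enumeration that would exceed the table budget raises an explicit
  resource error rather than approximating.
- **Odds ratios**: cross-product estimate with Woolf log-scale 95% CI;
  Haldane–Anscombe +0.5 on all cells when any cell is zero (flagged);
  p from the exact 2×2 test on uncorrected counts. Control comparisons
  pool carriers of truncating HDR-gene variants across the gene set
  before computing one OR; per-gene ORs are emitted but flagged
  low-power.
- **Median test**: the classical nonparametric two-sample median test —
  counts above vs. not-above the pooled median (ties count as "not
  above"), Pearson chi-square with Yates continuity correction, 1 df.
  This is the standard reading of a "median test with continuity
  correction" as implemented in common statistics packages. Degenerate
  splits return p = 1.
- **Mean CIs**: mean ± t(0.975, n−1)·sd/√n.
- Carrier aggregation: a patient is a carrier iff ≥ 1 carried variant in
  the gene set reaches the severity floor (default
  `likely_pathogenic`); each patient counts once. The truncating-carrier
  restriction additionally requires a stop-gained/frameshift consequence
  outside the last coding exon.
- The default HPV stratification for the 2-df test is
  {HPV16, HPV18, other positive} among invasive cases; strata are
  configurable.

No multiple-testing correction is applied (none is part of the modelled
analysis).

## Synthetic cohort generator

Defaults are the study conditions: 728 patients; overall
pathogenic-carrier rate 4.0% split as 2.6% HDR / 1.4% MMR; histology
76% squamous / 19% adenocarcinoma / 5% other and HPV distribution
55% HPV16 / 15% HPV18 / 22% other-positive / 8% negative (typical of a
European, invasive-enriched cervical series; the source cohort's full
phenotype table is not printed, so these two categoricals are fixed
once at field-plausible values); 75% invasive; planted odds ratios 3.0
(HDR carrier ↔ HPV18) and 4.0 (MMR carrier ↔ adenocarcinoma); carrier
ages N(44, 11), non-carrier ages N(47.3, 11) years. The default variant
class mix mirrors the study's rare-variant spectrum (23 of 65
pathogenic/likely pathogenic).

Carrier status follows a logistic model per pathway whose intercept is
solved numerically (Brent's method) so the realized marginal carrier
frequency equals the configured rate; each carrier receives one
pathogenic/likely-pathogenic variant of the matching pathway, and
non-pathogenic variants are scattered one patient each. Evidence scores
are drawn from truncated normals strictly on the intended side of the
triage thresholds (e.g. damaging missense: ESM1b ~ N(−15, 2) truncated
≤ −10, AlphaMissense ~ N(0.92, 0.04) truncated to (0.8, 1]), which
guarantees generator/classifier agreement; each generated variant's
class is verified against the classifier at generation time and the
intended class is stored as a hidden truth label. Variant identities
are normalized at generation so truth labels, annotation keys and
pipeline outputs coincide.

Randomness: one seed per run; each stage (transcripts, variants,
patients, controls) draws from its own labelled substream
(`default_rng([seed, stage_id])`), so adding a stage never perturbs
earlier stages. A fixed config reproduces every output file
byte-for-byte.

What the generator does *not* emulate: linkage disequilibrium, realistic
gene sequence or site-frequency spectra, sequencing error, HPV
integration biology, or correlated phenotypes beyond the two planted
odds ratios. Passing tests on synthetic data therefore demonstrate the
correctness of the pipeline's logic and the recoverability of planted
effects at the study's scale — not calling accuracy on real reads.

## Numerical choices and problem sizes

- Exact-test tie tolerance 1e−7 (relative); 2×K enumeration budget
  5×10⁶ tables by default.
- The packaged cohort table is transcribed with its reported
  consequences and ClinVar strings; predictor scores for it are
  synthetic stand-ins consistent with each variant's reported
  concordance category (the source prints categories, not scores); the
  splice variant carries its published MaxEnt scores 10.57 → 8.38.
- Validation problem sizes: the 2×2 sweep covers all 628,055 tables with
  n ≤ 60; null calibration uses 10,000 replicates at group sizes 30/34;
  parameter recovery uses 500 cohorts of 728 patients; the consequence
  oracle sweep covers every exonic SNV of 50 transcripts of 60–140
  codons (> 30,000 substitutions). These sizes give tight Monte-Carlo
  error at desk-scale runtime.

## Known limitations

- One canonical transcript per gene; genes with multiple 3' ends are
  represented by that transcript's last exon.
- Protein naming for complex delins falls back to frameshift naming;
  3'-shifted HGVS protein descriptions are not produced, so names may
  differ from registry descriptions for shifted in-frame deletions.
- Indels spanning exon/intron boundaries are conservatively reported as
  splice-region rather than decomposed.
- The exact 2×K test is limited by enumeration budget; very large
  minor row margins with many columns raise a resource error by design.
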