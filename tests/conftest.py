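import numpy as np
import pytest

from germtriage.fixture import build_cohort, load_panel_table, panel_records
from germtriage.models import ReferenceWindow, TranscriptModel
from germtriage.pipeline import classified_lookup
from germtriage.triage import classify_cohort


@pytest.fixture(scope="session")
def panel_df():
    return load_panel_table()


@pytest.fixture(scope="session")
def panel_classification():
    return classify_cohort(panel_records())


@pytest.fixture(scope="session")
def panel_lookup(panel_classification):
    return classified_lookup(panel_classification.table)


@pytest.fixture(scope="session")
def panel_cohort():
    patients, counts = build_cohort()
    return patients


def make_transcript(cds, strand="+", exon_sizes=None, chrom="t1", start=1001,
                    intron_len=50, rng=None):
    """Build a transcript + reference window from an explicit CDS string.

    ``exon_sizes`` splits the CDS (transcript orientation); introns are
    filled with a fixed or random sequence. ``start`` is the 1-based
    genomic position of the window's first base.
    """
    if exon_sizes is None:
        exon_sizes = [len(cds)]
    assert sum(exon_sizes) == len(cds)
    if rng is None:
        rng = np.random.default_rng(0)
    chunks = []
    off = 0
    for sz in exon_sizes:
        chunks.append(cds[off:off + sz])
        off += sz
    if strand == "-":
        comp = str.maketrans("ACGT", "TGCA")
        genomic_chunks = [c.translate(comp)[::-1] for c in reversed(chunks)]
    else:
        genomic_chunks = chunks
    pieces, exons = [], []
    cursor = start - 1  # 0-based
    for i, chunk in enumerate(genomic_chunks):
        if i > 0:
            intron = "".join(rng.choice(list("ACGT"), size=intron_len))
            pieces.append(intron)
            cursor += intron_len
        exons.append((cursor, cursor + len(chunk)))
        pieces.append(chunk)
        cursor += len(chunk)
    t = TranscriptModel(
        gene="SYNGENE", transcript_id="SYN.1", strand=strand,
        exons=tuple(exons), cds_start=exons[0][0], cds_end=exons[-1][1],
        chrom=chrom,
    )
    window = ReferenceWindow(chrom=chrom, start=start, seq="".join(pieces))
    return t, window


def random_cds(rng, n_codons):
    stops = {"TAA", "TAG", "TGA"}
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(list("ACGT"), size=3))
        if c not in stops:
            codons.append(c)
    codons.append(str(rng.choice(sorted(stops))))
    return "".join(codons)
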