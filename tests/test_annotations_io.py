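"""Parsing, validation, and round-trip contracts of the IO layer."""

import pytest

from riboprox import annotations_io as aio
from riboprox.annotations_io import (
    AlignabilityMask,
    FootprintRead,
    FormatError,
    GeneAnnotation,
    TranscriptModel,
    ValidationError,
)

# ---------------------------------------------------------------------------
# transcript models
# ---------------------------------------------------------------------------

TRANSCRIPT_TSV = (
    "gene_id\ttranscript_id\ttranscript_length_nt\tcds_start_nt\tcds_length_nt\n"
    "GENE1\tTX1\t900\t60\t600\n"
)

# same geometry (600 nt transcript, CDS offset 60, 300 nt CDS incl. stop) as
# two spliced exons on either strand
GTF_PLUS = "\n".join(
    [
        'chr1\ttest\texon\t101\t400\t.\t+\t.\tgene_id "GENE1"; transcript_id "TX1";',
        'chr1\ttest\texon\t501\t800\t.\t+\t.\tgene_id "GENE1"; transcript_id "TX1";',
        'chr1\ttest\tCDS\t161\t400\t.\t+\t0\tgene_id "GENE1"; transcript_id "TX1";',
        'chr1\ttest\tCDS\t501\t557\t.\t+\t0\tgene_id "GENE1"; transcript_id "TX1";',
        'chr1\ttest\tstop_codon\t558\t560\t.\t+\t0\tgene_id "GENE1"; transcript_id "TX1";',
    ]
)
GTF_MINUS = "\n".join(
    [
        'chr1\ttest\texon\t101\t400\t.\t-\t.\tgene_id "GENE1"; transcript_id "TX1";',
        'chr1\ttest\texon\t501\t800\t.\t-\t.\tgene_id "GENE1"; transcript_id "TX1";',
        'chr1\ttest\tCDS\t501\t740\t.\t-\t0\tgene_id "GENE1"; transcript_id "TX1";',
        'chr1\ttest\tCDS\t344\t400\t.\t-\t0\tgene_id "GENE1"; transcript_id "TX1";',
        'chr1\ttest\tstop_codon\t341\t343\t.\t-\t0\tgene_id "GENE1"; transcript_id "TX1";',
    ]
)
BED12_PLUS = "chr1\t100\t800\tGENE1|TX1\t0\t+\t160\t560\t0\t2\t300,300\t0,400\n"
BED12_MINUS = "chr1\t100\t800\tGENE1|TX1\t0\t-\t340\t740\t0\t2\t300,300\t0,400\n"
SPLICED_TSV = TRANSCRIPT_TSV.replace("900\t60\t600", "600\t60\t300")


def test_tsv_row_yields_forced_codon_arithmetic(tmp_path):
    path = tmp_path / "tx.tsv"
    path.write_text(TRANSCRIPT_TSV)
    models, report = aio.load_transcripts(path, "tsv")
    (tx,) = models
    assert (tx.gene_id, tx.transcript_id) == ("GENE1", "TX1")
    assert tx.codon_count == 200
    assert tx.protein_length_aa == 199
    assert report.n_loaded == 1 and report.n_dropped == 0


@pytest.mark.parametrize(
    "fmt,text",
    [
        ("tsv", SPLICED_TSV),
        ("gtf", GTF_PLUS),
        ("gtf", GTF_MINUS),
        ("bed12", BED12_PLUS),
        ("bed12", BED12_MINUS),
    ],
)
def test_cross_format_geometry_agrees(tmp_path, fmt, text):
    """GTF (both strands) and BED12 project to the flat-TSV geometry."""
    path = tmp_path / f"tx.{fmt}"
    path.write_text(text + "\n")
    models, _ = aio.load_transcripts(path, fmt)
    (tx,) = models
    assert tx == TranscriptModel("GENE1", "TX1", 600, 60, 300)


def test_non_triplet_cds_dropped_and_counted(tmp_path):
    path = tmp_path / "tx.tsv"
    path.write_text(TRANSCRIPT_TSV + "GENE2\tTX2\t900\t60\t601\n")
    models, report = aio.load_transcripts(path, "tsv")
    assert [tx.transcript_id for tx in models] == ["TX1"]
    assert report.dropped["non_triplet_cds"] == 1
    assert report.n_loaded + report.n_dropped == report.n_input == 2


def test_duplicate_transcript_id_raises_naming_the_id(tmp_path):
    path = tmp_path / "tx.tsv"
    path.write_text(TRANSCRIPT_TSV + "GENE1\tTX1\t900\t60\t600\n")
    with pytest.raises(FormatError, match="TX1"):
        aio.load_transcripts(path, "tsv")


def test_transcript_invariants_rejected():
    with pytest.raises(ValidationError):
        TranscriptModel("G", "T", 900, 60, 601)  # non-triplet
    with pytest.raises(ValidationError):
        TranscriptModel("G", "T", 500, 60, 600)  # CDS past end


def test_primary_transcript_selection_prefers_longest_cds():
    a = TranscriptModel("G", "TA", 900, 60, 300)
    b = TranscriptModel("G", "TB", 900, 60, 600)
    chosen = aio.select_primary_transcripts([a, b])
    assert chosen["G"].transcript_id == "TB"


# ---------------------------------------------------------------------------
# gene annotations
# ---------------------------------------------------------------------------

ANN_HEADER = "gene_id\tis_mito\tsub_localization\tprotein_length_aa\tis_secretome\tphylo_origin\n"


def test_annotation_parse_and_normalization(tmp_path):
    path = tmp_path / "ann.tsv"
    path.write_text(
        ANN_HEADER
        + "NDUFB9\tTRUE\tIMM\t179\tFALSE\teukaryotic\n"
        + "ALDH18A1\ttrue\tMatrix \t795\tfalse\tProkaryotic\n"
        + "WEIRD\tfalse\tcytoplasm\t100\ttrue\tnope\n"
    )
    ann = aio.load_annotations(path)
    assert ann["NDUFB9"].is_mito and ann["NDUFB9"].sub_localization == "IMM"
    assert ann["ALDH18A1"].sub_localization == "matrix"
    assert ann["ALDH18A1"].phylo_origin == "prokaryotic"
    assert ann["WEIRD"].sub_localization == "unknown"
    assert ann["WEIRD"].phylo_origin == "unknown"
    assert "MISSING" not in ann


def test_mito_and_secretome_are_mutually_exclusive(tmp_path):
    path = tmp_path / "ann.tsv"
    path.write_text(ANN_HEADER + "X\tTRUE\tIMM\t100\tTRUE\tunknown\n")
    with pytest.raises(ValidationError, match="X"):
        aio.load_annotations(path)


# ---------------------------------------------------------------------------
# footprints
# ---------------------------------------------------------------------------

FP_HEADER = "transcript_id\tfive_prime_pos_nt\tlength_nt\tcount\n"


def test_footprint_totals_sum_multiplicities(tmp_path, transcript):
    path = tmp_path / "fp.tsv"
    path.write_text(FP_HEADER + "TX1\t10\t30\t1\nTX1\t20\t28\t2\nTX1\t30\t33\t1\n")
    reads, total, report = aio.load_footprints(path, {"TX1": transcript})
    assert len(reads) == 3
    assert total == 4
    assert report.n_loaded == 3


def test_footprint_past_transcript_end_skipped_not_fatal(tmp_path, transcript):
    path = tmp_path / "fp.tsv"
    path.write_text(FP_HEADER + "TX1\t890\t30\t1\nTX1\t10\t30\t1\n")
    reads, total, report = aio.load_footprints(path, {"TX1": transcript})
    assert len(reads) == 1 and total == 1
    assert report.dropped["out_of_bounds"] == 1


def test_empty_footprint_file(tmp_path, transcript):
    path = tmp_path / "fp.tsv"
    path.write_text(FP_HEADER)
    reads, total, _ = aio.load_footprints(path, {"TX1": transcript})
    assert reads == [] and total == 0


def test_sam_footprints_match_tsv(tmp_path, transcript):
    """A transcriptome-aligned SAM yields the same reads as the flat TSV."""
    sam = tmp_path / "fp.sam"
    sam.write_text(
        "@HD\tVN:1.6\n@SQ\tSN:TX1\tLN:900\n"
        "r1\t0\tTX1\t11\t255\t30M\t*\t0\t0\t" + "A" * 30 + "\t*\n"
        "r2\t0\tTX1\t21\t255\t28M\t*\t0\t0\t" + "A" * 28 + "\t*\n"
    )
    reads, total, _ = aio.load_footprints(sam, {"TX1": transcript})
    assert [(r.five_prime_pos_nt, r.length_nt) for r in reads] == [(10, 30), (20, 28)]
    assert total == 2


# ---------------------------------------------------------------------------
# round trips
# ---------------------------------------------------------------------------


def test_tables_round_trip_bit_exact(tmp_path, transcript):
    transcripts = [transcript, TranscriptModel("G2", "TX2", 300, 30, 150)]
    aio.write_transcripts(transcripts, tmp_path / "tx.tsv")
    reloaded, _ = aio.load_transcripts(tmp_path / "tx.tsv", "tsv")
    assert reloaded == transcripts

    ann = {
        "G1": GeneAnnotation("G1", True, "matrix", 199, False, "prokaryotic"),
        "G2": GeneAnnotation("G2", False, "unknown", 49, True, "unknown"),
    }
    aio.write_annotations(ann, tmp_path / "ann.tsv")
    assert aio.load_annotations(tmp_path / "ann.tsv") == ann

    reads = [FootprintRead("TX1", 10, 30, 2), FootprintRead("TX1", 50, 27, 1)]
    aio.write_footprints(reads, tmp_path / "fp.tsv")
    reloaded_reads, total, _ = aio.load_footprints(tmp_path / "fp.tsv", {"TX1": transcript})
    assert reloaded_reads == reads and total == 3

    masks = {"TX1": AlignabilityMask("TX1", frozenset({5, 63, 64}))}
    aio.write_mask(masks, tmp_path / "mask.tsv")
    assert aio.load_mask(tmp_path / "mask.tsv", {"TX1": transcript}) == masks


def test_mask_position_outside_transcript_rejected(tmp_path, transcript):
    path = tmp_path / "mask.tsv"
    path.write_text("transcript_id\tposition_nt\nTX1\t900\n")
    with pytest.raises(ValidationError):
        aio.load_mask(path, {"TX1": transcript})
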