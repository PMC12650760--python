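"""Readers and writers for transcript models, gene annotations, alignability
masks, and ribosome-footprint records.

Conventions
-----------
All transcript coordinates are 0-based and half-open, with position 0 at the
transcript 5' end regardless of genomic strand.  Codon indices exposed in
output tables are 1-based from the start codon.  The CDS length stored on a
:class:`TranscriptModel` includes the stop codon, so a protein of ``n`` amino
acids has a CDS of ``3 * (n + 1)`` nucleotides.

Genomic-to-transcript projection (GTF/BED12 input) happens only here; every
downstream module works purely in transcript coordinates.
"""

from __future__ import annotations

import csv
import logging
import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

log = logging.getLogger(__name__)

_TRUE_STRINGS = {"true", "t", "1", "yes", "y"}
_FALSE_STRINGS = {"false", "f", "0", "no", "n"}

SUB_LOCALIZATIONS = ("matrix", "IMM", "IMS", "OMM", "membrane", "unknown")
PHYLO_ORIGINS = ("prokaryotic", "eukaryotic", "unknown")


class FormatError(ValueError):
    """Input file does not parse in the declared format."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


@dataclass(frozen=True)
class TranscriptModel:
    """CDS geometry of one transcript in transcript coordinates."""

    gene_id: str
    transcript_id: str
    transcript_length_nt: int
    cds_start_nt: int
    cds_length_nt: int

    def __post_init__(self) -> None:
        if self.transcript_length_nt <= 0:
            raise ValidationError(f"{self.transcript_id}: non-positive transcript length")
        if self.cds_length_nt <= 0:
            raise ValidationError(f"{self.transcript_id}: non-positive CDS length")
        if self.cds_length_nt % 3 != 0:
            raise ValidationError(
                f"{self.transcript_id}: CDS length {self.cds_length_nt} is not a multiple of 3"
            )
        if self.cds_start_nt < 0:
            raise ValidationError(f"{self.transcript_id}: negative CDS start")
        if self.cds_start_nt + self.cds_length_nt > self.transcript_length_nt:
            raise ValidationError(f"{self.transcript_id}: CDS extends past transcript end")

    @property
    def codon_count(self) -> int:
        return self.cds_length_nt // 3

    @property
    def protein_length_aa(self) -> int:
        """Protein length in amino acids (stop codon excluded)."""
        return self.codon_count - 1

    @property
    def cds_end_nt(self) -> int:
        return self.cds_start_nt + self.cds_length_nt


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene-level localization annotation (MitoCarta-style)."""

    gene_id: str
    is_mito: bool
    sub_localization: str = "unknown"
    protein_length_aa: int = 0
    is_secretome: bool = False
    phylo_origin: str = "unknown"

    def __post_init__(self) -> None:
        if self.is_mito and self.is_secretome:
            raise ValidationError(
                f"{self.gene_id}: flagged both mitochondrial and secretome; the secretome "
                "is defined to exclude mitochondrial proteins"
            )
        if self.sub_localization not in SUB_LOCALIZATIONS:
            raise ValidationError(f"{self.gene_id}: bad sub_localization {self.sub_localization!r}")
        if self.phylo_origin not in PHYLO_ORIGINS:
            raise ValidationError(f"{self.gene_id}: bad phylo_origin {self.phylo_origin!r}")


@dataclass(frozen=True)
class AlignabilityMask:
    """Transcript positions to which short reads cannot uniquely align."""

    transcript_id: str
    masked_positions: frozenset[int] = frozenset()


@dataclass(frozen=True)
class FootprintRead:
    """One aligned ribosome footprint in transcript coordinates.

    ``multiplicity`` carries the number of identical collapsed reads so that
    large libraries can be represented compactly.
    """

    transcript_id: str
    five_prime_pos_nt: int
    length_nt: int
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.length_nt <= 0:
            raise ValidationError(f"{self.transcript_id}: non-positive read length")
        if self.five_prime_pos_nt < 0:
            raise ValidationError(f"{self.transcript_id}: negative read position")
        if self.multiplicity <= 0:
            raise ValidationError(f"{self.transcript_id}: non-positive multiplicity")


@dataclass(frozen=True)
class AnalysisParams:
    """Tunable constants of the footprint-enrichment analysis.

    Defaults follow the published protocol: footprints of 27-36 nt with 13 nt
    nibbled from each end for center-weighted assignment; genes with fewer
    than 64 CDS-mapping footprints in the total input are excluded; codon
    profiles use a 0.1 RPM pseudo-count, a 21-codon smoothing window and a
    >=3 footprints/codon coverage gate; localized translation is called at
    log2 enrichment 1.5 (or below -0.3 for the post-translational class) with
    the 200/400 aa protein-length cut-offs.
    """

    read_len_min: int = 27
    read_len_max: int = 36
    nibble_nt: int = 13
    min_input_cds_footprints: float = 64.0
    pseudo_rpm: float = 0.1
    half_window_codons: int = 10
    min_mean_fp_per_codon: float = 3.0
    enrich_threshold_log2: float = 1.5
    post_threshold_log2: float = -0.3
    short_max_aa: int = 200
    long_min_aa: int = 400

    def __post_init__(self) -> None:
        if self.read_len_min <= 2 * self.nibble_nt:
            raise ValidationError("read_len_min must exceed twice the nibble length")
        if self.read_len_max < self.read_len_min:
            raise ValidationError("read_len_max below read_len_min")
        if self.half_window_codons < 0:
            raise ValidationError("half_window_codons must be >= 0")
        for name in ("min_input_cds_footprints", "pseudo_rpm", "min_mean_fp_per_codon"):
            if not getattr(self, name) >= 0:
                raise ValidationError(f"{name} must be non-negative")


DEFAULT_PARAMS = AnalysisParams()


@dataclass
class LoadReport:
    """Bookkeeping for records dropped during loading."""

    n_input: int = 0
    n_loaded: int = 0
    dropped: Counter = field(default_factory=Counter)

    def drop(self, reason: str) -> None:
        self.dropped[reason] += 1

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())


# ---------------------------------------------------------------------------
# transcript models
# ---------------------------------------------------------------------------

_TRANSCRIPT_COLUMNS = (
    "gene_id",
    "transcript_id",
    "transcript_length_nt",
    "cds_start_nt",
    "cds_length_nt",
)


def load_transcripts(
    path: str | os.PathLike, fmt: str = "tsv"
) -> tuple[list[TranscriptModel], LoadReport]:
    """Load transcript models from a flat TSV, Ensembl-dialect GTF, or BED12.

    Transcripts whose CDS length is not a multiple of 3 are dropped and
    counted under ``non_triplet_cds`` in the returned :class:`LoadReport`;
    any other invariant violation is counted under ``invalid_geometry``.
    Duplicate transcript ids raise :class:`FormatError`.
    """
    if fmt == "tsv":
        raw = _read_transcript_tsv(path)
    elif fmt == "gtf":
        raw = _read_transcript_gtf(path)
    elif fmt == "bed12":
        raw = _read_transcript_bed12(path)
    else:
        raise ValueError(f"unknown transcript format {fmt!r}")

    report = LoadReport()
    models: list[TranscriptModel] = []
    seen: set[str] = set()
    for gene_id, tx_id, tx_len, cds_start, cds_len in raw:
        report.n_input += 1
        if tx_id in seen:
            raise FormatError(f"duplicate transcript_id {tx_id!r}")
        seen.add(tx_id)
        try:
            model = TranscriptModel(gene_id, tx_id, tx_len, cds_start, cds_len)
        except ValidationError as exc:
            reason = "non_triplet_cds" if cds_len % 3 != 0 else "invalid_geometry"
            log.warning("dropping transcript %s: %s", tx_id, exc)
            report.drop(reason)
            continue
        models.append(model)
        report.n_loaded += 1
    return models, report


def _read_transcript_tsv(path) -> list[tuple[str, str, int, int, int]]:
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not set(_TRANSCRIPT_COLUMNS) <= set(reader.fieldnames):
            raise FormatError(
                f"{path}: transcript TSV requires columns {', '.join(_TRANSCRIPT_COLUMNS)}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                rows.append(
                    (
                        row["gene_id"],
                        row["transcript_id"],
                        int(row["transcript_length_nt"]),
                        int(row["cds_start_nt"]),
                        int(row["cds_length_nt"]),
                    )
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: bad transcript row ({exc})") from exc
    return rows


def _read_transcript_gtf(path) -> list[tuple[str, str, int, int, int]]:
    """Project CDS geometry out of an Ensembl-dialect GTF.

    The CDS interval is taken as the union of ``CDS`` and ``stop_codon``
    features so that the stored CDS length includes the stop codon.  Minus
    strand transcripts are flipped so position 0 is the transcript 5' end.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_transcripts=True,
            disable_infer_genes=True,
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise FormatError(f"{path}: cannot parse GTF ({exc})") from exc

    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    strand: dict[str, str] = {}
    gene_of: dict[str, str] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS", "stop_codon"):
            continue
        tx_ids = feat.attributes.get("transcript_id")
        if not tx_ids:
            raise FormatError(f"{path}: {feat.featuretype} feature lacks transcript_id")
        tx = tx_ids[0]
        strand[tx] = feat.strand
        gene_ids = feat.attributes.get("gene_id", [tx])
        gene_of[tx] = gene_ids[0]
        interval = (feat.start - 1, feat.end)  # GTF is 1-based inclusive
        if feat.featuretype == "exon":
            exons.setdefault(tx, []).append(interval)
        else:
            cds.setdefault(tx, []).append(interval)

    rows = []
    for tx in sorted(exons):
        if tx not in cds:
            continue
        ex = sorted(exons[tx])
        tx_len = sum(e - s for s, e in ex)
        cds_start_g = min(s for s, _ in cds[tx])
        cds_end_g = max(e for _, e in cds[tx])
        cds_len = sum(e - s for s, e in cds[tx])
        # transcript-coordinate offset of a genomic position on the plus-oriented
        # exon chain
        def tx_pos(g: int) -> int:
            off = 0
            for s, e in ex:
                if g < s:
                    break
                if g < e:
                    return off + (g - s)
                off += e - s
            return off

        if strand[tx] == "-":
            cds_start_tx = tx_len - (tx_pos(cds_end_g - 1) + 1)
        else:
            cds_start_tx = tx_pos(cds_start_g)
        rows.append((gene_of[tx], tx, tx_len, cds_start_tx, cds_len))
    return rows


def _read_transcript_bed12(path) -> list[tuple[str, str, int, int, int]]:
    """Read BED12; thickStart/thickEnd delimit the CDS (stop codon included)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise FormatError(f"{path}:{lineno}: expected 12 BED columns, got {len(parts)}")
            try:
                chrom_start = int(parts[1])
                name = parts[3]
                strand_ = parts[5]
                thick_start = int(parts[6])
                thick_end = int(parts[7])
                n_blocks = int(parts[9])
                sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
                starts = [int(x) for x in parts[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad BED12 record ({exc})") from exc
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise FormatError(f"{path}:{lineno}: block count mismatch")
            tx_len = sum(sizes)
            before = 0  # transcript nt (plus orientation) upstream of thickStart
            inside = 0  # transcript nt overlapping the thick interval
            for size, rel in zip(sizes, starts):
                b_start = chrom_start + rel
                b_end = b_start + size
                before += max(0, min(b_end, thick_start) - b_start)
                inside += max(0, min(b_end, thick_end) - max(b_start, thick_start))
            cds_start_tx = before if strand_ != "-" else tx_len - before - inside
            gene_id, _, tx_id = name.partition("|")
            if not tx_id:
                gene_id = tx_id = name
            rows.append((gene_id, tx_id, tx_len, cds_start_tx, inside))
    return rows


def select_primary_transcripts(
    transcripts: Iterable[TranscriptModel],
) -> dict[str, TranscriptModel]:
    """Collapse to one transcript per gene, keeping the longest CDS.

    Ties break on transcript_id so the choice is deterministic.  Gene-level
    counting and profile math assume a single isoform per gene.
    """
    chosen: dict[str, TranscriptModel] = {}
    for tx in transcripts:
        prev = chosen.get(tx.gene_id)
        if prev is None:
            chosen[tx.gene_id] = tx
        elif (tx.cds_length_nt, tx.transcript_id) > (prev.cds_length_nt, prev.transcript_id):
            log.info(
                "gene %s: selecting transcript %s over %s (longer CDS)",
                tx.gene_id,
                tx.transcript_id,
                prev.transcript_id,
            )
            chosen[tx.gene_id] = tx
    return chosen


def write_transcripts(transcripts: Iterable[TranscriptModel], path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TRANSCRIPT_COLUMNS)
        for tx in transcripts:
            writer.writerow(
                [tx.gene_id, tx.transcript_id, tx.transcript_length_nt, tx.cds_start_nt, tx.cds_length_nt]
            )


# ---------------------------------------------------------------------------
# gene annotations
# ---------------------------------------------------------------------------

_ANNOTATION_COLUMNS = (
    "gene_id",
    "is_mito",
    "sub_localization",
    "protein_length_aa",
    "is_secretome",
    "phylo_origin",
)

_SUBLOC_ALIASES = {s.lower(): s for s in SUB_LOCALIZATIONS}
_PHYLO_ALIASES = {s.lower(): s for s in PHYLO_ORIGINS}


def _parse_bool(value: str, where: str) -> bool:
    v = value.strip().lower()
    if v in _TRUE_STRINGS:
        return True
    if v in _FALSE_STRINGS:
        return False
    raise FormatError(f"{where}: cannot parse boolean {value!r}")


def load_annotations(path: str | os.PathLike) -> dict[str, GeneAnnotation]:
    """Load the gene annotation table; returns a gene_id -> annotation map.

    Sub-localization and phylogenetic-origin strings are whitespace- and
    case-normalized; unknown values map to ``unknown``.
    """
    annotations: dict[str, GeneAnnotation] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not set(_ANNOTATION_COLUMNS) <= set(reader.fieldnames):
            raise FormatError(
                f"{path}: annotation TSV requires columns {', '.join(_ANNOTATION_COLUMNS)}"
            )
        for lineno, row in enumerate(reader, start=2):
            where = f"{path}:{lineno}"
            subloc = _SUBLOC_ALIASES.get(row["sub_localization"].strip().lower(), "unknown")
            phylo = _PHYLO_ALIASES.get(row["phylo_origin"].strip().lower(), "unknown")
            try:
                ann = GeneAnnotation(
                    gene_id=row["gene_id"],
                    is_mito=_parse_bool(row["is_mito"], where),
                    sub_localization=subloc,
                    protein_length_aa=int(row["protein_length_aa"]),
                    is_secretome=_parse_bool(row["is_secretome"], where),
                    phylo_origin=phylo,
                )
            except ValueError as exc:
                if isinstance(exc, ValidationError):
                    raise
                raise FormatError(f"{where}: bad annotation row ({exc})") from exc
            annotations[ann.gene_id] = ann
    return annotations


def write_annotations(annotations: Mapping[str, GeneAnnotation], path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_ANNOTATION_COLUMNS)
        for gene_id in sorted(annotations):
            a = annotations[gene_id]
            writer.writerow(
                [a.gene_id, a.is_mito, a.sub_localization, a.protein_length_aa, a.is_secretome, a.phylo_origin]
            )


# ---------------------------------------------------------------------------
# alignability masks
# ---------------------------------------------------------------------------


def load_mask(
    path: str | os.PathLike,
    transcripts: Optional[Mapping[str, TranscriptModel]] = None,
) -> dict[str, AlignabilityMask]:
    """Load a mask TSV (columns ``transcript_id``, ``position_nt``).

    When transcript models are supplied, positions outside the transcript
    raise :class:`ValidationError`.
    """
    positions: dict[str, set[int]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"transcript_id", "position_nt"} <= set(reader.fieldnames):
            raise FormatError(f"{path}: mask TSV requires columns transcript_id, position_nt")
        for lineno, row in enumerate(reader, start=2):
            tx = row["transcript_id"]
            try:
                pos = int(row["position_nt"])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad position ({exc})") from exc
            if transcripts is not None and tx in transcripts:
                if not 0 <= pos < transcripts[tx].transcript_length_nt:
                    raise ValidationError(f"{path}:{lineno}: masked position {pos} outside {tx}")
            positions.setdefault(tx, set()).add(pos)
    return {tx: AlignabilityMask(tx, frozenset(pos)) for tx, pos in positions.items()}


def write_mask(masks: Mapping[str, AlignabilityMask], path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["transcript_id", "position_nt"])
        for tx in sorted(masks):
            for pos in sorted(masks[tx].masked_positions):
                writer.writerow([tx, pos])


# ---------------------------------------------------------------------------
# footprint reads
# ---------------------------------------------------------------------------

_FOOTPRINT_COLUMNS = ("transcript_id", "five_prime_pos_nt", "length_nt", "count")


def load_footprints(
    path: str | os.PathLike,
    transcripts: Mapping[str, TranscriptModel],
    fmt: Optional[str] = None,
) -> tuple[list[FootprintRead], float, LoadReport]:
    """Load footprint records from a TSV or a transcriptome-aligned BAM/SAM.

    Returns ``(reads, total, report)`` where ``total`` is the library-size
    denominator: the summed multiplicity of all reads mapping to any loaded
    transcript.  No length filtering happens here (that is the counting
    module's job).  Reads extending past the transcript end, or mapping to an
    unknown transcript, are skipped with a warning.
    """
    if fmt is None:
        fmt = "bam" if str(path).endswith((".bam", ".sam", ".cram")) else "tsv"
    if fmt == "bam":
        raw = _iter_bam_footprints(path)
    elif fmt == "tsv":
        raw = _iter_tsv_footprints(path)
    else:
        raise ValueError(f"unknown footprint format {fmt!r}")

    reads: list[FootprintRead] = []
    total = 0.0
    report = LoadReport()
    for tx_id, pos, length, mult in raw:
        report.n_input += 1
        model = transcripts.get(tx_id)
        if model is None:
            log.warning("footprint on unknown transcript %s skipped", tx_id)
            report.drop("unknown_transcript")
            continue
        if pos < 0 or pos + length > model.transcript_length_nt:
            log.warning(
                "footprint at %s:%d (len %d) extends past transcript end; skipped",
                tx_id,
                pos,
                length,
            )
            report.drop("out_of_bounds")
            continue
        reads.append(FootprintRead(tx_id, pos, length, mult))
        total += mult
        report.n_loaded += 1
    return reads, total, report


def _iter_tsv_footprints(path):
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return
        if not set(_FOOTPRINT_COLUMNS) <= set(reader.fieldnames):
            raise FormatError(
                f"{path}: footprint TSV requires columns {', '.join(_FOOTPRINT_COLUMNS)}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                yield (
                    row["transcript_id"],
                    int(row["five_prime_pos_nt"]),
                    int(row["length_nt"]),
                    int(row["count"]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad footprint row ({exc})") from exc


def _iter_bam_footprints(path):
    import pysam

    mode = "r" if str(path).endswith(".sam") else "rb"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            yield (
                aln.reference_name,
                aln.reference_start,
                aln.query_length or aln.infer_query_length() or 0,
                1,
            )


def write_footprints(reads: Iterable[FootprintRead], path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_FOOTPRINT_COLUMNS)
        for r in reads:
            writer.writerow([r.transcript_id, r.five_prime_pos_nt, r.length_nt, r.multiplicity])
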