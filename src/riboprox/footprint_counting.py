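"""Center-weighted per-codon footprint counting.

A footprint of length L (27-36 nt) is trimmed by 13 nt ("nibbled") at each
end and its count is spread uniformly over the remaining L - 26 central
positions.  Weighted positions falling inside the CDS — and not excluded by
an alignability mask — are binned into codons.  Counts are fractional by
construction and are kept as reals end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .annotations_io import (
    AlignabilityMask,
    AnalysisParams,
    DEFAULT_PARAMS,
    FootprintRead,
    TranscriptModel,
)


@dataclass
class CodonCounts:
    """Per-codon weighted footprint counts for one gene in one library."""

    gene_id: str
    library_id: str
    counts: np.ndarray
    n_cds_footprints: float
    n_reads_used: int

    @property
    def codon_count(self) -> int:
        return len(self.counts)

    @property
    def mean_fp_per_codon(self) -> float:
        return self.n_cds_footprints / self.codon_count if self.codon_count else 0.0


@dataclass(frozen=True)
class LibraryStats:
    """Library-size denominator: all reads mapping to any annotated transcript."""

    library_id: str
    total_transcriptome_reads: float

    def __post_init__(self) -> None:
        if not self.total_transcriptome_reads > 0:
            raise ValueError(f"{self.library_id}: library total must be positive")


def center_weights(
    read: FootprintRead, params: AnalysisParams = DEFAULT_PARAMS
) -> list[tuple[int, float]]:
    """Center-weighted (position, weight) pairs for one footprint.

    Reads outside the accepted length range yield an empty list.  Weights sum
    to the read's multiplicity.
    """
    if not params.read_len_min <= read.length_nt <= params.read_len_max:
        return []
    span = read.length_nt - 2 * params.nibble_nt
    start = read.five_prime_pos_nt + params.nibble_nt
    w = read.multiplicity / span
    return [(start + i, w) for i in range(span)]


def _weighted_positions(
    reads: Sequence[FootprintRead], params: AnalysisParams
) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorized center weighting over many reads.

    Returns (positions, weights, n_reads_used) where n_reads_used sums the
    multiplicities of length-accepted reads.
    """
    if not reads:
        return np.empty(0, dtype=np.int64), np.empty(0), 0
    lengths = np.fromiter((r.length_nt for r in reads), dtype=np.int64, count=len(reads))
    fives = np.fromiter((r.five_prime_pos_nt for r in reads), dtype=np.int64, count=len(reads))
    mults = np.fromiter((r.multiplicity for r in reads), dtype=np.float64, count=len(reads))
    keep = (lengths >= params.read_len_min) & (lengths <= params.read_len_max)
    lengths, fives, mults = lengths[keep], fives[keep], mults[keep]
    if lengths.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0), 0
    spans = lengths - 2 * params.nibble_nt
    starts = fives + params.nibble_nt
    total = int(spans.sum())
    # ragged arange: offsets 0..span-1 within each read's central window
    offsets = np.arange(total) - np.repeat(np.cumsum(spans) - spans, spans)
    positions = np.repeat(starts, spans) + offsets
    weights = np.repeat(mults / spans, spans)
    return positions, weights, int(mults.sum())


def count_codons(
    reads: Iterable[FootprintRead],
    transcript: TranscriptModel,
    mask: Optional[AlignabilityMask] = None,
    params: AnalysisParams = DEFAULT_PARAMS,
    library_id: str = "",
) -> CodonCounts:
    """Bin center-weighted footprint positions into CDS codons.

    Each weighted nucleotide position p with
    ``cds_start_nt <= p < cds_start_nt + cds_length_nt`` and not masked adds
    its weight to codon ``(p - cds_start_nt) // 3``.  Positions outside the
    CDS, or masked, contribute nothing; weight straddling the CDS boundary is
    not rescaled.  Masked positions reduce counted weight but do not shorten
    the CDS length used downstream for densities.
    """
    reads = list(reads)
    for r in reads:
        if r.transcript_id != transcript.transcript_id:
            raise ValueError(
                f"read on {r.transcript_id} passed to transcript {transcript.transcript_id}"
            )
    positions, weights, n_used = _weighted_positions(reads, params)
    in_cds = (positions >= transcript.cds_start_nt) & (positions < transcript.cds_end_nt)
    positions, weights = positions[in_cds], weights[in_cds]
    if mask is not None and mask.masked_positions:
        masked = np.fromiter(mask.masked_positions, dtype=np.int64)
        keep = ~np.isin(positions, masked)
        positions, weights = positions[keep], weights[keep]
    codons = (positions - transcript.cds_start_nt) // 3
    counts = np.bincount(codons, weights=weights, minlength=transcript.codon_count)
    return CodonCounts(
        gene_id=transcript.gene_id,
        library_id=library_id,
        counts=counts,
        n_cds_footprints=float(counts.sum()),
        n_reads_used=n_used,
    )


def write_codon_counts(counts: Iterable[CodonCounts], path) -> None:
    """Emit a per-gene codon-count TSV (codon_index is 1-based)."""
    with open(path, "w", newline="") as fh:
        fh.write("gene_id\tlibrary_id\tcodon_index\tcount\n")
        for cc in counts:
            for i, c in enumerate(cc.counts, start=1):
                fh.write(f"{cc.gene_id}\t{cc.library_id}\t{i}\t{c:.10g}\n")
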