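"""Gene-level localization enrichment from footprint and RNA-seq densities.

The localization score of a gene is the log2 ratio of its pulldown CDS
footprint density (RPKM) to the matched total-input density.  Genes with
fewer than 64 CDS-mapping footprints in the total input are excluded from
all analyses.  The intact-mRNA readout uses the same ratio over
whole-transcript FPKM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotations_io import AnalysisParams, DEFAULT_PARAMS, GeneAnnotation, TranscriptModel
from .footprint_counting import CodonCounts, LibraryStats


@dataclass
class EnrichmentRecord:
    """Gene-level pulldown/input densities and log2 enrichment.

    ``log2_enrichment`` is NaN when either density is zero; such records are
    flagged ``defined=False`` and excluded from summaries (the codon-level
    pseudo-count is not extended to gene-level ratios).
    """

    gene_id: str
    pulldown_density_rpkm: float
    input_density_rpkm: float
    log2_enrichment: float
    input_cds_footprints: float
    passed_filter: bool
    defined: bool

    @property
    def fold_enrichment(self) -> float:
        return 2.0 ** self.log2_enrichment if self.defined else math.nan


@dataclass
class RnaEnrichmentRecord:
    """Whole-transcript FPKM enrichment from the intact-mRNA readout."""

    gene_id: str
    pulldown_fpkm: float
    input_fpkm: float
    log2_enrichment: float
    defined: bool

    @property
    def fold_enrichment(self) -> float:
        return 2.0 ** self.log2_enrichment if self.defined else math.nan


def cds_density_rpkm(
    counts: CodonCounts, transcript: TranscriptModel, stats: LibraryStats
) -> float:
    """CDS footprint density in reads per kilobase of CDS per million mapped."""
    if not stats.total_transcriptome_reads > 0:
        raise ValueError("library total must be positive")
    return (
        counts.n_cds_footprints
        / (transcript.cds_length_nt / 1000.0)
        / (stats.total_transcriptome_reads / 1e6)
    )


def gene_enrichment(
    pd_counts: CodonCounts,
    inp_counts: CodonCounts,
    transcript: TranscriptModel,
    pd_stats: LibraryStats,
    inp_stats: LibraryStats,
    params: AnalysisParams = DEFAULT_PARAMS,
) -> EnrichmentRecord:
    """Gene-level log2(pulldown RPKM / input RPKM) with the input-depth filter."""
    if pd_counts.gene_id != inp_counts.gene_id:
        raise ValueError(f"gene mismatch: {pd_counts.gene_id} vs {inp_counts.gene_id}")
    pd_rpkm = cds_density_rpkm(pd_counts, transcript, pd_stats)
    inp_rpkm = cds_density_rpkm(inp_counts, transcript, inp_stats)
    defined = pd_rpkm > 0 and inp_rpkm > 0
    log2 = math.log2(pd_rpkm / inp_rpkm) if defined else math.nan
    return EnrichmentRecord(
        gene_id=pd_counts.gene_id,
        pulldown_density_rpkm=pd_rpkm,
        input_density_rpkm=inp_rpkm,
        log2_enrichment=log2,
        input_cds_footprints=inp_counts.n_cds_footprints,
        passed_filter=inp_counts.n_cds_footprints >= params.min_input_cds_footprints,
        defined=defined,
    )


def rnaseq_enrichment(
    gene_id: str,
    pd_fragments: float,
    inp_fragments: float,
    transcript_length_nt: int,
    pd_total: float,
    inp_total: float,
) -> RnaEnrichmentRecord:
    """Whole-transcript FPKM log2 ratio for the intact-mRNA readout."""
    if not (pd_total > 0 and inp_total > 0):
        raise ValueError("library totals must be positive")
    kb = transcript_length_nt / 1000.0
    pd_fpkm = pd_fragments / kb / (pd_total / 1e6)
    inp_fpkm = inp_fragments / kb / (inp_total / 1e6)
    defined = pd_fpkm > 0 and inp_fpkm > 0
    log2 = math.log2(pd_fpkm / inp_fpkm) if defined else math.nan
    return RnaEnrichmentRecord(gene_id, pd_fpkm, inp_fpkm, log2, defined)


DEFAULT_THRESHOLD_GRID = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0)


def cohort_summary(
    records: Iterable[EnrichmentRecord],
    annotations: Mapping[str, GeneAnnotation],
    thresholds: Sequence[float] = DEFAULT_THRESHOLD_GRID,
) -> pd.DataFrame:
    """Count/percentage of mito vs non-mito genes above each log2 threshold.

    Only filter-passing records with a defined enrichment and a matching
    annotation are tallied.
    """
    rows = []
    usable = [
        r
        for r in records
        if r.passed_filter and r.defined and r.gene_id in annotations
    ]
    for threshold in thresholds:
        for is_mito, group in ((True, "mito"), (False, "non_mito")):
            members = [r for r in usable if annotations[r.gene_id].is_mito == is_mito]
            n_total = len(members)
            n_above = sum(r.log2_enrichment > threshold for r in members)
            rows.append(
                {
                    "threshold_log2": threshold,
                    "group": group,
                    "n_total": n_total,
                    "n_above": n_above,
                    "pct_above": 100.0 * n_above / n_total if n_total else math.nan,
                }
            )
    return pd.DataFrame(rows)


def enrichment_table(records: Iterable[EnrichmentRecord]) -> pd.DataFrame:
    """Flatten records into the output table written by the pipeline."""
    rows = []
    for r in records:
        rows.append(
            {
                "gene_id": r.gene_id,
                "pulldown_rpkm": r.pulldown_density_rpkm,
                "input_rpkm": r.input_density_rpkm,
                "log2_enrichment": r.log2_enrichment,
                "fold_enrichment": r.fold_enrichment,
                "input_cds_footprints": r.input_cds_footprints,
                "passed_filter": r.passed_filter,
            }
        )
    return pd.DataFrame(rows).sort_values("gene_id").reset_index(drop=True)
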