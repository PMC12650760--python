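"""End-to-end orchestration: count -> enrich -> profile -> classify -> metagene.

This is the library-level pipeline behind the command-line interface; every
stage exchanges only plain tables (or the in-memory records they serialize),
so any stage can be re-run from intermediate TSVs.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .annotations_io import (
    AlignabilityMask,
    AnalysisParams,
    DEFAULT_PARAMS,
    FootprintRead,
    GeneAnnotation,
    TranscriptModel,
)
from .enrichment import EnrichmentRecord, enrichment_table, gene_enrichment
from .footprint_counting import CodonCounts, LibraryStats, count_codons
from .metagene import (
    GeneClass,
    MetageneCurve,
    PositionalProfile,
    build_profile,
    classify_gene,
    estimate_onset,
    metagene_curve,
)


@dataclass
class CohortResult:
    """All per-gene and aggregate outputs of one analysis run."""

    records: dict[str, EnrichmentRecord]
    classes: dict[str, GeneClass]
    profiles: dict[str, PositionalProfile]
    onsets: dict[str, Optional[int]]
    curves: dict[GeneClass, MetageneCurve]
    pulldown_counts: dict[str, CodonCounts] = field(default_factory=dict)
    input_counts: dict[str, CodonCounts] = field(default_factory=dict)

    @property
    def enrichment(self) -> pd.DataFrame:
        return enrichment_table(self.records.values())

    def classification_table(
        self, annotations: Mapping[str, GeneAnnotation]
    ) -> pd.DataFrame:
        rows = []
        for gene_id in sorted(self.records):
            record = self.records[gene_id]
            ann = annotations.get(gene_id)
            rows.append(
                {
                    "gene_id": gene_id,
                    "protein_length_aa": ann.protein_length_aa if ann else "",
                    "log2_enrichment": record.log2_enrichment,
                    "passed_filter": record.passed_filter,
                    "gene_class": self.classes.get(gene_id, GeneClass.UNCLASSIFIED).value,
                    "onset_codon": self.onsets.get(gene_id, None),
                }
            )
        return pd.DataFrame(rows)


def group_reads_by_transcript(
    reads: Iterable[FootprintRead],
) -> dict[str, list[FootprintRead]]:
    grouped: dict[str, list[FootprintRead]] = defaultdict(list)
    for r in reads:
        grouped[r.transcript_id].append(r)
    return dict(grouped)


def count_cohort(
    transcript_of_gene: Mapping[str, TranscriptModel],
    reads: Iterable[FootprintRead],
    masks: Optional[Mapping[str, AlignabilityMask]] = None,
    params: AnalysisParams = DEFAULT_PARAMS,
    library_id: str = "",
) -> dict[str, CodonCounts]:
    """Per-codon counts for every gene in one library."""
    grouped = group_reads_by_transcript(reads)
    counts: dict[str, CodonCounts] = {}
    for gene_id, tx in transcript_of_gene.items():
        mask = masks.get(tx.transcript_id) if masks else None
        counts[gene_id] = count_codons(
            grouped.get(tx.transcript_id, []), tx, mask, params, library_id
        )
    return counts


def analyze_cohort(
    transcript_of_gene: Mapping[str, TranscriptModel],
    pulldown_reads: Iterable[FootprintRead],
    input_reads: Iterable[FootprintRead],
    pd_stats: LibraryStats,
    inp_stats: LibraryStats,
    annotations: Mapping[str, GeneAnnotation],
    params: AnalysisParams = DEFAULT_PARAMS,
    masks: Optional[Mapping[str, AlignabilityMask]] = None,
) -> CohortResult:
    """Run the full footprint pipeline over one matched library pair.

    Genes failing the input-depth filter (or with undefined enrichment) are
    left unclassified; positional profiles are built for every filter-passing
    gene and metagene curves aggregate only coverage-passing members of each
    assigned class.
    """
    pd_counts = count_cohort(transcript_of_gene, pulldown_reads, masks, params, pd_stats.library_id)
    inp_counts = count_cohort(transcript_of_gene, input_reads, masks, params, inp_stats.library_id)

    records: dict[str, EnrichmentRecord] = {}
    classes: dict[str, GeneClass] = {}
    profiles: dict[str, PositionalProfile] = {}
    onsets: dict[str, Optional[int]] = {}

    for gene_id, tx in transcript_of_gene.items():
        record = gene_enrichment(
            pd_counts[gene_id], inp_counts[gene_id], tx, pd_stats, inp_stats, params
        )
        records[gene_id] = record
        ann = annotations.get(gene_id)
        if record.passed_filter and ann is not None:
            classes[gene_id] = classify_gene(record, ann.protein_length_aa, params)
        else:
            classes[gene_id] = GeneClass.UNCLASSIFIED
        if record.passed_filter:
            profile = build_profile(
                pd_counts[gene_id], inp_counts[gene_id], pd_stats, inp_stats, params
            )
            if profile.passes_coverage:
                profiles[gene_id] = profile
                onsets[gene_id] = estimate_onset(profile.normalized)

    curves: dict[GeneClass, MetageneCurve] = {}
    for cls in (
        GeneClass.SHORT_MRNA_TARGETED,
        GeneClass.LONG_COTRANSLATIONAL,
        GeneClass.POST_TRANSLATIONAL,
    ):
        members = sorted(g for g, c in classes.items() if c is cls and g in profiles)
        curves[cls] = metagene_curve(profiles, members)

    return CohortResult(
        records=records,
        classes=classes,
        profiles=profiles,
        onsets=onsets,
        curves=curves,
        pulldown_counts=pd_counts,
        input_counts=inp_counts,
    )
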