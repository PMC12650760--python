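"""Codon-resolution positional enrichment, metagene aggregation, and
localized-translation classification.

Per-codon log2 enrichment is computed on RPM-scaled counts with a 0.1 RPM
pseudo-count, smoothed over a 21-codon window (truncated at the transcript
ends), and scaled so the largest absolute smoothed value within the gene is
1.  Metagene curves aggregate the normalized profiles of a gene class at
each codon position, excluding transcripts that end before that position.
Because the aggregated values live on the log2 scale, the per-position mean
is the arithmetic mean of log2 values, i.e. the geometric mean of the
enrichment ratios.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotations_io import AnalysisParams, DEFAULT_PARAMS
from .enrichment import EnrichmentRecord
from .footprint_counting import CodonCounts, LibraryStats


class GeneClass(str, enum.Enum):
    """Localized-translation classes.

    post_translational: long proteins (>400 aa) depleted at the membrane
    (log2 enrichment < -0.3) — imported after synthesis completes.
    long_cotranslational: long proteins (>400 aa) enriched (log2 > 1.5) —
    recruited mid-synthesis, visible as a positional rise in enrichment.
    short_mrna_targeted: short proteins (<200 aa) enriched (log2 > 1.5) —
    their mRNAs are recruited before translation begins, so enrichment is
    uniform from the start codon.
    """

    POST_TRANSLATIONAL = "post_translational"
    LONG_COTRANSLATIONAL = "long_cotranslational"
    SHORT_MRNA_TARGETED = "short_mrna_targeted"
    UNCLASSIFIED = "unclassified"


@dataclass
class PositionalProfile:
    """Raw/smoothed/normalized per-codon log2 enrichment for one gene."""

    gene_id: str
    raw_log2: np.ndarray
    smoothed_log2: np.ndarray
    normalized: np.ndarray
    mean_input_fp_per_codon: float
    passes_coverage: bool

    @property
    def codon_count(self) -> int:
        return len(self.raw_log2)


@dataclass
class MetageneCurve:
    """Aggregate curve over one gene class, aligned at the start codon."""

    position: np.ndarray  # 1-based codon index
    mean: np.ndarray
    sd: np.ndarray
    n_transcripts: np.ndarray

    def __len__(self) -> int:
        return len(self.position)

    def window_mean(self, first_codon: int, last_codon: int) -> float:
        """Mean of the curve over an inclusive 1-based codon window."""
        sel = (self.position >= first_codon) & (self.position <= last_codon)
        return float(np.mean(self.mean[sel])) if sel.any() else math.nan


def codon_log2_profile(
    pd_counts: CodonCounts,
    inp_counts: CodonCounts,
    pd_stats: LibraryStats,
    inp_stats: LibraryStats,
    params: AnalysisParams = DEFAULT_PARAMS,
) -> np.ndarray:
    """Per-codon log2 enrichment after RPM conversion and pseudo-counting.

    Each codon count is scaled to reads per million, 0.1 RPM is added to both
    libraries, and the log2 quotient is returned.
    """
    if pd_counts.codon_count != inp_counts.codon_count:
        raise ValueError(
            f"{pd_counts.gene_id}: codon count mismatch "
            f"({pd_counts.codon_count} vs {inp_counts.codon_count})"
        )
    pd_rpm = pd_counts.counts / pd_stats.total_transcriptome_reads * 1e6
    inp_rpm = inp_counts.counts / inp_stats.total_transcriptome_reads * 1e6
    return np.log2(pd_rpm + params.pseudo_rpm) - np.log2(inp_rpm + params.pseudo_rpm)


def smooth_profile(raw: Sequence[float], half_window: int = 10) -> np.ndarray:
    """Mean over a (2*half_window + 1)-codon window, truncated at the ends.

    Codon i (1-based) averages codons max(1, i - hw) .. min(L, i + hw); for
    the first hw codons this is the codon itself, all preceding codons, and
    the hw subsequent ones, and the last hw codons use the mirrored rule.
    """
    raw = np.asarray(raw, dtype=float)
    n = len(raw)
    cum = np.concatenate(([0.0], np.cumsum(raw)))
    idx = np.arange(n)
    lo = np.maximum(0, idx - half_window)
    hi = np.minimum(n, idx + half_window + 1)
    return (cum[hi] - cum[lo]) / (hi - lo)


def normalize_profile(smoothed: Sequence[float]) -> np.ndarray:
    """Scale by the largest absolute value; all-zero input maps to all zeros."""
    smoothed = np.asarray(smoothed, dtype=float)
    peak = np.max(np.abs(smoothed)) if smoothed.size else 0.0
    if peak == 0.0:
        return np.zeros_like(smoothed)
    return smoothed / peak


def coverage_gate(inp_counts: CodonCounts, params: AnalysisParams = DEFAULT_PARAMS) -> bool:
    """True iff mean total-input footprints per codon is at least 3.

    Input depth limits the interpretability of both libraries, so the gate is
    applied to the total-input library.
    """
    if inp_counts.codon_count == 0:
        return False
    return inp_counts.mean_fp_per_codon >= params.min_mean_fp_per_codon


def build_profile(
    pd_counts: CodonCounts,
    inp_counts: CodonCounts,
    pd_stats: LibraryStats,
    inp_stats: LibraryStats,
    params: AnalysisParams = DEFAULT_PARAMS,
) -> PositionalProfile:
    """Raw -> smoothed -> normalized profile plus the coverage flag."""
    raw = codon_log2_profile(pd_counts, inp_counts, pd_stats, inp_stats, params)
    smoothed = smooth_profile(raw, params.half_window_codons)
    return PositionalProfile(
        gene_id=pd_counts.gene_id,
        raw_log2=raw,
        smoothed_log2=smoothed,
        normalized=normalize_profile(smoothed),
        mean_input_fp_per_codon=inp_counts.mean_fp_per_codon,
        passes_coverage=coverage_gate(inp_counts, params),
    )


def classify_gene(
    record: EnrichmentRecord,
    protein_length_aa: int,
    params: AnalysisParams = DEFAULT_PARAMS,
) -> GeneClass:
    """Assign a localized-translation class from gene-level enrichment.

    Requires a record that passed the input-depth filter.  Genes with an
    undefined enrichment fall into UNCLASSIFIED.
    """
    if not record.passed_filter:
        raise ValueError(f"{record.gene_id}: classification requires a filter-passing record")
    if not record.defined:
        return GeneClass.UNCLASSIFIED
    log2 = record.log2_enrichment
    if log2 < params.post_threshold_log2 and protein_length_aa > params.long_min_aa:
        return GeneClass.POST_TRANSLATIONAL
    if log2 > params.enrich_threshold_log2:
        if protein_length_aa > params.long_min_aa:
            return GeneClass.LONG_COTRANSLATIONAL
        if protein_length_aa < params.short_max_aa:
            return GeneClass.SHORT_MRNA_TARGETED
    return GeneClass.UNCLASSIFIED


def metagene_curve(
    profiles: Mapping[str, PositionalProfile],
    class_members: Iterable[str],
) -> MetageneCurve:
    """Aggregate normalized profiles of the member genes position by position.

    At position p only transcripts with at least p codons contribute; the
    mean is the arithmetic mean of the normalized log2-scale values and the
    sd their population standard deviation.
    """
    members = [profiles[g] for g in class_members if g in profiles]
    if not members:
        empty = np.empty(0)
        return MetageneCurve(np.empty(0, dtype=int), empty, empty, np.empty(0, dtype=int))
    longest = max(p.codon_count for p in members)
    stack = np.full((len(members), longest), np.nan)
    for i, p in enumerate(members):
        stack[i, : p.codon_count] = p.normalized
    n = np.sum(~np.isnan(stack), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=0)
    keep = n > 0
    return MetageneCurve(
        position=np.arange(1, longest + 1)[keep],
        mean=mean[keep],
        sd=sd[keep],
        n_transcripts=n[keep].astype(int),
    )


def estimate_onset(
    normalized: Sequence[float],
    rise_level: float = 0.5,
    sustain_codons: int = 50,
) -> Optional[int]:
    """First sustained crossing of the normalized profile above ``rise_level``.

    Returns the smallest 1-based codon p such that every value from p through
    min(p + sustain_codons, L) is >= rise_level, or None if no position
    sustains the rise.  The sustain requirement rejects transient noise peaks.
    """
    v = np.asarray(normalized, dtype=float)
    n = len(v)
    if n == 0:
        return None
    above = v >= rise_level
    # run[i]: length of the True run starting at i
    run = np.zeros(n, dtype=int)
    acc = 0
    for i in range(n - 1, -1, -1):
        acc = acc + 1 if above[i] else 0
        run[i] = acc
    for i in range(n):
        needed = min(i + sustain_codons, n - 1) - i + 1
        if run[i] >= needed:
            return i + 1
    return None


def profiles_table(profiles: Mapping[str, PositionalProfile]) -> pd.DataFrame:
    rows = []
    for gene_id in sorted(profiles):
        p = profiles[gene_id]
        for i in range(p.codon_count):
            rows.append(
                {
                    "gene_id": gene_id,
                    "codon_index": i + 1,
                    "raw_log2": p.raw_log2[i],
                    "smoothed_log2": p.smoothed_log2[i],
                    "normalized": p.normalized[i],
                }
            )
    return pd.DataFrame(rows)


def metagene_table(curves: Mapping[GeneClass, MetageneCurve]) -> pd.DataFrame:
    rows = []
    for cls in sorted(curves, key=lambda c: c.value):
        curve = curves[cls]
        for pos, mean, sd, n in zip(curve.position, curve.mean, curve.sd, curve.n_transcripts):
            rows.append(
                {"class": cls.value, "position": int(pos), "mean": mean, "sd": sd, "n_transcripts": int(n)}
            )
    return pd.DataFrame(rows)
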