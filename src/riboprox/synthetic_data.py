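"""Synthetic matched pulldown/input libraries with known ground truth.

The generator emulates the statistical structure of a proximity-labeling
ribosome profiling experiment at the outer mitochondrial membrane:

* short-CDS mRNA-targeted genes are uniformly enriched from the start codon;
* long-CDS cotranslationally targeted genes sit at baseline until an onset
  codon drawn from ~250-400 aa, then ramp logistically to a plateau;
* post-translationally imported genes are mildly depleted; non-local genes
  are flat at baseline;
* an unenriched bulk-background transcript supplies the large majority of
  each library's reads, as in real data where the analyzed cohort is a small
  fraction of the transcriptome.  This anchors the RPM normalization so that
  non-local genes measure close to log2 = 0.

Per-codon counts are Poisson draws around ``depth x expression-weight``
(input) and the truth-fold-scaled equivalent (pulldown, globally rescaled so
both library totals match).  Counts are expanded into footprint reads whose
center-weighted mass falls in (or, for the widest footprints, tightly
around) the source codon.

Long-gene (length, onset) pairs are accepted only when the generator's
expectation calculator puts the diluted gene-level log2 enrichment above
``min_detectable_long_log2``: the real cotranslational class is, by
construction, the set of genes whose whole-gene enrichment cleared the
detection threshold despite pre-onset dilution.

Identical seeds produce byte-identical output tables.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .annotations_io import (
    FootprintRead,
    GeneAnnotation,
    TranscriptModel,
    write_annotations,
    write_footprints,
    write_transcripts,
)
from .footprint_counting import LibraryStats
from .metagene import GeneClass


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Lengths are protein lengths in amino acids; the CDS adds a stop codon.
    ``onset_aa`` is the uniform window for the cotranslational recruitment
    onset.  ``plateau_*_log2`` are the true log2 enrichment effect sizes.
    ``background_mass_ratio`` sets the unenriched bulk-transcriptome read
    mass relative to the cohort's input mass (30 puts the cohort at ~3% of
    the library).  ``overdispersion`` > 0 switches the count noise to a
    gamma-Poisson mixture with that squared coefficient of variation.
    """

    n_short: int = 100
    n_long: int = 100
    n_post: int = 50
    n_nonlocal: int = 50
    short_len_aa: tuple[int, int] = (60, 199)
    long_len_aa: tuple[int, int] = (401, 1000)
    post_len_aa: tuple[int, int] = (401, 1000)
    nonlocal_len_aa: tuple[int, int] = (60, 1000)
    onset_aa: tuple[int, int] = (250, 400)
    plateau_short_log2: float = 2.5
    plateau_long_log2: float = 2.5
    plateau_post_log2: float = -0.5
    onset_ramp_scale_codons: float = 15.0
    min_detectable_long_log2: float = 1.7
    expression_log_sigma: float = 0.5
    mean_input_depth_fp_per_codon: float = 5.0
    read_len_min: int = 27
    read_len_max: int = 36
    utr5_nt: int = 60
    utr3_nt: int = 60
    background_mass_ratio: float = 30.0
    background_codons: int = 3000
    overdispersion: float = 0.0
    rnaseq_mean_fragments_per_kb: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.mean_input_depth_fp_per_codon > 0:
            raise ValueError("input depth must be positive")
        if not 0 < self.onset_aa[0] <= self.onset_aa[1] < self.long_len_aa[0]:
            raise ValueError("onset window must lie strictly inside the shortest long CDS")
        if self.utr5_nt < 30 or self.utr3_nt < 30:
            raise ValueError("UTRs must leave room for footprints spanning the CDS edges")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        kwargs = {}
        for f in cls.__dataclass_fields__.values():
            if f.name in d:
                value = d[f.name]
                if isinstance(value, (list, tuple)):
                    value = tuple(value)
                kwargs[f.name] = value
        return cls(**kwargs)


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one simulated gene."""

    gene_id: str
    true_class: GeneClass
    onset_codon: Optional[int]
    plateau_log2: float
    input_rpm: float = math.nan

    def __post_init__(self) -> None:
        if (self.onset_codon is not None) != (self.true_class is GeneClass.LONG_COTRANSLATIONAL):
            raise ValueError(
                f"{self.gene_id}: onset_codon must be present iff the gene is long_cotranslational"
            )


BACKGROUND_GENE_ID = "BULK_BG"


@dataclass
class SimResult:
    """Everything the pipeline needs plus the generator's own bookkeeping."""

    config: SimConfig
    transcripts: dict[str, TranscriptModel]  # keyed by transcript_id
    transcript_of_gene: dict[str, TranscriptModel]
    annotations: dict[str, GeneAnnotation]
    truths: dict[str, SimTruth]  # cohort genes only (background excluded)
    pulldown_reads: list[FootprintRead]
    input_reads: list[FootprintRead]
    pd_stats: LibraryStats
    inp_stats: LibraryStats
    input_codon_counts: dict[str, np.ndarray] = field(default_factory=dict)
    input_codon_expectation: dict[str, np.ndarray] = field(default_factory=dict)


def truth_profile(truth: SimTruth, codon_count: int, ramp_scale: float = 15.0) -> np.ndarray:
    """True per-codon log2 enrichment implied by a gene's class.

    Short/post/non-local genes are flat; long cotranslational genes ramp
    logistically from 0 to the plateau, centered at the onset codon.
    """
    if truth.true_class is GeneClass.LONG_COTRANSLATIONAL:
        codons = np.arange(1, codon_count + 1, dtype=float)
        return truth.plateau_log2 * expit((codons - truth.onset_codon) / ramp_scale)
    return np.full(codon_count, truth.plateau_log2, dtype=float)


def expected_gene_log2(delta: np.ndarray) -> float:
    """Gene-level log2 enrichment implied by a per-codon truth profile.

    The whole-gene ratio of expected densities is the (uniform-expression)
    mean of per-codon fold enrichments, so pre-onset codons dilute the
    gene-level score of cotranslational genes.
    """
    return float(np.log2(np.mean(2.0 ** np.asarray(delta, dtype=float))))


@dataclass(frozen=True)
class _SimGene:
    truth: SimTruth
    transcript: TranscriptModel
    annotation: GeneAnnotation
    expression_weight: float
    delta: np.ndarray


def _make_transcript(gene_id: str, aa: int, cfg: SimConfig) -> TranscriptModel:
    cds_len = 3 * (aa + 1)
    return TranscriptModel(
        gene_id=gene_id,
        transcript_id=f"T_{gene_id}",
        transcript_length_nt=cfg.utr5_nt + cds_len + cfg.utr3_nt,
        cds_start_nt=cfg.utr5_nt,
        cds_length_nt=cds_len,
    )


def _sample_genes(cfg: SimConfig) -> list[_SimGene]:
    """Deterministically draw the cohort's gene structures from the seed."""
    rng = np.random.default_rng([cfg.seed, 0])
    genes: list[_SimGene] = []

    def add(gene_id, true_class, aa, onset, plateau, is_mito, subloc, phylo):
        truth = SimTruth(gene_id, true_class, onset, plateau)
        tx = _make_transcript(gene_id, aa, cfg)
        delta = truth_profile(truth, tx.codon_count, cfg.onset_ramp_scale_codons)
        ann = GeneAnnotation(
            gene_id=gene_id,
            is_mito=is_mito,
            sub_localization=subloc,
            protein_length_aa=aa,
            is_secretome=False,
            phylo_origin=phylo,
        )
        weight = float(rng.lognormal(mean=0.0, sigma=cfg.expression_log_sigma))
        genes.append(_SimGene(truth, tx, ann, weight, delta))

    for i in range(cfg.n_short):
        aa = int(rng.integers(cfg.short_len_aa[0], cfg.short_len_aa[1] + 1))
        add(f"GS{i + 1:04d}", GeneClass.SHORT_MRNA_TARGETED, aa, None,
            cfg.plateau_short_log2, True, "IMM", "eukaryotic")

    for i in range(cfg.n_long):
        # accept (length, onset) only when the diluted gene-level enrichment
        # clears the detection threshold — the observable cotranslational
        # class is defined by that detection
        while True:
            aa = int(rng.integers(cfg.long_len_aa[0], cfg.long_len_aa[1] + 1))
            onset = int(rng.integers(cfg.onset_aa[0], cfg.onset_aa[1] + 1))
            probe = SimTruth(f"GL{i + 1:04d}", GeneClass.LONG_COTRANSLATIONAL, onset,
                             cfg.plateau_long_log2)
            delta = truth_profile(probe, aa + 1, cfg.onset_ramp_scale_codons)
            if expected_gene_log2(delta) >= cfg.min_detectable_long_log2:
                break
        add(f"GL{i + 1:04d}", GeneClass.LONG_COTRANSLATIONAL, aa, onset,
            cfg.plateau_long_log2, True, "matrix", "prokaryotic")

    for i in range(cfg.n_post):
        aa = int(rng.integers(cfg.post_len_aa[0], cfg.post_len_aa[1] + 1))
        add(f"GP{i + 1:04d}", GeneClass.POST_TRANSLATIONAL, aa, None,
            cfg.plateau_post_log2, True, "matrix", "unknown")

    for i in range(cfg.n_nonlocal):
        aa = int(rng.integers(cfg.nonlocal_len_aa[0], cfg.nonlocal_len_aa[1] + 1))
        add(f"GN{i + 1:04d}", GeneClass.UNCLASSIFIED, aa, None, 0.0,
            False, "unknown", "unknown")

    return genes


def _draw_counts(rng: np.random.Generator, lam: np.ndarray, cfg: SimConfig) -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    if cfg.overdispersion > 0:
        shape = 1.0 / cfg.overdispersion
        lam = rng.gamma(shape, lam * cfg.overdispersion)
    return rng.poisson(lam)


def _counts_to_reads(
    rng: np.random.Generator,
    counts: np.ndarray,
    transcript: TranscriptModel,
    cfg: SimConfig,
) -> list[FootprintRead]:
    """Expand per-codon counts into footprint records.

    One collapsed record per occupied codon: a footprint length is drawn and
    the read is placed so its center-weighted window is centered on the
    codon's middle nucleotide.  Windows of 1-3 nt fall entirely inside the
    codon; wider windows (reads > 29 nt) spill symmetrically into the
    adjacent codons, a sub-codon blur far below the 21-codon smoothing scale.
    """
    occupied = np.flatnonzero(counts)
    if occupied.size == 0:
        return []
    lengths = rng.integers(cfg.read_len_min, cfg.read_len_max + 1, size=occupied.size)
    spans = lengths - 26
    centers = transcript.cds_start_nt + 3 * occupied + 1
    fives = centers - (spans - 1) // 2 - 13
    reads = []
    tx_id = transcript.transcript_id
    for codon, five, length in zip(occupied, fives, lengths):
        reads.append(FootprintRead(tx_id, int(five), int(length), int(counts[codon])))
    return reads


def simulate_cohort(config: SimConfig) -> SimResult:
    """Generate matched pulldown/input footprint libraries with truth tables."""
    genes = _sample_genes(config)
    rng = np.random.default_rng([config.seed, 1])
    depth = config.mean_input_depth_fp_per_codon

    # expectation pass: cohort and background input mass, pulldown scaling
    inp_mass = sum(depth * g.expression_weight * g.transcript.codon_count for g in genes)
    pd_mass = sum(
        depth * g.expression_weight * float(np.sum(2.0 ** g.delta)) for g in genes
    )
    bg_mass = config.background_mass_ratio * inp_mass
    scaling = (inp_mass + bg_mass) / (pd_mass + bg_mass)  # match library totals

    bg_tx = TranscriptModel(
        gene_id=BACKGROUND_GENE_ID,
        transcript_id=f"T_{BACKGROUND_GENE_ID}",
        transcript_length_nt=config.utr5_nt + 3 * config.background_codons + config.utr3_nt,
        cds_start_nt=config.utr5_nt,
        cds_length_nt=3 * config.background_codons,
    )
    bg_ann = GeneAnnotation(BACKGROUND_GENE_ID, False, "unknown",
                            config.background_codons - 1, False, "unknown")

    input_reads: list[FootprintRead] = []
    pulldown_reads: list[FootprintRead] = []
    input_codon_counts: dict[str, np.ndarray] = {}
    input_codon_expectation: dict[str, np.ndarray] = {}
    inp_total = 0
    pd_total = 0
    truths: dict[str, SimTruth] = {}

    for g in genes + [None]:  # None sentinel = background transcript
        if g is None:
            tx = bg_tx
            lam_in = np.full(tx.codon_count, bg_mass / config.background_codons)
            lam_pd = scaling * lam_in
        else:
            tx = g.transcript
            lam_in = np.full(tx.codon_count, depth * g.expression_weight)
            lam_pd = scaling * lam_in * 2.0 ** g.delta
        c_in = _draw_counts(rng, lam_in, config)
        c_pd = _draw_counts(rng, lam_pd, config)
        input_reads.extend(_counts_to_reads(rng, c_in, tx, config))
        pulldown_reads.extend(_counts_to_reads(rng, c_pd, tx, config))
        inp_total += int(c_in.sum())
        pd_total += int(c_pd.sum())
        if g is not None:
            input_codon_counts[tx.gene_id] = c_in
            input_codon_expectation[tx.gene_id] = lam_in

    expected_inp_total = inp_mass + bg_mass
    for g in genes:
        rpm = depth * g.expression_weight / expected_inp_total * 1e6
        truths[g.truth.gene_id] = replace(g.truth, input_rpm=rpm)

    transcripts = {g.transcript.transcript_id: g.transcript for g in genes}
    transcripts[bg_tx.transcript_id] = bg_tx
    transcript_of_gene = {g.transcript.gene_id: g.transcript for g in genes}
    transcript_of_gene[BACKGROUND_GENE_ID] = bg_tx
    annotations = {g.annotation.gene_id: g.annotation for g in genes}
    annotations[BACKGROUND_GENE_ID] = bg_ann

    return SimResult(
        config=config,
        transcripts=transcripts,
        transcript_of_gene=transcript_of_gene,
        annotations=annotations,
        truths=truths,
        pulldown_reads=pulldown_reads,
        input_reads=input_reads,
        pd_stats=LibraryStats("pulldown", float(pd_total)),
        inp_stats=LibraryStats("input", float(inp_total)),
        input_codon_counts=input_codon_counts,
        input_codon_expectation=input_codon_expectation,
    )


def simulate_rnaseq(config: SimConfig) -> pd.DataFrame:
    """Gene-level fragment counts for the intact-mRNA readout.

    A single labeled ribosome suffices to pull down a whole transcript, so a
    gene's RNA-level fold enrichment is the translation-weighted mean of its
    per-codon fold enrichments, applied flat across the transcript.  Returns
    a table with per-gene fragment counts and the two library totals in the
    ``pd_total``/``inp_total`` columns (identical on every row).
    """
    genes = _sample_genes(config)
    rng = np.random.default_rng([config.seed, 2])

    folds = np.array([float(np.mean(2.0 ** g.delta)) for g in genes])
    kb = np.array([g.transcript.transcript_length_nt / 1000.0 for g in genes])
    weights = np.array([g.expression_weight for g in genes])
    lam_in = config.rnaseq_mean_fragments_per_kb * weights * kb

    bg_kb = (config.utr5_nt + 3 * config.background_codons + config.utr3_nt) / 1000.0
    bg_lam = config.background_mass_ratio * float(lam_in.sum())

    scaling = (lam_in.sum() + bg_lam) / ((lam_in * folds).sum() + bg_lam)
    lam_pd = scaling * lam_in * folds

    frag_in = rng.poisson(np.append(lam_in, bg_lam))
    frag_pd = rng.poisson(np.append(lam_pd, scaling * bg_lam))

    rows = []
    gene_ids = [g.truth.gene_id for g in genes] + [BACKGROUND_GENE_ID]
    tx_len = [g.transcript.transcript_length_nt for g in genes] + [int(bg_kb * 1000)]
    for gid, length, fi, fp in zip(gene_ids, tx_len, frag_in, frag_pd):
        rows.append(
            {
                "gene_id": gid,
                "transcript_length_nt": length,
                "pulldown_fragments": int(fp),
                "input_fragments": int(fi),
                "pd_total": int(frag_pd.sum()),
                "inp_total": int(frag_in.sum()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_TRUTH_COLUMNS = ("gene_id", "true_class", "onset_codon", "plateau_log2", "input_rpm")


def write_truth(truths: Mapping[str, SimTruth], path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(_TRUTH_COLUMNS) + "\n")
        for gene_id in sorted(truths):
            t = truths[gene_id]
            onset = "" if t.onset_codon is None else str(t.onset_codon)
            # repr round-trips doubles exactly, keeping reload == original
            fh.write(
                f"{t.gene_id}\t{t.true_class.value}\t{onset}\t{t.plateau_log2!r}\t{t.input_rpm!r}\n"
            )


def read_truth(path: str | os.PathLike) -> dict[str, SimTruth]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    truths = {}
    for row in df.itertuples(index=False):
        onset = None if pd.isna(row.onset_codon) else int(row.onset_codon)
        truths[row.gene_id] = SimTruth(
            row.gene_id, GeneClass(row.true_class), onset, float(row.plateau_log2),
            float(row.input_rpm),
        )
    return truths


def write_cohort(result: SimResult, outdir: str | os.PathLike) -> dict[str, str]:
    """Write the simulated cohort in the same TSV dialects the loaders read."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "transcripts": os.path.join(outdir, "transcripts.tsv"),
        "annotations": os.path.join(outdir, "annotations.tsv"),
        "truth": os.path.join(outdir, "truth.tsv"),
        "pulldown_footprints": os.path.join(outdir, "pulldown.footprints.tsv"),
        "input_footprints": os.path.join(outdir, "input.footprints.tsv"),
    }
    write_transcripts(
        [result.transcripts[tx] for tx in sorted(result.transcripts)], paths["transcripts"]
    )
    write_annotations(result.annotations, paths["annotations"])
    write_truth(result.truths, paths["truth"])
    write_footprints(result.pulldown_reads, paths["pulldown_footprints"])
    write_footprints(result.input_reads, paths["input_footprints"])
    return paths
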