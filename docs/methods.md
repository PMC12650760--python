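# Methods

## The measurement being modelled

Proximity-specific ribosome profiling tags ribosomes near a membrane of
interest (here the outer mitochondrial membrane, OMM), pulls down the tagged
fraction, and sequences ribosome-protected mRNA footprints from both the
pulldown and the matched unenriched total lysate ("input").  Because each
footprint marks a ribosome at a specific codon, the ratio of pulldown to
input footprint density reports *where along a coding sequence* translation
happens at the membrane:

* mRNAs recruited before translation begins (short-CDS, mRNA-targeted genes)
  are enriched uniformly from the start codon;
* cotranslationally recruited genes (long CDSes) sit at baseline until the
  nascent chain engages the membrane, then rise to a plateau;
* post-translationally imported genes are mildly depleted throughout.

This package implements the quantification side of such an experiment:
counting, enrichment scores, codon-resolution profiles, metagene curves,
classification, onset estimation, and reporter-assay (qPCR/RIP-qPCR)
normalization — plus a synthetic-data generator so every stage is testable
without sequencing data.

## Counting and gene-level enrichment

Footprints of 27–36 nt are **center-weighted**: 13 nt are trimmed from each
end and the read's count is spread uniformly over the remaining L − 26
central positions.  Positions inside the CDS (0-based, half-open transcript
coordinates; the CDS includes the stop codon) and not excluded by an
alignability mask are binned into codons.  Counts are fractional by
construction and stay fractional end to end.  Two deliberate edge rules:

* weight straddling the CDS boundary contributes only its in-CDS part, with
  no rescaling of the remainder;
* masked positions reduce counted weight but do *not* shorten the CDS length
  used for densities.

Gene-level enrichment is `log2(pulldown RPKM / input RPKM)` over the CDS,
with the library-size denominator taken over *all* reads mapping to any
annotated transcript.  Genes with fewer than 64 CDS-mapping footprints in
the total input are excluded (`passed_filter`); the 64 is compared against
the weighted (fractional) count, since center weighting makes integer counts
unavailable.  A gene with zero density in either library carries an explicit
undefined state rather than a pseudo-counted value — the pseudo-count below
is defined only for codon-level profiles, and we do not extend it silently.
The intact-mRNA readout uses the same log2 ratio over whole-transcript FPKM.

## Codon-resolution profiles

Per codon: counts are converted to RPM, 0.1 RPM is added to both libraries,
and the log2 quotient is taken.  Profiles are smoothed with a 21-codon
moving average truncated at the transcript ends (codon i averages codons
max(1, i−10)..min(L, i+10)); the stated edge rule covers only the first 10
codons, and we mirror it at the 3′ end for symmetry.  The truncated window
*includes* the focal codon.  Smoothed profiles are normalized by the largest
absolute smoothed value in the gene, so every profile lies in [−1, 1] with
max |value| = 1; an identically-zero profile maps to zeros.  Normalization
follows smoothing.  Profiles are built only for genes with a mean total-input
depth of ≥ 3 footprints/codon; the gate uses the input library because input
depth limits the interpretability of both libraries.

## Metagene curves and classification

At each codon position the normalized values of all member transcripts that
are at least that long are aggregated; transcripts that end earlier are
excluded at that position, so membership counts are non-increasing.  The
aggregate is described as a geometric mean of enrichment ratios; since the
values are already on the log2 scale, this is the arithmetic mean of the
log-scale values (a literal geometric mean of signed log values would be
undefined), with the population standard deviation alongside.

Classification uses gene-level enrichment from a single designated replicate
and protein length:

| class | enrichment | protein length |
|---|---|---|
| post_translational | log2 < −0.3 | > 400 aa |
| long_cotranslational | log2 > 1.5 | > 400 aa |
| short_mrna_targeted | log2 > 1.5 | < 200 aa |

Everything else (including boundary values — the thresholds are strict) is
unclassified.

## Onset estimation

The recruitment onset of a cotranslational gene is the smallest codon p such
that the normalized profile stays at or above `rise_level` (default 0.5)
from p through min(p + 50, L).  The 0.5 level matches the half-plateau point
of a logistic rise — for a symmetric ramp the crossing sits at the true
onset — and the 50-codon sustain requirement rejects transient noise peaks.
With the default 0.1 RPM pseudo-count the plateau is shrunk toward zero but
the normalized crossing moves by only ~2 codons at default depths.  No
changepoint model is attempted; the rule is deliberately transparent.

## The synthetic-data generator

`simulate_cohort` draws, per gene: a protein length uniform in its class
range (short 60–199 aa, long/post 401–1000 aa, non-local 60–1000 aa), a
log-normal expression weight (σ = 0.5, median 1), and for long genes an
onset uniform in 250–400 aa.  The true per-codon log2 enrichment is flat for
short (+2.5), post (−0.5), and non-local (0) genes; long genes follow a
logistic ramp from 0 to +2.5 centered at the onset with a 15-codon scale (a
gradual engagement over ~60 aa rather than a hard step; the scale is a
generator knob, not a claim).  Input per-codon expected counts are
`depth × weight` (default depth 5 footprints/codon); pulldown expectations
multiply by `2^truth` and a single global scaling that equalizes the two
library totals.  Counts are Poisson (optionally gamma-Poisson via
`overdispersion`), drawn per codon, and expanded into collapsed footprint
records whose center-weighted window is centered on the codon's middle
nucleotide.  For reads of 27–29 nt the window (1–3 nt) falls entirely inside
the codon; wider windows spill sub-codon weight into the neighbouring
codons, a blur far below the 21-codon smoothing scale.  All randomness flows
from one integer seed; identical seeds give byte-identical output tables.

Two structural choices matter and were fixed analytically, up front:

* **Bulk background.**  Enrichment scores are relative to whole-library
  composition: with only an enriched cohort in the library, RPM
  normalization would shift every score down by log2 of the cohort's mean
  fold (≈ 1.3 at the default class mix), and non-local genes would not
  center at 0.  Real libraries do not behave this way because the analyzed
  cohort is a small slice of the transcriptome.  The generator therefore
  adds one large unenriched background transcript carrying
  `background_mass_ratio` (default 30) times the cohort's input mass —
  cohort ≈ 3% of reads — leaving a residual composition shift of ≈ −0.07
  log2 units, visible in the recovered baseline.
* **Detectable long genes.**  A long gene's whole-gene enrichment is diluted
  by its pre-onset segment: expected log2 = log2(mean over codons of
  2^truth).  For independent draws of length and onset, roughly a fifth of
  pairs would fall below the 1.5 classification threshold no matter how deep
  the sequencing — those genes are real biology but would never be *called*
  cotranslational.  Since the cotranslational class is, operationally, the
  set of genes that cleared detection, the generator resamples (length,
  onset) until its expectation calculator (`expected_gene_log2`) gives
  ≥ `min_detectable_long_log2` (default 1.7, a modest margin over the
  threshold so Poisson noise does not straddle it).

What the generator does **not** emulate: positional coverage bias (ramps at
start codons, pause sites), rRNA contamination, UMI structure, ligation
biases, multi-isoform genes, overdispersion beyond the optional
gamma-Poisson, or biological scatter in per-gene effect sizes.  Passing
recovery tests therefore demonstrates that the pipeline's estimators are
correct and well calibrated under the stated noise model — not that the
biological thresholds would perform identically on real libraries.

`simulate_rnaseq` reuses the same genes: because one labeled ribosome pulls
down a whole transcript, a gene's RNA-level fold is the mean of its
per-codon folds applied flat, with gene-level Poisson fragment counts
(default 100 fragments/kb at weight 1) and the same background.

## Reporter quantification

qPCR inputs are relative quantities (post ΔCt); efficiency modelling is out
of scope.  Enrichment is pulldown/input per amplicon; reporters are
normalized to an endogenously expressed reference gene in the same sample
and expressed as a percentage of the identically normalized positive-control
reporter; RIP-qPCR binding scores are log2 ratios against an inert-protein
(mCherry) control; an endogenous non-target gene (e.g. H2AC17) serves as a
per-batch internal control.  All ratios are computed per replicate and
summarized as mean ± sd (the per-replicate-then-average reading; the
alternative, ratios of averaged quantities, differs only at second order).

## Numerical and engineering choices

* Isoform collapse: one transcript per gene, longest CDS, ties broken by
  transcript id; the choice is logged.
* Duplicate transcript ids are an error naming the id; non-triplet CDSes are
  dropped and counted in a load report (retained + dropped = input).
* The input-depth filter (≥ 64) and coverage gate (≥ 3/codon) are inclusive
  at the boundary and exact — no epsilon.
* Output tables are written with deterministic ordering and `%.10g` floats;
  the truth table uses `repr` round-tripping so reloading reproduces the
  exact doubles.
* Depth invariance holds bit-exactly under power-of-two rescaling; other
  factors re-round the fractional 1/(L−26) weights and agree to the last ulp
  (≲ 1e−15).
* Problem sizes: acceptance-level runs use the 300-gene default cohort plus
  a 150-gene cotranslational-only cohort for onset recovery (the coverage
  gate passes ~78/100 long genes at default expression scatter, so 150 keeps
  ≥ 100 genes evaluated); unit tests use 10–60-gene cohorts.

## Known limitations

* Whether the original 64-footprint filter counted raw or center-weighted
  reads, whether the crossmap mask shortens the effective CDS in RPKM, which
  library the coverage gate used, and whether the original edge window
  includes the focal codon are not documented upstream; the choices above
  are stated and tested but may differ from the original scripts.
* Multi-isoform quantification is out of scope; genes are single-isoform by
  construction after the longest-CDS collapse.
* The onset estimator reports the sustained-crossing codon of the
  *normalized* profile; for genes whose plateau is weak relative to noise it
  can return nothing, and no uncertainty is attached.
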