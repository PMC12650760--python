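# riboprox

Analysis of **proximity-specific ribosome profiling**: where on each mRNA is
translation happening at a membrane of interest?

In this experimental design, ribosomes near a target compartment (e.g. the
outer mitochondrial membrane) are tagged, the tagged fraction is pulled down,
and ribosome footprints are sequenced from both the pulldown and the matched
total-input lysate.  For a gene with CDS footprint densities
$d_{\mathrm{pd}}$ and $d_{\mathrm{in}}$ (RPKM, with the library total taken
over all transcript-mapped reads), the localization score is

$$\mathrm{enrichment} = \log_2\!\frac{d_{\mathrm{pd}}}{d_{\mathrm{in}}}$$

and the per-codon version of the same ratio (RPM-scaled counts, 0.1 RPM
pseudo-count, 21-codon smoothing, max-|value| normalization) resolves *when
during synthesis* a transcript reaches the membrane.  The package covers the
full quantification chain for such experiments:

* **`annotations_io`** — transcript models (flat TSV, Ensembl GTF, BED12),
  gene annotation tables, alignability masks, footprint records (TSV or
  transcriptome-aligned BAM/SAM);
* **`footprint_counting`** — center-weighted per-codon counting (27–36 nt
  reads, 13 nt nibbled from each end) with optional masking;
* **`enrichment`** — gene-level footprint RPKM and RNA-seq FPKM log2
  enrichment, the 64-footprint input filter, threshold summaries;
* **`metagene`** — codon-resolution profiles, smoothing/normalization,
  metagene curves, classification into post-translational (<−0.3, >400 aa),
  long-CDS cotranslational (>1.5, >400 aa) and short-CDS mRNA-targeted
  (>1.5, <200 aa) classes, and recruitment-onset estimation;
* **`reporter_quant`** — qPCR/RIP-qPCR normalization chains (endogenous
  reference, percent-of-control, internal control, log2 vs inert control);
* **`synthetic_data`** — a fully seeded generator of matched
  pulldown/input libraries with known classes, onsets and effect sizes;
* **`cli_pipeline`** (`riboprox` command) — `simulate`, `count`, `enrich`,
  `rnaseq-enrich`, `metagene`, `classify`, `reporter`, `run-all`.

## Worked example

Simulate a small cohort with known ground truth and run the full pipeline:

```python
from riboprox import SimConfig, simulate_cohort, analyze_cohort, GeneClass

sim = simulate_cohort(SimConfig(n_short=20, n_long=20, n_post=10, n_nonlocal=10, seed=42))
result = analyze_cohort(sim.transcript_of_gene, sim.pulldown_reads, sim.input_reads,
                        sim.pd_stats, sim.inp_stats, sim.annotations)

rec = result.records["GL0001"]
truth = sim.truths["GL0001"]
print(f"GL0001: log2 enrichment {rec.log2_enrichment:.2f} "
      f"(fold {rec.fold_enrichment:.1f}), class {result.classes['GL0001'].value}")
print(f"        estimated onset codon {result.onsets['GL0001']}, true onset {truth.onset_codon}")

n_correct = sum(result.classes[g] is t.true_class for g, t in sim.truths.items())
print(f"classes recovered: {n_correct}/{len(sim.truths)}")

curve = result.curves[GeneClass.LONG_COTRANSLATIONAL]
print(f"long-class metagene mean, codons 1-100: {curve.window_mean(1, 100):.3f}; "
      f"codons 450-500: {curve.window_mean(450, 500):.3f}")
```

prints

```
GL0001: log2 enrichment 1.87 (fold 3.7), class long_cotranslational
        estimated onset codon 370, true onset 362
classes recovered: 60/60
long-class metagene mean, codons 1-100: -0.031; codons 450-500: 0.868
```

`GL0001` is a simulated cotranslationally targeted gene: its whole-gene
enrichment (1.87) is diluted below the +2.5 per-codon plateau by the
unenriched pre-onset segment, yet clears the 1.5 detection threshold, and
the positional profile pins recruitment to within a handful of codons of the
true onset.  The metagene contrast — flat near the start codon, high past
codon 450 — is the signature that separates cotranslational recruitment from
start-codon-anchored mRNA targeting.

The same analysis from the shell:

```sh
riboprox run-all --seed 42 --out results/demo
```

writes `enrichment.tsv`, `classification.tsv`, `profiles.tsv`,
`metagene.tsv`, the simulated inputs, and a `manifest.json` with parameter
values, input checksums and per-stage record counts.  Identical seeds give
byte-identical outputs.

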