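# flagseq

Analysis toolkit for systemic anti-flagellin antibody repertoires measured
by phage-display immunoprecipitation sequencing (PhIP-Seq), together with a
synthetic-data generator that plants recoverable disease-specific binding
patterns in case/control cohorts.

## What it does

- **`flagseq.enrich`** — PhIP-Seq pre-processing and enrichment calling:
  read normalization (cap 1.25M / floor 750k, hypergeometric subsampling),
  a generalized Poisson null fitted per input-read level with parameter
  interpolation (contamination-robust refitting), upper-tail p-values,
  Bonferroni seropositivity, fold changes (seropositive peptides with >= 25
  input reads only), and per-sample QC (< 200 enriched peptides excluded).
- **`flagseq.librarydesign`** — antigen-library encoding: 64/20 (or 54/20)
  peptide tiling with an end-anchored final tile, reverse translation with
  an *E. coli* high-expression codon table and EcoRI/HindIII site avoidance,
  and Hamming-distance error-correcting DNA barcodes (distance 3 corrects 1
  error, distance 5 corrects 2) with bounded-distance decoding.
- **`flagseq.seqcompare`** — pairwise protein alignment (BLOSUM62, affine
  gaps 11/1), percent identity, N-/C-terminal domain annotation by mapping
  reference domains, relative epitope start positions, and case/control
  prevalence ratios with a half-subject continuity correction.
- **`flagseq.classify`** — stimulator/silent/evader classification from
  TLR5 binding/activation readouts relative to a PIM-like reference, and
  class-similarity profiling of antibody-bound flagellins (full-length,
  peptide, N-domain, C-domain scopes) with Friedman / Kruskal-Wallis +
  Dunn-Bonferroni comparisons, including a bound-vs-unbound contrast.
- **`flagseq.stats_report`** — rank-test battery (Wilcoxon-Mann-Whitney
  with exact small-sample p, Spearman, Friedman with exact small-sample
  permutation p, Kruskal-Wallis + Dunn, chi-square), per-sample flagellin
  burden, cohort balance checks, and pipeline orchestration.
- **`flagseq.synthgen`** — synthetic flagellin panels (template-derived
  stimulator/silent/evader classes with known domain coordinates), tiled
  peptide libraries with non-flagellin background proteins, matched
  case/control cohorts, and generalized-Poisson count matrices with planted
  per-signature enrichment and full ground truth.

## CLI

```bash
flagseq simulate --out run/sim --seed 1           # library + count matrices
flagseq score --input run/sim/input.tsv --output run/sim/output.tsv \
    --out calls.tsv --floor 0 --min-enriched 0    # enrichment calling
flagseq domains --proteins prot.fasta --nref nref.fasta --cref cref.fasta
flagseq classify --queries bound.fasta --refs refs.fasta --ref-meta refs.tsv
flagseq report --out run/full --seed 1            # end-to-end pipeline
```

`flagseq report` simulates a CD-like and an ME/CFS-like cohort mimic over a
shared library, calls enrichment, and reproduces the analysis flow:
flagellin burden tests, cross-cohort prevalence concordance,
relative-position profiles, domain annotation, and class-similarity
statistics. Outputs (TSV tables, `summary.json`, plots) land in the run
directory; reruns with the same seed are bit-identical.

Note on scale: synthetic runs use a desk-scale geometry (about 3,000
peptides, 40 cases + 40 controls, 200k reads/sample), so `score` defaults
meant for full-size data (`--floor 750000`, `--min-enriched 200`) should be
relaxed as shown above; `flagseq report` does this automatically.

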