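# tssbreadth

Breadth patterns of the H3K4me3 chromatin mark at transcription start sites
(TSSs) and their association with differential gene transcription in
disease.

H3K4me3 is the canonical active-promoter mark. Beyond peak *height*, its
*breadth* around the TSS carries regulatory information: some promoters
show a narrow peak confined to ±250 bp, others extend upstream, downstream
(to ~650 bp, where the transition to the elongation mark H3K36me3 is often
found), or both. This package implements, as a reusable and tested
pipeline, an analysis of those patterns in case/control ChIP-seq + RNA-seq
cohorts (modeled on SLE monocytes vs healthy controls):

- **Coverage**: reads extended to 200 bp, per-base depth around each TSS
  averaged into a TSS × 41 matrix (50 bp bins, −1025..+1025 bp, oriented in
  transcription direction), normalized so that 0 = input background and
  ±1.0 = two-fold above/below background.
- **Classification**: two-component univariate normal mixtures (EM) on the
  TSS-region mean (marked vs unmarked) and on the upstream−TSS and
  downstream−TSS differences (extended vs not, per side) yield four
  high-confidence patterns — narrow peak, upstream extended, downstream
  extended, broad symmetric — plus unclassified/unmarked.
- **Association**: per-pattern expression premium (Wilcoxon rank-sum vs the
  unclassified group), Loess-detrended between-sample variance, Fisher
  odds ratios against differential expression, hypergeometric gene-set
  overrepresentation with BH FDR.
- **Dose–response**: % H3K4me3 change per region (upstream/TSS/downstream,
  linear scale), OLS residualization of the inter-region dependence, the
  response slope of % transcription change per 1 % downstream H3K4me3
  change over the 1–10 % range, fraction-increased summaries for DE-up
  genes, and zero-centered region summaries for external gene lists.
- **Motifs**: PWM log-odds scanning of −1..+1 kb promoter windows (both
  strands, MEME-minimal input) with breadth-stratified positional
  enrichment.
- **Synthetic data**: a first-class generator producing reads, input
  controls, expression tables, promoter sequences and ground-truth labels
  with the statistical structure the analysis assumes, so the whole chain
  is testable without any external download.

Key classification agreement statistics (Cohen's κ with the asymptotic
null test) quantify pattern persistence between conditions.

## Worked example

The numbered scripts under `analysis/` run the full story on synthetic
cohorts and write their tables under `results/analysis/`. For example:

```bash
python analysis/02_classify_breadth.py
```

prints (seed 11, 600 TSSs, 6 samples per group):

```
ctrl: label counts {'unmarked': 279, 'downstream_extended': 111,
                    'upstream_extended': 109, 'broad_symmetric': 62,
                    'narrow_peak': 39}
ctrl: recovered 100.0% of true pattern labels
pattern persistence: 96.3% same label, kappa = 0.948 (p = 1.70e-170, n = 321)
```

i.e. the mixture classifier recovers every planted pattern label, and the
control-vs-disease reclassification agrees at the rate implied by the
generator's persistence probability. Continuing the chain:

```bash
python analysis/03_transcription_association.py
python analysis/04_dose_response.py
```

```
   downstream_extended: +161.1% (n=891, Wilcoxon p=1.89e-190)
           narrow_peak: OR= 0.13 p=4.86e-35
   downstream_extended: OR= 2.53 p=2.49e-48
downstream slope over 1-10%: 1.509 +- 0.030 % transcription per % H3K4me3
of 628 DE-up genes, % with increased residualized H3K4me3 per region:
    upstream: 48.4%   tss: 57.8%   downstream: 79.3%
```

Downstream-extended promoters carry a ~+150 % expression premium over
unclassified ones and are ~2.4× enriched among overexpressed genes, while
narrow peaks are strongly depleted (OR ≈ 0.14); every 1 % increase of
downstream H3K4me3 raises transcription by ~1.5 % on average, and ~79 % of
overexpressed genes gain downstream H3K4me3 — the pattern of numbers the
pipeline is built to measure.

A one-shot orchestration (simulates its own cohort when no reads are
configured) is also available:

```bash
tssbreadth run-all --seed 13 --out results/run
tssbreadth simulate --out results/sim     # write BED/TSV/FASTA/MEME bundle
tssbreadth profile --reads a.bed --input inp.bed --tss tss.bed --out m.tsv
tssbreadth classify --matrix m.tsv --out patterns.tsv
```

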