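# enhancerkit

Two-stage enhancer prediction and boundary localization for 4000 bp genomic
regions.

**Stage 1 — region classification.** Candidate regions are labeled from peak
overlaps (STARR-seq ∩ DNase-seq candidates supported by at least one ChIP-seq
peak for H3K27ac/H3K4me3/H3K4me1/H3K9ac), negatives are sampled at a 1:10
ratio, and per-base signal is averaged in 10 bp bins (400 values per signal
per region). A blending ensemble fits a registry of base classifiers per
signal kind on a 7:3 stratified split with 10:1 positive:negative sample
weights; their hard-label (0/1) holdout predictions, stacked column-wise and
concatenated across signals, feed a Kolmogorov–Arnold network (KAN)
meta-classifier trained with Adam and class-weighted cross-entropy under
stratified 5-fold cross-validation. The KAN is implemented from scratch in
numpy: learnable cubic B-spline edge functions on a uniform grid plus a
silu residual, with analytic gradients (checked against finite differences
in the test suite).

**Stage 2 — boundary localization.** Positive regions are segmented into
200 bp windows at a 50 bp step (77 windows per 4000 bp region). Window
sequences are embedded (normalized k-mer frequencies by default, or an
externally supplied embedding matrix), scored by a stacking ensemble
(gradient-boosted level-1 learner whose 10-fold out-of-fold predictions are
concatenated to the original features for a selected meta-learner), and the
per-window probabilities become a single boundary call: windows with
probability ≥ mean − 0.3·std are retained, consecutive retained windows are
merged, and the run with the highest mean probability is reported as BED6.

A synthetic-data module generates peaks, bedGraph tracks, labeled signal
matrices, and sequences with planted motif-dense enhancers so the full
pipeline runs and is tested without any external downloads.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: structural
constants (77 windows, 400 bins), oracle-equivalence suites (interval
intersection vs per-base masks, dynamic-threshold calling vs exhaustive run
enumeration, AUROC vs the O(n²) pairwise oracle, KAN gradients vs central
finite differences), synthetic recovery benchmarks, and the noise-robustness
trend.

## CLI

Single entry point `enhancerkit` with subcommands:

```bash
# synthetic data (signals | regions | windows | genome)
enhancerkit simulate genome --seed 1 --n-pos 10 --out genome/

# stage 1: label regions + bin signals, train, predict, evaluate
enhancerkit prep --starr genome/starr_peaks.bed --dnase genome/dnase_peaks.bed \
    --chip genome/h3k27ac_peaks.bed --chip genome/h3k4me3_peaks.bed \
    --track DNase genome/dnase_signal.bedgraph \
    --track H3K27ac genome/h3k27ac_signal.bedgraph \
    --chrom-sizes genome/chrom.sizes --seed 0 --out matrix
enhancerkit train-region --matrix matrix --out blend.joblib --report report.json
enhancerkit predict-region --matrix matrix --model blend.joblib --out pred.tsv
enhancerkit eval-region --predictions pred.tsv --matrix matrix

# stage 2: train the window scorer, score windows, call boundaries
enhancerkit train-locator --seed 0 --out locator.joblib
enhancerkit score-windows --fasta regions.fa --model locator.joblib --out probs.bedgraph
enhancerkit locate --fasta regions.fa --model locator.joblib --out calls.bed

# full synthetic end-to-end pipeline from a JSON/YAML config
enhancerkit run --config pipeline.json
```

Exit codes: 0 ok, 1 user error, 2 internal error.

## Layout

```
src/enhancerkit/
  regions.py    # BED/bedGraph/chrom.sizes I/O, labeling, binning, noise
  kan.py        # from-scratch KAN classifier (B-splines, Adam, persistence)
  blending.py   # base-classifier registry, 7:3 blend, KAN meta-classifier CV
  locator.py    # windows, k-mer/external embeddings, stacking, threshold calls
  synthetic.py  # seeded generators for every stage + on-disk genome fixture
  metrics.py    # accuracy/sensitivity/specificity/MCC, rank AUROC, AUPRC
  cli.py        # click CLI and end-to-end pipeline runner
```
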