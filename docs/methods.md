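# Methods

This note documents the models, procedures, and numerical choices behind
the package, and what its synthetic benchmarks do and do not demonstrate.

## Problem setting

Spent embryo culture medium (SECM) contains cell-free DNA from two
sources: the embryo itself and maternal cumulus cells. Read-depth
copy-number analysis of SECM for noninvasive preimplantation genetic
testing (niPGT-A) is confounded by the maternal fraction: once maternal
contamination dominates, embryonic aneuploidies are diluted toward the
diploid baseline and disappear from the profile (a false negative), and
the sex call can flip from XY to XX. The package addresses this by
(1) scoring each bisulfite-sequencing read with the probability that it
is maternal in origin, using sequence plus per-base methylation calls;
(2) estimating the sample's maternal fraction from the score set;
(3) filtering to an embryo-enriched read subset with a contamination-
dependent threshold; and (4) reconstructing the copy-number profile from
the retained reads.

## Read representation

Reads are aligned records carrying a Bismark-XM-style methylation call
string (`Z`/`z` methylated/unmethylated CpG, `H`/`h`, `X`/`x` for CH
context, `.` no call). Preprocessing removes the first 5 bases from the
5' end of every read (adapter-adjacent artifacts) and truncates the 3'
end to a uniform 66 bp; shorter reads are dropped. R2 reads with more
than 3 unmethylated-CH calls are discarded together with their R1 mates;
unpaired reads have the rule applied directly. Whether the 5' trim
applies to both mates is ambiguous in paired protocols; this package
applies it to every read and counts what it drops.

Each 66 bp read is one-hot encoded as a 66 x 5 binary matrix with
channels (A, C, G, T, mC). A methylated CpG cytosine sets both the C and
mC channels, giving the row (0,1,0,0,1); CH-context methylation does not
activate the mC channel; N bases are all-zero rows (zero-padding keeps
the per-position channel-sum invariant testable).

## Read-origin model

The classifier maps the encoded read to P(maternal):

1. a 1D convolution (default 100 filters, width 10, stride 1) with ReLU,
   extracting local sequence/methylation features;
2. multi-head scaled dot-product self-attention over the 57 feature
   positions (softmax(QK^T/sqrt(d_k))V per head, concatenated and
   projected), added residually;
3. a bidirectional LSTM whose final hidden states (both directions,
   concatenated) summarize the read;
4. a linear head with sigmoid output.

Score orientation is high = maternal, low = embryonic; embryo-enriched
filtering keeps low-score reads. Module toggles allow ablations (a
disabled attention block becomes the identity; without the LSTM the
features are mean-pooled).

No deep-learning framework is a dependency: the network runs on a
compact reverse-mode automatic-differentiation engine over numpy arrays
(`decent.nn`), implementing exactly the primitives the model needs.
Unit tests check every building block against hand-rolled oracles
(brute-force softmax attention, explicit LSTM gate equations, numeric
gradients).

Training uses binary cross-entropy on logits (numerically stable
softplus form), Adam (default lr 1e-3, batch 128), an 80/20
train/validation split with no overlap, 1:1 class balancing by
down-sampling, and retains the best-validation-AUC checkpoint. The
optimizer, learning rate and batch size are package defaults (exposed in
`TrainConfig`); they are not prescribed by the underlying method.
Runs are deterministic given the seed (single-threaded CPU execution).

Checkpoints are an `.npz` of weights plus a JSON sidecar holding the
architecture and estimator parameters.

### Evaluation protocol

ROC/PR evaluation treats embryonic reads as the positive class (their
score is 1 - s). An optional exclusion band (c, d) removes ambiguous
mid-range scores before computing the curves; excluding the central mode
raises AUC, reflecting that precision on confident reads — not full
coverage — is what CNV reconstruction needs.

## Contamination estimation

Given scores s_1..s_N and maternal fraction r, uniform priors on r and
on the score distribution imply class-conditional score densities 2s
(maternal) and 2(1-s) (embryonic), hence the posterior

    P(r | s) ∝ prod_i [ r s_i + (1-r)(1-s_i) ].

The MAP estimate maximizes the log form (the product underflows at large
N). The log-likelihood is concave in r — each term is the log of a
positive affine function of r — so a grid search (step 1e-4, ties broken
toward smaller r) followed by a bounded scalar refinement inside the
winning cell finds the global optimum. Scores are clamped to
[1e-6, 1 - 1e-6] so no term vanishes. The naive comparator reports the
share of scores strictly above 0.5; across synthetic mixtures its
regression slope against truth is far shallower than the MAP slope
(≈0.5 vs ≈0.9 on the default benchmark), reproducing the qualitative
superiority of MAP estimation.

No correction is applied for non-uniform score priors; balanced training
classes are the mitigation, and the limitation is inherited from the
model assumptions.

## Threshold policy and read budget

The filtering threshold depends on the estimated contamination r:
retain all reads at r <= 0.10; threshold 0.2 for 0.10 < r < 0.60;
stringent 0.15 at r >= 0.60. Band boundaries are exposed in
`ThresholdPolicy`. "Below the threshold" is strict.

The input-read budget for reliable CNV reconstruction at contamination r
is `ceil(120/(1-r) x 10,000)` — 1.2M reads at r = 0 (of which roughly
10% survive a 0.15 filter, comfortably above the ~100k-read floor for
whole-chromosome detection) rising to 3M at r = 0.6. `sufficiency_check`
is advisory and never blocks a run.

## Copy-number reconstruction

A self-contained re-implementation of the classic read-depth workflow:

* **Binning**: fixed-width tiling (default 500 kb; the scaled-down test
  genomes use 100 kb), last bin truncated; caller-supplied variable bins
  and a blacklist BED are supported. Fixed-width is the default because
  mappability-based variable bins require external tracks.
* **GC correction**: per-bin counts divided by the lowess fit of count
  vs GC (span 0.3, exposed), rescaled to preserve the genome-wide mean
  exactly.
* **Reference normalization**: ratios against a diploid reference
  profile (the reference pool is filtered at 0.15 with the same
  classifier when the sample is filtered, so both sides share the
  retention bias), median-centered to 1 over autosomes; copy number =
  ratio x reference ploidy (autosomes 2; X/Y per the reference sex,
  default XY). Median-centering assumes a mostly-diploid genome and will
  mis-scale near-haploid profiles.
* **Segmentation**: recursive binary splitting maximizing the
  two-sample t statistic, accepted while p < alpha (default 0.01) with
  at least 3 bins per side (CBS-style). A noiseless copy-number step is
  localized within one bin; zero-variance splits are accepted directly.
* **Calling**: segment states are rounded means clamped at 0;
  whole-chromosome non-diploid segments are aneuploidies labeled
  "+chrN"/"-chrN", partial segments are sub-chromosomal events labeled
  with a cytoband span when a cytoband table is given. Sex is called
  from X/Y dosage (Y present at mean CN >= 0.5, exposed). A
  karyotype-style summary string ("47,XY,+19") is assembled from the
  autosome count and whole-chromosome events.
* **Display shrink**: for plotting only, per-bin values are contracted
  about their group mean by 1/sqrt(2), halving the variance exactly
  while preserving means; analysis values are untouched.

## Interpretability

Position-frequency matrices over {A, C, G, T, M} (M = methylated CpG)
summarize each first-layer filter: input windows whose activation
exceeds the 0.75 quantile of that filter's positive activations are
collected and letter-counted per position (the threshold quantile is a
package choice, exposed). PFMs export to MEME minimal format with the
M channel folded into C for 4-letter motif tools and the M frequencies
preserved as a parallel track.

Attributions use integrated gradients: the gradient of the maternal
probability is averaged over 32 midpoints of the straight path from a
reference (all-zero by default; shuffled-read and user-supplied
references available) and multiplied by (input - reference). The method
satisfies summation-to-delta — contributions sum to the score difference
between read and reference — with the residual reported on every map;
on benchmark models over 95% of reads have residual below 0.05. On the
synthetic benchmark, high-score (maternal) reads show systematically
larger mC-channel attribution than low-score reads, mirroring the
methylation dependence of the classification.

## Synthetic data generator

The generator makes every stage testable offline:

* **Genome**: named chromosomes (default: human-like 22 autosomes + X +
  Y at desk scale, autosomes a few Mb, Y half-length), a smooth GC
  landscape (Gaussian-blurred noise, correlation length 200 kb, mean GC
  0.42), and CpG sites planted at a configurable density. The default
  density (0.06/bp) is CpG-island-like rather than genome-wide-average,
  because the discriminative methylation signal in real data lives in
  CpG-dense regions and a 66 bp read needs several CpGs to be
  classifiable.
* **Methylation classes**: the genome is tiled into 1 kb regions; a
  configurable fraction (default 0.7) is discriminative, with embryonic
  vs maternal CpG methylation probabilities 0.2 vs 0.8, the rest shared
  at 0.5. CpGs on a read methylate i.i.d. with the regional probability;
  CH cytosines carry unmethylated calls at a small background rate
  (0.01) so default reads survive the CH filter. The "separable"
  variant (0.02 vs 0.98 on 90% of regions) gives nearly disjoint
  signatures for end-to-end tests.
* **Copy-number events**: read sampling is piecewise-uniform with rate
  scaled by copy_number/2 under each event; sex karyotypes are expressed
  as events (XY embryo: X and Y at CN 1; XX cumulus: Y at CN 0).
* **Mixtures**: explicit counts or a target maternal fraction (maternal
  reads needed solve x/(n_e + x) = f); sampling is without replacement,
  falling back to with-replacement with a warning; the exact true
  fraction is recorded in provenance.
* **Score populations**: class-conditional mixtures of clipped normals
  with a class mode (0.2 embryonic, 0.7 maternal — the third mode is a
  parameter since reported values vary between 0.7 and 0.8) and a shared
  ambiguous component at 0.5 (weight 0.35), emulating the trimodal score
  histogram of a trained model where the central mode is reads plausible
  under both classes. Score noise is zero-mean Gaussian with variance
  drawn once per benchmark run uniformly from [0, 0.1], clipped to
  [0, 1]; one draw is shared across a run's mixture series.

What the generator does **not** emulate: fragment-length distributions
and end motifs, bisulfite conversion errors beyond the flat CH rate,
polar-body or sperm contamination, mappability structure, or real CpG
island geometry. Tests passing on this generator show the pipeline's
statistical machinery is correct under its stated assumptions, not that
the classifier reaches any particular accuracy on real SECM data.

## Benchmark scales and derived bounds

All benchmarks are sized for a single CPU: training sets of 12-16k
reads, a reduced-width network (32 filters, 4 heads, LSTM hidden 16)
that keeps the full layer sequence, 8-12 epochs, genomes of a few Mb per
chromosome with 100 kb bins, and mixtures of ~100k reads. At these
scales the default-generator Bayes-optimal AUC — computable exactly from
the generator's known class densities — is 0.849, and the trained model
reaches within ~0.02 of it; tests assert proximity to this oracle rather
than an arbitrary constant. The MAP-fidelity benchmark (11 mixture
fractions x 10,000 reads x 5 runs) yields a mean Pearson correlation of
~0.995 between estimated and true fractions. The end-to-end scenario
(embryonic pool with -16, +18 and XY spiked, mixed to 60-75% maternal,
filtered at 0.15, reconstructed against a filtered diploid reference)
recovers both events and the sex call, while the same mixtures without
filtering mask the events and mis-call the sex — the false-negative mode
the filtering exists to remove.

## Known limitations

* The MAP model assumes the score densities 2s/2(1-s); real score
  distributions are trimodal, so estimates are monotone but compressed
  near the extremes (correlation with truth stays >= 0.99 on the
  benchmark, the absolute value can be biased).
* Uniparental disomy is invisible to pure read-depth analysis.
* Median-centering mis-scales near-haploid genomes.
* Mosaicism fractions are not quantified; a segment's non-integer mean
  is simply rounded.
* Sub-bin events (< ~3 bins) are not called at the default segmentation
  settings.
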