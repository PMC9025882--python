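# Methods

## Problem and model

`m5csub` classifies fixed-length, C-centered RNA windows as substrates or
non-substrates of an m5C regulator (the writer NSUN2 or the readers
YBX1/ALYREF). The underlying assumption is that substrate specificity is
encoded locally in the sequence around the modified cytosine, so a window
of 2·flank+1 nt (default 41) carries enough signal for discrimination.
Labels come from data overlap, not experiments performed here: a
methylated cytosine is a substrate when its window intersects a same-strand
CLIP peak of the regulator.

## Coordinates and sequence handling

Internal coordinates are 0-based half-open; BED is consumed natively and
GTF exon records (1-based inclusive) are converted on read. All sequence
is normalized to RNA (T→U, uppercase) at ingestion. Two transcript models
are supported: **mature mRNA** (spliced sequence, sites restricted to
exons) and **full transcript** (unspliced pre-mRNA). Windows that run past
a transcript end are padded with `N` rather than discarded; every encoder
defines its `N` handling (zero blocks for positional codes, exclusion from
frequency denominators, mean-imputed zero-deviation values in the
covariance family). Peak matching uses genomic coordinates by default.

## Dataset construction

Pipeline order: peak overlap (flank fixed at 20 regardless of the later
encoding window, so labeling is invariant under the window-length scan) →
IVT blacklist filter (exact chrom/position/strand match) → exon filter
(mature model only) → same-transcript 1:1 negative sampling → window
extraction → per-class redundancy removal → class re-balancing →
stratified 80/20 split.

Negatives are drawn uniformly without replacement from each transcript's
remaining cytosines (the union pool: unmethylated plus
methylated-but-unbound). If a transcript has fewer eligible cytosines than
positives, the deficit is recorded with a warning rather than padded from
other transcripts.

Redundancy removal is greedy representative clustering on equal-length
windows: in input order, a window joins the first cluster whose
representative shares ≥ 85% identity (`N` never matches), else founds a
cluster; representatives are kept. By construction, every retained pair is
< 85% identical. This is an in-package reimplementation of the usual
external clustering step; it does not reproduce word-filter heuristics of
tools like CD-HIT, but on equal-length windows plain identity is exact and
the operation is idempotent. It runs per class, positives first, and
*before* the split so near-duplicates cannot leak across train/test.
Because per-class clustering can unbalance the classes, the larger class is
then trimmed at random (seeded) back to 1:1.

## Encoders

Dimensions for window length L, lag cap Λ = min(λ, L−2):
conposi 16, onehot 4L, psnp L−1, eiip L, chemprop 3L, autocov 10Λ,
crosscov 90Λ, pseknc 4^k + λ_pse.

Notable numerical choices:

- **psnp** `z(i,j) = F⁺(diNᵢ|j) − F⁻(diNᵢ|j)` (frequency *difference*,
  the position-specific nucleotide propensity standard). Frequencies are
  computed over `N`-free dinucleotides per position; entries lie in
  [−1, 1] and columns sum to 0 for `N`-free training data. The matrix is a
  label statistic: it is fit on training data only and **re-fit inside
  every CV fold**. Fitting it once on the full data before CV inflates
  null-data AUROC from ≈0.5 to ≈0.9 in our regression test — the single
  most consequential design choice in the package.
- **autocov/crosscov** use the standard covariance convention: the
  property mean is taken over all L−1 dinucleotides of the window, and the
  cross term centers each property by its own mean. The lag cap λ = 39
  (capturing long-range order in 41-nt windows) is adapted to min(39, L−2)
  so 21-nt windows in the length scan remain encodable.
- **physicochemical table**: 10 RNA dinucleotide properties (shift, slide,
  rise, tilt, roll, twist, stacking energy, enthalpy, entropy, free
  energy) bundled as TSV, standardized to mean 0/sd 1 across the 16
  dinucleotides, and user-replaceable via `PCTable.from_tsv`. The values
  are a declared fixture compiled from standard structural/thermodynamic
  surveys; analyses depending on the *specific* property values should
  supply their own table.
- **pseknc** is type-1 with declared defaults k=3, λ=5, w=0.05; the
  correlation factors use the standardized property vectors with `N`
  dinucleotides at the table mean.
- **chemprop** triplets are ordered (ring, amino/keto, hydrogen bond):
  A=(1,1,1), C=(0,1,0), G=(1,0,0), U=(0,0,1), the field-standard code.

## Classifiers and evaluation

Fixed defaults, no tuning: SVM = RBF kernel, C=1, gamma='scale', with
sigmoid (Platt) probability calibration on cross-validated margins;
GLM = logistic regression; RF and XGBoost at library defaults; all seeded.
SVM and GLM are wrapped with feature standardization. AUROC is computed by
the rank/Mann–Whitney formulation with tie correction (exact,
O(n log n)); Sn/Sp/Acc use a 0.5 probability threshold, the natural
operating point for the 1:1 class design. Cross-validation is stratified
(protects small substrate sets); independent tests verify train/test
disjointness. The prediction CLI flags probability **strictly greater**
than the confidence threshold (default 0.95).

## Synthetic corpus

The generator emulates: multi-exon transcripts (2–3 exons of 250–400 nt,
introns 60–150 nt) on both strands, a GC-biased background
(P(G)=P(C)=0.3, mirroring the GC enrichment reported around m5C sites),
methylated cytosines at designed spliced positions, and peaks placed
exactly over substrate sites (optional jitter). Substrates carry a planted
`GGG` starting 1–3 nt 3' of the centered C — an NGGG-style motif with the
site itself as the N — with probability `planting_rate` (default 0.9).
Site centers are ≥ 40 nt apart so no window can touch a neighboring
site's peak; peak-overlap labeling therefore recovers the designed truth
exactly, separating labeling correctness from classifier evaluation.

Defaults are the benchmark study conditions: 500 positives, 100
methylated-but-unbound decoys, 60 transcripts, planting rate 0.9.
Benchmarks in the test suite use 150–500 windows per class — sizes at
which the planted signal is comfortably learnable while the full suite
stays fast.

What the generator does **not** emulate: real transcriptome annotation
complexity (overlapping genes, alternative isoforms), bisulfite read-level
noise, peak-calling uncertainty, composition differences between substrate
classes beyond the planted motif, and inter-site dependence. Passing the
synthetic benchmarks therefore demonstrates that the pipeline is correct
and leak-free and that the classifiers can recover a positional sequence
signal at realistic effect sizes — not that any particular AUROC will be
attained on real CLIP/bisulfite data.

## Degenerate inputs and tie-breaks

All-`N` windows encode to zero vectors with a warning; empty classes,
mixed window lengths, single-class label vectors and degenerate
(zero-variance) feature matrices raise errors. Greedy clustering breaks
ties by input order (first representative wins). Splits take
floor(0.8·n) training members per class and require ≥ 5 per class so the
training part still supports 5-fold CV.

## Known limitations

- Peak overlap is binary; peak scores/heights are ignored.
- Sites on transcripts absent from the annotation are dropped.
- The greedy identity clustering is order-dependent (as is the external
  tool it replaces).
- Only k=3 tuples and the bundled 10-property set are exercised by
  default; secondary-structure and learned representations are out of
  scope.
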