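# m5csub

Sequence-based substrate prediction for 5-methylcytosine (m5C) regulators.

5-methylcytosine is a widespread post-transcriptional RNA modification
deposited by writer enzymes (NSUN2) and recognized by reader proteins
(YBX1, ALYREF). Knowing *that* a cytosine is methylated does not say *which*
regulator acts on it. `m5csub` addresses that gap for computational
epitranscriptomics: given base-resolution m5C site lists and regulator
binding intervals (PAR-CLIP/eCLIP peaks), it labels each methylated
cytosine as a substrate or non-substrate of a regulator, encodes the
surrounding fixed-length RNA window with sequence-derived features, and
trains classifiers that predict substrate status for new cytosines.

## Method

A site is a **positive** for a regulator when its 41-nt C-centered window
overlaps a same-strand binding peak; **negatives** are cytosines drawn 1:1
from the same transcripts. Optional filters remove in-vitro-transcription
(IVT) artifacts and, under the mature-mRNA model, non-exonic sites;
near-duplicate windows are collapsed by greedy clustering at 85% identity
before the stratified 80/20 train/test split.

Eight encodings map a window *s₁…s_L* to features:

- **conposi** — dinucleotide composition, 16 frequencies
- **onehot** — per-position binary code, 4L
- **psnp** — position-specific dinucleotide propensity,
  `z(i,j) = F⁺(diNᵢ|j) − F⁻(diNᵢ|j)`, the per-position frequency contrast
  between positive and negative training windows (L−1 features; re-fit
  inside every cross-validation fold — it is a training-set statistic)
- **eiip** — electron-ion interaction pseudopotential per base
  (A 0.1260, C 0.1340, G 0.0806, U 0.1335), L features
- **autocov / crosscov** — lagged auto-/cross-covariance of dinucleotide
  physicochemical property profiles, `AC_λ(i) = ⟨(PCᵢⱼ−PC̄ᵢ)(PCᵢ,ⱼ₊λ−PC̄ᵢ)⟩`,
  over a bundled 10-property table, lags up to λ = 39
- **pseknc** — type-1 pseudo k-tuple composition (k = 3, λ = 5, w = 0.05)
- **chemprop** — ring / amino-keto / hydrogen-bond triplet per base

Classifiers (RBF-SVM with Platt calibration, logistic GLM, random forest,
XGBoost) are evaluated by stratified 5-fold cross-validation and an
independent test, scored with AUROC, sensitivity, specificity and accuracy.
Experiment drivers compare encoding schemes, window lengths 21–81 nt, and
algorithms on a shared split. A synthetic corpus generator plants an
NGGG-style G-run next to designated substrate cytosines so every stage is
testable offline and signal recovery is measurable.

## Worked example

```sh
python examples/03_signal_recovery.py
```

prints

```
planted (rate 0.9): 5-fold CV AUROC = 0.896 (n = 1000)
null    (rate 0.0): 5-fold CV AUROC = 0.524 (n = 1000)
```

With the planted G-run present in 90% of positives, propensity features +
SVM recover the signal (AUROC 0.90); with no planted signal the same
pipeline stays at chance (0.52), confirming the evaluation is leak-free.
The other scripts under `examples/` walk through encoding, dataset
construction, scheme/algorithm comparison, the window-length scan and
motif counting.

The same workflow is available from the shell:

```sh
m5csub simulate --seed 3 --outdir sim
m5csub build-dataset --sites sim/m5c_sites.bed --peaks sim/peaks.bed \
    --gtf sim/annotation.gtf --fasta sim/genome.fa --seed 3 --outdir ds
m5csub train --dataset-dir ds --outdir model
m5csub predict --model model/model.pkl --fasta ds/test.fa --threshold 0.95
```

`predict` flags candidates whose substrate probability is strictly greater
than the threshold (default 0.95) as high-confidence.

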