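# iscpipe

Intersubject-correlation (ISC) analysis of multi-subject EEG responses to
naturalistic video, with movement annotation from pose keypoints and a
luminance-dynamics covariate feeding a moderated mixed-effects model.

The pipeline:

1. **synthkit** — synthetic multi-subject EEG sharing a band-limited latent
   source whose inter-subject coupling is modulated by per-frame movement
   categories, plus keypoint tracks (jitter / genuine movement / scene
   cuts) and grayscale frame stacks with known average luminance
   difference (ALD). Everything is reproducible from the seed and carries
   its ground truth.
2. **preprocess** — zero-phase 1–50 Hz band-pass, bad-channel zeroing
   (power > mean + 4 SD across channels), FastICA eye-artifact removal,
   outlier zeroing (|x| > mean(|x|) + 3 SD(|x|), ±40 ms pad), per-channel
   z-scoring, and excision of the first 5 s of every clip as a mask.
3. **corrca** — correlated component analysis: generalized eigenproblem of
   the pooled between- vs (shrinkage-regularized) within-subject
   covariance; leave-one-out per-subject ISC summed over the top-3
   components, globally and on 1.5 s windows sliding by 0.3 s with the
   global projection vectors held fixed.
4. **movement** — dual-threshold Euclidean displacement of limb keypoints
   between consecutive frames (lower bound rejects camera jitter, upper
   bound rejects scene cuts), aggregated to window categories
   {neither, arm, leg, both} on the ISC window grid.
5. **visual** — ALD per frame transition (mean squared grayscale
   difference), max-downsampled onto the same window grid.
6. **model** — linear mixed-effects model `isc ~ group * movement + ald`
   with subject random intercepts (REML, Satterthwaite degrees of
   freedom), plus post-hoc pairwise Wilcoxon signed-rank tests on
   per-subject condition means with a median ALD split and Bonferroni
   correction.

## CLI

```sh
iscpipe run --out runs/demo                 # full synthetic pipeline
iscpipe run --config my.yaml --out runs/x   # with a declarative config
iscpipe report --out runs/demo              # model + condition-means report
iscpipe isc --out runs/y --window-len 1.5 --hop 0.3 --k-sum 3 --gamma 0.1
iscpipe convert eeg.h5 out_dir --from h5 --to matrix
```

Subcommands `simulate`, `preprocess`, `isc`, `annotate`, `ald`, `model`
run the pipeline up to the named stage; every output table is stamped
with the config hash and seed, and identical configs produce
byte-identical tables. Exit code 2 marks config/validation errors, 1
computation failures.

## Formats

EEG travels as an HDF5 container (one dataset per subject) or a plain
per-subject TSV matrix directory; keypoints as a pose JSON dialect
(per-frame `people` arrays with flat `[x, y, confidence, ...]` lists,
consolidated or one file per frame); frame stacks as `.npz` or a PNG
directory; all stage outputs as stamped TSV tables.
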