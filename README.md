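# spiderseg

Brain-MRI tumor screening pipeline for 8-bit grayscale 2-D images:

1. **phantom** — synthetic brain-like MRI generator (dark background, skull
   annulus, two tissue regimes, optional tumor lesion) with ground-truth
   masks and a CSV manifest, so the whole pipeline is testable without any
   external imaging data.
2. **preprocess** — background removal: binarize at a normalized 0.05
   threshold (8-bit cut 12.75), keep the largest connected component with
   holes filled, mask the image, then 2x2 mean downsampling.
3. **sso** — a social spider optimization maximizer over bounded vectors
   (distance-attenuated vibrations, masked random walk), seeded and
   deterministic.
4. **segment** — multilevel thresholding driven by a pseudo-additive
   Tsallis-entropy objective; C regions = C − 1 thresholds optimized by SSO,
   plus an exhaustive brute-force oracle for small instances.
5. **features** — SVD of the flattened segmented corpus (samples as rows)
   with the 99%-of-squared-singular-values rank rule and out-of-sample
   projection onto the training basis.
6. **ensemble** — majority vote of a linear-kernel SVM, Gaussian naive
   Bayes, and 3-NN (Euclidean), all trained on the same features.
7. **evaluate** — repeated stratified 70/30 holdout (default 20 reps) or
   stratified 10-fold CV, with per-split refits, pooled confusion matrix,
   accuracy/sensitivity/specificity, and a vote-score ROC/AUC.

## CLI

All stages are exposed through one entry point:

```sh
spiderseg simulate  --config config.yaml --out data/            # phantom dataset
spiderseg preprocess --image data/tumor_0060.png --out pre.png
spiderseg segment   --image pre.png --out seg.png --regions 5 --seed 1
spiderseg extract   --manifest data/manifest.csv --out features.csv
spiderseg train     --features features.csv --out model.joblib
spiderseg predict   --model model.joblib --features features.csv --out preds.csv
spiderseg run       --manifest data/manifest.csv --config config.yaml --out out/
```

`config.yaml` is optional (defaults reproduce the reference experimental
setup: 5 regions, q = 0.8, 20 holdout repetitions, 70% training fraction,
0.99 energy fraction). Example:

```yaml
phantom: {image_size: 250, n_normal: 60, n_tumor: 60, seed: 5}
segment: {regions: 5, q: 0.8}
sso: {population_size: 25, max_iterations: 100}
evaluate: {mode: holdout, reps: 20, train_frac: 0.7}
seed: 0
```

Exit codes: 0 success, 2 validation/config error, 3 data error.

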