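# libspect

Classification of broadband LIBS (laser-induced breakdown spectroscopy)
spectra with a three-stage pipeline:

1. **Gaussian smoothing** — each spectrum is convolved with a normalized
   discrete Gaussian kernel (default 5 taps, σ = 1.5 channels) to suppress
   high-frequency noise.
2. **Stacked channel selection** — channels are ranked by a normalized
   mutual information against the class label,
   `MIC(X, Y) = I(X; Y) / √(H(X)·H(Y))`, the top k are kept, and redundant
   channels are pruned greedily so that no retained pair has absolute
   Spearman correlation above a threshold τ; both k and τ can be set by
   validation-accuracy grid search.
3. **Weighted fusion** — an RBF-SVM, a random forest and a KNN classifier
   are pre-trained independently; each sub-model i votes for its predicted
   class c with weight `W[i, c] = P_i[c] · R_i[c]` (its per-class precision ×
   recall on the validation split), and the class with the largest summed
   weight wins.

A LIBS spectrum has tens of thousands of wavelength channels of which only
the sparse emission-line channels carry class information — the intended
users are chemometrics practitioners classifying specimens (e.g. medicinal
plant varieties) from such spectra. Because no public dataset accompanies
the method, the package ships a synthetic LIBS-like spectrum generator with
controlled class structure, so every stage is testable end to end; see
`docs/methods.md` for the model, the generator's assumptions, and its
limits.

Everything is organized as scikit-learn estimators (`GaussianSmoother`,
`StackedFeatureSelector`, `FusionClassifier`, and the composite
`SpectralPipeline`), so the pieces compose with sklearn pipelines and model
selection; module-level functions (`smooth`, `rank_channels`,
`prune_redundant`, `fit_pipeline`, ...) are thin wrappers over them.

## Worked example

```python
import libspect as ls

# 10 classes x 90 spectra on a 4000-channel 200-975 nm axis
config = ls.default_config(seed=1)
dataset = ls.split_dataset(ls.simulate_dataset(config), seed=1)   # 60/20/20

pipe = ls.SpectralPipeline(random_state=1).fit(dataset)
print("selected channels:", pipe.selection_.selected.size)
print("fusion test accuracy:", round(pipe.score_split(dataset, "test"), 4))

test = dataset.split_part("test")
report = ls.compute_report(test.labels, pipe.predict(test.intensities))
print("macro F1:", round(report.macro_f1, 4))
```

Output:

```
selected channels: 155
fusion test accuracy: 0.9722
macro F1: 0.9722
```

155 of 4000 channels survive selection (top-300 by MIC, then Spearman
pruning at τ = 0.9): the selector has collapsed each informative emission
line to its most label-relevant channel or two and dropped the pure-noise
channels. The fused classifier assigns 97.2% of the held-out spectra to the
correct variety; for comparison, the same three classifiers on all raw
channels reach 0.67–0.81 on this benchmark. On the noiseless variant of the
same geometry the pipeline reaches accuracy 1.0 with under 1% of the
channels.

The same workflow is available from the shell:

```sh
libspect simulate --out spectra.csv --seed 1
libspect preprocess --in spectra.csv --out smoothed.csv
libspect select --in smoothed.csv --k 300 --tau 0.9 --out selection.json
libspect train --in smoothed.csv --selection selection.json --out model.joblib
libspect evaluate --model model.joblib --in smoothed.csv --report report.json
libspect run-all --out-dir run1 --seed 1     # all stages + t-SNE figure
```

`run-all` also writes a four-panel t-SNE diagnostic (raw / smoothed /
top-k-selected / stacked-selected) with per-class marginal normal curves,
showing how class clusters tighten and separate stage by stage.

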