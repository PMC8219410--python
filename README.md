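# attn-eeg

EEG attention monitoring and closed-loop neurofeedback toolkit.

The pipeline classifies attention into five ordinal levels (low,
medium-low, medium, medium-high, high) from four EEG channels
(TP9, AF7, AF8, TP10) sampled at 256 Hz:

1. **Wavelet multiresolution analysis** (`attn_eeg.wavelet_mra`) — 5-level
   orthonormal db4 decomposition into six subbands (D1–D5, A5), adaptive
   soft-threshold denoising with the SURE ("rigrsure") rule, per-subband
   reconstruction, and a dyadic subband → EEG-band map
   (A5 = delta 0–4 Hz, D5 = theta 4–8 Hz, D4 = alpha 8–16 Hz,
   D3 = beta 16–32 Hz, D2 = gamma 32–64 Hz; D1 treated as noise).
2. **Band-power features** (`attn_eeg.features`) — 4 channels × 5 bands
   = 20 features per epoch (mean squared amplitude of each band-limited
   reconstruction, optional log10 transform).
3. **Improved random forest** (`attn_eeg.irf`) — bootstrap CART ensemble
   with per-node random feature subsets and majority voting (ties break
   toward the lower attention level), two-phase coarse-to-fine grid search
   over (n_estimators, max_features, min_samples_leaf), and S-fold
   cross-validation (default S = 10). Fully deterministic under one master
   seed; models serialize to versioned JSON.
4. **Neurofeedback control** (`attn_eeg.neurofeedback`) — quantizes levels
   to control values {0, 0.25, 0.5, 0.75, 1} and runs three headless game
   rules (sustained / selective / focus) that produce the training
   indicators (win time, game score, skill times).

Supporting modules: `attn_eeg.eeg_io` (CSV/EDF reading, channel selection,
epoching, feature CSV round-trip), `attn_eeg.synth` (labelled synthetic EEG
with class-dependent band-power profiles, Markov level streams) and
`attn_eeg.evaluation` (confusion matrices, macro metrics, multi-classifier
CV comparison on identical folds, paired t-test).

## CLI

```sh
# synthesize labelled recordings
attn-eeg simulate --n-per-class 50 --seed 7 --out sim/

# features from a recording (CSV header = channel names, or an EDF file)
attn-eeg extract --in rec.csv --fs 256 --channels TP9,AF7,AF8,TP10 \
    --epoch 1.0 --labels labels.csv --out features.csv

# grid-search + train, then predict
attn-eeg train --features features.csv --folds 10 --seed 7 --out model.json
attn-eeg predict --model model.json --features new.csv --out pred.csv

# compare classifiers on identical folds
attn-eeg benchmark --features features.csv --folds 10 --seed 7 \
    --classifiers svm,knn,adaboost,et,rf,irf --out table.csv

# run a headless neurofeedback game session from a level stream
attn-eeg session --game sustained --levels levels.csv --out session.json
```

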