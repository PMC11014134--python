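# fessemg

Recognition of lower-limb motion and muscle-fatigue state from surface
electromyography (sEMG) recorded **during functional electrical stimulation
(FES)** — the setting of wearable closed-loop FES trainers, where the
stimulator's own 20 Hz pulse train contaminates the very signal that should
drive it.

The package implements the complete processing chain as a tested, seeded
pipeline:

1. **Synthetic data** — a generator for labelled 4-channel sEMG (left/right
   tibialis anterior and gastrocnemius, 8 kHz) under a 20 Hz / 300 µs biphasic
   stimulation train, covering six motions (sitting, walking, climbing
   stairs, ankle dorsiflexion, ankle plantarflexion, cycling) and three
   Borg-RPE fatigue bands (none / medium / extreme).
2. **Artifact removal** — empirical mode decomposition (EMD): intrinsic mode
   functions dominated by the stimulation harmonics are discarded, and
   zero-phase notch filters remove the residual line components at k·20 Hz.
3. **Time–frequency imaging** — each 500 ms window (4000 samples) becomes an
   image via the STFT spectrogram |X(t,f)|², the bump-wavelet CWT scalogram
   |W(τ,s)|², or the Hilbert–Huang spectrum (EMD + per-mode analytic signal,
   amplitudes a(t) deposited at (t, ω(t)) and summed over modes).
4. **Dual-task network** — four parallel CNN branches (one per electrode
   channel; 4 × [conv→batch-norm→ReLU→2×2 pool]) whose concatenated features
   feed a 6-way motion softmax head, while per-branch two-layer LSTMs feed a
   3-way fatigue softmax head; trained with the summed cross-entropy
   `loss = CE(motion) + CE(fatigue)` (Adam, lr 0.001, batch 50, dropout 0.3).
   Implemented in NumPy with hand-written backpropagation.
5. **Baselines** — the classic hand-crafted features with a closed-form LDA
   classifier: MAV/WL/ZC/SSC (time domain) for motion, RMS/iEMG/MF/MPF
   (amplitude + Welch-spectral) for fatigue.
6. **Evaluation** — per-class precision/recall/F1 and accuracy (percent),
   from raw counts or directly from row-normalized percentage confusion
   matrices as printed in results tables.

## Worked example

```python
from fessemg import (SimulationConfig, generate_recording, segment,
                     remove_fes_artifacts, window_to_image, tff_features)

cfg = SimulationConfig(seed=1)                      # 20 Hz FES, 4 channels, 8 kHz
rec = generate_recording(cfg, "cycling", "extreme", duration_s=2.0)
windows = segment(rec, window_s=0.5, overlap_fraction=0.5)
print(len(windows))                                 # 28 (7 positions x 4 channels)

clean = remove_fes_artifacts(windows[0])            # EMD + zero-phase notches
fv = tff_features(clean)
print(dict(zip(fv.names, fv.values.round(2))))
# {'RMS': 2.19, 'iEMG': 4525.43, 'MF': 87.88, 'MPF': 106.6}

img = window_to_image(clean, method="HHT")          # 256 x 256 x 3 in [0, 1]
print(img.pixels.shape)                             # (256, 256, 3)
```

The median frequency of 87.9 Hz sits below the ≈ 98 Hz the same generator
produces unfatigued: extreme fatigue compresses the spectrum (by a jittered
per-recording factor), grows the RMS, slows the contraction bursts and adds
tremor-band amplitude modulation — the cues the fatigue head of the network
learns to read.

End to end:

```bash
fessemg run --out runs/demo --seed 0
```

simulates 1200 recordings (200 windows per motion class), cleans and images
them (STFT at 32×32 in the reduced CPU profile), trains the network for 40
epochs, fits both LDA baselines on the identical split, and writes metrics,
confusion matrices and a manifest into `runs/demo/`. On seed 0 this prints
held-out accuracies of 94.2% (motion) and 90.0% (fatigue) for the network
versus 80.8% and 85.0% for the corresponding LDA baselines — the deep model
out-performs the hand-crafted features on both tasks, at desk scale.

Individual stages are also available as subcommands: `simulate`,
`preprocess`, `images`, `baseline`, `train`, `predict`, `evaluate` and
`table-metrics` (metrics from a printed row-normalized confusion matrix).

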