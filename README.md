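# recallnets

Forward encoding models of **content** and **context** reinstatement during
free recall, for researchers analyzing intracranial EEG (or simulating it).

When people recall a studied word list, the brain re-expresses activity
patterns from encoding. This package asks *which* cortical system
reinstates *what*: does the posterior medial (PM) network carry temporal
context (when an item was studied) and the anterior temporal (AT) network
semantic content (what it was)? The approach:

1. **Behavior.** Recall organization is scored with temporal and category
   clustering factors — the percentile rank of each recall transition's
   |serial-position lag| (or 0/1 category distance) among all available
   transitions, averaged; 0.5 is chance. Structure-matched nulls remove
   biases introduced by the paired-category list design.
2. **Features.** Spectral power via Morlet wavelets (wave number 5) at 8
   log-spaced frequencies, 3–180 Hz, log-transformed, downsampled to
   50 Hz, z-scored per session.
3. **Encoding models.** Ridge regression predicts each neural feature from
   stimulus attributes — a 300-dim category-centroid embedding (content
   model) or one-hot serial position/list/session (context model) — with
   5-fold outer cross-validation over words and 10-fold inner selection of
   the penalty λ ∈ {1e-2 … 1e10} per neural feature:
   ŵ = argmin ‖y − Xw‖² + λ‖w‖².
4. **Decoding.** Class probabilities = softmax over Pearson correlations
   between an observed pattern and each class's predicted pattern; scored
   by macro one-vs-rest AUC, with 5-electrode bootstrap sampling to equate
   network coverage.
5. **Reinstatement.** The encoding-trained models decode each 20 ms sample
   from 900 to 100 ms before recall vocalization; the AUC time series is
   tested against 0.5 with threshold-free cluster enhancement (TFCE,
   Σₖ hᵏ^H·e(hₖ)^E·dh with H=2, E=0.5, dh=0.01) and sign-flip max-statistic
   permutation, and correlated across subjects with the clustering factors.
6. **Connectivity.** Within- vs between-network coupling of trial-to-trial
   power, estimated with a distance-matched bootstrap so electrode
   proximity cannot masquerade as network coupling.

A first-class synthetic-data generator reproduces the task structure
(25-list sessions; 12-item lists of 3 categories × 4 items presented in
same-category pairs from a 25-category pool), clustered recall behavior,
and power tensors with network-specific planted signal — so every stage is
testable with known ground truth. See `docs/methods.md` for the full model.

## Worked example

```python
from recallnets.synthetic_data import SimulationConfig, simulate_subject
from recallnets.behavior import structure_matched_z
from recallnets.encoding_models import (build_content_design,
                                        build_context_design,
                                        bootstrap_electrode_auc)

cfg = SimulationConfig(n_lists=10, seed=42)   # 5 PM + 5 AT electrodes
sub = simulate_subject(cfg)

fs = structure_matched_z(sub.recalls, sub.structures, n_null=500, seed=0)
print(f"temporal factor   {fs.temporal:.3f}  (z = {fs.temporal_z:+.2f})")
print(f"category factor   {fs.categorical:.3f}  (z = {fs.categorical_z:+.2f})")

d_content = build_content_design(sub.events, sub.truth.true_embeddings,
                                 sub.truth.word_categories)
d_context = build_context_design(sub.events)
for name, design in [("category", d_content), ("serial position", d_context)]:
    out = bootstrap_electrode_auc(sub.encoding, design, cfg.network_labels,
                                  k=5, n_boot=20, seed=1)
    print(f"{name:16s} decoding AUC:  PM {out['PM']['mean']:.3f}"
          f"   AT {out['AT']['mean']:.3f}")
```

prints

```
temporal factor   0.856  (z = +4.87)
category factor   0.575  (z = +1.29)
category         decoding AUC:  PM 0.481   AT 0.977
serial position  decoding AUC:  PM 1.000   AT 0.482
```

The simulated subject recalls with strong temporal clustering (factor
0.856, z = +4.87 against structure-matched random recall). Decoding shows
the planted double dissociation: the item's semantic category is readable
only from AT electrodes (AUC 0.98 vs 0.48), its serial position only from
PM electrodes (AUC 1.00 vs 0.48); 0.5 is chance. With default noise the
effects shrink toward the modest AUCs typical of real recordings.

A full pipeline run (simulate → behavior → fit/decode → reinstate →
connectivity → stats, with a reproducibility manifest):

```bash
recallnets run-all --seed 3 --out runs/demo
```

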