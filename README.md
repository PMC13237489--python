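# cglkit

A toolkit for family-specialized enzyme engineering of cystathionine
gamma-lyases (CGL, EC 4.4.1.1): weak-label dataset curation, a residue-level
transformer activity classifier trained on frozen protein-language-model
embeddings, leakage-aware evaluation with label-permutation null models, and
in-silico prioritization of single-point mutants, together with the
downstream analysis utilities such a campaign needs (MD contact-occupancy
statistics and Michaelis–Menten post-processing).

## Who this is for

Protein engineers who have (or can produce) weak, family-level activity
annotations — e.g. LLM-derived ecological labels — and want to train a
specialized classifier that ranks candidate point mutations of a target
enzyme, with honest controls: does the label signal survive permutation
nulls? does performance survive sequence-identity-capped and species-holdout
splits?

## The model

Each protein of length *L* is represented by a frozen per-residue embedding
matrix *X* ∈ ℝ^{L×D} (D = 1152 for the 600M-parameter embedder; any provider
satisfying the contract works). The classifier is a stack of pre-norm
transformer encoder blocks

  h ← h + Dropout(MultiHeadAttention(LayerNorm(h)))
  h ← h + Dropout(FFN(LayerNorm(h)))     (FFN expansion ×4)

followed by masked mean pooling over residues and a linear head onto the
three putative groups {High activity, Low activity, No activity}. Training
minimizes the focal loss −w_c (1−p_c)^γ log p_c (γ = 2, per-fold
inverse-frequency class weights) under stratified 5-fold cross-validation
with early stopping on validation Macro-F1 (patience 5). At prediction time
the minority high-activity class has a tunable acceptance threshold
τ_high ∈ [0.3, 0.9], and an optional rejection rule withholds any prediction
whose maximum probability is below 0.55. Variants of a target enzyme are
ranked by the fold-ensemble mean P(High activity) after a conservativeness
pre-filter ΔPSSM = PSSM(mut) − PSSM(wt) ≥ −7.

The network, its backpropagation, the optimizers and integrated-gradients
attribution are implemented in numpy (see `docs/methods.md`); gradient
correctness is enforced by finite-difference tests.

## Worked example

Train and evaluate on the built-in synthetic benchmark (no downloads; a
600-sequence homolog family with a planted context-dependent label rule):

```bash
cglkit simulate family --n 600 --seed 7 --out runs/
cglkit embed --fasta runs/family.fa --dim 64 --seed 7 --out runs/emb.npz
cglkit curate --fasta runs/family.fa --out runs/dataset.tsv
cglkit train --dataset runs/dataset.tsv --embeddings runs/emb.npz \
             --num-blocks 1 --n-heads 16 --seed 21 --out runs/model/
```

or equivalently in Python:

```python
from cglkit import benchmarks
records, labels, embeddings, fixture = benchmarks.planted_dataset()
cv = benchmarks.reference_cv(embeddings, labels)
print(f"mean CV Macro-F1 {cv.mean_macro_f1:.3f}  MCC {cv.mean_mcc:.3f}")
```

which prints (protocol seeds, one CPU):

```
mean CV Macro-F1 0.937  MCC 0.951
```

meaning the 5-fold mean Macro-F1 over the three activity groups is 0.937 —
the transformer recovers the planted motif-pair rule — while the same
pipeline with a linear head on the pooled embedding stays near 0.65, because
the rule is deliberately not a linear function of pooled features.

Kinetics post-processing of a plate-reader export:

```bash
cglkit simulate kinetics --seed 1 --out assay/
cglkit kinetics --curves assay/curves.csv --standard assay/standard.csv --enzyme-uM 3
# {"vmax_uM_min": 5.0, "km_mM": 3.0, "kcat_per_s": 0.02778}
```

Here `vmax_uM_min` and `km_mM` are the Michaelis–Menten parameters fitted to
calibrated initial velocities, and `kcat_per_s` = Vmax / [E] / 60 is the
turnover number.

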