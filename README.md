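# dscahla

Dual-stream cross-attention modelling of peptide–HLA class II presentation,
with binding-core localization and antibody immunogenicity screening.

HLA class II molecules — αβ heterodimers of the DR/DP/DQ loci — present
exogenous peptides to CD4⁺ T cells; which peptides a given allele presents
is governed largely by a 9-residue *binding core* whose anchor residues
(P1, P6, P9) sit in pockets of the binding groove. `dscahla` is a
pan-allele predictor for this process: it consumes the peptide sequence and
the full α/β chain sequences of the allele (so it extends to alleles never
seen in training) and returns a presentation probability, the predicted
binding core, and risk summaries built on top of them. Intended users are
computational immunologists and antibody engineers who need a trainable,
fully inspectable presentation model that runs offline on a CPU.

## The model

Each sequence is embedded per residue as
`E_multi = [proj(E_plm); E_onehot; SelfAttn(E_onehot)]` — a protein-
language-model block (deterministic offline fallback or an ESMC-600M
adapter), the one-hot encoding, and a context-enhanced one-hot from a
single self-attention layer. Peptides are standardized to 32 positions and
HLA chains to 100 + 100. Each stream then extracts global features
**X** (three transformer encoder layers) and local features **H** (a
rectified 1-D convolution; kernel 9 on the peptide so window *i* is the
candidate core start *i*, kernel 5 on the HLA chains). The two sequences
interact through dual-stream cross-attention: per stream,

```
Q = X_self W_Q,  K = H_self W_K,  V = H_other W_V
Attn = softmax(Q Kᵀ / √d),   O = Attn·V,   Õ = O / ‖O‖₂ (row-wise)
H_stream = Conv1D(Õ) + X_self
```

so each sequence's global view queries its own informative windows while
*values* flow across from the partner sequence. Global max pooling of both
stream outputs feeds an MLP + sigmoid head trained with binary
cross-entropy (Adadelta, weight decay 1e-4, early stopping patience 7,
5-fold cross-validation split at the peptide level). The binding core of a
peptide is the 9-mer window the trained model rates most presentable; a
sequence-logo/PFM export and a sliding-window antibody screen (12–19-mer
windows × an 8-allele DRB1 panel, prevalence filter > 22, probability
cutoff) are built on the same scores. See `docs/methods.md` for every
modelling choice and its rationale.

Everything — including the training stack — runs on NumPy; the network is
implemented on a small reverse-mode autodiff engine (`dscahla.nn`) that is
finite-difference-verified in the test suite.

## Worked example

`examples/01_simulate_and_train.py` builds a synthetic study in which each
allele's binding preference is a planted 9-mer motif (strong anchors at
P1/P6/P9), trains the model briefly, and evaluates on held-out peptides of
seen alleles (warm) and on an allele never seen in training (cold):

```
train=4320 pairs, warm test=1080, cold test=1800 (allele SYN-01-003)
best validation AUROC 0.980 at epoch 3
warm: AUROC 0.951  AUPR 0.830  MCC 0.629 over 1080 pairs
cold: AUROC 0.885  AUPR 0.603  MCC 0.356 over 1800 pairs
```

Warm AUROC 0.951 means presented peptides rank almost perfectly above
background decoys for alleles the model has seen; the cold row shows the
allele-chain → motif mapping transferring to an unseen allele that shares a
binding-pocket code with a training allele. The other examples cover core
localization against the planted ground truth (`02`), sequence-logo export
whose most informative columns recover the planted anchors (`03`), the
antibody immunogenicity screen (`04`), and the paired bootstrap model
comparison (`05`).

A thin CLI wraps the same library for shell use:

```bash
dscahla simulate --seed 7 --n-pos 300 --out run/
dscahla train --pairs run/pairs.csv --registry run/registry.csv --seed 7 --out run/
dscahla predict --model run/model.npz --pairs run/pairs.csv \
    --registry run/registry.csv --out run/scores.csv
```

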