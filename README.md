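# pestpair

Multi-label recognition of natural enemies (predatory/parasitoid insects)
and their target pests in a single image, with explicit modelling of
predator–pest *pairing*: a hybrid CNN + Transformer backbone, a label
co-attention head, and a pairwise label matching loss. Because no public
predator–pest pairing dataset is deposited, the package ships a seedable
synthetic scene generator with planted co-occurrence structure, so every
stage — augmentation, training, pair-level evaluation, the unseen-pair
generalization protocol — runs end to end from a single integer seed.

Intended users: researchers in agricultural computer vision / biological
control who want a tested, CPU-reproducible reference implementation of
image–label cross-attention and pairwise co-occurrence supervision for
multi-label insect recognition.

## The model

Patch features `f_j` come from a conv stack (stride-2 conv → BN → GELU,
reaching 256×14×14 from a 224×224 input) flattened to N = 196 tokens and
contextualized by multi-head self-attention. Learned label embeddings
`e_i` (CL = 8 categories, d = 256) query the patches:

    Att_ij = (e_i W_Q)(f_j W_K)ᵀ / √d
    z_i    = Σ_j softmax_j(Att_ij) · (f_j W_V)

Each `z_i` is fused through an MLP + residual + channel gate into a
per-label probability `p̂_i`. Training minimises

    L_total = L_bce + λ · L_pair ,   λ = 0.4
    L_pair  = − Σ_{(i,j)∈P} [ y_ij log(p̂_i p̂_j) + (1−y_ij) log(1−p̂_i p̂_j) ]

where `y_ij = 1` iff labels i and j are both present — a BCE over joint
probabilities of label pairs that rewards ecologically valid combinations
(ladybug–aphid, pirate-bug–thrips, …) and suppresses spurious ones.
See `docs/methods.md` for the full account.

## Worked example

```python
import pestpair as pp

schema = pp.make_default_schema()          # 4 predators + 4 pests
cooc = pp.default_cooccurrence(schema)     # planted pair structure
manifest = pp.generate_dataset(600, schema, cooc, seed=11,
                               out_dir="scenes", canvas_size=64)
train_m, val_m = pp.split_train_val(manifest, 0.7, seed=1)

model = pp.InsectPairModel.from_manifest(train_m, val_m, schema=schema)
results = model.fit(pp.TrainConfig(epochs=12, seed=3, lr_init=1.5e-3))
print(results.evaluate().as_series().round(1))
names = [f"{schema.names[i]}-{schema.names[j]}" for i, j in schema.canonical_pairs]
print(results.evaluate_pairs(pairs=list(schema.canonical_pairs),
                             pair_names=names).round(1).to_string(index=False))
```

Output from this exact configuration (desk profile, 600 synthetic scenes,
12 epochs on one CPU):

```
precision          72.8
recall             56.4
f1                 63.6
micro_precision    76.9
micro_recall       60.5
micro_f1           67.7
mAP                73.1
dtype: float64
                         pair  precision  recall   f1  tp  fp  fn
C. septempunctata-A. gossypii       82.1    92.0 86.8  46  10   4
          C. sinica-N. lugens       76.5    44.8 56.5  13   4  16
         O. sauteri-T. tabaci       67.9    46.3 55.1  19   9  22
    T. chilonis-O. furnacalis       47.4    31.0 37.5   9  10  20
                      Average       68.5    53.6 59.0  87  33  62
```

`precision/recall/f1` are macro percentages at threshold 0.5 (F1 is the
harmonic mean of the printed P and R); `mAP` is ranking-based mean average
precision over categories. The pair table scores joint predictions: an
image counts for pair (i, j) only when both member labels clear the
threshold and both are truly present. On this stylized synthetic benchmark
the flagship ladybug–aphid pair is recovered at F1 ≈ 87; the macro pair-F1
of 59 is dominated by the two smallest-bodied glyph classes, which are the
hardest to detect at 64×64.

A command-line interface mirrors the library:

```bash
pestpair generate --seed 1 --out scenes/
pestpair train    --train-manifest scenes/manifest_train.json \
                  --val-manifest scenes/manifest_val.json --seed 1 --out model.npz
pestpair ablate   --train-manifest scenes/manifest_train.json \
                  --val-manifest scenes/manifest_val.json --seed 1 --out ablation.csv
pestpair holdout-eval --manifest scenes/manifest.json --seed 1 --out unseen.csv
```

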