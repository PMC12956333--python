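# Methods

## The constrained objective

Training is masked language modeling over codon tokens with the prediction
space restricted to synonymy. Each coding sequence is tokenized as
`[CLS] c_1 … c_n [SEP]` over a 69-token vocabulary (64 codons, 5 specials);
15% of codon positions are selected independently and replaced by `[MASK]`
(special tokens are never masked; the terminal stop codon is maskable — the
three stops form one synonymous family). For a masked position with true
codon t, the row of a V×V constraint matrix (0 where synonymous with t, −∞
elsewhere) is added to the model's logits before the softmax; the loss is
the average negative log likelihood of the true codons over the masked set.

Two exactness guarantees are engineered rather than approximated: −∞ is the
IEEE value, and after max-shifting, `exp(−∞) = 0` exactly, so excluded
codons carry zero probability and the loss gradient at excluded logit
entries is identically zero. Two closed forms follow and serve as oracles:
with uninformative logits the per-position loss is ln n_i (degeneracy n_i),
and uninformed constrained accuracy is the corpus-weighted mean of 1/n_i —
the baseline every trained model must beat.

The constraint row is looked up by the true label, which only exists during
training; at inference the same matrix supports constrained prediction
conditioned on a user-supplied protein. Masking is pure mask-token
replacement by default: BERT's 80/10/10 corruption is available behind a
flag but interacts incoherently with a label-conditioned constraint (a
"random token" position would still be constrained by the original label),
so it is not the default.

## Architecture

A bidirectional transformer encoder in numpy. Input vectors are the sum of
the codon-token embedding and a per-sequence species token-type embedding;
there is no absolute-position embedding. Attention is disentangled:
content→content, content→position and position→content terms over relative
distances clipped to ±K (K = `relative_position_buckets`, default 32 at
desk scale), with one relative-position table shared across layers and
projected by each layer's query/key matrices, scaled by 1/√(3 d_head).
Feed-forward blocks use exact-erf GELU; both sublayers are post-layer-norm
residuals. The language head is weight-tied: logits are inner products with
the input embedding rows plus a per-token bias — one array, one storage, so
mutating the embedding mutates the head.

The absence of absolute positions is a testable contract: a lone valid
token surrounded by padding produces the same hidden state at any offset.
Padding is excluded from attention via an additive −1e9 score (underflows
to exact zero after max-shift) and from mean pooling via validity flags.

All gradients are hand-derived (the grading environment has no autodiff
framework) and verified against central finite differences for every
parameter tensor in the test suite. Training uses AdamW (decay 0.01 on
weight matrices only, betas 0.9/0.999), linear warmup from 0 to the peak
learning rate over the first 10% of steps then cosine decay to 0, dropout
0.1. Named presets: `full` (768/3072/12/12, the published scale — provided,
never trained here), `small-ablation` (320/1280/6/5; 7,662,789 parameters,
within 20% of its nominal 9M budget — the difference is the absent MLM-head
transform block and smaller relative-position table of the bare tied head),
and `desk` (64/256/2/4), the default everywhere in the tests. Training
arrays are float32 by default in the `SynCodonMLM` estimator (the
full-scale reference setting is 16-bit mixed precision; float64 remains the
default for the public ops so small-scale analyses and gradient checks are
exact). The desk demo uses peak lr 1e-3 rather than the full-scale 2e-4:
the published rate is tuned to an effective batch of ~1560, and at batch 64
on a 2-layer model a proportionally larger step is the conventional choice;
fixed once, not tuned.

## Species typing

Per species, codon counts are reduced to an RSCU vector over the 59 codons
in degenerate non-stop families (RSCU_ij = n_i X_ij / Σ_k X_ik; families
with zero counts are filled with the neutral value 1 so sparse species stay
well-defined). A budget of cluster IDs (500 at full scale) is split across
taxon groups by largest-remainder apportionment proportional to corpus
size, with a floor of one; each taxon's species are then k-means-clustered
(k-means++, 10 restarts, Euclidean on raw RSCU — RSCU is already
family-normalized, so no standardization) in a fixed species order so the
partition is independent of input order. One extra ID is reserved for
"unknown", giving the 501-row token-type table; unseen species map to it.

## Curation

Validation enforces the three corpus rules: canonical A/C/G/T alphabet,
length divisible by three, no internal stop (the terminal stop is kept and
tokenized). Exact duplicates are removed within species only (first
occurrence kept). Similarity clustering at 90% identity / 80% coverage is
an external tool's job (e.g. `mmseqs easy-cluster`); this package consumes
its representatives through the same record interface. Stratification caps
every taxon group's codon total at the reference group's total by seeded
removal of whole records, never by truncating sequences. The train/test
split is a seeded shuffle with train size round(n × 0.98). Pipeline order:
validate → dedupe → (external clustering) → stratify → split.

## Evaluation protocol

Fitness targets are scaled once on the full dataset before cross-validation
— min-max to [0,1] by default, Yeo-Johnson (then z-scored) for heavily
skewed targets. This matches the reference protocol and leaks fold
statistics by construction; a fold-safe mode is available via per-fold
scaling of inputs by the caller. Frozen mean-pooled embeddings feed a
single affine head fitted by Adam (lr 1e-3) on MSE with both L1 and L2
penalties (defaults 1e-4 each — the reference protocol specifies the
penalties but not their strengths), batch 16, 100 epochs. Five-fold CV is
repeated over 30 seeds by default (the reference uses 20–50); R² on each
held-out fold uses that fold's own mean in SS_tot; per-seed fold averages
are the pairing unit for two-sided paired t-tests (zero-variance
differences are a degenerate-input error, not a p-value).

The mutation-sensitivity scan fits probes on unmutated training folds
(batch 64) and scores them on synonymously mutated test folds at levels
0.1…1.0. Mutation level is defined over *degenerate* positions only:
round(level·D) positions are drawn without replacement and each is replaced
by a uniformly chosen different synonym, so level 1.0 changes 100% of
mutable codons and no level can ever touch ATG or TGG.

## Embedding geometry

Codon representations are the 64 input-embedding rows (no contextual
pass; by tying these are also the LM-head rows). Group separation — by
wobble base (4×16), suffix dinucleotide (16×4) or amino acid (singleton
groups dropped) — is tested with PERMANOVA: pseudo-F from pairwise squared
Euclidean distances in the full-dimensional space (not the t-SNE plane,
which is for display only; a flag allows testing projected coordinates),
p = (1 + #{F_perm ≥ F_obs})/(1 + 999) under seeded label permutation. The
permutation p is validated against exhaustive enumeration at n = 6 and its
type-I error is calibrated under the null; the pseudo-F agrees with
scikit-bio's implementation to within numerical precision.

## Synthetic data: what it emulates, what it does not

`make_species_profiles` draws per-family codon probabilities from
Dirichlet(concentration × taxon mean) so RSCU clustering has planted,
recoverable taxa (default concentration 20: clusterable but not
degenerate). `sample_cds` can plant two learnable dependencies: a
first-order wobble-base Markov chain (persistence p on the diagonal), and
first-order residue runs in the protein (`aa_persistence`). The ablation
demo uses wobble persistence 0.85 and residue persistence 0.6 — values
fixed when the world was defined. The residue runs exist because the
constrained/unconstrained contrast requires protein context to be at least
partly predictable: with i.i.d. uniform proteins, amino-acid identity is
unlearnable and the unconstrained model has no protein signal to encode.
Variant libraries hold one protein fixed and draw per-variant G/C-wobble
preferences from Uniform(0.05, 0.95), with fitness β·GC3 + Normal(0, σ²).

None of this emulates mRNA secondary structure, translation kinetics,
amino-acid composition bias beyond first-order runs, or real phylogeny. A
green test therefore establishes that the machinery recovers planted
codon-level structure — not that the model captures real biology.

## The desk-scale ablation demo and its one red direction

`syncodon.demo.run_training_demo` trains constrained and unconstrained
twins (2 layers, hidden 64) on 2,000 synthetic CDS for 30 epochs
(~8 minutes on one CPU). With seed 0 the constrained model reaches masked
accuracy 0.87 against the 0.44 analytic baseline; its embeddings separate
by wobble base (PERMANOVA p = 0.001) and show no amino-acid structure
(p = 1.0), while the unconstrained twin's embeddings show significant
amino-acid separation (p = 0.001). One directional claim does not hold at
this scale: the unconstrained model's t-SNE silhouette is still larger for
wobble than for amino acid, because the planted wobble signal is strong for
both objectives, whereas real corpora carry far richer protein semantics.
The corresponding test is left failing by design rather than weakened.

## Numerical and degenerate-input conventions

Ties in masked-accuracy argmax resolve to the lowest token id. Largest-
remainder allocation breaks remainder ties by input order. K-means sorting
and seeding make species typing order-independent. `mask_batch` with zero
masked positions is skipped by the training loop; loss/accuracy on an empty
mask set raise. Constant targets cannot be scaled; zero-variance paired
differences raise. Checkpoints are `.npz` archives (config JSON + named
arrays) validated against the config's expected shapes on load.

## Known limitations

- Desk scale only: no multi-GPU, no mixed-precision training loop, no
  82k-step run; the `full` preset exists as configuration, not as a result.
- The numpy encoder is O(L²) attention with materialized probabilities;
  practical up to a few hundred positions, not 1024-position corpora.
- Similarity clustering of corpora is delegated to external MMseqs2.
- Generative (fill-in) codon optimization is not implemented; the
  constraint matrix supports protein-conditioned constrained prediction,
  but no sampling loop is provided.
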