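# Methods

This note documents the model, the data pipeline, the synthetic benchmark,
and the numerical and design choices the implementation had to settle.

## Problem

Kinase inhibitors contact their target kinase at a sparse subset of their
atoms (interaction sites).  Given only the ligand — its atoms typed in the
SYBYL vocabulary and its bonds — the task is per-atom binary
classification: does this atom contact a kinase residue in any crystal
structure of the complex?

## Molecular encoding

A ligand with N atoms becomes a pair of matrices:

* `F ∈ {0,1}^{N×35}` — one-hot SYBYL atom-type "colors", one row per atom.
  The 35-type table (and the 16-element merge used by the reduced-color
  ablation) is a fixed, versioned vocabulary in `pispki.mol2`; parsing
  fails loudly on types outside it.
* `S ∈ {0..4}^{N×N}` — symmetric bond-class adjacency with zero diagonal.
  MOL2 bond strings collapse to four classes: single/triple/dummy/
  unknown/not-connected → 1, double → 2, amide → 3, aromatic → 4; anything
  else → 0 (treated as "not bonded").

One molecule yields N samples: sample i appends a binary mark column to F
that is 1 only at row i, asking "is atom i an interaction site?".  The
marked atom's color entries are additionally scaled by 2 (see *Marking*
below).  Labels come from the union rule: an atom is positive if it binds
the kinase in any crystal structure of the same (kinase, inhibitor) pair,
which removes the noise of structures that disagree.

## Model

Per sample the forward pass is:

1. **WL Boxes** (feature branch).  A box is L layers × T time steps of
   switch-weighted Weisfeiler-Lehman updates
   `h(i) ← h(i) + Σ_j w[t,l,S_ij] · h(j)`,
   run independently per layer from `h = F_marked`, with one Leaky-ReLU at
   the end of each layer's chain.  `w[t,l,e]` is a trainable scalar per
   (time step, layer, bond type); bond type 0 is a hard-wired zero, not a
   parameter.  Two 3×3 boxes are chained: each block of box 1 passes
   through box 2 separately and the outputs concatenate, giving 9 blocks.
   No degree normalisation is applied (the update is implemented exactly as
   written), so magnitudes can grow with T; with the default |w| ≤ 0.1
   initialisation and T = 3 this growth is mild.
2. **Convolutional branch** (structure branch).  Input `S_conv = S −
   diag(l_1..l_N)` (color indices on the diagonal); two stages of 3×3
   convolutions (1→2→5 channels, stride 1, zero-padded "same" so blocks
   stay N×N), Leaky ReLU after each; 5 output blocks.
3. **Spatial pyramid pooling.**  Every block is pooled at stages
   k = 1..K (K = 10 for feature blocks, 3 for structure blocks): the block
   is zero-extended to a multiple of k, split into a k×k grid of
   ceil(R/k)×ceil(C/k) regions, and each region reduced to one number.
   All stages of all blocks flatten row-major and concatenate, features
   first: a fixed 3535-long vector regardless of N.  No input padding is
   ever needed.
4. **Dense head.**  5 hidden layers (width 2000 by default), Leaky ReLU,
   dropout 0.05 in training, then a single sigmoid unit; prediction is
   probability ≥ 0.5.

Ablation variants: `no_wl` (raw marked features as the single feature
block), `one_box`, `no_conv`, `merged_colors` (35 → 16 colors).

### Pooling-mode assignment

The two pyramid branches use different reductions, and the two available
descriptions of the model assign them in opposite ways (the prose says max
pooling on the WL output and average on the conv output; the printed
formulas say the reverse).  The package default is **average for the
feature branch and max for the structure branch**, i.e. the formulas;
`PyramidConfig.prose_mode()` provides the transposed assignment.  Average
pooling divides the region sum by the full region area *including padded
zeros*, exactly as the formula states; this dilutes cells in ragged
regions, which is documented rather than corrected.  A padded zero can win
a max-pooled region whose true entries are all negative; again the literal
contract.

### Marking

How the "mark" is encoded is not specified anywhere; two readings exist
(a dedicated extra channel, or an in-place modification of the color
entry).  The package uses both at once: an appended binary mark column
*and* a scaling of the marked atom's color entries by `MARK_EMPHASIS = 3`.
The extra column alone turns out to starve learning at small optimisation
budgets: the WL update mixes rows but never columns, so a mark confined to
its own column can only meet the color information in the dense head,
which must then synthesise mark×color products from scratch — empirically
a very long plateau at chance before any learning.  Scaling the marked
row's color writes the conjunction "the marked atom has color c" directly
into column c, and after one WL step "a neighbour of the marked atom via
bond type e has color c" as well, so these become linearly present in the
pooled features and training takes off within a few epochs.  The scale 3
separates the marked contribution from ordinary color counts in pooled
region sums; the encoding is invertible (`strip_mark` drops the column and
rescales the row), so no information is added or lost.

### Initialisation

* Switch weights: uniform on [−0.1, 0.1].
* Dense and convolution weights: He fan-in scaling (normal with
  std = sqrt(2/fan_in)), biases zero.
* The first convolution stage is additionally scaled by 1/35: `S_conv`
  carries color indices up to 35 on its diagonal, and without this the
  structure branch enters the pooling layer ~50× louder than the feature
  branch and dominates every dense unit at the start of training.

All initialisation draws come from a single master seed, so runs replay
exactly on CPU.

## Training protocol

* Per epoch, a fresh class-balanced bootstrap **turn** is drawn from the
  training partition (2048/class by default) and from the validation
  partition (256/class); heavy class imbalance is thus handled by
  resampling, not by loss weighting.
* Loss: binary cross-entropy on the logit.  Optimiser: Adam, lr 1e-3,
  batch 16.  These are unstated in the source description; standard
  choices, exposed in `TrainConfig`.
* Early stopping: patience 5 on validation accuracy.  The recorded
  accuracy is the one of the last improving epoch — the sixth-to-last
  validation when the stop triggers — and the model rolls back to that
  epoch's weights.
* Splits are class-stratified 10% test / 10% validation / 80% train.
  Expansion happens before splitting by default (matching the upstream
  protocol); this lets reindexed copies of one molecule cross splits, so
  `split-first` remains available where leakage matters.

## Dataset expander

Reindexing relabels atom order by a seeded permutation.  The default
`consistent` mode permutes F rows and S rows+columns together — a graph
isomorphism, verified against an exact (factorial-time) canonical form for
N ≤ 6.  The printed batch algorithm permutes S rows only, which does not
preserve the graph; it is kept verbatim under `paper_literal` for fidelity
experiments.  The batch expander emits l·r samples cycling through the l
sources in order and refreshes the permutation seed every 10 outputs.
Rates are chosen per class as ceil(target/n) with a 2,560-sample default
floor.

## Synthetic benchmark

`pispki.synth` generates connected molecule-like graphs: a random spanning
tree grown under a valence cap of 4, plus ~0.3·N extra degree-capped
edges; bond types drawn with probabilities (0.55, 0.15, 0.10, 0.20) for
types 1..4; colors uniform over a 12-type alphabet; default 8–60 atoms
(a stress preset up to several hundred atoms only changes `atom_range`).
The planted rule — positive iff the atom's color is in an acceptor set AND
it has at least one aromatic-bonded neighbour — is deliberately one-hop
relational so that neighbour aggregation matters; the acceptor set is
auto-sized so the noiseless positive fraction is closest to the 0.30
target.  Labels then flip independently with probability `noise` (default
0.05), capping any model's accuracy at ~1 − noise (the Bayes oracle in
`synth.rule_predict` realises this ceiling and the tests assert it).

What the generator does *not* emulate: real chemistry (valence rules per
element, aromatic ring closure), 3-D geometry, and the correlation
structure of real binding sites.  Passing the synthetic benchmark shows
the pipeline can extract a planted relational signal end-to-end; it says
nothing about accuracy on curated protein-ligand data.

## Desk-scale problem sizes

The acceptance checks run the full pipeline at reduced size, chosen so a
single CPU finishes comfortably: ~120 molecules (~4,000 samples), dense
width 128, turns of 256/class, at most 30 epochs, 3 seeds.  The SVM
baseline uses an RBF kernel on zero-padded flattened feature matrices;
the conv-net baseline is two convolution stages plus one dense layer on
the same padded input.

## Known limitations

* The WL update is unnormalised; very deep boxes (large T) can grow
  activations geometrically if switch weights exceed ~1/max-degree.
* The model is *not* permutation invariant (pooling regions are
  index-dependent); the expander exists precisely to teach approximate
  invariance, and the tests exhibit a witness rather than pretending
  otherwise.
* Average-pooled cells shrink as 1/(region area) in ragged regions; with
  K_F = 10 and small N most feature-stage cells are near zero, which makes
  optimisation sensitive to branch scale (hence the 1/35 conv scaling).
* The autodiff engine is deliberately minimal (no broadcasting beyond what
  the model uses, no GPU); every op's gradient is finite-difference tested.
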