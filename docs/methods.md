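# Methods

This note documents the models and procedures implemented in `rnaforge`, the
assumptions behind them, the defaults that matter, and what the synthetic
benchmarks do and do not demonstrate.

## Coarse-grained representation and rigid frames

Each nucleotide is reduced to three atoms — backbone phosphate P, sugar C4',
and the glycosidic nitrogen of the base (N1 for pyrimidines, N9 for purines)
— plus a rigid frame (rotation + translation) that maps a shared local atom
template into global coordinates.  Frames act on column vectors in a
right-handed Å coordinate system.

* **Frame fitting.** Frames are fit to observed atom triples by least
  squares (Kabsch).  A centered three-point set is planar, so the
  cross-covariance is rank-2 and the rank-aware proper-rotation construction
  is used; collinear triples are rejected.  The standalone
  `symmetric_orthogonalize` operation — the polar factor `M (MᵀM)^(-1/2)`
  computed by eigendecomposition — is exposed for full-rank inputs and is
  the re-orthogonalization step of the structure module.
* **Template.** The default `LocalAtomTemplate` is the package's own
  idealized coarse nucleotide: P = (0, 0, 0), C4' = (1.6, 0, 1.3),
  N = (5.0, 0, 0) Å, chosen to be consistent with the synthetic-structure
  generator (a 19 Å strand separation yields a 9.0 Å N–N distance across a
  pair).  One template is shared by all four nucleotide types and it is an
  explicit argument everywhere, so an A-form-derived template extracted from
  a real helix is drop-in.
* **Denoising perturbation.** `perturb_frames` slerps every rotation toward
  an independent uniform random rotation (unit-quaternion sampling) with
  weight `w` and adds isotropic Gaussian noise of scale `sigma` (Å) to every
  translation.  The structure-module training default is `w = 0.1`,
  `sigma = 0.1` Å — a deliberately small perturbation that diversifies the
  initialization without destroying the structural signal.

## Composite-likelihood language model

The training objective augments the usual masked-LM pseudo-likelihood with
ordered second-order terms:

    L = − Σ_{i∈M} log P(X_i = x_i)
        − Σ_{(i,j): i≠j, i∈M or j∈M} log P(X_i = x_i, X_j = x_j)

where M is the masked set and the pair events are 16-class ordered
categoricals (class = 4a + b), so (x_i, x_j) and (x_j, x_i) occupy distinct
classes.  Pairs with both endpoints unmasked are excluded, following the
index condition of the objective.  Probabilities are floored at 1e-9 before
logarithms.  `composite_loss` reports the plain sum; with the pair term
removed it reduces exactly to the pseudo-likelihood masked-LM loss.

**Architecture.**  One-hot input (4 nucleotides + a dedicated mask symbol)
→ linear embedding plus a learned absolute positional table (initialized to
zero, so the embedding is position-free at initialization) → pair
representation built from row/column projections of the sequence
representation plus a clipped relative-position embedding → a stack of
transformer blocks (attention with pair bias, transition, outer-product
mean, triangle multiplicative updates; the language-model variant omits
triangle attention) → a 4-class sequence head and a 16-class pair head.
Desk-scale defaults: 2 blocks, d_s = 32, d_z = 16, 4 attention heads,
relative-position clip 64 (covering full-span pairs at the lengths exercised
here).  Residual output projections are zero-initialized and multiplicative
gates start open (bias +1), which stabilizes early training.

**Training loop.**  Adam with peak learning rate 2.5e-3, 100-step linear
warmup, cosine decay to 10 % of peak; batches of 4 (8 in the contact
benchmark) drawn with replacement; sequences longer than the crop limit are
cropped to a random contiguous window.  15 % of positions are selected per
sequence; selected positions are replaced by the mask symbol (80 %), a
random nucleotide (10 %), or kept (10 %), and all selected positions are
supervised.  The random/keep fractions matter beyond convention here: the
contact probe below runs on complete sequences, and a model that only ever
sees corrupted positions as mask symbols goes blind to context at visible
positions.  For optimization the two likelihood terms are balanced by their
counts (each masked position contributes ~2L pair terms but only one
first-order term; the raw sum would starve the sequence head).  The reported
composite loss remains the unweighted sum.

## Contact extraction via the categorical Jacobian

For any model f mapping a sequence to an L×4 distribution,

    J[i, a, j, b] = f(X with x_i→a)[j, b] − f(X)[j, b]

is estimated by finite differences (the base forward pass is reused for
mutations to self, so 3L + 1 model calls suffice and identity-mutation
slices are exactly zero).  The L×L map is the Euclidean norm over both
nucleotide axes, and the Average Product Correction subtracts
`row_i · col_j / total` to remove background coupling.  Ranking symmetrizes
the corrected map as (C + Cᵀ)/2 and excludes |i − j| < 4; both choices are
recorded in the map metadata and configurable.  Mutant passes use complete,
mask-free sequences.  The marginalized read-out of the pair head (sum each
(i, j) slice over the partner state, average over partners, renormalize)
runs through the identical pipeline.

Contacts against coordinates are defined by glycosidic N–N distance below a
threshold (default 12 Å; 16 and 20 Å are common alternatives).

## Folding losses

* **gFAPE.**  Every nucleotide's template atoms are expressed in every
  frame's local coordinates and compared between prediction and reference;
  the per-atom deviation `sqrt(‖Δ‖² + ε)` (ε = 1e-3) is clamped at a
  per-pair cutoff, weighted per pair, and summed over all ordered pairs
  including i = j, with no normalization.  The value at identity is
  therefore the analytic floor Σ λ_ij · 3 · √ε.  The clamp is applied per
  atom.  An optional mean-normalized mode exists for training stability.
* **Reference reweighting.**  Pairs with reference C4'–C4' distance < 20 Å
  get λ = 3, no clamp; all others λ = 1, 30 Å clamp.  The atom used for the
  20 Å rule is a configuration choice (C4' here); the boundary case d = 20 Å
  takes the far branch.
* **Structure loss.**  gFAPE to the target minus 0.1 × gFAPE to the
  black-hole frames (all identity) with λ = 1 and a 2 Å clamp — a bounded
  repulsion that pushes early predictions away from the degenerate start.
* **Distance binning.**  40 bins: (−∞, 2), 38 × 1 Å bins over [2, 40), and
  [40, ∞).  The distogram loss is the cross-entropy (negative
  log-likelihood, floored probabilities) of the observed bins over the three
  atom-pair channels and all ordered pairs; a sign-free sum of log
  probabilities would be degenerate to minimize, so the negative-log form is
  used.  Total loss = structure + 0.2 × distance.

## Denoising structure module

Sequence and pair representations are layer-normalized and fed to an
invariant-point-attention loop (scalar + point queries in local frames, pair
bias, distance-dependent head weights).  Each iteration predicts a
quaternion update (parameterized as q = (1, b, c, d)/|q|, exactly orthogonal
and smooth near the identity) and a translation update, composed on the left
of the current frames; symmetric orthogonalization is applied as numerical
cleanup with a straight-through gradient (its input is already a rotation to
float precision, so the correction is sub-epsilon).  Inference starts from
black-hole initialization (identity rotations, zero translations);
training perturbs the start with `perturb_frames(·, 0.1, 0.1)`.  Heads: a
linear distogram head (softmax per channel/pair) and a softplus pair-error
head.  Attention dropout (25 % of attention weights zeroed, rows
renormalized, dead rows falling back to the unmasked row) is active only in
training.  Desk defaults: 2 stack blocks, 2 IPA iterations, 4 heads,
4 query points.

## Consensus protocol (filter → score → select → optimize → cluster)

Given N decoys with distograms and optional pair-error maps:

* **E_e2e** sums the unclamped gFAPE between the candidate and every decoy,
  with the decoy's pair-error map as the per-pair λ weights (uniform when
  absent).
* **E_dist** sums, over decoys, channels and ordered pairs i ≠ j,
  `−log[(P(observed bin) + 0.001) / (P(reference bin) + 0.001)]`, the
  reference state being the last bin below 40 Å.  Lower is better; a
  conformation whose distances fall in high-probability bins is rewarded.
  (The positive-log form would invert the ranking and drive the optimizer
  away from the consensus.)
* **Filtering**: for targets above 150 nt, decoys with fewer than 90 % of
  the maximum geometric base-pair count are dropped; the maximum-count decoy
  always survives.
* **Selection**: the 5 lowest-E_global decoys against the filtered pool
  (stable ties by pool index).
* **Optimization**: frames parameterized as per-nucleotide quaternion +
  translation, L-BFGS with analytic gradients from the autodiff engine.
  The binned E_dist is piecewise constant, so the optimizer minimizes its
  linear interpolation across bin centers (evenly spaced at 1.5 … 40.5 Å);
  scoring and ranking always use the exact binned form.  Consequently an
  optimum can sit up to ~half a bin (0.5 Å) from the distogram's exact mode
  — the optimizer tolerance quoted in the tests.  The start is returned
  whenever the optimizer fails to improve the objective.
* **Clustering**: greedy neighbor clustering on pairwise P-atom RMSD; the
  cutoff is the smallest of {2, 4, 6, 8} Å placing ≥ 30 % of decoys in the
  densest neighborhood, at most 5 clusters.  Cluster centers are optimized
  the same way (scored against the filtered pool); models are emitted in
  ascending E_opt order, so model 1 always has the lowest energy.  Final
  structures transport each starting decoy's own atoms with the frame
  update, so local atom geometry is preserved exactly; a full-atom
  refinement hook may be configured and is a no-op by default.

## Assessment metrics

* **RMSD** after optimal proper-rotation superposition (Kabsch), on P atoms.
* **TM-score** on P atoms, normalized by reference length with the RNA
  calibration d0 = 0.6·√(L − 0.5) − 2.5 clamped below at 0.5 Å; the
  superposition search seeds from sliding fragments of lengths L, L/2, L/4
  (minimum 4) with iterative distance-threshold refinement, and the result
  dominates any single Kabsch superposition.  The conventional 0.45
  (same fold) and 0.21 (random baseline) thresholds are exposed as constants
  for labeling only.
* **Base-pair detection** on the coarse representation: greedy
  one-partner-per-nucleotide matching of pairs with |i − j| ≥ 3 whose N–N
  and C4'–C4' distances both fall inside windows calibrated to the toy
  geometry (7.5–10.0 Å and 14.5–16.6 Å).  Category-resolved INF (wc / nwc /
  stack) requires externally supplied annotations (three-column TSV); the
  internal detector reports category "any".
* **INF** = √(precision × recall); **DI** = RMSD / INF_all, undefined (and
  signalled) when INF_all = 0.

## Synthetic data

* **Families.**  A nested secondary-structure spec (uniformly sampled by
  exact big-integer interval counting; minimum hairpin loop 3) plants column
  pairs.  Paired columns draw one of the six complementary combinations
  (AU/UA/GC/CG/GU/UG, uniform) with probability `complement_prob` (default
  0.9), otherwise independent background letters; uniform per-symbol
  mutation noise at `mutation_rate` (default 0.02) follows.  The default
  background composition is A/U-rich, (0.30, 0.20, 0.22, 0.28) for
  (A, C, G, U), as in real non-coding RNA; a skewed background also makes
  unpaired columns genuinely learnable (under a uniform background the best
  possible masked recovery at unpaired columns is exactly chance, so "above
  chance" would be undecidable).  The model is an explicit complementarity
  model rather than a fitted Potts model because it gives controllable
  signal strength and analytic expectations (the observed complementary
  fraction before mutation is p + (1 − p) · Σ q_a q_b over the six
  complementary combinations).
* **Toy structures.**  A planar ladder-and-arc layout (the classical
  secondary-structure drawing): stems are straight ladders with 6 Å backbone
  rise and 19 Å strand separation; loops are circular arcs solved as chord
  chains so backbone spacing stays at 6 Å exactly.  C4' sits 1.6 Å toward
  the partner with a 1.3 Å out-of-plane lift; the glycosidic N extends
  5.0 Å toward the partner for paired residues and 2.5 Å toward the loop
  center for unpaired ones (unpaired bases do not present paired geometry,
  which keeps the detector windows free of false positives).  The layout is
  deterministic.  It is a drawing, not a physical helix: no twist, no
  stacking energetics, planar except for the C4' lift.
* **Decoy pools.**  Decoys perturb the reference's frames at a list of
  translation noise scales (round-robin) with rotational weight
  w = min(0.5, 0.05 σ), moving each nucleotide's own atoms with its frame
  update.  Synthetic distograms put `sharpness` of the mass on the
  reference's true bin, the remainder uniform; pair-error maps are uniform.

**What passing the synthetic benchmarks shows** — that the objectives,
extraction pipeline, consensus energies and optimizer behave as specified
under controlled, analyzable conditions.  **What it does not show** — that
the desk-scale models reach useful accuracy on real RNA: real families have
phylogenetic correlation, gaps, non-canonical and tertiary contacts; real
structures have helical twist and full-atom sterics; and the trained models
here are orders of magnitude smaller than production systems.

## Problem sizes and determinism

The in-repo benchmarks use: contact recovery on one family (L = 40, 16
planted pairs, 3 000 sequences, 2 000 training steps, batch 8 — the model
sees 16 000 sequence draws); consensus recovery on 20-decoy pools at noise
scales {0.5, 1, 2} Å; folding overfit on a single 12-nt target.  The
acceptance script scales the language-model run to 800 steps so the whole
pipeline completes comfortably on one CPU.  Every stochastic routine takes
an explicit seed; training is deterministic on a single worker, and the
consensus protocol is deterministic given its inputs.

## Known limitations

* The numpy autodiff engine is single-threaded and keeps whole activation
  graphs in memory; it is sized for desk-scale models, not production
  training.
* The TM-score search is a fragment-seeded heuristic; it lower-bounds the
  exhaustive optimum (and dominates single-superposition scores) but is not
  a re-implementation of the reference alignment programs.
* The geometric base-pair detector is calibrated to the toy geometry; on
  real structures its windows would need re-calibration, and category-level
  INF relies on external annotations.
* Sequences longer than the positional-table capacity (512) are rejected by
  the embedder; the language model crops its training inputs instead.
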