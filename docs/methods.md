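# Methods

## Molecular graphs and featurization

Molecules enter the model as heavy-atom connectivity graphs built with RDKit.
Hydrogens are never nodes; they influence the representation only through
each atom's total-valence and degree blocks. The atom feature vector (length
32) concatenates one-hot blocks for element {C, N, O, P, S, F, Cl, Br, I,
other}, degree 0–5 and total valence 0–6, a formal charge scalar clipped to
[−2, +2], a radical-electron count, a hybridization one-hot {sp, sp², sp³,
sp³d, sp³d², other}, and an aromaticity flag. Bonds carry a bond-type one-hot
{single, double, triple, aromatic} plus conjugation and in-ring flags. The
block layout is versioned (`mmrt-feat-1`) and stored in serialized models, so
a model trained under one layout refuses graphs featurized under another.

Choices worth noting:

* The element vocabulary covers the metabolite space the method targets;
  anything else (selenium, metals) falls into "other" rather than erroring.
* Multi-fragment SMILES (salts) are rejected by default; `strip_salts`
  (CLI `--strip-salts`) keeps the largest fragment instead. Silently taking
  the largest fragment by default would hide curation problems in input
  tables.
* Stereochemistry is deliberately ignored by the features (the canonical
  SMILES retains it for bookkeeping only). Enantiomers therefore receive
  identical predictions — a real limitation for a chiral stationary phase,
  and an accepted one here because none of the feature blocks are chiral.
* Formal charge and radical count are scalars, not one-hots; their ranges in
  metabolite data are tiny and a scalar keeps the vector short.

## The regression model

Node states are initialized by zero-padding atom features to the hidden
width d (default 64, configurable; d must be ≥ 32). For T = 4 rounds, each
atom receives the sum over bonded neighbors of A(e_ij) · h_j, where the edge
network A is a one-hidden-layer MLP mapping the 6-dimensional bond feature
vector to a d×d matrix, and updates its state with a gated recurrent unit.
Messages flow in both directions of every bond with the same A(e). After
message passing, a set2set readout runs M = 4 processing steps: an LSTM
(input 2d, hidden d) produces a query, dot-product attention over node
states yields a read vector, and query‖read feeds the next step; the final
2d vector is permutation-invariant by construction. A single hidden ReLU
layer plus linear output produces the prediction.

Targets are z-scored during training and the constants travel with the
model, so predictions come back in minutes. The loss is mean squared error,
minimized with Adam (lr 1e-3, β = 0.9/0.999) over 100 epochs of shuffled
mini-batches of 64 — the training protocol of the chromatographic study this
package models, which is silent on hidden width and optimizer; those are our
defaults. No early stopping. Training is exactly reproducible from (dataset
order, seed): all initialization and shuffling derive from one generator.

The network and its gradients are implemented in numpy on a small
reverse-mode autodiff engine (`mmrt._autodiff`) rather than a deep-learning
framework; analytic gradients are verified against central finite
differences to ~1e-6 in the test suite. On one CPU core a 300-molecule,
100-epoch training run takes roughly four minutes.

Dataset splitting uses train size = round-half-up(n × fraction), which
reproduces the 318:80 split of 398 records at 80%. Cross-validation defaults
to k independent random 80/20 resplits (matching a "k randomly generated
training and test sets" protocol) rather than disjoint folds;
`disjoint_folds=True` provides the classical partition.

## Ghost-atom attribution

The effect of atom i is є_i = E_T − E_T,i, where E_T,i is the prediction
with atom i's feature vector zeroed. Both numbers come from fresh forward
passes — nothing is cached between them. Fragment-level analysis enumerates
every connected subgraph of ≤ 5 heavy atoms none of whose induced bonds lie
in a ring ("ignoring ring fragments" is read as *exclude any subgraph
containing an in-ring bond*; the laxer reading — exclude only complete
rings — is available via `ring_rule`). Within a molecule subgraphs are
unique by atom-index set; across a dataset occurrences are pooled by
canonical fragment SMILES, counted per occurrence (a molecule with two
amides contributes two), filtered at ≥ 30 occurrences by default, and
ranked by the **mean** of Σє_i over occurrences. Mean rather than total is
the defensible comparator when groups differ widely in frequency; the
per-occurrence totals are retained on the result object for anyone who
prefers sums.

**Known limitation — the occlusion baseline.** Ghosting does not delete an
atom; it leaves an anonymous node in place. A trained network therefore
imputes something like the *expected substituent in that context* for the
ghost, and є_i measures the atom's effect relative to that expectation, not
relative to absence. On the synthetic benchmark the expected-substituent
effect is ≈ +2 min, so groups whose true effect is smaller in magnitude
(hydroxyl, +0.5 min planted) measure *negative* (≈ −1.1 min), while atoms
with a true zero effect (bare scaffold carbons) measure ≈ −0.1 min and
strong groups keep their sign and approximate magnitude. Occlusion
attributions are reliable for effects well clear of the imputation baseline
and untrustworthy below it.

## Baselines

The linear and random-forest comparators use a stand-in descriptor set
(element counts, ring/aromatic counts, H-bond donors/acceptors, net formal
charge, and counts of phosphate, carboxylic acid, amide, amine, hydroxyl by
SMARTS). On synthetic data several descriptors are exactly collinear (e.g.
oxygen count is a linear function of group counts), so the linear fit falls
back to a lightly regularized ridge solution with a warning; predictions are
unaffected by the degeneracy even though individual coefficients are not
identifiable. The forest uses 200 trees, default depth, seeded.

## Annotation

Feature filtering keeps rows with p < 0.01, fold change > 2 and intensity
> 1e6, all strict inequalities, preserving input order. Candidate matching
computes neutral monoisotopic mass from the formula (pyteomics, standard
isotope masses), applies single-charge negative-mode adducts [M−H]⁻
(−1.007276 Da, electron mass folded in) and [M+Cl]⁻ (+34.968853 Da), and
retains candidates within 3 ppm by default (the upstream peak-annotation
convention of 5 ppm is a documented alternative). Ranking is ascending
|predicted − observed| RT with ties broken by |ppm error| then name.
Candidate SMILES that fail to parse are skipped with a logged warning.

## Synthetic ground truth

The generator decorates random branched alkane trees (3–10 carbons, uniform)
with 1–4 functional groups drawn uniformly from {phosphate, carboxylic acid,
amide, amine, hydroxyl}, subject to valence; true RT is
8.0 + Σ count·effect minutes with effects (+15, +4, −7, −3, +0.5) and
observation noise N(0, 0.5²) min. The phosphate, acid and amide magnitudes
mirror the attribution findings the package is designed to reproduce; the
amine and hydroxyl values are invented for coverage (only the amine's
negative sign is documented). Uniform group sampling was chosen for
identifiability — every group appears ~140–170 times in 300 molecules, far
above the ≥ 30-occurrence reporting threshold. Optional pairwise interaction
terms exist for robustness experiments but default to zero, because the
attribution method's own premise is additive group effects.

What the generator does *not* emulate: real elution physics (an additive
group model can produce negative RTs for heavily amide-substituted
scaffolds, and these are kept rather than clamped to preserve exact
linearity), isomer-resolving retention differences (positional isomers share
a true RT up to noise), matrix effects, and peak-shape/intensity structure.
Passing the recovery benchmark therefore shows the learning and attribution
machinery works when a recoverable additive answer exists — not that the
model generalizes across real metabolite chemistry.

The feature-table generator pairs each true hit (m/z = [M−H]⁻ of a database
molecule perturbed by < 2 ppm, RT = that molecule's generated RT) with
formula-matched positional-isomer decoys whose RTs differ, and pads the
table with rows designed to fail exactly one filter each. With an oracle RT
model the true candidate's RT delta is zero, so rank 1 is forced — the
fixture isolates the plumbing from model quality. Calibration curves use 13
levels in 3-fold steps from 0.0254 pmole with a proportional-response model,
a fixed noise floor for S:N, and an analytically known detection limit.

## Problem sizes and numerics

The recovery benchmark (and the acceptance script) uses 300 molecules,
an 80/20 split and the full 100-epoch protocol; held-out RMSE lands around
1.0–1.5 min depending on seed, against an irreducible 0.5 min noise floor.
Permutation invariance holds to ~1e-14 min (floating-point association
order only). Degenerate inputs: empty graphs error; single-atom graphs run
with zero messages; an all-identical-RT training set trains (the z-score
scale falls back to 1) and predicts the constant; datasets smaller than one
batch train with a single batch and a warning. The packaged 33-row
validation table is checksummed at load; the one typographical cell in the
printed source ("z12.4") is cleaned with a logged note. Its median
|mass error| (0.54 ppm over metabolites) is reported but is knowingly not
the same statistic as the per-injection median the method's authors quote
(0.49 ppm), so nothing asserts equality.
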