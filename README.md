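# mmrt — retention-time modeling for mixed-mode LC-MS metabolomics

Central-carbon metabolites — sugars, sugar phosphates, carboxylic acids and
their amino-acid relatives — are hard to retain on reverse-phase columns, and
mixed-mode (MM) chromatography methods that do retain them produce elution
orders that no simple polarity rule predicts. `mmrt` is a toolkit for
scientists running such methods who want to (a) predict the MM retention time
(RT) of a candidate structure, (b) understand *which* parts of a molecule the
model believes drive retention, and (c) use predicted RT to rank the
candidate identities of untargeted MS features that tie on exact mass.

## What it does

**RT regression.** A molecule is featurized as its heavy-atom connectivity
graph (element, degree, valence, charge, radicals, hybridization and
aromaticity per atom; bond type, conjugation and ring membership per bond). A
message-passing neural network maps the graph to a retention time E_T in
minutes: T = 4 rounds of message passing in which each atom receives
Σ_j A(e_ij) h_j from its bonded neighbors (the *edge network* A maps a bond
feature vector to a hidden×hidden matrix) and updates through a gated
recurrent unit, followed by an M = 4-step set2set readout (attention-driven,
permutation-invariant) and a one-hidden-layer ReLU head. The network is
implemented in pure numpy on a small reverse-mode autodiff engine, so results
are bit-reproducible from (data, config, seed) on any machine. Linear and
random-forest models on hand-picked descriptors are included as the
conventional QSRR baselines.

**Ghost-atom attribution.** The effect of atom *i* is
є_i = E_T − E_T,i, where E_T,i is the prediction after zeroing atom *i*'s
feature vector ("ghosting": the atom keeps its bonds but loses all
properties). Summing є_i over every connected acyclic subgraph of ≤ 5 heavy
atoms and pooling occurrences across a dataset ranks functional groups by
their influence on retention — phosphates and carboxylic acids at the
positive extreme, amides and amines at the negative one.

**Annotation.** Untargeted feature tables (m/z, RT, intensity, p, fold
change) are filtered (p < 0.01, FC > 2, intensity > 1e6 by default), matched
against a candidate database by adduct-corrected ppm error ([M−H]⁻ and
[M+Cl]⁻, 3 ppm), and the mass-tied candidates are ranked by
|predicted − observed| RT.

**Synthetic benchmark.** Because the underlying standards library is
proprietary, the package generates its own ground truth: decorated alkane
scaffolds whose RT is exactly linear in functional-group counts
(phosphate +15, carboxylic acid +4, amide −7, amine −3, hydroxyl +0.5 min,
noise sd 0.5 min). Training on these molecules has a known right answer, so
model and attribution quality are measurable.

## Worked example

```bash
mmrt simulate molecules --n 300 --seed 11 --out data/
mmrt train --data data/molecules.csv --epochs 100 --seed 11 --out data/model.npz
# trained on 300 molecules: train RMSE 0.79 min, 99.0% within 2 min
mmrt attribute --model data/model.npz --data data/molecules.csv \
     --min-count 30 --out data/effects.csv
```

`effects.csv` ranks fragments by mean effect; on the synthetic benchmark the
phosphate-containing fragments head the positive end and amide fragments the
negative end, e.g. (one run, seed 11):

```
fragment_smiles  n_occurrences  mean_effect_min
CCCOP                      258            15.71
OCCOP                       32            15.43
CC(C)OP                    125            14.71
...
CC(N)=O                    133            -9.42
CCC(N)=O                   227            -9.85
```

i.e. the network attributes ≈ +15 min to phosphate-bearing fragments and
≈ −9 min to amide-bearing ones — close to the planted effects. Prediction for new
structures and candidate ranking for untargeted features:

```bash
mmrt predict --model data/model.npz --data query.csv --out predictions.csv
mmrt annotate --features features.csv --db candidates.csv \
     --model data/model.npz --ppm 3 --out matches.csv
```

`matches.csv` lists, per filtered feature, every candidate within the ppm
tolerance with its adduct, ppm error, predicted RT and rank (rank 1 =
closest predicted RT). `mmrt qc --summary` prints the packaged 33-standard
method-validation summaries, and `mmrt evaluate` recomputes per-subset
RMSE/within-2-min tables for any molecule CSV with a `subset` tag column —
useful when a measured RT library is available.

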