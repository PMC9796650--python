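# resqa — residue-specific quality assessment of protein models

Protein structure predictors emit many candidate tertiary structures
("decoys") for one target sequence, and their accuracy varies not just
between models but along the chain of a single model.  Estimation of model
accuracy (EMA / QA) at the residue level answers the question *which parts
of this model can I trust?* — the signal needed to pick the best model from
a pool, to guide refinement, and to flag unreliable regions before a model
is used downstream.

`resqa` is a toolkit for this problem aimed at structural bioinformaticians:
it implements two single-model residue-specific predictors, the complete
feature pipeline behind them, and the CASP-style local-accuracy evaluation
suite used to compare such predictors.

## The methods

Both predictors estimate, for every residue *i* of a model, the deviation
*d&#7522;* (Å) between its Cα and the native position after superposition.
Internally they predict the bounded **S-score**

&nbsp;&nbsp;&nbsp;&nbsp;*S(d) = 1 / (1 + (d/d₀)²)*

with *d₀ = 3* Å for the prediction head, and convert back with
*d = d₀·√(1/S − 1)*.

* **`Mass2Regressor`** — a two-branch 1-D residual CNN.  Branch one
  convolves the concatenated features of each residue's five spatially
  closest residues at sequence separation > 6; branch two passes the
  residue's own 83-dimensional features through a convolution and six
  residual blocks.  The concatenated branches run through another 18
  residual blocks (24 total, each two Conv1D–BatchNorm–Dropout–LeakyReLU
  layers with an identity skip) and a width-1 projection with a sigmoid.
* **`LawRegressor`** — a graph network.  The model becomes a graph with an
  edge between every residue pair within 8 Å (bi-directed, unweighted) with
  edge features (distance/8, cosine of the centroid-centred position
  vectors, |i−j|/L), 77-dimensional node features, and the six global
  secondary-structure / accessibility agreement scores as graph features.
  Five blocks of edge → node → global updates (Linear–ReLU–Linear update
  functions φ, scatter-mean aggregations ρ) feed a three-convolution
  readout to the same sigmoid head.

Feature categories per residue: amino-acid one-hot (21), PSSM log-odds
(20), REF15-style per-residue energies plus their sum, z-scored (20),
windowed Q3/SOV'99/SOV_refine agreement between sequence-based and
model-based secondary structure and solvent accessibility (6), the same
six scores computed globally (6), six model-level statistical potentials
(6), and sinusoidal positional encodings (4) — 83 columns for the CNN, 77
for graph nodes (the global agreement scores live on the graph instead).

The evaluation suite (`resqa.evalsuite`) scores predicted against true
deviations per model: **ASE** = (1 − mean |S-score error|)·100 with d₀ = 5;
**AUC** of the accurate/inaccurate classification at 3.8 Å; precision /
recall / **F1 of unreliable local regions** (ULR: runs of ≥ 3 inaccurate
residues, merged across single accurate residues under a strict ULR-1 and
a looser ULR-2 rule, matched within ±2 residues of true region
boundaries); and **SOV'99 / SOV_refine** segment-overlap scores of the
binary accuracy strings.  Scores are averaged over models, then over
evaluation units, and predictor groups are ranked by summed standardised
metrics (Z-1, Z-2).  Everything runs from Cα coordinates; deviations and a
simplified GDT_TS come from a single Kabsch superposition.

A synthetic-data generator (`resqa.synthdata`) produces natives, decoy
pools with controlled per-residue damage, companion feature files in the
exact dialects the readers parse, and multi-group QA submissions — so the
whole toolkit is exercisable offline.

## Worked example

Generate a synthetic study (2 targets, 12 decoys each, 4 predictor groups
whose prediction noise increases strictly from G01 to G04), then evaluate
and rank the groups on models with GDT_TS > 40:

```bash
resqa synth --out study --targets 2 --length 50 --decoys 12 --groups 4 --seed 7
resqa evaluate --data study --out eval --regime gt40
cat eval/ranking.tsv
```

```
flavor  rank  group  z
Z1      1     G01    3.5531
Z1      2     G02    1.8016
Z1      3     G03    -1.4807
Z1      4     G04    -3.8740
Z2      1     G01    4.5666
Z2      2     G02    2.5325
Z2      3     G03    -2.1361
Z2      4     G04    -4.9630
```

The ranking recovers the construction exactly: G01 predicts true deviations
with zero noise, so it tops both the Z-1 ranking (standardised ASE/100 +
AUC + ULR-1.F1) and Z-2 (ASE/100 + AUC + ULR-2.F1 + SOV_refine).  The
per-EU table shows why — e.g. G01 scores ASE ≈ 100, AUC = 1.0, ULR-1.F1 =
1.0 on every evaluation unit, while G02's noisy predictions already drop
to ASE ≈ 95 and ULR-1.F1 ≈ 0.80:

```
group  eu        ASE      AUC     ULR1_F1  ULR2_F1  SOV99   SOV_refine
G01    S0001-D1  99.9975  1.0000  1.0000   1.0000   1.0000  1.0000
G02    S0001-D1  95.1915  0.9891  0.8000   0.8000   0.9408  0.9476
```

Training and prediction follow the same pattern:

```bash
resqa train --data study --method LAW --epochs 100 --out ckpt/law.npz --seed 1
resqa predict --checkpoint ckpt/law.npz --method LAW \
      --features study/features/S0001 --target S0001 \
      --out pred study/decoys/S0001_decoy001.pdb
```

which emits a CASP QA-format file plus a per-residue TSV of predicted
deviations.  From Python, the estimators follow scikit-learn conventions
(`fit(X, y)` / `predict(X)` / `get_params()`), where `X` is a list of
featurized models (feature tuples for the CNN, `ProteinGraph` objects for
the graph net) and `y` the matching per-residue true deviations.

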