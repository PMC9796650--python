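# Methods

## Problem and quantities

A predicted protein tertiary structure is scored residue by residue: the
target quantity is the deviation *d&#7522;* (Å) between the model's Cα and
the native Cα after rigid-body superposition.  All learning and most
metrics operate on the bounded S-score transform
*S(d) = 1/(1 + (d/d₀)²)*: *S* = 1 for a perfect residue, 0.5 at *d = d₀*.
Two constants are used deliberately: **d₀ = 3 Å** for the prediction head
and its training targets (so the network resolves the accurate end of the
scale finely), and **d₀ = 5 Å** for the ASE evaluation metric.  The
head's inverse transform is *d = d₀·√(1/S − 1)*, the unique algebraic
inverse of the S-score; the round-trip is exact to < 1e-12.

## Deviations and GDT_TS

True deviations come from one least-squares (Kabsch) superposition of all
Cα pairs shared by author residue number; residues missing from the
reference get a missing value and are excluded from losses and metrics
(never imputed).  The simplified GDT_TS is
25·(P₁+P₂+P₄+P₈) with P꜀ the fraction of shared Cα within *c* Å under that
same single superposition.  CASP's LGA program instead maximises each P꜀
over many fragment superpositions, so our values are systematically equal
or lower; they are used for regime filtering (>40, 40–60, >90), not for
comparison with published GDT_TS numbers.

## Features

Per residue: one-hot amino-acid encoding (L×21, column 21 for
non-canonical letters); PSSM log-odds squashed by sigmoid(x/10) to (0,1)
(the raw integer scale is unbounded and PSSMs from different searches vary
in magnitude); per-residue energies (19 terms plus their row sum as a 20th)
z-scored per column — against stored training-corpus statistics when a
checkpoint supplies them, else the model's own columns; windowed agreement
scores (Q3, SOV'99, SOV_refine) between sequence-derived and
model-derived secondary-structure strings and binarised relative
accessibility strings, on a 13-residue window (centre + 6 each side,
truncated at termini — the centre is included so the window is never
empty); the same six scores computed on the full strings; six model-level
statistical potentials; and sinusoidal positional encodings
(sin p, cos p, sin p/100, cos p/100 for p = 1..L).

Relative accessibility is binarised buried/exposed at 0.25, the common
convention.  DSSP 8-state codes collapse H,G,I→H; E,B→E; else C.

### Statistical potentials

Six deterministic model-level scores, each a sum of −log frequency-ratio
terms against reference tables shipped as package data
(`src/resqa/data/potential_tables.json`, regenerated by
`scripts/make_potential_tables.py` from a fixed-seed ensemble of 40
ideal-geometry synthetic structures): pseudo-bond-angle (Cα angle
histograms conditioned on secondary-structure state), burial
(neighbour count within 10 Å by hydrophobicity class), sequence-separation
dependent pair distances (three separation bands, 2 Å distance bins),
contact class-pair preferences among pairs within 8 Å, relative-accessibility
preferences by residue class, and local packing (neighbour count within
6.5 Å).  Lower is more native-like; an ideal helix beats an
angle-randomised trace on the pseudo-bond-angle term in 20/20 paired
trials.  These are simplified reimplementations: the tables are estimated
from synthetic reference geometry, not from the PDB, so absolute values
are not comparable with any published potential — the contract is six
deterministic, discriminative model-level scores.

The module-level potential values are extensive (sums over the model).
The feature pipeline feeds their intensive form (divided by L): the graph
network has no normalisation layer, and an O(100) feature block next to
O(1) blocks saturates its first update layer.

## Architectures

**Residual CNN (MASS2-style).**  Branch 1: the features of each residue's
five spatially closest residues at sequence separation ≥ 7 (ties broken by
lower index; missing slots zero-padded, with a 5-column presence mask
appended internally), through three Conv1D+LeakyReLU layers.  Branch 2:
the residue's own 83 features through one convolution and six residual
blocks.  Concatenated branches pass through 18 further residual blocks
(24 total) and a fully connected width-1 projection with a sigmoid.  Each
residual block is two Conv1D–BatchNorm–Dropout–LeakyReLU layers plus an
identity skip.  Defaults: 32 channels per branch (the trunk runs at 64),
kernel 3, dropout 0.2, leaky slope 0.01 — chosen for single-CPU
desk-scale training; all overridable constructor parameters.

**Graph network (LAW-style).**  Edges connect every residue pair with Cα
distance ≤ 8 Å, both directions, no self-edges.  Edge features: distance/8
∈ (0,1]; the cosine of the angle between the two residues' position
vectors after centering the model at its centroid (the literal
"vectors from the origin" form is origin-dependent; centroid-centering
makes it a well-defined, rotation-invariant model property); and |i−j|/L
(normalised so edge features stay O(1)).  Five graph blocks, each: (1)
edge update φₑ on [sender ∥ receiver ∥ edge ∥ global]; (2) a message map
on [sender ∥ updated edge], scatter-mean over receivers, then node update
φᵥ on [node ∥ aggregate ∥ global]; (3) means of updated edges and nodes,
then global update φᵤ.  Every φ is Linear–ReLU–Linear, hidden width 64.
Readout: mean incoming edge features per node, concatenated with node and
global features, through three convolutions (64 → 16 → 1) and a sigmoid —
the same output activation as the CNN, by symmetry.  The network is
permutation-equivariant and edge-order invariant (mean aggregation).

## Training

Loss is mean-squared error between predicted and true S-scores (d₀ = 3 on
both sides), masked over residues with no reference counterpart.  Adam
(lr 1e-3, one model per step) with global-norm gradient clipping at 5.0 —
without clipping, a single hard model can spike the loss and permanently
saturate the sigmoid head.  Fully connected layers use Glorot
initialisation (He gain compounds through the concatenation-heavy graph
blocks and explodes activations); convolutions use He.  Early stopping
watches a validation split when one is configured (the CLI default holds
out 20%), plus a floor rule that stops once eval-mode training MSE drops
below 0.008.  The reported training MSE is computed in eval mode (dropout
off) at epoch end.  Batch normalisation always normalises with the current
model's own length-axis statistics — with one-model batches, running
averages across models of different lengths do not match any single
model's statistics at inference; running statistics are still tracked and
checkpointed.  All randomness (init, shuffling, dropout) derives from
`random_state`; fixed seeds give bitwise-identical training histories on
CPU.

Checkpoints are single NPZ archives holding parameters, buffers,
constructor parameters, architecture metadata and a format version.

## Segment-overlap scores

Q3 is positional identity.  SOV'99 follows the published segment-overlap
definition (per-class enumeration of overlapping reference/observed
segment pairs, minov/maxov ratio with the half-segment allowance,
normalised by reference segment length including non-overlapped
segments).  SOV_refine here uses an agreement-scaled allowance
δ = min(maxov − minov, λ·(minov/maxov)·(maxov − minov)), λ = 1 by
default: the allowance shrinks as segments disagree, every pair ratio
stays ≤ 1, the score is exactly 1 only for identical strings and 0 when no
same-class segments overlap, and it is invariant under relabeling of the
alphabet.  The originally published refined variant is specified in its
own publication, which this package intentionally does not reproduce
term-for-term; the properties above are the contract, and every use in
this package (features and evaluation) is internally consistent.

## Evaluation suite

A residue is accurately modelled iff its deviation is strictly below
3.8 Å; binary strings use 0 = accurate, 1 = inaccurate.  AUC uses mid-rank
tie handling (the normalised Mann–Whitney statistic), scores oriented so
larger = more accurate (predicted deviations are converted to S-scores
with d₀ = 5 first); one-class models are excluded.  ULRs are runs of ≥ 3
inaccurate residues; merging bridges exactly one accurate residue between
two regions (ULR-1) or between a region and any inaccurate run (ULR-2),
repeated to a fixed point.  Matching is greedy left-to-right one-to-one
with a ±2-residue tolerance on both boundaries; F1 = 2PR/(P+R), 0 when
P+R = 0, and undefined (excluded from averages) when both interval sets
are empty — an all-accurate model should not collect free F1 = 1 scores.
Aggregation is the unweighted mean over models within an evaluation unit,
then over units.  Z-rankings standardise each metric across groups per EU
with the population standard deviation (z = 0 if the sd vanishes, no
flooring of negative z), average over EUs, and sum ASE/100 + AUC +
ULR-1.F1 (Z-1) or ASE/100 + AUC + ULR-2.F1 + SOV_refine (Z-2).

## Synthetic data

The generator emulates the *structure* of the evaluation problem, not
protein physics: natives are ideal-geometry Cα traces (helix rise 1.5 Å at
100°/residue on a 2.3 Å radius, strand rise 3.3 Å with alternating pleat,
coil as a direction-correlated 3.8 Å random walk; consecutive Cα distances
3.8 ± 0.1 Å everywhere, including segment junctions).  Decoys apply a
random rigid motion, segment-wise Gaussian noise graded across the pool
(0.05–3 Å sd by default), and forced displacements of ~8–10 Å on
contiguous segments covering, on average, the configured fraction of
residues (default 0.15, graded 0 → 2× across the pool) — so every pool
spans GDT_TS ≤ 40 through > 90 and contains genuine unreliable local
regions.  True deviations are recomputed through the package's own
superposition rather than taken from the construction noise, so generator
and evaluator cannot disagree.  Companion files carry learnable signal:
PSSM rows peak on the true residue in ~90% of positions; energy columns
increase with local deviation (rank correlation of the summed column with
deviation > 0.3 over a pool); model-derived secondary structure flips to
coil where the model is badly wrong.  Group QA predictions add Gaussian
noise of strictly increasing sd (0, then 0.8–4 Å) to the true deviations.

Passing tests on these pools demonstrates that the architectures can
extract real signal and that the evaluation machinery is correct; it does
not calibrate either predictor for real CASP models — no side chains, no
physically realistic decoy error correlations, and statistical-potential
tables from synthetic geometry.

## Problem sizes and runtime

The learning checks train on 20 models and hold out 5 (60 residues each),
≤ 300 epochs; the reported results reach training MSE < 0.008 (CNN, ~40
epochs) and < 0.007 (graph net, < 10 epochs) with held-out Pearson
correlations of ~0.67 and ~0.89 between predicted and true S-scores.
Ranking recovery uses 5 groups × 4 units × 10 models.  The full test
suite runs in about two minutes on one CPU.

## Known limitations

No multi-chain support (first chain read unless specified); pairing is by
author numbering, never by sequence alignment; no mmCIF; no all-atom
superposition; GDT_TS and deviations are not bit-comparable with LGA
output; potential tables are synthetic-reference; the networks ship
untrained — users train on their own pools or the synthetic generator.
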