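# Methods

## Problem and data model

A fusion-expression screen pairs each target gene (in-frame CDS, here
144–3162 nt, no stop codon — the stop belongs to the vector's downstream
region) with six expression vectors. Each pairing is one instance with one
of three outcomes read off SDS-PAGE-style fractionation: soluble, insoluble
(inclusion body), or non-expression. The outcomes form a two-level taxonomy
(soluble/insoluble under a shared *expressed* parent), and every feature is
computed on the whole cloning and expression region, because tag identity
changes both the transcript and the fusion protein.

Construct assembly is literal concatenation `upstream + insert + downstream`
with the upstream region required to end in the EcoRI site (GAATTC) at a
frame-preserving offset and the downstream region to begin with the XhoI
site (CTCGAG). Translation uses the standard code; a single trailing stop is
dropped, an internal in-frame stop is an error (it would truncate the
fusion). Coordinates are 0-based half-open; only the coding strand is
modeled.

The six bundled scaffolds are **synthetic**: the real vectors' cloning
regions are unpublished, so `scaffolds.py` generates deterministic stand-ins
with the real tags' approximate lengths (CBP 26 aa, GST 220, His 8, MBP 370,
NusA 495, Trx 109), per-vector codon-preference levels, and a His6 + stop
downstream region. Real vector sequences can be substituted through the
FASTA + JSON manifest interface; nothing downstream depends on the bundled
sequences.

## Features (617)

Order: 84 k-mer frequencies (k=1,2,3; overlapping windows, each k-block sums
to 1), transcript length, GC content, CAI | 6 Wilkinson–Harrison covariates
| 444 composition/physicochemical descriptors | isoelectric point | 8
peptide statistics | 71 PTM motif counts. Block widths 87 / 459 / 71 are
asserted at construction.

Specific conventions:

- **CAI** is the geometric mean of each codon's relative adaptiveness
  (w = usage / max synonymous usage, from a bundled *E. coli* K12 table);
  all sense codons are included (EMBOSS convention), a single trailing stop
  codon is ignored to match the translation convention.
- **Wilkinson–Harrison**: charge average ((K+R)−(D+E))/n, turn-forming
  fraction (N+G+P+S)/n, Cys and Pro fractions, mean Hopp-Woods
  hydrophilicity, molecular weight (average masses).
- The **444-descriptor block** is 20 monomer + 400 dimer composition
  fractions + 24 physicochemical descriptors (length, MW, GRAVY, aliphatic
  index, instability index, net charge at pH 7, six reduced-alphabet group
  fractions, hydrophobic-patch counts at windows 5/7/11 with mean
  Kyte-Doolittle ≥ 1.5, and nine residue-scale averages). The exact
  descriptor roster behind this historical dimension is not fully published;
  our 24 are defined in one place (`scales.py`) and explicitly swappable —
  the block's *width* is the stable contract, not the roster.
- **Isoelectric point** solves net charge = 0 by bisection on the
  Henderson–Hasselbalch function with the EMBOSS default pKa set (N-term
  8.6, C-term 3.6, K 10.8, R 12.5, H 6.5, D 3.9, E 4.1, C 8.5, Y 10.1);
  the charge is monotone in pH so bisection cannot fail. Tolerance 1e-4 pH.
- **Peptide statistics**: MW, residue count, mean residue weight, net charge
  at pH 7, aromaticity, aliphatic index, GRAVY, molar extinction at 280 nm
  with reduced cysteines (5500·W + 1490·Y).
- **PTM block**: the original screen scored 71 PTM classes with a trained
  predictor behind a now-retired web service. We substitute deterministic
  PROSITE-style motif scanning over a bundled 71-class table (a synthetic
  curation of classic PROSITE entries plus kinase consensus motifs); one
  count of non-overlapping matches per class. Dimension-faithful and
  reproducible, but not a calibrated PTM predictor.

Features are standardized to zero mean and unit SD with training-set
statistics only; zero-variance features are centered and left unscaled (with
a warning) rather than producing NaNs.

## Classifiers

All three architectures use RBF-kernel SVMs (scikit-learn `SVC`,
LIBSVM-style C/gamma).

- **flatSVM**: three pairwise binary SVMs on pooled-standardized data;
  majority vote; a 1-1-1 cyclic tie goes to the label with the largest sum
  of signed pairwise decision values, then to the larger training prior.
  Class probabilities couple the pairwise Platt probabilities by per-class
  summation and normalization (sums to 1 by construction; argmax can
  disagree with the vote near exact ties, empirically <5%).
- **nestSVM**: stage 1 (expressed = soluble ∪ insoluble vs non-expression)
  sees only the 87 nucleotide features; stage 2 (soluble vs insoluble) sees
  only the 530 protein features and is trained only on expressed-labelled
  instances. Prediction is a hard cascade — stage-1 negatives are final.
  Probabilities: P(non)=1−p1, P(sol)=p1·p2, P(insol)=p1·(1−p2).
- **hierSVM**: a reduction of hierarchical structured classification to one
  binary SVM. Per training instance with label l, both expansions
  x ⊗ (a_l − a_l') are positives and their exact sign-flips negatives
  (4 expansions per instance, dimension 4×617 = 2468). Standardization is
  applied to the 617-dim x *before* expansion. Prediction evaluates all 6
  ordered label pairs, averages each label's two decision values, and takes
  the argmax; probabilities are a softmax over the three averaged decisions.
  Because the training set is sign-symmetric, the fitted decision function
  satisfies f(v) + f(−v) = 2b with bias b ≈ 0 (asserted in tests).
- **Ensemble**: unweighted mean of member probability vectors, argmax.

Hyperparameters: the canonical search surface is the LIBSVM-guide log2 grid
(C ∈ 2^−3..2^7, gamma ∈ 2^−9..2^1) selected by inner stratified k-fold CV
accuracy. The protocol functions take the grid and fold count as arguments;
the shipped benchmarks use a reduced in-grid subset (C ∈ {2^2, 2^4},
gamma = 2^−9, 3 inner folds) — with 617 standardized features, gamma near
1/dim is where the kernel is informative, and the reduced grid reproduces
the full search's selections on this data family at a fraction of the cost.
Every stochastic step takes an explicit seed (default 20100118).

## Evaluation protocol

Stratified partition into m parts (per-class shuffle + round-robin deal;
per-class sizes differ by ≤1 across parts), m−1 parts for training with
inner-CV hyperparameter selection, the last part held out; repeated n times
with mean ± SD reporting (defaults m=10, n=10; the bundled benchmarks use
n=3).

- The multi-class F1 is **micro-averaged**: 2ΣA_j / (2ΣA_j + ΣB_j + ΣC_j),
  which for single-label multi-class prediction equals accuracy (ΣB = ΣC);
  this identity is fuzz-tested. A macro-F1 alternative is provided.
- Binary reduction for comparability with solubility-only predictors:
  soluble is positive, insoluble ∪ non-expression negative. ROC and PRC are
  built by sweeping every unique score; auROC uses trapezoids with (0,0)/(1,1)
  endpoints; auPRC uses trapezoids over recall with the curve anchored at
  recall 0 at the precision of the top-score block.
- **Yule's Q** = (N11·N00 − N01·N10)/(N11·N00 + N01·N10) over two methods'
  per-instance correctness on shared test sets (same protocol seed ⇒ same
  partitions); degenerate denominators raise rather than return a value.
- Method comparison uses a **paired two-sided t-test** across the shared
  repeats; zero-variance difference vectors short-circuit to p=1 (equal
  means) or p=0 (constant offset) with a warning.
- The per-vector protocol trains one flat three-class model per vector on
  its own 121 instances with a 5-part rotation.

## Synthetic screen generator

The original 121-gene dataset is private, so the generator emulates its
statistical structure: 121 random in-frame ORFs (leading ATG, no internal
stop) with lengths uniform over in-frame values in [144, 3162] nt, fused
into all six scaffolds (726 instances), with class marginals targeted at
the real screen's 231:236:259.

Genes vary in three ways a real cross-species cohort does: per-gene residue
composition (Dirichlet around globular frequencies with a bimodal
hydropathy tilt — aggregation-prone vs well-behaved proteins), per-gene
codon adaptation (bimodal: host-adapted vs poorly adapted heterologous
genes), and per-gene GC bias.

Labels follow a planted two-stage rule mirroring the taxonomy: an
*expression* score linear in z-scored construct CAI, GC and length plus a
vector offset, and a *solubility* score (expressed cases only) linear in
z-scored turn fraction, charge average and GRAVY plus vector offsets (vector
offsets are recoverable from the features, since the scaffold sequence
identifies the vector, so the nested architecture's structural assumption —
expression from nucleotide features, solubility from protein features —
holds exactly). Stage intercepts are calibrated by quantile so marginals hit
their targets; independent label noise (default 0.1, flip to a uniformly
random other class) is applied last.

Calibration uses **rejection**: genes are drawn from a 3× pool and kept only
if all their constructs clear a margin (0.4 score-SDs) around both planted
boundaries. This gives the rule a genuine decision gap — without it,
tag-dilution of insert CAI (a 495-aa NusA tag halves the insert's weight in
construct CAI) fills the boundary region and no classifier family can
separate what is intrinsically ambiguous. Rejection changes the gene
distribution, not label-given-features, so labels remain deterministic in
the features at noise 0 and the planted coefficients remain recoverable by
stage-wise logistic refits (tested).

What passing benchmarks on this generator does **not** show: performance on
real screens. Real labels are not a linear threshold rule in six features;
real genes have phylogenetic structure, real vectors have linkers and
protease sites, and real non-expression has causes (toxicity, mRNA
structure) the features only proxy. The generator validates the machinery —
architectures, protocol, design loops — not the biology.

## Sequence design

- **Synonymous beam search**: neighbors are all single-base substitutions
  inside the insert whose codon still encodes the same residue (enumerated
  exhaustively, ordered by position then base). Each iteration expands all
  neighbors of each beam member, ranks by the model's soluble probability,
  keeps the top 5 (width configurable), and stops on a soluble prediction or
  after 5 steps; a mutated site is never revisited, so the Hamming distance
  from the original equals the step count. Ties break toward higher score,
  fewer steps, lowest position. Mutations never touch the vector scaffold.
  Since the protein is invariant, protein-block features are cached and only
  the 87 nucleotide features are recomputed per candidate.
- **Codon-optimized resynthesis** replaces every codon with its amino acid's
  w=1 codon (alphabetically first on ties), giving CAI exactly 1 and an
  unchanged protein.
- The recovery simulation applies both procedures to every
  non-expression-labelled case and tabulates flips to soluble / insoluble /
  unchanged (a partition of the failure set). The acceptance script runs
  resynthesis on all failures and beam search on the ten shortest-insert
  failures at 2 steps / width 3 — neighbor counts scale with insert length,
  and the short cases already demonstrate the behavior.

## Numerical and degenerate-input choices

- Zero-variance features: centered, unit scale, warning.
- Absent curve classes (single-class truth) and degenerate Yule's Q
  denominators raise `ValueError` rather than returning sentinel values.
- Precision/recall with empty denominators are defined as 0 with a warning;
  micro-F1 of an empty confusion is 0.
- k-mer blocks for sequences shorter than k are zero with a warning.
- Model files are joblib payloads with a format-version field; round-trip
  identity of predictions and scores is tested.

## Known limitations

- The PTM block and the 24-descriptor roster are stand-ins of the correct
  dimensionality, not reproductions of the original feature generators.
- The bundled scaffolds are synthetic; junction chemistry (linkers, protease
  sites) is simplified to direct concatenation at the EcoRI site.
- Probability coupling for flatSVM is the simple normalized pairwise-sum,
  not the iterative pairwise-coupling solver; near-tie argmax can deviate
  from the vote.
- Benchmarks at n=3 repeats trade SD resolution for runtime; pass
  `n_repeats=10` for the full protocol.
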