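# fxpress

Predicting the expression efficacy of recombinant fusion constructs in
*Escherichia coli*: will a given gene, cloned into a given fusion vector,
yield **soluble** protein, an **inclusion body**, or **no expression** at all?

High-throughput expression screens clone each target gene, flanked by
EcoRI/XhoI sites, into several fusion vectors in parallel (CBP, GST, His,
MBP, NusA, Trx tags) — and the same protein routinely behaves differently in
different vectors. Most solubility predictors ignore both facts: they score
the target protein alone and assume it is expressed. `fxpress` instead
models the **entire cloning and expression region** (tag CDS + insert +
downstream region) and treats the problem as three-class classification over
a label taxonomy in which *soluble* and *insoluble* share the parent
*expressed*.

## Method

Each gene x vector construct is summarized by a fixed 617-dimensional
feature vector:

| block       | width | contents |
|-------------|------:|----------|
| nucleotide  |    87 | k-mer frequencies (k=1..3, 84), transcript length, GC content, CAI (*E. coli* K12 relative adaptiveness) |
| protein     |   459 | 6 Wilkinson–Harrison inclusion-body covariates, 444 composition/physicochemical descriptors, isoelectric point, 8 peptide statistics |
| PTM         |    71 | motif-scan counts for 71 post-translational-modification classes |

Three RBF-SVM architectures consume it:

- **flatSVM** — one binary SVM per class pair (1-vs-1), majority vote,
  margin-sum tie-break;
- **nestSVM** — a cascade mirroring transcription-then-folding: stage 1
  (expressed vs not) on the 87 nucleotide features, stage 2 (soluble vs
  insoluble) on the 530 protein features, applied only to stage-1 positives;
- **hierSVM** — labels embedded as 4-digit attribute vectors
  (soluble ⟨1,0,0,1⟩, insoluble ⟨0,1,0,1⟩, non-expression ⟨0,0,1,0⟩; the
  4th digit marks the *expressed* parent); each instance **x** is expanded by
  the tensor product **x** ⊗ (**a**−**b**) into 2468 dimensions and a single
  binary SVM scores all 6 ordered label pairs at prediction time.

Around the classifiers the package provides the full evaluation protocol
(stratified repeated hold-out with inner-CV model selection, micro-F1,
soluble-vs-rest ROC/PRC with trapezoid AUCs, Yule's Q diversity, paired
t-tests), a synthetic-screen generator with a planted, recoverable
label rule (the original 121-gene dataset is private), and two sequence-design
procedures: a bounded beam search over synonymous point mutations (≤5 sites,
protein never changes) and codon-optimized resynthesis (every codon rewritten
to relative adaptiveness w=1, so CAI=1).

## Worked example

```bash
python examples/02_train_and_predict.py
```

```
flatSVM: held-out accuracy 0.800 on 40 constructs
nestSVM: held-out accuracy 0.750 on 40 constructs
hierSVM: held-out accuracy 0.725 on 40 constructs

per-class probabilities (flatSVM) for three test constructs:
  g083 x  GST: P(sol)=0.27 P(incl)=0.08 P(non)=0.65  true=non_expression
  g104 x  GST: P(sol)=0.02 P(incl)=0.33 P(non)=0.66  true=non_expression
  g074 x  CBP: P(sol)=0.19 P(incl)=0.62 P(non)=0.18  true=insoluble
```

Each accuracy is measured on constructs held out from training (here a
reduced 40-gene cohort; the full 121-gene screen trains above 0.80). The
probability rows are the calibrated class scores the beam search maximizes
when redesigning a failed construct. The other examples cover assembly and
featurization (`01`), the full evaluation protocol with Yule's Q and t-tests
(`03`), and the two sequence-design simulations (`04`).

A thin CLI mirrors the library:

```bash
fx simulate --seed 7 -o sim/            # synthetic screen: genes, vectors, labels
fx assemble --genes sim/genes.fa -o constructs.fa
fx featurize constructs.fa -o features.tsv
fx train --method flat --features features.tsv --labels sim/labels.tsv -o model.fxm
fx predict model.fxm features.tsv -o pred.tsv
fx design codon-opt sim/genes.fa -o optimized.fa
```

## Layout

```
src/fxpress/
  constructs.py   FASTA/label I/O, scaffold manifests, construct assembly
  scaffolds.py    six bundled synthetic vector scaffolds (user-replaceable)
  features.py     the 617-feature extractor + standardization
  motifs.py       PROSITE-style PTM motif scanning
  classifiers.py  flat / nested / hierarchical SVMs, scores, ensembles
  evaluation.py   metrics, curves, protocol, diversity statistics
  design.py       synonymous beam search, codon optimization, recovery sim
  synthetic.py    planted-rule screen generator
  pipeline.py     construct -> features -> prediction wrapper
  cli.py          the `fx` command
```

See `docs/methods.md` for the model assumptions, parameter choices and
limitations.
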