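"""Assemble a gene into all six fusion vectors and inspect its features.

The classifier never looks at the target protein alone: each feature vector
describes the *entire* cloning and expression region of one gene x vector
pairing, so the same insert yields six different vectors of 617 features.
"""

from fxpress import (
    TargetGene,
    assemble_construct,
    default_scaffolds,
    feature_names,
    featurize,
    load_codon_table,
    load_motif_table,
)

gene = TargetGene(
    id="demo",
    cds="ATG" + "AAAGAAGGTCTGATTCCGTTTAGC" * 6,  # 147 nt toy insert
)
table = load_codon_table()
motifs = load_motif_table()
names = feature_names(motifs)

print(f"insert: {len(gene.cds)} nt")
for scaffold in default_scaffolds():
    construct = assemble_construct(gene, scaffold)
    fv = featurize(construct, table, motifs)
    length = fv.values[names.index("nt_length")]
    gc = fv.values[names.index("gc_content")]
    cai = fv.values[names.index("cai")]
    gravy = fv.values[names.index("pep_gravy")]
    print(
        f"{scaffold.name:>5s}: construct {int(length):5d} nt "
        f"({len(construct.aa)} aa)  GC {gc:.3f}  CAI {cai:.3f}  GRAVY {gravy:+.3f}"
    )

# Each line is one of the 726-style scenarios: the same insert fused to a
# different tag changes length, GC, CAI and the protein-level statistics,
# which is why expression efficacy is predicted per gene x vector pairing.
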