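"""Synthetic stand-ins for the six fusion-vector scaffolds.

The six expression vectors of the screen (CBP, GST, His, MBP, NusA, Trx) are
proprietary plasmids whose cloning-region sequences are not published.  This
module generates six *synthetic* scaffolds with the real tags' approximate
lengths, so the assembly/featurization/classification pipeline sees inputs
of realistic size and composition.  They are deterministic (fixed internal
seed) and user-replaceable: real vector sequences can be supplied through the
FASTA + JSON manifest interface of :mod:`fxpress.constructs`.

Layout of each synthetic scaffold:

    upstream   = ATG + tag CDS + GAATTC        (EcoRI junction, frame kept)
    downstream = CTCGAG + His6 codons + TAA    (XhoI junction through stop)
"""

from __future__ import annotations

import numpy as np

from .constructs import VectorScaffold, ECORI_SITE, XHOI_SITE

__all__ = ["TAG_LENGTHS_AA", "default_scaffolds"]

# approximate lengths (aa) of the real fusion tags
TAG_LENGTHS_AA = {
    "CBP": 26,
    "GST": 220,
    "His": 8,
    "MBP": 370,
    "NusA": 495,
    "Trx": 109,
}

_SCAFFOLD_SEED = 774_001  # fixed: scaffolds are part of the shipped artifact

# typical globular-protein residue frequencies (rounded, renormalized)
_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_FREQ = np.array(
    [8.3, 1.4, 5.4, 6.7, 3.9, 7.1, 2.3, 5.9, 5.8, 9.7,
     2.4, 4.1, 4.7, 3.9, 5.5, 6.6, 5.4, 6.9, 1.1, 2.9]
)
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()

# two synonymous codons per amino acid (one E. coli-preferred, one alternate)
_CODON_CHOICES = {
    "A": ("GCG", "GCC"), "C": ("TGC", "TGT"), "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"), "F": ("TTT", "TTC"), "G": ("GGC", "GGT"),
    "H": ("CAT", "CAC"), "I": ("ATT", "ATC"), "K": ("AAA", "AAG"),
    "L": ("CTG", "TTA"), "M": ("ATG", "ATG"), "N": ("AAC", "AAT"),
    "P": ("CCG", "CCA"), "Q": ("CAG", "CAA"), "R": ("CGC", "CGT"),
    "S": ("AGC", "TCT"), "T": ("ACC", "ACG"), "V": ("GTG", "GTT"),
    "W": ("TGG", "TGG"), "Y": ("TAT", "TAC"),
}

_HIS6_CODONS = "CATCACCATCACCATCAC"


def _back_translate(aa: str, rng: np.random.Generator, preferred_frac: float) -> str:
    codons = []
    for res in aa:
        pref, alt = _CODON_CHOICES[res]
        codons.append(pref if rng.random() < preferred_frac else alt)
    return "".join(codons)


def _random_tag(length: int, rng: np.random.Generator) -> str:
    idx = rng.choice(len(_AA), size=length, p=_AA_FREQ)
    return "".join(_AA[i] for i in idx)


def default_scaffolds() -> list[VectorScaffold]:
    """The six bundled synthetic scaffolds, in fixed vector-name order."""
    rng = np.random.default_rng(_SCAFFOLD_SEED)
    scaffolds = []
    for name in ("CBP", "GST", "His", "MBP", "NusA", "Trx"):
        n_aa = TAG_LENGTHS_AA[name]
        if name == "His":
            tag_aa = "H" * n_aa  # poly-histidine tag is literal
        else:
            tag_aa = _random_tag(n_aa, rng)
        # per-vector codon-preference level, so scaffolds differ in CAI/GC
        preferred_frac = float(rng.uniform(0.55, 0.9))
        upstream = "ATG" + _back_translate(tag_aa, rng, preferred_frac) + ECORI_SITE
        downstream = XHOI_SITE + _HIS6_CODONS + "TAA"
        scaffolds.append(
            VectorScaffold(name=name, upstream_nt=upstream, downstream_nt=downstream)
        )
    return scaffolds
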