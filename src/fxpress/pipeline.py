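"""End-to-end wrapper: construct -> features -> trained model -> prediction.

Bundles the codon table, the motif table and a trained model so callers (and
the design simulations) can classify raw constructs directly.  Protein-level
features are cached by protein sequence: synonymous redesigns share the same
fusion protein, so only the 87 nucleotide-level features are recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import classifiers as clf
from .constructs import FusionConstruct
from .features import (
    CodonUsageTable,
    load_codon_table,
    nt_block_features,
    protein_block_features,
)
from .motifs import MotifTable, load_motif_table

__all__ = ["ConstructClassifier"]


@dataclass
class ConstructClassifier:
    """A trained model plus the feature configuration it was trained with."""

    model: object
    codon_table: CodonUsageTable = field(default_factory=load_codon_table)
    motifs: MotifTable = field(default_factory=load_motif_table)
    _protein_cache: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def features(self, construct: FusionConstruct) -> np.ndarray:
        protein = self._protein_cache.get(construct.aa)
        if protein is None:
            protein = protein_block_features(construct.aa, self.motifs)
            self._protein_cache[construct.aa] = protein
        return np.concatenate(
            [nt_block_features(construct.nt, self.codon_table), protein]
        )

    def predict(self, construct: FusionConstruct) -> str:
        return str(clf.predict(self.model, self.features(construct)))

    def predict_scores(self, construct: FusionConstruct) -> np.ndarray:
        return clf.predict_scores(self.model, self.features(construct))

    def __call__(self, construct: FusionConstruct) -> tuple[str, float]:
        """(predicted label, soluble probability) — the design-search scorer."""
        x = self.features(construct)
        label = str(clf.predict(self.model, x))
        soluble_p = float(
            clf.predict_scores(self.model, x)[clf.LABELS.index(clf.SOLUBLE)]
        )
        return label, soluble_p
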