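"""Sequence-design simulations: turn a predicted failure into a soluble hit.

Two in-silico procedures mirror what a cloning lab would actually do:

* **Bounded synonymous beam search** — mutate at most ``max_steps`` single
  nucleotides inside the target-gene insert, never changing the encoded
  protein, steering by the model's soluble-class probability and keeping the
  ``beam`` best candidates per step.
* **Codon-optimized resynthesis** — rewrite every insert codon to the host's
  preferred synonymous codon (relative adaptiveness w = 1), so the resulting
  insert has CAI exactly 1.

Both leave the vector scaffold untouched and preserve the translation at
every step (asserted).  Since mutations are synonymous, only the 87
nucleotide-level features can change; protein-level features are reused
verbatim, which keeps per-candidate scoring cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constructs import FusionConstruct, TargetGene, VectorScaffold, assemble_construct
from .features import CodonUsageTable
from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "MutationStep",
    "MutationTrace",
    "synonymous_neighbors",
    "codon_optimize",
    "beam_search_solubilize",
    "simulate_recovery",
]

_BASES = "ACGT"
_CODON_TABLE = standard_dna_table.forward_table
_STOPS = set(standard_dna_table.stop_codons)


@dataclass(frozen=True)
class MutationStep:
    """One synonymous single-nucleotide substitution inside the insert."""

    position: int  # 0-based nt index within the insert
    from_base: str
    to_base: str

    def __post_init__(self) -> None:
        if self.from_base == self.to_base:
            raise ValueError("mutation must change the base")


@dataclass
class MutationTrace:
    """Ordered mutation path with per-step predictions for one construct."""

    key: tuple[str, str]
    steps: list[MutationStep] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)     # predicted label after each step
    scores: list[float] = field(default_factory=list)   # soluble probability after each step
    start_label: str = ""
    start_score: float = 0.0
    success: bool = False
    final_insert: str = ""


def synonymous_neighbors(nt_insert: str) -> list[tuple[MutationStep, str]]:
    """All single-nt substitutions of an in-frame insert that keep the protein.

    Exhaustive and deterministically ordered by (position, new base A<C<G<T).
    """
    if len(nt_insert) % 3 != 0:
        raise ValueError("insert must be in frame")
    out = []
    for pos in range(len(nt_insert)):
        codon_start = 3 * (pos // 3)
        codon = nt_insert[codon_start : codon_start + 3]
        within = pos - codon_start
        aa = _CODON_TABLE.get(codon)
        for base in _BASES:
            if base == nt_insert[pos]:
                continue
            new_codon = codon[:within] + base + codon[within + 1 :]
            if new_codon in _STOPS:
                continue
            if _CODON_TABLE.get(new_codon) != aa:
                continue
            mutated = nt_insert[:pos] + base + nt_insert[pos + 1 :]
            out.append((MutationStep(pos, nt_insert[pos], base), mutated))
    return out


def codon_optimize(nt_insert: str, table: CodonUsageTable) -> str:
    """Resynthesize the insert from preferred codons only (CAI becomes 1)."""
    if len(nt_insert) % 3 != 0:
        raise ValueError("insert must be in frame")
    codons = []
    for i in range(0, len(nt_insert), 3):
        codon = nt_insert[i : i + 3]
        if codon in _STOPS:
            raise ValueError(f"internal stop codon at codon index {i // 3}")
        codons.append(table.preferred_codon(_CODON_TABLE[codon]))
    return "".join(codons)


def _translate_insert(nt: str) -> str:
    return "".join(_CODON_TABLE[nt[i : i + 3]] for i in range(0, len(nt), 3))


def beam_search_solubilize(
    scorer,
    gene: TargetGene,
    scaffold: VectorScaffold,
    max_steps: int = 5,
    beam: int | None = 5,
) -> MutationTrace:
    """Search synonymous mutations of the insert for a soluble prediction.

    ``scorer`` maps a :class:`FusionConstruct` to (predicted label, soluble
    probability); see :class:`fxpress.pipeline.ConstructClassifier`.  Each
    iteration expands every synonymous neighbor of each beam member (one new
    site per step; a site is never revisited), ranks candidates by soluble
    probability and keeps the top ``beam`` (``None`` = unbounded).  Stops as
    soon as the best candidate is predicted soluble, or after ``max_steps``.
    Ties break toward higher score, fewer steps, lowest mutated position.
    """
    target_aa = _translate_insert(gene.cds)
    start = assemble_construct(gene, scaffold)
    start_label, start_score = scorer(start)
    trace = MutationTrace(
        key=start.key, start_label=start_label, start_score=float(start_score),
        final_insert=gene.cds,
    )
    if start_label == "soluble":
        trace.success = True
        return trace

    # beam entries: (insert, steps, label, score)
    frontier = [(gene.cds, [], start_label, float(start_score))]
    best_entry = None
    for _ in range(max_steps):
        candidates = []
        for insert, steps, _, _ in frontier:
            used = {s.position for s in steps}
            for step, mutated in synonymous_neighbors(insert):
                if step.position in used:
                    continue
                assert _translate_insert(mutated) == target_aa
                construct = assemble_construct(
                    TargetGene(id=gene.id, cds=mutated), scaffold
                )
                label, score = scorer(construct)
                candidates.append((mutated, steps + [step], label, float(score)))
        if not candidates:
            break
        # higher score first, then fewer steps, then lowest last-mutated position
        candidates.sort(key=lambda c: (-c[3], len(c[1]), c[1][-1].position))
        if beam is not None:
            candidates = candidates[:beam]
        frontier = candidates
        best_entry = candidates[0]
        if best_entry[2] == "soluble":
            break

    if best_entry is not None:
        insert, steps, label, score = best_entry
        trace.steps = steps
        trace.final_insert = insert
        trace.labels = [label]  # label/score after the final step
        trace.scores = [score]
        trace.success = label == "soluble"
    return trace


def simulate_recovery(
    scorer,
    genes: dict[str, TargetGene],
    scaffolds: dict[str, VectorScaffold],
    labels: dict[tuple[str, str], str],
    table: CodonUsageTable,
    max_steps: int = 5,
    beam: int | None = 5,
) -> dict[str, dict[str, int]]:
    """Try both design procedures on every non_expression-labelled case.

    Returns ``{"beam_search": {...}, "codon_optimization": {...}}`` where each
    inner dict counts cases flipped to soluble / insoluble / unchanged
    (categories partition the non_expression set).
    """
    summary = {
        "beam_search": {"soluble": 0, "insoluble": 0, "unchanged": 0},
        "codon_optimization": {"soluble": 0, "insoluble": 0, "unchanged": 0},
    }
    for (gene_id, vec), label in labels.items():
        if label != "non_expression":
            continue
        gene, scaffold = genes[gene_id], scaffolds[vec]
        trace = beam_search_solubilize(scorer, gene, scaffold, max_steps, beam)
        if trace.success:
            summary["beam_search"]["soluble"] += 1
        elif trace.labels and trace.labels[-1] == "insoluble":
            summary["beam_search"]["insoluble"] += 1
        else:
            summary["beam_search"]["unchanged"] += 1

        optimized = codon_optimize(gene.cds, table)
        construct = assemble_construct(TargetGene(id=gene_id, cds=optimized), scaffold)
        opt_label, _ = scorer(construct)
        if opt_label == "soluble":
            summary["codon_optimization"]["soluble"] += 1
        elif opt_label == "insoluble":
            summary["codon_optimization"]["insoluble"] += 1
        else:
            summary["codon_optimization"]["unchanged"] += 1
    return summary


def render_alignment(original: str, mutated: str, width: int = 60) -> str:
    """Text rendering of original vs mutated insert, marking changed sites."""
    if len(original) != len(mutated):
        raise ValueError("sequences must have equal length")
    lines = []
    for start in range(0, len(original), width):
        o = original[start : start + width]
        m = mutated[start : start + width]
        marks = "".join("*" if a != b else " " for a, b in zip(o, m))
        lines += [f"orig {start + 1:>6} {o}", f"mut  {start + 1:>6} {m}",
                  f"            {marks}", ""]
    return "\n".join(lines)
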