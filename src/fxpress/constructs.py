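"""Sequence I/O and fusion-construct assembly.

A high-throughput fusion-expression screen clones each target gene, flanked
by EcoRI/XhoI sticky ends, into six expression vectors in parallel.  The
classifier operates on the *entire* cloning and expression region (tag CDS +
insert + downstream region), so this module assembles that region exactly:
``nt = upstream + insert + downstream`` and translates it with the standard
genetic code.

Conventions: sequences are stored 5'->3' uppercase, coordinates are 0-based
half-open, only the coding strand is handled.  Trailing stop codons are
dropped from translations; an internal in-frame stop is an error (a real
fusion would be truncated).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

__all__ = [
    "TargetGene",
    "VectorScaffold",
    "FusionConstruct",
    "ConstructError",
    "VECTOR_NAMES",
    "ECORI_SITE",
    "XHOI_SITE",
    "translate",
    "assemble_construct",
    "read_fasta",
    "write_fasta",
    "read_scaffolds",
    "write_scaffolds",
    "read_label_table",
    "write_label_table",
]

VECTOR_NAMES = ("CBP", "GST", "His", "MBP", "NusA", "Trx")
ECORI_SITE = "GAATTC"
XHOI_SITE = "CTCGAG"

LABELS = ("soluble", "insoluble", "non_expression")

_DNA = set("ACGT")
_CODON_TABLE = standard_dna_table.forward_table
_STOP_CODONS = set(standard_dna_table.stop_codons)

# default bounds of the gene cohort this tool targets (nt, in-frame)
DEFAULT_MIN_LEN = 144
DEFAULT_MAX_LEN = 3162


class ConstructError(ValueError):
    """Raised on malformed sequences or impossible assemblies."""


def _check_dna(seq: str, name: str) -> str:
    seq = seq.upper()
    for i, c in enumerate(seq):
        if c not in _DNA:
            raise ConstructError(f"{name}: non-ACGT character {c!r} at position {i}")
    return seq


def translate(nt: str) -> str:
    """Translate an in-frame DNA string with the standard genetic code.

    A single trailing stop codon is dropped; an internal in-frame stop raises
    :class:`ConstructError` naming the codon index.
    """
    nt = _check_dna(nt, "sequence")
    if len(nt) % 3 != 0:
        raise ConstructError(f"length {len(nt)} is not a multiple of 3")
    n_codons = len(nt) // 3
    aa_chars = []
    for i in range(n_codons):
        codon = nt[3 * i : 3 * i + 3]
        if codon in _STOP_CODONS:
            if i == n_codons - 1:
                break  # trailing stop dropped
            raise ConstructError(f"internal stop codon {codon} at codon index {i}")
        aa_chars.append(_CODON_TABLE[codon])
    return "".join(aa_chars)


@dataclass(frozen=True)
class TargetGene:
    """One target coding sequence (5'->3', in frame, no stop codon)."""

    id: str
    cds: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "cds", _check_dna(self.cds, f"gene {self.id}"))
        if len(self.cds) % 3 != 0:
            raise ConstructError(
                f"gene {self.id}: length {len(self.cds)} is not a multiple of 3"
            )


@dataclass(frozen=True)
class VectorScaffold:
    """Cloning/expression region of one fusion vector, split at the insert.

    ``upstream_nt`` runs from the tag CDS start through the EcoRI junction
    (must end with GAATTC and preserve frame into the insert); ``downstream_nt``
    runs from the XhoI junction (must start with CTCGAG) through the stop.
    """

    name: str
    upstream_nt: str
    downstream_nt: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "upstream_nt", _check_dna(self.upstream_nt, f"{self.name} upstream")
        )
        object.__setattr__(
            self,
            "downstream_nt",
            _check_dna(self.downstream_nt, f"{self.name} downstream"),
        )
        if not self.upstream_nt.endswith(ECORI_SITE):
            raise ConstructError(f"{self.name}: upstream must end with EcoRI {ECORI_SITE}")
        if not self.downstream_nt.startswith(XHOI_SITE):
            raise ConstructError(
                f"{self.name}: downstream must start with XhoI {XHOI_SITE}"
            )
        if len(self.upstream_nt) % 3 != 0:
            raise ConstructError(
                f"{self.name}: upstream length {len(self.upstream_nt)} breaks the "
                "reading frame into the insert"
            )


@dataclass(frozen=True)
class FusionConstruct:
    """Entire cloning and expression region of one gene x vector pairing."""

    gene_id: str
    vector_name: str
    nt: str
    aa: str

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_id, self.vector_name)


def assemble_construct(gene: TargetGene, scaffold: VectorScaffold) -> FusionConstruct:
    """Concatenate upstream + insert + downstream and translate the result."""
    nt = scaffold.upstream_nt + gene.cds + scaffold.downstream_nt
    aa = translate(nt)  # raises on an introduced internal stop
    return FusionConstruct(gene_id=gene.id, vector_name=scaffold.name, nt=nt, aa=aa)


# ---------------------------------------------------------------------------
# file formats


def read_fasta(
    path: str | Path,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    enforce_bounds: bool = False,
) -> list[TargetGene]:
    """Read target genes from FASTA, uppercasing and validating each record.

    Records with non-ACGT characters or a length that is not a multiple of 3
    are rejected with a diagnostic.  Length bounds are only enforced when
    ``enforce_bounds`` is set (the screen's cohort spans 144-3162 nt but the
    tool accepts any in-frame CDS by default).
    """
    genes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        gene = TargetGene(id=rec.id, cds=seq)  # raises with diagnostics
        if enforce_bounds and not (min_len <= len(seq) <= max_len):
            raise ConstructError(
                f"gene {rec.id}: length {len(seq)} outside [{min_len}, {max_len}]"
            )
        genes.append(gene)
    return genes


def write_fasta(genes: Iterable[TargetGene], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(g.cds), id=g.id, description="") for g in genes
    ]
    SeqIO.write(records, str(path), "fasta-2line")


def write_constructs_fasta(constructs: Iterable[FusionConstruct], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(c.nt), id=f"{c.gene_id}|{c.vector_name}", description="")
        for c in constructs
    ]
    SeqIO.write(records, str(path), "fasta-2line")


def read_scaffolds(manifest_path: str | Path) -> list[VectorScaffold]:
    """Load vector scaffolds from a JSON manifest next to a FASTA file.

    Manifest format: ``{"fasta": "vectors.fa", "vectors": [{"name": ...,
    "upstream_fasta_id": ..., "downstream_fasta_id": ...}, ...]}``; the FASTA
    path is resolved relative to the manifest.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    fasta = manifest_path.parent / manifest["fasta"]
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
    scaffolds = []
    for entry in manifest["vectors"]:
        scaffolds.append(
            VectorScaffold(
                name=entry["name"],
                upstream_nt=seqs[entry["upstream_fasta_id"]],
                downstream_nt=seqs[entry["downstream_fasta_id"]],
            )
        )
    return scaffolds


def write_scaffolds(scaffolds: Iterable[VectorScaffold], manifest_path: str | Path) -> None:
    """Write scaffolds as a JSON manifest plus a sibling FASTA file."""
    manifest_path = Path(manifest_path)
    fasta_name = manifest_path.stem + ".fa"
    records, entries = [], []
    for sc in scaffolds:
        up_id, down_id = f"{sc.name}_up", f"{sc.name}_down"
        records.append(SeqRecord(Seq(sc.upstream_nt), id=up_id, description=""))
        records.append(SeqRecord(Seq(sc.downstream_nt), id=down_id, description=""))
        entries.append(
            {"name": sc.name, "upstream_fasta_id": up_id, "downstream_fasta_id": down_id}
        )
    SeqIO.write(records, str(manifest_path.parent / fasta_name), "fasta-2line")
    with open(manifest_path, "w") as fh:
        json.dump({"fasta": fasta_name, "vectors": entries}, fh, indent=1)


def read_label_table(path: str | Path) -> dict[tuple[str, str], str]:
    """Read a TSV with header ``gene_id  vector  label`` into a key->label map."""
    table: dict[tuple[str, str], str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["gene_id", "vector", "label"]:
            raise ConstructError(f"unexpected label-table header: {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            gene_id, vector, label = line.rstrip("\n").split("\t")[:3]
            if label not in LABELS:
                raise ConstructError(f"line {lineno}: unknown label {label!r}")
            key = (gene_id, vector)
            if key in table:
                raise ConstructError(f"line {lineno}: duplicate key {key}")
            table[key] = label
    return table


def write_label_table(table: dict[tuple[str, str], str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tvector\tlabel\n")
        for (gene_id, vector), label in table.items():
            fh.write(f"{gene_id}\t{vector}\t{label}\n")
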