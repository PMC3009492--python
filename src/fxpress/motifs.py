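"""PROSITE-style motif scanning for post-translational-modification features.

The original study scored 71 PTM classes with a trained predictor served by a
web service that has since been retired.  This package replaces it with a
deterministic, dimension-faithful stand-in: a bundled table of 71 PTM classes
(``data/ptm_motifs_synthetic.tsv``, a synthetic curation mixing classic
PROSITE entries with kinase consensus motifs) scanned as regular expressions.
Each class contributes one feature: its count of non-overlapping matches in
the fusion protein.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = ["MotifTable", "prosite_to_regex", "load_motif_table"]

_ELEMENT_RE = re.compile(
    r"(?P<body><|>|x|[A-Z]|\[[A-Z]+\]|\{[A-Z]+\})(?:\((?P<lo>\d+)(?:,(?P<hi>\d+))?\))?"
)


def prosite_to_regex(pattern: str) -> str:
    """Convert a PROSITE-style pattern to a Python regex.

    Supported syntax: hyphen-separated elements; ``x`` any residue; ``[ABC]``
    alternatives; ``{ABC}`` exclusion; ``(n)`` / ``(n,m)`` repetition;
    ``<`` / ``>`` sequence anchors.
    """
    parts = []
    for element in pattern.strip().rstrip(".").split("-"):
        prefix = suffix = ""
        if element.startswith("<") and len(element) > 1:
            prefix, element = "^", element[1:]
        if element.endswith(">") and len(element) > 1:
            suffix, element = "$", element[:-1]
        m = _ELEMENT_RE.fullmatch(element)
        if m is None:
            raise ValueError(f"bad PROSITE element {element!r} in {pattern!r}")
        body = m.group("body")
        if body == "x":
            body = "."
        elif body == "<":
            body = "^"
        elif body == ">":
            body = "$"
        elif body.startswith("{"):
            body = "[^" + body[1:-1] + "]"
        lo, hi = m.group("lo"), m.group("hi")
        if hi is not None:
            body += f"{{{lo},{hi}}}"
        elif lo is not None:
            body += f"{{{lo}}}"
        parts.append(prefix + body + suffix)
    return "".join(parts)


@dataclass(frozen=True)
class MotifTable:
    """Ordered PTM-class -> compiled-pattern table (exactly 71 classes)."""

    names: tuple[str, ...]
    patterns: tuple[re.Pattern, ...]

    N_CLASSES = 71

    def __post_init__(self) -> None:
        if len(self.names) != len(self.patterns):
            raise ValueError("names/patterns length mismatch")
        if len(self.names) != self.N_CLASSES:
            raise ValueError(f"expected {self.N_CLASSES} PTM classes, got {len(self.names)}")

    def counts(self, aa: str) -> list[int]:
        """Non-overlapping match counts per PTM class, in table order."""
        return [len(pat.findall(aa)) for pat in self.patterns]


def _parse(lines) -> MotifTable:
    names, patterns = [], []
    header = next(lines).rstrip("\n").split("\t")
    if header[:2] != ["ptm_name", "pattern"]:
        raise ValueError(f"unexpected motif-table header: {header}")
    for line in lines:
        if not line.strip():
            continue
        name, pattern = line.rstrip("\n").split("\t")[:2]
        names.append(name)
        patterns.append(re.compile(prosite_to_regex(pattern)))
    return MotifTable(names=tuple(names), patterns=tuple(patterns))


def load_motif_table(path: str | Path | None = None) -> MotifTable:
    """Load a motif table TSV; defaults to the bundled synthetic 71-class table."""
    if path is None:
        ref = resources.files("fxpress.data") / "ptm_motifs_synthetic.tsv"
        with ref.open() as fh:
            return _parse(iter(fh))
    with open(path) as fh:
        return _parse(iter(fh))
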