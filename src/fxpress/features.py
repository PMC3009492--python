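"""The fixed 617-dimensional feature vector of a fusion construct.

Every feature is computed on the *entire* cloning and expression region —
the fusion tag plus the insert — not on the target protein alone, since the
same insert behaves differently in different vectors.  Layout (fixed order):

====================  =====  =======================================
block                 width  contents
====================  =====  =======================================
nucleotide               87  84 k-mer frequencies (k=1,2,3) + length
                             + GC content + CAI
protein                 459  6 Wilkinson-Harrison + 444 composition/
                             physicochemical + pI + 8 peptide stats
PTM                      71  motif-scan counts for 71 PTM classes
====================  =====  =======================================

The nucleotide block drives the expression stage of the nested classifier
(mRNA abundance/stability and codon adaptation); the protein and PTM blocks
drive the solubility stage.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from Bio.SeqUtils import molecular_weight
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from . import scales
from .constructs import ConstructError, FusionConstruct
from .motifs import MotifTable, load_motif_table

__all__ = [
    "CodonUsageTable",
    "FeatureVector",
    "load_codon_table",
    "kmer_frequencies",
    "gc_content",
    "cai",
    "wilkinson_harrison_features",
    "idicula_thomas_features",
    "isoelectric_point",
    "net_charge",
    "pepstats",
    "ptm_features",
    "featurize",
    "feature_names",
    "StandardTransform",
    "standardize",
    "N_FEATURES",
    "NT_SLICE",
    "PROTEIN_SLICE",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_STOPS = {"TAA", "TAG", "TGA"}

# block widths, asserted at construction
N_KMER = 84
N_NT = 87            # 84 k-mer + length + GC + CAI
N_WH = 6
N_IT = 444           # 20 + 400 + 24
N_PEPSTATS = 8
N_PROTEIN = N_WH + N_IT + 1 + N_PEPSTATS  # 459
N_PTM = 71
N_FEATURES = N_NT + N_PROTEIN + N_PTM     # 617
assert N_NT == N_KMER + 3
assert N_PROTEIN == 459 and N_FEATURES == 617

NT_SLICE = slice(0, N_NT)
PROTEIN_SLICE = slice(N_NT, N_FEATURES)  # 530 protein-level features (incl. PTM)


# ---------------------------------------------------------------------------
# codon usage


@dataclass(frozen=True)
class CodonUsageTable:
    """Relative adaptiveness ``w`` of each sense codon (preferred codon: w=1)."""

    w: dict[str, float]
    aa_of: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.w) != 61:
            raise ValueError(f"expected 61 sense codons, got {len(self.w)}")
        by_aa: dict[str, float] = {}
        for codon, wval in self.w.items():
            if not 0 < wval <= 1:
                raise ValueError(f"w out of (0,1] for {codon}: {wval}")
            aa = self.aa_of[codon]
            by_aa[aa] = max(by_aa.get(aa, 0.0), wval)
        bad = {aa: m for aa, m in by_aa.items() if abs(m - 1.0) > 1e-9}
        if bad:
            raise ValueError(f"max w per amino acid must be 1, violations: {bad}")

    def preferred_codon(self, aa: str) -> str:
        """The w=1 codon for an amino acid (lowest alphabetically on ties)."""
        best = [c for c, wv in self.w.items() if self.aa_of[c] == aa and abs(wv - 1.0) < 1e-9]
        if not best:
            raise KeyError(f"no codon for amino acid {aa!r}")
        return min(best)


def load_codon_table(path: str | Path | None = None) -> CodonUsageTable:
    """Load codon usage (codon, aa, per_thousand TSV) as relative adaptiveness.

    Defaults to the bundled *E. coli* K12 table.  ``w`` for each codon is its
    usage divided by the usage of the most-used synonymous codon.
    """
    if path is None:
        ref = resources.files("fxpress.data") / "ecoli_k12_codon_usage.tsv"
        lines = ref.read_text().splitlines()
    else:
        lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    if header[:3] != ["codon", "aa", "per_thousand"]:
        raise ValueError(f"unexpected codon-table header: {header}")
    freq: dict[str, float] = {}
    aa_of: dict[str, str] = {}
    for line in lines[1:]:
        if not line.strip():
            continue
        codon, aa, per_thousand = line.split("\t")[:3]
        if aa == "*":
            continue
        freq[codon] = float(per_thousand)
        aa_of[codon] = aa
    max_by_aa: dict[str, float] = {}
    for codon, f in freq.items():
        aa = aa_of[codon]
        max_by_aa[aa] = max(max_by_aa.get(aa, 0.0), f)
    w = {codon: f / max_by_aa[aa_of[codon]] for codon, f in freq.items()}
    return CodonUsageTable(w=w, aa_of=aa_of)


# ---------------------------------------------------------------------------
# nucleotide-level features


def kmer_frequencies(nt: str, k_max: int = 3) -> np.ndarray:
    """Overlapping k-mer frequencies for k=1..k_max, lexicographic order.

    Each k-block is counts/windows so it sums to 1; a sequence shorter than k
    yields an all-zero block with a warning.  Width 4+16+64=84 for k_max=3.
    """
    if not nt:
        raise ValueError("empty sequence")
    codes = np.fromiter((_BASE_INDEX[c] for c in nt), dtype=np.int64, count=len(nt))
    blocks = []
    for k in range(1, k_max + 1):
        n_windows = len(nt) - k + 1
        if n_windows <= 0:
            warnings.warn(f"sequence shorter than k={k}; zero block")
            blocks.append(np.zeros(4**k))
            continue
        window_codes = np.zeros(n_windows, dtype=np.int64)
        for j in range(k):
            window_codes = window_codes * 4 + codes[j : j + n_windows]
        blocks.append(np.bincount(window_codes, minlength=4**k) / n_windows)
    return np.concatenate(blocks)


def gc_content(nt: str) -> float:
    if not nt:
        raise ValueError("empty sequence")
    return (nt.count("G") + nt.count("C")) / len(nt)


def cai(nt: str, table: CodonUsageTable) -> float:
    """Codon Adaptation Index: geometric mean of relative adaptiveness.

    All sense codons are included (EMBOSS convention, no ATG/TGG exclusion).
    A single trailing stop codon is ignored, mirroring the translation
    convention; an internal stop or unknown codon is an error.
    """
    if len(nt) % 3 != 0:
        raise ValueError(f"length {len(nt)} is not a multiple of 3")
    codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
    if codons and codons[-1] in _STOPS:
        codons = codons[:-1]
    if not codons:
        raise ValueError("no sense codons")
    log_sum = 0.0
    for i, codon in enumerate(codons):
        if codon in _STOPS:
            raise ValueError(f"stop codon {codon} at codon index {i}")
        if codon not in table.w:
            raise ValueError(f"unknown codon {codon!r} at codon index {i}")
        log_sum += np.log(table.w[codon])
    return float(np.exp(log_sum / len(codons)))


# ---------------------------------------------------------------------------
# protein-level features


def _check_protein(aa: str) -> None:
    if not aa:
        raise ValueError("empty protein")
    bad = set(aa) - set(scales.AMINO_ACIDS)
    if bad:
        raise ValueError(f"unknown residues {sorted(bad)}")


def _scale_mean(aa: str, scale: dict[str, float]) -> float:
    return sum(scale[c] for c in aa) / len(aa)


def wilkinson_harrison_features(aa: str) -> np.ndarray:
    """The six classic inclusion-body covariates.

    [charge average ((K+R)-(D+E))/n, turn-forming fraction (N+G+P+S)/n,
    Cys fraction, Pro fraction, mean Hopp-Woods hydrophilicity, MW in Da].
    """
    _check_protein(aa)
    n = len(aa)
    charge = (aa.count("K") + aa.count("R") - aa.count("D") - aa.count("E")) / n
    turn = sum(aa.count(c) for c in "NGPS") / n
    return np.array(
        [
            charge,
            turn,
            aa.count("C") / n,
            aa.count("P") / n,
            _scale_mean(aa, scales.HOPP_WOODS),
            molecular_weight(aa, seq_type="protein"),
        ]
    )


def _composition(aa: str) -> np.ndarray:
    n = len(aa)
    return np.array([aa.count(c) / n for c in scales.AMINO_ACIDS])


def _dipeptide_composition(aa: str) -> np.ndarray:
    counts = np.zeros(400)
    if len(aa) < 2:
        return counts
    idx = {c: i for i, c in enumerate(scales.AMINO_ACIDS)}
    for a, b in zip(aa, aa[1:]):
        counts[idx[a] * 20 + idx[b]] += 1
    return counts / (len(aa) - 1)


def aliphatic_index(aa: str) -> float:
    """Ikai's aliphatic index on mole-percent A/V/I/L."""
    n = len(aa)
    xa, xv = 100 * aa.count("A") / n, 100 * aa.count("V") / n
    xil = 100 * (aa.count("I") + aa.count("L")) / n
    return xa + 2.9 * xv + 3.9 * xil


def _hydrophobic_patches(aa: str, window: int, cutoff: float) -> int:
    """Number of window positions whose mean Kyte-Doolittle >= cutoff."""
    if len(aa) < window:
        return 0
    kd = np.array([scales.KYTE_DOOLITTLE[c] for c in aa])
    means = np.convolve(kd, np.ones(window) / window, mode="valid")
    return int(np.sum(means >= cutoff))


def idicula_thomas_features(aa: str) -> np.ndarray:
    """444 sequence-derived protein features.

    20 amino-acid composition fractions, 400 dipeptide composition
    fractions, and 24 physicochemical descriptors (length, MW, GRAVY,
    aliphatic index, instability index, net charge at pH 7, six
    reduced-alphabet group fractions, hydrophobic-patch counts at three
    window sizes, and nine residue-scale averages — see
    :mod:`fxpress.scales` for the configurable scale/group lists).
    """
    _check_protein(aa)
    n = len(aa)
    descriptors = [
        float(n),
        molecular_weight(aa, seq_type="protein"),
        _scale_mean(aa, scales.KYTE_DOOLITTLE),
        aliphatic_index(aa),
        ProteinAnalysis(aa).instability_index(),
        net_charge(aa, 7.0),
    ]
    descriptors += [
        sum(aa.count(c) for c in group) / n for group in scales.RESIDUE_GROUPS.values()
    ]
    descriptors += [
        _hydrophobic_patches(aa, w, scales.PATCH_CUTOFF) for w in scales.PATCH_WINDOWS
    ]
    descriptors += [_scale_mean(aa, s) for s in scales.SCALE_AVERAGES.values()]
    out = np.concatenate([_composition(aa), _dipeptide_composition(aa), descriptors])
    assert out.shape == (N_IT,)
    return out


def net_charge(aa: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge at a given pH (EMBOSS pKa set)."""
    _check_protein(aa)
    pos = 1.0 / (1.0 + 10 ** (ph - scales.PKA_NTERM))
    for res, pka in scales.PKA_POSITIVE.items():
        pos += aa.count(res) / (1.0 + 10 ** (ph - pka))
    neg = 1.0 / (1.0 + 10 ** (scales.PKA_CTERM - ph))
    for res, pka in scales.PKA_NEGATIVE.items():
        neg += aa.count(res) / (1.0 + 10 ** (pka - ph))
    return pos - neg


def isoelectric_point(aa: str, tol: float = 1e-4) -> float:
    """pH of zero net charge, by bisection (the charge is monotone in pH)."""
    _check_protein(aa)
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(aa, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def pepstats(aa: str) -> np.ndarray:
    """Eight peptide statistics.

    [MW Da, residue count, average residue weight, net charge at pH 7,
    aromaticity fraction (F+W+Y), aliphatic index, GRAVY, molar extinction
    coefficient at 280 nm with reduced cysteines].
    """
    _check_protein(aa)
    n = len(aa)
    mw = molecular_weight(aa, seq_type="protein")
    extinction = sum(aa.count(res) * eps for res, eps in scales.EXTINCTION.items())
    return np.array(
        [
            mw,
            float(n),
            mw / n,
            net_charge(aa, 7.0),
            sum(aa.count(c) for c in "FWY") / n,
            aliphatic_index(aa),
            _scale_mean(aa, scales.KYTE_DOOLITTLE),
            extinction,
        ]
    )


def ptm_features(aa: str, motifs: MotifTable) -> np.ndarray:
    """Non-overlapping motif-match counts for the 71 PTM classes."""
    _check_protein(aa)
    return np.asarray(motifs.counts(aa), dtype=float)


# ---------------------------------------------------------------------------
# assembly of the full vector


@dataclass(frozen=True)
class FeatureVector:
    """Ordered 617-value feature vector of one construct, with named blocks."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} features, got {v.shape}")
        object.__setattr__(self, "values", v)

    @property
    def nt_block(self) -> np.ndarray:
        return self.values[NT_SLICE]

    @property
    def protein_block(self) -> np.ndarray:
        return self.values[PROTEIN_SLICE]


def _kmer_names() -> list[str]:
    names = []
    for k in (1, 2, 3):
        for mer in itertools.product(_BASES, repeat=k):
            names.append("kmer_" + "".join(mer))
    return names


def feature_names(motifs: MotifTable | None = None) -> list[str]:
    """Ordered names of all 617 features (PTM names from the motif table)."""
    if motifs is None:
        motifs = load_motif_table()
    names = _kmer_names() + ["nt_length", "gc_content", "cai"]
    names += [
        "wh_charge_average", "wh_turn_fraction", "wh_cys_fraction",
        "wh_pro_fraction", "wh_hydrophilicity", "wh_molecular_weight",
    ]
    names += [f"comp_{c}" for c in scales.AMINO_ACIDS]
    names += [f"dipep_{a}{b}" for a in scales.AMINO_ACIDS for b in scales.AMINO_ACIDS]
    names += [
        "it_length", "it_molecular_weight", "it_gravy", "it_aliphatic_index",
        "it_instability_index", "it_net_charge_ph7",
    ]
    names += [f"it_frac_{g}" for g in scales.RESIDUE_GROUPS]
    names += [f"it_patches_w{w}" for w in scales.PATCH_WINDOWS]
    names += [f"it_mean_{s}" for s in scales.SCALE_AVERAGES]
    names += ["isoelectric_point"]
    names += [
        "pep_molecular_weight", "pep_residue_count", "pep_avg_residue_weight",
        "pep_net_charge_ph7", "pep_aromaticity", "pep_aliphatic_index",
        "pep_gravy", "pep_extinction_280",
    ]
    names += [f"ptm_{n}" for n in motifs.names]
    assert len(names) == N_FEATURES
    return names


def nt_block_features(nt: str, table: CodonUsageTable) -> np.ndarray:
    """The 87 nucleotide-level features of a construct's full DNA."""
    return np.concatenate(
        [kmer_frequencies(nt), [float(len(nt)), gc_content(nt), cai(nt, table)]]
    )


def protein_block_features(aa: str, motifs: MotifTable) -> np.ndarray:
    """The 530 protein-level features (incl. PTM counts) of the fusion protein."""
    return np.concatenate(
        [
            wilkinson_harrison_features(aa),
            idicula_thomas_features(aa),
            [isoelectric_point(aa)],
            pepstats(aa),
            ptm_features(aa, motifs),
        ]
    )


def featurize(
    construct: FusionConstruct,
    table: CodonUsageTable,
    motifs: MotifTable,
) -> FeatureVector:
    """Compute the full 617-value feature vector of a fusion construct.

    Nucleotide-level features are computed on the entire fusion DNA and
    protein-level features on the entire fusion protein.
    """
    values = np.concatenate(
        [
            nt_block_features(construct.nt, table),
            protein_block_features(construct.aa, motifs),
        ]
    )
    return FeatureVector(values=values)


# ---------------------------------------------------------------------------
# standardization


@dataclass
class StandardTransform:
    """Per-feature z-score transform frozen on the training statistics."""

    mean_: np.ndarray = field(default_factory=lambda: np.array([]))
    scale_: np.ndarray = field(default_factory=lambda: np.array([]))

    def fit(self, X: np.ndarray) -> "StandardTransform":
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 vectors to standardize")
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        zero = sd == 0
        if zero.any():
            warnings.warn(f"{int(zero.sum())} zero-variance features left centered")
            sd = sd.copy()
            sd[zero] = 1.0
        self.scale_ = sd
        return self

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_


def standardize(train_vectors: np.ndarray) -> tuple[StandardTransform, np.ndarray]:
    """Fit a z-score transform on training vectors and return both."""
    transform = StandardTransform().fit(train_vectors)
    return transform, transform.apply(train_vectors)
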