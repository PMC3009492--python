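"""Synthetic fusion-expression datasets with a planted, recoverable rule.

The real screen (121 target genes x 6 vectors = 726 labelled constructs,
with roughly a third of cases in each of soluble / inclusion-body /
non-expression) is private.  This generator emulates its statistical
structure so that every pipeline stage is testable:

* genes are random in-frame ORFs, 144-3162 nt, with per-gene codon
  optimality, GC bias and residue-composition variation;
* labels follow a planted two-stage rule mirroring the label taxonomy —
  an *expression* stage that is a linear rule in nucleotide-level construct
  features (CAI, GC content, length) plus a vector-specific offset, and a
  *solubility* stage (only for expressed cases) linear in protein-level
  features (turn-forming fraction, charge average, GRAVY) plus vector
  offsets;
* stage intercepts are calibrated by quantile so the class marginals land on
  the configured targets; independent label noise is then applied.

Because expression depends only on nucleotide-block features and solubility
only on protein-block features, the nested classifier's structural
assumption holds exactly on noiseless data.  The generating coefficients
are returned so tests can verify they are recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import scales
from .classifiers import LABELS, LabeledInstance
from .constructs import FusionConstruct, TargetGene, VectorScaffold, assemble_construct
from .features import CodonUsageTable, FeatureVector, featurize, feature_names, load_codon_table
from .motifs import MotifTable, load_motif_table
from .scaffolds import default_scaffolds

__all__ = ["GeneratorConfig", "SyntheticDataset", "generate_genes", "generate_dataset"]

_AA_BASE = {
    "A": 8.3, "C": 1.4, "D": 5.4, "E": 6.7, "F": 3.9, "G": 7.1, "H": 2.3,
    "I": 5.9, "K": 5.8, "L": 9.7, "M": 2.4, "N": 4.1, "P": 4.7, "Q": 3.9,
    "R": 5.5, "S": 6.6, "T": 5.4, "V": 6.9, "W": 1.1, "Y": 2.9,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the emulated screen (defaults mirror the real one)."""

    n_genes: int = 121
    min_len_nt: int = 144
    max_len_nt: int = 3162
    # target class marginals (soluble, insoluble, non_expression) ~ 231:236:259
    class_marginals: tuple[float, float, float] = (231 / 726, 236 / 726, 259 / 726)
    # expression stage: weights on z-scored construct CAI, GC content, length
    expression_coefs: dict = field(
        default_factory=lambda: {"cai": 3.0, "gc_content": 1.0, "nt_length": -0.5}
    )
    expression_offsets: dict = field(
        default_factory=lambda: {
            "CBP": -0.41, "GST": -0.24, "His": -0.31,
            "MBP": 0.35, "NusA": 0.48, "Trx": 0.23,
        }
    )
    # solubility stage: weights on z-scored turn fraction, charge average, GRAVY
    solubility_coefs: dict = field(
        default_factory=lambda: {
            "wh_turn_fraction": 0.8, "wh_charge_average": -0.8, "pep_gravy": -3.0,
        }
    )
    solubility_offsets: dict = field(
        default_factory=lambda: {
            "CBP": -1.29, "GST": -0.06, "His": -0.81,
            "MBP": 0.76, "NusA": 1.03, "Trx": -0.22,
        }
    )
    noise_rate: float = 0.1
    # rejection calibration: genes are drawn from a pool_factor-times larger
    # pool and kept only if all their constructs clear boundary_margin
    # (in score-SD units) around both planted decision boundaries
    pool_factor: int = 3
    boundary_margin: float = 0.4
    seed: int = 20100118

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.class_marginals), 1.0):
            raise ValueError("class marginals must sum to 1")
        if not 0 <= self.noise_rate < 1:
            raise ValueError("noise rate must be in [0, 1)")
        if self.min_len_nt % 3 or self.max_len_nt % 3:
            raise ValueError("length bounds must be multiples of 3")


@dataclass
class SyntheticDataset:
    genes: list[TargetGene]
    scaffolds: list[VectorScaffold]
    constructs: list[FusionConstruct]
    instances: list[LabeledInstance]
    labels: dict[tuple[str, str], str]
    truth: dict


def _codon_choices(table: CodonUsageTable) -> dict[str, list[tuple[str, float]]]:
    by_aa: dict[str, list[tuple[str, float]]] = {}
    for codon, w in table.w.items():
        by_aa.setdefault(table.aa_of[codon], []).append((codon, w))
    return {aa: sorted(choices) for aa, choices in by_aa.items()}


def generate_genes(
    cfg: GeneratorConfig, table: CodonUsageTable | None = None
) -> list[TargetGene]:
    """Random in-frame ORFs (leading ATG, no stops) under the configured bounds.

    Per gene, residue composition is Dirichlet-perturbed around globular
    averages, and codon choice mixes codon-adaptiveness preference with a GC
    bias, so constructs span a realistic CAI/GC range.  Deterministic for a
    given config seed.
    """
    if table is None:
        table = load_codon_table()
    rng = np.random.default_rng(cfg.seed)
    choices = _codon_choices(table)
    aas = list(_AA_BASE)
    base = np.array([_AA_BASE[a] for a in aas])
    base = base / base.sum()
    genes = []
    lo, hi = cfg.min_len_nt // 3, cfg.max_len_nt // 3
    kd = np.array([scales.KYTE_DOOLITTLE[a] for a in aas]) / 4.5
    for i in range(cfg.n_genes):
        n_aa = int(rng.integers(lo, hi + 1))
        # hydropathy disposition is likewise bimodal: aggregation-prone
        # hydrophobic proteins vs well-behaved hydrophilic ones
        tilt = float(rng.choice([-0.8, 0.8]))
        w = base * np.exp(tilt * kd)
        comp = rng.dirichlet(w / w.sum() * 25)
        seq_aa = ["M"] + list(rng.choice(aas, size=n_aa - 1, p=comp))
        # codon adaptation is bimodal across the cohort: host-adapted genes
        # vs poorly adapted heterologous ones (the screen spans virus..human)
        if rng.random() < 0.5:
            pref_strength = float(rng.uniform(2.5, 4.5))
        else:
            pref_strength = float(rng.uniform(-1.5, 0.0))
        gc_bias = float(rng.uniform(-1.0, 1.0))
        codons = []
        for aa in seq_aa:
            opts = choices[aa]
            logw = np.array(
                [
                    pref_strength * np.log(w)
                    + gc_bias * (c.count("G") + c.count("C"))
                    for c, w in opts
                ]
            )
            p = np.exp(logw - logw.max())
            p /= p.sum()
            codons.append(opts[int(rng.choice(len(opts), p=p))][0])
        genes.append(TargetGene(id=f"g{i + 1:03d}", cds="".join(codons)))
    return genes


def _feature_index(names: list[str], wanted: dict) -> dict[str, int]:
    return {name: names.index(name) for name in wanted}


def generate_dataset(
    cfg: GeneratorConfig = GeneratorConfig(),
    scaffolds: list[VectorScaffold] | None = None,
    table: CodonUsageTable | None = None,
    motifs: MotifTable | None = None,
) -> SyntheticDataset:
    """Assemble, featurize and label every gene x vector construct.

    Labels follow the planted two-stage rule (expression then solubility)
    with quantile-calibrated intercepts and independent label noise; the
    generating parameters are returned in ``truth`` for recovery tests.
    """
    if table is None:
        table = load_codon_table()
    if motifs is None:
        motifs = load_motif_table()
    if scaffolds is None:
        scaffolds = default_scaffolds()
    rng = np.random.default_rng(cfg.seed + 1)
    names = feature_names(motifs)
    p_sol, p_insol, p_non = cfg.class_marginals
    frac_insol_given_expr = p_insol / (p_sol + p_insol)

    def assemble_pool(gene_list):
        constructs, rows = [], []
        for gene in gene_list:
            for sc in scaffolds:
                c = assemble_construct(gene, sc)
                constructs.append(c)
                rows.append(featurize(c, table, motifs).values)
        return constructs, np.stack(rows)

    def planted_score(coefs, offsets, constructs, X):
        idx = _feature_index(names, coefs)
        score = np.zeros(len(constructs))
        for fname, coef in coefs.items():
            col = X[:, idx[fname]]
            score += coef * (col - col.mean()) / col.std()
        score += np.array([offsets[c.vector_name] for c in constructs])
        return score

    def scores_and_cuts(constructs, X):
        es = planted_score(cfg.expression_coefs, cfg.expression_offsets, constructs, X)
        ec = np.quantile(es, p_non)
        ss = planted_score(cfg.solubility_coefs, cfg.solubility_offsets, constructs, X)
        sc = np.quantile(ss[es > ec], frac_insol_given_expr)
        return es, ec, ss, sc

    # rejection calibration: draw a larger gene pool, score it against
    # preliminary cuts, and keep genes whose constructs all clear a margin
    # around both boundaries, so the planted rule has a real decision gap
    pool_cfg = GeneratorConfig(
        **{**cfg.__dict__, "n_genes": cfg.n_genes * cfg.pool_factor}
    )
    pool_genes = generate_genes(pool_cfg, table)
    pool_constructs, pool_X = assemble_pool(pool_genes)
    es, ec, ss, sc = scores_and_cuts(pool_constructs, pool_X)
    n_vec = len(scaffolds)
    gene_margin = np.empty(len(pool_genes))
    for gi in range(len(pool_genes)):
        rows = slice(gi * n_vec, (gi + 1) * n_vec)
        m_expr = np.abs(es[rows] - ec) / es.std()
        expr_mask = es[rows] > ec
        m_sol = np.abs(ss[rows][expr_mask] - sc) / ss.std()
        gene_margin[gi] = min(m_expr.min(), m_sol.min() if m_sol.size else np.inf)
    keep = [gi for gi in range(len(pool_genes)) if gene_margin[gi] >= cfg.boundary_margin]
    if len(keep) < cfg.n_genes:  # top up with the least boundary-adjacent rest
        rest = [gi for gi in np.argsort(-gene_margin) if gi not in set(keep)]
        keep += rest[: cfg.n_genes - len(keep)]
    keep = sorted(keep[: cfg.n_genes])
    genes = [pool_genes[gi] for gi in keep]
    rows = np.concatenate([np.arange(gi * n_vec, (gi + 1) * n_vec) for gi in keep])
    constructs = [pool_constructs[i] for i in rows]
    X = pool_X[rows]

    # final calibration on the selected cohort
    expr_score, expr_cut, sol_score, sol_cut = scores_and_cuts(constructs, X)
    expressed = expr_score > expr_cut

    clean = np.where(
        ~expressed, "non_expression", np.where(sol_score > sol_cut, "soluble", "insoluble")
    )
    noisy = clean.copy()
    flip = rng.random(len(constructs)) < cfg.noise_rate
    for i in np.flatnonzero(flip):
        others = [l for l in LABELS if l != clean[i]]
        noisy[i] = others[int(rng.integers(2))]

    instances = [
        LabeledInstance(key=c.key, x=x, y=str(y))
        for c, x, y in zip(constructs, X, noisy)
    ]
    labels = {c.key: str(y) for c, y in zip(constructs, noisy)}
    truth = {
        "expression_coefs": dict(cfg.expression_coefs),
        "expression_offsets": dict(cfg.expression_offsets),
        "expression_cut": float(expr_cut),
        "solubility_coefs": dict(cfg.solubility_coefs),
        "solubility_offsets": dict(cfg.solubility_offsets),
        "solubility_cut": float(sol_cut),
        "expression_score": expr_score,
        "solubility_score": sol_score,
        "clean_labels": clean,
    }
    return SyntheticDataset(
        genes=genes,
        scaffolds=scaffolds,
        constructs=constructs,
        instances=instances,
        labels=labels,
        truth=truth,
    )
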