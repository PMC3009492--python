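"""Feature extraction: k-mers, CAI, protein descriptors, PTM scan, blocks."""

import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fxpress import features as F
from fxpress.constructs import TargetGene, assemble_construct
from fxpress.motifs import MotifTable, prosite_to_regex

dna = st.text(alphabet="ACGT", min_size=3, max_size=120)


# -- k-mers -----------------------------------------------------------------


def test_kmer_uniform_single_bases():
    v = F.kmer_frequencies("ACGT")
    assert np.allclose(v[:4], 0.25)


def test_kmer_homopolymer():
    v = F.kmer_frequencies("AAAA")
    assert v[0] == 1.0          # A
    assert v[4] == 1.0          # AA
    assert v[20] == 1.0         # AAA
    assert v.sum() == pytest.approx(3.0)


def test_kmer_hand_counted_windows():
    # "AAT": 2-mers AA and AT, one window each
    v = F.kmer_frequencies("AAT")
    k2 = v[4:20]
    assert k2[0] == pytest.approx(0.5)   # AA
    assert k2[3] == pytest.approx(0.5)   # AT
    assert k2.sum() == pytest.approx(1.0)


@settings(derandomize=True, max_examples=50)
@given(dna)
def test_kmer_blocks_sum_to_one(seq):
    v = F.kmer_frequencies(seq)
    assert v.shape == (84,)
    for k, (lo, hi) in enumerate([(0, 4), (4, 20), (20, 84)], start=1):
        if len(seq) >= k:
            assert v[lo:hi].sum() == pytest.approx(1.0)


def test_kmer_short_sequence_zero_block_warns():
    with pytest.warns(UserWarning):
        v = F.kmer_frequencies("AC")  # no 3-mer window
    assert np.all(v[20:] == 0)


# -- GC and CAI -------------------------------------------------------------


@pytest.mark.parametrize("nt, gc", [("GGCC", 1.0), ("ATAT", 0.0), ("ACGT", 0.5)])
def test_gc_content(nt, gc):
    assert F.gc_content(nt) == pytest.approx(gc)


def _toy_table():
    base = F.load_codon_table()
    w = dict.fromkeys(base.w, 1.0)
    w["CTA"] = 0.25  # a Leu codon; CTG stays at 1
    return F.CodonUsageTable(w=w, aa_of=base.aa_of)


def test_cai_all_preferred_codons_is_one():
    assert F.cai("CTGCTG", _toy_table()) == pytest.approx(1.0)


def test_cai_hand_geometric_mean():
    # sqrt(1.0 * 0.25) = 0.5
    assert F.cai("CTGCTA", _toy_table()) == pytest.approx(0.5)


def test_cai_ignores_single_trailing_stop(codon_table):
    assert F.cai("ATGGAATAA", codon_table) == pytest.approx(
        F.cai("ATGGAA", codon_table)
    )


def test_cai_rejects_internal_stop(codon_table):
    with pytest.raises(ValueError, match="stop codon"):
        F.cai("TAAATG", codon_table)


@settings(derandomize=True, max_examples=30)
@given(st.lists(st.sampled_from(sorted(F.load_codon_table().w)), min_size=1, max_size=40))
def test_cai_invariant_under_repetition(codons):
    table = F.load_codon_table()
    s = "".join(codons)
    assert F.cai(s, table) == pytest.approx(F.cai(s + s, table))


def test_bundled_table_has_61_sense_codons_max_w_one(codon_table):
    assert len(codon_table.w) == 61
    by_aa = {}
    for codon, w in codon_table.w.items():
        aa = codon_table.aa_of[codon]
        by_aa[aa] = max(by_aa.get(aa, 0.0), w)
    assert all(abs(m - 1.0) < 1e-12 for m in by_aa.values())


# -- Wilkinson-Harrison and Idicula-Thomas blocks ---------------------------


def test_wh_turn_and_charge_extremes():
    v = F.wilkinson_harrison_features("GGGG")
    charge, turn, cys, pro, _, _ = v
    assert (charge, turn, cys, pro) == (0.0, 1.0, 0.0, 0.0)
    assert F.wilkinson_harrison_features("KKKK")[0] == pytest.approx(1.0)


def test_wh_molecular_weight_hand_sum():
    # average residue masses N+G+P+S plus one water
    expected = 114.1038 + 57.0519 + 97.1167 + 87.0782 + 18.0153
    v = F.wilkinson_harrison_features("NGPS")
    assert v[1] == pytest.approx(1.0)          # all turn-forming
    assert v[5] == pytest.approx(expected, abs=0.2)


def test_wh_rejects_unknown_residue():
    with pytest.raises(ValueError, match="unknown residues"):
        F.wilkinson_harrison_features("ABCD")


def test_it_block_dimensions_and_compositions():
    v = F.idicula_thomas_features("AAAA")
    assert v.shape == (444,)
    assert v[0] == 1.0                   # composition A
    assert v[20] == 1.0                  # dipeptide AA
    assert np.sum(v[:20]) == pytest.approx(1.0)

    v = F.idicula_thomas_features("AR")
    assert v[0] == pytest.approx(0.5)    # A
    assert v[np.flatnonzero([c == "R" for c in F.scales.AMINO_ACIDS])[0]] == pytest.approx(0.5)
    # dipeptide AR: row A (index 0), column R
    col_r = F.scales.AMINO_ACIDS.index("R")
    assert v[20 + col_r] == pytest.approx(1.0)


# -- isoelectric point and pepstats -----------------------------------------


@pytest.mark.parametrize("peptide", ["MKKLLR", "DDEEWY", "ACDEFGHIKLMNPQRSTVWY"])
def test_pi_is_zero_charge_point(peptide):
    pi = F.isoelectric_point(peptide)
    assert abs(F.net_charge(peptide, pi)) < 1e-3


def test_pi_acidic_below_basic():
    assert F.isoelectric_point("DDDD") < F.isoelectric_point("KKKK")


def test_pi_matches_independent_grid_search_oracle():
    peptide = "MKWVTFISLLFLFSSAYS"
    # brute-force oracle on the same pKa set: finest zero crossing on a grid
    grid = np.arange(0.0, 14.0, 1e-4)
    charges = np.array([F.net_charge(peptide, ph) for ph in grid])
    oracle = grid[np.argmin(np.abs(charges))]
    assert F.isoelectric_point(peptide) == pytest.approx(oracle, abs=1e-3)


def test_pepstats_values():
    v = F.pepstats("IIII")
    assert v[1] == 4.0                       # residue count
    assert v[6] == pytest.approx(4.5)        # GRAVY of poly-Ile (Kyte-Doolittle)
    assert v[7] == 0.0                       # no W/Y -> zero extinction
    v48 = F.pepstats("A" * 48)
    assert v48[1] == 48.0
    assert v48[2] == pytest.approx(v48[0] / 48)


# -- PTM scan ----------------------------------------------------------------


def test_prosite_conversion():
    assert prosite_to_regex("N-{P}-[ST]-{P}") == "N[^P][ST][^P]"
    assert prosite_to_regex("R-x(2)-[ST]") == "R.{2}[ST]"
    assert prosite_to_regex("<M-[ADEGS]") == "^M[ADEGS]"
    assert prosite_to_regex("C-[ALIV]-[ALIV]-x>") == "C[ALIV][ALIV].$"


def _toy_motifs():
    names = ["ptm1"] + [f"pad{i}" for i in range(70)]
    patterns = [re.compile("NG")] + [re.compile("W{20}")] * 70
    return MotifTable(names=tuple(names), patterns=tuple(patterns))


def test_ptm_counts_toy_table():
    v = F.ptm_features("ANGA", _toy_motifs())
    assert v.shape == (71,)
    assert v[0] == 1.0
    assert np.all(v[1:] == 0)


def test_ptm_zero_vector_when_nothing_matches():
    v = F.ptm_features("AAAA", _toy_motifs())
    assert v.shape == (71,)
    assert np.all(v == 0)


def test_bundled_motif_table_has_71_classes(motif_table):
    assert len(motif_table.names) == 71
    assert len(set(motif_table.names)) == 71


# -- full vector, names, standardization ------------------------------------


def test_featurize_layout_and_determinism(codon_table, motif_table, scaffolds):
    gene = TargetGene(id="g1", cds="ATG" + "GGTGAAAAATTC" * 6)
    c = assemble_construct(gene, scaffolds[1])
    fv1 = F.featurize(c, codon_table, motif_table)
    fv2 = F.featurize(c, codon_table, motif_table)
    assert fv1.values.shape == (617,)
    assert np.array_equal(fv1.values, fv2.values)
    assert fv1.nt_block.shape == (87,)
    assert fv1.protein_block.shape == (530,)
    assert fv1.values[84] == len(c.nt)  # nt length feature


def test_feature_names_align_with_layout(motif_table):
    names = F.feature_names(motif_table)
    assert len(names) == 617
    assert names[84:87] == ["nt_length", "gc_content", "cai"]
    assert names[87].startswith("wh_")
    assert names[546].startswith("ptm_")
    assert len(set(names)) == 617


def test_block_count_conservation():
    assert F.N_KMER + 3 == F.N_NT == 87
    assert F.N_WH + F.N_IT + 1 + F.N_PEPSTATS == F.N_PROTEIN == 459
    assert F.N_PROTEIN + F.N_PTM == 530
    assert F.N_NT + F.N_PROTEIN + F.N_PTM == F.N_FEATURES == 617


def test_standardize_contract():
    rng = np.random.default_rng(5)
    X = rng.normal(2.0, 3.0, size=(40, 6))
    X[:, 2] = 7.0  # constant column
    with pytest.warns(UserWarning, match="zero-variance"):
        transform, Xs = F.standardize(X)
    assert np.allclose(Xs.mean(axis=0), 0.0, atol=1e-9)
    keep = [0, 1, 3, 4, 5]
    assert np.allclose(Xs[:, keep].std(axis=0), 1.0, atol=1e-9)
    assert np.all(Xs[:, 2] == 0.0) and not np.any(np.isnan(Xs))
    # reapplying the stored transform reproduces the standardized set
    assert np.array_equal(transform.apply(X), Xs)
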