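"""Codon-model selection analysis: aligner, back-translation, likelihood
correctness, omega recovery, and the NG86 counting estimator."""

import math

import numpy as np
import pytest

from stratigraph import selection as sel


# --- protein alignment -----------------------------------------------------

def test_identical_pair_aligns_gap_free():
    a, b = sel.nw_align("MKVLITAAG", "MKVLITAAG")
    assert a == b == "MKVLITAAG"


def test_internal_deletion_opens_one_gap_of_three():
    ref = "MKVDEQWLITAAGHHRR"
    mut = ref[:5] + ref[8:]  # 3-aa internal deletion
    a, b = sel.nw_align(ref, mut)
    assert a == ref
    assert b.count("-") == 3
    assert "---" in b  # one contiguous gap


def test_msa_width_at_least_longest_input():
    seqs = {"a": "MKVLITAAGWW", "b": "MKVITAAG", "c": "MKVLITAG"}
    aln = sel.align_proteins(seqs)
    width = {len(v) for v in aln.values()}
    assert len(width) == 1
    assert width.pop() >= max(len(s) for s in seqs.values())
    for k, s in seqs.items():
        assert aln[k].replace("-", "") == s


def test_empty_sequence_rejected():
    with pytest.raises(ValueError, match="empty"):
        sel.align_proteins({"a": "", "b": "MK"})


# --- back-translation ------------------------------------------------------

def test_backtranslate_mirrors_protein_columns():
    aln = {"x": "MK-V", "y": "MKAV"}
    cds = {"x": "ATGAAAGTT", "y": "ATGAAAGCTGTA"}
    ca = sel.backtranslate(aln, cds)
    assert ca.rows["x"] == "ATGAAA---GTT"
    assert ca.rows["y"] == "ATGAAAGCTGTA"
    # round trip: degapped rows reproduce the CDS
    assert ca.rows["x"].replace("-", "") == cds["x"]


def test_stop_residues_are_masked_with_positions():
    protein = "MKVLITAAGH*PQR"
    cds_parts = dict(M="ATG", K="AAA", V="GTT", L="CTT", I="ATT", T="ACT",
                     A="GCT", G="GGT", H="CAT", P="CCT", Q="CAA", R="CGT")
    cds = "".join("TAA" if c == "*" else cds_parts[c] for c in protein)
    ca = sel.backtranslate({"x": protein}| {"y": protein.replace("*", "L")},
                           {"x": cds, "y": cds.replace("TAA", "CTT")})
    assert ca.masked_stops["x"] == [11]
    assert ca.rows["x"][30:33] == "---"


def test_length_mismatch_names_the_row():
    with pytest.raises(ValueError, match="row 'x'"):
        sel.backtranslate({"x": "MKV"}, {"x": "ATGAAA"})


# --- likelihood machinery --------------------------------------------------

def _brute_force_lnl_2tax(aln, bl, kappa, omega):
    pats, counts = sel._site_patterns(aln, aln.taxa)
    pi_nuc = sel.nuc_freqs_from_alignment(aln)
    pi = sel.f1x4_codon_freqs(pi_nuc)
    Q = sel.codon_q(kappa, omega, pi, pi_nuc=pi_nuc)
    P1 = sel.transition_matrix(Q, pi, bl[0])
    P2 = sel.transition_matrix(Q, pi, bl[1])
    out = 0.0
    for j in range(pats.shape[1]):
        a, b = pats[0, j], pats[1, j]
        site = sum(pi[r] * P1[r, a] * P2[r, b] for r in range(61))
        out += math.log(site) * counts[j]
    return out


def test_pruning_equals_brute_force_two_taxa():
    rng = np.random.default_rng(0)
    c1, c2 = sel.simulate_mg94_pair(5, 0.3, 0.5, 2.0, rng)
    aln = sel.CodonAlignment({"a": c1, "b": c2}, {"a": [], "b": []})
    pats, counts = sel._site_patterns(aln, aln.taxa)
    tree = sel.two_taxon_tree("a", "b")
    n = sel._index_edges(tree)
    bl = np.array([0.2, 0.1])
    pi_nuc = sel.nuc_freqs_from_alignment(aln)
    pi = sel.f1x4_codon_freqs(pi_nuc)
    got = sel.log_likelihood(tree, aln.taxa, pats, counts, bl, 1.7,
                             np.full(n, 0.4), pi, pi_nuc)
    assert got == pytest.approx(_brute_force_lnl_2tax(aln, bl, 1.7, 0.4),
                                abs=1e-6)


def test_pruning_equals_brute_force_three_taxa():
    rng = np.random.default_rng(1)
    c1, c2 = sel.simulate_mg94_pair(4, 0.3, 0.6, 2.0, rng)
    c3 = sel.simulate_mg94_pair(4, 0.2, 0.6, 2.0, rng)[1]
    aln = sel.CodonAlignment({"a": c1, "b": c2, "c": c3},
                             {"a": [], "b": [], "c": []})
    pats, counts = sel._site_patterns(aln, aln.taxa)
    tree = sel.ladder_subtree(["a", "b", "c"])  # ((a,b),c)
    n = sel._index_edges(tree)
    bl = np.array([0.1, 0.15, 0.2, 0.25])[:n]
    pi_nuc = sel.nuc_freqs_from_alignment(aln)
    pi = sel.f1x4_codon_freqs(pi_nuc)
    got = sel.log_likelihood(tree, aln.taxa, pats, counts, bl, 1.7,
                             np.full(n, 0.4), pi, pi_nuc)
    # exhaustive sum over both internal nodes
    Q = sel.codon_q(1.7, 0.4, pi, pi_nuc=pi_nuc)
    Ps = [sel.transition_matrix(Q, pi, t) for t in bl]
    bf = 0.0
    for j in range(pats.shape[1]):
        sa, sb, sc = pats[:, j]
        tot = 0.0
        for root in range(61):
            inner = (Ps[1][:, sa] * Ps[2][:, sb])
            tot += pi[root] * (Ps[0][root] @ inner) * Ps[3][root, sc]
        bf += math.log(tot) * counts[j]
    assert got == pytest.approx(bf, abs=1e-6)


def test_rate_matrix_is_a_proper_generator():
    pi_nuc = np.array([0.3, 0.2, 0.3, 0.2])
    pi = sel.f1x4_codon_freqs(pi_nuc)
    Q = sel.codon_q(2.0, 0.5, pi, pi_nuc=pi_nuc)
    assert np.allclose(Q.sum(axis=1), 0, atol=1e-12)
    assert -(pi * np.diag(Q)).sum() == pytest.approx(1.0)
    # detailed balance (reversibility)
    assert np.allclose(pi[:, None] * Q, (pi[:, None] * Q).T, atol=1e-12)


# --- fitting ---------------------------------------------------------------

def test_identical_sequences_are_insufficient_data():
    c = "ATGGCTTGGACTCGT" * 5
    aln = sel.CodonAlignment({"a": c, "b": c}, {"a": [], "b": []})
    res = sel.fit_omega(aln)
    assert isinstance(res, sel.InsufficientData)
    assert "substitution" in res.reason


def test_too_few_columns_refused():
    rng = np.random.default_rng(3)
    c1, c2 = sel.simulate_mg94_pair(10, 0.4, 0.5, 2.0, rng)
    aln = sel.CodonAlignment({"a": c1, "b": c2}, {"a": [], "b": []})
    res = sel.fit_omega(aln)
    assert isinstance(res, sel.InsufficientData)


def test_alt_likelihood_dominates_null():
    rng = np.random.default_rng(4)
    c1, c2 = sel.simulate_mg94_pair(120, 0.5, 0.3, 2.0, rng)
    aln = sel.CodonAlignment({"a": c1, "b": c2}, {"a": [], "b": []})
    res = sel.fit_omega(aln)
    assert isinstance(res, sel.SelectionResult)
    assert res.lnl_alt >= res.lnl_null - 1e-4
    assert res.mode == "single-omega"
    assert res.df == 1
    assert res.omegas["tree"] < 1.0  # purifying simulation


def test_per_branch_mode_for_more_taxa():
    rng = np.random.default_rng(5)
    c1, c2 = sel.simulate_mg94_pair(80, 0.3, 0.5, 2.0, rng)
    c3 = sel.simulate_mg94_pair(80, 0.3, 0.5, 2.0, rng)[1]
    aln = sel.CodonAlignment({"sp0": c1, "sp1": c2, "sp2": c3},
                             {"sp0": [], "sp1": [], "sp2": []})
    res = sel.fit_omega(aln)
    assert isinstance(res, sel.SelectionResult)
    assert res.mode == "per-branch"
    assert res.df == len(res.omegas) >= 3


# --- NG86 ------------------------------------------------------------------

def test_ng86_identical_pair_undefined_omega():
    r = sel.ng86("TTTAAAGGG" * 10, "TTTAAAGGG" * 10)
    assert r["dN"] == 0 and r["dS"] == 0 and r["omega"] is None


def test_ng86_single_synonymous_difference():
    a = "TTT" + "AAA" * 99
    b = "TTC" + "AAA" * 99
    r = sel.ng86(a, b)
    assert r["dN"] == 0 and r["dS"] > 0


def test_ng86_single_nonsynonymous_difference():
    a = "TTT" + "AAA" * 99
    b = "TGT" + "AAA" * 99
    r = sel.ng86(a, b)
    assert r["dN"] > 0 and r["dS"] == 0 and r["omega"] is None


def test_ng86_input_validation():
    with pytest.raises(ValueError, match="length"):
        sel.ng86("ATGC", "ATGC")
    with pytest.raises(ValueError, match="stop"):
        sel.ng86("TAAAAA", "AAAAAA")


def test_write_phylip_codon_shape():
    aln = sel.CodonAlignment({"a": "ATGAAA", "b": "ATGAAG"},
                             {"a": [], "b": []})
    text = sel.write_phylip_codon(aln)
    first = text.splitlines()[0].split()
    assert first == ["2", "6"]
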