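"""The search engine: six-frame translation, Smith-Waterman scores
against a brute-force oracle, and Karlin-Altschul statistics."""

import math
import random

import numpy as np
import pytest
from Bio.Seq import Seq

from stratigraph import homsearch as hs

AA20 = "ARNDCQEGHILKMFPSTWYV"

# independent per-codon lookup (standard genetic code, written out here
# so the oracle does not share code with the implementation)
CODON_TABLE = {}
_bases = "TCAG"
_aas = ("FFLLSSSSYY**CC*W" "LLLLPPPPHHQQRRRR"
        "IIIMTTTTNNKKSSRR" "VVVVAAAADDEEGGGG")
for _i, _b1 in enumerate(_bases):
    for _j, _b2 in enumerate(_bases):
        for _k, _b3 in enumerate(_bases):
            CODON_TABLE[_b1 + _b2 + _b3] = _aas[16 * _i + 4 * _j + _k]


def sw_oracle(q, s, mat, gap_open, gap_ext):
    """Quadratic-DP affine Smith-Waterman, pure python."""
    m, n = len(q), len(s)
    NEG = -10 ** 9
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    go = gap_open + gap_ext
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - go, E[i][j - 1] - gap_ext)
            F[i][j] = max(H[i - 1][j] - go, F[i - 1][j] - gap_ext)
            H[i][j] = max(0, H[i - 1][j - 1] + mat[q[i - 1], s[j - 1]],
                          E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


# --- six-frame translation -------------------------------------------------

def test_frame_plus_one():
    assert hs.translate_six_frames("ATGAAATAG")[1] == "MK*"


def test_revcomp_symmetry():
    rng = random.Random(7)
    s = "".join(rng.choice("ACGT") for _ in range(120))
    rc = str(Seq(s).reverse_complement())
    f_s = hs.translate_six_frames(s)
    f_rc = hs.translate_six_frames(rc)
    for f in (1, 2, 3):
        assert f_s[-f] == f_rc[f]


def test_six_frames_agree_with_codon_table():
    rng = random.Random(11)
    s = "".join(rng.choice("ACGT") for _ in range(300))
    frames = hs.translate_six_frames(s)
    rc = str(Seq(s).reverse_complement())
    for f in (1, 2, 3):
        for seq, key in ((s, f), (rc, -f)):
            sub = seq[f - 1:]
            expected = "".join(CODON_TABLE[sub[i:i + 3]]
                               for i in range(0, len(sub) - 2, 3))
            assert frames[key] == expected


def test_translate_rejects_bad_input():
    with pytest.raises(ValueError, match="codon"):
        hs.translate_six_frames("AT")
    with pytest.raises(ValueError, match="IUPAC"):
        hs.translate_six_frames("ATGJJJ")


# --- Smith-Waterman vs oracle ----------------------------------------------

def test_sw_scores_match_brute_force_oracle():
    rng = random.Random(0)
    for _ in range(12):
        q = "".join(rng.choice(AA20) for _ in range(rng.randint(15, 120)))
        s = "".join(rng.choice(AA20) for _ in range(rng.randint(15, 160)))
        qe, se = hs.encode_protein(q), hs.encode_protein(s)
        fast = hs._sw_score(qe, se, hs.BLOSUM62, 11, 1)[0]
        full = hs._sw_full(qe, se, hs.BLOSUM62, 11, 1)[0]
        assert fast == full == sw_oracle(qe, se, hs.BLOSUM62, 11, 1)


def test_sw_nucleotide_scores_match_oracle():
    rng = random.Random(3)
    for _ in range(6):
        q = "".join(rng.choice("ACGT") for _ in range(rng.randint(30, 150)))
        s = "".join(rng.choice("ACGT") for _ in range(rng.randint(30, 200)))
        qe, se = hs.encode_nucl(q), hs.encode_nucl(s)
        assert hs._sw_score(qe, se, hs.NUCL_MATRIX, 5, 2)[0] == \
            sw_oracle(qe, se, hs.NUCL_MATRIX, 5, 2)


def test_sw_path_is_consistent_with_full():
    rng = random.Random(5)
    q = "".join(rng.choice("ACGT") for _ in range(80))
    s = q[:40] + "TTTTT" + q[40:]  # insertion in the subject
    score, qiv, siv, qmap = hs.sw_map(q, s, nucl=True)
    full = hs._sw_full(hs.encode_nucl(q), hs.encode_nucl(s),
                       hs.NUCL_MATRIX, 5, 2)
    assert score == full[0]
    aligned = [(i, j) for i, j in enumerate(qmap) if j >= 0]
    assert all(j2 > j1 for (_, j1), (_, j2) in zip(aligned, aligned[1:]))


# --- search semantics ------------------------------------------------------

def test_self_hit_is_perfect_and_minimal_evalue():
    prot = "MKVLITAGHEWQRNDFYCPS" * 5
    others = [("other", "WYYHH" + prot[5:40])]
    hits = hs.search([("q", prot)], [("self", prot)] + others,
                     hs.SearchParams.protein(1.0))
    assert hits[0].subject_id == "self"
    assert hits[0].pct_identity == 100.0
    assert hits[0].e_value == min(h.e_value for h in hits)


def test_empty_query_and_duplicate_subject_ids_error():
    p = hs.SearchParams.protein()
    with pytest.raises(ValueError, match="query"):
        hs.search([], [("a", "MKV")], p)
    with pytest.raises(ValueError, match="duplicate"):
        hs.search([("q", "MKVL")], [("a", "MKV"), ("a", "MKW")], p)


def test_evalue_strictly_decreases_with_score():
    p = hs.SearchParams.protein()
    es = [hs._evalue(p, 100, 10000, s) for s in range(30, 120, 10)]
    assert all(a > b for a, b in zip(es, es[1:]))


def test_threshold_is_inclusive():
    prot = "MKVLITAGHEWQRNDFYCPS" * 3
    subj = prot[:30]
    loose = hs.search([("q", prot)], [("s", subj)],
                      hs.SearchParams.protein(10.0))
    e = loose[0].e_value
    kept = hs.search([("q", prot)], [("s", subj)],
                     hs.SearchParams.protein(e, inclusive=True))
    dropped = hs.search([("q", prot)], [("s", subj)],
                        hs.SearchParams.protein(e, inclusive=False))
    assert len(kept) == 1 and len(dropped) == 0


def test_seeding_only_prunes_never_changes_scores(dataset):
    queries = sorted(dataset.proteins["sp0"].items())[:12]
    db = sorted(dataset.proteins["sp1"].items())
    p_seed = hs.SearchParams.protein(use_seeding=True)
    p_full = hs.SearchParams.protein(use_seeding=False)
    seeded = {(h.query_id, h.subject_id): h.raw_score
              for h in hs.search(queries, db, p_seed)}
    full = {(h.query_id, h.subject_id): h.raw_score
            for h in hs.search(queries, db, p_full)}
    assert seeded == full  # every significant pair shares a seed word here


def test_tblastn_reports_frame_and_genomic_interval():
    cds = "ATGGCTTGGACTCGTATGAAACAGCACGAGTGGTTTCCGAACGAC"
    prot = str(Seq(cds).translate())
    genome = "C" * 31 + cds + "G" * 20  # offset 31 -> frame +2
    hits = hs.search([("q", prot)], [("chr", genome)],
                     hs.SearchParams.translated(10.0))
    h = hits[0]
    assert h.subject_frame == 2
    s, e = h.subject_interval
    assert genome[s:e] == cds
    # reverse-complemented genome: same hit on the minus strand
    rc = str(Seq(genome).reverse_complement())
    h2 = hs.search([("q", prot)], [("chr", rc)],
                   hs.SearchParams.translated(10.0))[0]
    assert h2.subject_frame < 0 and h2.subject_strand == "-"
    s2, e2 = h2.subject_interval
    assert str(Seq(rc[s2:e2]).reverse_complement()) == cds


def test_outfmt6_round_trip():
    prot = "MKVLITAGHEWQRNDFYCPS" * 4
    hits = hs.search([("q", prot)], [("s", prot[:60])],
                     hs.SearchParams.protein())
    text = hs.write_outfmt6(hits)
    back = hs.read_outfmt6(text, mode="blastp")
    assert back[0].query_id == "q" and back[0].subject_id == "s"
    assert back[0].query_interval == hits[0].query_interval
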