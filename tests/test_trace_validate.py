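"""Trace-matrix categories and read-based structure confirmation."""

import numpy as np
import pytest

from stratigraph.core_model import (GeneModel, SpliceReadAlignment,
                                    compute_phases)
from stratigraph.simulate import rand_orf, rand_seq
from stratigraph.trace_validate import (StructureParams, TracePattern,
                                        high_confidence_set, structure_table,
                                        trace_homology, trace_table,
                                        validate_structure)


# --- category rules --------------------------------------------------------

def _pattern(cells):
    p = TracePattern("g", cells)
    return p.categorize()


def test_untraceable_is_all_false():
    assert _pattern({"s1": {"transcripts": False, "genome": False,
                            "transcriptome": False}}) == "untraceable"


def test_assembly_gap_pattern():
    assert _pattern({"s1": {"transcripts": False, "genome": False,
                            "transcriptome": True}}) == \
        "assembly-gap-candidate"


def test_all_three_and_partial():
    assert _pattern({"s1": {"transcripts": True, "genome": True,
                            "transcriptome": True}}) == "all-three"
    assert _pattern({"s1": {"transcripts": False, "genome": True,
                            "transcriptome": False}}) == "partial"


def test_unknown_cells_are_not_false():
    # a missing database must not make a gene untraceable
    assert _pattern({"s1": {"transcripts": None, "genome": None,
                            "transcriptome": None}}) == "partial"


def test_trace_homology_on_tiny_databases():
    rng = np.random.default_rng(2)
    tx1, tx2 = rand_orf(rng, 60), rand_orf(rng, 60)
    from stratigraph.simulate import protein_of
    ssogs = {"g1": {"protein": protein_of(tx1), "transcript": tx1},
             "g2": {"protein": protein_of(tx2), "transcript": tx2}}
    dbs = {"s1": {"transcripts": {}, "genome": {},
                  "transcriptome": {"hom": tx1}},
           "s2": {"transcripts": {}, "genome": {}}}  # transcriptome missing
    pats = trace_homology(ssogs, dbs)
    assert pats["g1"].category == "assembly-gap-candidate"
    assert pats["g2"].cells["s2"]["transcriptome"] is None
    assert pats["g2"].category == "untraceable"
    t1 = trace_table(pats).to_csv(sep="\t", index=False)
    t2 = trace_table(trace_homology(ssogs, dbs)).to_csv(sep="\t", index=False)
    assert t1 == t2  # deterministic


# --- structure validation --------------------------------------------------

def _gene(exons, strand="+"):
    cds = compute_phases([(a, b) for a, b in exons], strand)
    return GeneModel("g", "sp0", "c1", strand, exons, cds)


def _read(rid, blocks, strand="+"):
    return SpliceReadAlignment(rid, "c1", strand, blocks)


@pytest.fixture()
def two_exon_gene():
    # exons 60 nt / 60 nt with a 60 nt intron, fully coding
    return _gene([(100, 160), (220, 280)])


def _full_support(n_exon=3, n_junction=2):
    reads = []
    for i in range(n_exon):
        reads.append(_read(f"e1_{i}", [(100, 160)]))
        reads.append(_read(f"e2_{i}", [(220, 280)]))
    for i in range(n_junction):
        reads.append(_read(f"j_{i}", [(130, 160), (220, 250)]))
    return reads


def test_two_reads_everywhere_is_fully_confirmed(two_exon_gene):
    st = validate_structure(two_exon_gene, _full_support(), stranded=True)
    assert st.status == "fully-confirmed"
    # junction-read blocks cover 30/60 nt < the 80% span requirement,
    # so only the three full-exon reads support each exon
    assert st.exon_support == [3, 3]
    assert st.junction_support == [2]


def test_single_junction_read_caps_at_partially(two_exon_gene):
    st = validate_structure(two_exon_gene, _full_support(n_junction=1))
    assert st.status == "partially-confirmed"


def test_junction_edges_must_match_exactly(two_exon_gene):
    reads = _full_support(n_junction=0)
    reads += [_read(f"j{i}", [(130, 161), (220, 250)]) for i in range(2)]
    st = validate_structure(two_exon_gene, reads)
    assert st.junction_support == [0]
    assert st.status == "partially-confirmed"


def test_single_exon_gene_is_excluded():
    g = _gene([(100, 220)])
    st = validate_structure(g, [_read(f"r{i}", [(100, 220)])
                                for i in range(20)])
    assert st.status == "single-exon-excluded"


def test_empty_read_set_is_unconfirmed_not_an_error(two_exon_gene):
    st = validate_structure(two_exon_gene, [])
    assert st.status == "unconfirmed"
    assert st.exon_support == [0, 0] and st.junction_support == [0]


def test_antisense_support_caps_status(two_exon_gene):
    reads = _full_support()
    flipped = [_read(r.read_id, r.blocks, "-") for r in reads[:2]]
    st = validate_structure(two_exon_gene, flipped + reads[2:],
                            stranded=True)
    assert st.strand_consistent is False
    assert st.status == "partially-confirmed"
    st2 = validate_structure(two_exon_gene, flipped + reads[2:],
                             stranded=False)
    assert st2.status == "fully-confirmed"  # unstranded: no strand check


def test_counts_match_brute_force_interval_scan(two_exon_gene):
    rng = np.random.default_rng(5)
    reads = []
    for i in range(120):
        s = int(rng.integers(60, 300))
        ln = int(rng.integers(20, 90))
        if rng.random() < 0.3:
            reads.append(_read(f"s{i}", [(s, s + 30), (s + 90, s + 120)]))
        else:
            reads.append(_read(f"u{i}", [(s, s + ln)]))
    st = validate_structure(two_exon_gene, reads)
    # independent oracle: plain interval arithmetic
    for (ea, eb), got in zip(two_exon_gene.exons, st.exon_support):
        need = 0.8 * (eb - ea)
        exp = sum(1 for r in reads
                  if any(min(b, eb) - max(a, ea) >= need
                         for a, b in r.blocks))
        assert got == exp
    jb, jc = two_exon_gene.introns()[0]
    exp_j = sum(1 for r in reads if len(r.blocks) > 1
                and any(b1 == jb and a2 == jc
                        for (_, b1), (a2, _) in zip(r.blocks, r.blocks[1:])))
    assert st.junction_support == [exp_j]


def test_high_confidence_requires_trace_and_full_confirmation():
    t_ok = TracePattern("a", {})
    t_ok.category = "partial"
    t_un = TracePattern("b", {})
    t_un.category = "untraceable"
    from stratigraph.trace_validate import StructureStatus
    s_full = StructureStatus("x", 2, 2, status="fully-confirmed")
    s_part = StructureStatus("x", 2, 2, status="partially-confirmed")
    traces = {"a": t_ok, "b": t_un}
    statuses = {"a": s_full, "b": s_full}
    assert high_confidence_set(["a", "b"], traces, statuses) == ["a"]
    statuses["a"] = s_part
    assert high_confidence_set(["a", "b"], traces, statuses) == []


def test_planted_structure_statuses_recovered(structure_tsv, truth):
    exp = truth[(truth.species == "sp0")
                & (truth.expected_structure != "")]
    got = dict(zip(structure_tsv.gene_id, structure_tsv.status))
    for row in exp.itertuples():
        assert got[row.gene_id] == row.expected_structure, row.gene_id
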