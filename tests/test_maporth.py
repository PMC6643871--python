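"""Synteny chaining, orthologous-region extraction, and spliced
protein-to-genome alignment."""

import itertools
import random

import numpy as np
import pytest
from Bio.Seq import Seq

from stratigraph import maporth as mo
from stratigraph.core_model import GeneModel, compute_phases
from stratigraph.simulate import rand_orf, rand_seq


def _coords(order, contig="c", step=1000, strand="+"):
    return {g: (contig, i * step, i * step + 500, strand)
            for i, g in enumerate(order)}


def test_collinear_run_gives_one_block():
    pairs = [(f"a{i}", f"b{i}") for i in range(5)]
    blocks = mo.find_synteny_blocks(pairs,
                                    _coords([p[0] for p in pairs]),
                                    _coords([p[1] for p in pairs]))
    assert len(blocks) == 1
    assert blocks[0].anchors == pairs
    assert blocks[0].orientation == "+"


def test_inverted_gene_excluded_from_chain():
    pairs = [(f"a{i}", f"b{i}") for i in range(7)]
    coords_b = _coords([p[1] for p in pairs])
    # move b3 far out of order: it cannot sit in the increasing chain
    coords_b["b3"] = ("c", 99_000, 99_500, "-")
    blocks = mo.find_synteny_blocks(pairs,
                                    _coords([p[0] for p in pairs]), coords_b)
    assert ("a3", "b3") not in blocks[0].anchors
    assert len(blocks[0].anchors) == 6


def test_lis_against_exhaustive_oracle():
    rng = random.Random(0)
    for _ in range(20):
        n = rng.randint(4, 10)
        perm = list(range(n))
        rng.shuffle(perm)
        got = len(mo._lis_indices(perm))
        best = max(len(sub) for r in range(1, n + 1)
                   for sub in itertools.combinations(perm, r)
                   if all(a < b for a, b in zip(sub, sub[1:])))
        assert got == best


def test_synteny_symmetry():
    pairs = [(f"a{i}", f"b{i}") for i in range(6)]
    ca = _coords([p[0] for p in pairs])
    cb = _coords([p[1] for p in pairs][::-1])  # inverted order in B
    ab = mo.find_synteny_blocks(pairs, ca, cb, "A", "B")
    ba = mo.find_synteny_blocks([(b, a) for a, b in pairs], cb, ca, "B", "A")
    assert len(ab) == len(ba) == 1
    assert ab[0].orientation == ba[0].orientation == "-"
    assert sorted(ab[0].anchors) == sorted((a, b) for b, a in ba[0].anchors)


def test_orthologous_region_between_anchors():
    pairs = [("a0", "b0"), ("a1", "b1"), ("a2", "b2")]
    ca, cb = _coords(["a0", "a1", "a2"]), _coords(["b0", "b1", "b2"])
    blocks = mo.find_synteny_blocks(pairs, ca, cb, "A", "B")
    r = mo.orthologous_region(("c", 600, 900), blocks, ca, cb)
    assert isinstance(r, mo.OrthologousRegion)
    assert (r.start, r.end) == (500, 1000)  # between b0 end and b1 start
    edge = mo.orthologous_region(("c", 2600, 2700), blocks, ca, cb)
    assert isinstance(edge, mo.NoOrthologousRegion)


def test_orthologous_intron_same_index():
    exons_h = [(0, 60), (100, 160), (400, 460)]
    host = GeneModel("h", "sp0", "c1", "+", exons_h,
                     compute_phases(exons_h, "+"))
    exons_o = [(10, 70), (120, 180), (1580, 1640)]  # intron 2 is 1.4 kb
    orth = GeneModel("o", "sp1", "c9", "+", exons_o,
                     compute_phases(exons_o, "+"))
    assert mo.intron_index_containing(host, 200, 300) == 1
    r = mo.orthologous_intron(host, 1, orth)
    assert (r.contig, r.start, r.end) == ("c9", 180, 1580)
    assert r.end - r.start == 1400
    missing = mo.orthologous_intron(host, 5, orth)
    assert isinstance(missing, mo.NoOrthologousRegion)


# --- spliced alignment -----------------------------------------------------

@pytest.fixture()
def gene_window():
    rng = np.random.default_rng(4)
    cds = rand_orf(rng, 40)
    exon1, exon2 = cds[:60], cds[60:]
    intron = "GT" + rand_seq(rng, 46) + "AG"
    window = rand_seq(rng, 80) + exon1 + intron + exon2 + rand_seq(rng, 80)
    from stratigraph.simulate import protein_of
    return protein_of(cds), window, (80, 140), (190, 190 + len(exon2))


def test_self_mapping_reproduces_exon_structure(gene_window):
    prot, window, e1, e2 = gene_window
    m = mo.spliced_align("q", prot, window)
    assert not m.is_empty and m.strand == "+"
    spans = sorted(s.genomic_interval for s in m.segments)
    # the terminal stop codon is not part of the protein
    assert spans[0] == e1
    assert spans[1][0] == e2[0] and abs(spans[1][1] - (e2[1] - 3)) <= 3


def test_strand_symmetry_of_spliced_alignment(gene_window):
    prot, window, e1, e2 = gene_window
    rc = str(Seq(window).reverse_complement())
    m = mo.spliced_align("q", prot, rc)
    assert not m.is_empty and m.strand == "-"
    L = len(window)
    spans = sorted((L - b, L - a) for a, b in
                   (s.genomic_interval for s in m.segments))
    assert spans[0] == e1


def test_window_cap_is_enforced():
    with pytest.raises(ValueError, match="cap"):
        mo.spliced_align("q", "MKVL", "A" * (mo.MAX_SPLICED_WINDOW + 1))


def test_chain_score_matches_exhaustive_oracle():
    rng = np.random.default_rng(9)
    window = rand_seq(rng, 400)
    segs = []
    for _ in range(10):
        qa = int(rng.integers(0, 60))
        qb = qa + int(rng.integers(5, 25))
        ga = int(rng.integers(0, 350))
        gb = ga + 3 * (qb - qa)
        segs.append(mo.MapSegment((qa, qb), (ga, min(gb, 400)), 1,
                                  float(rng.integers(26, 80))))
    params = mo.SplicedAlignParams()
    chain, got = mo.chain_segments(segs, window, params)

    def link(a, b):
        if b.protein_interval[0] < a.protein_interval[1]:
            return None
        gap = b.genomic_interval[0] - a.genomic_interval[1]
        if gap < 0:
            return None
        if gap >= mo.MIN_INTRON:
            lo, hi = a.genomic_interval[1], b.genomic_interval[0]
            if window[lo:lo + 2] == "GT" and window[hi - 2:hi] == "AG":
                return params.splice_bonus
            return -params.noncanonical_penalty
        return -2.0

    best = 0.0
    order = sorted(range(len(segs)),
                   key=lambda i: (segs[i].protein_interval[0],
                                  segs[i].genomic_interval[0]))
    for r in range(1, len(segs) + 1):
        for combo in itertools.combinations(order, r):
            total = segs[combo[0]].score
            ok = True
            for i, j in zip(combo, combo[1:]):
                lk = link(segs[i], segs[j])
                if lk is None:
                    ok = False
                    break
                total += segs[j].score + lk
            if ok:
                best = max(best, total)
    assert got == pytest.approx(best)


def test_planted_ortholog_intervals_recovered(ctx, dataset, truth):
    """The simulator's conserved neighborhoods come back as synteny
    blocks covering nearly all conserved genes, and a planted
    orthologous interval is recovered within +-50 bp."""
    conserved = set(truth[(truth.species == "sp0")
                          & (truth.true_class == "Conserved")].gene_id)
    anchored = {a for b in ctx.synteny["sp1"] for a, _ in b.anchors}
    assert len(anchored & conserved) >= 0.9 * len(conserved)
    # the intergenic de novo plant: region between the same anchors
    import json
    row = truth[truth.gene_id == "sp1_region_dn_intergenic"].iloc[0]
    contig, ra, rb = json.loads(row.ortho_intervals)["sp1"]
    g = next(x for x in dataset.genes["sp0"]
             if x.gene_id == "sp0_mech_dn_intergenic")
    r = mo.orthologous_region((g.contig, g.start, g.end),
                              ctx.synteny["sp1"], ctx.coords("sp0"),
                              ctx.coords("sp1"))
    assert isinstance(r, mo.OrthologousRegion)
    # the extracted interval spans the planted region, padded by at most
    # one intergenic spacer on either side
    assert ra - 500 <= r.start <= ra and rb <= r.end <= rb + 500
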