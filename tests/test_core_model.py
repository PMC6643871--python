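"""Gene models, coordinate conventions, and format round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stratigraph.core_model import (GeneModel, SpeciesTree, blocks_from_cigar,
                                    compute_phases, ladder_newick,
                                    read_annotation, write_annotation,
                                    write_fasta)


# --- species tree ----------------------------------------------------------

def test_ladder_indices_on_pure_ladder():
    tree = SpeciesTree(ladder_newick(10), focal="sp0")
    assert [tree.ladder_index(f"sp{k}") for k in range(10)] == list(range(10))
    assert tree.non_focal() == [f"sp{k}" for k in range(1, 10)]


def test_path_length_increases_along_ladder():
    tree = SpeciesTree(ladder_newick(6, 0.01), focal="sp0")
    d = [tree.path_length("sp0", f"sp{k}") for k in range(1, 6)]
    assert all(a < b for a, b in zip(d, d[1:]))


@pytest.mark.parametrize("newick,focal,msg", [
    ("(a:1,b:1,c:1);", "a", "unrooted"),
    ("((a:1,a:1):1,b:1);", "a", "duplicate"),
    ("((a:1,b:1):1,c:1);", "zz", "not present"),
])
def test_tree_errors_name_the_problem(newick, focal, msg):
    with pytest.raises(ValueError, match=msg):
        SpeciesTree(newick, focal)


# --- CIGAR -----------------------------------------------------------------

def test_spliced_cigar_blocks():
    # 30M200N40M at 0-based position 100
    blocks = blocks_from_cigar(100, [(0, 30), (3, 200), (0, 40)])
    assert blocks == [(100, 130), (330, 370)]


def test_short_deletion_stays_in_block_long_one_splits():
    assert blocks_from_cigar(0, [(0, 10), (2, 5), (0, 10)]) == [(0, 25)]
    assert blocks_from_cigar(0, [(0, 10), (2, 50), (0, 10)]) == \
        [(0, 10), (60, 70)]


def test_clips_consume_no_reference():
    assert blocks_from_cigar(10, [(4, 5), (0, 20), (5, 3)]) == [(10, 30)]


def test_unknown_cigar_op_is_an_error():
    with pytest.raises(ValueError, match="CIGAR"):
        blocks_from_cigar(0, [(11, 5)])


# --- gene models and GFF3 --------------------------------------------------

def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return str(p)


def test_minus_strand_two_exon_translation(tmp_path):
    # hand-built fixture: transcription-order CDS = ATG AAA TTT GGG TAA,
    # exon1 = ATGAAATTT, exon2 = GGGTAA, gene on the minus strand
    from Bio.Seq import Seq
    exon1, exon2 = "ATGAAATTT", "GGGTAA"
    intron = "CTTTTTTTTTTTTTTTTTTTTTAC"  # revcomp(GT..AG)
    contig = ("CCCCC" + str(Seq(exon2).reverse_complement()) + intron
              + str(Seq(exon1).reverse_complement()) + "CCCCC")
    e_left = (5, 11)                      # revcomp(exon2)
    e_right = (11 + len(intron), 11 + len(intron) + 9)  # revcomp(exon1)
    cds = compute_phases([e_left, e_right], "-")
    gene = GeneModel("g1", "spX", "c1", "-", [e_left, e_right], cds)
    assert gene.protein(contig) == "MKFG"
    write_fasta({"c1": contig}, tmp_path / "g.fasta")
    gff = write_annotation([gene])
    models = read_annotation(_write(tmp_path, "g.gff3", gff),
                             str(tmp_path / "g.fasta"), species="spX")
    assert len(models) == 1
    assert models[0].protein(contig) == "MKFG"


def test_malformed_cds_flagged_and_excluded(tmp_path, caplog):
    contig = "ATGAAAT" + "C" * 20
    write_fasta({"c1": contig}, tmp_path / "m.fasta")
    gene = GeneModel("bad", "spX", "c1", "+", [(0, 7)], [(0, 7, 0)])
    gff = write_annotation([gene])
    with caplog.at_level("WARNING", logger="stratigraph"):
        models = read_annotation(_write(tmp_path, "m.gff3", gff),
                                 str(tmp_path / "m.fasta"))
    assert models == []
    assert any("malformed" in r.message for r in caplog.records)


def test_cds_outside_contig_is_hard_error(tmp_path):
    write_fasta({"c1": "ATGAAATAA"}, tmp_path / "s.fasta")
    gene = GeneModel("g", "spX", "c1", "+", [(0, 300)], [(0, 300, 0)])
    with pytest.raises(ValueError, match="exceed"):
        read_annotation(_write(tmp_path, "s.gff3", write_annotation([gene])),
                        str(tmp_path / "s.fasta"))


def test_gff3_round_trip_is_byte_identical(run_dir, dataset):
    for sp in ("sp0", "sp3"):
        path = run_dir / "dataset" / sp / "annotation.gff3"
        models = read_annotation(str(path),
                                 str(run_dir / "dataset" / sp / "genome.fasta"),
                                 species=sp)
        assert write_annotation(models) == path.read_text()


def test_translations_never_contain_internal_stop(dataset):
    for sp in dataset.species:
        contigs = dataset.genomes[sp]
        for g in dataset.genes[sp]:
            if not g.pseudo:
                assert "*" not in g.protein(contigs[g.contig]), g.gene_id


@settings(max_examples=500, derandomize=True)
@given(st.integers(0, 10 ** 7), st.integers(1, 10 ** 4))
def test_coordinate_round_trip(start, length):
    # internal 0-based half-open <-> GFF3 1-based inclusive
    end = start + length
    gff_start, gff_end = start + 1, end
    assert (gff_start - 1, gff_end) == (start, end)
    assert gff_end - (gff_start - 1) == length


def test_compute_phases_minus_strand():
    # two CDS pieces of 7 and 8 nt, minus strand: transcription starts at
    # the right piece (phase 0), the left piece starts mid-codon
    phased = compute_phases([(0, 7), (100, 108)], "-")
    assert phased == [(0, 7, (3 - 8 % 3) % 3), (100, 108, 0)]


def test_read_sam_matches_simulated_blocks(run_dir, reads, dataset):
    assert reads, "no reads parsed"
    spliced = [r for r in reads if r.is_spliced]
    assert spliced, "no spliced reads parsed"
    genes = {g.gene_id: g for g in dataset.genes["sp0"]}
    junctions = {j for g in genes.values() for j in g.introns()}
    hits = sum(1 for r in spliced
               for (a1, b1), (a2, b2) in zip(r.blocks, r.blocks[1:])
               if (b1, a2) in junctions)
    # spliced reads come from transcripts, so their gaps are real introns
    assert hits == sum(len(r.blocks) - 1 for r in spliced)
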