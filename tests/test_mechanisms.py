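"""Origin-mechanism detectors: frame-shift DP, exclusion rules, rescue
logic, de novo stop-codon extraction, and priority orchestration."""

import numpy as np
import pytest
from Bio.Seq import Seq

from stratigraph import mechanisms as mech
from stratigraph.simulate import rand_orf


# --- frame-shift DP --------------------------------------------------------

def _region_and_protein(rng, n_codons=60):
    cds = rand_orf(rng, n_codons + 1)[:-3]  # open frame, no terminal stop
    return cds


def test_single_insertion_switches_frame_once():
    rng = np.random.default_rng(0)
    region = _region_and_protein(rng)
    # the candidate protein reads frame 0 for 20 codons, then the +1
    # frame of the same region (as after a 1-nt insertion)
    p1 = str(Seq(region[:60]).translate())
    tail = region[61:]
    p2 = str(Seq(tail[:len(tail) - len(tail) % 3]).translate())
    protein = (p1 + p2).replace("*", "S")
    res = mech.detect_frame_shift(protein, region)
    assert res["status"] == "ok"
    assert res["n_switches"] == 1
    assert res["segments"][0]["frame"] == 0
    assert res["segments"][0]["codon_end"] == 20
    assert res["segments"][1]["frame"] == 1


def test_no_indel_means_single_frame():
    rng = np.random.default_rng(1)
    region = _region_and_protein(rng)
    protein = str(Seq(region).translate()).replace("*", "S")
    res = mech.detect_frame_shift(protein, region)
    assert res["n_switches"] == 0
    assert res["segments"][0]["frame"] == 0


def test_compensating_indels_return_to_frame_zero():
    rng = np.random.default_rng(2)
    region = _region_and_protein(rng)
    # codons 0-14 in frame 0, codons 15-29 in frame +1, then back
    pa = str(Seq(region[:45]).translate())
    pb = str(Seq(region[46:91]).translate())
    pc = str(Seq(region[90:90 + 3 * ((len(region) - 90) // 3)]).translate())
    protein = (pa + pb + pc).replace("*", "S")
    res = mech.detect_frame_shift(protein, region)
    frames = [s["frame"] for s in res["segments"]]
    assert res["n_switches"] == 2
    assert frames[0] == 0 and frames[-1] == 0 and frames[1] != 0


def test_short_region_is_insufficient():
    res = mech.detect_frame_shift("MKVLITAG", "ATG" * 6)
    assert res["status"] == "insufficient"


# --- de novo frame extraction ---------------------------------------------

def test_extracted_stops_equal_translate_and_scan(dataset, evidence):
    """Detector-reported stop positions equal a brute-force
    translate-and-scan of the emitted sister sequence."""
    per = evidence["sp0_mech_dn_intronic"]["evidence"]["per_species"]
    assert per["sp3"]["stop_codons"] == [31, 36]
    assert per["sp4"]["stop_codons"] == [11, 14]
    # oracle for sp4: slide the candidate's exons over the sister intron
    cand = next(g for g in dataset.genes["sp0"]
                if g.gene_id == "sp0_mech_dn_intronic")
    g0 = dataset.genomes["sp0"][cand.contig]
    host4 = next(g for g in dataset.genes["sp4"] if g.gene_id == "sp4_host")
    ia, ib = host4.introns()[1]
    intron4 = dataset.genomes["sp4"][host4.contig][ia:ib]
    stops = []
    codon_off = 0
    for (ea, eb) in cand.exons:
        exon = g0[ea:eb]
        best, off = -1, 0
        for o in range(len(intron4) - len(exon) + 1):
            m = sum(a == b for a, b in zip(exon, intron4[o:o + len(exon)]))
            if m > best:
                best, off = m, o
        aa = str(Seq(intron4[off:off + len(exon)]).translate())
        stops += [codon_off + i + 1 for i, c in enumerate(aa) if c == "*"]
        codon_off += len(exon) // 3
    assert per["sp4"]["stop_codons"] == [s for s in stops if s < codon_off]


def test_de_novo_birth_node_is_mrca_of_intact_species(evidence):
    ev = evidence["sp0_mech_dn_intronic"]["evidence"]
    assert ev["intact_in"] == ["sp1", "sp2"]
    assert ev["birth_node"] == 2
    assert ev["subtype"] == "intronic"
    ev2 = evidence["sp0_mech_dn_intergenic"]["evidence"]
    assert ev2["subtype"] == "intergenic"
    assert ev2["per_species"]["sp1"]["stop_codons"] == [4]
    assert evidence["sp0_mech_dn_intergenic"]["confidence"] == "weak"


# --- exclusion rules -------------------------------------------------------

def test_chimera_needs_two_distinct_sources(ctx):
    # an ordinary conserved two-exon gene: both exons hit one ortholog
    gene = ctx.focal_gene("sp0_cons00")
    assert mech.detect_chimera(gene, ctx) is None


def test_overprint_ignores_same_frame_duplicates(ctx):
    # the chimera candidate has same-frame transcript similarity to its
    # source genes' focal orthologs: not an overprint
    gene = ctx.focal_gene("sp0_mech_chimera")
    assert mech.detect_overprint(gene, ctx) is None


def test_overprint_fires_with_frame_pair_and_openness(ctx, evidence):
    call = mech.detect_overprint(ctx.focal_gene("sp0_mech_ovp"), ctx)
    assert call is not None and call.mechanism == "overprint"
    assert call.evidence["paralog"] == "sp0_ovpA"
    f1, f2 = call.evidence["frame_pair"]
    assert f1 != f2
    assert all(all(v.values())
               for v in call.evidence["orf_openness"].values())


def test_strand_switch_requires_antisense_exon(ctx):
    # de novo intronic gene: genomic hits are same-strand and intronic
    assert mech.detect_strand_switch(
        ctx.focal_gene("sp0_mech_dn_intronic"), ctx) is None
    call = mech.detect_strand_switch(ctx.focal_gene("sp0_mech_strand"), ctx)
    assert call is not None
    assert call.evidence["antisense_of"].endswith("_strG")
    assert call.evidence["frame"] < 0


def test_rescue_declines_genome_wide_discoverable_hits(ctx):
    # the intronic de novo region is discoverable by standard tblastn:
    # missing protein homology is not a search failure there
    assert mech.rescue_heuristic_failure(
        ctx.focal_gene("sp0_mech_dn_intronic"), ctx) is None
    call = mech.rescue_heuristic_failure(ctx.focal_gene("sp0_mech_heur"),
                                         ctx)
    assert call is not None
    assert call.reclassify_to == "TROG"
    assert call.reclassify_stratum == 1
    assert call.evidence["homolog"] == "sp1_mech_heur"


def test_gene_split_finds_partner_and_modifiers(ctx):
    call = mech.detect_gene_split(ctx.focal_gene("sp0_mech_split"), ctx)
    assert call is not None
    assert call.evidence["ancestral_gene"] == "sp1_splitA"
    assert call.evidence["complementary_gene"] == "sp0_splitB"
    assert set(call.modifiers) == {"de-novo-exon", "frame-shift"}
    assert call.evidence["mixed_origin"] is True
    # a gene mapping to a full-length ortholog is not a split product
    assert mech.detect_gene_split(ctx.focal_gene("sp0_cons00"), ctx) is None


# --- orchestration ---------------------------------------------------------

def test_exactly_one_primary_mechanism_per_gene(ctx, mechanisms_tsv):
    assert mechanisms_tsv.gene_id.is_unique
    assert set(mechanisms_tsv.mechanism) <= set(mech.PRIORITY) | \
        {"unresolved"}


def test_failed_revalidation_is_an_artifact(ctx):
    calls = mech.call_mechanisms(["sp0_ssog_partial"], ctx)
    assert calls["sp0_ssog_partial"].mechanism == "artifact"


def test_unexplained_candidate_is_unresolved(mechanisms_tsv):
    row = mechanisms_tsv[mechanisms_tsv.gene_id == "sp0_ssog_gap"]
    assert row.iloc[0].mechanism == "unresolved"


def test_reclassification_keeps_partition(final_classes):
    assert set(final_classes.final_class) <= {"Conserved", "TROG", "SSOG"}
    assert final_classes.gene_id.is_unique
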