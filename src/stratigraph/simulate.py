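"""Synthetic ladder-phylogeny dataset with planted gene classes and origin
mechanisms.

The generator stands in for a clade-genomics data set: ten small genomes on
a ladder-like phylogeny around a focal species, with conserved gene
families, taxon-restricted orphans (TROGs) born at chosen tree nodes,
species-specific orphans (SSOGs), and one exemplar of each origin
mechanism (chimera, gene split with de novo exon and frame shift, strand
switch, overprinting, heuristic search failure, de novo intronic, de novo
intergenic), plus pre-aligned spliced RNA-seq reads for the focal species
and a machine-readable ground-truth table.

Gene order is collinear across species (synteny is the backbone that the
orthologous-region machinery relies on).  Coding sequence evolves by
HKY-biased substitution with accept/reject steps that keep planted ORFs
open; coding regions carry no indels, and intergenic spacers are
independent random sequence per species (so they are unalignable unless a
homologous region is planted deliberately).  Divergence of the planted
failure-mode genes is calibrated against the package's own aligner so the
detectability thresholds are crossed where intended.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import homsearch as hs
from .core_model import GeneModel, compute_phases, ladder_newick, write_fasta

STOPS = {"TAA", "TAG", "TGA"}
BASES = "ACGT"
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

CONSERVED_STRATUM = -1  # placeholder replaced by n_species in truth rows


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study conditions for the synthetic dataset.

    Branch length is substitutions/site per ladder step; focal-to-species-k
    patristic distance is 2*k*branch_length.  Defaults keep conserved and
    taxon-restricted homologs comfortably above the search thresholds while
    the planted failure modes sit just past them.
    """

    n_species: int = 10
    branch_length: float = 0.01
    n_conserved: int = 60  # includes the named special families
    n_trog_per_stratum: int = 2
    n_ssog_untraceable: int = 4
    kappa: float = 2.0
    intergenic_len: int = 300
    read_length: int = 100
    coverage_depth: int = 5
    stranded: bool = True
    outgroup_extra_divergence: float = 0.06
    max_genome_length: int | None = None
    seed: int = 1

    def validate(self):
        for name in ("branch_length", "kappa", "intergenic_len",
                     "read_length", "coverage_depth",
                     "outgroup_extra_divergence"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_species < 2:
            raise ValueError("need at least two species")
        if self.n_conserved < 12:
            raise ValueError("n_conserved must cover the named families (>=12)")


# ---------------------------------------------------------------------------
# Sequence primitives
# ---------------------------------------------------------------------------

def rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def rand_codon(rng) -> str:
    while True:
        c = rand_seq(rng, 3)
        if c not in STOPS:
            return c


def rand_orf(rng, n_codons: int) -> str:
    """ATG + (n_codons-2) sense codons + TAA."""
    return "ATG" + "".join(rand_codon(rng) for _ in range(n_codons - 2)) + "TAA"


def _mutate_base(b: str, rng, kappa: float) -> str:
    if rng.random() < kappa / (kappa + 2.0):
        return TRANSITION[b]
    choices = [x for x in BASES if x != b and x != TRANSITION[b]]
    return choices[rng.integers(0, len(choices))]


def evolve_free(seq: str, t: float, rng, kappa: float = 2.0) -> str:
    n_sub = rng.poisson(len(seq) * t)
    s = list(seq)
    for _ in range(n_sub):
        p = rng.integers(0, len(s))
        s[p] = _mutate_base(s[p], rng, kappa)
    return "".join(s)


def evolve_cds(cds: str, t: float, rng, kappa: float = 2.0,
               extra_open_frames: tuple[int, ...] = ()) -> str:
    """HKY substitutions with accept/reject that keeps the frame-0 ORF
    open (start and stop codons protected) and, optionally, additional
    reading frames free of stop codons."""
    s = list(cds)
    n_sub = rng.poisson(len(s) * t)
    last = len(s) - 3
    for _ in range(n_sub):
        for _try in range(10):
            p = int(rng.integers(0, len(s)))
            if p < 3 or p >= last:  # protect ATG and terminal stop
                continue
            old = s[p]
            s[p] = _mutate_base(old, rng, kappa)
            c0 = (p // 3) * 3
            ok = "".join(s[c0:c0 + 3]) not in STOPS
            if ok:
                for f in extra_open_frames:
                    cf = ((p - f) // 3) * 3 + f
                    if 0 <= cf and cf + 3 <= len(s):
                        if "".join(s[cf:cf + 3]) in STOPS:
                            ok = False
                            break
            if ok:
                break
            s[p] = old
    return "".join(s)


def sanitize_frame(seq: str, offset: int, keep: set[int] | None = None) -> str:
    """Remove stop codons from the reading frame starting at ``offset``
    (codon indices in ``keep`` are left untouched)."""
    s = list(seq)
    i = 0
    while offset + 3 * i + 3 <= len(s):
        if keep and i in keep:
            i += 1
            continue
        a = offset + 3 * i
        if "".join(s[a:a + 3]) in STOPS:
            s[a + 2] = "C"
        i += 1
    return "".join(s)


def plant_stop(seq: str, offset: int, codon_idx: int, stop: str = "TAA") -> str:
    a = offset + 3 * codon_idx
    return seq[:a] + stop + seq[a + 3:]


def protein_of(cds: str) -> str:
    from Bio.Seq import Seq
    aa = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
    return aa[:-1] if aa.endswith("*") else aa


# ---------------------------------------------------------------------------
# Gene plans
# ---------------------------------------------------------------------------

@dataclass
class GeneSeq:
    """Exon/intron layout in transcription orientation; coding exons hold
    whole codons so introns fall on codon boundaries."""

    exons: list[str]
    introns: list[str]
    coding: list[bool]

    def cds(self) -> str:
        return "".join(e for e, c in zip(self.exons, self.coding) if c)

    def with_cds(self, cds: str) -> "GeneSeq":
        exons, pos = [], 0
        for e, c in zip(self.exons, self.coding):
            if c:
                exons.append(cds[pos:pos + len(e)])
                pos += len(e)
            else:
                exons.append(e)
        return GeneSeq(exons, list(self.introns), list(self.coding))


def evolve_gene(gs: GeneSeq, t: float, rng, kappa: float = 2.0,
                extra_open_frames: tuple[int, ...] = ()) -> GeneSeq:
    out = gs.with_cds(evolve_cds(gs.cds(), t, rng, kappa, extra_open_frames))
    out.exons = [e if c else evolve_free(e, t, rng, kappa)
                 for e, c in zip(out.exons, out.coding)]
    out.introns = [evolve_free(i, t, rng, kappa) for i in gs.introns]
    return out


def make_gene(rng, exon_codons: list[int], intron_lens: list[int],
              coding: list[bool] | None = None) -> GeneSeq:
    coding = coding or [True] * len(exon_codons)
    cds_codons = sum(n for n, c in zip(exon_codons, coding) if c)
    cds = rand_orf(rng, cds_codons)
    exons, pos = [], 0
    for n, c in zip(exon_codons, coding):
        if c:
            exons.append(cds[pos:pos + 3 * n])
            pos += 3 * n
        else:
            exons.append(rand_seq(rng, 3 * n))
    introns = [rand_seq(rng, ln) for ln in intron_lens]
    # canonical splice motifs help the spliced aligner reward real junctions
    introns = ["GT" + i[2:-2] + "AG" if len(i) >= 4 else i for i in introns]
    return GeneSeq(exons, introns, coding)


@dataclass
class PlannedGene:
    """One annotated (or deliberately unannotated) element at a locus,
    in body coordinates and transcription orientation."""

    gene_id: str
    body: str
    exon_spans: list[tuple[int, int]]
    cds_spans: list[tuple[int, int]]
    strand: str = "+"
    annotate: bool = True
    # genes physically nested inside this body (body coords, + orientation)
    children: list["PlannedGene"] = field(default_factory=list)

    @classmethod
    def from_geneseq(cls, gene_id: str, gs: GeneSeq, strand: str = "+",
                     annotate: bool = True) -> "PlannedGene":
        body, spans, cspans = "", [], []
        for i, ex in enumerate(gs.exons):
            s = len(body)
            body += ex
            spans.append((s, s + len(ex)))
            if gs.coding[i]:
                cspans.append((s, s + len(ex)))
            if i < len(gs.introns):
                body += gs.introns[i]
        return cls(gene_id, body, spans, cspans, strand, annotate)

    def transcript(self) -> str:
        return "".join(self.body[a:b] for a, b in self.exon_spans)

    def cds(self) -> str:
        return "".join(self.body[a:b] for a, b in self.cds_spans)

    def protein(self) -> str:
        return protein_of(self.cds())


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    config: SimConfig
    tree_newick: str
    focal: str
    species: list[str]
    genomes: dict[str, dict[str, str]]
    genes: dict[str, list[GeneModel]]
    proteins: dict[str, dict[str, str]]
    transcripts: dict[str, dict[str, str]]
    transcriptome: dict[str, dict[str, str]]
    outgroup_proteins: dict[str, str]
    outgroup_genome: dict[str, str]
    uniprot_like: dict[str, str]
    sam_text: str
    truth: pd.DataFrame


# ---------------------------------------------------------------------------
# The simulator
# ---------------------------------------------------------------------------

def _spine_seqs(gs: GeneSeq, birth: int, cfg: SimConfig, rng,
                extra_frames: tuple[int, ...] = ()) -> dict[str, GeneSeq]:
    """Evolve a family born at ladder node ``birth`` down to its carrier
    tips sp0..sp{birth}.  Node j is the MRCA of sp0 and spj."""
    bl = cfg.branch_length
    node = {birth: gs}
    for j in range(birth, 1, -1):
        node[j - 1] = evolve_gene(node[j], bl, rng, cfg.kappa, extra_frames)
    tips = {"sp0": evolve_gene(node[1], bl, rng, cfg.kappa, extra_frames)}
    for j in range(1, birth + 1):
        tips[f"sp{j}"] = evolve_gene(node[j], bl * j, rng, cfg.kappa,
                                     extra_frames)
    tips["_deepest_node"] = node[birth]
    return tips


def _walk_into_window(cds: str, ref_proteins: list[str],
                      window: tuple[float, float], rng, kappa: float,
                      region: tuple[int, int] | None = None,
                      floor_refs: list[str] | None = None,
                      query_slice: tuple[int, int] | None = None,
                      max_steps: int = 4000) -> str:
    """Descend the alignment score into ``window`` by single
    substitutions.

    The ceiling is enforced on the max score over ``ref_proteins``; the
    floor on the max over ``floor_refs`` (default: the same set).  A
    mutation is accepted only while the floor holds and the ceiling
    score does not rise, so the walk cannot jump far past either bound;
    overshooting mutations are simply retried elsewhere.
    """
    ceil_encs = [hs.encode_protein(r) for r in ref_proteins]
    floor_encs = ([hs.encode_protein(r) for r in floor_refs]
                  if floor_refs is not None else ceil_encs)

    def scores_of(c: str) -> tuple[int, int]:
        p = protein_of(c)
        if query_slice is not None:
            p = p[query_slice[0]:query_slice[1]]
        aa = hs.encode_protein(p)
        ceil = max(hs._sw_score(aa, ref, hs.BLOSUM62, 11, 1)[0]
                   for ref in ceil_encs)
        if floor_encs is ceil_encs:
            return ceil, ceil
        floor = max(hs._sw_score(aa, ref, hs.BLOSUM62, 11, 1)[0]
                    for ref in floor_encs)
        return ceil, floor

    lo, hi = window
    a, b = region or (3, len(cds) - 3)
    cur = cds
    ceil, floor = scores_of(cur)
    for _ in range(max_steps):
        if ceil <= hi and floor >= lo:
            return cur
        if floor < lo:  # started below the window: restart at the source
            cur = cds
            ceil, floor = scores_of(cds)
            continue
        p = int(rng.integers(a, b))
        old = cur[p]
        new = _mutate_base(old, rng, kappa)
        cand = cur[:p] + new + cur[p + 1:]
        c0 = (p // 3) * 3
        if cand[c0:c0 + 3] in STOPS:
            continue
        c2, f2 = scores_of(cand)
        if f2 >= lo and c2 <= ceil:
            cur, ceil, floor = cand, c2, f2
    return cur


def _dual_orf_transcript(rng, n_codons: int) -> tuple[str, int, int]:
    """A transcript whose frame-0 ORF spans it fully and whose frame-2
    ORF (ATG..stop) is open over nearly its whole length.

    Returns (sequence, cds2_start, cds2_end).
    """
    n = 3 * n_codons
    while True:
        s = list(rand_orf(rng, n_codons))
        # frame-2 ATG at codon 1 and stop near the end
        s[5:8] = "ATG"
        stop_at = 3 * (n_codons - 3) + 2
        s[stop_at:stop_at + 3] = "TAA"
        seq = "".join(s)
        ok = True
        for i in range(1, n_codons - 1):
            if seq[3 * i:3 * i + 3] in STOPS:
                ok = False
                break
        if ok:
            for j in range((stop_at - 5) // 3):
                c = seq[5 + 3 * j:8 + 3 * j]
                if c in STOPS:
                    ok = False
                    break
        if ok:
            return seq, 5, stop_at + 3


def simulate_dataset(cfg: SimConfig | None = None) -> Dataset:
    cfg = cfg or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_species
    species = [f"sp{k}" for k in range(n)]
    newick = ladder_newick(n, cfg.branch_length)

    def gs2(codons=None, introns=None, coding=None):
        codons = codons or [int(rng.integers(22, 31)), int(rng.integers(18, 27))]
        introns = introns or [int(rng.integers(50, 71))]
        return make_gene(rng, codons, introns, coding)

    # ---- family construction (order fixed for determinism) ---------------
    truth_rows: list[dict] = []
    # loci: list of (locus_id, {species: PlannedGene}, meta)
    loci: list[tuple[str, dict[str, PlannedGene]]] = []
    fam_meta: dict[str, dict] = {}

    def plan_family(fam: str, tips: dict[str, GeneSeq], carriers: list[str],
                    strand: str) -> dict[str, PlannedGene]:
        return {sp: PlannedGene.from_geneseq(f"{sp}_{fam}", tips[sp], strand)
                for sp in carriers}

    named_cons = ["host", "ovpA", "chimX", "chimY", "strG", "splitA",
                  "c2a", "c2b", "hgta", "hgtb"]
    n_plain = cfg.n_conserved - len(named_cons)
    cons_ids = [f"cons{i:02d}" for i in range(n_plain)] + named_cons

    cons_tips: dict[str, dict[str, GeneSeq]] = {}
    for fam in cons_ids:
        if fam == "host":
            root = make_gene(rng, [24, 20, 22], [55, 300])
        elif fam == "splitA":
            root = make_gene(rng, [20, 15, 15], [55, 60])
        elif fam in ("c2a", "c2b", "hgta", "hgtb"):
            # these must clear the stricter translated-search threshold
            # for every ingroup species, so give them more codons
            root = make_gene(rng, [40, 38], [int(rng.integers(50, 71))])
        elif fam == "ovpA":
            seq, c2s, c2e = _dual_orf_transcript(rng, 60)
            root = GeneSeq([seq[:90], seq[90:]], [rand_seq(rng, 60)],
                           [True, True])
            root.introns = ["GT" + root.introns[0][2:-2] + "AG"]
            fam_meta["ovpA"] = {"cds2": (c2s, c2e)}
        else:
            root = gs2()
        extra = (2,) if fam == "ovpA" else ()
        cons_tips[fam] = _spine_seqs(root, n - 1, cfg, rng, extra)
    # outgroup copies, evolved beyond the deepest ingroup node (computed
    # here so the planted failure modes can calibrate against them too)
    og_tips = {fam: evolve_gene(cons_tips[fam]["_deepest_node"],
                                cfg.outgroup_extra_divergence, rng,
                                cfg.kappa)
               for fam in cons_ids}

    trog_tips: dict[str, dict[str, GeneSeq]] = {}
    trog_ids = []
    for k in range(1, n):
        for i in range(cfg.n_trog_per_stratum):
            fam = f"trog{k}_{i}"
            trog_ids.append((fam, k))
            trog_tips[fam] = _spine_seqs(gs2(), k, cfg, rng)

    # ---- mechanism plants -------------------------------------------------
    sp1 = "sp1"

    # chimera: two exons calibrated so that, against every carrier copy
    # of the source exon, the score sits between the whole-protein
    # classification ceiling and the per-exon detection floor
    CHIMERA_WINDOW = (52, 60)  # floor: per-exon detectability against
    # the pooled ingroup; ceiling: whole-protein classification safety

    def family_proteins(fam: str) -> tuple[list[str], list[str]]:
        """(ingroup full proteins, ingroup + outgroup full proteins)."""
        ingroup = [protein_of(cons_tips[fam][sp].cds()) for sp in species
                   if sp != "sp0"]
        return ingroup, ingroup + [protein_of(og_tips[fam].cds())]

    in_x, all_x = family_proteins("chimX")
    in_y, all_y = family_proteins("chimY")
    chim_e1 = cons_tips["chimX"][sp1].exons[1]
    chim_e2 = cons_tips["chimY"][sp1].exons[0][3:]  # drop the source ATG
    chim_cds = sanitize_frame("ATG" + chim_e1 + chim_e2 + "TAA", 0)
    n1 = 3 + len(chim_e1)
    nc = len(chim_cds) // 3
    # calibrate each exon exactly as the detector scores it: the exon's
    # slice of the candidate protein against full-length source proteins
    chim_cds = _walk_into_window(chim_cds, all_x, CHIMERA_WINDOW, rng,
                                 cfg.kappa, region=(3, n1),
                                 floor_refs=in_x,
                                 query_slice=(0, n1 // 3))
    chim_cds = _walk_into_window(chim_cds, all_y, CHIMERA_WINDOW, rng,
                                 cfg.kappa, region=(n1, len(chim_cds) - 3),
                                 floor_refs=in_y,
                                 query_slice=(n1 // 3, nc))
    chim_gs = GeneSeq([chim_cds[:n1], chim_cds[n1:]],
                      ["GT" + rand_seq(rng, 50) + "AG"], [True, True])

    # gene split: focal candidate = splitA exon1 + 1-nt insertion (frame
    # shift) + a de novo exon; focal neighbour carries exons 2-3
    splitA_sp0 = cons_tips["splitA"]["sp0"]
    e1 = splitA_sp0.exons[0]
    shifted = e1[:24] + "A" + e1[24:]  # insertion at codon 8
    denovo_ex = rand_seq(rng, 44)
    split_cds = sanitize_frame(shifted + denovo_ex, 0)
    split_cds = split_cds[:-3] + "TAA"
    assert len(split_cds) % 3 == 0
    # keep the residual ancestral-frame similarity below the protein
    # search thresholds (the shifted exon may still echo the source)
    splitA_vars = [protein_of(cons_tips["splitA"][sp].cds())
                   for sp in species] + [protein_of(og_tips["splitA"].cds())]
    split_cds = _walk_into_window(split_cds, splitA_vars, (10, 55), rng,
                                  cfg.kappa, region=(3, len(shifted)))
    split_gs = GeneSeq([split_cds[:len(shifted)], split_cds[len(shifted):]],
                       ["GT" + rand_seq(rng, 48) + "AG"], [True, True])
    neigh_gs = GeneSeq([splitA_sp0.exons[1], splitA_sp0.exons[2]],
                       [splitA_sp0.introns[1]], [True, True])

    # strand switch: candidate ORF from the reverse strand of the strG
    # coding sequence (interior codons, so the ends stay unconstrained)
    from Bio.Seq import Seq as _Seq
    strg_src = cons_tips["strG"][sp1].cds()[3:-3]
    strg_rc = str(_Seq(strg_src).reverse_complement())
    sw = evolve_free(strg_rc, 0.05, rng, cfg.kappa)
    sw_cds = "ATG" + sanitize_frame(sw, 0)
    sw_cds = sw_cds[: 3 * (len(sw_cds) // 3) - 3] + "TAA"
    half = 3 * ((len(sw_cds) // 2) // 3)
    strand_gs = GeneSeq([sw_cds[:half], sw_cds[half:]],
                        ["GT" + rand_seq(rng, 46) + "AG"], [True, True])

    # overprint: duplicate of ovpA's focal transcript, annotated in frame 2
    ovp_src = cons_tips["ovpA"]["sp0"]
    ovp_dup = evolve_gene(ovp_src, 0.04, rng, cfg.kappa, extra_open_frames=(2,))
    c2s, c2e = fam_meta["ovpA"]["cds2"]
    ovp_plan_body = PlannedGene.from_geneseq("tmp", ovp_dup)
    t_dup = ovp_dup  # exon layout identical to source
    ex_l = len(t_dup.exons[0])

    def split_cds_spans(cs, ce, exon_lens, intron_lens):
        """Map transcript-coordinate CDS [cs,ce) onto body exon spans."""
        spans, tpos, bpos = [], 0, 0
        for i, el in enumerate(exon_lens):
            a, b = max(cs, tpos), min(ce, tpos + el)
            if a < b:
                spans.append((bpos + a - tpos, bpos + b - tpos))
            tpos += el
            bpos += el + (intron_lens[i] if i < len(intron_lens) else 0)
        return spans

    # heuristic failure: repeat-rich pair with a short unique core,
    # calibrated so the pair scores just past the standard search
    # thresholds (blastp 1e-3, tblastn 1e-5) but is recoverable from the
    # syntenic interval at the relaxed threshold
    core = rand_orf(rng, 24)[3:-3]  # 22 unique codons
    rep1 = "".join("GG" + BASES[i] for i in rng.integers(0, 4, size=6))
    rep2 = "".join("GG" + BASES[i] for i in rng.integers(0, 4, size=6))
    heur_sp1_cds = sanitize_frame("ATG" + rep1 + core + rep2 + "TAA", 0)
    heur_sp1_prot = protein_of(heur_sp1_cds)
    # a frame-nudging indel scrambles the repeat arms' translation while
    # leaving their DNA nearly identical (so the nucleotide trace
    # survives); only the core is mutated during score calibration
    r1m = "G" + rep1[:-1]
    heur_sp0_cds = sanitize_frame("ATG" + r1m + core + rep2 + "TAA", 0)
    core_region = (3 + len(r1m), 3 + len(r1m) + len(core))
    heur_sp0_cds = _walk_into_window(heur_sp0_cds, [heur_sp1_prot],
                                     (46, 54), rng, cfg.kappa,
                                     region=core_region)
    hh = 3 * ((len(heur_sp0_cds) // 2) // 3)
    heur_sp0 = GeneSeq([heur_sp0_cds[:hh], heur_sp0_cds[hh:]],
                       ["GT" + rand_seq(rng, 52) + "AG"], [True, True])
    hh1 = 3 * ((len(heur_sp1_cds) // 2) // 3)
    heur_sp1_gs = GeneSeq([heur_sp1_cds[:hh1], heur_sp1_cds[hh1:]],
                          ["GT" + rand_seq(rng, 52) + "AG"], [True, True])

    # de novo intronic: candidate inside host intron 2; sister introns are
    # controlled copies (intact near the focal species, stop-disrupted
    # beyond the planted birth node at ladder index 2)
    dni_cds = rand_orf(rng, 50)  # 60 nt exon1 + 90 nt exon2
    dni_gs = GeneSeq([dni_cds[:60], dni_cds[60:]],
                     ["GT" + rand_seq(rng, 46) + "AG"], [True, True])
    dni_plan = PlannedGene.from_geneseq("sp0_mech_dn_intronic", dni_gs)
    host_intron2 = (rand_seq(rng, 30) + dni_plan.body
                    + rand_seq(rng, 300 - 30 - len(dni_plan.body)))
    dni_off = 30  # candidate body offset inside the host intron

    def intron_variant(ladder: int) -> str:
        t = 0.03 if ladder <= 2 else (0.05 if ladder <= 4 else 0.10)
        v = evolve_free(host_intron2, t, rng, cfg.kappa)
        # candidate exon frames inside the intron copy
        off1 = dni_off
        off2 = dni_off + 60 + len(dni_gs.introns[0])
        v = sanitize_frame(v, off1)
        v = sanitize_frame(v, off2)
        if ladder <= 2:
            return v
        if ladder == 3:  # stops mid 2nd exon (global codons 30 and 35)
            v = plant_stop(v, off2, 10)
            v = plant_stop(v, off2, 15)
        elif ladder == 4:  # stops at codons 11 and 14 (1-based), exon 1
            v = plant_stop(v, off1, 10)
            v = plant_stop(v, off1, 13)
        else:
            v = plant_stop(v, off1, 5)
            v = plant_stop(v, off2, 8)
        return v

    # de novo intergenic: UTR exon + single coding exon; sp1 carries a
    # homologous non-transcribed region with an early stop (codon 4)
    dig_cds = rand_orf(rng, 40)
    dig_gs = GeneSeq([rand_seq(rng, 60), dig_cds],
                     ["GT" + rand_seq(rng, 46) + "AG"], [False, True])
    dig_plan = PlannedGene.from_geneseq("sp0_mech_dn_intergenic", dig_gs)
    dig_cds_off = dig_plan.cds_spans[0][0]
    dig_region = evolve_free(dig_plan.body, 0.05, rng, cfg.kappa)
    dig_region = sanitize_frame(dig_region, dig_cds_off)
    dig_region = plant_stop(dig_region, dig_cds_off, 3)  # codon 4, 1-based

    # plain SSOGs
    ssog_plans = {}
    for i in range(cfg.n_ssog_untraceable):
        ssog_plans[f"ssog_untrace{i}"] = gs2()
    ssog_plans["ssog_gap"] = gs2()
    ssog_plans["ssog_single"] = make_gene(rng, [40], [])
    ssog_plans["ssog_partial"] = gs2()
    ssog_plans["ssog_unconf"] = gs2()

    # ---- locus assembly ---------------------------------------------------
    strands = {}
    for fam in cons_ids:
        strands[fam] = "+" if fam in ("host", "strG", "splitA", "ovpA") else \
            ("+" if rng.random() < 0.5 else "-")

    def cons_locus(fam: str) -> tuple[str, dict[str, PlannedGene]]:
        plans = plan_family(fam, cons_tips[fam], species, strands[fam])
        if fam == "ovpA":  # annotated in frame 0 everywhere
            pass
        return (fam, plans)

    plain = [f"cons{i:02d}" for i in range(n_plain)]
    order: list[tuple[str, dict[str, PlannedGene]]] = []

    def add_cons_block(k):
        for fam in plain[add_cons_block.i:add_cons_block.i + k]:
            order.append(cons_locus(fam))
        add_cons_block.i += k
    add_cons_block.i = 0

    add_cons_block(4)
    # host (+ intronic candidate in focal, controlled introns in sisters)
    host_plans = {}
    for sp in species:
        gseq = cons_tips["host"][sp]
        k = species.index(sp)
        gseq = GeneSeq(list(gseq.exons), list(gseq.introns), list(gseq.coding))
        if sp == "sp0":
            gseq.introns[1] = host_intron2
        else:
            gseq.introns[1] = intron_variant(k)
        pg = PlannedGene.from_geneseq(f"{sp}_host", gseq, "+")
        if sp == "sp0":
            child = PlannedGene(
                "sp0_mech_dn_intronic", dni_plan.body,
                dni_plan.exon_spans, dni_plan.cds_spans, "+")
            ex2 = pg.exon_spans[1]
            intron2_start = ex2[1]
            child_off = intron2_start + dni_off
            child = PlannedGene(
                child.gene_id, pg.body,
                [(a + child_off, b + child_off) for a, b in dni_plan.exon_spans],
                [(a + child_off, b + child_off) for a, b in dni_plan.cds_spans],
                "+")
            pg.children.append(child)
        host_plans[sp] = pg
    order.append(("host", host_plans))
    add_cons_block(4)

    # chimera sources and candidate
    order.append(cons_locus("chimX"))
    add_cons_block(2)
    order.append(cons_locus("chimY"))
    order.append(("mech_chimera",
                  {"sp0": PlannedGene.from_geneseq("sp0_mech_chimera",
                                                   chim_gs, "+")}))
    add_cons_block(4)

    # split family: intact in sisters, two genes in focal
    split_plans = plan_family("splitA", cons_tips["splitA"],
                              [s for s in species if s != "sp0"], "+")
    order.append(("mech_split",
                  {"sp0": PlannedGene.from_geneseq("sp0_mech_split",
                                                   split_gs, "+")}))
    order.append(("splitA",
                  {**split_plans,
                   "sp0": PlannedGene.from_geneseq("sp0_splitB", neigh_gs,
                                                   "+")}))
    add_cons_block(4)

    # strand switch next to its source
    order.append(cons_locus("strG"))
    order.append(("mech_strand",
                  {"sp0": PlannedGene.from_geneseq("sp0_mech_strand",
                                                   strand_gs, "+")}))
    add_cons_block(4)

    # overprint pair: source everywhere, duplicate only in focal
    order.append(cons_locus("ovpA"))
    ovp_cds2 = split_cds_spans(c2s, c2e, [len(t_dup.exons[0]),
                                          len(t_dup.exons[1])],
                               [len(t_dup.introns[0])])
    ovp_body = PlannedGene.from_geneseq("tmp", t_dup).body
    ovp_exspans = PlannedGene.from_geneseq("tmp", t_dup).exon_spans
    order.append(("mech_ovp",
                  {"sp0": PlannedGene("sp0_mech_ovp", ovp_body, ovp_exspans,
                                      ovp_cds2, "+")}))
    add_cons_block(4)

    # heuristic failure inside a conserved syntenic run
    order.append(("mech_heur",
                  {"sp0": PlannedGene.from_geneseq("sp0_mech_heur",
                                                   heur_sp0, "+"),
                   "sp1": PlannedGene.from_geneseq("sp1_mech_heur",
                                                   heur_sp1_gs, "+")}))
    add_cons_block(4)

    # de novo intergenic with its planted sp1 region
    order.append(("mech_dn_intergenic",
                  {"sp0": dig_plan,
                   "sp1": PlannedGene("sp1_region_dn_intergenic", dig_region,
                                      [], [], "+", annotate=False)}))
    add_cons_block(4)

    # TROGs interleaved with remaining conserved anchors
    for fam, k in trog_ids:
        carriers = [f"sp{j}" for j in range(k + 1)]
        order.append((fam, plan_family(fam, trog_tips[fam], carriers,
                                       "+" if rng.random() < 0.5 else "-")))
        if add_cons_block.i < n_plain:
            add_cons_block(1)

    # plain SSOGs and the remaining conserved anchors
    for name, gseq in ssog_plans.items():
        order.append((name, {"sp0": PlannedGene.from_geneseq(
            f"sp0_{name}", gseq, "+")}))
        if add_cons_block.i < n_plain:
            add_cons_block(1)
    add_cons_block(n_plain - add_cons_block.i)

    # step-2 / step-3 conserved exemplars at the end
    for fam in ("c2a", "c2b", "hgta", "hgtb"):
        order.append(cons_locus(fam))

    # ---- genome assembly --------------------------------------------------
    genomes: dict[str, dict[str, str]] = {}
    genes: dict[str, list[GeneModel]] = {sp: [] for sp in species}
    proteins: dict[str, dict[str, str]] = {sp: {} for sp in species}
    transcripts: dict[str, dict[str, str]] = {sp: {} for sp in species}
    gene_intervals: dict[str, dict[str, tuple[str, int, int]]] = {}

    est_len = sum(len(p["sp0"].body) if "sp0" in p else 0 for _, p in order) \
        + cfg.intergenic_len * (len(order) + 1)
    if cfg.max_genome_length is not None and est_len > cfg.max_genome_length:
        raise ValueError(
            f"configured genes need ~{est_len} bp > max_genome_length "
            f"{cfg.max_genome_length}; nothing was written")

    def place(pg: PlannedGene, contig: str, off: int, sp: str):
        L = len(pg.body)
        if pg.strand == "+":
            ex = [(off + a, off + b) for a, b in pg.exon_spans]
            cd = [(off + a, off + b) for a, b in pg.cds_spans]
        else:
            ex = sorted((off + L - b, off + L - a) for a, b in pg.exon_spans)
            cd = sorted((off + L - b, off + L - a) for a, b in pg.cds_spans)
        if pg.annotate:
            gm = GeneModel(gene_id=pg.gene_id, species=sp, contig=contig,
                           strand=pg.strand, exons=ex,
                           cds=compute_phases(cd, pg.strand))
            genes[sp].append(gm)
            proteins[sp][pg.gene_id] = pg.protein()
            transcripts[sp][pg.gene_id + ".t1"] = pg.transcript()
        gene_intervals.setdefault(pg.gene_id, {})[sp] = (
            contig, off, off + L)

    for sp in species:
        contig = f"{sp}_chr1"
        parts = []
        pos = 0
        for locus_id, plans in order:
            spacer = rand_seq(rng, int(rng.integers(cfg.intergenic_len - 50,
                                                    cfg.intergenic_len + 51)))
            parts.append(spacer)
            pos += len(spacer)
            if sp in plans:
                pg = plans[sp]
                body = pg.body if pg.strand == "+" else \
                    str(_Seq(pg.body).reverse_complement())
                place(pg, contig, pos, sp)
                for child in pg.children:
                    place(child, contig, pos, sp)
                parts.append(body)
                pos += len(body)
        parts.append(rand_seq(rng, cfg.intergenic_len))
        genomes[sp] = {contig: "".join(parts)}
        genes[sp].sort(key=lambda g: (g.contig, g.start, g.gene_id))

    # ---- transcriptome assemblies ----------------------------------------
    transcriptome = {sp: dict(transcripts[sp]) for sp in species}
    gap_hom = evolve_free(ssog_plans["ssog_gap"].cds(), 0.05, rng, cfg.kappa)
    transcriptome["sp1"]["asm_gap_homolog"] = gap_hom

    # ---- outgroup databases ----------------------------------------------
    og_prot, og_genome_parts, uni = {}, [rand_seq(rng, 2000)], {}
    for fam in cons_ids:
        pg = PlannedGene.from_geneseq(f"og_{fam}", og_tips[fam])
        if fam in ("c2a", "c2b"):
            og_genome_parts.append(pg.body)
            og_genome_parts.append(rand_seq(rng, 800))
        elif fam in ("hgta", "hgtb"):
            uni[f"uni_{fam}"] = pg.protein()
        else:
            og_prot[f"og_{fam}"] = pg.protein()
    for i in range(5):
        uni[f"uni_decoy{i}"] = protein_of(rand_orf(rng, 80))
    # decoy outgroup proteins: give the outgroup database a realistic
    # search-space size, so its E-values are on the same footing as the
    # pooled ingroup searches
    for i in range(100):
        og_prot[f"og_decoy{i:03d}"] = protein_of(
            rand_orf(rng, int(rng.integers(220, 320))))
    og_genome = {"og_chr1": "".join(og_genome_parts) + rand_seq(rng, 2000)}

    # ---- focal RNA-seq ----------------------------------------------------
    sam_text = _make_sam(cfg, genomes["sp0"], genes["sp0"], rng)

    # ---- ground truth -----------------------------------------------------
    mech_expect = {
        "mech_chimera": ("chimera", "partial-or-better", "fully-confirmed"),
        "mech_split": ("gene-split", "partial-or-better", "fully-confirmed"),
        "mech_strand": ("strand-switch", "partial-or-better", "fully-confirmed"),
        "mech_ovp": ("overprint", "all-three", "fully-confirmed"),
        "mech_heur": ("heuristic-failure", "partial-or-better",
                      "fully-confirmed"),
        "mech_dn_intronic": ("de-novo", "partial", "fully-confirmed"),
        "mech_dn_intergenic": ("de-novo", "partial", "fully-confirmed"),
    }
    for sp in species:
        k = species.index(sp)
        for g in genes[sp]:
            fam = g.gene_id.split("_", 1)[1]
            if fam in cons_ids or fam == "splitB":
                cls, stratum = "Conserved", n
            elif fam.startswith("trog"):
                birth = int(fam[4:].split("_")[0])
                cls, stratum = "TROG", birth
            else:
                cls, stratum = "SSOG", 0
            final_cls = cls
            mech, trace, struct = "none", "", ""
            if sp == "sp0":
                if fam in mech_expect:
                    mech, trace, struct = mech_expect[fam]
                    if fam == "mech_heur":
                        final_cls, stratum = "TROG", 1
                elif fam.startswith("ssog_untrace"):
                    trace, struct = "untraceable", "fully-confirmed"
                elif fam == "ssog_gap":
                    trace, struct = "assembly-gap-candidate", "fully-confirmed"
                elif fam == "ssog_single":
                    trace, struct = "untraceable", "single-exon-excluded"
                elif fam == "ssog_partial":
                    trace, struct = "untraceable", "partially-confirmed"
                elif fam == "ssog_unconf":
                    trace, struct = "untraceable", "unconfirmed"
            if fam == "mech_heur" and sp == "sp1":
                cls = final_cls = "SSOG"
            intervals = {s: list(v) for s, v in
                         sorted(gene_intervals.get(g.gene_id, {}).items())}
            # for family members, orthologous intervals live under family ids
            fam_int = {}
            for s2 in species:
                gid2 = f"{s2}_{fam}"
                if gid2 in gene_intervals and s2 in gene_intervals[gid2]:
                    fam_int[s2] = list(gene_intervals[gid2][s2])
            truth_rows.append(dict(
                gene_id=g.gene_id, species=sp, family=fam, true_class=cls,
                final_class=final_cls, phylostratum=stratum, mechanism=mech,
                expected_trace=trace, expected_structure=struct,
                ortho_intervals=json.dumps(fam_int or intervals,
                                           sort_keys=True)))
    # the planted non-coding region of the intergenic de novo gene
    truth_rows.append(dict(
        gene_id="sp1_region_dn_intergenic", species="sp1",
        family="mech_dn_intergenic", true_class="region",
        final_class="region", phylostratum=-1, mechanism="none",
        expected_trace="", expected_structure="",
        ortho_intervals=json.dumps(
            {s: list(v) for s, v in
             gene_intervals["sp1_region_dn_intergenic"].items()},
            sort_keys=True)))
    truth = pd.DataFrame(truth_rows).sort_values(
        ["species", "gene_id"]).reset_index(drop=True)

    return Dataset(
        config=cfg, tree_newick=newick, focal="sp0", species=species,
        genomes=genomes, genes=genes, proteins=proteins,
        transcripts=transcripts, transcriptome=transcriptome,
        outgroup_proteins=og_prot, outgroup_genome=og_genome,
        uniprot_like=uni, sam_text=sam_text, truth=truth)


# ---------------------------------------------------------------------------
# Read simulation (pre-aligned SAM)
# ---------------------------------------------------------------------------

def _transcript_to_genomic(gene: GeneModel, ts: int, te: int
                           ) -> list[tuple[int, int]]:
    """Map a transcript interval to genomic blocks (ascending)."""
    exons = gene.exons if gene.strand == "+" else gene.exons[::-1]
    blocks, tpos = [], 0
    for a, b in exons:
        ln = b - a
        s, e = max(ts, tpos), min(te, tpos + ln)
        if s < e:
            if gene.strand == "+":
                blocks.append((a + s - tpos, a + e - tpos))
            else:
                blocks.append((b - (e - tpos), b - (s - tpos)))
        tpos += ln
    return sorted(blocks)


def _make_sam(cfg: SimConfig, genome: dict[str, str],
              gene_list: list[GeneModel], rng) -> str:
    rl, depth = cfg.read_length, cfg.coverage_depth
    records = []
    counter = 0

    def emit(gene: GeneModel, ts: int, te: int):
        nonlocal counter
        blocks = _transcript_to_genomic(gene, ts, te)
        if not blocks or sum(b - a for a, b in blocks) < 20:
            return
        contig = gene.contig
        seq = "".join(genome[contig][a:b] for a, b in blocks)
        cig = []
        for i, (a, b) in enumerate(blocks):
            if i:
                cig.append(f"{a - blocks[i - 1][1]}N")
            cig.append(f"{b - a}M")
        flag = 0 if gene.strand == "+" else 16
        records.append((contig, blocks[0][0],
                        f"r{counter:06d}", flag, "".join(cig), seq))
        counter += 1

    for gene in gene_list:
        fam = gene.gene_id.split("_", 1)[1]
        tlen = sum(b - a for a, b in gene.exons)
        if fam == "ssog_unconf":
            continue
        if fam == "ssog_partial":
            # exons covered, but a single junction-spanning read
            exons_t = []
            tpos = 0
            ex_iter = gene.exons if gene.strand == "+" else gene.exons[::-1]
            for a, b in ex_iter:
                exons_t.append((tpos, tpos + b - a))
                tpos += b - a
            for (ta, tb) in exons_t:
                for _ in range(3):
                    emit(gene, ta, min(tb, ta + rl))
            j = exons_t[0][1]
            emit(gene, max(0, j - 30), min(tlen, j + 30))
            continue
        step = max(1, rl // (depth + 2))
        for s in range(-rl + step, tlen, step):
            emit(gene, max(0, s), min(tlen, s + rl))

    records.sort(key=lambda r: (r[0], r[1], r[2]))
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for contig in sorted(genome):
        lines.append(f"@SQ\tSN:{contig}\tLN:{len(genome[contig])}")
    for contig, pos, rid, flag, cig, seq in records:
        lines.append("\t".join([
            rid, str(flag), contig, str(pos + 1), "60", cig, "*", "0", "0",
            seq, "*"]))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# On-disk layout
# ---------------------------------------------------------------------------

def write_dataset(ds: Dataset, outdir: str) -> None:
    import os

    from .core_model import write_annotation
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "tree.nwk"), "w") as fh:
        fh.write(ds.tree_newick + "\n")
    with open(os.path.join(outdir, "focal.txt"), "w") as fh:
        fh.write(ds.focal + "\n")
    for sp in ds.species:
        d = os.path.join(outdir, sp)
        os.makedirs(d, exist_ok=True)
        write_fasta(ds.genomes[sp], os.path.join(d, "genome.fasta"))
        with open(os.path.join(d, "annotation.gff3"), "w") as fh:
            fh.write(write_annotation(ds.genes[sp]))
        write_fasta(ds.proteins[sp], os.path.join(d, "proteins.fasta"))
        write_fasta(ds.transcripts[sp], os.path.join(d, "transcripts.fasta"))
        write_fasta(ds.transcriptome[sp],
                    os.path.join(d, "transcriptome.fasta"))
    write_fasta(ds.outgroup_proteins,
                os.path.join(outdir, "outgroup_proteins.fasta"))
    write_fasta(ds.outgroup_genome,
                os.path.join(outdir, "outgroup_genome.fasta"))
    write_fasta(ds.uniprot_like, os.path.join(outdir, "uniprot_like.fasta"))
    with open(os.path.join(outdir, "sp0", "rnaseq.sam"), "w") as fh:
        fh.write(ds.sam_text)
    ds.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
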