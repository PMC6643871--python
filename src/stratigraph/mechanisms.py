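"""Automated detectors for the origin mechanisms of species-specific
orphan genes (SSOGs).

Each detector formalizes one narrative of orphan-gene birth: chimeric
assembly of exons from distinct source genes, gene splitting with de novo
exon gain and reading-frame shifts, strand switching onto the antisense
frame of an existing exon, overprinting (an alternative same-strand ORF
of a duplicated gene), failure of the thresholded homology search
(rescued by an exhaustive search of the syntenic interval), and de novo
birth from ancestrally non-coding sequence (diagnosed by stop codons in
the orthologous frame of outgroup species).  Detectors run in a fixed
priority order — artifact screen, then search-failure rescue, then
divergence-based mechanisms, then de novo — so that artifacts and missed
homologies are excluded before any evolutionary claim, and mechanisms
that retain ancestral frame/strand evidence outrank de novo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import homsearch as hs
from . import maporth as mo
from .core_model import GeneModel, SpeciesTree, SpliceReadAlignment
from .trace_validate import StructureParams, validate_structure

PRIORITY = ("artifact", "heuristic-failure", "overprint", "chimera",
            "gene-split", "strand-switch", "frame-shift", "de-novo")

STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class MechanismCall:
    gene_id: str
    mechanism: str  # one of PRIORITY, or 'unresolved'
    confidence: str = "supported"  # 'supported' | 'weak'
    modifiers: list[str] = field(default_factory=list)  # 'mixed origin' parts
    evidence: dict = field(default_factory=dict)
    reclassify_to: str | None = None  # 'TROG' after a rescue
    reclassify_stratum: int | None = None


@dataclass
class MechanismContext:
    """Everything the detectors need, precomputed once per run."""

    tree: SpeciesTree
    genomes: dict[str, dict[str, str]]
    genes: dict[str, dict[str, GeneModel]]  # species -> id -> model
    proteins: dict[str, dict[str, str]]
    transcripts: dict[str, dict[str, str]]
    transcriptome: dict[str, dict[str, str]]
    reads: list[SpliceReadAlignment]
    stranded: bool = True
    synteny: dict[str, list[mo.SyntenyBlock]] = field(default_factory=dict)
    rbh: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    structure_params: StructureParams = field(default_factory=StructureParams)

    @property
    def focal(self) -> str:
        return self.tree.focal

    def sisters(self) -> list[str]:
        return self.tree.non_focal()

    def focal_gene(self, gid: str) -> GeneModel:
        return self.genes[self.focal][gid]

    def coords(self, species: str) -> mo.GeneCoords:
        return {g.gene_id: (g.contig, g.start, g.end, g.strand)
                for g in self.genes[species].values()}

    def contig_seq(self, species: str, contig: str) -> str:
        return self.genomes[species][contig]

    def gene_protein(self, species: str, gid: str) -> str:
        return self.proteins[species][gid]

    def gene_at(self, species: str, contig: str, start: int, end: int,
                exonic: bool = True) -> GeneModel | None:
        """Annotated gene whose exons (or span) overlap [start, end)."""
        for g in self.genes[species].values():
            if g.contig != contig:
                continue
            if exonic:
                if any(max(a, start) < min(b, end) for a, b in g.exons):
                    return g
            elif max(g.start, start) < min(g.end, end):
                return g
        return None


def _unseeded(p: hs.SearchParams) -> hs.SearchParams:
    p.use_seeding = False
    return p


def _exon_proteins(gene: GeneModel, genome: str) -> list[str]:
    """Per coding exon, the translation of that exon's CDS portion in the
    gene's own frame."""
    cds_parts = []
    order = gene.cds if gene.strand == "+" else gene.cds[::-1]
    pos = 0
    out = []
    for a, b, _p in order:
        seq = genome[a:b]
        if gene.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        lead = (3 - pos % 3) % 3  # bases completing the previous codon
        sub = seq[lead:]
        sub = sub[: len(sub) - len(sub) % 3]
        aa = str(Seq(sub).translate()).replace("*", "") if sub else ""
        out.append(aa)
        pos += b - a
        cds_parts.append(seq)
    return out


# ---------------------------------------------------------------------------
# Individual detectors
# ---------------------------------------------------------------------------

def detect_chimera(gene: GeneModel, ctx: MechanismContext,
                   exon_evalue: float = 0.05) -> MechanismCall | None:
    """Fires when >=2 exons align to exons of *distinct* source genes in
    other species (per-exon search sidesteps the length-driven E-value
    failure of the whole-protein search) and no single gene covers the
    whole protein."""
    if len(gene.coding_exons) < 2:
        return None
    genome = ctx.contig_seq(ctx.focal, gene.contig)
    exon_aas = [aa for aa in _exon_proteins(gene, genome) if len(aa) >= 8]
    if len(exon_aas) < 2:
        return None
    params = _unseeded(hs.SearchParams.protein(exon_evalue))
    n_pool = sum(len(s) for sp in ctx.sisters()
                 for s in ctx.proteins[sp].values())
    # distinct sources must be distinct genes of the SAME species:
    # orthologs across species carry different ids but are one source
    best_call = None
    for sp in ctx.sisters():
        db = sorted(ctx.proteins[sp].items())
        if not db:
            continue
        per_exon = []
        for i, aa in enumerate(exon_aas):
            hits = hs.search([(f"exon{i}", aa)], db, params,
                             n_override=n_pool)
            per_exon.append(hits[0] if hits else None)
        sources = {h.subject_id for h in per_exon if h is not None}
        n_hit = sum(1 for h in per_exon if h is not None)
        if n_hit < 2 or len(sources) < 2:
            continue
        combined = sum(math.log(h.e_value) for h in per_exon
                       if h is not None)
        if best_call is None or combined < best_call[0]:
            best_call = (combined, sp, per_exon, sources)
    if best_call is None:
        return None
    _, sp, per_exon, sources = best_call
    return MechanismCall(
        gene.gene_id, "chimera",
        evidence={"species": sp, "sources": sorted(sources),
                  "per_exon": [
                      None if h is None else
                      {"source": h.subject_id,
                       "identity": round(h.pct_identity, 1),
                       "e_value": h.e_value}
                      for h in per_exon]})


def detect_gene_split(gene: GeneModel, ctx: MechanismContext
                      ) -> MechanismCall | None:
    """Fires when the gene maps (same strand, nucleotide level) to a
    terminal part of a sister-species gene while an adjacent focal gene
    maps to the complementary part."""
    tx = ctx.transcripts[ctx.focal].get(gene.gene_id + ".t1")
    if tx is None:
        return None
    nucl = _unseeded(hs.SearchParams.nucl())
    best = None
    best_sp = None
    for sp in ctx.sisters():
        db = sorted(ctx.transcripts[sp].items())
        if not db:
            continue
        hits = [h for h in hs.search([(gene.gene_id, tx)], db, nucl)
                if h.subject_strand == "+"]
        if hits and (best is None or hits[0].e_value < best.e_value):
            best, best_sp = hits[0], sp
    if best is None:
        return None
    subj_tx = ctx.transcripts[best_sp][best.subject_id]
    L = len(subj_tx)
    ss, se = best.subject_interval
    is_prefix = ss <= 0.1 * L and se <= 0.7 * L
    is_suffix = ss >= 0.3 * L and se >= 0.9 * L
    if not (is_prefix or is_suffix):
        return None
    # complementary coverage by an adjacent focal gene
    focal_genes = sorted(ctx.genes[ctx.focal].values(),
                         key=lambda g: (g.contig, g.start))
    idx = next(i for i, g in enumerate(focal_genes)
               if g.gene_id == gene.gene_id)
    neighbors = [g for g in focal_genes[max(0, idx - 1):idx + 2]
                 if g.gene_id != gene.gene_id and g.contig == gene.contig]
    partner = None
    for nb in neighbors:
        ntx = ctx.transcripts[ctx.focal].get(nb.gene_id + ".t1")
        if ntx is None:
            continue
        nh = [h for h in hs.search(
            [(nb.gene_id, ntx)],
            [(best.subject_id, subj_tx)], nucl) if h.subject_strand == "+"]
        if not nh:
            continue
        ns, ne = nh[0].subject_interval
        rem = (se, L) if is_prefix else (0, ss)
        cover = max(0, min(ne, rem[1]) - max(ns, rem[0]))
        if rem[1] > rem[0] and cover >= 0.5 * (rem[1] - rem[0]):
            partner = nb.gene_id
            break
    subj_gene_id = best.subject_id.removesuffix(".t1")
    call = MechanismCall(
        gene.gene_id, "gene-split",
        confidence="supported" if partner else "weak",
        evidence={"ancestral_gene": subj_gene_id, "species": best_sp,
                  "part": "prefix" if is_prefix else "suffix",
                  "subject_interval": list(best.subject_interval),
                  "complementary_gene": partner})
    # modifiers: de novo exons and frame shifts over the shared part
    genome = ctx.contig_seq(ctx.focal, gene.contig)
    exon_nucl = _unseeded(hs.SearchParams.nucl())
    for i, (a, b) in enumerate(gene.exons):
        ex = genome[a:b]
        if gene.strand == "-":
            ex = str(Seq(ex).reverse_complement())
        dbs = sorted(ctx.transcripts[best_sp].items()) + \
            sorted(ctx.genomes[best_sp].items())
        if not hs.search([(f"ex{i}", ex)], dbs, exon_nucl):
            call.modifiers.append("de-novo-exon")
    subj_gene = ctx.genes[best_sp].get(subj_gene_id)
    if subj_gene is not None:
        subj_cds = subj_gene.coding_sequence(
            ctx.contig_seq(best_sp, subj_gene.contig))
        prot = ctx.gene_protein(ctx.focal, gene.gene_id)
        fs = detect_frame_shift(prot, subj_cds if is_prefix
                                else subj_cds[ss - ss % 3:])
        if fs["status"] == "ok" and fs["n_switches"] >= 1:
            call.modifiers.append("frame-shift")
            call.evidence["frame_shift"] = fs
    if call.modifiers:
        call.evidence["mixed_origin"] = True
    return call


def detect_frame_shift(protein: str, orthologous_cds: str,
                       switch_penalty: float = 8.0,
                       min_codons: int = 10) -> dict:
    """Per-column best-frame assignment of a protein against the three
    same-strand frames of an orthologous coding sequence.

    Assumes rough collinearity (residue i sits near nucleotide 3*i+f);
    a small-state DP with a frame-switch penalty segments the protein
    into frame runs, exposing the indels implicated at each switch.
    """
    n = len(protein)
    usable = [i for i in range(n)
              if 3 * i + 2 + 3 <= len(orthologous_cds)]
    if len(usable) < min_codons:
        return {"status": "insufficient", "frames": [], "n_switches": 0,
                "segments": []}
    m = len(usable)
    emis = np.full((m, 3), -4.0)
    pidx = hs.encode_protein(protein)
    for c, i in enumerate(usable):
        for f in range(3):
            a = 3 * i + f
            codon = orthologous_cds[a:a + 3]
            if len(codon) < 3:
                continue
            aa = "*" if codon in STOPS else str(Seq(codon).translate())
            emis[c, f] = hs.BLOSUM62[pidx[i], hs._P_INDEX.get(aa, 22)]
    dp = np.zeros((m, 3))
    bp = np.zeros((m, 3), dtype=int)
    dp[0] = emis[0]
    for c in range(1, m):
        for f in range(3):
            cand = dp[c - 1] - switch_penalty * (np.arange(3) != f)
            bp[c, f] = int(np.argmax(cand))
            dp[c, f] = emis[c, f] + cand[bp[c, f]]
    frames = np.zeros(m, dtype=int)
    frames[-1] = int(np.argmax(dp[-1]))
    for c in range(m - 1, 0, -1):
        frames[c - 1] = bp[c, frames[c]]
    segments = []
    start = 0
    for c in range(1, m + 1):
        if c == m or frames[c] != frames[c - 1]:
            segments.append({"codon_start": usable[start] + 1,  # 1-based
                             "codon_end": usable[c - 1] + 1,
                             "frame": int(frames[c - 1])})
            start = c
    return {"status": "ok", "frames": frames.tolist(),
            "n_switches": len(segments) - 1, "segments": segments}


def detect_strand_switch(gene: GeneModel, ctx: MechanismContext,
                         min_score: float = 45.0
                         ) -> MechanismCall | None:
    """Fires when the best relaxed translated hit in a sister genome is
    antisense to the annotated gene whose exon it overlaps.

    The score floor keeps chance alignments out: at a relaxed E-value a
    genome-wide search always returns short noise alignments, which are
    never antisense *evidence* however they fall.
    """
    prot = ctx.gene_protein(ctx.focal, gene.gene_id)
    params = _unseeded(hs.relaxed(hs.SearchParams.translated()))
    best = None
    best_sp = None
    for sp in ctx.sisters():
        db = sorted(ctx.genomes[sp].items())
        hits = [h for h in hs.search([(gene.gene_id, prot)], db, params)
                if h.raw_score >= min_score]
        if hits and (best is None or hits[0].e_value < best.e_value):
            best, best_sp = hits[0], sp
    if best is None:
        return None
    s, e = best.subject_interval
    subj_gene = ctx.gene_at(best_sp, best.subject_id, s, e, exonic=True)
    if subj_gene is None or best.subject_strand == subj_gene.strand:
        return None
    return MechanismCall(
        gene.gene_id, "strand-switch",
        confidence="supported" if best.e_value <= 1e-3 else "weak",
        evidence={"species": best_sp, "antisense_of": subj_gene.gene_id,
                  "frame": best.subject_frame,
                  "subject_interval": [s, e],
                  "e_value": best.e_value})


def _orf_open(seq: str, frame: int, start: int, end: int) -> bool:
    a = start + (frame - start) % 3
    while a + 3 <= end:
        if seq[a:a + 3] in STOPS:
            return False
        a += 3
    return True


def detect_overprint(gene: GeneModel, ctx: MechanismContext,
                     min_identity: float = 70.0,
                     min_query_coverage: float = 0.5
                     ) -> MechanismCall | None:
    """Fires for a within-species transcript paralog whose annotated ORF
    sits in a different same-strand frame, with both frames open in both
    copies.

    The paralog must look like a recent duplicate — high nucleotide
    identity over most of the transcript — not a short local repeat.
    """
    focal = ctx.focal
    tx = ctx.transcripts[focal].get(gene.gene_id + ".t1")
    if tx is None:
        return None
    db = sorted((k, v) for k, v in ctx.transcripts[focal].items()
                if k != gene.gene_id + ".t1")
    if not db:
        return None
    nucl = _unseeded(hs.SearchParams.nucl())
    hits = [h for h in hs.search([(gene.gene_id, tx)], db, nucl)
            if h.subject_strand == "+"
            and h.pct_identity >= min_identity
            and (h.query_interval[1] - h.query_interval[0])
            >= min_query_coverage * len(tx)]
    if not hits:
        return None
    h = hits[0]
    para_id = h.subject_id.removesuffix(".t1")
    para = ctx.genes[focal].get(para_id)
    if para is None:
        return None
    para_tx = ctx.transcripts[focal][h.subject_id]

    def cds_start_in_tx(g: GeneModel) -> int:
        ex = g.exons if g.strand == "+" else g.exons[::-1]
        cds = g.cds_spans()
        c0 = (min(s for s, _ in cds) if g.strand == "+"
              else max(e for _, e in cds))
        t = 0
        for a, b in ex:
            if g.strand == "+":
                if a <= c0 < b:
                    return t + c0 - a
            else:
                if a < c0 <= b:
                    return t + b - c0
            t += b - a
        return 0

    qs, qe = h.query_interval
    ss, se = h.subject_interval
    qc = cds_start_in_tx(gene)
    pc = cds_start_in_tx(para)
    frame_q = (qc - qs) % 3
    frame_p = (pc - ss) % 3
    if frame_q == frame_p:
        return None  # ordinary duplicate
    # openness is judged on the shared interior: the terminal stop codons
    # of either annotated ORF are not evidence of closure
    trim = 9

    def window(a, b):
        return a + 3, max(a + 3, b - trim)
    openness = {
        "candidate": {
            f"frame{frame_q}": _orf_open(tx, qs + frame_q, *window(qs, qe)),
            f"frame{frame_p}": _orf_open(tx, qs + frame_p, *window(qs, qe))},
        "paralog": {
            f"frame{frame_q}": _orf_open(para_tx, ss + frame_q,
                                         *window(ss, se)),
            f"frame{frame_p}": _orf_open(para_tx, ss + frame_p,
                                         *window(ss, se))},
    }
    weak = not openness["paralog"][f"frame{frame_q}"]
    return MechanismCall(
        gene.gene_id, "overprint",
        confidence="weak" if weak else "supported",
        evidence={"paralog": para_id, "frame_pair": [frame_q, frame_p],
                  "identity": round(h.pct_identity, 1),
                  "e_value": h.e_value, "orf_openness": openness})


def rescue_heuristic_failure(gene: GeneModel, ctx: MechanismContext,
                             pad: int = 500) -> MechanismCall | None:
    """Full (unseeded) local search of the syntenic interval at the
    relaxed threshold; fires when it recovers a homologous segment that
    overlaps an unpaired annotated sister gene and that the standard
    genome-wide searches could not have found.  A firing rescue
    reclassifies the SSOG as a TROG."""
    prot = ctx.gene_protein(ctx.focal, gene.gene_id)
    coords_f = ctx.coords(ctx.focal)
    relaxed_t = _unseeded(hs.relaxed(hs.SearchParams.translated()))
    std_t = _unseeded(hs.SearchParams.translated())
    for sp in ctx.sisters():
        blocks = ctx.synteny.get(sp, [])
        region = mo.orthologous_region(
            (gene.contig, gene.start, gene.end), blocks,
            coords_f, ctx.coords(sp))
        if isinstance(region, mo.NoOrthologousRegion):
            continue
        seq_full = ctx.contig_seq(sp, region.contig)
        a = max(0, region.start - pad)
        b = min(len(seq_full), region.end + pad)
        hits = hs.search([(gene.gene_id, prot)],
                         [(region.contig, seq_full[a:b])], relaxed_t)
        if not hits:
            continue
        h = hits[0]
        s, e = h.subject_interval[0] + a, h.subject_interval[1] + a
        subj_gene = ctx.gene_at(sp, region.contig, s, e, exonic=True)
        if subj_gene is None or h.subject_strand != subj_gene.strand:
            continue
        paired = {b_ for _, b_ in ctx.rbh.get(sp, [])}
        if subj_gene.gene_id in paired:
            continue  # the sister gene already has a focal ortholog
        # would the standard genome-wide search have found this?
        gw = hs.search([(gene.gene_id, prot)],
                       sorted(ctx.genomes[sp].items()), std_t)
        if gw:
            continue  # not a heuristic failure: discoverable genome-wide
        return MechanismCall(
            gene.gene_id, "heuristic-failure",
            evidence={"species": sp, "homolog": subj_gene.gene_id,
                      "interval": [s, e], "score": h.raw_score,
                      "e_value_in_interval": h.e_value},
            reclassify_to="TROG",
            reclassify_stratum=ctx.tree.ladder_index(sp))
    return None


# ---------------------------------------------------------------------------
# De novo detection
# ---------------------------------------------------------------------------

def _candidate_regions(gene: GeneModel, ctx: MechanismContext
                       ) -> tuple[str, dict[str, mo.OrthologousRegion]]:
    """Orthologous regions per sister species, via the host intron when
    the gene is intronic, else via flanking synteny anchors."""
    focal = ctx.focal
    host = None
    for g in ctx.genes[focal].values():
        if g.gene_id == gene.gene_id or g.contig != gene.contig:
            continue
        idx = mo.intron_index_containing(g, gene.start, gene.end)
        if idx is not None:
            host = (g, idx)
            break
    coords_f = ctx.coords(focal)
    regions = {}
    if host is not None:
        hostg, idx = host
        for sp in ctx.sisters():
            orth_id = dict(ctx.rbh.get(sp, [])).get(hostg.gene_id)
            if orth_id is None:
                continue
            r = mo.orthologous_intron(hostg, idx, ctx.genes[sp][orth_id])
            if isinstance(r, mo.OrthologousRegion):
                regions[sp] = r
        return "intronic", regions
    for sp in ctx.sisters():
        r = mo.orthologous_region((gene.contig, gene.start, gene.end),
                                  ctx.synteny.get(sp, []), coords_f,
                                  ctx.coords(sp))
        if isinstance(r, mo.OrthologousRegion):
            regions[sp] = r
    return "intergenic", regions


def cds_segments(gene: GeneModel, genome: str) -> list[tuple[int, str]]:
    """(codon offset, sequence) per CDS interval, transcription order."""
    order = gene.cds if gene.strand == "+" else gene.cds[::-1]
    out, pos = [], 0
    for a, b, _p in order:
        seq = genome[a:b]
        if gene.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        out.append((pos // 3, seq))
        pos += b - a
    return out


def extract_orthologous_frame(segments: list[tuple[int, str]],
                              region_seq: str,
                              min_segment_score: int = 30) -> dict:
    """Align each CDS segment of a candidate to an orthologous region
    (one strand for all segments) and read off the region's sequence in
    the candidate's frame.

    Aligning per coding exon keeps short first exons from being dropped
    when the region still carries the candidate's intron.  Returns
    status 'unalignable', or 'intact'/'disrupted' with internal stop
    positions in 1-based codon units, plus the codon-aligned row
    ('---' where unaligned) for downstream selection analysis.
    """
    n_codons = sum(len(s) // 3 for _, s in segments)
    last_codon = max(off + len(s) // 3 for off, s in segments)
    best = None
    for strand in ("+", "-"):
        seq = region_seq if strand == "+" else \
            str(Seq(region_seq).reverse_complement())
        total = 0
        maps = []
        for off, part in segments:
            score, _q, _s, qmap = hs.sw_map(part, seq, nucl=True)
            if score >= min_segment_score:
                total += score
                maps.append((off, part, qmap))
        if best is None or total > best[0]:
            best = (total, strand, maps, seq)
    total, strand, maps, seq = best
    if total <= 0 or not maps:
        return {"status": "unalignable", "score": int(total)}
    stops = []
    aligned = 0
    row = ["---"] * n_codons
    for off, part, qmap in maps:
        for i in range(len(part) // 3):
            js = [qmap[3 * i + k] for k in range(3)]
            if any(j < 0 for j in js) or js[2] - js[0] != 2:
                continue
            aligned += 1
            codon = seq[js[0]:js[0] + 3]
            global_codon = off + i
            if codon in STOPS:
                if global_codon < last_codon - 1:
                    stops.append(global_codon + 1)  # 1-based
            else:
                row[global_codon] = codon
    if aligned < 0.3 * n_codons:
        return {"status": "unalignable", "score": int(total)}
    return {"status": "disrupted" if stops else "intact",
            "stop_codons": stops, "aligned_codons": aligned,
            "score": int(total), "strand": strand,
            "codon_row": "".join(row)}


def _transcribed(region: mo.OrthologousRegion, ctx: MechanismContext
                 ) -> bool | None:
    """Any transcriptome evidence overlapping the region (None =
    unknown: no transcriptome for that species)."""
    db = ctx.transcriptome.get(region.species)
    if db is None:
        return None
    seq = ctx.contig_seq(region.species, region.contig)[
        region.start:region.end]
    if len(seq) < 30:
        return False
    hits = hs.search([("region", seq)], sorted(db.items()),
                     _unseeded(hs.SearchParams.nucl()))
    return bool(hits)


def detect_de_novo(gene: GeneModel, ctx: MechanismContext
                   ) -> MechanismCall | None:
    """Fires when at least one sister species carries a disrupted (or
    unalignable) ORF in the orthologous region while the region aligns at
    the nucleotide level somewhere in the ingroup and shows no
    transcription; the birth node is the MRCA of the intact-ORF species."""
    subtype, regions = _candidate_regions(gene, ctx)
    if not regions:
        return None
    genome = ctx.contig_seq(ctx.focal, gene.contig)
    segments = cds_segments(gene, genome)
    per_species = {}
    transcribed_any = False
    unknown_transcription = False
    for sp in sorted(regions, key=ctx.tree.ladder_index):
        r = regions[sp]
        seq = ctx.contig_seq(sp, r.contig)[r.start:r.end]
        if not seq:
            per_species[sp] = {"status": "unalignable", "score": 0}
            continue
        res = extract_orthologous_frame(segments, seq)
        res.pop("codon_row", None)
        tr = _transcribed(r, ctx)
        if tr is None:
            unknown_transcription = True
        elif tr:
            transcribed_any = True
        res["transcribed"] = tr
        res["region"] = [r.contig, r.start, r.end]
        per_species[sp] = res
    statuses = {sp: d["status"] for sp, d in per_species.items()}
    alignable = [sp for sp, s in statuses.items() if s != "unalignable"]
    broken = [sp for sp, s in statuses.items()
              if s in ("disrupted", "unalignable")]
    if not alignable or not broken:
        return None
    intact = [sp for sp, s in statuses.items() if s == "intact"]
    if transcribed_any and not broken:
        return None
    birth = max((ctx.tree.ladder_index(sp) for sp in intact), default=0)
    weak = (len(alignable) <= 1) or unknown_transcription
    return MechanismCall(
        gene.gene_id, "de-novo",
        confidence="weak" if weak else "supported",
        evidence={"subtype": subtype, "birth_node": birth,
                  "per_species": per_species,
                  "intact_in": intact})


def detect_frame_shift_mech(gene: GeneModel, ctx: MechanismContext
                            ) -> MechanismCall | None:
    """Standalone frame-shift call: the protein aligns same-strand to an
    orthologous coding region but across multiple reading frames."""
    prot = ctx.gene_protein(ctx.focal, gene.gene_id)
    nucl = _unseeded(hs.SearchParams.nucl())
    tx = ctx.transcripts[ctx.focal].get(gene.gene_id + ".t1")
    if tx is None:
        return None
    for sp in ctx.sisters():
        db = sorted(ctx.transcripts[sp].items())
        if not db:
            continue
        hits = [h for h in hs.search([(gene.gene_id, tx)], db, nucl)
                if h.subject_strand == "+"]
        if not hits:
            continue
        subj_gene = ctx.genes[sp].get(hits[0].subject_id.removesuffix(".t1"))
        if subj_gene is None:
            continue
        cds = subj_gene.coding_sequence(ctx.contig_seq(sp, subj_gene.contig))
        fs = detect_frame_shift(prot, cds)
        if fs["status"] == "ok" and fs["n_switches"] >= 1 \
                and len({s["frame"] for s in fs["segments"]}) >= 2:
            return MechanismCall(
                gene.gene_id, "frame-shift",
                evidence={"species": sp, "ortholog": subj_gene.gene_id,
                          "frame_shift": fs})
        return None
    return None


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def call_mechanisms(high_confidence: list[str], ctx: MechanismContext
                    ) -> dict[str, MechanismCall]:
    """Run the detectors in priority order; the first supported call
    wins, with modifiers preserved ('mixed origin')."""
    calls: dict[str, MechanismCall] = {}
    for gid in sorted(high_confidence):
        gene = ctx.focal_gene(gid)
        # artifact screen: the structure must survive a re-validation
        st = validate_structure(gene, ctx.reads, ctx.stranded,
                                ctx.structure_params)
        if st.status != "fully-confirmed":
            calls[gid] = MechanismCall(gid, "artifact",
                                       evidence={"structure": st.status})
            continue
        detectors = (
            rescue_heuristic_failure,
            detect_overprint,
            detect_chimera,
            detect_gene_split,
            detect_strand_switch,
            detect_frame_shift_mech,
            detect_de_novo,
        )
        call = None
        for det in detectors:
            call = det(gene, ctx)
            if call is not None:
                break
        calls[gid] = call or MechanismCall(gid, "unresolved", "weak")
    return calls


def mechanisms_table(calls: dict[str, MechanismCall]) -> pd.DataFrame:
    rows = [dict(gene_id=g, mechanism=c.mechanism, confidence=c.confidence,
                 modifiers=",".join(c.modifiers),
                 reclassified_to=c.reclassify_to or "",
                 reclassified_stratum="" if c.reclassify_stratum is None
                 else c.reclassify_stratum)
            for g, c in sorted(calls.items())]
    return pd.DataFrame(rows)
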