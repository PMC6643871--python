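"""Synteny blocks, orthologous-region extraction, and simplified spliced
protein-to-genome alignment.

Synteny is found by chaining best-reciprocal protein hits that are
collinear on both genomes (longest-increasing-subsequence chaining of
anchor order).  The orthologous region of a focal locus is the interval
between the mapped flanking anchors (for an intronic locus, the
same-index intron of the mapped host ortholog).  Spliced alignment
chains six-frame local alignments with a bonus for canonical GT..AG
splice gaps; non-canonical gaps are allowed at a penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import homsearch as hs
from .core_model import GeneModel, HomologyHit

MIN_INTRON = 20


# ---------------------------------------------------------------------------
# Best-reciprocal anchors and collinear chaining
# ---------------------------------------------------------------------------

def best_reciprocal_pairs(hits_ab: list[HomologyHit],
                          hits_ba: list[HomologyHit]
                          ) -> list[tuple[str, str]]:
    best_ab = hs.best_hits_by_query(hits_ab)
    best_ba = hs.best_hits_by_query(hits_ba)
    pairs = []
    for a, h in best_ab.items():
        b = h.subject_id
        rb = best_ba.get(b)
        if rb is not None and rb.subject_id == a:
            pairs.append((a, b))
    return sorted(pairs)


@dataclass
class SyntenyBlock:
    species_a: str
    species_b: str
    contig_a: str
    contig_b: str
    orientation: str  # '+' collinear, '-' inverted
    anchors: list[tuple[str, str]]  # (gene_a, gene_b), ascending in a


def _lis_indices(seq: list[int]) -> list[int]:
    """Indices of one longest strictly increasing subsequence."""
    if not seq:
        return []
    best_len = [1] * len(seq)
    prev = [-1] * len(seq)
    for i in range(len(seq)):
        for j in range(i):
            if seq[j] < seq[i] and best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    end = max(range(len(seq)), key=lambda i: (best_len[i], -i))
    out = []
    while end != -1:
        out.append(end)
        end = prev[end]
    return out[::-1]


GeneCoords = dict[str, tuple[str, int, int, str]]  # id -> contig,start,end,strand


def find_synteny_blocks(pairs: list[tuple[str, str]],
                        coords_a: GeneCoords, coords_b: GeneCoords,
                        species_a: str = "A", species_b: str = "B",
                        min_anchors: int = 3) -> list[SyntenyBlock]:
    """Maximal collinear chains of best-reciprocal pairs, greedy LIS per
    contig pair, both orientations; blocks do not overlap on genome A."""
    by_contig: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for a, b in pairs:
        if a not in coords_a or b not in coords_b:
            continue
        key = (coords_a[a][0], coords_b[b][0])
        by_contig.setdefault(key, []).append((a, b))
    blocks = []
    for (ca, cb), plist in sorted(by_contig.items()):
        plist = sorted(plist, key=lambda p: coords_a[p[0]][1])
        remaining = plist
        while len(remaining) >= min_anchors:
            order_b = sorted(range(len(remaining)),
                             key=lambda i: coords_b[remaining[i][1]][1])
            rank = [0] * len(remaining)
            for r, i in enumerate(order_b):
                rank[i] = r
            fwd = _lis_indices(rank)
            rev = _lis_indices([-r for r in rank])
            idx, orient = (fwd, "+") if len(fwd) >= len(rev) else (rev, "-")
            if len(idx) < min_anchors:
                break
            chain = [remaining[i] for i in idx]
            blocks.append(SyntenyBlock(species_a, species_b, ca, cb,
                                       orient, chain))
            used = set(idx)
            remaining = [p for i, p in enumerate(remaining) if i not in used]
    blocks.sort(key=lambda b: (b.contig_a, coords_a[b.anchors[0][0]][1]))
    return blocks


def synteny_table(blocks: list[SyntenyBlock]) -> pd.DataFrame:
    rows = []
    for i, b in enumerate(blocks):
        rows.append(dict(block=i, species_a=b.species_a,
                         species_b=b.species_b, contig_a=b.contig_a,
                         contig_b=b.contig_b, orientation=b.orientation,
                         n_anchors=len(b.anchors),
                         anchors=";".join(f"{x}|{y}" for x, y in b.anchors)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Orthologous regions
# ---------------------------------------------------------------------------

@dataclass
class OrthologousRegion:
    species: str
    contig: str
    start: int
    end: int
    orientation: str  # '+' if the region runs in the same direction as
    # the focal locus context, '-' if inverted


@dataclass
class NoOrthologousRegion:
    reason: str


def orthologous_region(locus: tuple[str, int, int],
                       blocks: list[SyntenyBlock],
                       coords_a: GeneCoords, coords_b: GeneCoords
                       ) -> OrthologousRegion | NoOrthologousRegion:
    """Interval between the orthologs of the anchors flanking a focal
    locus (typed no-region result when anchors are missing)."""
    contig, start, end = locus
    for b in blocks:
        if b.contig_a != contig:
            continue
        left = right = None
        for (ga, gb) in b.anchors:
            _, s, e, _ = coords_a[ga]
            if e <= start:
                left = (ga, gb)
            if s >= end and right is None:
                right = (ga, gb)
        if left and right:
            lb, rb = coords_b[left[1]], coords_b[right[1]]
            if lb[0] != rb[0]:
                return NoOrthologousRegion("flanking anchors map to "
                                           "different contigs")
            # inner interval between the two anchor genes (whichever
            # order the block orientation puts them in); degenerate
            # overlaps fall back to the anchors' joint span
            inner = (min(lb[2], rb[2]), max(lb[1], rb[1]))
            if inner[0] >= inner[1]:
                inner = (min(lb[1], rb[1]), max(lb[2], rb[2]))
            return OrthologousRegion(b.species_b, lb[0], inner[0], inner[1],
                                     b.orientation)
    return NoOrthologousRegion("no synteny block with flanking anchors")


def intron_index_containing(gene: GeneModel, start: int, end: int
                            ) -> int | None:
    """Transcription-order index (0-based) of the intron containing
    [start, end), or None."""
    introns = gene.introns()
    order = introns if gene.strand == "+" else introns[::-1]
    for i, (a, b) in enumerate(order):
        if a <= start and end <= b:
            return i
    return None


def orthologous_intron(host: GeneModel, intron_idx: int,
                       ortholog: GeneModel
                       ) -> OrthologousRegion | NoOrthologousRegion:
    """Same-index intron (transcription order) of the host's ortholog."""
    introns = ortholog.introns()
    order = introns if ortholog.strand == "+" else introns[::-1]
    if intron_idx >= len(order):
        return NoOrthologousRegion(
            f"ortholog {ortholog.gene_id} has no intron {intron_idx}")
    a, b = order[intron_idx]
    orientation = "+" if ortholog.strand == host.strand else "-"
    return OrthologousRegion(ortholog.species, ortholog.contig, a, b,
                             orientation)


# ---------------------------------------------------------------------------
# Spliced protein-to-genome alignment
# ---------------------------------------------------------------------------

MAX_SPLICED_WINDOW = 200_000


@dataclass
class MapSegment:
    protein_interval: tuple[int, int]
    genomic_interval: tuple[int, int]  # forward coordinates
    frame: int
    score: float


@dataclass
class SplicedMap:
    query_id: str
    strand: str
    segments: list[MapSegment] = field(default_factory=list)
    total_score: float = 0.0

    @property
    def is_empty(self) -> bool:
        return not self.segments


@dataclass
class SplicedAlignParams:
    min_segment_score: float = 25.0
    min_total_score: float = 40.0
    splice_bonus: float = 10.0
    noncanonical_penalty: float = 10.0
    max_segments_per_frame: int = 6


def _frame_segments(protein: str, window: str,
                    params: SplicedAlignParams) -> list[MapSegment]:
    """Local alignments of the protein against each of the six frames,
    extracted greedily with masking."""
    q = hs.encode_protein(protein)
    frames = hs.translate_six_frames(window)
    segs = []
    for frame in (1, 2, 3, -1, -2, -3):
        aa = frames[frame]
        if not aa:
            continue
        s = hs.encode_protein(aa)
        mask_val = hs.PROTEIN_ALPHABET.index("X")
        for _ in range(params.max_segments_per_frame):
            score, qs, qe, ss, se, _m, _a = hs._sw_full(
                q, s, hs.BLOSUM62, 11, 1)
            if score < params.min_segment_score or qe <= qs:
                break
            g = hs.frame_to_genomic(frame, ss, se, len(window))
            segs.append(MapSegment((qs, qe), g, frame, float(score)))
            s = s.copy()
            s[ss:se] = mask_val
    return segs


def chain_segments(segs: list[MapSegment], window: str,
                   params: SplicedAlignParams | None = None
                   ) -> tuple[list[MapSegment], float]:
    """Best-scoring collinear chain of segments on one strand, with a
    splice-site bonus for canonical GT..AG gaps (DP over segments)."""
    params = params or SplicedAlignParams()
    best_chain: list[MapSegment] = []
    best_score = 0.0
    for strand in ("+", "-"):
        ss = [s for s in segs if (s.frame > 0) == (strand == "+")]
        ss.sort(key=lambda s: (s.protein_interval[0], s.genomic_interval[0]))
        n = len(ss)
        score = [s.score for s in ss]
        prev = [-1] * n
        for i in range(n):
            for j in range(i):
                a, b = ss[j], ss[i]
                if b.protein_interval[0] < a.protein_interval[1]:
                    continue
                if strand == "+":
                    gap = b.genomic_interval[0] - a.genomic_interval[1]
                else:
                    gap = a.genomic_interval[0] - b.genomic_interval[1]
                if gap < 0:
                    continue
                if gap >= MIN_INTRON:
                    if strand == "+":
                        lo, hi = a.genomic_interval[1], b.genomic_interval[0]
                    else:
                        lo, hi = b.genomic_interval[1], a.genomic_interval[0]
                    donor = window[lo:lo + 2]
                    accept = window[hi - 2:hi]
                    if strand == "-":
                        donor, accept = accept, donor  # motifs on - strand
                        canonical = (window[hi - 2:hi] == "AC"
                                     and window[lo:lo + 2] == "CT")
                    else:
                        canonical = donor == "GT" and accept == "AG"
                    link = (params.splice_bonus if canonical
                            else -params.noncanonical_penalty)
                else:
                    link = -2.0
                cand = score[j] + ss[i].score + link
                if cand > score[i]:
                    score[i] = cand
                    prev[i] = j
        if n:
            end = int(np.argmax(score))
            if score[end] > best_score:
                best_score = float(score[end])
                chain = []
                while end != -1:
                    chain.append(ss[end])
                    end = prev[end]
                best_chain = chain[::-1]
    return best_chain, best_score


def spliced_align(query_id: str, protein: str, window: str,
                  params: SplicedAlignParams | None = None) -> SplicedMap:
    """Best chain of six-frame local alignments of a protein against a
    genomic window (empty map if below the score threshold)."""
    if len(window) > MAX_SPLICED_WINDOW:
        raise ValueError(
            f"window of {len(window)} bp exceeds the "
            f"{MAX_SPLICED_WINDOW} bp cap; narrow it via synteny first")
    params = params or SplicedAlignParams()
    segs = _frame_segments(protein, window, params)
    chain, score = chain_segments(segs, window, params)
    if score < params.min_total_score:
        return SplicedMap(query_id, "+", [], 0.0)
    strand = "+" if chain and chain[0].frame > 0 else "-"
    return SplicedMap(query_id, strand, chain, score)


def spliced_maps_gff3(maps: list[SplicedMap], contig: str) -> str:
    lines = ["##gff-version 3"]
    for m in maps:
        if m.is_empty:
            continue
        gs = min(s.genomic_interval[0] for s in m.segments)
        ge = max(s.genomic_interval[1] for s in m.segments)
        lines.append("\t".join([
            contig, "stratigraph", "match", str(gs + 1), str(ge),
            f"{m.total_score:.0f}", m.strand, ".", f"ID=map_{m.query_id}"]))
        for s in m.segments:
            a, b = s.genomic_interval
            lines.append("\t".join([
                contig, "stratigraph", "match_part", str(a + 1), str(b),
                f"{s.score:.0f}", m.strand, ".",
                f"Parent=map_{m.query_id};Target={m.query_id} "
                f"{s.protein_interval[0] + 1} {s.protein_interval[1]}"]))
    return "\n".join(lines) + "\n"
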