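"""Domain types and readers/writers for the formats touched by the pipeline.

Internal coordinates are 0-based half-open everywhere; conversion to the
1-based inclusive convention of GFF3 happens only at I/O boundaries.
Writers are deterministic: records sorted by (contig, start, id).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import dendropy
import pysam
from Bio.Seq import Seq

logger = logging.getLogger("stratigraph")

#: Gaps in a SAM alignment at least this long are treated as introns
#: (separate blocks); shorter deletions stay inside a block.  Short-intron
#: nematode genomes motivate the low default; override per call if needed.
MIN_INTRON_LEN = 20

STOP = "*"


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------

class SpeciesTree:
    """A rooted species tree with one designated focal leaf.

    The *ladder index* of a non-focal leaf is the number of internal nodes
    on the path between it and the focal leaf (1 = sister species).  On a
    ladder-like phylogeny this doubles as the phylostratum index of the
    ancestral node where the two lineages meet.
    """

    def __init__(self, newick: str, focal: str):
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick")
        except Exception as e:
            if "Duplicate" in type(e).__name__ or \
                    "Multiple occurrences" in str(e):
                raise ValueError("duplicate leaf names in tree") from None
            raise ValueError(f"invalid newick: {e}") from None
        if len(tree.seed_node.child_nodes()) > 2:
            raise ValueError(
                "tree is unrooted (basal polytomy with >2 children); "
                "a rooted tree is required"
            )
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(leaves)) != len(leaves):
            raise ValueError("duplicate leaf names in tree")
        if focal not in leaves:
            raise ValueError(f"focal leaf {focal!r} not present in tree")
        self._tree = tree
        self.newick = newick
        self.focal = focal
        self.leaves = leaves

    def _leaf(self, name: str):
        for lf in self._tree.leaf_node_iter():
            if lf.taxon.label == name:
                return lf
        raise KeyError(name)

    def _path_nodes(self, a: str, b: str):
        """Internal nodes on the leaf-to-leaf path (endpoints excluded)."""
        na, nb = self._leaf(a), self._leaf(b)
        anc_a = []
        n = na.parent_node
        while n is not None:
            anc_a.append(n)
            n = n.parent_node
        anc_b = []
        n = nb.parent_node
        while n is not None:
            anc_b.append(n)
            n = n.parent_node
        mrca = next(n for n in anc_a if n in anc_b)
        path = []
        for n in anc_a:
            path.append(n)
            if n is mrca:
                break
        for n in anc_b:
            if n is mrca:
                break
            path.append(n)
        return path

    def ladder_index(self, species: str) -> int:
        if species == self.focal:
            return 0
        return len(self._path_nodes(self.focal, species))

    def path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths between two leaves."""
        na, nb = self._leaf(a), self._leaf(b)
        pdm = self._tree.phylogenetic_distance_matrix()
        return pdm.patristic_distance(na.taxon, nb.taxon)

    def non_focal(self) -> list[str]:
        return sorted(
            (s for s in self.leaves if s != self.focal),
            key=self.ladder_index,
        )


def read_tree(newick: str, focal: str) -> SpeciesTree:
    return SpeciesTree(newick, focal)


def ladder_newick(n_species: int, branch_length: float = 0.04,
                  prefix: str = "sp") -> str:
    """Newick for a pure ladder: focal ``sp0`` sister to sp1, then sp2, ..."""
    s = f"{prefix}0:{branch_length}"
    for k in range(1, n_species):
        s = f"({prefix}{k}:{branch_length * k},{s}):{branch_length}"
    return s + ";"


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A stranded, multi-exon gene with CDS intervals and frame.

    ``exons`` and ``cds`` are lists of 0-based half-open genomic intervals
    in ascending genomic order; each CDS interval carries a GFF3 phase.
    """

    gene_id: str
    species: str
    contig: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int, int]]  # (start, end, phase)
    pseudo: bool = False
    malformed: bool = False

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        self.exons = sorted(tuple(e[:2]) for e in self.exons)
        self.cds = sorted(tuple(c) for c in self.cds)
        for (a, b) in self.exons:
            if not a < b:
                raise ValueError(f"{self.gene_id}: empty exon [{a},{b})")
        for (a, b), (c, d) in zip(self.exons, self.exons[1:]):
            if c < b:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        for (a, b, _p) in self.cds:
            if not any(ea <= a and b <= eb for ea, eb in self.exons):
                raise ValueError(f"{self.gene_id}: CDS [{a},{b}) not inside an exon")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def coding_exons(self) -> list[tuple[int, int]]:
        """Exons that contain at least one CDS base."""
        out = []
        for ea, eb in self.exons:
            if any(max(ea, a) < min(eb, b) for a, b, _ in self.cds):
                out.append((ea, eb))
        return out

    def cds_spans(self) -> list[tuple[int, int]]:
        return [(a, b) for a, b, _ in self.cds]

    def introns(self) -> list[tuple[int, int]]:
        """Inter-exon gaps in ascending genomic order."""
        return [(b, c) for (_, b), (c, _) in zip(self.exons, self.exons[1:])]

    def spliced_transcript(self, contig_seq: str) -> str:
        parts = [contig_seq[a:b] for a, b in self.exons]
        s = "".join(parts)
        return s if self.strand == "+" else str(Seq(s).reverse_complement())

    def coding_sequence(self, contig_seq: str) -> str:
        parts = [contig_seq[a:b] for a, b, _ in self.cds]
        s = "".join(parts)
        if self.strand == "-":
            s = str(Seq(s).reverse_complement())
        # trim to the annotated phase of the 5'-most CDS segment
        first_phase = self.cds[0][2] if self.strand == "+" else self.cds[-1][2]
        return s[first_phase:]

    def protein(self, contig_seq: str) -> str:
        cds = self.coding_sequence(contig_seq)
        cds = cds[: len(cds) - len(cds) % 3]
        aa = str(Seq(cds).translate())
        return aa[:-1] if aa.endswith(STOP) else aa


def validate_gene(gene: GeneModel, contig_seq: str) -> GeneModel:
    """Enforce the coding invariants; return the gene flagged if broken."""
    if gene.end > len(contig_seq):
        raise ValueError(
            f"{gene.gene_id}: coordinates exceed contig "
            f"{gene.contig} (len {len(contig_seq)})"
        )
    first_phase = gene.cds[0][2] if gene.strand == "+" else gene.cds[-1][2]
    total = sum(b - a for a, b, _ in gene.cds) - first_phase
    if total % 3 != 0:
        logger.warning("%s: CDS length %d not a multiple of 3 after phase; "
                       "flagged malformed", gene.gene_id, total)
        return replace(gene, malformed=True)
    aa = gene.protein(contig_seq)
    if STOP in aa and not gene.pseudo:
        logger.warning("%s: internal stop codon; flagged malformed",
                       gene.gene_id)
        return replace(gene, malformed=True)
    return gene


# ---------------------------------------------------------------------------
# GFF3 I/O
# ---------------------------------------------------------------------------

def read_annotation(gff3_path: str, fasta_path: str,
                    species: str = "") -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features into validated GeneModels.

    Malformed genes (CDS length not a multiple of 3, internal stops) are
    flagged and excluded from the returned list with a logged warning;
    coordinates outside a contig are a hard error.
    """
    import gffutils
    contigs = read_fasta(fasta_path)
    db = gffutils.create_db(gff3_path, ":memory:", force=True,
                            keep_order=True,
                            merge_strategy="create_unique")
    out = []
    for gf in db.features_of_type("gene"):
        exons, cds = [], []
        for mrna in db.children(gf, featuretype="mRNA"):
            for ex in db.children(mrna, featuretype="exon"):
                exons.append((ex.start - 1, ex.end))
            for c in db.children(mrna, featuretype="CDS"):
                cds.append((c.start - 1, c.end,
                            int(c.frame) if c.frame != "." else 0))
            break  # one transcript per gene in this pipeline
        if not exons:  # features attached directly to the gene
            for ex in db.children(gf, featuretype="exon"):
                exons.append((ex.start - 1, ex.end))
            for c in db.children(gf, featuretype="CDS"):
                cds.append((c.start - 1, c.end,
                            int(c.frame) if c.frame != "." else 0))
        if gf.seqid not in contigs:
            raise ValueError(f"{gf.id}: unknown contig {gf.seqid}")
        gene = GeneModel(gene_id=gf.id, species=species, contig=gf.seqid,
                         strand=gf.strand, exons=exons, cds=cds,
                         pseudo=gf.attributes.get("pseudo", ["false"])[0]
                         == "true")
        gene = validate_gene(gene, contigs[gf.seqid])
        if gene.malformed:
            continue
        out.append(gene)
    out.sort(key=lambda g: (g.contig, g.start, g.gene_id))
    return out


def write_annotation(models: list[GeneModel]) -> str:
    """Canonical GFF3 text: one mRNA per gene, sorted by (contig, start, id)."""
    lines = ["##gff-version 3"]
    for g in sorted(models, key=lambda m: (m.contig, m.start, m.gene_id)):
        gs, ge = g.start + 1, g.end
        extra = ";pseudo=true" if g.pseudo else ""
        lines.append("\t".join([
            g.contig, "stratigraph", "gene", str(gs), str(ge), ".",
            g.strand, ".", f"ID={g.gene_id}{extra}"]))
        tid = f"{g.gene_id}.t1"
        lines.append("\t".join([
            g.contig, "stratigraph", "mRNA", str(gs), str(ge), ".",
            g.strand, ".", f"ID={tid};Parent={g.gene_id}"]))
        for a, b in g.exons:
            lines.append("\t".join([
                g.contig, "stratigraph", "exon", str(a + 1), str(b), ".",
                g.strand, ".", f"Parent={tid}"]))
        for a, b, p in g.cds:
            lines.append("\t".join([
                g.contig, "stratigraph", "CDS", str(a + 1), str(b), ".",
                g.strand, str(p), f"Parent={tid}"]))
    return "\n".join(lines) + "\n"


def compute_phases(cds_spans: list[tuple[int, int]], strand: str
                   ) -> list[tuple[int, int, int]]:
    """Attach GFF3 phases to CDS spans, assuming translation starts at the
    5'-most base (phase 0 for the first segment in transcription order)."""
    spans = sorted(cds_spans)
    order = spans if strand == "+" else spans[::-1]
    phased, acc = {}, 0
    for a, b in order:
        phased[(a, b)] = (3 - acc % 3) % 3
        acc += b - a
    return [(a, b, phased[(a, b)]) for a, b in spans]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(seqs: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# SAM spliced reads
# ---------------------------------------------------------------------------

@dataclass
class SpliceReadAlignment:
    """One aligned RNA-seq read, reduced to its gapless reference blocks."""

    read_id: str
    contig: str
    strand: str  # '+', '-', or '?' when the protocol is unstranded
    blocks: list[tuple[int, int]] = field(default_factory=list)

    @property
    def is_spliced(self) -> bool:
        return len(self.blocks) > 1


_CONSUME_REF = {0: True, 1: False, 2: True, 3: True, 4: False,
                5: False, 6: False, 7: True, 8: True}


def blocks_from_cigar(pos: int, cigartuples, min_intron: int = MIN_INTRON_LEN
                      ) -> list[tuple[int, int]]:
    """Aligned reference blocks; N gaps (and deletions >= min_intron) split
    blocks, clips consume no reference."""
    blocks, cur_start, cur = [], pos, pos
    for op, ln in cigartuples:
        if op not in _CONSUME_REF:
            raise ValueError(f"unknown CIGAR op code {op}")
        if op in (0, 7, 8):  # M, =, X
            cur += ln
        elif op == 2:  # D
            if ln >= min_intron:
                blocks.append((cur_start, cur))
                cur_start = cur + ln
            cur += ln
        elif op == 3:  # N
            if cur > cur_start:
                blocks.append((cur_start, cur))
            cur += ln
            cur_start = cur
        # I, S, H, P: no reference advance
    if cur > cur_start:
        blocks.append((cur_start, cur))
    return blocks


def read_sam(path: str, stranded: bool = True,
             min_intron: int = MIN_INTRON_LEN) -> list[SpliceReadAlignment]:
    out = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.cigartuples is None:
                continue
            blocks = blocks_from_cigar(rec.reference_start, rec.cigartuples,
                                       min_intron)
            strand = "?" if not stranded else ("-" if rec.is_reverse else "+")
            out.append(SpliceReadAlignment(
                read_id=rec.query_name, contig=rec.reference_name,
                strand=strand, blocks=blocks))
    return out


# ---------------------------------------------------------------------------
# Homology hits
# ---------------------------------------------------------------------------

@dataclass
class HomologyHit:
    """One local alignment between a query and a subject database entry."""

    query_id: str
    subject_id: str
    mode: str  # 'blastp' | 'blastn' | 'tblastn'
    bit_score: float
    raw_score: float
    e_value: float
    pct_identity: float
    query_interval: tuple[int, int]
    subject_interval: tuple[int, int]  # genomic/forward coordinates
    subject_frame: int = 0  # -3..+3; 0 for untranslated subjects
    subject_strand: str = "+"  # strand of the subject match (blastn/tblastn)
    subject_db_kind: str = ""

    def __post_init__(self):
        if self.e_value < 0:
            raise ValueError("negative E-value")
        if not 0 <= self.pct_identity <= 100:
            raise ValueError("identity outside [0, 100]")
        if (self.subject_frame != 0) != (self.mode == "tblastn"):
            raise ValueError("frame must be nonzero iff mode is translated")
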