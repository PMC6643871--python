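"""Homology tracing of SSOGs across sister-species databases and
RNA-seq confirmation of gene structures.

Tracing asks, per sister species, whether an SSOG leaves a signal in
(i) annotated transcripts (nucleotide search: screens for ORF switching),
(ii) the genome assembly (translated search: catches non-coding
homologous regions of de novo candidates), and
(iii) the transcriptome assembly (nucleotide search: flags homology lost
to assembly gaps).  Structure confirmation requires, for a multi-exon
gene, at least two reads supporting every coding exon and at least two
spliced reads with exact inner edges at every junction; single-exon genes
are excluded outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import homsearch as hs
from .core_model import GeneModel, SpliceReadAlignment

TRACE_DB_KINDS = ("transcripts", "genome", "transcriptome")


@dataclass
class TraceParams:
    # the trace asks whether a *signal* exists per cell, so its cutoffs
    # sit below the chance-alignment regime of a whole-database search;
    # looser cutoffs would light up every cell and leave nothing
    # untraceable
    nucl_evalue: float = 1e-4    # transcripts / transcriptome (blastn)
    genome_evalue: float = 1e-5  # genome (tblastn)
    use_seeding: bool = False


@dataclass
class TracePattern:
    gene_id: str
    # cells[species][dbkind] -> True | False | None (None = db missing)
    cells: dict[str, dict[str, bool | None]]
    category: str = ""

    def categorize(self) -> str:
        known = [v for by_kind in self.cells.values()
                 for v in by_kind.values() if v is not None]
        if known and not any(known):
            self.category = "untraceable"
            return self.category
        for by_kind in self.cells.values():
            if (by_kind.get("transcriptome") is True
                    and by_kind.get("genome") is False
                    and by_kind.get("transcripts") is False):
                self.category = "assembly-gap-candidate"
                return self.category
        for by_kind in self.cells.values():
            if all(by_kind.get(k) is True for k in TRACE_DB_KINDS):
                self.category = "all-three"
                return self.category
        self.category = "partial"
        return self.category


def trace_homology(ssogs: dict[str, dict[str, str]],
                   per_species_dbs: dict[str, dict[str, dict[str, str]]],
                   params: TraceParams | None = None) -> dict[str, TracePattern]:
    """Trace matrix for SSOGs.

    ``ssogs``: gene id -> {'protein': aa, 'transcript': nucl}.
    ``per_species_dbs``: species -> {dbkind -> {seq id -> seq}}; a species
    missing a db kind yields an 'unknown' cell, never a silent False.
    """
    params = params or TraceParams()
    patterns = {g: TracePattern(g, {}) for g in ssogs}
    nucl_p = hs.SearchParams.nucl(params.nucl_evalue,
                                  use_seeding=params.use_seeding)
    gen_p = hs.SearchParams.translated(params.genome_evalue,
                                       use_seeding=params.use_seeding)
    tx_queries = sorted((g, d["transcript"]) for g, d in ssogs.items())
    aa_queries = sorted((g, d["protein"]) for g, d in ssogs.items())
    for species in sorted(per_species_dbs):
        dbs = per_species_dbs[species]
        for g in patterns:
            patterns[g].cells[species] = {}
        for kind in TRACE_DB_KINDS:
            if kind not in dbs or dbs[kind] is None:
                for g in patterns:
                    patterns[g].cells[species][kind] = None
                continue
            db = sorted(dbs[kind].items())
            if kind == "genome":
                hits = hs.search(aa_queries, db, gen_p) if db else []
            else:
                hits = hs.search(tx_queries, db, nucl_p) if db else []
            with_hit = {h.query_id for h in hits}
            for g in patterns:
                patterns[g].cells[species][kind] = g in with_hit
    for p in patterns.values():
        p.categorize()
    return patterns


def trace_table(patterns: dict[str, TracePattern]) -> pd.DataFrame:
    rows = []
    for g in sorted(patterns):
        p = patterns[g]
        row = {"gene_id": g, "category": p.category}
        for sp in sorted(p.cells):
            for kind in TRACE_DB_KINDS:
                v = p.cells[sp][kind]
                row[f"{sp}:{kind}"] = "unknown" if v is None else str(v)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Structure validation
# ---------------------------------------------------------------------------

@dataclass
class StructureParams:
    min_support: int = 2
    exon_overlap_frac: float = 0.8  # read block must cover this much of
    # an exon's CDS span; junction inner edges must match exactly
    min_strand_disagreement: int = 2


@dataclass
class StructureStatus:
    gene_id: str
    n_exons: int
    n_coding_exons: int
    exon_support: list[int] = field(default_factory=list)
    junction_support: list[int] = field(default_factory=list)
    status: str = "unconfirmed"
    strand_consistent: bool | None = None  # None = unknown (unstranded)


def _exon_cds_span(gene: GeneModel, exon: tuple[int, int]
                   ) -> tuple[int, int] | None:
    a, b = exon
    spans = [(max(a, s), min(b, e)) for s, e, _ in gene.cds
             if max(a, s) < min(b, e)]
    if not spans:
        return None
    return min(s for s, _ in spans), max(e for _, e in spans)


def validate_structure(gene: GeneModel, reads: list[SpliceReadAlignment],
                       stranded: bool = True,
                       params: StructureParams | None = None
                       ) -> StructureStatus:
    """Read-support status for one gene; an empty read set yields
    'unconfirmed' with zeroed counts (not an error)."""
    params = params or StructureParams()
    st = StructureStatus(gene_id=gene.gene_id, n_exons=gene.n_exons,
                         n_coding_exons=len(gene.coding_exons))
    if gene.n_exons < 2:
        st.status = "single-exon-excluded"
        st.strand_consistent = None if not stranded else True
        return st
    reads = [r for r in reads if r.contig == gene.contig
             and r.blocks[-1][1] > gene.start and r.blocks[0][0] < gene.end]
    cds_spans = [s for e in gene.coding_exons
                 if (s := _exon_cds_span(gene, e)) is not None]
    exon_support = []
    supporting: set[int] = set()
    for (sa, sb) in cds_spans:
        need = params.exon_overlap_frac * (sb - sa)
        n = 0
        for ri, r in enumerate(reads):
            if any(min(b, sb) - max(a, sa) >= need for a, b in r.blocks):
                n += 1
                supporting.add(ri)
        exon_support.append(n)
    junction_support = []
    for (jb, jc) in gene.introns():
        n = 0
        for ri, r in enumerate(reads):
            if not r.is_spliced:
                continue
            for (a1, b1), (a2, b2) in zip(r.blocks, r.blocks[1:]):
                if b1 == jb and a2 == jc:
                    n += 1
                    supporting.add(ri)
                    break
        junction_support.append(n)
    st.exon_support = exon_support
    st.junction_support = junction_support
    m = params.min_support
    if all(n >= m for n in exon_support) and \
            all(n >= m for n in junction_support) and exon_support:
        st.status = "fully-confirmed"
    elif any(exon_support) or any(junction_support):
        st.status = "partially-confirmed"
    else:
        st.status = "unconfirmed"
    if stranded:
        disagree = sum(1 for ri in supporting
                       if reads[ri].strand not in ("?", gene.strand))
        st.strand_consistent = disagree < params.min_strand_disagreement
        if not st.strand_consistent and st.status == "fully-confirmed":
            st.status = "partially-confirmed"
    return st


def structure_table(statuses: list[StructureStatus]) -> pd.DataFrame:
    rows = [dict(
        gene_id=s.gene_id, n_exons=s.n_exons,
        n_coding_exons=s.n_coding_exons,
        exon_support=",".join(map(str, s.exon_support)),
        junction_support=",".join(map(str, s.junction_support)),
        status=s.status,
        strand_consistent="unknown" if s.strand_consistent is None
        else str(s.strand_consistent))
        for s in sorted(statuses, key=lambda x: x.gene_id)]
    return pd.DataFrame(rows)


def high_confidence_set(ssogs: list[str],
                        traces: dict[str, TracePattern],
                        statuses: dict[str, StructureStatus]) -> list[str]:
    """SSOGs that are traceable (not 'untraceable') and fully confirmed,
    sorted by gene id — the starting set for origin analysis."""
    out = []
    for g in ssogs:
        t, s = traces.get(g), statuses.get(g)
        if t is None or s is None:
            continue
        if t.category != "untraceable" and s.status == "fully-confirmed":
            out.append(g)
    return sorted(out)
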