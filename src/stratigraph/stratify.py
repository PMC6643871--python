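"""Orphan-gene classification cascade and phylostratigraphy.

Genes are first split into Conserved vs Orphan by a strict three-step
cascade against outgroup data (protein DBs, genomes, then a broad
protein knowledgebase); orphans are then split into taxon-restricted
orphans (TROGs: a protein homolog in at least one other ingroup species)
and species-specific orphans (SSOGs).  Genomic (tblastn) matches are
deliberately ignored at the TROG/SSOG step so pseudogenes and non-coding
regions cannot masquerade as protein homologs.  Focal-species orphans are
finally placed into phylostrata: the ladder index of the most recent
common ancestor of the focal species and its most distant homolog-bearing
relative, with stratum 0 reserved for SSOGs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import homsearch as hs
from .core_model import SpeciesTree


@dataclass
class StratifyParams:
    step1_evalue: float = 1e-3   # blastp vs outgroup proteins
    step2_evalue: float = 1e-5   # tblastn vs outgroup genomes
    step3_evalue: float = 1e-3   # blastp vs broad protein knowledgebase
    trog_evalue: float = 1e-3    # blastp vs ingroup proteins
    use_seeding: bool = True


@dataclass
class StratumAssignment:
    gene_id: str
    species: str
    gene_class: str  # 'Conserved' | 'TROG' | 'SSOG'
    conserved_step: int | None = None  # 1|2|3, None for orphans
    hgt_candidate: bool = False
    phylostratum: int | None = None  # focal species only
    supporting_hits: list[str] = field(default_factory=list)


ProteinDB = dict[str, str]  # gene id -> protein sequence


def _as_queries(genes: ProteinDB) -> list[tuple[str, str]]:
    return sorted(genes.items())


def classify_conserved(genes: ProteinDB,
                       outgroup_protein_dbs: dict[str, ProteinDB],
                       outgroup_genomes: dict[str, dict[str, str]],
                       uniprot_like_db: ProteinDB,
                       params: StratifyParams | None = None
                       ) -> dict[str, tuple[str, int | None, str]]:
    """Three-step cascade; steps run strictly in order and a gene reaches
    step k+1 only if it failed step k.

    Returns per gene: ('Conserved', step, evidence) or ('Orphan', None, '').
    A *missing* database argument is an error; an *empty* database is a
    valid no-hit database.
    """
    for name, db in (("outgroup_protein_dbs", outgroup_protein_dbs),
                     ("outgroup_genomes", outgroup_genomes),
                     ("uniprot_like_db", uniprot_like_db)):
        if db is None:
            raise ValueError(f"{name} is missing (pass an empty dict for "
                             "a legitimately empty database)")
    params = params or StratifyParams()
    result: dict[str, tuple[str, int | None, str]] = {}
    remaining = _as_queries(genes)

    def run_step(step: int, dbs: list[tuple[str, str]], sp: hs.SearchParams):
        nonlocal remaining
        if not remaining or not dbs:
            return
        hits = hs.search(remaining, dbs, sp)
        best = hs.best_hits_by_query(hits)
        for gid, h in best.items():
            result[gid] = ("Conserved", step,
                           f"{h.subject_id}:{h.e_value:.2e}")
        remaining = [(g, s) for g, s in remaining if g not in result]

    run_step(1, sorted((k, v) for db in outgroup_protein_dbs.values()
                       for k, v in db.items()),
             hs.SearchParams.protein(params.step1_evalue,
                                     use_seeding=params.use_seeding))
    run_step(2, sorted((k, v) for g in outgroup_genomes.values()
                       for k, v in g.items()),
             hs.SearchParams.translated(params.step2_evalue,
                                        use_seeding=params.use_seeding))
    run_step(3, sorted(uniprot_like_db.items()),
             hs.SearchParams.protein(params.step3_evalue,
                                     use_seeding=params.use_seeding))
    for gid, _ in remaining:
        result[gid] = ("Orphan", None, "")
    return result


def split_trog_ssog(orphans: ProteinDB, own_species: str,
                    ingroup_protein_dbs: dict[str, ProteinDB],
                    params: StratifyParams | None = None
                    ) -> dict[str, tuple[str, dict[str, hs.HomologyHit]]]:
    """TROG iff >=1 protein-protein hit (E <= threshold) in >=1 *other*
    ingroup species; protein homology only, by design.

    Returns per gene: (class, {species: best hit}).
    """
    params = params or StratifyParams()
    if own_species not in ingroup_protein_dbs:
        raise ValueError(f"own species {own_species!r} missing from "
                         "ingroup protein DBs")
    own_db = ingroup_protein_dbs[own_species]
    for gid in orphans:
        if gid not in own_db:
            raise ValueError(f"gene {gid!r} absent from the protein DB of "
                             f"its own species {own_species!r}")
    queries = _as_queries(orphans)
    sp = hs.SearchParams.protein(params.trog_evalue,
                                 use_seeding=params.use_seeding)
    # E-values are computed against the pooled size of all non-self
    # ingroup databases, exactly as one concatenated database would be
    n_pool = sum(len(s) for other, db in ingroup_protein_dbs.items()
                 if other != own_species for s in db.values())
    per_gene: dict[str, dict[str, hs.HomologyHit]] = {g: {} for g in orphans}
    if queries:
        for other in sorted(ingroup_protein_dbs):
            if other == own_species:
                continue  # self/paralog hits never affect class
            db = _as_queries(ingroup_protein_dbs[other])
            if not db:
                continue
            best = hs.best_hits_by_query(
                hs.search(queries, db, sp, n_override=n_pool))
            for gid, h in best.items():
                per_gene[gid][other] = h
    return {gid: (("TROG" if per_gene[gid] else "SSOG"), per_gene[gid])
            for gid in orphans}


def assign_phylostrata(focal_assignments: list[StratumAssignment],
                       trog_hits: dict[str, dict[str, hs.HomologyHit]],
                       tree: SpeciesTree) -> None:
    """Fill in phylostrata (in place) for focal-species assignments.

    TROG stratum = max ladder index over homolog-bearing species; SSOGs
    get stratum 0; Conserved genes get the oldest stratum (one beyond the
    deepest ingroup node) and stay out of the orphan strata.
    """
    oldest = max(tree.ladder_index(s) for s in tree.non_focal()) + 1
    for a in focal_assignments:
        if a.species != tree.focal:
            raise ValueError(f"{a.gene_id}: phylostrata are assigned for "
                             f"the focal species only (got {a.species!r})")
        if a.gene_class == "Conserved":
            a.phylostratum = oldest
        elif a.gene_class == "SSOG":
            a.phylostratum = 0
        else:
            hits = trog_hits.get(a.gene_id, {})
            if not hits:
                raise ValueError(f"{a.gene_id}: TROG without ingroup hits")
            a.phylostratum = max(tree.ladder_index(s) for s in hits)


def classify_species(species: str, genes: ProteinDB,
                     outgroup_protein_dbs: dict[str, ProteinDB],
                     outgroup_genomes: dict[str, dict[str, str]],
                     uniprot_like_db: ProteinDB,
                     ingroup_protein_dbs: dict[str, ProteinDB],
                     tree: SpeciesTree | None = None,
                     params: StratifyParams | None = None
                     ) -> list[StratumAssignment]:
    """Full cascade for one species; phylostrata filled when ``species``
    is the focal leaf of ``tree``."""
    params = params or StratifyParams()
    cons = classify_conserved(genes, outgroup_protein_dbs, outgroup_genomes,
                              uniprot_like_db, params)
    orphans = {g: genes[g] for g, (cls, _, _) in cons.items()
               if cls == "Orphan"}
    trog = split_trog_ssog(orphans, species, ingroup_protein_dbs, params)
    out = []
    for gid in sorted(genes):
        cls, step, evid = cons[gid]
        if cls == "Conserved":
            out.append(StratumAssignment(
                gene_id=gid, species=species, gene_class="Conserved",
                conserved_step=step, hgt_candidate=(step == 3),
                supporting_hits=[evid]))
        else:
            tcls, hits = trog[gid]
            out.append(StratumAssignment(
                gene_id=gid, species=species, gene_class=tcls,
                supporting_hits=sorted(
                    f"{sp}:{h.subject_id}:{h.e_value:.2e}"
                    for sp, h in hits.items())))
    # partition invariant: exhaustive and exclusive by construction;
    # assert it anyway so violations fail loudly
    assert len(out) == len(genes)
    if tree is not None and species == tree.focal:
        trog_hits = {g: h for g, (c, h) in trog.items() if c == "TROG"}
        assign_phylostrata(out, trog_hits, tree)
    return out


def assignments_table(assignments: list[StratumAssignment]) -> pd.DataFrame:
    rows = [dict(
        gene_id=a.gene_id, species=a.species, gene_class=a.gene_class,
        conserved_step=a.conserved_step if a.conserved_step else "none",
        hgt_candidate=a.hgt_candidate,
        phylostratum="" if a.phylostratum is None else a.phylostratum,
        best_hit_evidence=";".join(a.supporting_hits[:3]))
        for a in sorted(assignments, key=lambda x: (x.species, x.gene_id))]
    return pd.DataFrame(rows)
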