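"""End-to-end orchestration: simulate -> classify -> trace -> validate ->
map -> mechanisms -> selection, with deterministic TSV/JSON outputs.

The pipeline always round-trips the dataset through disk (the simulator
writes the standard formats, the analysis stages read them back), so a
run on pre-existing files behaves identically to a simulated run and
every output is byte-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import homsearch as hs
from . import maporth as mo
from . import mechanisms as mech
from . import selection as sel
from . import stratify as st
from . import trace_validate as tv
from .core_model import (SpeciesTree, read_annotation, read_fasta, read_sam,
                         read_tree)
from .simulate import Dataset, SimConfig, simulate_dataset, write_dataset

logger = logging.getLogger("stratigraph")

ALL_STEPS = ("simulate", "classify", "map", "trace", "validate",
             "mechanisms", "selection")


@dataclass
class RunConfig:
    outdir: str
    seed: int = 1
    steps: tuple[str, ...] = ALL_STEPS
    dataset_dir: str | None = None  # pre-existing dataset instead of simulate
    sim: SimConfig = field(default_factory=SimConfig)
    stratify_params: st.StratifyParams = field(
        default_factory=st.StratifyParams)
    trace_params: tv.TraceParams = field(default_factory=tv.TraceParams)
    structure_params: tv.StructureParams = field(
        default_factory=tv.StructureParams)
    stranded: bool = True
    lrt_alpha: float = 0.05

    def validate(self):
        for s in self.steps:
            if s not in ALL_STEPS:
                raise ValueError(f"unknown step {s!r}")
        if "simulate" not in self.steps and self.dataset_dir is None:
            raise ValueError("either enable the simulate step or point "
                             "dataset_dir at an existing dataset")


def load_dataset(d: str) -> Dataset:
    """Read a written dataset back through the standard-format readers."""
    with open(os.path.join(d, "tree.nwk")) as fh:
        newick = fh.read().strip()
    with open(os.path.join(d, "focal.txt")) as fh:
        focal = fh.read().strip()
    tree = read_tree(newick, focal)
    species = sorted(tree.leaves, key=tree.ladder_index)
    genomes, genes, proteins, transcripts, transcriptome = {}, {}, {}, {}, {}
    for sp in species:
        sd = os.path.join(d, sp)
        genomes[sp] = read_fasta(os.path.join(sd, "genome.fasta"))
        genes[sp] = read_annotation(os.path.join(sd, "annotation.gff3"),
                                    os.path.join(sd, "genome.fasta"),
                                    species=sp)
        proteins[sp] = read_fasta(os.path.join(sd, "proteins.fasta"))
        transcripts[sp] = read_fasta(os.path.join(sd, "transcripts.fasta"))
        transcriptome[sp] = read_fasta(
            os.path.join(sd, "transcriptome.fasta"))
    with open(os.path.join(d, "sp0", "rnaseq.sam")) as fh:
        sam_text = fh.read()
    truth_path = os.path.join(d, "truth.tsv")
    truth = (pd.read_csv(truth_path, sep="\t", keep_default_na=False)
             if os.path.exists(truth_path) else pd.DataFrame())
    return Dataset(
        config=None, tree_newick=newick, focal=focal, species=species,
        genomes=genomes, genes=genes, proteins=proteins,
        transcripts=transcripts, transcriptome=transcriptome,
        outgroup_proteins=read_fasta(
            os.path.join(d, "outgroup_proteins.fasta")),
        outgroup_genome=read_fasta(os.path.join(d, "outgroup_genome.fasta")),
        uniprot_like=read_fasta(os.path.join(d, "uniprot_like.fasta")),
        sam_text=sam_text, truth=truth)


def _write_tsv(df: pd.DataFrame, path: str):
    df.to_csv(path, sep="\t", index=False)


def build_context(ds: Dataset, tree: SpeciesTree, reads,
                  structure_params: tv.StructureParams,
                  stranded: bool) -> mech.MechanismContext:
    """Precompute reciprocal hits and synteny blocks focal-vs-sister."""
    focal = tree.focal
    genes_by_id = {sp: {g.gene_id: g for g in ds.genes[sp]}
                   for sp in ds.species}
    ctx = mech.MechanismContext(
        tree=tree, genomes=ds.genomes, genes=genes_by_id,
        proteins=ds.proteins, transcripts=ds.transcripts,
        transcriptome=ds.transcriptome, reads=reads, stranded=stranded,
        structure_params=structure_params)
    params = hs.SearchParams.protein()
    focal_q = sorted(ds.proteins[focal].items())
    for sp in tree.non_focal():
        db = sorted(ds.proteins[sp].items())
        if not db:
            ctx.rbh[sp], ctx.synteny[sp] = [], []
            continue
        hits_ab = hs.search(focal_q, db, params)
        hits_ba = hs.search(db, focal_q, params)
        pairs = mo.best_reciprocal_pairs(hits_ab, hits_ba)
        ctx.rbh[sp] = pairs
        ctx.synteny[sp] = mo.find_synteny_blocks(
            pairs, ctx.coords(focal), ctx.coords(sp),
            species_a=focal, species_b=sp)
    return ctx


def run_all(cfg: RunConfig) -> dict:
    """Run the enabled steps and return the summary dict (also written
    to summary.json / summary.tsv)."""
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)

    # -- dataset ------------------------------------------------------------
    if "simulate" in cfg.steps:
        sim_cfg = cfg.sim
        sim_cfg.seed = cfg.seed
        logger.info("simulating dataset (seed=%d)", cfg.seed)
        ds = simulate_dataset(sim_cfg)
        dataset_dir = os.path.join(cfg.outdir, "dataset")
        write_dataset(ds, dataset_dir)
    else:
        dataset_dir = cfg.dataset_dir
    for sub in ("tree.nwk", "focal.txt"):
        if not os.path.exists(os.path.join(dataset_dir, sub)):
            raise FileNotFoundError(f"dataset input missing: {sub}")
    ds = load_dataset(dataset_dir)
    tree = read_tree(ds.tree_newick, ds.focal)
    focal = ds.focal
    reads = read_sam(os.path.join(dataset_dir, focal, "rnaseq.sam"),
                     stranded=cfg.stranded)
    summary: dict = {"seed": cfg.seed, "focal": focal,
                     "thresholds": {
                         "step1_evalue": cfg.stratify_params.step1_evalue,
                         "step2_evalue": cfg.stratify_params.step2_evalue,
                         "step3_evalue": cfg.stratify_params.step3_evalue,
                         "trog_evalue": cfg.stratify_params.trog_evalue,
                         "relaxed_evalue": hs.RELAXED_E,
                         "min_read_support":
                             cfg.structure_params.min_support,
                         "lrt_alpha": cfg.lrt_alpha}}

    # -- classification -----------------------------------------------------
    assignments: dict[str, list[st.StratumAssignment]] = {}
    if "classify" in cfg.steps:
        logger.info("classifying genes for %d species", len(ds.species))
        og_prot = {"outgroup": ds.outgroup_proteins}
        og_gen = {"outgroup": ds.outgroup_genome}
        for sp in ds.species:
            assignments[sp] = st.classify_species(
                sp, ds.proteins[sp], og_prot, og_gen, ds.uniprot_like,
                ds.proteins, tree=tree, params=cfg.stratify_params)
        table = pd.concat([st.assignments_table(a)
                           for a in assignments.values()],
                          ignore_index=True)
        _write_tsv(table, os.path.join(cfg.outdir, "classification.tsv"))
        fractions = {}
        for sp in ds.species:
            counts = {"Conserved": 0, "TROG": 0, "SSOG": 0}
            for a in assignments[sp]:
                counts[a.gene_class] += 1
            total = max(sum(counts.values()), 1)
            fractions[sp] = {k: round(v / total, 4)
                             for k, v in counts.items()}
            fractions[sp]["n_genes"] = total
        summary["class_fractions"] = fractions
        strata: dict[int, int] = {}
        for a in assignments[focal]:
            if a.gene_class in ("TROG", "SSOG"):
                strata[a.phylostratum] = strata.get(a.phylostratum, 0) + 1
        summary["phylostratum_counts"] = {str(k): strata[k]
                                          for k in sorted(strata)}

    # -- synteny / mapping context ------------------------------------------
    ctx = None
    if {"map", "trace", "validate", "mechanisms", "selection"} & set(cfg.steps):
        logger.info("computing reciprocal hits and synteny blocks")
        ctx = build_context(ds, tree, reads, cfg.structure_params,
                            cfg.stranded)
    if "map" in cfg.steps:
        blocks = [b for sp in tree.non_focal() for b in ctx.synteny[sp]]
        _write_tsv(mo.synteny_table(blocks),
                   os.path.join(cfg.outdir, "synteny_blocks.tsv"))
        summary["synteny"] = {
            sp: {"n_blocks": len(ctx.synteny[sp]),
                 "n_anchors": sum(len(b.anchors) for b in ctx.synteny[sp])}
            for sp in tree.non_focal()}

    ssogs = sorted(a.gene_id for a in assignments.get(focal, [])
                   if a.gene_class == "SSOG")

    # -- trace matrix -------------------------------------------------------
    traces: dict[str, tv.TracePattern] = {}
    if "trace" in cfg.steps and ssogs:
        logger.info("tracing %d SSOGs across sister databases", len(ssogs))
        queries = {g: {"protein": ds.proteins[focal][g],
                       "transcript": ds.transcripts[focal][g + ".t1"]}
                   for g in ssogs}
        per_species_dbs = {
            sp: {"transcripts": ds.transcripts[sp],
                 "genome": ds.genomes[sp],
                 "transcriptome": ds.transcriptome[sp]}
            for sp in tree.non_focal()}
        traces = tv.trace_homology(queries, per_species_dbs,
                                   cfg.trace_params)
        _write_tsv(tv.trace_table(traces),
                   os.path.join(cfg.outdir, "trace_matrix.tsv"))
        cats = {}
        for p in traces.values():
            cats[p.category] = cats.get(p.category, 0) + 1
        summary["trace_categories"] = {k: cats[k] for k in sorted(cats)}

    # -- structure validation ------------------------------------------------
    statuses: dict[str, tv.StructureStatus] = {}
    if "validate" in cfg.steps and ssogs:
        genes_by_id = {g.gene_id: g for g in ds.genes[focal]}
        for g in ssogs:
            statuses[g] = tv.validate_structure(
                genes_by_id[g], reads, cfg.stranded, cfg.structure_params)
        _write_tsv(tv.structure_table(list(statuses.values())),
                   os.path.join(cfg.outdir, "structure_status.tsv"))
        summary["structure_status"] = {
            s: sum(1 for x in statuses.values() if x.status == s)
            for s in ("fully-confirmed", "partially-confirmed",
                      "unconfirmed", "single-exon-excluded")}

    high_conf: list[str] = []
    if traces and statuses:
        high_conf = tv.high_confidence_set(ssogs, traces, statuses)
        with open(os.path.join(cfg.outdir, "high_confidence.txt"), "w") as fh:
            fh.write("\n".join(high_conf) + ("\n" if high_conf else ""))
        summary["n_high_confidence"] = len(high_conf)

    # -- mechanisms ----------------------------------------------------------
    calls: dict[str, mech.MechanismCall] = {}
    if "mechanisms" in cfg.steps and high_conf:
        logger.info("calling origin mechanisms for %d candidates",
                    len(high_conf))
        calls = mech.call_mechanisms(high_conf, ctx)
        _write_tsv(mech.mechanisms_table(calls),
                   os.path.join(cfg.outdir, "mechanisms.tsv"))
        with open(os.path.join(cfg.outdir, "mechanism_evidence.json"),
                  "w") as fh:
            json.dump({g: {"mechanism": c.mechanism,
                           "confidence": c.confidence,
                           "modifiers": c.modifiers,
                           "evidence": c.evidence}
                       for g, c in sorted(calls.items())},
                      fh, indent=1, sort_keys=True, default=str)
        tally: dict[str, int] = {}
        for c in calls.values():
            tally[c.mechanism] = tally.get(c.mechanism, 0) + 1
        summary["mechanism_tally"] = {k: tally[k] for k in sorted(tally)}
        # apply heuristic-failure reclassifications to the final classes
        final = {}
        for a in assignments.get(focal, []):
            cls, stratum = a.gene_class, a.phylostratum
            c = calls.get(a.gene_id)
            if c is not None and c.reclassify_to:
                cls, stratum = c.reclassify_to, c.reclassify_stratum
            final[a.gene_id] = (cls, stratum)
        if final:
            df = pd.DataFrame(
                [dict(gene_id=g, final_class=v[0], final_stratum=v[1])
                 for g, v in sorted(final.items())])
            _write_tsv(df, os.path.join(cfg.outdir, "final_classes.tsv"))
            counts = {"Conserved": 0, "TROG": 0, "SSOG": 0}
            for cls, _ in final.values():
                counts[cls] += 1
            summary["final_class_counts"] = counts

    # -- selection -----------------------------------------------------------
    if "selection" in cfg.steps and calls:
        logger.info("selection analysis of de novo candidates")
        rows = []
        for gid, c in sorted(calls.items()):
            if c.mechanism != "de-novo":
                continue
            res = selection_for_de_novo(gid, c, ctx, cfg.lrt_alpha)
            if res is None:
                continue
            kind, payload = res
            if kind == "result":
                r: sel.SelectionResult = payload
                rows.append(dict(
                    gene_id=gid, mode=r.mode,
                    omegas=";".join(f"{k}={v:.3g}"
                                    for k, v in sorted(r.omegas.items())),
                    kappa=round(r.kappa, 3),
                    lnl_alt=round(r.lnl_alt, 4),
                    lnl_null=round(r.lnl_null, 4),
                    lrt=round(r.lrt, 4), df=r.df,
                    p_value=f"{r.p_value:.3g}",
                    significant=r.significant,
                    note=r.null_hypothesis))
            else:
                rows.append(dict(gene_id=gid, mode="n/a", omegas="",
                                 kappa="", lnl_alt="", lnl_null="",
                                 lrt="", df="", p_value="",
                                 significant="", note=payload))
        _write_tsv(pd.DataFrame(rows),
                   os.path.join(cfg.outdir, "selection.tsv"))
        summary["n_selection_tested"] = len(rows)

    with open(os.path.join(cfg.outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    flat = []
    for k, v in sorted(summary.items()):
        flat.append(dict(key=k, value=json.dumps(v, sort_keys=True)))
    _write_tsv(pd.DataFrame(flat), os.path.join(cfg.outdir, "summary.tsv"))
    return summary


def selection_for_de_novo(gid: str, call: mech.MechanismCall,
                          ctx: mech.MechanismContext, alpha: float
                          ) -> tuple[str, object] | None:
    """Build the codon alignment of a de novo candidate against the
    extracted orthologous frames (stops masked) and fit omega; the mode
    follows the one-sister/many-sisters rule automatically."""
    gene = ctx.focal_gene(gid)
    genome = ctx.contig_seq(ctx.focal, gene.contig)
    segments = mech.cds_segments(gene, genome)
    n_codons = sum(len(s) // 3 for _, s in segments)
    focal_row = ["---"] * n_codons
    for off, part in segments:
        for i in range(len(part) // 3):
            focal_row[off + i] = part[3 * i:3 * i + 3]
    focal_row[n_codons - 1] = "---"  # terminal stop column masked
    rows = {ctx.focal: "".join(focal_row)}
    masked: dict[str, list[int]] = {ctx.focal: [n_codons]}
    per_species = call.evidence.get("per_species", {})
    _subtype, regions = mech._candidate_regions(gene, ctx)
    n_sisters = 0
    for sp in sorted(per_species, key=ctx.tree.ladder_index):
        info = per_species[sp]
        if info.get("status") == "unalignable" or sp not in regions:
            continue
        if n_sisters >= 4:  # closest informative frames carry the signal
            break
        r = regions[sp]
        region_seq = ctx.contig_seq(sp, r.contig)[r.start:r.end]
        res = mech.extract_orthologous_frame(segments, region_seq)
        if res["status"] == "unalignable" or "codon_row" not in res:
            continue
        row = res["codon_row"]
        row = row[:-3] + "---"
        aligned = sum(1 for i in range(0, len(row), 3)
                      if row[i:i + 3] != "---")
        if aligned < 0.6 * n_codons:
            continue  # too gappy: would wipe out shared columns
        rows[sp] = row
        masked[sp] = res["stop_codons"]
        n_sisters += 1
    if len(rows) < 2:
        return None
    aln = sel.CodonAlignment(rows, masked)
    res = sel.fit_omega(aln, mode="auto", alpha=alpha)
    if isinstance(res, sel.SelectionResult):
        return ("result", res)
    return ("skip", getattr(res, "reason", "unusable alignment"))


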