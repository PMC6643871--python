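# Methods

`stratigraph` implements a phylostratigraphic analysis of orphan-gene
origin for a focal species embedded in a densely sampled, ladder-like
clade, together with a synthetic-genome generator that plants every gene
class and origin mechanism the analysis is meant to recover. This note
documents the models, the thresholds and their rationale, the numerical
choices, and what the synthetic data can and cannot show.

## The classification model

Genes are partitioned by a strict three-step cascade against outgroup
data, applied in order, with a gene reaching step *k*+1 only if it
failed step *k*:

1. protein–protein search against outgroup proteomes, E ≤ 10⁻³;
2. translated search (protein vs. six-frame genome) against outgroup
   genome assemblies, E ≤ 10⁻⁵;
3. protein–protein search against a broad protein knowledgebase,
   E ≤ 10⁻³ — genes conserved only at this step are flagged as
   horizontal-gene-transfer candidates, not removed.

Genes failing all three steps are orphans. Orphans with a
protein-level homolog (E ≤ 10⁻³) in at least one *other* ingroup
species are taxon-restricted orphans (TROGs); the remainder are
species-specific orphans (SSOGs). The TROG/SSOG split deliberately uses
protein homology only: translated hits against genomes would let
pseudogenes and non-coding relics masquerade as protein homologs.
Self-hits and within-species paralogs never affect the class.

Each focal orphan is assigned a phylostratum: the ladder index of the
most recent common ancestor of the focal species and its most distant
homolog-bearing relative (the max rule). SSOGs occupy stratum 0;
conserved genes are placed one node beyond the deepest ingroup stratum.

### Search-space statistics

E-values follow Karlin–Altschul, E = K·m·n·e^(−λS), with the published
gapped parameters as engine constants (BLOSUM62 11/1: λ = 0.267,
K = 0.041; nucleotide +2/−3, 5/2: λ = 0.625, K = 0.41) and raw m·n
(no effective-length correction) — a deliberate simplification at desk
scale, stated here so thresholds are interpreted consistently. When one
logical search is executed as several per-species searches (the
TROG/SSOG split, per-exon chimera scans), E-values are computed against
the pooled database size, exactly as a single concatenated database
would behave; otherwise per-species granularity would silently move the
thresholds. Thresholds phrased "≤" are inclusive; the relaxed rescue
threshold E < 10 is strict.

Every reported alignment score is the full affine-gap Smith–Waterman
optimum for its pair (a gap of length L costs open + L·extend). The
word-seeding stage can only prune query/subject pairs that share no
seed word (3-mer for proteins, 11-mer for nucleotides); it never
changes a reported score. Detector-level and rescue searches run
unseeded.

## Homology tracing and structure validation

For each SSOG, three searches per sister species build the trace
matrix: nucleotide search against annotated transcripts (screens for
ORF switching), translated search against the genome assembly (catches
non-coding homologous regions of de novo candidates), and nucleotide
search against the transcriptome assembly (flags homology lost to
assembly gaps). Cells for missing databases are recorded as unknown,
never as absent. Categories: *untraceable* (every known cell false),
*assembly-gap candidate* (transcriptome yes, genome and transcripts no,
in ≥ 1 species), *all-three* (all database kinds hit in one species),
*partial* (everything else).

The trace cutoffs are 10⁻⁵ (translated) and 10⁻⁴ (nucleotide). They
are deliberately below the relaxed exploratory threshold: at a
genome-wide search size, a cutoff of E < 10 admits ~10 chance
alignments per search *by definition*, which would light up every cell
and leave nothing untraceable. The planted homologous regions sit
orders of magnitude below these cutoffs, so the choice separates signal
from the chance-alignment regime rather than tuning against it.

Structure validation operationalizes the read criterion: a gene needs
at least two exons (single-exon genes are excluded outright); every
coding exon needs ≥ 2 reads whose aligned block covers ≥ 80% of the
exon's CDS span; every junction needs ≥ 2 spliced reads whose inner
block edges match the annotated boundaries exactly (splice sites are
base-precise; a near-miss indicates a different isoform). Exclusion is
keyed on *total* exon count while support is required per *coding*
exon, so a validated UTR-plus-single-CDS-exon gene — the shape of one
planted intergenic de novo exemplar — can still be fully confirmed.
With strand-specific reads, ≥ 2 supporting reads on the wrong strand
cap the status at partially confirmed. The high-confidence set is the
SSOGs that are both traceable (not untraceable) and fully confirmed.
The "two spliced reads straddling such exons" criterion is read as
per-junction (the stricter reading); this is configurable.

## Synteny and orthologous regions

Anchors are best-reciprocal protein hits between the focal species and
each sister. Blocks are maximal collinear chains of anchors (greedy
longest-increasing-subsequence chaining per contig pair, both
orientations, ≥ 3 anchors). The orthologous region of a focal locus is
the interval between the orthologs of its flanking anchors; for a locus
inside a host gene's intron, it is the same-index intron (transcription
order) of the host's reciprocal-best ortholog. Both extractions return
a typed "no region" result rather than raising. Extracted intervals
are bounded by anchor gene edges, so they carry up to one intergenic
spacer of slack on either side — callers align into the region rather
than trusting its endpoints.

Spliced protein-to-genome alignment chains six-frame local alignments
under a segment DP with a +10 bonus for canonical GT..AG gaps ≥ 20 bp,
a −10 penalty for non-canonical gaps, and −2 for short gaps; windows
are capped at 200 kb (narrow via synteny first). The chain score is
exactly optimal over the extracted segments (verified against
exhaustive enumeration in tests), not over all possible segmentations.

## Origin-mechanism detectors

Detectors run in a fixed priority order — artifact screen,
heuristic-failure rescue, overprint, chimera, gene split, strand
switch, frame shift, de novo, unresolved — and the first supported call
wins, with modifiers preserved ("mixed origin"). The order encodes a
conservative stance: annotation artifacts and search failures must be
excluded before any evolutionary claim, and mechanisms that retain
ancestral frame or strand evidence outrank de novo birth.

- **Artifact**: the gene structure fails re-validation against the
  reads.
- **Heuristic failure**: an exhaustive (unseeded) local search of the
  syntenic interval at the relaxed threshold recovers a homologous
  segment that (i) overlaps an annotated sister gene on its own strand,
  (ii) whose gene has no reciprocal-best focal ortholog (the unpaired
  partner pattern), and (iii) that the standard genome-wide searches
  could not have found. The disqualifier (iii) runs at the standard
  thresholds: at the relaxed threshold everything is "discoverable" by
  chance, and the genuinely strong genomic traces of de novo candidates
  must not be mistaken for search failures. A firing rescue
  reclassifies the SSOG as a TROG at the partner's stratum.
- **Overprint**: a same-strand within-species transcript paralog
  (≥ 70% identity over ≥ 50% of the transcript — a recent duplicate,
  not a local repeat) whose annotated ORF is in a different frame, with
  both frames open in both copies over the shared interior (the ORFs'
  own terminal stops are not evidence of closure). A closed candidate
  frame in the paralog downgrades confidence to weak.
- **Chimera**: ≥ 2 exons align (per-exon translated queries at E ≤ 0.05
  against pooled sister proteomes) to *distinct genes of the same
  species*, with no single gene covering the whole protein. Comparing
  within one species matters: orthologs across species carry different
  identifiers but are one source.
- **Gene split**: the transcript maps, same strand at the nucleotide
  level, to a terminal part (prefix/suffix) of a sister gene while an
  adjacent focal gene maps to the complementary part (weak confidence
  without the partner). Exons with no homology anywhere gain a
  "de-novo-exon" modifier; a frame-shift modifier is attached when the
  frame DP (below) finds switches over the shared exon.
- **Frame shift** (also standalone): per-codon best-frame assignment of
  the protein against the three same-strand frames of the orthologous
  coding sequence, via a 3-state DP with a switch penalty of 8
  (≈ 1.5 average match scores: one spurious switch must cost more than
  a couple of chance matches can pay). The DP assumes rough
  collinearity (residue *i* near nucleotide 3*i*+f), which holds for
  the exon-scale comparisons it is applied to. Regions under 10 codons
  are "insufficient".
- **Strand switch**: the best relaxed translated hit in a sister genome
  (raw score ≥ 45 — below that, relaxed genome-wide hits are chance
  alignments regardless of where they fall) lies antisense to the
  annotated gene whose exon it overlaps. Supported at E ≤ 10⁻³, weak
  above.
- **De novo**: per sister species with an orthologous region, each CDS
  segment of the candidate is aligned into the region (per coding exon,
  one strand for all segments — aligning per exon keeps short first
  exons from being dropped when the region still carries the
  candidate's intron) and the region's sequence is read off in the
  candidate's frame: *intact*, *disrupted* (internal stop positions in
  1-based codon units), or *unalignable*. The call fires when ≥ 1
  species is disrupted or unalignable while the region aligns at the
  nucleotide level somewhere in the ingroup and sister regions show no
  transcription (any transcriptome hit overlapping the region counts;
  a missing transcriptome gives "unknown", which caps confidence at
  weak, as does having only a single alignable sister). The birth node
  is the MRCA of the intact-ORF species; the intronic/intergenic
  subtype comes from the focal annotation context.

## Selection analysis

Orthologous reading frames are extracted as above (in-frame stops are
masked as missing data with their codon positions recorded — a codon
model cannot host a stop state, but the stop positions are themselves
the de novo evidence and are reported). The codon model is MG94×HKY:
61 sense codons, rates κ-weighted for transitions and ω-weighted for
nonsynonymous changes, F1x4 equilibrium frequencies estimated from the
alignment, matrix scaled to one expected substitution per codon per
unit branch length. Likelihoods use Felsenstein pruning over
gap-cleaned, pattern-compressed columns; P(t) comes from the symmetric
eigendecomposition of the reversible generator. Optimization is
L-BFGS-B over log-parameters (branch lengths, κ, ω; bounds 10⁻⁶–20,
0.05–20, 10⁻⁴–50), with the alternative model started at the null
optimum so lnL_alt ≥ lnL_null holds by construction.

With one sister frame the model fits a single ω for the tree; with
more, one ω per branch (the rooted ladder subtopology over the included
taxa). The null hypothesis is ω = 1 (neutrality) for all tested
branches; the LRT statistic is referred to χ² with df = number of freed
ω parameters, significance at p < 0.05. Alignments with < 20 clean
codon columns, or with zero substitutions, return a typed
"insufficient data" result rather than an estimate. An NG86
(Nei–Gojobori pathway counting with Jukes–Cantor correction) estimator
provides an independent direction-of-selection check; ω is undefined
when dS = 0.

## The synthetic data: what it emulates and what it does not

The generator builds ten genomes on a ladder phylogeny (branch length
0.01 substitutions/site per step, so the focal-to-species-*k* distance
is 0.02 k) with collinear gene order, ~60 conserved families (two of
which are detectable only by translated search against the outgroup
genome, and two only in the broad knowledgebase — the step-2 and step-3
exemplars, which are longer so they clear the stricter translated
threshold for every carrier), two TROG families per stratum 1–9, a set
of SSOGs covering every trace category and structure status, and one
exemplar of each origin mechanism with the signature its detector
expects. Coding sequence evolves by HKY(κ = 2) substitution with
accept/reject steps that keep planted ORFs open; coding regions carry
no indels (so orthologous proteins are directly comparable
position-wise), intergenic spacers are independent random sequence per
species, and introns fall on codon boundaries. Reads are emitted
pre-aligned (SAM) — the validation criterion operates on alignments,
and embedding a read aligner would add nothing the criterion tests —
tiled so every CDS base reaches the configured depth, with junction
reads arising naturally from transcript-coordinate projection. There
is no sequencing-error model, no paired-end structure, and no
codon-usage realism.

Failure-mode plants are *calibrated*, not merely diverged: a
deterministic single-substitution walk moves each planted sequence
until its alignment score against its source sits in a prescribed
window (accepting only steps that keep the score above the window
floor, so the walk cannot overshoot). The chimera exons sit between
the per-exon detection floor and the whole-protein classification
ceiling against every carrier copy of their sources, including the
outgroup copy; the heuristic-failure pair sits just past the standard
thresholds but within reach of the relaxed in-interval rescue, with
repeat arms whose DNA stays nearly identical (a frame-nudging indel
scrambles their translation) so the nucleotide trace survives. This
calibration is the point of the exercise — the planted classes must be
unambiguous — but it is also the main caveat: real orphan genes are
not engineered to sit on the detectable side of thresholds, so recovery
rates on this data say "the machinery implements its definitions
exactly", not "these detectors would achieve this sensitivity on real
genomes". Two paper-described behaviors are intrinsically heuristic
artifacts of real BLAST (a 100%-identical short exon missed by the
whole-protein search; a repeat-rich pair missed despite strong local
similarity): an exact Smith–Waterman engine always finds such
alignments, so the corresponding plants are constructed as
borderline-score cases instead, which is the mechanism the rescue and
per-exon logic actually address.

Default study conditions: 10 species, ~93 focal genes, genome ≈ 47 kb
per species, read length 100 at depth 5, stranded. These sizes make a
full pipeline run take well under a minute while leaving every E-value
margin analyzed above intact; all sizes are configurable.

## Known limitations

- One best local alignment per query/subject pair (no HSP chaining
  across frames, no PSSMs, no composition-based statistics).
- The frame-shift DP anchors residue *i* at nucleotide 3*i*+f and so
  degrades over regions with many large indels.
- Branch lengths in the codon model are re-estimated from the data
  (the species-tree lengths are in amino-acid substitutions/site, the
  wrong units for a codon model); with two taxa only their sum is
  identifiable, which is harmless for the LRT but means individual
  pendant lengths are not interpretable.
- Per-branch ω on minimal alignments routinely hits the optimizer
  bounds for near-zero-substitution branches; the LRT remains valid,
  the individual ω values on such branches are not informative.
- The progressive protein aligner is reference-anchored and suited to
  the few closely related frames this pipeline compares, not to deep
  or many-sequence alignments.
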