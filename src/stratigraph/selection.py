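"""Selection analysis of candidate ORFs.

Orthologous reading frames (including in-frame stop codons, which are
masked as missing data with their positions recorded) are aligned at the
protein level, back-translated to codons, and fitted with a
Muse-Gaut/Goldman-Yang style codon model (MG94 x HKY, F1x4 codon
frequencies) by maximum likelihood with Felsenstein pruning.  The
alternative model frees one omega (dN/dS) for the whole tree or one per
branch; the null fixes omega = 1 (neutrality), and a likelihood-ratio
test with df = number of freed omega parameters gives the p-value.
An NG86 (Nei-Gojobori with Jukes-Cantor correction) counting estimator
serves as an independent sanity check on the direction of selection.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq
from scipy import optimize, stats

from . import homsearch as hs

STOPS = ("TAA", "TAG", "TGA")
NUCS = "TCAG"
CODONS = ["".join(c) for c in itertools.product(NUCS, repeat=3)
          if "".join(c) not in STOPS]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
AA_OF = {c: str(Seq(c).translate()) for c in CODONS}
N_CODONS = len(CODONS)  # 61


# ---------------------------------------------------------------------------
# Protein alignment (global, affine gaps, BLOSUM62)
# ---------------------------------------------------------------------------

def nw_align(a: str, b: str, gap_open: int = 11, gap_extend: int = 1
             ) -> tuple[str, str]:
    """Needleman-Wunsch global alignment with affine gaps; deterministic
    tie-break (diagonal > up > left)."""
    if not a or not b:
        raise ValueError("empty sequence")
    ea, eb = hs.encode_protein(a), hs.encode_protein(b)
    mat = hs.BLOSUM62
    m, n = len(a), len(b)
    NEG = -10 ** 7
    go = gap_open + gap_extend
    M = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    X = np.full((m + 1, n + 1), NEG, dtype=np.int64)  # gap in b (up)
    Y = np.full((m + 1, n + 1), NEG, dtype=np.int64)  # gap in a (left)
    M[0, 0] = 0
    for i in range(1, m + 1):
        X[i, 0] = -go - gap_extend * (i - 1)
    for j in range(1, n + 1):
        Y[0, j] = -go - gap_extend * (j - 1)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = mat[ea[i - 1], eb[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1],
                          Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - go, X[i - 1, j] - gap_extend)
            Y[i, j] = max(M[i, j - 1] - go, Y[i, j - 1] - gap_extend)
    out_a, out_b = [], []
    i, j = m, n
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            prev = int(np.argmax([M[i - 1, j - 1], X[i - 1, j - 1],
                                  Y[i - 1, j - 1]]))
            i, j, state = i - 1, j - 1, prev
        elif state == 1 and i > 0:
            out_a.append(a[i - 1])
            out_b.append("-")
            if X[i, j] == M[i - 1, j] - go:
                state = 0
            i -= 1
        elif j > 0:
            out_a.append("-")
            out_b.append(b[j - 1])
            if Y[i, j] == M[i, j - 1] - go:
                state = 0
            j -= 1
        else:
            state = 0 if i > 0 else 2
            if i > 0:
                state = 1
    return "".join(out_a[::-1]), "".join(out_b[::-1])


def align_proteins(seqs: dict[str, str]) -> dict[str, str]:
    """Progressive global alignment anchored on the lexicographically
    first identifier; suitable for the few closely related frames this
    pipeline compares."""
    ids = sorted(seqs)
    if len(ids) < 2:
        raise ValueError("need at least two sequences")
    for k, s in seqs.items():
        if not s:
            raise ValueError(f"empty sequence for {k}")
    ref_id = ids[0]
    ref = seqs[ref_id]
    # per-reference-position insertion widths across all pairwise aligns
    pair = {}
    ins = [0] * (len(ref) + 1)
    for other in ids[1:]:
        a, b = nw_align(ref, seqs[other].replace("*", "W"), 11, 1)
        # '*' scored as W (bulky, rare) to keep stops alignable; restore below
        bi = iter(seqs[other])
        b = "".join(next(bi) if c != "-" else "-" for c in b)
        pair[other] = (a, b)
        run, pos = 0, 0
        for c in a:
            if c == "-":
                run += 1
            else:
                ins[pos] = max(ins[pos], run)
                run, pos = 0, pos + 1
        ins[len(ref)] = max(ins[len(ref)], run)
    out = {}
    # build reference row
    row = []
    for p, c in enumerate(ref):
        row.append("-" * ins[p])
        row.append(c)
    row.append("-" * ins[len(ref)])
    out[ref_id] = "".join(row)
    for other in ids[1:]:
        a, b = pair[other]
        cols = []
        pos, run_chars = 0, []
        chunks = {p: [] for p in range(len(ref) + 1)}
        for ca, cb in zip(a, b):
            if ca == "-":
                chunks[pos].append(cb)
            else:
                chunks[pos].append(("anchor", cb))
                pos += 1
        orow = []
        p = 0
        for p in range(len(ref) + 1):
            inserted = [c for c in chunks[p] if not isinstance(c, tuple)]
            orow.append("".join(inserted).rjust(ins[p], "-"))
            anchors = [c[1] for c in chunks[p] if isinstance(c, tuple)]
            orow.extend(anchors)
        out[other] = "".join(orow)
    width = len(out[ref_id])
    assert all(len(v) == width for v in out.values())
    return out


# ---------------------------------------------------------------------------
# Codon alignment
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    rows: dict[str, str]  # codon-aligned nucleotides, '---' gaps
    masked_stops: dict[str, list[int]]  # 1-based codon columns per taxon
    taxa: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.taxa = sorted(self.rows)
        widths = {len(v) for v in self.rows.values()}
        if len(widths) != 1 or next(iter(widths)) % 3:
            raise ValueError("rows must share a length divisible by 3")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) // 3


def backtranslate(protein_alignment: dict[str, str],
                  cds_map: dict[str, str]) -> CodonAlignment:
    """Thread each CDS onto its aligned protein row (codon columns mirror
    protein columns x3); in-frame stop codons ('*' residues) are masked
    as missing data with their positions recorded."""
    rows, masked = {}, {}
    for name, aln in protein_alignment.items():
        cds = cds_map[name]
        res = aln.replace("-", "")
        if len(cds) == 3 * len(res) + 3 and cds[-3:] in STOPS:
            cds = cds[:-3]  # tolerate a trailing stop codon on the CDS
        if len(cds) != 3 * len(res):
            raise ValueError(
                f"row {name!r}: {len(res)} aligned residues need "
                f"{3 * len(res)} nt but CDS has {len(cds)}")
        out, masked[name] = [], []
        k = 0
        col = 0
        for c in aln:
            col += 1
            if c == "-":
                out.append("---")
                continue
            codon = cds[3 * k:3 * k + 3]
            if c == "*" or codon in STOPS:
                masked[name].append(col)
                out.append("---")
            else:
                out.append(codon)
            k += 1
        rows[name] = "".join(out)
    return CodonAlignment(rows, masked)


# ---------------------------------------------------------------------------
# MG94 x HKY machinery
# ---------------------------------------------------------------------------

def f1x4_codon_freqs(pi_nuc: np.ndarray) -> np.ndarray:
    pi = np.array([pi_nuc["TCAG".index(c[0])]
                   * pi_nuc["TCAG".index(c[1])]
                   * pi_nuc["TCAG".index(c[2])] for c in CODONS])
    return pi / pi.sum()


def nuc_freqs_from_alignment(aln: CodonAlignment) -> np.ndarray:
    counts = np.ones(4)
    for row in aln.rows.values():
        for c in row:
            i = "TCAG".find(c)
            if i >= 0:
                counts[i] += 1
    return counts / counts.sum()


def _rate_parts(kappa: float, pi_nuc: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """Q(omega) = S + omega*N: synonymous and nonsynonymous parts of the
    unscaled MG94 x HKY rate matrix."""
    S = np.zeros((N_CODONS, N_CODONS))
    N = np.zeros((N_CODONS, N_CODONS))
    transitions = {("T", "C"), ("C", "T"), ("A", "G"), ("G", "A")}
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            a, b = diffs[0]
            rate = pi_nuc["TCAG".index(b)]
            if (a, b) in transitions:
                rate *= kappa
            if AA_OF[ci] == AA_OF[cj]:
                S[i, j] = rate
            else:
                N[i, j] = rate
    return S, N


def codon_q(kappa: float, omega: float, pi_codon: np.ndarray,
            parts: tuple[np.ndarray, np.ndarray] | None = None,
            pi_nuc: np.ndarray | None = None,
            normalize: bool = True) -> np.ndarray:
    if parts is None:
        parts = _rate_parts(kappa, pi_nuc)
    S, N = parts
    Q = S + omega * N
    Q = Q - np.diag(Q.sum(axis=1))
    if normalize:
        mu = -(pi_codon * np.diag(Q)).sum()
        if mu > 0:
            Q = Q / mu
    return Q


def transition_matrix(Q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt) via symmetric eigendecomposition (Q reversible)."""
    d = np.sqrt(np.maximum(pi, 1e-12))
    B = (Q * d[:, None]) / d[None, :]
    w, U = np.linalg.eigh((B + B.T) / 2)
    P = (U * np.exp(w * t)) @ U.T
    P = P / d[:, None] * d[None, :]
    P = np.maximum(P, 0)
    return P / P.sum(axis=1, keepdims=True)


# --- tree plumbing ---------------------------------------------------------

@dataclass
class TreeNode:
    name: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    edge_id: int = -1  # index into the branch-parameter vectors

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        return [x for c in self.children for x in c.leaves()]


def two_taxon_tree(a: str, b: str) -> TreeNode:
    # one identifiable distance: put it all on one pendant edge
    root = TreeNode(children=[TreeNode(a), TreeNode(b)])
    return root


def ladder_subtree(taxa: list[str]) -> TreeNode:
    """Rooted ladder topology over taxa sorted by their numeric suffix
    (the induced species-tree shape on a pure ladder)."""
    order = sorted(taxa, key=lambda s: (len(s), s))
    node = TreeNode(order[0])
    for t in order[1:]:
        node = TreeNode(children=[node, TreeNode(t)])
    return node


def _index_edges(root: TreeNode) -> int:
    """Assign edge ids to all non-root nodes; returns the edge count."""
    counter = 0

    def walk(n: TreeNode, is_root: bool):
        nonlocal counter
        if not is_root:
            n.edge_id = counter
            counter += 1
        for c in n.children:
            walk(c, False)
    walk(root, True)
    return counter


# --- likelihood ------------------------------------------------------------

def _site_patterns(aln: CodonAlignment, taxa: list[str]
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Codon-state matrix (taxa x sites, -1 = missing) compressed to
    unique patterns with counts; columns with any missing data are
    dropped (cleandata)."""
    cols = []
    nc = aln.n_columns
    for s in range(nc):
        states = []
        for t in taxa:
            codon = aln.rows[t][3 * s:3 * s + 3]
            states.append(CODON_INDEX.get(codon, -1))
        if all(x >= 0 for x in states):
            cols.append(tuple(states))
    if not cols:
        return np.zeros((len(taxa), 0), dtype=int), np.zeros(0)
    uniq: dict[tuple, int] = {}
    for c in cols:
        uniq[c] = uniq.get(c, 0) + 1
    pats = np.array(sorted(uniq), dtype=int).T
    counts = np.array([uniq[tuple(pats[:, i])] for i in range(pats.shape[1])],
                      dtype=float)
    return pats, counts


def log_likelihood(root: TreeNode, taxa: list[str], pats: np.ndarray,
                   counts: np.ndarray, branch_lens: np.ndarray,
                   kappa: float, omegas: np.ndarray,
                   pi_codon: np.ndarray, pi_nuc: np.ndarray) -> float:
    """Felsenstein pruning over compressed site patterns."""
    parts = _rate_parts(kappa, pi_nuc)
    P_cache: dict[tuple[float, float], np.ndarray] = {}

    def P_for(edge_id: int) -> np.ndarray:
        w = float(omegas[edge_id])
        t = float(branch_lens[edge_id])
        key = (w, t)
        if key not in P_cache:
            Q = codon_q(kappa, w, pi_codon, parts=parts)
            P_cache[key] = transition_matrix(Q, pi_codon, t)
        return P_cache[key]

    tidx = {t: i for i, t in enumerate(taxa)}
    n_sites = pats.shape[1]

    def partial(node: TreeNode) -> np.ndarray:
        if not node.children:
            states = pats[tidx[node.name]]
            L = np.zeros((n_sites, N_CODONS))
            L[np.arange(n_sites), states] = 1.0
            return L
        L = np.ones((n_sites, N_CODONS))
        for c in node.children:
            Lc = partial(c)
            L = L * (Lc @ P_for(c.edge_id).T)
        return L
    site_like = partial(root) @ pi_codon
    site_like = np.maximum(site_like, 1e-300)
    return float(np.log(site_like) @ counts)


# --- fitting ---------------------------------------------------------------

@dataclass
class InsufficientData:
    reason: str


@dataclass
class FitFailure:
    reason: str
    best_lnl: float


@dataclass
class SelectionResult:
    mode: str  # 'single-omega' | 'per-branch'
    omegas: dict[str, float]  # branch label -> omega estimate
    kappa: float
    lnl_alt: float
    lnl_null: float
    lrt: float
    df: int
    p_value: float
    significant: bool
    n_columns: int
    null_hypothesis: str = "omega = 1 (neutrality)"


def _branch_labels(root: TreeNode) -> dict[int, str]:
    labels = {}

    def walk(n: TreeNode):
        if n.edge_id >= 0:
            labels[n.edge_id] = (n.name if n.name
                                 else "mrca(" + ",".join(sorted(n.leaves()))
                                 + ")")
        for c in n.children:
            walk(c)
    walk(root)
    return labels


def fit_omega(aln: CodonAlignment, mode: str = "auto",
              tree: TreeNode | None = None, alpha: float = 0.05,
              min_columns: int = 20
              ) -> SelectionResult | InsufficientData | FitFailure:
    """ML fit of the codon model with an LRT against omega = 1.

    ``mode``: 'auto' follows the design rule — a single omega when only
    one sister frame is present (two taxa), independent per-branch omegas
    otherwise.
    """
    taxa = aln.taxa
    if len(taxa) < 2:
        return InsufficientData("need at least two taxa")
    if tree is None:
        tree = (two_taxon_tree(*taxa) if len(taxa) == 2
                else ladder_subtree(taxa))
    n_edges = _index_edges(tree)
    pats, counts = _site_patterns(aln, taxa)
    n_cols = int(counts.sum())
    if n_cols < min_columns:
        return InsufficientData(
            f"only {n_cols} unmasked codon columns (< {min_columns})")
    rows = {t: "".join(CODONS[pats[i, j]] for j in range(pats.shape[1]))
            for i, t in enumerate(taxa)}
    if len(set(rows.values())) == 1:
        return InsufficientData("zero substitutions: omega unidentifiable")
    if mode == "auto":
        mode = "single-omega" if len(taxa) == 2 else "per-branch"
    pi_nuc = nuc_freqs_from_alignment(aln)
    pi_codon = f1x4_codon_freqs(pi_nuc)
    n_omega = 1 if mode == "single-omega" else n_edges

    def unpack(x, with_omega):
        bl = np.exp(x[:n_edges])
        kappa = math.exp(x[n_edges])
        if with_omega:
            om = np.exp(x[n_edges + 1:])
            omegas = np.repeat(om, n_edges) if len(om) == 1 else om
        else:
            omegas = np.ones(n_edges)
        return bl, kappa, omegas

    def negll(x, with_omega):
        bl, kappa, omegas = unpack(x, with_omega)
        return -log_likelihood(tree, taxa, pats, counts, bl, kappa,
                               omegas, pi_codon, pi_nuc)

    def fit(with_omega, x0):
        nb = n_edges + 1 + (n_omega if with_omega else 0)
        bounds = ([(math.log(1e-6), math.log(20.0))] * n_edges
                  + [(math.log(0.05), math.log(20.0))]
                  + [(math.log(1e-4), math.log(50.0))]
                  * (n_omega if with_omega else 0))
        best = None
        for start in x0:
            res = optimize.minimize(negll, start, args=(with_omega,),
                                    method="L-BFGS-B", bounds=bounds,
                                    options={"maxiter": 500})
            if best is None or res.fun < best.fun:
                best = res
        return best

    x_null0 = np.concatenate([np.log(np.full(n_edges, 0.1)),
                              [math.log(2.0)]])
    r_null = fit(False, [x_null0])
    x_alt0 = np.concatenate([r_null.x, np.zeros(n_omega)])  # omega = 1
    x_alt1 = np.concatenate([r_null.x, np.full(n_omega, math.log(0.3))])
    r_alt = fit(True, [x_alt0, x_alt1])
    lnl_null, lnl_alt = -r_null.fun, -r_alt.fun
    if lnl_alt < lnl_null - 1e-4:
        return FitFailure("optimizer failed to reach the null optimum",
                          best_lnl=lnl_alt)
    _, kappa, omegas = unpack(r_alt.x, True)
    labels = _branch_labels(tree)
    if mode == "single-omega":
        om = {"tree": float(np.exp(r_alt.x[n_edges + 1]))}
    else:
        om = {labels[i]: float(omegas[i]) for i in range(n_edges)}
    lrt = max(0.0, 2.0 * (lnl_alt - lnl_null))
    df = n_omega
    p = float(stats.chi2.sf(lrt, df))
    return SelectionResult(mode=mode, omegas=om, kappa=float(kappa),
                           lnl_alt=lnl_alt, lnl_null=lnl_null, lrt=lrt,
                           df=df, p_value=p, significant=p < alpha,
                           n_columns=n_cols)


# ---------------------------------------------------------------------------
# NG86 counting estimator
# ---------------------------------------------------------------------------

def _codon_sites(codon: str) -> tuple[float, float]:
    """Expected synonymous / nonsynonymous site counts for one codon."""
    syn = 0.0
    for pos in range(3):
        for b in "TCAG":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt in STOPS:
                continue
            if AA_OF[alt] == AA_OF[codon]:
                syn += 1 / 3
    return syn, 3 - syn


def _path_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Average synonymous / nonsynonymous differences over all orderings
    of the single-base steps between two codons (stop-free paths only)."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    results = []
    for perm in itertools.permutations(positions):
        cur = c1
        sd = nd = 0
        ok = True
        for pos in perm:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOPS:
                ok = False
                break
            if AA_OF[cur] == AA_OF[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    if not results:
        return 0.0, float(len(positions))
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


def ng86(cds1: str, cds2: str) -> dict:
    """Nei-Gojobori (1986) dN/dS with Jukes-Cantor correction; omega is
    None when dS = 0 (undefined)."""
    if len(cds1) != len(cds2):
        raise ValueError("codon sequences differ in length")
    if len(cds1) % 3:
        raise ValueError("length not a multiple of 3")
    S = N = Sd = Nd = 0.0
    for i in range(0, len(cds1), 3):
        a, b = cds1[i:i + 3], cds2[i:i + 3]
        if a in STOPS or b in STOPS:
            raise ValueError(f"stop codon at codon {i // 3 + 1}")
        sa, na = _codon_sites(a)
        sb, nb = _codon_sites(b)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        sd, nd = _path_diffs(a, b)
        Sd += sd
        Nd += nd

    def jc(p):
        if p <= 0:
            return 0.0
        if p >= 0.75:
            return float("inf")
        return -0.75 * math.log(1 - 4 * p / 3)
    dN = jc(Nd / N) if N else 0.0
    dS = jc(Sd / S) if S else 0.0
    omega = (dN / dS) if dS > 0 and math.isfinite(dS) else None
    return {"dN": dN, "dS": dS, "omega": omega, "Nd": Nd, "Sd": Sd,
            "N": N, "S": S}


# ---------------------------------------------------------------------------
# Simulation under the model (parameter-recovery harness)
# ---------------------------------------------------------------------------

def simulate_mg94_pair(n_codons: int, t: float, omega: float,
                       kappa: float, rng: np.random.Generator,
                       pi_nuc: np.ndarray | None = None
                       ) -> tuple[str, str]:
    """A codon-sequence pair separated by distance t (expected
    substitutions/codon) under MG94 x HKY."""
    if pi_nuc is None:
        pi_nuc = np.full(4, 0.25)
    pi_codon = f1x4_codon_freqs(pi_nuc)
    Q = codon_q(kappa, omega, pi_codon, pi_nuc=pi_nuc)
    P = transition_matrix(Q, pi_codon, t)
    anc = rng.choice(N_CODONS, size=n_codons, p=pi_codon)
    der = np.array([rng.choice(N_CODONS, p=P[a]) for a in anc])
    return ("".join(CODONS[i] for i in anc),
            "".join(CODONS[i] for i in der))


# ---------------------------------------------------------------------------
# PAML interop
# ---------------------------------------------------------------------------

def write_phylip_codon(aln: CodonAlignment) -> str:
    """PHYLIP-style codon alignment (sequential) for cross-running
    codeml."""
    lines = [f" {len(aln.taxa)} {aln.n_columns * 3}"]
    for t in aln.taxa:
        lines.append(f"{t[:30]:<32}{aln.rows[t]}")
    return "\n".join(lines) + "\n"
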