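"""Self-contained homology search engine (blastp/blastn/tblastn modes).

The engine reports, for every query/subject pair that survives the seed
stage, the full Smith-Waterman affine-gap optimum; the seed stage only
prunes pairs, it never changes a reported score.  Significance follows
Karlin-Altschul statistics, E = K * m * n * exp(-lambda * S), with raw
m * n (no effective-length correction) so thresholds are interpreted
consistently at desk scale.  The published gapped defaults are used as
engine constants: BLOSUM62 11/1 (lambda=0.267, K=0.041) and +2/-3 5/2
(lambda=0.625, K=0.41).

A gap of length L costs gap_open + gap_extend * L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from numba import njit

from .core_model import HomologyHit

# --- alphabets and scoring matrices ----------------------------------------

PROTEIN_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
NUCL_ALPHABET = "ACGTN"
IUPAC_NUCL = set("ACGTUNRYSWKMBDHVacgtunryswkmbdhv")

_P_INDEX = {c: i for i, c in enumerate(PROTEIN_ALPHABET)}
_N_INDEX = {c: i for i, c in enumerate(NUCL_ALPHABET)}


def _blosum62() -> np.ndarray:
    m = substitution_matrices.load("BLOSUM62")
    n = len(PROTEIN_ALPHABET)
    out = np.zeros((n, n), dtype=np.int32)
    for i, a in enumerate(PROTEIN_ALPHABET):
        for j, b in enumerate(PROTEIN_ALPHABET):
            out[i, j] = int(m[a][b])
    return out


def _nucl_matrix(match: int = 2, mismatch: int = -3) -> np.ndarray:
    n = len(NUCL_ALPHABET)
    out = np.full((n, n), mismatch, dtype=np.int32)
    np.fill_diagonal(out, match)
    out[_N_INDEX["N"], :] = 0
    out[:, _N_INDEX["N"]] = 0
    return out


BLOSUM62 = _blosum62()
NUCL_MATRIX = _nucl_matrix()


def encode_protein(seq: str) -> np.ndarray:
    idx = _P_INDEX
    try:
        return np.array([idx[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as e:
        raise ValueError(f"non-protein character {e.args[0]!r}") from None


def encode_nucl(seq: str) -> np.ndarray:
    idx = _N_INDEX
    return np.array([idx.get(c, idx["N"]) for c in seq.upper()],
                    dtype=np.int8)


# --- parameters ------------------------------------------------------------

@dataclass
class SearchParams:
    mode: str  # 'blastp' | 'blastn' | 'tblastn'
    gap_open: int
    gap_extend: int
    e_value_threshold: float
    inclusive: bool = True  # hit kept iff E <= threshold (else strictly <)
    seed_word_size: int = 3
    use_seeding: bool = True
    low_complexity_filter: bool = False  # off by default, deliberately
    lam: float = 0.267
    K: float = 0.041

    @staticmethod
    def protein(e_value_threshold: float = 1e-3, **kw) -> "SearchParams":
        return SearchParams(mode="blastp", gap_open=11, gap_extend=1,
                            e_value_threshold=e_value_threshold,
                            seed_word_size=3, lam=0.267, K=0.041, **kw)

    @staticmethod
    def nucl(e_value_threshold: float = 1e-3, **kw) -> "SearchParams":
        return SearchParams(mode="blastn", gap_open=5, gap_extend=2,
                            e_value_threshold=e_value_threshold,
                            seed_word_size=11, lam=0.625, K=0.41, **kw)

    @staticmethod
    def translated(e_value_threshold: float = 1e-5, **kw) -> "SearchParams":
        return SearchParams(mode="tblastn", gap_open=11, gap_extend=1,
                            e_value_threshold=e_value_threshold,
                            seed_word_size=3, lam=0.267, K=0.041, **kw)

    @property
    def matrix(self) -> np.ndarray:
        return NUCL_MATRIX if self.mode == "blastn" else BLOSUM62


RELAXED_E = 10.0  # the rescue threshold, applied strictly (E < 10)


def relaxed(params: SearchParams) -> SearchParams:
    return replace(params, e_value_threshold=RELAXED_E, inclusive=False)


# --- Smith-Waterman kernels ------------------------------------------------

@njit(cache=True)
def _sw_score(q, s, mat, gap_open, gap_ext):
    """Best local score and its end cell (1-based ends)."""
    m, n = len(q), len(s)
    NEG = -10 ** 7
    H = np.zeros(n + 1, dtype=np.int32)   # previous row of H
    F = np.full(n + 1, NEG, dtype=np.int32)  # vertical gap state per column
    best = 0
    bi = 0
    bj = 0
    go = gap_open + gap_ext
    for i in range(1, m + 1):
        qi = q[i - 1]
        hdiag = H[0]
        hleft = 0
        e = NEG
        for j in range(1, n + 1):
            e = max(hleft - go, e - gap_ext)
            F[j] = max(H[j] - go, F[j] - gap_ext)
            h = hdiag + mat[qi, s[j - 1]]
            if e > h:
                h = e
            if F[j] > h:
                h = F[j]
            if h < 0:
                h = 0
            hdiag = H[j]
            H[j] = h
            hleft = h
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj


@njit(cache=True)
def _sw_full(q, s, mat, gap_open, gap_ext):
    """Full DP with traceback.

    Returns (score, qstart, qend, sstart, send, matches, aln_len),
    intervals 0-based half-open on query/subject.
    """
    m, n = len(q), len(s)
    NEG = -10 ** 7
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    # pointers: 0 stop, 1 diag, 2 up(gap in subject), 3 left(gap in query)
    ptr = np.zeros((m + 1, n + 1), dtype=np.int8)
    go = gap_open + gap_ext
    best, bi, bj = 0, 0, 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            E[i, j] = max(H[i, j - 1] - go, E[i, j - 1] - gap_ext)
            F[i, j] = max(H[i - 1, j] - go, F[i - 1, j] - gap_ext)
            d = H[i - 1, j - 1] + mat[qi, s[j - 1]]
            h, p = 0, 0
            if d > h:
                h, p = d, 1
            if F[i, j] > h:
                h, p = F[i, j], 2
            if E[i, j] > h:
                h, p = E[i, j], 3
            H[i, j] = h
            ptr[i, j] = p
            if h > best:
                best, bi, bj = h, i, j
    # traceback
    i, j = bi, bj
    matches = 0
    aln = 0
    while i > 0 and j > 0 and H[i, j] > 0 and ptr[i, j] != 0:
        p = ptr[i, j]
        aln += 1
        if p == 1:
            if q[i - 1] == s[j - 1]:
                matches += 1
            i -= 1
            j -= 1
        elif p == 2:
            i -= 1
        else:
            j -= 1
    return best, i, bi, j, bj, matches, aln


def sw_align(q: np.ndarray, s: np.ndarray, mat: np.ndarray,
             gap_open: int, gap_extend: int):
    """Python-facing wrapper around the traceback kernel."""
    return _sw_full(q, s, mat, gap_open, gap_extend)


@njit(cache=True)
def _sw_path(q, s, mat, gap_open, gap_ext):
    """Like _sw_full but additionally returns, for every query position,
    the subject position aligned to it (-1 where gapped/unaligned)."""
    m, n = len(q), len(s)
    NEG = -10 ** 7
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    ptr = np.zeros((m + 1, n + 1), dtype=np.int8)
    go = gap_open + gap_ext
    best, bi, bj = 0, 0, 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            E[i, j] = max(H[i, j - 1] - go, E[i, j - 1] - gap_ext)
            F[i, j] = max(H[i - 1, j] - go, F[i - 1, j] - gap_ext)
            d = H[i - 1, j - 1] + mat[qi, s[j - 1]]
            h, p = 0, 0
            if d > h:
                h, p = d, 1
            if F[i, j] > h:
                h, p = F[i, j], 2
            if E[i, j] > h:
                h, p = E[i, j], 3
            H[i, j] = h
            ptr[i, j] = p
            if h > best:
                best, bi, bj = h, i, j
    qmap = np.full(m, -1, dtype=np.int32)
    i, j = bi, bj
    while i > 0 and j > 0 and H[i, j] > 0 and ptr[i, j] != 0:
        p = ptr[i, j]
        if p == 1:
            qmap[i - 1] = j - 1
            i -= 1
            j -= 1
        elif p == 2:
            i -= 1
        else:
            j -= 1
    return best, i, bi, j, bj, qmap


def sw_map(query: str, subject: str, nucl: bool = True,
           params: SearchParams | None = None):
    """Best local alignment with a per-query-position subject map.

    Returns (score, (qs, qe), (ss, se), qmap) where qmap[i] is the
    subject index aligned to query position i, or -1.
    """
    if params is None:
        params = SearchParams.nucl() if nucl else SearchParams.protein()
    enc = encode_nucl if nucl else encode_protein
    score, qs, qe, ss, se, qmap = _sw_path(
        enc(query), enc(subject), params.matrix,
        params.gap_open, params.gap_extend)
    return score, (qs, qe), (ss, se), qmap


# --- six-frame translation -------------------------------------------------

def translate_six_frames(nucl: str) -> dict[int, str]:
    """Translations of all six frames, keyed +1,+2,+3,-1,-2,-3.

    Stops render as '*'.  Trailing partial codons are dropped.
    """
    if len(nucl) < 3:
        raise ValueError("sequence shorter than one codon")
    bad = set(nucl) - IUPAC_NUCL
    if bad:
        raise ValueError(f"non-IUPAC nucleotide characters: {sorted(bad)}")
    fwd = nucl.upper().replace("U", "T")
    rev = str(Seq(fwd).reverse_complement())
    out = {}
    for f in (1, 2, 3):
        for strand, seq in ((f, fwd), (-f, rev)):
            sub = seq[f - 1:]
            sub = sub[: len(sub) - len(sub) % 3]
            out[strand] = str(Seq(sub).translate()) if sub else ""
    return out


def frame_to_genomic(frame: int, aa_start: int, aa_end: int,
                     nucl_len: int) -> tuple[int, int]:
    """Map an amino-acid interval on a frame translation to forward-strand
    genomic coordinates (0-based half-open)."""
    if frame > 0:
        off = frame - 1
        return off + 3 * aa_start, off + 3 * aa_end
    off = -frame - 1
    return nucl_len - off - 3 * aa_end, nucl_len - off - 3 * aa_start


# --- seeding ---------------------------------------------------------------

def _words(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _shares_word(q: str, s: str, k: int) -> bool:
    if len(q) < k or len(s) < k:
        return True  # too short to seed; fall through to full DP
    return not _words(q, k).isdisjoint(_words(s, k))


# --- low-complexity masking (optional, off by default) ---------------------

def mask_low_complexity(seq: str, window: int = 12,
                        max_entropy: float = 1.6) -> str:
    """Replace residues in low-entropy windows with 'X' (a minimal
    SEG-like filter; the reference configuration leaves it off)."""
    marks = [False] * len(seq)
    for i in range(0, max(1, len(seq) - window + 1)):
        w = seq[i:i + window]
        counts = {c: w.count(c) for c in set(w)}
        ent = -sum(c / len(w) * math.log2(c / len(w)) for c in counts.values())
        if ent <= max_entropy:
            for j in range(i, i + len(w)):
                marks[j] = True
    return "".join("X" if m else c for c, m in zip(seq, marks))


# --- the search ------------------------------------------------------------

def _evalue(params: SearchParams, m: int, n: int, score: float) -> float:
    return params.K * m * n * math.exp(-params.lam * score)


def bit_score(params: SearchParams, score: float) -> float:
    return (params.lam * score - math.log(params.K)) / math.log(2)


def min_score_for(params: SearchParams, m: int, n: int) -> float:
    """Smallest raw score whose E-value passes the threshold."""
    return math.log(params.K * m * n / params.e_value_threshold) / params.lam


def search(queries: list[tuple[str, str]],
           subject_db: list[tuple[str, str]],
           params: SearchParams,
           subject_db_kind: str = "",
           n_override: int | None = None) -> list[HomologyHit]:
    """Best local alignment per query/subject pair, thresholded on E-value.

    ``queries``/``subject_db`` are (id, sequence) lists; hits come back
    sorted by (E-value, query_id, subject_id).  blastn scans both subject
    strands; tblastn scans all six subject frames and reports the frame
    and the forward-strand genomic interval of the hit.
    """
    if not queries or any(not s for _, s in queries):
        raise ValueError("empty query")
    ids = [i for i, _ in subject_db]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate IDs in subject database")

    if params.mode == "blastp":
        n_total = sum(len(s) for _, s in subject_db)
    elif params.mode == "blastn":
        n_total = 2 * sum(len(s) for _, s in subject_db)
    elif params.mode == "tblastn":
        n_total = sum(6 * (len(s) // 3) for _, s in subject_db)
    else:
        raise ValueError(f"unknown mode {params.mode!r}")
    if n_override is not None:
        # E-values computed as if the subject were part of a larger
        # database (e.g. several species' proteins searched separately
        # but thresholded jointly, as a concatenated database would be)
        n_total = n_override
    n_total = max(n_total, 1)

    mat = params.matrix
    hits: list[HomologyHit] = []
    for qid, qseq in queries:
        if params.mode != "blastn" and params.low_complexity_filter:
            qseq = mask_low_complexity(qseq)
        m = len(qseq)
        smin = min_score_for(params, m, n_total)
        qenc = (encode_nucl(qseq) if params.mode == "blastn"
                else encode_protein(qseq))
        for sid, sseq in subject_db:
            if params.mode == "blastp":
                cands = [(sseq, 0, "+")]
            elif params.mode == "blastn":
                cands = [(sseq, 0, "+"),
                         (str(Seq(sseq).reverse_complement()), 0, "-")]
            else:
                frames = translate_six_frames(sseq)
                cands = [(aa, f, "+" if f > 0 else "-")
                         for f, aa in sorted(frames.items(), reverse=True)
                         if aa]
            best = None
            for text, frame, strand in cands:
                if params.use_seeding and not _shares_word(
                        qseq, text, params.seed_word_size):
                    continue
                senc = (encode_nucl(text) if params.mode == "blastn"
                        else encode_protein(text))
                if len(senc) == 0:
                    continue
                score, _bi, _bj = _sw_score(qenc, senc, mat,
                                            params.gap_open,
                                            params.gap_extend)
                if score < smin or score <= 0:
                    continue
                if best is None or score > best[0]:
                    best = (score, text, frame, strand, senc)
            if best is None:
                continue
            score, text, frame, strand, senc = best
            (score, qs, qe, ss, se, matches, aln) = _sw_full(
                qenc, senc, mat, params.gap_open, params.gap_extend)
            ev = _evalue(params, m, n_total, score)
            ok = (ev <= params.e_value_threshold if params.inclusive
                  else ev < params.e_value_threshold)
            if not ok:
                continue
            if params.mode == "tblastn":
                s_int = frame_to_genomic(frame, ss, se, len(sseq))
            elif params.mode == "blastn" and strand == "-":
                s_int = (len(sseq) - se, len(sseq) - ss)
            else:
                s_int = (ss, se)
            hits.append(HomologyHit(
                query_id=qid, subject_id=sid, mode=params.mode,
                bit_score=round(bit_score(params, score), 2),
                raw_score=float(score), e_value=ev,
                pct_identity=100.0 * matches / max(aln, 1),
                query_interval=(qs, qe), subject_interval=s_int,
                subject_frame=frame if params.mode == "tblastn" else 0,
                subject_strand=strand,
                subject_db_kind=subject_db_kind))
    hits.sort(key=lambda h: (h.e_value, h.query_id, h.subject_id))
    return hits


def best_hits_by_query(hits: list[HomologyHit]) -> dict[str, HomologyHit]:
    out: dict[str, HomologyHit] = {}
    for h in hits:
        if h.query_id not in out or h.e_value < out[h.query_id].e_value:
            out[h.query_id] = h
    return out


# --- BLAST tabular interop (external-engine escape hatch) ------------------

def read_outfmt6(text: str, mode: str, subject_db_kind: str = ""
                 ) -> list[HomologyHit]:
    """Parse BLAST tabular (outfmt 6) rows into HomologyHits, for users
    who ran a real engine on real genomes."""
    hits = []
    for line in text.strip().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        qs, qe = int(f[6]) - 1, int(f[7])
        ss, se = int(f[8]) - 1, int(f[9])
        strand = "+"
        if ss > se - 2 and int(f[8]) > int(f[9]):
            ss, se = int(f[9]) - 1, int(f[8])
            strand = "-"
        hits.append(HomologyHit(
            query_id=f[0], subject_id=f[1], mode=mode,
            bit_score=float(f[11]), raw_score=float(f[11]),
            e_value=float(f[10]), pct_identity=float(f[2]),
            query_interval=(qs, qe), subject_interval=(ss, se),
            subject_frame=(1 if strand == "+" else -1) if mode == "tblastn" else 0,
            subject_strand=strand, subject_db_kind=subject_db_kind))
    return hits


def write_outfmt6(hits: list[HomologyHit]) -> str:
    rows = []
    for h in hits:
        qs, qe = h.query_interval
        ss, se = h.subject_interval
        if h.subject_strand == "-":
            sa, sb = se, ss + 1
        else:
            sa, sb = ss + 1, se
        rows.append("\t".join(map(str, [
            h.query_id, h.subject_id, f"{h.pct_identity:.2f}",
            qe - qs, 0, 0, qs + 1, qe, sa, sb,
            f"{h.e_value:.2e}", f"{h.bit_score:.1f}"])))
    return "\n".join(rows) + ("\n" if rows else "")
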