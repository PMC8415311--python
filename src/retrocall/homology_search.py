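"""Protein-vs-genome and nucleotide alignment.

The builtin engine is an exhaustive three-frame local aligner: each protein
query is aligned with affine-gap Smith-Waterman (Gotoh) against all six
translation frames of the genome, scanned in overlapping windows to bound
memory.  No seeding or indexing heuristics are used — every DP cell is
computed — which keeps the engine exact at desk scale; an external aligner
(e.g. LAST) can be substituted through the tabular adapter for large genomes.

Frameshifted retrocopies are deliberately *not* modelled within a single hit:
the post-shift region aligns in a different frame and surfaces as a second
hit at the same locus, which the caller's merge step (gap <= 40 bp)
reconstitutes.

Scoring defaults follow common protein-search practice: BLOSUM62 with gap
cost ``gap_open + gap_extend * L`` for a gap of length L (11 + L).
"""

from __future__ import annotations

import logging
import shutil
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from numba import njit

from .genome_io import GenomeSequence, ProteinQuery, revcomp

log = logging.getLogger("retrocall")

__all__ = [
    "AlignerConfig",
    "AlignmentHit",
    "NucleotideAlignment",
    "AlignmentError",
    "align_proteins_to_genome",
    "three_frame_align",
    "align_dna",
    "parse_external_tab",
    "write_external_tab",
    "run_external_aligner",
]


class AlignmentError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Alphabet and scoring
# ---------------------------------------------------------------------------

_AA = "ARNDCQEGHILKMFPSTWYVBZX*"
_MASK_CODE = len(_AA)  # code for masked-out target positions
_AA_TO_CODE = np.full(128, _AA.index("X"), dtype=np.int8)
for _i, _c in enumerate(_AA):
    _AA_TO_CODE[ord(_c)] = _i


def _build_matrix(name: str = "BLOSUM62") -> np.ndarray:
    m = substitution_matrices.load(name)
    size = len(_AA) + 1
    mat = np.full((size, size), -4, dtype=np.int16)
    for i, a in enumerate(_AA):
        for j, b in enumerate(_AA):
            try:
                mat[i, j] = int(m[a, b])
            except KeyError:
                mat[i, j] = -4
    mat[_MASK_CODE, :] = -10_000
    mat[:, _MASK_CODE] = -10_000
    return mat


_MATRICES: dict[str, np.ndarray] = {}


def get_matrix(name: str = "BLOSUM62") -> np.ndarray:
    if name not in _MATRICES:
        _MATRICES[name] = _build_matrix(name)
    return _MATRICES[name]


def encode_protein(seq: str) -> np.ndarray:
    return _AA_TO_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class AlignerConfig:
    """Scoring and scanning parameters for the builtin engine."""

    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    min_score: int = 50          # matrix units; hits below are not reported
    window: int = 100_000        # bp per genome window
    overlap: int = 1_000         # bp shared between adjacent windows
    max_hits_per_frame: int = 100
    # nucleotide alignment defaults (align_dna)
    dna_match: int = 2
    dna_mismatch: int = -3
    dna_gap_open: int = 5
    dna_gap_extend: int = 2


# ---------------------------------------------------------------------------
# Hit records
# ---------------------------------------------------------------------------

@dataclass
class AlignmentHit:
    """One protein-vs-genome local alignment.

    ``blocks`` lists gapless segments as ((q_aa_start, q_aa_end),
    (g_bp_start, g_bp_end)); all coordinates 0-based half-open, genome
    coordinates on the forward strand regardless of hit strand.
    """

    query_id: str
    chrom: str
    g_start: int
    g_end: int
    strand: str
    q_start: int
    q_end: int
    identity: float
    aligned_columns: int
    score: int
    q_len: int
    blocks: list[tuple[tuple[int, int], tuple[int, int]]] = field(default_factory=list)


@dataclass
class NucleotideAlignment:
    """A pairwise local DNA alignment with gapped strings."""

    a_aligned: str
    b_aligned: str
    identity: float
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    score: float


# ---------------------------------------------------------------------------
# Gotoh local DP kernel (numba)
# ---------------------------------------------------------------------------
#
# Pointer byte layout per cell: bits 0-1 = H source (0 none, 1 diagonal,
# 2 horizontal gap E, 3 vertical gap F); bit 2 = E extends E; bit 3 = F
# extends F.  Ties prefer diagonal, then E, then F (deterministic).

@njit(cache=True)
def _gotoh_best(q, t, mat, go, ge):  # pragma: no cover - exercised via wrappers
    """Score-only pass: best local score and its end cell."""
    n = q.shape[0]
    m = t.shape[0]
    H = np.zeros(m + 1, dtype=np.int32)
    F = np.full(m + 1, -1_000_000, dtype=np.int32)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        diag = 0
        e = -1_000_000
        for j in range(1, m + 1):
            hup = H[j]
            e = max(e - ge, H[j - 1] - go - ge)
            F[j] = max(F[j] - ge, hup - go - ge)
            h = diag + mat[qi, t[j - 1]]
            if e > h:
                h = e
            if F[j] > h:
                h = F[j]
            if h < 0:
                h = 0
            diag = hup
            H[j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj


@njit(cache=True)
def _gotoh_ptr(q, t, mat, go, ge, ptr):  # pragma: no cover - exercised via wrappers
    n = q.shape[0]
    m = t.shape[0]
    H = np.zeros(m + 1, dtype=np.int32)
    F = np.full(m + 1, -1_000_000, dtype=np.int32)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        diag = 0
        e = -1_000_000
        for j in range(1, m + 1):
            hup = H[j]
            # E: gap consuming target (horizontal)
            e_open = H[j - 1] - go - ge
            e_ext = e - ge
            if e_ext > e_open:
                e = e_ext
                eflag = 4
            else:
                e = e_open
                eflag = 0
            # F: gap consuming query (vertical)
            f_open = hup - go - ge
            f_ext = F[j] - ge
            if f_ext > f_open:
                F[j] = f_ext
                fflag = 8
            else:
                F[j] = f_open
                fflag = 0
            h = diag + mat[qi, t[j - 1]]
            src = 1
            if e >= h:
                h = e
                src = 2
            if F[j] > h:
                h = F[j]
                src = 3
            d = diag + mat[qi, t[j - 1]]
            if d >= h:
                h = d
                src = 1
            if h <= 0:
                h = 0
                src = 0
            ptr[i - 1, j - 1] = src | eflag | fflag
            diag = hup
            H[j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj


def _traceback(qcodes, tcodes, ptr, bi, bj):
    """Walk pointers from the best cell; returns (q0, t0, columns) where
    columns is a list of (qi, tj) with -1 marking a gap on that axis."""
    i, j = bi, bj
    cols: list[tuple[int, int]] = []
    state = 0  # 0=H, 1=E, 2=F
    while i > 0 and j > 0:
        p = ptr[i - 1, j - 1]
        if state == 0:
            src = p & 3
            if src == 0:
                break
            if src == 1:
                cols.append((i - 1, j - 1))
                i -= 1
                j -= 1
            elif src == 2:
                state = 1
            else:
                state = 2
        elif state == 1:  # E consumed t[j-1]
            cols.append((-1, j - 1))
            ext = p & 4
            j -= 1
            state = 1 if ext else 0
        else:  # F consumed q[i-1]
            cols.append((i - 1, -1))
            ext = p & 8
            i -= 1
            state = 2 if ext else 0
    cols.reverse()
    return i, j, cols


def _hits_in_frame(qcodes, frame_codes, cfg, max_hits):
    """All local hits of one query against one translated frame, found by
    best-hit extraction and masking until the score drops below threshold.

    Returns a list of (score, q0, q1, t0, t1, identity, columns, blocks)
    with t-coordinates in frame (aa) space.
    """
    mat = get_matrix(cfg.matrix)
    n, m = len(qcodes), len(frame_codes)
    if n == 0 or m == 0:
        return []
    # cheap score-only prescreen: most windows hold no hit at all
    best, _, _ = _gotoh_best(qcodes, frame_codes, mat, cfg.gap_open, cfg.gap_extend)
    if best < cfg.min_score:
        return []
    t = frame_codes.copy()
    ptr = np.empty((n, m), dtype=np.uint8)
    out = []
    for _ in range(max_hits):
        score, bi, bj = _gotoh_ptr(qcodes, t, mat, cfg.gap_open, cfg.gap_extend, ptr)
        if score < cfg.min_score:
            break
        q0, t0, cols = _traceback(qcodes, t, ptr, bi, bj)
        if not cols:
            break
        ident = sum(
            1
            for qi, tj in cols
            if qi >= 0 and tj >= 0 and qcodes[qi] == t[tj] and qcodes[qi] != _MASK_CODE
        )
        # gapless blocks: maximal runs of diagonal columns
        blocks = []
        run_q = run_t = None
        prev_q = prev_t = None
        for qi, tj in cols:
            if qi >= 0 and tj >= 0:
                if run_q is None:
                    run_q, run_t = qi, tj
                prev_q, prev_t = qi, tj
            else:
                if run_q is not None:
                    blocks.append(((run_q, prev_q + 1), (run_t, prev_t + 1)))
                    run_q = run_t = None
        if run_q is not None:
            blocks.append(((run_q, prev_q + 1), (run_t, prev_t + 1)))
        identity = 100.0 * ident / len(cols)
        out.append((int(score), q0, bi, t0, bj, identity, len(cols), blocks))
        t[t0:bj] = _MASK_CODE
    return out


# ---------------------------------------------------------------------------
# Frame translation and coordinate mapping
# ---------------------------------------------------------------------------

def _translate_frames(dna: str):
    """Yield (strand, frame, aa_string) for all six frames of *dna*."""
    rc = revcomp(dna)
    for strand, s in (("+", dna), ("-", rc)):
        for f in range(3):
            sub = s[f:]
            sub = sub[: len(sub) - len(sub) % 3]
            if len(sub) < 3:
                continue
            yield strand, f, str(Seq(sub).translate())


def _frame_to_genome(strand: str, frame: int, win_start: int, win_len: int,
                     t0: int, t1: int) -> tuple[int, int]:
    """Map a frame-space aa interval [t0, t1) to forward-strand genome bp."""
    if strand == "+":
        return win_start + frame + 3 * t0, win_start + frame + 3 * t1
    return (
        win_start + win_len - frame - 3 * t1,
        win_start + win_len - frame - 3 * t0,
    )


def _window_frames(dna: str) -> list[tuple[str, int, np.ndarray]]:
    """Translate and encode all six frames of a window once."""
    return [
        (strand, frame, encode_protein(aa)) for strand, frame, aa in _translate_frames(dna)
    ]


def _query_vs_frames(
    query: ProteinQuery,
    qcodes: np.ndarray,
    frames: list[tuple[str, int, np.ndarray]],
    dna_len: int,
    cfg: AlignerConfig,
    chrom: str,
    offset: int,
) -> list[AlignmentHit]:
    hits: list[AlignmentHit] = []
    for strand, frame, frame_codes in frames:
        for (score, q0, q1, t0, t1, identity, ncols, blocks) in _hits_in_frame(
            qcodes, frame_codes, cfg, cfg.max_hits_per_frame
        ):
            g0, g1 = _frame_to_genome(strand, frame, offset, dna_len, t0, t1)
            gblocks = []
            for (qa, qb), (ta, tb) in blocks:
                gb = _frame_to_genome(strand, frame, offset, dna_len, ta, tb)
                gblocks.append(((qa, qb), gb))
            gblocks.sort(key=lambda b: b[1][0])
            hits.append(
                AlignmentHit(
                    query_id=query.gene_id,
                    chrom=chrom,
                    g_start=g0,
                    g_end=g1,
                    strand=strand,
                    q_start=q0,
                    q_end=q1,
                    identity=identity,
                    aligned_columns=ncols,
                    score=score,
                    q_len=len(query.protein),
                    blocks=gblocks,
                )
            )
    hits.sort(key=lambda h: (h.chrom, h.g_start, h.query_id, h.strand))
    return hits


def three_frame_align(
    query: ProteinQuery,
    dna: str,
    cfg: AlignerConfig | None = None,
    chrom: str = "seq",
    offset: int = 0,
) -> list[AlignmentHit]:
    """Align one protein against all six frames of a DNA segment.

    ``offset`` shifts reported genome coordinates (the segment is treated as
    ``chrom[offset : offset + len(dna)]``).
    """
    cfg = cfg or AlignerConfig()
    frames = _window_frames(dna)
    return _query_vs_frames(
        query, encode_protein(query.protein), frames, len(dna), cfg, chrom, offset
    )


def align_proteins_to_genome(
    queries: list[ProteinQuery] | dict[str, ProteinQuery],
    genome: GenomeSequence,
    cfg: AlignerConfig | None = None,
    engine: str = "builtin",
    external_tab: str | Path | None = None,
) -> list[AlignmentHit]:
    """Protein queries vs whole genome, both strands, deterministic order.

    ``engine='builtin'`` runs the exhaustive three-frame scanner in
    overlapping windows; ``engine='external'`` loads a precomputed adapter
    table (see :func:`parse_external_tab`).
    """
    cfg = cfg or AlignerConfig()
    if isinstance(queries, dict):
        queries = list(queries.values())
    if not queries:
        raise ValueError("empty query set")
    if engine == "external":
        if external_tab is None:
            raise AlignmentError(
                "engine='external' requires a precomputed alignment table "
                "(see parse_external_tab for the 12-column schema)"
            )
        return parse_external_tab(external_tab)
    if engine != "builtin":
        raise AlignmentError(f"unknown alignment engine {engine!r}")

    hits: list[AlignmentHit] = []
    step = max(cfg.window - cfg.overlap, 1)
    qcodes = {q.gene_id: encode_protein(q.protein) for q in queries}
    for chrom, seq in genome.sequences.items():
        for win_start in range(0, max(len(seq) - cfg.overlap, 1), step):
            window = seq[win_start : win_start + cfg.window]
            if len(window) < 3:
                continue
            frames = _window_frames(window)
            for q in queries:
                hits.extend(
                    _query_vs_frames(
                        q, qcodes[q.gene_id], frames, len(window), cfg, chrom, win_start
                    )
                )
    # windows overlap: deduplicate identical hits
    seen = set()
    unique = []
    for h in sorted(hits, key=lambda h: (h.chrom, h.g_start, h.query_id, h.strand, -h.score)):
        key = (h.query_id, h.chrom, h.strand, h.g_start, h.g_end, h.q_start, h.q_end)
        if key in seen:
            continue
        seen.add(key)
        unique.append(h)
    unique.sort(key=lambda h: (h.chrom, h.g_start, h.query_id))
    return unique


# ---------------------------------------------------------------------------
# External aligner adapter (12-column TSV)
# ---------------------------------------------------------------------------

_TAB_COLUMNS = [
    "query_id", "chrom", "strand", "q_start", "q_end", "g_start", "g_end",
    "identity", "aligned_columns", "score", "q_len", "blocks",
]


def run_external_aligner(binary: str, *args: str) -> None:
    """Check for an external aligner binary; invocation is delegated to the
    user's arguments verbatim.  Raises a naming error when missing."""
    if shutil.which(binary) is None:
        raise AlignmentError(
            f"external aligner binary {binary!r} not found on PATH; install it or "
            f"run with the builtin engine, then feed its tabular output through "
            f"the 12-column adapter (parse_external_tab)"
        )
    raise NotImplementedError("direct invocation is intentionally left to the shell")


def _format_blocks(blocks) -> str:
    if not blocks:
        return "."
    return ",".join(f"{qa}-{qb}:{ga}-{gb}" for (qa, qb), (ga, gb) in blocks)


def _parse_blocks(text: str, lineno: int):
    if text == ".":
        return []
    blocks = []
    try:
        for part in text.split(","):
            qpart, gpart = part.split(":")
            qa, qb = (int(x) for x in qpart.split("-"))
            ga, gb = (int(x) for x in gpart.split("-"))
            blocks.append(((qa, qb), (ga, gb)))
    except ValueError:
        raise GenomeTabError(f"line {lineno}: malformed block descriptor {text!r}") from None
    return blocks


class GenomeTabError(ValueError):
    pass


def parse_external_tab(path: str | Path) -> list[AlignmentHit]:
    """Load hits from the documented 12-column adapter TSV.

    Header must match exactly: query_id, chrom, strand, q_start, q_end,
    g_start, g_end, identity, aligned_columns, score, q_len, blocks.
    Coordinates are already in the internal 0-based half-open convention.
    """
    hits = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TAB_COLUMNS:
            raise GenomeTabError(
                f"bad adapter header; expected columns: {', '.join(_TAB_COLUMNS)}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise GenomeTabError(f"line {lineno}: expected 12 columns, got {len(cols)}")
            try:
                (qid, chrom, strand, q0, q1, g0, g1, ident, ncols, score, qlen, blocks) = cols
                q0, q1, g0, g1 = int(q0), int(q1), int(g0), int(g1)
                ident = float(ident)
                ncols, score, qlen = int(ncols), int(score), int(qlen)
            except ValueError:
                raise GenomeTabError(f"line {lineno}: malformed field") from None
            if strand not in "+-":
                raise GenomeTabError(f"line {lineno}: bad strand {strand!r}")
            if not (0.0 <= ident <= 100.0):
                raise GenomeTabError(f"line {lineno}: identity {ident} outside [0, 100]")
            if q1 <= q0 or g1 <= g0:
                raise GenomeTabError(f"line {lineno}: empty or inverted interval")
            hits.append(
                AlignmentHit(qid, chrom, g0, g1, strand, q0, q1, ident, ncols, score,
                             qlen, _parse_blocks(blocks, lineno))
            )
    hits.sort(key=lambda h: (h.chrom, h.g_start, h.query_id))
    return hits


def write_external_tab(hits: list[AlignmentHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TAB_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.chrom}\t{h.strand}\t{h.q_start}\t{h.q_end}\t"
                f"{h.g_start}\t{h.g_end}\t{h.identity!r}\t{h.aligned_columns}\t"
                f"{h.score}\t{h.q_len}\t{_format_blocks(h.blocks)}\n"
            )


# ---------------------------------------------------------------------------
# Nucleotide alignment (local)
# ---------------------------------------------------------------------------

def align_dna(
    seq_a: str,
    seq_b: str,
    match: int = 2,
    mismatch: int = -3,
    gap_open: int = 5,
    gap_extend: int = 2,
) -> NucleotideAlignment | None:
    """Local pairwise DNA alignment (match +2 / mismatch -3 defaults).

    Returns None when no positive-scoring local alignment exists.  Identity
    is computed over all aligned columns, gaps included.
    """
    from Bio import Align

    if not seq_a or not seq_b:
        raise ValueError("align_dna requires non-empty sequences")
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    score = aligner.score(seq_a, seq_b)
    if score <= 0:
        return None
    aln = aligner.align(seq_a, seq_b)[0]
    blocks_a, blocks_b = aln.aligned
    a0, a1 = int(blocks_a[0][0]), int(blocks_a[-1][1])
    b0, b1 = int(blocks_b[0][0]), int(blocks_b[-1][1])
    # rebuild gapped strings from the aligned blocks (version-robust, and
    # restricted to the locally aligned region rather than the full inputs)
    prev_a, prev_b = a0, b0
    out_a: list[str] = []
    out_b: list[str] = []
    for (sa, ea), (sb, eb) in zip(blocks_a, blocks_b):
        sa, ea, sb, eb = int(sa), int(ea), int(sb), int(eb)
        if sa > prev_a:
            out_a.append(seq_a[prev_a:sa])
            out_b.append("-" * (sa - prev_a))
        if sb > prev_b:
            out_a.append("-" * (sb - prev_b))
            out_b.append(seq_b[prev_b:sb])
        out_a.append(seq_a[sa:ea])
        out_b.append(seq_b[sb:eb])
        prev_a, prev_b = ea, eb
    a_gapped = "".join(out_a)
    b_gapped = "".join(out_b)
    ncols = len(a_gapped)
    ident = sum(1 for x, y in zip(a_gapped, b_gapped) if x == y and x != "-")
    identity = 100.0 * ident / ncols if ncols else 0.0
    return NucleotideAlignment(a_gapped, b_gapped, identity, a0, a1, b0, b1, float(score))
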