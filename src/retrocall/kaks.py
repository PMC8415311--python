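"""NG86 Ka/Ks estimation with protein-guided codon alignment.

The Nei-Gojobori (1986) counting method, with the usual stop-codon
adjustment: per codon position, mutations leading to stop codons are removed
from the denominator when counting synonymous-site fractions, and mutational
pathways passing through stop codons are skipped when averaging observed
differences over orderings.  Multiple-hit correction is Jukes-Cantor,
d = -(3/4) ln(1 - 4p/3); proportions >= 3/4 are reported as saturated
(null) rather than raised.

Codon alignment is protein-guided: the retrocopy is translated in the
parent's reading frame (truncated at the first frameshift indel), the two
proteins are aligned globally, and codons are threaded back through the
protein alignment — which can never introduce frame-breaking gaps.

Ks between a retrocopy and its parent serves as a relative age proxy;
Ka/Ks < 1 indicates purifying selection on the copy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .homology_search import align_dna

log = logging.getLogger("retrocall")

__all__ = [
    "CodonAlignment",
    "KaKsResult",
    "ng_sites",
    "ng_differences",
    "compute_kaks",
    "codon_align",
    "kaks_for_pair",
]

_BASES = "ACGT"
_CODON_TO_AA = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)
_SENSE = sorted(_CODON_TO_AA)


def _aa(codon: str) -> str | None:
    """Amino acid for a sense codon, None for a stop."""
    return _CODON_TO_AA.get(codon)


# ---------------------------------------------------------------------------
# Site and difference counting
# ---------------------------------------------------------------------------

_SITE_CACHE: dict[str, tuple[float, float]] = {}


def ng_sites(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts for a sense codon.

    At each of the three positions the synonymous fraction is the share of
    synonymous changes among the single-nucleotide changes that do not create
    a stop codon; n is the stop-adjusted complement so that s + n = 3 when no
    mutation leads to a stop.
    """
    if codon in _SITE_CACHE:
        return _SITE_CACHE[codon]
    if codon in _STOPS or codon not in _CODON_TO_AA:
        raise ValueError(f"ng_sites requires a sense codon, got {codon!r}")
    aa0 = _CODON_TO_AA[codon]
    s = 0.0
    n = 0.0
    for pos in range(3):
        syn = 0
        legal = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in _STOPS:
                continue
            legal += 1
            if _CODON_TO_AA[mut] == aa0:
                syn += 1
        if legal:
            frac = syn / legal
            s += frac
            n += 1.0 - frac
        # a position whose every change is a stop contributes no sites
    _SITE_CACHE[codon] = (s, n)
    return s, n


_DIFF_CACHE: dict[tuple[str, str], tuple[float, float]] = {}


def ng_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences between two
    sense codons: average step classifications over all orderings of the
    differing positions, skipping pathways that pass through a stop codon."""
    key = (codon_a, codon_b)
    if key in _DIFF_CACHE:
        return _DIFF_CACHE[key]
    if codon_a not in _CODON_TO_AA or codon_b not in _CODON_TO_AA:
        raise ValueError("ng_differences requires sense codons")
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    k = len(diff_pos)
    if k == 0:
        return 0.0, 0.0
    total_s = total_n = 0.0
    n_paths = 0
    for order in permutations(diff_pos):
        cur = codon_a
        path_s = path_n = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                ok = False
                break
            if _CODON_TO_AA[cur] == _CODON_TO_AA[nxt]:
                path_s += 1
            else:
                path_n += 1
            cur = nxt
        if ok:
            total_s += path_s
            total_n += path_n
            n_paths += 1
    if n_paths == 0:
        # no stop-free pathway: fall back to unrestricted averaging so the
        # pair still contributes k differences
        for order in permutations(diff_pos):
            cur = codon_a
            for pos in order:
                nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
                a1, a2 = _CODON_TO_AA.get(cur), _CODON_TO_AA.get(nxt)
                if a1 is not None and a2 is not None and a1 == a2:
                    total_s += 1
                else:
                    total_n += 1
                cur = nxt
            n_paths += 1
    result = (total_s / n_paths, total_n / n_paths)
    _DIFF_CACHE[key] = result
    return result


# ---------------------------------------------------------------------------
# Alignment containers and Ka/Ks
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """Paired codon strings of equal length; '---' marks a gap codon."""

    codons_a: list[str]
    codons_b: list[str]
    a_start: int = 0  # nt offset of first aligned codon on input a
    b_start: int = 0

    def __post_init__(self):
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("codon rows differ in length")


@dataclass
class KaKsResult:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float | None
    pN: float | None
    Ks: float | None
    Ka: float | None
    ratio: float | None
    n_codons: int
    flag: str = "ok"  # ok | unreliable | saturated_s | saturated_n | saturated
    method: str = "NG"


def _jukes_cantor(p: float) -> float | None:
    if p >= 0.75:
        return None
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def _comparable(codon: str) -> bool:
    return codon in _CODON_TO_AA  # sense codon, no gaps/N/stop


def compute_kaks(aln: CodonAlignment, min_codons: int = 10) -> KaKsResult:
    """NG86 Ka/Ks over a codon alignment.

    Codon pairs containing gaps, ambiguous bases or stop codons in either
    sequence are excluded pairwise; site totals are averaged over the two
    sequences; fewer than *min_codons* comparable pairs flags the result
    unreliable with null rates.
    """
    Sa = Na = Sb = Nb = 0.0
    Sd = Nd = 0.0
    n_cod = 0
    for ca, cb in zip(aln.codons_a, aln.codons_b):
        if not (_comparable(ca) and _comparable(cb)):
            continue
        n_cod += 1
        s1, n1 = ng_sites(ca)
        s2, n2 = ng_sites(cb)
        Sa += s1
        Na += n1
        Sb += s2
        Nb += n2
        sd, nd = ng_differences(ca, cb)
        Sd += sd
        Nd += nd
    S = (Sa + Sb) / 2.0
    N = (Na + Nb) / 2.0
    if n_cod < min_codons:
        return KaKsResult(S, N, Sd, Nd, None, None, None, None, None, n_cod, "unreliable")
    pS = Sd / S if S > 0 else None
    pN = Nd / N if N > 0 else None
    Ks = _jukes_cantor(pS) if pS is not None else None
    Ka = _jukes_cantor(pN) if pN is not None else None
    flag = "ok"
    if pS is not None and Ks is None and pN is not None and Ka is None:
        flag = "saturated"
    elif pS is not None and Ks is None:
        flag = "saturated_s"
    elif pN is not None and Ka is None:
        flag = "saturated_n"
    ratio = None
    if Ka is not None and Ks is not None and Ks > 0:
        ratio = Ka / Ks
    return KaKsResult(S, N, Sd, Nd, pS, pN, Ks, Ka, ratio, n_cod, flag)


# ---------------------------------------------------------------------------
# Protein-guided codon alignment
# ---------------------------------------------------------------------------

def _codons(seq: str) -> list[str]:
    return [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]


def _frame_region(retro_seq: str, parent_cds: str):
    """Locate the retrocopy region homologous to the parent CDS and trim it
    to the parent's codon frame, truncating at the first frameshift indel.

    Returns (retro_inframe, retro_nt_start, parent_codon_offset) or None.
    """
    aln = align_dna(retro_seq, parent_cds)
    if aln is None:
        return None
    # walk columns; find the first column at a parent codon boundary, and the
    # first frameshift: a contiguous gap run whose net length shift (inserted
    # retro bases minus deleted parent bases) is not a multiple of 3
    a_pos, b_pos = aln.a_start, aln.b_start
    net = 0  # net shift of the current gap run
    run_a = None  # retro position where the current gap run started
    cut_a = None  # retro position of the first frameshift
    first_start_a = None
    first_codon_b = None
    for x, y in zip(aln.a_aligned, aln.b_aligned):
        if x != "-" and y != "-":
            if net % 3 != 0 and cut_a is None:
                cut_a = run_a
            net = 0
            run_a = None
            if first_start_a is None and b_pos % 3 == 0:
                first_start_a = a_pos
                first_codon_b = b_pos // 3
            a_pos += 1
            b_pos += 1
        elif y == "-":  # extra base in retro
            if run_a is None:
                run_a = a_pos
            net += 1
            a_pos += 1
        else:  # base missing from retro
            if run_a is None:
                run_a = a_pos
            net -= 1
            b_pos += 1
    if net % 3 != 0 and cut_a is None:
        cut_a = run_a
    if first_start_a is None:
        return None
    end_a = cut_a if (cut_a is not None and cut_a > first_start_a) else aln.a_end
    sub = retro_seq[first_start_a:end_a]
    sub = sub[: len(sub) - len(sub) % 3]
    if not sub:
        return None
    return sub, first_start_a, first_codon_b


def codon_align(
    retro_seq: str,
    parent_cds: str,
    parent_protein: str | None = None,
) -> CodonAlignment | None:
    """Protein-guided codon alignment of a retrocopy against its parent CDS.

    The retrocopy is translated in the parent's frame (regions past the
    first frameshift are dropped), the proteins are aligned globally with
    free end gaps, and codons are threaded back through the protein
    alignment; gap codons are written as ``---``.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    region = _frame_region(retro_seq, parent_cds)
    if region is None:
        return None
    retro_frame, retro_nt_start, parent_codon_offset = region
    retro_codons = _codons(retro_frame)
    parent_codons = _codons(parent_cds)
    if parent_protein is None:
        parent_protein = str(Seq(parent_cds[: len(parent_cds) - len(parent_cds) % 3]).translate())
        if parent_protein.endswith("*"):
            parent_protein = parent_protein[:-1]
    retro_prot = str(Seq(retro_frame).translate())
    if retro_prot.endswith("*"):  # terminal stop pairs with nothing
        retro_prot = retro_prot[:-1]
        retro_codons = retro_codons[: len(retro_prot)]
    if not retro_prot:
        return None

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_internal_gap_score = -11
    aligner.extend_internal_gap_score = -1
    aligner.end_gap_score = 0.0  # free end gaps: semi-global protein alignment
    try:
        aln = aligner.align(retro_prot, parent_protein)[0]
    except Exception:
        return None
    cols_a: list[str] = []
    cols_b: list[str] = []
    ra, pa = aln.aligned
    prev_r, prev_p = 0, 0
    pairs: list[tuple[int, int]] = []  # (retro_aa or -1, parent_aa or -1)
    for (sr, er), (sp, ep) in zip(ra, pa):
        sr, er, sp, ep = int(sr), int(er), int(sp), int(ep)
        for i in range(prev_r, sr):
            pairs.append((i, -1))
        for j in range(prev_p, sp):
            pairs.append((-1, j))
        for i, j in zip(range(sr, er), range(sp, ep)):
            pairs.append((i, j))
        prev_r, prev_p = er, ep
    for i in range(prev_r, len(retro_prot)):
        pairs.append((i, -1))
    for j in range(prev_p, len(parent_protein)):
        pairs.append((-1, j))
    for i, j in pairs:
        cols_a.append(retro_codons[i] if i >= 0 else "---")
        cols_b.append(parent_codons[j] if j >= 0 else "---")
    return CodonAlignment(cols_a, cols_b, a_start=retro_nt_start,
                          b_start=3 * parent_codon_offset)


def kaks_for_pair(retro_seq: str, parent_cds: str,
                  parent_protein: str | None = None) -> KaKsResult | None:
    """Convenience wrapper: codon-align then estimate NG86 Ka/Ks."""
    aln = codon_align(retro_seq, parent_cds, parent_protein)
    if aln is None:
        return None
    return compute_kaks(aln)
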