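"""Retrocopy calling: cluster, filter, assign parents, count lost introns,
reject DNA duplications, classify.

The evidence chain for a retrocopy is: a genomic locus that (i) aligns to a
multiexon parent protein with sufficient identity and coverage, (ii) lacks at
least two of the parent's introns at their projected positions (excluding the
first and last 10 aa of the aligned region — intron sites in the margins are
unreliable), (iii) aligns as a single exon-like block, and (iv) is not better
explained by DNA-level duplication (multiple highly similar genomic copies).
Surviving calls are classified: a premature stop codon or frameshift relative
to the parent makes a retropseudogene; an undamaged copy inserted within
another annotated gene is a chimeric retrogene (that gene is its host);
anything else is an intact retrocopy.  Disablement takes precedence over
chimerism — chimeric status presumes an intact reading frame.

Default thresholds: identity >= 50%, coverage_rate >= 50%, coverage_len >=
50 aa, >= 2 lost introns, merge gap 40 bp, countable intron length >= 60 bp,
tolerated secondary block <= 30 aa, duplication cut at >= 90% identity /
>= 90% coverage with at most 1 extra genomic copy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import edlib

from .genome_io import GeneModel, GenomeSequence, ProteinQuery, build_queries, revcomp
from .homology_search import (
    AlignerConfig,
    AlignmentHit,
    align_dna,
    align_proteins_to_genome,
    three_frame_align,
)
from .kaks import KaKsResult, kaks_for_pair

log = logging.getLogger("retrocall")

__all__ = [
    "CallerConfig",
    "CandidateLocus",
    "RetrocopyCall",
    "Disablements",
    "cluster_hits",
    "filter_candidates",
    "assign_parent",
    "count_lost_introns",
    "enforce_single_exon",
    "dna_duplication_filter",
    "detect_disablements",
    "classify",
    "call_retrocopies",
    "call_from_hits",
]


@dataclass
class CallerConfig:
    identity_min: float = 50.0          # %
    coverage_rate_min: float = 0.50     # fraction of parent protein
    coverage_len_min: int = 50          # aa
    intron_loss_num_min: int = 2
    gap_len: int = 40                   # bp, hit-merge distance
    parent_loss_intron_len_min: int = 60  # bp, minimum countable intron
    retro_extra_block_max: int = 30     # aa, tolerated secondary block
    edge_exclusion: int = 10            # aa, fixed alignment-margin exclusion
    dup_identity_min: float = 90.0      # %
    dup_coverage_min: float = 0.90
    dup_extra_copies_max: int = 1

    def __post_init__(self):
        for name in (
            "identity_min", "coverage_rate_min", "coverage_len_min",
            "intron_loss_num_min", "gap_len", "parent_loss_intron_len_min",
            "retro_extra_block_max", "edge_exclusion", "dup_identity_min",
            "dup_coverage_min", "dup_extra_copies_max",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"CallerConfig.{name} must be >= 0")


@dataclass
class CandidateLocus:
    chrom: str
    start: int
    end: int
    strand: str
    hits: list[AlignmentHit]
    parent_gene_id: str | None = None
    identity: float = 0.0
    coverage_rate: float = 0.0
    coverage_len: int = 0
    q_start: int = 0
    q_end: int = 0
    n_merged_blocks: int = 0
    back_hits: list[AlignmentHit] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Disablements:
    has_premature_stop: bool
    has_frameshift: bool
    mutations: list[tuple[str, int]] = field(default_factory=list)

    @property
    def any(self) -> bool:
        return self.has_premature_stop or self.has_frameshift


@dataclass
class RetrocopyCall:
    retrocopy_id: str
    chrom: str
    start: int
    end: int
    strand: str
    parent_gene_id: str
    parent_transcript_id: str
    identity: float
    coverage_rate: float
    coverage_len: int
    n_lost_introns: int
    classification: str  # retropseudogene | intact | chimeric
    host_gene_id: str | None = None
    kaks: KaKsResult | None = None
    mutations: list[tuple[str, int]] = field(default_factory=list)

    @property
    def ka(self):
        return self.kaks.Ka if self.kaks else None

    @property
    def ks(self):
        return self.kaks.Ks if self.kaks else None

    @property
    def ka_ks(self):
        return self.kaks.ratio if self.kaks else None

    @property
    def length(self) -> int:
        return self.end - self.start


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def _interval_union_len(intervals) -> int:
    total = 0
    prev_end = None
    for s, e in sorted(intervals):
        if prev_end is None or s > prev_end:
            total += e - s
            prev_end = e
        elif e > prev_end:
            total += e - prev_end
            prev_end = e
    return total


def _rank_queries(hits: list[AlignmentHit]):
    """Aggregate hits per query: (query_id, total_score, weighted_identity,
    union q intervals, q_len), best first; ties by identity then id."""
    agg: dict[str, dict] = {}
    for h in hits:
        a = agg.setdefault(h.query_id, {"score": 0, "wid": 0.0, "cols": 0,
                                        "q_ivals": [], "q_len": h.q_len})
        a["score"] += h.score
        a["wid"] += h.identity * h.aligned_columns
        a["cols"] += h.aligned_columns
        a["q_ivals"].append((h.q_start, h.q_end))
    rows = []
    for qid, a in agg.items():
        identity = a["wid"] / a["cols"] if a["cols"] else 0.0
        rows.append((qid, a["score"], identity, a["q_ivals"], a["q_len"]))
    rows.sort(key=lambda r: (-r[1], -r[2], r[0]))
    return rows


# ---------------------------------------------------------------------------
# Clustering and filtering
# ---------------------------------------------------------------------------

def cluster_hits(hits: list[AlignmentHit], gap_len: int = 40) -> list[CandidateLocus]:
    """Merge hits on the same chromosome and strand whose genomic gap is
    <= gap_len into candidate loci (transitive, query-agnostic).

    Per-locus identity is the column-weighted mean over the best candidate
    parent's member hits; coverage is computed from the union of that
    parent's query intervals.
    """
    loci: list[CandidateLocus] = []
    keyed: dict[tuple[str, str], list[AlignmentHit]] = {}
    for h in hits:
        keyed.setdefault((h.chrom, h.strand), []).append(h)
    for (chrom, strand), group in sorted(keyed.items()):
        group.sort(key=lambda h: (h.g_start, h.g_end, h.query_id))
        current: list[AlignmentHit] = []
        cur_end = None
        for h in group:
            if current and h.g_start - cur_end > gap_len:
                loci.append(_make_locus(chrom, strand, current))
                current = []
                cur_end = None
            current.append(h)
            cur_end = h.g_end if cur_end is None else max(cur_end, h.g_end)
        if current:
            loci.append(_make_locus(chrom, strand, current))
    loci.sort(key=lambda l: (l.chrom, l.start, l.strand))
    return loci


def _make_locus(chrom: str, strand: str, members: list[AlignmentHit]) -> CandidateLocus:
    start = min(h.g_start for h in members)
    end = max(h.g_end for h in members)
    qid, score, identity, q_ivals, q_len = _rank_queries(members)[0]
    cov_len = _interval_union_len(q_ivals)
    parent_hits = [h for h in members if h.query_id == qid]
    return CandidateLocus(
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        hits=members,
        parent_gene_id=qid,
        identity=identity,
        coverage_rate=cov_len / q_len if q_len else 0.0,
        coverage_len=cov_len,
        q_start=min(h.q_start for h in parent_hits),
        q_end=max(h.q_end for h in parent_hits),
        n_merged_blocks=len(members),
    )


def filter_candidates(loci: list[CandidateLocus], cfg: CallerConfig) -> list[CandidateLocus]:
    """Inclusive thresholds on identity, coverage rate and coverage length,
    applied after merging so split (frameshifted) hits are judged jointly."""
    return [
        l
        for l in loci
        if l.identity >= cfg.identity_min
        and l.coverage_rate >= cfg.coverage_rate_min
        and l.coverage_len >= cfg.coverage_len_min
    ]


# ---------------------------------------------------------------------------
# Parent assignment
# ---------------------------------------------------------------------------

def assign_parent(
    locus: CandidateLocus,
    queries: dict[str, ProteinQuery],
    genome: GenomeSequence,
    aln_cfg: AlignerConfig | None = None,
) -> CandidateLocus | None:
    """Align the merged locus sequence back against *all* multiexon query
    proteins; the top-scoring protein becomes the parent (ties: higher
    identity, then lexicographically smaller gene id).  Identity and coverage
    are recomputed against the assigned parent.  Returns None when nothing
    scores above the reporting threshold."""
    aln_cfg = aln_cfg or AlignerConfig()
    seq = genome[locus.chrom][locus.start : locus.end]
    all_hits: list[AlignmentHit] = []
    for q in queries.values():
        all_hits.extend(
            three_frame_align(q, seq, aln_cfg, chrom=locus.chrom, offset=locus.start)
        )
    if not all_hits:
        log.info("locus %s:%d-%d: no protein scores above minimum, discarded",
                 locus.chrom, locus.start, locus.end)
        return None
    ranked = _rank_queries(all_hits)
    qid, score, identity, q_ivals, q_len = ranked[0]
    if len(ranked) > 1 and ranked[1][1] == score and ranked[1][2] == identity:
        log.warning(
            "locus %s:%d-%d: ambiguous parent (%s vs %s tie, id order used)",
            locus.chrom, locus.start, locus.end, qid, ranked[1][0],
        )
    parent_hits = sorted(
        (h for h in all_hits if h.query_id == qid), key=lambda h: h.q_start
    )
    cov_len = _interval_union_len((h.q_start, h.q_end) for h in parent_hits)
    strand_weight: dict[str, int] = {}
    for h in parent_hits:
        strand_weight[h.strand] = strand_weight.get(h.strand, 0) + h.score
    strand = max(strand_weight, key=lambda s: (strand_weight[s], s))
    return replace(
        locus,
        # trim the locus to where the assigned parent actually aligns: the
        # merged cluster may have absorbed unrelated neighbouring hits (e.g.
        # a host gene's self-hits), which would bloat the reported interval
        # and blind the downstream duplication filter
        start=min(h.g_start for h in parent_hits),
        end=max(h.g_end for h in parent_hits),
        parent_gene_id=qid,
        identity=identity,
        coverage_rate=cov_len / q_len if q_len else 0.0,
        coverage_len=cov_len,
        q_start=min(h.q_start for h in parent_hits),
        q_end=max(h.q_end for h in parent_hits),
        back_hits=parent_hits,
        strand=strand,
        n_merged_blocks=len(parent_hits),
    )


# ---------------------------------------------------------------------------
# Intron-loss evidence
# ---------------------------------------------------------------------------

def _all_blocks(locus: CandidateLocus):
    """Gapless blocks of the back-alignment, sorted by query position."""
    blocks = []
    for h in locus.back_hits or locus.hits:
        if h.blocks:
            blocks.extend(h.blocks)
        else:
            blocks.append(((h.q_start, h.q_end), (h.g_start, h.g_end)))
    blocks.sort(key=lambda b: b[0][0])
    return blocks


def _genomic_gap_at(locus: CandidateLocus, aa_pos: int) -> int:
    """Genomic distance between the aligned blocks flanking a projected
    intron position; 0 when the position falls inside a block."""
    blocks = _all_blocks(locus)
    for (q1, g1), (q2, g2) in zip(blocks, blocks[1:]):
        if q1[1] <= aa_pos <= q2[0]:
            gap = max(g1[0], g2[0]) - min(g1[1], g2[1])
            return max(gap, 0)
    return 0


def count_lost_introns(
    locus: CandidateLocus, parent: ProteinQuery, cfg: CallerConfig
) -> int:
    """Number of parent introns absent from the locus.

    An intron counts as lost iff its projected residue lies inside
    [q_start + 10, q_end - 10) of the aligned query region, its genomic
    length is >= parent_loss_intron_len_min, and the locus shows no genomic
    gap >= gap_len at the projected position (which would mean the intron is
    still there)."""
    q0, q1 = locus.q_start, locus.q_end
    count = 0
    for aa_pos, intron_len in parent.intron_sites:
        if not (q0 + cfg.edge_exclusion <= aa_pos < q1 - cfg.edge_exclusion):
            continue
        if intron_len < cfg.parent_loss_intron_len_min:
            continue
        if _genomic_gap_at(locus, aa_pos) >= cfg.gap_len:
            continue
        count += 1
    return count


def enforce_single_exon(locus: CandidateLocus, cfg: CallerConfig) -> bool:
    """A retrocopy must align as one exon-like run.

    Back-alignment blocks are grouped into segments broken at genomic gaps
    > gap_len; true for one segment, or for exactly two when the secondary
    segment spans <= retro_extra_block_max aa."""
    blocks = sorted(_all_blocks(locus), key=lambda b: b[1][0])
    if not blocks:
        return False
    segments: list[list] = [[blocks[0]]]
    for prev, cur in zip(blocks, blocks[1:]):
        if cur[1][0] - prev[1][1] > cfg.gap_len:
            segments.append([cur])
        else:
            segments[-1].append(cur)
    if len(segments) == 1:
        return True
    if len(segments) == 2:
        aa_lens = [_interval_union_len([b[0] for b in seg]) for seg in segments]
        return min(aa_lens) <= cfg.retro_extra_block_max
    return False


# ---------------------------------------------------------------------------
# DNA-duplication filter
# ---------------------------------------------------------------------------

def dna_duplication_filter(
    call_seq: str,
    genome: GenomeSequence,
    own_interval: tuple[str, int, int],
    parent_span: tuple[str, int, int] | None,
    cfg: CallerConfig,
    max_rounds: int = 25,
) -> bool:
    """Keep a candidate unless the genome holds more than
    ``dup_extra_copies_max`` additional highly similar copies.

    Copies are found by full-query infix edit-distance search (both strands)
    with threshold (1 - dup_identity_min/100) * len(call_seq): edit distance
    jointly bounds mismatches and missing bases, so a counted copy satisfies
    both the identity and the coverage cut.  Hits overlapping the candidate
    itself or its parent gene span are excluded.
    """
    L = len(call_seq)
    k = int(L * (1.0 - cfg.dup_identity_min / 100.0))
    exclude = [own_interval]
    if parent_span is not None:
        exclude.append(parent_span)
    extra = 0
    for chrom, seq in genome.sequences.items():
        clen = len(seq)
        for strand in "+-":
            target = seq if strand == "+" else revcomp(seq)
            masked = bytearray(target.encode())
            for _ in range(max_rounds):
                res = edlib.align(call_seq, masked.decode(), mode="HW",
                                  task="locations", k=k)
                if res["editDistance"] == -1:
                    break
                # merge co-optimal overlapping locations into clusters
                locs = sorted((s, e + 1) for s, e in res["locations"])
                clusters: list[list[int]] = []
                for s, e in locs:
                    if clusters and s <= clusters[-1][1]:
                        clusters[-1][1] = max(clusters[-1][1], e)
                    else:
                        clusters.append([s, e])
                for s, e in clusters:
                    if strand == "+":
                        g0, g1 = s, e
                    else:
                        g0, g1 = clen - e, clen - s
                    hit_excluded = any(
                        c == chrom and _overlap(g0, g1, x0, x1) > 0
                        for c, x0, x1 in exclude
                    )
                    if not hit_excluded:
                        extra += 1
                        if extra > cfg.dup_extra_copies_max:
                            return False
                    masked[s:e] = b"\x00" * (e - s)
    return extra <= cfg.dup_extra_copies_max


# ---------------------------------------------------------------------------
# Disablements and classification
# ---------------------------------------------------------------------------

def detect_disablements(
    call_seq: str, parent_cds: str, parent_protein: str | None = None
) -> Disablements | None:
    """Frameshifts and premature stops of a call relative to its parent CDS.

    The call is aligned to the parent's spliced CDS at the nucleotide level.
    A frameshift is a contiguous indel run whose net length shift is not a
    multiple of 3.  Premature stops are found by translating the aligned call
    region in the parent's reading frame (scanning stops at the first
    frameshift, where downstream frame is undefined): a stop codon mapping
    strictly before the parent's final codon is premature.  Returns None when
    the sequences do not align at all (candidate becomes a no-call)."""
    aln = align_dna(call_seq, parent_cds)
    if aln is None:
        log.info("disablement scan: call does not align to parent CDS, no-call")
        return None
    mutations: list[tuple[str, int]] = []
    a_pos, b_pos = aln.a_start, aln.b_start
    a2b: dict[int, int] = {}
    net = 0
    run_b = None
    frameshift_a: int | None = None
    for x, y in zip(aln.a_aligned, aln.b_aligned):
        if x != "-" and y != "-":
            if net % 3 != 0:
                mutations.append(("frameshift", run_b))
                if frameshift_a is None:
                    frameshift_a = a_pos
            net = 0
            run_b = None
            a2b[a_pos] = b_pos
            a_pos += 1
            b_pos += 1
        elif y == "-":
            if run_b is None:
                run_b = b_pos
            net += 1
            a_pos += 1
        else:
            if run_b is None:
                run_b = b_pos
            net -= 1
            b_pos += 1
    if net % 3 != 0:
        mutations.append(("frameshift", run_b))
        if frameshift_a is None:
            frameshift_a = a_pos
    has_frameshift = any(m[0] == "frameshift" for m in mutations)

    # translate the aligned call region in the parent frame
    from Bio.Seq import Seq

    start_a = None
    for a, b in sorted(a2b.items()):
        if b % 3 == 0:
            start_a = a
            break
    has_stop = False
    if start_a is not None:
        end_a = frameshift_a if frameshift_a is not None else aln.a_end
        region = call_seq[start_a:end_a]
        region = region[: len(region) - len(region) % 3]
        prot = str(Seq(region).translate())
        parent_last_codon = len(parent_cds) // 3 - 1
        for i, aa in enumerate(prot):
            if aa != "*":
                continue
            codon_a = start_a + 3 * i
            b_positions = [a2b[p] for p in (codon_a, codon_a + 1, codon_a + 2) if p in a2b]
            if not b_positions:
                continue
            if max(b_positions) // 3 < parent_last_codon:
                has_stop = True
                mutations.append(("premature_stop", max(b_positions) // 3))
    return Disablements(has_stop, has_frameshift, mutations)


def classify(
    chrom: str,
    start: int,
    end: int,
    parent_gene_id: str,
    genes: list[GeneModel],
    disablements: Disablements,
) -> tuple[str, str | None]:
    """Partition into retropseudogene / chimeric / intact.

    Disablement wins (a chimeric retrogene presumes an intact frame); an
    undamaged call whose interval overlaps the transcript span of a
    non-parent gene is chimeric with that gene as host (largest overlap,
    ties by gene id); otherwise intact."""
    if disablements.any:
        return "retropseudogene", None
    best: tuple[int, str] | None = None
    for g in genes:
        if g.gene_id == parent_gene_id or g.chrom != chrom:
            continue
        ov = _overlap(start, end, g.start, g.end)
        if ov > 0 and (
            best is None or ov > best[0] or (ov == best[0] and g.gene_id < best[1])
        ):
            best = (ov, g.gene_id)
    if best is not None:
        return "chimeric", best[1]
    return "intact", None


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def call_from_hits(
    genome: GenomeSequence,
    genes: list[GeneModel],
    queries: dict[str, ProteinQuery],
    hits: list[AlignmentHit],
    cfg: CallerConfig | None = None,
    aln_cfg: AlignerConfig | None = None,
) -> list[RetrocopyCall]:
    """The post-search pipeline: cluster/merge -> filter -> parent assignment
    -> intron-loss test -> single-exon test -> duplication filter ->
    disablement scan and classification.  Deterministic output ordering and
    serial ids (RC000001, ...)."""
    cfg = cfg or CallerConfig()
    aln_cfg = aln_cfg or AlignerConfig()
    genes_by_id = {g.gene_id: g for g in genes}

    # a gene trivially matches itself: drop self-hits before clustering, or a
    # gene's own locus (which can bridge its introns in one gapped alignment)
    # would absorb, and mis-parent, anything inserted inside that gene
    hits = [
        h
        for h in hits
        if not (
            (g := genes_by_id.get(h.query_id)) is not None
            and g.chrom == h.chrom
            and _overlap(h.g_start, h.g_end, g.start, g.end) > 0
        )
    ]
    loci = cluster_hits(hits, cfg.gap_len)
    loci = [l for l in loci if not _overlaps_gene(l, genes_by_id.get(l.parent_gene_id))]
    loci = filter_candidates(loci, cfg)

    calls: list[RetrocopyCall] = []
    for locus in loci:
        locus = assign_parent(locus, queries, genome, aln_cfg)
        if locus is None:
            continue
        parent_gene = genes_by_id.get(locus.parent_gene_id)
        if _overlaps_gene(locus, parent_gene):
            continue
        if not (
            locus.identity >= cfg.identity_min
            and locus.coverage_rate >= cfg.coverage_rate_min
            and locus.coverage_len >= cfg.coverage_len_min
        ):
            continue
        parent = queries[locus.parent_gene_id]
        n_lost = count_lost_introns(locus, parent, cfg)
        if n_lost < cfg.intron_loss_num_min:
            continue
        if not enforce_single_exon(locus, cfg):
            continue
        call_seq_fwd = genome[locus.chrom][locus.start : locus.end]
        parent_span = None
        if parent_gene is not None:
            parent_span = (parent_gene.chrom, parent_gene.start, parent_gene.end)
        if not dna_duplication_filter(
            call_seq_fwd, genome, (locus.chrom, locus.start, locus.end), parent_span, cfg
        ):
            continue
        call_seq = call_seq_fwd if locus.strand == "+" else revcomp(call_seq_fwd)
        dis = detect_disablements(call_seq, parent.cds, parent.protein)
        if dis is None:
            continue
        classification, host = classify(
            locus.chrom, locus.start, locus.end, locus.parent_gene_id, genes, dis
        )
        kres = kaks_for_pair(call_seq, parent.cds, parent.protein)
        calls.append(
            RetrocopyCall(
                retrocopy_id="",
                chrom=locus.chrom,
                start=locus.start,
                end=locus.end,
                strand=locus.strand,
                parent_gene_id=locus.parent_gene_id,
                parent_transcript_id=parent.transcript_id,
                identity=locus.identity,
                coverage_rate=locus.coverage_rate,
                coverage_len=locus.coverage_len,
                n_lost_introns=n_lost,
                classification=classification,
                host_gene_id=host,
                kaks=kres,
                mutations=dis.mutations,
            )
        )
    calls.sort(key=lambda c: (c.chrom, c.start, c.end))
    for i, c in enumerate(calls, start=1):
        c.retrocopy_id = f"RC{i:06d}"
    return calls


def _overlaps_gene(locus: CandidateLocus, gene: GeneModel | None) -> bool:
    return (
        gene is not None
        and gene.chrom == locus.chrom
        and _overlap(locus.start, locus.end, gene.start, gene.end) > 0
    )


def call_retrocopies(
    genome: GenomeSequence,
    genes: list[GeneModel],
    cfg: CallerConfig | None = None,
    aln_cfg: AlignerConfig | None = None,
    engine: str = "builtin",
    external_tab=None,
) -> list[RetrocopyCall]:
    """Full pipeline from genome + gene models to retrocopy calls."""
    queries = build_queries(genes, genome)
    if not queries:
        return []
    hits = align_proteins_to_genome(
        list(queries.values()), genome, aln_cfg, engine=engine, external_tab=external_tab
    )
    return call_from_hits(genome, genes, queries, hits, cfg, aln_cfg)
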