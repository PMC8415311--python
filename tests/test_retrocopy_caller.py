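"""Caller stages in isolation: clustering, filters, intron counting,
duplication rejection, disablement detection and classification."""

import numpy as np
import pytest
from Bio.Seq import Seq

from retrocall.genome_io import GeneModel, GenomeSequence, ProteinQuery, TranscriptModel, revcomp
from retrocall.retrocopy_caller import (
    CallerConfig,
    CandidateLocus,
    Disablements,
    classify,
    cluster_hits,
    count_lost_introns,
    detect_disablements,
    dna_duplication_filter,
    enforce_single_exon,
    filter_candidates,
)

from conftest import make_hit


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

class TestClusterHits:
    def test_gap_at_threshold_merges(self):
        hits = [make_hit(g_start=100, g_end=400), make_hit(g_start=430, g_end=700)]
        loci = cluster_hits(hits, gap_len=40)
        assert len(loci) == 1
        assert (loci[0].start, loci[0].end) == (100, 700)

    def test_gap_forty_merges_forty_one_splits(self):
        merged = cluster_hits(
            [make_hit(g_start=0, g_end=100), make_hit(g_start=140, g_end=240)], 40
        )
        split = cluster_hits(
            [make_hit(g_start=0, g_end=100), make_hit(g_start=141, g_end=241)], 40
        )
        assert len(merged) == 1
        assert len(split) == 2

    def test_transitive_chain(self):
        hits = [
            make_hit(g_start=0, g_end=100),
            make_hit(g_start=120, g_end=220),
            make_hit(g_start=240, g_end=340),
        ]
        loci = cluster_hits(hits, 40)
        assert len(loci) == 1
        assert (loci[0].start, loci[0].end) == (0, 340)

    def test_strands_never_merge(self):
        hits = sorted(
            [make_hit(g_start=0, g_end=100, strand="+"),
             make_hit(g_start=110, g_end=210, strand="-")],
            key=lambda h: h.g_start,
        )
        assert len(cluster_hits(hits, 40)) == 2

    def test_identity_is_column_weighted(self):
        hits = [
            make_hit(g_start=0, g_end=300, q_start=0, q_end=100, identity=100.0),
            make_hit(g_start=310, g_end=370, q_start=100, q_end=120, identity=70.0),
        ]
        (locus,) = cluster_hits(hits, 40)
        assert locus.identity == pytest.approx((100 * 100 + 70 * 20) / 120)
        assert locus.coverage_len == 120


# ---------------------------------------------------------------------------
# Candidate filters (inclusive thresholds)
# ---------------------------------------------------------------------------

def _locus(identity=95.0, coverage_rate=0.9, coverage_len=100, **kw):
    defaults = dict(chrom="chr1", start=0, end=300, strand="+", hits=[],
                    parent_gene_id="gX", q_start=0, q_end=coverage_len)
    defaults.update(kw)
    return CandidateLocus(identity=identity, coverage_rate=coverage_rate,
                          coverage_len=coverage_len, **defaults)


@pytest.mark.parametrize(
    "identity,cov_rate,cov_len,kept",
    [
        (50.0, 0.50, 50, True),    # all thresholds inclusive
        (49.9, 0.90, 100, False),  # identity just below
        (95.0, 0.49, 100, False),
        (95.0, 0.90, 49, False),   # conjunction of filters
        (95.0, 0.90, 50, True),
    ],
)
def test_filter_candidates_boundaries(identity, cov_rate, cov_len, kept):
    loci = [_locus(identity=identity, coverage_rate=cov_rate, coverage_len=cov_len)]
    assert bool(filter_candidates(loci, CallerConfig())) is kept


# ---------------------------------------------------------------------------
# Intron-loss counting
# ---------------------------------------------------------------------------

def _parent(intron_sites, length=200):
    return ProteinQuery("gP", "gP.t1", "M" * length, intron_sites)


def _aligned_locus(q_start=0, q_end=200, blocks=None):
    hit = make_hit(query_id="gP", g_start=1000, g_end=1000 + 3 * (q_end - q_start),
                   q_start=q_start, q_end=q_end, q_len=200, blocks=blocks)
    return _locus(q_start=q_start, q_end=q_end, back_hits=[hit])


class TestCountLostIntrons:
    def test_two_interior_introns(self):
        parent = _parent([(50, 200), (120, 500)])
        assert count_lost_introns(_aligned_locus(), parent, CallerConfig()) == 2

    def test_edge_exclusion_suppresses_terminal_intron(self):
        parent = _parent([(5, 200), (120, 500)])
        assert count_lost_introns(_aligned_locus(), parent, CallerConfig()) == 1

    def test_edge_exclusion_boundary_is_inclusive(self):
        # aa == q_start + 10 counts; aa == q_end - 10 does not (half-open)
        parent = _parent([(10, 200), (190, 500)])
        assert count_lost_introns(_aligned_locus(), parent, CallerConfig()) == 1

    @pytest.mark.parametrize("length,counted", [(60, 1), (59, 0), (55, 0)])
    def test_minimum_intron_length(self, length, counted):
        parent = _parent([(100, length)])
        assert count_lost_introns(_aligned_locus(), parent, CallerConfig()) == counted

    def test_retained_intron_gap_not_counted(self):
        # two aligned blocks separated by a 300 bp genomic gap at aa 100:
        # the intron is still present at the locus
        blocks = [((0, 100), (1000, 1300)), ((100, 200), (1600, 1900))]
        locus = _aligned_locus(blocks=blocks)
        parent = _parent([(100, 300)])
        assert count_lost_introns(locus, parent, CallerConfig()) == 0

    def test_small_alignment_wobble_still_counts(self):
        # a gap below gap_len at the intron position does not rescue it
        blocks = [((0, 100), (1000, 1300)), ((100, 200), (1320, 1620))]
        locus = _aligned_locus(blocks=blocks)
        parent = _parent([(100, 300)])
        assert count_lost_introns(locus, parent, CallerConfig()) == 1


# ---------------------------------------------------------------------------
# Single-exon enforcement
# ---------------------------------------------------------------------------

class TestEnforceSingleExon:
    def test_single_block(self):
        assert enforce_single_exon(_aligned_locus(), CallerConfig()) is True

    def test_small_satellite_tolerated(self):
        blocks = [((0, 100), (1000, 1300)), ((100, 125), (1500, 1575))]
        assert enforce_single_exon(_aligned_locus(blocks=blocks), CallerConfig()) is True

    def test_two_large_blocks_rejected(self):
        blocks = [((0, 100), (1000, 1300)), ((100, 200), (3300, 3600))]
        assert enforce_single_exon(_aligned_locus(blocks=blocks), CallerConfig()) is False

    def test_satellite_boundary_thirty_aa(self):
        ok = [((0, 100), (1000, 1300)), ((100, 130), (1500, 1590))]
        too_big = [((0, 100), (1000, 1300)), ((100, 131), (1500, 1593))]
        assert enforce_single_exon(_aligned_locus(blocks=ok), CallerConfig()) is True
        assert enforce_single_exon(_aligned_locus(blocks=too_big), CallerConfig()) is False


# ---------------------------------------------------------------------------
# DNA-duplication filter
# ---------------------------------------------------------------------------

def _genome_with_copies(rng, payload, n_copies, mutate=0.0):
    bg = "".join(rng.choice(list("ACGT"), 20000))
    parts = [bg[:2000]]
    intervals = []
    pos = 2000
    for i in range(n_copies):
        copy = payload
        if mutate and i > 0:
            copy = list(payload)
            for p in rng.choice(len(payload), int(mutate * len(payload)), replace=False):
                copy[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[copy[p]]
            copy = "".join(copy)
        parts.append(copy)
        intervals.append((pos, pos + len(copy)))
        pos += len(copy)
        parts.append(bg[2000 + i * 1000 : 3000 + i * 1000])
        pos += 1000
    parts.append(bg[10000:])
    return GenomeSequence({"chr1": "".join(parts)}), intervals


class TestDnaDuplicationFilter:
    def test_unique_copy_kept(self, rng):
        payload = "".join(rng.choice(list("ACGT"), 400))
        genome, ivals = _genome_with_copies(rng, payload, 1)
        assert dna_duplication_filter(payload, genome, ("chr1", *ivals[0]), None,
                                      CallerConfig()) is True

    def test_three_identical_copies_deleted(self, rng):
        payload = "".join(rng.choice(list("ACGT"), 400))
        genome, ivals = _genome_with_copies(rng, payload, 3)
        cfg = CallerConfig()
        for iv in ivals:
            assert dna_duplication_filter(payload, genome, ("chr1", *iv), None, cfg) is False

    def test_one_similar_segmental_copy_tolerated(self, rng):
        payload = "".join(rng.choice(list("ACGT"), 400))
        genome, ivals = _genome_with_copies(rng, payload, 2, mutate=0.05)
        assert dna_duplication_filter(payload, genome, ("chr1", *ivals[0]), None,
                                      CallerConfig()) is True

    def test_parent_span_excluded_from_count(self, rng):
        payload = "".join(rng.choice(list("ACGT"), 400))
        genome, ivals = _genome_with_copies(rng, payload, 2)
        parent_span = ("chr1", *ivals[1])
        assert dna_duplication_filter(payload, genome, ("chr1", *ivals[0]),
                                      parent_span, CallerConfig()) is True

    def test_minus_strand_copy_counted(self, rng):
        payload = "".join(rng.choice(list("ACGT"), 400))
        genome, ivals = _genome_with_copies(rng, revcomp(payload), 2)
        # two reverse-orientation copies elsewhere: one extra allowed, two not
        genome.sequences["chr1"] += revcomp(payload)
        own = ("chr1", 0, 1)  # candidate sits elsewhere entirely
        assert dna_duplication_filter(payload, genome, own, None, CallerConfig()) is False


# ---------------------------------------------------------------------------
# Disablements
# ---------------------------------------------------------------------------

@pytest.fixture
def parent_cds(rng):
    from retrocall.synthetic_fixtures import _random_cds

    return _random_cds(rng, 80)


class TestDetectDisablements:
    def test_exact_copy_is_clean(self, parent_cds):
        d = detect_disablements(parent_cds, parent_cds)
        assert not d.has_premature_stop and not d.has_frameshift

    def test_single_bp_deletion_is_frameshift(self, parent_cds):
        pos = 60  # inside codon 20
        retro = parent_cds[:pos] + parent_cds[pos + 1:]
        d = detect_disablements(retro, parent_cds)
        assert d.has_frameshift

    def test_in_frame_codon_deletion_is_not_frameshift(self, parent_cds):
        retro = parent_cds[:60] + parent_cds[63:]
        d = detect_disablements(retro, parent_cds)
        assert not d.has_frameshift

    def test_interior_stop_detected_with_independent_translation(self, parent_cds):
        ci = 40
        retro = parent_cds[: 3 * ci] + "TGA" + parent_cds[3 * ci + 3:]
        # independent check: translating the mutated copy shows the stop
        assert "*" in str(Seq(retro[: len(retro) - 3]).translate())
        d = detect_disablements(retro, parent_cds)
        assert d.has_premature_stop and not d.has_frameshift

    def test_terminal_stop_is_not_premature(self, parent_cds):
        d = detect_disablements(parent_cds, parent_cds)
        assert not d.has_premature_stop

    def test_unalignable_returns_none(self, parent_cds):
        assert detect_disablements("A" * 200, "C" * 240) is None


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _gene(gene_id, start, end, chrom="chr1"):
    t = TranscriptModel(f"{gene_id}.t1", gene_id, chrom, "+",
                        [(start, end)], [(start, end, 0)])
    return GeneModel(gene_id, chrom, "+", start, end, [t])


class TestClassify:
    def test_disablement_takes_precedence_over_host(self):
        genes = [_gene("gHost", 0, 5000)]
        dis = Disablements(False, True, [("frameshift", 10)])
        cls, host = classify("chr1", 1000, 1600, "gP", genes, dis)
        assert cls == "retropseudogene"
        assert host is None

    def test_clean_call_in_host_gene_is_chimeric(self):
        genes = [_gene("gHost", 0, 5000)]
        cls, host = classify("chr1", 1000, 1600, "gP", genes,
                             Disablements(False, False))
        assert (cls, host) == ("chimeric", "gHost")

    def test_clean_intergenic_call_is_intact(self):
        genes = [_gene("gFar", 10000, 12000)]
        cls, host = classify("chr1", 1000, 1600, "gP", genes,
                             Disablements(False, False))
        assert (cls, host) == ("intact", None)

    def test_parent_overlap_is_not_chimeric(self):
        genes = [_gene("gP", 0, 5000)]
        cls, host = classify("chr1", 1000, 1600, "gP", genes,
                             Disablements(False, False))
        assert (cls, host) == ("intact", None)

    def test_largest_overlap_wins(self):
        genes = [_gene("gA", 0, 1100), _gene("gB", 1050, 5000)]
        cls, host = classify("chr1", 1000, 1600, "gP", genes,
                             Disablements(False, False))
        assert (cls, host) == ("chimeric", "gB")
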