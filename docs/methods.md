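# Methods

`retrocall` annotates retrocopies — gene copies created when a spliced mRNA
is reverse-transcribed and reinserted at an ectopic genomic locus — from a
genome FASTA and a GFF3 gene annotation.  This note documents the model, the
parameters that matter, the numerical choices, what the synthetic benchmark
does and does not show, and known limitations.

## The evidence model

A retrocopy is recognised by four joint signals relative to a candidate
parental gene:

1. **Protein homology.** The parent's protein (longest-CDS isoform) aligns
   to the locus with sufficient identity and coverage.
2. **Intron loss.** Introns present in the parent are absent at the locus at
   their positions projected onto protein coordinates.  Because a single
   missing intron is weak evidence (annotation errors, intron gain/loss in
   paralogs), at least two lost introns are required, so only multi-exon
   parents (≥ 2 CDS segments) enter the query set.
3. **Single-exon structure.** The locus aligns as one contiguous exon-like
   run (one small secondary block is tolerated).
4. **No DNA-duplication explanation.** A locus whose sequence recurs at
   several near-identical genomic copies is better explained by DNA-level
   (segmental) duplication and is discarded.

Surviving calls are classified: a premature stop codon or frameshift
relative to the parent ⇒ **retropseudogene**; otherwise a call inserted
within another annotated gene ⇒ **chimeric** (that gene becomes the host);
otherwise **intact**.  Disablement takes precedence over chimerism, since a
chimeric retrogene presupposes an intact reading frame.  "Inserted within"
is operationalised as interval overlap with a non-parent gene's
transcript span (first to last exon): recruiting regulatory elements or
exons is not computable from FASTA+GFF alone, and span containment is the
computable surrogate; the largest overlap wins, ties broken by gene id.

## Pipeline

1. **Queries** (`genome_io`). Per gene, the transcript with the longest
   spliced CDS is kept (ties: lexicographically smallest transcript id;
   CDS length is the relevant measure because proteins are what get
   aligned).  CDS-interrupting intron positions are projected to amino-acid
   coordinates as ⌊cumulative CDS bp before the intron / 3⌋ after phase
   trimming.  Internal coordinates are 0-based half-open everywhere;
   conversion to GFF3's 1-based closed convention happens only at file I/O.
2. **Search** (`homology_search`). Every query is aligned against all six
   translation frames of the genome with an exhaustive affine-gap local
   aligner (Gotoh), scanned in 100 kb windows with 1 kb overlap to bound
   memory; duplicate hits from overlapping windows are removed.  No
   seeding heuristics: every DP cell is computed, so desk-scale results are
   exact; for large genomes an external aligner's output can be supplied
   through a 12-column tabular adapter.  Multiple hits per frame come from
   best-hit extraction followed by masking.  Frameshifted copies surface as
   two hits in different frames and are reunited by the merge step.
3. **Cluster/merge** (`retrocopy_caller`). Hits on the same chromosome and
   strand whose genomic gap is ≤ `gap_len` (40 bp) merge transitively into
   candidate loci — 40 bp is safely below real intron lengths, so exons of
   a spliced gene copy stay separate while split frameshift hits rejoin.
   Self-hits (a query aligning inside its own gene span) are dropped before
   clustering; a gene's own gapped self-alignment can otherwise bridge an
   intron and absorb anything inserted there.
4. **Filter.** Inclusive thresholds on identity (≥ 50 %), coverage rate
   (≥ 0.50 of the parent protein) and coverage length (≥ 50 aa), applied
   after merging so frameshifted copies are judged jointly.
5. **Parent assignment.** The merged locus sequence is aligned back against
   *all* queries; the top total score wins (ties: higher identity, then
   smaller gene id, logged as ambiguous).  Identity/coverage are recomputed
   against the assigned parent and the locus interval is trimmed to the
   span the parent actually aligns to — merged clusters can absorb
   unrelated neighbouring hits, which would bloat the reported interval and
   blind the duplication filter.
6. **Intron-loss count.** An intron counts as lost iff (a) its projected
   residue lies in `[q_start+10, q_end−10)` of the aligned region — the
   10-aa edge exclusion, applied to the aligned region rather than the
   whole protein because marginal intron sites are unreliable; (b) its
   genomic length is ≥ 60 bp (shorter gaps are not reliably
   distinguishable from alignment wobble); (c) the locus shows no genomic
   gap ≥ `gap_len` at the projected position (which would mean the intron
   is still there).  Calls need ≥ 2.
7. **Single-exon test.** Back-alignment blocks are segmented at genomic
   gaps > `gap_len`; one segment passes, two pass when the secondary spans
   ≤ 30 aa, more fail.
8. **DNA-duplication filter.** The call sequence is searched against both
   strands of the whole genome by full-query infix edit-distance scan
   (edlib), mask-and-repeat, with threshold `(1 − dup_identity_min/100)·L`
   edits.  Edit distance jointly bounds mismatches and missing bases, so a
   counted copy meets both the ≥ 90 % identity and ≥ 90 % coverage cuts
   (the scan is slightly conservative: a copy exactly at both bounds can
   exceed the edit budget).  Hits overlapping the candidate itself or its
   parent gene span are excluded; more than one extra copy deletes the
   call.
9. **Disablements.** The call is aligned to the parent's spliced CDS at the
   nucleotide level (local, +2/−3, gap 5+2·L).  A frameshift is a
   contiguous indel run with net length shift ≢ 0 (mod 3).  Premature
   stops are found by translating the aligned region in the parent's frame
   up to the first frameshift (downstream of a frameshift the frame is
   undefined); a stop mapping strictly before the parent's final codon is
   premature.
10. **Ka/Ks** (`kaks`). See below.

Raising any of `identity_min`, `coverage_rate_min`, `coverage_len_min`,
`intron_loss_num_min` can only remove calls (all filters are conjunctive),
which the test suite checks on a 5-point grid per parameter.

## Parameters

| name | default | unit | role |
|---|---|---|---|
| identity_min | 50 | % | minimum alignment identity of a candidate |
| coverage_rate_min | 0.50 | fraction | of parent protein covered |
| coverage_len_min | 50 | aa | absolute covered length |
| intron_loss_num_min | 2 | count | lost introns required |
| gap_len | 40 | bp | hit-merge distance / retained-intron gap |
| parent_loss_intron_len_min | 60 | bp | minimum countable intron |
| retro_extra_block_max | 30 | aa | tolerated secondary block |
| edge_exclusion | 10 | aa | fixed margin on the aligned region |
| dup_identity_min / dup_coverage_min | 90 % / 0.90 | | duplication-copy cut |
| dup_extra_copies_max | 1 | count | extra copies tolerated |

Coverage uses the parent protein length as denominator (the query is the
natural frame of reference when proteins are aligned).  Merged-locus
identity is the column-weighted mean over member hits, weighting long
blocks over short satellites for stability.

Aligner scoring: BLOSUM62, gap cost `11 + 1·L` (protein); +2/−3 with gap
`5 + 2·L` (DNA); minimum reported protein hit score 50 matrix units.  These
are standard protein-search defaults; all are exposed in `AlignerConfig`.

## NG86 Ka/Ks

The Nei–Gojobori (1986) counting method with stop-codon adjustment:

- **Sites.** Per codon position, the synonymous fraction is computed over
  the single-nucleotide changes that do not create a stop codon; `s` sums
  these fractions, `n = 3 − s` (positions whose every change is a stop
  contribute no sites).  S and N are averaged over the two sequences.
- **Differences.** For k differing positions, step classifications are
  averaged over all k! orderings, skipping pathways that pass through stop
  codons; if no stop-free pathway exists the unrestricted average is used
  so the pair still contributes k differences.
- **Correction.** Jukes–Cantor, `d = −(3/4)·ln(1 − 4p/3)`; p ≥ 3/4 yields a
  null rate flagged `saturated` rather than an exception.  Ka/Ks is null
  when Ks = 0 (a null ratio asserts nothing, and reports treat it as
  outside any Ka/Ks-based set).

Codon alignment is protein-guided: the retrocopy is translated in the
parent's frame — truncated at the first frameshift, so Ka/Ks of
frameshifted retropseudogenes covers only the pre-shift prefix and is
flagged by its reduced codon count — then the proteins are aligned globally
(BLOSUM62, free end gaps) and codons are threaded back through the protein
alignment, which cannot introduce frame-breaking gaps.  Codon pairs
containing gaps, ambiguous bases or stops are excluded pairwise; fewer than
10 comparable codons flags the result `unreliable` with null rates.

A note on "synonymous-only" simulations: two successive synonymous
single-base changes in the *same* codon can average to a fractional
nonsynonymous difference under pathway counting (e.g. TTA→CTA→CTC passes
through Phe on one ordering), so the simulator's synonymous-only mode
mutates each codon at most once, preserving the exact Ka = 0 property.

## The synthetic benchmark

`synthetic_fixtures.simulate_genome` builds chromosomes left-to-right —
features are placed with random intergenic spacers, never inserted post
hoc — so coordinates are final at emission and a fixed seed reproduces
byte-identical FASTA/GFF3/truth output.  Defaults describe the standard
benchmark: 2 × 500 kb chromosomes, 60 genes (3–6 exons of 90–240 bp, introns
100–400 bp, random sense-codon CDS), 20 planted retrocopies with 0–8 %
nucleotide divergence (a quarter each frameshifted and stop-disabled, a
fifth chimeric), 5 DNA-duplication decoys, intergenic GC 0.42.  Exon
minimum 90 bp keeps projected intron sites ≥ 30 aa from the protein
termini, i.e. planted events are compliant with the edge exclusion by
construction; intron minimum 100 bp keeps every lost intron countable.

Chimeric copies are embedded inside a host-gene intron (hosts, parents and
decoy sources are disjoint gene sets), which leaves the host's own gene
model valid.  Decoys come in two kinds: copies of the *unspliced* genomic
interval of a gene (2 copies; rejected by the intron tests) and multi-copy
plants of a spliced CDS at 3 loci (these pass every retrocopy test and are
killed only by the duplication filter, making that filter load-bearing in
the benchmark).  Truth records carry the applied mutational history and an
expected class derived symbolically from it.

What the benchmark does **not** emulate: repeat families and transposable
elements (the dominant source of real-world runtime and of spurious
homology), poly-A tails and target-site duplications (signals this method
does not use), UTRs and alternative isoforms, sequencing/assembly error,
and realistic codon usage or GC heterogeneity.  Passing it therefore shows
the *logic* of the pipeline is correct under the stated event model, not
that real-genome precision matches the benchmark's.

Problem sizes were chosen so a full run (search, calling, Ka/Ks) completes
in a few minutes on one CPU: the exhaustive aligner computes roughly
2.4 × 10¹⁰ DP cells on the benchmark genome at ~2 × 10⁸ cells/s.

## Numerical and degenerate-case choices

- DP tie-breaking prefers diagonal, then query-gap, then target-gap moves;
  score equality with the oracle is asserted, block structure only needs to
  be internally consistent (co-optimal alignments are legitimate).
- Hits below 50 matrix units are never reported; random-sequence hits above
  it exist (~tens per Mb of queries×genome) but die at the coverage
  filters.
- `align_dna` returns `None` (no alignment) rather than a zero-score
  object; a candidate whose sequence no longer aligns to its parent CDS at
  the disablement stage becomes a no-call and is dropped with a log line.
- Empty inputs: an annotation with no multi-exon genes yields zero queries
  and an empty (valid) result; the CLI exits 0 on empty call sets.
- GFF dialect: both `mRNA` and `transcript` feature types are accepted;
  `ID`/`Parent` preferred with `gene_id`/`transcript_id` fallbacks; an mRNA
  without a gene row gets a gene synthesized from its span (logged);
  missing CDS phase is recomputed from the cumulative length.
- `--threads` is accepted for interface compatibility but the pipeline is
  single-threaded; results never depend on thread count.

## Known limitations

- No spliced-alignment model: a retrocopy that itself gained an intron
  after insertion would be split and likely rejected by the single-exon
  rule.
- Retrocopies of single-exon parents are out of scope by design (the
  intron-loss signal does not exist for them).
- Retrocopies inserted *inside their own parent's gene* are discarded by
  the self-overlap rule.
- The duplication filter's edit-distance surrogate slightly over-rejects
  copies near the identity/coverage boundary (see step 8).
- NG86 only; no transition/transversion weighting, no codon-model ML, no
  gamma rate correction.  Method tagging in `KaKsResult` leaves room for
  alternatives.
- The external-aligner adapter parses precomputed tabular output; it does
  not drive the external binary itself.
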