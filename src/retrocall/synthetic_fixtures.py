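"""Seeded genome simulator with planted retrotransposition events.

Emulates the event model the caller is built for: multi-exon protein-coding
genes on random intergenic background, spliced-mRNA copies of parent genes
reinserted at ectopic loci with configurable divergence, frameshift indels,
premature stop codons, chimeric insertions inside host-gene introns, and
DNA-duplication decoys.  Every planted event carries a machine-readable
truth record whose expected class is derived symbolically from the applied
mutations — the acceptance oracle for the caller.

Two decoy kinds are planted: copies of the *unspliced* genomic interval of a
gene (introns included; the intron-loss tests reject these) and multi-copy
plants of a spliced CDS at several loci (these pass every retrocopy test and
exist to exercise the DNA-duplication filter).

Chromosomes are assembled left to right — features are placed with random
intergenic spacers, never inserted post hoc — so all coordinates are final
at emission time and a fixed seed reproduces byte-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from .genome_io import (
    GeneModel,
    GenomeSequence,
    TranscriptModel,
    revcomp,
    write_fasta,
    write_gff3,
)

log = logging.getLogger("retrocall")

__all__ = [
    "SimConfig",
    "TruthRecord",
    "simulate_genome",
    "write_truth_tsv",
    "read_truth_tsv",
    "write_simulation",
    "evaluate_calls",
    "plant_dna_duplication_decoy",
]

_BASES = np.array(list("ACGT"))
_SENSE_CODONS = sorted(
    c
    for c in ("".join(t) for t in product("ACGT", repeat=3))
    if str(Seq(c).translate()) != "*"
)
_STOP_CODONS = ["TAA", "TAG", "TGA"]


@dataclass
class SimConfig:
    """Study conditions for the planted-event genomes.

    Defaults describe the standard benchmark: 2 chromosomes of 500 kb,
    60 genes of 3-6 exons, 20 planted retrocopies with up to 8% nucleotide
    divergence, a quarter each frameshifted and stop-disabled, a fifth
    chimeric, plus 5 DNA-duplication decoys.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 500_000
    n_genes: int = 60
    exons_per_gene: tuple[int, int] = (3, 6)
    exon_length: tuple[int, int] = (90, 240)      # bp
    intron_length: tuple[int, int] = (100, 400)   # bp, min must stay >= 60
    n_retrocopies: int = 20
    divergence: tuple[float, float] = (0.0, 0.08)  # per-event substitution rate
    synonymous_only: bool = False
    frac_frameshift: float = 0.25
    frac_premature_stop: float = 0.25
    frac_chimeric: float = 0.20
    n_dna_duplication_decoys: int = 5
    intergenic_gc: float = 0.42
    spacer_length: tuple[int, int] = (700, 1600)  # bp between features

    def validate(self) -> None:
        for f in (self.frac_frameshift, self.frac_premature_stop, self.frac_chimeric):
            if not 0.0 <= f <= 1.0:
                raise ValueError("class fractions must lie in [0, 1]")
        if not 0.0 <= self.divergence[0] <= self.divergence[1] <= 1.0:
            raise ValueError("divergence range must lie in [0, 1]")
        if self.intron_length[0] < 60:
            raise ValueError("minimum intron length must be >= 60 bp to keep events countable")
        n_chim = int(round(self.frac_chimeric * self.n_retrocopies))
        need = self.n_retrocopies + n_chim + self.n_dna_duplication_decoys
        if self.n_genes < need:
            raise ValueError(
                f"n_genes={self.n_genes} too small: need >= {need} for parents, "
                f"hosts and decoy sources"
            )


@dataclass
class TruthRecord:
    event_id: str
    parent_gene_id: str | None
    chrom: str
    start: int
    end: int
    strand: str
    mutations: list[tuple[str, int]]
    expected_class: str  # intact | retropseudogene | chimeric | none (decoys)
    expected_lost_introns: int
    is_decoy: bool
    host_gene_id: str | None = None


# ---------------------------------------------------------------------------
# Gene design
# ---------------------------------------------------------------------------

@dataclass
class _DesignedGene:
    gene_id: str
    strand: str
    exon_bp: list[int]
    intron_bp: list[int]
    cds: str           # spliced CDS including terminal stop
    introns: list[str] = field(default_factory=list)
    # chimeric payload: (intron_index, sense_insert, event) or None
    chimera: tuple[int, str, "_Event"] | None = None

    @property
    def protein_len(self) -> int:
        return len(self.cds) // 3 - 1  # minus terminal stop

    def intron_aa_positions(self) -> list[tuple[int, int]]:
        sites = []
        cum = 0
        for ebp, ibp in zip(self.exon_bp[:-1], self.intron_bp):
            cum += ebp
            sites.append((cum // 3, ibp))
        return sites


@dataclass
class _Event:
    event_id: str
    parent_idx: int
    klass: str  # intact | frameshift | stop | chimeric
    seq: str    # mutated spliced CDS (mRNA sense)
    mutations: list[tuple[str, int]]
    strand: str  # orientation of the copy on the genome
    host_idx: int | None = None


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = ["ATG"]
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons - 2)
    codons.extend(_SENSE_CODONS[i] for i in idx)
    codons.append(_STOP_CODONS[rng.integers(0, 3)])
    return "".join(codons)


def _design_gene(rng: np.random.Generator, gene_id: str, cfg: SimConfig) -> _DesignedGene:
    n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    exon_bp = [int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1))
               for _ in range(n_exons)]
    total = sum(exon_bp)
    exon_bp[-1] += (3 - total % 3) % 3
    intron_bp = [int(rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1))
                 for _ in range(n_exons - 1)]
    cds = _random_cds(rng, sum(exon_bp) // 3)
    strand = "+" if rng.random() < 0.5 else "-"
    introns = [_random_dna(rng, ibp, cfg.intergenic_gc) for ibp in intron_bp]
    return _DesignedGene(gene_id, strand, exon_bp, intron_bp, cds, introns)


# ---------------------------------------------------------------------------
# Mutation machinery
# ---------------------------------------------------------------------------

def _apply_substitutions(cds: str, rate: float, rng: np.random.Generator,
                         synonymous_only: bool) -> tuple[str, list[tuple[str, int]]]:
    """Random substitutions at the given per-base rate, never touching the
    start or stop codon and never creating an in-frame stop (rejection
    sampling); synonymous-only mode swaps codons for same-amino-acid codons
    reachable by a single nucleotide change."""
    seq = list(cds)
    n_codons = len(cds) // 3
    muts: list[tuple[str, int]] = []
    n_sub = int(rng.binomial(len(cds), rate))
    attempts = 0
    touched: set[int] = set()
    while n_sub > 0 and attempts < 50 * (n_sub + 1):
        attempts += 1
        ci = int(rng.integers(1, n_codons - 1))
        if synonymous_only and ci in touched:
            # one hit per codon: two same-codon synonymous steps can average
            # to a fractional nonsynonymous difference under NG86 pathway
            # counting, which would break the Ka = 0 guarantee
            continue
        codon = "".join(seq[3 * ci : 3 * ci + 3])
        pos = int(rng.integers(0, 3))
        base = "ACGT"[int(rng.integers(0, 4))]
        if base == codon[pos]:
            continue
        new = codon[:pos] + base + codon[pos + 1 :]
        if str(Seq(new).translate()) == "*":
            continue
        if synonymous_only and str(Seq(new).translate()) != str(Seq(codon).translate()):
            continue
        seq[3 * ci + pos] = base
        muts.append(("sub", 3 * ci + pos))
        touched.add(ci)
        n_sub -= 1
    return "".join(seq), muts


def _plant_frameshift(cds: str, rng: np.random.Generator) -> tuple[str, tuple[str, int]]:
    n = len(cds)
    pos = int(rng.integers(int(0.35 * n), int(0.65 * n)))
    if rng.random() < 0.5:
        width = 1 if rng.random() < 0.7 else 2
        return cds[:pos] + cds[pos + width :], ("frameshift_del", pos)
    extra = "ACGT"[int(rng.integers(0, 4))]
    return cds[:pos] + extra + cds[pos:], ("frameshift_ins", pos)


def _plant_stop(cds: str, rng: np.random.Generator) -> tuple[str, tuple[str, int]]:
    n_codons = len(cds) // 3
    ci = int(rng.integers(int(0.35 * n_codons), int(0.65 * n_codons)))
    stop = _STOP_CODONS[int(rng.integers(0, 3))]
    return cds[: 3 * ci] + stop + cds[3 * ci + 3 :], ("premature_stop", ci)


def _expected_class(klass: str) -> str:
    return {
        "intact": "intact",
        "chimeric": "chimeric",
        "frameshift": "retropseudogene",
        "stop": "retropseudogene",
    }[klass]


def _expected_lost_introns(parent: _DesignedGene, edge: int = 10,
                           min_len: int = 60) -> int:
    n_aa = parent.protein_len
    return sum(
        1
        for aa, ibp in parent.intron_aa_positions()
        if ibp >= min_len and edge <= aa < n_aa - edge
    )


def plant_dna_duplication_decoy(source_len: int, n_copies: int) -> list[int]:
    """Validate a DNA-duplication decoy request; returns copy indices.

    The simulator plants ``n_copies`` copies of the source interval; fewer
    than 2 copies cannot exercise the duplication filter and is an error."""
    if n_copies < 2:
        raise ValueError("a DNA-duplication decoy needs n_copies >= 2")
    if source_len <= 0:
        raise ValueError("empty source interval")
    return list(range(n_copies))


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def _gene_sense_sequence(g: _DesignedGene) -> tuple[str, list[tuple[int, int]]]:
    """Concatenate exons and introns (with any chimeric payload embedded);
    returns the sense-space sequence and exon offset intervals."""
    introns = list(g.introns)
    if g.chimera is not None:
        i_idx, insert, _event = g.chimera
        mid = len(introns[i_idx]) // 2
        introns[i_idx] = introns[i_idx][:mid] + insert + introns[i_idx][mid:]
    parts = []
    exon_ivals = []
    off = 0
    cds_pos = 0
    for j, ebp in enumerate(g.exon_bp):
        parts.append(g.cds[cds_pos : cds_pos + ebp])
        exon_ivals.append((off, off + ebp))
        cds_pos += ebp
        off += ebp
        if j < len(introns):
            parts.append(introns[j])
            off += len(introns[j])
    return "".join(parts), exon_ivals


def _chimera_sense_interval(g: _DesignedGene) -> tuple[int, int]:
    """Sense-space interval of the embedded chimeric insert."""
    i_idx, insert, _ = g.chimera
    off = 0
    for j in range(i_idx + 1):
        off += g.exon_bp[j]
        if j < i_idx:
            off += len(g.introns[j])
    off += len(g.introns[i_idx]) // 2
    return off, off + len(insert)


def _gene_model(g: _DesignedGene, chrom: str, gstart: int, total_len: int,
                exon_ivals: list[tuple[int, int]]) -> GeneModel:
    def to_genome(a: int, b: int) -> tuple[int, int]:
        if g.strand == "+":
            return gstart + a, gstart + b
        return gstart + total_len - b, gstart + total_len - a

    exons = [to_genome(a, b) for a, b in exon_ivals]
    cds_segments = []
    cum = 0
    for (a, b) in exon_ivals:
        phase = (3 - cum % 3) % 3
        s, e = to_genome(a, b)
        cds_segments.append((s, e, phase))
        cum += b - a
    t = TranscriptModel(
        transcript_id=f"{g.gene_id}.t1",
        gene_id=g.gene_id,
        chrom=chrom,
        strand=g.strand,
        exons=exons,
        cds_segments=cds_segments,
    )
    return GeneModel(g.gene_id, chrom, g.strand, gstart, gstart + total_len, [t])


def simulate_genome(cfg: SimConfig) -> tuple[GenomeSequence, list[GeneModel], list[TruthRecord]]:
    """Generate a genome, its annotation and the planted-event truth table.

    Deterministic under a fixed ``cfg.seed``: running twice yields
    byte-identical FASTA/GFF3/truth output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    genes = [_design_gene(rng, f"g{i + 1:04d}", cfg) for i in range(cfg.n_genes)]

    # role assignment: parents, chimeric hosts, decoy sources are disjoint
    n = cfg.n_retrocopies
    n_fs = int(round(cfg.frac_frameshift * n))
    n_stop = int(round(cfg.frac_premature_stop * n))
    n_chim = int(round(cfg.frac_chimeric * n))
    while n_fs + n_stop + n_chim > n:
        n_chim -= 1
    classes = (["frameshift"] * n_fs + ["stop"] * n_stop + ["chimeric"] * n_chim
               + ["intact"] * (n - n_fs - n_stop - n_chim))
    rng.shuffle(classes)

    order = rng.permutation(cfg.n_genes)
    parent_idx = list(order[:n])
    cursor = n
    host_idx = list(order[cursor : cursor + n_chim])
    cursor += n_chim
    n_multi = cfg.n_dna_duplication_decoys // 2
    n_unspliced = cfg.n_dna_duplication_decoys - n_multi
    unspliced_src = list(order[cursor : cursor + n_unspliced])
    cursor += n_unspliced
    multi_src = list(order[cursor : cursor + n_multi])

    # build events
    events: list[_Event] = []
    host_iter = iter(host_idx)
    for ei, (pi, klass) in enumerate(zip(parent_idx, classes)):
        parent = genes[pi]
        rate = float(rng.uniform(*cfg.divergence))
        seq, muts = _apply_substitutions(parent.cds, rate, rng, cfg.synonymous_only)
        if klass == "frameshift":
            seq, m = _plant_frameshift(seq, rng)
            muts.append(m)
        elif klass == "stop":
            seq, m = _plant_stop(seq, rng)
            muts.append(m)
        strand = "+" if rng.random() < 0.5 else "-"
        ev = _Event(f"ev{ei + 1:03d}", pi, klass, seq, muts, strand)
        if klass == "chimeric":
            hi = next(host_iter)
            ev.host_idx = hi
            host = genes[hi]
            i_idx = int(rng.integers(0, len(host.intron_bp)))
            # genome fragment must read the event in ev.strand orientation
            genome_frag = seq if ev.strand == "+" else revcomp(seq)
            sense_insert = genome_frag if host.strand == "+" else revcomp(genome_frag)
            host.chimera = (i_idx, sense_insert, ev)
        events.append(ev)

    # placement items: genes + intergenic inserts (events, decoy copies)
    items: list[tuple] = [("gene", i) for i in range(cfg.n_genes)]
    for ev in events:
        if ev.klass != "chimeric":
            items.append(("event", ev))
    decoy_records_meta: list[tuple] = []
    for d, si in enumerate(unspliced_src):
        seq, _ = _gene_sense_sequence(genes[si])
        frag = seq if genes[si].strand == "+" else revcomp(seq)
        for c in plant_dna_duplication_decoy(len(frag), 2):
            items.append(("decoy", f"dup{d + 1:02d}u.{c + 1}", genes[si].gene_id, frag))
    for d, si in enumerate(multi_src):
        frag = genes[si].cds
        for c in plant_dna_duplication_decoy(len(frag), 3):
            items.append(("decoy", f"dup{d + 1:02d}m.{c + 1}", genes[si].gene_id, frag))

    chrom_of = rng.integers(0, cfg.n_chromosomes, size=len(items))
    chrom_items: list[list[tuple]] = [[] for _ in range(cfg.n_chromosomes)]
    for item, ci in zip(items, chrom_of):
        chrom_items[ci].append(item)
    for bucket in chrom_items:
        rng.shuffle(bucket)

    sequences: dict[str, str] = {}
    gene_models: list[GeneModel] = []
    truth: list[TruthRecord] = []
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        parts: list[str] = []
        pos = 0
        for item in chrom_items[ci]:
            spacer = int(rng.integers(*cfg.spacer_length))
            parts.append(_random_dna(rng, spacer, cfg.intergenic_gc))
            pos += spacer
            if item[0] == "gene":
                g = genes[item[1]]
                sense, exon_ivals = _gene_sense_sequence(g)
                frag = sense if g.strand == "+" else revcomp(sense)
                gene_models.append(_gene_model(g, chrom, pos, len(sense), exon_ivals))
                if g.chimera is not None:
                    a, b = _chimera_sense_interval(g)
                    ev = g.chimera[2]
                    if g.strand == "+":
                        e0, e1 = pos + a, pos + b
                    else:
                        e0, e1 = pos + len(sense) - b, pos + len(sense) - a
                    # the sense-space insert already compensates for host
                    # orientation, so the copy reads in ev.strand on the genome
                    truth.append(_event_truth(ev, genes, chrom, e0, e1, ev.strand))
            elif item[0] == "event":
                ev = item[1]
                frag = ev.seq if ev.strand == "+" else revcomp(ev.seq)
                truth.append(_event_truth(ev, genes, chrom, pos, pos + len(frag), ev.strand))
            else:  # decoy copy
                _, did, src_gene_id, frag = item
                truth.append(
                    TruthRecord(did, src_gene_id, chrom, pos, pos + len(frag), "+",
                                [], "none", 0, True)
                )
            parts.append(frag)
            pos += len(frag)
        if pos >= cfg.chrom_length:
            raise ValueError(
                f"chromosome {chrom} too small: {pos} bp of features vs "
                f"chrom_length={cfg.chrom_length}"
            )
        parts.append(_random_dna(rng, cfg.chrom_length - pos, cfg.intergenic_gc))
        sequences[chrom] = "".join(parts)

    gene_models.sort(key=lambda g: (g.chrom, g.start))
    truth.sort(key=lambda t: (t.chrom, t.start))
    return GenomeSequence(sequences), gene_models, truth


def _event_truth(ev: _Event, genes: list[_DesignedGene], chrom: str,
                 start: int, end: int, strand: str) -> TruthRecord:
    parent = genes[ev.parent_idx]
    return TruthRecord(
        event_id=ev.event_id,
        parent_gene_id=parent.gene_id,
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        mutations=ev.mutations,
        expected_class=_expected_class(ev.klass),
        expected_lost_introns=_expected_lost_introns(parent),
        is_decoy=False,
        host_gene_id=genes[ev.host_idx].gene_id if ev.host_idx is not None else None,
    )


# ---------------------------------------------------------------------------
# Truth table I/O and evaluation
# ---------------------------------------------------------------------------

_TRUTH_COLUMNS = [
    "event_id", "parent_gene_id", "chrom", "start", "end", "strand",
    "expected_class", "expected_lost_introns", "is_decoy", "host_gene_id",
    "mutations",
]


def write_truth_tsv(records: list[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TRUTH_COLUMNS) + "\n")
        for r in records:
            muts = ";".join(f"{t}:{p}" for t, p in r.mutations) or "."
            fh.write(
                f"{r.event_id}\t{r.parent_gene_id or '.'}\t{r.chrom}\t{r.start}\t"
                f"{r.end}\t{r.strand}\t{r.expected_class}\t{r.expected_lost_introns}\t"
                f"{int(r.is_decoy)}\t{r.host_gene_id or '.'}\t{muts}\n"
            )


def read_truth_tsv(path: str | Path) -> list[TruthRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TRUTH_COLUMNS:
            raise ValueError("unexpected truth table header")
        for line in fh:
            (eid, pgid, chrom, s, e, strand, cls, nli, dec, host, muts) = (
                line.rstrip("\n").split("\t")
            )
            mutations = []
            if muts != ".":
                for part in muts.split(";"):
                    t, _, p = part.rpartition(":")
                    mutations.append((t, int(p)))
            records.append(
                TruthRecord(eid, None if pgid == "." else pgid, chrom, int(s), int(e),
                            strand, mutations, cls, int(nli), bool(int(dec)),
                            None if host == "." else host)
            )
    return records


def write_simulation(genome: GenomeSequence, genes: list[GeneModel],
                     truth: list[TruthRecord], outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(genome, outdir / "genome.fa")
    write_gff3(genes, outdir / "annotation.gff3")
    write_truth_tsv(truth, outdir / "truth.tsv")


def _reciprocal_match(a0, a1, b0, b1) -> bool:
    ov = max(0, min(a1, b1) - max(a0, b0))
    return ov > 0.5 * (a1 - a0) and ov > 0.5 * (b1 - b0)


def evaluate_calls(calls, truth: list[TruthRecord]) -> dict:
    """Score calls against the truth table.

    A call matches a truth event when on the same chromosome with >50%
    reciprocal span overlap.  Decoy records must produce no call.  Returns
    recall/precision over non-decoy events, parent-assignment and
    classification accuracy among matched pairs, and the decoy call count.
    """
    positives = [t for t in truth if not t.is_decoy]
    decoys = [t for t in truth if t.is_decoy]
    matched: list[tuple] = []
    used_calls = set()
    for t in positives:
        for c in calls:
            if id(c) in used_calls or c.chrom != t.chrom:
                continue
            if _reciprocal_match(c.start, c.end, t.start, t.end):
                matched.append((t, c))
                used_calls.add(id(c))
                break
    decoy_calls = sum(
        1
        for c in calls
        for d in decoys
        if c.chrom == d.chrom and _reciprocal_match(c.start, c.end, d.start, d.end)
    )
    n_true = len(positives)
    n_calls = len(calls)
    recall = len(matched) / n_true if n_true else 1.0
    precision = len(matched) / n_calls if n_calls else 1.0
    parent_ok = sum(1 for t, c in matched if c.parent_gene_id == t.parent_gene_id)
    class_ok = sum(1 for t, c in matched if c.classification == t.expected_class)
    return {
        "n_true": n_true,
        "n_calls": n_calls,
        "n_matched": len(matched),
        "recall": recall,
        "precision": precision,
        "parent_accuracy": parent_ok / len(matched) if matched else 1.0,
        "classification_accuracy": class_ok / len(matched) if matched else 1.0,
        "decoy_calls": decoy_calls,
        "matched": matched,
    }
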