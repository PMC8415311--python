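"""Genome and annotation I/O: FASTA/GFF3 parsing, gene models, protein queries.

Internal coordinates are 0-based half-open throughout; conversion to/from the
1-based closed GFF3 convention happens only at the file boundary.  Gene models
carry their exon and CDS intervals in *transcription order* (for minus-strand
transcripts that is decreasing genomic coordinate), which makes splicing,
phase handling and intron projection strand-agnostic.

The protein query objects produced here are the units the rest of the
pipeline works with: the longest-CDS isoform of each gene, translated, with
every CDS-interrupting intron projected onto amino-acid coordinates.  A
retrocopy is recognised later precisely by the *absence* of those introns at
the ectopic locus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger("retrocall")

__all__ = [
    "GenomeSequence",
    "TranscriptModel",
    "GeneModel",
    "ProteinQuery",
    "GenomeIOError",
    "parse_genome_fasta",
    "parse_gff",
    "write_gff3",
    "select_longest_transcript",
    "extract_protein",
    "project_introns_to_protein",
    "build_queries",
    "revcomp",
]


class GenomeIOError(ValueError):
    """Malformed FASTA/GFF3 input."""


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
# anything outside {A,C,G,T,N} (after uppercasing) becomes N
_NORMALIZE = {c: c for c in "ACGTN"}
_NORM_TABLE = str.maketrans(
    {chr(i): (chr(i) if chr(i) in _NORMALIZE else "N") for i in range(33, 127)}
)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeSequence:
    """Name -> uppercase DNA over {A,C,G,T,N}."""

    sequences: dict[str, str]

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def names(self) -> list[str]:
        return list(self.sequences)

    def length(self, name: str) -> int:
        return len(self.sequences[name])


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    #: exon intervals (start, end), 0-based half-open, transcription order
    exons: list[tuple[int, int]]
    #: CDS segments (start, end, phase), transcription order
    cds_segments: list[tuple[int, int, int]]

    @property
    def spliced_cds_length(self) -> int:
        return sum(e - s for s, e, _ in self.cds_segments)

    @property
    def n_cds_introns(self) -> int:
        return max(len(self.cds_segments) - 1, 0)


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class ProteinQuery:
    """Longest-isoform protein with intron positions in aa coordinates.

    ``intron_sites`` holds ``(aa_position, intron_genomic_length)`` for every
    CDS-interrupting intron: ``aa_position`` indexes the residue whose codon
    is interrupted by (or immediately follows) the intron, and the length is
    the genomic gap between the flanking CDS segments.
    """

    gene_id: str
    transcript_id: str
    protein: str
    intron_sites: list[tuple[int, int]]
    #: phase-trimmed spliced CDS (terminal stop codon retained if annotated)
    cds: str = ""

    @property
    def n_introns(self) -> int:
        return len(self.intron_sites)

    def __len__(self) -> int:
        return len(self.protein)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def parse_genome_fasta(path: str | Path) -> GenomeSequence:
    """Load a (possibly line-wrapped) multi-record FASTA.

    Lowercase bases are uppercased and any character outside {A,C,G,T,N} is
    mapped to N.  Duplicate record names and empty files are hard errors.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise GenomeIOError(f"duplicate sequence name in {path}: {rec.id!r}")
        seq = str(rec.seq).upper().translate(_NORM_TABLE)
        if not seq:
            raise GenomeIOError(f"empty sequence record in {path}: {rec.id!r}")
        sequences[rec.id] = seq
    if not sequences:
        raise GenomeIOError(f"no FASTA records found in {path}")
    return GenomeSequence(sequences)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_TRANSCRIPT_TYPES = {"mRNA", "transcript"}


def _parse_attributes(attr_col: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in attr_col.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise GenomeIOError(
                f"GFF line {lineno}: unparseable attribute {part!r} (expected key=value)"
            )
        key, _, value = part.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def parse_gff(path: str | Path, genome: GenomeSequence) -> list[GeneModel]:
    """Parse a GFF3 annotation into gene models.

    Accepts both ``mRNA`` and ``transcript`` feature types; features on
    chromosomes absent from *genome* are dropped with a warning; transcripts
    without CDS (and genes left with no transcript) are dropped; an mRNA whose
    parent gene row is missing gets a gene synthesized from its own span.
    """
    genes: dict[str, dict] = {}
    transcripts: dict[str, dict] = {}
    order: list[str] = []  # gene ids in file order

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("##FASTA"):
                break
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GenomeIOError(
                    f"GFF line {lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            chrom, _source, ftype, start_s, end_s, _score, strand, phase_s, attr_col = cols
            if ftype not in {"gene", "exon", "CDS"} | _TRANSCRIPT_TYPES:
                continue
            try:
                start = int(start_s) - 1  # to 0-based half-open
                end = int(end_s)
            except ValueError:
                raise GenomeIOError(f"GFF line {lineno}: non-integer coordinates") from None
            if start < 0 or end <= start:
                raise GenomeIOError(f"GFF line {lineno}: invalid interval {start_s}..{end_s}")
            if chrom not in genome:
                log.warning("GFF line %d: unknown chromosome %r, feature dropped", lineno, chrom)
                continue
            attrs = _parse_attributes(attr_col, lineno)

            if ftype == "gene":
                gid = attrs.get("ID") or attrs.get("gene_id")
                if gid is None:
                    raise GenomeIOError(f"GFF line {lineno}: gene without ID attribute")
                genes[gid] = {"chrom": chrom, "strand": strand, "start": start, "end": end}
                order.append(gid)
            elif ftype in _TRANSCRIPT_TYPES:
                tid = attrs.get("ID") or attrs.get("transcript_id")
                if tid is None:
                    raise GenomeIOError(f"GFF line {lineno}: {ftype} without ID attribute")
                parent = attrs.get("Parent") or attrs.get("gene_id") or tid + "_gene"
                transcripts[tid] = {
                    "gene": parent,
                    "chrom": chrom,
                    "strand": strand,
                    "start": start,
                    "end": end,
                    "exons": [],
                    "cds": [],
                }
            else:  # exon / CDS
                parents = (attrs.get("Parent") or attrs.get("transcript_id") or "").split(",")
                parents = [p for p in parents if p]
                if not parents:
                    raise GenomeIOError(f"GFF line {lineno}: {ftype} without Parent attribute")
                if end > genome.length(chrom):
                    raise GenomeIOError(
                        f"GFF line {lineno}: {ftype} extends past end of {chrom} "
                        f"({end} > {genome.length(chrom)})"
                    )
                phase = int(phase_s) if phase_s.isdigit() else None
                for pid in parents:
                    if pid not in transcripts:
                        # tolerate exon/CDS rows preceding their mRNA row only via
                        # a placeholder; filled when the mRNA row arrives
                        transcripts.setdefault(
                            pid,
                            {
                                "gene": pid + "_gene",
                                "chrom": chrom,
                                "strand": strand,
                                "start": start,
                                "end": end,
                                "exons": [],
                                "cds": [],
                                "implicit": True,
                            },
                        )
                    rec = transcripts[pid]
                    if ftype == "exon":
                        rec["exons"].append((start, end))
                    else:
                        rec["cds"].append((start, end, phase))

    models: dict[str, GeneModel] = {}
    for tid, rec in transcripts.items():
        if not rec["cds"]:
            log.warning("transcript %s has no CDS, dropped", tid)
            continue
        gid = rec["gene"]
        if gid not in genes:
            log.warning("mRNA %s has no parent gene row; gene %s synthesized from span", tid, gid)
            genes[gid] = {
                "chrom": rec["chrom"],
                "strand": rec["strand"],
                "start": rec["start"],
                "end": rec["end"],
            }
            order.append(gid)
        tm = _finalize_transcript(tid, gid, rec)
        if gid not in models:
            g = genes[gid]
            models[gid] = GeneModel(gid, g["chrom"], g["strand"], g["start"], g["end"])
        gm = models[gid]
        gm.transcripts.append(tm)
        gm.start = min(gm.start, min(s for s, _ in tm.exons))
        gm.end = max(gm.end, max(e for _, e in tm.exons))

    out = [models[g] for g in order if g in models]
    for gm in out:
        gm.transcripts.sort(key=lambda t: t.transcript_id)
    return out


def _finalize_transcript(tid: str, gid: str, rec: dict) -> TranscriptModel:
    strand = rec["strand"]
    exons = sorted(set(rec["exons"]))
    cds = sorted({(s, e) for s, e, _ in rec["cds"]})
    phases = {(s, e): p for s, e, p in rec["cds"]}
    if not exons:
        exons = list(cds)
    if strand == "-":
        exons = exons[::-1]
        cds = cds[::-1]
    # recompute missing phases by cumulative CDS length in transcription order
    cum = 0
    segs: list[tuple[int, int, int]] = []
    for s, e in cds:
        phase = phases.get((s, e))
        if phase is None:
            phase = (3 - cum % 3) % 3
        segs.append((s, e, phase))
        cum += e - s
    return TranscriptModel(tid, gid, rec["chrom"], strand, exons, segs)


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Serialize gene models back to GFF3 (1-based closed coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tretrocall\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for t in g.transcripts:
                t_start = min(s for s, _ in t.exons)
                t_end = max(e for _, e in t.exons)
                fh.write(
                    f"{g.chrom}\tretrocall\tmRNA\t{t_start + 1}\t{t_end}\t.\t{t.strand}\t.\t"
                    f"ID={t.transcript_id};Parent={g.gene_id}\n"
                )
                for s, e in sorted(t.exons):
                    fh.write(
                        f"{g.chrom}\tretrocall\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                        f"Parent={t.transcript_id}\n"
                    )
                for s, e, phase in sorted(t.cds_segments):
                    fh.write(
                        f"{g.chrom}\tretrocall\tCDS\t{s + 1}\t{e}\t.\t{t.strand}\t{phase}\t"
                        f"Parent={t.transcript_id}\n"
                    )


# ---------------------------------------------------------------------------
# Gene-model operations
# ---------------------------------------------------------------------------

def select_longest_transcript(gene: GeneModel) -> TranscriptModel:
    """The transcript with the longest spliced CDS; ties go to the
    lexicographically smallest transcript id (deterministic)."""
    with_cds = [t for t in gene.transcripts if t.cds_segments]
    if not with_cds:
        raise ValueError(f"gene {gene.gene_id} has no transcript with CDS")
    return max(with_cds, key=lambda t: (t.spliced_cds_length, _neg_id(t.transcript_id)))


def _neg_id(tid: str):
    # max() helper: prefer lexicographically smaller ids on length ties
    return tuple(-ord(c) for c in tid)


def project_introns_to_protein(t: TranscriptModel) -> list[tuple[int, int]]:
    """Project CDS-interrupting introns onto protein coordinates.

    Only introns between consecutive CDS segments count (UTR introns are
    invisible to the protein).  The residue index is the floor of the spliced
    CDS length (post phase-trim) preceding the intron, divided by 3; the
    length is the genomic gap between the flanking segments.
    """
    segs = t.cds_segments
    if len(segs) < 2:
        return []
    first_phase = segs[0][2]
    sites: list[tuple[int, int]] = []
    cum = -first_phase
    for i in range(len(segs) - 1):
        s, e, _ = segs[i]
        cum += e - s
        ns, ne, _ = segs[i + 1]
        if t.strand == "+":
            gap = ns - e
        else:
            gap = s - ne
        sites.append((max(cum, 0) // 3, gap))
    return sites


def extract_protein(t: TranscriptModel, genome: GenomeSequence) -> ProteinQuery:
    """Splice and translate the CDS of a transcript.

    Minus-strand CDS is reverse-complemented before splicing, the first
    segment's phase is trimmed, a trailing length remainder (mod 3) is trimmed
    with a warning, and the terminal stop is removed from the protein.
    Internal stops are permitted (annotation noise) but logged.
    """
    chrom_seq = genome[t.chrom]
    parts = [chrom_seq[s:e] for s, e in sorted((s, e) for s, e, _ in t.cds_segments)]
    spliced = "".join(parts)
    if t.strand == "-":
        spliced = revcomp(spliced)
    phase = t.cds_segments[0][2]
    spliced = spliced[phase:]
    if len(spliced) % 3:
        log.warning(
            "transcript %s: spliced CDS length %d not divisible by 3, trailing remainder trimmed",
            t.transcript_id,
            len(spliced),
        )
        spliced = spliced[: len(spliced) - len(spliced) % 3]
    if len(spliced) < 3:
        raise ValueError(f"transcript {t.transcript_id}: spliced CDS shorter than one codon")
    protein = str(Seq(spliced).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        log.warning("transcript %s: internal stop codon(s) in translation", t.transcript_id)
    sites = [
        (min(aa, len(protein) - 1), length)
        for aa, length in project_introns_to_protein(t)
        if len(protein) > 0
    ]
    return ProteinQuery(t.gene_id, t.transcript_id, protein, sites, cds=spliced)


def build_queries(genes: list[GeneModel], genome: GenomeSequence) -> dict[str, ProteinQuery]:
    """Protein query set: longest isoform of every *multiexon* gene.

    Genes whose longest transcript has a single CDS segment are excluded —
    an intronless parent cannot lose introns, and retrocopy evidence requires
    at least two lost introns downstream.
    """
    queries: dict[str, ProteinQuery] = {}
    for gene in genes:
        try:
            t = select_longest_transcript(gene)
        except ValueError:
            continue
        if len(t.cds_segments) < 2:
            continue
        q = extract_protein(t, genome)
        if len(q.protein) == 0:
            continue
        queries[gene.gene_id] = q
    return queries
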