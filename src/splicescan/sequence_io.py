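"""FASTA/GTF input-output and splice-site derivation from exon annotation.

Coordinate conventions used throughout the package:

* genome coordinates are 1-based;
* GTF exons are 1-based closed intervals (standard GTF);
* a splice-site *boundary* is the 1-based position of the last base before
  the junction, so the junction lies between ``boundary`` and ``boundary+1``.
  For a donor this is the last exonic base (the intron starts at
  ``boundary+1`` with the canonical ``GT``); for an acceptor it is the last
  intronic base (the intron ends with the canonical ``AG`` at
  ``boundary-1..boundary``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

from .errors import (
    AlphabetError,
    CoordinateError,
    FastaFormatError,
    GtfFormatError,
)

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

DONOR = "donor"
ACCEPTOR = "acceptor"
SITE_TYPES = (DONOR, ACCEPTOR)

CANONICAL_DONOR_DIMER = "GT"
CANONICAL_ACCEPTOR_DIMER = "AG"


@dataclass(frozen=True)
class GenomeSequence:
    """A named DNA sequence over {A,C,G,T,N} with 1-based accessors."""

    name: str
    seq: str

    def __post_init__(self):
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise AlphabetError(
                f"sequence {self.name!r} contains invalid characters: "
                f"{sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    def subseq(self, start: int, end: int) -> str:
        """Bases ``start..end`` inclusive, 1-based."""
        if start < 1 or end > len(self.seq) or start > end:
            raise CoordinateError(
                f"interval {start}..{end} outside sequence {self.name!r} "
                f"of length {len(self.seq)}"
            )
        return self.seq[start - 1 : end]

    def dinucleotide(self, pos: int) -> str:
        """The two bases at ``pos`` and ``pos+1``."""
        return self.subseq(pos, pos + 1)


class Region(NamedTuple):
    """A 1-based closed interval on a named sequence."""

    seq_name: str
    start: int
    end: int

    @classmethod
    def parse(cls, text: str) -> "Region":
        """Parse ``name:start-end`` (1-based closed)."""
        try:
            name, span = text.rsplit(":", 1)
            lo, hi = span.split("-")
            region = cls(name, int(lo), int(hi))
        except ValueError as exc:
            raise ValueError(f"cannot parse region {text!r}; "
                             "expected name:start-end") from exc
        if region.start < 1 or region.start > region.end:
            raise CoordinateError(f"invalid region span in {text!r}")
        return region

    def __str__(self) -> str:
        return f"{self.seq_name}:{self.start}-{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ExonRecord:
    seq_name: str
    gene_id: str
    transcript_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str = "+"

    def __post_init__(self):
        if self.start < 1 or self.start > self.end:
            raise CoordinateError(
                f"exon {self.gene_id}/{self.transcript_id} has invalid "
                f"interval {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise GtfFormatError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True, order=True)
class SpliceSite:
    seq_name: str
    boundary: int  # last base before the junction
    site_type: str  # "donor" | "acceptor"
    canonical: bool

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.seq_name, self.site_type, self.boundary)


def read_fasta(path) -> list[GenomeSequence]:
    """Read a (possibly multi-record, multi-line) FASTA file.

    Sequences are uppercased; soft-masking is discarded. Raises
    :class:`FastaFormatError` naming the offending line for an empty file
    or a file whose first non-blank line is not a header.
    """
    path = Path(path)
    with open(path) as handle:
        lines = handle.readlines()
    first_content = None
    for i, line in enumerate(lines, start=1):
        if line.strip():
            first_content = i
            break
    if first_content is None:
        raise FastaFormatError(f"empty FASTA file: {path}", line=1)
    if not lines[first_content - 1].startswith(">"):
        raise FastaFormatError(
            f"malformed FASTA header in {path}: expected '>'",
            line=first_content,
        )
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise FastaFormatError(
                f"record {rec.id!r} in {path} contains invalid characters "
                f"{sorted(bad)!r}"
            )
        out.append(GenomeSequence(rec.id, seq))
    return out


def write_fasta(sequences: Iterable[GenomeSequence], path, line_width: int = 60):
    """Write sequences as wrapped FASTA; round-trips with :func:`read_fasta`."""
    records = [SeqRecord(Seq(g.seq), id=g.name, description="") for g in sequences]
    with open(path, "w") as handle:
        writer = FastaWriter(handle, wrap=line_width)
        writer.write_file(records)


def read_gtf_exons(path) -> list[ExonRecord]:
    """Read exon rows from a GTF file.

    Non-exon features are ignored. Rows lacking a ``gene_id`` or
    ``transcript_id`` attribute raise :class:`GtfFormatError` with the
    1-based line number.
    """
    path = Path(path)
    exons: list[ExonRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise GtfFormatError(
                    f"unparseable GTF row in {path}: {exc}", line=lineno
                ) from exc
            if feat.featuretype != "exon":
                continue
            attrs = feat.attributes
            for required in ("gene_id", "transcript_id"):
                if required not in attrs or not attrs[required]:
                    raise GtfFormatError(
                        f"exon row missing mandatory attribute "
                        f"{required!r} in {path}",
                        line=lineno,
                    )
            exons.append(
                ExonRecord(
                    seq_name=feat.seqid,
                    gene_id=attrs["gene_id"][0],
                    transcript_id=attrs["transcript_id"][0],
                    start=feat.start,
                    end=feat.end,
                    strand=feat.strand,
                )
            )
    return exons


def write_gtf(exons: Iterable[ExonRecord], path):
    """Write exon records as GTF; round-trips with :func:`read_gtf_exons`."""
    with open(path, "w") as handle:
        for e in exons:
            attrs = f'gene_id "{e.gene_id}"; transcript_id "{e.transcript_id}";'
            handle.write(
                "\t".join(
                    [
                        e.seq_name,
                        "splicescan",
                        "exon",
                        str(e.start),
                        str(e.end),
                        ".",
                        e.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def _as_genome_map(
    genome: GenomeSequence | Iterable[GenomeSequence] | Mapping[str, GenomeSequence],
) -> dict[str, GenomeSequence]:
    if isinstance(genome, GenomeSequence):
        return {genome.name: genome}
    if isinstance(genome, Mapping):
        return dict(genome)
    return {g.name: g for g in genome}


_REVCOMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_REVCOMP)[::-1]


def extract_splice_sites(
    exons: Iterable[ExonRecord],
    genome: GenomeSequence | Iterable[GenomeSequence] | Mapping[str, GenomeSequence],
    include_reverse: bool = False,
) -> list[SpliceSite]:
    """Derive the annotated splice sites implied by exon records.

    Per transcript with k >= 2 exons sorted by start, the junction between
    consecutive exons yields one donor (boundary = upstream exon end) and
    one acceptor (boundary = downstream exon start - 1). Transcript-terminal
    exon boundaries are transcription start/termination sites, not splice
    junctions, and contribute nothing. Sites shared between transcripts
    (alternative splicing) are de-duplicated on (seq_name, site_type,
    boundary). The canonical flag is read off the genome (GT after a donor,
    AG before an acceptor; checked on the reverse complement for
    minus-strand transcripts).

    Minus-strand transcripts are skipped with a warning unless
    ``include_reverse`` is set.
    """
    genomes = _as_genome_map(genome)
    by_transcript: dict[tuple[str, str], list[ExonRecord]] = {}
    for exon in exons:
        if exon.seq_name not in genomes:
            raise CoordinateError(
                f"exon references unknown sequence {exon.seq_name!r}"
            )
        g = genomes[exon.seq_name]
        if exon.end > g.length:
            raise CoordinateError(
                f"exon {exon.start}..{exon.end} outside sequence "
                f"{exon.seq_name!r} of length {g.length}"
            )
        by_transcript.setdefault((exon.seq_name, exon.transcript_id), []).append(exon)

    seen: set[tuple[str, str, int]] = set()
    sites: list[SpliceSite] = []
    n_skipped_reverse = 0
    for (seq_name, _tid), tx_exons in sorted(by_transcript.items()):
        strand = tx_exons[0].strand
        if strand == "-" and not include_reverse:
            n_skipped_reverse += 1
            continue
        if len(tx_exons) < 2:
            continue
        g = genomes[seq_name]
        ordered = sorted(tx_exons, key=lambda e: e.start)
        for left, right in zip(ordered, ordered[1:]):
            if strand == "+":
                junctions = [
                    (left.end, DONOR),
                    (right.start - 1, ACCEPTOR),
                ]
            else:
                # In transcript orientation the donor sits at the genomic
                # right end of the intron and the acceptor at its left end.
                junctions = [
                    (right.start - 1, DONOR),
                    (left.end, ACCEPTOR),
                ]
            for boundary, site_type in junctions:
                if boundary < 2 or boundary > g.length - 2:
                    raise CoordinateError(
                        f"splice boundary {boundary} too close to the edge "
                        f"of sequence {seq_name!r}"
                    )
                key = (seq_name, site_type, boundary)
                if key in seen:
                    continue
                seen.add(key)
                sites.append(
                    SpliceSite(
                        seq_name=seq_name,
                        boundary=boundary,
                        site_type=site_type,
                        canonical=_is_canonical(g, boundary, site_type, strand),
                    )
                )
    if n_skipped_reverse:
        logger.warning(
            "skipped %d minus-strand transcript(s); pass include_reverse=True "
            "to derive their sites",
            n_skipped_reverse,
        )
    return sorted(sites)


def _is_canonical(
    g: GenomeSequence, boundary: int, site_type: str, strand: str = "+"
) -> bool:
    if strand == "+":
        if site_type == DONOR:
            return g.dinucleotide(boundary + 1) == CANONICAL_DONOR_DIMER
        return g.dinucleotide(boundary - 1) == CANONICAL_ACCEPTOR_DIMER
    if site_type == DONOR:
        return reverse_complement(g.dinucleotide(boundary - 1)) == CANONICAL_DONOR_DIMER
    return reverse_complement(g.dinucleotide(boundary + 1)) == CANONICAL_ACCEPTOR_DIMER


def write_sites_tsv(sites: Iterable[SpliceSite], path):
    frame = pd.DataFrame(
        [
            {
                "seq_name": s.seq_name,
                "site_type": s.site_type,
                "boundary": s.boundary,
                "canonical": s.canonical,
            }
            for s in sites
        ],
        columns=["seq_name", "site_type", "boundary", "canonical"],
    )
    frame.to_csv(path, sep="\t", index=False)


def read_sites_tsv(path) -> list[SpliceSite]:
    frame = pd.read_csv(path, sep="\t")
    return [
        SpliceSite(
            seq_name=str(row.seq_name),
            boundary=int(row.boundary),
            site_type=str(row.site_type),
            canonical=bool(row.canonical),
        )
        for row in frame.itertuples()
    ]
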