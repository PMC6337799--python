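"""Standard-format I/O: FASTQ pairs, FASTA genomes, BED intervals, TSV tables.

Coordinates are 0-based half-open internally; BED output keeps that
convention, human-readable TSV reports are 1-based (handled in `report`).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Raised for malformed input files."""


@dataclass
class ReadPair:
    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str
    sample_id: str | None = None


def _fastq_records(path: str | Path):
    return SeqIO.parse(str(path), "fastq")


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> Iterator[ReadPair]:
    """Stream read pairs from two FASTQ files, pairing records by order.

    Identifiers must agree per pair (a trailing ``/1``/``/2`` suffix is
    tolerated); unequal record counts or identifier mismatches raise
    :class:`FormatError`.
    """
    it1, it2 = _fastq_records(r1_path), _fastq_records(r2_path)
    sentinel = object()
    n = 0
    while True:
        rec1 = next(it1, sentinel)
        rec2 = next(it2, sentinel)
        if rec1 is sentinel and rec2 is sentinel:
            return
        if rec1 is sentinel or rec2 is sentinel:
            raise FormatError(
                f"unequal record counts in {r1_path} / {r2_path} (stopped after {n} pairs)")
        id1 = rec1.id.removesuffix("/1")
        id2 = rec2.id.removesuffix("/2")
        if id1 != id2:
            raise FormatError(f"mismatched pair identifiers at record {n + 1}: {rec1.id} vs {rec2.id}")
        n += 1
        yield ReadPair(
            read_id=id1,
            seq1=str(rec1.seq),
            qual1="".join(chr(q + 33) for q in rec1.letter_annotations["phred_quality"]),
            seq2=str(rec2.seq),
            qual2="".join(chr(q + 33) for q in rec2.letter_annotations["phred_quality"]),
        )


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    """Write (id, seq, qual) triples as 4-line Phred+33 FASTQ."""
    seq_records = []
    for read_id, seq, qual in records:
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
        seq_records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fastq")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a genome FASTA into an ordered name -> sequence dict (upper-case)."""
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise FormatError(f"duplicate sequence name {rec.id!r} in {path}")
        genome[rec.id] = str(rec.seq).upper()
    return genome


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_sites_bed(sites, path: str | Path) -> None:
    """Write sites as BED6 (0-based half-open; score column = abundance).

    Strand is the site's majority orientation ('+' on ties).
    """
    rows = []
    for site in sites:
        plus = site.strands.get("+", 0)
        minus = site.strands.get("-", 0)
        strand = "+" if plus >= minus else "-"
        rows.append((site.chrom, site.position, site.position + 1,
                     site.site_id, site.abundance, strand))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str, float, str]]:
    """Read BED3+ lines as (chrom, start, end, name, score, strand) tuples."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{i}: fewer than 3 BED fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end < start:
                raise FormatError(f"{path}:{i}: negative-width interval")
            name = fields[3] if len(fields) > 3 else f"feature_{i}"
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            strand = fields[5] if len(fields) > 5 else "+"
            out.append((chrom, start, end, name, score, strand))
    return out
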