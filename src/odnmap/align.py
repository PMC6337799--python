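"""Fragment placement on the reference.

A built-in exact/seeded ungapped aligner covers synthetic genomes (the
junction base must be recovered exactly); externally aligned real data
enters through SAM import. ``junction_pos`` is the genomic coordinate of
the ODN-genome junction base, ``break_pos`` the sonication end, both
0-based and inclusive, so ``|break - junction| + 1`` equals fragment length.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import pysam

from .dna import revcomp
from .io import FormatError
from .reads import TrimmedFragment


@dataclass
class FragmentAlignment:
    read_id: str
    chrom: str
    strand: str  # '+' or '-'
    junction_pos: int
    break_pos: int
    score: int  # matched bases
    unique: bool

    @property
    def fragment_length(self) -> int:
        return abs(self.break_pos - self.junction_pos) + 1

    @property
    def start(self) -> int:
        """Left end of the covered interval (0-based)."""
        return min(self.junction_pos, self.break_pos)

    @property
    def end(self) -> int:
        """Right end, half-open."""
        return max(self.junction_pos, self.break_pos) + 1


class KmerIndex:
    """Exact k-mer position index over the forward strand of a genome.

    Reverse-strand placements are found by seeding the reverse complement
    of the query, so the index itself stays strand-agnostic. K-mers
    containing N are skipped.
    """

    def __init__(self, genome: dict[str, str], k: int = 15):
        if len(set(genome)) != len(genome):
            raise ValueError("duplicate sequence names in genome")
        self.k = k
        self.genome = genome
        self.positions: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name, seq in genome.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                if "N" not in kmer:
                    self.positions[kmer].append((name, i))
        self.positions = dict(self.positions)

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self.positions.get(kmer, [])


def build_index(genome: dict[str, str], k: int = 15) -> KmerIndex:
    return KmerIndex(genome, k=k)


def _candidate_placements(seq: str, index: KmerIndex) -> set[tuple[str, int]]:
    """Placement starts implied by exact seed hits at every k-th query offset."""
    k = index.k
    L = len(seq)
    candidates: set[tuple[str, int]] = set()
    offsets = list(range(0, L - k + 1, k))
    if offsets and offsets[-1] != L - k:
        offsets.append(L - k)
    for off in offsets:
        for chrom, pos in index.lookup(seq[off:off + k]):
            start = pos - off
            if start >= 0 and start + L <= len(index.genome[chrom]):
                candidates.add((chrom, start))
    return candidates


def align_fragment(
    frag: TrimmedFragment | str,
    index: KmerIndex,
    max_mismatch_frac: float = 0.05,
    read_id: str = "",
) -> list[FragmentAlignment]:
    """Seed-and-extend ungapped alignment; returns all best-scoring placements.

    Seeds are exact k-mers at stride k (plus a terminal seed), so any
    placement with fewer mismatches than the number of seeds is guaranteed
    to be found. ``unique`` is True iff a single placement attains the best
    score; ties are reported with ``unique=False`` rather than picking one.
    The fragment's position 0 anchors ``junction_pos``.
    """
    if isinstance(frag, TrimmedFragment):
        seq, read_id = frag.genomic_seq, frag.read_id
    else:
        seq = frag
    L = len(seq)
    if L < index.k:
        return []
    budget = int(max_mismatch_frac * L)
    hits: list[tuple[str, int, str, int]] = []  # chrom, start, strand, score
    for strand, query in (("+", seq), ("-", revcomp(seq))):
        for chrom, start in _candidate_placements(query, index):
            ref = index.genome[chrom][start:start + L]
            mm = sum(a != b for a, b in zip(query, ref))
            if mm <= budget:
                hits.append((chrom, start, strand, L - mm))
    if not hits:
        return []
    best = max(h[3] for h in hits)
    best_hits = sorted({h for h in hits if h[3] == best})
    unique = len(best_hits) == 1
    out = []
    for chrom, start, strand, score in best_hits:
        if strand == "+":
            junction, brk = start, start + L - 1
        else:
            junction, brk = start + L - 1, start
        out.append(FragmentAlignment(read_id, chrom, strand, junction, brk, score, unique))
    return out


def _resolve_break_from_mate(
    aln: FragmentAlignment,
    frag: TrimmedFragment,
    index: KmerIndex,
    max_mismatch_frac: float,
    max_insert: int,
) -> int:
    """The sonication break comes from the adapter-side mate when the
    fragment outruns the ODN-side read: the mate's position-0 base is the
    break. A compatible placement must sit on the same chromosome, in the
    opposite orientation, on the junction's 3' side, within ``max_insert``.
    Falls back to the ODN-side read's own extent when no single compatible
    mate placement exists."""
    if len(frag.mate_seq) < index.k:
        return aln.break_pos
    mate_hits = align_fragment(frag.mate_seq, index, max_mismatch_frac,
                               read_id=frag.read_id)
    compatible = []
    for mh in mate_hits:
        if mh.chrom != aln.chrom or mh.strand == aln.strand:
            continue
        if aln.strand == "+" and 0 <= mh.junction_pos - aln.junction_pos < max_insert:
            compatible.append(mh.junction_pos)
        elif aln.strand == "-" and 0 <= aln.junction_pos - mh.junction_pos < max_insert:
            compatible.append(mh.junction_pos)
    if len(compatible) == 1:
        return compatible[0]
    return aln.break_pos


def align_all(
    frags: list[TrimmedFragment],
    index: KmerIndex,
    max_mismatch_frac: float = 0.05,
    max_insert: int = 10_000,
) -> tuple[dict[str, FragmentAlignment], dict[str, int]]:
    """Align fragments (using the mate to pin the sonication break); returns
    unique best placements keyed by read id plus a tally of
    {aligned, multimapped, unaligned}."""
    placements: dict[str, FragmentAlignment] = {}
    tally = {"aligned": 0, "multimapped": 0, "unaligned": 0}
    for frag in frags:
        hits = align_fragment(frag, index, max_mismatch_frac)
        if not hits:
            tally["unaligned"] += 1
        elif hits[0].unique:
            aln = hits[0]
            aln.break_pos = _resolve_break_from_mate(
                aln, frag, index, max_mismatch_frac, max_insert)
            placements[frag.read_id] = aln
            tally["aligned"] += 1
        else:
            tally["multimapped"] += 1
    return placements, tally


def import_sam(
    path: str | Path,
    odn_side_read: str = "r1",
    mapq_min: int = 30,
) -> list[FragmentAlignment]:
    """Derive fragment alignments from a headered SAM file.

    The ODN-side read (``r1`` by convention; ``r2`` or ``any`` accepted)
    carries the junction at its 5' alignment end: forward-strand records
    put the junction at POS, reverse-strand records at the CIGAR reference
    end minus one. The opposite end of the aligned span is taken as the
    sonication break. Reads with secondary/supplementary records or MAPQ
    below ``mapq_min`` (a convention, not a published value) are flagged
    ``unique=False``.
    """
    if odn_side_read not in ("r1", "r2", "any"):
        raise ValueError(f"odn_side_read must be r1/r2/any, got {odn_side_read!r}")
    path = str(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("@"):
        raise FormatError(f"{path}: SAM header required")
    primary: dict[str, pysam.AlignedSegment] = {}
    multi: set[str] = set()
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            if rec.is_paired:
                if odn_side_read == "r1" and not rec.is_read1:
                    continue
                if odn_side_read == "r2" and not rec.is_read2:
                    continue
            if rec.is_secondary or rec.is_supplementary:
                multi.add(rec.query_name)
                continue
            if rec.query_name in primary:
                multi.add(rec.query_name)
                continue
            primary[rec.query_name] = rec
    out = []
    for name, rec in sorted(primary.items()):
        start = rec.reference_start
        end = rec.reference_end  # half-open CIGAR reference end
        if rec.is_reverse:
            strand, junction, brk = "-", end - 1, start
        else:
            strand, junction, brk = "+", start, end - 1
        unique = name not in multi and (rec.mapping_quality >= mapq_min)
        score = sum(length for op, length in (rec.cigartuples or []) if op == 0)
        out.append(FragmentAlignment(name, rec.reference_name, strand,
                                     junction, brk, score, unique))
    return out
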