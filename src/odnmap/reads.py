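"""Read processing: demultiplexing, reporter detection, and fragment trimming.

The sequencing amplicon reads out as:

* ODN-side read (R1): ``primer2 + reporter + genomic flank`` for correctly
  primed molecules, or ``primer2 + genomic`` for misprimed ones — mispriming
  copies the primer itself into the product, so only the reporter segment
  distinguishes the two.
* adapter-side read (R2): ``barcode + adapter + revcomp(genomic flank)``
  read inward from the sonication break.

Trimming leaves ``genomic_seq`` whose position 0 is the ODN-genome junction
base, and ``mate_seq`` whose position 0 is the sonication break.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .config import OdnSpec, SampleSpec
from .dna import hamming_distance, revcomp
from .io import ReadPair

AMBIGUOUS = "ambiguous"


@dataclass
class ReporterHit:
    found: bool
    mismatches: int | None
    end_pos: int | None
    reason: str = ""


@dataclass
class TrimmedFragment:
    read_id: str
    sample_id: str
    genomic_seq: str
    mate_seq: str
    reporter_found: bool
    reporter_mismatches: int | None
    primer_trimmed: bool


def demultiplex(
    pairs: Iterable[ReadPair],
    samples: list[SampleSpec],
    tolerance: int = 0,
) -> tuple[dict[str, list[ReadPair]], dict[str, int]]:
    """Assign read pairs to samples by the barcode prefix of the R2 read.

    Exact match by default; with ``tolerance`` > 0 a pair is assigned to the
    unique sample within Hamming distance ``tolerance`` (ties or no hit go to
    the ``ambiguous`` bin). The matched barcode prefix is stripped from R2.
    Returns (bins, counts) where counts includes every input pair.
    """
    bins: dict[str, list[ReadPair]] = {s.sample_id: [] for s in samples}
    bins[AMBIGUOUS] = []
    counts = {k: 0 for k in bins}
    for pair in pairs:
        hits = []
        for s in samples:
            prefix = pair.seq2[: len(s.barcode)]
            if len(prefix) == len(s.barcode):
                d = hamming_distance(prefix, s.barcode)
                if d <= tolerance:
                    hits.append((d, s))
        hits.sort(key=lambda h: h[0])
        if len(hits) == 1 or (len(hits) > 1 and hits[0][0] < hits[1][0]):
            s = hits[0][1]
            n = len(s.barcode)
            assigned = ReadPair(pair.read_id, pair.seq1, pair.qual1,
                                pair.seq2[n:], pair.qual2[n:], sample_id=s.sample_id)
            bins[s.sample_id].append(assigned)
            counts[s.sample_id] += 1
        else:
            bins[AMBIGUOUS].append(pair)
            counts[AMBIGUOUS] += 1
    return bins, counts


def detect_reporter(seq: str, odn: OdnSpec) -> ReporterHit:
    """Ungapped reporter check at the start of the post-primer read.

    ``seq`` must begin at the primer2 3' end; the reporter is compared
    against the read prefix and found iff the mismatch count is at most
    ``odn.reporter_max_mismatch``. ``end_pos`` is the index of the first
    genomic base when found.
    """
    rep = odn.reporter
    if len(seq) < len(rep):
        return ReporterHit(False, None, None, reason="too_short")
    mm = hamming_distance(seq[: len(rep)], rep)
    if mm <= odn.reporter_max_mismatch:
        return ReporterHit(True, mm, len(rep))
    return ReporterHit(False, mm, None, reason="no_reporter")


def _trim_readthrough(seq: str, element: str, min_overlap: int = 6) -> str:
    """Remove a 3' read-through into ``element`` (the reverse-complemented
    opposite amplicon element). The earliest suffix of ``seq`` that is a
    prefix of ``element`` is cut, requiring ``min_overlap`` matched bases
    unless the full element is present."""
    full = seq.find(element)
    if full >= 0:
        return seq[:full]
    max_tail = min(len(seq), len(element) - 1)
    for tail_len in range(max_tail, min_overlap - 1, -1):
        if seq.endswith(element[:tail_len]):
            return seq[: len(seq) - tail_len]
    return seq


def trim_fragment(pair: ReadPair, odn: OdnSpec) -> TrimmedFragment | None:
    """Trim ODN/primer/adapter sequence, leaving the genomic fragment.

    The ODN-side read loses primer2 (tolerating ``primer_max_mismatch``
    substitutions) and, when detected, the reporter, so that position 0 of
    ``genomic_seq`` is the junction base. The adapter-side read loses the
    adapter prefix. 3' read-through into the reverse complement of the
    opposite element is removed on both mates. A fragment fully consumed by
    trimming returns None (dropped).

    Reporter trimming happens whenever the reporter is present regardless of
    analysis mode — only the downstream *filter* is mode-dependent — so that
    junction coordinates agree between the two pipeline modes.
    """
    seq1 = pair.seq1
    primer_trimmed = False
    p2 = odn.primer2
    if len(seq1) >= len(p2) and hamming_distance(seq1[: len(p2)], p2) <= odn.primer_max_mismatch:
        seq1 = seq1[len(p2):]
        primer_trimmed = True
    hit = detect_reporter(seq1, odn)
    if hit.found:
        genomic = seq1[hit.end_pos:]
    else:
        genomic = seq1
    # read-through past the sonication break runs into the ligated adapter
    genomic = _trim_readthrough(genomic, revcomp(odn.adapter))

    mate = pair.seq2
    ad = odn.adapter
    if len(mate) >= len(ad) and hamming_distance(mate[: len(ad)], ad) <= odn.primer_max_mismatch:
        mate = mate[len(ad):]
    # read-through past the junction runs into the ODN (reporter then primer)
    mate = _trim_readthrough(mate, revcomp(odn.reporter))

    if not genomic:
        return None
    return TrimmedFragment(
        read_id=pair.read_id,
        sample_id=pair.sample_id or "",
        genomic_seq=genomic,
        mate_seq=mate,
        reporter_found=hit.found,
        reporter_mismatches=hit.mismatches,
        primer_trimmed=primer_trimmed,
    )


def trim_all(
    pairs: Iterable[ReadPair], odn: OdnSpec
) -> tuple[list[TrimmedFragment], int]:
    """Trim a stream of pairs; returns (fragments, n_dropped)."""
    frags, dropped = [], 0
    for pair in pairs:
        frag = trim_fragment(pair, odn)
        if frag is None:
            dropped += 1
        else:
            frags.append(frag)
    return frags, dropped


def filter_by_reporter(
    frags: Iterable[TrimmedFragment],
) -> tuple[list[TrimmedFragment], list[TrimmedFragment], dict[str, int]]:
    """Split fragments into correctly-primed (reporter found) vs rejected.

    The tally feeds the control accounting (no-ODN control samples should
    keep ~nothing).
    """
    kept, rejected = [], []
    for frag in frags:
        (kept if frag.reporter_found else rejected).append(frag)
    tally = {"kept": len(kept), "rejected": len(rejected)}
    return kept, rejected, tally
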