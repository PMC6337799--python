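"""Incorporation events, site clustering, and fragment-signature abundance.

Each uniquely placed fragment is one incorporation event. Events are
clustered into sites by single-linkage chaining along the chromosome, and a
site's abundance is the number of distinct sonication fragment signatures
(strand, junction, break) among its events — the "inferred cells" measure:
PCR duplicates share a signature and collapse, independent cellular
isolation events almost never do.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .align import FragmentAlignment


@dataclass
class IncorporationEvent:
    sample_id: str
    chrom: str
    strand: str
    junction_pos: int
    break_pos: int
    reporter_found: bool

    @property
    def signature(self) -> tuple[str, int, int]:
        return (self.strand, self.junction_pos, self.break_pos)

    @property
    def start(self) -> int:
        return min(self.junction_pos, self.break_pos)

    @property
    def end(self) -> int:
        return max(self.junction_pos, self.break_pos) + 1


@dataclass
class Site:
    site_id: str
    chrom: str
    span: tuple[int, int]  # [min, max) over member junctions
    position: int  # abundance-weighted modal junction
    strands: dict[str, int]
    read_count: int
    abundance: int
    events: list[IncorporationEvent] = field(repr=False, default_factory=list)


def call_events(
    alignments: dict[str, FragmentAlignment] | list[FragmentAlignment],
    fragment_meta: dict[str, tuple[str, bool]] | None = None,
) -> tuple[list[IncorporationEvent], int]:
    """One event per uniquely placed fragment; non-unique placements are
    excluded and counted. ``fragment_meta`` maps read_id to
    (sample_id, reporter_found)."""
    if isinstance(alignments, dict):
        alignments = list(alignments.values())
    events, excluded = [], 0
    for aln in alignments:
        if not aln.unique:
            excluded += 1
            continue
        sample_id, reporter = ("", True)
        if fragment_meta and aln.read_id in fragment_meta:
            sample_id, reporter = fragment_meta[aln.read_id]
        events.append(IncorporationEvent(
            sample_id=sample_id, chrom=aln.chrom, strand=aln.strand,
            junction_pos=aln.junction_pos, break_pos=aln.break_pos,
            reporter_found=reporter))
    return events, excluded


def quantify_abundance(site: Site) -> int:
    """Distinct (strand, junction, break) fragment signatures at the site."""
    return len({e.signature for e in site.events})


def _site_position(events: list[IncorporationEvent]) -> int:
    """Abundance-weighted modal junction, ties broken toward the smaller
    coordinate: each junction is weighted by its distinct fragment
    signatures, not raw reads, so PCR jackpots cannot move the site."""
    weights: Counter[int] = Counter()
    for sig in {e.signature for e in events}:
        weights[sig[1]] += 1
    best = max(weights.items(), key=lambda kv: (kv[1], -kv[0]))
    return best[0]


def cluster_sites(events: list[IncorporationEvent], cluster_gap: int) -> list[Site]:
    """Single-linkage chaining: consecutive junctions within ``cluster_gap``
    bp (either strand) join one site. Deterministic and permutation-invariant
    (events are sorted internally)."""
    ordered = sorted(events, key=lambda e: (e.chrom, e.junction_pos, e.strand, e.break_pos))
    sites: list[Site] = []
    cluster: list[IncorporationEvent] = []

    def flush() -> None:
        if not cluster:
            return
        junctions = [e.junction_pos for e in cluster]
        site = Site(
            site_id="",
            chrom=cluster[0].chrom,
            span=(min(junctions), max(junctions) + 1),
            position=_site_position(cluster),
            strands=dict(Counter(e.strand for e in cluster)),
            read_count=len(cluster),
            abundance=0,
            events=list(cluster),
        )
        site.abundance = quantify_abundance(site)
        sites.append(site)

    for event in ordered:
        if cluster and (event.chrom != cluster[-1].chrom
                        or event.junction_pos - cluster[-1].junction_pos > cluster_gap):
            flush()
            cluster = []
        cluster.append(event)
    flush()
    for i, site in enumerate(sites, 1):
        site.site_id = f"site_{i:04d}"
    return sites


def coverage_profile(site: Site, halfwidth: int) -> np.ndarray:
    """Per-base depth of member fragments over
    [position - halfwidth, position + halfwidth), normalized to max 1.
    Zero vector when the site has no events."""
    if halfwidth <= 0:
        raise ValueError("halfwidth must be > 0")
    lo = site.position - halfwidth
    depth = np.zeros(2 * halfwidth, dtype=float)
    for event in site.events:
        a = max(event.start - lo, 0)
        b = min(event.end - lo, 2 * halfwidth)
        if b > a:
            depth[a:b] += 1
    peak = depth.max()
    if peak > 0:
        depth /= peak
    return depth


def incorporation_distribution(
    site: Site, cut_pos: int
) -> dict[str, Counter[int]]:
    """Histogram of junction offsets relative to the expected cut, per strand.

    Offsets away from zero read as resection / deletion edges at the cleavage
    site: the ODN ends up ligated at the deletion boundary, so the junction
    coordinate reports how far the break was chewed back before repair.
    """
    hist: dict[str, Counter[int]] = {"+": Counter(), "-": Counter()}
    for event in site.events:
        hist[event.strand][event.junction_pos - cut_pos] += 1
    return hist
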