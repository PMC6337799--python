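"""Near-match guide scanning, site annotation, and on-target specificity.

The off-target filter is the published one: a locus counts as guide-related
when at least ``match_min`` of the 20 protospacer bases match (positional
identities, no gaps or bulges) AND the adjacent PAM satisfies its IUPAC
pattern exactly, and a break site is assigned to such a locus when the
locus' cut position lies within ``match_window`` bp of the site position
(defaults 14/20 and 100 bp).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import GuideSpec
from .dna import iupac_lookup, revcomp, seq_to_array
from .sites import Site


@dataclass(frozen=True)
class GuideMatch:
    guide: str
    chrom: str
    strand: str
    protospacer_start: int  # 0-based start of the 20-mer window on the forward strand
    matched_bases: int
    mismatches: int
    pam_seq: str
    cut_pos: int
    aligned_seq: str  # protospacer-oriented genomic sequence

    @property
    def is_on_target(self) -> bool:
        return self.mismatches == 0


def _forward_scan(arr: np.ndarray, proto: str, pam: str, match_min: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized forward-strand scan: window starts and matched-base counts
    for every position whose PAM matches exactly and protospacer matches
    >= match_min bases. N in the genome matches nothing."""
    P, Q = len(proto), len(pam)
    n_windows = len(arr) - P - Q + 1
    if n_windows <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    matches = np.zeros(n_windows, dtype=np.int16)
    for j, base in enumerate(proto):
        matches += arr[j:j + n_windows] == ord(base)
    pam_ok = np.ones(n_windows, dtype=bool)
    for j, code in enumerate(pam):
        pam_ok &= iupac_lookup(code)[arr[P + j:P + j + n_windows]]
    keep = np.flatnonzero(pam_ok & (matches >= match_min))
    return keep, matches[keep].astype(np.int64)


def scan_guide(
    genome: dict[str, str],
    guide: GuideSpec,
    match_min: int = 14,
) -> list[GuideMatch]:
    """Scan both strands of the genome for near matches to the guide.

    ``cut_pos`` is derived from the guide's ``cut_offset`` (default -3: the
    blunt cut falls between protospacer bases 17 and 18, 3 bp 5' of the
    PAM); for '-' strand matches the coordinate is mirrored accordingly.
    Lowering ``match_min`` only ever adds matches (nested output sets).
    """
    proto, pam = guide.protospacer, guide.pam
    P, Q = len(proto), len(pam)
    out: list[GuideMatch] = []
    for chrom, seq in genome.items():
        N = len(seq)
        arr = seq_to_array(seq)
        starts, matched = _forward_scan(arr, proto, pam, match_min)
        for w, m in zip(starts.tolist(), matched.tolist()):
            out.append(GuideMatch(
                guide=guide.name, chrom=chrom, strand="+", protospacer_start=w,
                matched_bases=m, mismatches=P - m, pam_seq=seq[w + P:w + P + Q],
                cut_pos=w + P + guide.cut_offset, aligned_seq=seq[w:w + P]))
        rc = revcomp(seq)
        starts, matched = _forward_scan(seq_to_array(rc), proto, pam, match_min)
        for p, m in zip(starts.tolist(), matched.tolist()):
            w = N - p - P  # forward-strand start of the protospacer window
            out.append(GuideMatch(
                guide=guide.name, chrom=chrom, strand="-", protospacer_start=w,
                matched_bases=m, mismatches=P - m,
                pam_seq=revcomp(seq[w - Q:w]),
                cut_pos=w - 1 - guide.cut_offset,
                aligned_seq=revcomp(seq[w:w + P])))
    out.sort(key=lambda gm: (gm.chrom, gm.protospacer_start, gm.strand))
    return out


@dataclass
class SiteAssignment:
    match: GuideMatch
    distance: int


def assign_sites(
    sites: list[Site],
    matches: list[GuideMatch],
    match_window: int = 100,
) -> dict[str, SiteAssignment]:
    """Assign each site to the nearest guide match whose cut position lies
    within ``match_window`` bp of the site position; unassigned sites are
    absent from the returned mapping. The cut position anchors the distance
    (the biologically meaningful end of the locus)."""
    by_chrom: dict[str, list[GuideMatch]] = {}
    for m in matches:
        by_chrom.setdefault(m.chrom, []).append(m)
    for lst in by_chrom.values():
        lst.sort(key=lambda m: m.cut_pos)
    out: dict[str, SiteAssignment] = {}
    for site in sites:
        candidates = by_chrom.get(site.chrom, [])
        if not candidates:
            continue
        cuts = [m.cut_pos for m in candidates]
        i = np.searchsorted(cuts, site.position)
        best: tuple[int, GuideMatch] | None = None
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(candidates):
                d = abs(site.position - candidates[j].cut_pos)
                if d <= match_window and (best is None or d < best[0]):
                    best = (d, candidates[j])
        if best is not None:
            out[site.site_id] = SiteAssignment(match=best[1], distance=best[0])
    return out


@dataclass
class SpecificityReport:
    guide: str
    pct_on_target_filtered: float  # over guide-matched sites only; NaN if none
    pct_on_target_unfiltered: float  # over all sites
    abundance_on_target: int
    abundance_guide_matched: int
    abundance_total: int
    note: str = ""


def specificity(
    sites: list[Site],
    assignments: dict[str, SiteAssignment],
    guide_name: str,
) -> SpecificityReport:
    """On-target percentage under both denominators.

    ``filtered`` restricts the denominator to sites assigned to the guide
    (the published filter); ``unfiltered`` divides by all site abundance,
    spontaneous breaks included — the two can differ dramatically.
    """
    on_target = 0
    guide_matched = 0
    total = sum(s.abundance for s in sites)
    for site in sites:
        a = assignments.get(site.site_id)
        if a is None or a.match.guide != guide_name:
            continue
        guide_matched += site.abundance
        if a.match.is_on_target:
            on_target += site.abundance
    pct_filtered = 100.0 * on_target / guide_matched if guide_matched else math.nan
    pct_unfiltered = 100.0 * on_target / total if total else math.nan
    note = "" if guide_matched else "no guide-matched abundance"
    return SpecificityReport(
        guide=guide_name,
        pct_on_target_filtered=pct_filtered,
        pct_on_target_unfiltered=pct_unfiltered,
        abundance_on_target=on_target,
        abundance_guide_matched=guide_matched,
        abundance_total=total,
        note=note,
    )


def highlight_mismatches(aligned_seq: str, protospacer: str) -> str:
    """Render a matched 20-mer with mismatched positions in lower case."""
    return "".join(a if a == p else a.lower() for a, p in zip(aligned_seq, protospacer))


def offtarget_table(
    mode_results: dict[str, tuple[list[Site], dict[str, SiteAssignment]]],
    guide: GuideSpec,
    top_n: int = 100,
) -> pd.DataFrame:
    """Per-locus off-target table with abundance columns per pipeline mode.

    ``mode_results`` maps a mode label (e.g. 'guideseq', 'reporter') to that
    mode's (sites, assignments) computed from the same reads. Rows are guide
    match loci, sorted by total abundance descending, capped at ``top_n``.
    """
    loci: dict[tuple[str, int, str], dict] = {}
    for mode, (sites, assignments) in mode_results.items():
        for site in sites:
            a = assignments.get(site.site_id)
            if a is None or a.match.guide != guide.name:
                continue
            key = (a.match.chrom, a.match.protospacer_start, a.match.strand)
            row = loci.setdefault(key, {
                "chrom": a.match.chrom,
                "position": a.match.protospacer_start,
                "strand": a.match.strand,
                "aligned_seq": highlight_mismatches(a.match.aligned_seq, guide.protospacer),
                "pam": a.match.pam_seq,
                "mismatches": a.match.mismatches,
                **{f"abund_{m}": 0 for m in mode_results},
            })
            row[f"abund_{mode}"] += site.abundance
    rows = sorted(
        loci.values(),
        key=lambda r: (-sum(r[f"abund_{m}"] for m in mode_results),
                       r["mismatches"], r["chrom"], r["position"]),
    )[:top_n]
    columns = ["chrom", "position", "strand", "aligned_seq", "pam", "mismatches"] + [
        f"abund_{m}" for m in mode_results]
    return pd.DataFrame(rows, columns=columns)
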