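"""Synthetic truth generation: genome, planted guide loci, breaks, and reads.

The generator emulates the data-generating process end to end so every
pipeline stage is testable without external data:

* an i.i.d. random genome with a "genes" annotation track;
* planted guide target loci (on-target plus off-targets at chosen mismatch
  counts, each with a concrete PAM);
* ODN incorporation events at break sites in both orientations, with small
  resection offsets around the cut;
* sonication producing variable fragment lengths, hence distinct fragment
  signatures, plus PCR duplicates replicating exact fragments;
* nested-PCR read structure (primer2 + reporter + genomic flank on the
  ODN-side read; barcode + adapter + reverse-complemented flank on the
  adapter-side read);
* misprimed reads arising at planted genomic loci whose upstream flank IS
  the primer (and which share almost nothing with the reporter), carrying
  no reporter.

Every read traces to a truth record, so recovered sites, abundances and
filter outcomes can be asserted exactly. Sequencing error is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import GuideSpec, OdnSpec
from .dna import DNA_BASES, IUPAC, hamming_distance, revcomp

#: Default mixture weights for the origin of correctly-primed fragments.
#: Nuclease cleavage concentrates on the perfect-match locus (B2M/TRAC-class
#: guides put ~99% of guide-matched abundance on target), while spontaneous
#: cell-cycle breakage forms a large diffuse background that dominates the
#: unfiltered denominator.
ON_TARGET_WEIGHT = 50.0
OFF_TARGET_WEIGHT = 0.5
SPONTANEOUS_WEIGHT = 1.0


@dataclass(frozen=True)
class PlantedLocus:
    guide: str
    chrom: str
    strand: str
    protospacer_start: int
    cut_pos: int
    mismatches: int
    pam_seq: str


@dataclass(frozen=True)
class BreakSite:
    key: str
    chrom: str
    position: int  # expected junction center (cut position for edits)
    kind: str  # 'edit' or 'spontaneous'
    weight: float


@dataclass(frozen=True)
class MisprimeLocus:
    key: str
    chrom: str
    strand: str
    junction: int


@dataclass
class SimTruth:
    genome: dict[str, str]
    gene_intervals: list[tuple[str, int, int]]
    guide_loci: list[PlantedLocus] = field(default_factory=list)
    break_sites: list[BreakSite] = field(default_factory=list)
    misprime_loci: list[MisprimeLocus] = field(default_factory=list)
    reads: pd.DataFrame | None = None
    seed: int = 0


def simulate_genome(
    length: int,
    gc: float = 0.5,
    seed: int = 0,
    gene_fraction: float = 0.3,
    chrom_name: str = "chr1",
) -> SimTruth:
    """An i.i.d. random genome at the given GC with a non-overlapping
    "genes" interval track covering ~``gene_fraction`` of it."""
    if length < 10_000:
        raise ValueError("genome length must be >= 10 kb")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    seq = "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=probs)])
    genes: list[tuple[str, int, int]] = []
    covered = 0
    cursor = 0
    while covered < gene_fraction * length and cursor < length - 2000:
        gap = int(rng.integers(500, 5000))
        glen = int(rng.integers(2000, 8000))
        start = cursor + gap
        end = min(start + glen, length)
        if end <= start:
            break
        genes.append((chrom_name, start, end))
        covered += end - start
        cursor = end
    return SimTruth(genome={chrom_name: seq}, gene_intervals=genes, seed=seed)


def _mutate_protospacer(protospacer: str, n_mismatches: int, rng) -> str:
    if not 0 <= n_mismatches <= len(protospacer):
        raise ValueError(
            f"mismatch count must be in [0, {len(protospacer)}], got {n_mismatches}")
    seq = list(protospacer)
    for i in rng.choice(len(seq), size=n_mismatches, replace=False):
        seq[i] = rng.choice([b for b in DNA_BASES if b != seq[i]])
    return "".join(seq)


def _concrete_pam(pattern: str, rng) -> str:
    return "".join(rng.choice(sorted(IUPAC[code] - {"N"})) for code in pattern)


def plant_guide_sites(
    truth: SimTruth,
    guide: GuideSpec,
    offtargets: list[int],
    seed: int = 0,
    margin: int = 2000,
    min_separation: int = 2000,
) -> SimTruth:
    """Write the on-target locus (0 mismatches) and one off-target per
    requested mismatch count into the genome, on random strands at
    non-overlapping positions; records exact coordinates and cut positions.
    """
    rng = np.random.default_rng(seed)
    chrom = next(iter(truth.genome))
    seq = bytearray(truth.genome[chrom].encode())
    N = len(seq)
    occupied = [(l.protospacer_start - min_separation, l.protospacer_start + min_separation)
                for l in truth.guide_loci]
    P, Q = len(guide.protospacer), len(guide.pam)
    for n_mm in [0] + list(offtargets):
        proto = _mutate_protospacer(guide.protospacer, n_mm, rng)
        pam = _concrete_pam(guide.pam, rng)
        for _attempt in range(1000):
            w = int(rng.integers(margin, N - margin - P - Q))
            if any(lo <= w <= hi for lo, hi in occupied):
                continue
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            if strand == "+":
                seq[w:w + P] = proto.encode()
                seq[w + P:w + P + Q] = pam.encode()
                cut = w + P + guide.cut_offset
            else:
                seq[w:w + P] = revcomp(proto).encode()
                seq[w - Q:w] = revcomp(pam).encode()
                cut = w - 1 - guide.cut_offset
            occupied.append((w - min_separation, w + min_separation))
            truth.guide_loci.append(PlantedLocus(
                guide=guide.name, chrom=chrom, strand=strand,
                protospacer_start=w, cut_pos=cut, mismatches=n_mm, pam_seq=pam))
            break
        else:
            raise RuntimeError("could not place locus without overlap; genome too small")
    truth.genome[chrom] = seq.decode()
    for locus in truth.guide_loci:
        key = f"{locus.guide}_mm{locus.mismatches}_{locus.protospacer_start}"
        if not any(b.key == key for b in truth.break_sites):
            truth.break_sites.append(BreakSite(
                key=key, chrom=locus.chrom, position=locus.cut_pos, kind="edit",
                weight=ON_TARGET_WEIGHT if locus.mismatches == 0 else OFF_TARGET_WEIGHT))
    return truth


def add_spontaneous_breaks(
    truth: SimTruth,
    n_sites: int,
    seed: int = 0,
    gene_bias: float = 0.0,
    margin: int = 2000,
    min_separation: int = 500,
) -> SimTruth:
    """Spontaneous double-strand-break sites, optionally biased into gene
    intervals with probability ``gene_bias`` (cell-cycle breakage happens
    everywhere; the bias emulates its preference for active chromatin)."""
    rng = np.random.default_rng(seed)
    chrom = next(iter(truth.genome))
    N = len(truth.genome[chrom])
    taken = [b.position for b in truth.break_sites]
    genes = [g for g in truth.gene_intervals if g[0] == chrom]
    lengths = np.array([e - s for _, s, e in genes], dtype=float)
    placed = 0
    while placed < n_sites:
        if genes and rng.random() < gene_bias:
            gi = rng.choice(len(genes), p=lengths / lengths.sum())
            _, s, e = genes[gi]
            pos = int(rng.integers(max(s, margin), min(e, N - margin)))
        else:
            pos = int(rng.integers(margin, N - margin))
        if any(abs(pos - t) < min_separation for t in taken):
            continue
        taken.append(pos)
        truth.break_sites.append(BreakSite(
            key=f"spont_{pos}", chrom=chrom, position=pos, kind="spontaneous",
            weight=SPONTANEOUS_WEIGHT))
        placed += 1
    return truth


def add_misprime_loci(
    truth: SimTruth,
    odn: OdnSpec,
    n_loci: int,
    seed: int = 0,
    margin: int = 2000,
    min_separation: int = 500,
) -> SimTruth:
    """Plant genomic loci where the primer can misprime: the ``primer2``
    sequence is written immediately 5' of the junction on the priming
    strand. Downstream genomic sequence is constrained to share fewer than
    ``len(reporter) - reporter_max_mismatch`` bases with the reporter so
    reporter filtering has zero false keeps by construction."""
    rng = np.random.default_rng(seed)
    chrom = next(iter(truth.genome))
    seq = bytearray(truth.genome[chrom].encode())
    N = len(seq)
    primer = odn.primer2
    L = len(primer)
    rep = odn.reporter
    max_shared = len(rep) - odn.reporter_max_mismatch - 1
    taken = [b.position for b in truth.break_sites] + [m.junction for m in truth.misprime_loci]
    placed = 0
    attempts = 0
    while placed < n_loci:
        attempts += 1
        if attempts > 100_000:
            raise RuntimeError("could not place mispriming loci")
        j = int(rng.integers(margin, N - margin))
        if any(abs(j - t) < min_separation for t in taken):
            continue
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        if strand == "+":
            downstream = seq[j:j + len(rep)].decode()
        else:
            downstream = revcomp(seq[j - len(rep) + 1:j + 1].decode())
        if len(rep) - hamming_distance(downstream, rep) > max_shared:
            continue
        if strand == "+":
            seq[j - L:j] = primer.encode()
        else:
            seq[j + 1:j + 1 + L] = revcomp(primer).encode()
        taken.append(j)
        truth.misprime_loci.append(MisprimeLocus(
            key=f"misprime_{j}", chrom=chrom, strand=strand, junction=j))
        placed += 1
    truth.genome[chrom] = seq.decode()
    return truth


def simulate_reads(
    truth: SimTruth,
    odn: OdnSpec,
    n_reads: int,
    misprime_frac: float = 0.0,
    dup_rate: float = 0.0,
    read_len: int = 100,
    seed: int = 0,
    barcode: str = "ACGTACGT",
    sample_id: str = "sample1",
    resection_max: int = 2,
    error_rate: float = 0.0,
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]]]:
    """Emit paired reads from the planted truth; the truth table of every
    read lands in ``truth.reads``.

    Correctly-primed reads carry ``primer2 + reporter + genomic flank``
    (junction at the event position); misprimed reads carry
    ``primer2 + genomic`` with no reporter. Fragment lengths are uniform on
    [read_len, 3*read_len] (sonication); with probability ``dup_rate`` a
    read replicates an already-emitted fragment of the same origin exactly
    (PCR duplication). Returns (r1_records, r2_records) as (id, seq, qual)
    triples ready for FASTQ writing.
    """
    if misprime_frac and not truth.misprime_loci:
        raise ValueError("misprime_frac > 0 but no mispriming loci planted")
    if not truth.break_sites and misprime_frac < 1:
        raise ValueError("no break sites planted")
    rng = np.random.default_rng(seed)
    chrom = next(iter(truth.genome))
    genome_seq = truth.genome[chrom]
    N = len(genome_seq)
    weights = np.array([b.weight for b in truth.break_sites], dtype=float)
    probs = weights / weights.sum() if len(weights) else None
    site_kind = {b.key: b.kind for b in truth.break_sites}
    fragments: dict[str, list[tuple[str, int, int]]] = {}  # origin -> signatures
    r1_records, r2_records = [], []
    rows = []
    rc_adapter = revcomp(odn.adapter)
    rc_barcode = revcomp(barcode)
    for i in range(n_reads):
        read_id = f"read_{i:07d}"
        misprimed = bool(truth.misprime_loci) and rng.random() < misprime_frac
        if misprimed:
            locus = truth.misprime_loci[rng.integers(0, len(truth.misprime_loci))]
            origin, center, strand = locus.key, locus.junction, locus.strand
            junction = center  # priming fixes the junction exactly
        else:
            site = truth.break_sites[rng.choice(len(truth.break_sites), p=probs)]
            origin, center = site.key, site.position
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            junction = center + int(rng.integers(-resection_max, resection_max + 1))
        pool = fragments.setdefault(origin, [])
        if pool and rng.random() < dup_rate:
            strand, junction, brk = pool[rng.integers(0, len(pool))]
        else:
            length = int(rng.integers(read_len, 3 * read_len + 1))
            if strand == "+":
                brk = min(junction + length - 1, N - 1)
            else:
                brk = max(junction - length + 1, 0)
            pool.append((strand, junction, brk))
        if strand == "+":
            genomic = genome_seq[junction:brk + 1]
        else:
            genomic = revcomp(genome_seq[brk:junction + 1])
        reporter = "" if misprimed else odn.reporter
        r1 = (odn.primer2 + reporter + genomic + rc_adapter + rc_barcode)[:read_len]
        r2 = (barcode + odn.adapter + revcomp(genomic)
              + revcomp(reporter) + revcomp(odn.primer2))[:read_len]
        if error_rate > 0:
            r1 = _add_errors(r1, error_rate, rng)
            r2 = _add_errors(r2, error_rate, rng)
        qual = "I" * read_len
        r1_records.append((read_id, r1, qual[:len(r1)]))
        r2_records.append((read_id, r2, qual[:len(r2)]))
        rows.append({
            "read_id": read_id, "sample_id": sample_id, "origin": origin,
            "kind": "misprime" if misprimed else site_kind[origin],
            "chrom": chrom, "strand": strand, "junction": junction,
            "break_pos": brk, "misprimed": misprimed,
        })
    truth.reads = pd.DataFrame(rows)
    return r1_records, r2_records


def _add_errors(seq: str, rate: float, rng) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in DNA_BASES if b != out[i]])
    return "".join(out)


def planted_fragment_counts(truth: SimTruth, kept_only: bool = True) -> pd.Series:
    """Distinct fragment signatures per origin among emitted reads — the
    ground-truth abundance the pipeline should recover. ``kept_only``
    restricts to correctly-primed reads (those that pass reporter filtering)."""
    if truth.reads is None:
        raise ValueError("simulate_reads has not been run")
    df = truth.reads
    if kept_only:
        df = df[~df["misprimed"]]
    return df.groupby("origin").apply(
        lambda g: len(set(zip(g["strand"], g["junction"], g["break_pos"]))),
        include_groups=False)
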