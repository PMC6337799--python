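"""End-to-end orchestration: reads -> sites -> annotation -> QC -> tables.

The two analysis modes run over the *same* trimmed, aligned fragments:

* ``reporter`` — only fragments whose ODN reporter was detected feed site
  calling (mispriming artifacts removed);
* ``guideseq`` — reporter filtering disabled, emulating the original
  protocol that cannot distinguish mispriming from true incorporation.

``mode='both'`` runs the two side by side so their site lists, specificity
estimates and mispriming diagnostics can be compared read-for-read.
All randomness (mispriming null, enrichment controls/permutations) derives
from the run seed; outputs are deterministic TSVs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .align import FragmentAlignment, align_all, build_index, import_sam
from .config import RunConfig
from .enrichment import (DEFAULT_WINDOW_SIZES, FeatureTrack, enrichment_heatmap)
from .guides import (GuideMatch, SiteAssignment, assign_sites, offtarget_table,
                     scan_guide, specificity)
from .io import read_fasta, read_fastq_pairs, write_sites_bed
from .mispriming import mispriming_test, null_distribution, score_sites
from .reads import AMBIGUOUS, demultiplex, filter_by_reporter, trim_all
from .sites import (Site, call_events, cluster_sites, coverage_profile,
                    incorporation_distribution)

MODES = ("reporter", "guideseq")


@dataclass
class SampleModeResult:
    sites: list[Site]
    assignments: dict[str, SiteAssignment]
    n_events: int


@dataclass
class PipelineResult:
    outdir: Path
    tally: pd.DataFrame
    sites: dict[tuple[str, str], SampleModeResult] = field(default_factory=dict)
    matches: dict[str, list[GuideMatch]] = field(default_factory=dict)
    specificity: pd.DataFrame | None = None
    mispriming: pd.DataFrame | None = None
    enrichment: pd.DataFrame | None = None


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _sites_frame(sites: list[Site], sample_id: str, mode: str) -> pd.DataFrame:
    rows = [{
        "sample_id": sample_id, "mode": mode, "site_id": s.site_id,
        "chrom": s.chrom, "position": s.position,
        "span_start": s.span[0], "span_end": s.span[1],
        "plus_events": s.strands.get("+", 0), "minus_events": s.strands.get("-", 0),
        "read_count": s.read_count, "abundance": s.abundance,
    } for s in sites]
    return pd.DataFrame(rows, columns=[
        "sample_id", "mode", "site_id", "chrom", "position", "span_start",
        "span_end", "plus_events", "minus_events", "read_count", "abundance"])


def run_pipeline(
    config: RunConfig,
    outdir: str | Path,
    r1: str | Path | None = None,
    r2: str | Path | None = None,
    sam: str | Path | None = None,
    genome: dict[str, str] | None = None,
    mode: str = "both",
    track_paths: dict[str, str] | None = None,
    tracks: list[FeatureTrack] | None = None,
    window_sizes: tuple[int, ...] = DEFAULT_WINDOW_SIZES,
    n_null: int = 1000,
    coverage_halfwidth: int = 200,
    enrichment_method: str = "permutation",
) -> PipelineResult:
    """Run every stage and write the report tables under ``outdir``."""
    outdir = Path(outdir)
    if genome is None:
        if not config.genome_path:
            raise ValueError("no genome: set genome_path in the configuration or pass genome=")
        genome = read_fasta(config.genome_path)
    if r1 is None and sam is None:
        raise ValueError("either paired FASTQ (r1/r2) or a SAM file is required")
    modes = list(MODES) if mode == "both" else [mode]
    for m in modes:
        if m not in MODES:
            raise ValueError(f"unknown mode {m!r}")
    outdir.mkdir(parents=True, exist_ok=True)

    index = build_index(genome)
    at_track = FeatureTrack.at_content(genome)
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    all_tracks = [at_track] + (tracks or [])
    for name, path in (track_paths or {}).items():
        all_tracks.append(FeatureTrack.from_bed(name, path, chrom_lengths))

    # --- per-sample read processing + alignment (shared by both modes) ---
    tally_rows = []
    per_sample: dict[str, tuple[dict[str, FragmentAlignment], dict]] = {}
    if sam is not None:
        alignments = {a.read_id: a for a in import_sam(sam) if a.unique}
        meta = {a: ("sample1", True) for a in alignments}
        per_sample["sample1"] = (alignments, meta)
        tally_rows.append({"sample_id": "sample1", "total": len(alignments),
                           "kept": len(alignments), "rejected": 0, "dropped": 0})
    else:
        pairs = read_fastq_pairs(r1, r2)
        bins, counts = demultiplex(pairs, config.samples)
        for sample in config.samples:
            sample_pairs = bins[sample.sample_id]
            frags, dropped = trim_all(sample_pairs, config.odn)
            kept, rejected, ftally = filter_by_reporter(frags)
            alignments, atally = align_all(frags, index)
            meta = {f.read_id: (f.sample_id, f.reporter_found) for f in frags}
            per_sample[sample.sample_id] = (alignments, meta)
            tally_rows.append({
                "sample_id": sample.sample_id, "total": counts[sample.sample_id],
                "kept": ftally["kept"], "rejected": ftally["rejected"],
                "dropped": dropped, "aligned": atally["aligned"],
                "multimapped": atally["multimapped"],
                "unaligned": atally["unaligned"]})
        if counts.get(AMBIGUOUS):
            tally_rows.append({"sample_id": AMBIGUOUS, "total": counts[AMBIGUOUS],
                               "kept": 0, "rejected": 0, "dropped": 0,
                               "aligned": 0, "multimapped": 0, "unaligned": 0})
    tally = pd.DataFrame(tally_rows)
    _write_tsv(tally, outdir / "tally.tsv")

    result = PipelineResult(outdir=outdir, tally=tally)

    # --- guide scanning (genome-wide, mode-independent) ---
    for guide in config.guides:
        result.matches[guide.name] = scan_guide(genome, guide, config.match_min)

    # --- per sample x mode: sites, specificity, mispriming ---
    sites_frames, spec_rows, qc_rows = [], [], []
    for sample_id in sorted(per_sample):
        alignments, meta = per_sample[sample_id]
        events_all, _ = call_events(alignments, meta)
        for m in modes:
            events = events_all if m == "guideseq" else [
                e for e in events_all if e.reporter_found]
            sites = cluster_sites(events, config.cluster_gap)
            assignments: dict[str, SiteAssignment] = {}
            for guide in config.guides:
                sub = assign_sites(sites, result.matches[guide.name], config.match_window)
                for sid, a in sub.items():
                    if sid not in assignments or a.distance < assignments[sid].distance:
                        assignments[sid] = a
            result.sites[(sample_id, m)] = SampleModeResult(sites, assignments, len(events))
            sites_frames.append(_sites_frame(sites, sample_id, m))
            write_sites_bed(sites, outdir / f"sites_{sample_id}_{m}.bed")
            for guide in config.guides:
                rep = specificity(sites, assignments, guide.name)
                spec_rows.append({
                    "sample_id": sample_id, "mode": m, "guide": guide.name,
                    "pct_on_target_filtered": rep.pct_on_target_filtered,
                    "pct_on_target_unfiltered": rep.pct_on_target_unfiltered,
                    "abundance_on_target": rep.abundance_on_target,
                    "abundance_guide_matched": rep.abundance_guide_matched,
                    "abundance_total": rep.abundance_total,
                    "note": rep.note})
            # mispriming diagnostic over sites, run for both nested primers
            for primer_name, primer in (("primer1", config.odn.primer1),
                                        ("primer2", config.odn.primer2)):
                scores, skipped = score_sites(sites, genome, primer)
                row = {"sample_id": sample_id, "mode": m, "primer": primer_name,
                       "n_scored": int(scores.size), "n_skipped": skipped}
                if scores.size:
                    null = null_distribution(genome, primer, n_null,
                                             seed=config.seed + 7919)
                    test = mispriming_test(scores, null)
                    row.update({
                        "mean_score": float(scores.mean()),
                        "null_mean": float(null.mean()),
                        "statistic": test.statistic, "p_value": test.p_value,
                        "direction": test.direction,
                        "frac_above_null_p99": test.frac_above_null_p99})
                qc_rows.append(row)
    if sites_frames:
        _write_tsv(pd.concat(sites_frames, ignore_index=True), outdir / "sites.tsv")
    result.specificity = pd.DataFrame(spec_rows)
    _write_tsv(result.specificity, outdir / "specificity.tsv")
    result.mispriming = pd.DataFrame(qc_rows)
    _write_tsv(result.mispriming, outdir / "mispriming_qc.tsv")

    # --- off-target tables (modes side by side, per guide) ---
    for guide in config.guides:
        for sample_id in sorted(per_sample):
            mode_results = {
                m: (result.sites[(sample_id, m)].sites,
                    result.sites[(sample_id, m)].assignments)
                for m in modes}
            table = offtarget_table(mode_results, guide)
            table.insert(0, "sample_id", sample_id)
            _write_tsv(table, outdir / f"offtargets_{sample_id}_{guide.name}.tsv")

    # --- on-target coverage + incorporation-offset profiles ---
    profile_rows, offset_rows = [], []
    for sample_id in sorted(per_sample):
        for m in modes:
            smr = result.sites[(sample_id, m)]
            for site in smr.sites:
                a = smr.assignments.get(site.site_id)
                if a is None or not a.match.is_on_target:
                    continue
                prof = coverage_profile(site, coverage_halfwidth)
                for i, depth in enumerate(prof):
                    if depth > 0:
                        profile_rows.append({
                            "sample_id": sample_id, "mode": m, "guide": a.match.guide,
                            "offset": i - coverage_halfwidth,
                            "relative_coverage": float(depth)})
                hist = incorporation_distribution(site, a.match.cut_pos)
                for strand, counter in hist.items():
                    for off, n in sorted(counter.items()):
                        offset_rows.append({
                            "sample_id": sample_id, "mode": m, "guide": a.match.guide,
                            "strand": strand, "offset": off, "count": n})
    _write_tsv(pd.DataFrame(profile_rows), outdir / "ontarget_coverage.tsv")
    _write_tsv(pd.DataFrame(offset_rows), outdir / "incorporation_offsets.tsv")

    # --- enrichment (all sites per mode, pooled across samples) ---
    enr_frames = []
    for m in modes:
        positions = []
        for sample_id in sorted(per_sample):
            positions.extend(
                (s.chrom, s.position) for s in result.sites[(sample_id, m)].sites)
        if not positions:
            continue
        df = enrichment_heatmap(
            positions, all_tracks, genome, window_sizes=tuple(
                w for w in window_sizes if w <= 2 * max(chrom_lengths.values())),
            seed=config.seed, method=enrichment_method)
        df.insert(0, "mode", m)
        enr_frames.append(df)
    if enr_frames:
        result.enrichment = pd.concat(enr_frames, ignore_index=True)
        _write_tsv(result.enrichment, outdir / "enrichment.tsv")

    metadata = {
        "version": __version__,
        "parameters": {
            "match_min": config.match_min,
            "protospacer_len": config.protospacer_len,
            "pam_policy": "exact",
            "match_window": config.match_window,
            "cluster_gap": config.cluster_gap,
            "reporter_max_mismatch": config.odn.reporter_max_mismatch,
            "window_sizes": list(window_sizes),
            "enrichment_pct_definition":
                "100*(mean site density - mean control density)/mean control density",
        },
        "seed": config.seed,
        "modes": modes,
        "guides": [g.name for g in config.guides],
        "samples": sorted(per_sample),
    }
    with open(outdir / "metadata.json", "w") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True)
    return result
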