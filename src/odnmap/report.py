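"""Render the pipeline's TSV outputs as one markdown summary document.

Rendering only re-formats numbers already present in the TSVs (positions
become 1-based for human reading); nothing is recomputed here.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def _table(df: pd.DataFrame, max_rows: int = 25) -> str:
    if df.empty:
        return "_(empty)_\n"
    shown = df.head(max_rows)
    out = shown.to_markdown(index=False, floatfmt=".4g")
    if len(df) > max_rows:
        out += f"\n\n_... {len(df) - max_rows} more rows in the TSV._"
    return out + "\n"


def _load(outdir: Path, name: str) -> pd.DataFrame | None:
    path = outdir / name
    if not path.exists():
        return None
    try:
        return pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def render_report(outdir: str | Path, path: str | Path | None = None) -> str:
    """Assemble the summary report from the tables in ``outdir``.

    Sections: read accounting, mispriming QC (flank-score diagnostic),
    on-target coverage profile, off-target tables per guide with abundance
    per mode, and the enrichment heatmap table. Missing inputs mark their
    section as skipped rather than failing.
    """
    outdir = Path(outdir)
    lines: list[str] = ["# Break-site mapping summary report", ""]

    tally = _load(outdir, "tally.tsv")
    lines += ["## Read accounting", ""]
    lines.append(_table(tally) if tally is not None else "_skipped: no tally_\n")

    qc = _load(outdir, "mispriming_qc.tsv")
    lines += ["## Mispriming diagnostic (flank identity to primer)", ""]
    if qc is not None and not qc.empty:
        lines.append(_table(qc))
    else:
        lines.append("_skipped: no QC table_\n")

    sites = _load(outdir, "sites.tsv")
    lines += ["## Sites", ""]
    if sites is not None and not sites.empty:
        view = sites.copy()
        view["position"] = view["position"] + 1  # 1-based for reading
        view = view.sort_values("abundance", ascending=False)
        lines.append(_table(view))
    else:
        lines.append("_no sites_\n")

    cov = _load(outdir, "ontarget_coverage.tsv")
    lines += ["## On-target coverage profile", ""]
    if cov is not None and not cov.empty:
        summary = (cov.groupby(["sample_id", "mode", "guide"])
                   .agg(covered_bases=("offset", "size"),
                        peak=("relative_coverage", "max"))
                   .reset_index())
        lines.append(_table(summary))
        lines.append("_Per-base profile in ontarget_coverage.tsv._\n")
    else:
        lines.append("_no on-target site recovered_\n")

    lines += ["## Off-target tables", ""]
    ot_files = sorted(outdir.glob("offtargets_*.tsv"))
    if ot_files:
        for f in ot_files:
            df = _load(outdir, f.name)
            lines += [f"### {f.stem.removeprefix('offtargets_')}", ""]
            lines.append(_table(df))
    else:
        lines.append("_skipped: no off-target tables_\n")

    spec = _load(outdir, "specificity.tsv")
    lines += ["## Specificity", ""]
    lines.append(_table(spec) if spec is not None else "_skipped_\n")

    enr = _load(outdir, "enrichment.tsv")
    lines += ["## Genomic-feature enrichment (ROC areas)", ""]
    if enr is not None and not enr.empty:
        lines.append("Areas > 0.5 (red): sites favor the annotation; "
                     "< 0.5 (blue): avoidance; 0.5 (white): none.\n")
        lines.append(_table(enr, max_rows=60))
    else:
        lines.append("_skipped: no tracks_\n")

    text = "\n".join(lines)
    target = Path(path) if path else outdir / "report.md"
    target.write_text(text)
    return text
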