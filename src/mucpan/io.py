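"""Readers and writers for the pipeline's on-disk formats.

All interchange is plain text: TSV tables, SEG segmented copy number
(1-based inclusive coordinates), GMT gene sets, per-sample report text
files, and JSON for structured results.  Stages communicate exclusively
through these files, so each stage is independently runnable.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .genomics import SegmentRecord, PATHWAY_NAMES
from .simulate import CohortBundle

__all__ = [
    "read_seg", "write_seg", "read_gmt", "write_gmt",
    "read_matrix", "read_samples", "read_reports_dir", "write_cohort",
]

SEG_COLUMNS = ("sample_id", "chromosome", "start", "end", "num_mark", "seg_mean")


def write_seg(segments: list[SegmentRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SEG_COLUMNS) + "\n")
        for s in segments:
            fh.write(
                f"{s.sample_id}\t{s.chromosome}\t{s.start}\t{s.end}\t{s.num_mark}\t"
                f"{s.log2_ratio:.6g}\n"
            )


def read_seg(path) -> list[SegmentRecord]:
    """Parse a SEG file; malformed lines raise with their line number."""
    segments = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) != 6:
            raise ValueError(f"{path}: expected 6 SEG columns, got {len(header)}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}, line {lineno}: expected 6 fields, got {len(parts)}")
            try:
                seg = SegmentRecord(
                    sample_id=parts[0], chromosome=parts[1],
                    start=int(parts[2]), end=int(parts[3]),
                    log2_ratio=float(parts[5]), num_mark=int(parts[4]),
                )
            except ValueError as e:
                raise ValueError(f"{path}, line {lineno}: {e}") from e
            segments.append(seg)
    return segments


def write_gmt(gene_sets: dict[str, frozenset[str] | set[str]], path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name in gene_sets:
            fh.write("\t".join([name, description, *sorted(gene_sets[name])]) + "\n")


def read_gmt(path, restrict_to_pathways: bool = False) -> dict[str, frozenset[str]]:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ...

    With ``restrict_to_pathways`` the set names must be the ten canonical
    oncogenic pathways.
    """
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}, line {lineno}: GMT rows need name, description, genes")
            name, genes = parts[0], frozenset(g for g in parts[2:] if g)
            if not genes:
                raise ValueError(f"{path}, line {lineno}: gene set {name!r} is empty")
            sets[name] = genes
    if restrict_to_pathways:
        unknown = set(sets) - set(PATHWAY_NAMES)
        if unknown:
            raise ValueError(f"{path}: unknown pathway name(s): {sorted(unknown)}")
    return sets


def read_matrix(path) -> pd.DataFrame:
    """Feature x sample numeric TSV with the feature id in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_samples(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def read_reports_dir(directory) -> dict[str, str]:
    """Load ``<sample_id>.txt`` report files from a directory."""
    directory = Path(directory)
    reports = {}
    for p in sorted(directory.glob("*.txt")):
        reports[p.stem] = p.read_text()
    if not reports:
        raise ValueError(f"no *.txt reports found in {directory}")
    return reports


def write_cohort(bundle: CohortBundle, outdir) -> dict[str, Path]:
    """Write every layer of a cohort to ``outdir``; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def tsv(name: str, df: pd.DataFrame, **kw) -> None:
        p = outdir / name
        df.to_csv(p, sep="\t", **kw)
        paths[name] = p

    tsv("samples.tsv", bundle.samples)
    tsv("counts.tsv", bundle.counts)
    tsv("betas.tsv", bundle.betas.round(6))
    tsv("gene_lengths.tsv", bundle.gene_lengths.to_frame())
    tsv("probe_map.tsv", bundle.probe_map.to_frame())
    tsv("mutations.tsv", bundle.mutations, index=False)
    tsv("alterations.tsv", bundle.alterations, index=False)
    tsv("bases_sequenced.tsv", bundle.bases_sequenced.to_frame())

    seg_path = outdir / "segments.seg"
    write_seg(bundle.segments, seg_path)
    paths["segments.seg"] = seg_path

    reports_dir = outdir / "reports"
    reports_dir.mkdir(exist_ok=True)
    for sid, text in bundle.reports.items():
        (reports_dir / f"{sid}.txt").write_text(text + "\n")
    paths["reports"] = reports_dir

    truth_path = outdir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(bundle.truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["truth.json"] = truth_path
    return paths
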