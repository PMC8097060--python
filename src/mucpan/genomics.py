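"""Genomic landscape statistics: TMB, FGA, CNA calls, recurrent oncogenic
alterations, pathway-level alteration matrices, and the MSI-H step.

Definitions
-----------
TMB
    Non-synonymous mutation count divided by bases sequenced (also reported
    per megabase).
FGA
    Fraction of genome altered: the length-weighted proportion of segmented
    genome whose copy-number log2 ratio is strictly above +0.2 or strictly
    below -0.2.  The denominator defaults to the total segmented length of
    the sample and can be fixed to a genome size instead.
CNA calls
    Per fixed-width genome bin, the length-weighted dominant overlapping
    segment decides gain (log2 > 0.2), loss (log2 < -0.2) or neutral;
    uncovered bins are missing.
Oncogenic alterations
    Gene-level events (mutation, amplification, deletion, fusion,
    epigenetic_silencing) carrying an externally supplied oncogenicity flag;
    a (gene, event type) is "recurrent" in a cohort when oncogenic and
    carried by at least 1% of samples.  A sample alters a pathway when any
    member gene of the curated template carries an oncogenic event.

Tumours flagged MSI-H (microsatellite-instability high) are hypermutated and
are removed before the genomic comparisons, after testing their enrichment
in the mucinous group.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import defaultdict

import numpy as np
import pandas as pd

from .stats import Table2x2, Assoc2x2Result, assoc_test_2x2, bh_fdr

__all__ = [
    "SegmentRecord",
    "EVENT_TYPES",
    "PATHWAY_NAMES",
    "DEFAULT_PATHWAYS",
    "CNA_THRESHOLD",
    "compute_tmb",
    "compute_fga",
    "make_bins",
    "call_cna",
    "cna_frequency",
    "recurrent_oncogenic",
    "pathway_matrix",
    "driver_counts",
    "compare_binary_freq",
    "msi_step",
]

CNA_THRESHOLD = 0.2

EVENT_TYPES = frozenset(
    {"mutation", "amplification", "deletion", "fusion", "epigenetic_silencing"}
)

#: the ten canonical oncogenic signalling pathways
PATHWAY_NAMES = (
    "RTK-RAS", "p53", "Cell cycle", "Wnt", "PI3K",
    "Notch", "TGF-Beta", "Myc", "Hippo", "Nrf2",
)

#: compact curated templates (representative member genes per pathway)
DEFAULT_PATHWAYS: dict[str, frozenset[str]] = {
    "RTK-RAS": frozenset({"KRAS", "NRAS", "BRAF", "EGFR", "ERBB2", "NF1", "MET"}),
    "p53": frozenset({"TP53", "MDM2", "MDM4", "ATM", "CHEK2", "RPS6KA3"}),
    "Cell cycle": frozenset({"CDKN2A", "CDKN1B", "CCND1", "CCNE1", "CDK4", "CDK6", "RB1"}),
    "Wnt": frozenset({"APC", "CTNNB1", "AXIN1", "AXIN2", "TCF7", "TCF7L2", "RNF43"}),
    "PI3K": frozenset({"PIK3CA", "PIK3R1", "PTEN", "AKT1", "MTOR", "TSC1", "TSC2"}),
    "Notch": frozenset({"NOTCH1", "NOTCH2", "NOTCH3", "FBXW7", "SPEN"}),
    "TGF-Beta": frozenset({"SMAD4", "SMAD2", "SMAD3", "TGFBR1", "TGFBR2", "ACVR2A"}),
    "Myc": frozenset({"MYC", "MYCN", "MYCL", "MAX", "MXD1", "MNT"}),
    "Hippo": frozenset({"NF2", "LATS1", "LATS2", "SAV1", "YAP1", "TAOK1"}),
    "Nrf2": frozenset({"NFE2L2", "KEAP1", "CUL3"}),
}


@dataclass(frozen=True)
class SegmentRecord:
    """One row of segmented copy-number data (SEG convention).

    Coordinates are 1-based inclusive base-pair positions; ``log2_ratio`` is
    the segment-mean log2 copy ratio relative to diploid.
    """

    sample_id: str
    chromosome: str
    start: int
    end: int
    log2_ratio: float
    num_mark: int = 0

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid segment coordinates {self.chromosome}:{self.start}-{self.end} "
                f"(need 1 <= start <= end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def altered(self) -> bool:
        return self.log2_ratio > CNA_THRESHOLD or self.log2_ratio < -CNA_THRESHOLD


def _check_non_overlapping(segments: list[SegmentRecord]) -> None:
    by_chrom: dict[str, list[SegmentRecord]] = defaultdict(list)
    for s in segments:
        by_chrom[s.chromosome].append(s)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for prev, cur in zip(segs, segs[1:]):
            if cur.start <= prev.end:
                raise ValueError(
                    f"overlapping segments for sample {prev.sample_id!r} on {chrom}: "
                    f"{prev.start}-{prev.end} overlaps {cur.start}-{cur.end}"
                )


def compute_tmb(n_nonsynonymous: int, bases_sequenced: int) -> tuple[float, float]:
    """Tumor mutational burden as (per-base rate, per-megabase rate)."""
    if n_nonsynonymous < 0:
        raise ValueError("mutation count must be non-negative")
    if bases_sequenced <= 0:
        raise ValueError("bases sequenced must be positive")
    rate = n_nonsynonymous / bases_sequenced
    return rate, rate * 1e6


def compute_fga(
    segments: list[SegmentRecord],
    threshold: float = CNA_THRESHOLD,
    genome_size: int | None = None,
) -> float:
    """Fraction of genome altered for one sample's segments.

    Altered length is the total length of segments with |log2 ratio| strictly
    exceeding ``threshold``; the denominator is the total segmented length,
    or ``genome_size`` when given.
    """
    if not segments:
        raise ValueError("need at least one segment")
    _check_non_overlapping(segments)
    altered = sum(
        s.length for s in segments if s.log2_ratio > threshold or s.log2_ratio < -threshold
    )
    denom = genome_size if genome_size is not None else sum(s.length for s in segments)
    if denom <= 0:
        raise ValueError("denominator must be positive")
    return altered / denom


def fga_by_sample(
    segments: list[SegmentRecord],
    threshold: float = CNA_THRESHOLD,
    genome_size: int | None = None,
) -> pd.Series:
    """FGA for every sample present in a mixed segment list."""
    by_sample: dict[str, list[SegmentRecord]] = defaultdict(list)
    for s in segments:
        by_sample[s.sample_id].append(s)
    return pd.Series(
        {sid: compute_fga(segs, threshold, genome_size) for sid, segs in sorted(by_sample.items())},
        name="fga",
    )


def make_bins(chrom_sizes: dict[str, int], width: int) -> list[tuple[str, int, int]]:
    """Fixed-width bins tiling a genome; 1-based inclusive coordinates."""
    if width <= 0:
        raise ValueError("bin width must be positive")
    bins = []
    for chrom, size in chrom_sizes.items():
        start = 1
        while start <= size:
            bins.append((chrom, start, min(start + width - 1, size)))
            start += width
    return bins


def call_cna(
    segments: list[SegmentRecord],
    bins: list[tuple[str, int, int]],
    threshold: float = CNA_THRESHOLD,
) -> pd.DataFrame:
    """Per-bin gain/loss/neutral calls for every sample.

    For each bin the overlapping segment covering the largest share of the
    bin decides the call from its log2 ratio; bins with no overlapping
    segment are missing (NaN).  Returns a bin x sample DataFrame with values
    in {"gain", "loss", "neutral"}.
    """
    for chrom, start, end in bins:
        if end - start + 1 <= 0:
            raise ValueError(f"bin width must be positive: {chrom}:{start}-{end}")
    by_sample: dict[str, list[SegmentRecord]] = defaultdict(list)
    for s in segments:
        by_sample[s.sample_id].append(s)
    for segs in by_sample.values():
        _check_non_overlapping(segs)

    labels = [f"{c}:{s}-{e}" for c, s, e in bins]
    out = pd.DataFrame(index=labels, columns=sorted(by_sample), dtype=object)
    for sid, segs in by_sample.items():
        by_chrom: dict[str, list[SegmentRecord]] = defaultdict(list)
        for s in segs:
            by_chrom[s.chromosome].append(s)
        for (chrom, bstart, bend), label in zip(bins, labels):
            best_len, best_log2 = 0, None
            for s in by_chrom.get(chrom, ()):
                ov = min(s.end, bend) - max(s.start, bstart) + 1
                if ov > best_len:
                    best_len, best_log2 = ov, s.log2_ratio
            if best_log2 is None:
                continue
            if best_log2 > threshold:
                out.loc[label, sid] = "gain"
            elif best_log2 < -threshold:
                out.loc[label, sid] = "loss"
            else:
                out.loc[label, sid] = "neutral"
    return out


def cna_frequency(calls: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-bin gain and loss frequencies per group.

    Frequency = altered samples / non-missing samples at that bin, computed
    separately for gain and loss within each label group.
    """
    labels = labels.reindex(calls.columns)
    if labels.isna().any():
        raise ValueError("every sample column needs a group label")
    out = {}
    for group in sorted(labels.unique()):
        cols = labels.index[labels == group]
        if len(cols) == 0:
            raise ValueError(f"group {group!r} is empty")
        sub = calls[cols]
        denom = sub.notna().sum(axis=1)
        with np.errstate(invalid="ignore"):
            out[f"gain_{group}"] = (sub == "gain").sum(axis=1) / denom
            out[f"loss_{group}"] = (sub == "loss").sum(axis=1) / denom
    return pd.DataFrame(out, index=calls.index)


def _validate_alterations(alterations: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "gene", "event_type", "oncogenic"}
    missing = required - set(alterations.columns)
    if missing:
        raise ValueError(f"alteration table missing columns: {sorted(missing)}")
    bad = set(alterations["event_type"]) - EVENT_TYPES
    if bad:
        raise ValueError(f"unknown event types: {sorted(bad)}")
    if (alterations["gene"].astype(str) == "").any():
        raise ValueError("gene must be non-empty")
    return alterations


def recurrent_oncogenic(
    alterations: pd.DataFrame, samples: list[str], min_freq: float = 0.01
) -> pd.DataFrame:
    """Recurrent oncogenic (gene, event type) pairs within a sample set.

    Keeps pairs with oncogenic=True carried by at least ``min_freq`` of
    ``samples`` (>=, so exactly 1% of the cohort qualifies at the default).
    Returns a DataFrame with gene, event_type, n_carriers, freq.
    """
    if not 0 < min_freq <= 1:
        raise ValueError(f"min_freq must lie in (0, 1], got {min_freq}")
    if not samples:
        raise ValueError("sample set must be non-empty")
    alterations = _validate_alterations(alterations)
    sub = alterations[
        alterations["oncogenic"] & alterations["sample_id"].isin(samples)
    ]
    n = len(samples)
    grp = (
        sub.groupby(["gene", "event_type"])["sample_id"]
        .nunique()
        .rename("n_carriers")
        .reset_index()
    )
    grp["freq"] = grp["n_carriers"] / n
    keep = grp[grp["freq"] >= min_freq].sort_values(["gene", "event_type"])
    return keep.reset_index(drop=True)


def pathway_matrix(
    alterations: pd.DataFrame,
    samples: list[str],
    templates: dict[str, frozenset[str]] | None = None,
) -> pd.DataFrame:
    """Binary sample x pathway alteration matrix.

    A pathway is altered for a sample iff at least one member gene carries an
    oncogenic event; genes shared by two templates flag both pathways.
    Template names must come from the canonical ten.
    """
    if templates is None:
        templates = DEFAULT_PATHWAYS
    unknown = set(templates) - set(PATHWAY_NAMES)
    if unknown:
        raise ValueError(f"unknown pathway name(s) in template: {sorted(unknown)}")
    for name, genes in templates.items():
        if not genes:
            raise ValueError(f"pathway template {name!r} has an empty gene set")
    alterations = _validate_alterations(alterations)
    onc = alterations[alterations["oncogenic"]]
    mat = pd.DataFrame(0, index=list(samples), columns=list(templates), dtype=np.int8)
    for name, genes in templates.items():
        carriers = onc.loc[onc["gene"].isin(genes), "sample_id"].unique()
        mat.loc[mat.index.intersection(carriers), name] = 1
    return mat


def gene_event_matrix(
    alterations: pd.DataFrame, samples: list[str], recurrent: pd.DataFrame
) -> pd.DataFrame:
    """Binary sample x (gene:event_type) matrix restricted to recurrent pairs."""
    alterations = _validate_alterations(alterations)
    onc = alterations[alterations["oncogenic"]]
    cols = [f"{g}:{e}" for g, e in zip(recurrent["gene"], recurrent["event_type"])]
    mat = pd.DataFrame(0, index=list(samples), columns=cols, dtype=np.int8)
    for (gene, event), col in zip(zip(recurrent["gene"], recurrent["event_type"]), cols):
        carriers = onc.loc[
            (onc["gene"] == gene) & (onc["event_type"] == event), "sample_id"
        ].unique()
        mat.loc[mat.index.intersection(carriers), col] = 1
    return mat


def driver_counts(
    alterations: pd.DataFrame, samples: list[str], include_silencing: bool = True
) -> pd.Series:
    """Number of oncogenic (driver) events per sample.

    Counts all oncogenic events of every type; epigenetic-silencing events
    can be excluded.
    """
    alterations = _validate_alterations(alterations)
    sub = alterations[alterations["oncogenic"]]
    if not include_silencing:
        sub = sub[sub["event_type"] != "epigenetic_silencing"]
    counts = sub.groupby("sample_id").size()
    return counts.reindex(list(samples), fill_value=0).rename("n_driver")


def compare_binary_freq(
    binary: pd.DataFrame, labels: pd.Series, method: str = "auto"
) -> pd.DataFrame:
    """Per-feature 2x2 group-frequency comparison with BH adjustment.

    ``binary`` is a sample x feature 0/1 matrix; ``labels`` assigns each
    sample to one of exactly two groups.  The first group in sorted label
    order is the numerator group of the odds ratio (mucinous sorts before
    control alphabetically reversed — the groups are reported explicitly in
    the output).  Features constant across both groups get p = 1 and a flag.
    """
    labels = labels.reindex(binary.index)
    if labels.isna().any():
        raise ValueError("every sample needs a group label")
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    # mucinous vs control reads naturally with mucinous first
    if set(groups) == {"mucinous", "control"}:
        groups = ["mucinous", "control"]
    g1 = labels.index[labels == groups[0]]
    g2 = labels.index[labels == groups[1]]
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("both groups must be non-empty")

    rows = []
    for feat in binary.columns:
        a = int(binary.loc[g1, feat].sum())
        c = int(binary.loc[g2, feat].sum())
        tab = Table2x2(a, len(g1) - a, c, len(g2) - c)
        if (a == 0 and c == 0) or (a == len(g1) and c == len(g2)):
            res = Assoc2x2Result(float("nan"), 1.0, method, float("nan"), True)
        else:
            res = assoc_test_2x2(tab, method=method)
        rows.append(
            (feat, a, len(g1), c, len(g2), res.odds_ratio, res.p_value, res.method,
             "constant" if res.degenerate else "")
        )
    out = pd.DataFrame(
        rows,
        columns=["feature", f"n_alt_{groups[0]}", f"n_{groups[0]}",
                 f"n_alt_{groups[1]}", f"n_{groups[1]}", "odds_ratio", "p", "method", "flag"],
    ).set_index("feature")
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def msi_step(samples: pd.DataFrame) -> tuple[Table2x2, Assoc2x2Result, list[str]]:
    """Test MSI-H enrichment in the mucinous group, then drop MSI-H samples.

    ``samples`` needs ``histology_group`` (mucinous/control) and
    ``msi_status`` (MSI-H/MSS) columns; returns the 2x2 table, the
    association test result (auto method), and the sample ids retained for
    downstream genomic analyses.
    """
    samples = samples.set_index("sample_id") if "sample_id" in samples.columns else samples
    for col in ("histology_group", "msi_status"):
        if col not in samples.columns or samples[col].isna().any():
            raise ValueError(f"samples table needs a complete {col!r} column")
    muc = samples["histology_group"] == "mucinous"
    msih = samples["msi_status"] == "MSI-H"
    tab = Table2x2(
        int((muc & msih).sum()), int((muc & ~msih).sum()),
        int((~muc & msih).sum()), int((~muc & ~msih).sum()),
    )
    res = assoc_test_2x2(tab, method="auto")
    kept = samples.index[~msih].tolist()
    return tab, res, kept
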