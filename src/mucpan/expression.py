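"""Expression normalization, differential expression, and mucin signatures.

The differential-expression engine here is a deliberately simple, fully
specified two-group test: median-of-ratios size factors, log2(normalized
count + 1), a per-gene Welch t-test and Benjamini-Hochberg adjustment.  The
downstream cross-cancer intersection consumes only the set of genes passing
q < 0.05 and their fold-change signs, which any calibrated two-group test
supplies.

Mucin metagene signatures follow the secreted gel-forming / membrane-bound
split: the per-sample mean RPKM over the signature genes, scaled to a
standard deviation of one and centered around zero across samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_fdr

__all__ = [
    "GEL_MUCIN_GENES",
    "MEMBRANE_MUCIN_GENES",
    "MucinSignatureDef",
    "GEL_MUC",
    "MEMBRANE_MUC",
    "size_factors",
    "rpkm",
    "differential_expression",
    "mucin_signature",
]

GEL_MUCIN_GENES: tuple[str, ...] = ("MUC2", "MUC5B", "MUC5AC", "MUC6", "MUC19")
MEMBRANE_MUCIN_GENES: tuple[str, ...] = (
    "MUC1", "MUC3A", "MUC3B", "MUC4", "MUC12", "MUC13", "MUC14",
    "MUC15", "MUC16", "MUC17", "MUC20", "MUC21", "MUC22",
)

MUCINOUS, CONTROL = "mucinous", "control"


@dataclass(frozen=True)
class MucinSignatureDef:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("signature gene list must be non-empty")


GEL_MUC = MucinSignatureDef("Gel-MUC", GEL_MUCIN_GENES)
MEMBRANE_MUC = MucinSignatureDef("Membrane-MUC", MEMBRANE_MUCIN_GENES)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample size factors, rescaled to geometric mean 1.

    For each gene expressed (count > 0) in every sample, the ratio of each
    sample's count to the gene's geometric mean is formed; a sample's factor
    is the median ratio.  Requires at least one all-sample-expressed gene.
    """
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("counts must be non-negative")
    allpos = (mat > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("no gene has nonzero counts in all samples; cannot normalize")
    sub = mat[allpos]
    log_geo = np.log(sub).mean(axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(sub) - log_geo, axis=0))
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean 1
    return pd.Series(factors, index=counts.columns, name="size_factor")


def rpkm(counts: pd.DataFrame, gene_lengths: pd.Series, library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads.

    ``rpkm = count / (length / 1e3) / (library_size / 1e6)``.  Library sizes
    default to the column sums of ``counts``.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()[:5]
        raise ValueError(f"gene lengths missing for: {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    else:
        library_sizes = library_sizes.reindex(counts.columns)
    if (library_sizes <= 0).any() or library_sizes.isna().any():
        raise ValueError("library sizes must be positive for every sample")
    return counts.div(lengths / 1e3, axis=0).div(library_sizes / 1e6, axis=1)


def differential_expression(counts: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Two-group differential expression (mucinous vs control).

    Counts are normalized by median-of-ratios size factors and transformed to
    log2(normalized + 1); each gene then gets a two-sided Welch t-test.
    log2FC is mean(mucinous) - mean(control) on the log2 scale; q-values are
    Benjamini-Hochberg across tested genes.  Genes with zero counts in every
    sample are excluded from testing and flagged in the ``excluded`` column
    of the returned frame (NaN statistics).

    Returns a DataFrame indexed by gene with columns
    ``log2fc, stat, p, q, excluded``.
    """
    labels = labels.reindex(counts.columns)
    if labels.isna().any():
        raise ValueError("every sample column needs a group label")
    bad = set(labels.unique()) - {MUCINOUS, CONTROL}
    if bad:
        raise ValueError(f"labels must be '{MUCINOUS}' or '{CONTROL}', got {sorted(bad)}")
    muc_cols = labels.index[labels == MUCINOUS]
    ctl_cols = labels.index[labels == CONTROL]
    if len(muc_cols) < 2 or len(ctl_cols) < 2:
        raise ValueError("each group needs at least 2 samples")

    sf = size_factors(counts)
    logn = np.log2(counts.div(sf, axis=1) + 1.0)
    tested = counts.sum(axis=1) > 0

    x = logn.loc[tested, muc_cols].to_numpy()
    y = logn.loc[tested, ctl_cols].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        stat, p = sps.ttest_ind(x, y, axis=1, equal_var=False)
    # zero-variance genes in both groups with equal means: no evidence
    p = np.where(np.isnan(p), 1.0, p)
    stat = np.where(np.isnan(stat), 0.0, stat)
    log2fc = x.mean(axis=1) - y.mean(axis=1)

    out = pd.DataFrame(
        {"log2fc": np.nan, "stat": np.nan, "p": np.nan, "q": np.nan, "excluded": ~tested},
        index=counts.index,
    )
    out.loc[tested, "log2fc"] = log2fc
    out.loc[tested, "stat"] = stat
    out.loc[tested, "p"] = p
    out.loc[tested, "q"] = bh_fdr(p)
    return out


def mucin_signature(rpkm_matrix: pd.DataFrame, sig: MucinSignatureDef) -> pd.Series:
    """Per-sample metagene score: mean RPKM over signature genes, z-scored.

    Signature genes absent from the matrix are dropped with a warning; at
    least one must be present.  The score is centered to mean 0 and scaled to
    SD 1 (ddof=1) across samples; zero variance across samples is an error.
    """
    present = [g for g in sig.genes if g in rpkm_matrix.index]
    missing = [g for g in sig.genes if g not in rpkm_matrix.index]
    if not present:
        raise ValueError(f"no {sig.name} signature gene present in the expression matrix")
    if missing:
        warnings.warn(
            f"{sig.name}: {len(missing)} signature gene(s) absent, using {len(present)}: "
            f"missing {missing}",
            stacklevel=2,
        )
    if rpkm_matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples to scale a signature")
    mean_expr = rpkm_matrix.loc[present].mean(axis=0)
    sd = mean_expr.std(ddof=1)
    if sd == 0:
        raise ValueError(f"{sig.name} signature has zero variance across samples")
    score = (mean_expr - mean_expr.mean()) / sd
    score.name = sig.name
    return score
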