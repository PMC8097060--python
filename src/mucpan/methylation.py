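"""Differential methylation between mucinous and control groups.

Per-probe one-way ANOVA F-tests on beta values (methylation proportions in
[0, 1]), with an optional empirical-Bayes-style variance moderation: the
per-probe residual variance s^2 is shrunk toward the across-probe mean
residual variance s_bar^2 as

    s_shrunk^2 = (d0 * s_bar^2 + df * s^2) / (d0 + df),   d0 = 3

with the residual degrees of freedom left unchanged.  Without shrinkage and
with two groups, F is exactly the square of the pooled-variance t statistic.
Significant probes are selected at Benjamini-Hochberg FDR < 0.05 and mapped
to genes via a single-valued probe -> gene map.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_fdr, spearman

__all__ = ["dmp_finder", "map_probes", "meth_expr_association", "SHRINK_PRIOR_DF"]

SHRINK_PRIOR_DF = 3.0


def dmp_finder(betas: pd.DataFrame, labels: pd.Series, shrink: bool = True) -> pd.DataFrame:
    """One-way ANOVA F-test per probe for differential methylation.

    Parameters
    ----------
    betas
        probe x sample matrix of beta values in [0, 1].
    labels
        sample -> group; any number of groups >= 2, each with >= 2 samples.
    shrink
        Moderate per-probe residual variances toward their across-probe mean
        with prior degrees of freedom ``SHRINK_PRIOR_DF``.

    Returns a DataFrame indexed by probe with one ``mean_<group>`` column per
    group plus ``F, p, q``.
    """
    mat = betas.to_numpy(dtype=float)
    if ((mat < 0) | (mat > 1)).any():
        raise ValueError("beta values must lie in [0, 1]")
    labels = labels.reindex(betas.columns)
    if labels.isna().any():
        raise ValueError("every sample column needs a group label")
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    cols = {g: np.flatnonzero((labels == g).to_numpy()) for g in groups}
    for g, ix in cols.items():
        if len(ix) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")

    n_total = mat.shape[1]
    k = len(groups)
    grand = mat.mean(axis=1)
    ss_between = np.zeros(mat.shape[0])
    ss_within = np.zeros(mat.shape[0])
    means = {}
    for g, ix in cols.items():
        gm = mat[:, ix].mean(axis=1)
        means[g] = gm
        ss_between += len(ix) * (gm - grand) ** 2
        ss_within += ((mat[:, ix] - gm[:, None]) ** 2).sum(axis=1)

    df_between = k - 1
    df_within = n_total - k
    ms_between = ss_between / df_between
    s2 = ss_within / df_within
    if shrink:
        s2_bar = s2.mean()
        s2 = (SHRINK_PRIOR_DF * s2_bar + df_within * s2) / (SHRINK_PRIOR_DF + df_within)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ms_between / s2
    # a probe constant in every sample carries no signal
    F = np.where(np.isnan(F), 0.0, F)
    p = sps.f.sf(F, df_between, df_within)

    out = pd.DataFrame({f"mean_{g}": means[g] for g in groups}, index=betas.index)
    out["F"] = F
    out["p"] = p
    out["q"] = bh_fdr(p)
    return out


def map_probes(dmp: pd.DataFrame, probe_map: pd.Series, q_threshold: float = 0.05):
    """Collapse probe-level results to genes.

    ``probe_map`` maps probe id -> gene symbol and must be single-valued
    (one gene per probe).  Returns ``(gene_table, unmapped_probes)`` where
    the gene table has, per gene, the best (minimum-q) probe, its q, and the
    number of probes significant at ``q < q_threshold``.
    """
    if probe_map.empty:
        raise ValueError("probe map is empty")
    if probe_map.index.duplicated().any():
        dup = probe_map.index[probe_map.index.duplicated()].tolist()[:5]
        raise ValueError(f"probe map must be single-valued; duplicated probes: {dup}")
    mapped_gene = probe_map.reindex(dmp.index)
    unmapped = dmp.index[mapped_gene.isna()].tolist()
    sub = dmp.loc[mapped_gene.notna()].copy()
    sub["gene"] = mapped_gene.dropna()

    rows = []
    for gene, grp in sub.groupby("gene", sort=True):
        best = grp["q"].idxmin()
        rows.append(
            (gene, best, float(grp.loc[best, "q"]), int((grp["q"] < q_threshold).sum()), len(grp))
        )
    table = pd.DataFrame(
        rows, columns=["gene", "best_probe", "best_q", "n_significant", "n_probes"]
    ).set_index("gene")
    return table, unmapped


def meth_expr_association(beta_vector, expr_vector) -> tuple[float, float]:
    """Spearman correlation between a probe's betas and a gene's expression.

    A negative rho with small p supports methylation-driven repression.
    Constant input yields ``(nan, nan)``.
    """
    return spearman(beta_vector, expr_vector)
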