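"""Nearest-neighbour matched-control selection.

Each case (a tumour with mucinous differentiation) is matched to ``ratio``
controls drawn without replacement from a pool of non-mucinous tumours of the
same cancer type.  Categorical covariates listed in ``exact_vars`` must agree
exactly (e.g. sex, stage, or ER/PR/HER2 status in breast cancer); continuous
covariates (age, year of diagnosis) are standardized to z-scores over the
combined case+pool table and matched by Euclidean distance.

Matching is greedy and sequential: cases are processed in input order, each
taking its ``ratio`` nearest compatible unused controls; distance ties break
toward the smaller pool index.  This makes the procedure deterministic, at
the cost of order dependence that the balance diagnostics let you inspect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MatchSpec", "MatchedDesign", "MatchingError", "match_controls", "balance_table"]


class MatchingError(ValueError):
    """Raised when a strict design cannot be filled from the control pool."""


@dataclass(frozen=True)
class MatchSpec:
    exact_vars: tuple[str, ...] = ()
    continuous_vars: tuple[str, ...] = ()
    ratio: int = 3
    strict: bool = True

    def __post_init__(self) -> None:
        if self.ratio < 1:
            raise ValueError(f"ratio must be >= 1, got {self.ratio}")
        object.__setattr__(self, "exact_vars", tuple(self.exact_vars))
        object.__setattr__(self, "continuous_vars", tuple(self.continuous_vars))


@dataclass
class MatchedDesign:
    """case_id -> ordered control ids, with parallel matching distances."""

    pairs: dict[str, list[str]]
    distances: dict[str, list[float]]
    shortfall: dict[str, int] = field(default_factory=dict)  # controls missing per case

    @property
    def control_ids(self) -> list[str]:
        return [c for ctrls in self.pairs.values() for c in ctrls]

    @property
    def case_ids(self) -> list[str]:
        return list(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (case, rank, ctrl, self.distances[case][rank])
            for case, ctrls in self.pairs.items()
            for rank, ctrl in enumerate(ctrls)
        ]
        return pd.DataFrame(rows, columns=["case_id", "rank", "control_id", "distance"])


def _check_columns(df: pd.DataFrame, spec: MatchSpec) -> None:
    missing = [v for v in (*spec.exact_vars, *spec.continuous_vars) if v not in df.columns]
    if missing:
        raise ValueError(f"covariates not in sample table: {missing}")


def match_controls(cases: pd.DataFrame, pool: pd.DataFrame, spec: MatchSpec) -> MatchedDesign:
    """Greedy 1:ratio nearest-neighbour matching without replacement.

    ``cases`` and ``pool`` are sample tables indexed by sample_id (or with a
    ``sample_id`` column) and must be disjoint.  Continuous covariates may
    not be missing.  In strict mode a case that cannot obtain ``ratio``
    exact-compatible controls raises :class:`MatchingError`; otherwise the
    shortfall is recorded on the design.
    """
    cases = cases.set_index("sample_id") if "sample_id" in cases.columns else cases
    pool = pool.set_index("sample_id") if "sample_id" in pool.columns else pool
    overlap = cases.index.intersection(pool.index)
    if len(overlap):
        raise ValueError(f"cases and pool must be disjoint; shared ids: {list(overlap[:5])}")
    _check_columns(cases, spec)
    _check_columns(pool, spec)

    cont = list(spec.continuous_vars)
    if cont:
        combined = pd.concat([cases[cont], pool[cont]]).astype(float)
        if combined.isna().any().any():
            bad = combined.columns[combined.isna().any()].tolist()
            raise ValueError(f"continuous covariates contain missing values: {bad}")
        mu = combined.mean()
        sd = combined.std(ddof=1).replace(0.0, 1.0)  # constant covariate adds 0 distance
        z_cases = ((cases[cont] - mu) / sd).to_numpy(float)
        z_pool = ((pool[cont] - mu) / sd).to_numpy(float)
    else:
        z_cases = np.zeros((len(cases), 0))
        z_pool = np.zeros((len(pool), 0))

    pool_ids = pool.index.to_numpy()
    used = np.zeros(len(pool), dtype=bool)
    pairs: dict[str, list[str]] = {}
    distances: dict[str, list[float]] = {}
    shortfall: dict[str, int] = {}

    for i, case_id in enumerate(cases.index):
        compatible = ~used
        for var in spec.exact_vars:
            compatible &= (pool[var] == cases[var].iloc[i]).to_numpy()
        idx = np.flatnonzero(compatible)
        dist = np.linalg.norm(z_pool[idx] - z_cases[i], axis=1)
        # stable sort on distance keeps smaller pool index first on ties
        order = idx[np.argsort(dist, kind="stable")]
        chosen = order[: spec.ratio]
        if len(chosen) < spec.ratio:
            if spec.strict:
                raise MatchingError(
                    f"case {case_id!r}: pool supplies only {len(chosen)} of "
                    f"{spec.ratio} exact-compatible controls"
                )
            shortfall[str(case_id)] = spec.ratio - len(chosen)
        used[chosen] = True
        pairs[str(case_id)] = [str(s) for s in pool_ids[chosen]]
        dist_sorted = np.sort(dist, kind="stable")
        distances[str(case_id)] = [float(d) for d in dist_sorted[: len(chosen)]]

    return MatchedDesign(pairs, distances, shortfall)


def balance_table(design: MatchedDesign, samples: pd.DataFrame, spec: MatchSpec) -> pd.DataFrame:
    """Covariate balance diagnostics for a matched design.

    Continuous covariates get the standardized mean difference
    SMD = (mean_case - mean_ctrl) / pooled SD with pooled SD =
    sqrt((s_case^2 + s_ctrl^2) / 2).  When the pooled SD is zero the SMD is 0
    if the means agree and flagged undefined (NaN) otherwise.  Categorical
    covariates get one row per level with the case-control proportion
    difference.
    """
    samples = samples.set_index("sample_id") if "sample_id" in samples.columns else samples
    case_df = samples.loc[design.case_ids]
    ctrl_df = samples.loc[design.control_ids]
    rows = []
    for var in spec.continuous_vars:
        xc = case_df[var].astype(float)
        xt = ctrl_df[var].astype(float)
        diff = xc.mean() - xt.mean()
        pooled = np.sqrt((xc.var(ddof=1) + xt.var(ddof=1)) / 2.0)
        if pooled == 0 or np.isnan(pooled):
            smd, flag = (0.0, "") if np.isclose(diff, 0.0) else (float("nan"), "undefined_smd")
        else:
            smd, flag = diff / pooled, ""
        rows.append((var, "", "continuous", float(diff), float(smd), flag))
    for var in spec.exact_vars:
        levels = sorted(set(case_df[var]) | set(ctrl_df[var]), key=str)
        for lv in levels:
            pdiff = (case_df[var] == lv).mean() - (ctrl_df[var] == lv).mean()
            rows.append((var, str(lv), "categorical", float(pdiff), float(pdiff), ""))
    return pd.DataFrame(
        rows, columns=["covariate", "level", "kind", "mean_diff", "smd", "flag"]
    )
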