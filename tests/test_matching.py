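"""Nearest-neighbour matched-control selection and balance diagnostics."""

import numpy as np
import pandas as pd
import pytest

from mucpan.matching import MatchSpec, MatchingError, balance_table, match_controls


def _samples(ids, **cols):
    return pd.DataFrame({"sample_id": ids, **cols}).set_index("sample_id")


class TestMatchControls:
    def test_exact_pool_fully_selected(self):
        cases = _samples(["c1"], sex=["F"], age=[50.0])
        pool = _samples(["p1", "p2", "p3"], sex=["F"] * 3, age=[48.0, 51.0, 55.0])
        spec = MatchSpec(exact_vars=("sex",), continuous_vars=("age",), ratio=3)
        design = match_controls(cases, pool, spec)
        assert set(design.pairs["c1"]) == {"p1", "p2", "p3"}

    def test_nearest_by_age(self):
        cases = _samples(["c1"], age=[50.0])
        pool = _samples(["p49", "p60", "p70", "p51", "p52"], age=[49.0, 60.0, 70.0, 51.0, 52.0])
        spec = MatchSpec(continuous_vars=("age",), ratio=3)
        design = match_controls(cases, pool, spec)
        assert set(design.pairs["c1"]) == {"p49", "p51", "p52"}
        assert design.distances["c1"] == sorted(design.distances["c1"])

    def test_strict_shortfall_raises(self):
        cases = _samples(["c1"], sex=["F"], age=[50.0])
        pool = _samples(["p1", "p2", "p3"], sex=["F", "F", "M"], age=[48.0, 51.0, 50.0])
        spec = MatchSpec(exact_vars=("sex",), continuous_vars=("age",), ratio=3, strict=True)
        with pytest.raises(MatchingError, match="c1"):
            match_controls(cases, pool, spec)

    def test_best_effort_records_shortfall(self):
        cases = _samples(["c1"], sex=["F"], age=[50.0])
        pool = _samples(["p1", "p2", "p3"], sex=["F", "F", "M"], age=[48.0, 51.0, 50.0])
        spec = MatchSpec(exact_vars=("sex",), continuous_vars=("age",), ratio=3, strict=False)
        design = match_controls(cases, pool, spec)
        assert design.pairs["c1"] == ["p2", "p1"]  # age 51 nearer 50 than 48
        assert design.shortfall == {"c1": 1}

    def test_without_replacement_disjoint(self):
        rng = np.random.default_rng(0)
        cases = _samples([f"c{i}" for i in range(10)], age=rng.normal(60, 5, 10))
        pool = _samples([f"p{i}" for i in range(40)], age=rng.normal(60, 5, 40))
        spec = MatchSpec(continuous_vars=("age",), ratio=3)
        design = match_controls(cases, pool, spec)
        ctrls = design.control_ids
        assert len(ctrls) == len(set(ctrls)) == 30

    def test_pool_order_invariant_with_distinct_distances(self):
        cases = _samples(["c1", "c2"], age=[50.0, 70.0])
        pool = _samples(
            [f"p{i}" for i in range(8)], age=[48.0, 52.5, 69.0, 71.5, 40.0, 80.0, 55.0, 66.0]
        )
        spec = MatchSpec(continuous_vars=("age",), ratio=2)
        d1 = match_controls(cases, pool, spec)
        d2 = match_controls(cases, pool.iloc[::-1], spec)
        assert {k: set(v) for k, v in d1.pairs.items()} == {
            k: set(v) for k, v in d2.pairs.items()
        }

    def test_tie_break_smaller_pool_index(self):
        cases = _samples(["c1"], age=[50.0])
        pool = _samples(["pA", "pB", "pC"], age=[49.0, 51.0, 49.0])  # pA/pC tie, pB ties too
        spec = MatchSpec(continuous_vars=("age",), ratio=1)
        design = match_controls(cases, pool, spec)
        assert design.pairs["c1"] == ["pA"]

    def test_overlapping_ids_rejected(self):
        df = _samples(["x"], age=[1.0])
        with pytest.raises(ValueError, match="disjoint"):
            match_controls(df, df, MatchSpec(continuous_vars=("age",), ratio=1))

    def test_missing_continuous_rejected(self):
        cases = _samples(["c1"], age=[np.nan])
        pool = _samples(["p1"], age=[50.0])
        with pytest.raises(ValueError, match="missing"):
            match_controls(cases, pool, MatchSpec(continuous_vars=("age",), ratio=1))

    def test_never_matches_across_strata(self, tiny_cohort):
        samples = tiny_cohort.samples
        for stratum in ("CRC", "BRCA"):
            sub = samples[samples["cancer_type"] == stratum]
            cases = sub[sub["histology_group"] == "mucinous"]
            pool = sub[sub["histology_group"] == "control"]
            design = match_controls(
                cases, pool, MatchSpec(continuous_vars=("age", "year_dx"), ratio=3)
            )
            picked = samples.loc[design.control_ids, "cancer_type"].unique()
            assert list(picked) == [stratum]


class TestBalanceTable:
    def test_identical_distributions_zero_smd(self):
        cases = _samples(["c1", "c2"], age=[50.0, 60.0], sex=["F", "M"])
        pool = _samples(["p1", "p2"], age=[50.0, 60.0], sex=["F", "M"])
        spec = MatchSpec(exact_vars=("sex",), continuous_vars=("age",), ratio=1)
        design = match_controls(cases, pool, spec)
        bal = balance_table(design, pd.concat([cases, pool]), spec)
        assert bal.loc[bal["covariate"] == "age", "smd"].iloc[0] == pytest.approx(0.0)

    def test_smd_formula(self):
        # means 50 vs 60 with pooled SD 10 -> SMD = -1.0
        rng = np.random.default_rng(5)
        case_age = 50 + 10 * rng.standard_normal(2000)
        ctrl_age = 60 + 10 * rng.standard_normal(2000)
        case_age = (case_age - case_age.mean()) / case_age.std(ddof=1) * 10 + 50
        ctrl_age = (ctrl_age - ctrl_age.mean()) / ctrl_age.std(ddof=1) * 10 + 60
        samples = _samples(
            [f"c{i}" for i in range(2000)] + [f"p{i}" for i in range(2000)],
            age=np.concatenate([case_age, ctrl_age]),
        )
        from mucpan.matching import MatchedDesign

        design = MatchedDesign(
            pairs={f"c{i}": [f"p{i}"] for i in range(2000)},
            distances={f"c{i}": [0.0] for i in range(2000)},
        )
        spec = MatchSpec(continuous_vars=("age",), ratio=1)
        bal = balance_table(design, samples, spec)
        assert bal["smd"].iloc[0] == pytest.approx(-1.0, abs=1e-9)

    def test_exact_matched_categorical_zero_difference(self):
        cases = _samples(["c1", "c2"], sex=["F", "F"], age=[50.0, 52.0])
        pool = _samples(["p1", "p2", "p3"], sex=["F", "F", "M"], age=[49.0, 53.0, 50.0])
        spec = MatchSpec(exact_vars=("sex",), continuous_vars=("age",), ratio=1)
        design = match_controls(cases, pool, spec)
        bal = balance_table(design, pd.concat([cases, pool]), spec)
        cat = bal[(bal["covariate"] == "sex") & (bal["level"] == "F")]
        assert cat["mean_diff"].iloc[0] == pytest.approx(0.0)

    def test_zero_pooled_sd_flagged_when_means_differ(self):
        samples = _samples(["c1", "c2", "p1", "p2"], age=[50.0, 50.0, 60.0, 60.0])
        from mucpan.matching import MatchedDesign

        design = MatchedDesign(
            pairs={"c1": ["p1"], "c2": ["p2"]},
            distances={"c1": [0.0], "c2": [0.0]},
        )
        spec = MatchSpec(continuous_vars=("age",), ratio=1)
        bal = balance_table(design, samples, spec)
        assert bal["flag"].iloc[0] == "undefined_smd"
        assert np.isnan(bal["smd"].iloc[0])
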