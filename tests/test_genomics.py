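"""TMB, FGA, CNA calls, recurrent alterations, pathways, MSI step."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mucpan.genomics import (
    DEFAULT_PATHWAYS, SegmentRecord, call_cna, cna_frequency, compare_binary_freq,
    compute_fga, compute_tmb, driver_counts, fga_by_sample, gene_event_matrix,
    make_bins, msi_step, pathway_matrix, recurrent_oncogenic,
)


def _seg(sample, chrom, start, end, log2):
    return SegmentRecord(sample, chrom, start, end, log2)


class TestTmb:
    def test_formula(self):
        rate, per_mb = compute_tmb(100, 10**6)
        assert rate == pytest.approx(1e-4)
        assert per_mb == pytest.approx(100.0)

    def test_zero_mutations(self):
        assert compute_tmb(0, 10**6) == (0.0, 0.0)

    @pytest.mark.parametrize("n,b", [(-1, 100), (5, 0)])
    def test_validation(self, n, b):
        with pytest.raises(ValueError):
            compute_tmb(n, b)


class TestFga:
    def test_all_neutral(self):
        segs = [_seg("s", "chr1", 1, 100, 0.0), _seg("s", "chr2", 1, 50, 0.1)]
        assert compute_fga(segs) == 0.0

    def test_length_weighting(self):
        segs = [_seg("s", "chr1", 1, 40, 0.5), _seg("s", "chr1", 41, 100, 0.0)]
        assert compute_fga(segs) == pytest.approx(0.4)

    def test_threshold_is_strict(self):
        segs = [_seg("s", "chr1", 1, 50, 0.2), _seg("s", "chr1", 51, 100, -0.2)]
        assert compute_fga(segs) == 0.0
        segs2 = [_seg("s", "chr1", 1, 50, 0.2000001)]
        assert compute_fga(segs2) == 1.0

    def test_fixed_genome_denominator(self):
        segs = [_seg("s", "chr1", 1, 40, 0.5)]
        assert compute_fga(segs, genome_size=400) == pytest.approx(0.1)

    def test_overlap_rejected_with_pair_named(self):
        segs = [_seg("s", "chr1", 1, 50, 0.0), _seg("s", "chr1", 50, 80, 0.3)]
        with pytest.raises(ValueError, match="1-50 overlaps 50-80"):
            compute_fga(segs)

    @given(st.integers(2, 99), st.floats(-1.5, 1.5))
    @settings(max_examples=40)
    def test_split_invariance(self, cut, log2):
        whole = [_seg("s", "chr1", 1, 100, log2), _seg("s", "chr2", 1, 60, 0.0)]
        split = [
            _seg("s", "chr1", 1, cut, log2), _seg("s", "chr1", cut + 1, 100, log2),
            _seg("s", "chr2", 1, 60, 0.0),
        ]
        assert compute_fga(whole) == pytest.approx(compute_fga(split))

    def test_order_independent_per_sample(self):
        segs = [
            _seg("a", "chr1", 1, 100, 0.5), _seg("b", "chr1", 1, 100, 0.0),
            _seg("a", "chr2", 1, 100, 0.0),
        ]
        f1 = fga_by_sample(segs)
        f2 = fga_by_sample(segs[::-1])
        pd.testing.assert_series_equal(f1, f2)
        assert f1["a"] == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_fga([])


class TestCnaCalls:
    BINS = [("chr1", 1, 100), ("chr1", 101, 200), ("chr2", 1, 100)]

    def test_threshold_calls(self):
        segs = [
            _seg("s", "chr1", 1, 100, 0.3),
            _seg("s", "chr1", 101, 200, -0.25),
            _seg("s", "chr2", 1, 100, 0.1),
        ]
        calls = call_cna(segs, self.BINS)
        assert calls.loc["chr1:1-100", "s"] == "gain"
        assert calls.loc["chr1:101-200", "s"] == "loss"
        assert calls.loc["chr2:1-100", "s"] == "neutral"

    def test_length_weighted_dominance(self):
        segs = [_seg("s", "chr1", 1, 70, 0.5), _seg("s", "chr1", 71, 200, 0.0)]
        calls = call_cna(segs, self.BINS)
        assert calls.loc["chr1:1-100", "s"] == "gain"  # 70% of bin at 0.5
        assert calls.loc["chr1:101-200", "s"] == "neutral"

    def test_uncovered_bin_missing(self):
        segs = [_seg("s", "chr1", 1, 100, 0.3)]
        calls = call_cna(segs, self.BINS)
        assert pd.isna(calls.loc["chr2:1-100", "s"])

    def test_make_bins_tiles_genome(self):
        bins = make_bins({"chr1": 250}, 100)
        assert bins == [("chr1", 1, 100), ("chr1", 101, 200), ("chr1", 201, 250)]
        with pytest.raises(ValueError):
            make_bins({"chr1": 100}, 0)


class TestCnaFrequency:
    def test_frequency_over_non_missing(self):
        calls = pd.DataFrame(
            {"a": ["gain"], "b": ["gain"], "c": ["neutral"], "d": ["loss"]},
            index=["chr1:1-100"],
        )
        labels = pd.Series(["mucinous"] * 4, index=list("abcd"))
        freq = cna_frequency(calls, labels)
        assert freq.loc["chr1:1-100", "gain_mucinous"] == pytest.approx(0.5)
        assert freq.loc["chr1:1-100", "loss_mucinous"] == pytest.approx(0.25)

    def test_lower_mucinous_burden_recovered(self, tiny_cohort):
        samples = tiny_cohort.samples
        ids = tiny_cohort.stratum_ids("CRC")
        segs = [s for s in tiny_cohort.segments if s.sample_id in set(ids)]
        bins = make_bins({f"chr{i}": 5_000_000 for i in range(1, 23)}, 1_000_000)
        calls = call_cna(segs, bins)
        freq = cna_frequency(calls, samples.loc[ids, "histology_group"])
        muc = (freq["gain_mucinous"] + freq["loss_mucinous"]).mean()
        ctl = (freq["gain_control"] + freq["loss_control"]).mean()
        assert muc < ctl

    def test_frequencies_bounded(self, tiny_cohort):
        ids = tiny_cohort.stratum_ids("BRCA")[:20]
        segs = [s for s in tiny_cohort.segments if s.sample_id in set(ids)]
        bins = make_bins({"chr1": 5_000_000}, 1_000_000)
        freq = cna_frequency(call_cna(segs, bins), tiny_cohort.samples.loc[ids, "histology_group"])
        vals = freq.to_numpy(float)
        assert ((vals >= 0) & (vals <= 1)).all()


def _alts(rows):
    return pd.DataFrame(rows, columns=["sample_id", "gene", "event_type", "oncogenic"])


class TestRecurrentOncogenic:
    def test_one_percent_rule(self):
        samples = [f"s{i}" for i in range(200)]
        alt = _alts([("s0", "RARE", "mutation", True)]
                    + [(f"s{i}", "KRAS", "mutation", True) for i in range(2)])
        rec = recurrent_oncogenic(alt, samples, min_freq=0.01)
        assert list(rec["gene"]) == ["KRAS"]  # 2/200 = exactly 1% kept, 1/200 dropped

    def test_non_oncogenic_ignored(self):
        samples = [f"s{i}" for i in range(10)]
        alt = _alts([(s, "TP53", "mutation", False) for s in samples[:5]])
        assert recurrent_oncogenic(alt, samples).empty

    def test_min_freq_validated(self):
        with pytest.raises(ValueError):
            recurrent_oncogenic(_alts([]), ["s0"], min_freq=0.0)


class TestPathwayMatrix:
    def test_smad4_flags_tgf_beta(self):
        alt = _alts([("s1", "SMAD4", "mutation", True)])
        mat = pathway_matrix(alt, ["s1", "s2"])
        assert mat.loc["s1", "TGF-Beta"] == 1
        assert mat.loc["s2"].sum() == 0  # no events -> all-zero row

    def test_unknown_pathway_rejected(self):
        with pytest.raises(ValueError, match="unknown pathway"):
            pathway_matrix(_alts([]), ["s1"], {"NotAPathway": frozenset({"TP53"})})

    def test_gene_in_two_templates_flags_both(self):
        templates = {
            "p53": frozenset({"TP53"}),
            "Cell cycle": frozenset({"TP53", "RB1"}),
        }
        alt = _alts([("s1", "TP53", "mutation", True)])
        mat = pathway_matrix(alt, ["s1"], templates)
        assert mat.loc["s1", "p53"] == 1 and mat.loc["s1", "Cell cycle"] == 1

    def test_monotone_and_bounded(self):
        alt = _alts([("s1", "TP53", "mutation", True)])
        more = _alts([("s1", "TP53", "mutation", True), ("s1", "KRAS", "amplification", True)])
        m1 = pathway_matrix(alt, ["s1"])
        m2 = pathway_matrix(more, ["s1"])
        assert (m2.loc["s1"] >= m1.loc["s1"]).all()
        assert m2.loc["s1"].sum() <= len(DEFAULT_PATHWAYS)

    def test_driver_counts_and_silencing_switch(self):
        alt = _alts([
            ("s1", "TP53", "mutation", True),
            ("s1", "TCF7", "epigenetic_silencing", True),
            ("s1", "APC", "mutation", False),
        ])
        assert driver_counts(alt, ["s1", "s2"])["s1"] == 2
        assert driver_counts(alt, ["s1"], include_silencing=False)["s1"] == 1
        assert driver_counts(alt, ["s1", "s2"])["s2"] == 0


class TestCompareBinaryFreq:
    @staticmethod
    def _binary_from_counts(n1, k1, n2, k2, feature="PI3K"):
        idx = [f"m{i}" for i in range(n1)] + [f"c{i}" for i in range(n2)]
        vals = [1] * k1 + [0] * (n1 - k1) + [1] * k2 + [0] * (n2 - k2)
        binary = pd.DataFrame({feature: vals}, index=idx)
        labels = pd.Series(["mucinous"] * n1 + ["control"] * n2, index=idx)
        return binary, labels

    def test_brca_pi3k_table_rounds_to_printed_value(self):
        binary, labels = self._binary_from_counts(32, 8, 98, 58)
        row = compare_binary_freq(binary, labels, method="chisq").loc["PI3K"]
        assert round(row["p"], 3) == 0.001
        assert row["odds_ratio"] < 1  # deficit in the mucinous group

    def test_all_zero_feature_p_one(self):
        binary, labels = self._binary_from_counts(10, 0, 10, 0)
        row = compare_binary_freq(binary, labels).loc["PI3K"]
        assert row["p"] == 1.0
        assert row["flag"] == "constant"

    def test_q_dominates_p(self):
        rng = np.random.default_rng(0)
        idx = [f"s{i}" for i in range(60)]
        binary = pd.DataFrame(
            rng.integers(0, 2, (60, 8)), index=idx, columns=[f"f{i}" for i in range(8)]
        )
        labels = pd.Series(["mucinous"] * 30 + ["control"] * 30, index=idx)
        res = compare_binary_freq(binary, labels)
        assert (res["q"] >= res["p"] - 1e-12).all()

    def test_planted_frequencies_recovered_across_seeds(self):
        # TP53 at 25% of 48 mucinous vs 77% of 189 controls
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            idx = [f"m{i}" for i in range(48)] + [f"c{i}" for i in range(189)]
            vals = np.concatenate([rng.random(48) < 0.25, rng.random(189) < 0.772])
            binary = pd.DataFrame({"TP53": vals.astype(int)}, index=idx)
            labels = pd.Series(["mucinous"] * 48 + ["control"] * 189, index=idx)
            row = compare_binary_freq(binary, labels, method="fisher").loc["TP53"]
            hits += (row["odds_ratio"] < 1) and (row["q"] < 0.05)
        assert hits >= 19


class TestMsiStep:
    @staticmethod
    def _samples(n_muc, msih_muc, n_ctl, msih_ctl):
        rows = []
        for i in range(n_muc):
            rows.append((f"m{i}", "mucinous", "MSI-H" if i < msih_muc else "MSS"))
        for i in range(n_ctl):
            rows.append((f"c{i}", "control", "MSI-H" if i < msih_ctl else "MSS"))
        return pd.DataFrame(rows, columns=["sample_id", "histology_group", "msi_status"])

    def test_filter_removes_msih(self):
        tab, res, kept = msi_step(self._samples(5, 1, 5, 1))
        assert len(kept) == 8
        assert tab.a == 1 and tab.c == 1

    def test_crc_printed_table_significant(self):
        tab, res, kept = msi_step(self._samples(73, 26, 215, 27))
        assert res.p_value < 0.001
        assert len(kept) == (73 - 26) + (215 - 27)

    def test_no_msih_identity_filter(self):
        df = self._samples(4, 0, 6, 0)
        _, res, kept = msi_step(df)
        assert len(kept) == 10
        assert res.p_value == 1.0  # degenerate MSI-H column

    def test_missing_column_rejected(self):
        df = self._samples(4, 1, 4, 1).drop(columns="msi_status")
        with pytest.raises(ValueError, match="msi_status"):
            msi_step(df)


class TestGeneEventMatrix:
    def test_restricted_to_recurrent(self):
        samples = [f"s{i}" for i in range(10)]
        alt = _alts(
            [(s, "TP53", "mutation", True) for s in samples[:4]]
            + [("s0", "TP53", "deletion", True)]
        )
        rec = recurrent_oncogenic(alt, samples, min_freq=0.2)
        mat = gene_event_matrix(alt, samples, rec)
        assert list(mat.columns) == ["TP53:mutation"]
        assert mat["TP53:mutation"].sum() == 4
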