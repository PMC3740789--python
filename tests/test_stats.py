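import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import ks_two_sample_oracle
from methylannot import fixtures as fx
from methylannot.stats import (
    BetaMatrix,
    beta_from_m,
    flag_highly_variable,
    m_from_beta,
    m_from_intensities,
    methylation_level,
    methylation_levels,
    prefilter_probes,
    relative_enrichment,
    sd_distribution_compare,
    select_tdm,
    sex_differential,
    within_group_sd,
)


def make_matrix(values, tissues=None, sexes=None):
    values = pd.DataFrame(values)
    n = values.shape[1]
    values.columns = [f"s{i}" for i in range(n)]
    tissues = tissues or ["blood"] * n
    tissue = pd.Series(dict(zip(values.columns, tissues)))
    sex = pd.Series(dict(zip(values.columns, sexes))) if sexes else None
    return BetaMatrix(values=values, tissue=tissue, sex=sex)


class TestTransforms:
    def test_equal_intensities_zero(self):
        assert m_from_intensities(7.0, 7.0) == 0.0

    def test_three_one(self):
        assert m_from_intensities(3.0, 1.0) == pytest.approx(1.0)

    def test_zero_zero_pseudocount(self):
        assert m_from_intensities(0.0, 0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            m_from_intensities(-1.0, 2.0)

    def test_m_zero_is_half(self):
        assert beta_from_m(0.0) == pytest.approx(0.5)

    def test_log2_3(self):
        assert beta_from_m(np.log2(3)) == pytest.approx(0.75)

    def test_round_trip(self):
        assert beta_from_m(m_from_beta(0.3)) == pytest.approx(0.3, abs=1e-12)

    @given(st.floats(min_value=1e-6, max_value=1 - 1e-6))
    def test_round_trip_property(self, b):
        assert beta_from_m(m_from_beta(b)) == pytest.approx(b, abs=1e-9)

    @given(st.floats(min_value=-30, max_value=30), st.floats(min_value=-30, max_value=30))
    def test_monotone(self, m1, m2):
        if m1 + 1e-9 < m2:
            assert beta_from_m(m1) < beta_from_m(m2)

    def test_boundary_beta_clamped(self):
        assert np.isfinite(m_from_beta(0.0))
        assert np.isfinite(m_from_beta(1.0))

    def test_beta_outside_unit_rejected(self):
        with pytest.raises(ValueError):
            m_from_beta(1.5)


class TestWithinGroupSd:
    def test_constant_probe_zero(self):
        m = make_matrix([[0.4, 0.4, 0.4, 0.4]])
        assert within_group_sd(m)["blood"].iloc[0] == 0.0

    def test_closed_form(self):
        m = make_matrix([[0.0, 0.0, 1.0, 1.0]])
        assert within_group_sd(m)["blood"].iloc[0] == pytest.approx(
            np.sqrt(1 / 3), abs=1e-4
        )

    def test_permutation_invariant(self):
        m1 = make_matrix([[0.1, 0.5, 0.9, 0.3]])
        m2 = make_matrix([[0.9, 0.3, 0.1, 0.5]])
        assert within_group_sd(m1)["blood"].iloc[0] == pytest.approx(
            within_group_sd(m2)["blood"].iloc[0]
        )

    def test_singleton_group_nan(self):
        m = make_matrix([[0.1, 0.2, 0.3]], tissues=["blood", "blood", "villi"])
        sds = within_group_sd(m)
        assert np.isnan(sds["villi"].iloc[0])
        assert not np.isnan(sds["blood"].iloc[0])


class TestFlagHighlyVariable:
    def test_boundary_inclusive(self):
        flags = flag_highly_variable(pd.Series([0.25, 0.249, 0.3]))
        assert list(flags) == [True, False, True]


class TestKs:
    def test_class_equals_all_is_zero(self):
        sds = pd.Series(np.linspace(0.1, 0.5, 100),
                        index=[f"cg{i}" for i in range(100)])
        res = sd_distribution_compare(sds, {"all": set(sds.index)})
        assert res["all"][0] == 0.0

    def test_disjoint_supports_is_one(self):
        # the sub-class occupies a range disjoint from the rest
        idx = [f"cg{i}" for i in range(200)]
        values = np.concatenate([np.linspace(0.1, 0.2, 100),
                                 np.linspace(0.4, 0.5, 100)])
        sds = pd.Series(values, index=idx)
        res = sd_distribution_compare(sds, {"low": set(idx[:100])})
        # D of class vs all is bounded by the complement fraction
        assert res["low"][0] == pytest.approx(0.5)

    def test_small_sd_removed(self):
        sds = pd.Series([0.05, 0.09, 0.2, 0.3],
                        index=["cg1", "cg2", "cg3", "cg4"])
        res = sd_distribution_compare(sds, {"c": {"cg1", "cg2"}})
        assert np.isnan(res["c"][0])  # class emptied by the SD < 0.10 screen

    def test_matches_ecdf_oracle(self):
        rng = np.random.default_rng(5)
        from scipy.stats import ks_2samp

        for _ in range(20):
            x = rng.normal(size=rng.integers(5, 200))
            y = rng.normal(loc=rng.uniform(-1, 1), size=rng.integers(5, 200))
            assert ks_2samp(x, y).statistic == pytest.approx(
                ks_two_sample_oracle(x, y), abs=1e-12
            )


class TestMethylationLevel:
    @pytest.mark.parametrize(
        "beta,expected",
        [(0.0, "hypo"), (0.2, "hypo"), (0.2001, "hetero"), (0.5, "hetero"),
         (0.7999, "hetero"), (0.8, "hyper"), (1.0, "hyper")],
    )
    def test_boundaries(self, beta, expected):
        assert methylation_level(beta) == expected

    def test_vectorised_agrees(self):
        values = pd.Series([0.0, 0.2, 0.3, 0.8, 1.0])
        assert list(methylation_levels(values)) == [
            methylation_level(v) for v in values
        ]

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            methylation_level(1.2)


class TestSelectTdm:
    def test_identical_groups_zero(self):
        m = make_matrix(
            [[0.3, 0.4, 0.3, 0.4]], tissues=["blood", "blood", "villi", "villi"]
        )
        res = select_tdm(m, "blood", "villi")
        assert res["z"].iloc[0] == 0.0
        assert not res["significant"].iloc[0]

    def test_zero_variance_equal_means(self):
        m = make_matrix(
            [[0.3, 0.3, 0.3, 0.3]], tissues=["blood", "blood", "villi", "villi"]
        )
        res = select_tdm(m, "blood", "villi")
        assert res["z"].iloc[0] == 0.0

    def test_planted_difference_detected(self):
        spec = fx.tdm_beta_spec(n_probes=200, n_planted=10, n_per_tissue=4,
                                delta=0.3, noise_sd=0.05)
        mat, truth = fx.gen_beta(spec, seed=11)
        res = select_tdm(mat, "blood", "villi")
        planted = truth.index[truth.kind == "tissue_diff"]
        assert res.loc[planted, "significant"].mean() >= 0.9
        # at n=4/tissue the normal-tail z is mildly anti-conservative on
        # nulls; only a small false-positive rate is expected
        null = truth.index[truth.kind == "null"]
        assert res.loc[null, "significant"].mean() <= 0.05

    def test_bonferroni_bound(self):
        spec = fx.tdm_beta_spec(n_probes=500, n_planted=0, n_per_tissue=10,
                                noise_sd=0.1, base_mean=0.5)
        mat, _ = fx.gen_beta(spec, seed=3)
        res = select_tdm(mat, "blood", "villi")
        assert (res.loc[res["significant"], "p"] < 0.05 / 500).all()

    def test_pooled_option_runs(self):
        m = make_matrix(
            [[0.1, 0.2, 0.8, 0.9]], tissues=["blood", "blood", "villi", "villi"]
        )
        res = select_tdm(m, "blood", "villi", pooled=True)
        assert np.isfinite(res["z"].iloc[0])

    def test_needs_two_samples(self):
        m = make_matrix([[0.1, 0.2]], tissues=["blood", "villi"])
        with pytest.raises(ValueError):
            select_tdm(m, "blood", "villi")


class TestRelativeEnrichment:
    def _run(self, labels, flags):
        labels = pd.Series(labels)
        flags = pd.Series(flags, index=labels.index)
        return {r.class_label: r for r in relative_enrichment(flags, labels)}

    def test_equal_fractions_zero(self):
        labels = ["a"] * 50 + ["b"] * 50
        flags = [True, False] * 50  # 50% tdm in both classes
        res = self._run(labels, flags)
        assert res["a"].pct_relative_enrichment == pytest.approx(0.0)
        assert res["b"].pct_relative_enrichment == pytest.approx(0.0)

    def test_doubled_fraction_plus_100(self):
        # class a: 25% of probes overall but 50% of the tdm set
        labels = ["a"] * 25 + ["b"] * 75
        flags = [True] * 10 + [False] * 15 + [True] * 10 + [False] * 65
        res = self._run(labels, flags)
        assert res["a"].pct_relative_enrichment == pytest.approx(100.0)

    def test_halved_fraction_minus_50(self):
        # class a: 50% of probes overall but 25% of the tdm set
        labels = ["a"] * 50 + ["b"] * 50
        flags = [True] * 5 + [False] * 45 + [True] * 15 + [False] * 35
        res = self._run(labels, flags)
        assert res["a"].pct_relative_enrichment == pytest.approx(-50.0)

    def test_duplication_invariance(self):
        rng = np.random.default_rng(8)
        labels = pd.Series(rng.choice(["a", "b", "c"], size=300),
                           index=[f"cg{i}" for i in range(300)])
        flags = pd.Series(rng.random(300) < 0.3, index=labels.index)
        base = {r.class_label: r.pct_relative_enrichment
                for r in relative_enrichment(flags, labels)}
        dup_labels = pd.concat([labels, labels.set_axis(
            [f"{i}_dup" for i in labels.index])])
        dup_flags = pd.concat([flags, flags.set_axis(
            [f"{i}_dup" for i in flags.index])])
        doubled = {r.class_label: r.pct_relative_enrichment
                   for r in relative_enrichment(dup_flags, dup_labels)}
        for cls in base:
            assert doubled[cls] == pytest.approx(base[cls])

    def test_depletion_is_significant_tail(self):
        labels = ["a"] * 500 + ["b"] * 500
        flags = [True] * 5 + [False] * 495 + [True] * 195 + [False] * 305
        res = self._run(labels, flags)
        assert res["a"].pct_relative_enrichment < 0
        assert res["a"].p < 1e-7


class TestSexDifferential:
    def test_null_permutation_empty(self):
        spec = fx.sex_beta_spec(n_probes=500, n_planted=0, n_per_sex=20,
                                noise_sd=0.05)
        mat, _ = fx.gen_beta(spec, seed=4)
        table, meta = sex_differential(mat)
        assert meta["method"] == "standin"
        assert int(table["selected"].sum()) == 0

    def test_planted_effects_recovered(self):
        spec = fx.sex_beta_spec(n_probes=500, n_planted=50, n_per_sex=50,
                                delta=0.2, noise_sd=0.03)
        mat, truth = fx.gen_beta(spec, seed=5)
        table, _ = sex_differential(mat)
        planted = truth.index[truth.kind == "sex_diff"]
        assert int(table.loc[planted, "selected"].sum()) >= 45
        null = truth.index[truth.kind == "null"]
        assert int(table.loc[null, "selected"].sum()) == 0

    def test_min_delta_zero_reduces_to_fdr(self):
        spec = fx.sex_beta_spec(n_probes=200, n_planted=10, n_per_sex=20)
        mat, _ = fx.gen_beta(spec, seed=6)
        table, _ = sex_differential(mat, min_delta=0.0)
        assert (table["selected"] == table["fdr_pass"]).all()

    def test_single_sex_rejected(self):
        m = make_matrix([[0.1, 0.2, 0.3, 0.4]], sexes=["M"] * 4)
        with pytest.raises(ValueError):
            sex_differential(m)


class TestPrefilter:
    def _matrix(self):
        values = pd.DataFrame(
            np.full((6, 3), 0.5),
            index=["cg1", "cg2", "ch3", "rs4", "cg5", "cg6"],
            columns=["s0", "s1", "s2"],
        )
        values.loc["cg6", "s1"] = np.nan
        tissue = pd.Series({"s0": "blood", "s1": "blood", "s2": "blood"})
        return BetaMatrix(values=values, tissue=tissue)

    def test_all_rules(self):
        detection = pd.DataFrame(
            0.001, index=self._matrix().values.index, columns=["s0", "s1", "s2"]
        )
        detection.loc["cg5", "s2"] = 0.02
        filtered, log = prefilter_probes(
            self._matrix(),
            detection_p=detection,
            probe_chrom={"cg1": "chrX", "cg2": "chr2", "ch3": "chr1",
                         "rs4": "chr1", "cg5": "chr1", "cg6": "chr1"},
            non_specific={"cg2": True},
        )
        assert log.removed_detection_p == 1  # cg5
        assert log.removed_missing_beta == 1  # cg6
        assert log.removed_rs_ch == 2  # ch3, rs4
        assert log.removed_sex_chrom == 1  # cg1
        assert log.removed_non_specific == 1  # cg2
        assert list(filtered.values.index) == []

    def test_skipped_rules_logged(self):
        filtered, log = prefilter_probes(self._matrix())
        assert set(log.skipped_rules) == {"detection_p", "sex_chrom",
                                          "non_specific"}
        assert log.removed_rs_ch == 2
        assert list(filtered.values.index) == ["cg1", "cg2", "cg5"]

    def test_beta_range_validated(self):
        with pytest.raises(ValueError):
            make_matrix([[0.1, 1.4]])
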