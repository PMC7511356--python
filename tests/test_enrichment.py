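"""Size factors, dispersion estimation, the NB Wald test, BH adjustment and
binder calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ripcpe import (
    GeneratorConfig,
    RIPEnrichment,
    SampleDesign,
    TruthLabels,
    adjust_fdr,
    call_binders,
    estimate_dispersion,
    generate_count_matrix,
    size_factors,
)
from ripcpe import test_enrichment as nb_wald_test

from conftest import bh_stepup


def make_design(n_ip=3, n_control=3):
    groups = {f"IP{i+1}": "IP" for i in range(n_ip)}
    groups.update({f"CTRL{i+1}": "control" for i in range(n_control)})
    return SampleDesign(groups)


def null_counts(n=400, n_ip=3, n_control=3, dispersion=0.1, depth=2e5, seed=0):
    cfg = GeneratorConfig(
        n_transcripts=n, ip_fold_change=1.0, dispersion=dispersion,
        n_ip=n_ip, n_control=n_control, depth=depth, seed=seed,
    )
    truth = TruthLabels({f"T{i:06d}": False for i in range(n)})
    return generate_count_matrix(truth, cfg)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        df = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5], "c": [10, 20, 5]})
        assert np.allclose(size_factors(df), 1.0)

    def test_doubled_column_hand_oracle(self):
        # five transcripts; third sample doubled exactly
        base = np.array([10, 20, 40, 80, 160])
        df = pd.DataFrame({"s1": base, "s2": base, "s3": 2 * base})
        f = size_factors(df)
        assert f["s3"] / f["s1"] == pytest.approx(2.0)
        # hand median-of-ratios: ratios to geomean are (2^-1/3, 2^-1/3, 2^2/3)
        assert f["s1"] == pytest.approx(2 ** (-1 / 3))
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_single_sample_gets_unit_factor(self):
        df = pd.DataFrame({"only": [3, 0, 9]})
        assert size_factors(df).tolist() == [1.0]

    def test_all_zero_matrix_is_an_error(self):
        with pytest.raises(ValueError):
            size_factors(pd.DataFrame({"a": [0, 0], "b": [0, 0]}))

    def test_fallback_when_no_transcript_everywhere_nonzero(self):
        df = pd.DataFrame({"a": [4, 0], "b": [0, 8]})
        f = size_factors(df)  # column totals 4 and 8, rescaled
        assert f["b"] / f["a"] == pytest.approx(2.0)


class TestDispersion:
    def test_poisson_data_floors_the_median(self):
        counts, design = null_counts(n=2000, dispersion=0.0, seed=11)
        f = size_factors(counts)
        d = estimate_dispersion(counts, design, f, moderate=False)
        assert np.median(d) == pytest.approx(1e-8)

    def test_constant_counts_hit_the_floor(self):
        df = pd.DataFrame({s: [50, 7] for s in ["IP1", "IP2", "CTRL1", "CTRL2"]})
        d = estimate_dispersion(df, make_design(2, 2), size_factors(df), moderate=False)
        assert (d == 1e-8).all()

    def test_nb_dispersion_recovered_within_band(self):
        cfg = GeneratorConfig(n_transcripts=5000, ip_fold_change=1.0, dispersion=0.2, seed=12)
        truth = TruthLabels({f"T{i:06d}": False for i in range(5000)})
        counts, design = generate_count_matrix(truth, cfg)
        f = size_factors(counts)
        d = estimate_dispersion(counts, design, f, moderate=False)
        assert 0.1 <= float(np.median(d)) <= 0.3

    def test_moderation_only_raises_estimates(self):
        counts, design = null_counts(seed=13)
        f = size_factors(counts)
        raw = estimate_dispersion(counts, design, f, moderate=False)
        mod = estimate_dispersion(counts, design, f, moderate=True)
        assert (mod >= raw - 1e-15).all()
        assert (mod >= np.median(raw)).all()


class TestWaldTest:
    def test_null_pvalues_approximately_uniform(self):
        # large counts, known dispersion: p should be close to U(0,1)
        counts, design = null_counts(n=2000, dispersion=0.05, depth=2e7, seed=14)
        f = size_factors(counts)
        disp = pd.Series(0.05, index=counts.index)
        tab = nb_wald_test(counts, design, f, disp)
        p = tab["pvalue"].dropna().to_numpy()
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_eightfold_enrichment_detected(self):
        rng = np.random.default_rng(15)
        n = 50
        mu = rng.uniform(500, 2000, n)
        size = 1 / 0.05
        cols = {}
        for s in ["IP1", "IP2", "IP3"]:
            cols[s] = rng.negative_binomial(size, size / (size + 8 * mu))
        for s in ["CTRL1", "CTRL2", "CTRL3"]:
            cols[s] = rng.negative_binomial(size, size / (size + mu))
        counts = pd.DataFrame(cols)
        design = make_design()
        f = size_factors(counts)
        # size factors absorb part of a global 8x shift; supply unit factors
        f[:] = 1.0
        disp = pd.Series(0.05, index=counts.index)
        tab = nb_wald_test(counts, design, f, disp)
        assert abs(float(tab["log2fc"].median()) - 3.0) < 0.2
        assert (np.abs(tab["log2fc"] - 3.0) < 0.5).mean() >= 0.9
        assert (tab["pvalue"] < 1e-3).all()

    def test_all_zero_transcript_is_untestable(self):
        counts, design = null_counts(n=50, seed=16)
        counts.iloc[0] = 0
        f = size_factors(counts)
        disp = estimate_dispersion(counts, design, f)
        tab = nb_wald_test(counts, design, f, disp)
        assert np.isnan(tab["pvalue"].iloc[0])
        assert tab["log2fc"].iloc[0] == 0.0
        called = call_binders(tab)
        assert np.isnan(called["qvalue"].iloc[0])
        assert not called["is_binder"].iloc[0]
        # the NA transcript is excluded from the BH batch
        expected = bh_stepup(tab["pvalue"].iloc[1:].to_numpy())
        assert np.allclose(called["qvalue"].iloc[1:].to_numpy(), expected)

    def test_scaling_one_sample_leaves_log2fc_invariant(self):
        counts, design = null_counts(n=300, depth=2e6, seed=17)
        f0 = size_factors(counts)
        disp = pd.Series(0.1, index=counts.index)
        t0 = nb_wald_test(counts, design, f0, disp)
        scaled = counts.copy()
        scaled["IP1"] = scaled["IP1"] * 4
        f1 = size_factors(scaled)
        # factors are rescaled to geometric mean 1, so the scaling shows up
        # in the factor relative to the unscaled samples
        rel0 = f0["IP1"] / f0["CTRL1"]
        rel1 = f1["IP1"] / f1["CTRL1"]
        assert rel1 / rel0 == pytest.approx(4.0, rel=1e-6)
        t1 = nb_wald_test(scaled, design, f1, disp)
        assert np.abs(t1["log2fc"] - t0["log2fc"]).max() < 0.01

    def test_permuting_transcripts_permutes_outputs(self):
        counts, design = null_counts(n=120, seed=18)
        res_a = RIPEnrichment(counts, design).fit()
        perm = counts.sample(frac=1.0, random_state=1)
        res_b = RIPEnrichment(perm, design).fit()
        pd.testing.assert_frame_equal(
            res_a.table.loc[perm.index], res_b.table, check_exact=True
        )


class TestFDR:
    def test_worked_stepup_case(self):
        q = adjust_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_pvalue_unchanged(self):
        assert adjust_fdr([0.03])[0] == pytest.approx(0.03)

    def test_all_ones_stay_ones(self):
        assert np.allclose(adjust_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_matches_hand_stepup_on_random_vectors(self):
        rng = np.random.default_rng(19)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(adjust_fdr(p), bh_stepup(p), atol=1e-12)

    def test_na_passthrough_and_range_check(self):
        q = adjust_fdr([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and not np.isnan(q[0])
        with pytest.raises(ValueError):
            adjust_fdr([-0.1, 0.5])


class TestBinderCalling:
    def make_records(self, log2fc, qvalue):
        df = pd.DataFrame({"log2fc": [log2fc], "pvalue": [qvalue]})
        out = call_binders(df)
        return bool(out["is_binder"].iloc[0])

    def test_enriched_and_significant_is_binder(self):
        assert self.make_records(0.5, 0.005)

    def test_wrong_direction_is_not_binder(self):
        assert not self.make_records(-0.2, 0.001)

    def test_not_significant_is_not_binder(self):
        assert not self.make_records(2.0, 0.5)

    def test_empty_records_give_empty_output(self):
        out = call_binders(pd.DataFrame({"log2fc": [], "pvalue": []}))
        assert len(out) == 0

    def test_thresholds_are_configurable(self):
        df = pd.DataFrame({"log2fc": [1.5], "pvalue": [0.03]})
        assert not call_binders(df)["is_binder"].iloc[0]
        assert call_binders(df, fdr_max=0.05)["is_binder"].iloc[0]
        assert not call_binders(df, lfc_min=2.0, fdr_max=0.05)["is_binder"].iloc[0]


class TestModelAPI:
    def test_from_dataframes_and_summary(self):
        counts, design = null_counts(n=100, seed=20)
        model = RIPEnrichment.from_dataframes(counts, design.to_frame())
        res = model.fit()
        assert res.table.shape[0] == 100
        assert "binders called" in res.summary()
        assert set(res.to_frame().columns) >= {
            "transcript_id", "base_mean", "log2fc", "se_log2fc",
            "pvalue", "qvalue", "is_binder",
        }

    def test_invalid_designs_rejected(self):
        counts, _ = null_counts(n=10, seed=21)
        with pytest.raises(ValueError):
            SampleDesign({"IP1": "IP"})  # no control group
        with pytest.raises(ValueError):
            SampleDesign({"IP1": "IP", "CTRL1": "igg"})  # unknown label
        with pytest.raises(ValueError):
            RIPEnrichment(counts, SampleDesign({"IP1": "IP", "CTRL1": "control"}))
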