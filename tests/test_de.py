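import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ploidysig import (
    DegenerateDataError,
    DesignError,
    EBayesParams,
    ExpressionMatrix,
    build_tiered_lists,
    change_filter,
    fit_ebayes,
    moderated_t_test,
    quantile_normalize,
)
from ploidysig.de import ordinary_t_test
from ploidysig.io import OrthologTable, SampleSheet
from ploidysig.pipeline import ploidy_contrasts


def _matrix(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


class TestQuantileNormalize:
    def test_hand_example_mean_order_statistics(self):
        m = quantile_normalize(_matrix([[1, 4], [2, 5], [3, 6]]))
        np.testing.assert_allclose(m.values, [[2.5, 2.5], [3.5, 3.5],
                                              [4.5, 4.5]])

    def test_identical_columns_fixed_point(self):
        vals = np.tile(np.array([[5.0], [1.0], [3.0]]), (1, 3))
        m = quantile_normalize(_matrix(vals))
        np.testing.assert_allclose(m.values, vals)

    def test_ties_get_mean_of_reference_at_tied_ranks(self):
        # column 0 has a 3-way tie at the bottom ranks
        m = quantile_normalize(_matrix([[1, 10], [1, 20], [1, 30], [9, 40]]))
        ref = np.sort(m.values, axis=0).mean(axis=1)
        col0 = m.values[:, 0]
        np.testing.assert_allclose(col0[:3], col0[0])

    def test_single_sample_rejected(self):
        with pytest.raises(DesignError):
            quantile_normalize(_matrix([[1.0], [2.0]]))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_columns_share_sorted_values_afterward(self, seed):
        rng = np.random.default_rng(seed)
        m = quantile_normalize(_matrix(rng.normal(0, 1, (30, 4))))
        ref = np.sort(m.values[:, 0])
        for j in range(1, 4):
            np.testing.assert_allclose(np.sort(m.values[:, j]), ref,
                                       atol=1e-12)


class TestEBayes:
    def test_identical_variances_give_infinite_prior_df(self):
        params = fit_ebayes(np.full(50, 0.3), 4)
        assert math.isinf(params.d0)
        assert params.s0_sq == pytest.approx(0.3, rel=1e-9)

    def test_parameter_recovery_from_scaled_f_prior(self):
        rng = np.random.default_rng(11)
        d0, s0_sq, df = 4.0, 0.25, 4
        s2 = s0_sq * rng.f(df, d0, 20_000)
        params = fit_ebayes(s2, df)
        assert 3.0 <= params.d0 <= 5.0
        assert params.s0_sq == pytest.approx(s0_sq, rel=0.10)

    def test_too_few_genes_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_ebayes([0.1, 0.2], 4)

    def test_all_zero_variances_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_ebayes(np.zeros(100), 4)


def _two_group(delta, s, n=3, genes=20, seed=0):
    rng = np.random.default_rng(seed)
    x1 = rng.normal(8 + delta, s, (genes, n))
    x2 = rng.normal(8, s, (genes, n))
    samples = [f"P{i}" for i in range(n)] + [f"D{i}" for i in range(n)]
    m = _matrix(np.hstack([x1, x2]), samples=samples)
    sheet = SampleSheet(pd.DataFrame({
        "sample_id": samples,
        "species": "MM", "tissue": "liver",
        "ploidy_class": ["polyploid"] * n + ["diploid"] * n,
        "replicate": list(range(1, n + 1)) * 2,
    }))
    return m, sheet, (("MM", "liver", "polyploid"), ("MM", "liver", "diploid"))


class TestModeratedT:
    def test_hand_worked_statistic(self):
        # n1=n2=3, delta=1, s_g^2=0.25, d0=4, s0^2=0.25:
        # posterior variance 0.25, t = 1/(0.5*sqrt(2/3)), df_total = 8
        x1 = np.array([[1.0, 1.5, 0.5]]) + 8.0   # mean 9, ss = 0.5
        x2 = np.array([[0.0, 0.5, -0.5]]) + 8.0  # mean 8, ss = 0.5
        m = _matrix(np.hstack([x1, x2]), genes=["G0"],
                    samples=["P1", "P2", "P3", "D1", "D2", "D3"])
        sheet = SampleSheet(pd.DataFrame({
            "sample_id": m.sample_ids, "species": "MM", "tissue": "liver",
            "ploidy_class": ["polyploid"] * 3 + ["diploid"] * 3,
            "replicate": [1, 2, 3, 1, 2, 3],
        }))
        params = EBayesParams(d0=4.0, s0_sq=0.25)
        res = moderated_t_test(m, sheet, (("MM", "liver", "polyploid"),
                                          ("MM", "liver", "diploid")), params)
        assert res.loc["G0", "delta"] == pytest.approx(1.0)
        assert res.loc["G0", "s2_post"] == pytest.approx(0.25)
        assert res.loc["G0", "t_mod"] == pytest.approx(1 / (0.5 * np.sqrt(2 / 3)))
        assert res.loc["G0", "df_total"] == 8

    def test_zero_delta_gives_p_one(self):
        x = np.full((1, 6), 8.0)
        m = _matrix(x, samples=["P1", "P2", "P3", "D1", "D2", "D3"])
        sheet = SampleSheet(pd.DataFrame({
            "sample_id": m.sample_ids, "species": "MM", "tissue": "liver",
            "ploidy_class": ["polyploid"] * 3 + ["diploid"] * 3,
            "replicate": [1, 2, 3, 1, 2, 3],
        }))
        res = moderated_t_test(m, sheet, (("MM", "liver", "polyploid"),
                                          ("MM", "liver", "diploid")),
                               EBayesParams(d0=4, s0_sq=0.25))
        assert res["t_mod"].iloc[0] == 0.0
        assert res["p"].iloc[0] == 1.0

    def test_d0_to_zero_limit_matches_ordinary_t(self):
        m, sheet, contrast = _two_group(1.0, 0.5, genes=30, seed=2)
        params = EBayesParams(d0=1e-9, s0_sq=1.0)
        mod = moderated_t_test(m, sheet, contrast, params)
        ref = ordinary_t_test(m, sheet, contrast)
        np.testing.assert_allclose(mod["t_mod"], ref["t"], rtol=1e-6)

    def test_huge_d0_matches_z_statistic_with_prior_sd(self):
        m, sheet, contrast = _two_group(1.0, 0.5, genes=30, seed=3)
        s0_sq = 0.25
        mod = moderated_t_test(m, sheet, contrast,
                               EBayesParams(d0=1e8, s0_sq=s0_sq))
        delta = mod["delta"].to_numpy()
        z = delta / np.sqrt(s0_sq * (2 / 3))
        np.testing.assert_allclose(mod["t_mod"], z, rtol=1e-6)

    def test_sign_consistency_invariant(self):
        m, sheet, contrast = _two_group(0.5, 0.5, genes=50, seed=4)
        res = moderated_t_test(m, sheet, contrast)
        nz = res["delta"] != 0
        assert (np.sign(res.loc[nz, "t_mod"]) == np.sign(res.loc[nz, "delta"])).all()

    def test_missing_condition_raises_design_error(self):
        m, sheet, _ = _two_group(0.5, 0.5)
        with pytest.raises(DesignError):
            moderated_t_test(m, sheet, (("HS", "heart"), ("MM", "heart")))


class TestChangeFilter:
    @pytest.mark.parametrize("ratio,passed,direction", [
        (1.10, False, "none"),
        (1.20, True, "up"),
        (1.15, True, "up"),               # boundary inclusive
        (1 / 1.15, True, "down"),
        (1 / 1.10, False, "none"),
    ])
    def test_threshold_rules(self, ratio, passed, direction):
        df = pd.DataFrame({"ratio": [ratio]}, index=["G"])
        out = change_filter(df)
        assert bool(out["passed"].iloc[0]) is passed
        assert out["direction"].iloc[0] == direction

    def test_boundary_from_log2_delta(self):
        delta = np.log2(1.15)
        df = pd.DataFrame({"ratio": [2 ** delta]}, index=["G"])
        out = change_filter(df)
        assert out["direction"].iloc[0] == "up"


def _de_frame(entries):
    """entries: gene -> (ratio, p)"""
    return pd.DataFrame(
        {"ratio": [v[0] for v in entries.values()],
         "p": [v[1] for v in entries.values()],
         "delta": [np.log2(v[0]) for v in entries.values()]},
        index=list(entries),
    )


class TestTieredLists:
    def test_all_gates_pass_lands_in_all_tiers(self):
        orth = OrthologTable(pd.DataFrame({
            "group_id": ["G1"], "gene_a": ["HS_G1"], "gene_b": ["MM_G1"]}))
        heart = _de_frame({"G1": (1.20, 0.001)})
        liver = _de_frame({"G1": (1.18, 0.005)})
        decidua = _de_frame({"MM_G1": (1.25, 0.002)})
        tiers = build_tiered_lists(heart, liver, decidua, orth)
        assert tiers.tier_A_up == {"G1"}
        assert tiers.tier_B_up == {"G1"}
        assert tiers.tier_C_up == {"MM_G1"}

    def test_discordant_direction_excluded(self):
        heart = _de_frame({"G1": (1.30, 0.001)})
        liver = _de_frame({"G1": (0.70, 0.001)})
        tiers = build_tiered_lists(heart, liver, None, None)
        assert "G1" not in tiers.tier_B_up
        assert "G1" not in tiers.tier_B_down

    def test_significance_gate_can_be_disabled(self):
        heart = _de_frame({"G1": (1.30, 0.5)})
        liver = _de_frame({"G1": (1.30, 0.5)})
        gated = build_tiered_lists(heart, liver, None, None)
        ungated = build_tiered_lists(heart, liver, None, None, require_p=False)
        assert "G1" not in gated.tier_B_up
        assert "G1" in ungated.tier_B_up

    def test_decidua_without_orthologs_stays_in_tier_c(self):
        orth = OrthologTable(pd.DataFrame({
            "group_id": ["G1"], "gene_a": ["HS_G1"], "gene_b": ["MM_G1"]}))
        heart = _de_frame({"G1": (1.2, 0.001)})
        liver = _de_frame({"G1": (1.2, 0.001)})
        decidua = _de_frame({"MM_G1": (1.2, 0.001), "MM_NOV": (1.3, 0.001)})
        tiers = build_tiered_lists(heart, liver, decidua, orth)
        assert "MM_NOV" in tiers.tier_C_up

    def test_tier_subset_invariant_on_random_datasets(self):
        rng = np.random.default_rng(6)
        genes = [f"G{i}" for i in range(80)]
        orth = OrthologTable(pd.DataFrame({
            "group_id": genes, "gene_a": [f"HS_{g}" for g in genes],
            "gene_b": [f"MM_{g}" for g in genes]}))
        for _ in range(30):
            def rand_de(index):
                return pd.DataFrame({
                    "ratio": np.exp2(rng.normal(0, 0.5, len(index))),
                    "p": rng.uniform(0, 1, len(index)) ** 2,
                }, index=index)
            tiers = build_tiered_lists(
                rand_de(genes), rand_de(genes),
                rand_de([f"MM_{g}" for g in genes]), orth)
            assert tiers.tier_A_up <= tiers.tier_B_up
            assert tiers.tier_A_down <= tiers.tier_B_down


class TestRecovery:
    def test_planted_genes_recovered_with_low_fdp(self, cross_dataset):
        matrix, sheet, orth, truth = cross_dataset
        norm = quantile_normalize(matrix)
        contrasts = ploidy_contrasts(sheet)
        from ploidysig import PloidyContrast
        h = PloidyContrast(norm, sheet, *contrasts["heart"]).fit().table
        l = PloidyContrast(norm, sheet, *contrasts["liver"]).fit().table
        tiers = build_tiered_lists(h, l, None, orth)
        planted = truth.ploidy_up | truth.ploidy_down
        found = tiers.tier_B_up | tiers.tier_B_down
        assert len(found & planted) / len(planted) >= 0.7
        assert len(found - planted) / max(len(found), 1) <= 0.2
        # directions agree with the planted signs
        assert tiers.tier_B_up <= truth.ploidy_up | (found - planted)
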