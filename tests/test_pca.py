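import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ploidysig import (
    DesignError,
    ExpressionMatrix,
    PloidyPCA,
    SampleSheet,
    condition_profiles,
    fit_pca,
    quantile_normalize,
    variance_fraction_from_loadings,
)

# printed loading patterns of the four-condition heart-liver fit and the
# two-condition decidua fit, used as fixed reference data
HEART_LIVER_LOADINGS = np.array([
    [0.691, 0.529, -0.390, -0.301],
    [0.690, -0.539, -0.366, 0.313],
    [0.650, 0.583, 0.394, 0.286],
    [0.670, -0.556, 0.398, -0.290],
])
DECIDUA_LOADINGS = np.array([[0.981, 0.193], [0.981, -0.193]])


def _random_profiles(seed, genes=200, nvars=4):
    rng = np.random.default_rng(seed)
    base = rng.normal(8, 2, genes)
    cols = {f"V{j}": base + rng.normal(0, 1, genes) for j in range(nvars)}
    return pd.DataFrame(cols, index=[f"G{i}" for i in range(genes)])


class TestConditionProfiles:
    def test_replicate_mean(self, tiny_matrix):
        matrix, sheet = tiny_matrix
        prof = condition_profiles(matrix, sheet)
        assert prof.shape == (40, 4)
        samples = sheet.samples_for(("HS", "heart"))
        np.testing.assert_allclose(
            prof["HS_heart"], matrix.data[samples].mean(axis=1))


class TestFitPCA:
    def test_two_variable_closed_form(self):
        prof = _random_profiles(1, nvars=2)
        r = np.corrcoef(prof.to_numpy().T)[0, 1]
        res = fit_pca(prof)
        np.testing.assert_allclose(
            res.var_fraction.to_numpy(), [(1 + r) / 2, (1 - r) / 2],
            atol=1e-12)
        np.testing.assert_allclose(
            np.abs(res.loadings["PC1"]), np.sqrt((1 + r) / 2), atol=1e-12)
        np.testing.assert_allclose(
            np.abs(res.loadings["PC2"]), np.sqrt((1 - r) / 2), atol=1e-12)

    def test_printed_decidua_loadings_are_self_consistent(self):
        # per-variable squared loadings sum to ~1 (correlation-scale PCA)
        sums = (DECIDUA_LOADINGS ** 2).sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=5e-3)

    def test_mean_squared_printed_loadings_reproduce_variance_shares(self):
        shares = variance_fraction_from_loadings(HEART_LIVER_LOADINGS)
        np.testing.assert_allclose(shares[:3] * 100, [45.6, 30.5, 15.0],
                                   atol=0.2)
        shares_d = variance_fraction_from_loadings(DECIDUA_LOADINGS)
        np.testing.assert_allclose(shares_d * 100, [96.3, 3.7], atol=0.2)

    def test_constant_variable_rejected_by_name(self):
        prof = _random_profiles(2)
        prof["V1"] = 5.0
        with pytest.raises(DesignError, match="V1"):
            fit_pca(prof)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_rotation_identities_on_random_inputs(self, seed):
        prof = _random_profiles(seed)
        res = fit_pca(prof)
        # variance fractions sum to 1; per-variable loadings sum to 1
        assert res.var_fraction.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(
            (res.loadings.to_numpy() ** 2).sum(axis=1), 1.0, atol=1e-9)
        # mean squared loading per component equals its variance fraction
        np.testing.assert_allclose(
            variance_fraction_from_loadings(res.loadings),
            res.var_fraction.to_numpy(), atol=1e-9)
        # scores standardized
        s = res.scores.to_numpy()
        np.testing.assert_allclose(s.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(s.std(axis=0), 1, atol=1e-9)
        # full-rank reconstruction of the standardized profiles
        X = prof.to_numpy()
        Z = (X - X.mean(axis=0)) / X.std(axis=0)
        np.testing.assert_allclose(res.reconstruct(), Z, atol=1e-8)


class TestLabeling:
    def test_synthetic_hierarchy_labels_in_component_order(self, cross_dataset):
        matrix, sheet, _, _ = cross_dataset
        res = PloidyPCA(quantile_normalize(matrix), sheet).fit()
        labels = [res.labels[c] for c in res.components]
        assert labels == ["shared", "tissue", "species", "ploidy"]
        # hierarchy of explained variance is strictly decreasing
        vf = res.var_fraction.to_numpy()
        assert np.all(np.diff(vf) < 0)

    def test_two_condition_pattern_labels_shared_then_ploidy(
            self, two_condition_dataset):
        matrix, sheet, _ = two_condition_dataset
        res = PloidyPCA(quantile_normalize(matrix), sheet).fit()
        assert [res.labels[c] for c in res.components] == ["shared", "ploidy"]

    def test_ploidy_orientation_polyploid_negative(self, cross_dataset):
        matrix, sheet, _, truth = cross_dataset
        res = PloidyPCA(quantile_normalize(matrix), sheet).fit()
        comp = res.component_for("ploidy")
        for cond in sheet.conditions():
            meta = sheet.condition_meta(cond)
            label = f"{meta['species']}_{meta['tissue']}"
            sign = np.sign(res.loadings.loc[label, comp])
            assert sign == (-1 if meta["ploidy_class"] == "polyploid" else +1)
        # hence planted up-genes sit at low (negative) scores
        up_scores = res.scores.loc[sorted(truth.ploidy_up), comp]
        assert up_scores.mean() < -1

    def test_unmatched_pattern_is_unassigned(self, tiny_matrix):
        # force a sign pattern matching no factor coding (up to global flip)
        from ploidysig.pca import label_components
        matrix, sheet = tiny_matrix
        prof = condition_profiles(matrix, sheet)
        res = fit_pca(prof)
        # variables: HS_heart, HS_liver, MM_heart, MM_liver
        # codings: tissue (+,-,+,-), species (+,+,-,-), ploidy (+,-,-,+)
        res.loadings["PC2"] = np.array([0.5, -0.5, 0.5, 0.5])
        labeled = label_components(res, sheet)
        assert labeled.labels["PC2"] == "unassigned"

    def test_confounded_design_rejected(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(30)]
        data, rows = {}, []
        # species and ploidy move together: HS polyploid, MM diploid
        for species, ploidy in [("HS", "polyploid"), ("MM", "diploid")]:
            for tissue in ("heart", "liver"):
                sid = f"{species}_{tissue}"
                data[sid] = rng.normal(8, 1, 30)
                rows.append((sid, species, tissue, ploidy, 1))
        matrix = ExpressionMatrix(pd.DataFrame(data, index=genes))
        sheet = SampleSheet(pd.DataFrame(
            rows, columns=["sample_id", "species", "tissue", "ploidy_class",
                           "replicate"]))
        with pytest.raises(DesignError, match="confounded"):
            PloidyPCA(matrix, sheet).fit()


class TestSelectionAndDiagnostics:
    def test_selection_empty_when_scores_within_band(self, two_condition_dataset):
        matrix, sheet, _ = two_condition_dataset
        res = PloidyPCA(quantile_normalize(matrix), sheet).fit()
        induced, suppressed = res.select_by_score("ploidy", sd_threshold=50)
        assert induced == frozenset() and suppressed == frozenset()

    def test_threshold_nesting(self, two_condition_dataset):
        matrix, sheet, _ = two_condition_dataset
        res = PloidyPCA(quantile_normalize(matrix), sheet).fit()
        i2, s2 = res.select_by_score("ploidy", 2)
        i3, s3 = res.select_by_score("ploidy", 3)
        assert i3 <= i2 and s3 <= s2

    def test_selection_recovers_planted_direction(self, two_condition_dataset):
        matrix, sheet, truth = two_condition_dataset
        res = PloidyPCA(quantile_normalize(matrix), sheet).fit()
        induced, suppressed = res.select_by_score("ploidy", 2)
        assert len(induced & truth.ploidy_up) / max(len(induced), 1) >= 0.7
        assert len(suppressed & truth.ploidy_down) / max(len(suppressed), 1) >= 0.7

    def test_no_ploidy_component_raises(self):
        prof = _random_profiles(3, nvars=2)
        res = fit_pca(prof)  # unlabeled
        with pytest.raises(DesignError):
            res.select_by_score("ploidy", 2)

    def test_kurtosis_hand_moments(self):
        # raw scores {0,0,0,0,10}: m4/m2^2 = 832/256 = 3.25 after centering
        s = np.array([0, 0, 0, 0, 10.0])
        s = (s - s.mean())
        res = fit_pca(_random_profiles(4, genes=5, nvars=2))
        res.scores["PC1"] = s / s.std()
        k, _ = res.score_diagnostics("PC1")
        assert k == pytest.approx(3.25)

    def test_kurtosis_two_point_symmetric_is_one(self):
        res = fit_pca(_random_profiles(5, genes=6, nvars=2))
        res.scores["PC1"] = np.array([1.0, -1, 1, -1, 1, -1])
        k, _ = res.score_diagnostics("PC1")
        assert k == pytest.approx(1.0)

    def test_kurtosis_of_gaussian_scores_near_three(self):
        rng = np.random.default_rng(8)
        genes = 10**6
        res = fit_pca(pd.DataFrame(
            {"A": rng.normal(0, 1, 10), "B": rng.normal(0, 1, 10)}))
        res.scores = pd.DataFrame({"PC1": rng.normal(0, 1, genes)})
        k, p99 = res.score_diagnostics("PC1")
        assert k == pytest.approx(3.0, abs=0.05)
        assert p99 == pytest.approx(2.576, abs=0.02)

    def test_sparse_planted_effect_inflates_kurtosis(self, cross_dataset):
        matrix, sheet, _, _ = cross_dataset
        res = PloidyPCA(quantile_normalize(matrix), sheet).fit()
        k, _ = res.score_diagnostics(res.component_for("ploidy"))
        assert k > 6  # heavy-tailed: far above the Gaussian value of 3

    def test_no_planted_effect_kurtosis_near_three(self):
        from ploidysig import SynthConfig, generate_cross_species_dataset
        cfg = SynthConfig(n_genes=3000, frac_ploidy_up=0, frac_ploidy_down=0,
                          seed=21)
        matrix, sheet, _, _ = generate_cross_species_dataset(cfg)
        res = PloidyPCA(quantile_normalize(matrix), sheet).fit()
        # with nothing planted the smallest component is pure noise
        last = res.components[-1]
        k, _ = res.score_diagnostics(last)
        assert k == pytest.approx(3.0, abs=0.35)
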