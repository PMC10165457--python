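"""The raw-intensity -> volcano statistical pipeline: floor, log2,
normality gate, completeness filter, downshift imputation, median
normalization, Welch test, marker selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.pipeline import Pipeline

from phosphodia import (
    DownshiftImputer,
    FilterParams,
    GroupCompletenessFilter,
    ImputationParams,
    IntensityFloor,
    Log2Transformer,
    MedianNormalizer,
    NormalityGate,
    SiteTable,
    heatmap_marker_selection,
    impute_downshift,
    log2_transform,
    median_normalize,
    qc_floor,
    welch_volcano,
)


def make_table(values, samples=None, groups=None, scale="raw"):
    frame = pd.DataFrame(
        np.asarray(values, dtype=float),
        index=pd.MultiIndex.from_tuples(
            [(f"P{i}", "S", i + 1) for i in range(len(values))],
            names=["protein_accession", "residue", "position"],
        ),
        columns=samples or [f"s{j}" for j in range(np.shape(values)[1])],
    )
    g = None
    if groups is not None:
        g = pd.Series(groups, index=frame.columns, name="group")
    return SiteTable(abundance=frame, groups=g, scale=scale)


def welch_oracle(a, b):
    """Textbook closed-form Welch t, Satterthwaite df and two-sided p."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return t, df, p


class TestIntensityFloor:
    def test_strict_boundary(self):
        table = make_table([[29.9, 30.0, 31.0]])
        out = qc_floor(table, 30.0)
        row = out.abundance.iloc[0]
        assert np.isnan(row["s0"])
        assert row["s1"] == 30.0
        assert row["s2"] == 31.0

    def test_all_above_floor_unchanged(self):
        table = make_table([[100.0, 200.0], [40.0, 50.0]])
        out = qc_floor(table)
        pd.testing.assert_frame_equal(out.abundance, table.abundance)

    def test_log_scale_rejected(self):
        table = make_table([[10.0, 11.0]], scale="log2")
        with pytest.raises(ValueError, match="raw"):
            qc_floor(table)


class TestLog2Transform:
    def test_values_and_missing_preserved(self):
        table = make_table([[1024.0, 30.0, np.nan]])
        out = log2_transform(table)
        assert out.scale == "log2"
        row = out.abundance.iloc[0]
        assert row["s0"] == 10.0
        assert row["s1"] == pytest.approx(4.906890595608519)
        assert np.isnan(row["s2"])

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="nonpositive"):
            log2_transform(make_table([[-1.0, 2.0]]))


class TestNormalityGate:
    def test_type_one_error_near_alpha(self):
        """Normal samples at alpha 0.01 (absolute mode): roughly 1%
        excluded."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(400, 200))
        gate = NormalityGate(alpha=0.01, mode="absolute").fit(X)
        excluded = 1.0 - gate.retained_.mean()
        assert 0.0 <= excluded < 0.03

    def test_bimodal_sample_excluded(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 300))
        X[7] = np.concatenate(
            [rng.normal(-3, 0.3, 150), rng.normal(3, 0.3, 150)]
        )
        for mode in ("absolute", "cohort"):
            gate = NormalityGate(alpha=0.01, mode=mode).fit(X)
            assert not gate.retained_[7]
            if mode == "cohort":
                assert gate.retained_.sum() == 19

    def test_alpha_zero_disables_exclusion(self):
        rng = np.random.default_rng(2)
        X = rng.exponential(size=(5, 100))  # grossly non-normal
        gate = NormalityGate(alpha=0.0).fit(X)
        assert gate.retained_.all()

    def test_too_few_observations_untestable(self):
        X = np.full((3, 10), np.nan)
        X[:, :5] = 1.0
        gate = NormalityGate().fit(X)
        assert gate.untestable_.all()
        assert gate.retained_.all()


class TestGroupCompletenessFilter:
    def test_strict_threshold(self):
        n = 14
        y = ["A"] * n + ["B"] * n
        # 10/14 = 71.4% in A -> kept; 9/14 = 64% both -> dropped
        X = np.full((2 * n, 2), np.nan)
        X[:10, 0] = 1.0
        X[:9, 1] = 1.0
        X[n : n + 9, 1] = 1.0
        filt = GroupCompletenessFilter(0.70).fit(X, y)
        assert list(filt.support_) == [True, False]

    def test_exactly_at_fraction_dropped(self):
        y = ["A"] * 10 + ["B"] * 10
        X = np.full((20, 1), np.nan)
        X[:7, 0] = 1.0  # exactly 70% in A
        X[10:17, 0] = 1.0  # exactly 70% in B
        filt = GroupCompletenessFilter(0.70).fit(X, y)
        assert not filt.support_[0]

    def test_fully_observed_kept(self):
        y = ["A"] * 4 + ["B"] * 4
        X = np.ones((8, 3))
        filt = GroupCompletenessFilter(0.70).fit(X, y)
        assert filt.support_.all()


class TestDownshiftImputer:
    def test_no_missing_is_identity(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 50))
        out = DownshiftImputer(random_state=1).fit_transform(X)
        np.testing.assert_array_equal(out.to_numpy(), X)

    def test_moments_of_imputed_values(self):
        """20k-cell standard-normal sample with 20% MCAR missingness:
        imputed mean ~ -1.8 observed SDs, imputed SD ~ 0.3 observed SDs."""
        rng = np.random.default_rng(3)
        full = rng.standard_normal(20000)
        missing = rng.random(20000) < 0.2
        X = full.copy()
        X[missing] = np.nan
        out = DownshiftImputer(random_state=9).fit_transform(X[None, :]).to_numpy()[0]
        obs = full[~missing]
        imputed = out[missing]
        shift = (obs.mean() - imputed.mean()) / obs.std(ddof=1)
        ratio = imputed.std(ddof=1) / obs.std(ddof=1)
        assert shift == pytest.approx(1.8, abs=0.02)
        assert ratio == pytest.approx(0.3, abs=0.02)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(4, 100))
        X[rng.random(X.shape) < 0.3] = np.nan
        a = DownshiftImputer(random_state=7).fit_transform(X)
        b = DownshiftImputer(random_state=7).fit_transform(X)
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_observed_rejected(self):
        X = np.array([[1.0, np.nan, np.nan]])
        with pytest.raises(ValueError, match="fewer than 2"):
            DownshiftImputer(random_state=0).fit_transform(X)

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            ImputationParams(width_sd=0.0)


class TestMedianNormalizer:
    def test_equalizes_medians_to_grand_median(self):
        table = make_table(
            [[9.0, 11.0], [10.0, 12.0], [11.0, 13.0]], scale="log2"
        )
        out = median_normalize(table)
        medians = out.abundance.median(axis=0)
        # sample medians 10 and 12 -> both at the grand median 11
        assert medians["s0"] == pytest.approx(11.0)
        assert medians["s1"] == pytest.approx(11.0)

    def test_identity_when_medians_equal(self):
        table = make_table([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]], scale="log2")
        out = median_normalize(table)
        pd.testing.assert_frame_equal(out.abundance, table.abundance)

    def test_within_sample_differences_preserved(self):
        rng = np.random.default_rng(5)
        table = make_table(rng.normal(10, 2, size=(20, 6)), scale="log2")
        out = median_normalize(table)
        for s in table.samples:
            before = np.diff(table.abundance[s])
            after = np.diff(out.abundance[s])
            np.testing.assert_allclose(after, before, atol=1e-12)


class TestWelchVolcano:
    def test_textbook_example(self):
        X = pd.DataFrame({"site": [1.0, 2.0, 3.0, 2.0, 3.0, 4.0]})
        y = np.array(["A"] * 3 + ["B"] * 3)
        res = welch_volcano(X, y, "A", "B")
        assert res.loc["site", "t_statistic"] == pytest.approx(-1.224744871, abs=1e-8)
        assert res.loc["site", "df"] == pytest.approx(4.0, abs=1e-9)
        assert res.loc["site", "p_value"] == pytest.approx(0.287864135, abs=1e-8)

    def test_matches_closed_form_oracle_100_instances(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            na, nb = rng.integers(3, 12, size=2)
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), na)
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), nb)
            X = pd.DataFrame({"f": np.concatenate([a, b])})
            y = np.array(["A"] * na + ["B"] * nb)
            res = welch_volcano(X, y, "A", "B")
            t, df, p = welch_oracle(a, b)
            assert res.loc["f", "t_statistic"] == pytest.approx(t, abs=1e-10)
            assert res.loc["f", "df"] == pytest.approx(df, abs=1e-10)
            assert res.loc["f", "p_value"] == pytest.approx(p, abs=1e-10)

    def test_identical_groups_not_significant(self):
        X = pd.DataFrame({"f": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
        y = np.array(["A"] * 3 + ["B"] * 3)
        res = welch_volcano(X, y, "A", "B")
        assert res.loc["f", "log2_difference"] == 0.0
        assert res.loc["f", "volcano_class"] == "not_significant"

    def test_degenerate_zero_variance(self):
        X = pd.DataFrame({"flat": [5.0] * 6, "sep": [5.0] * 3 + [4.0] * 3})
        y = np.array(["A"] * 3 + ["B"] * 3)
        res = welch_volcano(X, y, "A", "B")
        assert res.loc["flat", "p_value"] == 1.0
        assert res.loc["flat", "volcano_class"] == "not_significant"
        assert res.loc["sep", "p_value"] == 0.0
        assert res.loc["sep", "volcano_class"] == "up"

    def test_classification_obeys_both_cutoffs(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(20, 300)))
        X.iloc[:10, :150] += rng.uniform(0, 1.2, size=150)
        y = np.array(["A"] * 10 + ["B"] * 10)
        params = FilterParams()
        res = welch_volcano(X, y, "A", "B", params)
        up = (res.p_value <= 0.05) & (res.log2_difference >= 0.5)
        down = (res.p_value <= 0.05) & (res.log2_difference <= -0.5)
        assert ((res.volcano_class == "up") == up).all()
        assert ((res.volcano_class == "down") == down).all()

    def test_fdr_column_optional(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(10, 20)))
        y = np.array(["A"] * 5 + ["B"] * 5)
        assert "q_value" not in welch_volcano(X, y, "A", "B").columns
        res = welch_volcano(X, y, "A", "B", fdr=True)
        assert (res.q_value >= res.p_value - 1e-12).all()

    def test_small_groups_rejected(self):
        X = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="at least 2"):
            welch_volcano(X, np.array(["A", "B", "B"]), "A", "B")


class TestHeatmapMarkerSelection:
    def _data(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 8
        y = np.repeat(["HC", "CKD", "low_grade", "high_grade"], n)
        X = pd.DataFrame(
            rng.normal(size=(4 * n, 3)), columns=["high_only", "flat", "both"]
        )
        X.loc[y == "high_grade", "high_only"] += 2.0
        X.loc[np.isin(y, ["low_grade", "high_grade"]), "both"] += 2.0
        return X, y

    def test_planted_marker_selected_for_its_group(self):
        X, y = self._data()
        sel = heatmap_marker_selection(X, y)
        assert "high_only" in sel["high_grade"]
        assert "high_only" not in sel["low_grade"]

    def test_flat_site_not_selected(self):
        X, y = self._data()
        sel = heatmap_marker_selection(X, y)
        assert "flat" not in sel["high_grade"]
        assert "flat" not in sel["low_grade"]

    def test_shared_elevation_fails_all_mode_passes_any_mode(self):
        X, y = self._data()
        strict = heatmap_marker_selection(X, y, mode="all")
        assert "both" not in strict["low_grade"]
        loose = heatmap_marker_selection(X, y, mode="any")
        assert "both" in loose["low_grade"]

    def test_small_groups_rejected(self):
        X = pd.DataFrame(np.zeros((4, 1)))
        y = np.array(["A", "A", "B", "B"])
        with pytest.raises(ValueError, match="fewer than 3"):
            heatmap_marker_selection(X, y, target_groups=("A",))


class TestPipelineOrderAndComposition:
    def test_sklearn_pipeline_composes(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.uniform(20, 4000, size=(6, 40)))
        X[X < 30] = np.nan
        pipe = Pipeline(
            [
                ("floor", IntensityFloor(30.0)),
                ("log2", Log2Transformer()),
                ("impute", DownshiftImputer(random_state=0)),
                ("normalize", MedianNormalizer()),
            ]
        )
        out = pipe.fit_transform(X)
        assert out.shape == X.shape
        assert np.isfinite(out.to_numpy()).all()
        medians = out.median(axis=1)
        np.testing.assert_allclose(medians, medians.iloc[0], atol=1e-12)

    def test_imputation_before_normalization_matters(self):
        """Regression guard on stage order: swapping imputation and median
        normalization changes the completed table."""
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.normal(12, 2, size=(6, 60)))
        X[rng.random(X.shape) < 0.25] = np.nan
        X.iloc[0] += 3.0  # a sample needing normalization
        imputer = DownshiftImputer(random_state=5)
        normalizer = MedianNormalizer()
        canonical = normalizer.fit_transform(imputer.fit_transform(X))
        swapped = imputer.fit_transform(normalizer.fit_transform(X))
        assert not np.allclose(canonical.to_numpy(), swapped.to_numpy())

    def test_site_table_wrappers_enforce_scale(self, gated_tiny_table):
        assert gated_tiny_table.scale == "log2"
        with pytest.raises(ValueError, match="raw"):
            qc_floor(gated_tiny_table)
        with pytest.raises(ValueError, match="raw"):
            log2_transform(gated_tiny_table)
        completed = impute_downshift(gated_tiny_table, ImputationParams(seed=1))
        again = impute_downshift(gated_tiny_table, ImputationParams(seed=1))
        pd.testing.assert_frame_equal(completed.abundance, again.abundance)
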