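"""Transforms, per-feature models, BH correction, PCA, Spearman."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from redoxomics.cleaning import FeatureTable
from redoxomics.stats import (GlogParams, bh_adjust, fit_feature_models,
                              glog_transform, pareto_scale, pca_scores,
                              spearman_gas_correlation)


def _table(rows: dict, samples=None):
    df = pd.DataFrame.from_dict(rows, orient="index")
    if samples:
        df.columns = samples
    return FeatureTable(df.astype(float), require_nonnegative=False)


class TestGlog:
    def test_standard_handles_zero(self):
        t = _table({"f": [0.0, 1024.0]})
        out = glog_transform(t, GlogParams(a=2.0))
        assert out.data.loc["f"].iloc[0] == pytest.approx(0.0)  # log2(1)
        assert out.data.loc["f"].iloc[1] == pytest.approx(10.0, abs=1e-5)

    def test_literal_mode_matches_printed_form(self):
        t = _table({"f": [0.0, 3.0]})
        out = glog_transform(t, GlogParams(a=2.0, mode="literal"))
        assert out.data.loc["f"].iloc[0] == pytest.approx(1.0)   # sqrt(4)/2
        assert out.data.loc["f"].iloc[1] == pytest.approx(np.sqrt(13) / 2)

    def test_offset_auto_derived_as_min_nonzero(self):
        t = _table({"f": [0.0, 4.0], "g": [2.0, 8.0]})
        manual = glog_transform(t, GlogParams(a=2.0))
        auto = glog_transform(t, GlogParams())
        assert np.allclose(manual.values, auto.values)

    def test_zero_offset_with_zeros_rejected(self):
        with pytest.raises(ValueError):
            glog_transform(_table({"f": [0.0, 1.0]}), GlogParams(a=0.0))

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.integers(0, 10**9), min_size=2, max_size=10, unique=True),
           st.floats(0.01, 100))
    def test_strict_monotonicity(self, xs, a):
        t = _table({"f": sorted(float(x) for x in xs)})
        std = glog_transform(t, GlogParams(a=a)).values[0]
        lit = glog_transform(t, GlogParams(a=a, mode="literal")).values[0]
        assert np.all(np.diff(std) > 0)
        assert np.all(np.diff(lit) > 0)
        assert np.all(lit >= a / 2)


class TestPareto:
    def test_divides_by_sqrt_sd(self):
        row = np.array([0.0, 2.0, 4.0, 6.0])
        out = pareto_scale(_table({"f": row}))
        sd = row.std(ddof=1)
        assert sd == pytest.approx(2.581989, rel=1e-6)
        assert out.data.loc["f"].iloc[1] == pytest.approx(2 / np.sqrt(sd))
        assert out.data.loc["f"].iloc[1] == pytest.approx(1.244665, rel=1e-6)

    def test_constant_row_passes_through(self):
        out = pareto_scale(_table({"f": [3.0, 3.0, 3.0]}))
        assert np.allclose(out.values, 3.0)

    def test_global_rescaling_scales_by_sqrt_c(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(1, 100, (5, 8))
        t = FeatureTable(pd.DataFrame(x))
        c = 9.0
        tc = FeatureTable(pd.DataFrame(c * x))
        assert np.allclose(pareto_scale(tc).values,
                           np.sqrt(c) * pareto_scale(t).values)

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            pareto_scale(_table({"f": [1.0]}))


class TestBenjaminiHochberg:
    def test_hand_example_all_tie_at_largest(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_single_and_degenerate(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 200)
        _, q_sm, *_ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_adjust(p), q_sm)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_bh_properties(self, p):
        q = bh_adjust(p)
        p = np.asarray(p)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def _design(days=(0, 7), reps=3, bog_final=None, fen_final=None):
    rows = []
    for hab in ("bog", "fen"):
        hab_days = list(days)
        extra = bog_final if hab == "bog" else fen_final
        if extra is not None:
            hab_days.append(extra)
        for d in hab_days:
            for r in range(reps):
                rows.append({"sample_id": f"{hab}_d{d}_r{r}",
                             "habitat": hab, "day": d})
    return pd.DataFrame(rows)


class TestFeatureModels:
    def test_constant_feature_has_zero_estimates(self):
        design = _design()
        t = _table({"f": [5.0] * len(design)}, samples=list(design["sample_id"]))
        for res in fit_feature_models(t, design):
            assert res.estimate == pytest.approx(0.0)
            assert res.q_value >= res.p_value

    def test_matches_statsmodels_cell_means(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        design = _design(days=(0, 7, 14))
        y = rng.normal(0, 1, len(design))
        t = _table({"f": y}, samples=list(design["sample_id"]))
        results = {r.timepoint: r for r in fit_feature_models(t, design)}

        cells = sorted(set(zip(design["habitat"], design["day"])))
        X = np.zeros((len(design), len(cells)))
        for i, (h, d) in enumerate(zip(design["habitat"], design["day"])):
            X[i, cells.index((h, d))] = 1.0
        fit = sm.OLS(y, X).fit()
        for day in (0, 7, 14):
            c = np.zeros(len(cells))
            c[cells.index(("bog", day))] = 1
            c[cells.index(("fen", day))] = -1
            tt = fit.t_test(c)
            assert results[str(day)].estimate == pytest.approx(float(tt.effect[0]))
            assert results[str(day)].p_value == pytest.approx(float(tt.pvalue))

    def test_recovers_planted_habitat_shift(self):
        """bog-fen difference of 2.0 at one timepoint, residual sd 0.1,
        n=3/group: mean recovered estimate within 0.1 over 100 seeds."""
        ests = []
        design = _design(days=(0, 7))
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = rng.normal(0, 0.1, len(design))
            shift = (design["habitat"] == "bog") & (design["day"] == 7)
            y = y + 2.0 * shift.to_numpy()
            t = _table({"f": y}, samples=list(design["sample_id"]))
            res = {r.timepoint: r for r in fit_feature_models(t, design)}
            ests.append(res["7"].estimate)
        assert np.mean(ests) == pytest.approx(2.0, abs=0.1)

    def test_final_day_alignment_pools_unequal_endpoints(self):
        design = _design(days=(0,), bog_final=28, fen_final=35)
        rng = np.random.default_rng(0)
        t = _table({"f": rng.normal(0, 1, len(design))},
                   samples=list(design["sample_id"]))
        timepoints = {r.timepoint for r in fit_feature_models(t, design)}
        assert timepoints == {"0", "final"}

    def test_missing_cell_is_reported(self):
        design = _design(days=(0, 7))
        design = design[~((design["habitat"] == "fen") & (design["day"] == 7))]
        t = _table({"f": np.arange(len(design), dtype=float)},
                   samples=list(design["sample_id"]))
        with pytest.raises(ValueError, match="fen"):
            fit_feature_models(t, design)


class TestPca:
    def test_perfectly_correlated_features_give_one_component(self):
        t = _table({"a": [1, 2, 3, 4], "b": [2, 4, 6, 8]})
        _, _, ev = pca_scores(t, 2)
        assert ev[0] == pytest.approx(1.0)
        assert ev[1] == pytest.approx(0.0, abs=1e-12)

    def test_identical_samples_zero_scores(self):
        t = _table({"a": [3, 3, 3], "b": [5, 5, 5]})
        scores, _, _ = pca_scores(t, 1)
        assert np.allclose(scores, 0.0)

    def test_eigenvalues_match_hand_decomposition(self):
        x = np.array([[2.0, 0.0, 1.0], [0.0, 2.0, 1.0], [1.0, 1.0, 2.0]])
        t = FeatureTable(pd.DataFrame(x.T))  # features x samples
        _, _, ev = pca_scores(t, 3)
        cov = np.cov(x.T, rowvar=False, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert np.allclose(ev, eig / eig.sum())

    def test_too_many_components_rejected(self):
        t = _table({"a": [1, 2], "b": [3, 5]})
        with pytest.raises(ValueError):
            pca_scores(t, 3)


class TestSpearman:
    def test_monotone_relationships(self):
        t = _table({"up": [1, 5, 20, 100], "down": [100, 20, 5, 1]})
        rho = spearman_gas_correlation(t, np.array([1.0, 2.0, 3.0, 4.0]))
        assert rho["up"] == pytest.approx(1.0)
        assert rho["down"] == pytest.approx(-1.0)

    def test_tied_ranks_match_scipy(self):
        from scipy.stats import spearmanr

        t = _table({"f": [3, 1, 4, 1, 5]})
        gas = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        rho = spearman_gas_correlation(t, gas)
        assert rho["f"] == pytest.approx(spearmanr([3, 1, 4, 1, 5], gas).statistic)

    def test_constant_gas_flagged_not_raised(self):
        t = _table({"f": [1, 2, 3]})
        rho = spearman_gas_correlation(t, np.array([2.0, 2.0, 2.0]))
        assert np.isnan(rho["f"])
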