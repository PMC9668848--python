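"""Mixed models, logRR effect sizes and the permutation multivariate suite."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from pulsetrace.stats import (
    LogRRModel,
    ManagementModel,
    bray_curtis,
    fit_vectors,
    hellinger,
    log_response_ratio,
    pcoa,
    permanova,
    permdisp,
)

# ---------------------------------------------------------------------------
# transforms and distances
# ---------------------------------------------------------------------------


class TestHellinger:
    def test_uniform_row(self):
        out = hellinger([[1.0, 1.0, 1.0, 1.0]])
        assert np.allclose(out, 0.5)

    def test_single_column(self):
        assert np.allclose(hellinger([[3.0], [7.0]]), 1.0)

    def test_row_scale_invariance(self):
        a = np.array([[1.0, 2.0, 3.0], [5.0, 1.0, 0.0]])
        assert np.allclose(hellinger(a), hellinger(a * 17.0))

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError, match="zero-total"):
            hellinger([[1.0, 1.0], [0.0, 0.0]])


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        d = bray_curtis([[1.0, 2.0], [1.0, 2.0]])
        assert d[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        d = bray_curtis([[1.0, 0.0], [0.0, 5.0]])
        assert d[0, 1] == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        d = bray_curtis([[1.0, 2.0], [2.0, 1.0]])
        assert d[0, 1] == pytest.approx(1.0 / 3.0)

    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 5, size=(7, 4))
        assert np.allclose(bray_curtis(x), squareform(pdist(x, "braycurtis")))


class TestPCoA:
    def test_recovers_euclidean_configuration(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(10, 2))
        d = squareform(pdist(pts))
        res = pcoa(d)
        assert res.coordinates.shape[1] >= 2
        # Procrustes: distances between recovered points match the originals
        d_rec = squareform(pdist(res.coordinates[:, :2]))
        assert np.allclose(d_rec, d, atol=1e-8)

    def test_all_zero_distances(self):
        res = pcoa(np.zeros((4, 4)))
        assert res.coordinates.size == 0 or np.allclose(res.coordinates, 0.0)

    def test_eigenvalue_sum_equals_centred_trace(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 3))
        d = squareform(pdist(pts))
        res = pcoa(d)
        n = 8
        j = np.eye(n) - 1.0 / n
        b = -0.5 * j @ (d**2) @ j
        assert res.eigenvalues.sum() + res.negative_eigenvalues.sum() == pytest.approx(
            np.trace(b), rel=1e-9
        )

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            pcoa([[0.0, 1.0], [2.0, 0.0]])


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------


def _euclidean_pseudo_f(pts, labels):
    """Independent PERMANOVA oracle from centroid geometry (Euclidean case)."""
    pts = np.asarray(pts, float)
    labels = np.asarray(labels)
    grand = pts.mean(axis=0)
    ss_within = ss_among = 0.0
    for g in np.unique(labels):
        sub = pts[labels == g]
        c = sub.mean(axis=0)
        ss_within += ((sub - c) ** 2).sum()
        ss_among += len(sub) * ((c - grand) ** 2).sum()
    a = len(np.unique(labels))
    n = len(pts)
    return (ss_among / (a - 1)) / (ss_within / (n - a))


class TestPermanova:
    def test_pseudo_f_equals_geometry_oracle(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(6, 2))
        pts[3:] += 2.0
        labels = ["a"] * 3 + ["b"] * 3
        d = squareform(pdist(pts))
        res = permanova(d, labels, n_permutations=99, seed=0)
        assert res.statistic == pytest.approx(_euclidean_pseudo_f(pts, labels), rel=1e-10)

    def test_exhaustive_permutation_p_value(self):
        """Six points, 3+3 labels: p agrees with full enumeration."""
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(6, 2))
        pts[3:] += 1.5
        d = squareform(pdist(pts))
        labels = np.array(["a"] * 3 + ["b"] * 3)
        f_obs = _euclidean_pseudo_f(pts, labels)
        fs = []
        for combo in itertools.combinations(range(6), 3):
            lab = np.array(["b"] * 6)
            lab[list(combo)] = "a"
            fs.append(_euclidean_pseudo_f(pts, lab))
        p_exact = np.mean(np.array(fs) >= f_obs - 1e-12)
        res = permanova(d, labels, n_permutations=9999, seed=1)
        assert res.statistic == pytest.approx(f_obs, rel=1e-10)
        assert res.p_value == pytest.approx(p_exact, abs=0.02)

    def test_matches_scikit_bio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as skbio_permanova

        rng = np.random.default_rng(9)
        x = rng.uniform(0, 4, size=(12, 5))
        d = squareform(pdist(x, "braycurtis"))
        labels = ["a"] * 6 + ["b"] * 6
        ours = permanova(d, labels, n_permutations=99, seed=0)
        theirs = skbio_permanova(
            skbio.DistanceMatrix(d), grouping=list(labels), permutations=99
        )
        assert ours.statistic == pytest.approx(theirs["test statistic"], rel=1e-8)

    def test_perfect_separation(self):
        x = np.array([[0.0, 0], [0, 0], [0, 0], [10, 10], [10, 10], [10, 10]])
        d = squareform(pdist(x))
        res = permanova(d, ["a"] * 3 + ["b"] * 3, n_permutations=199, seed=0)
        assert res.statistic > 100
        assert res.p_value <= 0.2  # limited by distinct relabelings of 6 points

    def test_row_reordering_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(10, 3))
        labels = np.array(["a"] * 5 + ["b"] * 5)
        d = squareform(pdist(x))
        perm = rng.permutation(10)
        a = permanova(d, labels, n_permutations=49, seed=3)
        b = permanova(d[np.ix_(perm, perm)], labels[perm], n_permutations=49, seed=3)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-10)

    def test_estimator_range_and_groups_validation(self):
        d = squareform(pdist(np.arange(6.0)[:, None]))
        res = permanova(d, ["a", "a", "a", "b", "b", "b"], n_permutations=99, seed=0)
        assert 0.0 < res.p_value <= 1.0
        with pytest.raises(ValueError):
            permanova(d, ["a"] * 6, n_permutations=9)
        with pytest.raises(ValueError):
            permanova(d, ["a"] * 5 + ["b"], n_permutations=9)


class TestPermdisp:
    def test_centroid_distances_match_geometry(self):
        rng = np.random.default_rng(5)
        pts = np.vstack([rng.normal(0, 1, (6, 2)), rng.normal(5, 3, (6, 2))])
        labels = np.array(["a"] * 6 + ["b"] * 6)
        d = squareform(pdist(pts))
        from pulsetrace.stats import _codes, _dispersion_distances

        z = _dispersion_distances(d, _codes(labels), 2)
        expected = np.concatenate(
            [
                np.linalg.norm(pts[:6] - pts[:6].mean(axis=0), axis=1),
                np.linalg.norm(pts[6:] - pts[6:].mean(axis=0), axis=1),
            ]
        )
        assert np.allclose(z, expected, atol=1e-8)

    def test_zero_dispersion_vs_spread_group(self):
        pts = np.vstack([np.zeros((5, 2)), np.random.default_rng(0).normal(0, 3, (5, 2))])
        pts[:5] += [[0, 0]]
        d = squareform(pdist(pts + np.random.default_rng(1).normal(0, 1e-9, pts.shape)))
        res = permdisp(d, ["a"] * 5 + ["b"] * 5, n_permutations=199, seed=0)
        assert res.p_value < 0.05

    def test_equal_dispersion_not_significant(self):
        rng = np.random.default_rng(6)
        pts = np.vstack([rng.normal(0, 1, (8, 2)), rng.normal(10, 1, (8, 2))])
        d = squareform(pdist(pts))
        res = permdisp(d, ["a"] * 8 + ["b"] * 8, n_permutations=199, seed=0)
        assert res.p_value > 0.05


class TestFitVectors:
    def test_axis_aligned_variable(self):
        rng = np.random.default_rng(8)
        coords = rng.normal(size=(20, 2))
        coords -= coords.mean(axis=0)
        vars_df = pd.DataFrame({"v": coords[:, 0]})
        out = fit_vectors(coords, vars_df, n_permutations=99, seed=0)
        row = out.iloc[0]
        assert row["r_squared"] == pytest.approx(1.0, abs=1e-10)
        assert abs(row["axis1"]) == pytest.approx(1.0, abs=1e-6)
        assert row["axis2"] == pytest.approx(0.0, abs=1e-6)
        assert row["retained"]

    def test_identical_variables_identical_vectors(self):
        rng = np.random.default_rng(10)
        coords = rng.normal(size=(15, 2))
        y = rng.normal(size=15)
        out = fit_vectors(coords, pd.DataFrame({"a": y, "b": y}), n_permutations=49, seed=0)
        assert np.allclose(out.iloc[0][["axis1", "axis2"]].astype(float),
                           out.iloc[1][["axis1", "axis2"]].astype(float))

    def test_constant_variable_skipped(self):
        coords = np.random.default_rng(0).normal(size=(10, 2))
        out = fit_vectors(coords, pd.DataFrame({"c": np.ones(10)}), n_permutations=9)
        assert out.empty


# ---------------------------------------------------------------------------
# mixed models and logRR
# ---------------------------------------------------------------------------


def _balanced_data(rng, shift=1.0, site_sd=0.5, resid_sd=(1.0, 0.6, 0.4, 0.25), n_rep=3):
    rows = []
    days = [0, 1, 2, 5][: len(resid_sd)]
    for s in range(3):
        site_eff = rng.normal(0, site_sd)
        for mgmt, mu in (("extensive", 0.0), ("intensive", shift)):
            for rep in range(n_rep):
                for day, sd in zip(days, resid_sd):
                    rows.append(
                        {
                            "site": f"S{s}", "management": mgmt, "replicate": rep,
                            "day": day, "y": mu + site_eff + rng.normal(0, sd),
                        }
                    )
    return pd.DataFrame(rows)


class TestManagementModel:
    def test_degenerate_limit_equals_mean_difference(self):
        """Single time point: the REML estimate is the plain group difference."""
        rng = np.random.default_rng(1)
        df = _balanced_data(rng, shift=1.0, resid_sd=(0.8,))
        res = ManagementModel(df, "y", preset="enrichment").fit()
        means = df.groupby("management")["y"].mean()
        diff = means["intensive"] - means["extensive"]
        assert res.params["management[intensive]"] == pytest.approx(diff, abs=1e-8)

    def test_matches_statsmodels_random_intercept(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(2)
        df = _balanced_data(rng, shift=0.7, resid_sd=(0.5, 0.5, 0.5, 0.5))
        ours = ManagementModel(df, "y", preset="enrichment").fit()
        # homoscedastic truth: compare against MixedLM with a site intercept
        md = sm.MixedLM.from_formula("y ~ C(management)", groups="site", data=df)
        ref = md.fit(reml=True)
        est_ref = ref.params["C(management)[T.intensive]"]
        assert ours.params["management[intensive]"] == pytest.approx(est_ref, abs=0.02)
        assert ours.bse["management[intensive]"] == pytest.approx(
            ref.bse["C(management)[T.intensive]"], rel=0.2
        )

    def test_heteroscedastic_variances_ordered(self):
        rng = np.random.default_rng(3)
        df = _balanced_data(rng, shift=0.0, resid_sd=(2.0, 0.1, 0.1, 0.1), n_rep=6)
        res = ManagementModel(df, "y", preset="enrichment").fit()
        v = res.residual_variances
        assert v[0] > v[1] and v[0] > v[5]

    def test_zero_site_variance_flagged_as_gls_fallback(self):
        rng = np.random.default_rng(4)
        df = _balanced_data(rng, shift=0.5, site_sd=0.0, resid_sd=(0.5, 0.5), n_rep=12)
        # remove all between-site signal so the variance sits on the boundary
        df["y"] -= df.groupby("site")["y"].transform("mean") - df["y"].mean()
        res = ManagementModel(df, "y", preset="enrichment").fit()
        assert res.fallback_gls
        assert res.variance_components["site"] == 0.0

    def test_biomass_preset_crossed_effects(self):
        rng = np.random.default_rng(5)
        df = _balanced_data(rng, shift=1.0)
        res = ManagementModel(df, "y", preset="biomass").fit()
        assert set(res.variance_components) == {"site", "time"}
        assert res.params["management[intensive]"] == pytest.approx(1.0, abs=1.0)

    def test_requires_two_sites_and_two_levels(self):
        df = _balanced_data(np.random.default_rng(0))
        with pytest.raises(ValueError):
            ManagementModel(df[df.site == "S0"], "y")
        with pytest.raises(ValueError):
            ManagementModel(df[df.management == "extensive"], "y")

    def test_summary_mentions_fixed_effect(self):
        res = ManagementModel(_balanced_data(np.random.default_rng(6)), "y").fit()
        assert "management[intensive]" in res.summary()


class TestLogRR:
    def _paired_data(self, ratios, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(3):
            for mgmt in ("extensive", "intensive"):
                for rep in range(3):
                    base = 1.0 + rng.uniform(0, 1)
                    for day in (0, 1, 2):
                        rows.append({"site": f"S{s}", "management": mgmt,
                                     "treatment": "control", "replicate": rep, "day": day,
                                     "value": base * (1 + noise * rng.normal())})
                        rows.append({"site": f"S{s}", "management": mgmt,
                                     "treatment": "drought", "replicate": rep, "day": day,
                                     "value": base * ratios[mgmt] * (1 + noise * rng.normal())})
        return pd.DataFrame(rows)

    def test_equal_pairs_give_zero_with_ci_containing_zero(self):
        df = self._paired_data({"extensive": 1.0, "intensive": 1.0})
        res = log_response_ratio(df, "value")
        assert np.allclose(res.per_management["logRR"], 0.0, atol=1e-12)
        assert not res.per_management["significant"].any()

    def test_single_pair_definition(self):
        df = pd.DataFrame(
            [
                {"site": "S1", "management": "extensive", "treatment": "control",
                 "replicate": 1, "value": 1.0},
                {"site": "S1", "management": "extensive", "treatment": "drought",
                 "replicate": 1, "value": 2.0},
            ]
        )
        model = LogRRModel(df, "value")
        assert model.pairs["logRR"].iloc[0] == pytest.approx(np.log(2.0))

    def test_known_ratio_recovered(self):
        df = self._paired_data({"extensive": 0.7, "intensive": 0.7}, noise=0.02, seed=3)
        res = log_response_ratio(df, "value")
        for row in res.per_management.itertuples():
            assert row.logRR == pytest.approx(np.log(0.7), abs=0.05)
            assert row.significant and row.ci_high < 0

    def test_date_order_invariance(self):
        df = self._paired_data({"extensive": 0.8, "intensive": 1.2}, noise=0.05, seed=4)
        shuffled = df.sample(frac=1.0, random_state=1)
        a = log_response_ratio(df, "value").per_management
        b = log_response_ratio(shuffled, "value").per_management
        assert np.allclose(a["logRR"], b["logRR"])

    def test_nonpositive_mean_pairs_dropped(self):
        df = self._paired_data({"extensive": 1.0, "intensive": 1.0})
        df.loc[(df.site == "S0") & (df.management == "extensive")
               & (df.treatment == "control") & (df.replicate == 0), "value"] = 0.0
        model = LogRRModel(df, "value")
        assert len(model.dropped_pairs) == 1
        assert len(model.pairs) == 17
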