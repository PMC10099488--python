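"""Tidal connection, distance matrices, Mantel tests, and lake summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lakerad.seascape import (
    INDO_PACIFIC_SURVEY,
    categorize_connection,
    connection_distance_matrix,
    environment_distance_matrix,
    geographic_distance_matrix,
    linearize_fst,
    mantel,
    spearman_diversity,
    summarize_profiles,
    tidal_fraction,
    validate_distance_matrix,
)


class TestTidalFraction:
    def test_identical_series_gives_one(self):
        series = np.sin(np.linspace(0, 12 * np.pi, 200)) + 3
        assert tidal_fraction(series, series) == 1.0

    def test_amplitude_ratio(self):
        t = np.linspace(0, 12 * np.pi, 200)
        lake = 0.2 * np.sin(t) + 5  # amplitude 0.4 m
        sea = 0.25 * np.sin(t) + 7  # amplitude 0.5 m
        assert tidal_fraction(lake, sea) == pytest.approx(0.8, abs=1e-9)

    def test_flat_lake_gives_zero(self):
        sea = np.sin(np.linspace(0, 12 * np.pi, 100))
        assert tidal_fraction(np.zeros(100), sea) == 0.0

    def test_flat_sea_rejected(self):
        with pytest.raises(ValueError, match="flat sea"):
            tidal_fraction(np.ones(50), np.ones(50))

    def test_overshoot_clamped_with_warning(self):
        t = np.linspace(0, 6 * np.pi, 100)
        with pytest.warns(UserWarning, match="clamped"):
            c = tidal_fraction(2 * np.sin(t), np.sin(t))
        assert c == 1.0


class TestCategories:
    @pytest.mark.parametrize(
        "c,expected",
        [(0.1, "low"), (0.3, "low"), (0.4, "low"), (0.5, "medium"),
         (0.7, "medium"), (0.8, "high"), (1.0, "high"), ("open", "open")],
    )
    def test_thresholds(self, c, expected):
        assert categorize_connection(c) == expected

    def test_gap_values_flagged(self):
        with pytest.warns(UserWarning, match="gap"):
            assert categorize_connection(0.45) == "medium"
        with pytest.warns(UserWarning, match="gap"):
            assert categorize_connection(0.75) == "high"


class TestDistances:
    def _profiles(self, rows):
        return pd.DataFrame(rows)

    def test_geographic_equator_degree(self):
        prof = self._profiles(
            [{"code": "a", "lat": 0.0, "lon": 0.0}, {"code": "b", "lat": 0.0, "lon": 1.0}]
        )
        d = geographic_distance_matrix(prof)
        assert d.loc["a", "b"] == pytest.approx(111_195, abs=1.0)
        validate_distance_matrix(d)

    def test_geographic_identical_coordinates_zero(self):
        prof = self._profiles(
            [{"code": "a", "lat": -2.0, "lon": 130.0}, {"code": "b", "lat": -2.0, "lon": 130.0}]
        )
        assert geographic_distance_matrix(prof).loc["a", "b"] == 0.0

    def test_environment_equals_zscore_distance(self):
        prof = self._profiles(
            [
                {"code": "a", "temperature_c": 29.0, "salinity_ppt": 33.0},
                {"code": "b", "temperature_c": 32.0, "salinity_ppt": 24.0},
                {"code": "c", "temperature_c": 30.5, "salinity_ppt": 28.0},
            ]
        )
        d = environment_distance_matrix(prof)
        z = prof[["temperature_c", "salinity_ppt"]].to_numpy(float)
        z = (z - z.mean(axis=0)) / z.std(axis=0, ddof=1)
        for i, j in itertools.combinations(range(3), 2):
            expect = np.linalg.norm(z[i] - z[j])
            assert d.iloc[i, j] == pytest.approx(expect, abs=1e-9)

    def test_environment_monotone_in_similarity(self):
        prof = self._profiles(
            [
                {"code": "a", "temperature_c": 30.0, "salinity_ppt": 28.0},
                {"code": "similar", "temperature_c": 30.2, "salinity_ppt": 28.3},
                {"code": "dissimilar", "temperature_c": 32.4, "salinity_ppt": 23.5},
            ]
        )
        d = environment_distance_matrix(prof)
        assert d.loc["a", "similar"] < d.loc["a", "dissimilar"]

    def test_environment_missing_rejected(self):
        prof = self._profiles(
            [{"code": "a", "temperature_c": np.nan, "salinity_ppt": 33.0},
             {"code": "b", "temperature_c": 30.0, "salinity_ppt": 30.0}]
        )
        with pytest.raises(ValueError, match="missing"):
            environment_distance_matrix(prof)

    def test_connection_formula_values(self):
        prof = self._profiles(
            [
                {"code": "open1", "tidal_fraction": np.nan, "category": "open"},
                {"code": "open2", "tidal_fraction": np.nan, "category": "open"},
                {"code": "iso1", "tidal_fraction": 0.0, "category": "low"},
                {"code": "iso2", "tidal_fraction": 0.0, "category": "low"},
                {"code": "weak", "tidal_fraction": 0.1, "category": "low"},
                {"code": "strong", "tidal_fraction": 0.8, "category": "high"},
            ]
        )
        d = connection_distance_matrix(prof)
        assert d.loc["open1", "open2"] == 0.0
        assert d.loc["iso1", "iso2"] == 1.0
        assert d.loc["weak", "strong"] == pytest.approx(0.55)
        assert d.loc["iso1", "iso2"] > d.loc["weak", "strong"] > d.loc["open1", "open2"]

    def test_connection_missing_c_excluded_with_warning(self):
        prof = self._profiles(
            [
                {"code": "a", "tidal_fraction": 0.5, "category": "medium"},
                {"code": "nocp", "tidal_fraction": np.nan, "category": "medium"},
                {"code": "b", "tidal_fraction": 0.8, "category": "high"},
            ]
        )
        with pytest.warns(UserWarning, match="nocp"):
            d = connection_distance_matrix(prof)
        assert list(d.index) == ["a", "b"]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        ci=st.floats(0, 1), cj=st.floats(0, 1), ck=st.floats(0, 1)
    )
    def test_connection_ordering_property(self, ci, cj, ck):
        """More connected lakes are never farther from any fixed partner."""
        prof = pd.DataFrame(
            [
                {"code": "i", "tidal_fraction": max(ci, cj), "category": "low"},
                {"code": "j", "tidal_fraction": min(ci, cj), "category": "low"},
                {"code": "k", "tidal_fraction": ck, "category": "low"},
            ]
        )
        d = connection_distance_matrix(prof)
        assert d.loc["i", "k"] <= d.loc["j", "k"] + 1e-12


class TestLinearize:
    def test_values(self):
        m = pd.DataFrame(
            [[0.0, 0.5, 0.63], [0.5, 0.0, 0.0], [0.63, 0.0, 0.0]],
            index=list("abc"), columns=list("abc"),
        )
        lin = linearize_fst(m)
        assert lin.loc["a", "b"] == pytest.approx(1.0)
        assert lin.loc["a", "c"] == pytest.approx(0.63 / 0.37, abs=1e-4)
        assert lin.loc["a", "c"] == pytest.approx(1.7027, abs=1e-4)
        assert lin.loc["b", "c"] == 0.0

    def test_unit_entry_capped_with_warning(self):
        m = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=list("ab"), columns=list("ab"))
        with pytest.warns(UserWarning, match="cap"):
            lin = linearize_fst(m, cap=50.0)
        assert lin.loc["a", "b"] == 50.0


def _random_dist(rng, n):
    x = rng.random((n, 2))
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    labels = [f"s{i}" for i in range(n)]
    return pd.DataFrame(d, index=labels, columns=labels)


class TestMantel:
    def test_perfect_correlation(self, rng):
        d1 = _random_dist(rng, 6)
        res = mantel(d1, 2 * d1, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100)

    def test_exact_enumeration_matches_brute_force(self, rng):
        """4x4 exact p equals enumeration over all 24 label permutations."""
        d1 = _random_dist(rng, 4)
        d2 = _random_dist(rng, 4)
        res = mantel(d1, d2, n_perm="exact")
        a, b = d1.to_numpy(), d2.to_numpy()
        iu = np.triu_indices(4, 1)
        r_obs = np.corrcoef(a[iu], b[iu])[0, 1]
        count = 0
        for perm in itertools.permutations(range(4)):
            p = np.asarray(perm)
            r = np.corrcoef(a[iu], b[np.ix_(p, p)][iu])[0, 1]
            if r >= r_obs - 1e-12:
                count += 1
        assert res.p == pytest.approx(count / 24, abs=1e-12)
        assert res.n_perm == 24

    def test_matches_skbio_oracle(self, rng):
        """Permutation r and p agree with the scikit-bio implementation."""
        from skbio.stats.distance import DistanceMatrix, mantel as sk_mantel

        d1 = _random_dist(rng, 8)
        d2 = _random_dist(rng, 8)
        res = mantel(d1, d2, n_perm=999, seed=1)
        r_sk, p_sk, _ = sk_mantel(
            DistanceMatrix(d1.to_numpy(), ids=list(d1.index)),
            DistanceMatrix(d2.to_numpy(), ids=list(d2.index)),
            method="pearson", permutations=999, alternative="greater",
        )
        assert res.r == pytest.approx(float(r_sk), abs=1e-12)
        assert abs(res.p - float(p_sk)) < 0.05  # independent permutation draws

    def test_relabeling_invariance(self, rng):
        d1 = _random_dist(rng, 6)
        d2 = _random_dist(rng, 6)
        res1 = mantel(d1, d2, n_perm=499, seed=7)
        perm = rng.permutation(6)
        ids = [d1.index[i] for i in perm]
        d1p = d1.loc[ids, ids]
        d2p = d2.loc[ids, ids]
        res2 = mantel(d1p, d2p, n_perm=499, seed=7)
        assert res1.r == pytest.approx(res2.r, abs=1e-12)

    def test_constant_matrix_rejected(self):
        labels = list("abcd")
        flat = pd.DataFrame(1.0 - np.eye(4), index=labels, columns=labels)
        other = pd.DataFrame(
            np.abs(np.subtract.outer(range(4), range(4))).astype(float),
            index=labels, columns=labels,
        )
        with pytest.raises(ValueError, match="constant"):
            mantel(flat, other, n_perm=9)


class TestSpearmanAndSummary:
    def _tables(self):
        prof = INDO_PACIFIC_SURVEY.copy()
        div = prof[["code", "nucleotide_diversity", "heterozygosity_he"]].rename(
            columns={
                "code": "population",
                "nucleotide_diversity": "pi",
                "heterozygosity_he": "He",
            }
        )
        return div, prof

    def test_perfectly_monotone(self):
        div = pd.DataFrame(
            {"population": list("abcde"), "pi": [1, 2, 3, 4, 5], "He": [5, 4, 3, 2, 1]}
        )
        prof = pd.DataFrame(
            {"code": list("abcde"), "area_1000m2": [10, 20, 30, 40, 50]}
        )
        out = spearman_diversity(div, prof, predictors=("area_1000m2",))
        rho = {r.response: r.rho for r in out}
        assert rho["pi"] == pytest.approx(1.0)
        assert rho["He"] == pytest.approx(-1.0)

    def test_ties_match_rank_formula_oracle(self):
        from scipy import stats

        div = pd.DataFrame(
            {"population": list("abcdef"), "pi": [1, 2, 2, 3, 4, 5], "He": [1] * 6}
        )
        prof = pd.DataFrame(
            {"code": list("abcdef"), "area_1000m2": [3, 1, 4, 1, 5, 9]}
        )
        (res,) = spearman_diversity(div, prof, predictors=("area_1000m2",), responses=("pi",))
        # oracle: Pearson correlation of midranks
        rx = stats.rankdata(prof["area_1000m2"])
        ry = stats.rankdata(div["pi"])
        expect = np.corrcoef(rx, ry)[0, 1]
        assert res.rho == pytest.approx(expect, abs=1e-12)

    def test_survey_correlations_are_weak(self):
        """On the reference survey, diversity is not strongly tied to area."""
        div, prof = self._tables()
        out = spearman_diversity(div, prof, predictors=("area_1000m2",))
        for r in out:
            assert not (r.strong and r.significant)

    def test_summary_reproduces_survey_statistics(self):
        s = summarize_profiles(INDO_PACIFIC_SURVEY)
        assert round(s["lake_temperature_mean"], 1) == 30.8
        assert round(s["lake_temperature_sd"], 1) == 1.2
        assert round(s["lake_salinity_mean"], 1) == 27.3
        assert round(s["lake_salinity_sd"], 1) == 2.7
        assert s["total_individuals"] == 125
        assert s["individuals_per_lineage"]["B"] == 105
        assert s["category_counts"]["low"] == 4
        assert s["category_counts"]["high"] == 2

    def test_summary_requires_both_site_kinds(self):
        lakes_only = INDO_PACIFIC_SURVEY[INDO_PACIFIC_SURVEY["category"] != "open"]
        with pytest.raises(ValueError):
            summarize_profiles(lakes_only)
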