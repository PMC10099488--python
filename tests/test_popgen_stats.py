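"""Diversity, differentiation, AMOVA, PCA, SFS, and migration networks."""

import numpy as np
import pytest

from lakerad.genotyping import GenotypeCalls, Site
from lakerad.popgen_stats import (
    amova,
    diversity,
    folded_sfs,
    pairwise_fst,
    pca_covariance,
    relative_migration_network,
    _directional_values,
)


def _calls(geno, loci=None):
    geno = np.asarray(geno, dtype=np.int8)
    n_ind, n_sites = geno.shape
    loci = loci or [f"L{j}" for j in range(n_sites)]
    return GenotypeCalls(
        individuals=[f"i{k}" for k in range(n_ind)],
        sites=[Site(loci[j], 0, "A", "C") for j in range(n_sites)],
        genotypes=geno,
        site_depth=np.full(n_sites, 30.0),
    )


def _labels(calls, sizes):
    labels = {}
    i = 0
    for pop, n in sizes.items():
        for _ in range(n):
            labels[calls.individuals[i]] = pop
            i += 1
    return labels


class TestDiversity:
    def test_monomorphic_population_zero(self):
        calls = _calls(np.zeros((4, 5)))
        (est,) = diversity(calls, _labels(calls, {"p": 4}), total_sites=100)
        assert est.pi == 0.0 and est.He == 0.0

    def test_he_closed_form_at_half(self):
        # p = 0.5 with 2n = 20: He = (20/19) * 0.5
        geno = np.array([[0] * 5 + [2] * 5]).T.reshape(10, 1)
        calls = _calls(geno)
        (est,) = diversity(calls, _labels(calls, {"p": 10}), total_sites=1)
        assert est.He == pytest.approx((20 / 19) * 0.5, rel=1e-12)

    def test_pi_from_pairwise_difference(self):
        # two haplotypes (one diploid) differing at 1 of 100 sites
        geno = np.array([[1]])
        calls = _calls(geno)
        (est,) = diversity(calls, _labels(calls, {"p": 1}), total_sites=100)
        assert est.pi == pytest.approx(0.01, rel=1e-12)
        assert est.warning == "n<2"

    def test_total_sites_validated(self):
        calls = _calls(np.array([[0, 1], [1, 0]]))
        with pytest.raises(ValueError):
            diversity(calls, _labels(calls, {"p": 2}), total_sites=1)


class TestPairwiseFst:
    def test_identical_frequencies_zero(self):
        block = np.array([[0], [1], [2], [1]])
        geno = np.vstack([block, block])
        calls = _calls(geno)
        res = pairwise_fst(calls, _labels(calls, {"a": 4, "b": 4}), n_perm=0)
        assert res["gst"].loc["a", "b"] == pytest.approx(0.0, abs=1e-12)
        assert res["fst_std"].loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_fixed_alternate_alleles_maximal(self):
        geno = np.vstack([np.zeros((5, 3)), np.full((5, 3), 2)])
        calls = _calls(geno)
        res = pairwise_fst(calls, _labels(calls, {"a": 5, "b": 5}), n_perm=0)
        assert res["fst_std"].loc["a", "b"] == pytest.approx(1.0, abs=1e-9)

    def test_monomorphic_pair_flagged(self):
        calls = _calls(np.zeros((6, 4)))
        res = pairwise_fst(calls, _labels(calls, {"a": 3, "b": 3}), n_perm=0)
        assert ("a", "b") in res["monomorphic"]
        assert np.isnan(res["fst_std"].loc["a", "b"])

    def test_single_locus_matches_hand_formulas(self):
        """p1 = 0.2, p2 = 0.8, n = 20 each: independent HS/HT/G''ST transcription."""
        g1 = np.array([2] * 4 + [0] * 16).reshape(-1, 1)  # p(alt) = 0.2
        g2 = np.array([2] * 16 + [0] * 4).reshape(-1, 1)  # p(alt) = 0.8
        calls = _calls(np.vstack([g1, g2]))
        res = pairwise_fst(calls, _labels(calls, {"a": 20, "b": 20}), n_perm=0)
        # oracle
        n = 20
        h1 = (2 * n / (2 * n - 1)) * 2 * 0.2 * 0.8
        h2 = (2 * n / (2 * n - 1)) * 2 * 0.8 * 0.2
        hs = (h1 + h2) / 2
        pbar = 0.5
        ht = 2 * pbar * (1 - pbar) + hs / (2 * n * 2)
        gst = (ht - hs) / ht
        gpp = 2 * (ht - hs) / ((2 * ht - hs) * (1 - hs))
        assert res["gst"].loc["a", "b"] == pytest.approx(gst, abs=1e-10)
        assert res["fst_std"].loc["a", "b"] == pytest.approx(gpp, abs=1e-10)

    def test_standardized_at_least_gst(self, rng):
        geno = rng.integers(0, 3, size=(24, 40)).astype(np.int8)
        geno[:8] += rng.integers(0, 2, size=(8, 40)).astype(np.int8)
        geno = np.clip(geno, 0, 2)
        calls = _calls(geno)
        res = pairwise_fst(
            calls, _labels(calls, {"a": 8, "b": 8, "c": 8}), n_perm=0
        )
        for a in "abc":
            for b in "abc":
                if a < b:
                    assert (
                        res["fst_std"].loc[a, b] >= res["gst"].loc[a, b] - 1e-12
                    )

    def test_permutation_p_small_for_strong_structure(self):
        geno = np.vstack([np.zeros((8, 10)), np.full((8, 10), 2)])
        calls = _calls(geno)
        res = pairwise_fst(calls, _labels(calls, {"a": 8, "b": 8}), n_perm=99, seed=1)
        assert res["p_value"].loc["a", "b"] == pytest.approx(1 / 100)


def _amova_oracle(geno, pop_of, group_of):
    """Independent AMOVA path: per-locus deviation-from-mean sums of squares."""
    geno = np.asarray(geno, dtype=float)
    n = geno.shape[0]
    pops = sorted(set(pop_of))
    groups = sorted(set(group_of))
    pop_of = np.asarray(pop_of, dtype=object)
    group_of = np.asarray(group_of, dtype=object)

    def ss_dev(idx):
        sub = geno[idx]
        return float(((sub - sub.mean(axis=0)) ** 2).sum())

    ss_total = ss_dev(np.arange(n))
    ss_wp = sum(ss_dev(np.nonzero(pop_of == p)[0]) for p in pops)
    ss_wg = sum(ss_dev(np.nonzero(group_of == g)[0]) for g in groups)
    ss_ap = ss_wg - ss_wp
    ss_ag = ss_total - ss_wg
    df_ag, df_ap, df_wp = len(groups) - 1, len(pops) - len(groups), n - len(pops)
    sizes = {p: int((pop_of == p).sum()) for p in pops}
    gsizes = {g: int((group_of == g).sum()) for g in groups}
    pgroup = {p: group_of[pop_of == p][0] for p in pops}
    s1 = sum(sizes[p] ** 2 / gsizes[pgroup[p]] for p in pops)
    s2 = sum(sizes[p] ** 2 for p in pops) / n
    s3 = sum(v**2 for v in gsizes.values()) / n
    n1 = (n - s1) / df_ap
    sigma_c = ss_wp / df_wp
    sigma_b = (ss_ap / df_ap - sigma_c) / n1
    if df_ag:
        n2 = (s1 - s2) / df_ag
        n3 = (n - s3) / df_ag
        sigma_a = (ss_ag / df_ag - sigma_c - n2 * sigma_b) / n3
    else:
        sigma_a = 0.0
    return sigma_a, sigma_b, sigma_c


class TestAmova:
    def test_identical_populations_near_zero_among(self, rng):
        block = rng.integers(0, 3, size=(6, 20)).astype(np.int8)
        geno = np.vstack([block, block, block])
        calls = _calls(geno)
        labels = _labels(calls, {"a": 6, "b": 6, "c": 6})
        res = amova(calls, labels, n_perm=0)
        assert res.percents["among_pops_within_groups"] == pytest.approx(0, abs=1e-9)

    def test_fixed_populations_all_variance_among(self):
        geno = np.vstack([np.zeros((6, 10)), np.full((6, 10), 2)])
        calls = _calls(geno)
        res = amova(calls, _labels(calls, {"a": 6, "b": 6}), n_perm=0)
        assert res.percents["among_pops_within_groups"] == pytest.approx(100.0)
        assert res.phi["phi_st"] == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        calls = _calls(np.ones((6, 5)))
        res = amova(calls, _labels(calls, {"a": 3, "b": 3}), n_perm=0)
        assert any("zero total variance" in w for w in res.warnings)

    def test_three_level_matches_independent_oracle(self, rng):
        """3 pops x 10 ind x 20 loci vs the deviation-SS transcription."""
        geno = rng.integers(0, 3, size=(30, 20)).astype(np.int8)
        geno[:10] = np.clip(geno[:10] + 1, 0, 2)
        calls = _calls(geno)
        grouping = {}
        for i, ind in enumerate(calls.individuals):
            pop = f"p{i // 10}"
            grp = "g0" if i < 20 else "g1"
            grouping[ind] = (grp, pop)
        res = amova(calls, grouping, n_perm=0)
        pop_of = [f"p{i // 10}" for i in range(30)]
        group_of = ["g0" if i < 20 else "g1" for i in range(30)]
        a, b, c = _amova_oracle(geno, pop_of, group_of)
        assert res.components["within_pops"] == pytest.approx(max(c, 0), abs=1e-10)
        assert res.components["among_pops_within_groups"] == pytest.approx(
            max(b, 0), abs=1e-10
        )
        assert res.components["among_groups"] == pytest.approx(max(a, 0), abs=1e-10)

    def test_percents_sum_to_hundred(self, rng):
        geno = rng.integers(0, 3, size=(18, 15)).astype(np.int8)
        calls = _calls(geno)
        res = amova(calls, _labels(calls, {"a": 6, "b": 6, "c": 6}), n_perm=0)
        assert sum(res.percents.values()) == pytest.approx(100.0, abs=0.1)


class TestPCA:
    def test_two_clusters_single_axis(self):
        geno = np.vstack([np.zeros((4, 10)), np.full((4, 10), 2)])
        coords, pct = pca_covariance(_calls(geno))
        assert pct[0] == pytest.approx(100.0)
        assert np.ptp(np.sign(coords[:4, 0])) == 0
        assert np.sign(coords[0, 0]) != np.sign(coords[-1, 0])

    def test_percent_variance_shape(self, rng):
        geno = rng.integers(0, 3, size=(10, 25)).astype(np.int8)
        _, pct = pca_covariance(_calls(geno))
        assert pct.sum() <= 100 + 1e-9
        assert (np.diff(pct) <= 1e-9).all()

    def test_matches_eigh_oracle_up_to_sign(self, rng):
        geno = rng.integers(0, 3, size=(6, 4)).astype(np.int8)
        calls = _calls(geno)
        coords, _ = pca_covariance(calls)
        x = geno - geno.mean(axis=0)
        cov = x @ x.T / 4
        vals, vecs = np.linalg.eigh(cov)
        order = np.argsort(vals)[::-1]
        expect = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0))
        for j in range(4):
            assert np.allclose(coords[:, j], expect[:, j], atol=1e-9) or np.allclose(
                coords[:, j], -expect[:, j], atol=1e-9
            )


class TestFoldedSFS:
    def test_monomorphic_all_zero(self):
        calls = _calls(np.zeros((5, 8)))
        sfs = folded_sfs(calls, _labels(calls, {"p": 5}), "p")
        assert sfs.bins.sum() == 0
        assert sfs.monomorphic_sites == 8

    def test_singleton_bin(self):
        geno = np.zeros((10, 1), dtype=np.int8)
        geno[0, 0] = 1
        calls = _calls(geno)
        sfs = folded_sfs(calls, _labels(calls, {"p": 10}), "p")
        assert sfs.bins[0] == 1 and sfs.bins[1:].sum() == 0
        assert sfs.n_alleles == 20

    def test_missing_sites_excluded_and_counted(self):
        geno = np.array([[1, -1], [0, 1], [0, 0]], dtype=np.int8)
        calls = _calls(geno)
        sfs = folded_sfs(calls, _labels(calls, {"p": 3}), "p")
        assert sfs.excluded_missing == 1
        assert sfs.bins[0] == 1

    def test_constant_ne_spectrum_matches_theory(self):
        """Folded bins within 3 SE of theta (1/i + 1/(2n-i)) per bin."""
        from lakerad.synthetic_data import (
            DemographyConfig,
            simulate_metapopulation,
            truth_genotype_calls,
        )

        ne, mu, L, n_loci, n_dip = 2000, 5e-7, 40, 8000, 5
        cfg = DemographyConfig(
            n_lakes=0, n_sea=1, ancestral_size=ne, mutation_rate=mu,
            n_loci=n_loci, locus_length=L, n_contaminant=0, n_repeat=0, seed=41,
        )
        s = simulate_metapopulation(cfg, {"sea1": n_dip})
        calls = truth_genotype_calls(s)
        labels = {i: "sea1" for i in s.individuals}
        sfs = folded_sfs(calls, labels, "sea1")
        theta_sites = 4 * ne * mu * L * n_loci
        n_all = 2 * n_dip
        for i in range(1, n_dip + 1):
            if i == n_all - i:
                expect = theta_sites / i
            else:
                expect = theta_sites * (1 / i + 1 / (n_all - i))
            se = np.sqrt(expect)  # Poisson-scale error over independent loci
            assert abs(sfs.bins[i - 1] - expect) < 3 * max(se, 1)


class TestMigrationNetwork:
    def test_symmetric_pair_both_edges_one(self):
        g1 = np.array([[0], [1], [2], [1]] * 3)
        g2 = np.array([[2], [1], [0], [1]] * 3)
        calls = _calls(np.vstack([g1, g2]))
        net = relative_migration_network(
            calls, _labels(calls, {"a": 12, "b": 12}), n_boot=0
        )
        w = net.weights.to_numpy()
        off = w[~np.eye(2, dtype=bool)]
        assert np.allclose(off, 1.0)

    def test_normalization_max_is_one(self, rng):
        geno = rng.integers(0, 3, size=(18, 30)).astype(np.int8)
        geno[:6] = np.clip(geno[:6] + 1, 0, 2)
        calls = _calls(geno)
        net = relative_migration_network(
            calls, _labels(calls, {"a": 6, "b": 6, "c": 6}), n_boot=0, threshold=0.0
        )
        assert np.nanmax(net.weights.to_numpy()) == pytest.approx(1.0)

    def test_isolated_fixed_population_loses_edges(self):
        rng = np.random.default_rng(7)
        connected1 = rng.integers(0, 3, size=(8, 40)).astype(np.int8)
        noise = (rng.random((8, 40)) < 0.1).astype(np.int8)
        connected2 = np.clip(connected1 + noise, 0, 2)
        isolated = np.tile((rng.random(40) < 0.5).astype(np.int8) * 2, (8, 1))
        calls = _calls(np.vstack([connected1, connected2, isolated]))
        net = relative_migration_network(
            calls, _labels(calls, {"a": 8, "b": 8, "iso": 8}),
            threshold=0.2, n_boot=0,
        )
        iso_edges = [e for e in net.edges if "iso" in (e[0], e[1])]
        assert iso_edges == []
        assert any({e[0], e[1]} == {"a", "b"} for e in net.edges)

    def test_three_population_toy_matches_transcription(self):
        """Directional values equal an independent transcription of the
        migrant-pool construction on a fixed frequency table."""
        freqs = {
            "a": np.array([0.1, 0.5, 0.9]),
            "b": np.array([0.2, 0.4, 0.8]),
            "c": np.array([0.9, 0.1, 0.2]),
        }
        names = ["a", "b", "c"]
        vals = _directional_values(freqs, {}, names)
        for i, x in enumerate(names):
            for j, y in enumerate(names):
                if i == j:
                    continue
                px, py = freqs[x], freqs[y]
                pool = (px + py) / 2
                hs = np.mean((2 * py * (1 - py) + 2 * pool * (1 - pool)) / 2)
                ht = np.mean(2 * ((py + pool) / 2) * (1 - (py + pool) / 2))
                gst = (ht - hs) / ht
                expect = (1 / gst - 1) / 4
                assert vals[i, j] == pytest.approx(expect, abs=1e-10)
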