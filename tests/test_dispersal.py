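import itertools

import numpy as np
import pandas as pd
import pytest

from msatpop.dispersal import (_burrows_r2_pair, _expected_r2, _ne_from_r2,
                               dispersal_chain, geo_distances, ibd_fit, ld_ne,
                               vincenty_km)
from msatpop.fstats import chord_distance
from msatpop.genotypes import SiteHierarchy
from msatpop.simulate import SimulationConfig, simulate_stepping_stone

from conftest import table_from_calls


class TestBurrows:
    def test_matches_hand_computed_composite_covariance(self):
        g1 = np.array([[1, 1], [1, 2], [2, 2], [1, 2], [1, 1], [2, 2]])
        g2 = np.array([[3, 4], [3, 3], [4, 4], [3, 4], [3, 3], [4, 4]])
        r2s, n = _burrows_r2_pair(g1, g2, pcrit=0.0)
        # hand computation for allele pair (1, 3)
        X = (g1 == 1).sum(axis=1)
        Y = (g2 == 3).sum(axis=1)
        pA, pB = X.mean() / 2, Y.mean() / 2
        delta = ((X * Y).mean() / 2 - 2 * pA * pB) * n / (n - 1)
        expect = delta ** 2 / (pA * (1 - pA) * pB * (1 - pB))
        assert n == 6
        assert r2s[0] == pytest.approx(expect, rel=1e-12)

    def test_rare_alleles_screened_by_pcrit(self):
        g1 = np.array([[1, 1]] * 19 + [[1, 2]])   # allele 2 at freq 1/40
        g2 = np.array([[3, 4]] * 20)
        r2s, _ = _burrows_r2_pair(g1, g2, pcrit=0.05)
        assert r2s == []


def test_ne_inversion_limits():
    assert np.isinf(_ne_from_r2(0.0, 50))
    assert np.isinf(_ne_from_r2(-0.01, 50))
    # stronger disequilibrium -> smaller Ne, both sample-size regimes
    for S in (20, 60):
        e = _expected_r2(S)
        nes = [_ne_from_r2(r2, S) for r2 in (0.01, 0.05, 0.2)]
        assert nes[0] > nes[1] > nes[2] > 0


def test_ld_ne_recovers_wright_fisher_truth():
    """Single panmictic deme of 50 diploids: median estimate within a
    factor two of the census/effective size."""
    nes = []
    for seed in range(10):
        cfg = SimulationConfig(seed=seed, n_per_site=50, n_loci=20)
        t, _, _ = simulate_stepping_stone(cfg, n_demes=1, migration_m=0.0,
                                          mutation_mu=5e-3, generations=100)
        nes.append(ld_ne(t, pcrit=0.05).ne)
    assert 25 <= np.median(nes) <= 100


def test_ld_ne_rejects_unusable_input():
    t = table_from_calls([[[1, 1], [2, 2]]] * 12)
    with pytest.raises(ValueError):
        ld_ne(t)


class TestGeodesics:
    def test_zero_distance_for_identical_points(self):
        assert vincenty_km(42.0, 18.0, 42.0, 18.0) == 0.0

    def test_equatorial_arc(self):
        assert vincenty_km(0, 0, 0, 1) == pytest.approx(111.3195, abs=0.01)

    @pytest.mark.parametrize("p1,p2,km", [
        # frozen from an independent WGS84 Vincenty implementation
        ((40.256415, 17.891478), (42.375633, 27.717717), 855.199481),
        ((42.331039, 27.755451), (44.5775, 35.20333333), 652.122461),
        ((40.256415, 17.891478), (40.0, 15.0), 248.079773),
    ])
    def test_matches_independent_geodesic_oracle(self, p1, p2, km):
        assert vincenty_km(*p1, *p2) == pytest.approx(km, abs=1e-4)

    def test_neighbouring_study_sites_below_ten_km(self):
        # two sampling stations on the same stretch of coast
        assert vincenty_km(42.375633, 27.717717, 42.331039, 27.755451) < 10

    def test_user_matrix_validated_and_passed_through(self):
        h = SiteHierarchy(pd.DataFrame({
            "site": ["a", "b"], "sea": "x", "basin": "x",
            "lat": [0.0, 1.0], "lon": [0.0, 1.0]}))
        m = pd.DataFrame([[0.0, 5.0], [5.0, 0.0]], index=["a", "b"],
                         columns=["a", "b"])
        out = geo_distances(h, user_matrix=m)
        assert out.loc["a", "b"] == 5.0
        bad = pd.DataFrame([[0.0, 5.0], [4.0, 0.0]], index=["a", "b"],
                           columns=["a", "b"])
        with pytest.raises(ValueError, match="symmetric"):
            geo_distances(h, user_matrix=bad)


class TestIBDFit:
    def _mats(self, gen, km, sites=None):
        sites = sites or [f"s{i}" for i in range(len(km))]
        return (pd.DataFrame(gen, index=sites, columns=sites),
                pd.DataFrame(km, index=sites, columns=sites))

    def test_exact_linear_relation_recovered_to_machine_precision(self):
        k = 6
        km = np.zeros((k, k))
        for i, j in itertools.combinations(range(k), 2):
            km[i, j] = km[j, i] = 5.0 * (1 + i + j)
        gen = np.where(km > 0, 0.05 * np.log(km, where=km > 0) + 0.2, 0.0)
        np.fill_diagonal(gen, 0)
        g, d = self._mats(gen, km)
        fit = ibd_fit(g, d, n_perm=50, seed=0)
        assert fit.slope == pytest.approx(0.05, abs=1e-12)

    def test_constant_genetic_distance_flat_and_nonsignificant(self):
        k = 5
        km = np.abs(np.subtract.outer(np.arange(k), np.arange(k))) * 10.0
        gen = np.full((k, k), 0.3)
        np.fill_diagonal(gen, 0)
        # keep off-diagonal constant: fill_diagonal already done
        g, d = self._mats(gen, km)
        fit = ibd_fit(g, d, n_perm=200, seed=1)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.mantel_p == 1.0

    def test_mantel_p_matches_exhaustive_site_permutations(self):
        rng = np.random.default_rng(4)
        k = 5
        km = np.abs(np.subtract.outer(np.arange(k), np.arange(k))) * 7.0 + \
            rng.uniform(0, 2, (k, k))
        km = (km + km.T) / 2
        np.fill_diagonal(km, 0)
        gen = rng.uniform(0, 0.5, (k, k))
        gen = (gen + gen.T) / 2
        np.fill_diagonal(gen, 0)
        g, d = self._mats(gen, km)
        iu = np.triu_indices(k, 1)
        x = np.log(km[iu])

        def slope(order):
            y = gen[np.ix_(order, order)][iu]
            return np.polyfit(x, y, 1)[0]

        obs = slope(np.arange(k))
        perms = list(itertools.permutations(range(k)))
        exact = np.mean([slope(np.array(p)) >= obs for p in perms])
        fit = ibd_fit(g, d, n_perm=20000, seed=5)
        band = 3 * np.sqrt(exact * (1 - exact) / 20000) + 1e-3
        assert abs(fit.mantel_p - exact) < band

    def test_too_few_sites_rejected(self):
        km = np.ones((3, 3)) - np.eye(3)
        g, d = self._mats(km * 0.1, km)
        with pytest.raises(ValueError):
            ibd_fit(g, d)

    def test_stepping_stone_slope_decreases_with_migration(self):
        """At quasi-equilibrium the IBD slope of linearized theta falls
        toward 0 as migration rises (bounded distances like the chord
        saturate under near-complete isolation, so the Rousset-linearized
        theta/(1-theta) is the right measure for this comparison)."""
        from msatpop.fstats import pairwise_fst
        slopes = []
        for m in (0.005, 0.05, 0.5):
            cfg = SimulationConfig(seed=2, n_per_site=40, n_loci=10)
            t, _, truth = simulate_stepping_stone(cfg, n_demes=8,
                                                  migration_m=m,
                                                  mutation_mu=1e-3,
                                                  generations=1000)
            th = pairwise_fst(t, n_perm=0).theta
            lin = th / (1 - th)
            np.fill_diagonal(lin.values, 0)
            fit = ibd_fit(lin, truth.geo_km, n_perm=10, seed=0)
            slopes.append(fit.slope)
        assert slopes[0] > slopes[1] > slopes[2]
        assert abs(slopes[2]) < 0.05


class TestDispersalChain:
    def test_adriatic_worked_example(self):
        est = dispersal_chain(0.121, Ne=78.55, K_range=(10, 100),
                              area_km2=138000.0)
        assert round(est.nb) == 8
        assert round(est.nem, 2) == 1.32
        assert round(est.delta_m[0]) == 186

    def test_black_sea_worked_example(self):
        est = dispersal_chain(0.0238, De_range=(0.014, 0.140))
        assert round(est.nb) == 42
        assert round(est.nem, 2) == 6.69
        assert round(est.delta_m[0]) == 129

    def test_algebraic_identities_exact(self):
        est = dispersal_chain(0.07, De_range=(0.01, 0.1))
        assert est.nb * 0.07 == pytest.approx(1.0, rel=1e-15)
        assert 2 * np.pi * 0.07 * est.nem == pytest.approx(1.0, rel=1e-15)

    def test_delta_monotone_in_density_and_slope(self):
        grid_de = [0.005, 0.02, 0.08]
        grid_b = [0.01, 0.05, 0.2]
        prev = None
        for de in grid_de:
            d = dispersal_chain(0.05, De_range=(de, de)).delta_m[0]
            if prev is not None:
                assert d > prev
            prev = d
        prev = None
        for b in grid_b:
            d = dispersal_chain(b, De_range=(0.02, 0.02)).delta_m[0]
            if prev is not None:
                assert d > prev
            prev = d

    def test_dimensional_variant_available(self):
        lit = dispersal_chain(0.0238, De_range=(0.014, 0.014))
        dim = dispersal_chain(0.0238, De_range=(0.014, 0.014),
                              variant="dimensional")
        assert lit.delta_m[0] != dim.delta_m[0]

    def test_nonpositive_slope_refused(self):
        with pytest.raises(ValueError, match="positive"):
            dispersal_chain(-0.01, De_range=(0.01, 0.1))

    def test_requires_exactly_one_density_route(self):
        with pytest.raises(ValueError):
            dispersal_chain(0.1)
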