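import numpy as np
import pytest
from scipy import optimize

from msatpop.fstats import (chord_distance, em_null_freq, ena_corrected_fst,
                            hierarchical_fstats, pairwise_fst, resampling_cis,
                            wc_fstats)
from msatpop.genotypes import GenotypeTable
from msatpop.simulate import SimulationConfig, simulate_hierarchical_fmodel

from conftest import table_from_calls


# ---------------------------------------------------------------------------
# Independent brute-force estimator: per-allele variance components coded
# directly from the published component formulas, plain dict/loops.
# ---------------------------------------------------------------------------

def bruteforce_wc(table, grouping=None):
    grouping = list(table.sites) if grouping is None else list(grouping)
    groups = list(dict.fromkeys(grouping))
    A = B = C = 0.0
    for j in range(table.n_loci):
        site_counts = []
        for g in groups:
            pairs = [tuple(table.alleles[i, j])
                     for i in range(table.n_individuals)
                     if grouping[i] == g and table.alleles[i, j, 0] != 0]
            if pairs:
                site_counts.append(pairs)
        r = len(site_counts)
        if r < 2:
            continue
        alleles = sorted({a for pairs in site_counts for ab in pairs for a in ab})
        ns = [len(p) for p in site_counts]
        nbar = sum(ns) / r
        nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
        for al in alleles:
            ps, hs = [], []
            for pairs in site_counts:
                n = len(pairs)
                ps.append(sum(int(a == al) + int(b == al)
                              for a, b in pairs) / (2 * n))
                hs.append(sum(1 for a, b in pairs if a != b and al in (a, b)) / n)
            pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
            s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
            hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
            a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                     - hbar / 4) / (nbar - 1))
            b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                       - (2 * nbar - 1) / (4 * nbar) * hbar)
            A, B, C = A + a, B + b, C + hbar / 2
    f = 1 - C / (B + C)
    theta = A / (A + B + C)
    F = 1 - C / (A + B + C)
    return f, theta, F


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_wc_matches_bruteforce_on_toys(seed):
    """2 sites x 6 individuals x 2 loci with missing data, to 1e-10."""
    rng = np.random.default_rng(seed)
    calls = np.sort(rng.integers(1, 5, size=(12, 2, 2)), axis=2)
    calls[rng.random((12, 2)) < 0.15] = 0
    t = table_from_calls(calls, sites=["s1"] * 6 + ["s2"] * 6)
    est = wc_fstats(t)
    f, theta, F = bruteforce_wc(t)
    assert est.f == pytest.approx(f, abs=1e-10)
    assert est.theta == pytest.approx(theta, abs=1e-10)
    assert est.Fit == pytest.approx(F, abs=1e-10)
    # algebraic identity of the summed components
    assert (1 - est.f) * (1 - est.theta) == pytest.approx(1 - est.Fit, abs=1e-12)


def test_fixed_difference_sites_theta_one_f_undefined():
    calls = [[[1, 1]]] * 10 + [[[2, 2]]] * 10
    t = table_from_calls(calls, sites=["a"] * 10 + ["b"] * 10)
    est = wc_fstats(t)
    assert est.theta == pytest.approx(1.0)
    assert np.isnan(est.f)


def test_duplicated_site_gives_near_zero_theta():
    """Identical duplicated subsamples: s^2 = 0 exactly, so theta reduces to
    the estimator's small negative finite-sample term, -O(1/n)."""
    rng = np.random.default_rng(3)
    half = np.sort(rng.integers(1, 6, size=(15, 3, 2)), axis=2)
    calls = np.concatenate([half, half])
    t = table_from_calls(calls, sites=["a"] * 15 + ["b"] * 15)
    theta = wc_fstats(t).theta
    assert theta <= 0
    assert abs(theta) < 1 / 14


def test_all_monomorphic_is_undefined():
    t = table_from_calls([[[1, 1]], [[1, 1]]], sites=["a", "b"])
    with pytest.raises(ValueError, match="monomorphic"):
        wc_fstats(t)


class TestResampling:
    def _toy(self, n_loci=5, seed=0):
        rng = np.random.default_rng(seed)
        calls = np.sort(rng.integers(1, 5, size=(30, n_loci, 2)), axis=2)
        return table_from_calls(calls, sites=["a"] * 10 + ["b"] * 10 + ["c"] * 10)

    def test_identical_loci_give_zero_width_bootstrap_ci(self):
        rng = np.random.default_rng(1)
        one = np.sort(rng.integers(1, 5, size=(30, 1, 2)), axis=2)
        calls = np.repeat(one, 4, axis=1)
        t = table_from_calls(calls, sites=["a"] * 10 + ["b"] * 10 + ["c"] * 10)
        est = resampling_cis(t, n_boot=200, seed=0)
        assert est.ci_theta[1] - est.ci_theta[0] < 1e-12
        assert est.strderr_fst < 1e-12

    def test_jackknife_se_matches_textbook_formula(self):
        t = self._toy()
        est = resampling_cis(t, n_boot=100, seed=0)
        comp = est.per_locus
        vals = []
        for j in range(5):
            keep = [k for k in range(5) if k != j]
            A = comp.loc[keep, "a"].sum()
            B = comp.loc[keep, "b"].sum()
            C = comp.loc[keep, "c"].sum()
            vals.append(A / (A + B + C))
        vals = np.array(vals)
        se = np.sqrt(4 / 5 * ((vals - vals.mean()) ** 2).sum())
        assert est.strderr_fst == pytest.approx(se, rel=1e-12)

    def test_bootstrap_ci_brackets_point_estimate(self):
        t = self._toy(seed=4)
        est = resampling_cis(t, n_boot=1000, seed=2)
        assert est.ci_theta[0] <= est.theta <= est.ci_theta[1]

    def test_deterministic_under_seed(self):
        t = self._toy(seed=5)
        a = resampling_cis(t, n_boot=200, seed=9, n_perm=50)
        b = resampling_cis(t, n_boot=200, seed=9, n_perm=50)
        assert a.ci_f == b.ci_f and a.p_theta == b.p_theta

    def test_too_few_loci_or_sites_raise(self):
        rng = np.random.default_rng(0)
        calls = np.sort(rng.integers(1, 4, size=(20, 2, 2)), axis=2)
        t = table_from_calls(calls, sites=["a"] * 10 + ["b"] * 10)
        with pytest.raises(ValueError):
            resampling_cis(t, n_boot=10)


class TestPairwise:
    def test_matrix_symmetric_zero_diagonal(self):
        cfg = SimulationConfig(seed=3, n_seas=1, sites_per_sea=3,
                               n_per_site=15, n_loci=5,
                               theta_within_sea=0.1, miss_rate=0.0)
        t, _, _ = simulate_hierarchical_fmodel(cfg)
        d = pairwise_fst(t, n_perm=0).theta.to_numpy()
        assert np.allclose(d, d.T) and np.all(np.diag(d) == 0)

    def test_fixed_difference_pair_maximally_significant(self):
        calls = [[[1, 1]] * 3] * 10 + [[[2, 2]] * 3] * 10
        t = table_from_calls(calls, sites=["a"] * 10 + ["b"] * 10)
        res = pairwise_fst(t, n_perm=200, seed=0)
        # ties possible when a permutation reproduces the exact partition
        assert res.theta_p.iloc[0, 1] <= 2 / 201

    def test_randomly_split_site_shows_no_structure(self):
        rng = np.random.default_rng(6)
        calls = np.sort(rng.integers(1, 6, size=(40, 6, 2)), axis=2)
        t = table_from_calls(calls, sites=["a"] * 20 + ["b"] * 20)
        res = pairwise_fst(t, n_perm=200, seed=1)
        assert abs(res.theta.iloc[0, 1]) < 0.05
        assert res.theta_p.iloc[0, 1] > 0.05


# ---------------------------------------------------------------------------
# Null-allele EM and ENA correction
# ---------------------------------------------------------------------------

def _em_loglik(r, p, het_counts, hom_counts, n_blanks):
    ll = n_blanks * np.log(max(r, 1e-300) ** 2)
    for (a, b), c in het_counts.items():
        ll += c * np.log(2 * p[a] * p[b])
    for a, c in hom_counts.items():
        ll += c * np.log(p[a] ** 2 + 2 * p[a] * r)
    return ll


def test_em_agrees_with_independent_direct_maximizer():
    rng = np.random.default_rng(2)
    # truth: alleles 1..3 at (0.4, 0.3, 0.1), null 0.2, HWE, n = 400
    freqs = np.array([0.4, 0.3, 0.1, 0.2])
    n = 400
    g = rng.choice(4, size=(n, 2), p=freqs)
    visible = []
    blanks = 0
    for a, b in g:
        if a == 3 and b == 3:
            blanks += 1
        elif a == 3:
            visible.append((b + 1, b + 1))
        elif b == 3:
            visible.append((a + 1, a + 1))
        else:
            visible.append((min(a, b) + 1, max(a, b) + 1))
    visible = np.array(visible)
    r_em, p_em, conv = em_null_freq(visible, blanks)
    assert conv

    het_counts, hom_counts = {}, {}
    for a, b in visible:
        if a == b:
            hom_counts[a] = hom_counts.get(a, 0) + 1
        else:
            het_counts[(a, b)] = het_counts.get((a, b), 0) + 1
    alleles = sorted(p_em)

    def neg(x):
        z = np.concatenate([x, [0.0]])
        w = np.exp(z - z.max())
        w /= w.sum()
        p = {a: w[i] for i, a in enumerate(alleles)}
        return -_em_loglik(w[-1], p, het_counts, hom_counts, blanks)

    best = None
    for s in range(4):
        x0 = rng.normal(size=len(alleles))
        res = optimize.minimize(neg, x0, method="Nelder-Mead",
                                options={"maxiter": 5000, "xatol": 1e-10,
                                         "fatol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    z = np.concatenate([best.x, [0.0]])
    w = np.exp(z - z.max())
    w /= w.sum()
    assert r_em == pytest.approx(w[-1], abs=1e-3)


def test_ena_is_noop_without_blanks_or_deficit():
    """Exact-HWE genotype counts, no blanks: null frequencies 0 and
    ENA F_ST equal to the uncorrected theta to 1e-6."""
    def hwe_site(a, b, k):
        return [[a, a]] * k + [[a, b]] * (2 * k) + [[b, b]] * k
    calls = [[g1, g2] for g1, g2 in zip(hwe_site(100, 102, 5),
                                        hwe_site(200, 202, 5))]
    calls += [[g1, g2] for g1, g2 in zip(hwe_site(104, 106, 5),
                                         hwe_site(200, 202, 5))]
    t = table_from_calls(calls, sites=["s1"] * 20 + ["s2"] * 20,
                         loci=["L1", "L2"])
    res = ena_corrected_fst(t, n_boot=50)
    assert res.null_freqs.to_numpy().max() == 0.0
    assert abs(res.fst_ena_global - res.fst_uncorrected_global) < 1e-6


def test_ena_recovers_truth_better_with_segregating_nulls():
    """Null allele drifting through the hierarchy at r = 0.2 on half the
    loci: the ENA-corrected F_ST is closer to the target than the
    uncorrected estimate (median over 10 seeds)."""
    errs_u, errs_e = [], []
    for seed in range(10):
        cfg = SimulationConfig(seed=seed, n_seas=1, sites_per_sea=8,
                               n_per_site=60, n_loci=10, alleles_per_locus=8,
                               theta_between_seas=0.0, theta_within_sea=0.2,
                               fis_target=0.0, null_freq=[0.2] * 5 + [0.0] * 5,
                               null_segregating=True, miss_rate=0.0)
        t, _, _ = simulate_hierarchical_fmodel(cfg)
        res = ena_corrected_fst(t, n_boot=10)
        errs_u.append(abs(res.fst_uncorrected_global - 0.2))
        errs_e.append(abs(res.fst_ena_global - 0.2))
    assert np.median(errs_e) < np.median(errs_u)


class TestChordDistance:
    def test_identical_sites_zero(self):
        rng = np.random.default_rng(1)
        half = np.sort(rng.integers(1, 6, size=(10, 3, 2)), axis=2)
        calls = np.concatenate([half, half])
        t = table_from_calls(calls, sites=["a"] * 10 + ["b"] * 10)
        assert chord_distance(t).iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_alleles_hit_upper_bound(self):
        calls = [[[1, 1]]] * 5 + [[[2, 2]]] * 5
        t = table_from_calls(calls, sites=["a"] * 5 + ["b"] * 5)
        assert chord_distance(t).iloc[0, 1] == pytest.approx(
            2 * np.sqrt(2) / np.pi)

    def test_symmetry_and_bounds_on_random_fixture(self, small_structured_table):
        t, _, _ = small_structured_table
        d = chord_distance(t).to_numpy()
        assert np.allclose(d, d.T) and np.all(np.diag(d) == 0)
        assert np.nanmax(d) <= 2 * np.sqrt(2) / np.pi + 1e-12

    def test_ina_variant_runs_and_stays_bounded(self, small_structured_table):
        t, _, _ = small_structured_table
        d = chord_distance(t, correction="INA").to_numpy()
        assert np.nanmax(d) <= 2 * np.sqrt(2) / np.pi + 1e-12


class TestHierarchical:
    def test_degenerate_hierarchy_collapses_to_wc(self, small_structured_table):
        import pandas as pd
        from msatpop.genotypes import SiteHierarchy
        t, h, _ = small_structured_table
        flat = SiteHierarchy(pd.DataFrame({
            "site": h.sites, "sea": "one", "basin": "one",
            "lat": 0.0, "lon": 0.0}))
        est = wc_fstats(t)
        hf = hierarchical_fstats(t, flat, n_boot=10)
        assert hf.F["site/sea"] == pytest.approx(est.theta, abs=1e-10)
        assert hf.F["individual/site"] == pytest.approx(est.f, abs=1e-10)

    def test_recovers_level_ordering(self):
        """theta between seas 0.25 vs within 0.05: sea contrast exceeds
        site contrast in >= 9/10 seeds."""
        wins = 0
        for seed in range(10):
            cfg = SimulationConfig(seed=seed, n_seas=3, sites_per_sea=3,
                                   n_per_site=20, n_loci=10,
                                   alleles_per_locus=8,
                                   theta_between_seas=0.25,
                                   theta_within_sea=0.05,
                                   fis_target=0.0, miss_rate=0.0)
            t, h, _ = simulate_hierarchical_fmodel(cfg)
            hf = hierarchical_fstats(t, h, n_boot=0)
            wins += hf.F["sea/basin"] > hf.F["site/sea"]
        assert wins >= 9


def test_wahlund_pooling_raises_f():
    """Pooling differentiated sites inflates the heterozygote deficit."""
    hits = 0
    for seed in range(10):
        cfg = SimulationConfig(seed=seed, n_seas=1, sites_per_sea=4,
                               n_per_site=30, n_loci=8, alleles_per_locus=8,
                               theta_between_seas=0.0, theta_within_sea=0.12,
                               fis_target=0.0, miss_rate=0.0)
        t, _, _ = simulate_hierarchical_fmodel(cfg)
        f_sep = wc_fstats(t).f
        pooled = ["p1" if s.endswith(("1", "2")) else "p2" for s in t.sites]
        f_pool = wc_fstats(t, pooled).f
        hits += f_pool > f_sep
    assert hits >= 9
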