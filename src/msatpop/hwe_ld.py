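"""Hardy–Weinberg U tests, G-based linkage-disequilibrium tests and
Benjamini–Yekutieli FDR adjustment.

The U test for heterozygote deficiency (or excess) is a score test: the
statistic sums, over the tested loci and sites, the gap between the
unbiased Hardy–Weinberg expectation of the heterozygote count and the
observed count.  Its null distribution is built by Monte-Carlo
randomization of allele copies among individuals within each site — the
same exact null the Markov-chain implementations target — with +1-smoothed
p-values so p is never 0.

The LD test sums a G log-likelihood statistic on the two-locus genotype
contingency table over sites and permutes single-locus genotypes among
individuals within sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .genotypes import GenotypeTable

__all__ = ["TestResult", "hw_u_test", "ld_gtest", "by_fdr"]


@dataclass
class TestResult:
    statistic: float
    p: float
    direction: str           # deficit | excess | two-sided
    scope: str               # e.g. "global", "site:x", "locus:y"
    n_perm: int
    adjusted_p: float | None = None
    applicable: bool = True


def _unit_expected_het(calls: np.ndarray) -> float:
    """Unbiased HWE expectation of the heterozygote count for one
    site x locus unit (Levene correction 2n/(2n-1))."""
    n = len(calls)
    copies = calls.ravel()
    vals, counts = np.unique(copies, return_counts=True)
    p = counts / counts.sum()
    return n * (1 - (p ** 2).sum()) * (2 * n) / (2 * n - 1)


def _collect_units(table: GenotypeTable, scope: str):
    """Yield (scope label, list of call arrays) where each call array is the
    typed genotypes of one site x locus cell inside the scope."""
    sarr = np.asarray(table.sites)
    sites = table.site_labels()

    def cell(site, j):
        rows = sarr == site
        cc = table.alleles[rows, j, :]
        return cc[cc[:, 0] != 0]

    if scope == "global":
        yield "global", [(s, j) for s in sites for j in range(table.n_loci)]
    elif scope == "site":
        for s in sites:
            yield f"site:{s}", [(s, j) for j in range(table.n_loci)]
    elif scope == "locus":
        for j, name in enumerate(table.loci):
            yield f"locus:{name}", [(s, j) for s in sites]
    elif scope == "cell":
        for s in sites:
            for j, name in enumerate(table.loci):
                yield f"site:{s}/locus:{name}", [(s, j)]
    else:
        raise ValueError("scope must be global, site, locus or cell")


def hw_u_test(table: GenotypeTable, scope: str = "global",
              direction: str = "deficit", n_perm: int = 10000,
              seed: int = 0) -> list[TestResult]:
    """U score test for heterozygote deficiency/excess.

    ``scope`` pools site x locus cells globally, per site, per locus or per
    cell.  Cells need at least 5 typed individuals and 2 alleles to enter;
    a scope with no usable cell is reported inapplicable.  The statistic is
    U = sum over cells of (expected het count - observed het count); for
    the deficit direction large U is extreme.
    """
    if direction not in ("deficit", "excess"):
        raise ValueError("direction must be 'deficit' or 'excess'")
    rng = np.random.default_rng(seed)
    sarr = np.asarray(table.sites)
    results = []
    for label, cells in _collect_units(table, scope):
        usable = []
        for site, j in cells:
            rows = sarr == site
            cc = table.alleles[rows, j, :]
            cc = cc[cc[:, 0] != 0]
            if len(cc) >= 5 and len(np.unique(cc)) >= 2:
                usable.append(cc)
        if not usable:
            results.append(TestResult(np.nan, np.nan, direction, label,
                                      n_perm, applicable=False))
            continue
        exp = np.array([_unit_expected_het(cc) for cc in usable])
        obs_het = np.array([float((cc[:, 0] != cc[:, 1]).sum()) for cc in usable])
        u_obs = float((exp - obs_het).sum())
        hits = 0
        for _ in range(n_perm):
            u = 0.0
            for cc, e in zip(usable, exp):
                pool = rng.permutation(cc.ravel()).reshape(-1, 2)
                u += e - float((pool[:, 0] != pool[:, 1]).sum())
            if direction == "deficit":
                hits += u >= u_obs
            else:
                hits += u <= u_obs
        p = (hits + 1) / (n_perm + 1)
        results.append(TestResult(u_obs, p, direction, label, n_perm))
    return results


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------

def _geno_codes(calls: np.ndarray) -> np.ndarray:
    """Map diploid genotypes (sorted pairs) to integer categories."""
    combo = calls[:, 0].astype(np.int64) * 100000 + calls[:, 1]
    _, codes = np.unique(combo, return_inverse=True)
    return codes


def _g_from_codes(c1: np.ndarray, c2: np.ndarray) -> float:
    k1 = c1.max() + 1
    k2 = c2.max() + 1
    tab = np.zeros((k1, k2))
    np.add.at(tab, (c1, c2), 1.0)
    total = tab.sum()
    exp = tab.sum(1, keepdims=True) * tab.sum(0, keepdims=True) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(tab > 0, tab * np.log(tab / exp), 0.0)
    return float(2 * term.sum())


def ld_gtest(table: GenotypeTable, locus_pair: tuple[str, str],
             n_perm: int = 10000, seed: int = 0) -> TestResult:
    """G-based linkage-disequilibrium test for one locus pair, combined
    over sites.

    Within each site the G statistic is computed on the contingency table of
    single-locus genotypes; the overall statistic is the sum over sites, and
    the null permutes the second locus's genotypes among individuals within
    sites.
    """
    j1 = table.loci.index(locus_pair[0])
    j2 = table.loci.index(locus_pair[1])
    sarr = np.asarray(table.sites)
    rng = np.random.default_rng(seed)
    site_data = []
    for site in table.site_labels():
        rows = sarr == site
        g1 = table.alleles[rows, j1, :]
        g2 = table.alleles[rows, j2, :]
        ok = (g1[:, 0] != 0) & (g2[:, 0] != 0)
        if ok.sum() < 2:
            continue
        c1 = _geno_codes(g1[ok])
        c2 = _geno_codes(g2[ok])
        if c1.max() == 0 or c2.max() == 0:
            continue  # fewer than 2 distinct genotypes at a locus
        site_data.append((c1, c2))
    label = f"{locus_pair[0]}x{locus_pair[1]}"
    if not site_data:
        return TestResult(np.nan, np.nan, "two-sided", label, n_perm,
                          applicable=False)
    obs = sum(_g_from_codes(c1, c2) for c1, c2 in site_data)
    hits = 0
    for _ in range(n_perm):
        stat = sum(_g_from_codes(c1, rng.permutation(c2)) for c1, c2 in site_data)
        hits += stat >= obs
    p = (hits + 1) / (n_perm + 1)
    return TestResult(float(obs), p, "two-sided", label, n_perm)


def all_pairs_ld(table: GenotypeTable, n_perm: int = 10000, seed: int = 0,
                 fdr: bool = True) -> list[TestResult]:
    """LD G-tests for every unordered locus pair, with optional B-Y FDR."""
    results = []
    pairs = [
        (a, b) for i, a in enumerate(table.loci) for b in table.loci[i + 1:]
    ]
    for k, pair in enumerate(pairs):
        results.append(ld_gtest(table, pair, n_perm=n_perm, seed=seed + k))
    if fdr:
        ok = [r for r in results if r.applicable]
        if ok:
            adj = by_fdr(np.array([r.p for r in ok]))
            for r, a in zip(ok, adj):
                r.adjusted_p = float(a)
    return results


def by_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Yekutieli step-up adjusted p-values (valid under arbitrary
    dependence): adjusted_(i) = min_{j>=i} min(1, p_(j) * m * c(m) / j) with
    c(m) the m-th harmonic number."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_by")[1]
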