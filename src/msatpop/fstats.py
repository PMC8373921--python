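"""Weir–Cockerham F-statistics and genetic distance matrices.

Implements the classical variance-component estimators f (F_IS), theta
(F_ST) and F (F_IT): per-allele components a (among subsamples),
b (among individuals within subsamples) and c (within individuals) are
computed per locus and summed over alleles and loci before the ratios are
formed (the Fstat weighting — never means of per-locus ratios).  Estimates
may be negative and are reported as-is.

Also here: jackknife/bootstrap resampling, permutation tests, pairwise
theta with G-based exact-style tests, EM estimation of null-allele
frequencies from apparent homozygote excess and blanks, the ENA-corrected
F_ST of the FreeNA approach, Cavalli-Sforza & Edwards chord distances, and
hierarchical F-statistics on a basin/sea/site nesting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable

__all__ = [
    "FStatEstimate",
    "HierarchicalFResult",
    "DistanceMatrices",
    "wc_fstats",
    "resampling_cis",
    "pairwise_fst",
    "ena_corrected_fst",
    "chord_distance",
    "hierarchical_fstats",
    "em_null_freq",
]


# ---------------------------------------------------------------------------
# Per-locus site summaries
# ---------------------------------------------------------------------------

@dataclass
class _LocusSiteStats:
    """Per-site allele summaries for one locus.

    alleles : sorted allele codes observed anywhere at the locus
    n       : typed individuals per site
    blanks  : untyped individuals per site
    p       : (n_sites, n_alleles) visible allele frequencies among typed
    h       : (n_sites, n_alleles) proportion of typed individuals that are
              heterozygous *and* carry the allele
    """

    alleles: np.ndarray
    n: np.ndarray
    blanks: np.ndarray
    p: np.ndarray
    h: np.ndarray


def _locus_site_stats(table: GenotypeTable, grouping: list[str]) -> list[_LocusSiteStats]:
    groups = list(dict.fromkeys(grouping))
    gidx_map = {g: i for i, g in enumerate(groups)}
    gidx = np.array([gidx_map[g] for g in grouping])
    G = len(groups)
    out: list[_LocusSiteStats] = []
    for j in range(table.n_loci):
        calls = table.alleles[:, j, :]
        typed = calls[:, 0] != 0
        alleles = np.unique(calls[typed])
        K = len(alleles)
        n = np.bincount(gidx[typed], minlength=G).astype(float)
        blanks = np.bincount(gidx[~typed], minlength=G).astype(float)
        p = np.zeros((G, K))
        h = np.zeros((G, K))
        if K:
            cc = calls[typed]
            gg = gidx[typed]
            a_idx = np.searchsorted(alleles, cc)        # (n_typed, 2)
            np.add.at(p, (gg, a_idx[:, 0]), 1.0)
            np.add.at(p, (gg, a_idx[:, 1]), 1.0)
            het = cc[:, 0] != cc[:, 1]
            np.add.at(h, (gg[het], a_idx[het, 0]), 1.0)
            np.add.at(h, (gg[het], a_idx[het, 1]), 1.0)
            nz = n > 0
            p[nz] /= (2 * n[nz])[:, None]
            h[nz] /= n[nz][:, None]
        out.append(_LocusSiteStats(alleles=alleles, n=n, blanks=blanks, p=p, h=h))
    return out


def _wc_components(n: np.ndarray, p: np.ndarray, h: np.ndarray) -> tuple[float, float, float]:
    """Summed-over-alleles Weir–Cockerham components (a, b, c) for one locus.

    ``n`` is typed sample size per subsample; ``p``/``h`` are per-subsample
    allele frequencies and allele-specific heterozygote proportions.
    Subsamples with n == 0 must already be excluded.
    """
    r = len(n)
    if r < 2:
        return 0.0, 0.0, 0.0
    nbar = n.mean()
    if nbar <= 1:
        return 0.0, 0.0, 0.0
    nc = (r * nbar - (n ** 2).sum() / (r * nbar)) / (r - 1)
    A = B = C = 0.0
    for k in range(p.shape[1]):
        pk = p[:, k]
        hk = h[:, k]
        pbar = (n * pk).sum() / (r * nbar)
        s2 = (n * (pk - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n * hk).sum() / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        A += a
        B += b
        C += c
    return A, B, C


def _ratios(A: float, B: float, C: float) -> tuple[float, float, float]:
    """(f, theta, F) from summed components; nan where undefined."""
    with np.errstate(invalid="ignore", divide="ignore"):
        f = 1 - C / (B + C) if (B + C) != 0 else np.nan
        theta = A / (A + B + C) if (A + B + C) != 0 else np.nan
        F = 1 - C / (A + B + C) if (A + B + C) != 0 else np.nan
    return f, theta, F


@dataclass
class FStatEstimate:
    """Point estimates plus (optionally) resampling uncertainty."""

    per_locus: pd.DataFrame          # locus, a, b, c, f, theta, Fit
    f: float
    theta: float
    Fit: float
    strderr_fis: float | None = None     # jackknife over loci
    strderr_fst: float | None = None
    ci_f: tuple[float, float] | None = None        # bootstrap over loci
    ci_theta: tuple[float, float] | None = None
    ci_Fit: tuple[float, float] | None = None
    jackknife_subsamples: pd.DataFrame | None = None  # per-locus SEs
    p_f: float | None = None         # permutation p-values
    p_theta: float | None = None


def _locus_components(table: GenotypeTable, grouping: list[str]) -> pd.DataFrame:
    stats = _locus_site_stats(table, grouping)
    rows = []
    for locus, st in zip(table.loci, stats):
        keep = st.n > 0
        A, B, C = _wc_components(st.n[keep], st.p[keep], st.h[keep])
        f, theta, F = _ratios(A, B, C)
        rows.append((locus, A, B, C, f, theta, F))
    return pd.DataFrame(rows, columns=["locus", "a", "b", "c", "f", "theta", "Fit"])


def wc_fstats(table: GenotypeTable, grouping: list[str] | None = None) -> FStatEstimate:
    """Weir–Cockerham f, theta and F, per locus and multilocus.

    Monomorphic loci contribute zero components (and so drop out of the
    ratios); if every locus is monomorphic the statistics are undefined.
    """
    grouping = list(table.sites) if grouping is None else list(grouping)
    per_locus = _locus_components(table, grouping)
    A, B, C = per_locus["a"].sum(), per_locus["b"].sum(), per_locus["c"].sum()
    if A == 0 and B == 0 and C == 0:
        raise ValueError("all loci monomorphic: F-statistics undefined")
    f, theta, F = _ratios(A, B, C)
    return FStatEstimate(per_locus=per_locus, f=f, theta=theta, Fit=F)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def _jackknife_se(values: np.ndarray) -> float:
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    g = len(v)
    if g < 2:
        return np.nan
    return float(np.sqrt((g - 1) / g * ((v - v.mean()) ** 2).sum()))


def resampling_cis(
    table: GenotypeTable,
    grouping: list[str] | None = None,
    n_boot: int = 5000,
    seed: int = 0,
    n_perm: int = 0,
) -> FStatEstimate:
    """Fill an :class:`FStatEstimate` with resampling uncertainty.

    * jackknife over subsamples -> per-locus SEs of f and theta
    * jackknife over loci -> multilocus StrdErrFIS / StrdErrFST
    * percentile bootstrap over loci -> 95% CIs of multilocus f, theta, F
    * optional permutation tests (``n_perm`` > 0): theta by permuting
      individuals among subsamples, f by permuting alleles within them.
    """
    grouping = list(table.sites) if grouping is None else list(grouping)
    est = wc_fstats(table, grouping)
    comp = est.per_locus
    L = len(comp)
    groups = list(dict.fromkeys(grouping))
    if L < 3:
        raise ValueError("need >= 3 loci for bootstrap over loci")
    if len(groups) < 3:
        raise ValueError("need >= 3 subsamples for jackknife over subsamples")

    # jackknife over loci (multilocus)
    A, B, C = comp["a"].to_numpy(), comp["b"].to_numpy(), comp["c"].to_numpy()
    fs, ths = [], []
    for j in range(L):
        m = np.arange(L) != j
        f_j, th_j, _ = _ratios(A[m].sum(), B[m].sum(), C[m].sum())
        fs.append(f_j)
        ths.append(th_j)
    est.strderr_fis = _jackknife_se(np.array(fs))
    est.strderr_fst = _jackknife_se(np.array(ths))

    # jackknife over subsamples, per locus
    garr = np.asarray(grouping)
    rows = []
    for locus in table.loci:
        j = table.loci.index(locus)
        sub = GenotypeTable(table.ids, table.sites, [locus],
                            table.alleles[:, [j], :], table.provenance)
        fvals, tvals = [], []
        for g in groups:
            keep = garr != g
            try:
                e = wc_fstats(sub.subset(keep), list(garr[keep]))
                fvals.append(e.f)
                tvals.append(e.theta)
            except ValueError:
                fvals.append(np.nan)
                tvals.append(np.nan)
        rows.append((locus, _jackknife_se(np.array(fvals)), _jackknife_se(np.array(tvals))))
    est.jackknife_subsamples = pd.DataFrame(rows, columns=["locus", "se_f", "se_theta"])

    # bootstrap over loci
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, L, size=(n_boot, L))
    bf = np.empty(n_boot)
    bt = np.empty(n_boot)
    bF = np.empty(n_boot)
    for i in range(n_boot):
        s = idx[i]
        bf[i], bt[i], bF[i] = _ratios(A[s].sum(), B[s].sum(), C[s].sum())
    est.ci_f = tuple(np.nanpercentile(bf, [2.5, 97.5]))
    est.ci_theta = tuple(np.nanpercentile(bt, [2.5, 97.5]))
    est.ci_Fit = tuple(np.nanpercentile(bF, [2.5, 97.5]))

    if n_perm > 0:
        est.p_theta = _perm_theta(table, grouping, est.theta, n_perm, rng)
        est.p_f = _perm_f(table, grouping, est.f, n_perm, rng)
    return est


def _perm_theta(table, grouping, observed, n_perm, rng) -> float:
    garr = np.asarray(grouping)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(garr)
        try:
            e = wc_fstats(table, list(perm))
        except ValueError:
            continue
        if e.theta >= observed:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def _perm_f(table, grouping, observed, n_perm, rng) -> float:
    """One-sided test for heterozygote deficit (f > 0): reshuffle allele
    copies among individuals within each subsample."""
    garr = np.asarray(grouping)
    groups = list(dict.fromkeys(grouping))
    hits = 0
    base = table.alleles
    for _ in range(n_perm):
        alle = base.copy()
        for g in groups:
            rows = np.flatnonzero(garr == g)
            for j in range(table.n_loci):
                typed = alle[rows, j, 0] != 0
                tr = rows[typed]
                if len(tr) < 2:
                    continue
                pool = alle[tr, j, :].ravel()
                pool = rng.permutation(pool)
                alle[tr, j, :] = pool.reshape(-1, 2)
        try:
            e = wc_fstats(
                GenotypeTable(table.ids, table.sites, table.loci, alle), grouping
            )
        except ValueError:
            continue
        if e.f >= observed:
            hits += 1
    return (hits + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Pairwise theta and G-based differentiation tests
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrices:
    sites: list[str]
    theta: pd.DataFrame | None = None
    theta_p: pd.DataFrame | None = None
    fst_ena_global: float | None = None
    fst_uncorrected_global: float | None = None
    ci_ena: tuple[float, float] | None = None
    null_freqs: pd.DataFrame | None = None   # site x locus EM estimates
    chord: pd.DataFrame | None = None


def _g_statistic(counts: np.ndarray) -> float:
    """G log-likelihood-ratio statistic for an r x c contingency table."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        return 0.0
    exp = counts.sum(axis=1, keepdims=True) * counts.sum(axis=0, keepdims=True) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(counts > 0, counts * np.log(counts / exp), 0.0)
    return float(2 * term.sum())


def _pair_g(table: GenotypeTable, rows_a: np.ndarray, rows_b: np.ndarray) -> float:
    """Summed-over-loci G on site x allele count tables for two sites."""
    g = 0.0
    for j in range(table.n_loci):
        counts = {}
        for rows, side in ((rows_a, 0), (rows_b, 1)):
            calls = table.alleles[rows, j, :]
            calls = calls[calls[:, 0] != 0]
            for a in calls.ravel():
                counts.setdefault(a, [0, 0])[side] += 1
        if len(counts) < 2:
            continue
        g += _g_statistic(np.array(list(counts.values())))
    return g


def pairwise_fst(table: GenotypeTable, n_perm: int = 1000, seed: int = 0) -> DistanceMatrices:
    """Pairwise Weir–Cockerham theta with G-based permutation significance.

    The test statistic is the G statistic on allele counts summed over loci;
    the null permutes individuals between the two sites.
    """
    sites = table.site_labels()
    k = len(sites)
    if k < 2:
        raise ValueError("need >= 2 sites")
    theta = np.zeros((k, k))
    pmat = np.full((k, k), np.nan)
    rng = np.random.default_rng(seed)
    sarr = np.asarray(table.sites)
    for i in range(k):
        for j in range(i + 1, k):
            rows_i = np.flatnonzero(sarr == sites[i])
            rows_j = np.flatnonzero(sarr == sites[j])
            if len(rows_i) < 2 or len(rows_j) < 2:
                theta[i, j] = theta[j, i] = np.nan
                continue
            keep = np.concatenate([rows_i, rows_j])
            sub = table.subset(np.isin(np.arange(table.n_individuals), keep))
            try:
                theta[i, j] = theta[j, i] = wc_fstats(sub).theta
            except ValueError:
                theta[i, j] = theta[j, i] = np.nan
                continue
            if n_perm > 0:
                ra = np.arange(len(rows_i))
                all_rows = np.arange(sub.n_individuals)
                obs = _pair_g(sub, ra, np.setdiff1d(all_rows, ra))
                hits = 0
                for _ in range(n_perm):
                    perm = rng.permutation(all_rows)
                    if _pair_g(sub, perm[: len(rows_i)], perm[len(rows_i):]) >= obs:
                        hits += 1
                pmat[i, j] = pmat[j, i] = (hits + 1) / (n_perm + 1)
    return DistanceMatrices(
        sites=sites,
        theta=pd.DataFrame(theta, index=sites, columns=sites),
        theta_p=pd.DataFrame(pmat, index=sites, columns=sites),
    )


# ---------------------------------------------------------------------------
# Null alleles: EM and the ENA-corrected F_ST
# ---------------------------------------------------------------------------

def em_null_freq(
    genotypes: np.ndarray,
    n_blanks: int,
    tol: float = 1e-9,
    max_iter: int = 2000,
) -> tuple[float, dict[int, float], bool]:
    """EM estimate of the null-allele frequency at one locus in one site.

    ``genotypes`` is an (n_typed, 2) array of visible calls.  Blanks are
    treated as candidate null homozygotes.  Under the model, allele
    frequencies (visible alleles plus one null allele) follow HWE; an
    apparent homozygote a/a is either a true a/a or a/null.

    Returns (null frequency, visible allele frequencies summing to
    1 - null frequency, converged flag).
    """
    genotypes = np.asarray(genotypes)
    n = len(genotypes) + n_blanks
    if n == 0:
        raise ValueError("no data")
    alleles = np.unique(genotypes) if len(genotypes) else np.array([], dtype=int)
    K = len(alleles)
    aidx = {a: k for k, a in enumerate(alleles)}
    het_counts = np.zeros(K)
    hom_counts = np.zeros(K)
    for a, b in genotypes:
        if a == b:
            hom_counts[aidx[a]] += 1
        else:
            het_counts[aidx[a]] += 1
            het_counts[aidx[b]] += 1
    raw = het_counts + 2 * hom_counts
    obs_p = raw / raw.sum() if K and raw.sum() else np.zeros(K)
    # boundary shortcut: with no blanks and no homozygote excess the
    # likelihood is maximized at r = 0 (EM only creeps to that boundary)
    if n_blanks == 0 and K:
        n_typed = len(genotypes)
        exp_hom = n_typed * (obs_p ** 2).sum()
        if hom_counts.sum() <= exp_hom + 1e-9:
            return 0.0, {int(a): float(obs_p[k]) for k, a in enumerate(alleles)}, True
    # init: visible frequencies scaled by an initial null guess
    r = max(np.sqrt(n_blanks / n), 1e-3)
    p = obs_p * (1 - r) if K and raw.sum() else np.full(K, (1 - r) / K)
    converged = False
    for _ in range(max_iter):
        # E-step: expected allele-copy counts
        copies = het_counts.copy()
        null_copies = 2.0 * n_blanks
        with np.errstate(divide="ignore", invalid="ignore"):
            w_true = np.where(p > 0, p ** 2 / (p ** 2 + 2 * p * r), 1.0)
        copies += hom_counts * (2 * w_true + (1 - w_true))
        null_copies += (hom_counts * (1 - w_true)).sum()
        new_p = copies / (2 * n)
        new_r = null_copies / (2 * n)
        if abs(new_r - r) + np.abs(new_p - p).sum() < tol:
            p, r = new_p, new_r
            converged = True
            break
        p, r = new_p, new_r
    return float(r), {int(a): float(p[k]) for k, a in enumerate(alleles)}, converged


def estimate_null_matrix(table: GenotypeTable, grouping: list[str] | None = None) -> pd.DataFrame:
    """EM null-allele frequency for every site x locus cell."""
    grouping = list(table.sites) if grouping is None else list(grouping)
    groups = list(dict.fromkeys(grouping))
    garr = np.asarray(grouping)
    out = np.zeros((len(groups), table.n_loci))
    for gi, g in enumerate(groups):
        rows = garr == g
        for j in range(table.n_loci):
            calls = table.alleles[rows, j, :]
            typed = calls[calls[:, 0] != 0]
            blanks = int((calls[:, 0] == 0).sum())
            if len(typed) + blanks == 0:
                out[gi, j] = np.nan
                continue
            r, _, _ = em_null_freq(typed, blanks)
            out[gi, j] = r
    return pd.DataFrame(out, index=groups, columns=table.loci)


def _ena_locus_components(table, garr, groups, j) -> tuple[float, float, float]:
    """WC components at locus j with EM-corrected visible frequencies
    (null allele excluded from the summation, FreeNA's ENA approach).

    The corrected per-site frequency of a visible allele lives on the full
    simplex (visible alleles sum to 1 - r); the per-allele heterozygote
    proportion is completed for the visible/null heterozygotes miscalled as
    homozygotes: h_true = h_obs (1 - r^2) + 2 p r.  With r = 0 both reduce
    to the observed quantities, so the correction is then an exact no-op.
    """
    calls = table.alleles[:, j, :]
    alleles = np.unique(calls[calls[:, 0] != 0])
    aidx = {a: k for k, a in enumerate(alleles)}
    K = len(alleles)
    ns, ps, hs = [], [], []
    for g in groups:
        rows = garr == g
        cc = calls[rows]
        typed = cc[cc[:, 0] != 0]
        blanks = int((cc[:, 0] == 0).sum())
        if len(typed) == 0:
            continue
        r, freqs, _ = em_null_freq(typed, blanks)
        p = np.zeros(K)
        for a, v in freqs.items():
            p[aidx[a]] = v
        h_obs = np.zeros(K)
        for a, b in typed:
            if a != b:
                h_obs[aidx[a]] += 1
                h_obs[aidx[b]] += 1
        h_obs /= len(typed)
        h = h_obs * (1 - r ** 2) + 2 * p * r
        ns.append(len(typed) + blanks)
        ps.append(p)
        hs.append(np.minimum(h, 1.0))
    if len(ns) < 2:
        return 0.0, 0.0, 0.0
    return _wc_components(np.array(ns, dtype=float), np.array(ps), np.array(hs))


def ena_corrected_fst(
    table: GenotypeTable,
    grouping: list[str] | None = None,
    n_boot: int = 5000,
    seed: int = 0,
) -> DistanceMatrices:
    """Global F_ST excluding null alleles (ENA), with bootstrap-over-loci CI.

    Per site x locus the null frequency is estimated by EM (blanks treated
    as candidate null homozygotes); theta is then recomputed from the
    corrected visible-allele frequencies.  With no blanks and no
    heterozygote deficit the correction is a no-op.
    """
    grouping = list(table.sites) if grouping is None else list(grouping)
    groups = list(dict.fromkeys(grouping))
    garr = np.asarray(grouping)
    comps = np.array([
        _ena_locus_components(table, garr, groups, j) for j in range(table.n_loci)
    ])
    A, B, C = comps.sum(axis=0)
    _, theta_ena, _ = _ratios(A, B, C)
    uncorrected = wc_fstats(table, grouping).theta
    rng = np.random.default_rng(seed)
    L = len(comps)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        s = rng.integers(0, L, size=L)
        _, boots[i], _ = _ratios(*comps[s].sum(axis=0))
    ci = tuple(np.nanpercentile(boots, [2.5, 97.5]))
    return DistanceMatrices(
        sites=groups,
        fst_ena_global=float(theta_ena),
        fst_uncorrected_global=float(uncorrected),
        ci_ena=ci,
        null_freqs=estimate_null_matrix(table, grouping),
    )


# ---------------------------------------------------------------------------
# Chord distance
# ---------------------------------------------------------------------------

def chord_distance(table: GenotypeTable, correction: str = "none") -> pd.DataFrame:
    """Cavalli-Sforza & Edwards chord distance matrix between sites.

    Per locus ``D = (2/pi) * sqrt(2 * (1 - sum_a sqrt(p_a q_a)))``, averaged
    over loci typed in both sites.  ``correction="INA"`` includes the
    EM-estimated null allele as an additional allele with its corrected
    frequency.
    """
    if correction not in ("none", "INA"):
        raise ValueError("correction must be 'none' or 'INA'")
    sites = table.site_labels()
    sarr = np.asarray(table.sites)
    k = len(sites)
    # per site x locus frequency dictionaries
    freqs: list[list[dict[int, float] | None]] = []
    for g in sites:
        rows = sarr == g
        per_locus = []
        for j in range(table.n_loci):
            cc = table.alleles[rows, j, :]
            typed = cc[cc[:, 0] != 0]
            blanks = int((cc[:, 0] == 0).sum())
            if len(typed) == 0:
                per_locus.append(None)
                continue
            if correction == "INA":
                r, f, _ = em_null_freq(typed, blanks)
                f = dict(f)
                f[-1] = r  # null coded as pseudo-allele -1
            else:
                vals, counts = np.unique(typed.ravel(), return_counts=True)
                f = {int(a): c / counts.sum() for a, c in zip(vals, counts)}
            per_locus.append(f)
        freqs.append(per_locus)
    D = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            ds = []
            for l in range(table.n_loci):
                fi, fj = freqs[i][l], freqs[j][l]
                if fi is None or fj is None:
                    continue
                s = sum(np.sqrt(fi[a] * fj[a]) for a in set(fi) & set(fj))
                ds.append((2 / np.pi) * np.sqrt(max(2 * (1 - s), 0.0)))
            D[i, j] = D[j, i] = np.mean(ds) if ds else np.nan
    return pd.DataFrame(D, index=sites, columns=sites)


# ---------------------------------------------------------------------------
# Hierarchical F-statistics (nested random-effects ANOVA on allele indicators)
# ---------------------------------------------------------------------------

@dataclass
class HierarchicalFResult:
    levels: list[str]                       # e.g. basin, sea, site, individual
    components: pd.DataFrame                # per locus: variance components
    F: dict[str, float] = field(default_factory=dict)
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)


def _nested_components(y: np.ndarray, labels: list[np.ndarray]) -> np.ndarray:
    """Moment estimators of variance components in an unbalanced fully
    nested design.

    ``y`` is the observation vector (allele indicators over gene copies) and
    ``labels`` the nested grouping factors from outermost to innermost; the
    residual (within innermost group) component is appended last.  Solves
    the expected-mean-square equations with Searle's coefficients for
    unbalanced nested classifications.
    """
    L = len(labels)
    N = len(y)
    # composite keys so that equal labels under different parents stay distinct
    keys: list[np.ndarray] = []
    comp: np.ndarray | None = None
    for lab in labels:
        lab = np.asarray(lab).astype(str)
        comp = lab if comp is None else np.char.add(np.char.add(comp, "|"), lab)
        keys.append(comp)

    inv_list, cnt_list, mean_list = [], [], []
    for k in keys:
        _, inv, cnt = np.unique(k, return_inverse=True, return_counts=True)
        inv_list.append(inv)
        cnt_list.append(cnt.astype(float))
        mean_list.append(np.bincount(inv, weights=y) / cnt)

    grand = y.mean()
    SS = np.zeros(L + 1)
    df = np.zeros(L + 1)
    prev_obs_mean = np.full(N, grand)
    prev_units = 1
    for u in range(L):
        obs_mean = mean_list[u][inv_list[u]]
        SS[u] = ((obs_mean - prev_obs_mean) ** 2).sum()
        df[u] = len(cnt_list[u]) - prev_units
        prev_obs_mean = obs_mean
        prev_units = len(cnt_list[u])
    SS[L] = ((y - prev_obs_mean) ** 2).sum()
    df[L] = N - prev_units

    def T(v: int, w: int) -> float:
        """sum over level-v units of (sum of squared sizes of the level-w
        units inside) / unit size; v = -1 means the total."""
        wcnt = cnt_list[w]
        if v == -1:
            return float((wcnt ** 2).sum() / N)
        # parent v-unit of each w-unit (nested: well defined)
        parent = np.zeros(len(wcnt), dtype=int)
        seen = np.zeros(len(wcnt), dtype=bool)
        for obs_idx in range(N):
            wu = inv_list[w][obs_idx]
            if not seen[wu]:
                parent[wu] = inv_list[v][obs_idx]
                seen[wu] = True
        num = np.bincount(parent, weights=wcnt ** 2, minlength=len(cnt_list[v]))
        return float((num / cnt_list[v]).sum())

    Cmat = np.zeros((L + 1, L + 1))
    for u in range(L):
        if df[u] <= 0:
            continue
        for w in range(u, L):
            Cmat[u, w] = (T(u, w) - T(u - 1, w)) / df[u]
        Cmat[u, L] = 1.0
    Cmat[L, L] = 1.0

    with np.errstate(invalid="ignore", divide="ignore"):
        MS = np.where(df > 0, SS / np.where(df > 0, df, 1.0), np.nan)
    sigma = np.zeros(L + 1)
    sigma[L] = MS[L] if df[L] > 0 else 0.0
    for u in range(L - 1, -1, -1):
        if df[u] <= 0 or not np.isfinite(MS[u]):
            sigma[u] = np.nan
            continue
        acc = MS[u] - sigma[L]
        for w in range(u + 1, L):
            if np.isfinite(sigma[w]):
                acc -= Cmat[u, w] * sigma[w]
        sigma[u] = acc / Cmat[u, u]
    return sigma


def _hier_locus_components(table, j, basins, seas, sites) -> np.ndarray:
    calls = table.alleles[:, j, :]
    typed = calls[:, 0] != 0
    if typed.sum() < 2:
        return np.zeros(5)
    alleles = np.unique(calls[typed])
    if len(alleles) < 2:
        return np.zeros(5)
    rows = np.flatnonzero(typed)
    ind = np.repeat(rows, 2)
    copies = calls[rows].ravel()
    lab_basin = np.asarray(basins)[ind]
    lab_sea = np.asarray(seas)[ind]
    lab_site = np.asarray(sites)[ind]
    lab_ind = ind.astype(str)
    total = np.zeros(5)
    for a in alleles:
        yv = (copies == a).astype(float)
        total += _nested_components(yv, [lab_basin, lab_sea, lab_site, lab_ind])
    return total


def hierarchical_fstats(table: GenotypeTable, hierarchy, n_boot: int = 1000,
                        seed: int = 0) -> HierarchicalFResult:
    """Nested F-statistics for the basin / sea / site / individual hierarchy.

    Variance components are estimated per locus by a moment-based nested
    ANOVA on allele indicators over gene copies, summed over alleles and
    loci; each F contrast is the ratio of the focal component to the sum of
    it and all finer components.  Bootstrap over loci gives 95% CIs.
    """
    seas = [hierarchy.sea_of(s) for s in table.sites]
    basins = [hierarchy.basin_of(s) for s in table.sites]
    comp = np.array([
        _hier_locus_components(table, j, basins, seas, table.sites)
        for j in range(table.n_loci)
    ])
    comp = np.nan_to_num(comp, nan=0.0)
    names = ["basin", "sea", "site", "individual", "gene"]

    def contrasts(total: np.ndarray) -> dict[str, float]:
        out = {}
        labels = ["basin/total", "sea/basin", "site/sea", "individual/site"]
        for i, lab in enumerate(labels):
            denom = total[i:].sum()
            out[lab] = total[i] / denom if denom != 0 else np.nan
        return out

    F = contrasts(comp.sum(axis=0))
    rng = np.random.default_rng(seed)
    L = comp.shape[0]
    boot = {k: [] for k in F}
    for _ in range(n_boot):
        s = rng.integers(0, L, size=L)
        for k, v in contrasts(comp[s].sum(axis=0)).items():
            boot[k].append(v)
    ci = ({k: tuple(np.nanpercentile(v, [2.5, 97.5])) for k, v in boot.items()}
          if n_boot > 0 else {})
    return HierarchicalFResult(
        levels=names,
        components=pd.DataFrame(comp, index=table.loci, columns=names),
        F=F,
        ci=ci,
    )
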