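"""Identity disequilibrium (g2) and maximum-likelihood selfing rates.

g2 measures the excess of double heterozygosity at pairs of loci relative
to random association, standardized by the marginal heterozygosities — the
signature of variance in inbreeding (e.g. partial selfing) that is robust
to locus-specific technical artifacts.  The estimator used here is the
missing-data-robust two-locus heterozygosity-correlation form: the ratio
of the mean within-individual double-heterozygosity to the between-
individual expectation, minus one; significance comes from permuting each
locus's heterozygosity column independently among individuals.

The selfing rate is estimated by maximizing the likelihood of the observed
per-individual heterozygosity patterns under a mixture over selfing depth:
an individual derives from t >= 0 consecutive selfing generations with
probability (1-s) s^t, and a locus with outcrossed heterozygosity h is
heterozygous with probability h / 2^t after t generations.  The outcrossed
heterozygosities are profiled out; the s = 0 constrained fit gives a
1-d.f. deviance test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .genotypes import GenotypeTable

__all__ = ["IdentityDisequilibrium", "SelfingFit", "g2_estimate", "selfing_ml"]

_MAX_DEPTH = 20  # geometric truncation; residual mass < s^21, negligible


@dataclass
class IdentityDisequilibrium:
    g2: float
    sd: float
    p: float
    n_iterations: int


def _het_matrix(table: GenotypeTable) -> np.ndarray:
    """(n, L) heterozygosity indicators with NaN where untyped."""
    h = table.heterozygous.astype(float)
    h[~table.typed] = np.nan
    return h


def _g2_from_h(h: np.ndarray) -> float:
    """Definitional g2 on a heterozygosity matrix (NaN = missing)."""
    m = (~np.isnan(h)).astype(float)
    t = np.nan_to_num(h)
    tt = t.T @ t          # within-individual double-het counts per pair
    mm = m.T @ m          # individuals typed at both loci
    s = t.sum(axis=0)     # het counts per locus
    n = m.sum(axis=0)
    L = h.shape[1]
    iu = np.triu_indices(L, k=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (tt / mm)[iu]
        den = ((np.outer(s, s) - tt) / (np.outer(n, n) - mm))[iu]
    ok = np.isfinite(num) & np.isfinite(den)
    if not ok.any() or den[ok].sum() == 0:
        return np.nan
    return float(num[ok].sum() / den[ok].sum() - 1)


def g2_estimate(table: GenotypeTable, n_iter: int = 1000, seed: int = 0) -> IdentityDisequilibrium:
    """g2 for one site with permutation significance and bootstrap SD.

    Loci without a single heterozygote are excluded (they carry no signal).
    The null reshuffles each locus's heterozygosity column independently;
    the SD is a bootstrap over individuals (resampling rows).
    """
    h = _het_matrix(table)
    het_counts = np.nansum(h, axis=0)
    usable = het_counts > 0
    if usable.sum() < 2:
        raise ValueError("need >= 2 loci with heterozygotes")
    if h.shape[0] < 5:
        raise ValueError("need >= 5 individuals")
    h = h[:, usable]
    obs = _g2_from_h(h)
    rng = np.random.default_rng(seed)
    n, L = h.shape
    hits = 0
    for _ in range(n_iter):
        perm = np.column_stack([h[rng.permutation(n), j] for j in range(L)])
        if _g2_from_h(perm) >= obs:
            hits += 1
    p = (hits + 1) / (n_iter + 1)
    boots = []
    for _ in range(200):
        rows = rng.integers(0, n, size=n)
        boots.append(_g2_from_h(h[rows]))
    sd = float(np.nanstd(boots, ddof=1))
    return IdentityDisequilibrium(g2=obs, sd=sd, p=p, n_iterations=n_iter)


# ---------------------------------------------------------------------------
# Selfing-rate maximum likelihood
# ---------------------------------------------------------------------------

@dataclass
class SelfingFit:
    s_hat: float
    lnl_unconstrained: float
    lnl_constrained: float
    delta_dev: float
    p: float
    at_boundary: bool = False


def _lnl(s: float, h: np.ndarray, x: np.ndarray, mask: np.ndarray) -> float:
    """Log-likelihood of het patterns ``x`` (n, L; mask = typed) given
    selfing rate s and outcrossed heterozygosities h (L,)."""
    t = np.arange(_MAX_DEPTH + 1)
    w = (1 - s) * s ** t
    w /= w.sum()
    ph = h[None, :] * 0.5 ** t[:, None]            # (T+1, L)
    ph = np.clip(ph, 1e-12, 1 - 1e-12)
    # log P(x_i | t) = sum_l typed x log ph + (1-x) log(1-ph)
    lp = (x[:, None, :] * np.log(ph)[None, :, :]
          + (1 - x[:, None, :]) * np.log1p(-ph)[None, :, :])
    lp = np.where(mask[:, None, :], lp, 0.0).sum(axis=2)   # (n, T+1)
    mx = lp.max(axis=1, keepdims=True)
    lik = (np.exp(lp - mx) * w[None, :]).sum(axis=1)
    return float((np.log(lik) + mx[:, 0]).sum())


def selfing_ml(table: GenotypeTable) -> SelfingFit:
    """Maximum-likelihood selfing rate from multilocus heterozygosity.

    Fits s and the per-locus outcrossed heterozygosities jointly, compares
    with the s = 0 fit (whose profile solution is the observed mean
    heterozygosity per locus) and reports the 1-d.f. chi-square deviance
    test.  Loci monomorphic within the sample are dropped.
    """
    h = _het_matrix(table)
    usable = np.nansum(h, axis=0) > 0
    h = h[:, usable]
    n, L = h.shape
    if L < 3:
        raise ValueError("need >= 3 polymorphic loci")
    if n < 10:
        import warnings
        warnings.warn("fewer than 10 individuals: low power for selfing ML")
    mask = ~np.isnan(h)
    x = np.nan_to_num(h)

    h0 = np.clip(np.nansum(h, axis=0) / mask.sum(axis=0), 1e-6, 1 - 1e-6)
    lnl_con = _lnl(0.0, h0, x, mask)

    def neg(params):
        s = params[0]
        hh = params[1:]
        return -_lnl(s, hh, x, mask)

    bounds = [(0.0, 0.99)] + [(1e-4, 1 - 1e-4)] * L
    best = None
    for s0 in (0.02, 0.2, 0.5):
        res = optimize.minimize(neg, x0=np.concatenate([[s0], h0]),
                                method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    lnl_unc = -best.fun
    s_hat = float(best.x[0])
    if lnl_unc < lnl_con:          # optimizer fell short of the nested fit
        lnl_unc, s_hat = lnl_con, 0.0
    dd = 2 * (lnl_unc - lnl_con)
    return SelfingFit(
        s_hat=s_hat,
        lnl_unconstrained=lnl_unc,
        lnl_constrained=lnl_con,
        delta_dev=dd,
        p=float(stats.chi2.sf(dd, df=1)),
        at_boundary=s_hat >= 0.985,
    )
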