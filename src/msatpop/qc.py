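"""Marker-quality diagnostics and the determination key separating
technical from demographic causes of heterozygote deficits.

Per locus the module estimates null-allele frequencies (maximum likelihood
of the blanks-are-null-homozygotes Hardy–Weinberg model, computed by EM),
tests whether the observed number of blanks is compatible with those
frequencies (one-sided exact binomial), screens for short-allele dominance
(one-sided Spearman correlation between allele size and per-allele F_IS /
F_IT) and for stuttering (deficit of one-repeat-apart heterozygotes against
their Hardy–Weinberg expectation).

The determination key then combines multilocus f and theta, their
jackknife-over-loci standard errors, the Pearson correlation of per-locus
F_IS with F_ST and the Spearman correlation of F_IS with missing-data
counts into a rule-based diagnosis: null alleles likely, Wahlund/demographic
deficit, SAD, stuttering, or panmixia not rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeTable
from .fstats import FStatEstimate, em_null_freq, wc_fstats

__all__ = [
    "LocusQCReport",
    "DeterminationKeyReport",
    "estimate_null_brookfield2",
    "blanks_binomial_test",
    "sad_test",
    "stuttering_test",
    "determination_key",
]


def estimate_null_brookfield2(genotypes: np.ndarray, n_blanks: int) -> float:
    """Null-allele frequency for one site x locus, blanks treated as null
    homozygotes.

    Maximum-likelihood estimate of the Hardy–Weinberg model in which each
    apparent homozygote is either a true homozygote or a visible/null
    heterozygote and every blank is a null homozygote (the model behind the
    second Brookfield estimator); computed by EM.
    """
    genotypes = np.asarray(genotypes)
    if len(genotypes) + n_blanks < 5:
        raise ValueError("need >= 5 typed-or-blank individuals")
    r, _, _ = em_null_freq(genotypes, n_blanks)
    return float(r)


def blanks_binomial_test(N: int, r_hat: float, observed_blanks: int) -> float:
    """One-sided exact binomial test of the observed blank count.

    Under a null-allele frequency ``r_hat``, blanks (null homozygotes) occur
    with probability r_hat^2 among ``N`` typed-or-blank individuals.  The
    alternative is that fewer blanks are observed than expected; a small p
    means nulls cannot explain the heterozygote deficit, a large p leaves
    them plausible.
    """
    if not 0 <= r_hat <= 1:
        raise ValueError("r_hat must be in [0, 1]")
    if observed_blanks > N:
        raise ValueError("observed_blanks > N")
    return float(stats.binom.cdf(observed_blanks, N, r_hat ** 2))


# ---------------------------------------------------------------------------
# Short-allele dominance
# ---------------------------------------------------------------------------

def _per_allele_fstats(table: GenotypeTable, j: int) -> pd.DataFrame:
    """Collapse locus ``j`` to focal-allele-vs-rest and compute f and F for
    each allele (the standard per-allele construction)."""
    calls = table.alleles[:, j, :]
    typed = calls[:, 0] != 0
    alleles = np.unique(calls[typed])
    rows = []
    for a in alleles:
        recoded = np.where(calls == a, 1, 2)
        recoded[~typed] = 0
        sub = GenotypeTable(table.ids, table.sites, [f"bi{a}"],
                            recoded[:, None, :])
        try:
            e = wc_fstats(sub)
            rows.append((int(a), e.f, e.Fit))
        except ValueError:
            rows.append((int(a), np.nan, np.nan))
    return pd.DataFrame(rows, columns=["allele", "f", "Fit"])


def sad_test(table: GenotypeTable, locus: str) -> dict:
    """Short-allele dominance screen for one locus.

    One-sided (rho < 0) Spearman rank correlations between allele size and
    the per-allele F_IS, and between size and per-allele F_IT (the latter
    raises power).  Needs >= 4 distinct alleles.
    """
    j = table.loci.index(locus)
    per = _per_allele_fstats(table, j)
    per = per.dropna()
    if len(per) < 4:
        return {"applicable": False, "locus": locus}
    rho_fis, p_fis = stats.spearmanr(per["allele"], per["f"], alternative="less")
    rho_fit, p_fit = stats.spearmanr(per["allele"], per["Fit"], alternative="less")
    return {
        "applicable": True, "locus": locus,
        "rho_fis": float(rho_fis), "p_fis": float(p_fis),
        "rho_fit": float(rho_fit), "p_fit": float(p_fit),
    }


# ---------------------------------------------------------------------------
# Stuttering
# ---------------------------------------------------------------------------

def stuttering_test(table: GenotypeTable, locus: str, motif_len: int) -> dict:
    """One-sided deficit test for heterozygotes one repeat unit apart.

    Stuttering miscalls one-step heterozygotes as short-allele homozygotes,
    selectively depleting that heterozygote class.  To stay robust against
    processes that deplete *all* heterozygotes alike (null alleles, Wahlund
    pooling, inbreeding), the statistic conditions on the observed
    heterozygotes: among them, is the fraction whose alleles differ by
    exactly one repeat lower than its Hardy–Weinberg share of the expected
    heterozygosity?  Expected shares are pooled over sites and compared
    with an exact binomial (mid-p to soften the discreteness).
    """
    j = table.loci.index(locus)
    sarr = np.asarray(table.sites)
    het_total = 0
    onestep_obs = 0
    weighted_share = 0.0
    any_onestep = False
    for site in table.site_labels():
        cc = table.alleles[sarr == site, j, :]
        cc = cc[cc[:, 0] != 0]
        n = len(cc)
        if n < 2:
            continue
        vals, counts = np.unique(cc.ravel(), return_counts=True)
        p = counts / counts.sum()
        exp_het = 1 - (p ** 2).sum()
        if exp_het <= 0:
            continue
        onestep = 0.0
        for ai in range(len(vals)):
            for bi in range(ai + 1, len(vals)):
                if vals[bi] - vals[ai] == motif_len:
                    onestep += 2 * p[ai] * p[bi]
        if onestep == 0:
            continue
        any_onestep = True
        het = cc[cc[:, 0] != cc[:, 1]]
        het_total += len(het)
        onestep_obs += int(((het[:, 1] - het[:, 0]) == motif_len).sum())
        weighted_share += len(het) * (onestep / exp_het)
    if not any_onestep or het_total == 0:
        return {"applicable": False, "locus": locus}
    prob = min(weighted_share / het_total, 1.0)
    p = float(stats.binom.cdf(onestep_obs - 1, het_total, prob)
              + 0.5 * stats.binom.pmf(onestep_obs, het_total, prob))
    return {"applicable": True, "locus": locus, "observed": onestep_obs,
            "expected": weighted_share, "p": p}


# ---------------------------------------------------------------------------
# Locus QC report and determination key
# ---------------------------------------------------------------------------

@dataclass
class LocusQCReport:
    per_locus: pd.DataFrame   # r_hat, expected/observed blanks, binomial p,
                              # SAD rho/p, stuttering p, f, theta


def locus_qc(table: GenotypeTable, motif_len: int = 2) -> LocusQCReport:
    """Assemble the per-locus QC table feeding the determination key."""
    est = wc_fstats(table)
    rows = []
    sarr = np.asarray(table.sites)
    for j, locus in enumerate(table.loci):
        calls = table.alleles[:, j, :]
        typed = calls[calls[:, 0] != 0]
        blanks = int((calls[:, 0] == 0).sum())
        N = len(calls)
        # pooled null estimate: mean of per-site EM estimates weighted by n
        rs, ws = [], []
        for site in table.site_labels():
            cc = calls[sarr == site]
            tt = cc[cc[:, 0] != 0]
            bb = int((cc[:, 0] == 0).sum())
            if len(tt) + bb >= 5:
                r, _, _ = em_null_freq(tt, bb)
                rs.append(r)
                ws.append(len(tt) + bb)
        r_hat = float(np.average(rs, weights=ws)) if rs else np.nan
        p_binom = blanks_binomial_test(N, r_hat, blanks) if np.isfinite(r_hat) else np.nan
        sad = sad_test(table, locus)
        stut = stuttering_test(table, locus, motif_len)
        rows.append({
            "locus": locus,
            "r_hat": r_hat,
            "expected_blanks": N * r_hat ** 2 if np.isfinite(r_hat) else np.nan,
            "observed_blanks": blanks,
            "p_blanks": p_binom,
            "rho_fis": sad.get("rho_fis", np.nan),
            "p_sad_fis": sad.get("p_fis", np.nan),
            "rho_fit": sad.get("rho_fit", np.nan),
            "p_sad_fit": sad.get("p_fit", np.nan),
            "p_stutter": stut.get("p", np.nan),
            "f": est.per_locus.loc[j, "f"],
            "theta": est.per_locus.loc[j, "theta"],
            "missing": blanks,
        })
    return LocusQCReport(per_locus=pd.DataFrame(rows))


def _any_significant_fdr(p: pd.Series, alpha: float) -> bool:
    """Any locus significant after Benjamini–Yekutieli control."""
    from .hwe_ld import by_fdr
    vals = p.dropna().to_numpy()
    vals = vals[(vals > 0) & (vals <= 1)]
    if vals.size == 0:
        return False
    return bool((by_fdr(vals) < alpha).any())


@dataclass
class DeterminationKeyReport:
    f: float
    theta: float
    strderr_fis: float
    strderr_fst: float
    se_ratio: float
    pearson_fis_fst: float
    pearson_p: float
    spearman_fis_missing: float
    spearman_p: float
    p_deficit: float
    flags: dict[str, bool] = field(default_factory=dict)


def determination_key(
    table: GenotypeTable,
    fstats_est: FStatEstimate,
    qc: LocusQCReport,
    alpha: float = 0.05,
    se_ratio_null: float = 1.0,
    se_ratio_comparable: tuple[float, float] = (0.5, 2.0),
    p_deficit: float | None = None,
) -> DeterminationKeyReport:
    """Rule-based diagnosis of heterozygote-deficit causes.

    Inputs: a resampled :class:`FStatEstimate` (must carry StrdErrFIS,
    StrdErrFST and, unless ``p_deficit`` is given, the permutation p for f)
    and a :class:`LocusQCReport`.  Flags emitted:

    * ``panmixia-not-rejected`` — multilocus deficit not significant;
    * ``null-alleles-likely`` — deficit significant, per-locus F_IS
      correlates with missing counts (one-sided Spearman rho > 0) and
      StrdErrFIS < StrdErrFST (``se_ratio_null``): the across-loci
      signature of locus-specific amplification failure;
    * ``wahlund-or-demographic`` — deficit significant, no missing-data
      correlation, F_IS/F_ST correlation non-negative and SEs of
      comparable magnitude (``se_ratio_comparable`` band);
    * ``sad`` / ``stuttering`` — any locus significant in those screens.
    """
    if len(qc.per_locus) < 5:
        raise ValueError("determination key needs >= 5 loci")
    if fstats_est.strderr_fis is None or fstats_est.strderr_fst is None:
        raise ValueError("fstats_est must carry jackknife-over-loci SEs")
    pl = fstats_est.per_locus.dropna(subset=["f", "theta"])
    r, r_p = stats.pearsonr(pl["f"], pl["theta"])
    miss = qc.per_locus["missing"]
    if miss.nunique() > 1:
        rho, rho_p = stats.spearmanr(qc.per_locus["f"], miss,
                                     alternative="greater", nan_policy="omit")
    else:
        rho, rho_p = np.nan, 1.0  # no missing-data variation: no signal
    pdef = fstats_est.p_f if p_deficit is None else p_deficit
    if pdef is None:
        raise ValueError("no deficit p-value available (run permutation tests)")
    ratio = fstats_est.strderr_fis / fstats_est.strderr_fst \
        if fstats_est.strderr_fst else np.inf
    deficit = (pdef < alpha) and (fstats_est.f > 0)
    miss_corr = rho_p < alpha
    flags = {
        "panmixia-not-rejected": not deficit,
        "null-alleles-likely": deficit and miss_corr and ratio < se_ratio_null,
        "wahlund-or-demographic": (
            deficit and not miss_corr and (np.isnan(r) or r >= 0)
            and se_ratio_comparable[0] <= ratio <= se_ratio_comparable[1]
        ),
        "sad": _any_significant_fdr(
            pd.concat([qc.per_locus["p_sad_fis"], qc.per_locus["p_sad_fit"]]),
            alpha),
        "stuttering": _any_significant_fdr(qc.per_locus["p_stutter"], alpha),
    }
    return DeterminationKeyReport(
        f=fstats_est.f, theta=fstats_est.theta,
        strderr_fis=fstats_est.strderr_fis, strderr_fst=fstats_est.strderr_fst,
        se_ratio=float(ratio),
        pearson_fis_fst=float(r), pearson_p=float(r_p),
        spearman_fis_missing=float(rho), spearman_p=float(rho_p),
        p_deficit=float(pdef), flags=flags,
    )
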