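"""Clone screening and per-site diversity statistics.

Clone detection works through the probability of identity (PI): the chance
that two independently sampled outbred individuals share one multilocus
genotype.  Pairs identical at every mutually typed locus are flagged and,
where the site-level multilocus PI is below a threshold (default 1.8e-5),
annotated as presumed clones; one representative per clone group is kept.

Diversity summaries follow the Fstat conventions: mean alleles per locus
(N_all), rarefied allelic richness A_r (expected alleles in a random
subsample of g diploids, hypergeometric form), Nei gene diversity H_S with
the small-sample correction, observed heterozygosity and the per-individual
multilocus heterozygosity count (MLH).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import GenotypeTable, SiteHierarchy

__all__ = [
    "ClonalReport",
    "DiversitySummary",
    "probability_of_identity",
    "find_clones",
    "keep_unique_genotypes",
    "diversity_stats",
    "compare_groups",
    "site_allele_freqs",
]


def site_allele_freqs(table: GenotypeTable) -> dict[str, list[dict[int, float]]]:
    """Observed allele frequencies per site (keys) per locus (list index)."""
    out: dict[str, list[dict[int, float]]] = {}
    sarr = np.asarray(table.sites)
    for site in table.site_labels():
        rows = sarr == site
        per_locus = []
        for j in range(table.n_loci):
            cc = table.alleles[rows, j, :]
            typed = cc[cc[:, 0] != 0]
            if len(typed) == 0:
                per_locus.append({})
                continue
            vals, counts = np.unique(typed.ravel(), return_counts=True)
            per_locus.append({int(a): c / counts.sum() for a, c in zip(vals, counts)})
        out[site] = per_locus
    return out


def probability_of_identity(freqs: list[np.ndarray | dict]) -> tuple[np.ndarray, float]:
    """Per-locus and multilocus probability of identity.

    Per locus ``PI = sum_i p_i^4 + sum_{i<j} (2 p_i p_j)^2``; the multilocus
    PI is the product over loci.
    """
    if len(freqs) == 0:
        raise ValueError("no allele frequencies supplied")
    per_locus = []
    for f in freqs:
        p = np.asarray(list(f.values()) if isinstance(f, dict) else f, dtype=float)
        if p.size == 0:
            raise ValueError("empty frequency vector")
        hom = (p ** 4).sum()
        cross = 0.0
        for i in range(len(p)):
            for j in range(i + 1, len(p)):
                cross += (2 * p[i] * p[j]) ** 2
        per_locus.append(hom + cross)
    per_locus = np.array(per_locus)
    return per_locus, float(np.prod(per_locus))


@dataclass
class ClonalReport:
    pi_per_site: pd.DataFrame            # site x locus PI (NaN where no data)
    pi_product: pd.Series                # multilocus PI per site
    pairs: list[dict] = field(default_factory=list)
    groups: list[list[str]] = field(default_factory=list)
    retained: dict[str, str] = field(default_factory=dict)  # group key -> kept id


def _identical_pair(a: np.ndarray, b: np.ndarray) -> tuple[bool, int]:
    """Compare two individuals' call arrays; returns (identical at all
    mutually typed loci, number of mutually typed loci)."""
    typed = (a[:, 0] != 0) & (b[:, 0] != 0)
    shared = int(typed.sum())
    if shared == 0:
        return False, 0
    same = np.all(a[typed] == b[typed])
    return bool(same), shared


def find_clones(table: GenotypeTable, min_shared_loci: int = 6,
                pi_threshold: float = 1.8e-5) -> ClonalReport:
    """Flag pairs identical at every mutually typed locus.

    A pair needs at least ``min_shared_loci`` mutually typed loci.  A match
    is annotated "presumed clone" only where the multilocus PI of its site
    is below ``pi_threshold`` (within-site allele frequencies; the global
    frequencies are used for sites with fewer than 5 individuals).
    """
    freqs = site_allele_freqs(table)
    sites = table.site_labels()
    sarr = np.asarray(table.sites)
    # global fallback frequencies for tiny sites
    global_freqs = []
    for j in range(table.n_loci):
        cc = table.alleles[:, j, :]
        typed = cc[cc[:, 0] != 0]
        if len(typed) == 0:
            global_freqs.append({})
            continue
        vals, counts = np.unique(typed.ravel(), return_counts=True)
        global_freqs.append({int(a): c / counts.sum() for a, c in zip(vals, counts)})

    pi_rows = []
    pi_prod = {}
    for site in sites:
        n_site = int((sarr == site).sum())
        use = freqs[site] if n_site >= 5 else global_freqs
        per_locus = []
        usable = [f for f in use if f]
        for f in use:
            per_locus.append(probability_of_identity([f])[0][0] if f else np.nan)
        pi_rows.append(per_locus)
        pi_prod[site] = probability_of_identity(usable)[1] if usable else np.nan
    pi_df = pd.DataFrame(pi_rows, index=sites, columns=table.loci)
    pi_s = pd.Series(pi_prod)

    n = table.n_individuals
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    pairs = []
    for i in range(n):
        for k in range(i + 1, n):
            same, shared = _identical_pair(table.alleles[i], table.alleles[k])
            if not same or shared < min_shared_loci:
                continue
            site_i = table.sites[i]
            presumed = bool(pi_s.get(site_i, np.nan) < pi_threshold)
            pairs.append({
                "id1": table.ids[i], "id2": table.ids[k],
                "site1": site_i, "site2": table.sites[k],
                "shared_loci": shared, "presumed_clone": presumed,
            })
            ri, rk = find(i), find(k)
            if ri != rk:
                parent[max(ri, rk)] = min(ri, rk)

    groups_idx: dict[int, list[int]] = {}
    for i in range(n):
        groups_idx.setdefault(find(i), []).append(i)
    groups = []
    retained = {}
    for root, members in groups_idx.items():
        if len(members) < 2:
            continue
        ids = [table.ids[m] for m in members]
        groups.append(ids)
        retained[ids[0]] = ids[0]  # lowest (first-appearing) id kept
    return ClonalReport(pi_per_site=pi_df, pi_product=pi_s, pairs=pairs,
                        groups=groups, retained=retained)


def keep_unique_genotypes(table: GenotypeTable, report: ClonalReport) -> GenotypeTable:
    """Drop all but the first-appearing member of each clone group."""
    drop = set()
    for group in report.groups:
        drop.update(group[1:])
    if not drop:
        return table
    keep = np.array([i not in drop for i in table.ids])
    return table.subset(keep)


# ---------------------------------------------------------------------------
# Diversity statistics
# ---------------------------------------------------------------------------

@dataclass
class DiversitySummary:
    per_site: pd.DataFrame        # N, N_all, A_r, H_S, H_O
    mlh: dict[str, np.ndarray]    # site -> per-individual heterozygous count
    rarefaction_g: int
    excluded_sites: list[str] = field(default_factory=list)


def _log_comb(n: float, k: float) -> float:
    if k > n or k < 0:
        return -np.inf
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _rarefied_richness(counts: np.ndarray, g: int) -> float:
    """Expected allele count in a random subsample of g diploids (2g genes)."""
    total = counts.sum()
    acc = 0.0
    for c in counts:
        log_ratio = _log_comb(total - c, 2 * g) - _log_comb(total, 2 * g)
        acc += 1 - (np.exp(log_ratio) if np.isfinite(log_ratio) else 0.0)
    return acc


def diversity_stats(table: GenotypeTable, hierarchy: SiteHierarchy | None = None,
                    rarefaction_g: int = 5) -> DiversitySummary:
    """Per-site diversity summary (N, N_all, A_r, H_S, H_O) plus MLH vectors.

    Sites whose minimum per-locus typed sample size is below ``rarefaction_g``
    are excluded from A_r (reported NaN) with a warning.
    """
    sarr = np.asarray(table.sites)
    rows = []
    mlh = {}
    excluded = []
    for site in table.site_labels():
        mask = sarr == site
        sub_alleles = table.alleles[mask]
        n_ind = int(mask.sum())
        typed = sub_alleles[:, :, 0] != 0
        het = typed & (sub_alleles[:, :, 0] != sub_alleles[:, :, 1])
        mlh[site] = het.sum(axis=1)
        n_alleles, ar_vals, hs_vals, ho_vals = [], [], [], []
        min_typed = None
        for j in range(table.n_loci):
            calls = sub_alleles[typed[:, j], j, :]
            n_typed = len(calls)
            if n_typed == 0:
                warnings.warn(f"site {site}: locus {table.loci[j]} untyped, skipped")
                continue
            min_typed = n_typed if min_typed is None else min(min_typed, n_typed)
            vals, counts = np.unique(calls.ravel(), return_counts=True)
            n_alleles.append(len(vals))
            p = counts / counts.sum()
            ho = float((calls[:, 0] != calls[:, 1]).mean())
            ho_vals.append(ho)
            if n_typed > 1:
                hs = n_typed / (n_typed - 1) * (1 - (p ** 2).sum() - ho / (2 * n_typed))
            else:
                hs = np.nan
            hs_vals.append(hs)
            if n_typed >= rarefaction_g:
                ar_vals.append(_rarefied_richness(counts, rarefaction_g))
        if min_typed is not None and min_typed < rarefaction_g:
            excluded.append(site)
            warnings.warn(
                f"site {site}: typed sample size {min_typed} < g={rarefaction_g}; "
                "excluded from allelic richness"
            )
            ar = np.nan
        else:
            ar = float(np.mean(ar_vals)) if ar_vals else np.nan
        rows.append({
            "site": site,
            "N": n_ind,
            "N_all": float(np.mean(n_alleles)) if n_alleles else np.nan,
            "A_r": ar,
            "H_S": float(np.nanmean(hs_vals)) if hs_vals else np.nan,
            "H_O": float(np.mean(ho_vals)) if ho_vals else np.nan,
        })
    per_site = pd.DataFrame(rows).set_index("site")
    return DiversitySummary(per_site=per_site, mlh=mlh,
                            rarefaction_g=rarefaction_g, excluded_sites=excluded)


def compare_groups(values: np.ndarray, group_assignment: np.ndarray,
                   n_perm: int = 10000, seed: int = 0) -> float:
    """Two-sided randomization test for a difference in a per-site statistic
    between two groups of sites.

    Permutes the site-to-group labels; p is the +1-smoothed proportion of
    permutations with |mean difference| at least the observed one.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(group_assignment)
    labels = list(dict.fromkeys(groups))
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    m1, m2 = groups == labels[0], groups == labels[1]
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("each group needs >= 2 sites")
    obs = abs(values[m1].mean() - values[m2].mean())
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        p1, p2 = perm == labels[0], perm == labels[1]
        if abs(values[p1].mean() - values[p2].mean()) >= obs - 1e-15:
            hits += 1
    return (hits + 1) / (n_perm + 1)
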