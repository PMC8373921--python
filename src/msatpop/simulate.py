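"""Synthetic microsatellite datasets with known truth.

Two generators are provided:

* a nested Dirichlet F-model (basins -> seas -> sites) with direct control
  of the target differentiation at each level, within-site inbreeding and
  geometric-depth selfing — the workhorse for estimator-recovery tests;
* a forward Wright–Fisher stepping-stone simulation on a 1-D lattice with
  nearest-neighbour migration and stepwise (+/-1 repeat) mutation, used for
  isolation-by-distance and effective-size recovery.

A corruption layer injects the classical microsatellite artifacts: null
alleles (heterozygote-with-null -> apparent homozygote, null homozygote ->
blank), random amplification failure, size-dependent short-allele dominance
and one-repeat stuttering.  Clonal duplicates can be added on top.

The default configuration emulates the structure of a fragmented coastal
seaweed survey: 15 sites in 3 seas (the last sea in its own basin), 20-35
diploids per site, 12 loci with around a dozen alleles each, sea-level
differentiation near 0.3, mild within-sea structure, a few percent missing
data and a small number of clone pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .genotypes import GenotypeTable, SiteHierarchy
import pandas as pd

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "simulate_hierarchical_fmodel",
    "simulate_stepping_stone",
    "corrupt_genotypes",
    "inject_clones",
]


@dataclass
class SimulationConfig:
    seed: int = 0
    n_seas: int = 3
    sites_per_sea: int = 5
    n_per_site: int = 25
    n_loci: int = 12
    alleles_per_locus: int | list[int] = 12
    theta_between_seas: float | list[float] = 0.30
    theta_within_sea: float | list[float] = 0.10
    fis_target: float = 0.05
    selfing_s: float = 0.0
    null_freq: float | list[float] = 0.0
    null_segregating: bool = False
    miss_rate: float = 0.02
    sad_rate: float = 0.0
    stutter_rate: float = 0.0
    clone_pairs: int = 0
    motif_len: int = 2

    def __post_init__(self) -> None:
        for name in ("theta_between_seas", "theta_within_sea", "fis_target",
                     "selfing_s", "miss_rate", "sad_rate", "stutter_rate"):
            v = getattr(self, name)
            vals = v if isinstance(v, (list, tuple)) else [v]
            if any(not 0 <= x < 1 for x in vals):
                raise ValueError(f"{name}={v} outside [0, 1)")
        for name in ("n_seas", "sites_per_sea", "n_per_site", "n_loci", "motif_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.clone_pairs < 0:
            raise ValueError("clone_pairs must be >= 0")
        nf = self.null_freq
        for v in (nf if isinstance(nf, (list, tuple)) else [nf]):
            if not 0 <= v < 1:
                raise ValueError("null_freq entries must be in [0, 1)")

    def allele_counts(self) -> list[int]:
        a = self.alleles_per_locus
        return list(a) if isinstance(a, (list, tuple)) else [a] * self.n_loci

    def theta_per_locus(self) -> tuple[np.ndarray, np.ndarray]:
        """(theta_between, theta_within) broadcast to per-locus arrays.

        Per-locus differentiation targets model the locus-specific effective
        drift (mutation-rate variation) seen in real microsatellite panels.
        """
        def bcast(v):
            if isinstance(v, (list, tuple)):
                if len(v) != self.n_loci:
                    raise ValueError("per-locus theta list length != n_loci")
                return np.asarray(v, dtype=float)
            return np.full(self.n_loci, float(v))
        return bcast(self.theta_between_seas), bcast(self.theta_within_sea)

    def null_freqs(self) -> np.ndarray:
        nf = self.null_freq
        if isinstance(nf, (list, tuple)):
            if len(nf) != self.n_loci:
                raise ValueError("null_freq list length != n_loci")
            return np.asarray(nf, dtype=float)
        return np.full(self.n_loci, float(nf))


@dataclass
class TruthRecord:
    """Ground truth emitted alongside a simulated table."""

    config: dict = field(default_factory=dict)
    site_freqs: dict = field(default_factory=dict)     # locus -> site -> {allele: p}
    inbred_depth: list[int] = field(default_factory=list)  # selfing generations per ind
    null_events: int = 0
    blank_events: int = 0
    sad_events: int = 0
    stutter_events: int = 0
    clone_pairs: list[tuple[str, str]] = field(default_factory=list)
    ibd_slope_sign: int = 0
    geo_km: pd.DataFrame | None = None


def _dirichlet_child(rng: np.random.Generator, parent: np.ndarray, theta: float) -> np.ndarray:
    """Draw child frequencies centred on ``parent`` with target F = theta."""
    if theta >= 1:
        raise ValueError("theta must be < 1")
    if theta == 0:
        return parent.copy()
    conc = (1 - theta) / theta
    alpha = np.maximum(parent * conc, 1e-9)
    return rng.dirichlet(alpha)


def _locus_allele_codes(n_alleles: int, locus_index: int, motif_len: int) -> np.ndarray:
    """Plausible fragment sizes: an arithmetic ladder of motif_len steps."""
    base = 100 + 12 * locus_index
    return base + motif_len * np.arange(n_alleles)


def _draw_genotypes(rng, freqs: np.ndarray, codes: np.ndarray, n: int,
                    fis: float, depth: np.ndarray) -> np.ndarray:
    """Genotypes for one site x locus: HWE draws with probability-``fis``
    identity-by-descent, then ``depth`` generations of selfing applied to
    each individual (heterozygosity halves per generation)."""
    k = len(freqs)
    a1 = rng.choice(k, size=n, p=freqs)
    a2 = rng.choice(k, size=n, p=freqs)
    ibd = rng.random(n) < fis
    a2[ibd] = a1[ibd]
    het = a1 != a2
    # selfing depth t: remain heterozygous w.p. 2^-t else collapse randomly
    if depth.max(initial=0) > 0:
        stay = rng.random(n) < 0.5 ** depth
        collapse = het & ~stay
        pick = rng.random(n) < 0.5
        a2 = np.where(collapse, np.where(pick, a1, a2), a2)
        a1 = np.where(collapse, np.where(pick, a1, a2), a1)
        a1, a2 = np.minimum(a1, a2), np.maximum(a1, a2)
    g = np.stack([codes[a1], codes[a2]], axis=1)
    return np.sort(g, axis=1)


def _fabricate_hierarchy(n_seas: int, sites_per_sea: int) -> SiteHierarchy:
    rows = []
    for s in range(n_seas):
        basin = "basinB" if (n_seas > 1 and s == n_seas - 1) else "basinA"
        for t in range(sites_per_sea):
            rows.append({
                "site": f"sea{s + 1}_site{t + 1}",
                "sea": f"sea{s + 1}",
                "basin": basin,
                "lat": 40.0 + 2.0 * s + 0.05 * t,
                "lon": 15.0 + 5.0 * s + 0.08 * t,
            })
    return SiteHierarchy(pd.DataFrame(rows))


def simulate_hierarchical_fmodel(config: SimulationConfig) -> tuple[GenotypeTable, SiteHierarchy, TruthRecord]:
    """Nested F-model: ancestral -> sea -> site allele frequencies, then
    genotypes with within-site inbreeding and optional selfing."""
    rng = np.random.default_rng(config.seed)
    hierarchy = _fabricate_hierarchy(config.n_seas, config.sites_per_sea)
    counts = config.allele_counts()
    truth = TruthRecord(config=asdict(config))
    ids: list[str] = []
    sites: list[str] = []
    n_total = config.n_seas * config.sites_per_sea * config.n_per_site
    alleles = np.zeros((n_total, config.n_loci, 2), dtype=np.int64)

    # selfing depth per individual: geometric, P(t) = (1-s) s^t
    s = config.selfing_s
    if s > 0:
        depth_all = rng.geometric(1 - s, size=n_total) - 1
    else:
        depth_all = np.zeros(n_total, dtype=int)

    site_list = hierarchy.sites
    for i_site, site in enumerate(site_list):
        for k in range(config.n_per_site):
            ids.append(f"{site}_{k + 1:03d}")
            sites.append(site)

    th_b, th_w = config.theta_per_locus()
    nulls = config.null_freqs() if config.null_segregating else np.zeros(config.n_loci)
    NULL_CODE = -1
    for j in range(config.n_loci):
        codes = _locus_allele_codes(counts[j], j, config.motif_len)
        anc = rng.dirichlet(np.ones(counts[j]))
        if nulls[j] > 0:
            # the null is a segregating non-amplifying allele: it enters the
            # frequency hierarchy and drifts like any other allele
            anc = np.concatenate([anc * (1 - nulls[j]), [nulls[j]]])
            codes = np.concatenate([codes, [NULL_CODE]])
        truth.site_freqs[f"L{j + 1}"] = {}
        row0 = 0
        for s_i in range(config.n_seas):
            sea_f = _dirichlet_child(rng, anc, th_b[j])
            for t in range(config.sites_per_sea):
                site_f = _dirichlet_child(rng, sea_f, th_w[j])
                site = site_list[s_i * config.sites_per_sea + t]
                truth.site_freqs[f"L{j + 1}"][site] = {
                    int(c): float(p) for c, p in zip(codes, site_f)
                }
                rows = slice(row0, row0 + config.n_per_site)
                g = _draw_genotypes(
                    rng, site_f, codes, config.n_per_site,
                    config.fis_target, depth_all[rows],
                )
                if nulls[j] > 0:
                    isnull = g == NULL_CODE
                    one = isnull.sum(axis=1) == 1
                    both = isnull.sum(axis=1) == 2
                    vis = np.where(isnull[:, 0], g[:, 1], g[:, 0])
                    g[one, 0] = vis[one]
                    g[one, 1] = vis[one]
                    g[both, :] = 0
                    truth.null_events += int(one.sum())
                    truth.blank_events += int(both.sum())
                alleles[rows, j, :] = np.sort(g, axis=1)
                row0 += config.n_per_site
    truth.inbred_depth = depth_all.tolist()
    table = GenotypeTable(
        ids=ids, sites=sites,
        loci=[f"L{j + 1}" for j in range(config.n_loci)],
        alleles=alleles, provenance=f"fmodel(seed={config.seed})",
    )
    return table, hierarchy, truth


# ---------------------------------------------------------------------------
# Stepping-stone Wright-Fisher
# ---------------------------------------------------------------------------

def simulate_stepping_stone(
    config: SimulationConfig,
    n_demes: int,
    migration_m: float,
    mutation_mu: float,
    generations: int,
    spacing_km: float = 10.0,
) -> tuple[GenotypeTable, SiteHierarchy, TruthRecord]:
    """Forward Wright–Fisher on a 1-D lattice with stepwise mutation.

    Each deme holds ``config.n_per_site`` diploids.  Every offspring gamete
    comes from a uniformly chosen neighbouring deme with probability
    ``migration_m`` (edge demes have a single neighbour), otherwise from its
    own deme; allele states are repeat counts mutating +/-1 with rate
    ``mutation_mu``.  Demes sit on a line ``spacing_km`` apart.
    """
    if not 0 <= migration_m <= 0.5:
        raise ValueError("migration_m must be in [0, 0.5]")
    if mutation_mu >= 0.1:
        raise ValueError("mutation_mu must be < 0.1")
    if generations < 1:
        raise ValueError("generations must be >= 1")
    rng = np.random.default_rng(config.seed)
    N = config.n_per_site
    L = config.n_loci
    # founders: common pool of moderately polymorphic repeat counts
    state = rng.integers(18, 23, size=(n_demes, 2 * N, L))
    left = np.clip(np.arange(n_demes) - 1, 0, n_demes - 1)
    right = np.clip(np.arange(n_demes) + 1, 0, n_demes - 1)
    has_two = (np.arange(n_demes) > 0) & (np.arange(n_demes) < n_demes - 1)
    for _ in range(generations):
        new = np.empty_like(state)
        for d in range(n_demes):
            src = np.full(2 * N, d)
            mig = rng.random(2 * N) < migration_m
            if has_two[d]:
                go_left = rng.random(2 * N) < 0.5
                src[mig & go_left] = left[d]
                src[mig & ~go_left] = right[d]
            else:
                src[mig] = left[d] if d == n_demes - 1 else right[d]
            # free recombination: each locus independently takes one of the
            # two copies of a random parent in the source deme
            par = rng.integers(0, N, size=2 * N)
            pick = rng.integers(0, 2, size=(2 * N, L))
            new[d] = state[src[:, None], 2 * par[:, None] + pick, np.arange(L)[None, :]]
        mut = rng.random(new.shape) < mutation_mu
        step = rng.choice([-1, 1], size=new.shape)
        new = np.where(mut, np.maximum(new + step, 2), new)
        state = new

    codes = state * config.motif_len + 80  # repeat count -> fragment size
    ids, sites = [], []
    alleles = np.zeros((n_demes * N, L, 2), dtype=np.int64)
    rows = []
    for d in range(n_demes):
        site = f"deme{d + 1}"
        rows.append({"site": site, "sea": "lattice", "basin": "lattice",
                     "lat": 0.0, "lon": spacing_km * d / 111.32})
        for k in range(N):
            ids.append(f"{site}_{k + 1:03d}")
            sites.append(site)
            g = codes[d, [2 * k, 2 * k + 1], :].T  # (L, 2)
            alleles[d * N + k] = np.sort(g, axis=1)
    hierarchy = SiteHierarchy(pd.DataFrame(rows))
    dist = np.abs(np.subtract.outer(np.arange(n_demes), np.arange(n_demes))) * spacing_km
    labels = [r["site"] for r in rows]
    truth = TruthRecord(
        config={**asdict(config), "n_demes": n_demes, "migration_m": migration_m,
                "mutation_mu": mutation_mu, "generations": generations},
        ibd_slope_sign=1 if migration_m < 0.5 else 0,
        geo_km=pd.DataFrame(dist.astype(float), index=labels, columns=labels),
    )
    table = GenotypeTable(
        ids=ids, sites=sites, loci=[f"L{j + 1}" for j in range(L)],
        alleles=alleles,
        provenance=f"stepping_stone(seed={config.seed}, m={migration_m})",
    )
    return table, hierarchy, truth


# ---------------------------------------------------------------------------
# Artifact injection
# ---------------------------------------------------------------------------

def corrupt_genotypes(table: GenotypeTable, config: SimulationConfig) -> tuple[GenotypeTable, TruthRecord]:
    """Inject null alleles, random blanks, short-allele dominance and
    stuttering.  All rates zero -> identity.

    Null alleles: each gene copy independently becomes null with the locus
    rate r, so visible/null heterozygotes show as apparent homozygotes and
    null homozygotes (probability r^2) as blanks.  SAD: in a heterozygote the
    longer allele drops with probability ``sad_rate * size_diff/size_range``.
    Stuttering: heterozygotes one repeat apart miscalled as homozygous for
    the shorter allele with probability ``stutter_rate``.
    """
    rng = np.random.default_rng(config.seed + 7_654_321)
    alle = table.alleles.copy()
    truth = TruthRecord(config=asdict(config))
    nulls = config.null_freqs()
    n, L, _ = alle.shape
    for j in range(L):
        typed = alle[:, j, 0] != 0
        if not typed.any():
            continue
        r = nulls[j]
        if r > 0:
            null1 = (rng.random(n) < r) & typed
            null2 = (rng.random(n) < r) & typed
            both = null1 & null2
            one = (null1 ^ null2)
            # visible copy of a half-null heterozygote duplicates
            keep_second = null1 & ~null2
            vis = np.where(keep_second, alle[:, j, 1], alle[:, j, 0])
            alle[one, j, 0] = vis[one]
            alle[one, j, 1] = vis[one]
            alle[both, j, :] = 0
            truth.null_events += int(one.sum())
            truth.blank_events += int(both.sum())
            typed = alle[:, j, 0] != 0
        if config.sad_rate > 0:
            sizes = alle[:, j, :]
            het = typed & (sizes[:, 0] != sizes[:, 1])
            obs = np.unique(sizes[typed])
            rng_span = float(obs.max() - obs.min()) if len(obs) > 1 else 1.0
            diff = (sizes[:, 1] - sizes[:, 0]).astype(float)
            pdrop = config.sad_rate * np.where(het, diff / max(rng_span, 1.0), 0.0)
            drop = het & (rng.random(n) < pdrop)
            alle[drop, j, 1] = alle[drop, j, 0]
            truth.sad_events += int(drop.sum())
        if config.stutter_rate > 0:
            sizes = alle[:, j, :]
            het1 = typed & (sizes[:, 1] - sizes[:, 0] == config.motif_len)
            hit = het1 & (rng.random(n) < config.stutter_rate)
            alle[hit, j, 1] = alle[hit, j, 0]
            truth.stutter_events += int(hit.sum())
        if config.miss_rate > 0:
            typed = alle[:, j, 0] != 0
            fail = typed & (rng.random(n) < config.miss_rate)
            alle[fail, j, :] = 0
            truth.blank_events += int(fail.sum())
    out = GenotypeTable(table.ids, table.sites, table.loci, alle,
                        provenance=table.provenance + "+corrupted")
    return out, truth


def inject_clones(table: GenotypeTable, n_pairs: int, seed: int = 0) -> tuple[GenotypeTable, TruthRecord]:
    """Duplicate ``n_pairs`` randomly chosen individuals within their sites.

    The duplicate is inserted right after the original with an adjacent
    ``-b`` id suffix, emulating field resampling of the same genet under
    sequential sample numbers.
    """
    if n_pairs > table.n_individuals:
        raise ValueError("n_pairs exceeds number of individuals")
    truth = TruthRecord()
    if n_pairs == 0:
        return table, truth
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(table.n_individuals, size=n_pairs, replace=False))
    ids, sites, rows = [], [], []
    for i in range(table.n_individuals):
        ids.append(table.ids[i])
        sites.append(table.sites[i])
        rows.append(table.alleles[i])
        if i in chosen:
            ids.append(table.ids[i] + "-b")
            sites.append(table.sites[i])
            rows.append(table.alleles[i].copy())
            truth.clone_pairs.append((table.ids[i], table.ids[i] + "-b"))
    out = GenotypeTable(ids, sites, table.loci, np.array(rows),
                        provenance=table.provenance + "+clones")
    return out, truth
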