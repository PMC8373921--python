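"""Genotype containers and standard-format I/O.

Diploid multilocus microsatellite genotypes are held in a
:class:`GenotypeTable`: one row per individual, one column per locus, each
cell an unordered pair of positive integer allele codes (fragment sizes in bp
or repeat indices) or missing.  Site metadata (site -> sea -> basin plus
WGS84 coordinates) lives in a :class:`SiteHierarchy`.

Supported exchange formats: Genepop text files (2- or 3-digit concatenated
diploid codes, all-zero code = missing, POP-delimited) and a long-format CSV
(individual, site, locus, allele1, allele2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = 0  # sentinel allele code for an untyped call (both slots zero)

__all__ = [
    "MISSING",
    "GenotypeTable",
    "SiteHierarchy",
    "GenepopParseError",
    "GenepopEncodeError",
    "read_genepop",
    "write_genepop",
    "read_long_csv",
    "write_long_csv",
    "load_site_metadata",
    "filter_min_loci",
]


class GenepopParseError(ValueError):
    """Raised when a Genepop file cannot be parsed; message names the line."""


class GenepopEncodeError(ValueError):
    """Raised when allele codes do not fit the requested digit width."""


@dataclass
class GenotypeTable:
    """Individuals x loci diploid genotype matrix.

    Parameters
    ----------
    ids
        Individual identifiers, one per row.
    sites
        Site label of each individual (parallel to ``ids``).
    loci
        Ordered locus names.
    alleles
        Integer array of shape ``(n_individuals, n_loci, 2)``.  A typed call
        holds two positive allele codes sorted ascending; an untyped call is
        ``(0, 0)``.
    provenance
        Free-text source tag.
    """

    ids: list[str]
    sites: list[str]
    loci: list[str]
    alleles: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        n, L = len(self.ids), len(self.loci)
        if n < 1 or L < 1:
            raise ValueError("GenotypeTable needs at least 1 individual and 1 locus")
        if len(self.sites) != n:
            raise ValueError("ids and sites must have equal length")
        if self.alleles.shape != (n, L, 2):
            raise ValueError(
                f"alleles shape {self.alleles.shape} != ({n}, {L}, 2)"
            )
        if np.any(self.alleles < 0):
            raise ValueError("allele codes must be positive (0 = missing)")
        half = (self.alleles == MISSING).sum(axis=2) == 1
        if np.any(half):
            raise ValueError("single-allele calls are invalid (exactly 0 or 2 codes)")
        # unordered pairs: store sorted ascending so phase is never implied
        self.alleles = np.sort(self.alleles, axis=2)

    # -- convenience views -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def typed(self) -> np.ndarray:
        """Boolean (n, L) mask of non-missing calls."""
        return self.alleles[:, :, 0] != MISSING

    @property
    def heterozygous(self) -> np.ndarray:
        """Boolean (n, L) mask: typed and two distinct alleles."""
        return self.typed & (self.alleles[:, :, 0] != self.alleles[:, :, 1])

    def site_labels(self) -> list[str]:
        """Distinct site labels in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.sites:
            seen.setdefault(s)
        return list(seen)

    def site_mask(self, site: str) -> np.ndarray:
        return np.array([s == site for s in self.sites])

    def subset(self, row_mask: np.ndarray, provenance: str | None = None) -> "GenotypeTable":
        idx = np.flatnonzero(np.asarray(row_mask))
        return GenotypeTable(
            ids=[self.ids[i] for i in idx],
            sites=[self.sites[i] for i in idx],
            loci=list(self.loci),
            alleles=self.alleles[idx].copy(),
            provenance=self.provenance if provenance is None else provenance,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.ids == other.ids
            and self.sites == other.sites
            and self.loci == other.loci
            and np.array_equal(self.alleles, other.alleles)
        )


@dataclass
class SiteHierarchy:
    """Site -> sea -> basin hierarchy with WGS84 coordinates.

    ``table`` has columns site, sea, basin, lat, lon (one row per site).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = ["site", "sea", "basin", "lat", "lon"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"site metadata missing columns: {missing}")
        t = self.table.loc[:, required].copy()
        t["site"] = t["site"].astype(str)
        t["sea"] = t["sea"].astype(str)
        t["basin"] = t["basin"].astype(str)
        t["lat"] = t["lat"].astype(float)
        t["lon"] = t["lon"].astype(float)
        if t["site"].duplicated().any():
            dup = t.loc[t["site"].duplicated(), "site"].tolist()
            raise ValueError(f"duplicate site labels: {dup}")
        if ((t["lat"] < -90) | (t["lat"] > 90)).any():
            raise ValueError("latitude out of [-90, 90]")
        if ((t["lon"] < -180) | (t["lon"] > 180)).any():
            raise ValueError("longitude out of [-180, 180]")
        sea_basins = t.groupby("sea")["basin"].nunique()
        bad = sea_basins[sea_basins > 1]
        if len(bad):
            raise ValueError(f"sea mapped to more than one basin: {list(bad.index)}")
        self.table = t.reset_index(drop=True)

    @property
    def sites(self) -> list[str]:
        return self.table["site"].tolist()

    def sea_of(self, site: str) -> str:
        row = self.table.loc[self.table["site"] == site]
        if row.empty:
            raise KeyError(f"unknown site {site!r}")
        return row["sea"].iloc[0]

    def basin_of(self, site: str) -> str:
        row = self.table.loc[self.table["site"] == site]
        if row.empty:
            raise KeyError(f"unknown site {site!r}")
        return row["basin"].iloc[0]

    def coords(self) -> pd.DataFrame:
        return self.table.set_index("site")[["lat", "lon"]]


# ---------------------------------------------------------------------------
# Genepop format
# ---------------------------------------------------------------------------

_SITE_MARKER = "[sites:"


def read_genepop(path, allele_digits: int = 3, pop_labels: list[str] | None = None) -> GenotypeTable:
    """Read a Genepop text file.

    The all-zero code (``000`` / ``00``) decodes to missing.  Site labels are
    taken, in order of preference, from ``pop_labels``, from a
    ``[sites: a|b|c]`` marker that :func:`write_genepop` embeds in the title
    line, or from the Genepop convention of naming each POP after its last
    individual.
    """
    if allele_digits not in (2, 3):
        raise ValueError("allele_digits must be 2 or 3")
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GenepopParseError("empty file")
    title = lines[0]
    embedded_sites: list[str] | None = None
    if _SITE_MARKER in title:
        frag = title[title.index(_SITE_MARKER) + len(_SITE_MARKER):]
        frag = frag.split("]", 1)[0]
        embedded_sites = [s.strip() for s in frag.split("|")]

    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        line = lines[i].strip()
        if not line:
            raise GenepopParseError(f"line {i + 1}: blank line in locus list")
        if "," in line:
            loci.extend(x.strip() for x in line.split(",") if x.strip())
        else:
            loci.append(line)
        i += 1
    if i == len(lines):
        raise GenepopParseError("no POP separator found")
    if not loci:
        raise GenepopParseError("no locus names before first POP")

    pops: list[list[tuple[str, list[tuple[int, int]]]]] = []
    current: list[tuple[str, list[tuple[int, int]]]] | None = None
    for lineno in range(i, len(lines)):
        raw = lines[lineno]
        line = raw.strip()
        if not line:
            continue
        if line.upper() == "POP":
            current = []
            pops.append(current)
            continue
        if current is None:  # pragma: no cover - guarded above
            raise GenepopParseError(f"line {lineno + 1}: data before first POP")
        if "," not in line:
            raise GenepopParseError(f"line {lineno + 1}: missing ',' after individual name")
        name, geno = line.split(",", 1)
        fields = geno.split()
        if len(fields) != len(loci):
            raise GenepopParseError(
                f"line {lineno + 1}: {len(fields)} genotype fields, expected {len(loci)}"
            )
        calls: list[tuple[int, int]] = []
        for f in fields:
            if len(f) != 2 * allele_digits:
                raise GenepopParseError(
                    f"line {lineno + 1}: genotype field {f!r} is not "
                    f"{2 * allele_digits} digits"
                )
            try:
                a = int(f[:allele_digits])
                b = int(f[allele_digits:])
            except ValueError as exc:
                raise GenepopParseError(f"line {lineno + 1}: non-numeric field {f!r}") from exc
            if (a == 0) != (b == 0):
                raise GenepopParseError(
                    f"line {lineno + 1}: half-missing genotype {f!r} is invalid"
                )
            calls.append((a, b))
        current.append((name.strip(), calls))

    if any(len(p) == 0 for p in pops):
        raise GenepopParseError("empty POP block")

    if pop_labels is not None:
        if len(pop_labels) != len(pops):
            raise ValueError("pop_labels length does not match number of POP blocks")
        labels = list(pop_labels)
    elif embedded_sites is not None and len(embedded_sites) == len(pops):
        labels = embedded_sites
    else:
        labels = [p[-1][0] for p in pops]

    ids: list[str] = []
    sites: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    for label, pop in zip(labels, pops):
        for name, calls in pop:
            ids.append(name)
            sites.append(label)
            rows.append(calls)
    alleles = np.array(rows, dtype=np.int64)
    return GenotypeTable(ids=ids, sites=sites, loci=loci, alleles=alleles,
                         provenance=str(path))


def write_genepop(table: GenotypeTable, path, allele_digits: int = 3,
                  title: str | None = None) -> None:
    """Write a Genepop file; missing calls become the all-zero code.

    The site labels are embedded in the title line (``[sites: ...]``) so that
    :func:`read_genepop` round-trips the table exactly.
    """
    if allele_digits not in (2, 3):
        raise ValueError("allele_digits must be 2 or 3")
    limit = 10 ** allele_digits
    if int(table.alleles.max(initial=0)) >= limit:
        raise GenepopEncodeError(
            f"allele code {int(table.alleles.max())} does not fit in "
            f"{allele_digits} digits"
        )
    site_order = table.site_labels()
    marker = _SITE_MARKER + " " + "|".join(site_order) + "]"
    head = title if title is not None else (table.provenance or "msatpop export")
    out = [f"{head} {marker}"]
    out.extend(table.loci)
    for site in site_order:
        out.append("POP")
        for i in np.flatnonzero(table.site_mask(site)):
            parts = [
                f"{a:0{allele_digits}d}{b:0{allele_digits}d}"
                for a, b in table.alleles[i]
            ]
            out.append(f"{table.ids[i]} , " + " ".join(parts))
    with open(path, "w") as fh:
        fh.write("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Long-format CSV (individual, site, locus, allele1, allele2)
# ---------------------------------------------------------------------------

def write_long_csv(table: GenotypeTable, path) -> None:
    recs = []
    for i, (ind, site) in enumerate(zip(table.ids, table.sites)):
        for j, locus in enumerate(table.loci):
            a, b = table.alleles[i, j]
            recs.append((ind, site, locus, int(a), int(b)))
    pd.DataFrame(recs, columns=["individual", "site", "locus", "allele1", "allele2"]) \
        .to_csv(path, index=False)


def read_long_csv(path) -> GenotypeTable:
    df = pd.read_csv(path, dtype={"individual": str, "site": str, "locus": str})
    required = ["individual", "site", "locus", "allele1", "allele2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"long CSV missing columns: {missing}")
    loci = list(dict.fromkeys(df["locus"]))
    inds = list(dict.fromkeys(zip(df["individual"], df["site"])))
    locus_idx = {l: j for j, l in enumerate(loci)}
    ind_idx = {key: i for i, key in enumerate(inds)}
    alleles = np.zeros((len(inds), len(loci), 2), dtype=np.int64)
    for row in df.itertuples(index=False):
        i = ind_idx[(row.individual, row.site)]
        j = locus_idx[row.locus]
        alleles[i, j] = (int(row.allele1), int(row.allele2))
    return GenotypeTable(
        ids=[k[0] for k in inds],
        sites=[k[1] for k in inds],
        loci=loci,
        alleles=alleles,
        provenance=str(path),
    )


def load_site_metadata(path) -> SiteHierarchy:
    """Load and validate a site metadata CSV (site, sea, basin, lat, lon)."""
    return SiteHierarchy(pd.read_csv(path))


def filter_min_loci(table: GenotypeTable, min_loci: int) -> tuple[GenotypeTable, int]:
    """Keep individuals typed at ``min_loci`` loci or more.

    Returns the filtered table and the number of removed individuals.
    Raises if nothing survives.
    """
    if not 1 <= min_loci <= table.n_loci:
        raise ValueError("min_loci must be in [1, n_loci]")
    keep = table.typed.sum(axis=1) >= min_loci
    removed = int((~keep).sum())
    if not keep.any():
        raise ValueError("filter_min_loci removed every individual")
    if removed == 0:
        return table, 0
    return table.subset(keep), removed
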