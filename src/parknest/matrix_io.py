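"""Reading, validating, subsetting and ordering community matrices.

The central container is :class:`CommunityMatrix`, a labelled species x sites
abundance matrix. Species are held in rows internally regardless of the
orientation of the input file; all downstream metrics assume this convention.

Companion tables:

* :class:`SiteAttributes` — park (site) areas in hectares,
* a *group table* classifying each species (passerine / resident / diet
  guild / waterbird flag),
* a *trait table* of continuous species traits (body size, wing length).

Group and trait tables are plain :class:`pandas.DataFrame` objects indexed by
species id; see :func:`read_group_table` and :func:`read_trait_table` for the
expected columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("parknest")

#: diet guilds accepted in a group table
DIET_GUILDS = frozenset(
    {"insectivorous", "omnivorous", "carnivorous", "nectarivorous", "granivorous", "other"}
)

#: species groups that carry enough species to be analysed for nestedness
ANALYZABLE_GROUPS = ("all", "passerine", "resident", "insectivorous", "omnivorous")

#: recognised row/column ordering specifications
ORDERINGS = ("marginal_totals_desc", "external_attribute_desc", "given")


class MatrixError(ValueError):
    """Invalid community matrix (labels, shapes or cell values)."""


class InsufficientGroupError(ValueError):
    """A species-group subset is too small (or not analysable) for nestedness."""


class MissingAttributeError(KeyError):
    """An external ordering attribute is missing for some matrix label."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CommunityMatrix:
    """Labelled non-negative integer abundance matrix, species in rows.

    Parameters
    ----------
    data:
        DataFrame with species ids as the index and site ids as columns.
        Cells are non-negative integer abundances.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dupes = sorted(df.index[df.index.duplicated()].unique())
            raise MatrixError(f"duplicate species labels: {dupes}")
        if df.columns.has_duplicates:
            dupes = sorted(df.columns[df.columns.duplicated()].unique())
            raise MatrixError(f"duplicate site labels: {dupes}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = _first_non_numeric(df)
            raise MatrixError(f"non-numeric cell at {bad}")
        if np.isnan(values.astype(float)).any():
            bad = _first_nan(df)
            raise MatrixError(f"missing/non-numeric cell at {bad}")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise MatrixError(
                f"negative abundance at (species={df.index[i]!r}, site={df.columns[j]!r})"
            )
        if not np.allclose(values, np.round(values)):
            i, j = np.argwhere(~np.isclose(values, np.round(values)))[0]
            raise MatrixError(
                f"non-integer abundance at (species={df.index[i]!r}, site={df.columns[j]!r})"
            )
        object.__setattr__(self, "data", df.astype(np.int64))

    # -- basic views --------------------------------------------------------

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def species_ids(self) -> list:
        return list(self.data.index)

    @property
    def site_ids(self) -> list:
        return list(self.data.columns)

    @property
    def n_species(self) -> int:
        return self.data.shape[0]

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    @property
    def grand_total(self) -> int:
        """N — total number of individuals."""
        return int(self.values.sum())

    @property
    def fill(self) -> int:
        """F — number of non-zero cells."""
        return int((self.values > 0).sum())

    def species_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def site_totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    def site_richness(self) -> pd.Series:
        """Observed species richness per site."""
        return (self.data > 0).sum(axis=0)

    def binary(self) -> np.ndarray:
        """Presence/absence view (presence = abundance > 0)."""
        return (self.values > 0).astype(np.int64)

    def drop_empty_species(self) -> "CommunityMatrix":
        """Drop all-zero species rows (a species observed nowhere carries no
        information for nestedness); all-zero sites are kept."""
        empty = self.data.sum(axis=1) == 0
        if empty.any():
            logger.warning(
                "dropping %d all-zero species row(s): %s",
                int(empty.sum()),
                list(self.data.index[empty]),
            )
            return CommunityMatrix(self.data.loc[~empty])
        return self

    def with_values(self, values: np.ndarray) -> "CommunityMatrix":
        """Same labels, new cell values (used by null-model generators)."""
        return CommunityMatrix(
            pd.DataFrame(values, index=self.data.index, columns=self.data.columns)
        )


@dataclass(frozen=True)
class SiteAttributes:
    """Site areas in hectares, indexed by site id."""

    area: pd.Series

    def __post_init__(self) -> None:
        s = pd.Series(self.area, dtype=float)
        if s.index.has_duplicates:
            raise MatrixError("duplicate site labels in site attributes")
        if (s <= 0).any() or s.isna().any():
            bad = list(s.index[(s <= 0) | s.isna()])
            raise MatrixError(f"non-positive or missing area for sites: {bad}")
        object.__setattr__(self, "area", s)

    def aligned_to(self, site_ids: Sequence) -> pd.Series:
        missing = [s for s in site_ids if s not in self.area.index]
        if missing:
            raise MissingAttributeError(f"no area for site(s): {missing}")
        return self.area.loc[list(site_ids)]

    def relative_area(self, site_ids: Sequence | None = None) -> pd.Series:
        a = self.area if site_ids is None else self.aligned_to(site_ids)
        return a / a.sum()


def _first_non_numeric(df: pd.DataFrame) -> str:
    for j, col in enumerate(df.columns):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            return f"(species={df.index[i]!r}, site={col!r})"
    return "(unknown)"


def _first_nan(df: pd.DataFrame) -> str:
    mask = df.isna().to_numpy()
    i, j = np.argwhere(mask)[0]
    return f"(species={df.index[i]!r}, site={df.columns[j]!r})"


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        return pd.read_excel(path, index_col=0, **kwargs)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, index_col=0, sep=sep, **kwargs)


def read_community_matrix(path: str | Path, orientation: str = "species_rows") -> CommunityMatrix:
    """Read a community matrix from delimited text (or a spreadsheet).

    Layout: first column = row labels, first row = column labels. With
    ``orientation="species_rows"`` (default) rows are species; with
    ``"species_cols"`` the table is transposed on read so that species end up
    in rows internally.
    """
    if orientation not in {"species_rows", "species_cols"}:
        raise ValueError(f"orientation must be species_rows/species_cols, got {orientation!r}")
    df = _read_table(path)
    if orientation == "species_cols":
        df = df.T
    m = CommunityMatrix(df)
    logger.info(
        "read community matrix %s: %d species x %d sites, N=%d, fill=%d",
        path, m.n_species, m.n_sites, m.grand_total, m.fill,
    )
    return m


def write_community_matrix(m: CommunityMatrix, path: str | Path) -> None:
    sep = "\t" if Path(path).suffix.lower() in {".tsv", ".tab"} else ","
    m.data.to_csv(path, sep=sep)


def convert_spreadsheet(xlsx_path: str | Path, csv_path: str | Path, **kwargs) -> Path:
    """Convert a spreadsheet matrix to the canonical delimited form."""
    df = pd.read_excel(xlsx_path, index_col=0, **kwargs)
    csv_path = Path(csv_path)
    df.to_csv(csv_path)
    logger.info("converted %s -> %s (%d rows, %d cols)", xlsx_path, csv_path, *df.shape)
    return csv_path


def read_site_attributes(path: str | Path) -> SiteAttributes:
    """Read a site table with columns ``site_id, area`` (area in hectares)."""
    df = _read_table(path)
    col = "area" if "area" in df.columns else df.columns[0]
    return SiteAttributes(df[col].astype(float))


def read_group_table(path: str | Path) -> pd.DataFrame:
    """Read a species group table.

    Expected columns: ``is_passerine``, ``is_resident``, ``diet_guild``,
    ``is_waterbird``; index = species id.
    """
    df = _read_table(path)
    return validate_group_table(df)


def validate_group_table(df: pd.DataFrame) -> pd.DataFrame:
    required = {"is_passerine", "is_resident", "diet_guild", "is_waterbird"}
    missing = required - set(df.columns)
    if missing:
        raise MatrixError(f"group table missing columns: {sorted(missing)}")
    bad = set(df["diet_guild"]) - DIET_GUILDS
    if bad:
        raise MatrixError(f"unknown diet guild(s): {sorted(bad)}")
    out = df.copy()
    for c in ("is_passerine", "is_resident", "is_waterbird"):
        out[c] = out[c].astype(bool)
    return out


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read a continuous trait table (index = species id, one column per trait)."""
    df = _read_table(path)
    if df.shape[1] == 0:
        raise MatrixError("trait table has no trait columns")
    return df.astype(float)


# ---------------------------------------------------------------------------
# subsetting and ordering
# ---------------------------------------------------------------------------


def subset_by_group(m: CommunityMatrix, groups: pd.DataFrame, group: str) -> CommunityMatrix:
    """Restrict a matrix to one analysable species group.

    Waterbirds are always removed first (they were surveyed incidentally and
    excluded from analysis). ``group`` must be one of
    ``all, passerine, resident, insectivorous, omnivorous``; smaller guilds
    (carnivores, nectarivores, granivores, non-passerines, migrants) are not
    analysable due to sample size and are rejected. Sites with zero remaining
    species are retained — zero richness is meaningful.
    """
    if group not in ANALYZABLE_GROUPS:
        raise InsufficientGroupError(
            f"group {group!r} is not analysable; choose one of {ANALYZABLE_GROUPS}"
        )
    unclassified = [s for s in m.species_ids if s not in groups.index]
    if unclassified:
        raise MatrixError(f"species missing from group table: {unclassified}")
    g = groups.loc[m.species_ids]
    keep = ~g["is_waterbird"]
    if group == "passerine":
        keep &= g["is_passerine"]
    elif group == "resident":
        keep &= g["is_resident"]
    elif group in {"insectivorous", "omnivorous"}:
        keep &= g["diet_guild"] == group
    selected = [s for s, k in zip(m.species_ids, keep) if k]
    if len(selected) < 2:
        raise InsufficientGroupError(
            f"group {group!r} retains {len(selected)} species (< 2)"
        )
    logger.info("subset %r: %d of %d species retained", group, len(selected), m.n_species)
    return CommunityMatrix(m.data.loc[selected])


def _desc_order(keys: np.ndarray) -> np.ndarray:
    # stable argsort on negated keys: ties keep input order
    return np.argsort(-np.asarray(keys, dtype=float), kind="stable")


def order_matrix(
    m: CommunityMatrix,
    row_key: str = "marginal_totals_desc",
    col_key: str = "marginal_totals_desc",
    row_attribute: pd.Series | None = None,
    col_attribute: pd.Series | None = None,
) -> CommunityMatrix:
    """Permute rows and columns of a matrix by an ordering specification.

    ``marginal_totals_desc`` sorts by decreasing marginal (abundance) totals,
    ``external_attribute_desc`` by a supplied attribute (e.g. park area),
    ``given`` keeps the current order. Ties are broken by input order (stable).
    A pure permutation: cells, marginals and the grand total are unchanged.
    """
    df = m.data

    def resolve(key: str, labels, attribute, totals) -> np.ndarray:
        if key not in ORDERINGS:
            raise ValueError(f"unknown ordering {key!r}; choose from {ORDERINGS}")
        if key == "given":
            return np.arange(len(labels))
        if key == "marginal_totals_desc":
            return _desc_order(totals)
        if attribute is None:
            raise MissingAttributeError("external_attribute_desc needs an attribute series")
        missing = [l for l in labels if l not in attribute.index]
        if missing:
            raise MissingAttributeError(f"attribute missing for: {missing}")
        return _desc_order(attribute.loc[list(labels)].to_numpy())

    ri = resolve(row_key, df.index, row_attribute, df.sum(axis=1).to_numpy())
    ci = resolve(col_key, df.columns, col_attribute, df.sum(axis=0).to_numpy())
    return CommunityMatrix(df.iloc[ri, ci])
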