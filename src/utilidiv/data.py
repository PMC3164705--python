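"""Tabular domain objects and their CSV serializations.

Four tables drive the analysis:

* :class:`TraitTable` — species x utilitarian-property matrix (two ordinal
  preference ranks, four binary uses).
* :class:`CommunityMatrix` — the species present in one plot; collections of
  these are exchanged as long-form (plot_id, species_id) or wide 0/1 CSV.
* plot covariates — basal area, felled trees, canopy height, distance from
  the nearest village, trails, elevation (one row per plot).
* stem records — individual woody stems with DBH (diameter at 1.3 m), kept
  only above the 10 cm survey inclusion threshold.

Every reader validates fully before returning: a malformed file raises a
typed error from :mod:`utilidiv.errors` and never yields a partial object.
CSV dialect is comma-separated UTF-8 with a header row and "." decimals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ReferentialIntegrityError,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Canonical utilitarian properties. Construction and firewood carry a
#: preference rank (0 = not used, 1 = least, 2 = moderate, 3 = high
#: preference); the remaining four are plain use/non-use indicators.
ORDINAL_PROPERTIES: tuple[str, ...] = ("construction", "firewood")
BINARY_PROPERTIES: tuple[str, ...] = ("medicinal", "food", "tools", "furniture")
PROPERTIES: tuple[str, ...] = ORDINAL_PROPERTIES + BINARY_PROPERTIES

ORDINAL_LEVELS = (0, 1, 2, 3)

COVARIATE_COLUMNS: tuple[str, ...] = (
    "basal_area",
    "felled_trees",
    "canopy_height",
    "distance_village",
    "trails",
    "elevation",
)

DBH_MIN_CM = 10.0  # survey inclusion rule: stems > 10 cm DBH


@dataclass(frozen=True)
class TraitTable:
    """Species x utilitarian-property table, the Gower input.

    ``data`` is indexed by species_id (row order is the canonical pool
    order); ``ordinal`` / ``binary`` name which columns are rank-scaled
    versus 0/1. The canonical six-property schema is the default, but a
    reduced table (e.g. after removing one property for the importance
    analysis) is a first-class object.
    """

    data: pd.DataFrame
    ordinal: tuple[str, ...] = ORDINAL_PROPERTIES
    binary: tuple[str, ...] = BINARY_PROPERTIES

    def __post_init__(self) -> None:
        validate_trait_frame(self.data, self.ordinal, self.binary)

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def properties(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def n_species(self) -> int:
        return len(self.data)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def drop_property(self, name: str) -> "TraitTable":
        """Return a new table without ``name`` (for removal analyses)."""
        if name not in self.data.columns:
            raise SchemaError(f"no such property: {name!r}")
        remaining = [c for c in self.data.columns if c != name]
        if not remaining:
            raise SchemaError("cannot drop the last property")
        return TraitTable(
            self.data[remaining].copy(),
            ordinal=tuple(c for c in self.ordinal if c != name),
            binary=tuple(c for c in self.binary if c != name),
        )


def validate_trait_frame(
    frame: pd.DataFrame,
    ordinal: tuple[str, ...],
    binary: tuple[str, ...],
) -> None:
    expected = list(ordinal) + list(binary)
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise SchemaError(f"trait table missing columns: {missing}")
    extra = [c for c in frame.columns if c not in expected]
    if extra:
        raise SchemaError(f"trait table has undeclared columns: {extra}")
    if len(frame) < 2:
        raise SchemaError("trait table needs at least 2 species")
    ids = frame.index
    if ids.has_duplicates:
        dupes = ids[ids.duplicated()].unique().tolist()
        raise SchemaError(f"duplicate species_id: {dupes}")
    if any(not isinstance(s, str) or not s for s in ids):
        raise SchemaError("species_id values must be non-empty strings")
    if frame.isna().any().any():
        bad = frame.columns[frame.isna().any()].tolist()
        raise ValidationError(f"missing trait values in columns {bad}")
    for col in expected:
        vals = frame[col]
        if not np.all(vals == vals.astype(int)):
            raise ValidationError(f"non-integer value in column {col!r}")
        allowed = ORDINAL_LEVELS if col in ordinal else (0, 1)
        bad_mask = ~vals.isin(allowed)
        if bad_mask.any():
            row = int(np.flatnonzero(bad_mask.to_numpy())[0])
            raise ValidationError(
                f"value {vals.iloc[row]} outside {allowed} in column {col!r}, "
                f"row {row + 1} (species {ids[row]!r})"
            )


@dataclass(frozen=True)
class CommunityMatrix:
    """The species present in one plot (presence only; no abundance)."""

    plot_id: str
    members: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.plot_id:
            raise SchemaError("plot_id must be non-empty")
        if len(self.members) < 1:
            raise SchemaError(f"plot {self.plot_id!r} has no members")

    @property
    def richness(self) -> int:
        return len(self.members)


def _check_membership(communities: list[CommunityMatrix], traits: TraitTable) -> None:
    pool = set(traits.species)
    for com in communities:
        unknown = sorted(com.members - pool)
        if unknown:
            raise ReferentialIntegrityError(
                f"plot {com.plot_id!r} lists species absent from the trait "
                f"table: {unknown}"
            )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, dtype={0: str})
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty CSV: {path}") from exc


def read_trait_table(path) -> TraitTable:
    """Load and validate a traits CSV (species_id + the six properties)."""
    raw = _read_csv(path)
    if "species_id" not in raw.columns:
        raise SchemaError("traits CSV must have a species_id column")
    frame = raw.set_index("species_id")
    for col in frame.columns:
        frame[col] = pd.to_numeric(frame[col], errors="raise")
    return TraitTable(frame)


def write_trait_table(traits: TraitTable, path) -> None:
    traits.data.to_csv(path, index_label="species_id")


def read_community_matrix(path, traits: TraitTable, wide: bool = False) -> list[CommunityMatrix]:
    """Load plot memberships from long-form (plot_id, species_id) or wide 0/1 CSV.

    Plot order follows first appearance in the file; every member must occur
    in ``traits``.
    """
    raw = _read_csv(path)
    communities: list[CommunityMatrix] = []
    if wide:
        if raw.columns[0] != "plot_id":
            raise SchemaError("wide community CSV must start with plot_id")
        frame = raw.set_index("plot_id")
        bad = frame.columns[~frame.isin([0, 1]).all()].tolist()
        if bad:
            raise ValidationError(f"wide community matrix has non-0/1 entries in {bad}")
        for plot_id, row in frame.iterrows():
            members = frozenset(frame.columns[row.to_numpy(dtype=int) == 1])
            communities.append(CommunityMatrix(str(plot_id), members))
    else:
        required = {"plot_id", "species_id"}
        if not required.issubset(raw.columns):
            raise SchemaError(f"long community CSV needs columns {sorted(required)}")
        for plot_id, group in raw.groupby("plot_id", sort=False):
            members = frozenset(str(s) for s in group["species_id"])
            communities.append(CommunityMatrix(str(plot_id), members))
    _check_membership(communities, traits)
    return communities


def write_community_matrix(communities: list[CommunityMatrix], path) -> None:
    """Write long-form plot_id,species_id rows (members in sorted order)."""
    rows = [
        {"plot_id": c.plot_id, "species_id": s}
        for c in communities
        for s in sorted(c.members)
    ]
    pd.DataFrame(rows, columns=["plot_id", "species_id"]).to_csv(path, index=False)


def read_covariates(path) -> pd.DataFrame:
    """Load the plot covariate table (one row per plot, six numeric columns)."""
    raw = _read_csv(path)
    if "plot_id" not in raw.columns:
        raise SchemaError("covariates CSV must have a plot_id column")
    missing = [c for c in COVARIATE_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"covariates CSV missing columns: {missing}")
    frame = raw.set_index("plot_id")[list(COVARIATE_COLUMNS)]
    if frame.index.has_duplicates:
        raise SchemaError("duplicate plot_id in covariates")
    for col in COVARIATE_COLUMNS:
        try:
            frame[col] = pd.to_numeric(frame[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"non-numeric covariate in column {col!r}") from exc
    if frame.isna().any().any():
        bad = frame.columns[frame.isna().any()].tolist()
        raise ValidationError(f"missing covariate values in columns {bad}")
    if (frame["basal_area"] < 0).any():
        raise ValidationError("negative basal_area")
    if (frame["canopy_height"] <= 0).any():
        raise ValidationError("canopy_height must be positive")
    for col in ("felled_trees", "distance_village", "trails"):
        if (frame[col] < 0).any():
            raise ValidationError(f"negative {col}")
    return frame


def write_covariates(covariates: pd.DataFrame, path) -> None:
    covariates.to_csv(path, index_label="plot_id")


def read_stems(path) -> pd.DataFrame:
    """Load stem records; stems at or below 10 cm DBH are dropped with a logged count."""
    raw = _read_csv(path)
    required = {"plot_id", "species_id", "dbh"}
    if not required.issubset(raw.columns):
        raise SchemaError(f"stems CSV needs columns {sorted(required)}")
    frame = raw[["plot_id", "species_id", "dbh"]].copy()
    frame["plot_id"] = frame["plot_id"].astype(str)
    frame["species_id"] = frame["species_id"].astype(str)
    try:
        frame["dbh"] = pd.to_numeric(frame["dbh"], errors="raise")
    except (ValueError, TypeError) as exc:
        raise ValidationError("non-numeric dbh") from exc
    if frame["dbh"].isna().any():
        raise ValidationError("missing dbh values")
    keep = frame["dbh"] > DBH_MIN_CM
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning(
            "excluded %d stems with DBH <= %.0f cm (survey inclusion rule)",
            n_dropped,
            DBH_MIN_CM,
        )
    out = frame[keep].reset_index(drop=True)
    return out


def write_stems(stems: pd.DataFrame, path) -> None:
    stems.to_csv(path, index=False)
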