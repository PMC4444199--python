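"""Community and land-cover table I/O.

The table dialects mirror the supplementary CSV layout of paired-census bird
surveys: a community table has a site-identifier first column and one 0/1
column per species code; a land-cover table has a site-identifier column,
longitude/latitude, hedgerow length (m) and five percentage covers of the
125 m-radius census buffer (woodland, wooded fallow, juniper fallow,
permanent grassland, crop).  Percentages need not sum to 100 — unmapped
covers (housing, roads) exist — but may not exceed it by more than a small
tolerance.

A semicolon dialect is accepted for French-locale exports.  Readers take an
optional column mapping because header spellings vary between exports.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CommunityMatrix",
    "LandCoverTable",
    "FormatError",
    "read_community",
    "write_community",
    "read_landcover",
    "write_landcover",
    "align_censuses",
    "drop_empty_either",
    "write_run_manifest",
    "LANDCOVER_VARIABLES",
    "PERCENT_VARIABLES",
]

#: the six land-cover predictors, in reporting order
LANDCOVER_VARIABLES = (
    "hedgerow",
    "woodland",
    "wooded_fallow",
    "juniper_fallow",
    "grassland",
    "crop",
)
#: the five that are percentages of the buffer (hedgerow is a length in m)
PERCENT_VARIABLES = LANDCOVER_VARIABLES[1:]


class FormatError(ValueError):
    """A table violates the expected dialect (non-binary cell, duplicate id, ...)."""


@dataclass(frozen=True)
class CommunityMatrix:
    """Sites × species boolean occurrence table for one census."""

    site_ids: tuple
    species_ids: tuple
    occ: np.ndarray  # bool, shape (n_sites, n_species)
    census_label: str = ""

    def __post_init__(self):
        occ = np.asarray(self.occ, dtype=bool)
        object.__setattr__(self, "occ", occ)
        object.__setattr__(self, "site_ids", tuple(self.site_ids))
        object.__setattr__(self, "species_ids", tuple(self.species_ids))
        if occ.shape != (len(self.site_ids), len(self.species_ids)):
            raise FormatError(
                f"occurrence shape {occ.shape} does not match "
                f"{len(self.site_ids)} sites x {len(self.species_ids)} species"
            )
        if len(set(self.site_ids)) != len(self.site_ids):
            raise FormatError("duplicate site identifiers")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise FormatError("duplicate species identifiers")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def richness(self) -> np.ndarray:
        """Per-site species counts."""
        return self.occ.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.occ.astype(int), index=list(self.site_ids), columns=list(self.species_ids)
        )


@dataclass(frozen=True)
class LandCoverTable:
    """Per-site land-cover state at one date."""

    frame: pd.DataFrame  # index: site ids; columns: longitude, latitude, six covers
    census_label: str = ""

    def __post_init__(self):
        missing = [v for v in LANDCOVER_VARIABLES if v not in self.frame.columns]
        if missing:
            raise FormatError(f"land-cover table missing columns: {missing}")
        if self.frame.index.has_duplicates:
            raise FormatError("duplicate site identifiers in land-cover table")
        pct = self.frame[list(PERCENT_VARIABLES)].to_numpy(float)
        if (pct < 0).any() or (pct > 100).any():
            raise FormatError("percentage covers must lie in [0, 100]")
        if (self.frame["hedgerow"].to_numpy(float) < 0).any():
            raise FormatError("hedgerow length must be non-negative")
        if (pct.sum(axis=1) > 100 + 1e-6).any():
            raise FormatError("percentage covers sum to more than 100 at some site")

    @property
    def site_ids(self) -> tuple:
        return tuple(self.frame.index)


def _read_table(path, dialect: str) -> pd.DataFrame:
    sep = {"comma": ",", "semicolon": ";"}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}; use 'comma' or 'semicolon'")
    return pd.read_csv(path, sep=sep, index_col=0)


def read_community(path, dialect: str = "comma", census_label: str = "") -> CommunityMatrix:
    """Read a site × species 0/1 CSV, validating every cell.

    Raises :class:`FormatError` naming the offending site/species for any cell
    that is not exactly 0 or 1, and for duplicate site ids.
    """
    df = _read_table(path, dialect)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].tolist()
        raise FormatError(f"duplicate site id(s) {dup} in {path}")
    vals = df.to_numpy()
    bad = ~np.isin(vals, [0, 1])
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise FormatError(
            f"non-binary cell {vals[i, j]!r} at site {df.index[i]!r}, "
            f"species {df.columns[j]!r} in {path}"
        )
    return CommunityMatrix(
        site_ids=tuple(df.index),
        species_ids=tuple(df.columns),
        occ=vals.astype(bool),
        census_label=census_label or str(path),
    )


def write_community(cm: CommunityMatrix, path, dialect: str = "comma") -> None:
    sep = {"comma": ",", "semicolon": ";"}[dialect]
    cm.to_frame().to_csv(path, sep=sep, index_label="site")


def read_landcover(
    path,
    dialect: str = "comma",
    column_map: dict[str, str] | None = None,
    census_label: str = "",
) -> LandCoverTable:
    """Read a land-cover CSV; ``column_map`` renames file headers to canonical names."""
    df = _read_table(path, dialect)
    if column_map:
        df = df.rename(columns=column_map)
    for coord in ("longitude", "latitude"):
        if coord not in df.columns:
            df[coord] = np.nan
    cols = ["longitude", "latitude", *LANDCOVER_VARIABLES]
    return LandCoverTable(frame=df[cols].astype(float), census_label=census_label or str(path))


def write_landcover(lc: LandCoverTable, path, dialect: str = "comma") -> None:
    sep = {"comma": ",", "semicolon": ";"}[dialect]
    lc.frame.to_csv(path, sep=sep, index_label="site")


def align_censuses(
    cm_a: CommunityMatrix, cm_b: CommunityMatrix
) -> tuple[CommunityMatrix, CommunityMatrix]:
    """Restrict two censuses to shared sites and the union of species.

    Site and species order follow the first (earlier) census; species present
    only in the second are appended in their original order, with all-zero
    columns where absent.
    """
    shared = [s for s in cm_a.site_ids if s in set(cm_b.site_ids)]
    if not shared:
        raise ValueError("censuses share no sites")
    species = list(cm_a.species_ids) + [
        sp for sp in cm_b.species_ids if sp not in set(cm_a.species_ids)
    ]

    def _reindex(cm: CommunityMatrix) -> CommunityMatrix:
        df = cm.to_frame().reindex(index=shared, columns=species, fill_value=0)
        return CommunityMatrix(
            site_ids=tuple(shared),
            species_ids=tuple(species),
            occ=df.to_numpy(dtype=bool),
            census_label=cm.census_label,
        )

    return _reindex(cm_a), _reindex(cm_b)


def drop_empty_either(
    cm_a: CommunityMatrix, cm_b: CommunityMatrix
) -> tuple[CommunityMatrix, CommunityMatrix, list]:
    """Remove sites with zero richness in either census.

    Temporal dissimilarity is undefined (null denominator) where an assemblage
    is empty at one of the two dates, so such sites are dropped from both
    matrices.  Returns the two filtered matrices and the removed site ids.
    """
    if cm_a.site_ids != cm_b.site_ids:
        raise ValueError("matrices must be aligned before empty-site removal")
    keep = (cm_a.richness() > 0) & (cm_b.richness() > 0)
    removed = [s for s, k in zip(cm_a.site_ids, keep) if not k]
    kept_ids = tuple(s for s, k in zip(cm_a.site_ids, keep) if k)

    def _take(cm: CommunityMatrix) -> CommunityMatrix:
        return replace(cm, site_ids=kept_ids, occ=cm.occ[keep])

    return _take(cm_a), _take(cm_b), removed


def _checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_run_manifest(path, *, seed, parameters: dict, input_files=()) -> dict:
    """Write a JSON manifest recording seed, parameters and input checksums."""
    import tempbeta

    manifest = {
        "seed": seed,
        "parameters": parameters,
        "inputs": {str(p): _checksum(p) for p in input_files},
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "tempbeta": tempbeta.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
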