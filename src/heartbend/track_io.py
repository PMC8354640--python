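"""Reading, validation, filtering and writing of 3D+t cell-track tables.

A *track* is the time series of one cell's 3D position (in microns) as
exported from a spot-tracking tool (e.g. an Imaris spots/tracks CSV export).
Every point carries an anatomical region label — ``ventricle``, ``avcanal``
or ``atrium`` — assigned once per track from the cell's starting location.

The canonical on-disk format is a UTF-8, RFC-4180 CSV with header::

    track_id,t_index,t_hours,x_um,y_um,z_um,region

Foreign dialects (different column names, capitalised region labels) are
adapted through a :class:`Dialect` column mapping rather than hard-coded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("heartbend.track_io")

#: The exactly-three anatomical regions of the early heart tube.
REGIONS = ("ventricle", "avcanal", "atrium")

VENTRICLE, AVCANAL, ATRIUM = REGIONS

#: Canonical column order of the track CSV.
CANONICAL_COLUMNS = ("track_id", "t_index", "t_hours", "x_um", "y_um", "z_um", "region")

#: Nominal full-stack acquisition period, hours (≈13 min per frame).
DEFAULT_FRAME_PERIOD_HOURS = 13.0 / 60.0

#: Confocal time-lapse voxel size (x, y, z) in microns.
DEFAULT_VOXEL_SIZE_UM = (0.889, 0.889, 2.000)


class TrackSchemaError(ValueError):
    """A required column is missing or a value fails to parse."""


class TrackIntegrityError(ValueError):
    """Structural invariant violated (duplicate timepoint, bad region...)."""


@dataclass(frozen=True)
class Dialect:
    """Column mapping adapting a foreign CSV dialect to the canonical schema.

    ``columns`` maps canonical names to the source file's column names.
    ``t_hours`` may map to ``None`` (synthesized from ``t_index`` ×
    frame period). Region strings are matched case-insensitively when
    ``region_case_insensitive`` is set; ``region_aliases`` maps additional
    source spellings (already lower-cased if case-insensitive) onto one of
    the three canonical labels.
    """

    columns: dict[str, str] = field(
        default_factory=lambda: {c: c for c in CANONICAL_COLUMNS}
    )
    region_case_insensitive: bool = True
    region_aliases: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "Dialect":
        """Load a dialect from a YAML/JSON key-value config file."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        cols = {c: c for c in CANONICAL_COLUMNS}
        cols.update(raw.get("columns", {}))
        return cls(
            columns=cols,
            region_case_insensitive=bool(raw.get("region_case_insensitive", True)),
            region_aliases=dict(raw.get("region_aliases", {})),
        )

    def normalize_region(self, label: str, row: int | None = None) -> str:
        s = str(label).strip()
        if self.region_case_insensitive:
            s = s.lower()
        s = self.region_aliases.get(s, s)
        if s not in REGIONS:
            where = f" (row {row})" if row is not None else ""
            raise TrackIntegrityError(
                f"unknown region label {label!r}{where}; expected one of {REGIONS}"
            )
        return s


@dataclass
class TrackSet:
    """A set of cell tracks: one row per (cell, timepoint) plus metadata.

    ``records`` is a DataFrame with the canonical columns, sorted by
    ``(track_id, t_index)``. Invariants: finite coordinates, region one of
    :data:`REGIONS`, ``(track_id, t_index)`` unique, ``t_index`` strictly
    increasing within each track.
    """

    records: pd.DataFrame
    frame_period_hours: float = DEFAULT_FRAME_PERIOD_HOURS
    voxel_size_um: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_UM
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.frame_period_hours <= 0:
            raise ValueError("frame_period_hours must be positive")
        self.records = _validate_records(self.records)

    # -- convenience accessors -------------------------------------------

    @property
    def n_tracks(self) -> int:
        return self.records["track_id"].nunique()

    @property
    def n_frames(self) -> int:
        return self.records["t_index"].nunique()

    def frames(self) -> np.ndarray:
        """Sorted unique frame indices present in the set."""
        return np.sort(self.records["t_index"].unique())

    def positions(self, mask=None) -> np.ndarray:
        df = self.records if mask is None else self.records[mask]
        return df[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)

    def with_records(self, records: pd.DataFrame) -> "TrackSet":
        return replace(self, records=records.reset_index(drop=True))

    def track_regions(self) -> pd.Series:
        """Region of each track (fixed per track for the whole movie)."""
        return self.records.groupby("track_id", sort=True)["region"].first()


def _validate_records(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrackSchemaError(f"missing column(s): {', '.join(missing)}")
    df = df.loc[:, list(CANONICAL_COLUMNS)].copy()
    df["track_id"] = df["track_id"].astype(str)
    for col in ("t_hours", "x_um", "y_um", "z_um"):
        df[col] = df[col].astype(float)
    df["t_index"] = df["t_index"].astype(np.int64)
    if (df["t_index"] < 0).any():
        raise TrackIntegrityError("negative t_index")
    coords = df[["x_um", "y_um", "z_um", "t_hours"]].to_numpy()
    if not np.isfinite(coords).all():
        bad = int(np.argwhere(~np.isfinite(coords))[0, 0])
        raise TrackIntegrityError(f"non-finite coordinate or time at row {bad}")
    bad_regions = set(df["region"].unique()) - set(REGIONS)
    if bad_regions:
        raise TrackIntegrityError(
            f"unknown region label(s) {sorted(bad_regions)}; expected one of {REGIONS}"
        )
    dup = df.duplicated(subset=["track_id", "t_index"])
    if dup.any():
        tid, ti = df.loc[dup.idxmax(), ["track_id", "t_index"]]
        raise TrackIntegrityError(f"duplicate (track_id, t_index) = ({tid!r}, {ti})")
    df = df.sort_values(["track_id", "t_index"], kind="mergesort").reset_index(drop=True)
    mixed = df.groupby("track_id")["region"].nunique()
    if (mixed > 1).any():
        raise TrackIntegrityError(
            f"track {mixed.idxmax()!r} has multiple region labels; "
            "region is fixed per track"
        )
    return df


def read_tracks(
    path,
    dialect: Dialect | None = None,
    frame_period_hours: float = DEFAULT_FRAME_PERIOD_HOURS,
    provenance: str | None = None,
) -> TrackSet:
    """Read a track CSV into a validated :class:`TrackSet`.

    Missing ``t_hours`` (column mapped to ``None`` or absent) is synthesized
    as ``t_index * frame_period_hours``. Raises :class:`TrackSchemaError`
    for missing columns or unparseable coordinates (naming the row) and
    :class:`TrackIntegrityError` for duplicates or unknown region labels.
    """
    dialect = dialect or Dialect()
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = {}
    for canon in CANONICAL_COLUMNS:
        src = dialect.columns.get(canon, canon)
        if src is None or src not in raw.columns:
            if canon == "t_hours":
                out[canon] = None
                continue
            raise TrackSchemaError(
                f"missing column {src or canon!r} (for canonical field {canon!r})"
            )
        out[canon] = raw[src]
    df = pd.DataFrame({k: v for k, v in out.items() if v is not None})
    for col in ("t_hours", "x_um", "y_um", "z_um"):
        if col not in df.columns:
            continue
        try:
            # astype(float) parses correctly rounded, so full-precision
            # coordinates round-trip bit-comparably (pd.to_numeric does not)
            df[col] = df[col].astype(float)
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce")
            row = int(bad.index[bad.isna()][0])
            raise TrackSchemaError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col!r} "
                f"at data row {row}"
            ) from None
    df["t_index"] = pd.to_numeric(df["t_index"], errors="raise").astype(np.int64)
    if "t_hours" not in df.columns:
        df["t_hours"] = df["t_index"] * frame_period_hours
    df["region"] = [
        dialect.normalize_region(r, row=i) for i, r in enumerate(df["region"])
    ]
    return TrackSet(
        records=df,
        frame_period_hours=frame_period_hours,
        provenance=provenance if provenance is not None else str(path),
    )


def write_tracks(ts: TrackSet, path) -> None:
    """Write a TrackSet as the canonical CSV.

    Coordinates are serialized with Python shortest-repr floats, so
    ``read_tracks(write_tracks(ts))`` reproduces every field bit-comparably.
    """
    df = ts.records.loc[:, list(CANONICAL_COLUMNS)]
    df.to_csv(path, index=False, lineterminator="\n")


def filter_min_length(ts: TrackSet, min_points: int = 15) -> TrackSet:
    """Keep only tracks with at least ``min_points`` acquisition points.

    The default of 15 points is the track-curation threshold used for the
    looping time-lapses. The boundary is inclusive (a 15-point track is
    kept); surviving records are untouched and order-preserved.
    """
    if min_points < 1:
        raise ValueError("min_points must be >= 1")
    counts = ts.records.groupby("track_id")["t_index"].size()
    keep = counts.index[counts >= min_points]
    out = ts.records[ts.records["track_id"].isin(keep)]
    logger.info(
        "filter_min_length(min_points=%d): kept %d / %d tracks",
        min_points, len(keep), len(counts),
    )
    return ts.with_records(out)
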