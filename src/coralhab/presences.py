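"""Species presence records: loading, cleaning, per-cell deduplication.

Multiple records inside one grid cell would weight the habitat model
towards the conditions of that cell, so at most one presence per cell is
retained (stable first-in-input-order tie-break).  Records outside the
analysis area — the set of cells valid in every environmental layer — are
removed, since the model needs a complete covariate vector at every
presence.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GeoTransform, Grid, LayerStack, normalize_lon

__all__ = [
    "PresenceRecord",
    "PresenceSet",
    "load_presences",
    "dedup_and_filter",
    "combine_species",
    "export_swd",
    "read_swd",
    "COMBINED_LABEL",
]

log = logging.getLogger(__name__)

COMBINED_LABEL = "ALL"


@dataclass(frozen=True)
class PresenceRecord:
    species: str
    lon: float
    lat: float

    def __post_init__(self):
        object.__setattr__(self, "lon", float(normalize_lon(self.lon)))
        object.__setattr__(self, "lat", float(self.lat))
        if not -90 <= self.lat <= 90:
            raise ValueError(f"latitude {self.lat} out of range")


@dataclass
class PresenceSet:
    """Deduplicated presences of one species (or the combined set) on a
    reference geotransform: at most one record per cell, every record on a
    valid cell."""

    species: str
    records: list[PresenceRecord]
    reference_geotransform: GeoTransform

    def __len__(self) -> int:
        return len(self.records)

    @property
    def lons(self) -> np.ndarray:
        return np.array([r.lon for r in self.records])

    @property
    def lats(self) -> np.ndarray:
        return np.array([r.lat for r in self.records])

    def cell_indices(self, grid: Grid) -> tuple[np.ndarray, np.ndarray]:
        rows, cols, ok = grid.cell_index_array(self.lons, self.lats)
        if not ok.all():
            raise ValueError("presence set contains records outside the grid extent")
        return rows, cols


def load_presences(path) -> list[PresenceRecord]:
    """Parse a species,lon,lat CSV; rows with unparsable coordinates are
    dropped (and counted in the log)."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    missing = [c for c in ("species", "lon", "lat") if c not in cols]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records = []
    dropped = 0
    for _, row in df.iterrows():
        try:
            lon = float(row[cols["lon"]])
            lat = float(row[cols["lat"]])
            if not (np.isfinite(lon) and np.isfinite(lat)):
                raise ValueError
            records.append(PresenceRecord(str(row[cols["species"]]), lon, lat))
        except (TypeError, ValueError):
            dropped += 1
    if dropped:
        log.info("load_presences: dropped %d rows with unparsable coordinates", dropped)
    log.info("load_presences: %d records loaded from %s", len(records), path)
    return records


def dedup_and_filter(
    records: list[PresenceRecord], stack: LayerStack, species: str | None = None
) -> PresenceSet:
    """Remove records outside the analysis area and deduplicate per cell.

    Removal classes (each logged): outside the stack extent; on a cell
    where any layer is nodata; duplicate within an already-occupied cell
    (first record in input order wins).
    """
    ref = stack.reference
    valid = stack.valid_mask
    kept: list[PresenceRecord] = []
    seen: set[tuple[int, int]] = set()
    n_outside = n_invalid = n_dup = 0
    for rec in records:
        idx = ref.cell_index(rec.lon, rec.lat)
        if idx is None:
            n_outside += 1
            continue
        if not valid[idx]:
            n_invalid += 1
            continue
        if idx in seen:
            n_dup += 1
            continue
        seen.add(idx)
        kept.append(rec)
    label = species if species is not None else (kept[0].species if kept else "")
    log.info(
        "dedup_and_filter[%s]: kept %d of %d (outside extent %d, invalid cell %d, "
        "duplicate cell %d)",
        label, len(kept), len(records), n_outside, n_invalid, n_dup,
    )
    return PresenceSet(label, kept, ref.geotransform)


def combine_species(sets: list[PresenceSet], stack: LayerStack) -> PresenceSet:
    """Union of per-species sets re-deduplicated to one record per cell,
    labelled with the combined-analysis tag."""
    if not sets:
        raise ValueError("no presence sets to combine")
    ref_gt = sets[0].reference_geotransform
    for s in sets[1:]:
        if s.reference_geotransform != ref_gt:
            raise ValueError("presence sets on mismatched geotransforms")
    merged = [rec for s in sets for rec in s.records]
    out = dedup_and_filter(merged, stack, species=COMBINED_LABEL)
    return out


def export_swd(pset: PresenceSet, stack: LayerStack, path) -> None:
    """Write the samples-with-data CSV: species, lon, lat, then one column
    per layer sampled at the record's cell."""
    ref = stack.reference
    rows_idx, cols_idx = pset.cell_indices(ref)
    cov = stack.covariates_at_cells(rows_idx, cols_idx)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["species", "lon", "lat", *stack.names])
        for rec, vals in zip(pset.records, cov):
            writer.writerow(
                [rec.species, repr(rec.lon), repr(rec.lat), *[repr(float(v)) for v in vals]]
            )


def read_swd(path) -> pd.DataFrame:
    """Read a samples-with-data CSV back into a DataFrame."""
    df = pd.read_csv(path)
    if list(df.columns[:3]) != ["species", "lon", "lat"]:
        raise ValueError(f"{path}: not an SWD file (expects species,lon,lat,...)")
    return df
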