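"""From raw circle-year detections to per-decade presence sets.

Implements the survey-data filters of the study design: the 5%
misidentification filter (a species recorded in fewer than 5% of a
circle's surveyed years is treated as absent there), decadal binning to
presence-only records, one-presence-per-grid-cell spatial thinning,
uniform background (pseudo-absence) sampling, and the random 25% test
holdout.

Grid indices are 0-based, row-major, origin at the top-left cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import stream
from .gridio import GridGeometry

__all__ = [
    "DetectionTable",
    "OccurrenceSet",
    "apply_misid_filter",
    "bin_by_decade",
    "thin_to_grid",
    "sample_background",
    "split_train_test",
    "build_occurrence_sets",
]

log = logging.getLogger(__name__)


@dataclass
class DetectionTable:
    """Detection records plus the survey-effort index.

    ``records`` columns: circle_id, species_id, year, detected (bool).
    ``effort`` maps circle_id -> set of years the circle was surveyed
    (a species not detected in a surveyed year is an implicit absence).
    """

    records: pd.DataFrame
    effort: dict[str, set[int]]

    def __post_init__(self) -> None:
        need = {"circle_id", "species_id", "year", "detected"}
        missing = need - set(self.records.columns)
        if missing:
            raise ValueError(f"records missing columns {sorted(missing)}")
        unknown = set(self.records["circle_id"]) - set(self.effort)
        if unknown:
            raise ValueError(
                f"effort index missing circles {sorted(unknown)[:5]}")
        for cid, years in self.effort.items():
            if len(years) == 0:
                raise ValueError(f"circle {cid!r} has zero surveyed years")


@dataclass
class OccurrenceSet:
    """Per-species, per-decade modelling inputs."""

    species_id: str
    decade: str
    presence_cells: np.ndarray            # (n, 2) unique (row, col)
    background_cells: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2), dtype=int))
    train_idx: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    test_idx: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    @property
    def train_cells(self) -> np.ndarray:
        return self.presence_cells[self.train_idx]

    @property
    def test_cells(self) -> np.ndarray:
        return self.presence_cells[self.test_idx]


def apply_misid_filter(table: DetectionTable,
                       threshold: float = 0.05) -> DetectionTable:
    """Drop likely misidentifications.

    For each (circle, species), if detections span strictly fewer than
    ``threshold`` of the circle's *surveyed* years, every detection of
    that pair is treated as absent. Recording exactly the threshold
    fraction retains the pair (the rule is strictly "less than").
    Idempotent: surviving pairs are unchanged.
    """
    rec = table.records
    det = rec[rec["detected"]]
    keep_mask = np.ones(len(rec), dtype=bool)
    n_years = {cid: len(ys) for cid, ys in table.effort.items()}
    frac = (det.groupby(["circle_id", "species_id"])["year"].nunique())
    for (cid, sid), nyr in frac.items():
        if nyr / n_years[cid] < threshold:
            pair = (rec["circle_id"] == cid) & (rec["species_id"] == sid)
            keep_mask &= ~(pair & rec["detected"])
    return DetectionTable(records=rec[keep_mask].reset_index(drop=True),
                          effort=table.effort)


def bin_by_decade(table: DetectionTable,
                  decade_edges: dict[str, tuple[int, int]]) -> pd.DataFrame:
    """Presence-only decadal bins.

    ``decade_edges`` maps a decade label to an inclusive (start, end)
    year range; the ranges must cover every record's year. A circle is a
    presence for a species in a decade iff it has >= 1 surviving
    detection there in that decade; absences are discarded. Returns a
    frame with columns species_id, decade, circle_id.
    """
    det = table.records[table.records["detected"]]
    year = det["year"].to_numpy()
    decade = np.full(len(det), "", dtype=object)
    for label, (lo, hi) in decade_edges.items():
        decade[(year >= lo) & (year <= hi)] = label
    bad = decade == ""
    if bad.any():
        rows = det[bad].head(10)
        raise ValueError(f"years outside all decade bins:\n{rows}")
    out = det.assign(decade=decade)[["species_id", "decade", "circle_id"]]
    return out.drop_duplicates().reset_index(drop=True)


def thin_to_grid(presences: pd.DataFrame, circles: pd.DataFrame,
                 geometry: GridGeometry) -> np.ndarray:
    """Map circle presences to grid cells, one presence per cell.

    Each presence is assigned to the cell containing its circle's
    center; duplicates collapse to a single cell. Presences outside the
    grid extent are dropped with a logged count. Returns (n, 2) unique
    (row, col) sorted cells.
    """
    merged = presences.merge(circles[["circle_id", "row", "col"]],
                             on="circle_id", how="left")
    if merged[["row", "col"]].isna().any().any():
        missing = merged[merged["row"].isna()]["circle_id"].unique()
        raise ValueError(f"presences reference unknown circles {missing[:5]}")
    rows = merged["row"].to_numpy(int)
    cols = merged["col"].to_numpy(int)
    inside = geometry.contains(rows, cols)
    n_dropped = int((~inside).sum())
    if n_dropped:
        log.warning("thin_to_grid: dropped %d presences outside the grid",
                    n_dropped)
    cells = np.unique(np.column_stack([rows[inside], cols[inside]]), axis=0)
    return cells


def sample_background(mask: np.ndarray, n: int = 10000,
                      seed: int | np.random.Generator = 0) -> np.ndarray:
    """Uniform background (pseudo-absence) cells from an extent mask.

    Draws without replacement when the extent has >= n cells, with
    replacement otherwise. Returns (n, 2) (row, col) cells.
    """
    mask = np.asarray(mask, dtype=bool)
    cand = np.argwhere(mask)
    if len(cand) == 0:
        raise ValueError("background extent mask is empty")
    rng = (seed if isinstance(seed, np.random.Generator)
           else stream(seed, "background"))
    replace = len(cand) < n
    idx = rng.choice(len(cand), size=n, replace=replace)
    return cand[idx]


def split_train_test(presences: np.ndarray, test_fraction: float = 0.25,
                     seed: int | np.random.Generator = 0,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Random holdout split of presence indices.

    Test size is round-half-up(test_fraction * n). Returns
    (train_idx, test_idx), a disjoint exhaustive partition of range(n).
    Raises ValueError below 4 presences (the species is un-modelable).
    """
    n = len(presences)
    if n < 4:
        raise ValueError(f"need >= 4 presences to split, got {n}")
    n_test = int(np.floor(test_fraction * n + 0.5))
    rng = (seed if isinstance(seed, np.random.Generator)
           else stream(seed, "split"))
    perm = rng.permutation(n)
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


def build_occurrence_sets(table: DetectionTable,
                          circles: pd.DataFrame,
                          geometry: GridGeometry,
                          decade_edges: dict[str, tuple[int, int]],
                          extent_mask: np.ndarray | None = None,
                          n_background: int = 10000,
                          misid_threshold: float = 0.05,
                          test_fraction: float = 0.25,
                          seed: int = 0,
                          ) -> dict[tuple[str, str], OccurrenceSet]:
    """Full occurrence pipeline: filter, bin, thin, background, split.

    Species-decade pairs with fewer than 4 thinned presences are skipped
    with a logged message. One background sample is drawn per
    species-decade (stream-keyed, so results do not depend on which
    other species are present).
    """
    if extent_mask is None:
        extent_mask = np.ones((geometry.rows, geometry.cols), dtype=bool)
    filtered = apply_misid_filter(table, threshold=misid_threshold)
    binned = bin_by_decade(filtered, decade_edges)
    out: dict[tuple[str, str], OccurrenceSet] = {}
    for (sid, dec), grp in binned.groupby(["species_id", "decade"]):
        cells = thin_to_grid(grp, circles, geometry)
        if len(cells) < 4:
            log.info("skipping %s/%s: %d presences (< 4)", sid, dec,
                     len(cells))
            continue
        bg = sample_background(extent_mask, n=n_background,
                               seed=stream(seed, "background", sid, dec))
        train, test = split_train_test(cells, test_fraction,
                                       seed=stream(seed, "split", sid, dec))
        out[(sid, dec)] = OccurrenceSet(species_id=sid, decade=dec,
                                        presence_cells=cells,
                                        background_cells=bg,
                                        train_idx=train, test_idx=test)
    return out
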