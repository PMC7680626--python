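"""Demographic and environmental covariates for each sampled site.

Builds the four explanatory variables used by the morphology models —
years colonised, latitude, mean temperature during development, and
the 10-year mean annual temperature (T10) — together with the
colonisation-confidence classification based on recorder effort and
emergence-curve estimation of voltinism.

Colonisation year is the first record of the focal species in a 10 km
grid. Because occurrence data reflect recorder effort, each grid-year
is scored "well-recorded" when at least 10% of regional species
richness (the species pool of the 100 nearest neighbouring grids) was
recorded that year; confidence in the colonisation year follows from
how many well-recorded years precede the first record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)

#: First records strictly before this year mark the species' core range.
CORE_RANGE_CUTOFF_YEAR = 1975

#: Minimum count of well-recorded years before first record for a
#: high-confidence colonisation year.
MIN_WELL_RECORDED_PRIOR = 3

#: Fraction of regional richness that must be recorded in a grid-year
#: for it to count as well-recorded (inclusive).
WELL_RECORDED_FRACTION = 0.10

#: Number of nearest neighbouring grids pooled for regional richness.
N_NEIGHBOUR_GRIDS = 100

#: Relative prominence floor for emergence peaks (fraction of the
#: smoothed curve's maximum).
PEAK_HEIGHT_FRACTION = 0.20

STUDY_WINDOW = (1965, 2018)

EARTH_RADIUS_KM = 6371.0


class UnivoltineError(ValueError):
    """Raised when a second generation is required but only one exists."""


@dataclass
class GridCell:
    """A 10 km grid cell with its occurrence records.

    ``records`` is a set of (species, year) pairs: the species observed
    in that grid in that year.
    """

    grid_id: str
    centroid: tuple[float, float]  # (lat, lon) degrees
    records: set[tuple[str, int]] = field(default_factory=set)

    def species_in_year(self, year: int) -> set[str]:
        return {sp for sp, yr in self.records if yr == year}

    def all_species(self) -> set[str]:
        return {sp for sp, _ in self.records}

    def first_record_year(self, species: str) -> int | None:
        years = [yr for sp, yr in self.records if sp == species]
        return min(years) if years else None


@dataclass
class ColonisationAssessment:
    """Colonisation year of a grid with a recorder-effort confidence class."""

    grid_id: str
    first_record_year: int | None
    well_recorded_years: set[int]
    confidence: str  # core | high | low | unoccupied

    def years_colonised_at(self, year: int) -> int:
        if self.first_record_year is None:
            raise ValueError(f"grid {self.grid_id} has no focal record")
        return year - self.first_record_year


@dataclass
class EmergenceCurve:
    """Smoothed seasonal abundance with detected generation peaks."""

    days: np.ndarray       # evaluation grid, day of year
    smoothed: np.ndarray   # fitted abundance on the grid
    peaks: list[int]       # peak days, ascending
    n_generations: int

    @property
    def second_gen_peak_day(self) -> int:
        if self.n_generations < 2:
            raise UnivoltineError(
                "univoltine at this grid: no second-generation peak"
            )
        return self.peaks[1]

    @property
    def second_gen_peak_month(self) -> int:
        return day_of_year_to_month(self.second_gen_peak_day)


@dataclass
class SiteCovariates:
    """The explanatory variables attached to one sampled site."""

    site_id: str
    grid_id: str
    latitude: float
    years_colonised: int
    t10: float
    dev_temp: float
    standardised_collection_date: int
    expansion: str
    confidence: str = "high"


def day_of_year_to_month(day: int) -> int:
    """Calendar month (1-12) containing a day of a non-leap year."""
    cum = np.cumsum([0, 31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
    day = int(day)
    if not 1 <= day <= 365:
        raise ValueError(f"day of year {day} outside 1..365")
    return int(np.searchsorted(cum, day, side="left"))


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance between two lat/lon points, in km."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2 - lon1)
    a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def _nearest_neighbours(grid: GridCell, all_grids: list[GridCell]) -> list[GridCell]:
    others = [g for g in all_grids if g.grid_id != grid.grid_id]
    if len(others) < N_NEIGHBOUR_GRIDS:
        logger.info(
            "grid %s: only %d neighbouring grids available (< %d); using all",
            grid.grid_id, len(others), N_NEIGHBOUR_GRIDS,
        )
        return others
    # Ties in distance broken by grid_id lexical order for determinism.
    keyed = sorted(
        others,
        key=lambda g: (
            haversine_km(*grid.centroid, *g.centroid),
            g.grid_id,
        ),
    )
    return keyed[:N_NEIGHBOUR_GRIDS]


def regional_richness(
    grid: GridCell, all_grids: list[GridCell], per_year: int | None = None
) -> int:
    """Distinct species across the 100 nearest neighbouring grids.

    Species are pooled across all years by default; pass ``per_year``
    to count only that year's records (alternative richness
    definition, kept behind a flag).
    """
    neighbours = _nearest_neighbours(grid, all_grids)
    pool: set[str] = set()
    for g in neighbours:
        pool |= g.species_in_year(per_year) if per_year is not None else g.all_species()
    return len(pool)


def well_recorded_years(
    grid: GridCell, all_grids: list[GridCell]
) -> set[int]:
    """Years in which the grid recorded >= 10% of regional richness."""
    richness = regional_richness(grid, all_grids)
    if richness == 0:
        raise ValueError(f"grid {grid.grid_id}: zero regional species richness")
    years = {yr for _, yr in grid.records}
    out = set()
    for yr in years:
        if len(grid.species_in_year(yr)) / richness >= WELL_RECORDED_FRACTION:
            out.add(yr)
    return out


def classify_colonisation(
    grid: GridCell, all_grids: list[GridCell], focal_species: str
) -> ColonisationAssessment:
    """Colonisation year and confidence class for one grid.

    core: focal species first recorded before 1975 (continuously
    occupied range). high: at least three well-recorded years strictly
    before the first record — probable absence followed by presence.
    low: the first record falls in or before the third well-recorded
    year, so colonisation cannot be separated from discovery.
    unoccupied: no focal record at all.
    """
    first = grid.first_record_year(focal_species)
    wr = well_recorded_years(grid, all_grids)
    if first is None:
        confidence = "unoccupied"
    elif first < CORE_RANGE_CUTOFF_YEAR:
        confidence = "core"
    elif len([y for y in wr if y < first]) >= MIN_WELL_RECORDED_PRIOR:
        confidence = "high"
    else:
        confidence = "low"
    return ColonisationAssessment(
        grid_id=grid.grid_id,
        first_record_year=first,
        well_recorded_years=wr,
        confidence=confidence,
    )


def emergence_curve(
    days: np.ndarray | list[int], counts: np.ndarray | list[float]
) -> EmergenceCurve:
    """Estimate the seasonal emergence pattern from count data.

    Counts are smoothed with a cubic smoothing spline whose penalty is
    chosen by generalised cross-validation; generations are the local
    maxima of the smooth exceeding 20% of its global maximum.
    """
    days = np.asarray(days, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if days.size != counts.size:
        raise ValueError("days and counts must have equal length")
    if days.size < 20:
        raise ValueError("need at least 20 observation days across the season")
    if counts.max() <= 0:
        raise ValueError("all counts are zero; no emergence signal")
    order = np.argsort(days)
    days, counts = days[order], counts[order]
    spline = make_smoothing_spline(days, counts)  # GCV-chosen penalty
    grid = np.arange(int(days.min()), int(days.max()) + 1, dtype=float)
    smoothed = np.clip(spline(grid), 0.0, None)
    floor = PEAK_HEIGHT_FRACTION * smoothed.max()
    idx, _ = find_peaks(smoothed, height=floor)
    peaks = [int(grid[i]) for i in idx]
    return EmergenceCurve(
        days=grid,
        smoothed=smoothed,
        peaks=peaks,
        n_generations=len(peaks),
    )


def _month_window(peak_month: int, collection_year: int) -> list[tuple[int, int]]:
    """(year, month) triples: the peak month and the two preceding.

    Windows that start before January take months from the preceding
    calendar year.
    """
    out = []
    for back in (2, 1, 0):
        m = peak_month - back
        y = collection_year
        if m < 1:
            m += 12
            y -= 1
        out.append((y, m))
    return out


def _monthly_map(monthly_temps: pd.DataFrame) -> dict[tuple[int, int], float]:
    return {
        (int(y), int(m)): float(t)
        for y, m, t in zip(
            monthly_temps["year"], monthly_temps["month"], monthly_temps["mean_temp_c"]
        )
    }


def dev_temperature(
    monthly_temps: pd.DataFrame, peak_month: int, collection_year: int
) -> float:
    """Mean temperature during development.

    Arithmetic mean of the monthly means for the local
    second-generation peak month and the two preceding months, in the
    collection year (a June peak averages April-June). ``monthly_temps``
    needs columns year, month, mean_temp_c for one grid.
    """
    table = _monthly_map(monthly_temps)
    vals = []
    for y, m in _month_window(peak_month, collection_year):
        if (y, m) not in table:
            raise ValueError(f"missing temperature for ({y}, {m})")
        vals.append(table[(y, m)])
    return float(np.mean(vals))


def t10(monthly_temps: pd.DataFrame, collection_year: int) -> float:
    """10-year mean annual temperature before collection.

    Mean of the monthly means over the window running from eleven
    years before collection through the year before collection — a
    2018 sample uses 2007-2017, matching the variable's published
    definition by worked example.
    """
    table = _monthly_map(monthly_temps)
    vals = []
    for y in range(collection_year - 11, collection_year):
        for m in range(1, 13):
            if (y, m) not in table:
                raise ValueError(f"missing temperature for ({y}, {m})")
            vals.append(table[(y, m)])
    return float(np.mean(vals))


def standardised_collection_date(
    collection_day: int, curve: EmergenceCurve
) -> int:
    """Signed days between collection and the second-generation peak.

    Positive when collection follows the peak. Raises for univoltine
    grids, where no second-generation reference exists.
    """
    return int(collection_day) - curve.second_gen_peak_day


def grids_from_records(
    records: pd.DataFrame, grids: pd.DataFrame
) -> list[GridCell]:
    """Assemble GridCell objects from tidy records/grids tables.

    ``records`` needs columns grid_id, species, year; ``grids`` needs
    grid_id, lat, lon.
    """
    by_grid: dict[str, set[tuple[str, int]]] = {g: set() for g in grids["grid_id"]}
    for row in records.itertuples(index=False):
        by_grid.setdefault(row.grid_id, set()).add((row.species, int(row.year)))
    out = []
    for row in grids.itertuples(index=False):
        out.append(
            GridCell(
                grid_id=row.grid_id,
                centroid=(float(row.lat), float(row.lon)),
                records=by_grid.get(row.grid_id, set()),
            )
        )
    return out
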