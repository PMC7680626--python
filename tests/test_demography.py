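"""Colonisation classification, emergence curves and temperature windows."""

import numpy as np
import pandas as pd
import pytest

from wingclines import (
    GridCell,
    SyntheticConfig,
    classify_colonisation,
    dev_temperature,
    emergence_curve,
    gen_abundance_counts,
    gen_occurrence_records,
    gen_sites,
    regional_richness,
    standardised_collection_date,
    t10,
    well_recorded_years,
)
from wingclines.demography import (
    UnivoltineError,
    day_of_year_to_month,
    grids_from_records,
    haversine_km,
)

FOCAL = "Pararge aegeria"


def pool_grid(grid_id, lat, lon, species, year=1980):
    return GridCell(grid_id, (lat, lon), {(sp, year) for sp in species})


class TestRichness:
    def test_shared_pool(self):
        pool = [f"sp{i}" for i in range(30)]
        grids = [pool_grid(f"g{i}", 50 + i * 0.1, 0.0, pool) for i in range(6)]
        assert regional_richness(grids[0], grids) == 30

    def test_disjoint_union_oracle(self):
        # Hand-built union across constructed neighbour sets.
        grids = [
            pool_grid("a", 50.0, 0.0, ["s1", "s2"]),
            pool_grid("b", 50.1, 0.0, ["s2", "s3"]),
            pool_grid("c", 50.2, 0.0, ["s4"]),
        ]
        assert regional_richness(grids[0], grids) == len({"s2", "s3", "s4"})

    def test_fewer_than_100_uses_all(self):
        grids = [pool_grid(f"g{i}", 50 + i, 0.0, [f"sp{i}"]) for i in range(5)]
        # focal excluded: union over the other four
        assert regional_richness(grids[0], grids) == 4

    def test_nearest_selection(self):
        # 101 distant grids with pool A, 100 near with pool B: only the
        # 100 nearest should count.
        near = [pool_grid(f"n{i}", 50.0 + i * 0.01, 0.0, ["near_sp"]) for i in range(100)]
        far = [pool_grid(f"f{i}", 80.0 + i * 0.01, 0.0, ["far_sp"]) for i in range(101)]
        focal = pool_grid("x", 50.0, 0.1, [])
        assert regional_richness(focal, [focal] + near + far) == 1

    def test_haversine_sanity(self):
        # one degree of latitude is ~111 km
        assert haversine_km(50.0, 0.0, 51.0, 0.0) == pytest.approx(111.2, abs=1.0)


class TestWellRecorded:
    def _grids(self, focal_records):
        pool = [f"sp{i}" for i in range(50)]
        neighbours = [pool_grid(f"n{i}", 50.0 + 0.1 * i, 1.0, pool) for i in range(3)]
        focal = GridCell("x", (50.0, 0.0), focal_records)
        return focal, [focal] + neighbours

    def test_ten_percent_boundary_inclusive(self):
        recs = {(f"sp{i}", 1990) for i in range(5)} | {(f"sp{i}", 1991) for i in range(4)}
        focal, grids = self._grids(recs)
        wr = well_recorded_years(focal, grids)
        assert 1990 in wr     # 5/50 = 10% exactly
        assert 1991 not in wr  # 4/50 below threshold


def scripted_grid(first_record_year, well_recorded, grid_id="x"):
    """A grid whose well-recorded years and focal first record are scripted.

    Neighbours share a 30-species pool; recording 3 species in a year
    meets the 10% threshold exactly.
    """
    pool = [f"sp{i}" for i in range(30)]
    neighbours = [pool_grid(f"n{i}", 51.0 + 0.1 * i, 1.0, pool) for i in range(3)]
    records = set()
    for yr in well_recorded:
        records |= {(f"sp{i}", yr) for i in range(3)}
    if first_record_year is not None:
        records.add((FOCAL, first_record_year))
    focal = GridCell(grid_id, (51.0, 0.0), records)
    return focal, [focal] + neighbours


class TestColonisationClass:
    def test_core_before_1975(self):
        focal, grids = scripted_grid(1970, set())
        assert classify_colonisation(focal, grids, FOCAL).confidence == "core"

    def test_core_boundary(self):
        focal, grids = scripted_grid(1974, set())
        assert classify_colonisation(focal, grids, FOCAL).confidence == "core"
        focal, grids = scripted_grid(1975, {1965, 1966, 1967})
        assert classify_colonisation(focal, grids, FOCAL).confidence == "high"

    def test_high_confidence(self):
        focal, grids = scripted_grid(1999, {1990, 1992, 1995})
        a = classify_colonisation(focal, grids, FOCAL)
        assert a.confidence == "high"
        assert a.first_record_year == 1999
        assert a.years_colonised_at(2018) == 19

    def test_low_confidence(self):
        # First record in or before the third well-recorded year.
        focal, grids = scripted_grid(1991, {1990, 1992, 1995})
        assert classify_colonisation(focal, grids, FOCAL).confidence == "low"

    def test_unoccupied(self):
        focal, grids = scripted_grid(None, {1990, 1991, 1992})
        a = classify_colonisation(focal, grids, FOCAL)
        assert a.confidence == "unoccupied"
        assert a.first_record_year is None


class TestOccurrenceClosedLoop:
    def test_full_effort_recovers_every_year(self):
        cfg = SyntheticConfig(seed=31, n_sites=12)
        sites, _, _ = gen_sites(cfg)
        records, truth = gen_occurrence_records(sites, cfg)
        grids = grids_from_records(records, sites[["grid_id", "lat", "lon"]])
        truth_map = dict(zip(truth.grid_id, truth.colonisation_year))
        for g in grids:
            a = classify_colonisation(g, grids, FOCAL)
            assert a.first_record_year == truth_map[g.grid_id]
            assert a.confidence in ("core", "high")

    def test_zero_prior_effort_gives_low_confidence(self):
        cfg = SyntheticConfig(seed=32, n_sites=8)
        sites, _, _ = gen_sites(cfg)
        # Pick a post-1975 coloniser and zero its effort before first record.
        target = sites[sites.colonisation_year >= 1980].iloc[0]
        first = int(target.colonisation_year)
        effort = {target.grid_id: {y: 0.3 for y in range(first, 2019)}}
        records, _ = gen_occurrence_records(sites, cfg, effort=effort)
        grids = grids_from_records(records, sites[["grid_id", "lat", "lon"]])
        focal = next(g for g in grids if g.grid_id == target.grid_id)
        assert classify_colonisation(focal, grids, FOCAL).confidence == "low"


class TestEmergence:
    def test_two_peaks_recovered(self):
        cfg = SyntheticConfig(seed=33)
        counts = gen_abundance_counts("s", [150, 210], dispersion=0.02, config=cfg)
        curve = emergence_curve(counts["day"], counts["count"])
        assert curve.n_generations == 2
        assert abs(curve.second_gen_peak_day - 210) <= 7
        assert curve.peaks == sorted(curve.peaks)

    def test_single_bump(self):
        cfg = SyntheticConfig(seed=34)
        counts = gen_abundance_counts("s", [180], dispersion=0.02, config=cfg)
        curve = emergence_curve(counts["day"], counts["count"])
        assert curve.n_generations == 1
        with pytest.raises(UnivoltineError):
            _ = curve.second_gen_peak_day

    def test_noiseless_counts_equal_rounded_curve(self):
        cfg = SyntheticConfig(seed=35)
        counts = gen_abundance_counts("s", [150, 210], dispersion=0.0, config=cfg)
        days = counts["day"].to_numpy()
        mu = 80.0 * (
            np.exp(-((days - 150) ** 2) / (2 * 12.0**2))
            + np.exp(-((days - 210) ** 2) / (2 * 12.0**2))
        )
        np.testing.assert_array_equal(counts["count"].to_numpy(), np.rint(mu))

    def test_flat_and_short_series_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            emergence_curve(np.arange(90, 300, 7), np.zeros(30))
        with pytest.raises(ValueError, match="20 observation"):
            emergence_curve([100, 150, 200], [1, 5, 1])

    def test_peak_bounds_checked(self):
        cfg = SyntheticConfig(seed=36)
        with pytest.raises(ValueError, match="outside"):
            gen_abundance_counts("s", [400], dispersion=0.1, config=cfg)


class TestTemperatureWindows:
    def _temps(self, values):
        rows = [(y, m, t) for (y, m), t in values.items()]
        return pd.DataFrame(rows, columns=["year", "month", "mean_temp_c"])

    def test_worked_example_april_june(self):
        temps = self._temps({(2018, 4): 8.0, (2018, 5): 11.0, (2018, 6): 14.0})
        assert dev_temperature(temps, peak_month=6, collection_year=2018) == 11.0

    def test_cross_year_window(self):
        temps = self._temps({(2017, 11): 4.0, (2017, 12): 2.0, (2018, 1): 3.0})
        assert dev_temperature(temps, peak_month=1, collection_year=2018) == 3.0

    def test_missing_month_named(self):
        temps = self._temps({(2018, 5): 11.0, (2018, 6): 14.0})
        with pytest.raises(ValueError, match=r"\(2018, 4\)"):
            dev_temperature(temps, peak_month=6, collection_year=2018)

    def test_t10_window_and_linearity(self):
        # Linear yearly trend: hand-computable window mean over 2007-2017.
        vals = {
            (y, m): 10.0 + 0.1 * (y - 2007) for y in range(2007, 2018) for m in range(1, 13)
        }
        temps = self._temps(vals)
        expected = np.mean([10.0 + 0.1 * (y - 2007) for y in range(2007, 2018)])
        assert t10(temps, collection_year=2018) == pytest.approx(expected, abs=1e-12)
        # Linearity: adding c to every month adds c to both outputs.
        shifted = temps.assign(mean_temp_c=temps.mean_temp_c + 2.5)
        assert t10(shifted, 2018) == pytest.approx(t10(temps, 2018) + 2.5, abs=1e-12)

    def test_t10_missing_year_rejected(self):
        vals = {(y, m): 10.0 for y in range(2008, 2018) for m in range(1, 13)}
        with pytest.raises(ValueError, match="2007"):
            t10(self._temps(vals), collection_year=2018)

    def test_constant_series(self):
        vals = {(y, m): 10.0 for y in range(2006, 2019) for m in range(1, 13)}
        temps = self._temps(vals)
        assert t10(temps, 2018) == 10.0
        assert dev_temperature(temps, 6, 2018) == 10.0


class TestStandardisedDate:
    def test_offsets(self):
        cfg = SyntheticConfig(seed=37)
        counts = gen_abundance_counts("s", [150, 210], dispersion=0.0, config=cfg)
        curve = emergence_curve(counts["day"], counts["count"])
        peak = curve.second_gen_peak_day
        assert standardised_collection_date(peak, curve) == 0
        assert standardised_collection_date(peak + 5, curve) == 5
        assert abs(peak - 210) <= 7

    def test_month_mapping(self):
        assert day_of_year_to_month(1) == 1
        assert day_of_year_to_month(31) == 1
        assert day_of_year_to_month(32) == 2
        assert day_of_year_to_month(172) == 6
        assert day_of_year_to_month(365) == 12
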