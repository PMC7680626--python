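"""Synthetic study data with known clines.

Generates every input the analysis consumes — landmark configurations,
wing photographs, occurrence histories, seasonal counts and monthly
temperature series — with the statistical structure the downstream
stages assume, so the whole pipeline is testable end to end against
known truth. The defaults emulate the study conditions: ~54 sites of
10-20 males each spanning ~7 degrees of latitude, wing size growing
~2% per degree of latitude, colonisation proceeding northwards from a
pre-1975 core, annual temperature correlating with latitude at -0.74,
and cream spots lightening faster with latitude than the brown ground
colour so that contrast increases northwards.

Every operation is driven by the config seed alone: the same config
yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .colour import CalibrationPatch, WingImage
from .morphometrics import (
    FOREWING_N_LANDMARKS,
    HINDWING_N_LANDMARKS,
    LandmarkConfiguration,
    centroid_size,
    write_tps,
)

#: Collection year of the simulated survey; temperature tables span the
#: T10 window for this year plus the collection year itself.
COLLECTION_YEAR = 2018
TEMPERATURE_YEARS = tuple(range(COLLECTION_YEAR - 11, COLLECTION_YEAR + 1))

OCCURRENCE_YEARS = (1965, COLLECTION_YEAR)

#: 58 butterfly species form the regional recording pool.
FOCAL_SPECIES = "Pararge aegeria"
SPECIES_POOL = tuple(f"species_{i:02d}" for i in range(1, 58)) + (FOCAL_SPECIES,)

# Sub-stream labels so each operation draws from an independent,
# seed-derived stream.
_STREAMS = {"sites": 1, "landmarks": 2, "images": 3, "records": 4, "counts": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, _STREAMS[stream])))


# ---------------------------------------------------------------------------
# Wing templates: fixed mean shapes (versioned constants). Coordinates
# approximate a butterfly fore/hindwing outline with landmarks at
# vein-vein and vein-margin intersections; exact values are arbitrary.
# ---------------------------------------------------------------------------

FOREWING_TEMPLATE = np.array(
    [
        [0.00, 0.00],   # 1  wing base / shoulder
        [0.25, 0.38],
        [0.55, 0.52],
        [0.90, 0.55],
        [1.25, 0.50],
        [1.52, 0.38],
        [1.65, 0.18],   # 7  apex region
        [1.60, -0.05],
        [1.38, -0.22],
        [1.05, -0.32],
        [0.70, -0.34],
        [0.38, -0.28],
        [0.15, -0.16],
        [0.45, 0.05],   # 14 interior vein junction
    ]
)

HINDWING_TEMPLATE = np.array(
    [
        [0.00, 0.00],   # 1  wing base
        [0.30, 0.30],
        [0.68, 0.40],
        [1.05, 0.35],
        [1.32, 0.18],   # 5
        [1.38, -0.05],
        [1.25, -0.28],
        [1.00, -0.42],
        [0.68, -0.46],
        [0.35, -0.38],
        [0.12, -0.20],  # 11
    ]
)

assert FOREWING_TEMPLATE.shape[0] == FOREWING_N_LANDMARKS
assert HINDWING_TEMPLATE.shape[0] == HINDWING_N_LANDMARKS

#: Baseline centroid sizes (cm units) at the southern range edge,
#: matching the observed bivoltine means.
BASE_CS = {"forewing": 2.60, "hindwing": 2.39}


def _unit_template(template: np.ndarray) -> np.ndarray:
    centred = template - template.mean(axis=0)
    return centred / np.sqrt((centred**2).sum())


def shape_deformation_direction(wing: str) -> np.ndarray:
    """The fixed unit-norm tangent direction used for shape clines.

    Built deterministically from the wing template: a smooth bending
    pattern orthogonalised against the similarity nuisance directions
    (translation, scale, rotation) at the template, so deformation
    moves the shape within tangent space only.
    """
    template = FOREWING_TEMPLATE if wing == "forewing" else HINDWING_TEMPLATE
    unit = _unit_template(template)
    k = unit.shape[0]
    # A smooth, wing-specific displacement field.
    t = np.linspace(0.0, 2.0 * np.pi, k, endpoint=False)
    raw = np.column_stack([np.sin(2 * t), np.cos(3 * t)]).reshape(-1)
    flat = unit.reshape(-1)
    # Nuisance basis: x/y translation, scaling (the shape itself),
    # in-plane rotation.
    tx = np.tile([1.0, 0.0], k)
    ty = np.tile([0.0, 1.0], k)
    rot = unit @ np.array([[0.0, -1.0], [1.0, 0.0]])
    basis = np.column_stack([tx, ty, flat, rot.reshape(-1)])
    q, _ = np.linalg.qr(basis)
    raw = raw - q @ (q.T @ raw)
    return raw / np.linalg.norm(raw)


# ---------------------------------------------------------------------------
# Configuration and truth
# ---------------------------------------------------------------------------


@dataclass
class ImageParams:
    """Grey-level geometry of generated wing photographs."""

    brown_grey: float = 80.0        # ground colour at the southern edge
    cream_grey: float = 195.0       # spot colour at the southern edge
    brown_slope_per_degree: float = 1.49
    cream_slope_per_degree: float = 3.38
    spot_count: int = 3
    background_grey: float = 230.0
    patch_nominals: tuple[float, float] = (60.0, 200.0)
    canvas: tuple[int, int] = (180, 240)   # rows, cols

    @property
    def contrast_slope_per_degree(self) -> float:
        return self.cream_slope_per_degree - self.brown_slope_per_degree


@dataclass
class SyntheticConfig:
    """All knobs of the generator; the defaults are the study conditions."""

    seed: int = 0
    n_sites: int = 54
    n_per_site: int | None = None          # None: uniform 10-20 per site
    lat_range: tuple[float, float] = (50.0, 57.2)
    size_slope: float = 0.02               # log-CS change per degree latitude
    colonisation_slope: float = -0.001     # log-CS change per year colonised
    shape_deformation_scale: float = 0.003  # tangent units per covariate unit
    landmark_noise_sd: float = 0.01
    lat_temp_correlation: float = -0.74
    site_size_sd: float = 0.01             # site-level log-CS intercept sd
    specimen_size_sd: float = 0.03         # within-site log-CS sd
    years_colonised_noise_sd: float = 8.0
    image_params: ImageParams = field(default_factory=ImageParams)

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ValueError("n_sites must be at least 2")
        if abs(self.lat_temp_correlation) > 1:
            raise ValueError(
                f"lat_temp_correlation must lie in [-1, 1], "
                f"got {self.lat_temp_correlation}"
            )
        if self.landmark_noise_sd < 0:
            raise ValueError("landmark_noise_sd must be non-negative")
        ip = self.image_params
        if abs(ip.cream_grey - ip.brown_grey) < 10:
            raise ValueError(
                "spot grey must differ from base grey by at least 10 units"
            )


@dataclass
class SyntheticTruth:
    """Ground truth for everything generated; one row per artefact."""

    sites: pd.DataFrame | None = None
    specimens: pd.DataFrame | None = None
    images: pd.DataFrame | None = None
    colonisation: pd.DataFrame | None = None
    peaks: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# Sites, covariates, temperatures
# ---------------------------------------------------------------------------


def gen_sites(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Site table, monthly temperature table, and truth.

    Latitudes are uniform over the configured range; the annual-mean
    temperature of each site correlates with latitude at the configured
    level; years colonised decline northwards (the expansion wave) with
    noise around the linear trend; each site gets 1-3 emergence peaks
    (three generations only in the warm south) and an expansion label
    splitting England from Scotland.
    """
    rng = _rng(config.seed, "sites")
    n = config.n_sites
    lo, hi = config.lat_range
    lat = np.sort(rng.uniform(lo, hi, size=n))
    lon = rng.uniform(-5.5, 0.5, size=n)

    # Annual-mean temperature with the configured latitude correlation.
    rho = config.lat_temp_correlation
    lat_z = (lat - lat.mean()) / lat.std()
    eps = rng.standard_normal(n)
    # Remove the sample correlation between eps and lat so the
    # configured rho is hit up to scaling, not double-counted.
    eps = eps - eps.mean()
    eps = eps - lat_z * (eps @ lat_z) / (lat_z @ lat_z)
    if eps.std() > 0:
        eps = eps / eps.std()
    temp_z = rho * lat_z + np.sqrt(1.0 - rho**2) * eps
    annual_mean = 9.5 + 1.0 * temp_z

    # Expansion wave: southern core colonised by 1965, leading edge
    # colonised within the last few years.
    span = hi - lo
    trend = 53.0 - 50.0 * (lat - lo) / span
    years_colonised = np.clip(
        np.rint(trend + rng.normal(0.0, config.years_colonised_noise_sd, size=n)),
        1,
        53,
    ).astype(int)
    colonisation_year = COLLECTION_YEAR - years_colonised

    expansion = np.where(lat < 54.5, "England", "Scotland")
    n_generations = np.where(lat < lo + span / 3.0, 3, 2)
    peak1 = np.rint(150 + 2.0 * (lat - lo)).astype(int)
    peak2 = np.rint(210 + 2.0 * (lat - lo)).astype(int)
    collection_day = peak2 + rng.integers(-10, 11, size=n)

    site_id = [f"S{i + 1:03d}" for i in range(n)]
    grid_id = [f"G{i + 1:03d}" for i in range(n)]
    sites = pd.DataFrame(
        {
            "site_id": site_id,
            "grid_id": grid_id,
            "lat": lat,
            "lon": lon,
            "expansion": expansion,
            "years_colonised": years_colonised,
            "colonisation_year": colonisation_year,
            "collection_year": COLLECTION_YEAR,
            "collection_day": collection_day,
            "annual_mean_temp": annual_mean,
            "n_generations": n_generations,
            "peak1_day": peak1,
            "peak2_day": peak2,
        }
    )

    # Monthly series: annual mean + seasonal sinusoid + small noise.
    months = np.arange(1, 13)
    seasonal = -5.5 * np.cos(2.0 * np.pi * (months - 1) / 12.0)  # peak in July
    rows = []
    for i in range(n):
        for year in TEMPERATURE_YEARS:
            year_effect = rng.normal(0.0, 0.2)
            noise = rng.normal(0.0, 0.3, size=12)
            temps = annual_mean[i] + seasonal + year_effect + noise
            for m, t in zip(months, temps):
                rows.append((grid_id[i], year, int(m), float(t)))
    temperatures = pd.DataFrame(
        rows, columns=["grid_id", "year", "month", "mean_temp_c"]
    )

    truth = SyntheticTruth(
        sites=sites.copy(),
        peaks=sites[["site_id", "grid_id", "n_generations", "peak1_day", "peak2_day"]].copy(),
        colonisation=sites[["grid_id", "colonisation_year"]].copy(),
    )
    return sites, temperatures, truth


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------


def gen_landmarks(
    sites: pd.DataFrame,
    config: SyntheticConfig,
    wings: tuple[str, ...] = ("forewing", "hindwing"),
) -> tuple[list[LandmarkConfiguration], pd.DataFrame]:
    """Specimen landmark configurations plus per-specimen truth.

    Each specimen is the wing template scaled by its true centroid
    size, deformed along the fixed tangent direction in proportion to
    its covariate score (years colonised, centred at the range
    midpoint), perturbed by isotropic landmark noise, then rotated and
    translated at random (the nuisance similarity transform GPA must
    undo). True log CS follows the configured latitude and
    colonisation clines with site- and specimen-level noise.
    """
    rng = _rng(config.seed, "landmarks")
    lat_ref = config.lat_range[0]
    configs: list[LandmarkConfiguration] = []
    truth_rows = []
    directions = {w: shape_deformation_direction(w) for w in wings}
    templates = {
        "forewing": _unit_template(FOREWING_TEMPLATE),
        "hindwing": _unit_template(HINDWING_TEMPLATE),
    }
    for site in sites.itertuples(index=False):
        n_spec = (
            int(rng.integers(10, 21))
            if config.n_per_site is None
            else config.n_per_site
        )
        site_effects = {w: rng.normal(0.0, config.site_size_sd) for w in wings}
        score = float(site.years_colonised) - 27.0  # centred covariate score
        for j in range(n_spec):
            specimen_id = f"{site.site_id}_{j + 1:02d}"
            for wing in wings:
                k = templates[wing].shape[0]
                log_cs = (
                    np.log(BASE_CS[wing])
                    + config.size_slope * (site.lat - lat_ref)
                    + config.colonisation_slope * site.years_colonised
                    + site_effects[wing]
                    + rng.normal(0.0, config.specimen_size_sd)
                )
                true_cs = float(np.exp(log_cs))
                shape = (
                    templates[wing]
                    + (config.shape_deformation_scale * score)
                    * directions[wing].reshape(k, 2)
                )
                # Renormalise so the deformation changes shape only and
                # the specimen's centroid size is exactly true_cs.
                shape = shape / np.sqrt((shape**2).sum())
                coords = shape * true_cs
                coords = coords + rng.normal(0.0, config.landmark_noise_sd, size=coords.shape)
                theta = rng.uniform(0.0, 2.0 * np.pi)
                rot = np.array(
                    [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
                )
                coords = coords @ rot.T + rng.uniform(-5.0, 5.0, size=2)
                configs.append(
                    LandmarkConfiguration(
                        specimen_id=specimen_id,
                        wing=wing,
                        coords=coords,
                        side="left",
                        wear_physical=int(rng.integers(1, 5)),
                        wear_scale=int(rng.integers(1, 5)),
                    )
                )
                truth_rows.append(
                    {
                        "specimen_id": specimen_id,
                        "site_id": site.site_id,
                        "grid_id": site.grid_id,
                        "wing": wing,
                        "lat": site.lat,
                        "years_colonised": site.years_colonised,
                        "true_log_cs": float(log_cs),
                        "true_cs": true_cs,
                        "shape_score": config.shape_deformation_scale * score,
                    }
                )
    return configs, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------


def _ellipse_mask(
    shape: tuple[int, int],
    centre: tuple[float, float],
    semi_axes: tuple[float, float],
) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    r0, c0 = centre
    a, b = semi_axes
    return ((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2 <= 1.0


#: Spot centres/radii in wing-relative coordinates (fractions of the
#: wing semi-axes from the wing centre).
_SPOT_LAYOUT = [
    (-0.35, 0.45, 0.16),
    (0.30, 0.30, 0.14),
    (0.05, -0.35, 0.15),
    (-0.45, -0.25, 0.12),
    (0.45, -0.15, 0.11),
]


def gen_wing_images(
    sites: pd.DataFrame,
    config: SyntheticConfig,
    n_per_site: int = 2,
) -> tuple[list[WingImage], pd.DataFrame]:
    """Dorsal forewing photographs with calibration patches, plus truth.

    Each image holds a brown elliptical wing silhouette with cream
    elliptical spots on a uniform background, two calibration patches
    of known nominal grey, and an affine lighting distortion
    (gain/offset) that calibration must undo. Grey levels follow the
    configured latitudinal slopes; the true brown/cream greys,
    contrast and silhouette area are recorded per image.
    """
    rng = _rng(config.seed, "images")
    ip = config.image_params
    lat_ref = config.lat_range[0]
    h, w = ip.canvas
    patch = 18
    patches = [
        CalibrationPatch((2, 2 + patch, 2, 2 + patch), ip.patch_nominals[0]),
        CalibrationPatch((2, 2 + patch, w - 2 - patch, w - 2), ip.patch_nominals[1]),
    ]
    wing_centre = (h * 0.58, w * 0.5)
    semi_axes = (h * 0.30, w * 0.33)

    images: list[WingImage] = []
    rows = []
    for site in sites.itertuples(index=False):
        brown = ip.brown_grey + ip.brown_slope_per_degree * (site.lat - lat_ref)
        cream = ip.cream_grey + ip.cream_slope_per_degree * (site.lat - lat_ref)
        brown = float(np.clip(brown, 0.0, 255.0))
        cream = float(np.clip(cream, 0.0, 255.0))
        if abs(cream - brown) < 10:
            raise ValueError(
                f"site {site.site_id}: spot grey {cream:.0f} within 10 units "
                f"of base grey {brown:.0f}"
            )
        for j in range(n_per_site):
            specimen_id = f"{site.site_id}_{j + 1:02d}"
            canvas = np.full((h, w), ip.background_grey, dtype=float)
            wing_mask = _ellipse_mask((h, w), wing_centre, semi_axes)
            canvas[wing_mask] = brown
            for (fr, fc, frad) in _SPOT_LAYOUT[: ip.spot_count]:
                centre = (
                    wing_centre[0] + fr * semi_axes[0],
                    wing_centre[1] + fc * semi_axes[1],
                )
                radius = frad * min(semi_axes)
                spot = _ellipse_mask((h, w), centre, (radius, radius * 1.2))
                canvas[spot & wing_mask] = cream
            for p in patches:
                r0, r1, c0, c1 = p.bounds
                canvas[r0:r1, c0:c1] = p.nominal_grey
            gain = rng.uniform(0.92, 1.06)
            offset = rng.uniform(-8.0, 6.0)
            distorted = np.clip(canvas * gain + offset, 0.0, 255.0)
            pixels = np.repeat(
                distorted.round().astype(np.uint8)[:, :, None], 3, axis=2
            )
            attachment = (int(wing_centre[0]), int(wing_centre[1] - semi_axes[1]) + 1)
            images.append(
                WingImage(
                    pixels=pixels,
                    attachment_point=attachment,
                    patches=patches,
                    specimen_id=specimen_id,
                    wing="forewing",
                    surface="dorsal",
                )
            )
            rows.append(
                {
                    "specimen_id": specimen_id,
                    "site_id": site.site_id,
                    "lat": site.lat,
                    "true_brown": brown,
                    "true_cream": cream,
                    "true_contrast": cream - brown,
                    "true_area_px": int(wing_mask.sum()),
                    "gain": gain,
                    "offset": offset,
                }
            )
    return images, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Occurrence records and abundance counts
# ---------------------------------------------------------------------------


def gen_occurrence_records(
    sites: pd.DataFrame,
    config: SyntheticConfig,
    effort: dict[str, dict[int, float]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Yearly species lists per grid, plus truth colonisation years.

    The focal species is recorded in every year from its true
    colonisation year onwards, so its first record is exactly the
    truth. Recorder effort — the fraction of the 57 non-focal species
    recorded in a grid-year — defaults to 0.3 everywhere (ample for
    well-recorded status) and can be overridden per grid and year to
    script confidence scenarios.
    """
    rng = _rng(config.seed, "records")
    y0, y1 = OCCURRENCE_YEARS
    non_focal = [s for s in SPECIES_POOL if s != FOCAL_SPECIES]
    rows = []
    for site in sites.itertuples(index=False):
        grid_effort = (effort or {}).get(site.grid_id, {})
        for year in range(y0, y1 + 1):
            f = grid_effort.get(year, 0.3 if effort is None or site.grid_id not in effort else 0.0)
            n_rec = int(round(f * len(non_focal)))
            if n_rec > 0:
                for sp in rng.choice(non_focal, size=n_rec, replace=False):
                    rows.append((site.grid_id, sp, year))
            if year >= site.colonisation_year:
                rows.append((site.grid_id, FOCAL_SPECIES, year))
    records = pd.DataFrame(rows, columns=["grid_id", "species", "year"])
    truth = sites[["grid_id", "colonisation_year"]].copy()
    return records, truth


def gen_abundance_counts(
    site_id: str,
    peaks: list[int],
    dispersion: float,
    config: SyntheticConfig,
    amplitude: float = 80.0,
    peak_sd: float = 12.0,
    day_range: tuple[int, int] = (90, 300),
    step: int = 7,
) -> pd.DataFrame:
    """Weekly count series around a mixture of Gaussian emergence bumps.

    Counts are negative-binomial around the expected curve with the
    given overdispersion (variance mu + dispersion * mu^2); dispersion
    of zero returns the expected curve rounded.
    """
    if not 1 <= len(peaks) <= 3:
        raise ValueError("between 1 and 3 peaks required")
    for p in peaks:
        if not 1 <= p <= 365:
            raise ValueError(f"peak day {p} outside 1..365")
    rng = np.random.default_rng(
        np.random.SeedSequence((config.seed, _STREAMS["counts"], hash(site_id) % 2**31))
    )
    days = np.arange(day_range[0], day_range[1] + 1, step)
    mu = np.zeros_like(days, dtype=float)
    for p in peaks:
        mu += amplitude * np.exp(-((days - p) ** 2) / (2.0 * peak_sd**2))
    if dispersion <= 0:
        counts = np.rint(mu).astype(int)
    else:
        r = 1.0 / dispersion
        prob = r / (r + np.clip(mu, 1e-12, None))
        counts = rng.negative_binomial(r, prob)
        counts[mu < 1e-9] = 0
    return pd.DataFrame({"site_id": site_id, "day": days, "count": counts})


# ---------------------------------------------------------------------------
# Dataset writer
# ---------------------------------------------------------------------------


def write_dataset(config: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write the full synthetic dataset to disk.

    Emits sites.csv, temperatures.csv, records.csv, counts.csv,
    truth.csv (specimen truth), TPS landmark files per wing, and PNG
    images. Returns the paths written.
    """
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sites, temps, truth = gen_sites(config)
    configs, spec_truth = gen_landmarks(sites, config)
    images, img_truth = gen_wing_images(sites, config)
    records, col_truth = gen_occurrence_records(sites, config)
    counts = pd.concat(
        [
            gen_abundance_counts(
                s.site_id,
                [s.peak1_day, s.peak2_day][: 2 if s.n_generations >= 2 else 1],
                dispersion=0.2,
                config=config,
            )
            for s in sites.itertuples(index=False)
        ],
        ignore_index=True,
    )

    paths: dict[str, Path] = {}
    for name, frame in [
        ("sites", sites),
        ("temperatures", temps),
        ("records", records),
        ("counts", counts),
        ("truth", spec_truth),
        ("image_truth", img_truth),
        ("colonisation_truth", col_truth),
    ]:
        p = outdir / f"{name}.csv"
        frame.to_csv(p, index=False)
        paths[name] = p
    for wing in ("forewing", "hindwing"):
        p = outdir / f"{wing}.tps"
        write_tps([c for c in configs if c.wing == wing], p)
        paths[f"{wing}_tps"] = p
    img_dir = outdir / "images"
    img_dir.mkdir(exist_ok=True)
    for img in images:
        iio.imwrite(img_dir / f"{img.specimen_id}.png", img.pixels)
    paths["images"] = img_dir
    return paths
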