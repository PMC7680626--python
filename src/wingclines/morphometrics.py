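"""Landmark-based geometric morphometrics.

Landmark I/O (TPS dialect), centroid size, generalised Procrustes
analysis (GPA), Procrustes distance, multivariate allometry regression
with permutation inference, and wireframe shape predictions.

Shapes are k x 2 arrays of landmark coordinates. The forewing carries
14 landmarks and the hindwing 11, each placed at vein-vein or
vein-margin intersections; only the counts matter to the algebra here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm

FOREWING_N_LANDMARKS = 14
HINDWING_N_LANDMARKS = 11

WING_LANDMARK_COUNTS = {
    "forewing": FOREWING_N_LANDMARKS,
    "hindwing": HINDWING_N_LANDMARKS,
}

#: GPA convergence tolerance on the RMS change of the consensus.
DEFAULT_GPA_TOL = 1e-10
DEFAULT_GPA_MAX_ITER = 100

#: Default permutation count for allometry inference.
DEFAULT_N_PERM = 10_000


class TPSParseError(ValueError):
    """Raised when a TPS file violates the expected dialect."""


class DegenerateConfigurationError(ValueError):
    """Raised when all landmarks of a configuration coincide."""


@dataclass
class LandmarkConfiguration:
    """One wing's digitised landmarks plus specimen metadata.

    Coordinates are Cartesian (origin bottom-left, the tpsDig
    convention), in image pixel units already multiplied by any TPS
    SCALE factor. Wear grades run 1 (pristine) to 4 (heavy damage).
    """

    specimen_id: str
    wing: str
    coords: np.ndarray
    side: str = "left"
    wear_physical: int = 1
    wear_scale: int = 1

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be a k x 2 array")
        if self.wing not in WING_LANDMARK_COUNTS:
            raise ValueError(f"unknown wing type {self.wing!r}")
        expected = WING_LANDMARK_COUNTS[self.wing]
        if self.coords.shape[0] != expected:
            raise ValueError(
                f"{self.wing} requires {expected} landmarks, "
                f"got {self.coords.shape[0]}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("landmark coordinates must be finite")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        for grade in (self.wear_physical, self.wear_scale):
            if not 1 <= int(grade) <= 4:
                raise ValueError("wear grades must be integers in 1..4")

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]

    def mirrored(self) -> "LandmarkConfiguration":
        """Return a copy reflected about the y-axis (x negated).

        Used to map right wings into left-wing orientation before
        superimposition; landmark order is preserved.
        """
        out = replace(self, coords=self.coords * np.array([-1.0, 1.0]))
        return out


@dataclass
class ProcrustesResult:
    """Superimposed configurations in tangent space."""

    aligned: np.ndarray          # n x k x 2, tangent-projected
    consensus: np.ndarray        # k x 2, unit centroid size
    centroid_sizes: np.ndarray   # n, original CS of each input
    log_cs: np.ndarray           # n, natural log of CS
    iterations: int
    converged: bool

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def k(self) -> int:
        return self.aligned.shape[1]

    def flat(self) -> np.ndarray:
        """Aligned shapes as an n x 2k matrix (x1 y1 x2 y2 ...)."""
        return self.aligned.reshape(self.n, -1)


@dataclass
class AllometryModel:
    """Multivariate regression of shape on log centroid size.

    ``coefficients`` is the 2k shape-change vector per unit log CS;
    ``regression_scores`` project each specimen's (centred) shape onto
    the unit-norm coefficient direction, giving the shape variable with
    the greatest covariation with size. Residual shapes are the
    size-adjusted shape variables used downstream.
    """

    coefficients: np.ndarray
    intercept: np.ndarray
    pct_variance_explained: float
    permutation_p: float
    regression_scores: np.ndarray
    residual_shapes: np.ndarray
    slope: float
    slope_se: float
    log_cs: np.ndarray
    n_perm: int
    seed: int


# ---------------------------------------------------------------------------
# TPS I/O
# ---------------------------------------------------------------------------

_TPS_KV = re.compile(r"^(LM|IMAGE|ID|SCALE)\s*=\s*(.*)$", re.IGNORECASE)


def parse_tps(path: str | Path, wing: str | None = None) -> list[LandmarkConfiguration]:
    """Parse a TPS landmark file.

    Records start with ``LM=<k>`` followed by k ``x y`` lines and
    optional ``IMAGE=``, ``ID=``, ``SCALE=`` lines. SCALE multiplies
    coordinates. The wing type is inferred from the landmark count
    (14 forewing, 11 hindwing) unless given explicitly.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    configs: list[LandmarkConfiguration] = []
    i = 0
    block_no = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        m = _TPS_KV.match(line)
        if not m or m.group(1).upper() != "LM":
            raise TPSParseError(
                f"{path.name}: expected LM=<k> at line {i + 1}, got {line!r}"
            )
        block_no += 1
        try:
            k = int(m.group(2))
        except ValueError as exc:
            raise TPSParseError(f"{path.name}: bad LM count in block {block_no}") from exc
        i += 1
        coords = np.empty((k, 2), dtype=float)
        for j in range(k):
            if i >= len(lines) or _TPS_KV.match(lines[i].strip()):
                raise TPSParseError(
                    f"{path.name}: block {block_no} declares LM={k} but has "
                    f"only {j} coordinate lines"
                )
            parts = lines[i].split()
            if len(parts) != 2:
                raise TPSParseError(
                    f"{path.name}: block {block_no} line {i + 1}: "
                    f"expected 'x y', got {lines[i]!r}"
                )
            coords[j] = [float(parts[0]), float(parts[1])]
            i += 1
        spec_id = f"block{block_no}"
        scale = None
        while i < len(lines):
            stripped = lines[i].strip()
            if not stripped:
                i += 1
                continue
            m2 = _TPS_KV.match(stripped)
            if not m2 or m2.group(1).upper() == "LM":
                break
            key, val = m2.group(1).upper(), m2.group(2).strip()
            if key == "ID":
                spec_id = val
            elif key == "SCALE":
                scale = float(val)
            i += 1
        if scale is not None:
            coords = coords * scale
        wing_type = wing
        if wing_type is None:
            for name, count in WING_LANDMARK_COUNTS.items():
                if count == k:
                    wing_type = name
                    break
        if wing_type is None:
            # Tolerate arbitrary k for generic use by bypassing the wing check.
            cfg = LandmarkConfiguration.__new__(LandmarkConfiguration)
            cfg.specimen_id = spec_id
            cfg.wing = f"generic{k}"
            cfg.coords = coords
            cfg.side = "left"
            cfg.wear_physical = 1
            cfg.wear_scale = 1
            configs.append(cfg)
        else:
            configs.append(
                LandmarkConfiguration(specimen_id=spec_id, wing=wing_type, coords=coords)
            )
    return configs


def write_tps(
    configs: Iterable[LandmarkConfiguration], path: str | Path
) -> None:
    """Write configurations as TPS records (6-decimal fixed notation)."""
    out = []
    for cfg in configs:
        out.append(f"LM={cfg.n_landmarks}")
        for x, y in cfg.coords:
            out.append(f"{x:.6f} {y:.6f}")
        out.append(f"ID={cfg.specimen_id}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Centroid size and superimposition
# ---------------------------------------------------------------------------


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Square root of summed squared landmark distances from the centroid.

    The standard geometric-morphometric size measure; homogeneous of
    degree one, so scaling all coordinates by c scales CS by ``|c|``.
    """
    coords = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    centred = coords - coords.mean(axis=0)
    cs = float(np.sqrt((centred**2).sum()))
    if cs == 0.0:
        raise DegenerateConfigurationError("all landmarks coincide; centroid size is zero")
    return cs


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """2-D rotation (det +1, no reflection) minimising ||source R - target||."""
    h = source.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    correction = np.diag([1.0, d])
    return u @ correction @ vt


def _centre_and_scale(coords: np.ndarray) -> tuple[np.ndarray, float]:
    centred = coords - coords.mean(axis=0)
    cs = np.sqrt((centred**2).sum())
    if cs == 0.0:
        raise DegenerateConfigurationError("degenerate (zero-size) configuration")
    return centred / cs, float(cs)


def gpa(
    configs: Sequence[LandmarkConfiguration] | np.ndarray,
    tol: float = DEFAULT_GPA_TOL,
    max_iter: int = DEFAULT_GPA_MAX_ITER,
    mirror_right: bool = True,
) -> ProcrustesResult:
    """Generalised Procrustes superimposition with tangent projection.

    Each configuration is centred, scaled to unit centroid size and
    rotated (reflections excluded) to the running consensus; the
    consensus is the renormalised mean, iterated until its RMS change
    drops below ``tol``. Right-side configurations are mirrored first
    so left and right wings are directly comparable. Final shapes are
    orthogonally projected onto the tangent plane at the consensus.
    """
    if isinstance(configs, np.ndarray):
        arr = np.asarray(configs, dtype=float)
        if arr.ndim != 3 or arr.shape[2] != 2:
            raise ValueError("array input must be n x k x 2")
        raw = [arr[i] for i in range(arr.shape[0])]
    else:
        wings = {c.wing for c in configs}
        if len(wings) > 1:
            raise ValueError(f"mixed wing types in one GPA: {sorted(wings)}")
        raw = [
            (c.mirrored() if (mirror_right and c.side == "right") else c).coords
            for c in configs
        ]
    n = len(raw)
    if n < 2:
        raise ValueError("GPA requires at least two configurations")

    scaled = []
    sizes = np.empty(n)
    for i, coords in enumerate(raw):
        unit, cs = _centre_and_scale(coords)
        scaled.append(unit)
        sizes[i] = cs
    shapes = np.stack(scaled)  # n x k x 2, unit CS, centred
    k = shapes.shape[1]

    consensus = shapes[0].copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            shapes[i] = shapes[i] @ _optimal_rotation(shapes[i], consensus)
        new_consensus = shapes.mean(axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        new_consensus /= np.sqrt((new_consensus**2).sum())
        change = np.sqrt(((new_consensus - consensus) ** 2).mean())
        consensus = new_consensus
        if change < tol:
            converged = True
            break

    # Orthogonal projection onto the tangent plane at the consensus:
    # remove the component of each shape along the consensus direction.
    c = consensus.reshape(-1)
    flat = shapes.reshape(n, -1)
    coef = flat @ c  # per-shape projection onto consensus (|c| = 1)
    tangent = flat - np.outer(coef - 1.0, c)
    aligned = tangent.reshape(n, k, 2)

    return ProcrustesResult(
        aligned=aligned,
        consensus=consensus,
        centroid_sizes=sizes,
        log_cs=np.log(sizes),
        iterations=iterations,
        converged=converged,
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance between two landmark configurations.

    Both shapes are centred and scaled to unit centroid size, b is
    rotated optimally onto a (no reflection), and the root summed
    squared difference is returned. Zero iff the shapes are identical
    up to a similarity transform.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"landmark count mismatch: {a.shape} vs {b.shape}")
    ua, _ = _centre_and_scale(a)
    ub, _ = _centre_and_scale(b)
    rot = _optimal_rotation(ub, ua)
    return float(np.sqrt(((ub @ rot - ua) ** 2).sum()))


# ---------------------------------------------------------------------------
# Allometry
# ---------------------------------------------------------------------------


def _allometry_pct(flat: np.ndarray, log_cs: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares shape-on-size fit; % variance explained, slopes, fitted."""
    x = log_cs - log_cs.mean()
    y = flat - flat.mean(axis=0)
    sxx = float(x @ x)
    beta = (x @ y) / sxx            # 2k slope vector
    fitted = np.outer(x, beta)
    ss_pred = float((fitted**2).sum())
    ss_tot = float((y**2).sum())
    if ss_tot == 0.0:
        return 0.0, beta, fitted
    return 100.0 * ss_pred / ss_tot, beta, fitted


def allometry_regression(
    proc: ProcrustesResult,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> AllometryModel:
    """Multivariate regression of superimposed shape on log centroid size.

    The statistic is the percentage of total shape variance explained
    by size; its permutation p-value shuffles log CS ``n_perm`` times
    and uses the (b+1)/(n_perm+1) estimator. The regression score is
    the projection of each centred shape onto the unit-norm
    coefficient vector; residual shapes (observed minus predicted) are
    the size-adjusted shape variables.
    """
    if seed is None:
        raise ValueError("seed is required for reproducible permutations")
    flat = proc.flat()
    log_cs = proc.log_cs
    n = flat.shape[0]
    if n <= 3:
        raise ValueError("allometry regression requires n > 3")
    if np.ptp(log_cs) == 0.0:
        raise ValueError("log centroid size is constant; no size variation to regress on")

    pct, beta, fitted = _allometry_pct(flat, log_cs)
    y = flat - flat.mean(axis=0)
    residuals = y - fitted

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(log_cs)
        pct_perm, _, _ = _allometry_pct(flat, perm)
        if pct_perm >= pct:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)

    direction = beta / np.linalg.norm(beta)
    scores = y @ direction
    # Slope of the regression score on log CS (simple OLS) with SE.
    x = log_cs - log_cs.mean()
    sxx = float(x @ x)
    slope = float(x @ scores) / sxx
    resid = scores - slope * x
    dof = n - 2
    slope_se = float(np.sqrt((resid @ resid) / dof / sxx))

    return AllometryModel(
        coefficients=beta,
        intercept=flat.mean(axis=0),
        pct_variance_explained=pct,
        permutation_p=p,
        regression_scores=scores,
        residual_shapes=residuals,
        slope=slope,
        slope_se=slope_se,
        log_cs=log_cs.copy(),
        n_perm=n_perm,
        seed=seed,
    )


def compare_allometry_slopes(
    model_a: AllometryModel, model_b: AllometryModel
) -> tuple[float, float]:
    """ANCOVA of the two regression-score-on-log-CS slopes.

    Stacks both datasets and F-tests the group x log CS interaction,
    answering whether allometry differs between the two wings.
    Returns (F, p).
    """
    x = np.concatenate([model_a.log_cs, model_b.log_cs])
    y = np.concatenate([model_a.regression_scores, model_b.regression_scores])
    g = np.concatenate(
        [np.zeros(model_a.log_cs.size), np.ones(model_b.log_cs.size)]
    )
    design = np.column_stack([np.ones_like(x), x, g, x * g])
    fit = sm.OLS(y, design).fit()
    ftest = fit.f_test(np.array([[0.0, 0.0, 0.0, 1.0]]))
    return float(ftest.fvalue), float(ftest.pvalue)


def wireframe_delta(
    consensus: np.ndarray, direction: np.ndarray, covariate_value: float
) -> np.ndarray:
    """Predicted shape at a covariate value along a linear shape direction.

    Returns ``consensus + value * direction`` as a k x 2 array, for
    wireframe plots of shape change against the mean shape.
    """
    consensus = np.asarray(consensus, dtype=float)
    direction = np.asarray(direction, dtype=float).reshape(consensus.shape)
    return consensus + covariate_value * direction
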