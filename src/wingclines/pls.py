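"""Two-block partial least squares and the RV coefficient.

2B-PLS finds paired axes maximising the covariation between two blocks
of variables measured on the same specimens — here size-adjusted wing
shape (block 1) and environmental/demographic covariates (block 2) —
via the singular value decomposition of the between-block
cross-covariance matrix. The RV coefficient summarises the overall
strength of association in [0, 1], generalising the bivariate R².
Inference is by permutation of block-2 rows under the null of complete
independence between blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_N_PERM = 10_000


@dataclass
class PlsResult:
    """Paired singular axes and permutation inference for 2B-PLS."""

    block1_axes: np.ndarray          # p x a, unit columns
    block2_axes: np.ndarray          # q x a, unit columns
    singular_values: np.ndarray      # a, descending
    pct_covariation: np.ndarray      # a, sums to 100
    block_correlation_r: np.ndarray  # a, per-axis score correlation
    scores1: np.ndarray              # n x a
    scores2: np.ndarray              # n x a
    rv: float
    permutation_p_overall: float
    permutation_p_per_axis_r: np.ndarray
    n_perm: int
    seed: int

    @property
    def n_axes(self) -> int:
        return self.singular_values.size


def _centre(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=0)


def rv_coefficient(x: np.ndarray, y: np.ndarray) -> float:
    """Escoufier's RV coefficient between two column-centred blocks.

    rv = tr(S12 S21) / sqrt(tr(S11^2) tr(S22^2)), symmetric in its
    arguments and invariant to orthogonal rotation of either block.
    With single-column blocks it reduces to the squared Pearson
    correlation.
    """
    x = _centre(np.asarray(x, dtype=float))
    y = _centre(np.asarray(y, dtype=float))
    if x.shape[0] != y.shape[0]:
        raise ValueError("blocks must have the same number of rows")
    s11 = x.T @ x
    s22 = y.T @ y
    s12 = x.T @ y
    denom = np.sqrt(np.trace(s11 @ s11) * np.trace(s22 @ s22))
    if denom == 0.0:
        raise ValueError("zero total variance in a block; RV undefined")
    return float(np.trace(s12 @ s12.T) / denom)


def _svd_axes(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = x.shape[0]
    s12 = x.T @ y / (n - 1)
    u, s, vt = np.linalg.svd(s12, full_matrices=False)
    return u, s, vt.T


def two_block_pls(
    block1: np.ndarray,
    block2: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    standardise_block2: bool = True,
) -> PlsResult:
    """Two-block PLS with RV coefficient and permutation tests.

    Both blocks are column-centred internally; block 2 is additionally
    z-scored by default because its variables (degrees latitude, years,
    °C) are on incommensurable scales. The overall permutation p uses
    the RV statistic; per-axis p-values use the absolute correlation
    between paired axis scores, with the null built by permuting the
    rows of block 2 only. Axes are oriented so the largest-magnitude
    block-2 loading on each axis is positive.
    """
    if seed is None:
        raise ValueError("seed is required for reproducible permutations")
    x = np.asarray(block1, dtype=float)
    y = np.asarray(block2, dtype=float)
    if x.ndim != 2 or y.ndim != 2:
        raise ValueError("blocks must be 2-D matrices")
    if x.shape[0] != y.shape[0]:
        raise ValueError(
            f"row mismatch between blocks: {x.shape[0]} vs {y.shape[0]}"
        )
    n = x.shape[0]
    if n < 3:
        raise ValueError("two-block PLS requires n >= 3")

    x = _centre(x)
    y = _centre(y)
    sd = y.std(axis=0, ddof=1)
    if np.any(sd == 0.0):
        bad = int(np.flatnonzero(sd == 0.0)[0])
        raise ValueError(f"zero-variance column {bad} in block 2")
    if standardise_block2:
        y = y / sd

    u, s, v = _svd_axes(x, y)
    # Sign convention: largest |loading| in block 2 positive per axis.
    for a in range(s.size):
        j = int(np.argmax(np.abs(v[:, a])))
        if v[j, a] < 0:
            v[:, a] = -v[:, a]
            u[:, a] = -u[:, a]

    scores1 = x @ u
    scores2 = y @ v
    total = float((s**2).sum())
    pct = 100.0 * s**2 / total if total > 0 else np.zeros_like(s)
    r = np.array(
        [
            np.corrcoef(scores1[:, a], scores2[:, a])[0, 1]
            if scores1[:, a].std() > 0 and scores2[:, a].std() > 0
            else 0.0
            for a in range(s.size)
        ]
    )
    rv_obs = rv_coefficient(x, y)

    rng = np.random.default_rng(seed)
    rv_exceed = 0
    r_exceed = np.zeros(s.size, dtype=int)
    abs_r = np.abs(r)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = y[perm]
        if rv_coefficient(x, yp) >= rv_obs:
            rv_exceed += 1
        up, sp, vp = _svd_axes(x, yp)
        sc1 = x @ up
        sc2 = yp @ vp
        for a in range(s.size):
            if sc1[:, a].std() > 0 and sc2[:, a].std() > 0:
                rp = abs(np.corrcoef(sc1[:, a], sc2[:, a])[0, 1])
            else:
                rp = 0.0
            if rp >= abs_r[a]:
                r_exceed[a] += 1

    p_overall = (rv_exceed + 1) / (n_perm + 1)
    p_axis = (r_exceed + 1) / (n_perm + 1)

    return PlsResult(
        block1_axes=u,
        block2_axes=v,
        singular_values=s,
        pct_covariation=pct,
        block_correlation_r=r,
        scores1=scores1,
        scores2=scores2,
        rv=rv_obs,
        permutation_p_overall=p_overall,
        permutation_p_per_axis_r=p_axis,
        n_perm=n_perm,
        seed=seed,
    )


def pls_axis_loadings_report(
    result: PlsResult, variable_names: list[str]
) -> pd.DataFrame:
    """Per-axis block-2 loadings table with the dominant variable flagged.

    One row per block-2 variable (loadings; the max-|loading| variable
    starred, first-in-order wins ties) plus rows for percent
    covariation explained, between-block correlation r, and the
    per-axis permutation p — the familiar PLS summary-table layout.
    """
    q = result.block2_axes.shape[0]
    if len(variable_names) != q:
        raise ValueError(
            f"{len(variable_names)} names given for {q} block-2 variables"
        )
    cols = [f"PLS{a + 1}" for a in range(result.n_axes)]
    body: dict[str, list] = {c: [] for c in cols}
    for a, col in enumerate(cols):
        loadings = result.block2_axes[:, a]
        star = int(np.argmax(np.abs(loadings)))
        for j in range(q):
            mark = "*" if j == star else ""
            body[col].append(f"{loadings[j]:.2f}{mark}")
    for a, col in enumerate(cols):
        body[col].append(f"{result.pct_covariation[a]:.2f}")
        body[col].append(f"{result.block_correlation_r[a]:.2f}")
        body[col].append(f"{result.permutation_p_per_axis_r[a]:.4f}")
    index = list(variable_names) + [
        "Covariation explained (%)",
        "Correlation between blocks (r)",
        "Correlation coeff. P-value (perm.)",
    ]
    return pd.DataFrame(body, index=index)
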