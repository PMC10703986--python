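"""Morris elementary-effects screening: design, effects and summaries.

The Morris method is a randomised one-at-a-time (OAT) global sensitivity
analysis.  Each of R trajectories starts at a random point of a p-level
grid in the normalised unit cube [0, 1]^K and takes K single-factor steps
of magnitude Delta = p / (2(p-1)), visiting every factor exactly once.
For the factor moved between consecutive trajectory points, the
elementary effect is the finite difference

    EE = (f(x + Delta_i e_i) - f(x)) / Delta_i,

with a signed Delta_i so forward and backward moves of a linear model
give identical effects.  Per factor, the R effects are summarised by
their mean mu, mean absolute value mu* (robust to sign cancellation in
non-monotonic models), sample standard deviation sigma (nonlinearity /
interaction indicator), and the distance D = sqrt(mu*^2 + sigma^2) used
to rank factor importance.

Effects are computed in normalised factor space by default so factors
with different physical units (HU, mm) share one mu*-sigma plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "MorrisDesign",
    "build_design",
    "denormalise",
    "normalise",
    "elementary_effects",
    "summarise",
    "classify",
]

LABEL_NEGLIGIBLE = "negligible"
LABEL_LINEAR = "linear/additive"
LABEL_NONLINEAR = "nonlinear-or-interacting"


@dataclass(frozen=True)
class FactorSpec:
    """One input factor with its physical range (e.g. HU or mm)."""

    name: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError(f"factor '{self.name}': lower bound exceeds upper bound")


@dataclass(frozen=True)
class MorrisDesign:
    """An OAT design of R trajectories over K factors in [0, 1]^K.

    ``matrix`` has N = R*(K+1) rows; rows r*(K+1) .. (r+1)*(K+1)-1 form
    trajectory r, consecutive rows differing in exactly one factor by
    +/- ``delta``.
    """

    factors: tuple[FactorSpec, ...]
    repetitions: int
    levels: int
    delta: float
    seed: object
    matrix: np.ndarray

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def k(self) -> int:
        return len(self.factors)

    def trajectories(self):
        """Iterate over (K+1, K) trajectory blocks."""
        step = self.k + 1
        for r in range(self.repetitions):
            yield self.matrix[r * step:(r + 1) * step]


def build_design(
    factors,
    repetitions: int,
    levels: int = 4,
    seed=0,
) -> MorrisDesign:
    """Random p-level OAT trajectories with Delta = p / (2(p-1)).

    Each trajectory: a base point drawn from the level grid
    {0, 1/(p-1), ..., 1}, then one +/-Delta move per factor in random
    order; a move that would leave [0, 1] takes the opposite sign (with
    the standard Delta exactly one sign is feasible from any level).
    """
    factors = tuple(factors)
    k = len(factors)
    if k < 1:
        raise ValueError("at least one factor required")
    if repetitions < 2:
        raise ValueError("repetitions must be >= 2")
    if levels < 2 or levels % 2 != 0:
        raise ValueError("levels must be an even integer >= 2")
    rng = np.random.default_rng(seed)
    delta = levels / (2.0 * (levels - 1))
    jump = levels // 2  # Delta expressed in integer grid levels

    # Integer level arithmetic keeps every coordinate exactly on the grid.
    rows_lvl = np.empty((repetitions * (k + 1), k), dtype=np.int64)
    for r in range(repetitions):
        base = rng.integers(0, levels, size=k)
        order = rng.permutation(k)
        signs = rng.choice([-1, 1], size=k)
        traj = np.empty((k + 1, k), dtype=np.int64)
        traj[0] = base
        current = base.copy()
        for step, i in enumerate(order):
            move = int(signs[step]) * jump
            if not (0 <= current[i] + move <= levels - 1):
                move = -move
            if not (0 <= current[i] + move <= levels - 1):
                raise ValueError("infeasible OAT move; check levels")
            current = current.copy()
            current[i] += move
            traj[step + 1] = current
        rows_lvl[r * (k + 1):(r + 1) * (k + 1)] = traj
    rows = rows_lvl / (levels - 1)
    return MorrisDesign(
        factors=factors,
        repetitions=repetitions,
        levels=levels,
        delta=delta,
        seed=seed,
        matrix=rows,
    )


def denormalise(matrix: np.ndarray, factors) -> np.ndarray:
    """Affine map of normalised [0, 1] columns onto physical factor ranges."""
    factors = tuple(factors)
    matrix = np.asarray(matrix, dtype=float)
    lo = np.array([f.lower for f in factors])
    hi = np.array([f.upper for f in factors])
    return lo + matrix * (hi - lo)


def normalise(matrix: np.ndarray, factors) -> np.ndarray:
    """Inverse of :func:`denormalise`; degenerate ranges map to 0."""
    factors = tuple(factors)
    matrix = np.asarray(matrix, dtype=float)
    lo = np.array([f.lower for f in factors])
    span = np.array([f.upper - f.lower for f in factors])
    out = np.zeros_like(matrix)
    nz = span != 0
    out[:, nz] = (matrix[:, nz] - lo[nz]) / span[nz]
    return out


def elementary_effects(design: MorrisDesign, outputs) -> pd.DataFrame:
    """R elementary effects per factor from the model outputs.

    ``outputs`` must align row-for-row with ``design.matrix``.  Returns a
    (R x K) DataFrame with one column per factor name.
    """
    outputs = np.asarray(outputs, dtype=float)
    if outputs.shape != (design.n_rows,):
        raise ValueError(
            f"expected {design.n_rows} outputs aligned with the design, "
            f"got shape {outputs.shape}"
        )
    bad = np.flatnonzero(~np.isfinite(outputs))
    if bad.size:
        raise ValueError(f"non-finite model output at design row {int(bad[0])}")

    names = [f.name for f in design.factors]
    ee = np.full((design.repetitions, design.k), np.nan)
    step = design.k + 1
    for r in range(design.repetitions):
        block = design.matrix[r * step:(r + 1) * step]
        out = outputs[r * step:(r + 1) * step]
        for s in range(design.k):
            diff = block[s + 1] - block[s]
            moved = np.flatnonzero(np.abs(diff) > 1e-12)
            if moved.size != 1:
                raise ValueError(
                    f"trajectory {r}, step {s}: expected exactly one factor "
                    f"to move, found {moved.size}"
                )
            i = int(moved[0])
            ee[r, i] = (out[s + 1] - out[s]) / diff[i]
    return pd.DataFrame(ee, columns=names)


def summarise(ee: pd.DataFrame) -> pd.DataFrame:
    """Per-factor mu, sigma (sample sd), mu* and distance D.

    D = sqrt(mu*^2 + sigma^2) is the Euclidean distance of the factor's
    point in the mu*-sigma plane from the origin; larger D means a more
    influential factor.
    """
    if len(ee) < 2:
        raise ValueError("need at least 2 elementary effects per factor")
    if ee.isna().any().any():
        raise ValueError("missing elementary effects")
    mu = ee.mean(axis=0)
    sigma = ee.std(axis=0, ddof=1)
    mu_star = ee.abs().mean(axis=0)
    dist = np.sqrt(mu_star**2 + sigma**2)
    return pd.DataFrame(
        {"mu": mu, "sigma": sigma, "mu_star": mu_star, "distance": dist}
    ).rename_axis("factor")


def classify(summary: pd.DataFrame, negligible_frac: float = 0.05) -> pd.DataFrame:
    """Label factors and rank them by descending distance D.

    A factor is *negligible* when both mu* and sigma fall below
    ``negligible_frac`` of the largest D; otherwise it is
    *nonlinear-or-interacting* when sigma exceeds mu* (dispersion
    dominates the mean absolute effect) and *linear/additive* otherwise.
    """
    if summary.empty:
        raise ValueError("summary has no factors")
    out = summary.copy()
    threshold = negligible_frac * float(out["distance"].max())
    labels = []
    for _, row in out.iterrows():
        if row["mu_star"] <= threshold and row["sigma"] <= threshold:
            labels.append(LABEL_NEGLIGIBLE)
        elif row["sigma"] > row["mu_star"]:
            labels.append(LABEL_NONLINEAR)
        else:
            labels.append(LABEL_LINEAR)
    out["label"] = labels
    out["rank"] = (
        out["distance"].rank(ascending=False, method="first").astype(int)
    )
    return out
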