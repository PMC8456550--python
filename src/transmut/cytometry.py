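"""Plate-based flow cytometry: the normalization chain and the two-level
permutation test for calling expression changes.

The normalization chain mirrors a plate experiment in which a reference
strain occupies 20 fixed control wells per plate and a non-fluorescent
strain quantifies autofluorescence: per-cell fluorescence is scaled by cell
size, well medians are corrected for positional gradients fitted on the
control wells, optionally mapped through a log-linear calibration onto an
expression-linear scale, and finally expressed relative to the reference
strain after autofluorescence subtraction.

The two-level permutation test accounts for the nested variance structure of
such plates (replicate populations grown at the same position resemble each
other more than populations grown at different positions), which makes naive
t-tests against the pooled reference panel overpowered.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class PlateWell:
    plate_id: str
    row: int
    col: int
    strain_id: str
    replicate: int
    value: float
    is_control: bool = False
    is_autofluorescence: bool = False


@dataclass
class ReferencePanel:
    """Replicated reference-strain measurements at many plate positions.

    ``values`` is an (n_positions, n_replicates) array; the canonical panel
    has 146 positions with 4 replicate populations each.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] == 0:
            raise ConfigurationError("panel must be a non-empty 2-D array")


@dataclass
class CalibrationCurve:
    """Ordered (fluorescence, expression) anchors, increasing in both."""

    fluorescence: np.ndarray
    expression: np.ndarray

    def __post_init__(self) -> None:
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        self.expression = np.asarray(self.expression, dtype=float)
        if (np.diff(self.fluorescence) <= 0).any() or (np.diff(self.expression) <= 0).any():
            raise ConfigurationError("calibration anchors must be strictly increasing")


# ---------------------------------------------------------------------------
# Per-well summary
# ---------------------------------------------------------------------------


def summarize_well(events: np.ndarray, min_events: int = 100) -> float:
    """Median size-normalized fluorescence of one well.

    ``events`` is an (n, 2) array of (size, fluorescence) pairs.  Log
    fluorescence is regressed on log size within the sample and the
    normalized per-cell value is exp(residual + mean log fluorescence), so a
    well whose fluorescence is exactly proportional to cell size yields a
    value independent of per-cell size variation.
    """
    events = np.asarray(events, dtype=float)
    if events.ndim != 2 or events.shape[1] != 2:
        raise DataError("events must be an (n, 2) array of (size, fluorescence)")
    if len(events) < min_events:
        raise DataError(f"need >= {min_events} events, got {len(events)}")
    size, fl = events[:, 0], events[:, 1]
    if (size <= 0).any() or (fl <= 0).any():
        raise DataError("sizes and fluorescence values must be positive")
    ls, lf = np.log(size), np.log(fl)
    if np.var(ls) < 1e-12:
        warnings.warn("degenerate cell-size variance; returning raw median")
        return float(np.median(fl))
    slope = np.cov(ls, lf, bias=True)[0, 1] / np.var(ls)
    resid = lf - lf.mean() - slope * (ls - ls.mean())
    return float(np.median(np.exp(resid + lf.mean())))


# ---------------------------------------------------------------------------
# Position-effect correction
# ---------------------------------------------------------------------------


def correct_position_effects(wells: pd.DataFrame) -> pd.DataFrame:
    """Remove plate positional gradients estimated from control wells.

    Per plate, a linear model value ~ intercept + row + col (numeric
    coordinates) is fitted to the control wells; every well's value is then
    shifted by (fitted value at its position - mean fitted value over the
    controls), which leaves the control mean unchanged by construction.
    Plates with fewer than 3 controls are passed through with a warning.
    Returns a copy with a ``corrected`` column.
    """
    for col in ("plate_id", "row", "col", "value", "is_control"):
        if col not in wells.columns:
            raise ConfigurationError(f"wells table lacks column {col!r}")
    out = wells.copy()
    out["corrected"] = out["value"].astype(float)
    for plate, sub in out.groupby("plate_id", sort=False):
        ctrl = sub[sub["is_control"]]
        if len(ctrl) < 3:
            warnings.warn(f"plate {plate}: fewer than 3 control wells, no correction")
            continue
        X = np.column_stack(
            [np.ones(len(ctrl)), ctrl["row"].to_numpy(float), ctrl["col"].to_numpy(float)]
        )
        beta, *_ = np.linalg.lstsq(X, ctrl["value"].to_numpy(float), rcond=None)
        fitted_ctrl = X @ beta
        Xall = np.column_stack(
            [np.ones(len(sub)), sub["row"].to_numpy(float), sub["col"].to_numpy(float)]
        )
        fitted_all = Xall @ beta
        out.loc[sub.index, "corrected"] = (
            sub["value"].to_numpy(float) - (fitted_all - fitted_ctrl.mean())
        )
    return out


# ---------------------------------------------------------------------------
# Calibration and relative expression
# ---------------------------------------------------------------------------


def transform_to_expression(
    values: np.ndarray, curve: CalibrationCurve | None = None
) -> np.ndarray:
    """Map fluorescence onto an expression-linear scale via the calibration
    anchors, interpolating piecewise-linearly in log-log space (so a
    two-anchor curve of log-log slope s turns a 1% fluorescence change into
    an ~s% expression change).  Identity when no curve is given."""
    values = np.asarray(values, dtype=float)
    if curve is None:
        return values.copy()
    lx = np.log(curve.fluorescence)
    ly = np.log(curve.expression)
    q = np.log(values)
    out = np.interp(q, lx, ly)
    # linear extrapolation with the end-segment slopes
    if len(lx) >= 2:
        lo = q < lx[0]
        hi = q > lx[-1]
        s0 = (ly[1] - ly[0]) / (lx[1] - lx[0])
        s1 = (ly[-1] - ly[-2]) / (lx[-1] - lx[-2])
        out[lo] = ly[0] + s0 * (q[lo] - lx[0])
        out[hi] = ly[-1] + s1 * (q[hi] - lx[-1])
    return np.exp(out)


def normalize_to_reference(
    values: np.ndarray, autofluorescence_mean: float, reference_mean: float
) -> np.ndarray:
    """Relative expression: (value - autofl) / (reference - autofl), so the
    reference replicates average to 1 and autofluorescence maps to 0."""
    denom = reference_mean - autofluorescence_mean
    if denom <= 0:
        raise DataError("reference mean must exceed autofluorescence mean")
    return (np.asarray(values, dtype=float) - autofluorescence_mean) / denom


def mad_filter(values: np.ndarray, k: float = 5.0) -> np.ndarray:
    """Drop replicate values farther than k times the median absolute
    deviation from the replicate median.  A zero MAD drops nothing."""
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise DataError("need >= 3 replicates for MAD filtering")
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    if mad == 0:
        return values.copy()
    return values[np.abs(values - med) <= k * mad]


# ---------------------------------------------------------------------------
# Two-level permutation test
# ---------------------------------------------------------------------------


def two_level_permutation_test(
    test_values: np.ndarray,
    panel: ReferencePanel | np.ndarray,
    n_iter: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Permutation test with two levels of resampling.

    Each iteration draws a panel position uniformly, computes the observed
    absolute difference D_obs between the test-strain mean and that
    position's mean, pools the 8 values and splits them uniformly at random
    into two sets of 4 whose absolute mean difference is D_perm, and records
    D = D_obs - D_perm.  The p-value is the fraction of negative D among the
    non-zero D; if every D is zero the test is uninformative and p = 1.

    Draws consume one seeded generator: the n_iter position indices first,
    then the n_iter permutations.
    """
    test = np.asarray(test_values, dtype=float)
    if test.shape != (4,):
        raise ConfigurationError("test_values must hold exactly 4 replicates")
    values = panel.values if isinstance(panel, ReferencePanel) else np.asarray(panel, float)
    if values.ndim != 2 or values.shape[0] == 0:
        raise ConfigurationError("panel must be a non-empty 2-D array")
    if values.shape[1] != 4:
        raise ConfigurationError("each panel position must hold 4 replicates")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    idx = rng.integers(0, values.shape[0], n_iter)
    chosen = values[idx]
    d_obs = np.abs(test.mean() - chosen.mean(axis=1))
    pool = np.concatenate([np.broadcast_to(test, (n_iter, 4)), chosen], axis=1)
    order = np.argsort(rng.random((n_iter, 8)), axis=1)
    perm = np.take_along_axis(pool, order, axis=1)
    d_perm = np.abs(perm[:, :4].mean(axis=1) - perm[:, 4:].mean(axis=1))
    d = d_obs - d_perm
    # classify D with a scale-relative tolerance so that ties survive the
    # roundoff introduced by shifting or rescaling the raw values
    eps = 1e-9 * max(float(np.max(np.abs(pool))), 1e-300)
    nonzero = int(np.sum(np.abs(d) > eps))
    if nonzero == 0:
        return 1.0
    return float(np.sum(d < -eps) / nonzero)


def call_expression_change(
    test_values: np.ndarray,
    panel: ReferencePanel | np.ndarray,
    min_effect: float = 0.01,
    alpha: float = 0.05,
    n_iter: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> bool:
    """Call a significant expression change: the strain's relative expression
    must differ from the panel mean by more than ``min_effect`` (1% by
    default) AND the two-level permutation p-value must fall below alpha."""
    test = np.asarray(test_values, dtype=float)
    values = panel.values if isinstance(panel, ReferencePanel) else np.asarray(panel, float)
    relative = test.mean() / values.mean()
    if abs(relative - 1.0) <= min_effect:
        return False
    p = two_level_permutation_test(test, values, n_iter=n_iter, seed=seed)
    return p < alpha
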