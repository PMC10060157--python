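"""Extrapolated structure factors and activation-level determination.

A partial-occupancy photoproduct at activation level A percent is amplified
to notional full occupancy by the linear approximation

    F_extra = (100 / A) * (F_obs(light) - F_obs(dark)) + F_calc.

The activation level itself is read off the data: maps with coefficients
(2 F_extra - F_calc, phi_dark) are built for a grid of candidate A values,
the negative density around reporter atoms (which show negative Fo-Fo
features) is integrated, and the elbow of the resulting curve -- flat while
A overestimates the true level, rising once A underestimates it -- is
located as the intersection of two fitted straight lines.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .diffmaps import DifferenceSet, difference_amplitudes
from .reflections import ReflectionSet, integrate_density, synthesize_map

__all__ = [
    "ExtrapolationConfig",
    "ActivationScan",
    "extrapolate",
    "activation_scan",
    "find_breakpoint",
    "recover_activation",
]


@dataclasses.dataclass
class ExtrapolationConfig:
    """Scan settings; defaults match the standard analysis recipe.

    a_grid : candidate activation levels in percent (10..50 step 1).
    radius : integration radius around each reporter atom (A).
    threshold : negative-density cut in map sigma units.
    grid_spacing : map grid spacing (A); None picks d_min/3.
    """

    a_grid: np.ndarray = dataclasses.field(
        default_factory=lambda: np.arange(10.0, 51.0, 1.0))
    radius: float = 1.5
    threshold: float = 1.5
    grid_spacing: float | None = None

    def __post_init__(self) -> None:
        self.a_grid = np.asarray(self.a_grid, dtype=float)
        if np.any(np.diff(self.a_grid) <= 0) or np.any(self.a_grid <= 0):
            raise ValueError("a_grid must be strictly increasing and positive")
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclasses.dataclass
class ActivationScan:
    """Negative extrapolated density versus activation level, with the
    fitted two-line breakpoint A*."""

    table: pd.DataFrame  # columns: A, neg_density
    breakpoint: float
    left_line: tuple[float, float]  # slope, intercept
    right_line: tuple[float, float]
    sse: float
    near_parallel: bool = False
    clamped: bool = False


def extrapolate(diff: DifferenceSet, f_calc: ReflectionSet,
                a_percent: float) -> ReflectionSet:
    """F_extra = (100/A) dF + F_calc on the usable difference records.

    Phases are carried from the dark model (``f_calc``).  The linear formula
    can go negative at small A; such records are clamped to zero amplitude
    and flagged False.
    """
    if a_percent <= 0:
        raise ValueError("activation level must be positive")
    if f_calc.observable != "F":
        raise ValueError("f_calc must be an amplitude set")
    cm = f_calc.index_map()
    mask = diff.used.copy()
    rows = []
    for i, h in enumerate(diff.hkl):
        if not mask[i]:
            continue
        j = cm.get(tuple(h))
        if j is None:
            mask[i] = False
            continue
        rows.append((i, j))
    if not rows:
        raise ValueError("no overlap between difference set and F_calc")
    di, cj = np.array(rows).T
    f_extra = (100.0 / a_percent) * diff.dF[di] + f_calc.value[cj]
    clamped = f_extra < 0
    f_extra = np.clip(f_extra, 0.0, None)
    phase = f_calc.phase[cj] if f_calc.phase is not None else None
    sigma = (100.0 / a_percent) * diff.sigma[di]
    return ReflectionSet(f_calc.cell, f_calc.spacegroup, diff.hkl[di],
                         f_extra, sigma, "F", phase=phase, flag=~clamped)


def activation_scan(diff: DifferenceSet, f_calc: ReflectionSet,
                    centers_ortho: np.ndarray,
                    config: ExtrapolationConfig | None = None) -> ActivationScan:
    """Scan candidate activation levels and locate the breakpoint.

    For each A in the grid a map with coefficients (2 F_extra - F_calc,
    phi_dark) is synthesized and the density below ``-threshold`` within
    ``radius`` of the reporter centers is integrated over the union of
    spheres (each voxel once).  Scans for different datasets are fully
    independent -- no state is shared.
    """
    if config is None:
        config = ExtrapolationConfig()
    if f_calc.phase is None:
        raise ValueError("f_calc must carry dark-model phases")
    centers = np.atleast_2d(np.asarray(centers_ortho, dtype=float))
    if centers.size == 0:
        raise ValueError("no reporter centers supplied")
    cm = f_calc.index_map()
    rows = []
    for a in config.a_grid:
        fx = extrapolate(diff, f_calc, float(a))
        cj = np.array([cm[tuple(h)] for h in fx.hkl])
        coeff = 2.0 * fx.value - f_calc.value[cj]
        rs = ReflectionSet(fx.cell, fx.spacegroup, fx.hkl, np.abs(coeff),
                           fx.sigma, "F", phase=fx.phase)
        grid = synthesize_map(rs, config.grid_spacing, coefficients=coeff)
        _, total = integrate_density(grid, centers, config.radius,
                                     config.threshold, sign="negative")
        rows.append((float(a), total))
    table = pd.DataFrame(rows, columns=["A", "neg_density"])
    bp = find_breakpoint(table["A"].to_numpy(), table["neg_density"].to_numpy())
    return ActivationScan(table, *bp)


def find_breakpoint(a_values: np.ndarray, y: np.ndarray,
                    min_points: int = 3, parallel_tol: float = 1e-3):
    """Two-segment least-squares fit; A* is the lines' intersection.

    Exhaustive search over interior split points with ordinary least squares
    on each side; the split minimizing total SSE wins.  The negative density
    falls steeply while the level is underestimated and levels off once it
    is not, so only splits whose left slope is steeper (more negative) than
    the right slope describe an elbow; splits with the opposite orientation
    are not considered.

    Degenerate scans are handled explicitly: a flat curve (no elbow
    information) returns the split abscissa with ``near_parallel`` set; a
    curve that declines over the whole grid without levelling off places the
    elbow at the top of the grid with ``clamped`` set, as does any fitted
    intersection outside the scanned range.

    Returns (A*, left_line, right_line, sse, near_parallel, clamped).
    """
    a_values = np.asarray(a_values, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(a_values) < 6:
        raise ValueError("need at least 6 scan rows to fit two lines")

    def ols(x, t):
        m = np.vstack([x, np.ones_like(x)]).T
        coef, *_ = np.linalg.lstsq(m, t, rcond=None)
        res = t - m @ coef
        return coef, float(res @ res)

    lo, hi = float(a_values[0]), float(a_values[-1])
    a_scale = np.ptp(a_values)
    y_scale = float(np.ptp(y))

    if y_scale <= 1e-9 * max(float(np.max(np.abs(y))), 1e-300):
        mid = len(a_values) // 2
        line = (0.0, float(np.mean(y)))
        return float(a_values[mid]), line, line, 0.0, True, False

    best = None
    for split in range(min_points, len(a_values) - min_points + 1):
        left, lsse = ols(a_values[:split], y[:split])
        right, rsse = ols(a_values[split:], y[split:])
        if left[0] >= right[0]:
            continue  # wrong orientation: not an elbow
        sse = lsse + rsse
        if best is None or sse < best[0] - 1e-15:
            best = (sse, split, left, right)

    if best is None:
        whole, sse = ols(a_values, y)
        line = (float(whole[0]), float(whole[1]))
        if whole[0] < -parallel_tol * y_scale / a_scale:
            # still declining at the top of the grid: elbow lies at/beyond it
            return hi, line, line, sse, False, True
        return float(a_values[len(a_values) // 2]), line, line, sse, True, False

    sse, split, left, right = best
    near_parallel = bool(abs(left[0] - right[0])
                         < parallel_tol * y_scale / a_scale)
    clamped = False
    if near_parallel:
        a_star = float(a_values[split])
    else:
        a_star = float((right[1] - left[1]) / (left[0] - right[0]))
        if not lo <= a_star <= hi:
            a_star = min(max(a_star, lo), hi)
            clamped = True
    return (a_star, (float(left[0]), float(left[1])),
            (float(right[0]), float(right[1])), sse, near_parallel, clamped)


def recover_activation(light: ReflectionSet, dark: ReflectionSet,
                       f_calc: ReflectionSet, centers_ortho: np.ndarray,
                       config: ExtrapolationConfig | None = None,
                       sigma_cut: float = 3.0, d_max: float = 9.0,
                       d_min: float = 1.8) -> ActivationScan:
    """End-to-end activation-level recovery from light/dark amplitude sets.

    Runs difference_amplitudes -> activation_scan -> find_breakpoint and
    returns the full scan with its breakpoint A* (percent).
    """
    diff = difference_amplitudes(light, dark, sigma_cut=sigma_cut,
                                 d_max=d_max, d_min=d_min)
    if diff.phase is None:
        if f_calc.phase is None:
            raise ValueError("dark-model phases are required")
        from .diffmaps import _attach_phases

        _attach_phases(diff, f_calc)
    return activation_scan(diff, f_calc, centers_ortho, config)
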