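"""Lattice-translocation-disorder detection and correction.

A crystal in which a fraction ``kappa`` of layers is shifted by a fractional
translation ``t`` produces observed intensities

    I_obs(h) = I_true(h) * G(h),
    G(h) = (1 - kappa)^2 + kappa^2 + 2 kappa (1 - kappa) cos(2 pi h.t),

the interference factor of two coherently scattering domains.  The defect
announces itself as an off-origin Patterson peak at +/- t; correction divides
the intensities by G(h), and the translated fraction is found by scanning
kappa until that peak is flattened.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .reflections import (
    MapGrid,
    ReflectionSet,
    patterson_map,
    _frac_matrix,
    _orth_matrix,
)

__all__ = [
    "LTDModel",
    "PattersonPeakReport",
    "g_factor",
    "detect_translation_peak",
    "flatness_at",
    "correct_intensities",
    "kappa_scan",
]


@dataclasses.dataclass
class LTDModel:
    """Fractional translation vector t and translated-domain fraction kappa."""

    t: np.ndarray
    kappa: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float) % 1.0
        if not 0.0 <= self.kappa <= 0.5:
            raise ValueError("kappa must lie in [0, 0.5]")


@dataclasses.dataclass
class PattersonPeakReport:
    """Highest off-origin Patterson maximum, heights in map-sigma units."""

    peak_position: np.ndarray
    peak_height: float
    local_background: float
    flatness: float


def g_factor(hkl, t, kappa: float) -> np.ndarray:
    """Two-domain interference factor G(h) = |(1-k) + k exp(2 pi i h.t)|^2."""
    if not 0.0 <= kappa <= 0.5:
        raise ValueError("kappa must lie in [0, 0.5]")
    ht = np.atleast_2d(np.asarray(hkl, dtype=float)) @ np.asarray(t, dtype=float)
    g = (1 - kappa) ** 2 + kappa**2 + 2 * kappa * (1 - kappa) * np.cos(2 * np.pi * ht)
    return g if np.ndim(hkl) > 1 else float(g[0])


def _periodic_distances(grid: MapGrid, frac_center: np.ndarray) -> np.ndarray:
    fa, fb, fc = grid.frac_coords()
    frac = np.stack(np.meshgrid(fa, fb, fc, indexing="ij"), axis=-1)
    delta = (frac - np.asarray(frac_center, float) + 0.5) % 1.0 - 0.5
    orth = _orth_matrix(grid.cell)
    cart = delta @ orth.T
    return np.sqrt(np.einsum("...i,...i", cart, cart))


def _shell_background(grid: MapGrid, frac_pos, inner: float, outer: float) -> float:
    """Median |density| (sigma units) in a shell around a fractional position."""
    rms = grid.rms_sigma
    if rms <= 0:
        return 0.0
    dist = _periodic_distances(grid, frac_pos)
    shell = (dist >= inner) & (dist <= outer)
    if not shell.any():
        return 0.0
    return float(np.median(np.abs(grid.values[shell]))) / rms


def detect_translation_peak(patterson: MapGrid, exclusion_radius: float = 2.5,
                            axis: int | None = None,
                            background_shell: tuple[float, float] = (2.0, 4.0),
                            ) -> PattersonPeakReport:
    """Locate the highest off-origin Patterson maximum.

    ``exclusion_radius`` (A) masks the origin peak; ``axis`` optionally
    restricts the search to one cell axis (0, 1 or 2) when the translocation
    direction is known.  Background is the median |density| in a shell
    around the peak, and ``flatness`` is peak minus background.
    """
    if exclusion_radius <= 0:
        raise ValueError("exclusion_radius must be positive")
    rms = patterson.rms_sigma
    if rms <= 0:
        return PattersonPeakReport(np.zeros(3), 0.0, 0.0, 0.0)
    dist0 = _periodic_distances(patterson, np.zeros(3))
    allowed = dist0 > exclusion_radius
    if axis is not None:
        fa, fb, fc = patterson.frac_coords()
        frac = np.stack(np.meshgrid(fa, fb, fc, indexing="ij"), axis=-1)
        on_axis = np.ones(patterson.shape, dtype=bool)
        for other in range(3):
            if other != axis:
                wrapped = (frac[..., other] + 0.5) % 1.0 - 0.5
                on_axis &= np.isclose(wrapped, 0.0, atol=1e-9)
        allowed &= on_axis
    if not allowed.any():
        raise ValueError("origin exclusion removed every grid point")
    masked = np.where(allowed, patterson.values, -np.inf)
    idx = np.unravel_index(np.argmax(masked), patterson.shape)
    frac_pos = np.array(idx) / np.array(patterson.shape)
    height = float(patterson.values[idx]) / rms
    background = _shell_background(patterson, frac_pos, *background_shell)
    return PattersonPeakReport(frac_pos, height, background, height - background)


def flatness_at(patterson: MapGrid, frac_pos,
                background_shell: tuple[float, float] = (2.0, 4.0)) -> float:
    """Signed residual peak height at a known position: density (sigma units)
    at the nearest grid point minus the shell-median background."""
    rms = patterson.rms_sigma
    if rms <= 0:
        return 0.0
    value = patterson.value_at_frac(frac_pos) / rms
    return value - _shell_background(patterson, frac_pos, *background_shell)


def correct_intensities(i_obs: ReflectionSet, ltd: LTDModel,
                        clamp: float = 0.05) -> ReflectionSet:
    """Recover single-domain intensities: I_corr = I_obs / max(G, clamp).

    The floor prevents noise blow-up where G approaches zero near kappa =
    0.5; clamped records are flagged False so downstream difference maps can
    drop them.  Sigmas are scaled by the same deterministic factor.
    """
    if i_obs.observable != "I":
        raise ValueError("correct_intensities expects intensities")
    if clamp <= 0:
        raise ValueError("clamp must be positive")
    g = np.atleast_1d(g_factor(i_obs.hkl, ltd.t, ltd.kappa))
    clamped = g < clamp
    factor = 1.0 / np.maximum(g, clamp)
    flag = i_obs.flag & ~clamped
    return ReflectionSet(i_obs.cell, i_obs.spacegroup, i_obs.hkl,
                         i_obs.value * factor, i_obs.sigma * factor, "I",
                         phase=None if i_obs.phase is None else i_obs.phase.copy(),
                         flag=flag)


def kappa_scan(i_obs: ReflectionSet, t, kappa_grid=None,
               grid_spacing: float | None = None, clamp: float = 0.05,
               origin_removed: bool = True):
    """Scan kappa from 0 to 0.5, flattening the Patterson peak at t.

    For each kappa the intensities are corrected, the (origin-removed)
    Patterson rebuilt and the signed residual peak at t recorded.  The
    returned ``kappa_star`` minimizes |flatness|, ties broken toward smaller
    kappa; the full table (kappa, flatness) supports plotting.  The scan is
    deterministic given the data.
    """
    if kappa_grid is None:
        kappa_grid = np.round(np.arange(0.0, 0.501, 0.01), 4)
    t = np.asarray(t, dtype=float)
    rows = []
    for kappa in kappa_grid:
        corrected = correct_intensities(i_obs, LTDModel(t, float(kappa)), clamp)
        pat = patterson_map(corrected, grid_spacing, origin_removed=origin_removed)
        rows.append((float(kappa), flatness_at(pat, t)))
    table = pd.DataFrame(rows, columns=["kappa", "flatness"])
    best = int(np.argmin(np.abs(table["flatness"].to_numpy())))
    kappa_star = float(table["kappa"].iloc[best])
    flat = table["flatness"].to_numpy()
    # under-correction leaves a positive residual, over-correction a negative
    # one, so the signed flatness should fall monotonically with kappa
    if len(flat) > 4 and np.any(np.diff(flat) > 0.5):
        warnings.warn("kappa scan is not monotone; argmin may be unstable",
                      stacklevel=2)
    return kappa_star, table
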