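"""Reflection sets, amplitude conversion, relative scaling and Fourier synthesis.

The :class:`ReflectionSet` is the common currency of the whole pipeline: a
Friedel-unique list of Miller indices with either intensities (``I``) or
amplitudes (``F``), their uncertainties, and optional phases (degrees).
Real-space density lives in a :class:`MapGrid`, whose ``rms_sigma`` is the
root-mean-square density of the unit cell after mean removal -- the sigma in
which contour levels and integration thresholds are expressed.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import gemmi
import numpy as np
from scipy.fft import next_fast_len
from scipy.optimize import least_squares

__all__ = [
    "ReflectionSet",
    "MapGrid",
    "ScaleModel",
    "get_spacegroup",
    "d_spacing",
    "intensities_to_amplitudes",
    "fit_scale",
    "synthesize_map",
    "patterson_map",
    "density_at_points",
    "integrate_density",
]

_SG_ALIASES = {
    "P1": "P 1",
    "P 1": "P 1",
    "P21": "P 1 21 1",
    "P 21": "P 1 21 1",
    "P 1 21 1": "P 1 21 1",
}


class UnsupportedSymmetryError(ValueError):
    """Raised for space groups outside the supported P1 / P21 pair."""


def get_spacegroup(symbol: str) -> gemmi.SpaceGroup:
    """Resolve a space-group symbol, restricted to P1 and P21."""
    try:
        hm = _SG_ALIASES[symbol.strip()]
    except KeyError:
        raise UnsupportedSymmetryError(
            f"space group {symbol!r} not supported (use P1 or P21)"
        ) from None
    return gemmi.SpaceGroup(hm)


def _frac_matrix(cell: gemmi.UnitCell) -> np.ndarray:
    """3x3 fractionalization matrix; its rows are the reciprocal basis (1/A)."""
    return np.array(cell.frac.mat.tolist(), dtype=float)


def _orth_matrix(cell: gemmi.UnitCell) -> np.ndarray:
    return np.array(cell.orth.mat.tolist(), dtype=float)


def d_spacing(hkl, cell: gemmi.UnitCell):
    """Resolution d (A) of one Miller index or an (N,3) array of them.

    Uses the general triclinic metric: 1/d = |h a* + k b* + l c*|.
    """
    arr = np.asarray(hkl, dtype=float)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if np.any(np.all(arr == 0, axis=1)):
        raise ValueError("d-spacing undefined for (0,0,0)")
    s = arr @ _frac_matrix(cell)
    d = 1.0 / np.linalg.norm(s, axis=1)
    return float(d[0]) if single else d


@dataclasses.dataclass
class ReflectionSet:
    """Friedel-unique reflections with one observable per record.

    Parameters
    ----------
    cell, spacegroup : crystal context shared by all records.
    hkl : (N,3) integer Miller indices, unique per set.
    value : observable, intensities or amplitudes depending on ``observable``.
    sigma : standard uncertainty of ``value`` (same units).
    observable : ``"I"`` or ``"F"``.
    phase : optional phases in degrees (required for map synthesis).
    flag : per-record usability; records flagged ``False`` were clamped or
        otherwise marked suspect upstream and can be filtered by consumers.
    """

    cell: gemmi.UnitCell
    spacegroup: str
    hkl: np.ndarray
    value: np.ndarray
    sigma: np.ndarray
    observable: str
    phase: np.ndarray | None = None
    flag: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        self.value = np.asarray(self.value, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.observable not in ("I", "F"):
            raise ValueError("observable must be 'I' or 'F'")
        n = len(self.hkl)
        if len(self.value) != n or len(self.sigma) != n:
            raise ValueError("hkl/value/sigma length mismatch")
        if self.phase is not None:
            self.phase = np.asarray(self.phase, dtype=float)
            if len(self.phase) != n:
                raise ValueError("phase length mismatch")
        if self.flag is None:
            self.flag = np.ones(n, dtype=bool)
        else:
            self.flag = np.asarray(self.flag, dtype=bool)
        keys = set(map(tuple, self.hkl))
        if len(keys) != n:
            raise ValueError("duplicate Miller indices in ReflectionSet")
        if self.observable == "F" and np.any(self.value < 0):
            raise ValueError("amplitudes must be non-negative")
        get_spacegroup(self.spacegroup)  # validate early

    @property
    def n(self) -> int:
        return len(self.hkl)

    def d_spacings(self) -> np.ndarray:
        return d_spacing(self.hkl, self.cell)

    def select(self, mask: np.ndarray) -> "ReflectionSet":
        return ReflectionSet(
            self.cell,
            self.spacegroup,
            self.hkl[mask],
            self.value[mask],
            self.sigma[mask],
            self.observable,
            None if self.phase is None else self.phase[mask],
            self.flag[mask],
        )

    def copy(self) -> "ReflectionSet":
        return self.select(np.ones(self.n, dtype=bool))

    def index_map(self) -> dict[tuple[int, int, int], int]:
        return {tuple(h): i for i, h in enumerate(self.hkl)}


@dataclasses.dataclass
class MapGrid:
    """Real-space density samples on the unit-cell grid (a fastest axis order
    ``values[ia, ib, ic]`` with fractional coordinate ``ia/na`` etc.)."""

    values: np.ndarray
    cell: gemmi.UnitCell

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("map grid must be 3-D with >= 2 samples per axis")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        return self.cell.volume / self.values.size

    @property
    def rms_sigma(self) -> float:
        v = self.values - self.values.mean()
        return float(np.sqrt(np.mean(v * v)))

    def frac_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        na, nb, nc = self.shape
        return (
            np.arange(na) / na,
            np.arange(nb) / nb,
            np.arange(nc) / nc,
        )

    def value_at_frac(self, frac: Sequence[float]) -> float:
        """Density at the grid point nearest a fractional position."""
        idx = tuple(
            int(np.rint(frac[i] * self.shape[i])) % self.shape[i] for i in range(3)
        )
        return float(self.values[idx])


@dataclasses.dataclass
class ScaleModel:
    """Overall scale k and isotropic scale B (A^2): F_ref ~ k exp(-B s^2/4) F_mov."""

    k: float
    B: float

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("scale factor k must be positive")

    def factors(self, hkl: np.ndarray, cell: gemmi.UnitCell) -> np.ndarray:
        s2 = 1.0 / d_spacing(hkl, cell) ** 2
        return self.k * np.exp(-self.B * s2 / 4.0)


# ---------------------------------------------------------------------------
# intensity -> amplitude conversion
# ---------------------------------------------------------------------------

def _centric_mask(rs: ReflectionSet) -> np.ndarray:
    ops = get_spacegroup(rs.spacegroup).operations()
    return np.array([ops.is_reflection_centric(list(h)) for h in rs.hkl], dtype=bool)


def _wilson_shells(s2: np.ndarray, intensities: np.ndarray, min_per_shell: int = 10):
    """Per-reflection Wilson mean intensity estimated in equal-count shells.

    Returns (Sigma, ok) where ok is False when any shell is too thin to
    support the prior estimate.
    """
    n = len(s2)
    n_shells = max(1, min(20, n // max(min_per_shell, 30)))
    order = np.argsort(s2)
    bounds = np.array_split(order, n_shells)
    sigma = np.empty(n)
    ok = True
    for idx in bounds:
        if len(idx) < min_per_shell:
            ok = False
        mean_i = float(np.mean(intensities[idx]))
        if mean_i <= 0:
            ok = False
            mean_i = max(float(np.mean(np.abs(intensities[idx]))), 1e-12)
        sigma[idx] = mean_i
    return sigma, ok


def _sqrt_truncate(rs: ReflectionSet) -> tuple[np.ndarray, np.ndarray]:
    f = np.sqrt(np.clip(rs.value, 0.0, None))
    sig_f = np.where(f > 0, rs.sigma / np.maximum(2.0 * f, 1e-300),
                     np.sqrt(np.clip(rs.sigma, 0.0, None)))
    return f, sig_f


def _french_wilson_posterior(i_obs: float, sig_i: float, big_sigma: float,
                             centric: bool) -> tuple[float, float]:
    """Posterior mean/uncertainty of F under a Wilson prior.

    Works in the substituted variable u = sqrt(J) so the centric 1/sqrt(J)
    prior singularity is integrable on a plain trapezoid grid.
    """
    if sig_i <= 0:
        f = np.sqrt(max(i_obs, 0.0))
        return f, 0.0
    u_max = np.sqrt(max(i_obs, 0.0) + 8.0 * sig_i)
    u = np.linspace(0.0, u_max, 600)
    j = u * u
    log_like = -((j - i_obs) ** 2) / (2.0 * sig_i**2)
    if centric:
        log_prior = -j / (2.0 * big_sigma)
        jac = np.ones_like(u)  # 2u du * J^(-1/2) ~ const
    else:
        log_prior = -j / big_sigma
        jac = u  # 2u du, constant factor cancels
    w = jac * np.exp(log_like - log_like.max() + log_prior)
    norm = np.trapezoid(w, u)
    if norm <= 0:
        return np.sqrt(max(i_obs, 0.0)), np.sqrt(max(sig_i, 0.0))
    e_f = np.trapezoid(w * u, u) / norm
    e_f2 = np.trapezoid(w * j, u) / norm
    var = max(e_f2 - e_f * e_f, 0.0)
    return float(e_f), float(np.sqrt(var))


def intensities_to_amplitudes(i_set: ReflectionSet,
                              method: str = "french_wilson") -> ReflectionSet:
    """Convert merged intensities to amplitudes.

    ``sqrt_truncate``: F = sqrt(max(I,0)), error-propagated sigma.
    ``french_wilson``: Bayesian posterior mean under a Wilson prior with the
    mean intensity estimated per resolution shell; negative intensities keep
    positive amplitude estimates.  Thin shells fall back to ``sqrt_truncate``
    with a warning.
    """
    if i_set.observable != "I":
        raise ValueError("intensities_to_amplitudes expects an intensity set")
    if i_set.n == 0:
        raise ValueError("empty reflection set")
    if method == "sqrt_truncate":
        f, sig_f = _sqrt_truncate(i_set)
    elif method == "french_wilson":
        s2 = 1.0 / i_set.d_spacings() ** 2
        big_sigma, ok = _wilson_shells(s2, i_set.value)
        if not ok:
            warnings.warn(
                "resolution shells too thin for a Wilson prior; "
                "falling back to sqrt_truncate",
                stacklevel=2,
            )
            f, sig_f = _sqrt_truncate(i_set)
        else:
            centric = _centric_mask(i_set)
            f = np.empty(i_set.n)
            sig_f = np.empty(i_set.n)
            for i in range(i_set.n):
                f[i], sig_f[i] = _french_wilson_posterior(
                    i_set.value[i], i_set.sigma[i], big_sigma[i], centric[i]
                )
    else:
        raise ValueError(f"unknown conversion method {method!r}")
    return ReflectionSet(
        i_set.cell, i_set.spacegroup, i_set.hkl, f, sig_f, "F",
        None if i_set.phase is None else i_set.phase.copy(), i_set.flag.copy(),
    )


# ---------------------------------------------------------------------------
# relative scaling
# ---------------------------------------------------------------------------

def fit_scale(reference: ReflectionSet, moving: ReflectionSet,
              min_overlap: int = 20) -> ScaleModel:
    """Least-squares (k, B) minimizing sum (F_ref - k exp(-B s^2/4) F_mov)^2."""
    ref_idx = reference.index_map()
    pairs = [(ref_idx[tuple(h)], i) for i, h in enumerate(moving.hkl)
             if tuple(h) in ref_idx]
    if len(pairs) < min_overlap:
        raise ValueError(
            f"only {len(pairs)} overlapping reflections (need >= {min_overlap})"
        )
    ir, im = np.array(pairs).T
    f_ref = reference.value[ir]
    f_mov = moving.value[im]
    s2 = 1.0 / d_spacing(moving.hkl[im], moving.cell) ** 2

    # log-linear start point on records where both amplitudes are positive
    pos = (f_ref > 0) & (f_mov > 0)
    if pos.sum() >= 2:
        a = np.vstack([np.ones(pos.sum()), -s2[pos] / 4.0]).T
        coef, *_ = np.linalg.lstsq(a, np.log(f_ref[pos] / f_mov[pos]), rcond=None)
        k0, b0 = float(np.exp(coef[0])), float(coef[1])
    else:
        k0, b0 = 1.0, 0.0

    def resid(p):
        return f_ref - p[0] * np.exp(-p[1] * s2 / 4.0) * f_mov

    sol = least_squares(resid, x0=[max(k0, 1e-6), b0], method="lm", xtol=1e-14,
                        ftol=1e-14, gtol=1e-14)
    return ScaleModel(k=float(sol.x[0]), B=float(sol.x[1]))


# ---------------------------------------------------------------------------
# Fourier synthesis
# ---------------------------------------------------------------------------

def _expand_coefficients(hkl: np.ndarray, coeff: np.ndarray,
                         spacegroup: str) -> dict[tuple[int, int, int], complex]:
    """Symmetry- and Friedel-expand complex coefficients to the full sphere.

    For an operation x -> R x + t the related reflection is h' = h R with
    F(h') = F(h) exp(-2 pi i h.t).  Duplicated equivalents (e.g. centric
    zones) are placed once.
    """
    ops = list(get_spacegroup(spacegroup).operations())
    out: dict[tuple[int, int, int], complex] = {}
    for op in ops:
        rot = np.array(op.rot, dtype=float) / op.DEN
        tran = np.array(op.tran, dtype=float) / op.DEN
        hp = hkl @ rot
        hp_int = np.rint(hp).astype(int)
        if not np.allclose(hp, hp_int, atol=1e-9):
            raise ValueError("non-integral symmetry-transformed index")
        shift = np.exp(-2j * np.pi * (hkl @ tran))
        vals = coeff * shift
        for h, v in zip(hp_int, vals):
            for key, val in ((tuple(h), v), (tuple(-h), np.conj(v))):
                if key not in out:
                    out[key] = val
    return out


def _choose_shape(cell: gemmi.UnitCell, hkl: np.ndarray,
                  grid_spacing: float) -> tuple[int, int, int]:
    lengths = (cell.a, cell.b, cell.c)
    hmax = np.max(np.abs(hkl), axis=0)
    return tuple(
        next_fast_len(int(max(np.ceil(lengths[i] / grid_spacing), 2 * hmax[i] + 2)))
        for i in range(3)
    )


def default_grid_spacing(rs: ReflectionSet) -> float:
    """d_min/3 -- finer than the usual d_min/2 so small integration spheres
    contain enough voxels for stable integrals."""
    return float(np.min(rs.d_spacings())) / 3.0


def synthesize_map(f_set: ReflectionSet, grid_spacing: float | None = None,
                   coefficients: np.ndarray | None = None) -> MapGrid:
    """Fourier synthesis rho(x) = (1/V) sum_h F(h) exp(i phi) exp(-2 pi i h.x).

    F(000) is implicitly zero, so the map has zero mean.  ``coefficients``
    optionally overrides ``value`` (it may be signed; a negative coefficient
    is a 180-degree phase flip).
    """
    if f_set.phase is None:
        raise ValueError("map synthesis requires phases")
    if f_set.n == 0:
        raise ValueError("empty reflection set")
    if grid_spacing is None:
        grid_spacing = default_grid_spacing(f_set)
    amp = f_set.value if coefficients is None else np.asarray(coefficients, float)
    coeff = amp * np.exp(1j * np.deg2rad(f_set.phase))
    full = _expand_coefficients(f_set.hkl, coeff, f_set.spacegroup)
    shape = _choose_shape(f_set.cell, np.array(list(full.keys())), grid_spacing)
    grid = np.zeros(shape, dtype=complex)
    for h, v in full.items():
        grid[h[0] % shape[0], h[1] % shape[1], h[2] % shape[2]] += v
    rho = np.fft.fftn(grid).real / f_set.cell.volume
    return MapGrid(rho, f_set.cell)


def patterson_map(rs: ReflectionSet, grid_spacing: float | None = None,
                  origin_removed: bool = False) -> MapGrid:
    """Phase-free synthesis with |F|^2 (or I) coefficients.

    ``origin_removed`` subtracts the per-shell mean from the coefficients
    before synthesis, suppressing the origin peak and its termination ripple
    while leaving off-origin translation peaks in place.
    """
    coeff = rs.value.copy() if rs.observable == "I" else rs.value**2
    if origin_removed:
        s2 = 1.0 / rs.d_spacings() ** 2
        n_shells = max(1, min(20, rs.n // 30))
        order = np.argsort(s2)
        for idx in np.array_split(order, n_shells):
            coeff[idx] -= coeff[idx].mean()
    phased = ReflectionSet(
        rs.cell, rs.spacegroup, rs.hkl, np.abs(coeff),
        np.zeros(rs.n), "F", phase=np.where(coeff >= 0, 0.0, 180.0),
    )
    return synthesize_map(phased, grid_spacing)


# ---------------------------------------------------------------------------
# density integration
# ---------------------------------------------------------------------------

def _sphere_masks(grid: MapGrid, centers_ortho: np.ndarray, radius: float):
    """Boolean voxel masks (one per center) for periodic spheres."""
    fa, fb, fc = grid.frac_coords()
    frac = np.stack(np.meshgrid(fa, fb, fc, indexing="ij"), axis=-1)
    orth = _orth_matrix(grid.cell)
    frac_mat = _frac_matrix(grid.cell)
    masks = []
    for center in np.atleast_2d(centers_ortho):
        cfrac = frac_mat @ np.asarray(center, dtype=float)
        delta = (frac - cfrac + 0.5) % 1.0 - 0.5
        cart = delta @ orth.T
        masks.append(np.einsum("...i,...i", cart, cart) <= radius * radius)
    return masks


def density_at_points(grid: MapGrid, points_ortho: np.ndarray) -> np.ndarray:
    """Nearest-voxel density (map units) at orthogonal-A positions."""
    frac_mat = _frac_matrix(grid.cell)
    out = []
    for p in np.atleast_2d(points_ortho):
        out.append(grid.value_at_frac(frac_mat @ np.asarray(p, dtype=float)))
    return np.array(out)


def integrate_density(grid: MapGrid, centers_ortho: np.ndarray, radius: float,
                      threshold: float = 0.0, sign: str = "positive",
                      absolute: bool = False):
    """Integrate thresholded density in spheres around the given centers.

    A voxel contributes when its center lies within ``radius`` (A) of a
    sphere center (periodic minimum-image convention) and its value in map
    sigma exceeds ``threshold`` (positive) or lies below ``-threshold``
    (negative).  Results are in sigma*A^3: (value / rms_sigma) * voxel
    volume; negative integration returns magnitudes.  ``total`` counts every
    voxel once over the union of spheres.

    ``absolute=True`` keeps the threshold in sigma units but reports the
    integral in map-units*A^3 instead of sigma*A^3 -- the right scale when
    comparing maps whose rms differs (e.g. a fluence series).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    rms = grid.rms_sigma
    if rms <= 0:
        centers = np.atleast_2d(centers_ortho)
        return np.zeros(len(centers)), 0.0
    if sign not in ("positive", "negative"):
        raise ValueError("sign must be 'positive' or 'negative'")
    vals_sigma = grid.values / rms
    if sign == "positive":
        selected = np.where(vals_sigma > threshold, vals_sigma, 0.0)
    else:
        selected = np.where(vals_sigma < -threshold, -vals_sigma, 0.0)
    masks = _sphere_masks(grid, centers_ortho, radius)
    vol = grid.voxel_volume * (rms if absolute else 1.0)
    per_center = np.array([float(selected[m].sum()) * vol for m in masks])
    union = np.logical_or.reduce(masks)
    total = float(selected[union].sum()) * vol
    return per_center, total
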