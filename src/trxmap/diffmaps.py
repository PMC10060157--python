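"""Fo(light) - Fo(dark) difference structure factors, maps and integrals.

The light amplitudes are scaled onto the dark ones with an overall (k, B)
model, records outside the resolution window or weaker than the sigma cut
in either set are rejected (each with exactly one primary reason), and the
surviving dF = k exp(-B s^2/4) F_light - F_dark are synthesized with phases
of the refined dark model.  Positive difference density integrated around
reporter atoms as a function of pump fluence gives the fluence-response
curve.
"""

from __future__ import annotations

import dataclasses
import warnings

import gemmi
import numpy as np

from .reflections import (
    MapGrid,
    ReflectionSet,
    ScaleModel,
    d_spacing,
    fit_scale,
    integrate_density,
    synthesize_map,
)

__all__ = [
    "DifferenceSet",
    "FluenceResponse",
    "difference_amplitudes",
    "difference_map",
    "fluence_response",
    "equalize_pattern_counts",
]

REASONS = ("resolution", "sigma-cut", "ltd-clamp", "missing-mate", "missing-phase")


@dataclasses.dataclass
class DifferenceSet:
    """Scaled amplitude differences with per-record rejection bookkeeping.

    ``used`` marks records entering synthesis; every rejected record carries
    one primary reason from :data:`REASONS`.  ``phase`` (degrees, from the
    dark model) may be attached at construction or by
    :func:`difference_map`.
    """

    cell: gemmi.UnitCell
    spacegroup: str
    hkl: np.ndarray
    dF: np.ndarray
    sigma: np.ndarray
    used: np.ndarray
    reason: np.ndarray
    scale: ScaleModel
    phase: np.ndarray | None = None

    @property
    def n_used(self) -> int:
        return int(self.used.sum())

    def used_set(self) -> ReflectionSet:
        """The usable records as a ReflectionSet carrying signed dF in
        ``value`` (sign folded into the phase at synthesis time)."""
        mask = self.used
        phase = None if self.phase is None else self.phase[mask]
        return ReflectionSet(self.cell, self.spacegroup, self.hkl[mask],
                             np.abs(self.dF[mask]), self.sigma[mask], "F",
                             phase=phase)


def difference_amplitudes(light: ReflectionSet, dark: ReflectionSet,
                          sigma_cut: float = 3.0, d_max: float = 9.0,
                          d_min: float = 1.8,
                          ltd_flags: bool = True) -> DifferenceSet:
    """Build scaled difference amplitudes with the standard rejection rules.

    Common reflections only; the resolution window [d_min, d_max] and the
    F/sigF < sigma_cut test (in either input set) reject records before the
    (k, B) scale is fitted on the survivors.  Records flagged False upstream
    (e.g. clamped during LTD correction) are rejected with reason
    ``ltd-clamp`` when ``ltd_flags`` is set.
    """
    if light.observable != "F" or dark.observable != "F":
        raise ValueError("difference_amplitudes expects amplitude sets")
    dark_idx = dark.index_map()
    pairs = [(dark_idx[tuple(h)], i) for i, h in enumerate(light.hkl)
             if tuple(h) in dark_idx]
    if not pairs:
        raise ValueError("no common Miller indices between light and dark")
    id_, il = np.array(pairs).T
    hkl = light.hkl[il]
    d = d_spacing(hkl, dark.cell)

    used = np.ones(len(hkl), dtype=bool)
    reason = np.array([""] * len(hkl), dtype=object)

    out_of_window = (d < d_min) | (d > d_max)
    reason[out_of_window] = "resolution"
    used &= ~out_of_window

    with np.errstate(divide="ignore", invalid="ignore"):
        snr_l = np.where(light.sigma[il] > 0, light.value[il] / light.sigma[il],
                         np.inf)
        snr_d = np.where(dark.sigma[id_] > 0, dark.value[id_] / dark.sigma[id_],
                         np.inf)
    weak = (snr_l < sigma_cut) | (snr_d < sigma_cut)
    newly = used & weak
    reason[newly] = "sigma-cut"
    used &= ~weak

    if ltd_flags:
        clamped = ~(light.flag[il] & dark.flag[id_])
        newly = used & clamped
        reason[newly] = "ltd-clamp"
        used &= ~clamped

    if not used.any():
        raise ValueError("no reflections survive the rejection rules")

    scale = fit_scale(dark.select(np.isin(np.arange(dark.n), id_[used])),
                      light.select(np.isin(np.arange(light.n), il[used])))
    factors = scale.factors(hkl, dark.cell)
    dF = factors * light.value[il] - dark.value[id_]
    sigma = np.sqrt((factors * light.sigma[il]) ** 2 + dark.sigma[id_] ** 2)

    phase = None
    if dark.phase is not None:
        phase = dark.phase[id_].copy()
    return DifferenceSet(dark.cell, dark.spacegroup, hkl, dF, sigma, used,
                         reason, scale, phase)


def _attach_phases(diff: DifferenceSet, phases: ReflectionSet) -> None:
    """Pull dark-model phases into the difference set; records without a
    phase are rejected with reason ``missing-phase``."""
    pm = phases.index_map()
    phase = np.zeros(len(diff.hkl))
    for i, h in enumerate(diff.hkl):
        j = pm.get(tuple(h))
        if j is None or phases.phase is None:
            if diff.used[i]:
                diff.used[i] = False
                diff.reason[i] = "missing-phase"
        else:
            phase[i] = phases.phase[j]
    if (diff.reason == "missing-phase").any():
        warnings.warn("records without a dark-model phase were rejected",
                      stacklevel=3)
    diff.phase = phase


def difference_map(diff: DifferenceSet,
                   dark_model_phases: ReflectionSet | None = None,
                   grid_spacing: float | None = None) -> MapGrid:
    """Synthesize the (dF, phi_dark) difference Fourier map."""
    if dark_model_phases is not None:
        _attach_phases(diff, dark_model_phases)
    if diff.phase is None:
        raise ValueError("difference set has no phases; pass dark_model_phases")
    mask = diff.used
    rs = ReflectionSet(diff.cell, diff.spacegroup, diff.hkl[mask],
                       np.abs(diff.dF[mask]), diff.sigma[mask], "F",
                       phase=diff.phase[mask])
    return synthesize_map(rs, grid_spacing, coefficients=diff.dF[mask])


@dataclasses.dataclass
class FluenceResponse:
    """Integrated positive difference density versus pump fluence."""

    fluences: np.ndarray
    integrals: np.ndarray
    atom_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        order = np.argsort(self.fluences)
        self.fluences = np.asarray(self.fluences, float)[order]
        self.integrals = np.asarray(self.integrals, float)[order]
        if np.any(self.integrals < 0):
            raise ValueError("integrated positive density cannot be negative")


def fluence_response(maps, centers_ortho, radius: float = 2.0,
                     threshold: float = 0.0,
                     atom_labels: tuple[str, ...] = (),
                     absolute: bool = True) -> FluenceResponse:
    """Positive-density integrals around reporter atoms for a fluence series.

    ``maps`` is a sequence of (MapGrid, fluence) pairs sharing one cell; the
    default threshold of 0 sigma integrates the entire positive difference
    density within ``radius`` of the centers.  Integrals default to absolute
    map-units*A^3 because the rms sigma of a difference map itself grows
    with excitation, which would mask the response on a per-map sigma scale.
    """
    maps = list(maps)
    if len(maps) < 2:
        raise ValueError("need at least two maps for a response curve")
    cell0 = maps[0][0].cell
    for grid, _ in maps[1:]:
        if not np.allclose(
            [grid.cell.a, grid.cell.b, grid.cell.c,
             grid.cell.alpha, grid.cell.beta, grid.cell.gamma],
            [cell0.a, cell0.b, cell0.c, cell0.alpha, cell0.beta, cell0.gamma],
        ):
            raise ValueError("all maps must share the unit cell")
    fluences, integrals = [], []
    for grid, fluence in maps:
        _, total = integrate_density(grid, centers_ortho, radius, threshold,
                                     sign="positive", absolute=absolute)
        fluences.append(float(fluence))
        integrals.append(total)
    return FluenceResponse(np.array(fluences), np.array(integrals), atom_labels)


def equalize_pattern_counts(datasets: list[ReflectionSet], target: int,
                            seed: int = 0) -> list[ReflectionSet]:
    """Seeded random subsampling of each dataset's records to ``target``.

    Puts datasets of unequal size on an equal statistical footing before
    merged-statistics comparisons (the record list stands in for the
    per-pattern lists merged upstream of this package).
    """
    if target <= 0:
        raise ValueError("target must be positive")
    smallest = min(ds.n for ds in datasets)
    if target > smallest:
        raise ValueError(f"target {target} exceeds smallest dataset ({smallest})")
    rng = np.random.default_rng(seed)
    out = []
    for ds in datasets:
        if ds.n == target:
            out.append(ds.copy())
            continue
        pick = np.sort(rng.choice(ds.n, size=target, replace=False))
        mask = np.zeros(ds.n, dtype=bool)
        mask[pick] = True
        out.append(ds.select(mask))
    return out
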