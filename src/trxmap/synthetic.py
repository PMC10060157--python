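"""Seeded toy two-state crystals and their merged intensity data.

The generator emulates the statistical structure of a pump-probe
crystallography dataset: a crystal whose content is a coherent mixture of a
majority resting ("dark") conformation and a minority photoactivated
("light") conformation, optionally degraded by a two-domain lattice
translocation defect and Gaussian measurement noise.  Structure factors use
the textbook direct sum with point-atom scattering factors (f = atomic
number) and isotropic B -- adequate for exercising map algebra, and fast
enough that the full pipeline runs in seconds.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import gemmi
import numpy as np

from .ltd import LTDModel, g_factor
from .reflections import (
    ReflectionSet,
    d_spacing,
    get_spacegroup,
    _frac_matrix,
    _orth_matrix,
)

__all__ = [
    "Atom",
    "ToyCrystal",
    "NoiseModel",
    "make_toy_crystal",
    "structure_factors",
    "intensities_from_amplitudes",
    "mix_states",
    "apply_ltd",
    "add_noise",
    "displaced_indices",
]

DEFAULT_CELL = (24.0, 26.0, 22.0, 90.0, 90.0, 90.0)


@dataclasses.dataclass
class Atom:
    element: str
    frac_xyz: np.ndarray
    b_factor: float = 10.0
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.frac_xyz = np.asarray(self.frac_xyz, dtype=float) % 1.0
        if self.b_factor < 0:
            raise ValueError("b_factor must be >= 0")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")

    @property
    def z(self) -> int:
        return gemmi.Element(self.element).atomic_number


@dataclasses.dataclass
class ToyCrystal:
    """Two conformations of the same toy structure in one lattice."""

    cell: gemmi.UnitCell
    spacegroup: str
    atoms_dark: list[Atom]
    atoms_light: list[Atom]
    seed: int

    def __post_init__(self) -> None:
        if len(self.atoms_dark) != len(self.atoms_light):
            raise ValueError("dark and light atom lists must be index-aligned")
        for a, b in zip(self.atoms_dark, self.atoms_light):
            if a.element != b.element:
                raise ValueError("dark/light atoms must not change element")


@dataclasses.dataclass
class NoiseModel:
    """Gaussian intensity noise: sigma_I = fractional_sigma * I + floor."""

    fractional_sigma: float
    floor: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fractional_sigma < 0 or self.floor < 0:
            raise ValueError("noise parameters must be >= 0")


def _as_cell(cell) -> gemmi.UnitCell:
    if isinstance(cell, gemmi.UnitCell):
        return cell
    return gemmi.UnitCell(*cell)


def make_toy_crystal(seed: int, n_atoms: int = 12, cell=DEFAULT_CELL,
                     spacegroup: str = "P1", displacement: float = 0.5,
                     elements: Sequence[str] = ("C", "N", "O"),
                     b_factor: float = 10.0,
                     n_displaced: int | None = None) -> ToyCrystal:
    """Build a reproducible two-state crystal.

    The light state equals the dark state except that a random subset of
    atoms (at least one; default ``max(1, n_atoms // 4)``) is displaced by
    vectors of exactly ``displacement`` A in random directions.
    """
    if n_atoms < 2:
        raise ValueError("need at least two atoms")
    if displacement < 0:
        raise ValueError("displacement must be >= 0")
    get_spacegroup(spacegroup)
    ucell = _as_cell(cell)
    rng = np.random.default_rng(seed)
    frac = rng.random((n_atoms, 3))
    dark = [
        Atom(elements[i % len(elements)], frac[i], b_factor=b_factor)
        for i in range(n_atoms)
    ]
    if n_displaced is None:
        n_displaced = max(1, n_atoms // 4)
    n_displaced = max(1, min(n_displaced, n_atoms))
    moved = rng.choice(n_atoms, size=n_displaced, replace=False)
    frac_mat = _frac_matrix(ucell)
    light = [Atom(a.element, a.frac_xyz.copy(), a.b_factor, a.occupancy)
             for a in dark]
    for i in moved:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        delta_frac = frac_mat @ (direction * displacement)
        light[i] = Atom(dark[i].element,
                        (dark[i].frac_xyz + delta_frac) % 1.0,
                        dark[i].b_factor, dark[i].occupancy)
    return ToyCrystal(ucell, spacegroup, dark, light, int(seed))


def displaced_indices(crystal: ToyCrystal, tol: float = 1e-9) -> np.ndarray:
    """Indices of atoms whose light position differs from the dark one."""
    out = []
    for i, (a, b) in enumerate(zip(crystal.atoms_dark, crystal.atoms_light)):
        delta = (b.frac_xyz - a.frac_xyz + 0.5) % 1.0 - 0.5
        if np.linalg.norm(delta) > tol:
            out.append(i)
    return np.array(out, dtype=int)


def _unique_reflections(cell: gemmi.UnitCell, spacegroup: str,
                        d_min: float) -> np.ndarray:
    sg = get_spacegroup(spacegroup)
    ops = sg.operations()
    asu = gemmi.ReciprocalAsu(sg)
    hmax = int(np.floor(cell.a / d_min)) + 1
    kmax = int(np.floor(cell.b / d_min)) + 1
    lmax = int(np.floor(cell.c / d_min)) + 1
    grid = np.mgrid[-hmax:hmax + 1, -kmax:kmax + 1, -lmax:lmax + 1]
    hkl = grid.reshape(3, -1).T
    hkl = hkl[np.any(hkl != 0, axis=1)]
    d = d_spacing(hkl, cell)
    hkl = hkl[d >= d_min]
    keep = [h for h in hkl
            if asu.is_in(list(h)) and not ops.is_systematically_absent(list(h))]
    return np.array(keep, dtype=int)


def structure_factors(atoms: Sequence[Atom], cell, spacegroup: str = "P1",
                      d_min: float = 1.8) -> ReflectionSet:
    """Direct-summation structure factors for the unique reflections to d_min.

    F(h) = sum_j occ_j f_j exp(-B_j s^2/4) exp(2 pi i h.x_j) with the
    point-atom convention f_j = Z_j; the cell content is expanded over the
    space-group operators before summation.  Returns amplitudes with phases
    (degrees); Friedel mates are not duplicated.
    """
    if len(atoms) == 0:
        raise ValueError("empty atom list")
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    ucell = _as_cell(cell)
    hkl = _unique_reflections(ucell, spacegroup, d_min)
    ops = list(get_spacegroup(spacegroup).operations())
    xs, zs, bs, occs = [], [], [], []
    for atom in atoms:
        for op in ops:
            rot = np.array(op.rot, dtype=float) / op.DEN
            tran = np.array(op.tran, dtype=float) / op.DEN
            xs.append((rot @ atom.frac_xyz + tran) % 1.0)
            zs.append(atom.z)
            bs.append(atom.b_factor)
            occs.append(atom.occupancy)
    xs = np.array(xs)
    zs = np.array(zs, dtype=float)
    bs = np.array(bs, dtype=float)
    occs = np.array(occs, dtype=float)
    s2 = (1.0 / d_spacing(hkl, ucell) ** 2)[:, None]
    phases = np.exp(2j * np.pi * (hkl @ xs.T))
    debye = np.exp(-bs[None, :] * s2 / 4.0)
    f = (phases * debye * (occs * zs)[None, :]).sum(axis=1)
    return ReflectionSet(
        ucell, spacegroup, hkl, np.abs(f), np.zeros(len(hkl)), "F",
        phase=np.rad2deg(np.angle(f)),
    )


def _complex_values(rs: ReflectionSet) -> np.ndarray:
    if rs.phase is None:
        raise ValueError("reflection set carries no phases")
    return rs.value * np.exp(1j * np.deg2rad(rs.phase))


def intensities_from_amplitudes(rs: ReflectionSet) -> ReflectionSet:
    """|F|^2 as a sigma-free intensity set (noise is added separately)."""
    if rs.observable != "F":
        raise ValueError("expected an amplitude set")
    return ReflectionSet(rs.cell, rs.spacegroup, rs.hkl, rs.value**2,
                         np.zeros(rs.n), "I")


def mix_states(f_dark: ReflectionSet, f_light: ReflectionSet,
               alpha: float) -> ReflectionSet:
    """Coherent amplitude mixing F = (1-alpha) F_dark + alpha F_light.

    Models a crystal in which a fraction ``alpha`` of unit cells holds the
    light conformation; the small-substitution coherent regime is exactly
    what the linear extrapolation formula downstream presumes.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if f_dark.n != f_light.n or not np.array_equal(f_dark.hkl, f_light.hkl):
        raise ValueError("mix_states requires index-aligned reflection sets")
    mixed = (1.0 - alpha) * _complex_values(f_dark) + alpha * _complex_values(f_light)
    return ReflectionSet(
        f_dark.cell, f_dark.spacegroup, f_dark.hkl, np.abs(mixed),
        np.zeros(f_dark.n), "F", phase=np.rad2deg(np.angle(mixed)),
    )


def apply_ltd(i_true: ReflectionSet, ltd: LTDModel) -> ReflectionSet:
    """Modulate intensities by the two-domain interference factor G(h)."""
    if i_true.observable != "I":
        raise ValueError("apply_ltd expects intensities")
    g = g_factor(i_true.hkl, ltd.t, ltd.kappa)
    return ReflectionSet(i_true.cell, i_true.spacegroup, i_true.hkl,
                         i_true.value * g, i_true.sigma * g, "I",
                         phase=None if i_true.phase is None else i_true.phase.copy())


def add_noise(i_set: ReflectionSet, model: NoiseModel) -> ReflectionSet:
    """Add seeded Gaussian noise with sigma_I = fractional_sigma * I + floor.

    Negative noisy intensities are retained; amplitude conversion handles
    them downstream.
    """
    if i_set.observable != "I":
        raise ValueError("add_noise expects intensities")
    rng = np.random.default_rng(model.seed)
    sigma = model.fractional_sigma * i_set.value + model.floor
    noisy = i_set.value + rng.standard_normal(i_set.n) * sigma
    return ReflectionSet(i_set.cell, i_set.spacegroup, i_set.hkl, noisy,
                         sigma, "I")
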