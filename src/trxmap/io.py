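"""File formats: reflection TSV dialect, MTZ, structure-factor mmCIF,
PDB/mmCIF models, CCP4 maps, and atom selections.

The TSV dialect is the plain-text interchange format of the package:
comment lines start with ``#``; ``#CELL a b c alpha beta gamma`` and
``#SG symbol`` carry the crystal context; a header line declares the
columns ``H K L`` followed by ``I SIGI`` or ``F SIGF`` (optionally ``PHI``);
records are whitespace-separated.  Round-trips are lossless to the printed
precision.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import gemmi
import numpy as np

from .reflections import MapGrid, ReflectionSet, get_spacegroup
from .synthetic import Atom, ToyCrystal

__all__ = [
    "read_reflections",
    "write_reflections",
    "read_reflections_tsv",
    "write_reflections_tsv",
    "read_reflections_mtz",
    "write_reflections_mtz",
    "write_reflections_mmcif",
    "read_reflections_mmcif",
    "write_map_ccp4",
    "read_model",
    "select_atoms",
    "ModelAtom",
    "write_crystal_pdb",
]


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

def write_reflections_tsv(rs: ReflectionSet, path) -> None:
    cell = rs.cell
    with open(path, "w") as fh:
        fh.write(f"#CELL {cell.a:.6g} {cell.b:.6g} {cell.c:.6g} "
                 f"{cell.alpha:.6g} {cell.beta:.6g} {cell.gamma:.6g}\n")
        fh.write(f"#SG {rs.spacegroup}\n")
        cols = ["H", "K", "L"]
        cols += ["I", "SIGI"] if rs.observable == "I" else ["F", "SIGF"]
        if rs.phase is not None:
            cols.append("PHI")
        fh.write(" ".join(cols) + "\n")
        for i in range(rs.n):
            row = [str(rs.hkl[i, 0]), str(rs.hkl[i, 1]), str(rs.hkl[i, 2]),
                   f"{rs.value[i]:.10g}", f"{rs.sigma[i]:.10g}"]
            if rs.phase is not None:
                row.append(f"{rs.phase[i]:.10g}")
            fh.write(" ".join(row) + "\n")


def read_reflections_tsv(path) -> ReflectionSet:
    cell = None
    sg = None
    header: list[str] | None = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts and parts[0].upper() == "CELL":
                    if len(parts) != 7:
                        raise ValueError(f"{path}: malformed #CELL line")
                    cell = gemmi.UnitCell(*map(float, parts[1:]))
                elif parts and parts[0].upper() == "SG":
                    sg = " ".join(parts[1:])
                continue
            if header is None:
                header = line.split()
                continue
            rows.append([float(x) for x in line.split()])
    if cell is None:
        raise ValueError(f"{path}: missing #CELL comment line")
    if sg is None:
        raise ValueError(f"{path}: missing #SG comment line")
    if header is None or header[:3] != ["H", "K", "L"]:
        raise ValueError(f"{path}: header must start with 'H K L'")
    body = header[3:]
    if body[:2] == ["I", "SIGI"]:
        observable = "I"
    elif body[:2] == ["F", "SIGF"]:
        observable = "F"
    else:
        raise ValueError(f"{path}: unknown observable columns {body!r}")
    has_phi = len(body) > 2 and body[2] == "PHI"
    data = np.array(rows, dtype=float)
    if data.shape[1] != 3 + 2 + int(has_phi):
        raise ValueError(f"{path}: column count does not match header")
    return ReflectionSet(
        cell, sg, data[:, :3].astype(int), data[:, 3], data[:, 4], observable,
        phase=data[:, 5] if has_phi else None,
    )


# ---------------------------------------------------------------------------
# MTZ and structure-factor mmCIF (via gemmi)
# ---------------------------------------------------------------------------

def write_reflections_mtz(rs: ReflectionSet, path) -> None:
    mtz = gemmi.Mtz(with_base=True)
    mtz.spacegroup = get_spacegroup(rs.spacegroup)
    mtz.set_cell_for_all(rs.cell)
    mtz.add_dataset("trxmap")
    if rs.observable == "I":
        mtz.add_column("I", "J")
        mtz.add_column("SIGI", "Q")
    else:
        mtz.add_column("F", "F")
        mtz.add_column("SIGF", "Q")
    if rs.phase is not None:
        mtz.add_column("PHI", "P")
    cols = [rs.hkl[:, 0], rs.hkl[:, 1], rs.hkl[:, 2], rs.value, rs.sigma]
    if rs.phase is not None:
        cols.append(rs.phase)
    mtz.set_data(np.column_stack(cols).astype(np.float32))
    mtz.write_to_file(str(path))


def read_reflections_mtz(path) -> ReflectionSet:
    mtz = gemmi.read_mtz_file(str(path))
    labels = [c.label for c in mtz.columns]
    arr = np.array(mtz, copy=True)
    hkl = arr[:, :3].astype(int)

    def col(name):
        return arr[:, labels.index(name)]

    if "I" in labels:
        observable, value, sigma = "I", col("I"), col("SIGI")
    elif "F" in labels:
        observable, value, sigma = "F", col("F"), col("SIGF")
    else:
        raise ValueError(f"{path}: no I or F column found")
    phase = col("PHI") if "PHI" in labels else None
    sg = mtz.spacegroup.hm.replace(" ", "")
    sg = {"P1": "P1", "P1211": "P21"}.get(sg, mtz.spacegroup.hm)
    return ReflectionSet(mtz.cell, sg, hkl, value.astype(float),
                         sigma.astype(float), observable,
                         phase=None if phase is None else phase.astype(float))


def write_reflections_mmcif(rs: ReflectionSet, path) -> None:
    mtz = gemmi.Mtz(with_base=True)
    mtz.spacegroup = get_spacegroup(rs.spacegroup)
    mtz.set_cell_for_all(rs.cell)
    mtz.add_dataset("trxmap")
    if rs.observable == "I":
        mtz.add_column("I", "J")
        mtz.add_column("SIGI", "Q")
    else:
        mtz.add_column("F", "F")
        mtz.add_column("SIGF", "Q")
    cols = [rs.hkl[:, 0], rs.hkl[:, 1], rs.hkl[:, 2], rs.value, rs.sigma]
    mtz.set_data(np.column_stack(cols).astype(np.float32))
    doc = gemmi.MtzToCif().write_cif_to_string(mtz)
    Path(path).write_text(doc)


def read_reflections_mmcif(path) -> ReflectionSet:
    rblocks = gemmi.as_refln_blocks(gemmi.cif.read(str(path)))
    rb = rblocks[0]
    hkl = np.array(rb.make_miller_array(), dtype=int)
    cell = rb.cell
    sg = rb.spacegroup.hm.replace(" ", "")
    sg = {"P1": "P1", "P1211": "P21"}.get(sg, rb.spacegroup.hm)
    for vcol, scol, obs in (("intensity_meas", "intensity_sigma", "I"),
                            ("F_meas_au", "F_meas_sigma_au", "F")):
        values = rb.make_float_array(vcol)
        if not np.all(np.isnan(values)):
            sigmas = rb.make_float_array(scol)
            return ReflectionSet(cell, sg, hkl, values,
                                 np.nan_to_num(sigmas), obs)
    raise ValueError(f"{path}: no recognized observable in refln block")


_FORMAT_READERS = {
    "tsv": read_reflections_tsv,
    "mtz": read_reflections_mtz,
    "sf-mmcif": read_reflections_mmcif,
}
_FORMAT_WRITERS = {
    "tsv": write_reflections_tsv,
    "mtz": write_reflections_mtz,
    "sf-mmcif": write_reflections_mmcif,
}


def _guess_format(path) -> str:
    suffix = Path(path).suffix.lower()
    return {".mtz": "mtz", ".cif": "sf-mmcif", ".ent": "sf-mmcif"}.get(suffix, "tsv")


def read_reflections(path, fmt: str | None = None) -> ReflectionSet:
    """Read a reflection file (``mtz``, ``sf-mmcif`` or ``tsv``; guessed
    from the suffix when ``fmt`` is None)."""
    fmt = fmt or _guess_format(path)
    try:
        reader = _FORMAT_READERS[fmt]
    except KeyError:
        raise ValueError(f"unknown reflection format {fmt!r}") from None
    return reader(path)


def write_reflections(rs: ReflectionSet, path, fmt: str | None = None) -> None:
    fmt = fmt or _guess_format(path)
    try:
        writer = _FORMAT_WRITERS[fmt]
    except KeyError:
        raise ValueError(f"unknown reflection format {fmt!r}") from None
    writer(rs, path)


# ---------------------------------------------------------------------------
# maps
# ---------------------------------------------------------------------------

def write_map_ccp4(grid: MapGrid, path) -> None:
    """Write a CCP4/MRC map with correct cell and default (X,Y,Z) axis order."""
    fg = gemmi.FloatGrid(*grid.shape)
    fg.set_unit_cell(grid.cell)
    fg.spacegroup = gemmi.SpaceGroup("P 1")
    arr = np.array(fg, copy=False)
    arr[...] = grid.values.astype(np.float32)
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = fg
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# atomic models
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ModelAtom:
    """One atom read from a coordinate file, with its selection label
    ``chain/resname/atomname``."""

    element: str
    pos_ortho: np.ndarray
    frac_xyz: np.ndarray
    b_factor: float
    occupancy: float
    chain: str
    residue: str
    name: str

    @property
    def label(self) -> str:
        return f"{self.chain}/{self.residue}/{self.name}"


def read_model(path, fmt: str | None = None) -> tuple[list[ModelAtom], gemmi.UnitCell, str]:
    """Read a PDB/mmCIF model; returns (atoms, cell, spacegroup symbol)."""
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    cell = st.cell
    sg = (st.spacegroup_hm or "P 1").replace(" ", "")
    sg = {"P1": "P1", "P1211": "P21"}.get(sg, st.spacegroup_hm or "P 1")
    atoms = []
    model = st[0]
    for chain in model:
        for res in chain:
            for atom in res:
                pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                frac = cell.fractionalize(atom.pos)
                atoms.append(ModelAtom(
                    element=atom.element.name,
                    pos_ortho=pos,
                    frac_xyz=np.array([frac.x, frac.y, frac.z]),
                    b_factor=atom.b_iso,
                    occupancy=atom.occ,
                    chain=chain.name,
                    residue=res.name,
                    name=atom.name,
                ))
    return atoms, cell, sg


def select_atoms(atoms: list[ModelAtom], selection: str) -> list[ModelAtom]:
    """Resolve a ``[chain/]resname/atomname`` selection (e.g. ``RET/C20``).

    Raises a descriptive error when nothing matches.
    """
    parts = selection.split("/")
    if len(parts) == 2:
        chain, resname, name = None, parts[0], parts[1]
    elif len(parts) == 3:
        chain, resname, name = parts
    else:
        raise ValueError(f"selection {selection!r} is not [chain/]resname/atomname")
    hits = [a for a in atoms
            if (chain is None or a.chain == chain)
            and a.residue == resname and a.name == name]
    if not hits:
        raise KeyError(f"selection {selection!r} matched no atom")
    return hits


def write_crystal_pdb(crystal: ToyCrystal, path, state: str = "dark") -> None:
    """Write one conformation of a toy crystal as a minimal PDB.

    Atoms go into chain A, residue TOY 1, named ``<element><index>`` so that
    selections like ``TOY/C1`` resolve uniquely.
    """
    atoms = crystal.atoms_dark if state == "dark" else crystal.atoms_light
    st = gemmi.Structure()
    st.cell = crystal.cell
    st.spacegroup_hm = get_spacegroup(crystal.spacegroup).hm
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    res = gemmi.Residue()
    res.name = "TOY"
    res.seqid = gemmi.SeqId(1, " ")
    for i, atom in enumerate(atoms, start=1):
        ga = gemmi.Atom()
        ga.name = f"{atom.element}{i}"
        ga.element = gemmi.Element(atom.element)
        pos = crystal.cell.orthogonalize(gemmi.Fractional(*atom.frac_xyz))
        ga.pos = pos
        ga.occ = atom.occupancy
        ga.b_iso = atom.b_factor
        res.add_atom(ga)
    chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.write_pdb(str(path))


def crystal_from_model(atoms: list[ModelAtom]) -> list[Atom]:
    """Convert read model atoms to synthetic-module atoms (fractional)."""
    return [Atom(a.element, a.frac_xyz, a.b_factor, a.occupancy) for a in atoms]
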