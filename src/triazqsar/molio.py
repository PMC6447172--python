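"""File I/O for aligned molecules and volumetric field maps.

Molecules come in as MOL2 (coordinates + partial charges), SDF (charges via
an optional property tag) or extended XYZ with a trailing charge column;
field maps go out as OpenDX grids or Gaussian cube files for external
renderers.  All paths return/accept the in-memory types of
:mod:`triazqsar.mif_engine`.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np

from .mif_engine import AlignedMoleculeSet, Grid, Molecule

__all__ = [
    "read_mol2",
    "read_sdf",
    "read_xyz",
    "write_xyz",
    "read_molecules",
    "write_dx",
    "read_dx",
    "write_cube",
    "read_cube",
]

BOHR_PER_ANGSTROM = 1.0 / 0.529177210903


def _element_from_mol2(name: str, mol2_type: str) -> str:
    # Tripos atom types look like "C.3", "N.ar", "Cl"; fall back to the name.
    base = mol2_type.split(".")[0]
    if base and base[0].isalpha():
        return base.capitalize() if len(base) > 1 else base.upper()
    return "".join(c for c in name if c.isalpha()).capitalize()


def read_mol2(path: str | Path, molecule_id: int) -> Molecule:
    """One molecule from a Tripos MOL2 file, charges from the charge column."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path), format="MOL2")
        elements = [
            _element_from_mol2(a.name, getattr(a, "type", a.name)) for a in u.atoms
        ]
        charges = (
            u.atoms.charges.astype(float)
            if hasattr(u.atoms, "charges")
            else np.zeros(len(u.atoms))
        )
        return Molecule(molecule_id, elements, u.atoms.positions.astype(float), charges)


def read_sdf(path: str | Path, start_id: int = 1) -> AlignedMoleculeSet:
    """Molecules from an SDF; partial charges are taken from a whitespace
    separated ``partial_charges`` property when present, else zero."""
    from rdkit import Chem

    mols = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    for offset, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"{path}: unreadable molecule at index {offset}")
        conf = mol.GetConformer()
        coords = np.array(
            [[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y, conf.GetAtomPosition(i).z]
             for i in range(mol.GetNumAtoms())]
        )
        elements = [a.GetSymbol() for a in mol.GetAtoms()]
        if mol.HasProp("partial_charges"):
            charges = np.array([float(v) for v in mol.GetProp("partial_charges").split()])
        else:
            charges = np.zeros(mol.GetNumAtoms())
        mols.append(Molecule(start_id + offset, elements, coords, charges))
    return AlignedMoleculeSet(mols)


def read_xyz(path: str | Path) -> AlignedMoleculeSet:
    """Extended XYZ with a charge column: per frame, ``natoms`` line, comment
    line (``id=N`` honoured), then ``element x y z charge`` rows.  Multiple
    concatenated frames become one aligned set."""
    lines = Path(path).read_text().splitlines()
    mols = []
    pos = 0
    next_id = 1
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        natoms = int(lines[pos].strip())
        comment = lines[pos + 1]
        mol_id = next_id
        for token in comment.replace(",", " ").split():
            if token.startswith("id="):
                mol_id = int(token[3:])
        elements, coords, charges = [], [], []
        for ln in lines[pos + 2 : pos + 2 + natoms]:
            parts = ln.split()
            elements.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
            charges.append(float(parts[4]) if len(parts) > 4 else 0.0)
        mols.append(Molecule(mol_id, elements, np.array(coords), np.array(charges)))
        next_id = mol_id + 1
        pos += 2 + natoms
    return AlignedMoleculeSet(mols)


def write_xyz(molecules: AlignedMoleculeSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for mol in molecules.molecules:
            fh.write(f"{len(mol.elements)}\n")
            fh.write(f"id={mol.id} Properties=species:S:1:pos:R:3:charge:R:1\n")
            for el, xyz, q in zip(mol.elements, mol.coords, mol.charges):
                fh.write(f"{el} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f} {q:.6f}\n")


def read_molecules(path: str | Path, molecule_id: int = 1) -> AlignedMoleculeSet:
    """Dispatch on extension: .mol2, .sdf or .xyz/.exyz."""
    suffix = Path(path).suffix.lower()
    if suffix == ".mol2":
        return AlignedMoleculeSet([read_mol2(path, molecule_id)])
    if suffix == ".sdf":
        return read_sdf(path, start_id=molecule_id)
    if suffix in (".xyz", ".exyz"):
        return read_xyz(path)
    raise ValueError(f"unsupported molecule format: {suffix!r}")


def write_dx(values: np.ndarray, grid: Grid, path: str | Path) -> None:
    """Write a scalar field (length n_points, x-fastest linear order) as an
    OpenDX grid."""
    from gridData import Grid as DxGrid

    volume = grid.values_to_volume(np.asarray(values, dtype=float))
    DxGrid(volume, origin=grid.origin, delta=grid.spec.spacing).export(str(path), "DX")


def read_dx(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (volume nx*ny*nz, origin, delta) from an OpenDX file."""
    from gridData import Grid as DxGrid

    g = DxGrid(str(path))
    return np.asarray(g.grid), np.asarray(g.origin), np.asarray(g.delta)


def write_cube(
    values: np.ndarray,
    grid: Grid,
    path: str | Path,
    molecule: Molecule | None = None,
    comment: str = "triazqsar field map",
) -> None:
    """Write a Gaussian cube file (lengths in Bohr, orthogonal axes).

    Data order is the cube convention: x slowest, z fastest.  Without a
    molecule a single placeholder carbon sits at the grid origin so that
    strict readers find an atom block.
    """
    volume = grid.values_to_volume(np.asarray(values, dtype=float))
    nx, ny, nz = grid.counts
    h = grid.spec.spacing * BOHR_PER_ANGSTROM
    origin = grid.origin * BOHR_PER_ANGSTROM
    if molecule is None:
        atom_lines = [(6, 0.0, origin)]
    else:
        from .mif_engine import load_lj_table  # noqa: F401  (element check only)

        numbers = {"H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "P": 15, "S": 16,
                   "Cl": 17, "Br": 35, "I": 53}
        atom_lines = [
            (numbers.get(el, 6), float(q), xyz * BOHR_PER_ANGSTROM)
            for el, q, xyz in zip(molecule.elements, molecule.charges, molecule.coords)
        ]
    with open(path, "w") as fh:
        fh.write(f"{comment}\n")
        fh.write("scalar field, kcal/mol per grid node\n")
        fh.write(f"{len(atom_lines):5d} {origin[0]:12.6f} {origin[1]:12.6f} {origin[2]:12.6f}\n")
        fh.write(f"{nx:5d} {h:12.6f} {0.0:12.6f} {0.0:12.6f}\n")
        fh.write(f"{ny:5d} {0.0:12.6f} {h:12.6f} {0.0:12.6f}\n")
        fh.write(f"{nz:5d} {0.0:12.6f} {0.0:12.6f} {h:12.6f}\n")
        for z, q, xyz in atom_lines:
            fh.write(f"{z:5d} {q:12.6f} {xyz[0]:12.6f} {xyz[1]:12.6f} {xyz[2]:12.6f}\n")
        flat = volume.ravel(order="C")  # x slowest, z fastest
        for start in range(0, len(flat), 6):
            fh.write(" ".join(f"{v: .5E}" for v in flat[start : start + 6]) + "\n")


def read_cube(path: str | Path) -> tuple[np.ndarray, np.ndarray, float]:
    """Return (volume nx*ny*nz, origin in angstrom, spacing in angstrom)."""
    lines = Path(path).read_text().splitlines()
    natoms = int(lines[2].split()[0])
    origin = np.array([float(v) for v in lines[2].split()[1:4]]) / BOHR_PER_ANGSTROM
    counts = []
    spacing = None
    for axis, ln in enumerate(lines[3:6]):
        parts = ln.split()
        counts.append(int(parts[0]))
        step = float(parts[1 + axis])
        spacing = step / BOHR_PER_ANGSTROM
    data_lines = lines[6 + natoms :]
    flat = np.array([float(v) for ln in data_lines for v in ln.split()])
    volume = flat.reshape(tuple(counts), order="C")
    return volume, origin, float(spacing)
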