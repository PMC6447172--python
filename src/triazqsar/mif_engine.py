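"""CoMFA-style molecular interaction fields on a regular 3D lattice.

For each pre-aligned molecule, a probe atom (sp3 carbon carrying +1 e) is
placed at every node of a rectangular grid and two interaction energies are
evaluated in kcal/mol:

* steric: Lennard-Jones 6-12, ``E_vdw = sum_i A_i/r_i^12 - B_i/r_i^6``
* electrostatic: Coulomb, ``E_ele = k * sum_i q_i / r_i^m``

The per-atom ``A_i``/``B_i`` come from an editable per-element parameter
table combined with the probe (Lorentz-Berthelot-style).  The raw fields are
then filtered the way CoMFA practice prescribes before PLS: small values
zeroed, energies truncated to a cutoff, and uninformative columns (flat or
almost-always-zero across the molecule set) dropped.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import yaml

__all__ = [
    "GridSpec",
    "Grid",
    "Molecule",
    "AlignedMoleculeSet",
    "ProbeParams",
    "FieldBlock",
    "PreprocessConfig",
    "MifMatrix",
    "make_grid",
    "steric_field",
    "electrostatic_field",
    "compute_fields",
    "preprocess_fields",
    "load_lj_table",
]

#: Coulomb constant in kcal*angstrom/(mol*e^2).
COULOMB_K = 332.0636
#: Energy assigned where a grid node coincides with an atom; the +/-30
#: kcal/mol cutoff later truncates it like any other close contact.
SINGULARITY_SENTINEL = 1.0e6

FieldKind = Literal["steric", "electrostatic"]


@dataclass(frozen=True)
class GridSpec:
    """Rectangular lattice: extents in angstrom per axis, uniform spacing.

    Node counts per axis are ``floor(extent/spacing) + 1`` (a 26 x 18 x 22
    box at 2 angstrom spacing gives 14 x 10 x 12 = 1680 nodes).  ``origin``
    None means the grid is centred on the centroid of the molecule set;
    give an explicit origin for bit-reproducible maps.
    """

    extents: tuple[float, float, float] = (26.0, 18.0, 22.0)
    spacing: float = 2.0
    origin: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if not self.spacing > 0:
            raise ValueError("spacing must be > 0")
        if any(e < self.spacing for e in self.extents):
            raise ValueError("each extent must be >= spacing")

    @property
    def counts(self) -> tuple[int, int, int]:
        return tuple(int(np.floor(e / self.spacing)) + 1 for e in self.extents)

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.counts
        return nx * ny * nz


@dataclass(frozen=True)
class Grid:
    """Realized lattice with node coordinates.

    Linear index convention: x fastest, ``idx = i + nx*j + nx*ny*k``.
    """

    spec: GridSpec
    origin: np.ndarray  # (3,)

    @property
    def counts(self) -> tuple[int, int, int]:
        return self.spec.counts

    @property
    def n_points(self) -> int:
        return self.spec.n_points

    def points(self) -> np.ndarray:
        """All node coordinates, shape (n_points, 3), x fastest."""
        nx, ny, nz = self.counts
        h = self.spec.spacing
        i, j, k = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
        ijk = np.stack([i.ravel(order="F"), j.ravel(order="F"), k.ravel(order="F")], axis=1)
        return self.origin + ijk * h

    def linear_to_ijk(self, idx: np.ndarray) -> np.ndarray:
        nx, ny, _ = self.counts
        idx = np.asarray(idx)
        return np.stack([idx % nx, (idx // nx) % ny, idx // (nx * ny)], axis=-1)

    def values_to_volume(self, values: np.ndarray) -> np.ndarray:
        """Reshape a length-n_points vector to an (nx, ny, nz) volume."""
        nx, ny, nz = self.counts
        return np.asarray(values).reshape((nz, ny, nx)).transpose(2, 1, 0)


@dataclass
class Molecule:
    id: int
    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3) angstrom
    charges: np.ndarray  # (n_atoms,) elementary charges

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        n = len(self.elements)
        if self.coords.shape != (n, 3) or self.charges.shape != (n,):
            raise ValueError(f"molecule {self.id}: inconsistent atom arrays")
        if not np.isfinite(self.coords).all():
            raise ValueError(f"molecule {self.id}: non-finite coordinates")


@dataclass
class AlignedMoleculeSet:
    """Molecules sharing one alignment frame (no re-alignment performed)."""

    molecules: list[Molecule]

    def __post_init__(self) -> None:
        if not self.molecules:
            raise ValueError("molecule set is empty")
        ids = [m.id for m in self.molecules]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate molecule ids")

    @property
    def ids(self) -> list[int]:
        return [m.id for m in self.molecules]

    def centroid(self) -> np.ndarray:
        return np.concatenate([m.coords for m in self.molecules]).mean(axis=0)


@dataclass(frozen=True)
class ProbeParams:
    """The probe defining both fields: sp3 carbon with +1 e charge."""

    charge: float = 1.0
    k: float = COULOMB_K
    m: int = 1  # 1 = unit dielectric, 2 = distance-dependent dielectric
    lj_R: float = 1.70  # angstrom, half r_min of the probe
    lj_epsilon: float = 0.107  # kcal/mol

    def __post_init__(self) -> None:
        if self.m not in (1, 2):
            raise ValueError("dielectric exponent m must be 1 or 2")
        if not self.k > 0:
            raise ValueError("Coulomb constant must be > 0")


@dataclass
class FieldBlock:
    kind: FieldKind
    molecule_id: int
    values: np.ndarray  # (n_points,) kcal/mol

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.isnan(self.values).any():
            raise ValueError(f"NaN in {self.kind} field of molecule {self.molecule_id}")


@dataclass(frozen=True)
class PreprocessConfig:
    zero_threshold: float = 0.05  # kcal/mol
    cutoff: float = 30.0  # kcal/mol
    min_sd: float = 0.1
    min_nonzero: int = 5  # columns with fewer nonzero entries are dropped

    def __post_init__(self) -> None:
        if min(self.zero_threshold, self.cutoff, self.min_sd, self.min_nonzero) <= 0:
            raise ValueError("all preprocessing thresholds must be positive")


@dataclass
class MifMatrix:
    """Molecules x grid-variables matrix after preprocessing.

    Columns are ordered steric block first then electrostatic, each in grid
    linear-index order.  ``values`` holds every column post zeroing/cutoff;
    ``kept`` marks the columns that survived the variance and sparsity
    filters, with a ``drop_reason`` per dropped column.
    """

    molecule_ids: list[int]
    kinds: np.ndarray  # (n_cols,) of "steric"/"electrostatic"
    grid_indices: np.ndarray  # (n_cols,) linear grid index per column
    values: np.ndarray  # (n_molecules, n_cols)
    kept: np.ndarray  # (n_cols,) bool
    drop_reason: list[str | None]
    grid: Grid | None = None

    @property
    def X(self) -> np.ndarray:
        """Kept columns only, the matrix handed to PLS."""
        return self.values[:, self.kept]

    @property
    def kept_kinds(self) -> np.ndarray:
        return self.kinds[self.kept]

    @property
    def kept_indices(self) -> np.ndarray:
        return self.grid_indices[self.kept]

    def drop_counts(self) -> dict[str, int]:
        reasons = [r for r in self.drop_reason if r is not None]
        return {r: reasons.count(r) for r in sorted(set(reasons))}


def load_lj_table() -> dict:
    """The packaged per-element van der Waals parameter table."""
    ref = importlib.resources.files("triazqsar.data") / "lj_params.yaml"
    return yaml.safe_load(ref.read_text())


def combine_lj(
    elements: Sequence[str],
    probe: ProbeParams,
    table: dict | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-atom A_i, B_i against the probe: r_min = R_i + R_probe,
    eps = sqrt(eps_i * eps_probe); A = eps*r_min^12, B = 2*eps*r_min^6."""
    table = table if table is not None else load_lj_table()
    params = table["elements"]
    A = np.empty(len(elements))
    B = np.empty(len(elements))
    for i, el in enumerate(elements):
        if el not in params:
            raise KeyError(f"no van der Waals parameters for element {el!r}")
        r_min = params[el]["R"] + probe.lj_R
        eps = np.sqrt(params[el]["epsilon"] * probe.lj_epsilon)
        A[i] = eps * r_min**12
        B[i] = 2.0 * eps * r_min**6
    return A, B


def make_grid(spec: GridSpec, molecules: AlignedMoleculeSet | None = None) -> Grid:
    """Build the lattice; without an explicit origin it is centred on the
    centroid of all atoms in the set."""
    if spec.origin is not None:
        origin = np.asarray(spec.origin, dtype=float)
    else:
        if molecules is None:
            raise ValueError("need a molecule set to centre the grid (or give origin)")
        nx, ny, nz = spec.counts
        span = (np.array([nx, ny, nz]) - 1) * spec.spacing
        origin = molecules.centroid() - span / 2.0
    return Grid(spec=spec, origin=origin)


def _distances(points: np.ndarray, coords: np.ndarray) -> np.ndarray:
    diff = points[:, None, :] - coords[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def steric_field(
    molecule: Molecule,
    grid: Grid,
    probe: ProbeParams = ProbeParams(),
    lj_table: dict | None = None,
) -> FieldBlock:
    """Lennard-Jones 6-12 probe energy at every grid node (kcal/mol).

    A node exactly on an atom gets the singularity sentinel, which the
    cutoff filter later truncates like any steeply repulsive contact.
    """
    A, B = combine_lj(molecule.elements, probe, lj_table)
    r = _distances(grid.points(), molecule.coords)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        contrib = A / r**12 - B / r**6
    contrib[r == 0] = SINGULARITY_SENTINEL
    contrib = np.nan_to_num(contrib, posinf=SINGULARITY_SENTINEL, neginf=-SINGULARITY_SENTINEL)
    return FieldBlock("steric", molecule.id, contrib.sum(axis=1))


def electrostatic_field(
    molecule: Molecule,
    grid: Grid,
    probe: ProbeParams = ProbeParams(),
) -> FieldBlock:
    """Coulomb energy of the +1 e probe: k * sum_i q_i / r_i^m (kcal/mol)."""
    r = _distances(grid.points(), molecule.coords)
    with np.errstate(divide="ignore"):
        contrib = probe.k * probe.charge * molecule.charges[None, :] / r**probe.m
    zero = r == 0
    if zero.any():
        contrib[zero] = np.sign(molecule.charges[None, :].repeat(len(r), 0)[zero]) * SINGULARITY_SENTINEL
    return FieldBlock("electrostatic", molecule.id, contrib.sum(axis=1))


def compute_fields(
    molecules: AlignedMoleculeSet,
    grid: Grid,
    probe: ProbeParams = ProbeParams(),
    kinds: Sequence[FieldKind] = ("steric", "electrostatic"),
    lj_table: dict | None = None,
) -> dict[FieldKind, list[FieldBlock]]:
    """Both fields for every molecule in the set, one pass."""
    lj_table = lj_table if lj_table is not None else load_lj_table()
    out: dict[FieldKind, list[FieldBlock]] = {k: [] for k in kinds}
    for mol in molecules.molecules:
        if "steric" in out:
            out["steric"].append(steric_field(mol, grid, probe, lj_table))
        if "electrostatic" in out:
            out["electrostatic"].append(electrostatic_field(mol, grid, probe))
    return out


def preprocess_fields(
    blocks: dict[FieldKind, list[FieldBlock]],
    config: PreprocessConfig = PreprocessConfig(),
    grid: Grid | None = None,
) -> MifMatrix:
    """Assemble the x-variable matrix and apply the four filters in order.

    1. values with magnitude below ``zero_threshold`` are set to zero;
    2. values are truncated to ``[-cutoff, +cutoff]``;
    3. columns with standard deviation below ``min_sd`` are dropped;
    4. columns with fewer than ``min_nonzero`` nonzero entries are dropped.

    The operation is idempotent: running it on its own kept output changes
    nothing.
    """
    kinds_present = [k for k in ("steric", "electrostatic") if k in blocks and blocks[k]]
    if not kinds_present:
        raise ValueError("no field blocks given")
    ids = [b.molecule_id for b in blocks[kinds_present[0]]]
    col_values, col_kinds, col_idx = [], [], []
    for kind in kinds_present:
        kind_blocks = blocks[kind]
        if [b.molecule_id for b in kind_blocks] != ids:
            raise ValueError(f"molecule ids differ between field kinds ({kind})")
        lengths = {len(b.values) for b in kind_blocks}
        if len(lengths) != 1:
            raise ValueError("field blocks computed on inconsistent grids")
        mat = np.stack([b.values for b in kind_blocks])
        col_values.append(mat)
        col_kinds.append(np.full(mat.shape[1], kind, dtype=object))
        col_idx.append(np.arange(mat.shape[1]))
    values = np.concatenate(col_values, axis=1)
    kinds = np.concatenate(col_kinds)
    grid_indices = np.concatenate(col_idx)

    values = values.copy()
    values[np.abs(values) < config.zero_threshold] = 0.0
    np.clip(values, -config.cutoff, config.cutoff, out=values)

    sd = values.std(axis=0)
    nonzero = (values != 0).sum(axis=0)
    kept = np.ones(values.shape[1], dtype=bool)
    drop_reason: list[str | None] = [None] * values.shape[1]
    for j in range(values.shape[1]):
        if sd[j] < config.min_sd:
            kept[j] = False
            drop_reason[j] = "sd_below_min"
        elif nonzero[j] < config.min_nonzero:
            kept[j] = False
            drop_reason[j] = "too_few_nonzero"
    return MifMatrix(
        molecule_ids=list(ids),
        kinds=kinds,
        grid_indices=grid_indices,
        values=values,
        kept=kept,
        drop_reason=drop_reason,
        grid=grid,
    )
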