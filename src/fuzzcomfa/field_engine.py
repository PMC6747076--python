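"""CoMFA-style molecular interaction fields on a shared lattice.

Aligned molecules with partial charges are probed on a regular 3D grid by an
sp3-carbon probe.  Two fields are computed at every lattice point:

* steric — Lennard-Jones 6-12 energy, ``E = sum_a eps_a' [(R_a'/r)^12 -
  2 (R_a'/r)^6]`` with Lorentz/Berthelot-style combining rules
  ``R_a' = R_vdw(atom) + R_vdw(probe)``, ``eps_a' = sqrt(eps_atom eps_probe)``,
  truncated at +30 kcal/mol (the conventional CoMFA threshold, 125.4 kJ/mol);
* electrostatic — Coulomb energy with a distance-dependent dielectric
  ``eps(r) = r``, i.e. ``E = sum_a 332.0636 q_a q_probe / r^2``, magnitude
  truncated at 30 kcal/mol.  Points buried inside a molecule (steric value at
  the cutoff) carry no meaningful electrostatics and are flagged; during
  descriptor assembly those cells are imputed by the column mean over the
  unburied molecules (switchable to dropping the column).

The per-molecule field vectors are assembled into a PLS design matrix: flat
columns labelled by lattice point and field type, near-constant columns
dropped, and each field block scaled to unit total variance so neither field
dominates the regression (standard CoMFA block scaling).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "Atom",
    "Molecule",
    "GridSpec",
    "ProbeSpec",
    "FieldBlock",
    "DescriptorTable",
    "UnderdeterminedAlignmentError",
    "VDW_PARAMS",
    "CARBON_PROBE",
    "STERIC_CUTOFF_KCAL",
    "COULOMB_CONSTANT",
    "read_structures",
    "write_sdf",
    "superpose_on_framework",
    "make_grid",
    "steric_field",
    "electrostatic_field",
    "compute_field_block",
    "assemble_descriptor_table",
]

# Steric truncation: printed in the source settings as 125.4 kJ/mol, which is
# the classic 30 kcal/mol CoMFA default. Internal unit is kcal/mol throughout.
STERIC_CUTOFF_KCAL = 30.0
KCAL_PER_KJ = 1.0 / 4.184

# Coulomb constant for kcal/mol with charges in e and distances in A.
COULOMB_CONSTANT = 332.0636

# Small bundled per-element Lennard-Jones table: (vdW radius A, epsilon
# kcal/mol). Radii follow Bondi's compilation; well depths are generic
# OPLS/Tripos-magnitude values. Elements outside this table error loudly.
VDW_PARAMS: dict[str, tuple[float, float]] = {
    "H": (1.20, 0.030),
    "C": (1.70, 0.107),
    "N": (1.55, 0.095),
    "O": (1.52, 0.116),
    "F": (1.47, 0.080),
    "S": (1.80, 0.250),
    "Cl": (1.75, 0.300),
    "Br": (1.85, 0.390),
}


class UnderdeterminedAlignmentError(ValueError):
    """Fewer than 3 non-collinear mapped atoms: rigid superposition has no
    unique solution."""


@dataclass
class Atom:
    element: str
    coords: np.ndarray  # (3,) Angstrom
    partial_charge: float  # elementary charges
    vdw_radius: float  # Angstrom
    lj_epsilon: float  # kcal/mol

    @classmethod
    def from_element(cls, element: str, coords, partial_charge: float = 0.0) -> "Atom":
        try:
            radius, eps = VDW_PARAMS[element]
        except KeyError:
            raise KeyError(
                f"no van der Waals parameters for element {element!r}; "
                f"supported: {sorted(VDW_PARAMS)}"
            ) from None
        return cls(element, np.asarray(coords, dtype=float), partial_charge, radius, eps)


@dataclass
class Molecule:
    """A rigid 3D structure with per-atom charges and LJ parameters.

    ``framework_map`` maps this molecule's atom indices onto the atom indices
    of an alignment template (the shared pharmacophore framework).
    ``labels`` tags named attachment points (e.g. substitution positions) by
    atom index.
    """

    id: str
    atoms: list[Atom]
    framework_map: dict[int, int] | None = None
    labels: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("molecule needs at least one atom")
        for a in self.atoms:
            if not np.all(np.isfinite(a.coords)):
                raise ValueError("atom coordinates must be finite")
            if a.vdw_radius <= 0:
                raise ValueError("vdw radius must be positive")
        if self.framework_map is not None:
            n = len(self.atoms)
            if any(i < 0 or i >= n for i in self.framework_map):
                raise ValueError("framework_map indices out of range")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms], dtype=float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Molecule":
        rot = np.asarray(rotation, dtype=float)
        tr = np.asarray(translation, dtype=float)
        new_atoms = [replace(a, coords=rot @ a.coords + tr) for a in self.atoms]
        return Molecule(self.id, new_atoms, self.framework_map, dict(self.labels))


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned regular lattice: origin + isotropic spacing + counts."""

    origin: tuple[float, float, float]
    spacing: float
    counts: tuple[int, int, int]

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if any(c < 2 for c in self.counts):
            raise ValueError("need at least 2 lattice points per axis")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.counts
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """All lattice points, shape (n_points, 3), z fastest (C order)."""
        axes = [
            self.origin[k] + self.spacing * np.arange(self.counts[k])
            for k in range(3)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


@dataclass(frozen=True)
class ProbeSpec:
    vdw_radius: float = 1.70  # A
    lj_epsilon: float = 0.107  # kcal/mol
    charge: float = 1.0  # e

    def __post_init__(self):
        if self.vdw_radius <= 0:
            raise ValueError("probe radius must be positive")


# Classical CoMFA probe: sp3 carbon with +1 charge.
CARBON_PROBE = ProbeSpec()


@dataclass
class FieldBlock:
    molecule_id: str
    grid: GridSpec
    steric: np.ndarray  # (n_points,) kcal/mol
    electrostatic: np.ndarray  # (n_points,) kcal/mol
    buried: np.ndarray  # (n_points,) bool: steric at cutoff


# ---------------------------------------------------------------------------
# structure I/O (RDKit-backed)
# ---------------------------------------------------------------------------

_CHARGE_PROP = "PARTIAL_CHARGES"
_RADII_PROP = "VDW_RADII"


def _mol_from_rdkit(rdmol, mol_id: str, charge_hook=None) -> Molecule:
    from rdkit import Chem

    conf = rdmol.GetConformer()
    n = rdmol.GetNumAtoms()
    coords = conf.GetPositions()

    charges = None
    if charge_hook is not None:
        charges = np.asarray(charge_hook(rdmol), dtype=float)
    elif rdmol.HasProp(_CHARGE_PROP):
        charges = np.array(rdmol.GetProp(_CHARGE_PROP).split(), dtype=float)
    elif all(
        a.HasProp("_TriposPartialCharge") for a in rdmol.GetAtoms()
    ):  # MOL2 route
        charges = np.array(
            [a.GetDoubleProp("_TriposPartialCharge") for a in rdmol.GetAtoms()]
        )
    if charges is None or len(charges) != n:
        raise ValueError(
            f"molecule {mol_id!r} carries no usable partial charges "
            f"(property {_CHARGE_PROP!r}, MOL2 charge column, or charge_hook)"
        )

    radii = None
    if rdmol.HasProp(_RADII_PROP):
        radii = np.array(rdmol.GetProp(_RADII_PROP).split(), dtype=float)
        if len(radii) != n:
            raise ValueError(f"{_RADII_PROP} length mismatch on {mol_id!r}")

    atoms = []
    for i, a in enumerate(rdmol.GetAtoms()):
        atom = Atom.from_element(a.GetSymbol(), coords[i], float(charges[i]))
        if radii is not None:
            atom.vdw_radius = float(radii[i])
        atoms.append(atom)
    return Molecule(mol_id, atoms)


def read_structures(path, fmt: str | None = None, charge_hook=None) -> list[Molecule]:
    """Read an SDF (V2000) or MOL2 file into :class:`Molecule` records.

    Charges come from (in priority order) a ``charge_hook(rdmol) -> array``
    callable, a whitespace-separated ``PARTIAL_CHARGES`` molecule property
    (SDF), or the MOL2 per-atom charge column.  A ``VDW_RADII`` property
    overrides the per-element radius table (used by the synthetic series,
    whose substituent size varies continuously).
    """
    from rdkit import Chem

    path = str(path)
    if fmt is None:
        fmt = "mol2" if path.lower().endswith(".mol2") else "sdf"
    fmt = fmt.lower()
    mols: list[Molecule] = []
    if fmt == "sdf":
        supplier = Chem.SDMolSupplier(path, removeHs=False, sanitize=False)
        for k, rdmol in enumerate(supplier):
            if rdmol is None:
                raise ValueError(f"unparseable record {k} in {path}")
            name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else f"mol{k}"
            mols.append(_mol_from_rdkit(rdmol, name or f"mol{k}", charge_hook))
    elif fmt == "mol2":
        rdmol = Chem.MolFromMol2File(path, removeHs=False, sanitize=False)
        if rdmol is None:
            raise ValueError(f"unparseable MOL2 file {path}")
        name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else "mol0"
        mols.append(_mol_from_rdkit(rdmol, name, charge_hook))
    else:
        raise ValueError(f"unknown structure format {fmt!r}")
    return mols


def write_sdf(molecules: list[Molecule], path) -> None:
    """Write molecules to an SDF with charges (and non-tabular radii) stored
    as molecule-level properties, so :func:`read_structures` round-trips."""
    from rdkit import Chem
    from rdkit.Chem import AllChem
    from rdkit.Geometry import Point3D

    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for mol in molecules:
            rw = Chem.RWMol()
            for a in mol.atoms:
                rw.AddAtom(Chem.Atom(a.element))
            conf = Chem.Conformer(len(mol.atoms))
            for i, a in enumerate(mol.atoms):
                conf.SetAtomPosition(i, Point3D(*map(float, a.coords)))
            rdmol = rw.GetMol()
            rdmol.AddConformer(conf)
            rdmol.SetProp("_Name", mol.id)
            rdmol.SetProp(_CHARGE_PROP, " ".join(f"{a.partial_charge:.6f}" for a in mol.atoms))
            default_radii = [VDW_PARAMS.get(a.element, (np.nan,))[0] for a in mol.atoms]
            radii = [a.vdw_radius for a in mol.atoms]
            if not np.allclose(radii, default_radii, equal_nan=False):
                rdmol.SetProp(_RADII_PROP, " ".join(f"{r:.6f}" for r in radii))
            writer.write(rdmol)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# rigid-body superposition
# ---------------------------------------------------------------------------

def superpose_on_framework(mol: Molecule, template: Molecule) -> tuple[Molecule, float]:
    """Least-squares rigid superposition (Kabsch) of the mapped framework
    atoms of ``mol`` onto ``template``; no scaling.

    Returns the transformed copy and the RMSD over mapped atoms.
    """
    if not mol.framework_map:
        raise ValueError(f"molecule {mol.id!r} has no framework_map")
    pairs = sorted(mol.framework_map.items())
    mob = np.array([mol.atoms[i].coords for i, _ in pairs])
    ref = np.array([template.atoms[j].coords for _, j in pairs])
    if len(pairs) < 3:
        raise UnderdeterminedAlignmentError(
            f"{len(pairs)} mapped atoms; need >= 3 non-collinear"
        )
    centered = mob - mob.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise UnderdeterminedAlignmentError("mapped atoms are collinear")

    mob_c = mob.mean(axis=0)
    ref_c = ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - ref_c, mob - mob_c)
    rmat = rot.as_matrix()
    translation = ref_c - rmat @ mob_c
    moved = mol.transformed(rmat, translation)
    mapped = np.array([moved.atoms[i].coords for i, _ in pairs])
    rmsd = float(np.sqrt(np.mean(np.sum((mapped - ref) ** 2, axis=1))))
    return moved, rmsd


# ---------------------------------------------------------------------------
# lattice construction and field evaluation
# ---------------------------------------------------------------------------

def make_grid(molecules, spacing: float = 2.0, margin: float = 4.0) -> GridSpec:
    """Axis-aligned lattice covering the union bounding box of all atoms
    extended by ``margin``, snapped outward to whole steps of ``spacing``.

    Degenerate axes (single point after snapping) are expanded to 2 points.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    mols = list(molecules)
    if not mols:
        raise ValueError("need at least one molecule")
    allc = np.vstack([m.coords for m in mols])
    lo = allc.min(axis=0) - margin
    hi = allc.max(axis=0) + margin
    origin = spacing * np.floor(lo / spacing + 1e-9)
    top = spacing * np.ceil(hi / spacing - 1e-9)
    counts = np.maximum(np.rint((top - origin) / spacing).astype(int) + 1, 2)
    return GridSpec(tuple(map(float, origin)), float(spacing), tuple(map(int, counts)))


def steric_field(
    mol: Molecule,
    grid: GridSpec,
    probe: ProbeSpec = CARBON_PROBE,
    cutoff: float = STERIC_CUTOFF_KCAL,
) -> np.ndarray:
    """Lennard-Jones 6-12 probe energy at every lattice point, kcal/mol,
    truncated above at ``cutoff``. Probe-on-atom coincidence gets the cutoff."""
    pts = grid.points()
    coords = mol.coords
    radii = np.array([a.vdw_radius for a in mol.atoms]) + probe.vdw_radius
    eps = np.sqrt(np.array([a.lj_epsilon for a in mol.atoms]) * probe.lj_epsilon)

    d = np.linalg.norm(pts[:, None, :] - coords[None, :, :], axis=2)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        ratio6 = (radii[None, :] / d) ** 6
        e = eps[None, :] * (ratio6**2 - 2.0 * ratio6)
    e[~np.isfinite(e)] = cutoff
    total = e.sum(axis=1)
    return np.minimum(total, cutoff)


def electrostatic_field(
    mol: Molecule,
    grid: GridSpec,
    probe: ProbeSpec = CARBON_PROBE,
    cutoff: float = STERIC_CUTOFF_KCAL,
) -> np.ndarray:
    """Coulomb probe energy with distance-dependent dielectric eps(r) = r
    (energy ~ 1/r^2), kcal/mol, magnitude truncated at ``cutoff``."""
    pts = grid.points()
    coords = mol.coords
    q = mol.charges * probe.charge

    d = np.linalg.norm(pts[:, None, :] - coords[None, :, :], axis=2)
    with np.errstate(divide="ignore"):
        e = COULOMB_CONSTANT * q[None, :] / d**2
    coincident = ~np.isfinite(e)
    if coincident.any():
        e[coincident] = np.sign(np.broadcast_to(q, e.shape)[coincident]) * cutoff
    total = e.sum(axis=1)
    return np.clip(total, -cutoff, cutoff)


def compute_field_block(
    mol: Molecule,
    grid: GridSpec,
    probe: ProbeSpec = CARBON_PROBE,
    cutoff: float = STERIC_CUTOFF_KCAL,
) -> FieldBlock:
    """Both fields for one molecule; lattice points whose steric energy sits
    at the cutoff are flagged as buried (their electrostatics are later
    imputed column-wise)."""
    s = steric_field(mol, grid, probe, cutoff)
    e = electrostatic_field(mol, grid, probe, cutoff)
    buried = s >= cutoff - 1e-12
    return FieldBlock(mol.id, grid, s, e, buried)


# ---------------------------------------------------------------------------
# descriptor assembly
# ---------------------------------------------------------------------------

@dataclass
class DescriptorTable:
    """PLS-ready design matrix with the bookkeeping needed to map columns
    back to lattice points and to transform new molecules consistently."""

    X: pd.DataFrame  # rows = molecules, filtered + block-scaled columns
    y: pd.Series  # response (CEI) aligned with X rows
    grid: GridSpec
    column_meta: pd.DataFrame  # per retained column: field, point index, sd, scale
    impute_means: pd.Series  # electrostatic imputation means, by raw column label
    block_scale: dict[str, float]  # per-field multiplicative scale factor

    def transform(self, blocks: list[FieldBlock]) -> pd.DataFrame:
        """Apply the training-time imputation, column selection and block
        scaling to new field blocks (e.g. designed derivatives)."""
        raw = _raw_matrix(blocks, self.grid, self.impute_means)
        X = raw[self.column_meta.index].copy()
        for fld, fac in self.block_scale.items():
            cols = self.column_meta.index[self.column_meta["field"] == fld]
            X.loc[:, cols] = X.loc[:, cols] * fac
        return X


def _raw_matrix(
    blocks: list[FieldBlock], grid: GridSpec, impute_means: pd.Series | None = None
) -> pd.DataFrame:
    rows, index = [], []
    buried_rows = []
    for b in blocks:
        if b.grid != grid:
            raise ValueError(f"grid mismatch for molecule {b.molecule_id!r}")
        rows.append(np.concatenate([b.steric, b.electrostatic]))
        buried_rows.append(np.concatenate([np.zeros_like(b.buried), b.buried]))
        index.append(b.molecule_id)
    n = grid.n_points
    columns = [f"S{i}" for i in range(n)] + [f"E{i}" for i in range(n)]
    X = pd.DataFrame(np.array(rows), index=index, columns=columns)
    buried = pd.DataFrame(np.array(buried_rows, dtype=bool), index=index, columns=columns)

    if impute_means is None:
        # training mode: column mean over unburied entries (0 if all buried)
        masked = X.where(~buried)
        impute_means = masked.mean(axis=0).fillna(0.0)
    X = X.where(~buried, impute_means, axis=1)
    X.attrs["impute_means"] = impute_means
    return X


def assemble_descriptor_table(
    blocks: list[FieldBlock],
    response: pd.Series,
    min_sigma: float = 0.05,
) -> DescriptorTable:
    """Build the PLS design matrix from per-molecule field blocks.

    Columns with standard deviation below ``min_sigma`` (kcal/mol) are
    dropped (CoMFA's minimum-sigma filter), then each field block is scaled
    to unit total variance so the two fields contribute equally a priori.
    """
    if not blocks:
        raise ValueError("no field blocks")
    grid = blocks[0].grid
    raw = _raw_matrix(blocks, grid)
    impute_means = raw.attrs["impute_means"]

    missing = [i for i in raw.index if i not in response.index]
    if missing:
        raise ValueError(f"response missing molecules: {missing}")
    y = response.loc[raw.index].astype(float)

    sd = raw.std(axis=0, ddof=1)
    keep = sd >= min_sigma
    if not keep.any():
        raise ValueError(
            f"no columns retained: min_sigma={min_sigma} exceeds every column sd "
            f"(max sd {sd.max():.4g})"
        )
    X = raw.loc[:, keep].copy()
    kept_sd = sd[keep]

    block_scale: dict[str, float] = {}
    meta_field = pd.Series(
        ["steric" if c.startswith("S") else "electrostatic" for c in X.columns],
        index=X.columns,
    )
    for fld in ("steric", "electrostatic"):
        cols = X.columns[meta_field == fld]
        if len(cols) == 0:
            block_scale[fld] = 1.0
            continue
        total_var = float((kept_sd[cols] ** 2).sum())
        fac = 1.0 / np.sqrt(total_var) if total_var > 0 else 1.0
        block_scale[fld] = fac
        X.loc[:, cols] = X.loc[:, cols] * fac

    meta = pd.DataFrame(
        {
            "field": meta_field,
            "point": [int(c[1:]) for c in X.columns],
            "raw_sd": kept_sd,
            "scale": [block_scale[f] for f in meta_field],
        }
    )
    return DescriptorTable(X, y, grid, meta, impute_means, block_scale)
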