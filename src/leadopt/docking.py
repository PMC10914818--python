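"""Docking-validation stage: grid-box construction, receptor/ligand
preparation, engine invocation (20 poses by default), pose parsing, and
geometric hydrogen-bond contact analysis.

The engine itself sits behind an adapter (any object exposing
``run(ligand, receptor, box, n_poses, seed) -> report text``); both
Vina-style result tables and AutoDock DLG pose blocks are understood.
Hydrogen bonds use the heavy-atom donor-acceptor criterion: distance <=
3.5 angstroms, with the donor-H-acceptor angle >= 120 degrees additionally
required whenever an explicit hydrogen is present; distances class as
strong (<= 2.5), moderate (<= 3.5) or weak (beyond, only reported when the
cutoff is raised).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from rdkit import Chem

from .chem import Conformer
from .rewards import DockingEngineError, parse_engine_report

STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
WATER_RESIDUES = {"HOH", "WAT", "DOD"}

# Side-chain hydrogen-bond roles per residue (heavy atoms); the backbone
# amide N donates and the carbonyl O accepts for every residue.
_SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"}, "ASN": {"ND2"}, "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"}, "LYS": {"NZ"}, "SER": {"OG"}, "THR": {"OG1"},
    "TRP": {"NE1"}, "TYR": {"OH"},
}
_SIDECHAIN_ACCEPTORS = {
    "ASN": {"OD1"}, "ASP": {"OD1", "OD2"}, "GLN": {"OE1"},
    "GLU": {"OE1", "OE2"}, "HIS": {"ND1", "NE2"}, "SER": {"OG"},
    "THR": {"OG1"}, "TYR": {"OH"},
}


class DockingError(RuntimeError):
    pass


@dataclass(frozen=True)
class GridBox:
    """Rectangular docking search volume in the receptor coordinate frame."""

    npts: tuple[int, int, int]
    spacing: float
    center: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.npts):
            raise DockingError(f"npts must all be >= 2, got {self.npts}")
        if self.spacing <= 0:
            raise DockingError(f"spacing must be > 0, got {self.spacing}")

    @property
    def extents(self) -> tuple[float, float, float]:
        """Physical edge lengths (angstroms): points * spacing per axis."""
        return tuple(n * self.spacing for n in self.npts)

    def contains(self, point, margin: float = 0.0) -> bool:
        p = np.asarray(point, dtype=float)
        c = np.asarray(self.center, dtype=float)
        half = np.asarray(self.extents) / 2.0 + margin
        return bool(np.all(np.abs(p - c) <= half))

    def gpf_fields(self) -> dict[str, str]:
        """Grid parameters in the engine's native parameter-file dialect."""
        return {
            "npts": " ".join(str(n) for n in self.npts),
            "spacing": f"{self.spacing:g}",
            "gridcenter": " ".join(f"{c:g}" for c in self.center),
        }


def build_grid_box(npts, spacing: float, center) -> GridBox:
    """Validated grid box from points-per-axis, grid spacing and center."""
    return GridBox(npts=tuple(int(n) for n in npts), spacing=float(spacing),
                   center=tuple(float(c) for c in center))


@dataclass(frozen=True)
class ReceptorAtom:
    serial: int
    name: str
    resname: str
    resseq: int
    chain: str
    coords: tuple[float, float, float]
    element: str

    @property
    def residue_label(self) -> str:
        return f"{self.resname}-{self.resseq}"

    @property
    def is_donor(self) -> bool:
        if self.resname in STANDARD_RESIDUES:
            if self.name == "N" and self.resname != "PRO":
                return True
            return self.name in _SIDECHAIN_DONORS.get(self.resname, ())
        return self.element in ("N", "O")  # unknown residue: permissive

    @property
    def is_acceptor(self) -> bool:
        if self.resname in STANDARD_RESIDUES:
            if self.name in ("O", "OXT"):
                return True
            return self.name in _SIDECHAIN_ACCEPTORS.get(self.resname, ())
        return self.element in ("N", "O")


@dataclass
class Receptor:
    """Prepared receptor: heavy atoms with preserved residue numbering."""

    atoms: list[ReceptorAtom]
    source: str = ""
    warnings: list[str] = field(default_factory=list)

    def polar_atoms(self) -> list[ReceptorAtom]:
        return [a for a in self.atoms if a.element in ("N", "O")]

    def atom(self, resseq: int, name: str) -> ReceptorAtom:
        for a in self.atoms:
            if a.resseq == resseq and a.name == name:
                return a
        raise KeyError(f"no atom {name} in residue {resseq}")

    def write_pdb(self, path) -> None:
        with open(path, "w") as fh:
            for a in self.atoms:
                x, y, z = a.coords
                fh.write(
                    f"ATOM  {a.serial:>5} {a.name:<4} {a.resname:>3} "
                    f"{a.chain}{a.resseq:>4}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {a.element:>2}\n"
                )
            fh.write("END   \n")  # padded to the 6-column record width


def prepare_receptor(pdb_path, strip_waters: bool = True) -> Receptor:
    """Load a PDB receptor, drop waters and hydrogens, keep residue
    numbering.  Nonstandard residues pass through with an explicit warning
    (never silently repaired)."""
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("receptor", str(pdb_path))
    atoms: list[ReceptorAtom] = []
    warns: list[str] = []
    seen_unknown: set[str] = set()
    for model in structure:
        for chain in model:
            for residue in chain:
                resname = residue.get_resname().strip()
                if strip_waters and resname in WATER_RESIDUES:
                    continue
                resseq = residue.get_id()[1]
                if resname not in STANDARD_RESIDUES:
                    label = f"{resname}-{resseq}"
                    if label not in seen_unknown:
                        seen_unknown.add(label)
                        msg = f"nonstandard residue {label} passed through"
                        warns.append(msg)
                        warnings.warn(msg)
                for atom in residue:
                    element = (atom.element or atom.get_name()[0]).strip().upper()
                    if element == "H":
                        continue
                    x, y, z = (float(v) for v in atom.get_coord())
                    atoms.append(ReceptorAtom(
                        serial=atom.get_serial_number(), name=atom.get_name(),
                        resname=resname, resseq=resseq, chain=chain.get_id(),
                        coords=(x, y, z), element=element,
                    ))
        break  # first model only
    if not atoms:
        raise DockingError(f"no atoms read from {pdb_path}")
    return Receptor(atoms=atoms, source=str(pdb_path), warnings=warns)


def write_ligand_pdbqt(conf: Conformer, path) -> None:
    """Minimal rigid-ligand PDBQT (zero partial charges, element atom types)."""
    with open(path, "w") as fh:
        fh.write("ROOT\n")
        for i, atom in enumerate(conf.mol.GetAtoms()):
            x, y, z = conf.coords[i]
            sym = atom.GetSymbol()
            fh.write(
                f"ATOM  {i + 1:>5} {sym:<4}LIG A   1    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{0.00:6.2f}{0.00:6.2f}"
                f"    {0.000:6.3f} {sym:<2}\n"
            )
        fh.write("ENDROOT\nTORSDOF 0\n")


@dataclass(frozen=True)
class DockingPose:
    """One engine pose: rank 1 holds the minimum (best) energy."""

    energy: float
    rank: int
    ligand: Chem.Mol = field(repr=False, default=None)
    coords: np.ndarray | None = field(repr=False, default=None)
    provenance: str = ""


def dock(ligand: Chem.Mol, receptor: Receptor, box: GridBox, engine,
         n_poses: int = 20, seed: int = 0) -> list[DockingPose]:
    """Run the docking engine and return energy-sorted poses (stable
    report order on ties).  Warns when the engine returns fewer poses than
    requested; the best energy is ``poses[0].energy``."""
    try:
        report = engine.run(ligand, receptor, box, n_poses, seed)
    except DockingEngineError:
        raise
    except Exception as exc:
        raise DockingEngineError(f"docking engine failed: {exc}") from exc
    energies = parse_engine_report(report)
    if len(energies) > n_poses:
        energies = energies[:n_poses]
    if len(energies) < n_poses:
        warnings.warn(
            f"engine returned {len(energies)} poses, {n_poses} requested"
        )
    order = sorted(range(len(energies)), key=lambda i: energies[i])
    provenance = getattr(engine, "name", type(engine).__name__)
    coords = getattr(engine, "last_pose_coords", None)
    return [
        DockingPose(energy=energies[i], rank=rank + 1, ligand=ligand,
                    coords=coords, provenance=provenance)
        for rank, i in enumerate(order)
    ]


# ---------------------------------------------------------------------------
# Hydrogen-bond analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HBondGeometry:
    """Geometric hydrogen-bond criterion (heavy-atom based)."""

    cutoff: float = 3.5  # donor-acceptor distance, angstroms
    strong_max: float = 2.5
    moderate_max: float = 3.5
    angle_min_deg: float = 120.0  # applied only with an explicit donor H


def classify_hbond(distance: float, geo: HBondGeometry | None = None) -> str:
    geo = geo or HBondGeometry()
    if distance <= geo.strong_max:
        return "strong"
    if distance <= geo.moderate_max:
        return "moderate"
    return "weak"


@dataclass(frozen=True)
class HBondContact:
    """One donor-acceptor contact across the ligand-receptor interface."""

    donor_owner: str  # "ligand" | "receptor"
    donor_label: str  # residue NAME-number or ligand group label
    acceptor_owner: str
    acceptor_label: str
    distance: float
    strength: str  # strong | moderate | weak


def _ligand_polar_atoms(mol: Chem.Mol):
    """(index, is_donor, is_acceptor, label) for every ligand N/O atom."""
    out = []
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in ("N", "O"):
            continue
        n_h = atom.GetTotalNumHs(includeNeighbors=True)
        label = f"{sym}{atom.GetIdx() + 1}"
        if n_h > 0:
            label += "H"
        out.append((atom.GetIdx(), n_h > 0, True, label))
    return out


def detect_hbonds(pose: DockingPose, receptor: Receptor,
                  geo: HBondGeometry | None = None,
                  box: GridBox | None = None) -> list[HBondContact]:
    """All ligand-receptor donor-acceptor pairs satisfying the geometric
    criterion, classed by distance and reported with PDB residue labels
    (e.g. ASN-519).  When an explicit hydrogen sits on a ligand donor the
    donor-H-acceptor angle must also reach the configured minimum.

    A warning is raised when the ligand centroid falls outside the search
    box (a likely coordinate-frame mismatch).
    """
    geo = geo or HBondGeometry()
    if pose.coords is None:
        raise DockingError("pose carries no coordinates")
    mol = pose.ligand
    coords = np.asarray(pose.coords, dtype=float)
    if coords.shape[0] != mol.GetNumAtoms():
        raise DockingError(
            f"coordinate count {coords.shape[0]} != atom count "
            f"{mol.GetNumAtoms()}"
        )
    if box is not None and not box.contains(coords.mean(axis=0), margin=2.0):
        warnings.warn("ligand centroid lies outside the grid box; "
                      "possible coordinate-frame mismatch")
    # explicit hydrogens attached to each heavy atom, for the angle test
    h_neighbors: dict[int, list[int]] = {}
    for atom in mol.GetAtoms():
        if atom.GetSymbol() == "H":
            for nb in atom.GetNeighbors():
                h_neighbors.setdefault(nb.GetIdx(), []).append(atom.GetIdx())

    def angle_ok(donor_idx: int, acceptor_xyz: np.ndarray) -> bool:
        hs = h_neighbors.get(donor_idx)
        if not hs:
            return True  # no explicit H: distance-only criterion
        d = coords[donor_idx]
        for h in hs:
            v1 = d - coords[h]
            v2 = acceptor_xyz - coords[h]
            cosang = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if ang >= geo.angle_min_deg:
                return True
        return False

    contacts: dict[tuple, HBondContact] = {}
    rec_polar = receptor.polar_atoms()
    for lig_idx, lig_don, lig_acc, lig_label in _ligand_polar_atoms(mol):
        lxyz = coords[lig_idx]
        for ra in rec_polar:
            rxyz = np.asarray(ra.coords)
            dist = float(np.linalg.norm(lxyz - rxyz))
            if dist > geo.cutoff or dist <= 0.0:
                continue
            pair_key = (lig_idx, ra.serial)
            if pair_key in contacts:
                continue
            if lig_don and ra.is_acceptor and angle_ok(lig_idx, rxyz):
                contacts[pair_key] = HBondContact(
                    donor_owner="ligand", donor_label=lig_label,
                    acceptor_owner="receptor",
                    acceptor_label=f"{ra.residue_label}:{ra.name}",
                    distance=dist, strength=classify_hbond(dist, geo),
                )
            elif lig_acc and ra.is_donor:
                contacts[pair_key] = HBondContact(
                    donor_owner="receptor",
                    donor_label=f"{ra.residue_label}:{ra.name}",
                    acceptor_owner="ligand", acceptor_label=lig_label,
                    distance=dist, strength=classify_hbond(dist, geo),
                )
    return sorted(contacts.values(), key=lambda c: (c.distance, c.donor_label))
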