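"""Molecular graph core: SMILES round-tripping, valence accounting, 3-D embedding.

Molecules are RDKit graphs kept with implicit hydrogens throughout editing;
hydrogens become explicit only when a 3-D conformer is generated.  Aromatic
rings are perceived on parse and their bonds are treated as frozen order-1.5
bonds by the editing layer, so kekulization never churns during an episode.

Generated molecules are restricted to the neutral valence table C:4, N:3,
O:2 (no formal charges); parsed *input* molecules may contain anything RDKit
sanitizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

RDLogger.DisableLog("rdApp.*")  # errors surface as exceptions, not stderr noise

#: Permitted total valence for elements allowed in generated molecules.
VALENCE_TABLE: dict[str, int] = {"C": 4, "N": 3, "O": 2}

#: Ideal single-bond covalent C-H length in angstroms, used in sanity checks.
CH_BOND_LENGTH = 1.09


class ChemError(ValueError):
    """Base class for molecular-graph errors."""


class SmilesParseError(ChemError):
    """The SMILES text could not be tokenized/parsed."""


class ValenceError(ChemError):
    """The molecular graph violates a permitted valence."""


class EmbeddingError(ChemError):
    """3-D coordinate generation failed for the molecule."""


def parse_smiles(text: str) -> Chem.Mol:
    """Parse ``text`` into a sanitized RDKit molecule.

    Aromaticity is perceived and stereo descriptors present in the input are
    kept.  Raises :class:`SmilesParseError` for unparsable text and
    :class:`ValenceError` for chemically invalid (e.g. hypervalent) input,
    naming the offending atom or token.
    """
    if not text or not text.strip():
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(text, sanitize=False)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {text!r}")
    problems = Chem.DetectChemistryProblems(mol)
    if problems:
        msgs = "; ".join(p.Message() for p in problems)
        if any(p.GetType() == "AtomValenceException" for p in problems):
            raise ValenceError(f"invalid valence in {text!r}: {msgs}")
        raise SmilesParseError(f"cannot sanitize {text!r}: {msgs}")
    Chem.SanitizeMol(mol)
    return mol


def to_canonical_smiles(mol: Chem.Mol) -> str:
    """Canonical (isomeric where stereo is present) SMILES, atom-order invariant."""
    return Chem.MolToSmiles(mol)


def validate_valence(mol: Chem.Mol) -> None:
    """Raise :class:`ValenceError` unless every atom passes RDKit sanitization."""
    problems = Chem.DetectChemistryProblems(mol)
    if problems:
        raise ValenceError("; ".join(p.Message() for p in problems))


def free_valence(mol: Chem.Mol, idx: int, table: dict[str, int] | None = None) -> int:
    """Open bonding capacity of atom ``idx``: permitted valence minus the
    bond-order sum over heavy-atom bonds (aromatic bonds count 1.5).

    Implicit hydrogens occupy no capacity here — they are the placeholders a
    new bond displaces — so a methane carbon reports 4 and an ethanol
    hydroxyl oxygen reports 1.  Away from aromatic rings this equals RDKit's
    hydrogen count; on aromatic atoms it can be stricter (a pyrrole-type NH
    keeps its hydrogen yet has no open slot).  Atoms outside the table fall
    back to the hydrogen count; results clamp at zero.
    """
    if idx < 0 or idx >= mol.GetNumAtoms():
        raise IndexError(f"atom index {idx} out of range for {mol.GetNumAtoms()} atoms")
    atom = mol.GetAtomWithIdx(idx)
    table = table if table is not None else VALENCE_TABLE
    sym = atom.GetSymbol()
    if sym in table and atom.GetFormalCharge() == 0:
        order_sum = sum(b.GetBondTypeAsDouble() for b in atom.GetBonds())
        return max(0, int(round(table[sym] - order_sum)))
    return atom.GetTotalNumHs()


@dataclass(frozen=True)
class Conformer:
    """A single embedded 3-D geometry with explicit hydrogens.

    ``mol`` carries the hydrogen-expanded graph whose conformer 0 holds the
    coordinates; ``coords`` is the (n_atoms, 3) array in angstroms and
    ``seed`` the embedding seed that reproduces it bit-for-bit.
    """

    mol: Chem.Mol = field(repr=False)
    coords: np.ndarray = field(repr=False)
    seed: int = 0

    @property
    def num_atoms(self) -> int:
        return self.mol.GetNumAtoms()

    def write_sdf(self, path: str) -> None:
        with Chem.SDWriter(str(path)) as w:
            w.write(self.mol)


def embed_3d(mol: Chem.Mol, seed: int = 0) -> Conformer:
    """Generate one low-energy 3-D conformer (ETKDG + MMFF94 relaxation).

    Deterministic for a fixed ``seed``.  Raises :class:`EmbeddingError` for
    disconnected input or when distance-geometry embedding fails.
    """
    if len(Chem.GetMolFrags(mol)) != 1:
        raise EmbeddingError(
            f"cannot embed disconnected molecule {to_canonical_smiles(mol)!r}"
        )
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    conf_id = AllChem.EmbedMolecule(molh, params)
    if conf_id < 0:
        raise EmbeddingError(
            f"embedding failed for {to_canonical_smiles(mol)!r} (seed {seed})"
        )
    try:
        AllChem.MMFFOptimizeMolecule(molh, confId=conf_id)
    except Exception:
        pass  # unrelaxed ETKDG geometry is still a valid conformer
    coords = np.asarray(molh.GetConformer(conf_id).GetPositions(), dtype=float)
    return Conformer(mol=molh, coords=coords, seed=int(seed))
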