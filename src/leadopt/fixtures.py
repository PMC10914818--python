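"""Synthetic stand-ins for every external input, so the full pipeline runs
and is tested entirely offline.

Provides: the packaged lead structure (3,6-bis(benzimidazol-1-yl)pyridazine,
the template every episode starts from); a programmatically generated toy
receptor carrying ARG-515, ASN-519 and LYS-520 side chains at known
coordinates (synthetic, built with idealized geometry — not a fragment of
any deposited structure); deterministic mock docking-engine reports in both
Vina-table and AutoDock-DLG dialects; the surrogate affinity oracle wiring;
and a seeded desk-scale smoke configuration.  Nothing here touches the
network, and everything regenerates bit-identically.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from rdkit import Chem

from .agent import AgentConfig
from .chem import parse_smiles
from .docking import DockingPose, GridBox, Receptor, ReceptorAtom, prepare_receptor
from .mdp import MDPConfig
from .rewards import (
    RewardConfig,
    RewardVector,
    SurrogateParams,
    qed_score,
    sa_score,
    surrogate_affinity,
)

#: 3,6-bis(benzimidazol-1-yl)pyridazine - the lead structure (24 heavy atoms,
#: 6 nitrogens: two benzimidazoles N-linked to the 3,6 positions of a
#: pyridazine).
LEAD_SMILES = "c1ccc2c(c1)ncn2-c1ccc(nn1)-n1cnc2ccccc21"

#: The production grid box for the estrogen-receptor target.
DEFAULT_GRID_BOX = GridBox(
    npts=(80, 60, 60), spacing=0.375, center=(23.895, 49.094, 134.275)
)


def lead_structure() -> Chem.Mol:
    """The parsed, validated lead molecule (canonical SMILES is stable)."""
    return parse_smiles(LEAD_SMILES)


def surrogate_reward_fn(params: SurrogateParams | None = None):
    """Callable mol -> RewardVector using the deterministic surrogate
    affinity oracle plus the real QED and SA evaluators."""
    p = params or SurrogateParams()

    def _reward(mol: Chem.Mol) -> RewardVector:
        return RewardVector(
            affinity=surrogate_affinity(mol, p),
            qed=qed_score(mol),
            sa=sa_score(mol),
        )

    return _reward


# ---------------------------------------------------------------------------
# Toy receptor (synthetic): ARG-515, ASN-519, LYS-520 on chain A
# ---------------------------------------------------------------------------

_BACKBONE = [("N", "N", (0.0, 0.0, 0.0)), ("CA", "C", (1.46, 0.0, 0.0)),
             ("C", "C", (2.0, 1.4, 0.0)), ("O", "O", (1.4, 2.45, 0.0))]
_SIDECHAINS = {
    "ARG": [("CB", "C", (2.0, -1.4, 0.0)), ("CG", "C", (3.5, -1.5, 0.0)),
            ("CD", "C", (4.1, -2.9, 0.0)), ("NE", "N", (5.5, -3.0, 0.0)),
            ("CZ", "C", (6.3, -4.1, 0.0)), ("NH1", "N", (5.8, -5.3, 0.0)),
            ("NH2", "N", (7.6, -4.0, 0.0))],
    "ASN": [("CB", "C", (2.0, -1.4, 0.0)), ("CG", "C", (3.5, -1.5, 0.0)),
            ("OD1", "O", (4.15, -1.5, 1.1)), ("ND2", "N", (4.1, -1.6, -1.2))],
    "LYS": [("CB", "C", (2.0, -1.4, 0.0)), ("CG", "C", (3.5, -1.5, 0.0)),
            ("CD", "C", (4.1, -2.9, 0.0)), ("CE", "C", (5.6, -3.0, 0.0)),
            ("NZ", "N", (6.2, -4.3, 0.0))],
}
_TOY_RESIDUES = [("ARG", 515, 0.0), ("ASN", 519, 10.0), ("LYS", 520, 20.0)]


def toy_receptor() -> Receptor:
    """A synthetic tri-residue receptor fragment with idealized side-chain
    geometry, residue numbers 515/519/520 on chain A."""
    atoms: list[ReceptorAtom] = []
    serial = 1
    for resname, resseq, xshift in _TOY_RESIDUES:
        for name, element, (x, y, z) in _BACKBONE + _SIDECHAINS[resname]:
            atoms.append(ReceptorAtom(
                serial=serial, name=name, resname=resname, resseq=resseq,
                chain="A", coords=(x + xshift, y, z), element=element,
            ))
            serial += 1
    return Receptor(atoms=atoms, source="toy_receptor()")


def toy_receptor_pdb(path=None) -> Path:
    """The toy receptor written as a PDB file (round-trips through a strict
    PDB reader with preserved residue numbering)."""
    if path is None:
        path = Path(tempfile.mkstemp(suffix=".pdb")[1])
    toy_receptor().write_pdb(path)
    return Path(path)


def probe_hydroxyl_pose(distance: float = 1.9) -> DockingPose:
    """A methanol probe whose hydroxyl oxygen sits exactly ``distance``
    angstroms from ASN-519's side-chain carbonyl oxygen (OD1), pointing away
    from every other polar receptor atom - by construction it makes exactly
    one hydrogen bond at the default cutoff."""
    od1 = np.asarray(toy_receptor().atom(519, "OD1").coords)
    o_xyz = od1 + np.array([0.0, 0.0, distance])
    c_xyz = o_xyz + np.array([0.0, 0.0, 1.43])
    mol = parse_smiles("CO")
    # parse_smiles("CO") yields atom order [C, O]
    coords = np.stack([c_xyz, o_xyz])
    return DockingPose(energy=0.0, rank=1, ligand=mol, coords=coords,
                       provenance="probe_hydroxyl_pose")


# ---------------------------------------------------------------------------
# Mock docking engine
# ---------------------------------------------------------------------------

def mock_engine_report(n_poses: int, energies, style: str = "vina") -> str:
    """Syntactically valid engine-report text embedding the given pose
    energies (kcal/mol), in either the Vina result-table or the AutoDock
    DLG dialect."""
    energies = list(energies)
    if len(energies) != n_poses:
        raise ValueError(
            f"got {len(energies)} energies for {n_poses} poses"
        )
    if n_poses == 0:
        raise ValueError("a report needs at least one pose")
    if style == "vina":
        lines = [
            "mode |   affinity | dist from best mode",
            "     | (kcal/mol) | rmsd l.b.| rmsd u.b.",
            "-----+------------+----------+----------",
        ]
        for i, e in enumerate(energies, start=1):
            lines.append(f"{i:>4}       {e:>8.3f}      0.000      0.000")
        return "\n".join(lines) + "\n"
    if style == "dlg":
        lines = []
        for i, e in enumerate(energies, start=1):
            lines += [
                f"DOCKED: MODEL        {i}",
                f"DOCKED: USER    Estimated Free Energy of Binding    ="
                f"  {e:+.2f} kcal/mol",
                "DOCKED: ENDMDL",
            ]
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown report style {style!r}")


class MockDockingEngine:
    """Deterministic stand-in engine: pose energies derive from the
    surrogate affinity oracle with a fixed per-pose spread, emitted as real
    report text so the full parse path is exercised."""

    name = "mock"

    def __init__(self, params: SurrogateParams | None = None,
                 style: str = "vina", pose_spread: float = 0.15):
        self.params = params or SurrogateParams()
        self.style = style
        self.pose_spread = pose_spread
        self.last_pose_coords = None

    def run(self, mol, receptor, box: GridBox, n_poses: int, seed: int) -> str:
        best = surrogate_affinity(mol, self.params)
        energies = [best + self.pose_spread * k for k in range(n_poses)]
        return mock_engine_report(n_poses, energies, style=self.style)


class FixedReportEngine:
    """Engine adapter returning one canned report - for replaying a recorded
    docking result through the same parse-and-minimize path."""

    name = "fixed-report"

    def __init__(self, report: str):
        self.report = report
        self.last_pose_coords = None

    def run(self, mol, receptor, box, n_poses, seed) -> str:
        return self.report


# ---------------------------------------------------------------------------
# Seeded desk-scale smoke configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SmokeConfig:
    """Everything a deterministic desk-scale end-to-end run needs."""

    mdp: MDPConfig
    agent: AgentConfig
    reward: RewardConfig
    surrogate: SurrogateParams
    seed: int


def seeded_smoke_config(seed: int = 1) -> SmokeConfig:
    """200 surrogate-reward episodes at step limit 8 with a compact
    Q-network - minutes on one CPU, byte-identical across reruns."""
    return SmokeConfig(
        mdp=MDPConfig(step_limit=8),
        agent=AgentConfig(
            episodes=200,
            epsilon_decrement=Fraction(1, 200),
            replay_capacity=2000,
            batch_size=32,
            target_sync_every=10,
            fingerprint_bits=128,
            hidden_sizes=(32, 32),
            learning_rate=1e-3,
            seed=seed,
        ),
        reward=RewardConfig(),
        surrogate=SurrogateParams(),
        seed=seed,
    )
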