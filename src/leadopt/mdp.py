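"""Molecule-modification Markov decision process.

A state is the current molecule plus a step counter with a hard limit
(default 16 edits).  The four action families are atom addition, bond
addition (new ring bonds and +1 order increments), bond removal (order
decrement or full deletion), and "no modification".  Every candidate is
valence-valid against the neutral C/N/O table, and candidates are
deduplicated by canonical SMILES so symmetric edits collapse to one action.

Aromatic bonds are frozen: never incremented, never removed.  Bond removal
that disconnects the graph keeps the largest fragment.  Triple bonds may
only join C/N pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from rdkit import Chem

from .chem import VALENCE_TABLE, free_valence, parse_smiles, to_canonical_smiles

_BOND_TYPES = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
}


class MDPError(ValueError):
    pass


class IllegalActionError(MDPError):
    """The chosen molecule is not in the legal action set of the state."""


@dataclass(frozen=True)
class MDPConfig:
    """Editing rules for one optimization run.

    ``step_limit`` bounds how far an episode may drift from the lead.
    ``allow_bond_increments`` / ``allow_ring_formation`` split the two
    readings of "bond addition" so either can be switched off.
    """

    step_limit: int = 16
    allowed_elements: tuple[str, ...] = ("C", "N", "O")
    allowed_bond_orders: tuple[int, ...] = (1, 2, 3)
    allow_bond_increments: bool = True
    allow_ring_formation: bool = True

    def __post_init__(self) -> None:
        if self.step_limit < 1:
            raise MDPError(f"step_limit must be >= 1, got {self.step_limit}")
        if not self.allowed_elements:
            raise MDPError("allowed_elements must be non-empty")
        unknown = [e for e in self.allowed_elements if e not in VALENCE_TABLE]
        if unknown:
            raise MDPError(f"elements outside the valence table: {unknown}")
        bad = [b for b in self.allowed_bond_orders if b not in (1, 2, 3)]
        if bad:
            raise MDPError(f"bond orders must be in {{1,2,3}}, got {bad}")


@dataclass(frozen=True)
class MDPState:
    """Current molecule plus step bookkeeping; molecule is always valence-valid."""

    mol: Chem.Mol = field(repr=False)
    steps_taken: int
    step_limit: int

    @property
    def steps_remaining(self) -> int:
        return self.step_limit - self.steps_taken

    @property
    def terminal(self) -> bool:
        return self.steps_taken >= self.step_limit

    @property
    def smiles(self) -> str:
        return to_canonical_smiles(self.mol)


def initial_state(lead: Chem.Mol, cfg: MDPConfig) -> MDPState:
    """Wrap the unmodified lead structure as the episode's first state."""
    smiles = to_canonical_smiles(lead)  # also proves lead is serializable
    mol = parse_smiles(smiles)  # round-trip => sanitized, valence-valid
    return MDPState(mol=mol, steps_taken=0, step_limit=cfg.step_limit)


def _sanitized_copy(rw: Chem.RWMol) -> Chem.Mol | None:
    """Sanitize an edited graph; None when the edit produced invalid chemistry."""
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol | None:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if not frags:
        return None
    # largest by heavy-atom count; ties broken by canonical SMILES so the
    # choice is deterministic under atom reordering
    best = max(
        frags, key=lambda f: (f.GetNumHeavyAtoms(), to_canonical_smiles(f))
    )
    if best.GetNumHeavyAtoms() == 0:
        return None
    return best


def _atom_additions(mol: Chem.Mol, cfg: MDPConfig) -> list[Chem.Mol]:
    out = []
    for idx in range(mol.GetNumAtoms()):
        fv = free_valence(mol, idx)
        if fv <= 0:
            continue
        for elem in cfg.allowed_elements:
            for order in cfg.allowed_bond_orders:
                if order > fv or order > VALENCE_TABLE[elem]:
                    continue
                if order == 3:
                    syms = {elem, mol.GetAtomWithIdx(idx).GetSymbol()}
                    if not syms <= {"C", "N"}:
                        continue
                rw = Chem.RWMol(mol)
                new_idx = rw.AddAtom(Chem.Atom(elem))
                rw.AddBond(idx, new_idx, _BOND_TYPES[order])
                cand = _sanitized_copy(rw)
                if cand is not None:
                    out.append(cand)
    return out


def _bond_additions(mol: Chem.Mol, cfg: MDPConfig) -> list[Chem.Mol]:
    out = []
    n = mol.GetNumAtoms()
    fvs = [free_valence(mol, i) for i in range(n)]
    if cfg.allow_ring_formation:
        for i in range(n):
            for j in range(i + 1, n):
                if mol.GetBondBetweenAtoms(i, j) is not None:
                    continue
                for order in cfg.allowed_bond_orders:
                    if fvs[i] < order or fvs[j] < order:
                        continue
                    if order == 3:
                        syms = {
                            mol.GetAtomWithIdx(i).GetSymbol(),
                            mol.GetAtomWithIdx(j).GetSymbol(),
                        }
                        if not syms <= {"C", "N"}:
                            continue
                    rw = Chem.RWMol(mol)
                    rw.AddBond(i, j, _BOND_TYPES[order])
                    cand = _sanitized_copy(rw)
                    if cand is not None:
                        out.append(cand)
    if cfg.allow_bond_increments:
        for bond in mol.GetBonds():
            if bond.GetIsAromatic():
                continue
            order = int(bond.GetBondTypeAsDouble())
            new_order = order + 1
            if new_order not in cfg.allowed_bond_orders:
                continue
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            if fvs[i] < 1 or fvs[j] < 1:
                continue
            if new_order == 3:
                syms = {
                    mol.GetAtomWithIdx(i).GetSymbol(),
                    mol.GetAtomWithIdx(j).GetSymbol(),
                }
                if not syms <= {"C", "N"}:
                    continue
            rw = Chem.RWMol(mol)
            rw.GetBondBetweenAtoms(i, j).SetBondType(_BOND_TYPES[new_order])
            cand = _sanitized_copy(rw)
            if cand is not None:
                out.append(cand)
    return out


def _bond_removals(mol: Chem.Mol, cfg: MDPConfig) -> list[Chem.Mol]:
    out = []
    for bond in mol.GetBonds():
        if bond.GetIsAromatic():
            continue
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        order = int(bond.GetBondTypeAsDouble())
        # decrement by one, and full deletion as a distinct action
        new_orders = {order - 1, 0}
        for new_order in new_orders:
            rw = Chem.RWMol(mol)
            if new_order == 0:
                rw.RemoveBond(i, j)
            else:
                rw.GetBondBetweenAtoms(i, j).SetBondType(_BOND_TYPES[new_order])
            cand = _sanitized_copy(rw)
            if cand is None:
                continue
            if new_order == 0 and len(Chem.GetMolFrags(cand)) > 1:
                cand = _largest_fragment(cand)
                if cand is None:
                    continue
                try:
                    Chem.SanitizeMol(cand)
                except Exception:
                    continue
            out.append(cand)
    return out


def enumerate_actions(state: MDPState, cfg: MDPConfig) -> list[Chem.Mol]:
    """All legal successor molecules of ``state``, deduplicated by canonical
    SMILES and sorted by it (a deterministic action ordering).

    The unchanged molecule ("no modification") is always a member.  Raises
    :class:`MDPError` on a terminal state.
    """
    if state.terminal:
        raise MDPError("cannot enumerate actions of a terminal state")
    mol = state.mol
    candidates: dict[str, Chem.Mol] = {to_canonical_smiles(mol): mol}
    for cand in (
        _atom_additions(mol, cfg)
        + _bond_additions(mol, cfg)
        + _bond_removals(mol, cfg)
    ):
        candidates.setdefault(to_canonical_smiles(cand), cand)
    return [candidates[s] for s in sorted(candidates)]


def step(state: MDPState, chosen: Chem.Mol, cfg: MDPConfig) -> MDPState:
    """Apply an action, returning the successor state with the counter advanced.

    ``chosen`` must be a member of ``enumerate_actions(state, cfg)`` (by
    canonical-SMILES identity), else :class:`IllegalActionError`.
    """
    legal = {to_canonical_smiles(m) for m in enumerate_actions(state, cfg)}
    smiles = to_canonical_smiles(chosen)
    if smiles not in legal:
        raise IllegalActionError(f"{smiles!r} is not a legal action of this state")
    return MDPState(
        mol=parse_smiles(smiles),
        steps_taken=state.steps_taken + 1,
        step_limit=state.step_limit,
    )


def trajectory_record(step_index: int, state_smiles: str, action_smiles: str) -> str:
    """One JSON-lines trajectory record."""
    return json.dumps(
        {"step": step_index, "state": state_smiles, "action": action_smiles}
    )
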