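"""Molecule-modification MDP: action families, step accounting, and
equivalence with an independent brute-force enumerator."""

import itertools

import pytest
from rdkit import Chem

import leadopt as L
from leadopt.mdp import MDPError

CFG = L.MDPConfig()


def smiles_set(mols):
    return {L.to_canonical_smiles(m) for m in mols}


def state_of(smiles, cfg=CFG):
    return L.initial_state(L.parse_smiles(smiles), cfg)


# ---------------------------------------------------------------------------
# Independent brute-force enumerator (the oracle): plain nested loops over
# RDKit editable molecules, written without reference to the implementation.
# ---------------------------------------------------------------------------

_VAL = {"C": 4, "N": 3, "O": 2}
_BT = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}


def _try(rw):
    m = rw.GetMol()
    try:
        Chem.SanitizeMol(m)
        return Chem.MolToSmiles(m)
    except Exception:
        return None


def brute_force_actions(smiles: str, cfg: L.MDPConfig = CFG) -> set:
    mol = Chem.MolFromSmiles(smiles)
    out = {Chem.MolToSmiles(mol)}  # no-modification
    n = mol.GetNumAtoms()
    fv = [a.GetTotalNumHs() for a in mol.GetAtoms()]
    sym = [a.GetSymbol() for a in mol.GetAtoms()]

    def triple_ok(a_sym, b_sym):
        return a_sym in ("C", "N") and b_sym in ("C", "N")

    # atom additions
    for i, elem, order in itertools.product(
        range(n), cfg.allowed_elements, cfg.allowed_bond_orders
    ):
        if order > fv[i] or order > _VAL[elem]:
            continue
        if order == 3 and not triple_ok(sym[i], elem):
            continue
        rw = Chem.RWMol(mol)
        j = rw.AddAtom(Chem.Atom(elem))
        rw.AddBond(i, j, _BT[order])
        s = _try(rw)
        if s:
            out.add(s)
    # new bonds between unbonded pairs
    for i, j in itertools.combinations(range(n), 2):
        if mol.GetBondBetweenAtoms(i, j) is not None:
            continue
        for order in cfg.allowed_bond_orders:
            if order > min(fv[i], fv[j]):
                continue
            if order == 3 and not triple_ok(sym[i], sym[j]):
                continue
            rw = Chem.RWMol(mol)
            rw.AddBond(i, j, _BT[order])
            s = _try(rw)
            if s:
                out.add(s)
    # +1 increments on existing non-aromatic bonds
    for b in mol.GetBonds():
        if b.GetIsAromatic():
            continue
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        new = int(b.GetBondTypeAsDouble()) + 1
        if new not in cfg.allowed_bond_orders or min(fv[i], fv[j]) < 1:
            continue
        if new == 3 and not triple_ok(sym[i], sym[j]):
            continue
        rw = Chem.RWMol(mol)
        rw.GetBondBetweenAtoms(i, j).SetBondType(_BT[new])
        s = _try(rw)
        if s:
            out.add(s)
    # decrements and deletions
    for b in mol.GetBonds():
        if b.GetIsAromatic():
            continue
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        for new in {int(b.GetBondTypeAsDouble()) - 1, 0}:
            rw = Chem.RWMol(mol)
            if new == 0:
                rw.RemoveBond(i, j)
            else:
                rw.GetBondBetweenAtoms(i, j).SetBondType(_BT[new])
            m2 = rw.GetMol()
            try:
                Chem.SanitizeMol(m2)
            except Exception:
                continue
            frags = Chem.GetMolFrags(m2, asMols=True)
            if len(frags) > 1:  # keep the largest fragment
                m2 = max(
                    frags,
                    key=lambda f: (f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)),
                )
            out.add(Chem.MolToSmiles(m2))
    return out


def oracle_reachable(max_atoms: int) -> set:
    """Closure of the action space over C/N/O seeds, capped by atom count,
    generated entirely by the brute-force oracle."""
    frontier = {"C", "N", "O"}
    seen = set(frontier)
    while frontier:
        nxt = set()
        for s in frontier:
            for s2 in brute_force_actions(s):
                m = Chem.MolFromSmiles(s2)
                if m.GetNumHeavyAtoms() <= max_atoms and s2 not in seen:
                    seen.add(s2)
                    nxt.add(s2)
        frontier = nxt
    return seen


# ---------------------------------------------------------------------------


class TestInitialState:
    def test_lead_default_limit(self, lead):
        st = L.initial_state(lead, L.MDPConfig())
        assert st.steps_remaining == 16 and st.steps_taken == 0
        assert st.smiles == L.to_canonical_smiles(lead)

    def test_single_edit_episode(self, lead):
        assert L.initial_state(lead, L.MDPConfig(step_limit=1)).steps_remaining == 1

    def test_zero_limit_rejected(self):
        with pytest.raises(MDPError):
            L.MDPConfig(step_limit=0)


class TestEnumerateActions:
    def test_methane_candidates(self):
        # 3 C-additions + 3 N-additions + 2 O-additions + no-modification
        got = smiles_set(L.enumerate_actions(state_of("C"), CFG))
        assert got == {"C", "CC", "C=C", "C#C", "CN", "C=N", "C#N", "CO", "C=O"}

    def test_ethane_single_bond_increment(self):
        got = smiles_set(L.enumerate_actions(state_of("CC"), CFG))
        assert "C=C" in got and "C#C" not in got  # increments are +1 only

    @pytest.mark.parametrize("smiles", ["C", "CCO", "c1ccccc1", "C1CC1N"])
    def test_no_modification_always_legal(self, smiles):
        st = state_of(smiles)
        assert st.smiles in smiles_set(L.enumerate_actions(st, CFG))

    def test_terminal_state_rejected(self, lead):
        st = L.MDPState(mol=lead, steps_taken=2, step_limit=2)
        with pytest.raises(MDPError):
            L.enumerate_actions(st, CFG)

    def test_aromatic_bonds_frozen(self):
        # no candidate of benzene loses or changes the order of a ring
        # bond (edits only add atoms or bridge existing atoms, which keep
        # the original indices 0..5)
        for m in L.enumerate_actions(state_of("c1ccccc1"), CFG):
            for i in range(6):
                b = m.GetBondBetweenAtoms(i, (i + 1) % 6)
                assert b is not None
                assert b.GetBondTypeAsDouble() == 1.5

    def test_disconnecting_removal_keeps_largest_fragment(self):
        got = smiles_set(L.enumerate_actions(state_of("CCO"), CFG))
        assert "CO" in got  # C-C deletion keeps the larger CO fragment
        assert not any("." in s for s in got)

    def test_candidates_valence_valid_and_unique(self, lead):
        cands = L.enumerate_actions(
            L.initial_state(lead, L.MDPConfig(step_limit=8)),
            L.MDPConfig(step_limit=8),
        )
        keys = [L.to_canonical_smiles(m) for m in cands]
        assert len(keys) == len(set(keys))
        for m in cands:
            L.validate_valence(m)


class TestStep:
    def test_counter_advances_and_terminates(self):
        cfg = L.MDPConfig(step_limit=2)
        st = state_of("C", cfg)
        st = L.step(st, L.enumerate_actions(st, cfg)[0], cfg)
        assert st.steps_taken == 1 and not st.terminal
        st = L.step(st, L.enumerate_actions(st, cfg)[0], cfg)
        assert st.terminal

    def test_no_modification_still_counts(self):
        st = state_of("CCO")
        nxt = L.step(st, st.mol, CFG)
        assert nxt.smiles == st.smiles and nxt.steps_taken == 1

    def test_illegal_action_rejected(self):
        with pytest.raises(L.IllegalActionError):
            L.step(state_of("C"), L.parse_smiles("c1ccccc1"), CFG)


class TestOracleEquivalence:
    def test_matches_brute_force_on_small_molecules(self):
        # quick closure (the exhaustive <= 5-atom sweep runs with the
        # end-to-end checks) plus hand-picked tricky probes: rings,
        # aromatics, cumulated/triple bonds, branched heteroatoms
        probes = sorted(oracle_reachable(max_atoms=3)) + [
            "C1CC1", "C1=CC1N", "c1ccccc1", "c1ccncc1", "N#CC(=O)O",
            "C=C=O", "OC1CN1", "CC(C)(C)O",
        ]
        for s in probes:
            got = smiles_set(L.enumerate_actions(state_of(s), CFG))
            assert got == brute_force_actions(s), f"mismatch at {s}"

    def test_drift_bounded_by_step_limit(self, smoke, smoke_records):
        # replaying any trajectory: per-step heavy-atom change is at most 1,
        # so the final molecule differs from the lead by <= step_limit edits
        lead_n = L.lead_structure().GetNumHeavyAtoms()
        for rec in smoke_records[:20]:
            assert len(rec.trajectory) == smoke.mdp.step_limit
            n = L.parse_smiles(rec.smiles).GetNumHeavyAtoms()
            assert abs(n - lead_n) <= smoke.mdp.step_limit
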