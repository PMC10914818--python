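"""The three reward evaluators: drug-likeness (QED), synthetic accessibility
(SA, rescaled to [0,1] with 1 = easiest), and binding affinity in kcal/mol.

Affinity comes either from an external docking engine behind an adapter
(QuickVina-2-style result tables and AutoDock DLG pose blocks are both
parsed) or from a deterministic additive surrogate oracle suited to desk-
scale runs and testing.  QED and SA are pure functions of the molecular
graph.
"""

from __future__ import annotations

import os
import re
import sys
from dataclasses import dataclass, field

from rdkit import Chem, RDConfig
from rdkit.Chem import Lipinski, QED

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit contrib module, importable only after the path hook)

from .chem import to_canonical_smiles, validate_valence

SA_RAW_MIN, SA_RAW_MAX = 1.0, 10.0


class RewardError(RuntimeError):
    pass


class DockingEngineError(RewardError):
    """The external docking engine failed or produced unparsable output."""


@dataclass(frozen=True)
class RewardVector:
    """Per-molecule reward triple.

    affinity: predicted binding free energy, kcal/mol (more negative is
    stronger); qed, sa: dimensionless scores in [0, 1].
    """

    affinity: float
    qed: float
    sa: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.qed <= 1.0):
            raise ValueError(f"qed out of [0,1]: {self.qed}")
        if not (0.0 <= self.sa <= 1.0):
            raise ValueError(f"sa out of [0,1]: {self.sa}")
        if not (self.affinity == self.affinity and abs(self.affinity) < float("inf")):
            raise ValueError(f"affinity not finite: {self.affinity}")


def qed_score(mol: Chem.Mol) -> float:
    """Quantitative estimate of drug-likeness: geometric mean of the eight
    desirability functions (MW, ALOGP, HBA, HBD, PSA, rotatable bonds,
    aromatic rings, structural alerts).  Strictly inside (0, 1)."""
    validate_valence(mol)
    try:
        return float(QED.qed(mol))
    except Exception as exc:  # pragma: no cover - descriptor failures are exotic
        raise RewardError(f"QED descriptor failure: {exc}") from exc


def sa_raw(mol: Chem.Mol) -> float:
    """Fragment-contribution synthetic-accessibility score on the native
    1 (easy) .. 10 (hard) scale."""
    validate_valence(mol)
    return float(sascorer.calculateScore(mol))


def sa_score(mol: Chem.Mol) -> float:
    """Normalized SA in [0,1] with 1 = easiest: (10 - raw) / 9.

    The normalization is a package choice: the native fragment score runs
    1-10 with 1 easiest, while screening expects "easy" near 1.
    """
    return rescale_sa(sa_raw(mol))


def rescale_sa(raw: float) -> float:
    """Monotone-decreasing linear map of the 1-10 raw scale onto [0,1]."""
    raw = min(max(raw, SA_RAW_MIN), SA_RAW_MAX)
    return (SA_RAW_MAX - raw) / (SA_RAW_MAX - SA_RAW_MIN)


# ---------------------------------------------------------------------------
# Docking-engine report parsing (adapter side)
# ---------------------------------------------------------------------------

_VINA_ROW = re.compile(r"^\s*(\d+)\s+(-?\d+(?:\.\d+)?)\s+\S+\s+\S+\s*$")
_DLG_ENERGY = re.compile(
    r"Estimated Free Energy of Binding\s*=\s*(-?\d+(?:\.\d+)?)\s*kcal/mol"
)


def parse_vina_report(text: str) -> list[float]:
    """Pose energies (kcal/mol) from a Vina-style result table, report order."""
    energies = []
    for line in text.splitlines():
        m = _VINA_ROW.match(line)
        if m:
            energies.append(float(m.group(2)))
    if not energies:
        raise DockingEngineError("no pose rows found in Vina-style report")
    return energies


def parse_dlg_report(text: str) -> list[float]:
    """Pose energies from AutoDock DLG 'DOCKED' blocks, report order."""
    energies = [
        float(m.group(1))
        for line in text.splitlines()
        if line.startswith("DOCKED:")
        for m in _DLG_ENERGY.finditer(line)
    ]
    if not energies:
        raise DockingEngineError("no DOCKED energy lines found in DLG report")
    return energies


def parse_engine_report(text: str) -> list[float]:
    """Dispatch on report dialect (DLG blocks vs Vina table)."""
    if "DOCKED:" in text:
        return parse_dlg_report(text)
    return parse_vina_report(text)


class DockingAffinityOracle:
    """Best-pose affinity through a docking engine, cached by canonical SMILES.

    ``engine`` is any object with ``run(mol, receptor, box, n_poses, seed)
    -> report text`` (see :mod:`leadopt.docking` for the adapter and
    :mod:`leadopt.fixtures` for the deterministic mock engine).
    """

    def __init__(self, engine, receptor, box, n_poses: int = 20, seed: int = 0):
        self.engine = engine
        self.receptor = receptor
        self.box = box
        self.n_poses = n_poses
        self.seed = seed
        self._cache: dict[str, float] = {}

    def __call__(self, mol: Chem.Mol) -> float:
        key = to_canonical_smiles(mol)
        if key in self._cache:
            return self._cache[key]
        try:
            report = self.engine.run(
                mol, self.receptor, self.box, self.n_poses, self.seed
            )
        except DockingEngineError:
            raise
        except Exception as exc:
            raise DockingEngineError(f"engine failure for {key!r}: {exc}") from exc
        energy = min(parse_engine_report(report))
        self._cache[key] = energy
        return energy


# ---------------------------------------------------------------------------
# Deterministic surrogate affinity oracle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurrogateParams:
    """Parameters of the additive surrogate affinity oracle (kcal/mol).

    Each heavy atom contributes by element; every hydrogen-bond donor and
    acceptor earns ``hbond_bonus`` (negative = favorable); heavy atoms
    beyond ``size_pivot`` pay ``size_penalty`` each.  Scores are clipped to
    [clip_low, clip_high].  Defaults put the 24-atom lead structure at
    -8.1 kcal/mol, near the modal affinity of a full optimization run.
    """

    element_contrib: dict[str, float] = field(
        default_factory=lambda: {"C": -0.15, "N": -0.35, "O": -0.40}
    )
    hbond_bonus: float = -0.55
    size_pivot: int = 26
    size_penalty: float = 0.35
    clip_low: float = -14.0
    clip_high: float = 0.0

    def __post_init__(self) -> None:
        if self.hbond_bonus >= 0:
            raise ValueError("hbond_bonus must be negative")
        if self.size_penalty < 0:
            raise ValueError("size_penalty must be >= 0")


def surrogate_affinity(mol: Chem.Mol, params: SurrogateParams | None = None) -> float:
    """Deterministic affinity stand-in: sum of per-element contributions,
    H-bond-group bonuses, and a size penalty, clipped to the params' range."""
    p = params or SurrogateParams()
    score = 0.0
    for atom in mol.GetAtoms():
        score += p.element_contrib.get(atom.GetSymbol(), 0.0)
    n_hb = Lipinski.NumHDonors(mol) + Lipinski.NumHAcceptors(mol)
    score += p.hbond_bonus * n_hb
    extra = mol.GetNumHeavyAtoms() - p.size_pivot
    if extra > 0:
        score += p.size_penalty * extra
    return min(max(score, p.clip_low), p.clip_high)


# ---------------------------------------------------------------------------
# Scalarization for Q-learning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RewardConfig:
    """Weights of the scalarized multi-objective reward.

    The scalar is w_aff * (-affinity/10) + w_qed * qed + w_sa * sa, which
    puts the affinity term on roughly the same [0, 1.4] footing as the two
    unit-interval scores.  All three components are always logged separately.
    """

    w_affinity: float = 1.0
    w_qed: float = 1.0
    w_sa: float = 1.0

    def scalarize(self, rv: RewardVector) -> float:
        return (
            self.w_affinity * (-rv.affinity / 10.0)
            + self.w_qed * rv.qed
            + self.w_sa * rv.sa
        )


def evaluate_rewards(mol: Chem.Mol, affinity_oracle, cfg: RewardConfig | None = None):
    """Full reward triple plus scalar for one molecule.

    ``affinity_oracle`` is any callable mol -> kcal/mol (surrogate or
    docking).  Returns (RewardVector, scalar).
    """
    cfg = cfg or RewardConfig()
    rv = RewardVector(
        affinity=float(affinity_oracle(mol)),
        qed=qed_score(mol),
        sa=sa_score(mol),
    )
    return rv, cfg.scalarize(rv)
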