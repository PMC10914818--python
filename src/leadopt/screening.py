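"""Post-run analytics over an episode log: the three-threshold candidate
filter, fraction-better statistics, reward-density estimates, and trend
tests against episode index."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .agent import EpisodeRecord


class ScreeningError(ValueError):
    pass


@dataclass(frozen=True)
class ScreeningThresholds:
    """Candidate-selection thresholds.

    Defaults are the production screen: SA >= 0.6, QED >= 0.7 and affinity
    <= -10.0 kcal/mol, all inclusive (a candidate sitting exactly on a
    threshold passes).
    """

    sa_min: float = 0.6
    qed_min: float = 0.7
    affinity_max: float = -10.0
    inclusive: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.sa_min <= 1.0 and 0.0 <= self.qed_min <= 1.0):
            raise ScreeningError("sa_min and qed_min must lie in [0,1]")

    def passes(self, affinity: float, qed: float, sa: float) -> bool:
        if self.inclusive:
            return sa >= self.sa_min and qed >= self.qed_min \
                and affinity <= self.affinity_max
        return sa > self.sa_min and qed > self.qed_min \
            and affinity < self.affinity_max


def filter_candidates(log: list[EpisodeRecord],
                      thresholds: ScreeningThresholds | None = None,
                      ) -> list[EpisodeRecord]:
    """Episodes meeting all three thresholds, deduplicated by canonical
    SMILES (keeping the occurrence with the best scalar reward), in stable
    episode-index order.  Malformed/failed records are skipped with a
    warning; an empty passing set is a valid result."""
    t = thresholds or ScreeningThresholds()
    best: dict[str, EpisodeRecord] = {}
    order: list[str] = []
    for rec in log:
        if rec.failed or rec.reward is None or not math.isfinite(rec.scalar_reward):
            warnings.warn(f"skipping malformed episode record {rec.episode}")
            continue
        rv = rec.reward
        if not t.passes(rv.affinity, rv.qed, rv.sa):
            continue
        prev = best.get(rec.smiles)
        if prev is None:
            best[rec.smiles] = rec
            order.append(rec.smiles)
        elif rec.scalar_reward > prev.scalar_reward:
            best[rec.smiles] = rec  # keep original position in `order`
    return [best[s] for s in order]


def fraction_beyond(values, threshold: float, direction: str = "<=",
                    inclusive: bool = True) -> float:
    """Proportion of ``values`` on the better side of ``threshold``.

    ``direction`` is "<=" (smaller is better, e.g. affinity) or ">="
    (larger is better, e.g. QED/SA); strict variants apply when
    ``inclusive`` is False.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ScreeningError("fraction_beyond needs a non-empty value list")
    if direction in ("<=", "<"):
        hits = vals <= threshold if inclusive else vals < threshold
    elif direction in (">=", ">"):
        hits = vals >= threshold if inclusive else vals > threshold
    else:
        raise ScreeningError(f"unknown direction {direction!r}")
    return float(hits.sum() / vals.size)


@dataclass(frozen=True)
class DensityEstimate:
    """A normalized density curve on an explicit grid plus its mode(s)."""

    grid: np.ndarray
    density: np.ndarray
    modes: tuple[float, ...]
    degenerate: bool = False

    def integral(self) -> float:
        if self.degenerate:
            return 1.0
        return float(np.trapezoid(self.density, self.grid))


def reward_density(values, grid_size: int = 512,
                   bandwidth: str | float = "silverman") -> DensityEstimate:
    """Gaussian-kernel density of a score column (Silverman bandwidth by
    default), renormalized on its grid to integrate to 1 within 1e-6.

    All-equal input degenerates to a reported single point mass instead of
    crashing.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 10:
        raise ScreeningError(f"need >= 10 values for a density, got {vals.size}")
    if np.ptp(vals) == 0.0:
        point = float(vals[0])
        return DensityEstimate(grid=np.array([point]), density=np.array([1.0]),
                               modes=(point,), degenerate=True)
    kde = stats.gaussian_kde(vals, bw_method=bandwidth)
    bw = np.sqrt(float(kde.covariance[0, 0]))
    lo, hi = vals.min() - 3 * bw, vals.max() + 3 * bw
    grid = np.linspace(lo, hi, grid_size)
    dens = kde(grid)
    dens = dens / np.trapezoid(dens, grid)
    peak = dens.max()
    modes = tuple(float(g) for g, d in zip(grid, dens) if d == peak)
    return DensityEstimate(grid=grid, density=dens, modes=modes)


@dataclass(frozen=True)
class TrendResult:
    rho: float
    p_value: float
    n: int
    field: str
    defined: bool = True


def trend_statistic(log: list[EpisodeRecord], field: str) -> TrendResult:
    """Spearman rank correlation of a reward field ("affinity", "qed", "sa"
    or "scalar_reward") against episode index, with a two-sided p-value.
    A constant field yields an explicitly flagged undefined correlation."""
    ok = [r for r in log if not r.failed and r.reward is not None]
    if len(ok) < 10:
        raise ScreeningError("need >= 10 valid records for a trend statistic")
    idx = np.array([r.episode for r in ok], dtype=float)
    if field == "scalar_reward":
        y = np.array([r.scalar_reward for r in ok])
    else:
        y = np.array([getattr(r.reward, field) for r in ok])
    if np.ptp(y) == 0.0:
        return TrendResult(rho=float("nan"), p_value=float("nan"), n=len(ok),
                           field=field, defined=False)
    rho, p = stats.spearmanr(idx, y)
    return TrendResult(rho=float(rho), p_value=float(p), n=len(ok), field=field)


def screening_report(log: list[EpisodeRecord],
                     thresholds: ScreeningThresholds | None = None) -> dict:
    """Summary dictionary: passing candidates, the three fraction-better
    statistics (both inclusive and strict), and per-field trends."""
    t = thresholds or ScreeningThresholds()
    ok = [r for r in log if not r.failed and r.reward is not None]
    aff = [r.reward.affinity for r in ok]
    qed = [r.reward.qed for r in ok]
    sa = [r.reward.sa for r in ok]
    passing = filter_candidates(log, t)
    report = {
        "n_episodes": len(log),
        "n_valid": len(ok),
        "thresholds": {"sa_min": t.sa_min, "qed_min": t.qed_min,
                       "affinity_max": t.affinity_max,
                       "inclusive": t.inclusive},
        "fraction_better": {
            "sa": fraction_beyond(sa, t.sa_min, ">="),
            "qed": fraction_beyond(qed, t.qed_min, ">="),
            "affinity": fraction_beyond(aff, t.affinity_max, "<="),
        },
        "fraction_better_strict": {
            "sa": fraction_beyond(sa, t.sa_min, ">=", inclusive=False),
            "qed": fraction_beyond(qed, t.qed_min, ">=", inclusive=False),
            "affinity": fraction_beyond(aff, t.affinity_max, "<=",
                                        inclusive=False),
        },
        "n_passing": len(passing),
        "passing": [
            {"episode": r.episode, "smiles": r.smiles,
             "affinity_kcal_mol": r.reward.affinity, "qed": r.reward.qed,
             "sa": r.reward.sa, "scalar_reward": r.scalar_reward}
            for r in passing
        ],
        "trend": {
            f: vars(trend_statistic(log, f))
            for f in ("affinity", "qed", "sa", "scalar_reward")
        },
    }
    return report


def passing_to_dataframe(report: dict) -> pd.DataFrame:
    return pd.DataFrame(
        report["passing"],
        columns=["episode", "smiles", "affinity_kcal_mol", "qed", "sa",
                 "scalar_reward"],
    )
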