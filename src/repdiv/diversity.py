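"""Per-repertoire diversity and clonality statistics.

All indices operate on the clonotype UMI-count vector; Shannon uses natural
logarithms so that ``exp(shannon) == hill(q=1)`` holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from repdiv.errors import DomainError, UndefinedStatisticError
from repdiv.io_clonotypes import Repertoire

__all__ = [
    "DiversityProfile",
    "chao1",
    "cumulative_clonotype_curve",
    "d50",
    "diversity_profile",
    "hill_curve",
    "hill_number",
    "rank_abundance",
    "richness",
    "shannon",
    "simpson",
    "top100",
]

DEFAULT_Q_GRID = np.arange(0.0, 8.25, 0.25)


def _counts(rep) -> np.ndarray:
    c = rep.counts if isinstance(rep, Repertoire) else np.asarray(rep, dtype=np.int64)
    if c.size == 0:
        raise UndefinedStatisticError("statistic undefined for an empty repertoire")
    if np.any(c < 1):
        raise ValueError("counts must be positive")
    return c


def richness(rep) -> int:
    """Number of unique clonotypes."""
    return int(_counts(rep).size)


def shannon(rep) -> float:
    """Shannon–Wiener index H = −Σ p_i ln p_i (nats)."""
    p = _counts(rep)
    p = p / p.sum()
    return float(-np.sum(p * np.log(p)))


def simpson(rep) -> tuple[float, float]:
    """Simpson dominance D = Σ p_i² and diversity 1 − D.

    Returns ``(dominance, diversity)``; reports must state which form is
    plotted, as the two directions are easily confused.
    """
    p = _counts(rep)
    p = p / p.sum()
    dom = float(np.sum(p * p))
    return dom, 1.0 - dom


def d50(rep) -> float:
    """Percent of top-ranked unique clonotypes accounting for 50% of UMIs.

    Clonotypes are ranked by descending count; ``k`` is the smallest number
    of top clonotypes with cumulative frequency >= 0.5 and D50 = 100·k/S.
    """
    c = np.sort(_counts(rep))[::-1]
    cum = np.cumsum(c) / c.sum()
    k = int(np.searchsorted(cum, 0.5, side="left") + 1)
    return 100.0 * k / c.size


def chao1(rep, bias_corrected: bool = False) -> float:
    """Chao1 richness estimator from singleton/doubleton UMI counts.

    Classic form ``S + f1²/(2·f2)`` when f2 > 0; the bias-corrected form
    ``S + f1(f1−1)/(2(f2+1))`` is used when f2 == 0 or on request.
    """
    c = _counts(rep)
    s_obs = c.size
    f1 = int(np.sum(c == 1))
    f2 = int(np.sum(c == 2))
    if bias_corrected or f2 == 0:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    return s_obs + f1 * f1 / (2.0 * f2)


def top100(rep) -> float:
    """Percent of all UMIs carried by the 100 most abundant clonotypes."""
    c = np.sort(_counts(rep))[::-1]
    if c.size <= 100:
        return 100.0
    return float(100.0 * c[:100].sum() / c.sum())


def hill_number(rep, q: float) -> float:
    """Hill number (true diversity) of order q.

    ``(Σ p_i^q)^(1/(1−q))`` for q ≠ 1; the q→1 limit is exp(Shannon);
    q = 0 gives richness.
    """
    if q < 0:
        raise DomainError(f"Hill order q must be nonnegative, got {q}")
    c = _counts(rep)
    p = c / c.sum()
    if q == 0:
        return float(p.size)
    if abs(q - 1.0) < 1e-12:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def hill_curve(rep, q_grid=None) -> list[tuple[float, float]]:
    """Hill-number profile over a grid of orders (default 0..8 step 0.25)."""
    grid = DEFAULT_Q_GRID if q_grid is None else np.asarray(q_grid, dtype=float)
    c = _counts(rep)
    return [(float(q), hill_number(c, float(q))) for q in grid]


def rank_abundance(rep) -> list[tuple[int, float]]:
    """Clonotype frequencies sorted descending; ranks are 1-based."""
    c = np.sort(_counts(rep))[::-1]
    f = c / c.sum()
    return [(i + 1, float(fi)) for i, fi in enumerate(f)]


def cumulative_clonotype_curve(rep) -> list[tuple[float, float]]:
    """Cumulative UMI frequency versus fraction of unique clonotypes.

    Clonotypes are sorted by descending count; the curve is non-decreasing
    and ends at (1, 1).
    """
    c = np.sort(_counts(rep))[::-1]
    cum = np.cumsum(c) / c.sum()
    n = c.size
    return [((i + 1) / n, float(cum[i])) for i in range(n)]


@dataclass
class DiversityProfile:
    """Per-sample bundle of the standard indices."""

    richness: int
    shannon: float
    simpson_dominance: float
    simpson_diversity: float
    d50: float
    chao1: float
    top100: float
    hill: list[tuple[float, float]]


def diversity_profile(rep, q_grid=None) -> DiversityProfile:
    c = _counts(rep)
    dom, div = simpson(c)
    return DiversityProfile(
        richness=richness(c),
        shannon=shannon(c),
        simpson_dominance=dom,
        simpson_diversity=div,
        d50=d50(c),
        chao1=chao1(c),
        top100=top100(c),
        hill=hill_curve(c, q_grid),
    )


# Registry of scalar indices addressable by name (rarefaction, CLI).
INDEX_FUNCTIONS = {
    "richness": richness,
    "shannon": shannon,
    "simpson_dominance": lambda rep: simpson(rep)[0],
    "simpson_diversity": lambda rep: simpson(rep)[1],
    "d50": d50,
    "chao1": chao1,
    "top100": top100,
}
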