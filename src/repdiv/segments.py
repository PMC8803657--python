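"""V/D/J gene usage frequencies and combination matrices.

Weighting ``total`` divides summed UMI counts by the total count;
``unique`` divides clonotype counts by richness.  Missing D calls are
pooled into an explicit ``unassigned`` bin so tables always sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from repdiv.errors import ConfigurationError, UndefinedStatisticError
from repdiv.io_clonotypes import Repertoire

__all__ = ["UsageTable", "combination_matrix", "compare_usage", "usage"]

UNASSIGNED = "unassigned"

_AXIS_FIELDS = {
    "V": ("v_gene",),
    "D": ("d_gene",),
    "J": ("j_gene",),
    "VJ": ("v_gene", "j_gene"),
    "VDJ": ("v_gene", "d_gene", "j_gene"),
}


@dataclass
class UsageTable:
    axis: str
    weighting: str
    entries: dict
    n: float  # weight base (total UMIs or richness), used by count-based tests

    def as_series(self) -> pd.Series:
        return pd.Series(self.entries, dtype=float).sort_index()


def _gene_of(ct, field: str) -> str:
    g = getattr(ct, field)
    return g if g else UNASSIGNED


def usage(rep: Repertoire, axis: str = "V", weighting: str = "total") -> UsageTable:
    """Per-gene (or gene-tuple) frequency table."""
    if axis not in _AXIS_FIELDS:
        raise ConfigurationError(f"unknown axis {axis!r}; valid: {sorted(_AXIS_FIELDS)}")
    if weighting not in ("total", "unique"):
        raise ConfigurationError(f"unknown weighting {weighting!r}")
    if rep.richness == 0:
        raise UndefinedStatisticError("usage undefined for an empty repertoire")
    fields = _AXIS_FIELDS[axis]
    acc: dict = {}
    for ct in rep:
        key = tuple(_gene_of(ct, f) for f in fields)
        if len(fields) == 1:
            key = key[0]
        w = ct.count if weighting == "total" else 1
        acc[key] = acc.get(key, 0) + w
    total = sum(acc.values())
    return UsageTable(
        axis=axis,
        weighting=weighting,
        entries={k: v / total for k, v in acc.items()},
        n=total,
    )


def combination_matrix(rep: Repertoire, axis: str = "VJ", weighting: str = "total") -> UsageTable:
    """Joint V–J or V–D–J frequency table; marginals match the 1-D usages."""
    if axis not in ("VJ", "VDJ"):
        raise ConfigurationError(f"combination axis must be VJ or VDJ, got {axis!r}")
    return usage(rep, axis=axis, weighting=weighting)


def marginalize(table: UsageTable, positions: tuple[int, ...]) -> dict:
    """Sum a tuple-keyed table over all but the given tuple positions."""
    out: dict = {}
    for key, v in table.entries.items():
        sub = tuple(key[p] for p in positions)
        if len(sub) == 1:
            sub = sub[0]
        out[sub] = out.get(sub, 0.0) + v
    return out


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    return stats.false_discovery_control(p, method="bh")


def _adjust(p: np.ndarray, correction: str) -> np.ndarray:
    if correction == "bh":
        return _bh_adjust(p)
    if correction == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if correction == "none":
        return p.copy()
    raise ConfigurationError(f"unknown correction {correction!r}")


def compare_usage(
    group_a: list[UsageTable],
    group_b: list[UsageTable],
    method: str = "t_test",
    correction: str = "bh",
) -> pd.DataFrame:
    """Per-gene two-group comparison of usage frequencies.

    ``t_test`` / ``wilcoxon`` compare per-sample frequencies across samples
    (genes absent from a sample enter as 0); ``chi2`` pools counts per group
    and tests each gene's 2x2 contingency table.  Genes absent from both
    groups are not emitted.  Degenerate variance yields a flagged p = 1 row
    rather than a crash.
    """
    if method in ("t_test", "wilcoxon") and (len(group_a) < 2 or len(group_b) < 2):
        raise ConfigurationError(f"{method} requires >= 2 samples per group")
    genes = sorted(
        {g for t in group_a for g in t.entries} | {g for t in group_b for g in t.entries},
        key=str,
    )
    rows = []
    for gene in genes:
        fa = np.array([t.entries.get(gene, 0.0) for t in group_a])
        fb = np.array([t.entries.get(gene, 0.0) for t in group_b])
        degenerate = False
        if method == "t_test":
            if np.ptp(fa) == 0 and np.ptp(fb) == 0:
                stat, degenerate = 0.0, True
                p = 1.0 if fa[0] == fb[0] else 0.0
            else:
                res = stats.ttest_ind(fa, fb)
                stat, p = float(res.statistic), float(res.pvalue)
        elif method == "wilcoxon":
            res = stats.ranksums(fa, fb)
            stat, p = float(res.statistic), float(res.pvalue)
            if np.all(fa == fa[0]) and np.all(fb == fa[0]):
                degenerate = True
        elif method == "chi2":
            ka = sum(t.entries.get(gene, 0.0) * t.n for t in group_a)
            kb = sum(t.entries.get(gene, 0.0) * t.n for t in group_b)
            na = sum(t.n for t in group_a)
            nb = sum(t.n for t in group_b)
            table = np.array([[ka, na - ka], [kb, nb - kb]])
            if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
                stat, p, degenerate = 0.0, 1.0, True
            else:
                res = stats.chi2_contingency(table)
                stat, p = float(res.statistic), float(res.pvalue)
        else:
            raise ConfigurationError(f"unknown method {method!r}")
        rows.append(
            {"gene": gene, "statistic": stat, "p": p, "degenerate": degenerate}
        )
    df = pd.DataFrame(rows)
    df["p_adjusted"] = _adjust(df["p"].to_numpy(), correction)
    return df[["gene", "statistic", "p", "p_adjusted", "degenerate"]]
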