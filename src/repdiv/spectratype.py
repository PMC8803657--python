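"""CDR3 length distributions (spectratype) and their summary statistics."""

from __future__ import annotations

import math

import pandas as pd

from repdiv.errors import DomainError, UndefinedStatisticError
from repdiv.io_clonotypes import Repertoire

__all__ = ["complexity_score", "length_distribution", "length_skewness"]


def length_distribution(
    rep: Repertoire, weighting: str = "total", unit: str = "nt"
) -> dict[int, float]:
    """Frequency per CDR3 length; exact bins, no smoothing.

    Lengths are nucleotides by default; ``unit='aa'`` uses amino-acid
    lengths of productive clonotypes.
    """
    if rep.richness == 0:
        raise UndefinedStatisticError("length distribution undefined for empty repertoire")
    acc: dict[int, float] = {}
    for ct in rep:
        if unit == "nt":
            length = len(ct.cdr3_nt)
        elif unit == "aa":
            if not ct.productive:
                continue
            length = len(ct.cdr3_aa)
        else:
            raise ValueError(f"unknown unit {unit!r}")
        w = ct.count if weighting == "total" else 1
        acc[length] = acc.get(length, 0) + w
    total = sum(acc.values())
    return {length: w / total for length, w in sorted(acc.items())}


def complexity_score(hist: dict[int, float], threshold: float = 0.01) -> int:
    """Number of length bins at or above a frequency threshold.

    Operationalizes the spectratyping peak count; the threshold is part of
    the reported parameterization.
    """
    if not 0 < threshold < 1:
        raise DomainError(f"threshold must lie in (0, 1), got {threshold}")
    total = sum(hist.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"histogram is not normalized (sum {total:.6g})")
    return sum(1 for f in hist.values() if f >= threshold)


def length_skewness(
    rep_or_hist, weighting: str = "total", unit: str = "nt"
) -> tuple[float, bool]:
    """Third standardized moment of the length distribution.

    Accepts a Repertoire or a pre-computed histogram.  Returns
    ``(skewness, degenerate)`` — degenerate (skewness 0 by convention) when
    fewer than 2 distinct lengths are present.
    """
    if isinstance(rep_or_hist, Repertoire):
        hist = length_distribution(rep_or_hist, weighting=weighting, unit=unit)
    else:
        hist = dict(rep_or_hist)
    if len(hist) < 2:
        return 0.0, True
    mu = sum(length * f for length, f in hist.items())
    var = sum(f * (length - mu) ** 2 for length, f in hist.items())
    if var <= 0:
        return 0.0, True
    sigma = math.sqrt(var)
    skew = sum(f * ((length - mu) / sigma) ** 3 for length, f in hist.items())
    return skew, False


def spectratype_table(rep: Repertoire, threshold: float = 0.01) -> pd.DataFrame:
    """Tidy summary: complexity and skewness for both weightings."""
    rows = []
    for weighting in ("total", "unique"):
        hist = length_distribution(rep, weighting=weighting)
        skew, degenerate = length_skewness(hist)
        rows.append(
            {
                "sample_id": rep.sample_id,
                "weighting": weighting,
                "complexity": complexity_score(hist, threshold),
                "skewness": skew,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)
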