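"""CDR3 amino-acid composition and self-reactivity indices.

Positional indices are 1-based from the conserved cysteine that opens the
CDR3 (IMGT junction convention); the hydrophobic index looks at the residue
doublet at positions 6–7 of a fixed CDR3 length class (default 13), and the
cysteine index looks for non-anchor cysteines within a window of the CDR3
apex.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from repdiv.errors import DomainError, UndefinedStatisticError
from repdiv.io_clonotypes import AA_ALPHABET, Repertoire

__all__ = [
    "DEFAULT_HYDROPHOBIC_RESIDUES",
    "aa_composition",
    "bhattacharyya_distance",
    "cysteine_index",
    "default_doublet_set",
    "hydrophobic_index",
    "positional_composition",
]

# Strongly hydrophobic residues (Kyte–Doolittle positive or aromatic).
DEFAULT_HYDROPHOBIC_RESIDUES = frozenset("ACFILMVWY")


def default_doublet_set() -> frozenset[tuple[str, str]]:
    """All doublets with both residues in the strongly hydrophobic class."""
    return frozenset(
        (a, b) for a in DEFAULT_HYDROPHOBIC_RESIDUES for b in DEFAULT_HYDROPHOBIC_RESIDUES
    )


def _productive(rep: Repertoire):
    cts = [ct for ct in rep if ct.productive]
    if not cts:
        raise UndefinedStatisticError(
            f"no productive clonotypes in sample {rep.sample_id!r}"
        )
    return cts


def aa_composition(rep: Repertoire, weighting: str = "total") -> pd.Series:
    """Pooled residue frequencies over all productive CDR3aa.

    Count-weighted for ``total``, one vote per clonotype for ``unique``.
    Returns a 20-vector indexed by the amino-acid alphabet, summing to 1.
    """
    counts = dict.fromkeys(AA_ALPHABET, 0.0)
    for ct in _productive(rep):
        w = ct.count if weighting == "total" else 1
        for aa in ct.cdr3_aa:
            counts[aa] = counts.get(aa, 0.0) + w
    vec = pd.Series(counts, dtype=float).reindex(list(AA_ALPHABET)).fillna(0.0)
    return vec / vec.sum()


def bhattacharyya_distance(p, q) -> float:
    """BD = −ln Σ √(p·q); 0 iff p == q, +inf for disjoint supports."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("composition vectors must have equal length")
    for name, v in (("p", p), ("q", q)):
        if abs(v.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} is not normalized (sum {v.sum():.6g})")
    bc = float(np.sum(np.sqrt(p * q)))
    if bc <= 0.0:
        return math.inf
    return max(0.0, -math.log(min(bc, 1.0)))


def hydrophobic_index(
    rep: Repertoire,
    length_class: int = 13,
    doublet_set=None,
    weighting: str = "total",
) -> float:
    """Fraction of length-class CDR3s with a hydrophobic doublet at 6–7."""
    if doublet_set is None:
        doublet_set = default_doublet_set()
    num = den = 0.0
    for ct in _productive(rep):
        if len(ct.cdr3_aa) != length_class:
            continue
        w = ct.count if weighting == "total" else 1
        den += w
        if (ct.cdr3_aa[5], ct.cdr3_aa[6]) in doublet_set:
            num += w
    if den == 0:
        raise UndefinedStatisticError(
            f"no productive clonotype of length {length_class} in {rep.sample_id!r}"
        )
    return num / den


def _anchor_position(length: int, anchor: str) -> int:
    """1-based anchor position for the cysteine window."""
    if anchor == "midpoint":
        return (length + 1) // 2
    if anchor == "start":
        return 1
    if anchor == "end":
        return length
    raise ValueError(f"unknown anchor {anchor!r}")


def cysteine_index(
    rep: Repertoire,
    window: int = 2,
    anchor: str = "midpoint",
    weighting: str = "total",
) -> float:
    """Fraction of CDR3s with a non-anchor cysteine near the CDR3 apex.

    A sequence scores if it has 'C' within ±``window`` positions of the
    anchor (default: midpoint), excluding the invariant position-1 cysteine.
    """
    num = den = 0.0
    for ct in _productive(rep):
        aa = ct.cdr3_aa
        w = ct.count if weighting == "total" else 1
        den += w
        mid = _anchor_position(len(aa), anchor)
        lo = max(2, mid - window)  # position 1 is the conserved C
        hi = min(len(aa), mid + window)
        if "C" in aa[lo - 1 : hi]:
            num += w
    return num / den


def positional_composition(
    rep: Repertoire, length_class: int = 13, position: int = 6, weighting: str = "total"
) -> pd.Series:
    """Residue frequencies at a 1-based position among length-class CDR3s."""
    if position > length_class or position < 1:
        raise DomainError(
            f"position {position} outside CDR3 length class {length_class}"
        )
    counts = dict.fromkeys(AA_ALPHABET, 0.0)
    seen = 0.0
    for ct in _productive(rep):
        if len(ct.cdr3_aa) != length_class:
            continue
        w = ct.count if weighting == "total" else 1
        counts[ct.cdr3_aa[position - 1]] = counts.get(ct.cdr3_aa[position - 1], 0.0) + w
        seen += w
    if seen == 0:
        raise UndefinedStatisticError(
            f"no productive clonotype of length {length_class} in {rep.sample_id!r}"
        )
    vec = pd.Series(counts, dtype=float).reindex(list(AA_ALPHABET)).fillna(0.0)
    return vec / vec.sum()
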