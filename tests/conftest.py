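"""Shared fixtures: programmatic repertoire builders (no stored fixtures)."""

from __future__ import annotations

import numpy as np
import pytest

from repdiv.io_clonotypes import Clonotype, Repertoire, translate_nt

# Four synonymous alanine codons: base-4 digits encode distinct junctions
# that all translate cleanly (no stops).
_SAFE_CODONS = ("GCA", "GCC", "GCG", "GCT")


def nt_for_index(i: int, width: int = 6) -> str:
    """Deterministic productive junction for integer i: C + Ala^width + F."""
    digits = []
    for _ in range(width):
        digits.append(i % 4)
        i //= 4
    body = "".join(_SAFE_CODONS[d] for d in digits)
    return "TGT" + body + "TTT"


def make_clonotype(i: int, count: int = 1, v: str = "TRBV1", j: str = "TRBJ1-1",
                   d: str = "", width: int = 6) -> Clonotype:
    nt = nt_for_index(i, width)
    return Clonotype(
        cdr3_nt=nt, cdr3_aa=translate_nt(nt), v_gene=v, j_gene=j, d_gene=d,
        count=count, productive=True,
    )


def rep_from_counts(counts, sample_id: str = "s", group: str = "other") -> Repertoire:
    """Repertoire with the given count vector and distinct junctions."""
    cts = [make_clonotype(i, count=int(c)) for i, c in enumerate(counts)]
    return Repertoire.from_clonotypes(sample_id, cts, group=group)


def random_counts(rng: np.random.Generator, max_clones: int = 30,
                  max_count: int = 50) -> list[int]:
    n = int(rng.integers(1, max_clones + 1))
    return [int(c) for c in rng.integers(1, max_count + 1, size=n)]


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def uniform4():
    return rep_from_counts([1, 1, 1, 1])


@pytest.fixture
def skewed():
    return rep_from_counts([2, 1, 1])
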