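"""Depth normalization by random UMI subsampling.

Sampling is without replacement from the multiset of UMIs (multivariate
hypergeometric), not multinomial: the depths are physical molecule counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from repdiv.errors import ConfigurationError, DepthError
from repdiv.diversity import INDEX_FUNCTIONS
from repdiv.io_clonotypes import Clonotype, Repertoire

__all__ = ["DEFAULT_DEPTHS", "RarefactionPlan", "rarefy_index", "subsample"]

DEFAULT_DEPTHS = (4000, 6000, 8000, 10000, 12000)


@dataclass
class RarefactionPlan:
    depths: tuple[int, ...] = DEFAULT_DEPTHS
    replicates: int = 10
    seed: int = 0

    def __post_init__(self):
        self.depths = tuple(sorted(int(d) for d in self.depths))
        if any(d < 1 for d in self.depths):
            raise ValueError("all depths must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def subsample(rep: Repertoire, depth: int, seed) -> Repertoire:
    """Draw exactly ``depth`` UMIs without replacement from a repertoire.

    Deterministic given ``seed`` (an int or ``numpy.random.Generator``);
    clonotypes whose subsampled count is 0 are removed.
    """
    total = rep.total_count
    if depth > total:
        raise DepthError(
            f"depth {depth} exceeds total UMI count {total} of sample {rep.sample_id!r}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    members = list(rep.clonotypes.values())
    counts = np.array([ct.count for ct in members], dtype=np.int64)
    new_counts = rng.multivariate_hypergeometric(counts, depth)
    kept = [
        Clonotype(
            cdr3_nt=ct.cdr3_nt,
            cdr3_aa=ct.cdr3_aa,
            v_gene=ct.v_gene,
            j_gene=ct.j_gene,
            d_gene=ct.d_gene,
            count=int(c),
            productive=ct.productive,
        )
        for ct, c in zip(members, new_counts)
        if c > 0
    ]
    return Repertoire.from_clonotypes(
        rep.sample_id, kept, group=rep.group, subset=rep.subset
    )


def rarefy_index(rep: Repertoire, plan: RarefactionPlan, index_fn) -> pd.DataFrame:
    """Evaluate a named (or callable) index on rarefied replicates.

    Returns a tidy frame with one row per (depth, replicate); depths deeper
    than the sample are skipped with a warning.  Reproducible under a fixed
    plan seed.
    """
    if isinstance(index_fn, str):
        if index_fn not in INDEX_FUNCTIONS:
            raise ConfigurationError(
                f"unknown index {index_fn!r}; valid names: "
                + ", ".join(sorted(INDEX_FUNCTIONS))
            )
        name, fn = index_fn, INDEX_FUNCTIONS[index_fn]
    else:
        name, fn = getattr(index_fn, "__name__", "index"), index_fn

    total = rep.total_count
    rows = []
    ss = np.random.SeedSequence(plan.seed)
    children = ss.spawn(len(plan.depths) * plan.replicates)
    i = 0
    for depth in plan.depths:
        if depth > total:
            warnings.warn(
                f"sample {rep.sample_id!r} has {total} UMIs; skipping depth {depth}",
                stacklevel=2,
            )
            i += plan.replicates
            continue
        for r in range(plan.replicates):
            sub = subsample(rep, depth, np.random.default_rng(children[i]))
            rows.append(
                {
                    "sample_id": rep.sample_id,
                    "depth": depth,
                    "replicate": r,
                    "index": name,
                    "value": float(fn(sub)),
                }
            )
            i += 1
    return pd.DataFrame(rows, columns=["sample_id", "depth", "replicate", "index", "value"])
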