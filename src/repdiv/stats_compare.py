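"""Cohort-level machinery: feature assembly, PCA segregation, group tests."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from repdiv import diversity
from repdiv.errors import ConfigurationError
from repdiv.io_clonotypes import Repertoire
from repdiv.segments import usage

__all__ = [
    "DEFAULT_FEATURES",
    "FeatureMatrix",
    "assemble_features",
    "dunnett_tests",
    "group_test",
    "pca_segregation",
]

DEFAULT_FEATURES = ("shannon", "simpson", "total_sequences", "unique_sequences")

_SCALAR_FEATURES = {
    "shannon": diversity.shannon,
    "simpson": lambda rep: diversity.simpson(rep)[1],  # diversity form 1-D
    "simpson_dominance": lambda rep: diversity.simpson(rep)[0],
    "total_sequences": lambda rep: float(rep.total_count),
    "unique_sequences": lambda rep: float(rep.richness),
    "d50": diversity.d50,
    "chao1": diversity.chao1,
    "top100": diversity.top100,
}


@dataclass
class FeatureMatrix:
    data: pd.DataFrame  # rows: sample ids, columns: features
    scaling: str = "none"
    groups: dict[str, str] | None = None

    def zscored(self) -> "FeatureMatrix":
        x = self.data
        sd = x.std(axis=0, ddof=0)
        keep = sd > 0
        if not keep.all():
            warnings.warn(
                f"dropping zero-variance features: {list(x.columns[~keep])}",
                stacklevel=2,
            )
        x = x.loc[:, keep]
        z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
        return FeatureMatrix(data=z, scaling="zscore", groups=self.groups)


def assemble_features(
    reps: list[Repertoire],
    features=DEFAULT_FEATURES,
    usage_axis: str | None = None,
    log10_counts: bool = False,
) -> FeatureMatrix:
    """Build the sample x feature matrix.

    ``features`` names scalar indices; alternatively ``usage_axis`` (V, VJ,
    VDJ) switches to usage-based columns, one per gene (tuple) observed in
    any sample.  ``log10_counts`` log-transforms the two sequence-count
    features.
    """
    if len(reps) < 3:
        raise ConfigurationError("feature assembly requires >= 3 samples")
    ids = [r.sample_id for r in reps]
    if usage_axis is not None:
        tables = [usage(r, axis=usage_axis, weighting="total") for r in reps]
        genes = sorted({g for t in tables for g in t.entries}, key=str)
        data = pd.DataFrame(
            [[t.entries.get(g, 0.0) for g in genes] for t in tables],
            index=ids,
            columns=[g if isinstance(g, str) else "|".join(g) for g in genes],
        )
    else:
        for f in features:
            if f not in _SCALAR_FEATURES:
                raise ConfigurationError(
                    f"unknown feature {f!r}; valid: {sorted(_SCALAR_FEATURES)}"
                )
        data = pd.DataFrame(
            {f: [_SCALAR_FEATURES[f](r) for r in reps] for f in features}, index=ids
        )
        if log10_counts:
            for col in ("total_sequences", "unique_sequences"):
                if col in data:
                    data[col] = np.log10(data[col])
    groups = {r.sample_id: r.group for r in reps}
    return FeatureMatrix(data=data, scaling="none", groups=groups)


def pca_segregation(fm: FeatureMatrix, n_components: int = 2):
    """PCA on the (z-scored) feature matrix with a fixed sign convention.

    Each loading vector's largest-magnitude entry is forced positive so
    repeated runs are bit-comparable.  Returns ``(scores, loadings,
    explained_variance_ratio)``; components are truncated with a warning if
    the matrix rank is lower than requested.
    """
    z = fm.zscored() if fm.scaling != "zscore" else fm
    x = z.data.to_numpy(dtype=float)
    n, p = x.shape
    max_rank = min(n - 1, p)
    if n_components > max_rank:
        raise ConfigurationError(
            f"n_components {n_components} exceeds min(n_samples-1, n_features) = {max_rank}"
        )
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    k = min(n_components, rank)
    if k < n_components:
        warnings.warn(f"rank-deficient matrix: returning {k} components", stacklevel=2)
    for j in range(k):
        pivot = np.argmax(np.abs(vt[j]))
        if vt[j, pivot] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    scores = pd.DataFrame(
        u[:, :k] * s[:k],
        index=z.data.index,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    loadings = pd.DataFrame(
        vt[:k], index=[f"PC{i + 1}" for i in range(k)], columns=z.data.columns
    )
    evr = (s**2 / np.sum(s**2))[:k]
    return scores, loadings, evr


@dataclass
class TestResult:
    statistic: float
    p: float
    p_adjusted: float
    method: str
    degenerate: bool = False


def group_test(
    values_a, values_b, method: str = "t_test", n_family: int = 1
) -> TestResult:
    """Two-sided two-group test; Bonferroni-style family adjustment.

    ``n_family`` is the size of the declared test family for the adjusted
    p-value (1 = no adjustment).  Identical constant groups give a flagged
    p = 1 rather than a NaN.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigurationError("group_test requires >= 2 values per group")
    if np.all(a == a[0]) and np.all(b == a[0]):
        return TestResult(0.0, 1.0, 1.0, method, degenerate=True)
    if method == "t_test":
        res = stats.ttest_ind(a, b)
    elif method == "wilcoxon":
        res = stats.ranksums(a, b)
    else:
        raise ConfigurationError(f"unknown method {method!r}")
    p = float(res.pvalue)
    return TestResult(float(res.statistic), p, min(1.0, p * n_family), method)


def dunnett_tests(control, *treatments) -> list[TestResult]:
    """Many-to-one comparisons against a control (Dunnett's procedure)."""
    res = stats.dunnett(*[np.asarray(t, dtype=float) for t in treatments],
                        control=np.asarray(control, dtype=float))
    return [
        TestResult(float(s), float(p), float(p), "dunnett")
        for s, p in zip(np.atleast_1d(res.statistic), np.atleast_1d(res.pvalue))
    ]
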