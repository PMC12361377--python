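"""Richness, rarefaction and community-comparison statistics.

Covers the in-house diversity computations of the pipeline: the Chao1
nonparametric richness estimator (on genus or KO count vectors), rarefaction
curves with percentile confidence bands from repeated subsampling without
replacement, Bray-Curtis dissimilarity, and a distance-based PERMANOVA with
a label-permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _scipy_braycurtis

__all__ = ["chao1", "rarefaction", "RarefactionCurve", "bray_curtis",
           "permanova", "PermanovaResult"]


def _counts(vector) -> np.ndarray:
    x = np.asarray(pd.Series(vector).to_numpy(), dtype=float)
    if x.size == 0:
        raise ValueError("empty abundance vector")
    if np.any(x < 0) or not np.allclose(x, np.round(x)):
        raise ValueError("abundances must be non-negative integers")
    return x.astype(np.int64)


def chao1(vector) -> float:
    """Chao1 richness estimate from a category count vector.

    Classic form S_obs + F1^2 / (2 F2) when doubletons exist; the
    bias-corrected form S_obs + F1 (F1 - 1) / (2 (F2 + 1)) when F2 = 0.
    F1 and F2 are the singleton and doubleton category counts.  Always
    >= S_obs.
    """
    x = _counts(vector)
    s_obs = int(np.sum(x > 0))
    if s_obs == 0:
        raise ValueError("no observed categories")
    f1 = int(np.sum(x == 1))
    f2 = int(np.sum(x == 2))
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0  # = F1(F1-1)/(2(F2+1)) at F2=0


@dataclass(frozen=True)
class RarefactionCurve:
    """Mean rarefied richness with a 95% percentile band per depth."""

    depths: tuple[int, ...]
    mean: tuple[float, ...]
    lower: tuple[float, ...]
    upper: tuple[float, ...]
    randomizations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"depth": self.depths, "mean_richness": self.mean,
             "ci_lower": self.lower, "ci_upper": self.upper}
        )


def rarefaction(
    vector,
    depths: Sequence[int],
    randomizations: int = 100,
    seed: int | np.random.Generator = 0,
) -> RarefactionCurve:
    """Rarefy a count vector by subsampling without replacement.

    At each depth, ``randomizations`` seeded subsamples are drawn and the
    number of distinct categories counted; the band is the 2.5th-97.5th
    percentile.
    """
    x = _counts(vector)
    total = int(x.sum())
    if total == 0:
        raise ValueError("total count must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = np.repeat(np.arange(x.size), x)
    means, los, his = [], [], []
    for depth in depths:
        if depth > total:
            raise ValueError(f"depth {depth} exceeds total count {total}")
        if depth < 1:
            raise ValueError("depths must be >= 1")
        rich = np.empty(randomizations)
        for r in range(randomizations):
            take = rng.choice(labels, size=depth, replace=False)
            rich[r] = np.unique(take).size
        means.append(float(rich.mean()))
        los.append(float(np.percentile(rich, 2.5)))
        his.append(float(np.percentile(rich, 97.5)))
    return RarefactionCurve(tuple(int(d) for d in depths), tuple(means),
                            tuple(los), tuple(his), randomizations)


def bray_curtis(v1, v2) -> float:
    """Bray-Curtis dissimilarity of two abundance vectors.

    Vectors are union-aligned on their category index when given as pandas
    Series; BC = 1 - 2 sum_i min(a_i, b_i) / sum_i (a_i + b_i), in [0, 1].
    """
    s1, s2 = pd.Series(v1), pd.Series(v2)
    if isinstance(v1, (pd.Series, dict)) or isinstance(v2, (pd.Series, dict)):
        idx = s1.index.union(s2.index)
        s1 = s1.reindex(idx, fill_value=0)
        s2 = s2.reindex(idx, fill_value=0)
    a = s1.to_numpy(dtype=float)
    b = s2.to_numpy(dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must align")
    if a.sum() + b.sum() == 0:
        raise ValueError("both vectors are all-zero")
    return float(_scipy_braycurtis(a, b))


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_samples: int
    n_groups: int
    permutations: int


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if idx.size < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    if df_within <= 0 or ss_within <= 0:
        return np.inf if ss_among > 0 else 0.0
    return (ss_among / df_among) / (ss_within / df_within)


def permanova(
    distances: np.ndarray | pd.DataFrame,
    labels: Sequence,
    permutations: int = 10000,
    seed: int | np.random.Generator = 0,
) -> PermanovaResult:
    """Distance-based PERMANOVA.

    ``distances`` is a square symmetric dissimilarity matrix; ``labels``
    assigns each sample to a group.  The pseudo-F statistic compares
    among-group to within-group sums of squared distances; the p-value is
    (1 + #{F_perm >= F_obs}) / (permutations + 1) over uniform label
    permutations.  Groups of size 1 are permitted but contribute no
    within-group term.
    """
    d = np.asarray(pd.DataFrame(distances).to_numpy(), dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    labels = np.asarray(list(labels))
    if labels.size != d.shape[0]:
        raise ValueError("labels must match the matrix dimension")
    uniq, codes = np.unique(labels, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("at least two groups are required")
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    d2 = d ** 2
    f_obs = _pseudo_f(d2, codes, uniq.size)
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(codes)
        if _pseudo_f(d2, perm, uniq.size) >= f_obs:
            count += 1
    p = (1.0 + count) / (permutations + 1.0)
    return PermanovaResult(float(f_obs), float(p), int(labels.size),
                           int(uniq.size), int(permutations))
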