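"""Distance-based community comparison: Bray-Curtis, PERMANOVA, correlation.

The distance matrix produced here is the input to an external nMDS
ordination; the ordination itself is out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy import stats as sps

from .table import SVTable


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative sample-by-sample distance matrix, zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if len(self.labels) and np.nanmax(np.abs(np.diag(v))) > 0:
            raise ValueError("distance matrix diagonal must be zero")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def bray_curtis(table: SVTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between every pair of samples.

    d(i, j) = 1 - 2 * sum_k min(x_ki, x_kj) / (sum_k x_ki + sum_k x_kj),
    bounded in [0, 1] for nonnegative counts. A pair of all-zero samples has
    no defined dissimilarity; it is reported as NaN with a warning.
    """
    x = table.counts.to_numpy(dtype=float).T  # samples x SVs
    totals = x.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = squareform(pdist(x, metric="braycurtis"))
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        warnings.warn(
            f"samples with zero totals: {[table.sample_ids[i] for i in zero]}; "
            "pairwise distances between them are undefined (NaN)",
            stacklevel=2,
        )
        # all-zero vs non-empty sample: no shared taxa -> distance 1
        for i in zero:
            d[i, :] = np.where(totals > 0, 1.0, np.nan)
            d[:, i] = d[i, :]
        d[np.diag_indices_from(d)] = 0.0
    return DistanceMatrix(list(table.sample_ids), d)


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int, sizes: np.ndarray) -> float:
    """Anderson's PERMANOVA pseudo-F from squared distances and group codes."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        m = codes == g
        ss_within += d2[np.ix_(m, m)].sum() / (2.0 * sizes[g])
    ss_among = ss_total - ss_within
    if ss_within <= 0.0:
        return np.inf if ss_among > 0 else 0.0
    return (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))


def permanova(
    dm: DistanceMatrix,
    grouping: list[str] | np.ndarray | pd.Series,
    n_perm: int = 9999,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Permutational multivariate ANOVA on a distance matrix.

    Returns the observed pseudo-F and the permutation p-value
    ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)`` (add-one convention, so p
    is never exactly zero). Label permutations are uniform given ``seed``.
    """
    grouping = np.asarray(grouping)
    if len(grouping) != len(dm.labels):
        raise ValueError("grouping length does not match distance matrix")
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    uniq, codes = np.unique(grouping, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    sizes = np.bincount(codes)
    d2 = dm.values ** 2
    if np.isnan(d2).any():
        raise ValueError("distance matrix contains undefined (NaN) entries")
    f_obs = _pseudo_f(d2, codes, len(uniq), sizes)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(codes))
        if _pseudo_f(d2, codes[perm], len(uniq), sizes) >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(f_obs), float(p)


def correlate_reads_abundance(
    reads: np.ndarray | pd.Series,
    chla: np.ndarray | pd.Series,
) -> tuple[float, float]:
    """Pearson correlation between per-sample read totals and chl-a.

    Returns (r, two-sided p from the t distribution). Zero variance in
    either variable makes the correlation undefined: (nan, nan) with a
    warning.
    """
    x = np.asarray(reads, dtype=float)
    y = np.asarray(chla, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("reads and chla must be paired 1-D arrays")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("reads and chla must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance: correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
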