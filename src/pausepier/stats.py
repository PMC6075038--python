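"""Reusable statistics: robust Z-scores, 2x2 chi-square, two-sample KS,
K-means with a stable labeling convention, and allele read fractions."""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import scipy.stats
from sklearn.cluster import KMeans

#: consistency constant making MAD estimate sigma for normal data
MAD_SCALE = 1.4826


class RobustZResult(NamedTuple):
    z: np.ndarray
    degenerate: bool


def robust_zscore(values: Sequence[float]) -> RobustZResult:
    """Robust Z-scores: (x - median) / (1.4826 * MAD).

    If the MAD is 0 (more than half the values tied at the median), the
    sample standard deviation is used instead; if that is also 0 the vector
    is constant and an all-zero result is returned with ``degenerate=True``.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("robust_zscore: empty input")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad > 0:
        scale = MAD_SCALE * mad
    else:
        sd = x.std(ddof=1) if x.size > 1 else 0.0
        if sd > 0:
            scale = sd
        else:
            return RobustZResult(np.zeros_like(x), True)
    return RobustZResult((x - med) / scale, False)


class Chi2Result(NamedTuple):
    statistic: float
    pvalue: float


def pearson_chi2_2x2(a: int, b: int, c: int, d: int) -> Chi2Result:
    """Pearson chi-square on a 2x2 table, no continuity correction.

    chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); p from the df=1
    chi-square survival function.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be non-negative")
    n = a + b + c + d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if any(m == 0 for m in margins):
        raise ValueError("chi-square undefined: zero marginal total")
    stat = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    return Chi2Result(float(stat), float(scipy.stats.chi2.sf(stat, df=1)))


class KsResult(NamedTuple):
    statistic: float
    pvalue: float


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> KsResult:
    """Two-sided two-sample Kolmogorov-Smirnov test, asymptotic p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("ks_two_sample: empty sample")
    with np.errstate(divide="ignore"):
        # singleton samples hit a benign divide-by-zero in the asymptotic
        # null distribution; the returned p is still well-defined
        res = scipy.stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return KsResult(float(res.statistic), float(min(res.pvalue, 1.0)))


@dataclass
class KmeansResult:
    labels: np.ndarray
    centroids: np.ndarray
    inertia: float
    seed: int


def kmeans_fit(
    records: np.ndarray, k: int, seed: int, restarts: int = 10
) -> KmeansResult:
    """K-means (k-means++ init, best of ``restarts`` runs), deterministic
    given ``seed``.

    Cluster indices are relabeled by descending cluster size, ties broken by
    ascending first centroid coordinate, so labels are stable across runs.
    """
    X = np.asarray(records, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if k < 1 or n < k:
        raise ValueError(f"need n >= k >= 1, got n={n}, k={k}")
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        # duplicate-only input legitimately yields fewer distinct clusters
        warnings.simplefilter("ignore", ConvergenceWarning)
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(X)
    sizes = np.bincount(km.labels_, minlength=k)
    order = sorted(range(k), key=lambda j: (-sizes[j], km.cluster_centers_[j, 0]))
    remap = np.empty(k, dtype=int)
    for new, old in enumerate(order):
        remap[old] = new
    return KmeansResult(
        labels=remap[km.labels_],
        centroids=km.cluster_centers_[order],
        inertia=float(km.inertia_),
        seed=seed,
    )


def allele_read_fraction(mut_region_reads: int, total_region_reads: int) -> float:
    """Fraction of reads over a locus carrying the mutant-allele sequence."""
    if total_region_reads <= 0:
        raise ValueError("total_region_reads must be positive")
    if mut_region_reads < 0 or mut_region_reads > total_region_reads:
        raise ValueError("need 0 <= mut_region_reads <= total_region_reads")
    return mut_region_reads / total_region_reads
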