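"""Chemical-space projection, outlier designation, and diverse splitting.

Compounds are projected into a principal-component chemical space, flagged
as outliers by simple structural thresholds (rotatable-bond and oxygen
counts, optionally a Mahalanobis distance rule in PC space), and the
remainder partitioned into training and test sets at a ~4:1 ratio with a
greedy farthest-point (max-min) test-set selection so both sets span the
descriptor space.  A Kolmogorov-Smirnov report quantifies how similar the
two sets are property by property.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from .core_io import CompoundRecord, DescriptorTable

__all__ = [
    "DataSplit",
    "pca_project",
    "flag_outliers",
    "mahalanobis_outliers",
    "diverse_split",
    "distribution_report",
    "round_half_away",
]


@dataclass
class DataSplit:
    """Disjoint train/test/outlier id sets and the requested train ratio."""

    train_ids: list[str]
    test_ids: list[str]
    outlier_ids: list[str]
    ratio: float

    def __post_init__(self) -> None:
        tr, te, ou = map(set, (self.train_ids, self.test_ids, self.outlier_ids))
        if tr & te or tr & ou or te & ou:
            raise ValueError("train/test/outlier sets must be disjoint")


def round_half_away(x: float) -> int:
    """Round half away from zero (91 * 0.8 = 72.8 -> 73)."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def pca_project(table: DescriptorTable, n_components: int = 3
                ) -> tuple[np.ndarray, np.ndarray]:
    """Project onto the top principal axes of the column-centered matrix.

    Returns the n x k score matrix and the k explained-variance fractions
    (non-increasing, summing to at most 1).
    """
    n, p = table.shape
    if n_components > p:
        raise ValueError(
            f"n_components={n_components} exceeds descriptor count {p}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(table.values)
    return scores, pca.explained_variance_ratio_


def flag_outliers(
    records: Sequence[CompoundRecord],
    nrot_threshold: int = 8,
    n_oxygen_threshold: int = 11,
    *,
    nrot_name: str = "N_rot",
    n_oxygen_name: str = "N_O",
) -> set[str]:
    """Flag compounds with many rotatable bonds or many oxygens.

    A compound is an outlier iff N_rot >= ``nrot_threshold`` or
    N_O >= ``n_oxygen_threshold``.
    """
    flagged = set()
    for rec in records:
        for needed in (nrot_name, n_oxygen_name):
            if needed not in rec.descriptors:
                raise KeyError(
                    f"record {rec.id!r} lacks required descriptor {needed!r}")
        if (rec.descriptors[nrot_name] >= nrot_threshold
                or rec.descriptors[n_oxygen_name] >= n_oxygen_threshold):
            flagged.add(rec.id)
    return flagged


def mahalanobis_outliers(scores: np.ndarray, ids: Sequence[str],
                         quantile: float = 0.975) -> set[str]:
    """Score-distance outlier rule: Mahalanobis distance in PC space above
    the chi-squared quantile for the score dimensionality."""
    X = np.asarray(scores, dtype=float)
    mu = X.mean(axis=0)
    cov = np.cov(X, rowvar=False)
    inv = np.linalg.pinv(np.atleast_2d(cov))
    d2 = np.einsum("ij,jk,ik->i", X - mu, inv, X - mu)
    cut = stats.chi2.ppf(quantile, df=X.shape[1])
    return {ids[i] for i in np.nonzero(d2 > cut)[0]}


def diverse_split(scores: np.ndarray, ids: Sequence[str],
                  train_fraction: float = 0.8, seed: int = 0,
                  outlier_ids: Sequence[str] = ()) -> DataSplit:
    """Partition ids into train/test with a diversity-preserving test set.

    The training size is round-half-away(``train_fraction`` * n).  Test
    compounds are picked by greedy max-min (farthest-point) selection in
    score space: a seeded random start, then repeatedly the candidate
    farthest from the already-chosen test compounds.  Outliers must already
    be excluded from ``ids``; they are carried through in the split record.
    """
    X = np.asarray(scores, dtype=float)
    ids = list(ids)
    n = len(ids)
    if X.shape[0] != n:
        raise ValueError("scores and ids length mismatch")
    if n < 5:
        raise ValueError(f"need at least 5 compounds to honor the ratio, got {n}")
    n_train = round_half_away(train_fraction * n)
    n_test = n - n_train
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    if n_test > 0:
        chosen.append(int(rng.integers(n)))
        # min distance from every candidate to the chosen test set
        d = np.linalg.norm(X - X[chosen[0]], axis=1)
        d[chosen[0]] = -np.inf
        while len(chosen) < n_test:
            nxt = int(np.argmax(d))
            chosen.append(nxt)
            d = np.minimum(d, np.linalg.norm(X - X[nxt], axis=1))
            d[nxt] = -np.inf
    test_idx = set(chosen)
    train_ids = [ids[i] for i in range(n) if i not in test_idx]
    test_ids = [ids[i] for i in sorted(test_idx)]
    return DataSplit(train_ids, test_ids, list(outlier_ids),
                     ratio=train_fraction)


def distribution_report(
    train: Sequence[CompoundRecord],
    test: Sequence[CompoundRecord],
    properties: Sequence[str],
    n_bins: int = 10,
) -> dict[str, dict]:
    """Two-sample KS statistic + shared-bin histogram densities per property.

    Quantifies chemical/biological similarity between the training and test
    sets: a small KS statistic means the two distributions overlap well.
    """
    if not train or not test:
        raise ValueError("both sets must be non-empty")
    report: dict[str, dict] = {}
    for prop in properties:
        a = np.array([_prop(r, prop) for r in train], dtype=float)
        b = np.array([_prop(r, prop) for r in test], dtype=float)
        ks = stats.ks_2samp(a, b)
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        if lo == hi:
            hi = lo + 1.0
        bins = np.linspace(lo, hi, n_bins + 1)
        report[prop] = {
            "ks_statistic": float(ks.statistic),
            "ks_pvalue": float(ks.pvalue),
            "bins": bins.tolist(),
            "train_density": np.histogram(a, bins=bins, density=True)[0].tolist(),
            "test_density": np.histogram(b, bins=bins, density=True)[0].tolist(),
        }
    return report


def _prop(rec: CompoundRecord, prop: str) -> float:
    if prop == "log_kp":
        if rec.log_kp_obs is None:
            raise KeyError(f"record {rec.id!r} has no observed log Kp")
        return rec.log_kp_obs
    if prop not in rec.descriptors:
        raise KeyError(f"record {rec.id!r} lacks property {prop!r}")
    return rec.descriptors[prop]
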