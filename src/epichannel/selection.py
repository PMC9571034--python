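"""Correlation-based feature screening and candidate group assembly.

The screen works on a per-segment feature table (rows pooled over
channels and subjects) with a binary class label.  It computes

* the pairwise Pearson correlation matrix between features, with
  two-sided p-values for H0: rho = 0 from the t statistic
  ``t = r * sqrt((n - 2) / (1 - r^2))`` on n - 2 degrees of freedom;
* a per-feature point-biserial association with the 0/1 label, tested
  the same way.

Group assembly keeps the label-significant features, isolates the
mutually high-correlated cluster among them (all pairwise |r| at or
above ``high_thr``), takes as "core" the remaining kept features whose
mutual correlations stay at or below ``low_thr``, and emits one
candidate group per cluster member: core plus that member.  With
redundant band powers this yields groups that differ only in which band
power they carry.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CorrelationReport:
    """Pairwise feature correlations and label associations.

    Attributes
    ----------
    feature_names : tuple of str
    r : ndarray (p, p)
        Pearson correlation matrix.
    p : ndarray (p, p)
        Two-sided p-values for each pairwise correlation (diagonal 0).
    class_r : ndarray (p,)
        Point-biserial correlation of each feature with the binary label.
    class_p : ndarray (p,)
        Two-sided p-value of each label association.
    n : int
        Number of rows the statistics were computed from.
    """

    feature_names: tuple[str, ...]
    r: np.ndarray
    p: np.ndarray
    class_r: np.ndarray
    class_p: np.ndarray
    n: int

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
        idx = list(self.feature_names)
        return (
            pd.DataFrame(self.r, index=idx, columns=idx),
            pd.DataFrame(self.p, index=idx, columns=idx),
            pd.DataFrame(
                {"class_r": self.class_r, "class_p": self.class_p}, index=idx
            ),
        )


@dataclass(frozen=True)
class FeatureGroup:
    """A candidate 5-feature input group for the classifier."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.members) != 5 or len(set(self.members)) != 5:
            raise ValueError(
                f"a feature group needs exactly 5 distinct members, "
                f"got {self.members}"
            )


def _pearson_p(r: float, n: int) -> float:
    r = min(max(r, -1.0), 1.0)
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def correlation_screen(table: pd.DataFrame, labels) -> CorrelationReport:
    """Compute the pairwise and label-association correlation report.

    ``table`` holds one row per segment and one numeric column per
    feature; ``labels`` is a matching binary vector (0/1 or a two-level
    categorical).  Constant columns are rejected because their Pearson
    correlation is undefined.
    """
    if table.shape[0] < 3:
        raise ValueError("need at least 3 rows for a correlation screen")
    names = tuple(table.columns)
    X = table.to_numpy(dtype=float)
    n = X.shape[0]
    stds = X.std(axis=0)
    constant = [names[j] for j in np.flatnonzero(stds == 0.0)]
    if constant:
        raise ValueError(f"constant feature column(s): {constant}")

    y = np.asarray(pd.factorize(np.asarray(labels))[0], dtype=float)
    if y.size != n:
        raise ValueError("labels length does not match the table")
    if len(np.unique(y)) != 2:
        raise ValueError("labels must take exactly two values")

    r = np.corrcoef(X, rowvar=False)
    p = np.zeros_like(r)
    k = len(names)
    for i, j in combinations(range(k), 2):
        p[i, j] = p[j, i] = _pearson_p(r[i, j], n)

    class_r = np.array(
        [np.corrcoef(X[:, j], y)[0, 1] for j in range(k)]
    )
    class_p = np.array([_pearson_p(v, n) for v in class_r])
    return CorrelationReport(
        feature_names=names, r=r, p=p, class_r=class_r, class_p=class_p, n=n
    )


def _largest_mutual_cluster(names, r, high_thr):
    """Largest subset with all pairwise |r| >= high_thr (greedy + exact
    fallback for the small feature counts involved)."""
    k = len(names)
    adj = np.abs(r) >= high_thr
    best: tuple[int, ...] = ()
    # Exact search is fine for <= 15 features restricted to each node's
    # neighbourhood.
    for size in range(k, 1, -1):
        if size <= len(best):
            break
        for combo in combinations(range(k), size):
            if all(adj[i, j] for i, j in combinations(combo, 2)):
                best = combo
                break
        if best:
            break
    return [names[i] for i in best]


def build_feature_groups(
    report: CorrelationReport,
    alpha: float = 0.05,
    low_thr: float = 0.20,
    high_thr: float = 0.80,
) -> list[FeatureGroup]:
    """Assemble candidate 5-feature groups from a correlation report.

    See the module docstring for the selection logic.  Raises a
    descriptive error when fewer than five features survive screening or
    when the surviving structure does not produce 5-member groups.
    """
    names = list(report.feature_names)
    kept = [
        nm for nm, cp in zip(names, report.class_p) if cp < alpha
    ]
    if len(kept) < 5:
        raise ValueError(
            f"only {len(kept)} features are label-significant at "
            f"alpha={alpha}: {kept}; need at least 5"
        )
    kept_idx = [names.index(nm) for nm in kept]
    r_kept = report.r[np.ix_(kept_idx, kept_idx)]

    cluster = _largest_mutual_cluster(kept, r_kept, high_thr)
    outside = [nm for nm in kept if nm not in cluster]
    out_idx = [kept.index(nm) for nm in outside]
    core = []
    for nm, i in zip(outside, out_idx):
        ok = all(
            abs(r_kept[i, kept.index(other)]) <= low_thr
            for other in outside
            if other != nm
        )
        if ok:
            core.append(nm)

    if not cluster:
        if len(core) != 5:
            raise ValueError(
                f"no high-correlation cluster and the low-correlation core "
                f"has {len(core)} members ({core}); cannot form 5-feature "
                f"groups"
            )
        return [FeatureGroup(name="group-1", members=tuple(core))]

    if len(core) + 1 != 5:
        raise ValueError(
            f"core {core} plus one cluster member has {len(core) + 1} "
            f"features; cannot form 5-feature groups"
        )
    return [
        FeatureGroup(name=f"group-{i + 1}", members=tuple(core) + (member,))
        for i, member in enumerate(cluster)
    ]
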