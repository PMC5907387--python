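"""Compositional statistics for paired-intervention abundance tables.

Rank aggregation, detection-limit-aware log transforms, ecological distances
(Bray-Curtis, abundance-weighted Jaccard, Manhattan), principal coordinate analysis,
PERMANOVA, per-dog baseline-to-post shift analysis, taxon-set ratio tests, and the
leave-out robustness sweep that re-tests a focal comparison after removing every small
subset of genera.
"""

from __future__ import annotations

import itertools
import logging
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform

from .taxonomy import RANKS

logger = logging.getLogger(__name__)

Metric = Literal["bray_curtis", "weighted_jaccard", "manhattan"]

__all__ = [
    "aggregate_rank",
    "feature_pseudocounts",
    "log_transform",
    "distance_matrix",
    "pcoa",
    "permanova",
    "paired_shift",
    "compare_shift_groups",
    "ratio_test",
    "leave_out_robustness",
]


def aggregate_rank(
    abundance: pd.DataFrame,
    lineages: Mapping[str, Mapping[str, str]],
    rank: str,
    unassigned_label: str = "unassigned",
) -> pd.DataFrame:
    """Sum feature abundances by taxon at ``rank``; mass without a label at that rank
    is kept in an ``unassigned`` row (so columns keep their totals)."""
    if rank not in RANKS:
        raise ValueError(f"unknown rank: {rank!r}")
    labels = [
        lineages.get(f, {}).get(rank, unassigned_label) or unassigned_label
        for f in abundance.index
    ]
    out = abundance.groupby(pd.Index(labels, name=rank)).sum()
    return out


def feature_pseudocounts(abundance: pd.DataFrame, policy: str = "feature_min_tenth") -> pd.Series:
    """Per-feature pseudo-counts: 1/10 the feature's lowest nonzero value by default.

    ``policy`` may be ``"feature_min_tenth"``, ``"global_min_tenth"`` or ``"fixed:<x>"``.
    Features that are entirely zero fall back to the global minimum nonzero / 10.
    """
    vals = abundance.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("abundances must be nonnegative")
    nz = vals[vals > 0]
    if nz.size == 0:
        raise ValueError("abundance table is entirely zero")
    global_pseudo = float(nz.min()) / 10.0
    if policy.startswith("fixed:"):
        return pd.Series(float(policy.split(":", 1)[1]), index=abundance.index)
    if policy == "global_min_tenth":
        return pd.Series(global_pseudo, index=abundance.index)
    if policy != "feature_min_tenth":
        raise ValueError(f"unknown pseudo-count policy: {policy!r}")
    out = {}
    for f in abundance.index:
        row = abundance.loc[f].to_numpy(dtype=float)
        rnz = row[row > 0]
        if rnz.size == 0:
            logger.warning("feature %s entirely zero; global pseudo-count used", f)
            out[f] = global_pseudo
        else:
            out[f] = float(rnz.min()) / 10.0
    return pd.Series(out)


def log_transform(
    abundance: pd.DataFrame,
    pseudo_policy: str = "feature_min_tenth",
    shift_to_nonnegative: bool = False,
) -> pd.DataFrame:
    """log10(x + pseudo), pseudo per feature under the given policy.

    With ``shift_to_nonnegative`` the global minimum of the transformed matrix
    (= log10 of the smallest pseudo-count) is subtracted, yielding a nonnegative matrix
    suitable for Bray-Curtis / weighted Jaccard.
    """
    pseudo = feature_pseudocounts(abundance, pseudo_policy)
    out = np.log10(abundance.add(pseudo, axis=0))
    if shift_to_nonnegative:
        out = out - np.log10(pseudo.min())
    return out


def _pairwise(x: np.ndarray, metric: Metric) -> np.ndarray:
    if metric in ("bray_curtis", "weighted_jaccard") and (x < 0).any():
        raise ValueError(f"{metric} requires nonnegative input")
    n = x.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = x[:, i], x[:, j]
            if metric == "bray_curtis":
                denom = (a + b).sum()
                val = np.abs(a - b).sum() / denom if denom > 0 else 0.0
            elif metric == "weighted_jaccard":
                denom = np.maximum(a, b).sum()
                val = 1.0 - np.minimum(a, b).sum() / denom if denom > 0 else 0.0
            else:
                val = np.abs(a - b).sum()
            d[i, j] = d[j, i] = val
    return d


def distance_matrix(matrix: pd.DataFrame, metric: Metric = "bray_curtis") -> pd.DataFrame:
    """All-pairs sample distances over the columns of a feature x sample matrix."""
    x = matrix.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("matrix contains non-finite entries")
    d = _pairwise(x, metric)
    return pd.DataFrame(d, index=matrix.columns, columns=matrix.columns)


def pcoa(d: pd.DataFrame, k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal coordinate analysis of a distance matrix.

    Gower-centers -1/2 J D^2 J, eigendecomposes, and returns the top-``k``
    positive-eigenvalue axes scaled by sqrt(eigenvalue).  All eigenvalues (including
    negative ones) are returned; axes with non-positive eigenvalues yield zero
    coordinates.  Axis signs are fixed so the largest-magnitude loading is positive.
    """
    n = d.shape[0]
    if k > n:
        raise ValueError("k cannot exceed the number of samples")
    dm = d.to_numpy(dtype=float)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    coords = np.zeros((n, k))
    for axis in range(k):
        if evals[axis] > 1e-12:
            v = evecs[:, axis] * np.sqrt(evals[axis])
            if np.abs(v).max() > 0 and v[np.argmax(np.abs(v))] < 0:
                v = -v
            coords[:, axis] = v
    cols = [f"PCo{i + 1}" for i in range(k)]
    return pd.DataFrame(coords, index=d.index, columns=cols), evals


def permanova(
    d: pd.DataFrame,
    labels: Sequence[str] | pd.Series,
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutational multivariate ANOVA on a distance matrix.

    Pseudo-F from the between/within partition of summed squared distances; the p-value
    is the add-one permutation estimate under random label shuffles (or exact if
    exhaustive enumeration of label arrangements is requested via
    ``n_permutations=None``, feasible only for tiny n).
    """
    labels = np.asarray(labels)
    dm = d.to_numpy(dtype=float)
    n = len(labels)
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least two samples")

    iu = np.triu_indices(n, k=1)
    d2 = dm[iu] ** 2

    def pseudo_f(lab: np.ndarray) -> float:
        ss_total = d2.sum() / n
        ss_within = 0.0
        for g in groups:
            idx = np.flatnonzero(lab == g)
            sub = dm[np.ix_(idx, idx)]
            ss_within += (sub[np.triu_indices(len(idx), k=1)] ** 2).sum() / len(idx)
        k = len(groups)
        with np.errstate(divide="ignore"):
            # perfect within-group homogeneity gives F = +inf
            return float(((ss_total - ss_within) / (k - 1)) / (ss_within / (n - k)))

    f_obs = pseudo_f(labels)
    if n_permutations is None:
        # exhaustive over distinct assignments of labels to positions
        count = 0
        total = 0
        for perm in set(itertools.permutations(labels)):
            total += 1
            if pseudo_f(np.asarray(perm)) >= f_obs - 1e-12:
                count += 1
        return f_obs, count / total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        if pseudo_f(rng.permutation(labels)) >= f_obs - 1e-12:
            count += 1
    return f_obs, (1 + count) / (n_permutations + 1)


def paired_shift(
    abundance: pd.DataFrame,
    metadata: pd.DataFrame,
    metric: Metric = "bray_curtis",
    pseudo_policy: str = "feature_min_tenth",
    log: bool = True,
) -> pd.DataFrame:
    """Per-dog distance between the (log-transformed) baseline and post profiles.

    Returns one row per dog with both timepoints: ``dog_id``, ``diet`` (intervention),
    ``condition``, ``shift``.  Dogs missing a timepoint are excluded and logged.
    """
    mat = (
        log_transform(abundance, pseudo_policy, shift_to_nonnegative=True)
        if log
        else abundance
    )
    rows = []
    for dog, sub in metadata.groupby("dog_id"):
        base = sub[sub.timepoint == "baseline"]
        post = sub[sub.timepoint == "post"]
        if len(base) != 1 or len(post) != 1:
            logger.warning("dog %s lacks a complete baseline/post pair; excluded", dog)
            continue
        a = mat[base.sample_id.item()].to_numpy(dtype=float)
        b = mat[post.sample_id.item()].to_numpy(dtype=float)
        d = _pairwise(np.column_stack([a, b]), metric)[0, 1]
        rows.append(
            {
                "dog_id": dog,
                "diet": post.diet.item(),
                "condition": post.condition.item(),
                "shift": d,
            }
        )
    return pd.DataFrame(rows)


def compare_shift_groups(
    shifts: pd.DataFrame, mask_a: pd.Series, mask_b: pd.Series
) -> tuple[float, float]:
    """Two-tailed Mann-Whitney-Wilcoxon between two shift subgroups (exact for small,
    tie-free samples per scipy's contract)."""
    a = shifts.loc[mask_a, "shift"].to_numpy()
    b = shifts.loc[mask_b, "shift"].to_numpy()
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def ratio_test(
    abundance: pd.DataFrame,
    numerator: Sequence[str],
    denominator: Sequence[str],
    groups: Mapping[str, Sequence[str]],
    pseudo_policy: str = "feature_min_tenth",
) -> dict:
    """Per-sample abundance ratio between two taxon sets, compared across groups.

    The ratio is (summed numerator abundance) / (summed denominator abundance +
    pseudo-count); two groups are compared by two-tailed Mann-Whitney-Wilcoxon, three
    or more by Kruskal-Wallis with all pairwise Mann-Whitney follow-ups.
    """
    numerator, denominator = list(numerator), list(denominator)
    if not numerator or not denominator:
        raise ValueError("numerator and denominator taxon sets must be non-empty")
    missing = (set(numerator) | set(denominator)) - set(abundance.index)
    if missing:
        raise KeyError(f"taxa not in table: {sorted(missing)}")
    num = abundance.loc[numerator].sum(axis=0)
    den = abundance.loc[denominator].sum(axis=0)
    den_pseudo = feature_pseudocounts(pd.DataFrame(den).T, pseudo_policy).iloc[0]
    ratios = num / (den + den_pseudo)

    by_group = {g: ratios[list(s)].to_numpy() for g, s in groups.items()}
    names = sorted(by_group)
    result: dict = {"ratios": ratios, "groups": by_group}
    arrays = [by_group[g] for g in names]
    if np.ptp(np.concatenate(arrays)) == 0:
        # all samples tied across all groups: no association by construction
        result["test"] = "degenerate"
        result["p_value"] = 1.0
        return result
    if len(names) == 2:
        stat, p = stats.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
        result.update(test="mann_whitney", statistic=float(stat), p_value=float(p))
    else:
        stat, p = stats.kruskal(*arrays)
        result.update(test="kruskal_wallis", statistic=float(stat), p_value=float(p))
        pairwise = {}
        for ga, gb in itertools.combinations(names, 2):
            s, pp = stats.mannwhitneyu(by_group[ga], by_group[gb], alternative="two-sided")
            pairwise[(ga, gb)] = float(pp)
        result["pairwise_p"] = pairwise
    return result


def leave_out_robustness(
    abundance: pd.DataFrame,
    metadata: pd.DataFrame,
    focal_comparison: Callable[[pd.DataFrame], float],
    max_k: int = 3,
    alpha: float = 0.05,
    metric: Metric = "bray_curtis",
) -> dict:
    """Re-test a focal shift comparison after removing every genus subset of size
    1..max_k.

    ``focal_comparison`` maps a shift table (from :func:`paired_shift`) to a p-value —
    e.g. HPLC/OW dogs vs all others.  Each removal re-closes the composition before
    recomputing shifts.  Returns per-subset p-values, their range, and whether every
    subset stayed below ``alpha``.
    """
    genera = list(abundance.index)
    if len(genera) < max_k + 1:
        raise ValueError("too few genera for the requested removal depth")
    records = []
    for k in range(1, max_k + 1):
        for subset in itertools.combinations(genera, k):
            kept = abundance.drop(index=list(subset))
            totals = kept.sum(axis=0)
            reclosed = kept.div(totals.where(totals > 0, 1.0), axis=1)
            shifts = paired_shift(reclosed, metadata, metric=metric)
            records.append({"removed": subset, "p_value": focal_comparison(shifts)})
    report = pd.DataFrame(records)
    return {
        "subsets": report,
        "n_subsets": len(report),
        "min_p": float(report.p_value.min()),
        "max_p": float(report.p_value.max()),
        "all_significant": bool((report.p_value < alpha).all()),
        "breaking_subsets": [
            tuple(r) for r in report.loc[report.p_value >= alpha, "removed"]
        ],
    }
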