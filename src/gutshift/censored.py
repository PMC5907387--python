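"""Detection-limit-aware censored ratio testing.

The intervention's effect on a taxon is measured as the log10 ratio of its
post-intervention to baseline abundance in each dog.  A relative-abundance detection
limit makes these ratios doubly censored: a baseline below the limit only bounds the
ratio from below (right-censored), a post sample below it only bounds from above
(left-censored), and dogs below the limit at both timepoints carry no information and
are dropped.  Groups of such ratios are compared with Gehan's generalized Wilcoxon test
for doubly censored data, whose pairwise score is +1/-1 only when the two observations'
possible ranges are strictly ordered, and whose p-value here comes from permutation of
group membership (exhaustive when the split count is small, Monte Carlo otherwise).

Multiple testing across taxa uses the two-stage (adaptive) Benjamini-Hochberg
procedure; prevalence (detected / not detected) changes across diets use Fisher's exact
test with Bonferroni correction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CensoredValue",
    "TestResult",
    "censored_log_ratios",
    "gehan_score",
    "gehan_test",
    "two_stage_bh",
    "prevalence_test",
    "fisher_exact_2xg",
    "censored_ratio_table",
]

Status = Literal["observed", "left", "right"]

EXACT_SPLIT_LIMIT = 50_000


@dataclass(frozen=True)
class CensoredValue:
    """A log-ratio with censoring status.

    ``left`` means the true ratio is at most ``value`` (post sample below detection);
    ``right`` means it is at least ``value`` (baseline below detection).
    """

    value: float
    status: Status = "observed"

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError("censored value must be finite")
        if self.status not in ("observed", "left", "right"):
            raise ValueError(f"invalid status: {self.status}")

    @property
    def lower(self) -> float:
        return self.value if self.status in ("observed", "right") else -math.inf

    @property
    def upper(self) -> float:
        return self.value if self.status in ("observed", "left") else math.inf


@dataclass
class TestResult:
    statistic: float
    p_value: float
    q_value: float | None = None
    n_used: int = 0
    n_excluded: int = 0


def censored_log_ratios(
    baseline: Sequence[float],
    post: Sequence[float],
    pseudo: float,
    detection_limit: float | None = None,
) -> tuple[list[CensoredValue], int]:
    """Per-dog post/baseline log10 ratios with censoring statuses.

    ``pseudo`` is the pseudo-count added to every measurement (1/10 of the feature's
    lowest nonzero detection under the package default policy).  A measurement counts
    as below the detection limit when it is < ``detection_limit`` (or exactly 0 when no
    limit is given).  Dogs below the limit at both timepoints are dropped; the second
    return value counts them.
    """
    b = np.asarray(baseline, dtype=float)
    p = np.asarray(post, dtype=float)
    if b.shape != p.shape:
        raise ValueError("baseline and post must be aligned by dog")
    if (b < 0).any() or (p < 0).any():
        raise ValueError("abundances must be nonnegative")
    limit = detection_limit if detection_limit is not None else 0.0
    below_b = b < limit if limit > 0 else b == 0
    below_p = p < limit if limit > 0 else p == 0

    values: list[CensoredValue] = []
    n_excluded = 0
    for bi, pi, cb, cp in zip(b, p, below_b, below_p):
        if cb and cp:
            n_excluded += 1
            continue
        ratio = math.log10((pi + pseudo) / (bi + pseudo))
        if cb:
            status: Status = "right"
        elif cp:
            status = "left"
        else:
            status = "observed"
        values.append(CensoredValue(ratio, status))
    return values, n_excluded


def gehan_score(a: CensoredValue, b: CensoredValue) -> int:
    """Pairwise Gehan score: +1 if ``a`` is definitely larger than ``b``, -1 if
    definitely smaller, 0 when the censoring leaves the order indeterminate."""
    if a.lower > b.upper:
        return 1
    if a.upper < b.lower:
        return -1
    return 0


def _score_matrix(values: Sequence[CensoredValue]) -> np.ndarray:
    lower = np.array([v.lower for v in values])
    upper = np.array([v.upper for v in values])
    s = np.zeros((len(values), len(values)), dtype=np.int8)
    s[lower[:, None] > upper[None, :]] = 1
    s[upper[:, None] < lower[None, :]] = -1
    return s


def gehan_test(
    group1: Sequence[CensoredValue],
    group2: Sequence[CensoredValue],
    mode: Literal["auto", "exact", "monte_carlo"] = "auto",
    n_permutations: int = 9999,
    seed: int = 0,
) -> TestResult:
    """Two-sided Gehan test comparing two groups of censored log-ratios.

    The statistic is W = sum over cross-group pairs of :func:`gehan_score`.  The
    two-sided p-value is computed by permuting group membership: exhaustively over all
    C(n, n1) splits when that count is at most 50,000 (or mode="exact" forces it), else
    by Monte Carlo with the add-one estimator (1 + #{|W*| >= |W|}) / (B + 1).
    """
    if len(group1) == 0 or len(group2) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = list(group1) + list(group2)
    n1, n = len(group1), len(pooled)
    s = _score_matrix(pooled)
    idx1 = np.arange(n1)
    idx2 = np.arange(n1, n)
    w_obs = int(s[np.ix_(idx1, idx2)].sum())

    n_splits = math.comb(n, n1)
    use_exact = mode == "exact" or (mode == "auto" and n_splits <= EXACT_SPLIT_LIMIT)
    # W for a split = total positive-order weight restricted to (G1, G2) pairs; compute
    # via row sums: sum_{i in G1} rowsum_i - sum_{i in G1, j in G1} s_ij
    row_sums = s.sum(axis=1)
    if use_exact:
        count = 0
        for comb in itertools.combinations(range(n), n1):
            comb = np.array(comb)
            w = row_sums[comb].sum() - s[np.ix_(comb, comb)].sum()
            if abs(w) >= abs(w_obs) - 1e-9:
                count += 1
        p = count / n_splits
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            comb = rng.choice(n, size=n1, replace=False)
            w = row_sums[comb].sum() - s[np.ix_(comb, comb)].sum()
            if abs(w) >= abs(w_obs) - 1e-9:
                count += 1
        p = (1 + count) / (n_permutations + 1)
    return TestResult(statistic=float(w_obs), p_value=float(p), n_used=n)


def two_stage_bh(
    p_values: Sequence[float], q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage (adaptive) Benjamini-Hochberg FDR control.

    Stage 1 runs BH at level q/(1+q) to estimate the number of true nulls
    m0 = m - r1; stage 2 reruns BH at level q*m/m0.  Returns (rejected boolean array,
    stage-2 adjusted q-values).  r1 = 0 rejects nothing; m0 = 0 rejects everything.
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)

    def bh_reject(pv: np.ndarray, level: float) -> np.ndarray:
        order = np.argsort(pv, kind="stable")
        thresh = level * (np.arange(1, m + 1)) / m
        passed = pv[order] <= thresh
        rejected = np.zeros(m, dtype=bool)
        if passed.any():
            kmax = np.max(np.flatnonzero(passed))
            rejected[order[: kmax + 1]] = True
        return rejected

    def bh_adjust(pv: np.ndarray) -> np.ndarray:
        order = np.argsort(pv, kind="stable")
        ranked = pv[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(adj, 1.0)
        return out

    r1 = int(bh_reject(p, q / (1.0 + q)).sum())
    if r1 == 0:
        return np.zeros(m, dtype=bool), np.minimum(bh_adjust(p), 1.0)
    m0 = m - r1
    if m0 == 0:
        return np.ones(m, dtype=bool), np.zeros(m)
    rejected = bh_reject(p, q * m / m0)
    q_values = np.minimum(bh_adjust(p) * m0 / m, 1.0)
    return rejected, q_values


def fisher_exact_2xg(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2 x g contingency table.

    g = 2 delegates to the hypergeometric-tail construction (scipy); g >= 3 enumerates
    all tables with the observed margins under the multivariate hypergeometric null and
    sums the probabilities of tables as or less probable than the observed one.
    """
    t = np.asarray(table, dtype=int)
    if t.shape[0] != 2:
        raise ValueError("table must have two rows (detected / not detected)")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    if t.shape[1] == 2:
        return float(stats.fisher_exact(t, alternative="two-sided")[1])

    col_totals = t.sum(axis=0)
    d = int(t[0].sum())  # detected margin
    n_total = int(t.sum())

    def log_prob(ks: tuple[int, ...]) -> float:
        # log of prod_j C(n_j, k_j) / C(N, d)
        lp = -(math.lgamma(n_total + 1) - math.lgamma(d + 1) - math.lgamma(n_total - d + 1))
        for n_j, k_j in zip(col_totals, ks):
            lp += math.lgamma(n_j + 1) - math.lgamma(k_j + 1) - math.lgamma(n_j - k_j + 1)
        return lp

    lp_obs = log_prob(tuple(int(k) for k in t[0]))
    g = t.shape[1]

    total = 0.0
    p_sum = 0.0

    def recurse(j: int, remaining: int, ks: list[int]) -> None:
        nonlocal total, p_sum
        if j == g - 1:
            if remaining > col_totals[j]:
                return
            lp = log_prob(tuple(ks + [remaining]))
            pr = math.exp(lp)
            total += pr
            if lp <= lp_obs + 1e-9:
                p_sum += pr
            return
        for k in range(0, min(col_totals[j], remaining) + 1):
            recurse(j + 1, remaining - k, ks + [k])

    recurse(0, d, [])
    return float(min(p_sum / total, 1.0))


def prevalence_test(
    presence: pd.DataFrame,
    diet_labels: pd.Series,
    alpha: float = 0.05,
    mode: Literal["pairwise", "joint"] = "pairwise",
) -> pd.DataFrame:
    """Per-taxon Fisher exact test of detection prevalence across diet groups.

    ``presence`` is a taxon x sample boolean table (detected at or above the detection
    limit); ``diet_labels`` maps sample -> diet.  ``pairwise`` tests each diet pair with
    a 2x2 table and reports the minimum p; ``joint`` builds one 2 x g table per taxon.
    Bonferroni multiplies by the number of taxa tested (and diet pairs in pairwise
    mode), capped at 1.
    """
    diets = sorted(diet_labels.unique())
    if len(diets) < 2:
        raise ValueError("need at least two diet groups")
    for d in diets:
        if (diet_labels == d).sum() == 0:
            raise ValueError(f"diet group {d} is empty")
    samples_by_diet = {d: diet_labels.index[diet_labels == d] for d in diets}

    rows = []
    for taxon in presence.index:
        det = presence.loc[taxon]
        if mode == "joint":
            tab = np.array(
                [
                    [int(det[samples_by_diet[d]].sum()) for d in diets],
                    [int((~det[samples_by_diet[d]]).sum()) for d in diets],
                ]
            )
            p = fisher_exact_2xg(tab)
            rows.append({"taxon": taxon, "comparison": "all", "p_value": p})
        else:
            for da, db in itertools.combinations(diets, 2):
                tab = np.array(
                    [
                        [int(det[samples_by_diet[da]].sum()), int(det[samples_by_diet[db]].sum())],
                        [
                            int((~det[samples_by_diet[da]]).sum()),
                            int((~det[samples_by_diet[db]]).sum()),
                        ],
                    ]
                )
                p = fisher_exact_2xg(tab)
                rows.append({"taxon": taxon, "comparison": f"{da}_vs_{db}", "p_value": p})
    out = pd.DataFrame(rows)
    n_tests = len(out)
    out["p_bonferroni"] = np.minimum(out["p_value"] * n_tests, 1.0)
    out["significant"] = out["p_bonferroni"] < alpha
    return out


def censored_ratio_table(
    baseline: pd.DataFrame,
    post: pd.DataFrame,
    group_labels: pd.Series,
    pseudo_policy: str = "feature_min_tenth",
    detection_limit: float | None = None,
    q: float = 0.05,
    n_permutations: int = 9999,
    seed: int = 0,
) -> pd.DataFrame:
    """Gehan-test every feature's censored log-ratios between two groups of dogs.

    ``baseline`` and ``post`` are feature x dog tables aligned on columns;
    ``group_labels`` maps dog -> group (exactly two groups).  Per-feature pseudo-counts
    follow ``pseudo_policy`` over the concatenated baseline+post values.  P-values are
    corrected with :func:`two_stage_bh`.
    """
    from .composition import feature_pseudocounts

    if list(baseline.columns) != list(post.columns):
        raise ValueError("baseline and post must share the same dog columns")
    groups = sorted(group_labels.unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups are required")
    dogs_a = [d for d in baseline.columns if group_labels[d] == groups[0]]
    dogs_b = [d for d in baseline.columns if group_labels[d] == groups[1]]

    pseudo = feature_pseudocounts(pd.concat([baseline, post], axis=1), pseudo_policy)
    rows = []
    for i, feature in enumerate(baseline.index):
        res = {}
        for key, dogs in (("a", dogs_a), ("b", dogs_b)):
            vals, n_exc = censored_log_ratios(
                baseline.loc[feature, dogs],
                post.loc[feature, dogs],
                pseudo=float(pseudo[feature]),
                detection_limit=detection_limit,
            )
            res[key] = vals
            res[f"n_excluded_{key}"] = n_exc
        if not res["a"] or not res["b"]:
            rows.append(
                {
                    "feature": feature,
                    "statistic": np.nan,
                    "p_value": np.nan,
                    "n_used": 0,
                    "n_excluded": res["n_excluded_a"] + res["n_excluded_b"],
                }
            )
            continue
        t = gehan_test(
            res["a"], res["b"], n_permutations=n_permutations, seed=seed + i
        )
        rows.append(
            {
                "feature": feature,
                "statistic": t.statistic,
                "p_value": t.p_value,
                "n_used": t.n_used,
                "n_excluded": res["n_excluded_a"] + res["n_excluded_b"],
            }
        )
    out = pd.DataFrame(rows).set_index("feature")
    tested = out["p_value"].notna()
    q_values = np.full(len(out), np.nan)
    if tested.any():
        rejected, qv = two_stage_bh(out.loc[tested, "p_value"].to_numpy(), q=q)
        q_values[tested.to_numpy()] = qv
        sig = np.zeros(len(out), dtype=bool)
        sig[tested.to_numpy()] = rejected
        out["significant"] = sig
    out["q_value"] = q_values
    return out
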