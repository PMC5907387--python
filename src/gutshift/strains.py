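"""Strain-level population structure from SNP allele frequencies.

Samples with sufficient coverage of a species' genome (vertical depth and horizontal
breadth gates) are compared by the mean absolute difference of allele frequencies over
the SNP positions observed in both samples — a normalized Manhattan distance that is 0
for identical variation profiles and 1 for completely distinct ones.  The resulting
distance matrix feeds principal coordinate analysis for host-specificity questions.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

from .composition import pcoa

logger = logging.getLogger(__name__)

__all__ = ["filter_coverage", "snp_distance", "pairwise_snp_distances", "strain_pcoa"]


def filter_coverage(
    coverage: pd.DataFrame, min_depth: float = 5.0, min_breadth: float = 0.8
) -> list[str]:
    """Samples with mean depth >= ``min_depth`` (5x vertical) and covered-position
    fraction >= ``min_breadth`` (80% horizontal).

    ``coverage`` is indexed by sample with columns ``mean_depth`` and ``breadth``.
    """
    keep = coverage[
        (coverage["mean_depth"] >= min_depth) & (coverage["breadth"] >= min_breadth)
    ]
    return list(keep.index)


def snp_distance(f_a: pd.Series, f_b: pd.Series, min_shared: int = 1) -> float:
    """Normalized Manhattan distance between two allele-frequency profiles.

    Restricted to positions non-missing in both samples; the summed |difference| is
    normalized by the number of examined positions, so identical profiles score 0 and
    completely distinct ones (0 vs 1 everywhere) score 1.
    """
    a = f_a.to_numpy(dtype=float)
    b = f_b.reindex(f_a.index).to_numpy(dtype=float)
    shared = ~(np.isnan(a) | np.isnan(b))
    n = int(shared.sum())
    if n < max(min_shared, 1):
        raise ValueError(f"only {n} shared positions (min_shared={min_shared})")
    if ((a[shared] < 0) | (a[shared] > 1) | (b[shared] < 0) | (b[shared] > 1)).any():
        raise ValueError("allele frequencies must lie in [0, 1]")
    return float(np.abs(a[shared] - b[shared]).mean())


def pairwise_snp_distances(
    freqs: pd.DataFrame, min_shared: int = 50
) -> pd.DataFrame:
    """All-pairs normalized Manhattan distance; incomparable pairs (too few shared
    positions) become NaN and are logged."""
    samples = list(freqs.columns)
    d = pd.DataFrame(0.0, index=samples, columns=samples)
    for a, b in itertools.combinations(samples, 2):
        try:
            val = snp_distance(freqs[a], freqs[b], min_shared=min_shared)
        except ValueError:
            logger.warning("pair (%s, %s) incomparable; recorded as missing", a, b)
            val = np.nan
        d.loc[a, b] = d.loc[b, a] = val
    return d


def strain_pcoa(
    freqs: pd.DataFrame,
    host_labels: pd.Series,
    coverage: pd.DataFrame | None = None,
    min_depth: float = 5.0,
    min_breadth: float = 0.8,
    min_shared: int = 50,
    k: int = 2,
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Coverage-gated PCoA of strain profiles plus an annotated pair table.

    Returns (coordinates, eigenvalues, pair table); the pair table lists every sample
    pair with its distance and whether the two samples share a host label.  Samples
    with incomparable pairs are dropped (most-missing first) until the matrix is
    complete.
    """
    cols = list(freqs.columns)
    if coverage is not None:
        cols = [c for c in filter_coverage(coverage, min_depth, min_breadth) if c in cols]
    if len(cols) < 3:
        raise ValueError("need at least 3 eligible samples")
    d = pairwise_snp_distances(freqs[cols], min_shared=min_shared)
    while d.isna().any().any():
        worst = d.isna().sum(axis=1).idxmax()
        logger.warning("dropping %s (incomparable with %d samples)", worst, int(d.isna().sum(axis=1).max()))
        d = d.drop(index=worst, columns=worst)
    if d.shape[0] < 3:
        raise ValueError("fewer than 3 mutually comparable samples remain")

    coords, evals = pcoa(d, k=min(k, d.shape[0]))
    rows = []
    for a, b in itertools.combinations(d.index, 2):
        rows.append(
            {
                "sample_a": a,
                "sample_b": b,
                "distance": float(d.loc[a, b]),
                "same_host": bool(host_labels[a] == host_labels[b]),
            }
        )
    return coords, evals, pd.DataFrame(rows)
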