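"""Species-level marker-gene linkage groups (mOTU-LGs).

Universal single-copy marker genes from one species co-vary in abundance across
samples.  Linking genes whose length-normalized, log-transformed abundance profiles
correlate above a permutation-calibrated threshold (empirical FDR, default 0.02)
recovers species-level groups without reference genomes.  Group abundance is coverage:
summed base counts over summed gene length, closed per sample; the per-sample detection
limit is the relative abundance of the least-abundant group, and the global limit the
worst (largest) of these.  Taxonomic labels migrate from member genes to the group only
under 100% agreement at each rank, with species additionally requiring every member's
percent identity to exceed its family's clustering cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .taxonomy import RANKS

__all__ = [
    "LinkageGroup",
    "DetectionLimits",
    "link_marker_genes",
    "lg_abundance",
    "detection_limits",
    "annotate_lg",
]


@dataclass
class LinkageGroup:
    """A set of marker genes inferred to originate from one species."""

    name: str
    genes: list[str]
    families: list[str]
    lineage: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class DetectionLimits:
    per_sample: pd.Series
    global_limit: float


def _normalized_log(table: pd.DataFrame) -> np.ndarray:
    counts = table.drop(columns=["family", "length"]).to_numpy(dtype=float)
    lengths = table["length"].to_numpy(dtype=float)[:, None]
    return np.log10(1.0 + counts / lengths)


def link_marker_genes(
    table: pd.DataFrame,
    target_fdr: float = 0.02,
    n_permutations: int = 100,
    seed: int = 0,
    method: Literal["pearson", "spearman"] = "pearson",
) -> list[LinkageGroup]:
    """Group marker genes into linkage groups by abundance correlation.

    ``table`` is indexed by gene id with columns ``family``, ``length`` and one column
    per sample.  Correlations are computed on log10(1 + count/length); the linking
    threshold is the smallest correlation whose empirical FDR — null pair correlations
    from independent per-gene sample permutations over observed pair correlations — is
    at or below ``target_fdr``.  Components of the thresholded graph are agglomerated
    strongest-edge-first under the one-gene-per-family constraint; singletons are
    discarded.
    """
    n_genes = len(table)
    n_samples = table.shape[1] - 2
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    if n_samples < 8:
        raise ValueError("need at least 8 samples to calibrate the permutation null")

    x = _normalized_log(table)
    if method == "spearman":
        x = stats.rankdata(x, axis=1)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(x)
    corr = np.nan_to_num(corr, nan=0.0)
    iu = np.triu_indices(n_genes, k=1)
    observed = corr[iu]

    rng = np.random.default_rng(seed)
    null_pool = []
    for _ in range(n_permutations):
        xp = x.copy()
        for g in range(n_genes):
            xp[g] = xp[g, rng.permutation(n_samples)]
        with np.errstate(invalid="ignore"):
            cp = np.corrcoef(xp)
        null_pool.append(np.nan_to_num(cp, nan=0.0)[iu])
    null = np.sort(np.concatenate(null_pool))

    # empirical FDR(r) = mean null pairs >= r / observed pairs >= r; smallest r passing
    obs_sorted = np.sort(observed)
    threshold = None
    for r in np.unique(obs_sorted)[::-1]:
        n_obs = n_genes * (n_genes - 1) // 2 - np.searchsorted(obs_sorted, r, side="left")
        n_null = (len(null) - np.searchsorted(null, r, side="left")) / n_permutations
        if n_obs > 0 and n_null / n_obs <= target_fdr:
            threshold = r
        else:
            break
    if threshold is None:
        return []

    families = table["family"].tolist()
    genes = table.index.tolist()
    edges = [
        (corr[i, j], i, j)
        for i, j in zip(*iu)
        if corr[i, j] >= threshold
    ]
    edges.sort(reverse=True)

    # strongest-edge-first agglomeration; merge only if family sets stay disjoint
    cluster_of = list(range(n_genes))
    members: dict[int, set[int]] = {i: {i} for i in range(n_genes)}
    fams: dict[int, set[str]] = {i: {families[i]} for i in range(n_genes)}
    for _, i, j in edges:
        ci, cj = cluster_of[i], cluster_of[j]
        if ci == cj:
            continue
        if fams[ci] & fams[cj]:
            continue
        if len(fams[ci]) < len(fams[cj]):
            ci, cj = cj, ci
        for g in members[cj]:
            cluster_of[g] = ci
        members[ci] |= members.pop(cj)
        fams[ci] |= fams.pop(cj)

    groups = []
    for k, (cid, mem) in enumerate(sorted(members.items())):
        if len(mem) < 2:
            continue
        gene_ids = sorted(genes[g] for g in mem)
        groups.append(
            LinkageGroup(
                name=f"LG{len(groups):04d}",
                genes=gene_ids,
                families=sorted(families[g] for g in mem),
            )
        )
    return groups


def lg_abundance(table: pd.DataFrame, groups: Sequence[LinkageGroup]) -> pd.DataFrame:
    """Linkage-group relative abundances.

    Per group and sample: summed member base counts standardized to the summed member
    gene length (i.e. coverage), then closed to relative abundance per sample.
    """
    sample_cols = [c for c in table.columns if c not in ("family", "length")]
    rows = {}
    for grp in groups:
        if not grp.genes:
            raise ValueError(f"group {grp.name} is empty")
        sub = table.loc[grp.genes]
        cov = sub[sample_cols].sum(axis=0) / sub["length"].sum()
        rows[grp.name] = cov
    raw = pd.DataFrame(rows).T
    totals = raw.sum(axis=0)
    rel = raw.div(totals.where(totals > 0, 1.0), axis=1)
    rel.index.name = "linkage_group"
    return rel


def detection_limits(abundance: pd.DataFrame) -> DetectionLimits:
    """Per-sample limit = least nonzero relative abundance; global = max (least
    sensitive) of the per-sample limits."""
    limits = {}
    for col in abundance.columns:
        vals = abundance[col].to_numpy(dtype=float)
        nz = vals[vals > 0]
        if nz.size == 0:
            raise ValueError(f"sample {col} has no detected features")
        limits[col] = float(nz.min())
    per_sample = pd.Series(limits, name="detection_limit")
    return DetectionLimits(per_sample=per_sample, global_limit=float(per_sample.max()))


def annotate_lg(
    per_gene_lineages: Mapping[str, Mapping[str, str]],
    per_gene_identities: Mapping[str, float] | None = None,
    family_identity_cutoffs: Mapping[str, float] | None = None,
    gene_families: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Migrate member-gene annotations to the group under the unanimity rule.

    Walking ranks from superkingdom down, a label is adopted iff every annotated member
    carries that label; the walk stops at the first disagreement.  The species label is
    adopted only if, additionally, every member's best-hit identity exceeds its marker
    family's clustering cutoff.
    """
    lineages = [dict(lin) for lin in per_gene_lineages.values()]
    if not lineages:
        raise ValueError("need at least one annotated member gene")
    adopted: dict[str, str] = {}
    for rank in RANKS:
        labels = {lin.get(rank) for lin in lineages}
        if labels == {None}:
            continue  # rank absent from every member; keep walking
        if len(labels) != 1 or None in labels:
            break
        (label,) = labels
        if rank == "species":
            if per_gene_identities is None or family_identity_cutoffs is None:
                break
            ok = True
            for gene, ident in per_gene_identities.items():
                fam = (gene_families or {}).get(gene)
                cutoff = family_identity_cutoffs.get(fam, family_identity_cutoffs.get(gene, None))
                if cutoff is None or ident <= cutoff:
                    ok = False
                    break
            if not ok:
                break
        adopted[rank] = label
    return adopted
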