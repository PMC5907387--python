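"""Co-abundance network inference on compositional data.

Relative abundances sum to one, which induces spurious negative correlation between
taxa; sparCC-style basis-correlation inference corrects for this by estimating the
correlations of the unobserved absolute ("basis") abundances from the variation matrix
of pairwise log-ratios, under the assumption that true correlations are sparse and
average to zero.  Edge significance comes from permutation p-values (each taxon's
samples shuffled independently), edge magnitude from Spearman correlation — an edge
enters the network only when |Spearman r| exceeds the magnitude threshold AND the
sparCC permutation q-value (Benjamini-Hochberg across all pairs) clears the FDR.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .composition import feature_pseudocounts

__all__ = [
    "sparcc_correlations",
    "sparcc_pvalues",
    "build_network",
    "network_groups",
    "write_edge_list",
]


def _prepare_fractions(abundance: pd.DataFrame) -> np.ndarray:
    """Replace zeros with per-feature pseudo-counts and re-close columns."""
    x = abundance.to_numpy(dtype=float).copy()
    pseudo = feature_pseudocounts(abundance).to_numpy()
    x = x + pseudo[:, None]
    if (x <= 0).any():
        raise ValueError("fractions must be positive after pseudo-count replacement")
    return x / x.sum(axis=0, keepdims=True)


def _basis_correlations(
    log_f: np.ndarray, exclusion_threshold: float, max_exclusion_iters: int
) -> np.ndarray:
    d = log_f.shape[0]
    t = np.var(log_f[:, None, :] - log_f[None, :, :], axis=2, ddof=1)

    included = ~np.eye(d, dtype=bool)  # pair inclusion mask for the linear system

    def solve(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # t_i. ~= k_i * w_i^2 + sum_{j in mask_i} w_j^2 under mean-zero correlations
        m = mask.astype(float)
        a = m.copy()
        np.fill_diagonal(a, mask.sum(axis=1))
        ti = (t * m).sum(axis=1)
        omega2 = np.linalg.solve(a, ti)
        omega2 = np.maximum(omega2, 1e-12)
        omega = np.sqrt(omega2)
        rho = (omega2[:, None] + omega2[None, :] - t) / (2.0 * np.outer(omega, omega))
        np.fill_diagonal(rho, 1.0)
        return np.clip(rho, -1.0, 1.0), omega

    rho, _ = solve(included)
    for _ in range(max_exclusion_iters):
        off = np.abs(rho) * included
        np.fill_diagonal(off, 0.0)
        i, j = np.unravel_index(np.argmax(off), off.shape)
        if off[i, j] <= exclusion_threshold:
            break
        included[i, j] = included[j, i] = False
        if (included.sum(axis=1) < 3).any():
            break
        rho, _ = solve(included)
    return rho


def sparcc_correlations(
    abundance: pd.DataFrame,
    exclusion_threshold: float = 0.1,
    max_exclusion_iters: int = 10,
) -> pd.DataFrame:
    """Basis (absolute-scale) correlation estimates from compositional fractions.

    Computes the variation matrix t_ij = Var(log(x_i / x_j)), solves the linear system
    t_ij ~= w_i^2 + w_j^2 for the basis variances under the sparse mean-zero-correlation
    approximation, and recovers rho_ij = (w_i^2 + w_j^2 - t_ij) / (2 w_i w_j), clipped
    to [-1, 1].  The single strongest correlated pair above ``exclusion_threshold`` is
    iteratively removed from the system (up to ``max_exclusion_iters`` times) so that a
    few strongly coupled taxa do not bias every basis variance.
    """
    if abundance.shape[0] < 4:
        raise ValueError("sparCC needs at least 4 taxa for identifiability")
    f = _prepare_fractions(abundance)
    rho = _basis_correlations(np.log(f), exclusion_threshold, max_exclusion_iters)
    return pd.DataFrame(rho, index=abundance.index, columns=abundance.index)


def sparcc_pvalues(
    abundance: pd.DataFrame,
    n_permutations: int = 99,
    seed: int = 0,
    exclusion_threshold: float = 0.1,
    max_exclusion_iters: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-sided empirical p-values for sparCC correlations.

    Each permutation independently shuffles every taxon's values across samples
    (destroying both real correlation and the shared compositional constraint's
    sample structure) and recomputes the basis correlations; the per-pair p-value is
    the add-one fraction of permutations with |rho*| >= |rho|.  Returns (rho, p).
    """
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations for empirical p-values")
    rho = sparcc_correlations(abundance, exclusion_threshold, max_exclusion_iters)
    f = _prepare_fractions(abundance)
    log_f = np.log(f)
    d, n = log_f.shape
    rng = np.random.default_rng(seed)
    obs = np.abs(rho.to_numpy())
    count = np.zeros((d, d))
    for _ in range(n_permutations):
        perm = np.empty_like(log_f)
        for i in range(d):
            perm[i] = log_f[i, rng.permutation(n)]
        rho_star = _basis_correlations(perm, exclusion_threshold, max_exclusion_iters)
        count += np.abs(rho_star) >= obs - 1e-12
    p = (1.0 + count) / (n_permutations + 1.0)
    np.fill_diagonal(p, 1.0)
    return rho, pd.DataFrame(p, index=abundance.index, columns=abundance.index)


def build_network(
    abundance: pd.DataFrame,
    r_threshold: float = 0.5,
    fdr: float = 0.05,
    n_permutations: int = 99,
    seed: int = 0,
) -> nx.Graph:
    """Co-abundance network: edges need |Spearman r| > ``r_threshold`` and a sparCC
    permutation q-value (BH over all pairs) at or below ``fdr``.

    Edge attributes: ``spearman_r``, ``sparcc_rho``, ``p``, ``q``, ``sign``.
    """
    taxa = list(abundance.index)
    spearman = stats.spearmanr(abundance.to_numpy(dtype=float), axis=1)[0]
    spearman = np.atleast_2d(spearman)
    rho, p = sparcc_pvalues(abundance, n_permutations=n_permutations, seed=seed)

    pairs = list(itertools.combinations(range(len(taxa)), 2))
    p_flat = np.array([p.iloc[i, j] for i, j in pairs])
    q_flat = multipletests(p_flat, method="fdr_bh")[1]

    g = nx.Graph()
    g.add_nodes_from(taxa)
    for (i, j), p_ij, q_ij in zip(pairs, p_flat, q_flat):
        r = float(spearman[i, j])
        if abs(r) > r_threshold and q_ij <= fdr:
            g.add_edge(
                taxa[i],
                taxa[j],
                spearman_r=r,
                sparcc_rho=float(rho.iloc[i, j]),
                p=float(p_ij),
                q=float(q_ij),
                sign=1 if r > 0 else -1,
            )
    return g


def network_groups(
    net: nx.Graph, abundance: pd.DataFrame | None = None
) -> tuple[list[set[str]], pd.DataFrame | None]:
    """Connected components over positive edges only, plus (optionally) each
    multi-node group's summed relative abundance per sample."""
    pos = nx.Graph()
    pos.add_nodes_from(net.nodes)
    pos.add_edges_from(
        (u, v) for u, v, d in net.edges(data=True) if d.get("sign", 1) > 0
    )
    components = [set(c) for c in nx.connected_components(pos)]
    components.sort(key=lambda c: (-len(c), sorted(c)[0]))
    sums = None
    if abundance is not None:
        rows = {}
        for k, comp in enumerate(c for c in components if len(c) > 1):
            members = sorted(comp & set(abundance.index))
            rows[f"group_{k}"] = abundance.loc[members].sum(axis=0)
        sums = pd.DataFrame(rows).T if rows else pd.DataFrame()
    return components, sums


def write_edge_list(net: nx.Graph, path) -> None:
    rows = [
        {
            "source": u,
            "target": v,
            "spearman_r": d["spearman_r"],
            "sparcc_rho": d["sparcc_rho"],
            "p": d["p"],
            "q": d["q"],
            "sign": d["sign"],
        }
        for u, v, d in net.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "spearman_r", "sparcc_rho", "p", "q", "sign"]).to_csv(
        path, sep="\t", index=False
    )
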