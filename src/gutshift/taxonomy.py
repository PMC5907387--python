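"""Rooted taxonomy, LCA queries, and dual-search least-common-ancestor gene annotation.

The annotation procedure assigns a taxon to a query gene from homology hits: a first
search establishes the best homolog and its e-value; a second search seeded with the
matched region of that best homolog collects the "homolog neighborhood" — every
second-search hit at least as good as the first search's best e-value — and the gene is
assigned the least common ancestor of the neighborhood's taxa.  Queries whose best first
hit is worse than the e-value threshold (default 1e-5) are reported as no-hit.

The homology search itself is injected via the :class:`SearchBackend` protocol, so the
module is agnostic to whether hits come from DIAMOND/BLAST tabular output or a test
stub.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

RANKS = ("superkingdom", "phylum", "class", "order", "family", "genus", "species")

NO_HIT = "no hit"


@dataclass(frozen=True)
class Hit:
    """One homology-search hit: subject, e-value, matched subject region, identity."""

    subject: str
    evalue: float
    sstart: int = 0
    send: int = 0
    pident: float = 100.0

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError("e-value must be positive")
        if self.sstart > self.send:
            raise ValueError("matched region begin must not exceed end")


class SearchBackend(Protocol):
    """Homology search abstraction.

    ``search(query)`` and ``search_region(subject, start, end)`` return hits sorted by
    ascending e-value; both must be deterministic for fixed inputs.
    """

    def search(self, query: str) -> Sequence[Hit]: ...

    def search_region(self, subject: str, start: int, end: int) -> Sequence[Hit]: ...


class TaxonomyTree:
    """Rooted taxonomy supporting parent walks, LCA, and lineage extraction."""

    def __init__(
        self,
        parent: Mapping[str, str],
        names: Mapping[str, str] | None = None,
        ranks: Mapping[str, str] | None = None,
    ) -> None:
        self.parent = dict(parent)
        self.names = dict(names or {})
        self.ranks = dict(ranks or {})
        roots = [n for n, p in self.parent.items() if p == n or p is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {roots}")
        self.root = roots[0]
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        for node in self.parent:
            seen = set()
            cur = node
            while cur != self.root:
                if cur in seen:
                    raise ValueError(f"cycle detected at {cur}")
                seen.add(cur)
                nxt = self.parent.get(cur)
                if nxt is None:
                    raise ValueError(f"node {cur} has no path to root")
                cur = nxt

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.parent

    def ancestors(self, taxon: str) -> list[str]:
        """Path from ``taxon`` (inclusive) up to the root (inclusive)."""
        if taxon not in self.parent:
            raise KeyError(f"unknown taxon: {taxon}")
        path = [taxon]
        while path[-1] != self.root:
            path.append(self.parent[path[-1]])
        return path

    def lineage(self, taxon: str) -> dict[str, str]:
        """Named-rank labels along the root path, e.g. ``{"genus": "G1", ...}``."""
        out: dict[str, str] = {}
        for node in self.ancestors(taxon):
            rank = self.ranks.get(node, "no rank")
            if rank in RANKS and rank not in out:
                out[rank] = self.names.get(node, node)
        return out

    @classmethod
    def from_tsv(cls, edges_path: str | Path, names_path: str | Path | None = None) -> "TaxonomyTree":
        """Read an NCBI-dump-like dialect: a child/parent TSV plus optional
        taxon/name/rank TSV (columns ``taxon``, ``name``, ``rank``)."""
        edges = pd.read_csv(edges_path, sep="\t", dtype=str)
        parent = dict(zip(edges.iloc[:, 0], edges.iloc[:, 1]))
        names = ranks = None
        if names_path is not None:
            meta = pd.read_csv(names_path, sep="\t", dtype=str)
            names = dict(zip(meta.iloc[:, 0], meta.iloc[:, 1]))
            ranks = dict(zip(meta.iloc[:, 0], meta.iloc[:, 2]))
        return cls(parent, names, ranks)


def lca(tree: TaxonomyTree, taxa: Iterable[str]) -> str:
    """Deepest node ancestral to (or equal to) every taxon in the set."""
    taxa = list(taxa)
    if not taxa:
        raise ValueError("taxon set must be non-empty")
    common: list[str] | None = None
    for t in taxa:
        path = tree.ancestors(t)
        if common is None:
            common = path
        else:
            keep = set(path)
            common = [n for n in common if n in keep]
    assert common  # root is always shared
    return common[0]


def annotate_gene(
    query: str,
    backend: SearchBackend,
    tree: TaxonomyTree,
    subject_taxon: Mapping[str, str],
    e_threshold: float = 1e-5,
) -> dict[str, str] | None:
    """Dual-search LCA annotation of one query gene.

    Returns the lineage dict of the assigned taxon, or ``None`` for no-hit.  Hits whose
    subject has no taxon mapping are skipped with a warning.  First-search ties at the
    best e-value are broken by subject id (lexicographic) for determinism.
    """
    first = [h for h in backend.search(query)]
    first = sorted(first, key=lambda h: (h.evalue, h.subject))
    first = [h for h in first if h.evalue <= e_threshold]
    if not first:
        return None
    best = first[0]
    best_evalue = best.evalue

    second = backend.search_region(best.subject, best.sstart, best.send)
    neighborhood: set[str] = set()
    for h in second:
        if h.evalue <= best_evalue:
            taxon = subject_taxon.get(h.subject)
            if taxon is None:
                logger.warning("subject %s has no taxon mapping; hit skipped", h.subject)
                continue
            neighborhood.add(taxon)
    if not neighborhood:
        # the seed subject itself satisfies the e-value condition by construction
        taxon = subject_taxon.get(best.subject)
        if taxon is None:
            logger.warning("best-hit subject %s unmapped; no annotation", best.subject)
            return None
        neighborhood.add(taxon)
    node = lca(tree, neighborhood)
    return tree.lineage(node)


def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Tabular BLAST-like TSV: qseqid, sseqid, pident, evalue, sstart, send."""
    cols = ["qseqid", "sseqid", "pident", "evalue", "sstart", "send"]
    return pd.read_csv(path, sep="\t", names=cols, comment="#")


class TableBackend:
    """SearchBackend over precomputed hit tables (one per query / subject region).

    ``first_hits`` maps query id -> hits; ``second_hits`` maps subject id -> hits of the
    region-seeded search.  Region coordinates are accepted but ignored (the tables are
    assumed to be precomputed for the regions in play).
    """

    def __init__(
        self,
        first_hits: Mapping[str, Sequence[Hit]],
        second_hits: Mapping[str, Sequence[Hit]],
    ) -> None:
        self.first_hits = {q: sorted(h, key=lambda x: (x.evalue, x.subject)) for q, h in first_hits.items()}
        self.second_hits = {s: sorted(h, key=lambda x: (x.evalue, x.subject)) for s, h in second_hits.items()}

    def search(self, query: str) -> Sequence[Hit]:
        return self.first_hits.get(query, [])

    def search_region(self, subject: str, start: int, end: int) -> Sequence[Hit]:
        return self.second_hits.get(subject, [])
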