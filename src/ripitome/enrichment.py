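"""Gene-set overrepresentation analysis in the ImmuneMap style.

A pathway collection (GMT) is tested against a query gene list with the
upper-tail hypergeometric test: with a universe of N genes, a pathway of K
genes and a query of n genes sharing k members, the p-value is
P(X >= k) for X ~ Hypergeometric(N, K, n).  P-values are Benjamini-Hochberg
adjusted across all pathways of the collection.  Significant pathways can be
exported as a bipartite pathway-gene network in SIF form for Cytoscape.

Only overrepresentation is tested; the universe is an explicit argument
because its choice (typically the expressed-gene list) is the most
result-sensitive free parameter of this kind of analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "read_gmt",
    "write_gmt",
    "bh_adjust",
    "hypergeometric_enrichment",
    "export_network",
]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets with free-text descriptions."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str]

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"pathway {name!r} is empty")
            if any(not g for g in genes):
                raise ValueError(f"pathway {name!r} contains an empty gene id")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]


@dataclass(frozen=True)
class EnrichmentResult:
    pathway: str
    k: int  # overlap with query
    K: int  # pathway size within the universe
    n: int  # query size within the universe
    N: int  # universe size
    p_value: float
    adj_p: float
    significant: bool


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a tab-separated GMT file (name, description, genes...).

    Duplicate genes within a line are collapsed; a line with fewer than three
    fields raises a parse error naming the line number.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, desc, *genes = fields
            sets[name] = frozenset(g for g in genes if g)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection:
            desc = collection.descriptions.get(name, "")
            genes = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``adj_(i) = min_{j >= i} m * p_(j) / j`` over the sorted p-values, capped
    at 1.  Values outside [0, 1] raise ``ValueError``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


def hypergeometric_enrichment(
    query: Iterable[str],
    sets: GeneSetCollection,
    universe: Iterable[str],
    alpha: float = 0.05,
) -> tuple[list[EnrichmentResult], int]:
    """Upper-tail hypergeometric enrichment of every pathway for a query list.

    Query genes outside the universe are dropped (their count is returned);
    pathways are intersected with the universe.  Returns the per-pathway
    results and the number of dropped query genes.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("universe must be nonempty")
    query_all = set(query)
    query_set = query_all & universe_set
    dropped = len(query_all) - len(query_set)

    N, n = len(universe_set), len(query_set)
    results: list[EnrichmentResult] = []
    pvals: list[float] = []
    for name in sets:
        members = sets[name] & universe_set
        K = len(members)
        k = len(members & query_set)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        pvals.append(min(p, 1.0))
        results.append(EnrichmentResult(name, k, K, n, N, pvals[-1], 1.0, False))

    adj = bh_adjust(pvals)
    results = [
        EnrichmentResult(r.pathway, r.k, r.K, r.n, r.N, r.p_value,
                         float(q), bool(q < alpha))
        for r, q in zip(results, adj)
    ]
    return results, dropped


def export_network(
    results: Sequence[EnrichmentResult],
    sets: GeneSetCollection,
    query: Iterable[str],
    gene_directions: Mapping[str, str] | None = None,
) -> tuple[list[tuple[str, str]], str, str]:
    """Bipartite pathway-gene network over the significant pathways.

    Emits one edge per (significant pathway, pathway member present in the
    query list).  Returns ``(edges, sif_text, node_table_text)``: the SIF has
    one ``pathway<TAB>contains<TAB>gene`` line per edge and the node table
    carries the per-gene direction annotation (up/down/spliced/mixed).
    """
    query_set = set(query)
    gene_directions = gene_directions or {}
    edges: list[tuple[str, str]] = []
    for r in results:
        if not r.significant:
            continue
        for gene in sorted(sets[r.pathway] & query_set):
            edges.append((r.pathway, gene))
    sif = "".join(f"{p}\tcontains\t{g}\n" for p, g in edges)
    genes = sorted({g for _, g in edges})
    node_lines = ["gene\tdirection\n"]
    node_lines += [f"{g}\t{gene_directions.get(g, 'none')}\n" for g in genes]
    return edges, sif, "".join(node_lines)
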