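"""Term enrichment for genes behind a cell type's top pathways.

After ranking the most heavily weighted pathway nodes per cell type, the
member genes of those pathways form a query list; overrepresentation of
annotation terms (e.g. GO-style gene sets read from GMT) in that list is
assessed with the one-sided hypergeometric test, corrected across terms by
Benjamini-Hochberg at alpha = 0.05.

The default universe is the model's input gene space — the genes the
network could possibly have used — rather than a whole genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .data_io import GeneSetCollection
from .encoding import NodeRanking


@dataclass
class EnrichmentResult:
    """One row per annotation term, sorted by q then p."""

    table: pd.DataFrame  # term, overlap, query_size, term_size, universe_size, p, q, significant
    alpha: float

    @property
    def significant_terms(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "term"])


def hypergeometric_enrichment(
    query: set[str],
    annotation: GeneSetCollection,
    universe: set[str],
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of each annotation term.

    p = P(X >= overlap) with X ~ Hypergeom(N=|universe|, K=|term ∩ universe|,
    n=|query|). Query genes outside the universe are dropped with a warning.
    Terms with zero overlap are kept (p = 1) so that the BH correction runs
    over every tested term.
    """
    universe = {str(g).strip() for g in universe}
    if len(universe) < 2:
        raise ValueError("universe must contain at least 2 genes")
    query = {str(g).strip() for g in query}
    outside = query - universe
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the universe dropped",
            stacklevel=2,
        )
        query &= universe
    if not query:
        raise ValueError("query is empty after restricting to the universe")

    N, n = len(universe), len(query)
    rows = []
    for name, _, members in annotation.sets:
        term_genes = members & universe
        K = len(term_genes)
        overlap = len(query & term_genes)
        # P(X >= overlap); sf(k) = P(X > k)
        p = float(hypergeom.sf(overlap - 1, N, K, n)) if K else 1.0
        rows.append(
            {
                "term": name,
                "overlap": overlap,
                "query_size": n,
                "term_size": K,
                "universe_size": N,
                "p": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    reject, q, _, _ = multipletests(df["p"], alpha=alpha, method="fdr_bh")
    df["q"] = q
    df["significant"] = reject
    df = df.sort_values(["q", "p", "term"], kind="stable").reset_index(drop=True)
    return EnrichmentResult(table=df, alpha=alpha)


def genes_from_top_nodes(
    ranking: NodeRanking,
    collection: GeneSetCollection,
    cls: str | None = None,
    mask_aware: bool = True,
    input_genes: list[str] | None = None,
) -> dict[str, set[str]] | set[str]:
    """Union of member genes of each class's top-ranked pathways.

    With ``mask_aware`` the union is restricted to ``input_genes`` — the
    genes the trained model actually saw. Returns a per-class dict, or a
    single set when ``cls`` is given.
    """
    known = set(collection.names)
    restrict = set(input_genes) if (mask_aware and input_genes is not None) else None

    def one(class_name: str) -> set[str]:
        genes: set[str] = set()
        for node, _ in ranking.per_class[class_name]:
            if node not in known:
                raise KeyError(f"ranked node {node!r} not in the gene-set collection")
            genes |= collection.members(node)
        if restrict is not None:
            genes &= restrict
        return genes

    if cls is not None:
        return one(cls)
    return {c: one(c) for c in ranking.per_class}
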