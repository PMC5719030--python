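"""Gene-set over-representation and the overlap network.

The genes feeding the analysis are the union of three upstream streams:
genes from the regional association scan, candidate-locus hits, and
genes spanned by case-only CNVs. Over-representation of each gene set is
scored with the hypergeometric tail against a gene universe, corrected
by Benjamini–Hochberg; the retained sets become nodes of a network whose
edges connect sets sharing members (overlap coefficient
|A∩B| / min(|A|, |B|), the Enrichment-Map convention), with each node
tagged by the CNV-type composition of its supporting genes
(duplications only vs duplications and deletions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "assemble_gene_list",
    "EnrichedSet",
    "enrich_genesets",
    "overlap_coefficient",
    "GeneSetGraph",
    "build_overlap_network",
]


def assemble_gene_list(
    regional_hits: Iterable[str],
    candidate_hits: Iterable[str],
    case_only_genes: Iterable[str],
) -> Tuple[List[str], Dict[str, Set[str]]]:
    """Union the three gene streams, deduplicated and sorted.

    Returns ``(genes, provenance)`` where ``provenance[gene]`` is the
    subset of {"regional", "candidate", "case_only"} that contributed it.
    """
    provenance: Dict[str, Set[str]] = {}
    for source, genes in (
        ("regional", regional_hits),
        ("candidate", candidate_hits),
        ("case_only", case_only_genes),
    ):
        for g in genes:
            provenance.setdefault(g, set()).add(source)
    return sorted(provenance), provenance


@dataclass(frozen=True)
class EnrichedSet:
    name: str
    genes: frozenset  # full membership (intersected with the universe)
    hits: frozenset  # members found in the input gene list
    p: float
    q: float


def enrich_genesets(
    gene_list: Sequence[str],
    geneset_db: Mapping[str, Set[str]],
    universe: Iterable[str],
    q_threshold: float = 0.05,
) -> List[EnrichedSet]:
    """Hypergeometric over-representation of each gene set in ``gene_list``.

    For a universe of N genes, a set with K members in the universe and a
    gene list of n draws with k hits, p = P(X >= k) for
    X ~ Hypergeom(N, K, n). Benjamini–Hochberg q-values are computed over
    all testable sets; sets with q <= ``q_threshold`` are returned,
    sorted by ascending p.
    """
    uni = set(universe)
    if not uni.issuperset(gene_list):
        raise ValueError("universe must contain every gene in gene_list")
    draws = set(gene_list)
    names, pvals, rows = [], [], []
    for name in sorted(geneset_db):
        members = geneset_db[name] & uni
        if not members:
            import warnings

            warnings.warn(f"gene set {name!r} has no members in the universe; skipped")
            continue
        hits = members & draws
        # P(X >= k); sf(k-1) is the upper tail inclusive of k
        p = float(stats.hypergeom.sf(len(hits) - 1, len(uni), len(members), len(draws)))
        names.append(name)
        pvals.append(p)
        rows.append((name, members, hits))
    if not names:
        return []
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    enriched = [
        EnrichedSet(name, frozenset(members), frozenset(hits), p, float(q))
        for (name, members, hits), p, q in zip(rows, pvals, qvals)
        if q <= q_threshold
    ]
    return sorted(enriched, key=lambda e: (e.p, e.name))


def overlap_coefficient(a: Set[str], b: Set[str]) -> float:
    """|A∩B| / min(|A|, |B|); 1 iff one set contains the other."""
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))


@dataclass
class GeneSetGraph:
    """Enriched gene sets as nodes, overlap-coefficient edges (networkx-backed)."""

    graph: nx.Graph

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def write_graphml(self, path) -> None:
        g = self.graph.copy()
        for _, data in g.nodes(data=True):
            data["genes"] = ",".join(sorted(data["genes"]))
            data["hits"] = ",".join(sorted(data["hits"]))
        nx.write_graphml(g, path)

    @classmethod
    def read_graphml(cls, path) -> "GeneSetGraph":
        g = nx.read_graphml(path)
        for _, data in g.nodes(data=True):
            data["genes"] = frozenset(data["genes"].split(","))
            data["hits"] = frozenset(data["hits"].split(",")) if data["hits"] else frozenset()
        return cls(g)

    def write_edge_tsv(self, path) -> None:
        rows = [
            {"set_a": a, "set_b": b, "overlap_coefficient": d["overlap_coefficient"]}
            for a, b, d in sorted(self.graph.edges(data=True))
        ]
        pd.DataFrame(rows, columns=["set_a", "set_b", "overlap_coefficient"]).to_csv(
            path, sep="\t", index=False
        )


def build_overlap_network(
    enriched_sets: Sequence[EnrichedSet],
    cutoff: float = 0.5,
    gene_cnv_types: Optional[Mapping[str, Set[str]]] = None,
    metric: str = "overlap",
) -> GeneSetGraph:
    """Connect enriched sets whose member-gene overlap reaches ``cutoff``.

    ``gene_cnv_types`` maps a gene symbol to the CNV types
    ({"deletion", "duplication"}) of its supporting calls; each node is
    labelled ``duplications_only`` or ``duplications_and_deletions``
    accordingly (the two colours of the published map; nodes with no type
    information are labelled ``unknown``). ``metric`` may be ``"overlap"``
    (the default overlap coefficient) or ``"jaccard"``.
    """
    if metric not in ("overlap", "jaccard"):
        raise ValueError("metric must be 'overlap' or 'jaccard'")
    g = nx.Graph()
    for e in enriched_sets:
        types: Set[str] = set()
        if gene_cnv_types:
            for gene in e.hits:
                types |= gene_cnv_types.get(gene, set())
        if not types:
            composition = "unknown"
        elif types == {"duplication"}:
            composition = "duplications_only"
        else:
            composition = "duplications_and_deletions"
        g.add_node(
            e.name, genes=frozenset(e.genes), hits=frozenset(e.hits),
            p=e.p, q=e.q, cnv_composition=composition,
        )
    items = sorted(enriched_sets, key=lambda e: e.name)
    for i, a in enumerate(items):
        for b in items[i + 1:]:
            if metric == "overlap":
                coef = overlap_coefficient(set(a.genes), set(b.genes))
            else:
                union = a.genes | b.genes
                coef = len(a.genes & b.genes) / len(union) if union else 0.0
            if coef >= cutoff and coef > 0:
                g.add_edge(a.name, b.name, overlap_coefficient=coef)
    return GeneSetGraph(g)
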