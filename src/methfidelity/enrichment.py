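"""Gene-set enrichment: probe-bias-aware Wallenius test, Fisher ORA,
redundancy reduction and the multi-contrast hypomethylated-gene intersection.

Methylation arrays annotate very different numbers of CpGs per gene, so a
gene with more probes is more likely to fall in a DMR by chance.  The
Wallenius noncentral hypergeometric test corrects for this by weighting
genes with the per-gene CpG count: the odds parameter of each term is the
ratio of the mean CpG count of term genes to that of non-term genes.  With
uniform bias it reduces to the central hypergeometric, i.e. ordinary
over-representation analysis (Fisher).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, nchypergeom_wallenius
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "read_gmt",
    "gene_cpg_bias",
    "wallenius_test",
    "ora_fisher",
    "reduce_redundancy",
    "intersect_hypo",
]


@dataclass
class GeneSetCollection:
    sets: dict[str, set[str]]                      # term id -> member genes
    names: dict[str, str] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        for term, genes in self.sets.items():
            if not genes:
                raise ValueError(f"empty gene set: {term}")

    def items(self):
        return self.sets.items()


@dataclass
class EnrichmentResult:
    term: str
    p: float
    q: float | None
    overlap: set[str]
    k: int               # overlap count
    term_size: int       # term genes in universe
    universe_size: int


def read_gmt(path: str | Path, source: str = "") -> GeneSetCollection:
    """Read a GMT file (term, description, tab-separated genes)."""
    sets: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if term in sets:
            raise ValueError(f"duplicate term id: {term}")
        sets[term] = set(genes)
        names[term] = desc
    return GeneSetCollection(sets=sets, names=names, source=source)


def gene_cpg_bias(manifest: pd.DataFrame) -> pd.Series:
    """Per-gene CpG (probe) count over the manifest; the Wallenius bias."""
    genic = manifest[manifest["gene"] != ""]
    return genic.groupby("gene").size().astype(float)


def _bh(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    if not results:
        return results
    _, q, _, _ = multipletests([r.p for r in results], method="fdr_bh")
    for r, qv in zip(results, q):
        r.q = float(qv)
    return results


def wallenius_test(
    query_genes: set[str],
    genesets: GeneSetCollection,
    bias: pd.Series,
    universe: set[str],
) -> list[EnrichmentResult]:
    """Wallenius noncentral hypergeometric enrichment, CpG-count biased.

    For each term, the odds weight is the mean bias of term genes divided
    by the mean bias of non-term genes; the p-value is the upper tail
    P(X >= k) of the Wallenius distribution with that odds, followed by
    Benjamini–Hochberg correction across terms.
    """
    query = set(query_genes) & universe
    if query != set(query_genes):
        raise ValueError("query must be a subset of the universe")
    missing = universe - set(bias.index)
    if missing:
        raise ValueError(f"bias missing for {len(missing)} universe genes")
    if (bias.loc[list(universe)] < 1).any():
        raise ValueError("bias must be >= 1 for every universe gene")

    M, N = len(universe), len(query)
    results = []
    for term, members in genesets.items():
        in_uni = members & universe
        if not in_uni:
            warnings.warn(f"term {term} disjoint from universe; skipped")
            continue
        n = len(in_uni)
        k = len(in_uni & query)
        out_uni = universe - in_uni
        odds = (
            float(bias.loc[list(in_uni)].mean() / bias.loc[list(out_uni)].mean())
            if out_uni
            else 1.0
        )
        dist = nchypergeom_wallenius(M, n, N, odds)
        p = float(np.clip(dist.sf(k - 1), 0.0, 1.0))
        results.append(EnrichmentResult(term, p, None, in_uni & query, k, n, M))
    return _bh(results)


def ora_fisher(
    query_genes: set[str],
    genesets: GeneSetCollection,
    universe: set[str],
) -> list[EnrichmentResult]:
    """One-sided Fisher over-representation analysis with BH correction."""
    query = set(query_genes) & universe
    if not query:
        raise ValueError("empty query")
    M, N = len(universe), len(query)
    results = []
    for term, members in genesets.items():
        in_uni = members & universe
        if not in_uni:
            warnings.warn(f"term {term} disjoint from universe; skipped")
            continue
        n = len(in_uni)
        k = len(in_uni & query)
        p = float(hypergeom.sf(k - 1, M, n, N))
        results.append(EnrichmentResult(term, p, None, in_uni & query, k, n, M))
    return _bh(results)


def reduce_redundancy(
    results: list[EnrichmentResult],
    genesets: GeneSetCollection,
    cutoff: float = 0.3,
) -> list[EnrichmentResult]:
    """Greedy redundancy reduction by member-gene Jaccard similarity.

    Terms are visited by ascending p (ties by term id for determinism); a
    term is kept unless its Jaccard similarity with an already-kept term
    exceeds ``cutoff``.
    """
    kept: list[EnrichmentResult] = []
    for res in sorted(results, key=lambda r: (r.p, r.term)):
        genes = genesets.sets[res.term]
        redundant = False
        for other in kept:
            og = genesets.sets[other.term]
            j = len(genes & og) / len(genes | og)
            if j > cutoff:
                redundant = True
                break
        if not redundant:
            kept.append(res)
    return kept


def intersect_hypo(
    lists: dict[str, set[str]],
) -> tuple[set[str], pd.DataFrame]:
    """Intersection of per-contrast hypomethylated gene sets.

    Returns the genes shared by all contrasts and a Venn-style membership
    table: one row per observed membership pattern with its gene count
    (columns are the contrast labels, plus ``n_lists`` and ``count``).
    """
    if len(lists) < 2:
        raise ValueError("need >= 2 gene lists")
    labels = list(lists)
    if any(len(s) == 0 for s in lists.values()):
        warnings.warn("an input list is empty; intersection is empty")
    shared = set.intersection(*[set(s) for s in lists.values()])

    membership: dict[tuple[bool, ...], int] = {}
    for gene in set.union(*[set(s) for s in lists.values()]):
        pat = tuple(gene in lists[lb] for lb in labels)
        membership[pat] = membership.get(pat, 0) + 1
    rows = [
        {**{lb: m for lb, m in zip(labels, pat)},
         "n_lists": sum(pat), "count": cnt}
        for pat, cnt in sorted(membership.items(), reverse=True)
    ]
    return shared, pd.DataFrame(rows)
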