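"""Hypergeometric GO-term enrichment with multiple-testing correction.

Each term with at least one annotated background gene is tested with the
upper-tail hypergeometric probability P(X >= k); correction (BH by default,
Bonferroni selectable) is applied within each GO namespace separately, and a
term is significant when its adjusted p-value is <= 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from sirnakit.diffexpr import benjamini_hochberg

logger = logging.getLogger(__name__)

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")


@dataclass
class EnrichmentResult:
    go_term: str
    namespace: str
    k: int  # target genes annotated to the term
    n: int  # target-set size
    K: int  # background genes annotated to the term
    N: int  # background size
    p_value: float
    adjusted_p: float = float("nan")
    significant: bool = False


def hypergeom_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Upper tail P(X >= k), X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(n, K) and k <= n <= N and K <= N):
        raise ValueError(f"invalid hypergeometric bounds: k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); scipy computes this with stable log-space terms
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def adjust_pvalues(p_values, method: str = "bh") -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    if method == "bh":
        return benjamini_hochberg(p)
    if method == "bonferroni":
        return np.minimum(p * len(p), 1.0)
    raise ValueError(f"unknown method: {method}")


def read_go_map(path: Path) -> list[tuple[str, str, str]]:
    """(gene_id, go_id, namespace) triples from a 2/3-column TSV."""
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        has_ns = len(header) >= 3
        if header[0] not in ("gene_id", "gene"):  # headerless file: keep line
            fh.seek(0)
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            ns = parts[2] if has_ns and len(parts) >= 3 else "biological_process"
            rows.append((parts[0], parts[1], ns))
    return rows


def enrich(
    target_gene_ids: set[str],
    background_gene_ids: set[str],
    go_map: list[tuple[str, str, str]],
    method: str = "bh",
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """One result per GO term with K >= 1; sorted by adjusted_p, then term id.

    ``target_gene_ids`` must be a subset of the background; genes absent from
    the map still count toward N.
    """
    if not target_gene_ids <= background_gene_ids:
        raise ValueError("target set must be a subset of the background")
    if not target_gene_ids:
        logger.warning("empty target set: no enrichment computed")
        return []

    term_genes: dict[tuple[str, str], set[str]] = {}
    for gene, term, ns in go_map:
        if gene in background_gene_ids:
            term_genes.setdefault((term, ns), set()).add(gene)

    N = len(background_gene_ids)
    n = len(target_gene_ids)
    results = []
    for (term, ns), genes in term_genes.items():
        K = len(genes)
        k = len(genes & target_gene_ids)
        results.append(
            EnrichmentResult(term, ns, k, n, K, N, hypergeom_pvalue(k, n, K, N))
        )

    for ns in {r.namespace for r in results}:
        group = [r for r in results if r.namespace == ns]
        adjusted = adjust_pvalues([r.p_value for r in group], method)
        for r, adj in zip(group, adjusted):
            r.adjusted_p = float(adj)
            r.significant = bool(adj <= alpha)

    results.sort(key=lambda r: (r.adjusted_p, r.go_term))
    return results


def write_enrichment_tsv(results: list[EnrichmentResult], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("go_term\tnamespace\tk\tn\tK\tN\tp_value\tadjusted_p\tsignificant\n")
        for r in results:
            fh.write(
                f"{r.go_term}\t{r.namespace}\t{r.k}\t{r.n}\t{r.K}\t{r.N}\t"
                f"{r.p_value:.6g}\t{r.adjusted_p:.6g}\t{int(r.significant)}\n"
            )
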