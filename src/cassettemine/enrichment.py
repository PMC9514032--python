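"""Hypergeometric over-representation analysis with Benjamini-Hochberg FDR.

For a query of ``n`` genes drawn from a universe of ``N``, a term annotating
``K`` universe genes and ``k`` query genes has upper-tail p-value

    p = sum_{i=k}^{min(n, K)} C(K, i) C(N-K, n-i) / C(N, n)

computed in log-space.  Raw p-values are corrected with the BH step-up
procedure and terms with adjusted p <= alpha (default 0.05) are flagged
significant.  Term-to-gene maps are inputs (TSV: term_id, term_name, gene);
no ontology is fetched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, TextIO

import numpy as np
from scipy.special import gammaln

from .model import DataError


def _log_comb(n: int, r) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), in log-space."""
    if not (0 <= k <= min(n, K) and k <= n <= N and K <= N):
        raise DataError(f"invalid hypergeometric counts k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    i = np.arange(k, min(n, K) + 1)
    log_terms = _log_comb(K, i) + _log_comb(N - K, n - i) - _log_comb(N, n)
    m = log_terms.max()
    return float(min(1.0, np.exp(m) * np.exp(log_terms - m).sum()))


def bh_adjust(pvalues: Iterable[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise DataError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out.tolist()


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int
    n: int
    K: int
    N: int
    p: float
    p_adj: float
    significant: bool

    @property
    def gene_ratio(self) -> float:
        return self.k / self.n


def run_ora(
    query_genes: set[str],
    term_map: dict[str, tuple[str, set[str]]],
    universe: set[str],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Over-representation of each term in the query against the universe.

    ``term_map`` maps term_id -> (term_name, annotated genes).  Terms with no
    query overlap are omitted; results are sorted by raw p ascending, ties by
    term_id; ``significant`` means adjusted p <= alpha (inclusive).
    """
    if not universe:
        raise DataError("empty universe")
    if not query_genes <= universe:
        raise DataError(f"query genes outside universe: {sorted(query_genes - universe)}")
    N = len(universe)
    n = len(query_genes)
    rows = []
    for term_id in sorted(term_map):
        term_name, genes = term_map[term_id]
        annotated = genes & universe
        k = len(query_genes & annotated)
        if k == 0:
            continue
        K = len(annotated)
        rows.append((term_id, term_name, k, K, hypergeom_upper_tail(k, K, n, N)))
    adjusted = bh_adjust([r[4] for r in rows])
    results = [
        EnrichmentResult(
            term_id=tid,
            term_name=tname,
            k=k,
            n=n,
            K=K,
            N=N,
            p=p,
            p_adj=padj,
            significant=padj <= alpha,
        )
        for (tid, tname, k, K, p), padj in zip(rows, adjusted)
    ]
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def read_term_map(source: TextIO) -> dict[str, tuple[str, set[str]]]:
    """Read a term map TSV (term_id, term_name, gene)."""
    expected = ["term_id", "term_name", "gene"]
    out: dict[str, tuple[str, set[str]]] = {}
    header: list[str] | None = None
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            if header != expected:
                raise DataError(f"term map TSV: expected header {expected}, got {header}")
            continue
        if len(fields) != 3:
            raise DataError(f"term map TSV: malformed line {lineno}")
        tid, tname, gene = fields
        name, genes = out.setdefault(tid, (tname, set()))
        genes.add(gene)
    return out
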