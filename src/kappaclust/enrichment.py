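"""Hypergeometric over-representation and module enrichment scores.

Each annotation term carried by a module is tested for over-representation
against a background gene universe (ideally the full transcriptome the gene
list was drawn from): with N background genes of which K carry the term,
and a module of n genes of which k carry it, the p-value is the upper tail
P(X >= k) of Hypergeometric(N, K, n).

The module enrichment score aggregates the per-term p-values as

    score = -log10( geometric mean of p-values )
          = mean of -log10(p)  over the module's terms,

so a score of 1.3 corresponds to a geometric-mean p of 0.05 — the
conventional significance cut-off for calling a module enriched.

The plain hypergeometric test is the default; DAVID's jackknifed EASE
variant (overlap counted as k-1) is available via ``ease=True`` for
comparability with the web tool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import AnnotationMatrix, BackgroundAnnotation
from .clustering import Module

__all__ = ["TermRecord", "EnrichmentResult", "hypergeom_p", "score_module", "score_from_pvalues"]

DEFAULT_SIG_THRESHOLD = 1.3  # -log10(0.05), the enriched-module cut-off


def hypergeom_p(k: int, n: int, K: int, N: int, *, ease: bool = False) -> float:
    """Upper-tail hypergeometric p-value P(X >= k), inclusive of k.

    Parameters
    ----------
    k
        Module genes carrying the term.
    n
        Module size.
    K
        Background genes carrying the term.
    N
        Background size.
    ease
        Apply the EASE jackknife (test k-1 instead of k; k=0 stays 0).
    """
    if not (0 <= k <= n <= N) or not (0 <= K <= N):
        raise ValueError(f"impossible counts k={k}, n={n}, K={K}, N={N}")
    if k > K:
        raise ValueError(f"overlap k={k} exceeds background term count K={K}")
    if ease:
        k = max(k - 1, 0)
    if k == 0:
        return 1.0
    # P(X >= k) = sf(k - 1); scipy's sf is exact enough but can return
    # exactly 0 by underflow for extreme tails, so floor at the log-survival
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    if p <= 0.0:
        p = float(np.exp(stats.hypergeom.logsf(k - 1, N, K, n)))
    return min(max(p, np.nextafter(0, 1)), 1.0)


def score_from_pvalues(p_values: np.ndarray | list[float]) -> float:
    """Enrichment score of a p-value vector.

    -log10 of the geometric mean, computed as the arithmetic mean of
    -log10(p) so that very small p-values cannot underflow the product.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return float(np.mean(-np.log10(p)))


@dataclass(frozen=True)
class TermRecord:
    """One term's over-representation test inside one module."""

    term_id: str
    k: int
    n: int
    K: int
    N: int
    p_value: float


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-term tests and the aggregate score for one module."""

    module_id: int
    terms: tuple[TermRecord, ...]
    enrichment_score: float
    significant: bool
    sig_threshold: float = DEFAULT_SIG_THRESHOLD

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-term table with Benjamini-Hochberg adjusted p-values.

        The BH column is informational; the enrichment score aggregates the
        raw p-values.
        """
        df = pd.DataFrame(
            [
                {
                    "module_id": self.module_id,
                    "term_id": t.term_id,
                    "k": t.k,
                    "n": t.n,
                    "K": t.K,
                    "N": t.N,
                    "p_value": t.p_value,
                }
                for t in self.terms
            ]
        )
        df["bh_adjusted_p"] = _benjamini_hochberg(df["p_value"].to_numpy())
        return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def score_module(
    module: Module,
    matrix: AnnotationMatrix,
    background: BackgroundAnnotation | AnnotationMatrix | None = None,
    sig_threshold: float = DEFAULT_SIG_THRESHOLD,
    *,
    min_overlap: int = 1,
    ease: bool = False,
) -> EnrichmentResult:
    """Score one module's biological coherence against the background.

    Every term annotated to at least ``min_overlap`` module members enters
    the geometric mean (default: all terms with any member).  If no
    background is given the query annotation itself serves as the universe,
    which measures enrichment only relative to the input list.
    """
    if background is None:
        background = matrix
    missing = module.members - set(matrix.gene_ids)
    if missing:
        raise KeyError(f"module genes absent from annotation: {sorted(missing)[:5]}")
    sub = matrix.subset_genes(module.members, reindex_terms=True)
    n = sub.n_genes
    N = background.n_genes
    bg_counts = background.term_gene_counts()
    records: list[TermRecord] = []
    for term, k in sub.term_gene_counts().items():
        if k < min_overlap:
            continue
        K = int(bg_counts.get(term, 0))
        # a query term absent from the background universe: count at least
        # the observed module genes so the table stays consistent
        K = max(K, k)
        records.append(
            TermRecord(term, int(k), n, K, N, hypergeom_p(int(k), n, K, N, ease=ease))
        )
    if not records:
        raise ValueError(f"module {module.module_id} has no annotated terms")
    score = score_from_pvalues([r.p_value for r in records])
    return EnrichmentResult(
        module_id=module.module_id,
        terms=tuple(records),
        enrichment_score=score,
        significant=score >= sig_threshold,
        sig_threshold=sig_threshold,
    )
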