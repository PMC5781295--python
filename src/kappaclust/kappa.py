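"""Pairwise Cohen's kappa between binary gene annotation profiles.

For two genes with 0/1 term profiles over a universe of T terms, the 2x2
contingency table counts

    a = terms annotated to both genes
    b = terms annotated to the first only
    c = terms annotated to the second only
    d = terms annotated to neither

Observed agreement O = (a + d) / T, chance agreement
E = ((a+b)(a+c) + (c+d)(b+d)) / T^2, and kappa = (O - E) / (1 - E).
Kappa is 1 for identical profiles, near 0 for chance-level co-annotation,
and negative for systematic disagreement.

The contingency counts are exact integers; only the final ratio is floating
point, so the matrix is bit-reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation_io import AnnotationMatrix

__all__ = ["KappaMatrix", "kappa_pair", "kappa_matrix", "neighbors_at", "write_kappa_pairs"]


class DegenerateProfileError(ValueError):
    """A profile with 0 or T set terms reached a kappa computation."""


def kappa_pair(profile_a: np.ndarray, profile_b: np.ndarray, T: int | None = None) -> float:
    """Cohen's kappa for one gene pair.

    Parameters
    ----------
    profile_a, profile_b
        0/1 term vectors of equal length.
    T
        Term-universe size; defaults to the profile length.

    Raises
    ------
    DegenerateProfileError
        If either profile is all-0 or all-1 (chance agreement is then 1 and
        kappa undefined); such genes are excluded during input validation,
        so reaching this error indicates a contract violation upstream.
    """
    pa = np.asarray(profile_a, dtype=np.int64)
    pb = np.asarray(profile_b, dtype=np.int64)
    if pa.shape != pb.shape:
        raise ValueError("profiles differ in length")
    if T is None:
        T = pa.size
    elif T != pa.size:
        raise ValueError(f"T={T} does not match profile length {pa.size}")
    a = int(np.sum(pa & pb))
    na, nb = int(pa.sum()), int(pb.sum())
    if na in (0, T) or nb in (0, T):
        raise DegenerateProfileError("degenerate (all-0 or all-1) annotation profile")
    b = na - a
    c = nb - a
    d = T - a - b - c
    # exact rational arithmetic for O, E; float only at the end
    O = Fraction(a + d, T)
    E = Fraction((a + b) * (a + c) + (c + d) * (b + d), T * T)
    return float((O - E) / (1 - E))


@dataclass(frozen=True)
class KappaMatrix:
    """Symmetric gene×gene kappa scores aligned with an :class:`AnnotationMatrix`."""

    gene_ids: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=np.float64)
        n = len(self.gene_ids)
        if s.shape != (n, n):
            raise ValueError(f"scores shape {s.shape} != ({n}, {n})")
        object.__setattr__(self, "scores", s)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self._lookup[gene_id]
        except AttributeError:
            lookup = {g: i for i, g in enumerate(self.gene_ids)}
            object.__setattr__(self, "_lookup", lookup)
            return lookup[gene_id]

    def value(self, gene_a: str, gene_b: str) -> float:
        return float(self.scores[self.gene_index(gene_a), self.gene_index(gene_b)])

    def neighbors_at(self, gene: str, t: float) -> set[str]:
        """Genes h != gene with kappa(gene, h) >= t."""
        i = self.gene_index(gene)
        hits = np.flatnonzero(self.scores[i] >= t)
        return {self.gene_ids[j] for j in hits if j != i}

    def qualifying_pair_count(self, t: float) -> int:
        """Number of unordered gene pairs with kappa >= t."""
        iu = np.triu_indices(self.n_genes, k=1)
        return int(np.count_nonzero(self.scores[iu] >= t))


def kappa_matrix(matrix: AnnotationMatrix) -> KappaMatrix:
    """All-pairs kappa from a validated annotation matrix.

    Vectorised: the four contingency counts for every pair come from one
    integer Gram matrix ``inc @ inc.T`` and the per-gene term counts, then
    kappa is evaluated in double precision.  Equivalent to calling
    :func:`kappa_pair` on every pair (tested against that double loop).
    """
    if matrix.n_genes < 2:
        raise ValueError("kappa matrix needs at least 2 genes")
    inc = matrix.incidence.astype(np.int64)
    T = matrix.term_universe_size
    counts = inc.sum(axis=1)
    if np.any(counts == 0) or np.any(counts == T):
        raise DegenerateProfileError("degenerate profiles present; validate input first")
    a = inc @ inc.T  # co-annotated terms per pair
    na = counts[:, None]
    nb = counts[None, :]
    d = T - na - nb + a
    # O and E as exact integer numerators over T and T^2
    O_num = (a + d).astype(np.float64)
    E_num = (na * nb + (T - nb) * (T - na)).astype(np.float64)
    denom = T * T - E_num  # T^2 * (1 - E)
    scores = (T * O_num - E_num) / denom
    np.fill_diagonal(scores, 1.0)
    return KappaMatrix(matrix.gene_ids, scores)


def neighbors_at(kmat: KappaMatrix, gene: str, t: float) -> set[str]:
    """Functional neighbours of ``gene`` at kappa threshold ``t``."""
    return kmat.neighbors_at(gene, t)


def write_kappa_pairs(kmat: KappaMatrix, path: str | Path, floor: float = 0.0) -> None:
    """Audit export: TSV of (gene_a, gene_b, kappa) for pairs with kappa >= floor."""
    iu, ju = np.triu_indices(kmat.n_genes, k=1)
    sel = kmat.scores[iu, ju] >= floor
    df = pd.DataFrame(
        {
            "gene_a": [kmat.gene_ids[i] for i in iu[sel]],
            "gene_b": [kmat.gene_ids[j] for j in ju[sel]],
            "kappa": kmat.scores[iu[sel], ju[sel]],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
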