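"""Parsing of gene→annotation-term mappings into binary incidence matrices.

The central object is :class:`AnnotationMatrix`, a validated gene×term 0/1
incidence structure over an opaque term universe.  Annotation terms are
treated as flat labels (no ontology traversal): a "flat matrix" of custom
identifiers is the whole input contract, which is what makes the toolkit
species-agnostic.

Three dialects are read:

``tsv2col``
    Two tab-separated columns ``gene_id<TAB>term_id``; ``#`` comments; an
    optional header is auto-detected.
``gaf``
    GAF 2.x gene association files; columns 2 (DB Object ID) and 5 (GO ID)
    are consumed, ``!`` comment lines skipped.
``blast2go``
    First column gene id, second column a semicolon- or comma-separated
    list of GO ids.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Format = Literal["tsv2col", "gaf", "blast2go"]

__all__ = [
    "AnnotationMatrix",
    "BackgroundAnnotation",
    "ExclusionReport",
    "read_flat_annotation",
    "annotation_from_pairs",
    "validate_profiles",
    "write_flat_annotation",
]


class AnnotationError(ValueError):
    """Raised for empty or malformed annotation input."""


@dataclass(frozen=True)
class ExclusionReport:
    """Genes dropped during validation, with the rule that removed each."""

    excluded: tuple[tuple[str, str], ...] = ()  # (gene_id, reason)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.excluded)

    def genes(self) -> list[str]:
        return [g for g, _ in self.excluded]


@dataclass(frozen=True)
class AnnotationMatrix:
    """Binary gene×term incidence for a gene list.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, lexicographically sorted.
    term_ids
        Unique term identifiers, lexicographically sorted.
    incidence
        ``(n_genes, n_terms)`` uint8 array of 0/1 memberships.
    term_category
        Optional mapping term_id → category label (e.g. a GO namespace);
        carried through untouched, used only by :meth:`filter_category`.
    """

    gene_ids: tuple[str, ...]
    term_ids: tuple[str, ...]
    incidence: np.ndarray
    term_category: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        inc = np.asarray(self.incidence, dtype=np.uint8)
        if inc.shape != (len(self.gene_ids), len(self.term_ids)):
            raise AnnotationError(
                f"incidence shape {inc.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.term_ids)} terms"
            )
        if not np.isin(inc, (0, 1)).all():
            raise AnnotationError("incidence must be strictly 0/1")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise AnnotationError("duplicate gene ids")
        if len(set(self.term_ids)) != len(self.term_ids):
            raise AnnotationError("duplicate term ids")
        object.__setattr__(self, "incidence", inc)

    # -- basic queries -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_terms(self) -> int:
        return len(self.term_ids)

    @property
    def term_universe_size(self) -> int:
        """T, the kappa contingency-table denominator."""
        return len(self.term_ids)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self._gene_lookup[gene_id]
        except AttributeError:
            lookup = {g: i for i, g in enumerate(self.gene_ids)}
            object.__setattr__(self, "_gene_lookup", lookup)
            return lookup[gene_id]

    def profile(self, gene_id: str) -> np.ndarray:
        """0/1 term vector of one gene."""
        return self.incidence[self.gene_index(gene_id)]

    def terms_of(self, gene_id: str) -> set[str]:
        row = self.profile(gene_id)
        return {self.term_ids[j] for j in np.flatnonzero(row)}

    def term_gene_counts(self) -> pd.Series:
        """Number of genes carrying each term."""
        return pd.Series(
            self.incidence.sum(axis=0).astype(int), index=list(self.term_ids)
        )

    # -- derived matrices ----------------------------------------------
    def subset_genes(self, genes: Iterable[str], *, reindex_terms: bool = True) -> "AnnotationMatrix":
        """Restrict to ``genes``; optionally drop now-empty term columns.

        With ``reindex_terms`` the term universe is recomputed over the
        subset, which is the behaviour sub-clustering requires.
        """
        keep = sorted(set(genes))
        missing = set(keep) - set(self.gene_ids)
        if missing:
            raise KeyError(f"unknown genes: {sorted(missing)[:5]}")
        rows = [self.gene_index(g) for g in keep]
        inc = self.incidence[rows]
        terms = list(self.term_ids)
        if reindex_terms:
            nz = np.flatnonzero(inc.sum(axis=0) > 0)
            inc = inc[:, nz]
            terms = [self.term_ids[j] for j in nz]
        cat = {t: c for t, c in self.term_category.items() if t in set(terms)}
        return AnnotationMatrix(tuple(keep), tuple(terms), inc, cat)

    def filter_category(self, category: str) -> "AnnotationMatrix":
        """Keep only terms of one annotation category (e.g. one GO namespace)."""
        terms = [t for t in self.term_ids if self.term_category.get(t) == category]
        if not terms:
            raise AnnotationError(f"no terms in category {category!r}")
        cols = [self.term_ids.index(t) for t in terms]
        return AnnotationMatrix(
            self.gene_ids,
            tuple(terms),
            self.incidence[:, cols],
            {t: category for t in terms},
        )

    def to_pairs(self) -> pd.DataFrame:
        """Tidy (gene_id, term_id) long form of the incidence."""
        gi, tj = np.nonzero(self.incidence)
        return pd.DataFrame(
            {
                "gene_id": [self.gene_ids[i] for i in gi],
                "term_id": [self.term_ids[j] for j in tj],
            }
        )


class BackgroundAnnotation(AnnotationMatrix):
    """Annotation of the reference gene universe used by the hypergeometric test.

    Structurally identical to :class:`AnnotationMatrix`; the distinct type
    documents intent and lets enrichment validate that the background covers
    the query gene list.
    """

    def covers(self, matrix: AnnotationMatrix) -> bool:
        return set(matrix.gene_ids) <= set(self.gene_ids)


# ---------------------------------------------------------------------------
# parsing


def _parse_tsv2col(path: Path) -> list[tuple[str, str]]:
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        first_data = True
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 2 tab-separated columns"
                )
            gene, term = fields[0].strip(), fields[1].strip()
            if first_data:
                first_data = False
                # header auto-detection on the second field
                low = term.lower()
                if any(k in low for k in ("term", "go", "annotation")) and not _looks_like_id(term):
                    continue
            if gene and term:
                pairs.append((gene, term))
    return pairs


def _looks_like_id(token: str) -> bool:
    # a GO-style id ("GO:0008150") is data even though it contains "go"
    return ":" in token or token[:1].isdigit()


def _parse_gaf(path: Path) -> list[tuple[str, str]]:
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise AnnotationError(
                    f"{path}:{lineno}: malformed GAF record (needs >=5 columns, got {len(fields)})"
                )
            gene, go_id = fields[1].strip(), fields[4].strip()
            if not gene or not go_id:
                raise AnnotationError(
                    f"{path}:{lineno}: malformed GAF record (empty object id or GO id)"
                )
            pairs.append((gene, go_id))
    return pairs


def _parse_blast2go(path: Path) -> list[tuple[str, str]]:
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise AnnotationError(
                    f"{path}:{lineno}: expected gene<TAB>GO-list"
                )
            gene = fields[0].strip()
            for term in fields[1].replace(",", ";").split(";"):
                term = term.strip()
                if term:
                    pairs.append((gene, term))
    return pairs


_PARSERS = {"tsv2col": _parse_tsv2col, "gaf": _parse_gaf, "blast2go": _parse_blast2go}


def annotation_from_pairs(
    pairs: Iterable[tuple[str, str]],
    term_category: dict[str, str] | None = None,
    *,
    validate: bool = True,
    cls: type = AnnotationMatrix,
) -> AnnotationMatrix:
    """Build a canonical (sorted, deduplicated) incidence from (gene, term) pairs."""
    pairs = list(pairs)
    if not pairs:
        raise AnnotationError("zero valid (gene, term) pairs")
    df = pd.DataFrame(pairs, columns=["gene_id", "term_id"]).drop_duplicates()
    genes = tuple(sorted(df["gene_id"].unique()))
    terms = tuple(sorted(df["term_id"].unique()))
    gi = {g: i for i, g in enumerate(genes)}
    tj = {t: j for j, t in enumerate(terms)}
    inc = np.zeros((len(genes), len(terms)), dtype=np.uint8)
    inc[df["gene_id"].map(gi), df["term_id"].map(tj)] = 1
    mat = cls(genes, terms, inc, term_category or {})
    if validate:
        mat, report = validate_profiles(mat)
        if report.excluded:
            logger.warning(
                "excluded %d gene(s) with degenerate annotation profiles: %s",
                len(report.excluded),
                report.excluded[:10],
            )
    return mat


def read_flat_annotation(
    path: str | Path,
    format: Format = "tsv2col",
    *,
    validate: bool = True,
    background: bool = False,
) -> AnnotationMatrix:
    """Parse an annotation file into a validated :class:`AnnotationMatrix`.

    Repeated (gene, term) rows collapse to a single incidence of 1.  Genes
    with degenerate profiles (no terms, or every term in the universe) are
    dropped with a warning; see :func:`validate_profiles`.

    Parameters
    ----------
    path
        Input file.
    format
        One of ``tsv2col``, ``gaf``, ``blast2go``.
    validate
        Apply degenerate-profile exclusion (default).
    background
        Return a :class:`BackgroundAnnotation` instead.
    """
    path = Path(path)
    if format not in _PARSERS:
        raise AnnotationError(f"unknown format {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    pairs = _PARSERS[format](path)
    cls = BackgroundAnnotation if background else AnnotationMatrix
    return annotation_from_pairs(pairs, validate=validate, cls=cls)


def validate_profiles(matrix: AnnotationMatrix) -> tuple[AnnotationMatrix, ExclusionReport]:
    """Drop genes annotated to zero terms or to the full term universe.

    Both profiles make the pairwise kappa contingency table degenerate
    (chance agreement 1, kappa undefined), so they are excluded up front
    rather than special-cased downstream.
    """
    counts = matrix.incidence.sum(axis=1)
    T = matrix.n_terms
    excluded: list[tuple[str, str]] = []
    keep: list[int] = []
    for i, g in enumerate(matrix.gene_ids):
        if counts[i] == 0:
            excluded.append((g, "empty profile"))
        elif counts[i] == T:
            excluded.append((g, "full profile"))
        else:
            keep.append(i)
    if not keep:
        raise AnnotationError("all genes excluded by profile validation")
    if not excluded:
        return matrix, ExclusionReport()
    genes = tuple(matrix.gene_ids[i] for i in keep)
    kept = matrix.__class__(genes, matrix.term_ids, matrix.incidence[keep], matrix.term_category)
    for g, reason in excluded:
        warnings.warn(f"gene {g!r} excluded: {reason}", stacklevel=2)
    return kept, ExclusionReport(tuple(excluded))


def write_flat_annotation(matrix: AnnotationMatrix, path: str | Path) -> None:
    """Write tsv2col (``gene_id<TAB>term_id``) that round-trips exactly."""
    matrix.to_pairs().to_csv(path, sep="\t", header=False, index=False)
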