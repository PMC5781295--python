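"""Fuzzy heuristic multiple-linkage partitioning of a kappa matrix.

The agglomeration follows DAVID's gene functional classification heuristic:

1. *Seeding.*  Every gene nominates a candidate group consisting of itself
   plus all genes whose kappa with it meets the threshold.  The candidate
   qualifies as a seed if it is large enough (``initial_group_membership``)
   and a majority of its internal gene pairs (``membership_fraction``) also
   meet the kappa threshold — i.e. the neighbourhood is itself tight, not a
   hub with unrelated spokes.
2. *Merging.*  Seeds sharing a majority of members (``linkage_fraction``
   of the smaller group, by default) merge iteratively into their union
   until no pair of groups qualifies.  A gene may sit in several surviving
   groups: the clustering is soft, reflecting multi-function genes.
3. *Filtering.*  Groups below ``final_group_membership`` are dropped; the
   survivors become numbered modules (largest first), and genes in no
   module are reported as unclustered.

Merging scans group pairs in a fixed order and restarts after every merge,
which makes the whole procedure deterministic for a given input — the
heuristic's agglomeration order is inherently ambiguous, so determinism is
the contract here, not order-optimality.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal

import numpy as np

from .annotation_io import AnnotationMatrix, validate_profiles
from .kappa import KappaMatrix, kappa_matrix

__all__ = [
    "ClusteringParams",
    "Module",
    "ClusteringResult",
    "find_seeds",
    "merge_seeds",
    "cluster",
    "subcluster",
]

LinkageDenominator = Literal["min", "max", "union"]


@dataclass(frozen=True)
class ClusteringParams:
    """Stringency knobs of the fuzzy clustering heuristic.

    Defaults mirror the published DAVID classification defaults: groups of
    at least 4 genes, majority (0.5) membership and linkage fractions.
    ``kappa_threshold`` is the dominant control and the one worth sweeping.

    ``linkage_denominator`` sets what the shared-member fraction is taken
    over when two groups are compared for merging: the smaller group
    (``min``), the larger (``max``), or their union (``union``, default).
    The union denominator lets small tight modules survive inside a large
    diffuse one — the regime where a giant low-kappa module coexists with
    many overlapping sub-modules — whereas ``min`` absorbs any nested
    group outright.
    """

    kappa_threshold: float = 0.35
    initial_group_membership: int = 4
    membership_fraction: float = 0.5
    linkage_fraction: float = 0.5
    final_group_membership: int = 4
    linkage_denominator: LinkageDenominator = "union"

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa_threshold <= 1.0:
            raise ValueError("kappa_threshold must be in [0, 1]")
        for name in ("membership_fraction", "linkage_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")
        for name in ("initial_group_membership", "final_group_membership"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if self.linkage_denominator not in ("min", "max", "union"):
            raise ValueError("linkage_denominator must be min, max or union")

    def with_kappa(self, kappa_threshold: float) -> "ClusteringParams":
        return replace(self, kappa_threshold=kappa_threshold)


@dataclass(frozen=True)
class Module:
    """One soft cluster: a named set of genes with provenance."""

    module_id: int
    members: frozenset[str]
    origin: Literal["seed", "merged", "submodule"]
    parent_kappa: float
    lineage: int | None = None  # parent module id when origin == "submodule"

    @property
    def size(self) -> int:
        return len(self.members)

    def sorted_members(self) -> list[str]:
        return sorted(self.members)


@dataclass(frozen=True)
class ClusteringResult:
    """Modules plus the unclustered complement for one parameter setting."""

    modules: tuple[Module, ...]
    unclustered: frozenset[str]
    params: ClusteringParams
    gene_ids: tuple[str, ...]

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    @property
    def clustered_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for m in self.modules:
            out |= m.members
        return frozenset(out)

    def membership_counts(self) -> dict[str, int]:
        """gene → number of modules containing it (clustered genes only)."""
        counts: dict[str, int] = {}
        for m in self.modules:
            for g in m.members:
                counts[g] = counts.get(g, 0) + 1
        return counts

    def module(self, module_id: int) -> Module:
        for m in self.modules:
            if m.module_id == module_id:
                return m
        raise KeyError(f"no module with id {module_id}")


# ---------------------------------------------------------------------------
# seeding


def _qualifying_pair_fraction(group: Iterable[str], kmat: KappaMatrix, t: float) -> float:
    idx = np.array([kmat.gene_index(g) for g in group])
    n = idx.size
    qualifying = kmat.scores[np.ix_(idx, idx)] >= t
    good = (int(qualifying.sum()) - n) // 2  # drop diagonal, halve symmetry
    return good / (n * (n - 1) // 2)


def find_seeds(kmat: KappaMatrix, params: ClusteringParams) -> list[frozenset[str]]:
    """Candidate seed groups: each gene plus its kappa-thresholded neighbours.

    A candidate is emitted iff it has at least ``initial_group_membership``
    members and strictly more than ``membership_fraction`` of its internal
    unordered pairs have kappa >= the threshold.  Identical member sets are
    collapsed; the returned order is deterministic (by sorted member tuple).
    """
    t = params.kappa_threshold
    qualifying = kmat.scores >= t
    np.fill_diagonal(qualifying, False)
    seen: set[frozenset[int]] = set()
    seeds: set[frozenset[str]] = set()
    for i in range(kmat.n_genes):
        idx = np.flatnonzero(qualifying[i])
        n = idx.size + 1
        if n < params.initial_group_membership:
            continue
        cand = frozenset(idx) | {i}
        if cand in seen:
            continue
        seen.add(cand)
        rows = np.fromiter(cand, dtype=np.int64)
        good = int(qualifying[np.ix_(rows, rows)].sum()) // 2
        total = n * (n - 1) // 2
        if good / total > params.membership_fraction:
            seeds.add(frozenset(kmat.gene_ids[j] for j in cand))
    return sorted(seeds, key=lambda s: tuple(sorted(s)))


# ---------------------------------------------------------------------------
# merging


def _sharing_fraction(a: frozenset[str], b: frozenset[str], denominator: LinkageDenominator) -> float:
    shared = len(a & b)
    if denominator == "min":
        denom = min(len(a), len(b))
    elif denominator == "max":
        denom = max(len(a), len(b))
    else:
        denom = len(a | b)
    return shared / denom


def merge_seeds(seeds: Iterable[frozenset[str]], params: ClusteringParams) -> list[Module]:
    """Iteratively merge groups sharing a majority of members.

    Scans ordered group pairs; the first pair whose sharing fraction meets
    ``linkage_fraction`` is replaced by its union (at the first group's
    position), duplicates of the union are collapsed, and the scan
    restarts.  Terminates when no pair qualifies (each merge reduces the
    group count by one).  Groups smaller than ``final_group_membership``
    are then dropped and survivors numbered by descending size, ties
    broken by the lexicographically smallest member.

    Internally groups are kept as bit rows over the participating genes so
    that all pairwise intersection counts come from one integer matrix
    product, updated incrementally after each merge.
    """
    unique = list(dict.fromkeys(frozenset(s) for s in seeds))
    if not unique:
        return []
    gene_list = sorted(set().union(*unique))
    gidx = {g: i for i, g in enumerate(gene_list)}
    M = np.zeros((len(unique), len(gene_list)), dtype=np.float32)
    for r, s in enumerate(unique):
        M[r, [gidx[g] for g in s]] = 1.0
    merged_flag = [False] * len(unique)

    inter = M @ M.T  # pairwise intersection counts; diagonal = sizes
    thr = params.linkage_fraction
    denom_kind = params.linkage_denominator
    while True:
        sizes = np.diag(inter)
        si = sizes[:, None]
        sj = sizes[None, :]
        if denom_kind == "min":
            denom = np.minimum(si, sj)
        elif denom_kind == "max":
            denom = np.maximum(si, sj)
        else:
            denom = si + sj - inter
        qualifies = inter >= thr * denom
        qualifies[np.tril_indices_from(qualifies)] = False
        hits = np.argwhere(qualifies)
        if hits.size == 0:
            break
        i, j = map(int, hits[0])  # argwhere is row-major: first scan order
        M[i] = np.maximum(M[i], M[j])
        merged_flag[i] = True
        # union's intersections with every group, then drop j and any
        # group now identical to the union (first occurrence i kept)
        new_row = M @ M[i]
        inter[i, :] = new_row
        inter[:, i] = new_row
        size_i = inter[i, i]
        dup = np.flatnonzero((inter[i] == size_i) & (np.diag(inter) == size_i))
        drop = sorted(set(dup[dup != i].tolist()) | {j})
        keep = [r for r in range(M.shape[0]) if r not in drop]
        M = M[keep]
        inter = inter[np.ix_(keep, keep)]
        merged_flag = [merged_flag[r] for r in keep]

    survivors = []
    for r in range(M.shape[0]):
        members = frozenset(gene_list[c] for c in np.flatnonzero(M[r]))
        if len(members) >= params.final_group_membership:
            survivors.append((members, merged_flag[r]))
    survivors.sort(key=lambda gm: (-len(gm[0]), min(gm[0])))
    return [
        Module(
            module_id=k + 1,
            members=g,
            origin="merged" if was_merged else "seed",
            parent_kappa=params.kappa_threshold,
        )
        for k, (g, was_merged) in enumerate(survivors)
    ]


# ---------------------------------------------------------------------------
# top-level


def cluster(
    matrix: AnnotationMatrix,
    params: ClusteringParams | None = None,
    *,
    kmat: KappaMatrix | None = None,
) -> ClusteringResult:
    """Full pass: kappa matrix → seeds → merged soft modules.

    ``kmat`` may be supplied to reuse a precomputed kappa matrix (the sweep
    engine does this; kappa scores do not depend on the threshold).
    """
    params = params or ClusteringParams()
    if kmat is None:
        kmat = kappa_matrix(matrix)
    seeds = find_seeds(kmat, params)
    modules = merge_seeds(seeds, params)
    clustered: set[str] = set()
    for m in modules:
        clustered |= m.members
    unclustered = frozenset(set(matrix.gene_ids) - clustered)
    return ClusteringResult(tuple(modules), unclustered, params, matrix.gene_ids)


def subcluster(
    result: ClusteringResult,
    module_id: int,
    matrix: AnnotationMatrix,
    higher_params: ClusteringParams,
) -> ClusteringResult:
    """Re-cluster one module's members at a stricter kappa threshold.

    Large, weakly enriched modules that appear at low thresholds can hide
    finer functional structure; re-running the partition on just their
    members at a higher kappa exposes enrichable sub-modules.  The term
    universe is recomputed over the module's members, and the resulting
    sub-modules carry ``lineage`` back to the parent.
    """
    parent = result.module(module_id)
    if higher_params.kappa_threshold <= result.params.kappa_threshold:
        raise ValueError(
            "sub-clustering requires a kappa threshold above the parent's "
            f"({higher_params.kappa_threshold} <= {result.params.kappa_threshold})"
        )
    sub_matrix = matrix.subset_genes(parent.members)
    if len({r.tobytes() for r in sub_matrix.incidence}) == 1:
        # identical annotation profiles are inseparable at any threshold
        one = Module(1, parent.members, "submodule", higher_params.kappa_threshold, module_id)
        return ClusteringResult((one,), frozenset(), higher_params, sub_matrix.gene_ids)
    # reindexing the term universe to the module can create full profiles
    sub_matrix, _ = validate_profiles(sub_matrix)
    sub = cluster(sub_matrix, higher_params)
    modules = tuple(
        Module(
            module_id=m.module_id,
            members=m.members,
            origin="submodule",
            parent_kappa=higher_params.kappa_threshold,
            lineage=module_id,
        )
        for m in sub.modules
    )
    return ClusteringResult(modules, sub.unclustered, higher_params, sub_matrix.gene_ids)
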