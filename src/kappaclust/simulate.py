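"""Synthetic annotation matrices with planted functional groups.

Real inputs to functional classification are differentially-expressed gene
lists annotated with GO-like terms.  The generator emulates their essential
structure:

* *tight groups* — each defined by a disjoint block of terms its member
  genes carry with probability ``p_within`` (optionally per group: real
  functional families vary widely in annotation coherence, and the spread
  of coherence is what makes modules fragment progressively as the kappa
  threshold rises rather than all at once);
* *multi-function genes* — ``overlap_genes`` members assigned to two
  groups, carrying both term blocks;
* *diffuse glue* — an optional block of broad, weakly-held terms spread
  over a random subset of genes, modelling high-level ontology terms
  (signalling, metabolism, binding) that co-annotate otherwise unrelated
  genes.  The glue is what fuses everything into one giant module at low
  kappa thresholds while tight groups persist as overlapping sub-modules
  inside it, and it dissolves as the threshold rises;
* *background noise* — i.i.d. per-(gene, term) annotation with probability
  ``p_noise``.

The model is a deliberately stylised planted-partition stand-in: it does
not model GO DAG structure, term-frequency skew beyond the two annotation
scales, or any upstream RNA-seq step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation_io import AnnotationMatrix, annotation_from_pairs

__all__ = [
    "FixtureSpec",
    "DiffuseGlue",
    "GroundTruth",
    "generate",
    "paper_scale_specs",
    "two_block_spec",
    "nested_block_matrix",
]


@dataclass(frozen=True)
class DiffuseGlue:
    """Broad-term annotation layer shared across groups.

    ``n_terms`` diffuse terms are carried, each with probability
    ``density``, by a random sample of genes: a fraction
    ``group_gene_fraction`` of the tight-group genes plus
    ``n_background_genes`` genes from outside any group.
    """

    n_terms: int = 80
    density: float = 0.3
    group_gene_fraction: float = 0.6
    n_background_genes: int = 30

    def __post_init__(self) -> None:
        if not 0.0 <= self.density <= 1.0:
            raise ValueError("density must be in [0, 1]")
        if not 0.0 <= self.group_gene_fraction <= 1.0:
            raise ValueError("group_gene_fraction must be in [0, 1]")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic annotation matrix.

    Parameters
    ----------
    n_genes
        Total genes, group members plus background.
    n_terms
        Total terms: group blocks, then free noise vocabulary, with the
        diffuse-glue block (if any) at the end.
    groups
        One ``(member_count, term_block_size)`` or
        ``(member_count, term_block_size, p_within)`` tuple per planted
        group; a missing third element falls back to the global
        ``p_within``.
    overlap_genes
        Genes assigned to two groups (consecutive group pairs round-robin,
        drawn deterministically from the source group), modelling
        multi-function genes.
    p_within
        Default probability a group gene carries each of its group terms.
    p_noise
        Probability any gene carries any term, independently.
    diffuse
        Optional :class:`DiffuseGlue` layer.
    seed
        RNG seed; generation is fully reproducible.
    """

    n_genes: int = 200
    n_terms: int = 120
    groups: tuple[tuple, ...] = ((40, 15), (40, 15), (40, 15))
    overlap_genes: int = 4
    p_within: float = 0.9
    p_noise: float = 0.02
    diffuse: DiffuseGlue | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        norm = []
        for g in self.groups:
            if len(g) == 2:
                norm.append((int(g[0]), int(g[1]), float(self.p_within)))
            elif len(g) == 3:
                norm.append((int(g[0]), int(g[1]), float(g[2])))
            else:
                raise ValueError("each group must be (members, terms[, p_within])")
        object.__setattr__(self, "groups", tuple(norm))
        if sum(g for g, _, _ in self.groups) > self.n_genes:
            raise ValueError("more group genes than n_genes")
        diffuse_terms = self.diffuse.n_terms if self.diffuse else 0
        if sum(t for _, t, _ in self.groups) + diffuse_terms > self.n_terms:
            raise ValueError("group + diffuse term blocks exceed n_terms")
        if self.overlap_genes and len(self.groups) < 2:
            raise ValueError("overlap_genes requires at least 2 groups")
        for name in ("p_within", "p_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for _, _, p in self.groups:
            if not 0.0 <= p <= 1.0:
                raise ValueError("per-group p_within must be in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """Planted membership: gene id → tuple of group indices (0-based).

    Background genes map to an empty tuple.  ``group_members`` lists each
    group's genes including the dual-membership overlap genes;
    ``diffuse_members`` the genes carrying the glue layer.
    """

    labels: dict[str, tuple[int, ...]]
    group_members: tuple[frozenset[str], ...] = field(default_factory=tuple)
    diffuse_members: frozenset[str] = frozenset()

    def hard_labels(self) -> dict[str, int]:
        """First planted group per gene; background genes get -1."""
        return {g: (grps[0] if grps else -1) for g, grps in self.labels.items()}


def _gene_name(i: int, width: int) -> str:
    return f"g{i:0{width}d}"


def generate(spec: FixtureSpec) -> tuple[AnnotationMatrix, GroundTruth]:
    """Draw one annotation matrix and its planted ground truth.

    Genes that end up with empty or full profiles are excluded by the
    standard validation (their ground-truth entries remain, keyed by name).
    """
    rng = np.random.default_rng(spec.seed)
    gw = len(str(max(spec.n_genes - 1, 1)))
    tw = len(str(max(spec.n_terms - 1, 1)))
    genes = [_gene_name(i, gw) for i in range(spec.n_genes)]
    inc = np.zeros((spec.n_genes, spec.n_terms), dtype=np.uint8)

    # carve disjoint term blocks and contiguous gene blocks per group
    labels: dict[str, list[int]] = {g: [] for g in genes}
    term_start = 0
    gene_start = 0
    blocks: list[tuple[list[int], slice, float]] = []
    for gi, (g_count, t_count, p) in enumerate(spec.groups):
        rows = list(range(gene_start, gene_start + g_count))
        tsl = slice(term_start, term_start + t_count)
        blocks.append((rows, tsl, p))
        for r in rows:
            labels[genes[r]].append(gi)
        gene_start += g_count
        term_start += t_count

    # dual-membership genes: borrow members of group i into group (i+1) mod k
    k = len(spec.groups)
    for o in range(spec.overlap_genes):
        src = o % k
        dst = (src + 1) % k
        row = blocks[src][0][o // k]  # deterministic pick inside the source block
        if dst not in labels[genes[row]]:
            labels[genes[row]].append(dst)

    # within-group annotations (carriers include borrowed overlap genes)
    for gi, (_rows, tsl, p) in enumerate(blocks):
        carriers = [r for r in range(spec.n_genes) if gi in labels[genes[r]]]
        block = rng.random((len(carriers), tsl.stop - tsl.start)) < p
        inc[np.ix_(carriers, range(tsl.start, tsl.stop))] |= block.astype(np.uint8)

    # diffuse glue over a random gene subset, occupying the last terms
    diffuse_rows: np.ndarray = np.array([], dtype=np.int64)
    if spec.diffuse is not None:
        d = spec.diffuse
        group_rows = np.array([r for r in range(gene_start)], dtype=np.int64)
        bg_rows = np.array([r for r in range(gene_start, spec.n_genes)], dtype=np.int64)
        n_from_groups = int(round(d.group_gene_fraction * group_rows.size))
        picks = [rng.choice(group_rows, size=n_from_groups, replace=False)] if n_from_groups else []
        n_bg = min(d.n_background_genes, bg_rows.size)
        if n_bg:
            picks.append(rng.choice(bg_rows, size=n_bg, replace=False))
        diffuse_rows = np.sort(np.concatenate(picks)) if picks else diffuse_rows
        cols = range(spec.n_terms - d.n_terms, spec.n_terms)
        layer = rng.random((diffuse_rows.size, d.n_terms)) < d.density
        inc[np.ix_(diffuse_rows, cols)] |= layer.astype(np.uint8)

    # background noise over the whole matrix
    if spec.p_noise > 0:
        inc |= (rng.random(inc.shape) < spec.p_noise).astype(np.uint8)

    pairs = [(genes[i], f"t{j:0{tw}d}") for i, j in zip(*np.nonzero(inc))]
    matrix = annotation_from_pairs(pairs, validate=True)
    truth = GroundTruth(
        labels={g: tuple(v) for g, v in labels.items()},
        group_members=tuple(
            frozenset(g for g, v in labels.items() if gi in v) for gi in range(k)
        ),
        diffuse_members=frozenset(genes[i] for i in diffuse_rows),
    )
    return matrix, truth


def two_block_spec(seed: int = 0, *, overlap_genes: int = 0) -> FixtureSpec:
    """Small noise-free two-group fixture: blocks are exactly recoverable."""
    return FixtureSpec(
        n_genes=20,
        n_terms=16,
        groups=((10, 8), (10, 8)),
        overlap_genes=overlap_genes,
        p_within=1.0,
        p_noise=0.0,
        seed=seed,
    )


def nested_block_matrix(
    *,
    sub_size: int = 10,
    sub_terms: int = 10,
    shared_terms: int = 6,
    outgroup_size: int = 10,
    outgroup_terms: int = 16,
) -> tuple[AnnotationMatrix, tuple[frozenset[str], frozenset[str]]]:
    """Deterministic fixture with two sub-blocks nested inside one module.

    Sub-blocks A and B each carry ``sub_terms`` terms, ``shared_terms`` of
    them in common, plus a disjoint out-group C over its own terms.  With
    the defaults the A-B kappa is exactly 0.4: at a moderate threshold
    (e.g. 0.35) A and B fuse into one large module, and re-clustering that
    module at a stricter threshold (e.g. 0.6) — where the recomputed term
    universe drops C's terms and the A-B kappa turns negative — splits it
    back into A and B.  Returns the matrix and the (A, B) member sets.
    """
    if shared_terms >= sub_terms:
        raise ValueError("shared_terms must be below sub_terms")
    pairs: list[tuple[str, str]] = []
    t_a = [f"t{j:03d}" for j in range(sub_terms)]
    t_b = [f"t{j:03d}" for j in range(sub_terms - shared_terms, 2 * sub_terms - shared_terms)]
    t_c = [f"t{j:03d}" for j in range(100, 100 + outgroup_terms)]
    a_genes = frozenset(f"a{i:02d}" for i in range(sub_size))
    b_genes = frozenset(f"b{i:02d}" for i in range(sub_size))
    for g in sorted(a_genes):
        pairs += [(g, t) for t in t_a]
    for g in sorted(b_genes):
        pairs += [(g, t) for t in t_b]
    for i in range(outgroup_size):
        pairs += [(f"c{i:02d}", t) for t in t_c]
    return annotation_from_pairs(pairs, validate=True), (a_genes, b_genes)


def _scaled_groups(sizes: list[int], p_lo: float, p_hi: float) -> tuple[tuple, ...]:
    ps = np.linspace(p_lo, p_hi, len(sizes))
    return tuple((s, max(6, s), float(p)) for s, p in zip(sizes, ps))


def paper_scale_specs() -> dict[int, FixtureSpec]:
    """Presets at the annotated-gene-list sizes of a typical RNA-seq study.

    Three differential-expression comparisons of decreasing depth — 3340,
    1313 and 555 annotated genes — with group counts and term vocabularies
    scaled roughly proportionally — except the diffuse broad-term
    vocabulary, which stays fixed across presets because the broad layer
    of an ontology is a property of the annotation source, not of the
    gene list.  Each preset plants many small groups
    whose coherence spreads from loose (p_within 0.55) to near-perfect
    (0.97), plus a diffuse broad-term glue layer; together these reproduce
    the canonical kappa-sweep dynamics: a giant module hosting overlapping
    sub-modules at low thresholds, progressive fragmentation, then decay.
    """
    sizes_555 = [18, 16, 15, 14, 13, 12, 12, 11, 11, 10, 10, 10, 9, 9, 9,
                 8, 8, 8, 8, 7, 7, 7, 7, 6, 6, 6, 6, 6, 5, 5, 5, 5]
    sizes_1313 = [30, 27, 25, 24, 22, 21, 20, 19, 18, 17, 16, 16, 15, 15, 14,
                  14, 13, 13, 12, 12, 11, 11, 10, 10, 10, 9, 9, 9, 8, 8, 8,
                  8, 7, 7, 7, 7, 6, 6, 6, 6, 5, 5, 5, 5]
    sizes_3340 = [55, 50, 46, 43, 40, 38, 36, 34, 33, 31, 30, 29, 28, 27, 26,
                  25, 24, 24, 23, 22, 21, 21, 20, 20, 19, 18, 18, 17, 17, 16,
                  16, 15, 15, 14, 14, 13, 13, 12, 12, 11, 11, 10, 10, 10, 9,
                  9, 9, 8, 8, 8, 8, 7, 7, 7, 7, 6, 6, 6, 6, 5, 5, 5, 5]
    return {
        555: FixtureSpec(
            n_genes=555,
            n_terms=420,
            groups=_scaled_groups(sizes_555, 0.55, 0.97),
            overlap_genes=0,
            p_noise=0.004,
            diffuse=DiffuseGlue(n_terms=80, density=0.3, group_gene_fraction=0.6,
                                n_background_genes=30),
            seed=555,
        ),
        1313: FixtureSpec(
            n_genes=1313,
            n_terms=800,
            groups=_scaled_groups(sizes_1313, 0.55, 0.97),
            overlap_genes=0,
            p_noise=0.003,
            diffuse=DiffuseGlue(n_terms=80, density=0.3, group_gene_fraction=0.6,
                                n_background_genes=60),
            seed=1313,
        ),
        3340: FixtureSpec(
            n_genes=3340,
            n_terms=1600,
            groups=_scaled_groups(sizes_3340, 0.55, 0.97),
            overlap_genes=0,
            p_noise=0.002,
            diffuse=DiffuseGlue(n_terms=80, density=0.3, group_gene_fraction=0.6,
                                n_background_genes=140),
            seed=3340,
        ),
    }
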