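import numpy as np
import pytest

from kappaclust.annotation_io import AnnotationMatrix, annotation_from_pairs


@pytest.fixture
def toy_pairs():
    """Five genes over six terms with two tight families and one loner."""
    return [
        ("gA", "t1"), ("gA", "t2"), ("gA", "t3"),
        ("gB", "t1"), ("gB", "t2"), ("gB", "t3"),
        ("gC", "t1"), ("gC", "t2"), ("gC", "t4"),
        ("gD", "t5"), ("gD", "t6"),
        ("gE", "t5"), ("gE", "t6"),
    ]


@pytest.fixture
def toy_matrix(toy_pairs):
    return annotation_from_pairs(toy_pairs)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_annotation(rng, n_genes=20, n_terms=15, density=0.3) -> AnnotationMatrix:
    """Random non-degenerate annotation matrix for oracle comparisons."""
    while True:
        inc = (rng.random((n_genes, n_terms)) < density).astype(np.uint8)
        rows = inc.sum(axis=1)
        if np.all((rows > 0) & (rows < n_terms)):
            break
    genes = tuple(f"g{i:03d}" for i in range(n_genes))
    terms = tuple(f"t{j:03d}" for j in range(n_terms))
    return AnnotationMatrix(genes, terms, inc)
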