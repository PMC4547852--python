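import itertools

import numpy as np
import pytest

from epint.data_model import AlterationClass, AlterationMatrix, AlterationMeta


def make_meta(
    alteration_id,
    alteration_class=AlterationClass.MUTATION,
    chromosome=None,
    genes=None,
):
    if chromosome is None and alteration_class.is_cna:
        chromosome = "1"
    return AlterationMeta(
        alteration_id=alteration_id,
        alteration_class=alteration_class,
        chromosome=chromosome,
        genes=frozenset(genes or {alteration_id}),
    )


def make_matrix(incidence, cancer_types=None, classes=None, chromosomes=None):
    """Small AlterationMatrix from a dense 0/1 array."""
    incidence = np.asarray(incidence, dtype=np.uint8)
    n, m = incidence.shape
    cancer_types = cancer_types or ["T"] * n
    classes = classes or [AlterationClass.MUTATION] * m
    chromosomes = chromosomes or [None] * m
    meta = [
        make_meta(f"a{j}", classes[j], chromosomes[j]) for j in range(m)
    ]
    return AlterationMatrix(
        incidence, [f"s{i}" for i in range(n)], cancer_types, meta
    )


def enumerate_margin_matrices(row_sums, col_sums):
    """All 0/1 matrices with the given margins, by exhaustive search."""
    row_sums = np.asarray(row_sums)
    col_sums = np.asarray(col_sums)
    n, m = len(row_sums), len(col_sums)
    out = []
    for rows in itertools.product(
        *[
            [
                np.array(bits, dtype=np.uint8)
                for bits in itertools.product([0, 1], repeat=m)
                if sum(bits) == row_sums[i]
            ]
            for i in range(n)
        ]
    ):
        mat = np.vstack(rows)
        if (mat.sum(axis=0) == col_sums).all():
            out.append(mat)
    return out


@pytest.fixture
def toy_matrix():
    """5 samples x 3 mutations, one cancer type."""
    inc = [
        [1, 1, 0],
        [1, 0, 1],
        [0, 1, 1],
        [1, 1, 0],
        [0, 0, 1],
    ]
    return make_matrix(inc)
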