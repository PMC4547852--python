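"""Fixed-margin randomization of binary alteration matrices.

The null model for every test in the pipeline: incidence is randomized
independently within each (cancer type x alteration class) block by a
checkerboard-swap Markov chain, so that every permuted matrix preserves

* each sample's event count within each class ("mutational load"), and
* each alteration's altered-sample count within each cancer type.

The swap move picks two rows and two columns uniformly at random; when the
2x2 submatrix is a checkerboard ([[1,0],[0,1]] or [[0,1],[1,0]]) the four
entries are exchanged, otherwise nothing happens.  The move is its own
inverse and the resulting chain's stationary distribution over the set of
matrices with the given margins is uniform.  Attempted (not successful)
swaps are counted toward burn-in and thinning, which makes cost predictable
on sparse blocks.

Two sampling modes are offered:

``sequential``
    one chain per block: burn-in of ``10 x nnz`` attempted swaps, then one
    matrix emitted every ``nnz`` attempted swaps (the default, cheap);
``restart``
    each permutation restarts the chain from the observed block and runs a
    full burn-in, giving independent (rather than autocorrelated) samples
    at higher cost.

Randomness is fully determined by (plan.seed, block index[, permutation
index]), so serial and repeated runs produce bitwise-identical streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np
from numba import njit

from .data_model import AlterationMatrix

_CHUNK = 1 << 15


@njit(cache=True)
def _swap_kernel(mat, rows, cols):  # pragma: no cover - numba-compiled
    for t in range(rows.shape[0]):
        i = rows[t, 0]
        j = rows[t, 1]
        k = cols[t, 0]
        l = cols[t, 1]
        if i == j or k == l:
            continue
        a = mat[i, k]
        b = mat[i, l]
        c = mat[j, k]
        d = mat[j, l]
        if a == 1 and d == 1 and b == 0 and c == 0:
            mat[i, k] = 0
            mat[j, l] = 0
            mat[i, l] = 1
            mat[j, k] = 1
        elif a == 0 and d == 0 and b == 1 and c == 1:
            mat[i, k] = 1
            mat[j, l] = 1
            mat[i, l] = 0
            mat[j, k] = 0


def _run_swaps(block: np.ndarray, rng: np.random.Generator, n_swaps: int) -> None:
    """Apply ``n_swaps`` attempted checkerboard swaps to ``block`` in place."""
    n_rows, n_cols = block.shape
    if n_rows < 2 or n_cols < 2:
        return
    done = 0
    while done < n_swaps:
        chunk = min(_CHUNK, n_swaps - done)
        rows = rng.integers(0, n_rows, size=(chunk, 2))
        cols = rng.integers(0, n_cols, size=(chunk, 2))
        _swap_kernel(block, rows, cols)
        done += chunk


def swap_randomize_block(
    block: np.ndarray, rng: np.random.Generator, n_swaps: int
) -> np.ndarray:
    """Return a margin-preserving randomization of a 0/1 block.

    Row and column sums of the output equal those of the input exactly; a
    block admitting no checkerboard swap is returned unchanged (as a copy).
    """
    out = np.ascontiguousarray(block, dtype=np.uint8).copy()
    _run_swaps(out, rng, n_swaps)
    return out


@dataclass(frozen=True)
class PermutationPlan:
    """How many permutations to draw and how the chain is driven.

    ``burn_in_swaps`` / ``thinning_swaps``, when given, override the
    nnz-proportional defaults (10 x nnz and 1 x nnz attempted swaps per
    block).
    """

    n_permutations: int = 10_000
    seed: int = 0
    burn_in_factor: float = 10.0
    thinning_factor: float = 1.0
    burn_in_swaps: int | None = None
    thinning_swaps: int | None = None
    mode: str = "sequential"

    def __post_init__(self) -> None:
        if self.n_permutations < 0:
            raise ValueError("n_permutations must be >= 0")
        if self.mode not in ("sequential", "restart"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def with_(self, **kw) -> "PermutationPlan":
        return replace(self, **kw)

    def burn_in_for(self, nnz: int) -> int:
        if self.burn_in_swaps is not None:
            return self.burn_in_swaps
        return max(1, math.ceil(self.burn_in_factor * nnz))

    def thinning_for(self, nnz: int) -> int:
        if self.thinning_swaps is not None:
            return self.thinning_swaps
        return max(1, math.ceil(self.thinning_factor * nnz))


def _blocks_of(matrix: AlterationMatrix) -> list[tuple[np.ndarray, np.ndarray]]:
    """(row indices, column indices) for each (cancer type x class) block."""
    ctypes = np.asarray(matrix.cancer_types)
    classes = np.asarray([m.alteration_class.value for m in matrix.meta])
    blocks = []
    for t in matrix.cancer_type_labels():
        ridx = np.nonzero(ctypes == t)[0]
        for cls in sorted(set(classes)):
            cidx = np.nonzero(classes == cls)[0]
            if ridx.size and cidx.size:
                blocks.append((ridx, cidx))
    return blocks


def stratified_permute(
    matrix: AlterationMatrix,
    rng: np.random.Generator,
    plan: PermutationPlan | None = None,
) -> AlterationMatrix:
    """One margin-preserving randomization of every (type x class) block.

    Sample/alteration ordering and metadata are untouched; each block gets
    a burn-in's worth of attempted swaps from ``rng``.
    """
    plan = plan or PermutationPlan()
    inc = matrix.incidence.copy()
    for ridx, cidx in _blocks_of(matrix):
        block = np.ascontiguousarray(inc[np.ix_(ridx, cidx)])
        nnz = int(block.sum())
        if nnz == 0:
            continue
        _run_swaps(block, rng, plan.burn_in_for(nnz))
        inc[np.ix_(ridx, cidx)] = block
    return matrix.with_incidence(inc)


class PermutedMatrixStream:
    """Reproducible stream of permuted incidence arrays.

    Iterating yields ``plan.n_permutations`` uint8 arrays of the source
    matrix's shape, each preserving every block's row and column sums.
    Permutation ``k`` depends only on ``(plan.seed, k)``: re-iterating, or
    asking for :meth:`nth`, reproduces the same arrays bit for bit.
    """

    def __init__(self, source: AlterationMatrix, plan: PermutationPlan) -> None:
        self.source = source
        self.plan = plan
        self._blocks = _blocks_of(source)

    def __len__(self) -> int:
        return self.plan.n_permutations

    def _block_states(self) -> list[dict]:
        states = []
        for b, (ridx, cidx) in enumerate(self._blocks):
            block = np.ascontiguousarray(
                self.source.incidence[np.ix_(ridx, cidx)]
            )
            states.append(
                {
                    "ridx": ridx,
                    "cidx": cidx,
                    "block": block.copy(),
                    "nnz": int(block.sum()),
                    "id": b,
                }
            )
        return states

    def __iter__(self) -> Iterator[np.ndarray]:
        plan = self.plan
        if plan.mode == "sequential":
            states = self._block_states()
            rngs = [
                np.random.default_rng(
                    np.random.SeedSequence([plan.seed & 0x7FFFFFFF, st["id"]])
                )
                for st in states
            ]
            for st, rng in zip(states, rngs):
                if st["nnz"]:
                    _run_swaps(st["block"], rng, plan.burn_in_for(st["nnz"]))
            for _ in range(plan.n_permutations):
                inc = self.source.incidence.copy()
                for st, rng in zip(states, rngs):
                    if st["nnz"]:
                        _run_swaps(st["block"], rng, plan.thinning_for(st["nnz"]))
                    inc[np.ix_(st["ridx"], st["cidx"])] = st["block"]
                yield inc
        else:  # restart: independent chain per permutation
            for k in range(plan.n_permutations):
                inc = self.source.incidence.copy()
                for b, (ridx, cidx) in enumerate(self._blocks):
                    block = np.ascontiguousarray(inc[np.ix_(ridx, cidx)])
                    nnz = int(block.sum())
                    if nnz == 0:
                        continue
                    rng = np.random.default_rng(
                        np.random.SeedSequence(
                            [plan.seed & 0x7FFFFFFF, b, k]
                        )
                    )
                    _run_swaps(block, rng, plan.burn_in_for(nnz))
                    inc[np.ix_(ridx, cidx)] = block
                yield inc

    def nth(self, k: int) -> np.ndarray:
        """The k-th permuted incidence, identical to the k-th from a sweep."""
        if not 0 <= k < self.plan.n_permutations:
            raise IndexError(k)
        for i, inc in enumerate(self):
            if i == k:
                return inc
        raise AssertionError("unreachable")

    def matrices(self) -> Iterator[AlterationMatrix]:
        for inc in self:
            yield self.source.with_incidence(inc)


def permutation_stream(
    matrix: AlterationMatrix, plan: PermutationPlan
) -> PermutedMatrixStream:
    """Stream of stratified margin-preserving permutations of ``matrix``."""
    return PermutedMatrixStream(matrix, plan)
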