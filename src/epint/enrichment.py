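"""PPI enrichment of detected interaction pairs by resampling.

Two alterations are linked in a protein-protein-interaction (PPI) sense
when at least one gene of the first has an edge to a gene of the second
(existential, not counted).  Enrichment compares the number of PPI-linked
pairs among the detected interactions, N_obs, with its distribution over
random draws of equally many pairs from the testable recurrent-alteration
pool:

    fold = N_obs / mean(N_random),
    P    = (#{N_random >= N_obs} + 1) / (n_resamples + 1).

Edge lists are consumed as generic two-column TSVs with an optional
numeric score column (a cutoff can be applied when sources publish
confidence scores).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import AlterationMatrix, pair_key


@dataclass
class PPINetwork:
    """Undirected gene-gene edge set (physical or functional interactions)."""

    edges: frozenset[tuple[str, str]]
    source_label: str = ""

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str]], source_label: str = ""
    ) -> "PPINetwork":
        edges = frozenset(
            pair_key(a, b) for a, b in pairs if a != b
        )
        return cls(edges=edges, source_label=source_label)

    @classmethod
    def from_tsv(
        cls, path, score_cutoff: float | None = None, source_label: str = ""
    ) -> "PPINetwork":
        df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
        if df.shape[1] < 2:
            raise ValueError("PPI edge list needs at least two columns")
        if score_cutoff is not None:
            if df.shape[1] < 3:
                raise ValueError("score cutoff requested but no score column")
            df = df[df.iloc[:, 2].astype(float) > score_cutoff]
        return cls.from_pairs(
            zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)),
            source_label=source_label or str(path),
        )

    def has_edge(self, a: str, b: str) -> bool:
        return pair_key(a, b) in self.edges


@dataclass
class EnrichmentResult:
    n_obs_ppi: int
    mean_random_ppi: float
    fold: float
    empirical_p: float
    ci95: tuple[float, float]
    n_resamples: int
    n_detected: int


def pair_has_ppi(
    genes_a: frozenset[str] | set[str],
    genes_b: frozenset[str] | set[str],
    network: PPINetwork,
) -> bool:
    """True iff any cross edge links the two alterations' gene sets."""
    if not genes_a or not genes_b:
        raise ValueError("empty gene set")
    small, large = sorted((set(genes_a), set(genes_b)), key=len)
    for g in small:
        for h in large:
            if g != h and network.has_edge(g, h):
                return True
    return False


def _count_ppi(
    pairs: Sequence[tuple[str, str]],
    matrix: AlterationMatrix,
    network: PPINetwork,
) -> int:
    n = 0
    for a, b in pairs:
        if pair_has_ppi(
            matrix.meta_of(a).genes, matrix.meta_of(b).genes, network
        ):
            n += 1
    return n


def enrichment_score(
    detected_pairs: Sequence[tuple[str, str]],
    pool: Sequence[tuple[str, str]],
    matrix: AlterationMatrix,
    network: PPINetwork,
    n_resamples: int = 1_000,
    rng: np.random.Generator | int = 0,
) -> EnrichmentResult:
    """Fold enrichment of detected pairs for PPI links, against random pairs.

    ``pool`` is the set of testable pairs of recurrent alterations (same-
    chromosome CNA-CNA pairs excluded, as in detection); each resample
    draws ``len(detected_pairs)`` distinct pairs uniformly without
    replacement.  ``fold`` degenerates to infinity when no random draw
    hits a PPI but the detected pairs do, and to 1 when both counts are
    zero.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    k = len(detected_pairs)
    if len(pool) < k:
        raise ValueError(
            f"pool ({len(pool)} pairs) smaller than detected set ({k})"
        )
    n_obs = _count_ppi(detected_pairs, matrix, network)
    draws = np.empty(n_resamples, dtype=np.int64)
    pool = list(pool)
    for r in range(n_resamples):
        idx = rng.choice(len(pool), size=k, replace=False)
        draws[r] = _count_ppi([pool[i] for i in idx], matrix, network)
    mean_rand = float(draws.mean()) if n_resamples else 0.0
    if mean_rand > 0:
        fold = n_obs / mean_rand
    else:
        fold = float("inf") if n_obs > 0 else 1.0
    p = (int((draws >= n_obs).sum()) + 1) / (n_resamples + 1)
    lo, hi = (
        (float(np.percentile(draws, 2.5)), float(np.percentile(draws, 97.5)))
        if n_resamples
        else (0.0, 0.0)
    )
    return EnrichmentResult(
        n_obs_ppi=n_obs,
        mean_random_ppi=mean_rand,
        fold=float(fold),
        empirical_p=p,
        ci95=(lo, hi),
        n_resamples=n_resamples,
        n_detected=k,
    )
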