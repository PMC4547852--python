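"""Empirical co-occurrence / mutual-exclusivity testing with BH FDR control.

For each eligible pair the observed number of samples altered in both
members is compared with its distribution across fixed-margin permutations
of the cohort:

* ``P_co`` — fraction of permutations whose co-occurrence is >= observed
  (evidence for co-occurrence when small);
* ``P_me`` — fraction of permutations whose co-occurrence is <= observed
  (evidence for mutual exclusivity when small).

Ties count toward both sides (non-strict inequalities) and values are
floored at 1/N, so both P-values lie in (0, 1] and P_co + P_me >= 1.  The
smaller one-sided value ``p_min`` is BH-adjusted across all pairs of a
scope; a capped two-sided value ``2 x p_min`` is carried alongside for
users who prefer it.  The pan-cancer statistic sums within-type
co-occurrence over cancer types, with permutation still stratified by type.

All pairs of a scope are evaluated against one shared permutation stream —
the whole matrix is permuted once per iteration — so pair statistics are
comparable within a permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .data_model import PAN, AlterationMatrix, pair_key
from .permutation import PermutationPlan, permutation_stream

CO_OCCURRENCE = "co_occurrence"
MUTUAL_EXCLUSIVITY = "mutual_exclusivity"


@dataclass
class InteractionResult:
    """One tested pair in one scope (a cancer type or PAN)."""

    pair: tuple[str, str]
    scope: str
    co_observed: int
    P_co: float
    P_me: float
    p_min: float
    direction: str
    odds_ratio: float
    log_odds_ratio: float
    p_two_sided: float
    q_value: float = float("nan")
    n_permutations: int = 0


@dataclass
class InteractionNetwork:
    """Detected interactions at an FDR threshold, as a weighted graph.

    Edge weight is |log odds ratio| (interaction strength); every edge's
    ``q_value`` is <= the threshold.  ``results`` keeps all tested pairs,
    significant or not, with their BH-adjusted q-values.
    """

    graph: nx.Graph
    results: list[InteractionResult]
    threshold: float
    scope: str

    @property
    def edges(self) -> list[InteractionResult]:
        return [r for r in self.results if r.q_value <= self.threshold]


def empirical_pvalues(
    observed: float, permuted: Sequence[float]
) -> tuple[float, float]:
    """(P_co, P_me) from an observed statistic and its permuted values.

    Non-strict inequalities on both sides (ties count toward both), floored
    at 1/N so an empirical P never reaches 0.
    """
    permuted = np.asarray(permuted, dtype=float)
    n = len(permuted)
    if n == 0:
        raise ValueError("no permuted values")
    p_co = max(int((permuted >= observed).sum()), 1) / n
    p_me = max(int((permuted <= observed).sum()), 1) / n
    return p_co, p_me


def cooccurrence_count(
    matrix: AlterationMatrix, pair: tuple[str, str], scope: str = PAN
) -> int:
    """Number of scope samples altered in both members of the pair."""
    mask = matrix.sample_mask(scope)
    a = matrix.alteration_loc(pair[0])
    b = matrix.alteration_loc(pair[1])
    inc = matrix.incidence[mask]
    if inc[:, a].sum() == 0 or inc[:, b].sum() == 0:
        raise ValueError(f"pair {pair} not altered within scope {scope!r}")
    return int((inc[:, a] & inc[:, b]).sum())


def _pair_indices(
    matrix: AlterationMatrix, pairs: Sequence[tuple[str, str]]
) -> tuple[np.ndarray, np.ndarray]:
    ia = np.array([matrix.alteration_loc(a) for a, _ in pairs], dtype=np.intp)
    ib = np.array([matrix.alteration_loc(b) for _, b in pairs], dtype=np.intp)
    return ia, ib


def _co_counts(inc: np.ndarray, ia: np.ndarray, ib: np.ndarray) -> np.ndarray:
    gram = inc.astype(np.float64).T @ inc.astype(np.float64)
    return gram[ia, ib]


def _odds_ratio(
    inc: np.ndarray, ia: np.ndarray, ib: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Continuity-corrected (+0.5 per cell) odds ratio for each pair."""
    n = inc.shape[0]
    ka = inc[:, ia].sum(axis=0).astype(np.float64)
    kb = inc[:, ib].sum(axis=0).astype(np.float64)
    co = _co_counts(inc, ia, ib)
    a = co + 0.5
    b = ka - co + 0.5
    c = kb - co + 0.5
    d = n - ka - kb + co + 0.5
    orr = (a * d) / (b * c)
    return orr, co


def _assemble_results(
    pairs: Sequence[tuple[str, str]],
    scope: str,
    obs: np.ndarray,
    ge: np.ndarray,
    le: np.ndarray,
    orr: np.ndarray,
    n_perm: int,
) -> list[InteractionResult]:
    out = []
    for i, pr in enumerate(pairs):
        p_co = max(int(ge[i]), 1) / n_perm
        p_me = max(int(le[i]), 1) / n_perm
        p_min = min(p_co, p_me)
        if p_co < p_me:
            direction = CO_OCCURRENCE
        elif p_me < p_co:
            direction = MUTUAL_EXCLUSIVITY
        else:
            direction = CO_OCCURRENCE if orr[i] >= 1 else MUTUAL_EXCLUSIVITY
        out.append(
            InteractionResult(
                pair=pair_key(*pr),
                scope=scope,
                co_observed=int(obs[i]),
                P_co=p_co,
                P_me=p_me,
                p_min=p_min,
                direction=direction,
                odds_ratio=float(orr[i]),
                log_odds_ratio=float(np.log(orr[i])),
                p_two_sided=min(1.0, 2 * p_min),
                n_permutations=n_perm,
            )
        )
    return out


def empirical_interaction_test(
    matrix: AlterationMatrix,
    pairs: Sequence[tuple[str, str]],
    plan: PermutationPlan,
    scope: str,
) -> list[InteractionResult]:
    """Permutation test of every pair within one cancer type.

    ``matrix`` should already be restricted to the scope's recurrent
    alterations (see :func:`epint.data_model.filter_recurrent`).
    """
    if not pairs:
        return []
    scoped = matrix.restrict_scope(scope)
    ia, ib = _pair_indices(scoped, pairs)
    obs = _co_counts(scoped.incidence, ia, ib)
    orr, _ = _odds_ratio(scoped.incidence, ia, ib)
    ge = np.zeros(len(pairs), dtype=np.int64)
    le = np.zeros(len(pairs), dtype=np.int64)
    for inc in permutation_stream(scoped, plan):
        co = _co_counts(inc, ia, ib)
        ge += co >= obs
        le += co <= obs
    return _assemble_results(
        pairs, scope, obs, ge, le, orr, plan.n_permutations
    )


def pan_cancer_test(
    matrix: AlterationMatrix,
    pairs: Sequence[tuple[str, str]],
    plan: PermutationPlan,
) -> list[InteractionResult]:
    """Pan-cancer permutation test: co-occurrence summed over cancer types.

    Permutation remains stratified within each cancer type; the test
    statistic for a pair is the sum over types of its within-type
    co-occurrence, which for the observed matrix equals the plain
    co-occurrence over all samples.
    """
    if not pairs:
        return []
    ia, ib = _pair_indices(matrix, pairs)
    obs = _co_counts(matrix.incidence, ia, ib)
    orr, _ = _odds_ratio(matrix.incidence, ia, ib)
    ge = np.zeros(len(pairs), dtype=np.int64)
    le = np.zeros(len(pairs), dtype=np.int64)
    for inc in permutation_stream(matrix, plan):
        co = _co_counts(inc, ia, ib)
        ge += co >= obs
        le += co <= obs
    return _assemble_results(pairs, PAN, obs, ge, le, orr, plan.n_permutations)


def fdr_and_classify(
    results: Sequence[InteractionResult],
    threshold: float = 0.1,
    matrix: AlterationMatrix | None = None,
) -> InteractionNetwork:
    """BH-adjust p_min across a scope's pairs and build the network.

    Edges are pairs with q <= threshold, weighted by |log OR|; when
    ``matrix`` is given, nodes carry alteration class and altered-sample
    frequency attributes.
    """
    results = list(results)
    scopes = {r.scope for r in results}
    if len(scopes) > 1:
        raise ValueError(f"results span multiple scopes: {sorted(scopes)}")
    scope = scopes.pop() if scopes else PAN
    if results:
        q = multipletests(
            [r.p_min for r in results], method="fdr_bh"
        )[1]
        for r, qv in zip(results, q):
            r.q_value = float(qv)
    graph = nx.Graph()
    if matrix is not None:
        counts = matrix.alteration_counts(
            scope if scope in matrix.cancer_type_labels() else PAN
        )
        n = int(matrix.sample_mask(
            scope if scope in matrix.cancer_type_labels() else PAN
        ).sum())
        for j, m in enumerate(matrix.meta):
            graph.add_node(
                m.alteration_id,
                alteration_class=m.alteration_class.value,
                frequency=counts[j] / n if n else 0.0,
            )
    for r in results:
        if r.q_value <= threshold:
            a, b = r.pair
            graph.add_edge(
                a,
                b,
                direction=r.direction,
                weight=abs(r.log_odds_ratio),
                q_value=r.q_value,
                odds_ratio=r.odds_ratio,
            )
    return InteractionNetwork(
        graph=graph, results=results, threshold=threshold, scope=scope
    )


def detect_interactions(
    matrix: AlterationMatrix,
    plan: PermutationPlan,
    scope: str = PAN,
    threshold: float = 0.1,
    min_frequency: float = 0.02,
) -> InteractionNetwork:
    """Recurrence-filter a scope, test all eligible pairs, BH-adjust.

    Convenience wrapper for one detection run: within one cancer type when
    ``scope`` names a type, pan-cancer (stratified permutation, summed
    co-occurrence) when ``scope`` is ``PAN``.
    """
    from .data_model import eligible_pairs, filter_recurrent

    sub = filter_recurrent(matrix, min_frequency=min_frequency, scope=scope)
    pairs = eligible_pairs(sub)
    if scope == PAN:
        results = pan_cancer_test(sub, pairs, plan)
    else:
        results = empirical_interaction_test(sub, pairs, plan, scope)
    return fdr_and_classify(results, threshold=threshold, matrix=sub)


def results_to_frame(results: Sequence[InteractionResult]) -> pd.DataFrame:
    """Tabular (TSV-ready) view of interaction results."""
    return pd.DataFrame(
        {
            "alteration_a": [r.pair[0] for r in results],
            "alteration_b": [r.pair[1] for r in results],
            "scope": [r.scope for r in results],
            "co_observed": [r.co_observed for r in results],
            "P_co": [r.P_co for r in results],
            "P_me": [r.P_me for r in results],
            "p_min": [r.p_min for r in results],
            "p_two_sided": [r.p_two_sided for r in results],
            "q_value": [r.q_value for r in results],
            "direction": [r.direction for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "log_odds_ratio": [r.log_odds_ratio for r in results],
        }
    )


def write_network(network: InteractionNetwork, graphml_path=None, sif_path=None):
    """Export a detection network as GraphML and/or SIF."""
    if graphml_path is not None:
        nx.write_graphml(network.graph, graphml_path)
    if sif_path is not None:
        with open(sif_path, "w") as fh:
            for a, b, data in network.graph.edges(data=True):
                fh.write(f"{a}\t{data['direction']}\t{b}\n")
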