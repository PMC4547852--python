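"""Differential genetic interactions between cancer types.

A pair detected as interacting in one cancer type is re-tested in every
other type where both members are individually recurrent (>= 2% of that
type's samples).  Each comparison forms two 2x2 strata — (both altered,
A only, B only, neither) in the detected and in the compared type — and
asks whether one common odds ratio fits both, via the Breslow-Day
chi-square with Tarone's correction:

    T = sum_k (a_k - E[a_k])^2 / V_k  -  (sum_k (a_k - E[a_k]))^2 / sum_k V_k

where E[a_k] is the both-altered count expected under the Mantel-Haenszel
common OR with the stratum's margins fixed (positive root of a quadratic)
and V_k is the asymptotic variance (inverse sum of reciprocal fitted
cells).  Because the chi-square reference is unreliable under the strong
load heterogeneity of tumor cohorts, significance instead comes from the
fixed-margin permutation null: the empirical P is the fraction of permuted
matrices whose statistic strictly exceeds the observed T, floored at 1/N,
BH-adjusted across all comparisons of a screen.

Effect direction is the change in log odds ratio between the two types,
computed from continuity-corrected (+0.5 per cell) ORs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .data_model import AlterationMatrix, pair_key, recurrence_threshold
from .interaction import InteractionNetwork
from .permutation import PermutationPlan, permutation_stream

logger = logging.getLogger(__name__)

HIGHER_OR = "higher_OR"
LOWER_OR = "lower_OR"
NOT_DIFFERENTIAL = "not_differential"


@dataclass(frozen=True)
class StratumTable:
    """2x2 contingency table for one pair in one cancer type."""

    co: int
    a_only: int
    b_only: int
    neither: int
    cancer_type: str = ""

    @property
    def total(self) -> int:
        return self.co + self.a_only + self.b_only + self.neither

    def cells(self) -> tuple[int, int, int, int]:
        return (self.co, self.a_only, self.b_only, self.neither)


@dataclass
class DifferentialResult:
    """One (pair, detected type, compared type) heterogeneity test."""

    pair: tuple[str, str]
    detected_type: str
    compared_type: str
    or_detected: float
    or_compared: float
    delta_log_or: float
    T_obs: float
    p_empirical: float
    q_value: float = float("nan")
    call: str = NOT_DIFFERENTIAL
    n_permutations: int = 0


def contingency(
    matrix: AlterationMatrix, pair: tuple[str, str], cancer_type: str
) -> StratumTable:
    """(both, A-only, B-only, neither) counts within one cancer type."""
    mask = matrix.sample_mask(cancer_type)
    a = matrix.incidence[mask, matrix.alteration_loc(pair[0])]
    b = matrix.incidence[mask, matrix.alteration_loc(pair[1])]
    co = int((a & b).sum())
    return StratumTable(
        co=co,
        a_only=int(a.sum()) - co,
        b_only=int(b.sum()) - co,
        neither=int(mask.sum()) - int(a.sum()) - int(b.sum()) + co,
        cancer_type=cancer_type,
    )


def corrected_odds_ratio(table: StratumTable) -> float:
    """Odds ratio with 0.5 added to each cell to avoid division by zero."""
    return ((table.co + 0.5) * (table.neither + 0.5)) / (
        (table.a_only + 0.5) * (table.b_only + 0.5)
    )


def _tarone_vec(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    d: np.ndarray,
    continuity: str = "auto",
) -> np.ndarray:
    """Breslow-Day-Tarone statistic, vectorized over comparisons.

    ``a, b, c, d`` have shape (K, M): K strata by M comparisons.  Under
    ``auto`` continuity, 0.5 is added to every cell of a comparison's
    strata whenever any of its cells is zero; ``always`` corrects every
    comparison, ``never`` uses raw counts.
    """
    a = np.asarray(a, dtype=np.float64).copy()
    b = np.asarray(b, dtype=np.float64).copy()
    c = np.asarray(c, dtype=np.float64).copy()
    d = np.asarray(d, dtype=np.float64).copy()
    if continuity not in ("auto", "always", "never"):
        raise ValueError(f"unknown continuity mode {continuity!r}")
    if continuity == "always":
        corr = np.ones(a.shape[1], dtype=bool)
    elif continuity == "auto":
        corr = ((a == 0) | (b == 0) | (c == 0) | (d == 0)).any(axis=0)
    else:
        corr = np.zeros(a.shape[1], dtype=bool)
    for arr in (a, b, c, d):
        arr[:, corr] += 0.5

    n = a + b + c + d
    # Mantel-Haenszel common odds ratio over strata
    with np.errstate(divide="ignore", invalid="ignore"):
        psi = (a * d / n).sum(axis=0) / (b * c / n).sum(axis=0)
    p = a + b  # first-member margin
    q = a + c  # second-member margin
    # fitted both-altered count under psi: root of
    # (1 - psi) x^2 + (n - p - q + psi (p + q)) x - psi p q = 0
    A = 1.0 - psi
    B = (n - p - q) + psi * (p + q)
    C = -psi * p * q
    lo = np.maximum(0.0, p + q - n)
    hi = np.minimum(p, q)
    with np.errstate(invalid="ignore", divide="ignore"):
        disc = np.sqrt(np.maximum(B * B - 4.0 * A * C, 0.0))
        r1 = np.where(A != 0, (-B + disc) / (2.0 * A), -C / B)
        r2 = np.where(A != 0, (-B - disc) / (2.0 * A), -C / B)
    tol = 1e-9 * np.maximum(n, 1.0)
    ok1 = (r1 >= lo - tol) & (r1 <= hi + tol)
    fitted = np.where(ok1, r1, r2)
    fitted = np.clip(fitted, lo, hi)

    with np.errstate(divide="ignore"):
        v = 1.0 / (
            1.0 / fitted
            + 1.0 / (p - fitted)
            + 1.0 / (q - fitted)
            + 1.0 / (n - p - q + fitted)
        )
    resid = a - fitted
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (resid * resid / v).sum(axis=0) - resid.sum(axis=0) ** 2 / v.sum(
            axis=0
        )
    t = np.where(np.isfinite(t), t, 0.0)
    return np.maximum(t, 0.0)


def tarone_statistic(
    tables: Sequence[StratumTable], continuity: str = "auto"
) -> tuple[float, int]:
    """Breslow-Day statistic with Tarone's correction over K strata.

    Returns ``(T, df)`` with ``df = K - 1``; identical strata (or K = 1)
    give T = 0.
    """
    k = len(tables)
    if k == 0:
        raise ValueError("at least one stratum required")
    if k == 1:
        return 0.0, 0
    a = np.array([[t.co] for t in tables], dtype=np.float64)
    b = np.array([[t.a_only] for t in tables], dtype=np.float64)
    c = np.array([[t.b_only] for t in tables], dtype=np.float64)
    d = np.array([[t.neither] for t in tables], dtype=np.float64)
    t_val = _tarone_vec(a, b, c, d, continuity=continuity)[0]
    return float(t_val), k - 1


@dataclass(frozen=True)
class _Comparison:
    pair: tuple[str, str]
    detected_type: str
    compared_type: str


def _eligible(
    matrix: AlterationMatrix,
    pair: tuple[str, str],
    compared_type: str,
    min_frequency: float,
) -> bool:
    mask = matrix.sample_mask(compared_type)
    thr = recurrence_threshold(int(mask.sum()), min_frequency)
    ka = int(matrix.incidence[mask, matrix.alteration_loc(pair[0])].sum())
    kb = int(matrix.incidence[mask, matrix.alteration_loc(pair[1])].sum())
    return ka >= thr and kb >= thr


def _batch_test(
    matrix: AlterationMatrix,
    comparisons: Sequence[_Comparison],
    plan: PermutationPlan,
    continuity: str,
) -> list[DifferentialResult]:
    """Test comparisons sharing one (detected, compared) type pair.

    One permutation stream over the two types' samples serves every pair;
    all other alterations are permuted along with the pair's own columns
    (whole-matrix stratified permutation).
    """
    types = (comparisons[0].detected_type, comparisons[0].compared_type)
    ctypes = np.asarray(matrix.cancer_types)
    sub = matrix.subset(sample_idx=np.nonzero(np.isin(ctypes, types))[0])
    masks = [sub.sample_mask(t) for t in types]
    n_t = np.array([int(m.sum()) for m in masks], dtype=np.float64)

    ia = np.array(
        [sub.alteration_loc(c.pair[0]) for c in comparisons], dtype=np.intp
    )
    ib = np.array(
        [sub.alteration_loc(c.pair[1]) for c in comparisons], dtype=np.intp
    )

    def cells(inc: np.ndarray):
        a = np.empty((2, len(comparisons)))
        b = np.empty_like(a)
        c = np.empty_like(a)
        d = np.empty_like(a)
        for s, mask in enumerate(masks):
            blk = inc[mask].astype(np.float64)
            co = (blk.T @ blk)[ia, ib]
            ka = blk[:, ia].sum(axis=0)
            kb = blk[:, ib].sum(axis=0)
            a[s] = co
            b[s] = ka - co
            c[s] = kb - co
            d[s] = n_t[s] - ka - kb + co
        return a, b, c, d

    a0, b0, c0, d0 = cells(sub.incidence)
    t_obs = _tarone_vec(a0, b0, c0, d0, continuity=continuity)
    exceed = np.zeros(len(comparisons), dtype=np.int64)
    for inc in permutation_stream(sub, plan):
        t_rand = _tarone_vec(*cells(inc), continuity=continuity)
        exceed += t_rand > t_obs

    results = []
    for i, comp in enumerate(comparisons):
        tab_det = StratumTable(
            int(a0[0, i]), int(b0[0, i]), int(c0[0, i]), int(d0[0, i]),
            comp.detected_type,
        )
        tab_cmp = StratumTable(
            int(a0[1, i]), int(b0[1, i]), int(c0[1, i]), int(d0[1, i]),
            comp.compared_type,
        )
        or_det = corrected_odds_ratio(tab_det)
        or_cmp = corrected_odds_ratio(tab_cmp)
        results.append(
            DifferentialResult(
                pair=comp.pair,
                detected_type=comp.detected_type,
                compared_type=comp.compared_type,
                or_detected=or_det,
                or_compared=or_cmp,
                delta_log_or=float(np.log(or_det) - np.log(or_cmp)),
                T_obs=float(t_obs[i]),
                p_empirical=max(int(exceed[i]), 1) / plan.n_permutations,
                n_permutations=plan.n_permutations,
            )
        )
    return results


def differential_interaction_test(
    pair: tuple[str, str],
    detected_type: str,
    compared_type: str,
    matrix: AlterationMatrix,
    plan: PermutationPlan,
    continuity: str = "auto",
    min_frequency: float = 0.02,
) -> DifferentialResult | None:
    """Permutation-calibrated Tarone test for one pair between two types.

    Returns ``None`` (with a logged reason) when the pair is not
    individually recurrent in the compared type.
    """
    pair = pair_key(*pair)
    if not _eligible(matrix, pair, compared_type, min_frequency):
        logger.info(
            "pair %s skipped: below %.0f%% recurrence in %s",
            pair, 100 * min_frequency, compared_type,
        )
        return None
    comp = _Comparison(pair, detected_type, compared_type)
    return _batch_test(matrix, [comp], plan, continuity)[0]


def differential_screen(
    detected: Mapping[str, InteractionNetwork],
    matrix: AlterationMatrix,
    plan: PermutationPlan,
    threshold: float = 0.1,
    continuity: str = "auto",
    min_frequency: float = 0.02,
) -> list[DifferentialResult]:
    """Re-test every detected per-type interaction in every other type.

    BH is applied across all comparisons of the screen (a single FDR over
    pair x compared-type tests); a comparison is called ``higher_OR`` or
    ``lower_OR`` by the sign of the change in log OR when q <= threshold.
    Comparisons sharing a type pair share one permutation stream, with a
    per-type-pair seed derived from ``plan.seed``.
    """
    groups: dict[tuple[str, str], list[_Comparison]] = {}
    all_types = matrix.cancer_type_labels()
    for det_type, network in detected.items():
        for res in network.edges:
            for other in all_types:
                if other == det_type:
                    continue
                if _eligible(matrix, res.pair, other, min_frequency):
                    groups.setdefault((det_type, other), []).append(
                        _Comparison(res.pair, det_type, other)
                    )
    results: list[DifferentialResult] = []
    for g, (key, comps) in enumerate(sorted(groups.items())):
        sub_seed = int(
            np.random.SeedSequence([plan.seed & 0x7FFFFFFF, g]).generate_state(1)[0]
            % (1 << 31)
        )
        results.extend(
            _batch_test(matrix, comps, plan.with_(seed=sub_seed), continuity)
        )
    if results:
        q = multipletests([r.p_empirical for r in results], method="fdr_bh")[1]
        for r, qv in zip(results, q):
            r.q_value = float(qv)
            if qv <= threshold:
                r.call = HIGHER_OR if r.delta_log_or > 0 else LOWER_OR
    return results


def screen_summary(results: Sequence[DifferentialResult]) -> dict:
    """Comparison and non-redundant pair counts for a differential screen."""
    called = [r for r in results if r.call != NOT_DIFFERENTIAL]
    return {
        "n_comparisons": len(results),
        "n_differential_comparisons": len(called),
        "n_pairs_tested": len({r.pair for r in results}),
        "n_pairs_differential": len({r.pair for r in called}),
    }


def differential_to_frame(results: Sequence[DifferentialResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "alteration_a": [r.pair[0] for r in results],
            "alteration_b": [r.pair[1] for r in results],
            "detected_type": [r.detected_type for r in results],
            "compared_type": [r.compared_type for r in results],
            "or_detected": [r.or_detected for r in results],
            "or_compared": [r.or_compared for r in results],
            "delta_log_or": [r.delta_log_or for r in results],
            "T_obs": [r.T_obs for r in results],
            "p_empirical": [r.p_empirical for r in results],
            "q_value": [r.q_value for r in results],
            "call": [r.call for r in results],
        }
    )


def differential_network(
    results: Sequence[DifferentialResult], strongest_only: bool = True
) -> nx.Graph:
    """Graph of differential calls; optionally keep only the strongest
    |delta log OR| comparison per pair."""
    called = [r for r in results if r.call != NOT_DIFFERENTIAL]
    if strongest_only:
        best: dict[tuple[str, str], DifferentialResult] = {}
        for r in called:
            cur = best.get(r.pair)
            if cur is None or abs(r.delta_log_or) > abs(cur.delta_log_or):
                best[r.pair] = r
        called = list(best.values())
    graph = nx.Graph()
    for r in called:
        graph.add_edge(
            r.pair[0],
            r.pair[1],
            call=r.call,
            detected_type=r.detected_type,
            compared_type=r.compared_type,
            delta_log_or=r.delta_log_or,
            q_value=r.q_value,
        )
    return graph
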