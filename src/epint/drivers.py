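"""Concordance ranking of candidate genes inside copy-number regions.

A recurrent copy-number region usually spans many genes, only some of
which are the functional targets.  Genes whose mRNA expression tracks the
copy-number status of the region are the better driver candidates: for
each gene the samples of a cancer type are split into altered vs
non-altered for the region and compared with a two-sided Mann-Whitney
rank-sum test (exact enumeration when both groups have at most 8 samples
and no ties; otherwise the normal approximation with tie correction).
Genes are ranked by BH-adjusted q-value within the region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import AlterationMatrix

logger = logging.getLogger(__name__)

_EXACT_MAX = 8


@dataclass
class GeneRank:
    gene: str
    u_statistic: float
    p_value: float
    q_value: float


def _mannwhitney(altered: np.ndarray, other: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum test; degenerate all-tied input gives p = 1."""
    if np.ptp(np.concatenate([altered, other])) == 0:
        return len(altered) * len(other) / 2.0, 1.0
    has_ties = len(np.unique(np.concatenate([altered, other]))) < (
        len(altered) + len(other)
    )
    if len(altered) <= _EXACT_MAX and len(other) <= _EXACT_MAX and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        altered, other, alternative="two-sided", method=method
    )
    return float(res.statistic), float(res.pvalue)


def rank_genes_in_region(
    region: str,
    matrix: AlterationMatrix,
    expression: pd.DataFrame,
    cancer_type: str,
) -> list[GeneRank] | None:
    """Rank a CNA region's genes by copy-number/expression concordance.

    ``expression`` is a samples x genes log2 matrix indexed by sample id.
    Returns ``None`` (with a logged reason) when either the altered or the
    non-altered group is empty in the overlap of cohort and expression
    samples.
    """
    meta = matrix.meta_of(region)
    if not meta.alteration_class.is_cna:
        raise ValueError(f"{region!r} is not a copy-number alteration")
    mask = matrix.sample_mask(cancer_type)
    idx = np.nonzero(mask)[0]
    common = [
        i for i in idx if matrix.sample_ids[i] in expression.index
    ]
    if not common:
        logger.info("region %s: no expression for cohort %s", region, cancer_type)
        return None
    j = matrix.alteration_loc(region)
    altered_ids = [
        matrix.sample_ids[i] for i in common if matrix.incidence[i, j]
    ]
    other_ids = [
        matrix.sample_ids[i] for i in common if not matrix.incidence[i, j]
    ]
    if not altered_ids or not other_ids:
        logger.info(
            "region %s skipped in %s: empty altered or non-altered group",
            region,
            cancer_type,
        )
        return None
    genes = [g for g in sorted(meta.genes) if g in expression.columns]
    if not genes:
        logger.info("region %s: none of its genes have expression", region)
        return None
    stats_p = [
        _mannwhitney(
            expression.loc[altered_ids, g].to_numpy(dtype=float),
            expression.loc[other_ids, g].to_numpy(dtype=float),
        )
        for g in genes
    ]
    pvals = [p for _, p in stats_p]
    qvals = multipletests(pvals, method="fdr_bh")[1]
    ranks = [
        GeneRank(g, u, p, float(q))
        for g, (u, p), q in zip(genes, stats_p, qvals)
    ]
    ranks.sort(key=lambda r: (r.q_value, r.p_value, r.gene))
    return ranks


def ranks_to_frame(region: str, ranks: list[GeneRank]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region": region,
            "gene": [r.gene for r in ranks],
            "U": [r.u_statistic for r in ranks],
            "p_value": [r.p_value for r in ranks],
            "q_value": [r.q_value for r in ranks],
            "rank": np.arange(1, len(ranks) + 1),
        }
    )
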