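"""Domain types, TSV I/O, cohort filtering and pair-eligibility rules.

The central container is :class:`AlterationMatrix`: a binary sample x
alteration incidence matrix whose rows carry a cancer-type label and whose
columns carry alteration metadata (class, chromosome for CNAs, member genes).
Every downstream stage (permutation null, interaction tests, differential
screen, enrichment, saturation) operates on this object.

Cohort filtering follows two rules applied in order:

1. hyper-altered exclusion — samples whose total event count strictly
   exceeds Q3 + 4.5 x IQR of per-sample counts are dropped;
2. recurrence — only alterations present in at least 2% of the samples
   under consideration (``ceil(0.02 * n)``) are retained within a scope.

CNA-CNA pairs on the same chromosome are never tested, to avoid linkage
confounding; this is the only location-based exclusion.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PAN = "PAN"
"""Scope label meaning "all cancer types jointly"."""

MISSING_CHROM = "."


class AlterationClass(str, Enum):
    """The four classes of binary driver events."""

    MUTATION = "mutation"
    CNA_GAIN = "CNA_gain"
    CNA_LOSS = "CNA_loss"
    METHYLATION = "methylation"

    @property
    def is_cna(self) -> bool:
        return self in (AlterationClass.CNA_GAIN, AlterationClass.CNA_LOSS)


_CLASS_VALUES = {c.value for c in AlterationClass}


@dataclass(frozen=True)
class AlterationMeta:
    """Metadata for one alteration: class, chromosome (CNAs) and member genes."""

    alteration_id: str
    alteration_class: AlterationClass
    chromosome: str | None = None
    genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.alteration_id:
            raise ValueError("alteration_id must be non-empty")
        if self.alteration_class.is_cna and not self.chromosome:
            raise ValueError(
                f"CNA alteration {self.alteration_id!r} has no chromosome"
            )
        if not self.genes:
            raise ValueError(f"alteration {self.alteration_id!r} has no genes")


class AlterationMatrix:
    """Binary sample x alteration incidence with sample strata and metadata.

    Parameters
    ----------
    incidence
        0/1 array of shape (n_samples, n_alterations).
    sample_ids, cancer_types
        Parallel sequences labelling the rows.
    meta
        One :class:`AlterationMeta` per column, in column order.
    """

    def __init__(
        self,
        incidence: np.ndarray,
        sample_ids: Sequence[str],
        cancer_types: Sequence[str],
        meta: Sequence[AlterationMeta],
    ) -> None:
        incidence = np.asarray(incidence, dtype=np.uint8)
        if incidence.ndim != 2:
            raise ValueError("incidence must be 2-D")
        if not np.isin(incidence, (0, 1)).all():
            raise ValueError("incidence entries must be 0 or 1")
        n, m = incidence.shape
        if len(sample_ids) != n or len(cancer_types) != n:
            raise ValueError("sample labels do not match incidence rows")
        if len(meta) != m:
            raise ValueError("metadata does not match incidence columns")
        if len(set(sample_ids)) != n:
            raise ValueError("duplicate sample_id")
        ids = [mt.alteration_id for mt in meta]
        if len(set(ids)) != m:
            raise ValueError("duplicate alteration_id")
        self.incidence = incidence
        self.sample_ids = list(sample_ids)
        self.cancer_types = list(cancer_types)
        self.meta = list(meta)
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}
        self._alt_index = {a: j for j, a in enumerate(ids)}

    # -- basic views ---------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_alterations(self) -> int:
        return self.incidence.shape[1]

    @property
    def alteration_ids(self) -> list[str]:
        return [m.alteration_id for m in self.meta]

    def sample_loc(self, sample_id: str) -> int:
        return self._sample_index[sample_id]

    def alteration_loc(self, alteration_id: str) -> int:
        try:
            return self._alt_index[alteration_id]
        except KeyError:
            raise KeyError(f"unknown alteration {alteration_id!r}") from None

    def meta_of(self, alteration_id: str) -> AlterationMeta:
        return self.meta[self.alteration_loc(alteration_id)]

    def cancer_type_labels(self) -> list[str]:
        """Distinct cancer types in first-appearance order."""
        seen: dict[str, None] = {}
        for t in self.cancer_types:
            seen.setdefault(t)
        return list(seen)

    def sample_mask(self, scope: str) -> np.ndarray:
        """Boolean row mask for one cancer type, or all rows for ``PAN``."""
        if scope == PAN:
            return np.ones(self.n_samples, dtype=bool)
        mask = np.array([t == scope for t in self.cancer_types], dtype=bool)
        if not mask.any():
            raise KeyError(f"unknown cancer type {scope!r}")
        return mask

    def sample_counts(self) -> np.ndarray:
        """Per-sample total event count."""
        return self.incidence.sum(axis=1).astype(np.int64)

    def alteration_counts(self, scope: str = PAN) -> np.ndarray:
        """Per-alteration altered-sample count within a scope."""
        mask = self.sample_mask(scope)
        return self.incidence[mask].sum(axis=0).astype(np.int64)

    # -- subsetting ----------------------------------------------------------

    def subset(
        self,
        sample_idx: np.ndarray | None = None,
        alt_idx: np.ndarray | None = None,
    ) -> "AlterationMatrix":
        inc = self.incidence
        sids, ctypes, meta = self.sample_ids, self.cancer_types, self.meta
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx)
            inc = inc[sample_idx]
            sids = [sids[i] for i in sample_idx]
            ctypes = [ctypes[i] for i in sample_idx]
        if alt_idx is not None:
            alt_idx = np.asarray(alt_idx)
            inc = inc[:, alt_idx]
            meta = [meta[j] for j in alt_idx]
        return AlterationMatrix(inc.copy(), sids, ctypes, meta)

    def restrict_scope(self, scope: str) -> "AlterationMatrix":
        if scope == PAN:
            return self
        return self.subset(sample_idx=np.nonzero(self.sample_mask(scope))[0])

    def with_incidence(self, incidence: np.ndarray) -> "AlterationMatrix":
        """Same labels/metadata, different 0/1 entries (used by permutation)."""
        return AlterationMatrix(
            incidence, self.sample_ids, self.cancer_types, self.meta
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlterationMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.cancer_types == other.cancer_types
            and self.meta == other.meta
            and np.array_equal(self.incidence, other.incidence)
        )


@dataclass
class CohortFilterReport:
    """Record of the hyper-altered exclusion and recurrence filtering."""

    excluded_hyper_samples: list[dict] = field(default_factory=list)
    thresholds: dict[str, float] = field(default_factory=dict)
    quartile_method: str = "linear"
    multiplier: float = 4.5
    min_frequency: float = 0.02
    retained_alterations: dict[str, list[dict]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "excluded_hyper_samples": self.excluded_hyper_samples,
                "thresholds": self.thresholds,
                "quartile_method": self.quartile_method,
                "multiplier": self.multiplier,
                "min_frequency": self.min_frequency,
                "retained_alterations": self.retained_alterations,
            },
            indent=2,
        )

    def to_frame(self) -> pd.DataFrame:
        """Excluded samples as a TSV-ready table."""
        return pd.DataFrame(
            self.excluded_hyper_samples,
            columns=["sample_id", "event_count", "threshold", "scope"],
        )


# -- TSV I/O ----------------------------------------------------------------

EVENT_COLUMNS = ["sample_id", "alteration_id", "alteration_class", "cancer_type"]
META_COLUMNS = ["alteration_id", "alteration_class", "chromosome", "genes"]


def _parse_meta_frame(meta_df: pd.DataFrame) -> list[AlterationMeta]:
    metas = []
    for row in meta_df.itertuples(index=False):
        cls = str(row.alteration_class)
        if cls not in _CLASS_VALUES:
            raise ValueError(f"unknown alteration_class {cls!r}")
        chrom = str(row.chromosome)
        genes = frozenset(g for g in str(row.genes).split(";") if g)
        metas.append(
            AlterationMeta(
                alteration_id=str(row.alteration_id),
                alteration_class=AlterationClass(cls),
                chromosome=None if chrom == MISSING_CHROM else chrom,
                genes=genes,
            )
        )
    return metas


def load_events(
    events_path,
    meta_path,
    keep_zero_alterations: bool = False,
) -> AlterationMatrix:
    """Read long-format event and metadata TSVs into an AlterationMatrix.

    ``keep_zero_alterations`` retains alterations listed in the metadata but
    absent from the events as all-zero columns (default: dropped).
    """
    events = pd.read_csv(events_path, sep="\t", dtype=str)
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"events file lacks columns {missing}")
    meta_df = pd.read_csv(meta_path, sep="\t", dtype=str)
    missing = [c for c in META_COLUMNS if c not in meta_df.columns]
    if missing:
        raise ValueError(f"metadata file lacks columns {missing}")
    if meta_df["alteration_id"].duplicated().any():
        dup = meta_df.loc[meta_df["alteration_id"].duplicated(), "alteration_id"]
        raise ValueError(f"duplicate alteration_id in metadata: {dup.iloc[0]!r}")

    metas = _parse_meta_frame(meta_df)
    meta_by_id = {m.alteration_id: m for m in metas}

    dup = events.duplicated(subset=["sample_id", "alteration_id"])
    if dup.any():
        row = events[dup].iloc[0]
        raise ValueError(
            "duplicate event row for sample "
            f"{row['sample_id']!r}, alteration {row['alteration_id']!r}"
        )
    ct = events.groupby("sample_id")["cancer_type"].nunique()
    if (ct > 1).any():
        bad = ct[ct > 1].index[0]
        raise ValueError(f"sample {bad!r} mapped to multiple cancer types")

    for row in events.itertuples(index=False):
        m = meta_by_id.get(row.alteration_id)
        if m is None:
            raise ValueError(
                f"event references unknown alteration {row.alteration_id!r}"
            )
        if m.alteration_class.value != row.alteration_class:
            raise ValueError(
                f"alteration {row.alteration_id!r}: class "
                f"{row.alteration_class!r} in events but "
                f"{m.alteration_class.value!r} in metadata"
            )

    sample_ids = list(dict.fromkeys(events["sample_id"]))
    type_of = dict(zip(events["sample_id"], events["cancer_type"]))
    if keep_zero_alterations:
        kept = metas
    else:
        present = set(events["alteration_id"])
        kept = [m for m in metas if m.alteration_id in present]

    inc = np.zeros((len(sample_ids), len(kept)), dtype=np.uint8)
    srow = {s: i for i, s in enumerate(sample_ids)}
    acol = {m.alteration_id: j for j, m in enumerate(kept)}
    for row in events.itertuples(index=False):
        inc[srow[row.sample_id], acol[row.alteration_id]] = 1
    return AlterationMatrix(
        inc, sample_ids, [type_of[s] for s in sample_ids], kept
    )


def write_events(matrix: AlterationMatrix, events_path, meta_path) -> None:
    """Write a matrix back to the long-format event/metadata TSV dialect."""
    rows = []
    sids = np.nonzero(matrix.incidence)
    for i, j in zip(*sids):
        m = matrix.meta[j]
        rows.append(
            (
                matrix.sample_ids[i],
                m.alteration_id,
                m.alteration_class.value,
                matrix.cancer_types[i],
            )
        )
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(
        events_path, sep="\t", index=False
    )
    meta_rows = [
        (
            m.alteration_id,
            m.alteration_class.value,
            m.chromosome if m.chromosome is not None else MISSING_CHROM,
            ";".join(sorted(m.genes)),
        )
        for m in matrix.meta
    ]
    pd.DataFrame(meta_rows, columns=META_COLUMNS).to_csv(
        meta_path, sep="\t", index=False
    )


# -- filtering --------------------------------------------------------------


def _hyper_threshold(counts: np.ndarray, multiplier: float) -> float:
    q1, q3 = np.percentile(counts, [25, 75], method="linear")
    return float(q3 + multiplier * (q3 - q1))


def filter_hypermutated(
    matrix: AlterationMatrix,
    multiplier: float = 4.5,
    scope: str = "global",
) -> tuple[AlterationMatrix, CohortFilterReport]:
    """Drop samples whose event count strictly exceeds Q3 + multiplier x IQR.

    ``scope`` is ``"global"`` (one threshold over all samples, the default) or
    ``"per_cancer_type"`` (a threshold per cohort).  Quartiles use linear
    interpolation between order statistics.  Thresholds are computed once on
    the input; they are not recomputed after exclusion.
    """
    report = CohortFilterReport(multiplier=multiplier)
    if matrix.n_samples == 0:
        return matrix, report
    counts = matrix.sample_counts()
    keep = np.ones(matrix.n_samples, dtype=bool)
    if scope == "global":
        groups = {"global": np.arange(matrix.n_samples)}
    elif scope == "per_cancer_type":
        groups = {
            t: np.nonzero(matrix.sample_mask(t))[0]
            for t in matrix.cancer_type_labels()
        }
    else:
        raise ValueError(f"unknown scope {scope!r}")
    for label, idx in groups.items():
        if len(idx) < 4:
            warnings.warn(
                f"scope {label!r} has fewer than 4 samples; "
                "hyper-altered filtering skipped",
                stacklevel=2,
            )
            continue
        thr = _hyper_threshold(counts[idx], multiplier)
        report.thresholds[label] = thr
        over = idx[counts[idx] > thr]
        keep[over] = False
        for i in over:
            report.excluded_hyper_samples.append(
                {
                    "sample_id": matrix.sample_ids[i],
                    "event_count": int(counts[i]),
                    "threshold": thr,
                    "scope": label,
                }
            )
    filtered = matrix.subset(sample_idx=np.nonzero(keep)[0])
    return filtered, report


def recurrence_threshold(n_samples: int, min_frequency: float = 0.02) -> int:
    """Minimum altered-sample count: ``ceil(min_frequency * n)``."""
    return math.ceil(min_frequency * n_samples)


def filter_recurrent(
    matrix: AlterationMatrix,
    min_frequency: float = 0.02,
    scope: str = PAN,
) -> AlterationMatrix:
    """Restrict to scope samples and alterations recurrent within the scope."""
    if not 0 < min_frequency <= 1:
        raise ValueError("min_frequency must be in (0, 1]")
    scoped = matrix.restrict_scope(scope)
    thr = recurrence_threshold(scoped.n_samples, min_frequency)
    counts = scoped.alteration_counts(PAN)
    return scoped.subset(alt_idx=np.nonzero(counts >= thr)[0])


def eligible_pairs(matrix: AlterationMatrix) -> list[tuple[str, str]]:
    """All unordered alteration pairs except same-chromosome CNA-CNA pairs.

    Mutation and methylation events are never excluded by location; only a
    pair of copy-number alterations (gain or loss) on one chromosome is
    dropped, to avoid linkage confounding.
    """
    metas = matrix.meta
    for m in metas:
        if m.alteration_class.is_cna and not m.chromosome:
            raise ValueError(f"CNA {m.alteration_id!r} lacks a chromosome")
    pairs = []
    for j in range(len(metas)):
        for k in range(j + 1, len(metas)):
            a, b = metas[j], metas[k]
            if (
                a.alteration_class.is_cna
                and b.alteration_class.is_cna
                and a.chromosome == b.chromosome
            ):
                continue
            pairs.append((a.alteration_id, b.alteration_id))
    return pairs


def pair_key(a: str, b: str) -> tuple[str, str]:
    """Canonical (sorted) form of an unordered pair."""
    return (a, b) if a <= b else (b, a)
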