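"""Down-sampling (saturation) curves for interaction discovery.

Three modes estimate how the number of detected interactions grows with
cohort size: adding samples within one cancer type (step 10), adding
samples to the pan-cancer cohort proportionally across types (step 100),
and adding whole cancer types in random orders.  Recurrence filtering is
recomputed inside every subsample — the 2% rule always refers to the
samples under consideration — and within a replicate the subsets are
nested (each size extends the previous draw), which reduces replicate
variance.  The final point of every curve is the full cohort in its
original order, so with a shared permutation seed it reproduces the full
analysis exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import PAN, AlterationMatrix
from .interaction import detect_interactions
from .permutation import PermutationPlan

WITHIN_TYPE = "within_type"
PAN_SAMPLES = "pan_samples"
PAN_TYPES = "pan_types"


@dataclass
class SaturationCurve:
    mode: str
    points: list[tuple[int, int, int]] = field(default_factory=list)
    # (subset size or number of types, replicate id, n detected)

    def add(self, size: int, replicate: int, n_detected: int) -> None:
        self.points.append((size, replicate, n_detected))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.points, columns=["size", "replicate", "n_detected"]
        ).assign(mode=self.mode)

    def mean_curve(self) -> pd.Series:
        df = self.to_frame()
        return df.groupby("size")["n_detected"].mean()

    def final_points(self) -> list[int]:
        last = max(s for s, _, _ in self.points)
        return [n for s, _, n in self.points if s == last]


def _sizes(step: int, total: int, start: int | None = None) -> list[int]:
    start = step if start is None else start
    sizes = list(range(start, total + 1, step))
    if not sizes or sizes[-1] != total:
        sizes.append(total)
    return sizes


def _detect_count(
    matrix: AlterationMatrix,
    plan: PermutationPlan,
    scope: str,
    threshold: float,
    min_frequency: float,
) -> int:
    network = detect_interactions(
        matrix, plan, scope=scope, threshold=threshold,
        min_frequency=min_frequency,
    )
    return len(network.edges)


def saturation_within_type(
    matrix: AlterationMatrix,
    cancer_type: str,
    plan: PermutationPlan,
    step: int = 10,
    reps: int = 10,
    threshold: float = 0.1,
    min_frequency: float = 0.02,
    nested: bool = True,
) -> SaturationCurve:
    """Detected-interaction counts over growing subsamples of one type."""
    idx = np.nonzero(matrix.sample_mask(cancer_type))[0]
    if len(idx) < step:
        raise ValueError(f"{cancer_type!r} has fewer than {step} samples")
    curve = SaturationCurve(WITHIN_TYPE)
    for rep in range(reps):
        rng = np.random.default_rng(
            np.random.SeedSequence([plan.seed & 0x7FFFFFFF, 101, rep])
        )
        order = rng.permutation(idx)
        for size in _sizes(step, len(idx)):
            if not nested:
                order = rng.permutation(idx)
            chosen = np.sort(order[:size])
            sub = matrix.subset(sample_idx=chosen)
            curve.add(
                size,
                rep,
                _detect_count(sub, plan, cancer_type, threshold, min_frequency),
            )
    return curve


def _proportional_quota(n_by_type: np.ndarray, size: int) -> np.ndarray:
    """Largest-remainder apportionment of ``size`` across types."""
    total = n_by_type.sum()
    exact = n_by_type * size / total
    quota = np.floor(exact).astype(int)
    remainder = exact - quota
    short = size - quota.sum()
    for i in np.argsort(-remainder)[:short]:
        quota[i] += 1
    return np.minimum(quota, n_by_type)


def saturation_pan_samples(
    matrix: AlterationMatrix,
    plan: PermutationPlan,
    step: int = 100,
    reps: int = 10,
    cap: int = 3_000,
    threshold: float = 0.1,
    min_frequency: float = 0.02,
) -> SaturationCurve:
    """Pan-cancer curve over subsamples drawn proportionally across types."""
    types = matrix.cancer_type_labels()
    idx_by_type = [np.nonzero(matrix.sample_mask(t))[0] for t in types]
    n_by_type = np.array([len(i) for i in idx_by_type])
    total = int(n_by_type.sum())
    curve = SaturationCurve(PAN_SAMPLES)
    grid = [s for s in _sizes(step, total) if s <= cap or s == total]
    for rep in range(reps):
        rng = np.random.default_rng(
            np.random.SeedSequence([plan.seed & 0x7FFFFFFF, 102, rep])
        )
        orders = [rng.permutation(i) for i in idx_by_type]
        for size in grid:
            quota = _proportional_quota(n_by_type, size)
            chosen = np.sort(
                np.concatenate([o[:q] for o, q in zip(orders, quota)])
            )
            sub = matrix.subset(sample_idx=chosen)
            curve.add(
                int(quota.sum()),
                rep,
                _detect_count(sub, plan, PAN, threshold, min_frequency),
            )
    return curve


def plot_curve(curve: SaturationCurve, path) -> None:
    """Write a curve as SVG: per-replicate points plus the mean line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = curve.to_frame()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.scatter(df["size"], df["n_detected"], s=12, alpha=0.5, label="replicates")
    mean = curve.mean_curve()
    ax.plot(mean.index, mean.values, color="C1", label="mean")
    ax.set_xlabel(
        "number of cancer types" if curve.mode == PAN_TYPES else "subsample size"
    )
    ax.set_ylabel("detected interactions")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)


def saturation_by_type(
    matrix: AlterationMatrix,
    plan: PermutationPlan,
    n_orderings: int | None = None,
    threshold: float = 0.1,
    min_frequency: float = 0.02,
) -> SaturationCurve:
    """Pan-cancer counts as cancer types are added in random orders."""
    types = matrix.cancer_type_labels()
    if len(types) < 2:
        raise ValueError("need at least two cancer types")
    if n_orderings is None:
        n_orderings = len(types)
    ctypes = np.asarray(matrix.cancer_types)
    curve = SaturationCurve(PAN_TYPES)
    for rep in range(n_orderings):
        rng = np.random.default_rng(
            np.random.SeedSequence([plan.seed & 0x7FFFFFFF, 103, rep])
        )
        order = [types[i] for i in rng.permutation(len(types))]
        for k in range(1, len(order) + 1):
            chosen = np.sort(np.nonzero(np.isin(ctypes, order[:k]))[0])
            sub = matrix.subset(sample_idx=chosen)
            curve.add(
                k,
                rep,
                _detect_count(sub, plan, PAN, threshold, min_frequency),
            )
    return curve
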