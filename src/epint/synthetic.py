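"""Synthetic tumor cohorts with planted pairwise interactions.

The generator emulates the statistical structure the permutation null is
designed to control for: per-cancer-type cohorts of tumors with
heterogeneous per-sample alteration loads, alterations split into classes
(mutation, copy-number gain/loss, methylation), a small fraction of
hyper-altered outlier samples, and planted pairwise interactions with
specified per-type odds ratios.

Planted pairs are drawn jointly from the bivariate Bernoulli distribution
with given marginals (pA, pB) and odds ratio theta, whose both-altered
cell probability is the root of

    (theta - 1) p11^2 - [1 + (pA + pB)(theta - 1)] p11 + theta pA pB = 0

lying between max(0, pA + pB - 1) and min(pA, pB).  Per-sample load
heterogeneity is induced afterwards, by logit-space sample effects applied
to non-planted alterations only, so planted odds ratios stay analytically
exact.  A :class:`GroundTruthManifest` records the implied cell
probabilities, the planted differential pairs and the realized
frequencies, for recovery testing of every downstream stage.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    AlterationClass,
    AlterationMatrix,
    AlterationMeta,
    write_events,
)
from .enrichment import PPINetwork


def joint_bernoulli_with_or(
    p_a: float, p_b: float, theta: float
) -> tuple[float, float, float, float]:
    """Cell probabilities (p11, p10, p01, p00) with given marginals and OR.

    theta = 1 gives independence (p11 = pA pB); theta > 1 co-occurrence;
    theta < 1 mutual exclusivity.  The returned cells reproduce the
    requested marginals and odds ratio exactly (analytic construction).
    """
    if not (0 < p_a < 1 and 0 < p_b < 1):
        raise ValueError("marginals must lie in (0, 1)")
    if theta <= 0:
        raise ValueError("theta must be positive")
    if theta == 1.0:
        p11 = p_a * p_b
    else:
        a = theta - 1.0
        b = -(1.0 + (p_a + p_b) * (theta - 1.0))
        c = theta * p_a * p_b
        disc = b * b - 4.0 * a * c
        if disc < 0:
            raise ValueError("no valid root for the requested parameters")
        sq = np.sqrt(disc)
        lo, hi = max(0.0, p_a + p_b - 1.0), min(p_a, p_b)
        # the root on the correct branch is (-b - sqrt) / (2a)
        p11 = (-b - sq) / (2.0 * a)
        if not (lo - 1e-12 <= p11 <= hi + 1e-12):
            p11 = (-b + sq) / (2.0 * a)
        if not (lo - 1e-12 <= p11 <= hi + 1e-12):
            raise ValueError("no valid root for the requested parameters")
        p11 = min(max(p11, lo), hi)
    p10 = p_a - p11
    p01 = p_b - p11
    p00 = 1.0 - p_a - p_b + p11
    return (p11, p10, p01, p00)


@dataclass(frozen=True)
class AlterationSpec:
    """Declaration of one alteration in a synthetic cohort."""

    alteration_id: str
    alteration_class: AlterationClass
    frequency: float | Mapping[str, float]
    chromosome: str | None = None
    genes: tuple[str, ...] = ()

    def freq_in(self, cancer_type: str) -> float:
        if isinstance(self.frequency, Mapping):
            return float(self.frequency[cancer_type])
        return float(self.frequency)

    def meta(self) -> AlterationMeta:
        genes = self.genes or (self.alteration_id,)
        return AlterationMeta(
            alteration_id=self.alteration_id,
            alteration_class=self.alteration_class,
            chromosome=self.chromosome,
            genes=frozenset(genes),
        )


@dataclass(frozen=True)
class PlantedInteraction:
    """A pair with per-cancer-type target odds ratios.

    ``theta`` may be a scalar (same OR in every type) or a mapping from
    cancer type to OR; theta = 1 plants nothing (null), theta > 1
    co-occurrence, theta < 1 mutual exclusivity.
    """

    pair: tuple[str, str]
    theta: float | Mapping[str, float]

    def theta_in(self, cancer_type: str) -> float:
        if isinstance(self.theta, Mapping):
            return float(self.theta.get(cancer_type, 1.0))
        return float(self.theta)


@dataclass
class SyntheticSpec:
    """Full generative description of a synthetic cohort."""

    cancer_types: list[tuple[str, int]]
    alterations: list[AlterationSpec]
    planted: list[PlantedInteraction] = field(default_factory=list)
    sample_load_dispersion: float = 0.5
    hyper_fraction: float = 0.0
    # logit-scale load boost for hyper-altered outliers; +6 drives most
    # non-planted alteration probabilities toward 1, emulating a
    # hypermutator phenotype an order of magnitude above typical load
    hyper_shift: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [a.alteration_id for a in self.alterations]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate alteration ids")
        known = set(ids)
        used: set[str] = set()
        for p in self.planted:
            a, b = p.pair
            if a not in known or b not in known:
                raise ValueError(f"planted pair {p.pair} references unknown ids")
            if a in used or b in used:
                raise ValueError(
                    "an alteration may participate in at most one planted pair"
                )
            used.update(p.pair)
        for a in self.alterations:
            for t, _ in self.cancer_types:
                f = a.freq_in(t)
                if not 0 < f < 1:
                    raise ValueError(
                        f"frequency of {a.alteration_id} in {t} not in (0,1)"
                    )

    @property
    def planted_ids(self) -> set[str]:
        return {x for p in self.planted for x in p.pair}


@dataclass
class GroundTruthManifest:
    """Planted truth realized by one generated cohort."""

    cell_probabilities: dict  # pair -> type -> (p11, p10, p01, p00)
    planted_thetas: dict  # pair -> type -> theta
    differential_pairs: list  # pairs whose theta differs across types
    conserved_pairs: list  # planted non-null pairs with equal theta everywhere
    realized_frequencies: dict  # type -> alteration_id -> fraction
    hyper_samples: list
    seed: int

    def to_json(self) -> str:
        def _k(d):
            return {
                "|".join(k) if isinstance(k, tuple) else k: v
                for k, v in d.items()
            }

        return json.dumps(
            {
                "cell_probabilities": {
                    "|".join(p): v for p, v in self.cell_probabilities.items()
                },
                "planted_thetas": {
                    "|".join(p): v for p, v in self.planted_thetas.items()
                },
                "differential_pairs": [list(p) for p in self.differential_pairs],
                "conserved_pairs": [list(p) for p in self.conserved_pairs],
                "realized_frequencies": _k(self.realized_frequencies),
                "hyper_samples": self.hyper_samples,
                "seed": self.seed,
            },
            indent=2,
        )


def load_spec(path) -> SyntheticSpec:
    """Read a SyntheticSpec from a YAML or JSON config file.

    Expected layout::

        cancer_types: [[TypeA, 300], [TypeB, 300]]
        alterations:
          - {id: M01, class: mutation, frequency: 0.1, genes: [TP53]}
          - {id: G01, class: CNA_gain, frequency: 0.2, chromosome: "8",
             genes: [MYC, PVT1]}
        planted:
          - {pair: [M01, G01], theta: 8.0}       # or theta: {TypeA: 8.0}
        sample_load_dispersion: 0.5
        hyper_fraction: 0.02
        seed: 0
    """
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    alterations = [
        AlterationSpec(
            alteration_id=str(a["id"]),
            alteration_class=AlterationClass(a["class"]),
            frequency=a["frequency"],
            chromosome=str(a["chromosome"]) if a.get("chromosome") else None,
            genes=tuple(a.get("genes", ())),
        )
        for a in data["alterations"]
    ]
    planted = [
        PlantedInteraction(pair=tuple(p["pair"]), theta=p["theta"])
        for p in data.get("planted", [])
    ]
    return SyntheticSpec(
        cancer_types=[(str(t), int(n)) for t, n in data["cancer_types"]],
        alterations=alterations,
        planted=planted,
        sample_load_dispersion=float(data.get("sample_load_dispersion", 0.5)),
        hyper_fraction=float(data.get("hyper_fraction", 0.0)),
        hyper_shift=float(data.get("hyper_shift", 6.0)),
        seed=int(data.get("seed", 0)),
    )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def generate_matrix(
    spec: SyntheticSpec,
) -> tuple[AlterationMatrix, GroundTruthManifest]:
    """Draw one cohort; returns the incidence matrix and its ground truth."""
    rng = np.random.default_rng(spec.seed)
    metas = [a.meta() for a in spec.alterations]
    for p in spec.planted:
        ma = next(m for m in metas if m.alteration_id == p.pair[0])
        mb = next(m for m in metas if m.alteration_id == p.pair[1])
        if (
            ma.alteration_class.is_cna
            and mb.alteration_class.is_cna
            and ma.chromosome == mb.chromosome
        ):
            warnings.warn(
                f"planted pair {p.pair} is a same-chromosome CNA pair and "
                "will be excluded from testing downstream",
                stacklevel=2,
            )
    col = {a.alteration_id: j for j, a in enumerate(spec.alterations)}
    planted_ids = spec.planted_ids

    sample_ids: list[str] = []
    ctype_labels: list[str] = []
    rows: list[np.ndarray] = []
    hyper_samples: list[str] = []
    cellp: dict = {p.pair: {} for p in spec.planted}
    thetas: dict = {p.pair: {} for p in spec.planted}

    for t, n_t in spec.cancer_types:
        inc = np.zeros((n_t, len(spec.alterations)), dtype=np.uint8)
        # per-sample load effects (logit scale), hyper outliers inflated
        u = rng.normal(0.0, spec.sample_load_dispersion, size=n_t)
        n_hyper = int(round(spec.hyper_fraction * n_t))
        hyper_idx = rng.choice(n_t, size=n_hyper, replace=False)
        u[hyper_idx] += spec.hyper_shift
        # planted pairs: joint draw with exact marginals and OR
        for p in spec.planted:
            sa = next(
                a for a in spec.alterations if a.alteration_id == p.pair[0]
            )
            sb = next(
                a for a in spec.alterations if a.alteration_id == p.pair[1]
            )
            th = p.theta_in(t)
            cells = joint_bernoulli_with_or(sa.freq_in(t), sb.freq_in(t), th)
            cellp[p.pair][t] = cells
            thetas[p.pair][t] = th
            draw = rng.choice(4, size=n_t, p=cells)
            inc[:, col[p.pair[0]]] = (draw == 0) | (draw == 1)
            inc[:, col[p.pair[1]]] = (draw == 0) | (draw == 2)
        # independent alterations with load heterogeneity
        for a in spec.alterations:
            if a.alteration_id in planted_ids:
                continue
            prob = _sigmoid(_logit(a.freq_in(t)) + u)
            inc[:, col[a.alteration_id]] = rng.random(n_t) < prob
        ids = [f"{t}_s{i:04d}" for i in range(n_t)]
        sample_ids.extend(ids)
        ctype_labels.extend([t] * n_t)
        hyper_samples.extend(ids[i] for i in sorted(hyper_idx))
        rows.append(inc)

    incidence = np.vstack(rows) if rows else np.zeros((0, len(metas)), np.uint8)
    matrix = AlterationMatrix(incidence, sample_ids, ctype_labels, metas)

    realized = {}
    for t, _ in spec.cancer_types:
        mask = matrix.sample_mask(t)
        n_t = int(mask.sum())
        counts = matrix.incidence[mask].sum(axis=0)
        realized[t] = {
            m.alteration_id: counts[j] / n_t for j, m in enumerate(metas)
        }
    differential = [
        p.pair
        for p in spec.planted
        if len({round(p.theta_in(t), 12) for t, _ in spec.cancer_types}) > 1
    ]
    conserved = [
        p.pair
        for p in spec.planted
        if p.pair not in differential
        and any(p.theta_in(t) != 1.0 for t, _ in spec.cancer_types)
    ]
    manifest = GroundTruthManifest(
        cell_probabilities=cellp,
        planted_thetas=thetas,
        differential_pairs=differential,
        conserved_pairs=conserved,
        realized_frequencies=realized,
        hyper_samples=hyper_samples,
        seed=spec.seed,
    )
    return matrix, manifest


def generate_cohort(
    spec: SyntheticSpec, events_path=None, meta_path=None
) -> tuple[AlterationMatrix, GroundTruthManifest]:
    """Generate a cohort, optionally writing the event/metadata TSVs.

    The long event format only lists samples carrying at least one event;
    the returned matrix keeps all samples.
    """
    matrix, manifest = generate_matrix(spec)
    if events_path is not None and meta_path is not None:
        write_events(matrix, events_path, meta_path)
    return matrix, manifest


def generate_ppi(
    spec: SyntheticSpec,
    background_density: float = 0.01,
    guarantee_planted: bool = True,
    rng: np.random.Generator | int | None = None,
) -> PPINetwork:
    """Erdos-Renyi gene network, optionally guaranteeing planted cross edges."""
    if not 0 <= background_density <= 1:
        raise ValueError("density must lie in [0, 1]")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(spec.seed if rng is None else int(rng))
    genes = sorted({g for a in spec.alterations for g in (a.genes or (a.alteration_id,))})
    edges: set[tuple[str, str]] = set()
    if background_density > 0:
        for i, g in enumerate(genes):
            for h in genes[i + 1 :]:
                if rng.random() < background_density:
                    edges.add((g, h))
    if guarantee_planted:
        by_id = {a.alteration_id: a for a in spec.alterations}
        for p in spec.planted:
            ga = sorted(by_id[p.pair[0]].genes or (p.pair[0],))
            gb = sorted(by_id[p.pair[1]].genes or (p.pair[1],))
            edges.add(tuple(sorted((ga[0], gb[0]))))
    return PPINetwork.from_pairs(edges, source_label="synthetic")


def generate_expression(
    spec: SyntheticSpec,
    matrix: AlterationMatrix,
    shifts: Mapping[tuple[str, str], float],
    noise_sd: float = 1.0,
    baseline: float = 8.0,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Log2 expression: Gaussian baseline, shifted in CNA-altered samples.

    ``shifts`` maps (region alteration_id, gene) to a log2 shift added to
    that gene in samples altered for the region.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(spec.seed if rng is None else int(rng))
    genes = sorted({g for a in spec.alterations for g in (a.genes or (a.alteration_id,))})
    expr = baseline + rng.normal(
        0.0, noise_sd, size=(matrix.n_samples, len(genes))
    )
    gcol = {g: j for j, g in enumerate(genes)}
    for (region, gene), shift in shifts.items():
        j = matrix.alteration_loc(region)
        if gene not in matrix.meta[j].genes:
            raise ValueError(f"gene {gene!r} not in region {region!r}")
        altered = matrix.incidence[:, j].astype(bool)
        expr[altered, gcol[gene]] += shift
    return pd.DataFrame(expr, index=matrix.sample_ids, columns=genes)
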